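"""Structure, sequence, trajectory and configuration I/O.

PDB is the only structure interchange format.  Reading reduces an all-atom
or bead file to the bead representation (Calpha / Cbeta for protein
residues; P, N1 and a base-centroid site per nucleotide); writing emits
fixed-column ATOM records that round-trip losslessly at PDB coordinate
precision.  Trajectories are stored as one ``.npz`` per run with
coordinates in single precision, energies and the walker table, plus a PDB
escape hatch for any frame.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import (
    BeadStructure,
    DuplexSpec,
    Ensemble,
    Frame,
    ReplicaLadder,
    Site,
    ladder_from_dict,
    ladder_to_dict,
    structure_from_dict,
    structure_to_dict,
    validate_duplex,
)

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_fasta",
    "save_ensemble",
    "load_ensemble",
    "frame_to_pdb",
    "load_config",
    "dump_config",
]

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_DNA_RES = {"DA", "DT", "DG", "DC", "A", "T", "G", "C"}
_AA_CHARGE = {"LYS": 1.0, "ARG": 1.0, "ASP": -1.0, "GLU": -1.0}

# bead name <-> PDB atom name used by the writer
_ATOM_NAME = {"CA": "CA", "CB": "CB", "P": "P", "N1": "N1",
              "BASE": "BAS", "DUMMY": "DUM"}
_NAME_ATOM = {v: k for k, v in _ATOM_NAME.items()}

_SITE_DEFAULTS = {  # name -> (radius, mass)
    "CA": (1.6, 110.0),
    "CB": (1.6, 50.0),
    "P": (1.6, 95.0),
    "N1": (1.5, 40.0),
    "BASE": (2.0, 100.0),
    "DUMMY": (0.1, 0.0),
}

_BACKBONE_DNA = {"P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'",
                 "C3'", "O3'", "C2'", "C1'", "O2'"}


def _site_charge(resname: str, name: str) -> float:
    if name == "P":
        return -1.0
    if name == "CA":
        return _AA_CHARGE.get(resname, 0.0)
    return 0.0


def read_pdb(path: str | Path) -> BeadStructure:
    """Parse a PDB file into the bead representation.

    All-atom protein residues reduce to their CA (and CB) atoms; all-atom
    nucleotides to P, N1 and the centroid of their base (non-sugar,
    non-phosphate) atoms.  Files written by :func:`write_pdb` round-trip
    exactly.  Malformed ATOM records raise with the line number.
    """
    from Bio.PDB import PDBParser
    import warnings as _w

    path = Path(path)
    _validate_atom_records(path)
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("x", str(path))

    sites: list[Site] = []
    coords: list[np.ndarray] = []
    prot_chains: list[str] = []
    dna_chains: list[str] = []

    model = next(iter(structure))
    for chain in model:
        cid = chain.id.strip() or "A"
        for res in chain:
            resname = res.get_resname().strip()
            atoms = {a.get_name().strip(): a for a in res}
            rid = res.get_id()[1]
            is_bead_file = set(atoms) <= set(_NAME_ATOM) | {"CA", "CB", "P", "N1"}

            if resname in _AA3 or ("CA" in atoms and resname not in _DNA_RES):
                if cid not in prot_chains:
                    prot_chains.append(cid)
                for an in ("CA", "CB"):
                    if an in atoms:
                        _append_site(sites, coords, cid, rid, resname, an,
                                     atoms[an].get_coord())
                for an in ("BAS", "DUM"):
                    if an in atoms:
                        _append_site(sites, coords, cid, rid, resname,
                                     _NAME_ATOM[an], atoms[an].get_coord())
            elif resname in _DNA_RES or {"P", "N1"} & set(atoms):
                if cid not in dna_chains:
                    dna_chains.append(cid)
                for an in ("P", "N1"):
                    if an in atoms:
                        _append_site(sites, coords, cid, rid, resname, an,
                                     atoms[an].get_coord())
                if "BAS" in atoms:
                    _append_site(sites, coords, cid, rid, resname, "BASE",
                                 atoms["BAS"].get_coord())
                elif not is_bead_file:
                    base_atoms = [
                        a.get_coord()
                        for an, a in atoms.items()
                        if an not in _BACKBONE_DNA and not an.startswith("H")
                    ]
                    if base_atoms:
                        _append_site(sites, coords, cid, rid, resname, "BASE",
                                     np.mean(base_atoms, axis=0))
                if "DUM" in atoms:
                    _append_site(sites, coords, cid, rid, resname, "DUMMY",
                                 atoms["DUM"].get_coord())
    if not sites:
        raise ValueError(f"{path}: no recognizable sites (need CA/CB/P/N1)")

    molecules: dict[str, list[str]] = {}
    if prot_chains:
        molecules["protein"] = prot_chains
    if dna_chains:
        molecules["dna"] = dna_chains

    out = BeadStructure(sites, np.asarray(coords), molecules=molecules)
    # re-tie dummies to the N1 of their own residue
    for i, s in enumerate(out.sites):
        if s.name == "DUMMY" and out.has_site(s.chain, s.residue_index, "N1"):
            out.dummy_parent[i] = out.index_of(s.chain, s.residue_index, "N1")
    return out


def _append_site(sites, coords, cid, rid, resname, name, xyz) -> None:
    radius, mass = _SITE_DEFAULTS.get(name, (2.0, 100.0))
    sites.append(
        Site(cid, rid, resname, name, _site_charge(resname, name), radius, mass)
    )
    coords.append(np.asarray(xyz, dtype=float))


def _validate_atom_records(path: Path) -> None:
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise ValueError(f"{path}:{ln}: truncated ATOM record")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError:
                raise ValueError(
                    f"{path}:{ln}: malformed coordinates in ATOM record"
                ) from None


def write_pdb(structure: BeadStructure, path: str | Path) -> None:
    """Write the bead structure as fixed-column PDB ATOM records."""
    path = Path(path)
    lines = []
    serial = 0
    last_chain = None
    for i, s in enumerate(structure.sites):
        if last_chain is not None and s.chain != last_chain:
            lines.append("TER")
        last_chain = s.chain
        serial += 1
        x, y, z = structure.coords[i]
        name = _ATOM_NAME[s.name] if s.name in _ATOM_NAME else s.name[:4]
        lines.append(
            f"ATOM  {serial:5d} {name:^4s}{s.residue_name:>4s} "
            f"{s.chain[:1]}{s.residue_index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> list[DuplexSpec]:
    """Read duplex specs from FASTA (header becomes the label)."""
    from Bio import SeqIO

    path = Path(path)
    specs = [
        validate_duplex(DuplexSpec(str(rec.seq).upper(), label=rec.id))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not specs:
        raise ValueError(f"{path}: empty or not FASTA")
    return specs


# ---------------------------------------------------------------------------
# Trajectory store
# ---------------------------------------------------------------------------


def save_ensemble(
    ensemble: Ensemble, structure: BeadStructure, path: str | Path
) -> None:
    """One-file-per-run store: coordinates (single precision), energies,
    walker table, ladder and structure metadata."""
    path = Path(path)
    frames = ensemble.frames
    np.savez_compressed(
        path,
        replica=np.asarray([f.replica for f in frames], dtype=np.int32),
        round_index=np.asarray([f.round_index for f in frames], dtype=np.int32),
        walker=np.asarray([f.walker for f in frames], dtype=np.int32),
        coords=np.asarray([f.coords for f in frames], dtype=np.float32),
        potential_energy=np.asarray(
            [f.potential_energy for f in frames], dtype=np.float64
        ),
        restraint_energy=np.asarray(
            [f.restraint_energy for f in frames], dtype=np.float64
        ),
        ladder_json=np.asarray(json.dumps(ladder_to_dict(ensemble.ladder))),
        structure_json=np.asarray(json.dumps(structure_to_dict(structure))),
    )


def load_ensemble(path: str | Path) -> tuple[Ensemble, BeadStructure]:
    with np.load(Path(path), allow_pickle=False) as z:
        ladder = ladder_from_dict(json.loads(str(z["ladder_json"])))
        structure = structure_from_dict(json.loads(str(z["structure_json"])))
        frames = [
            Frame(
                replica=int(z["replica"][k]),
                round_index=int(z["round_index"][k]),
                walker=int(z["walker"][k]),
                coords=z["coords"][k],
                potential_energy=float(z["potential_energy"][k]),
                restraint_energy=float(z["restraint_energy"][k]),
            )
            for k in range(len(z["replica"]))
        ]
    return Ensemble(frames=frames, ladder=ladder).validate(), structure


def frame_to_pdb(
    ensemble: Ensemble,
    structure: BeadStructure,
    frame_index: int,
    path: str | Path,
) -> None:
    """Export one stored frame as PDB."""
    s = structure.copy()
    s.coords = ensemble.frames[frame_index].coords.astype(float)
    write_pdb(s, path)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_DEFAULTS: dict[str, object] = {
    "seed": 0,
    "sequence": None,
    "protein": "fixture:clamp",
    "binding_residues": None,
    "n_replicas": 8,
    "t_min": 1.0,
    "t_max": 3.0,
    "n_rounds": 100,
    "steps_per_round": 50,
    "active_fraction": 0.5,
    "prune_radius": 20.0,
    "protocol": 1,
    "screening_length": 10.0,
    "cluster_cutoff": 3.0,
    "bound_cutoff": 8.0,
    "duplex_separation": 60.0,
    "swap_prob": 0.1,
    "freeze": None,
}

_CONFIG_TYPES: dict[str, tuple] = {
    "seed": (int,),
    "n_replicas": (int,),
    "n_rounds": (int,),
    "steps_per_round": (int,),
    "protocol": (int,),
    "t_min": (int, float),
    "t_max": (int, float),
    "active_fraction": (int, float),
    "prune_radius": (int, float),
    "screening_length": (int, float),
    "cluster_cutoff": (int, float),
    "bound_cutoff": (int, float),
    "duplex_separation": (int, float),
    "swap_prob": (int, float),
}


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON run config, apply defaults, validate field types.

    Violations raise ``ValueError`` naming the offending field path.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config: top level must be a mapping")
    cfg = dict(_CONFIG_DEFAULTS)
    for key, value in raw.items():
        if key not in _CONFIG_DEFAULTS:
            raise ValueError(f"config.{key}: unknown field")
        cfg[key] = value
    for key, types in _CONFIG_TYPES.items():
        v = cfg[key]
        if v is not None and not isinstance(v, types):
            raise ValueError(
                f"config.{key}: expected {'/'.join(t.__name__ for t in types)},"
                f" got {type(v).__name__}"
            )
    if cfg["binding_residues"] is not None:
        br = cfg["binding_residues"]
        if not isinstance(br, list):
            raise ValueError("config.binding_residues: expected a list")
        for k, item in enumerate(br):
            if not (isinstance(item, (list, tuple)) and len(item) == 2):
                raise ValueError(
                    f"config.binding_residues[{k}]: expected [chain, resid]"
                )
        cfg["binding_residues"] = [(str(c), int(r)) for c, r in br]
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    """Echo the resolved config (defaults applied, seed included)."""
    import yaml

    out = dict(cfg)
    if out.get("binding_residues"):
        out["binding_residues"] = [list(t) for t in out["binding_residues"]]
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))
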