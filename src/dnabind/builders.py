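"""System and data construction: idealized B-DNA, dummy sites, the three
data protocols, scaffold restraints, and unbound / competitive assemblies.

Data protocols
--------------
1.  *General binding*: every binding-domain Calpha is ambiguously paired
    with a dummy site riding on each purine N1 — one group per residue,
    one contact active per group, and only a fraction of the groups
    enforced at a time.  Dummies sit on the helix axis side of the bases,
    so neither groove orientation is favored.
2.  *Known binding mode along an oligomer*: binding-domain Cbeta sites are
    combinatorially paired with every backbone phosphate, which lets one
    binding mode register at repeated sites along the sequence.
3.  *Competitive binding*: the known-binding-mode data are duplicated onto
    two co-simulated duplexes under an OR-selection, with a separation
    restraint keeping the duplexes from interacting directly.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .model import (
    BeadStructure,
    DuplexSpec,
    FlatBottomRestraint,
    PURINES,
    RestraintCollection,
    RestraintGroup,
    Site,
    merge_structures,
    validate_duplex,
)

__all__ = [
    "build_bdna",
    "place_dummy_sites",
    "protocol1_data",
    "protocol2_data",
    "scaffold_restraints",
    "assemble_unbound",
    "competitive_system",
    "positional_freeze",
    "DEFAULT_DATA_BOUNDS",
]

# Helical placement of the bead sites (radius in angstrom, phase in degrees
# relative to the base-pair azimuth; sign flips for strand 2).  Values give
# standard B-form backbone radius and an N1-N1 pair distance of ~3.4 A.
_P_RADIUS, _P_PHASE = 8.9, 77.0
_N1_RADIUS, _N1_PHASE = 4.0, 22.0  # chord 8*sin(22 deg) ~ 3.0 A between paired N1
_BASE_RADIUS, _BASE_PHASE = 2.5, 12.0

# data-contact flat-bottom window (r1, r2, r3, r4) in angstrom: satisfied
# out to 6 A, harmonic to 8 A, linear beyond — makes the 5 A heavy-atom
# contact criterion reachable without steric collapse
DEFAULT_DATA_BOUNDS = (0.0, 0.0, 6.0, 8.0)

_BASE_PAIR_BOUNDS = (0.0, 0.0, 3.2, 3.6)

_AA_CHARGE = {"LYS": 1.0, "ARG": 1.0, "ASP": -1.0, "GLU": -1.0, "HIS": 0.0}


def _helix_point(radius: float, azimuth_deg: float, z: float) -> np.ndarray:
    a = math.radians(azimuth_deg)
    return np.array([radius * math.cos(a), radius * math.sin(a), z])


def build_bdna(
    spec: DuplexSpec,
    rise: float = 3.38,
    twist: float = 36.0,
    chain_ids: tuple[str, str] = ("D", "E"),
) -> BeadStructure:
    """Idealized B-form duplex as P / N1 / BASE beads on a helix (axis = z).

    Strand 1 runs 5'->3' with base pair ``i`` (0-based) at azimuth
    ``i * twist`` and height ``i * rise``; strand 2 is stored 5'->3' with
    residue ``j`` pairing strand-1 residue ``n - j + 1``.  Phosphates carry
    -1 e (the repeating charged backbone); bases are neutral.
    """
    spec = validate_duplex(spec)
    n = spec.n_bp
    sites: list[Site] = []
    coords: list[np.ndarray] = []

    def add(chain, resid, resname, name, pos, charge, radius, mass):
        sites.append(Site(chain, resid, resname, name, charge, radius, mass))
        coords.append(pos)

    for strand, (chain, seq) in enumerate(
        zip(chain_ids, (spec.sequence, spec.complement))
    ):
        sign = 1.0 if strand == 0 else -1.0
        for j, base in enumerate(seq, start=1):
            i = (j - 1) if strand == 0 else (n - j)  # base-pair index
            theta = i * twist
            z = i * rise
            resname = "D" + base
            add(chain, j, resname, "P",
                _helix_point(_P_RADIUS, theta + sign * _P_PHASE, z), -1.0, 1.6, 95.0)
            add(chain, j, resname, "N1",
                _helix_point(_N1_RADIUS, theta + sign * _N1_PHASE, z), 0.0, 1.5, 40.0)
            add(chain, j, resname, "BASE",
                _helix_point(_BASE_RADIUS, theta + sign * _BASE_PHASE, z), 0.0, 2.0, 100.0)

    duplex = BeadStructure(
        sites,
        np.asarray(coords),
        molecules={spec.label: list(chain_ids)},
        is_duplex=True,
    )
    return duplex


def place_dummy_sites(dna: BeadStructure) -> BeadStructure:
    """Add massless, chargeless DUMMY sites coincident with purine N1 atoms.

    Dummies are ghosts for all non-bonded terms; they exist only as
    restraint endpoints and ride rigidly on their parent N1.
    """
    if dna.dummy_parent:
        raise ValueError("structure already has dummy sites")
    # insert each DUMMY at the end of its own residue block so site order
    # survives PDB round trips (readers group atoms by residue)
    sites: list[Site] = []
    coords: list[np.ndarray] = []
    dummy_parent: dict[int, int] = {}

    def flush_residue(block: list[tuple[Site, np.ndarray]]) -> None:
        n1_local = None
        for s, xyz in block:
            sites.append(s)
            coords.append(xyz)
            if s.name == "N1" and s.residue_name[-1] in PURINES:
                n1_local = len(sites) - 1
        if n1_local is not None:
            s = sites[n1_local]
            sites.append(
                Site(s.chain, s.residue_index, s.residue_name, "DUMMY",
                     0.0, 0.1, 0.0)
            )
            coords.append(coords[n1_local])
            dummy_parent[len(sites) - 1] = n1_local

    block: list[tuple[Site, np.ndarray]] = []
    current: tuple[str, int] | None = None
    for s, xyz in zip(dna.sites, dna.coords):
        key = (s.chain, s.residue_index)
        if current is not None and key != current:
            flush_residue(block)
            block = []
        current = key
        block.append((s, xyz))
    if block:
        flush_residue(block)
    return BeadStructure(
        sites,
        np.asarray(coords),
        molecules=dna.molecules,
        is_duplex=dna.is_duplex,
        dummy_parent=dummy_parent,
    )


def _ca_key(protein: BeadStructure, res: tuple[str, int]) -> tuple[str, int, str]:
    return (res[0], res[1], "CA")


def protocol1_data(
    protein: BeadStructure,
    binding_residues: list[tuple[str, int]],
    dna: BeadStructure,
    prune_radius: float = 20.0,
    active_fraction: float = 0.5,
    bounds: tuple[float, float, float, float] = DEFAULT_DATA_BOUNDS,
    k: float = 1.0,
) -> RestraintCollection:
    """Ambiguous Calpha-to-purine-dummy contact data (general binding).

    One group per binding residue with one restraint to every dummy site
    and ``n_active = 1``; the collection activates
    ``ceil(active_fraction * n_groups)`` groups.  Residue pairs whose
    bound-state Calpha separation exceeds ``prune_radius`` cannot plausibly
    touch the same base, so their shared-dummy pick combinations go on the
    collection's exclusion list.
    """
    if not binding_residues:
        raise ValueError("binding_residues must be non-empty")
    dummy_sites = [
        s.key() for s in dna.sites if s.name == "DUMMY"
    ]
    if not dummy_sites:
        raise ValueError("DNA has no dummy sites; call place_dummy_sites first")
    groups = []
    for res in binding_residues:
        ca = _ca_key(protein, res)
        protein.index_of(*ca)  # raise early on a bad residue
        groups.append(
            RestraintGroup(
                [FlatBottomRestraint(ca, d, *bounds, k=k) for d in dummy_sites],
                n_active=1,
            )
        )
    n_active_groups = max(1, math.ceil(active_fraction * len(groups)))

    exclusions: list[tuple[tuple[int, int], tuple[int, int]]] = []
    if np.isfinite(prune_radius):
        ca_xyz = np.asarray(
            [protein.coords[protein.index_of(*_ca_key(protein, r))] for r in binding_residues]
        )
        for a in range(len(binding_residues)):
            for b in range(a + 1, len(binding_residues)):
                if np.linalg.norm(ca_xyz[a] - ca_xyz[b]) > prune_radius:
                    exclusions.extend(
                        ((a, d), (b, d)) for d in range(len(dummy_sites))
                    )
    return RestraintCollection(
        groups, n_active_groups, label="data", exclusions=exclusions
    )


def protocol2_data(
    protein: BeadStructure,
    binding_residues: list[tuple[str, int]],
    dna: BeadStructure,
    active_fraction: float = 0.5,
    bounds: tuple[float, float, float, float] = DEFAULT_DATA_BOUNDS,
    k: float = 1.0,
) -> RestraintCollection:
    """Combinatorial Cbeta-phosphate pairing (known-mode, repeated sites).

    Glycine has no Cbeta; such residues fall back to Calpha with a warning.
    No phosphate is masked, so one binding mode can register at every
    repeat along the oligomer.
    """
    if not binding_residues:
        raise ValueError("binding_residues must be non-empty")
    p_sites = [s.key() for s in dna.sites if s.name == "P"]
    if not p_sites:
        raise ValueError("DNA has no P sites")
    groups = []
    for res in binding_residues:
        key = (res[0], res[1], "CB")
        if not protein.has_site(*key):
            warnings.warn(
                f"residue {res} has no CB site (glycine?); using CA",
                stacklevel=2,
            )
            key = _ca_key(protein, res)
        groups.append(
            RestraintGroup(
                [FlatBottomRestraint(key, p, *bounds, k=k) for p in p_sites],
                n_active=1,
            )
        )
    n_active_groups = max(1, math.ceil(active_fraction * len(groups)))
    return RestraintCollection(groups, n_active_groups, label="data")


def scaffold_restraints(
    protein: BeadStructure,
    dna: BeadStructure | None = None,
    contact_cutoff: float = 8.0,
    min_sequence_separation: int = 3,
    k_protein: float = 2.0,
    k_dna: float = 5.0,
) -> list[RestraintCollection]:
    """Restraints that keep both molecules folded at high temperature.

    (a) protein native contacts: every Calpha pair within ``contact_cutoff``
    in the supplied (bound) conformation and at least
    ``min_sequence_separation`` apart in sequence gets a flat-bottom window
    of +/-1 A about its bound-state distance, all simultaneously active
    (this covers helical i,i+4 contacts, so secondary structure is held
    without torsion terms); (b) one restraint per DNA base pair between the
    paired N1 sites, holding the hydrogen-bonded register so the duplex
    cannot melt.
    """
    out: list[RestraintCollection] = []
    ca = [(s, i) for i, s in enumerate(protein.sites) if s.name == "CA"]
    contacts: list[FlatBottomRestraint] = []
    for a in range(len(ca)):
        for b in range(a + 1, len(ca)):
            sa, ia = ca[a]
            sb, ib = ca[b]
            if sa.chain == sb.chain and abs(sa.residue_index - sb.residue_index) < min_sequence_separation:
                continue
            d0 = float(np.linalg.norm(protein.coords[ia] - protein.coords[ib]))
            if d0 <= contact_cutoff:
                contacts.append(
                    FlatBottomRestraint(
                        sa.key(), sb.key(),
                        max(0.0, d0 - 1.0), max(0.0, d0 - 0.5),
                        d0 + 0.5, d0 + 1.0, k=k_protein,
                    )
                )
    if contacts:
        out.append(
            RestraintCollection(
                [RestraintGroup(contacts, n_active=len(contacts))],
                n_active_groups=1,
                label="scaffold",
            )
        )
    if dna is not None:
        out.extend(_base_pair_collections(dna, k_dna))
    return out


def _base_pair_collections(dna: BeadStructure, k: float) -> list[RestraintCollection]:
    # chains carrying N1 sites are DNA strands; pair them consecutively
    # in storage order (each duplex contributes its two strands together)
    chains = [
        c
        for c in dna.chain_ids()
        if any(s.chain == c and s.name == "N1" for s in dna.sites)
    ]
    if dna.is_duplex:
        duplexes = [chains]
    else:
        duplexes = [chains[i : i + 2] for i in range(0, len(chains) - 1, 2)]
    out = []
    for c1, c2 in duplexes:
        n = len(dna.residues(c1))
        pairs = [
            FlatBottomRestraint(
                (c1, i, "N1"), (c2, n - i + 1, "N1"), *_BASE_PAIR_BOUNDS, k=k
            )
            for i in range(1, n + 1)
        ]
        out.append(
            RestraintCollection(
                [RestraintGroup(pairs, n_active=len(pairs))],
                n_active_groups=1,
                label="scaffold",
            )
        )
    return out


def _min_intermolecular_distance(
    xa: np.ndarray, xb: np.ndarray
) -> float:
    from scipy.spatial.distance import cdist

    return float(cdist(xa, xb).min())


def _place_apart(
    mobile: np.ndarray,
    fixed: np.ndarray,
    direction: np.ndarray,
    min_separation: float,
    slack: float = 2.0,
) -> np.ndarray:
    """Translate ``mobile`` along ``direction`` until the minimum distance
    to ``fixed`` lies in [min_separation, min_separation + slack]."""
    u = direction / np.linalg.norm(direction)
    c_fixed = fixed.mean(axis=0)
    c_mobile = mobile.mean(axis=0)
    span = (
        np.linalg.norm(fixed - c_fixed, axis=1).max()
        + np.linalg.norm(mobile - c_mobile, axis=1).max()
    )
    lo, hi = 0.0, span + min_separation + slack
    base = mobile - c_mobile
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        d = _min_intermolecular_distance(base + c_fixed + mid * u, fixed)
        if d < min_separation:
            lo = mid
        elif d > min_separation + slack:
            hi = mid
        else:
            break
    mid = 0.5 * (lo + hi)
    placed = base + c_fixed + mid * u
    if _min_intermolecular_distance(placed, fixed) < min_separation:
        placed = base + c_fixed + hi * u
    return placed


def assemble_unbound(
    protein: BeadStructure,
    dna: BeadStructure,
    min_separation: float = 30.0,
    seed: int = 0,
) -> BeadStructure:
    """Rigidly place the protein, randomly oriented, >= ``min_separation``
    angstrom from the DNA.  Deterministic for a given seed; the internal
    geometry of both molecules is untouched."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng)
    c = protein.coords.mean(axis=0)
    rotated = rot.apply(protein.coords - c) + c
    direction = rng.normal(size=3)
    placed = _place_apart(rotated, dna.coords, direction, min_separation)
    prot = protein.copy()
    prot.coords = placed
    return merge_structures([prot, dna], molecule_names=["protein", "dna"])


def positional_freeze(
    structure: BeadStructure,
    molecule: str,
    reference_coords: np.ndarray | None = None,
    width: float = 1.0,
    k: float = 10.0,
) -> RestraintCollection:
    """Flat-bottom positional restraints pinning a molecule's sites within
    ``width`` angstrom of reference coordinates (apo or holo freezing).

    Implemented as anchored restraints rather than fixed coordinates so the
    propagator is unchanged; the molecule can still fluctuate inside the
    flat window.
    """
    idx = structure.molecule_site_indices(molecule)
    ref = structure.coords if reference_coords is None else reference_coords
    restraints = [
        FlatBottomRestraint(
            structure.sites[i].key(), None,
            0.0, 0.0, width, width + 0.5, k=k,
            anchor=tuple(float(v) for v in ref[i]),
        )
        for i in idx
        if structure.sites[i].name != "DUMMY"
    ]
    return RestraintCollection(
        [RestraintGroup(restraints, n_active=len(restraints))],
        n_active_groups=1,
        label="scaffold",
    )


def competitive_system(
    protein: BeadStructure,
    duplexA: DuplexSpec,
    duplexB: DuplexSpec,
    data_for_binding_mode: list[tuple[tuple[str, int, str], tuple[int, int, str]]],
    duplex_separation: float = 60.0,
    min_protein_separation: float = 30.0,
    bounds: tuple[float, float, float, float] = DEFAULT_DATA_BOUNDS,
    k: float = 1.0,
    seed: int = 0,
    freeze: str | None = None,
) -> tuple[BeadStructure, list[RestraintCollection]]:
    """Protocol-3 assembly: one protein, two duplexes, OR-selected data.

    ``data_for_binding_mode`` lists the known binding mode as pairs of a
    protein site key and a DNA site *role* ``(strand, residue index, site
    name)`` with strand 0/1, so the same data apply to either duplex.  The
    returned data collection holds two duplex-specific groups (every
    binding-mode restraint in each, all active) under ``n_active_groups=1``
    — the protein satisfies the data by binding either duplex but never
    needs both.  A separation collection keeps the duplex centers near
    their initial spacing, and ``freeze='apo'`` pins both duplexes to their
    built (B-form) coordinates.

    Raises ``KeyError`` if the data reference sites absent from a duplex.
    """
    dnaA = place_dummy_sites(build_bdna(duplexA, chain_ids=("D", "E")))
    dnaB = place_dummy_sites(build_bdna(duplexB, chain_ids=("F", "G")))
    dnaA.molecules = {"duplexA": ["D", "E"]}
    dnaB.molecules = {"duplexB": ["F", "G"]}
    # Place the duplexes as exact images under a two-fold rotation about the
    # lab y axis: A centered at (-sep/2, 0, 0), B = C2y(A-placed frame).
    # The C2 symmetry is what makes the sampler's partner-swap move an
    # energy-preserving map for self-competition.
    dnaA = dnaA.copy()
    dnaB = dnaB.copy()
    offset = np.array([-duplex_separation / 2.0, 0.0, 0.0])
    dnaA.coords = dnaA.coords - dnaA.coords.mean(axis=0) + offset
    placedB = dnaB.coords - dnaB.coords.mean(axis=0) + offset
    dnaB.coords = placedB * np.array([-1.0, 1.0, -1.0])  # pi about y

    rng = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation

    c = protein.coords.mean(axis=0)
    rotated = Rotation.random(rng=rng).apply(protein.coords - c) + c
    both = np.concatenate([dnaA.coords, dnaB.coords], axis=0)
    placed = _place_apart(rotated, both, np.array([0.0, 1.0, 0.0]), min_protein_separation)
    prot = protein.copy()
    prot.coords = placed

    system = merge_structures(
        [prot, dnaA, dnaB], molecule_names=["protein", "duplexA", "duplexB"]
    )

    chain_pairs = {"duplexA": ("D", "E"), "duplexB": ("F", "G")}
    groups = []
    for mol in ("duplexA", "duplexB"):
        chains = chain_pairs[mol]
        restraints = []
        for prot_site, (strand, resid, name) in data_for_binding_mode:
            target = (chains[strand], resid, name)
            system.index_of(*target)  # KeyError if the role is absent
            restraints.append(
                FlatBottomRestraint(prot_site, target, *bounds, k=k)
            )
        groups.append(RestraintGroup(restraints, n_active=len(restraints)))
    data = RestraintCollection(groups, n_active_groups=1, label="data")

    nA = len(dnaA.residues("D"))
    nB = len(dnaB.residues("F"))
    sep = FlatBottomRestraint(
        ("D", (nA + 1) // 2, "BASE"),
        ("F", (nB + 1) // 2, "BASE"),
        max(0.0, duplex_separation - 12.0),
        max(0.0, duplex_separation - 8.0),
        duplex_separation + 8.0,
        duplex_separation + 12.0,
        k=2.0,
    )
    separation = RestraintCollection(
        [RestraintGroup([sep], n_active=1)],
        n_active_groups=1,
        label="duplex-separation",
    )

    collections = [data, separation]
    if freeze is not None:
        if freeze not in {"apo", "holo"}:
            raise ValueError("freeze must be 'apo', 'holo' or None")
        for mol in ("duplexA", "duplexB"):
            collections.append(positional_freeze(system, mol))
    return system, collections
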