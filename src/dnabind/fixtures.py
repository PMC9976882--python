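"""Synthetic test systems.

Everything here is generated programmatically so the whole suite runs with
no downloads.  The central fixture is a "clamp": a 12-bead arginine-rich
arc built in a bound pose wrapping an 8-bp duplex, which serves as the
bound-conformation input, the scoring reference, and (after rigid
displacement) the unbound starting state.  A symmetric two-duplex
competition assembly and a planted two-mode ensemble for clustering tests
are derived from it.

These are desk-scale stand-ins for experimental complexes; the clamp is
labelled synthetic throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .backends import CGBeadModel
from .builders import (
    assemble_unbound,
    build_bdna,
    competitive_system,
    place_dummy_sites,
    protocol1_data,
    scaffold_restraints,
)
from .model import (
    BeadStructure,
    DuplexSpec,
    RestraintCollection,
    Site,
    merge_structures,
)

__all__ = [
    "ClampFixture",
    "clamp_protein",
    "clamp_fixture",
    "clamp_unbound_system",
    "make_cg_backend",
    "symmetric_competition",
    "two_mode_frames",
    "FIXTURE_SEQUENCE",
]

# palindromic 8-mer: equal purine content on both strands, so neither
# duplex orientation is information-favoured
FIXTURE_SEQUENCE = "GCGATCGC"

_N_RES = 12
_ARC_RADIUS = 12.5  # angstrom from the helix axis in the bound pose
_CB_RADIUS = 13.0
_ARC_STEP_DEG = 30.0
_LAYER_DZ = 2.2  # half-gap between the two stacked arcs


def clamp_protein(dna_center_z: float) -> BeadStructure:
    """Synthetic 12-residue clamp in its bound conformation.

    Two stacked 6-residue arcs (a hairpin-like fold) wrapping the helix at
    12.5 A radius, so residues i and 13-i touch across the layers and give
    the scaffold genuine tertiary contacts.  The middle six residues are
    arginines (+1 e, the binding domain), residue 1 a glycine (no Cbeta),
    the rest alanines.  Cbeta beads sit just outside the Calpha ring,
    clear of the phosphate shell.
    """
    sites: list[Site] = []
    coords: list[np.ndarray] = []
    for k in range(_N_RES):
        resid = k + 1
        if resid == 1:
            resname = "GLY"
        elif 4 <= resid <= 9:
            resname = "ARG"
        else:
            resname = "ALA"
        charge = 1.0 if resname == "ARG" else 0.0
        if k < 6:  # outbound arc, lower layer
            phi = math.radians(_ARC_STEP_DEG * k)
            z = dna_center_z - _LAYER_DZ
        else:  # return arc, upper layer
            phi = math.radians(_ARC_STEP_DEG * (11 - k))
            z = dna_center_z + _LAYER_DZ
        ca = np.array(
            [_ARC_RADIUS * math.cos(phi), _ARC_RADIUS * math.sin(phi), z]
        )
        sites.append(Site("A", resid, resname, "CA", charge, 1.6, 110.0))
        coords.append(ca)
        if resname != "GLY":
            cb = np.array(
                [_CB_RADIUS * math.cos(phi), _CB_RADIUS * math.sin(phi), z]
            )
            sites.append(Site("A", resid, resname, "CB", 0.0, 1.6, 50.0))
            coords.append(cb)
    return BeadStructure(
        sites, np.asarray(coords), molecules={"protein": ["A"]}
    )


@dataclass
class ClampFixture:
    protein: BeadStructure  # bound conformation, at the binding site
    dna: BeadStructure  # duplex with dummy sites, in the build frame
    reference: BeadStructure  # merged bound complex (scoring reference)
    binding_residues: list[tuple[str, int]]
    spec: DuplexSpec


def clamp_fixture(sequence: str = FIXTURE_SEQUENCE) -> ClampFixture:
    spec = DuplexSpec(sequence, label="fixture")
    dna = place_dummy_sites(build_bdna(spec))
    center_z = dna.coords[
        dna.site_indices(name="BASE")
    ][:, 2].mean()
    protein = clamp_protein(center_z)
    reference = merge_structures(
        [protein, dna], molecule_names=["protein", "dna"]
    )
    binding_residues = [("A", r) for r in range(4, 10)]
    return ClampFixture(protein, dna, reference, binding_residues, spec)


def clamp_unbound_system(
    seed: int = 0,
    sequence: str = FIXTURE_SEQUENCE,
    active_fraction: float = 0.5,
    prune_radius: float = 20.0,
) -> tuple[BeadStructure, list[RestraintCollection], ClampFixture]:
    """Unbound clamp system with scaffold + protocol-1 data collections."""
    fx = clamp_fixture(sequence)
    system = assemble_unbound(fx.protein, fx.dna, min_separation=30.0, seed=seed)
    collections = scaffold_restraints(fx.protein, fx.dna)
    collections.append(
        protocol1_data(
            fx.protein,
            fx.binding_residues,
            fx.dna,
            prune_radius=prune_radius,
            active_fraction=active_fraction,
        )
    )
    return system, collections, fx


def _chain_bonds(system: BeadStructure) -> list[tuple[int, int, float]]:
    """Consecutive-CA, CA-CB and strand P(i)-P(i+1) bonds at built lengths."""
    bonds: list[tuple[int, int, float]] = []

    def add(i: int, j: int) -> None:
        r0 = float(np.linalg.norm(system.coords[i] - system.coords[j]))
        bonds.append((i, j, r0))

    for chain in system.chain_ids():
        residues = system.residues(chain)
        prev_ca = prev_p = None
        for _, resid, _ in residues:
            if system.has_site(chain, resid, "CA"):
                ca = system.index_of(chain, resid, "CA")
                if prev_ca is not None:
                    add(prev_ca, ca)
                prev_ca = ca
                if system.has_site(chain, resid, "CB"):
                    add(ca, system.index_of(chain, resid, "CB"))
            if system.has_site(chain, resid, "P"):
                p = system.index_of(chain, resid, "P")
                if prev_p is not None:
                    add(prev_p, p)
                prev_p = p
    return bonds


def make_cg_backend(
    system: BeadStructure,
    screening_length: float = 10.0,
    epsilon: float = 1.0,
) -> CGBeadModel:
    """Coarse-grained backend over a fixture system with chain bonds."""
    return CGBeadModel(
        structure=system,
        bonds=_chain_bonds(system),
        screening_length=screening_length,
        epsilon=epsilon,
    )


def binding_mode_data(
    fx: ClampFixture, max_pairs_per_residue: int = 1
) -> list[tuple[tuple[str, int, str], tuple[int, int, str]]]:
    """The clamp's known binding mode as (protein site, DNA site role) pairs.

    For each binding residue, the nearest non-dummy DNA site in the bound
    reference; roles are (strand, residue index, site name), so they apply
    to any duplex of the same length.
    """
    from scipy.spatial.distance import cdist

    chains = fx.dna.chain_ids()
    out = []
    for chain, resid in fx.binding_residues:
        ca = fx.protein.index_of(chain, resid, "CA")
        dna_idx = np.asarray(
            [i for i, s in enumerate(fx.dna.sites) if s.name != "DUMMY"],
            dtype=int,
        )
        d = cdist(fx.protein.coords[ca][None, :], fx.dna.coords[dna_idx])[0]
        order = np.argsort(d)
        for j in order[:max_pairs_per_residue]:
            s = fx.dna.sites[dna_idx[j]]
            out.append(
                (
                    (chain, resid, "CA"),
                    (chains.index(s.chain), s.residue_index, s.name),
                )
            )
    return out


def symmetric_competition(
    seed: int = 0, sequence: str = FIXTURE_SEQUENCE
) -> tuple[BeadStructure, list[RestraintCollection], ClampFixture]:
    """Self-competition assembly: clamp protein between two identical
    duplexes, scaffold restraints included."""
    fx = clamp_fixture(sequence)
    system, collections = competitive_system(
        fx.protein,
        DuplexSpec(sequence, label="duplexA"),
        DuplexSpec(sequence, label="duplexB"),
        binding_mode_data(fx),
        seed=seed,
    )
    collections = collections + scaffold_restraints(fx.protein, system)
    return system, collections, fx


def two_mode_frames(
    seed: int = 0,
    n_frames: int = 200,
    populations: tuple[float, float] = (0.7, 0.3),
    mode_separation: float = 15.0,
    jitter: float = 1.0,
) -> tuple[BeadStructure, list[np.ndarray], list[int]]:
    """Planted two-binding-mode ensemble for clustering validation.

    Mode 0 is the bound clamp pose; mode 1 the protein rotated about the
    helix axis so the two poses differ by ``mode_separation`` angstrom in
    ligand RMSD.  Frames carry Gaussian jitter on the protein beads and are
    shuffled; true labels are returned for scoring.
    """
    fx = clamp_fixture()
    system = fx.reference
    rng = np.random.default_rng(seed)
    lidx = system.molecule_site_indices("protein")

    # rotation angle giving the requested ligand displacement: the CA arc
    # sits near radius R, so |dx| ~ 2 R sin(theta/2)
    theta = 2.0 * math.asin(min(1.0, mode_separation / (2.0 * _ARC_RADIUS)))
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    mode1 = system.coords.copy()
    mode2 = system.coords.copy()
    mode2[lidx] = mode2[lidx] @ rot.T

    counts = [round(populations[0] * n_frames)]
    counts.append(n_frames - counts[0])
    labels = np.repeat([0, 1], counts)
    rng.shuffle(labels)
    frames = []
    for lab in labels:
        base = mode1 if lab == 0 else mode2
        f = base.copy()
        f[lidx] = f[lidx] + rng.normal(scale=jitter, size=(len(lidx), 3))
        frames.append(f)
    return system, frames, labels.tolist()
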