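"""Domain types shared by every other module.

A molecular system is a :class:`BeadStructure`: a flat list of named sites
(one or a few beads per residue) with coordinates in angstroms, plus chain /
residue bookkeeping.  Restraint containers implement the two-level
lowest-energy-subset likelihood: individual flat-bottom terms are collected
into :class:`RestraintGroup` (k-of-n at the restraint level) and groups into
:class:`RestraintCollection` (k-of-n at the group level).  A
:class:`ReplicaLadder` holds the per-replica temperature and restraint-scale
schedule, and an :class:`Ensemble` the frames a replica-exchange run produced.

No computation happens here beyond validation; energies live in
:mod:`dnabind.restraints` and dynamics in :mod:`dnabind.sampler`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

SITE_NAMES = {"CA", "CB", "P", "N1", "DUMMY", "BASE"}

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}
PURINES = {"A", "G"}


@dataclass(frozen=True)
class Site:
    """One bead: chain / residue identity plus physical attributes."""

    chain: str
    residue_index: int  # 1-based
    residue_name: str
    name: str  # CA, CB, P, N1, DUMMY, BASE or a generic token
    charge: float = 0.0  # elementary charges
    radius: float = 2.0  # angstrom
    mass: float = 1.0  # amu (reduced); DUMMY sites may be massless

    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_index, self.name)


class BeadStructure:
    """A molecular model as named sites with an (n, 3) coordinate array.

    Parameters
    ----------
    sites:
        Site records, in storage order.
    coords:
        Array of shape ``(len(sites), 3)`` in angstrom.
    molecules:
        Optional mapping ``molecule id -> list of chain ids``; defaults to
        one molecule per chain.  Rigid-body movers and inter-molecular
        non-bonded terms operate at molecule granularity.
    is_duplex:
        Tag for structures representing a DNA double helix; enforces the
        two-equal-chains invariant.
    dummy_parent:
        ``site index -> parent site index`` for DUMMY beads that ride
        rigidly on another site (purine N1 dummies).
    """

    def __init__(
        self,
        sites: Sequence[Site],
        coords: np.ndarray,
        molecules: dict[str, list[str]] | None = None,
        is_duplex: bool = False,
        dummy_parent: dict[int, int] | None = None,
    ):
        self.sites: list[Site] = list(sites)
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.sites), 3):
            raise ValueError(
                f"coords shape {coords.shape} != ({len(self.sites)}, 3)"
            )
        self.coords = coords
        self.is_duplex = bool(is_duplex)
        self.dummy_parent: dict[int, int] = dict(dummy_parent or {})
        if molecules is None:
            molecules = {c: [c] for c in self.chain_ids()}
        self.molecules: dict[str, list[str]] = {
            m: list(cs) for m, cs in molecules.items()
        }
        self._index: dict[tuple[str, int, str], int] = {}
        self.validate()

    # -- bookkeeping ---------------------------------------------------

    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.sites:
            if s.chain not in seen:
                seen.append(s.chain)
        return seen

    def index_of(self, chain: str, residue_index: int, name: str) -> int:
        try:
            return self._index[(chain, residue_index, name)]
        except KeyError:
            raise KeyError(
                f"no site ({chain}, {residue_index}, {name}) in structure"
            ) from None

    def has_site(self, chain: str, residue_index: int, name: str) -> bool:
        return (chain, residue_index, name) in self._index

    def site_indices(
        self, chains: Iterable[str] | None = None, name: str | None = None
    ) -> np.ndarray:
        chains = None if chains is None else set(chains)
        out = [
            i
            for i, s in enumerate(self.sites)
            if (chains is None or s.chain in chains)
            and (name is None or s.name == name)
        ]
        return np.asarray(out, dtype=int)

    def molecule_of_site(self) -> np.ndarray:
        """Integer molecule label per site (order of ``self.molecules``)."""
        chain_to_mol = {
            c: k
            for k, (_, chains) in enumerate(self.molecules.items())
            for c in chains
        }
        return np.asarray([chain_to_mol[s.chain] for s in self.sites], dtype=int)

    def molecule_site_indices(self, molecule: str) -> np.ndarray:
        chains = set(self.molecules[molecule])
        return self.site_indices(chains=chains)

    def residues(self, chain: str | None = None) -> list[tuple[str, int, str]]:
        out: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int]] = set()
        for s in self.sites:
            if chain is not None and s.chain != chain:
                continue
            if (s.chain, s.residue_index) not in seen:
                seen.add((s.chain, s.residue_index))
                out.append((s.chain, s.residue_index, s.residue_name))
        return out

    # -- validation ----------------------------------------------------

    def validate(self) -> "BeadStructure":
        self._index.clear()
        for i, s in enumerate(self.sites):
            k = s.key()
            if k in self._index:
                raise ValueError(f"duplicate site {k}")
            self._index[k] = i
            if s.radius <= 0:
                raise ValueError(f"site {k}: radius must be > 0")
            if s.name == "DUMMY":
                if s.mass < 0:
                    raise ValueError(f"site {k}: negative mass")
            elif s.mass <= 0:
                raise ValueError(f"site {k}: mass must be > 0")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.is_duplex:
            chains = self.chain_ids()
            if len(chains) != 2:
                raise ValueError("duplex must have exactly two chains")
            n0 = len(self.residues(chains[0]))
            n1 = len(self.residues(chains[1]))
            if n0 != n1:
                raise ValueError("duplex strands differ in residue count")
        mol_chains = [c for cs in self.molecules.values() for c in cs]
        if sorted(mol_chains) != sorted(self.chain_ids()):
            raise ValueError("molecules must partition the chains")
        return self

    # -- convenience ---------------------------------------------------

    def copy(self) -> "BeadStructure":
        return BeadStructure(
            self.sites,
            self.coords.copy(),
            molecules=self.molecules,
            is_duplex=self.is_duplex,
            dummy_parent=self.dummy_parent,
        )

    def tie_dummies(self, coords: np.ndarray | None = None) -> np.ndarray:
        """Return coordinates with DUMMY sites snapped onto their parents."""
        c = self.coords if coords is None else coords
        if self.dummy_parent:
            c = c.copy()
            for d, p in self.dummy_parent.items():
                c[d] = c[p]
        return c

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<BeadStructure {self.n_sites} sites, chains {self.chain_ids()}>"
        )


def merge_structures(
    parts: Sequence[BeadStructure],
    molecule_names: Sequence[str] | None = None,
) -> BeadStructure:
    """Concatenate structures into one system.

    Chain ids must be globally unique across parts.  Each part becomes one
    molecule (or keeps its own molecule partition if it has several).
    """
    if molecule_names is None:
        molecule_names = [f"mol{k}" for k in range(len(parts))]
    sites: list[Site] = []
    coords = []
    molecules: dict[str, list[str]] = {}
    dummy_parent: dict[int, int] = {}
    offset = 0
    for part, mname in zip(parts, molecule_names):
        sites.extend(part.sites)
        coords.append(part.coords)
        if len(part.molecules) == 1:
            molecules[mname] = part.chain_ids()
        else:
            for sub, chains in part.molecules.items():
                molecules[f"{mname}.{sub}"] = list(chains)
        for d, p in part.dummy_parent.items():
            dummy_parent[d + offset] = p + offset
        offset += part.n_sites
    return BeadStructure(
        sites,
        np.concatenate(coords, axis=0),
        molecules=molecules,
        dummy_parent=dummy_parent,
    )


# ---------------------------------------------------------------------------
# DNA duplex specification
# ---------------------------------------------------------------------------


def wc_complement(sequence: str) -> str:
    """Watson-Crick complement of a 5'->3' strand, returned 5'->3'."""
    try:
        return "".join(_WC[b] for b in reversed(sequence))
    except KeyError:
        for pos, b in enumerate(sequence, start=1):
            if b not in _WC:
                raise ValueError(
                    f"non-ACGT character {b!r} at position {pos}"
                ) from None
        raise


@dataclass
class DuplexSpec:
    """A B-DNA duplex given by strand 1 (5'->3'); strand 2 is derived.

    ``complement`` is stored 5'->3'; base ``i`` (0-based) of ``sequence``
    pairs with base ``n-1-i`` of ``complement``.
    """

    sequence: str
    label: str = "duplex"
    complement: str = field(default="")

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.complement:
            self.complement = wc_complement(self.sequence)

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    def purine_count(self) -> int:
        """Purines over both strands; equals n_bp for any WC duplex."""
        both = self.sequence + self.complement
        return sum(1 for b in both if b in PURINES)


def validate_duplex(spec: DuplexSpec) -> DuplexSpec:
    """Validate sequence alphabet / length and (re)derive the complement.

    Raises ``ValueError`` naming the first offending position for a
    non-ACGT character, and for duplexes shorter than 4 bp.
    """
    seq = spec.sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    for pos, b in enumerate(seq, start=1):
        if b not in _WC:
            raise ValueError(f"non-ACGT character {b!r} at position {pos}")
    if len(seq) < 4:
        raise ValueError(f"duplex must be >= 4 bp, got {len(seq)}")
    spec.sequence = seq
    spec.complement = wc_complement(seq)
    return spec


# ---------------------------------------------------------------------------
# Restraints
# ---------------------------------------------------------------------------


@dataclass
class FlatBottomRestraint:
    """Pairwise flat-bottom term: zero on [r2, r3], harmonic walls out to
    r1 / r4, linear beyond with matched slope (C1 everywhere).

    ``site_b`` may be ``None`` for a positional restraint, in which case
    ``anchor`` is the fixed Cartesian point the distance is measured to.
    """

    site_a: tuple[str, int, str]
    site_b: tuple[str, int, str] | None
    r1: float
    r2: float
    r3: float
    r4: float
    k: float = 1.0
    anchor: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.r1 <= self.r2 <= self.r3 <= self.r4):
            raise ValueError(
                f"require 0 <= r1 <= r2 <= r3 <= r4, got "
                f"({self.r1}, {self.r2}, {self.r3}, {self.r4})"
            )
        if self.k < 0:
            raise ValueError("force constant must be >= 0")
        if self.site_b is None and self.anchor is None:
            raise ValueError("positional restraint needs an anchor point")


@dataclass
class RestraintGroup:
    """k-of-n container: only the ``n_active`` lowest-energy members count."""

    restraints: list[FlatBottomRestraint]
    n_active: int

    def __post_init__(self) -> None:
        if not (1 <= self.n_active <= len(self.restraints)):
            raise ValueError(
                f"n_active={self.n_active} outside 1..{len(self.restraints)}"
            )


@dataclass
class RestraintCollection:
    """Groups with k-of-n selection at the group level.

    ``label`` routes ladder scaling: ``data`` collections are multiplied by
    the replica's restraint scale, ``scaffold`` and ``duplex-separation``
    collections stay on at full strength on every rung.

    ``exclusions`` lists pairs ``((gi, ri), (gj, rj))`` of (group index,
    restraint index) picks that may not be active simultaneously — used by
    the protocol-1 pruning of far-apart residues sharing one dummy site.
    """

    groups: list[RestraintGroup]
    n_active_groups: int
    label: str = "data"
    exclusions: list[tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        if not (1 <= self.n_active_groups <= len(self.groups)):
            raise ValueError(
                f"n_active_groups={self.n_active_groups} outside "
                f"1..{len(self.groups)}"
            )
        if self.label not in {"data", "scaffold", "duplex-separation"}:
            raise ValueError(f"unknown collection label {self.label!r}")

    def n_restraints(self) -> int:
        return sum(len(g.restraints) for g in self.groups)


# ---------------------------------------------------------------------------
# Replica ladder and ensembles
# ---------------------------------------------------------------------------


@dataclass
class ReplicaLadder:
    """Per-replica (temperature, restraint scale) schedule.

    Temperatures ascend strictly; scales are in [0, 1], start at 1 on the
    lowest rung and never increase with replica index, so low rungs are
    bound-compatible (cool, data on) and high rungs unbound-compatible
    (hot, data off).
    """

    temperatures: list[float]
    restraint_scales: list[float]
    exchange_interval: int = 500

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        s = np.asarray(self.restraint_scales, dtype=float)
        if t.size != s.size:
            raise ValueError("temperatures and restraint_scales differ in length")
        if t.size < 2:
            raise ValueError("need at least 2 replicas")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly ascending")
        if abs(s[0] - 1.0) > 1e-12:
            raise ValueError("restraint_scales[0] must be 1")
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("restraint scales must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("restraint scales must be non-increasing")
        if self.exchange_interval < 1:
            raise ValueError("exchange_interval must be >= 1")

    @property
    def n_replicas(self) -> int:
        return len(self.temperatures)


@dataclass
class Frame:
    """One stored state of one replica at the end of a round."""

    replica: int
    round_index: int
    walker: int
    coords: np.ndarray  # (n_sites, 3) float32
    potential_energy: float
    restraint_energy: float


@dataclass
class Ensemble:
    """Frames from a replica-exchange run plus the ladder that produced them.

    Within each round the walker ids across replicas form a permutation of
    ``0..n_replicas-1``; coordinates swap at exchanges and walker labels
    follow, so binding/unbinding cycles of individual walkers are
    reconstructible.
    """

    frames: list[Frame]
    ladder: ReplicaLadder

    def validate(self) -> "Ensemble":
        n = self.ladder.n_replicas
        by_round: dict[int, list[int]] = {}
        for f in self.frames:
            by_round.setdefault(f.round_index, []).append(f.walker)
            if f.restraint_energy < -1e-9:
                raise ValueError("negative restraint energy")
        for rnd, walkers in by_round.items():
            if sorted(walkers) != list(range(n)):
                raise ValueError(f"round {rnd}: walker ids not a permutation")
        return self

    def replica_frames(self, replica: int) -> list[Frame]:
        return [f for f in self.frames if f.replica == replica]

    def walker_trace(self, walker: int) -> list[Frame]:
        out = [f for f in self.frames if f.walker == walker]
        out.sort(key=lambda f: f.round_index)
        return out


# ---------------------------------------------------------------------------
# Serialization (round-trip safe, plain JSON)
# ---------------------------------------------------------------------------


def structure_to_dict(s: BeadStructure) -> dict:
    return {
        "sites": [dataclasses.asdict(x) for x in s.sites],
        "coords": s.coords.tolist(),
        "molecules": s.molecules,
        "is_duplex": s.is_duplex,
        "dummy_parent": {str(k): v for k, v in s.dummy_parent.items()},
    }


def structure_from_dict(d: dict) -> BeadStructure:
    return BeadStructure(
        [Site(**x) for x in d["sites"]],
        np.asarray(d["coords"], dtype=float),
        molecules=d.get("molecules"),
        is_duplex=d.get("is_duplex", False),
        dummy_parent={int(k): v for k, v in d.get("dummy_parent", {}).items()},
    )


def duplex_to_dict(spec: DuplexSpec) -> dict:
    return dataclasses.asdict(spec)


def duplex_from_dict(d: dict) -> DuplexSpec:
    return DuplexSpec(**d)


def ladder_to_dict(l: ReplicaLadder) -> dict:
    return dataclasses.asdict(l)


def ladder_from_dict(d: dict) -> ReplicaLadder:
    return ReplicaLadder(**d)


def dumps(obj) -> str:
    """JSON text for any of the serializable domain types."""
    if isinstance(obj, BeadStructure):
        return json.dumps({"type": "BeadStructure", **structure_to_dict(obj)})
    if isinstance(obj, DuplexSpec):
        return json.dumps({"type": "DuplexSpec", **duplex_to_dict(obj)})
    if isinstance(obj, ReplicaLadder):
        return json.dumps({"type": "ReplicaLadder", **ladder_to_dict(obj)})
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def loads(text: str):
    d = json.loads(text)
    t = d.pop("type")
    if t == "BeadStructure":
        return structure_from_dict(d)
    if t == "DuplexSpec":
        return duplex_from_dict(d)
    if t == "ReplicaLadder":
        return ladder_from_dict(d)
    raise TypeError(f"cannot deserialize {t}")
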