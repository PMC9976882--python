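"""Ensemble analysis: binding-mode clustering, interface RMSD, fraction of
native contacts, success calls and competitive-binding populations.

The posterior ensemble is the lowest replica.  Binding modes are found by
hierarchical average-linkage clustering of a ligand-RMSD metric (protein
RMSD after superposing frames on the DNA), ranked by population; clusters
are optionally scored against a reference complex with the community
interface-RMSD and fnat conventions (interface = residues within 10 A of
the partner in the reference; contact = any site pair within 5 A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from scipy.spatial.transform import Rotation

from .model import BeadStructure, Ensemble

__all__ = [
    "ClusterReport",
    "ClusterInfo",
    "kabsch_rmsd",
    "superpose",
    "interface_rmsd",
    "fnat",
    "cluster_ensemble",
    "success_call",
    "competitive_populations",
]


# ---------------------------------------------------------------------------
# RMSD primitives
# ---------------------------------------------------------------------------


def _check_selection(x: np.ndarray) -> None:
    if x.shape[0] < 3:
        raise ValueError("need at least 3 sites for superposition")
    centered = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) selection")


def superpose(
    X: np.ndarray, Y: np.ndarray
) -> tuple[Rotation, np.ndarray, np.ndarray]:
    """Optimal rigid superposition of Y onto X (rotation R, translation t).

    Returns ``(R, t, Y_aligned)`` with ``Y_aligned = R.apply(Y) + t``.
    Proper rotations only (no reflection), via the SVD-based Kabsch
    construction as implemented in ``Rotation.align_vectors``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("coordinate sets differ in shape")
    _check_selection(X)
    _check_selection(Y)
    cx = X.mean(axis=0)
    cy = Y.mean(axis=0)
    R, _ = Rotation.align_vectors(X - cx, Y - cy)
    t = cx - R.apply(cy[None, :])[0]
    return R, t, R.apply(Y) + t


def kabsch_rmsd(
    X: np.ndarray, Y: np.ndarray, selection: np.ndarray | None = None
) -> float:
    """Minimum RMSD between two conformations over rigid superposition."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if selection is not None:
        X = X[selection]
        Y = Y[selection]
    _, _, Ya = superpose(X, Y)
    return float(np.sqrt(((X - Ya) ** 2).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# Reference-based scores
# ---------------------------------------------------------------------------


def _molecule_split(structure: BeadStructure) -> tuple[np.ndarray, np.ndarray]:
    """Site indices of the first molecule and of everything else."""
    mols = list(structure.molecules)
    if len(mols) < 2:
        raise ValueError("need at least two molecules for interface scores")
    a = structure.molecule_site_indices(mols[0])
    b = np.asarray(
        sorted(
            set(range(structure.n_sites)) - set(a.tolist())
        ),
        dtype=int,
    )
    return a, b


def _non_dummy(structure: BeadStructure, idx: np.ndarray) -> np.ndarray:
    return np.asarray(
        [i for i in idx if structure.sites[i].name != "DUMMY"], dtype=int
    )


def interface_rmsd(
    model: np.ndarray | BeadStructure,
    reference: BeadStructure,
    interface_cutoff: float = 10.0,
) -> float:
    """RMSD over interface sites after superposing on the interface.

    Interface residues are those of either molecule with any site within
    ``interface_cutoff`` of the partner *in the reference*; the model is
    superposed on the reference over the interface sites and their RMSD
    reported (CAPRI-style convention).
    """
    model_coords = model.coords if isinstance(model, BeadStructure) else np.asarray(model, dtype=float)
    ia, ib = _molecule_split(reference)
    ia = _non_dummy(reference, ia)
    ib = _non_dummy(reference, ib)
    ref = reference.coords
    d = cdist(ref[ia], ref[ib])
    res_a = {
        (reference.sites[i].chain, reference.sites[i].residue_index)
        for k, i in enumerate(ia)
        if d[k].min() <= interface_cutoff
    }
    res_b = {
        (reference.sites[j].chain, reference.sites[j].residue_index)
        for k, j in enumerate(ib)
        if d[:, k].min() <= interface_cutoff
    }
    iface = res_a | res_b
    if not iface:
        raise ValueError("empty interface at this cutoff")
    sel = np.asarray(
        [
            i
            for i, s in enumerate(reference.sites)
            if (s.chain, s.residue_index) in iface and s.name != "DUMMY"
        ],
        dtype=int,
    )
    return kabsch_rmsd(ref[sel], model_coords[sel])


def _residue_min_distances(
    structure: BeadStructure,
    coords: np.ndarray,
    ia: np.ndarray,
    ib: np.ndarray,
) -> dict[tuple, float]:
    d = cdist(coords[ia], coords[ib])
    out: dict[tuple, float] = {}
    for k, i in enumerate(ia):
        ra = (structure.sites[i].chain, structure.sites[i].residue_index)
        for l, j in enumerate(ib):
            rb = (structure.sites[j].chain, structure.sites[j].residue_index)
            key = (ra, rb)
            v = d[k, l]
            if key not in out or v < out[key]:
                out[key] = float(v)
    return out


def fnat(
    model: np.ndarray | BeadStructure,
    reference: BeadStructure,
    cutoff: float = 5.0,
) -> float:
    """Fraction of the reference's inter-molecular residue contacts
    reproduced by the model (contact: any site pair within ``cutoff``; bead
    pairs stand in for heavy-atom pairs at this resolution)."""
    model_coords = model.coords if isinstance(model, BeadStructure) else np.asarray(model, dtype=float)
    ia, ib = _molecule_split(reference)
    ia = _non_dummy(reference, ia)
    ib = _non_dummy(reference, ib)
    ref_d = _residue_min_distances(reference, reference.coords, ia, ib)
    native = {k for k, v in ref_d.items() if v <= cutoff}
    if not native:
        raise ValueError("reference has no inter-molecular contacts")
    mod_d = _residue_min_distances(reference, model_coords, ia, ib)
    kept = sum(1 for k in native if mod_d[k] <= cutoff)
    return kept / len(native)


def native_contact_count(reference: BeadStructure, cutoff: float = 5.0) -> int:
    ia, ib = _molecule_split(reference)
    ia = _non_dummy(reference, ia)
    ib = _non_dummy(reference, ib)
    ref_d = _residue_min_distances(reference, reference.coords, ia, ib)
    return sum(1 for v in ref_d.values() if v <= cutoff)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterInfo:
    members: list[int]
    population: float
    representative: int
    irmsd: float | None = None
    fnat: float | None = None


@dataclass
class ClusterReport:
    """Ranked binding modes (population descending)."""

    clusters: list[ClusterInfo]
    n_frames: int
    frame_ids: list[int] = field(default_factory=list)

    def validate(self) -> "ClusterReport":
        seen: set[int] = set()
        total = 0.0
        for c in self.clusters:
            if seen & set(c.members):
                raise ValueError("cluster member sets overlap")
            seen |= set(c.members)
            total += c.population
        if total > 1.0 + 1e-9:
            raise ValueError("populations exceed 1")
        pops = [c.population for c in self.clusters]
        if pops != sorted(pops, reverse=True):
            raise ValueError("clusters not sorted by population")
        return self

    def scored(self) -> bool:
        return all(c.irmsd is not None for c in self.clusters)


def _pairwise_binding_metric(
    structure: BeadStructure,
    frames: list[np.ndarray],
    receptor_idx: np.ndarray,
    ligand_idx: np.ndarray,
) -> np.ndarray:
    """Ligand RMSD after receptor superposition, all frame pairs."""
    n = len(frames)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            R, t, _ = superpose(frames[i][receptor_idx], frames[j][receptor_idx])
            lig_j = R.apply(frames[j][ligand_idx]) + t
            d = np.sqrt(((frames[i][ligand_idx] - lig_j) ** 2).sum(axis=1).mean())
            dm[i, j] = dm[j, i] = d
    return dm


def cluster_ensemble(
    ensemble_or_frames,
    structure: BeadStructure,
    cutoff: float = 3.0,
    replica: int = 0,
    receptor: str | None = None,
    ligand: str = "protein",
    reference: BeadStructure | None = None,
    max_frames: int = 400,
    rng: np.random.Generator | None = None,
) -> ClusterReport:
    """Cluster the lowest-replica ensemble into binding modes.

    The metric is the ligand (protein) RMSD after superposing each pair of
    frames on the receptor (DNA) — a binding-mode distance insensitive to
    global motion.  Hierarchical average linkage is cut at ``cutoff``
    angstrom; clusters are ranked by population and represented by their
    medoid.  With a ``reference``, each representative gets interface RMSD
    and fnat columns.  At most ``max_frames`` frames enter the O(n^2)
    metric (evenly subsampled); populations remain fractions of the
    analyzed frames.
    """
    if isinstance(ensemble_or_frames, Ensemble):
        rep_frames = ensemble_or_frames.replica_frames(replica)
        frames = [structure.tie_dummies(f.coords.astype(float)) for f in rep_frames]
    else:
        frames = [np.asarray(f, dtype=float) for f in ensemble_or_frames]
    if not frames:
        raise ValueError("no frames to cluster")
    frame_ids = list(range(len(frames)))
    if len(frames) > max_frames:
        sel = np.linspace(0, len(frames) - 1, max_frames).astype(int)
        frames = [frames[i] for i in sel]
        frame_ids = [frame_ids[i] for i in sel]

    if receptor is None:
        receptor = next(m for m in structure.molecules if m != ligand)
    ridx = _non_dummy(structure, structure.molecule_site_indices(receptor))
    lidx = _non_dummy(structure, structure.molecule_site_indices(ligand))

    if len(frames) == 1:
        labels = np.asarray([1])
        dm = np.zeros((1, 1))
    else:
        dm = _pairwise_binding_metric(structure, frames, ridx, lidx)
        Z = linkage(squareform(dm, checks=False), method="average")
        labels = fcluster(Z, t=cutoff, criterion="distance")

    clusters: list[ClusterInfo] = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        sub = dm[np.ix_(members, members)]
        medoid = members[int(np.argmin(sub.sum(axis=0)))]
        info = ClusterInfo(
            members=[frame_ids[m] for m in members],
            population=len(members) / len(frames),
            representative=frame_ids[medoid],
        )
        if reference is not None:
            rep_coords = frames[medoid]
            info.irmsd = interface_rmsd(rep_coords, reference)
            info.fnat = fnat(rep_coords, reference)
        clusters.append(info)
    clusters.sort(key=lambda c: (-c.population, c.members[0]))
    return ClusterReport(
        clusters=clusters, n_frames=len(frames), frame_ids=frame_ids
    ).validate()


def success_call(
    report: ClusterReport, threshold: float = 5.0, top_n: int = 5
) -> tuple[bool, float, float]:
    """Prediction success: a sub-``threshold`` interface RMSD among the
    representatives of the ``top_n`` most populated clusters.

    Returns (success, best iRMSD in the top n, best iRMSD overall).
    """
    if not report.scored():
        raise ValueError("report is not scored against a reference")
    irmsds = [c.irmsd for c in report.clusters]
    top = irmsds[:top_n]
    best_top = float(min(top))
    best_all = float(min(irmsds))
    return best_top < threshold, best_top, best_all


# ---------------------------------------------------------------------------
# Competitive binding
# ---------------------------------------------------------------------------


@dataclass
class CompetitionResult:
    fraction_a: float
    fraction_b: float
    fraction_unbound: float
    n_bound: int
    n_frames: int
    ci95_a: tuple[float, float]

    @property
    def bound_share_a(self) -> float:
        """A's share among bound frames (the competitive-affinity readout)."""
        if self.n_bound == 0:
            return float("nan")
        return self.fraction_a * self.n_frames / self.n_bound

    def swap(self) -> "CompetitionResult":
        return CompetitionResult(
            self.fraction_b,
            self.fraction_a,
            self.fraction_unbound,
            self.n_bound,
            self.n_frames,
            (1 - self.ci95_a[1], 1 - self.ci95_a[0]) if self.n_bound else self.ci95_a,
        )


def competitive_populations(
    ensemble: Ensemble,
    structure: BeadStructure,
    binding_sites: list[tuple[str, int, str]],
    duplex_a: str = "duplexA",
    duplex_b: str = "duplexB",
    bound_cutoff: float = 8.0,
    n_min: int | None = None,
    replica: int = 0,
) -> CompetitionResult:
    """Assign lowest-replica frames to duplex A / B / unbound and report
    bound fractions with a 95% binomial CI on the A-share of bound frames.

    A frame is bound to a duplex when at least ``n_min`` of the protein's
    binding-domain sites lie within ``bound_cutoff`` of any of its sites
    and fewer than ``n_min`` are near the other duplex; frames near both
    count as ambiguous (warned) and join the unbound pool.  ``n_min``
    defaults to half the binding sites, rounded up.
    """
    from statsmodels.stats.proportion import proportion_confint

    if n_min is None:
        n_min = (len(binding_sites) + 1) // 2
    bidx = np.asarray([structure.index_of(*s) for s in binding_sites], dtype=int)
    ia = _non_dummy(structure, structure.molecule_site_indices(duplex_a))
    ib = _non_dummy(structure, structure.molecule_site_indices(duplex_b))

    n_a = n_b = n_u = n_ambig = 0
    for f in ensemble.replica_frames(replica):
        c = f.coords.astype(float)
        near_a = int((cdist(c[bidx], c[ia]).min(axis=1) <= bound_cutoff).sum())
        near_b = int((cdist(c[bidx], c[ib]).min(axis=1) <= bound_cutoff).sum())
        a_bound = near_a >= n_min
        b_bound = near_b >= n_min
        if a_bound and b_bound:
            n_ambig += 1
            n_u += 1
        elif a_bound:
            n_a += 1
        elif b_bound:
            n_b += 1
        else:
            n_u += 1
    if n_ambig:
        warnings.warn(
            f"{n_ambig} frames satisfied both duplexes; counted ambiguous",
            stacklevel=2,
        )
    n = n_a + n_b + n_u
    n_bound = n_a + n_b
    if n_bound:
        lo, hi = proportion_confint(n_a, n_bound, alpha=0.05, method="wilson")
    else:
        lo = hi = float("nan")
    return CompetitionResult(
        fraction_a=n_a / n if n else 0.0,
        fraction_b=n_b / n if n else 0.0,
        fraction_unbound=n_u / n if n else 0.0,
        n_bound=n_bound,
        n_frames=n,
        ci95_a=(float(lo), float(hi)),
    )
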