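"""Flat-bottom restraint energies, forces and lowest-energy-subset selection.

The likelihood over ambiguous data is realized as a two-level hierarchy:
within a group only the ``n_active`` lowest-energy restraints contribute,
and within a collection only the ``n_active_groups`` lowest-energy groups.
The sampler therefore pays an energy penalty only for the *best* subset of
the data of the prescribed size, which is what lets noisy and mutually
inconsistent contacts coexist in one run.

Selection is re-evaluated at every energy call (no hysteresis) and ties are
broken by ascending restraint / group index so replays are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    BeadStructure,
    FlatBottomRestraint,
    RestraintCollection,
    RestraintGroup,
)

__all__ = [
    "flat_bottom_energy",
    "flat_bottom_denergy",
    "restraint_force",
    "group_energy",
    "collection_energy",
    "total_restraint_energy",
    "CompiledCollection",
    "compile_collection",
    "collections_to_table",
    "collections_from_table",
]


def flat_bottom_energy(r: float, rst: FlatBottomRestraint, scale: float = 1.0) -> float:
    """Energy of one flat-bottom restraint at separation ``r``.

    Zero on [r2, r3]; half-harmonic ``0.5*k*(r-r3)**2`` on (r3, r4] and the
    mirror image on [r1, r2); linear beyond r4 (and below r1) with the slope
    of the harmonic wall at the matching point, offset so the energy is C1
    everywhere.  Linear tails keep forces bounded at the >= 30 A initial
    separations.
    """
    return scale * _fb_energy_arr(
        np.asarray(r, dtype=float), rst.r1, rst.r2, rst.r3, rst.r4, rst.k
    ).item()


def _fb_energy_arr(r, r1, r2, r3, r4, k):
    r = np.asarray(r, dtype=float)
    e = np.zeros_like(r)
    # upper harmonic wall
    m = (r > r3) & (r <= r4)
    e = np.where(m, 0.5 * k * (r - r3) ** 2, e)
    # upper linear tail, C1-matched at r4
    slope_hi = k * (r4 - r3)
    m = r > r4
    e = np.where(m, 0.5 * k * (r4 - r3) ** 2 + slope_hi * (r - r4), e)
    # lower harmonic wall
    m = (r < r2) & (r >= r1)
    e = np.where(m, 0.5 * k * (r - r2) ** 2, e)
    # lower linear tail, C1-matched at r1
    slope_lo = k * (r2 - r1)
    m = r < r1
    e = np.where(m, 0.5 * k * (r2 - r1) ** 2 + slope_lo * (r1 - r), e)
    return e


def _fb_denergy_arr(r, r1, r2, r3, r4, k):
    """dE/dr of the flat-bottom form (vectorized)."""
    r = np.asarray(r, dtype=float)
    g = np.zeros_like(r)
    g = np.where((r > r3) & (r <= r4), k * (r - r3), g)
    g = np.where(r > r4, k * (r4 - r3), g)
    g = np.where((r < r2) & (r >= r1), k * (r - r2), g)
    g = np.where(r < r1, -k * (r2 - r1), g)
    return g


def flat_bottom_denergy(r: float, rst: FlatBottomRestraint, scale: float = 1.0) -> float:
    return scale * _fb_denergy_arr(
        np.asarray(r, dtype=float), rst.r1, rst.r2, rst.r3, rst.r4, rst.k
    ).item()


def restraint_force(
    rst: FlatBottomRestraint,
    structure: BeadStructure,
    coords: np.ndarray | None = None,
    scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic forces on (site_a, site_b); equal and opposite.

    For a positional restraint the second vector is the force on the fixed
    anchor and is reported for bookkeeping only.  Coincident sites get zero
    force by convention.
    """
    c = structure.coords if coords is None else coords
    xa = c[structure.index_of(*rst.site_a)]
    if rst.site_b is not None:
        xb = c[structure.index_of(*rst.site_b)]
    else:
        xb = np.asarray(rst.anchor, dtype=float)
    d = xa - xb
    r = float(np.linalg.norm(d))
    if r < 1e-12:
        z = np.zeros(3)
        return z, z.copy()
    dedr = flat_bottom_denergy(r, rst, scale)
    fa = -dedr * d / r
    return fa, -fa


def _restraint_distances(
    restraints: list[FlatBottomRestraint],
    structure: BeadStructure,
    coords: np.ndarray,
) -> np.ndarray:
    ia = [structure.index_of(*r.site_a) for r in restraints]
    xa = coords[ia]
    xb = np.empty_like(xa)
    for k, r in enumerate(restraints):
        if r.site_b is not None:
            xb[k] = coords[structure.index_of(*r.site_b)]
        else:
            xb[k] = r.anchor
    return np.linalg.norm(xa - xb, axis=1)


def _member_energies(
    group: RestraintGroup, structure: BeadStructure, coords: np.ndarray, scale: float
) -> np.ndarray:
    d = _restraint_distances(group.restraints, structure, coords)
    params = np.asarray(
        [(r.r1, r.r2, r.r3, r.r4, r.k) for r in group.restraints], dtype=float
    )
    return scale * _fb_energy_arr(
        d, params[:, 0], params[:, 1], params[:, 2], params[:, 3], params[:, 4]
    )


def _lowest_k(energies: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest energies, ties broken by ascending index."""
    order = np.argsort(energies, kind="stable")
    return np.sort(order[:k])


def group_energy(
    group: RestraintGroup,
    structure: BeadStructure,
    coords: np.ndarray | None = None,
    scale: float = 1.0,
) -> tuple[float, list[int]]:
    """Sum of the ``n_active`` lowest member energies and the active set."""
    c = structure.coords if coords is None else coords
    e = _member_energies(group, structure, c, scale)
    active = _lowest_k(e, group.n_active)
    return float(e[active].sum()), active.tolist()


def collection_energy(
    collection: RestraintCollection,
    structure: BeadStructure,
    coords: np.ndarray | None = None,
    scale: float = 1.0,
) -> tuple[float, list[int]]:
    """Sum of the ``n_active_groups`` lowest group energies + active groups.

    With a non-empty exclusion list, active groups are processed in
    ascending unconstrained-energy order and each picks its lowest-energy
    admissible member set given the picks already made (greedy resolution;
    only meaningful for n_active = 1 groups as built by protocol 1).
    """
    c = structure.coords if coords is None else coords
    member_e = [
        _member_energies(g, structure, c, scale) for g in collection.groups
    ]
    ge = np.asarray(
        [float(e[_lowest_k(e, g.n_active)].sum()) for g, e in zip(collection.groups, member_e)]
    )
    active_groups = _lowest_k(ge, collection.n_active_groups)

    if not collection.exclusions:
        return float(ge[active_groups].sum()), active_groups.tolist()

    # Greedy exclusion-aware resolution: process active groups cheapest
    # first; each takes its best member choice not conflicting with picks
    # already made.
    banned: dict[int, set[int]] = {}
    for (gi, ri), (gj, rj) in collection.exclusions:
        banned.setdefault(gi, set())
        banned.setdefault(gj, set())
    chosen: dict[int, int] = {}  # group -> member index (n_active==1 case)
    total = 0.0
    order = sorted(active_groups.tolist(), key=lambda g: (ge[g], g))
    for g in order:
        e = member_e[g]
        grp = collection.groups[g]
        if grp.n_active != 1 or g not in banned:
            act = _lowest_k(e, grp.n_active)
            total += float(e[act].sum())
            if grp.n_active == 1:
                chosen[g] = int(act[0])
            continue
        blocked = {
            rj
            for (gi, ri), (gj, rj) in collection.exclusions
            if gj == g and chosen.get(gi) == ri
        } | {
            ri
            for (gi, ri), (gj, rj) in collection.exclusions
            if gi == g and chosen.get(gj) == rj
        }
        order_m = np.argsort(e, kind="stable")
        pick = next((int(m) for m in order_m if int(m) not in blocked), int(order_m[0]))
        chosen[g] = pick
        total += float(e[pick])
    return total, sorted(active_groups.tolist())


def total_restraint_energy(
    collections: list[RestraintCollection],
    structure: BeadStructure,
    coords: np.ndarray | None = None,
    replica_scale: float = 1.0,
) -> tuple[float, dict[str, float]]:
    """Grand total and per-collection decomposition at one replica.

    ``data`` collections are multiplied by the replica's restraint scale;
    ``scaffold`` and ``duplex-separation`` collections are evaluated at full
    strength on every rung (they keep the molecules folded / apart at high
    temperature).
    """
    c = structure.coords if coords is None else coords
    decomposition: dict[str, float] = {}
    total = 0.0
    for k, col in enumerate(collections):
        s = replica_scale if col.label == "data" else 1.0
        e, _ = collection_energy(col, structure, c, s)
        decomposition[f"{k}:{col.label}"] = e
        total += e
    return total, decomposition


# ---------------------------------------------------------------------------
# Fast path for samplers
# ---------------------------------------------------------------------------


@dataclass
class CompiledCollection:
    """Index-resolved arrays for one collection (hot loop form)."""

    ia: np.ndarray  # (n,) site index of end A
    ib: np.ndarray  # (n,) site index of end B, -1 for positional
    anchors: np.ndarray  # (n, 3) anchor point where ib == -1
    params: np.ndarray  # (n, 5) r1 r2 r3 r4 k
    group_of: np.ndarray  # (n,) group index per restraint
    group_n_active: np.ndarray  # (G,)
    n_active_groups: int
    scaled: bool  # True for 'data' collections

    def energy(self, coords: np.ndarray, replica_scale: float) -> float:
        s = replica_scale if self.scaled else 1.0
        if s == 0.0:
            return 0.0
        xa = coords[self.ia]
        xb = np.where((self.ib >= 0)[:, None], coords[self.ib], self.anchors)
        r = np.linalg.norm(xa - xb, axis=1)
        p = self.params
        e = s * _fb_energy_arr(r, p[:, 0], p[:, 1], p[:, 2], p[:, 3], p[:, 4])
        n_groups = len(self.group_n_active)
        ge = np.empty(n_groups)
        for g in range(n_groups):
            eg = e[self.group_of == g]
            na = self.group_n_active[g]
            if na >= eg.size:
                ge[g] = eg.sum()
            else:
                ge[g] = np.partition(eg, na - 1)[:na].sum()
        if self.n_active_groups >= n_groups:
            return float(ge.sum())
        return float(np.partition(ge, self.n_active_groups - 1)[: self.n_active_groups].sum())


def compile_collection(
    collection: RestraintCollection, structure: BeadStructure
) -> CompiledCollection:
    ia, ib, anchors, params, group_of = [], [], [], [], []
    for g, grp in enumerate(collection.groups):
        for r in grp.restraints:
            ia.append(structure.index_of(*r.site_a))
            if r.site_b is not None:
                ib.append(structure.index_of(*r.site_b))
                anchors.append((0.0, 0.0, 0.0))
            else:
                ib.append(-1)
                anchors.append(r.anchor)
            params.append((r.r1, r.r2, r.r3, r.r4, r.k))
            group_of.append(g)
    return CompiledCollection(
        ia=np.asarray(ia, dtype=int),
        ib=np.asarray(ib, dtype=int),
        anchors=np.asarray(anchors, dtype=float),
        params=np.asarray(params, dtype=float),
        group_of=np.asarray(group_of, dtype=int),
        group_n_active=np.asarray(
            [g.n_active for g in collection.groups], dtype=int
        ),
        n_active_groups=collection.n_active_groups,
        scaled=collection.label == "data",
    )


# ---------------------------------------------------------------------------
# Plain-text table round trip
# ---------------------------------------------------------------------------

_HEADER = (
    "# collection\tlabel\tn_active_groups\tgroup\tn_active\t"
    "chain_a\tres_a\tsite_a\tchain_b\tres_b\tsite_b\tr1\tr2\tr3\tr4\tk"
)


def collections_to_table(collections: list[RestraintCollection]) -> str:
    """One restraint per line, tab-separated; anchors encoded in site_b."""
    lines = [_HEADER]
    for ci, col in enumerate(collections):
        for gi, grp in enumerate(col.groups):
            for r in grp.restraints:
                if r.site_b is not None:
                    b = (r.site_b[0], str(r.site_b[1]), r.site_b[2])
                else:
                    b = ("@", "0", ",".join(f"{x:.4f}" for x in r.anchor))
                lines.append(
                    "\t".join(
                        [
                            str(ci),
                            col.label,
                            str(col.n_active_groups),
                            str(gi),
                            str(grp.n_active),
                            r.site_a[0],
                            str(r.site_a[1]),
                            r.site_a[2],
                            *b,
                            f"{r.r1:g}",
                            f"{r.r2:g}",
                            f"{r.r3:g}",
                            f"{r.r4:g}",
                            f"{r.k:g}",
                        ]
                    )
                )
    return "\n".join(lines) + "\n"


def collections_from_table(text: str) -> list[RestraintCollection]:
    rows = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        f = ln.split("\t")
        if len(f) != 16:
            raise ValueError(f"malformed restraint line: {ln!r}")
        rows.append(f)
    cols: dict[int, dict] = {}
    for f in rows:
        ci = int(f[0])
        col = cols.setdefault(
            ci, {"label": f[1], "nag": int(f[2]), "groups": {}}
        )
        gi = int(f[3])
        grp = col["groups"].setdefault(gi, {"na": int(f[4]), "restraints": []})
        site_a = (f[5], int(f[6]), f[7])
        if f[8] == "@":
            site_b, anchor = None, tuple(float(x) for x in f[10].split(","))
        else:
            site_b, anchor = (f[8], int(f[9]), f[10]), None
        grp["restraints"].append(
            FlatBottomRestraint(
                site_a,
                site_b,
                float(f[11]),
                float(f[12]),
                float(f[13]),
                float(f[14]),
                float(f[15]),
                anchor=anchor,
            )
        )
    out = []
    for ci in sorted(cols):
        col = cols[ci]
        groups = [
            RestraintGroup(col["groups"][gi]["restraints"], col["groups"][gi]["na"])
            for gi in sorted(col["groups"])
        ]
        out.append(
            RestraintCollection(groups, col["nag"], label=col["label"])
        )
    return out
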