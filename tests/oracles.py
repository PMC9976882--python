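"""Independent brute-force oracles used by the tests.

Everything here deliberately ignores the library's selection shortcuts:
subset choices are exhaustively enumerated, derivatives come from finite
differences, and superposition minima from a rotation grid.
"""

from itertools import combinations

import numpy as np

from dnabind.model import BeadStructure, RestraintCollection, Site
from dnabind.restraints import flat_bottom_energy


def member_energies(group, structure, coords, scale=1.0):
    out = []
    for r in group.restraints:
        xa = coords[structure.index_of(*r.site_a)]
        if r.site_b is not None:
            xb = coords[structure.index_of(*r.site_b)]
        else:
            xb = np.asarray(r.anchor)
        out.append(flat_bottom_energy(float(np.linalg.norm(xa - xb)), r, scale))
    return np.asarray(out)


def brute_force_group_energy(group, structure, coords, scale=1.0):
    """Minimum total over all C(n, n_active) member subsets."""
    e = member_energies(group, structure, coords, scale)
    best = None
    for subset in combinations(range(len(e)), group.n_active):
        tot = float(e[list(subset)].sum())
        if best is None or tot < best:
            best = tot
    return best


def brute_force_collection_energy(collection, structure, coords, scale=1.0):
    """Minimum over all (group subset x per-group member subset) choices."""
    per_group = [
        brute_force_group_energy(g, structure, coords, scale)
        for g in collection.groups
    ]
    best = None
    for subset in combinations(range(len(per_group)), collection.n_active_groups):
        tot = sum(per_group[i] for i in subset)
        if best is None or tot < best:
            best = tot
    return best


def random_restraint_instance(rng, max_groups=5, max_restraints=5):
    """A random bead cloud plus a random restraint collection over it."""
    from dnabind.model import FlatBottomRestraint, RestraintGroup

    n_sites = 12
    sites = [
        Site("X", i + 1, "GEN", "CA", 0.0, 1.0, 1.0) for i in range(n_sites)
    ]
    coords = rng.uniform(-10, 10, size=(n_sites, 3))
    structure = BeadStructure(sites, coords)
    n_groups = int(rng.integers(1, max_groups + 1))
    groups = []
    for _ in range(n_groups):
        n_r = int(rng.integers(1, max_restraints + 1))
        restraints = []
        for _ in range(n_r):
            i, j = rng.choice(n_sites, size=2, replace=False)
            r2, r3 = np.sort(rng.uniform(0, 8, size=2))
            r1 = max(0.0, r2 - rng.uniform(0, 2))
            r4 = r3 + rng.uniform(0, 2)
            restraints.append(
                FlatBottomRestraint(
                    ("X", int(i) + 1, "CA"),
                    ("X", int(j) + 1, "CA"),
                    float(r1), float(r2), float(r3), float(r4),
                    k=float(rng.uniform(0.2, 2.0)),
                )
            )
        groups.append(RestraintGroup(restraints, int(rng.integers(1, n_r + 1))))
    collection = RestraintCollection(
        groups, int(rng.integers(1, n_groups + 1)), label="data"
    )
    return structure, collection


def grid_min_rmsd(X, Y, n_angles=40):
    """Exhaustive rotation-grid minimum RMSD (centered), reflection-free."""
    from scipy.spatial.transform import Rotation

    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    best = np.inf
    angles = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    for a in angles:
        for b in angles:
            for c in angles[: n_angles // 2]:
                R = Rotation.from_euler("zyz", [a, b, c])
                d = np.sqrt(((Xc - R.apply(Yc)) ** 2).sum(axis=1).mean())
                if d < best:
                    best = d
    return best
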