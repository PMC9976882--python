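"""Energy backends and propagators for the replica-exchange engine.

The production engine the method was designed around (all-atom MD in
implicit solvent) is replaced by a pluggable contract: anything exposing
``energy(coords)``, ``forces(coords)`` and a propagator can sit under the
sampler.  Two backends ship:

``DoubleWell1D``
    A one-particle toy, U(x) = a (x^2 - 1)^2 + b x, used for statistical
    validation of the replica-exchange machinery against the analytically
    integrable Boltzmann distribution.

``CGBeadModel``
    A coarse-grained bead model: harmonic bonds within molecules,
    Weeks-Chandler-Andersen excluded volume between molecules, and
    Debye-Hueckel screened electrostatics.  Reduced units: kT at the lowest
    replica is 1, distances in angstrom.

Propagation is either BAOAB Langevin dynamics (flexible beads) or
rigid-molecule Metropolis Monte Carlo (the workhorse for binding runs,
where the scaffold keeps each molecule internally near-rigid anyway).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import BeadStructure

__all__ = [
    "DoubleWell1D",
    "CGBeadModel",
    "ReplicaPotential",
    "langevin_baoab",
    "rigid_mc_sweep",
    "mc_sweep_1d",
]

# Bjerrum length of water at room temperature, in angstrom; sets the
# Coulomb prefactor in reduced units (U = l_B q_i q_j exp(-r/lambda)/r, kT=1).
BJERRUM_LENGTH = 7.0


class DoubleWell1D:
    """U(x) = a (x^2 - 1)^2 + b x; minima near x = +/-1, barrier a at x=0."""

    def __init__(self, a: float = 1.0, b: float = 0.0):
        self.a = float(a)
        self.b = float(b)

    def energy(self, coords: np.ndarray) -> float:
        x = float(np.asarray(coords).reshape(-1)[0])
        return self.a * (x * x - 1.0) ** 2 + self.b * x

    def forces(self, coords: np.ndarray) -> np.ndarray:
        x = np.asarray(coords, dtype=float)
        return -(4.0 * self.a * x * (x * x - 1.0) + self.b)

    def boltzmann_split(self, beta: float) -> tuple[float, float]:
        """Analytic (quadrature) Boltzmann weights of the x<0 and x>0 states."""
        from scipy.integrate import quad

        zl = quad(lambda x: np.exp(-beta * self.energy([x])), -8.0, 0.0)[0]
        zr = quad(lambda x: np.exp(-beta * self.energy([x])), 0.0, 8.0)[0]
        z = zl + zr
        return zl / z, zr / z


@dataclass
class CGBeadModel:
    """Coarse-grained pair potential over a :class:`BeadStructure`.

    Parameters
    ----------
    structure:
        Defines sites, charges, radii and the molecule partition.
    bonds:
        ``(i, j, r0)`` harmonic bonds (within molecules), spring ``k_bond``.
    epsilon:
        WCA well depth (reduced energy).
    bjerrum:
        Coulomb prefactor in angstrom (7 = water at room temperature).
    screening_length:
        Debye length in angstrom; ``inf`` recovers bare Coulomb.

    DUMMY sites are ghosts: excluded from all non-bonded terms (they exist
    only as restraint endpoints and ride rigidly on their parent site).
    """

    structure: BeadStructure
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    k_bond: float = 100.0
    epsilon: float = 1.0
    bjerrum: float = BJERRUM_LENGTH
    screening_length: float = 10.0

    def __post_init__(self) -> None:
        s = self.structure
        self._charge = np.asarray([x.charge for x in s.sites], dtype=float)
        self._radius = np.asarray([x.radius for x in s.sites], dtype=float)
        ghost = np.asarray([x.name == "DUMMY" for x in s.sites])
        mol = s.molecule_of_site()
        n = s.n_sites
        ii, jj = np.triu_indices(n, k=1)
        keep = (mol[ii] != mol[jj]) & ~ghost[ii] & ~ghost[jj]
        self._pi = ii[keep]
        self._pj = jj[keep]
        self._sigma = self._radius[self._pi] + self._radius[self._pj]
        self._qq = self._charge[self._pi] * self._charge[self._pj]
        self._bi = np.asarray([b[0] for b in self.bonds], dtype=int)
        self._bj = np.asarray([b[1] for b in self.bonds], dtype=int)
        self._b0 = np.asarray([b[2] for b in self.bonds], dtype=float)

    # -- energy terms --------------------------------------------------

    def _pair_r(self, coords: np.ndarray) -> np.ndarray:
        return np.linalg.norm(coords[self._pi] - coords[self._pj], axis=1)

    def energy_terms(self, coords: np.ndarray) -> dict[str, float]:
        out = {"bond": 0.0, "wca": 0.0, "elec": 0.0}
        if self._bi.size:
            rb = np.linalg.norm(coords[self._bi] - coords[self._bj], axis=1)
            out["bond"] = float(0.5 * self.k_bond * ((rb - self._b0) ** 2).sum())
        if self._pi.size:
            r = np.maximum(self._pair_r(coords), 1e-9)
            # WCA: purely repulsive LJ, truncated+shifted at 2^(1/6) sigma
            rc = 2.0 ** (1.0 / 6.0) * self._sigma
            m = r < rc
            if np.any(m):
                sr6 = (self._sigma[m] / r[m]) ** 6
                out["wca"] = float(
                    (4.0 * self.epsilon * (sr6 * sr6 - sr6) + self.epsilon).sum()
                )
            qq = self._qq
            nz = qq != 0.0
            if np.any(nz):
                rn = r[nz]
                if np.isinf(self.screening_length):
                    screen = 1.0
                else:
                    screen = np.exp(-rn / self.screening_length)
                out["elec"] = float((self.bjerrum * qq[nz] * screen / rn).sum())
        return out

    def energy(self, coords: np.ndarray) -> float:
        return float(sum(self.energy_terms(coords).values()))

    def forces(self, coords: np.ndarray) -> np.ndarray:
        f = np.zeros_like(coords)
        if self._bi.size:
            d = coords[self._bi] - coords[self._bj]
            r = np.maximum(np.linalg.norm(d, axis=1), 1e-9)
            fmag = -self.k_bond * (r - self._b0)  # dE/dr with minus sign
            fv = (fmag / r)[:, None] * d
            np.add.at(f, self._bi, fv)
            np.add.at(f, self._bj, -fv)
        if self._pi.size:
            d = coords[self._pi] - coords[self._pj]
            r = np.maximum(np.linalg.norm(d, axis=1), 1e-9)
            dedr = np.zeros_like(r)
            rc = 2.0 ** (1.0 / 6.0) * self._sigma
            m = r < rc
            if np.any(m):
                sr6 = (self._sigma[m] / r[m]) ** 6
                dedr[m] += 4.0 * self.epsilon * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r[m]
            nz = self._qq != 0.0
            if np.any(nz):
                rn = r[nz]
                if np.isinf(self.screening_length):
                    dedr[nz] += -self.bjerrum * self._qq[nz] / rn**2
                else:
                    lam = self.screening_length
                    dedr[nz] += (
                        -self.bjerrum
                        * self._qq[nz]
                        * np.exp(-rn / lam)
                        * (1.0 / rn**2 + 1.0 / (lam * rn))
                    )
            fv = (-dedr / r)[:, None] * d
            np.add.at(f, self._pi, fv)
            np.add.at(f, self._pj, -fv)
        return f


class ReplicaPotential:
    """Effective potential of one replica: backend + scaled restraints.

    This is the posterior energy the sampler Boltzmann-samples: the backend
    is the physical prior, the restraint term the (replica-scaled) data
    likelihood.
    """

    def __init__(self, backend, compiled_collections, replica_scale: float):
        self.backend = backend
        self.compiled = list(compiled_collections)
        self.replica_scale = float(replica_scale)

    def restraint_energy(self, coords: np.ndarray) -> float:
        return float(
            sum(c.energy(coords, self.replica_scale) for c in self.compiled)
        )

    def energy(self, coords: np.ndarray) -> float:
        return self.backend.energy(coords) + self.restraint_energy(coords)


# ---------------------------------------------------------------------------
# Propagators
# ---------------------------------------------------------------------------


def langevin_baoab(
    potential,
    coords: np.ndarray,
    masses: np.ndarray,
    n_steps: int,
    temperature: float,
    dt: float,
    gamma: float,
    rng: np.random.Generator,
    force_fn=None,
) -> np.ndarray:
    """BAOAB-splitting Langevin integrator in reduced units (k_B = 1).

    ``force_fn`` defaults to the backend's analytic forces plus a central
    finite difference of the restraint energy is NOT used — callers supply
    a full-force function when restraint forces are needed; the default
    integrates the backend alone.  Raises on energy explosion.
    """
    x = np.array(coords, dtype=float)
    m = np.asarray(masses, dtype=float).reshape(-1, 1)
    free = (m > 0).reshape(-1)
    v = np.zeros_like(x)
    v[free] = rng.normal(size=x[free].shape) * np.sqrt(temperature / m[free])
    f = force_fn(x) if force_fn else potential.backend.forces(x)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(np.maximum(1.0 - c1 * c1, 0.0))
    e0 = potential.energy(x)
    for _ in range(n_steps):
        v[free] += 0.5 * dt * f[free] / m[free]
        x[free] += 0.5 * dt * v[free]
        v[free] = c1 * v[free] + c2 * np.sqrt(temperature / m[free]) * rng.normal(
            size=v[free].shape
        )
        x[free] += 0.5 * dt * v[free]
        f = force_fn(x) if force_fn else potential.backend.forces(x)
        v[free] += 0.5 * dt * f[free] / m[free]
    e1 = potential.energy(x)
    if not np.isfinite(e1) or e1 > e0 + 1e6:
        raise RuntimeError(
            "energy explosion during Langevin dynamics; reduce the time step"
        )
    return x


def rigid_mc_sweep(
    potential,
    structure: BeadStructure,
    coords: np.ndarray,
    n_moves: int,
    temperature: float,
    rng: np.random.Generator,
    sigma_t: float = 1.5,
    sigma_r: float = 0.25,
    mobile_molecules: list[str] | None = None,
    swap_pair: tuple[str, str] | None = None,
    swap_prob: float = 0.0,
) -> tuple[np.ndarray, float, float]:
    """Rigid-molecule Metropolis MC: random translation+rotation per move.

    Each move picks a mobile molecule, applies a Gaussian translation and a
    rotation about its centroid, and accepts by the Metropolis rule on the
    replica's effective energy.  With ``swap_pair=(protein, other)`` and
    ``swap_prob > 0``, a fraction of moves instead proposes mapping the
    protein through the midplane between the two named molecules (the rigid
    map carrying one duplex frame onto the other) — a long-range move that
    lets a bound protein exchange partners without a full unbinding
    excursion; it is Metropolis-accepted like any other move, so it biases
    nothing.

    Returns (coords, final energy, acceptance fraction).
    """
    from scipy.spatial.transform import Rotation

    if mobile_molecules is None:
        mobile_molecules = list(structure.molecules)
    mol_idx = {m: structure.molecule_site_indices(m) for m in mobile_molecules}
    x = np.array(coords, dtype=float)
    e = potential.energy(x)
    beta = 1.0 / temperature
    accepted = 0
    # temperature-adapted step sizes: hotter replicas take bolder moves
    st = sigma_t * np.sqrt(temperature)
    for _ in range(n_moves):
        if swap_pair is not None and rng.random() < swap_prob:
            xnew = _propose_partner_swap(structure, x, swap_pair)
        else:
            m = mobile_molecules[rng.integers(len(mobile_molecules))]
            idx = mol_idx[m]
            xnew = x.copy()
            sub = xnew[idx]
            center = sub.mean(axis=0)
            rot = Rotation.from_rotvec(rng.normal(scale=sigma_r, size=3))
            xnew[idx] = rot.apply(sub - center) + center + rng.normal(scale=st, size=3)
        enew = potential.energy(xnew)
        if enew <= e or rng.random() < np.exp(-beta * (enew - e)):
            x, e = xnew, enew
            accepted += 1
    return x, e, accepted / max(n_moves, 1)


def _propose_partner_swap(
    structure: BeadStructure, coords: np.ndarray, pair: tuple[str, str]
) -> np.ndarray:
    """Rotate every molecule not in ``pair`` by pi about the two-fold axis
    between the two named molecules (self-inverse proper rotation).

    The axis runs through the midpoint of the two molecules' centroids,
    along the lab y direction projected orthogonal to the centroid-centroid
    line — the C2 axis of a competitive assembly built by
    :func:`dnabind.builders.competitive_system`.  For identical duplexes in
    their symmetric placement the move maps a pose bound to one duplex onto
    the energy-identical pose bound to the other.
    """
    ia = structure.molecule_site_indices(pair[0])
    ib = structure.molecule_site_indices(pair[1])
    ca = coords[ia].mean(axis=0)
    cb = coords[ib].mean(axis=0)
    sep = cb - ca
    nn = np.linalg.norm(sep)
    if nn < 1e-9:
        return coords.copy()
    sep = sep / nn
    axis = np.array([0.0, 1.0, 0.0]) - (np.array([0.0, 1.0, 0.0]) @ sep) * sep
    an = np.linalg.norm(axis)
    if an < 1e-9:  # degenerate: centroid line along y; fall back to z
        axis = np.array([0.0, 0.0, 1.0]) - (np.array([0.0, 0.0, 1.0]) @ sep) * sep
        an = np.linalg.norm(axis)
    u = axis / an
    mid = 0.5 * (ca + cb)
    xnew = coords.copy()
    fixed = set(ia.tolist()) | set(ib.tolist())
    other = np.asarray(
        [i for i in range(structure.n_sites) if i not in fixed], dtype=int
    )
    # Rodrigues for angle pi: x -> 2 u (u . x) - x
    rel = xnew[other] - mid
    xnew[other] = mid + 2.0 * np.outer(rel @ u, u) - rel
    return xnew


def mc_sweep_1d(
    potential,
    coords: np.ndarray,
    n_moves: int,
    temperature: float,
    rng: np.random.Generator,
    sigma: float = 0.5,
) -> tuple[np.ndarray, float, float]:
    """Metropolis random walk for the 1D toy backend."""
    x = float(np.asarray(coords).reshape(-1)[0])
    e = potential.energy([x])
    beta = 1.0 / temperature
    steps = rng.normal(scale=sigma, size=n_moves)
    us = rng.random(n_moves)
    accepted = 0
    for k in range(n_moves):
        xn = x + steps[k]
        en = potential.energy([xn])
        if en <= e or us[k] < np.exp(-beta * (en - e)):
            x, e = xn, en
            accepted += 1
    return np.asarray([[x, 0.0, 0.0]]), e, accepted / max(n_moves, 1)
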