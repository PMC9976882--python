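"""Hamiltonian/temperature replica exchange over pluggable backends.

Each replica holds a (temperature, restraint scale) condition from the
:class:`~dnabind.model.ReplicaLadder`.  Low rungs are cool with the data
restraints fully on (bound-compatible), high rungs hot with the data scaled
away (unbound-compatible).  Walkers migrate through the ladder via
nearest-neighbour Metropolis exchanges, going through cycles of binding and
unbinding; the lowest rung is the posterior ensemble used for analysis.

Per-replica random streams are spawned from the master seed, so results do
not depend on execution order, and Monte Carlo runs replay bit-identically
for a fixed (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .backends import (
    ReplicaPotential,
    mc_sweep_1d,
    rigid_mc_sweep,
)
from .model import (
    BeadStructure,
    Ensemble,
    Frame,
    ReplicaLadder,
    RestraintCollection,
)
from .restraints import compile_collection

__all__ = [
    "make_ladder",
    "make_replica_potentials",
    "exchange_probability",
    "run_remd",
    "MCMoveSpec",
]


def make_replica_potentials(
    backend,
    collections: list[RestraintCollection],
    structure: BeadStructure,
    ladder: ReplicaLadder,
) -> list[ReplicaPotential]:
    """One effective potential per rung: backend + restraints at that
    rung's scale (the form :func:`exchange_probability` consumes)."""
    compiled = [compile_collection(c, structure) for c in collections]
    return [
        ReplicaPotential(backend, compiled, s) for s in ladder.restraint_scales
    ]


def make_ladder(
    n_replicas: int = 30,
    t_min: float = 1.0,
    t_max: float = 3.0,
    scale_profile: str | Sequence[float] = "default",
    exchange_interval: int = 500,
) -> ReplicaLadder:
    """Geometric temperature ladder with a restraint-scale profile.

    The default profile holds the scale at 1 over the lowest third of the
    ladder and ramps linearly from 1 to 0 above it, so the top rung carries
    no data restraints at all.  ``scale_profile`` may also be an explicit
    sequence of per-replica scales.
    """
    if n_replicas < 2:
        raise ValueError("need at least 2 replicas")
    if not t_min < t_max:
        raise ValueError("require t_min < t_max")
    i = np.arange(n_replicas)
    temps = t_min * (t_max / t_min) ** (i / (n_replicas - 1))
    if isinstance(scale_profile, str):
        if scale_profile != "default":
            raise ValueError(f"unknown scale profile {scale_profile!r}")
        flat_top = max(1, int(np.floor(n_replicas / 3)))
        scales = np.ones(n_replicas)
        ramp = n_replicas - flat_top
        if ramp > 0:
            scales[flat_top:] = 1.0 - (np.arange(1, ramp + 1) / ramp)
        scales = np.clip(scales, 0.0, 1.0)
    else:
        scales = np.asarray(scale_profile, dtype=float)
    return ReplicaLadder(
        temperatures=temps.tolist(),
        restraint_scales=scales.tolist(),
        exchange_interval=exchange_interval,
    )


def exchange_probability(
    i: int,
    j: int,
    coords_i: np.ndarray,
    coords_j: np.ndarray,
    ladder: ReplicaLadder,
    potentials: Sequence[ReplicaPotential],
) -> float:
    """Metropolis acceptance for swapping configurations of replicas i, j.

    p = min(1, exp(beta_i U_i(x_i) + beta_j U_j(x_j)
                   - beta_i U_i(x_j) - beta_j U_j(x_i)))

    with U_k the replica-k effective energy (backend + restraints at that
    rung's scale) and beta_k = 1/T_k in reduced units.
    """
    bi = 1.0 / ladder.temperatures[i]
    bj = 1.0 / ladder.temperatures[j]
    delta = (
        bi * potentials[i].energy(coords_i)
        + bj * potentials[j].energy(coords_j)
        - bi * potentials[i].energy(coords_j)
        - bj * potentials[j].energy(coords_i)
    )
    return float(min(1.0, np.exp(min(delta, 700.0))))


@dataclass
class MCMoveSpec:
    """Monte Carlo move parameters for :func:`run_remd` in ``rigid_mc`` mode."""

    sigma_t: float = 1.5  # angstrom, at T=1 (scaled by sqrt(T))
    sigma_r: float = 0.25  # radians
    mobile_molecules: list[str] | None = None
    swap_pair: tuple[str, str] | None = None
    swap_prob: float = 0.0


def run_remd(
    system: BeadStructure | np.ndarray,
    collections: list[RestraintCollection],
    ladder: ReplicaLadder,
    backend,
    n_rounds: int,
    steps_per_round: int,
    seed: int,
    mode: str = "rigid_mc",
    move_spec: MCMoveSpec | None = None,
    mc_sigma_1d: float = 0.5,
    initial_coords: np.ndarray | None = None,
    progress: Callable[[int, float], None] | None = None,
) -> Ensemble:
    """Run replica exchange and return the recorded ensemble.

    Rounds alternate propagation (``steps_per_round`` moves per replica at
    its own temperature and restraint scale) with a nearest-neighbour
    exchange sweep over even pairs on even rounds and odd pairs on odd
    rounds.  One frame per replica is recorded at the end of every round;
    walker ids travel with the configurations.

    ``mode`` is ``rigid_mc`` (bead systems), ``mc_1d`` (the 1D toy) or
    ``langevin`` (flexible beads; restraint forces via the compiled
    collections are not included — Langevin mode is for backend-only
    validation).  ``n_rounds = 0`` records just the initial states.
    """
    is_structure = isinstance(system, BeadStructure)
    if is_structure:
        base_coords = system.coords if initial_coords is None else initial_coords
        compiled = [compile_collection(c, system) for c in collections]
    else:
        base_coords = np.asarray(system, dtype=float)
        compiled = []
        if collections:
            raise ValueError("restraint collections require a BeadStructure system")

    n_rep = ladder.n_replicas
    potentials = [
        ReplicaPotential(backend, compiled, ladder.restraint_scales[r])
        for r in range(n_rep)
    ]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_rep + 1)
    rngs = [np.random.default_rng(c) for c in children[:n_rep]]
    ex_rng = np.random.default_rng(children[n_rep])

    coords = [np.array(base_coords, dtype=float) for _ in range(n_rep)]
    walkers = list(range(n_rep))
    move_spec = move_spec or MCMoveSpec()

    frames: list[Frame] = []

    def record(rnd: int) -> None:
        for r in range(n_rep):
            e_r = potentials[r].restraint_energy(coords[r]) if compiled else 0.0
            e_p = backend.energy(coords[r])
            frames.append(
                Frame(
                    replica=r,
                    round_index=rnd,
                    walker=walkers[r],
                    coords=coords[r].astype(np.float32),
                    potential_energy=float(e_p),
                    restraint_energy=float(e_r),
                )
            )

    record(0)
    for rnd in range(1, n_rounds + 1):
        acc_sum = 0.0
        for r in range(n_rep):
            t = ladder.temperatures[r]
            if mode == "rigid_mc":
                coords[r], _, acc = rigid_mc_sweep(
                    potentials[r],
                    system,
                    coords[r],
                    steps_per_round,
                    t,
                    rngs[r],
                    sigma_t=move_spec.sigma_t,
                    sigma_r=move_spec.sigma_r,
                    mobile_molecules=move_spec.mobile_molecules,
                    swap_pair=move_spec.swap_pair,
                    swap_prob=move_spec.swap_prob,
                )
            elif mode == "mc_1d":
                coords[r], _, acc = mc_sweep_1d(
                    potentials[r], coords[r], steps_per_round, t, rngs[r], mc_sigma_1d
                )
            elif mode == "langevin":
                from .backends import langevin_baoab

                masses = np.asarray([s.mass for s in system.sites]) if is_structure else np.ones(1)
                coords[r] = langevin_baoab(
                    potentials[r], coords[r], masses, steps_per_round, t,
                    dt=0.005, gamma=1.0, rng=rngs[r],
                )
                acc = 1.0
            else:
                raise ValueError(f"unknown mode {mode!r}")
            if not np.isfinite(potentials[r].energy(coords[r])):
                raise RuntimeError(
                    f"NaN energy at replica {r}, round {rnd}; last valid state kept"
                )
            acc_sum += acc
        # nearest-neighbour exchange sweep, even/odd alternation
        start = 0 if rnd % 2 == 1 else 1
        for i in range(start, n_rep - 1, 2):
            p = exchange_probability(i, i + 1, coords[i], coords[i + 1], ladder, potentials)
            if ex_rng.random() < p:
                coords[i], coords[i + 1] = coords[i + 1], coords[i]
                walkers[i], walkers[i + 1] = walkers[i + 1], walkers[i]
        record(rnd)
        if progress is not None:
            progress(rnd, acc_sum / n_rep)

    return Ensemble(frames=frames, ladder=ladder).validate()
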