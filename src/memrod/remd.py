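"""Hamiltonian replica exchange over the rod curvature C_rod.

All replicas share one temperature; adjacent replicas periodically attempt
to swap their C_rod labels with the Metropolis probability
``min(1, exp(-dU/kT))`` where

    dU = [U_a(C_b) + U_b(C_a)] - [U_a(C_a) + U_b(C_b)].

Only the intra-rod bend energy depends on C_rod (through the pair C_bd), so
dU is evaluated from the rod bend/tilt terms alone.  A swap moves labels,
never configurations, so the multiset of sampled configurations is
unchanged by exchanges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Trajectory
from .dynamics import LangevinIntegrator
from .potentials import rod_cbd_for_curvature

__all__ = ["ReplicaLadder", "rod_bend_energy_at", "attempt_exchange",
           "run_remd", "default_ladder"]


@dataclass
class ReplicaLadder:
    c_rod_values: np.ndarray
    exchange_interval: int = 500
    seeds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.c_rod_values = np.asarray(self.c_rod_values, dtype=float)
        if len(self.c_rod_values) > 1 and np.any(
                np.diff(self.c_rod_values) <= 0):
            raise ValueError("C_rod ladder must be strictly increasing")
        if self.seeds is None:
            self.seeds = np.arange(len(self.c_rod_values))
        self.seeds = np.asarray(self.seeds)

    def __len__(self) -> int:
        return len(self.c_rod_values)


def default_ladder(r_rod: float = 10.0, lo: float = 0.0, hi: float = 3.5,
                   spacing: float = 0.25, **kw) -> ReplicaLadder:
    """Uniform ladder in C_rod * r_rod over the scan range [0, 3.5]."""
    vals = np.arange(lo, hi + 0.5 * spacing, spacing) / r_rod
    return ReplicaLadder(vals, **kw)


def rod_bend_energy_at(integ: LangevinIntegrator, c_rod: float) -> float:
    """Intra-rod bend/tilt energy of a replica evaluated under a given C_rod."""
    cbd = rod_cbd_for_curvature(integ.spec.copy(c_rod=c_rod), integ.params)
    energy, _, _, _ = integ.ff.compute(integ.state, integ.box,
                                       zero_membrane=True, zero_pairwise=True,
                                       zero_bonds=True, cbd_rod_override=cbd)
    return energy.u_bend + energy.u_tilt


def attempt_exchange(rep_a: LangevinIntegrator, rep_b: LangevinIntegrator,
                     rng: np.random.Generator) -> bool:
    """Metropolis swap of the C_rod labels of two replicas."""
    ca = rep_a.spec.c_rod
    cb = rep_b.spec.c_rod
    du = (rod_bend_energy_at(rep_a, cb) + rod_bend_energy_at(rep_b, ca)
          - rod_bend_energy_at(rep_a, ca) - rod_bend_energy_at(rep_b, cb))
    if du <= 0 or rng.random() < np.exp(-du / rep_a.cfg.kbt):
        rep_a.set_c_rod(cb)
        rep_b.set_c_rod(ca)
        return True
    return False


@dataclass
class ExchangeStats:
    attempts: np.ndarray
    accepts: np.ndarray
    log: list = field(default_factory=list)     # (sweep, pair, dU-ish, outcome)
    visits: list = field(default_factory=list)  # label index per replica per sweep

    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.attempts > 0, self.accepts / self.attempts,
                            np.nan)

    def round_trips(self) -> np.ndarray:
        """Completed bottom-to-top-to-bottom label excursions per replica."""
        if not self.visits:
            return np.zeros(0, dtype=int)
        v = np.asarray(self.visits)            # (sweeps, n_replicas)
        n_rep = v.shape[1]
        trips = np.zeros(n_rep, dtype=int)
        top = v.max()
        for r in range(n_rep):
            stage = 0  # 0: seek bottom, 1: seek top, 2: seek bottom again
            for lab in v[:, r]:
                if stage == 0 and lab == 0:
                    stage = 1
                elif stage == 1 and lab == top:
                    stage = 2
                elif stage == 2 and lab == 0:
                    trips[r] += 1
                    stage = 1
            trips[r] = trips[r]
        return trips


def run_remd(ladder: ReplicaLadder, make_replica, n_sweeps: int,
             stride_frames: int = 1, master_seed: int = 0):
    """Run REMD: ``make_replica(c_rod, seed) -> LangevinIntegrator``.

    Each sweep advances every replica ``exchange_interval`` steps, then
    attempts swaps between adjacent C_rod labels with alternating parity.
    Returns ``(trajectories, stats)`` where ``trajectories`` maps each
    C_rod value to the demultiplexed :class:`Trajectory` of frames sampled
    under that curvature.
    """
    n_rep = len(ladder)
    reps = [make_replica(ladder.c_rod_values[i], int(ladder.seeds[i]))
            for i in range(n_rep)]
    rng = np.random.default_rng(master_seed)
    label_of = {float(c): i for i, c in enumerate(ladder.c_rod_values)}
    trajs = {float(c): Trajectory(metadata={"c_rod": float(c)})
             for c in ladder.c_rod_values}
    stats = ExchangeStats(np.zeros(max(n_rep - 1, 1), dtype=int),
                          np.zeros(max(n_rep - 1, 1), dtype=int))
    for sweep in range(n_sweeps):
        for rep in reps:
            rep.step(ladder.exchange_interval)
            if not np.isfinite(rep.energy.total):
                raise FloatingPointError("replica diverged (non-finite energy)")
        # demultiplex frames by current label
        if sweep % stride_frames == 0:
            for rep in reps:
                c = float(rep.spec.c_rod)
                trajs[c].append(rep.state, rep.time + 1e-12 * sweep, rep.box)
        # adjacent swaps, alternating parity; pairs ordered by current label
        order = np.argsort([rep.spec.c_rod for rep in reps])
        start = sweep % 2
        for k in range(start, n_rep - 1, 2):
            a, b = reps[order[k]], reps[order[k + 1]]
            stats.attempts[k] += 1
            if attempt_exchange(a, b, rng):
                stats.accepts[k] += 1
                stats.log.append((sweep, k, "swap", True))
            else:
                stats.log.append((sweep, k, "swap", False))
        stats.visits.append([label_of[float(rep.spec.c_rod)] for rep in reps])
    return trajs, stats
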