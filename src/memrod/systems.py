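"""Builders for the three experiment geometries.

* membrane tube: N particles on a cylinder of radius ``R_cyl`` with imposed
  periodic length ``L_z`` (the standard study geometries tie the length to the
  particle number, ``L_z / r_rod = 0.00167 N`` for ``R_cyl / r_rod = 1.18``
  and ``0.0015 N`` for ``1.31``); the radius is an initial condition only
  and relaxes freely during a run;
* tensionless flat membrane: square periodic patch whose area is sampled by
  Monte-Carlo area moves at zero imposed tension;
* membrane strip: a flat band spanning the periodic x direction with two
  free edges, used for the edge-line-tension measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (ParticleState, SimulationBox, MembraneParams, RodSpec,
                   TOPOLOGY_FLAT, TOPOLOGY_TUBE)
from .dynamics import IntegratorConfig, LangevinIntegrator

__all__ = ["TubeSpec", "FlatSpec", "tube_geometry", "build_tube",
           "build_flat_patch", "build_flat_tensionless", "build_strip",
           "prepare_tubulation", "A0_REF"]

A0_REF = 1.2778   # target area per particle of the tensionless membrane


@dataclass
class TubeSpec:
    n: int
    r_cyl: float          # initial tube radius, sigma
    l_z: float            # imposed periodic length, sigma
    a0: float = A0_REF

    def __post_init__(self) -> None:
        area = 2.0 * np.pi * self.r_cyl * self.l_z
        if abs(area - self.n * self.a0) > 0.10 * self.n * self.a0:
            raise ValueError(
                f"inconsistent tube: area {area:.1f} vs N a0 "
                f"{self.n * self.a0:.1f} (>10% mismatch)")


@dataclass
class FlatSpec:
    n: int
    a0: float = A0_REF    # initial area per particle
    tension: float = 0.0  # target frame tension (0 = tensionless)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("N must be positive")


def tube_geometry(n: int, radius_ratio: float, r_rod: float = 10.0) -> TubeSpec:
    """The standard tube geometries: L_z tied to N through the radius.

    ``radius_ratio = R_cyl / r_rod`` of 1.18 pairs with
    ``L_z / r_rod = 0.00167 N``; 1.31 pairs with ``0.0015 N``.
    """
    if abs(radius_ratio - 1.18) < 1e-9:
        lz = 0.00167 * n * r_rod
    elif abs(radius_ratio - 1.31) < 1e-9:
        lz = 0.0015 * n * r_rod
    else:
        raise ValueError("standard geometries use R_cyl/r_rod = 1.18 or 1.31")
    return TubeSpec(n=n, r_cyl=radius_ratio * r_rod, l_z=lz)


def _near_square_grid(n: int, aspect: float):
    """Factor n ~= nx * ny with nx/ny close to the requested aspect."""
    best = None
    for nx in range(2, n):
        ny = int(round(n / nx))
        if ny < 2:
            break
        score = abs(nx - aspect * ny) / max(nx, 1) + abs(nx * ny - n) / n * 5.0
        if best is None or score < best[0]:
            best = (score, nx, ny)
    _, nx, ny = best
    return nx, ny


def build_flat_patch(spec: FlatSpec, seed: int = 0,
                     jitter: float = 0.05) -> tuple:
    """Triangular-lattice flat patch; orientations along +z.

    The particle count is rounded to the nearest nx * ny factorization with
    a near-square box; the realized N is ``state.n``.
    """
    rng = np.random.default_rng(seed)
    s = np.sqrt(2.0 * spec.a0 / np.sqrt(3.0))    # lattice constant
    nx, ny = _near_square_grid(spec.n, np.sqrt(3.0) / 2.0)
    lx = nx * s
    ly = ny * s * np.sqrt(3.0) / 2.0
    xs = []
    for iy in range(ny):
        off = 0.5 * s if iy % 2 else 0.0
        for ix in range(nx):
            xs.append((ix * s + off, iy * s * np.sqrt(3.0) / 2.0, 0.0))
    pos = np.asarray(xs)
    pos[:, :2] += rng.uniform(-jitter, jitter, (len(pos), 2))
    orient = np.tile([0.0, 0.0, 1.0], (len(pos), 1))
    state = ParticleState.membrane_only(pos, orient)
    box = SimulationBox([lx, ly, max(20.0, 6.0)], TOPOLOGY_FLAT)
    return state, box


def build_tube(spec: TubeSpec, seed: int = 0, relax_steps: int = 0,
               params: MembraneParams | None = None) -> tuple:
    """Particles on a cylinder (axis z), orientations along the outward normal."""
    rng = np.random.default_rng(seed)
    s = np.sqrt(2.0 * spec.a0 / np.sqrt(3.0))
    # the standard geometries carry a few % more particles than
    # 2 pi R L_z / a0 (that excess area feeds the shape deformations);
    # build at a slightly larger radius so the lattice is never compressed
    r_build = max(spec.r_cyl,
                  0.98 * spec.n * spec.a0 / (2.0 * np.pi * spec.l_z))
    circumference = 2.0 * np.pi * r_build
    n_th = max(3, int(round(circumference / s)))
    n_z = max(1, int(np.ceil(spec.n / n_th)))
    dz = spec.l_z / n_z
    pos, orient = [], []
    count = 0
    for iz in range(n_z):
        off = 0.5 if iz % 2 else 0.0
        # the last (partial) ring spreads its particles evenly in angle
        in_row = min(n_th, spec.n - count)
        if in_row <= 0:
            break
        for it in range(in_row):
            th = 2.0 * np.pi * (it + off) / (n_th if in_row == n_th
                                             else in_row)
            th += rng.uniform(-0.02, 0.02) / r_build   # ~0.02 sigma jitter
            pos.append((r_build * np.cos(th), r_build * np.sin(th),
                        iz * dz))
            orient.append((np.cos(th), np.sin(th), 0.0))
            count += 1
    state = ParticleState.membrane_only(np.asarray(pos), np.asarray(orient))
    box = SimulationBox([4 * spec.r_cyl + 20, 4 * spec.r_cyl + 20, spec.l_z],
                        TOPOLOGY_TUBE)
    if relax_steps and params is not None:
        integ = LangevinIntegrator(state, box, params,
                                   cfg=IntegratorConfig(seed=seed))
        integ.step(relax_steps)
        state = integ.state
    return state, box


def build_strip(n: int, params: MembraneParams | None = None, seed: int = 0,
                a0: float = A0_REF, width_rows: int | None = None) -> tuple:
    """Flat band spanning the periodic x direction with two free edges.

    The band fills roughly half of the y extent of the box so the edges
    cannot interact through the periodic image.
    """
    rng = np.random.default_rng(seed)
    s = np.sqrt(2.0 * a0 / np.sqrt(3.0))
    ny = width_rows or max(6, int(round(np.sqrt(n / 2.0))))
    nx = max(6, int(round(n / ny)))
    lx = nx * s
    wy = ny * s * np.sqrt(3.0) / 2.0
    ly = 2.5 * wy
    xs = []
    for iy in range(ny):
        off = 0.5 * s if iy % 2 else 0.0
        for ix in range(nx):
            xs.append((ix * s + off, 0.5 * (ly - wy) + iy * s * np.sqrt(3.0) / 2.0,
                       0.0))
    pos = np.asarray(xs)
    pos[:, :2] += rng.uniform(-0.05, 0.05, (len(pos), 2))
    orient = np.tile([0.0, 0.0, 1.0], (len(pos), 1))
    state = ParticleState.membrane_only(pos, orient)
    box = SimulationBox([lx, ly, 20.0], TOPOLOGY_FLAT)
    return state, box


def build_flat_tensionless(spec: FlatSpec, params: MembraneParams,
                           seed: int = 0, equil_steps: int = 20000,
                           cfg: IntegratorConfig | None = None,
                           area_interval: int = 20,
                           dlnA_max: float = 0.002) -> LangevinIntegrator:
    """Build a flat patch and equilibrate it in the zero-tension ensemble.

    Returns the integrator (state/box inside) after ``equil_steps`` of
    Langevin dynamics interleaved with MC area moves.  Convergence is
    checked on the drift of the area per particle over the last two
    quarters of the equilibration.
    """
    state, box = build_flat_patch(spec, seed=seed)
    cfg = cfg or IntegratorConfig(seed=seed)
    integ = LangevinIntegrator(state, box, params, cfg=cfg)
    areas = []
    done = 0
    while done < equil_steps:
        integ.step(area_interval)
        done += area_interval
        integ.mc_area_move(dlnA_max)
        areas.append(integ.box.area_xy / integ.state.n)
    q = len(areas) // 4
    if q >= 2:
        drift = abs(np.mean(areas[-q:]) - np.mean(areas[-2 * q:-q]))
        scale = np.std(areas[-2 * q:]) / np.sqrt(q) + 1e-12
        if drift > 6.0 * scale and drift > 0.025:
            raise RuntimeError(
                f"tensionless controller not converged (drift {drift:.4g})")
    return integ


def prepare_tubulation(n: int, phi_rod: float, c_rod_target: float,
                       spec: RodSpec, params: MembraneParams, seed: int = 0,
                       equil_steps: int = 20000,
                       production_steps: int = 100000,
                       cfg: IntegratorConfig | None = None):
    """Tubulation protocol: equilibrate rods at c_rod = 0 on a tensionless
    flat membrane, then switch the curvature to the target at t = 0.

    Returns ``(integrator, schedule)``; feed both to
    :func:`memrod.dynamics.run`.  ``phi_rod`` is realized by embedding
    ``round(phi_rod * N / 10)`` rods.
    """
    from .rods import embed_rods

    state, box = build_flat_patch(FlatSpec(n=n), seed=seed)
    n_rods = int(round(phi_rod * state.n / spec.n_backbone))
    cfg = cfg or IntegratorConfig(seed=seed, dt=0.002)
    if n_rods > 0:
        # brief membrane pre-relaxation before carving rods out of it
        pre = LangevinIntegrator(state, box, params, cfg=cfg)
        pre.step(500)
        state = pre.state
        state = embed_rods(state, n_rods, spec.copy(c_rod=0.0), box, seed=seed)
        # gentle quench defuses residual insertion overlaps without
        # ejecting particles (strong friction, small step, low force cap)
        quench_cfg = IntegratorConfig(seed=seed, dt=0.0005, gamma_t=5.0,
                                      gamma_r=5.0, f_clamp=500.0)
        quench = LangevinIntegrator(state, box, params,
                                    spec.copy(c_rod=0.0), quench_cfg)
        quench.step(2000)
        state = quench.state
    integ = LangevinIntegrator(state, box, params, spec.copy(c_rod=0.0), cfg)
    schedule = [
        (equil_steps, {"zero_tension": True}),
        (production_steps, {"c_rod": c_rod_target, "zero_tension": True}),
    ]
    return integ, schedule
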