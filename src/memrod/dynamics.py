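"""Langevin dynamics for positions and orientations.

Translations follow underdamped Langevin dynamics integrated with the
BAOAB splitting.  Orientations are unit vectors evolved as rigid linear
rotors: an angular velocity ``omega_i`` (kept perpendicular to ``u_i``, two
rotational degrees of freedom) is driven by the torque ``-u x dU/du``,
damped and thermalized the same way, and ``u_i`` is rotated exactly about
``omega_i`` so its norm never drifts.

The time step is quoted in intrinsic units ``sigma (m / k_B T)^{1/2}``.
Physical results are reported against ``tau = r_rod^2 / D`` with ``D`` the
membrane-particle in-plane diffusion coefficient of the tensionless
membrane, which :func:`measure_diffusion` estimates; the friction and time
step themselves therefore never enter any reported quantity.

A zero-tension ensemble for flat patches is provided by Monte-Carlo area
moves (:meth:`LangevinIntegrator.mc_area_move`): symmetric proposals in
``ln A`` accepted with probability ``min(1, exp(-beta dU + (N+1) dlnA))``,
which samples the exact zero-tension distribution so that both the mean
area and its fluctuations (area compressibility) are meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .core import ParticleState, SimulationBox, MembraneParams, RodSpec
from .potentials import ForceField, rod_cbd_for_curvature

__all__ = ["IntegratorConfig", "LangevinIntegrator", "run", "measure_diffusion",
           "measure_tension", "save_checkpoint", "load_checkpoint"]


@dataclass
class IntegratorConfig:
    dt: float = 0.004
    gamma_t: float = 0.5        # translational friction (low: faster diffusion)
    gamma_r: float = 0.5        # rotational friction
    mass: float = 1.0
    inertia: float = 1.0
    kbt: float = 1.0
    seed: int = 0
    skin: float = 0.4
    thermostat: bool = True
    z_spring: float = 0.0   # weak flattening restraint (z only; no x,y virial)
    f_clamp: float = 1e4    # per-particle force cap (displacement limiting)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.gamma_t < 0 or self.gamma_r < 0:
            raise ValueError("frictions must be non-negative")


def _rotate_about(u: np.ndarray, axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of each row of u about each row of axis (unit)."""
    c = np.cos(angle)[:, None]
    s = np.sin(angle)[:, None]
    dot = (axis * u).sum(axis=1, keepdims=True)
    return u * c + np.cross(axis, u) * s + axis * dot * (1.0 - c)


class LangevinIntegrator:
    """Owns the evolving state; positions are kept unwrapped."""

    MAX_FORCE = 1e6

    def __init__(self, state: ParticleState, box: SimulationBox,
                 params: MembraneParams, spec: RodSpec | None = None,
                 cfg: IntegratorConfig | None = None,
                 init_velocities: bool = True):
        self.cfg = cfg or IntegratorConfig()
        self.state = state.copy()
        self.state.normalize_orientations()
        self.box = box.copy()
        self.params = params
        self.spec = spec
        self.ff = ForceField(params, spec, self.state, skin=self.cfg.skin)
        self.rng = np.random.default_rng(self.cfg.seed)
        n = self.state.n
        self.vel = np.zeros((n, 3))
        self.omega = np.zeros((n, 3))
        if init_velocities and self.cfg.thermostat:
            kt, m, i_r = self.cfg.kbt, self.cfg.mass, self.cfg.inertia
            self.vel = self.rng.normal(0.0, np.sqrt(kt / m), (n, 3))
            self.omega = self._project(self.rng.normal(0.0, np.sqrt(kt / i_r), (n, 3)))
        self.time = 0.0
        self.nsteps_done = 0
        self.mc_attempts = 0
        self.mc_accepts = 0
        self._recompute()

    # -- forces ------------------------------------------------------------
    def _project(self, w: np.ndarray) -> np.ndarray:
        u = self.state.orient
        return w - (w * u).sum(axis=1, keepdims=True) * u

    def _recompute(self) -> None:
        self.energy, self.forces, gu, self.virial = self.ff.compute(
            self.state, self.box)
        if self.cfg.z_spring > 0.0:
            dz = self.state.pos[:, 2] - self.state.pos[:, 2].mean()
            self.forces[:, 2] -= self.cfg.z_spring * dz
        if not np.all(np.isfinite(self.forces)):
            raise FloatingPointError("non-finite force (catastrophic overlap?)")
        if self.cfg.f_clamp > 0:
            # cap rare deep-overlap spikes (states this high in energy are
            # never sampled in equilibrium; the cap only limits displacement)
            norms = np.linalg.norm(self.forces, axis=1)
            over = norms > self.cfg.f_clamp
            if over.any():
                self.forces[over] *= (self.cfg.f_clamp / norms[over])[:, None]
        fmax = np.abs(self.forces).max() if self.state.n else 0.0
        if fmax > self.MAX_FORCE:
            raise FloatingPointError(
                f"force overflow ({fmax:.3g}): particles overlap too deeply")
        self.torque = -np.cross(self.state.orient, gu)

    def set_c_rod(self, c_rod: float) -> None:
        """Switch the rod spontaneous curvature (tubulation / REMD protocols)."""
        if self.spec is None:
            raise ValueError("no rod spec attached")
        self.spec = self.spec.copy(c_rod=c_rod)
        self.ff.spec = self.spec
        self.ff.cbd_rod = rod_cbd_for_curvature(self.spec, self.params)
        self._recompute()

    # -- integration -------------------------------------------------------
    def step(self, nsteps: int = 1) -> None:
        cfg = self.cfg
        dt = cfg.dt
        m, i_r, kt = cfg.mass, cfg.inertia, cfg.kbt
        if cfg.thermostat:
            c1t = np.exp(-cfg.gamma_t * dt)
            c2t = np.sqrt(kt / m * (1.0 - c1t * c1t))
            c1r = np.exp(-cfg.gamma_r * dt)
            c2r = np.sqrt(kt / i_r * (1.0 - c1r * c1r))
        st = self.state
        for _ in range(nsteps):
            self.vel += 0.5 * dt * self.forces / m
            self.omega = self._project(self.omega + 0.5 * dt * self.torque / i_r)
            self._advance_positions(0.5 * dt)
            if cfg.thermostat:
                self.vel = c1t * self.vel + c2t * self.rng.normal(size=self.vel.shape)
                self.omega = self._project(
                    c1r * self.omega + c2r * self.rng.normal(size=self.omega.shape))
            self._advance_positions(0.5 * dt)
            self._recompute()
            self.vel += 0.5 * dt * self.forces / m
            self.omega = self._project(self.omega + 0.5 * dt * self.torque / i_r)
            self.time += dt
            self.nsteps_done += 1

    def _advance_positions(self, h: float) -> None:
        st = self.state
        st.pos += h * self.vel
        wmag = np.linalg.norm(self.omega, axis=1)
        moving = wmag > 1e-14
        if moving.any():
            axis = np.zeros_like(self.omega)
            axis[moving] = self.omega[moving] / wmag[moving, None]
            st.orient[moving] = _rotate_about(st.orient[moving], axis[moving],
                                              wmag[moving] * h)
            norms = np.linalg.norm(st.orient, axis=1, keepdims=True)
            st.orient /= norms

    # -- zero-tension area sampling ---------------------------------------
    def mc_area_move(self, dlnA_max: float = 0.002) -> bool:
        """One Monte-Carlo area move (flat topology only)."""
        if self.box.topology != "flat":
            raise ValueError("area moves only apply to flat patches")
        self.mc_attempts += 1
        delta = self.rng.uniform(-dlnA_max, dlnA_max)
        s = np.exp(0.5 * delta)
        old_pos = self.state.pos.copy()
        old_box = self.box.copy()
        e_old = self.energy.total
        self.state.pos[:, 0] *= s
        self.state.pos[:, 1] *= s
        self.box.lengths[0] *= s
        self.box.lengths[1] *= s
        self.ff.refresh_pairs(self.state, self.box)
        e_new = self.ff.compute(self.state, self.box)[0].total
        n = self.state.n
        log_acc = -(e_new - e_old) / self.cfg.kbt + (n + 1) * delta
        if np.log(self.rng.random() + 1e-300) < log_acc:
            self.mc_accepts += 1
            self._recompute()
            return True
        self.state.pos = old_pos
        self.box = old_box
        self.ff.refresh_pairs(self.state, self.box)
        self._recompute()
        return False

    def rescale_area(self, factor: float) -> None:
        """Deterministic affine in-plane rescaling (Berendsen-style control)."""
        s = np.sqrt(factor)
        self.state.pos[:, 0] *= s
        self.state.pos[:, 1] *= s
        self.box.lengths[0] *= s
        self.box.lengths[1] *= s
        self._recompute()

    # -- measurements ------------------------------------------------------
    def instantaneous_tension(self) -> float:
        """Mechanical in-plane tension of a flat patch from the pair virial.

        gamma = -(N k_B T + (W_xx + W_yy)/2) / A; positive when stretched.
        """
        wxx, wyy, _ = self.virial
        n = self.state.n
        a = self.box.area_xy
        return -(n * self.cfg.kbt + 0.5 * (wxx + wyy)) / a

    def axial_virial_force(self) -> float:
        """Excess contractile force along x of a strip spanning x.

        Uses the stress anisotropy (W_yy - W_xx) / L_x, which cancels the
        isotropic membrane contribution (including undulation softening and
        kinetic terms; the free edges enforce <N kT + W_yy> = 0) and leaves
        the edge pull, 2 Gamma.
        """
        return (self.virial[1] - self.virial[0]) / self.box.lengths[0]

    def kinetic_energy(self) -> tuple:
        ke_t = 0.5 * self.cfg.mass * float((self.vel ** 2).sum())
        ke_r = 0.5 * self.cfg.inertia * float((self.omega ** 2).sum())
        return ke_t, ke_r


def run(integrator: LangevinIntegrator, schedule, stride: int = 500,
        trajectory=None):
    """Execute a protocol: a list of ``(n_steps, overrides)`` phases.

    ``overrides`` is a dict; supported keys: ``c_rod`` (switched exactly at
    the phase start, as in the tubulation protocol), ``zero_tension`` (bool:
    run MC area moves every ``area_interval`` steps), ``area_interval``,
    ``dlnA_max``.  Returns a :class:`memrod.core.Trajectory` with a frame
    every ``stride`` steps and metadata recording the switch times.
    """
    from .core import Trajectory

    traj = trajectory if trajectory is not None else Trajectory()
    if not traj.frames:
        traj.metadata.update({
            "seed": integrator.cfg.seed,
            "c_rod": getattr(integrator.spec, "c_rod", None),
            "epsilon_ss": getattr(integrator.spec, "epsilon_ss", None),
            "n": integrator.state.n,
            "topology": integrator.box.topology,
            "switch_times": [],
        })
        traj.append(integrator.state, integrator.time - integrator.cfg.dt * 1e-9,
                    integrator.box)
        # the initial frame is stamped an infinitesimal step early so that
        # the t = 0 production frame can be appended at exactly time 0
    for n_steps, overrides in schedule:
        overrides = overrides or {}
        if "c_rod" in overrides:
            integrator.set_c_rod(overrides["c_rod"])
            traj.metadata["switch_times"].append(integrator.time)
        zero_tension = overrides.get("zero_tension", False)
        interval = int(overrides.get("area_interval", 20))
        dln = float(overrides.get("dlnA_max", 0.002))
        done = 0
        while done < n_steps:
            chunk = min(stride, n_steps - done)
            if zero_tension:
                sub = 0
                while sub < chunk:
                    block = min(interval, chunk - sub)
                    integrator.step(block)
                    sub += block
                    integrator.mc_area_move(dln)
            else:
                integrator.step(chunk)
            done += chunk
            traj.append(integrator.state, integrator.time, integrator.box)
    return traj


def measure_tension(integrator: LangevinIntegrator, steps: int,
                    sample_every: int = 10, equil: int = 0):
    """Time-averaged in-plane tension with a block standard error."""
    if equil:
        integrator.step(equil)
    vals = []
    done = 0
    while done < steps:
        integrator.step(sample_every)
        done += sample_every
        vals.append(integrator.instantaneous_tension())
    vals = np.asarray(vals)
    nb = max(1, len(vals) // 10)
    blocks = np.array_split(vals, nb)
    means = np.array([b.mean() for b in blocks])
    se = means.std(ddof=1) / np.sqrt(len(means)) if len(means) > 1 else np.inf
    return float(vals.mean()), float(se)


def measure_diffusion(integrator: LangevinIntegrator, steps: int,
                      sample_every: int = 50, fit_fraction=(0.15, 0.6),
                      r_rod: float = 10.0):
    """In-plane diffusion coefficient D and tau = r_rod^2 / D.

    Tracks the in-plane mean-square displacement of membrane particles over
    the run (positions are unwrapped) and fits MSD = 4 D t over the tail
    window.  Raises if the MSD is visibly non-linear there (R^2 < 0.9).
    """
    st = integrator.state
    mask = st.kind == 0
    snaps = [st.pos[mask][:, :2].copy()]
    done = 0
    while done < steps:
        integrator.step(sample_every)
        done += sample_every
        snaps.append(integrator.state.pos[mask][:, :2].copy())
    snaps = np.asarray(snaps)                     # (n_t, n_p, 2)
    n_t = len(snaps)
    # multiple-time-origin MSD
    lags = np.arange(1, n_t)
    msds = np.empty(len(lags))
    for k, lag in enumerate(lags):
        d = snaps[lag:] - snaps[:-lag or None]
        msds[k] = float((d ** 2).sum(axis=2).mean())
    times = lags * sample_every * integrator.cfg.dt
    lo = int(fit_fraction[0] * len(times))
    hi = int(fit_fraction[1] * len(times))
    t_fit, m_fit = times[lo:hi], msds[lo:hi]
    slope, intercept = np.polyfit(t_fit, m_fit, 1)
    pred = slope * t_fit + intercept
    ss_res = ((m_fit - pred) ** 2).sum()
    ss_tot = ((m_fit - m_fit.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if r2 < 0.9 or slope <= 0:
        raise RuntimeError("non-diffusive regime: MSD not linear in fit window")
    d_coeff = slope / 4.0
    return d_coeff, r_rod ** 2 / d_coeff


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(integrator: LangevinIntegrator, path) -> None:
    """Self-describing HDF5 checkpoint; restart reproduces the run exactly.

    The neighbor list is refreshed before saving so that the saved run and
    a restart continue from the same (deterministically rebuilt) pair list
    and produce bitwise-identical trajectories.
    """
    import h5py

    integrator.ff.refresh_pairs(integrator.state, integrator.box)
    integrator._recompute()
    st = integrator.state
    with h5py.File(path, "w") as f:
        f.attrs["time"] = integrator.time
        f.attrs["nsteps_done"] = integrator.nsteps_done
        f.attrs["topology"] = integrator.box.topology
        f.attrs["rng_state"] = json.dumps(integrator.rng.bit_generator.state)
        f.attrs["cfg"] = json.dumps(asdict(integrator.cfg))
        f.create_dataset("lengths", data=integrator.box.lengths)
        for name in ("pos", "orient", "kind", "rod_id", "seg"):
            f.create_dataset(name, data=getattr(st, name))
        f.create_dataset("vel", data=integrator.vel)
        f.create_dataset("omega", data=integrator.omega)


def load_checkpoint(path, params: MembraneParams, spec: RodSpec | None = None
                    ) -> LangevinIntegrator:
    import h5py

    with h5py.File(path, "r") as f:
        box = SimulationBox(f["lengths"][:], f.attrs["topology"])
        st = ParticleState(f["pos"][:], f["orient"][:], f["kind"][:],
                           f["rod_id"][:], f["seg"][:])
        cfg = IntegratorConfig(**json.loads(f.attrs["cfg"]))
        integ = LangevinIntegrator(st, box, params, spec, cfg,
                                   init_velocities=False)
        integ.vel = f["vel"][:]
        integ.omega = f["omega"][:]
        integ.time = float(f.attrs["time"])
        integ.nsteps_done = int(f.attrs["nsteps_done"])
        integ.rng.bit_generator.state = json.loads(f.attrs["rng_state"])
    integ._recompute()
    return integ
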