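"""Membrane elastic-constant measurements and coefficient calibration.

The membrane model is specified through emergent elastic properties rather
than through the (free) repulsion/attraction coefficients:

* ``a0``: area per particle of the tensionless membrane (sigma^2),
* ``K_A``: area compression modulus (kT / sigma^2),
* ``kappa``: bending rigidity from the height-fluctuation spectrum
  ``<|h_q|^2> = kT / (A (gamma q^2 + kappa q^4))`` of a tensionless patch,
* ``Gamma``: edge line tension from the contractile axial force of a
  membrane strip with two free edges (force = 2 Gamma),
* ``D``: in-plane diffusion coefficient, fixing the time unit
  ``tau = r_rod^2 / D``.

:func:`calibrate` adjusts chosen free coefficients until the measured
report matches target values; the shipped canonical parameter set in
``data/params_canonical.yaml`` was produced this way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MembraneParams, ParticleState, SimulationBox, KIND_HOOK
from .dynamics import IntegratorConfig, LangevinIntegrator, measure_tension
from .systems import FlatSpec, build_flat_patch, build_flat_tensionless, build_strip

__all__ = ["ElasticReport", "measure_a0", "measure_KA", "measure_kappa",
           "measure_gamma", "height_spectrum", "fit_spectrum",
           "synthetic_height_frames", "calibrate", "CalibrationKnob"]


@dataclass
class ElasticReport:
    kappa: float = np.nan
    kappa_err: float = np.nan
    a0: float = np.nan
    a0_err: float = np.nan
    k_area: float = np.nan
    k_area_err: float = np.nan
    gamma_edge: float = np.nan
    gamma_edge_err: float = np.nan
    diffusion: float = np.nan
    run_params: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("kappa", "kappa_err", "a0", "a0_err", "k_area", "k_area_err",
                 "gamma_edge", "gamma_edge_err", "diffusion")}


def _block_se(x: np.ndarray, nblocks: int = 10):
    nb = max(1, min(nblocks, len(x) // 2))
    means = np.array([b.mean() for b in np.array_split(x, nb)])
    if len(means) < 2:
        return float("inf")
    return float(means.std(ddof=1) / np.sqrt(len(means)))


def measure_a0(integ: LangevinIntegrator, steps: int = 20000,
               area_interval: int = 20, dlnA_max: float = 0.002):
    """Area per particle from a converged zero-tension flat run.

    ``integ`` must hold a flat patch (e.g. from
    :func:`memrod.systems.build_flat_tensionless`).  Returns
    ``(a0, standard_error, areas)``; the trace is reused by the
    fluctuation-route K_A.
    """
    areas = []
    done = 0
    while done < steps:
        integ.step(area_interval)
        done += area_interval
        integ.mc_area_move(dlnA_max)
        areas.append(integ.box.area_xy)
    areas = np.asarray(areas)
    n = integ.state.n
    return float(areas.mean() / n), _block_se(areas / n), areas


def measure_KA(params: MembraneParams, n: int = 512, seed: int = 0,
               route: str = "strain", strains=(-0.04, -0.02, 0.02, 0.04),
               equil_steps: int = 4000, steps: int = 8000,
               a0: float | None = None, areas: np.ndarray | None = None,
               kbt: float = 1.0):
    """Area compression modulus K_A.

    ``route='strain'``: fixed-area runs at small areal strains around the
    tensionless area; K_A is the slope of tension vs strain.
    ``route='fluctuation'``: K_A = kT <A> / Var(A) from a zero-tension area
    trace (pass ``areas`` from :func:`measure_a0`).
    """
    if route == "fluctuation":
        if areas is None:
            raise ValueError("fluctuation route needs a zero-tension area trace")
        a = np.asarray(areas)
        var = a.var(ddof=1)
        ka = kbt * a.mean() / var
        # jackknife over blocks for the error
        nb = max(4, min(10, len(a) // 50))
        blocks = np.array_split(a, nb)
        est = []
        for i in range(nb):
            rest = np.concatenate([b for j, b in enumerate(blocks) if j != i])
            est.append(kbt * rest.mean() / rest.var(ddof=1))
        return float(ka), _jackknife_se(np.asarray(est))
    if route != "strain":
        raise ValueError("route must be 'strain' or 'fluctuation'")
    if a0 is None:
        a0 = _quick_a0(params, n, seed)
    gammas, errs, eps_list = [], [], []
    for eps in strains:
        spec = FlatSpec(n=n, a0=a0 * (1.0 + eps))
        state, box = build_flat_patch(spec, seed=seed)
        integ = LangevinIntegrator(state, box, params,
                                   cfg=IntegratorConfig(seed=seed + 17))
        g, ge = measure_tension(integ, steps, equil=equil_steps)
        gammas.append(g)
        errs.append(ge)
        eps_list.append(eps)
    coef, cov = np.polyfit(eps_list, gammas, 1, cov=True)
    return float(coef[0]), float(np.sqrt(cov[0, 0]))


def _jackknife_se(est: np.ndarray) -> float:
    n = len(est)
    return float(np.sqrt((n - 1) / n * ((est - est.mean()) ** 2).sum()))


def _quick_a0(params: MembraneParams, n: int, seed: int) -> float:
    integ = build_flat_tensionless(FlatSpec(n=n), params, seed=seed,
                                   equil_steps=6000)
    a0, _, _ = measure_a0(integ, steps=6000)
    return a0


# -- bending rigidity ------------------------------------------------------

def height_spectrum(frames, grid_spacing: float = 1.8):
    """Binned height field spectrum of flat-membrane frames.

    ``frames`` yields ``(state, box)``.  Returns ``(q, S)`` where ``S(q)``
    is the shell-averaged ``A <|h_q|^2>`` with the discrete Fourier
    transform normalized so that the continuum prediction is
    ``A <|h_q|^2> = kT / (gamma q^2 + kappa q^4)``.
    """
    acc = {}
    for state, box in frames:
        lx, ly = box.lengths[0], box.lengths[1]
        nx = max(4, int(round(lx / grid_spacing)))
        ny = max(4, int(round(ly / grid_spacing)))
        mask = state.kind != KIND_HOOK
        x = np.mod(state.pos[mask, 0], lx)
        y = np.mod(state.pos[mask, 1], ly)
        z = state.pos[mask, 2]
        ix = np.minimum((x / lx * nx).astype(int), nx - 1)
        iy = np.minimum((y / ly * ny).astype(int), ny - 1)
        h = np.zeros((nx, ny))
        cnt = np.zeros((nx, ny))
        np.add.at(h, (ix, iy), z)
        np.add.at(cnt, (ix, iy), 1.0)
        filled = cnt > 0
        h[filled] /= cnt[filled]
        h[~filled] = z.mean()
        h -= h.mean()
        hq = np.fft.fft2(h) / (nx * ny)
        s2 = np.abs(hq) ** 2 * (lx * ly)
        qx = 2 * np.pi * np.fft.fftfreq(nx, d=lx / nx)
        qy = 2 * np.pi * np.fft.fftfreq(ny, d=ly / ny)
        qq = np.sqrt(qx[:, None] ** 2 + qy[None, :] ** 2)
        for qv, sv in zip(np.round(qq.ravel(), 6), s2.ravel()):
            if qv == 0:
                continue
            rec = acc.setdefault(qv, [0.0, 0])
            rec[0] += sv
            rec[1] += 1
    qs = np.array(sorted(acc))
    ss = np.array([acc[q][0] / acc[q][1] for q in qs])
    return qs, ss


def fit_spectrum(q: np.ndarray, s: np.ndarray, kbt: float = 1.0,
                 q_max: float = 1.0, n_discard: int = 2):
    """Fit kT / S(q) = gamma q^2 + kappa q^4 over the fluctuation window.

    Discards the ``n_discard`` smallest wavenumber shells (finite-size and
    center-of-mode contamination) and everything above ``q_max`` (protrusion
    regime).  Returns ``(kappa, gamma, kappa_err)``.
    """
    keep = q <= q_max
    qs, ss = q[keep], s[keep]
    if len(qs) <= n_discard + 2:
        raise ValueError("no valid q window: patch too small")
    qs, ss = qs[n_discard:], ss[n_discard:]
    y = kbt / ss
    basis = np.column_stack([qs ** 2, qs ** 4])
    # weight shells equally in log space: weight by 1/y
    w = 1.0 / y
    coef, res, _, _ = np.linalg.lstsq(basis * w[:, None], y * w, rcond=None)
    gamma, kappa = coef[0], coef[1]
    dof = max(1, len(qs) - 2)
    resid = (basis @ coef - y) * w
    sigma2 = (resid ** 2).sum() / dof
    cov = np.linalg.inv((basis * w[:, None]).T @ (basis * w[:, None])) * sigma2
    return float(kappa), float(gamma), float(np.sqrt(cov[1, 1]))


def synthetic_height_frames(kappa: float, lx: float, ly: float,
                            n_grid: int, n_frames: int, seed: int = 0,
                            kbt: float = 1.0, gamma: float = 0.0):
    """Frames whose height field is drawn from the kappa q^4 spectrum.

    An independent parameter-recovery oracle for the spectrum estimator:
    membrane particles sit on a grid with Gaussian mode amplitudes
    ``A <|h_q|^2> = kT / (gamma q^2 + kappa q^4)``.
    """
    rng = np.random.default_rng(seed)
    qx = 2 * np.pi * np.fft.fftfreq(n_grid, d=lx / n_grid)
    qy = 2 * np.pi * np.fft.fftfreq(n_grid, d=ly / n_grid)
    q2 = qx[:, None] ** 2 + qy[None, :] ** 2
    denom = gamma * q2 + kappa * q2 ** 2
    var = np.zeros_like(denom)
    nz = denom > 0
    var[nz] = kbt / (denom[nz] * lx * ly)
    xs = np.linspace(0, lx, n_grid, endpoint=False)
    ys = np.linspace(0, ly, n_grid, endpoint=False)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    frames = []
    for _ in range(n_frames):
        amp = (rng.normal(size=denom.shape) + 1j * rng.normal(size=denom.shape))
        hq = amp * np.sqrt(var / 2.0)
        # taking the real part halves the mode variance; restore it
        h = np.fft.ifft2(hq * n_grid * n_grid).real * np.sqrt(2.0)
        pos = np.column_stack([gx.ravel(), gy.ravel(), h.ravel()])
        orient = np.tile([0.0, 0.0, 1.0], (len(pos), 1))
        state = ParticleState.membrane_only(pos, orient)
        box = SimulationBox([lx, ly, 50.0], "flat")
        frames.append((state, box))
    return frames


def measure_kappa(integ: LangevinIntegrator, steps: int = 40000,
                  sample_every: int = 200, q_max: float = 1.0,
                  grid_spacing: float = 1.8):
    """Bending rigidity of a flat patch from its height-fluctuation spectrum.

    The box is held fixed during sampling (equilibrate to the tensionless
    area first) so every frame shares one q-grid; residual frame tension is
    absorbed by the gamma q^2 term of the fit.
    """
    frames = []
    done = 0
    while done < steps:
        integ.step(sample_every)
        done += sample_every
        frames.append((integ.state.copy(), integ.box.copy()))
    q, s = height_spectrum(frames, grid_spacing=grid_spacing)
    kappa, gamma, err = fit_spectrum(q, s, kbt=integ.cfg.kbt, q_max=q_max)
    return kappa, err, (q, s, gamma)


def measure_gamma(params: MembraneParams, n: int = 300, seed: int = 0,
                  equil_steps: int = 12000, steps: int = 16000,
                  sample_every: int = 10, a0: float | None = None):
    """Edge line tension from the axial contractile force of a strip.

    The strip spans the periodic x direction with two free edges; the
    time-averaged pulling force along x equals ``2 Gamma``.  The strip must
    be built at the model's own tensionless area per particle (``a0``;
    measured on the fly when omitted) so that the interior membrane stress
    vanishes and only the edges pull.
    """
    from .systems import A0_REF

    if a0 is None:
        a0 = _quick_a0(params, min(n, 400), seed)
    state, box = build_strip(n, params, seed=seed, a0=a0)
    # weak z confinement suppresses slow strip flapping; it acts only along
    # z and cancels in the in-plane stress anisotropy that defines Gamma
    integ = LangevinIntegrator(state, box, params,
                               cfg=IntegratorConfig(seed=seed + 31,
                                                    z_spring=0.5))
    integ.step(equil_steps)
    lo_z = integ.state.pos[:, 2].std()
    vals = []
    done = 0
    while done < steps:
        integ.step(sample_every)
        done += sample_every
        vals.append(integ.axial_virial_force())
    # edge disintegration guard: the strip must stay a connected band
    from .observables import membrane_z_span
    if membrane_z_span(integ.state) > 5.0 + lo_z:
        raise RuntimeError("strip disintegrated during the edge-tension run")
    vals = np.asarray(vals)
    gamma = vals.mean() / 2.0
    return float(gamma), _block_se(vals) / 2.0


# -- calibration -----------------------------------------------------------

@dataclass
class CalibrationKnob:
    """One free coefficient driven toward one target observable."""
    param: str          # MembraneParams field
    target: str         # key of the measured report
    gain: float = 1.0   # update exponent (multiplicative secant)
    mode: str = "power"  # 'power': p *= (target/measured)^gain; 'linear'


def calibrate(targets: dict, knobs, measure, params: MembraneParams,
              max_iter: int = 6, rtol: float = 0.02):
    """Derivative-free fixed-point search for the free coefficients.

    ``measure(params) -> dict`` returns the observables named by the knobs'
    targets.  Each iteration updates every knob from its own residual
    (diagonal secant); convergence when all targets match within ``rtol``
    relative (or 2 combined standard errors if the measurement provides
    ``<name>_err`` entries).  Returns ``(params, history)``; on budget
    exhaustion the best candidate and residuals are returned.
    """
    history = []
    best = (np.inf, params, None)
    for it in range(max_iter):
        report = measure(params)
        resid = {}
        worst = 0.0
        for kn in knobs:
            meas = report[kn.target]
            tgt = targets[kn.target]
            err = report.get(kn.target + "_err", 0.0)
            tol = max(rtol * abs(tgt), 2.0 * err)
            resid[kn.target] = meas - tgt
            worst = max(worst, abs(meas - tgt) / tol if tol > 0 else np.inf)
        history.append({"iter": it, "report": dict(report),
                        "params": params, "worst": worst})
        if worst < best[0]:
            best = (worst, params, dict(report))
        if worst <= 1.0:
            return params, history
        updates = {}
        for kn in knobs:
            cur = getattr(params, kn.param)
            meas = report[kn.target]
            tgt = targets[kn.target]
            if kn.mode == "power" and meas > 0 and tgt > 0:
                updates[kn.param] = cur * (tgt / meas) ** kn.gain
            else:
                updates[kn.param] = cur + kn.gain * (tgt - meas)
        params = params.copy(**updates)
    return best[1], history
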