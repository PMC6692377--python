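"""Energy terms and their analytic gradients.

The total potential is ``U = U_rep + U_att + U_bend + U_tilt`` plus the rod
internal bonds and the optional inter-rod Lennard-Jones side attraction.

* ``U_bend/kT = (k_bend/2) sum_{i<j} (u_i - u_j - C_bd rhat_ij)^2 w_cv(r_ij)``
* ``U_tilt/kT = (k_tilt/2) sum_{i<j} [(u_i.rhat_ij)^2 + (u_j.rhat_ij)^2] w_cv(r_ij)``
* ``U_rep``: steep exponential core of diameter sigma with a smooth compact
  cutoff,
* ``U_att``: multibody cohesion: each particle contributes
  ``eps_att * psi(rho_i)`` where ``rho_i = sum_j f_rho(r_ij)`` is a weighted
  local density and ``psi`` decreases linearly below the saturation density
  ``rho_star`` and flattens above it (implicit solvent).

Within a rod the bend/tilt coefficients are ``k_rod`` and the pair
spontaneous-curvature parameter ``C_bd`` is chosen so that the backbone's
energy minimum is an arc of curvature ``c_rod`` (see
:func:`rod_cbd_for_curvature`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from . import _kernels as K
from .core import (KIND_BACKBONE, KIND_HOOK, MembraneParams, ParticleState,
                   RodSpec, SimulationBox)

__all__ = ["EnergyBreakdown", "ForceField", "total_energy",
           "bend_tilt_energy", "repulsion_attraction_energy",
           "rod_internal_energy", "side_attraction_energy",
           "rod_cbd_for_curvature", "build_bond_arrays"]


@dataclass
class EnergyBreakdown:
    u_rep: float = 0.0
    u_att: float = 0.0
    u_bend: float = 0.0
    u_tilt: float = 0.0
    u_rod_bond: float = 0.0
    u_lj: float = 0.0

    @property
    def total(self) -> float:
        return (self.u_rep + self.u_att + self.u_bend + self.u_tilt
                + self.u_rod_bond + self.u_lj)


def _check_orientations(state: ParticleState) -> None:
    norms = np.linalg.norm(state.orient, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("orientation vectors must have unit norm")


def build_bond_arrays(state: ParticleState, spec: RodSpec):
    """Harmonic-bond topology (backbone chains + 3x-stiffened hook triangles)."""
    bi, bj, bk, br0 = [], [], [], []
    d = spec.bond_length
    for rid in range(state.n_rods):
        back = state.rod_backbone_indices(rid)
        nb = len(back)
        hooks = np.where((state.rod_id == rid) & (state.kind == KIND_HOOK))[0]
        end_bonds = {0, nb - 2} if len(hooks) else set()
        for s in range(nb - 1):
            k = spec.bond_k * (spec.triangle_bond_factor if s in end_bonds else 1.0)
            bi.append(back[s])
            bj.append(back[s + 1])
            bk.append(k)
            br0.append(d)
        for h in hooks:
            # anchor pair: the two nearest backbone ends (segments 0,1 or 8,9)
            d0 = np.linalg.norm(state.pos[h] - state.pos[back[0]])
            d9 = np.linalg.norm(state.pos[h] - state.pos[back[-1]])
            a1, a2 = (back[0], back[1]) if d0 < d9 else (back[-1], back[-2])
            for a in (a1, a2):
                bi.append(h)
                bj.append(a)
                bk.append(spec.bond_k * spec.triangle_bond_factor)
                br0.append(d)
    return (np.asarray(bi, dtype=np.int64), np.asarray(bj, dtype=np.int64),
            np.asarray(bk, dtype=float), np.asarray(br0, dtype=float))


class ForceField:
    """Caches interaction topology and evaluates energies/forces/torques.

    The neighbor list is rebuilt when any particle has moved more than half
    the skin since the last build, or when the box changed.
    """

    def __init__(self, params: MembraneParams, spec: RodSpec | None = None,
                 state: ParticleState | None = None, skin: float = 0.4):
        self.params = params
        self.spec = spec
        self.skin = float(skin)
        self._pairs = None
        self._ref_pos = None
        self._ref_box = None
        if state is not None and spec is not None and state.n_rods > 0:
            self.bonds = build_bond_arrays(state, spec)
            self.is_att_seg = self._att_mask(state, spec)
            self.cbd_rod = rod_cbd_for_curvature(spec, params)
        else:
            z = np.zeros(0, dtype=np.int64)
            self.bonds = (z, z, np.zeros(0), np.zeros(0))
            self.is_att_seg = (np.zeros(state.n, dtype=np.bool_)
                               if state is not None else None)
            self.cbd_rod = 0.0

    @staticmethod
    def _att_mask(state: ParticleState, spec: RodSpec) -> np.ndarray:
        mask = np.zeros(state.n, dtype=np.bool_)
        if spec.epsilon_ss > 0:
            segs = np.asarray(spec.attraction_segments)
            mask = (state.kind == KIND_BACKBONE) & np.isin(state.seg, segs)
        return mask

    @property
    def list_cutoff(self) -> float:
        rc = self.params.r_cut
        if self.spec is not None and self.spec.epsilon_ss > 0:
            rc = max(rc, self.spec.lj_cutoff)
        return rc + self.skin

    def _need_rebuild(self, state: ParticleState, box: SimulationBox) -> bool:
        if self._pairs is None or self._ref_box is None:
            return True
        if (self._ref_box.topology != box.topology
                or not np.array_equal(self._ref_box.lengths, box.lengths)):
            return True
        disp = state.pos - self._ref_pos
        return bool((disp * disp).sum(axis=1).max() > (0.5 * self.skin) ** 2)

    def refresh_pairs(self, state: ParticleState, box: SimulationBox) -> None:
        self._pairs = K.build_pairs(state.pos, box.lengths, box.periodic,
                                    self.list_cutoff)
        self._ref_pos = state.pos.copy()
        self._ref_box = box.copy()

    def compute(self, state: ParticleState, box: SimulationBox,
                zero_membrane: bool = False, zero_rod: bool = False,
                zero_pairwise: bool = False, zero_bonds: bool = False,
                cbd_rod_override: float | None = None):
        """Evaluate everything.

        Returns ``(EnergyBreakdown, forces, gu, virial_diag)`` where ``gu``
        is the unprojected orientation gradient dU/du_i and ``virial_diag``
        the (W_xx, W_yy, W_zz) pair virial.
        """
        p = self.params
        spec = self.spec
        if self._need_rebuild(state, box):
            self.refresh_pairs(state, box)
        n = state.n
        forces = np.zeros((n, 3))
        gu = np.zeros((n, 3))
        is_att = (self.is_att_seg if self.is_att_seg is not None
                  else np.zeros(n, dtype=np.bool_))
        eps_ss = spec.epsilon_ss if spec is not None else 0.0
        lj_rc = spec.lj_cutoff if spec is not None else 3.0
        cbd_rod = self.cbd_rod if cbd_rod_override is None else cbd_rod_override
        krod = spec.k_rod if spec is not None else 0.0
        kb, kt = p.k_bend, p.k_tilt
        eps_rep, eps_att = p.eps_rep, p.eps_att
        if zero_membrane:
            kb = kt = 0.0
        if zero_rod:
            krod = 0.0
        if zero_pairwise:
            eps_rep = eps_att = 0.0
        per = box.periodic
        out = K.compute_interactions(
            state.pos, state.orient, state.kind, state.rod_id, is_att,
            self._pairs[0], self._pairs[1],
            box.lengths[0], box.lengths[1], box.lengths[2],
            bool(per[0]), bool(per[1]), bool(per[2]),
            kb, kt, p.c_bd, krod, cbd_rod,
            eps_rep, p.rep_alpha, p.rep_cutoff, p.rep_n, p.rep_a,
            eps_att, p.att_beta, p.rho_star, p.att_cutoff, p.att_n, p.att_a,
            p.wcv_cutoff, p.wcv_n, p.wcv_a,
            eps_ss, eps_ss > 0, lj_rc,
            forces, gu)
        e_rep, e_att, e_bend, e_tilt, e_lj, wxx, wyy, wzz = out
        e_bond = 0.0
        if not zero_bonds and len(self.bonds[0]):
            e_bond, bx, by, bz = K.compute_bonds(
                state.pos, *self.bonds,
                box.lengths[0], box.lengths[1], box.lengths[2],
                bool(per[0]), bool(per[1]), bool(per[2]), forces)
            wxx += bx
            wyy += by
            wzz += bz
        energy = EnergyBreakdown(e_rep, e_att, e_bend, e_tilt, e_bond, e_lj)
        return energy, forces, gu, np.array([wxx, wyy, wzz])


def total_energy(state: ParticleState, box: SimulationBox,
                 params: MembraneParams, spec: RodSpec | None = None
                 ) -> EnergyBreakdown:
    """Full energy decomposition of a configuration."""
    _check_orientations(state)
    ff = ForceField(params, spec, state)
    energy, _, _, _ = ff.compute(state, box)
    return energy


def bend_tilt_energy(state: ParticleState, box: SimulationBox,
                     params: MembraneParams, spec: RodSpec | None = None):
    """Membrane + rod bend/tilt energy with analytic gradients.

    Returns ``(u_bend, u_tilt, forces, gu_tangent)``; the orientation
    gradient is projected tangent to the unit sphere.
    """
    _check_orientations(state)
    ff = ForceField(params, spec, state)
    energy, forces, gu, _ = ff.compute(state, box, zero_pairwise=True,
                                       zero_bonds=True)
    gu_t = gu - (gu * state.orient).sum(axis=1, keepdims=True) * state.orient
    return energy.u_bend, energy.u_tilt, forces, gu_t


def repulsion_attraction_energy(state: ParticleState, box: SimulationBox,
                                params: MembraneParams):
    """U_rep + U_att (multibody density cohesion) and position gradients."""
    ff = ForceField(params, None, state)
    energy, forces, _, _ = ff.compute(state, box, zero_membrane=True,
                                      zero_rod=True, zero_bonds=True)
    return energy.u_rep + energy.u_att, forces


def rod_internal_energy(state: ParticleState, spec: RodSpec,
                        box: SimulationBox, params: MembraneParams):
    """Backbone bonds, hook-triangle bonds and intra-rod bend/tilt terms."""
    report = []
    for rid in range(state.n_rods):
        back = state.rod_backbone_indices(rid)
        if len(back) != spec.n_backbone:
            report.append(rid)
    if report:
        raise ValueError(f"malformed rod topology for rods {report}")
    ff = ForceField(params, spec, state)
    # membrane-coefficient pairs and pairwise rep/att off: rod terms only
    energy, forces, gu, _ = ff.compute(state, box, zero_membrane=True,
                                       zero_pairwise=True)
    gu_t = gu - (gu * state.orient).sum(axis=1, keepdims=True) * state.orient
    return energy, forces, gu_t


def side_attraction_energy(state: ParticleState, spec: RodSpec,
                           box: SimulationBox,
                           params: MembraneParams | None = None):
    """Inter-rod Lennard-Jones energy of the attraction-segment particles."""
    if spec.epsilon_ss <= 0:
        raise ValueError("side attraction requires epsilon_ss > 0")
    params = params or MembraneParams()
    ff = ForceField(params, spec, state)
    energy, forces, _, _ = ff.compute(state, box, zero_membrane=True,
                                      zero_rod=True, zero_pairwise=True,
                                      zero_bonds=True)
    return energy.u_lj, forces


def _arc_chain(n: int, d: float, curvature: float):
    """Positions/orientations of an n-particle arc with chord spacing d."""
    if abs(curvature) < 1e-12:
        pos = np.zeros((n, 3))
        pos[:, 0] = (np.arange(n) - (n - 1) / 2) * d
        u = np.tile([0.0, 0.0, 1.0], (n, 1))
        return pos, u
    # arc center at (0, 0, -R); orientations = outward normals (away from
    # the curvature center), which limits to +z as curvature -> 0
    R = 1.0 / curvature
    dphi = 2.0 * np.arcsin(min(1.0, d * curvature / 2.0))
    phi = (np.arange(n) - (n - 1) / 2) * dphi
    pos = np.column_stack([R * np.sin(phi), np.zeros(n), R * np.cos(phi) - R])
    u = np.column_stack([np.sin(phi), np.zeros(n), np.cos(phi)])
    return pos, u


def _arc_bend_tilt(spec: RodSpec, params: MembraneParams, cbd: float,
                   curvature: float) -> float:
    """Intra-rod bend+tilt energy of a circular-arc backbone."""
    n = spec.n_backbone
    pos, u = _arc_chain(n, spec.bond_length, curvature)
    e = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            rij = pos[i] - pos[j]
            r = np.linalg.norm(rij)
            w = K.fc_weight(r, params.wcv_cutoff, params.wcv_n, params.wcv_a)
            if w == 0.0:
                continue
            rhat = rij / r
            dvec = u[i] - u[j] - cbd * rhat
            e += 0.5 * spec.k_rod * (dvec @ dvec) * w
            e += 0.5 * spec.k_rod * ((u[i] @ rhat) ** 2 + (u[j] @ rhat) ** 2) * w
    return e


def rod_cbd_for_curvature(spec: RodSpec, params: MembraneParams) -> float:
    """Pair C_bd that makes an arc of curvature ``c_rod`` the energy minimum.

    The intra-rod bend/tilt energy restricted to circular arcs is quadratic
    in the arc curvature, and the minimizing curvature is linear in C_bd, so
    a single numerical probe fixes the map.  (For the 2D membrane the
    analogous relation is C_0 sigma = C_bd / 2.)
    """
    if abs(spec.c_rod) < 1e-14:
        return 0.0
    probe = 0.2

    def cmin(cbd: float) -> float:
        res = minimize_scalar(lambda c: _arc_bend_tilt(spec, params, cbd, c),
                              bounds=(-0.1, 0.8), method="bounded",
                              options={"xatol": 1e-10})
        return res.x

    gain = cmin(probe) / probe
    cbd = spec.c_rod / gain
    for _ in range(2):   # secant polish (the map is linear only to first order)
        c_here = cmin(cbd)
        if abs(c_here - spec.c_rod) < 1e-4 * abs(spec.c_rod):
            break
        cbd *= spec.c_rod / c_here
    return cbd
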