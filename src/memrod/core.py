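"""Domain types and periodic geometry shared by the whole package.

Units: the membrane particle diameter ``sigma`` is the length unit and the
thermal energy ``k_B T`` the energy unit; both are fixed to 1.  Times are
quoted in the intrinsic unit ``tau = r_rod**2 / D`` where ``D`` is the
in-plane diffusion coefficient of a membrane particle in the tensionless
membrane (see :mod:`memrod.dynamics`).

Particles are points with a position ``r_i`` and a unit orientation vector
``u_i`` (the local membrane normal).  Three kinds exist:

* ``KIND_MEMBRANE`` (0): free membrane particle,
* ``KIND_BACKBONE`` (1): membrane particle belonging to a protein-rod
  backbone (10 per rod),
* ``KIND_HOOK`` (2): excluded-volume-only hook particle that makes a rod
  chiral (2 per hooked rod).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

SIGMA = 1.0
KBT = 1.0

KIND_MEMBRANE = 0
KIND_BACKBONE = 1
KIND_HOOK = 2

KIND_NAMES = {KIND_MEMBRANE: "membrane", KIND_BACKBONE: "rod_backbone",
              KIND_HOOK: "rod_hook"}

TOPOLOGY_TUBE = "tube"
TOPOLOGY_FLAT = "flat"


@dataclass
class SimulationBox:
    """Periodic cell.

    ``tube`` topology is periodic along z only (the tube length ``L_z`` is an
    imposed parameter; the radius is free).  ``flat`` topology is periodic in
    x and y with open z (a membrane patch).
    """

    lengths: np.ndarray
    topology: str = TOPOLOGY_FLAT

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float).copy()
        if self.lengths.shape != (3,):
            raise ValueError("box lengths must be a 3-vector")
        if not np.all(self.lengths > 0):
            raise ValueError("box lengths must be positive")
        if self.topology not in (TOPOLOGY_TUBE, TOPOLOGY_FLAT):
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def periodic(self) -> np.ndarray:
        """Boolean mask of periodic directions."""
        if self.topology == TOPOLOGY_TUBE:
            return np.array([False, False, True])
        return np.array([True, True, False])

    def copy(self) -> "SimulationBox":
        return SimulationBox(self.lengths.copy(), self.topology)

    @property
    def area_xy(self) -> float:
        return float(self.lengths[0] * self.lengths[1])


def minimum_image(displacement: np.ndarray, box: SimulationBox) -> np.ndarray:
    """Wrap a displacement (or array of displacements) into the primary cell.

    Each periodic component of the result lies in ``[-L/2, L/2)``; open
    components are returned unchanged.  Idempotent.
    """
    d = np.array(displacement, dtype=float, copy=True)
    per = box.periodic
    L = box.lengths
    for ax in range(3):
        if per[ax]:
            d[..., ax] -= L[ax] * np.floor(d[..., ax] / L[ax] + 0.5)
    return d


@dataclass
class MembraneParams:
    """Coefficients of the membrane potential U = U_rep + U_att + U_bend + U_tilt.

    ``k_bend``/``k_tilt`` and ``C_bd`` (via ``C_0 sigma = C_bd / 2``) are the
    printed model parameters; the repulsion/attraction coefficients are free
    parameters of the meshless family fixed by the elastic-constant
    calibration (see :mod:`memrod.calibration` and ``data/params_canonical.yaml``).
    """

    k_bend: float = 10.0
    k_tilt: float = 10.0
    c_bd: float = 0.0            # membrane spontaneous-curvature bond parameter (C_0 = 0)

    eps_rep: float = 4.0         # excluded-volume energy scale
    rep_alpha: float = 20.0      # exponential steepness of the core
    rep_cutoff: float = 1.2
    rep_n: float = 12.0
    rep_a: float = 1.0

    eps_att: float = 2.5         # multibody attraction scale (solvent cohesion)
    att_beta: float = 6.0        # sharpness of the density saturation
    rho_star: float = 7.68       # saturation density
    att_cutoff: float = 1.9      # range of the density weight f_rho
    att_n: float = 12.0
    att_a: float = 0.462

    wcv_cutoff: float = 2.4      # range of the bend/tilt weight w_cv
    wcv_n: float = 4.0
    wcv_a: float = 2.0

    kbt: float = 1.0

    @property
    def r_cut(self) -> float:
        """Largest interaction cutoff of any membrane term."""
        return max(self.rep_cutoff, self.att_cutoff, self.wcv_cutoff)

    def copy(self, **changes) -> "MembraneParams":
        return replace(self, **changes)


CHIRAL = "chiral"
ACHIRAL_HOOKED = "achiral_hooked"
ACHIRAL_PLAIN = "achiral_plain"
CHIRALITIES = (CHIRAL, ACHIRAL_HOOKED, ACHIRAL_PLAIN)


@dataclass
class RodSpec:
    """Geometry and coefficients of a crescent protein rod.

    Ten membrane particles are linearly connected by harmonic bonds
    (``r_rod = 10 sigma`` end to end) and carry much stiffer bend/tilt
    coefficients (``k_rod = 80``) with a spontaneous curvature ``c_rod``
    along the backbone.  Hook particles are added between the first and
    second particles of both rod ends; for a chiral rod they sit on
    right-handed positions, for an achiral hooked rod both sit on the same
    side.  Hooks interact through excluded volume only.
    """

    n_backbone: int = 10
    r_rod: float = 10.0
    c_rod: float = 0.0                   # spontaneous curvature, 1/sigma
    chirality: str = CHIRAL
    k_rod: float = 80.0
    bond_k: float = 2500.0               # backbone bond stiffness (fluctuations < 2%)
    triangle_bond_factor: float = 3.0
    epsilon_ss: float = 0.0              # side-to-side LJ depth; 0 disables
    attraction_segments: tuple = (1, 2, 7, 8)   # 2nd/3rd particles from both ends
    hook_offset_factor: float = 1.0      # hook displacement in bond lengths
    hook_elevation_deg: float = 60.0     # hook tilt out of the membrane plane
    lj_cutoff: float = 3.0

    def __post_init__(self) -> None:
        if self.chirality not in CHIRALITIES:
            raise ValueError(f"invalid chirality {self.chirality!r}")
        if self.epsilon_ss < 0:
            raise ValueError("epsilon_ss must be >= 0")
        if self.triangle_bond_factor < 1:
            raise ValueError("triangle_bond_factor must be >= 1")

    @property
    def bond_length(self) -> float:
        return self.r_rod / (self.n_backbone - 1)

    @property
    def has_hooks(self) -> bool:
        return self.chirality in (CHIRAL, ACHIRAL_HOOKED)

    @property
    def n_particles(self) -> int:
        return self.n_backbone + (2 if self.has_hooks else 0)

    def copy(self, **changes) -> "RodSpec":
        return replace(self, **changes)


@dataclass
class ParticleState:
    """Positions, orientations and labels of every particle in the system."""

    pos: np.ndarray          # (N, 3) float
    orient: np.ndarray       # (N, 3) float, unit vectors
    kind: np.ndarray         # (N,) int8
    rod_id: np.ndarray       # (N,) int32, -1 for free membrane particles
    seg: np.ndarray          # (N,) int16, backbone index 0..9, -1 otherwise

    def __post_init__(self) -> None:
        self.pos = np.ascontiguousarray(self.pos, dtype=float)
        self.orient = np.ascontiguousarray(self.orient, dtype=float)
        self.kind = np.ascontiguousarray(self.kind, dtype=np.int8)
        self.rod_id = np.ascontiguousarray(self.rod_id, dtype=np.int32)
        self.seg = np.ascontiguousarray(self.seg, dtype=np.int16)
        n = len(self.pos)
        for name in ("orient", "kind", "rod_id", "seg"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")

    @classmethod
    def membrane_only(cls, pos: np.ndarray, orient: np.ndarray) -> "ParticleState":
        n = len(pos)
        return cls(pos, orient,
                   np.zeros(n, dtype=np.int8),
                   np.full(n, -1, dtype=np.int32),
                   np.full(n, -1, dtype=np.int16))

    @property
    def n(self) -> int:
        return len(self.pos)

    @property
    def n_rods(self) -> int:
        m = self.rod_id >= 0
        return 0 if not m.any() else int(self.rod_id[m].max()) + 1

    def rod_backbone_indices(self, rid: int) -> np.ndarray:
        """Backbone particle indices of rod ``rid`` ordered by segment."""
        idx = np.where((self.rod_id == rid) & (self.kind == KIND_BACKBONE))[0]
        return idx[np.argsort(self.seg[idx])]

    def copy(self) -> "ParticleState":
        return ParticleState(self.pos.copy(), self.orient.copy(),
                             self.kind.copy(), self.rod_id.copy(),
                             self.seg.copy())

    def normalize_orientations(self) -> None:
        norms = np.linalg.norm(self.orient, axis=1, keepdims=True)
        self.orient /= norms


def phi_rod(state: ParticleState) -> float:
    """Protein density: fraction of non-hook particles in rod backbones."""
    non_hook = state.kind != KIND_HOOK
    n_backbone = int(np.count_nonzero(state.kind == KIND_BACKBONE))
    return n_backbone / int(np.count_nonzero(non_hook))


def validate_state(state: ParticleState, box: SimulationBox,
                   spec: RodSpec | None = None,
                   overlap_threshold: float = 0.25) -> list:
    """Diagnostic invariant check; returns a list of violation strings.

    Checks unit orientations, rod completeness (10 backbone particles with
    segments 0..9, two hooks when the rod kind carries hooks), hook labels
    and catastrophic overlaps between periodic images.
    """
    report: list = []
    norms = np.linalg.norm(state.orient, axis=1)
    bad = np.where(np.abs(norms - 1.0) > 1e-9)[0]
    for i in bad[:20]:
        report.append(f"particle {i}: orientation norm {norms[i]:.6g} != 1")

    hooks_no_rod = np.where((state.kind == KIND_HOOK) & (state.rod_id < 0))[0]
    for i in hooks_no_rod[:20]:
        report.append(f"particle {i}: hook without rod_id")

    n_back = spec.n_backbone if spec is not None else 10
    rids = np.unique(state.rod_id[state.rod_id >= 0])
    for rid in rids:
        mask = state.rod_id == rid
        backbone = np.sort(state.seg[mask & (state.kind == KIND_BACKBONE)])
        n_hooks = int(np.count_nonzero(mask & (state.kind == KIND_HOOK)))
        if not np.array_equal(backbone, np.arange(n_back)):
            report.append(f"rod {rid} incomplete: backbone segments {backbone.tolist()}")
        if spec is not None:
            want = 2 if spec.has_hooks else 0
            if n_hooks != want:
                report.append(f"rod {rid}: {n_hooks} hooks, expected {want}")
        elif n_hooks not in (0, 2):
            report.append(f"rod {rid}: {n_hooks} hooks, expected 0 or 2")

    # deep overlaps through the minimum image (catastrophic only)
    if state.n <= 4000:
        d = state.pos[:, None, :] - state.pos[None, :, :]
        d = minimum_image(d, box)
        r2 = (d ** 2).sum(axis=-1)
        np.fill_diagonal(r2, np.inf)
        ii, jj = np.where(r2 < overlap_threshold ** 2)
        for i, j in zip(ii[:20], jj[:20]):
            if i < j:
                report.append(f"particles {i},{j}: overlap r={np.sqrt(r2[i, j]):.3g}")
    return report


@dataclass
class Trajectory:
    """Time-ordered snapshots with the run metadata needed for analysis."""

    frames: list = field(default_factory=list)      # ParticleState
    times: list = field(default_factory=list)       # simulation time units
    boxes: list = field(default_factory=list)       # SimulationBox per frame
    metadata: dict = field(default_factory=dict)    # seed, c_rod, eps, N, ...

    def append(self, state: ParticleState, time: float, box: SimulationBox) -> None:
        if self.times and time <= self.times[-1]:
            raise ValueError("frame times must be strictly increasing")
        if self.frames and state.n != self.frames[0].n:
            raise ValueError("particle count must be constant across frames")
        self.frames.append(state.copy())
        self.times.append(float(time))
        self.boxes.append(box.copy())

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator:
        return iter(zip(self.times, self.frames, self.boxes))
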