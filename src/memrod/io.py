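"""Configuration, trajectory I/O and deterministic test fixtures.

Frames are stored as extended XYZ (text; per-particle columns: species,
position, orientation, kind, rod_id, segment) or in HDF5 trajectories.
Run configurations are single YAML documents with a strict key schema;
unknown keys are rejected with a field-level message.
"""

from __future__ import annotations

import dataclasses
import importlib.resources as resources
from pathlib import Path

import numpy as np
import yaml

from .core import (ParticleState, SimulationBox, MembraneParams, RodSpec,
                   KIND_NAMES, TOPOLOGY_FLAT, TOPOLOGY_TUBE)

__all__ = ["RunConfig", "ConfigError", "load_config", "canonical_params",
           "write_frame", "read_frame", "write_trajectory_h5",
           "read_trajectory_h5", "make_fixture", "FIXTURES"]

_SPECIES = {0: "M", 1: "B", 2: "H"}
_SPECIES_INV = {v: k for k, v in _SPECIES.items()}


# -- canonical calibrated parameters --------------------------------------

def canonical_params() -> MembraneParams:
    """The shipped calibrated membrane parameter set."""
    with resources.files("memrod.data").joinpath(
            "params_canonical.yaml").open() as f:
        doc = yaml.safe_load(f)
    return MembraneParams(**doc["membrane"])


# -- run configuration ------------------------------------------------------

class ConfigError(ValueError):
    pass


_EXPERIMENTS = ("tube", "tube_remd", "flat", "tubulate", "calibrate", "analyze")

_MEMBRANE_KEYS = {f.name for f in dataclasses.fields(MembraneParams)}
_ROD_KEYS = {f.name for f in dataclasses.fields(RodSpec)}
_RUN_KEYS = {"experiment", "n", "r_cyl_over_r_rod", "phi_rod", "n_rods",
             "c_rod_r_rod", "c_rod_r_rod_ladder", "duration_steps",
             "equil_steps", "stride", "seed", "dt", "output", "trajectory",
             "membrane", "rod", "exchange_interval"}


@dataclasses.dataclass
class RunConfig:
    experiment: str
    membrane: MembraneParams
    rod: RodSpec
    n: int = 1200
    r_cyl_over_r_rod: float = 1.31
    phi_rod: float = 0.0833
    n_rods: int | None = None
    c_rod_r_rod: float = 0.0
    c_rod_r_rod_ladder: list | None = None
    duration_steps: int = 10000
    equil_steps: int = 2000
    exchange_interval: int = 500
    stride: int = 500
    seed: int = 0
    dt: float = 0.002
    output: str = "memrod_out"
    trajectory: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["membrane"] = dataclasses.asdict(self.membrane)
        d["rod"] = dataclasses.asdict(self.rod)
        d["rod"]["attraction_segments"] = list(self.rod.attraction_segments)
        return d


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Membrane parameters default to the shipped calibrated set; rod
    parameters default to :class:`RodSpec` defaults.  Unknown keys raise a
    :class:`ConfigError` naming the offending field.
    """
    with open(path) as f:
        doc = yaml.safe_load(f) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config must be a YAML mapping")
    unknown = set(doc) - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "experiment" not in doc:
        raise ConfigError(
            f"missing required key 'experiment' (one of {_EXPERIMENTS}); "
            f"other keys: {sorted(_RUN_KEYS)}")
    if doc["experiment"] not in _EXPERIMENTS:
        raise ConfigError(f"experiment must be one of {_EXPERIMENTS}")
    mem_doc = doc.pop("membrane", {}) or {}
    unknown = set(mem_doc) - _MEMBRANE_KEYS
    if unknown:
        raise ConfigError(f"unknown membrane keys: {sorted(unknown)}")
    membrane = canonical_params().copy(**mem_doc)
    rod_doc = doc.pop("rod", {}) or {}
    unknown = set(rod_doc) - _ROD_KEYS
    if unknown:
        raise ConfigError(f"unknown rod keys: {sorted(unknown)}")
    if "attraction_segments" in rod_doc:
        rod_doc["attraction_segments"] = tuple(rod_doc["attraction_segments"])
    rod = RodSpec(**rod_doc)
    cfg = RunConfig(membrane=membrane, rod=rod, **doc)
    # realize C_rod from the dimensionless C_rod * r_rod
    cfg.rod = cfg.rod.copy(c_rod=cfg.c_rod_r_rod / cfg.rod.r_rod)
    return cfg


def dump_effective_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg.to_dict(), f, sort_keys=True)


# -- extended XYZ -----------------------------------------------------------

def write_frame(path, state: ParticleState, box: SimulationBox,
                time: float = 0.0, mode: str = "w") -> None:
    """Write one extended-XYZ frame (text, appendable)."""
    lx, ly, lz = box.lengths
    props = "species:S:1:pos:R:3:orient:R:3:kind:I:1:rod_id:I:1:seg:I:1"
    with open(path, mode) as f:
        f.write(f"{state.n}\n")
        f.write(f'Lattice="{lx} 0 0 0 {ly} 0 0 0 {lz}" '
                f'Properties={props} topology={box.topology} time={time}\n')
        for i in range(state.n):
            p = state.pos[i]
            u = state.orient[i]
            f.write(f"{_SPECIES[int(state.kind[i])]} "
                    f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g} "
                    f"{u[0]:.12g} {u[1]:.12g} {u[2]:.12g} "
                    f"{int(state.kind[i])} {int(state.rod_id[i])} "
                    f"{int(state.seg[i])}\n")


def read_frame(path):
    """Read the first extended-XYZ frame -> (state, box, time)."""
    with open(path) as f:
        lines = f.readlines()
    if len(lines) < 2:
        raise ValueError("malformed XYZ: missing header")
    n = int(lines[0])
    header = lines[1]
    fields = dict(_parse_header(header))
    if "Lattice" not in fields:
        raise ValueError("malformed XYZ: no Lattice in header")
    lat = np.array(fields["Lattice"].split(), dtype=float).reshape(3, 3)
    box = SimulationBox(np.diag(lat), fields.get("topology", TOPOLOGY_FLAT))
    time = float(fields.get("time", 0.0))
    if len(lines) < 2 + n:
        raise ValueError("malformed XYZ: truncated frame")
    pos = np.empty((n, 3))
    orient = np.empty((n, 3))
    kind = np.empty(n, dtype=np.int8)
    rid = np.empty(n, dtype=np.int32)
    seg = np.empty(n, dtype=np.int16)
    for i, ln in enumerate(lines[2:2 + n]):
        parts = ln.split()
        if len(parts) < 10:
            raise ValueError(
                f"malformed XYZ line {i + 3}: expected 10 columns "
                f"(species pos(3) orient(3) kind rod_id seg), got {len(parts)}")
        pos[i] = [float(v) for v in parts[1:4]]
        orient[i] = [float(v) for v in parts[4:7]]
        kind[i] = int(parts[7])
        rid[i] = int(parts[8])
        seg[i] = int(parts[9])
    return ParticleState(pos, orient, kind, rid, seg), box, time


def _parse_header(header: str):
    out = []
    i = 0
    while i < len(header):
        eq = header.find("=", i)
        if eq < 0:
            break
        key = header[i:eq].strip().split()[-1]
        if eq + 1 < len(header) and header[eq + 1] == '"':
            end = header.find('"', eq + 2)
            val = header[eq + 2:end]
            i = end + 1
        else:
            end = header.find(" ", eq + 1)
            if end < 0:
                end = len(header)
            val = header[eq + 1:end]
            i = end + 1
        out.append((key, val.strip()))
    return out


# -- HDF5 trajectories ------------------------------------------------------

def write_trajectory_h5(path, traj) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for k, v in traj.metadata.items():
            if v is not None:
                f.attrs[k] = v
        for idx, (t, st, box) in enumerate(traj):
            g = f.create_group(f"frame_{idx:06d}")
            g.attrs["time"] = t
            g.attrs["topology"] = box.topology
            g.create_dataset("lengths", data=box.lengths)
            for name in ("pos", "orient", "kind", "rod_id", "seg"):
                g.create_dataset(name, data=getattr(st, name))


def read_trajectory_h5(path):
    import h5py

    from .core import Trajectory

    traj = Trajectory()
    with h5py.File(path, "r") as f:
        traj.metadata = {k: f.attrs[k] for k in f.attrs}
        for key in sorted(f.keys()):
            g = f[key]
            st = ParticleState(g["pos"][:], g["orient"][:], g["kind"][:],
                               g["rod_id"][:], g["seg"][:])
            box = SimulationBox(g["lengths"][:], g.attrs["topology"])
            traj.append(st, float(g.attrs["time"]), box)
    return traj


# -- fixtures ---------------------------------------------------------------

def _fixture_flat_patch_100(seed):
    from .systems import FlatSpec, build_flat_patch

    return build_flat_patch(FlatSpec(n=100), seed=seed)


def _fixture_tube_small(seed):
    from .systems import TubeSpec, build_tube

    return build_tube(TubeSpec(n=1200, r_cyl=11.8, l_z=0.00167 * 1200 * 10),
                      seed=seed)


def _fixture_rod(chirality):
    def make(seed):
        from .rods import build_rod

        spec = RodSpec(c_rod=0.25, chirality=chirality)
        st = build_rod(spec)
        box = SimulationBox([60.0, 60.0, 60.0], TOPOLOGY_FLAT)
        return st, box
    return make


def _ellipse_points(a, b, n):
    """n points approximately uniform in arc length on an ellipse."""
    t = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
    dx = -a * np.sin(t)
    dy = b * np.cos(t)
    ds = np.hypot(dx, dy)
    s = np.cumsum(ds)
    s /= s[-1]
    targets = (np.arange(n) + 0.5) / n
    idx = np.searchsorted(s, targets)
    return t[idx]


def _fixture_elliptical(seed, r0: float = 13.1, lz: float = 72.0,
                        with_rods: bool = True, aspect: float = 1.45):
    """Elliptical tube with two rod lanes along the high-curvature edges.

    The default aspect keeps the edge curvature radius b^2/a near the rod
    preferred radius so the lanes sit comfortably on the edges.
    """
    rng = np.random.default_rng(seed)
    a, b = aspect * r0, r0 / aspect
    spacing = 1.2
    n_ring = int(2 * np.pi * r0 / spacing)  # equal-area ellipse, ~same perimeter
    n_rows = int(lz / (spacing * np.sqrt(3) / 2))
    pos, orient, kind, rid, seg = [], [], [], [], []
    rod_rows = set(range(1, n_rows, 3))
    next_rod = 0
    for iz in range(n_rows):
        z = iz * lz / n_rows
        ts = _ellipse_points(a, b, n_ring) + (0.5 / n_ring if iz % 2 else 0.0)
        xy = np.column_stack([a * np.cos(ts), b * np.sin(ts)])
        nrm = np.column_stack([b * np.cos(ts), a * np.sin(ts)])
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        # rod lanes: 10 consecutive ring particles centred on each edge
        lane = np.full(len(ts), False)
        lane_ids = np.full(len(ts), -1)
        lane_seg = np.full(len(ts), -1)
        if iz in rod_rows and with_rods:
            for t_edge in (0.0, np.pi):
                delta = np.angle(np.exp(1j * (ts - t_edge)))
                order = np.argsort(np.abs(delta))[:10]
                # segments ordered along the arc (signed angle), so bonds
                # connect spatial neighbors even across the t = 0 wrap
                sel = order[np.argsort(delta[order])]
                lane[sel] = True
                lane_ids[sel] = next_rod
                lane_seg[sel] = np.arange(10)
                next_rod += 1
        for k in range(len(ts)):
            pos.append((xy[k, 0], xy[k, 1], z))
            orient.append((nrm[k, 0], nrm[k, 1], 0.0))
            kind.append(1 if lane[k] else 0)
            rid.append(lane_ids[k])
            seg.append(lane_seg[k])
    st = ParticleState(np.asarray(pos), np.asarray(orient),
                       np.asarray(kind), np.asarray(rid), np.asarray(seg))
    box = SimulationBox([6 * a, 6 * a, lz], TOPOLOGY_TUBE)
    return st, box


def _fixture_helical_wrap(seed, chirality="achiral_plain",
                          c_rod_r_rod: float = 3.0, pitch: float = 1.3,
                          n_turns: int = 4):
    """Cylindrical tube wrapped by a connected helical rod assembly.

    Helix radius sized for the rod preferred curvature radius (slightly
    above ``1/C_rod``); rods run head to tail along the helix path and the
    membrane fills the remaining cylinder surface.  The default pitch packs
    adjacent turns at side-by-side contact distance (the packed helical
    strip); a larger pitch leaves membrane gaps between turns.
    """
    rng = np.random.default_rng(seed)
    r_rod = 10.0
    radius = 1.15 * r_rod / c_rod_r_rod
    pitch_angle = np.arctan(pitch / (2 * np.pi * radius))
    lz = n_turns * pitch + 9.0
    path_len = n_turns * 2 * np.pi * radius / np.cos(pitch_angle)
    spec = RodSpec(c_rod=c_rod_r_rod / r_rod, chirality=chirality)
    d = spec.bond_length
    n_rods = int(path_len / d) // spec.n_backbone
    pos, orient, kind, rid, seg = [], [], [], [], []
    for k in range(n_rods * spec.n_backbone):
        s = k * d
        phi = s * np.cos(pitch_angle) / radius
        z = s * np.sin(pitch_angle)
        pos.append((radius * np.cos(phi), radius * np.sin(phi), z % lz))
        orient.append((np.cos(phi), np.sin(phi), 0.0))
        kind.append(1)
        rid.append(k // spec.n_backbone)
        seg.append(k % spec.n_backbone)
    if spec.has_hooks:
        from .rods import hook_positions

        n_back = spec.n_backbone
        arr_pos = np.asarray(pos)
        arr_u = np.asarray(orient)
        for r in range(n_rods):
            bp = arr_pos[r * n_back:(r + 1) * n_back].copy()
            # unwrap z across the periodic boundary for local geometry
            for s in range(1, n_back):
                dz = bp[s, 2] - bp[s - 1, 2]
                bp[s, 2] -= lz * np.floor(dz / lz + 0.5)
            bu = arr_u[r * n_back:(r + 1) * n_back]
            for hp in hook_positions(bp, bu, spec):
                pos.append((hp[0], hp[1], hp[2] % lz))
                nvec = np.array([hp[0], hp[1], 0.0])
                nvec /= np.linalg.norm(nvec)
                orient.append(tuple(nvec))
                kind.append(2)
                rid.append(r)
                seg.append(-1)
    rodpos = np.asarray(pos)
    # membrane fill on the same cylinder, skipping sites near the helix
    spacing = 1.15
    n_ring = int(2 * np.pi * radius / spacing)
    n_rows = int(lz / (spacing * np.sqrt(3) / 2))
    for iz in range(n_rows):
        z = iz * lz / n_rows
        for it in range(n_ring):
            phi = 2 * np.pi * (it + (0.5 if iz % 2 else 0.0)) / n_ring
            p = np.array([radius * np.cos(phi), radius * np.sin(phi), z])
            dz = rodpos[:, 2] - p[2]
            dz -= lz * np.floor(dz / lz + 0.5)
            d2 = ((rodpos[:, 0] - p[0]) ** 2 + (rodpos[:, 1] - p[1]) ** 2
                  + dz ** 2)
            if d2.min() < spacing ** 2 * 0.81:
                continue
            pos.append(tuple(p))
            orient.append((np.cos(phi), np.sin(phi), 0.0))
            kind.append(0)
            rid.append(-1)
            seg.append(-1)
    st = ParticleState(np.asarray(pos), np.asarray(orient),
                       np.asarray(kind), np.asarray(rid), np.asarray(seg))
    box = SimulationBox([8 * radius, 8 * radius, lz], TOPOLOGY_TUBE)
    _resolve_overlaps(st, box, min_dist=0.85, movable=st.kind == 2)
    return st, box


def _resolve_overlaps(st: ParticleState, box: SimulationBox,
                      min_dist: float = 0.85,
                      movable: np.ndarray | None = None,
                      max_iter: int = 200) -> None:
    """Push apart build-time overlaps (moving only ``movable`` particles)."""
    from .core import minimum_image

    if movable is None:
        movable = np.ones(st.n, dtype=bool)
    for _ in range(max_iter):
        d = st.pos[:, None, :] - st.pos[None, :, :]
        d = minimum_image(d, box)
        r = np.sqrt((d ** 2).sum(axis=-1))
        np.fill_diagonal(r, np.inf)
        ii, jj = np.where(r < min_dist)
        if len(ii) == 0:
            return
        done = True
        for i, j in zip(ii, jj):
            if i >= j:
                continue
            step = d[i, j] / (r[i, j] + 1e-12) * (min_dist - r[i, j] + 0.02)
            if movable[i]:
                st.pos[i] += step * (0.5 if movable[j] else 1.0)
            if movable[j]:
                st.pos[j] -= step * (0.5 if movable[i] else 1.0)
            if movable[i] or movable[j]:
                done = False
        if done:
            return


FIXTURES = {
    "flat_patch_100": _fixture_flat_patch_100,
    "tube_small": _fixture_tube_small,
    "rod_chiral": _fixture_rod("chiral"),
    "rod_achiral_hooked": _fixture_rod("achiral_hooked"),
    "rod_achiral_plain": _fixture_rod("achiral_plain"),
    "elliptical": _fixture_elliptical,
    "helical_wrap": _fixture_helical_wrap,
}


def make_fixture(name: str, seed: int = 0, **kwargs):
    """Deterministic small test systems -> (state, box).

    ``helical_wrap`` accepts ``chirality`` and ``c_rod_r_rod`` keywords.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    return FIXTURES[name](seed, **kwargs)
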