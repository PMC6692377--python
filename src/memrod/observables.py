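"""Analysis quantities: Fourier shape/density modes, helical-assembly
radius, cluster statistics, membrane span and tube-shape classification.

On a tube (periodic z, axis z) the lowest-mode Fourier amplitudes are

    r_qz     = (1/N) sum_i r2D_i exp(-i 2 pi z_i / L_z)
    r_qtheta = (1/N) sum_i r2D_i exp(-2 i theta_i)

with ``r2D_i = sqrt(x_i^2 + y_i^2)`` and ``theta_i = atan2(x_i, y_i)``
computed after recentering the axis on the in-plane center of mass.  The
shape modes run over all non-hook particles; the rod density modes
(``n_qz``, ``n_qtheta``) are the same sums restricted to rod backbone
particles and normalized by their count.  The qtheta mode uses angular
wavenumber 2, so an elliptical cross-section (two-fold) maximizes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .core import (KIND_BACKBONE, KIND_HOOK, KIND_MEMBRANE, ParticleState,
                   SimulationBox, TOPOLOGY_TUBE, TOPOLOGY_FLAT, minimum_image)

__all__ = ["ModeAmplitudes", "HelixFit", "fourier_modes", "helix_radius",
           "cluster_sizes", "mean_cluster_size", "membrane_z_span",
           "classify_tube_shape", "ShapeThresholds"]


@dataclass
class ModeAmplitudes:
    r_qz: complex
    r_qtheta: complex
    n_qz: complex
    n_qtheta: complex
    mean_r2d: float

    def normalized(self, ref: "ModeAmplitudes") -> dict:
        """Moduli divided by a reference (the c_rod = 0 'starred' values)."""
        out = {}
        for name in ("r_qz", "r_qtheta", "n_qz", "n_qtheta"):
            r = abs(getattr(ref, name))
            out[name] = abs(getattr(self, name)) / r if r > 0 else np.inf
        return out


@dataclass
class HelixFit:
    r_hel: float
    z_center: float
    n_slice: int
    residual: float


def _tube_frame(state: ParticleState, box: SimulationBox):
    if box.topology != TOPOLOGY_TUBE:
        raise ValueError("Fourier tube modes are defined on tube topology only")
    shape_mask = state.kind != KIND_HOOK
    xy = state.pos[:, :2]
    center = xy[shape_mask].mean(axis=0)
    x = state.pos[:, 0] - center[0]
    y = state.pos[:, 1] - center[1]
    return shape_mask, x, y


def fourier_modes(state: ParticleState, box: SimulationBox) -> ModeAmplitudes:
    """Lowest shape and rod-density Fourier modes of a membrane tube."""
    shape_mask, x, y = _tube_frame(state, box)
    lz = box.lengths[2]
    r2d = np.hypot(x, y)
    theta = np.arctan2(x, y)
    ph_z = np.exp(-1j * 2.0 * np.pi * state.pos[:, 2] / lz)
    ph_t = np.exp(-2j * theta)
    w = r2d
    sm = shape_mask
    r_qz = (w[sm] * ph_z[sm]).mean()
    r_qt = (w[sm] * ph_t[sm]).mean()
    rod = state.kind == KIND_BACKBONE
    if rod.any():
        n_qz = (w[rod] * ph_z[rod]).mean()
        n_qt = (w[rod] * ph_t[rod]).mean()
    else:
        n_qz = 0.0 + 0.0j
        n_qt = 0.0 + 0.0j
    return ModeAmplitudes(complex(r_qz), complex(r_qt), complex(n_qz),
                          complex(n_qt), float(r2d[sm].mean()))


def helix_radius(state: ParticleState, box: SimulationBox,
                 slice_width: float = 4.0) -> HelixFit:
    """Radius of the rod assembly from the central axial slice.

    The slice of width ``0.4 r_rod`` (4 sigma by default) is centered on
    the rod assembly's axial midpoint (circular mean over the periodic z).
    ``R_hel = (1/N_sl) sum |r2D_i - r2D_g|`` with ``r2D_g`` the projected
    center of mass of the slice particles.
    """
    if box.topology != TOPOLOGY_TUBE:
        raise ValueError("helix radius is defined on tube topology only")
    rod = state.kind == KIND_BACKBONE
    if not rod.any():
        raise ValueError("no rod particles present")
    lz = box.lengths[2]
    psi = 2.0 * np.pi * state.pos[rod, 2] / lz
    z_mid = (lz / (2.0 * np.pi)) * np.angle(np.exp(1j * psi).mean())
    dz = state.pos[rod, 2] - z_mid
    dz -= lz * np.floor(dz / lz + 0.5)
    sl = np.abs(dz) <= 0.5 * slice_width
    if sl.sum() < 3:
        raise ValueError("fewer than 3 rod particles in the central slice")
    xy = state.pos[rod][sl][:, :2]
    g = xy.mean(axis=0)
    d = np.linalg.norm(xy - g, axis=1)
    return HelixFit(float(d.mean()), float(z_mid % lz), int(sl.sum()),
                    float(d.std()))


def _rod_contacts(state: ParticleState, box: SimulationBox, cutoff: float):
    rod = np.where(state.kind == KIND_BACKBONE)[0]
    ids = state.rod_id[rod]
    nr = state.n_rods
    pos = state.pos[rod]
    edges_i, edges_j = [], []
    # chunked all-pairs with minimum image (rod particle counts are small)
    for a in range(0, len(pos), 512):
        d = pos[a:a + 512, None, :] - pos[None, :, :]
        d = minimum_image(d, box)
        r2 = (d ** 2).sum(axis=-1)
        ii, jj = np.where(r2 < cutoff * cutoff)
        edges_i.append(ids[a + ii])
        edges_j.append(ids[jj])
    ei = np.concatenate(edges_i)
    ej = np.concatenate(edges_j)
    keep = ei != ej
    g = coo_matrix((np.ones(keep.sum()), (ei[keep], ej[keep])), shape=(nr, nr))
    return g, nr


def cluster_sizes(state: ParticleState, box: SimulationBox,
                  cutoff: float = 1.25) -> np.ndarray:
    """Sizes of single-linkage rod clusters (two rods are connected when
    any inter-rod backbone pair is within ``cutoff``)."""
    g, nr = _rod_contacts(state, box, cutoff)
    if nr == 0:
        return np.zeros(0, dtype=int)
    _, labels = connected_components(g, directed=False)
    return np.bincount(labels)


def mean_cluster_size(state: ParticleState, box: SimulationBox,
                      cutoff: float = 1.25, weight: str = "rod") -> float:
    """Mean rod cluster size <N_cl>.

    ``weight='rod'`` averages the cluster size experienced by a rod
    (sum Nc^2 / sum Nc); ``weight='cluster'`` averages over clusters
    (sum Nc / #clusters).  Both are logged because the convention is a
    choice; trends are identical.
    """
    sizes = cluster_sizes(state, box, cutoff)
    if len(sizes) == 0:
        return 0.0
    if weight == "rod":
        return float((sizes.astype(float) ** 2).sum() / sizes.sum())
    if weight == "cluster":
        return float(sizes.mean())
    raise ValueError("weight must be 'rod' or 'cluster'")


def membrane_z_span(state: ParticleState, box: SimulationBox | None = None,
                    exclude_gas: bool = True) -> float:
    """Root-mean-square vertical span <z_mb^2>^(1/2) of the membrane
    particles about their mean plane (flat topology).

    The membrane coexists with a dilute vapor of monomers; by default
    particles with fewer than 2 neighbors within 1.6 sigma are excluded so
    rare evaporated particles do not dominate the rms.
    """
    if box is not None and box.topology != TOPOLOGY_FLAT:
        raise ValueError("membrane span is defined for flat topology")
    mask = state.kind == KIND_MEMBRANE
    if not mask.any():
        mask = state.kind != KIND_HOOK
    if exclude_gas and box is not None and state.n <= 20000:
        d = state.pos[:, None, :] - state.pos[None, :, :]
        d = minimum_image(d, box)
        r2 = (d ** 2).sum(axis=-1)
        np.fill_diagonal(r2, np.inf)
        neighbors = (r2 < 1.6 ** 2).sum(axis=1)
        mask = mask & (neighbors >= 2)
    z = state.pos[mask, 2]
    return float(np.sqrt(((z - z.mean()) ** 2).mean()))


@dataclass
class ShapeThresholds:
    """Documented classifier thresholds (dimensionless)."""
    ellipticity: float = 0.12        # |r_qtheta| / <r2D> above -> elliptical
    cluster_fraction: float = 0.5    # dominant-cluster share for a helix
    winding: float = 1.5 * np.pi     # accumulated azimuthal wrap for a helix
    contact_cutoff: float = 1.25


def _dominant_cluster_winding(state: ParticleState, box: SimulationBox,
                              thr: ShapeThresholds):
    """(fraction of rods in largest cluster, its unwrapped azimuthal span)."""
    g, nr = _rod_contacts(state, box, thr.contact_cutoff)
    if nr == 0:
        return 0.0, 0.0
    _, labels = connected_components(g, directed=False)
    sizes = np.bincount(labels)
    main = int(np.argmax(sizes))
    frac = sizes[main] / nr
    rod = state.kind == KIND_BACKBONE
    sel = rod.copy()
    sel[rod] = np.isin(state.rod_id[rod],
                       np.where(labels == main)[0])
    _, x, y = _tube_frame(state, box)
    theta = np.arctan2(x[sel], y[sel])
    z = state.pos[sel, 2]
    order = np.argsort(z)
    th = np.unwrap(theta[order])
    if len(th) < 2:
        return frac, 0.0
    return float(frac), float(abs(th[-1] - th[0]))


def classify_tube_shape(state: ParticleState, box: SimulationBox,
                        thresholds: ShapeThresholds | None = None) -> str:
    """Classify a tube frame: cylindrical / elliptical / helical_cylinder.

    * elliptical: the normalized two-fold shape mode
      ``|r_qtheta| / <r2D>`` exceeds the ellipticity threshold;
    * helical_cylinder: the cross-section stays round while most rods form
      one connected assembly winding at least ``winding`` radians of
      azimuth along z;
    * cylindrical otherwise; 'ambiguous' when both signatures fire.
    """
    thr = thresholds or ShapeThresholds()
    modes = fourier_modes(state, box)
    ell = abs(modes.r_qtheta) / modes.mean_r2d if modes.mean_r2d > 0 else 0.0
    elliptical = ell > thr.ellipticity
    helical = False
    if (state.kind == KIND_BACKBONE).any():
        frac, wind = _dominant_cluster_winding(state, box, thr)
        helical = frac >= thr.cluster_fraction and wind >= thr.winding
    if elliptical and helical:
        return "ambiguous"
    if elliptical:
        return "elliptical"
    if helical:
        return "helical_cylinder"
    return "cylindrical"
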