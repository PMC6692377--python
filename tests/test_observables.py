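"""Fourier modes, helix radius, cluster statistics, membrane span,
shape classification."""

import numpy as np
import pytest

from memrod import (ParticleState, SimulationBox, classify_tube_shape,
                    cluster_sizes, fourier_modes, helix_radius, make_fixture,
                    mean_cluster_size, membrane_z_span, minimum_image)
from memrod.core import KIND_BACKBONE, KIND_MEMBRANE


def tube_state(r2d, theta, z, kind=None, rod_id=None, lz=40.0):
    n = len(theta)
    # theta measured from the y axis: x = r sin(theta), y = r cos(theta)
    pos = np.column_stack([r2d * np.sin(theta), r2d * np.cos(theta), z])
    u = np.column_stack([np.sin(theta), np.cos(theta), np.zeros(n)])
    state = ParticleState(
        pos, u,
        np.zeros(n, dtype=np.int8) if kind is None else kind,
        np.full(n, -1, dtype=np.int32) if rod_id is None else rod_id,
        np.full(n, -1, dtype=np.int16))
    return state, SimulationBox([100.0, 100.0, lz], "tube")


class TestFourierModes:
    def test_uniform_cylinder_has_vanishing_modes(self):
        rng = np.random.default_rng(0)
        n = 4000
        theta = rng.uniform(0, 2 * np.pi, n)
        z = rng.uniform(0, 40, n)
        state, box = tube_state(np.full(n, 8.0), theta, z)
        m = fourier_modes(state, box)
        assert abs(m.r_qtheta) < 8.0 * 3 / np.sqrt(n)
        assert abs(m.r_qz) < 8.0 * 3 / np.sqrt(n)

    def test_elliptical_cross_section_matches_analytic_integral(self):
        """|r_qtheta| of an ellipse equals the closed-form Fourier integral
        (numerical quadrature oracle); |r_qz| stays at the noise floor."""
        a, b, n = 10.0, 6.0, 120000
        rng = np.random.default_rng(1)
        t = rng.uniform(0, 2 * np.pi, n)   # uniform in angle parameter
        x = a * np.sin(t)
        y = b * np.cos(t)
        z = rng.uniform(0, 40, n)
        theta = np.arctan2(x, y)
        r2d = np.hypot(x, y)
        state, box = tube_state(r2d, theta, z)
        state.pos[:, 0] = x
        state.pos[:, 1] = y
        m = fourier_modes(state, box)
        # oracle: (1/2pi) int r(t) exp(-2 i theta(t)) dt over the same
        # parameter measure
        tt = np.linspace(0, 2 * np.pi, 200001)[:-1]
        xx, yy = a * np.sin(tt), b * np.cos(tt)
        rr = np.hypot(xx, yy)
        th = np.arctan2(xx, yy)
        oracle = np.mean(rr * np.exp(-2j * th))
        assert abs(m.r_qtheta) == pytest.approx(abs(oracle), rel=0.02)
        assert abs(m.r_qtheta) > 10 * abs(m.r_qz)

    def test_rod_density_mode_at_delta_distribution(self):
        """All rods at theta = 0 -> |n_qtheta| equals the mean rod r2D."""
        n = 600
        rng = np.random.default_rng(2)
        theta = np.zeros(n)
        z = rng.uniform(0, 40, n)
        r2d = np.full(n, 7.0)
        kind = np.full(n, KIND_BACKBONE, dtype=np.int8)
        rid = np.zeros(n, dtype=np.int32)
        state, box = tube_state(r2d, theta, z, kind=kind, rod_id=rid)
        # add a uniform membrane background so the axis recentering is fair
        bg_theta = rng.uniform(0, 2 * np.pi, 4000)
        bg_z = rng.uniform(0, 40, 4000)
        bg, _ = tube_state(np.full(4000, 7.0), bg_theta, bg_z)
        full = ParticleState(
            np.vstack([state.pos, bg.pos]),
            np.vstack([state.orient, bg.orient]),
            np.concatenate([state.kind, bg.kind]),
            np.concatenate([state.rod_id, bg.rod_id]),
            np.concatenate([state.seg, bg.seg]))
        m = fourier_modes(full, box)
        rod_mask = full.kind == KIND_BACKBONE
        r2d_mean = np.hypot(full.pos[rod_mask, 0] - full.pos[:, 0].mean(),
                            full.pos[rod_mask, 1] - full.pos[:, 1].mean())
        assert abs(m.n_qtheta) == pytest.approx(r2d_mean.mean(), rel=0.02)

    def test_moduli_invariant_under_axial_rotation(self):
        rng = np.random.default_rng(3)
        n = 500
        theta = rng.uniform(0, 2 * np.pi, n) ** 1.3 % (2 * np.pi)
        z = rng.uniform(0, 40, n)
        r2d = 8.0 + rng.normal(0, 0.5, n)
        state, box = tube_state(r2d, theta, z)
        m0 = fourier_modes(state, box)
        phi = 0.9
        rot = np.array([[np.cos(phi), -np.sin(phi), 0],
                        [np.sin(phi), np.cos(phi), 0], [0, 0, 1.0]])
        rstate = ParticleState(state.pos @ rot.T, state.orient @ rot.T,
                               state.kind, state.rod_id, state.seg)
        m1 = fourier_modes(rstate, box)
        assert abs(m1.r_qtheta) == pytest.approx(abs(m0.r_qtheta), abs=1e-12)
        assert abs(m1.r_qz) == pytest.approx(abs(m0.r_qz), abs=1e-12)

    def test_flat_topology_rejected(self):
        state, box = make_fixture("flat_patch_100")
        with pytest.raises(ValueError):
            fourier_modes(state, box)


class TestHelixRadius:
    def make_helix(self, radius, lz=40.0, pitch=1.5, n=2000):
        s = np.linspace(0, lz / pitch * 2 * np.pi, n)
        theta = s
        z = s / (2 * np.pi) * pitch
        kind = np.full(n, KIND_BACKBONE, dtype=np.int8)
        rid = np.zeros(n, dtype=np.int32)
        return tube_state(np.full(n, radius), theta, z % lz, kind=kind,
                          rod_id=rid, lz=lz)

    def test_perfect_helix_returns_exact_radius(self):
        """Full turns inside the analysis slice: the slice center of mass
        sits exactly on the axis and R_hel equals the helix radius."""
        turns, per_turn = 3, 50
        n = turns * per_turn
        theta = np.linspace(0, 2 * np.pi * turns, n, endpoint=False)
        z = 20.0 + np.linspace(-1.9, 1.9, n)   # all inside the 4-sigma slice
        kind = np.full(n, KIND_BACKBONE, dtype=np.int8)
        state, box = tube_state(np.full(n, 5.0), theta, z, kind=kind,
                                rod_id=np.zeros(n, dtype=np.int32))
        fit = helix_radius(state, box)
        assert fit.r_hel == pytest.approx(5.0, abs=1e-10)
        assert fit.n_slice == n

    def test_dense_helix_radius_close(self):
        state, box = self.make_helix(5.0)
        fit = helix_radius(state, box)
        assert fit.r_hel == pytest.approx(5.0, rel=0.02)
        assert fit.n_slice >= 3

    def test_translation_along_z_and_rotation_invariance(self):
        state, box = self.make_helix(5.0)
        f0 = helix_radius(state, box)
        shifted = state.copy()
        shifted.pos[:, 2] = (shifted.pos[:, 2] + 13.7) % box.lengths[2]
        f1 = helix_radius(shifted, box)
        assert f1.r_hel == pytest.approx(f0.r_hel, abs=1e-9)

    def test_two_concentric_rings_average(self):
        n = 400
        rng = np.random.default_rng(4)
        theta = rng.uniform(0, 2 * np.pi, n)
        r2d = np.where(np.arange(n) % 2 == 0, 4.0, 6.0)
        z = np.full(n, 20.0)
        kind = np.full(n, KIND_BACKBONE, dtype=np.int8)
        state, box = tube_state(r2d, theta, z, kind=kind,
                                rod_id=np.zeros(n, dtype=np.int32))
        fit = helix_radius(state, box)
        # direct averaging oracle: mean distance from the ring center
        assert fit.r_hel == pytest.approx(5.0, abs=0.15)

    def test_no_rods_rejected(self):
        state, box = make_fixture("tube_small")
        with pytest.raises(ValueError):
            helix_radius(state, box)


def brute_force_clusters(state, box, cutoff):
    """O(n_rods^2) connected-components oracle via label propagation."""
    rods = np.unique(state.rod_id[state.rod_id >= 0])
    labels = {r: r for r in rods}
    pts = {r: state.pos[(state.rod_id == r) & (state.kind == KIND_BACKBONE)]
           for r in rods}
    changed = True
    while changed:
        changed = False
        for a in rods:
            for b in rods:
                if labels[a] == labels[b]:
                    continue
                d = pts[a][:, None, :] - pts[b][None, :, :]
                d = minimum_image(d, box)
                if (d ** 2).sum(axis=-1).min() < cutoff ** 2:
                    new = min(labels[a], labels[b])
                    old = max(labels[a], labels[b])
                    for r in rods:
                        if labels[r] == old:
                            labels[r] = new
                    changed = True
    sizes = {}
    for r in rods:
        sizes[labels[r]] = sizes.get(labels[r], 0) + 1
    return sorted(sizes.values())


class TestClusters:
    def test_isolated_rods_give_unit_mean(self):
        state, box = self._random_rods(8, spread=30.0, seed=0)
        assert mean_cluster_size(state, box) == pytest.approx(1.0)

    def test_single_cluster_gives_rod_count(self):
        state, box = self._random_rods(6, spread=2.0, seed=1)
        # force contact: put all rods within one blob
        assert mean_cluster_size(state, box) == pytest.approx(6.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_components(self, seed):
        state, box = self._random_rods(12, spread=9.0, seed=seed)
        sizes = sorted(cluster_sizes(state, box).tolist())
        assert sizes == brute_force_clusters(state, box, 1.25)

    def test_rod_vs_cluster_weighting(self):
        # two clusters of sizes 3 and 1
        state, box = self._random_rods(4, spread=30.0, seed=3)
        pos = state.pos.copy()
        for r in (1, 2):
            mask = state.rod_id == r
            base = state.pos[state.rod_id == 0][:mask.sum()]
            pos[mask] = base + np.array([0.0, 0.5 * r, 0.0])
        state = ParticleState(pos, state.orient, state.kind, state.rod_id,
                              state.seg)
        assert mean_cluster_size(state, box, weight="cluster") == \
            pytest.approx((3 + 1) / 2)
        assert mean_cluster_size(state, box, weight="rod") == \
            pytest.approx((9 + 1) / (3 + 1))

    @staticmethod
    def _random_rods(n_rods, spread, seed):
        rng = np.random.default_rng(seed)
        pos, kind, rid, seg = [], [], [], []
        for r in range(n_rods):
            start = rng.uniform(0, spread, 3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            for s in range(10):
                pos.append(start + s * 1.11 * direction)
                kind.append(KIND_BACKBONE)
                rid.append(r)
                seg.append(s)
        n = len(pos)
        state = ParticleState(np.asarray(pos),
                              np.tile([0.0, 0, 1], (n, 1)),
                              np.asarray(kind, dtype=np.int8),
                              np.asarray(rid, dtype=np.int32),
                              np.asarray(seg, dtype=np.int16))
        return state, SimulationBox([60.0, 60.0, 60.0], "flat")


class TestMembraneSpan:
    def test_flat_sheet_at_offset_has_zero_span(self):
        pos = np.column_stack([np.arange(100) % 10, np.arange(100) // 10,
                               np.full(100, 3.7)])
        state = ParticleState.membrane_only(pos,
                                            np.tile([0.0, 0, 1], (100, 1)))
        assert membrane_z_span(state) == pytest.approx(0.0, abs=1e-12)

    def test_two_level_sheet_closed_form(self):
        z = np.where(np.arange(200) % 2 == 0, 2.0, -2.0)
        pos = np.column_stack([np.arange(200) * 0.5, np.zeros(200), z])
        state = ParticleState.membrane_only(pos,
                                            np.tile([0.0, 0, 1], (200, 1)))
        assert membrane_z_span(state) == pytest.approx(2.0, rel=1e-12)

    def test_sinusoidal_sheet_rms_amplitude(self):
        lx, amp, n = 40.0, 1.3, 400
        x = np.linspace(0, lx, n, endpoint=False)
        z = amp * np.sin(2 * np.pi * x / lx)
        pos = np.column_stack([x, np.zeros(n), z])
        state = ParticleState.membrane_only(pos,
                                            np.tile([0.0, 0, 1], (n, 1)))
        assert membrane_z_span(state) == pytest.approx(amp / np.sqrt(2),
                                                       rel=1e-3)

    def test_tube_topology_rejected(self):
        state, box = make_fixture("tube_small")
        with pytest.raises(ValueError):
            membrane_z_span(state, box)


class TestClassifier:
    def test_plain_tube_is_cylindrical(self):
        state, box = make_fixture("tube_small")
        assert classify_tube_shape(state, box) == "cylindrical"

    def test_elliptical_fixture(self):
        state, box = make_fixture("elliptical")
        assert classify_tube_shape(state, box) == "elliptical"

    def test_helical_wrap_fixture(self):
        state, box = make_fixture("helical_wrap")
        assert classify_tube_shape(state, box) == "helical_cylinder"

    def test_fixture_determinism(self):
        a, _ = make_fixture("helical_wrap", seed=5)
        b, _ = make_fixture("helical_wrap", seed=5)
        assert np.array_equal(a.pos, b.pos)
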