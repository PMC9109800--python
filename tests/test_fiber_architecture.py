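"""Cardiac-frame angles, disarray index, transmural profiles, layer detection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from septumkit.fiber_architecture import (
    LayerReportRow,
    TransmuralProfile,
    build_local_frames,
    compute_angle_maps,
    compute_mdi,
    detect_layer_discontinuity,
    frames_from_sidecar,
    layer_report_table,
    summarize_specimens,
    transmural_profile,
)


def _slab_frames(shape=(4, 4, 4)):
    from septumkit.fiber_architecture import LocalFrame

    full = lambda v: np.broadcast_to(np.asarray(v, float), shape + (3,)).copy()
    rho = np.broadcast_to(
        (np.arange(shape[1]) + 0.5)[None, :, None] / shape[1], shape
    ).copy()
    return LocalFrame(
        c_hat=full([1, 0, 0]),
        l_hat=full([0, 0, 1]),
        t_hat=full([0, 1, 0]),
        rho=rho,
        mask=np.ones(shape, bool),
    )


class TestFrames:
    def test_sidecar_frames_match_slab_axes(self, noiseless_phantom):
        fr = frames_from_sidecar(noiseless_phantom)
        assert np.allclose(fr.c_hat[..., 0], 1.0)
        assert np.allclose(fr.t_hat[..., 1], 1.0)
        assert np.allclose(fr.l_hat[..., 2], 1.0)
        assert fr.orthonormality_defect() < 1e-10

    def test_annulus_radial_frame_geometry(self):
        """A voxel on the +x axis has transmural +x and circumferential +y."""
        shape = (21, 21, 3)
        center = np.array([10.0, 10.0, 1.0]) * 1.0
        idx = np.moveaxis(np.indices(shape), 0, -1).astype(float)
        r = np.linalg.norm(idx[..., :2] - center[:2], axis=-1)
        mask = (r >= 4) & (r <= 9)
        fr = build_local_frames(mask, (1.0, 1.0, 1.0), long_axis=(0, 0, 1),
                                chamber_center=center)
        vox = (18, 10, 1)  # on the +x ray from the center
        assert fr.mask[vox]
        assert np.allclose(fr.t_hat[vox], [1, 0, 0], atol=1e-12)
        assert np.allclose(fr.c_hat[vox], [0, 1, 0], atol=1e-12)
        assert fr.orthonormality_defect() < 1e-10
        assert fr.rho[mask].min() >= 0.0 and fr.rho[mask].max() <= 1.0

    def test_on_axis_voxels_excluded(self):
        shape = (5, 5, 3)
        mask = np.ones(shape, bool)
        fr = build_local_frames(mask, (1.0, 1.0, 1.0), chamber_center=(2.0, 2.0, 1.0))
        assert not fr.mask[2, 2, :].any()


class TestAngleMaps:
    @pytest.mark.parametrize(
        "v, expect_ha",
        [
            ([1, 0, 0], 0.0),          # circumferential
            ([0, 0, 1], 90.0),         # longitudinal (+90 by convention)
            ([np.sqrt(0.5), 0, np.sqrt(0.5)], 45.0),
        ],
    )
    def test_helix_angle_reference_directions(self, v, expect_ha):
        fr = _slab_frames()
        field = np.broadcast_to(np.asarray(v, float), fr.mask.shape + (3,)).copy()
        maps = compute_angle_maps(field, None, None, fr)
        assert np.allclose(maps["HA"][fr.mask], expect_ha, atol=1e-10)
        assert np.allclose(maps["TA"][fr.mask], 0.0, atol=1e-10)

    def test_all_angles_invariant_under_eigenvector_sign_flip(self, rng):
        fr = _slab_frames()
        v1 = rng.normal(size=fr.mask.shape + (3,))
        v1 /= np.linalg.norm(v1, axis=-1, keepdims=True)
        v3 = rng.normal(size=fr.mask.shape + (3,))
        v3 /= np.linalg.norm(v3, axis=-1, keepdims=True)
        signs = np.where(rng.random(fr.mask.shape) < 0.5, -1.0, 1.0)[..., None]
        a = compute_angle_maps(v1, None, v3, fr)
        b = compute_angle_maps(v1 * signs, None, v3 * -signs, fr)
        for key in ("HA", "TA", "SE", "SA"):
            assert np.allclose(a[key], b[key], equal_nan=True)

    def test_transmural_v1_flagged_undefined(self):
        fr = _slab_frames()
        v1 = np.broadcast_to([0.0, 1.0, 0.0], fr.mask.shape + (3,)).copy()
        maps = compute_angle_maps(v1, None, None, fr)
        assert not maps["valid"].any()
        assert np.isnan(maps["HA"]).all()


class TestMdi:
    def test_uniform_field_is_one(self):
        v1 = np.broadcast_to([1.0, 0.0, 0.0], (5, 5, 5, 3)).copy()
        mdi = compute_mdi(v1, np.ones((5, 5, 5), bool))
        assert np.allclose(mdi[1:-1, 1:-1, 1:-1], 1.0)

    def test_sign_flip_of_neighbors_invisible(self, rng):
        v1 = np.broadcast_to([0.0, 1.0, 0.0], (5, 5, 5, 3)).copy()
        signs = np.where(rng.random((5, 5, 5)) < 0.5, -1.0, 1.0)
        mdi = compute_mdi(v1 * signs[..., None], np.ones((5, 5, 5), bool))
        assert np.allclose(mdi[1:-1, 1:-1, 1:-1], 1.0)

    def test_uniform_random_orientations_average_half(self, rng):
        """E|cos angle| = 1/2 for directions uniform on the sphere."""
        n = 47  # ~1e5 voxels
        v1 = rng.normal(size=(n, n, n, 3))
        v1 /= np.linalg.norm(v1, axis=-1, keepdims=True)
        mdi = compute_mdi(v1, np.ones((n, n, n), bool))
        assert np.nanmean(mdi) == pytest.approx(0.5, abs=0.01)

    def test_monotone_in_angular_dispersion(self, rng):
        base = np.array([1.0, 0.0, 0.0])
        means = []
        for sigma in (0.05, 0.2, 0.5, 1.0):
            v1 = base + rng.normal(scale=sigma, size=(12, 12, 12, 3))
            v1 /= np.linalg.norm(v1, axis=-1, keepdims=True)
            means.append(np.nanmean(compute_mdi(v1, np.ones((12, 12, 12), bool))))
        assert np.all(np.diff(means) < 0)

    def test_window_validation_and_isolated_voxel(self):
        v1 = np.broadcast_to([1.0, 0.0, 0.0], (5, 5, 5, 3)).copy()
        with pytest.raises(ValueError):
            compute_mdi(v1, np.ones((5, 5, 5), bool), window=4)
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        assert np.isnan(compute_mdi(v1, mask)[2, 2, 2])


def _profile_from_median(median, edges=None):
    n = len(median)
    edges = np.linspace(0, 1, n + 1) if edges is None else edges
    med = np.asarray(median, float)
    return TransmuralProfile(
        bin_edges=edges, median=med, q25=med, q75=med, count=np.ones(n, int)
    )


class TestProfile:
    def test_linear_field_profiles_linearly(self):
        fr = _slab_frames(shape=(4, 40, 4))
        ha_true = 60.0 - 120.0 * fr.rho
        prof = transmural_profile(ha_true, fr.rho, fr.mask, n_bins=20)
        expect = 60.0 - 120.0 * prof.bin_centers
        assert np.abs(prof.median - expect).max() <= 0.5 * 120.0 / 20.0

    def test_constant_map_zero_iqr(self):
        fr = _slab_frames(shape=(4, 40, 4))
        prof = transmural_profile(np.full(fr.mask.shape, 33.0), fr.rho, fr.mask, 20)
        assert np.allclose(prof.median, 33.0)
        assert np.allclose(prof.q75 - prof.q25, 0.0, atol=1e-12)

    def test_plateau_at_minus_84_beyond_layer_boundary(self, noiseless_phantom):
        from septumkit.dti import tensor_metrics

        met = tensor_metrics(noiseless_phantom.tensors)
        fr = frames_from_sidecar(noiseless_phantom)
        maps = compute_angle_maps(met["v1"], None, None, fr)
        prof = transmural_profile(maps["HA"], fr.rho, fr.mask, n_bins=25)
        plateau = prof.median[prof.bin_centers > 0.62]
        assert np.allclose(plateau, -84.0, atol=0.5)

    def test_empty_bins_recorded_missing(self):
        fr = _slab_frames(shape=(4, 4, 4))  # only 4 distinct rho values
        prof = transmural_profile(np.zeros(fr.mask.shape), fr.rho, fr.mask, n_bins=20)
        assert np.isnan(prof.median).any()
        assert (prof.count == 0).any()

    def test_axial_statistics_unbiased_near_90(self, rng):
        """Orientation noise around -84 deg must not drag the median toward 0."""
        vals = -84.0 + rng.normal(0, 8.0, 4000)
        vals = (vals + 90.0) % 180.0 - 90.0  # fold like a measured orientation
        rho = np.full(vals.shape, 0.5)
        prof = transmural_profile(vals, rho, np.ones(vals.shape, bool), n_bins=20)
        assert prof.median[10] == pytest.approx(-84.0, abs=1.0)


class TestLayerDetection:
    def test_piecewise_profile_from_measured_averages(self):
        """Jump at rho = 0.608 to -84 reproduces the 60.8/39.2 split."""
        edges = np.linspace(0.0, 1.0, 126)  # 0.608 falls on a bin boundary
        centers = 0.5 * (edges[:-1] + edges[1:])
        median = np.where(
            centers < 0.608, 57.0 + (-40.0 - 57.0) * centers / 0.608, -84.0
        )
        row = detect_layer_discontinuity(_profile_from_median(median, edges))
        assert row.has_discontinuity
        assert row.lv_layer_percent == pytest.approx(60.8, abs=1e-9)
        assert row.rv_layer_percent == pytest.approx(39.2, abs=1e-9)
        # first-bin median sits at the bin center of the ramp, just below 57
        assert row.orientation_lv_endo == pytest.approx(57.0, abs=1.0)
        assert row.orientation_rv_endo == pytest.approx(-84.0)

    def test_smooth_linear_profile_has_no_discontinuity(self):
        centers = np.linspace(0.01, 0.99, 50)
        row = detect_layer_discontinuity(_profile_from_median(60.0 - 120.0 * centers))
        assert not row.has_discontinuity
        assert row.rho_star is None

    def test_jump_below_threshold_rejected(self):
        median = np.where(np.arange(30) < 15, 10.0, -10.0)  # 20 deg jump
        row = detect_layer_discontinuity(_profile_from_median(median))
        assert not row.has_discontinuity
        assert row.jump_deg == pytest.approx(20.0)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            detect_layer_discontinuity(_profile_from_median(np.zeros(10)))


class TestSpecimenSummary:
    ROWS = [
        ("Sheep 1", 61.9, 38.1, 60.7, -89.4),
        ("Sheep 2", 58.3, 41.7, 51.6, -81.6),
        ("Sheep 3", 62.1, 37.9, 58.4, -81.3),
    ]

    def _rows(self):
        return [
            LayerReportRow(name, True, lv / 100.0, lv, rv, o_lv, o_rv, 45.0)
            for name, lv, rv, o_lv, o_rv in self.ROWS
        ]

    def test_measured_specimen_average(self):
        """Per-column means reproduce the published average row exactly."""
        avg = summarize_specimens(self._rows())
        assert avg["lv_layer_percent"] == 60.8
        assert avg["rv_layer_percent"] == 39.2
        assert avg["orientation_lv_endo"] == 57
        assert avg["orientation_rv_endo"] == -84

    def test_single_row_unchanged(self):
        avg = summarize_specimens(self._rows()[:1])
        assert avg["lv_layer_percent"] == 61.9
        assert avg["orientation_rv_endo"] == -89

    def test_report_table_has_average_row(self):
        df = layer_report_table(self._rows())
        assert list(df["specimen"]) == ["Sheep 1", "Sheep 2", "Sheep 3", "Average"]
        assert df.iloc[-1]["lv_layer_percent"] == 60.8


def test_quadrant_masks_partition_annulus():
    """Sector x level masks are disjoint and cover the annular mask."""
    from septumkit.fiber_architecture import build_local_frames, quadrant_masks

    shape = (21, 21, 8)
    center = np.array([10.0, 10.0, 3.5])
    idx = np.moveaxis(np.indices(shape), 0, -1).astype(float)
    r = np.linalg.norm(idx[..., :2] - center[:2], axis=-1)
    mask = (r >= 4) & (r <= 9)
    fr = build_local_frames(mask, (1.0, 1.0, 1.0), chamber_center=center)
    coords = idx  # unit voxels
    masks = quadrant_masks(fr, coords, center)
    assert len(masks) == 16
    total = np.zeros(shape, int)
    for m in masks.values():
        assert not (m & ~fr.mask).any()
        total += m
    assert (total[fr.mask] == 1).all()  # disjoint cover of the in-mask voxels
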