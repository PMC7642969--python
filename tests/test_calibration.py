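import numpy as np
import pytest
from scipy.special import erf

import spexi
from spexi import SystemGeometry
from spexi import synthetic as syn
from spexi.calibration import (
    AttenuationImage,
    BeamRegion,
    CalibrationAnchors,
    EdgeTrace,
    energy_map_one_point,
    energy_map_two_point,
    estimate_resolution,
    find_beam_region,
    find_edge,
    find_two_point_anchors,
    normalize,
)
from spexi.geometry import HC_KEV_ANGSTROM, bragg_angle, plane_spacing


class TestNormalize:
    def test_half_transmission(self):
        att = normalize(np.full((2, 2), 60.0), np.full((2, 2), 10.0),
                        np.full((2, 2), 110.0))
        np.testing.assert_allclose(att.values, np.log(2), rtol=1e-12)

    def test_tomo_equal_flat_gives_zero(self):
        flat = np.full((3, 3), 200.0)
        att = normalize(flat, np.zeros((3, 3)), flat)
        np.testing.assert_allclose(att.values, 0.0, atol=1e-14)

    def test_degenerate_pixel_masked_not_fatal(self):
        flat = np.array([[100.0, 10.0]])
        att = normalize(np.array([[50.0, 5.0]]), np.array([[0.0, 10.0]]), flat)
        assert att.mask[0, 0] and not att.mask[0, 1]
        assert np.isnan(att.values[0, 1])

    def test_all_masked_is_an_error(self):
        with pytest.raises(ValueError, match="all pixels masked"):
            normalize(np.zeros((2, 2)), np.ones((2, 2)), np.zeros((2, 2)))

    def test_inverted_exactly_by_forward_model(self):
        # -ln round trip without noise, down to float precision
        rng = np.random.default_rng(0)
        a_true = rng.uniform(0.0, 3.0, (20, 10))
        dark = np.full((20, 10), 100.0)
        flat = dark + 1e4
        tomo = dark + 1e4 * np.exp(-a_true)
        att = normalize(tomo, dark, flat)
        np.testing.assert_allclose(att.values, a_true, atol=1e-12)


class TestBeamRegion:
    def test_gaussian_profile_run_matches_fwhm(self):
        rows = np.arange(400, dtype=float)[:, None]
        sigma = 30.0
        flat = 1000.0 * np.exp(-0.5 * ((rows - 200) / sigma) ** 2) * np.ones((1, 5))
        region = find_beam_region(flat, np.zeros_like(flat), 0.5)
        fwhm = 2 * np.sqrt(2 * np.log(2)) * sigma
        widths = region.bottom - region.top
        assert np.all(np.abs(widths - fwhm) <= 1.5)

    def test_uniform_column_fully_retained(self):
        flat = np.full((50, 3), 10.0)
        region = find_beam_region(flat, np.zeros_like(flat), 0.5)
        assert np.all(region.top == 0) and np.all(region.bottom == 50)

    def test_all_zero_flat_is_beam_absent(self):
        with pytest.raises(ValueError, match="beam absent"):
            find_beam_region(np.zeros((20, 4)), np.zeros((20, 4)), 0.1)

    def test_short_runs_excluded(self):
        flat = np.zeros((50, 2))
        flat[10:14, 0] = 10.0  # 4-row run, below the 8-row minimum
        flat[5:45, 1] = 10.0
        region = find_beam_region(flat, np.zeros_like(flat), 0.5)
        assert not region.valid[0] and region.valid[1]

    def test_threshold_fraction_validated(self):
        with pytest.raises(ValueError):
            find_beam_region(np.ones((20, 2)), np.zeros((20, 2)), 1.5)


def _edge_image(n_rows=400, n_cols=8, rows_at=None, sigma_px=1.0, jump=1.5):
    """Attenuation image with an erf edge centred at rows_at[col]."""
    if rows_at is None:
        rows_at = np.full(n_cols, 240.0)
    rows = np.arange(n_rows, dtype=float)[:, None]
    a = 0.5 + 0.5 * jump * (1 + erf((rows_at[None, :] - rows)
                                    / (np.sqrt(2) * sigma_px)))
    return AttenuationImage(values=a, mask=np.ones_like(a, dtype=bool))


def _full_region(n_rows, n_cols):
    return BeamRegion(
        top=np.zeros(n_cols, dtype=int),
        bottom=np.full(n_cols, n_rows),
        valid=np.ones(n_cols, dtype=bool),
    )


class TestFindEdge:
    def test_step_centred_at_240_recovered_subpixel(self):
        att = _edge_image()
        trace = find_edge(att, _full_region(400, 8))
        assert np.all(np.abs(trace.row - 240.0) <= 0.25)

    def test_quadratic_bow_recovered(self):
        cols = np.arange(1024)
        rows_at = 240.0 + 0.0005 * (cols - 512.0) ** 2
        att = _edge_image(n_cols=1024, rows_at=rows_at)
        trace = find_edge(att, _full_region(400, 1024))
        rms = np.sqrt(np.mean((trace.row - rows_at) ** 2))
        assert rms < 0.5

    def test_edge_free_column_flagged_invalid(self):
        att = _edge_image(n_cols=4)
        att.values[:, 2] = 1.0  # flat column
        trace = find_edge(att, _full_region(400, 4))
        assert not trace.valid[2] and trace.valid[[0, 1, 3]].all()

    def test_no_valid_column_is_an_error(self):
        att = AttenuationImage(values=np.ones((50, 3)),
                               mask=np.ones((50, 3), dtype=bool))
        with pytest.raises(ValueError, match="no valid column"):
            find_edge(att, _full_region(50, 3))

    def test_localization_unbiased_under_poisson_noise(self, rng):
        # 200 noisy columns at the default simulator count level
        n_cols, true_row = 200, 240.3
        clean = _edge_image(n_cols=n_cols, rows_at=np.full(n_cols, true_row))
        dark = np.full(clean.values.shape, 100.0)
        flat = dark + 1e4
        tomo = rng.poisson(1e4 * np.exp(-clean.values)) + dark
        att = normalize(tomo, dark, flat)
        trace = find_edge(att, _full_region(400, n_cols))
        errors = trace.row[trace.valid] - true_row
        assert abs(errors.mean()) < 0.1

    def test_unblurred_step_width_hits_discretization_floor(self):
        att = _edge_image(sigma_px=0.05)
        trace = find_edge(att, _full_region(400, 8))
        assert np.all(trace.fwhm[trace.valid] <= 2.0)
        assert np.all(trace.fwhm[trace.valid] > 0.0)


class TestEnergyMapOnePoint:
    def _trace(self, n_cols=3, at=200.0):
        return EdgeTrace(row=np.full(n_cols, at), fwhm=np.full(n_cols, 2.0),
                         valid=np.ones(n_cols, dtype=bool))

    def test_edge_row_maps_to_edge_energy_exactly(self, geometry):
        emap = energy_map_one_point(self._trace(), geometry, 400)
        np.testing.assert_allclose(emap.energies[200, :], 12.658, rtol=1e-14)

    def test_closed_form_oracle_100_px_from_anchor(self, geometry):
        # hand evaluation: theta_K + arctan(0.9 mm / 500 mm), then hc/(2 d sin)
        emap = energy_map_one_point(self._trace(), geometry, 400)
        theta = bragg_angle(12.658, geometry) + np.arctan(100 * 0.009 / 500.0)
        expected = HC_KEV_ANGSTROM / (2 * plane_spacing(geometry) * np.sin(theta))
        assert emap.energies[300, 0] == pytest.approx(expected, rel=1e-12)

    def test_strictly_monotonic_along_columns(self, geometry):
        emap = energy_map_one_point(self._trace(), geometry, 400)
        assert np.all(np.diff(emap.energies, axis=0) < 0)  # direction +1

    def test_direction_flip_reverses_monotonicity(self):
        g = SystemGeometry(energy_direction=-1)
        emap = energy_map_one_point(self._trace(), g, 400)
        assert np.all(np.diff(emap.energies, axis=0) > 0)

    def test_local_linearity_of_dispersion(self, geometry):
        # dE/dp ~ -E cot(theta_K) * pixel / F within 1% for |dp| <= 20 px
        emap = energy_map_one_point(self._trace(), geometry, 400)
        theta_k = bragg_angle(12.658, geometry)
        predicted = 12.658 / np.tan(theta_k) * geometry.pixel_size / 500.0
        de = np.diff(emap.energies[180:221, 0])
        np.testing.assert_allclose(np.abs(de), predicted, rtol=0.01)


class TestEnergyMapTwoPoint:
    def test_reproduces_both_anchor_energies(self, geometry):
        anchors = CalibrationAnchors.from_energies(193.6, 12.667, 184.1, 12.681,
                                                   geometry)
        emap = energy_map_two_point(anchors, geometry, 400)
        rows = np.arange(400)
        # linear interpolation between integer rows limits agreement to ~1e-7
        assert np.interp(193.6, rows, emap.energies[:, 0]) == pytest.approx(
            12.667, abs=1e-6
        )
        assert np.interp(184.1, rows, emap.energies[:, 0]) == pytest.approx(
            12.681, abs=1e-6
        )

    def test_degenerate_anchors_rejected(self, geometry):
        with pytest.raises(ValueError, match="degenerate"):
            CalibrationAnchors.from_energies(100.0, 12.667, 100.0, 12.681, geometry)

    def test_truth_placed_anchors_reproduce_generating_map(self, edge_sim, geometry):
        # selenate anchors at the known peak energies, rows taken from the
        # simulator's generating map: the two-point map must agree with it
        # to < 1e-4 keV everywhere in the beam
        stacks, truth = edge_sim
        e = truth.energy_map.energies
        n_rows, n_cols = e.shape
        rows = np.arange(n_rows)
        p1 = np.array([np.interp(-12.667, -e[:, c], rows) for c in range(n_cols)])
        p2 = np.array([np.interp(-12.681, -e[:, c], rows) for c in range(n_cols)])
        anchors = CalibrationAnchors.from_energies(p1, 12.667, p2, 12.681, geometry)
        emap = energy_map_two_point(anchors, geometry, n_rows)
        dark = spexi.average_stack(stacks["dark"])
        flat = spexi.average_stack(stacks["flat"])
        region = find_beam_region(flat, dark, 0.10)
        in_beam = region.row_mask(n_rows)
        assert np.nanmax(np.abs(emap.energies - e)[in_beam]) < 1e-4

    def test_detected_anchors_give_accurate_map(self, edge_sim, geometry):
        stacks, truth = edge_sim
        dark = spexi.average_stack(stacks["dark"])
        flat = spexi.average_stack(stacks["flat"])
        region = find_beam_region(flat, dark, 0.10)
        att = normalize(spexi.average_stack(stacks["edge_speciation"]), dark, flat)
        anchors = find_two_point_anchors(
            att, region, (12.667, 12.681), geometry,
            reference=syn.species_spectrum("selenate"),
        )
        emap = energy_map_two_point(anchors, geometry, flat.shape[0])
        in_beam = region.row_mask(flat.shape[0])
        err = np.abs(emap.energies - truth.energy_map.energies)[in_beam]
        assert np.nanmax(err) < 2e-3  # within the edge-energy tolerance


@pytest.fixture(scope="module")
def fine_geometry():
    # longer focus-to-detector distance: finer energy pitch per pixel,
    # so a 1e-4 relative edge width spans several pixels
    return SystemGeometry(focus_to_detector=5000.0)


class TestEstimateResolution:

    def _measure(self, geometry, sigma_scale=1.0, seed=21):
        sigma = sigma_scale * 1e-4 * 12.658 / (2 * np.sqrt(2 * np.log(2)))
        stacks, truth = syn.simulate_scan(
            None, geometry, noise=False, n_cols=8, sigma_e=sigma, seed=seed
        )
        dark = spexi.average_stack(stacks["dark"])
        flat = spexi.average_stack(stacks["flat"])
        region = find_beam_region(flat, dark, 0.10)
        att = normalize(spexi.average_stack(stacks["edge_elemental"]), dark, flat)
        trace = find_edge(att, region)
        emap = energy_map_one_point(trace, geometry, flat.shape[0])
        return estimate_resolution(trace, emap, geometry), truth

    def test_relative_width_1e4_recovered_within_15_percent(self, fine_geometry):
        res, _ = self._measure(fine_geometry)
        assert res.relative == pytest.approx(1e-4, rel=0.15)

    def test_doubled_blur_doubles_the_estimate(self, fine_geometry):
        res1, _ = self._measure(fine_geometry, sigma_scale=1.0)
        res2, _ = self._measure(fine_geometry, sigma_scale=2.0)
        assert res2.fwhm_energy / res1.fwhm_energy == pytest.approx(2.0, rel=0.15)

    def test_sigma_fwhm_relation(self, fine_geometry):
        res, _ = self._measure(fine_geometry)
        assert res.gaussian_sigma == pytest.approx(
            res.fwhm_energy / (2 * np.sqrt(2 * np.log(2))), rel=1e-12
        )
        assert res.relative == pytest.approx(res.fwhm_energy / 12.658, rel=1e-12)

    def test_invalid_trace_is_an_error(self, geometry):
        trace = EdgeTrace(row=np.array([200.0]), fwhm=np.array([np.nan]),
                          valid=np.array([False]))
        emap = energy_map_one_point(
            EdgeTrace(row=np.array([200.0]), fwhm=np.array([2.0]),
                      valid=np.array([True])), geometry, 400)
        with pytest.raises(ValueError, match="invalid trace"):
            estimate_resolution(trace, emap, geometry)
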