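import time

import numpy as np
import pytest

from spexi.calibration import AttenuationImage, BeamRegion, EnergyMap
from spexi.references import MaterialSpectrum
from spexi.unmixing import (
    MaterialSinogram,
    assemble,
    fit_column,
    fit_projection,
    resample_references,
    to_concentration,
)


def _band(n=200):
    return np.linspace(12.5, 12.8, n)


def _refs(n_mat=4, n=400, seed=0):
    """Smooth, mutually distinct synthetic reference spectra."""
    rng = np.random.default_rng(seed)
    e = np.linspace(12.45, 12.85, n)
    refs = []
    for i in range(n_mat):
        mu = (
            2.0 + i
            + np.sin((e - 12.45) * (6 + 3 * i) + i)
            + 0.5 * np.exp(-0.5 * ((e - 12.55 - 0.06 * i) / 0.02) ** 2)
        )
        refs.append(MaterialSpectrum(f"mat{i}", e, mu, provenance="synthetic",
                                     molar_mass=100.0 + i))
    return refs


class TestFitColumn:
    def test_two_of_four_references_recovered_exactly(self):
        refs = _refs()
        e = _band()
        x_true = {"mat0": 0.02, "mat2": 0.005}
        att = sum(x * np.interp(e, refs[int(k[-1])].energy_grid,
                                refs[int(k[-1])].mu_rho)
                  for k, x in x_true.items())
        fit = fit_column(att, e, refs)
        norm = np.linalg.norm(list(x_true.values()))
        assert fit.coefficients["mat0"] == pytest.approx(0.02, rel=1e-9)
        assert fit.coefficients["mat2"] == pytest.approx(0.005, rel=1e-9)
        assert abs(fit.coefficients["mat1"]) <= 1e-9 * norm
        assert abs(fit.coefficients["mat3"]) <= 1e-9 * norm
        assert fit.residual_rms <= 1e-10
        assert fit.dof == len(e) - 4

    def test_zero_attenuation_gives_zero_coefficients(self):
        fit = fit_column(np.zeros(200), _band(), _refs())
        assert all(abs(v) < 1e-12 for v in fit.coefficients.values())

    def test_identical_references_rejected(self):
        refs = _refs()
        twin = MaterialSpectrum("twin", refs[0].energy_grid,
                                2.0 * refs[0].mu_rho, provenance="synthetic")
        with pytest.raises(ValueError, match="degenerate reference pair.*mat0.*twin"):
            fit_column(np.zeros(200), _band(), [refs[0], twin])

    def test_insufficient_pixels_rejected(self):
        with pytest.raises(ValueError, match="insufficient pixels"):
            fit_column(np.zeros(3), _band(3), _refs())

    def test_masked_pixels_dropped_not_imputed(self):
        refs = _refs()
        e = _band()
        att = 0.01 * np.interp(e, refs[0].energy_grid, refs[0].mu_rho)
        att_bad = att.copy()
        att_bad[50:60] = np.nan  # corrupted pixels must not influence the fit
        fit = fit_column(att_bad, e, refs)
        assert fit.coefficients["mat0"] == pytest.approx(0.01, rel=1e-9)
        assert fit.n_pixels == len(e) - 10

    def test_nonnegative_mode(self):
        refs = _refs(2)
        e = _band()
        att = -0.01 * np.interp(e, refs[0].energy_grid, refs[0].mu_rho)
        fit = fit_column(att, e, refs, nonneg=True)
        assert all(v >= 0 for v in fit.coefficients.values())


def _projection(x_cols, refs, emap, noise=None, rng=None):
    """Forward-model a projection from per-column coefficient vectors."""
    n_rows, n_cols = emap.energies.shape
    cube = resample_references(refs, emap)
    att = np.einsum("rcm,mc->rc", np.asarray(cube.data), x_cols)
    if noise:
        att = att + rng.normal(0.0, noise, att.shape)
    return AttenuationImage(values=att, mask=np.ones_like(att, dtype=bool))


def _flat_emap(n_rows=200, n_cols=32):
    e = np.linspace(12.8, 12.5, n_rows)[:, None] * np.ones((1, n_cols))
    return EnergyMap(energies=e)


def _region(n_rows, n_cols):
    return BeamRegion(top=np.zeros(n_cols, dtype=int),
                      bottom=np.full(n_cols, n_rows),
                      valid=np.ones(n_cols, dtype=bool))


class TestFitProjection:
    def test_uniform_slab_constant_across_columns(self):
        refs = _refs()
        emap = _flat_emap()
        x = np.zeros((4, 32))
        x[1] = 0.01
        att = _projection(x, refs, emap)
        result = fit_projection(att, emap, _region(200, 32), refs)
        np.testing.assert_allclose(result.density_of("mat1"), 0.01, rtol=1e-9)

    def test_empty_projection_fits_to_zero(self):
        refs = _refs()
        emap = _flat_emap()
        att = AttenuationImage(values=np.zeros((200, 32)),
                               mask=np.ones((200, 32), dtype=bool))
        result = fit_projection(att, emap, _region(200, 32), refs)
        np.testing.assert_allclose(result.projected_density, 0.0, atol=1e-12)
        np.testing.assert_allclose(result.residual_rms, 0.0, atol=1e-12)

    def test_dead_column_flagged_others_unaffected(self):
        refs = _refs()
        emap = _flat_emap()
        x = np.zeros((4, 32)); x[0] = 0.02
        att = _projection(x, refs, emap)
        att.mask[:, 7] = False
        att.values[:, 7] = np.nan
        result = fit_projection(att, emap, _region(200, 32), refs)
        assert not result.valid[7]
        assert np.isnan(result.projected_density[:, 7]).all()
        ok = np.delete(np.arange(32), 7)
        np.testing.assert_allclose(result.projected_density[0, ok], 0.02, rtol=1e-9)

    def test_unbiased_under_noise(self, rng):
        # 500 simulated columns: mean recovered/true within [0.99, 1.01]
        # attenuation SNR comparable to the default simulator (peak
        # attenuation a few units, counting noise ~ a few 1e-3)
        refs = _refs()
        emap = _flat_emap(200, 500)
        x = np.zeros((4, 500))
        x[0], x[2] = 0.02, 0.004
        att = _projection(x, refs, emap, noise=0.002, rng=rng)
        result = fit_projection(att, emap, _region(200, 500), refs)
        for i, true in ((0, 0.02), (2, 0.004)):
            ratio = result.projected_density[i].mean() / true
            assert 0.99 <= ratio <= 1.01

    def test_extra_orthogonalish_reference_harmless(self, rng):
        refs = _refs()
        emap = _flat_emap(200, 64)
        x = np.zeros((3, 64)); x[0] = 0.02
        att = _projection(x, refs[:3], emap, noise=0.005, rng=rng)
        r3 = fit_projection(att, emap, _region(200, 64), refs[:3])
        r4 = fit_projection(att, emap, _region(200, 64), refs)
        shift = np.abs(r4.density_of("mat0") - r3.density_of("mat0"))
        # adding a reference may redistribute noise but not the signal
        assert np.mean(shift) < 5 * np.std(r3.density_of("mat0"))

    def test_batch_performance_contract(self):
        # 1024 columns x 200 pixels x 4 materials in under 2 s
        refs = _refs()
        emap = _flat_emap(200, 1024)
        x = np.zeros((4, 1024)); x[1] = 0.01
        att = _projection(x, refs, emap)
        cube = resample_references(refs, emap)
        start = time.perf_counter()
        fit_projection(att, emap, _region(200, 1024), refs, design_cube=cube)
        assert time.perf_counter() - start < 2.0

    def test_fitted_spectrum_is_design_times_coefficients(self):
        refs = _refs()
        emap = _flat_emap(100, 4)
        x = np.zeros((4, 4)); x[0] = 0.01; x[3] = 0.002
        att = _projection(x, refs, emap)
        result = fit_projection(att, emap, _region(100, 4), refs)
        np.testing.assert_allclose(result.fitted, att.values, atol=1e-12)


class TestAssemble:
    def _results(self, n=3, n_cols=10):
        refs = _refs(2)
        emap = _flat_emap(60, n_cols)
        out = []
        for _ in range(n):
            x = np.zeros((2, n_cols)); x[0] = 0.01
            att = _projection(x, refs, emap)
            out.append(fit_projection(att, emap, _region(60, n_cols), refs))
        return out

    def test_scan_mode_shape(self):
        maps = assemble(self._results(), mode="scan")
        assert maps["mat0"].shape == (3, 10)

    def test_ct_mode_records_angles(self):
        angles = np.linspace(0, 179, 3)
        sinos = assemble(self._results(), mode="ct", angles=angles)
        assert isinstance(sinos["mat0"], MaterialSinogram)
        np.testing.assert_array_equal(sinos["mat0"].angles, angles)

    def test_mismatched_material_lists_rejected(self):
        a = self._results(1)[0]
        b = self._results(1)[0]
        b.materials = ["other0", "other1"]
        with pytest.raises(ValueError, match="inconsistent material"):
            assemble([a, b], mode="scan")


class TestToConcentration:
    def _se_like(self):
        return MaterialSpectrum("Se", np.array([12.0, 13.0]), np.array([20.0, 150.0]),
                                provenance="synthetic", molar_mass=78.97)

    def test_unit_conversion_oracle(self):
        # 7.897e-3 g/cm^2 over 1 cm at 78.97 g/mol -> 100 mmol/L
        assert to_concentration(7.897e-3, 1.0, self._se_like()) == pytest.approx(100.0)

    def test_zero_density_gives_zero(self):
        assert to_concentration(0.0, 1.0, self._se_like()) == 0.0

    def test_zero_path_rejected(self):
        with pytest.raises(ValueError, match="path_length"):
            to_concentration(1e-3, 0.0, self._se_like())

    def test_missing_molar_mass_rejected(self):
        spec = MaterialSpectrum("x", np.array([12.0, 13.0]), np.array([1.0, 2.0]),
                                provenance="synthetic")
        with pytest.raises(ValueError, match="molar mass"):
            to_concentration(1e-3, 1.0, spec)
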