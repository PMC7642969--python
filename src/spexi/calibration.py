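"""Normalization, beam region, edge localization and energy mapping.

The flat and dark images normalize sample transmission into attenuation
(-ln of the flat/dark-corrected transmission).  An edge image -- taken with
a reference film of the contrast element in the beam -- localizes the
absorption edge in every detector column via the peak of the column
derivative; Bragg's law then assigns an energy to every pixel, either from
that single anchor (one-point map) or from two spectral features of known
energy (two-point map, which removes the dependence on the assumed
focus-to-detector distance).  The width of the derivative peak doubles as
the system's energy-resolution estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence, Union

import numpy as np
from scipy.ndimage import uniform_filter1d

from .geometry import HC_KEV_ANGSTROM, SystemGeometry, bragg_angle, plane_spacing

GAUSSIAN_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class AttenuationImage:
    """-ln transmission per pixel with a validity mask.

    ``mask`` is False wherever (flat - dark) or (tomo - dark) was not
    positive; ``values`` are NaN there.
    """

    values: np.ndarray
    mask: np.ndarray

    @property
    def filled(self) -> np.ndarray:
        """Values with masked pixels replaced by 0 (for weighted solvers)."""
        return np.where(self.mask, self.values, 0.0)


@dataclass
class BeamRegion:
    """Per-column useful beam rows, half-open [top, bottom), 0-based."""

    top: np.ndarray
    bottom: np.ndarray
    valid: np.ndarray

    def row_mask(self, n_rows: int) -> np.ndarray:
        """Boolean (n_rows, n_cols) mask of pixels inside the beam region."""
        rows = np.arange(n_rows)[:, None]
        return (
            self.valid[None, :]
            & (rows >= self.top[None, :])
            & (rows < self.bottom[None, :])
        )


@dataclass
class EdgeTrace:
    """Per-column subpixel edge row and derivative-peak FWHM (pixels)."""

    row: np.ndarray
    fwhm: np.ndarray
    valid: np.ndarray


@dataclass
class CalibrationAnchors:
    """Two spectral anchors (row, energy, Bragg angle) for two-point mapping.

    Rows may be scalars or per-column arrays (the latter honours the beam
    bow).  Energies in keV, angles in radians.
    """

    row1: Union[float, np.ndarray]
    energy1: float
    row2: Union[float, np.ndarray]
    energy2: float
    theta1: float
    theta2: float

    @classmethod
    def from_energies(
        cls,
        row1: Union[float, np.ndarray],
        energy1: float,
        row2: Union[float, np.ndarray],
        energy2: float,
        geometry: SystemGeometry,
    ) -> "CalibrationAnchors":
        if np.any(np.asarray(row1) == np.asarray(row2)) or energy1 == energy2:
            raise ValueError("degenerate anchors: rows and energies must differ")
        return cls(
            row1, energy1, row2, energy2,
            bragg_angle(energy1, geometry), bragg_angle(energy2, geometry),
        )


@dataclass
class EnergyMap:
    """Per-pixel X-ray energy (keV), computed per column to honour beam bow."""

    energies: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.energies.shape


@dataclass
class ResolutionEstimate:
    """System energy resolution from the edge-derivative FWHM."""

    fwhm_energy: float  # keV
    gaussian_sigma: float  # keV, = fwhm / (2 sqrt(2 ln 2))
    relative: float  # fwhm / edge energy


def normalize(
    tomo: np.ndarray, dark: np.ndarray, flat: np.ndarray
) -> AttenuationImage:
    """Flat/dark-correct a projection into attenuation: -ln[(tomo-dark)/(flat-dark)].

    Pixels where either difference is non-positive are masked, not errors;
    an all-masked result raises (wrong role assignment or dead detector).
    """
    tomo, dark, flat = (np.asarray(a, dtype=float) for a in (tomo, dark, flat))
    if not tomo.shape == dark.shape == flat.shape:
        raise ValueError("tomo, dark and flat must share one shape")
    num = tomo - dark
    den = flat - dark
    mask = (num > 0) & (den > 0)
    if not mask.any():
        raise ValueError("all pixels masked: check image roles / detector state")
    values = np.full(tomo.shape, np.nan)
    values[mask] = -np.log(num[mask] / den[mask])
    return AttenuationImage(values=values, mask=mask)


def find_beam_region(
    flat: np.ndarray,
    dark: np.ndarray,
    threshold_fraction: float = 0.10,
    min_height: int = 8,
) -> BeamRegion:
    """Largest contiguous run of rows per column above a fractional threshold.

    The vertical beam profile is near-Gaussian; per column, rows where
    (flat - dark) >= threshold_fraction x that column's maximum form the
    useful region.  Columns whose longest run is shorter than ``min_height``
    rows are excluded.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    signal = np.asarray(flat, dtype=float) - np.asarray(dark, dtype=float)
    n_rows, n_cols = signal.shape
    col_max = signal.max(axis=0)
    above = signal >= threshold_fraction * np.maximum(col_max, 1e-300)[None, :]
    above &= signal > 0
    top = np.zeros(n_cols, dtype=int)
    bottom = np.zeros(n_cols, dtype=int)
    valid = np.zeros(n_cols, dtype=bool)
    padded = np.zeros((n_rows + 2, n_cols), dtype=int)
    padded[1:-1] = above
    d = np.diff(padded, axis=0)
    for c in range(n_cols):
        starts = np.nonzero(d[:, c] == 1)[0]
        ends = np.nonzero(d[:, c] == -1)[0]
        if len(starts) == 0:
            continue
        lengths = ends - starts
        i = int(np.argmax(lengths))
        if lengths[i] >= min_height:
            top[c], bottom[c], valid[c] = starts[i], ends[i], True
    if not valid.any():
        raise ValueError("beam absent: no column has a usable beam region")
    return BeamRegion(top=top, bottom=bottom, valid=valid)


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Subpixel peak position from a parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return i + 0.5 * (y[i - 1] - y[i + 1]) / denom


def _peak_fwhm(y: np.ndarray, i: int) -> float:
    """FWHM of the peak around index ``i`` by linear-interpolated half crossings."""
    half = y[i] / 2.0
    left = right = np.nan
    for j in range(i, 0, -1):
        if y[j - 1] <= half:
            right_y, left_y = y[j], y[j - 1]
            left = j - 1 + (half - left_y) / (right_y - left_y)
            break
    for j in range(i, len(y) - 1):
        if y[j + 1] <= half:
            right = j + (y[j] - half) / (y[j] - y[j + 1])
            break
    if np.isnan(left) or np.isnan(right):
        return np.nan
    return right - left


def _gaussian_peak_fwhm(grad: np.ndarray, i: int) -> float:
    """FWHM of the derivative peak by a local Gaussian fit (fallback: crossings)."""
    from scipy.optimize import curve_fit

    h = max(4, int(2 * _peak_fwhm(grad, i)) if np.isfinite(_peak_fwhm(grad, i)) else 4)
    lo, hi = max(i - h, 0), min(i + h + 1, len(grad))
    x = np.arange(lo, hi, dtype=float)
    y = grad[lo:hi]

    def model(xx, amp, mu, sig, c0):
        return amp * np.exp(-0.5 * ((xx - mu) / sig) ** 2) + c0

    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, x, y, p0=(grad[i], float(i), 1.0, float(np.min(y))), maxfev=2000
            )
        sig = abs(popt[2])
        if 0 < sig < len(grad):
            return GAUSSIAN_FWHM_PER_SIGMA * sig
    except (RuntimeError, ValueError):
        pass
    return _peak_fwhm(grad, i)


@lru_cache(maxsize=8)
def _processing_fwhm(smooth_window: int) -> float:
    """Gaussian-equivalent FWHM (px) of the estimator's own derivative kernel.

    The boxcar smoothing convolved with the first difference turns an ideal
    step into a trapezoidal derivative peak; this computes, once, the FWHM a
    Gaussian fit reports for that kernel alone so it can be removed in
    quadrature from measured edge widths.
    """
    from scipy.optimize import curve_fit

    fine = 64
    half = (smooth_window + 2) * fine
    x = np.arange(-half, half + 1, dtype=float) / fine
    w = smooth_window if smooth_window > 1 else 1
    # trapezoid = boxcar(w) (*) boxcar(1), unit area
    b1 = np.where(np.abs(x) <= w / 2.0, 1.0 / w, 0.0)
    b2 = np.where(np.abs(x) <= 0.5, 1.0, 0.0)
    kernel = np.convolve(b1, b2, mode="same") / fine

    def model(xx, amp, mu, sig, c0):
        return amp * np.exp(-0.5 * ((xx - mu) / sig) ** 2) + c0

    popt, _ = curve_fit(model, x, kernel, p0=(kernel.max(), 0.0, w / 2.0, 0.0))
    return GAUSSIAN_FWHM_PER_SIGMA * abs(popt[2])


def find_edge(
    edge_attenuation: AttenuationImage,
    region: BeamRegion,
    smooth_window: int = 3,
    prominence_mad: float = 5.0,
) -> EdgeTrace:
    """Localize the absorption edge per column from the derivative peak.

    Each column of the (boxcar-smoothed) edge attenuation is differentiated
    along rows (first difference); the peak of the derivative magnitude
    marks the edge, refined to subpixel by parabolic interpolation.  The
    edge width is the FWHM of the derivative peak (local Gaussian fit) with
    the estimator's own known kernel -- the boxcar smoothing convolved with
    the first difference, variance w^2/12 pixels^2 -- removed in quadrature,
    so the reported width reflects the beam, not the processing.  Columns
    whose peak prominence is below ``prominence_mad`` times the column's
    derivative noise (median absolute deviation) are flagged invalid.
    """
    values = edge_attenuation.values
    n_rows, n_cols = values.shape
    row = np.full(n_cols, np.nan)
    fwhm = np.full(n_cols, np.nan)
    valid = np.zeros(n_cols, dtype=bool)
    for c in range(n_cols):
        if not region.valid[c]:
            continue
        t, b = region.top[c], region.bottom[c]
        col = values[t:b, c]
        if np.isnan(col).any():
            # fill masked pixels from neighbours so the derivative is defined
            idx = np.arange(len(col))
            good = ~np.isnan(col)
            if good.sum() < max(5, smooth_window + 2):
                continue
            col = np.interp(idx, idx[good], col[good])
        if smooth_window > 1:
            col = uniform_filter1d(col, smooth_window, mode="nearest")
        grad = np.abs(np.diff(col))  # first difference, at half-integer rows
        i = int(np.argmax(grad))
        med = np.median(grad)
        mad = np.median(np.abs(grad - med)) + 1e-12
        if grad[i] - med < prominence_mad * mad:
            continue
        row[c] = t + 0.5 + _parabolic_refine(grad, i)
        raw_fwhm = _gaussian_peak_fwhm(grad, i)
        proc = _processing_fwhm(smooth_window)
        floor = 0.2 * GAUSSIAN_FWHM_PER_SIGMA
        fwhm[c] = np.sqrt(max(raw_fwhm**2 - proc**2, floor**2))
        valid[c] = t <= row[c] < b
    if not valid.any():
        raise ValueError("no valid column: edge not found in any column")
    return EdgeTrace(row=row, fwhm=fwhm, valid=valid)


def _refine_peak_gaussian(col: np.ndarray, i: int, halfwidth: int = 4) -> float:
    """Subpixel peak position by a Gaussian-plus-linear-baseline local fit.

    A bare 3-point parabola is biased by up to ~0.2 px for peaks only one
    or two pixels wide sitting on a sloping background (an absorption peak
    on the edge step); fitting an explicit peak model over a small window
    removes most of that bias.  Falls back to the parabola if the fit fails.
    """
    from scipy.optimize import curve_fit

    lo = max(i - halfwidth, 0)
    hi = min(i + halfwidth + 1, len(col))
    x = np.arange(lo, hi, dtype=float)
    y = col[lo:hi]
    p0 = (col[i] - y.min(), float(i), 1.5, y.min(), 0.0)

    def model(xx, amp, mu, sig, c0, c1):
        return amp * np.exp(-0.5 * ((xx - mu) / sig) ** 2) + c0 + c1 * (xx - i)

    try:
        popt, _ = curve_fit(model, x, y, p0=p0, maxfev=2000)
        mu = float(popt[1])
        if lo <= mu <= hi - 1:
            return mu
    except (RuntimeError, ValueError):
        pass
    return _parabolic_refine(col, i)


def _match_spectrum_column(
    raw: np.ndarray,
    rows: np.ndarray,
    reference,
    theta1: float,
    theta2: float,
    p1_0: float,
    p2_0: float,
    geometry: SystemGeometry,
) -> tuple[float, float]:
    """Refine both anchor rows by matching the full column spectrum.

    The column attenuation is modelled as amplitude x mu_ref(E(row)) plus a
    linear background, with E(row) the exact Bragg map parameterized by the
    first anchor row and an effective focus distance.  Least squares over
    those two nonlinear parameters (amplitudes projected linearly) uses the
    whole beam-region spectrum as baseline, so the anchor spacing -- which a
    two-peak picker reads off a few-pixel baseline -- is constrained by
    every pixel of the edge structure.
    """
    from scipy.optimize import least_squares

    eg, mu_ref = reference.energy_grid, reference.mu_rho
    d_hkl = plane_spacing(geometry)
    dtheta = theta2 - theta1
    s = geometry.pixel_size

    def emap_of(params):
        p1, f_eff = params
        theta = theta1 + np.arctan((rows - p1) * s / f_eff)
        return HC_KEV_ANGSTROM / (2.0 * d_hkl * np.sin(theta))

    def residual(params):
        e = emap_of(params)
        mu = np.interp(e, eg, mu_ref)
        design = np.stack([mu, np.ones_like(e), rows - params[0]], axis=1)
        coef, *_ = np.linalg.lstsq(design, raw, rcond=None)
        return design @ coef - raw

    f0 = s * (p2_0 - p1_0) / np.tan(dtheta)
    fit = least_squares(
        residual, x0=[p1_0, f0], diff_step=[1e-3, 1e-3], xtol=1e-12, ftol=1e-12
    )
    p1, f_eff = fit.x
    p2 = p1 + f_eff * np.tan(dtheta) / s
    return float(p1), float(p2)


def find_two_point_anchors(
    edge_attenuation: AttenuationImage,
    region: BeamRegion,
    energies: Sequence[float],
    geometry: SystemGeometry,
    smooth_window: int = 3,
    reference=None,
) -> CalibrationAnchors:
    """Locate two absorption peaks per column and pair them with known energies.

    ``energies`` are the two feature energies in ascending keV order (e.g.
    the two selenate absorption peaks).  Per column the two most prominent
    local maxima of the smoothed attenuation are taken and assigned to the
    energies according to the geometry's energy direction (with direction
    +1, the higher energy lies at the smaller row index), then refined: by
    a full-spectrum match against ``reference`` (the calibration species'
    mass-attenuation spectrum) when one is supplied -- the recommended mode,
    since it constrains the anchor spacing with the whole edge structure --
    or else by a local Gaussian-plus-baseline peak fit.
    """
    e_lo, e_hi = sorted(float(e) for e in energies)
    values = edge_attenuation.values
    n_cols = values.shape[1]
    p_lo = np.full(n_cols, np.nan)
    p_hi = np.full(n_cols, np.nan)
    for c in range(n_cols):
        if not region.valid[c]:
            continue
        t, b = region.top[c], region.bottom[c]
        col = values[t:b, c]
        idx = np.arange(len(col))
        good = ~np.isnan(col)
        if good.sum() < 8:
            continue
        raw = np.interp(idx, idx[good], col[good])
        sm = (
            uniform_filter1d(raw, smooth_window, mode="nearest")
            if smooth_window > 1
            else raw
        )
        from scipy.signal import find_peaks

        peaks, props = find_peaks(sm, prominence=0.0)
        if len(peaks) < 2:
            continue
        order = np.argsort(props["prominences"])[::-1][:2]
        two = np.sort(peaks[order])
        # refine on the unsmoothed column: smoothing is only for robust
        # peak picking, the boxcar would widen (and can shift) narrow peaks
        r = [t + _refine_peak_gaussian(raw, int(i)) for i in two]
        # smaller row index = higher energy when direction is +1
        if geometry.energy_direction == 1:
            r_hi, r_lo = r[0], r[1]
        else:
            r_lo, r_hi = r[0], r[1]
        if reference is not None:
            th_lo = bragg_angle(e_lo, geometry)
            th_hi = bragg_angle(e_hi, geometry)
            rows_abs = np.arange(t, b, dtype=float)
            r_lo, r_hi = _match_spectrum_column(
                raw, rows_abs, reference, th_lo, th_hi, r_lo, r_hi, geometry
            )
        p_lo[c], p_hi[c] = r_lo, r_hi
    ok = ~np.isnan(p_lo) & ~np.isnan(p_hi)
    if not ok.any():
        raise ValueError("two-point anchors not found in any column")
    p_lo[~ok] = np.nan
    p_hi[~ok] = np.nan
    return CalibrationAnchors.from_energies(p_lo, e_lo, p_hi, e_hi, geometry)


def _energies_from_theta(theta: np.ndarray, geometry: SystemGeometry) -> np.ndarray:
    if np.nanmin(theta) <= 0 or np.nanmax(theta) >= np.pi / 2:
        raise ValueError("pixel Bragg angle outside (0, pi/2); check geometry")
    return HC_KEV_ANGSTROM / (2.0 * plane_spacing(geometry) * np.sin(theta))


def energy_map_one_point(
    trace: EdgeTrace, geometry: SystemGeometry, n_rows: int
) -> EnergyMap:
    """Energy map anchored on the edge row of each column.

    theta_i = theta_K + direction * arctan[(p_i - p_K) * pixel / F];
    E_i = hc / (2 d sin theta_i).  At p_i = p_K the map equals the edge
    energy exactly.  Columns with an invalid trace are NaN.
    """
    theta_k = bragg_angle(geometry.edge_energy, geometry)
    rows = np.arange(n_rows, dtype=float)[:, None]
    p_k = np.where(trace.valid, trace.row, np.nan)[None, :]
    alpha = np.arctan(
        (rows - p_k) * geometry.pixel_size / geometry.focus_to_detector
    )
    theta = theta_k + geometry.energy_direction * alpha
    with np.errstate(invalid="ignore"):
        energies = np.where(
            np.isnan(theta), np.nan, _energies_from_theta(np.nan_to_num(theta, nan=theta_k), geometry)
        )
    return EnergyMap(energies=energies)


def energy_map_two_point(
    anchors: CalibrationAnchors, geometry: SystemGeometry, n_rows: int
) -> EnergyMap:
    """Energy map anchored on two spectral features of known energy.

    The focus-to-detector distance is replaced by an effective distance
    F_eff = pixel * (p1 - p2) / tan(theta1 - theta2) fixed by the anchors, so
    the map reproduces both anchor energies exactly and does not depend on
    the assumed geometry distance.
    """
    p1 = np.atleast_1d(np.asarray(anchors.row1, dtype=float))[None, :]
    p2 = np.atleast_1d(np.asarray(anchors.row2, dtype=float))[None, :]
    dtheta = anchors.theta1 - anchors.theta2
    if dtheta == 0:
        raise ValueError("degenerate anchors: equal Bragg angles")
    f_eff = geometry.pixel_size * (p1 - p2) / np.tan(dtheta)
    rows = np.arange(n_rows, dtype=float)[:, None]
    theta = anchors.theta1 + np.arctan((rows - p1) * geometry.pixel_size / f_eff)
    with np.errstate(invalid="ignore"):
        energies = np.where(
            np.isnan(theta),
            np.nan,
            _energies_from_theta(np.nan_to_num(theta, nan=anchors.theta1), geometry),
        )
    if energies.shape[1] == 1:
        energies = np.broadcast_to(energies, (n_rows, 1)).copy()
    return EnergyMap(energies=energies)


def estimate_resolution(
    trace: EdgeTrace,
    emap: EnergyMap,
    geometry: SystemGeometry,
) -> ResolutionEstimate:
    """Energy resolution from the median edge-derivative FWHM across columns.

    The per-column FWHM in pixels is converted to keV through the local
    energy-per-pixel gradient at the edge row; the median over valid columns
    (robust to bow-induced outliers at the beam edges) is reported together
    with the equivalent Gaussian sigma and the relative width FWHM/E_K.
    """
    ok = trace.valid & ~np.isnan(trace.fwhm)
    if not ok.any():
        raise ValueError("invalid trace: no column with a measured edge width")
    n_rows = emap.shape[0]
    fwhm_kev = []
    grad = np.gradient(emap.energies, axis=0)
    for c in np.nonzero(ok)[0]:
        r = int(round(trace.row[c]))
        r = min(max(r, 0), n_rows - 1)
        g = abs(grad[r, c])
        if np.isfinite(g) and g > 0:
            fwhm_kev.append(trace.fwhm[c] * g)
    if not fwhm_kev:
        raise ValueError("energy gradient undefined at every edge row")
    fwhm_energy = float(np.median(fwhm_kev))
    return ResolutionEstimate(
        fwhm_energy=fwhm_energy,
        gaussian_sigma=fwhm_energy / GAUSSIAN_FWHM_PER_SIGMA,
        relative=fwhm_energy / geometry.edge_energy,
    )
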