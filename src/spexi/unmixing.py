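"""Per-column least-squares decomposition into projected densities.

Every detector column of a projection holds the attenuation spectrum of one
horizontal sample position.  With the references resampled onto that
column's pixel energies, the attenuation is an over-determined linear
system A_p = Sum_m (mu/rho)_m(E_p) * (rho t)_m, solved per column by
ordinary least squares (optionally non-negative).  Materials absent from
the sample fit to coefficients near zero, so offering extra references is
harmless in the noiseless limit.  Projections assemble into per-material
2-D maps (vertical scan) or sinograms (CT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls

from .calibration import AttenuationImage, BeamRegion, EnergyMap
from .references import MaterialSpectrum

#: Design-matrix condition number above which a warning is emitted
#: (references must be distinctively different as a function of energy).
CONDITION_WARN = 1e8


@dataclass
class ColumnFit:
    """One column's fitted projected densities and diagnostics."""

    coefficients: dict[str, float]
    residual_rms: float
    fitted_spectrum: np.ndarray  # same length as the input, NaN where masked
    n_pixels: int
    dof: int


@dataclass
class FitResult:
    """Per-projection fit: projected densities per material per sample column."""

    materials: list[str]
    projected_density: np.ndarray  # (n_materials, n_cols), NaN where not fitted
    residual_rms: np.ndarray  # (n_cols,)
    valid: np.ndarray  # (n_cols,) bool
    fitted: Optional[np.ndarray] = None  # (n_rows, n_cols) diagnostics

    def density_of(self, name: str) -> np.ndarray:
        return self.projected_density[self.materials.index(name)]


@dataclass
class MaterialSinogram:
    """Projected densities of one material indexed by (angle, sample column)."""

    name: str
    values: np.ndarray  # (n_angles, n_cols), g/cm^2
    angles: np.ndarray  # degrees

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.values.shape[0] != len(self.angles):
            raise ValueError("one angle per sinogram row required")


def _check_degenerate(design: np.ndarray, names: Sequence[str]) -> None:
    """Raise if two reference columns are (numerically) proportional."""
    norms = np.linalg.norm(design, axis=0)
    if np.any(norms == 0):
        i = int(np.argmin(norms))
        raise ValueError(f"reference {names[i]!r} is zero over the fitted band")
    unit = design / norms
    gram = unit.T @ unit
    n = len(names)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(gram[i, j]) > 1.0 - 1e-12:
                raise ValueError(
                    f"degenerate reference pair: {names[i]!r} and {names[j]!r} "
                    "are proportional over the fitted band"
                )


def fit_column(
    attenuation: np.ndarray,
    energies: np.ndarray,
    references: Sequence[MaterialSpectrum],
    nonneg: bool = False,
    mask: Optional[np.ndarray] = None,
) -> ColumnFit:
    """Least-squares fit of one column's attenuation spectrum.

    ``attenuation`` may be a masked array or a plain array with NaNs (and/or
    an explicit ``mask`` of valid pixels); masked pixels are dropped from
    the design-matrix rows, not imputed.
    """
    from .references import resample_to_column

    att = np.ma.masked_invalid(np.ma.asarray(attenuation, dtype=float))
    if mask is not None:
        att = np.ma.masked_where(~np.asarray(mask, dtype=bool), att)
    energies = np.asarray(energies, dtype=float)
    cols = [resample_to_column(ref, energies) for ref in references]
    design_m = np.ma.stack(cols, axis=1)
    row_ok = ~np.ma.getmaskarray(att) & ~np.ma.getmaskarray(design_m).any(axis=1)
    n_pix = int(row_ok.sum())
    names = [r.name for r in references]
    if n_pix <= len(references):
        raise ValueError(
            f"insufficient pixels: {n_pix} unmasked for {len(references)} materials"
        )
    a = np.asarray(design_m.data)[row_ok]
    y = np.asarray(att.filled(0.0))[row_ok]
    _check_degenerate(a, names)
    cond = np.linalg.cond(a)
    if cond > CONDITION_WARN:
        warnings.warn(
            f"ill-conditioned design matrix (cond={cond:.2e}); "
            "references may not be distinct enough over this band",
            stacklevel=2,
        )
    if nonneg:
        x, _ = nnls(a, y)
    else:
        x, *_ = np.linalg.lstsq(a, y, rcond=None)
    fitted_band = a @ x
    resid = y - fitted_band
    fitted = np.full(att.shape, np.nan)
    fitted[row_ok] = fitted_band
    return ColumnFit(
        coefficients=dict(zip(names, x.tolist())),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        fitted_spectrum=fitted,
        n_pixels=n_pix,
        dof=n_pix - len(references),
    )


def resample_references(
    references: Sequence[MaterialSpectrum], emap: EnergyMap
) -> np.ma.MaskedArray:
    """References interpolated onto every pixel energy of the map.

    Returns a masked (n_rows, n_cols, n_materials) cube; out-of-range or
    NaN pixel energies are masked.  Computing this once and reusing it
    across projections is what makes CT-scale fitting fast.
    """
    e = emap.energies
    flat = e.ravel()
    cols = []
    for ref in references:
        eg, mu = ref.energy_grid, ref.mu_rho
        with np.errstate(invalid="ignore"):
            inside = (flat >= eg[0]) & (flat <= eg[-1])
        vals = np.interp(np.where(inside, flat, eg[0]), eg, mu)
        cols.append(np.ma.MaskedArray(vals, mask=~inside).reshape(e.shape))
    return np.ma.stack(cols, axis=-1)


def fit_projection(
    attenuation: AttenuationImage,
    emap: EnergyMap,
    region: BeamRegion,
    references: Sequence[MaterialSpectrum],
    nonneg: bool = False,
    design_cube: Optional[np.ma.MaskedArray] = None,
) -> FitResult:
    """Fit every retained column of a projection.

    Columns excluded by the beam region, or with too few valid pixels, are
    flagged invalid (NaN densities) without failing the projection.  The
    batch path solves the per-column normal equations in one vectorized
    pass; ``design_cube`` (from :func:`resample_references`) can be supplied
    to amortize reference resampling across the projections of a scan.
    """
    n_rows, n_cols = attenuation.values.shape
    names = [r.name for r in references]
    n_mat = len(references)
    if design_cube is None:
        design_cube = resample_references(references, emap)
    mu = np.asarray(design_cube.data)  # (rows, cols, mat)
    w = (
        attenuation.mask
        & region.row_mask(n_rows)
        & ~np.ma.getmaskarray(design_cube).any(axis=-1)
    ).astype(float)
    _check_degenerate(
        mu.reshape(-1, n_mat)[w.ravel() > 0][:: max(1, w.size // 4096)], names
    )
    y = np.where(w > 0, np.nan_to_num(attenuation.values), 0.0)

    n_pix = w.sum(axis=0)
    valid = n_pix > n_mat
    gram = np.einsum("rcm,rcn,rc->cmn", mu, mu, w, optimize=True)
    rhs = np.einsum("rcm,rc,rc->cm", mu, y, w, optimize=True)
    x = np.full((n_cols, n_mat), np.nan)
    ok = valid.copy()
    if ok.any():
        g = gram[ok]
        try:
            sol = np.linalg.solve(g, rhs[ok][..., None])[..., 0]
        except np.linalg.LinAlgError:
            sol = np.stack(
                [np.linalg.lstsq(gi, bi, rcond=None)[0] for gi, bi in zip(g, rhs[ok])]
            )
        x[ok] = sol
    if nonneg:
        for c in np.nonzero(valid)[0]:
            rows = w[:, c] > 0
            x[c], _ = nnls(mu[rows, c, :], y[rows, c])

    fitted = np.einsum("rcm,cm->rc", mu, np.nan_to_num(x))
    resid2 = ((y - fitted) ** 2 * w).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        residual_rms = np.sqrt(resid2 / np.maximum(n_pix, 1))
    residual_rms[~valid] = np.nan
    fitted = np.where(w > 0, fitted, np.nan)
    return FitResult(
        materials=names,
        projected_density=x.T,
        residual_rms=residual_rms,
        valid=valid,
        fitted=fitted,
    )


def assemble(
    results: Sequence[FitResult],
    mode: str = "scan",
    angles: Optional[Sequence[float]] = None,
):
    """Stack projection fits into per-material 2-D maps or sinograms.

    ``scan`` mode returns {material: (n_projections, n_cols) array};
    ``ct`` mode returns {material: :class:`MaterialSinogram`} and requires
    one angle (degrees) per projection.
    """
    if mode not in ("scan", "ct"):
        raise ValueError(f"mode must be 'scan' or 'ct', got {mode!r}")
    if not results:
        raise ValueError("no fit results to assemble")
    materials = results[0].materials
    n_cols = results[0].projected_density.shape[1]
    for r in results[1:]:
        if r.materials != materials:
            raise ValueError("inconsistent material lists across projections")
        if r.projected_density.shape[1] != n_cols:
            raise ValueError("inconsistent column counts across projections")
    stacks = {
        m: np.stack([r.projected_density[i] for r in results])
        for i, m in enumerate(materials)
    }
    if mode == "scan":
        return stacks
    if angles is None or len(angles) != len(results):
        raise ValueError("ct mode requires one angle per projection")
    return {
        m: MaterialSinogram(name=m, values=v, angles=np.asarray(angles, dtype=float))
        for m, v in stacks.items()
    }


def to_concentration(
    rho_t, path_length: float, material: MaterialSpectrum
):
    """Convert projected density (g/cm^2) to molar concentration (mmol/L).

    concentration = rho_t / (path_length * molar_mass) * 1e6, with the path
    length in cm through the solution.
    """
    if material.molar_mass is None:
        raise ValueError(f"material {material.name!r} has no molar mass")
    if not path_length > 0:
        raise ValueError("path_length must be positive")
    out = np.asarray(rho_t, dtype=float) / (path_length * material.molar_mass) * 1e6
    return float(out) if out.ndim == 0 else out
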