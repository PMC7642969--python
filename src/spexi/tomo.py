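"""CT utilities: beam-decay correction, rotation-center finding, FBP.

Storage-ring current decays during a CT scan, multiplying all counts by a
slowly falling flux factor; in attenuation (-ln) space that is a constant
additive offset per projection, measured from sample-free margins at the
left and right of the field of view and subtracted.  The rotation center
is found from the correlation between the first projection and the
horizontally flipped projection nearest 180 degrees away.  Reconstruction
is standard filtered back projection with the usual ramp-family filters,
scaled so voxel values are volumetric densities (g/cm^3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from skimage.transform import iradon

from .calibration import AttenuationImage
from .unmixing import MaterialSinogram

FILTERS = ("ramp", "shepp-logan", "cosine", "hamming", "hann")

#: Minimum angular span (degrees) accepted by the 0/180 center search;
#: slightly under 180 so endpoint-exclusive scans over [0, 180) qualify.
MIN_CENTER_SPAN = 170.0


@dataclass
class ReconstructedMap:
    """FBP reconstruction of one material, voxel values in g/cm^3."""

    values: np.ndarray
    pixel_spacing: float  # cm
    filter_name: str
    center_used: float  # subpixel sinogram column


def decay_correct(
    attenuations: Sequence[AttenuationImage],
    margins: tuple[int, int],
    row_mask: Optional[np.ndarray] = None,
) -> tuple[list[AttenuationImage], np.ndarray]:
    """Remove per-projection flux-decay offsets using empty margins.

    ``margins`` is the number of sample-free columns on the (left, right)
    of the field of view.  For each projection the mean attenuation over
    the margin pixels is the decay offset -ln(flux factor); it is
    subtracted from the whole projection.  ``row_mask`` (e.g. the useful
    beam region) restricts the estimate to well-exposed pixels, avoiding
    the positive bias of -ln at near-zero counts.  Post-correction margin
    means are zero up to the numerical noise of the mean itself.
    """
    left, right = margins
    if left <= 0 and right <= 0:
        raise ValueError("zero-width margins: decay correction needs empty columns")
    n_cols = attenuations[0].values.shape[1]
    if left + right >= n_cols:
        raise ValueError("margins wider than the image")
    corrected = []
    offsets = np.zeros(len(attenuations))
    for i, att in enumerate(attenuations):
        sel = np.zeros(n_cols, dtype=bool)
        sel[:left] = True
        if right > 0:
            sel[n_cols - right :] = True
        vals = att.values[:, sel]
        ok = att.mask[:, sel]
        if row_mask is not None:
            ok = ok & row_mask[:, sel]
        if not ok.any():
            raise ValueError(f"projection {i}: no valid margin pixels")
        offsets[i] = float(np.mean(vals[ok]))
        corrected.append(
            AttenuationImage(values=att.values - offsets[i], mask=att.mask.copy())
        )
    return corrected, offsets


def _corr_peak_subpixel(corr: np.ndarray) -> float:
    i = int(np.argmax(corr))
    if 0 < i < len(corr) - 1:
        denom = corr[i - 1] - 2 * corr[i] + corr[i + 1]
        if denom != 0:
            return i + 0.5 * (corr[i - 1] - corr[i + 1]) / denom
    return float(i)


def find_center(
    sinogram: Union[MaterialSinogram, np.ndarray],
    angles: Optional[Sequence[float]] = None,
    min_span: float = MIN_CENTER_SPAN,
) -> float:
    """Rotation-center column of a sinogram, to subpixel precision.

    A projection at angle theta+180 is the mirror image of the one at theta
    about the rotation center; the pair of projections closest to 180
    degrees apart is cross-correlated (one of them flipped) and the
    correlation peak, refined by parabolic interpolation, gives the center.
    """
    if isinstance(sinogram, MaterialSinogram):
        values, angles = sinogram.values, sinogram.angles
    else:
        values = np.asarray(sinogram, dtype=float)
        if angles is None:
            raise ValueError("angles required with a bare sinogram array")
        angles = np.asarray(angles, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("center finding needs at least 2 projections")
    span = float(np.max(angles) - np.min(angles))
    if span < min_span:
        raise ValueError(
            f"angular span {span:.1f} deg < required {min_span:.1f} deg"
        )
    # pair closest to 180 degrees apart
    diff = np.abs(np.subtract.outer(angles, angles)) - 180.0
    i, j = np.unravel_index(np.argmin(np.abs(diff)), diff.shape)
    w = values.shape[1]
    if abs(diff[i, j]) > 10.0:
        # no usable opposed pair: fall back to the center-of-mass sinusoid
        # (the projection centroid traces c + A cos(theta + phi))
        x = np.arange(w, dtype=float)
        v = np.nan_to_num(values)
        com = (v * x).sum(axis=1) / np.maximum(v.sum(axis=1), 1e-300)
        th = np.radians(np.asarray(angles, dtype=float))
        design = np.stack([np.ones_like(th), np.cos(th), np.sin(th)], axis=1)
        coef, *_ = np.linalg.lstsq(design, com, rcond=None)
        return float(coef[0])
    p = values[i] - np.nanmean(values[i])
    q = values[j][::-1] - np.nanmean(values[j])
    p = np.nan_to_num(p)
    q = np.nan_to_num(q)
    corr = np.correlate(p, q, mode="full")
    lag = _corr_peak_subpixel(corr) - (w - 1)
    # q_flip[k] = p[k + 2*(c - (w-1)/2)]  =>  c = (w-1)/2 + lag/2
    return (w - 1) / 2.0 + lag / 2.0


def reconstruct_fbp(
    sinogram: Union[MaterialSinogram, np.ndarray],
    center: Optional[float] = None,
    filter_name: str = "ramp",
    pixel_spacing: float = 1.0,
    angles: Optional[Sequence[float]] = None,
) -> ReconstructedMap:
    """Filtered back projection of a sinogram of line integrals (g/cm^2).

    The sinogram rows are shifted so the rotation center sits at the array
    center, filtered with the chosen ramp-family filter, and back projected
    with linear interpolation; the output is divided by ``pixel_spacing``
    (cm) so voxels carry g/cm^3.  Values outside the inscribed circle are 0.
    """
    if filter_name not in FILTERS:
        raise ValueError(
            f"unknown filter {filter_name!r}; valid names: {', '.join(FILTERS)}"
        )
    if isinstance(sinogram, MaterialSinogram):
        values, angles = sinogram.values, sinogram.angles
    else:
        values = np.asarray(sinogram, dtype=float)
        if angles is None:
            raise ValueError("angles required with a bare sinogram array")
        angles = np.asarray(angles, dtype=float)
    values = np.nan_to_num(values)
    w = values.shape[1]
    mid = (w - 1) / 2.0
    if center is None:
        center = mid
    if abs(center - mid) > 1e-9:
        values = ndimage.shift(
            values, (0.0, mid - center), order=1, mode="constant", cval=0.0
        )
    recon = iradon(
        values.T,
        theta=np.asarray(angles, dtype=float),
        filter_name=filter_name,
        interpolation="linear",
        circle=True,
        output_size=w,
    )
    return ReconstructedMap(
        values=recon / pixel_spacing,
        pixel_spacing=pixel_spacing,
        filter_name=filter_name,
        center_used=float(center),
    )
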