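"""End-to-end orchestration: stacks in, session archive and maps out.

``analyze_stacks`` wires the documented stages together: average the
correction images, normalize, find the useful beam region, localize the
absorption edge, build the energy map (one- or two-point), estimate the
energy resolution and blur the references to it, fit every projection,
and assemble maps or sinograms.  ``reconstruct_maps`` takes the sinograms
through decay-aware center finding and filtered back projection.  Both are
thin compositions of the stage modules; the CLI wraps them.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import calibration, tomo, unmixing
from .calibration import AttenuationImage, EnergyMap
from .geometry import SystemGeometry
from .imaging_io import ImageStack, SessionArchive, average_stack
from .references import MaterialSpectrum, blur_spectrum
from .unmixing import MaterialSinogram

logger = logging.getLogger(__name__)


@dataclass
class AnalysisSettings:
    """Tunable parameters of one analysis run, echoed to the settings record."""

    calibration_mode: str = "two_point"  # or "one_point"
    anchor_energies: tuple[float, float] = (12.667, 12.681)
    calibration_species: str = "selenate"  # reference for full-spectrum anchor match
    threshold_fraction: float = 0.10
    smooth_window: int = 3
    min_region_height: int = 8
    margins: Optional[tuple[int, int]] = None  # empty columns for decay correction
    nonneg: bool = False
    blur_references: bool = True

    def record(self) -> str:
        lines = ["# analysis settings"]
        for k, v in vars(self).items():
            lines.append(f"{k} = {v}")
        return "\n".join(lines) + "\n"


@dataclass
class AnalysisResult:
    """In-memory products of :func:`analyze_stacks`."""

    archive: SessionArchive
    energy_map: EnergyMap
    region: calibration.BeamRegion
    trace: calibration.EdgeTrace
    resolution: calibration.ResolutionEstimate
    attenuations: list[AttenuationImage]
    fits: list[unmixing.FitResult]
    maps: dict
    decay_offsets: Optional[np.ndarray] = None
    sinograms: dict[str, MaterialSinogram] = field(default_factory=dict)


def analyze_stacks(
    stacks: dict[str, ImageStack],
    geometry: SystemGeometry,
    references: Sequence[MaterialSpectrum],
    settings: Optional[AnalysisSettings] = None,
) -> AnalysisResult:
    """Run the full analysis on in-memory stacks.

    ``stacks`` must hold ``dark``, ``flat``, ``edge_elemental`` and ``tomo``
    (with per-frame angles for CT mode); ``edge_speciation`` is required for
    two-point calibration.  ``references`` are the unblurred candidate
    material spectra; they are blurred to the measured resolution before
    fitting unless ``settings.blur_references`` is off.
    """
    settings = settings or AnalysisSettings()
    t0 = time.perf_counter()
    for key in ("dark", "flat", "edge_elemental", "tomo"):
        if key not in stacks:
            raise ValueError(f"calibration input missing: stack {key!r} required")

    dark = average_stack(stacks["dark"])
    flat = average_stack(stacks["flat"])
    region = calibration.find_beam_region(
        flat, dark, settings.threshold_fraction, settings.min_region_height
    )
    att_edge = calibration.normalize(average_stack(stacks["edge_elemental"]), dark, flat)
    trace = calibration.find_edge(att_edge, region, settings.smooth_window)
    n_rows = flat.shape[0]

    if settings.calibration_mode == "two_point":
        if "edge_speciation" not in stacks:
            raise ValueError(
                "calibration input missing: two-point mode needs an "
                "'edge_speciation' stack"
            )
        att_spec = calibration.normalize(
            average_stack(stacks["edge_speciation"]), dark, flat
        )
        cal_ref = next(
            (r for r in references if r.name == settings.calibration_species), None
        )
        anchors = calibration.find_two_point_anchors(
            att_spec, region, settings.anchor_energies, geometry,
            settings.smooth_window, reference=cal_ref,
        )
        emap = calibration.energy_map_two_point(anchors, geometry, n_rows)
    elif settings.calibration_mode == "one_point":
        emap = calibration.energy_map_one_point(trace, geometry, n_rows)
    else:
        raise ValueError(f"unknown calibration mode {settings.calibration_mode!r}")

    resolution = calibration.estimate_resolution(trace, emap, geometry)
    logger.info(
        "calibration done in %.2f s (FWHM %.4g keV)",
        time.perf_counter() - t0, resolution.fwhm_energy,
    )

    refs = list(references)
    if settings.blur_references:
        refs = [blur_spectrum(r, resolution.gaussian_sigma) for r in refs]

    t1 = time.perf_counter()
    attenuations = [
        calibration.normalize(frame, dark, flat) for frame in stacks["tomo"].frames
    ]
    decay_offsets = None
    if settings.margins is not None:
        attenuations, decay_offsets = tomo.decay_correct(
            attenuations, settings.margins, row_mask=region.row_mask(n_rows)
        )

    cube = unmixing.resample_references(refs, emap)
    fits = [
        unmixing.fit_projection(att, emap, region, refs, settings.nonneg, cube)
        for att in attenuations
    ]
    angles = stacks["tomo"].angles
    mode = "ct" if angles is not None else "scan"
    assembled = unmixing.assemble(fits, mode=mode, angles=angles)
    logger.info("fitting done in %.2f s (%d projections)",
                time.perf_counter() - t1, len(fits))

    sinograms = assembled if mode == "ct" else {}
    maps = (
        {m: s.values for m, s in assembled.items()} if mode == "ct" else assembled
    )
    archive = SessionArchive(
        geometry=geometry,
        settings_record=settings.record(),
        energy_map=emap.energies,
        beam_top=region.top,
        beam_bottom=region.bottom,
        beam_valid=region.valid,
        edge_row=trace.row,
        edge_fwhm=trace.fwhm,
        attenuation=np.stack([a.values for a in attenuations]),
        angles=np.asarray(angles, dtype=float) if angles is not None else None,
        references={r.name: np.stack([r.energy_grid, r.mu_rho]) for r in refs},
        maps=maps,
        residual_rms=np.stack([f.residual_rms for f in fits]),
        decay_offsets=decay_offsets,
        resolution_fwhm_kev=resolution.fwhm_energy,
    )
    return AnalysisResult(
        archive=archive,
        energy_map=emap,
        region=region,
        trace=trace,
        resolution=resolution,
        attenuations=attenuations,
        fits=fits,
        maps=maps,
        decay_offsets=decay_offsets,
        sinograms=sinograms,
    )


def reconstruct_maps(
    sinograms: dict[str, MaterialSinogram],
    pixel_spacing: float,
    center: Optional[float] = None,
    filter_name: str = "ramp",
    center_material: Optional[str] = None,
) -> dict[str, tomo.ReconstructedMap]:
    """Center-find (auto unless given) and FBP every material sinogram.

    The center is estimated once, on ``center_material`` (default: the
    sinogram with the largest total signal, normally the matrix material),
    and shared by all materials of the scan.
    """
    if not sinograms:
        raise ValueError("no sinograms to reconstruct")
    if center is None:
        if center_material is None:
            center_material = max(
                sinograms, key=lambda m: float(np.nansum(np.abs(sinograms[m].values)))
            )
        center = tomo.find_center(sinograms[center_material])
        logger.info("auto rotation center: %.2f (on %s)", center, center_material)
    return {
        m: tomo.reconstruct_fbp(s, center=center, filter_name=filter_name,
                                pixel_spacing=pixel_spacing)
        for m, s in sinograms.items()
    }
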