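"""Forward simulator of the energy-dispersive imaging system.

Generates dark/flat/edge/tomo stacks with full ground truth so every
downstream stage (normalization, edge localization, energy mapping,
unmixing, decay correction, reconstruction) is testable without beamline
data.  The model: a near-Gaussian vertical beam profile whose center and
absorption-edge row bow quadratically across columns (non-uniform crystal
bending), a one-point Bragg energy map per column, attenuation by
line-integral projected densities through a phantom, reference spectra
pre-blurred by the system energy resolution, a monotonic flux decay across
the CT scan, and optional Poisson counting noise (deterministic per seed).

Species near-edge spectra (selenate, selenite, selenomethionine) are
stylized: the elemental selenium edge jump shifted by a chemical shift plus
Gaussian white-line peaks at stated energies, on top of the tabulated
attenuation of the compound's light elements.  They are used identically in
the forward and inverse directions -- the pipeline's correctness, not
atomic physics, is what simulations test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.transform import radon

from .calibration import EnergyMap
from .geometry import SystemGeometry, bragg_angle
from .imaging_io import ImageStack
from .references import (
    ATOMIC_MASS,
    MaterialSpectrum,
    blur_spectrum,
    element_mu_rho,
    water_spectrum,
)

#: Selenium K-edge as tabulated (keV); the geometry's nominal edge energy
#: (12.658) is this value at the printed precision.
SE_K_EDGE = 12.6578

#: Density of elemental selenium (g/cm^3) for the edge reference film.
SE_DENSITY = 4.79

#: Default edge-reference film thickness, cm (0.2 mm selenium).
SE_FILM_CM = 0.02

#: The two absorption peaks of the selenate calibration species (keV).
SELENATE_PEAKS = (12.667, 12.681)

#: Stylized near-edge models: composition, molar mass (g/mol), chemical
#: shift of the edge (keV), and white-line peaks (center keV, amplitude as
#: a fraction of the elemental edge jump, sigma keV).
_SPECIES = {
    "selenate": dict(
        formula={"Na": 2, "Se": 1, "O": 4},
        molar_mass=188.94,
        edge_shift=0.0060,
        peaks=[(SELENATE_PEAKS[0], 0.90, 0.0030), (SELENATE_PEAKS[1], 0.35, 0.0030)],
    ),
    "selenite": dict(
        formula={"Na": 2, "Se": 1, "O": 3},
        molar_mass=172.94,
        edge_shift=0.0030,
        peaks=[(12.6635, 0.75, 0.0030)],
    ),
    "selenomethionine": dict(
        formula={"C": 5, "H": 11, "N": 1, "O": 2, "Se": 1},
        molar_mass=196.12,
        edge_shift=0.0,
        peaks=[(12.6600, 0.55, 0.0030)],
    ),
}

#: Intrinsic (pre-resolution) edge transition half-width, keV.  Together
#: with the few-eV white-line sigmas above this reflects solution-phase
#: near-edge structure, which is several eV wide, not resolution-limited.
_EDGE_WIDTH = 0.0015

DEFAULT_N_ROWS = 400
DEFAULT_N_COLS = 1024
DEFAULT_BEAM_FWHM_ROWS = 120.0
DEFAULT_DARK_LEVEL = 100.0
DEFAULT_DARK_SIGMA = 2.0
DEFAULT_BOW = 5e-4  # quadratic bow coefficient, px / col^2
DEFAULT_MARGIN = 32  # empty detector columns each side of the sample


def _mass_fractions(formula: dict[str, int], molar_mass: float) -> dict[str, float]:
    w = {el: n * ATOMIC_MASS[el] / molar_mass for el, n in formula.items()}
    total = sum(w.values())
    return {el: v / total for el, v in w.items()}


def default_species_grid() -> np.ndarray:
    """Near-edge energy grid covering the detector band, 0.2 eV pitch."""
    return np.arange(12.30, 13.10, 0.0002)


def species_spectrum(
    name: str, energy_grid: Optional[np.ndarray] = None
) -> MaterialSpectrum:
    """Stylized near-edge reference spectrum of a selenium species.

    The selenium contribution is the tabulated below-edge attenuation
    continued smoothly above the edge, plus the elemental edge jump moved
    to the species' chemically shifted edge energy (arctan transition) and
    Gaussian white-line peaks; light elements contribute their tabulated
    attenuation.  Provenance is ``synthetic``.
    """
    if name == "water":
        return water_spectrum(
            default_species_grid() if energy_grid is None else energy_grid
        )
    if name not in _SPECIES:
        raise KeyError(f"unknown species {name!r}; known: {sorted(_SPECIES)}")
    p = _SPECIES[name]
    e = default_species_grid() if energy_grid is None else np.asarray(energy_grid)
    w = _mass_fractions(p["formula"], p["molar_mass"])

    mu = np.zeros_like(e, dtype=float)
    for el, frac in w.items():
        if el != "Se":
            mu += frac * element_mu_rho(el, e)

    below_anchor = float(element_mu_rho("Se", SE_K_EDGE - 0.0005))
    above_anchor = float(element_mu_rho("Se", SE_K_EDGE + 0.0005))
    jump = above_anchor - below_anchor
    # below-edge curve continued across the band (E^-3 continuation)
    base = np.where(
        e < SE_K_EDGE - 0.0005,
        element_mu_rho("Se", np.minimum(e, SE_K_EDGE - 0.0005)),
        below_anchor * ((SE_K_EDGE - 0.0005) / e) ** 3,
    )
    e0 = SE_K_EDGE + p["edge_shift"]
    step = 0.5 * (1.0 + (2.0 / np.pi) * np.arctan((e - e0) / _EDGE_WIDTH))
    se_part = base + jump * step * (e0 / e) ** 3
    for center, amp, sigma in p["peaks"]:
        se_part += jump * amp * np.exp(-0.5 * ((e - center) / sigma) ** 2)
    mu += w["Se"] * se_part
    return MaterialSpectrum(
        name=name,
        energy_grid=e,
        mu_rho=mu,
        provenance="synthetic",
        molar_mass=p["molar_mass"],
        element_mass_fraction=w,
    )


def solution_density(name: str, concentration_mM: float) -> float:
    """Dissolved-compound mass density (g/cm^3) of a solution in mmol/L."""
    return concentration_mM * 1e-6 * _SPECIES[name]["molar_mass"]


@dataclass
class Phantom:
    """2-D per-material density maps in the rotation plane.

    ``grids`` maps material name to a (W, W) density image in g/cm^3;
    ``inserts`` records named regions with their true densities and (for
    solutions) concentrations, for recovery reporting.
    """

    grids: dict[str, np.ndarray]
    materials: list[MaterialSpectrum]
    pixel_spacing: float  # cm
    inserts: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [m.name for m in self.materials]
        if len(set(names)) != len(names):
            raise ValueError("materials must be distinct")
        shapes = {g.shape for g in self.grids.values()}
        if len(shapes) != 1:
            raise ValueError("all density grids must share one shape")
        for n, g in self.grids.items():
            if n not in names:
                raise ValueError(f"grid {n!r} has no matching material spectrum")
            if np.any(g < 0):
                raise ValueError(f"negative density in grid {n!r}")

    @property
    def width(self) -> int:
        return next(iter(self.grids.values())).shape[0]


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside the generated stacks."""

    energy_map: EnergyMap
    edge_row: np.ndarray  # per-column elemental edge row used
    flux_factors: np.ndarray
    rho_t: dict[str, np.ndarray]  # material -> (n_angles, n_detector_cols)
    sigma_e: float  # keV, resolution blur applied to references
    de_pixel: float  # keV, energy span of one detector pixel at beam center
    angles: np.ndarray  # degrees
    center_col: float  # rotation-center detector column
    pixel_spacing: float  # cm


def _disk(w: int, cy: float, cx: float, radius: float) -> np.ndarray:
    y, x = np.mgrid[0:w, 0:w]
    return (y - cy) ** 2 + (x - cx) ** 2 <= radius**2


def make_demo_phantom(kind: str, width: int = 144) -> Phantom:
    """Demonstration phantoms with recorded ground truth.

    ``three_species_disks``: a water cylinder holding three disks of
    selenate, selenite and selenomethionine solutions, each prepared at
    100 mM.  ``seedpod``: a central selenomethionine insert at 7 mg/cm^3 in
    a water matrix (a plant-tissue analogue).  Pixel spacing is chosen so
    the cylinder is about 0.9 cm across.
    """
    s = 1.0 / 160.0  # cm per phantom pixel
    w = width
    c = (w - 1) / 2.0
    holder = _disk(w, c, c, 0.445 * w)
    water = np.where(holder, 1.0, 0.0)
    materials = [
        species_spectrum("water"),
        species_spectrum("selenate"),
        species_spectrum("selenite"),
        species_spectrum("selenomethionine"),
    ]
    grids = {m.name: np.zeros((w, w)) for m in materials}
    grids["water"] = water
    inserts: dict[str, dict] = {}

    if kind == "three_species_disks":
        conc = 100.0  # mM, preparation concentration of every solution
        r_ins = 0.125 * w
        r_pos = 0.26 * w
        for name, ang in (
            ("selenate", 90.0),
            ("selenite", 210.0),
            ("selenomethionine", 330.0),
        ):
            cy = c - r_pos * np.sin(np.radians(ang))
            cx = c + r_pos * np.cos(np.radians(ang))
            m = _disk(w, cy, cx, r_ins)
            rho = solution_density(name, conc)
            grids[name][m] = rho
            inserts[name] = dict(
                material=name,
                mask=m,
                interior=_disk(w, cy, cx, r_ins - 3.0),
                density=rho,
                concentration_mM=conc,
            )
    elif kind == "seedpod":
        rho = 7.0e-3  # g/cm^3 selenomethionine in the seedpod
        m = _disk(w, c, c, 0.155 * w)
        grids["selenomethionine"][m] = rho
        inserts["seedpod"] = dict(
            material="selenomethionine",
            mask=m,
            interior=_disk(w, c, c, 0.155 * w - 3.0),
            density=rho,
            concentration_mM=rho / 196.12 * 1e6,
        )
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    return Phantom(
        grids=grids, materials=materials, pixel_spacing=s, inserts=inserts
    )


def _truth_energy_map(
    geometry: SystemGeometry,
    n_rows: int,
    n_cols: int,
    edge_row_center: float,
    bow: float,
) -> tuple[EnergyMap, np.ndarray]:
    cols = np.arange(n_cols, dtype=float)
    p_k = edge_row_center + bow * (cols - (n_cols - 1) / 2.0) ** 2
    theta_k = bragg_angle(geometry.edge_energy, geometry)
    rows = np.arange(n_rows, dtype=float)[:, None]
    alpha = np.arctan(
        (rows - p_k[None, :]) * geometry.pixel_size / geometry.focus_to_detector
    )
    theta = theta_k + geometry.energy_direction * alpha
    if theta.min() <= 0 or theta.max() >= np.pi / 2:
        raise ValueError("detector extends beyond the physical Bragg-angle range")
    from .geometry import HC_KEV_ANGSTROM, plane_spacing

    energies = HC_KEV_ANGSTROM / (2.0 * plane_spacing(geometry) * np.sin(theta))
    return EnergyMap(energies=energies), p_k


def _interp_clamped(spectrum: MaterialSpectrum, energies: np.ndarray) -> np.ndarray:
    return np.interp(energies, spectrum.energy_grid, spectrum.mu_rho)


def _pixel_integrate(spectrum: MaterialSpectrum, width_kev: float) -> MaterialSpectrum:
    """Convolve a spectrum with a boxcar of one detector pixel's energy span.

    Real detector pixels integrate the dispersed spectrum over their finite
    height; applying the equivalent boxcar to the references keeps the
    simulated data consistent with what an edge-width measurement on them
    reports.
    """
    from dataclasses import replace

    from scipy.ndimage import uniform_filter1d

    eg = spectrum.energy_grid
    step = float(np.min(np.diff(eg)))
    size = max(int(round(width_kev / step)), 1)
    uniform = np.arange(eg[0], eg[-1] + step, step)
    dense = np.interp(uniform, eg, spectrum.mu_rho)
    smooth = uniform_filter1d(dense, size, mode="nearest")
    return replace(spectrum, mu_rho=np.interp(eg, uniform, smooth))


def apply_system_resolution(
    spectrum: MaterialSpectrum, sigma_e: float, de_pixel: float
) -> MaterialSpectrum:
    """Resolution blur followed by detector pixel integration.

    This is the exact spectral response the simulator applies to every
    reference before exponentiation; round-trip tests reuse it to build
    truth-consistent references.
    """
    return _pixel_integrate(blur_spectrum(spectrum, sigma_e), de_pixel)


def simulate_scan(
    phantom: Optional[Phantom],
    geometry: Optional[SystemGeometry] = None,
    n_angles: int = 180,
    counts_flat: float = 1e4,
    noise: bool = True,
    decay_to: float = 1.0,
    bow: float = DEFAULT_BOW,
    sigma_e: Optional[float] = None,
    seed: int = 0,
    n_rows: int = DEFAULT_N_ROWS,
    n_cols: Optional[int] = None,
    margin: int = DEFAULT_MARGIN,
    beam_fwhm_rows: float = DEFAULT_BEAM_FWHM_ROWS,
    n_correction_frames: int = 10,
    n_edge_frames: int = 5,
    film_thickness_cm: float = SE_FILM_CM,
) -> tuple[dict[str, ImageStack], SimulationTruth]:
    """Simulate a full acquisition: dark, flat, edge and tomo stacks.

    With ``phantom=None`` only the correction and calibration stacks are
    produced (``n_cols`` then defaults to 1024).  ``decay_to`` is the flux
    factor of the last projection (linear decay from 1.0); ``sigma_e`` the
    Gaussian energy-resolution blur in keV, defaulting to a relative edge
    width FWHM/E of 1e-4.  Given a seed the output is bit-reproducible.
    """
    geometry = geometry or SystemGeometry()
    if not counts_flat > 0:
        raise ValueError("counts_flat must be positive")
    if not 0.0 < decay_to <= 1.0:
        raise ValueError("decay_to must lie in (0, 1]")
    if sigma_e is None:
        sigma_e = 1e-4 * geometry.edge_energy / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    if phantom is not None:
        n_cols = phantom.width + 2 * margin
    elif n_cols is None:
        n_cols = DEFAULT_N_COLS

    emap, p_k = _truth_energy_map(geometry, n_rows, n_cols, n_rows * 0.5, bow)
    rc, cc = n_rows // 2, n_cols // 2
    de_pixel = abs(emap.energies[rc + 1, cc] - emap.energies[rc, cc])
    sigma_rows = beam_fwhm_rows / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    rows = np.arange(n_rows, dtype=float)[:, None]
    profile = np.exp(-0.5 * ((rows - p_k[None, :]) / sigma_rows) ** 2)
    flat_clean = counts_flat * profile
    dark_level = DEFAULT_DARK_LEVEL

    def make_frames(beam_clean: np.ndarray, n: int) -> np.ndarray:
        out = np.empty((n,) + beam_clean.shape)
        for i in range(n):
            if noise:
                frame = rng.poisson(beam_clean).astype(float)
                frame += dark_level + rng.normal(0.0, DEFAULT_DARK_SIGMA, beam_clean.shape)
            else:
                frame = beam_clean + dark_level
            out[i] = np.clip(frame, 0.0, None)
        return out

    stacks: dict[str, ImageStack] = {}
    stacks["dark"] = ImageStack(
        role="dark", frames=make_frames(np.zeros((n_rows, n_cols)), n_correction_frames)
    )
    stacks["flat"] = ImageStack(
        role="flat", frames=make_frames(flat_clean, n_correction_frames)
    )

    # calibration films
    se_film = MaterialSpectrum(
        name="Se_film",
        energy_grid=default_species_grid(),
        mu_rho=element_mu_rho("Se", default_species_grid()),
        provenance="tabulated",
    )
    se_blur = apply_system_resolution(se_film, sigma_e, de_pixel)
    t_el = np.exp(-_interp_clamped(se_blur, emap.energies) * SE_DENSITY * film_thickness_cm)
    stacks["edge_elemental"] = ImageStack(
        role="edge", frames=make_frames(flat_clean * t_el, n_edge_frames)
    )
    selenate_blur = apply_system_resolution(species_spectrum("selenate"), sigma_e, de_pixel)
    water_blur = apply_system_resolution(water_spectrum(default_species_grid()), sigma_e, de_pixel)
    t_sp = np.exp(
        -_interp_clamped(selenate_blur, emap.energies) * 0.02
        - _interp_clamped(water_blur, emap.energies) * 0.2
    )
    stacks["edge_speciation"] = ImageStack(
        role="edge", frames=make_frames(flat_clean * t_sp, n_edge_frames)
    )

    angles = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    flux = np.linspace(1.0, decay_to, n_angles)
    rho_t: dict[str, np.ndarray] = {}
    if phantom is not None:
        w = phantom.width
        mu_cube = {
            m.name: _interp_clamped(apply_system_resolution(m, sigma_e, de_pixel), emap.energies)
            for m in phantom.materials
        }
        for m in phantom.materials:
            sino = radon(phantom.grids[m.name], theta=angles, circle=True)
            rt = np.zeros((n_angles, n_cols))
            rt[:, margin : margin + w] = sino.T * phantom.pixel_spacing
            rho_t[m.name] = rt
        frames = np.empty((n_angles, n_rows, n_cols))
        for a in range(n_angles):
            att = np.zeros((n_rows, n_cols))
            for name, mu in mu_cube.items():
                att += mu * rho_t[name][a][None, :]
            beam = flat_clean * flux[a] * np.exp(-att)
            frames[a] = make_frames(beam, 1)[0]
        stacks["tomo"] = ImageStack(role="tomo", frames=frames, angles=angles)

    truth = SimulationTruth(
        energy_map=emap,
        edge_row=p_k,
        flux_factors=flux,
        rho_t=rho_t,
        sigma_e=sigma_e,
        de_pixel=de_pixel,
        angles=angles,
        center_col=(margin + (phantom.width - 1) / 2.0) if phantom else (n_cols - 1) / 2.0,
        pixel_spacing=phantom.pixel_spacing if phantom else np.nan,
    )
    return stacks, truth
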