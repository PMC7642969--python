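"""Detector image I/O: stacks, averaging, and the session archive.

Raw data arrive as stacks of 2-D TIFF images in four roles: ``dark`` (beam
off), ``flat`` (beam on, no sample), ``edge`` (reference film in beam) and
``tomo`` (sample projections).  Dark and flat stacks are averaged (ten
frames by default) before use.  Analysis results, including mid-way
products useful for in-depth evaluation (energy map, beam region, corrected
attenuation, references in use), are stored in a single HDF5 keyed-dataset
archive together with per-material float TIFF maps and a plain-text
settings record; the archive round-trips every array bit-exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np
import tifffile

from . import geometry as geo
from .geometry import SystemGeometry

logger = logging.getLogger(__name__)

ROLES = ("dark", "flat", "edge", "tomo")

#: Default number of frames averaged for dark and flat stacks.
DEFAULT_CORRECTION_FRAMES = 10


@dataclass
class ImageStack:
    """Role-tagged stack of same-shape 2-D count images.

    ``angles`` (degrees, one per frame) is used for tomo stacks acquired in
    CT mode; ``slice_index`` groups multi-slice scans.
    """

    role: str
    frames: np.ndarray  # (n_frames, rows, cols)
    slice_index: Optional[int] = None
    angles: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        frames = np.asarray(self.frames)
        if frames.ndim != 3 or frames.shape[0] == 0:
            raise ValueError("frames must be a non-empty (n, rows, cols) stack")
        if not np.all(np.isfinite(frames)) or frames.min() < 0:
            raise ValueError("counts must be finite and non-negative")
        self.frames = frames
        if self.angles is not None:
            self.angles = np.asarray(self.angles, dtype=float)
            if len(self.angles) != len(frames):
                raise ValueError("angles must have one entry per frame")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def load_stack(
    paths: Sequence[Union[str, Path]],
    role: str,
    n_limit: Optional[int] = None,
    angles: Optional[Sequence[float]] = None,
) -> ImageStack:
    """Read TIFF files into an :class:`ImageStack`, frames ordered by filename.

    ``n_limit`` caps the number of frames; it defaults to 10 for dark and
    flat stacks and to no limit for edge and tomo stacks.
    """
    if len(paths) == 0:
        raise ValueError("empty file list")
    if n_limit is None and role in ("dark", "flat"):
        n_limit = DEFAULT_CORRECTION_FRAMES
    ordered = sorted(Path(p) for p in paths)
    if n_limit is not None:
        ordered = ordered[:n_limit]
        if angles is not None:
            angles = list(angles)[: len(ordered)]
    frames = []
    for p in ordered:
        img = np.asarray(tifffile.imread(str(p)))
        if img.ndim != 2:
            raise ValueError(f"{p} is not a 2-D image (shape {img.shape})")
        if frames and img.shape != frames[0].shape:
            raise ValueError(
                f"shape mismatch: {p} has {img.shape}, expected {frames[0].shape}"
            )
        frames.append(img)
    return ImageStack(role=role, frames=np.stack(frames), angles=angles)


def group_by_slice(
    paths: Sequence[Union[str, Path]], pattern: str = r"slice[_-]?(\d+)"
) -> dict[int, list[Path]]:
    """Group tomo file paths by slice index extracted with a filename regex.

    The regex must contain one integer capture group; files that do not
    match are assigned to slice 0.
    """
    rx = re.compile(pattern)
    groups: dict[int, list[Path]] = {}
    for p in sorted(Path(q) for q in paths):
        m = rx.search(p.name)
        idx = int(m.group(1)) if m else 0
        groups.setdefault(idx, []).append(p)
    return groups


def average_stack(stack: ImageStack) -> np.ndarray:
    """Element-wise arithmetic mean of the frames, as float64."""
    if len(stack) == 0:
        raise ValueError("cannot average an empty stack")
    return stack.frames.mean(axis=0, dtype=np.float64)


@dataclass
class SessionArchive:
    """All analysis products of one run, as saved to/loaded from disk.

    ``maps`` holds the per-material result arrays (2-D scan maps or
    angle x column sinograms); every other field is a mid-way product kept
    for in-depth evaluation of the run.
    """

    geometry: SystemGeometry
    settings_record: str = ""
    energy_map: Optional[np.ndarray] = None
    beam_top: Optional[np.ndarray] = None
    beam_bottom: Optional[np.ndarray] = None
    beam_valid: Optional[np.ndarray] = None
    edge_row: Optional[np.ndarray] = None
    edge_fwhm: Optional[np.ndarray] = None
    attenuation: Optional[np.ndarray] = None  # (n_proj, rows, cols), NaN = masked
    angles: Optional[np.ndarray] = None
    references: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (2, n)
    maps: dict[str, np.ndarray] = field(default_factory=dict)
    residual_rms: Optional[np.ndarray] = None
    decay_offsets: Optional[np.ndarray] = None
    resolution_fwhm_kev: Optional[float] = None

    _ARRAYS = (
        "energy_map", "beam_top", "beam_bottom", "beam_valid", "edge_row",
        "edge_fwhm", "attenuation", "angles", "residual_rms", "decay_offsets",
    )


def save_session(archive: SessionArchive, out_dir: Union[str, Path]) -> list[Path]:
    """Write the archive file, per-material float TIFFs and the settings record.

    Returns the list of paths written.  Reloading the archive with
    :func:`load_session` reproduces all arrays bit-exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    h5path = out / "session.h5"
    with h5py.File(h5path, "w") as f:
        g = f.create_group("geometry")
        gm = archive.geometry
        g.attrs.update(
            asymmetry_angle=gm.asymmetry_angle,
            reflection=list(gm.reflection),
            edge_energy=gm.edge_energy,
            pixel_size=gm.pixel_size,
            focus_to_detector=gm.focus_to_detector,
            energy_direction=gm.energy_direction,
            lattice_constant=gm.lattice_constant,
        )
        f.attrs["settings_record"] = archive.settings_record
        if archive.resolution_fwhm_kev is not None:
            f.attrs["resolution_fwhm_kev"] = archive.resolution_fwhm_kev
        for name in SessionArchive._ARRAYS:
            arr = getattr(archive, name)
            if arr is not None:
                f.create_dataset(name, data=np.asarray(arr))
        rg = f.create_group("references")
        for name, arr in archive.references.items():
            rg.create_dataset(name, data=np.asarray(arr))
        mg = f.create_group("maps")
        for name, arr in archive.maps.items():
            mg.create_dataset(name, data=np.asarray(arr))
    written.append(h5path)

    if not archive.maps:
        logger.warning("no fit results to save; archive written without maps")
    for name, arr in archive.maps.items():
        p = out / f"{name}_map.tif"
        tifffile.imwrite(str(p), np.asarray(arr, dtype=np.float32))
        written.append(p)

    spath = out / "settings.txt"
    spath.write_text(
        geo.write_arrangement(archive.geometry, _Null()) + archive.settings_record
    )
    written.append(spath)
    return written


class _Null:
    def write(self, _s: str) -> None:
        pass


def load_session(path: Union[str, Path]) -> SessionArchive:
    """Reload a :func:`save_session` archive (``session.h5`` or its directory)."""
    p = Path(path)
    if p.is_dir():
        p = p / "session.h5"
    with h5py.File(p, "r") as f:
        g = f["geometry"].attrs
        geometry = SystemGeometry(
            asymmetry_angle=float(g["asymmetry_angle"]),
            reflection=tuple(int(i) for i in g["reflection"]),
            edge_energy=float(g["edge_energy"]),
            pixel_size=float(g["pixel_size"]),
            focus_to_detector=float(g["focus_to_detector"]),
            energy_direction=int(g["energy_direction"]),
            lattice_constant=float(g["lattice_constant"]),
        )
        archive = SessionArchive(
            geometry=geometry, settings_record=str(f.attrs["settings_record"])
        )
        if "resolution_fwhm_kev" in f.attrs:
            archive.resolution_fwhm_kev = float(f.attrs["resolution_fwhm_kev"])
        for name in SessionArchive._ARRAYS:
            if name in f:
                setattr(archive, name, f[name][()])
        for name, ds in f["references"].items():
            archive.references[name] = ds[()]
        for name, ds in f["maps"].items():
            archive.maps[name] = ds[()]
    return archive


def write_map_tiffs(
    maps: dict[str, np.ndarray], out_dir: Union[str, Path], suffix: str = "map"
) -> list[Path]:
    """Write one 32-bit float TIFF per material, named ``<material>_<suffix>.tif``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in maps.items():
        p = out / f"{name}_{suffix}.tif"
        tifffile.imwrite(str(p), np.asarray(arr, dtype=np.float32))
        paths.append(p)
    return paths
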