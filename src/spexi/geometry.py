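"""System geometry and Bragg-law conversions.

A cylindrically bent Laue monochromator disperses energy along the
diffraction (vertical) plane: each diffraction angle selects one energy,
and at a distance behind the focus the angle-energy correlation becomes a
row-energy correlation on an area detector.  This module holds the system
parameters that fix the angle <-> energy <-> pixel mapping and provides the
Bragg-law conversions used by the calibration stage.

Angles are radians internally; the arrangement-file interface uses degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Union

#: Conversion constant E[keV] * lambda[Angstrom]; single authoritative value
#: used by every operation in the package.
HC_KEV_ANGSTROM = 12.398420

#: Cubic lattice constant of silicon in Angstrom (default crystal).
SILICON_LATTICE_A = 5.431

_REQUIRED_KEYS = (
    "asymmetry_angle_deg",
    "reflection",
    "edge_energy_keV",
    "pixel_size_mm",
    "focus_to_detector_mm",
)


@dataclass(frozen=True)
class SystemGeometry:
    """Monochromator/detector parameters fixing the angle-energy-pixel mapping.

    Parameters
    ----------
    asymmetry_angle : float
        Angle between the diffracting Bragg planes and the crystal surface,
        degrees.  Recorded as metadata (the pixel-energy mapping itself is
        anchored on measured spectral features, not on the asymmetry angle).
    reflection : tuple of int
        Miller indices (h, k, l) of the Bragg planes.
    edge_energy : float
        K-edge energy of the contrast element, keV.
    pixel_size : float
        Effective detector pixel pitch, mm.
    focus_to_detector : float
        Distance between the focus of the diffracted beam and the detector, mm.
    energy_direction : int
        +1 if energy increases with decreasing row index (row 0 = top of the
        detector), -1 otherwise.
    lattice_constant : float
        Cubic lattice constant of the crystal, Angstrom (default silicon).
    """

    asymmetry_angle: float = 0.0
    reflection: tuple[int, int, int] = (1, 1, 1)
    edge_energy: float = 12.658
    pixel_size: float = 0.009
    focus_to_detector: float = 500.0
    energy_direction: int = 1
    lattice_constant: float = SILICON_LATTICE_A

    def __post_init__(self) -> None:
        if len(self.reflection) != 3 or not all(
            float(i).is_integer() for i in self.reflection
        ):
            raise ValueError("reflection must be a triple of integers")
        object.__setattr__(self, "reflection", tuple(int(i) for i in self.reflection))
        if self.reflection == (0, 0, 0):
            raise ValueError("reflection (0,0,0) is not a Bragg reflection")
        for name in ("pixel_size", "focus_to_detector", "lattice_constant"):
            if not getattr(self, name) > 0:
                raise ValueError(f"non-positive length: {name}")
        if not self.edge_energy > 0:
            raise ValueError(f"edge_energy must be positive, got {self.edge_energy}")
        if self.energy_direction not in (1, -1):
            raise ValueError("energy_direction must be +1 or -1")


def plane_spacing(geometry: SystemGeometry) -> float:
    """Lattice spacing d_hkl of the Bragg planes in Angstrom (cubic crystal)."""
    h, k, l = geometry.reflection
    return geometry.lattice_constant / math.sqrt(h * h + k * k + l * l)


def bragg_angle(energy: float, geometry: SystemGeometry) -> float:
    """Bragg angle (radians) diffracting X-rays of ``energy`` (keV).

    Raises ``ValueError`` if the energy is below the minimum reachable,
    hc/(2 d), where sin(theta) would exceed 1.
    """
    s = HC_KEV_ANGSTROM / (2.0 * plane_spacing(geometry) * energy)
    if not 0.0 < s <= 1.0:
        raise ValueError(
            f"energy {energy} keV below the minimum diffraction energy "
            f"{HC_KEV_ANGSTROM / (2 * plane_spacing(geometry)):.4f} keV"
        )
    return math.asin(s)


def bragg_energy(angle: float, geometry: SystemGeometry) -> float:
    """X-ray energy (keV) diffracted at Bragg ``angle`` (radians)."""
    if not 0.0 < angle < math.pi / 2:
        raise ValueError(f"Bragg angle must lie in (0, pi/2), got {angle}")
    return HC_KEV_ANGSTROM / (2.0 * plane_spacing(geometry) * math.sin(angle))


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    if key == "reflection":
        parts = [p for p in raw.replace(",", " ").split() if p]
        if len(parts) != 3:
            raise ValueError(f"reflection must be three integers, got {raw!r}")
        try:
            return tuple(int(p) for p in parts)
        except ValueError as exc:
            raise ValueError(f"non-numeric value for {key}: {raw!r}") from exc
    try:
        value = float(raw)
    except ValueError as exc:
        raise ValueError(f"non-numeric value for {key}: {raw!r}") from exc
    if key == "energy_direction":
        return int(value)
    return value


def parse_arrangement(source: Union[str, Path, IO[str]]) -> SystemGeometry:
    """Parse an arrangement file into a :class:`SystemGeometry`.

    The file is line-oriented UTF-8 text with ``key = value`` pairs and ``#``
    comments.  Required keys: ``asymmetry_angle_deg``, ``reflection`` (h,k,l),
    ``edge_energy_keV``, ``pixel_size_mm``, ``focus_to_detector_mm``.
    Optional: ``lattice_constant_A``, ``energy_direction``.  Unknown keys are
    tolerated.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        path = Path(source)
        if path.exists() or "\n" not in str(source):
            text = path.read_text()
        else:  # raw text passed directly
            text = str(source)

    values: dict[str, object] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed arrangement line: {line!r}")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key in _REQUIRED_KEYS or key in ("lattice_constant_A", "energy_direction"):
            values[key] = _parse_value(key, raw)
        # unknown keys are tolerated and ignored

    missing = [k for k in _REQUIRED_KEYS if k not in values]
    if missing:
        raise ValueError(f"missing key(s) in arrangement file: {', '.join(missing)}")

    kwargs = dict(
        asymmetry_angle=values["asymmetry_angle_deg"],
        reflection=values["reflection"],
        edge_energy=values["edge_energy_keV"],
        pixel_size=values["pixel_size_mm"],
        focus_to_detector=values["focus_to_detector_mm"],
    )
    if "lattice_constant_A" in values:
        kwargs["lattice_constant"] = values["lattice_constant_A"]
    if "energy_direction" in values:
        kwargs["energy_direction"] = values["energy_direction"]
    return SystemGeometry(**kwargs)


def write_arrangement(geometry: SystemGeometry, dest: Union[str, Path, IO[str]]) -> str:
    """Serialize ``geometry`` to arrangement-file text; also written to ``dest``."""
    h, k, l = geometry.reflection
    text = "\n".join(
        [
            "# system arrangement",
            f"asymmetry_angle_deg = {geometry.asymmetry_angle!r}",
            f"reflection = {h},{k},{l}",
            f"edge_energy_keV = {geometry.edge_energy!r}",
            f"pixel_size_mm = {geometry.pixel_size!r}",
            f"focus_to_detector_mm = {geometry.focus_to_detector!r}",
            f"lattice_constant_A = {geometry.lattice_constant!r}",
            f"energy_direction = {geometry.energy_direction}",
            "",
        ]
    )
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)
    return text


def with_edge_energy(geometry: SystemGeometry, edge_energy: float) -> SystemGeometry:
    """Copy of ``geometry`` with a different contrast-element edge energy."""
    return replace(geometry, edge_energy=edge_energy)
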