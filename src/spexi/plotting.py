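"""Fit-diagnostic plotting: per-column spectrum panels rendered to PNG.

One panel shows the reference mass-attenuation curves; the other overlays
the measured attenuation spectrum of a chosen sample column with the fitted
spectrum and each reference scaled by its fitted projected density, so a
bad reference set or a miscalibrated energy axis is visible at a glance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .calibration import AttenuationImage, BeamRegion, EnergyMap
from .references import MaterialSpectrum
from .unmixing import FitResult


def fit_diagnostic(
    attenuation: AttenuationImage,
    emap: EnergyMap,
    region: BeamRegion,
    references: Sequence[MaterialSpectrum],
    fit: FitResult,
    column: int,
    out_path: Union[str, Path],
) -> Path:
    """Render a two-panel fit diagnostic for one sample column to PNG."""
    t, b = region.top[column], region.bottom[column]
    e = emap.energies[t:b, column]
    meas = attenuation.values[t:b, column]
    fitted = fit.fitted[t:b, column] if fit.fitted is not None else None

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.6), constrained_layout=True)
    for ref in references:
        ax1.plot(ref.energy_grid, ref.mu_rho, label=ref.name, lw=1)
    ax1.set_xlim(np.nanmin(e), np.nanmax(e))
    ax1.set_xlabel("energy (keV)")
    ax1.set_ylabel(r"$\mu/\rho$ (cm$^2$/g)")
    ax1.set_title("reference spectra")
    ax1.legend(fontsize=7)

    order = np.argsort(e)
    ax2.plot(e[order], meas[order], ".", ms=2, label="measured", color="0.4")
    if fitted is not None:
        ax2.plot(e[order], fitted[order], "-", lw=1.2, label="fitted", color="C3")
    for i, ref in enumerate(references):
        x = fit.projected_density[i, column]
        if np.isfinite(x):
            mu = np.interp(e, ref.energy_grid, ref.mu_rho)
            ax2.plot(e[order], (mu * x)[order], "--", lw=0.8,
                     label=f"{ref.name} ({x:.3g} g/cm$^2$)")
    ax2.set_xlabel("energy (keV)")
    ax2.set_ylabel("attenuation")
    ax2.set_title(f"column {column}")
    ax2.legend(fontsize=7)

    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
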