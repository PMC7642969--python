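# spexi — spectral X-ray imaging analysis

`spexi` analyses data from **spectral K-edge subtraction (KES)** and
**wide-field energy-dispersive XAS (EDXAS)** imaging systems built around a
bent-Laue monochromator.  Such a system prepares a focused line beam whose
energy varies along the diffraction (vertical) direction; an area detector
behind the focus therefore records, in a single exposure, a full attenuation
spectrum for every horizontal position of the sample.  The package turns raw
energy-dispersed detector images into quantified projected-density maps of
each candidate material — and, for rotation scans, into CT reconstructions of
their volumetric densities.  It is written for beamline scientists and
biomedical-imaging groups deploying these systems, and ships a forward
simulator so the entire pipeline can be exercised and validated without
beamline data.

## The model

With dark (beam off) and flat (beam on, no sample) correction images, the
measured counts in a sample image give the attenuation at each detector
pixel:

```
A = -ln[(N_tomo - N_dark) / (N_flat - N_dark)] = Σ_i (μ/ρ)_i(E) · (ρt)_i
```

where `(μ/ρ)_i(E)` is the energy-dependent mass-attenuation coefficient of
material *i* (cm²/g) and `(ρt)_i` its projected density (g/cm²).  The pixel
energy `E` follows from Bragg's law.  Anchoring the map at the measured
absorption-edge row `p_K` of a reference film:

```
θ_i = θ_K + arctan[(p_i − p_K) · s / F],      E_i = hc / (2 d_hkl sin θ_i)
```

with pixel pitch `s` and focus-to-detector distance `F`; a two-point variant
anchored on two spectral features of known energy (e.g. the selenate
absorption peaks at 12.667 and 12.681 keV) replaces `F` by an effective
distance fixed by the data and is the recommended, more accurate mode.

Each detector column then yields an over-determined linear system in the
projected densities of the offered reference materials, solved by least
squares; materials absent from the sample fit to coefficients near zero.
Stacking columns over a vertical scan gives 2-D `ρt` maps; over a rotation
scan it gives per-material sinograms, which — after flux-decay correction
using empty margins and automatic rotation-center finding — are
reconstructed by filtered back projection into g/cm³ maps.

## Worked example

Simulate a 180-angle CT scan of a water cylinder holding three 100 mM
selenium-species solutions (selenate, selenite, selenomethionine), with
Poisson noise at 10⁴ flat counts and a linear flux decay to 90%, then run
the complete analysis:

```python
import numpy as np
import spexi
from spexi import pipeline, synthetic

phantom = synthetic.make_demo_phantom("three_species_disks")
geometry = spexi.SystemGeometry()          # Si(111), Se K-edge, F = 500 mm
stacks, truth = synthetic.simulate_scan(
    phantom, geometry, n_angles=180, counts_flat=1e4,
    noise=True, decay_to=0.90, seed=11,
)
settings = pipeline.AnalysisSettings(margins=(28, 28))  # empty columns
result = pipeline.analyze_stacks(stacks, geometry, phantom.materials, settings)
print(f"energy resolution FWHM: {result.resolution.fwhm_energy*1e3:.2f} eV "
      f"(dE/E = {result.resolution.relative:.2e})")
recons = pipeline.reconstruct_maps(result.sinograms, phantom.pixel_spacing)
for name, insert in phantom.inserts.items():
    values = recons[insert["material"]].values
    interior = np.zeros(values.shape, bool)
    m, w = 32, phantom.width
    interior[m:m+w, m:m+w] = insert["interior"]
    conc = values[interior].mean() / synthetic.species_spectrum(name).molar_mass * 1e6
    print(f"{name:18s} recovered {conc:6.1f} mM   (prepared "
          f"{insert['concentration_mM']:.0f} mM)")
```

Output:

```
energy resolution FWHM: 0.68 eV (dE/E = 5.34e-05)
selenate           recovered   99.1 mM   (prepared 100 mM)
selenite           recovered   96.3 mM   (prepared 100 mM)
selenomethionine   recovered   98.0 mM   (prepared 100 mM)
```

Each insert's reconstructed interior-mean concentration comes back within a
few percent of the prepared solution concentration, through calibration,
spectral unmixing, decay correction and reconstruction combined.

The same pipeline is available from the shell: `spexi simulate` writes TIFF
stacks (plus a ground-truth archive), `spexi analyze` produces per-material
maps, a session archive (HDF5) with all mid-way products, and a plain-text
settings record, and `spexi reconstruct` applies center finding and FBP with
a choice of `ramp`, `shepp-logan`, `cosine`, `hamming` or `hann` filters.
`spexi.plotting.fit_diagnostic` renders per-column fit panels to PNG.

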