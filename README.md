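# oraleis

Multiscale finite-element simulation of tetrapolar electrical impedance
spectroscopy (EIS) of stratified oral mucosa.

## The problem

Oral potentially malignant disorders (OPMD, i.e. epithelial dysplasia) are
diagnosed today by biopsy and histology. EIS offers a real-time
alternative: a small AC current is driven through the tissue surface by a
tetrapolar probe and the frequency-dependent transfer impedance is
recorded over 76 Hz – 625 kHz. Dysplasia widens the extracellular space
and de-flattens superficial cells, lowering the low-frequency impedance;
surface keratinisation — normal at some oral sites, and also a response to
irritation — raises it. This package exists to simulate how those
structural changes shape the measured spectra, for people developing or
interpreting oral EIS measurements.

## The model

Two coupled finite-element levels, both solving the quasi-static complex
potential equation ∇·(σ\*∇φ) = 0 with σ\* = 1/ρ + jωε₀εᵣ on conforming
hexahedral grids:

1. **Cellular scale** — an epithelial cell is a nested box (extracellular
   space, 8 nm membrane, cytoplasm, optional spherical nucleus), tessellated
   with a half-cell "brick" offset. The smallest symmetry unit is solved
   with a 1 V harmonic drive in the through-thickness (Z) and in-plane (XY)
   directions; the impedance Z\* = V/I\* becomes the impedivity
   ρ\* = Z\*A/l (Ω·m), split per frequency into an effective resistivity
   Re ρ\* and relative permittivity εᵣ = Im(1/ρ\*)/(ωε₀). Membrane charging
   produces the beta dispersion.
2. **Tissue scale** — a 40×40×5 mm stack: saliva film, optional
   keratinised layer, the three homogenized anisotropic epithelial strata
   with histology-derived thicknesses, stroma, and optionally fat, bone or
   muscle below. Four circular surface electrodes: drive (6.08 µA peak),
   grounded receive, and two floating sense electrodes giving
   Z = (φ_m1 − φ_m2)/I per frequency.

The keratinised layer uses either dry keratin (0.1 MΩ·m, εᵣ 1.17) or a
stratum-corneum-based dispersive model (0.049 MΩ·m → 65 Ω·m across the
band) whose resistivity is divided by a hydration factor up to 40.
Scripted studies sweep keratin resistivity, hydration, pathology templates
(7 histology cases), keratinised-layer thickness (15–90 µm) and
sub-stromal substrates. See `docs/methods.md` for assumptions, parameter
provenance and limitations.

## Worked example

Homogenize the normal superficial cell layer and simulate the normal
hard-palate template at three frequencies:

```python
import numpy as np
from oraleis import default_config, experiments

cfg = default_config()
freqs = np.array([76.0, 2.0e4, 625.0e3])

eff = experiments.epithelial_properties(cfg, "normal", freqs)["superficial"]
print("superficial rho_z(76 Hz) =", round(eff.rho_z[0], 1), "ohm-m")

sp = experiments.template_spectrum(cfg, case_id=2, freqs=freqs)
for f, z in zip(sp.freqs, sp.abs_z):
    print(f"|Z({f:9.0f} Hz)| = {z:7.1f} ohm")
```

prints

```
superficial rho_z(76 Hz) = 903.9 ohm-m
|Z(       76 Hz)| =  4504.8 ohm
|Z(    20000 Hz)| =   978.5 ohm
|Z(   625000 Hz)| =   151.1 ohm
```

The superficial layer's ~0.9 kΩ·m low-frequency resistivity reflects
current forced through the thin intercellular clefts of flattened,
tightly packed cells. The tissue spectrum shows the canonical shape: a
~4.5 kΩ low-frequency plateau set by the resistive keratinised and
superficial layers under the conductive saliva film, a beta dispersion in
the tens of kHz as membranes short out, and a ~150 Ω high-frequency floor
set by current spreading in the stroma.

The same studies are available from the shell:

```sh
oraleis --nfreq 6 templates --case 2 --no-bounds
oraleis substrate --case 3
```

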