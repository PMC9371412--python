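# Methods

`oraleis` simulates tetrapolar electrical impedance spectroscopy (EIS) of
stratified oral mucosa with a two-level ("multiscale") finite-element
approach: epithelial cell layers are first homogenized into effective
anisotropic dispersive materials, and those materials then fill the strata
of a tissue-scale layered model carrying a four-electrode surface array.
This note records the model, its assumptions, the numerical choices, and
the provenance and calibration of every default parameter.

## Governing equations and discretisation

Within the 76 Hz – 625 kHz band the problem is quasi-static: magnetic
induction is neglected and the complex potential φ satisfies
∇·(σ\* ∇φ) = 0 with admittivity σ\*(f) = 1/ρ(f) + j·2πf·ε₀·εᵣ(f) under the
e^{+jωt} convention (capacitive admittance +jωε). Discretisation uses
trilinear 8-node hexahedra on tensor-product (rectilinear) grids whose
planes conform to every material interface; for axis-aligned bricks the
element matrix has the exact closed form implemented in `fem_core`
(verified in the tests against independent Gauss quadrature). The global
system (K_σ + jωK_ε)φ = I is complex symmetric and solved by sparse direct
LU factorisation (SuperLU, symmetric-mode minimum-degree ordering).
One-dimensional potential fields are represented exactly by this
discretisation, so laterally uniform layer stacks reproduce the series
closed form t/(σ\*A) to machine precision — that closed form, the
homogeneous-block formula ρl/A and the point-electrode half-space formula
ρ/2π·Σ±1/r serve as independent oracles in the test suite.

Electrodes are perfectly conducting footprints: each electrode's surface
nodes are merged into a single degree of freedom (equipotential coupling),
either fixed (driven/grounded) or floating with zero net current (sense
electrodes). Reaction currents on constrained sets are recovered from the
residual of the unconstrained equations, which is exact for the discrete
system. All outer surfaces not covered by an electrode carry the natural
zero-normal-current condition.

## Cellular scale

A generic epithelial cell is a nested box — extracellular space (ECS)
shell, 8 nm membrane, cytoplasm — with an optional spherical nucleus
(radius 2 µm) and nuclear envelope. Cells tessellate with a half-pitch
"brick" offset along one lateral axis; the other lateral axis is
unstaggered. The ECS is split half-and-half between neighbours so the
assembled layer has a single gap of the full stated width between adjacent
membranes.

The bricked packing has mirror planes through cell centres and through gap
centres; the smallest repeating unit is bounded by such planes, so its
zero-current side walls are exact. A 1 V peak harmonic potential
difference across coupled node sets on two opposite faces yields
Z\* = V/I\*, converted to the size-independent impedivity ρ\* = Z\*A/l and
split into resistivity (Re ρ\*) and relative permittivity (from the
imaginary admittance, εᵣ = Im(1/ρ\*)/(ωε₀)). The through-thickness (Z)
unit spans two cell layers between horizontal mid-gap planes, capturing
the brick offset; the in-plane (XY) unit drives along the unstaggered
lateral axis between vertical mid-gap planes, so no electrode plane cuts a
cell interior. Each stratum is solved in both directions at every grid
frequency, giving a transversely isotropic effective material with the
beta dispersion produced naturally by membrane charging.

Numerical choices at this scale:

- Membranes are meshed at true thickness by default (one element across
  8 nm); the high element aspect ratio is unproblematic for rectilinear
  trilinear elements with a direct solver. An optional scaled-membrane
  mode thickens the membrane k-fold while dividing its resistivity by k
  and multiplying its permittivity by k (preserving per-area
  trans-membrane admittance); the two modes agree within 2% on test cells.
- The nucleus is a centroid-voxelized sphere, resolved so the karyoplasm
  volume error is ≤5%. The tens-of-nm nuclear envelope cannot be
  voxelized; it is meshed as a one-voxel band just outside the sphere with
  the same admittance-preserving material rescale. Default runs omit the
  nucleus entirely: including it moves the unit impedance by under 5%
  (asserted in the acceptance tests), so anuclear models are used
  throughout the tissue studies.
- Cytoplasm-scale mesh target is one sixth of the cell dimension per axis
  (one quarter of the nucleus radius when nucleated); the per-solve
  residual is that of a direct factorisation (≈machine precision), and a
  2×2 lateral tiling of symmetry units reproduces the single-unit
  impedivity, confirming unit-count convergence.

## Tissue scale

The tissue is a 40 mm × 40 mm × 5 mm cuboid (large enough that enlarging
the footprint changes Z by <1%): a 0.01 mm saliva film (ρ = 1 Ω·m,
εᵣ = 72), an optional isotropic keratinised layer, the three homogenized
anisotropic epithelial strata with case-specific thicknesses, and
isotropic stroma filling to 5 mm — or, for the sub-stromal studies, 1 mm
of stroma over fat, bone or muscle. The basal boundary is flat (no rete
pegs). Four circular electrodes sit on the saliva surface: the drive
injects 6.08 µA peak, the receive is grounded, and the transfer impedance
is Z = (φ_m1 − φ_m2)/I from the two floating sense electrodes.

The mesh grades laterally from a fine uniform core under the electrode row
(0.2 mm elements in the default "coarse" preset, 0.1 mm in "standard")
to the far boundary by geometric coarsening, and vertically resolves each
thin layer with 1–3 elements before geometric growth through the stroma.
Electrode footprints are pixelated discs (surface elements whose centre
lies inside the circle); at the standard resolution the pixelated area is
within 10% of the ideal disc. A collinear layout on y = 0 is mirror
symmetric, so the y ≥ 0 half-domain is solved with half the drive current
— an exact optimisation, not an approximation. The coarse preset solves
one frequency of a full template in a few seconds on one core, which is
the problem size used by the test suite and the scripted studies.

## Material models and parameter provenance

- **Keratinised layer.** Two models: (i) frequency-independent dry
  keratin, ρ = 0.1 MΩ·m (configurable down to 1 kΩ·m for sensitivity
  sweeps; the lower bound keeps keratin more resistive than the
  superficial cells), εᵣ = 1.17; (ii) a stratum-corneum-based dispersive
  model anchored at (76 Hz: 0.049 MΩ·m, εᵣ 30) and (625 kHz: 65 Ω·m,
  εᵣ 5.7), log-log interpolated between the anchors (the standard choice
  for broad dielectric dispersions; additional interior anchors can be
  supplied via configuration). Oral hydration divides the resistivity by
  up to 40; at the maximum adjustment the 76 Hz value is 1.225 kΩ·m, and
  that fully hydrated model is the default for all template studies.
- **Cell compartments.** ECS 0.7 Ω·m, cytoplasm 2 Ω·m (both εᵣ 72),
  membrane 10⁷ Ω·m with εᵣ = 9 (≈0.01 F/m² at 8 nm), nucleoplasm
  1.1 Ω·m, nuclear envelope 10⁵ Ω·m. These are provisional averages from
  the cervical-epithelium modelling literature, shipped in the
  configuration file and fully overridable.
- **Morphologies and ECS widths.** Flattened superficial, intermediate
  prickle and cuboidal basal cells per dysplasia grade, with ECS widening
  and superficial cells rounding as grade increases (moderate ≈ CIN II,
  severe ≈ CIN III). No oral ECS measurements exist; the normal
  superficial half-width (12 nm, i.e. a 24 nm intercellular cleft) was
  calibrated once so the homogenized normal superficial layer reproduces
  its published low-frequency resistivity anchor (~0.96 kΩ·m), and the
  dysplastic widths were chosen to preserve the published ordering of the
  template magnitudes. These are inputs of the study conditions, fixed in
  the bundled configuration.
- **Stroma.** Mildly dispersive placeholder (3.6 → 2.1 Ω·m across the
  band), deliberately close to skeletal muscle: the published sub-stromal
  comparison shows tongue spectra essentially coincident with and without
  an explicit muscle layer, which requires stroma ≈ muscle electrically.
- **Substrates.** Bundled CSV dispersion tables for infiltrated fat,
  cancellous bone and skeletal muscle at literature magnitudes (the
  buccal submucosa and palatal bone are perfused tissues, not pure lipid
  or cortical bone). Replaceable configuration data.
- **Electrode layout.** The clinical probe's radii and spacing are not
  published. The default is an explicit placeholder — four 0.3 mm-radius
  circles in a collinear row at 2.4 mm pitch — calibrated once against
  the published normal-template anchors (~4 kΩ at 76 Hz, ~200 Ω at
  625 kHz) and then frozen; it should be replaced with device values when
  available.

## What the simulated conditions do and do not capture

The bundled defaults emulate the published study conditions: Table-style
histology thicknesses per case, a 14-point geometric frequency grid over
the device band, and the fitted hydrated-keratin surface layer. They do
not capture rete-peg geometry, electrode–electrolyte interface impedance,
contact pressure, intra-case biological variability beyond the mean ± SD
thickness bounds, or measured oral ECS and compartment properties (all
borrowed or calibrated). Passing tests therefore demonstrate internal
consistency of the multiscale pipeline and reproduction of the published
simulation magnitudes under documented placeholder inputs — not validation
against clinical measurements.

## Known limitations

- With the calibrated placeholder geometry the high-frequency current
  penetrates roughly an electrode pitch (~2 mm) into the tissue. Two
  published qualitative claims are then not reproducible at strict
  tolerance, and their checks are deliberately left failing rather than
  tuned around:
  - an explicit fat or bone substrate below 1 mm of stroma shifts
    |Z(625 kHz)| by far more than 5% (muscle, matching stroma, stays
    below 3%);
  - the dry-keratin (0.1 MΩ·m) spectrum is flat through the beta band
    (<4% to 50 kHz) but drops ~30% at 625 kHz, where the keratin layer's
    own capacitance (εᵣ = 1.17) begins to conduct.
  Both effects shrink with a shorter-pitch probe, but a shorter pitch is
  incompatible with the ~4 kΩ / ~200 Ω template anchors; resolving the
  tension requires the true device geometry.
- The saliva film thickness (0.01 mm) is influential at low frequency and
  is an assumed constant.
- Tensor-product grids cannot grade locally in 3-D: refinement under the
  electrodes extends across the whole domain in bands, which is wasteful
  but robust.
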