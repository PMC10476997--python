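# Methods

## Scope and model

`rowdplan` computes and optimizes the RBE- and OER-weighted dose (ROWD) for
proton therapy. The chain per voxel is: dose-averaged LET `L` and proton
dose `Dp` from the beam engine → OER from `L` and the voxel oxygen pressure
`p` → aerobic proton LQ parameters (α_RBE, β_RBE) from an RBE model → hypoxic
parameters α_h = α_RBE/OER, β_h = β_RBE/OER² → photon-equivalent ROWD by
inverting the aerobic photon LQ effect. The optimizer then reweights
pencil-beam spots toward a homogeneous target ROWD.

### OER model

The OER is the iso-survival dose ratio at 10% survival between `p` and the
aerobic reference pressure pₐ = 30 mmHg, with LQ parameters in saturation
form (anoxic and aerobic limits blended by K = 3 mmHg):

* α(L, p) = ((a₁ + a₂L)p + (a₃ + a₄L)K)/(p + K), constants a₁ = 0.10 Gy⁻¹,
  a₂ = 0.0010 µm/(Gy·keV), a₃ = 0.010 Gy⁻¹, a₄ = 0.0100 µm/(Gy·keV). Since
  a₄ > a₂, LET sensitises anoxic tissue faster than aerobic tissue, so OER
  decreases with LET.
* β(p): the printed constants b₁ = 0.765, b₂ = 0.273 carry units Gy⁻¹,
  which is dimensionally √β, so by default the saturation expression
  (b₁p + b₂K)/(p + K) is squared (`beta_convention="sqrt"`). The alternative
  reading — the expression used directly as β — is available as
  `beta_convention="linear"`. The sqrt default also yields severe-hypoxia
  OER values (≈1.45 at 2.5 mmHg) in the range expected for proton data,
  whereas the linear reading gives ≈1.2 and an implausible anoxic
  α/β ≈ 0.1 Gy.
* Voxels at or above 60 mmHg are treated as normoxic (OER ≡ 1), and the OER
  is floored at 1 (`clamp_floor_one`) so that pressures slightly above pₐ
  never sensitise. Between pₐ and 60 mmHg the raw ratio dips a fraction of a
  percent below 1; the floor removes this artifact.

### RBE models

Three aerobic models feed (α_RBE, β_RBE): a constant RBE of 1.1
(α_RBE = 1.1α_x, β_RBE = 1.21β_x); the McNamara model, with
RBE_max = 0.99064 + 0.35605·L/(α/β)_x and
RBE_min = 1.1012 − 0.0038703·√((α/β)_x)·L; and `ROR_approx`, a
dose-averaged-LET reduction of the Rørvik LET-spectrum model with
RBE_max = 1 + 0.578·L/(α/β)_x and RBE_min = 1. Coefficients live in a
versioned JSON file (`rowdplan/data/rbe_coefficients.json`) with provenance
notes, never in code. `ROR_approx` is deliberately so named: the original
model weights the full LET spectrum with a response function that saturates
at high LET, which a fixed affine slope in LET_d cannot represent. The
approximation therefore overestimates RBE above ≈8 keV/µm, and plans
optimized with it require correspondingly less physical dose in high-LET
hypoxic subvolumes than the full model would.

### Tissue parameters

Only the (α/β)_x ratio is physically pinned (10 Gy for targets, 3 Gy for
OARs). Absolute defaults are α_x = 0.10 Gy⁻¹, β_x = 0.010 Gy⁻² (target) and
α_x = 0.105, β_x = 0.035 (OAR); they are configurable and echoed into every
run manifest. The ROWD is invariant to a common rescaling of (α_x, β_x) only
through the RBE-model dependence on (α/β)_x, so the absolute values matter
solely via the explicit α_x/2β_x terms, which depend on the ratio alone.

## Beam engine

Monte Carlo transport is replaced by an analytical pencil-beam model whose
purpose is morphological fidelity (SOBP shape, LET-depth behaviour), not
absolute dosimetry:

* **Depth dose**: plateau (entrance fraction 0.30 of the unit peak,
  quadratic rise 0.15 toward the peak) × sigmoid distal cutoff + Gaussian
  peak at the nominal range with σ = max(1 mm, 1.2% of range) (range
  straggling). Entrance-to-peak ratio ≈0.24, distal dose <1% of peak within
  6σ — both inside published pristine-peak bands.
* **Depth LET_d**: L(z) = 12·(2 mm/(r + 2 mm))^0.56 keV/µm with residual
  range r = max(R − z, 0): ≈1.5 at the entrance of an 8 cm beam, 12 at the
  peak. Beyond the range LET_d keeps rising toward 15 keV/µm with a 2 mm
  relaxation length, representing the stopping protons of the distal
  falloff. The peak value is a calibration constant constrained to the
  8–15 keV/µm distal-edge band.
* **Lateral spread**: voxel-integrated Gaussian with σ(z) = 3 mm + 0.03·z
  (multiple-Coulomb-scattering growth), amplitude scaled by (σ₀/σ(z))² so
  lateral integral dose is conserved with depth.
* **Influence**: d_ij (dose per unit weight) and n_ij = L·d_ij are stored as
  sparse CSR matrices; entries below 10⁻³ of each spot's maximum are
  dropped. Fields are axis-aligned (the phantom geometry is coaxial, and
  this removes resampling ambiguity).

Not modelled: nuclear halo, secondary non-proton dose (the
`secondary_fraction` of total-to-proton dose defaults to 0, making D = Dp
and the leading ROWD ratio exactly 1), CT-based stopping power, gantry
angles.

### Initial plans and field arrangement

`init_sobp_plan` lays a spot lattice over the target (5 mm lateral spacing,
4 mm energy-layer spacing in range, distal layer anchored at the distal
target face) and optimizes weights with the constant-1.1 model and OER
disabled so that 1.1×Dp matches the prescription — the RBE1.1 first
approximation that all plan types start from, and the reference plan for
comparisons. For two opposing fields each field's layer stack is truncated
at the target midplane plus one layer spacing (`split_opposing_fields`), a
standard integral-dose-minimising arrangement for coaxial opposed beams; it
also places both fields' stopping protons centrally, which is what allows
the optimizer to push the central (most hypoxic) slab LET_d above
10 keV/µm. Full-depth coverage per field is available by disabling the
flag, but then plateau pass-through dilutes the achievable central LET_d to
≈7 keV/µm and the symmetric weight update cannot undo it.

## Optimizer

Cost = mean over target voxels of (ROWD − P)² plus a one-sided quadratic
penalty mean(max(0, ROWD − level)²) per constraint structure (the exact
published cost lives in an unavailable supplement; this quadratic form is
the package's own declared choice). The update is multiplicative
dose-difference: w_j ← max(w_min, w_j·[Σ d_ij·P_eff / Σ d_ij·ROWD]^λ) with
damping λ = 0.7, P_eff the prescription on target voxels and the constraint
level on violated constraint voxels. ROWD is nonlinear in the weights, so
it is held fixed within a step; LET_d and (α_h, β_h) are refreshed every
`let_refresh_every` iterations (default every iteration). Spots that see no
objective voxel keep their weight and are reported. A projected-gradient
variant (`method="gradient"`) is provided; on the phantom it reaches the
same plateau more slowly.

Loop controls: `max_iters=600`, `rel_tol=1e-7` on the relative cost change.
The fixed point is approached slowly near the plateau — on the phantom the
cost is monotone after the first iterations, and hypoxic-slab LET keeps
sharpening until roughly iteration 500, which is why the default budget is
generous. Everything is deterministic; the `seed` field exists for future
stochastic tie-breaking only.

Degenerate cases: all-zero accumulated ROWD for a spot freezes its weight
with a warning; a non-finite cost aborts with a diagnostic dump; empty
target masks and misaligned grids are configuration errors.

## Synthetic data

The **water phantom** is a water box (80×80×160 mm, 2 mm voxels) with a
4×4×4 cm³ target at 8 cm depth, divided into seven slabs along the beam
axis with pO2 values [30, 15, 7.5, 2.5, 5, 11, 22] mmHg — seven distinct
levels spanning 2.5–30 mmHg with the most hypoxic slab central — and
normoxic surroundings (160 mmHg). The slab sequence is configurable; study
metrics are evaluated on "the most hypoxic slab", so the ordering is not
load-bearing. The phantom prescription is 2 Gy(RBE).

**Patient-like cases** are smoothed Gaussian random fields (correlation
length 8 mm) mapped through a monotone piecewise-linear transform that
sends a chosen PTV quantile to the 60 mmHg hypoxia threshold, so the
realized sub-60 fraction matches the request to within the quantile
resolution (defaults emulate the two clinical profiles: 95% and 50%
hypoxic PTV). What they do not emulate: PET physics (PSF, noise,
reconstruction), anatomically structured hypoxia (necrotic cores, vessel
distance gradients), or heterogeneous density — so passing tests show the
optimizer handles prescribed oxygenation statistics, not that clinical
plans would be deliverable.

The PET-uptake path is a pluggable two-column calibration table
(uptake → pO2) applied by clamped piecewise-linear interpolation; no
specific tracer curve is shipped.

## Numerical choices

* DVH metrics use the ≥-threshold convention without interpolation
  (D_q = largest level with V ≥ q, default bin 0.01 Gy) for bit-stable
  tests; zero-dose voxels have LET_d = 0 by convention.
* Grids are float64 in memory, float32 on disk (NIfTI, RAS, mm, origin at
  the first-voxel centre); alignment is checked, never resampled.
* The OER evaluation at p = pₐ is exactly 1 by construction (identical
  float expressions), so OER-on and OER-off optimizations of a uniformly
  aerobic phantom are bitwise identical.
* Problem sizes: the full phantom study uses ~128k voxels and 1100 (single
  field) / 1400 (opposing) spots; scaled-down specs for quick exploration
  use a 1.6 cm target.

## Known limitations

* The beam engine is calibrated to morphology, not measured data; absolute
  LET_d values inherit the configured peak/falloff constants, and the
  phantom LET results should be read with the stated ±2 keV/µm latitude.
* `ROR_approx` overestimates RBE at high LET_d (see above); ROWD-optimized
  physical dose in strongly hypoxic, high-LET regions is a lower bound on
  what the full spectrum-weighted model would prescribe.
* The dose-difference update preserves any symmetry of the initial plan; it
  finds a fixed point of the update, not a certified cost minimum.
* Patient results (multi-field HNC plans on CT anatomy) are out of scope;
  only phantom-class geometries are exercised.
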