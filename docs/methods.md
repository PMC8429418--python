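# Methods

This note records the scientific model behind `spinepdt`, the defaults and
why they were chosen, the numerical decisions, and the limits of what the
synthetic phantom can show about patient anatomy.

## Threshold-dose model

PDT damage is modelled as a binary threshold on fluence: a voxel of tissue
necroses exactly when its accumulated fluence (J/mm²) reaches that tissue's
threshold Φ_thr. No sigmoid dose–response, photobleaching, oxygen dynamics
or explicit singlet-oxygen dosimetry is modelled; the drug–light interval is
fixed implicitly through the uptake values.

Φ_thr derives from the photon-count necrosis threshold *T* (photons absorbed
by the photosensitizer per cm³):

Φ_thr = (h·c₀/λ) · T / μ_a^PS,  μ_a^PS = ln(10)·ε·c  (cm⁻¹),

where c is the molar photosensitizer concentration obtained from the tissue
uptake C (µg drug per g tissue) with tissue density 1 g/cm³ and BPD-MA molar
mass 718.8 g/mol, and ε is the molar extinction coefficient (33 000 M⁻¹cm⁻¹
at 690 nm, 6 724 at 565 nm). Constants: h = 6.626×10⁻³⁴ J·s,
c₀ = 2.998×10⁸ m/s. Canonical internal units are mm, mm⁻¹, J, J/mm²; all
conversions happen at module boundaries.

The shipped 690 nm threshold defaults are the published values (cord 0.02,
bone 0.1, metastasis 0.4, muscle 0.1 J/mm²). Two of them do not follow
exactly from the formula with their stated T and C: bone computes to
0.091 (published 0.1) and muscle to 0.21 (published 0.1). The published
values govern the library defaults; the formula remains available and is
regression-tested on the cord and metastasis entries, which it reproduces at
printed precision. No published 565 nm thresholds exist; the defaults scale
the 690 nm values by the formula ratio (ε₆₉₀·λ₆₉₀)/(ε₅₆₅·λ₅₆₅) ≈ 5.99, and
are overridable in the tissue-library config. Whether a study should instead
hold thresholds fixed across wavelengths is an open modelling question; the
scaling choice is the one implied by the threshold formula itself.

The per-mass extinction unit sometimes quoted for BPD-MA is internally
inconsistent with the molar values; only the molar path is used here, since
it reproduces the published thresholds.

## Synthetic phantom

The phantom emulates a segmented metastatic vertebra with geometric
primitives: an elliptic-cylinder vertebral body of bone (height 30 mm,
lateral/AP axis ratio 1.1), an ellipsoidal lesion inside it (axis ratios
1 : 0.75 : 0.58), a cylindrical cord spanning the 50 mm phantom height
inside a posterior canal, and muscle filling an outer elliptic cylinder.
Labels are voxel-center assignments at a default 1 mm pitch; +y is
posterior.

Primitive scales are set by monotone 1-D bisection on the voxelized volume
(cord radius → lesion scale → body cross-section → outer boundary, in
dependency order) until each achieved tissue volume is within 2% (default
tolerance) of its target; the default targets are the case-1-like volumes
23.21 / 4.72 / 31.14 / 171.84 cm³ for metastasis / cord / bone / muscle.
Unreachable targets raise an error naming the limiting dimension. The
construction is deterministic; a seed matters only if optional boundary
jitter is enabled (default off).

The lesion sits 3.5 mm posterior of the body centre and the cord canal
29.4 mm posterior, leaving a ≈3.4 mm bone+muscle gap between lesion surface
and cord surface. This emulates posterior vertebral-body involvement — the
clinically critical configuration in which covering the posterior lesion rim
inevitably doses the cord at 690 nm. The canal offset deliberately avoids
half-integer alignment with 1 mm voxel centres, which would make the
voxelized cord volume jump in coarse steps during bisection. No published
lesion shape or lesion–cord distance exists for any case; both are free
spec parameters.

What the phantom does **not** emulate: trabecular/cortical bone structure,
CSF and dura around the cord, nerve roots, irregular lesion margins,
multi-vertebra anatomy, CT intensities. Passing tests on the phantom show
the pipeline's physics and optimization behave correctly on a
vertebra-scale heterogeneous geometry; they do not certify dosimetry for
any real patient anatomy.

## Light sources

* **Cut-end fibre** (400 µm core, NA 0.22): launch positions uniform on the
  core disc; directions uniform in solid angle inside the acceptance cone of
  half-angle asin(NA/n_tissue) about the fibre axis. NA is defined in air,
  so the in-tissue cone (≈8.1° in bone-like tissue) is used — standard fibre
  optics; the sources give no in-tissue prescription.
* **Cylindrical diffuser** (500 µm radius): positions uniform along the
  lateral surface (uniform power per unit length, matching the mW/cm
  convention for such devices), Lambertian directions about the outward
  radial normal; end caps dark. Diffuser length is never published; the
  default spans the lesion long axis minus a 4 mm margin.

Default placements encode the described geometry qualitatively — four
fibres around the lesion centroid at 45° to the anterior direction, tilted
away from the cord, or two parallel diffusers symmetric about the centroid —
and every emitter is checked to lie inside the lesion. Exact coordinates are
config-overridable; fibre-position optimization is out of scope (positions
are fixed inputs).

## Monte Carlo transport

Weighted photon packets on the labelled voxel grid: free path sampled as
−ln ξ/μ_t of the current tissue; at each interaction the weight is reduced
by the single-scatter albedo and the direction resampled from the
Henyey–Greenstein phase function (inverse CDF); fluence is scored with the
track-length estimator Σ w·ℓ / V_voxel per unit launched energy, which has
much lower variance than absorption scoring in low-μa bone. At voxel faces
where the refractive index changes (including tissue–air at the outer
boundary, n_air = 1), unpolarized Fresnel reflection or Snell refraction is
applied using the axis-aligned face normal. Packets below weight 10⁻⁴ play
Russian roulette with survival probability 1/10; packets entering air or
leaving the grid are tallied as escaped and not re-entered (the outer
muscle boundary is convex, so re-entry is negligible).

Implementation: a single-threaded numba kernel with an inline xorshift128+
generator (seeded via splitmix64 from a 31-bit batch seed) and
rejection-sampled azimuths. Identical `RNGSpec` (master seed, stream) gives
bit-identical kernels. Packets are traced in batches (default 10); the
batch-to-batch spread provides the per-voxel relative-standard-error map.
The weight ledger (absorbed + escaped − net roulette creation = launched)
closes to float precision by construction and is asserted in tests; the
physical statement — absorbed + escaped = launched in expectation — is
verified to 10⁻⁶ over 20 seeds × 50 000 packets.

Validation oracle: the diffusion-approximation point source,
φ(r) = e^{−μ_eff r}/(4πDr) with D = 1/(3(μa + μs(1−g))),
μ_eff = √(μa/D). Agreement within 15% over r ∈ [2, 8] mm holds for bone at
both wavelengths (<2% deviation) and muscle at 690 nm (≤5%). For muscle at
565 nm the oracle itself is outside its validity domain (μs′/μa ≈ 2.3):
the true transport solution decays more slowly than the diffusion μ_eff,
and the measured MC/diffusion ratio grows from 0.93 at r = 2 mm to 1.47 at
r = 8 mm regardless of packet count. The code warns whenever the closed
form is evaluated with μs′ < 10 μa; the corresponding validation case is
kept in the suite as a faithful record of the oracle's breakdown.

Default packet counts: 10⁶ per source is the recommended production
setting; the shipped validation and example runs use 2×10⁴–10⁵ per
medium/source (with shell averaging for radial profiles), which keeps
statistical noise at the few-percent level appropriate to the 15% and
directional acceptance bands.

## Plan optimization

Dose is linear in per-source energies, d_i = Σ_j K_ij E_j, so planning is a
linear program over E ≥ 0.

**Coverage mode.** Inner LP (slack formulation): minimize
Σ_OAR w_oar·max(0, d_i − Φ_oar) + w_t·Σ_tum max(0, Φ_tum − d_i). An outer
geometric bisection on the tumour weight w_t raises/lowers coverage until
the full-grid tumour coverage (fraction of tumour voxels with d ≥ Φ_tum)
lands in [target, target + 0.002]. Among iterates meeting the target the
plan with minimal cord damage, then minimal total energy, is kept; if
coverage still overshoots the band (e.g. when OAR penalties are inactive),
all energies are scaled down uniformly until coverage just meets the target
— dose overshoot beyond the prescription serves no purpose and only damages
normal tissue. If the target is unreachable at the weight upper bound
(possible only when part of the tumour receives zero kernel), the plan at
the bound is returned flagged `coverage_reached = False`.

**Sparing mode.** Maximizes the concave coverage surrogate
Σ_tum min(d_i, Φ_tum) subject to hard per-voxel constraints
d_i ≤ Φ_cord·(1−10⁻⁶) on *all* cord voxels — the relative margin keeps
boundary-active voxels strictly below threshold, so reported cord damage is
exactly zero by construction. E = 0 is always feasible. A soft-penalty
variant (`cord_constraint="soft"`) replaces the hard rows with a large
one-sided penalty, for exploring near-zero rather than zero cord damage.

Degenerate optima are resolved lexicographically with tiny objective terms
(≈10⁻⁶ of the objective scale on total energy, one tenth of that on the
peak per-source energy). The peak term selects the balanced allocation on
symmetric geometries and reflects real per-fibre power limits. OAR voxels
may be subsampled by uniform stride for LP size control (default cap 4000
voxels per tissue, penalty reweighted by the subsampling factor, cord
constraints in sparing mode always on the full grid); achieved coverage and
damage volumes are always recomputed on the full grid. Default OAR weights:
cord 1.0, bone 0.05, muscle 0.05 — the cord is the organ at risk; bone and
muscle penalties are small regularizers.

The exact objective and weight schedule of the original planning software
are not published; this formulation is a convex, auditable stand-in that
reproduces the described behaviours (automatic tumour-weight adjustment;
a near-zero-cord-damage palliative mode) and is checked against exhaustive
search on a toy problem to 10⁻³.

## Evaluation

DVHs are cumulative volume-fraction-at-or-above-dose curves on a linear
grid (512 bins by default, plus one bin past the maximum so the curve ends
at 0), exported as two-column CSV. Damage volumes are voxel counts at or
above threshold times voxel volume; tumour coverage is the damaged tumour
fraction. Treatment time is total energy / (linear power density × total
emitting length), with the diffuser length an explicit argument (it is not
published). Dose maps export as float32 NIfTI with optional binary
iso-threshold masks; label volumes and kernels also use NIfTI (with a JSON
sidecar for kernel metadata).

## Validation problem sizes

The shipped test suite runs, on one CPU in a few minutes: phantom volume
fidelity at 1 mm pitch; transport-vs-diffusion at 2×10⁴–10⁵ packets per
medium on 51³ grids; conservation over 20×5×10⁴ packets; optimizer checks
against brute force and closed forms; and the two-wavelength headline
comparison on the default phantom at 2 mm pitch with 5×10⁴ packets per
fibre. These sizes are the package's validation defaults; production
planning runs should use the 1 mm pitch and ≥10⁶ packets per source and
scale timings accordingly.

## Known limitations

- Binary threshold dose model only; thresholds carry substantial preclinical
  uncertainty, and absolute energies/damage volumes inherit it. Relative and
  directional findings (cross-wavelength trade-offs) are robust to a common
  threshold rescaling.
- Voxel geometry (no tetrahedral mesh); interface normals are axis-aligned,
  which slightly staircases oblique refraction at n-mismatched boundaries.
- The diffusion oracle is only meaningful in scattering-dominated media (see
  above).
- Blood-content-dependent absorption variation, photobleaching, two-
  wavelength combination plans and fibre-position optimization are out of
  scope.
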