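# Methods

This note documents the models, parameter choices and numerical
decisions behind `strokebbb`, and what the synthetic-data validation
does and does not establish.

## Pharmacokinetic model

Contrast leakage across the BBB is modelled as unidirectional transfer
from plasma into an extravascular compartment (no back-flux over the
~4.6 min acquisition):

    C_t(t) = Ki · ∫₀ᵗ C_p(τ) dτ + v_p · C_p(t)

with `Ki` the influx (permeability) constant and `v_p` the plasma
volume fraction. Dividing by `C_p` gives the Patlak linearization; the
slope and intercept are estimated by ordinary least squares over frames
after bolus arrival with `C_p` above a positivity floor (0.1 % of the
peak). The cumulative integral uses the trapezoid rule on the 9 s frame
grid — the same discretisation as the forward simulator, which is why
noise-free round trips are exact to machine precision rather than
merely accurate. `Ki` (min⁻¹) is reported as the permeability–surface-
area product `KPS = Ki·100/ρ` in mL/100 g/min with tissue density
ρ = 1.0 g/mL by default (configurable; ρ is a convention, not a fitted
quantity).

Bolus arrival (`fit_start`) is the first frame where the input function
exceeds its baseline mean + 3 SD, falling back to the frame after the
baseline block for noise-free curves. Negative fitted slopes are kept
(clamping would bias ROI means upward) and surfaced as a QC count. The
venous input is used as-is, with no delay or dispersion correction:
arterial and capillary concentrations are assumed sufficiently similar,
which is the standard operating assumption for this model in acute
stroke.

## Signal model and conversion

The dynamic sequence is a spoiled gradient echo (TR 5.9 ms, TE 1.5 ms,
FA 20°, 31 volumes at 9 s). Signal relates to the longitudinal rate by

    S = s₀ sin α (1 − E₁)/(1 − cos α E₁),   E₁ = exp(−TR·R1),
    R1(t) = 1/T1₀ + r₁·C(t)

The conversion to concentration inverts this equation exactly: the
per-voxel proton-density scale is estimated from the pre-bolus baseline
(first 5 frames by default) and an *assumed* T1₀, because no T1 map is
acquired in the acute stroke setting. Defaults: blood T1 800 ms (fixed
for all subjects), tissue T1 1000 ms (configurable — the dominant
systematic in this pipeline), gadodiamide relaxivity r₁ = 4.3 s⁻¹mM⁻¹
at 1.5 T. Signals outside the invertible SPGR range are clamped to the
range edge and flagged; inversion negatives from noise are clamped to
zero, which introduces a small positive bias in low-enhancement voxels
at low SNR (visible as a few-percent overestimate of background KPS at
SNR 20; the lesion ROI, with its stronger enhancement, stays within a
few percent of truth). A linear relative-enhancement mode
(`signal_model="linear"`, ΔR1 = R1₀·ΔS/S₀) is provided for comparison
with cruder pipelines.

The input function is the mean sinus signal converted at blood T1 and
divided by (1 − Hct), Hct = 0.45 by default; Hct = 0 disables the
plasma correction.

## ADC, lesion and contralateral ROIs

ADC is the two-point log decay at b = 1000 s/mm². Voxels with
non-physical decay (S_b ≤ 0 or S_b > S₀, possible under noise) get
ADC = 0, are excluded from ROI statistics, and are counted in QC. The
lesion is segmented as voxels below 0.85 × a normal-tissue reference
mean (whole-brain valid-voxel mean by default), keeping the largest
26-connected component; the explicit relative threshold replaces the
manual ROI placement of clinical practice with a reproducible rule. The
contralateral homologue is the voxelwise reflection across the
midsagittal plane (grid centre of the left–right axis, configurable
offset); reflection is an exact involution on the lattice, lesions
straddling the midline are rejected with a voxel count.

## Registration

Diffusion-to-dynamic alignment is a single global affine (12 parameters:
translation, rotation, scale, shear; 6 or 9 selectable) maximizing the
mutual information of a 32-bin joint histogram, binned over each
volume's 1st–99th percentile range with out-of-range values clipped to
the edge bins. The optimizer is Nelder–Mead over a staged schedule:
rigid parameters over a smoothing pyramid (Gaussian σ = 2, 1, 0 voxels)
followed by full-affine refinement at native resolution with shrinking
simplex steps and a final small-step polish. Two numerical findings
shaped this design: (i) decimated pyramid levels starve the histogram
of samples and let the interpolation-blur penalty on the moving image
outweigh the alignment signal, biasing rotations toward zero — hence
smoothing without decimation; (ii) a cold-started 12-parameter simplex
reliably stalls off-optimum — hence rigid-first staging. Masks are
resampled nearest-neighbour (binary in, binary out); intensity volumes
trilinearly. Transforms live in world coordinates (mm, RAS) and map
fixed coordinates to moving coordinates.

## Synthetic phantom

The phantom is the smallest geometry that exercises every stage:
a 64×64×16 grid (3.75×3.75×5 mm voxels), an ellipsoidal brain, one
spherical lesion (default radius 5 voxels) placed 10 voxels off the
midline, and a small para-midline posterior sinus slab carrying whole-
blood signal. Defaults encode an acute ischemic lesion: ADC
6.0×10⁻⁴ mm²/s against 8.5×10⁻⁴ background, lesion KPS 1.0 against
0.5 mL/100 g/min background, v_p = 0.03. The bolus is a mode-normalised
gamma-variate (peak 5 mM plasma concentration — a free parameter with
no clinical anchor — arriving at 45 s, α = 2.5, τ = 6 s) plus a
recirculation plateau (15 % of peak, 80 s washout). A smooth seeded
proton-density texture (±15 %, σ = 2.5 voxels) multiplies all signals;
it cancels exactly in the ADC log-ratio and the baseline-normalised
SPGR inversion but gives the MI metric intensity structure away from
edges, without which registration of a piecewise-constant phantom is
ill-posed. Noise is additive Gaussian on magnitude signal (the
high-SNR approximation of Rician noise); "SNR 20" means σ = baseline
tissue signal / 20. All randomness flows from one seed; identical
seeds give bit-identical volumes.

What the phantom does **not** emulate: realistic anatomy, motion,
partial-volume effects, T1 heterogeneity across tissue, B1/coil
inhomogeneity, or scanner-specific artifacts. Passing phantom tests
therefore demonstrates the *estimator chain* is correct and noise-
stable, not that the pipeline is robust to everything clinical data can
present.

## Synthetic cohort

The cohort generator draws per-patient measures from per-phase
distributions with group sizes 20/11/11 (hyperacute/acute/subacute) and
an optional 7-patient HT subgroup with roughly doubled permeability,
scanned only in the hyperacute window. Three design choices matter:

* **Moment matching.** Draws are truncated at zero for physical
  non-negativity, but naive truncation shifts the mean; the underlying
  normal parameters are therefore solved so the *post-truncation*
  mean/SD equal the requested values. Lesion volume, whose requested
  coefficient of variation exceeds 1 (impossible for a lower-truncated
  normal, whose CV tops out at the exponential limit), uses a
  moment-matched lognormal — also the natural shape for volumes.
* **Within-patient coupling.** Infarct and contralateral measures are
  coupled through a Gaussian copula with rank correlation 0.9. The
  marginals alone do not determine this; the value is derived from the
  reported significance of paired infarct-vs-contralateral comparisons
  in acute-stroke permeability cohorts, which bounds the SD of paired
  differences well below what independent draws would give (implied
  correlation ≳ 0.8–0.86 given the marginal SDs). Without the coupling
  the generated cohorts would lack the paired structure the analysis
  is designed to exploit.
* **Onset times** are uniform within each phase window (1.3–6, 6–48,
  48–90.7 h), and the stored phase label is recomputed from the drawn
  time so the table always satisfies the phase-assignment invariant.

A note on power: with the acute phase's large infarct-KPS SD (0.69
against a contralateral SD of 0.14), the SD of paired differences is
bounded below by their difference for *any* joint distribution with
those Gaussian marginals, which caps the acute-phase paired-t
noncentrality near 2.6. Single cohorts can and do reach very small
paired p-values, but no generator faithful to these marginals can make
p < 0.005 a near-certain event in that phase; the replicate-level
validation therefore targets the group-mean orderings (infarct above
contralateral everywhere; ratio peaking in the acute phase), which are
stable properties of the generating distributions.

## Statistics

ANOVA is the classical equal-variance one-way test; variance
heterogeneity across phases is surfaced through a Levene diagnostic
rather than by switching to Welch, keeping the primary test the one
named in standard practice. Tukey follow-ups use the Tukey–Kramer
studentized-range procedure (valid for unequal group sizes). Paired
comparisons are two-tailed Student t-tests; zero-variance differences
are flagged explicitly instead of being reported as p = 1. SDs are
sample SDs (n − 1). Missing values are excluded per measure with a
logged count. Implementations are scipy-backed; the test suite checks
them against base R (`aov`, `TukeyHSD`, `t.test`) to 10⁻⁶ on
randomized fixtures.

## Problem sizes and determinism

Validation runs use the default 64×64×16 phantom (~29k brain voxels,
31 frames), a ~200-voxel lesion for the noise study, 100 randomized
fixtures for the statistics cross-check and 200 seeded cohort
replicates for the pattern checks — sizes chosen so the full suite and
the acceptance script each complete in minutes on one CPU while keeping
Monte-Carlo uncertainty well inside the asserted margins. Every random
draw descends from an explicit seed; reruns of any pipeline stage with
the same configuration are byte-identical, and each output directory
carries a provenance JSON (config hash, seed, package version, QC
counters) sufficient to reproduce it.

## Known limitations

* Fixed assumed T1s propagate directly into concentration scale; there
  is no T1 mapping.
* The single global affine has no local refinement; it is adequate for
  same-session intra-subject alignment, not inter-subject work.
* The Patlak model ignores back-flux; it underestimates permeability
  when efflux is appreciable within the scan window.
* The segmentation threshold (0.85 × reference) is a pragmatic stand-in
  for expert ROI placement and has no claim to clinical optimality.
* Gaussian (not Rician) noise; invalid at low SNR magnitudes.
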