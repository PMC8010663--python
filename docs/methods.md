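# Methods

## Forward model

The simulator integrates the Bloch–McConnell equations for water plus N
dilute solute pools. Per pool the state is (Mx, My, Mz); the system matrix
couples transverse relaxation, off-resonance precession at
`2π(δᵢ·larmor − Δ_rf)`, the CW saturation field `ω₁ = 2π·γ·B1` about x,
longitudinal relaxation, and two-site exchange with water under detailed
balance (water→solute rate `fₛ·kₛ`, solute→water rate `kₛ`, with
`fₛ = [solute protons]/[water protons]`, water = 111 M protons). The affine
system `dM/dt = AM + b` is propagated exactly over each interval with the
matrix exponential. Ill-conditioned systems (condition number above 1e14,
e.g. nonsensical exchange rates) raise `SimulationError` instead of
returning silent garbage.

**Acquisition cycle.** Each repetition is modeled as: readout that spoils
all magnetization to zero → free recovery for `TR − t_sat` → CW saturation
for `t_sat` at the offset of interest → readout of water |Mz|. The cycle is
iterated to its periodic steady state (fixed-point tolerance 1e−8; with a
fully spoiling readout the cycle is memoryless and converges at the second
iteration — the iteration is kept so partial-spoiling readouts can be added
without changing the contract). This cycle is what gives the TR series its
meaning: longer TR leaves more recovery time before saturation, raising
MTRasym exactly as observed in the phantom optimization series. The
reference S0 is produced by the *same* cycle with saturation applied at the
10 kHz reference offset, not by switching saturation off.

**Magnitude detection.** On-resonance nutation can leave a transiently
negative water Mz at readout; magnitude images cannot carry a sign, so the
readout takes |Mz|. This keeps noise-free Z-spectra within [0, 1].

**pH dependence.** Hydroxyl exchange is base-catalysed in this regime:
`k(pH) = k_ref · 10^(pH − pH_ref)`.

## Frozen parameter set

All defaults live in `src/glucocest/data/defaults.yaml` and are used by
every simulation; none are adjusted per experiment.

| parameter | value | rationale |
|---|---|---|
| larmor | 7 T × 42.577 MHz/T = 298.04 Hz/ppm | the acquisition field |
| glucose pool | +1.2 ppm, 5 protons/molecule | single effective hydroxyl pool; the analysis evaluates one asymmetry point (0.9 ppm), so the five OH resonances are lumped at their effective weighted shift |
| glucose k_ref (pH 7.4) | 2500 s⁻¹ | within the literature range for glucose hydroxyls; uniquely among candidate rates it reproduces the full set of printed phantom behaviors — the ~10% effect at pH 7.4 *and* the monotone decrease of the effect from pH 6.4 to 8.4 under the base-catalysed law (slower rates put pH 6.4 below the slow-exchange optimum and invert that ordering; faster rates collapse the pH 7.4 effect) |
| glucose T1/T2 | 1.0 s / 10 ms | literature-scale solute relaxation |
| water (phantom) | T1 3.0 s, T2 1.0 s | PBS + 1% agarose; the agarose semisolid MT pool is omitted — its broad component is symmetric at the analysis offset and outside the asymmetry analysis |
| water (in vivo) | T1 2.0 s, T2 60 ms | rat brain parenchyma at 7 T |
| metabolite presets | Cr +1.9, Glu +3.0, GABA +2.75, Cho +0.9 ppm | literature-default shifts/rates for the selectivity phantom; implementation defaults, not measured values |

Two model-physics limits are worth stating. First, MTRasym is near-linear
in concentration only in the dilute regime (deviation <10% up to ~12.5 mM);
by 100 mM the effect saturates (23% rather than a linear 40%), which is what
the printed 10→25% range itself shows. Second, with any exchange rate that
also yields ~10% at B1 = 1.5 μT, the B1 response at 0.9 ppm peaks near
2.5–3 μT and declines mildly by 4 μT from direct-water-saturation spillover;
the package therefore asserts the robust qualitative facts (net rise from
1.5 to 4 μT, monotone upfield shift of the asymmetry-curve peak) rather than
pointwise monotonicity of the interior of that series.

**t_sat sweeps.** The phantom protocol fixes TR = 5.04 s while sweeping
t_sat up to 6 s, which a cycle with `t_sat ≤ TR` cannot represent. The sweep
therefore holds the *recovery interval* `TR − t_sat` fixed and lets TR move
with t_sat; this isolates the saturation-duration effect without starving
the recovery segment.

## Z-spectrum processing

- Normalization divides by the reference signal and sorts offsets; values
  above 1.05 are flagged as suspect.
- **B0 estimation** fits a cubic spline to the spectrum within ±150 Hz of
  water and takes the minimum on a 1 Hz grid. The window is deliberately
  narrow: the symmetric direct-saturation dip dominates there, while wider
  windows let solute CEST shoulders bias the minimum by several Hz. With
  noise-free spectra the default (interpolating) spline recovers injected
  shifts in {−90…+90 Hz} within ±2 Hz; per-voxel use on noisy data should
  pass a positive smoothing budget.
- **B0 correction** resamples the measured spectrum at `offset + shift` by
  cubic spline; grid points whose source falls outside the measured support
  are marked invalid, never silently zeroed.
- **MTRasym(0.9 ppm)** is evaluated by cubic-spline interpolation to exactly
  ±0.9 ppm (±268.2 Hz) — the 30 Hz acquisition grid does not contain that
  offset, so nearest-sample evaluation is rejected by design.
- The voxelwise map evaluates the corrected value in a single interpolation
  (the measured spectrum read at `±0.9 ppm + shift`), which is numerically
  equivalent to resample-then-evaluate but avoids compounding two splines;
  voxels with non-positive S0, non-finite data or out-of-support shifts are
  masked with an explicit validity flag.

## Dynamic enhancement

GCE uses the post − pre convention: `mean(map@inf40, map@post10) − baseline`,
so glucose uptake is positive and reduced uptake in the AD group appears as
reduced GCE (a `sign="pre-post"` flag flips it). ROI time courses report
baseline-subtracted and raw ROI means; bilateral structures are analyzed as
L∪R unions with per-side values also available.

## DTI

With exactly six directions the log-linear system is square, so the
noiseless fit is exact by construction. ADC = trace/3 from the fitted
tensor; FA is computed after clamping negative eigenvalues (noise artifacts)
to zero. Voxels with any non-attenuating direction (Sᵢ ≥ S0) or non-positive
signal are excluded rather than partially fitted, matching the simple map
computation the pipeline feeds.

## Synthetic cohort generator

The generator emulates the study design the analysis stages were built for:
two groups of 6 animals, seven infusion timepoints (0, 10, 20, 30, 40 min
infusion; +10, +20 min post), 61 offsets (−900…+900 Hz, 30 Hz step), B1
1.5 μT, t_sat 5 s, TR 6 s.

- **Uptake curves** (ΔMTRasym at 0.9 ppm): control rises to a 0.03 plateau
  and holds (homeostatic uptake); AD rises to a lower 0.012 plateau and then
  declines below baseline late in the infusion, with its minimum at the
  40-min timepoint. Baseline MTRasym is 0.05 for both groups by default (an
  elevated AD baseline is configurable but off by default so recovery tests
  stay clean).
- **Animal effects**: normal random effects (sd 0.005) on baseline and on
  the plateau; the plateau effect scales the whole uptake curve, preserving
  its shape.
- **Voxel synthesis**: each region's target MTRasym is converted to a full
  Z-spectrum through the Bloch–McConnell model — a per-scheme library of
  spectra over a glucose-concentration grid is inverted on its monotone
  concentration→MTRasym curve. MTRasym is a linear functional of the
  spectrum, so the interpolated spectrum attains its target *exactly*, and a
  noise-free cohort is recovered exactly by the pipeline (the basis of the
  round-trip tests). Targets above the achievable ceiling raise an error.
- **B0 and noise**: an optional 2-D polynomial shift field displaces the
  stored spectra (the true field map is carried alongside, as an acquired
  B0 map would be); additive Gaussian noise on the normalized images
  (default sd 0.002, the >20 SNR regime where the Rician floor is
  negligible). All randomness flows from one seed; CEST, DWI and metabolite
  streams are split so omitting one block does not perturb the others.
- **Myo-inositol link**: mI = α + β·GCE_true + ε with α = 4 mM, β = 40
  mM per GCE unit, and ε calibrated by default so the *population* R² of
  the link equals 0.626; the R² acceptance check then asks that the
  sampling distribution at n = 10 covers that value, not that any single
  draw reproduce it.
- **Problem sizes**: the default grid is 32×32 (configurable to the 64×64
  acquisition matrix); spatial resolution only dilutes ROI voxel counts and
  is kept modest so that replicate-heavy statistical checks (200-cohort
  power runs) remain cheap. DWI ground truth is an axially symmetric tensor
  with ADC 0.8×10⁻³ mm²/s and FA 0.3 at b = 1031 s/mm².

What the generator does **not** emulate: anatomically realistic rat
geometry, arterial glucose kinetics (uptake curves are imposed, not driven
by an input function), motion, B1 inhomogeneity, and Rician noise floors at
low SNR. Passing tests therefore demonstrate the correctness of the
processing chain and the statistical machinery under the declared model —
not robustness to those acquisition artifacts.

## Statistics

Comparisons mirror the small-sample decision flow: optional 1.5×IQR
screening per group (the reproducible surrogate for graphical stem-and-leaf
inspection; removal is opt-in and the removed ids are logged), Shapiro–Wilk
per group and Levene's test (center = mean, mirroring SPSS) gating at
α = 0.05 into a pooled-variance two-sided t-test, otherwise a two-sided
Mann–Whitney U (exact when untied, normal approximation with tie correction
otherwise). Two groups of all-equal values are reported as an explicit
degenerate result rather than a test. Tests are two-sided throughout; no
multiple-testing correction is applied, matching the analysis this package
reproduces. Regression is ordinary least squares with the two-sided slope
p-value.

## Numerical choices

- Matrix exponentials via scipy's scaling-and-squaring; steady states via
  direct solve of `AM = −b` with a condition-number guard at 1e14.
- Cubic splines (not-a-knot) for all spectral interpolation; linear spectra
  are reproduced exactly, which the tests exploit to build stacks with
  exactly known MTRasym.
- The evolution is verified against an independent implicit Radau
  integration as between-offset signal ratios (the 10 kHz reference leg
  precesses ~3×10⁵ cycles over t_sat and cannot be time-stepped at oracle
  accuracy; it cancels in ratios and is instead covered by the closed-form
  steady-state oracle, which includes the reference).
- Reproducibility: every generator entry point takes a seed or Generator;
  identical seeds produce byte-identical on-disk cohorts (uncompressed
  NIfTI, fixed headers).

## Known limitations

Pulsed saturation trains, semisolid MT/NOE pools, B1 correction,
temperature dependence and multi-site glucose pools (a 3-site variant is a
natural extension of the preset table) are out of scope. The B1 series'
interior non-monotonicity discussed above is a genuine property of two-pool
CW saturation, not an implementation artifact.
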