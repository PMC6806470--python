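# Methods

This package simulates how intrafraction prostate motion degrades clinical
target volume (CTV) dose coverage under two passive proton delivery
techniques — double scattering (DS) and uniform scanning (US) — and how
fractionation washes that degradation out. Everything is self-contained:
the beam, the target and the motion cohort are synthetic models whose
parameters are documented here.

## Beam model

**Pristine peak.** A planning system's per-layer dose matrices are replaced
by an analytic pristine Bragg peak: a constant entrance plateau that rolls
off (erfc) just proximal of the peak, plus an asymmetric Gaussian peak with
proximal sigma equal to `peak_width_gcm2` (default 0.6 g/cm²) and distal
sigma half of it, reflecting the sharp distal edge of real peaks. The
plateau mixing weight is solved numerically (Brent root-finding) so the
entrance-to-peak dose ratio equals `entrance_ratio` (default 0.35) exactly.
Depths are water-equivalent (homogeneous 1 g/cm³ medium, 10 mm ≡ 1 g/cm²),
a reasonable idealisation for lateral prostate beams with a rectal balloon,
where no sharp range perturbations sit in the beam path.

**Energy layers.** A field with range *R* and modulation width *M* is
decomposed into `ceil(M / spacing)` layers whose ranges step proximally by
`spacing_gcm2` (default 0.6 g/cm², so the clinical 8.4 g/cm² modulation
yields 14 layers). The layer count uses a 1e-9 relative guard because
8.4/0.6 is slightly above 14 in binary floating point.

**SOBP weights.** Per-layer weights are solved by nonnegative least squares
against a flat 100% target on a 0.1 g/cm² depth grid over `[R − M, R]` —
deterministic and reproducible. The solver reports the achieved flatness
and raises if it exceeds `flatness_tol`. The clinical 14-layer field is
flat to better than 2%; short modulations (few layers) carry a physically
real proximal-shoulder dip and need a looser tolerance. The distal layer
always receives the largest weight.

**3D dose grids.** Per-layer grids are separable: the pristine depth-dose
along the beam axis times a lateral fluence that is flat inside the
aperture (the beam's-eye-view CTV ellipse expanded by `aperture_margin_mm`,
default 10 mm) with an error-function penumbra of 80–20 width
`penumbra_80_20_mm` (default 6 mm). The SOBP is anchored so the distal
layer's range falls `distal_margin_mm` (5 mm) beyond the CTV, with the
modulation reaching at least `proximal_margin_mm` (10 mm) upstream.
LAO/RAO fields are modelled as pure lateral ±x beams; their clinical
obliquity of up to ~10° is ignored. Grids are 1 mm isotropic by default,
centred on the CTV so the CTV centre is an exact lattice point.

**Normalisation.** Doses are percent of the fraction prescription, with the
composed beam scaled to 100% at the CTV centre. One consequence: the SOBP
ripple (±1–2%) straddles exactly 100%, so V100 of the static plan is a
knife-edge statistic (a voxel at 99.9% counts as a miss). Clinical plans
are typically normalised "hot" (plan D95 above prescription), which is why
published V100 values sit near 100%. V110, V95 and the D-metrics are
unaffected by this convention; analyses of technique differences here lean
on those.

## Motion model

Traces emulate 10 Hz electromagnetic-transponder tracking over 4–10 min.
Each trace is a sum of four components in (LR, SI, AP) coordinates:

- **drift** — linear, `rate × t`, the slow posterior/inferior prostate
  wander seen clinically;
- **persistent offset** — a sigmoid-onset step (onset uniform in
  0.15–0.55 of the trace, time constant 8 s) sustained to trace end;
- **transient excursions** — Poisson-counted raised-cosine pulses
  (default duration 25 s) that return to baseline;
- **jitter** — white high-frequency noise.

All random vectors share a correlation structure with corr(SI, AP) = 0.6,
reproducing the strong positive SI–AP coupling of real prostate motion.
Traces are endpoint-inclusive (a 300 s trace at 10 Hz has 3001 samples), so
a pure drift reaches exactly `rate × duration` at the last sample.

**Cohort sampler.** The cohort generator is parameterised directly by the
target systematic components Σ = (0.3, 0.5, 0.6) mm and random components
σ = (0.7, 1.4, 1.9) mm in (LR, SI, AP) — the estimator conventions are:
systematic = SD across patients of the per-patient mean displacement;
random = RMS of per-patient displacement SDs. Internally these targets are
mapped to mechanism scales by inverting first-order variance expressions
(variance shares: drift 0.35, persistent 0.30, excursions 0.25, jitter
0.10 of σ²; systematic split 0.4 drift / 0.6 persistent), with a shrink
factor on the patient-level biases that cancels the finite-fraction
inflation of the systematic estimator in expectation. Per-patient motion
character (an activity multiplier, lognormal with E[a²] = 1, plus drift and
offset biases) is drawn once and reused across that patient's fractions
with per-fraction noise, giving the within-patient consistency real
cohorts show. With 17 patients × 14 fractions of 300 s the estimators
recover the targets to within ~6% when averaged over 20 seeds (per-seed
scatter at n = 17 is large, hence the 35% test tolerance); the fraction of
patients spending ≥10% of tracked time beyond 3/5/7 mm (3D) averages about
11/2.7/0.7 of 17, close to the 9/3/1 pattern of real cohorts. This was
treated as a soft calibration check, not an assertion.

Seeding uses `numpy.random.SeedSequence(seed)` spawned per patient and per
fraction, so any single trace is reproducible in isolation.

**What the generator does not emulate:** transponder measurement noise and
dropouts, prostate rotation or deformation (motion is rigid translation),
interfraction setup error, and any coupling between motion and the
treatment (e.g. couch corrections). Passing tests therefore demonstrate
correctness of the pipeline under a rigid-translation motion model with
realistic second-order statistics, not fidelity to any individual patient.

## Delivery and 4D accumulation

Timelines start with a 25 s pre-beam delay (target moves, no dose). DS then
delivers the whole SOBP continuously for `fraction_dose / dose_rate`
(60 s for 2 Gy at 2 Gy/min): the rotating modulator sweeps all energies
every 0.1 s (600 RPM), so the per-second dose matrix is the composed beam
rescaled to one second; the sub-second modulator phase is deliberately not
resolved. US delivers layers sequentially, distal to proximal, each for a
time proportional to its weight (constant beam current at fixed dose rate —
the delivery system's layer timing rule is not public, and
MU-proportionality is the natural constant-current model), separated by
0.5 s beam-off switching gaps: 7.25 Gy across 14 layers spans
217.5 + 13×0.5 = 224 s. For the 2 Gy arm the same arithmetic gives
25 + 60 + 6.5 = 91.5 s; published descriptions quote "the first 91 s" of
trace, a 0.5 s bookkeeping discrepancy we resolve in favour of the explicit
schedule.

Accumulation follows the per-second sum
`D_CTV(v) = Σ_t d_t(v + u(t))`: traces are down-sampled to 1 Hz by
per-window arithmetic means (unbiased and noise-suppressing; plain
decimation would alias the jitter), the CTV voxel lattice is rigidly
shifted by the displacement of second *t*, and the active source grid is
sampled by trilinear interpolation. Seconds straddling segment boundaries
apportion dose by exact sub-second overlap, keeping the 224 s schedule
exact at 1 s resolution. A shifted voxel leaving the grid is an error, not
a zero-fill — the grid pad (default 25 mm) must cover the largest credible
motion.

Courses deliver one field per fraction, alternating LAO/RAO starting with
LAO (for 14 fractions: 7 + 7; for the 5-fraction SBRT arm: 3 LAO + 2 RAO,
an ordering chosen here since no convention is published). Each fraction
delivers its full prescription through its single field; the course dose is
the voxelwise mean of per-fraction percent doses, i.e. percent of the total
prescription.

## DVH metrics

Cumulative DVHs are computed on the equal-volume CTV samples with a
0–130% level grid in 0.1% steps and closed-inequality counting (a voxel at
exactly the level counts as receiving it). V100/V95/V110 are volume
percentages at those dose levels. D100/D95/D5 are exact order statistics on
the samples (dose at descending rank `ceil(y/100 · n)`), not inversions of
the discretised curve, removing binning artifacts; the curve is kept for
plotting. Hot and cold screening follows V110 > 2% and D95 < 95%.

## Cohort comparison

Every patient shares one beam/CTV geometry, isolating intrafraction motion
from planning variability. The identical down-sampled trace drives both
techniques for each (patient, fraction) — verified by content hashes in the
run manifest — so DS-vs-US tests are two-sided *paired* Student t-tests by
default (unpaired is available); no multiple-testing correction is applied
across the six metrics, and the significance threshold (0.05) is
configurable. Zero-variance zero-mean differences return p = 1 by
convention. Summary tables report Mean/STD/Max/Min per metric and
technique at the single-fraction and course level for both fractionation
arms (2 Gy × 14 and 7.25 Gy × 5 SBRT).

The fraction-averaging property — course-level STDs no larger than
single-fraction STDs — is asserted on records pooled across five cohort
seeds rather than seed-by-seed: for metrics that are nearly
motion-insensitive (DS D5 in particular) the two spreads are equal up to
sampling noise, so only the pooled estimator makes the ordering
well-posed. In the high-motion interplay check, V100 is excluded from the
course-convergence comparison for the normalisation reason above.

## Numerical choices and problem sizes

- Trilinear interpolation throughout (`scipy` RegularGridInterpolator);
  out-of-grid is an error.
- NNLS weight solving on a 0.1 g/cm² grid; weights re-normalised to sum
  to 1 within 1e-9.
- CTV sampled at 2 mm in the default configuration (~5900 voxels for the
  50 × 40 × 45 mm ellipsoid); tests use a smaller 8-layer field (range 16,
  modulation 4.8 g/cm²) with 4 mm CTV sampling and 2 mm grids where the
  property under test is scale-free, and the full clinical field where the
  study conditions matter. Full-cohort test runs use five seeds of the
  17 × 14 default study.
- Zero-weight layers produce zero-duration timeline segments (logged, not
  errors).
- Ties at DVH thresholds count as received; D-metrics reject volume
  percentages outside (0, 100].

## Known limitations

- The analytic beam has no nuclear halo, no heterogeneity, no range
  uncertainty, and margins stand in for aperture/compensator hardware;
  absolute DVH values are therefore not comparable to planning-system
  output, only the DS-vs-US contrast and its motion dependence are.
- Intra-layer scanning structure (3 Hz / 30 Hz sweeps, repainting) is not
  resolved: each layer is treated as a quasi-instantaneous dose cloud,
  which is adequate when repainting is heavy.
- One field per fraction and rigid translation only; no gating, tracking
  or couch correction.
- The plateau-normalisation makes V100 a knife-edge statistic (see above).
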