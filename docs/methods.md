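# Methods

This note documents the models, algorithms and numerical choices behind
ctdikit: what the synthetic generator emulates, how the automated event
detection works, how normalization and inference are defined, and what
the validation does and does not establish.

## Beat and trace model

A cardiac cycle is tiled by six phases in fixed order: atrial
contraction (AC), pre-ejection (PE), ejection (EJ), post-ejection
(POST), rapid ventricular filling (RF), slow ventricular filling (SF).
Each velocity wave is a raised-cosine (Hann) lobe with compact support:
ejection positive, E and A negative in the canonical sign convention
(clinical reports quote magnitudes only, so the convention is internal).
With the default `wave_width_frac = 0.5` the A, S and E lobes exactly
fill their phases, making every phase boundary an exact zero point of
the waveform — this is what allows the detector to be checked against
ground truth at one-sample resolution.

Default phase fractions are (0.15, 0.05, 0.35, 0.05, 0.20, 0.20) at the
template's nominal heart rate.  These are conventions: published
sources report peak velocities, not phase durations, so the defaults
were chosen once as physiologically plausible values and are exposed in
the template.  Isovolumic spike amplitude defaults to zero; a nonzero
value renders biphasic wiggles in PE/POST but blurs the zero-crossing
boundary definitions, so the one-sample boundary guarantee applies to
the default template.

**Heart-rate compression and E/A fusion.**  The template's fractions
define *absolute* phase durations at its nominal rate.  Rendering at a
higher rate shortens slow filling first (diastasis disappears, as in
real hearts); once slow filling is exhausted, RF and AC compress while
the wave widths keep their nominal absolute durations.  The E and A
lobes then physically overlap and eventually merge into a single
diastolic extremum.  With default parameters the supports first touch
at 175 bpm and the rendered diastole becomes single-troughed by
around 200 bpm; between these the transition is monotone.  Fusion is
therefore a geometric property of the rendered waveform — the ground
truth flags it by counting separated minima in the noiseless diastole,
and the detector must rediscover it from the (noisy) trace.  Because a
fusion event joins beat *k*'s E wave to beat *k+1*'s A wave, both
participating beats are flagged and lose their Am/Em.

Per-beat cycle-length jitter multiplies all durations and widths by a
common factor (truncated Gaussian, coefficient of variation
`beat_jitter_cv`), so jitter alone never creates fusion.  Measurement
noise is additive white Gaussian.  Basal orientation negates the
complete noisy trace, so apical/basal twins are exact negations.  All
wave centers and edges are quantized to the sampling grid; with zero
noise the peak samples equal the template amplitudes exactly.

## Cohort model

Each simulated fetus receives one transfusion with paired exams.  True
z-scores per variable and wall are drawn as
`z = base_z + residual` (residual SD `residual_z_sd`, default 1), with
the Em z-score additionally shifted by
`slope_em_z_per_mom · (1 − Hb MoM)` — the anemia-dependent hyperdynamic
elevation.  Post-transfusion z-scores are
`z_after = z_before + delta + residual`, so the paired-difference noise
SD equals `residual_z_sd`.  Absolute amplitudes come from the reference
model's inverse `mean(GA) + z·SD(GA)`, clipped just above zero with a
warning recorded in the ground truth.  Heart rates are drawn
~N(140.4, 9.1) before and ~N(132.7, 14.4) bpm after; frame rates
~N(207.7, 13.1) truncated at 173 fps; views are apical with
probability 0.43 — the acquisition conditions of the transfusion-cohort
setting the package targets.  MCA PSV MoM is generated as
`1 + 0.8·(1 − Hb MoM)` plus small noise, reproducing its inverse
relation to hemoglobin.

When an exact population rank correlation is needed, setting
`target_rho_em_am` draws (Hb MoM, LV Em/Am z) through a Gaussian copula
with Pearson parameter `2·sin(π·ρ/6)`; both margins are monotone
transforms of the Gaussians, so the population Spearman correlation
equals the target exactly.  The LV Em amplitude is then derived as
ratio × Am.

Note that the values-only mode (`render_traces=False`) consumes the
random stream differently from the rendered mode, so the two modes
produce different (each internally reproducible) cohorts for the same
seed.

## Event detection

1. **Orientation.**  Declared metadata is honored (basal traces are
   negated).  Unknown orientation is inferred from which sign carries
   the widest suprathreshold wave — the ejection wave has the longest
   duty cycle.  Near-symmetric cases raise an error rather than guess;
   deeply fused diastoles can approach this limit, so unknown-orientation
   inference is only guaranteed for unfused morphology.
2. **Beats.**  The global cycle length is the autocovariance maximum
   within 80–220 bpm (fetal physiological band with margin; peak must
   exceed 10% of the zero-lag value).  Ejection peaks are picked at
   ≥45% of the trace's upper velocity envelope with a 0.6-cycle
   minimum separation.  Each beat is anchored at the sub-sample
   half-height crossing of its ejection upstroke; the cycle boundary
   (AC onset) is placed a fixed offset before the anchor — the offset
   is the median anchor-to-A-wave-onset distance over all beats, which
   suppresses per-beat noise — and snapped to the nearest raw zero
   sample.  When the E and A supports overlap without merging, the
   A-wave onset is the trough between the two diastolic minima
   (prominence ≥ 15% of the run depth, minimum separation 8% of the
   cycle).  Heart rate is 60/(mean accepted anchor spacing), which is
   sub-sample accurate.
3. **Phases.**  Beats are resampled to a common length (400 samples)
   and the sample-wise median forms the consensus template; beat
   quality is the Pearson correlation against the template, beats below
   0.6 are excluded from the consensus (and from averaging), and traces
   with fewer than three usable beats are rejected.  Template
   boundaries are the zero crossings flanking the ejection wave, the
   first negative wave after it (RF) and the negative wave opening the
   cycle (AC); PE, POST and SF are the residual intervals.  Per-beat
   boundaries map the template fractions onto the cycle and snap to the
   nearest matching wave-edge zero crossing on the raw samples (radius
   3); each boundary kind has its own sign pattern, exact at a
   compact-support wave edge.  Boundaries are made monotone so phases
   always tile the cycle.
4. **Fusion.**  The diastolic interval from one beat's RF onset through
   the next beat's AC end is fused when it lacks two negative extrema
   whose separating trough has prominence ≥ 10% of the smaller
   extremum.  The 10% threshold is a package convention (exposed in
   config); no published criterion exists.
5. **Cross-segment refinement.**  When ≥ 2 walls of one exam share a
   time base and agree on the beat count, per-beat cycle bounds are
   replaced by the across-wall median and phases re-derived; otherwise
   refinement is skipped with a warning.  Whether clinical wall
   recordings are simultaneous varies by acquisition; the refinement
   assumes they are when given together.

## Metrics and quality policy

Sm/Em/Am are the maximum |velocity| within EJ/RF/AC per beat; fused
beats yield Sm only.  Segment values are arithmetic means over usable
cycles, and Em/Am is the ratio of means (robust when individual beats
lack one peak; for identical beats it equals the per-beat ratio).  No
outlier trimming is applied within a trace beyond the quality filter.

Two omission rules mirror clinical trace review: (i) a mean Am or Em
below 3× the trace's estimated noise floor (robust MAD of first
differences) is omitted as unmeasurable; (ii) at the cohort level an
audit flags |z| > 4 values for inspection and can drop them.  Without
rule (i), exams whose true amplitudes sit near the noise floor produce
rank-scrambling Em/Am errors that visibly attenuate recovered
correlations.

## Normalization and inference

z = (value − mean(GA))/SD(GA) with polynomial curves (degree ≤ 3) over
a declared GA support; Δz = z_after − z_before; MoM = value/median(GA).
Anemia grades use half-open intervals closed on the lower-severity
side (severe < 0.55 ≤ moderate < 0.65 ≤ mild < 0.84 ≤ none), a
convention made explicit because printed interval endpoints overlap.
**The packaged reference curves are synthetic**: linear mean curves
anchored to plausible mid-gestation magnitudes with constant SDs.  They
make z-scores well-defined for simulation and testing but are not a
clinical reference.

Mean z-scores before transfusion get t-based 95% CIs (the CI method is
not fixed by convention; t was chosen), flagged significant when the CI
excludes zero.  Correlations are Spearman's rho with two-sided p.
Paired changes use the Wilcoxon signed-rank test — exact null for
n ≤ 25 without ties, normal approximation with continuity correction
otherwise — reporting the median and IQR of after−before differences,
marked at p < 0.01 in the change tables.  No multiple-testing
correction is applied (matching the p < 0.05 convention of the setting;
a caveat, not a recommendation).  Repeated transfusions per fetus would
be treated as independent in all-transfusion analyses; a
first-transfusion-only switch is the mitigation.

## Validation scope and problem sizes

The test suite and `scripts/acceptance.py` validate against simulator
ground truth: one-sample boundary agreement and machine-precision peaks
on noiseless traces (120–170 bpm, 10 s), peak MAE ≤ 1.5× noise SD and
heart-rate error ≤ 2 bpm at 10%-of-Sm noise over 100 traces, the fusion
sweep 110–210 bpm, exact orientation invariance, z calibration on 1000
draws, Spearman recovery of an imposed −0.8 through the full pipeline
at n = 500 exams (LV wall), and Wilcoxon power (200 replicates at
n = 66, imposed Δz = −0.6) with null calibration (500 replicates) run on
ground-truth z tables.  These sizes keep the whole validation in the
low tens of seconds while leaving Monte-Carlo error well inside the
asserted bands.

Passing these checks shows the chain is internally correct under the
generator's assumptions.  Real cTDI traces differ in ways the generator
does not model: asymmetric wave shapes, baseline drift and clutter,
breathing and fetal movement artifacts, angle-dependent amplitude bias,
ROI placement variability and speckle noise.  Performance on clinical
recordings therefore requires its own validation, and clinical use
additionally requires real reference curves.

## Known limitations

* The event logic is one faithful reading of a sketched algorithm
  (cross-beat consensus, cross-segment comparison); companion
  engineering papers defining the original in detail were not
  reconstructed.
* Correlation recovery through the pipeline attenuates by ~0.02–0.04 in
  rho at the default noise level due to residual measurement error —
  visible in the acceptance output as recovered values near −0.77 to
  −0.80 for an imposed −0.8.
* The orientation inference (as opposed to declared orientation) is
  unreliable for fully fused traces.
* Fused beats lose both Em and Am on both participating beats; a
  partial-attribution scheme could retain more data but has no ground
  truth to validate against.
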