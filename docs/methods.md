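# Methods

This note documents the models, conventions and numerical choices behind
`ecglvh`, in the order data flows through the package.

## Synthetic ECG model

Each lead of a simulated record is a train of identical beats at a fixed
RR interval. One beat is a sum of six Gaussian waves — Ppos, Pneg, Q, R,
S, T — with per-wave amplitude (mV), centre and width σ (ms), and a
per-wave 8-vector of lead multipliers. A Gaussian-bump beat (rather
than a dynamical-system simulator) was chosen deliberately: every
fiducial has a closed form, so delineation error is measurable to the
sample. The price is realism — see Limitations.

Ground-truth conventions, used consistently by the generator and (as
estimation targets) by the delineator:

* **Wave peak** — the extremum of the noise-free composite within ±σ of
  the wave centre (on a 0.05 ms grid). A wave is *present* only when
  that composite extremum reaches the presence floor (20 µV for QRS and
  T waves, 12 µV for the smaller P components): a small Q riding on a
  large R's tail may produce no deflection of its own, in which case
  neither the truth nor any delineator can see it.
* **Wave onset/offset** — the 1 %-of-amplitude crossing of the
  composite, i.e. centre ± 3.035 σ for an isolated wave.
* **Sub-wave boundary** (Q end, P component boundary) — the baseline
  crossing between adjacent waves.
* **T end / T onset** — the closed-form tangent intersection: the
  tangent at the inflection of a Gaussian A·exp(−(t−c)²/2σ²) meets the
  baseline at c ± 2σ. T "duration" is the distance between the two
  tangent feet (4σ).

Default template (single-lead values before lead scaling): P⁺ 0.045 mV /
σ 12 ms at 100 ms, P⁻ −0.038 / 12 at 135, Q −0.08 / 6.5 at 225,
R 0.45 / 9 at 250, S −0.29 / 6.5 at 275, T 0.15 / 26.5 at 535; RR
1000 ms, fs 500 Hz, 15 s records. These are population-median adult
resting values; the implied intervals land in the expected regime
(QRS ≈ 89 ms, P ≈ 108 ms, QT ≈ 383 ms at 60 bpm, T ≈ 106 ms). The
sampling rate is a documented default, not a measured fact about any
particular device. Lead scalings mimic the normal precordial
progression (deep S in V1–V2, tall R in V4–V6, no Q in V1–V2, the most
biphasic P in V1) and have median 1.0 per wave across the 8 leads, so
global-median biomarkers equal the template values. Artefact is
additive: a sinusoidal baseline wander below the 1 Hz high-pass cutoff
plus white noise, both seeded.

## Cohort model

`generate_cohort` draws clinical covariates with the marginal structure
of a middle-aged community imaging cohort (age ≈ 64 ± 9, 52 % female,
BP/cholesterol/HbA1c/smoking in routine ranges; medication-masked raw
values are generated from the adjusted latents so the clinical module's
adjustments recover them). The latent QRS amplitude is log-normal
(median 0.90 mV, log-sd 0.254, matching the reference interquartile
range). The LVH label is Bernoulli with
`p = expit(β₀ + 4.0·QRS[mV] + 0.04·SBP[mmHg])`; β₀ is solved by
bisection (monotone, bracketed in ±60) so the mean probability equals
the prevalence target, 1.5 % by default. LV mass is then drawn
consistently with the label around the sex-specific indexed thresholds,
so the clinical derivation reproduces the label exactly.

Labelled records are remodelled: QRS amplitudes scaled ×1.25 and widened
×1.09, QRS duration +8 ms, heart rate −4 bpm, QT dispersion +30 %, P⁺
amplitude +0.02 mV, with `lvh_effect_scale` switching the secondary
effects off for null experiments. Effect sizes were set once from the
LVH-vs-normal contrasts of published cohort characteristics (e.g. QRS
duration 97 vs 89 ms, rate 58 vs 62 bpm).

The cohort table carries template-implied biomarkers with per-lead
log-normal gain jitter (sd 0.30) and 15 µV sensor noise — the "tabular
fast path" — so cohort-scale experiments need no waveform synthesis.
`beat_template_for` returns the matching waveform template per record;
the two paths are cross-checked in the tests at small n. Imaging-centre
labels are multinomial with probabilities 0.713 / 0.175 / 0.056 / 0.056
(proportional to the per-centre case counts of the rotation design).

What the generator does **not** emulate: lead-to-lead timing differences
(all leads share the template's fiducial times, so QT dispersion in the
waveform path is near zero and is injected only in the tabular path),
beat-to-beat variability, ectopy, bundle-branch morphologies, rate-
adaptive intervals, and the real correlation structure between clinical
covariates (drawn independently except where stated). Passing tests
therefore demonstrate correctness of the measurement and modelling
machinery under known structure, not performance on real ECGs.

## Preprocessing

Zero-phase (forward–backward) order-4 Butterworth band-pass, 1–45 Hz.
R detection computes the smoothed Hilbert envelope of an 8–25 Hz
QRS-band-emphasised copy (so tall T waves cannot masquerade as beats),
picks peaks ≥ half the envelope's 99th percentile with a 200 ms
refractory constraint, refines each to the signed signal extremum, and
rejects records whose envelope peaks do not stand ≥ 3× above the median
envelope (pure noise) or with < 3 beats. The median beat spans 300 ms
before to 500 ms after R; "same morphology" is correlation ≥ 0.9 with
the ensemble mean of the concatenated 8-lead beat, so a beat corrupted
in any lead is rejected for all leads consistently.

## Baseline and delineation

The 1 Hz high-pass attenuates the beat train's RR fundamental — by half
at 60 bpm, by > 80 % when the rate falls below the cutoff — leaving a
slow periodic tilt on the median beat. Before delineation the package
fits `a + b·cos(ωt) + c·sin(ωt)` at the RR fundamental to fixed
isoelectric windows (start of the beat window, PR segment, TP segment)
and removes it; the fit is rejected in favour of a constant level if its
swing exceeds 3× the span actually observed in the quiet windows
(ill-conditioning guard under noise). Higher harmonics pass the filter
essentially unchanged and are not fitted. The final isoelectric level
is the median of the 40 ms window ending 20 ms before QRS onset.

**QRS bounds.** The analytic-signal (Hilbert) envelope's maximum-slope
point on each side of R defines a tangent whose baseline intersection is
the initial bound (bounds are ABSENT if the tangent fails to intersect
within ±150 ms of R). The bound is then refined to the package's wave-
extent convention: from the outermost significant sub-wave, march
outward until the signal settles within 1 % of the wave amplitude of
the *local* post-wave level (the band-pass leaves ring/recovery
plateaus of a few percent beside large narrow waves; measuring against
the local level rather than zero recovers the true extent). Outermost-
wave candidates are sub-baseline dips within ±90 ms of R — in the
monophasic-per-side wave model the flanking waves (Q, S) are negative,
which excludes P, T and the positive ring lobes — accepted only above a
16 µV detection floor (slightly below the 20 µV generation floor, to
tolerate the filter's few-percent amplitude loss) and above 5 % of the
inner accepted wave. A model-based cap bounds runaway walks: a
quadratic fit to log|x| over the outer-flank core (≥ 30 % of the peak)
recovers the wave's centre and σ, de-biased through a calibration table
built by passing reference Gaussians through the package's own filter,
and the 1 % boundary follows analytically; the cap replaces the walk
only when the walk overshoots it by more than 2 ms.

**Wave labelling.** Baseline crossings partition the complex; the
dominant supra-baseline wave is R, significant negative waves before and
after are Q and S (sub-20 µV detection floor as above). With no
supra-baseline wave the complex is QS: the first negative wave is
labelled Q.

**P wave.** Search window 250–40 ms before QRS onset. The positive
component contains the window maximum; a following sub-baseline wave is
the negative terminal component. Outer boundaries use Gaussian-width
extrapolation — σ̂ from the outer-flank half-maximum width, boundary at
peak ∓ 3.035 σ̂ — because a 1 %-amplitude threshold on a ~45 µV wave
would sit below the noise.

**T wave.** Peak is the absolute extremum in 80–400 ms after QRS
offset; inverted T is handled by reflection. The beat is smoothed
(Savitzky–Golay, 24 ms, order 2) and the tangent at the steepest
down-slope — constrained to the part of the limb above 30 % of the peak
— is intersected with the isoelectric line for T end; T onset mirrors
this on the up-slope.

Measured accuracy on the validation grid (81 templates spanning QRS
amplitude ×0.7–1.4, width ×0.85–1.2, RR 800–1200 ms, T 0.10–0.22 mV):
noise-free, 100 % of contract landmarks within ±4 ms of analytic truth;
at 0.02 mV white noise, ≈ 99 % within ±10 ms. The residual clean-grid
extreme (4 ms) is the R-peak location in V1, where the deep narrow S
wave's filter ring genuinely shifts the small R's maximum.

## Biomarkers

QRS wave amplitudes are measured relative to the signal value at QRS
onset; P and T amplitudes relative to the isoelectric level. QRS
amplitude is peak-to-trough (R − S with absent waves contributing zero):
this definition is consistent with the reference magnitudes (≈ 0.90 mV
against R 0.45 / S −0.29). Slopes are the extreme central-difference
derivatives on the R up/down-stroke (mV/s). ST deviation is the
absolute offset at J + 60 ms. Global features are nan-medians across
leads (≥ 4 leads required). QTc uses Bazett by default (QT/√RR[s]),
with Fridericia as a config switch. QT dispersion is max − min QT over
leads. PTFV1 is the signed-negative product of the V1 terminal-P
amplitude and duration (mV·ms). Sokolow–Lyon: S(V1) + max(R(V5),
R(V6)) ≥ 3.5 mV. Cornell: R(aVL) + S(V3) > 2.8 mV (men) / 2.0 mV
(women); only the independent leads are analysed, so R(aVL) is
reconstructed linearly as R(I) − R(II)/2, valid on median beats where R
peaks are synchronous, clipped at zero. Pathological Q: any lead with
Q duration ≥ 40 ms or Q depth ≥ 25 % of R (a Minnesota-style rule;
config-exposed).

## Clinical derivation

BP is the mean of two readings, +15/+10 mmHg systolic/diastolic under
antihypertensive medication; total and non-HDL cholesterol are divided
by 0.73 and 0.66 under lipid-lowering medication. Flags are inclusive
(≥ 130/85 mmHg on the *adjusted* BP, ≥ 5 mmol/L, ≥ 48 mmol/mol); the
LVH thresholds are strict (> 70 / > 55 g/m² by sex) on Mosteller-indexed
LV mass. Records without LV mass get a missing label and are excluded
from modelling.

## Feature QC and modelling protocol

All QC statistics are learned on training rows and applied to test rows
— the leakage test asserts bit-identical training artefacts under
permutation of test-row features. Within the training side the order is
Tukey-fence masking (1.5 × IQR beyond the quartiles, inclusive fences) →
zero-variance and ≥ 10 %-missing feature removal → greedy correlation
elimination at |r| ≥ 0.9 (drop the member with the larger mean absolute
correlation) → chained-equation imputation (iterative ridge regression,
10 cycles, seeded, single imputation — classification input, not
coefficient inference) → z-scoring. Chi-square ranking decile-bins
continuous features. The split is stratified 80/20; the training
majority class is randomly down-sampled to the minority count; the test
set is untouched.

Classifiers: weakly L2-regularised logistic regression (C = 100);
RBF-kernel SVM with C ∈ {0.5, 2, 8} × γ ∈ {scale, 0.05, 0.2} tuned by
3-fold CV on the training folds and Platt-style sigmoid calibration for
probabilities; bagged random forest (200 trees) with depth ∈ {4, 8, ∞}
and features-per-split ∈ {√p, p/2} tuned the same way. Test-set metrics
at the 0.5 probability threshold are primary; 10-fold CV training
metrics are reported alongside; internal fold counts shrink automatically
when a (small) balanced training set cannot support them, and training
sets with fewer than two records of a class are rejected with a clear
error. AUC is the Mann–Whitney rank statistic
(ties counted half), verified against exhaustive concordant-pair
counting. Centre rotation runs three experiments —
{Cheadle+Newcastle → Reading+Bristol}, {Newcastle+Reading+Bristol →
Cheadle}, {Cheadle+Reading+Bristol → Newcastle} — refitting the entire
QC/selection/standardisation/tuning pipeline within each experiment's
training centres.

## Problem sizes and determinism

The validation grid uses 81 records (≈ 8 100 landmark comparisons) per
noise condition; modelling experiments use cohorts of n = 20 000
(≈ 300 cases; balanced training sets of ≈ 460) and the study-scale
cohort check uses n = 37 534. Every random draw flows from explicit
integer seeds (numpy `default_rng`); repeated runs are bit-identical.

## Known limitations

* The Gaussian beat model cannot represent notched/slurred QRS, U
  waves, ST-segment pathology or rate-dependent interval adaptation;
  delineation accuracy on real ECGs will be worse than on the grid.
* Classifier AUCs on the synthetic cohort (≈ 0.95–0.99) exceed what is
  achievable on real data, because the generative label model shares its
  features with the classifier and covariate noise is mild; only the
  qualitative ordering (ECG + clinical ≫ clinical-only) should be read.
* Voltage-criterion positive rates (Sokolow–Lyon, Cornell) are lower
  than real-cohort rates: single-scale amplitude variation with
  independent lead jitter understates the tail of lead-specific
  voltages.
* aVL reconstruction assumes synchronous R peaks across leads — exact
  for median beats of this generator, approximate for real signals.
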