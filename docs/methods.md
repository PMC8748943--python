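# Methods

This note documents the models, conventions and numerical choices behind
`cardiomotor`, and what the synthetic experiments do and do not establish
about real recordings.

## Signal model and R-peak detection

The ECG model is deliberately minimal: a recording is a sum of identical
QRS-like pulses (a raised-cosine of 20 ms total width and unit amplitude,
one per heartbeat, peak sample aligned to the beat time), Gaussian white
noise, and an optional linear drift. Three-electrode synthesis places the
cardiac signal on two electrodes against a common reference so that the
bipolar combination `mean(ch2 - ch1, ch3 - ch1)` recovers it exactly while
common-mode offsets cancel; with per-channel noise sd `s` the combined lead
has noise sd `s*sqrt(1.5)`.

Detection operates on the combined, filtered, 1000 Hz signal:

1. **High-pass.** Second-order Butterworth at 0.01 Hz, run forward-backward
   (`sosfiltfilt`) so the phase response is exactly zero — peak *timing* is
   the measurand, so any phase distortion is unacceptable. A cutoff this low
   has transients of tens of seconds; the filter pads 60 s of reflected
   signal at each edge so transients decay outside the data.
2. **Resampling.** Polyphase resampling with the exact rational ratio
   1000/fs; output trimmed to `round(n * 1000/fs)` samples. All event and
   peak times are then integer milliseconds (rounded half-up).
3. **Smoothing before thresholding.** An 11-ms symmetric moving average is
   applied before the threshold. Without it, an adaptive threshold at half
   the 99th-percentile amplitude sits only 2.5-3 noise standard deviations
   above zero at peak SNR 10, which over a 7-minute record produces
   thousands of false crossings; after smoothing the same threshold sits
   ~8 noise sd up and false detections are practically impossible. A
   symmetric window does not move the maximum of a symmetric QRS, so timing
   is unbiased; residual noise-induced jitter is ~1 ms.
4. **Threshold and localization.** Threshold = 0.5 x the 99th percentile of
   the absolute smoothed signal (scale-invariant, robust to isolated
   artifacts); one peak per contiguous suprathreshold excursion at its local
   maximum; a 250 ms refractory period (240 bpm physiological ceiling)
   merges double detections, keeping the larger. The detector considers
   positive excursions only; `orient_polarity` flips an inverted lead first
   (the pipeline applies it automatically).

Sustained detection above 250 bpm aborts with a QC error. The R-R quality
report flags intervals outside 300-2000 ms and intervals more than 40% away
from the local median (centered window of 11 intervals); these bounds are
stated package choices, standing in for manual inspection. Events inside
flagged intervals count toward totals but are excluded from window and
phase assignment.

## Time-domain windows

Latency lambda is measured from the preceding R-peak. Windows are half-open
with the lower edge included: [-100, 100) -> 0, [100, 300) -> 200,
[300, 500) -> 400, [500, 700) -> 600. Because the 0-ms window straddles the
peak, an event within 100 ms of the *next* peak (lambda >= T_R - 100) is
re-referenced to that peak and assigned window 0; this precedence beats
window 600 whenever T_R < 800 ms makes the two overlap, so assignment is
total and single-valued. Latencies in [700, T_R - 100) belong to no window.

Two consequences are worth stating plainly:

- **Denominator.** Proportions divide by *all* of a subject's events by
  default ("proportion of motor events"); unassigned and QC-excluded events
  stay in the denominator. Renormalizing over assigned events is a config
  switch (`denominator="assigned"`).
- **The scheme is not exactly null-neutral.** When an R-R interval is
  shorter than 800 ms, the re-referencing rule takes measure from the
  600-ms window while windows 0/200/400 keep 200 ms each. Under uniform
  event phases with mean R-R 825 ms and sd 40 ms this produces a real,
  small expected deficit (~0.004-0.008) in window 600 — a property of the
  windowing itself, shared by any analysis using these definitions. It is
  one reason the measured type-I rate of the ANOVA Time effect sits near
  0.075 rather than 0.05 (see Calibration below). Note the bias *inflates*
  window 0, so a reported deficit near the R-peak is conservative with
  respect to it.

## Phase domain

Phase is `(t_e - prev R)/T_R * 360` in [0, 360). Bin edges sit at multiples
of 18 degrees, so bin centers are 9, 27, ..., 351 — the convention that
makes reported bin centers such as 81 degrees exact. Histograms are
normalized per subject x condition (each subject contributes equally),
smoothed as `out[i] = (in[i-1] + in[i] + in[i+1])/3` with circular wrap
(the only wrap consistent with circular data), which preserves total mass
to 1e-12. Smoothing is applied per subject before cross-subject testing by
default (`smooth_per_subject`). The per-bin test is a two-sided one-sample
*t* against 0.05 on the (smoothed) subject proportions, df = n_subjects - 1,
Bonferroni family of 20 bins within each condition (40 pooled is a switch).
The Rayleigh p-value uses the standard small-sample approximation
`exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))`, R = n*Rbar, valid for n >= 4;
it matches a 10^6-draw Monte-Carlo null to <0.001 at n = 8.

At 1 ms resolution a phase is quantized to steps of 360/T_R (< 0.5 degrees
for T_R >= 720 ms). An event whose rounded time coincides exactly with an
R-peak has no defined phase and is excluded from phase tables (~0.1% of
events); the window analysis keeps it (latency 0 -> window 0).

## Group inference

The ANOVA is the classical two-way fully-within decomposition; each effect
is tested against its own effect-by-subject interaction. Sphericity is
handled by Greenhouse-Geisser epsilon from orthonormal contrasts — for main
effects on the per-subject factor means, for the interaction with the
Kronecker product of both factors' contrasts on the raw cell matrix —
yielding fractional corrected dfs (eps*df1, eps*df2) and a corrected p
alongside the uncorrected one. The implementation agrees with a loop-based
sums-of-squares oracle to 1e-8 and with statsmodels' AnovaRM and pingouin's
two-way rm_anova (F, epsilon and corrected p) to 1e-9 on random tables.

Paired comparisons report t, df, two-sided p and paired Cohen's
d = mean(diff)/sd(diff); the d sign matches t, so a deficit in the earlier
window of a contrast gives negative t and d. Post-hoc family is the six
pairwise window contrasts within each condition (12 pooled as a switch);
Bonferroni is exactly `min(1, m*p)`. Identical paired inputs return t = 0,
p = 1 with a degeneracy flag; a nonzero constant difference raises instead.
"Movement time" is the mean interval between consecutive endpoints within a
trial, averaged over trials, during execution.

## The synthetic generator

What it emulates: per-dyad turn-taking by block (executor alternates; each
subject executes exactly half the blocks), 10 trials of 6 endpoints per
block, ~40 min sessions, mean R-R 825 ms, and within-dyad correlation of
movement speeds (subject mean inter-endpoint gaps drawn from a bivariate
normal with configurable correlation, default mean 1250 ms, between-subject
sd 200 ms, within-subject gap sd 150 ms). R-R intervals are i.i.d.
truncated normal on [300, 2000] ms with sd 40 ms (a typical short-term
beat-to-beat variability for resting young adults); serial heart-rate
structure is omitted because every analysis is local to one or two
consecutive intervals.

Coupling modes: `uniform` draws each endpoint's phase uniformly (the exact
null in phase); `von_mises` draws phases from von Mises(mu, kappa) and maps
them into the containing interval, making the injected phase law exact by
construction; `time_suppression` thins paced candidates whose latency to
the *nearest* R-peak falls within center +- halfwidth, keeping them with
probability `suppression_factor`. Candidates are paced by the movement-time
process rather than placed uniformly in time; because the gap sd (150 ms)
and R-R variability wrap the lattice within a few beats, candidate
latencies are effectively uniform, which the flat null histograms confirm
(every bin within 0.05 +- 0.005 at 1e5 events). Injected coupling applies
to the executing subject's heart; the same physical events are mirrored to
the partner as observation, so the observation condition under a coupled
mode is a natural null against the observer's own heart.

Ground-truth phases are recomputed from the quantized integer-millisecond
times, so they agree with the phase module exactly. Seeding fans out from a
master seed by fixed (dyad, subject) offsets; identical seeds reproduce
event tables byte for byte.

**Cohort structure.** `generate_cohort` builds the 25-subject analysis
cohort the way the emulated study was actually composed: 14 subjects in 7
mutual dyads (both members analyzed) and 11 subjects paired with unanalyzed
partners. This matters because dyad partners share physical movement
events: with every subject's heart beating at the same mean rate, a shared
event sequence stays phase-coherent on both R-R lattices and partners'
window proportions correlate (~0.25 in an all-pairs cohort), inflating the
ANOVA's effective type-I rate. The mixed cohort halves that dependence; the
residual is a faithful property of the dyadic design itself.

What the generator does **not** model: realistic PQRST morphology,
respiratory sinus arrhythmia or any serial R-R structure, ectopic beats,
between-subject heart-rate differences, drifts in movement speed, or
observation-side coupling. Passing tests therefore establish that the
pipeline recovers what it claims under clean, known-truth conditions — not
that real recordings meet these assumptions.

## Calibration and power (measured)

Under the uniform null (2000 replicate 25-subject cohorts): per-bin
uncorrected rejection 0.051, subject-mean Rayleigh rejection 0.052, ANOVA
Time-effect rejection (Greenhouse-Geisser p) 0.075. The Time-effect
elevation above the nominal 0.05 is explained and reproducible: partner
dependence in the mutual dyads plus the window-600 geometry described
above; the per-window proportion analysis itself, fed independent
multinomial subjects, rejects at 0.055. With suppression factor 0.5 within
+-100 ms of the R-peak, all three Bonferroni post-hoc contrasts against
window 0 are significant in ~100% of replicates; with a weak von Mises
preference (mu = 81, kappa = 0.5) the 81-degree bin is elevated and flagged
uncorrected in the large majority of replicates. A generator correlation of
0.6 between dyad movement times is recovered as sample r ~ 0.6 over 200
dyads from the event tables alone.

Problem sizes in the automated checks (500-beat detection runs, 100-2000
replicate calibrations) were chosen to give Monte-Carlo standard errors
well inside the asserted bands.

## Known limitations

- The window scheme's structural bias (above) means "uniform phases" is not
  an exact null for the time-domain ANOVA whenever R-R < 800 ms occurs.
- The per-bin t-tests treat bins separately; smoothing correlates adjacent
  bins, so neighboring flags are not independent evidence.
- The Rayleigh approximation is used at n as low as 4 subjects only behind
  an explicit precondition; its accuracy there is ~1e-3 in p.
- QC thresholds (300-2000 ms, 40% local deviation, window 11) are sensible
  defaults, not validated clinical criteria.
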