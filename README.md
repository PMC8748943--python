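# cardiomotor

Analysis of how self-paced movements align with the cardiac cycle, for
experiments in which pairs of subjects take turns executing and observing a
memorized movement sequence while both ECGs are recorded. The package covers
the full path from raw multi-electrode ECG to group statistics, plus a
synthetic dyadic generator with explicit ground truth so every stage can be
validated without any real recording.

## The analysis

Each heartbeat is located by its R-peak; successive R-peaks bound one
cardiac cycle of length *T_R* (the R-R interval). A movement endpoint at
time *t_e* — the moment the moved object touches the target pad — is related
to the heartbeat in two complementary ways:

- **Time domain.** The endpoint's latency to the nearest R-peak assigns it to
  one of four 200-ms windows centered 0, 200, 400, 600 ms after the peak
  (the 0-ms window straddles the peak, -100 to 100 ms). Per-subject window
  proportions enter a Condition (execution/observation) x Time (4 windows)
  repeated-measures ANOVA with Greenhouse-Geisser correction and Bonferroni
  post-hoc paired *t*-tests.
- **Phase domain.** The endpoint's cardiac phase is
  `phi = (t_e - prev R) / T_R * 360` degrees. Per subject and condition the
  package computes circular means (with resultant length R̄), Rayleigh tests
  of uniformity (z = n R̄²), and normalized 20-bin circular histograms,
  smoothed over three neighboring bins with circular wrap-around; per-bin
  one-sample *t*-tests compare subject proportions against the uniform
  expectation 1/20 = 0.05.

ECG preprocessing follows the standard three-electrode protocol: linear
subtraction into two bipolar leads that are averaged, a zero-phase 0.01 Hz
high-pass to remove drift, resampling to 1000 Hz (so every time stamp is an
integer millisecond), and adaptive threshold + local-maximum R-peak
detection with a 250 ms refractory period. Automated R-R quality flags
(intervals outside 300-2000 ms or >40% off the local median) replace manual
inspection; events inside flagged intervals are excluded from alignment.

The synthetic generator emulates the dyadic design — turn-taking by block,
two blocks of ten six-endpoint trials per dyad by default, mean R-R 825 ms,
correlated movement speeds within a dyad — and can inject known structure:
uniform phases (null), a von Mises phase preference, or suppression of
events near the R-peak.

## Worked example

Recover an injected R-peak-locked deficit (event rate halved within
+-100 ms of the R-peak) in a 25-subject cohort:

```bash
python examples/02_time_windows.py
```

```
mean proportion per window (both conditions):
window_center_ms
0      0.173
200    0.252
400    0.269
600    0.262
condition                           F(1.00, 24.0) =   1.53, p = 0.23 (Greenhouse-Geisser)
window_center_ms                    F(2.73, 65.5) =  21.51, p = 2.5e-09 (Greenhouse-Geisser)
condition * window_center_ms        F(2.43, 58.3) =  14.86, p = 1.5e-06 (Greenhouse-Geisser)

execution post-hocs against window 0 (Bonferroni):
  0 vs 200: t(24) =  -9.11, d = -1.82, p_bonf = 1.8e-08
  0 vs 400: t(24) = -12.03, d = -2.41, p_bonf = 7.1e-11
  0 vs 600: t(24) = -10.10, d = -2.02, p_bonf = 2.4e-09
```

The 0-ms window holds ~0.17 of endpoints against ~0.26 elsewhere — the
injected deficit — the Time main effect is strongly significant with
fractional (sphericity-corrected) degrees of freedom, and every post-hoc
contrast of window 0 is negative and significant. The other examples cover
R-peak detection from noisy ECG (`01`), the phase-domain pipeline (`03`),
and a full config-driven run producing `report.json` (`04`). A thin CLI
mirrors the stages: `cardiomotor simulate|detect|align|phase|infer|run-all`.

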