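# Methods

This note documents the models, the numerical choices, and the limits of what
the synthetic validation can show.

## Synthetic gait model

### Stride waveform

One stride of duration ST seconds at sampling rate f_s comprises
n = round(ST·f_s) samples, of which S = round(PST/100·n) are stance. Each of
the four insole sensors (heel, big toe, 5th and 1st metatarsophalangeal
joints) is modeled as a product of raised-cosine (half-cosine) loading and
unloading transitions, with relative peak loads 1.00 / 0.60 / 0.35 / 0.35
(uncalibrated — FSR insoles are not force-calibrated, only loading *timing*
and *order* matter for event detection):

- the heel loads over a fast edge of width w = max(4, round(0.06·f_s))
  samples starting at heel strike, and unloads slowly across mid-stance;
- the metatarsal sensors load sequentially in early/mid-stance over wide,
  low-slope windows;
- the toe loads last (window centered at ≈ 78 % of stance) and the three
  forefoot sensors unload *together* over one fast edge of width w centered
  at toe-off — this fast terminal unloading is the physical reason toe-off is
  a sharp falling edge in the summed signal.

The window widths were chosen so that, in the summed signal, only the initial
(heel) rising edge exceeds one sixth of the maximum first difference and only
the terminal fall exceeds one seventh of the minimum — i.e. the template
satisfies, by construction, the edge-uniqueness contract that the detector's
threshold rule assumes. Mid-stance slopes stay at ≤ 0.85 of the thresholds
across the whole 1–4 km/h range (worst at 4 km/h, where stance is shortest).

At speeds ≥ 3 km/h the heel-unloading window is shifted earlier, which turns
the stance plateau into the double-peaked shape seen in faster walking
(swing-phase initiation of the opposite leg). Swing-phase shoe-contact
artifacts are modeled as one broad, low-slope bump per swing (default 10 % of
the heel load) placed randomly inside the swing window.

**Event conventions.** Ground-truth heel strike is the *onset* of the rising
edge and ground-truth toe-off the *onset* of terminal unloading, matching the
edge semantics of the detector ("beginning of the falling/rising edge"). A
force plate would time stance end slightly later (force reaches zero at the
*end* of unloading, w/2 ≈ 30 ms after the onset); with the onset convention
the truth is self-consistent with what any edge-based detector can recover,
and stride times are unaffected by the choice (it is common-mode).

### Session composition

Walking blocks are assembled stride by stride. Stride times are jittered
multiplicatively (Gaussian, cv = 0.05, clipped at ±3σ) around a piecewise-
linear interpolation of the treadmill reference means over speeds
1.0–4.0 km/h (2.05 s at 1.0 km/h down to 1.14 s at 4.0 km/h, clamped outside
the grid); stance percentage is jittered additively (σ = 1.0 pp) around the
reference means (76.3 % down to 66.6 %). Per-stride scalar gain (cv = 0.08)
and per-channel gains (cv = 0.05) model stride-to-stride contact-pressure
variability; without them the time-normalized stride-morphology CoV of the
synthetic signal was ≈ 0.035, well under the ≈ 0.1 observed for real FSR
insoles, with them it is ≈ 0.07. Each walking block begins and ends with
0.5 s of light, constant shoe contact (ramped down over 0.15 s) so that the
first/last swing minima are well defined; standing blocks are constant
partial load on all sensors. Quiet standing produces no gait events and no
activity.

The per-channel voltages pass a first-order low-pass at f_c = 15.92 Hz
(exact pole mapping, state primed with the first sample) and are quantized to
the 12-bit ADC grid over 0–3.3 V with additive Gaussian noise of 4 counts
(≈ 3 mV, a typical resistive-divider + ADC noise floor). Default sampling
rate is 100 Hz for both FSR and acceleration; the rate is configurable since
hardware implementations vary between a 100 Hz sensor rate and a 20 ms global
sampling period.

Thigh acceleration is gravity plus a stride-locked two-harmonic oscillation
whose amplitude grows with speed so that peak magnitudes approach ±3.5 g at
4 km/h; at rest it is 1 g plus 1.5 mg sensor noise.

### What the generator does *not* emulate

Real FSR data contain inter-subject morphology differences (foot geometry,
footwear), non-stationary baseline drift, partial-contact and shuffling
steps, sensor saturation, and transmission dropouts. Passing the synthetic
validation therefore shows that the algorithms are *correct under their
stated signal model* (clean edge morphology with realistic timing/amplitude
statistics and front-end distortion) — the published accuracies on real
recordings act as bounds that the cleaner synthetic study must meet, not as
quantities the study re-estimates.

## Event detection

Thresholds are derived per recording: thr_rising = ⅙·max diff,
thr_falling = ⅐·min diff, where diff is the per-sample first difference
(the derivative's normalization is a convention; thresholds are ratios of the
same signal, so the sample spacing cancels). The integer fractions are fixed
constants originally obtained from the turning points of the normalized eCDF
of the difference signal (closest points to the corners (1,1) and (0,0)); the
eCDF analysis is recomputed and reported as a diagnostic, and the fractions
are exposed as parameters.

Swing minima are local minima of the summed signal with ≥ 0.7 s separation
(`scipy.signal.find_peaks`, whose distance rule keeps the deeper of two
conflicting minima; plateau minima are reported at their midpoint, which
makes noiseless recordings well-defined). From each minimum the toe-off is
the first sample of the nearest *contiguous run* of differences at or below
the falling threshold searching backward, and the heel strike the first
difference at or above the rising threshold searching forward. The recording
start acts as a virtual minimum for the forward search and the recording end
for the backward search, so the first HS and last TO are found without a
flanking baseline minimum. Duplicate finds (several minima mapping to the
same edge) are merged; strict alternation is enforced by dropping the later
of two same-kind events; searches that leave the recording yield flagged
boundary-partial events which are excluded from stride statistics.

Thresholds are global per recording (or per active interval in the gated
pipeline), not per stride. Whether toe-off should anchor at the run's first
sample or at the closest crossing is ambiguous in edge terms; the run onset
is used because the "beginning of the falling edge" *is* its first
sub-threshold sample.

## Activity detection

Non-overlapping 1 s windows (so one index equals one second, and the
5-sample median filter spans five seconds); population standard deviation of
the SVM per window; binarization at 0.1 g; binary median filter with
edge-replication padding (majority vote); morphological opening with a flat
structuring element of 10 windows. The opening length is not prescribed by
the underlying method description ("eliminate short periods") — 10 s was
chosen as the shortest bout length for which per-minute gait statistics are
meaningful, and it is a parameter. The opening is idempotent, sub-threshold
noise can never activate a window, and enlarging a true bout never shrinks
the detected set.

## Gait parameters

Heel strikes are the stride basis (the heel edge is the sharpest, most
reliably detected landmark). Mean stride time and PST are aggregated per
60 s bin, assigning each stride to the bin containing its starting heel
strike. Morphology CoV is the pointwise std/mean ratio of time-normalized
(100-point, linear resampling) HS→HS cycles, averaged over the portion of
the cycle with positive mean — for flat cycles with multiplicative gains this
equals the gain cv exactly, which the tests exploit as a closed-form oracle.
Bland–Altman limits use the n−1 standard deviation of the differences.

## Clock synchronization

The slave oscillator runs at (1 + drift·1e−6), optionally with a slow
quadratic term; counters are 32-bit at 10 µs and the recording must not
exceed the wrap time (11.93 h). Beacons arrive every second with Gaussian
reception jitter (default 2 ticks) and a processing delay modeled as a
deterministic 300 µs plus jitter-scaled variability (a fixed code path on
real hardware); on a missed beacon the previous correction state is retained.

The drift fit is a quadratic in t = k/F_s of (T_MN_sync − T_SN_sync)·tick;
divergence is the linear coefficient, linearity the ratio p2/p1, and the
RMSE is taken about the linear part *of the same quadratic fit* (a separate
linear fit would absorb curvature into the slope). A device fails at
|divergence| > 1 ms/s — at that level every other beacon is missed and TDMA
slots can collide. The residual divergence after the timestamp adjustment is
the |slope| of (adjusted local time − true master time): with per-beacon
re-synchronization, drift accumulates only within one beacon interval
(≤ drift·1 s, a stationary sawtooth), so the residual slope is orders of
magnitude below 1 µs/s.

One subtlety: with the sensor timestamp latched at processing time,
subtracting ΔT_proc in the adjustment leaves a constant ≈ 2·ΔT_proc latency
offset in the *absolute* adjusted time. All drift indicators are slopes and
are unaffected; the simulator-oracle test therefore bounds the spread about
that constant offset and the offset magnitude separately.

## Barometric altitude

Hypsometric formula with a linear lapse (0.0065 K/m) at a configurable
reference temperature, default 15 °C / 1013.25 hPa. The sea-level gradient is
then ρ₀·g ≈ 12.01 Pa/m, so 1.3 Pa of sensor noise maps to ≈ 10.8 cm of
altitude noise; the exact figure depends on the assumed temperature (hence
the ±0.3 cm tolerance in the validation). The altitude↔pressure pair is an
exact analytic inverse (round trip < 1 mm over ±500 m).

## Problem sizes and determinism

The synthetic treadmill study uses 10 subjects × 7 speeds × 60 s (70 runs,
≈ 3000 strides) — one minute per speed step mirrors the constant-speed
segments of a treadmill protocol and is one aggregation bin. The
synchronization experiment uses 3600 beacons (1 h). All randomness flows
from `numpy.random.default_rng` seeded per run (study seeds are spawned from
one root seed via `SeedSequence`); identical seeds give bit-identical
sessions, logs, and reports.

## Known limitations

- Per-sensor event detection (e.g. heel-only timing) is not implemented; the
  detector operates on the summed signal only.
- Sub-phases (mid-stance, mid-swing), center-of-pressure trajectories, and
  double/single-support times (which need both feet) are out of scope.
- The activity detector cannot distinguish walking from other leg-dominant
  movement; the generator only ever produces walking or rest.
- No pathological gait models; stance percentages outside ≈ 55–90 % are
  clipped by the generator.
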