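# Methods

This note documents the models implemented in `aopwv`, the defaults and
units of every parameter that matters, the numerical choices behind the
estimators, what the synthetic generator does and does not emulate, and the
package's known limitations.

## Units

Time in ms, distance in mm, velocity in cm/s, PWV in m/s. The conversion
1 m/s = 1 mm/ms is applied at the boundaries, so PWV in m/s is obtained
directly from mm and ms without numeric factors.

## Shared preprocessing

Acquisition-resolution mean-velocity curves are (1) interpolated to a 1-ms
grid with a cubic spline (not-a-knot end conditions; the spline passes
through every original sample, so curves already on the 1-ms grid are
unchanged), and (2) min-max normalized to [0, 1] over the full cycle.
Min-max normalization makes the upslope decile thresholds absolute levels:
the analysed portion of the systolic upslope is delimited by the first
upward crossings of 0.2 and 0.8 ("2nd and 8th decile" read as amplitude
fractions, not time deciles — the time-decile reading would make the window
depend on upslope curvature rather than on signal level). The systolic
foot is the last sample at or below 0.05 normalized units before the
earliest global maximum; 0.05 tolerates baseline noise without clipping the
rise. Crossings are localized to sub-ms precision by linear interpolation
between grid samples. Non-monotone upslopes use first crossings and emit a
warning.

## Transit-time estimators

All three estimators take the upstream curve x and the downstream curve y,
preprocessed as above, and return a delay in ms.

**TTc (time domain).** The shift s of x is searched over
[0, systolic duration of x] (foot to first post-peak return below the foot
level) that maximizes the overlap with y over y's 2nd-8th-decile upslope
window; the overlap functional is the negated sum of squared differences of
the aligned segments. A mean- or scale-normalized correlation cannot serve
as the objective here: the decile segment of a smooth upslope is nearly
linear, so a standardized correlation is invariant to exactly the
offset/scale information that localizes the alignment (and a cosine
similarity locks onto the self-similar exponential decay). The integer-ms
argmin is refined by a 0.05-ms local scan of the same objective with
fractionally shifted segments (linear interpolation); a parabolic vertex is
not used because the objective is kinked at the optimum and the vertex is
biased by up to ~1 ms. The Pearson correlation of the aligned segments is
reported as a diagnostic, with a warning below 0.5.

**TTw (time-frequency domain).** Continuous wavelet transforms W_x, W_y
with the 4th-order complex Gaussian wavelet on 32 logarithmic scales whose
characteristic frequencies span 0.5-15 Hz (cardiac fundamental and
harmonics). The cross-spectrum C = W_x conj(W_y) yields a per-(scale, time)
delay

    delay = -arg(C) / (2 pi f_inst),

with f_inst the mean of the two curves' instantaneous frequencies
(time-derivative of the unwrapped CWT phase). Dividing by the scale's
nominal center frequency instead would bias the delay ~6-8% on a chirping
upslope; the instantaneous-frequency (midpoint) form is second-order
accurate for a pure delay. TTw is the |C|-weighted mean of the delay over
the union of the two curves' decile windows. Two numerical details:
(1) the CWT is evaluated on a 3-copy periodic extension of the cycle and
the central copy kept — retrospectively gated cine data is one period of a
periodic signal, and zero-padding otherwise leaves edge-artifact phase at
the largest scales (support > the 1-s record) that can corrupt the estimate
by several ms; (2) phase is wrapped to (-pi, pi], so delays at frequency f
are resolvable only below 1/(2f) — at 15 Hz that is 33 ms, which covers
transit times of a 0.25-m aorta above ~4 m/s but wraps below that at the
top scales (their weight is small).

**TTf (frequency domain).** Over the full cycle, H(f) = Y(f)/X(f) from the
DFTs; group delay GD = -d(unwrapped arg H)/d(2 pi f) by central differences
on the retained-bin grid. Retained bins: 0 < f <= 10 Hz with |X(f)| at
least 1% of the spectral maximum; weights |X(f)|^2 (power; amplitude
weighting is available as config — the two differ by <1 ms on clean data).
TTf is exact on circular shifts (DFT shift theorem) and is the only
estimator using the entire cycle; consequently it inherits a positive bias
when a backward-travelling reflected wave distorts the late cycle (see
Limitations).

**Oracle.** An exhaustive integer-ms least-squares search over the same
window, written as an explicit loop independent of the production code;
used by the tests as the reference for TTc and for delay ground truth.

Sign convention: arguments are always (proximal/upstream, distal/downstream);
the search ranges and weighting make the result non-negative for forward
propagation.

## PWV strategies

**S1 (two-plane).** PWV = D/TT between the extreme planes, with TT from any
of the three estimators. Fails (structured `EstimationError`) on
non-positive TT.

**S2 (iterative fit).** TT_i between the reference plane and each of the
other N-1 planes; unweighted OLS TT_i = a D_i + b with free intercept;
PWV = 1/a. The reciprocal is dimensionally required for a TT-vs-D fit.
Pairs with failed TT estimation are dropped (at least 3 must remain);
R^2, intercept and drop counts are reported. A Theil-Sen variant and a
forced-through-origin variant sit behind flags; with two planes and b = 0,
S2 reduces to S1.

**S3 (plane fit).** All (d_i, t, v) samples of every plane's decile segment
are pooled and fitted with v = alpha t + beta d + gamma by least squares in
v (v is the noisy measured quantity; a total-least-squares variant is
behind a flag). A pure traveling wave v = s(t - d/c) gives alpha = s,
beta = -s/c, hence PWV = -alpha/beta; beta >= 0 (no forward propagation)
is a structured failure.

**Cramér-Rao bound.** sigma_c = c^2/(SNR phi_max) sqrt(6 dt dx t_rise/L^3)
(SI units; result in m/s). Useful as a design rule: the bound falls as
L^(3/2), so covering the whole aorta rather than a short segment is the
most effective way to control PWV error.

## Bramwell-Hill reference

Distensibility D = ((A_sys - A_dia)/A_dia) / PP with PP converted
mmHg -> Pa at 133.322 Pa/mmHg (areas enter only as a ratio, so their unit
cancels); PWV = 1/sqrt(rho D) with rho = 1060 kg/m^3 by default.

## Agreement statistics

Bland-Altman bias = mean(A - B) with limits bias +/- 1.96 sd (sample sd,
n-1). ICC is the two-way random-effects, absolute-agreement, single-measure
form ICC(2,1) from the standard mean-squares decomposition (the variant is
an interpretation: sources rarely state which ICC they use; absolute
agreement is the right choice for comparing two measurement procedures).
The rank-sum test uses the exact null distribution for small untied
samples and the tie-corrected normal approximation otherwise, without
continuity correction so that identical groups give p = 1 exactly.

## Synthetic data

The generator emulates the waveform data a 4D-flow exam yields after
segmentation and plane placement — not the MR physics. One template
waveform per subject: zero baseline, half-cosine upslope (foot at 100 ms,
rise 80 ms, peak 80 cm/s), exponential decay with a 150-ms time constant
over a 1000-ms cycle (aortic mean velocity is near zero through late
diastole, which also keeps the single-cycle record nearly periodic); a
gamma-pulse shape is available as an alternative. The template propagates
at the true PWV: the plane at arc-length distance D receives it delayed by
D/PWV ms and attenuated by (1 - attenuation_per_mm)^D. An optional
reflected wave travels backward from beyond the most distal plane
(arrival at distance D: reflection_delay - D/PWV; amplitude a fraction of
the local forward wave; defaults 0.2 and 300 ms, plausible for late-systolic
augmentation), so it reaches distal planes first and is confined to the
late cycle. Acquisition sampling takes n_frames uniform frames per cycle
(50 by default; 20 for the low-temporal-resolution arm) and adds i.i.d.
Gaussian noise with sd = noise_sd x the reference-plane peak (noise is an
acquisition property, so its absolute level is plane-independent). Default
plane layout: 25 planes over 240 mm; default cohort truth: uniform
4-12 m/s with per-subject child seeds, so cohorts of different sizes share
their leading subjects.

What it does not emulate: per-plane waveform shape variation (every plane
shares one template, so sampling distortion is coherent across planes —
harsher for regression-based estimators than real data, where shapes
decorrelate), Rician magnitude noise, segmentation error, dispersion
(frequency-dependent wave speed), and anatomically realistic geometry
(the rasterizer uses a parametric curved tube). Passing recovery tests
therefore demonstrates estimator correctness and noise/sampling behavior,
not performance on real cohorts.

The rasterizer writes plane waveforms into a gridded time-resolved field
(nearest plane by arc length, velocity along the local tangent, voxel
centers at (index + 0.5) x voxel size), from which the extraction chain —
PC-MRA (modulus x speed averaged over the systolic peak +/- 2 frames),
centerline arc length (chord sum), 25 perpendicular planes at equal
arc-length fractions with central-difference tangents, and mean
through-plane velocity over a half-voxel-diagonal slab — reproduces the
input curves to well under 1% RMS on the bundled fixtures.

## Experiment harness and problem sizes

`run_experiment` generates a seeded cohort at each configured frame count,
runs the seven-estimator battery, and tabulates per-estimator ICC and
Bland-Altman agreement between the reference (50-frame) and
lower-resolution runs. Everything is deterministic given the config; the
report carries a config hash. The bundled experiment and the acceptance
script use 20 subjects, 25 planes, 5 clean recovery speeds and 100 noisy
oracle-agreement pairs — sizes chosen so the full validation runs in a few
minutes on one CPU while keeping the ICC estimates meaningful.

## Known limitations

- At 20 frames per cycle the frame spacing (50 ms) is comparable to the
  upslope duration (80 ms); spline reconstruction then distorts the upslope
  in a frame-phase-dependent way, and time-domain estimates carry errors of
  up to ~10 ms. This is the mechanism behind the low-temporal-resolution
  fragility of TTc-based estimators (and is coherent across planes in the
  simulator, see above). ICCs computed on 20-subject synthetic cohorts
  under 5% noise consequently rank the wavelet-based multi-plane estimators
  (S2-TTw/TTf, ICC ~0.8-0.9) clearly above time-domain and two-plane ones
  (ICC ~0.1-0.6), but the ordering among the fragile estimators themselves
  is seed-sensitive.
- TTf's full-cycle transfer function is sensitive to reflected waves: with
  the default 0.2 reflection the single-pair transit time is biased high by
  ~25-30% regardless of harmonic cutoff or weighting. Upslope-windowed
  methods (TTc, TTw, S3) are shielded by construction.
- TTw's phase wrapping bounds resolvable delays at the top scales
  (see above); for vessels much longer than ~0.3 m or speeds below
  ~3 m/s the scale grid should be lowered.
- S2 keeps all plane pairs, including near-zero-TT neighbors of the
  reference plane; dropping early planes is a documented alternative that
  was not adopted (no principled cutoff without real-data guidance).
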