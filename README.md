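# aopwv

Aortic pulse wave velocity (PWV) estimation from 4D-flow CMR velocity
waveforms.

Aortic stiffness is a marker of cardiovascular aging, and PWV — the speed at
which the systolic pressure/flow wave travels along the aorta — is its
standard non-invasive surrogate. Time-resolved 3D phase-contrast MRI ("4D
flow") provides mean-velocity waveforms at many cross-sectional planes along
the aortic centerline, from which PWV can be estimated in several ways. This
package implements, for researchers comparing such methods, the full
estimator battery:

- **Transit-time estimators** between two normalized velocity curves
  x(t), y(t):
  - **TTc** — time-domain overlap matching of the systolic upslopes,
    restricted to the 2nd–8th amplitude deciles of the rising limb;
  - **TTw** — 4th-order complex Gaussian wavelet cross-spectrum
    W_x·conj(W_y): the per-(scale, time) phase is converted to a delay and
    averaged over the upslope window, weighted by the cross-spectrum
    modulus;
  - **TTf** — Fourier transfer function H(f) = Y(f)/X(f) over the full
    cycle: TT is the group delay −d(arg H)/d(2πf) averaged over the input
    harmonics, weighted by |X(f)|².
- **PWV strategies**:
  - **S1** (two-plane): PWV = D / TT between the extreme planes;
  - **S2** (iterative fit): TT_i against distance D_i for all planes;
    OLS TT_i = a·D_i + b, PWV = 1/a;
  - **S3** (plane fitting): pooled upslope samples (d, t, v) fitted with the
    plane v = αt + βd + γ; a traveling wave v = s(t − d/c) gives
    PWV = −α/β.
- **Bramwell–Hill reference**: PWV = 1/√(ρ·D) from lumen-area
  distensibility D = (A_sys − A_dia)/(A_dia·PP) and blood density
  ρ = 1060 kg/m³.
- **Cramér–Rao bound** on the PWV standard error,
  σ_c = c²/(SNR·φ_max)·√(6·Δt·Δx·t_rise / L³).
- **Agreement statistics**: Bland–Altman bias ± 1.96 SD limits, ICC(2,1),
  univariate regression, Wilcoxon rank-sum.
- **Synthetic-data generator**: a parametric systolic pulse propagating at a
  known speed (4–12 m/s) over 0–250 mm of centerline, sampled at 50 or 20
  frames per ~1 s cycle, with additive Gaussian noise and an optional
  backward-travelling reflected wave — the ground truth used to validate
  every estimator by parameter recovery. A curved-tube rasterizer and plane
  extraction (PC-MRA, centerline arc length, 25 perpendicular planes, mean
  through-plane velocity) close the loop from gridded fields to waveforms.

## Worked example

```python
from aopwv import (TemplateWaveform, PropagationSpec, propagate,
                   sample_acquisition, estimate_all)

# a 25-plane subject with true PWV 8 m/s, noiseless 50-frame acquisition
dense, truth = propagate(TemplateWaveform(), PropagationSpec(pwv_true=8.0))
curves = sample_acquisition(dense, n_frames=50, noise_sd=0.0, seed=0)
for label, est in estimate_all(curves).items():
    print(f"{label:7s} {est.value:6.3f} m/s")
```

prints

```
S1-TTc   8.108 m/s
S1-TTw   7.953 m/s
S1-TTf   8.023 m/s
S2-TTc   8.011 m/s
S2-TTw   7.962 m/s
S2-TTf   8.040 m/s
S3       8.024 m/s
```

— all seven estimators recover the generating speed within about 1.5%; the
residual error reflects the 20-ms frame spacing, the 1-ms spline
interpolation grid and the decile windowing, not the estimators' algebra.

The same battery is available from the shell:

```sh
aopwv simulate --n-subjects 20 --seed 0 --out waves.csv
aopwv estimate waves.csv --strategy s2 --tt-method ttw --out pwv.csv
aopwv compare pwv_a.csv pwv_b.csv --out agreement.json
aopwv run-experiment --out results/
```

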