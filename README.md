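# fluoropaint

Quantitative analysis for **fluorogenic DNA probe** experiments in
single-molecule fluorescence microscopy: ssDNA strands carrying a
fluorophore (F) and a dark quencher (Q) that are dark in solution and light
up upon hybridizing to their complementary docking sequence. Such probes
break the "high concentration barrier" of TIRF imaging and enable very
short (6-nt) DNA-PAINT imagers; this package implements the complete
analysis chain needed to characterize them and to exploit them for
super-resolution imaging of rod-like targets such as influenza vRNP
segments — together with synthetic-data generators that make every stage
verifiable with known ground truth.

## What it computes

**Fluorogenic factor (FF).** The fold change in emission upon
hybridization,

    S_N = S_FQ / S_F,     B_N,mol = B_FQ,mol / B_F,mol,     FF = S_N / B_N,mol,

where `S_FQ` is the mean single-spot brightness of the F/Q probe, `B_FQ,mol`
the slope of the diffuse background vs probe concentration, and the `F`
quantities the same for a fluorophore-only reference. The pipeline covers
sCMOS photon conversion (`ADU = baseline + gain·photons`), Picasso-style
spot detection and Gaussian fitting, spot-free background extraction, the
exclusion of the unquenched (dead-quencher) brightness population via a
Gaussian-mixture fit, and first-order error propagation.

**Hybridization kinetics.** Two-state Gaussian HMM segmentation of
intensity traces, censoring-aware dwell extraction, and maximum-likelihood
lifetime fitting with the finite-exposure (truncated exponential)
likelihood

    f(t) = (1/τ) e^(−t/τ) / (e^(−t_min/τ) − e^(−t_max/τ)),

with bootstrap confidence intervals and lifetime ratios (e.g. matched vs
single-mismatch targets).

**DNA-PAINT cluster analysis and morphometry.** Windowed cross-correlation
drift correction (100-frame windows, 60 nm caps), DBSCAN with
acquisition-derived parameters (`eps = 0.5 px`, `min_samples = 0.01 ×
frames`), core-sample-ratio filtering, per-cluster on-rates
(localizations/s), and segment morphometry: Gaussian rendering (σ = 3.9 nm),
order-1 Butterworth (50 nm cutoff period) + Gaussian (σ = 5.85 nm)
smoothing, ISODATA binarization with a 5000 nm² area cap, Hilditch
skeletonization, longest-branch spine, and the median skeleton-to-boundary
distance as the segment radius. Per-cluster Fourier ring correlation with a
mono-exponential fit thresholded at 1/7 reports the achieved resolution.

## Worked example

```python
import numpy as np
from fluoropaint import (count_binding_registers, ff_characterization_study,
                         DwellSet, fit_dwell_mle)

# how many binding registers does the 6-nt imager see on the docking extension?
count_binding_registers("TGGTGG", "CCACCACCACCA")
# 3

# recover the FF of a highly fluorogenic probe (true S_N = 1, B_N = 1.6%)
# from simulated probe/reference movies over five concentrations
res = ff_characterization_study(seed=7, n_molecules=200)
print(f"S_N = {res.s_n:.3f}, B_N,mol = {res.b_n_mol:.4f}, "
      f"FF = {res.ff:.1f} +/- {res.se_ff:.1f}")
# S_N = 0.998, B_N,mol = 0.0159, FF = 62.8 +/- 1.1

# censored lifetime fit: 1500 dwells with tau_true = 0.5 s, observable
# window [0.2 s, 300 s] — the naive mean is ~40% high, the MLE is not
rng = np.random.default_rng(0)
u = rng.random(1500)
a, b = np.exp(-0.2 / 0.5), np.exp(-300.0 / 0.5)
t = -0.5 * np.log(a - u * (a - b))
est = fit_dwell_mle(DwellSet(t, 0.2, 300.0), seed=0)
print(f"naive mean = {t.mean():.3f} s; tau_hat = {est.tau_s:.3f} s "
      f"[{est.ci_low:.3f}, {est.ci_high:.3f}]")
# naive mean = 0.711 s; tau_hat = 0.511 s [0.483, 0.536]
```

The first number says the repetitive docking extension presents three
overlapping binding sites to the imager (tripling its effective on-rate);
the FF of ~63 means the probe brightens ~63-fold upon hybridization; the
lifetime fit shows the finite-exposure correction removing the censoring
bias that inflates the naive dwell mean.

A `fluoropaint` CLI exposes the same stages (`simulate`, `localize`, `ff`,
`kinetics`, `cluster`, `morphometry`, `frc`, `pipeline`); every stochastic
command takes `--seed` and is bit-reproducible.

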