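# vretina — a virtual retina

`vretina` is a toolkit for computational neuroscientists studying how
populations of retinal ganglion cells encode visual scenes. It implements a
complete encode–evaluate stack on synthetic data:

- **Encoding.** Each cell is a linear–nonlinear–Poisson (LNP) cascade: the
  firing rate is λ(t) = N((L ∗ s)(t)), where *s* is the stimulus movie, *L*
  is a separable spatiotemporal filter (a 10×10 spatial profile centred on
  the receptive field, times a temporal kernel spanning 18 frame bins of
  1/15 s, parameterised by 10 raised cosines on a log-warped time axis),
  *N* is a static nonlinearity (exponential, or a 7-knot cubic spline), and
  λ(t) drives an inhomogeneous Poisson spike generator.
- **Fitting.** Parameters maximise the Poisson log-likelihood
  Z = Σᵢ log λ(tᵢ) − ∫ λ(t) dt of observed spike trains, in two stages:
  blockwise coordinate ascent under an exponential nonlinearity (each block
  a concave Poisson GLM), then alternation between spline-coefficient and
  filter updates until the per-spike Z changes by less than 10⁻⁶ nats.
- **Evaluation.** Mutual information I(S;R) between a discrete stimulus set
  (1 s movie segments, uniform prior) and binned spike counts, estimated
  under the Poisson model (Monte-Carlo with exact stimulus marginal, or
  brute-force enumeration when feasible) or distribution-free over response
  levels {0, 1, 2, ≥3}, with quadratic-extrapolation debiasing; Bayesian
  average posterior matrices Q̄ᵢⱼ = ⟨p(sⱼ|r)⟩ and their row-wise distances
  (shuffle-normalised MSE, Jeffreys-regularised K–L, plug-in Jensen–Shannon),
  each summarised by the median across rows (the α value); maximum-likelihood
  population decoding with conditionally independent cells; and 2AFC
  grating-detection contrast sensitivity with a 75%-correct threshold.
- **Synthetic ground truth.** Stimulus generators (binary white noise,
  drifting sine gratings, natural-like movies with 1/f^2.04 temporal and
  1/w^2.09 spatial power spectra, 1 s segments interleaved with 333 ms gray)
  and ON/OFF-transient-like cell populations with known parameters, so every
  stage of the pipeline can be validated against the truth that generated
  the data.

## Worked example

Fit an LNP cell to four minutes of simulated white-noise responses and check
how well it generalises:

```python
import numpy as np
import vretina as vr

# 1. a ground-truth ON cell and 4 minutes of binary white noise at 15 Hz
cell = vr.make_population(vr.PopulationSpec(n_cells=1, seed=3))[0]
movie = vr.make_binary_white_noise(duration=240.0, seed=20)
rates = vr.firing_rate(cell, movie)
raster = vr.sample_spikes(rates, n_trials=1, bin_width=movie.frame_dt, seed=21)

# 2. two-stage maximum-likelihood fit
model = vr.LNPEncoder(movie, raster, rf_center=cell.rf_center)
result = model.fit()
print(result.summary())

# 3. how well does the fitted cell generalise?
heldout = vr.make_binary_white_noise(duration=60.0, seed=33)
lam_true = vr.firing_rate(cell, heldout)
lam_fit = result.predict(heldout)
v = ~np.isnan(lam_true)
print(f"held-out rate correlation: {np.corrcoef(lam_true[v], lam_fit[v])[0, 1]:.3f}")
```

Output:

```
LNP encoder fit
==============================================
n trials                       1
n spikes                    1118
rf center                (23, 6)
nonlinearity        cubic_spline
outer iterations              27
converged                   True
Z initial (nats)          977.94
Z final (nats)           1572.77
Z/spike (nats)            1.4068
knot range          [61.468, 70.159]

held-out rate correlation: 0.947
```

The fit converged in 27 outer iterations, raising the training
log-likelihood from 978 to 1573 nats over 1118 spikes, and the fitted cell's
firing rate on a fresh white-noise movie correlates at 0.947 with the
ground-truth rate. The end-to-end harness `vr.run_recovery(seed=1)` repeats
this for a 5-cell population (20 min of training data, half white noise and
half natural movie), then compares truth and fitted models on a 30-stimulus
test ensemble: mutual information, posterior matrices and α distances.

A thin command-line interface mirrors the library:

```bash
vr stim noise --seed 1 --duration 60 --out noise.h5
vr fit --movie noise.h5 --spikes raster.csv --out cell.json
vr recover --seed 1 --out report.json
```

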