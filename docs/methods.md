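# Methods

## The encoding model

A model cell is a linear–nonlinear–Poisson (LNP) cascade. The firing rate
elicited by a stimulus movie *s* is

    λ(t) = N((L ∗ s)(t)),

where ∗ is spatiotemporal convolution. The linear filter *L* is separable:
a 10×10 spatial weight matrix centred on the receptive field, times a
temporal kernel over 18 bins of exactly 1/15 s (one stimulus frame;
"67 ms" is the rounded print), i.e. 1.2 s of history. The temporal kernel
is a linear combination of 10 raised-cosine basis functions

    b_j(t) = ½(1 + cos(π · clip((φ(t) − c_j)/δ, −1, 1))),  φ(t) = log(t + ψ),

with peaks c_j evenly spaced in φ and δ the peak spacing. The warp constant
ψ defaults to 0.5 s: with a much smaller ψ the warp is so strong that the
earliest bumps collapse onto a single grid point of the 18-bin lattice and
the basis loses rank. Each row is rescaled to attain 1 on the grid (the
continuous-time peak generally falls between grid points). The nonlinearity
*N* is either exponential, N(g) = exp(gain·g + offset), or a natural cubic
spline through 7 knots with linear extrapolation beyond the outer knots
(slope of the boundary cubic). Rates are clamped below at a floor of
10⁻³ spikes/s so log-likelihoods stay finite. λ(t) is the intensity of an
inhomogeneous Poisson process; spike times are drawn per frame bin
(Poisson count, uniform placement within the bin), which is exact for a
piecewise-constant intensity.

Bins whose 1.2 s convolution history is incomplete (the first 17 frames of
a stream) are marked invalid (NaN) rather than zero-padded, and are excluded
from all likelihoods and information sums. Test streams are therefore given
a 1.4 s gray lead-in so every labelled segment has full history.

## Fitting

Parameters maximise the discretised Poisson log-likelihood

    Z = Σ_bins [ n·log λ − λ·Δt ]   (nats, summed over trials),

in two stages. Stage 1 assumes an exponential nonlinearity, under which Z is
concave in each filter block; spatial weights are initialised from the
spike-triggered average (rank-1 SVD of the 18×100 STA), temporal
coefficients by least-squares projection of the STA time course onto the
basis, and the drive is rescaled to unit variance before the first step.
Blocks (spatial + intercept, temporal + intercept) are then cycled with
L-BFGS solves of the corresponding Poisson GLM. Stage 2 places 7 knots
evenly over the range of the stage-1 drive, warm-starts the spline on the
exponential curve, and alternates (i) spline-coefficient maximisation and
(ii) filter-block maximisation until the per-spike Z change falls below
`tol` (default 10⁻⁶ nats/spike) or 50 outer iterations.

Numerical choices worth knowing:

- The design matrices are built from the mean-centred stimulus; the DC drive
  of the raw stimulus mean is folded back into the returned nonlinearity
  (exponential offset, or a shift of the spline knots), so a fitted cell
  evaluates correctly on raw luminance movies.
- The pair (filter scale, spline input scale) is unidentifiable, and a
  spline with linear extrapolation lets filter updates drift off the knot
  span. During the first 10 outer iterations the knots are therefore
  re-spanned over the current drive whenever it extends more than 5% beyond
  them (or has shrunk to less than half the span), with the spline
  re-warm-started by evaluating the old nonlinearity at the new knots. After
  iteration 10 the knots are frozen so the alternation terminates cleanly.
  Temporal coefficients are renormalised to unit norm after every filter
  step (the scale moves into the spatial weights).
- The Z trajectory ascends monotonically within each stage; the
  exponential→spline handover can dip by a few nats because the 7-knot warm
  start only approximates the exponential curve. The best iterate seen is
  returned if the loop hits the iteration cap.
- A blocked L-BFGS step that fails to improve Z is discarded (the previous
  block value is kept), so no accepted step decreases Z.

## Stimuli

All generators produce luminance frame stacks at 15 Hz in abstract linear
units with defaults mirroring a photopic recording condition (mean 1.7,
RMS contrast 0.27). Gratings drift along the horizontal axis with phase 0 at
t = 0, x = 0; a spatial frequency above the pixel Nyquist limit is an error.
Binary white noise takes mean ± amplitude per pixel-frame independently.
Natural-like movies are synthesised spectrally: a Gaussian field shaped so
temporal power falls as 1/f^2.04 and spatial power as 1/w^2.09 (w = radial
frequency), with random phases, rescaled affinely to the target mean and
contrast and clipped at zero (a warning is logged if more than 1% of mass is
clipped; at the default mean/contrast ratio clipping is negligible, ~6 s.d.).
Test ensembles are 1 s segments interleaved with 333 ms of gray, which at
15 Hz rounds to 5 frames; a 30-segment ensemble with a uniform prior has a
stimulus entropy of log₂30 = 4.9 bits. The default geometry (32×32 pixels,
~2.16 deg/pixel so that a 0.058 cyc/deg grating puts ~4 cycles across the
patch) is configuration, not a measured fact.

The spectrum estimator fits a least-squares line to log power vs log
frequency: along time, the periodogram is averaged over pixels; along space,
the 2-D periodogram is averaged over frames and every (kx, ky) point with
0 < w ≤ Nyquist enters the fit (no radial binning, which would bias the
slope). It recovers an exactly synthesised 1/f² signal to ±0.05 and the
generator's default exponents to well within ±0.1.

## Information estimators

Responses to the 1 s segments are binned at Δt ∈ {250, 125, 62.5, 31.25} ms
(4–32 bins per segment); gray-segment spikes are excluded. The count in bin
k under stimulus s is treated as Poisson with mean u[s,k], the
trial-averaged count. Mutual information I(S;R) = ⟨log₂ p(r|s)/p(r)⟩ is
computed exactly by enumerating the outcome space when it is small (counts
capped at the 1−10⁻⁶ Poisson quantile, ≤10⁶ points — this enumeration is
also the oracle the Monte-Carlo path is tested against), and otherwise by
sampling (s, r) pairs with the marginal p(r) summed exactly over the
stimulus set (this exact marginal substantially reduces variance). Zero
mean counts are floored at 10⁻⁹ to keep log p(r|s) finite. All information
is reported in bits.

The distribution-free alternative maps counts to levels {0, 1, 2, ≥3} and
replaces the per-bin Poisson pmf by the empirical multinomial over levels;
the joint level-vector information is then computed by the same
enumeration/Monte-Carlo machinery. (A per-bin sum of informations would
ignore across-bin redundancy and can exceed the stimulus entropy; the joint
computation is the meaningful counterpart of the Poisson estimator, and the
two agree within a few percent on matched simulations in the sparse-count
regime.) Plug-in estimates are debiased by quadratic extrapolation: the
estimate is computed at data fractions 1, ½ and ¼ (the reduced fractions
averaged over 20 seeded trial subsamples), a quadratic in x = 1/(fraction ·
n_trials) is fitted, and its value at x = 0 is reported.

## Posterior matrices and α values

With likelihoods from a disjoint training half of the trials and a uniform
prior, each test trial yields a posterior p(s_j|r) by Bayes' rule; the
average posterior matrix row Q̄ᵢ· averages these over the test trials of
stimulus sᵢ. Model and data matrices are compared row by row:

- **MSE α**: per-row mean squared error divided by the mean MSE between the
  data row and seeded within-row permutations of the model row (default
  100 shuffles); 0 = identical, 1 = shuffle-level, values >1 possible and
  never clipped. Rows whose shuffle MSE is zero (constant rows) are excluded
  with a log entry.
- **K–L α**: rows are regularised by the Jeffreys add-½ rule applied on a
  counts-equivalent scale, q̃ = (q·n_trials + 0.5)/(n_trials + 0.5·N_stim),
  then D(real‖model) in bits. The regularisation constant (n_trials = 25)
  is part of the index definition and is held fixed when comparing indices
  computed from different amounts of data — otherwise data-dependent
  shrinkage, not the posteriors, would dominate the comparison. An
  unregularised mode provides the analytic reference: a delta row against a
  uniform row over 30 stimuli gives the 4.9-bit stimulus entropy. The K–L
  direction is a flag; the wording "divergence of the model row with the
  real row" is ambiguous and D(real‖model) is the documented default.
- **J–S α**: plug-in Jensen–Shannon divergence, base 2 (bounded by 1 bit),
  no regularisation needed.

Each index is summarised by the median across rows (the α value).

## Decoding and contrast sensitivity

Population maximum-likelihood decoding treats cells as conditionally
independent: log p(r|s) = Σ_m log p(r^m|s). A trial is correct when the
presented stimulus attains the posterior argmax; ties are resolved to the
lowest option index and counted. Stimulus-independent responses over 7
equiprobable options decode at 1/7.

The 2AFC task presents, per temporal frequency and contrast, either a 1 s
grating segment or uniform gray ("present"/"absent", catch rate ½). Option
profiles are estimated from simulated training trials (mean counts), test
trials are decoded by ML, and the contrast threshold is the lowest grid
contrast with ≥75% correct; sensitivity is its reciprocal (peak-normalised
for display). At zero contrast the two options are identical up to training
noise and performance sits at chance.

## Synthetic ground-truth populations

`make_population` draws cells with difference-of-Gaussians spatial profiles
(centre s.d. 1.2–1.8 px, surround twice as wide at 35% weight, unit L2
norm; ON positive, OFF negative centre — metadata only), biphasic temporal
filters (difference of gamma-like lobes projected onto the basis; the
scotopic preset is slower and more sustained than the photopic one — these
presets are illustrative fixtures, not measured values), and a saturating
logistic-shaped spline nonlinearity r(g) = r_max·sigmoid(gain·(g−g_DC)+s₀)
sampled at 7 knots, anchored so the cell fires at its base rate under
uniform mean-luminance illumination. The lower logistic tail is locally
exponential (so the exponential first stage of the fitter is a good
approximation) and the saturation keeps full-contrast gratings at realistic
peak rates instead of diverging as a pure exponential would. Defaults —
base 1.5–4 spikes/s, saturation 30–60 spikes/s, gain 4–6 — put responses in
the sparse regime where nearly all 62.5 ms bins hold ≤3 spikes.

What the generator deliberately does not emulate: spike-history and
refractory effects, cross-cell noise correlations, adaptation beyond the
linear filter, photoreceptor light adaptation (scotopic/photopic are
parameter presets, not a photoreceptor model), and eye movements. Passing
recovery tests therefore shows the estimator stack is self-consistent on
data generated by the model class, not that the model class captures every
property of real retinal data.

## The recovery harness and problem sizes

`run_recovery` simulates → fits → evaluates end to end, reproducibly under a
master seed (per-stage seeds derive from it by stable hashing). Defaults: 5
cells; 20 min of training data (half binary white noise, half natural
movie, one long trial); 2 min of held-out movie for rate prediction; a
30-stimulus test ensemble (15 gratings at 1–8.25 Hz, 15 natural segments)
presented for 50 trials, split in half for posterior training/testing
(25 test trials per stimulus); information at 62.5 ms bins with 50,000
Monte-Carlo samples. At this scale the harness runs in about a minute on
one CPU and typically yields median filter correlation ≈0.99, held-out rate
correlation ≈0.98, fitted/truth information ratios within a few percent of
1, and α values ≲0.1.

## Known limitations

- The raised-cosine warp constant and the coordinate-ascent schedule are
  config defaults; the fitted basis coefficients are only comparable across
  fits that share them.
- The spline's linear extrapolation means predictions for drives far
  outside the training range are linear in g; training on stimuli whose
  drive spans the test range (the white-noise + natural mix) is what makes
  grating extrapolation benign.
- The quartile estimator truncates at ≥3 spikes per bin and loses
  information when that level is common; it is intended for the sparse
  regime.
- Monte-Carlo information estimates carry O(1/√M) error; the reported s.e.
  should be checked when comparing values closer than a few hundredths of
  a bit.
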