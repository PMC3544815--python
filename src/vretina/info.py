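"""Mutual information between stimuli and spike-count responses.

Responses to 1 s stimulus segments are binned (4, 8, 16 or 32 bins per
segment) and the count in each bin is treated as a Poisson random variable
whose mean is the trial-averaged count for that stimulus and bin.  Mutual
information I(S;R) = <log2 p(r|s)/p(r)> is then estimated either exactly
(enumerating the capped outcome space, used as the brute-force oracle on
small problems) or by Monte Carlo sampling of (s, r) pairs with the marginal
p(r) summed exactly over the stimulus set.  A distribution-free alternative
maps counts to four response levels (0, 1, 2, >=3 spikes) and uses the
plug-in multinomial estimator, debiased by quadratic extrapolation in
inverse sample size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

from .lnp import SpikeRaster
from .stimulus import GRAY_LABEL

logger = logging.getLogger(__name__)

#: Floor for zero mean counts, keeps log p(r|s) finite.
RATE_PROFILE_FLOOR = 1e-9
#: Admissible bin widths for 1 s segments (4, 8, 16, 32 bins).
SEGMENT_BIN_WIDTHS = (0.25, 0.125, 0.0625, 0.03125)
#: Largest enumerable outcome space for the exact estimator.
MAX_ENUMERATION = 10**6


@dataclass
class BinnedResponse:
    """Spike counts per (trial, stimulus, bin) for labelled 1 s segments."""

    counts: np.ndarray  # (n_trials, n_stim, n_bins) non-negative ints
    dt: float
    labels: list[str]
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (trial, stimulus, bin)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.labels) != self.counts.shape[1]:
            raise ValueError("one label per stimulus required")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_stim(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    def subset(self, trial_index: np.ndarray) -> "BinnedResponse":
        ids = None if self.trial_ids is None else self.trial_ids[trial_index]
        return BinnedResponse(self.counts[trial_index], self.dt, self.labels, ids)


@dataclass
class RateProfiles:
    """Trial-averaged mean count per bin and stimulus (u[s, k])."""

    u: np.ndarray  # (n_stim, n_bins)
    dt: float
    labels: list[str]
    n_trials: int = 0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 2:
            raise ValueError("u must be (stimulus, bin)")
        if np.any(self.u < 0):
            raise ValueError("mean counts must be non-negative")


@dataclass
class MIResult:
    """A mutual-information estimate in bits."""

    value: float
    estimator: str
    dt: float
    mc_samples: int = 0
    seed: int | None = None
    debiased: bool = False
    se: float | None = None
    exact: bool = False


def segment_occurrences(frame_labels: np.ndarray, frame_rate: float,
                        segment_duration: float = 1.0):
    """Contiguous non-gray label runs -> (ordered labels, start times per label)."""
    frame_labels = np.asarray(frame_labels, dtype=object)
    starts: dict[str, list[float]] = {}
    order: list[str] = []
    t = 0
    n = frame_labels.size
    n_seg_frames = int(round(segment_duration * frame_rate))
    while t < n:
        lab = frame_labels[t]
        run = t
        while run < n and frame_labels[run] == lab:
            run += 1
        if lab != GRAY_LABEL:
            if run - t != n_seg_frames:
                raise ValueError(
                    f"segment {lab!r} spans {run - t} frames, expected {n_seg_frames}"
                )
            if lab not in starts:
                starts[lab] = []
                order.append(lab)
            starts[lab].append(t / frame_rate)
        t = run
    return order, starts


def bin_counts(
    raster: SpikeRaster,
    frame_labels: np.ndarray,
    dt: float,
    frame_rate: float = 15.0,
    segment_duration: float = 1.0,
) -> BinnedResponse:
    """Bin segment responses into half-open [t, t+dt) bins.

    Gray-segment spikes are excluded.  If a label occurs more than once in
    the stream, each occurrence contributes an additional trial row.
    """
    n_bins_f = segment_duration / dt
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError(f"dt={dt} does not divide the {segment_duration} s segment")
    order, starts = segment_occurrences(frame_labels, frame_rate, segment_duration)
    if not order:
        raise ValueError("no labelled segments in the stream")
    n_occ = {lab: len(starts[lab]) for lab in order}
    if len(set(n_occ.values())) != 1:
        raise ValueError("all labels must occur equally often in the stream")
    occ = next(iter(n_occ.values()))

    counts = np.zeros((raster.n_trials * occ, len(order), n_bins), dtype=int)
    for tr, spikes in enumerate(raster.trials):
        for s_idx, lab in enumerate(order):
            for o_idx, t0 in enumerate(starts[lab]):
                sel = spikes[(spikes >= t0) & (spikes < t0 + segment_duration)]
                rel = (sel - t0) / dt
                idx = np.floor(rel).astype(int)
                # half-open bins despite float error: a spike numerically just
                # below an edge belongs to the bin the edge opens
                idx[rel - idx > 1 - 1e-9] += 1
                idx = np.minimum(idx, n_bins - 1)
                np.add.at(counts[tr * occ + o_idx, s_idx], idx, 1)
    return BinnedResponse(counts=counts, dt=dt, labels=order)


def rate_profiles(binned: BinnedResponse) -> RateProfiles:
    """Mean count per bin across trials (the Poisson intensities u[s, k])."""
    if binned.n_trials < 1:
        raise ValueError("need at least one trial per stimulus")
    return RateProfiles(
        u=binned.counts.mean(axis=0),
        dt=binned.dt,
        labels=list(binned.labels),
        n_trials=binned.n_trials,
    )


def profiles_from_rates(
    rates: np.ndarray,
    frame_rate: float,
    start_times: list[float],
    dt: float,
    labels: list[str],
    segment_duration: float = 1.0,
) -> RateProfiles:
    """Exact expected counts per bin from a piecewise-constant rate series.

    ``start_times[i]`` is the onset of segment ``labels[i]`` within the
    stream whose frame rates are ``rates`` (NaN warm-up treated as 0).
    """
    lam = np.where(np.isnan(rates), 0.0, np.asarray(rates, float))
    frame_dt = 1.0 / frame_rate
    cum = np.concatenate([[0.0], np.cumsum(lam) * frame_dt])
    t_grid = np.arange(lam.size + 1) * frame_dt
    n_bins = int(round(segment_duration / dt))
    u = np.empty((len(labels), n_bins))
    for i, t0 in enumerate(start_times):
        edges = t0 + np.arange(n_bins + 1) * dt
        cum_edges = np.interp(edges, t_grid, cum)
        u[i] = np.diff(cum_edges)
    return RateProfiles(u=u, dt=dt, labels=list(labels), n_trials=0)


def response_log_prob(counts: np.ndarray, u: np.ndarray,
                      floor: float = RATE_PROFILE_FLOOR) -> float:
    """log p(r|s) = sum_k log Pois(n_k; u_k), natural log."""
    counts = np.asarray(counts)
    u = np.asarray(u, dtype=float)
    if counts.shape != u.shape:
        raise ValueError("counts and u must have matching shapes")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    uu = np.maximum(u, floor)
    return float(np.sum(counts * np.log(uu) - uu - gammaln(counts + 1.0)))


def _log_pmf_matrix(counts: np.ndarray, u: np.ndarray,
                    floor: float = RATE_PROFILE_FLOOR) -> np.ndarray:
    """log p(r_m | s_j) for count rows (M, K) against profiles (S, K) -> (M, S)."""
    uu = np.maximum(u, floor)  # (S, K)
    const = -np.sum(gammaln(counts + 1.0), axis=1)  # (M,)
    return counts @ np.log(uu).T - uu.sum(axis=1)[None, :] + const[:, None]


def _enumeration_caps(u: np.ndarray) -> np.ndarray | None:
    umax = u.max(axis=0)
    caps = poisson.ppf(1.0 - 1e-6, np.maximum(umax, RATE_PROFILE_FLOOR)).astype(int)
    caps = np.maximum(caps, 1)
    space = np.prod(caps + 1.0)
    return caps if space <= MAX_ENUMERATION else None


def _mi_exact(u: np.ndarray, prior: np.ndarray, caps: np.ndarray) -> float:
    """Brute-force I(S;R) in bits over the capped outcome space."""
    grids = np.meshgrid(*[np.arange(c + 1) for c in caps], indexing="ij")
    R = np.stack([g.ravel() for g in grids], axis=1)  # (space, K)
    logp = _log_pmf_matrix(R, u)  # (space, S)
    log_pr = logsumexp(logp + np.log(prior)[None, :], axis=1)  # (space,)
    mi = 0.0
    for j in range(u.shape[0]):
        pj = np.exp(logp[:, j])
        mi += prior[j] * np.sum(pj * (logp[:, j] - log_pr))
    return mi / np.log(2.0)


def mutual_information_poisson(
    profiles: RateProfiles,
    prior: np.ndarray | None = None,
    mc_samples: int = 50_000,
    seed: int | None = None,
    force_mc: bool = False,
) -> MIResult:
    """I(S;R) in bits under the independent-Poisson response model.

    When the capped outcome space is small enough the sum over responses is
    enumerated exactly; otherwise (s, r) pairs are drawn by Monte Carlo and
    the marginal p(r) is summed exactly over the stimulus set.
    """
    u = profiles.u
    S = u.shape[0]
    if prior is None:
        prior = np.full(S, 1.0 / S)
    prior = np.asarray(prior, dtype=float)
    if abs(prior.sum() - 1.0) > 1e-9:
        raise ValueError("prior must sum to 1")

    caps = None if force_mc else _enumeration_caps(u)
    if caps is not None:
        value = _mi_exact(u, prior, caps)
        return MIResult(value=value, estimator="poisson_exact", dt=profiles.dt,
                        exact=True)

    if mc_samples < 1000:
        warnings.warn("mc_samples < 1000: Monte-Carlo MI will be noisy")
    rng = np.random.default_rng(seed)
    log_prior = np.log(prior)
    vals = np.empty(mc_samples)
    done = 0
    chunk = 8192
    while done < mc_samples:
        m = min(chunk, mc_samples - done)
        s_idx = rng.choice(S, size=m, p=prior)
        r = rng.poisson(u[s_idx])  # (m, K)
        logp = _log_pmf_matrix(r, u)  # (m, S)
        log_pr = logsumexp(logp + log_prior[None, :], axis=1)
        vals[done:done + m] = logp[np.arange(m), s_idx] - log_pr
        done += m
    vals /= np.log(2.0)
    return MIResult(
        value=float(vals.mean()), estimator="poisson_mc", dt=profiles.dt,
        mc_samples=mc_samples, seed=seed,
        se=float(vals.std(ddof=1) / np.sqrt(mc_samples)),
    )


def _level_probs(counts: np.ndarray) -> np.ndarray:
    """Empirical P(level | s, k) over levels {0,1,2,>=3}, shape (S, K, 4)."""
    levels = np.minimum(counts, 3)  # (trials, S, K)
    n_tr, S, K = levels.shape
    p = np.zeros((S, K, 4))
    for s in range(S):
        for k in range(K):
            p[s, k] = np.bincount(levels[:, s, k], minlength=4) / n_tr
    return p


def _quartile_plugin(counts: np.ndarray, prior: np.ndarray,
                     mc_samples: int, rng: np.random.Generator) -> float:
    """Plug-in MI (bits) of the level-vector response under the empirical
    multinomial model, bins conditionally independent given the stimulus.

    The sum over level vectors is enumerated when the space (4^K) is small;
    otherwise it is estimated by Monte Carlo with the marginal over stimuli
    computed exactly.
    """
    p = _level_probs(counts)  # (S, K, 4)
    S, K, _ = p.shape
    with np.errstate(divide="ignore"):
        logp = np.log(p)  # -inf where a level was never observed
    log_prior = np.log(prior)

    if 4**K <= MAX_ENUMERATION:
        grids = np.meshgrid(*[np.arange(4)] * K, indexing="ij")
        L = np.stack([g.ravel() for g in grids], axis=1)  # (4^K, K)
        ll = logp[:, np.arange(K)[None, :], L].sum(axis=2)  # (S, 4^K)
        with np.errstate(invalid="ignore"):
            log_pr = logsumexp(ll + log_prior[:, None], axis=0)
        mi = 0.0
        for s in range(S):
            mask = np.isfinite(ll[s])
            ps = np.exp(ll[s, mask])
            mi += prior[s] * np.sum(ps * (ll[s, mask] - log_pr[mask]))
        return mi / np.log(2.0)

    vals = np.empty(mc_samples)
    done = 0
    while done < mc_samples:
        m = min(4096, mc_samples - done)
        s_idx = rng.choice(S, size=m, p=prior)
        u = rng.random((m, K, 1))
        cdf = np.cumsum(p[s_idx], axis=2)
        L = (u > cdf[:, :, :-1]).sum(axis=2)  # (m, K) sampled levels
        ll = logp[:, np.arange(K)[None, :], L].sum(axis=2)  # (S, m)
        log_pr = logsumexp(ll + log_prior[:, None], axis=0)
        vals[done:done + m] = ll[s_idx, np.arange(m)] - log_pr
        done += m
    return float(vals.mean() / np.log(2.0))


def mutual_information_quartile(
    binned: BinnedResponse,
    prior: np.ndarray | None = None,
    debias: bool = True,
    n_resamples: int = 20,
    mc_samples: int = 20_000,
    seed: int | None = None,
) -> MIResult:
    """Distribution-free MI over four response levels (0, 1, 2, >=3 spikes).

    Identical in structure to the Poisson estimator but with the per-bin
    count distribution replaced by the empirical multinomial over levels.
    The plug-in estimate is debiased by default using quadratic
    extrapolation over data fractions 1, 1/2 and 1/4, each reduced fraction
    averaged over seeded random trial subsamples.
    """
    if binned.n_trials < 2:
        raise ValueError("need at least 2 trials")
    S = binned.n_stim
    if prior is None:
        prior = np.full(S, 1.0 / S)
    prior = np.asarray(prior, dtype=float)
    rng = np.random.default_rng(seed)

    full = _quartile_plugin(binned.counts, prior, mc_samples, rng)
    if not debias:
        return MIResult(value=full, estimator="quartile", dt=binned.dt,
                        mc_samples=mc_samples, seed=seed)

    fractions = (1.0, 0.5, 0.25)
    values = []
    for frac in fractions:
        n_sub = max(2, int(round(frac * binned.n_trials)))
        if frac == 1.0:
            values.append(full)
            continue
        acc = 0.0
        for _ in range(n_resamples):
            idx = rng.choice(binned.n_trials, size=n_sub, replace=False)
            acc += _quartile_plugin(binned.counts[idx], prior, mc_samples, rng)
        values.append(acc / n_resamples)
    value = debias_quadratic(fractions, values, binned.n_trials)
    return MIResult(value=value, estimator="quartile", dt=binned.dt,
                    mc_samples=mc_samples, seed=seed, debiased=True)


def debias_quadratic(fractions, values, n_trials: int) -> float:
    """Quadratic extrapolation of an estimate to infinite sample size.

    Fits I(x) = I_inf + a*x + b*x^2 with x = 1/(fraction * n_trials) and
    returns I_inf.  At least three distinct fractions (including 1) are
    required.
    """
    fractions = np.asarray(fractions, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.unique(fractions).size < 3:
        raise ValueError("need at least 3 distinct data fractions")
    if not np.any(np.isclose(fractions, 1.0)):
        raise ValueError("fractions must include 1 (the full data)")
    x = 1.0 / (fractions * n_trials)
    coeffs = np.polyfit(x, values, 2)
    return float(np.polyval(coeffs, 0.0))
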