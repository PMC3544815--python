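"""Linear-nonlinear-Poisson (LNP) cells.

A cell is a separable spatiotemporal linear filter (10x10 spatial patch x
10-coefficient raised-cosine temporal filter spanning 18 frame bins of 67 ms)
followed by a static nonlinearity (exponential or 7-knot cubic spline) whose
output is the intensity of an inhomogeneous Poisson spike generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

PATCH_SIZE = 10
#: Temporal filter length in frame bins and the bin width in seconds.
#: One bin per 15 Hz stimulus frame (1/15 s, nominally 67 ms); 18 bins span
#: 1.2 s of stimulus history.
N_TEMPORAL_BINS = 18
TEMPORAL_BIN_WIDTH = 1.0 / 15.0
#: Default log-time warp constant of the raised-cosine basis (seconds).
#: Larger values weaken the warp; 0.5 keeps the 10 bumps distinct on the
#: 18-bin grid while still packing them more densely at short latencies.
DEFAULT_STRETCH = 0.5
#: Minimum admissible firing rate (spikes/s); keeps log-likelihoods finite.
RATE_FLOOR = 1e-3


@dataclass
class TemporalBasis:
    """Raised-cosine temporal basis on a log-warped time axis.

    ``basis`` has shape (n_basis, n_bins); each row is a non-negative bump
    with a single maximum rescaled to peak at 1 on the discrete grid, and
    the rows are linearly independent.
    """

    basis: np.ndarray
    bin_width: float = TEMPORAL_BIN_WIDTH
    stretch: float = DEFAULT_STRETCH

    @property
    def n_basis(self) -> int:
        return self.basis.shape[0]

    @property
    def n_bins(self) -> int:
        return self.basis.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    def filter_from_coeffs(self, coeffs: np.ndarray) -> np.ndarray:
        """Temporal filter (length n_bins) for a coefficient vector."""
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.shape != (self.n_basis,):
            raise ValueError(f"expected {self.n_basis} coefficients")
        return coeffs @ self.basis

    def project(self, waveform: np.ndarray) -> np.ndarray:
        """Least-squares projection of a length-n_bins waveform onto the basis."""
        coeffs, *_ = np.linalg.lstsq(self.basis.T, np.asarray(waveform, float))
        return coeffs


def raised_cosine_basis(
    n_basis: int = 10,
    n_bins: int = N_TEMPORAL_BINS,
    bin_width: float = TEMPORAL_BIN_WIDTH,
    stretch: float = DEFAULT_STRETCH,
) -> TemporalBasis:
    """Build a raised-cosine basis with log-spaced peaks.

    b_j(t) = 0.5 * (1 + cos(pi * clip((phi(t) - c_j) / delta, -1, 1))) with
    phi(t) = log(t + stretch), peaks c_j evenly spaced in phi between the
    first and last bin centres, and delta the peak spacing.  Each row is
    rescaled so its maximum on the grid is exactly 1.
    """
    if n_basis > n_bins:
        raise ValueError("n_basis must not exceed n_bins")
    if n_basis < 2:
        raise ValueError("need at least 2 basis functions")
    t = (np.arange(n_bins) + 0.5) * bin_width
    phi = np.log(t + stretch)
    centers = np.linspace(phi[0], phi[-1], n_basis)
    delta = centers[1] - centers[0]
    arg = np.clip((phi[None, :] - centers[:, None]) / delta, -1.0, 1.0)
    basis = 0.5 * (1.0 + np.cos(np.pi * arg))
    basis /= basis.max(axis=1, keepdims=True)
    return TemporalBasis(basis=basis, bin_width=bin_width, stretch=stretch)


@dataclass
class Nonlinearity:
    """Static rate nonlinearity N(g), clamped below at ``rate_floor``.

    ``exponential``: N(g) = exp(gain * g + offset).
    ``cubic_spline``: natural cubic spline through (knots, coeffs) with
    linear extrapolation beyond the outer knots (slope of the boundary
    cubic at the knot).
    """

    kind: str = "exponential"
    gain: float = 1.0
    offset: float = 0.0
    knots: np.ndarray | None = None
    coeffs: np.ndarray | None = None
    rate_floor: float = RATE_FLOOR

    def __post_init__(self) -> None:
        if self.kind not in ("exponential", "cubic_spline"):
            raise ValueError(f"unknown nonlinearity kind {self.kind!r}")
        if self.kind == "cubic_spline":
            self.knots = np.asarray(self.knots, dtype=float)
            self.coeffs = np.asarray(self.coeffs, dtype=float)
            if self.knots.ndim != 1 or self.knots.shape != self.coeffs.shape:
                raise ValueError("knots and coeffs must be matching 1-D arrays")
            if self.knots.size < 4:
                raise ValueError("a cubic spline needs at least 4 knots")
            if np.any(np.diff(self.knots) <= 0):
                raise ValueError("knots must be strictly increasing")

    def _spline(self) -> CubicSpline:
        return CubicSpline(self.knots, self.coeffs, bc_type="natural")

    def raw(self, g: np.ndarray) -> np.ndarray:
        """Evaluate the nonlinearity without the rate-floor clamp."""
        g = np.asarray(g, dtype=float)
        if self.kind == "exponential":
            return np.exp(self.gain * g + self.offset)
        sp = self._spline()
        out = sp(g)
        lo, hi = self.knots[0], self.knots[-1]
        dlo, dhi = sp(lo, 1), sp(hi, 1)
        out = np.where(g < lo, sp(lo) + dlo * (g - lo), out)
        out = np.where(g > hi, sp(hi) + dhi * (g - hi), out)
        return out

    def __call__(self, g: np.ndarray) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        nan = np.isnan(g)
        out = self.raw(np.where(nan, 0.0, g))
        out = np.maximum(out, self.rate_floor)
        return np.where(nan, np.nan, out)


@dataclass
class LNPCell:
    """A single model ganglion cell.

    The full linear filter is the outer product of ``spatial_weights``
    (10x10, centred at ``rf_center``) and the temporal filter implied by
    ``temporal_coeffs`` on ``basis``.
    """

    rf_center: tuple[int, int]
    spatial_weights: np.ndarray
    temporal_coeffs: np.ndarray
    nonlinearity: Nonlinearity
    basis: TemporalBasis = field(default_factory=raised_cosine_basis)
    polarity: str = "untyped"
    cell_id: str | None = None

    def __post_init__(self) -> None:
        self.spatial_weights = np.asarray(self.spatial_weights, dtype=float)
        self.temporal_coeffs = np.asarray(self.temporal_coeffs, dtype=float)
        if self.spatial_weights.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"spatial_weights must be {PATCH_SIZE}x{PATCH_SIZE}")
        if self.temporal_coeffs.shape != (self.basis.n_basis,):
            raise ValueError("temporal_coeffs must match the basis size")
        if self.polarity not in ("ON", "OFF", "untyped"):
            raise ValueError("polarity must be ON, OFF or untyped")
        energy = np.sum(self.spatial_weights**2) * np.sum(self.temporal_filter**2)
        if energy <= 0:
            raise ValueError("filter energy must be positive")

    @property
    def temporal_filter(self) -> np.ndarray:
        return self.basis.filter_from_coeffs(self.temporal_coeffs)

    @property
    def full_filter(self) -> np.ndarray:
        """Outer-product spatiotemporal filter, shape (n_bins, 10, 10)."""
        return self.temporal_filter[:, None, None] * self.spatial_weights[None, :, :]

    def patch_slices(self) -> tuple[slice, slice]:
        r, c = self.rf_center
        half = PATCH_SIZE // 2
        return slice(r - half, r - half + PATCH_SIZE), slice(c - half, c - half + PATCH_SIZE)


def extract_patch(frames: np.ndarray, cell: LNPCell) -> np.ndarray:
    """Stimulus patch under the cell's receptive field, shape (T, 10, 10)."""
    rs, cs = cell.patch_slices()
    h, w = frames.shape[1], frames.shape[2]
    if rs.start < 0 or cs.start < 0 or rs.stop > h or cs.stop > w:
        raise ValueError(
            f"receptive-field patch rows {rs.start}:{rs.stop}, cols "
            f"{cs.start}:{cs.stop} fall outside the {h}x{w} movie"
        )
    return frames[:, rs, cs]


def linear_drive(cell: LNPCell, movie) -> np.ndarray:
    """Generator signal g(t) = sum_tau sum_p spatial[p] temporal[tau] s(p, t-tau).

    Returned per stimulus frame; bins whose 1.2 s convolution history is
    incomplete (the first n_bins-1 frames) are NaN, not zero-padded.
    """
    if abs(movie.frame_dt - cell.basis.bin_width) > 1e-9:
        raise ValueError(
            f"movie frame duration {movie.frame_dt:.4f}s does not match the "
            f"temporal basis bin width {cell.basis.bin_width:.4f}s"
        )
    patch = extract_patch(movie.frames, cell)
    u = patch.reshape(patch.shape[0], -1) @ cell.spatial_weights.ravel()
    tf = cell.temporal_filter
    g = np.convolve(u, tf)[: u.shape[0]]
    g[: cell.basis.n_bins - 1] = np.nan
    return g


def firing_rate(cell: LNPCell, movie) -> np.ndarray:
    """Firing rate lambda(t) = max(N(g(t)), rate_floor), spikes/s per frame bin.

    Warm-up bins are NaN.  Raises if the nonlinearity produces a non-finite
    rate on any valid bin.
    """
    g = linear_drive(cell, movie)
    lam = cell.nonlinearity(g)
    valid = ~np.isnan(g)
    bad = valid & ~np.isfinite(np.where(valid, lam, 0.0))
    if np.any(bad):
        raise FloatingPointError(
            f"non-finite firing rate at bin {int(np.flatnonzero(bad)[0])}"
        )
    return lam


@dataclass
class SpikeRaster:
    """Per-trial spike times in seconds, within [0, duration)."""

    trials: list[np.ndarray]
    duration: float
    cell_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.trials) < 1:
            raise ValueError("need at least one trial")
        clean = []
        for spikes in self.trials:
            spikes = np.asarray(spikes, dtype=float)
            if spikes.size and (spikes.min() < 0 or spikes.max() >= self.duration):
                raise ValueError("spike times must lie in [0, duration)")
            if np.any(np.diff(spikes) < 0):
                raise ValueError("spike times must be sorted")
            clean.append(spikes)
        self.trials = clean

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trials))


def sample_spikes(
    rates: np.ndarray,
    n_trials: int,
    bin_width: float,
    seed: int | None = None,
    cell_id: str | None = None,
) -> SpikeRaster:
    """Inhomogeneous-Poisson spike trains from a piecewise-constant rate.

    Per trial and bin the count is Poisson(rate * bin_width); spike times are
    placed uniformly within the bin and sorted.  NaN rates (warm-up bins)
    produce no spikes.
    """
    rates = np.asarray(rates, dtype=float)
    lam = np.where(np.isnan(rates), 0.0, rates)
    if np.any(lam < 0):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    duration = rates.size * bin_width
    starts = np.arange(rates.size) * bin_width
    trials = []
    for _ in range(n_trials):
        counts = rng.poisson(lam * bin_width)
        times = np.repeat(starts, counts) + rng.random(int(counts.sum())) * bin_width
        trials.append(np.sort(times))
    return SpikeRaster(trials=trials, duration=duration, cell_id=cell_id)
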