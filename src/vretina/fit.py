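"""Maximum-likelihood fitting of LNP cells.

The public surface follows the familiar Model/Results pattern: build an
:class:`LNPEncoder` from a stimulus movie and a spike raster, call
``.fit()``, and receive an :class:`LNPFitResults` carrying the fitted cell,
the log-likelihood trajectory and diagnostics.

The Poisson log-likelihood of a spike train under rate lambda(t) is

    Z = sum_i log lambda(t_i) - integral lambda(t) dt,

discretised per frame bin as ``n_bin * log(lambda_bin) - lambda_bin * dt``.
Fitting proceeds in two stages: first the linear filters are optimised by
blockwise coordinate ascent under an exponential nonlinearity (for which Z
is concave in each block), then the exponential is replaced by a 7-knot
natural cubic spline and spline coefficients and filters are alternated
until the per-spike log-likelihood change falls below tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize
from scipy.signal import lfilter

from .lnp import (
    PATCH_SIZE,
    RATE_FLOOR,
    LNPCell,
    Nonlinearity,
    SpikeRaster,
    TemporalBasis,
    extract_patch,
    firing_rate,
    raised_cosine_basis,
    sample_spikes,
)

logger = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Tuning knobs of the two-stage fit.

    ``tol`` is the convergence tolerance on the change of the per-spike
    log-likelihood (nats/spike) between outer iterations.
    """

    max_outer_iters: int = 50
    tol: float = 1e-6
    stage1_iters: int = 15
    n_knots: int = 7
    spline_stage: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_knots < 4:
            raise ValueError("a cubic spline needs at least 4 knots")


def place_knots(g: np.ndarray, n_knots: int = 7) -> np.ndarray:
    """Spline knots evenly spaced over the range of the generator signal."""
    g = np.asarray(g, dtype=float)
    g = g[~np.isnan(g)]
    if g.size == 0 or g.max() <= g.min():
        raise ValueError("degenerate generator signal: max(g) must exceed min(g)")
    return np.linspace(g.min(), g.max(), n_knots)


def log_likelihood(cell: LNPCell, movie, raster: SpikeRaster) -> float:
    """Total Poisson log-likelihood Z (nats) of a raster under a cell.

    Warm-up bins (incomplete convolution history) are excluded; spikes that
    fall in them are dropped with a logged count.
    """
    lam = firing_rate(cell, movie)
    dt = movie.frame_dt
    y, n_excluded = _bin_spikes(raster, lam.size, dt)
    valid = ~np.isnan(lam)
    if n_excluded and np.any(~valid):
        warm = int(np.sum(y[~valid]))
        if warm:
            logger.info("excluded %d spikes in warm-up bins from Z", warm)
    lam_v = lam[valid]
    return float(np.sum(y[valid] * np.log(lam_v)) - raster.n_trials * dt * np.sum(lam_v))


def _bin_spikes(raster: SpikeRaster, n_bins: int, dt: float) -> tuple[np.ndarray, int]:
    """Spike counts per frame bin summed over trials."""
    y = np.zeros(n_bins)
    dropped = 0
    for spikes in raster.trials:
        idx = np.floor(spikes / dt).astype(int)
        inside = idx < n_bins
        dropped += int(np.sum(~inside))
        np.add.at(y, idx[inside], 1)
    return y, dropped


def _spline_design(knots: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Matrix A with A @ knot_values = spline(g) (natural cubic, linear
    extrapolation); evaluation is linear in the knot values."""
    n = knots.size
    cols = []
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        nl = Nonlinearity(kind="cubic_spline", knots=knots, coeffs=e)
        cols.append(nl.raw(g))
    return np.stack(cols, axis=1)


def _spline_deriv(knots: np.ndarray, yk: np.ndarray, g: np.ndarray) -> np.ndarray:
    sp = CubicSpline(knots, yk, bc_type="natural")
    d = sp(np.clip(g, knots[0], knots[-1]), 1)
    return d


class LNPEncoder:
    """LNP encoding model of one cell, built from a movie and a raster.

    Parameters
    ----------
    movie : StimulusMovie
        Training stimulus; frame duration must match the temporal basis
        bin width (15 Hz frames for the default 67 ms basis).
    raster : SpikeRaster
        Observed spike trains (one or more trials of the same movie).
    rf_center : (row, col), optional
        Centre of the 10x10 receptive-field patch.  If omitted it is taken
        at the pixel of maximal spike-triggered-average energy.
    basis : TemporalBasis, optional
    config : FitConfig, optional
    """

    def __init__(
        self,
        movie,
        raster: SpikeRaster,
        rf_center: tuple[int, int] | None = None,
        basis: TemporalBasis | None = None,
        config: FitConfig | None = None,
    ):
        self.movie = movie
        self.raster = raster
        self.basis = basis if basis is not None else raised_cosine_basis()
        self.config = config if config is not None else FitConfig()
        if abs(movie.frame_dt - self.basis.bin_width) > 1e-9:
            raise ValueError("movie frame duration must equal the basis bin width")
        if raster.n_spikes < 1:
            raise ValueError("raster must contain at least one spike")
        self._dt = movie.frame_dt
        self._T = movie.n_frames
        self._y, dropped = _bin_spikes(raster, self._T, self._dt)
        if dropped:
            logger.warning("%d spikes beyond the movie duration were dropped", dropped)
        self._valid = np.zeros(self._T, dtype=bool)
        self._valid[self.basis.n_bins - 1 :] = True
        if rf_center is None:
            rf_center = self._locate_rf()
        self.rf_center = (int(rf_center[0]), int(rf_center[1]))
        probe = LNPCell(
            rf_center=self.rf_center,
            spatial_weights=np.ones((PATCH_SIZE, PATCH_SIZE)),
            temporal_coeffs=np.ones(self.basis.n_basis),
            nonlinearity=Nonlinearity(),
            basis=self.basis,
        )
        patch = extract_patch(movie.frames, probe) - movie.mean_luminance
        self._P = patch.reshape(self._T, -1)

    # ------------------------------------------------------------------
    def _full_sta(self) -> np.ndarray:
        """Spike-triggered average over the whole frame, shape (n_bins, H, W)."""
        frames = self.movie.frames - self.movie.mean_luminance
        n_bins = self.basis.n_bins
        yv = np.where(self._valid, self._y, 0.0)
        total = yv.sum()
        if total == 0:
            raise ValueError("no spikes in valid bins")
        sta = np.empty((n_bins,) + frames.shape[1:])
        for tau in range(n_bins):
            sta[tau] = np.tensordot(yv[tau:], frames[: self._T - tau], axes=(0, 0)) / total
        return sta

    def _locate_rf(self) -> tuple[int, int]:
        sta = self._full_sta()
        energy = np.sum(sta**2, axis=0)
        r, c = np.unravel_index(np.argmax(energy), energy.shape)
        h, w = energy.shape
        half = PATCH_SIZE // 2
        r = int(np.clip(r, half, h - half))
        c = int(np.clip(c, half, w - half))
        return r, c

    def sta(self) -> np.ndarray:
        """Spike-triggered average on the 10x10 patch, shape (n_bins, 10, 10)."""
        n_bins = self.basis.n_bins
        yv = np.where(self._valid, self._y, 0.0)
        sta = np.empty((n_bins, self._P.shape[1]))
        for tau in range(n_bins):
            sta[tau] = yv[tau:] @ self._P[: self._T - tau] / yv.sum()
        return sta.reshape(n_bins, PATCH_SIZE, PATCH_SIZE)

    # ------------------------------------------------------------------
    def _drive(self, w: np.ndarray, c: np.ndarray) -> np.ndarray:
        u = self._P @ w
        tf = self.basis.filter_from_coeffs(c)
        return lfilter(tf, [1.0], u)

    def _dc_drive(self, w: np.ndarray, c: np.ndarray) -> float:
        """Drive of the raw (uncentred) stimulus mean through the filter."""
        tf = self.basis.filter_from_coeffs(c)
        return float(self.movie.mean_luminance * w.sum() * tf.sum())

    def _temporal_design(self, w: np.ndarray) -> np.ndarray:
        u = self._P @ w
        return np.stack(
            [lfilter(self.basis.basis[j], [1.0], u) for j in range(self.basis.n_basis)],
            axis=1,
        )

    def _spatial_design(self, c: np.ndarray) -> np.ndarray:
        tf = self.basis.filter_from_coeffs(c)
        return lfilter(tf, [1.0], self._P, axis=0)

    def _z_exp(self, g: np.ndarray, b: float) -> float:
        lam = np.exp(g[self._valid] + b)
        return float(np.sum(self._y[self._valid] * (g[self._valid] + b))
                     - self.raster.n_trials * self._dt * np.sum(lam))

    def _fit_exp_block(self, D: np.ndarray, beta0: np.ndarray, b0: float):
        """Concave Poisson-GLM step: maximize Z over (beta, intercept)."""
        Dv = D[self._valid]
        yv = self._y[self._valid]
        scale = self.raster.n_trials * self._dt

        def negloglik(theta):
            g = Dv @ theta[:-1] + theta[-1]
            g = np.clip(g, -50, 50)
            lam = np.exp(g)
            f = -(yv @ g - scale * lam.sum())
            resid = yv - scale * lam
            grad = -np.concatenate([Dv.T @ resid, [resid.sum()]])
            return f, grad

        theta0 = np.concatenate([beta0, [b0]])
        res = minimize(negloglik, theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 200})
        theta = res.x if res.fun <= negloglik(theta0)[0] else theta0
        return theta[:-1], float(theta[-1])

    def _fit_spline_coeffs(self, A: np.ndarray, yk0: np.ndarray) -> np.ndarray:
        Av = A[self._valid]
        yv = self._y[self._valid]
        scale = self.raster.n_trials * self._dt

        def negloglik(yk):
            raw = Av @ yk
            lam = np.maximum(raw, RATE_FLOOR)
            active = raw > RATE_FLOOR
            f = -(yv @ np.log(lam) - scale * lam.sum())
            grad = -(Av.T @ ((yv / lam - scale) * active))
            return f, grad

        res = minimize(negloglik, yk0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 200})
        return res.x if res.fun <= negloglik(yk0)[0] else yk0

    def _fit_spline_filter_block(self, D: np.ndarray, beta0: np.ndarray,
                                 knots: np.ndarray, yk: np.ndarray) -> np.ndarray:
        Dv = D[self._valid]
        yv = self._y[self._valid]
        scale = self.raster.n_trials * self._dt
        nl = Nonlinearity(kind="cubic_spline", knots=knots, coeffs=yk)

        def negloglik(beta):
            g = Dv @ beta
            raw = nl.raw(g)
            lam = np.maximum(raw, RATE_FLOOR)
            active = raw > RATE_FLOOR
            der = _spline_deriv(knots, yk, g)
            f = -(yv @ np.log(lam) - scale * lam.sum())
            grad = -(Dv.T @ ((yv / lam - scale) * der * active))
            return f, grad

        res = minimize(negloglik, beta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 100})
        return res.x if res.fun <= negloglik(beta0)[0] else beta0

    # ------------------------------------------------------------------
    def loglike(self, cell: LNPCell) -> float:
        """Z (nats) of the training raster under an arbitrary cell."""
        return log_likelihood(cell, self.movie, self.raster)

    def fit(self, start=None) -> "LNPFitResults":
        """Run the two-stage maximum-likelihood fit.

        ``start`` optionally provides ``(spatial_flat, temporal_coeffs,
        offset)`` to override the spike-triggered-average initialisation.
        """
        cfg = self.config
        n_spikes = float(self._y[self._valid].sum())
        if n_spikes == 0:
            raise ValueError("no spikes in valid bins")

        if start is None:
            sta = self.sta().reshape(self.basis.n_bins, -1)
            U, S, Vt = np.linalg.svd(sta, full_matrices=False)
            t_wave = U[:, 0] * S[0]
            w = Vt[0].copy()
            c = self.basis.project(t_wave)
        else:
            w = np.asarray(start[0], dtype=float).copy()
            c = np.asarray(start[1], dtype=float).copy()
        nrm = np.linalg.norm(c)
        if nrm == 0:
            raise ValueError("degenerate temporal initialisation")
        w *= nrm
        c /= nrm
        # scale the initial drive to unit variance so exp() starts well-posed
        g0 = self._drive(w, c)
        sd = np.nanstd(g0[self._valid])
        if sd > 0:
            w /= sd
        mean_rate = n_spikes / (self.raster.n_trials * self._dt * self._valid.sum())
        b = float(start[2]) if start is not None else float(np.log(max(mean_rate, RATE_FLOOR)))

        traj: list[float] = []
        # ---- stage 1: exponential nonlinearity, blockwise coordinate ascent
        z = self._z_exp(self._drive(w, c), b)
        traj.append(z)
        for _ in range(cfg.stage1_iters):
            w, b = self._fit_exp_block(self._spatial_design(c), w, b)
            c, b = self._fit_exp_block(self._temporal_design(w), c, b)
            nrm = np.linalg.norm(c)
            w, c = w * nrm, c / nrm
            z_new = self._z_exp(self._drive(w, c), b)
            traj.append(z_new)
            if abs(z_new - z) / n_spikes < cfg.tol:
                z = z_new
                break
            z = z_new

        if not cfg.spline_stage:
            # the design is mean-centred; absorb the DC drive of the raw
            # stimulus into the nonlinearity so the cell stands alone
            dc = self._dc_drive(w, c)
            cell = LNPCell(
                rf_center=self.rf_center, spatial_weights=w.reshape(PATCH_SIZE, PATCH_SIZE),
                temporal_coeffs=c, basis=self.basis,
                nonlinearity=Nonlinearity(kind="exponential", gain=1.0, offset=b - dc),
            )
            return LNPFitResults(self, cell, traj, True, len(traj) - 1)

        # ---- stage 2: replace the exponential by a 7-knot cubic spline
        g = self._drive(w, c)
        knots = place_knots(g[self._valid], cfg.n_knots)
        yk = np.exp(knots + b)  # warm start: spline through the exponential curve

        converged = False
        n_outer = 0

        def z_spline(g, knots, yk):
            lam = np.maximum(_spline_design(knots, g[self._valid]) @ yk, RATE_FLOOR)
            return float(np.sum(self._y[self._valid] * np.log(lam))
                         - self.raster.n_trials * self._dt * np.sum(lam))

        z = z_spline(g, knots, yk)
        traj.append(z)
        best = (z, w.copy(), c.copy(), knots.copy(), yk.copy())
        for n_outer in range(1, cfg.max_outer_iters + 1):
            # re-span the knots when the filter updates have shifted or
            # rescaled the drive materially: the spline must cover the drive
            # range rather than operate on its linear extrapolation
            gv = g[self._valid]
            span = knots[-1] - knots[0]
            drift = max(knots[0] - gv.min(), gv.max() - knots[-1])
            shrunk = (gv.max() - gv.min()) < 0.5 * span
            if n_outer <= 10 and (drift > 0.05 * span or shrunk):
                new_knots = place_knots(gv, cfg.n_knots)
                old_nl = Nonlinearity(kind="cubic_spline", knots=knots, coeffs=yk)
                knots, yk = new_knots, old_nl.raw(new_knots)
            A = _spline_design(knots, g)
            yk = self._fit_spline_coeffs(A, yk)
            w = self._fit_spline_filter_block(self._spatial_design(c), w, knots, yk)
            c = self._fit_spline_filter_block(self._temporal_design(w), c, knots, yk)
            nrm = np.linalg.norm(c)
            w, c = w * nrm, c / nrm
            g = self._drive(w, c)
            z_new = z_spline(g, knots, yk)
            traj.append(z_new)
            if z_new >= best[0]:
                best = (z_new, w.copy(), c.copy(), knots.copy(), yk.copy())
            if abs(z_new - z) / n_spikes < cfg.tol:
                z = z_new
                converged = True
                break
            z = z_new
        if not converged:
            logger.warning("fit reached max_outer_iters without converging; "
                           "returning the best iterate (Z=%.2f)", best[0])
        _, w, c, knots, yk = best

        dc = self._dc_drive(w, c)
        cell = LNPCell(
            rf_center=self.rf_center, spatial_weights=w.reshape(PATCH_SIZE, PATCH_SIZE),
            temporal_coeffs=c, basis=self.basis,
            nonlinearity=Nonlinearity(kind="cubic_spline", knots=knots + dc, coeffs=yk),
        )
        return LNPFitResults(self, cell, traj, converged, n_outer)


@dataclass
class LNPFitResults:
    """Results of an :class:`LNPEncoder` fit."""

    model: LNPEncoder
    cell: LNPCell
    z_trajectory: list[float] = field(default_factory=list)
    converged: bool = True
    n_iterations: int = 0

    @property
    def loglike(self) -> float:
        return self.z_trajectory[-1]

    @property
    def loglike_per_spike(self) -> float:
        return self.z_trajectory[-1] / self.model.raster.n_spikes

    def predict(self, movie) -> np.ndarray:
        """Firing rate lambda(t) of the fitted cell on a movie (spikes/s)."""
        return firing_rate(self.cell, movie)

    def simulate(self, movie, n_trials: int, seed: int | None = None) -> SpikeRaster:
        """Poisson spike trains of the fitted cell in response to a movie."""
        rates = self.predict(movie)
        return sample_spikes(rates, n_trials, movie.frame_dt, seed=seed,
                             cell_id=self.cell.cell_id)

    def summary(self) -> str:
        nl = self.cell.nonlinearity
        lines = [
            "LNP encoder fit",
            "=" * 46,
            f"n trials            {self.model.raster.n_trials:>12d}",
            f"n spikes            {self.model.raster.n_spikes:>12d}",
            f"rf center           {str(self.cell.rf_center):>12s}",
            f"nonlinearity        {nl.kind:>12s}",
            f"outer iterations    {self.n_iterations:>12d}",
            f"converged           {str(self.converged):>12s}",
            f"Z initial (nats)    {self.z_trajectory[0]:>12.2f}",
            f"Z final (nats)      {self.z_trajectory[-1]:>12.2f}",
            f"Z/spike (nats)      {self.loglike_per_spike:>12.4f}",
        ]
        if nl.kind == "cubic_spline":
            lines.append(f"knot range          [{nl.knots[0]:.3f}, {nl.knots[-1]:.3f}]")
        return "\n".join(lines)
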