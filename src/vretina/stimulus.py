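"""Synthetic visual stimuli: binary white noise, drifting gratings, and
natural-like movies with power-law spectra.

All movies are luminance frame stacks (time x height x width) in abstract
linear luminance units, presented at a nominal 15 Hz. Test stimuli are
organised as 1 s segments interleaved with 333 ms of uniform gray; each
segment is one element of a discrete stimulus set with a uniform prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Default frame rate of all stimuli (Hz).
DEFAULT_FRAME_RATE = 15.0
#: Default patch geometry (height, width) in pixels.
DEFAULT_GEOMETRY = (32, 32)
#: Degrees of visual angle per pixel.  Chosen so that a 0.058 cyc/deg grating
#: puts ~4 cycles across a 32-pixel patch (0.125 cyc/px / 0.058 cyc/deg).
DEFAULT_DEG_PER_PIXEL = 0.125 / 0.058
#: Default mean luminance and RMS contrast (abstract linear units; the
#: numerical values mirror a photopic recording condition of ~1.7 units mean,
#: 0.27 units RMS).
DEFAULT_MEAN_LUMINANCE = 1.7
DEFAULT_RMS_CONTRAST = 0.27

GRAY_LABEL = "GRAY"


@dataclass
class StimulusMovie:
    """A luminance movie: ``frames[t, y, x]`` at a fixed frame rate.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Non-negative linear luminance values.
    frame_rate : float
        Frames per second.
    deg_per_pixel : float
        Degrees of visual angle subtended by one pixel.
    mean_luminance, rms_contrast : float
        Nominal first and second moments, same units as ``frames``.
    """

    frames: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    deg_per_pixel: float = DEFAULT_DEG_PER_PIXEL
    mean_luminance: float = DEFAULT_MEAN_LUMINANCE
    rms_contrast: float = DEFAULT_RMS_CONTRAST

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (time, height, width) array")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames must be finite")
        if np.any(self.frames < 0):
            raise ValueError("luminance must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.deg_per_pixel <= 0:
            raise ValueError("deg_per_pixel must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def geometry(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def frame_dt(self) -> float:
        return 1.0 / self.frame_rate

    def concatenate(self, other: "StimulusMovie") -> "StimulusMovie":
        if self.geometry != other.geometry:
            raise ValueError("cannot concatenate movies with mismatched geometries")
        if self.frame_rate != other.frame_rate:
            raise ValueError("cannot concatenate movies with mismatched frame rates")
        return StimulusMovie(
            np.concatenate([self.frames, other.frames], axis=0),
            frame_rate=self.frame_rate,
            deg_per_pixel=self.deg_per_pixel,
            mean_luminance=self.mean_luminance,
            rms_contrast=self.rms_contrast,
        )


@dataclass
class StimulusEnsemble:
    """An ordered set of labelled 1 s stimulus segments with a uniform prior.

    Segments are interleaved with ``t_gray`` seconds of uniform gray when
    assembled into a presentation stream.
    """

    segments: list[tuple[str, StimulusMovie]]
    t_seg: float = 1.0
    t_gray: float = 0.333
    prior: dict[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.segments]
        if len(set(labels)) != len(labels):
            raise ValueError("segment labels must be distinct")
        if GRAY_LABEL in labels:
            raise ValueError(f"label {GRAY_LABEL!r} is reserved")
        geoms = {m.geometry for _, m in self.segments}
        rates = {m.frame_rate for _, m in self.segments}
        if len(geoms) > 1 or len(rates) > 1:
            raise ValueError("all segments must share geometry and frame rate")
        if self.prior is None:
            self.prior = {lab: 1.0 / len(labels) for lab in labels}
        total = sum(self.prior.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("prior must sum to 1")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.segments]

    @property
    def n_stim(self) -> int:
        return len(self.segments)

    @property
    def frame_rate(self) -> float:
        return self.segments[0][1].frame_rate

    def prior_array(self) -> np.ndarray:
        return np.array([self.prior[lab] for lab in self.labels])

    def entropy_bits(self) -> float:
        """Entropy of the stimulus prior in bits (log2 N_stim when uniform)."""
        p = self.prior_array()
        p = p[p > 0]
        return float(-np.sum(p * np.log2(p)))


def _check_geometry(geometry: tuple[int, int]) -> tuple[int, int]:
    h, w = geometry
    if h < 1 or w < 1:
        raise ValueError("geometry must be at least 1x1")
    return int(h), int(w)


def make_drifting_grating(
    temporal_freq: float,
    spatial_freq: float,
    contrast: float,
    mean_luminance: float = DEFAULT_MEAN_LUMINANCE,
    duration: float = 1.0,
    geometry: tuple[int, int] = DEFAULT_GEOMETRY,
    frame_rate: float = DEFAULT_FRAME_RATE,
    deg_per_pixel: float = DEFAULT_DEG_PER_PIXEL,
    seed: int | None = None,
) -> StimulusMovie:
    """Drifting sine-wave grating, drifting along the horizontal axis.

    luminance(x, t) = mean * (1 + contrast * sin(2*pi*(w*x - f*t))) with
    ``w`` in cycles/deg, ``x`` in degrees and ``f`` in Hz; phase 0 at
    t = 0, x = 0.  ``seed`` is accepted for interface uniformity but the
    generator is deterministic.
    """
    del seed
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must be in [0, 1]")
    if temporal_freq <= 0 or spatial_freq <= 0:
        raise ValueError("frequencies must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    nyquist = 1.0 / (2.0 * deg_per_pixel)
    if spatial_freq > nyquist:
        raise ValueError(
            f"spatial frequency {spatial_freq:g} cyc/deg exceeds the Nyquist "
            f"limit {nyquist:g} cyc/deg for {deg_per_pixel:g} deg/pixel"
        )
    h, w = _check_geometry(geometry)
    n_frames = int(round(duration * frame_rate))
    t = np.arange(n_frames) / frame_rate
    x = np.arange(w) * deg_per_pixel
    phase = 2.0 * np.pi * (spatial_freq * x[None, :] - temporal_freq * t[:, None])
    profile = mean_luminance * (1.0 + contrast * np.sin(phase))  # (T, W)
    frames = np.repeat(profile[:, None, :], h, axis=1)
    return StimulusMovie(
        frames,
        frame_rate=frame_rate,
        deg_per_pixel=deg_per_pixel,
        mean_luminance=mean_luminance,
        rms_contrast=contrast * mean_luminance / np.sqrt(2.0),
    )


def make_uniform_gray(
    mean_luminance: float = DEFAULT_MEAN_LUMINANCE,
    duration: float = 1.0,
    geometry: tuple[int, int] = DEFAULT_GEOMETRY,
    frame_rate: float = DEFAULT_FRAME_RATE,
    deg_per_pixel: float = DEFAULT_DEG_PER_PIXEL,
) -> StimulusMovie:
    """Uniform gray movie at the stated mean luminance."""
    h, w = _check_geometry(geometry)
    n_frames = int(round(duration * frame_rate))
    frames = np.full((n_frames, h, w), float(mean_luminance))
    return StimulusMovie(
        frames,
        frame_rate=frame_rate,
        deg_per_pixel=deg_per_pixel,
        mean_luminance=mean_luminance,
        rms_contrast=0.0,
    )


def make_binary_white_noise(
    mean_luminance: float = DEFAULT_MEAN_LUMINANCE,
    amplitude: float = DEFAULT_RMS_CONTRAST,
    duration: float = 1.0,
    geometry: tuple[int, int] = DEFAULT_GEOMETRY,
    frame_rate: float = DEFAULT_FRAME_RATE,
    deg_per_pixel: float = DEFAULT_DEG_PER_PIXEL,
    seed: int | None = None,
) -> StimulusMovie:
    """Binary spatiotemporal white noise: each pixel-frame independently takes
    ``mean_luminance +/- amplitude`` with probability 1/2.
    """
    if amplitude > mean_luminance:
        raise ValueError("amplitude must not exceed mean_luminance (luminance >= 0)")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    h, w = _check_geometry(geometry)
    n_frames = int(round(duration * frame_rate))
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_frames, h, w)) * 2 - 1
    frames = mean_luminance + amplitude * signs
    return StimulusMovie(
        frames,
        frame_rate=frame_rate,
        deg_per_pixel=deg_per_pixel,
        mean_luminance=mean_luminance,
        rms_contrast=amplitude,
    )


def make_natural_movie(
    temporal_exponent: float = 2.04,
    spatial_exponent: float = 2.09,
    mean_luminance: float = DEFAULT_MEAN_LUMINANCE,
    rms_contrast: float = DEFAULT_RMS_CONTRAST,
    duration: float = 1.0,
    geometry: tuple[int, int] = DEFAULT_GEOMETRY,
    frame_rate: float = DEFAULT_FRAME_RATE,
    deg_per_pixel: float = DEFAULT_DEG_PER_PIXEL,
    seed: int | None = None,
) -> StimulusMovie:
    """Natural-like movie synthesised from separable power-law spectra.

    A Gaussian random field is shaped in the Fourier domain so that temporal
    power falls as 1/f^temporal_exponent and spatial power as
    1/w^spatial_exponent (w = radial spatial frequency), with random phases.
    The field is then rescaled to the target mean and RMS contrast and clipped
    at zero luminance; if more than 1% of pixel-frames are clipped a warning
    is logged.
    """
    if temporal_exponent < 0 or spatial_exponent < 0:
        raise ValueError("spectral exponents must be non-negative")
    h, w = _check_geometry(geometry)
    n_frames = int(round(duration * frame_rate))
    if n_frames < 2:
        raise ValueError("duration too short for spectral synthesis")
    rng = np.random.default_rng(seed)

    white = rng.standard_normal((n_frames, h, w))
    spectrum = np.fft.fftn(white)

    f = np.abs(np.fft.fftfreq(n_frames, d=1.0 / frame_rate))
    kx = np.fft.fftfreq(w, d=deg_per_pixel)
    ky = np.fft.fftfreq(h, d=deg_per_pixel)
    wrad = np.sqrt(kx[None, :] ** 2 + ky[:, None] ** 2)

    with np.errstate(divide="ignore"):
        amp_t = np.where(f > 0, f ** (-temporal_exponent / 2.0), 0.0)
        amp_s = np.where(wrad > 0, wrad ** (-spatial_exponent / 2.0), 0.0)
    if temporal_exponent == 0:
        amp_t = np.ones_like(f)
    if spatial_exponent == 0:
        amp_s = np.ones_like(wrad)

    shaped = np.fft.ifftn(spectrum * amp_t[:, None, None] * amp_s[None, :, :]).real
    shaped -= shaped.mean()
    sd = shaped.std()
    if sd == 0:
        raise ValueError("degenerate spectrum: field has zero variance")
    frames = mean_luminance + rms_contrast * shaped / sd

    clipped_mass = np.mean(frames < 0)
    if clipped_mass > 0.01:
        logger.warning(
            "natural movie: %.2f%% of pixel-frames clipped at zero luminance; "
            "reduce rms_contrast relative to mean_luminance",
            100 * clipped_mass,
        )
    np.clip(frames, 0.0, None, out=frames)
    return StimulusMovie(
        frames,
        frame_rate=frame_rate,
        deg_per_pixel=deg_per_pixel,
        mean_luminance=mean_luminance,
        rms_contrast=rms_contrast,
    )


def assemble_stream(
    ensemble: StimulusEnsemble,
    order: list[str] | None = None,
    repeats: int = 1,
) -> tuple[StimulusMovie, np.ndarray]:
    """Concatenate segments into a presentation stream with gray separators.

    Returns the stream movie and a per-frame label track; gray separator
    frames are labelled ``GRAY``.  The number of gray frames is
    ``round(t_gray * frame_rate)`` (5 frames for 333 ms at 15 Hz).
    """
    if order is None:
        order = ensemble.labels
    unknown = set(order) - set(ensemble.labels)
    if unknown:
        raise ValueError(f"labels not in ensemble: {sorted(unknown)}")
    by_label = dict(ensemble.segments)
    if not order or repeats == 0:
        first = ensemble.segments[0][1]
        empty = StimulusMovie(
            np.zeros((0,) + first.geometry),
            frame_rate=first.frame_rate,
            deg_per_pixel=first.deg_per_pixel,
            mean_luminance=first.mean_luminance,
            rms_contrast=0.0,
        )
        return empty, np.array([], dtype=object)

    first = by_label[order[0]]
    n_gray = int(round(ensemble.t_gray * first.frame_rate))
    gray = np.full((n_gray,) + first.geometry, first.mean_luminance)

    blocks: list[np.ndarray] = []
    labels: list[str] = []
    for _ in range(repeats):
        for lab in order:
            seg = by_label[lab]
            if seg.geometry != first.geometry:
                raise ValueError("mismatched segment geometries")
            blocks.append(seg.frames)
            labels.extend([lab] * seg.n_frames)
            blocks.append(gray)
            labels.extend([GRAY_LABEL] * n_gray)
    frames = np.concatenate(blocks, axis=0)
    movie = StimulusMovie(
        frames,
        frame_rate=first.frame_rate,
        deg_per_pixel=first.deg_per_pixel,
        mean_luminance=first.mean_luminance,
        rms_contrast=first.rms_contrast,
    )
    return movie, np.array(labels, dtype=object)


def estimate_spectrum_exponent(
    movie: StimulusMovie,
    axis: str = "time",
    fit_band: tuple[float, float] | None = None,
) -> float:
    """Estimate the power-law exponent of a movie's spectrum along one axis.

    ``axis='time'``: the per-pixel temporal periodogram is averaged over
    pixels.  ``axis='space'``: the 2-D spatial periodogram is averaged over
    frames and treated as a function of radial frequency.  A least-squares
    line is fitted to log power vs log frequency over ``fit_band`` (Hz or
    cyc/deg; default = all resolvable non-zero frequencies) and the negative
    slope is returned.
    """
    frames = movie.frames
    if axis == "time":
        if movie.n_frames < 64:
            raise ValueError("need at least 64 frames for a temporal spectrum")
        x = frames.reshape(movie.n_frames, -1)
        x = x - x.mean(axis=0, keepdims=True)
        power = np.mean(np.abs(np.fft.rfft(x, axis=0)) ** 2, axis=1)
        freqs = np.fft.rfftfreq(movie.n_frames, d=movie.frame_dt)
        mask = freqs > 0
    elif axis == "space":
        h, w = movie.geometry
        if min(h, w) < 8 or movie.n_frames < 1:
            raise ValueError("spatial grid too small for a spectrum estimate")
        centered = frames - frames.mean(axis=(1, 2), keepdims=True)
        power2d = np.mean(np.abs(np.fft.fftn(centered, axes=(1, 2))) ** 2, axis=0)
        kx = np.fft.fftfreq(w, d=movie.deg_per_pixel)
        ky = np.fft.fftfreq(h, d=movie.deg_per_pixel)
        wrad = np.sqrt(kx[None, :] ** 2 + ky[:, None] ** 2)
        nyq = 1.0 / (2.0 * movie.deg_per_pixel)
        power = power2d.ravel()
        freqs = wrad.ravel()
        mask = (freqs > 0) & (freqs <= nyq)
    else:
        raise ValueError("axis must be 'time' or 'space'")

    if fit_band is not None:
        lo, hi = fit_band
        mask &= (freqs >= lo) & (freqs <= hi)
    mask &= power > 0
    if mask.sum() < 4:
        raise ValueError("fit_band leaves too few resolvable frequencies")
    slope = np.polyfit(np.log(freqs[mask]), np.log(power[mask]), 1)[0]
    return float(-slope)
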