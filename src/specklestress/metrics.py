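"""Speckle activity coefficients from a video frame stack.

Three scalar activity measures are computed per clip:

* the relaxation time of a stretched-exponential decay fitted to the
  frame-to-frame decorrelation curve (``tau``, with ``tau_star = ln(tau)``
  and stretch exponent ``beta``),
* the temporal speckle contrast (``tlasca``): per-pixel temporal
  standard deviation over temporal mean, averaged over the image,
* the inertia moment (``im``) of the gray-level co-occurrence matrix
  built from time-adjacent values of each pixel's time history.

All standard deviations use the sample (``ddof=1``) convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .stacks import FrameStack

__all__ = [
    "DecorrelationCurve",
    "StretchedExpFit",
    "SpeckleCoefficients",
    "AnalysisConfig",
    "NoMeasurableDecayError",
    "compute_decorrelation_curve",
    "fit_stretched_exponential",
    "compute_tlasca",
    "compute_inertia_moment",
    "analyze_stack",
]

logger = logging.getLogger(__name__)


class NoMeasurableDecayError(ValueError):
    """Raised when a decorrelation curve shows no measurable decay."""


@dataclass(frozen=True)
class DecorrelationCurve:
    """Correlation coefficient versus time lag for one frame stack.

    ``corr[k]`` is the Pearson correlation between pixel-intensity vectors
    of frame pairs separated by ``lags[k]`` seconds, averaged over all such
    pairs (``n_pairs[k]`` of them).  ``corr[0]`` is identically 1.
    """

    lags: np.ndarray
    corr: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        corr = np.asarray(self.corr, dtype=float)
        n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (len(lags) == len(corr) == len(n_pairs)):
            raise ValueError("lags, corr and n_pairs must have equal length")
        if len(lags) < 3:
            raise ValueError(f"need at least 3 lags, got {len(lags)}")
        if lags[0] != 0 or np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing and start at 0")
        if abs(corr[0] - 1.0) > 1e-12:
            raise ValueError(f"corr at lag 0 must equal 1, got {corr[0]!r}")
        if np.any(corr < -1 - 1e-12) or np.any(corr > 1 + 1e-12):
            raise ValueError("corr values must lie in [-1, 1]")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "corr", corr)
        object.__setattr__(self, "n_pairs", n_pairs)


@dataclass(frozen=True)
class StretchedExpFit:
    """Parameters of ``corr(t) = exp(-(t/tau)**beta)`` fitted to a curve."""

    tau: float
    beta: float
    rmse: float
    converged: bool

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not (0 < self.beta <= 2):
            raise ValueError(f"beta must be in (0, 2], got {self.beta}")
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")

    @property
    def tau_star(self) -> float:
        """Natural log of the relaxation time."""
        return float(np.log(self.tau))


@dataclass(frozen=True)
class SpeckleCoefficients:
    """Per-clip scalar activity measures for one laser channel."""

    fit: StretchedExpFit | None
    tlasca: float
    inertia_moment: float
    channel: str = ""
    source_id: str = ""
    fit_error: str | None = None

    def __post_init__(self) -> None:
        if self.tlasca < 0:
            raise ValueError("tlasca must be non-negative")
        if self.inertia_moment < 0:
            raise ValueError("inertia_moment must be non-negative")
        if self.fit is None and self.fit_error is None:
            raise ValueError("either fit or fit_error must be set")


@dataclass(frozen=True)
class AnalysisConfig:
    """Shared configuration for computing all three coefficients."""

    max_lag_frames: int | None = None  # None -> half the clip length
    corr_mode: Literal["all_pairs", "first_frame"] = "all_pairs"
    glcm_levels: int | None = None  # None -> 2**bit_depth (no re-quantization)
    glcm_symmetric: bool = False
    glcm_bin_range: Literal["bit_depth", "data"] = "bit_depth"
    zero_mean_policy: Literal["exclude", "raise"] = "exclude"
    decay_tolerance: float = 1e-6
    max_iterations: int = 1000


def _standardized_pixel_vectors(stack: FrameStack) -> np.ndarray:
    """Flatten frames to (time, pixel) and z-score each frame (ddof=1).

    With rows standardized this way, ``Z @ Z.T / (n_pixels - 1)`` is the
    matrix of pairwise Pearson correlation coefficients between frames.
    """
    x = stack.frames.reshape(stack.n_frames, -1).astype(np.float64)
    mean = x.mean(axis=1, keepdims=True)
    std = x.std(axis=1, ddof=1, keepdims=True)
    degenerate = np.flatnonzero(std[:, 0] == 0)
    if degenerate.size:
        raise ValueError(
            f"frame {degenerate[0]} has zero variance across pixels; "
            "Pearson correlation is undefined"
        )
    return (x - mean) / std


def compute_decorrelation_curve(
    stack: FrameStack,
    max_lag_frames: int,
    mode: Literal["all_pairs", "first_frame"] = "all_pairs",
) -> DecorrelationCurve:
    """Correlation between frame pairs at each lag from 0..max_lag_frames.

    In ``all_pairs`` mode (default) the Pearson coefficient at lag ``k``
    is averaged over every pair of frames ``k`` apart; in ``first_frame``
    mode only the pair ``(frame 0, frame k)`` is used.

    Raises
    ------
    ValueError
        If ``max_lag_frames`` is not in ``[1, n_frames)`` or any frame is
        spatially constant (zero pixel variance).
    """
    if not 1 <= max_lag_frames < stack.n_frames:
        raise ValueError(
            f"max_lag_frames must be in [1, {stack.n_frames - 1}], got {max_lag_frames}"
        )
    z = _standardized_pixel_vectors(stack)
    n_pixels = z.shape[1]
    gram = (z @ z.T) / (n_pixels - 1)

    lags = np.arange(max_lag_frames + 1) / stack.fps
    corr = np.empty(max_lag_frames + 1)
    n_pairs = np.empty(max_lag_frames + 1, dtype=int)
    for k in range(max_lag_frames + 1):
        if mode == "all_pairs":
            diag = np.diagonal(gram, offset=k)
            corr[k] = diag.mean()
            n_pairs[k] = diag.size
        elif mode == "first_frame":
            corr[k] = gram[0, k]
            n_pairs[k] = 1
        else:
            raise ValueError(f"unknown mode {mode!r}")
    corr[0] = 1.0  # exact by construction; clamp float residue
    np.clip(corr, -1.0, 1.0, out=corr)
    return DecorrelationCurve(lags=lags, corr=corr, n_pairs=n_pairs)


def _kww(t: np.ndarray, tau: float, beta: float) -> np.ndarray:
    return np.exp(-((t / tau) ** beta))


def fit_stretched_exponential(
    curve: DecorrelationCurve,
    decay_tolerance: float = 1e-6,
    max_iterations: int = 1000,
) -> StretchedExpFit:
    """Least-squares fit of ``exp(-(t/tau)**beta)`` to a decorrelation curve.

    The lag-0 point is excluded from the residual (the model passes
    through 1 exactly).  ``beta`` is bounded to ``(0.05, 2]`` and ``tau``
    to ``[lag_min/100, 100*lag_max]``.  Non-convergence within the
    iteration budget yields ``converged=False`` with best-so-far
    parameters rather than an exception.

    Raises
    ------
    ValueError
        If fewer than 3 positive-lag points are available.
    NoMeasurableDecayError
        If every correlation value is within ``decay_tolerance`` of 1.
    """
    pos = curve.lags > 0
    t = curve.lags[pos]
    y = curve.corr[pos]
    if t.size < 3:
        raise ValueError(f"need at least 3 positive-lag points, got {t.size}")
    if np.all(curve.corr >= 1 - decay_tolerance):
        raise NoMeasurableDecayError(
            "no measurable decay: all correlation values are at 1 within tolerance"
        )

    # Initial tau: first lag where corr drops below 1/e; fallback median lag.
    below = np.flatnonzero(y < np.exp(-1.0))
    tau0 = float(t[below[0]]) if below.size else float(np.median(t))
    lo = np.array([t[0] / 100.0, 0.05])
    hi = np.array([100.0 * t[-1], 2.0])
    x0 = np.clip([tau0, 1.0], lo, hi)

    result = least_squares(
        lambda p: _kww(t, p[0], p[1]) - y,
        x0=x0,
        bounds=(lo, hi),
        max_nfev=max_iterations,
        method="trf",
    )
    tau, beta = result.x
    rmse = float(np.sqrt(np.mean(result.fun**2)))
    return StretchedExpFit(
        tau=float(tau),
        beta=float(beta),
        rmse=rmse,
        converged=bool(result.success),
    )


def compute_tlasca(
    stack: FrameStack,
    zero_mean_policy: Literal["exclude", "raise"] = "exclude",
) -> float:
    """Temporal speckle contrast averaged over the spatial domain.

    Per pixel: temporal standard deviation (ddof=1) over temporal mean
    across all frames; the result is the spatial mean of these per-pixel
    ratios.  Pixels with zero temporal mean are excluded (with a logged
    count) by default, or raise under the ``"raise"`` policy.
    """
    x = stack.frames.astype(np.float64)
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=1)
    zero = mean == 0
    n_zero = int(zero.sum())
    if n_zero:
        if zero_mean_policy == "raise":
            raise ValueError(f"{n_zero} pixel(s) have zero temporal mean")
        logger.info("tlasca: excluded %d zero-temporal-mean pixel(s)", n_zero)
        if n_zero == zero.size:
            raise ValueError("all pixels have zero temporal mean")
    ratio = std[~zero] / mean[~zero]
    return float(ratio.mean())


def compute_inertia_moment(
    stack: FrameStack,
    levels: int | None = None,
    symmetric: bool = False,
    bin_range: Literal["bit_depth", "data"] = "bit_depth",
) -> float:
    """GLCM inertia moment of the time-history speckle pattern.

    Each pixel's time history forms one row of the THSP matrix; the GLCM
    accumulates ordered pairs of time-consecutive quantized values and is
    normalized by its total sum.  Returns ``sum GLCM[i,j] * (i - j)**2``.

    ``levels`` defaults to ``2**bit_depth`` (no re-quantization).  With
    ``bin_range="bit_depth"`` values are binned equal-width over
    ``[0, 2**bit_depth - 1]``; with ``"data"`` the bins span the observed
    data range instead (making the result invariant to intensity scaling).
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    n_levels = 2 ** stack.bit_depth if levels is None else int(levels)
    if n_levels < 2:
        raise ValueError(f"levels must be >= 2, got {n_levels}")
    if n_levels > 2 ** stack.bit_depth:
        raise ValueError(
            f"levels ({n_levels}) exceeds 2**bit_depth = {2 ** stack.bit_depth}"
        )

    if bin_range == "bit_depth":
        lo, span = 0.0, float(2 ** stack.bit_depth)
        q = (stack.frames * (n_levels / span)).astype(np.int64)
    elif bin_range == "data":
        lo = float(stack.frames.min())
        span = float(stack.frames.max()) - lo
        if span == 0:
            q = np.zeros(stack.frames.shape, dtype=np.int64)
        else:
            q = ((stack.frames - lo) * (n_levels / (span * (1 + 1e-12)))).astype(np.int64)
    else:
        raise ValueError(f"unknown bin_range {bin_range!r}")
    np.clip(q, 0, n_levels - 1, out=q)

    i = q[:-1].ravel()
    j = q[1:].ravel()
    counts = np.bincount(i * n_levels + j, minlength=n_levels * n_levels)
    counts = counts.reshape(n_levels, n_levels)
    if symmetric:
        counts = counts + counts.T
    idx = np.arange(n_levels, dtype=np.int64)
    weight = (idx[:, None] - idx[None, :]) ** 2
    # integer numerator is exact in int64 for any realistic stack size,
    # so normalization reduces to a single float division
    return float(int((counts * weight).sum()) / int(counts.sum()))


def analyze_stack(
    stack: FrameStack,
    channel: str = "",
    config: AnalysisConfig | None = None,
) -> SpeckleCoefficients:
    """Compute all three speckle coefficients with shared configuration.

    Deterministic for a fixed stack and configuration.  A fit failure
    (e.g. a static clip with no measurable decay) is captured in the
    ``fit_error`` field rather than raised, so tLASCA and IM are still
    reported.
    """
    cfg = config or AnalysisConfig()
    max_lag = cfg.max_lag_frames if cfg.max_lag_frames is not None else max(stack.n_frames // 2, 1)
    max_lag = min(max_lag, stack.n_frames - 1)

    fit: StretchedExpFit | None = None
    fit_error: str | None = None
    try:
        curve = compute_decorrelation_curve(stack, max_lag, mode=cfg.corr_mode)
        fit = fit_stretched_exponential(
            curve,
            decay_tolerance=cfg.decay_tolerance,
            max_iterations=cfg.max_iterations,
        )
    except (ValueError, NoMeasurableDecayError) as exc:
        fit_error = str(exc)

    tlasca = compute_tlasca(stack, zero_mean_policy=cfg.zero_mean_policy)
    im = compute_inertia_moment(
        stack,
        levels=cfg.glcm_levels,
        symmetric=cfg.glcm_symmetric,
        bin_range=cfg.glcm_bin_range,
    )
    return SpeckleCoefficients(
        fit=fit,
        tlasca=tlasca,
        inertia_moment=im,
        channel=channel,
        source_id=stack.source_id,
        fit_error=fit_error,
    )
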