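"""Synthetic dynamic-speckle video with known ground-truth dynamics.

The simulator draws a complex circular-Gaussian field whose temporal
field correlation is ``g1(dt) = exp(-(dt/tau_field)**beta_field)`` and
whose spatial correlation (speckle grain size) comes from Fourier-domain
low-pass filtering; intensity is the squared modulus of the field.  By
the Siegert relation the intensity correlation then decays as
``|g1|**2``, i.e. a stretched exponential with relaxation time
``tau_field * 2**(-1/beta_field)`` and the same stretch exponent — a
closed-form target for the estimators in :mod:`specklestress.metrics`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.linalg import cholesky, toeplitz, LinAlgError

from .stacks import FrameStack

__all__ = [
    "SpeckleSimConfig",
    "simulate_speckle_stack",
    "analytic_intensity_correlation",
    "siegert_tau",
]

# fraction of the intensity dynamic range at which the 99.9th percentile
# is placed before rounding, to avoid saturation-induced correlation bias
_HEADROOM = 0.9
_P999_EXPONENTIAL = -np.log(1e-3)  # 99.9th percentile of a unit exponential


@dataclass(frozen=True)
class SpeckleSimConfig:
    """Configuration for one simulated speckle clip."""

    n_frames: int = 300
    height: int = 64
    width: int = 64
    fps: float = 30.0
    tau_field: float = 0.5
    beta_field: float = 1.0
    grain_px: float = 2.0
    noise_sigma: float = 0.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.height < 1 or self.width < 1:
            raise ValueError("height and width must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.tau_field <= 0:
            raise ValueError("tau_field must be positive")
        if not (0 < self.beta_field <= 2):
            raise ValueError("beta_field must be in (0, 2]")
        if self.grain_px < 1:
            raise ValueError("grain_px must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def _temporal_mixing_matrix(config: SpeckleSimConfig) -> np.ndarray:
    """Cholesky factor of the Toeplitz temporal covariance of the field."""
    dt = np.arange(config.n_frames) / config.fps
    g1 = np.exp(-((dt / config.tau_field) ** config.beta_field))
    cov = toeplitz(g1)
    cov[np.diag_indices_from(cov)] += 1e-10
    try:
        return cholesky(cov, lower=True)
    except LinAlgError as exc:
        raise ValueError(
            "temporal covariance is not positive definite after jitter; "
            "try fewer frames or a larger beta_field"
        ) from exc


def _spatial_lowpass_mask(height: int, width: int, grain_px: float) -> np.ndarray:
    """Circular low-pass mask in FFT coordinates with cutoff ~ 1/grain_px."""
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    cutoff = 0.5 / grain_px
    return (np.sqrt(fy**2 + fx**2) <= cutoff).astype(np.float64)


def simulate_speckle_stack(config: SpeckleSimConfig) -> FrameStack:
    """Generate a dynamic speckle clip, reproducible from ``config.seed``.

    Intensity is scaled so its 99.9th percentile maps to 90% of the
    dynamic range before quantization; additive Gaussian camera noise is
    applied on the gray-level scale prior to rounding.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.n_frames, config.height, config.width)

    field = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2)
    if config.grain_px > 1:
        mask = _spatial_lowpass_mask(config.height, config.width, config.grain_px)
        field = np.fft.ifft2(np.fft.fft2(field, axes=(1, 2)) * mask, axes=(1, 2))

    mixing = _temporal_mixing_matrix(config)
    field = np.tensordot(mixing, field, axes=(1, 0))

    intensity = np.abs(field) ** 2
    max_value = 2 ** config.bit_depth - 1
    p999 = np.percentile(intensity, 99.9)
    if p999 > 0:
        intensity *= _HEADROOM * max_value / p999
    if config.noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sigma, size=shape)

    dtype = np.uint8 if config.bit_depth <= 8 else np.uint16
    frames = np.clip(np.rint(intensity), 0, max_value).astype(dtype)
    return FrameStack(
        frames=frames,
        fps=config.fps,
        bit_depth=config.bit_depth,
        source_id=f"sim-tau{config.tau_field}-beta{config.beta_field}-seed{config.seed}",
    )


def siegert_tau(tau_field: float, beta_field: float) -> float:
    """Intensity-correlation relaxation time implied by the field dynamics.

    ``|g1|**2 = exp(-2 (dt/tau_field)**beta) = exp(-(dt/tau')**beta)``
    with ``tau' = tau_field * 2**(-1/beta)``.
    """
    return tau_field * 2.0 ** (-1.0 / beta_field)


def analytic_intensity_correlation(
    config: SpeckleSimConfig, lags: np.ndarray
) -> np.ndarray:
    """Siegert-predicted intensity Pearson correlation at the given lags.

    Noise-free: ``|g1(dt)|**2``.  With camera noise the correlation is
    attenuated by ``var_signal / (var_signal + noise_sigma**2)``, where
    the signal variance uses the fully developed speckle statistics
    (unit contrast) at the simulator's quantization scaling.
    """
    lags = np.asarray(lags, dtype=float)
    g1_sq = np.exp(-2.0 * (lags / config.tau_field) ** config.beta_field)
    if config.noise_sigma == 0:
        return g1_sq
    max_value = 2 ** config.bit_depth - 1
    mean_gray = _HEADROOM * max_value / _P999_EXPONENTIAL
    var_signal = mean_gray**2  # exponential intensity: var = mean**2
    attenuation = var_signal / (var_signal + config.noise_sigma**2)
    return attenuation * g1_sq
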