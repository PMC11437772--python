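"""Synthetic experiment-level datasets with a known stress-onset structure.

Generates per-apple multi-signal time courses (log relaxation times for
two laser channels, chlorophyll fluorescence, CO2 respiration rate) over
a preconditioning -> zero-oxygen -> transition -> normal protocol, plus
per-apple phenotypes and a ground-truth table, so labeling and
classification are testable without any real data.

Signal dynamics are phenomenological: a logistic step at a per-apple
onset (a lagged response to oxygen removal) to an elevated plateau, a
logistic relaxation after the atmosphere is restored (respiration stays
elevated through the final hour), and AR(1) noise.  The red-channel
signal gets larger between-apple variance than the infrared one, and a
configurable fraction of apples shows no fluorescence response at all
(low chlorophyll content).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .timeseries import (
    EPOCH_COLUMNS,
    LABEL_AEROBIC,
    LABEL_STRESS,
    PHENOTYPE_COLUMNS,
    sphere_equivalent_area,
)

__all__ = ["ExperimentSimConfig", "simulate_experiment"]

SIGNALS = ("tau_star_ir", "tau_star_red", "cf", "respiration")

_DEFAULT_EFFECT_SIZES = {"tau_star_ir": 8.0, "tau_star_red": 8.0, "cf": 8.0, "respiration": 6.0}
_DEFAULT_NOISE_SIGMAS = {"tau_star_ir": 0.04, "tau_star_red": 0.06, "cf": 3.0, "respiration": 0.05}

# baseline level (mean, between-apple sd); red gets the larger spread
_BASELINES = {
    "tau_star_ir": (0.0, 0.05),
    "tau_star_red": (0.2, 0.30),
    "cf": (100.0, 10.0),
    "respiration": (1.0, 0.10),
}

# apple phenotypes: mean, sd (mass g, firmness N, soluble solids %)
_PHENOTYPE_DIST = {"mass": (163.92, 12.87), "firmness": (41.15, 3.32), "ssc": (12.67, 0.92)}
_APPLE_DENSITY_G_CM3 = 0.80


@dataclass(frozen=True)
class ExperimentSimConfig:
    """Configuration for one synthetic climate-chamber experiment."""

    n_apples: int = 15
    epoch_minutes: float = 8.0
    phase_durations_h: tuple[float, float, float, float] = (2.0, 3.25, 0.25, 1.0)
    onset_delay_h: float = 2.1
    onset_jitter_h: float = 1.0 / 6.0  # exponential jitter scale (10 min)
    effect_sizes: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_EFFECT_SIZES))
    noise_sigmas: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE_SIGMAS))
    ar_coeff: float = 0.3
    chlorophyll_low_fraction: float = 0.2
    rise_width_h: float = 8.0 / 60.0 / 2.0  # logistic rise over ~2 epochs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_apples < 1:
            raise ValueError("n_apples must be positive")
        if self.epoch_minutes <= 0:
            raise ValueError("epoch_minutes must be positive")
        if any(d <= 0 for d in self.phase_durations_h):
            raise ValueError("phase durations must be positive")
        if not 0 <= self.chlorophyll_low_fraction <= 1:
            raise ValueError("chlorophyll_low_fraction must be in [0, 1]")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("ar_coeff must be in [0, 1)")
        missing = set(SIGNALS) - set(self.effect_sizes)
        if missing:
            raise ValueError(f"effect_sizes missing signal(s): {sorted(missing)}")
        if any(v < 0 for v in self.effect_sizes.values()):
            raise ValueError("effect sizes must be non-negative")
        if any(v < 0 for v in self.noise_sigmas.values()):
            raise ValueError("noise sigmas must be non-negative")

    @property
    def total_h(self) -> float:
        return float(sum(self.phase_durations_h))

    @property
    def o2_removal_h(self) -> float:
        """Time at which oxygen is removed (end of preconditioning)."""
        return self.phase_durations_h[0]

    @property
    def restore_h(self) -> float:
        """Time at which the normal atmosphere starts being restored."""
        return self.phase_durations_h[0] + self.phase_durations_h[1]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phase_durations_h"] = list(self.phase_durations_h)
        return d


def _phase_at(config: ExperimentSimConfig, t: np.ndarray) -> np.ndarray:
    bounds = np.cumsum(config.phase_durations_h)
    names = ("preconditioning", "zero_oxygen", "transition", "normal")
    idx = np.searchsorted(bounds, t, side="right")
    idx = np.clip(idx, 0, len(names) - 1)
    return np.array([names[i] for i in idx])


def _ar1_noise(rng: np.random.Generator, n: int, sigma: float, ar: float) -> np.ndarray:
    """AR(1) noise with stationary marginal sd ``sigma``."""
    if sigma == 0:
        return np.zeros(n)
    innov_sd = sigma * np.sqrt(1 - ar**2)
    noise = np.empty(n)
    noise[0] = rng.normal(0, sigma)
    for i in range(1, n):
        noise[i] = ar * noise[i - 1] + rng.normal(0, innov_sd)
    return noise


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def simulate_experiment(
    config: ExperimentSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one experiment; returns (epochs, phenotypes, truth).

    The epochs table matches the ingestion schema of
    :mod:`specklestress.timeseries` exactly (``tau_red``/``tau_ir`` are
    emitted on the seconds scale, i.e. ``exp`` of the generated log
    values).  The truth table records the per-apple onset epoch and the
    per-epoch true physiological state: an epoch is truly stressed where
    the clean (noise-free) step profile of the relaxation-time response
    is at least half its plateau height.
    """
    rng = np.random.default_rng(config.seed)
    step_h = config.epoch_minutes / 60.0
    times = np.arange(0.0, config.total_h, step_h)
    n_epochs = times.size
    phases = _phase_at(config, times)

    n_low_cf = int(round(config.chlorophyll_low_fraction * config.n_apples))
    low_cf_apples = rng.choice(config.n_apples, size=n_low_cf, replace=False)

    epoch_rows, pheno_rows, truth_rows = [], [], []
    for a in range(config.n_apples):
        apple_id = f"apple_{a + 1:02d}"
        onset = (
            config.o2_removal_h
            + config.onset_delay_h
            - config.onset_jitter_h
            + rng.exponential(config.onset_jitter_h)
        )
        # clean step profile shared by the stress-responsive signals:
        # logistic rise at onset, logistic fall after atmosphere restoration
        rise = _logistic((times - onset) / config.rise_width_h)
        fall = _logistic((times - config.restore_h - config.rise_width_h) / config.rise_width_h)
        profile = rise * (1.0 - fall)
        sustained = rise  # respiration stays elevated through the final hour

        # with all effect sizes zero nothing physiological happens
        responsive = any(config.effect_sizes[sig] > 0 for sig in SIGNALS)
        truly_stressed = (profile >= 0.5) if responsive else np.zeros(n_epochs, dtype=bool)
        onset_epoch = int(np.argmax(truly_stressed)) if truly_stressed.any() else -1

        values: dict[str, np.ndarray] = {}
        for sig in SIGNALS:
            mu, spread = _BASELINES[sig]
            base = rng.normal(mu, spread)
            sigma = config.noise_sigmas[sig]
            effect = config.effect_sizes[sig] * sigma
            if sig == "cf" and a in low_cf_apples:
                effect = 0.0
            shape = sustained if sig == "respiration" else profile
            values[sig] = base + effect * shape + _ar1_noise(rng, n_epochs, sigma, config.ar_coeff)

        epoch_rows.append(
            pd.DataFrame(
                {
                    "apple_id": apple_id,
                    "time_h": times,
                    "phase": phases,
                    "cf": values["cf"],
                    "respiration": values["respiration"],
                    "tau_red": np.exp(values["tau_star_red"]),
                    "tau_ir": np.exp(values["tau_star_ir"]),
                }
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "apple_id": apple_id,
                    "time_h": times,
                    "onset_epoch": onset_epoch,
                    "onset_h": onset,
                    "true_state": np.where(truly_stressed, LABEL_STRESS, LABEL_AEROBIC),
                    "cf_responsive": a not in low_cf_apples,
                }
            )
        )

        mass = rng.normal(*_PHENOTYPE_DIST["mass"])
        volume = mass / _APPLE_DENSITY_G_CM3 * rng.normal(1.0, 0.02)
        pheno_rows.append(
            {
                "apple_id": apple_id,
                "mass": mass,
                "firmness": rng.normal(*_PHENOTYPE_DIST["firmness"]),
                "ssc": rng.normal(*_PHENOTYPE_DIST["ssc"]),
                "volume": volume,
            }
        )

    epochs = pd.concat(epoch_rows, ignore_index=True)[EPOCH_COLUMNS]
    phenotypes = pd.DataFrame(pheno_rows)[PHENOTYPE_COLUMNS]
    phenotypes["area"] = sphere_equivalent_area(phenotypes["volume"].to_numpy())
    truth = pd.concat(truth_rows, ignore_index=True)
    return epochs, phenotypes, truth
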