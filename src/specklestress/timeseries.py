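"""Per-apple, per-epoch signal tables: transforms and expert labeling.

The epoch table carries one row per (apple, epoch) with the raw signals
(relaxation times per laser channel, minimum chlorophyll fluorescence,
CO2 respiration rate) and the experiment phase.  This module applies the
modelling transforms — natural log of the relaxation times, first
derivative of respiration, optional per-apple normalization of the
fluorescence signal, sphere-equivalent surface area — and implements the
2-of-3 "considerable change" rule that produces ground-truth stress
labels.
"""

from __future__ import annotations

import logging
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "LABEL_AEROBIC",
    "LABEL_STRESS",
    "EPOCH_COLUMNS",
    "PHENOTYPE_COLUMNS",
    "first_derivative",
    "sphere_equivalent_area",
    "detect_considerable_change",
    "expert_label",
    "prepare_timeline",
    "read_epochs_csv",
    "read_phenotypes_csv",
]

logger = logging.getLogger(__name__)

PHASES = ("preconditioning", "zero_oxygen", "transition", "normal")
LABEL_AEROBIC = "aerobic"
LABEL_STRESS = "hypoxic_stress"

EPOCH_COLUMNS = ["apple_id", "time_h", "phase", "cf", "respiration", "tau_red", "tau_ir"]
PHENOTYPE_COLUMNS = ["apple_id", "mass", "firmness", "ssc", "volume"]

# MAD -> sigma for a normal distribution
_MAD_SCALE = 1.4826


def first_derivative(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """First derivative by central differences (one-sided at endpoints).

    ``times`` are in hours and must be strictly increasing; the output has
    the same length as the input and is exact for linear signals.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(np.diff(times) == 0):
        raise ValueError("duplicate timestamps")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be strictly increasing")
    return np.gradient(values, times)


def sphere_equivalent_area(volume: float | np.ndarray) -> float | np.ndarray:
    """Surface area of a sphere with the given volume: 4*pi*(3V/4pi)^(2/3)."""
    volume = np.asarray(volume, dtype=float)
    if np.any(volume <= 0):
        raise ValueError("volume must be positive")
    area = 4.0 * np.pi * (3.0 * volume / (4.0 * np.pi)) ** (2.0 / 3.0)
    return float(area) if area.ndim == 0 else area


def detect_considerable_change(
    series: Sequence[float] | np.ndarray,
    baseline: slice | np.ndarray,
    k: float = 3.0,
    direction: Literal["increase", "decrease", "both"] = "increase",
    relative_fallback: float = 0.10,
) -> np.ndarray:
    """Flag epochs whose value departs considerably from a baseline window.

    An epoch is flagged when the deviation from the baseline median, in
    the signal's stress direction, exceeds ``k`` times the MAD-scaled
    baseline sigma.  If the baseline has zero dispersion the rule falls
    back to a relative-change threshold (default 10% of the baseline
    median, logged).

    Parameters
    ----------
    series
        Signal values, one per epoch.
    baseline
        Slice or boolean/index array selecting the baseline epochs; must
        be non-empty.
    k
        Threshold multiplier on the robust baseline sigma.
    direction
        Which direction counts as stress: values above ("increase"),
        below ("decrease") the baseline median, or either ("both").

    Returns
    -------
    Boolean array, one flag per epoch (baseline epochs included).
    """
    values = np.asarray(series, dtype=float)
    base = values[baseline]
    if base.size == 0:
        raise ValueError("baseline window is empty")
    center = float(np.median(base))
    mad = float(np.median(np.abs(base - center)))
    sigma = _MAD_SCALE * mad
    if sigma == 0:
        logger.info(
            "zero baseline dispersion; falling back to %.0f%% relative threshold",
            100 * relative_fallback,
        )
        threshold = abs(center) * relative_fallback
        if threshold == 0:
            threshold = np.finfo(float).eps
    else:
        threshold = k * sigma
    deviation = values - center
    if direction == "increase":
        return deviation > threshold
    if direction == "decrease":
        return -deviation > threshold
    if direction == "both":
        return np.abs(deviation) > threshold
    raise ValueError(f"unknown direction {direction!r}")


def _baseline_mask(group: pd.DataFrame, baseline_phase: str) -> np.ndarray:
    mask = (group["phase"] == baseline_phase).to_numpy()
    if not mask.any():
        raise ValueError(
            f"apple {group['apple_id'].iloc[0]!r} has no epochs in baseline "
            f"phase {baseline_phase!r}"
        )
    return mask


def expert_label(
    records: pd.DataFrame,
    k: float = 3.0,
    baseline_phase: str = "preconditioning",
    tau_channel: Literal["ir", "red", "either"] = "ir",
) -> pd.DataFrame:
    """Apply the 2-of-3 considerable-change rule per apple.

    The three indicator signals are the log relaxation time
    (``tau_star_ir`` / ``tau_star_red`` per ``tau_channel``), chlorophyll
    fluorescence (``cf``) and the respiration-rate level
    (``respiration``); each is compared against its own baseline taken
    from the ``baseline_phase`` epochs of the same apple.  A row is
    labeled ``hypoxic_stress`` when at least two signals flag, else
    ``aerobic``.  Deterministic; no cross-apple information is used.

    Returns a copy with added boolean columns ``flag_tau``, ``flag_cf``,
    ``flag_respiration`` and a string ``label`` column.
    """
    required = {"apple_id", "phase", "cf", "respiration"}
    tau_cols = {
        "ir": ["tau_star_ir"],
        "red": ["tau_star_red"],
        "either": ["tau_star_ir", "tau_star_red"],
    }[tau_channel]
    missing = sorted((required | set(tau_cols)) - set(records.columns))
    if missing:
        raise ValueError(f"missing signal column(s): {', '.join(missing)}")

    out = records.copy()
    for col in ("flag_tau", "flag_cf", "flag_respiration"):
        out[col] = False
    out["label"] = LABEL_AEROBIC

    for _, group in out.groupby("apple_id", sort=False):
        base = _baseline_mask(group, baseline_phase)
        flag_tau = np.zeros(len(group), dtype=bool)
        for col in tau_cols:
            flag_tau |= detect_considerable_change(group[col].to_numpy(), base, k=k)
        flag_cf = detect_considerable_change(group["cf"].to_numpy(), base, k=k)
        flag_resp = detect_considerable_change(group["respiration"].to_numpy(), base, k=k)
        votes = flag_tau.astype(int) + flag_cf.astype(int) + flag_resp.astype(int)
        out.loc[group.index, "flag_tau"] = flag_tau
        out.loc[group.index, "flag_cf"] = flag_cf
        out.loc[group.index, "flag_respiration"] = flag_resp
        out.loc[group.index, "label"] = np.where(votes >= 2, LABEL_STRESS, LABEL_AEROBIC)
    return out


def prepare_timeline(
    epochs: pd.DataFrame,
    phenotypes: pd.DataFrame | None = None,
    normalize_cf: bool = True,
    baseline_phase: str = "preconditioning",
) -> pd.DataFrame:
    """Apply modelling transforms to a raw epoch table.

    Adds ``tau_star_red``/``tau_star_ir`` (natural log of the relaxation
    times), ``d_respiration`` (per-apple first derivative of the
    respiration rate, units/h) and, when ``normalize_cf`` is set, divides
    each apple's ``cf`` by its baseline median.  If a phenotype table is
    given it is joined on ``apple_id`` with a ``area`` column derived
    from the sphere-equivalent model.
    """
    _validate_columns(epochs, EPOCH_COLUMNS, "epochs")
    out = epochs.copy()
    for apple_id, group in out.groupby("apple_id", sort=False):
        times = group["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"apple {apple_id!r}: time_h must be strictly increasing")
        if np.any(times < 0):
            raise ValueError(f"apple {apple_id!r}: time_h must be non-negative")

    if (out[["tau_red", "tau_ir"]] <= 0).any().any():
        raise ValueError("relaxation times must be positive for the log transform")
    out["tau_star_red"] = np.log(out["tau_red"].to_numpy(dtype=float))
    out["tau_star_ir"] = np.log(out["tau_ir"].to_numpy(dtype=float))

    d_resp = np.empty(len(out))
    for _, group in out.groupby("apple_id", sort=False):
        d_resp[out.index.get_indexer(group.index)] = first_derivative(
            group["time_h"].to_numpy(), group["respiration"].to_numpy()
        )
    out["d_respiration"] = d_resp

    if normalize_cf:
        for _, group in out.groupby("apple_id", sort=False):
            base = _baseline_mask(group, baseline_phase)
            scale = float(np.median(group["cf"].to_numpy()[base]))
            if scale == 0:
                raise ValueError("baseline cf median is zero; cannot normalize")
            out.loc[group.index, "cf"] = group["cf"] / scale

    if phenotypes is not None:
        _validate_columns(phenotypes, PHENOTYPE_COLUMNS, "phenotypes")
        pheno = phenotypes.copy()
        if (pheno[["mass", "firmness", "ssc", "volume"]] <= 0).any().any():
            raise ValueError("phenotype values must be positive")
        pheno["area"] = sphere_equivalent_area(pheno["volume"].to_numpy(dtype=float))
        out = out.merge(pheno, on="apple_id", how="left", validate="many_to_one")
    return out


def _validate_columns(df: pd.DataFrame, required: Sequence[str], name: str) -> None:
    missing = sorted(set(required) - set(df.columns))
    if missing:
        raise ValueError(f"{name} table missing column(s): {', '.join(missing)}")


def read_epochs_csv(path) -> pd.DataFrame:
    """Read the epochs table, validating the required header strictly."""
    df = pd.read_csv(path, comment="#")
    _validate_columns(df, EPOCH_COLUMNS, "epochs")
    bad = ~df["phase"].isin(PHASES)
    if bad.any():
        raise ValueError(f"unknown phase value(s): {sorted(df.loc[bad, 'phase'].unique())}")
    return df


def read_phenotypes_csv(path) -> pd.DataFrame:
    """Read the phenotype table, validating the required header strictly."""
    df = pd.read_csv(path, comment="#")
    _validate_columns(df, PHENOTYPE_COLUMNS, "phenotypes")
    return df
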