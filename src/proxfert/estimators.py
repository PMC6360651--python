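"""Estimate every model input from a flat woman-level survey table.

The table is a pandas DataFrame (or CSV) with one row per woman:

======================  =====================================================
column                  meaning
======================  =====================================================
age_group               one of the seven labels ``15-19`` ... ``45-49``
in_union                1 if currently married or in consensual union
births_in_window        live births in the retrospective window
method                  ``none``/``pill``/``iud``/``sterilization``/
                        ``injection``/``other``
amenorrhea_months       postpartum amenorrhea after the most recent birth;
                        missing when there is no recent birth (structural,
                        never imputed)
wastage_in_window       foetal-wastage events (miscarriage + abortion +
                        stillbirth) in the window
region, wealth_quintile,
education, residence    categorical strata
weight                  optional sampling weight (> 0, default 1)
======================  =====================================================

All estimators are weight-aware; multiplying every weight by a positive
constant leaves every estimate unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig
from .model import (
    AGE_GROUPS,
    AgeSchedule,
    EstimationError,
    MethodMix,
    ProximateIndices,
    averted_fetal_wastage,
    index_contraception,
    index_fetal_wastage,
    index_marriage,
    index_postpartum,
    mean_use_effectiveness,
)

__all__ = [
    "METHODS",
    "STRATUM_VARS",
    "REQUIRED_COLUMNS",
    "WomanRecord",
    "EstimationWindow",
    "read_women_csv",
    "validate_women",
    "age_schedule",
    "tfr_from_schedule",
    "method_mix",
    "mean_amenorrhea",
    "total_fetal_wastage",
    "estimate_indices",
]

METHODS: tuple[str, ...] = ("none", "pill", "iud", "sterilization", "injection", "other")
STRATUM_VARS: tuple[str, ...] = ("region", "wealth_quintile", "education", "residence")
REQUIRED_COLUMNS: tuple[str, ...] = (
    "age_group",
    "in_union",
    "births_in_window",
    "method",
    "amenorrhea_months",
    "wastage_in_window",
    *STRATUM_VARS,
)


@dataclass(frozen=True)
class WomanRecord:
    """One survey-style woman-level observation."""

    age_group: str
    in_union: bool
    births_in_window: int
    method: str = "none"
    amenorrhea_months: float | None = None
    wastage_in_window: int = 0
    region: str = "all"
    wealth_quintile: str = "all"
    education: str = "all"
    residence: str = "all"
    weight: float = 1.0


@dataclass(frozen=True)
class EstimationWindow:
    """Retrospective exposure window in years (DHS convention: 3)."""

    window_years: float = 3.0

    def __post_init__(self) -> None:
        if self.window_years <= 0:
            raise EstimationError(
                f"window_years must be > 0, got {self.window_years!r}"
            )


def _as_window(window: EstimationWindow | float) -> float:
    if isinstance(window, EstimationWindow):
        return window.window_years
    return EstimationWindow(float(window)).window_years


def validate_women(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and invariants; returns the frame with a weight column."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise EstimationError(f"missing required columns: {missing}")
    df = df.copy()
    if "weight" not in df.columns:
        df["weight"] = 1.0
    bad_age = set(df["age_group"].unique()) - set(AGE_GROUPS)
    if bad_age:
        raise EstimationError(f"unknown age groups: {sorted(bad_age)}")
    bad_method = set(df["method"].unique()) - set(METHODS)
    if bad_method:
        raise EstimationError(f"unknown contraceptive methods: {sorted(bad_method)}")
    if (df["weight"] <= 0).any():
        raise EstimationError("sampling weights must be > 0")
    for col in ("births_in_window", "wastage_in_window"):
        if (df[col] < 0).any():
            raise EstimationError(f"{col} must be >= 0")
    using = df["method"] != "none"
    if (using & (df["in_union"].astype(int) == 0)).any():
        raise EstimationError(
            "method other than 'none' recorded for a woman not in union; "
            "prevalence is defined among in-union women"
        )
    return df


def read_women_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a woman-level CSV in the schema above."""
    df = pd.read_csv(path, dtype={"age_group": str, "method": str})
    return validate_women(df)


def _age_group_rates(
    df: pd.DataFrame, count_col: str, window_years: float
) -> tuple[float, ...]:
    """Weighted per-woman-per-year event rates by age group."""
    rates = []
    for group in AGE_GROUPS:
        sub = df[df["age_group"] == group]
        if sub.empty:
            raise EstimationError(f"no records in age group {group!r}")
        w = sub["weight"].to_numpy(dtype=float)
        events = sub[count_col].to_numpy(dtype=float)
        rates.append(float((w * events).sum() / (w.sum() * window_years)))
    return tuple(rates)


def age_schedule(
    df: pd.DataFrame, window: EstimationWindow | float = EstimationWindow()
) -> AgeSchedule:
    """Estimate m(a) (weighted in-union share) and g(a) (births per
    woman-year) for the seven age groups."""
    df = validate_women(df)
    window_years = _as_window(window)
    m = []
    for group in AGE_GROUPS:
        sub = df[df["age_group"] == group]
        if sub.empty:
            raise EstimationError(f"no records in age group {group!r}")
        w = sub["weight"].to_numpy(dtype=float)
        m.append(float((w * sub["in_union"].to_numpy(dtype=float)).sum() / w.sum()))
    g = _age_group_rates(df, "births_in_window", window_years)
    return AgeSchedule(m=tuple(m), g=g)


def tfr_from_schedule(schedule: AgeSchedule) -> float:
    """TFR = 5 * sum of age-specific annual rates."""
    return schedule.total_fertility_rate


def method_mix(df: pd.DataFrame, config: ModelConfig | None = None) -> MethodMix:
    """Prevalence u and per-method shares among in-union women."""
    df = validate_women(df)
    config = config or ModelConfig()
    union = df[df["in_union"].astype(int) == 1]
    if union.empty:
        raise EstimationError("no in-union women: contraceptive prevalence undefined")
    w = union["weight"].to_numpy(dtype=float)
    total = w.sum()
    shares = {}
    for method in METHODS:
        if method == "none":
            continue
        shares[method] = float(w[(union["method"] == method).to_numpy()].sum() / total)
    u = float(w[(union["method"] != "none").to_numpy()].sum() / total)
    # tiny float drift between u and the share sum breaks the invariant check
    u = sum(shares.values())
    return MethodMix(u=u, shares=shares, effectiveness=dict(config.effectiveness))


def mean_amenorrhea(df: pd.DataFrame) -> float:
    """Weighted mean amenorrhea duration over women with a recent birth.

    Rows with missing ``amenorrhea_months`` (no birth in the window) are
    structurally excluded, never imputed.
    """
    df = validate_women(df)
    eligible = df[df["amenorrhea_months"].notna()]
    if eligible.empty:
        raise EstimationError(
            "no women with a recorded postpartum amenorrhea duration"
        )
    w = eligible["weight"].to_numpy(dtype=float)
    x = eligible["amenorrhea_months"].to_numpy(dtype=float)
    return float((w * x).sum() / w.sum())


def total_fetal_wastage(
    df: pd.DataFrame, window: EstimationWindow | float = EstimationWindow()
) -> float:
    """Total foetal-wastage rate: built exactly like the TFR but counting
    wastage events, TFW = 5 * sum of age-specific annual wastage rates."""
    df = validate_women(df)
    rates = _age_group_rates(df, "wastage_in_window", _as_window(window))
    return 5.0 * float(np.sum(rates))


def estimate_indices(
    df: pd.DataFrame,
    window: EstimationWindow | float = EstimationWindow(),
    config: ModelConfig | None = None,
) -> ProximateIndices:
    """Assemble all four indices and the composed TFR from microdata."""
    config = config or ModelConfig()
    df = validate_women(df)

    def _component(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except EstimationError as err:
            raise EstimationError(f"{name}: {err}") from err

    schedule = _component("age_schedule", age_schedule, df, window)
    cm = _component("index_marriage", index_marriage, schedule)
    tfr_obs = tfr_from_schedule(schedule)

    mix = _component("method_mix", method_mix, df, config)
    if mix.u > 0:
        e = _component("mean_use_effectiveness", mean_use_effectiveness, mix)
        cc = index_contraception(mix.u, e, config.sterility_adjustment)
    else:
        cc = 1.0  # no contraceptive use: no inhibition by definition

    i = _component("mean_amenorrhea", mean_amenorrhea, df)
    ci = _component("index_postpartum", index_postpartum, i)

    tfw = _component("total_fetal_wastage", total_fetal_wastage, df, window)
    afw = averted_fetal_wastage(mix.u, tfw)
    cfw = _component("index_fetal_wastage", index_fetal_wastage, tfr_obs, afw)

    return ProximateIndices(
        cm=cm, cc=cc, ci=ci, cfw=cfw,
        tf=config.total_fecundity, tfr_observed=tfr_obs,
    )
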