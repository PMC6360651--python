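"""Generate woman-level populations with known implied indices.

The generator is the test bed for every estimator: given a
``PopulationSpec`` the four inhibition indices it implies are available
in closed form (``implied_indices``), so estimation on a simulated table
can be checked against exact ground truth at any sample size.

Sampling model (per woman):

* age group uniform over the seven groups unless ``age_distribution``
  overrides it;
* in-union ~ Bernoulli(m(a));
* contraceptive method: in-union women draw from the method shares,
  with probability ``1 - u`` of using none; women not in union never
  use a method;
* births in the window ~ Poisson(g(a) * window_years);
* postpartum amenorrhea ~ Gamma with mean ``i_mean`` and standard
  deviation ``i_sd`` for women with a recent birth, missing otherwise
  (only the mean matters to the postpartum index);
* wastage events ~ Poisson(tfw_target / 35 * window_years), i.e. the
  lifetime rate spread over the 35 reproductive years.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ModelConfig
from .estimators import METHODS, REQUIRED_COLUMNS, STRATUM_VARS
from .model import (
    AGE_GROUPS,
    BASE_BIRTH_INTERVAL_MONTHS,
    FULL_BIRTH_INTERVAL_MONTHS,
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
    "StratumSpec",
    "PopulationSpec",
    "spec_from_dict",
    "simulate_population",
    "implied_indices",
]

#: Reproductive span in years covered by the seven age groups.
REPRODUCTIVE_YEARS = 5.0 * len(AGE_GROUPS)

#: Default age-specific fertility shape (annual rates summing to TFR/5
#: after scaling); hump-shaped like observed schedules.
DEFAULT_G_SHAPE: tuple[float, ...] = (0.07, 0.21, 0.23, 0.18, 0.12, 0.05, 0.01)

#: Default in-union proportions by age, rising then plateauing.
DEFAULT_M_BY_AGE: tuple[float, ...] = (0.2, 0.55, 0.75, 0.8, 0.8, 0.75, 0.7)


@dataclass(frozen=True)
class StratumSpec:
    """One level of a stratification variable.

    ``share`` is the probability a woman belongs to this level;
    ``overrides`` replaces PopulationSpec fields within the level.
    """

    level: str
    share: float
    overrides: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.share <= 1.0):
            raise EstimationError(
                f"stratum {self.level!r} share must lie in (0, 1], got {self.share!r}"
            )
        object.__setattr__(self, "overrides", dict(self.overrides))


@dataclass(frozen=True)
class PopulationSpec:
    """Target parameters for a simulated survey population."""

    n: int = 15_000
    m_by_age: tuple[float, ...] = DEFAULT_M_BY_AGE
    g_by_age: tuple[float, ...] = tuple(0.95 * x for x in DEFAULT_G_SHAPE)
    u_target: float = 0.3
    method_shares: Mapping[str, float] = field(
        default_factory=lambda: {
            "pill": 0.06, "iud": 0.009, "sterilization": 0.006,
            "injection": 0.195, "other": 0.03,
        }
    )
    i_mean: float = 12.0
    i_sd: float = 6.0
    tfw_target: float = 0.5
    window_years: float = 3.0
    age_distribution: tuple[float, ...] | None = None
    strata: Mapping[str, Sequence[StratumSpec]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < len(AGE_GROUPS):
            raise EstimationError(
                f"n must be >= {len(AGE_GROUPS)} (one woman per age group)"
            )
        object.__setattr__(self, "m_by_age", tuple(float(x) for x in self.m_by_age))
        object.__setattr__(self, "g_by_age", tuple(float(x) for x in self.g_by_age))
        object.__setattr__(self, "method_shares", dict(self.method_shares))
        object.__setattr__(self, "strata", {k: tuple(v) for k, v in dict(self.strata).items()})
        # schedule validity (range checks) is delegated to AgeSchedule
        AgeSchedule(m=self.m_by_age, g=self.g_by_age)
        if not (0.0 <= self.u_target <= 1.0):
            raise EstimationError(f"u_target must lie in [0, 1], got {self.u_target!r}")
        share_sum = sum(self.method_shares.values())
        if share_sum > self.u_target + 1e-9:
            raise EstimationError(
                f"method shares sum to {share_sum!r}, exceeding u_target={self.u_target!r}"
            )
        if abs(share_sum - self.u_target) > 1e-9:
            raise EstimationError(
                f"method shares sum to {share_sum!r}, expected u_target={self.u_target!r}"
            )
        unknown = set(self.method_shares) - (set(METHODS) - {"none"})
        if unknown:
            raise EstimationError(f"unknown methods in shares: {sorted(unknown)}")
        if self.i_mean < 0 or self.i_sd <= 0:
            raise EstimationError("i_mean must be >= 0 and i_sd > 0")
        if self.tfw_target < 0:
            raise EstimationError("tfw_target must be >= 0")
        if self.window_years <= 0:
            raise EstimationError("window_years must be > 0")
        if self.age_distribution is not None:
            dist = tuple(float(x) for x in self.age_distribution)
            if len(dist) != len(AGE_GROUPS) or any(p < 0 for p in dist) or sum(dist) <= 0:
                raise EstimationError("age_distribution must be 7 non-negative shares")
            object.__setattr__(self, "age_distribution", dist)
        unknown_vars = set(self.strata) - set(STRATUM_VARS)
        if unknown_vars:
            raise EstimationError(f"unknown stratum variables: {sorted(unknown_vars)}")
        override_vars = [
            var for var, levels in self.strata.items()
            if any(level.overrides for level in levels)
        ]
        if len(override_vars) > 1:
            raise EstimationError(
                "parameter overrides on more than one stratum variable are "
                f"ambiguous: {sorted(override_vars)}"
            )
        for var, levels in self.strata.items():
            total = sum(level.share for level in levels)
            if abs(total - 1.0) > 1e-9:
                raise EstimationError(
                    f"shares for {var!r} sum to {total!r}, expected 1"
                )
        # overridden sub-specs must themselves be valid
        for level, sub in self._override_levels():
            sub_spec = self.for_level(level)
            AgeSchedule(m=sub_spec.m_by_age, g=sub_spec.g_by_age)

    # -- strata helpers ---------------------------------------------------

    @property
    def override_var(self) -> str | None:
        """The (single) stratum variable carrying parameter overrides."""
        for var, levels in self.strata.items():
            if any(level.overrides for level in levels):
                return var
        return None

    def _override_levels(self) -> list[tuple[str, StratumSpec]]:
        var = self.override_var
        if var is None:
            return []
        return [(level.level, level) for level in self.strata[var]]

    def for_level(self, level_name: str) -> "PopulationSpec":
        """Spec with the named override-level's parameters applied."""
        var = self.override_var
        if var is None:
            return self
        for level in self.strata[var]:
            if level.level == level_name:
                allowed = {
                    "m_by_age", "g_by_age", "u_target", "method_shares",
                    "i_mean", "i_sd", "tfw_target",
                }
                bad = set(level.overrides) - allowed
                if bad:
                    raise EstimationError(
                        f"overrides may only set {sorted(allowed)}, got {sorted(bad)}"
                    )
                return replace(self, strata={}, **level.overrides)
        raise EstimationError(f"no level {level_name!r} under {var!r}")

    # -- construction helpers --------------------------------------------

    @classmethod
    def from_target_indices(
        cls,
        cm: float,
        cc: float,
        ci: float,
        cfw: float,
        tfr_obs: float,
        *,
        n: int = 15_000,
        mix_weights: Mapping[str, float] | None = None,
        g_shape: Sequence[float] = DEFAULT_G_SHAPE,
        config: ModelConfig | None = None,
        **kwargs: Any,
    ) -> "PopulationSpec":
        """Invert the index formulas to a spec implying the given targets.

        ``mix_weights`` are method shares conditional on use (sum to 1);
        prevalence is solved from the contraception index, the mean
        amenorrhea from the postpartum index, and the wastage rate from
        the foetal-wastage index at the supplied observed TFR.
        """
        config = config or ModelConfig()
        if not (0.0 < cm <= 1.0 and 0.0 < cc <= 1.0 and 0.0 < ci <= 1.0 and 0.0 < cfw <= 1.0):
            raise EstimationError("target indices must lie in (0, 1]")
        if tfr_obs <= 0:
            raise EstimationError("target observed TFR must be > 0")
        mix_weights = dict(
            mix_weights
            or {"pill": 0.2, "iud": 0.03, "sterilization": 0.02,
                "injection": 0.65, "other": 0.10}
        )
        total_w = sum(mix_weights.values())
        if abs(total_w - 1.0) > 1e-9:
            raise EstimationError("mix_weights must sum to 1")
        e = sum(config.effectiveness[m] * w for m, w in mix_weights.items())
        if cc < 1.0:
            u = (1.0 - cc) / (config.sterility_adjustment * e)
            if u > 1.0:
                raise EstimationError(
                    f"target cc={cc} unreachable with mean effectiveness {e:.3f}"
                )
        else:
            u = 0.0
        shares = {m: u * w for m, w in mix_weights.items()}
        i_mean = FULL_BIRTH_INTERVAL_MONTHS / ci - BASE_BIRTH_INTERVAL_MONTHS
        scale = tfr_obs / (5.0 * sum(g_shape))
        g = tuple(scale * x for x in g_shape)
        afw = tfr_obs * (1.0 - cfw) / cfw
        tfw = afw / (0.4 * (1.0 + u)) if afw > 0 else 0.0
        return cls(
            n=n,
            m_by_age=tuple(cm for _ in AGE_GROUPS),
            g_by_age=g,
            u_target=u,
            method_shares=shares,
            i_mean=i_mean,
            tfw_target=tfw,
            **kwargs,
        )


def _draw_level_assignments(
    rng: np.random.Generator, n: int, levels: Sequence[StratumSpec]
) -> np.ndarray:
    names = np.array([level.level for level in levels], dtype=object)
    probs = np.array([level.share for level in levels], dtype=float)
    probs = probs / probs.sum()
    return names[rng.choice(len(levels), size=n, p=probs)]


def _simulate_block(
    rng: np.random.Generator, spec: PopulationSpec, n: int
) -> pd.DataFrame:
    """Draw n women from a single (possibly overridden) parameter set."""
    k = len(AGE_GROUPS)
    age_probs = (
        np.full(k, 1.0 / k)
        if spec.age_distribution is None
        else np.asarray(spec.age_distribution, dtype=float)
    )
    age_probs = age_probs / age_probs.sum()
    age_idx = rng.choice(k, size=n, p=age_probs)

    m = np.asarray(spec.m_by_age)[age_idx]
    in_union = (rng.random(n) < m).astype(int)

    method = np.full(n, "none", dtype=object)
    union_idx = np.flatnonzero(in_union == 1)
    if union_idx.size and spec.u_target > 0:
        names = [name for name in spec.method_shares]
        probs = np.array([1.0 - spec.u_target] + [spec.method_shares[name] for name in names])
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum()
        draws = rng.choice(len(probs), size=union_idx.size, p=probs)
        lookup = np.array(["none"] + names, dtype=object)
        method[union_idx] = lookup[draws]

    g = np.asarray(spec.g_by_age)[age_idx]
    births = rng.poisson(g * spec.window_years)

    amen = np.full(n, np.nan)
    recent = births > 0
    if spec.i_mean > 0:
        shape = (spec.i_mean / spec.i_sd) ** 2
        scale = spec.i_sd**2 / spec.i_mean
        amen[recent] = rng.gamma(shape, scale, size=int(recent.sum()))
    else:
        amen[recent] = 0.0

    wastage_rate = spec.tfw_target / REPRODUCTIVE_YEARS * spec.window_years
    wastage = rng.poisson(wastage_rate, size=n)

    return pd.DataFrame(
        {
            "age_group": np.array(AGE_GROUPS, dtype=object)[age_idx],
            "in_union": in_union,
            "births_in_window": births,
            "method": method,
            "amenorrhea_months": amen,
            "wastage_in_window": wastage,
        }
    )


def simulate_population(spec: PopulationSpec, seed: int | None = None) -> pd.DataFrame:
    """Simulate a woman-level table following the spec.

    Deterministic for a fixed ``(spec, seed)``; ``seed`` defaults to
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n

    assignments: dict[str, np.ndarray] = {}
    for var in STRATUM_VARS:
        if var in spec.strata:
            assignments[var] = _draw_level_assignments(rng, n, spec.strata[var])
        else:
            assignments[var] = np.full(n, "all", dtype=object)

    override_var = spec.override_var
    if override_var is None:
        df = _simulate_block(rng, spec, n)
    else:
        parts = []
        labels = assignments[override_var]
        for level in spec.strata[override_var]:
            mask = labels == level.level
            count = int(mask.sum())
            if count == 0:
                continue
            block = _simulate_block(rng, spec.for_level(level.level), count)
            block.index = np.flatnonzero(mask)
            parts.append(block)
        df = pd.concat(parts).sort_index()

    for var in STRATUM_VARS:
        df[var] = assignments[var]
    df["weight"] = 1.0
    return df.reset_index(drop=True)[list(REQUIRED_COLUMNS) + ["weight"]]


def implied_indices(
    spec: PopulationSpec, config: ModelConfig | None = None
) -> ProximateIndices:
    """Closed-form ground-truth indices implied by a spec's parameters."""
    config = config or ModelConfig()
    schedule = AgeSchedule(m=spec.m_by_age, g=spec.g_by_age)
    cm = index_marriage(schedule)
    if spec.u_target > 0:
        mix = MethodMix(
            u=sum(spec.method_shares.values()),
            shares=spec.method_shares,
            effectiveness=dict(config.effectiveness),
        )
        e = mean_use_effectiveness(mix)
        cc = index_contraception(spec.u_target, e, config.sterility_adjustment)
    else:
        cc = 1.0
    ci = index_postpartum(spec.i_mean)
    tfr = schedule.total_fertility_rate
    afw = averted_fetal_wastage(spec.u_target, spec.tfw_target)
    cfw = index_fetal_wastage(tfr, afw)
    return ProximateIndices(
        cm=cm, cc=cc, ci=ci, cfw=cfw,
        tf=config.total_fecundity, tfr_observed=tfr,
    )


def spec_from_dict(
    data: Mapping[str, Any], config: ModelConfig | None = None
) -> PopulationSpec:
    """Build a PopulationSpec from a plain mapping (YAML/JSON payload).

    Two layouts are accepted: direct ``PopulationSpec`` fields, or a
    ``target_indices`` block (``cm``/``cc``/``ci``/``cfw``/``tfr_obs``
    plus optional ``mix_weights``) inverted via ``from_target_indices``.
    ``strata`` is a mapping variable -> {level: {share: ..., <overrides>}}.
    """
    data = dict(data)
    strata_raw = data.pop("strata", None)
    strata: dict[str, tuple[StratumSpec, ...]] = {}
    if strata_raw:
        for var, levels in strata_raw.items():
            parsed = []
            for level_name, payload in levels.items():
                payload = dict(payload)
                share = payload.pop("share")
                parsed.append(
                    StratumSpec(level=str(level_name), share=float(share), overrides=payload)
                )
            strata[var] = tuple(parsed)

    targets = data.pop("target_indices", None)
    if targets is not None:
        targets = dict(targets)
        mix_weights = targets.pop("mix_weights", None)
        return PopulationSpec.from_target_indices(
            cm=float(targets.pop("cm")),
            cc=float(targets.pop("cc")),
            ci=float(targets.pop("ci")),
            cfw=float(targets.pop("cfw")),
            tfr_obs=float(targets.pop("tfr_obs")),
            mix_weights=mix_weights,
            config=config,
            strata=strata,
            **{**targets, **data},
        )
    return PopulationSpec(strata=strata, **data)
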