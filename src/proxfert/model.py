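"""Closed-form fertility-inhibition indices and their multiplicative composition.

The total fertility rate (TFR) is modelled as the product of four
unitless indices — marriage (Cm), contraception (Cc), foetal wastage
(Cfw) and postpartum infecundability (Ci) — applied to a biological
maximum, the total fecundity TF::

    TFR = Cm * Cc * Cfw * Ci * TF

Each index equals 1 when the corresponding behaviour exerts no
inhibition and approaches 0 as inhibition becomes complete.  The
formulas themselves do not enforce the (0, 1] range, so out-of-range
values are *flagged* (``IndexRangeWarning`` / ``ProximateIndices.flags``)
rather than clamped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "AGE_GROUPS",
    "DEFAULT_EFFECTIVENESS",
    "STERILITY_ADJUSTMENT",
    "TOTAL_FECUNDITY",
    "MINIMUM_ANOVULATION_MONTHS",
    "FULL_BIRTH_INTERVAL_MONTHS",
    "BASE_BIRTH_INTERVAL_MONTHS",
    "EstimationError",
    "IndexRangeWarning",
    "AgeSchedule",
    "MethodMix",
    "PostpartumInput",
    "FetalWastageInput",
    "ProximateIndices",
    "ProjectionScenario",
    "index_marriage",
    "mean_use_effectiveness",
    "index_contraception",
    "index_postpartum",
    "averted_fetal_wastage",
    "index_fetal_wastage",
    "compose_tfr",
    "percent_inhibition",
    "project_tfr",
]

#: The seven five-year reproductive age groups, fixed order.
AGE_GROUPS: tuple[str, ...] = (
    "15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
)

#: Method-specific use effectiveness; "other" covers every method not
#: named (condom, LAM, traditional, ...).
DEFAULT_EFFECTIVENESS: Mapping[str, float] = {
    "pill": 0.90,
    "iud": 0.95,
    "sterilization": 1.00,
    "injection": 0.99,
    "other": 0.70,
}

#: Adjustment for non-use of contraception by women who know they are sterile.
STERILITY_ADJUSTMENT: float = 1.08

#: Default total fecundity (births per woman absent all four inhibitors).
TOTAL_FECUNDITY: float = 15.3

#: Months of minimum postpartum anovulation.
MINIMUM_ANOVULATION_MONTHS: float = 1.5
#: Average birth interval (months) absent breastfeeding/abstinence:
#: 1.5 anovulation + 7.5 waiting + 2 intrauterine loss + 9 gestation.
FULL_BIRTH_INTERVAL_MONTHS: float = 20.0
#: Birth-interval months excluding postpartum infecundability (7.5 + 2 + 9).
BASE_BIRTH_INTERVAL_MONTHS: float = 18.5


class EstimationError(ValueError):
    """An index or estimator precondition was violated."""


class IndexRangeWarning(UserWarning):
    """A computed index fell outside the nominal (0, 1] range."""


def _check_proportion(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise EstimationError(f"{name} must lie in [0, 1], got {value!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeSchedule:
    """Per-age-group union proportions m(a) and fertility rates g(a).

    Parameters
    ----------
    m
        Proportion of women currently in union per age group, each in [0, 1].
    g
        Age-specific fertility rate per group (births per woman per year).
    age_groups
        Ordered labels; defaults to the seven five-year groups 15-19 ... 45-49.
    """

    m: tuple[float, ...]
    g: tuple[float, ...]
    age_groups: tuple[str, ...] = AGE_GROUPS

    def __post_init__(self) -> None:
        object.__setattr__(self, "m", tuple(float(x) for x in self.m))
        object.__setattr__(self, "g", tuple(float(x) for x in self.g))
        object.__setattr__(self, "age_groups", tuple(self.age_groups))
        if len(self.age_groups) != len(AGE_GROUPS):
            raise EstimationError(
                f"expected {len(AGE_GROUPS)} age groups, got {len(self.age_groups)}"
            )
        if len(self.m) != len(self.age_groups) or len(self.g) != len(self.age_groups):
            raise EstimationError("m and g must have one entry per age group")
        for label, value in zip(self.age_groups, self.m):
            if not (0.0 <= value <= 1.0):
                raise EstimationError(f"m({label}) must lie in [0, 1], got {value!r}")
        for label, value in zip(self.age_groups, self.g):
            if value < 0.0 or not math.isfinite(value):
                raise EstimationError(f"g({label}) must be finite and >= 0, got {value!r}")

    @property
    def total_fertility_rate(self) -> float:
        """TFR implied by the schedule: five times the sum of annual rates."""
        return 5.0 * sum(self.g)


@dataclass(frozen=True)
class MethodMix:
    """Contraceptive prevalence ``u`` partitioned into per-method shares.

    ``shares`` are absolute proportions of in-union women using each
    method and must sum to ``u`` (tolerance 1e-9).
    """

    u: float
    shares: Mapping[str, float]
    effectiveness: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTIVENESS)
    )

    def __post_init__(self) -> None:
        _check_proportion(self.u, "u")
        object.__setattr__(self, "shares", dict(self.shares))
        object.__setattr__(self, "effectiveness", dict(self.effectiveness))
        unknown = set(self.shares) - set(self.effectiveness)
        if unknown:
            raise EstimationError(
                f"methods without an effectiveness entry: {sorted(unknown)}"
            )
        for method, share in self.shares.items():
            if share < 0:
                raise EstimationError(f"share for {method!r} must be >= 0")
        total = sum(self.shares.values())
        if abs(total - self.u) > 1e-9:
            raise EstimationError(
                f"method shares sum to {total!r}, expected prevalence u={self.u!r}"
            )


@dataclass(frozen=True)
class PostpartumInput:
    """Mean duration of postpartum amenorrhea in months."""

    i: float

    def __post_init__(self) -> None:
        if self.i < 0 or not math.isfinite(self.i):
            raise EstimationError(f"amenorrhea duration must be >= 0, got {self.i!r}")


@dataclass(frozen=True)
class FetalWastageInput:
    """Observed TFR plus the foetal-wastage inputs needed for Cfw."""

    tfr_obs: float
    tfw: float
    u: float

    def __post_init__(self) -> None:
        if self.tfr_obs <= 0:
            raise EstimationError(f"observed TFR must be > 0, got {self.tfr_obs!r}")
        if self.tfw < 0:
            raise EstimationError(f"total foetal wastage rate must be >= 0, got {self.tfw!r}")
        _check_proportion(self.u, "u")

    @property
    def afw(self) -> float:
        """Births averted per woman by foetal wastage."""
        return averted_fetal_wastage(self.u, self.tfw)


@dataclass(frozen=True)
class ProximateIndices:
    """The four indices, total fecundity, and their composed TFR.

    ``flags`` names any index outside the nominal (0, 1] range; nothing
    is clamped.  ``tfr_observed`` optionally carries the directly
    estimated TFR alongside the model composition.
    """

    cm: float
    cc: float
    ci: float
    cfw: float
    tf: float = TOTAL_FECUNDITY
    tfr_observed: float | None = None

    def __post_init__(self) -> None:
        if self.tf <= 0 or not math.isfinite(self.tf):
            raise EstimationError(f"total fecundity must be > 0, got {self.tf!r}")
        for name in ("cm", "cc", "ci", "cfw"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise EstimationError(f"index {name} is not finite: {value!r}")

    @property
    def tfr_model(self) -> float:
        return compose_tfr(self.cm, self.cc, self.ci, self.cfw, self.tf)

    @property
    def flags(self) -> tuple[str, ...]:
        return tuple(
            name
            for name in ("cm", "cc", "ci", "cfw")
            if not (0.0 < getattr(self, name) <= 1.0)
        )

    def as_dict(self) -> dict[str, float]:
        out = {
            "cm": self.cm,
            "cc": self.cc,
            "ci": self.ci,
            "cfw": self.cfw,
            "tf": self.tf,
            "tfr_model": self.tfr_model,
        }
        if self.tfr_observed is not None:
            out["tfr_observed"] = self.tfr_observed
        return out


@dataclass(frozen=True)
class ProjectionScenario:
    """Baseline TFR plus prevalence/effectiveness at baseline and target.

    Only contraception changes between the two time points; the other
    three indices are held constant, so the projected TFR scales by the
    ratio of the contraception indices.
    """

    tfr1: float
    u1: float
    e1: float
    u2: float
    e2: float
    sterility_adjustment: float = STERILITY_ADJUSTMENT

    def __post_init__(self) -> None:
        if self.tfr1 <= 0:
            raise EstimationError(f"baseline TFR must be > 0, got {self.tfr1!r}")
        for name in ("u1", "u2", "e1", "e2"):
            _check_proportion(getattr(self, name), name)
        if self.cc1 <= 0:
            raise EstimationError(
                "baseline contraception index is not positive: "
                f"1 - {self.sterility_adjustment}*{self.u1}*{self.e1} = {self.cc1!r}"
            )

    @property
    def cc1(self) -> float:
        return 1.0 - self.sterility_adjustment * self.u1 * self.e1

    @property
    def cc2(self) -> float:
        return 1.0 - self.sterility_adjustment * self.u2 * self.e2

    def swapped(self) -> "ProjectionScenario":
        """Scenario running the projection backwards from its own output."""
        return ProjectionScenario(
            tfr1=project_tfr(self),
            u1=self.u2, e1=self.e2, u2=self.u1, e2=self.e1,
            sterility_adjustment=self.sterility_adjustment,
        )


# ---------------------------------------------------------------------------
# index formulas
# ---------------------------------------------------------------------------

def index_marriage(schedule: AgeSchedule) -> float:
    """Marriage index Cm = sum m(a) g(a) / sum g(a).

    A fertility-weighted average of the in-union proportions, hence
    bounded by [min m(a), max m(a)]; 1 when all women are in union.
    """
    total_g = sum(schedule.g)
    if total_g <= 0.0:
        raise EstimationError("marriage index undefined: no fertility in schedule")
    return sum(m * g for m, g in zip(schedule.m, schedule.g)) / total_g


def mean_use_effectiveness(mix: MethodMix) -> float:
    """Use-effectiveness e = sum e(m) u(m) / u, a share-weighted mean."""
    if mix.u <= 0.0:
        raise EstimationError(
            "effectiveness undefined when prevalence is zero"
        )
    return sum(
        mix.effectiveness[method] * share for method, share in mix.shares.items()
    ) / mix.u


def index_contraception(
    u: float, e: float, sterility_adjustment: float = STERILITY_ADJUSTMENT
) -> float:
    """Contraception index Cc = 1 - 1.08 u e.

    ``u`` is prevalence among in-union women and ``e`` the mean use
    effectiveness.  With u = 0 the index is exactly 1 (``e`` is then
    irrelevant and callers need not compute it).  Values <= 0 (very high
    effective prevalence) are returned with an ``IndexRangeWarning``.
    """
    _check_proportion(u, "u")
    _check_proportion(e, "e")
    value = 1.0 - sterility_adjustment * u * e
    if value <= 0.0:
        warnings.warn(
            f"contraception index is not positive ({value:.4f}); "
            "effective prevalence saturates the model",
            IndexRangeWarning,
            stacklevel=2,
        )
    return value


def index_postpartum(i: float) -> float:
    """Postpartum-infecundability index Ci = 20 / (18.5 + i).

    ``i`` is the mean months of postpartum amenorrhea.  Equals 1 at the
    1.5-month anovulation minimum and decreases as ``i`` grows; ``i``
    below 1.5 months yields a value above 1, which is flagged.
    """
    if i < 0 or not math.isfinite(i):
        raise EstimationError(f"amenorrhea duration must be >= 0, got {i!r}")
    value = FULL_BIRTH_INTERVAL_MONTHS / (BASE_BIRTH_INTERVAL_MONTHS + i)
    if value > 1.0:
        warnings.warn(
            f"postpartum index exceeds 1 ({value:.4f}) for i={i} months "
            f"below the {MINIMUM_ANOVULATION_MONTHS}-month anovulation minimum",
            IndexRangeWarning,
            stacklevel=2,
        )
    return value


def averted_fetal_wastage(u: float, tfw: float) -> float:
    """Births averted per woman: AFW = 0.4 (1 + u) TFW."""
    _check_proportion(u, "u")
    if tfw < 0:
        raise EstimationError(f"total foetal wastage rate must be >= 0, got {tfw!r}")
    return 0.4 * (1.0 + u) * tfw


def index_fetal_wastage(tfr_obs: float, afw: float) -> float:
    """Foetal-wastage index Cfw = TFR / (TFR + AFW); 1 iff AFW = 0."""
    if tfr_obs <= 0:
        raise EstimationError(f"observed TFR must be > 0, got {tfr_obs!r}")
    if afw < 0:
        raise EstimationError(f"averted births must be >= 0, got {afw!r}")
    return tfr_obs / (tfr_obs + afw)


def compose_tfr(
    cm: float, cc: float, ci: float, cfw: float, tf: float = TOTAL_FECUNDITY
) -> float:
    """Multiplicative composition TFR = Cm * Cc * Cfw * Ci * TF."""
    if tf <= 0 or not math.isfinite(tf):
        raise EstimationError(f"total fecundity must be > 0, got {tf!r}")
    for name, value in (("cm", cm), ("cc", cc), ("ci", ci), ("cfw", cfw)):
        if not math.isfinite(value):
            raise EstimationError(f"index {name} is not finite: {value!r}")
    return cm * cc * cfw * ci * tf


def percent_inhibition(c: float) -> float:
    """Percent by which an index reduces fertility: (1 - C) * 100."""
    if not (0.0 < c <= 1.0):
        raise EstimationError(f"index must lie in (0, 1] for inhibition, got {c!r}")
    return (1.0 - c) * 100.0


def project_tfr(scenario: ProjectionScenario) -> float:
    """Project the TFR under a contraception-only change.

    TFR2 = TFR1 * (1 - 1.08 u2 e2) / (1 - 1.08 u1 e1); all other
    inhibiting indices are assumed constant between the two years.
    """
    return scenario.tfr1 * scenario.cc2 / scenario.cc1
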