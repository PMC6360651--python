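"""End-to-end analysis: stratified estimation, decomposition, projection
and table rendering in the published column order (Cm, Cc, Ci, Cfw, TF, TFR)."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .config import ModelConfig
from .estimators import STRATUM_VARS, EstimationWindow, estimate_indices, validate_women
from .model import (
    EstimationError,
    ProjectionScenario,
    ProximateIndices,
    percent_inhibition,
    project_tfr,
)

__all__ = [
    "TABLE_COLUMNS",
    "StratifiedResult",
    "stratified_analysis",
    "decomposition_report",
    "run_projection",
    "indices_table",
    "render_tables",
    "read_indices_table",
]

TABLE_COLUMNS: tuple[str, ...] = ("Cm", "Cc", "Ci", "Cfw", "TF", "TFR")
_FORMATS: tuple[str, ...] = ("csv", "text")


@dataclass(frozen=True)
class StratifiedResult:
    """Per-level indices for one stratification variable.

    ``rows`` maps each level (in order of first appearance) to its
    ``ProximateIndices``; levels whose estimators failed are listed in
    ``warnings`` instead, so every input level appears exactly once.
    """

    stratum_var: str
    rows: Mapping[str, ProximateIndices]
    survey_label: str = ""
    warnings: tuple[str, ...] = ()
    flagged_levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", dict(self.rows))
        object.__setattr__(self, "warnings", tuple(self.warnings))
        object.__setattr__(self, "flagged_levels", tuple(self.flagged_levels))

    @property
    def warning_count(self) -> int:
        return len(self.warnings)


def stratified_analysis(
    df: pd.DataFrame,
    stratum_var: str,
    window: EstimationWindow | float = EstimationWindow(),
    config: ModelConfig | None = None,
    survey_label: str = "",
) -> StratifiedResult:
    """Estimate the full index bundle separately for each level of a covariate.

    Levels that violate an estimator precondition (for example a level
    with no in-union women) are excluded from ``rows`` and reported by
    name in ``warnings``.  Levels producing an index outside (0, 1] stay
    in ``rows`` but are listed in ``flagged_levels``.
    """
    if stratum_var not in STRATUM_VARS:
        raise EstimationError(
            f"unknown stratum variable {stratum_var!r}; expected one of {STRATUM_VARS}"
        )
    df = validate_women(df)
    rows: dict[str, ProximateIndices] = {}
    warnings_: list[str] = []
    flagged: list[str] = []
    for level, sub in df.groupby(stratum_var, sort=False):
        try:
            indices = estimate_indices(sub, window=window, config=config)
        except EstimationError as err:
            warnings_.append(f"{level}: {err}")
            continue
        rows[str(level)] = indices
        if indices.flags:
            flagged.append(str(level))
    return StratifiedResult(
        stratum_var=stratum_var,
        rows=rows,
        survey_label=survey_label,
        warnings=tuple(warnings_),
        flagged_levels=tuple(flagged),
    )


def decomposition_report(
    indices: ProximateIndices, config: ModelConfig | None = None
) -> pd.DataFrame:
    """Percent inhibition per index (ordered Cm, Cc, Ci, Cfw) plus the
    composed TFR, rounded per the reporting contract."""
    config = config or ModelConfig()
    rows = []
    for label, value in (
        ("Cm", indices.cm),
        ("Cc", indices.cc),
        ("Ci", indices.ci),
        ("Cfw", indices.cfw),
    ):
        rows.append(
            {
                "index": label,
                "value": round(value, config.index_digits),
                "inhibition_pct": round(percent_inhibition(value), config.percent_digits),
            }
        )
    rows.append(
        {
            "index": "TFR",
            "value": round(indices.tfr_model, config.tfr_digits),
            "inhibition_pct": float("nan"),
        }
    )
    return pd.DataFrame(rows, columns=["index", "value", "inhibition_pct"])


def run_projection(
    scenarios: Sequence[ProjectionScenario],
    labels: Sequence[str] | None = None,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """One row per scenario: inputs plus the projected TFR (rounded)."""
    config = config or ModelConfig()
    if labels is not None and len(labels) != len(scenarios):
        raise EstimationError("labels must match scenarios one to one")
    rows = []
    for k, scenario in enumerate(scenarios):
        rows.append(
            {
                "scenario": labels[k] if labels is not None else f"scenario-{k + 1}",
                "tfr1": scenario.tfr1,
                "u1": scenario.u1,
                "e1": scenario.e1,
                "u2": scenario.u2,
                "e2": scenario.e2,
                "tfr2": round(project_tfr(scenario), config.projection_digits),
            }
        )
    return pd.DataFrame(
        rows, columns=["scenario", "tfr1", "u1", "e1", "u2", "e2", "tfr2"]
    )


def indices_table(
    result: StratifiedResult, config: ModelConfig | None = None
) -> pd.DataFrame:
    """Stratified rows as a frame in published column order, rounded."""
    config = config or ModelConfig()
    if not result.rows:
        raise EstimationError("no rows to render")
    records = []
    for level, idx in result.rows.items():
        records.append(
            {
                "level": level,
                "Cm": round(idx.cm, config.index_digits),
                "Cc": round(idx.cc, config.index_digits),
                "Ci": round(idx.ci, config.index_digits),
                "Cfw": round(idx.cfw, config.index_digits),
                "TF": idx.tf,
                "TFR": round(idx.tfr_model, config.tfr_digits),
                "flagged": level in result.flagged_levels,
            }
        )
    return pd.DataFrame(records, columns=["level", *TABLE_COLUMNS, "flagged"])


def render_tables(
    result: StratifiedResult,
    fmt: str = "text",
    config: ModelConfig | None = None,
) -> str:
    """Render a stratified result as CSV or an aligned text table.

    Output is deterministic for a fixed input.
    """
    if fmt not in _FORMATS:
        raise EstimationError(
            f"unknown format {fmt!r}; supported formats: {', '.join(_FORMATS)}"
        )
    frame = indices_table(result, config)
    if fmt == "csv":
        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        return buf.getvalue()
    header = result.survey_label or result.stratum_var
    lines = [header, frame.to_string(index=False)]
    if result.warnings:
        lines.append("excluded levels:")
        lines.extend(f"  {w}" for w in result.warnings)
    return "\n".join(lines) + "\n"


def read_indices_table(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the CSV written by ``render_tables``."""
    frame = pd.read_csv(path)
    missing = [c for c in ("level", *TABLE_COLUMNS) if c not in frame.columns]
    if missing:
        raise EstimationError(f"missing columns in indices table: {missing}")
    return frame
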