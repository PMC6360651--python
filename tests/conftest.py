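from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from proxfert import AGE_GROUPS

# National index values for the two survey years (published Table 1),
# used as worked-example inputs throughout the suite.
TABLE1 = {
    2011: {"cm": 0.622, "cc": 0.715, "ci": 0.653, "cfw": 0.908},
    2016: {"cm": 0.656, "cc": 0.693, "ci": 0.655, "cfw": 0.908},
}

# Published stratified rows used as worked composition examples:
# (cm, cc, ci, cfw, tf, printed TFR).
STRATIFIED_ROWS = {
    ("Tigray", 2016): (0.648, 0.639, 0.590, 0.888, 15.3, 3.319),
    ("Somali", 2016): (0.760, 0.984, 0.746, 0.962, 15.3, 8.211),
    ("Highest", 2016): (0.493, 0.518, 0.803, 0.592, 15.3, 1.857),
    ("Addis Ababa", 2011): (0.316, 0.377, 0.901, 0.750, 15.3, 1.232),
}


def make_women(rows: list[dict]) -> pd.DataFrame:
    """Build a valid woman-level frame from partial row dicts."""
    defaults = {
        "age_group": AGE_GROUPS[0],
        "in_union": 0,
        "births_in_window": 0,
        "method": "none",
        "amenorrhea_months": np.nan,
        "wastage_in_window": 0,
        "region": "all",
        "wealth_quintile": "all",
        "education": "all",
        "residence": "all",
        "weight": 1.0,
    }
    return pd.DataFrame([{**defaults, **row} for row in rows])


def covering_rows(**overrides) -> list[dict]:
    """One quiet row per age group so schedule estimators are satisfiable."""
    return [{"age_group": group, **overrides} for group in AGE_GROUPS]


@pytest.fixture
def table1():
    return TABLE1


@pytest.fixture
def women_factory():
    return make_women


@pytest.fixture
def weighted_fixture_rows():
    """14 hand-written weighted records covering all 7 age groups."""
    rows = []
    rng_free = [
        ("15-19", 0, 0, "none", None, 0, 0.8),
        ("15-19", 1, 1, "pill", 4.0, 0, 1.2),
        ("20-24", 1, 2, "none", 9.0, 1, 2.0),
        ("20-24", 0, 0, "none", None, 0, 0.5),
        ("25-29", 1, 1, "injection", 14.0, 0, 1.0),
        ("25-29", 1, 0, "iud", None, 1, 1.5),
        ("30-34", 1, 2, "none", 11.0, 0, 0.7),
        ("30-34", 0, 1, "none", 16.0, 2, 1.3),
        ("35-39", 1, 0, "sterilization", None, 0, 2.2),
        ("35-39", 0, 0, "none", None, 1, 0.9),
        ("40-44", 1, 1, "other", 20.0, 0, 1.1),
        ("40-44", 1, 0, "none", None, 0, 0.6),
        ("45-49", 0, 0, "none", None, 0, 1.4),
        ("45-49", 1, 0, "none", None, 1, 1.0),
    ]
    for age, union, births, method, amen, wastage, weight in rng_free:
        rows.append(
            {
                "age_group": age,
                "in_union": union,
                "births_in_window": births,
                "method": method,
                "amenorrhea_months": amen,
                "wastage_in_window": wastage,
                "weight": weight,
                "region": "north" if weight > 1.0 else "south",
            }
        )
    return rows
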