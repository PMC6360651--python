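"""Independent brute-force oracles: naive pure-python tallies over row
dicts, kept deliberately free of any package estimator code."""

from __future__ import annotations

import math

AGE_GROUPS = ("15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49")
METHODS = ("pill", "iud", "sterilization", "injection", "other")


def oracle_age_schedule(rows, window_years):
    """Per-group (m, g) via explicit loops; rows are WomanRecord-like dicts."""
    m, g = [], []
    for group in AGE_GROUPS:
        w_sum = union_w = birth_w = 0.0
        for row in rows:
            if row["age_group"] != group:
                continue
            w = row.get("weight", 1.0)
            w_sum += w
            if row["in_union"]:
                union_w += w
            birth_w += w * row["births_in_window"]
        if w_sum == 0:
            raise ValueError(f"empty group {group}")
        m.append(union_w / w_sum)
        g.append(birth_w / (w_sum * window_years))
    return tuple(m), tuple(g)


def oracle_tfr(rows, window_years):
    _, g = oracle_age_schedule(rows, window_years)
    return 5.0 * sum(g)


def oracle_method_mix(rows):
    """(u, shares) among in-union rows."""
    w_union = 0.0
    by_method = {method: 0.0 for method in METHODS}
    for row in rows:
        if not row["in_union"]:
            continue
        w = row.get("weight", 1.0)
        w_union += w
        if row["method"] != "none":
            by_method[row["method"]] += w
    if w_union == 0:
        raise ValueError("no in-union rows")
    shares = {method: weight / w_union for method, weight in by_method.items()}
    return sum(shares.values()), shares


def oracle_mean_amenorrhea(rows):
    w_sum = total = 0.0
    for row in rows:
        value = row.get("amenorrhea_months")
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        w = row.get("weight", 1.0)
        w_sum += w
        total += w * value
    if w_sum == 0:
        raise ValueError("no amenorrhea observations")
    return total / w_sum


def oracle_total_fetal_wastage(rows, window_years):
    rates = []
    for group in AGE_GROUPS:
        w_sum = events = 0.0
        for row in rows:
            if row["age_group"] != group:
                continue
            w = row.get("weight", 1.0)
            w_sum += w
            events += w * row["wastage_in_window"]
        if w_sum == 0:
            raise ValueError(f"empty group {group}")
        rates.append(events / (w_sum * window_years))
    return 5.0 * sum(rates)
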