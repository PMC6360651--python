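import numpy as np
import pandas as pd
import pytest

from conftest import covering_rows, make_women
from helpers import (
    oracle_age_schedule,
    oracle_mean_amenorrhea,
    oracle_method_mix,
    oracle_tfr,
    oracle_total_fetal_wastage,
)
from proxfert import (
    AGE_GROUPS,
    AgeSchedule,
    EstimationError,
    EstimationWindow,
    age_schedule,
    estimate_indices,
    mean_amenorrhea,
    method_mix,
    read_women_csv,
    tfr_from_schedule,
    total_fetal_wastage,
    validate_women,
)


class TestValidation:
    def test_missing_columns(self):
        with pytest.raises(EstimationError, match="missing required columns"):
            validate_women(pd.DataFrame({"age_group": ["15-19"]}))

    def test_unknown_age_group(self):
        df = make_women([{"age_group": "50-54"}])
        with pytest.raises(EstimationError, match="unknown age groups"):
            validate_women(df)

    def test_unknown_method(self):
        df = make_women([{"in_union": 1, "method": "implant"}])
        with pytest.raises(EstimationError, match="unknown contraceptive methods"):
            validate_women(df)

    def test_method_without_union(self):
        df = make_women([{"in_union": 0, "method": "pill"}])
        with pytest.raises(EstimationError, match="not in union"):
            validate_women(df)

    def test_nonpositive_weight(self):
        df = make_women([{"weight": 0.0}])
        with pytest.raises(EstimationError, match="weights"):
            validate_women(df)

    def test_default_weight_added(self):
        df = make_women([{}]).drop(columns=["weight"])
        assert (validate_women(df)["weight"] == 1.0).all()


class TestAgeSchedule:
    def test_union_share(self):
        rows = covering_rows()
        rows += [{"age_group": "20-24", "in_union": 1} for _ in range(4)]
        rows += [{"age_group": "20-24", "in_union": 0} for _ in range(5)]
        schedule = age_schedule(make_women(rows))
        # 10 women in 20-24 (incl. the covering row), 4 in union
        assert schedule.m[1] == pytest.approx(0.4)

    def test_birth_rate(self):
        rows = covering_rows()
        rows += [{"age_group": "25-29", "births_in_window": b} for b in (2, 1, 0, 0)]
        schedule = age_schedule(make_women(rows), window=EstimationWindow(3.0))
        # 5 women in 25-29, 3 births over a 3-year window -> 0.2/woman-year
        assert schedule.g[2] == pytest.approx(3 / (5 * 3))

    def test_empty_group_named(self):
        rows = [r for r in covering_rows() if r["age_group"] != "40-44"]
        with pytest.raises(EstimationError, match="40-44"):
            age_schedule(make_women(rows))

    def test_weighted_fixture_matches_oracle(self, weighted_fixture_rows):
        schedule = age_schedule(make_women(weighted_fixture_rows), window=3.0)
        m, g = oracle_age_schedule(weighted_fixture_rows, 3.0)
        assert schedule.m == pytest.approx(m, abs=1e-12)
        assert schedule.g == pytest.approx(g, abs=1e-12)


class TestTfrFromSchedule:
    def test_zero(self):
        assert tfr_from_schedule(AgeSchedule(m=(0.5,) * 7, g=(0.0,) * 7)) == 0.0

    def test_flat_rates(self):
        assert tfr_from_schedule(
            AgeSchedule(m=(0.5,) * 7, g=(0.1,) * 7)
        ) == pytest.approx(3.5)

    def test_fixture_matches_hand_sum(self, weighted_fixture_rows):
        schedule = age_schedule(make_women(weighted_fixture_rows), window=3.0)
        assert tfr_from_schedule(schedule) == pytest.approx(5.0 * sum(schedule.g))
        assert tfr_from_schedule(schedule) == pytest.approx(
            oracle_tfr(weighted_fixture_rows, 3.0), abs=1e-12
        )


class TestMethodMix:
    def test_no_users(self):
        rows = covering_rows(in_union=1)
        mix = method_mix(make_women(rows))
        assert mix.u == 0.0
        assert all(share == 0.0 for share in mix.shares.values())

    def test_direct_proportions(self):
        rows = [{"age_group": "20-24", "in_union": 1} for _ in range(64)]
        rows += [{"age_group": "20-24", "in_union": 1, "method": "pill"} for _ in range(20)]
        rows += [{"age_group": "20-24", "in_union": 1, "method": "injection"} for _ in range(16)]
        mix = method_mix(make_women(rows))
        assert mix.u == pytest.approx(0.36)
        assert mix.shares["pill"] == pytest.approx(0.20)
        assert mix.shares["injection"] == pytest.approx(0.16)

    def test_no_union_errors(self):
        with pytest.raises(EstimationError, match="no in-union"):
            method_mix(make_women(covering_rows(in_union=0)))

    def test_share_sum_equals_u(self, weighted_fixture_rows):
        mix = method_mix(make_women(weighted_fixture_rows))
        assert sum(mix.shares.values()) == pytest.approx(mix.u, abs=1e-12)
        u, shares = oracle_method_mix(weighted_fixture_rows)
        assert mix.u == pytest.approx(u, abs=1e-12)
        for method, share in shares.items():
            assert mix.shares.get(method, 0.0) == pytest.approx(share, abs=1e-12)


class TestMeanAmenorrhea:
    def test_constant(self):
        rows = covering_rows(births_in_window=1, amenorrhea_months=12.0)
        assert mean_amenorrhea(make_women(rows)) == pytest.approx(12.0)

    def test_midpoint(self):
        rows = covering_rows()
        rows += [
            {"age_group": "25-29", "births_in_window": 1, "amenorrhea_months": 6.0},
            {"age_group": "25-29", "births_in_window": 1, "amenorrhea_months": 18.0},
        ]
        assert mean_amenorrhea(make_women(rows)) == pytest.approx(12.0)

    def test_structural_missingness_excluded(self):
        rows = covering_rows()  # nobody has a recent birth
        with pytest.raises(EstimationError, match="amenorrhea"):
            mean_amenorrhea(make_women(rows))

    def test_weighted_fixture(self, weighted_fixture_rows):
        assert mean_amenorrhea(make_women(weighted_fixture_rows)) == pytest.approx(
            oracle_mean_amenorrhea(weighted_fixture_rows), abs=1e-12
        )


class TestTotalFetalWastage:
    def test_zero(self):
        assert total_fetal_wastage(make_women(covering_rows())) == 0.0

    def test_flat_rates(self):
        # 0.02 events/woman-year in every group -> TFW = 5 * 7 * 0.02 = 0.7
        rows = []
        for group in AGE_GROUPS:
            rows += [
                {"age_group": group, "wastage_in_window": 3},
                *[{"age_group": group} for _ in range(49)],
            ]
        value = total_fetal_wastage(make_women(rows), window=EstimationWindow(3.0))
        assert value == pytest.approx(5 * 7 * (3 / (50 * 3)))
        assert value == pytest.approx(0.7)

    def test_fixture_matches_oracle(self, weighted_fixture_rows):
        assert total_fetal_wastage(
            make_women(weighted_fixture_rows), window=3.0
        ) == pytest.approx(
            oracle_total_fetal_wastage(weighted_fixture_rows, 3.0), abs=1e-12
        )


class TestWeightInvariance:
    @pytest.mark.parametrize("k", [0.25, 1.0, 3.7])
    def test_constant_rescaling_is_neutral(self, weighted_fixture_rows, k):
        base = make_women(weighted_fixture_rows)
        scaled = base.copy()
        scaled["weight"] = scaled["weight"] * k
        a = estimate_indices(base)
        b = estimate_indices(scaled)
        assert a.as_dict() == pytest.approx(b.as_dict(), abs=1e-12)


class TestStratumAdditivity:
    def test_weighted_tallies_sum_over_strata(self, weighted_fixture_rows):
        df = make_women(weighted_fixture_rows)
        whole_births = (df["weight"] * df["births_in_window"]).sum()
        whole_weight = df["weight"].sum()
        parts = df.groupby("region")
        assert sum(
            (sub["weight"] * sub["births_in_window"]).sum() for _, sub in parts
        ) == pytest.approx(whole_births, abs=1e-12)
        assert sum(sub["weight"].sum() for _, sub in parts) == pytest.approx(
            whole_weight, abs=1e-12
        )


class TestEstimateIndices:
    def test_all_unmarried_no_births_errors_from_marriage(self):
        df = make_women(covering_rows(in_union=0))
        with pytest.raises(EstimationError, match="index_marriage"):
            estimate_indices(df)

    def test_no_contraception_gives_unit_cc(self):
        rows = covering_rows(in_union=1, births_in_window=1, amenorrhea_months=9.0)
        bundle = estimate_indices(make_women(rows))
        assert bundle.cc == 1.0

    def test_component_errors_carry_identity(self):
        rows = covering_rows(in_union=1, births_in_window=1)  # amenorrhea missing
        with pytest.raises(EstimationError, match="mean_amenorrhea"):
            estimate_indices(make_women(rows))

    def test_fixture_against_component_oracles(self, weighted_fixture_rows):
        import warnings as _warnings

        from proxfert import (
            averted_fetal_wastage,
            index_contraception,
            index_fetal_wastage,
            index_marriage,
            index_postpartum,
        )

        df = make_women(weighted_fixture_rows)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            bundle = estimate_indices(df, window=3.0)
        m, g = oracle_age_schedule(weighted_fixture_rows, 3.0)
        assert bundle.cm == pytest.approx(
            index_marriage(AgeSchedule(m=m, g=g)), abs=1e-12
        )
        u, shares = oracle_method_mix(weighted_fixture_rows)
        eff = {"pill": 0.90, "iud": 0.95, "sterilization": 1.00,
               "injection": 0.99, "other": 0.70}
        e = sum(eff[mth] * s for mth, s in shares.items()) / u
        assert bundle.cc == pytest.approx(index_contraception(u, e), abs=1e-12)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            expected_ci = index_postpartum(oracle_mean_amenorrhea(weighted_fixture_rows))
        assert bundle.ci == pytest.approx(expected_ci, abs=1e-12)
        tfr = oracle_tfr(weighted_fixture_rows, 3.0)
        afw = averted_fetal_wastage(u, oracle_total_fetal_wastage(weighted_fixture_rows, 3.0))
        assert bundle.cfw == pytest.approx(index_fetal_wastage(tfr, afw), abs=1e-12)
        assert bundle.tfr_observed == pytest.approx(tfr, abs=1e-12)


class TestCsvRoundTrip:
    def test_read_women_csv(self, tmp_path, weighted_fixture_rows):
        df = make_women(weighted_fixture_rows)
        path = tmp_path / "women.csv"
        df.to_csv(path, index=False)
        back = read_women_csv(path)
        a = estimate_indices(df)
        b = estimate_indices(back)
        assert a.as_dict() == pytest.approx(b.as_dict(), abs=1e-12)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("age_group,in_union\n15-19,1\n")
        with pytest.raises(EstimationError, match="missing required columns"):
            read_women_csv(path)
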