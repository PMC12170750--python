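import math

import numpy as np
import pytest
from scipy.stats import norm

from osteosex import (
    FEMALE,
    MALE,
    GroupSummary,
    MeasurementRecord,
    StudyDataset,
    classify_by_cutoff,
    d_value,
    evaluate_cutoff,
    filter_calcined,
    fit_cutoff,
    load_fixture,
)
from conftest import grid_cutoff_oracle, make_record


def gs(mean, sd):
    return GroupSummary(n=10, mean=mean, sd=sd, min=mean - 2 * sd, max=mean + 2 * sd)


class TestFitCutoff:
    def test_equal_sd_midpoint(self):
        res = fit_cutoff(gs(0.0, 1.0), gs(2.0, 1.0))
        assert res.cutoff_x0 == pytest.approx(1.0, abs=1e-12)
        assert not res.fallback

    def test_unburnt_published_cutoffs_reproduce(self):
        t3 = load_fixture("table3_unburnt")
        assert fit_cutoff(*t3["maxt"]).cutoff_x0 == pytest.approx(19.41, abs=0.005)
        assert fit_cutoff(*t3["maxw"]).cutoff_x0 == pytest.approx(41.28, abs=0.005)

    def test_unequal_sd_root(self):
        # independently verified by fine grid scan of |densityF - densityM|
        res = fit_cutoff(gs(0.0, 1.0), gs(3.0, 2.0))
        assert res.cutoff_x0 == pytest.approx(1.4183, abs=1e-4)

    def test_agrees_with_grid_scan_oracle(self, rng):
        for _ in range(100):
            mf = rng.uniform(10, 40)
            mm = mf + rng.uniform(0.5, 8)
            f, m = gs(mf, rng.uniform(0.5, 5)), gs(mm, rng.uniform(0.5, 5))
            res = fit_cutoff(f, m)
            assert res.cutoff_x0 == pytest.approx(
                grid_cutoff_oracle(f, m), abs=1e-4
            ), (f, m)

    def test_no_in_interval_crossing_falls_back_to_d_max(self):
        # strongly unequal spreads push both density crossings outside the means
        t2 = load_fixture("table2_burnt")
        res = fit_cutoff(*t2["maxt"])
        assert res.fallback
        assert t2["maxt"][0].mean <= res.cutoff_x0 <= t2["maxt"][1].mean
        assert res.cutoff_x0 == pytest.approx(
            grid_cutoff_oracle(*t2["maxt"]), abs=1e-4
        )

    def test_reversed_polarity_is_flagged(self):
        res = fit_cutoff(gs(5.0, 1.0), gs(3.0, 1.0))
        assert res.polarity_reversed
        assert 3.0 < res.cutoff_x0 < 5.0
        assert res.d_value >= 0

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            fit_cutoff(GroupSummary(5, 10.0, 0.0, 10.0, 10.0), gs(12.0, 1.0))
        with pytest.raises(ValueError, match="equal"):
            fit_cutoff(gs(10.0, 1.0), gs(10.0, 2.0))


class TestDValue:
    def test_published_burnt_d_values_at_published_cutoffs(self):
        t2 = load_fixture("table2_burnt")
        assert d_value(35.87, *t2["maxh"]) == pytest.approx(0.423, abs=1e-3)
        assert d_value(17.55, *t2["maxt"]) == pytest.approx(0.220, abs=1e-3)
        assert d_value(37.53, *t2["maxw"]) == pytest.approx(0.453, abs=1e-3)

    def test_identical_distributions_give_zero(self):
        g = gs(20.0, 2.0)
        assert d_value(19.0, g, g) == 0.0

    def test_symmetric_unit_case(self):
        # Phi(1) - Phi(-1)
        assert d_value(0.0, gs(-1.0, 1.0), gs(1.0, 1.0)) == pytest.approx(
            0.6826894921370859, abs=1e-12
        )

    def test_equal_variance_closed_form(self, rng):
        for _ in range(50):
            mf = rng.uniform(10, 40)
            delta = rng.uniform(0.1, 10)
            s = rng.uniform(0.3, 6)
            f, m = gs(mf, s), gs(mf + delta, s)
            mid = mf + delta / 2
            assert d_value(mid, f, m) == pytest.approx(
                2 * norm.cdf(delta / (2 * s)) - 1, abs=1e-10
            )

    def test_affine_invariance(self, rng):
        for _ in range(25):
            f, m = gs(rng.uniform(10, 30), rng.uniform(1, 4)), gs(
                rng.uniform(31, 50), rng.uniform(1, 4)
            )
            x0 = fit_cutoff(f, m).cutoff_x0
            a, b = rng.uniform(0.5, 3), rng.uniform(-5, 5)
            fa = gs(a * f.mean + b, a * f.sd)
            ma = gs(a * m.mean + b, a * m.sd)
            assert d_value(a * x0 + b, fa, ma) == pytest.approx(
                d_value(x0, f, m), abs=1e-10
            )

    def test_d_maximised_at_fitted_cutoff(self, rng):
        for _ in range(25):
            f = gs(rng.uniform(10, 30), rng.uniform(0.5, 4))
            m = gs(f.mean + rng.uniform(1, 8), rng.uniform(0.5, 4))
            res = fit_cutoff(f, m)
            grid = np.linspace(f.mean, m.mean, 2001)
            d_grid = norm.cdf(grid, f.mean, f.sd) - norm.cdf(grid, m.mean, m.sd)
            assert res.d_value >= d_grid.max() - 1e-9


class TestClassification:
    @pytest.mark.parametrize(
        "value,x0,expected",
        [
            (30.00, 35.87, FEMALE),
            (42.93, 35.87, MALE),  # largest burnt female height exceeds the cut-off
            (35.87, 35.87, MALE),  # boundary goes to male ("falls below" = female)
        ],
    )
    def test_rule_and_tie_break(self, value, x0, expected):
        assert classify_by_cutoff(value, x0) == expected

    def test_nonfinite_is_error(self):
        with pytest.raises(ValueError):
            classify_by_cutoff(float("nan"), 35.0)

    def test_evaluate_cutoff_hand_count(self, toy_dataset):
        rep = evaluate_cutoff(toy_dataset, "maxh", 35.0)
        assert rep.percent_correct_female == 50.0
        assert rep.percent_correct_male == 50.0
        assert rep.percent_correct_total == 50.0
        assert (rep.n_female, rep.n_male) == (2, 2)

    def test_evaluate_cutoff_degenerate_threshold(self, toy_dataset):
        rep = evaluate_cutoff(toy_dataset, "maxh", 0.5)
        assert rep.percent_correct_female == 0.0
        assert rep.percent_correct_male == 100.0

    def test_missing_group_is_error(self):
        ds = StudyDataset(
            records=[make_record("a", FEMALE, 30.0), make_record("b", FEMALE, 31.0)]
        )
        with pytest.raises(ValueError, match="male"):
            evaluate_cutoff(ds, "maxh", 30.5)

    def test_percentages_are_rational_multiples(self, rng):
        recs = [
            make_record(i, FEMALE if i % 2 else MALE, float(rng.uniform(25, 45)))
            for i in range(17)
        ]
        ds = StudyDataset(records=recs)
        rep = evaluate_cutoff(ds, "maxh", 35.0)
        for pct, n in [
            (rep.percent_correct_female, rep.n_female),
            (rep.percent_correct_male, rep.n_male),
            (rep.percent_correct_total, rep.n_female + rep.n_male),
        ]:
            assert (pct * n / 100.0) == pytest.approx(round(pct * n / 100.0), abs=1e-9)

    def test_absent_values_are_excluded_and_counted(self):
        recs = [
            make_record("a", FEMALE, 30.0),
            make_record("b", FEMALE, None),
            make_record("c", MALE, 40.0),
        ]
        rep = evaluate_cutoff(StudyDataset(records=recs), "maxh", 35.0)
        assert rep.n_excluded == 1
        assert rep.percent_correct_total == 100.0


class TestCalcinedFilter:
    def test_retention_rule(self):
        kw = dict(side="right", burn_state="burnt")
        kept = make_record("a", FEMALE, 30.0, burn_temperature=1100.0, burn_colour="white", **kw)
        too_cool = make_record("b", FEMALE, 30.0, burn_temperature=700.0, burn_colour="white", **kw)
        wrong_colour = make_record("c", MALE, 40.0, burn_temperature=900.0, burn_colour="black", **kw)
        unburnt = make_record("d", MALE, 40.0, side="left", burn_state="unburnt")
        boundary = make_record("e", MALE, 41.0, burn_temperature=800.0, burn_colour="white", **kw)
        ds = StudyDataset(records=[kept, too_cool, wrong_colour, unburnt, boundary])
        out = filter_calcined(ds)
        assert [r.individual_id for r in out] == ["a", "e"]

    def test_empty_result_permitted(self, toy_dataset, caplog):
        with caplog.at_level("WARNING", logger="osteosex"):
            out = filter_calcined(toy_dataset)
        assert len(out) == 0
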