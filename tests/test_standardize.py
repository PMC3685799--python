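"""Activity-standardization algebra tests: correction, conservation, efficiencies."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from calorpart.datasets import example_lsmeans
from calorpart.standardize import (
    activity_ratio,
    cohort_summary,
    correct_activity,
    efficiency,
    impute_missing_fhp,
    net_energy,
)


class TestActivityRatio:
    def test_single_and_mean_of_ratios(self):
        assert activity_ratio([180.0], [2000.0]) == pytest.approx(0.09)
        assert activity_ratio([160.0, 200.0], [2000.0, 2000.0]) == pytest.approx(0.09)

    def test_mean_of_ratios_not_ratio_of_means(self):
        # AHP/ME = {0.10, 0.05} but ratio of sums would be 0.0667
        r = activity_ratio([100.0, 100.0], [1000.0, 2000.0])
        assert r == pytest.approx(0.075)

    def test_synthetic_cohort_recovers_generating_mean(self):
        rng = np.random.default_rng(5)
        me = rng.uniform(1800, 2600, 200)
        ratios = rng.normal(0.086, 0.01, 200)
        assert activity_ratio(ratios * me, me) == pytest.approx(
            ratios.mean(), rel=1e-12
        )

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            activity_ratio([], [])


class TestCorrectActivity:
    def test_above_ratio_branch_hand_arithmetic(self):
        cb = correct_activity(2000.0, 700.0, 200.0, 300.0, 800.0, 0.086)
        assert cb.AHP_c == pytest.approx(172.0)
        assert cb.TEF_c == pytest.approx(307.636, abs=5e-3)
        assert cb.RE_c == pytest.approx(820.364, abs=5e-3)
        # conservation: components still sum to ME
        assert 700.0 + cb.AHP_c + cb.TEF_c + cb.RE_c == pytest.approx(2000.0)

    def test_below_ratio_branch_hand_arithmetic(self):
        cb = correct_activity(2000.0, 700.0, 150.0, 300.0, 850.0, 0.086)
        assert cb.AHP_c == pytest.approx(172.0)
        assert cb.TEF_c == pytest.approx(294.261, abs=5e-3)
        assert cb.RE_c == pytest.approx(833.739, abs=5e-3)

    def test_fixed_point_when_ahp_already_at_ratio(self):
        cb = correct_activity(2000.0, 700.0, 172.0, 300.0, 828.0, 0.086)
        assert cb.AHP_c == pytest.approx(172.0)
        assert cb.TEF_c == pytest.approx(300.0)
        assert cb.RE_c == pytest.approx(828.0)

    def test_idempotence(self):
        cb = correct_activity(2000.0, 700.0, 230.0, 310.0, 760.0, 0.086)
        cb2 = correct_activity(2000.0, 700.0, cb.AHP_c, cb.TEF_c, cb.RE_c, 0.086)
        assert cb2.TEF_c == pytest.approx(cb.TEF_c)
        assert cb2.RE_c == pytest.approx(cb.RE_c)

    def test_tef_c_strictly_increasing_in_ahp(self):
        tefs = [
            correct_activity(2000.0, 700.0, ahp, 300.0, 1000.0 - ahp, 0.086).TEF_c
            for ahp in (120.0, 160.0, 200.0, 240.0)
        ]
        assert np.all(np.diff(tefs) > 0)

    def test_me_below_fhp_plus_ahp_rejected(self):
        with pytest.raises(ValueError, match="A7"):
            correct_activity(900.0, 700.0, 250.0, 100.0, -150.0, 0.086,
                             animal_id="A7")

    @given(
        me=st.floats(1500, 3500),
        fhp_frac=st.floats(0.2, 0.45),
        ahp_frac=st.floats(0.02, 0.16),
        tef_frac=st.floats(0.05, 0.3),
        ratio=st.floats(0.05, 0.12),
    )
    def test_conservation_exact_on_random_records(
        self, me, fhp_frac, ahp_frac, tef_frac, ratio
    ):
        fhp, ahp, tef = me * fhp_frac, me * ahp_frac, me * tef_frac
        re = me - fhp - ahp - tef
        cb = correct_activity(me, fhp, ahp, tef, re, ratio)
        assert fhp + cb.AHP_c + cb.TEF_c + cb.RE_c == pytest.approx(me, rel=1e-12)


class TestEfficiency:
    def test_zero_hi_limit(self):
        eff = efficiency(700.0, 0.0, 2000.0)
        assert eff.k_mg == pytest.approx(100.0)
        assert eff.me_m == pytest.approx(700.0)

    def test_hand_arithmetic(self):
        eff = efficiency(700.0, 479.64, 2000.0)
        assert eff.k_mg == pytest.approx(76.018, abs=1e-3)
        assert eff.me_m == pytest.approx(920.83, abs=0.05)

    def test_published_em_means_give_printed_me_m(self):
        # FHP 856, HI_c 21.6% of ME -> ME_m 1091 within LS-mean rounding
        ls = example_lsmeans()
        me = ls.loc["me", "EM"]
        eff = efficiency(
            ls.loc["fhp", "EM"], ls.loc["hi_c_pct_me", "EM"] / 100.0 * me, me
        )
        assert eff.me_m == pytest.approx(1091.0, rel=0.005)

    def test_hi_at_or_above_me_rejected(self):
        with pytest.raises(ValueError):
            efficiency(700.0, 2000.0, 2000.0)


class TestNetEnergy:
    def test_hand_arithmetic(self):
        ne, me_content, ne_content = net_energy(38.92, 9.00, 2.53)
        assert ne == pytest.approx(29.92)
        assert ne_content == pytest.approx(11.83, abs=0.005)

    def test_zero_hi_equalizes_contents(self):
        ne, me_content, ne_content = net_energy(38.92, 0.0, 2.53)
        assert ne_content == pytest.approx(me_content)

    def test_content_decreasing_in_hi(self):
        contents = [net_energy(38.92, hi, 2.53)[2] for hi in (0.0, 4.0, 8.0, 12.0)]
        assert np.all(np.diff(contents) < 0)


class TestImputation:
    def _cohort(self, fhps, classes=None):
        classes = classes or ["SC"] * len(fhps)
        return pd.DataFrame({"sex_class": classes, "fhp": fhps})

    def test_mean_of_same_class_values(self):
        df = self._cohort([700.0, 720.0, 740.0, 760.0, 780.0])
        assert impute_missing_fhp(df, "SC") == pytest.approx(740.0)

    def test_single_value_returned_as_is(self):
        df = self._cohort([731.0])
        assert impute_missing_fhp(df, "SC") == 731.0

    def test_other_classes_excluded(self):
        df = self._cohort([700.0, 900.0], classes=["SC", "EM"])
        assert impute_missing_fhp(df, "SC") == 700.0

    def test_no_values_rejected(self):
        df = self._cohort([np.nan])
        with pytest.raises(ValueError, match="SC"):
            impute_missing_fhp(df, "SC")


class TestCohortSummary:
    def test_published_castrated_group_averages(self):
        # SC/IC TEF_c 464 and 484 -> 474; NE 11.42 and 11.25 -> 11.34
        ls = example_lsmeans()
        df = ls.T.reset_index(names="sex_class")
        means = cohort_summary(df, "sex_class")
        castrated = means.loc[["SC", "IC"]].mean()
        assert castrated["tef_c"] == pytest.approx(474.0)
        assert castrated["ne_content_mj_kg_dm"] == pytest.approx(11.34, abs=0.005)

    def test_single_group_is_identity(self):
        df = pd.DataFrame({"sex_class": ["EM"], "x": [3.0]})
        assert cohort_summary(df, "sex_class").loc["EM", "x"] == 3.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary(pd.DataFrame(columns=["sex_class"]), "sex_class")
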