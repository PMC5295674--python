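"""Indicator scoring: HAZ/stunting, HFIAS, dietary diversity, wealth, TEM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stuntgeo import indicators as ind


# ---------------------------------------------------------------------------
# HAZ / stunting
# ---------------------------------------------------------------------------

class TestComputeHaz:
    def test_median_child_scores_zero(self, lms_table):
        row = lms_table[(lms_table.sex == "male") & (lms_table.age_months == 24)].iloc[0]
        assert ind.compute_haz(row.M, 24, "male", lms_table) == pytest.approx(0.0, abs=1e-12)

    def test_linear_case(self):
        ref = pd.DataFrame({"sex": ["male"], "age_months": [12], "L": [1.0],
                            "M": [80.0], "S": [0.05]})
        # L = 1 makes the formula exactly linear: (76/80 - 1)/0.05 = -1
        assert ind.compute_haz(76.0, 12, "male", ref) == pytest.approx(-1.0)

    def test_negative_power_matches_direct_formula(self):
        # independent numeric evaluation of ((h/M)^L - 1)/(L*S) at L = -0.5
        ref = pd.DataFrame({"sex": ["female"], "age_months": [6], "L": [-0.5],
                            "M": [85.0], "S": [0.04]})
        expected = ((80.0 / 85.0) ** -0.5 - 1.0) / (-0.5 * 0.04)
        assert expected == pytest.approx(-1.53883, abs=1e-4)  # frozen oracle value
        assert ind.compute_haz(80.0, 6, "female", ref) == pytest.approx(expected, rel=1e-12)

    def test_log_branch_when_power_zero(self):
        ref = pd.DataFrame({"sex": ["male"], "age_months": [3], "L": [0.0],
                            "M": [60.0], "S": [0.04]})
        expected = np.log(58.0 / 60.0) / 0.04
        assert ind.compute_haz(58.0, 3, "male", ref) == pytest.approx(expected, rel=1e-12)

    def test_uncovered_age_raises_lookup_error(self, lms_table):
        with pytest.raises(LookupError):
            ind.compute_haz(80.0, 99, "male", lms_table)

    def test_nonpositive_height_rejected(self, lms_table):
        with pytest.raises(ValueError):
            ind.compute_haz(0.0, 12, "male", lms_table)


class TestClassifyStunting:
    @pytest.mark.parametrize(
        "haz, expected",
        [(-2.0, ind.NOT_STUNTED),        # strict boundary: -2 exactly is not stunted
         (-2.5, ind.STUNTED),
         (-3.0, ind.STUNTED),            # strict boundary at -3 as well
         (-3.5, ind.SEVERELY_STUNTED),
         (0.4, ind.NOT_STUNTED)],
    )
    def test_thresholds(self, haz, expected):
        assert ind.classify_stunting(haz) == expected

    def test_partition_is_exclusive_and_exhaustive(self, rng):
        z = rng.normal(-1.5, 2.0, 500)
        classes = ind.classify_stunting(z)
        assert set(np.unique(classes)) <= {ind.NOT_STUNTED, ind.STUNTED, ind.SEVERELY_STUNTED}
        # severe subset of the <-2 prevalence definition
        assert (((z < -3) == (classes == ind.SEVERELY_STUNTED)).all())
        assert (((z < -2) == np.isin(classes, [ind.STUNTED, ind.SEVERELY_STUNTED])).all())

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ind.classify_stunting(np.nan)

    def test_implausible_flag(self):
        assert list(ind.is_implausible_haz([-6.5, -5.9, 7.0])) == [True, False, True]


# ---------------------------------------------------------------------------
# HFIAS
# ---------------------------------------------------------------------------

def _profile(**kv):
    occ = np.zeros(9, int)
    freq = np.ones(9, int)
    for item, f in kv.items():
        i = int(item[1:]) - 1
        occ[i], freq[i] = 1, f
    return occ, freq


class TestHfiasCategory:
    @pytest.mark.parametrize(
        "items, expected",
        [({}, 1),                      # none experienced -> food secure
         ({"q1": 1}, 1),               # sporadic worry only
         ({"q1": 2}, 2), ({"q2": 1}, 2), ({"q3": 1}, 2), ({"q4": 1}, 2),
         ({"q3": 2}, 3), ({"q4": 3}, 3), ({"q5": 1}, 3), ({"q6": 2}, 3),
         ({"q5": 3}, 4), ({"q6": 3}, 4),
         ({"q7": 1}, 4), ({"q8": 1}, 4), ({"q9": 1}, 4),   # last three scenarios
         ({"q1": 3, "q5": 2}, 3), ({"q2": 3, "q8": 1}, 4)],
    )
    def test_decision_table(self, items, expected):
        occ, freq = _profile(**items)
        assert ind.hfias_category(occ, freq) == expected

    def test_strict_severe_rule_differs_only_for_q5_q6_often(self):
        occ, freq = _profile(q5=3)
        assert ind.hfias_category(occ, freq, severe_rule="standard") == 4
        assert ind.hfias_category(occ, freq, severe_rule="strict") == 3
        occ, freq = _profile(q8=1)
        assert ind.hfias_category(occ, freq, severe_rule="strict") == 4

    def test_missing_item_reports_index(self):
        occ = np.zeros(9, float)
        occ[4] = np.nan
        with pytest.raises(ValueError, match="item 5"):
            ind.hfias_category(occ, np.ones(9))

    def test_missing_frequency_for_affirmed_item(self):
        occ, freq = _profile(q3=1)
        f = freq.astype(float)
        f[2] = np.nan
        with pytest.raises(ValueError, match="item 3"):
            ind.hfias_category(occ, f)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=9, max_size=9), st.data())
    def test_monotonicity(self, levels, data):
        """Making any response more severe never lowers the category."""
        base = np.asarray(levels)
        i = data.draw(st.integers(0, 8))
        worse = base.copy()
        worse[i] = data.draw(st.integers(base[i], 3))
        def cat(lv):
            return ind.hfias_category((lv > 0).astype(int), np.maximum(lv, 1))
        assert cat(worse) >= cat(base)


# ---------------------------------------------------------------------------
# Dietary diversity
# ---------------------------------------------------------------------------

class TestDietaryDiversity:
    @pytest.mark.parametrize("k, expected", [(0, "lowest"), (3, "lowest"),
                                             (4, "medium"), (5, "medium"),
                                             (6, "high"), (7, "high"), (12, "high")])
    def test_classes(self, k, expected):
        flags = [1] * k + [0] * (12 - k)
        score, cls = ind.dietary_diversity(flags)
        assert score == k and cls == expected

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            ind.dietary_diversity([1] * 11)


# ---------------------------------------------------------------------------
# Wealth index
# ---------------------------------------------------------------------------

class TestWealthIndex:
    def test_single_effective_indicator_orders_quintiles(self, rng):
        n = 50
        x = np.arange(n, dtype=float)
        assets = pd.DataFrame({"asset_a": x, "asset_const": np.ones(n),
                               "asset_b": x + rng.normal(0, 1e-9, n)})
        wi = ind.wealth_index(assets, positive_indicator="asset_a")
        # quintile ordering must follow the dominant indicator's ordering
        assert (np.diff(wi.quintiles.to_numpy()[np.argsort(x)]) >= 0).all()
        assert wi.quintiles.iloc[0] == 1 and wi.quintiles.iloc[-1] == 5

    def test_explained_share_matches_eigendecomposition(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 5)), columns=list("abcde"))
        X["a"] += X["b"]  # induce correlation
        wi = ind.wealth_index(X, positive_indicator="a")
        Z = (X - X.mean()) / X.std(ddof=0)
        eig = np.linalg.eigvalsh(np.corrcoef(Z.to_numpy().T))
        assert wi.explained_share == pytest.approx(eig.max() / eig.sum(), rel=1e-8)

    def test_sign_flip_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        wa = ind.wealth_index(X, positive_indicator="a")
        flipped = X.copy()
        flipped["a"] *= -1
        wb = ind.wealth_index(flipped, positive_indicator="b")
        # partition sizes invariant to the orientation convention
        assert (wa.quintiles.value_counts().sort_index().to_numpy()
                == wb.quintiles.value_counts().sort_index().to_numpy()).all()

    def test_quintiles_balanced(self, rng):
        X = pd.DataFrame(rng.normal(size=(101, 4)), columns=list("abcd"))
        wi = ind.wealth_index(X, positive_indicator="a")
        counts = wi.quintiles.value_counts()
        assert counts.max() - counts.min() <= 2  # 101 households across 5 bins

    def test_constant_matrix_rejected(self):
        X = pd.DataFrame({"a": np.ones(10), "b": np.zeros(10)})
        with pytest.raises(ValueError):
            ind.wealth_index(X)


# ---------------------------------------------------------------------------
# TEM / reliability
# ---------------------------------------------------------------------------

class TestTechnicalError:
    def test_identical_duplicates(self):
        tem, r = ind.technical_error_of_measurement([80, 90, 100], [80, 90, 100])
        assert tem == 0.0 and r == 1.0

    def test_closed_form_two_subjects(self):
        # diffs 1 and 1 cm: TEM = sqrt((1+1)/4) = sqrt(0.5)
        tem, _ = ind.technical_error_of_measurement([80.0, 90.0], [81.0, 91.0])
        assert tem == pytest.approx(np.sqrt(0.5))

    def test_reliability_matches_error_share(self, rng):
        # R should estimate 1 - error variance / total variance
        n, s_true, s_err = 4000, 4.0, 1.0
        truth = rng.normal(90, s_true, n)
        m1 = truth + rng.normal(0, s_err, n)
        m2 = truth + rng.normal(0, s_err, n)
        _, r = ind.technical_error_of_measurement(m1, m2)
        expected = 1.0 - s_err**2 / (s_true**2 + s_err**2)
        assert r == pytest.approx(expected, abs=0.02)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            ind.technical_error_of_measurement([80.0], [81.0])
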