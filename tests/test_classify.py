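import itertools

import numpy as np
import pandas as pd
import pytest

from stripenet.classify import (
    category_census,
    classify_category,
    classify_type,
    inducer_dependence,
    summarize_by_genotype,
)
from stripenet.core import enumerate_genotypes


def oracle_type(singles, combined, eps):
    """Brute-force ordering oracle for the type decision table.

    Works from min/max orderings for same-direction singles and from the
    per-single positions otherwise; written independently of the
    implementation's crossing loop.
    """
    if eps == 0:
        return ("none", "none")
    sign = "positive" if eps > 0 else "negative"
    lo, hi = min(singles), max(singles)
    if all(s > 0 for s in singles):
        form = "RSE" if combined < lo else ("magnitude" if combined > hi else "sign")
    elif all(s < 0 for s in singles):
        form = "RSE" if combined > hi else ("magnitude" if combined < lo else "sign")
    else:
        # mixed direction: a single is crossed when the combination falls on
        # the WT-ward side of its level
        crossed = sum(
            1 for s in singles if (s > 0 and combined < s) or (s < 0 and combined > s)
        )
        form = (
            "RSE"
            if crossed == len(singles)
            else ("magnitude" if crossed == 0 else "sign")
        )
    return sign, form


class TestClassifyType:
    @pytest.mark.parametrize(
        "singles,combined,expected_sign,expected_form",
        [
            ((0.3, 0.2), 0.1, "negative", "RSE"),  # below both singles
            ((0.3, 0.2), 0.25, "negative", "sign"),  # crosses one only
            ((0.3, 0.2), 0.45, "negative", "magnitude"),  # short of 0.5
            ((0.3, 0.2), 0.6, "positive", "magnitude"),  # beyond 0.5
            ((-0.3, -0.2), -0.1, "positive", "RSE"),  # mirrored all-lower
        ],
    )
    def test_worked_examples(self, singles, combined, expected_sign, expected_form):
        eps = combined - sum(singles)
        tc = classify_type(singles, combined, eps)
        assert (tc.sign, tc.form) == (expected_sign, expected_form)

    def test_direction_groups(self):
        assert classify_type((0.3, 0.2), 0.1, -0.4).direction_group == "all_higher"
        assert classify_type((-0.3, -0.2), -0.6, -0.1).direction_group == "all_lower"
        assert classify_type((0.3, -0.2), 0.0, -0.1).direction_group == "mixed"

    def test_zero_epsilon_is_none_class(self):
        tc = classify_type((0.3, 0.2), 0.5, 0.0)
        assert tc.form == "none" and tc.sign == "none"

    def test_agrees_with_ordering_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10_000):
            k = rng.integers(2, 4)
            singles = tuple(rng.normal(0, 0.4, size=k))
            combined = rng.normal(0, 0.6)
            eps = combined - sum(singles)
            tc = classify_type(singles, combined, eps)
            assert (tc.sign, tc.form) == oracle_type(singles, combined, eps)


def oracle_category(e):
    """Ordering oracle: position of the medium value among the three."""
    lo, me, hi = e
    if me == max(e):
        return "A"
    if me == min(e):
        return "D"
    return "B" if lo < hi else "C"


class TestClassifyCategory:
    @pytest.mark.parametrize(
        "eps,cat,traj",
        [
            ((-0.1, 0.2, 0.1), "A", "switching"),
            ((-0.3, -0.2, -0.1), "B", "always_negative"),
            ((0.3, 0.2, 0.1), "C", "always_positive"),
            ((0.2, -0.1, 0.3), "D", "switching"),
        ],
    )
    def test_worked_examples(self, eps, cat, traj):
        c, t, tie = classify_category(*eps)
        assert (c, t, tie) == (cat, traj, False)

    def test_all_strict_orderings_partition_exactly_once(self):
        """Every strict ordering of three reals maps to exactly one category."""
        for perm in itertools.permutations((1.0, 2.0, 3.0)):
            c, _, tie = classify_category(*perm)
            assert not tie
            assert c == oracle_category(perm)
        # census over the 6 orderings: A and D twice (medium extremum), B/C once
        cats = [classify_category(*p)[0] for p in itertools.permutations((1.0, 2.0, 3.0))]
        assert sorted(cats) == ["A", "A", "B", "C", "D", "D"]

    def test_random_triples_against_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(10_000):
            e = tuple(rng.normal(size=3))
            c, t, tie = classify_category(*e)
            assert c == oracle_category(e)
            assert not tie
            assert t == ("switching" if len({v > 0 for v in e}) > 1
                         else ("always_positive" if e[0] > 0 else "always_negative"))

    def test_ties_break_toward_medium_extremum_with_flag(self):
        c, _, tie = classify_category(0.2, 0.2, 0.1)
        assert c == "A" and tie
        c, _, tie = classify_category(0.1, 0.1, 0.2)
        assert c == "D" and tie
        c, _, tie = classify_category(0.5, 0.5, 0.5)
        assert c == "A" and tie

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_category(0.1, float("nan"), 0.2)


def _records(eps_by_level, sd=0.01):
    rows = []
    for (g, order), eps in eps_by_level.items():
        for lvl, e in zip(("low", "medium", "high"), eps):
            rows.append(
                {
                    "genotype": g,
                    "order": order,
                    "inducer_label": lvl,
                    "epsilon": e,
                    "sd_obs": sd,
                    "sd_exp": sd,
                }
            )
    return pd.DataFrame(rows)


class TestInducerDependence:
    def test_identical_levels_not_dependent(self):
        rec = _records({("sensor-1+output-1", 2): (0.2, 0.2, 0.2)})
        prof = inducer_dependence(rec, sigma_mode="sum_of_variances")
        assert not prof["dependent"].iloc[0]
        assert np.allclose(prof[["p_lm", "p_lh", "p_mh"]], 1.0)

    def test_extreme_separation_is_dependent(self):
        rec = _records(
            {("sensor-1+output-1", 2): (0.0, 0.0, 5.0)}, sd=1e-4
        )
        prof = inducer_dependence(rec, sigma_mode="sum_of_variances")
        assert bool(prof["dependent"].iloc[0])

    def test_family_size_three_contrasts_per_combination(self):
        eps = {}
        rng = np.random.default_rng(23)
        for g in enumerate_genotypes(2):
            if g.order == 2:
                eps[(g.name(), 2)] = tuple(rng.normal(size=3))
        prof = inducer_dependence(_records(eps), sigma_mode="sum_of_variances")
        assert len(prof) == 12
        assert {"p_lm", "p_lh", "p_mh", "q_lm", "q_lh", "q_mh"} <= set(prof.columns)

    def test_census_percentages_sum_to_100(self):
        rng = np.random.default_rng(24)
        eps = {
            (g.name(), g.order): tuple(rng.normal(size=3))
            for g in enumerate_genotypes(2)
            if g.order >= 2
        }
        prof = inducer_dependence(_records(eps), sigma_mode="sum_of_variances")
        census = category_census(prof)
        for _, sub in census.groupby("order"):
            assert sub["pct"].sum() == pytest.approx(100.0)


class TestSummarizeByGenotype:
    @staticmethod
    def _constant_records(M=10, eps=-0.2):
        rows = [
            {
                "genotype": g.name(),
                "order": g.order,
                "inducer_label": lvl,
                "epsilon": eps,
            }
            for g in enumerate_genotypes(M)
            if g.order >= 2
            for lvl in ("low", "medium", "high")
        ]
        return pd.DataFrame(rows)

    def test_counts_per_single_at_study_scale(self):
        """60 pairwise and 300 triplet eps values per single mutant at M=10."""
        agg = summarize_by_genotype(self._constant_records())
        pair = agg[agg["order"] == 2]
        trip = agg[agg["order"] == 3]
        assert set(pair["n"]) == {60}
        assert set(trip["n"]) == {300}
        assert len(pair) == len(trip) == 30

    def test_constant_epsilon_summaries(self):
        agg = summarize_by_genotype(self._constant_records(M=2))
        assert np.allclose(agg["mean"], -0.2)
        assert np.allclose(agg["sd"], 0.0)
        assert np.allclose(agg["cov"], 0.0)

    def test_zero_mean_cov_undefined(self):
        rec = self._constant_records(M=2)
        rec["epsilon"] = np.tile([-0.1, 0.1, 0.0], len(rec) // 3 + 1)[: len(rec)]
        agg = summarize_by_genotype(rec)
        zero_mean = agg[np.isclose(agg["mean"], 0)]
        if not zero_mean.empty:
            assert zero_mean["cov"].isna().all()

    def test_node_level_grouping(self):
        agg = summarize_by_genotype(self._constant_records(M=2), grouping="node_level")
        assert set(agg["node"]) == {"sensor", "regulator", "output"}
        assert {"low", "medium", "high"} == set(agg["inducer_label"])
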