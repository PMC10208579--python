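import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from conftest import random_lfc
from stripenet.epistasis import (
    epistasis,
    epistasis_table,
    expected_G,
    fdr_adjust,
    log_fold_changes,
    sigma_epistasis,
    storey_qvalues,
    t_test_summary,
    third_order,
)

LOG2 = math.log10(2)


def tidy(records):
    """records: (genotype, level, [replicate fluorescences])."""
    rows = []
    for g, lvl, vals in records:
        for i, v in enumerate(vals, 1):
            rows.append((g, lvl, 0.0, i, v))
    return pd.DataFrame(
        rows,
        columns=["genotype", "inducer_label", "inducer_pct", "replicate", "fluorescence"],
    )


class TestLogFoldChanges:
    def test_reference_and_simple_ratios(self):
        df = tidy(
            [
                ("WT", "low", [1.0, 1.0, 1.0]),
                ("sensor-1", "low", [10.0, 10.0, 10.0]),
                ("regulator-1", "low", [2.0, 2.0, 2.0]),
            ]
        )
        out = log_fold_changes(df).set_index("genotype")
        assert out.loc["WT", "G"] == 0.0
        assert out.loc["sensor-1", "G"] == pytest.approx(1.0)
        assert out.loc["sensor-1", "sd"] == 0.0
        assert out.loc["regulator-1", "G"] == pytest.approx(LOG2)

    def test_nonpositive_fluorescence_dropped(self, caplog):
        df = tidy(
            [("WT", "low", [1.0, 1.0, 1.0]), ("sensor-1", "low", [2.0, -1.0, 2.0])]
        )
        with caplog.at_level("WARNING"):
            out = log_fold_changes(df).set_index("genotype")
        assert out.loc["sensor-1", "n"] == 2
        assert "non-positive" in caplog.text

    def test_missing_wt_is_an_error(self):
        df = tidy([("sensor-1", "low", [2.0, 2.0, 2.0])])
        with pytest.raises(ValueError, match="WT"):
            log_fold_changes(df)


class TestExpectedG:
    def test_sum_of_logs(self):
        g, sd = expected_G([math.log10(2), math.log10(5)], [0.0, 0.0])
        assert g == pytest.approx(1.0)
        assert sd == 0.0

    def test_as_printed_sigma_uses_mean_multiplier(self):
        # x̄ = 0.5, sqrt(0.3^2 + 0.4^2) = 0.5 → 0.25
        g, sd = expected_G([0.2, 0.3], [0.3, 0.4], sigma_mode="as_printed")
        assert sd == pytest.approx(0.25)

    def test_sum_of_variances_mode(self):
        _, sd = expected_G([0.2, 0.3], [0.3, 0.4], sigma_mode="sum_of_variances")
        assert sd == pytest.approx(0.5)

    def test_arity_checked(self):
        with pytest.raises(ValueError):
            expected_G([0.1], [0.1])


class TestEpsilon:
    def test_multiplicative_null_is_zero(self):
        g_exp, _ = expected_G([math.log10(2), math.log10(5)], [0, 0])
        assert epistasis(math.log10(10), g_exp) == pytest.approx(0.0)

    def test_tenfold_shortfall(self):
        assert epistasis(math.log10(1), math.log10(10)) == pytest.approx(-1.0)

    def test_example_observed_point_six(self):
        g_exp, _ = expected_G([math.log10(2), math.log10(3)], [0, 0])
        assert epistasis(math.log10(0.6), g_exp) == pytest.approx(-1.0)

    def test_antisymmetry(self):
        assert epistasis(0.7, 0.2) == -epistasis(0.2, 0.7)


class TestThirdOrder:
    def test_hand_worked_triplet(self):
        """Singles g=2 each, pairs observed g=2, triplet observed g=1."""
        singles = [LOG2] * 3
        pairs = [LOG2] * 3
        g_trip = 0.0  # log10(1)
        g_exp, _ = expected_G(singles, [0, 0, 0])
        eps_trip = epistasis(g_trip, g_exp)
        assert eps_trip == pytest.approx(-3 * LOG2)  # ~ -0.90309
        g_tilde, eps3 = third_order(g_trip, pairs, singles)
        assert g_tilde == pytest.approx(0.0)
        # the pairs already carry all the epistasis, so none is exclusive
        assert eps3 == pytest.approx(0.0)
        sum_pair_eps = sum(p - 2 * LOG2 for p in pairs)
        assert sum_pair_eps == pytest.approx(-3 * LOG2)
        assert eps_trip == pytest.approx(eps3 + sum_pair_eps)

    def test_no_pairwise_epistasis_reduces_to_triplet_epsilon(self):
        singles = [0.1, 0.2, -0.3]
        pairs = [0.3, -0.2, -0.1]  # each pair = sum of its singles
        g_trip = 0.25
        g_tilde, eps3 = third_order(g_trip, pairs, singles)
        eps_trip = g_trip - sum(singles)
        assert eps3 == pytest.approx(eps_trip)

    def test_expected_triplet_gives_zero_exclusive_epistasis(self):
        singles = [0.1, 0.4, -0.2]
        pairs = [0.6, 0.0, 0.3]
        g_trip = sum(pairs) - sum(singles)  # observed equals pairs-based expectation
        _, eps3 = third_order(g_trip, pairs, singles)
        assert eps3 == pytest.approx(0.0)


def _t_density(x, df):
    # Student-t pdf written from its definition (independent oracle)
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + x**2 / df) ** (-(df + 1) / 2)


class TestTTestSummary:
    def test_equal_means_null(self):
        t, df, p = t_test_summary(0.5, 0.1, 3, 0.5, 0.2, 3)
        assert t == 0 and p == 1 and df == 4

    def test_pooled_worked_example_vs_integration_oracle(self):
        t, df, p = t_test_summary(0.0, 0.1, 3, 0.3, 0.1, 3, variant="pooled")
        assert df == 4
        assert t == pytest.approx(-0.3 / (0.1 * math.sqrt(2 / 3)), rel=1e-9)
        p_oracle = 2 * quad(_t_density, abs(t), np.inf, args=(df,))[0]
        assert p == pytest.approx(p_oracle, abs=1e-6)
        assert p == pytest.approx(0.0213, abs=5e-4)

    def test_welch_vs_integration_oracle(self):
        t, df, p = t_test_summary(0.0, 0.1, 3, 0.3, 0.3, 4, variant="welch")
        v1, v2 = 0.1**2 / 3, 0.3**2 / 4
        df_oracle = (v1 + v2) ** 2 / (v1**2 / 2 + v2**2 / 3)
        assert df == pytest.approx(df_oracle)
        p_oracle = 2 * quad(_t_density, abs(t), np.inf, args=(df,))[0]
        assert p == pytest.approx(p_oracle, abs=1e-6)

    def test_group_swap_symmetry(self):
        t1, _, p1 = t_test_summary(0.1, 0.2, 3, 0.5, 0.3, 3)
        t2, _, p2 = t_test_summary(0.5, 0.3, 3, 0.1, 0.2, 3)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_degenerate_cases(self):
        _, _, p = t_test_summary(0.3, 0.0, 3, 0.3, 0.0, 3)
        assert p == 1.0
        with pytest.warns(UserWarning):
            t, _, p = t_test_summary(0.0, 0.0, 3, 0.3, 0.0, 3)
        assert p == 0.0 and t == -np.inf

    def test_input_validation(self):
        with pytest.raises(ValueError):
            t_test_summary(0, 0.1, 1, 0, 0.1, 3)
        with pytest.raises(ValueError):
            t_test_summary(0, 0.1, 3, 0, 0.1, 3, variant="bayes")


class TestFDR:
    def test_identical_ps_bh(self):
        q, _ = fdr_adjust([0.02] * 5, method="bh")
        assert np.allclose(q, 0.02)

    def test_bh_step_up_hand_example(self):
        # min over ranks r >= i of p_r * m / r: all collapse to 0.04
        q, sig = fdr_adjust([0.01, 0.02, 0.03, 0.04], method="bh")
        assert np.allclose(q, 0.04)
        assert sig.all()

    def test_storey_with_pi0_one_equals_bh(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        q_bh, _ = fdr_adjust(p, method="bh")
        assert np.allclose(storey_qvalues(p, pi0=1.0), q_bh)

    def test_storey_pi0_bounded_and_q_monotone(self):
        rng = np.random.default_rng(6)
        p = np.concatenate([rng.uniform(size=300), rng.uniform(0, 0.01, size=50)])
        q, _ = fdr_adjust(p, method="storey")
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_bky_rejects_more_than_bh_under_signal(self):
        rng = np.random.default_rng(7)
        p = np.concatenate([rng.uniform(size=100), rng.uniform(0, 1e-4, size=100)])
        _, sig_bh = fdr_adjust(p, method="bh", threshold=0.05)
        _, sig_bky = fdr_adjust(p, method="bky", threshold=0.05)
        assert sig_bky.sum() >= sig_bh.sum()

    def test_p_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestSigmaEpistasis:
    def test_modes_and_degenerate_zero(self):
        assert sigma_epistasis(2.0, 0.3, 0.4) == pytest.approx(1.0)
        assert sigma_epistasis(2.0, 0.3, 0.4, "sum_of_variances") == pytest.approx(0.5)
        assert sigma_epistasis(1.0, 0.0, 0.0) == 0.0
        assert sigma_epistasis(0.0, 0.3, 0.4) == 0.0  # as-printed degeneracy


class TestEpistasisTable:
    def test_record_counts_m2(self):
        rng = np.random.default_rng(8)
        tab = epistasis_table(random_lfc(rng, mutants_per_node=2))
        assert (tab["order"] == 2).sum() == 12 * 3
        assert (tab["order"] == 3).sum() == 8 * 3

    def test_decomposition_identity_random_tables(self):
        """eps = eps3 + sum of pairwise eps for every triplet, any input."""
        rng = np.random.default_rng(9)
        for _ in range(25):
            tab = epistasis_table(random_lfc(rng, mutants_per_node=2))
            trip = tab[tab["order"] == 3]
            resid = trip["epsilon"] - trip["epsilon3_exclusive"] - trip["sum_pairwise_epsilon"]
            assert resid.abs().max() < 1e-9

    def test_missing_singles_error_names_the_gap(self):
        rng = np.random.default_rng(10)
        lfc = random_lfc(rng, mutants_per_node=1)
        lfc = lfc[lfc["genotype"] != "regulator-1"]
        with pytest.raises(ValueError, match="regulator-1"):
            epistasis_table(lfc)

    def test_null_cv0_all_zero_none_significant(self, null_cv0_m10_table):
        tab = null_cv0_m10_table
        assert tab["epsilon"].abs().max() < 1e-12
        assert not tab["significant"].any()
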