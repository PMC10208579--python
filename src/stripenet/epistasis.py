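"""Multiplicative-model epistasis: fold changes, expected vs observed log
expression, pairwise and exclusive third-order epistasis, error propagation,
and significance testing with FDR control.

Under the multiplicative (log-additive) null model the fold change of a
mutant combination relative to the wild type is the product of its singles'
fold changes. Writing ``G = log10 g`` for a fold change ``g``, the expected
combined value is the sum of the constituent singles' ``G`` and epistasis is

    eps = G_observed - G_expected

in log10 fold-change units, positive when the combination expresses more
than the singles predict. For triplets the expected value can instead be
built from the observed pairs (each pair counted once, singles subtracted to
avoid double counting), giving the exclusive third-order epistasis
``eps3 = G_obs(triplet) - [sum G_obs(pairs) - sum G(singles)]`` and the
identity ``eps(triplet) = eps3 + sum of the three pairwise eps``.

Error propagation follows the study's printed formulas, which scale the
root-sum-of-squares of the single-mutant SDs by the mean of the propagated
quantity (mode ``"as_printed"``, using ``|x̄|``); a conventional
root-sum-of-variances mode (``"sum_of_variances"``) is provided as well.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Genotype

logger = logging.getLogger(__name__)

SIGMA_MODES = ("as_printed", "sum_of_variances")
FDR_METHODS = ("storey", "bh", "bky")

#: mean differences below this count as equal in the degenerate
#: zero-variance t test (absorbs float rounding of an exact null)
ZERO_VARIANCE_ATOL = 1e-12


# ---------------------------------------------------------------------------
# Log fold changes
# ---------------------------------------------------------------------------

def log_fold_changes(
    tidy: pd.DataFrame, wt_genotype: str = "WT"
) -> pd.DataFrame:
    """Per-genotype log10 fold change vs the wild type, per inducer level.

    Each replicate's log10 ratio to the WT mean fluorescence at the same
    level is computed first; the table reports their mean, sample SD and n.
    The WT row itself is the reference and carries G = 0 by definition.
    Non-positive fluorescence values are dropped with a logged reason.

    Parameters
    ----------
    tidy
        Replicate-level table with columns ``genotype, inducer_label,
        replicate, fluorescence`` (extra columns ignored).
    """
    df = tidy.copy()
    bad = df["fluorescence"] <= 0
    if bad.any():
        for _, r in df[bad].iterrows():
            logger.warning(
                "dropping non-positive fluorescence for %s at %s (replicate %s)",
                r["genotype"], r["inducer_label"], r.get("replicate", "?"),
            )
        df = df[~bad]
    wt = df[df["genotype"] == wt_genotype]
    if wt.empty:
        raise ValueError(f"wild-type genotype {wt_genotype!r} absent from table")
    wt_mean = wt.groupby("inducer_label")["fluorescence"].mean().rename("wt_mean")
    levels_missing = set(df["inducer_label"]) - set(wt_mean.index)
    if levels_missing:
        raise ValueError(f"WT reference missing at levels {sorted(levels_missing)}")
    df = df.merge(wt_mean, on="inducer_label")
    df["g_rep"] = np.log10(df["fluorescence"] / df["wt_mean"])
    out = df.groupby(["genotype", "inducer_label"], as_index=False)["g_rep"].agg(
        G="mean", sd=lambda v: v.std(ddof=1), n="count"
    )
    out.loc[out["genotype"] == wt_genotype, "G"] = 0.0
    return out


# ---------------------------------------------------------------------------
# Expected values and epistasis
# ---------------------------------------------------------------------------

def _check_sigma_mode(mode: str) -> None:
    if mode not in SIGMA_MODES:
        raise ValueError(f"unknown sigma mode {mode!r}; expected one of {SIGMA_MODES}")


def expected_G(
    singles_G: Sequence[float],
    singles_sd: Sequence[float],
    sigma_mode: str = "as_printed",
) -> tuple[float, float]:
    """Expected combined log fold change and its propagated SD.

    ``G_expected`` is the sum of the 2 or 3 constituent singles' G. In
    ``as_printed`` mode the propagated SD is ``|G_expected| *
    sqrt(sum sd_i^2)``; in ``sum_of_variances`` mode it is
    ``sqrt(sum sd_i^2)``.
    """
    _check_sigma_mode(sigma_mode)
    if len(singles_G) not in (2, 3) or len(singles_G) != len(singles_sd):
        raise ValueError("expected 2 or 3 constituent singles with matching sds")
    g_exp = float(np.sum(singles_G))
    rss = math.sqrt(float(np.sum(np.square(singles_sd))))
    sd_exp = abs(g_exp) * rss if sigma_mode == "as_printed" else rss
    return g_exp, sd_exp


def epistasis(g_observed: float, g_expected: float) -> float:
    """eps = G_observed - G_expected (log10 fold-change units)."""
    return g_observed - g_expected


def third_order(
    triplet_G_obs: float,
    pair_G_obs: Sequence[float],
    single_G: Sequence[float],
) -> tuple[float, float]:
    """Pairs-based expectation and exclusive third-order epistasis.

    ``G_tilde = sum G_obs(pairs) - sum G(singles)``;
    ``eps3 = G_obs(triplet) - G_tilde``. Together with the pairwise eps this
    satisfies ``eps(triplet) = eps3 + sum pairwise eps`` identically.
    """
    if len(pair_G_obs) != 3 or len(single_G) != 3:
        raise ValueError("a triplet needs its 3 observed pairs and 3 singles")
    g_tilde = float(np.sum(pair_G_obs)) - float(np.sum(single_G))
    return g_tilde, triplet_G_obs - g_tilde


def sigma_epistasis(
    eps: float, sd_obs: float, sd_exp: float, sigma_mode: str = "as_printed"
) -> float:
    """Propagated SD of an epistasis value.

    ``as_printed``: ``|eps| * sqrt(sd_obs^2 + sd_exp^2)`` (degenerately 0
    when eps = 0); ``sum_of_variances``: ``sqrt(sd_obs^2 + sd_exp^2)``.
    """
    _check_sigma_mode(sigma_mode)
    rss = math.hypot(sd_obs, sd_exp)
    return abs(eps) * rss if sigma_mode == "as_printed" else rss


# ---------------------------------------------------------------------------
# Summary-statistics t tests
# ---------------------------------------------------------------------------

def t_test_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sided two-sample t test from summary statistics.

    ``pooled`` uses the equal-variance statistic with df = n1 + n2 - 2;
    ``welch`` uses the Welch-Satterthwaite df. When both SDs are zero the
    test degenerates: equal means give (0, df, 1); unequal means give p = 0
    with a warning.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    # a mean difference at the numerical floor is an exact null, whatever
    # the (equally negligible) variances are
    if abs(mean1 - mean2) <= ZERO_VARIANCE_ATOL:
        return 0.0, float(n1 + n2 - 2), 1.0
    if sd1 == 0 and sd2 == 0:
        df = float(n1 + n2 - 2)
        warnings.warn("zero variance with unequal means; p = 0")
        return math.copysign(math.inf, mean1 - mean2), df, 0.0
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def _t_test_arrays(
    mean1, sd1, n1, mean2, sd2, n2, variant: str = "pooled"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sided t test from summary statistics (internal)."""
    mean1, sd1, mean2, sd2 = map(np.asarray, (mean1, sd1, mean2, sd2))
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), mean1.shape)
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), mean2.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        if variant == "pooled":
            sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
            df = n1 + n2 - 2
        else:
            v1, v2 = sd1**2 / n1, sd2**2 / n2
            se = np.sqrt(v1 + v2)
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        t = (mean1 - mean2) / se
        p = 2 * stats.t.sf(np.abs(t), df)
    # degenerate records: a difference at the numerical floor is an exact
    # null; zero variance with a real difference is certain
    equal = np.abs(mean1 - mean2) <= ZERO_VARIANCE_ATOL
    zero = (se == 0) & ~equal
    t = np.where(equal, 0.0, t)
    p = np.where(equal, 1.0, np.where(zero, 0.0, p))
    t = np.where(zero, np.where(mean1 >= mean2, np.inf, -np.inf), t)
    if variant != "pooled":
        df = np.where(zero, n1 + n2 - 2, df)
    return t, df, p


# ---------------------------------------------------------------------------
# FDR control
# ---------------------------------------------------------------------------

def storey_pi0(
    p: np.ndarray, lambdas: np.ndarray | None = None
) -> float:
    """Estimate the null proportion pi0 with the lambda-grid smoother.

    ``pi0(lambda) = mean(p > lambda) / (1 - lambda)`` is evaluated on the
    grid 0.05..0.95 (step 0.05) and smoothed with a cubic least-squares fit
    evaluated at the largest lambda, then clamped to (0, 1].
    """
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    p = np.asarray(p, dtype=float)
    pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    if np.allclose(pi0_l, pi0_l[0]):
        pi0 = float(pi0_l[0])
    else:
        coef = np.polynomial.polynomial.polyfit(lambdas, pi0_l, deg=3)
        pi0 = float(np.polynomial.polynomial.polyval(lambdas[-1], coef))
    return min(max(pi0, 1.0 / len(p) if len(p) else 1e-8), 1.0)


def storey_qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: pi0-scaled step-up of ``p * m / rank``.

    With pi0 = 1 this reduces to Benjamini-Hochberg adjusted p values.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if pi0 is None:
        pi0 = storey_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1] * pi0
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fdr_adjust(
    p: Iterable[float], method: str = "storey", threshold: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Multiple-testing correction: q values plus significance flags.

    ``storey`` is the smoother-pi0 q-value; ``bh`` is Benjamini-Hochberg;
    ``bky`` is the Benjamini-Krieger-Yekutieli two-stage step-up.
    """
    p = np.asarray(list(p), dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    if method == "storey":
        q = storey_qvalues(p)
        return q, q < threshold
    if method == "bh":
        _, q, _, _ = multipletests(p, alpha=threshold, method="fdr_bh")
        return q, q < threshold
    if method == "bky":
        reject, q, _, _ = multipletests(p, alpha=threshold, method="fdr_tsbky")
        return q, reject
    raise ValueError(f"unknown FDR method {method!r}; expected one of {FDR_METHODS}")


# ---------------------------------------------------------------------------
# Full epistasis table
# ---------------------------------------------------------------------------

def _constituents(name: str) -> Genotype:
    return Genotype.from_name(name)


def epistasis_table(
    lfc: pd.DataFrame,
    sigma_mode: str = "as_printed",
    fdr_method: str = "storey",
    alpha: float = 0.05,
    n_replicates: int = 3,
    fdr_family: str = "per_order",
) -> pd.DataFrame:
    """Epistasis records for every combination x inducer level in ``lfc``.

    ``lfc`` is a log-fold-change table (``genotype, inducer_label, G, sd,
    n``) covering singles and combinations. Each record carries observed and
    expected G with SDs, eps (and for triplets the pairs-based expectation,
    exclusive third-order eps and the sum of pairwise eps), a pooled
    two-sample t test of observed vs expected, and an FDR-adjusted q. The
    FDR family is per order by default (e.g. all 900 pairwise tests across
    the three levels at M=10), or ``"pooled"`` across both orders.
    """
    _check_sigma_mode(sigma_mode)
    lfc = lfc.copy()
    lfc["_order"] = lfc["genotype"].map(lambda s: _constituents(s).order)
    idx = lfc.set_index(["genotype", "inducer_label"])
    G = idx["G"]
    SD = idx["sd"]

    combos = sorted(set(lfc.loc[lfc["_order"] >= 2, "genotype"]))
    levels = list(dict.fromkeys(lfc["inducer_label"]))

    # verify constituents are present, with an explicit gap list
    missing: list[str] = []
    parsed = {name: _constituents(name) for name in combos}
    for name, g in parsed.items():
        for s in g.singles():
            for lvl in levels:
                if (s.name(), lvl) not in idx.index:
                    missing.append(f"{s.name()}@{lvl}")
    if missing:
        raise ValueError(
            "missing single-mutant records for: " + ", ".join(sorted(set(missing)))
        )

    rows = []
    for name in combos:
        g = parsed[name]
        singles = [s.name() for s in g.singles()]
        pairs = [pg.name() for pg in g.pairs()] if g.order == 3 else []
        for lvl in levels:
            if (name, lvl) not in idx.index:
                continue
            g_obs = G[(name, lvl)]
            sd_obs = SD[(name, lvl)]
            sG = [G[(s, lvl)] for s in singles]
            sSD = [SD[(s, lvl)] for s in singles]
            g_exp, sd_exp = expected_G(sG, sSD, sigma_mode)
            eps = g_obs - g_exp
            rec = {
                "genotype": name,
                "order": g.order,
                "inducer_label": lvl,
                "G_obs": g_obs,
                "sd_obs": sd_obs,
                "G_exp": g_exp,
                "sd_exp": sd_exp,
                "epsilon": eps,
                "G_exp_pairs": np.nan,
                "epsilon3_exclusive": np.nan,
                "sum_pairwise_epsilon": np.nan,
            }
            if g.order == 3:
                missing_pairs = [pq for pq in pairs if (pq, lvl) not in idx.index]
                if missing_pairs:
                    raise ValueError(
                        f"missing pairwise records for triplet {name} at {lvl}: "
                        + ", ".join(missing_pairs)
                    )
                pG = [G[(pq, lvl)] for pq in pairs]
                g_tilde, eps3 = third_order(g_obs, pG, sG)
                rec["G_exp_pairs"] = g_tilde
                rec["epsilon3_exclusive"] = eps3
                rec["sum_pairwise_epsilon"] = eps - eps3
            rows.append(rec)
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no combination genotypes found in the fold-change table")

    t, df, p = _t_test_arrays(
        table["G_obs"].to_numpy(),
        table["sd_obs"].to_numpy(),
        n_replicates,
        table["G_exp"].to_numpy(),
        table["sd_exp"].to_numpy(),
        n_replicates,
        variant="pooled",
    )
    table["t"], table["df"], table["p"] = t, df, p

    table["q"] = np.nan
    table["significant"] = False
    if fdr_family == "pooled":
        fams = [table.index]
    else:
        fams = [table.index[table["order"] == k] for k in (2, 3)]
    for fam in fams:
        if len(fam) == 0:
            continue
        q, sig = fdr_adjust(table.loc[fam, "p"], method=fdr_method, threshold=alpha)
        table.loc[fam, "q"] = q
        table.loc[fam, "significant"] = sig
    return table
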