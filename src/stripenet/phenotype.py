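"""Pattern-phenotype projection and diversity comparison.

A genotype's expression pattern across the three inducer levels is
projected to the plane as

    Mx = G_medium - G_low,    My = G_high - G_medium

with G the log10 normalized fluorescence. The quadrants classify the
pattern: increase (Q1: Mx>0, My>0), anti-stripe (Q2), decrease (Q3) and
stripe (Q4: up then down); points within ``flat_radius`` of the origin are
a flat pattern. G here is absolute log expression (not fold change vs WT)
so the wild type and its stripe-preserving singles land in the stripe
quadrant; distances are invariant to that choice because per-level offsets
cancel in the differences.

Observed points come from measured combinations; expected points apply the
multiplicative model (WT log expression plus the sum of the singles' log
fold changes per level). Pattern diversity is compared as each genotype's
Euclidean distance to the WT point, observed vs expected, with a two-sided
Wilcoxon signed-rank test.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Genotype

CLASSES = ("increase", "anti_stripe", "decrease", "stripe", "flat")


def project(g_low: float, g_medium: float, g_high: float) -> tuple[float, float]:
    """(Mx, My) = (G_medium - G_low, G_high - G_medium)."""
    return g_medium - g_low, g_high - g_medium


def classify_pattern(mx: float, my: float, flat_radius: float = 0.0) -> str:
    """Quadrant class of a projected pattern.

    Boundary points (an axis value exactly 0) follow the half-open
    convention: the positive test is strict, so Mx = 0 counts as "not
    increasing" (e.g. (0, 1) is anti-stripe). ``flat_radius`` > 0 carves a
    flat class around the origin.
    """
    if not (np.isfinite(mx) and np.isfinite(my)):
        raise ValueError("projection coordinates must be finite")
    if np.hypot(mx, my) <= flat_radius:
        return "flat"
    if mx > 0:
        return "increase" if my > 0 else "stripe"
    return "anti_stripe" if my > 0 else "decrease"


def is_boundary(mx: float, my: float) -> bool:
    return mx == 0 or my == 0


def _wide_logG(summary: pd.DataFrame) -> pd.DataFrame:
    """Pivot a mean-expression summary to log10 G per level."""
    need = {"genotype", "inducer_label", "mean"}
    if not need <= set(summary.columns):
        raise ValueError(f"summary table needs columns {sorted(need)}")
    if (summary["mean"] <= 0).any():
        raise ValueError("expression means must be positive to take logs")
    wide = summary.pivot_table(
        index="genotype", columns="inducer_label", values="mean", aggfunc="first"
    )
    for lvl in ("low", "medium", "high"):
        if lvl not in wide.columns:
            raise ValueError(f"missing inducer level {lvl!r}")
    return np.log10(wide[["low", "medium", "high"]])


def observed_points(
    summary: pd.DataFrame, flat_radius: float = 0.0
) -> pd.DataFrame:
    """Project every genotype's measured pattern.

    ``summary`` is the expression-summary table (``genotype, inducer_label,
    mean``, normalized fluorescence).
    """
    logG = _wide_logG(summary)
    mx = logG["medium"] - logG["low"]
    my = logG["high"] - logG["medium"]
    out = pd.DataFrame(
        {
            "genotype": logG.index,
            "source": "observed",
            "Mx": mx.to_numpy(),
            "My": my.to_numpy(),
        }
    )
    out["class"] = [
        classify_pattern(x, y, flat_radius) for x, y in zip(out["Mx"], out["My"])
    ]
    out["boundary"] = [is_boundary(x, y) for x, y in zip(out["Mx"], out["My"])]
    return out


def expected_points(
    summary: pd.DataFrame,
    lfc: pd.DataFrame,
    flat_radius: float = 0.0,
    wt_genotype: str = "WT",
) -> pd.DataFrame:
    """Multiplicative-model expected pattern for every combination.

    Per level, expected log expression = WT log expression + sum of the
    constituent singles' log fold changes; the point is then projected and
    classified like an observed one.
    """
    logG = _wide_logG(summary[summary["genotype"] == wt_genotype])
    if logG.empty:
        raise ValueError(f"wild type {wt_genotype!r} absent from summary")
    wt = logG.iloc[0]
    gidx = lfc.set_index(["genotype", "inducer_label"])["G"]
    rows = []
    combos = sorted(
        {
            name
            for name in lfc["genotype"].unique()
            if Genotype.from_name(name).order >= 2
        }
    )
    for name in combos:
        g = Genotype.from_name(name)
        levels = {}
        for lvl in ("low", "medium", "high"):
            try:
                levels[lvl] = wt[lvl] + sum(
                    gidx[(s.name(), lvl)] for s in g.singles()
                )
            except KeyError as exc:
                raise ValueError(
                    f"missing single-mutant fold change for {name} at {lvl}"
                ) from exc
        mx, my = project(levels["low"], levels["medium"], levels["high"])
        rows.append(
            {
                "genotype": name,
                "source": "expected",
                "Mx": mx,
                "My": my,
                "class": classify_pattern(mx, my, flat_radius),
                "boundary": is_boundary(mx, my),
            }
        )
    return pd.DataFrame(rows)


def distance_to_wt(points: pd.DataFrame, wt_point: Sequence[float]) -> pd.Series:
    """Euclidean distance of each projected pattern to the WT pattern."""
    wx, wy = wt_point
    return np.hypot(points["Mx"] - wx, points["My"] - wy)


def distance_and_diversity(
    observed: pd.DataFrame,
    expected: pd.DataFrame,
    wt_point: Sequence[float],
) -> tuple[pd.DataFrame, dict]:
    """Pair observed and expected points and compare their spread around WT.

    Returns the per-genotype table (distances of both sources to the WT
    point, plus the literal observed-expected displacement as a
    supplementary column) and a summary dict with the two mean distances
    and the two-sided Wilcoxon signed-rank p value. Unpaired genotypes are
    excluded with a log entry; an all-zero difference vector is degenerate
    and reported as p = 1 with a flag.
    """
    import logging

    logger = logging.getLogger(__name__)
    obs = observed.set_index("genotype")
    exp = expected.set_index("genotype")
    common = obs.index.intersection(exp.index)
    dropped = obs.index.symmetric_difference(exp.index)
    for name in dropped:
        logger.warning("genotype %s unpaired between observed/expected; excluded", name)
    obs, exp = obs.loc[common], exp.loc[common]
    d_obs = distance_to_wt(obs, wt_point)
    d_exp = distance_to_wt(exp, wt_point)
    table = pd.DataFrame(
        {
            "genotype": common,
            "dist_observed": d_obs.to_numpy(),
            "dist_expected": d_exp.to_numpy(),
            "dist_obs_vs_exp": np.hypot(
                obs["Mx"] - exp["Mx"], obs["My"] - exp["My"]
            ).to_numpy(),
        }
    )
    diffs = table["dist_observed"] - table["dist_expected"]
    degenerate = bool(np.all(diffs == 0))
    if degenerate:
        warnings.warn("observed and expected distances identical; Wilcoxon degenerate")
        p = 1.0
    else:
        p = float(stats.wilcoxon(diffs, alternative="two-sided").pvalue)
    summary = {
        "n": int(len(table)),
        "mean_dist_observed": float(table["dist_observed"].mean()),
        "mean_dist_expected": float(table["dist_expected"].mean()),
        "wilcoxon_p": p,
        "degenerate": degenerate,
    }
    return table, summary


def class_census(points: pd.DataFrame) -> pd.DataFrame:
    """Counts of pattern classes per source (and per order if derivable)."""
    pts = points.copy()
    pts["order"] = pts["genotype"].map(lambda s: Genotype.from_name(s).order)
    return (
        pts.groupby(["order", "source", "class"]).size().rename("n").reset_index()
    )
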