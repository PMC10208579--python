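"""Classification of epistasis records.

Three independent axes are classified:

* **type** -- positive/negative (sign of eps) crossed with magnitude, sign
  or reciprocal sign epistasis (RSE), from the position of the combined
  log fold change relative to each constituent single's. A constituent is
  "crossed" when the combined expression falls on the wild-type side of
  that single's level; crossing none is magnitude, some-but-not-all is sign,
  and all is RSE. A direction group records whether the singles all express
  below the WT, all above, or mixed.
* **inducer dependence** -- Welch tests between eps at the three inducer
  levels with two-stage (Benjamini-Krieger-Yekutieli) FDR control; a
  combination is inducer-dependent when any of its three level contrasts is
  significant.
* **category and trajectory** -- which level holds the extremum of eps
  (A: max at medium, B: increasing, C: decreasing, D: min at medium) and
  whether eps keeps or switches its sign along the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Genotype
from .epistasis import fdr_adjust, sigma_epistasis, _t_test_arrays

LEVEL_ORDER = ("low", "medium", "high")


@dataclass(frozen=True)
class TypeClass:
    sign: str  # "positive" | "negative" | "none"
    form: str  # "magnitude" | "sign" | "RSE" | "none"
    direction_group: str  # "all_lower" | "all_higher" | "mixed"
    boundary: bool = False  # a single sits exactly at the WT level


def classify_type(
    singles_G: Sequence[float], combined_G: float, eps: float
) -> TypeClass:
    """Type-classify one epistasis record (pairwise or triplet).

    ``singles_G`` are the constituent singles' log fold changes (WT = 0),
    ``combined_G`` the observed combined log fold change and ``eps`` the
    epistasis value. eps = 0 exactly yields the "none" class.
    """
    singles_G = list(singles_G)
    if len(singles_G) not in (2, 3):
        raise ValueError("need 2 or 3 constituent singles")
    if all(g < 0 for g in singles_G):
        group = "all_lower"
    elif all(g > 0 for g in singles_G):
        group = "all_higher"
    else:
        group = "mixed"
    boundary = any(g == 0 for g in singles_G)
    if eps == 0:
        return TypeClass("none", "none", group, boundary)
    sign = "positive" if eps > 0 else "negative"
    crossed = [
        (g > 0 and combined_G < g) or (g < 0 and combined_G > g) for g in singles_G
    ]
    if all(crossed):
        form = "RSE"
    elif any(crossed):
        form = "sign"
    else:
        form = "magnitude"
    return TypeClass(sign, form, group, boundary)


def classify_category(
    eps_low: float, eps_medium: float, eps_high: float
) -> tuple[str, str, bool]:
    """Assign the inducer-dependence category and sign trajectory.

    Returns ``(category, trajectory, tie)``: A if eps is strictly highest at
    the medium level, D if strictly lowest, otherwise B (increasing) or C
    (decreasing); exact ties break toward the medium-extremum categories and
    raise the ``tie`` flag. Trajectory is always_positive / always_negative
    when the three point estimates share a sign, else switching.
    """
    e = (eps_low, eps_medium, eps_high)
    if not all(np.isfinite(e)):
        raise ValueError("category classification needs three finite eps values")
    tie = len({eps_low, eps_medium, eps_high}) < 3
    if eps_medium >= eps_low and eps_medium >= eps_high:
        cat = "A"
    elif eps_medium <= eps_low and eps_medium <= eps_high:
        cat = "D"
    elif eps_low < eps_high:
        cat = "B"
    else:
        cat = "C"
    if all(v > 0 for v in e):
        traj = "always_positive"
    elif all(v < 0 for v in e):
        traj = "always_negative"
    else:
        traj = "switching"
    return cat, traj, tie


def type_class_table(
    records: pd.DataFrame, lfc: pd.DataFrame, significant_only: bool = True
) -> pd.DataFrame:
    """Type-classify epistasis records against their singles' fold changes.

    Non-significant records are included with a ``significant=False`` flag
    when ``significant_only`` is off; the headline census uses significant
    records only.
    """
    idx = lfc.set_index(["genotype", "inducer_label"])["G"]
    df = records[records["significant"]] if significant_only else records
    rows = []
    for r in df.itertuples():
        g = Genotype.from_name(r.genotype)
        sG = [idx[(s.name(), r.inducer_label)] for s in g.singles()]
        tc = classify_type(sG, r.G_obs, r.epsilon)
        rows.append(
            {
                "genotype": r.genotype,
                "order": r.order,
                "inducer_label": r.inducer_label,
                "epsilon": r.epsilon,
                "significant": r.significant,
                "sign": tc.sign,
                "form": tc.form,
                "direction_group": tc.direction_group,
                "boundary": tc.boundary,
            }
        )
    return pd.DataFrame(rows)


def inducer_dependence(
    records: pd.DataFrame,
    alpha: float = 0.1,
    sigma_mode: str = "as_printed",
    n_replicates: int = 3,
    fdr_method: str = "bky",
) -> pd.DataFrame:
    """Per-combination inducer profile with the dependence call.

    For every combination the eps values at low/medium/high are compared
    pairwise (L-M, L-H, M-H) with Welch t tests using the propagated
    sigma_epistasis of each level; q values are computed across the whole
    per-order family and a combination is flagged ``dependent`` when any of
    its three contrasts has q < ``alpha``. Categories A-D and the sign
    trajectory are assigned from the point estimates regardless of
    significance. Combinations missing a level are skipped with a log entry.
    """
    need = {"genotype", "order", "inducer_label", "epsilon", "sd_obs", "sd_exp"}
    missing_cols = need - set(records.columns)
    if missing_cols:
        raise ValueError(f"records table missing columns {sorted(missing_cols)}")
    wide = records.pivot_table(
        index=["genotype", "order"],
        columns="inducer_label",
        values=["epsilon", "sd_obs", "sd_exp"],
        aggfunc="first",
    )
    rows = []
    import logging

    logger = logging.getLogger(__name__)
    for (name, order), r in wide.iterrows():
        if any(pd.isna(r.get(("epsilon", lvl), np.nan)) for lvl in LEVEL_ORDER):
            logger.warning("skipping %s: missing an inducer level", name)
            continue
        eps = {lvl: r[("epsilon", lvl)] for lvl in LEVEL_ORDER}
        sig = {
            lvl: sigma_epistasis(
                eps[lvl], r[("sd_obs", lvl)], r[("sd_exp", lvl)], sigma_mode
            )
            for lvl in LEVEL_ORDER
        }
        cat, traj, tie = classify_category(eps["low"], eps["medium"], eps["high"])
        rows.append(
            {
                "genotype": name,
                "order": order,
                "eps_low": eps["low"],
                "eps_medium": eps["medium"],
                "eps_high": eps["high"],
                "sigma_low": sig["low"],
                "sigma_medium": sig["medium"],
                "sigma_high": sig["high"],
                "category": cat,
                "trajectory": traj,
                "tie": tie,
            }
        )
    prof = pd.DataFrame(rows)
    if prof.empty:
        return prof

    contrasts = (
        ("lm", "eps_low", "sigma_low", "eps_medium", "sigma_medium"),
        ("lh", "eps_low", "sigma_low", "eps_high", "sigma_high"),
        ("mh", "eps_medium", "sigma_medium", "eps_high", "sigma_high"),
    )
    for tag, m1, s1, m2, s2 in contrasts:
        _, _, p = _t_test_arrays(
            prof[m1].to_numpy(),
            prof[s1].to_numpy(),
            n_replicates,
            prof[m2].to_numpy(),
            prof[s2].to_numpy(),
            n_replicates,
            variant="welch",
        )
        prof[f"p_{tag}"] = p
    # BKY across the whole family of 3 contrasts per combination, per order
    for order in sorted(prof["order"].unique()):
        sel = prof.index[prof["order"] == order]
        pvals = prof.loc[sel, ["p_lm", "p_lh", "p_mh"]].to_numpy().ravel()
        q, rej = fdr_adjust(pvals, method=fdr_method, threshold=alpha)
        q = q.reshape(-1, 3)
        rej = rej.reshape(-1, 3)
        prof.loc[sel, ["q_lm", "q_lh", "q_mh"]] = q
        prof.loc[sel, "dependent"] = rej.any(axis=1)
    prof["dependent"] = prof["dependent"].astype(bool)
    return prof


def category_census(profiles: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per category x trajectory, per order."""
    out = []
    for order, sub in profiles.groupby("order"):
        total = len(sub)
        counts = (
            sub.groupby(["category", "trajectory"]).size().rename("n").reset_index()
        )
        counts["order"] = order
        counts["pct"] = 100.0 * counts["n"] / total
        out.append(counts)
    return pd.concat(out, ignore_index=True)[
        ["order", "category", "trajectory", "n", "pct"]
    ]


def summarize_by_genotype(
    records: pd.DataFrame, grouping: str = "genotype"
) -> pd.DataFrame:
    """Mean, SD and CoV of eps over the combinations containing each single.

    ``grouping`` is ``"genotype"`` (all levels pooled; 60 pairwise / 300
    triplet values per single at M=10), ``"genotype_level"``, or
    ``"node_level"``. CoV = SD / mean, undefined (missing) when the mean
    is zero.
    """
    if grouping not in ("genotype", "genotype_level", "node_level"):
        raise ValueError(f"unknown grouping {grouping!r}")
    rows = []
    for r in records.itertuples():
        g = Genotype.from_name(r.genotype)
        for s in g.singles():
            rows.append(
                {
                    "single": s.name(),
                    "node": s.mutated_nodes()[0].value,
                    "order": r.order,
                    "inducer_label": r.inducer_label,
                    "epsilon": r.epsilon,
                }
            )
    long = pd.DataFrame(rows)
    keys = {
        "genotype": ["single", "node", "order"],
        "genotype_level": ["single", "node", "order", "inducer_label"],
        "node_level": ["node", "order", "inducer_label"],
    }[grouping]
    agg = long.groupby(keys, as_index=False)["epsilon"].agg(
        n="count", mean="mean", sd=lambda v: v.std(ddof=1)
    )
    if (agg["n"] < 2).any():
        raise ValueError("each summary group needs at least 2 epsilon values")
    agg["cov"] = np.where(agg["mean"] != 0, agg["sd"] / agg["mean"], np.nan)
    return agg
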