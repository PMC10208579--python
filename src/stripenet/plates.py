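"""Raw plate-reader processing: time-point selection, background and OD
correction, WT-based normalization, replicate QC and summary statistics.

Input is a tidy table of per-well time series with columns
``plate, well, role, genotype, condition, inducer_pct, time_min, od, gfp``
(as written by :func:`stripenet.simulate.generate_raw_plates`; real exports
reshaped to the same schema are accepted).

The processing chain follows the assay protocol: read every well at the
time the wild-type network peaks at medium inducer, subtract the media
blank, divide fluorescence by (blank-corrected) absorbance, scale each
plate so its wild-type wells average 1, exclude replicates whose growth
deviates from the plate's wild-type controls by more than 0.2 OD in any
condition, and summarize replicates as mean and sample SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RAW_COLUMNS = [
    "plate",
    "well",
    "role",
    "genotype",
    "condition",
    "inducer_pct",
    "time_min",
    "od",
    "gfp",
]

#: conditions that enter the expression summary (the metabolic-load control
#: participates in QC but is reported only as a pass-through flag).
SUMMARY_CONDITIONS = ("low", "medium", "high")


@dataclass
class QCReport:
    """Replicate exclusions with reasons, surviving n, and flags."""

    excluded: pd.DataFrame  # plate, genotype, reason
    surviving_n: pd.DataFrame  # genotype, condition, n
    needs_repeat: list[str] = field(default_factory=list)
    metabolic_load_flagged: list[str] = field(default_factory=list)


def select_timepoint(
    times: np.ndarray | pd.Series, fluorescence: np.ndarray | pd.Series
) -> float:
    """Time (min) of peak WT fluorescence at the medium inducer level.

    Ties break to the earliest time; a series still rising at its last point
    is flagged since no peak was reached within the run.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if t.size == 0 or f.size == 0:
        raise ValueError("empty fluorescence series")
    if t.size != f.size:
        raise ValueError("times and fluorescence must have equal length")
    order = np.argsort(t, kind="stable")
    t, f = t[order], f[order]
    i = int(np.argmax(f))  # first maximum -> earliest-time tie-break
    if np.all(f == f[0]) and f.size > 1:
        warnings.warn("constant fluorescence series; returning earliest time")
    elif i == f.size - 1 and f.size > 1 and f[-1] > f[-2]:
        warnings.warn("fluorescence still rising at last time point; no peak reached")
    return float(t[i])


def select_timepoint_from_plates(raw: pd.DataFrame) -> float:
    """Apply :func:`select_timepoint` to the pooled WT medium-level series."""
    wt = raw[(raw["role"] == "WT") & (raw["condition"] == "medium")]
    if wt.empty:
        raise ValueError("no WT wells at the medium condition")
    series = wt.groupby("time_min", sort=True)["gfp"].mean().reset_index()
    return select_timepoint(series["time_min"], series["gfp"])


def correct_and_normalize(
    raw: pd.DataFrame,
    timepoint: float | None = None,
    subtract_blank_od: bool = True,
) -> pd.DataFrame:
    """Blank/OD-correct every well at the chosen time and scale to WT = 1.

    Per plate: value = (gfp - mean blank gfp) / (od - mean blank od); wells
    with non-positive corrected OD are marked unusable. Each plate x
    condition is then scaled so its WT wells average exactly 1, and a second
    WT-based cross-plate scaling (idempotent after the first) adjusts for
    between-plate variation, following the two-stage protocol.
    """
    missing = [c for c in RAW_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"raw plate table is missing columns {missing}")
    if timepoint is None:
        timepoint = select_timepoint_from_plates(raw)
    # read every well at the measurement closest to the chosen time
    tdiff = (raw["time_min"] - timepoint).abs()
    at_t = raw[tdiff == tdiff.min()].copy()

    blanks = at_t[at_t["role"] == "blank"]
    if blanks.empty or blanks.groupby("plate").size().reindex(
        at_t["plate"].unique()
    ).isna().any():
        raise ValueError("every plate needs at least one media-blank well")
    blank_stats = blanks.groupby("plate").agg(
        blank_gfp=("gfp", "mean"), blank_od=("od", "mean")
    )
    at_t = at_t.merge(blank_stats, on="plate", how="left")

    od_ref = at_t["od"] - (at_t["blank_od"] if subtract_blank_od else 0.0)
    at_t["usable"] = od_ref > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        at_t["value"] = np.where(
            at_t["usable"], (at_t["gfp"] - at_t["blank_gfp"]) / od_ref, np.nan
        )

    wells = at_t[at_t["role"] != "blank"].copy()
    n_wt = wells[wells["role"] == "WT"].groupby("plate").size()
    if (n_wt.reindex(wells["plate"].unique()).fillna(0) < 3).any():
        raise ValueError("every plate needs at least three WT wells")

    for _stage in range(2):  # two-stage WT scaling; second pass is a no-op
        wt_mean = (
            wells[wells["role"] == "WT"]
            .groupby(["plate", "condition"])["value"]
            .mean()
            .rename("wt_scale")
        )
        wells = wells.merge(wt_mean, on=["plate", "condition"], how="left")
        wells["value"] = wells["value"] / wells["wt_scale"]
        wells = wells.drop(columns="wt_scale")

    wells = wells.rename(columns={"value": "fluorescence"})
    return wells[
        [
            "plate",
            "well",
            "role",
            "genotype",
            "condition",
            "inducer_pct",
            "od",
            "fluorescence",
            "usable",
        ]
    ].reset_index(drop=True)


def qc_filter(
    wells: pd.DataFrame, max_od_diff: float = 0.2
) -> tuple[pd.DataFrame, QCReport]:
    """Drop sample replicates whose growth deviates from the WT controls.

    A replicate (one genotype on one plate, measured across all conditions)
    is excluded if its OD differs from the mean WT OD on the same plate by
    more than ``max_od_diff`` in *any* condition. WT control wells are never
    removed. Genotypes left with fewer than two replicates are flagged
    "needs repeat" but their surviving replicate is kept.
    """
    wt_od = (
        wells[wells["role"] == "WT"]
        .groupby(["plate", "condition"])["od"]
        .mean()
        .rename("wt_od")
    )
    samples = wells[wells["role"] == "sample"].merge(
        wt_od, on=["plate", "condition"], how="left"
    )
    samples["od_dev"] = (samples["od"] - samples["wt_od"]).abs()
    bad = (
        samples[samples["od_dev"] > max_od_diff]
        .groupby(["plate", "genotype"])["od_dev"]
        .max()
        .reset_index()
    )
    bad["reason"] = "growth deviation >" + str(max_od_diff) + " OD vs plate WT"
    bad_keys = bad["plate"].str.cat(bad["genotype"], sep="\x00")
    well_keys = wells["plate"].str.cat(wells["genotype"], sep="\x00")
    keep_mask = ~(wells["role"].eq("sample") & well_keys.isin(set(bad_keys)))
    kept = wells[keep_mask & wells["usable"]].reset_index(drop=True)

    surviving = (
        kept[kept["role"] == "sample"]
        .groupby(["genotype", "condition"])
        .size()
        .rename("n")
        .reset_index()
    )
    low_n = (
        surviving[surviving["condition"].isin(SUMMARY_CONDITIONS)]
        .groupby("genotype")["n"]
        .min()
    )
    needs_repeat = sorted(low_n[low_n < 2].index.tolist())
    report = QCReport(
        excluded=bad[["plate", "genotype", "reason", "od_dev"]],
        surviving_n=surviving,
        needs_repeat=needs_repeat,
        metabolic_load_flagged=[],  # pass-through; no decision rule applied
    )
    return kept, report


def to_tidy(wells: pd.DataFrame) -> pd.DataFrame:
    """Reshape normalized wells to the replicate-level tidy schema.

    Replicate numbers are assigned per genotype x condition in plate order.
    The metabolic-load control is dropped here (pass-through QC only).
    """
    df = wells[
        (wells["condition"].isin(SUMMARY_CONDITIONS))
        & (wells["role"].isin(["sample", "WT"]))
    ].copy()
    # one WT value per plate x condition: average the control wells
    wt = (
        df[df["role"] == "WT"]
        .groupby(["plate", "condition", "inducer_pct"], as_index=False)["fluorescence"]
        .mean()
        .assign(genotype="WT")
    )
    smp = df[df["role"] == "sample"][
        ["plate", "condition", "inducer_pct", "genotype", "fluorescence"]
    ]
    tidy = pd.concat([smp, wt], ignore_index=True)
    tidy = tidy.sort_values(["genotype", "condition", "plate"], kind="stable")
    tidy["replicate"] = tidy.groupby(["genotype", "condition"]).cumcount() + 1
    tidy = tidy.rename(columns={"condition": "inducer_label"})
    return tidy[
        ["genotype", "inducer_label", "inducer_pct", "replicate", "fluorescence"]
    ].reset_index(drop=True)


def summarize(tidy: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD (n-1 denominator) and n per genotype x condition.

    Single-replicate groups get a missing SD and an ``sd_missing`` flag.
    """
    g = tidy.groupby(["genotype", "inducer_label", "inducer_pct"], as_index=False)[
        "fluorescence"
    ].agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    g["sd_missing"] = g["sd"].isna()
    return g


def replicate_correlation(x, y) -> float:
    """Squared Pearson correlation between two replicate vectors.

    Equals the R^2 of the least-squares line of y on x. Returns NaN when
    either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("replicate vectors must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)
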