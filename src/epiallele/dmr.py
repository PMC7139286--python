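"""Sliding-window detection of differentially methylated regions.

The genome is scanned in 1000-bp windows advanced by 100-bp steps.
Per window, cytosine counts are pooled within each treatment group over
sites whose pooled per-group coverage reaches the floor (default 5),
and the two groups are compared with a two-sided Fisher exact test on
the pooled 2x2 methylated/unmethylated table.  Significant windows
(p < 0.05) are merged into maximal regions (overlap or abutment), and
each candidate region is confirmed by a one-way ANOVA across the two
groups on per-site methylation levels (p < 0.05).  Direction is hyper
when the pooled treated level exceeds the control level.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals
from .errors import UnsortedInputError


@dataclass(frozen=True)
class DmrParams:
    window: int = 1000
    step: int = 100
    min_cov: int = 5
    p_window: float = 0.05
    p_region: float = 0.05
    conversion_rate: float = 1.0  # used for per-site corrected levels in the ANOVA


def pool_groups(records: pd.DataFrame, groups: dict[str, str]) -> pd.DataFrame:
    """Sum counts per (chrom, pos) within each group across samples/strands.

    Returns one row per site with columns mc_ctrl, umc_ctrl, mc_treat,
    umc_treat, sorted by (chrom, pos).
    """
    df = records.copy()
    df["group"] = df["sample_id"].map(groups)
    if df["group"].isna().any():
        missing = sorted(df.loc[df["group"].isna(), "sample_id"].unique())
        raise ValueError(f"samples without group assignment: {missing}")
    pooled = (
        df.groupby(["chrom", "pos", "group"], observed=True)[
            ["count_methylated", "count_unmethylated"]
        ]
        .sum()
        .unstack("group", fill_value=0)
    )
    out = pd.DataFrame(
        {
            "mc_ctrl": pooled.get(("count_methylated", "ctrl"), 0),
            "umc_ctrl": pooled.get(("count_unmethylated", "ctrl"), 0),
            "mc_treat": pooled.get(("count_methylated", "treat"), 0),
            "umc_treat": pooled.get(("count_unmethylated", "treat"), 0),
        }
    ).reset_index()
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def eligible_sites(pooled: pd.DataFrame, min_cov: int = 5) -> pd.DataFrame:
    """Sites whose pooled coverage reaches the floor in both groups."""
    cov_c = pooled["mc_ctrl"] + pooled["umc_ctrl"]
    cov_t = pooled["mc_treat"] + pooled["umc_treat"]
    return pooled.loc[(cov_c >= min_cov) & (cov_t >= min_cov)].reset_index(drop=True)


def enumerate_windows(
    pooled_sites: pd.DataFrame,
    window: int = 1000,
    step: int = 100,
    min_cov: int = 5,
) -> pd.DataFrame:
    """One window per step position per chromosome containing >= 1 eligible site.

    ``pooled_sites`` is the output of :func:`pool_groups` sorted by
    (chrom, pos); unsorted input raises (no silent re-sort).  Windows
    are 0-based half-open ``[k*step, k*step + window)``.
    """
    chroms = pooled_sites["chrom"].to_numpy()
    pos = pooled_sites["pos"].to_numpy()
    try:
        intervals.assert_sorted(chroms, pos)
    except ValueError as exc:
        raise UnsortedInputError(str(exc)) from exc
    sites = eligible_sites(pooled_sites, min_cov)
    rows = []
    for chrom, sub in sites.groupby("chrom", observed=True, sort=False):
        p0 = sub["pos"].to_numpy() - 1  # 0-based site coordinate
        counts = sub[["mc_ctrl", "umc_ctrl", "mc_treat", "umc_treat"]].to_numpy()
        # window start indices covering each site: k*step in (p0-window, p0]
        k_hi = p0 // step
        k_lo = np.maximum(0, (p0 - window) // step + 1)
        n_win = int(p0.max() // step) + 1 if len(p0) else 0
        acc = np.zeros((n_win, 4), dtype=np.int64)
        nsite = np.zeros(n_win, dtype=np.int64)
        for i in range(len(p0)):
            sl = slice(int(k_lo[i]), int(k_hi[i]) + 1)
            acc[sl] += counts[i]
            nsite[sl] += 1
        occupied = np.flatnonzero(nsite > 0)
        for k in occupied:
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(k * step),
                    "end": int(k * step + window),
                    "n_sites": int(nsite[k]),
                    "mc_ctrl": int(acc[k, 0]),
                    "umc_ctrl": int(acc[k, 1]),
                    "mc_treat": int(acc[k, 2]),
                    "umc_treat": int(acc[k, 3]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_sites",
                 "mc_ctrl", "umc_ctrl", "mc_treat", "umc_treat"],
    )


def window_test(mc_ctrl: int, umc_ctrl: int, mc_treat: int, umc_treat: int) -> float:
    """Two-sided Fisher exact p on the pooled 2x2 window table."""
    if (mc_ctrl + umc_ctrl == 0) or (mc_treat + umc_treat == 0) or (
        mc_ctrl + mc_treat == 0
    ) or (umc_ctrl + umc_treat == 0):
        warnings.warn("window with an empty margin; p set to 1", stacklevel=2)
        return 1.0
    _, p = stats.fisher_exact(
        [[mc_ctrl, umc_ctrl], [mc_treat, umc_treat]], alternative="two-sided"
    )
    return float(p)


def test_windows(windows: pd.DataFrame) -> pd.DataFrame:
    """Add a ``p_fisher`` column to an enumerated-window frame."""
    out = windows.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["p_fisher"] = [
            window_test(r.mc_ctrl, r.umc_ctrl, r.mc_treat, r.umc_treat)
            for r in windows.itertuples(index=False)
        ]
    return out


def merge_significant(windows: pd.DataFrame, p_threshold: float = 0.05) -> pd.DataFrame:
    """Maximal unions of overlapping-or-abutting significant windows."""
    sig = windows.loc[windows["p_fisher"] < p_threshold]
    regions = []
    for chrom, sub in sig.groupby("chrom", observed=True, sort=False):
        ivs = list(zip(sub["start"], sub["end"]))
        for start, end, members in intervals.merge(ivs, max_gap=0):
            regions.append(
                {"chrom": chrom, "start": start, "end": end, "n_windows": len(members)}
            )
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "n_windows"])


def region_filter(
    region: dict,
    sites: pd.DataFrame,
    alpha: float = 0.05,
    r: float = 0.0,
) -> tuple[dict | None, str]:
    """Confirm one candidate region by per-site two-group ANOVA.

    ``sites`` is the eligible-site frame of the region's chromosome.
    Per-site corrected methylation levels of the two groups form the
    ANOVA groups.  Returns (dmr_row, "ok") or (None, reason).
    """
    in_region = (sites["pos"] - 1 >= region["start"]) & (sites["pos"] - 1 < region["end"])
    sub = sites.loc[in_region]
    if len(sub) < 2:
        return None, "fewer than 2 eligible sites per group"
    ml_ctrl = sub["mc_ctrl"] / (sub["mc_ctrl"] + sub["umc_ctrl"])
    ml_treat = sub["mc_treat"] / (sub["mc_treat"] + sub["umc_treat"])
    if r > 0:
        ml_ctrl = np.clip((ml_ctrl - r) / (1 - r), 0, 1)
        ml_treat = np.clip((ml_treat - r) / (1 - r), 0, 1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(ml_ctrl, ml_treat)
    if not np.isfinite(p):
        p = 1.0  # zero between-group variance
    if p >= alpha:
        return None, f"region ANOVA p {p:.3g} >= {alpha}"
    pooled_ml_ctrl = sub["mc_ctrl"].sum() / (sub["mc_ctrl"].sum() + sub["umc_ctrl"].sum())
    pooled_ml_treat = sub["mc_treat"].sum() / (sub["mc_treat"].sum() + sub["umc_treat"].sum())
    row = {
        "chrom": region["chrom"],
        "start": region["start"],
        "end": region["end"],
        "length_bp": region["end"] - region["start"],
        "p_region": float(p),
        "ml_ctrl": float(pooled_ml_ctrl),
        "ml_treat": float(pooled_ml_treat),
        "direction": "hyper" if pooled_ml_treat > pooled_ml_ctrl else "hypo",
        "n_windows": region.get("n_windows", np.nan),
    }
    return row, "ok"


def call_dmrs(
    records: pd.DataFrame,
    groups: dict[str, str],
    params: DmrParams = DmrParams(),
) -> pd.DataFrame:
    """Full pipeline: pool -> enumerate -> Fisher -> merge -> ANOVA filter.

    Returns DMRs sorted by genomic position with pooled group levels,
    region p-value and hyper/hypo direction.
    """
    pooled = pool_groups(records, groups)
    sites = eligible_sites(pooled, params.min_cov)
    windows = enumerate_windows(pooled, params.window, params.step, params.min_cov)
    windows = test_windows(windows)
    regions = merge_significant(windows, params.p_window)
    r = 1.0 - params.conversion_rate
    dmrs = []
    for region in regions.to_dict("records"):
        chrom_sites = sites.loc[sites["chrom"] == region["chrom"]]
        row, _ = region_filter(region, chrom_sites, params.p_region, r)
        if row is not None:
            dmrs.append(row)
    out = pd.DataFrame(
        dmrs,
        columns=["chrom", "start", "end", "length_bp", "p_region",
                 "ml_ctrl", "ml_treat", "direction", "n_windows"],
    )
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/len_a, overlap/len_b); 0 when disjoint."""
    ov = intervals.overlap_length(a[0], a[1], b[0], b[1])
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def recovery_rate(
    dmrs: pd.DataFrame, truth: pd.DataFrame, min_reciprocal: float = 0.5
) -> float:
    """Fraction of planted regions recovered at the reciprocal-overlap bar."""
    if len(truth) == 0:
        raise ValueError("empty truth table")
    hit = 0
    for t in truth.itertuples(index=False):
        calls = dmrs.loc[dmrs["chrom"] == t.chrom]
        for c in calls.itertuples(index=False):
            if reciprocal_overlap((t.start, t.end), (c.start, c.end)) >= min_reciprocal:
                hit += 1
                break
    return hit / len(truth)
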