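"""24-nt siRNA cluster calling, locus merging and differential levels.

Clusters are maximal chains of 24-nt reads in which consecutive read
intervals are separated by at most ``link_gap`` bases; chains with at
least ten reads become clusters.  Clusters within 150 bp of each other
are merged into siRNA loci.  Per-library expression is normalised to
reads per million (RPM); differential loci require |log2 fold change|
>= 1 (with a 1-RPM pseudocount) and a Fisher exact p < 0.05 on
locus-versus-rest read counts.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals


def validate_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly-24-nt reads; the number rejected is recorded in
    ``.attrs['n_rejected']``."""
    ok = (reads["end"] - reads["start"]) == 24
    out = reads.loc[ok].reset_index(drop=True)
    out.attrs["n_rejected"] = int((~ok).sum())
    return out


def call_clusters(
    reads: pd.DataFrame, min_reads: int = 10, link_gap: int = 75
) -> pd.DataFrame:
    """Gap-linked read chains with at least ``min_reads`` members.

    ``reads`` needs chrom, start, end (0-based half-open, all length
    24), sorted by (chrom, start).  A read joins the open chain when the
    gap to the chain's current right edge is <= ``link_gap`` (an
    overlapping read has a negative gap).  The cluster span is the union
    of its member reads.
    """
    reads = validate_reads(reads)
    rows = []
    for chrom, sub in reads.groupby("chrom", observed=True, sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(np.diff(starts) < 0):
            raise ValueError(f"reads not sorted by start on {chrom!r}")
        for c_start, c_end, members in intervals.merge(
            list(zip(starts, ends)), max_gap=link_gap
        ):
            if len(members) >= min_reads:
                rows.append(
                    {"chrom": chrom, "start": int(c_start), "end": int(c_end),
                     "read_count": len(members)}
                )
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "read_count"])
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def merge_windows(clusters: pd.DataFrame, merge_distance: int = 150) -> pd.DataFrame:
    """Merge clusters separated by <= ``merge_distance`` bp (inclusive).

    Count columns (any column ending in ``read_count``) are summed over
    merged members; the operation is idempotent.
    """
    count_cols = [c for c in clusters.columns if c.endswith("read_count")]
    rows = []
    for chrom, sub in clusters.groupby("chrom", observed=True, sort=False):
        ivs = list(zip(sub["start"], sub["end"]))
        counts = sub[count_cols].to_numpy()
        for start, end, members in intervals.merge(ivs, max_gap=merge_distance):
            row = {"chrom": chrom, "start": int(start), "end": int(end)}
            summed = counts[members].sum(axis=0)
            for col, val in zip(count_cols, summed):
                row[col] = int(val)
            rows.append(row)
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", *count_cols])
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def call_loci(
    reads_by_library: dict[str, pd.DataFrame],
    min_reads: int = 10,
    link_gap: int = 75,
    merge_distance: int = 150,
) -> pd.DataFrame:
    """Per-library cluster calling followed by cross-library 150-bp merging.

    Returns loci with one ``<library>_read_count`` column per library
    (counts recounted as reads fully inside the locus, so a library
    below the calling floor still contributes its reads to a locus
    called from the other library).
    """
    per_lib = []
    for lib, reads in reads_by_library.items():
        clusters = call_clusters(reads, min_reads=min_reads, link_gap=link_gap)
        clusters["library"] = lib
        per_lib.append(clusters)
    allc = pd.concat(per_lib, ignore_index=True)
    if len(allc) == 0:
        cols = ["chrom", "start", "end"] + [f"{lib}_read_count" for lib in reads_by_library]
        return pd.DataFrame(columns=cols)
    allc = allc.sort_values(["chrom", "start"], kind="mergesort")
    merged = merge_windows(
        allc[["chrom", "start", "end", "read_count"]], merge_distance=merge_distance
    )
    # recount reads per library within each locus
    for lib, reads in reads_by_library.items():
        reads = validate_reads(reads)
        counts = np.zeros(len(merged), dtype=int)
        for chrom, sub in reads.groupby("chrom", observed=True, sort=False):
            sel = merged["chrom"] == chrom
            if not sel.any():
                continue
            loci_iv = list(zip(merged.loc[sel, "start"], merged.loc[sel, "end"]))
            read_iv = list(zip(sub["start"], sub["end"]))
            idx = np.flatnonzero(sel.to_numpy())
            for i, j, ov in intervals.intersect(loci_iv, read_iv):
                if ov == 24:  # read fully contained
                    counts[idx[i]] += 1
        merged[f"{lib}_read_count"] = counts
    return merged.drop(columns=["read_count"])


def rpm(count: float, library_total: int) -> float:
    """Reads per million mapped reads."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return count * 1e6 / library_total


def differential_cluster(
    count_ctrl: int,
    count_treat: int,
    total_ctrl: int,
    total_treat: int,
    pseudocount_rpm: float = 1.0,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """log2 fold change, Fisher p and significance flag for one locus.

    The fold change is computed on RPM with a pseudocount (default
    1 RPM) so fully silenced loci remain representable; the p-value is a
    two-sided Fisher exact test on locus-versus-rest counts per library.
    """
    rpm_c = rpm(count_ctrl, total_ctrl)
    rpm_t = rpm(count_treat, total_treat)
    log2fc = float(np.log2((rpm_t + pseudocount_rpm) / (rpm_c + pseudocount_rpm)))
    _, p = stats.fisher_exact(
        [[count_ctrl, total_ctrl - count_ctrl], [count_treat, total_treat - count_treat]],
        alternative="two-sided",
    )
    significant = bool(abs(log2fc) >= lfc_threshold and p < alpha)
    return log2fc, float(p), significant


def differential_loci(
    loci: pd.DataFrame,
    library_totals: dict[str, int],
    ctrl: str = "ctrl",
    treat: str = "treat",
    **kwargs,
) -> pd.DataFrame:
    """Apply :func:`differential_cluster` across a locus table."""
    out = loci.copy()
    res = [
        differential_cluster(
            int(row[f"{ctrl}_read_count"]), int(row[f"{treat}_read_count"]),
            library_totals[ctrl], library_totals[treat], **kwargs,
        )
        for _, row in loci.iterrows()
    ]
    out["rpm_ctrl"] = [rpm(c, library_totals[ctrl]) for c in loci[f"{ctrl}_read_count"]]
    out["rpm_treat"] = [rpm(c, library_totals[treat]) for c in loci[f"{treat}_read_count"]]
    out["log2fc"] = [r[0] for r in res]
    out["p_diff"] = [r[1] for r in res]
    out["significant"] = [r[2] for r in res]
    return out


def significant_fraction(n_significant: int, n_total: int) -> float:
    """Share of loci with significant level differences (e.g. 15793/69172)."""
    if n_total <= 0:
        raise ValueError("total locus count must be positive")
    return n_significant / n_total


def direction_fractions(n_up: int, n_down: int) -> tuple[float, float]:
    """Up- and down-regulated shares among significant loci."""
    total = n_up + n_down
    if total <= 0:
        raise ValueError("no significant loci")
    return n_up / total, n_down / total


def te_overlap(
    loci: pd.DataFrame,
    te_intervals: pd.DataFrame,
    genic_intervals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Flag loci overlapping a transposable element (>= 1 bp, half-open).

    When gene intervals are given, each locus is additionally stratified
    as genic (>= 1 bp overlap with a gene) or intergenic; use
    :func:`te_overlap_summary` for the per-stratum TE fractions.
    """
    out = loci.copy()
    out["te_overlap"] = _any_overlap(loci, te_intervals)
    if genic_intervals is not None:
        genic = _any_overlap(loci, genic_intervals)
        out["region"] = np.where(genic, "genic", "intergenic")
    return out


def _any_overlap(loci: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    flags = np.zeros(len(loci), dtype=bool)
    for chrom, sub in loci.groupby("chrom", observed=True, sort=False):
        feats = features.loc[features["chrom"] == chrom]
        if len(feats) == 0:
            continue
        idx = sub.index.to_numpy()
        pairs = intervals.intersect(
            list(zip(sub["start"], sub["end"])), list(zip(feats["start"], feats["end"]))
        )
        pos = {v: k for k, v in enumerate(loci.index)}
        for i, _, _ in pairs:
            flags[pos[idx[i]]] = True
    return flags


def te_overlap_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Fraction of TE-overlapping loci within genic vs intergenic strata."""
    if "region" not in annotated.columns:
        raise ValueError("loci are not stratified; pass genic intervals to te_overlap")
    return (
        annotated.groupby("region", observed=True)["te_overlap"]
        .agg(n_loci="size", te_fraction="mean")
        .reset_index()
    )
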