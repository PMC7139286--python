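"""Annotation of DMRs with overlapping genomic elements.

A feature (protein-coding gene, lncRNA, siRNA locus, transposable
element) lies "within" a DMR when the two intervals share at least one
base under half-open coordinates — partial overlap counts.  Each DMR is
classified by the multiset of overlapped element kinds (single gene,
single lncRNA, single siRNA locus, gene + siRNA, lncRNA + siRNA, other
multi-element combinations, or none).  The module also computes
strand-oriented meta-feature methylation profiles (upstream flank,
scaled body, downstream flank), coverage-weighted per bin.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import intervals

FEATURE_KINDS = ("gene", "lncRNA", "siRNA_locus", "TE")
# TE overlaps are recorded but do not enter the element class
_CLASS_KINDS = ("gene", "lncRNA", "siRNA_locus")


def intersect_frames(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """All >= 1 bp overlap pairs between two interval frames.

    Frames need chrom, start, end (0-based half-open).  Returns index
    pairs (into ``a`` and ``b``) with overlap lengths.
    """
    rows = []
    for chrom, sub_a in a.groupby("chrom", observed=True, sort=False):
        sub_b = b.loc[b["chrom"] == chrom]
        if len(sub_b) == 0:
            continue
        pairs = intervals.intersect(
            list(zip(sub_a["start"], sub_a["end"])),
            list(zip(sub_b["start"], sub_b["end"])),
        )
        ia = sub_a.index.to_numpy()
        ib = sub_b.index.to_numpy()
        for i, j, ov in pairs:
            rows.append({"index_a": ia[i], "index_b": ib[j], "overlap_bp": ov})
    return pd.DataFrame(rows, columns=["index_a", "index_b", "overlap_bp"])


def element_class(kind_counts: dict[str, int]) -> str:
    """Classify a DMR by its overlapped element kinds (TEs excluded)."""
    counts = {k: kind_counts.get(k, 0) for k in _CLASS_KINDS}
    total = sum(counts.values())
    if total == 0:
        return "none"
    if total == 1:
        if counts["gene"]:
            return "single_gene"
        if counts["lncRNA"]:
            return "single_lncRNA"
        return "single_siRNA"
    kinds = {k for k, v in counts.items() if v > 0}
    if kinds == {"gene", "siRNA_locus"}:
        return "gene_plus_siRNA"
    if kinds == {"lncRNA", "siRNA_locus"}:
        return "lncRNA_plus_siRNA"
    return "other_multi"


def annotate_dmrs(dmrs: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Per-DMR overlapping features and element class.

    ``features`` needs feature_id, kind (one of gene / lncRNA /
    siRNA_locus / TE), chrom, start, end.  Every overlap pair appears in
    exactly one DMR's feature list.
    """
    unknown = set(features["kind"]) - set(FEATURE_KINDS)
    if unknown:
        raise ValueError(f"unknown feature kinds: {sorted(unknown)}")
    pairs = intersect_frames(dmrs, features)
    rows = []
    for dmr_idx, dmr in dmrs.iterrows():
        mine = pairs.loc[pairs["index_a"] == dmr_idx]
        feats = features.loc[mine["index_b"]]
        kind_counts = feats["kind"].value_counts().to_dict()
        rows.append(
            {
                "chrom": dmr["chrom"],
                "start": dmr["start"],
                "end": dmr["end"],
                "features": ";".join(feats["feature_id"]) if len(feats) else "",
                "n_genes": int(kind_counts.get("gene", 0)),
                "n_lncRNAs": int(kind_counts.get("lncRNA", 0)),
                "n_siRNA_loci": int(kind_counts.get("siRNA_locus", 0)),
                "n_TEs": int(kind_counts.get("TE", 0)),
                "element_class": element_class(kind_counts),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "features", "n_genes", "n_lncRNAs",
                 "n_siRNA_loci", "n_TEs", "element_class"],
    )


def methylation_profile(
    features: pd.DataFrame,
    sites: pd.DataFrame,
    flank_bp: int = 2000,
    n_body_bins: int = 20,
    n_flank_bins: int = 10,
) -> pd.DataFrame:
    """Coverage-weighted mean methylation over meta-feature coordinates.

    ``features`` needs chrom, start, end, strand; ``sites`` needs chrom,
    pos (1-based), count_methylated, count_unmethylated.  Bins run
    upstream flank -> body -> downstream flank in the feature's
    orientation (minus-strand features are mirrored).  Bin value is
    sum(mC)/sum(mC+umC) over contributing sites.
    """
    n_bins = 2 * n_flank_bins + n_body_bins
    mc_acc = np.zeros(n_bins)
    cov_acc = np.zeros(n_bins)
    for _, feat in features.iterrows():
        sub = sites.loc[sites["chrom"] == feat["chrom"]]
        if len(sub) == 0:
            continue
        p0 = sub["pos"].to_numpy() - 1
        start, end, strand = int(feat["start"]), int(feat["end"]), feat["strand"]
        length = end - start
        in_range = (p0 >= start - flank_bp) & (p0 < end + flank_bp)
        p0 = p0[in_range]
        mc = sub["count_methylated"].to_numpy()[in_range]
        cov = mc + sub["count_unmethylated"].to_numpy()[in_range]
        # signed distance in the feature orientation
        if strand == "-":
            rel = end - 1 - p0  # 0 at the 3'-most genomic base = feature 5' end
        else:
            rel = p0 - start
        bins = np.empty(len(p0), dtype=int)
        upstream = rel < 0
        body = (rel >= 0) & (rel < length)
        downstream = rel >= length
        bins[upstream] = (
            n_flank_bins - 1 - np.minimum(n_flank_bins - 1, (-rel[upstream] - 1) * n_flank_bins // flank_bp)
        )
        bins[body] = n_flank_bins + rel[body] * n_body_bins // length
        bins[downstream] = (
            n_flank_bins + n_body_bins
            + np.minimum(n_flank_bins - 1, (rel[downstream] - length) * n_flank_bins // flank_bp)
        )
        np.add.at(mc_acc, bins, mc)
        np.add.at(cov_acc, bins, cov)
    zone = (["upstream"] * n_flank_bins + ["body"] * n_body_bins + ["downstream"] * n_flank_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        ml = np.where(cov_acc > 0, mc_acc / cov_acc, np.nan)
    return pd.DataFrame(
        {"bin": np.arange(n_bins), "zone": zone, "ml": ml, "coverage": cov_acc}
    )
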