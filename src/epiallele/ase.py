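"""Allele-specific expression quantification and differential ASE.

Starting from biallelic SNVs with per-sample allelic depths, the module
filters variants GATK-style (phred quality >= 20, removal of runs of
>= 3 SNPs spanning <= 35 bases), applies a read-depth floor (total
> 5 in each condition), classifies genotype transitions between
conditions, quantifies ASE as the allele fraction ALT/(ALT+REF) (and
A/R = ALT/REF), selects one representative locus per gene near the
3' UTR, and tests for condition differences with a Fisher exact test on
the summed replicate counts.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedRatioError


# ------------------------------------------------------------ filtering

def snp_cluster_mask(positions: np.ndarray, cluster_n: int = 3, cluster_window: int = 35) -> np.ndarray:
    """True for positions belonging to a run of ``cluster_n`` SNPs whose
    span (inclusive, last - first + 1) is <= ``cluster_window``.

    ``positions`` must be sorted; every member of a qualifying run is
    flagged.
    """
    pos = np.asarray(positions)
    n = len(pos)
    mask = np.zeros(n, dtype=bool)
    for i in range(n - cluster_n + 1):
        j = i + cluster_n - 1
        if pos[j] - pos[i] + 1 <= cluster_window:
            mask[i : j + 1] = True
    return mask


def filter_variants(
    loci: pd.DataFrame,
    min_qual: float = 20.0,
    cluster_n: int = 3,
    cluster_window: int = 35,
) -> pd.DataFrame:
    """Quality and SNP-cluster filtering of biallelic SNVs.

    ``loci`` needs chrom, pos (1-based, sorted within chromosome), ref,
    alt, qual.  Non-SNV rows (multi-base alleles) are dropped; SNVs with
    qual below the floor are dropped; all members of any run of
    ``cluster_n`` remaining SNPs spanning <= ``cluster_window`` bases are
    dropped.
    """
    bases = {"A", "C", "G", "T"}
    is_snv = loci["ref"].isin(bases) & loci["alt"].isin(bases)
    passing = loci.loc[is_snv & (loci["qual"] >= min_qual)].copy()
    keep_parts = []
    for _, sub in passing.groupby("chrom", observed=True, sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError("variant positions must be sorted within chromosome")
        clustered = snp_cluster_mask(pos, cluster_n, cluster_window)
        keep_parts.append(sub.loc[~clustered])
    if not keep_parts:
        return passing.iloc[0:0]
    return pd.concat(keep_parts).reset_index(drop=True)


def condition_counts(loci: pd.DataFrame, condition: str) -> tuple[pd.Series, pd.Series]:
    """Summed ref/alt counts over a condition's replicate columns."""
    ref_cols = [c for c in loci.columns if c.startswith(f"{condition}_") and c.endswith("_ref")]
    alt_cols = [c for c in loci.columns if c.startswith(f"{condition}_") and c.endswith("_alt")]
    if not ref_cols or not alt_cols:
        raise ValueError(f"no replicate count columns for condition {condition!r}")
    return loci[ref_cols].sum(axis=1), loci[alt_cols].sum(axis=1)


def depth_filter(loci: pd.DataFrame, min_total: int = 6) -> pd.DataFrame:
    """Keep loci with total reads strictly > min_total - 1 in BOTH conditions.

    The rule is depth-only: deeply covered homozygous-looking loci pass.
    """
    ref_c, alt_c = condition_counts(loci, "ctrl")
    ref_t, alt_t = condition_counts(loci, "treat")
    keep = ((ref_c + alt_c) >= min_total) & ((ref_t + alt_t) >= min_total)
    return loci.loc[keep].reset_index(drop=True)


# -------------------------------------------------- genotype transitions

def call_genotype(
    ref_count: int,
    alt_count: int,
    min_minor_frac: float = 0.1,
    min_minor_reads: int = 2,
) -> str:
    """'het', 'hom_ref' or 'hom_alt' from allelic read counts.

    Heterozygous iff the minor allele has >= ``min_minor_reads``
    supporting reads and a fraction >= ``min_minor_frac``.
    """
    total = ref_count + alt_count
    if total == 0:
        raise UndefinedRatioError("genotype undefined with zero reads")
    minor = min(ref_count, alt_count)
    if minor >= min_minor_reads and minor / total >= min_minor_frac:
        return "het"
    return "hom_alt" if alt_count > ref_count else "hom_ref"


def classify_transition(genotype_ctrl: str, genotype_treat: str) -> str:
    """One of het_het / het_hom / hom_het / other.

    "other" covers loci homozygous in both conditions (no allelic
    variation observed).
    """
    het_c = genotype_ctrl == "het"
    het_t = genotype_treat == "het"
    if het_c and het_t:
        return "het_het"
    if het_c:
        return "het_hom"
    if het_t:
        return "hom_het"
    return "other"


# -------------------------------------------------------- quantification

def ase_level(ref_count: int, alt_count: int) -> float:
    """Allele fraction ALT/(ALT+REF)."""
    total = ref_count + alt_count
    if total <= 0:
        raise UndefinedRatioError("allele fraction undefined with zero reads")
    return alt_count / total


def alt_over_ref(ref_count: int, alt_count: int) -> float:
    """A/R = ALT/REF; undefined (raises) when REF = 0."""
    if ref_count == 0:
        raise UndefinedRatioError("A/R undefined with zero reference reads")
    return alt_count / ref_count


def select_gene_locus(
    gene_model: dict,
    loci: pd.DataFrame,
    utr_window: int = 500,
) -> pd.Series | None:
    """Representative ASE locus of a gene: the depth-maximal SNP in or
    within ``utr_window`` bp beyond the 3' UTR (strand-aware, half-open).

    ``gene_model`` needs chrom, utr_start, utr_end (0-based half-open)
    and strand.  Support is the total read count summed over both
    conditions; ties break to the smallest genomic coordinate.  Returns
    None when no locus is eligible.
    """
    chrom = gene_model["chrom"]
    if gene_model["strand"] == "+":
        lo, hi = gene_model["utr_start"], gene_model["utr_end"] + utr_window
    else:
        lo, hi = gene_model["utr_start"] - utr_window, gene_model["utr_end"]
    cand = loci.loc[
        (loci["chrom"] == chrom)
        & (loci["pos"] - 1 >= lo)
        & (loci["pos"] - 1 < hi)
    ]
    if len(cand) == 0:
        return None
    ref_c, alt_c = condition_counts(cand, "ctrl")
    ref_t, alt_t = condition_counts(cand, "treat")
    support = ref_c + alt_c + ref_t + alt_t
    best = support.max()
    winners = cand.loc[support == best]
    return winners.sort_values("pos").iloc[0]


# ------------------------------------------------------ differential ASE

def differential_ase(loci: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Fisher exact test of allele fractions between conditions.

    Replicate counts are summed within condition; the 2x2 table is
    [[ref_ctrl, alt_ctrl], [ref_treat, alt_treat]].  ``delta`` is the
    treated-minus-control allele fraction.
    """
    ref_c, alt_c = condition_counts(loci, "ctrl")
    ref_t, alt_t = condition_counts(loci, "treat")
    f_ctrl = (alt_c / (alt_c + ref_c)).to_numpy()
    f_treat = (alt_t / (alt_t + ref_t)).to_numpy()
    pvals = np.ones(len(loci))
    for i, table in enumerate(zip(ref_c, alt_c, ref_t, alt_t)):
        rc, ac, rt, at = (int(x) for x in table)
        _, pvals[i] = stats.fisher_exact([[rc, ac], [rt, at]], alternative="two-sided")
    out = loci[["chrom", "pos", "ref", "alt"]].copy()
    out["ref_ctrl"], out["alt_ctrl"] = ref_c.to_numpy(), alt_c.to_numpy()
    out["ref_treat"], out["alt_treat"] = ref_t.to_numpy(), alt_t.to_numpy()
    out["ase_ctrl"], out["ase_treat"] = f_ctrl, f_treat
    with np.errstate(divide="ignore"):
        out["a_over_r_ctrl"] = np.where(ref_c > 0, alt_c / ref_c, np.inf)
        out["a_over_r_treat"] = np.where(ref_t > 0, alt_t / ref_t, np.inf)
    out["delta"] = f_treat - f_ctrl
    out["p_diff"] = pvals
    out["significant"] = pvals < alpha
    return out


def group_ase_shift(
    deg_sets: dict[str, list],
    ase_results: pd.DataFrame,
    gene_loci: dict[str, tuple[str, int]],
) -> pd.DataFrame:
    """Condition-wise A/R distribution summary per regulated gene set.

    ``deg_sets`` maps a set label (e.g. "up", "down") to gene ids;
    ``gene_loci`` maps gene id -> (chrom, pos) of its representative
    locus.  Per set, reports median A/R per condition and a paired
    Wilcoxon signed-rank p for the within-locus condition shift.
    Genes without a representative locus are skipped; an empty set
    yields an empty summary row set.
    """
    keyed = ase_results.set_index(["chrom", "pos"])
    rows = []
    for label, genes in deg_sets.items():
        a_ctrl, a_treat = [], []
        for g in genes:
            locus = gene_loci.get(g)
            if locus is None or locus not in keyed.index:
                continue
            rec = keyed.loc[locus]
            if np.isfinite(rec["a_over_r_ctrl"]) and np.isfinite(rec["a_over_r_treat"]):
                a_ctrl.append(rec["a_over_r_ctrl"])
                a_treat.append(rec["a_over_r_treat"])
        if len(a_ctrl) == 0:
            continue
        diffs = np.asarray(a_treat) - np.asarray(a_ctrl)
        if np.allclose(diffs, 0) or len(diffs) < 2:
            p = 1.0
        else:
            _, p = stats.wilcoxon(a_ctrl, a_treat)
        rows.append(
            {
                "set": label,
                "n_loci": len(a_ctrl),
                "median_a_over_r_ctrl": float(np.median(a_ctrl)),
                "median_a_over_r_treat": float(np.median(a_treat)),
                "p_shift": float(p),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["set", "n_loci", "median_a_over_r_ctrl", "median_a_over_r_treat", "p_shift"],
    )
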