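"""Per-cytosine methylation quantification and allelic genotyping.

Implements the site-level statistics of a whole-genome bisulfite
experiment: sequence-context classification (CG / CHG / CHH, H = A, C
or T), the methylation level ML = mC/(mC+umC), its conversion-rate
correction ML_corrected = (ML - r)/(1 - r) where r is the bisulfite
*non*-conversion (error) rate, a one-sided binomial test that a site is
genuinely methylated, the methylation support rate S used to genotype
CpG loci at the allele level, and the |S_treat - S_ctrl|/S_ctrl change
classifier.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, CoverageError, UndefinedRatioError

CONTEXTS = ("CG", "CHG", "CHH")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ------------------------------------------------------- context calling

def classify_context(genome: dict[str, str], chrom: str, pos: int, strand: str) -> str:
    """Context of the cytosine at 1-based ``pos`` on ``strand``.

    CG if the next base (strand-aware) is G; CHG if base+1 is H (A/C/T)
    and base+2 is G; otherwise CHH.  Minus-strand positions are
    evaluated on the reverse complement.  Raises ``ValueError`` for a
    non-cytosine position or when the needed downstream bases run past
    the chromosome end.
    """
    seq = genome[chrom]
    i = pos - 1
    if strand == "+":
        base = seq[i]
        nxt = seq[i + 1] if i + 1 < len(seq) else None
        nxt2 = seq[i + 2] if i + 2 < len(seq) else None
    elif strand == "-":
        base = seq[i].translate(_COMPLEMENT)
        nxt = seq[i - 1].translate(_COMPLEMENT) if i - 1 >= 0 else None
        nxt2 = seq[i - 2].translate(_COMPLEMENT) if i - 2 >= 0 else None
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if base != "C":
        raise ValueError(f"{chrom}:{pos}({strand}) is {base}, not a cytosine")
    if nxt is None:
        raise ValueError(f"{chrom}:{pos}({strand}) truncated: no downstream base")
    if nxt == "G":
        return "CG"
    if nxt2 is None:
        raise ValueError(f"{chrom}:{pos}({strand}) truncated: context needs 2 bases")
    return "CHG" if nxt2 == "G" else "CHH"


def cytosine_sites(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All classifiable cytosines of one chromosome, both strands.

    Returns 1-based positions, strands and contexts, sorted by position.
    Sites whose context would require bases beyond the chromosome end
    are excluded (no sequence is fabricated).
    """
    arr = np.frombuffer(seq.encode(), dtype="S1")
    n = len(arr)
    out_pos, out_strand, out_ctx = [], [], []

    # plus strand: C at i, context from i+1, i+2
    is_c = arr == b"C"
    idx = np.flatnonzero(is_c)
    idx = idx[idx + 1 < n]  # need at least one downstream base
    nxt = arr[idx + 1]
    cg = nxt == b"G"
    # CHG/CHH need two downstream bases
    noncg = idx[~cg]
    noncg = noncg[noncg + 2 < n]
    ctx_noncg = np.where(arr[noncg + 2] == b"G", "CHG", "CHH")
    out_pos.append(idx[cg] + 1)
    out_strand.append(np.full(cg.sum(), "+"))
    out_ctx.append(np.full(cg.sum(), "CG"))
    out_pos.append(noncg + 1)
    out_strand.append(np.full(len(noncg), "+"))
    out_ctx.append(ctx_noncg)

    # minus strand: G at i is a C on the reverse complement; context from
    # i-1, i-2 (complemented)
    is_g = arr == b"G"
    idx = np.flatnonzero(is_g)
    idx = idx[idx - 1 >= 0]
    nxt = arr[idx - 1]
    cg = nxt == b"C"  # complement of C is G
    noncg = idx[~cg]
    noncg = noncg[noncg - 2 >= 0]
    ctx_noncg = np.where(arr[noncg - 2] == b"C", "CHG", "CHH")
    out_pos.append(idx[cg] + 1)
    out_strand.append(np.full(cg.sum(), "-"))
    out_ctx.append(np.full(cg.sum(), "CG"))
    out_pos.append(noncg + 1)
    out_strand.append(np.full(len(noncg), "-"))
    out_ctx.append(ctx_noncg)

    pos = np.concatenate(out_pos)
    strand = np.concatenate(out_strand)
    ctx = np.concatenate(out_ctx)
    order = np.lexsort((strand, pos))
    return pos[order].astype(np.int64), strand[order], ctx[order]


# ------------------------------------------------------ level statistics

def methylation_level(mc: int, umc: int) -> float:
    """ML = mC / (mC + umC); undefined (raises) at zero total coverage."""
    total = mc + umc
    if total <= 0:
        raise UndefinedRatioError("methylation level undefined at zero coverage")
    return mc / total


def corrected_level(ml: float, r: float) -> float:
    """(ML - r) / (1 - r), clamped to [0, 1].

    ``r`` is the non-conversion (false-methylation) rate, i.e. one minus
    the bisulfite conversion rate.
    """
    if not (0.0 <= r < 1.0):
        raise ConfigurationError(f"non-conversion rate r must be in [0, 1), got {r}")
    return float(np.clip((ml - r) / (1.0 - r), 0.0, 1.0))


def methylation_support(mc_reads: int, c_reads: int) -> float:
    """S = mC reads / (mC reads + C reads) at a single CpG locus.

    Ranges from 0 (no methylation on either allele) to 1 (complete
    methylation of both alleles); S near 0.5 is the hemi-methylated
    pattern.
    """
    total = mc_reads + c_reads
    if total <= 0:
        raise UndefinedRatioError("methylation support undefined at zero reads")
    return mc_reads / total


# ------------------------------------------------------------- site test

@dataclass(frozen=True)
class MethylationCall:
    chrom: str
    pos: int
    strand: str
    context: str
    mc: int
    umc: int
    ml: float
    ml_corrected: float
    p_binomial: float
    is_methylated: bool


def binomial_site_pvalue(mc, n, r):
    """One-sided upper-tail P(X >= mc) for X ~ Binomial(n, r)."""
    return stats.binom.sf(np.asarray(mc) - 1, n, r)


def call_methylated_site(
    mc: int,
    umc: int,
    r: float,
    alpha: float = 0.05,
    min_coverage: int = 5,
    chrom: str = ".",
    pos: int = 0,
    strand: str = "+",
    context: str = "CG",
) -> MethylationCall:
    """Binomial test of a single site against the non-conversion rate.

    The null is that every methylated read is a non-conversion artefact
    (success probability r); a site is called methylated when the
    upper-tail p-value falls below ``alpha``.  Sites below the coverage
    floor are excluded (raise), never called unmethylated.
    """
    n = mc + umc
    if n < min_coverage:
        raise CoverageError(f"coverage {n} below floor {min_coverage}; site excluded")
    ml = methylation_level(mc, umc)
    p = float(binomial_site_pvalue(mc, n, r))
    return MethylationCall(
        chrom=chrom, pos=pos, strand=strand, context=context, mc=mc, umc=umc,
        ml=ml, ml_corrected=corrected_level(ml, r), p_binomial=p,
        is_methylated=bool(p < alpha),
    )


def call_sites(
    records: pd.DataFrame,
    conversion_rate: float,
    alpha: float = 0.05,
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Vectorised site calling over a cytosine-report frame.

    ``records`` needs chrom, pos, strand, context, count_methylated,
    count_unmethylated (sample_id carried through if present).  Sites
    below the per-sample coverage floor are dropped.  ``conversion_rate``
    is the bisulfite conversion rate c; the test and correction use the
    error rate r = 1 - c.
    """
    if not (0.0 < conversion_rate <= 1.0):
        raise ConfigurationError(f"conversion rate must be in (0, 1], got {conversion_rate}")
    r = 1.0 - conversion_rate
    mc = records["count_methylated"].to_numpy()
    umc = records["count_unmethylated"].to_numpy()
    total = mc + umc
    keep = total >= min_coverage
    out = records.loc[keep].copy()
    mc, total = mc[keep], total[keep]
    ml = mc / total
    out["ml"] = ml
    out["ml_corrected"] = np.clip((ml - r) / (1.0 - r), 0.0, 1.0)
    out["p_binomial"] = binomial_site_pvalue(mc, total, r)
    out["is_methylated"] = out["p_binomial"].to_numpy() < alpha
    return out.reset_index(drop=True)


def summarize_contexts(calls: pd.DataFrame) -> pd.Series:
    """Fractions of methylated sites per context (sum to 1)."""
    methylated = calls.loc[calls["is_methylated"]]
    if len(methylated) == 0:
        raise ValueError("no methylated calls to summarise")
    frac = methylated["context"].value_counts(normalize=True)
    return frac.reindex(CONTEXTS, fill_value=0.0)


# ------------------------------------------- allelic methylation change

@dataclass(frozen=True)
class CpGGenotype:
    chrom: str
    pos: int
    s_ctrl: float
    s_treat: float
    change_ratio: float
    changed: bool


def classify_allelic_change(
    s_treat: float,
    s_ctrl: float,
    threshold: float = 0.5,
    chrom: str = ".",
    pos: int = 0,
) -> CpGGenotype:
    """Flag an obvious change of allelic methylation level.

    change_ratio = |S_treat - S_ctrl| / S_ctrl; changed iff the ratio
    strictly exceeds ``threshold``.  A gain from S_ctrl = 0 is treated
    as an obvious change (infinite ratio); 0 -> 0 is unchanged.
    """
    if s_ctrl == 0.0:
        ratio = np.inf if s_treat > 0 else 0.0
    else:
        ratio = abs(s_treat - s_ctrl) / s_ctrl
    return CpGGenotype(
        chrom=chrom, pos=pos, s_ctrl=s_ctrl, s_treat=s_treat,
        change_ratio=float(ratio), changed=bool(ratio > threshold),
    )


def genotype_cpg_loci(
    records: pd.DataFrame,
    groups: dict[str, str],
    threshold: float = 0.5,
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Allelic methylation genotypes of CpG loci shared by both groups.

    Counts are pooled over the samples of each group per (chrom, pos,
    strand) CpG site; loci with pooled coverage below ``min_coverage``
    in either group are skipped.
    """
    cg = records.loc[records["context"] == "CG"].copy()
    cg["group"] = cg["sample_id"].map(groups)
    if cg["group"].isna().any():
        missing = sorted(cg.loc[cg["group"].isna(), "sample_id"].unique())
        raise ValueError(f"samples without group assignment: {missing}")
    pooled = (
        cg.groupby(["chrom", "pos", "strand", "group"], observed=True)[
            ["count_methylated", "count_unmethylated"]
        ]
        .sum()
        .unstack("group")
    )
    mc_c = pooled.get(("count_methylated", "ctrl"))
    if mc_c is None:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "s_ctrl", "s_treat",
                                     "change_ratio", "changed"])
    mc_t = pooled[("count_methylated", "treat")]
    um_c = pooled[("count_unmethylated", "ctrl")]
    um_t = pooled[("count_unmethylated", "treat")]
    tot_c, tot_t = mc_c + um_c, mc_t + um_t
    keep = (tot_c >= min_coverage) & (tot_t >= min_coverage)
    s_ctrl = (mc_c / tot_c)[keep]
    s_treat = (mc_t / tot_t)[keep]
    s_c, s_t = s_ctrl.to_numpy(), s_treat.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(s_t - s_c) / s_c
    zero = s_c == 0
    ratio[zero] = np.where(s_t[zero] > 0, np.inf, 0.0)
    out = pd.DataFrame(
        {
            "s_ctrl": s_c,
            "s_treat": s_t,
            "change_ratio": ratio,
            "changed": ratio > threshold,
        },
        index=s_ctrl.index,
    ).reset_index()
    return out


def changed_fraction(genotypes: pd.DataFrame) -> float:
    """Fraction of genotyped CpG loci flagged as changed."""
    if len(genotypes) == 0:
        raise ValueError("no genotyped loci")
    return float(genotypes["changed"].mean())
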