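"""FPKM normalisation and differential-expression calling.

A feature is differentially expressed when all three criteria hold:
(1) two-sided Fisher exact p < 0.05 on pooled fragment counts,
(2) fold change >= 2 (|log2 FC| >= 1) on group-mean FPKM, and
(3) FPKM > 5 in every sample.  A separate stable-expression filter for
lncRNAs keeps features with FPKM > 1 in at least one group and FPKM > 0
in the other.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def fpkm(fragments: float, feature_length_bp: int, total_mapped_fragments: int) -> float:
    """Fragments per kilobase of feature per million mapped fragments."""
    if feature_length_bp <= 0 or total_mapped_fragments <= 0:
        raise ValueError("feature length and library total must be positive")
    return fragments * 1e9 / (feature_length_bp * total_mapped_fragments)


def sample_columns(counts: pd.DataFrame, groups: dict[str, str]) -> dict[str, list[str]]:
    """Map group name -> list of its sample columns present in ``counts``."""
    by_group: dict[str, list[str]] = {}
    for sample, group in groups.items():
        if sample in counts.columns:
            by_group.setdefault(group, []).append(sample)
    if set(by_group) != {"ctrl", "treat"}:
        raise ValueError(f"need ctrl and treat sample columns, found groups {sorted(by_group)}")
    return by_group


def fpkm_table(
    counts: pd.DataFrame,
    groups: dict[str, str],
    library_totals: dict[str, int],
) -> pd.DataFrame:
    """Per-sample FPKM columns (named ``<sample>_fpkm``) added to ``counts``."""
    out = counts.copy()
    for sample in groups:
        if sample not in counts.columns:
            continue
        out[f"{sample}_fpkm"] = [
            fpkm(c, l, library_totals[sample])
            for c, l in zip(counts[sample], counts["length_bp"])
        ]
    return out


def call_deg(
    counts: pd.DataFrame,
    groups: dict[str, str],
    library_totals: dict[str, int],
    min_fpkm: float = 5.0,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential-expression calls over a fragment-count table.

    ``counts`` needs feature_id, length_bp and one fragment column per
    sample; ``groups`` maps sample -> {ctrl, treat}; ``library_totals``
    gives mapped fragments per sample.  log2 fold change is computed on
    group-mean FPKM; the p-value is a two-sided Fisher exact test on
    pooled fragments vs pooled library remainders; the FPKM floor is
    enforced strictly per replicate.
    """
    by_group = sample_columns(counts, groups)
    tab = fpkm_table(counts, groups, library_totals)
    fpkm_ctrl = tab[[f"{s}_fpkm" for s in by_group["ctrl"]]]
    fpkm_treat = tab[[f"{s}_fpkm" for s in by_group["treat"]]]
    mean_ctrl = fpkm_ctrl.mean(axis=1).to_numpy()
    mean_treat = fpkm_treat.mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_treat / mean_ctrl)
    pooled_ctrl = counts[by_group["ctrl"]].sum(axis=1).to_numpy()
    pooled_treat = counts[by_group["treat"]].sum(axis=1).to_numpy()
    total_ctrl = sum(library_totals[s] for s in by_group["ctrl"])
    total_treat = sum(library_totals[s] for s in by_group["treat"])
    pvals = np.ones(len(counts))
    for i in range(len(counts)):
        _, pvals[i] = stats.fisher_exact(
            [
                [int(pooled_ctrl[i]), total_ctrl - int(pooled_ctrl[i])],
                [int(pooled_treat[i]), total_treat - int(pooled_treat[i])],
            ],
            alternative="two-sided",
        )
    all_above_floor = (
        (fpkm_ctrl.gt(min_fpkm).all(axis=1)) & (fpkm_treat.gt(min_fpkm).all(axis=1))
    ).to_numpy()
    out = tab.copy()
    out["fpkm_ctrl"] = mean_ctrl
    out["fpkm_treat"] = mean_treat
    out["log2fc"] = log2fc
    out["p_value"] = pvals
    out["is_de"] = (np.abs(log2fc) >= lfc_threshold) & (pvals < alpha) & all_above_floor
    out["direction"] = np.where(log2fc > 0, "up", "down")
    return out


def lncrna_stable_filter(fpkm_ctrl: float, fpkm_treat: float) -> bool:
    """Stable expression: FPKM > 1 in at least one group, > 0 in the other."""
    return bool(
        (fpkm_ctrl > 1.0 or fpkm_treat > 1.0) and min(fpkm_ctrl, fpkm_treat) > 0.0
    )


def deg_summary(de_table: pd.DataFrame) -> pd.Series:
    """Up / down / total counts among DE features."""
    de = de_table.loc[de_table["is_de"]]
    n_up = int((de["direction"] == "up").sum())
    n_down = int((de["direction"] == "down").sum())
    return pd.Series({"n_up": n_up, "n_down": n_down, "n_total": n_up + n_down})
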