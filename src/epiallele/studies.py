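"""Reference synthetic studies exercising the pipeline end to end.

Each function defines one fixed study — sample sizes, planted effects
and noise levels are part of the study definition — runs the relevant
pipeline stage on freshly simulated data and returns the headline
metric(s).  They back both the acceptance test suite and the
reproduction script, so the numbers reported in either place are always
recomputed, never cached.

Published-count summaries take the printed component counts of the
source experiments as inputs and recompute the derived totals and
percentages through the package's own summary operations.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import ase as ase_mod
from . import association as assoc
from . import dmr as dmr_mod
from . import expression as expr
from . import methylome
from . import simulate as sim
from . import sirna as sirna_mod
from .config import AseSpec, CausalEffect, DmrSpec, PopulationConfig, SimulationConfig

GROUPS = {f"{g}_{r}": g for g in ("ctrl", "treat") for r in (1, 2, 3)}


# --------------------------------------------------- published arithmetic

def deg_total_from_direction_counts(n_up: int, n_down: int) -> int:
    """Total differentially expressed features from per-direction counts."""
    table = pd.DataFrame(
        {"is_de": True, "direction": ["up"] * n_up + ["down"] * n_down}
    )
    return int(expr.deg_summary(table)["n_total"])


def sirna_significant_percent(n_significant: int, n_total: int) -> float:
    return 100.0 * sirna_mod.significant_fraction(n_significant, n_total)


def sirna_up_percent(n_up: int, n_down: int) -> float:
    return 100.0 * sirna_mod.direction_fractions(n_up, n_down)[0]


def association_total_from_trait_counts(per_trait: dict[str, int]) -> int:
    """Grand total of significant SNP-trait associations from per-trait rows."""
    rows = []
    for trait, n in per_trait.items():
        for i in range(n):
            rows.append({"snp_id": f"{trait}_{i}", "trait": trait, "significant": True})
    results = pd.DataFrame(rows)
    return int(assoc.association_summary(results)["total"])


# ------------------------------------------------------ recovery studies

def dmr_recovery_study(seed: int) -> dict:
    """20 planted 3-kb DMRs (delta ML +0.4, coverage 30) on a 1-Mb genome.

    Planted regions are kb-scale so that the one-window boundary smear
    of the 1000/100 sliding scan stays below the 50%-reciprocal-overlap
    recovery bar.
    """
    starts = np.arange(20) * 50_000 + 10_000
    cfg = SimulationConfig(
        seed=seed,
        chrom_length_bp=1_000_000,
        coverage_mean=30,
        dmr_specs=[DmrSpec("chr1", int(s), int(s) + 3_000, 0.4) for s in starts],
    )
    genome = sim.simulate_genome(cfg)
    records, truth = sim.simulate_methylome(genome, cfg)
    params = dmr_mod.DmrParams(conversion_rate=cfg.conversion_rate)
    dmrs = dmr_mod.call_dmrs(records, GROUPS, params)
    rate = dmr_mod.recovery_rate(dmrs, truth, min_reciprocal=0.5)
    return {"recovery_pct": 100.0 * rate, "n_planted": len(truth), "n_called": len(dmrs)}


def allele_fraction_study(seed: int, n_loci: int = 10_000, depth: int = 100) -> dict:
    """Bias of the allele-fraction estimator at depth 100 over 10^4 loci."""
    rng = np.random.default_rng([seed, 101])
    fractions = rng.uniform(0.1, 0.9, size=n_loci)
    specs = [
        AseSpec("chr1", i + 1, float(f), float(f), depth=depth)
        for i, f in enumerate(fractions)
    ]
    cfg = SimulationConfig(seed=seed, ase_specs=specs, n_replicates_per_group=1)
    loci, truth = sim.simulate_allelic_counts(cfg)
    est = loci["ctrl_1_alt"] / (loci["ctrl_1_alt"] + loci["ctrl_1_ref"])
    err = est.to_numpy() - truth["f_ctrl"].to_numpy()
    return {"mean_error": float(err.mean()), "mean_abs_error": float(np.abs(err).mean())}


def effect_recovery_study(seed: int, n_replicates: int = 10) -> dict:
    """Additive/dominance recovery: a=0.6, d=0.9, n=500, residual SD 1.

    Replicated populations with one causal SNP each; errors are averaged
    over replicates (|a| is compared because the estimator orients the
    additive effect to the major allele).
    """
    a_true, d_true = 0.6, 0.9
    a_err, d_err = [], []
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            seed=int(np.random.default_rng([seed, 202, rep]).integers(2**31)),
            population=PopulationConfig(
                n_individuals=500, n_snps=50, maf_range=(0.3, 0.5),
                missing_rate=0.0,
                causal=(CausalEffect(snp_index=0, a=a_true, d=d_true),),
                polygenic_var=0.0, residual_var=1.0,
            ),
        )
        G, phenos, truth = sim.simulate_population(cfg)
        dec = assoc.effect_decomposition(
            phenos["trait"].to_numpy(), G[truth.iloc[0]["snp_id"]].to_numpy()
        )
        a_err.append(abs(dec["a"]) - a_true)
        d_err.append(dec["d"] - d_true)
    return {
        "a_true": a_true, "d_true": d_true,
        "a_error": float(np.mean(a_err)), "d_error": float(np.mean(d_err)),
        "a_abs_error": float(np.mean(np.abs(a_err))),
        "d_abs_error": float(np.mean(np.abs(d_err))),
    }


# --------------------------------------------------- calibration studies

def binomial_caller_type1_study(
    seed: int, n_sites: int = 10_000, coverage: int = 30, conversion_rate: float = 0.995
) -> dict:
    """False-positive rate of the methylated-site caller on pure noise."""
    rng = np.random.default_rng([seed, 303])
    r = 1.0 - conversion_rate
    mc = rng.binomial(coverage, r, size=n_sites)
    records = pd.DataFrame(
        {
            "chrom": "chr1", "pos": np.arange(1, n_sites + 1), "strand": "+",
            "context": "CG", "count_methylated": mc,
            "count_unmethylated": coverage - mc,
        }
    )
    calls = methylome.call_sites(records, conversion_rate, alpha=0.05)
    return {"type1_rate": float(calls["is_methylated"].mean()), "n_sites": n_sites}


def fisher_ase_type1_study(seed: int, n_loci: int = 10_000, depth: int = 100) -> dict:
    """False-positive rate of the differential-ASE Fisher test under the
    balanced null (f = 0.5 in both conditions)."""
    rng = np.random.default_rng([seed, 404])
    alt_c = rng.binomial(depth, 0.5, size=n_loci)
    alt_t = rng.binomial(depth, 0.5, size=n_loci)
    loci = pd.DataFrame(
        {
            "chrom": "chr1", "pos": np.arange(1, n_loci + 1), "ref": "A", "alt": "G",
            "qual": 60.0,
            "ctrl_1_ref": depth - alt_c, "ctrl_1_alt": alt_c,
            "treat_1_ref": depth - alt_t, "treat_1_alt": alt_t,
        }
    )
    res = ase_mod.differential_ase(loci, alpha=0.05)
    return {"type1_rate": float(res["significant"].mean()), "n_loci": n_loci}


def mlm_null_calibration_study(seed: int, n_individuals: int = 300, n_snps: int = 500) -> dict:
    """Uniformity of mixed-model p-values for null SNPs on a polygenic trait."""
    cfg = SimulationConfig(
        seed=seed,
        population=PopulationConfig(
            n_individuals=n_individuals, n_snps=n_snps, maf_range=(0.1, 0.5),
            missing_rate=0.0, polygenic_var=0.3, residual_var=0.7,
        ),
    )
    G, phenos, _ = sim.simulate_population(cfg)
    Gf = assoc.filter_snps(G)
    K = assoc.grm(Gf)
    model = assoc.MixedModel(y=phenos["trait"].to_numpy(), K=K.to_numpy(), method="reml")
    pvals = np.array([model.test_snp(Gf[c].to_numpy())["p_value"] for c in Gf.columns])
    ks = stats.kstest(pvals, "uniform")
    return {"ks_p": float(ks.pvalue), "n_snps_tested": len(pvals)}


def prominent_dominant_null_study(seed: int, n_causal: int = 20) -> dict:
    """Fraction of pure-additive causal SNPs misflagged as dominance-led."""
    cfg = SimulationConfig(
        seed=seed,
        population=PopulationConfig(
            n_individuals=500, n_snps=max(60, n_causal * 3), maf_range=(0.3, 0.5),
            missing_rate=0.0,
            causal=tuple(CausalEffect(snp_index=i, a=0.5, d=0.0) for i in range(n_causal)),
            polygenic_var=0.0, residual_var=1.0,
        ),
    )
    G, phenos, truth = sim.simulate_population(cfg)
    y = phenos["trait"].to_numpy()
    flagged = sum(
        assoc.effect_decomposition(y, G[s].to_numpy())["prominent_dominant"]
        for s in truth["snp_id"]
    )
    return {"prominent_rate": flagged / len(truth), "n_causal": len(truth)}
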