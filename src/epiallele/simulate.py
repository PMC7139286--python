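"""Synthetic data generator with machine-readable ground truth.

Every input the pipeline consumes can be generated here under known
parameters, so each downstream stage is testable by parameter recovery:

* a random genome with a chosen GC fraction,
* per-cytosine bisulfite counts with planted hyper-/hypo-methylated
  regions and a stated bisulfite conversion rate,
* binomial allelic read counts with condition-specific true alt-allele
  fractions,
* 24-nt siRNA reads placed uniformly within planted clusters,
* Poisson fragment counts with planted expression fold changes,
* a Hardy-Weinberg population whose phenotype carries known additive
  (a) and dominant (d) effects plus polygenic and residual noise.

All generators are deterministic given ``config.seed``; each draws from
an independent stream so adding one stage never perturbs another.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .methylome import cytosine_sites

_BASES = np.array(list("ACGT"))

# per-stage stream tags so generators are independent of call order
_STREAMS = {"genome": 1, "methylome": 2, "ase": 3, "sirna": 4, "expression": 5, "population": 6}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stage]])


# ---------------------------------------------------------------- genome

def simulate_genome(config: SimulationConfig) -> dict[str, str]:
    """Random genome with base probabilities (gc/2 for G and C)."""
    config.validate()
    rng = _rng(config, "genome")
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = {}
    for name in config.chrom_names():
        idx = rng.choice(4, size=config.chrom_length_bp, p=probs)
        genome[name] = "".join(_BASES[idx])
    return genome


# ------------------------------------------------------------- methylome

def true_methylation_levels(
    genome: dict[str, str], config: SimulationConfig
) -> pd.DataFrame:
    """Per-site true methylation level for both groups.

    Returns a frame with chrom, pos (1-based), strand, context, pi_ctrl,
    pi_treat; treated levels are shifted by ``delta_ml`` inside each
    planted region.
    """
    frames = []
    for chrom, seq in genome.items():
        pos, strand, context = cytosine_sites(seq)
        pi = np.array([config.baseline_ml[c] for c in context])
        pi_treat = pi.copy()
        for spec in config.dmr_specs:
            if spec.chrom != chrom:
                continue
            in_region = (
                (pos - 1 >= spec.start)
                & (pos - 1 < spec.end)
                & np.isin(context, list(spec.contexts))
            )
            pi_treat[in_region] = pi[in_region] + spec.delta_ml
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strand": strand,
                    "context": context,
                    "pi_ctrl": pi,
                    "pi_treat": pi_treat,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_methylome(
    genome: dict[str, str], config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample cytosine-report counts plus the planted-DMR truth table.

    A methylated cytosine always reads methylated; an unmethylated one
    reads methylated with probability ``1 - conversion_rate`` (bisulfite
    non-conversion), so the observed methylated-read probability at true
    level pi is ``pi + (1 - pi) * (1 - c)``.  Under this model the
    downstream correction (ML - r)/(1 - r) with r = 1 - c is unbiased.
    Coverage is Poisson with the configured mean; low-coverage sites are
    still emitted (filtering is the caller's job).
    """
    config.validate()
    rng = _rng(config, "methylome")
    levels = true_methylation_levels(genome, config)
    r = 1.0 - config.conversion_rate
    samples = []
    for group, pi_col in (("ctrl", "pi_ctrl"), ("treat", "pi_treat")):
        p_obs = levels[pi_col].to_numpy()
        p_obs = p_obs + (1.0 - p_obs) * r
        for rep in range(1, config.n_replicates_per_group + 1):
            cov = rng.poisson(config.coverage_mean, size=len(levels))
            m = rng.binomial(cov, p_obs)
            samples.append(
                pd.DataFrame(
                    {
                        "chrom": levels["chrom"],
                        "pos": levels["pos"],
                        "strand": levels["strand"],
                        "context": levels["context"],
                        "count_methylated": m,
                        "count_unmethylated": cov - m,
                        "sample_id": f"{group}_{rep}",
                    }
                )
            )
    records = pd.concat(samples, ignore_index=True)
    truth = pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "delta_ml": s.delta_ml,
                "direction": "hyper" if s.delta_ml > 0 else "hypo",
            }
            for s in config.dmr_specs
        ],
        columns=["chrom", "start", "end", "delta_ml", "direction"],
    )
    return records, truth


# ------------------------------------------------------------------- ASE

def simulate_allelic_counts(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allelic read counts at planted SNP loci.

    Alt counts are Binomial(depth, f_condition) independently per
    replicate; ref/alt bases are arbitrary distinct bases.  Returns the
    locus table (one row per SNP, one ref/alt count pair per sample) and
    the truth table of planted fractions.
    """
    config.validate()
    rng = _rng(config, "ase")
    rows, truth_rows = [], []
    for spec in config.ase_specs:
        base_idx = rng.integers(0, 4)
        alt_idx = (base_idx + 1 + rng.integers(0, 3)) % 4
        row = {
            "chrom": spec.chrom,
            "pos": spec.pos,
            "ref": _BASES[base_idx],
            "alt": _BASES[alt_idx],
            "qual": 60.0,
        }
        for group, f in (("ctrl", spec.f_ctrl), ("treat", spec.f_treat)):
            for rep in range(1, config.n_replicates_per_group + 1):
                alt_n = int(rng.binomial(spec.depth, f))
                row[f"{group}_{rep}_ref"] = spec.depth - alt_n
                row[f"{group}_{rep}_alt"] = alt_n
        rows.append(row)
        truth_rows.append(
            {"chrom": spec.chrom, "pos": spec.pos, "f_ctrl": spec.f_ctrl,
             "f_treat": spec.f_treat, "depth": spec.depth}
        )
    cols = ["chrom", "pos", "ref", "alt", "qual"] + [
        f"{g}_{r}_{a}"
        for g in ("ctrl", "treat")
        for r in range(1, config.n_replicates_per_group + 1)
        for a in ("ref", "alt")
    ]
    loci = pd.DataFrame(rows, columns=cols)
    truth = pd.DataFrame(truth_rows, columns=["chrom", "pos", "f_ctrl", "f_treat", "depth"])
    return loci, truth


# ----------------------------------------------------------------- siRNA

def simulate_sirna_reads(
    genome: dict[str, str], config: SimulationConfig
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """24-nt read intervals (BED6 frames) per library plus cluster truth.

    Reads are placed uniformly inside their planted cluster; optional
    background reads fall uniformly anywhere on the genome.  Every
    emitted interval is exactly 24 bp.
    """
    config.validate()
    rng = _rng(config, "sirna")
    chrom_names = config.chrom_names()
    libraries: dict[str, pd.DataFrame] = {}
    for group in ("ctrl", "treat"):
        chroms, starts = [], []
        for spec in config.sirna_specs:
            n = spec.reads_ctrl if group == "ctrl" else spec.reads_treat
            if n == 0:
                continue
            s = rng.integers(spec.start, spec.end - 24 + 1, size=n)
            chroms.extend([spec.chrom] * n)
            starts.extend(s.tolist())
        for _ in range(config.sirna_background_reads):
            chroms.append(chrom_names[rng.integers(0, len(chrom_names))])
            starts.append(int(rng.integers(0, config.chrom_length_bp - 24 + 1)))
        df = pd.DataFrame({"chrom": chroms, "start": starts})
        df["end"] = df["start"] + 24
        df["name"] = [f"{group}_read_{i}" for i in range(len(df))]
        df["score"] = 0
        df["strand"] = "+"
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        libraries[group] = df
    truth = pd.DataFrame(
        [
            {"chrom": s.chrom, "start": s.start, "end": s.end,
             "reads_ctrl": s.reads_ctrl, "reads_treat": s.reads_treat}
            for s in config.sirna_specs
        ],
        columns=["chrom", "start", "end", "reads_ctrl", "reads_treat"],
    )
    return libraries, truth


# ------------------------------------------------------------ expression

def simulate_expression_counts(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Poisson fragment counts per feature per replicate library.

    Expected fragments are back-computed from the planted FPKM so that
    the FPKM estimator recovers the planted level in expectation.
    """
    config.validate()
    rng = _rng(config, "expression")
    total = config.expression_library_size
    rows = []
    for spec in config.expression_specs:
        row: dict = {
            "feature_id": spec.feature_id,
            "feature_type": spec.feature_type,
            "length_bp": spec.length_bp,
        }
        for group in ("ctrl", "treat"):
            fpkm = spec.base_fpkm * (spec.fold_change if group == "treat" else 1.0)
            lam = fpkm * (spec.length_bp / 1e3) * (total / 1e6)
            for rep in range(1, config.n_replicates_per_group + 1):
                row[f"{group}_{rep}"] = int(rng.poisson(lam))
        rows.append(row)
    counts = pd.DataFrame(rows)
    truth = pd.DataFrame(
        [
            {"feature_id": s.feature_id, "base_fpkm": s.base_fpkm,
             "fold_change": s.fold_change}
            for s in config.expression_specs
        ],
        columns=["feature_id", "base_fpkm", "fold_change"],
    )
    return counts, truth


# ------------------------------------------------------------ population

def vanraden_grm(genotypes: np.ndarray) -> np.ndarray:
    """VanRaden genomic relationship matrix from a 0/1/2 matrix.

    Missing entries (NaN) are imputed to the per-SNP mean before
    centering.
    """
    G = np.asarray(genotypes, dtype=float).copy()
    col_mean = np.nanmean(G, axis=0)
    nan_idx = np.where(np.isnan(G))
    G[nan_idx] = np.take(col_mean, nan_idx[1])
    p = col_mean / 2.0
    Z = G - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic; relationship matrix undefined")
    return Z @ Z.T / denom


def simulate_population(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Hardy-Weinberg genotypes, a quantitative phenotype, and the truth.

    Phenotype model: y = mu + sum_causal(g * a + 1[g == 1] * d)
    + polygenic term with covariance proportional to the VanRaden
    relationship matrix + Gaussian residual.  Missingness is applied
    completely at random to the *emitted* genotypes only; the phenotype
    is built from the complete genotypes.
    """
    config.validate()
    pop = config.population
    rng = _rng(config, "population")
    n, m = pop.n_individuals, pop.n_snps
    maf = rng.uniform(pop.maf_range[0], pop.maf_range[1], size=m)
    G = rng.binomial(2, np.broadcast_to(maf, (n, m)))
    y = np.full(n, pop.mu, dtype=float)
    for eff in pop.causal:
        g = G[:, eff.snp_index]
        y += g * eff.a + (g == 1) * eff.d
    if pop.polygenic_var > 0:
        K = vanraden_grm(G)
        # symmetric PSD square root via eigendecomposition (jitter-free)
        w, U = np.linalg.eigh(K)
        w = np.clip(w, 0.0, None)
        u = U @ (np.sqrt(w) * rng.standard_normal(n))
        y += np.sqrt(pop.polygenic_var) * u
    if pop.residual_var > 0:
        y += np.sqrt(pop.residual_var) * rng.standard_normal(n)
    G_out = G.astype(float)
    if pop.missing_rate > 0:
        mask = rng.random(size=G.shape) < pop.missing_rate
        G_out[mask] = np.nan
    individuals = [f"ind_{i + 1}" for i in range(n)]
    snp_ids = [f"snp_{j + 1}" for j in range(m)]
    genotypes = pd.DataFrame(G_out, index=individuals, columns=snp_ids)
    phenotypes = pd.DataFrame({"trait": y}, index=individuals)
    truth = pd.DataFrame(
        [{"snp_id": snp_ids[c.snp_index], "a": c.a, "d": c.d} for c in pop.causal],
        columns=["snp_id", "a", "d"],
    )
    truth_maf = pd.DataFrame({"snp_id": snp_ids, "maf": maf})
    truth = truth.merge(truth_maf, on="snp_id", how="left") if len(truth) else truth
    return genotypes, phenotypes, truth
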