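import numpy as np
import pandas as pd
import pytest

from epiallele.config import (
    AseSpec,
    CausalEffect,
    DmrSpec,
    PopulationConfig,
    SimulationConfig,
    SirnaSpec,
)
from epiallele import simulate as sim


GROUPS = {f"{g}_{r}": g for g in ("ctrl", "treat") for r in (1, 2, 3)}


@pytest.fixture(scope="session")
def groups():
    return dict(GROUPS)


@pytest.fixture(scope="session")
def small_genome():
    cfg = SimulationConfig(seed=7, chrom_length_bp=10_000)
    return sim.simulate_genome(cfg)


@pytest.fixture(scope="session")
def planted_methylome():
    """100 kb methylome with one hyper and one CG-restricted hypo region."""
    cfg = SimulationConfig(
        seed=21,
        chrom_length_bp=100_000,
        coverage_mean=30,
        dmr_specs=[
            DmrSpec("chr1", 30_000, 33_000, 0.4),
            DmrSpec("chr1", 70_000, 73_000, -0.3, contexts=("CG",)),
        ],
    )
    genome = sim.simulate_genome(cfg)
    records, truth = sim.simulate_methylome(genome, cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def planted_ase():
    specs = [
        AseSpec("chr1", 1_000, f_ctrl=0.5, f_treat=0.9, depth=500),
        AseSpec("chr1", 2_000, f_ctrl=0.5, f_treat=0.5, depth=200),
        AseSpec("chr1", 3_000, f_ctrl=1.0, f_treat=1.0, depth=100),
    ]
    cfg = SimulationConfig(seed=5, ase_specs=specs)
    loci, truth = sim.simulate_allelic_counts(cfg)
    return cfg, loci, truth


@pytest.fixture(scope="session")
def planted_sirna():
    specs = [
        SirnaSpec("chr1", 10_000, 10_500, reads_ctrl=50, reads_treat=50),
        SirnaSpec("chr1", 40_000, 40_300, reads_ctrl=5, reads_treat=5),
        SirnaSpec("chr1", 60_000, 60_400, reads_ctrl=80, reads_treat=8),
    ]
    cfg = SimulationConfig(seed=9, chrom_length_bp=100_000, sirna_specs=specs)
    genome = sim.simulate_genome(cfg)
    reads, truth = sim.simulate_sirna_reads(genome, cfg)
    return cfg, reads, truth


@pytest.fixture(scope="session")
def small_population():
    cfg = SimulationConfig(
        seed=13,
        population=PopulationConfig(
            n_individuals=300,
            n_snps=120,
            maf_range=(0.2, 0.5),
            missing_rate=0.02,
            causal=(CausalEffect(snp_index=3, a=0.8, d=1.8),),
            polygenic_var=0.2,
            residual_var=0.8,
        ),
    )
    return (cfg, *sim.simulate_population(cfg))
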