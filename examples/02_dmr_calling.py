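"""Sliding-window DMR detection on a methylome with planted regions.

Plants one hypermethylated and one CG-restricted hypomethylated region
into a 100-kb genome, runs the 1000-bp/100-bp Fisher + ANOVA scan, and
prints the recovered regions next to the truth.
"""
from epiallele import simulate
from epiallele.config import DmrSpec, SimulationConfig
from epiallele.dmr import DmrParams, call_dmrs, recovery_rate

cfg = SimulationConfig(
    seed=21, chrom_length_bp=100_000, coverage_mean=30,
    dmr_specs=[
        DmrSpec("chr1", 30_000, 33_000, +0.4),
        DmrSpec("chr1", 70_000, 73_000, -0.3, contexts=("CG",)),
    ],
)
genome = simulate.simulate_genome(cfg)
records, truth = simulate.simulate_methylome(genome, cfg)
groups = {f"{g}_{r}": g for g in ("ctrl", "treat") for r in (1, 2, 3)}

dmrs = call_dmrs(records, groups, DmrParams(conversion_rate=cfg.conversion_rate))

print("planted regions:")
print(truth.to_string(index=False))
print("\ncalled DMRs:")
cols = ["chrom", "start", "end", "length_bp", "ml_ctrl", "ml_treat", "direction", "p_region"]
print(dmrs[cols].round(4).to_string(index=False))
print(f"\nrecovery at 50% reciprocal overlap: "
      f"{100 * recovery_rate(dmrs, truth):.0f}% of planted regions")
# Calls extend up to one window beyond each planted boundary — the
# resolution limit of a 1000-bp window advanced in 100-bp steps.
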