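"""End-to-end orchestration of the synthetic-study pipeline.

Stages run in dependency order: simulate -> methylome / expr / ase /
sirna -> dmr -> integrate -> assoc.  Every stage reads and writes plain
text files, so each is runnable standalone; a JSON manifest records
parameters and the SHA-256 checksum of every emitted file, making runs
reproducible byte-for-byte for a fixed seed.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import association as assoc_mod
from . import dmr as dmr_mod
from . import expression as expr_mod
from . import integrate as integrate_mod
from . import io
from . import methylome as methylome_mod
from . import simulate as sim_mod
from . import sirna as sirna_mod
from .config import SimulationConfig
from .errors import DependencyError

STAGES = ("simulate", "methylome", "dmr", "ase", "sirna", "expr", "integrate", "assoc")


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str = "epiallele_run"
    stages: tuple[str, ...] = STAGES
    dmr: dmr_mod.DmrParams = field(default_factory=dmr_mod.DmrParams)
    alpha: float = 0.05
    min_coverage: int = 5
    change_threshold: float = 0.5


def _require(path: str, stage: str, upstream: str) -> str:
    if not os.path.exists(path):
        raise DependencyError(
            f"stage {stage!r} needs {path} produced by stage {upstream!r}; run it first"
        )
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns the run manifest."""
    out = io.ensure_dir(config.out_dir)
    sim = config.simulation
    manifest: dict = {
        "seed": sim.seed,
        "stages": list(config.stages),
        "parameters": {
            "window": config.dmr.window,
            "step": config.dmr.step,
            "min_cov": config.dmr.min_cov,
            "alpha": config.alpha,
            "conversion_rate": sim.conversion_rate,
        },
        "outputs": {},
    }

    def emit(name: str, writer) -> str:
        path = os.path.join(out, name)
        writer(path)
        manifest["outputs"][name] = io.sha256_file(path)
        return path

    groups = {
        f"{g}_{r}": g
        for g in ("ctrl", "treat")
        for r in range(1, sim.n_replicates_per_group + 1)
    }

    if "simulate" in config.stages:
        genome = sim_mod.simulate_genome(sim)
        emit("genome.fa", lambda p: io.write_fasta(genome, p))
        records, dmr_truth = sim_mod.simulate_methylome(genome, sim)
        emit("cytosine_report.tsv", lambda p: io.write_cytosine_report(records, p))
        emit("truth_dmrs.tsv", lambda p: dmr_truth.to_csv(p, sep="\t", index=False))
        sheet = pd.DataFrame({"sample_id": list(groups), "group": list(groups.values())})
        emit("sample_sheet.tsv", lambda p: sheet.to_csv(p, sep="\t", index=False))
        loci, ase_truth = sim_mod.simulate_allelic_counts(sim)
        if len(loci):
            emit("allelic.vcf", lambda p: io.write_allelic_vcf(loci, groups, p))
            emit("truth_ase.tsv", lambda p: ase_truth.to_csv(p, sep="\t", index=False))
        reads, sirna_truth = sim_mod.simulate_sirna_reads(genome, sim)
        for lib, df in reads.items():
            emit(f"sirna_{lib}.bed", lambda p, df=df: io.write_bed(df, p))
        emit("truth_sirna.tsv", lambda p: sirna_truth.to_csv(p, sep="\t", index=False))
        counts, expr_truth = sim_mod.simulate_expression_counts(sim)
        if len(counts):
            emit("expression_counts.tsv", lambda p: counts.to_csv(p, sep="\t", index=False))
            emit("truth_expression.tsv", lambda p: expr_truth.to_csv(p, sep="\t", index=False))
        G, phenos, pop_truth = sim_mod.simulate_population(sim)
        emit("genotypes.tsv", lambda p: G.to_csv(p, sep="\t"))
        emit("phenotypes.tsv", lambda p: phenos.to_csv(p, sep="\t"))
        emit("truth_population.tsv", lambda p: pop_truth.to_csv(p, sep="\t", index=False))

    report_path = os.path.join(out, "cytosine_report.tsv")

    if "methylome" in config.stages:
        _require(report_path, "methylome", "simulate")
        records = io.read_cytosine_report(report_path)
        calls = methylome_mod.call_sites(
            records, sim.conversion_rate, config.alpha, config.min_coverage
        )
        emit("methylation_calls.tsv", lambda p: calls.to_csv(p, sep="\t", index=False))
        genos = methylome_mod.genotype_cpg_loci(
            records, groups, config.change_threshold, config.min_coverage
        )
        emit("cpg_genotypes.tsv", lambda p: genos.to_csv(p, sep="\t", index=False))

    if "dmr" in config.stages:
        _require(report_path, "dmr", "simulate")
        records = io.read_cytosine_report(report_path)
        params = dmr_mod.DmrParams(
            window=config.dmr.window, step=config.dmr.step, min_cov=config.dmr.min_cov,
            p_window=config.dmr.p_window, p_region=config.dmr.p_region,
            conversion_rate=sim.conversion_rate,
        )
        dmrs = dmr_mod.call_dmrs(records, groups, params)
        emit("dmrs.tsv", lambda p: dmrs.to_csv(p, sep="\t", index=False))
        bed = dmrs[["chrom", "start", "end"]].copy()
        bed["name"] = dmrs["direction"]
        with np.errstate(divide="ignore"):
            bed["score"] = np.minimum(
                1000, (-10 * np.log10(dmrs["p_region"].clip(lower=1e-300))).round().astype(int)
            )
        bed["strand"] = "."
        emit("dmrs.bed", lambda p: io.write_bed(bed, p))

    if "ase" in config.stages:
        vcf_path = _require(os.path.join(out, "allelic.vcf"), "ase", "simulate")
        loci = io.read_allelic_vcf(vcf_path)
        loci = ase_mod.filter_variants(loci)
        loci = ase_mod.depth_filter(loci)
        results = ase_mod.differential_ase(loci, config.alpha)
        emit("ase_results.tsv", lambda p: results.to_csv(p, sep="\t", index=False))

    if "sirna" in config.stages:
        reads = {}
        totals = {}
        for lib in ("ctrl", "treat"):
            path = _require(os.path.join(out, f"sirna_{lib}.bed"), "sirna", "simulate")
            reads[lib] = io.read_bed(path)
            totals[lib] = len(reads[lib])
        loci = sirna_mod.call_loci(reads)
        diff = sirna_mod.differential_loci(loci, totals)
        emit("sirna_loci.tsv", lambda p: diff.to_csv(p, sep="\t", index=False))

    if "expr" in config.stages:
        path = _require(os.path.join(out, "expression_counts.tsv"), "expr", "simulate")
        counts = pd.read_csv(path, sep="\t")
        totals = {s: sim.expression_library_size for s in groups}
        de = expr_mod.call_deg(counts, groups, totals)
        emit("deg_results.tsv", lambda p: de.to_csv(p, sep="\t", index=False))

    if "integrate" in config.stages:
        dmr_path = _require(os.path.join(out, "dmrs.tsv"), "integrate", "dmr")
        dmrs = pd.read_csv(dmr_path, sep="\t")
        feature_rows = []
        sirna_path = os.path.join(out, "sirna_loci.tsv")
        if os.path.exists(sirna_path):
            sl = pd.read_csv(sirna_path, sep="\t")
            for i, row in sl.iterrows():
                feature_rows.append(
                    {"feature_id": f"sirna_locus_{i}", "kind": "siRNA_locus",
                     "chrom": row["chrom"], "start": row["start"], "end": row["end"]}
                )
        features = pd.DataFrame(
            feature_rows, columns=["feature_id", "kind", "chrom", "start", "end"]
        )
        annotation = integrate_mod.annotate_dmrs(dmrs, features)
        emit("dmr_annotation.tsv", lambda p: annotation.to_csv(p, sep="\t", index=False))

    if "assoc" in config.stages:
        g_path = _require(os.path.join(out, "genotypes.tsv"), "assoc", "simulate")
        p_path = _require(os.path.join(out, "phenotypes.tsv"), "assoc", "simulate")
        G = pd.read_csv(g_path, sep="\t", index_col=0)
        phenos = pd.read_csv(p_path, sep="\t", index_col=0)
        results = assoc_mod.run_association(G, phenos, method="p3d")
        emit("association_results.tsv", lambda p: results.to_csv(p, sep="\t", index=False))

    manifest_path = os.path.join(out, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ------------------------------------------------------------ validation

def validate_inputs(paths: dict[str, str]) -> list[dict]:
    """Lightweight format linting; returns a list of findings.

    ``paths`` maps a role (cytosine_report, sample_sheet, vcf, bed,
    gff3) to a file path.  Each finding has path, severity
    (warning/error) and a message with the first offending line number.
    """
    findings = []

    def finding(path, severity, message, line=None):
        findings.append({"path": path, "severity": severity, "message": message, "line": line})

    for role, path in paths.items():
        if not os.path.exists(path):
            finding(path, "error", f"{role}: file does not exist")
            continue
        if role == "cytosine_report":
            header = open(path).readline().rstrip("\n").split("\t")
            missing = set(io.CYTOSINE_COLUMNS) - set(header)
            if missing:
                finding(path, "error", f"missing columns {sorted(missing)}", line=1)
        elif role == "sample_sheet":
            header = open(path).readline().rstrip("\n").split("\t")
            if "sample_id" not in header or "group" not in header:
                finding(path, "error", "sample sheet needs sample_id and group", line=1)
        elif role == "vcf":
            with open(path) as fh:
                first = fh.readline()
                if not first.startswith("##fileformat=VCF"):
                    finding(path, "error", "missing ##fileformat header", line=1)
                has_ad = any(
                    line.startswith("##FORMAT=<ID=AD") for line in fh if line.startswith("##")
                )
                if not has_ad:
                    finding(path, "error", "VCF lacks AD FORMAT field required for ASE")
        elif role == "bed":
            for i, line in enumerate(open(path), start=1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    finding(path, "error", f"BED line with {len(parts)} columns", line=i)
                    break
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError:
                    finding(path, "error", "non-integer BED coordinates", line=i)
                    break
                if end <= start:
                    finding(path, "warning",
                            "end <= start; possible 1-based coordinates in BED", line=i)
                    break
        elif role == "gff3":
            first = open(path).readline()
            if not first.startswith("##gff-version"):
                finding(path, "warning", "missing ##gff-version pragma", line=1)
    return findings
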