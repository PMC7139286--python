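"""Variant filtering, genotype transitions and differential ASE."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epiallele import ase
from epiallele.errors import UndefinedRatioError


def loci_frame(positions, qual=60.0, chrom="c"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "G", "qual": qual}
    )


def brute_cluster_scan(positions, n=3, window=35):
    """All-triples (all n-runs) scan marking members of qualifying runs."""
    pos = list(positions)
    flagged = set()
    for i in range(len(pos)):
        for j in range(i + n - 1, len(pos)):
            if pos[j] - pos[i] + 1 <= window and j - i + 1 >= n:
                flagged.update(range(i, j + 1))
    return flagged


class TestFilterVariants:
    def test_cluster_of_three_within_window_removed(self):
        out = ase.filter_variants(loci_frame([100, 110, 130]))
        assert len(out) == 0  # span 31 <= 35

    def test_pair_below_cluster_size_kept(self):
        out = ase.filter_variants(loci_frame([100, 150]))
        assert len(out) == 2

    def test_low_quality_removed_before_clustering(self):
        df = loci_frame([100, 110, 130])
        df.loc[1, "qual"] = 10.0  # removing the middle SNP breaks the run
        out = ase.filter_variants(df)
        assert out["pos"].tolist() == [100, 130]

    def test_non_snv_rows_dropped(self):
        df = loci_frame([100, 500])
        df.loc[0, "alt"] = "GT"
        assert ase.filter_variants(df)["pos"].tolist() == [500]

    @pytest.mark.parametrize("trial", range(120))
    def test_matches_brute_force_scan(self, trial):
        rng = np.random.default_rng(9_000 + trial)
        n = int(rng.integers(2, 60))
        pos = np.sort(rng.choice(np.arange(1, 800), size=n, replace=False))
        out = ase.filter_variants(loci_frame(pos.tolist()))
        expected = [p for i, p in enumerate(pos) if i not in brute_cluster_scan(pos)]
        assert out["pos"].tolist() == expected


class TestDepthFilter:
    def _locus(self, rc, ac, rt, at):
        return pd.DataFrame(
            [{"chrom": "c", "pos": 1, "ref": "A", "alt": "G", "qual": 60.0,
              "ctrl_1_ref": rc, "ctrl_1_alt": ac, "treat_1_ref": rt, "treat_1_alt": at}]
        )

    def test_total_six_kept(self):
        assert len(ase.depth_filter(self._locus(3, 3, 3, 3))) == 1

    def test_total_five_dropped(self):
        assert len(ase.depth_filter(self._locus(5, 0, 10, 10))) == 0

    def test_depth_only_rule_keeps_homozygous_looking_deep_locus(self):
        assert len(ase.depth_filter(self._locus(0, 100, 0, 100))) == 1

    def test_must_pass_in_both_conditions(self):
        assert len(ase.depth_filter(self._locus(10, 10, 2, 2))) == 0


class TestTransitions:
    def test_genotype_calls_from_counts(self):
        assert ase.call_genotype(10, 10) == "het"
        assert ase.call_genotype(99, 1) == "hom_ref"
        assert ase.call_genotype(1, 99) == "hom_alt"
        assert ase.call_genotype(18, 2) == "het"  # fraction exactly 0.1, 2 reads

    @pytest.mark.parametrize(
        "gc,gt,expected",
        [("het", "het", "het_het"), ("het", "hom_ref", "het_hom"),
         ("hom_alt", "het", "hom_het"), ("hom_ref", "hom_ref", "other")],
    )
    def test_transition_classes(self, gc, gt, expected):
        assert ase.classify_transition(gc, gt) == expected


class TestAseLevel:
    @pytest.mark.parametrize("ref,alt,expected", [(2, 6, 0.75), (5, 5, 0.5)])
    def test_allele_fraction(self, ref, alt, expected):
        assert ase.ase_level(ref, alt) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(ref=st.integers(0, 500), alt=st.integers(0, 500))
    def test_swap_symmetry(self, ref, alt):
        if ref + alt == 0:
            with pytest.raises(UndefinedRatioError):
                ase.ase_level(ref, alt)
        else:
            assert ase.ase_level(ref, alt) + ase.ase_level(alt, ref) == pytest.approx(1.0)

    def test_a_over_r_undefined_without_reference_reads(self):
        assert ase.alt_over_ref(4, 8) == pytest.approx(2.0)
        with pytest.raises(UndefinedRatioError):
            ase.alt_over_ref(0, 8)


class TestGeneLocusSelection:
    def _loci(self, positions, totals):
        rows = []
        for p, t in zip(positions, totals):
            rows.append(
                {"chrom": "c", "pos": p, "ref": "A", "alt": "G", "qual": 60.0,
                 "ctrl_1_ref": t // 4, "ctrl_1_alt": t // 4,
                 "treat_1_ref": t // 4, "treat_1_alt": t // 4}
            )
        return pd.DataFrame(rows)

    GENE = {"chrom": "c", "utr_start": 1000, "utr_end": 1200, "strand": "+"}

    def test_argmax_support(self):
        loci = self._loci([1050, 1100, 1150], [12, 40, 8])
        assert ase.select_gene_locus(self.GENE, loci)["pos"] == 1100

    def test_downstream_window_boundary_half_open(self):
        # 0-based position 1200 + 499 inside; + 500 outside
        inside = self._loci([1200 + 499 + 1], [20])
        outside = self._loci([1200 + 500 + 1], [20])
        assert ase.select_gene_locus(self.GENE, inside) is not None
        assert ase.select_gene_locus(self.GENE, outside) is None

    def test_minus_strand_window_extends_upstream_in_genome(self):
        gene = dict(self.GENE, strand="-")
        before = self._loci([1000 - 500 + 1], [20])  # 0-based 500, first eligible
        assert ase.select_gene_locus(gene, before) is not None
        after = self._loci([1200 + 100], [20])  # beyond UTR on minus strand
        assert ase.select_gene_locus(gene, after) is None

    def test_tie_breaks_to_smallest_coordinate(self):
        loci = self._loci([1150, 1050], [40, 40])
        chosen = ase.select_gene_locus(self.GENE, loci)
        assert chosen["pos"] == 1050
        # deterministic under re-run
        assert ase.select_gene_locus(self.GENE, loci)["pos"] == 1050

    def test_no_eligible_locus_returns_none(self):
        assert ase.select_gene_locus(self.GENE, self._loci([10], [40])) is None


class TestDifferentialAse:
    def _frame(self, rc, ac, rt, at):
        return pd.DataFrame(
            [{"chrom": "c", "pos": 1, "ref": "A", "alt": "G", "qual": 60.0,
              "ctrl_1_ref": rc, "ctrl_1_alt": ac, "treat_1_ref": rt, "treat_1_alt": at}]
        )

    def test_identical_fractions_null(self):
        res = ase.differential_ase(self._frame(50, 50, 50, 50)).iloc[0]
        assert res["p_diff"] == pytest.approx(1.0) and res["delta"] == 0.0

    def test_strong_flip_detected(self):
        res = ase.differential_ase(self._frame(90, 10, 10, 90)).iloc[0]
        assert res["p_diff"] < 1e-15
        assert res["delta"] == pytest.approx(0.8)
        assert res["significant"]

    def test_replicates_summed_within_condition(self):
        df = pd.DataFrame(
            [{"chrom": "c", "pos": 1, "ref": "A", "alt": "G", "qual": 60.0,
              "ctrl_1_ref": 45, "ctrl_1_alt": 5, "ctrl_2_ref": 45, "ctrl_2_alt": 5,
              "treat_1_ref": 5, "treat_1_alt": 45, "treat_2_ref": 5, "treat_2_alt": 45}]
        )
        res = ase.differential_ase(df).iloc[0]
        pooled = ase.differential_ase(self._frame(90, 10, 10, 90)).iloc[0]
        assert res["p_diff"] == pytest.approx(pooled["p_diff"])


class TestGroupShift:
    def _results(self):
        rows = []
        for i in range(12):
            # upregulated genes: alt fraction drops 0.6 -> 0.4
            rows.append({"chrom": "c", "pos": 100 + i, "ref": "A", "alt": "G",
                         "a_over_r_ctrl": 0.6 / 0.4 + 0.01 * i,
                         "a_over_r_treat": 0.4 / 0.6 + 0.01 * i})
        return pd.DataFrame(rows)

    def test_planted_drop_reflected_in_medians(self):
        res = self._results()
        gene_loci = {f"g{i}": ("c", 100 + i) for i in range(12)}
        summary = ase.group_ase_shift({"up": [f"g{i}" for i in range(12)]}, res, gene_loci)
        row = summary.iloc[0]
        assert row["median_a_over_r_treat"] < row["median_a_over_r_ctrl"]
        assert row["p_shift"] < 0.05

    def test_identical_conditions_no_shift(self):
        res = self._results()
        res["a_over_r_treat"] = res["a_over_r_ctrl"]
        gene_loci = {f"g{i}": ("c", 100 + i) for i in range(12)}
        summary = ase.group_ase_shift({"up": [f"g{i}" for i in range(12)]}, res, gene_loci)
        assert summary.iloc[0]["p_shift"] == 1.0

    def test_empty_gene_set_yields_empty_summary(self):
        summary = ase.group_ase_shift({"up": []}, self._results(), {})
        assert len(summary) == 0
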