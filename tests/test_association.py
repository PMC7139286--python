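"""SNP QC, mixed-model association and additive/dominance decomposition."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiallele import association as assoc
from epiallele import simulate as sim
from epiallele.config import CausalEffect, PopulationConfig, SimulationConfig


def geno_frame(columns: dict) -> pd.DataFrame:
    return pd.DataFrame(columns)


class TestFilterSnps:
    def _single(self, g):
        return pd.DataFrame({"s": np.asarray(g, dtype=float)})

    def test_maf_boundary_strictly_below_five_percent_excluded(self):
        n = 200
        # MAF exactly 0.05: 20 alt alleles over 400; keep classes viable
        g_keep = [1] * 14 + [2] * 3 + [0] * (n - 17)
        assert list(assoc.filter_snps(self._single(g_keep)).columns) == ["s"]
        g_drop = [1] * 10 + [2] * 3 + [0] * (n - 13)  # MAF 0.04
        assert list(assoc.filter_snps(self._single(g_drop)).columns) == []

    def test_missingness_above_quarter_dropped(self):
        n = 100
        g = [0] * 30 + [1] * 25 + [2] * 19 + [np.nan] * 26
        assert list(assoc.filter_snps(self._single(g)).columns) == []
        g2 = [0] * 31 + [1] * 25 + [2] * 19 + [np.nan] * 25
        assert list(assoc.filter_snps(self._single(g2)).columns) == ["s"]

    def test_monomorphic_dropped(self):
        assert list(assoc.filter_snps(self._single([0] * 100)).columns) == []

    def test_thin_genotype_class_dropped(self):
        g = [0] * 60 + [1] * 38 + [2] * 2  # minor hom class below 3
        assert list(assoc.filter_snps(self._single(g)).columns) == []


class TestGrm:
    def test_duplicated_individuals_share_maximal_entry(self):
        rng = np.random.default_rng(0)
        G = rng.binomial(2, 0.3, size=(30, 200)).astype(float)
        G[1] = G[0]
        K = assoc.grm(pd.DataFrame(G))
        k = K.to_numpy()
        off = k[~np.eye(30, dtype=bool)]
        assert k[0, 1] == pytest.approx(k[0, 0], rel=1e-12)
        assert k[0, 1] >= off.max() - 1e-12

    def test_unrelated_individuals_near_zero_off_diagonal(self):
        rng = np.random.default_rng(1)
        G = rng.binomial(2, rng.uniform(0.1, 0.5, size=1_000), size=(100, 1_000))
        K = assoc.grm(pd.DataFrame(G.astype(float))).to_numpy()
        off = K[~np.eye(100, dtype=bool)]
        assert abs(off.mean()) < 0.02

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(2)
        G = rng.binomial(2, 0.4, size=(40, 300)).astype(float)
        G[rng.random(G.shape) < 0.05] = np.nan  # imputation path
        K = assoc.grm(pd.DataFrame(G)).to_numpy()
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestMlm:
    def test_identity_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(3)
        n = 120
        g = rng.binomial(2, 0.4, size=n).astype(float)
        y = 0.3 * g + rng.standard_normal(n)
        res = assoc.mlm_assoc(y, g, K=np.eye(n))
        import statsmodels.api as sm

        X = sm.add_constant(np.column_stack([g, (g == 1).astype(float)]))
        ols = sm.OLS(y, X).fit()
        p_ols = float(ols.f_test(np.eye(3)[1:]).pvalue)
        assert res["p_value"] == pytest.approx(p_ols, abs=1e-6)

    def test_power_at_planted_additive_effect(self):
        cfg = SimulationConfig(
            seed=23,
            population=PopulationConfig(
                n_individuals=300, n_snps=50, maf_range=(0.3, 0.3),
                missing_rate=0.0,
                causal=(CausalEffect(snp_index=0, a=1.0, d=0.0),),
                polygenic_var=0.2, residual_var=0.8,
            ),
        )
        G, phenos, _ = sim.simulate_population(cfg)
        K = assoc.grm(G)
        model = assoc.MixedModel(
            y=phenos["trait"].to_numpy(), K=K.to_numpy(), method="reml"
        )
        res = model.test_snp(G["snp_1"].to_numpy())
        assert res["p_value"] < 1e-3
        assert 0.0 <= res["r_squared"] <= 1.0

    def test_r_squared_monotone_in_effect_size(self):
        r2 = []
        for i, a in enumerate((0.0, 0.5, 1.0, 2.0)):
            cfg = SimulationConfig(
                seed=29,
                population=PopulationConfig(
                    n_individuals=300, n_snps=40, maf_range=(0.4, 0.4),
                    missing_rate=0.0,
                    causal=(CausalEffect(snp_index=0, a=a, d=0.0),),
                    polygenic_var=0.0, residual_var=1.0,
                ),
            )
            G, phenos, _ = sim.simulate_population(cfg)
            res = assoc.mlm_assoc(
                phenos["trait"].to_numpy(), G["snp_1"].to_numpy(),
                K=assoc.grm(G).to_numpy(),
            )
            r2.append(res["r_squared"])
        assert all(b >= a - 0.02 for a, b in zip(r2, r2[1:]))

    def test_missing_genotypes_dropped_casewise(self, small_population):
        _, G, phenos, _ = small_population
        Gf = assoc.filter_snps(G)
        K = assoc.grm(Gf)
        model = assoc.MixedModel(y=phenos["trait"].to_numpy(), K=K.to_numpy())
        col = Gf.columns[0]
        g = Gf[col].to_numpy()
        assert np.isnan(g).any()
        res = model.test_snp(g)
        assert np.isfinite(res["p_value"]) and res["df_den"] < len(g) - 3


class TestEffectDecomposition:
    def _y_g(self, mean_aa_major, mean_het, mean_aa_minor, n=30):
        y = np.concatenate(
            [np.full(n, mean_aa_major), np.full(n // 2, mean_het), np.full(n // 3, mean_aa_minor)]
        )
        g = np.concatenate([np.zeros(n), np.ones(n // 2), np.full(n // 3, 2.0)])
        return y, g

    def test_hand_computed_prominent_case(self):
        y, g = self._y_g(10.0, 14.0, 6.0)
        res = assoc.effect_decomposition(y, g)
        assert res["a"] == pytest.approx(2.0)
        assert res["d"] == pytest.approx(6.0)
        assert res["d_over_a"] == pytest.approx(3.0)
        assert res["prominent_dominant"]

    def test_pure_additivity_not_prominent(self):
        y, g = self._y_g(10.0, 8.0, 6.0)
        res = assoc.effect_decomposition(y, g)
        assert res["a"] == pytest.approx(2.0) and res["d"] == pytest.approx(0.0)
        assert not res["prominent_dominant"]

    def test_ratio_exactly_two_is_not_prominent(self):
        y, g = self._y_g(10.0, 12.0, 6.0)  # a=2, d=4, d/a exactly 2
        res = assoc.effect_decomposition(y, g)
        assert res["d_over_a"] == pytest.approx(2.0)
        assert not res["prominent_dominant"]

    def test_zero_additive_effect_infinite_sentinel(self):
        y, g = self._y_g(10.0, 13.0, 10.0)
        res = assoc.effect_decomposition(y, g)
        assert np.isinf(res["d_over_a"]) and res["prominent_dominant"]

    def test_thin_class_raises(self):
        y = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        g = np.array([0.0, 0.0, 1.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            assoc.effect_decomposition(y, g)


class TestQvalues:
    def test_step_up_hand_computation(self):
        q, _ = assoc.qvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        q, sig = assoc.qvalues([1.0, 1.0, 1.0])
        assert np.allclose(q, 1.0) and not sig.any()

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 50)
        q, _ = assoc.qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_joint_significance_rule(self):
        p = np.array([5e-4, 5e-4, 0.5, 0.9])
        q, sig = assoc.qvalues(p)
        assert sig.tolist() == [True, True, False, False]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            assoc.qvalues([0.5, 1.5])


class TestRunAssociation:
    def test_end_to_end_flags_planted_locus(self, small_population):
        cfg, G, phenos, truth = small_population
        results = assoc.run_association(G, phenos, method="p3d")
        planted = results.loc[results["snp_id"] == truth.iloc[0]["snp_id"]].iloc[0]
        assert planted["p_value"] < 1e-3
        # d = 1.8, a = 0.8 -> d/a = 2.25 > 2 at the truth level
        assert planted["d_over_a"] > 1.5
        summary = assoc.association_summary(results)
        assert summary["total"] >= 1

    def test_pure_additive_rarely_flagged_prominent(self):
        cfg = SimulationConfig(
            seed=31,
            population=PopulationConfig(
                n_individuals=500, n_snps=60, maf_range=(0.3, 0.5),
                missing_rate=0.0,
                causal=tuple(CausalEffect(snp_index=i, a=0.5, d=0.0) for i in range(10)),
                polygenic_var=0.0, residual_var=1.0,
            ),
        )
        G, phenos, truth = sim.simulate_population(cfg)
        y = phenos["trait"].to_numpy()
        flagged = 0
        for snp_id in truth["snp_id"]:
            res = assoc.effect_decomposition(y, G[snp_id].to_numpy())
            flagged += res["prominent_dominant"]
        assert flagged / len(truth) <= 0.05 + 1e-9
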