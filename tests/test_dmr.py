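"""Sliding-window DMR calling against brute-force oracles."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiallele import dmr
from epiallele.errors import UnsortedInputError


def make_pooled(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "mc_ctrl", "umc_ctrl",
                                       "mc_treat", "umc_treat"])


def brute_force_windows(pooled, window=1000, step=100, min_cov=5):
    """Enumerate every k*step window per chromosome by direct scanning."""
    sites = dmr.eligible_sites(pooled, min_cov)
    rows = []
    for chrom, sub in sites.groupby("chrom", sort=False):
        p0 = sub["pos"].to_numpy() - 1
        if len(p0) == 0:
            continue
        max_start = int(p0.max() // step) * step
        for start in range(0, max_start + step, step):
            inside = (p0 >= start) & (p0 < start + window)
            if not inside.any():
                continue
            block = sub.loc[inside]
            rows.append(
                {"chrom": chrom, "start": start, "end": start + window,
                 "n_sites": int(inside.sum()),
                 "mc_ctrl": int(block["mc_ctrl"].sum()),
                 "umc_ctrl": int(block["umc_ctrl"].sum()),
                 "mc_treat": int(block["mc_treat"].sum()),
                 "umc_treat": int(block["umc_treat"].sum())}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                       "mc_ctrl", "umc_ctrl", "mc_treat", "umc_treat"])


def fisher_two_sided_by_enumeration(a, b, c, d):
    """Sum of hypergeometric pmfs not exceeding the observed table's pmf."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    pmf_obs = stats.hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(lo, hi + 1):
        p = stats.hypergeom.pmf(x, n, col1, row1)
        if p <= pmf_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


class TestWindowEnumeration:
    def test_window_geometry(self):
        pooled = make_pooled(
            [{"chrom": "c", "pos": p, "mc_ctrl": 3, "umc_ctrl": 3, "mc_treat": 3,
              "umc_treat": 3} for p in (51, 951)]
        )
        win = dmr.enumerate_windows(pooled, window=1000, step=100)
        first = win.loc[(win["start"] == 0)].iloc[0]
        assert first["n_sites"] == 2
        second = win.loc[(win["start"] == 100)].iloc[0]
        assert second["n_sites"] == 1  # only pos 951 remains

    def test_empty_chromosome_yields_no_windows(self):
        win = dmr.enumerate_windows(make_pooled([]))
        assert len(win) == 0

    def test_unsorted_input_rejected(self):
        pooled = make_pooled(
            [{"chrom": "c", "pos": p, "mc_ctrl": 5, "umc_ctrl": 5, "mc_treat": 5,
              "umc_treat": 5} for p in (900, 100)]
        )
        with pytest.raises(UnsortedInputError):
            dmr.enumerate_windows(pooled)

    @pytest.mark.parametrize("trial", range(10))
    def test_streaming_equals_brute_force(self, trial):
        rng = np.random.default_rng(300 + trial)
        n = 200
        pos = np.sort(rng.choice(np.arange(1, 10_001), size=n, replace=False))
        counts = rng.integers(0, 20, size=(n, 4))
        pooled = make_pooled(
            [{"chrom": "c", "pos": int(p), "mc_ctrl": int(c[0]), "umc_ctrl": int(c[1]),
              "mc_treat": int(c[2]), "umc_treat": int(c[3])}
             for p, c in zip(pos, counts)]
        )
        fast = dmr.enumerate_windows(pooled)
        slow = brute_force_windows(pooled)
        pd.testing.assert_frame_equal(fast.reset_index(drop=True), slow)


class TestWindowTest:
    def test_identical_rows_give_p_one(self):
        assert dmr.window_test(10, 90, 10, 90) == pytest.approx(1.0)

    def test_against_hypergeometric_enumeration(self):
        expected = fisher_two_sided_by_enumeration(10, 90, 30, 70)
        assert dmr.window_test(10, 90, 30, 70) == pytest.approx(expected, rel=1e-9)
        assert dmr.window_test(0, 5, 5, 0) == pytest.approx(1 / 126, rel=1e-9)

    def test_empty_margin_warns_p_one(self):
        with pytest.warns(UserWarning):
            assert dmr.window_test(0, 0, 5, 5) == 1.0


class TestMergeSignificant:
    def _windows(self, spans, ps):
        return pd.DataFrame(
            [{"chrom": "c", "start": s, "end": e, "p_fisher": p}
             for (s, e), p in zip(spans, ps)]
        )

    def test_overlap_union(self):
        w = self._windows([(0, 1000), (100, 1100)], [0.01, 0.01])
        regions = dmr.merge_significant(w)
        assert regions[["start", "end"]].values.tolist() == [[0, 1100]]

    def test_disjoint_regions_stay_separate(self):
        w = self._windows([(0, 1000), (5000, 6000)], [0.01, 0.01])
        assert len(dmr.merge_significant(w)) == 2

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_union_find_oracle(self, trial):
        rng = np.random.default_rng(40 + trial)
        starts = np.arange(200) * 100
        ps = rng.uniform(0, 1, size=200)
        w = self._windows([(s, s + 1000) for s in starts], ps)
        regions = dmr.merge_significant(w, p_threshold=0.3)
        # union-find oracle over the significant windows
        sig = [(s, s + 1000) for s, p in zip(starts, ps) if p < 0.3]
        parent = list(range(len(sig)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(sig)):
            for j in range(i + 1, len(sig)):
                if sig[i][0] <= sig[j][1] and sig[j][0] <= sig[i][1]:
                    parent[find(i)] = find(j)
        comps = {}
        for i, iv in enumerate(sig):
            comps.setdefault(find(i), []).append(iv)
        expected = sorted(
            (min(s for s, _ in c), max(e for _, e in c)) for c in comps.values()
        )
        assert regions[["start", "end"]].values.tolist() == [list(t) for t in expected]

    def test_merged_regions_cover_union_of_significant_windows(self):
        rng = np.random.default_rng(9)
        starts = np.arange(100) * 100
        ps = rng.uniform(0, 1, 100)
        w = self._windows([(s, s + 1000) for s in starts], ps)
        regions = dmr.merge_significant(w, 0.2)
        covered = set()
        for r in regions.itertuples():
            covered.update(range(r.start, r.end))
        expected = set()
        for s, p in zip(starts, ps):
            if p < 0.2:
                expected.update(range(s, s + 1000))
        assert covered == expected


class TestRegionFilter:
    def _sites(self, ml_ctrl, ml_treat, start=0):
        n = len(ml_ctrl)
        return pd.DataFrame(
            {
                "chrom": "c", "pos": np.arange(start + 1, start + n + 1),
                "mc_ctrl": (np.array(ml_ctrl) * 100).astype(int),
                "umc_ctrl": 100 - (np.array(ml_ctrl) * 100).astype(int),
                "mc_treat": (np.array(ml_treat) * 100).astype(int),
                "umc_treat": 100 - (np.array(ml_treat) * 100).astype(int),
            }
        )

    def test_separated_groups_retained_hyper(self):
        sites = self._sites([0.1, 0.1, 0.1], [0.9, 0.9, 0.9])
        row, reason = dmr.region_filter({"chrom": "c", "start": 0, "end": 100}, sites)
        assert reason == "ok" and row["direction"] == "hyper"

    def test_identical_groups_rejected(self):
        sites = self._sites([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        row, reason = dmr.region_filter({"chrom": "c", "start": 0, "end": 100}, sites)
        assert row is None

    def test_too_few_sites_rejected_with_reason(self):
        sites = self._sites([0.1], [0.9])
        row, reason = dmr.region_filter({"chrom": "c", "start": 0, "end": 100}, sites)
        assert row is None and "fewer than 2" in reason

    def test_two_group_anova_equals_squared_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(0, 1, 8), rng.uniform(0, 1, 8)
        f, p_f = stats.f_oneway(a, b)
        t, p_t = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)


class TestCallDmrs:
    def test_planted_regions_recovered_with_direction(self, planted_methylome, groups):
        cfg, records, truth = planted_methylome
        params = dmr.DmrParams(conversion_rate=cfg.conversion_rate)
        dmrs = dmr.call_dmrs(records, groups, params)
        assert dmr.recovery_rate(dmrs, truth, min_reciprocal=0.5) >= 0.5
        # hypo region found with hypo direction
        hypo_truth = truth.loc[truth["direction"] == "hypo"].iloc[0]
        near = dmrs.loc[
            (dmrs["start"] < hypo_truth.end) & (dmrs["end"] > hypo_truth.start)
        ]
        assert len(near) >= 1 and (near["direction"] == "hypo").all()
        assert (dmrs["length_bp"] >= 100).all()
        assert (dmrs["start"].diff().dropna() >= 0).all()

    def test_null_methylome_false_positive_bound(self, groups):
        from epiallele.config import SimulationConfig
        from epiallele import simulate as sim

        cfg = SimulationConfig(seed=33, chrom_length_bp=100_000, coverage_mean=30)
        genome = sim.simulate_genome(cfg)
        records, _ = sim.simulate_methylome(genome, cfg)
        params = dmr.DmrParams(conversion_rate=cfg.conversion_rate)
        windows = dmr.test_windows(dmr.enumerate_windows(dmr.pool_groups(records, groups)))
        dmrs = dmr.call_dmrs(records, groups, params)
        n = len(windows)
        # at most the binomial upper bound of significant windows can
        # survive merging + the ANOVA filter
        bound = 0.05 * n + 4 * np.sqrt(n * 0.05 * 0.95)
        assert len(dmrs) <= bound
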