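"""Group-inference statistics: rank tests, Holm, Mack-Skillings, NBS,
regional ANOVA gate, clinical correlations."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import wnet
from wnet.exceptions import InvalidArgumentError


class TestKruskalWallis:
    def test_extreme_separation(self):
        res = wnet.kruskal_wallis([[1, 2, 3], [101, 102, 103], [201, 202, 203]])
        # H is at its maximum for fully separated groups of 3/3/3
        ranks = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        n = 9
        h_max = 12 / (n * (n + 1)) * sum(3 * np.mean(r) ** 2 for r in ranks) - 3 * (n + 1)
        assert res.statistic == pytest.approx(h_max)
        assert res.p_raw < 0.05

    def test_monotone_transform_invariance(self):
        groups = [[1.0, 2, 5], [3.0, 4, 8], [0.5, 6, 7]]
        a = wnet.kruskal_wallis(groups).statistic
        b = wnet.kruskal_wallis([np.exp(g) for g in [np.array(x) for x in groups]]).statistic
        assert a == pytest.approx(b)

    def test_null_p_uniform(self):
        # permuted labels: p-values should be uniform (KS test at alpha=.01)
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(500):
            vals = rng.normal(size=18)
            g = vals.reshape(3, 6)
            ps.append(wnet.kruskal_wallis(list(g)).p_raw)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_small_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            wnet.kruskal_wallis([[1.0], [2.0, 3.0]])


class TestMannWhitneyHolm:
    def test_four_groups_give_six_comparisons(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(size=6) for _ in range(4)]
        res = wnet.mann_whitney_posthoc(groups, labels=list("ABCD"))
        assert len(res) == 6
        assert {r.comparison for r in res} == {("A", "B"), ("A", "C"), ("A", "D"),
                                               ("B", "C"), ("B", "D"), ("C", "D")}

    def test_holm_step_down_hand_example(self):
        adj = wnet.holm_adjust([.01, .02, .03, .04, .05, .06])
        np.testing.assert_allclose(adj, [.06, .10, .12, .12, .12, .12])
        assert np.all(np.diff(adj[np.argsort([.01, .02, .03, .04, .05, .06])]) >= 0)

    def test_holm_between_raw_and_bonferroni(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=8)
        holm = wnet.holm_adjust(p)
        bonf = np.minimum(p * len(p), 1.0)
        assert np.all(holm >= p - 1e-15)
        assert np.all(holm <= bonf + 1e-15)

    def test_group_order_flips_u_not_p(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=7), rng.normal(1.0, size=7)
        r1 = wnet.mann_whitney_posthoc([a, b])[0]
        r2 = wnet.mann_whitney_posthoc([b, a])[0]
        assert r1.p_raw == pytest.approx(r2.p_raw)
        assert r1.statistic == pytest.approx(49 - r2.statistic)


class TestMackSkillings:
    @staticmethod
    def _long(data):
        """data[group][block] = list of observations -> flat arrays."""
        vals, grp, blk = [], [], []
        for g, blocks in data.items():
            for b, obs in blocks.items():
                vals += list(obs)
                grp += [g] * len(obs)
                blk += [b] * len(obs)
        return np.array(vals), np.array(grp), np.array(blk)

    def test_identical_groups_null(self):
        data = {g: {b: [1.0, 2.0, 3.0] for b in range(4)} for g in "ABC"}
        v, g, b = self._long(data)
        res = wnet.mack_skillings(v, g, b)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_raw > 0.99

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(4)
        data = {g: {b: list(rng.normal(size=5) + (10.0 if g == "D" else 0.0))
                    for b in range(10)} for g in "ABCD"}
        v, g, b = self._long(data)
        res = wnet.mack_skillings(v, g, b)
        assert res.p_raw < 0.05

    def test_block_constant_invariance(self):
        rng = np.random.default_rng(5)
        base = {g: {b: list(rng.normal(size=3)) for b in range(5)} for g in "AB"}
        v, g, b = self._long(base)
        s1 = wnet.mack_skillings(v, g, b).statistic
        shift = np.array([10.0 * int(x) for x in b])
        s2 = wnet.mack_skillings(v + shift, g, b).statistic
        assert s1 == pytest.approx(s2)

    def test_reduces_to_friedman_without_replication(self):
        rng = np.random.default_rng(6)
        k, n_blocks = 4, 12
        table = rng.normal(size=(n_blocks, k))
        vals = table.ravel()
        grp = np.tile(np.arange(k), n_blocks)
        blk = np.repeat(np.arange(n_blocks), k)
        res = wnet.mack_skillings(vals, grp, blk)
        fried = sps.friedmanchisquare(*[table[:, j] for j in range(k)])
        assert res.statistic == pytest.approx(fried.statistic)
        assert res.p_raw == pytest.approx(fried.pvalue)

    def test_matches_within_block_permutation_oracle(self):
        rng = np.random.default_rng(7)
        data = {g: {b: list(rng.normal(size=3) + (0.8 if g == "B" else 0.0))
                    for b in range(4)} for g in "ABC"}
        v, g, b = self._long(data)
        obs = wnet.mack_skillings(v, g, b)
        # oracle: permute group labels within each block, recompute statistic
        n_shuffle = 2000
        count = 0
        for _ in range(n_shuffle):
            gp = g.copy()
            for blk_id in np.unique(b):
                sel = b == blk_id
                gp[sel] = rng.permutation(gp[sel])
            count += wnet.mack_skillings(v, gp, b).statistic >= obs.statistic
        p_perm = (1 + count) / (n_shuffle + 1)
        assert obs.p_raw == pytest.approx(p_perm, abs=0.05)

    def test_missing_cell_named(self):
        v = np.array([1.0, 2.0, 3.0])
        g = np.array(["A", "A", "B"])
        b = np.array([0, 1, 0])
        with pytest.raises(InvalidArgumentError, match="1"):
            wnet.mack_skillings(v, g, b)


def _subject_matrices(rng, n_subj, n_nodes, bump_edges=(), bump=0.0):
    mats = []
    for _ in range(n_subj):
        m = np.clip(rng.normal(0.3, 0.05, size=(n_nodes, n_nodes)), 0.01, 1)
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        for i, j in bump_edges:
            m[i, j] = m[j, i] = np.clip(m[i, j] + bump, 0, 1)
        mats.append(m)
    return mats


class TestNbs:
    def test_no_difference_high_threshold_no_components(self):
        rng = np.random.default_rng(8)
        mats = _subject_matrices(rng, 12, 10)
        res = wnet.nbs(mats, ["a"] * 6 + ["b"] * 6, stat="F", threshold=30.0,
                       n_perm=50, seed=0)
        assert res.components == []

    def test_single_supra_edge_single_component(self):
        rng = np.random.default_rng(9)
        mats = _subject_matrices(rng, 16, 8)
        for m, lab in zip(mats, ["a"] * 8 + ["b"] * 8):
            if lab == "b":
                m[0, 1] = m[1, 0] = m[0, 1] + 0.5
        res = wnet.nbs(mats, ["a"] * 8 + ["b"] * 8, stat="F", threshold=25.0,
                       n_perm=100, seed=1)
        assert any(c == [(0, 1)] for c in res.components)

    def test_permutation_p_bounds(self):
        rng = np.random.default_rng(10)
        mats = _subject_matrices(rng, 10, 8, bump_edges=[(0, 1), (1, 2)], bump=0.0)
        for m, lab in zip(mats, ["a"] * 5 + ["b"] * 5):
            if lab == "b":
                for i, j in [(0, 1), (1, 2)]:
                    m[i, j] = m[j, i] = m[i, j] + 0.4
        res = wnet.nbs(mats, ["a"] * 5 + ["b"] * 5, stat="t_onetail", threshold=3.8,
                       n_perm=200, seed=2)
        for p in res.component_p:
            assert 1 / 201 <= p <= 1.0

    def test_lenient_threshold_warns(self):
        rng = np.random.default_rng(11)
        mats = _subject_matrices(rng, 8, 6)
        with pytest.warns(UserWarning, match="50%"):
            wnet.nbs(mats, ["a"] * 4 + ["b"] * 4, stat="F", threshold=1e-9,
                     n_perm=10, seed=3)


class TestDistanceRangeTests:
    def test_output_grid_shape(self, layout16):
        rng = np.random.default_rng(12)
        profiles = []
        groups = []
        for g in ("HC", "AD", "DLB", "PDD"):
            for _ in range(5):
                w = np.clip(rng.normal(0.3, 0.05, (16, 16)), 0.01, 1)
                w = (w + w.T) / 2
                np.fill_diagonal(w, 0)
                m = wnet.ConnectivityMatrix(wpli=w, band="alpha",
                                            labels=layout16.labels, n_epochs_used=1)
                profiles.append(wnet.distance_profile(m, layout16))
                groups.append(g)
        out = wnet.distance_range_tests(profiles, groups)
        assert set(out) == set(wnet.DISTANCE_RANGES)
        for rng_name in out:
            assert isinstance(out[rng_name]["omnibus"], wnet.StatResult)
            assert len(out[rng_name]["posthoc"]) == 6


def _regional_table(rng, effect_region=None, effect=0.0, n_per_group=8):
    rows = []
    for g in ("A", "B"):
        for s in range(n_per_group):
            sid = f"{g}{s}"
            for r in wnet.REGIONS:
                v = rng.normal(1.0, 0.1)
                if g == "B" and r == effect_region:
                    v += effect
                rows.append({"subject": sid, "group": g, "region": r, "value": v})
    return pd.DataFrame(rows)


class TestRegionGroupGate:
    def test_uniform_group_effect_no_interaction(self):
        rng = np.random.default_rng(13)
        df = _regional_table(rng)
        df.loc[df["group"] == "B", "value"] += 0.5  # same shift in every region
        res = wnet.region_group_gate(df)
        assert not res["gate_passed"]
        assert res["per_region"] == {}

    def test_planted_regional_interaction_flagged(self):
        rng = np.random.default_rng(14)
        df = _regional_table(rng, effect_region="posterior", effect=1.0)
        res = wnet.region_group_gate(df)
        assert res["gate_passed"]
        post = res["per_region"]["posterior"]
        assert post["omnibus"].p_raw < 0.05

    def test_interaction_f_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(15)
        rows = []
        for g in ("A", "B"):
            for s in range(6):
                for r in ("r1", "r2"):
                    rows.append({"subject": f"{g}{s}", "group": g, "region": r,
                                 "value": rng.normal(float(g == "B" and r == "r2"), 1.0)})
        df = pd.DataFrame(rows)
        res = wnet.region_group_gate(df)
        # classical balanced split-plot decomposition
        n, G, R = 6, 2, 2
        grand = df["value"].mean()
        cell = df.groupby(["group", "region"])["value"].mean()
        gm = df.groupby("group")["value"].mean()
        rm = df.groupby("region")["value"].mean()
        ss_int = sum(n * (cell[g, r] - gm[g] - rm[r] + grand) ** 2
                     for g in ("A", "B") for r in ("r1", "r2"))
        subj = df.groupby(["subject", "group"])["value"].mean()
        ss_err = 0.0
        for _, row in df.iterrows():
            ss_err += (row["value"] - cell[row["group"], row["region"]]
                       - subj[row["subject"], row["group"]] + gm[row["group"]]) ** 2
        f_oracle = (ss_int / ((G - 1) * (R - 1))) / (ss_err / ((R - 1) * (G * n - G)))
        assert res["interaction_F"] == pytest.approx(f_oracle)

    def test_missing_cells_rejected(self):
        rng = np.random.default_rng(16)
        df = _regional_table(rng).iloc[:-1]  # drop one region row
        with pytest.raises(InvalidArgumentError):
            wnet.region_group_gate(df)


class TestClinicalCorrelations:
    @staticmethod
    def _tables(values, scores, group="A"):
        sids = [f"s{i}" for i in range(len(values))]
        meas = pd.DataFrame({"subject_id": sids, "group": group, "band": "alpha",
                             "measure": "mean_wpli", "value": values})
        clin = pd.DataFrame({"subject_id": sids, "group": group, "score": scores})
        return meas, clin

    def test_identity_gives_rho_one(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        out = wnet.clinical_correlations(*self._tables(vals, vals))
        assert out.iloc[0]["rho"] == pytest.approx(1.0)
        assert out.iloc[0]["correction"] == "uncorrected"

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(17)
        v = rng.normal(size=12)
        s = rng.normal(size=12)
        out = wnet.clinical_correlations(*self._tables(v, s))
        oracle = np.corrcoef(sps.rankdata(v), sps.rankdata(s))[0, 1]
        assert out.iloc[0]["rho"] == pytest.approx(oracle)

    def test_few_observations_flagged_unstable(self):
        out = wnet.clinical_correlations(*self._tables([1.0, 2, 3], [3.0, 2, 1]))
        assert bool(out.iloc[0]["unstable"])
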