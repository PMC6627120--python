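import itertools

import numpy as np
import pandas as pd
import pytest

import milkbiome as mb
from milkbiome.tableio import CountTableError


def euclidean_dm(points, ids=None):
    a = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
    ids = ids or [f"S{i}" for i in range(len(points))]
    return mb.DistanceMatrix(pd.DataFrame(a, index=ids, columns=ids),
                             "euclidean")


class TestPermanova:
    def test_perfect_separation(self):
        pts = np.array([[0.0, 0], [0, 0], [10, 10], [10, 10]])
        d = euclidean_dm(pts)
        groups = pd.Series(["a", "a", "b", "b"], index=d.ids)
        res = mb.permanova(d, groups, permutations=999, seed=0)
        assert res.ss_within == pytest.approx(0.0)
        assert np.isinf(res.pseudo_f)
        # only C(4,2)/2-ish relabelings tie the degenerate F; p is small but > 0
        assert 0 < res.p_value < 0.4

    def test_ss_decomposition_matches_centered_anova(self):
        """On Euclidean distances the SS partition equals a coordinate ANOVA."""
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        labels = np.array(["a"] * 5 + ["b"] * 4 + ["c"] * 3)
        d = euclidean_dm(pts)
        res = mb.permanova(d, pd.Series(labels, index=d.ids),
                           permutations=9, seed=0)
        grand = pts.mean(axis=0)
        ss_t = ((pts - grand) ** 2).sum()
        ss_w = sum(((pts[labels == g] - pts[labels == g].mean(axis=0)) ** 2).sum()
                   for g in "abc")
        assert res.ss_total == pytest.approx(ss_t, rel=1e-9)
        assert res.ss_within == pytest.approx(ss_w, rel=1e-9)
        assert res.ss_among == pytest.approx(ss_t - ss_w, rel=1e-9)

    def test_additivity_invariant(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 2))
        d = euclidean_dm(pts)
        groups = pd.Series(rng.choice(["x", "y"], 10), index=d.ids)
        res = mb.permanova(d, groups, permutations=9, seed=3)
        assert res.ss_among + res.ss_within == pytest.approx(res.ss_total,
                                                             abs=1e-9)

    def test_p_value_bounds_and_determinism(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(14, 2))
        d = euclidean_dm(pts)
        groups = pd.Series(["a"] * 7 + ["b"] * 7, index=d.ids)
        r1 = mb.permanova(d, groups, permutations=99, seed=7)
        r2 = mb.permanova(d, groups, permutations=99, seed=7)
        assert r1.p_value == r2.p_value
        assert 1 / 100 <= r1.p_value <= 1.0

    def test_invariant_under_label_renaming(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 2))
        d = euclidean_dm(pts)
        g1 = pd.Series(["a"] * 5 + ["b"] * 5, index=d.ids)
        g2 = g1.map({"a": "zebra", "b": "ant"})
        r1 = mb.permanova(d, g1, permutations=49, seed=5)
        r2 = mb.permanova(d, g2, permutations=49, seed=5)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f)
        assert r1.p_value == r2.p_value

    def test_agrees_with_skbio(self):
        """Cross-check pseudo-F against the independent scikit-bio routine."""
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 3))
        pts[:6] += 1.0
        d = euclidean_dm(pts)
        groups = ["a"] * 6 + ["b"] * 6
        res = mb.permanova(d, pd.Series(groups, index=d.ids),
                           permutations=9, seed=0)
        sk = sk_permanova(SkDM(d.values.to_numpy(), ids=d.ids),
                          grouping=groups, permutations=9)
        assert res.pseudo_f == pytest.approx(float(sk["test statistic"]),
                                             rel=1e-9)

    def test_single_group_rejected(self):
        d = euclidean_dm(np.zeros((4, 2)))
        with pytest.raises(CountTableError):
            mb.permanova(d, pd.Series(["a"] * 4, index=d.ids), 9, 0)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert mb.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(mb.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.random(9)
            q = mb.bh_adjust(p)
            m = len(p)
            order = np.argsort(p)
            expected = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                expected[i] = running
            np.testing.assert_allclose(q, expected, atol=1e-12)

    def test_order_preserving_and_bounded(self):
        rng = np.random.default_rng(7)
        p = rng.random(15)
        q = mb.bh_adjust(p)
        assert ((q >= p - 1e-12) & (q <= 1 + 1e-12)).all()
        sp = np.argsort(p)
        assert (np.diff(q[sp]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(CountTableError):
            mb.bh_adjust([0.5, 1.2])


class TestAlphaAnova:
    def alpha_df(self, values, names):
        return pd.DataFrame({"shannon": values}, index=names)

    def test_matches_hand_anova(self):
        vals = [1.0, 2.0, 3.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        names = [f"S{i}" for i in range(9)]
        groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=names)
        f, p = mb.alpha_anova(self.alpha_df(vals, names), groups)
        x = np.array(vals)
        means = [x[:3].mean(), x[3:6].mean(), x[6:].mean()]
        grand = x.mean()
        ssb = 3 * sum((m - grand) ** 2 for m in means)
        ssw = sum(((x[i * 3:(i + 1) * 3] - means[i]) ** 2).sum()
                  for i in range(3))
        f_hand = (ssb / 2) / (ssw / 6)
        assert f == pytest.approx(f_hand, rel=1e-9)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(8)
        vals = np.r_[rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10)]
        names = [f"S{i}" for i in range(20)]
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=names)
        _, p = mb.alpha_anova(self.alpha_df(vals, names), groups)
        assert p < 0.001

    def test_null_f_near_one_in_expectation(self):
        rng = np.random.default_rng(9)
        fs = []
        for _ in range(200):
            vals = rng.normal(size=12)
            names = [f"S{i}" for i in range(12)]
            groups = pd.Series(["a"] * 6 + ["b"] * 6, index=names)
            f, _ = mb.alpha_anova(self.alpha_df(vals, names), groups)
            fs.append(f)
        assert 0.7 < np.mean(fs) < 1.5

    def test_undersized_group_rejected(self):
        names = ["S0", "S1", "S2"]
        groups = pd.Series(["a", "a", "b"], index=names)
        with pytest.raises(CountTableError):
            mb.alpha_anova(self.alpha_df([1.0, 2.0, 3.0], names), groups)


class TestReplicateR2:
    def test_identical_columns(self):
        t = mb.CountTable(pd.DataFrame({"A": [5, 3, 9], "B": [5, 3, 9]},
                                       index=list("xyz")))
        assert mb.replicate_r2(t, ("A", "B")) == pytest.approx(1.0)

    def test_proportional_columns(self):
        t = mb.CountTable(pd.DataFrame({"A": [5, 3, 9], "B": [10, 6, 18]},
                                       index=list("xyz")))
        assert mb.replicate_r2(t, ("A", "B")) == pytest.approx(1.0)

    def test_deep_multinomial_duplicates_above_097(self, cohort):
        table = cohort[0]
        s = table.biological_samples[0]
        # re-draw the sample at high depth twice to emulate duplicate
        # library preparations of one extract
        deep = mb.generate_replicate_pair(table, s, depth=100_000, seed=21)
        deep = mb.generate_replicate_pair(deep, s, depth=100_000, seed=22)
        r2 = mb.replicate_r2(deep, (s + "_rep", s + "_rep2"))
        assert r2 > 0.97

    def test_zero_variance_rejected(self):
        t = mb.CountTable(pd.DataFrame({"A": [2, 2], "B": [1, 3]},
                                       index=["x", "y"]))
        with pytest.raises(CountTableError):
            mb.replicate_r2(t, ("A", "B"))


class TestCovariateScan:
    def make_inputs(self, seed=10):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(16, 3))
        ids = [f"S{i}" for i in range(16)]
        d = euclidean_dm(pts, ids)
        meta = pd.DataFrame({
            "site": ["A"] * 8 + ["B"] * 8,
            "mode": list(np.where(rng.random(16) < 0.5, "vag", "cs")),
        }, index=ids)
        return {"genus": d, "phylum": d}, meta

    def test_one_cell_per_covariate_level(self):
        distances, meta = self.make_inputs()
        rep = mb.covariate_scan(distances, meta, ["site", "mode"],
                                permutations=49, seed=0)
        assert len(rep.table) == 4
        assert set(rep.table.columns) >= {"covariate", "level", "p", "q"}

    def test_stable_under_input_order(self):
        distances, meta = self.make_inputs()
        r1 = mb.covariate_scan(distances, meta, ["site", "mode"],
                               permutations=49, seed=0)
        r2 = mb.covariate_scan(dict(reversed(list(distances.items()))),
                               meta, ["mode", "site"],
                               permutations=49, seed=0)
        k = ["covariate", "level"]
        pd.testing.assert_frame_equal(
            r1.table.sort_values(k).reset_index(drop=True),
            r2.table.sort_values(k).reset_index(drop=True))

    def test_q_dominates_p(self):
        distances, meta = self.make_inputs()
        rep = mb.covariate_scan(distances, meta, ["site", "mode"],
                                permutations=49, seed=0)
        assert (rep.table["q"] >= rep.table["p"] - 1e-12).all()
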