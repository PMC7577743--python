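"""GO densities, degree-preserving randomization, communities, associations."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from ppiseq.network_analysis import (
    binned_bootstrap_association,
    density_significance,
    density_variability,
    detect_communities,
    interaction_density,
    randomize_degree_preserving,
)


def _annotations(d):
    return pd.DataFrame(
        [(g, t) for g, ts in d.items() for t in ts], columns=["gene", "term"]
    )


class TestInteractionDensity:
    def test_simple_ratio(self):
        ann = _annotations({"a": ["T1"], "b": ["T2"], "c": ["T1"], "d": ["T2"]})
        out = interaction_density([("a", "b")], ann, [("a", "b"), ("c", "d")])
        row = out.set_index(["term_a", "term_b"]).loc[("T1", "T2")]
        assert row["density"] == pytest.approx(0.5)

    def test_zero_ppis(self):
        ann = _annotations({"a": ["T1"], "b": ["T2"]})
        out = interaction_density([], ann, [("a", "b")])
        assert (out["density"] == 0).all()

    def test_overlapping_terms_match_bruteforce(self, rng):
        genes = [f"g{i}" for i in range(10)]
        terms = ["T1", "T2", "T3"]
        ann_map = {g: list(rng.choice(terms, size=rng.integers(1, 3), replace=False)) for g in genes}
        assayed = list(combinations(genes, 2))
        calls = [assayed[i] for i in rng.choice(len(assayed), 12, replace=False)]
        out = interaction_density(calls, _annotations(ann_map), assayed).set_index(["term_a", "term_b"])
        # brute force: enumerate pairs per term pair directly
        call_set = {frozenset(c) for c in calls}
        for ta, tb in combinations_with_replacement_sorted(terms):
            n_a = sum(
                1
                for x, y in assayed
                if (ta in ann_map[x] and tb in ann_map[y]) or (tb in ann_map[x] and ta in ann_map[y])
            )
            n_p = sum(
                1
                for x, y in assayed
                if frozenset((x, y)) in call_set
                and ((ta in ann_map[x] and tb in ann_map[y]) or (tb in ann_map[x] and ta in ann_map[y]))
            )
            if n_a == 0:
                assert (ta, tb) not in out.index
            else:
                assert out.loc[(ta, tb), "n_assayed"] == n_a
                assert out.loc[(ta, tb), "n_ppi"] == n_p


def combinations_with_replacement_sorted(terms):
    from itertools import combinations_with_replacement

    return combinations_with_replacement(sorted(terms), 2)


class TestRandomization:
    EDGES = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("e", "f")]
    UNIVERSE = [f"u{i}" for i in range(20)] + ["a", "b", "c", "d", "e", "f"]

    def test_preserves_edge_count_and_degrees(self, rng):
        out = randomize_degree_preserving(self.EDGES, self.UNIVERSE, rng)
        assert len(out) == len(self.EDGES)

        def degseq(edges):
            d = {}
            for x, y in edges:
                d[x] = d.get(x, 0) + 1
                d[y] = d.get(y, 0) + 1
            return sorted(d.values())

        assert degseq(out) == degseq(self.EDGES)

    def test_per_node_degree_preserved_under_mapping(self, rng):
        out = randomize_degree_preserving(self.EDGES, self.UNIVERSE, rng)
        # "a" (degree 3) maps to some node that also has degree 3
        deg_out = {}
        for x, y in out:
            deg_out[x] = deg_out.get(x, 0) + 1
            deg_out[y] = deg_out.get(y, 0) + 1
        assert sorted(deg_out.values(), reverse=True)[0] == 3

    def test_seed_determinism(self):
        a = randomize_degree_preserving(self.EDGES, self.UNIVERSE, 5)
        b = randomize_degree_preserving(self.EDGES, self.UNIVERSE, 5)
        assert a == b

    def test_universe_must_cover_network(self, rng):
        with pytest.raises(ValueError):
            randomize_degree_preserving(self.EDGES, ["a", "b"], rng)


class TestDensitySignificance:
    def test_observed_above_all(self):
        assert density_significance(1.0, np.zeros(1000)) == pytest.approx(1 / 1001)

    def test_observed_at_median(self, rng):
        rand = rng.uniform(0, 1, 999)
        p = density_significance(float(np.median(rand)), rand)
        assert 0.4 < p < 0.6

    def test_p_uniform_under_null(self, rng):
        # permutation p of a null statistic is ~uniform over repeats
        ps = []
        for _ in range(200):
            obs = rng.uniform()
            ps.append(density_significance(obs, rng.uniform(size=199)))
        assert 0.4 < np.mean(ps) < 0.6
        assert min(ps) >= 1 / 200

    def test_requires_enough_randomizations(self):
        with pytest.raises(ValueError):
            density_significance(0.5, [0.1] * 50)


class TestDensityVariability:
    def test_constant_densities_zero_cv(self):
        df = pd.DataFrame(
            {"E1": [0.2, 0.5], "E2": [0.2, 0.5]},
            index=pd.MultiIndex.from_tuples([("A", "B"), ("A", "C")]),
        )
        cv, mean_cv = density_variability(df)
        assert np.allclose(cv, 0.0)

    def test_two_environment_arithmetic(self):
        df = pd.DataFrame(
            {"E1": [0.1], "E2": [0.3]},
            index=pd.MultiIndex.from_tuples([("A", "B")]),
        )
        cv, mean_cv = density_variability(df)
        assert cv.iloc[0] == pytest.approx(np.std([0.1, 0.3], ddof=1) / 0.2)
        assert mean_cv["A"] == pytest.approx(cv.iloc[0])

    def test_per_term_mean(self):
        df = pd.DataFrame(
            {"E1": [0.1, 0.4], "E2": [0.3, 0.2]},
            index=pd.MultiIndex.from_tuples([("A", "B"), ("A", "C")]),
        )
        cv, mean_cv = density_variability(df)
        assert mean_cv["A"] == pytest.approx(cv.mean())


class TestCommunities:
    @staticmethod
    def _clique(nodes):
        from itertools import combinations

        return list(combinations(nodes, 2))

    @pytest.mark.parametrize("method", ["fast_greedy", "walktrap", "infomap"])
    def test_two_cliques_one_bridge(self, method):
        c1 = [f"a{i}" for i in range(5)]
        c2 = [f"b{i}" for i in range(5)]
        edges = self._clique(c1) + self._clique(c2) + [("a0", "b0")]
        labels, summary = detect_communities(edges, method=method, seed=1)
        assert len(set(labels[c1])) == 1
        assert len(set(labels[c2])) == 1
        assert labels["a0"] != labels["b0"]

    @pytest.mark.parametrize("method", ["fast_greedy", "walktrap", "infomap"])
    def test_disjoint_cliques_separate(self, method):
        edges = []
        for k in range(3):
            edges += self._clique([f"c{k}_{i}" for i in range(4)])
        labels, _ = detect_communities(edges, method=method, seed=0)
        assert labels.nunique() == 3

    def test_complete_graph_single_community(self):
        labels, summary = detect_communities(self._clique(list("abcdef")), method="infomap", seed=0)
        assert labels.nunique() == 1
        assert summary["ppis_within"].sum() == 15

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            detect_communities([], method="infomap")


class TestBinnedBootstrap:
    def test_self_correlation_is_one(self, rng):
        scores = pd.Series(rng.uniform(0, 2, 100), index=[f"p{i}" for i in range(100)])
        degrees = pd.Series(rng.integers(1, 30, 100), index=scores.index)
        out = binned_bootstrap_association(scores, scores, degrees, n_boot=50, seed=1)
        assert np.allclose(out["spearman"].dropna(), 1.0)

    def test_independent_feature_near_zero(self, rng):
        n = 500
        idx = [f"p{i}" for i in range(n)]
        scores = pd.Series(rng.uniform(0, 2, n), index=idx)
        feature = pd.Series(rng.permutation(scores.to_numpy()), index=idx)
        degrees = pd.Series(rng.integers(1, 40, n), index=idx)
        out = binned_bootstrap_association(scores, feature, degrees, n_boot=50, seed=2)
        assert (out["spearman"].abs().dropna() < 0.15).all()

    def test_bootstrap_sd_positive_and_small_for_strong_signal(self, rng):
        n = 300
        idx = [f"p{i}" for i in range(n)]
        scores = pd.Series(rng.uniform(0, 2, n), index=idx)
        feature = scores + rng.normal(0, 0.01, n)
        degrees = pd.Series(rng.integers(1, 40, n), index=idx)
        out = binned_bootstrap_association(scores, feature, degrees, n_boot=100, seed=3)
        assert (out["bootstrap_sd"].dropna() < 0.05).all()
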