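import networkx as nx
import numpy as np
import pandas as pd
import pytest

import snpsom
from snpsom.genotype_io import SampleGroups
from snpsom.sample_topology import PairwiseCorrelationMap
from snpsom.som import SOMModel

from oracles import silhouette_oracle


def model_from_columns(cols, sample_ids=None):
    code = np.column_stack(cols).astype(float)
    m = code.shape[0]
    side = int(np.sqrt(m))
    assert side * side == m
    return SOMModel(
        width=side, height=side, codebook=code,
        assignment=np.zeros(1, dtype=int), snp_ids=["snp0"],
        sample_ids=sample_ids or [f"s{j}" for j in range(code.shape[1])],
    )


def pcm_from_matrix(corr, labels):
    ids = [f"s{i}" for i in range(len(labels))]
    groups = SampleGroups(assignment=pd.Series(labels, index=ids))
    return PairwiseCorrelationMap(values=corr, sample_ids=ids, groups=groups)


class TestPCM:
    def test_duplicate_samples_fully_correlated(self):
        v = np.array([1.0, -2.0, 0.5, 3.0])
        model = model_from_columns([v, v])
        groups = SampleGroups(assignment=pd.Series({"s0": "g", "s1": "g"}))
        pcm = snpsom.pairwise_correlation_map(model, groups)
        assert pcm.values[0, 1] == pytest.approx(1.0)

    def test_negated_portraits_anticorrelated(self):
        v = np.array([1.0, -2.0, 0.5, 3.0])
        model = model_from_columns([v, -v])
        groups = SampleGroups(assignment=pd.Series({"s0": "g", "s1": "h"}))
        pcm = snpsom.pairwise_correlation_map(model, groups)
        assert pcm.values[0, 1] == pytest.approx(-1.0)

    def test_within_block_exceeds_between_block(self, small_model, small_sim):
        _, truth = small_sim
        groups = SampleGroups.from_q(truth.q)
        pcm = snpsom.pairwise_correlation_map(small_model, groups)
        labels = np.asarray([pcm.group_of(s) for s in pcm.sample_ids])
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(len(labels), dtype=bool)
        within = pcm.values[same & off_diag].mean()
        between = pcm.values[~same].mean()
        assert within > between

    def test_invariant_under_unit_permutation(self, small_model, small_sim):
        _, truth = small_sim
        groups = SampleGroups.from_q(truth.q)
        base = snpsom.pairwise_correlation_map(small_model, groups)
        rng = np.random.default_rng(0)
        perm = rng.permutation(small_model.n_units)
        permuted = SOMModel(
            width=small_model.width, height=small_model.height,
            codebook=small_model.codebook[perm],
            assignment=small_model.assignment,
            snp_ids=small_model.snp_ids, sample_ids=small_model.sample_ids,
        )
        other = snpsom.pairwise_correlation_map(permuted, groups)
        assert np.allclose(base.values, other.values)

    def test_needs_two_samples(self):
        model = model_from_columns([np.ones(4)])
        groups = SampleGroups(assignment=pd.Series({"s0": "g"}))
        with pytest.raises(ValueError, match="2 samples"):
            snpsom.pairwise_correlation_map(model, groups)


class TestSilhouette:
    def _random_pcm(self, seed, n=20, k=3):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(n, 5))
        corr = np.corrcoef(base)
        labels = [f"g{i % k}" for i in range(n)]
        return pcm_from_matrix(corr, labels), labels

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        pcm, labels = self._random_pcm(seed)
        rep = snpsom.silhouette(pcm)
        expect = silhouette_oracle(1.0 - pcm.values, labels)
        got = dict(zip(rep.table["sample"], rep.table["silhouette"]))
        for sid, want in zip(pcm.sample_ids, expect):
            assert got[sid] == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_sklearn(self, seed):
        from sklearn.metrics import silhouette_samples

        pcm, labels = self._random_pcm(seed)
        rep = snpsom.silhouette(pcm)
        d = 1.0 - pcm.values
        np.fill_diagonal(d, 0.0)
        expect = silhouette_samples(d, labels, metric="precomputed")
        got = dict(zip(rep.table["sample"], rep.table["silhouette"]))
        for sid, want in zip(pcm.sample_ids, expect):
            assert got[sid] == pytest.approx(want, abs=1e-9)

    def test_equidistant_sample_scores_zero(self):
        # sample 0 sits exactly between two tight clusters
        corr = np.eye(5)
        pairs = {
            (0, 1): 0.5, (0, 2): 0.5, (0, 3): 0.5, (0, 4): 0.5,
            (1, 2): 0.9, (3, 4): 0.9, (1, 3): 0.1, (1, 4): 0.1,
            (2, 3): 0.1, (2, 4): 0.1,
        }
        for (i, j), r in pairs.items():
            corr[i, j] = corr[j, i] = r
        pcm = pcm_from_matrix(corr, ["left", "left", "left", "right", "right"])
        rep = snpsom.silhouette(pcm)
        got = dict(zip(rep.table["sample"], rep.table["silhouette"]))
        assert got["s0"] == pytest.approx(0.0, abs=1e-12)

    def test_nearest_group_never_own(self):
        pcm, _ = self._random_pcm(9)
        rep = snpsom.silhouette(pcm)
        assert (rep.table["nearest_group"] != rep.table["group"]).all()

    def test_singleton_group_scores_zero(self):
        corr = np.eye(3)
        pcm = pcm_from_matrix(corr, ["a", "a", "b"])
        rep = snpsom.silhouette(pcm)
        got = dict(zip(rep.table["sample"], rep.table["silhouette"]))
        assert got["s2"] == 0.0

    def test_single_group_rejected(self):
        pcm = pcm_from_matrix(np.eye(3), ["a", "a", "a"])
        with pytest.raises(ValueError, match="2 groups"):
            snpsom.silhouette(pcm)


class TestSimilarityNetwork:
    def test_two_blocks_disconnect(self):
        corr = np.full((4, 4), -0.2)
        corr[:2, :2] = 0.9
        corr[2:, 2:] = 0.9
        np.fill_diagonal(corr, 1.0)
        pcm = pcm_from_matrix(corr, ["a", "a", "b", "b"])
        coords, edges = snpsom.similarity_network(pcm, seed=1)
        graph = nx.Graph()
        graph.add_nodes_from(pcm.sample_ids)
        graph.add_edges_from(edges[["sample_a", "sample_b"]].itertuples(index=False))
        assert nx.number_connected_components(graph) == 2

    def test_same_seed_same_layout(self, small_model, small_sim):
        _, truth = small_sim
        groups = SampleGroups.from_q(truth.q)
        pcm = snpsom.pairwise_correlation_map(small_model, groups)
        c1, e1 = snpsom.similarity_network(pcm, seed=3)
        c2, e2 = snpsom.similarity_network(pcm, seed=3)
        assert c1 == c2
        assert e1.equals(e2)

    def test_bridging_group_connects_both_parents(self):
        """A group mixing two cluster profiles gains edges into both blocks."""
        rng = np.random.default_rng(2)
        a = rng.normal(size=25)
        b = rng.normal(size=25)
        cols, labels = [], []
        for i in range(4):
            cols.append(a + rng.normal(scale=0.2, size=25))
            labels.append("A")
        for i in range(4):
            cols.append(b + rng.normal(scale=0.2, size=25))
            labels.append("B")
        for i in range(3):
            cols.append(0.5 * a + 0.5 * b + rng.normal(scale=0.2, size=25))
            labels.append("mix")
        model = model_from_columns(cols)
        groups = SampleGroups(
            assignment=pd.Series(labels, index=[f"s{j}" for j in range(11)])
        )
        pcm = snpsom.pairwise_correlation_map(model, groups)
        _, edges = snpsom.similarity_network(pcm, seed=0, threshold=0.4)
        lab = dict(zip(pcm.sample_ids, [pcm.group_of(s) for s in pcm.sample_ids]))
        partners = {("mix", "A"): 0, ("mix", "B"): 0}
        for _, row in edges.iterrows():
            pair = tuple(sorted((lab[row["sample_a"]], lab[row["sample_b"]])))
            for key in list(partners):
                if tuple(sorted(key)) == pair:
                    partners[key] += 1
        assert partners[("mix", "A")] > 0 and partners[("mix", "B")] > 0
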