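"""Normalization, filters, network construction, clustering, monotonicity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from titrseq.dose_response import (
    ClusteringConfig,
    DoseProfileMatrix,
    ResponseCluster,
    classify_monotonic,
    cluster_profiles,
    compute_nmd_inclusion,
    filter_features,
    monotone_feature_sets,
    overlap_conditions,
    signed_adjacency,
    tom_similarity,
    upper_quartile_normalize,
)
from titrseq.io_formats import ExpressionTable, TranscriptAnnotation
from titrseq.synthetic_data import SimulationConfig, gen_expression


def _table(values, doses=None, ids=None, kind="gene", gene_ids=None):
    values = np.asarray(values, dtype=float)
    doses = doses or tuple(float(i) for i in range(values.shape[1]))
    ids = ids or [f"f{i}" for i in range(values.shape[0])]
    cols = ["DMSO" if d == 0 else f"{d:g}uM" for d in doses]
    gene_series = pd.Series(gene_ids, index=ids) if gene_ids else None
    return ExpressionTable(
        data=pd.DataFrame(values, index=ids, columns=cols),
        dose_values=tuple(doses),
        feature_kind=kind,
        gene_ids=gene_series,
    )


def _matrix(values, kind="fpkm"):
    t = _table(values)
    return DoseProfileMatrix(data=t.data, dose_values=t.dose_values, value_kind=kind)


class TestUpperQuartile:
    def test_proportional_columns_equalize(self):
        # cols B = 2A, C = 0.5A: UQs (4, 8, 2), geometric-mean ref 4,
        # scale factors (1, 0.5, 2) → all columns equal column A
        M = [[1, 2, 0.5], [2, 4, 1], [3, 6, 1.5], [4, 8, 2], [5, 10, 2.5]]
        out = upper_quartile_normalize(_table(M)).data.to_numpy()
        expected = np.array([[1, 1, 1], [2, 2, 2], [3, 3, 3], [4, 4, 4], [5, 5, 5]], float)
        np.testing.assert_allclose(out, expected)

    def test_identical_columns_unchanged(self):
        M = np.tile([[1.0], [2.0], [7.0]], (1, 4))
        out = upper_quartile_normalize(_table(M)).data.to_numpy()
        np.testing.assert_allclose(out, M)

    def test_zeros_preserved_and_all_zero_column_rejected(self):
        M = [[0, 1, 2], [4, 5, 6], [8, 9, 10]]
        out = upper_quartile_normalize(_table(M)).data.to_numpy()
        assert out[0, 0] == 0.0
        with pytest.raises(ValueError, match="all zeros"):
            upper_quartile_normalize(_table([[0, 1, 2], [0, 5, 6]]))

    def test_scale_invariance_of_downstream_monotone_set(self):
        cfg = SimulationConfig(seed=21, n_features=120, noise_sd=0.05)
        table, _ = gen_expression(cfg)
        scaled = _table(table.data.to_numpy() * np.array([1.0, 3.0, 0.5, 2.0, 1.7]),
                        doses=table.dose_values, ids=list(table.feature_ids))

        def monotone_set(t):
            m = filter_features(DoseProfileMatrix.from_expression(upper_quartile_normalize(t)))
            clusters = cluster_profiles(m, ClusteringConfig(min_module_size=10))
            sets = monotone_feature_sets(clusters)
            return sets["increasing"], sets["decreasing"]

        assert monotone_set(table) == monotone_set(scaled)


class TestFilters:
    @pytest.mark.parametrize(
        "profile,kept",
        [
            ((0.5, 0.6, 0.7, 0.8, 0.9), False),  # mean 0.7 < 1
            ((2, 2, 2, 2, 2), False),            # max/min = 1 < 1.5
            ((2, 2.5, 3, 3.5, 4), True),         # mean 3, ratio 2
            ((0, 0, 0, 9, 9), False),            # median 0
            ((1, 1, 1, 1, 1.5), True),           # ratio exactly 1.5, mean ≥ 1
        ],
    )
    def test_abundance_filter_contract(self, profile, kept):
        m = _matrix([list(profile)])
        out = filter_features(m)
        assert (len(out.data) == 1) is kept

    def test_nmd_inclusion_ratio_and_filters(self):
        genes = _table([[12, 12, 12], [10, 10, 10], [5, 5, 5]], ids=["gA", "gB", "gC"])
        iso = _table(
            [[3, 3, 3], [0.4, 0.4, 0.4], [1, 1, 1]],
            ids=["tA", "tB", "tC"],
            kind="isoform",
            gene_ids=["gA", "gB", "gC"],
        )
        annot = TranscriptAnnotation(
            gene_of={"tA": "gA", "tB": "gB", "tC": "gC"},
            is_nmd={"tA": True, "tB": True, "tC": True},
        )
        out = compute_nmd_inclusion(iso, genes, annot)
        # tA: 3/12 = 0.25 kept; tB: 0.04 mean ≤ 0.05 filtered; tC: 0.2 kept
        assert set(out.data.index) == {"tA", "tC"}
        np.testing.assert_allclose(out.data.loc["tA"], 0.25)

    def test_gene_zero_fpkm_drops_isoform(self, caplog):
        genes = _table([[10, 0, 10]], ids=["gA"])
        iso = _table([[1, 1, 1]], ids=["tA"], kind="isoform", gene_ids=["gA"])
        annot = TranscriptAnnotation(gene_of={"tA": "gA"}, is_nmd={"tA": True})
        with caplog.at_level("INFO"):
            out = compute_nmd_inclusion(iso, genes, annot)
        assert len(out.data) == 0
        assert "tA" in caplog.text

    def test_orphan_isoform_errors_by_name(self):
        genes = _table([[10, 10, 10]], ids=["gA"])
        iso = _table([[1, 1, 1]], ids=["tX"], kind="isoform", gene_ids=["gMissing"])
        annot = TranscriptAnnotation(gene_of={"tX": "gMissing"}, is_nmd={"tX": True})
        with pytest.raises(ValueError, match="tX"):
            compute_nmd_inclusion(iso, genes, annot)


class TestNetwork:
    def test_adjacency_closed_forms(self):
        # perfectly correlated, anticorrelated, and uncorrelated profiles
        m = _matrix([[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]])
        a = signed_adjacency(m, 6)
        assert a.loc["f0", "f1"] == pytest.approx(1.0)
        assert a.loc["f0", "f2"] == pytest.approx(0.0, abs=1e-12)
        m2 = _matrix([[1, 2, 1, 2], [1, 1, 2, 2]])
        a2 = signed_adjacency(m2, 6)
        assert a2.loc["f0", "f1"] == pytest.approx(2 ** -6)

    def test_adjacency_bounds_symmetry_diagonal(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.uniform(1, 10, size=(12, 5)))
        a = signed_adjacency(m, 10).to_numpy()
        assert np.allclose(a, a.T)
        assert np.allclose(np.diag(a), 1.0)
        assert a.min() >= 0 and a.max() <= 1

    def test_tom_two_feature_closed_form(self):
        m = _matrix([[1, 2, 3, 5], [1, 2, 4, 5]])
        a = signed_adjacency(m, 6)
        tom = tom_similarity(a)
        assert tom.iloc[0, 1] == pytest.approx(a.iloc[0, 1], abs=1e-12)

    def test_tom_all_ones(self):
        a = pd.DataFrame(np.ones((4, 4)))
        assert np.allclose(tom_similarity(a).to_numpy(), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_tom_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 9)
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        # independent brute-force oracle
        expected = np.ones((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                ki = sum(a[i, u] for u in range(n) if u != i)
                kj = sum(a[j, u] for u in range(n) if u != j)
                expected[i, j] = (shared + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
        np.testing.assert_allclose(tom, expected, atol=1e-12)


class TestClustering:
    def test_two_planted_blocks_recovered_exactly(self):
        up = [1, 2, 3, 4, 5]
        down = [5, 4, 3, 2, 1]
        values = [up] * 8 + [down] * 8
        m = _matrix(np.array(values) * np.arange(1, 17)[:, None])  # varied scales
        clusters = cluster_profiles(m, ClusteringConfig(min_module_size=5))
        real = [c for c in clusters if c.cluster_id != "unassigned"]
        assert len(real) == 2
        sizes = sorted(len(c.members) for c in real)
        assert sizes == [8, 8]
        labels = sorted(c.monotonic_label for c in real)
        assert labels == ["decreasing", "increasing"]

    def test_all_identical_profiles_pooled_deterministically(self):
        m = _matrix([[2, 2, 2, 2]] * 6)
        clusters = cluster_profiles(m, ClusteringConfig(min_module_size=3))
        # zero-variance features are dropped by the correlation guard
        assert len(clusters) == 1
        assert clusters[0].monotonic_label == "none"

    def test_synthetic_recovery_rand_index(self):
        from sklearn.metrics import rand_score

        cfg = SimulationConfig(seed=1, n_features=200, noise_sd=0.1)
        table, truth = gen_expression(cfg)
        m = filter_features(DoseProfileMatrix.from_expression(upper_quartile_normalize(table)))
        clusters = cluster_profiles(m, ClusteringConfig(min_module_size=10))
        assign = {f: c.cluster_id for c in clusters for f in c.members}
        # features removed by the abundance filter form their own pool
        pred = [assign.get(f, "unassigned") for f in truth.labels]
        true = [truth.labels[f] for f in truth.labels]
        assert rand_score(true, pred) >= 0.9


class TestMonotonic:
    @pytest.mark.parametrize(
        "profile,label",
        [
            ((0.1, 0.2, 0.4, 0.6, 0.9), "increasing"),
            ((0.5, 0.5, 0.5, 0.5, 0.5), "none"),
            ((0.9, 0.6, 0.4, 0.2, 0.1), "decreasing"),
            ((0.1, 0.5, 0.3, 0.7, 0.9), "none"),  # big dip breaks the step rule
        ],
    )
    def test_consensus_labels(self, profile, label):
        c = ResponseCluster("c", ("x",), np.array(profile))
        assert classify_monotonic(c) == label

    def test_small_dip_within_tolerance_still_monotone(self):
        # dip of 0.02 against range 0.8 is within 0.05 × range
        c = ResponseCluster("c", ("x",), np.array([0.1, 0.4, 0.38, 0.6, 0.8, 0.9]))
        assert classify_monotonic(c) == "increasing"


class TestOverlap:
    def test_two_set_enumeration(self):
        summary = overlap_conditions({"c1": {"a", "b"}, "c2": {"b", "c"}})
        counts = {tuple(sorted(k)): v for k, v in summary.counts().items()}
        assert counts == {("c1",): 1, ("c2",): 1, ("c1", "c2"): 1}
        assert summary.shared_fraction == pytest.approx(1 / 3)

    def test_identical_sets_single_bin(self):
        s = {"x", "y", "z"}
        summary = overlap_conditions({"a": set(s), "b": set(s)})
        assert summary.counts() == {frozenset({"a", "b"}): 3}
        assert summary.shared_fraction == 1.0

    @given(st.integers(0, 2 ** 20))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_bins_partition_union(self, seed):
        rng = np.random.default_rng(seed)
        sets = {
            f"c{i}": set(rng.choice(100, size=rng.integers(1, 60), replace=False).tolist())
            for i in range(4)
        }
        summary = overlap_conditions(sets)
        assert sum(summary.counts().values()) == summary.union_size
        # exclusive bins are disjoint
        all_ids = list(itertools.chain.from_iterable(summary.exclusive.values()))
        assert len(all_ids) == len(set(all_ids))
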