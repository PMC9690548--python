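import logging

import numpy as np
import pandas as pd
import pytest

from culicinet.io_formats import CountTable, SampleMetadata
from culicinet.network_inference import (
    CorrelationResult,
    network_summary,
    per_species_networks,
    spearman_matrix,
    threshold_edges,
)
from culicinet.io_formats import InteractionNetwork
from oracles import spearman_exact_p, spearman_rho


def _pct(columns):
    df = pd.DataFrame(columns)
    df.index = [f"s{i}" for i in range(len(df))]
    return CountTable(df)


class TestSpearman:
    def test_perfect_monotone_is_one(self):
        table = _pct({"x": [1, 2, 3, 4, 5, 6], "y": [2, 4, 6, 8, 10, 12]})
        res = spearman_matrix(table)
        row = res.pairs.iloc[0]
        assert row.rho == pytest.approx(1.0)
        assert row.p == pytest.approx(2 / 720)  # both extreme orderings

    def test_reversed_is_minus_one(self):
        table = _pct({"x": [1, 2, 3, 4, 5, 6], "y": [12, 10, 8, 6, 4, 2]})
        assert spearman_matrix(table).pairs.iloc[0].rho == pytest.approx(-1.0)

    def test_tied_data_matches_exhaustive_oracle(self):
        x = [1.0, 1.0, 2.0, 3.0, 3.0, 4.0]
        y = [5.0, 2.0, 2.0, 7.0, 1.0, 7.0]
        res = spearman_matrix(_pct({"x": x, "y": y}))
        row = res.pairs.iloc[0]
        assert row.rho == pytest.approx(spearman_rho(x, y), abs=1e-12)
        assert row.p == pytest.approx(spearman_exact_p(x, y), abs=1e-12)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(77)
        for n in (4, 5, 6):
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.random(n)
            x[0] += 0.5  # avoid constant column
            res = spearman_matrix(_pct({"x": list(x), "y": list(y)}))
            row = res.pairs.iloc[0]
            assert row.rho == pytest.approx(spearman_rho(x, y), abs=1e-12)
            assert row.p == pytest.approx(spearman_exact_p(x, y), abs=1e-12)

    def test_exact_and_t_approximation_agree_at_boundary(self):
        # sanity coupling of the two p-value paths at n = 8
        from culicinet.network_inference import _t_approx_p

        rng = np.random.default_rng(55)
        for _ in range(8):
            x = rng.random(8)
            y = 0.8 * x + 0.2 * rng.random(8)
            res = spearman_matrix(_pct({"x": list(x), "y": list(y)}))
            row = res.pairs.iloc[0]
            assert abs(row.p - _t_approx_p(row.rho, 8)) < 0.02

    def test_constant_taxon_excluded_with_nan_marker(self):
        table = _pct({"x": [1, 2, 3, 4, 5], "c": [7, 7, 7, 7, 7],
                      "y": [5, 3, 1, 2, 4]})
        res = spearman_matrix(table)
        assert res.constant_taxa == ["c"]
        nan_rows = res.pairs[res.pairs.rho.isna()]
        assert set(map(tuple, nan_rows[["taxon_a", "taxon_b"]].to_numpy())) == {
            ("x", "c"), ("c", "y")
        }
        net = threshold_edges(res, r_min=0.0, p_max=1.01)
        assert "c" not in net.nodes

    def test_min_nonzero_skips_sparse_taxa(self):
        table = _pct({"x": [1, 2, 3, 4, 5], "sparse": [0, 0, 0, 0, 9],
                      "y": [5, 3, 1, 2, 4]})
        res = spearman_matrix(table, min_nonzero=3)
        assert res.skipped_taxa == ["sparse"]
        assert "sparse" not in res.taxa

    def test_fewer_than_four_samples_is_error(self):
        with pytest.raises(ValueError, match="4 samples"):
            spearman_matrix(_pct({"x": [1, 2, 3], "y": [3, 2, 1]}))


class TestThreshold:
    def _corr(self, rows):
        pairs = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p", "n"])
        taxa = sorted(set(pairs.taxon_a) | set(pairs.taxon_b))
        return CorrelationResult(pairs=pairs, taxa=taxa, n_samples=10)

    def test_strong_positive_kept(self):
        net = threshold_edges(self._corr([("a", "b", 0.8, 0.01, 10)]))
        assert net.edges()[0][:2] == ("a", "b")
        assert net.edges()[0][4] == "positive"

    def test_strong_negative_kept_under_abs(self):
        net = threshold_edges(self._corr([("a", "b", -0.9, 0.001, 10)]))
        assert net.edges()[0][4] == "negative"

    def test_literal_positive_only_reading(self):
        corr = self._corr([("a", "b", -0.9, 0.001, 10),
                           ("c", "d", 0.9, 0.001, 10)])
        net = threshold_edges(corr, use_abs=False)
        assert [e[:2] for e in net.edges()] == [("c", "d")]

    def test_boundaries_are_strict(self):
        corr = self._corr([
            ("a", "b", 0.75, 0.01, 10),   # rho exactly at threshold: discarded
            ("c", "d", 0.90, 0.05, 10),   # p exactly at threshold: discarded
            ("e", "f", 0.76, 0.049, 10),  # both strictly inside: kept
        ])
        net = threshold_edges(corr)
        assert [e[:2] for e in net.edges()] == [("e", "f")]

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(9)
        rows = [(f"a{i}", f"b{i}", float(rng.uniform(-1, 1)),
                 float(rng.uniform(0, 0.2)), 10) for i in range(50)]
        corr = self._corr(rows)
        base = set(tuple(e[:2]) for e in threshold_edges(corr).edges())
        stricter_r = set(tuple(e[:2]) for e in
                         threshold_edges(corr, r_min=0.85).edges())
        stricter_p = set(tuple(e[:2]) for e in
                         threshold_edges(corr, p_max=0.01).edges())
        assert stricter_r <= base and stricter_p <= base

    def test_bh_adjustment_never_adds_edges(self):
        rng = np.random.default_rng(10)
        rows = [(f"a{i}", f"b{i}", float(rng.uniform(0.76, 1)),
                 float(rng.uniform(0, 0.05)), 10) for i in range(20)]
        corr = self._corr(rows)
        raw = set(tuple(e[:2]) for e in threshold_edges(corr).edges())
        bh = set(tuple(e[:2]) for e in
                 threshold_edges(corr, p_adjust="bh").edges())
        assert bh <= raw

    def test_isolated_taxa_reported_not_in_graph(self):
        corr = self._corr([("a", "b", 0.9, 0.001, 10),
                           ("c", "d", 0.1, 0.9, 10)])
        net = threshold_edges(corr)
        assert set(net.nodes) == {"a", "b"}
        assert set(net.isolated_taxa()) == {"c", "d"}


class TestSummary:
    def test_empty_network(self):
        summ = network_summary(InteractionNetwork.from_edges([]))
        assert summ.node_count == 0
        assert summ.positive_edges == summ.negative_edges == 0

    def test_signed_triangle(self):
        net = InteractionNetwork.from_edges([
            ("a", "b", 0.9, 0.01), ("b", "c", 0.8, 0.01), ("a", "c", -0.8, 0.01),
        ])
        summ = network_summary(net)
        assert (summ.positive_edges, summ.negative_edges) == (2, 1)
        assert (summ.per_node["degree"] == 2).all()
        assert summ.per_node["degree"].sum() == 2 * summ.edge_count

    def test_all_negative_interactions_node(self):
        net = InteractionNetwork.from_edges([
            ("Asaia", "x", -0.8, 0.01), ("Asaia", "y", -0.9, 0.01),
        ])
        summ = network_summary(net)
        assert summ.per_node.loc["Asaia", "positive_degree"] == 0
        assert summ.per_node.loc["Asaia", "negative_degree"] == 2


class TestMonotoneInvariance:
    def test_edges_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(12)
        data = {f"t{j}": list(rng.random(12) * 10) for j in range(6)}
        table = _pct(data)
        base = threshold_edges(spearman_matrix(table), r_min=0.3, p_max=0.2)
        warped = table.data.copy()
        warped["t2"] = warped["t2"] ** 3          # strictly monotone
        warped["t4"] = np.sqrt(warped["t4"])      # strictly monotone
        other = threshold_edges(
            spearman_matrix(CountTable(warped)), r_min=0.3, p_max=0.2
        )
        assert base.edges() == other.edges()


class TestPerSpecies:
    def test_small_species_skipped_with_warning(self, small_bundle, caplog):
        table, taxonomy, metadata, *_ = small_bundle
        species = dict(metadata.species)
        tiny = list(species)[:3]
        for s in tiny:
            species[s] = "spTiny"
        meta = SampleMetadata(species)
        with caplog.at_level(logging.WARNING):
            nets = per_species_networks(table, taxonomy, meta)
        assert "spTiny" not in nets
        assert any("spTiny" in r.message for r in caplog.records)
        assert len(nets) >= 1

    def test_planted_positive_pair_recovered(self, small_bundle):
        table, taxonomy, metadata, tree, truth = small_bundle
        nets = per_species_networks(table, taxonomy, metadata)
        net, summ = nets["spC"]  # the n=30 group
        edge_pairs = {frozenset(e[:2]): e[4] for e in net.edges()}
        strongest = truth.edges[0]  # planted rho = +0.95
        key = frozenset((strongest[0], strongest[1]))
        assert key in edge_pairs and edge_pairs[key] == "positive"
        assert summ.positive_edges >= 1

    def test_rejects_relative_input(self, small_bundle):
        from culicinet.abundance_filtering import relative_abundance

        table, taxonomy, metadata, *_ = small_bundle
        with pytest.raises(ValueError, match="raw"):
            per_species_networks(relative_abundance(table), taxonomy, metadata)
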