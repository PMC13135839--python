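import numpy as np
import pandas as pd
import pytest

from dconet.containers import (
    NORMALIZED,
    ExpressionMatrix,
    PcitNetwork,
    SampleDesign,
    ValidationError,
    edge_frame,
)
from dconet.regnet import dk_connectivity, rewiring_summary, rif_scores



def _norm_matrix(rng, features, design):
    data = rng.normal(5.0, 1.0, size=(len(features), len(design.sample_ids)))
    return ExpressionMatrix(
        pd.DataFrame(data, index=features, columns=design.sample_ids),
        NORMALIZED)


def _net(records, group="fertile"):
    return PcitNetwork(group, "gene", edge_frame(records))


class TestRif:
    def test_identical_groups_zero_rif1(self, design_2x6):
        rng = np.random.default_rng(0)
        features = [f"tf{i}" for i in range(4)] + [f"de{i}" for i in range(6)]
        half = _norm_matrix(rng, features, design_2x6).data.iloc[:, :6]
        # mirror fertile values into subfertile: r1 == r2, e1 == e2
        data = pd.concat([half, half.set_axis(design_2x6.sample_ids[6:],
                                              axis=1)], axis=1)
        m = ExpressionMatrix(data, NORMALIZED)
        table = rif_scores(m, design_2x6, [f"tf{i}" for i in range(4)],
                           [f"de{i}" for i in range(6)])
        np.testing.assert_allclose(table["rif1_raw"], 0.0, atol=1e-12)

    def test_z_columns_standardized(self, design_2x6):
        rng = np.random.default_rng(1)
        features = [f"tf{i}" for i in range(8)] + [f"de{i}" for i in range(5)]
        m = _norm_matrix(rng, features, design_2x6)
        table = rif_scores(m, design_2x6, [f"tf{i}" for i in range(8)],
                           [f"de{i}" for i in range(5)])
        for col in ("rif1_z", "rif2_z"):
            assert abs(table[col].mean()) < 1e-9
            assert table[col].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_fewer_than_three_tfs_rejected(self, design_2x6):
        rng = np.random.default_rng(2)
        features = ["tf0", "tf1", "de0"]
        m = _norm_matrix(rng, features, design_2x6)
        with pytest.raises(ValidationError, match="3"):
            rif_scores(m, design_2x6, ["tf0", "tf1"], ["de0"])

    def test_no_targets_rejected(self, design_2x6):
        rng = np.random.default_rng(3)
        m = _norm_matrix(rng, ["tf0", "tf1", "tf2"], design_2x6)
        with pytest.raises(ValidationError, match="target"):
            rif_scores(m, design_2x6, ["tf0", "tf1", "tf2"], [])

    def test_label_swap_negates_raw_scores(self, design_2x6):
        rng = np.random.default_rng(4)
        features = [f"tf{i}" for i in range(6)] + [f"de{i}" for i in range(5)]
        m = _norm_matrix(rng, features, design_2x6)
        tfs = [f"tf{i}" for i in range(6)]
        des = [f"de{i}" for i in range(5)]
        fwd = rif_scores(m, design_2x6, tfs, des)
        swapped = SampleDesign(design_2x6.groups.map(
            {"fertile": "subfertile", "subfertile": "fertile"}))
        rev = rif_scores(m, swapped, tfs, des)
        np.testing.assert_allclose(fwd["rif1_raw"], -rev["rif1_raw"],
                                   atol=1e-12)
        np.testing.assert_allclose(fwd["rif2_raw"], -rev["rif2_raw"],
                                   atol=1e-12)
        # |z| ranking unchanged
        assert list(fwd["rif2_z"].abs().rank()) == \
            list(rev["rif2_z"].abs().rank())

    def test_planted_regulator_flagged(self, small_study):
        from dconet.diffexpr import (filter_by_expression,
                                     log2_normalized_counts, nb_wald_test,
                                     significant_ids, size_factors)
        filt = filter_by_expression(small_study.counts)
        sf = size_factors(filt)
        norm = log2_normalized_counts(filt, sf)
        degs = significant_ids(nb_wald_test(filt, small_study.design, sf))
        tfs = [t for t in small_study.tf_ids
               if t in set(norm.feature_ids)]
        table = rif_scores(norm, small_study.design, tfs,
                           [d for d in degs if d in set(norm.feature_ids)])
        row = table[table["tf_id"] == small_study.truth.regulator_id]
        assert bool(row["significant"].iloc[0])


class TestDk:
    def test_identical_networks_zero_dk(self):
        edges = [("a", "b", 0.96, "fertile", "gene"),
                 ("b", "c", 0.97, "fertile", "gene")]
        table = dk_connectivity(_net(edges), _net(edges, "subfertile"))
        np.testing.assert_allclose(table["dk"], 0.0)
        assert not table["significant"].any()

    def test_star_hub_is_most_extreme(self):
        hub_edges = [("hub", f"n{i}", 0.96, "fertile", "gene")
                     for i in range(10)]
        other = [(f"n{i}", f"n{i+1}", 0.95, "fertile", "gene")
                 for i in range(0, 8, 2)]
        net_f = _net(hub_edges + other)
        net_s = _net(other, "subfertile")
        table = dk_connectivity(net_f, net_s).set_index("feature_id")
        assert table.loc["hub", "k_fertile"] == 1.0
        assert table.loc["hub", "k_subfertile"] == 0.0
        assert table["dk_z"].abs().idxmax() == "hub"

    def test_dk_z_standardized(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(20)]
        recs = [(a, b, 0.95, "fertile", "gene")
                for a in nodes for b in nodes
                if a < b and rng.random() < 0.2]
        recs2 = [(a, b, 0.95, "subfertile", "gene")
                 for a in nodes for b in nodes
                 if a < b and rng.random() < 0.2]
        table = dk_connectivity(_net(recs), _net(recs2, "subfertile"))
        assert abs(table["dk_z"].mean()) < 1e-9
        assert table["dk_z"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_dk_matches_brute_force_from_edge_lists(self, small_study):
        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(15)]
        def rand_net(group, p):
            return _net([(a, b, 0.95, group, "gene")
                         for a in nodes for b in nodes
                         if a < b and rng.random() < p], group)
        net_f, net_s = rand_net("fertile", 0.3), rand_net("subfertile", 0.25)
        table = dk_connectivity(net_f, net_s).set_index("feature_id")

        # independent recomputation straight from the edge tuples
        def degrees(net):
            d = {}
            for a, b in zip(net.edges["feature_a"], net.edges["feature_b"]):
                d[a] = d.get(a, 0) + 1
                d[b] = d.get(b, 0) + 1
            return d
        df, ds = degrees(net_f), degrees(net_s)
        kmax_f, kmax_s = max(df.values()), max(ds.values())
        for node in set(df) | set(ds):
            expected = df.get(node, 0) / kmax_f - ds.get(node, 0) / kmax_s
            assert table.loc[node, "dk"] == pytest.approx(expected, abs=1e-12)

    def test_label_swap_negates_dk(self):
        edges_f = [("a", "b", 0.96, "fertile", "gene"),
                   ("a", "c", 0.97, "fertile", "gene")]
        edges_s = [("b", "c", 0.95, "subfertile", "gene")]
        fwd = dk_connectivity(_net(edges_f), _net(edges_s, "subfertile"))
        rev = dk_connectivity(_net(edges_s, "subfertile"), _net(edges_f))
        merged = fwd.merge(rev, on="feature_id", suffixes=("_f", "_r"))
        np.testing.assert_allclose(merged["dk_f"], -merged["dk_r"],
                                   atol=1e-12)


class TestRewiring:
    def test_disjoint_networks(self):
        a = _net([("a", "b", 0.96, "fertile", "gene")])
        b = _net([("c", "d", 0.95, "subfertile", "gene")], "subfertile")
        s = rewiring_summary(a, b)
        assert s["n_nodes_shared"] == 0 and s["n_edges_shared"] == 0

    def test_sign_flip_detected(self):
        a = _net([("a", "b", 0.96, "fertile", "gene")])
        b = _net([("a", "b", -0.97, "subfertile", "gene")], "subfertile")
        s = rewiring_summary(a, b)
        assert s["n_edges_shared"] == 1 and s["n_sign_flipped"] == 1
        assert s["sign_flipped_pairs"] == [["a", "b"]]

    def test_identical_networks_no_flips(self):
        edges = [("a", "b", 0.96, "fertile", "gene"),
                 ("b", "c", -0.97, "fertile", "gene")]
        s = rewiring_summary(_net(edges), _net(edges, "subfertile"))
        assert s["n_edges_shared"] == 2 and s["n_sign_flipped"] == 0

    def test_node_partition(self):
        a = _net([("a", "b", 0.96, "fertile", "gene"),
                  ("b", "c", 0.95, "fertile", "gene")])
        b = _net([("b", "c", 0.95, "subfertile", "gene"),
                  ("c", "d", 0.95, "subfertile", "gene")], "subfertile")
        s = rewiring_summary(a, b)
        assert s["n_nodes_only_a"] + s["n_nodes_shared"] == s["n_nodes_a"]
        assert s["n_nodes_only_b"] + s["n_nodes_shared"] == s["n_nodes_b"]
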