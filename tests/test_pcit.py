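import numpy as np
import pandas as pd
import pytest

from dconet.containers import NORMALIZED, ExpressionMatrix, ValidationError
from dconet.pcit import (
    build_group_network,
    drop_unusable_features,
    edge_significance,
    partial_correlation,
    pcit_select,
    pearson_matrix,
)



def brute_force_pcit(R):
    """Independent O(n^3) triple-loop reference for the trio rule."""
    n = R.shape[0]
    keep = np.ones((n, n), dtype=bool)
    np.fill_diagonal(keep, False)
    for x in range(n):
        for y in range(n):
            if x == y:
                continue
            for z in range(n):
                if z == x or z == y:
                    continue
                rxy, rxz, ryz = R[x, y], R[x, z], R[y, z]
                pxy = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
                pxz = (rxz - rxy * ryz) / np.sqrt((1 - rxy**2) * (1 - ryz**2))
                pyz = (ryz - rxy * rxz) / np.sqrt((1 - rxy**2) * (1 - rxz**2))
                t1 = abs(pxy) / abs(rxy) if rxy != 0 else 0.0
                t2 = abs(pxz) / abs(rxz) if rxz != 0 else 0.0
                t3 = abs(pyz) / abs(ryz) if ryz != 0 else 0.0
                eps = (t1 + t2 + t3) / 3.0
                if abs(rxy) <= eps * abs(rxz) and abs(rxy) <= eps * abs(ryz):
                    keep[x, y] = keep[y, x] = False
    return keep


def random_correlation(rng, n, m):
    return np.corrcoef(rng.normal(size=(n, m)))


class TestPearsonMatrix:
    def test_duplicate_feature_r_one_and_negation_minus_one(self, design_2x3):
        rng = np.random.default_rng(0)
        x = rng.integers(1, 100, size=6)
        m = ExpressionMatrix(
            pd.DataFrame([x, x, -x + 200], index=["a", "b", "c"],
                         columns=design_2x3.sample_ids).astype(float),
            NORMALIZED)
        R = pearson_matrix(m)
        assert R.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)
        assert R.loc["a", "c"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=6), rng.normal(size=6)
        m = ExpressionMatrix(
            pd.DataFrame([x, y], index=["a", "b"],
                         columns=[f"s{i}" for i in range(6)]), NORMALIZED)
        r = pearson_matrix(m).loc["a", "b"]
        expected = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean())**2)
                              * np.sum((y - y.mean())**2)))
        assert r == pytest.approx(expected, abs=1e-12)
        assert abs(r) < 1

    def test_zero_variance_feature_is_an_error(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                         index=["flat", "ok"], columns=["s1", "s2", "s3"]),
            NORMALIZED)
        with pytest.raises(ValidationError, match="flat"):
            pearson_matrix(m)


class TestPartialCorrelation:
    def test_conditioning_on_uncorrelated_variable_is_identity(self):
        assert partial_correlation(0.9, 0.0, 0.0) == pytest.approx(0.9)

    def test_exact_cancellation(self):
        assert partial_correlation(0.72, 0.8, 0.9) == pytest.approx(0.0)

    def test_closed_form_half(self):
        assert partial_correlation(0.5, 0.5, 0.5) == pytest.approx(1 / 3)

    def test_degenerate_conditioning_rejected(self):
        with pytest.raises(ValidationError):
            partial_correlation(0.5, 1.0, 0.5)


class TestPcitSelect:
    def test_two_features_single_edge_kept(self):
        R = np.array([[1.0, 0.4], [0.4, 1.0]])
        keep = pcit_select(R)
        assert keep[0, 1] and keep[1, 0]

    def test_indirect_edge_eliminated_in_planted_chain(self):
        # x-z and z-y strong (0.7); x-y weak (0.3 < product would
        # suggest an indirect path): trio rule removes x-y only.
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.7   # x-z
        R[1, 2] = R[2, 1] = 0.7   # z-y
        R[0, 2] = R[2, 0] = 0.3   # x-y
        keep = pcit_select(R)
        assert not keep[0, 2]
        assert keep[0, 1] and keep[1, 2]

    def test_oracle_equivalence_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 16))
            R = random_correlation(rng, n, int(rng.integers(4, 10)))
            np.testing.assert_array_equal(pcit_select(R), brute_force_pcit(R))

    def test_keep_matrix_symmetric_diagonal_false(self):
        rng = np.random.default_rng(7)
        R = random_correlation(rng, 12, 6)
        keep = pcit_select(R)
        assert (keep == keep.T).all()
        assert not keep.diagonal().any()


class TestEdgeSignificance:
    def test_zero_correlation_p_one(self):
        assert edge_significance(0.0, 6) == pytest.approx(1.0)

    def test_hand_value_r095_n6(self):
        # t = 0.95*sqrt(4/(1-0.9025)) = 6.0849 on 4 df
        assert edge_significance(0.95, 6) == pytest.approx(0.0036875, rel=1e-4)

    def test_perfect_correlation_p_zero(self):
        assert edge_significance(1.0, 6) == 0.0

    def test_monotone_in_abs_r(self):
        rs = np.linspace(0.0, 0.99, 25)
        ps = np.asarray(edge_significance(rs, 6))
        assert (np.diff(ps) < 0).all()


class TestBuildGroupNetwork:
    def _matrix(self, rng, n_features, design):
        data = rng.normal(size=(n_features, len(design.sample_ids)))
        return ExpressionMatrix(
            pd.DataFrame(data, index=[f"f{i}" for i in range(n_features)],
                         columns=design.sample_ids), NORMALIZED)

    def test_anchor_rule_and_threshold_filters(self, design_2x6):
        rng = np.random.default_rng(0)
        m = self._matrix(rng, 20, design_2x6)
        all_anchor = build_group_network(
            m, design_2x6, "fertile", anchors=set(m.feature_ids), r_min=0.5)
        some_anchor = build_group_network(
            m, design_2x6, "fertile", anchors={"f0"}, r_min=0.5)
        assert len(some_anchor.edges) <= len(all_anchor.edges)
        if not some_anchor.edges.empty:
            touches = ((some_anchor.edges["feature_a"] == "f0")
                       | (some_anchor.edges["feature_b"] == "f0"))
            assert touches.all()
        assert (all_anchor.edges["r"].abs() >= 0.5).all()

    def test_empty_anchor_set_empty_network(self, design_2x6):
        rng = np.random.default_rng(1)
        m = self._matrix(rng, 10, design_2x6)
        net = build_group_network(m, design_2x6, "fertile", anchors=set(),
                                  r_min=0.5)
        assert net.edges.empty

    def test_raising_r_min_never_adds_edges(self, design_2x6):
        rng = np.random.default_rng(2)
        m = self._matrix(rng, 25, design_2x6)
        anchors = set(m.feature_ids)
        loose = build_group_network(m, design_2x6, "fertile", anchors, 0.5)
        tight = build_group_network(m, design_2x6, "fertile", anchors, 0.8)
        assert tight.edge_keys() <= loose.edge_keys()

    def test_deterministic(self, design_2x6):
        rng = np.random.default_rng(3)
        m = self._matrix(rng, 15, design_2x6)
        a = build_group_network(m, design_2x6, "fertile",
                                set(m.feature_ids), 0.6)
        b = build_group_network(m, design_2x6, "fertile",
                                set(m.feature_ids), 0.6)
        pd.testing.assert_frame_equal(a.edges, b.edges)

    def test_planted_regulator_edges_group_specific(self, small_study):
        from dconet.diffexpr import (filter_by_expression,
                                     log2_normalized_counts, size_factors)
        truth = small_study.truth
        filt = filter_by_expression(small_study.counts)
        sf = size_factors(filt)
        norm = log2_normalized_counts(filt, sf)
        anchors = set(truth.de_lfc) & set(norm.feature_ids)
        present = [t for t in truth.regulator_targets
                   if t in set(norm.feature_ids)]
        hits = {}
        for group in ("fertile", "subfertile"):
            usable = drop_unusable_features(
                norm, small_study.design.samples_in(group))
            net = build_group_network(
                usable, small_study.design, group,
                anchors=anchors & set(usable.feature_ids), r_min=0.9)
            keys = net.edge_keys()
            hits[group] = sum(
                tuple(sorted((truth.regulator_id, t))) in keys
                for t in present)
        other = ({"fertile", "subfertile"} - {truth.coupled_group}).pop()
        assert hits[truth.coupled_group] >= 0.9 * len(present)
        assert hits[other] <= 0.2 * len(present)


class TestDropUnusable:
    def test_removes_missing_and_flat_features(self, design_2x3):
        data = pd.DataFrame(
            [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
             [np.nan, 2.0, 3.0, 1.0, 2.0, 3.0],
             [5.0, 5.0, 5.0, 5.0, 5.0, 5.0]],
            index=["ok", "gap", "flat"], columns=design_2x3.sample_ids)
        m = ExpressionMatrix(data, NORMALIZED)
        out = drop_unusable_features(m, design_2x3.sample_ids)
        assert out.feature_ids == ["ok"]
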