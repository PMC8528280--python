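"""Interaction-matrix inference, thresholding and network summaries."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oifnet as o
from oifnet.network import import_edge_list, InteractionMatrix


def _matrix(W, **kw):
    W = np.asarray(W, dtype=float)
    return InteractionMatrix(W=W, delays=np.zeros(W.shape, dtype=int), **kw)


class TestInferMatrix:
    def test_copy_system_has_one_dominant_entry(self, rng):
        x = rng.normal(size=2000)
        y = np.empty_like(x)
        y[0] = 0
        y[1:] = x[:-1]
        im = o.infer_matrix(np.vstack([x, y]))
        assert im.W[0, 1] > 0.5
        assert im.W[1, 0] < 0.05

    def test_independent_community_below_fixed_threshold(self, rng):
        X = rng.normal(size=(4, 10_000))
        im = o.infer_matrix(X)
        off = im.W[~np.eye(4, dtype=bool)]
        assert np.all(off < 0.01)

    def test_single_species_errors(self, rng):
        with pytest.raises(ValueError, match="2 species"):
            o.infer_matrix(rng.normal(size=(1, 100)))

    def test_short_subset_warns_but_estimates(self, rng):
        with pytest.warns(UserWarning, match="short"):
            im = o.infer_matrix(rng.normal(size=(3, 12)), u_max=2)
        assert im.W.shape == (3, 3)


class TestThreshold:
    def test_fixed_zeroes_below_threshold(self):
        W = np.full((3, 3), 0.005)
        np.fill_diagonal(W, 0.0)
        im = o.apply_threshold(_matrix(W), "fixed")
        assert np.all(im.W == 0)

    def test_pareto20_keeps_exactly_42_of_15sp(self, rng):
        n = 15
        W = rng.uniform(0.001, 1.0, size=(n, n))
        np.fill_diagonal(W, 0.0)
        im = o.apply_threshold(_matrix(W), "pareto20")
        assert int((im.W > 0).sum()) == 42  # ceil(0.2 * 210)

    def test_zero_threshold_is_identity(self, rng):
        W = rng.uniform(0, 1, size=(4, 4))
        np.fill_diagonal(W, 0.0)
        im = o.apply_threshold(_matrix(W), "fixed", value=0.0)
        np.testing.assert_array_equal(im.W, W)

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError, match="mode"):
            o.apply_threshold(_matrix(np.zeros((2, 2))), "magic")

    @given(thr1=st.floats(0, 0.5), thr2=st.floats(0.5, 1.0))
    def test_raising_threshold_never_grows_network(self, thr1, thr2):
        rng = np.random.default_rng(5)
        W = rng.uniform(0, 1, size=(8, 8))
        np.fill_diagonal(W, 0.0)
        lo = o.apply_threshold(_matrix(W), "fixed", value=thr1)
        hi = o.apply_threshold(_matrix(W), "fixed", value=thr2)
        assert (hi.W > 0).sum() <= (lo.W > 0).sum()
        assert hi.W.sum() <= lo.W.sum() + 1e-12
        assert o.effective_alpha(hi) <= o.effective_alpha(lo)


class TestEffectiveAlpha:
    @pytest.mark.parametrize("build,expected", [
        (lambda: np.zeros((4, 4)), 0),
        (lambda: _single_link(4), 2),
        (lambda: _complete(4), 4),
    ])
    def test_examples(self, build, expected):
        assert o.effective_alpha(build()) == expected

    def test_matches_isolated_node_oracle(self, rng):
        W = rng.uniform(0, 1, size=(10, 10)) * (rng.random((10, 10)) < 0.2)
        np.fill_diagonal(W, 0.0)
        ae = o.effective_alpha(W)
        isolated = sum(1 for i in range(10)
                       if W[i].sum() == 0 and W[:, i].sum() == 0)
        assert ae == 10 - isolated


def _single_link(n):
    W = np.zeros((n, n))
    W[0, 1] = 0.3
    return W


def _complete(n):
    W = np.ones((n, n))
    np.fill_diagonal(W, 0.0)
    return W


class TestOptimizeThreshold:
    def test_constructed_fixture_returns_its_threshold(self):
        # 6 windows engineered so that exactly threshold 0.1 reproduces the
        # observed alpha: weights 0.05 (noise, must go) and 0.1/0.5 (signal)
        mats, alphas = [], []
        rng = np.random.default_rng(3)
        for g in range(6):
            n = 6
            W = np.zeros((n, n))
            k = 2 + (g % 3)           # connect species 0..k via 0.1+ links
            for i in range(k):
                W[i, (i + 1) % (k + 1)] = 0.1 if i % 2 else 0.5
            # sub-threshold noise touching otherwise isolated species
            W[n - 1, n - 2] = 0.05
            mats.append(_matrix(W))
            alphas.append(o.effective_alpha(np.where(W >= 0.1, W, 0)))
        thr = o.optimize_threshold(mats, np.array(alphas))
        assert thr == pytest.approx(0.1)

    def test_full_connectivity_forces_minimal_threshold(self):
        # every node carries exactly one link, so any threshold above the
        # smallest weight isolates nodes and the optimum is forced below it
        rng = np.random.default_rng(1)
        mats = []
        for _ in range(5):
            W = np.zeros((6, 6))
            for p in range(3):
                W[2 * p, 2 * p + 1] = rng.uniform(0.2, 1.0)
            mats.append(_matrix(W))
        thr = o.optimize_threshold(mats, np.full(5, 6.0))
        assert thr <= min(m.W[m.W > 0].min() for m in mats)

    def test_constant_unreachable_alpha_falls_back(self):
        rng = np.random.default_rng(2)
        mats = []
        for _ in range(5):
            W = rng.uniform(0.2, 1.0, size=(5, 5))
            np.fill_diagonal(W, 0.0)
            mats.append(_matrix(W))
        with pytest.warns(UserWarning, match="constant"):
            thr = o.optimize_threshold(mats, np.full(5, 0.5))
        assert thr == 0.01


class TestOTEAndDegrees:
    def test_single_entry_profile(self):
        W = np.zeros((10, 10))
        W[3, 7] = 0.4
        prof = o.ote_profile(_matrix(W))
        assert prof.ote[3] == pytest.approx(0.4)
        assert prof.ote.sum() == pytest.approx(0.4)
        assert prof.ranking[0][0] == "sp4"

    def test_ote_ite_conservation(self, rng):
        W = rng.uniform(0, 1, size=(8, 8))
        np.fill_diagonal(W, 0.0)
        prof = o.ote_profile(_matrix(W))
        assert prof.ote.sum() == pytest.approx(prof.ite.sum())
        assert prof.total_interaction == pytest.approx(W.sum())

    def test_degree_examples_and_oracle(self, rng):
        W = np.zeros((5, 5))
        W[0, 1] = 0.5
        df = o.degree_stats(_matrix(W))
        assert df.loc[0, "out_degree"] == 1 and df.loc[1, "in_degree"] == 1
        assert df.loc[0, "structural_degree"] == 1 == df.loc[1, "structural_degree"]
        Wr = rng.uniform(0, 1, size=(7, 7)) * (rng.random((7, 7)) < 0.4)
        np.fill_diagonal(Wr, 0.0)
        dfr = o.degree_stats(_matrix(Wr))
        A = Wr > 0
        assert dfr["out_degree"].tolist() == A.sum(axis=1).tolist()
        assert dfr["in_degree"].tolist() == A.sum(axis=0).tolist()


class TestExport:
    def test_roundtrip_preserves_weights(self, tmp_path, rng):
        W = rng.uniform(0, 1, size=(6, 6)) * (rng.random((6, 6)) < 0.5)
        np.fill_diagonal(W, 0.0)
        im = _matrix(W)
        p = o.export_network(im, tmp_path / "net.tsv")
        back = import_edge_list(p, im.species)
        np.testing.assert_allclose(back.W, W, atol=1e-12)

    def test_single_link_edge_list(self, tmp_path):
        im = _matrix(_single_link(3))
        p = o.export_network(im, tmp_path / "one.tsv")
        assert len(p.read_text().strip().splitlines()) == 2  # header + 1 edge

    def test_empty_matrix_header_only(self, tmp_path):
        im = _matrix(np.zeros((3, 3)))
        p = o.export_network(im, tmp_path / "empty.tsv")
        assert len(p.read_text().strip().splitlines()) == 1

    def test_graphml_export(self, tmp_path):
        import networkx as nx

        im = _matrix(_single_link(3))
        p = o.export_network(im, tmp_path / "net.graphml", fmt="graphml",
                             node_attrs={"ote": np.array([0.3, 0.0, 0.0])})
        g = nx.read_graphml(p)
        assert g.number_of_edges() == 1
        assert g.nodes["sp1"]["ote"] == pytest.approx(0.3)


class TestEdgeRecovery:
    def test_benchmark_recovers_true_edges(self):
        from oifnet.benchmarks import edge_recovery_benchmark

        m = edge_recovery_benchmark(seed=42, L=2000)
        assert m["precision_at_E"] >= 0.8
        assert m["average_precision"] > 0.85

    def test_recovery_beats_permuted_null(self, rng):
        """Rank-based recovery exceeds the 95th percentile of a permuted-
        labels null."""
        from oifnet.benchmarks import edge_recovery_benchmark
        from oifnet.synthetic import SyntheticConfig, gen_community
        from oifnet.network import infer_matrix

        cfg = SyntheticConfig(n_species=15, L=1000, seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab, truth = gen_community(cfg)
            im = o.infer_matrix(o.normalize(tab))
        ap = o.evaluate_recovery(im.W, truth)["average_precision"]
        null_aps = []
        off = ~np.eye(15, dtype=bool)
        scores = im.W[off]
        labels = truth.C[off] != 0
        for _ in range(200):
            perm = rng.permutation(labels)
            order = np.argsort(-scores)
            ranked = perm[order]
            hits = np.cumsum(ranked)
            prec = hits / np.arange(1, ranked.size + 1)
            null_aps.append((prec * ranked).sum() / ranked.sum())
        assert ap > np.quantile(null_aps, 0.95)
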