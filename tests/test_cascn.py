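"""Pseudotime causal analysis: ordering and residualization contracts,
path-coefficient exactness against a normal-equations oracle, retention and
degree rules, direction specificity and export round-trips."""

import numpy as np
import pandas as pd
import pytest

from morphnet.cascn import (CausalNetwork, build_pseudotime,
                            export_causal_network, gc_path_coefficient,
                            roi_network_gc, seed_to_map_gc)
from morphnet.io import default_atlas
from morphnet.synthetic import GroundTruth, gen_gmv_parcels, gen_subject_table


def gc_oracle(x, y):
    """Normal-equations solve of y_t ~ 1 + y_{t-1} + x_{t-1}."""
    X = np.column_stack([np.ones(len(y) - 1), y[:-1], x[:-1]])
    yt = y[1:]
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ yt
    resid = yt - X @ beta
    sigma2 = resid @ resid / (len(yt) - 3)
    se = np.sqrt(sigma2 * XtX_inv[2, 2])
    return beta[2], beta[2] / se


class TestBuildPseudotime:
    def test_duration_ordering(self):
        subs = pd.DataFrame({
            "id": list("abcdefghij"),
            "group": ["patient"] * 10,
            "age": 60.0, "sex": "M", "tiv": 1.4e6,
            "duration": [5.0, 2.0, 8.0, 1, 9, 4, 7, 3, 6, 10],
        })
        gmv = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 3)),
                           index=list("abcdefghij"), columns=list("XYZ"))
        ps = build_pseudotime(gmv, subs, covariates=())
        assert ps.order == ["d", "b", "h", "f", "a", "i", "g", "c", "e", "j"]

    def test_duration_ties_break_by_id(self):
        subs = pd.DataFrame({
            "id": ["b", "a"] + [f"x{i}" for i in range(8)],
            "group": ["patient"] * 10,
            "age": 60.0, "sex": "M", "tiv": 1.4e6,
            "duration": [3.0, 3.0] + list(range(4, 12)),
        })
        ids = subs["id"].tolist()
        gmv = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 2)),
                           index=ids, columns=["X", "Y"])
        ps = build_pseudotime(gmv, subs, covariates=())
        assert ps.order[:2] == ["a", "b"]

    def test_residuals_uncorrelated_with_covariates(self, small_cohort):
        subjects, gmv, _ = small_cohort
        ps = build_pseudotime(gmv, subjects)
        sub = subjects.set_index("id").loc[ps.order]
        for c in ("age", "tiv"):
            v = sub[c].to_numpy(dtype=float)
            for parcel in ps.parcels:
                r = np.corrcoef(v, ps.values[parcel])[0, 1]
                assert abs(r) < 1e-10

    def test_standardization(self, small_cohort):
        subjects, gmv, _ = small_cohort
        ps = build_pseudotime(gmv, subjects)
        np.testing.assert_allclose(ps.values.to_numpy().mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(ps.values.to_numpy().std(axis=0), 1.0, atol=1e-12)

    def test_collinear_parcel_dropped(self, small_cohort):
        subjects, gmv, _ = small_cohort
        data = gmv.copy()
        data["TWICE_TIV"] = 2.0 * subjects.set_index("id").loc[gmv.index, "tiv"]
        with pytest.warns(UserWarning, match="TWICE_TIV"):
            ps = build_pseudotime(data, subjects)
        assert "TWICE_TIV" in ps.dropped

    def test_missing_duration_rejected(self, small_cohort):
        subjects, gmv, _ = small_cohort
        subs = subjects.copy()
        subs.loc[subs.index[0], "duration"] = np.nan
        with pytest.raises(ValueError):
            build_pseudotime(gmv, subs)


class TestPathCoefficient:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(60)
        y = np.zeros(60)
        y[1:] = 0.7 * x[:-1]
        res = gc_path_coefficient(x, y)
        assert res.beta == pytest.approx(0.7, abs=1e-8)

    def test_matches_normal_equations_oracle(self):
        """Every instance with n <= 50 agrees with the oracle to 1e-10."""
        rng = np.random.default_rng(1)
        for n in (5, 8, 13, 21, 34, 50):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            res = gc_path_coefficient(x, y)
            b, z = gc_oracle(x, y)
            assert res.beta == pytest.approx(b, abs=1e-10)
            assert res.z == pytest.approx(z, abs=1e-10)

    def test_null_z_rarely_extreme(self):
        rng = np.random.default_rng(2)
        extreme = 0
        n_sim = 500
        for _ in range(n_sim):
            res = gc_path_coefficient(rng.standard_normal(60),
                                      rng.standard_normal(60))
            extreme += abs(res.z) >= 3
        assert extreme / n_sim <= 0.01

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            gc_path_coefficient(np.ones(3), np.ones(3))

    def test_collinear_lags_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            gc_path_coefficient(x, 2.0 * x)


class TestSeedToMap:
    def test_negative_betas_all_dropped(self):
        """Only positive path coefficients are retained."""
        rng = np.random.default_rng(3)
        n = 60
        x = rng.standard_normal(n)
        data = {"S": x}
        for j in range(3):  # targets anti-coupled to the seed
            y = np.zeros(n)
            y[1:] = -0.8 * x[:-1] + 0.1 * rng.standard_normal(n - 1)
            data[f"T{j}"] = y
        from morphnet.cascn import PseudotimeSeries
        vals = pd.DataFrame(data)
        vals = (vals - vals.mean()) / vals.std()
        ps = PseudotimeSeries(order=[str(i) for i in range(n)], values=vals,
                              covariates_removed=[])
        assert seed_to_map_gc(ps, "S") == []

    def test_planted_chain_recovered(self):
        truth = GroundTruth(seed=17, causal_edges=[("PAL.L", "PCUN.L", 0.6)])
        subs = gen_subject_table(60, 0, seed=17)
        gmv = gen_gmv_parcels(subs, truth)
        ps = build_pseudotime(gmv, subs)
        res = seed_to_map_gc(ps, "PAL.L")
        sig = {r.target for r in res if r.q < 0.05}
        assert "PCUN.L" in sig

    def test_dropped_seed_rejected(self, small_cohort):
        subjects, gmv, _ = small_cohort
        data = gmv.copy()
        data["FLAT"] = 1.0
        with pytest.warns(UserWarning):
            ps = build_pseudotime(data, subjects)
        with pytest.raises(ValueError):
            seed_to_map_gc(ps, "FLAT")


class TestRoiNetwork:
    def test_degree_counting(self):
        rois = ["A", "B", "C"]
        B = pd.DataFrame([[0, 1, 1], [0, 0, 1], [0, 0, 0]],
                         index=rois, columns=rois)
        net = CausalNetwork(nodes=rois, weights=B.astype(float), binary=B,
                            out_degree=B.sum(axis=1), in_degree=B.sum(axis=0),
                            q_level=0.05)
        assert net.out_degree.tolist() == [2, 1, 0]
        assert net.in_degree.tolist() == [0, 1, 2]
        assert net.out_degree.sum() == net.in_degree.sum() == net.n_edges

    def test_chain_recovery_and_degree_conservation(self):
        truth = GroundTruth.paper_like(seed=29)
        subs = gen_subject_table(80, 0, seed=29)
        gmv = gen_gmv_parcels(subs, truth)
        ps = build_pseudotime(gmv, subs)
        net = roi_network_gc(ps, ["PAL.L", "PCUN.L", "ITG.L"])
        assert net.out_degree.sum() == net.in_degree.sum() == net.n_edges
        assert net.out_degree["PAL.L"] == net.out_degree.max()

    def test_permuting_subject_order_destroys_edges(self):
        """Shuffling the pseudotime order removes the planted causality."""
        truth = GroundTruth.paper_like(seed=41)
        subs = gen_subject_table(80, 0, seed=41)
        gmv = gen_gmv_parcels(subs, truth)
        ps = build_pseudotime(gmv, subs)
        rng = np.random.default_rng(0)
        edges = []
        for _ in range(10):
            perm = rng.permutation(len(ps.order))
            shuffled = ps.values.iloc[perm].reset_index(drop=True)
            ps_shuf = type(ps)(order=[str(i) for i in range(len(perm))],
                               values=shuffled, covariates_removed=[])
            net = roi_network_gc(ps_shuf, ["PAL.L", "PCUN.L", "ITG.L"])
            edges.append(net.n_edges)
        assert np.mean(edges) < 1.0

    def test_duplicate_rois_rejected(self, small_cohort):
        subjects, gmv, _ = small_cohort
        ps = build_pseudotime(gmv, subjects)
        with pytest.raises(ValueError):
            roi_network_gc(ps, ["PAL.L", "PAL.L"])


class TestExport:
    def test_node_edge_roundtrip(self, tmp_path, small_cohort):
        subjects, gmv, _ = small_cohort
        ps = build_pseudotime(gmv, subjects)
        net = roi_network_gc(ps, ["PAL.L", "PCUN.L", "ITG.L"])
        atlas = default_atlas(parcels=list(gmv.columns))
        node, edge = tmp_path / "n.node", tmp_path / "e.edge"
        export_causal_network(net, atlas.centroids(), node, edge)
        W = np.loadtxt(edge, delimiter="\t")
        assert W.shape == (3, 3)
        np.testing.assert_allclose(W, net.weights.to_numpy(), atol=1e-6)
        lines = node.read_text().strip().splitlines()
        assert len(lines) == 3 and lines[0].split("\t")[5] == "PAL.L"

    def test_empty_network_valid_files(self, tmp_path):
        rois = ["A", "B"]
        Z = pd.DataFrame(np.zeros((2, 2)), index=rois, columns=rois)
        net = CausalNetwork(nodes=rois, weights=Z, binary=Z.astype(int),
                            out_degree=Z.sum(axis=1).astype(int),
                            in_degree=Z.sum(axis=0).astype(int), q_level=0.05)
        coords = {"A": np.zeros(3), "B": np.ones(3)}
        export_causal_network(net, coords, tmp_path / "n.node", tmp_path / "e.edge")
        assert np.loadtxt(tmp_path / "e.edge", delimiter="\t").sum() == 0

    def test_missing_coordinates_rejected(self, tmp_path):
        rois = ["A", "B"]
        Z = pd.DataFrame(np.zeros((2, 2)), index=rois, columns=rois)
        net = CausalNetwork(nodes=rois, weights=Z, binary=Z.astype(int),
                            out_degree=Z.sum(axis=1), in_degree=Z.sum(axis=0),
                            q_level=0.05)
        with pytest.raises(ValueError, match="B"):
            export_causal_network(net, {"A": np.zeros(3)},
                                  tmp_path / "n.node", tmp_path / "e.edge")
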