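import numpy as np
import pandas as pd
import pytest

import metabokit as mk
from metabokit.core_data import DataTableError
from metabokit.multivariate import CELL_HEIGHT, Ellipse, HEADER_HEIGHT


def make_dt(x, groups, factor2=None):
    values = pd.DataFrame(np.asarray(x, dtype=float),
                          index=[f"s{i}" for i in range(len(groups))])
    values.columns = [f"f{j}" for j in range(values.shape[1])]
    group = pd.Series(groups, index=values.index)
    f2 = None if factor2 is None else pd.Series(factor2, index=values.index)
    return mk.DataTable(values=values, group=group, factor2=f2)


class TestPca:
    def test_collinear_data_one_component(self):
        t = np.linspace(0, 1, 8)
        x = np.column_stack([t, 2 * t, -t])
        dt = make_dt(x, ["A"] * 4 + ["B"] * 4)
        sl = mk.pca(dt, n_components=2)
        assert sl.explained[0] == pytest.approx(1.0)
        assert sl.explained[1] == pytest.approx(0.0, abs=1e-12)

    def test_known_covariance_direction(self):
        rng = np.random.default_rng(19)
        cov = [[2.0, 1.0], [1.0, 2.0]]
        x = rng.multivariate_normal([0, 0], cov, size=4000)
        dt = make_dt(x, ["A"] * 2000 + ["B"] * 2000)
        sl = mk.pca(dt, n_components=2)
        direction = sl.loadings.iloc[:, 0].to_numpy()
        np.testing.assert_allclose(np.abs(direction), [1, 1] / np.sqrt(2),
                                   atol=0.03)

    def test_full_reconstruction(self, signal_table):
        k = min(signal_table.n_samples - 1, signal_table.n_features)
        sl = mk.pca(signal_table, n_components=k)
        xc = signal_table.values - signal_table.values.mean()
        recon = sl.scores.to_numpy() @ sl.loadings.to_numpy().T
        np.testing.assert_allclose(recon, xc.to_numpy(), atol=1e-8)

    def test_loadings_orthonormal(self, signal_table):
        sl = mk.pca(signal_table, n_components=4)
        gram = sl.loadings.to_numpy().T @ sl.loadings.to_numpy()
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)

    def test_explained_non_increasing_and_scores_centered(self, signal_table):
        sl = mk.pca(signal_table, n_components=5)
        assert (np.diff(sl.explained) <= 1e-12).all()
        assert sl.explained.sum() <= 1 + 1e-12
        assert np.abs(sl.scores.mean()).max() < 1e-10

    def test_total_score_variance_preserved(self, signal_table):
        k = min(signal_table.n_samples - 1, signal_table.n_features)
        sl = mk.pca(signal_table, n_components=k)
        xc = signal_table.values - signal_table.values.mean()
        assert sl.scores.to_numpy().var(ddof=1, axis=0).sum() == \
            pytest.approx(xc.to_numpy().var(ddof=1, axis=0).sum())

    def test_too_many_components(self, clean_table):
        with pytest.raises(DataTableError):
            mk.pca(clean_table, n_components=50)


class TestPlsda:
    def test_vip_identity(self, signal_table):
        sl = mk.plsda(signal_table)
        assert np.mean(sl.vip ** 2) == pytest.approx(1.0, abs=1e-8)

    def test_separating_feature_has_max_vip(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 10), scale=1.0)
        x[15:, 0] += 8.0   # only f0 separates the groups
        dt = make_dt(x, ["A"] * 15 + ["B"] * 15)
        sl = mk.plsda(dt)
        assert sl.vip.idxmax() == "f0"

    def test_duplicating_samples_keeps_directions(self, signal_table):
        sl1 = mk.plsda(signal_table)
        doubled = mk.DataTable(
            values=pd.concat([signal_table.values,
                              signal_table.values.set_axis(
                                  [f"{s}_dup" for s in signal_table.sample_ids])]),
            group=pd.concat([signal_table.group,
                             signal_table.group.set_axis(
                                 [f"{s}_dup" for s in signal_table.sample_ids])]))
        sl2 = mk.plsda(doubled)
        w1 = sl1.loadings.iloc[:, 0]
        w2 = sl2.loadings.iloc[:, 0]
        cos = np.abs(w1 @ w2 / np.linalg.norm(w1) / np.linalg.norm(w2))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_separable_groups_resubstitution(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(20, 5), scale=0.5)
        x[10:, 0] += 6.0
        dt = make_dt(x, ["A"] * 10 + ["B"] * 10)
        sl = mk.plsda(dt, n_components=2)
        # classify by nearest group centroid in score space
        scores = sl.scores.to_numpy()
        ca = scores[:10].mean(axis=0)
        cb = scores[10:].mean(axis=0)
        pred = ["A" if np.linalg.norm(s - ca) < np.linalg.norm(s - cb) else "B"
                for s in scores]
        assert pred == dt.group.tolist()


class TestConfidenceEllipse:
    def _scores(self, cov, n=400, seed=2):
        rng = np.random.default_rng(seed)
        pts = rng.multivariate_normal([0, 0], cov, size=n)
        scores = pd.DataFrame(pts, columns=["PC1", "PC2"],
                              index=[f"s{i}" for i in range(n)])
        group = pd.Series(["A"] * n, index=scores.index)
        return scores, group

    def test_isotropic_gives_circle(self):
        scores, group = self._scores(np.eye(2))
        [ell] = mk.confidence_ellipse(scores, group)
        assert ell.axes[0] / ell.axes[1] == pytest.approx(1.0, abs=0.15)

    def test_level_monotone(self):
        scores, group = self._scores([[2.0, 0.5], [0.5, 1.0]])
        [e90] = mk.confidence_ellipse(scores, group, level=0.90)
        [e99] = mk.confidence_ellipse(scores, group, level=0.99)
        assert (e99.axes > e90.axes).all()

    def test_axis_ratio_from_eigenvalues(self):
        scores, group = self._scores(np.diag([4.0, 1.0]), n=20000, seed=5)
        [ell] = mk.confidence_ellipse(scores, group)
        assert ell.axes[0] / ell.axes[1] == pytest.approx(2.0, abs=0.1)

    def test_collinear_flagged_degenerate(self):
        t = np.linspace(0, 1, 10)
        scores = pd.DataFrame({"PC1": t, "PC2": 2 * t},
                              index=[f"s{i}" for i in range(10)])
        group = pd.Series(["A"] * 10, index=scores.index)
        [ell] = mk.confidence_ellipse(scores, group)
        assert ell.degenerate


class TestHeatmap:
    def test_identical_features_merge_first(self, clean_table):
        dt = clean_table.copy()
        dt.values["dup"] = dt.values["f0"]
        spec = mk.hclust_heatmap(dt, linkage="average")
        assert spec.col_tree[0, 2] == pytest.approx(0.0)

    def test_detail_height_linear_rule(self):
        rng = np.random.default_rng(1)
        for m, other in ((100, 200),):
            dts = []
            for mm in (m, other):
                x = rng.normal(size=(8, mm))
                dts.append(make_dt(x, ["A"] * 4 + ["B"] * 4))
            h1 = mk.hclust_heatmap(dts[0], view="detail").image_height
            h2 = mk.hclust_heatmap(dts[1], view="detail").image_height
            assert h2 - h1 == (other - m) * CELL_HEIGHT
            assert h1 == HEADER_HEIGHT + m * CELL_HEIGHT

    def test_average_linkage_hand_agglomeration(self):
        # 1D points {0,1,10,11}: merges {0,1}, {10,11}, then the two pairs
        dt = make_dt(np.array([[0.0], [1.0], [10.0], [11.0]]),
                     ["A", "A", "B", "B"])
        spec = mk.hclust_heatmap(dt, linkage="average")
        tree = spec.row_tree
        assert tree[0, 2] == pytest.approx(1.0)
        assert tree[1, 2] == pytest.approx(1.0)
        assert tree[2, 2] == pytest.approx(10.0)  # mean of {9,10,10,11}
        order = [str(s) for s in spec.row_order]
        assert order in (["s0", "s1", "s2", "s3"], ["s2", "s3", "s0", "s1"],
                         ["s1", "s0", "s3", "s2"], ["s3", "s2", "s1", "s0"])

    def test_feature_cap_retains_top_variance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(10, 50)) * np.linspace(0.1, 5, 50)
        dt = make_dt(x, ["A"] * 5 + ["B"] * 5)
        spec = mk.hclust_heatmap(dt, view="detail", feature_cap=10)
        assert len(spec.col_order) == 10
        top = set(dt.values.var(ddof=1).nlargest(10).index)
        assert set(spec.col_order) == top
        assert spec.notes

    def test_row_permutation_invariance(self, signal_table):
        spec1 = mk.hclust_heatmap(signal_table)
        shuffled = signal_table.copy()
        rng = np.random.default_rng(9)
        order = rng.permutation(shuffled.values.index)
        shuffled.values = shuffled.values.loc[order]
        shuffled.group = shuffled.group.loc[order]
        spec2 = mk.hclust_heatmap(shuffled)
        assert [str(s) for s in spec1.col_order] == \
            [str(s) for s in spec2.col_order]


class TestCorrelationMap:
    def test_self_correlation_unit_diagonal(self, signal_table):
        corr, _ = mk.correlation_map(signal_table)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_negation_gives_minus_one(self, clean_table):
        dt = clean_table.copy()
        dt.values["neg"] = -dt.values["f0"]
        corr, _ = mk.correlation_map(dt)
        assert corr.loc["f0", "neg"] == pytest.approx(-1.0)

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(30)
        n = 4000
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        c = rng.normal(size=n)
        dt = make_dt(np.column_stack([a, b, c]), ["A"] * 2000 + ["B"] * 2000)
        corr, _ = mk.correlation_map(dt)
        assert corr.loc["f0", "f1"] == pytest.approx(0.9, abs=0.02)

    def test_zero_variance_reported_missing(self, clean_table):
        dt = clean_table.copy()
        dt.values["const"] = 3.0
        corr, spec = mk.correlation_map(dt)
        assert corr.loc["const", "f0"] != corr.loc["const", "f0"] or \
            np.isnan(corr.loc["f0", "const"])
        assert spec.row_order[-1] == "const"   # excluded from clustering


class TestTwoFactorCluster:
    def test_block_layout(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(12, 6))
        groups = ["A"] * 6 + ["B"] * 6
        times = ["t0", "t0", "t1", "t1", "t2", "t2"] * 2
        dt = make_dt(x, groups, factor2=times)
        spec = mk.two_factor_cluster(dt)
        assert len(spec.blocks) == 6
        labels = [b[0] for b in spec.blocks]
        assert labels == sorted(labels)   # group-major order

    def test_input_order_invariance(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(12, 6))
        groups = ["A"] * 6 + ["B"] * 6
        times = ["t0", "t0", "t1", "t1", "t2", "t2"] * 2
        dt = make_dt(x, groups, factor2=times)
        spec1 = mk.two_factor_cluster(dt)
        order = np.random.default_rng(1).permutation(dt.values.index)
        dt2 = mk.DataTable(values=dt.values.loc[order],
                           group=dt.group.loc[order],
                           factor2=dt.factor2.loc[order])
        spec2 = mk.two_factor_cluster(dt2)
        assert spec1.row_order == spec2.row_order
        assert [b[0] for b in spec1.blocks] == [b[0] for b in spec2.blocks]

    def test_feature_dendrogram_shared_with_hclust(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(12, 6))
        dt = make_dt(x, ["A"] * 6 + ["B"] * 6,
                     factor2=["t0", "t1"] * 6)
        spec1 = mk.two_factor_cluster(dt)
        spec2 = mk.hclust_heatmap(dt)
        np.testing.assert_allclose(spec1.col_tree, spec2.col_tree)

    def test_requires_factor2(self, clean_table):
        with pytest.raises(DataTableError):
            mk.two_factor_cluster(clean_table)
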