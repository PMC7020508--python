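import numpy as np
import pandas as pd
import pytest

from exprqc.errors import ValidationError
from exprqc.multivariate import (
    MFASkipped,
    correlate_samples,
    hcluster_samples,
    mfa,
    pca_samples,
)
from exprqc.normalize import log2p1, zscore_rows
from exprqc.simulate import scenario_presets, simulate
from exprqc.io import assemble

from conftest import make_counts, make_dataset


def eig_pca_oracle(X):
    """Brute-force PCA: eigendecompose the gene-gene covariance of the
    sample-by-gene matrix, project the centered data."""
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    return Xc @ evecs[:, order], evals[order]


class TestPCA:
    def test_duplicate_samples_collapse(self, rng):
        vals = rng.integers(0, 100, size=(15, 4)).astype(float)
        vals[:, 3] = vals[:, 0]
        res = pca_samples(make_counts(vals), "unnormalized")
        np.testing.assert_allclose(
            res.scores.iloc[0].to_numpy(), res.scores.iloc[3].to_numpy(), atol=1e-9
        )

    def test_scores_match_eigendecomposition_oracle(self, rng):
        vals = rng.normal(10, 3, size=(20, 5))
        res = pca_samples(pd.DataFrame(vals), "unnormalized")
        expected, _ = eig_pca_oracle(vals.T)
        got = res.scores.to_numpy()
        k = got.shape[1]
        for c in range(k):
            sign = np.sign(expected[np.argmax(np.abs(expected[:, c])), c]) * np.sign(
                got[np.argmax(np.abs(got[:, c])), c]
            )
            np.testing.assert_allclose(got[:, c], sign * expected[:, c], atol=1e-8)

    def test_variance_fractions_sum_to_one(self, rng):
        res = pca_samples(pd.DataFrame(rng.normal(size=(30, 6))), "unnormalized")
        assert res.variance_explained.sum() == pytest.approx(1.0)
        assert (res.variance_explained >= 0).all()

    def test_gene_relabeling_leaves_scores(self, rng):
        vals = rng.normal(size=(12, 5))
        a = pca_samples(pd.DataFrame(vals, index=[f"g{i}" for i in range(12)]), "zscored")
        b = pca_samples(pd.DataFrame(vals, index=[f"x{i}" for i in range(12)]), "zscored")
        np.testing.assert_allclose(a.scores.to_numpy(), b.scores.to_numpy())

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            pca_samples(pd.DataFrame({"s": [1.0, 2.0]}), "unnormalized")


class TestMFA:
    def test_no_covariates_returns_skip_marker(self, rng):
        ds = make_dataset(rng.integers(0, 50, size=(10, 4)))
        z = zscore_rows(log2p1(ds.counts))
        res = mfa(ds, z)
        assert isinstance(res, MFASkipped)
        assert "covariate" in res.reason

    def test_duplicated_covariate_groups_get_equal_weight(self, rng):
        vals = rng.integers(0, 80, size=(20, 6))
        labels = ["x", "x", "y", "y", "z", "z"]
        ds = make_dataset(vals, batch1=labels, batch2=labels)
        z = zscore_rows(log2p1(ds.counts))
        res = mfa(ds, z, include_expression=False)
        assert res.group_weights["batch1"] == pytest.approx(res.group_weights["batch2"])
        # identical blocks split every informative component 50/50; the
        # null-variance components mix arbitrarily and are not compared
        live = res.variance_explained > 1e-9
        np.testing.assert_allclose(
            res.group_contributions.loc["batch1"].to_numpy()[live],
            res.group_contributions.loc["batch2"].to_numpy()[live],
            atol=1e-9,
        )
        single = mfa(make_dataset(vals, batch1=labels), z, include_expression=False)
        k = int(live.sum())
        # doubling an identical group rescales the space but not its shape
        ratio = np.abs(res.scores.iloc[:, 0]).sum() / np.abs(single.scores.iloc[:, 0]).sum()
        np.testing.assert_allclose(
            np.abs(res.scores.to_numpy()[:, :k]),
            ratio * np.abs(single.scores.to_numpy()[:, :k]),
            atol=1e-8,
        )

    def test_constant_covariate_dropped(self, rng):
        ds = make_dataset(
            rng.integers(0, 50, size=(15, 4)),
            useless=["same"] * 4,
            batch=["x", "y", "x", "y"],
        )
        z = zscore_rows(log2p1(ds.counts))
        res = mfa(ds, z)
        assert "useless" in res.dropped_groups
        assert "useless" not in res.group_contributions.index

    def test_contributions_sum_to_one_per_component(self, rng):
        ds = make_dataset(
            rng.integers(0, 90, size=(25, 6)), batch=["x", "y", "x", "y", "x", "y"]
        )
        z = zscore_rows(log2p1(ds.counts))
        res = mfa(ds, z)
        np.testing.assert_allclose(
            res.group_contributions.sum(axis=0).to_numpy(), 1.0, atol=1e-9
        )

    def test_planted_protocol_effect_tops_covariate_contributions(self):
        wins = 0
        for seed in range(10):
            counts, pheno, anno = simulate(scenario_presets()["C"], seed=seed)
            ds = assemble(pheno, counts, anno, organism="other")
            z = zscore_rows(log2p1(ds.counts))
            res = mfa(ds, z)
            cov = res.group_contributions["PC1"].drop("expression")
            wins += cov.idxmax() == "protocol"
        assert wins >= 9


class TestHierarchicalClustering:
    def test_two_samples_single_merge_at_distance(self):
        m = pd.DataFrame({"a": [0.0, 0.0], "b": [3.0, 4.0]})
        dend = hcluster_samples(m)
        assert len(dend.merges) == 1
        assert dend.heights[0] == pytest.approx(5.0)

    def test_duplicate_sample_merges_first_at_zero(self, rng):
        vals = rng.normal(size=(10, 4))
        vals[:, 2] = vals[:, 0]
        dend = hcluster_samples(pd.DataFrame(vals))
        assert dend.heights[0] == pytest.approx(0.0, abs=1e-12)
        assert set(dend.merges[0]) == {0, 2}

    def test_two_tight_pairs_merge_before_joining(self):
        pts = np.array([[0, 0], [0.1, 0], [10, 10], [10.1, 10]])
        dend = hcluster_samples(pd.DataFrame(pts.T))
        assert {tuple(sorted(m)) for m in dend.merges[:2]} == {(0, 1), (2, 3)}

    def test_complete_linkage_heights_monotone(self, rng):
        dend = hcluster_samples(pd.DataFrame(rng.normal(size=(20, 8))))
        assert (np.diff(dend.heights) >= -1e-12).all()


class TestCorrelation:
    def test_unit_diagonal_and_symmetry(self, rng):
        m = pd.DataFrame(rng.normal(10, 2, size=(30, 5)))
        for method in ("pearson", "spearman"):
            res = correlate_samples(m, method)
            np.testing.assert_array_equal(np.diag(res.matrix), 1.0)
            np.testing.assert_array_equal(res.matrix.to_numpy(), res.matrix.to_numpy().T)
            assert (np.abs(res.matrix.to_numpy()) <= 1 + 1e-12).all()

    def test_monotone_transform_rank_invariance(self, rng):
        a = rng.normal(5, 1, 40)
        m = pd.DataFrame({"a": a, "b": a**3})
        assert correlate_samples(m, "spearman").matrix.loc["a", "b"] == pytest.approx(1.0)
        assert correlate_samples(m, "pearson").matrix.loc["a", "b"] < 1.0

    def test_pearson_matches_closed_form(self, rng):
        m = pd.DataFrame(rng.normal(size=(25, 3)), columns=["a", "b", "c"])
        res = correlate_samples(m, "pearson")
        arr = m.to_numpy()
        for i, a in enumerate(m.columns):
            for j, b in enumerate(m.columns):
                x, y = arr[:, i], arr[:, j]
                expected = np.mean((x - x.mean()) * (y - y.mean())) / (
                    x.std(ddof=0) * y.std(ddof=0)
                )
                assert res.matrix.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_sample_flagged(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "flat"])
        m["flat"] = 7.0
        res = correlate_samples(m, "pearson")
        assert res.undefined_samples == ["flat"]
        assert np.isnan(res.matrix.loc["flat", "a"])
        assert res.matrix.loc["flat", "flat"] == 1.0
        assert res.leaf_order[-1] == "flat"
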