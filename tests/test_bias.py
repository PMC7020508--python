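import numpy as np
import pytest

from exprqc.bias import (
    HousekeepingSkipped,
    gc_bias,
    gene_profile,
    housekeeping,
    lowess_fit,
    mapped_density,
)
from exprqc.errors import ValidationError
from exprqc.io import assemble
from exprqc.simulate import scenario_presets, simulate

from conftest import make_annotation, make_dataset


def tricube_local_linear_oracle(x, y, frac):
    """Direct local weighted least squares with tricube weights over the
    int(frac * n) nearest neighbours — the definition, evaluated naively."""
    n = len(x)
    k = int(frac * n)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    fitted = np.empty(n)
    for i, x0 in enumerate(xs):
        d = np.abs(xs - x0)
        h = np.sort(d)[k - 1]
        w = np.clip(1 - (d / np.maximum(h, 1e-300)) ** 3, 0, None) ** 3
        sw = np.sqrt(w)
        A = np.column_stack([np.ones(n), xs])
        beta, *_ = np.linalg.lstsq(A * sw[:, None], ys * sw, rcond=None)
        fitted[i] = beta[0] + beta[1] * x0
    return xs, fitted


class TestLowess:
    def test_matches_local_wls_oracle(self, rng):
        x = rng.uniform(0, 1, 50)
        y = np.sin(3 * x) + rng.normal(0, 0.1, 50)
        for frac in (0.3, 2.0 / 3.0):
            xs, fitted = lowess_fit(x, y, frac=frac, robust_iters=0)
            xo, expected = tricube_local_linear_oracle(x, y, frac)
            np.testing.assert_allclose(xs, xo)
            np.testing.assert_allclose(fitted, expected, atol=1e-8)

    def test_robustness_tames_one_wild_point(self, rng):
        x = np.linspace(0, 1, 60)
        y = 2 * x + rng.normal(0, 0.02, 60)
        y[30] += 50
        _, robust = lowess_fit(x, y, robust_iters=3)
        _, naive = lowess_fit(x, y, robust_iters=0)
        assert np.abs(robust - 2 * x).max() < np.abs(naive - 2 * x).max()


class TestGCBias:
    def _dataset(self, counts_arr, gc, rng):
        n = counts_arr.shape[0]
        anno = make_annotation(
            [f"g{i}" for i in range(n)], rng.integers(200, 2000, n), gc
        )
        return make_dataset(counts_arr, annotation=anno)

    def test_constant_counts_give_flat_curve(self, rng):
        gc = rng.beta(5, 5, 40)
        ds = self._dataset(np.full((40, 3), 7.0), gc, rng)
        for curve in gc_bias(ds):
            assert np.ptp(curve.fitted) < 1e-6

    def test_planted_monotone_trend_recovered(self):
        from scipy.stats import spearmanr

        for seed in range(20):
            rng = np.random.default_rng(seed)
            gc = rng.uniform(0.2, 0.8, 200)
            counts = rng.poisson(np.exp(2 + 4 * gc))[:, None] * np.ones(3, dtype=int)
            ds = self._dataset(counts, gc, rng)
            curve = gc_bias(ds)[0]
            rho = spearmanr(curve.fitted, curve.gc).statistic
            assert rho > 0.99

    def test_gc_depressed_sample_sits_below_on_high_gc_half(self):
        # the planted library artifact: one sample's counts down-weighted
        # at high GC; its fitted curve must lie under every other curve
        # on the high-GC side
        counts, pheno, anno = simulate(scenario_presets()["B"], seed=0)
        ds = assemble(pheno, counts, anno, organism="human")
        curves = {c.sample_id: c for c in gc_bias(ds)}
        high = curves["control4"].gc > 0.6
        for name, c in curves.items():
            if name != "control4":
                assert (curves["control4"].fitted[high] < c.fitted[high]).all()

    def test_annotation_required(self, rng):
        ds = make_dataset(rng.integers(0, 50, size=(30, 3)))
        with pytest.raises(ValidationError, match="annotation"):
            gc_bias(ds)

    def test_minimum_gene_overlap(self, rng):
        anno = make_annotation(["g0", "g1"], [300, 400], [0.3, 0.7])
        ds = make_dataset(rng.integers(0, 50, size=(30, 3)), annotation=anno)
        with pytest.raises(ValidationError, match="20"):
            gc_bias(ds)

    def test_gene_order_permutation_invariant(self, rng):
        from conftest import make_counts, make_pheno

        gc = rng.beta(5, 5, 50)
        counts = rng.integers(0, 200, size=(50, 3))
        genes = [f"g{i}" for i in range(50)]
        lengths = rng.integers(200, 2000, 50)
        anno = make_annotation(genes, lengths, gc)
        pheno = make_pheno(["s0", "s1", "s2"], ["a", "a", "b"])
        perm = rng.permutation(50)
        ds = assemble(pheno, make_counts(counts, genes=genes), anno)
        ds2 = assemble(
            pheno,
            make_counts(counts[perm], genes=[genes[i] for i in perm]),
            anno,
        )
        a, b = gc_bias(ds)[0], gc_bias(ds2)[0]
        np.testing.assert_allclose(a.gc, b.gc)
        np.testing.assert_allclose(a.fitted, b.fitted, atol=1e-10)


class TestDensity:
    def test_identical_samples_identical_curves(self, rng):
        col = rng.integers(0, 300, 50)
        ds = make_dataset(
            np.column_stack([col, col]),
            annotation=make_annotation(
                [f"g{i}" for i in range(50)], rng.integers(200, 2000, 50), rng.beta(5, 5, 50)
            ),
        )
        a, b = mapped_density(ds)
        np.testing.assert_allclose(a.density, b.density)

    def test_curves_integrate_to_one(self, rng):
        ds = make_dataset(rng.integers(0, 500, size=(60, 4)))
        for curve in mapped_density(ds):  # vst_like route (no annotation)
            integral = np.trapezoid(curve.density, curve.grid)
            assert 0.95 <= integral <= 1.05

    def test_collapsed_library_piles_mass_in_zero_region(self):
        # TPM cancels depth, but a 5% library drops many genes to zero
        # counts -> zero TPM: the outlier's curve carries the most mass
        # below log2(TPM+1) = 1
        counts, pheno, anno = simulate(scenario_presets()["B"], seed=3)
        ds = assemble(pheno, counts, anno, organism="human")
        curves = mapped_density(ds)

        def zero_mass(c):
            lo = c.grid <= 1.0
            return np.trapezoid(c.density[lo], c.grid[lo])

        masses = {c.sample_id: zero_mass(c) for c in curves}
        assert max(masses, key=masses.get) == "control4"

    def test_constant_sample_flat_flagged(self, rng):
        vals = rng.integers(1, 100, size=(30, 3)).astype(float)
        vals[:, 2] = 0.0
        ds = make_dataset(vals)
        ds.counts.is_raw = False  # use values as-is; avoids the size-factor route
        curves = mapped_density(ds)
        assert curves[2].flat and not curves[0].flat
        assert np.ptp(curves[2].density) == 0


class TestGeneProfiles:
    def test_zero_gene_zero_profile(self, rng):
        vals = rng.integers(1, 50, size=(10, 3)).astype(float)
        vals[4] = 0
        ds = make_dataset(vals)
        prof = gene_profile(ds, "g4")
        assert (prof.values == 0).all()

    def test_versioned_lookup_resolves(self, rng):
        import pandas as pd

        from conftest import make_counts, make_pheno

        counts = make_counts(
            rng.integers(0, 50, size=(3, 2)),
            genes=["ENSG00000075624", "ENSG00000111640", "ENSG00000000003"],
        )
        ds = assemble(make_pheno(counts.sample_ids, ["a", "b"]), counts)
        prof = gene_profile(ds, "ENSG00000000003.7")
        assert prof.gene == "ENSG00000000003"

    def test_profile_is_log2_of_counts(self, rng):
        vals = rng.integers(0, 100, size=(8, 4))
        ds = make_dataset(vals)
        prof = gene_profile(ds, "g5")
        np.testing.assert_allclose(prof.values, np.log2(vals[5] + 1.0))

    def test_absent_gene_suggests_near_matches(self, rng):
        ds = make_dataset(rng.integers(0, 50, size=(10, 3)))
        with pytest.raises(ValidationError, match="g1"):
            gene_profile(ds, "g1XX")


class TestHousekeeping:
    def test_symbol_lookup_returns_both(self):
        counts, pheno, anno = simulate(scenario_presets()["A"], seed=0)
        ds = assemble(pheno, counts, anno, organism="human")
        gapdh, actb = housekeeping(ds)
        assert {gapdh.gene, actb.gene} == {"GAPDH", "ACTB"}

    def test_missing_gene_skips_with_pointer(self, rng):
        ds = make_dataset(rng.integers(0, 50, size=(10, 4)))
        result = housekeeping(ds)
        assert isinstance(result, HousekeepingSkipped)
        assert "expression plot" in result.reason

    def test_other_organism_skips(self, rng):
        ds = make_dataset(rng.integers(0, 50, size=(10, 4)), organism="other")
        assert isinstance(housekeeping(ds), HousekeepingSkipped)

    def test_collapsed_library_lowest_housekeeping(self):
        counts, pheno, anno = simulate(scenario_presets()["B"], seed=0)
        ds = assemble(pheno, counts, anno, organism="human")
        gapdh, actb = housekeeping(ds)
        assert gapdh.values.idxmin() == "control4"
        assert actb.values.idxmin() == "control4"
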