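import numpy as np
import pandas as pd
import pytest

from astrodiverge.io_formats import ExpressionTable, OrthologTable
from astrodiverge import coexpr


def _bicor_reference(x, y, c=9.0):
    """Independent per-pair biweight midcorrelation, straight from the formula."""
    def transform(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (c * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        a = (v - med) * w
        return a / np.sqrt((a**2).sum())
    return float(transform(x) @ transform(y))


class TestPreprocess:
    def _tables(self):
        rng = np.random.default_rng(0)
        genes_h = [f"H{i}" for i in range(10)]
        genes_m = [f"m{i}" for i in range(10)]
        samples = ["c0", "c1", "t0", "t1"]

        def table(genes, prefix):
            vals = pd.DataFrame(rng.poisson(20, size=(10, 4)).astype(float),
                                index=genes, columns=[f"{prefix}{s}" for s in samples])
            vals.iloc[0] = 0.0
            if prefix == "h":
                vals.iloc[0, 0] = 3.0  # nonzero in 1 of 8 merged samples -> dropped
            meta = pd.DataFrame({
                "species": "human" if prefix == "h" else "mouse",
                "condition": ["control", "control", "treated", "treated"],
                "replicate_pair": [f"{prefix}p0", f"{prefix}p1", f"{prefix}p0", f"{prefix}p1"],
            }, index=vals.columns)
            return ExpressionTable(vals, meta)

        orth = OrthologTable(pd.DataFrame({"human": genes_h, "mouse": genes_m}))
        return table(genes_h, "h"), table(genes_m, "m"), orth

    def test_low_nonzero_gene_dropped_and_offset_applied(self):
        h, m, orth = self._tables()
        merged = coexpr.preprocess(h, m, orth)
        assert "H0" not in merged.index
        # a zero count maps to log2(0.001)
        h.values.iloc[1, 1] = 0.0
        merged = coexpr.preprocess(h, m, orth)
        pair_mean_effect = merged.loc["H1"]
        assert np.isfinite(pair_mean_effect).all()

    def test_within_pair_centering_is_exact(self):
        h, m, orth = self._tables()
        merged = coexpr.preprocess(h, m, orth)
        meta = pd.concat([h.meta, m.meta])
        for pair, cols in meta.groupby("replicate_pair").groups.items():
            np.testing.assert_allclose(merged[list(cols)].mean(axis=1), 0.0, atol=1e-12)

    def test_singleton_replicate_pair_rejected(self):
        h, m, orth = self._tables()
        h.meta.loc[h.sample_ids[0], "replicate_pair"] = "lonely"
        with pytest.raises(ValueError, match="single sample"):
            coexpr.preprocess(h, m, orth)


class TestBicor:
    def test_perfect_and_inverted(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=8)
        m = pd.DataFrame([x, -x], index=["a", "b"])
        r, fallback = coexpr.bicor(m)
        assert r.loc["a", "a"] == pytest.approx(1.0)
        assert r.loc["a", "b"] == pytest.approx(-1.0)
        assert fallback == []

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=8), rng.normal(size=8)
        m1 = pd.DataFrame([x, y])
        m2 = pd.DataFrame([3.0 * x + 5.0, 0.25 * y - 2.0])
        r1, _ = coexpr.bicor(m1)
        r2, _ = coexpr.bicor(m2)
        assert r1.iloc[0, 1] == pytest.approx(r2.iloc[0, 1], abs=1e-12)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(6, 8)))
        r, _ = coexpr.bicor(m)
        for i in range(6):
            for j in range(i + 1, 6):
                expected = _bicor_reference(m.iloc[i].to_numpy(), m.iloc[j].to_numpy())
                assert r.iloc[i, j] == pytest.approx(expected, abs=1e-10)

    def test_constant_gene_rejected_and_mad_zero_falls_back(self):
        with pytest.raises(ValueError, match="constant"):
            coexpr.bicor(pd.DataFrame([[1.0] * 6, [1, 2, 3, 4, 5, 6]]))
        # zero MAD but not constant: majority identical values
        m = pd.DataFrame([[1.0, 1, 1, 1, 1, 9], np.arange(6.0)], index=["spiky", "lin"])
        r, fallback = coexpr.bicor(m)
        assert fallback == ["spiky"]
        assert -1 <= r.loc["spiky", "lin"] <= 1


class TestScaleFree:
    def test_r2_bounds_and_degenerate_identity(self, block_expression):
        X, _ = block_expression(seed=1)
        corr, _ = coexpr.bicor(X)
        r2 = coexpr.scale_free_fit(corr, 18)
        assert 0.0 <= r2 <= 1.0
        identity = pd.DataFrame(np.eye(30))
        with pytest.raises(ValueError, match="degenerate"):
            coexpr.scale_free_fit(identity, 1)

    def test_power_sharpens_scale_free_fit_on_modular_data(self, block_expression):
        X, _ = block_expression(seed=2)
        corr, _ = coexpr.bicor(X)
        assert coexpr.scale_free_fit(corr, 18) > coexpr.scale_free_fit(corr, 1)


class TestTom:
    def test_bounds_symmetry_diagonal(self, block_expression):
        X, _ = block_expression(seed=3, nblocks=2, bsize=60, noise=30)
        corr, _ = coexpr.bicor(X)
        t = coexpr.tom(corr, 6).to_numpy()
        assert np.allclose(t, t.T)
        assert (t >= 0).all() and (t <= 1 + 1e-12).all()
        assert np.allclose(np.diag(t), 1.0)

    def test_shared_neighbor_monotonicity_against_brute_force(self):
        """Strengthening a shared neighbor cannot decrease TOM between i and j."""
        def tom_ij_brute(a):
            k = a.sum(axis=1) - np.diag(a)
            num = sum(a[0, u] * a[u, 1] for u in range(2, a.shape[0])) + a[0, 1]
            return num / (min(k[0], k[1]) + 1 - a[0, 1])

        base = np.array([
            [0.0, 0.3, 0.2, 0.1, 0.0],
            [0.3, 0.0, 0.2, 0.0, 0.1],
            [0.2, 0.2, 0.0, 0.4, 0.3],
            [0.1, 0.0, 0.4, 0.0, 0.2],
            [0.0, 0.1, 0.3, 0.2, 0.0],
        ])
        prev = tom_ij_brute(base)
        for w in (0.3, 0.5, 0.7, 0.9):
            stronger = base.copy()
            stronger[0, 2] = stronger[2, 0] = w
            stronger[1, 2] = stronger[2, 1] = w
            cur = tom_ij_brute(stronger)
            assert cur >= prev - 1e-12
            prev = cur
        # and the vectorized implementation agrees with brute force
        corr_like = pd.DataFrame(base + np.eye(5))
        t = coexpr.tom(corr_like, 1).iloc[0, 1]
        assert t == pytest.approx(tom_ij_brute(base), abs=1e-12)


class TestModules:
    def test_two_perfect_blocks_recovered_exactly(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(2, 12))
        X = pd.DataFrame(
            np.vstack([np.outer(rng.uniform(0.5, 2.0, 60), base[0]),
                       np.outer(rng.uniform(0.5, 2.0, 60), base[1])]),
            index=[f"g{i}" for i in range(120)])
        mods = coexpr.tom_modules(coexpr.bicor(X)[0], X)
        labels = mods.labels
        assert set(labels) == {1, 2}
        assert labels.iloc[:60].nunique() == 1 and labels.iloc[60:].nunique() == 1

    def test_planted_blocks_recovered_with_high_ari(self, block_expression):
        from sklearn.metrics import adjusted_rand_score
        aris = []
        for seed in range(3):
            X, truth = block_expression(seed=seed)
            mods = coexpr.tom_modules(coexpr.bicor(X)[0], X)
            aris.append(adjusted_rand_score(truth, mods.labels.to_numpy()))
        assert min(aris) > 0.9

    def test_label_invariance_under_gene_permutation(self, block_expression):
        X, _ = block_expression(seed=5, nblocks=2, bsize=60, noise=40)
        mods = coexpr.tom_modules(coexpr.bicor(X)[0], X)
        rng = np.random.default_rng(6)
        perm = rng.permutation(len(X))
        Xp = X.iloc[perm]
        mods_p = coexpr.tom_modules(coexpr.bicor(Xp)[0], Xp)
        # same partition up to module renaming
        a = mods.labels.loc[Xp.index].to_numpy()
        b = mods_p.labels.to_numpy()
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(a, b) == pytest.approx(1.0)


class TestModuleTrait:
    def test_eigengene_identical_and_orthogonal_traits(self, block_expression):
        X, _ = block_expression(seed=7, nblocks=1, bsize=60, noise=0, n_samp=20)
        mods = coexpr.tom_modules(coexpr.bicor(X)[0], X)
        eg = mods.eigengenes.iloc[0]
        traits = pd.DataFrame({"self": eg.to_numpy()}, index=mods.eigengenes.columns)
        out = coexpr.module_trait(mods.eigengenes, traits)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        rng = np.random.default_rng(8)
        ortho = rng.normal(size=len(eg))
        ortho -= ortho @ eg.to_numpy() / (eg @ eg) * eg.to_numpy()
        out2 = coexpr.module_trait(mods.eigengenes,
                                   pd.DataFrame({"ortho": ortho}, index=eg.index))
        assert abs(out2.loc[0, "r"]) < 1e-8

    def test_planted_treatment_module_detected(self):
        """A module shifted by 1 log2 unit in treated samples correlates with
        the treatment trait."""
        rng = np.random.default_rng(9)
        n_samp = 8  # 4 control + 4 treated
        trait = np.repeat([0.0, 1.0], 4)
        rows = []
        f = rng.normal(size=n_samp) * 0.3 + trait  # responsive module driver
        for _ in range(60):
            rows.append(f + rng.normal(size=n_samp) * 0.3)
        g = rng.normal(size=n_samp)
        for _ in range(60):
            rows.append(np.sqrt(0.7) * g + np.sqrt(0.3) * rng.normal(size=n_samp))
        X = pd.DataFrame(rows, index=[f"g{i}" for i in range(120)])
        cfg = coexpr.NetworkConfig(power=6.0, min_module_size=30)
        mods = coexpr.tom_modules(coexpr.bicor(X)[0], X, cfg)
        out = coexpr.module_trait(mods.eigengenes,
                                  pd.DataFrame({"treated": trait}, index=X.columns))
        assert out["r"].abs().max() > 0.8

    def test_constant_trait_rejected(self, block_expression):
        X, _ = block_expression(seed=10, nblocks=1, bsize=60, noise=0, n_samp=12)
        mods = coexpr.tom_modules(coexpr.bicor(X)[0], X)
        with pytest.raises(ValueError, match="constant trait"):
            coexpr.module_trait(mods.eigengenes,
                                pd.DataFrame({"flat": np.ones(12)},
                                             index=mods.eigengenes.columns))
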