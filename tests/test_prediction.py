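"""VanRaden kernels, simplex grids, REML GBLUP against the mixed-model
equation oracle, cross-validation and kernel combination."""

import numpy as np
import pandas as pd
import pytest

from pavomics import prediction as pr


def _W(n=10, m=50, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, m)), index=[f"i{k}" for k in range(n)])


class TestVanRaden:
    def test_single_column(self):
        W = _W(m=1)
        fm = pr.preprocess_features(W)
        G = pr.vanraden_kernel(fm)
        x = fm.W.to_numpy()[:, 0]
        assert np.allclose(G.to_numpy(), np.outer(x, x))
        assert np.diag(G).mean() == pytest.approx(1.0)

    def test_duplicated_columns_leave_G_unchanged(self):
        W = _W()
        G1 = pr.vanraden_kernel(pr.preprocess_features(W))
        G2 = pr.vanraden_kernel(pr.preprocess_features(pd.concat([W, W], axis=1)))
        assert np.allclose(G1.to_numpy(), G2.to_numpy())

    def test_matches_elementwise_bruteforce(self):
        fm = pr.preprocess_features(_W(n=10, m=50))
        G = pr.vanraden_kernel(fm).to_numpy()
        X = fm.W.to_numpy()
        brute = np.empty((10, 10))
        for i in range(10):
            for j in range(10):
                brute[i, j] = sum(X[i, k] * X[j, k] for k in range(50)) / 50
        assert np.abs(G - brute).max() < 1e-10

    def test_zero_variance_columns_dropped(self):
        W = _W()
        W["const"] = 1.0
        fm = pr.preprocess_features(W)
        assert fm.n_dropped == 1
        with pytest.raises(ValueError):
            pr.vanraden_kernel(pr.preprocess_features(W[["const"]]))


class TestSimplexGrid:
    @pytest.mark.parametrize("k, step, expected", [(3, 0.1, 66), (2, 0.1, 11), (1, 0.1, 1)])
    def test_cardinality(self, k, step, expected):
        grid = pr.simplex_grid(k, step)
        assert len(grid) == expected
        for w in grid:
            assert sum(w) == pytest.approx(1.0)
            assert all(v >= 0 for v in w)

    def test_k1_is_unit(self):
        assert pr.simplex_grid(1, 0.1) == [(1.0,)]

    def test_non_integer_step_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            pr.simplex_grid(3, 0.3)


class TestCombine:
    def test_vertex_returns_component(self):
        G1 = pr.vanraden_kernel(pr.preprocess_features(_W(seed=1)))
        G2 = pr.vanraden_kernel(pr.preprocess_features(_W(seed=2)))
        joint = pr.combine_kernels(pr.KernelSet({"a": G1, "b": G2}, np.array([1.0, 0.0])))
        assert np.allclose(joint.to_numpy(), G1.to_numpy())

    def test_equal_kernels_weight_invariant(self):
        G = pr.vanraden_kernel(pr.preprocess_features(_W()))
        j1 = pr.combine_kernels(pr.KernelSet({"a": G, "b": G}, np.array([0.3, 0.7])))
        j2 = pr.combine_kernels(pr.KernelSet({"a": G, "b": G}, np.array([0.9, 0.1])))
        assert np.allclose(j1.to_numpy(), j2.to_numpy())

    def test_non_psd_rejected(self):
        G = pr.vanraden_kernel(pr.preprocess_features(_W()))
        with pytest.raises(ValueError, match="positive semi-definite"):
            pr.KernelSet({"a": G, "b": -G}, np.array([0.5, 0.5]))

    def test_bad_weights_rejected(self):
        G = pr.vanraden_kernel(pr.preprocess_features(_W()))
        with pytest.raises(ValueError, match="sum"):
            pr.KernelSet({"a": G, "b": G}, np.array([0.5, 0.6]))


class TestGblup:
    def _mme_oracle(self, y, G, train, val, lam):
        """Brute-force mixed model equations with an explicit G inverse."""
        n = G.shape[0]
        Ginv = np.linalg.inv(G)
        Z = np.zeros((len(train), n))
        Z[np.arange(len(train)), train] = 1.0
        X = np.ones((len(train), 1))
        C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * Ginv]])
        rhs = np.concatenate([X.T @ y[train], Z.T @ y[train]])
        sol = np.linalg.solve(C, rhs)
        return sol[0] + sol[1:][val]

    @pytest.mark.parametrize("n, seed", [(6, 0), (8, 1), (7, 2)])
    def test_matches_mme_oracle(self, n, seed):
        # blend in a little identity: the MME oracle needs an invertible G
        # (a centered VanRaden kernel has the ones vector in its null space)
        rng = np.random.default_rng(seed)
        G = pr.vanraden_kernel(pr.preprocess_features(_W(n=n, m=2 * n, seed=seed)))
        G = pd.DataFrame(0.9 * G.to_numpy() + 0.1 * np.eye(n), index=G.index, columns=G.index)
        y = rng.normal(size=n)
        train = np.arange(n - 2)
        val = np.arange(n - 2, n)
        lam = 0.7
        pred, _, _ = pr.gblup_fit(y[train], G, train, val, lam=lam)
        oracle = self._mme_oracle(y, G.to_numpy(), train, val, lam)
        assert np.abs(pred - oracle).max() < 1e-8

    def test_identity_kernel_predicts_mean(self):
        n = 10
        G = pd.DataFrame(np.eye(n), index=range(n), columns=range(n))
        y = np.random.default_rng(3).normal(size=n - 3)
        pred, mu, _ = pr.gblup_fit(y, G, np.arange(n - 3), np.arange(n - 3, n))
        assert np.allclose(pred, mu)

    def test_noise_free_training_recovery(self):
        """With y generated exactly from the kernel and no noise, training
        predictions correlate with y at > 0.99."""
        n = 30
        G = pr.vanraden_kernel(pr.preprocess_features(_W(n=n, m=200, seed=4)))
        L = np.linalg.cholesky(G.to_numpy() + 1e-10 * np.eye(n))
        y = L @ np.random.default_rng(5).normal(size=n)
        train = np.arange(n)
        pred, _, _ = pr.gblup_fit(y, G, train, train)
        assert np.corrcoef(pred, y)[0, 1] > 0.99

    def test_reml_lambda_recovery(self):
        """REML recovers lambda = (1 - h2)/h2 within 25% at n = 200
        (median over 20 seeds)."""
        h2 = 0.72
        lam_true = (1 - h2) / h2
        rng = np.random.default_rng(0)
        W = (rng.random((200, 100)) < 0.5).astype(float)
        G = pr.vanraden_kernel(pr.preprocess_features(pd.DataFrame(W, index=range(200))))
        L = np.linalg.cholesky(G.to_numpy() + 1e-8 * np.eye(200))
        errs = []
        for s in range(20):
            r = np.random.default_rng(s)
            g = L @ r.normal(size=200)
            y = g + r.normal(0, np.sqrt(lam_true), 200)
            errs.append(abs(pr._reml_lambda(y, G.to_numpy()) / lam_true - 1))
        assert np.median(errs) < 0.25


class TestCrossValidation:
    def test_run_count_and_determinism(self):
        G = pr.vanraden_kernel(pr.preprocess_features(_W(n=23, m=100)))
        y = pd.Series(np.random.default_rng(0).normal(size=23), index=G.index)
        r1 = pr.cross_validate(y, G, folds=5, reps=20, seed=9)
        r2 = pr.cross_validate(y, G, folds=5, reps=20, seed=9)
        assert len(r1.accuracies) == 100
        assert np.array_equal(r1.accuracies, r2.accuracies, equal_nan=True)

    def test_fold_sizes_for_23(self):
        plans = pr.fold_plan(23, 5, 3, seed=0)
        for assign in plans:
            sizes = sorted(np.bincount(assign), reverse=True)
            assert sizes == [5, 5, 5, 4, 4]

    def test_affine_invariance_of_accuracy(self):
        G = pr.vanraden_kernel(pr.preprocess_features(_W(n=23, m=100, seed=6)))
        y = pd.Series(np.random.default_rng(7).normal(size=23), index=G.index)
        r1 = pr.cross_validate(y, G, reps=5, seed=1)
        r2 = pr.cross_validate(3.0 * y + 10.0, G, reps=5, seed=1)
        assert np.allclose(r1.accuracies, r2.accuracies, equal_nan=True)


class TestGridSearch:
    def _kernels(self, seed=0):
        return {
            "SV": pr.vanraden_kernel(pr.preprocess_features(_W(n=23, m=80, seed=seed))),
            "ePAV": pr.vanraden_kernel(pr.preprocess_features(_W(n=23, m=80, seed=seed + 1))),
            "T": pr.vanraden_kernel(pr.preprocess_features(_W(n=23, m=80, seed=seed + 2))),
        }

    def test_table_row_count(self):
        kernels = self._kernels()
        y = pd.Series(np.random.default_rng(0).normal(size=23), index=kernels["SV"].index)
        table, best = pr.grid_search(y, kernels, reps=2, seed=0, step=0.2)
        assert len(table) == len(pr.simplex_grid(3, 0.2))
        assert sum(best) == pytest.approx(1.0)

    def test_informative_kernel_attracts_weight(self):
        """When one kernel matches the causal structure and the others are
        noise, the maximizing weights concentrate on it (majority of seeds)."""
        hits = 0
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            kernels = self._kernels(seed=3 * seed)
            L = np.linalg.cholesky(kernels["SV"].to_numpy() + 1e-8 * np.eye(23))
            y = pd.Series(L @ rng.normal(size=23) + 0.1 * rng.normal(size=23),
                          index=kernels["SV"].index)
            _, best = pr.grid_search(y, kernels, reps=10, seed=seed, step=0.25)
            hits += best[0] >= 0.5
        assert hits >= 4

    def test_exchangeable_kernels_symmetric_accuracy(self):
        kernels = self._kernels(seed=11)
        kernels["ePAV"] = kernels["SV"].copy()
        y = pd.Series(np.random.default_rng(1).normal(size=23), index=kernels["SV"].index)
        table, _ = pr.grid_search(y, {"a": kernels["SV"], "b": kernels["ePAV"]},
                                  reps=10, seed=2, step=0.5)
        accs = table["median_accuracy"].to_numpy()
        assert np.allclose(accs, accs[0], atol=1e-9)


class TestDownsampling:
    def test_full_fraction_reproduces_pipeline(self, small_panel, small_cfg, small_pheno):
        from pavomics import simulate_variants
        from pavomics import pav_calling as pc

        expr, _, truth = small_panel
        raw = simulate_variants(truth, small_cfg)
        out = pr.downsample_experiment(
            expr, raw, small_pheno, fractions=(1.0,), n_reps=1, seed=4, cv_reps=3
        )
        # reference: the same features computed without thinning
        fpkm = expr.fpkm["seedling"]
        consensus = pc.merge_tissues([pc.call_tissue_pav(fpkm, "seedling")])
        full_t = pr.cross_validate(
            small_pheno,
            pr.vanraden_kernel(pr.preprocess_features(fpkm.T.loc[small_pheno.index])),
            folds=5,
            reps=3,
            seed=4,
            plan=pr.fold_plan(len(small_pheno), 5, 3, 4),
        )
        got = out[(out["predictor"] == "T")]["median_accuracy"].iloc[0]
        assert got == pytest.approx(full_t.median, abs=1e-12)

    def test_thinning_law(self, small_panel, small_cfg, small_pheno):
        """Thinned library sizes are binomial with mean fraction x original."""
        expr, _, _ = small_panel
        frac = 0.05
        orig = float(expr.library_sizes["seedling"].sum())
        rng = np.random.default_rng(0)
        totals = [
            pr._thin_coverage(expr, "seedling", frac, rng)[2].sum() for _ in range(30)
        ]
        expected = frac * orig
        sd = np.sqrt(orig * frac * (1 - frac))
        assert abs(np.mean(totals) - expected) < 3 * sd

    def test_invalid_fraction_rejected(self, small_panel, small_cfg, small_pheno):
        from pavomics import simulate_variants

        expr, _, truth = small_panel
        raw = simulate_variants(truth, small_cfg)
        with pytest.raises(ValueError, match="fraction"):
            pr.downsample_experiment(expr, raw, small_pheno, fractions=(0.0,))
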