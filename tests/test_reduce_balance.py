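import numpy as np
import pytest

from dtipred.dataset import PairFeatureTable, build_dataset, generate_raw_fixture, pair_features
from dtipred.reduce_balance import (BalanceConfig, choose_lambda_reg,
                                    lasso_select, smote_balance)


def make_table(X, y):
    n = len(y)
    return PairFeatureTable(np.array([f"T{i}" for i in range(n)], dtype=object),
                            np.array([f"D{i}" for i in range(n)], dtype=object),
                            np.asarray(y), X,
                            [f"f{j}" for j in range(X.shape[1])])


def random_table(rng, n=40, m=6, informative=None):
    X = rng.normal(size=(n, m))
    y = rng.integers(0, 2, size=n)
    if informative is not None:
        X[:, informative] += 2.0 * y[:, None]
    return make_table(X, y)


class TestLassoSelect:
    def test_unpenalized_full_rank_is_dense(self, rng):
        table = random_table(rng, n=50, m=5)
        model = lasso_select(table, 0.0)
        assert len(model.retained) == 5

    def test_huge_penalty_empty_support(self, rng):
        table = random_table(rng, n=50, m=5)
        assert len(lasso_select(table, 1e6).retained) == 0

    def test_soft_thresholding_on_orthonormal_design(self):
        # orthonormal 8x4 design: beta_hat = soft-threshold(X'y, lambda/2)
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.normal(size=(8, 4)))
        y = rng.integers(0, 2, size=8)
        table = make_table(Q, y)
        for lam in (0.05, 0.3, 1.0):
            model = lasso_select(table, lam, standardize=False)
            ols = Q.T @ y.astype(float)
            expected = np.sign(ols) * np.maximum(np.abs(ols) - lam / 2.0, 0.0)
            np.testing.assert_allclose(model.coefficients, expected, atol=1e-6)

    def test_constant_label_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="both labels"):
            lasso_select(make_table(X, np.ones(10, dtype=int)), 1.0)

    def test_transform_mask_and_dimension_check(self, rng):
        table = random_table(rng, n=60, m=8, informative=[1, 5])
        model = lasso_select(table, 5.0)
        reduced = model.transform(table)
        assert reduced.n_features == len(model.retained)
        # order-preserving: retained indices strictly increasing
        assert (np.diff(model.retained) > 0).all()
        assert reduced.feature_names == [table.feature_names[i] for i in model.retained]
        with pytest.raises(ValueError, match="mismatch"):
            model.transform(random_table(rng, n=5, m=3))

    def test_transform_deterministic(self, rng):
        table = random_table(rng, n=60, m=8, informative=[1])
        model = lasso_select(table, 5.0)
        a = model.transform(table)
        b = model.transform(table)
        np.testing.assert_array_equal(a.X, b.X)


class TestChooseLambda:
    def test_single_point_grid(self, rng):
        table = random_table(rng)
        assert choose_lambda_reg(table, 3, (2.5,), seed=0) == 2.5

    def test_noise_support_shrinks_along_grid(self, rng):
        table = random_table(rng, n=40, m=10)
        grid = (0.0, 1.0, 10.0, 100.0)
        sizes = [len(lasso_select(table, lam).retained) for lam in grid]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        chosen = choose_lambda_reg(table, 3, grid, seed=1)
        assert len(lasso_select(table, chosen).retained) <= sizes[0]

    def test_deterministic_given_seed(self, rng):
        table = random_table(rng, n=50, m=12, informative=[0, 3])
        grid = (0.1, 1.0, 10.0)
        assert choose_lambda_reg(table, 3, grid, seed=9) == \
            choose_lambda_reg(table, 3, grid, seed=9)

    def test_planted_signal_recovered_across_seeds(self):
        """Lasso at the CV-chosen penalty keeps features derived from the
        planted raw inputs in >= 90% of seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            bundle = generate_raw_fixture(n_targets=8, n_drugs=12, n_positives=16,
                                          signal_strength=5.0, seed=200 + seed)
            table = pair_features(build_dataset(bundle))
            lam = choose_lambda_reg(table, 3, (0.1, 1.0, 10.0), seed=seed)
            names = set(lasso_select(table, lam).retained_names)
            planted = bundle.planted_feature_names()
            prot_ok = any(n in names for n in planted if not n.startswith("fp2"))
            drug_ok = any(n in names for n in planted if n.startswith("fp2"))
            hits += prot_ok and drug_ok
        assert hits >= 0.9 * n_seeds


class TestSmote:
    def setup_table(self, rng, n_min=8, n_maj=60, m=5):
        X = np.vstack([rng.normal(5, 1, size=(n_min, m)),
                       rng.normal(0, 1, size=(n_maj, m))])
        y = np.array([1] * n_min + [0] * n_maj)
        return make_table(X, y)

    def test_exact_class_balance_500_120(self, rng):
        table = self.setup_table(rng, n_min=8, n_maj=60)
        out = smote_balance(table, BalanceConfig(500, 120, 5, seed=4))
        m = 8
        assert (out.labels == 1).sum() == 6 * m   # m original + 5m synthetic
        assert (out.labels == 0).sum() == 6 * m   # 1.2 x 5m majority kept
        assert (out.provenance == "synthetic").sum() == 5 * m

    def test_synthetic_rows_on_segment_between_minority_parents(self, rng):
        table = self.setup_table(rng)
        out = smote_balance(table, BalanceConfig(500, 120, 5, seed=0))
        minority = table.X[table.labels == 1]
        lo = minority.min(axis=0) - 1e-12
        hi = minority.max(axis=0) + 1e-12
        syn = out.X[out.provenance == "synthetic"]
        assert ((syn >= lo) & (syn <= hi)).all()
        # each synthetic row is an exact convex combination of two parents:
        # z_new - z = u * (zbar - z) for a single u per row
        for row in syn[:10]:
            found = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    dz = minority[j] - minority[i]
                    num = row - minority[i]
                    nz = np.abs(dz) > 1e-12
                    if not nz.any():
                        continue
                    u = num[nz] / dz[nz]
                    if np.allclose(u, u[0], atol=1e-8) and -1e-9 <= u[0] <= 1 + 1e-9 \
                            and np.allclose(num[~nz], 0, atol=1e-8):
                        found = True
                        break
                if found:
                    break
            assert found

    def test_original_minority_rows_unchanged(self, rng):
        table = self.setup_table(rng)
        out = smote_balance(table, BalanceConfig(500, 120, 5, seed=2))
        orig_min = out.X[(out.labels == 1) & (out.provenance == "original")]
        np.testing.assert_array_equal(np.sort(orig_min, axis=0),
                                      np.sort(table.X[table.labels == 1], axis=0))

    def test_majority_cap(self, rng):
        # majority smaller than 1.2 x synthetic count: keep all of it
        table = self.setup_table(rng, n_min=8, n_maj=20)
        out = smote_balance(table, BalanceConfig(500, 120, 5, seed=1))
        assert (out.labels == 0).sum() == 20

    def test_minority_too_small_for_k(self, rng):
        table = self.setup_table(rng, n_min=4, n_maj=30)
        with pytest.raises(ValueError, match="smaller k"):
            smote_balance(table, BalanceConfig(500, 120, 5, seed=0))

    def test_reproducible_under_seed(self, rng):
        table = self.setup_table(rng)
        a = smote_balance(table, BalanceConfig(500, 120, 5, seed=11))
        b = smote_balance(table, BalanceConfig(500, 120, 5, seed=11))
        np.testing.assert_array_equal(a.X, b.X)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BalanceConfig(perc_over=250)
        with pytest.raises(ValueError):
            BalanceConfig(k_neighbors=0)
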