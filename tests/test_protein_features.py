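import numpy as np
import pytest

from dtipred.profile_io import NormalizedProfile
from dtipred.protein_features import (PAIR_ORDER, dcca_pair, dcca_vector,
                                      psepssm, protein_feature_names,
                                      protein_feature_vector)


# --- independent brute-force oracle ----------------------------------------

def dcca_naive(x, y, s):
    """Literal window-by-window re-implementation with explicit normal
    equations; independent of the vectorized production path."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    L = len(x)
    X = np.array([x[:k + 1].sum() for k in range(L)])
    Y = np.array([y[:k + 1].sum() for k in range(L)])
    fxy, fxx, fyy = [], [], []
    for i in range(L - s):  # window starts i .. i+s (0-based)
        ks = np.arange(i, i + s + 1, dtype=float)
        resid = {}
        for name, series in (("x", X), ("y", Y)):
            w = series[i:i + s + 1]
            n = s + 1
            # normal equations for intercept a and slope b of w ~ a + b*k
            sk, sw, skk, skw = ks.sum(), w.sum(), (ks * ks).sum(), (ks * w).sum()
            b = (n * skw - sk * sw) / (n * skk - sk * sk)
            a = (sw - b * sk) / n
            resid[name] = w - (a + b * ks)
        fxy.append((resid["x"] * resid["y"]).sum() / (s + 1))
        fxx.append((resid["x"] ** 2).sum() / (s + 1))
        fyy.append((resid["y"] ** 2).sum() / (s + 1))
    return np.mean(fxy) / (np.sqrt(np.mean(fxx)) * np.sqrt(np.mean(fyy)))


def psepssm_naive(values, lam):
    L, _ = values.shape
    out = list(values.mean(axis=0))
    for l in range(1, lam + 1):
        for j in range(20):
            out.append(sum((values[i, j] - values[i + l, j]) ** 2
                           for i in range(L - l)) / (L - l))
    return np.array(out)


# --- PsePSSM ----------------------------------------------------------------

class TestPsePssm:
    def test_lambda_zero_is_column_means(self, random_normalized_profile):
        v = psepssm(random_normalized_profile, 0)
        assert v.values.shape == (20,)
        np.testing.assert_allclose(v.values, random_normalized_profile.values.mean(axis=0))

    def test_constant_columns_zero_theta(self):
        values = np.tile(np.linspace(0.1, 0.9, 20), (30, 1))
        v = psepssm(NormalizedProfile("c", values), 4)
        assert np.allclose(v.values[20:], 0.0)

    def test_lambda_three_gives_80_features(self, random_normalized_profile):
        assert psepssm(random_normalized_profile, 3).values.shape == (80,)

    def test_alternating_column_hand_expansion(self):
        # L=4, column (a,b,a,b), lag 1: theta = ((a-b)^2 * 3) / 3 = (a-b)^2
        a, b = 0.2, 0.7
        values = np.full((4, 20), 0.5)
        values[:, 3] = [a, b, a, b]
        v = psepssm(NormalizedProfile("alt", values), 1)
        assert v.values[20 + 3] == pytest.approx((a - b) ** 2, rel=1e-14)

    @pytest.mark.parametrize("lam", [0, 1, 5, 15])
    def test_length_contract(self, random_normalized_profile, lam):
        assert len(psepssm(random_normalized_profile, lam).values) == 20 + 20 * lam

    def test_lambda_at_length_is_domain_error(self, rng):
        values = rng.uniform(0.1, 0.9, size=(5, 20))
        with pytest.raises(ValueError, match="lambda_order"):
            psepssm(NormalizedProfile("short", values), 5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.05, 0.95, size=(rng.integers(10, 40), 20))
        prof = NormalizedProfile("o", values)
        lam = int(rng.integers(0, 5))
        np.testing.assert_allclose(psepssm(prof, lam).values,
                                   psepssm_naive(values, lam), atol=1e-12)


# --- DCCA -------------------------------------------------------------------

class TestDccaPair:
    def test_self_correlation_is_one(self, rng):
        x = rng.uniform(0, 1, 50)
        assert dcca_pair(x, x, 7) == 1.0

    def test_anti_correlation_is_minus_one(self, rng):
        x = rng.uniform(0, 1, 50)
        assert dcca_pair(x, -x, 7) == -1.0

    def test_matches_bruteforce_on_small_series(self):
        rng = np.random.default_rng(99)
        x = rng.uniform(0, 1, 8)
        y = rng.uniform(0, 1, 8)
        assert dcca_pair(x, y, 3) == pytest.approx(dcca_naive(x, y, 3), abs=1e-12)

    def test_single_window_case(self, rng):
        # L = s+1 gives exactly one window
        s = 6
        x = rng.uniform(0, 1, s + 1)
        y = rng.uniform(0, 1, s + 1)
        assert dcca_pair(x, y, s) == pytest.approx(dcca_naive(x, y, s), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.uniform(0, 1, 30), rng.uniform(0, 1, 30)
        assert dcca_pair(x, y, 5) == pytest.approx(dcca_pair(y, x, 5), abs=1e-14)

    @pytest.mark.parametrize("shift", [-3.0, 0.7, 100.0])
    def test_constant_shift_invariance(self, rng, shift):
        x, y = rng.uniform(0, 1, 40), rng.uniform(0, 1, 40)
        base = dcca_pair(x, y, 6)
        assert dcca_pair(x + shift, y, 6) == pytest.approx(base, abs=1e-9)
        assert dcca_pair(x, y + shift, 6) == pytest.approx(base, abs=1e-9)

    @pytest.mark.parametrize("c", [-2.5, -1.0, 0.5, 4.0])
    def test_scale_antisymmetry(self, rng, c):
        x, y = rng.uniform(0, 1, 40), rng.uniform(0, 1, 40)
        assert dcca_pair(x, c * y, 6) == pytest.approx(
            np.sign(c) * dcca_pair(x, y, 6), abs=1e-12)

    def test_constant_series_returns_zero_with_warning(self, rng, caplog):
        x = rng.uniform(0, 1, 30)
        with caplog.at_level("WARNING"):
            assert dcca_pair(x, np.full(30, 0.4), 5) == 0.0
        assert "undefined" in caplog.text

    @pytest.mark.parametrize("s", [0, 1, 30, 50])
    def test_out_of_range_s_rejected(self, rng, s):
        x = rng.uniform(0, 1, 30)
        with pytest.raises(ValueError):
            dcca_pair(x, x, s)


class TestDccaVector:
    def test_length_and_bounds(self, random_normalized_profile):
        v = dcca_vector(random_normalized_profile, 36)
        assert v.values.shape == (190,)
        assert (np.abs(v.values) <= 1).all()

    def test_identical_columns_give_unity(self, rng):
        values = rng.uniform(0.1, 0.9, size=(60, 20))
        values[:, 7] = values[:, 2]
        v = dcca_vector(NormalizedProfile("dup", values), 10)
        idx = PAIR_ORDER.index((2, 7))
        assert v.values[idx] == 1.0

    def test_matches_naive_oracle_per_pair(self, rng):
        values = rng.uniform(0.1, 0.9, size=(25, 20))
        prof = NormalizedProfile("o", values)
        v = dcca_vector(prof, 5)
        for idx in [0, 17, 100, 189]:
            j, jp = PAIR_ORDER[idx]
            assert v.values[idx] == pytest.approx(
                dcca_naive(values[:, j], values[:, jp], 5), abs=1e-12)

    def test_s_too_large_names_protein_and_length(self, rng):
        values = rng.uniform(0.1, 0.9, size=(20, 20))
        with pytest.raises(ValueError, match="shorty.*L=20"):
            dcca_vector(NormalizedProfile("shorty", values), 36)


def test_concatenated_feature_vector_and_names(random_normalized_profile):
    vec = protein_feature_vector(random_normalized_profile, 3, 36)
    names = protein_feature_names(3)
    assert len(vec) == len(names) == 270
    assert names[0] == "psepssm_mean_A"
    assert names[20] == "psepssm_l1_A"
    assert names[80] == "dcca_A_R"
    assert names[-1] == "dcca_Y_V"
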