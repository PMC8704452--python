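import numpy as np
import pytest

from dtipred.dataset import SyntheticDtiBundle
from dtipred.profile_io import AMINO_ACIDS, ProfileMatrix, NormalizedProfile
from dtipred.drug_features import FingerprintVector
from dtipred.pipeline import PipelineConfig
from dtipred.classify_eval import ForestConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_profile():
    """5-residue profile with hand-picked scores."""
    scores = np.zeros((5, 20), dtype=np.int64)
    scores[0, 0] = -2
    scores[1, 1] = 11
    scores[2, 5] = -9
    return ProfileMatrix("toy", "MKVLA", scores)


@pytest.fixture
def random_normalized_profile(rng):
    values = rng.uniform(0.05, 0.95, size=(100, 20))
    return NormalizedProfile("rand", values)


def make_profile(rng, protein_id="P", L=90):
    scores = np.clip(np.rint(rng.normal(-2, 3, size=(L, 20))), -9, 11).astype(np.int64)
    residues = "".join(rng.choice(list(AMINO_ACIDS), size=L))
    return ProfileMatrix(protein_id, residues, scores)


@pytest.fixture
def fast_config():
    """Pipeline config sized for unit tests: small forest, condensed grid."""
    return PipelineConfig(forest=ForestConfig(n_trees=60),
                          lasso_grid=(0.1, 1.0, 10.0))


def lag2_bundle(seed: int, n_targets: int = 40, L: int = 80,
                c: int = 4, d: int = 1) -> SyntheticDtiBundle:
    """Fixture whose class signal lives only in lag-2 profile differences.

    Half the targets are active. Column 0 of an active profile follows the
    period-4 pattern (0, c, 0, -c); inactive profiles alternate (-d, d).
    Both patterns have identical normalized column means and nearly
    identical lag-1 squared-difference statistics, but the lag-2 statistic
    is far larger for active targets. A single drug is used so every target
    occurs in exactly one pair and cross-validation cannot memorize
    entities across folds.
    """
    rng = np.random.default_rng(seed)
    profiles, active = [], set()
    for i in range(n_targets):
        tid = f"T{i:04d}"
        is_active = i < n_targets // 2
        if is_active:
            active.add(tid)
        scores = np.clip(np.rint(rng.normal(-2, 3, size=(L, 20))), -9, 11).astype(np.int64)
        phase = int(rng.integers(0, 4))
        base = [0, c, 0, -c] if is_active else [-d, d, -d, d]
        col = np.array([base[(k + phase) % 4] for k in range(L)])
        scores[:, 0] = np.clip(col + rng.integers(-1, 2, size=L), -9, 11)
        residues = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        profiles.append(ProfileMatrix(tid, residues, scores))
    fps = [FingerprintVector("D0000", rng.integers(0, 16, size=256))]
    edges = [(t, "D0000") for t in sorted(active)]
    return SyntheticDtiBundle(profiles, fps, edges, active, {"D0000"}, (0,), (), 0.0)
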