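"""Fixed-length protein descriptors from a normalized evolutionary profile.

Two descriptors are computed per protein:

* **PsePSSM** — the 20 column means of the normalized profile followed, for
  each lag ``lambda' = 1..lambda_order``, by the 20 mean squared differences
  between profile entries ``lambda'`` positions apart:

  ``theta_j(lam) = 1/(L-lam) * sum_i (E'[i,j] - E'[i+lam,j])**2``

  Length 20 + 20*lambda_order; at lambda_order = 0 it reduces to the plain
  column-mean profile summary.

* **DCCA coefficient vector** — each of the C(20,2) = 190 unordered column
  pairs of the profile is treated as two length-L series and summarized by
  the detrended cross-correlation coefficient rho_DCCA(s): cumulative sums
  of both series are split into L-s overlapping windows of s+1 points, each
  window is linearly detrended by ordinary least squares, and rho is the
  ratio of the window-averaged residual covariance to the product of the
  window-averaged residual standard deviations. rho lies in [-1, 1]; 1 is
  perfect cross-correlation, -1 perfect anti-correlation.

Defaults ``lambda_order = 3`` and ``segment_length = 36`` give the
80 + 190 = 270 protein features used throughout the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .profile_io import AMINO_ACIDS, NormalizedProfile

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 3
DEFAULT_SEGMENT = 36

#: The 190 unordered column pairs in fixed lexicographic order (0-based).
PAIR_ORDER: tuple[tuple[int, int], ...] = tuple(combinations(range(20), 2))


@dataclass(frozen=True)
class PsePssmVector:
    protein_id: str
    lambda_order: int
    values: np.ndarray  # length 20 + 20*lambda_order

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (20 + 20 * self.lambda_order,):
            raise ValueError(f"expected length {20 + 20 * self.lambda_order}, got {values.shape}")


@dataclass(frozen=True)
class DccaVector:
    protein_id: str
    segment_length: int
    values: np.ndarray  # length 190, one rho per pair in PAIR_ORDER

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (190,):
            raise ValueError(f"expected length 190, got {values.shape}")


def psepssm(profile: NormalizedProfile, lambda_order: int = DEFAULT_LAMBDA) -> PsePssmVector:
    """Compute the PsePSSM descriptor (length ``20 + 20*lambda_order``).

    Raises ``ValueError`` if ``lambda_order`` is negative or >= the sequence
    length L (the lagged sums need at least one term).
    """
    E = profile.values
    L = E.shape[0]
    if lambda_order < 0:
        raise ValueError("lambda_order must be non-negative")
    if lambda_order >= L:
        raise ValueError(
            f"lambda_order={lambda_order} must be < sequence length L={L} "
            f"for protein {profile.protein_id!r}")
    parts = [E.mean(axis=0)]
    for lam in range(1, lambda_order + 1):
        diff = E[:-lam] - E[lam:]
        parts.append((diff ** 2).mean(axis=0))
    return PsePssmVector(profile.protein_id, lambda_order, np.concatenate(parts))


def _window_residuals(series: np.ndarray, s: int) -> np.ndarray:
    """OLS straight-line residuals of the cumulative profile in each window.

    Returns an (L - s) x (s + 1) array: row i holds the residuals of the
    cumulative sums in the window starting at position i, after removing the
    best least-squares line in the window index.
    """
    L = series.shape[0]
    profile = np.cumsum(series)
    # all windows of length s+1, stride 1
    windows = np.lib.stride_tricks.sliding_window_view(profile, s + 1)  # (L-s, s+1)
    # residual-maker for the design [1, k]; shifting k by the window start is
    # an affine reparametrization, so relative indices 0..s give identical
    # residuals to absolute ones
    k = np.arange(s + 1, dtype=float)
    X = np.column_stack([np.ones(s + 1), k])
    hat = X @ np.linalg.inv(X.T @ X) @ X.T
    resid_maker = np.eye(s + 1) - hat
    return windows @ resid_maker.T


def dcca_pair(x: np.ndarray, y: np.ndarray, s: int) -> float:
    """Detrended cross-correlation coefficient of two equal-length series.

    ``s`` sets the window length (each window covers s+1 points); valid
    range is ``2 <= s <= L - 1``. Covariances use divisor s+1 within each
    window and the L-s windows are averaged before taking the ratio. The
    result is clipped to [-1, 1] against floating-point overshoot. If either
    series has zero detrended variance in every window (e.g. a constant
    series) the coefficient is undefined and 0 is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    L = x.shape[0]
    if not (2 <= s <= L - 1):
        raise ValueError(f"segment parameter s={s} outside valid range [2, {L - 1}]")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        # a constant series gives an exactly linear cumulative profile;
        # its detrended variance is 0 up to rounding and rho is undefined
        logger.warning("constant series: DCCA coefficient undefined, returning 0")
        return 0.0
    rx = _window_residuals(x, s)
    ry = _window_residuals(y, s)
    # per-window covariance with divisor s+1, then averaged over L-s windows
    f_xy = (rx * ry).sum(axis=1).mean() / (s + 1)
    f_xx = (rx * rx).sum(axis=1).mean() / (s + 1)
    f_yy = (ry * ry).sum(axis=1).mean() / (s + 1)
    return _rho(f_xy, f_xx, f_yy)


def _rho(f_xy: float, f_xx: float, f_yy: float) -> float:
    """f_xy / sqrt(f_xx * f_yy), exactly +-1 for perfectly (anti)correlated
    residuals and clipped against floating-point overshoot otherwise."""
    den2 = f_xx * f_yy
    if den2 == 0.0:
        logger.warning("zero detrended variance; DCCA coefficient undefined, returning 0")
        return 0.0
    if f_xy * f_xy == den2:
        return 1.0 if f_xy > 0 else -1.0
    return float(np.clip(f_xy / np.sqrt(den2), -1.0, 1.0))


def dcca_vector(profile: NormalizedProfile, s: int = DEFAULT_SEGMENT) -> DccaVector:
    """All-pairs DCCA coefficients of the 20 profile columns (length 190).

    Pairs are ordered lexicographically: (A,R), (A,N), ..., (Y,V).
    """
    L = profile.length
    if not (2 <= s <= L - 1):
        raise ValueError(
            f"segment parameter s={s} infeasible for protein "
            f"{profile.protein_id!r} with L={L} (need 2 <= s <= L-1)")
    # detrended window residuals per column, computed once
    resids = [_window_residuals(profile.values[:, j], s) for j in range(20)]
    f_xx = np.array([(r * r).sum(axis=1).mean() for r in resids]) / (s + 1)
    constant = np.array([np.ptp(profile.values[:, j]) == 0.0 for j in range(20)])
    values = np.empty(190)
    for idx, (j, jp) in enumerate(PAIR_ORDER):
        if constant[j] or constant[jp]:
            logger.warning(
                "constant column in pair (%s,%s) of %s; rho set to 0",
                AMINO_ACIDS[j], AMINO_ACIDS[jp], profile.protein_id)
            values[idx] = 0.0
            continue
        f_xy = (resids[j] * resids[jp]).sum(axis=1).mean() / (s + 1)
        values[idx] = _rho(f_xy, f_xx[j], f_xx[jp])
    return DccaVector(profile.protein_id, s, values)


def protein_feature_vector(profile: NormalizedProfile,
                           lambda_order: int = DEFAULT_LAMBDA,
                           s: int = DEFAULT_SEGMENT) -> np.ndarray:
    """Concatenated PsePSSM followed by DCCA features for one protein."""
    return np.concatenate([psepssm(profile, lambda_order).values,
                           dcca_vector(profile, s).values])


def protein_feature_names(lambda_order: int = DEFAULT_LAMBDA) -> list[str]:
    """Column names matching :func:`protein_feature_vector` output order."""
    names = [f"psepssm_mean_{aa}" for aa in AMINO_ACIDS]
    for lam in range(1, lambda_order + 1):
        names += [f"psepssm_l{lam}_{aa}" for aa in AMINO_ACIDS]
    names += [f"dcca_{AMINO_ACIDS[j]}_{AMINO_ACIDS[jp]}" for j, jp in PAIR_ORDER]
    return names
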