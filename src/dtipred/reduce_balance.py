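"""L1 feature selection and SMOTE class rebalancing.

Feature selection minimizes the squared-error Lasso objective on the 0/1
interaction label::

    sum_n (y_n - sum_m x_nm * beta_m)^2  +  lambda_reg * sum_m |beta_m|

(regression-form Lasso, not logistic). Features are standardized to zero
mean and unit variance before fitting and coefficients are reported on the
standardized scale; features with non-zero coefficients are retained.

Rebalancing follows the DMwR convention of SMOTE with coupled majority
undersampling: ``perc_over = 500`` creates 5 synthetic rows per minority
row by uniform interpolation toward one of its ``k = 5`` nearest minority
neighbors, and ``perc_under = 120`` keeps 1.2 x (number of synthetic rows)
majority rows, sampled uniformly without replacement. With defaults
(500, 120, 5) and m minority rows this yields exactly 6m minority
(m original + 5m synthetic) and 6m majority rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.model_selection import KFold

from .dataset import PairFeatureTable


@dataclass(frozen=True)
class BalanceConfig:
    """DMwR-style SMOTE parameters: percentages and neighbor count."""

    perc_over: int = 500
    perc_under: int = 120
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.perc_over % 100 != 0 or self.perc_over < 100:
            raise ValueError("perc_over must be a positive multiple of 100")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.perc_under < 0:
            raise ValueError("perc_under must be non-negative")


@dataclass
class SelectionModel:
    """Fitted Lasso selector: coefficients, support, and the transform."""

    lambda_reg: float
    coefficients: np.ndarray  # standardized scale
    intercept: float
    mean_: np.ndarray
    scale_: np.ndarray
    feature_names: list[str]

    @property
    def retained(self) -> np.ndarray:
        """Indices of features with non-zero coefficients, ascending."""
        return np.flatnonzero(self.coefficients)

    @property
    def retained_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.retained]

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return self.intercept + Xs @ self.coefficients

    def transform(self, table: PairFeatureTable) -> PairFeatureTable:
        """Keep only the retained feature columns of ``table``."""
        if table.n_features != len(self.coefficients):
            raise ValueError(
                f"feature dimension mismatch: table has {table.n_features}, "
                f"selector was fit on {len(self.coefficients)}")
        idx = self.retained
        return PairFeatureTable(table.target_ids, table.drug_ids, table.labels,
                                table.X[:, idx],
                                [table.feature_names[i] for i in idx],
                                table.provenance)

    def save_mask(self, path) -> None:
        from pathlib import Path
        Path(path).write_text("\n".join(self.retained_names) + "\n")


def _fit_lasso(X: np.ndarray, y: np.ndarray, lambda_reg: float,
               standardize: bool) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    n = X.shape[0]
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0  # constant columns carry no signal
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xs = (X - mean) / scale
    if lambda_reg == 0.0:
        model = LinearRegression(fit_intercept=standardize)
    else:
        # sklearn minimizes (1/2n)||y-Xb||^2 + alpha||b||_1; the unscaled
        # objective sum(y-Xb)^2 + lambda||b||_1 corresponds to alpha = lambda/(2n)
        model = Lasso(alpha=lambda_reg / (2.0 * n), fit_intercept=standardize,
                      max_iter=50_000, tol=1e-8)
    with warnings.catch_warnings():
        # near-converged duality gaps (~1e-6) are irrelevant for support recovery
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xs, y)
    coef = np.asarray(model.coef_, dtype=float).ravel()
    intercept = float(model.intercept_) if standardize else 0.0
    return coef, intercept, mean, scale


def lasso_select(table: PairFeatureTable, lambda_reg: float,
                 standardize: bool = True) -> SelectionModel:
    """Fit the squared-error Lasso on the 0/1 label and return the support.

    ``lambda_reg`` is the weight of the L1 penalty in the *unscaled*
    objective (no 1/N factor). ``standardize=False`` fits the raw design
    without intercept, matching the textbook objective exactly (used for
    closed-form checks on orthonormal designs).
    """
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be non-negative")
    y = table.labels.astype(float)
    if len(y) < 2 or len(np.unique(y)) < 2:
        raise ValueError("lasso_select needs >= 2 rows with both labels present")
    coef, intercept, mean, scale = _fit_lasso(table.X, y, lambda_reg, standardize)
    return SelectionModel(lambda_reg, coef, intercept, mean, scale,
                          list(table.feature_names))


def choose_lambda_reg(table: PairFeatureTable, n_folds: int,
                      grid: tuple[float, ...], seed: int = 0) -> float:
    """Pick the penalty weight minimizing cross-validated squared error.

    Deterministic given ``seed``; ties broken toward the larger penalty
    (sparser model).
    """
    grid = tuple(grid)
    if not grid:
        raise ValueError("lambda grid must be nonempty")
    if len(grid) == 1:
        return float(grid[0])
    y = table.labels.astype(float)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed % (2 ** 31))
    errors = {lam: 0.0 for lam in grid}
    for train_idx, val_idx in kf.split(table.X):
        for lam in grid:
            coef, intercept, mean, scale = _fit_lasso(
                table.X[train_idx], y[train_idx], lam, standardize=True)
            pred = intercept + ((table.X[val_idx] - mean) / scale) @ coef
            errors[lam] += float(((y[val_idx] - pred) ** 2).sum())
    best = min(grid, key=lambda lam: (errors[lam], -lam))
    return float(best)


def smote_balance(table: PairFeatureTable, cfg: BalanceConfig) -> PairFeatureTable:
    """Oversample the minority class by interpolation and undersample the rest.

    Every synthetic row is ``z + U * (zbar - z)`` for a minority row z, a
    uniformly chosen member zbar of its k nearest minority neighbors
    (Euclidean distance, ties broken by row index) and a single
    U ~ Uniform(0, 1) per row, so it lies on the segment between its
    parents. Original minority rows are all kept unchanged; majority rows
    are subsampled to ``perc_under/100 x (synthetic count)``, capped at the
    majority size. Synthetic rows carry provenance "synthetic" and their
    seed parent's pair ids.
    """
    labels = table.labels
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    minority_label = 1 if n_pos <= n_neg else 0
    min_idx = np.flatnonzero(labels == minority_label)
    maj_idx = np.flatnonzero(labels != minority_label)
    k = cfg.k_neighbors
    if len(min_idx) < k + 1:
        raise ValueError(
            f"minority class has {len(min_idx)} rows; SMOTE with k={k} needs "
            f"at least {k + 1} (use a smaller k_neighbors)")

    rng = np.random.default_rng(cfg.seed)
    Xmin = table.X[min_idx]
    # pairwise distances within the minority class; neighbor ties by row index
    d2 = ((Xmin[:, None, :] - Xmin[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    n_syn_per = cfg.perc_over // 100

    syn_rows, syn_t, syn_d = [], [], []
    for i in range(len(min_idx)):
        order = np.lexsort((np.arange(len(min_idx)), d2[i]))
        neighbors = order[:k]
        for _ in range(n_syn_per):
            j = int(rng.choice(neighbors))
            u = rng.uniform(0.0, 1.0)
            syn_rows.append(Xmin[i] + u * (Xmin[j] - Xmin[i]))
            syn_t.append(table.target_ids[min_idx[i]])
            syn_d.append(table.drug_ids[min_idx[i]])

    n_syn = len(syn_rows)
    n_keep = min(int(round(cfg.perc_under / 100.0 * n_syn)), len(maj_idx))
    kept_maj = np.sort(rng.choice(maj_idx, size=n_keep, replace=False))

    X = np.vstack([table.X[min_idx], np.vstack(syn_rows), table.X[kept_maj]])
    target_ids = np.concatenate([table.target_ids[min_idx], np.array(syn_t, dtype=object),
                                 table.target_ids[kept_maj]])
    drug_ids = np.concatenate([table.drug_ids[min_idx], np.array(syn_d, dtype=object),
                               table.drug_ids[kept_maj]])
    labels_out = np.concatenate([np.full(len(min_idx), minority_label),
                                 np.full(n_syn, minority_label),
                                 np.full(n_keep, 1 - minority_label)])
    provenance = np.concatenate([table.provenance[min_idx],
                                 np.full(n_syn, "synthetic", dtype=object),
                                 table.provenance[kept_maj]])
    return PairFeatureTable(target_ids, drug_ids, labels_out, X,
                            table.feature_names, provenance)
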