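"""Random-forest classification and cross-validated evaluation.

The classifier is a bagged ensemble of unpruned decision trees, each grown
on a bootstrap resample with ``mtry`` candidate features per split;
predicted interaction probability is the fraction of trees voting for the
positive class. Scalar metrics are computed at the fixed probability
threshold 0.5 (a pair is called interacting when its probability exceeds
0.5): ACC, sensitivity SE = TP/(TP+FN), specificity SP = TN/(TN+FP),
F = 2TP/(2TP+FP+FN), precision and recall, plus ROC/PR curves with AUC
(trapezoid) and AUPR (step-wise summation, no interpolation).

Cross-validation partitions the drug-target *pairs* at random into
``n_folds`` near-equal folds. In the default ``train_only`` mode, feature
selection and SMOTE are fit on the training folds only and the held-out
fold stays untouched. In ``global`` mode selection and balancing precede
the split, so held-out folds contain SMOTE-synthesized rows — this
reproduces the historical protocol but leaks minority structure into the
test set and inflates the apparent performance; reports always name the
mode used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve
from sklearn.metrics import auc as _trapezoid_auc

from .dataset import DtiDataset, PairFeatureTable, pair_features
from .reduce_balance import BalanceConfig, choose_lambda_reg, lasso_select, smote_balance

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import PipelineConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters.

    ``mtry=None`` means floor(sqrt(Q)) features per split, the conventional
    classification default.
    """

    n_trees: int = 500
    mtry: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class EvalReport:
    """Confusion counts, threshold-0.5 scalar metrics, and ranking curves."""

    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    se: float
    sp: float
    f: float
    precision: float
    recall: float
    auc: float = float("nan")
    aupr: float = float("nan")
    roc: tuple[np.ndarray, np.ndarray] | None = None  # (FPR, TPR)
    pr: tuple[np.ndarray, np.ndarray] | None = None   # (recall, precision)

    def to_dict(self) -> dict:
        return {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
                "ACC": self.acc, "SE": self.se, "SP": self.sp, "F": self.f,
                "P": self.precision, "R": self.recall,
                "AUC": self.auc, "AUPR": self.aupr}


def train_forest(table: PairFeatureTable, cfg: ForestConfig,
                 oob_score: bool = False) -> RandomForestClassifier:
    """Fit the forest; probability output is the positive-vote fraction.

    Unpruned trees on bootstrap resamples; raises on single-class input.
    ``oob_score=True`` additionally records out-of-bag accuracy.
    """
    y = table.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    mtry = cfg.mtry if cfg.mtry is not None else max(1, int(np.sqrt(table.n_features)))
    if mtry > table.n_features:
        raise ValueError(f"mtry={mtry} exceeds feature count {table.n_features}")
    clf = RandomForestClassifier(n_estimators=cfg.n_trees, max_features=mtry,
                                 bootstrap=True, random_state=cfg.seed % (2 ** 31),
                                 oob_score=oob_score, n_jobs=1)
    clf.fit(table.X, y)
    return clf


def predict_proba(clf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Positive-class probability for each row."""
    pos_col = list(clf.classes_).index(1)
    return clf.predict_proba(X)[:, pos_col]


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(labels: np.ndarray, probabilities: np.ndarray,
                    threshold: float = 0.5) -> EvalReport:
    """Confusion counts and scalar metrics at a fixed probability threshold.

    A pair is predicted interacting when its probability is strictly
    greater than ``threshold``. Ratios with zero denominators are reported
    as NaN, never silently as 0.
    """
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, dtype=float)
    if labels.size == 0:
        raise ValueError("empty evaluation set")
    pred = probabilities > threshold
    pos = labels == 1
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    se = _ratio(tp, tp + fn)
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn,
                      acc=_ratio(tp + tn, tp + tn + fp + fn),
                      se=se,
                      sp=_ratio(tn, tn + fp),
                      f=_ratio(2 * tp, 2 * tp + fp + fn),
                      precision=_ratio(tp, tp + fp),
                      recall=se)


def curves(labels: np.ndarray, probabilities: np.ndarray
           ) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray], float, float]:
    """ROC and PR curves with AUC and AUPR.

    Thresholds sweep the distinct scores (equal scores grouped); AUC is the
    trapezoid area under ROC, AUPR the step-wise precision-recall sum
    without interpolation. Raises on single-class labels, where neither
    curve is defined.
    """
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("curves undefined: labels contain a single class")
    fpr, tpr, _ = roc_curve(labels, probabilities, drop_intermediate=False)
    auc_value = float(_trapezoid_auc(fpr, tpr))
    prec, rec, _ = precision_recall_curve(labels, probabilities)
    aupr_value = float(average_precision_score(labels, probabilities))
    return (fpr, tpr), (rec, prec), auc_value, aupr_value


def evaluate(labels: np.ndarray, probabilities: np.ndarray,
             threshold: float = 0.5) -> EvalReport:
    """Scalar metrics plus curves in one report; curves NaN if single-class."""
    report = compute_metrics(labels, probabilities, threshold)
    try:
        report.roc, report.pr, report.auc, report.aupr = curves(labels, probabilities)
    except ValueError:
        warnings.warn("single-class evaluation fold: AUC/AUPR undefined (NaN)")
    return report


@dataclass
class CvResult:
    """Per-fold reports plus mean/SD summaries of the scalar metrics."""

    folds: list[EvalReport]
    balance_scope: str
    fold_assignment: np.ndarray  # fold id per evaluated row

    def _values(self, key: str) -> np.ndarray:
        return np.array([r.to_dict()[key] for r in self.folds], dtype=float)

    def mean(self) -> dict[str, float]:
        keys = ("ACC", "SE", "SP", "F", "P", "R", "AUC", "AUPR")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return {k: float(np.nanmean(self._values(k))) for k in keys}

    def sd(self) -> dict[str, float]:
        keys = ("ACC", "SE", "SP", "F", "P", "R", "AUC", "AUPR")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return {k: float(np.nanstd(self._values(k))) for k in keys}


def _fold_ids(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random partition into n_folds near-equal folds (sizes differ by <= 1)."""
    perm = rng.permutation(n)
    ids = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, n_folds)):
        ids[chunk] = fold
    return ids


def _select_lambda(table: PairFeatureTable, config: "PipelineConfig", seed: int) -> float:
    grid = tuple(config.lasso_grid)
    if len(grid) == 1:
        return float(grid[0])
    return choose_lambda_reg(table, n_folds=3, grid=grid, seed=seed)


def _balance_capped(table: PairFeatureTable, config: "PipelineConfig",
                    seed: int) -> PairFeatureTable:
    """SMOTE with k capped at minority-1 so small training folds still run."""
    n_min = int(min((table.labels == 1).sum(), (table.labels == 0).sum()))
    k = config.balance.k_neighbors
    if n_min < 2:
        warnings.warn("minority class too small for SMOTE; fold left unbalanced")
        return table
    if n_min < k + 1:
        warnings.warn(f"minority class has {n_min} rows; capping SMOTE k at {n_min - 1}")
        k = n_min - 1
    return smote_balance(table, BalanceConfig(config.balance.perc_over,
                                              config.balance.perc_under, k, seed=seed))


def _fit_and_score(train: PairFeatureTable, test: PairFeatureTable,
                   config: "PipelineConfig", seed: int,
                   balance: bool) -> EvalReport:
    lam = _select_lambda(train, config, seed)
    selector = lasso_select(train, lam)
    if len(selector.retained) == 0:
        logger.warning("Lasso retained no features (lambda=%g); falling back to all", lam)
    else:
        train = selector.transform(train)
        test = selector.transform(test)
    if balance:
        train = _balance_capped(train, config, seed)
    forest_cfg = ForestConfig(config.forest.n_trees, config.forest.mtry, seed=seed)
    clf = train_forest(train, forest_cfg)
    return evaluate(test.labels, predict_proba(clf, test.X))


def cross_validate(dataset: DtiDataset | PairFeatureTable, config: "PipelineConfig",
                   n_folds: int | None = None, seed: int | None = None) -> CvResult:
    """K-fold cross-validation of the full selection + balancing + forest stack.

    The unit of splitting is the drug-target pair. ``balance_scope`` in the
    config decides whether Lasso and SMOTE are fit inside each training
    fold (``train_only``, the sound default) or once on the complete table
    before splitting (``global``, the historical leaky protocol whose test
    folds contain synthetic rows).
    """
    table = dataset if isinstance(dataset, PairFeatureTable) else pair_features(dataset)
    n_folds = config.n_folds if n_folds is None else n_folds
    seed = config.seed if seed is None else seed
    scope = config.balance_scope
    if scope not in ("train_only", "global"):
        raise ValueError(f"unknown balance_scope {scope!r}")
    rng = np.random.default_rng(seed)

    if scope == "global":
        lam = _select_lambda(table, config, seed)
        selector = lasso_select(table, lam)
        if len(selector.retained) > 0:
            table = selector.transform(table)
        table = _balance_capped(table, config, seed)

    n = len(table.labels)
    fold_ids = _fold_ids(n, n_folds, rng)
    reports = []
    for fold in range(n_folds):
        test_mask = fold_ids == fold
        train_tbl = table.subset_rows(np.flatnonzero(~test_mask))
        test_tbl = table.subset_rows(np.flatnonzero(test_mask))
        if test_tbl.labels.sum() == 0:
            warnings.warn(f"fold {fold} has no positive pairs; positive-class "
                          "metrics will be NaN")
        fold_seed = int(rng.integers(2 ** 31))
        if scope == "global":
            clf = train_forest(train_tbl, ForestConfig(config.forest.n_trees,
                                                       config.forest.mtry, seed=fold_seed))
            reports.append(evaluate(test_tbl.labels, predict_proba(clf, test_tbl.X)))
        else:
            reports.append(_fit_and_score(train_tbl, test_tbl, config,
                                          fold_seed, balance=True))
    return CvResult(folds=reports, balance_scope=scope, fold_assignment=fold_ids)
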