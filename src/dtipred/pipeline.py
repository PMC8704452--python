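"""End-to-end orchestration: parameter scans, CV, and ranked inference.

The lag parameter of the pseudo-PSSM descriptor and the window parameter of
the DCCA coefficient are chosen by scanning candidate values, running
cross-validation per dataset at each value, and keeping the value with the
highest accuracy averaged across datasets (ties to the smallest value).
Inference trains on every known pair of a dataset and scores a query grid
of candidate targets x drugs, reporting pairs whose predicted interaction
probability exceeds a cutoff, ranked by probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import (DtiDataset, PairFeatureTable, SyntheticDtiBundle,
                      build_dataset, pair_features)
from .protein_features import DEFAULT_LAMBDA, DEFAULT_SEGMENT
from .reduce_balance import BalanceConfig, lasso_select, smote_balance
from .classify_eval import (CvResult, ForestConfig, cross_validate,
                            predict_proba, train_forest, _select_lambda,
                            _balance_capped)

logger = logging.getLogger(__name__)

#: Default L1-penalty grid (unscaled objective weight), log-spaced.
DEFAULT_LASSO_GRID: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class PipelineConfig:
    """All tunables of the prediction pipeline in one place."""

    lambda_order: int = DEFAULT_LAMBDA
    segment_length: int = DEFAULT_SEGMENT
    balance: BalanceConfig = field(default_factory=BalanceConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    lasso_grid: tuple[float, ...] = DEFAULT_LASSO_GRID
    balance_scope: str = "train_only"
    n_folds: int = 5
    seed: int = 0


@dataclass(frozen=True)
class PredictionRecord:
    drug_id: str
    drug_name: str
    target_id: str
    target_name: str
    probability: float


@dataclass
class PredictionResult:
    """Ranked candidate interactions plus the fraction of the grid called."""

    records: list[PredictionRecord]
    fraction_above_cutoff: float
    n_query_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.drug_id, r.drug_name, r.target_id, r.target_name, r.probability)
             for r in self.records],
            columns=["Drug", "Drug_Name", "Target", "Target_Name", "Prob"])


@dataclass
class ScanResult:
    """Per-value CV accuracies (one row per feasible value) and the argmax."""

    table: pd.DataFrame  # index: parameter value; columns: dataset names + "mean"
    selected: int


def _value_seed(master_seed: int, value: int) -> int:
    """Stable per-value seed so parallel scan order cannot change results."""
    state = np.random.SeedSequence([master_seed, value]).generate_state(1)[0]
    return int(state % (2 ** 31))


def _scan(bundles: list[SyntheticDtiBundle], values: list[int], config: PipelineConfig,
          feasible, build) -> ScanResult:
    if not bundles:
        raise ValueError("at least one dataset is required")
    names = [f"dataset_{i}" for i in range(len(bundles))]
    rows = {}
    for value in values:
        accs = []
        seed = _value_seed(config.seed, value)
        ok = all(feasible(b, value) for b in bundles)
        if not ok:
            logger.info("value %d infeasible for at least one dataset; excluded", value)
            continue
        for b in bundles:
            ds = build(b, value)
            cv = cross_validate(ds, config, seed=seed)
            accs.append(cv.mean()["ACC"])
        rows[value] = accs + [float(np.mean(accs))]
    if not rows:
        raise ValueError("no feasible parameter values")
    table = pd.DataFrame.from_dict(rows, orient="index", columns=names + ["mean"])
    # argmax of the mean; ties to the smallest value (index is sorted ascending)
    table = table.sort_index()
    selected = int(table["mean"].idxmax())
    return ScanResult(table=table, selected=selected)


def _min_length(bundle: SyntheticDtiBundle) -> int:
    return min(p.length for p in bundle.profiles)


def scan_lambda(bundles: list[SyntheticDtiBundle], values=range(0, 16),
                config: PipelineConfig | None = None) -> ScanResult:
    """Scan the pseudo-PSSM lag over ``values`` and pick the best mean ACC.

    A lag is infeasible (excluded) when it reaches any protein's length.
    """
    config = config or PipelineConfig()
    return _scan(bundles, list(values), config,
                 feasible=lambda b, lam: lam < _min_length(b),
                 build=lambda b, lam: build_dataset(b, lambda_order=lam,
                                                    s=config.segment_length))


def scan_s(bundles: list[SyntheticDtiBundle], values=range(9, 82),
           config: PipelineConfig | None = None) -> ScanResult:
    """Scan the DCCA window parameter; s is infeasible when s > L_min - 1."""
    config = config or PipelineConfig()
    return _scan(bundles, list(values), config,
                 feasible=lambda b, s: s <= _min_length(b) - 1,
                 build=lambda b, s: build_dataset(b, lambda_order=config.lambda_order, s=s))


def fit_full(train: DtiDataset, config: PipelineConfig):
    """Train selection + balancing + forest on every pair of ``train``.

    Returns (selector-or-None, classifier); all known pairs are used, with
    Lasso and SMOTE applied to the complete table (everything is training
    data at inference time).
    """
    table = pair_features(train)
    lam = _select_lambda(table, config, config.seed)
    selector = lasso_select(table, lam)
    if len(selector.retained) > 0:
        table = selector.transform(table)
    else:
        logger.warning("Lasso retained no features; training on all %d", table.n_features)
        selector = None
    table = _balance_capped(table, config, config.seed)
    clf = train_forest(table, ForestConfig(config.forest.n_trees, config.forest.mtry,
                                           seed=config.seed))
    return selector, clf


def predict_new(train: DtiDataset,
                query_protein_features: dict[str, np.ndarray],
                query_drug_features: dict[str, np.ndarray],
                config: PipelineConfig | None = None,
                cutoff: float = 0.5,
                target_names: dict[str, str] | None = None,
                drug_names: dict[str, str] | None = None) -> PredictionResult:
    """Score every query (target, drug) pair with a model trained on ``train``.

    Query feature vectors must be built with the same lag and window
    parameters as the training dataset. Records with probability strictly
    above ``cutoff`` are returned sorted by probability descending, ties by
    (drug id, target id); ``fraction_above_cutoff`` is their share of the
    whole query grid.
    """
    config = config or PipelineConfig()
    if not query_protein_features or not query_drug_features:
        raise ValueError("query targets and drugs must both be nonempty")
    prot_dim = len(next(iter(train.protein_features.values())))
    drug_dim = len(next(iter(train.drug_features.values())))
    bad = [t for t, v in query_protein_features.items() if len(v) != prot_dim]
    bad += [d for d, v in query_drug_features.items() if len(v) != drug_dim]
    if bad:
        raise ValueError(f"query entities with missing/mismatched features: {sorted(bad)}")

    selector, clf = fit_full(train, config)
    query = DtiDataset(targets=sorted(query_protein_features),
                       drugs=sorted(query_drug_features),
                       positives=set(),
                       protein_features=dict(query_protein_features),
                       drug_features=dict(query_drug_features),
                       protein_feature_names=train.protein_feature_names)
    qtable = pair_features(query)
    if selector is not None:
        qtable = selector.transform(qtable)
    probs = predict_proba(clf, qtable.X)

    target_names = target_names or {}
    drug_names = drug_names or {}
    records = []
    for t, d, p in zip(qtable.target_ids, qtable.drug_ids, probs):
        if p > cutoff:
            records.append(PredictionRecord(
                drug_id=str(d), drug_name=drug_names.get(d, str(d)),
                target_id=str(t), target_name=target_names.get(t, str(t)),
                probability=float(p)))
    records.sort(key=lambda r: (-r.probability, r.drug_id, r.target_id))
    n_grid = len(qtable.labels)
    return PredictionResult(records=records,
                            fraction_above_cutoff=len(records) / n_grid,
                            n_query_pairs=n_grid)
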