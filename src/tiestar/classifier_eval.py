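"""SVM training on a feature subset and ROC/AUC accuracy quantification.

Scores are continuous SVM decision values (higher = more case-like); AUC is
the Mann–Whitney statistic — the probability a random case outranks a random
control, ties earning half credit — which equals the trapezoidal area under
the empirical ROC curve.  Standardization and hyperparameter selection use
the training partition only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.svm import SVC

from .tabular_io import Dataset


@dataclass(frozen=True)
class EvalConfig:
    """SVM and internal model-selection settings.

    The linear kernel with a small cost grid is the transparent default;
    class weighting defaults to "balanced" because a ~17% minority outcome
    can degenerate an unweighted SVM to the majority rule.
    """

    kernel: str = "linear"
    cost_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    internal_folds: int = 5
    class_weighting: str = "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.internal_folds < 2:
            raise ValueError("internal_folds must be >= 2")
        if self.class_weighting not in ("none", "balanced"):
            raise ValueError(f"unknown class weighting {self.class_weighting!r}")
        if not self.cost_grid or any(c <= 0 for c in self.cost_grid):
            raise ValueError("cost_grid must contain positive values")


@dataclass(frozen=True)
class ROCSummary:
    auc: float
    operating_points: tuple[tuple[float, float, float], ...]  # (threshold, sens, spec)


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC: (concordant + 0.5·tied pairs) / (cases × controls)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _design_matrix(dataset: Dataset, feats: list[str]) -> np.ndarray:
    """Numeric design matrix: ordinal/binary columns as level codes, continuous raw.

    Ordinal clinical items carry rank information only — their numeric
    labels are arbitrary — so columns with declared levels are mapped to
    their level index before modelling.  This makes the classifier
    invariant to any monotone relabelling of an ordinal feature (schema
    levels are static metadata, so nothing is learned from test rows).
    """
    out = np.empty((dataset.n, len(feats)), dtype=float)
    for j, name in enumerate(feats):
        col = dataset.features[name].to_numpy(dtype=float)
        schema = dataset.schema_of(name)
        if schema.kind in ("ordinal", "binary") and schema.levels is not None:
            levels = np.asarray(schema.levels, dtype=float)
            out[:, j] = np.searchsorted(levels, col)
        else:
            out[:, j] = col
    return out


def _standardize(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (other - mu) / sd


def _fit_svm(X: np.ndarray, y: np.ndarray, cost: float, config: EvalConfig) -> SVC:
    weight = "balanced" if config.class_weighting == "balanced" else None
    model = SVC(kernel=config.kernel, C=cost, class_weight=weight, gamma="scale")
    model.fit(X, y)
    return model


def _internal_fold_codes(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Stratified fold codes for cost selection (within-class shuffle + round robin)."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def select_cost(X: np.ndarray, y: np.ndarray, config: EvalConfig) -> float:
    """Pick the grid cost with the best internal cross-validated AUC on train."""
    if len(config.cost_grid) == 1:
        return float(config.cost_grid[0])
    k = min(config.internal_folds, int(np.bincount(y).min()))
    if k < 2:
        return float(config.cost_grid[len(config.cost_grid) // 2])
    fold = _internal_fold_codes(y, k, config.seed)
    best = (-np.inf, np.inf)
    for cost in config.cost_grid:
        aucs = []
        for j in range(k):
            tr, te = fold != j, fold == j
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                continue
            Xtr, Xte = _standardize(X[tr], X[te])
            model = _fit_svm(Xtr, y[tr], cost, config)
            aucs.append(compute_auc(model.decision_function(Xte), y[te]))
        mean = float(np.mean(aucs)) if aucs else -np.inf
        # ties in CV AUC resolve toward the smaller (simpler) cost
        if mean > best[0] + 1e-12:
            best = (mean, cost)
    return float(best[1]) if np.isfinite(best[1]) else 1.0


def train_and_score(
    train: Dataset,
    test: Dataset,
    features: frozenset[str] | set[str] | list[str],
    config: EvalConfig = EvalConfig(),
) -> np.ndarray:
    """Fit an SVM on ``train`` restricted to ``features``; score ``test`` rows.

    Features are standardized by training-partition mean/scale; the cost is
    selected by internal CV on the training partition only.  Returns the
    continuous decision scores for the test rows.
    """
    feats = sorted(features)
    if not feats:
        raise ValueError("cannot train on an empty feature set")
    for name in feats:
        if name not in train.feature_names or name not in test.feature_names:
            raise KeyError(f"feature {name!r} missing from a partition")
    y = np.asarray(train.outcome)
    if len(np.unique(y)) < 2:
        raise ValueError("training outcome must contain both classes")
    Xtr = _design_matrix(train, feats)
    Xte = _design_matrix(test, feats)
    cost = select_cost(Xtr, y, config)
    Xtr_s, Xte_s = _standardize(Xtr, Xte)
    model = _fit_svm(Xtr_s, y, cost, config)
    return np.asarray(model.decision_function(Xte_s), dtype=float)


def sens_spec_table(
    scores: np.ndarray, labels: np.ndarray, thresholds: list[float] | np.ndarray
) -> ROCSummary:
    """Empirical sensitivity/specificity at each threshold, plus the AUC.

    sensitivity(t) = P(score >= t | case); specificity(t) = P(score < t | control).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = compute_auc(scores, labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    points = []
    for t in thresholds:
        sens = float((cases >= t).mean())
        spec = float((controls < t).mean())
        points.append((float(t), sens, spec))
    return ROCSummary(auc, tuple(points))
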