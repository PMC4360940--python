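"""Repeated stratified k-fold evaluation of the Markov-boundary enumeration.

Each of ``repeats`` × ``k`` runs enumerates boundaries with TIE* on the
training nine-tenths and scores every pooled boundary on the held-out fold;
nothing fitted ever sees test rows.  Aggregates follow the study design:
the pooled per-boundary test AUCs yield the mean accuracy and its empirical
95% range (2.5th/97.5th percentiles), and the fraction of all discovered
boundaries containing each feature measures that feature's predictive
robustness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier_eval import EvalConfig, compute_auc, train_and_score
from .mb_induction import InductionConfig, MarkovBoundary
from .tabular_io import Dataset, impute_missing
from .tie_star import EquivalenceCriterion, MBPool, canonicalize, run_tie_star

logger = logging.getLogger("tiestar")


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified partition of subjects into k non-overlapping folds."""

    fold_of_subject: np.ndarray
    k: int
    repeat_index: int
    seed: int

    def test_mask(self, fold: int) -> np.ndarray:
        return self.fold_of_subject == fold


def make_stratified_folds(labels: np.ndarray, k: int, seed: int, repeat_index: int = 0) -> FoldAssignment:
    """Within-class shuffle then round-robin: case and control counts per fold differ by <= 1."""
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2 (k=1 leaves no held-out data)")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= k={k} members, found counts {counts.tolist()}")
    rng = np.random.default_rng(seed)
    fold = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return FoldAssignment(fold, k, repeat_index, seed)


def schedule_runs(labels: np.ndarray, repeats: int, k: int, seed: int) -> list[FoldAssignment]:
    """One stratified fold assignment per repeat; repeats × k train/test runs total."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    return [make_stratified_folds(labels, k, seed + r, r) for r in range(repeats)]


@dataclass(frozen=True)
class RunRecord:
    repeat: int
    fold: int
    pool: MBPool
    test_aucs: tuple[float, ...]  # one per boundary, pool order


@dataclass
class CVResult:
    runs: list[RunRecord]
    mean_auc: float
    auc_range_95: tuple[float, float]
    mean_mbs_per_run: float
    feature_frequency: dict[str, float]

    def runs_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.runs:
            for mb, auc in zip(rec.pool.mbs, rec.test_aucs):
                rows.append(
                    {
                        "repeat": rec.repeat,
                        "fold": rec.fold,
                        "mb": canonicalize(mb.features),
                        "size": len(mb.features),
                        "train_auc": mb.auc,
                        "test_auc": auc,
                    }
                )
        return pd.DataFrame(rows)

    def frequency_frame(self) -> pd.DataFrame:
        items = sorted(self.feature_frequency.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(items, columns=["feature", "frequency"])


def feature_frequency(runs: list[RunRecord]) -> dict[str, float]:
    """Fraction of all discovered boundaries (across every run) containing each feature."""
    counts: dict[str, int] = {}
    total = 0
    for rec in runs:
        for mb in rec.pool.mbs:
            total += 1
            for f in mb.features:
                counts[f] = counts.get(f, 0) + 1
    if total == 0:
        raise ValueError("no Markov boundaries discovered across runs")
    return {f: c / total for f, c in counts.items()}


def robust_features(frequency: dict[str, float], threshold: float) -> list[str]:
    """Features present in strictly more than ``threshold`` of all boundaries.

    Sorted by descending frequency (name breaks ties).  The strict
    inequality matches the "over 75%" reading of robustness.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0,1)")
    keep = [(f, q) for f, q in frequency.items() if q > threshold]
    keep.sort(key=lambda kv: (-kv[1], kv[0]))
    return [f for f, _ in keep]


def run_repeated_cv(
    dataset: Dataset,
    repeats: int = 10,
    k: int = 10,
    induction: InductionConfig = InductionConfig(),
    eval_cfg: EvalConfig = EvalConfig(),
    criterion: EquivalenceCriterion = EquivalenceCriterion(),
    seed: int = 0,
    budget: int = 5000,
    bins: int = 3,
) -> CVResult:
    """Repeated stratified k-fold evaluation with TIE* inside every training split.

    Per run: boundaries are enumerated on the training partition only, then
    each pooled boundary's SVM is re-fit on the training partition and
    scored on the held-out fold.  Boundaries are never pooled across splits;
    the feature-frequency table is the only cross-run aggregation.  Fully
    reproducible from ``seed`` (per-repeat fold seeds derive from it).
    """
    dataset = impute_missing(dataset)
    assignments = schedule_runs(dataset.outcome, repeats, k, seed)
    runs: list[RunRecord] = []
    for fa in assignments:
        for fold in range(k):
            test_mask = fa.test_mask(fold)
            train = dataset.subset_rows(~test_mask)
            test = dataset.subset_rows(test_mask)
            run_seed = seed + 1000 * fa.repeat_index + fold
            run_induction = InductionConfig(
                ci=induction.ci,
                engine=induction.engine,
                max_candidates=induction.max_candidates,
                seed=run_seed,
            )
            pool = run_tie_star(train, run_induction, eval_cfg, criterion, budget, bins)
            if len(pool) == 0:
                logger.warning("repeat %d fold %d: empty pool", fa.repeat_index, fold)
                runs.append(RunRecord(fa.repeat_index, fold, pool, ()))
                continue
            aucs = []
            for mb in pool.mbs:
                scores = train_and_score(train, test, mb.features, eval_cfg)
                aucs.append(compute_auc(scores, test.outcome))
            runs.append(RunRecord(fa.repeat_index, fold, pool, tuple(aucs)))
            logger.info(
                "repeat %d fold %d: %d MBs, mean test AUC %.3f",
                fa.repeat_index, fold, len(pool), float(np.mean(aucs)),
            )

    pooled = np.array([auc for rec in runs for auc in rec.test_aucs], dtype=float)
    if pooled.size == 0:
        raise ValueError("no boundary was discovered in any run")
    mean_auc = float(pooled.mean())
    low, high = np.percentile(pooled, [2.5, 97.5])
    mean_mbs = float(np.mean([len(rec.pool) for rec in runs]))
    freq = feature_frequency(runs)
    return CVResult(runs, mean_auc, (float(low), float(high)), mean_mbs, freq)
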