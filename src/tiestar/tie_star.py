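"""TIE*-style enumeration of all Markov boundaries with equivalent predictive accuracy.

One Markov boundary rarely exhausts a clinical dataset: when several
features carry the same information about the outcome, many minimal,
equally predictive sets exist.  The procedure here makes that multiplicity
explicit: induce a reference boundary, score it, then repeatedly remove
subsets of already-discovered boundary features from the data, re-induce on
the reduced feature set, and keep each new boundary whose SVM accuracy is
equivalent to the reference — iterating until the removal agenda is
exhausted (or a budget is reached).
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np

from .classifier_eval import EvalConfig, _internal_fold_codes, compute_auc, train_and_score
from .independence import CITester
from .mb_induction import InductionConfig, MarkovBoundary, induce_mb
from .tabular_io import Dataset, discretize

logger = logging.getLogger("tiestar")


@dataclass(frozen=True)
class EquivalenceCriterion:
    """Rule deciding whether a new boundary's accuracy matches the reference.

    ``auc_margin`` (deterministic): accept iff AUC(new) >= AUC(ref) − margin.
    ``paired_permutation``: accept iff a two-sided paired permutation test of
    the AUC difference (per-subject score swaps) fails to reject at alpha.
    """

    kind: str = "auc_margin"
    alpha: float = 0.05
    margin: float = 0.01
    n_permutations: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("auc_margin", "paired_permutation"):
            raise ValueError(f"unknown equivalence criterion {self.kind!r}")


@dataclass
class MBPool:
    """Boundaries admitted as equivalent to the reference, in admission order."""

    mbs: list[MarkovBoundary]
    reference_auc: float
    criterion: EquivalenceCriterion
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.mbs)

    @property
    def feature_sets(self) -> list[frozenset[str]]:
        return [mb.features for mb in self.mbs]


def canonicalize(features) -> str:
    """Injective string key for a feature set: sorted names joined by '|'."""
    return "|".join(sorted(features))


def equivalence_check(
    scores_new: np.ndarray,
    scores_ref: np.ndarray,
    labels: np.ndarray,
    criterion: EquivalenceCriterion,
) -> bool:
    """Is the new model's AUC equivalent to the reference model's AUC?"""
    scores_new = np.asarray(scores_new, dtype=float)
    scores_ref = np.asarray(scores_ref, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores_new) != len(scores_ref) or len(scores_new) != len(labels):
        raise ValueError("score vectors and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("equivalence check requires both outcome classes")
    auc_new = compute_auc(scores_new, labels)
    auc_ref = compute_auc(scores_ref, labels)
    if criterion.kind == "auc_margin":
        return auc_new >= auc_ref - criterion.margin
    # paired permutation: swap the two models' scores per subject
    observed = abs(auc_new - auc_ref)
    rng = np.random.default_rng(criterion.seed)
    n = len(labels)
    hits = 0
    for _ in range(criterion.n_permutations):
        swap = rng.random(n) < 0.5
        a = np.where(swap, scores_ref, scores_new)
        b = np.where(swap, scores_new, scores_ref)
        if abs(compute_auc(a, labels) - compute_auc(b, labels)) >= observed - 1e-15:
            hits += 1
    p = (1 + hits) / (1 + criterion.n_permutations)
    return p > criterion.alpha


def internal_cv_scores(
    train: Dataset,
    features,
    eval_cfg: EvalConfig,
    seed: int,
) -> np.ndarray:
    """Out-of-fold SVM decision scores for every training subject.

    All candidate boundaries within one TIE* run are scored on the same
    internal stratified folds (derived from ``seed``), so their AUCs — and
    the paired equivalence test — compare like with like without touching
    any outer test data.
    """
    y = np.asarray(train.outcome)
    k = min(eval_cfg.internal_folds, int(np.bincount(y).min()))
    if k < 2:
        raise ValueError("too few members of a class for internal cross-validation")
    fold = _internal_fold_codes(y, k, seed)
    scores = np.empty(len(y), dtype=float)
    for j in range(k):
        tr = train.subset_rows(fold != j)
        te = train.subset_rows(fold == j)
        scores[fold == j] = train_and_score(tr, te, features, eval_cfg)
    return scores


def run_tie_star(
    train: Dataset,
    induction: InductionConfig = InductionConfig(),
    eval_cfg: EvalConfig = EvalConfig(),
    criterion: EquivalenceCriterion = EquivalenceCriterion(),
    budget: int = 5000,
    bins: int = 3,
) -> MBPool:
    """Enumerate all Markov boundaries predictively equivalent to the reference.

    The removal agenda starts with every single-feature exclusion drawn from
    the reference boundary; whenever a new boundary is admitted, the agenda
    is extended with every union of an already-processed exclusion set and
    one feature of the new boundary.  Exclusion sets are processed smallest
    first (lexicographic within a size) and never revisited.  ``budget``
    bounds the number of agenda entries processed; exceeding it returns the
    pool truncated.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    # CI testing happens on a discretized view (training data only, so the
    # bin edges can never leak outer test information); the SVM sees the
    # original numeric values.
    disc = discretize(train, bins=bins) if induction.engine == "g2" else train
    tester = CITester(disc, induction.ci, induction.engine)
    y = np.asarray(train.outcome)

    reference = induce_mb(disc, frozenset(), induction, tester)
    if not reference.features:
        logger.warning("empty reference Markov boundary; returning empty pool")
        return MBPool([], float("nan"), criterion)

    ref_scores = internal_cv_scores(train, reference.features, eval_cfg, induction.seed)
    ref_auc = compute_auc(ref_scores, y)
    pool = [reference.with_auc(ref_auc)]
    pool_keys = {canonicalize(reference.features)}

    visited: list[frozenset[str]] = [frozenset()]
    heap: list[tuple[int, tuple[str, ...]]] = []
    seen: set[tuple[str, ...]] = set()

    def push(exclusion: frozenset[str]) -> None:
        key = tuple(sorted(exclusion))
        if key not in seen:
            seen.add(key)
            heapq.heappush(heap, (len(key), key))

    for f in sorted(reference.features):
        push(frozenset([f]))

    processed = 0
    truncated = False
    while heap:
        if processed >= budget:
            truncated = True
            logger.warning("agenda budget %d reached; pool truncated", budget)
            break
        _, key = heapq.heappop(heap)
        exclusion = frozenset(key)
        processed += 1
        visited.append(exclusion)

        mb = induce_mb(disc, exclusion, induction, tester)
        if not mb.features:
            continue
        mb_key = canonicalize(mb.features)
        if mb_key in pool_keys:
            continue
        scores = internal_cv_scores(train, mb.features, eval_cfg, induction.seed)
        if not equivalence_check(scores, ref_scores, y, criterion):
            continue
        pool.append(mb.with_auc(compute_auc(scores, y)))
        pool_keys.add(mb_key)
        logger.info(
            "admitted MB #%d %s (agenda %d pending)", len(pool), mb_key, len(heap)
        )
        for prior in visited:
            for f in sorted(mb.features):
                push(prior | {f})

    return MBPool(pool, ref_auc, criterion, truncated)


def pool_to_frame(pool: MBPool):
    """Serialize a pool as a table: canonical key, size, AUC per boundary."""
    import pandas as pd

    return pd.DataFrame(
        {
            "mb": [canonicalize(mb.features) for mb in pool.mbs],
            "size": [len(mb.features) for mb in pool.mbs],
            "auc": [mb.auc for mb in pool.mbs],
        }
    )
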