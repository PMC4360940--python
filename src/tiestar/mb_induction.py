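"""Markov-boundary induction: the minimal feature set rendering all others non-significant.

The learner is a semi-interleaved forward/backward local search in the style
of HITON-PC: candidates enter in order of univariate association strength
with the outcome; after each admission the newcomer is challenged by
conditioning sets drawn from the current set, and a full backward pass
finishes the job.  On the flat tabular problems targeted here the outcome
has direct parents only, so the parents/children set is used as the Markov
boundary (no spouse-recovery phase).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from .independence import CITestConfig, CITester, renders_independent
from .tabular_io import Dataset

logger = logging.getLogger("tiestar")


@dataclass(frozen=True)
class MarkovBoundary:
    """A minimal maximally predictive feature set, with its evaluated AUC."""

    features: frozenset[str]
    auc: float | None = None
    provenance: str = ""

    def with_auc(self, auc: float) -> "MarkovBoundary":
        return MarkovBoundary(self.features, auc, self.provenance)

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class InductionConfig:
    ci: CITestConfig = field(default_factory=CITestConfig)
    engine: str = "g2"
    max_candidates: int | None = None
    seed: int = 0


def rank_by_association(
    dataset: Dataset,
    excluded: frozenset[str] | set[str] = frozenset(),
    config: InductionConfig = InductionConfig(),
    tester: CITester | None = None,
) -> list[str]:
    """Features outside ``excluded`` ordered by univariate association strength.

    Smaller unconditional p-value first; ties broken by larger statistic,
    then by name — the ordering is fully deterministic.
    """
    tester = tester or CITester(dataset, config.ci, config.engine)
    entries = []
    for name in dataset.feature_names:
        if name in excluded:
            continue
        res = tester.test(name, ())
        entries.append((res.p_value, -res.statistic, name))
    entries.sort()
    return [name for _, _, name in entries]


def induce_mb(
    dataset: Dataset,
    excluded: frozenset[str] | set[str] = frozenset(),
    config: InductionConfig = InductionConfig(),
    tester: CITester | None = None,
) -> MarkovBoundary:
    """Induce one Markov boundary of the outcome on ``dataset`` \\ ``excluded``.

    Semi-interleaved inclusion/elimination: admit candidates in association
    rank order, drop a newcomer as soon as some subset (size <= max_k) of
    the current set renders it independent of the outcome, and finish with
    a full backward pass over the surviving set.  Returns an empty boundary
    (with a logged warning) when no feature is dependent on the outcome.
    """
    tester = tester or CITester(dataset, config.ci, config.engine)
    ranked = rank_by_association(dataset, excluded, config, tester)
    candidates = [f for f in ranked if tester.dependent(f, ())]
    if config.max_candidates is not None:
        candidates = candidates[: config.max_candidates]
    provenance = f"{dataset.id}|excluded={'|'.join(sorted(excluded))}"
    if not candidates:
        logger.warning("no feature dependent on the outcome; empty Markov boundary")
        return MarkovBoundary(frozenset(), provenance=provenance)

    current: list[str] = []
    for f in candidates:
        current.append(f)
        if tester.separable(f, [g for g in current if g != f]):
            current.remove(f)

    # full backward pass: re-challenge every survivor against the final set
    for f in list(current):
        others = [g for g in current if g != f]
        if tester.separable(f, others):
            current.remove(f)

    return MarkovBoundary(frozenset(current), provenance=provenance)


def check_minimality(
    dataset: Dataset,
    mb: MarkovBoundary,
    config: InductionConfig = InductionConfig(),
    tester: CITester | None = None,
) -> bool:
    """True iff no member of ``mb`` is redundant given the others.

    A member is redundant when some subset of the remaining members (size
    <= max_k) renders it independent of the outcome at the configured alpha.
    """
    if not mb.features:
        raise ValueError("minimality is undefined for an empty boundary")
    tester = tester or CITester(dataset, config.ci, config.engine)
    members = sorted(mb.features)
    for f in members:
        if tester.separable(f, [g for g in members if g != f]):
            return False
    return True
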