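"""Conditional independence tests: G² on contingency tables and Fisher-z partials.

These tests are the statistical engine of Markov-boundary induction: a
feature is removed from a candidate boundary exactly when some conditioning
set renders it non-significant with respect to the outcome.  Two engines are
provided — the likelihood-ratio G² test for discrete (or discretized) data
and the Fisher-z partial-correlation test for continuous data.  Tests whose
contingency tables are too sparse (or whose correlation structure is
singular) are flagged ``reliable=False``; by the caller's policy an
unreliable test never removes a variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CITestConfig:
    """Thresholds shared by all CI tests.

    alpha : significance level for dependence calls.
    max_k : largest conditioning-set size the induction search will try.
    min_avg_cell : minimum average sample count per contingency cell for a
        G² test to be considered reliable (heuristic from the GLL family).
    """

    alpha: float = 0.05
    max_k: int = 3
    min_avg_cell: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if self.max_k < 0:
            raise ValueError("max_k must be >= 0")
        if self.min_avg_cell <= 0:
            raise ValueError("min_avg_cell must be positive")


@dataclass(frozen=True)
class CITestResult:
    statistic: float
    dof: int
    p_value: float
    reliable: bool
    test_kind: str


def _strata(Z: Sequence[np.ndarray], n: int) -> np.ndarray:
    """Combined stratum codes for a list of discrete conditioning columns."""
    if not Z:
        return np.zeros(n, dtype=np.int64)
    stacked = np.column_stack(Z)
    _, codes = np.unique(stacked, axis=0, return_inverse=True)
    return codes.astype(np.int64)


def g2_test(
    x: np.ndarray,
    y: np.ndarray,
    Z: Sequence[np.ndarray] = (),
    config: CITestConfig = CITestConfig(),
) -> CITestResult:
    """Likelihood-ratio G² test of X ⟂ Y | Z on discrete columns.

    G² = 2 Σ O ln(O/E), summed over the cells of the X×Y table within each
    stratum of Z; degrees of freedom accumulate (r−1)(c−1) per stratum using
    the realized (nonzero-marginal) level counts.  Reliability requires the
    average sample count per contingency cell to reach
    ``config.min_avg_cell``.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    n = len(x)
    if len(y) != n or any(len(z) != n for z in Z):
        raise ValueError("columns must have equal length")
    strata = _strata(Z, n)
    _, x_codes = np.unique(x, return_inverse=True)
    _, y_codes = np.unique(y, return_inverse=True)
    nx = int(x_codes.max()) + 1
    ny = int(y_codes.max()) + 1

    g2 = 0.0
    dof = 0
    cells = 0
    for s in np.unique(strata):
        mask = strata == s
        table = np.bincount(x_codes[mask] * ny + y_codes[mask], minlength=nx * ny)
        table = table.reshape(nx, ny)
        table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        r, c = table.shape
        cells += r * c
        if r < 2 or c < 2:
            continue
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        obs = table[table > 0]
        g2 += 2.0 * float(np.sum(obs * np.log(obs / expected[table > 0])))
        dof += (r - 1) * (c - 1)

    if dof == 0:
        if nx < 2 or ny < 2:
            # globally constant x or y: no evidence either way
            return CITestResult(0.0, 0, 1.0, False, "g2")
        # x (or y) varies overall but is constant within every stratum of Z:
        # in-sample functional determinism, which certifies X ⟂ Y | Z provided
        # the strata are well populated (otherwise it is a sparsity artifact)
        reliable = n / cells >= config.min_avg_cell
        return CITestResult(0.0, 0, 1.0, reliable, "g2")
    p = float(stats.chi2.sf(g2, dof))
    reliable = n / cells >= config.min_avg_cell
    return CITestResult(max(g2, 0.0), dof, p, reliable, "g2")


def fisher_z_test(
    x: np.ndarray,
    y: np.ndarray,
    Z: Sequence[np.ndarray] = (),
    config: CITestConfig = CITestConfig(),
) -> CITestResult:
    """Fisher-z test of zero partial correlation of X and Y given Z.

    The partial correlation is read off the inverse correlation matrix of
    (X, Y, Z); z = arctanh(r)·sqrt(n − |Z| − 3) is referred to the standard
    normal (two-sided).  A singular correlation structure yields an
    unreliable non-result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = len(Z)
    if n <= k + 3:
        raise ValueError("fisher_z requires n > |Z| + 3")
    data = np.column_stack([x, y, *[np.asarray(z, dtype=float) for z in Z]])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    if not np.all(np.isfinite(corr)):
        return CITestResult(0.0, max(n - k - 3, 0), 1.0, False, "fisher_z")
    if abs(corr[0, 1]) >= 1.0 - 1e-12:
        # perfectly correlated x and y: the partial correlation boundary r=±1
        return CITestResult(float("inf"), n - k - 3, 0.0, n > k + 10, "fisher_z")
    try:
        precision = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        return CITestResult(0.0, max(n - k - 3, 0), 1.0, False, "fisher_z")
    denom = precision[0, 0] * precision[1, 1]
    if denom <= 0 or not np.isfinite(denom):
        return CITestResult(0.0, max(n - k - 3, 0), 1.0, False, "fisher_z")
    r = float(-precision[0, 1] / np.sqrt(denom))
    r = float(np.clip(r, -1.0, 1.0))
    reliable = n > k + 10
    if abs(r) >= 1.0 - 1e-12:
        return CITestResult(float("inf"), n - k - 3, 0.0, reliable, "fisher_z")
    z = abs(np.arctanh(r)) * np.sqrt(n - k - 3)
    p = float(2.0 * stats.norm.sf(z))
    return CITestResult(float(z), n - k - 3, p, reliable, "fisher_z")


def is_dependent(result: CITestResult, config: CITestConfig) -> bool:
    """Positive dependence call: reliable and significant at ``alpha``."""
    return result.reliable and result.p_value <= config.alpha


def renders_independent(result: CITestResult, config: CITestConfig) -> bool:
    """True when the test gives positive, reliable evidence of independence.

    Unreliable tests never certify independence — under the induction
    algorithm's conservative policy, insufficient data cannot remove a
    candidate variable.
    """
    return result.reliable and result.p_value > config.alpha


class CITester:
    """Cached CI testing of (feature ⟂ outcome | conditioning set) on one dataset.

    All induction queries route through this object so repeated tests during
    the forward/backward search are computed once.  The engine is either
    ``"g2"`` (columns converted to integer level codes; dataset must be
    discrete) or ``"fisher_z"`` (raw numeric values).
    """

    def __init__(self, dataset, config: CITestConfig, engine: str = "g2"):
        if engine not in ("g2", "fisher_z"):
            raise ValueError(f"unknown CI engine {engine!r}")
        self.config = config
        self.engine = engine
        self.names = dataset.feature_names
        if engine == "g2":
            self._cols = {name: dataset.column_codes(name) for name in self.names}
        else:
            self._cols = {
                name: dataset.features[name].to_numpy(dtype=float) for name in self.names
            }
        self._y = np.asarray(dataset.outcome, dtype=np.int64)
        self._cache: dict[tuple[str, tuple[str, ...]], CITestResult] = {}

    def test(self, name: str, cond: Sequence[str] = ()) -> CITestResult:
        key = (name, tuple(sorted(cond)))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        Z = [self._cols[c] for c in key[1]]
        if self.engine == "g2":
            result = g2_test(self._cols[name], self._y, Z, self.config)
        else:
            result = fisher_z_test(self._cols[name], self._y.astype(float), Z, self.config)
        self._cache[key] = result
        return result

    def dependent(self, name: str, cond: Sequence[str] = ()) -> bool:
        return is_dependent(self.test(name, cond), self.config)

    def separable(self, name: str, others: Sequence[str]) -> bool:
        """Does some subset of ``others`` (size <= max_k) render ``name`` independent?"""
        others = list(others)
        for size in range(0, min(self.config.max_k, len(others)) + 1):
            for Z in combinations(others, size):
                if renders_independent(self.test(name, Z), self.config):
                    return True
        return False
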