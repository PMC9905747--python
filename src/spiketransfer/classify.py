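"""Classification accuracy from metric matrices, with an exact binomial null.

Each iteration yields one ``[n_in x n_out]`` metric matrix; for every input
(row) the winning output is the argbest column (max for coherence, Granger
causality and transfer entropy; min for reconstruction error).  Accumulating
winners over ``m`` iterations gives a confusion matrix with ``n = m * i``
trials.  Under the null that every input is matched to a uniformly random
output, the correct count ``K`` follows ``Binomial(n, 1/j)``, so the p-value
is the exact right tail ``P(K >= k)``; significance is assessed after
Bonferroni correction over the comparisons of a parameter search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as spst

__all__ = [
    "ClassifResult",
    "select_winner",
    "confusion_from_iterations",
    "binomial_pvalue",
    "expected_correct",
    "bonferroni_flag",
    "bootstrap_ci",
    "score_iterations",
]


@dataclass(frozen=True)
class ClassifResult:
    """Confusion counts, accuracy and its exact binomial test."""

    confusion: np.ndarray  # [i x j] counts over all trials
    k: int  # correct count
    n: int  # trial count = m * i
    accuracy: float
    p_value: float | None = None
    significant: bool | None = None
    ci: tuple[float, float] | None = None
    per_iteration_accuracy: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if int(self.confusion.sum()) != self.n:
            raise ValueError("confusion counts must sum to n")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy out of [0, 1]")


def select_winner(m: np.ndarray, direction: str = "max") -> np.ndarray:
    """Row-wise argbest output index for each input.

    ``direction`` is "max" (coherence, GC, TE) or "min" (RE).  NaN entries
    (flagged-missing pairs) never win.  Ties break toward the lowest index,
    with a warning so they cannot silently inflate accuracy.
    """
    m = np.asarray(m, dtype=float)
    if direction == "max":
        filled = np.where(np.isnan(m), -np.inf, m)
        winners = np.argmax(filled, axis=1)
        best = filled[np.arange(len(filled)), winners]
        n_ties = int(np.sum(np.sum(filled == best[:, None], axis=1) > 1))
    elif direction == "min":
        filled = np.where(np.isnan(m), np.inf, m)
        winners = np.argmin(filled, axis=1)
        best = filled[np.arange(len(filled)), winners]
        n_ties = int(np.sum(np.sum(filled == best[:, None], axis=1) > 1))
    else:
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    if n_ties:
        warnings.warn(
            f"{n_ties} tied row(s) resolved to the lowest output index",
            stacklevel=2,
        )
    return winners


def confusion_from_iterations(
    matrices: Sequence[np.ndarray], direction: str = "max"
) -> ClassifResult:
    """Accumulate winners over ``m`` iterations into a confusion matrix.

    Entry (q, o) counts the iterations in which input q selected output o;
    k is the diagonal sum and ``n = m * i``.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one iteration")
    n_in, n_out = matrices[0].shape
    confusion = np.zeros((n_in, n_out), dtype=np.int64)
    per_iter = np.empty(len(matrices))
    for it, m in enumerate(matrices):
        winners = select_winner(m, direction)
        correct = 0
        for q, o in enumerate(winners):
            confusion[q, o] += 1
            correct += int(q == o)
        per_iter[it] = correct / n_in
    k = int(np.trace(confusion))
    n = len(matrices) * n_in
    return ClassifResult(
        confusion=confusion,
        k=k,
        n=n,
        accuracy=k / n,
        per_iteration_accuracy=per_iter,
    )


def binomial_pvalue(k: int, n: int, p: float) -> float:
    """Exact right-tail binomial probability ``P(K >= k)`` for K ~ B(n, p)."""
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, {n}], got {k!r}")
    if not 0 < p < 1:
        raise ValueError(f"p must lie in (0, 1), got {p!r}")
    return float(spst.binom.sf(k - 1, n, p))


def expected_correct(n: int, p: float) -> float:
    """Expected correct count under the chance model: n * p."""
    return n * p


def bonferroni_flag(p_value: float, alpha: float = 0.05, n_comparisons: int = 1) -> bool:
    """Significance after Bonferroni correction for N comparisons."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return bool(p_value < alpha / n_comparisons)


def bootstrap_ci(
    per_iteration_accuracies: Sequence[float],
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval of the mean accuracy over iterations.

    Resamples iterations (not pooled trials) with replacement.
    """
    acc = np.asarray(list(per_iteration_accuracies), dtype=float)
    if acc.size == 0:
        raise ValueError("need at least one iteration accuracy")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, acc.size, size=(n_boot, acc.size))
    means = acc[idx].mean(axis=1)
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(means, lo)),
        float(np.quantile(means, 1.0 - lo)),
    )


def score_iterations(
    matrices: Sequence[np.ndarray],
    direction: str = "max",
    alpha: float = 0.05,
    n_comparisons: int = 1,
    ci_level: float = 0.95,
    n_boot: int = 10_000,
    seed: int = 0,
) -> ClassifResult:
    """Full scoring: confusion matrix, exact binomial p-value against chance
    1/j, Bonferroni flag and bootstrap CI of the mean accuracy."""
    base = confusion_from_iterations(matrices, direction)
    p_chance = 1.0 / base.confusion.shape[1]
    p_value = binomial_pvalue(base.k, base.n, p_chance)
    from dataclasses import replace

    return replace(
        base,
        p_value=p_value,
        significant=bonferroni_flag(p_value, alpha, n_comparisons),
        ci=bootstrap_ci(base.per_iteration_accuracy, ci_level, n_boot, seed),
    )
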