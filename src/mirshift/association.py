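"""Relating miRNA abundance to predicted repressive activity.

Two complementary views: a group comparison — are the miRNAs whose target
sets are significantly depressed (``combined_p < alpha``) more abundant than
the miRNAs with no predicted effect? — and a rank correlation between
(log) miRNA abundance and the significance of the predicted effect across
all measured families.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .activity import CombinedActivityResult, wilcoxon_shift_test

logger = logging.getLogger(__name__)

#: Largest n for which the Spearman permutation null is enumerated exactly.
EXACT_SPEARMAN_LIMIT = 9


@dataclass(frozen=True)
class GroupComparison:
    n_low: int
    n_background: int
    p_value: float


def _match(
    expr: Mapping[str, float], combined: Iterable[CombinedActivityResult]
) -> list[tuple[str, float, float]]:
    """(family, abundance, combined_p) for families present on both sides."""
    by_family = {r.family_id: r.combined_p for r in combined}
    matched = [
        (fam, float(a), by_family[fam]) for fam, a in expr.items() if fam in by_family
    ]
    dropped = len(expr) + len(by_family) - 2 * len(matched)
    if dropped:
        logger.info("association: %d unmatched families dropped", dropped)
    return matched


def compare_group_expression(
    expr: Mapping[str, float],
    combined: Iterable[CombinedActivityResult],
    alpha: float = 0.1,
) -> GroupComparison:
    """Compare miRNA abundance between predicted-effect groups.

    The 'low' group holds families whose combined p is below ``alpha``
    (their target sets sit low); the 'background' group holds the rest.
    A one-sided rank-sum test (same engine as the target-shift test) asks
    whether abundance in the 'low' group is higher.

    Raises
    ------
    ValueError
        When either group is empty after the alpha split (the message names
        the empty side), or no families match between the two inputs.
    """
    matched = _match(expr, combined)
    if not matched:
        raise ValueError("no families shared between abundance and activity results")
    low = [a for _, a, p in matched if p < alpha]
    back = [a for _, a, p in matched if p >= alpha]
    if not low:
        raise ValueError(f"'low' group empty: no family has combined p < {alpha}")
    if not back:
        raise ValueError(f"'background' group empty: every family has combined p < {alpha}")
    p = wilcoxon_shift_test(low, back, alternative="greater")
    return GroupComparison(n_low=len(low), n_background=len(back), p_value=p)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Exact permutation p for Spearman's rho by enumerating all n!
    orderings of one margin (midranks under ties)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rho_obs = _pearson(rx, ry)
    perms = np.array(list(itertools.permutations(ry)))
    cx = rx - rx.mean()
    cy = perms - perms.mean(axis=1, keepdims=True)
    denom = math.sqrt((cx**2).sum()) * np.sqrt((cy**2).sum(axis=1))
    rhos = cy @ cx / denom
    eps = 1e-12
    if alternative == "greater":
        hits = np.sum(rhos >= rho_obs - eps)
    elif alternative == "less":
        hits = np.sum(rhos <= rho_obs + eps)
    else:
        hits = np.sum(np.abs(rhos) >= abs(rho_obs) - eps)
    return float(hits / len(perms))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float((a * b).sum() / denom)


def correlate_expression_significance(
    expr: Mapping[str, float],
    combined: Iterable[CombinedActivityResult],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Spearman rank correlation between miRNA abundance and combined p.

    Pairs are matched by family id (unmatched families dropped, logged).
    Abundance is typically a log copy-number estimate; since the statistic
    is rank-based, any strictly increasing transform gives the same result.
    A repressive relationship shows as a *negative* rho: abundant miRNAs
    have small combined p.

    The p-value is an exact permutation probability for n ≤ 9 and a
    t-approximation above; ``alternative`` is ``"two-sided"`` (default),
    ``"less"`` (rho < 0) or ``"greater"``.

    Raises
    ------
    ValueError
        With fewer than 4 matched pairs or a constant vector on either side.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    matched = _match(expr, combined)
    if len(matched) < 4:
        raise ValueError(f"need >= 4 matched pairs, got {len(matched)}")
    x = np.array([a for _, a, _ in matched])
    y = np.array([p for _, _, p in matched])
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho = _pearson(stats.rankdata(x), stats.rankdata(y))
    n = len(x)
    if n <= EXACT_SPEARMAN_LIMIT:
        p = _spearman_exact_p(x, y, alternative)
    else:
        if abs(rho) >= 1.0:
            t = math.inf if rho > 0 else -math.inf
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        if alternative == "greater":
            p = float(stats.t.sf(t, n - 2))
        elif alternative == "less":
            p = float(stats.t.cdf(t, n - 2))
        else:
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
        p = min(1.0, max(p, np.nextafter(0, 1)))
    return rho, p
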