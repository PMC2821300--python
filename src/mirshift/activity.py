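"""The core statistic: per-miRNA target-set expression-shift testing.

A miRNA that actively destabilises its target mRNAs leaves a footprint in a
single expression profile: the expression values of its predicted targets sit
lower, as a group, than those of the other predicted-target genes.  Per
profile this is scored with a one-sided Wilcoxon rank-sum test (targets
stochastically *lower* than the background of all other targeted genes);
per tissue, the per-profile p-values are merged with Fisher's combined
probability test, −2·Σ ln pᵢ ~ χ² on 2k degrees of freedom.  Families whose
combined p falls below alpha are called as candidate active miRNAs, and genes
are ranked by how many such families predict them.

Size-matched random target sets (see :mod:`mirshift.target_sets`) run through
the same machinery to give the null control profile against which the
observed p-values are judged.
"""

from __future__ import annotations

import itertools
import logging
import math
import sys
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import GeneExpressionTable
from .target_sets import ExpressedTargetSets, generate_random_sets

logger = logging.getLogger(__name__)

#: Pooled-sample-size bound below which the rank-sum null is enumerated
#: exactly rather than normal-approximated.
EXACT_LIMIT = 12


@dataclass(frozen=True)
class ActivityResult:
    """One family's shift test in one profile."""

    family_id: str
    dataset_id: str
    n_targets: int
    avg_target_signal: float
    p_value: float


@dataclass(frozen=True)
class ControlProfile:
    """Per-family null summary over the random-set replicates."""

    family_id: str
    dataset_id: str
    n_sets: int
    mean_log10_p: float
    se_log10_p: float


@dataclass(frozen=True)
class CombinedActivityResult:
    """Fisher-combined result for one family in one tissue."""

    family_id: str
    tissue: str
    per_dataset_p: tuple[tuple[str, float], ...]
    chi2: float
    df: int
    combined_p: float
    significant: bool
    q_value: float | None = None


# ---------------------------------------------------------------------------
# Rank-sum machinery
# ---------------------------------------------------------------------------

def _rank_sum_p_exact(
    target: np.ndarray, background: np.ndarray, alternative: str
) -> float:
    """Exact permutation p by enumeration over the pooled midranks.

    Every size-n subset of the pooled values is equally likely under the
    null of exchangeability; ties are handled by midranks, which makes the
    enumeration valid with or without cross-group ties.
    """
    pooled = np.concatenate([target, background])
    ranks = stats.rankdata(pooled)
    n = len(target)
    observed = ranks[:n].sum()
    total = 0
    hits = 0
    eps = 1e-9
    for combo in itertools.combinations(ranks, n):
        total += 1
        s = sum(combo)
        if alternative == "less":
            hits += s <= observed + eps
        else:
            hits += s >= observed - eps
    return hits / total


def _rank_sum_p_normal(
    target: np.ndarray, background: np.ndarray, alternative: str
) -> float:
    """Normal approximation with midranks, tie-corrected variance and a 0.5
    continuity correction."""
    n, m = len(target), len(background)
    pooled = np.concatenate([target, background])
    big_n = n + m
    ranks = stats.rankdata(pooled)
    t_obs = ranks[:n].sum()
    mu = n * (big_n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (big_n * (big_n - 1))
    var = n * m / 12.0 * ((big_n + 1) - tie_term)
    if var <= 0:
        logger.warning("rank-sum test: zero variance after tie correction; p = 1")
        return 1.0
    sd = math.sqrt(var)
    if alternative == "less":
        z = (t_obs - mu + 0.5) / sd
        p = stats.norm.cdf(z)
    else:
        z = (t_obs - mu - 0.5) / sd
        p = stats.norm.sf(z)
    return float(min(1.0, max(p, sys.float_info.min)))


def wilcoxon_shift_test(
    target_values: Sequence[float],
    background_values: Sequence[float],
    alternative: str = "less",
    exact_limit: int = EXACT_LIMIT,
) -> float:
    """One-sided Wilcoxon rank-sum p-value for a group expression shift.

    ``alternative="less"`` (the default) tests whether the target values are
    stochastically lower than the background — the signature of miRNA-driven
    mRNA depression.  ``"greater"`` tests the opposite direction.

    When the pooled sample size is at most ``exact_limit`` the null is
    enumerated exactly (all rank assignments, midranks under ties);
    otherwise a tie-corrected, continuity-corrected normal approximation is
    used.  The returned p is clamped to (0, 1].

    Raises
    ------
    ValueError
        If either sample is empty or ``alternative`` is unrecognised.
    """
    if alternative not in ("less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    target = np.asarray(target_values, dtype=float)
    background = np.asarray(background_values, dtype=float)
    if target.size == 0 or background.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.all(np.concatenate([target, background]) == target[0]):
        logger.warning("rank-sum test: all values identical; p = 1")
        return 1.0
    if target.size + background.size <= exact_limit:
        return _rank_sum_p_exact(target, background, alternative)
    return _rank_sum_p_normal(target, background, alternative)


# ---------------------------------------------------------------------------
# Per-profile screening
# ---------------------------------------------------------------------------

def test_all_mirnas(
    table: GeneExpressionTable,
    ets: ExpressedTargetSets,
    min_targets: int = 50,
    background: str = "exclusive",
) -> list[ActivityResult]:
    """Shift-test every family with more than ``min_targets`` expressed targets.

    For each family the target sample is its expressed targets' values; the
    background is the expression of the remaining predicted-target genes
    (``background="exclusive"``, the default, keeps the two samples disjoint
    as the rank-sum test requires) or of *all* predicted-target genes
    including the family's own (``"inclusive"``, the literal composition of
    the original comparison).  Results carry the mean target signal (the
    "average target gene signal") and are sorted ascending by it, ties
    broken by family id.

    Raises
    ------
    ValueError
        If the universe holds fewer than 2 genes or ``background`` is
        unrecognised.
    """
    if background not in ("exclusive", "inclusive"):
        raise ValueError(f"unknown background mode {background!r}")
    if len(ets.universe) < 2:
        raise ValueError("universe must contain at least 2 genes")
    values = {g: table.values[g] for g in ets.universe}
    results: list[ActivityResult] = []
    for fam in sorted(ets.per_mirna):
        targets = ets.per_mirna[fam]
        n = len(targets)
        if n <= min_targets:
            continue
        tvals = np.array([values[g] for g in sorted(targets)])
        if background == "exclusive":
            bvals = np.array(
                [values[g] for g in sorted(ets.universe - targets)]
            )
        else:
            bvals = np.array([values[g] for g in sorted(ets.universe)])
        if bvals.size == 0:
            continue
        p = wilcoxon_shift_test(tvals, bvals, alternative="less")
        results.append(
            ActivityResult(
                family_id=fam,
                dataset_id=table.dataset_id,
                n_targets=n,
                avg_target_signal=float(tvals.mean()),
                p_value=p,
            )
        )
    results.sort(key=lambda r: (r.avg_target_signal, r.family_id))
    return results


def control_profile(
    table: GeneExpressionTable,
    ets: ExpressedTargetSets,
    n_sets: int = 5,
    *,
    seed: int,
    min_targets: int = 50,
    background: str = "exclusive",
) -> list[ControlProfile]:
    """Null p-value profile from size-matched random target sets.

    Runs :func:`test_all_mirnas` on each of ``n_sets`` random replicates and
    reports, per family, the mean and standard error of log10(p) across the
    replicates — the grey band of a ranked-significance plot.
    """
    replicates = generate_random_sets(ets, n_sets, seed=seed)
    log_ps: dict[str, list[float]] = {}
    for rep in replicates:
        for res in test_all_mirnas(table, rep, min_targets, background):
            log_ps.setdefault(res.family_id, []).append(math.log10(res.p_value))
    profiles = []
    for fam in sorted(log_ps):
        vals = np.array(log_ps[fam])
        se = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        profiles.append(
            ControlProfile(
                family_id=fam,
                dataset_id=table.dataset_id,
                n_sets=len(vals),
                mean_log10_p=float(vals.mean()),
                se_log10_p=se,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Meta-analysis across profiles
# ---------------------------------------------------------------------------

def fisher_combine(p_values: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's combined probability test.

    Returns ``(chi2, df, combined_p)`` with ``chi2 = −2·Σ ln pᵢ`` computed in
    log space and ``combined_p`` the upper-tail χ² probability on ``2k``
    degrees of freedom.  For a single p-value the combination is the
    identity.  Non-positive p-values are clamped to the smallest positive
    float (with a warning); p > 1 is an error.
    """
    if len(p_values) == 0:
        raise ValueError("cannot combine an empty list of p-values")
    clean = []
    for p in p_values:
        if p > 1.0:
            raise ValueError(f"p-value {p!r} exceeds 1")
        if p <= 0.0:
            logger.warning("fisher_combine: clamping non-positive p %r", p)
            p = sys.float_info.min
        clean.append(p)
    chi2 = -2.0 * sum(math.log(p) for p in clean)
    df = 2 * len(clean)
    combined = float(stats.chi2.sf(chi2, df))
    return chi2, df, combined


def combine_across_datasets(
    results_by_tissue: Mapping[str, Sequence[ActivityResult]],
    alpha: float = 0.05,
    add_bh: bool = False,
) -> list[CombinedActivityResult]:
    """Fisher-combine each family's per-profile p-values within a tissue.

    Only the profiles where the family passed the minimum-target filter
    contribute; the degrees of freedom reflect that count.  A family is
    called significant when its combined p is below ``alpha``.  Output is
    sorted ascending by combined p, ties broken by family id.

    ``add_bh=True`` attaches a Benjamini–Hochberg q-value per tissue — an
    extension beyond the headline uncorrected calls.
    """
    combined: list[CombinedActivityResult] = []
    for tissue, results in results_by_tissue.items():
        per_family: dict[str, list[tuple[str, float]]] = {}
        for res in results:
            per_family.setdefault(res.family_id, []).append(
                (res.dataset_id, res.p_value)
            )
        tissue_results = []
        for fam, pairs in per_family.items():
            pairs.sort()
            chi2, df, p = fisher_combine([p for _, p in pairs])
            tissue_results.append(
                CombinedActivityResult(
                    family_id=fam,
                    tissue=tissue,
                    per_dataset_p=tuple(pairs),
                    chi2=chi2,
                    df=df,
                    combined_p=p,
                    significant=p < alpha,
                )
            )
        if add_bh and tissue_results:
            from statsmodels.stats.multitest import multipletests

            qs = multipletests(
                [r.combined_p for r in tissue_results], method="fdr_bh"
            )[1]
            tissue_results = [
                CombinedActivityResult(
                    family_id=r.family_id,
                    tissue=r.tissue,
                    per_dataset_p=r.per_dataset_p,
                    chi2=r.chi2,
                    df=r.df,
                    combined_p=r.combined_p,
                    significant=r.significant,
                    q_value=float(q),
                )
                for r, q in zip(tissue_results, qs)
            ]
        combined.extend(tissue_results)
    combined.sort(key=lambda r: (r.combined_p, r.family_id))
    return combined


# ---------------------------------------------------------------------------
# Multi-miRNA gene ranking
# ---------------------------------------------------------------------------

def rank_genes_by_mirna_count(
    combined: Iterable[CombinedActivityResult],
    ets: ExpressedTargetSets,
    gene_list: set[str] | None = None,
) -> pd.DataFrame:
    """Rank genes by how many significant families predict them.

    Considers only the significant results in ``combined`` and the target
    membership in ``ets``.  Returns a DataFrame with columns ``gene``,
    ``n_mirnas`` and ``families`` (comma-joined), sorted by count descending
    then gene symbol.  When ``gene_list`` is given the table is restricted
    to those symbols (uppercased) — the focussed candidate-list view.
    """
    sig_families = sorted(
        {r.family_id for r in combined if r.significant}
    )
    if not sig_families:
        logger.warning("no significant families; gene ranking is empty")
    counts: dict[str, list[str]] = {}
    for fam in sig_families:
        for gene in ets.per_mirna.get(fam, ()):
            counts.setdefault(gene, []).append(fam)
    rows = [
        (gene, len(fams), ",".join(sorted(fams)))
        for gene, fams in counts.items()
    ]
    if gene_list is not None:
        wanted = {g.upper() for g in gene_list}
        rows = [r for r in rows if r[0] in wanted]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["gene", "n_mirnas", "families"])


def format_gene_count_rows(ranking: pd.DataFrame) -> list[str]:
    """``"count: GENE"`` lines for a candidate-list report."""
    return [f"{int(row.n_mirnas)}: {row.gene}" for row in ranking.itertuples()]
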