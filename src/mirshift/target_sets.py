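"""Target prediction sets, their intersection with expressed genes, and
size-matched random control sets.

Predictions come from a TargetScan-style flat file of conserved miRNA-family
to gene-symbol relationships.  For the shift test each family's predicted
targets are intersected with the genes expressed in a profile; the union of
all such sets is the background universe ("all the genes predicted to be
targeted by miRNAs").  Null controls re-assign, for every family, the same
number of targets uniformly at random from that universe.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .expression_io import GeneExpressionTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetPredictionSet:
    """miRNA-family id -> set of predicted target gene symbols.

    Family ids are opaque strings preserved verbatim (e.g. ``"miR-125/351"``);
    symbols are uppercased and deduplicated.
    """

    families: Mapping[str, frozenset[str]]

    def __len__(self) -> int:
        return len(self.families)


@dataclass(frozen=True)
class ExpressedTargetSets:
    """Per-family expressed targets within one profile, plus the background.

    ``universe`` is the union of all per-family sets: every predicted target
    gene that is expressed in the profile.  Families whose intersection is
    empty are retained (the minimum-target-count filter removes them later).
    """

    dataset_id: str
    per_mirna: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for fam, targets in self.per_mirna.items():
            if not targets <= self.universe:
                raise ValueError(
                    f"family {fam!r}: targets not contained in the universe"
                )


def load_target_predictions(
    path: str | Path,
    family_col: str | int | None = None,
    gene_col: str | int | None = None,
) -> TargetPredictionSet:
    """Load a TargetScan-style flat file (header line, tab-separated).

    The family and gene-symbol columns may be selected by name or 0-based
    index; by default they are located by header keywords (``family``/``mir``
    and ``symbol``/``gene``), falling back to the first two columns.  Extra
    columns are ignored; duplicate rows collapse into the set.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty prediction file")

    def pick(spec: str | int | None, tokens: tuple[str, ...], default: int) -> str:
        if isinstance(spec, int):
            return df.columns[spec]
        if isinstance(spec, str):
            return spec
        for col in df.columns:
            if any(tok in str(col).lower() for tok in tokens):
                return col
        return df.columns[default]

    fam_c = pick(family_col, ("family", "mir"), 0)
    gene_c = pick(gene_col, ("symbol", "gene"), 1)
    families: dict[str, set[str]] = {}
    for fam, gene in zip(df[fam_c], df[gene_c]):
        if pd.isna(fam) or pd.isna(gene):
            continue
        families.setdefault(str(fam).strip(), set()).add(str(gene).strip().upper())
    logger.info("loaded %d miRNA families from %s", len(families), path)
    return TargetPredictionSet(
        families={f: frozenset(g) for f, g in families.items()}
    )


def write_target_predictions(preds: TargetPredictionSet, path: str | Path) -> None:
    rows = [
        (fam, gene)
        for fam in sorted(preds.families)
        for gene in sorted(preds.families[fam])
    ]
    pd.DataFrame(rows, columns=["mirna_family", "gene_symbol"]).to_csv(
        path, sep="\t", index=False
    )


def build_expressed_sets(
    preds: TargetPredictionSet, table: GeneExpressionTable
) -> ExpressedTargetSets:
    """Intersect each family's predictions with the profile's expressed genes."""
    expressed = table.genes
    per_mirna = {fam: targets & expressed for fam, targets in preds.families.items()}
    universe = frozenset().union(*per_mirna.values()) if per_mirna else frozenset()
    return ExpressedTargetSets(
        dataset_id=table.dataset_id, per_mirna=per_mirna, universe=universe
    )


def _family_stream(seed: int, replicate: int, family_id: str) -> np.random.Generator:
    # Stable per-replicate, per-family substream: adding or reordering
    # families must not perturb the draws of the others.
    digest = int.from_bytes(
        hashlib.sha256(family_id.encode("utf-8")).digest()[:4], "big"
    )
    return np.random.default_rng(np.random.SeedSequence([seed, replicate, digest]))


def generate_random_sets(
    ets: ExpressedTargetSets,
    n_sets: int = 5,
    *,
    seed: int,
    preds: TargetPredictionSet | None = None,
) -> list[ExpressedTargetSets]:
    """Size-matched random control sets.

    For each of ``n_sets`` replicates, every family is assigned a uniform
    random sample, without replacement, from the universe — the same number
    of genes as its true expressed target set, so null and observed tests
    are identically powered.  Sampling is independent across families
    (control sets may overlap, as real predictions do) and fully
    reproducible from ``seed``.

    Passing ``preds`` switches to randomising the raw predictions instead:
    each family draws its *predicted* set size from the pool of all
    predicted genes, and the draw is then intersected with the expressed
    universe, so control set sizes fluctuate the way a pre-filter
    randomisation would make them.
    """
    universe = np.array(sorted(ets.universe))
    out: list[ExpressedTargetSets] = []
    if preds is None:
        pool = universe
        sizes = {fam: len(targets) for fam, targets in ets.per_mirna.items()}
    else:
        pool = np.array(sorted(frozenset().union(*preds.families.values())))
        sizes = {fam: len(preds.families.get(fam, ())) for fam in ets.per_mirna}
    for fam, size in sizes.items():
        if size > len(pool):
            raise ValueError(
                f"family {fam!r}: set size {size} exceeds sampling pool "
                f"size {len(pool)}"
            )
    for rep in range(n_sets):
        per_mirna = {}
        for fam in ets.per_mirna:
            rng = _family_stream(seed, rep, fam)
            draw = rng.choice(pool, size=sizes[fam], replace=False)
            sampled = frozenset(str(g) for g in draw)
            per_mirna[fam] = sampled if preds is None else sampled & ets.universe
        out.append(
            ExpressedTargetSets(
                dataset_id=f"{ets.dataset_id}#random{rep + 1}",
                per_mirna=per_mirna,
                universe=ets.universe,
            )
        )
    return out
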