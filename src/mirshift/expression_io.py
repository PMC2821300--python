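"""Reading, filtering and gene-level collapsing of probeset expression tables.

The pipeline consumes processed (MAS5-style) Affymetrix signal tables: one row
per probeset with a signal value and, optionally, a Present/Marginal/Absent
detection call.  Probesets are reduced to the single-gene-specific ``_at``
design, restricted to those detected in the profile, mapped to gene symbols
through a local annotation table, and averaged per gene to give the signal
used by the downstream target-set shift test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Detection call vocabulary.  ``unavailable`` marks rows from tables that
#: carry no call column at all.
CALLS = frozenset({"present", "marginal", "absent", "unavailable"})

#: Qualified Affymetrix probeset suffixes that may cross-hybridise to several
#: transcripts; only plain ``_at`` probesets are treated as single-gene.
QUALIFIED_SUFFIXES = (
    "_s_at", "_x_at", "_a_at", "_f_at", "_g_at", "_i_at", "_r_at", "_b_at",
)

_CALL_TOKENS = {
    "p": "present", "present": "present",
    "m": "marginal", "marginal": "marginal",
    "a": "absent", "absent": "absent",
}


class ExpressionParseError(ValueError):
    """Raised when an expression or annotation table violates its contract."""


class ProbeRecord(NamedTuple):
    probeset_id: str
    signal: float
    call: str


@dataclass(frozen=True)
class ExpressionDataset:
    """Probeset-level signals and detection calls for one expression profile.

    Parameters
    ----------
    dataset_id:
        Opaque identifier of the profile (e.g. a GEO sample accession).
    tissue:
        Label grouping profiles that are later meta-analysed together
        (e.g. ``"CE-RSC"``, ``"P4"``, ``"adult"``).
    records:
        One :class:`ProbeRecord` per probeset.  Signals are non-negative,
        arbitrary units; calls are from :data:`CALLS`.
    """

    dataset_id: str
    tissue: str
    records: tuple[ProbeRecord, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.probeset_id in seen:
                raise ExpressionParseError(
                    f"duplicate probeset id {rec.probeset_id!r} in dataset "
                    f"{self.dataset_id!r}"
                )
            seen.add(rec.probeset_id)
            if not np.isfinite(rec.signal) or rec.signal < 0:
                raise ExpressionParseError(
                    f"negative or non-finite signal {rec.signal!r} for "
                    f"probeset {rec.probeset_id!r}"
                )
            if rec.call not in CALLS:
                raise ExpressionParseError(
                    f"unknown detection call {rec.call!r} for probeset "
                    f"{rec.probeset_id!r}"
                )

    @property
    def has_calls(self) -> bool:
        """True when at least one record carries an actual detection call."""
        return any(rec.call != "unavailable" for rec in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ProbeAnnotation:
    """Probeset -> gene-symbol map (symbols uppercased).

    ``n_skipped`` counts input rows dropped for lacking a gene symbol.
    """

    entries: Mapping[str, str]
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class GeneExpressionTable:
    """Gene-symbol -> mean signal over the retained probesets of one profile."""

    dataset_id: str
    values: Mapping[str, float]

    def __len__(self) -> int:
        return len(self.values)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.values)


def _find_column(columns: Iterable[str], tokens: tuple[str, ...]) -> str | None:
    for col in columns:
        low = str(col).strip().lower()
        if any(tok in low for tok in tokens):
            return col
    return None


def _parse_call(token: object) -> str:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return "unavailable"
    text = str(token).strip().lower()
    if text == "":
        return "unavailable"
    if text not in _CALL_TOKENS:
        raise ExpressionParseError(f"unrecognised detection call {token!r}")
    return _CALL_TOKENS[text]


def load_expression_table(path: str | Path, dataset_id: str, tissue: str) -> ExpressionDataset:
    """Load a tab-delimited probeset expression table.

    The header must name a probeset column and a signal column (matched
    case-insensitively); a detection-call column is optional and, when
    absent, every record is marked ``unavailable``.  Calls are parsed
    case-insensitively (P/M/A or full words).

    Raises
    ------
    ExpressionParseError
        On a missing column, a non-numeric or negative signal (the message
        names the offending row), a duplicate probeset id, or an
        unrecognised call token.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    probe_col = _find_column(df.columns, ("probeset", "probe_id", "probe"))
    signal_col = _find_column(df.columns, ("signal", "value", "intensity"))
    if probe_col is None or signal_col is None:
        raise ExpressionParseError(
            f"{path}: header must name probeset and signal columns; "
            f"found {list(df.columns)!r}"
        )
    call_col = _find_column(df.columns, ("call", "detection"))

    signals = []
    for row, raw in enumerate(df[signal_col], start=1):
        try:
            value = float(raw)  # exact round-trip for repr-formatted floats
        except (TypeError, ValueError):
            value = math.nan
        if not math.isfinite(value) or value < 0:
            raise ExpressionParseError(
                f"{path}: non-numeric or negative signal {raw!r} at data "
                f"row {row} (probeset {df[probe_col].iloc[row - 1]!r})"
            )
        signals.append(value)

    if call_col is not None:
        calls = [_parse_call(v) for v in df[call_col]]
    else:
        calls = ["unavailable"] * len(df)

    records = tuple(
        ProbeRecord(str(p).strip(), float(s), c)
        for p, s, c in zip(df[probe_col], signals, calls)
    )
    ds = ExpressionDataset(dataset_id=dataset_id, tissue=tissue, records=records)
    logger.info("loaded %d probesets for dataset %s (%s)", len(ds), dataset_id, tissue)
    return ds


def write_expression_table(ds: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset back to the tab-delimited dialect read by
    :func:`load_expression_table`.  The call column is omitted when every
    record is ``unavailable``."""
    rows = {"probeset_id": [r.probeset_id for r in ds.records],
            "signal": [repr(r.signal) for r in ds.records]}
    if ds.has_calls:
        rows["call"] = [r.call[0].upper() for r in ds.records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Load a two-column tab-delimited probeset -> gene-symbol table.

    Symbols are uppercased; rows with an empty symbol are skipped (counted in
    ``n_skipped``).  A probeset mapped to two distinct symbols is an error:
    the filtering step upstream assumes single-gene-specific probesets.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ExpressionParseError(f"{path}: annotation needs two columns")
    probe_col, symbol_col = df.columns[:2]
    entries: dict[str, str] = {}
    skipped = 0
    for probe, symbol in zip(df[probe_col], df[symbol_col]):
        probe = str(probe).strip()
        if symbol is None or (isinstance(symbol, float) and np.isnan(symbol)) \
                or str(symbol).strip() == "":
            skipped += 1
            continue
        sym = str(symbol).strip().upper()
        if probe in entries and entries[probe] != sym:
            raise ExpressionParseError(
                f"{path}: probeset {probe!r} maps to both "
                f"{entries[probe]!r} and {sym!r}"
            )
        entries[probe] = sym
    if skipped:
        logger.info("annotation %s: skipped %d rows with empty symbol", path, skipped)
    return ProbeAnnotation(entries=entries, n_skipped=skipped)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        {"probeset_id": list(ann.entries), "gene_symbol": list(ann.entries.values())}
    ).to_csv(path, sep="\t", index=False)


def _is_single_gene(probeset_id: str) -> bool:
    return probeset_id.endswith("_at") and not any(
        probeset_id.endswith(suf) for suf in QUALIFIED_SUFFIXES
    )


def filter_probesets(ds: ExpressionDataset) -> ExpressionDataset:
    """Keep single-gene-specific, expressed probesets.

    A probeset is retained when (1) its id ends in plain ``_at`` (qualified
    suffixes such as ``_s_at``/``_x_at`` denote multi-transcript probesets and
    are dropped) and (2) it is expressed in the profile: ``present`` call when
    the dataset carries calls, otherwise signal strictly greater than the
    median signal of the suffix-passing probesets.

    In the median-fallback branch the retained records are re-labelled
    ``present``, recording the expression designation; filtering is therefore
    idempotent in both branches.  An empty result is a warning, not an error —
    the downstream minimum-target-count filter copes with it.
    """
    single = [r for r in ds.records if _is_single_gene(r.probeset_id)]
    if ds.has_calls:
        kept = tuple(r for r in single if r.call == "present")
    elif single:
        median = float(np.median([r.signal for r in single]))
        kept = tuple(
            ProbeRecord(r.probeset_id, r.signal, "present")
            for r in single if r.signal > median
        )
    else:
        kept = ()
    if not kept:
        logger.warning(
            "dataset %s: no probesets survive filtering", ds.dataset_id
        )
    return replace(ds, records=kept)


def collapse_to_genes(ds: ExpressionDataset, ann: ProbeAnnotation) -> GeneExpressionTable:
    """Average retained probesets per annotated gene.

    Each gene's value is the arithmetic mean of its retained probesets'
    signals; probesets without an annotation entry are dropped (logged).
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    dropped = 0
    for rec in ds.records:
        symbol = ann.entries.get(rec.probeset_id)
        if symbol is None:
            dropped += 1
            continue
        sums[symbol] = sums.get(symbol, 0.0) + rec.signal
        counts[symbol] = counts.get(symbol, 0) + 1
    if dropped:
        logger.info(
            "dataset %s: %d retained probesets lacked annotation", ds.dataset_id, dropped
        )
    values = {g: sums[g] / counts[g] for g in sums}
    return GeneExpressionTable(dataset_id=ds.dataset_id, values=values)


def write_gene_table(table: GeneExpressionTable, path: str | Path) -> None:
    """Audit output: the gene-level table as TSV (gene, signal)."""
    genes = sorted(table.values)
    pd.DataFrame(
        {"gene_symbol": genes, "signal": [repr(table.values[g]) for g in genes]}
    ).to_csv(path, sep="\t", index=False)
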