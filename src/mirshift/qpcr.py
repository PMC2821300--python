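"""qPCR quantification: standard curves, relative expression, and absolute
starting-template estimation.

Two quantities are computed from threshold-cycle (Ct) data.  *Relative*
expression inverts a standard curve (Ct regressed on log10 concentration of a
dilution series) at the sample's Ct.  *Absolute* starting template uses the
exponential amplification model: fluorescence at threshold is
``R_Ct = R_0 · (1 + E)^Ct``, so the starting fluorescence — proportional to
the starting template amount — is ``R_0 = R_Ct / (1 + E)^Ct``, with the
amplification efficiency E estimated from the standard-curve slope as
``E = 10^(−1/slope) − 1`` (perfect doubling gives slope −3.32, E = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QpcrRecord:
    """One reaction: a target (miRNA or gene) in one sample.

    ``r_ct`` is the fluorescence at the threshold cycle (arbitrary,
    instrument-specific units); ``efficiency`` is the per-cycle fractional
    template gain, optional until derived from a standard curve.
    """

    target_id: str
    sample_id: str
    ct: float
    r_ct: float | None = None
    efficiency: float | None = None

    def __post_init__(self) -> None:
        if not self.ct > 0:
            raise ValueError(f"Ct must be positive, got {self.ct!r}")
        if self.r_ct is not None and not self.r_ct > 0:
            raise ValueError(f"threshold fluorescence must be positive, got {self.r_ct!r}")


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Ct on log10 concentration over a dilution series."""

    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    efficiency: float


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit a dilution standard curve (log10 concentration, Ct).

    Requires at least three points at distinct concentrations; the slope
    must be negative (more template → earlier threshold crossing).  The
    amplification efficiency is ``10^(−1/slope) − 1``.
    """
    pts = tuple((float(c), float(ct)) for c, ct in points)
    if len(pts) < 3:
        raise ValueError(f"standard curve needs >= 3 points, got {len(pts)}")
    conc = np.array([c for c, _ in pts])
    ct = np.array([t for _, t in pts])
    if len(np.unique(conc)) < 2:
        raise ValueError("standard curve needs distinct concentrations")
    slope, intercept = np.polyfit(conc, ct, 1)
    if slope >= 0:
        raise ValueError(
            f"standard-curve slope must be negative, got {slope:.4g} "
            "(no amplification relationship)"
        )
    efficiency = 10.0 ** (-1.0 / slope) - 1.0
    return StandardCurve(
        points=pts, slope=float(slope), intercept=float(intercept),
        efficiency=float(efficiency),
    )


def relative_expression(record: QpcrRecord, curve: StandardCurve) -> float:
    """Template concentration read off the standard curve at the record's Ct.

    Returns ``10^((ct − intercept)/slope)`` — the concentration, on the
    dilution series' relative scale, that would reach threshold at this Ct.
    """
    return float(10.0 ** ((record.ct - curve.intercept) / curve.slope))


def rescale_to_max(values: Mapping[str, float], top: float = 100.0) -> dict[str, float]:
    """Rescale a per-sample value map so the highest sample equals ``top``
    (the convention for plotting relative expression across samples)."""
    if not values:
        return {}
    peak = max(values.values())
    if peak <= 0:
        raise ValueError("cannot rescale: maximum value is not positive")
    return {k: v / peak * top for k, v in values.items()}


def estimate_copy_number(record: QpcrRecord) -> float:
    """Starting fluorescence R0 = R_Ct / (1 + E)^Ct, proportional to the
    starting template amount.

    Requires the record to carry both threshold fluorescence and an
    amplification efficiency; E must be non-negative (E = 0 degenerates to
    no amplification, returning R_Ct itself).
    """
    if record.r_ct is None or record.efficiency is None:
        raise ValueError(
            f"record {record.target_id}/{record.sample_id}: needs r_ct and efficiency"
        )
    if record.efficiency < 0:
        raise ValueError(f"efficiency must be >= 0, got {record.efficiency!r}")
    return float(record.r_ct / (1.0 + record.efficiency) ** record.ct)


# ---------------------------------------------------------------------------
# Table-level IO
# ---------------------------------------------------------------------------

def load_qpcr_records(path: str | Path) -> list[QpcrRecord]:
    """TSV with columns target, sample, ct and optional r_ct."""
    df = pd.read_csv(path, sep="\t")
    cols = {str(c).lower(): c for c in df.columns}
    needed = [k for k in ("target", "sample", "ct") if k not in cols]
    if needed:
        raise ValueError(f"{path}: missing columns {needed}")
    records = []
    for row in df.itertuples(index=False):
        d = dict(zip((str(c).lower() for c in df.columns), row))
        r_ct = d.get("r_ct")
        records.append(
            QpcrRecord(
                target_id=str(d["target"]),
                sample_id=str(d["sample"]),
                ct=float(d["ct"]),
                r_ct=None if r_ct is None or pd.isna(r_ct) else float(r_ct),
            )
        )
    return records


def load_standard_curves(path: str | Path) -> dict[str, StandardCurve]:
    """TSV with columns target, log10_concentration, ct; one fitted curve
    per target."""
    df = pd.read_csv(path, sep="\t")
    cols = {str(c).lower(): c for c in df.columns}
    for k in ("target", "log10_concentration", "ct"):
        if k not in cols:
            raise ValueError(f"{path}: missing column {k}")
    curves = {}
    for target, grp in df.groupby(cols["target"]):
        pts = list(zip(grp[cols["log10_concentration"]], grp[cols["ct"]]))
        curves[str(target)] = fit_standard_curve(pts)
    return curves


def quantify(
    records: Sequence[QpcrRecord],
    curves: Mapping[str, StandardCurve],
    rescale: bool = True,
) -> pd.DataFrame:
    """Relative and, where threshold fluorescence is present, absolute
    quantification of every record with a matching standard curve.

    Relative values are optionally rescaled per target so the
    highest-expressing sample reads 100.  Returns a DataFrame with columns
    target, sample, ct, efficiency, relative_expression, r0.
    """
    rows = []
    for rec in records:
        curve = curves.get(rec.target_id)
        if curve is None:
            logger.warning("no standard curve for target %s; skipped", rec.target_id)
            continue
        rec = replace(rec, efficiency=curve.efficiency)
        rel = relative_expression(rec, curve)
        r0 = estimate_copy_number(rec) if rec.r_ct is not None else np.nan
        rows.append((rec.target_id, rec.sample_id, rec.ct, curve.efficiency, rel, r0))
    df = pd.DataFrame(
        rows,
        columns=["target", "sample", "ct", "efficiency", "relative_expression", "r0"],
    )
    if rescale and not df.empty:
        df["relative_expression"] = df.groupby("target")[
            "relative_expression"
        ].transform(lambda s: s / s.max() * 100.0)
    return df
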