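"""Synthetic inputs: prediction tables, expression profiles with planted
miRNA-mediated repression, and qPCR data.

The generator emulates the shape of the real inputs — probeset-level signal
tables from several profiles per tissue, a conserved-family target prediction
table with ~200 targets per family, and dilution-series qPCR runs — with a
known ground truth, so every pipeline stage is testable without external
downloads.

Model: each gene is either expressed in the tissue (latent state, default
60% of genes) or not; expressed genes draw an independent log2 baseline per
profile (profiles are independent experiments), non-expressed genes sit at a
low background level, and detection calls report the latent state.  An
active miRNA represses a fixed random fraction of its predicted targets
multiplicatively — a subtraction of log2(fold_change) that accumulates over
families sharing a target.  Measurement noise is additive in log2.  The
random streams for structure, baselines and noise are independent of the
planted-effect configuration, so runs differing only in ``active_mirnas``
are identical except at the affected genes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .expression_io import (
    ExpressionDataset,
    ProbeAnnotation,
    ProbeRecord,
    write_expression_table,
    write_probe_annotation,
)
from .qpcr import QpcrRecord
from .target_sets import TargetPredictionSet, write_target_predictions

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ActiveMirna:
    """A planted repressor: ``fraction_functional`` of its predicted targets
    are depressed ``fold_change``-fold at the mRNA level."""

    family: str
    fraction_functional: float
    fold_change: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_functional <= 1.0:
            raise ValueError("fraction_functional must be in [0, 1]")
        if self.fold_change < 1.0:
            raise ValueError("fold_change must be >= 1")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    Defaults describe a mid-sized screen: 5000 genes, 100 miRNA families
    with Poisson(200) predicted targets each, three profiles per tissue,
    60% of genes expressed, log2 baseline spread 0.5 between genes within a
    profile and measurement noise 0.4 log2 units.
    """

    n_genes: int = 5000
    n_mirnas: int = 100
    targets_per_mirna: float = 200.0
    two_probeset_fraction: float = 0.2
    decoy_probeset_fraction: float = 0.05
    expressed_fraction: float = 0.6
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 0.5
    unexpressed_log2_mean: float = 4.0
    unexpressed_log2_sd: float = 0.5
    active_mirnas: tuple[ActiveMirna, ...] = ()
    noise_sd: float = 0.4
    tissues: tuple[str, ...] = ("retina",)
    n_datasets: int = 3
    call_rule: str = "calls"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_datasets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.targets_per_mirna <= 0:
            raise ValueError("targets_per_mirna must be positive")
        for name in ("two_probeset_fraction", "decoy_probeset_fraction",
                     "expressed_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0 or self.baseline_log2_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.call_rule not in ("calls", "none"):
            raise ValueError(f"call_rule must be 'calls' or 'none', got {self.call_rule!r}")
        if not self.tissues:
            raise ValueError("at least one tissue required")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SyntheticConfig":
        raw = dict(raw)
        actives = tuple(
            ActiveMirna(**a) if isinstance(a, Mapping) else a
            for a in raw.pop("active_mirnas", ())
        )
        if "tissues" in raw:
            raw["tissues"] = tuple(raw["tissues"])
        return cls(active_mirnas=actives, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["active_mirnas"] = [dataclasses.asdict(a) for a in self.active_mirnas]
        d["tissues"] = list(self.tissues)
        return d


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulation.

    ``affected_genes`` maps each planted family to the *expressed* genes it
    represses — the ones whose depression the pipeline can in principle see.
    """

    active_families: tuple[str, ...]
    affected_genes: Mapping[str, frozenset[str]]
    expressed_genes: frozenset[str]


@dataclass(frozen=True)
class SyntheticExpressionData:
    datasets: tuple[ExpressionDataset, ...]
    annotation: ProbeAnnotation
    truth: SyntheticTruth


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def _digest(name: str) -> int:
    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")


def _gene_symbols(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_target_predictions(cfg: SyntheticConfig) -> TargetPredictionSet:
    """Random prediction table: per family a uniform gene sample of
    Poisson(``targets_per_mirna``) size (at least 1, at most ``n_genes``)."""
    rng = _stream(cfg.seed, 0)
    genes = np.array(_gene_symbols(cfg.n_genes))
    families: dict[str, frozenset[str]] = {}
    truncated = 0
    for i in range(cfg.n_mirnas):
        size = max(1, int(rng.poisson(cfg.targets_per_mirna)))
        if size > cfg.n_genes:
            size = cfg.n_genes
            truncated += 1
        draw = rng.choice(genes, size=size, replace=False)
        families[f"miR-{i + 1:03d}"] = frozenset(str(g) for g in draw)
    if truncated:
        logger.warning(
            "%d families truncated to the %d available genes", truncated, cfg.n_genes
        )
    return TargetPredictionSet(families=families)


def generate_expression_datasets(
    cfg: SyntheticConfig, preds: TargetPredictionSet
) -> SyntheticExpressionData:
    """Simulate probeset-level profiles with planted repression.

    Returns the profiles (``n_datasets`` per tissue), the probeset
    annotation, and the ground-truth record.  Signals are ``2**log2`` and
    hence non-negative; each gene carries one plain ``_at`` probeset, a
    second one for a fraction of genes, and a small fraction of genes add a
    cross-hybridising decoy (``_x_at``/``_s_at``) that the suffix filter
    must discard.
    """
    missing = [a.family for a in cfg.active_mirnas if a.family not in preds.families]
    if missing:
        raise ValueError(f"active families absent from predictions: {missing}")
    genes = _gene_symbols(cfg.n_genes)
    struct = _stream(cfg.seed, 1)
    latent = struct.random(cfg.n_genes) < cfg.expressed_fraction
    two_probe = struct.random(cfg.n_genes) < cfg.two_probeset_fraction
    decoy = struct.random(cfg.n_genes) < cfg.decoy_probeset_fraction

    # Planted repression, additive in log2 over families sharing a target.
    gene_index = {g: i for i, g in enumerate(genes)}
    repression = np.zeros(cfg.n_genes)
    affected: dict[str, frozenset[str]] = {}
    for active in cfg.active_mirnas:
        fam_rng = _stream(cfg.seed, 2, _digest(active.family))
        targets = sorted(preds.families[active.family])
        hit = fam_rng.random(len(targets)) < active.fraction_functional
        hit_genes = [g for g, h in zip(targets, hit) if h]
        for g in hit_genes:
            repression[gene_index[g]] += math.log2(active.fold_change)
        affected[active.family] = frozenset(
            g for g in hit_genes if latent[gene_index[g]]
        )
    repression = np.where(latent, repression, 0.0)

    # Probeset layout shared by every profile.
    probes: list[tuple[str, int]] = []  # (probeset_id, gene index)
    entries: dict[str, str] = {}
    for i, g in enumerate(genes):
        main = f"ps{i:05d}_at"
        probes.append((main, i))
        entries[main] = g
        if two_probe[i]:
            second = f"ps{i:05d}_2_at"
            probes.append((second, i))
            entries[second] = g
        if decoy[i]:
            suffix = "_x_at" if i % 2 == 0 else "_s_at"
            decoy_id = f"ps{i:05d}{suffix}"
            probes.append((decoy_id, i))
            entries[decoy_id] = g
    annotation = ProbeAnnotation(entries=entries)

    datasets = []
    ds_counter = 0
    for tissue in cfg.tissues:
        for _ in range(cfg.n_datasets):
            ds_counter += 1
            rng = _stream(cfg.seed, 3, ds_counter)
            base_expr = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
            base_unexpr = rng.normal(
                cfg.unexpressed_log2_mean, cfg.unexpressed_log2_sd, cfg.n_genes
            )
            noise = rng.normal(0.0, cfg.noise_sd, cfg.n_genes) if cfg.noise_sd > 0 \
                else np.zeros(cfg.n_genes)
            log2_sig = np.where(latent, base_expr, base_unexpr) - repression + noise
            signal = np.power(2.0, log2_sig)
            records = []
            for probe_id, gi in probes:
                call = "unavailable" if cfg.call_rule == "none" else (
                    "present" if latent[gi] else "absent"
                )
                records.append(ProbeRecord(probe_id, float(signal[gi]), call))
            datasets.append(
                ExpressionDataset(
                    dataset_id=f"{tissue}-ds{ds_counter}",
                    tissue=tissue,
                    records=tuple(records),
                )
            )
    truth = SyntheticTruth(
        active_families=tuple(a.family for a in cfg.active_mirnas),
        affected_genes=affected,
        expressed_genes=frozenset(g for g, l in zip(genes, latent) if l),
    )
    return SyntheticExpressionData(
        datasets=tuple(datasets), annotation=annotation, truth=truth
    )


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrSimulation:
    """Simulated dilution series and sample reactions with ground truth."""

    curve_points: Mapping[str, tuple[tuple[float, float], ...]]
    records: tuple[QpcrRecord, ...]
    true_efficiency: Mapping[str, float]
    true_r0: Mapping[str, float]


def generate_qpcr_data(
    cfg: SyntheticConfig,
    activity_strength: Mapping[str, float],
    *,
    r_ct_threshold: float = 1000.0,
    r0_scale: float = 1e-6,
    n_dilutions: int = 5,
    sample_id: str = "pooled",
) -> QpcrSimulation:
    """Simulate qPCR consistent with exponential amplification.

    Each family's true starting fluorescence is proportional (on the log
    scale) to its activity strength: ``r0 = r0_scale · 10**strength``.  The
    threshold cycle solves ``r_ct = r0 · (1+E)**ct`` at a fixed fluorescence
    threshold, with the per-family efficiency E drawn uniformly from
    [0.85, 1.0].  The ten-fold dilution series is generated from the same E,
    so fitting it recovers E exactly and a perfect-doubling family shows the
    canonical 3.32-cycle spacing.
    """
    rng = _stream(cfg.seed, 100)
    curve_points: dict[str, tuple[tuple[float, float], ...]] = {}
    records: list[QpcrRecord] = []
    true_e: dict[str, float] = {}
    true_r0: dict[str, float] = {}
    for fam in sorted(activity_strength):
        eff = float(rng.uniform(0.85, 1.0))
        r0 = r0_scale * 10.0 ** float(activity_strength[fam])
        if r0 >= r_ct_threshold:
            logger.warning("family %s: r0 >= threshold; clamping", fam)
            r0 = r_ct_threshold / 10.0
        ct0 = math.log(r_ct_threshold / r0) / math.log(1.0 + eff)
        slope = -1.0 / math.log10(1.0 + eff)
        points = tuple(
            (-float(i), ct0 - slope * float(i)) for i in range(n_dilutions)
        )
        curve_points[fam] = points
        records.append(
            QpcrRecord(
                target_id=fam, sample_id=sample_id, ct=ct0, r_ct=r_ct_threshold,
                efficiency=eff,
            )
        )
        true_e[fam] = eff
        true_r0[fam] = r0
    return QpcrSimulation(
        curve_points=curve_points,
        records=tuple(records),
        true_efficiency=true_e,
        true_r0=true_r0,
    )


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------

def simulate_to_dir(cfg: SyntheticConfig, outdir: str | Path) -> dict:
    """Write a complete input bundle in the dialects the pipeline consumes.

    Produces ``predictions.tsv``, ``annotation.tsv``, one expression TSV per
    profile, ``truth.json`` and a ready-to-run ``pipeline_config.yaml``.
    Returns the pipeline-config mapping.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    preds = generate_target_predictions(cfg)
    data = generate_expression_datasets(cfg, preds)
    write_target_predictions(preds, outdir / "predictions.tsv")
    write_probe_annotation(data.annotation, outdir / "annotation.tsv")
    dataset_entries = []
    for ds in data.datasets:
        path = outdir / f"expression_{ds.dataset_id}.tsv"
        write_expression_table(ds, path)
        dataset_entries.append(
            {"path": str(path), "dataset_id": ds.dataset_id, "tissue": ds.tissue}
        )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "active_families": list(data.truth.active_families),
                "affected_genes": {
                    f: sorted(g) for f, g in data.truth.affected_genes.items()
                },
                "n_expressed_genes": len(data.truth.expressed_genes),
            },
            fh, indent=2, sort_keys=True,
        )
    pipeline_cfg = {
        "datasets": dataset_entries,
        "annotation": str(outdir / "annotation.tsv"),
        "predictions": str(outdir / "predictions.tsv"),
        "seed": cfg.seed,
        "output_dir": str(outdir / "results"),
    }
    with open(outdir / "pipeline_config.yaml", "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=True)
    with open(outdir / "synthetic_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return pipeline_cfg
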