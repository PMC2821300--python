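"""End-to-end orchestration: load → filter → collapse → target sets →
per-profile tests → random controls → Fisher combination → gene ranking →
optional abundance association, with a reproducible report bundle.

Every output is a TSV (plus a JSON manifest) written deterministically: the
same configuration and seed produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .activity import (
    ActivityResult,
    CombinedActivityResult,
    ControlProfile,
    combine_across_datasets,
    control_profile,
    rank_genes_by_mirna_count,
    test_all_mirnas,
)
from .association import (
    GroupComparison,
    compare_group_expression,
    correlate_expression_significance,
)
from .expression_io import (
    collapse_to_genes,
    filter_probesets,
    load_expression_table,
    load_probe_annotation,
    write_gene_table,
)
from .target_sets import (
    ExpressedTargetSets,
    build_expressed_sets,
    load_target_predictions,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and the offending input."""


@dataclass(frozen=True)
class DatasetSpec:
    path: str
    dataset_id: str
    tissue: str


@dataclass(frozen=True)
class PipelineConfig:
    """Run settings; the constants of the screen live here.

    ``min_targets`` (default 50) is the strict lower bound on expressed
    targets; ``n_random_sets`` (default 5) the number of size-matched null
    replicates; ``alpha_table`` (0.05) the combined-p call threshold;
    ``alpha_group`` (0.1) the split for the abundance group comparison;
    ``background`` chooses the rank-sum background composition.
    """

    datasets: tuple[DatasetSpec, ...]
    annotation: str
    predictions: str
    output_dir: str
    min_targets: int = 50
    n_random_sets: int = 5
    alpha_table: float = 0.05
    alpha_group: float = 0.1
    background: str = "exclusive"
    seed: int = 0
    mirna_expression: str | None = None
    gene_list: str | None = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("at least one expression dataset required")
        for name in ("alpha_table", "alpha_group"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {a!r}")
        if self.background not in ("exclusive", "inclusive"):
            raise ValueError(f"unknown background mode {self.background!r}")
        if self.min_targets < 0 or self.n_random_sets < 1:
            raise ValueError("min_targets must be >= 0 and n_random_sets >= 1")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        specs = tuple(
            DatasetSpec(**d) if isinstance(d, Mapping) else d
            for d in raw.pop("datasets", ())
        )
        return cls(datasets=specs, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate_paths(self) -> None:
        missing = [
            p for p in (
                [d.path for d in self.datasets]
                + [self.annotation, self.predictions]
                + ([self.mirna_expression] if self.mirna_expression else [])
                + ([self.gene_list] if self.gene_list else [])
            )
            if not Path(p).exists()
        ]
        if missing:
            raise PipelineError(f"stage startup: missing input files {missing}")


@dataclass
class PipelineResult:
    per_dataset: dict[str, list[ActivityResult]]
    controls: dict[str, list[ControlProfile]]
    combined: list[CombinedActivityResult]
    gene_ranking: pd.DataFrame
    union_sets: ExpressedTargetSets
    group_comparisons: dict[str, GroupComparison] = field(default_factory=dict)
    correlations: dict[str, tuple[float, float]] = field(default_factory=dict)
    output_dir: Path | None = None


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage {name}: {exc}") from exc


def _read_abundance(path: str) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    fam_col, ab_col = df.columns[:2]
    return {str(f): float(a) for f, a in zip(df[fam_col], df[ab_col])}


def _read_gene_list(path: str) -> set[str]:
    return {
        line.strip().upper()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full screen and write the report bundle.

    See the module docstring for the stage order.  Any stage error aborts
    with a :class:`PipelineError` naming the stage.
    """
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "gene_tables").mkdir(exist_ok=True)

    pkg_logger = logging.getLogger("mirshift")
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    pkg_logger.addHandler(handler)
    prior_level = pkg_logger.level
    pkg_logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        pkg_logger.removeHandler(handler)
        pkg_logger.setLevel(prior_level)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> PipelineResult:
    annotation = _stage("annotation", load_probe_annotation, config.annotation)
    predictions = _stage("predictions", load_target_predictions, config.predictions)

    per_dataset: dict[str, list[ActivityResult]] = {}
    controls: dict[str, list[ControlProfile]] = {}
    tissue_of: dict[str, str] = {}
    union_per_mirna: dict[str, set[str]] = {}
    union_universe: set[str] = set()

    for spec in config.datasets:
        tissue_of[spec.dataset_id] = spec.tissue
        ds = _stage(
            f"load[{spec.dataset_id}]",
            load_expression_table, spec.path, spec.dataset_id, spec.tissue,
        )
        filtered = _stage(f"filter[{spec.dataset_id}]", filter_probesets, ds)
        table = _stage(
            f"collapse[{spec.dataset_id}]", collapse_to_genes, filtered, annotation
        )
        write_gene_table(table, outdir / "gene_tables" / f"{spec.dataset_id}.tsv")
        ets = _stage(
            f"target_sets[{spec.dataset_id}]", build_expressed_sets, predictions, table
        )
        for fam, targets in ets.per_mirna.items():
            union_per_mirna.setdefault(fam, set()).update(targets)
        union_universe |= ets.universe
        per_dataset[spec.dataset_id] = _stage(
            f"test[{spec.dataset_id}]",
            test_all_mirnas, table, ets, config.min_targets, config.background,
        )
        controls[spec.dataset_id] = _stage(
            f"controls[{spec.dataset_id}]",
            control_profile, table, ets, config.n_random_sets,
            seed=config.seed, min_targets=config.min_targets,
            background=config.background,
        )
        if config.make_plots:
            _stage(
                f"plot[{spec.dataset_id}]",
                _activity_figure,
                per_dataset[spec.dataset_id], controls[spec.dataset_id],
                outdir / f"figure_activity_{spec.dataset_id}.png",
            )

    by_tissue: dict[str, list[ActivityResult]] = {}
    for ds_id, results in per_dataset.items():
        by_tissue.setdefault(tissue_of[ds_id], []).extend(results)
    combined = _stage(
        "combine", combine_across_datasets, by_tissue, config.alpha_table
    )

    union_sets = ExpressedTargetSets(
        dataset_id="union",
        per_mirna={f: frozenset(g) for f, g in union_per_mirna.items()},
        universe=frozenset(union_universe),
    )
    gene_list = _read_gene_list(config.gene_list) if config.gene_list else None
    ranking = _stage(
        "gene_ranking", rank_genes_by_mirna_count, combined, union_sets
    )

    result = PipelineResult(
        per_dataset=per_dataset,
        controls=controls,
        combined=combined,
        gene_ranking=ranking,
        union_sets=union_sets,
        output_dir=outdir,
    )

    if config.mirna_expression:
        abundance = _stage("abundance", _read_abundance, config.mirna_expression)
        for tissue in sorted(by_tissue):
            tissue_combined = [r for r in combined if r.tissue == tissue]
            try:
                result.group_comparisons[tissue] = compare_group_expression(
                    abundance, tissue_combined, config.alpha_group
                )
            except ValueError as exc:
                logger.warning("group comparison skipped for %s: %s", tissue, exc)
            try:
                result.correlations[tissue] = correlate_expression_significance(
                    abundance, tissue_combined
                )
            except ValueError as exc:
                logger.warning("correlation skipped for %s: %s", tissue, exc)

    _stage("reports", _write_reports, config, result, tissue_of, gene_list, outdir)
    return result


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

def _write_reports(
    config: PipelineConfig,
    result: PipelineResult,
    tissue_of: Mapping[str, str],
    gene_list: set[str] | None,
    outdir: Path,
) -> None:
    rows = [
        (tissue_of[r.dataset_id], r.dataset_id, r.family_id, r.n_targets,
         repr(r.avg_target_signal), repr(r.p_value))
        for ds_id in sorted(result.per_dataset)
        for r in result.per_dataset[ds_id]
    ]
    pd.DataFrame(
        rows,
        columns=["tissue", "dataset_id", "family", "n_targets",
                 "avg_target_signal", "p_value"],
    ).to_csv(outdir / "per_dataset_results.tsv", sep="\t", index=False)

    rows = [
        (c.dataset_id, c.family_id, c.n_sets,
         repr(c.mean_log10_p), repr(c.se_log10_p))
        for ds_id in sorted(result.controls)
        for c in result.controls[ds_id]
    ]
    pd.DataFrame(
        rows,
        columns=["dataset_id", "family", "n_sets", "mean_log10_p", "se_log10_p"],
    ).to_csv(outdir / "control_profiles.tsv", sep="\t", index=False)

    rows = [
        (r.family_id, r.tissue,
         ";".join(f"{d}={p!r}" for d, p in r.per_dataset_p),
         repr(r.chi2), r.df, repr(r.combined_p), r.significant)
        for r in result.combined
    ]
    pd.DataFrame(
        rows,
        columns=["family", "tissue", "per_dataset_p", "chi2", "df",
                 "combined_p", "significant"],
    ).to_csv(outdir / "combined_results.tsv", sep="\t", index=False)

    result.gene_ranking.to_csv(
        outdir / "gene_mirna_counts.tsv", sep="\t", index=False
    )
    if gene_list is not None:
        restricted = rank_genes_by_mirna_count(
            result.combined, result.union_sets, gene_list
        )
        restricted.to_csv(outdir / "gene_list_counts.tsv", sep="\t", index=False)

    if result.group_comparisons:
        pd.DataFrame(
            [
                (t, g.n_low, g.n_background, repr(g.p_value))
                for t, g in sorted(result.group_comparisons.items())
            ],
            columns=["tissue", "n_low", "n_background", "p_value"],
        ).to_csv(outdir / "association_group.tsv", sep="\t", index=False)
    if result.correlations:
        pd.DataFrame(
            [
                (t, repr(rho), repr(p))
                for t, (rho, p) in sorted(result.correlations.items())
            ],
            columns=["tissue", "spearman_rho", "p_value"],
        ).to_csv(outdir / "association_correlation.tsv", sep="\t", index=False)

    manifest = {
        "package": "mirshift",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "min_targets": config.min_targets,
            "n_random_sets": config.n_random_sets,
            "alpha_table": config.alpha_table,
            "alpha_group": config.alpha_group,
            "background": config.background,
        },
        "inputs": {
            "datasets": [dataclasses.asdict(d) for d in config.datasets],
            "annotation": config.annotation,
            "predictions": config.predictions,
            "mirna_expression": config.mirna_expression,
            "gene_list": config.gene_list,
        },
        "n_families_combined": len(result.combined),
        "n_significant": sum(r.significant for r in result.combined),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _activity_figure(
    results: Sequence[ActivityResult],
    controls: Sequence[ControlProfile],
    path: Path,
) -> None:
    """Ranked average-target-signal panel over a −log10 p panel with the
    random-set control band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    fams = [r.family_id for r in results]
    x = np.arange(len(fams))
    ax1.bar(x, [r.avg_target_signal for r in results], color="steelblue")
    ax1.set_ylabel("Average target gene signal")
    ctrl = {c.family_id: c for c in controls}
    ax2.scatter(
        x, [np.log10(r.p_value) for r in results], color="red", s=12,
        label="predicted targets", zorder=3,
    )
    band = [ctrl[f].mean_log10_p if f in ctrl else np.nan for f in fams]
    err = [ctrl[f].se_log10_p if f in ctrl else 0.0 for f in fams]
    ax2.errorbar(
        x, band, yerr=err, color="grey", fmt="o", ms=3,
        label="random sets (mean ± se)",
    )
    ax2.set_ylabel("log10 p")
    ax2.set_xlabel("miRNA families (ranked by average target signal)")
    ax2.legend(frameon=False, fontsize=8)
    ax2.set_xticks(x)
    ax2.set_xticklabels(fams, rotation=90, fontsize=5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
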