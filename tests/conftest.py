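import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mirshift as m

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(records, dataset_id="ds1", tissue="retina"):
    return m.ExpressionDataset(
        dataset_id=dataset_id,
        tissue=tissue,
        records=tuple(m.ProbeRecord(*r) for r in records),
    )


@pytest.fixture
def call_dataset():
    """Mixed suffixes and calls; only A_at/present should survive filtering."""
    return make_dataset(
        [
            ("A_at", 10.0, "present"),
            ("B_s_at", 20.0, "present"),
            ("C_at", 5.0, "absent"),
        ]
    )


@pytest.fixture
def median_dataset():
    """No calls: the median fallback applies to the suffix-passing signals."""
    return make_dataset(
        [
            ("A_at", 10.0, "unavailable"),
            ("B_at", 5.0, "unavailable"),
            ("C_at", 7.0, "unavailable"),
            ("D_at", 1.0, "unavailable"),
            ("E_x_at", 100.0, "unavailable"),
        ]
    )


@pytest.fixture
def toy_annotation():
    return m.ProbeAnnotation(
        entries={"A_at": "GA", "B_at": "GB", "C_at": "GC", "D_at": "GD"}
    )


def planted_config(seed=7):
    """Small planted-effect simulation used by pipeline-level tests: two
    strong repressors among 15 families, unambiguous at alpha 1e-3."""
    return m.SyntheticConfig(
        n_genes=800,
        n_mirnas=15,
        targets_per_mirna=60.0,
        n_datasets=2,
        active_mirnas=(
            m.ActiveMirna("miR-001", 0.9, 2.5),
            m.ActiveMirna("miR-002", 0.9, 2.5),
        ),
        noise_sd=0.3,
        seed=seed,
    )


@pytest.fixture(scope="session")
def planted_bundle(tmp_path_factory):
    """On-disk synthetic bundle plus its pipeline config mapping."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = planted_config()
    pipeline_cfg = m.simulate_to_dir(cfg, outdir)
    pipeline_cfg.update({"min_targets": 10, "alpha_table": 1e-3})
    return cfg, pipeline_cfg


def rank_sum_oracle(target, background, alternative="less"):
    """Independent exact oracle: dynamic-programming count, over all
    equally likely size-n subsets of the pooled midranks, of those with a
    rank sum at least as extreme as the observed one.  Doubled midranks are
    integers, so the count is exact."""
    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(target, float), np.asarray(background, float)])
    ranks2 = np.rint(2 * rankdata(pooled)).astype(int)
    n = len(target)
    observed = int(ranks2[:n].sum())
    # counts[k] maps rank-sum -> number of size-k subsets reaching it
    counts = [dict() for _ in range(n + 1)]
    counts[0][0] = 1
    for r in ranks2:
        for k in range(min(n, len(counts)) - 1, -1, -1):
            for s, c in list(counts[k].items()):
                counts[k + 1][s + r] = counts[k + 1].get(s + r, 0) + c
    total = sum(counts[n].values())
    if alternative == "less":
        hits = sum(c for s, c in counts[n].items() if s <= observed)
    else:
        hits = sum(c for s, c in counts[n].items() if s >= observed)
    return hits / total
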