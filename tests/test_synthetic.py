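import dataclasses
import logging
import math

import numpy as np
import pytest

import mirshift as m

from conftest import planted_config


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            m.SyntheticConfig(n_genes=0)
        with pytest.raises(ValueError):
            m.SyntheticConfig(call_rule="sometimes")
        with pytest.raises(ValueError):
            m.ActiveMirna("m", fraction_functional=1.5, fold_change=2.0)
        with pytest.raises(ValueError):
            m.ActiveMirna("m", fraction_functional=0.5, fold_change=0.5)

    def test_yaml_round_trip(self, tmp_path):
        cfg = planted_config()
        import yaml

        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert m.SyntheticConfig.from_yaml(path) == cfg


class TestPredictions:
    def test_family_count_and_mean_size(self):
        cfg = m.SyntheticConfig(n_genes=5000, n_mirnas=50, seed=1)
        preds = m.generate_target_predictions(cfg)
        sizes = [len(s) for s in preds.families.values()]
        assert len(preds.families) == 50
        assert np.mean(sizes) == pytest.approx(200, rel=0.05)

    def test_reproducible(self):
        cfg = m.SyntheticConfig(n_genes=400, n_mirnas=5, targets_per_mirna=30, seed=3)
        assert (
            m.generate_target_predictions(cfg).families
            == m.generate_target_predictions(cfg).families
        )

    def test_sizes_truncated_at_gene_count(self, caplog):
        cfg = m.SyntheticConfig(
            n_genes=10, n_mirnas=3, targets_per_mirna=200.0, seed=0
        )
        with caplog.at_level(logging.WARNING):
            preds = m.generate_target_predictions(cfg)
        assert all(len(s) <= 10 for s in preds.families.values())
        assert any("truncated" in r.message for r in caplog.records)


class TestExpressionDatasets:
    def test_active_family_must_be_predicted(self):
        cfg = m.SyntheticConfig(
            n_genes=100, n_mirnas=2, targets_per_mirna=10,
            active_mirnas=(m.ActiveMirna("miR-999", 0.5, 2.0),), seed=0,
        )
        preds = m.generate_target_predictions(cfg)
        with pytest.raises(ValueError, match="miR-999"):
            m.generate_expression_datasets(cfg, preds)

    def test_full_repression_exactly_halves_signals(self):
        base_cfg = m.SyntheticConfig(
            n_genes=300, n_mirnas=4, targets_per_mirna=40, n_datasets=1,
            noise_sd=0.0, seed=5,
        )
        planted = dataclasses.replace(
            base_cfg, active_mirnas=(m.ActiveMirna("miR-001", 1.0, 2.0),)
        )
        preds = m.generate_target_predictions(base_cfg)
        null = m.generate_expression_datasets(base_cfg, preds)
        hit = m.generate_expression_datasets(planted, preds)
        affected = hit.truth.affected_genes["miR-001"]
        assert affected  # some targets are expressed
        null_sig = {r.probeset_id: r.signal for r in null.datasets[0].records}
        for rec in hit.datasets[0].records:
            gene = hit.annotation.entries[rec.probeset_id]
            if gene in affected:
                assert rec.signal == pytest.approx(
                    null_sig[rec.probeset_id] / 2.0, rel=1e-12
                )
            else:
                assert rec.signal == null_sig[rec.probeset_id]

    def test_datasets_per_tissue_and_calls(self):
        cfg = m.SyntheticConfig(
            n_genes=120, n_mirnas=3, targets_per_mirna=10,
            tissues=("P4", "adult"), n_datasets=2, seed=2,
        )
        preds = m.generate_target_predictions(cfg)
        data = m.generate_expression_datasets(cfg, preds)
        assert len(data.datasets) == 4
        assert {ds.tissue for ds in data.datasets} == {"P4", "adult"}
        for ds in data.datasets:
            assert ds.has_calls
            present = {
                data.annotation.entries[r.probeset_id]
                for r in ds.records if r.call == "present"
            }
            assert present == set(data.truth.expressed_genes)

    def test_call_rule_none_omits_calls(self):
        cfg = m.SyntheticConfig(
            n_genes=80, n_mirnas=2, targets_per_mirna=10, n_datasets=1,
            call_rule="none", seed=2,
        )
        data = m.generate_expression_datasets(cfg, m.generate_target_predictions(cfg))
        assert not data.datasets[0].has_calls

    def test_truth_affected_genes_are_expressed_targets(self):
        cfg = planted_config()
        preds = m.generate_target_predictions(cfg)
        data = m.generate_expression_datasets(cfg, preds)
        for fam, genes in data.truth.affected_genes.items():
            assert genes <= preds.families[fam]
            assert genes <= data.truth.expressed_genes

    def test_written_bundle_reloads_losslessly(self, tmp_path):
        cfg = m.SyntheticConfig(
            n_genes=60, n_mirnas=3, targets_per_mirna=8, n_datasets=1, seed=9
        )
        pipeline_cfg = m.simulate_to_dir(cfg, tmp_path)
        spec = pipeline_cfg["datasets"][0]
        ds = m.load_expression_table(spec["path"], spec["dataset_id"], spec["tissue"])
        data = m.generate_expression_datasets(cfg, m.generate_target_predictions(cfg))
        assert len(ds) == len(data.datasets[0])
        for loaded, orig in zip(ds.records, data.datasets[0].records):
            assert loaded.probeset_id == orig.probeset_id
            assert loaded.signal == orig.signal  # repr round-trips floats
            assert loaded.call == orig.call
        ann = m.load_probe_annotation(pipeline_cfg["annotation"])
        assert ann.entries == dict(data.annotation.entries)


class TestQpcrSimulation:
    def test_dilution_spacing_and_recovery(self):
        cfg = m.SyntheticConfig(seed=4)
        sim = m.generate_qpcr_data(cfg, {"miR-001": 2.0, "miR-002": 0.5})
        for fam, pts in sim.curve_points.items():
            eff = sim.true_efficiency[fam]
            spacing = pts[1][1] - pts[0][1]
            assert spacing == pytest.approx(1.0 / math.log10(1.0 + eff), rel=1e-9)
            curve = m.fit_standard_curve(pts)
            assert curve.efficiency == pytest.approx(eff, abs=1e-9)

    def test_copy_number_round_trip(self):
        cfg = m.SyntheticConfig(seed=4)
        sim = m.generate_qpcr_data(cfg, {"miR-001": 2.0, "miR-002": 0.5})
        for rec in sim.records:
            r0 = m.estimate_copy_number(rec)
            assert r0 == pytest.approx(sim.true_r0[rec.target_id], rel=1e-9)

    def test_r0_proportional_to_strength(self):
        cfg = m.SyntheticConfig(seed=4)
        sim = m.generate_qpcr_data(cfg, {"weak": 0.0, "strong": 3.0})
        assert sim.true_r0["strong"] / sim.true_r0["weak"] == pytest.approx(1e3)
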