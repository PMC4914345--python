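"""Synthetic-data generators: determinism, planted truth, round trips."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from tfscreen.promoters import PromoterSet, extract_promoters
from tfscreen.simulate import (
    ConfigError,
    SimConfig,
    desk_config,
    gen_array_intensities,
    gen_expression_cohorts,
    gen_growth_table,
    gen_promoters,
    gen_pwm_library,
    gen_survival_cohort,
    read_cohort_tsv,
    simulate_screen,
    write_inputs,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_planted_de": 9999}, "n_planted_de"),
            ({"n_tf_genes": 5000, "n_genes": 100}, "n_tf_genes"),
            ({"motif_plant_rate": 1.5}, "motif_plant_rate"),
            ({"censor_rate": -0.1}, "censor_rate"),
            ({"n_samples_per_group": 1}, "n_samples_per_group"),
        ],
    )
    def test_errors_name_the_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            SimConfig(**kwargs)


class TestDeterminism:
    def test_full_screen_outputs_are_byte_identical(self, tmp_path):
        for d in ("a", "b"):
            write_inputs(simulate_screen(desk_config(seed=5)), tmp_path / d)
        files = sorted(p.name for p in (tmp_path / "a").glob("*"))
        for name in files:
            a, b = tmp_path / "a" / name, tmp_path / "b" / name
            if a.is_dir():
                continue
            assert filecmp.cmp(a, b, shallow=False), name
        for name in ["cohort01.tsv", "cohort05.tsv"]:
            assert filecmp.cmp(tmp_path / "a" / "cohorts" / name,
                               tmp_path / "b" / "cohorts" / name, shallow=False)

    def test_generators_use_independent_substreams(self):
        cfg = SimConfig(seed=3, n_genes=100, n_tf_genes=20, n_planted_de=4,
                        n_cohorts=2, n_samples_per_group=3)
        surv_a, _ = gen_survival_cohort(cfg, n=50)
        gen_expression_cohorts(cfg)  # interleaving another generator
        surv_b, _ = gen_survival_cohort(cfg, n=50)
        pd.testing.assert_frame_equal(surv_a, surv_b)


class TestExpressionGenerator:
    def test_null_model_plants_nothing(self):
        cfg = SimConfig(seed=1, n_cohorts=3, n_genes=100, n_tf_genes=20,
                        n_planted_de=5, effect_size=0.0, n_samples_per_group=10)
        cohorts, truth = gen_expression_cohorts(cfg)
        assert truth.de_tfs == []
        pooled_shift = np.mean(
            [c.case_matrix().mean() - c.control_matrix().mean() for c in cohorts]
        )
        assert abs(pooled_shift) < 0.05

    def test_planted_genes_shifted_by_effect_size(self):
        cfg = SimConfig(seed=2, n_cohorts=4, n_genes=200, n_tf_genes=40,
                        n_planted_de=10, effect_size=2.0, n_samples_per_group=50)
        cohorts, truth = gen_expression_cohorts(cfg)
        for c in cohorts:
            idx = [c.values.index.get_loc(g) for g in truth.de_tfs]
            shift = (c.case_matrix()[idx].mean() - c.control_matrix()[idx].mean())
            assert shift == pytest.approx(2.0, abs=0.3)

    def test_dropout_thins_cohort_genes(self):
        cfg = SimConfig(seed=2, n_cohorts=3, n_genes=300, n_tf_genes=40,
                        n_planted_de=5, dropout_fraction=0.3,
                        n_samples_per_group=3)
        cohorts, _ = gen_expression_cohorts(cfg)
        sizes = [len(c.gene_ids) for c in cohorts]
        assert all(150 < s < 250 for s in sizes)
        assert len(set(sizes)) > 1

    def test_cohort_sizes_list(self):
        cfg = SimConfig(seed=1, n_cohorts=3, n_genes=50, n_tf_genes=10,
                        n_planted_de=2, cohort_sizes=[4, 6, 8])
        cohorts, _ = gen_expression_cohorts(cfg)
        assert [c.values.shape[1] for c in cohorts] == [8, 12, 16]


class TestPromoterGenerator:
    def test_promoter_shorter_than_motif_raises(self):
        cfg = SimConfig(seed=1, n_motifs=1, motif_length=12,
                        promoter_length=10, n_planted_de=2, n_tf_genes=10,
                        n_genes=50)
        pwms, _ = gen_pwm_library(cfg)
        with pytest.raises(ConfigError, match="shorter"):
            gen_promoters(cfg, pwms, ["G0001"], ["G0002"], ["M001"])

    def test_overlapping_gene_sets_raise(self):
        cfg = SimConfig(seed=1, n_planted_de=2, n_tf_genes=10, n_genes=50)
        pwms, _ = gen_pwm_library(cfg)
        with pytest.raises(ConfigError, match="overlap"):
            gen_promoters(cfg, pwms, ["G0001"], ["G0001"], [])

    def test_extraction_round_trips_generated_coordinates(self):
        cfg = SimConfig(seed=4, n_motifs=2, promoter_length=300,
                        n_planted_de=2, n_tf_genes=10, n_genes=80)
        pwms, _ = gen_pwm_library(cfg)
        targets = [f"G{i:04d}" for i in range(1, 11)]
        controls = [f"G{i:04d}" for i in range(11, 31)]
        genome, table, proms, _ = gen_promoters(cfg, pwms, targets, controls, ["M001"])
        extracted = extract_promoters(genome, table, upstream=299)
        assert extracted.sequences == proms.sequences
        assert set(table["strand"]) == {"+", "-"}

    def test_planted_positions_recorded(self):
        cfg = SimConfig(seed=4, n_motifs=1, promoter_length=200,
                        motif_plant_rate=1.0, n_planted_de=2, n_tf_genes=10,
                        n_genes=50)
        pwms, _ = gen_pwm_library(cfg)
        targets = [f"G{i:04d}" for i in range(1, 6)]
        _, _, proms, truth = gen_promoters(
            cfg, pwms, targets, ["G0009"], ["M001"], plant_consensus=True
        )
        consensus = pwms[0].consensus
        for gene in targets:
            (pos,) = truth.plant_positions[gene]
            assert proms.sequences[gene][pos - 1:pos - 1 + len(consensus)] == consensus

    def test_fasta_round_trip(self, tmp_path):
        proms = PromoterSet({"g1": "ACGTACGT", "g2": "GGGTTTAA"})
        proms.to_fasta(tmp_path / "p.fa")
        back = PromoterSet.from_fasta(tmp_path / "p.fa")
        assert back.sequences == proms.sequences


class TestArrayGenerator:
    def test_reference_auto_added_with_warning(self):
        cfg = SimConfig(seed=1, array_cv=0.0)
        with pytest.warns(UserWarning, match="auto-added"):
            t = gen_array_intensities(cfg, ["M001"])
        assert "TFIID" in set(t["motif_id"])

    def test_seeded_rerun_identical(self):
        cfg = SimConfig(seed=9)
        mids = [f"M{i:03d}" for i in range(1, 20)]
        a = gen_array_intensities(cfg, mids, bound_motifs=["M001"])
        b = gen_array_intensities(cfg, mids, bound_motifs=["M001"])
        pd.testing.assert_frame_equal(a, b)


class TestGrowthGenerator:
    def test_noiseless_patterns_classify_as_planted(self):
        from tfscreen.growth import classify_all
        from tfscreen.simulate import GROWTH_GROUP_MAP

        cfg = SimConfig(seed=1, growth_noise_sd=0.0)
        pattern = {"SOX11like": {"BT20": 50, "HCC1143": 55, "MDA468": 45,
                                 "MCF7": 95, "T47D": 94, "ZR751": 96}}
        table, truth = gen_growth_table(
            cfg, tfs=["SOX11like", "neutral"], critical_tfs=["SOX11like"],
            pattern=pattern,
        )
        calls = classify_all(table, GROWTH_GROUP_MAP)
        assert calls.loc["SOX11like", "label"] == "BLBC-specific"
        assert calls.loc["neutral", "label"] == "not-critical"
        assert truth.critical_tfs == ["SOX11like"]


class TestSurvivalGenerator:
    def test_censor_fraction_near_target(self):
        cfg = SimConfig(seed=2, censor_rate=0.3, n_subjects=4000)
        df, _ = gen_survival_cohort(cfg)
        assert 1 - df["event"].mean() == pytest.approx(0.3, abs=0.03)

    def test_marker_hazard_ratio_recovered(self):
        from tfscreen.survival import cox_fit

        cfg = SimConfig(seed=6)
        df, truth = gen_survival_cohort(cfg)
        fit = cox_fit(df)
        hr = fit.loc["marker", "hr"]
        assert 1.2 <= hr <= 1.7
        assert truth.true_surv_coefs["marker"] == pytest.approx(np.log(1.42))

    def test_seeded_rerun_identical(self):
        cfg = SimConfig(seed=8)
        a, _ = gen_survival_cohort(cfg, n=100)
        b, _ = gen_survival_cohort(cfg, n=100)
        pd.testing.assert_frame_equal(a, b)


class TestRoundTrips:
    def test_cohort_tsv_round_trip(self, tmp_path, desk_data):
        c = desk_data.cohorts[0]
        from tfscreen.simulate import write_cohort_tsv

        write_cohort_tsv(c, tmp_path / "v.tsv", tmp_path / "g.tsv")
        back = read_cohort_tsv(c.cohort_id, tmp_path / "v.tsv", tmp_path / "g.tsv")
        pd.testing.assert_frame_equal(
            back.values, c.values.rename_axis("gene")
        )
        pd.testing.assert_series_equal(back.group, c.group, check_names=False)

    def test_truth_json_round_trip(self, tmp_path, desk_data):
        desk_data.truth.to_json(tmp_path / "t.json")
        from tfscreen.simulate import PlantedTruth

        back = PlantedTruth.from_json(tmp_path / "t.json")
        assert back.de_tfs == desk_data.truth.de_tfs
        assert back.planted_motifs == desk_data.truth.planted_motifs
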