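"""Synthetic plasma-array generator: determinism, structure, and recovery."""

import numpy as np
import pandas as pd
import pytest

from mirscreen.io import COHORTS
from mirscreen.simulate import (
    ConfigError,
    SimConfig,
    blood_list_from_truth,
    manifest_from_truth,
    simulate_dataset,
    simulate_study_pair,
)
from mirscreen.preprocess import detect_mask, quantile_normalize, subtract_background
from mirscreen.filters import blood_cell_filter, low_abundance_filter
from mirscreen.screening import de_screen
from mirscreen.reproducibility import global_fc_correlation, study_de_from_contrasts

SMALL = SimConfig(
    n_probes=200, n_blood_cell=20, n_bc_specific=5, n_pan_cancer=5, n_non_regressing=5
)


def run_preprocess_and_filters(matrix, truth, config):
    bg = subtract_background(matrix, config.background_level)
    mask = detect_mask(bg)
    norm = quantile_normalize(bg)
    f1, r1 = blood_cell_filter(norm, manifest_from_truth(truth), blood_list_from_truth(truth))
    f2, r2 = low_abundance_filter(f1, mask)
    return f2, r1, r2


class TestSimulateDataset:
    def test_deterministic_given_config_and_seed(self):
        a = simulate_dataset(SMALL, seed=11)
        b = simulate_dataset(SMALL, seed=11)
        assert a[0].data.equals(b[0].data)
        assert a[1].frame.equals(b[1].frame)
        assert a[2].equals(b[2])
        c = simulate_dataset(SMALL, seed=12)
        assert not a[0].data.equals(c[0].data)

    def test_shapes_and_cohort_layout(self):
        matrix, sheet, truth = simulate_dataset(SMALL, seed=0)
        assert matrix.data.shape == (200, 70)
        assert sheet.cohort_sizes() == {
            "control": 20, "bc_pre": 20, "bc_post": 20, "other_cancer": 10
        }
        assert len(truth) == 200
        assert matrix.stage == "raw"
        assert (matrix.data.to_numpy() >= 0).all()

    def test_class_counts_and_disjointness(self):
        _, _, truth = simulate_dataset(SMALL, seed=1)
        counts = truth["class"].value_counts()
        assert counts["blood_cell"] == 20
        assert counts["bc_specific_regressing"] == 5
        assert counts["pan_cancer"] == 5
        assert counts["non_regressing"] == 5
        assert counts.sum() == 200  # one label per probe

    def test_null_probes_have_zero_effects(self):
        _, _, truth = simulate_dataset(SMALL, seed=2)
        nulls = truth[truth["class"].isin(["null", "low_abundance", "blood_cell"])]
        assert (nulls[["eff_bc_pre", "eff_bc_post", "eff_other"]] == 0).all().all()

    def test_effect_class_regression_structure(self):
        _, _, truth = simulate_dataset(SMALL, seed=3)
        bc = truth[truth["class"] == "bc_specific_regressing"]
        assert (bc["eff_bc_pre"] != 0).all()
        assert (bc["eff_bc_post"] == 0).all() and (bc["eff_other"] == 0).all()
        nr = truth[truth["class"] == "non_regressing"]
        assert (nr["eff_bc_post"] == nr["eff_bc_pre"]).all()
        pc = truth[truth["class"] == "pan_cancer"]
        assert (pc["eff_other"] == pc["eff_bc_pre"]).all()
        assert (pc["eff_bc_post"] == 0).all()

    def test_noise_free_no_effect_config_is_constant_across_samples(self):
        config = SimConfig(
            n_probes=50, n_blood_cell=5, n_bc_specific=0, n_pan_cancer=0,
            n_non_regressing=0, signal_log2_sd=0.0, noise_sd=0.0,
            blood_log2_sd=0.0, hemolysis_prob=0.0, low_abundance_fraction=0.2,
        )
        matrix, _, _ = simulate_dataset(config, seed=4)
        assert (matrix.data.nunique(axis=1) == 1).all()

    def test_zero_cohorts_rejected(self):
        with pytest.raises(ConfigError, match="cohort"):
            SimConfig(n_control=0, n_bc_pre=0, n_bc_post=0, n_other=0)

    def test_special_classes_cannot_exceed_probes(self):
        with pytest.raises(ConfigError):
            SimConfig(n_probes=100, n_blood_cell=90, n_bc_specific=20)

    def test_hemolysis_elevates_only_blood_probes(self):
        base = SimConfig(
            n_probes=100, n_blood_cell=10, n_bc_specific=0, n_pan_cancer=0,
            n_non_regressing=0, signal_log2_sd=0.0, noise_sd=0.0,
            blood_log2_sd=0.0, low_abundance_fraction=0.0, background_level=0.0,
        )
        quiet = simulate_dataset(
            SimConfig(**{**base.__dict__, "hemolysis_prob": 0.0}), seed=5
        )
        stormy = simulate_dataset(
            SimConfig(**{**base.__dict__, "hemolysis_prob": 1.0}), seed=5
        )
        truth = quiet[2]
        blood = truth["class"] == "blood_cell"
        ratio = stormy[0].data.to_numpy() / quiet[0].data.to_numpy()
        assert (ratio[blood.to_numpy()] >= 1.0 - 1e-9).all()
        assert np.allclose(ratio[~blood.to_numpy()], 1.0)
        assert ratio[blood.to_numpy()].max() <= base.hemolysis_max_fold + 1e-9


class TestFullCascadeOnSimulation:
    def test_blood_probes_never_survive_filter_one(self):
        matrix, sheet, truth = simulate_dataset(SMALL, seed=6)
        filtered, r1, _ = run_preprocess_and_filters(matrix, truth, SMALL)
        blood_probes = set(truth.loc[truth["class"] == "blood_cell", "probe_id"])
        assert blood_probes.isdisjoint(filtered.probe_ids)
        assert set(r1.probes_removed) == blood_probes

    def test_strong_planted_markers_dominate_final_set_at_low_noise(self):
        from mirscreen.screening import apply_cascade

        config = SimConfig(
            n_probes=300, n_blood_cell=30, n_bc_specific=8, n_pan_cancer=8,
            n_non_regressing=8, effect_log2_mean=2.5, effect_log2_sd=0.25,
            signal_log2_sd=0.2,
        )
        recovered, planted_total, impostors = 0, 0, 0
        for seed in range(3):
            matrix, sheet, truth = simulate_dataset(config, seed=seed)
            filtered, _, _ = run_preprocess_and_filters(matrix, truth, config)
            report = apply_cascade(de_screen(filtered, sheet))
            by_probe = truth.set_index("probe_id")["class"]
            final_classes = by_probe.loc[report.final_candidates]
            planted = truth[
                (truth["class"] == "bc_specific_regressing")
                & (truth["eff_bc_pre"].abs() >= 2)
            ]
            planted_total += len(planted)
            recovered += len(set(planted["probe_id"]) & set(report.final_candidates))
            impostors += int((final_classes != "bc_specific_regressing").sum())
        assert planted_total > 0
        assert recovered / planted_total >= 0.6
        assert impostors <= recovered  # the target class dominates the final set


class TestSimulateStudyPair:
    def test_rho_validation(self):
        with pytest.raises(ConfigError, match="correlation"):
            simulate_study_pair(SMALL, rho=1.5, seed=0)

    def test_shared_probes_independent_nuisance(self):
        (mA, sA, tA), (mB, sB, tB) = simulate_study_pair(SMALL, rho=0.5, seed=7)
        assert mA.probe_ids == mB.probe_ids
        assert (tA["class"] == tB["class"]).all()
        assert not mA.data.equals(mB.data)

    def test_rho_one_large_effects_recovers_near_unit_correlation(self):
        config = SimConfig(
            n_probes=200, n_blood_cell=20, pair_effect_log2_sd=2.0,
            signal_log2_sd=0.1, noise_sd=1.0,
        )
        (mA, sA, tA), (mB, sB, tB) = simulate_study_pair(config, rho=1.0, seed=8)
        fA, _, _ = run_preprocess_and_filters(mA, tA, config)
        fB, _, _ = run_preprocess_and_filters(mB, tB, config)
        a = study_de_from_contrasts(de_screen(fA, sA), "A")
        b = study_de_from_contrasts(de_screen(fB, sB), "B")
        report = global_fc_correlation(a, b)
        assert report.pearson_r > 0.95

    def test_rho_zero_centred_on_zero_over_seeds(self):
        rs = []
        for seed in range(6):
            (mA, sA, tA), (mB, sB, tB) = simulate_study_pair(SMALL, rho=0.0, seed=seed)
            fA, _, _ = run_preprocess_and_filters(mA, tA, SMALL)
            fB, _, _ = run_preprocess_and_filters(mB, tB, SMALL)
            a = study_de_from_contrasts(de_screen(fA, sA), "A")
            b = study_de_from_contrasts(de_screen(fB, sB), "B")
            rs.append(global_fc_correlation(a, b).pearson_r)
        assert abs(np.mean(rs)) < 0.1

    def test_recovered_correlation_monotone_in_rho(self):
        means = []
        for rho in (0.0, 0.5, 1.0):
            rs = []
            for seed in range(4):
                (mA, sA, tA), (mB, sB, tB) = simulate_study_pair(
                    SMALL, rho=rho, seed=100 + seed
                )
                fA, _, _ = run_preprocess_and_filters(mA, tA, SMALL)
                fB, _, _ = run_preprocess_and_filters(mB, tB, SMALL)
                a = study_de_from_contrasts(de_screen(fA, sA), "A")
                b = study_de_from_contrasts(de_screen(fB, sB), "B")
                rs.append(global_fc_correlation(a, b).pearson_r)
            means.append(np.mean(rs))
        assert means[0] < means[1] < means[2]
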