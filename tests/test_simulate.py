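"""Synthetic-study generator: determinism, planted effects, clinical links."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test
from scipy import stats

from exonet.errors import ConfigurationError, InputError
from exonet.screen import normalize_mirna_id
from exonet.simulate import (ClinicalConfig, SimulationConfig,
                             simulate_clinical, simulate_exosomal_intensities,
                             simulate_study, simulate_target_table,
                             simulate_tissue_counts)


class TestTissueCounts:
    def test_null_simulation_has_no_planted_effects(self):
        cfg = SimulationConfig(n_planted_de=0, n_planted_key=0, seed=3)
        _, truth, _ = simulate_tissue_counts(cfg)
        assert all(v == 0.0 for v in truth.true_log2fc["mrna"].values())
        assert truth.planted_de["mrna"] == set()

    def test_planted_fold_change_on_raw_mean_scale(self):
        # log2FC = 2 should give an empirical tumor/normal mean ratio near 4.
        cfg = SimulationConfig(n_features_mrna=300, n_tumor=100, n_control=100,
                               n_planted_de=40, n_planted_key=0,
                               planted_log2fc=2.0, baseline_mean=50.0, seed=11)
        matrix, truth, meta = simulate_tissue_counts(cfg)
        tumors = meta.index[meta["group"] == "tumor"]
        normals = meta.index[meta["group"] == "normal"]
        planted = sorted(truth.planted_de["mrna"])
        ratios = (matrix.data.loc[planted, tumors].mean(axis=1)
                  / matrix.data.loc[planted, normals].mean(axis=1))
        assert 3.6 < ratios.mean() < 4.4

    def test_same_seed_is_bit_identical(self):
        cfg = SimulationConfig(seed=5)
        a, _, _ = simulate_tissue_counts(cfg)
        b, _, _ = simulate_tissue_counts(cfg)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_counts_are_integers_with_expected_shape(self):
        cfg = SimulationConfig(n_tumor=12, n_control=4, n_features_mrna=50,
                               n_planted_de=5, n_planted_key=2, seed=1)
        matrix, _, _ = simulate_tissue_counts(cfg)
        assert matrix.shape == (50, 16)
        assert np.issubdtype(matrix.data.to_numpy().dtype, np.integer)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_tissue_counts(SimulationConfig(n_tumor=0))
        with pytest.raises(ConfigurationError):
            simulate_tissue_counts(SimulationConfig(nb_dispersion=-1.0))
        with pytest.raises(ConfigurationError):
            simulate_tissue_counts(
                SimulationConfig(n_planted_de=10, n_planted_key=11))


class TestExosomalIntensities:
    def test_default_cohort_is_88_tumor_11_control(self):
        _, _, meta = simulate_exosomal_intensities(SimulationConfig(seed=2))
        counts = meta["group"].value_counts()
        assert counts["tumor"] == 88 and counts["normal"] == 11

    def test_planted_shift_on_log2_scale(self):
        cfg = SimulationConfig(n_features_mirna=200, n_tumor=150, n_control=150,
                               n_planted_de=30, n_planted_key=0,
                               planted_log2fc=1.0, exo_noise_sd=1.0, seed=4)
        matrix, truth, meta = simulate_exosomal_intensities(cfg)
        log2 = np.log2(matrix.data)
        tumors = (meta["group"] == "tumor").to_numpy()
        normed = {normalize_mirna_id(i): i for i in matrix.features}
        diffs = [log2.loc[normed[f]][tumors].mean() - log2.loc[normed[f]][~tumors].mean()
                 for f in truth.planted_de["mirna"]]
        assert abs(np.mean(diffs) - 1.0) < 0.1

    def test_zero_shift_gives_equal_group_means(self):
        cfg = SimulationConfig(n_features_mirna=300, n_tumor=200, n_control=200,
                               n_planted_de=0, n_planted_key=0, seed=6)
        matrix, _, meta = simulate_exosomal_intensities(cfg)
        log2 = np.log2(matrix.data)
        tumors = (meta["group"] == "tumor").to_numpy()
        diff = (log2.loc[:, tumors].mean(axis=1) - log2.loc[:, ~tumors].mean(axis=1))
        assert abs(diff.mean()) < 0.05

    def test_ids_map_into_tissue_namespace(self):
        cfg = SimulationConfig(seed=7)
        exo, truth, _ = simulate_exosomal_intensities(cfg)
        namespace = set(truth.features["mirna"])
        assert {normalize_mirna_id(i) for i in exo.features} <= namespace
        # the lowercase-ID hazard is actually exercised
        assert any(i.startswith("hsa-mir-") for i in exo.features)


class TestTargetTable:
    def _truth(self, seed=0):
        study = simulate_study(seed=seed)
        return study.truth

    def test_zero_decoy_rate_gives_exactly_planted_edges(self):
        truth = self._truth()
        table = simulate_target_table(truth, n_sources=1, decoy_rate=0.0, seed=1)
        assert set(zip(table["mirna"], table["mrna"])) == truth.planted_edges
        assert (table["confidence"] == "high").all()

    def test_union_over_sources_contains_all_planted_edges(self):
        truth = self._truth()
        table = simulate_target_table(truth, n_sources=3, decoy_rate=0.01, seed=2)
        assert truth.planted_edges <= set(zip(table["mirna"], table["mrna"]))

    def test_fixed_seed_reproduces_table(self):
        truth = self._truth()
        a = simulate_target_table(truth, seed=9)
        b = simulate_target_table(truth, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_decoy_rate_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_target_table(self._truth(), decoy_rate=1.5, seed=0)


class TestClinical:
    def _matrix_meta(self, seed=0, n_tumor=120, n_control=20):
        cfg = SimulationConfig(n_features_mrna=20, n_tumor=n_tumor,
                               n_control=n_control, n_planted_de=2,
                               n_planted_key=1, seed=seed)
        return simulate_tissue_counts(cfg)

    def test_clinical_fields_only_for_tumors(self):
        matrix, _, meta = self._matrix_meta()
        out = simulate_clinical(matrix, meta, ClinicalConfig(seed=1))
        normals = out["group"] == "normal"
        for col in ("survival_time", "event", "stage", "msi"):
            assert out.loc[normals, col].isna().all()
            assert out.loc[~normals, col].notna().all()

    def test_unknown_sample_ids_rejected(self):
        matrix, _, meta = self._matrix_meta()
        bad = meta.rename(index={meta.index[0]: "MYSTERY"})
        with pytest.raises(InputError):
            simulate_clinical(matrix, bad, ClinicalConfig(seed=1))

    def test_null_hazard_link_is_calibrated(self):
        # With no expression-hazard link, median-split log-rank should
        # reject at roughly the nominal rate.
        matrix, _, meta = self._matrix_meta()
        feat = matrix.features[0]
        rejections = 0
        n_rep = 100
        for rep in range(n_rep):
            out = simulate_clinical(matrix, meta, ClinicalConfig(
                hazard_feature=feat, hazard_log_hr=0.0, seed=1000 + rep))
            tum = out[out["group"] == "tumor"]
            expr = matrix.data.loc[feat, tum.index]
            low = (expr <= expr.median()).to_numpy()
            res = logrank_test(tum["survival_time"][low], tum["survival_time"][~low],
                               event_observed_A=tum["event"][low],
                               event_observed_B=tum["event"][~low])
            rejections += res.p_value < 0.05
        assert rejections / n_rep < 0.12

    def test_null_msi_link_is_calibrated(self):
        matrix, _, meta = self._matrix_meta()
        feat = matrix.features[0]
        rejections = 0
        n_rep = 100
        for rep in range(n_rep):
            out = simulate_clinical(matrix, meta, ClinicalConfig(
                msi_feature=feat, msi_log_odds=0.0, msi_base_rate=0.4,
                seed=2000 + rep))
            tum = out[out["group"] == "tumor"]
            expr = matrix.data.loc[feat, tum.index].to_numpy(float)
            msi = tum["msi"].to_numpy()
            if len(set(msi)) < 2:
                continue
            p = stats.mannwhitneyu(expr[msi == "MSS"], expr[msi == "MSI-H"],
                                   alternative="two-sided").pvalue
            rejections += p < 0.05
        assert rejections / n_rep < 0.12


class TestStudy:
    def test_planted_keys_are_planted_de_and_edges_reference_keys(self):
        study = simulate_study(seed=3)
        truth = study.truth
        for mod in ("mrna", "mirna"):
            assert truth.planted_key[mod] <= truth.planted_de[mod]
        for mi, mr in truth.planted_edges:
            assert mi in truth.planted_key["mirna"]
            assert mr in truth.planted_key["mrna"]

    def test_study_is_deterministic(self):
        a = simulate_study(seed=8)
        b = simulate_study(seed=8)
        pd.testing.assert_frame_equal(a.exosomal_mirna.data, b.exosomal_mirna.data)
        pd.testing.assert_frame_equal(a.tissue_metadata, b.tissue_metadata)
        assert a.truth.planted_edges == b.truth.planted_edges
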