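"""The synthetic cohort generator: planted covariance, determinism, scores."""

import json

import numpy as np
import pytest
from scipy import stats

from scovnet.synthetic import (
    SyntheticConfig,
    generate_cohort,
    module_assignment,
    population_covariance,
    slot_assignment,
    write_cohort,
)
from scovnet.io import read_thickness_table


class TestConfigValidation:
    def test_between_above_within_rejected(self):
        with pytest.raises(ValueError, match="between_module_corr"):
            SyntheticConfig(within_module_corr=0.2, between_module_corr=0.3).validate()

    def test_non_pd_scaled_matrix_names_parameters(self):
        cfg = SyntheticConfig(
            n_regions=8, n_modules=2, within_module_corr=0.95,
            between_module_corr=0.95, group_effect=1.0,
        )
        with pytest.raises(ValueError, match="positive definite"):
            cfg.validate()

    def test_modules_sized_evenly(self):
        cfg = SyntheticConfig(n_regions=10, n_modules=3)
        sizes = np.bincount(module_assignment(cfg))
        assert sorted(sizes) == [3, 3, 4]


class TestPopulationCovariance:
    def test_single_module_equicorrelated(self):
        cfg = SyntheticConfig(n_regions=5, n_modules=1, within_module_corr=0.5,
                              between_module_corr=0.0)
        R = population_covariance(cfg)
        off = R[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 0.5) and np.allclose(np.diag(R), 1.0)

    def test_zero_between_is_block_diagonal(self):
        cfg = SyntheticConfig(n_regions=8, n_modules=2, within_module_corr=0.4,
                              between_module_corr=0.0)
        R = population_covariance(cfg)
        assert np.allclose(R[:4, 4:], 0.0)

    def test_two_modules_slot_matched_bridges(self):
        cfg = SyntheticConfig(n_regions=4, n_modules=2, within_module_corr=0.6,
                              between_module_corr=0.2)
        R = population_covariance(cfg)
        expected = np.array(
            [
                [1.0, 0.6, 0.2, 0.0],
                [0.6, 1.0, 0.0, 0.2],
                [0.2, 0.0, 1.0, 0.6],
                [0.0, 0.2, 0.6, 1.0],
            ]
        )
        assert np.allclose(R, expected)

    def test_low_group_scales_bridges_only(self):
        cfg = SyntheticConfig(n_regions=6, n_modules=2, within_module_corr=0.5,
                              between_module_corr=0.3, group_effect=0.5)
        R_hi = population_covariance(cfg, "high")
        R_lo = population_covariance(cfg, "low")
        mods = module_assignment(cfg)
        same = mods[:, None] == mods[None, :]
        assert np.allclose(R_lo[same], R_hi[same])
        cross = ~same
        assert np.allclose(R_lo[cross], 0.5 * R_hi[cross])


class TestGenerateCohort:
    def test_reference_dimensions_and_split(self):
        cohort = generate_cohort(SyntheticConfig(n_subjects=114, n_regions=148,
                                                 n_modules=4, seed=7))
        assert cohort.thickness_t1.values.shape == (114, 148)
        labels = list(cohort.truth["group_labels"].values())
        assert labels.count("low") == labels.count("high") == 57

    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(n_subjects=10, n_regions=8, n_modules=2, seed=5)
        c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
        assert (c1.thickness_t1.values == c2.thickness_t1.values).all()
        assert (c1.thickness_t2.values == c2.thickness_t2.values).all()
        assert (c1.component_scores.scores == c2.component_scores.scores).all()
        assert c1.covariates.equals(c2.covariates)

    def test_shared_orderings_across_timepoints(self, small_cohort):
        assert small_cohort.thickness_t1.subject_ids == small_cohort.thickness_t2.subject_ids
        assert small_cohort.thickness_t1.region_labels == small_cohort.thickness_t2.region_labels

    def test_sample_correlation_converges_to_planted(self):
        cfg = SyntheticConfig(n_subjects=5000, n_regions=12, n_modules=3, seed=1)
        cohort = generate_cohort(cfg)
        z = cohort.thickness_t1.values
        S = np.corrcoef(z, rowvar=False)
        R = population_covariance(cfg)
        assert np.abs(S - R).max() < 0.05

    def test_timepoint_correlation_converges(self):
        cfg = SyntheticConfig(n_subjects=5000, n_regions=6, n_modules=2,
                              timepoint_corr=0.7, seed=2)
        cohort = generate_cohort(cfg)
        for j in range(6):
            r = np.corrcoef(cohort.thickness_t1.values[:, j],
                            cohort.thickness_t2.values[:, j])[0, 1]
            assert abs(r - 0.7) < 0.05

    def test_score_skewness_near_target(self):
        cfg = SyntheticConfig(n_subjects=5000, n_regions=4, n_modules=1,
                              within_module_corr=0.3, seed=3)
        cohort = generate_cohort(cfg)
        for j, target in enumerate(cfg.score_skews):
            got = stats.skew(cohort.component_scores.scores[:, j])
            assert abs(got - target) < 0.5

    def test_null_groups_exchangeable(self):
        # group_effect = 1: label-defined halves (5000 subjects each) have
        # equal correlations up to sampling noise
        cfg = SyntheticConfig(n_subjects=10000, n_regions=6, n_modules=2,
                              group_effect=1.0, seed=4)
        cohort = generate_cohort(cfg)
        labels = cohort.truth["group_labels"]
        mask = np.array([labels[s] == "low" for s in cohort.thickness_t1.subject_ids])
        S_lo = np.corrcoef(cohort.thickness_t1.values[mask], rowvar=False)
        S_hi = np.corrcoef(cohort.thickness_t1.values[~mask], rowvar=False)
        assert np.abs(S_lo - S_hi).max() < 0.05

    def test_group_effect_expressed_in_low_group_bridges(self):
        cfg = SyntheticConfig(n_subjects=4000, n_regions=6, n_modules=2,
                              group_effect=0.4, seed=6)
        cohort = generate_cohort(cfg)
        labels = cohort.truth["group_labels"]
        mask = np.array([labels[s] == "low" for s in cohort.thickness_t1.subject_ids])
        mods = module_assignment(cfg)
        slots = slot_assignment(cfg)
        bridge = (mods[:, None] != mods[None, :]) & (slots[:, None] == slots[None, :])
        S_lo = np.corrcoef(cohort.thickness_t1.values[mask], rowvar=False)
        S_hi = np.corrcoef(cohort.thickness_t1.values[~mask], rowvar=False)
        b = cfg.between_module_corr
        assert abs(S_hi[bridge].mean() - b) < 0.05
        assert abs(S_lo[bridge].mean() - 0.4 * b) < 0.05

    def test_truth_recomputes_population_covariance(self, small_cohort):
        raw = dict(small_cohort.truth["config"])
        for key in ("score_skew", "effect_timepoints"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        cfg = SyntheticConfig(**raw)
        R = population_covariance(cfg)
        assert R.shape == (cfg.n_regions, cfg.n_regions)
        assert (module_assignment(cfg).tolist()
                == small_cohort.truth["module_assignment"])


class TestWriteCohort:
    def test_tables_roundtrip(self, small_cohort, tmp_path):
        paths = write_cohort(small_cohort, tmp_path)
        t1 = read_thickness_table(paths["thickness_t1"], timepoint="T1")
        assert (t1.values == small_cohort.thickness_t1.values).all()
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["group_labels"] == small_cohort.truth["group_labels"]
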