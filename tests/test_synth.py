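"""Generator contracts: determinism, configured distributions, planted and
recoverable structure."""

import numpy as np
import pandas as pd
import pytest

from mmconn.connectomes import RoiTimeseries, fc_from_timeseries
from mmconn.core import ValidationError
from mmconn.crossmodal import coupling
from mmconn.graphnet import ThresholdConfig, modularity_louvain, proportional_threshold
from mmconn.scn import build_scn, residualize_covariates
from mmconn.stats import spearman
from mmconn.synth import (
    GeneratorConfig,
    generate_morphometry,
    generate_structural_connectome,
    generate_subjects,
    generate_timeseries,
    module_partition,
    plant_clinical_link,
    _deficit_mask,
)


class TestGenerateSubjects:
    def test_same_seed_identical(self):
        cfg = GeneratorConfig()
        a = generate_subjects(cfg, np.random.default_rng(42)).rows
        b = generate_subjects(cfg, np.random.default_rng(42)).rows
        pd.testing.assert_frame_equal(a, b)

    def test_group_sizes_and_control_ceiling(self):
        c = generate_subjects(GeneratorConfig(), np.random.default_rng(0))
        assert len(c.patients) == 15
        assert len(c.controls) == 14
        assert (c.controls["alsfrs_r"] == 48).all()

    def test_large_sample_age_means(self):
        cfg = GeneratorConfig(n_patient=10_000, n_control=10_000)
        c = generate_subjects(cfg, np.random.default_rng(1))
        assert c.patients["age"].mean() == pytest.approx(64.7, abs=0.2)
        assert c.controls["age"].mean() == pytest.approx(63.7, abs=0.2)

    def test_nonpositive_group_size_rejected(self):
        with pytest.raises(ValidationError):
            GeneratorConfig(n_patient=0)


class TestStructuralConnectome:
    def test_nonnegative_symmetric_zero_diagonal(self, scheme, rng):
        m = generate_structural_connectome(scheme, GeneratorConfig(), "patient", rng)
        assert (m.values >= 0).all()
        assert np.all(np.diag(m.values) == 0)
        assert np.allclose(m.values, m.values.T)

    def test_zero_deficit_groups_match_in_expectation(self, scheme):
        cfg = GeneratorConfig(interhemispheric_deficit=0.0)
        mask = _deficit_mask(scheme)
        iu = np.triu_indices(104, 1)

        def mean_inter_motor(group, seed0):
            vals = []
            for s in range(40):
                m = generate_structural_connectome(
                    scheme, cfg, group, np.random.default_rng(seed0 + s))
                vals.append(m.values[iu][mask[iu]].mean())
            return np.mean(vals)

        a = mean_inter_motor("patient", 100)
        b = mean_inter_motor("control", 500)
        assert a == pytest.approx(b, rel=0.05)

    def test_planted_deficit_scales_motor_edges(self, scheme):
        delta = 0.5
        mask = _deficit_mask(scheme)
        iu = np.triu_indices(104, 1)
        ratios = []
        for s in range(40):
            mp = generate_structural_connectome(
                scheme, GeneratorConfig(interhemispheric_deficit=delta),
                "patient", np.random.default_rng(s))
            mc = generate_structural_connectome(
                scheme, GeneratorConfig(interhemispheric_deficit=delta),
                "control", np.random.default_rng(1000 + s))
            ratios.append(mp.values[iu][mask[iu]].mean() / mc.values[iu][mask[iu]].mean())
        assert np.mean(ratios) == pytest.approx(1 - delta, abs=0.05)

    def test_modular_structure_dominates_top_edges(self, scheme, rng):
        m = generate_structural_connectome(scheme, GeneratorConfig(), "control", rng)
        adj = proportional_threshold(m, ThresholdConfig(0.05, False))
        q, _ = modularity_louvain(adj, rng)
        assert q > 0.3


class TestTimeseries:
    def test_condition_lengths(self, scheme, rng):
        cfg = GeneratorConfig()
        m = generate_structural_connectome(scheme, cfg, "control", rng)
        assert generate_timeseries(m, cfg, "rest", rng).shape == (104, 300)
        assert generate_timeseries(m, cfg, "task", rng).shape == (104, 600)

    def test_zero_coupling_yields_null_correlation(self, scheme):
        cfg = GeneratorConfig(coupling_rho_sf=0.0)
        rs = []
        for s in range(10):
            rng = np.random.default_rng(700 + s)
            m = generate_structural_connectome(scheme, cfg, "control", rng)
            x = generate_timeseries(m, cfg, "rest", rng)
            rs.append(coupling(m, fc_from_timeseries(RoiTimeseries(x, scheme))).r)
        assert abs(np.mean(rs)) < 0.05

    def test_planted_coupling_recovered(self, scheme):
        cfg = GeneratorConfig(coupling_rho_sf=0.25)
        rs = []
        for s in range(10):
            rng = np.random.default_rng(800 + s)
            m = generate_structural_connectome(scheme, cfg, "control", rng)
            x = generate_timeseries(m, cfg, "rest", rng)
            rs.append(coupling(m, fc_from_timeseries(RoiTimeseries(x, scheme))).r)
        assert np.mean(rs) == pytest.approx(0.25, abs=0.07)

    def test_determinism(self, scheme):
        cfg = GeneratorConfig()
        m = generate_structural_connectome(scheme, cfg, "control", np.random.default_rng(3))
        x1 = generate_timeseries(m, cfg, "task", np.random.default_rng(4))
        x2 = generate_timeseries(m, cfg, "task", np.random.default_rng(4))
        assert np.array_equal(x1, x2)


class TestMorphometry:
    def _cohort(self, n=40, seed=0):
        return generate_subjects(
            GeneratorConfig(n_patient=n, n_control=n), np.random.default_rng(seed))

    def test_zero_betas_leave_values_centered(self, scheme):
        cfg = GeneratorConfig(beta_age=0.0, beta_sex=0.0, beta_tiv=0.0,
                              n_patient=20, n_control=20)
        cohort = generate_subjects(cfg, np.random.default_rng(0))
        morph = generate_morphometry(cohort, scheme, cfg, np.random.default_rng(1))
        adj = residualize_covariates(morph)
        centered = (morph.values - morph.values.mean(axis=0)).to_numpy()
        # with no planted effects only chance covariate alignment is removed,
        # a ~sqrt(k/n) fraction of the signal
        diff = adj.values.to_numpy() - centered
        assert np.sqrt((diff**2).mean()) / np.sqrt((centered**2).mean()) < 0.35
        assert np.abs(adj.values.to_numpy().mean(axis=0)).max() < 1e-10

    def test_module_factors_create_block_covariance(self, scheme):
        cfg = GeneratorConfig(n_patient=60, n_control=4,
                              module_factor_sd=0.2, morph_noise_sd=0.1)
        cohort = generate_subjects(cfg, np.random.default_rng(2))
        morph = generate_morphometry(cohort, scheme, cfg, np.random.default_rng(3))
        adj = residualize_covariates(morph)
        net = build_scn(adj, cohort.patients["subject_id"].tolist())
        part = module_partition(scheme)
        aff = scheme.affiliation
        same = aff[:, None] == aff[None, :]
        iu = np.triu_indices(104, 1)
        within = net.values[iu][same[iu]]
        between = net.values[iu][~same[iu]]
        assert within.mean() > between.mean()

    def test_determinism(self, scheme):
        cfg = GeneratorConfig()
        cohort = self._cohort(10, 5)
        a = generate_morphometry(cohort, scheme, cfg, np.random.default_rng(6))
        b = generate_morphometry(cohort, scheme, cfg, np.random.default_rng(6))
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)


class TestPlantClinicalLink:
    def _patients_with_metric(self, n, seed):
        cfg = GeneratorConfig(n_patient=n, n_control=4)
        cohort = generate_subjects(cfg, np.random.default_rng(seed))
        rng = np.random.default_rng(seed + 1)
        metric = pd.Series(rng.normal(size=len(cohort.rows)),
                           index=cohort.rows["subject_id"])
        return cohort, metric

    def test_zero_rho_near_independence(self):
        rhos = []
        for s in range(100):
            cohort, metric = self._patients_with_metric(15, 2000 + s)
            planted = plant_clinical_link(cohort, metric, 0.0,
                                          np.random.default_rng(s))
            pat = planted.patients.set_index("subject_id")
            r = spearman(metric.loc[pat.index], pat["grip_left"]).rho
            assert abs(r) < 0.9  # individual draws are noisy at n=15
            rhos.append(r)
        assert abs(np.mean(rhos)) < 0.05

    def test_planted_rho_recovered_at_large_n(self):
        rhos = []
        for s in range(5):
            cohort, metric = self._patients_with_metric(200, 3000 + s)
            planted = plant_clinical_link(cohort, metric, -0.70,
                                          np.random.default_rng(s))
            pat = planted.patients.set_index("subject_id")
            rhos.append(spearman(metric.loc[pat.index], pat["grip_left"]).rho)
        assert np.mean(rhos) == pytest.approx(-0.70, abs=0.05)

    def test_rank_invariance_under_monotone_metric_transform(self):
        cohort, metric = self._patients_with_metric(30, 4000)
        a = plant_clinical_link(cohort, metric, -0.5, np.random.default_rng(9))
        b = plant_clinical_link(cohort, np.exp(metric * 2), -0.5,
                                np.random.default_rng(9))
        pd.testing.assert_frame_equal(a.rows, b.rows)

    def test_invalid_rho_rejected(self):
        cohort, metric = self._patients_with_metric(10, 5000)
        with pytest.raises(ValidationError):
            plant_clinical_link(cohort, metric, 1.0, np.random.default_rng(0))
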