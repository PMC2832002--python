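"""Synthetic-cohort generators: determinism, noiseless round trips, and the
recovery harness."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from myofiber import (
    eigen_rate,
    fit_hill,
    fit_pi_dependence,
    fit_transient,
    phosphoform_percentages,
)
from myofiber.synth import (
    cohort_config,
    generate_densitometry,
    generate_force_pca_table,
    generate_kF_vs_Pi,
    generate_transients,
    recovery_experiment,
)


class TestDeterminism:
    def test_same_seed_identical_tables(self, perfused_cfg):
        a = generate_force_pca_table(perfused_cfg)
        b = generate_force_pca_table(perfused_cfg)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(
            generate_kF_vs_Pi(perfused_cfg), generate_kF_vs_Pi(perfused_cfg)
        )

    def test_same_seed_identical_traces_and_densitometry(self, perfused_cfg):
        cfg = replace(perfused_cfg, n_fibers=2)
        ta = generate_transients(cfg, duration=0.2)
        tb = generate_transients(cfg, duration=0.2)
        for x, y in zip(ta, tb):
            np.testing.assert_array_equal(x.force, y.force)
        da = generate_densitometry(cfg)
        db = generate_densitometry(cfg)
        assert [r.signals for r in da] == [r.signals for r in db]

    def test_different_seed_differs(self, perfused_cfg):
        other = replace(perfused_cfg, seed=perfused_cfg.seed + 1)
        assert not generate_force_pca_table(perfused_cfg)["force"].equals(
            generate_force_pca_table(other)["force"]
        )


class TestNoiselessRoundTrips:
    def test_hill_recovery_is_exact(self, perfused_cfg):
        cfg = replace(perfused_cfg, force_noise_frac=0.0, n_fibers=1)
        tbl = generate_force_pca_table(cfg)
        fit = fit_hill(tbl[["ca_uM", "force"]].to_numpy())
        assert fit.ec50 == pytest.approx(cfg.ec50, rel=1e-6)
        assert fit.fmax == pytest.approx(cfg.fmax, rel=1e-6)

    def test_pi_recovery_is_exact(self, perfused_cfg):
        cfg = replace(perfused_cfg, kf_noise_sd=0.0, n_fibers=1)
        tbl = generate_kF_vs_Pi(cfg)
        fit = fit_pi_dependence(tbl[["pi_mM", "kF_s"]].to_numpy())
        assert fit.k1 == pytest.approx(26.6, rel=1e-6)
        assert fit.k_minus1 == pytest.approx(42.3, rel=1e-6)
        assert fit.K2 == pytest.approx(39.4, rel=1e-6)

    def test_noiseless_ca_jump_rate_matches_eigen_oracle(self, perfused_cfg):
        cfg = replace(perfused_cfg, trace_noise_frac=0.0, n_fibers=1)
        trace = generate_transients(cfg, calibrate=False)[0]
        rate = fit_transient(trace).rate
        er = eigen_rate(cfg.params, 4.5, 0.0)
        assert abs(rate - er) / er < 0.05

    def test_densitometry_noiseless_percentages(self, perfused_cfg):
        cfg = replace(perfused_cfg, signal_noise=0.0, n_fibers=1)
        rec = generate_densitometry(cfg, kind="phosphoform")[0]
        pct = phosphoform_percentages(rec)
        assert pct["P1"] == pytest.approx(22.17, abs=0.01)
        assert pct["P2"] == pytest.approx(77.83, abs=0.01)


class TestGenerators:
    def test_pi_grid_must_include_zero(self, perfused_cfg):
        cfg = replace(perfused_cfg, pi_grid=(5.0, 10.0))
        with pytest.raises(ValueError):
            generate_kF_vs_Pi(cfg)

    def test_atp_jump_traces_dip_below_initial_force(self, perfused_cfg):
        cfg = replace(perfused_cfg, n_fibers=2, trace_noise_frac=0.0)
        for trace in generate_transients(cfg, protocol_kind="ATP_JUMP",
                                         duration=0.3):
            assert trace.force.min() < trace.force[0]

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            cohort_config("sham")

    def test_group_config_reaches_published_fmax(self):
        from myofiber import steady_state

        for group in ("perfused", "ischemic", "reperfused"):
            cfg = cohort_config(group)
            assert steady_state(cfg.params, 4.5, 0.0).force == pytest.approx(
                cfg.fmax, rel=1e-9
            )

    def test_fiber_heterogeneity_spreads_the_cohort(self, perfused_cfg):
        cfg = replace(perfused_cfg, fiber_cv=0.10, force_noise_frac=0.0,
                      n_fibers=6)
        tbl = generate_force_pca_table(cfg)
        top = tbl[tbl["pCa"] == 4.0].groupby("fiber_id")["force"].mean()
        assert top.std() > 0.5  # per-fiber fmax scatter


class TestRecoveryExperiment:
    def test_row_count_is_reps_times_groups(self):
        cfgs = [cohort_config(g, n_fibers=2) for g in ("perfused", "ischemic")]
        rep = recovery_experiment(cfgs, n_reps=3, seed=0)
        assert len(rep["replicates"]) == 6

    def test_noiseless_recovery_has_zero_bias(self):
        cfg = cohort_config(
            "perfused", n_fibers=2, force_noise_frac=0.0, kf_noise_sd=0.0
        )
        rep = recovery_experiment([cfg], n_reps=1, seed=0)
        assert np.allclose(rep["summary"]["bias"].to_numpy(), 0.0, atol=1e-4)
        assert (rep["replicates"]["error"] == "").all()

    def test_failures_are_recorded_not_raised(self):
        bad = cohort_config("perfused", n_fibers=1,
                            pca_grid=(6.0, 5.9, 5.8, 5.7))  # narrow Ca span
        rep = recovery_experiment([bad], n_reps=1, seed=0)
        assert rep["replicates"]["error"].iloc[0] != ""
        assert np.isnan(rep["replicates"]["ec50_hat"].iloc[0])
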