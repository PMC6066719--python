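"""Tissue simulator tests: splitting, decoupling, determinism, stimuli."""

import numpy as np
import pytest

from fracatrial.courtemanche import pace_cell
from fracatrial.fractional import FractionalOrder, spectral_symbol
from fracatrial.tissue import (PropagationError, RecordSpec, SheetConfig,
                               StimulusSpec, StrandConfig, initialize_tissue,
                               left_edge_mask, run_simulation)


@pytest.fixture(scope="module")
def small_strand():
    return StrandConfig(L=2.0, N=32, kappa=0.40)


class TestInitialization:
    def test_every_node_identical(self, small_strand, paced_caf):
        ts = initialize_tissue(small_strand, paced_caf.final_state)
        assert ts.S.shape == (21, 32)
        assert np.all(ts.S == paced_caf.final_state.values[:, None])

    def test_initial_voltage_depends_on_cell_state(self, small_strand,
                                                   paced_baseline, paced_caf):
        v0_base = initialize_tissue(small_strand, paced_baseline.final_state).V[0]
        v0_caf = initialize_tissue(small_strand, paced_caf.final_state).V[0]
        assert v0_caf < v0_base          # CAF rest is hyperpolarized

    def test_uniform_field_has_no_diffusive_drive(self, small_strand,
                                                  paced_caf):
        from fracatrial.fractional import apply_H

        ts = initialize_tissue(small_strand, paced_caf.final_state)
        out = apply_H(ts.V, small_strand.grid(), small_strand.order)
        assert np.abs(out).max() < 1e-9


class TestStepping:
    def test_zero_kappa_matches_independent_cells(self, caf_params, paced_caf):
        """kappa = 0 tissue must reproduce the single-cell trajectory exactly."""
        cfg = StrandConfig(L=2.0, N=16, kappa=0.0)
        all_nodes = np.ones(16, dtype=bool)
        stim = StimulusSpec(region=all_nodes, amplitude=40.0, onset_times=[0.0])
        rec = RecordSpec(movie_stride=1.0, probes=(7,))
        res = run_simulation(cfg, caf_params, [stim], 50.0, rec,
                             paced_cell_state=paced_caf.final_state)
        single = pace_cell(caf_params, bcl=1e9, duration=50.0,
                           stim_amplitude=40.0, sample_dt=0.01,
                           initial_state=paced_caf.final_state)
        # identical kernels and schedule; only floating-point reassociation
        # (loop vectorization width) distinguishes the two paths
        assert np.allclose(res.probe_V[0][1:], single.V, rtol=0, atol=1e-9)

    def test_quiescent_tissue_is_fixed_point(self, baseline_params):
        from fracatrial.courtemanche import resting_state

        cfg = StrandConfig(L=2.0, N=32, kappa=0.40)
        res = run_simulation(cfg, baseline_params, [], 50.0,
                             RecordSpec(movie_stride=10.0),
                             paced_cell_state=resting_state())
        assert np.abs(res.V[-1] - res.V[0]).max() < 0.05

    def test_bit_identical_reruns(self, caf_params, paced_caf):
        cfg = StrandConfig(L=2.0, N=32, kappa=0.40)
        stim = StimulusSpec(region=left_edge_mask(cfg), amplitude=40.0,
                            onset_times=[0.0])
        runs = [run_simulation(cfg, caf_params, [stim], 30.0,
                               RecordSpec(movie_stride=1.0),
                               paced_cell_state=paced_caf.final_state)
                for _ in range(2)]
        assert np.array_equal(runs[0].V, runs[1].V)
        assert np.array_equal(runs[0].final_state.S, runs[1].final_state.S)

    def test_split_scheme_matches_heat_kernel(self, caf_params, paced_caf):
        """With the reaction switched off and gamma = 2 + j0 the split
        scheme must follow the analytic diffusion mode decay to < 1%."""
        cfg = StrandConfig(L=2.0, N=64, kappa=1.0,
                           order=FractionalOrder(2.0, 0.0),
                           k_scale=1.0, lowpass_frac=None)
        init = initialize_tissue(cfg, paced_caf.final_state)
        x = cfg.node_positions()
        k0 = cfg.grid().wavenumbers()[3]
        amp = 5.0
        init.S[0] = -80.0 + amp * np.cos(k0 * x)
        res = run_simulation(cfg, caf_params, [], 50.0,
                             RecordSpec(movie_stride=50.0),
                             initial_state=init, reaction=False)
        lam = spectral_symbol(np.array([k0]), cfg.order)[0]
        expected = -80.0 + amp * np.exp(cfg.kappa * 1e-3 * lam * 50.0) * np.cos(k0 * x)
        assert np.abs(res.V[-1] - expected).max() < 0.01 * amp

    def test_instability_reports_node_and_time(self, caf_params, paced_caf):
        cfg = StrandConfig(L=2.0, N=32, kappa=0.40)
        stim = StimulusSpec(region=left_edge_mask(cfg), amplitude=1e5,
                            onset_times=[0.0])
        with pytest.raises(PropagationError, match="node"):
            run_simulation(cfg, caf_params, [stim], 10.0,
                           paced_cell_state=paced_caf.final_state)


class TestRecording:
    def test_stride_controls_frame_count(self, caf_params, paced_caf):
        cfg = StrandConfig(L=2.0, N=32, kappa=0.40)
        kw = dict(paced_cell_state=paced_caf.final_state)
        r1 = run_simulation(cfg, caf_params, [], 20.0,
                            RecordSpec(movie_stride=1.0), **kw)
        r2 = run_simulation(cfg, caf_params, [], 20.0,
                            RecordSpec(movie_stride=2.0), **kw)
        assert (len(r1.times) - 1) == 2 * (len(r2.times) - 1)

    def test_propagation_failure_flag(self, caf_params, paced_caf):
        """A subthreshold stimulus never activates distant tissue."""
        cfg = StrandConfig(L=2.0, N=64, kappa=0.40)
        stim = StimulusSpec(region=left_edge_mask(cfg), amplitude=1.0,
                            onset_times=[0.0])
        res = run_simulation(cfg, caf_params, [stim], 60.0,
                             RecordSpec(movie_stride=2.0),
                             paced_cell_state=paced_caf.final_state)
        assert res.propagation_failure

    def test_successful_propagation_clears_flag(self, caf_params, paced_caf,
                                                caf_amplitude):
        cfg = StrandConfig(L=2.0, N=64, kappa=0.40)
        stim = StimulusSpec(region=left_edge_mask(cfg), amplitude=2 * caf_amplitude,
                            onset_times=[0.0])
        res = run_simulation(cfg, caf_params, [stim], 60.0,
                             RecordSpec(movie_stride=2.0),
                             paced_cell_state=paced_caf.final_state)
        assert not res.propagation_failure


class TestValidation:
    def test_empty_stimulus_region_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(region=np.zeros(8, dtype=bool), amplitude=1.0,
                         onset_times=[0.0])

    def test_region_grid_mismatch(self, caf_params, paced_caf):
        cfg = StrandConfig(L=2.0, N=32, kappa=0.40)
        stim = StimulusSpec(region=np.ones(16, dtype=bool), amplitude=1.0,
                            onset_times=[0.0])
        with pytest.raises(ValueError):
            run_simulation(cfg, caf_params, [stim], 5.0,
                           paced_cell_state=paced_caf.final_state)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            StrandConfig(L=2.0, N=8)
        with pytest.raises(ValueError):
            StrandConfig(dt=0.2)
        with pytest.raises(ValueError):
            SheetConfig(N=8)


class TestKappaCalibration:
    def test_bisection_hits_target_cv(self, baseline_params, paced_baseline,
                                      baseline_amplitude):
        from fracatrial.tissue import calibrate_kappa, measure_strand_cv
        from dataclasses import replace

        cfg = StrandConfig(L=2.0, N=64, kappa=0.40)
        kap = calibrate_kappa(2.0, 63.0, cfg, baseline_params,
                              paced_baseline.final_state,
                              amplitude=2 * baseline_amplitude, tol=0.5)
        cv = measure_strand_cv(replace(cfg, kappa=kap,
                                       order=FractionalOrder(2.0, 0.0)),
                               baseline_params, paced_baseline.final_state,
                               amplitude=2 * baseline_amplitude)
        assert abs(cv - 63.0) <= 0.5

    def test_cv_monotone_in_kappa(self, baseline_params, paced_baseline,
                                  baseline_amplitude):
        from fracatrial.tissue import measure_strand_cv

        cfg_lo = StrandConfig(L=2.0, N=64, kappa=0.2)
        cfg_hi = StrandConfig(L=2.0, N=64, kappa=0.8)
        cv_lo = measure_strand_cv(cfg_lo, baseline_params,
                                  paced_baseline.final_state,
                                  amplitude=2 * baseline_amplitude)
        cv_hi = measure_strand_cv(cfg_hi, baseline_params,
                                  paced_baseline.final_state,
                                  amplitude=2 * baseline_amplitude)
        assert cv_hi > cv_lo
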