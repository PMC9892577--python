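"""Generator contracts: dwell laws, state structure, reproducibility."""

import numpy as np
import pytest

from exotrace.dwell import ks_test_exponential, ks_test_hypoexponential
from exotrace.idealize import run_length_encode
from exotrace.models import (
    BindingModel,
    DegradationModel,
    STATE_SPIKE,
    TraceConfig,
    R_GAS,
)
from exotrace.simulate import (
    draw_hypoexponential,
    mix_samples,
    simulate_binding_trace,
    simulate_degradation_read,
    simulate_session,
)


class TestBindingTrace:
    def test_vant_hoff_occupancy_closed_form(self):
        # K_T = exp[(-dH/T + dS)/R] evaluated at the defaults and 310 K
        b = BindingModel(dH=-87150.0, dS=-291.56)
        K = np.exp((87150.0 / 310.0 - 291.56) / R_GAS)
        assert b.equilibrium_constant(310.0) == pytest.approx(K)
        assert K == pytest.approx(0.286, abs=0.001)
        assert b.p_bound(310.0) == pytest.approx(0.778, abs=0.001)

    def test_zero_enthalpy_entropy_gives_half_occupancy(self):
        b = BindingModel(dH=0.0, dS=0.0)
        assert b.equilibrium_constant(300.0) == 1.0
        assert b.p_bound(300.0) == 0.5

    def test_noise_free_trace_has_exactly_two_levels(self, fast_config):
        b = BindingModel()
        cfg = TraceConfig(sampling_rate=7200.0, noise_sd=0.0, seed=1)
        trace, _ = simulate_binding_trace(b, cfg, 310.0, n_cycles=50)
        assert set(np.unique(trace.currents)) == {cfg.level_low, cfg.level_mid}

    def test_occupancy_matches_configuration(self, binding):
        cfg = TraceConfig(sampling_rate=7200.0, seed=2)
        trace, gt = simulate_binding_trace(binding, cfg, 310.0, n_cycles=2000,
                                           rng=np.random.default_rng(2))
        _, lengths, values = run_length_encode(gt.state_path)
        t_bound = lengths[values == 1].sum()
        p = t_bound / lengths.sum()
        # Monte-Carlo error on occupancy at 2000 cycles is ~1%
        assert p == pytest.approx(binding.p_bound(310.0), abs=0.03)

    def test_nonphysical_temperature_rejected(self, binding, fast_config):
        with pytest.raises(ValueError, match="temperature"):
            simulate_binding_trace(binding, fast_config, -1.0)


class TestDegradationRead:
    def test_processing_order_is_three_prime_to_five_prime(self, nk, dm):
        cfg = TraceConfig(sampling_rate=7200.0, seed=0)
        _, gt = simulate_degradation_read("CGA", nk, dm, cfg)
        assert gt.reads[0].step_bases == ["A", "G", "C"]

    def test_one_high_visit_per_base(self, nk, dm):
        cfg = TraceConfig(sampling_rate=7200.0, noise_sd=0.0, seed=0)
        _, gt = simulate_degradation_read("A" * 30, nk, dm, cfg)
        assert int((gt.event_states == 2).sum()) == 30

    def test_noise_free_homopolymer_has_three_levels(self, nk):
        dm = DegradationModel(vibration_amps=(0.0, 0.0))
        cfg = TraceConfig(sampling_rate=7200.0, noise_sd=0.0, seed=0)
        trace, _ = simulate_degradation_read("A" * 10, nk, dm, cfg)
        assert set(np.unique(trace.currents)) <= {1.0, 2.0, 3.0}

    def test_intermediate_level_carries_base_offset(self, nk, dm):
        cfg = TraceConfig(sampling_rate=7200.0, noise_sd=0.0, seed=0)
        trace, gt = simulate_degradation_read("G" * 5, nk, dm, cfg)
        mid_level = cfg.level_mid + nk["G"].current_offset
        assert mid_level in np.unique(trace.currents)

    def test_unknown_base_rejected(self, nk, dm, fast_config):
        with pytest.raises(ValueError, match="unknown base"):
            simulate_degradation_read("AXU", nk, dm, fast_config)

    def test_missing_table_entry_rejected(self, nk, dm, fast_config):
        partial = {b: nk[b] for b in "AU"}
        with pytest.raises(ValueError, match="missing"):
            simulate_degradation_read("ACG", partial, dm, fast_config)

    def test_hypoexponential_step_mean(self):
        # mean of the two-step dwell is tau1 + tau2 (poly(A) constants, ms)
        rng = np.random.default_rng(7)
        d = draw_hypoexponential(10_000, 8.86, 46.33, rng)
        se = d.std() / np.sqrt(d.size)
        assert abs(d.mean() - 55.19) < 3 * se

    def test_hypoexponential_moments_large_n(self):
        t1, t2 = 8.86, 46.33
        rng = np.random.default_rng(11)
        d = draw_hypoexponential(100_000, t1, t2, rng)
        se_mean = d.std() / np.sqrt(d.size)
        assert abs(d.mean() - (t1 + t2)) < 3 * se_mean
        c = d - d.mean()
        se_var = np.sqrt((np.mean(c ** 4) - np.var(d) ** 2) / d.size)
        assert abs(d.var() - (t1 ** 2 + t2 ** 2)) < 3 * se_var


class TestSession:
    def test_requested_reads_present(self, nk, dm, binding):
        cfg = TraceConfig(sampling_rate=7200.0, seed=3)
        _, gt = simulate_session(20, "A" * 30, nk, dm, binding, cfg)
        assert len(gt.reads) == 20
        assert all(r.n_steps == 30 for r in gt.reads)

    def test_zero_spike_rates_leave_no_spike_labels(self, nk, binding):
        dm = DegradationModel(spike_mode_rates=(0, 0, 0, 0))
        cfg = TraceConfig(sampling_rate=7200.0, seed=4)
        _, gt = simulate_session(3, "A" * 10, nk, dm, binding, cfg)
        assert STATE_SPIKE not in gt.state_path

    def test_spikes_are_labeled_distinctly(self, nk, dm, binding):
        cfg = TraceConfig(sampling_rate=7200.0, seed=5)
        _, gt = simulate_session(10, "A" * 30, nk, dm, binding, cfg,
                                 rng=np.random.default_rng(5))
        assert STATE_SPIKE in gt.state_path

    def test_short_duration_raises(self, nk, dm, binding):
        cfg = TraceConfig(sampling_rate=7200.0, seed=6, duration=0.5)
        with pytest.raises(ValueError, match="too short"):
            simulate_session(20, "A" * 30, nk, dm, binding, cfg)

    def test_total_length_near_analytic_expectation(self, nk, dm, binding):
        cfg = TraceConfig(sampling_rate=7200.0, seed=7)
        reads = 20
        trace, _ = simulate_session(reads, "A" * 30, nk, dm, binding, cfg)
        per_step = dm.tau1(310.15) + nk["A"].tau2_mean + dm.high_dwell_mean
        expected = reads * (30 * per_step + binding.free_dwell_ref)
        assert abs(trace.duration - expected) / expected < 0.2

    def test_seed_reproducibility_bit_for_bit(self, nk, dm, binding):
        cfg = TraceConfig(sampling_rate=7200.0, seed=8)
        t1, g1 = simulate_session(3, "CGAU", nk, dm, binding, cfg)
        t2, g2 = simulate_session(3, "CGAU", nk, dm, binding, cfg)
        assert np.array_equal(t1.currents, t2.currents)
        assert np.array_equal(g1.state_path, g2.state_path)


class TestMixSamples:
    def test_lengths_only_from_components(self, nk, dm, binding):
        cfg = TraceConfig(sampling_rate=7200.0, seed=9)
        _, gt = mix_samples("A" * 30, "U" * 24, (0.5, 0.5), 50, nk, dm,
                            binding, cfg)
        assert set(r.n_steps for r in gt.reads) <= {30, 24}

    def test_degenerate_proportion(self, nk, dm, binding):
        cfg = TraceConfig(sampling_rate=7200.0, seed=10)
        _, gt = mix_samples("A" * 30, "U" * 24, (1.0, 0.0), 20, nk, dm,
                            binding, cfg)
        assert all(r.n_steps == 30 for r in gt.reads)

    def test_mode_frequencies_within_binomial_ci(self, nk, dm, binding):
        cfg = TraceConfig(sampling_rate=7200.0, seed=11)
        _, gt = mix_samples("A" * 30, "U" * 24, (0.5, 0.5), 400, nk, dm,
                            binding, cfg, rng=np.random.default_rng(11))
        n30 = sum(r.n_steps == 30 for r in gt.reads)
        # binomial 99% CI half-width at p=0.5, n=400: 2.58*sqrt(0.25*400)
        assert abs(n30 - 200) < 2.58 * np.sqrt(100)

    def test_bad_proportions_rejected(self, nk, dm, binding, fast_config):
        with pytest.raises(ValueError, match="sum to 1"):
            mix_samples("A" * 5, "U" * 4, (0.7, 0.6), 5, nk, dm, binding,
                        fast_config)


class TestDwellLaws:
    """KS tests of simulated dwells against their generating laws."""

    def test_degradation_state_dwell_laws(self, nk, dm, binding):
        cfg = TraceConfig(sampling_rate=57600.0, seed=12)
        _, gt = simulate_session(170, "A" * 30, nk, dm, binding, cfg,
                                 spikes=False,
                                 rng=np.random.default_rng(12))
        starts, lengths, values = run_length_encode(gt.state_path)
        fs = cfg.sampling_rate
        mid = lengths[values == 1] / fs
        high = lengths[values == 2] / fs
        t1, hm = dm.tau1(310.15), dm.high_dwell_mean
        # mid: shift + Exp(tau1-shift) + Exp(tau2)
        p_mid = ks_test_hypoexponential(mid[:5000] - dm.tau1_min,
                                        t1 - dm.tau1_min, nk["A"].tau2_mean)
        assert p_mid > 0.01
        # high: shifted exponential
        p_high = ks_test_exponential(high[:5000] - dm.high_dwell_min,
                                     hm - dm.high_dwell_min)
        assert p_high > 0.01

    def test_binding_dwell_laws(self, binding):
        cfg = TraceConfig(sampling_rate=57600.0, seed=13)
        _, gt = simulate_binding_trace(binding, cfg, 310.0, n_cycles=5000,
                                       rng=np.random.default_rng(13))
        _, lengths, values = run_length_encode(gt.state_path)
        fs = cfg.sampling_rate
        p_b = binding.p_bound(310.0)
        cycle = binding.free_dwell_ref + binding.bound_dwell_ref
        assert ks_test_exponential(lengths[values == 0] / fs,
                                   (1 - p_b) * cycle) > 0.01
        assert ks_test_exponential(lengths[values == 1] / fs,
                                   p_b * cycle) > 0.01
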