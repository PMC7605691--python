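"""Irrigation-controller and growth simulator: conservation, recovery, DUC."""

import numpy as np
import pytest

from seedwater import (
    SimConfig,
    compute_duc,
    efficiency_table,
    estimate_gpf,
    generate_experiment,
    gpf_table,
    simulate_controller,
    simulate_growth,
)
from seedwater.core import DomainError


class TestController:
    def test_quantized_demand_gives_exact_actuation_count(self):
        # 60 days x 0.04 L/day = 2.40 L = exactly 73 quanta
        cfg = SimConfig(n_days=60, demand_per_day=0.04, event_volume_v4=2.40 / 73)
        log = simulate_controller(cfg)
        assert log.n_actuations == 73
        assert log.volumes["V4"] == pytest.approx(2.40, abs=1e-9)

    def test_volumes_proportional_to_emitter_flows(self):
        """Shared valve-open time keeps volume ratios equal to flow ratios."""
        cfg = SimConfig(emitter_flows=(1.2, 1.8, 2.1, 2.9))
        log = simulate_controller(cfg)
        for lv, flow in zip(("V1", "V2", "V3", "V4"), cfg.emitter_flows):
            assert log.volumes[lv] / log.volumes["V4"] == pytest.approx(
                flow / 2.9, abs=1e-9)

    def test_water_conservation_against_event_accounting(self):
        """Cumulative volumes equal an independent event-by-event re-tally."""
        cfg = SimConfig(demand_growth=0.001)  # ramping demand, uneven days
        log = simulate_controller(cfg)
        tally = dict.fromkeys(log.volumes, 0.0)
        for _day, duration in log.events:
            for lv, flow in zip(("V1", "V2", "V3", "V4"), cfg.emitter_flows):
                tally[lv] += flow * duration
        for lv in log.volumes:
            assert log.volumes[lv] == pytest.approx(tally[lv], abs=1e-9)
        assert log.volumes["V4"] == pytest.approx(
            cfg.emitter_flows[3] * log.total_open_time, abs=1e-9)

    def test_ramping_demand_fires_more_events_later(self):
        cfg = SimConfig(demand_growth=0.002)
        log = simulate_controller(cfg)
        days = [d for d, _ in log.events]
        first_half = sum(1 for d in days if d < cfg.n_days // 2)
        assert len(days) - first_half > first_half


class TestGrowth:
    def test_no_deficit_sensitivity_means_identical_sizes(self):
        ds, _ = generate_experiment(SimConfig(noise_cv=0.0, gpf_true=0.0))
        heights = {round(o.height, 12) for o in ds.observations}
        assert len(heights) == 1
        assert heights.pop() == pytest.approx(SimConfig().vm_true, abs=1e-12)

    def test_noiseless_deficit_law_substitution(self):
        """Half the water with gpf 0.4 gives 80% of the asymptotic size."""
        cfg = SimConfig(noise_cv=0.0, gpf_true=0.4,
                        emitter_flows=(1.45, 1.8, 2.1, 2.9))  # V1/V4 = 0.5
        ds, log = generate_experiment(cfg)
        assert log.volumes["V1"] / log.volumes["V4"] == pytest.approx(0.5, abs=1e-12)
        v1 = [o.height for o in ds.observations if o.treatment == "V1"]
        assert v1[0] == pytest.approx(0.8 * cfg.vm_true, rel=1e-12)

    def test_estimator_inverts_noiseless_simulator(self):
        """estimate_gpf recovers the generating parameters to 1e-9."""
        for gpf_true in (0.0, 0.1, 0.3, 0.5, 0.9):
            cfg = SimConfig(noise_cv=0.0, gpf_true=gpf_true, n_replicates=1)
            ds, log = generate_experiment(cfg)
            values = [(ds.treatments[(cfg.species_label, "tube", o.treatment)].total_volume,
                       o.height) for o in ds.observations]
            fit = estimate_gpf(values, volm=log.volumes["V4"])
            assert fit.gpf == pytest.approx(gpf_true, abs=1e-9)
            assert fit.vm == pytest.approx(cfg.vm_true, abs=1e-9)

    def test_seed_determinism_and_layer_separation(self):
        cfg = SimConfig(seed=42)
        ds_a, log_a = generate_experiment(cfg)
        ds_b, log_b = generate_experiment(cfg)
        assert ds_a.digest() == ds_b.digest()
        assert log_a.events == log_b.events

        ds_c, log_c = generate_experiment(SimConfig(seed=43))
        assert log_c.events == log_a.events      # controller is noise-free
        assert ds_c.digest() != ds_a.digest()    # growth noise differs

    def test_noiseless_we_recovery(self):
        """With no noise, the efficiency table is exactly size/volume per cell."""
        cfg = SimConfig(noise_cv=0.0, gpf_true=0.3)
        ds, log = generate_experiment(cfg)
        for rec in efficiency_table(ds, phase="tube"):
            size = next(o.height for o in ds.observations if o.treatment == rec.treatment)
            assert rec.hwe == pytest.approx(size / log.volumes[rec.treatment], rel=1e-12)

    def test_expected_size_monotone_in_volume(self):
        ds, log = generate_experiment(SimConfig(noise_cv=0.0, gpf_true=0.43))
        mean_h = {lv: np.mean([o.height for o in ds.observations if o.treatment == lv])
                  for lv in ("V1", "V2", "V3", "V4")}
        ordered = [mean_h[lv] for lv in ("V1", "V2", "V3", "V4")]
        assert all(a <= b for a, b in zip(ordered, ordered[1:]))


class TestParameterRecovery:
    def test_median_gpf_recovery_under_noise(self):
        """Median estimate over 200 seeds at 5% noise is within 0.05 of truth."""
        for gpf_true in (0.1, 0.3, 0.5):
            estimates = []
            for seed in range(200):
                cfg = SimConfig(gpf_true=gpf_true, noise_cv=0.05,
                                n_replicates=15, seed=seed)
                ds, _ = generate_experiment(cfg)
                fits = {f.response: f for f in gpf_table(ds)}
                estimates.append(fits["height"].gpf)
            assert abs(float(np.median(estimates)) - gpf_true) < 0.05


class TestDuc:
    def test_identical_flows_perfectly_uniform(self):
        assert compute_duc([1.5, 1.5, 1.5, 1.5]) == pytest.approx(100.0)

    def test_hand_computed_value(self):
        # mean 4/3; deviations (1/3, 1/3, 2/3); DUC = 100*(1 - (4/9)/(4/3))
        assert compute_duc([1.0, 1.0, 2.0]) == pytest.approx(100 * (1 - 1 / 3), abs=1e-9)

    def test_small_scatter_exceeds_design_criterion(self):
        """Emitters with 2% relative scatter clear the 95% acceptance bound."""
        rng = np.random.default_rng(8)
        flows = 2.0 * (1 + 0.02 * rng.standard_normal(25))
        assert compute_duc(flows) > 95.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DomainError):
            compute_duc([2.0])
        with pytest.raises(DomainError):
            compute_duc([1.0, -1.0])


class TestSimConfigValidation:
    def test_flows_must_increase(self):
        with pytest.raises(DomainError):
            SimConfig(emitter_flows=(2.9, 1.8, 2.1, 1.2))

    def test_noise_cv_bounds(self):
        with pytest.raises(DomainError):
            SimConfig(noise_cv=0.6)

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("gpf_true: 0.25\nseed: 9\nemitter_flows: [1.0, 2.0, 3.0, 4.0]\n")
        cfg = SimConfig.from_file(p)
        assert cfg.gpf_true == 0.25
        assert cfg.seed == 9
        assert cfg.emitter_flows == (1.0, 2.0, 3.0, 4.0)

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("gpf: 0.25\n")
        with pytest.raises(DomainError, match="unknown config key"):
            SimConfig.from_file(p)
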