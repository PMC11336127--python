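"""Chain simulator: closed-form pipeline delay, entrainment model,
noise composition, calibration algebra and determinism."""

import math
from dataclasses import replace

import numpy as np
import pytest

from gammachain.chain_sim import (ChainConfig, DegradedLockWarning,
                                  analytic_baseline_mean,
                                  analytic_baseline_sd, calibrate,
                                  default_config, entrainment_delay,
                                  event_driven_rt, is_locked, noiseless_rt,
                                  simulate_session, simulate_trial,
                                  simulate_trials)
from gammachain.gamma_core import StageConfig
from gammachain.protocol import build_schedule


def _single_stage_config(**kw):
    return ChainConfig(stages=(StageConfig("HO_1", freq_hz=40.0),),
                       afferent_delay_ms=0.0, **kw)


class _ZeroRng:
    """Degenerate generator: every noise draw returns zero."""

    def uniform(self, lo, hi, size=None):
        return np.zeros(size) if size is not None else 0.0

    def normal(self, mu, sd, size=None):
        return np.zeros(size) if size is not None else 0.0


class TestNoiselessRt:
    def test_single_stage_single_cycle(self):
        assert noiseless_rt(_single_stage_config()) == 25.0

    def test_stage_additivity(self):
        cfg = default_config()
        extra = replace(cfg, stages=cfg.stages + (StageConfig("HO_6"),))
        assert noiseless_rt(extra) - noiseless_rt(cfg) == 25.0

    def test_matches_event_driven_oracle_on_random_configs(self, rng):
        for _ in range(200):
            stages = tuple(
                StageConfig(f"S{i}", freq_hz=float(rng.uniform(20, 80)),
                            cycles=int(rng.integers(1, 4)),
                            window_ms_l4=1.0, window_ms_other=2.0)
                for i in range(rng.integers(1, 9)))
            cfg = ChainConfig(stages=stages,
                              afferent_delay_ms=float(rng.uniform(0, 80)),
                              motor_offset_ms=float(rng.uniform(0, 60)))
            delay = float(rng.uniform(0, 30))
            assert noiseless_rt(cfg, delay) == event_driven_rt(cfg, delay)


class TestGatingAbsorbsJitter:
    def test_sub_half_period_jitter_is_invisible(self, rng):
        cfg = default_config()
        clean = event_driven_rt(cfg)
        for _ in range(100):
            xi = rng.uniform(-12.4, 12.4, size=len(cfg.stages))
            assert event_driven_rt(cfg, 0.0, xi) == clean

    def test_super_half_period_jitter_slips_whole_cycles(self):
        cfg = _single_stage_config()
        assert event_driven_rt(cfg, 0.0, [13.0]) == 50.0   # one cycle late
        assert event_driven_rt(cfg, 0.0, [-13.0]) == 0.0   # one cycle early

    def test_stochastic_sd_not_inflated_by_pregate_jitter(self):
        base_cfg = calibrate(default_config())
        ref = simulate_trials(base_cfg, "baseline", 800, contaminate=0.0,
                              seed=5)
        ref_rts = np.array([r.rt_ms for r in ref])
        for w in (2.0, 6.0, 10.0, 12.0):
            cfg = replace(base_cfg, pregate_jitter_ms=w)
            out = simulate_trials(cfg, "baseline", 800, contaminate=0.0,
                                  seed=5)
            rts = np.array([r.rt_ms for r in out])
            # jitter is re-quantized away: identical trial-by-trial
            assert np.array_equal(rts, ref_rts)


class TestEntrainment:
    def test_third_of_period_inside_lock_range(self, calibrated_config):
        assert entrainment_delay(60.0, calibrated_config) == 20.0
        assert math.isclose(entrainment_delay(80.0, calibrated_config),
                            80.0 / 3.0)
        assert math.isclose(entrainment_delay(100.0, calibrated_config),
                            100.0 / 3.0)

    def test_no_inducer_means_no_delay(self, calibrated_config):
        assert entrainment_delay(None, calibrated_config) == 0.0
        assert not is_locked(None, calibrated_config)

    def test_saturation_beyond_lock_range(self, calibrated_config):
        with pytest.warns(DegradedLockWarning):
            d = entrainment_delay(120.0, calibrated_config)
        assert d == calibrated_config.entrain_fraction * 105.0
        assert not is_locked(120.0, calibrated_config)

    def test_monotone_on_lock_range(self, calibrated_config):
        periods = np.linspace(55, 105, 11)
        delays = [entrainment_delay(p, calibrated_config) for p in periods]
        assert np.all(np.diff(delays) > 0)

    def test_negative_period_rejected(self, calibrated_config):
        with pytest.raises(ValueError):
            entrainment_delay(-10.0, calibrated_config)


class TestSimulateTrial:
    def test_degenerate_noise_recovers_noiseless_rt(self, calibrated_config):
        cfg = replace(calibrated_config, motor_sd_ms=0.0)
        rec = simulate_trial(cfg, 1800.0, _ZeroRng())
        assert rec.rt_ms == noiseless_rt(cfg)

    def test_baseline_mean_matches_closed_form(self, calibrated_config):
        recs = simulate_trials(calibrated_config, "baseline", 20_000,
                               contaminate=0.0, seed=77)
        rts = np.array([r.rt_ms for r in recs])
        expected = analytic_baseline_mean(calibrated_config)
        se = rts.std(ddof=1) / math.sqrt(len(rts))
        assert abs(rts.mean() - expected) < 3 * se
        assert abs(rts.std(ddof=1)
                   - analytic_baseline_sd(calibrated_config)) < 1.0

    def test_cyclic_shift_is_exactly_a_third_of_period(self,
                                                       calibrated_config):
        # identical seeds give identical noise streams and gap draws, so
        # the per-trial difference is the pure entrainment delay P/3
        base = simulate_trials(calibrated_config, "baseline", 500,
                               contaminate=0.0, seed=3)
        cyc = simulate_trials(calibrated_config, "cyclic60", 500,
                              contaminate=0.0, seed=3)
        diffs = np.array([c.rt_ms - b.rt_ms for b, c in zip(base, cyc)])
        assert np.allclose(diffs, 20.0)

    def test_gap_bias_term(self, calibrated_config):
        cfg = replace(calibrated_config, motor_sd_ms=0.0, bias_slope=-0.083)
        short = simulate_trial(cfg, 1200.0, _ZeroRng())
        long = simulate_trial(cfg, 2400.0, _ZeroRng())
        assert math.isclose(short.rt_ms - long.rt_ms, 0.083 * 1200.0)


class TestCalibrate:
    def test_targets_reproduced_exactly(self):
        cfg = calibrate(default_config(), 281.0, 38.0)
        assert math.isclose(analytic_baseline_mean(cfg), 281.0)
        assert math.isclose(analytic_baseline_sd(cfg), 38.0)

    def test_motor_sd_variance_decomposition(self):
        cfg = calibrate(default_config(), 281.0, 38.0)
        expected = math.sqrt(38.0 ** 2 - 20.0 ** 2 / 12 - 25.0 ** 2 / 12)
        assert math.isclose(cfg.motor_sd_ms, expected)
        assert 36.7 < cfg.motor_sd_ms < 37.0

    def test_infeasible_sd_rejected(self):
        with pytest.raises(ValueError, match="structural floor"):
            calibrate(default_config(), 281.0, 4.0)

    def test_target_mean_below_structural_delay_rejected(self):
        with pytest.raises(ValueError, match="below the structural"):
            calibrate(default_config(), 100.0, 38.0)


class TestSimulateSession:
    def test_zero_contamination_keeps_model_trials(self, calibrated_config):
        sched = build_schedule("baseline", 120_000, seed=1)
        recs = simulate_session(calibrated_config, sched, contaminate=0.0,
                                seed=2)
        assert len(recs) == sched.n_trials
        assert all(r.rt_ms > 0 for r in recs)

    def test_contamination_produces_sub200_strikes(self, calibrated_config):
        recs = simulate_trials(calibrated_config, "baseline", 2000,
                               contaminate=0.06, seed=8)
        n_sub = sum(r.rt_ms < 200.0 for r in recs)
        # ~ binomial(2000, 0.06) strikes plus the model's own small tail
        assert 80 <= n_sub <= 220

    def test_identical_seed_identical_records(self, calibrated_config):
        a = simulate_trials(calibrated_config, "cyclic80", 200, seed=13)
        b = simulate_trials(calibrated_config, "cyclic80", 200, seed=13)
        assert a == b

    def test_contaminate_out_of_range_rejected(self, calibrated_config):
        sched = build_schedule("baseline", 60_000, seed=1)
        with pytest.raises(ValueError):
            simulate_session(calibrated_config, sched, contaminate=0.5)
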