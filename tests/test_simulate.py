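import numpy as np
import pytest
from scipy.stats import ks_2samp

from mtfold.constructs import ConstructModel, RegimeFits, default_construct
from mtfold.kinetics import (FOLD, UNFOLD, BellParams, critical_force,
                             sample_rupture_forces)
from mtfold.polymer import ElasticityParams, InvalidParameterError, step_size
from mtfold.simulate import (STATE_N, STATE_U, ForceProtocol,
                             SimulationConfig, ramp_transition_forces,
                             simulate_constant_force, simulate_force_jump,
                             simulate_ramp)


def symmetric_model(force=7.0, k=0.1):
    """Construct whose folding and unfolding rates are both k at `force`."""
    el = ElasticityParams()
    x_u, x_f = 0.9, 2.5
    k_u0 = k / np.exp(force * x_u / el.thermal_energy)
    k_f0 = k * np.exp(force * x_f / el.thermal_energy)
    fits = RegimeFits(
        low_force=BellParams(k0=k_u0, x=x_u, sign=UNFOLD),
        high_force=BellParams(k0=k_u0, x=x_u, sign=UNFOLD),
        folding=BellParams(k0=k_f0, x=x_f, sign=FOLD))
    return ConstructModel(construct_id="symmetric", regime_fits=fits,
                          elasticity=el)


def single_bell_model(k0=2.4e-2, x=0.7):
    """Construct with one Bell unfolding law across all forces and
    negligible refolding (for rupture-force distribution checks)."""
    el = ElasticityParams()
    bell = BellParams(k0=k0, x=x, sign=UNFOLD)
    fits = RegimeFits(low_force=bell, high_force=bell,
                      folding=BellParams(k0=1e-9, x=2.5, sign=FOLD))
    return ConstructModel(construct_id="single-bell", regime_fits=fits,
                          elasticity=el)


class TestProtocols:
    def test_force_range_validated(self):
        with pytest.raises(InvalidParameterError):
            ForceProtocol(kind="constant", constant_force=80.0)
        with pytest.raises(InvalidParameterError):
            ForceProtocol(kind="ramp", ramp_start=2, ramp_end=42,
                          ramp_rate=-1.0)
        with pytest.raises(InvalidParameterError):
            ForceProtocol(kind="jump", jump_schedule=())

    def test_seed_mandatory(self, le_model):
        with pytest.raises(TypeError):
            SimulationConfig(
                construct=le_model,
                protocol=ForceProtocol(kind="constant", constant_force=7.0),
                duration=10.0)


class TestConstantForce:
    def test_determinism(self, constant_config):
        a = simulate_constant_force(constant_config(seed=5, duration=50))
        b = simulate_constant_force(constant_config(seed=5, duration=50))
        np.testing.assert_array_equal(a.height, b.height)
        np.testing.assert_array_equal(a.true_state, b.true_state)

    def test_symmetric_rates_occupancy(self):
        occ = []
        model = symmetric_model()
        for seed in range(20):
            cfg = SimulationConfig(
                construct=model,
                protocol=ForceProtocol(kind="constant", constant_force=7.0),
                duration=500.0, seed=seed, noise_sigma=0.0,
                sampling_rate=50.0)
            traj = simulate_constant_force(cfg)
            occ.append((traj.true_state == STATE_U).mean())
        assert np.mean(occ) == pytest.approx(0.5, abs=0.05)

    def test_mean_dwell_exponential_oracle(self, le_model):
        # accumulate 1000 completed N dwells from ground-truth events
        f = 5.5
        k_u = le_model.unfolding_rate(f)
        durations = []
        seed = 0
        while len(durations) < 1000:
            cfg = SimulationConfig(
                construct=le_model,
                protocol=ForceProtocol(kind="constant", constant_force=f),
                duration=2000.0, seed=seed, noise_sigma=0.0,
                sampling_rate=10.0)
            traj = simulate_constant_force(cfg)
            ev = traj.events
            for a, b in zip(ev[:-1], ev[1:]):
                if a.to_state == STATE_N and b.to_state == STATE_U:
                    durations.append(b.time - a.time)
            seed += 1
        durations = np.array(durations[:1000])
        se = (1.0 / k_u) / np.sqrt(len(durations))
        assert abs(durations.mean() - 1.0 / k_u) < 3 * se

    def test_noiseless_two_levels(self, constant_config):
        cfg = constant_config(force=5.5, duration=200, seed=2,
                              noise_sigma=0.0)
        traj = simulate_constant_force(cfg)
        levels = np.unique(traj.height)
        assert len(levels) == 2
        dx = step_size(5.5, cfg.construct.elasticity)
        assert levels[1] - levels[0] == pytest.approx(dx, abs=1e-9)

    def test_labels_consistent_with_heights(self, constant_config):
        cfg = constant_config(force=6.0, duration=100, seed=3,
                              noise_sigma=0.0)
        traj = simulate_constant_force(cfg)
        dx = step_size(6.0, cfg.construct.elasticity)
        expected = np.where(traj.true_state == STATE_U, dx, 0.0)
        np.testing.assert_allclose(traj.height, expected, atol=1e-9)

    def test_undersampled_warning(self):
        model = symmetric_model(force=7.0, k=30.0)
        cfg = SimulationConfig(
            construct=model,
            protocol=ForceProtocol(kind="constant", constant_force=7.0),
            duration=5.0, seed=1, sampling_rate=50.0)
        with pytest.warns(RuntimeWarning, match="undersampled"):
            simulate_constant_force(cfg)

    def test_detailed_balance_at_critical_force(self, le_model):
        fits = le_model.regime_fits
        fc = critical_force(fits.low_force, fits.folding)
        occ = []
        for seed in range(10):
            cfg = SimulationConfig(
                construct=le_model,
                protocol=ForceProtocol(kind="constant",
                                       constant_force=float(fc)),
                duration=1500.0, seed=seed, noise_sigma=0.0,
                sampling_rate=20.0)
            traj = simulate_constant_force(cfg)
            occ.append((traj.true_state == STATE_U).mean())
        assert np.mean(occ) == pytest.approx(0.5, abs=0.06)


class TestRamp:
    def test_first_rupture_matches_inverse_cdf(self):
        model = single_bell_model()
        cfg = SimulationConfig(
            construct=model,
            protocol=ForceProtocol(kind="ramp", ramp_start=0.1, ramp_end=42,
                                   ramp_rate=1.0),
            seed=50, sampling_rate=200.0)
        unfold, _ = ramp_transition_forces(cfg, 2000)
        unfold = unfold[~np.isnan(unfold)]
        ref = sample_rupture_forces(2000, model.regime_fits.low_force, 1.0,
                                    seed=999)
        stat = ks_2samp(unfold, ref).statistic
        assert stat < 0.04  # two-sample KS at n=2000

    def test_hysteresis(self, ramp_config):
        cfg = ramp_config(seed=7)
        unfold, refold = ramp_transition_forces(cfg, 300)
        ok = ~np.isnan(unfold) & ~np.isnan(refold)
        assert ok.sum() > 100
        assert np.nanmean(refold[ok]) < np.nanmean(unfold[ok])
        # per-trace ordering holds in the large majority (traces that
        # happen to unfold very early can refold slightly higher)
        assert (refold[ok] < unfold[ok]).mean() > 0.8

    def test_zero_noise_single_discontinuity(self):
        model = single_bell_model()
        cfg = SimulationConfig(
            construct=model,
            protocol=ForceProtocol(kind="ramp", ramp_start=2, ramp_end=42,
                                   ramp_rate=1.0),
            seed=11, noise_sigma=0.0, sampling_rate=200.0)
        traj = simulate_ramp(cfg)
        ruptures = [e for e in traj.events if e.to_state == STATE_U]
        assert len(ruptures) == 1
        jumps = np.flatnonzero(np.abs(np.diff(traj.height)) > 1.0)
        assert len(jumps) == 1
        f_at_jump = traj.force[jumps[0] + 1]
        assert f_at_jump == pytest.approx(ruptures[0].force, abs=0.01)

    def test_determinism(self, ramp_config):
        a = simulate_ramp(ramp_config(seed=3))
        b = simulate_ramp(ramp_config(seed=3))
        np.testing.assert_array_equal(a.height, b.height)

    def test_uniform_sampling_round_trip_grid(self, ramp_config):
        traj = simulate_ramp(ramp_config(seed=3))
        dt = np.diff(traj.time)
        assert np.allclose(dt, dt[0])
        assert traj.force.max() == pytest.approx(42.0, abs=0.01)


class TestForceJump:
    def test_single_segment_equals_constant(self, le_model):
        jump_cfg = SimulationConfig(
            construct=le_model,
            protocol=ForceProtocol(kind="jump",
                                   jump_schedule=((5.5, 100.0),)),
            seed=21)
        const_cfg = SimulationConfig(
            construct=le_model,
            protocol=ForceProtocol(kind="constant", constant_force=5.5),
            duration=100.0, seed=21)
        a = simulate_force_jump(jump_cfg)
        b = simulate_constant_force(const_cfg)
        np.testing.assert_array_equal(a.height, b.height)
        np.testing.assert_array_equal(a.true_state, b.true_state)

    def test_survival_after_jump_is_exponential(self, le_model):
        # hold at 1 pN (k_u tiny), jump to 20 pN; N-state survival decays
        # at k_u(20)
        f_hi = 20.0
        k_true = le_model.unfolding_rate(f_hi)
        waits = []
        for seed in range(1000):
            cfg = SimulationConfig(
                construct=le_model,
                protocol=ForceProtocol(kind="jump",
                                       jump_schedule=((1.0, 1.0),
                                                      (f_hi, 50.0))),
                seed=seed, noise_sigma=0.0, sampling_rate=50.0)
            traj = simulate_force_jump(cfg)
            for e in traj.events:
                if e.to_state == STATE_U and e.time >= 1.0:
                    waits.append(e.time - 1.0)
                    break
        waits = np.array(waits)
        assert len(waits) > 950
        k_hat = 1.0 / waits.mean()
        assert abs(k_hat / k_true - 1.0) < 0.1

    def test_step_size_tracks_polymer_model(self, le_model):
        for f in (10.0, 20.0, 30.0):
            cfg = SimulationConfig(
                construct=le_model,
                protocol=ForceProtocol(kind="jump",
                                       jump_schedule=((1.0, 0.5), (f, 5.0))),
                seed=int(f), noise_sigma=0.0, sampling_rate=200.0,
                initial_state=STATE_N)
            traj = simulate_force_jump(cfg)
            seg = traj.height[traj.force == f]
            states = traj.true_state[traj.force == f]
            if (states == STATE_U).any() and (states == STATE_N).any():
                measured = (seg[states == STATE_U].mean()
                            - seg[states == STATE_N].mean())
                assert measured == pytest.approx(
                    step_size(f, le_model.elasticity), abs=1e-9)

    def test_state_carries_over(self, le_model):
        # long hold at high force unfolds; the following low-force hold
        # starts unfolded
        cfg = SimulationConfig(
            construct=le_model,
            protocol=ForceProtocol(kind="jump",
                                   jump_schedule=((25.0, 20.0), (1.0, 0.5))),
            seed=4, noise_sigma=0.0, sampling_rate=100.0)
        traj = simulate_force_jump(cfg)
        first_low = np.flatnonzero(traj.force == 1.0)[0]
        ev_before = [e for e in traj.events if e.time < traj.time[first_low]]
        assert ev_before  # unfolded during the high hold
        assert traj.true_state[first_low] == ev_before[-1].to_state
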