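import numpy as np
import pytest

from oscillo import (
    FreezingParams,
    GammaSpec,
    SessionDesign,
    SimulationConfig,
    ValidationError,
    generate_cohort,
    generate_lfp,
    generate_motion_trace,
    generate_schedule,
    score_freezing,
    welch_psd,
)
from oscillo.core import SignalTrace
from oscillo.simulate import animal_seed, powerlaw_noise


@pytest.fixture
def quiet_config():
    """Oscillations only, no stochastic components."""
    return SimulationConfig(
        sampling_rate_hz=1000.0, aperiodic_amp=0.0, line_noise_amp=0.0, noise_sd=0.0
    )


class TestDeterminism:
    def test_identical_seed_identical_samples(self, small_design):
        sch = generate_schedule(small_design)
        cfg = SimulationConfig(sampling_rate_hz=1000.0, seed=11)
        t1, _ = generate_lfp(cfg, sch)
        t2, _ = generate_lfp(cfg, sch)
        assert np.array_equal(t1.samples, t2.samples)

    def test_different_seed_different_samples(self, small_design):
        sch = generate_schedule(small_design)
        a, _ = generate_lfp(SimulationConfig(sampling_rate_hz=1000.0, seed=1), sch)
        b, _ = generate_lfp(SimulationConfig(sampling_rate_hz=1000.0, seed=2), sch)
        assert not np.array_equal(a.samples, b.samples)

    def test_cohort_reproducible_and_streams_independent(self, small_design):
        specs = {"control": {}, "mutant": {}}
        c1, _ = generate_cohort(2, specs, small_design, master_seed=5)
        c2, _ = generate_cohort(2, specs, small_design, master_seed=5)
        for r1, r2 in zip(c1, c2):
            assert r1.animal_id == r2.animal_id
            assert np.array_equal(r1.trace.samples, r2.trace.samples)
        seeds = {r.config.seed for r in c1}
        assert len(seeds) == len(c1)
        assert all(0 <= s < 2**31 for s in seeds)

    def test_animal_seed_stable_mapping(self):
        assert animal_seed(0, 0, 0) == animal_seed(0, 0, 0)
        assert animal_seed(0, 0, 0) != animal_seed(0, 0, 1)


class TestSignalComposition:
    def test_trace_duration_matches_schedule(self, small_design):
        sch = generate_schedule(small_design)
        tr, _ = generate_lfp(SimulationConfig(sampling_rate_hz=1000.0), sch)
        assert tr.n_samples == int(sch.end_s * 1000)

    def test_no_coupling_envelope_constant(self, quiet_config, small_design):
        # m=0: the gamma envelope has no theta modulation left
        sch = generate_schedule(small_design)
        cfg = SimulationConfig(
            **{**quiet_config.__dict__, "theta_amp": 0.0, "pac_depth": 0.0,
               "gamma_bands": (GammaSpec("low_gamma", 40.0, 10.0),)}
        )
        tr, _ = generate_lfp(cfg, sch)
        from scipy.signal import hilbert

        env = np.abs(hilbert(tr.samples))[1000:-1000]
        assert env.std() / env.mean() < 0.01

    def test_group_gain_scales_band_variance(self, quiet_config, small_design):
        sch = generate_schedule(small_design)
        base = dict(quiet_config.__dict__)
        base.update(theta_amp=0.0, pac_depth=0.0,
                    gamma_bands=(GammaSpec("low_gamma", 40.0, 10.0),))
        a, _ = generate_lfp(SimulationConfig(**base), sch)
        b, _ = generate_lfp(
            SimulationConfig(**{**base, "group_gain": {"*": {"low_gamma": 0.7}}}), sch
        )
        ratio = b.samples.var() / a.samples.var()
        assert ratio == pytest.approx(0.49, rel=0.01)

    def test_carrier_above_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(
                sampling_rate_hz=100.0, gamma_bands=(GammaSpec("high_gamma", 70.0, 5.0),)
            )

    def test_memory_budget_enforced(self, small_design):
        sch = generate_schedule(small_design)
        cfg = SimulationConfig(sampling_rate_hz=1000.0, max_samples=1000)
        with pytest.raises(ValidationError):
            generate_lfp(cfg, sch)

    def test_aperiodic_exponent_recovered_from_psd(self, small_design):
        # spectral-shape invariant: log-log slope over 5-100 Hz ~ -alpha
        sch = generate_schedule(small_design)
        for alpha in (1.0, 2.0):
            cfg = SimulationConfig(
                sampling_rate_hz=1000.0, aperiodic_exponent=alpha, aperiodic_amp=20.0,
                theta_amp=0.0, gamma_bands=(), line_noise_amp=0.0, noise_sd=0.0,
                seed=13,
            )
            tr, _ = generate_lfp(cfg, sch)
            psd = welch_psd(tr)
            mask = (psd.freqs >= 5.0) & (psd.freqs <= 100.0)
            slope = np.polyfit(np.log(psd.freqs[mask]), np.log(psd.power[mask]), 1)[0]
            assert slope == pytest.approx(-alpha, abs=0.3)

    def test_pac_envelope_peaks_in_preferred_phase_bin(self, quiet_config, small_design):
        sch = generate_schedule(small_design)
        phi0 = np.pi / 3
        cfg = SimulationConfig(
            **{**quiet_config.__dict__, "pac_depth": 1.0,
               "pac_preferred_phase": phi0, "theta_amp": 0.0,
               "gamma_bands": (GammaSpec("low_gamma", 40.0, 10.0),)}
        )
        tr, _ = generate_lfp(cfg, sch)
        from scipy.signal import hilbert

        env = np.abs(hilbert(tr.samples))
        t = tr.times()
        theta_phase = np.angle(np.exp(1j * 2 * np.pi * cfg.theta_hz * t))
        edges = np.linspace(-np.pi, np.pi, 19)
        idx = np.clip(np.digitize(theta_phase, edges[1:-1]), 0, 17)
        interior = slice(500, -500)
        profile = np.bincount(idx[interior], weights=env[interior], minlength=18)
        profile = profile / np.bincount(idx[interior], minlength=18)
        peak_bin = np.argmax(profile)
        assert edges[peak_bin] <= phi0 <= edges[peak_bin + 1]

    def test_ground_truth_books_every_interval(self, small_design):
        sch = generate_schedule(small_design)
        _, gt = generate_lfp(SimulationConfig(sampling_rate_hz=1000.0), sch)
        assert [r["label"] for r in gt.intervals] == list(sch.labels())
        assert gt.amplitude("tone_1", "low_gamma") > 0


class TestMotionTrace:
    def test_target_one_freezes_everywhere(self, small_design):
        sch = generate_schedule(small_design)
        mt = generate_motion_trace(sch, 1.0, seed=0)
        assert np.all(mt.motion_index[: int(sch.end_s * 30) - 1] < 18.0) or (
            score_freezing(mt, FreezingParams(), sch)["freezing_pct"] == 100.0
        ).all()

    def test_half_freezing_scored_exactly(self):
        # 30 s trial at 30 fps: a 450-frame bout scores exactly 50%
        sch = generate_schedule(SessionDesign(30.0, 1, 30.0, 5.0))
        mt = generate_motion_trace(sch, {"tone_1": 0.5}, seed=4)
        out = score_freezing(mt, FreezingParams(), sch)
        tone = out.loc[out["label"] == "tone_1", "freezing_pct"].item()
        assert tone == pytest.approx(50.0, abs=1e-12)

    def test_subminimum_target_bout_dropped(self):
        sch = generate_schedule(SessionDesign(30.0, 1, 30.0, 5.0))
        # 29/900 of a 30 s trial -> 29-frame bout, below the 30-frame minimum
        with pytest.warns(UserWarning, match="below the 30-frame minimum"):
            mt = generate_motion_trace(sch, {"tone_1": 29.0 / 900.0}, seed=2)
        out = score_freezing(mt, FreezingParams(), sch)
        assert out.loc[out["label"] == "tone_1", "freezing_pct"].item() == 0.0

    def test_achieved_fractions_recorded_in_ground_truth(self, small_design):
        sch = generate_schedule(small_design)
        cfg = SimulationConfig(sampling_rate_hz=1000.0)
        _, gt = generate_lfp(cfg, sch)
        generate_motion_trace(sch, {"tone_*": 0.6}, seed=1, ground_truth=gt)
        tone_recs = [r for r in gt.intervals if r["label"].startswith("tone_")]
        assert all(abs(r["freezing_frac"] - 0.6) < 0.01 for r in tone_recs)

    def test_bad_frame_rate_rejected(self, small_design):
        sch = generate_schedule(small_design)
        with pytest.raises(ValidationError):
            generate_motion_trace(sch, 0.5, frame_rate=0.0)


class TestCohort:
    def test_two_groups_of_five_gives_ten_records(self, small_design):
        cohort, _ = generate_cohort(
            5, {"control": {}, "mutant": {}}, small_design, master_seed=1
        )
        assert len(cohort) == 10
        assert sum(r.group == "control" for r in cohort) == 5

    def test_group_gain_reflected_in_ground_truth(self, small_design):
        specs = {"control": {}, "mutant": {"group_gain": {"*": {"low_gamma": 0.7}}}}
        cohort, _ = generate_cohort(3, specs, small_design, master_seed=2)
        amps = {g: [] for g in ("control", "mutant")}
        for rec in cohort:
            amps[rec.group].append(rec.ground_truth.amplitude("tone_1", "low_gamma"))
        ratio = np.mean(amps["mutant"]) / np.mean(amps["control"])
        assert ratio == pytest.approx(0.7, abs=1e-12)

    def test_unknown_config_field_rejected(self, small_design):
        with pytest.raises(ValidationError, match="unknown config fields"):
            generate_cohort(2, {"g": {"not_a_field": 1}}, small_design)

    def test_nonpositive_group_size_rejected(self, small_design):
        with pytest.raises(ValidationError):
            generate_cohort(0, {"g": {}}, small_design)


class TestPowerlawNoise:
    def test_unit_rms(self):
        rng = np.random.default_rng(0)
        x = powerlaw_noise(50_000, 1000.0, 1.5, rng)
        assert np.sqrt(np.mean(x**2)) == pytest.approx(1.0, abs=1e-9)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            SimulationConfig(pac_depth=1.5)
        with pytest.raises(ValidationError):
            SimulationConfig(theta_hz=20.0)
        with pytest.raises(ValidationError):
            SimulationConfig(group_gain={"tone": {"low_gamma": -1.0}})
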