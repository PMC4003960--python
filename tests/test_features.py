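import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.stats import spearmanr

from pdgait.features import (
    GaitFeatureSet,
    SampEnParams,
    StepDetectionError,
    detect_steps,
    dominant_frequency,
    extract_features,
    pendulum_step_length,
    sample_entropy,
    step_frequency,
    stride_length,
    stride_time_cv,
    velocity,
)
from pdgait.synthetic import GaitProfile, simulate_gait_acceleration


def sampen_bruteforce(series, m, r):
    """Exhaustive all-pairs oracle, independent of the vectorized path."""
    x = [float(v) for v in series]
    n = len(x)
    sd = float(np.std(np.asarray(x)))
    if sd == 0.0:
        return 0.0
    tol = r * sd

    def count(mm):
        c = 0
        for i in range(n - mm + 1):
            for j in range(i + 1, n - mm + 1):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= tol:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("inf")
    return -math.log(a / b)


class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert sample_entropy(np.ones(50)) == 0.0

    def test_alternating_series_matches_oracle_exactly(self):
        series = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2], dtype=float)
        params = SampEnParams(m=2, r=0.2)
        assert sample_entropy(series, params) == sampen_bruteforce(series, 2, 0.2)

    def test_noise_exceeds_periodic(self):
        rng = np.random.default_rng(0)
        t = np.arange(500)
        periodic = np.sin(2 * np.pi * t / 25)
        noise = rng.normal(0, np.std(periodic), size=t.size)
        assert sample_entropy(noise) > sample_entropy(periodic)

    def test_no_matches_infinite_sentinel(self):
        # strictly growing with huge steps: no template pair stays within tol
        series = np.array([0.0, 1e3, 3e3, 7e3, 15e3, 40e3, 90e3, 200e3])
        assert sample_entropy(series, SampEnParams(m=2, r=0.01)) == float("inf")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy([1.0, 2.0, 3.0], SampEnParams(m=2))

    @settings(max_examples=60, deadline=None)
    @given(
        series=hnp.arrays(
            np.float64,
            st.integers(min_value=8, max_value=60),
            elements=st.floats(min_value=-10, max_value=10, allow_nan=False),
        )
    )
    def test_matches_bruteforce_oracle(self, series):
        params = SampEnParams(m=2, r=0.2)
        assert sample_entropy(series, params) == sampen_bruteforce(series, 2, 0.2)

    @settings(max_examples=20, deadline=None)
    @given(
        scale=st.floats(min_value=0.1, max_value=50, allow_nan=False),
        shift=st.floats(min_value=-100, max_value=100, allow_nan=False),
    )
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(12)
        x = rng.normal(size=120)
        e1 = sample_entropy(x)
        e2 = sample_entropy(scale * x + shift)
        assert e1 == pytest.approx(e2, rel=1e-9)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            SampEnParams(m=0)
        with pytest.raises(ValueError):
            SampEnParams(r=0.0)

    def test_monotone_in_stride_variability(self):
        cvs = [0.0, 0.03, 0.06, 0.10, 0.15]
        entropies = []
        for cv in cvs:
            p = GaitProfile(stride_time_cv=cv, harmonic_noise_sd=0.03)
            sim = simulate_gait_acceleration(p, 30.0, seed=21)
            x = sim.signals["belt"][:, 0]
            entropies.append(sample_entropy(x - x.mean()))
        rho = spearmanr(cvs, entropies).statistic
        assert rho > 0

    def test_monotone_in_noise(self):
        sds = [0.01, 0.03, 0.06, 0.1]
        entropies = []
        for sd in sds:
            p = GaitProfile(stride_time_cv=0.02, harmonic_noise_sd=sd)
            sim = simulate_gait_acceleration(p, 30.0, seed=22)
            x = sim.signals["belt"][:, 0]
            entropies.append(sample_entropy(x - x.mean()))
        rho = spearmanr(sds, entropies).statistic
        assert rho > 0


class TestDetectSteps:
    def test_noiseless_gait_intervals(self, noiseless_profile):
        sim = simulate_gait_acceleration(noiseless_profile, 30.0, seed=0)
        steps = detect_steps(sim.signals["belt"][:, 0], 62.5)
        intervals = np.diff(steps)
        # interior intervals within one sample; first/last may carry the
        # filtfilt edge transient (allow two samples there)
        assert np.all(np.abs(intervals[1:-1] - 0.5) <= 1.0 / 62.5)
        assert np.all(np.abs(intervals - 0.5) <= 2.0 / 62.5)

    def test_noisy_frequency_error_bound(self):
        # 50 noisy trials: mean relative step-frequency error <= 1.88%
        rng = np.random.default_rng(123)
        errors = []
        for k in range(50):
            f = rng.uniform(1.5, 2.5)
            p = GaitProfile(step_frequency_hz=f, stride_time_cv=0.02, harmonic_noise_sd=0.03)
            sim = simulate_gait_acceleration(p, 30.0, seed=500 + k)
            steps = detect_steps(sim.signals["belt"][:, 0], 62.5)
            errors.append(abs(step_frequency(steps) - f) / f * 100.0)
        assert np.mean(errors) <= 1.88

    def test_resting_signal_skipped_with_reason(self):
        rng = np.random.default_rng(0)
        x = 1.0 + rng.normal(0, 0.005, size=2000)
        with pytest.raises(StepDetectionError):
            detect_steps(x, 62.5)

    def test_too_short_skipped(self):
        with pytest.raises(StepDetectionError, match="2 s"):
            detect_steps(np.zeros(50), 62.5)

    def test_dominant_frequency_pure_tone(self):
        t = np.arange(0, 10, 1 / 62.5)
        x = np.sin(2 * np.pi * 2.0 * t)
        assert dominant_frequency(x, 62.5) == pytest.approx(2.0, abs=0.11)


class TestStepFrequencyAndCV:
    def test_equal_intervals(self):
        t = np.arange(10) * 0.5
        assert step_frequency(t) == pytest.approx(2.0)
        assert stride_time_cv(t) == 0.0

    def test_too_few_steps_flagged(self):
        assert np.isnan(step_frequency(np.array([0.0, 0.5])))
        assert np.isnan(stride_time_cv(np.array([0.0, 0.5, 1.0])))

    def test_cv_recovery(self):
        # simulated CV = 0.10 recovered within 15% relative at >= 200 strides
        p = GaitProfile(step_frequency_hz=2.0, stride_time_cv=0.10, harmonic_noise_sd=0.02)
        sim = simulate_gait_acceleration(p, 220.0, seed=31)  # ~440 steps / 220 strides
        steps = detect_steps(sim.signals["belt"][:, 0], 62.5)
        assert steps.size >= 400
        assert stride_time_cv(steps) == pytest.approx(0.10, rel=0.15)


class TestStrideLength:
    def test_pendulum_closed_form(self):
        assert pendulum_step_length(1.0, 0.05) == pytest.approx(0.6244997998398398, abs=1e-12)

    def test_h_zero_boundary(self):
        assert pendulum_step_length(1.0, 0.0) == 0.0

    def test_h_clipped_to_leg_length(self):
        assert pendulum_step_length(1.0, 5.0) == pytest.approx(2.0)  # h -> l gives s = 2l... sqrt(2l*l-l*l)=l -> 2l? no: 2*sqrt(l^2)=2l

    def test_noiseless_end_to_end_within_5pct(self, noiseless_profile):
        sim = simulate_gait_acceleration(noiseless_profile, 60.0, seed=1)
        x = sim.signals["belt"][:, 0]
        steps = detect_steps(x, 62.5)
        per_step, mean_len, dropped = stride_length(x, 62.5, steps, 1.0)
        truth = noiseless_profile.step_length_m
        assert dropped == 0
        assert np.all(np.abs(per_step - truth) / truth <= 0.05)
        assert mean_len == pytest.approx(truth, rel=0.05)

    def test_too_few_steps(self):
        with pytest.raises(StepDetectionError):
            stride_length(np.zeros(100), 62.5, np.array([0.5]), 1.0)

    def test_leg_length_validation(self):
        with pytest.raises(ValueError):
            stride_length(np.zeros(100), 62.5, np.array([0.2, 0.7]), 0.0)


class TestVelocity:
    def test_product(self):
        assert velocity(2.0, 0.6) == pytest.approx(1.2)

    def test_zero(self):
        assert velocity(0.0, 123.0) == 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            velocity(float("nan"), 1.0)


class TestExtractFeatures:
    def test_full_feature_set(self, healthy_profile):
        sim = simulate_gait_acceleration(healthy_profile, 40.0, seed=3)
        fs = extract_features(sim.signals["belt"][:, 0], 62.5, 1.0)
        assert isinstance(fs, GaitFeatureSet)
        assert fs.step_frequency_hz == pytest.approx(2.0, rel=0.05)
        assert fs.stride_time_cv == pytest.approx(0.02, abs=0.02)
        assert 0 < fs.stride_length_m < 2 * healthy_profile.leg_length_m
        assert fs.velocity_consistent
        assert np.isfinite(fs.sample_entropy)
        assert fs.n_steps >= 4

    def test_resting_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(StepDetectionError):
            extract_features(1.0 + rng.normal(0, 0.004, 3000), 62.5, 1.0)
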