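"""Kinematic measures: speed, displacement rate, baseline ratio, blocks."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mobilearn import kinematics as kin
from mobilearn.errors import DegenerateBaselineError, InsufficientDataError
from mobilearn.kinematics import (
    PositionSeries,
    RateSeries,
    Session,
    SpeedSeries,
    baseline_ratio,
    block_means,
    displacement_rate,
    instantaneous_speed,
    relabel_limbs,
)


def _pos(t, x, y=None, z=None):
    zeros = np.zeros_like(t)
    return PositionSeries(
        t=t, x=x, y=zeros if y is None else y, z=zeros if z is None else z
    )


class TestInstantaneousSpeed:
    def test_constant_position_zero_speed(self):
        t = np.arange(100) / 60.0
        s = instantaneous_speed(_pos(t, np.full_like(t, 5.0)))
        assert np.all(s.v == 0)
        assert len(s) == 98  # endpoints dropped

    def test_linear_motion_exact(self):
        # velocity (3, 4, 0) mm/s -> speed 5 mm/s (central diff exact on lines)
        t = np.arange(200) / 60.0
        s = instantaneous_speed(_pos(t, 3 * t, 4 * t))
        np.testing.assert_allclose(s.v, 5.0, rtol=1e-12)
        np.testing.assert_allclose(s.t, t[1:-1])

    def test_circular_motion_matches_r_omega(self):
        # radius 10 mm, angular rate pi rad/s at 60 Hz: the central
        # difference returns r*omega*sinc(omega*T); both the exact
        # discretisation and the continuum limit r*omega are checked.
        r, w, fs = 10.0, np.pi, 60.0
        t = np.arange(int(4 * fs)) / fs
        s = instantaneous_speed(_pos(t, r * np.cos(w * t), r * np.sin(w * t)))
        exact_discrete = r * np.sin(w / fs) / (1.0 / fs)
        np.testing.assert_allclose(s.v, exact_discrete, rtol=1e-10)
        np.testing.assert_allclose(s.v, r * w, rtol=5e-4)

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            instantaneous_speed(_pos(np.array([0.0, 1 / 60]), np.array([0.0, 1.0])))


class TestDisplacementRate:
    def test_constant_speed_constant_rate_including_edges(self):
        t = np.arange(0, 120, 1 / 60)
        r = displacement_rate(SpeedSeries(t=t, v=np.full_like(t, 2.5)), tau=30)
        np.testing.assert_allclose(r.rate, 2.5, rtol=1e-12)

    def test_step_speed_window_average(self):
        # 1 mm/s on [0, 60), 3 mm/s on [60, 120): window mean at t=60 is 2
        t = np.arange(0, 120, 1 / 60)
        v = np.where(t < 60, 1.0, 3.0)
        r = displacement_rate(SpeedSeries(t=t, v=v), tau=30)
        at60 = r.rate[np.argmin(np.abs(r.t - 60.0))]
        assert at60 == pytest.approx(2.0, abs=1e-3)

    def test_interior_window_is_one_minute(self):
        # tau=30 s -> the full interior window spans 60 s of samples
        fs = 60.0
        t = np.arange(0, 720, 1 / fs)
        v = np.zeros_like(t)
        centre = len(t) // 2
        v[centre] = 1.0  # unit impulse
        r = displacement_rate(SpeedSeries(t=t, v=v), tau=30)
        support = r.rate > 0
        width = r.t[support][-1] - r.t[support][0]
        assert width == pytest.approx(60.0, abs=2 / fs)

    def test_naive_oracle_equivalence(self, rng):
        # sliding-window implementation == per-t loop to 1e-12 relative
        t = np.arange(0, 100, 0.25)
        v = rng.uniform(0, 10, size=len(t))
        r = displacement_rate(SpeedSeries(t=t, v=v), tau=10)
        naive = np.array(
            [v[(t >= ti - 10) & (t <= ti + 10)].mean() for ti in t]
        )
        np.testing.assert_allclose(r.rate, naive, rtol=1e-12)

    def test_insufficient_coverage_raises(self):
        t = np.arange(0, 30, 1 / 60)
        with pytest.raises(InsufficientDataError):
            displacement_rate(SpeedSeries(t=t, v=np.ones_like(t)), tau=30)


class TestBaselineRatio:
    def test_baseline_mean_is_one(self, rng):
        t = np.arange(0, 720, 1 / 60)
        rate = RateSeries(t=t, rate=rng.uniform(1, 5, len(t)), tau=30)
        ratio = baseline_ratio(rate, baseline=(0, 120))
        mask = kin.baseline_divisor_mask(t, (0, 120), 30)
        assert ratio.ratio[mask].mean() == pytest.approx(1.0, abs=1e-12)

    def test_divisor_uses_only_full_support_centres(self):
        # rate differs outside [30, 90]; the divisor must ignore it
        t = np.arange(0, 720, 1 / 60)
        rate = np.where((t >= 30) & (t <= 90), 2.0, 99.0)
        ratio = baseline_ratio(RateSeries(t=t, rate=rate, tau=30), (0, 120))
        assert ratio.baseline_mean == pytest.approx(2.0)

    def test_step_doubling_gives_late_ratio_two(self):
        t = np.arange(0, 720, 1 / 60)
        rate = np.where(t < 120, 1.5, 3.0)
        ratio = baseline_ratio(RateSeries(t=t, rate=rate, tau=30), (0, 120))
        late = ratio.ratio[t > 200]
        np.testing.assert_allclose(late, 2.0, rtol=1e-12)

    def test_zero_baseline_raises(self):
        t = np.arange(0, 720, 1 / 60)
        rate = np.where(t < 120, 0.0, 1.0)
        with pytest.raises(DegenerateBaselineError):
            baseline_ratio(RateSeries(t=t, rate=rate, tau=30), (0, 120))


class TestRelabelLimbs:
    @pytest.mark.parametrize(
        "side,expected",
        [
            (
                "right",
                {
                    "right_wrist": "ConA",
                    "left_wrist": "UncA",
                    "right_ankle": "IpsiL",
                    "left_ankle": "ContL",
                },
            ),
            (
                "left",
                {
                    "left_wrist": "ConA",
                    "right_wrist": "UncA",
                    "left_ankle": "IpsiL",
                    "right_ankle": "ContL",
                },
            ),
        ],
    )
    def test_role_mapping(self, side, expected):
        t = np.arange(0, 1, 1 / 60)
        limbs = {
            m: _pos(t, np.zeros_like(t)) for m in kin.MARKERS
        }
        s = Session(
            id="x", age_group="2mo", connected_side=side, limbs=limbs
        )
        assert relabel_limbs(s) == expected


class TestBlockMeans:
    def test_constant_series(self):
        t = np.arange(0, 720, 1 / 60)
        r = RateSeries(t=t, rate=np.full_like(t, 3.3), tau=30)
        m = block_means(r)
        assert list(m.index) == ["B", "P1", "P2", "P3", "P4", "P5"]
        np.testing.assert_allclose(m.to_numpy(), 3.3)

    def test_linear_ramp_midpoints(self):
        # ramp 0 -> 1 over the session: block means = interval midpoints
        t = np.arange(0, 720, 1 / 60)
        r = RateSeries(t=t, rate=t / 720.0, tau=30)
        m = block_means(r)
        expected = [(lo + hi) / 2 / 720 for lo, hi in kin.DEFAULT_BLOCKS.values()]
        np.testing.assert_allclose(m.to_numpy(), expected, atol=1e-4)

    def test_empty_block_raises(self):
        t = np.arange(0, 600, 1 / 60)  # no P5 coverage
        r = RateSeries(t=t, rate=np.ones_like(t), tau=30)
        with pytest.raises(InsufficientDataError):
            block_means(r)


class TestInvariants:
    @given(
        lam=st.floats(min_value=0.1, max_value=100.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_scale_equivariance(self, lam, seed):
        """Scaling positions by λ scales speed and rate by λ and leaves the
        ratio unchanged."""
        r = np.random.default_rng(seed)
        t = np.arange(0, 240, 1 / 20)
        x, y, z = (np.cumsum(r.normal(0, 1, len(t))) for _ in range(3))
        p1 = PositionSeries(t=t, x=x, y=y, z=z)
        p2 = PositionSeries(t=t, x=lam * x, y=lam * y, z=lam * z)
        s1, s2 = instantaneous_speed(p1), instantaneous_speed(p2)
        np.testing.assert_allclose(s2.v, lam * s1.v, rtol=1e-9)
        r1 = displacement_rate(s1, tau=30)
        r2 = displacement_rate(s2, tau=30)
        np.testing.assert_allclose(r2.rate, lam * r1.rate, rtol=1e-9)
        q1 = baseline_ratio(r1, (0, 120))
        q2 = baseline_ratio(r2, (0, 120))
        np.testing.assert_allclose(q2.ratio, q1.ratio, rtol=1e-9)

    def test_time_shift_equivariance(self, rng):
        """Shifting timestamps shifts speed/rate values identically on
        interior samples."""
        t = np.arange(0, 200, 0.05)
        v_track = np.cumsum(rng.normal(0, 1, len(t)))
        p1 = _pos(t, v_track)
        p2 = _pos(t + 17.0, v_track)
        s1, s2 = instantaneous_speed(p1), instantaneous_speed(p2)
        np.testing.assert_allclose(s1.v, s2.v, rtol=1e-12)
        r1 = displacement_rate(s1, tau=20)
        r2 = displacement_rate(s2, tau=20)
        np.testing.assert_allclose(r1.rate, r2.rate, rtol=1e-12)

    def test_generated_session_ratio_normalisation(self, tiny_cohort_processed):
        """The ratio normalisation invariant holds for every limb of every
        generated session."""
        for ps in tiny_cohort_processed:
            for role, ratio in ps.ratios.items():
                mask = kin.baseline_divisor_mask(ratio.t, (0, 120), 30)
                assert ratio.ratio[mask].mean() == pytest.approx(1.0, abs=1e-9)
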