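"""Continuous-relative-phase pipeline: centering, Hilbert phase, folding,
windowing, transition screening and trial summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bimanual.crp import (
    EDGE_MARGIN_S,
    CRPSeries,
    analytic_signal,
    center_signal,
    crp,
    detect_phase_transition,
    extract_window,
    phase_angle,
    summarize_trial,
)
from bimanual.hkb import HKBParams
from bimanual.synth import Mode, TrialConfig, simulate_phase, synthesize_kinematics


def _interior(t, margin=EDGE_MARGIN_S):
    return (t >= t[0] + margin) & (t <= t[-1] - margin)


class TestCenterSignal:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([0.0, 1.0, 2.0], [-1.0, 0.0, 1.0]),
            ([5.0, 6.0], [-0.5, 0.5]),
        ],
    )
    def test_midrange_removal(self, x, expected):
        np.testing.assert_allclose(center_signal(np.array(x)), expected)

    def test_symmetric_signal_unchanged_and_offset_removed(self):
        t = np.arange(10_000) / 1000.0
        x = np.sin(2 * np.pi * t)  # whole cycles, already symmetric
        np.testing.assert_allclose(center_signal(x), x, atol=1e-12)
        np.testing.assert_allclose(center_signal(x + 5.0), x, atol=1e-12)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError):
            center_signal(np.ones(100))


class TestAnalyticSignal:
    def test_cos_to_sin_hilbert_pair(self, time_1khz_45s):
        t = time_1khz_45s[:30_000]
        x, H = analytic_signal(np.cos(2 * np.pi * t))
        m = _interior(t, 1.0)
        assert np.max(np.abs(H - np.sin(2 * np.pi * t))[m]) < 0.01

    def test_sin_to_minus_cos_hilbert_pair(self, time_1khz_45s):
        t = time_1khz_45s[:30_000]
        _, H = analytic_signal(np.sin(2 * np.pi * t))
        m = _interior(t, 1.0)
        assert np.max(np.abs(H + np.cos(2 * np.pi * t))[m]) < 0.01

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=256)
        _, H = analytic_signal(x)
        _, H3 = analytic_signal(3.0 * x)
        np.testing.assert_allclose(H3, 3.0 * H, rtol=1e-12, atol=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            analytic_signal(np.array([1.0, 2.0]))


class TestPhaseAngle:
    def test_quadrant_reference_values(self):
        ps = phase_angle(np.array([1.0, 0.0, -1.0]), np.array([0.0, 1.0, 0.0]))
        np.testing.assert_allclose(ps.phase, [0.0, np.pi / 2, np.pi], atol=1e-12)

    def test_recovers_generating_angle_and_slope(self):
        t = np.arange(20_000) / 1000.0
        theta = 2 * np.pi * 1.5 * t
        ps = phase_angle(np.cos(theta), np.sin(theta), t=t)
        np.testing.assert_allclose(ps.phase, theta, atol=1e-9)
        slope = np.polyfit(t, ps.phase, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 1.5, rel=1e-9)

    def test_scaling_invariance(self):
        t = np.arange(5_000) / 1000.0
        x = np.cos(2 * np.pi * 1.3 * t)
        H = np.sin(2 * np.pi * 1.3 * t)
        np.testing.assert_allclose(
            phase_angle(x, H).phase, phase_angle(4.2 * x, 4.2 * H).phase, atol=1e-9
        )

    def test_dead_samples_propagate_previous_angle(self):
        x = np.array([1.0, 0.0, 1.0, 1.0])
        H = np.array([0.0, 0.0, 0.0, 0.0])
        ps = phase_angle(x, H)
        assert ps.phase[1] == ps.phase[0]


class TestCRP:
    def test_identical_traces_give_zero(self, time_1khz_45s):
        y = 0.05 * np.sin(2 * np.pi * time_1khz_45s)
        series = crp(y, y, t=time_1khz_45s)
        m = _interior(time_1khz_45s)
        assert np.max(np.abs(series.crp_deg[m])) < 0.5

    def test_negated_traces_give_180(self, time_1khz_45s):
        y = 0.05 * np.sin(2 * np.pi * time_1khz_45s)
        series = crp(y, -y, t=time_1khz_45s)
        m = _interior(time_1khz_45s)
        assert np.max(np.abs(series.crp_deg[m] - 180.0)) < 0.5

    def test_quarter_cycle_lag_gives_90(self, time_1khz_45s):
        t = time_1khz_45s
        omega = 2 * np.pi
        series = crp(np.sin(omega * t), np.sin(omega * t - np.pi / 2), t=t)
        m = _interior(t)
        assert np.max(np.abs(series.crp_deg[m] - 90.0)) < 0.5

    def test_hand_swap_symmetry_after_folding(self):
        t = np.arange(20_000) / 1000.0
        x1 = np.sin(2 * np.pi * t) + 0.01 * np.sin(2 * np.pi * 1.7 * t)
        x2 = np.sin(2 * np.pi * t - 0.8)
        a = crp(x1, x2, t=t)
        b = crp(x2, x1, t=t)
        np.testing.assert_allclose(a.crp_deg, b.crp_deg, atol=1e-9)

    def test_amplitude_invariance(self):
        t = np.arange(10_000) / 1000.0
        x1 = np.sin(2 * np.pi * t)
        x2 = np.sin(2 * np.pi * t - 0.5)
        base = crp(x1, x2, t=t)
        scaled = crp(7.3 * x1, 0.2 * x2, t=t)
        np.testing.assert_allclose(scaled.crp_deg, base.crp_deg, atol=1e-9)

    @given(
        f1=st.floats(0.5, 2.0),
        f2=st.floats(0.5, 2.0),
        ph=st.floats(0, 6.28),
        amp=st.floats(0.1, 10.0),
    )
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_folded_range_property(self, f1, f2, ph, amp):
        """Folded CRP always lies in [0, 180] degrees."""
        t = np.arange(5_000) / 1000.0
        x1 = amp * np.sin(2 * np.pi * f1 * t)
        x2 = np.sin(2 * np.pi * f2 * t + ph) + 0.3 * np.sin(2 * np.pi * f1 * t)
        series = crp(x1, x2, t=t)
        assert np.all(series.crp_deg >= 0.0)
        assert np.all(series.crp_deg <= 180.0)


class TestWindowing:
    def test_default_window_sample_count(self, time_1khz_45s):
        y = np.sin(2 * np.pi * time_1khz_45s)
        series = crp(y, np.roll(y, 3), t=time_1khz_45s)
        w = extract_window(series, 12.0, 42.0)
        assert len(w.crp_deg) == 30_000
        assert w.t[0] >= 12.0 and w.t[-1] < 42.0

    def test_identity_window(self):
        t = np.arange(45_000) / 1000.0
        series = CRPSeries(t=t, crp_deg=np.zeros_like(t), valid=np.ones_like(t, bool))
        w = extract_window(series, 0.0, 45.0)
        assert len(w.crp_deg) == len(t)

    def test_short_trial_rejected(self):
        t = np.arange(40_000) / 1000.0
        series = CRPSeries(t=t, crp_deg=np.zeros_like(t), valid=np.ones_like(t, bool))
        with pytest.raises(ValueError):
            extract_window(series, 12.0, 42.0)


class TestPhaseTransitionDetector:
    def _series(self, values, fs=1000.0):
        t = np.arange(len(values)) / fs
        return CRPSeries(t=t, crp_deg=np.asarray(values, float),
                         valid=np.ones(len(values), bool))

    def test_steady_series_not_flagged(self):
        s = self._series(np.full(30_000, 175.0))
        assert detect_phase_transition(s, 180.0) is False

    def test_sustained_crossing_flagged(self):
        vals = np.concatenate([
            np.full(10_000, 178.0),
            np.linspace(178.0, 5.0, 5_000),
            np.full(15_000, 5.0),
        ])
        assert detect_phase_transition(self._series(vals), 180.0) is True

    def test_single_sample_spike_not_flagged(self):
        vals = np.full(30_000, 178.0)
        vals[15_000] = 0.0
        assert detect_phase_transition(self._series(vals), 180.0) is False

    def test_too_short_series_returns_false(self):
        s = self._series(np.full(100, 10.0))
        assert detect_phase_transition(s, 0.0, window_s=3.0) is False


class TestSummarizeTrial:
    def _make_trial(self, phi, mode, noise=0.0):
        cfg = TrialConfig(mode=mode, measurement_noise_m=noise)
        return synthesize_kinematics(np.broadcast_to(phi, cfg.n_samples).copy(), cfg)

    def test_noiseless_inphase_trial(self):
        s = summarize_trial(self._make_trial(0.0, Mode.IN_PHASE))
        assert s.mean_crp_deg == pytest.approx(0.0, abs=0.5)
        assert s.sd_crp_deg < 0.5
        assert not s.excluded

    def test_held_170_degree_trial(self):
        s = summarize_trial(self._make_trial(np.radians(170.0), Mode.ANTI_PHASE))
        assert s.mean_crp_deg == pytest.approx(170.0, abs=0.5)
        assert s.deviation_deg == pytest.approx(10.0, abs=0.5)

    def test_transitioned_trial_flagged_excluded(self):
        cfg = TrialConfig(mode=Mode.ANTI_PHASE, measurement_noise_m=0.0)
        t = np.arange(cfg.n_samples) / cfg.fs
        # phase walks from anti-phase to in-phase at 20 s and stays
        phi = np.where(t < 20.0, np.pi, 0.05)
        s = summarize_trial(synthesize_kinematics(phi, cfg))
        assert s.excluded

    def test_stochastic_variability_matches_ou_prediction(self, symmetric_params):
        """Phase variability around the anti-phase well tracks the linearized
        small-noise (Ornstein-Uhlenbeck) prediction sqrt(Q / (2 * curvature)).

        Two assertions: (i) the SD of the raw simulated phase matches the OU
        prediction; (ii) the pipeline's SD of *folded* CRP matches the
        folding-adjusted prediction sqrt(1 - 2/pi) times the raw SD — folding
        about 180 deg maps pi + eps to 180 - |eps|, which shrinks the SD by
        exactly that factor for fluctuations centered on the fold point.
        """
        from bimanual.hkb import predicted_sd, fixed_points

        Q = 0.005
        fp = [f for f in fixed_points(symmetric_params)
              if abs(f.phi_star - np.pi) < 1e-6][0]
        pred_deg = np.degrees(predicted_sd(symmetric_params, Q, fp))
        fold_factor = np.sqrt(1.0 - 2.0 / np.pi)
        raw_sds, crp_sds = [], []
        for seed in range(8):
            phi = simulate_phase(symmetric_params, Q, np.pi, fs=250,
                                 duration_s=45, seed=100 + seed)
            raw_sds.append(np.degrees(np.std(phi[250 * 12 :])))
            cfg = TrialConfig(mode=Mode.ANTI_PHASE, fs=250.0, measurement_noise_m=0.0)
            s = summarize_trial(synthesize_kinematics(phi, cfg))
            crp_sds.append(s.sd_crp_deg)
        assert np.mean(raw_sds) == pytest.approx(pred_deg, rel=0.25)
        assert np.mean(crp_sds) == pytest.approx(fold_factor * pred_deg, rel=0.25)


class TestRoundTrip:
    def test_noiseless_roundtrip_recovers_generating_phase(self):
        """CRP of rendered kinematics equals the generating phase (folded)
        within 1 degree RMS over the analysis window."""
        cfg = TrialConfig(mode=Mode.ANTI_PHASE, measurement_noise_m=0.0)
        t = np.arange(cfg.n_samples) / cfg.fs
        phi = np.pi - 0.3 * np.sin(2 * np.pi * 0.05 * t)  # slow drift around pi
        trial = synthesize_kinematics(phi, cfg)
        series = crp(trial.pos_right[:, 1], trial.pos_left[:, 1], t=trial.t)
        w = extract_window(series, 12.0, 42.0)
        mask = (t >= 12.0) & (t < 42.0)
        fold = np.degrees(np.abs(np.mod(phi[mask] + np.pi, 2 * np.pi) - np.pi))
        rms = np.sqrt(np.mean((w.crp_deg - fold) ** 2))
        assert rms < 1.0
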