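"""Synthetic-data generator: forward model, noise injection, cohorts."""

import numpy as np
import pytest

from neonirs import (
    CohortConfig,
    GroundTruth,
    forward_mbll,
    inject_artifacts_and_noise,
    simulate_cohort,
    simulate_subject,
)
from neonirs.synth import (
    DEFAULT_NOISE,
    default_region_correlation,
    trial_response,
)

NO_NOISE = {k: 0.0 for k in DEFAULT_NOISE}


def quiet_truth(**kw):
    kw.setdefault("noise_params", dict(NO_NOISE))
    return GroundTruth(**kw)


class TestSimulateSubject:
    def test_zero_amplitudes_zero_output(self, layout, social_schedule):
        truth = quiet_truth(amplitude_map={})
        sub = simulate_subject(layout, social_schedule, truth)
        assert np.all(sub.hbo == 0) and np.all(sub.hbr == 0)

    def test_habituation_ordering_of_planted_peaks(self, layout, hand_schedule):
        amps = {ch: 0.0 for ch in range(18)}
        amap = {
            "Fam1": np.where(np.isin(np.arange(1, 19), (4, 7)), 1.0, 0.0),
            "Fam3": np.where(np.isin(np.arange(1, 19), (4, 7)), 0.3, 0.0),
        }
        truth = quiet_truth(amplitude_map=amap)
        sub = simulate_subject(layout, hand_schedule, truth)
        fs = sub.fs
        ch = np.flatnonzero(np.isin(layout.channel_id, (4, 7)))

        def epoch_peak(phase):
            idx = [i for i, t in enumerate(hand_schedule.trials) if t.phase == phase]
            peaks = []
            for i in idx:
                a = int(hand_schedule.trials[i].onset * fs)
                peaks.append(sub.hbo[a : a + 200, ch].max())
            return np.mean(peaks)

        assert epoch_peak("Fam1") > epoch_peak("Fam3")

    def test_hbr_opposite_sign(self, layout, social_schedule):
        truth = quiet_truth(amplitude_map={"N": np.full(18, 1.0), "V": np.full(18, 1.0)})
        sub = simulate_subject(layout, social_schedule, truth)
        # at the HbO peak, HbR is negative with ~1/3 magnitude
        i = np.argmax(sub.hbo[:, 0])
        assert sub.hbr[i, 0] < 0
        assert 0.2 < -sub.hbr[i, 0] / sub.hbo[i, 0] < 0.5

    def test_planted_amplitude_is_peak_hbo(self, layout, hand_schedule):
        truth = quiet_truth(amplitude_map={"Fam1": np.full(18, 0.8)})
        sub = simulate_subject(layout, hand_schedule, truth)
        assert sub.hbo.max() == pytest.approx(0.8, rel=1e-6)

    def test_fc_latent_correlations_recovered(self, layout, fc_schedule):
        # empirical ROI correlations within +-0.1 of targets, mean over seeds
        from neonirs.connectivity import roi_average

        C = default_region_correlation()
        C[1, 3] = C[3, 1] = 0.75
        C[0, 2] = C[2, 0] = 0.0
        errs = []
        for seed in range(20):
            truth = quiet_truth(region_correlation=C, seed=seed)
            sub = simulate_subject(layout, fc_schedule, truth)
            roi = roi_average(sub.hbo, layout)
            r = np.corrcoef(roi.T)
            errs.append(np.abs(r - C).max())
        assert np.mean(errs) < 0.1

    def test_non_psd_correlation_rejected(self):
        C = np.eye(4)
        C[0, 1] = C[1, 0] = 0.9
        C[1, 2] = C[2, 1] = 0.9
        C[0, 2] = C[2, 0] = -0.9
        with pytest.raises(ValueError, match="positive semi-definite"):
            GroundTruth(region_correlation=C)

    def test_trial_response_peak_time(self):
        # boxcar-convolved HRF peaks after the 7 s HRF peak, within the trial
        resp = trial_response(10.0, 8.0, 7.0, 1 / 6, 250)
        peak = np.argmax(resp) / 10.0
        assert 8.0 < peak < 14.0


class TestInjectArtifacts:
    def test_identity_with_no_noise_no_events(self, layout, social_schedule):
        truth = quiet_truth(amplitude_map={"N": np.full(18, 1.0)})
        sub = simulate_subject(layout, social_schedule, truth)
        noisy = inject_artifacts_and_noise(sub)
        np.testing.assert_array_equal(noisy.hbo, sub.hbo)
        np.testing.assert_array_equal(noisy.hbr, sub.hbr)

    def test_spike_raises_local_derivative(self, layout, social_schedule):
        exceed = 0
        for seed in range(20):
            truth = quiet_truth(
                amplitude_map={"N": np.full(18, 0.5), "V": np.full(18, 0.5)},
                artifact_events=[(100.0, "spike", 5.0)],
                seed=seed,
                noise_params={**NO_NOISE, "white": 0.02},
            )
            sub = simulate_subject(layout, social_schedule, truth)
            noisy = inject_artifacts_and_noise(sub)
            d = np.abs(np.diff(noisy.hbo[:, 0]))
            t = np.arange(len(d)) / sub.fs
            window = (t >= 99.5) & (t <= 100.5)
            exceed += d[window].max() > d[~window].max()
        assert exceed >= 18

    def test_shift_changes_level(self, layout, social_schedule):
        truth = quiet_truth(amplitude_map={}, artifact_events=[(60.0, "shift", 2.0)])
        sub = simulate_subject(layout, social_schedule, truth)
        noisy = inject_artifacts_and_noise(sub)
        i = int(60.0 * sub.fs)
        assert noisy.hbo[i + 5, 0] - noisy.hbo[i - 5, 0] == pytest.approx(2.0)

    def test_event_outside_span_rejected(self, layout, social_schedule):
        truth = quiet_truth(amplitude_map={}, artifact_events=[(1e5, "spike", 1.0)])
        sub = simulate_subject(layout, social_schedule, truth)
        with pytest.raises(ValueError, match="outside span"):
            inject_artifacts_and_noise(sub)

    def test_bad_channel_has_no_cardiac_coupling(self, layout, social_schedule):
        """Two-wavelength cardiac-band correlation is low on bad channels."""
        from neonirs.quality import QualityParams, windowed_sci_psp

        scis = []
        for seed in range(10):
            truth = GroundTruth(
                amplitude_map={}, bad_channels=frozenset({3}), seed=seed
            )
            sub = simulate_subject(layout, social_schedule, truth)
            rec = forward_mbll(inject_artifacts_and_noise(sub))
            sci, _ = windowed_sci_psp(rec, QualityParams())
            bad_idx = int(np.flatnonzero(layout.channel_id == 3)[0])
            scis.append(np.median(sci[bad_idx]))
        assert np.median(scis) < 0.2


class TestForwardMbll:
    def test_zero_hb_constant_intensity(self, layout, social_schedule):
        truth = quiet_truth(amplitude_map={})
        sub = simulate_subject(layout, social_schedule, truth)
        rec = forward_mbll(sub, i0=2.5)
        assert np.allclose(rec.intensity, 2.5)

    def test_round_trip_recovers_planted_hb(self, layout, social_schedule):
        from neonirs.preprocess import intensity_to_od, od_to_hb
        from neonirs.optics import OpticalConstants

        truth = quiet_truth(
            amplitude_map={"N": np.full(18, 1.2), "V": np.full(18, 0.4)}
        )
        sub = simulate_subject(layout, social_schedule, truth)
        optics = OpticalConstants()
        rec = forward_mbll(sub, optics)
        hb = od_to_hb(intensity_to_od(rec), rec.fs, optics)
        # OD uses a mean reference, so recovery is up to a per-channel constant
        got = hb.hbo - hb.hbo.mean(axis=0)
        want = sub.hbo - sub.hbo.mean(axis=0)
        scale = np.abs(want).max()
        assert np.abs(got - want).max() / scale < 1e-10

    def test_dpf_values(self):
        from neonirs.optics import DPF

        assert DPF[780.0] == 5.22
        assert DPF[850.0] == 4.23

    def test_invalid_i0(self, layout, social_schedule):
        sub = simulate_subject(layout, social_schedule, quiet_truth(amplitude_map={}))
        with pytest.raises(ValueError, match="I0"):
            forward_mbll(sub, i0=0.0)


class TestSimulateCohort:
    def test_determinism(self):
        a = simulate_cohort(2, CohortConfig(), master_seed=42, paradigms=("social",))
        b = simulate_cohort(2, CohortConfig(), master_seed=42, paradigms=("social",))
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(
                sa.recordings["social"].intensity, sb.recordings["social"].intensity
            )
        c = simulate_cohort(2, CohortConfig(), master_seed=43, paradigms=("social",))
        assert not np.array_equal(
            a[0].recordings["social"].intensity, c[0].recordings["social"].intensity
        )

    def test_planted_habituation_mean(self):
        # law of large numbers on the planted Fam1 - Fam3 amplitudes
        subs = simulate_cohort(
            30, CohortConfig(habituation=(0.7, 0.3)), master_seed=0, paradigms=()
        )
        ch4 = 3  # 0-based index of channel 4
        diffs = [
            s.truth.amplitude_map["Fam1"][ch4] - s.truth.amplitude_map["Fam3"][ch4]
            for s in subs
        ]
        se = 0.3 / np.sqrt(30)
        assert abs(np.mean(diffs) - 0.7) < 3 * se

    def test_null_cohort_has_no_planted_effects(self):
        subs = simulate_cohort(
            1,
            CohortConfig(habituation=(0.0, 0.0), n_amp=(0.0, 0.0), v_amp=(0.0, 0.0),
                         fam1_amp=(0.0, 0.0)),
            master_seed=0,
            paradigms=(),
        )
        t = subs[0].truth
        assert all(np.all(v == 0) for v in t.amplitude_map.values())

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            simulate_cohort(0)
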