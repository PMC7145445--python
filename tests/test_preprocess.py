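"""Preprocessing chain: filter, epoch, detrend, MBLL, rejection, averaging."""

import warnings

import numpy as np
import pytest

from babelnirs.config import Participant, PreprocessParams, StudyDesign
from babelnirs.preprocess import (
    AttenuationEpoch, ConcentrationEpoch, apply_looking_criterion,
    average_conditions, detrend_epoch, lowpass_filter, lowpass_gain,
    mbll_inverse, preprocess_recording, rereference_to_baseline,
    reject_trials, segment_epochs,
)
from babelnirs.simulate import forward_beer_lambert
from babelnirs.univariate import extract_peaks

PARAMS = PreprocessParams()
FS = 10.0


class TestLowpassFilter:
    def test_constant_signal_unchanged(self):
        s = np.full(500, 3.7)
        assert np.allclose(lowpass_filter(s, 1.7, FS), s)

    def test_3hz_sinusoid_strongly_attenuated(self):
        t = np.arange(2000) / FS
        s = np.sin(2 * np.pi * 3.0 * t)
        out = lowpass_filter(s, 1.7, FS)
        # steady-state amplitude (edges excluded) vs the analytic response
        mid = out[500:1500]
        gain = lowpass_gain(3.0, 1.7, FS)
        assert np.abs(mid).max() < 0.1
        assert np.abs(mid).max() == pytest.approx(gain, rel=0.05)

    def test_cardiac_band_attenuation_exceeds_20db(self):
        assert lowpass_gain(2.4, 1.7, FS) < 10 ** (-20 / 20)

    def test_passband_signal_preserved(self):
        t = np.arange(2000) / FS
        s = np.sin(2 * np.pi * 0.1 * t)
        out = lowpass_filter(s, 1.7, FS)
        assert np.allclose(out[200:-200], s[200:-200], atol=0.01)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            lowpass_filter(np.ones(100), 5.0, FS)


class TestSegmentEpochs:
    def test_cardinality_and_geometry(self, noisy_recording):
        rec, _ = noisy_recording
        epochs = segment_epochs(rec)
        assert len(epochs) == 20
        for ep in epochs:
            assert ep.data.shape[-1] == 240  # 24 s at 10 Hz
            assert ep.times[0] == pytest.approx(-4.0)
            assert ep.times[-1] == pytest.approx(20.0 - 0.1)  # half-open
            assert ep.looking_proportion is not None

    def test_edge_event_dropped_with_warning(self, noisy_recording):
        rec, _ = noisy_recording
        rec2 = type(rec)(
            participant=rec.participant,
            intensity=rec.intensity[:, :, :int(rec.events[-1][0] * 10) + 50],
            events=rec.events,
            looking_proportion=rec.looking_proportion,
            channel_ids=rec.channel_ids,
        )
        with pytest.warns(UserWarning, match="dropped"):
            epochs = segment_epochs(rec2)
        assert len(epochs) == 19


def _epoch_from(data):
    n = data.shape[-1]
    return AttenuationEpoch(
        data=data, times=np.arange(-40, n - 40) / FS,
        condition="English", looking_proportion=1.0,
        participant_id="p1", trial_index=0,
        channel_ids=list(range(1, data.shape[0] + 1)),
    )


class TestDetrendEpoch:
    def test_ramp_anchors_zeroed(self):
        data = np.linspace(0, 5, 240)[None, None, :]
        out = detrend_epoch(_epoch_from(data))
        assert out.data[..., :40].mean() == pytest.approx(0.0, abs=1e-12)
        assert out.data[..., -40:].mean() == pytest.approx(0.0, abs=1e-12)

    def test_constant_maps_to_zero(self):
        out = detrend_epoch(_epoch_from(np.full((1, 1, 240), 2.5)))
        assert np.allclose(out.data, 0.0)

    def test_matches_hand_built_anchor_line(self):
        # 6-sample toy at 1 Hz with 2-s anchors, line computed by hand
        y = np.array([1.0, 3.0, 10.0, -2.0, 5.0, 7.0])
        ep = AttenuationEpoch(
            data=y[None, None, :], times=np.arange(6.0), condition="c",
            looking_proportion=1.0, participant_id="p", trial_index=0,
            channel_ids=[1],
        )
        out = detrend_epoch(ep, anchor_s=2.0, sampling_rate_hz=1.0)
        m1, m2 = 2.0, 6.0        # means of first/last two samples
        t1, t2 = 0.5, 4.5        # anchor-window centers
        line = m1 + (m2 - m1) / (t2 - t1) * (np.arange(6.0) - t1)
        assert np.allclose(out.data[0, 0], y - line)

    def test_hrf_on_ramp_recovers_hrf_minus_anchor_line(self):
        from babelnirs.simulate import simulate_hrf
        hrf = np.concatenate([np.zeros(40), simulate_hrf(20, 10, 1.0)])
        ramp = 0.3 * np.arange(240) / FS
        out = detrend_epoch(_epoch_from((hrf + ramp)[None, None, :]))
        # independently build the anchor line of the HRF alone
        t = np.arange(-40, 200) / FS
        m1, m2 = hrf[:40].mean(), hrf[-40:].mean()
        t1, t2 = t[:40].mean(), t[-40:].mean()
        line = m1 + (m2 - m1) / (t2 - t1) * (t - t1)
        assert np.allclose(out.data[0, 0], hrf - line, atol=1e-10)


class TestMbllInverse:
    def test_zero_attenuation_zero_concentration(self):
        ep = _epoch_from(np.zeros((3, 2, 240)))
        conc = mbll_inverse(ep, PARAMS.extinction)
        assert not conc.data.any()

    def test_inverse_of_forward_model(self):
        rng = np.random.default_rng(0)
        hbo2 = rng.normal(size=(4, 240))
        hhb = rng.normal(size=(4, 240))
        atten = forward_beer_lambert(hbo2, hhb, PARAMS.extinction)
        ep = _epoch_from(np.transpose(atten, (1, 0, 2)))
        conc = mbll_inverse(ep, PARAMS.extinction)
        assert np.allclose(conc.data[:, 0], hbo2, rtol=1e-9, atol=1e-12)
        assert np.allclose(conc.data[:, 1], hhb, rtol=1e-9, atol=1e-12)

    def test_singular_matrix_rejected(self):
        bad = {770.0: {"hbo2": 1.0, "hhb": 1.0}, 850.0: {"hbo2": 1.0, "hhb": 1.0}}
        with pytest.raises(ValueError, match="singular"):
            mbll_inverse(_epoch_from(np.zeros((1, 2, 240))), bad)

    def test_commutes_with_detrend(self):
        # both operations are linear on disjoint axes, so order is irrelevant
        rng = np.random.default_rng(3)
        ep = _epoch_from(rng.normal(size=(2, 2, 240)))
        a = mbll_inverse(detrend_epoch(ep), PARAMS.extinction).data
        b = detrend_epoch(
            _epoch_from(mbll_inverse(ep, PARAMS.extinction).data)
        ).data
        assert np.allclose(a, b, atol=1e-12)


def _conc_epoch(data, condition="English", looking=1.0, trial=0):
    n = data.shape[-1]
    return ConcentrationEpoch(
        data=data, times=np.arange(-40, n - 40) / FS, condition=condition,
        looking_proportion=looking, participant_id="p1", trial_index=trial,
        channel_ids=list(range(1, data.shape[0] + 1)),
    )


class TestRejectTrials:
    def test_flat_epoch_valid_everywhere(self):
        eps = reject_trials([_conc_epoch(np.zeros((4, 2, 240)))])
        assert eps[0].valid.all()

    def test_stimulus_excursion_invalidates_only_that_channel(self):
        data = np.zeros((4, 2, 240))
        data[2, 0, 40 + 50] = 6.0  # +6 umol at t = 5 s
        eps = reject_trials([_conc_epoch(data)])
        assert list(eps[0].valid) == [True, True, False, True]

    def test_exact_threshold_remains_valid(self):
        data = np.zeros((1, 2, 240))
        data[0, 0, 40 + 50] = 5.0  # exactly +-5 during stimulus
        data[0, 1, 10] = -3.0      # exactly +-3 during baseline
        eps = reject_trials([_conc_epoch(data)])
        assert eps[0].valid.all()

    def test_baseline_threshold_is_tighter(self):
        data = np.zeros((1, 2, 240))
        data[0, 0, 10] = 3.5  # within +-5 but beyond +-3, in the baseline
        eps = reject_trials([_conc_epoch(data)])
        assert not eps[0].valid[0]

    def test_post_stimulus_window_not_screened(self):
        data = np.zeros((1, 2, 240))
        data[0, 0, 40 + 150] = 9.0  # t = 15 s, after the stimulus window
        eps = reject_trials([_conc_epoch(data)])
        assert eps[0].valid.all()


class TestLookingCriterion:
    def test_boundary_at_60_percent(self):
        eps = [_conc_epoch(np.zeros((1, 2, 240)), looking=p, trial=i)
               for i, p in enumerate([0.59, 0.60])]
        kept = apply_looking_criterion(eps)
        assert [e.looking_proportion for e in kept] == [0.60]

    def test_full_attention_keeps_all(self):
        eps = [_conc_epoch(np.zeros((1, 2, 240)), trial=i) for i in range(5)]
        assert len(apply_looking_criterion(eps)) == 5

    def test_mixed_fixture_counts(self):
        props = [0.9, 0.5, 0.95, 0.3, 1.0, 0.55, 0.8, 0.7, 0.1, 0.65]
        eps = [_conc_epoch(np.zeros((1, 2, 240)), looking=p, trial=i)
               for i, p in enumerate(props)]
        assert len(apply_looking_criterion(eps)) == 6

    def test_missing_proportion_dropped_with_warning(self):
        eps = [_conc_epoch(np.zeros((1, 2, 240)), looking=None)]
        with pytest.warns(UserWarning, match="missing"):
            assert apply_looking_criterion(eps) == []


class TestAverageConditions:
    design = StudyDesign()
    participant = Participant("p1", "monolingual")

    def _epochs(self, n_per_condition):
        eps = []
        trial = 0
        for cond, n in n_per_condition.items():
            for _ in range(n):
                eps.append(_conc_epoch(np.zeros((4, 2, 240)), condition=cond,
                                       trial=trial))
                trial += 1
        return eps

    def test_five_trials_each_included(self):
        avgs = average_conditions(
            self._epochs({"English": 5, "French": 5, "BSL": 5, "LSFB": 5}),
            self.participant, self.design,
        )
        flags = {a.key: a.included for a in avgs}
        assert all(flags.values())

    def test_paired_exclusion_within_modality(self):
        avgs = average_conditions(
            self._epochs({"English": 2, "French": 5, "BSL": 5, "LSFB": 5}),
            self.participant, self.design,
        )
        flags = {a.key: a.included for a in avgs if a.kind == "condition"}
        assert not flags["English"] and not flags["French"]
        assert flags["BSL"] and flags["LSFB"]

    def test_modality_inclusion_pools_conditions(self):
        # 2 + 2 spoken trials: both conditions excluded, but the spoken
        # modality pools 4 >= 3 valid trials and stays included
        avgs = average_conditions(
            self._epochs({"English": 2, "French": 2, "BSL": 5, "LSFB": 5}),
            self.participant, self.design,
        )
        modality = {a.key: a.included for a in avgs if a.kind == "modality"}
        assert modality["spoken"] and modality["signed"]

    def test_modality_below_three_excluded(self):
        avgs = average_conditions(
            self._epochs({"English": 1, "French": 1, "BSL": 5, "LSFB": 5}),
            self.participant, self.design,
        )
        modality = {a.key: a.included for a in avgs if a.kind == "modality"}
        assert not modality["spoken"]

    def test_channel_mean_uses_only_channelwise_valid_trials(self):
        eps = self._epochs({"English": 3, "French": 3, "BSL": 3, "LSFB": 3})
        for i, ep in enumerate(e for e in eps if e.condition == "English"):
            ep.data[:] = float(i + 1)
        # invalidate channel 0 of the third English trial: mean 1.5 vs 2.0
        english = [e for e in eps if e.condition == "English"]
        english[2].valid[0] = False
        avgs = average_conditions(eps, self.participant, self.design)
        eng = next(a for a in avgs if a.key == "English")
        assert eng.data[0, 0, 0] == pytest.approx(1.5)
        assert eng.data[1, 0, 0] == pytest.approx(2.0)
        assert eng.n_valid_trials[0] == 2 and eng.n_valid_trials[1] == 3


class TestEndToEndLosslessness:
    def test_noise_free_recovery_of_injected_peak(self, config, silent_recording):
        """The full chain recovers the injected 1.5 umol peak.

        The only residual distortion is the two-point detrend's interaction
        with the undecayed response tail (~2%); see docs/methods.md.
        """
        rec, truth = silent_recording
        avgs = preprocess_recording(rec, config.preprocess, None,
                                    config.montage, config.design)
        assert all(a.included for a in avgs)
        peaks = extract_peaks(avgs)
        sub = peaks[(peaks.kind == "condition") & (peaks.chromophore == "hbo2")]
        injected = 1.5  # pipeline-free oracle: curve max = injected amplitude
        assert sub.peak_amplitude.mean() == pytest.approx(injected, rel=0.05)
        hhb = peaks[(peaks.kind == "condition") & (peaks.chromophore == "hhb")]
        assert hhb.peak_amplitude.mean() == pytest.approx(-0.5, rel=0.08)

    def test_noise_free_no_trial_rejection(self, config, silent_recording):
        rec, _ = silent_recording
        avgs = preprocess_recording(rec, config.preprocess, None,
                                    config.montage, config.design)
        for a in avgs:
            if a.kind == "condition":
                assert (a.n_valid_trials == 5).all()

    def test_valid_trials_non_increasing_through_rejection(self, config,
                                                           noisy_recording):
        rec, _ = noisy_recording
        from babelnirs.preprocess import lowpass_filter as lpf
        filtered = lpf(rec.intensity, 1.7, 10.0)
        epochs_att = segment_epochs(rec, prefiltered=filtered)
        epochs = [
            rereference_to_baseline(
                mbll_inverse(detrend_epoch(ep), PARAMS.extinction)
            )
            for ep in epochs_att
        ]
        n0 = len(epochs)
        after_looking = apply_looking_criterion(epochs)
        n1 = len(after_looking)
        after_reject = reject_trials(after_looking)
        n2 = sum(ep.valid.all() for ep in after_reject)
        assert n0 >= n1 >= n2
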