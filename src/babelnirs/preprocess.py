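"""Hemodynamic preprocessing: filter, epoch, detrend, convert, reject, average.

The processing order follows the acquisition-to-analysis path for
continuous-wave fNIRS:

1. low-pass filter the intensity signal (1.7 Hz zero-phase Butterworth,
   removing cardiac oscillation and instrumentation noise);
2. convert to attenuation change and segment into 24-s blocks spanning 4 s
   of pre-stimulus baseline, the nominal 10-s stimulus, and the following
   10-s baseline;
3. de-trend each block with the line through the means of its first and
   last 4 s (removing slow drifts and trial-to-trial build-up);
4. convert attenuation to HbO2/HHb concentration changes (umol) with the
   modified Beer-Lambert law (DPF 5.13, 2 cm separation);
5. reject trials per channel when concentration changes exceed +-3 umol in
   the pre-stimulus baseline or +-5 umol during the stimulus;
6. keep only trials with >= 60% looking time, and average the survivors
   into per-participant condition and modality curves, requiring at least
   three valid trials per included condition (and per modality), with
   paired exclusion of the other condition of the same modality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .config import Montage, Participant, PreprocessParams, StudyDesign
from .qc import ChannelQCReport
from .recording import RawRecording
from .simulate import extinction_matrix


def lowpass_filter(x: np.ndarray, cutoff_hz: float,
                   sampling_rate_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter along the last axis.

    Forward-backward application doubles the effective order and removes
    phase distortion; DC gain is exactly 1.
    """
    nyquist = sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) Hz"
        )
    sos = sp_signal.butter(order, cutoff_hz, btype="low",
                           fs=sampling_rate_hz, output="sos")
    return sp_signal.sosfiltfilt(sos, np.asarray(x, float), axis=-1)


def lowpass_gain(freq_hz: float, cutoff_hz: float, sampling_rate_hz: float,
                 order: int = 4) -> float:
    """Analytic magnitude response of the zero-phase filter at one frequency."""
    sos = sp_signal.butter(order, cutoff_hz, btype="low",
                           fs=sampling_rate_hz, output="sos")
    _, h = sp_signal.sosfreqz(sos, worN=[freq_hz], fs=sampling_rate_hz)
    return float(np.abs(h[0]) ** 2)  # squared: forward + backward pass


def intensity_to_attenuation(intensity: np.ndarray) -> np.ndarray:
    """Attenuation change relative to the session mean: -ln(I / mean(I))."""
    intensity = np.asarray(intensity, float)
    ref = intensity.mean(axis=-1, keepdims=True)
    if np.any(ref <= 0):
        raise ValueError("non-positive mean intensity")
    return -np.log(np.maximum(intensity, 1e-300) / ref)


@dataclass
class AttenuationEpoch:
    """One 24-s attenuation block: channel x wavelength x 240 samples.

    The onset-relative time axis is half-open, [-4, 20) s at 10 Hz.
    """

    data: np.ndarray  # (n_channels, n_wavelengths, n_samples)
    times: np.ndarray  # onset-relative, seconds
    condition: str
    looking_proportion: float | None
    participant_id: str
    trial_index: int
    channel_ids: list[int]


@dataclass
class ConcentrationEpoch:
    """Chromophore concentration block: channel x {HbO2, HHb} x time, umol."""

    data: np.ndarray  # (n_channels, 2, n_samples); axis 1 = (hbo2, hhb)
    times: np.ndarray
    condition: str
    looking_proportion: float | None
    participant_id: str
    trial_index: int
    channel_ids: list[int]
    valid: np.ndarray = field(default=None)  # per-channel validity mask

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.data.shape[0], dtype=bool)


def segment_epochs(
    rec: RawRecording,
    window_s: tuple[float, float] = (-4.0, 20.0),
    prefiltered: np.ndarray | None = None,
) -> list[AttenuationEpoch]:
    """Cut the session attenuation into one onset-locked block per event.

    ``prefiltered`` may supply an already low-pass-filtered intensity array;
    otherwise the recording's raw intensity is used.  Events too close to a
    recording edge are dropped with a warning, not an error.
    """
    fs = rec.sampling_rate_hz
    atten = intensity_to_attenuation(
        rec.intensity if prefiltered is None else prefiltered
    )
    n = atten.shape[-1]
    lo = int(round(window_s[0] * fs))
    hi = int(round(window_s[1] * fs))
    epochs = []
    for k, (onset, condition) in enumerate(rec.events):
        i0 = int(round(onset * fs))
        if i0 + lo < 0 or i0 + hi > n:
            warnings.warn(
                f"trial {k} ({condition}) at {onset:.1f} s too close to the "
                "recording edge; epoch dropped"
            )
            continue
        looking = (rec.looking_proportion[k]
                   if k < len(rec.looking_proportion) else None)
        epochs.append(AttenuationEpoch(
            data=atten[:, :, i0 + lo:i0 + hi].copy(),
            times=np.arange(lo, hi) / fs,
            condition=condition,
            looking_proportion=looking,
            participant_id=rec.participant.participant_id,
            trial_index=k,
            channel_ids=list(rec.channel_ids),
        ))
    return epochs


def detrend_epoch(epoch: AttenuationEpoch,
                  anchor_s: float = 4.0,
                  sampling_rate_hz: float = 10.0) -> AttenuationEpoch:
    """Remove the line through the means of the first and last ``anchor_s``.

    After detrending, the mean of the first 4 s and the mean of the last
    4 s are both exactly zero; what is subtracted is the straight line
    through the two window-mean anchor points (evaluated at the window
    centers).
    """
    n_anchor = int(round(anchor_s * sampling_rate_hz))
    t = epoch.times
    data = epoch.data
    m1 = data[..., :n_anchor].mean(axis=-1, keepdims=True)
    m2 = data[..., -n_anchor:].mean(axis=-1, keepdims=True)
    t1 = t[:n_anchor].mean()
    t2 = t[-n_anchor:].mean()
    slope = (m2 - m1) / (t2 - t1)
    line = m1 + slope * (t - t1)
    return AttenuationEpoch(
        data=data - line,
        times=t,
        condition=epoch.condition,
        looking_proportion=epoch.looking_proportion,
        participant_id=epoch.participant_id,
        trial_index=epoch.trial_index,
        channel_ids=epoch.channel_ids,
    )


def mbll_inverse(
    epoch: AttenuationEpoch,
    extinction: dict[float, dict[str, float]],
    dpf: float = 5.13,
    separation_cm: float = 2.0,
) -> ConcentrationEpoch:
    """Solve the two-wavelength modified Beer-Lambert system per time point.

    Inverts ``dA = E @ dC * 1e-3 * d * DPF`` for ``dC = (HbO2, HHb)`` in
    umol, where ``E`` is the 2x2 extinction matrix (mM^-1 cm^-1), ``d`` the
    source-detector separation in cm.  Exact inverse of the generator's
    forward model.
    """
    E = extinction_matrix(extinction)
    det = np.linalg.det(E)
    if abs(det) < 1e-12:
        raise ValueError("extinction matrix is singular")
    scale = 1e-3 * separation_cm * dpf
    inv = np.linalg.inv(E) / scale
    # data: (ch, wl, t) -> conc: (ch, chromophore, t)
    conc = np.einsum("cw,nwt->nct", inv, epoch.data)
    return ConcentrationEpoch(
        data=conc,
        times=epoch.times,
        condition=epoch.condition,
        looking_proportion=epoch.looking_proportion,
        participant_id=epoch.participant_id,
        trial_index=epoch.trial_index,
        channel_ids=epoch.channel_ids,
    )


def rereference_to_baseline(epoch: ConcentrationEpoch) -> ConcentrationEpoch:
    """Reference concentrations to the pre-stimulus 4-s mean (per channel)."""
    baseline = epoch.times < 0
    epoch.data = epoch.data - epoch.data[..., baseline].mean(axis=-1, keepdims=True)
    return epoch


def reject_trials(
    epochs: list[ConcentrationEpoch],
    baseline_threshold_umol: float = 3.0,
    stimulus_threshold_umol: float = 5.0,
    stimulus_window_s: tuple[float, float] = (0.0, 10.0),
) -> list[ConcentrationEpoch]:
    """Flag motion-contaminated trials per channel (strict thresholds).

    A channel's trial is invalid iff, for either chromophore, |dC| exceeds
    ``baseline_threshold_umol`` anywhere in the pre-stimulus baseline
    [-4, 0) s or ``stimulus_threshold_umol`` anywhere in the stimulus window
    [0, 10) s.  Comparisons are strict ("greater than"), so an excursion of
    exactly the threshold remains valid.  Masks are combined with any
    pre-existing validity mask.
    """
    for ep in epochs:
        base = ep.times < 0
        stim = (ep.times >= stimulus_window_s[0]) & (ep.times < stimulus_window_s[1])
        over_base = (np.abs(ep.data[..., base]) > baseline_threshold_umol).any(
            axis=(1, 2)
        )
        over_stim = (np.abs(ep.data[..., stim]) > stimulus_threshold_umol).any(
            axis=(1, 2)
        )
        ep.valid = ep.valid & ~(over_base | over_stim)
    return epochs


def apply_looking_criterion(
    epochs: list[ConcentrationEpoch], threshold: float = 0.6
) -> list[ConcentrationEpoch]:
    """Keep trials watched for at least ``threshold`` of their duration.

    Trials with a missing looking proportion are dropped with a warning.
    """
    kept = []
    for ep in epochs:
        if ep.looking_proportion is None:
            warnings.warn(
                f"trial {ep.trial_index} ({ep.participant_id}): missing "
                "looking proportion; trial dropped"
            )
            continue
        if ep.looking_proportion >= threshold:
            kept.append(ep)
    return kept


@dataclass
class ConditionAverage:
    """Per-participant mean curve for one condition or one modality."""

    participant_id: str
    key: str  # condition name or modality name
    kind: str  # "condition" | "modality"
    data: np.ndarray  # (n_channels, 2, n_samples); NaN where unavailable
    times: np.ndarray
    n_valid_trials: np.ndarray  # per channel
    included: bool
    channel_ids: list[int]


def _overall_trial_valid(ep: ConcentrationEpoch, channel_ok: np.ndarray,
                         rule: float) -> bool:
    """Trial-level validity: valid in at least ``rule`` of retained channels."""
    n_ok = int(channel_ok.sum())
    if n_ok == 0:
        return False
    return (ep.valid & channel_ok).sum() >= rule * n_ok


def average_conditions(
    epochs: list[ConcentrationEpoch],
    participant: Participant,
    design: StudyDesign,
    qc_report: ChannelQCReport | None = None,
    min_valid_trials: int = 3,
    trial_validity_rule: float = 0.5,
) -> list[ConditionAverage]:
    """Average valid trials into condition- and modality-level curves.

    Channel means use only trials valid in that channel; QC-rejected
    channels are NaN throughout.  A condition is included when it has at
    least ``min_valid_trials`` overall-valid trials AND so does the other
    condition of its modality (paired exclusion); a modality average is
    included when the modality pools at least ``min_valid_trials``
    overall-valid trials.
    """
    if not epochs:
        return []
    channel_ids = epochs[0].channel_ids
    n_ch = len(channel_ids)
    channel_ok = np.ones(n_ch, dtype=bool)
    if qc_report is not None:
        rejected = set(qc_report.rejected_channels)
        channel_ok = np.array([cid not in rejected for cid in channel_ids])

    def collect(eps: list[ConcentrationEpoch]) -> tuple[np.ndarray, np.ndarray]:
        shape = (n_ch, 2, epochs[0].data.shape[-1])
        mean = np.full(shape, np.nan)
        n_valid = np.zeros(n_ch, dtype=int)
        if eps:
            stack = np.stack([e.data for e in eps])  # trial x ch x chrom x t
            mask = np.stack([e.valid for e in eps])  # trial x ch
            n_valid = mask.sum(axis=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                weights = mask[:, :, None, None]
                total = (stack * weights).sum(axis=0)
                mean = np.where(
                    n_valid[:, None, None] > 0,
                    total / np.maximum(n_valid, 1)[:, None, None],
                    np.nan,
                )
        mean[~channel_ok] = np.nan
        n_valid = np.where(channel_ok, n_valid, 0)
        return mean, n_valid

    by_condition = {c: [] for c in design.conditions}
    for ep in epochs:
        by_condition.setdefault(ep.condition, []).append(ep)

    n_overall = {
        c: sum(
            _overall_trial_valid(ep, channel_ok, trial_validity_rule)
            for ep in by_condition[c]
        )
        for c in design.conditions
    }
    included = {c: n_overall[c] >= min_valid_trials for c in design.conditions}
    # paired exclusion: dropping one condition drops its modality partner
    for c in design.conditions:
        partners = [
            o for o in design.conditions_of(design.modality(c)) if o != c
        ]
        if not all(included[o] for o in partners):
            included[c] = False

    out = []
    times = epochs[0].times
    for c in design.conditions:
        mean, n_valid = collect(by_condition[c])
        out.append(ConditionAverage(
            participant_id=participant.participant_id,
            key=c, kind="condition", data=mean, times=times,
            n_valid_trials=n_valid, included=included[c],
            channel_ids=channel_ids,
        ))
    for modality in ("spoken", "signed"):
        eps = [ep for c in design.conditions_of(modality) for ep in by_condition[c]]
        mean, n_valid = collect(eps)
        n_valid_overall = sum(
            _overall_trial_valid(ep, channel_ok, trial_validity_rule)
            for ep in eps
        )
        out.append(ConditionAverage(
            participant_id=participant.participant_id,
            key=modality, kind="modality", data=mean, times=times,
            n_valid_trials=n_valid,
            included=n_valid_overall >= min_valid_trials,
            channel_ids=channel_ids,
        ))
    return out


def preprocess_recording(
    rec: RawRecording,
    params: PreprocessParams | None = None,
    qc_report: ChannelQCReport | None = None,
    montage: Montage | None = None,
    design: StudyDesign | None = None,
) -> list[ConditionAverage]:
    """Run the full preprocessing chain for one recording."""
    params = params or PreprocessParams()
    design = design or StudyDesign()
    separation = (montage.source_detector_separation_cm if montage else 2.0)
    filtered = lowpass_filter(
        rec.intensity, params.lowpass_cutoff_hz, rec.sampling_rate_hz,
        params.filter_order,
    )
    epochs_att = segment_epochs(rec, params.epoch_window_s, prefiltered=filtered)
    epochs = [
        rereference_to_baseline(
            mbll_inverse(detrend_epoch(ep, sampling_rate_hz=rec.sampling_rate_hz),
                         params.extinction, params.dpf, separation)
        )
        for ep in epochs_att
    ]
    epochs = apply_looking_criterion(epochs, params.looking_threshold)
    epochs = reject_trials(
        epochs,
        params.baseline_reject_threshold_umol,
        params.stimulus_reject_threshold_umol,
        params.stimulus_window_s,
    )
    return average_conditions(
        epochs, rec.participant, design, qc_report,
        params.min_valid_trials, params.trial_validity_rule,
    )
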