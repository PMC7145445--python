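"""Synthetic cohort generator with known hemodynamic ground truth.

No recordings are distributed with the study this pipeline targets, so every
downstream stage is exercised on simulated data that reproduce its
structure: per-participant dual-wavelength (770/850 nm) intensity at 10 Hz
over a 46-channel montage, 20 experimental trials alternating between spoken
and signed modality, interleaved 10-s baselines, per-trial looking-time
proportions, and participant group labels.

The forward model is the exact inverse of the analysis path: known
chromophore concentration courses (a gamma-variate response peaking ~12 s
after stimulus onset for HbO2, with an opposite-signed HHb response) are
mapped to optical attenuation through the modified Beer-Lambert law, noise
components are added in attenuation units (cardiac oscillation above the
1.7 Hz analysis cutoff, slow linear drifts, broadband noise, motion-spike
artifacts, dead channels), and intensity is I0 * exp(-attenuation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Montage, Participant, StudyDesign
from .recording import RawRecording

DEFAULT_PEAK_TIME_S = 12.0
#: gamma-variate shape; chosen so the response resolves within the 10-s
#: post-stimulus baseline (see docs/methods.md)
DEFAULT_DISPERSION = 50.0
#: canonical HbO2/HHb amplitude asymmetry
DEFAULT_HHB_RATIO = -1.0 / 3.0


def simulate_hrf(
    duration_s: float,
    sampling_rate_hz: float,
    amplitude: float,
    peak_time_s: float = DEFAULT_PEAK_TIME_S,
    dispersion: float = DEFAULT_DISPERSION,
) -> np.ndarray:
    """Gamma-variate hemodynamic response on a regular grid.

    ``h(t) = amplitude * (t / tp)^a * exp(a * (1 - t / tp))`` with shape
    parameter ``a`` (dispersion) and peak time ``tp``: the curve starts at 0,
    attains its unique extremum ``amplitude`` exactly at ``tp``, and decays
    back toward 0.  ``amplitude`` may be negative (e.g., for HHb).

    Parameters are in seconds, Hz and umol; the returned course is in umol.
    """
    if duration_s <= 0 or sampling_rate_hz <= 0:
        raise ValueError("duration_s and sampling_rate_hz must be positive")
    if not (0 < peak_time_s < duration_s):
        raise ValueError("peak_time_s must lie strictly inside (0, duration_s)")
    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    with np.errstate(divide="ignore", invalid="ignore"):
        log_h = dispersion * (np.log(t / peak_time_s) + 1.0 - t / peak_time_s)
    h = np.exp(log_h)
    h[t == 0] = 0.0
    return amplitude * h


def forward_beer_lambert(
    hbo2: np.ndarray,
    hhb: np.ndarray,
    extinction: dict[float, dict[str, float]],
    dpf: float = 5.13,
    separation_cm: float = 2.0,
) -> np.ndarray:
    """Map chromophore concentration changes to attenuation changes.

    For each wavelength ``w``::

        dA_w = (eps_hbo2_w * dC_hbo2 + eps_hhb_w * dC_hhb) * 1e-3 * d * DPF

    with concentrations in umol/l, extinction coefficients in mM^-1 cm^-1,
    source-detector separation ``d`` in cm, and the differential pathlength
    factor accounting for the longer effective photon path.  Returns an
    array of shape ``(n_wavelengths,) + hbo2.shape``.
    """
    hbo2 = np.asarray(hbo2, float)
    hhb = np.asarray(hhb, float)
    E = extinction_matrix(extinction)
    if abs(np.linalg.det(E)) < 1e-12:
        raise ValueError("extinction matrix is singular")
    scale = 1e-3 * separation_cm * dpf
    return scale * np.stack(
        [E[w, 0] * hbo2 + E[w, 1] * hhb for w in range(E.shape[0])]
    )


def extinction_matrix(extinction: dict[float, dict[str, float]]) -> np.ndarray:
    """2x2 matrix of extinction coefficients, wavelength x (HbO2, HHb)."""
    wavelengths = sorted(extinction)
    return np.array(
        [[extinction[w]["hbo2"], extinction[w]["hhb"]] for w in wavelengths]
    )


@dataclass
class HemodynamicGroundTruth:
    """Per (participant, condition, channel) injected response parameters.

    ``table`` columns: participant_id, condition, channel, hbo2_amplitude
    (umol), hhb_amplitude (umol), peak_time_s.
    """

    table: pd.DataFrame

    COLUMNS = ("participant_id", "condition", "channel",
               "hbo2_amplitude", "hhb_amplitude", "peak_time_s")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"ground-truth table missing columns {sorted(missing)}")

    @classmethod
    def uniform(
        cls,
        participants: list[Participant],
        conditions: list[str] | tuple[str, ...],
        channel_ids: list[int],
        hbo2_amplitude: float = 1.5,
        hhb_ratio: float = DEFAULT_HHB_RATIO,
        peak_time_s: float = DEFAULT_PEAK_TIME_S,
    ) -> "HemodynamicGroundTruth":
        """Same response everywhere: a flat, fully covered truth table."""
        rows = [
            (p.participant_id, c, ch, hbo2_amplitude,
             hhb_ratio * hbo2_amplitude, peak_time_s)
            for p in participants for c in conditions for ch in channel_ids
        ]
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @classmethod
    def scenario(
        cls,
        participants: list[Participant],
        design: StudyDesign,
        montage: Montage,
        base_amplitude: float = 1.0,
        modality_boost: float = 0.5,
        lateralization: float = 0.6,
        hhb_ratio: float = DEFAULT_HHB_RATIO,
        peak_time_s: float = DEFAULT_PEAK_TIME_S,
    ) -> "HemodynamicGroundTruth":
        """Illustrative group/hemisphere-dependent response profile.

        Spoken conditions activate ``modality_boost`` umol more than signed
        ones; unimodal bilinguals carry a right-hemisphere amplitude
        advantage of ``lateralization`` umol while the other groups are
        symmetric.  These profiles are scenario choices for exercising the
        statistics, not estimates of any real effect size.
        """
        rows = []
        for p in participants:
            for c in design.conditions:
                amp_base = base_amplitude
                if design.modality(c) == "spoken":
                    amp_base = amp_base + modality_boost
                for ch in montage.channel_ids:
                    amp = amp_base
                    if (p.group == "unimodal_bilingual"
                            and montage.hemisphere_of(ch) == "right"):
                        amp = amp + lateralization
                    rows.append((p.participant_id, c, ch, amp,
                                 hhb_ratio * amp, peak_time_s))
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    def lookup(self, participant_id: str, condition: str,
               channel_ids: list[int]) -> pd.DataFrame:
        sub = self.table[
            (self.table.participant_id == participant_id)
            & (self.table.condition == condition)
        ].set_index("channel")
        missing = [ch for ch in channel_ids if ch not in sub.index]
        if missing:
            raise ValueError(
                f"ground truth missing channels {missing} for "
                f"({participant_id}, {condition})"
            )
        return sub.loc[channel_ids]

    def covers(self, participants: list[Participant],
               conditions, channel_ids: list[int]) -> bool:
        idx = set(zip(self.table.participant_id, self.table.condition,
                      self.table.channel))
        return all(
            (p.participant_id, c, ch) in idx
            for p in participants for c in conditions for ch in channel_ids
        )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HemodynamicGroundTruth":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class NoiseModel:
    """Noise components added in attenuation units (AU = ln-intensity).

    All rates and scales must be non-negative; ``seed`` fully determines
    the simulated cohort.  Defaults emulate a usable infant session: a
    cardiac oscillation above the analysis low-pass cutoff, slow per-channel
    drifts, broadband white + 1/f noise, occasional motion-spike artifacts
    large enough to trip the +-3/+-5 umol trial-rejection thresholds, and a
    small probability of optically dead channels.
    """

    cardiac_frequency_hz: float = 2.4  # infant heart rate, above 1.7 Hz cutoff
    cardiac_amplitude: float = 0.005
    cardiac_linewidth_hz: float = 0.1  # heart-rate wander (phase diffusion)
    drift_slope_scale: float = 1e-4  # AU per second, sd across channels
    motion_spike_rate_per_min: float = 0.1  # per channel
    motion_spike_magnitude: float = 0.2  # AU, ~13 umol HbO2 equivalent
    dead_channel_probability: float = 0.0
    white_noise_scale: float = 0.002
    pink_noise_scale: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cardiac_frequency_hz", "cardiac_amplitude",
                     "cardiac_linewidth_hz",
                     "drift_slope_scale", "motion_spike_rate_per_min",
                     "motion_spike_magnitude", "dead_channel_probability",
                     "white_noise_scale", "pink_noise_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"NoiseModel.{name} must be >= 0")

    @classmethod
    def silent(cls, seed: int = 0) -> "NoiseModel":
        """All noise components off (for losslessness checks)."""
        return cls(cardiac_amplitude=0.0, drift_slope_scale=0.0,
                   motion_spike_rate_per_min=0.0, dead_channel_probability=0.0,
                   white_noise_scale=0.0, pink_noise_scale=0.0, seed=seed)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Unit-variance 1/f noise along the last axis (FFT shaping)."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    weight = np.where(freqs > 0, 1.0 / np.sqrt(freqs + freqs[1]), 0.0)
    pink = np.fft.irfft(spec * weight, n=shape[-1], axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    return pink / np.where(sd > 0, sd, 1.0)


def _condition_sequence(design: StudyDesign, rng: np.random.Generator) -> list[str]:
    """20 trials alternating spoken/signed, 5 per condition, shuffled within modality."""
    per_modality = {}
    n_each = design.max_experimental_trials // 4
    for modality in ("spoken", "signed"):
        conds = design.conditions_of(modality)
        seq = np.array(conds * n_each)
        rng.shuffle(seq)
        per_modality[modality] = list(seq)
    first = str(rng.choice(["spoken", "signed"]))
    second = "signed" if first == "spoken" else "spoken"
    out = []
    for a, b in zip(per_modality[first], per_modality[second]):
        out.extend([str(a), str(b)])
    return out


def simulate_recording(
    participant: Participant,
    design: StudyDesign,
    montage: Montage,
    truth: HemodynamicGroundTruth,
    noise: NoiseModel,
    rng: np.random.Generator,
    hrf_dispersion: float = DEFAULT_DISPERSION,
    looking_beta: tuple[float, float] = (9.0, 1.0),
) -> RawRecording:
    """Simulate one participant's session (see :func:`simulate_cohort`)."""
    fs = montage.sampling_rate_hz
    n_ch = len(montage.channel_ids)
    n_wl = len(montage.wavelengths_nm)
    trial_period = 20.0  # response window: nominal 10 s stimulus + 10 s baseline
    durations = rng.uniform(*design.stimulus_duration_range_s,
                            size=design.max_experimental_trials)
    onsets = design.baseline_duration_s + np.concatenate(
        ([0.0], np.cumsum(durations[:-1] + design.baseline_duration_s))
    )
    onsets = np.round(onsets * fs) / fs  # snap to the sampling grid
    duration = onsets[-1] + trial_period + design.baseline_duration_s
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    conditions = _condition_sequence(design, rng)
    events = list(zip(onsets.tolist(), conditions))

    # --- injected chromophore concentrations (umol), channel x time
    hbo2 = np.zeros((n_ch, n))
    hhb = np.zeros((n_ch, n))
    resp_len = int(round(trial_period * fs))
    for onset, cond in events:
        tr = truth.lookup(participant.participant_id, cond, montage.channel_ids)
        peak_time = float(tr["peak_time_s"].iloc[0])
        unit = simulate_hrf(trial_period, fs, 1.0, peak_time, hrf_dispersion)
        i0 = int(round(onset * fs))
        sl = slice(i0, i0 + resp_len)
        hbo2[:, sl] += np.outer(tr["hbo2_amplitude"].to_numpy(), unit)
        hhb[:, sl] += np.outer(tr["hhb_amplitude"].to_numpy(), unit)

    from .config import PreprocessParams  # default extinction table
    pp = PreprocessParams()
    atten = forward_beer_lambert(
        hbo2, hhb, pp.extinction, pp.dpf, montage.source_detector_separation_cm
    )  # (n_wl, n_ch, n)
    atten = np.transpose(atten, (1, 0, 2))  # channel x wavelength x time

    # --- noise components, in attenuation units
    if noise.cardiac_amplitude > 0:
        # phase-diffusing oscillation: heart rate wanders, so cardiac power
        # spreads over a ~linewidth-wide band instead of a single FFT bin
        sigma = np.sqrt(2 * np.pi * noise.cardiac_linewidth_hz / fs)
        wander = np.cumsum(sigma * rng.standard_normal(n), axis=-1)
        phase0 = rng.uniform(0, 2 * np.pi, size=(n_ch, 1, 1))
        amp = noise.cardiac_amplitude * (1 + 0.1 * rng.standard_normal((n_ch, 1, 1)))
        atten = atten + amp * np.sin(
            2 * np.pi * noise.cardiac_frequency_hz * t + wander + phase0
        )
    if noise.drift_slope_scale > 0:
        slope = noise.drift_slope_scale * rng.standard_normal((n_ch, n_wl, 1))
        atten = atten + slope * t
    if noise.white_noise_scale > 0:
        atten = atten + noise.white_noise_scale * rng.standard_normal(
            (n_ch, n_wl, n)
        )
    if noise.pink_noise_scale > 0:
        atten = atten + noise.pink_noise_scale * _pink_noise(rng, (n_ch, n_wl, n))
    if noise.motion_spike_rate_per_min > 0:
        expected = noise.motion_spike_rate_per_min * duration / 60.0
        for ci in range(n_ch):
            for _ in range(rng.poisson(expected)):
                start = rng.uniform(0, duration - 1.0)
                width = rng.uniform(0.3, 1.0)
                sign = rng.choice([-1.0, 1.0])
                sl = slice(int(start * fs), int((start + width) * fs))
                atten[ci, :, sl] += sign * noise.motion_spike_magnitude

    # --- intensity
    log_i0 = rng.uniform(np.log(0.1), np.log(10.0), size=(n_ch, n_wl, 1))
    intensity = np.exp(log_i0) * np.exp(-atten)
    if noise.dead_channel_probability > 0:
        dead = rng.random(n_ch) < noise.dead_channel_probability
        if dead.any():
            wobble = np.abs(
                1.0 + 0.5 * rng.standard_normal((int(dead.sum()), n_wl, n))
            ) + 1e-6
            intensity[dead] = 1e-3 * np.exp(log_i0[dead]) * wobble

    looking = rng.beta(*looking_beta, size=len(events))
    return RawRecording(
        participant=participant,
        intensity=intensity,
        events=events,
        looking_proportion=[float(p) for p in looking],
        channel_ids=list(montage.channel_ids),
        wavelengths_nm=tuple(montage.wavelengths_nm),
        sampling_rate_hz=fs,
    )


def simulate_cohort(
    design: StudyDesign,
    participants: list[Participant],
    truth: HemodynamicGroundTruth,
    noise: NoiseModel,
    montage: Montage,
    hrf_dispersion: float = DEFAULT_DISPERSION,
    looking_beta: tuple[float, float] = (9.0, 1.0),
) -> tuple[list[RawRecording], HemodynamicGroundTruth]:
    """Simulate one recording per participant; returns (recordings, truth).

    Each participant draws from an independent random substream derived
    from ``noise.seed``, so the output is bit-identical for a fixed seed
    and unaffected by participant order.
    """
    if not truth.covers(participants, design.conditions, montage.channel_ids):
        raise ValueError(
            "ground truth does not cover every participant x condition x channel"
        )
    streams = np.random.SeedSequence(noise.seed).spawn(len(participants))
    recordings = [
        simulate_recording(
            p, design, montage, truth, noise,
            np.random.default_rng(stream),
            hrf_dispersion=hrf_dispersion, looking_beta=looking_beta,
        )
        for p, stream in zip(participants, streams)
    ]
    return recordings, truth


def make_participants(
    n_monolingual: int = 19,
    n_unimodal: int = 20,
    n_bimodal: int = 21,
    age_months: float = 5.0,
) -> list[Participant]:
    """Cohort roster with the study's group sizes by default."""
    out = []
    for prefix, group, n in (
        ("mono", "monolingual", n_monolingual),
        ("uni", "unimodal_bilingual", n_unimodal),
        ("bi", "bimodal_bilingual", n_bimodal),
    ):
        out.extend(
            Participant(f"{prefix}{i + 1:02d}", group, age_months)
            for i in range(n)
        )
    return out
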