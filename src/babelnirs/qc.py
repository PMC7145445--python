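"""Channel-level quality control on the raw optical signal.

Channels are screened per wavelength on the full-session signal: a channel
is rejected when the coefficient of variation of either wavelength exceeds
15% or when a single non-DC spectral component carries more than 50% of the
non-DC power (a strong periodic component unrelated to the experiment).
Participants with more than 15 rejected channels are excluded from all
analyses.  Thresholds are configuration, defaulted to the protocol values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import QCThresholds
from .recording import RawRecording

REASON_COV = "cov"
REASON_POWER = "power"
REASON_DRIFT = "drift"


def coefficient_of_variation(signal: np.ndarray) -> float:
    """Coefficient of variation in percent: 100 * sd / mean.

    Raises ``ValueError`` for an empty or zero-mean signal.
    """
    signal = np.asarray(signal, float)
    if signal.size == 0:
        raise ValueError("empty signal")
    mean = signal.mean()
    if mean == 0:
        raise ValueError("zero-mean signal: coefficient of variation undefined")
    return 100.0 * signal.std() / abs(mean)


def normalized_peak_power(signal: np.ndarray,
                          sampling_rate_hz: float = 10.0,
                          min_frequency_hz: float = 0.0) -> float:
    """Largest non-DC periodogram bin as a fraction of total non-DC power.

    Close to 1 for a pure periodic signal, well below 0.5 for broadband
    noise.  ``min_frequency_hz`` restricts the peak-bin search (not the
    total) to frequencies at or above a floor, so that screening can ignore
    the band occupied by the stimulus-locked hemodynamic response and flag
    only strong periodic components unrelated to the experiment.  Requires
    at least two seconds of signal.
    """
    signal = np.asarray(signal, float)
    if signal.size < 2 * sampling_rate_hz:
        raise ValueError("signal shorter than two seconds")
    spec = np.abs(np.fft.rfft(signal - signal.mean())) ** 2
    freqs = np.fft.rfftfreq(signal.size, d=1.0 / sampling_rate_hz)
    power = spec[1:]  # drop the DC bin
    total = power.sum()
    if total == 0:
        return 0.0
    searched = power[freqs[1:] >= min_frequency_hz]
    if searched.size == 0:
        return 0.0
    return float(searched.max() / total)


def _linear_drift_fraction(signal: np.ndarray) -> float:
    """|fitted linear change over the session| / |mean|, for drift screening."""
    t = np.arange(signal.size, dtype=float)
    slope = np.polyfit(t, signal, 1)[0]
    mean = signal.mean()
    if mean == 0:
        return np.inf
    return abs(slope) * signal.size / abs(mean)


@dataclass
class ChannelQCReport:
    """Per-channel QC metrics and the participant-level exclusion flag."""

    participant_id: str
    table: pd.DataFrame  # channel, cov_wl*, npp_wl*, rejected, reasons
    max_rejected_channels: int = 15

    @property
    def rejected_channels(self) -> list[int]:
        return self.table.loc[self.table.rejected, "channel"].tolist()

    @property
    def n_rejected(self) -> int:
        return int(self.table.rejected.sum())

    @property
    def participant_excluded(self) -> bool:
        return self.n_rejected > self.max_rejected_channels

    def summary(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "n_rejected": self.n_rejected,
            "participant_excluded": self.participant_excluded,
            "rejected_channels": self.rejected_channels,
        }

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def apply_channel_rejection(
    rec: RawRecording, thresholds: QCThresholds | None = None
) -> ChannelQCReport:
    """Screen every channel of a recording; a channel fails if ANY
    wavelength fails ANY enabled criterion.
    """
    thr = thresholds or QCThresholds()
    rows = []
    for ci, cid in enumerate(rec.channel_ids):
        covs, npps, reasons = [], [], []
        for wi, wl in enumerate(rec.wavelengths_nm):
            intensity = rec.intensity[ci, wi, :]
            if thr.cov_domain == "attenuation":
                ref = intensity.mean()
                series = -np.log(np.maximum(intensity, 1e-300) / max(ref, 1e-300))
            else:
                series = intensity
            try:
                cov = coefficient_of_variation(series)
            except ValueError:
                cov = np.inf
            npp = normalized_peak_power(
                intensity, rec.sampling_rate_hz, thr.npp_min_frequency_hz
            )
            covs.append(cov)
            npps.append(npp)
            if cov > thr.cov_threshold_percent:
                reasons.append(f"{REASON_COV}@{int(wl)}")
            if npp > thr.normalized_power_threshold:
                reasons.append(f"{REASON_POWER}@{int(wl)}")
            if thr.drift_screening_enabled and thr.drift_threshold is not None:
                if _linear_drift_fraction(intensity) > thr.drift_threshold:
                    reasons.append(f"{REASON_DRIFT}@{int(wl)}")
        rows.append({
            "channel": cid,
            **{f"cov_wl{int(wl)}": c
               for wl, c in zip(rec.wavelengths_nm, covs)},
            **{f"npp_wl{int(wl)}": p
               for wl, p in zip(rec.wavelengths_nm, npps)},
            "rejected": bool(reasons),
            "reasons": ";".join(reasons),
        })
    table = pd.DataFrame(rows)
    return ChannelQCReport(
        participant_id=rec.participant.participant_id,
        table=table,
        max_rejected_channels=thr.max_rejected_channels,
    )
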