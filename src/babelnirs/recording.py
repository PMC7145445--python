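"""Raw recording container, validation, and on-disk formats.

A :class:`RawRecording` holds the dual-wavelength optical intensity of one
participant (channel x wavelength x time), the stimulus events, and the
per-trial looking-time proportions.  Two interchangeable formats are
supported: a SNIRF-style HDF5 file (continuous-wave intensity,
``dataType == 1``) and a plain-text fallback of one wide TSV per wavelength
with a JSON sidecar for events, looking proportions and participant
metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import Montage, Participant, StudyDesign

#: seconds of recording required after the last stimulus onset
POST_EVENT_COVERAGE_S = 20.0


@dataclass
class RawRecording:
    """One participant's session: intensity, events and looking times."""

    participant: Participant
    intensity: np.ndarray  # (n_channels, n_wavelengths, n_samples), >= 0
    events: list[tuple[float, str]]  # (onset seconds, condition), increasing
    looking_proportion: list[float]  # one per event, in [0, 1]
    channel_ids: list[int] = field(default_factory=list)
    wavelengths_nm: tuple[float, float] = (770.0, 850.0)
    sampling_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (channels, wavelengths, time)")
        if not self.channel_ids:
            self.channel_ids = list(range(1, self.intensity.shape[0] + 1))

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel_index(self, channel_id: int) -> int:
        return self.channel_ids.index(channel_id)


def validate_recording(rec: RawRecording, design: StudyDesign) -> list[str]:
    """Check a recording against the study design; return all breaches.

    An empty list means the recording conforms.  Checks: intensity
    non-negativity and shape, one looking proportion per event, strictly
    increasing onsets, post-event coverage, the 20-trial cap, and the
    spoken/signed alternation rule.
    """
    breaches: list[str] = []
    if np.any(rec.intensity < 0):
        breaches.append("intensity: negative values present")
    if len(rec.looking_proportion) != len(rec.events):
        breaches.append(
            f"looking_proportion: {len(rec.looking_proportion)} values for "
            f"{len(rec.events)} events"
        )
    for p in rec.looking_proportion:
        if not (0.0 <= p <= 1.0):
            breaches.append(f"looking_proportion: value {p} outside [0, 1]")
            break
    onsets = [t for t, _ in rec.events]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        breaches.append("events: onsets not strictly increasing")
    if rec.events and rec.duration_s < onsets[-1] + POST_EVENT_COVERAGE_S:
        breaches.append(
            f"intensity: recording ends {rec.duration_s:.1f} s but last event "
            f"needs coverage to {onsets[-1] + POST_EVENT_COVERAGE_S:.1f} s"
        )
    if len(rec.events) > design.max_experimental_trials:
        breaches.append(
            f"events: {len(rec.events)} experimental trials exceed the "
            f"maximum of {design.max_experimental_trials}"
        )
    unknown = [c for _, c in rec.events if c not in design.conditions]
    if unknown:
        breaches.append(f"events: unknown conditions {sorted(set(unknown))}")
    else:
        modalities = [design.modality(c) for _, c in rec.events]
        if any(a == b for a, b in zip(modalities, modalities[1:])):
            breaches.append(
                "events: consecutive trials do not alternate between spoken "
                "and signed modality"
            )
    return breaches


# ---------------------------------------------------------------------------
# TSV + JSON sidecar

def write_recording_tsv(rec: RawRecording, directory: str | Path) -> None:
    """Write one wide TSV per wavelength plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pid = rec.participant.participant_id
    t = np.arange(rec.n_samples) / rec.sampling_rate_hz
    for wi, wl in enumerate(rec.wavelengths_nm):
        df = pd.DataFrame(
            rec.intensity[:, wi, :].T,
            columns=[f"ch_{cid}" for cid in rec.channel_ids],
        )
        df.insert(0, "time_s", t)
        df.to_csv(directory / f"{pid}_wl{int(wl)}.tsv", sep="\t", index=False)
    sidecar = {
        "participant_id": pid,
        "group": rec.participant.group,
        "age_months": rec.participant.age_months,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "wavelengths_nm": list(rec.wavelengths_nm),
        "channel_ids": list(rec.channel_ids),
        "events": [{"onset_s": t_, "condition": c} for t_, c in rec.events],
        "looking_proportion": list(rec.looking_proportion),
    }
    (directory / f"{pid}_events.json").write_text(json.dumps(sidecar, indent=1))


def read_recording_tsv(directory: str | Path, participant_id: str) -> RawRecording:
    directory = Path(directory)
    sidecar = json.loads((directory / f"{participant_id}_events.json").read_text())
    wavelengths = tuple(sidecar["wavelengths_nm"])
    channel_ids = [int(c) for c in sidecar["channel_ids"]]
    planes = []
    for wl in wavelengths:
        df = pd.read_csv(directory / f"{participant_id}_wl{int(wl)}.tsv", sep="\t")
        planes.append(df[[f"ch_{cid}" for cid in channel_ids]].to_numpy().T)
    intensity = np.stack(planes, axis=1)
    participant = Participant(
        participant_id=sidecar["participant_id"],
        group=sidecar["group"],
        age_months=float(sidecar.get("age_months", 5.0)),
    )
    return RawRecording(
        participant=participant,
        intensity=intensity,
        events=[(float(e["onset_s"]), e["condition"]) for e in sidecar["events"]],
        looking_proportion=[float(p) for p in sidecar["looking_proportion"]],
        channel_ids=channel_ids,
        wavelengths_nm=wavelengths,
        sampling_rate_hz=float(sidecar["sampling_rate_hz"]),
    )


# ---------------------------------------------------------------------------
# SNIRF-style HDF5 (continuous-wave intensity subset)

def write_recording_snirf(rec: RawRecording, path: str | Path,
                          montage: Montage | None = None) -> None:
    """Write a continuous-wave SNIRF file (intensity, dataType 1).

    Channel-to-optode mapping comes from the montage when given, otherwise
    sources and detectors are numbered by channel.
    """
    by_id = {c.channel_id: c for c in montage.channels} if montage else {}
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.participant.participant_id)
        meta.create_dataset("group", data=rec.participant.group)
        meta.create_dataset("age_months", data=float(rec.participant.age_months))
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset(
            "lookingProportion", data=np.asarray(rec.looking_proportion, float)
        )
        meta.create_dataset(
            "channelIDs", data=np.asarray(rec.channel_ids, dtype=np.int64)
        )

        probe = nirs.create_group("probe")
        probe.create_dataset(
            "wavelengths", data=np.asarray(rec.wavelengths_nm, float)
        )
        if montage is not None:
            sources = sorted({c.source_id for c in montage.channels})
            detectors = sorted({c.detector_id for c in montage.channels})
        else:
            sources = [f"S{cid}" for cid in rec.channel_ids]
            detectors = [f"D{cid}" for cid in rec.channel_ids]
        probe.create_dataset("sourceLabels", data=np.array(sources, dtype="S"))
        probe.create_dataset("detectorLabels", data=np.array(detectors, dtype="S"))

        data = nirs.create_group("data1")
        n_ch = len(rec.channel_ids)
        series = np.concatenate(
            [rec.intensity[:, wi, :] for wi in range(len(rec.wavelengths_nm))]
        ).T  # time x (n_ch * n_wl), wavelength-major blocks
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset(
            "time", data=np.arange(rec.n_samples) / rec.sampling_rate_hz
        )
        m = 0
        for wi in range(len(rec.wavelengths_nm)):
            for ci, cid in enumerate(rec.channel_ids):
                m += 1
                ml = data.create_group(f"measurementList{m}")
                if by_id:
                    src = sources.index(by_id[cid].source_id) + 1
                    det = detectors.index(by_id[cid].detector_id) + 1
                else:
                    src = det = ci + 1
                ml.create_dataset("sourceIndex", data=np.int64(src))
                ml.create_dataset("detectorIndex", data=np.int64(det))
                ml.create_dataset("wavelengthIndex", data=np.int64(wi + 1))
                ml.create_dataset("dataType", data=np.int64(1))
                ml.create_dataset("dataTypeIndex", data=np.int64(1))

        for cond in sorted({c for _, c in rec.events}):
            stim = nirs.create_group(f"stim_{cond}")
            stim.create_dataset("name", data=cond)
            onsets = [t for t, c in rec.events if c == cond]
            stim.create_dataset(
                "data",
                data=np.array([[t, 10.0, 1.0] for t in onsets], dtype=float),
            )


def read_recording_snirf(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        meta = nirs["metaDataTags"]
        participant = Participant(
            participant_id=_as_str(meta["SubjectID"][()]),
            group=_as_str(meta["group"][()]),
            age_months=float(meta["age_months"][()]),
        )
        looking = [float(p) for p in meta["lookingProportion"][()]]
        channel_ids = [int(c) for c in meta["channelIDs"][()]]
        wavelengths = tuple(float(w) for w in nirs["probe"]["wavelengths"][()])
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        fs = 1.0 / float(np.median(np.diff(time)))
        n_ch = len(channel_ids)
        intensity = np.stack(
            [series[:, wi * n_ch:(wi + 1) * n_ch].T
             for wi in range(len(wavelengths))],
            axis=1,
        )
        events: list[tuple[float, str]] = []
        for key in nirs:
            if key.startswith("stim_"):
                stim = nirs[key]
                name = _as_str(stim["name"][()])
                for row in np.atleast_2d(np.asarray(stim["data"])):
                    events.append((float(row[0]), name))
        events.sort(key=lambda e: e[0])
    return RawRecording(
        participant=participant,
        intensity=intensity,
        events=events,
        looking_proportion=looking,
        channel_ids=channel_ids,
        wavelengths_nm=wavelengths,
        sampling_rate_hz=round(fs, 6),
    )


def _as_str(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)
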