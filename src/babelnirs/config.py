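"""Shared data model: montage, study design, ROI definitions and configuration I/O.

The montage describes a 46-channel infant headgear (23 channels per
hemisphere, 2 cm source-detector separation) recording at two continuous
wavelengths (770 and 850 nm) sampled at 10 Hz.  The study design covers four
audiovisual language conditions -- two spoken (English, French) and two
signed (BSL, LSFB) -- presented in alternation between modalities and
interleaved with 10 s baselines.  All constants live in a single YAML
configuration so that every downstream stage reads the same numbers.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

SPOKEN = "spoken"
SIGNED = "signed"
GROUPS = ("monolingual", "unimodal_bilingual", "bimodal_bilingual")
CHROMOPHORES = ("hbo2", "hhb")


class ConfigError(ValueError):
    """A configuration file violates a structural invariant."""


@dataclass(frozen=True)
class Channel:
    channel_id: int
    source_id: str
    detector_id: str
    hemisphere: str  # "left" | "right"
    label: str = ""

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ConfigError(
                f"channel {self.channel_id}: hemisphere must be 'left' or "
                f"'right', got {self.hemisphere!r}"
            )


@dataclass(frozen=True)
class Montage:
    """Optode montage: 46 channels, 23 per hemisphere, 2 cm separation."""

    channels: tuple[Channel, ...]
    source_detector_separation_cm: float = 2.0
    wavelengths_nm: tuple[float, float] = (770.0, 850.0)
    sampling_rate_hz: float = 10.0

    N_CHANNELS = 46
    N_PER_HEMISPHERE = 23

    def __post_init__(self) -> None:
        if len(self.channels) != self.N_CHANNELS:
            raise ConfigError(
                f"montage.channels: expected {self.N_CHANNELS} channels, "
                f"got {len(self.channels)}"
            )
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ConfigError("montage.channels: duplicate channel_id")
        for hemi in ("left", "right"):
            n = sum(1 for c in self.channels if c.hemisphere == hemi)
            if n != self.N_PER_HEMISPHERE:
                raise ConfigError(
                    f"montage.channels: expected {self.N_PER_HEMISPHERE} "
                    f"{hemi}-hemisphere channels, got {n}"
                )
        if not self.source_detector_separation_cm > 0:
            raise ConfigError("montage.source_detector_separation_cm must be > 0")
        if len(self.wavelengths_nm) != 2:
            raise ConfigError("montage.wavelengths_nm must be a pair")
        if not self.sampling_rate_hz > 0:
            raise ConfigError("montage.sampling_rate_hz must be > 0")

    @property
    def channel_ids(self) -> list[int]:
        return [c.channel_id for c in self.channels]

    def hemisphere_of(self, channel_id: int) -> str:
        return self._by_id()[channel_id].hemisphere

    def hemisphere_ids(self, hemisphere: str) -> list[int]:
        return [c.channel_id for c in self.channels if c.hemisphere == hemisphere]

    def _by_id(self) -> dict[int, Channel]:
        return {c.channel_id: c for c in self.channels}

    def __contains__(self, channel_id: int) -> bool:
        return channel_id in self._by_id()


@dataclass(frozen=True)
class ROISet:
    """Inferior frontal and posterior temporal regions of interest.

    Each ROI contains eight montage channels, four per hemisphere.
    """

    inferior_frontal: tuple[int, ...]
    posterior_temporal: tuple[int, ...]

    ROI_SIZE = 8
    PER_HEMISPHERE = 4

    def validate(self, montage: Montage) -> None:
        for name in ("inferior_frontal", "posterior_temporal"):
            ids = getattr(self, name)
            if len(ids) != self.ROI_SIZE:
                raise ConfigError(
                    f"rois.{name}: expected {self.ROI_SIZE} channels, got {len(ids)}"
                )
            missing = [i for i in ids if i not in montage]
            if missing:
                raise ConfigError(
                    f"rois.{name}: channels {missing} not in montage"
                )
            for hemi in ("left", "right"):
                n = sum(1 for i in ids if montage.hemisphere_of(i) == hemi)
                if n != self.PER_HEMISPHERE:
                    raise ConfigError(
                        f"rois.{name}: expected {self.PER_HEMISPHERE} {hemi} "
                        f"channels, got {n}"
                    )

    def channels(self, roi: str, hemisphere: str | None = None,
                 montage: Montage | None = None) -> list[int]:
        ids = list(getattr(self, roi))
        if hemisphere is not None:
            if montage is None:
                raise ValueError("montage required to filter by hemisphere")
            ids = [i for i in ids if montage.hemisphere_of(i) == hemisphere]
        return ids


@dataclass(frozen=True)
class StudyDesign:
    """Experimental design constants.

    Four conditions in two modalities; consecutive experimental trials
    alternate between spoken and signed modality; each stimulus (9-12 s,
    nominal 10 s) is followed by a 10 s baseline; at most 20 experimental
    trials per participant.
    """

    conditions: tuple[str, ...] = ("English", "French", "BSL", "LSFB")
    modality_map: Mapping[str, str] = field(
        default_factory=lambda: {
            "English": SPOKEN, "French": SPOKEN, "BSL": SIGNED, "LSFB": SIGNED,
        }
    )
    familiarity_map: Mapping[str, Mapping[str, str]] = field(
        default_factory=lambda: {
            "monolingual": {"English": "familiar", "French": "unfamiliar",
                            "BSL": "n/a", "LSFB": "n/a"},
            "unimodal_bilingual": {"English": "familiar", "French": "unfamiliar",
                                   "BSL": "n/a", "LSFB": "n/a"},
            "bimodal_bilingual": {"English": "familiar", "French": "unfamiliar",
                                  "BSL": "familiar", "LSFB": "unfamiliar"},
        }
    )
    baseline_duration_s: float = 10.0
    stimulus_duration_range_s: tuple[float, float] = (9.0, 12.0)
    max_experimental_trials: int = 20

    def __post_init__(self) -> None:
        if self.baseline_duration_s != 10.0:
            raise ConfigError("design.baseline_duration_s must be 10 s")
        lo, hi = self.stimulus_duration_range_s
        if not (lo <= hi and lo >= 9.0 and hi <= 12.0):
            raise ConfigError(
                "design.stimulus_duration_range_s must lie within [9, 12] s"
            )
        if self.max_experimental_trials != 20:
            raise ConfigError("design.max_experimental_trials must be 20")
        missing = [c for c in self.conditions if c not in self.modality_map]
        if missing:
            raise ConfigError(f"design.modality_map: missing conditions {missing}")
        for g, fam in self.familiarity_map.items():
            if g not in GROUPS:
                raise ConfigError(f"design.familiarity_map: unknown group {g!r}")
            bad = [c for c in fam if c not in self.conditions]
            if bad:
                raise ConfigError(
                    f"design.familiarity_map[{g}]: unknown conditions {bad}"
                )

    def modality(self, condition: str) -> str:
        return self.modality_map[condition]

    def conditions_of(self, modality: str) -> list[str]:
        return [c for c in self.conditions if self.modality_map[c] == modality]

    def familiarity(self, group: str, condition: str) -> str:
        return self.familiarity_map[group][condition]


@dataclass(frozen=True)
class Participant:
    participant_id: str
    group: str
    age_months: float = 5.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigError(
                f"participant {self.participant_id}: group must be one of "
                f"{GROUPS}, got {self.group!r}"
            )


@dataclass(frozen=True)
class QCThresholds:
    """Channel-rejection thresholds; defaults follow the study protocol."""

    cov_threshold_percent: float = 15.0
    normalized_power_threshold: float = 0.5
    #: peak-bin search floor: the stimulus-locked response lives below
    #: ~0.5 Hz, so only components unrelated to the experiment are flagged
    npp_min_frequency_hz: float = 0.5
    max_rejected_channels: int = 15
    cov_domain: str = "intensity"  # or "attenuation"
    drift_screening_enabled: bool = False
    drift_threshold: float | None = None


@dataclass(frozen=True)
class PreprocessParams:
    """Filtering, epoching, conversion and trial-rejection parameters."""

    lowpass_cutoff_hz: float = 1.7
    filter_order: int = 4
    epoch_window_s: tuple[float, float] = (-4.0, 20.0)
    baseline_reject_threshold_umol: float = 3.0
    stimulus_reject_threshold_umol: float = 5.0
    stimulus_window_s: tuple[float, float] = (0.0, 10.0)
    looking_threshold: float = 0.6
    min_valid_trials: int = 3
    trial_validity_rule: float = 0.5  # trial valid overall if valid in >= this fraction of channels
    dpf: float = 5.13
    # molar extinction, mM^-1 cm^-1, keyed by wavelength then chromophore
    extinction: Mapping[float, Mapping[str, float]] = field(
        default_factory=lambda: {
            770.0: {"hbo2": 0.6500, "hhb": 1.3029},
            850.0: {"hbo2": 1.0580, "hhb": 0.6915},
        }
    )


@dataclass(frozen=True)
class AnalysisParams:
    peak_window_s: tuple[float, float] = (8.0, 16.0)
    n_channels_fdr: int = 46
    svm_c: float = 1.0
    n_permutations: int = 1000


@dataclass(frozen=True)
class PipelineConfig:
    montage: Montage
    rois: ROISet
    design: StudyDesign
    qc: QCThresholds = field(default_factory=QCThresholds)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)


# ---------------------------------------------------------------------------
# YAML I/O

def _montage_from_dict(d: dict) -> Montage:
    try:
        channels = tuple(
            Channel(
                channel_id=int(c["channel_id"]),
                source_id=str(c["source_id"]),
                detector_id=str(c["detector_id"]),
                hemisphere=str(c["hemisphere"]),
                label=str(c.get("label", "")),
            )
            for c in d["channels"]
        )
    except KeyError as e:
        raise ConfigError(f"montage.channels: missing field {e}") from e
    return Montage(
        channels=channels,
        source_detector_separation_cm=float(
            d.get("source_detector_separation_cm", 2.0)
        ),
        wavelengths_nm=tuple(float(w) for w in d.get("wavelengths_nm", (770, 850))),
        sampling_rate_hz=float(d.get("sampling_rate_hz", 10.0)),
    )


def _design_from_dict(d: dict) -> StudyDesign:
    kwargs: dict = {}
    if "conditions" in d:
        kwargs["conditions"] = tuple(d["conditions"])
    if "modality_map" in d:
        kwargs["modality_map"] = dict(d["modality_map"])
    if "familiarity_map" in d:
        kwargs["familiarity_map"] = {
            g: dict(v) for g, v in d["familiarity_map"].items()
        }
    if "baseline_duration_s" in d:
        kwargs["baseline_duration_s"] = float(d["baseline_duration_s"])
    if "stimulus_duration_range_s" in d:
        kwargs["stimulus_duration_range_s"] = tuple(
            float(x) for x in d["stimulus_duration_range_s"]
        )
    if "max_experimental_trials" in d:
        kwargs["max_experimental_trials"] = int(d["max_experimental_trials"])
    return StudyDesign(**kwargs)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a pipeline configuration; ``None`` loads the shipped default.

    Raises :class:`ConfigError` naming the offending field on any invariant
    violation (channel counts, hemisphere balance, ROI membership, design
    constants).
    """
    if path is None:
        text = (
            importlib.resources.files("babelnirs.data")
            .joinpath("default_config.yaml")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ConfigError(f"malformed YAML: {e}") from e
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    for section in ("montage", "rois", "design"):
        if section not in raw:
            raise ConfigError(f"missing section {section!r}")
    montage = _montage_from_dict(raw["montage"])
    rois = ROISet(
        inferior_frontal=tuple(int(i) for i in raw["rois"]["inferior_frontal"]),
        posterior_temporal=tuple(int(i) for i in raw["rois"]["posterior_temporal"]),
    )
    rois.validate(montage)
    design = _design_from_dict(raw["design"])

    def section(name: str, cls):
        d = raw.get(name, {})
        if name == "preprocess" and "extinction" in d:
            d = dict(d)
            d["extinction"] = {
                float(w): {k: float(v) for k, v in tab.items()}
                for w, tab in d["extinction"].items()
            }
        for key in ("epoch_window_s", "stimulus_window_s", "peak_window_s"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        try:
            return cls(**d)
        except TypeError as e:
            raise ConfigError(f"section {name!r}: {e}") from e

    return PipelineConfig(
        montage=montage,
        rois=rois,
        design=design,
        qc=section("qc", QCThresholds),
        preprocess=section("preprocess", PreprocessParams),
        analysis=section("analysis", AnalysisParams),
    )


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Serialize a configuration so that ``load_config`` round-trips it."""
    d = {
        "montage": {
            "channels": [asdict(c) for c in config.montage.channels],
            "source_detector_separation_cm":
                config.montage.source_detector_separation_cm,
            "wavelengths_nm": list(config.montage.wavelengths_nm),
            "sampling_rate_hz": config.montage.sampling_rate_hz,
        },
        "rois": {
            "inferior_frontal": list(config.rois.inferior_frontal),
            "posterior_temporal": list(config.rois.posterior_temporal),
        },
        "design": {
            "conditions": list(config.design.conditions),
            "modality_map": dict(config.design.modality_map),
            "familiarity_map": {
                g: dict(v) for g, v in config.design.familiarity_map.items()
            },
            "baseline_duration_s": config.design.baseline_duration_s,
            "stimulus_duration_range_s":
                list(config.design.stimulus_duration_range_s),
            "max_experimental_trials": config.design.max_experimental_trials,
        },
        "qc": asdict(config.qc),
        "preprocess": {
            **asdict(config.preprocess),
            "epoch_window_s": list(config.preprocess.epoch_window_s),
            "stimulus_window_s": list(config.preprocess.stimulus_window_s),
            "extinction": {
                w: dict(tab) for w, tab in config.preprocess.extinction.items()
            },
        },
        "analysis": {
            **asdict(config.analysis),
            "peak_window_s": list(config.analysis.peak_window_s),
        },
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
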