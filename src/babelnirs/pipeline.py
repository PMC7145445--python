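"""End-to-end orchestration: simulate -> qc -> preprocess -> univariate ->
roi -> mvpa, with a JSON run manifest.

The manifest records the configuration hash, the master seed and its
derived per-stage seeds, per-stage output digests, and attrition counters:
how many participants and trials each exclusion rule removed (channel QC,
looking time, amplitude rejection, the fewer-than-three-valid-trials rule).
A fixed master seed reproduces the whole run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import mvpa as mvpa_mod
from . import preprocess as pp_mod
from . import roi as roi_mod
from . import univariate as uni_mod
from .config import PipelineConfig, load_config, save_config
from .qc import apply_channel_rejection
from .recording import validate_recording
from .simulate import (
    HemodynamicGroundTruth, NoiseModel, make_participants, simulate_cohort,
)

STAGES = ("simulate", "qc", "preprocess", "univariate", "roi", "mvpa")


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed, kept below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def config_hash(config: PipelineConfig, tmpdir: Path) -> str:
    path = tmpdir / "_config_hash.yaml"
    save_config(config, path)
    h = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
    path.unlink()
    return h


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    stage_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # stage -> {file: sha256}
    counts: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig | None = None,
    outdir: str | Path = "babelnirs_run",
    seed: int = 0,
    group_sizes: tuple[int, int, int] = (19, 20, 21),
    stages: tuple[str, ...] = STAGES,
    n_permutations: int | None = None,
    scenario: str = "groups",
) -> RunManifest:
    """Run the requested pipeline stages on a simulated cohort.

    ``scenario`` selects the injected ground truth: ``"groups"`` (the
    illustrative group/hemisphere-dependent profile) or ``"null"`` (no
    class signal).  Stage outputs are written to ``outdir`` as TSV/JSON;
    later stages can be re-run from ``peaks.tsv`` via ``stages``.
    """
    config = config or load_config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed, config_hash=config_hash(config, outdir))
    for stage in STAGES:
        manifest.stage_seeds[stage] = derive_seed(seed, stage)

    requested = [s for s in STAGES if s in stages]
    counts = manifest.counts
    recordings = None
    averages_by_pid: dict = {}
    qc_by_pid: dict = {}
    groups: dict[str, str] = {}
    peaks = None

    if "simulate" in requested:
        participants = make_participants(*group_sizes)
        groups = {p.participant_id: p.group for p in participants}
        if scenario == "null":
            truth = HemodynamicGroundTruth.uniform(
                participants, config.design.conditions,
                config.montage.channel_ids, hbo2_amplitude=0.0,
            )
        else:
            truth = HemodynamicGroundTruth.scenario(
                participants, config.design, config.montage
            )
        noise = NoiseModel(seed=manifest.stage_seeds["simulate"],
                           dead_channel_probability=0.02)
        recordings, truth = simulate_cohort(
            config.design, participants, truth, noise, config.montage
        )
        truth.to_tsv(outdir / "ground_truth.tsv")
        breaches = {
            r.participant.participant_id: validate_recording(r, config.design)
            for r in recordings
        }
        assert not any(breaches.values()), breaches
        counts["participants_simulated"] = len(recordings)
        manifest.outputs["simulate"] = {
            "ground_truth.tsv": _digest(outdir / "ground_truth.tsv")
        }

    if "qc" in requested:
        if recordings is None:
            raise RuntimeError("qc stage needs the simulate stage in this run")
        qc_rows = []
        excluded = []
        for rec in recordings:
            report = apply_channel_rejection(rec, config.qc)
            qc_by_pid[rec.participant.participant_id] = report
            qc_rows.append(report.summary())
            if report.participant_excluded:
                excluded.append(rec.participant.participant_id)
        pd.DataFrame(qc_rows).to_csv(outdir / "qc_summary.tsv", sep="\t",
                                     index=False)
        counts["participants_excluded_qc"] = len(excluded)
        counts["channels_rejected_total"] = int(
            sum(r.n_rejected for r in qc_by_pid.values())
        )
        recordings = [
            r for r in recordings
            if r.participant.participant_id not in excluded
        ]
        manifest.outputs["qc"] = {
            "qc_summary.tsv": _digest(outdir / "qc_summary.tsv")
        }

    if "preprocess" in requested:
        if recordings is None:
            raise RuntimeError("preprocess stage needs upstream stages")
        n_looking_dropped = 0
        n_trials_invalidated = 0
        for rec in recordings:
            pid = rec.participant.participant_id
            avgs = pp_mod.preprocess_recording(
                rec, config.preprocess, qc_by_pid.get(pid),
                config.montage, config.design,
            )
            averages_by_pid[pid] = avgs
            n_looking_dropped += sum(
                1 for p in rec.looking_proportion
                if p < config.preprocess.looking_threshold
            )
        counts["trials_dropped_looking"] = n_looking_dropped
        peaks = uni_mod.extract_peaks(
            [a for avgs in averages_by_pid.values() for a in avgs],
            config.analysis.peak_window_s,
        )
        peaks["group"] = peaks.participant_id.map(groups)
        # %.17g: exact binary round-trip so resumed runs are bit-identical
        peaks.to_csv(outdir / "peaks.tsv", sep="\t", index=False,
                     float_format="%.17g")
        counts["participants_with_modality_averages"] = int(
            peaks[peaks.kind == "modality"].participant_id.nunique()
        )
        manifest.outputs["preprocess"] = {
            "peaks.tsv": _digest(outdir / "peaks.tsv")
        }

    if peaks is None and any(
        s in requested for s in ("univariate", "roi", "mvpa")
    ):
        peaks_path = outdir / "peaks.tsv"
        if not peaks_path.exists():
            raise RuntimeError(
                "downstream stages need peaks.tsv from a previous run"
            )
        peaks = pd.read_csv(peaks_path, sep="\t", float_precision="round_trip")
        groups = dict(zip(peaks.participant_id, peaks.group))

    if "univariate" in requested:
        maps = []
        for key in ("spoken", "signed"):
            hbo2_map = uni_mod.channel_map_tests(
                peaks, "hbo2", key,
                n_channels_fdr=config.analysis.n_channels_fdr,
            )
            hhb_map = uni_mod.channel_map_tests(
                peaks, "hhb", key,
                n_channels_fdr=config.analysis.n_channels_fdr,
            )
            if hbo2_map.empty or hhb_map.empty:
                continue
            labels = uni_mod.classify_activation(hbo2_map, hhb_map)
            merged = hbo2_map.merge(labels, on="channel", how="left")
            maps.append(merged)
            maps.append(hhb_map.assign(label=""))
        table = pd.concat(maps, ignore_index=True) if maps else pd.DataFrame()
        table.to_csv(outdir / "univariate.tsv", sep="\t", index=False)
        if not table.empty:
            counts["channels_significant_fdr"] = int(
                table[table.chromophore == "hbo2"].significant_fdr.sum()
            )
        manifest.outputs["univariate"] = {
            "univariate.tsv": _digest(outdir / "univariate.tsv")
        }

    if "roi" in requested:
        roi_table = roi_mod.build_roi_table(
            peaks, config.rois, config.montage, groups
        )
        roi_table.to_csv(outdir / "roi_table.tsv", sep="\t", index=False)
        anova_rows = []
        for roi_name in roi_mod.ROI_NAMES:
            sub = roi_table[roi_table.roi == roi_name]
            if sub.participant_id.nunique() < 6:
                continue
            aov = roi_mod.mixed_anova(sub)
            aov.insert(0, "roi", roi_name)
            anova_rows.append(aov)
        aov_table = (pd.concat(anova_rows, ignore_index=True)
                     if anova_rows else pd.DataFrame())
        aov_table.to_csv(outdir / "roi_anova.tsv", sep="\t", index=False)
        manifest.outputs["roi"] = {
            "roi_table.tsv": _digest(outdir / "roi_table.tsv"),
            "roi_anova.tsv": _digest(outdir / "roi_anova.tsv"),
        }

    if "mvpa" in requested:
        n_perm = n_permutations or config.analysis.n_permutations
        results = {}
        seed_m = manifest.stage_seeds["mvpa"]
        subsets = {
            "all": config.montage.channel_ids,
            "left": config.montage.hemisphere_ids("left"),
            "right": config.montage.hemisphere_ids("right"),
        }
        group_names = ["all"] + sorted(set(groups.values()))
        for gi, group in enumerate(group_names):
            if group == "all":
                sub_peaks = peaks
            else:
                sub_peaks = peaks[peaks.group == group]
            for si, (subset_name, channels) in enumerate(subsets.items()):
                try:
                    feats = mvpa_mod.build_features(
                        sub_peaks, ("spoken", "signed"), channels
                    )
                    res = mvpa_mod.permutation_test(
                        feats, n_perm, seed=seed_m + 100 * gi + si,
                        C=config.analysis.svm_c,
                    )
                except ValueError as e:
                    results[f"{group}/{subset_name}"] = {"error": str(e)}
                    continue
                results[f"{group}/{subset_name}"] = {
                    "accuracy": res.observed,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                    "n_participants": feats.n_participants,
                    "n_trials": len(feats.y),
                }
        (outdir / "mvpa.json").write_text(json.dumps(results, indent=1))
        counts["mvpa_cells"] = len(results)
        manifest.outputs["mvpa"] = {"mvpa.json": _digest(outdir / "mvpa.json")}

    manifest.save(outdir / "manifest.json")
    return manifest


def summarize_run(outdir: str | Path) -> str:
    """Human-readable report of a pipeline run's output files."""
    outdir = Path(outdir)
    lines = ["# Pipeline run summary", ""]
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
        lines.append(f"seed: {manifest.seed}   config: {manifest.config_hash}")
        for k, v in manifest.counts.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
    uni_path = outdir / "univariate.tsv"
    if uni_path.exists():
        table = pd.read_csv(uni_path, sep="\t")
        if not table.empty:
            lines.append("## Channel activation maps (HbO2)")
            hbo2 = table[table.chromophore == "hbo2"]
            for key, grp in hbo2.groupby("key"):
                n_unc = int(grp.significant_uncorrected.sum())
                n_fdr = int(grp.significant_fdr.sum())
                lines.append(
                    f"  {key}: {n_unc} channels significant uncorrected, "
                    f"{n_fdr} after FDR"
                )
            lines.append("")
    else:
        lines.append("## Univariate stage: not run\n")
    aov_path = outdir / "roi_anova.tsv"
    if aov_path.exists():
        aov = pd.read_csv(aov_path, sep="\t")
        if not aov.empty:
            lines.append("## ROI ANOVA")
            for _, r in aov.iterrows():
                lines.append(
                    f"  {r.roi} / {r.effect}: F({r.df_num}, {r.df_den}) = "
                    f"{r.F:.2f}, p = {r.p:.4f}, partial eta^2 = "
                    f"{r.partial_eta_sq:.3f}"
                )
            lines.append("")
    else:
        lines.append("## ROI stage: not run\n")
    mvpa_path = outdir / "mvpa.json"
    if mvpa_path.exists():
        results = json.loads(mvpa_path.read_text())
        lines.append("## MVPA decoding (spoken vs signed)")
        for cell, r in results.items():
            if "error" in r:
                lines.append(f"  {cell}: not computed ({r['error']})")
            else:
                lines.append(
                    f"  {cell}: accuracy = {r['accuracy']:.3f}, "
                    f"p = {r['p_value']:.4f} ({r['n_trials']} trials)"
                )
    else:
        lines.append("## MVPA stage: not run")
    return "\n".join(lines) + "\n"
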