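"""End-to-end pipeline driver, configuration, and report tables.

``run_pipeline`` wires the stages together: simulate (or load) epochs,
artifact-reject and RT-filter them, quantify the Ne/Pe condition effects,
then run the balanced SVM analyses for every mode (two within-task, two
across-task) and feature set (ne, pe, combined), emitting one TSV report
table per mode x feature set — twelve tables for the default analysis —
plus ERP statistics and a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import MODES, ClassificationReport, repeat_and_aggregate
from .epochs import Epochs
from .erp_stats import (
    NE_WINDOW,
    PE_WINDOW,
    rm_anova_2x2,
    rt_filter,
    subject_condition_table,
)
from .features import FeatureSetSpec
from .montage import Montage, analysis_montage, standard_montage
from .preprocess import FilterSpec, RejectionConfig, bandpass_filter, reject_artifact_trials
from .simulate import SimulationConfig, make_default_config, simulate_cohort

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "write_report_table",
    "report_to_frame",
]

logger = logging.getLogger(__name__)

WITHIN_COLUMNS = (
    "Subject",
    "Accuracy (mean)", "Accuracy (min)", "Accuracy (max)",
    "p (mean)", "p (min)", "p (max)",
)
TRANSFER_COLUMNS = WITHIN_COLUMNS + (
    "trials correct (mean)", "trials correct (min)", "trials correct (max)",
    "trials (total)",
)


@dataclass
class PipelineConfig:
    """Everything a full run needs; serialisable as flat-keyed YAML."""

    simulation: SimulationConfig
    filter_spec: FilterSpec = FilterSpec()
    apply_filter: bool = False  # simulator output is already band-limited
    rejection: RejectionConfig = RejectionConfig()
    feature_sets: tuple[str, ...] = ("combined", "ne", "pe")
    modes: tuple[str, ...] = MODES
    n_repeats: int = 10
    n_perm: int = 1000
    cv_folds: int = 10
    analysis_seed: int = 0
    output_dir: str = "erpdecode_output"

    # ------------------------------------------------------------- flat config
    def to_flat_dict(self) -> dict:
        sim = self.simulation
        flat = {
            "simulation.n_subjects": sim.n_subjects,
            "simulation.montage": _montage_preset_name(sim.montage),
            "simulation.sampling_rate": sim.sampling_rate,
            "simulation.epoch_window": list(sim.epoch_window),
            "simulation.between_subject_amplitude_sd": sim.between_subject_amplitude_sd,
            "simulation.seed": sim.seed,
            "simulation.noise.white_sd": sim.noise.white_sd,
            "simulation.noise.pink_sd": sim.noise.pink_sd,
            "simulation.noise.alpha_sd": sim.noise.alpha_sd,
        }
        for tname, task in sim.tasks.items():
            base = f"simulation.tasks.{tname}"
            flat[f"{base}.error_rate"] = task.error_rate
            flat[f"{base}.n_trials_range"] = list(task.n_trials_range)
            flat[f"{base}.rt_mean_correct"] = task.rt_mean_correct
            flat[f"{base}.rt_mean_error"] = task.rt_mean_error
            flat[f"{base}.rt_sd"] = task.rt_sd
            for cname, comp in (("ne", task.ne), ("pe", task.pe)):
                cbase = f"{base}.{cname}"
                flat[f"{cbase}.peak_latency"] = comp.peak_latency
                flat[f"{cbase}.width"] = comp.width
                flat[f"{cbase}.peak_channel"] = comp.peak_channel
                flat[f"{cbase}.spatial_sigma"] = comp.spatial_sigma
                flat[f"{cbase}.amplitude_error"] = comp.amplitude_error
                flat[f"{cbase}.amplitude_correct"] = comp.amplitude_correct
        flat.update(
            {
                "preprocessing.highpass_hz": self.filter_spec.highpass_hz,
                "preprocessing.lowpass_hz": self.filter_spec.lowpass_hz,
                "preprocessing.apply_filter": self.apply_filter,
                "preprocessing.z_criterion": self.rejection.z_criterion,
                "preprocessing.max_reject_fraction": self.rejection.max_reject_fraction,
                "analysis.feature_sets": list(self.feature_sets),
                "analysis.modes": list(self.modes),
                "analysis.n_repeats": self.n_repeats,
                "analysis.n_perm": self.n_perm,
                "analysis.cv_folds": self.cv_folds,
                "analysis.seed": self.analysis_seed,
                "output.dir": self.output_dir,
            }
        )
        return flat

    @classmethod
    def from_flat_dict(cls, flat: dict) -> "PipelineConfig":
        defaults = cls.default()
        base = defaults.to_flat_dict()
        unknown = set(flat) - set(base)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        base.update(flat)
        sim = make_default_config(
            n_subjects=int(base["simulation.n_subjects"]),
            montage=_montage_from_preset(base["simulation.montage"]),
            seed=int(base["simulation.seed"]),
        )
        sim.sampling_rate = float(base["simulation.sampling_rate"])
        sim.epoch_window = tuple(base["simulation.epoch_window"])
        sim.between_subject_amplitude_sd = float(base["simulation.between_subject_amplitude_sd"])
        sim.noise.white_sd = float(base["simulation.noise.white_sd"])
        sim.noise.pink_sd = float(base["simulation.noise.pink_sd"])
        sim.noise.alpha_sd = float(base["simulation.noise.alpha_sd"])
        for tname, task in sim.tasks.items():
            b = f"simulation.tasks.{tname}"
            task.error_rate = float(base[f"{b}.error_rate"])
            task.n_trials_range = tuple(int(v) for v in base[f"{b}.n_trials_range"])
            task.rt_mean_correct = float(base[f"{b}.rt_mean_correct"])
            task.rt_mean_error = float(base[f"{b}.rt_mean_error"])
            task.rt_sd = float(base[f"{b}.rt_sd"])
            for cname, comp in (("ne", task.ne), ("pe", task.pe)):
                cb = f"{b}.{cname}"
                comp.peak_latency = float(base[f"{cb}.peak_latency"])
                comp.width = float(base[f"{cb}.width"])
                comp.peak_channel = str(base[f"{cb}.peak_channel"])
                comp.spatial_sigma = float(base[f"{cb}.spatial_sigma"])
                comp.amplitude_error = float(base[f"{cb}.amplitude_error"])
                comp.amplitude_correct = float(base[f"{cb}.amplitude_correct"])
        sim.validate()
        return cls(
            simulation=sim,
            filter_spec=FilterSpec(
                highpass_hz=float(base["preprocessing.highpass_hz"]),
                lowpass_hz=float(base["preprocessing.lowpass_hz"]),
            ),
            apply_filter=bool(base["preprocessing.apply_filter"]),
            rejection=RejectionConfig(
                z_criterion=float(base["preprocessing.z_criterion"]),
                max_reject_fraction=float(base["preprocessing.max_reject_fraction"]),
            ),
            feature_sets=tuple(base["analysis.feature_sets"]),
            modes=tuple(base["analysis.modes"]),
            n_repeats=int(base["analysis.n_repeats"]),
            n_perm=int(base["analysis.n_perm"]),
            cv_folds=int(base["analysis.cv_folds"]),
            analysis_seed=int(base["analysis.seed"]),
            output_dir=str(base["output.dir"]),
        )

    @classmethod
    def default(cls, n_subjects: int = 20, seed: int = 0) -> "PipelineConfig":
        return cls(simulation=make_default_config(n_subjects=n_subjects, seed=seed))

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_flat_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_flat_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_flat_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _montage_preset_name(montage: Montage) -> str:
    if montage.channel_names == standard_montage().channel_names:
        return "full"
    if montage.channel_names == analysis_montage().channel_names:
        return "analysis"
    return ",".join(montage.channel_names)


def _montage_from_preset(name: str) -> Montage:
    if name == "full":
        return standard_montage()
    if name == "analysis":
        return analysis_montage()
    return standard_montage().subset(name.split(","))


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    tool_version: str
    seeds: dict
    stage_counts: dict
    started: str
    finished: str = ""

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path


def report_to_frame(reports: list[ClassificationReport], mode: str) -> pd.DataFrame:
    """Per-subject summary rows in the standard report-table column layout."""
    rows = []
    for rep in sorted(reports, key=lambda r: r.subject):
        am, amin, amax = rep.accuracy_mean_min_max
        pm, pmin, pmax = rep.p_mean_min_max
        row = {
            "Subject": rep.subject + 1,  # 1-based in printed tables
            "Accuracy (mean)": am, "Accuracy (min)": amin, "Accuracy (max)": amax,
            "p (mean)": pm, "p (min)": pmin, "p (max)": pmax,
        }
        if not mode.startswith("within-"):
            tm, tmin, tmax = rep.trials_correct_mean_min_max
            row.update(
                {
                    "trials correct (mean)": tm,
                    "trials correct (min)": tmin,
                    "trials correct (max)": tmax,
                    "trials (total)": rep.trials_total,
                }
            )
        rows.append(row)
    columns = WITHIN_COLUMNS if mode.startswith("within-") else TRANSFER_COLUMNS
    return pd.DataFrame(rows, columns=list(columns))


def write_report_table(reports: list[ClassificationReport], path, mode: str) -> Path:
    """Write one mode x feature-set report as TSV (3-decimal numbers)."""
    frame = report_to_frame(reports, mode)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.3f")
    return path


def _preprocess_subject(epochs: Epochs, config: PipelineConfig) -> tuple[Epochs, dict]:
    n_in = epochs.n_trials
    if config.apply_filter:
        epochs = bandpass_filter(epochs, config.filter_spec)
    epochs, rejected = reject_artifact_trials(epochs, config.rejection)
    epochs = rt_filter(epochs)
    counts = {"in": n_in, "artifact_rejected": len(rejected), "out": epochs.n_trials}
    return epochs, counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate, preprocess, quantify ERPs, classify, and write all outputs.

    Returns a dict with the report tables (``{(mode, feature_set):
    DataFrame}``), the ERP statistics frame, and the manifest.
    """
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("simulating cohort of %d subjects", config.simulation.n_subjects)
    cohort = simulate_cohort(config.simulation)

    stage_counts = {}
    for s_idx, entry in enumerate(cohort):
        for task, epochs in entry.items():
            entry[task], counts = _preprocess_subject(epochs, config)
            stage_counts[f"subject{s_idx}.{task}"] = counts

    # ERP statistics: Ne and Pe 2x2 rm-ANOVAs on the windowed means
    stats_rows = []
    for cw in (NE_WINDOW, PE_WINDOW):
        table = subject_condition_table(cohort, cw)
        if config.simulation.n_subjects >= 3:
            for res in rm_anova_2x2(table):
                stats_rows.append(
                    {
                        "component": cw.name, "effect": res.effect, "F": res.F,
                        "df1": res.df[0], "df2": res.df[1], "p": res.p, "eta_p2": res.eta_p2,
                    }
                )
    stats_frame = pd.DataFrame(stats_rows)
    stats_frame.to_csv(out_dir / "erp_anova.tsv", sep="\t", index=False, float_format="%.4f")

    tables = {}
    for mode in config.modes:
        for fs_name in config.feature_sets:
            spec = FeatureSetSpec(fs_name)
            reports = []
            for s_idx, entry in enumerate(cohort):
                logger.info("classifying subject %d, mode %s, features %s", s_idx, mode, fs_name)
                reports.append(
                    repeat_and_aggregate(
                        entry,
                        spec,
                        mode,
                        n_repeats=config.n_repeats,
                        n_perm=config.n_perm,
                        master_seed=_stage_seed(config.analysis_seed, mode, fs_name, s_idx),
                        k=config.cv_folds,
                    )
                )
            path = out_dir / f"report_{mode}_{fs_name}.tsv"
            write_report_table(reports, path, mode)
            tables[(mode, fs_name)] = report_to_frame(reports, mode)

    manifest = RunManifest(
        config_hash=config.config_hash(),
        tool_version=__version__,
        seeds={"simulation": config.simulation.seed, "analysis": config.analysis_seed},
        stage_counts=stage_counts,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out_dir / "manifest.json")
    config.to_yaml(out_dir / "config.yaml")
    return {"tables": tables, "erp_stats": stats_frame, "manifest": manifest}


def _stage_seed(analysis_seed: int, mode: str, fs_name: str, subject: int) -> int:
    key = f"{mode}|{fs_name}|{subject}".encode()
    digest = hashlib.sha256(key + analysis_seed.to_bytes(8, "little", signed=True)).digest()
    return int.from_bytes(digest[:4], "little")
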