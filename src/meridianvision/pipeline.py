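"""End-to-end orchestration: simulate a cohort, run staircase sessions,
summarize CSFs, generate and analyze sweep-VEP EEG, and build the
meridional-disparity report, all reproducibly from one seed.

The single run seed fans out to per-eye, per-stage substreams through a
counter-based `numpy.random.SeedSequence` scheme, so any stage can be
re-run in isolation and reproduce its outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .csf_metrics import CSFSummarizer, generative_aulcsf
from .staircase import StaircaseConfig, measure_csf_thresholds, session_to_frame
from .stats import (DisparityRecord, build_disparity_report, format_report,
                    group_contrast)
from .sweep_vep import SweepVEPAnalyzer
from .synthetic_data import (CohortSpec, GroupSpec, NoiseConfig, SweepStimulus,
                             _LOG_PARABOLA_K, generate_cohort,
                             generate_sweep_trial)

MERIDIANS = ("strong", "weak")


def substream(seed: int, *keys) -> np.random.Generator:
    """Derive an independent reproducible generator from the run seed and a
    tuple of stage/eye keys (strings are hashed with crc32)."""
    ints = [int(seed)]
    for k in keys:
        ints.append(zlib.crc32(k.encode()) if isinstance(k, str) else int(k))
    return np.random.default_rng(np.random.SeedSequence(ints))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one simulated study run."""

    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    stimulus: SweepStimulus = field(default_factory=SweepStimulus)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    sampling_rate: float = 2048.0
    snr_criterion: float = 3.0
    forgetting_factor: float = 1.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and not isinstance(d["cohort"], CohortSpec):
            groups = tuple(GroupSpec(**g) if not isinstance(g, GroupSpec) else g
                           for g in d["cohort"].get("groups", ()))
            d["cohort"] = CohortSpec(groups=groups)
        for key, typ in (("staircase", StaircaseConfig),
                         ("stimulus", SweepStimulus), ("noise", NoiseConfig)):
            if key in d and not isinstance(d[key], typ):
                sub = dict(d[key])
                if key == "staircase" and "sf_grid" in sub:
                    sub["sf_grid"] = tuple(sub["sf_grid"])
                d[key] = typ(**sub)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def demo_config(seed: int = 0, n_eyes: tuple = (3, 3), n_trials: int = 60,
                n_repeats: int = 4) -> RunConfig:
    """A scaled-down run (few eyes, shorter staircases, fewer sweep repeats)
    for demos and quick checks; distributions are unchanged."""
    base = CohortSpec()
    groups = tuple(dataclasses.replace(g, n_eyes=n)
                   for g, n in zip(base.groups, n_eyes))
    return RunConfig(
        seed=seed,
        cohort=CohortSpec(groups=groups),
        staircase=StaircaseConfig(n_trials=n_trials),
        stimulus=SweepStimulus(n_repeats=n_repeats),
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def simulate_cohort_stage(config: RunConfig) -> list:
    return generate_cohort(config.cohort, substream(config.seed, "cohort"))


def staircase_stage(config: RunConfig, cohort) -> tuple:
    """Run every eye's 14-block staircase session.

    Returns ``(trial_logs, thresholds)``: the concatenated trial-log frame
    and a tidy frame of per-cell contrast thresholds.
    """
    logs, rows = [], []
    for i, eye in enumerate(cohort):
        rng = substream(config.seed, "staircase", i)
        runs = measure_csf_thresholds(eye.observer, config.staircase, rng)
        frame = session_to_frame(runs)
        frame.insert(0, "eye_id", eye.eye_id)
        frame.insert(1, "group", eye.group)
        logs.append(frame)
        for (meridian, sf), run in runs.items():
            rows.append({"eye_id": eye.eye_id, "group": eye.group,
                         "meridian": meridian, "sf_cpd": sf,
                         "threshold": run.threshold_estimate,
                         "converged": run.converged,
                         "n_reversals": len(run.reversal_indices)})
    return pd.concat(logs, ignore_index=True), pd.DataFrame(rows)


def csf_stage(config: RunConfig, thresholds: pd.DataFrame) -> pd.DataFrame:
    """Summarize per-cell thresholds into per-(eye, meridian) CSF metrics."""
    rows = []
    summarizer = CSFSummarizer()
    for (eye_id, group, meridian), sub in thresholds.groupby(
            ["eye_id", "group", "meridian"], sort=False):
        cell = dict(zip(sub["sf_cpd"], sub["threshold"]))
        try:
            summarizer.fit(cell)
            rows.append({
                "eye_id": eye_id, "group": group, "meridian": meridian,
                "aulcsf": summarizer.aulcsf_,
                "csf_acuity": summarizer.csf_acuity_,
                "sf_threshold_80": summarizer.sf_threshold_,
                "acuity_extrapolated": summarizer.extrapolated_["csf_acuity"],
                "sf80_extrapolated": summarizer.extrapolated_["sf_threshold"],
                "n_omitted": len(summarizer.omitted_sfs_),
            })
        except ValueError as exc:
            rows.append({"eye_id": eye_id, "group": group, "meridian": meridian,
                         "aulcsf": math.nan, "csf_acuity": math.nan,
                         "sf_threshold_80": math.nan,
                         "acuity_extrapolated": False,
                         "sf80_extrapolated": False,
                         "n_omitted": -1, "error": str(exc)})
    return pd.DataFrame(rows)


def svep_stage(config: RunConfig, cohort) -> tuple:
    """Generate and analyze each eye's sweep-VEP trials for both meridians.

    Returns ``(responses, fits)``: per-epoch amplitude/SE/noise/SNR rows and
    per-(eye, meridian) threshold-fit rows.
    """
    analyzer = SweepVEPAnalyzer(
        temporal_freq=config.stimulus.temporal_freq,
        criterion_snr=config.snr_criterion,
        forgetting_factor=config.forgetting_factor,
    )
    resp_rows, fit_rows = [], []
    for i, eye in enumerate(cohort):
        for meridian in MERIDIANS:
            rng = substream(config.seed, "svep", i, meridian)
            trials = [
                generate_sweep_trial(eye.observer, config.stimulus, meridian,
                                     config.noise, rng,
                                     sampling_rate=config.sampling_rate)
                for _ in range(config.stimulus.n_repeats)
            ]
            analyzer.fit(trials)
            for k, sf in enumerate(analyzer.sweep_sfs_):
                resp_rows.append({
                    "eye_id": eye.eye_id, "group": eye.group,
                    "meridian": meridian, "epoch": k, "sf_cpd": sf,
                    "amplitude_uv": analyzer.amplitudes_[k],
                    "vector_se_uv": analyzer.vector_se_[k],
                    "noise_uv": analyzer.noise_amplitudes_[k],
                    "snr": analyzer.snr_[k],
                })
            fit = analyzer.fit_
            fit_rows.append({
                "eye_id": eye.eye_id, "group": eye.group, "meridian": meridian,
                "threshold_cpd": fit.intercept_sf, "slope_uv_per_cpd": fit.slope,
                "window_start": fit.included_epochs[0] if fit.included_epochs else -1,
                "window_end": fit.included_epochs[-1] if fit.included_epochs else -1,
                "valid": fit.valid, "reason": fit.reason,
            })
    return pd.DataFrame(resp_rows), pd.DataFrame(fit_rows)


def disparity_records(summaries: pd.DataFrame, fits: pd.DataFrame,
                      responses: pd.DataFrame | None = None,
                      thresholds: pd.DataFrame | None = None) -> list:
    """Assemble per-eye strong-minus-weak records for every reported metric.

    sVEP thresholds are excluded pairwise: an eye contributes only when both
    meridians' regression fits pass the SNR criterion.
    """
    records: list[DisparityRecord] = []

    wide = summaries.pivot_table(index=["eye_id", "group"], columns="meridian",
                                 values=["aulcsf", "csf_acuity",
                                         "sf_threshold_80"], aggfunc="first")
    for metric in ("aulcsf", "csf_acuity", "sf_threshold_80"):
        for (eye_id, group), row in wide[metric].iterrows():
            if np.isfinite(row.get("strong", np.nan)) and np.isfinite(row.get("weak", np.nan)):
                records.append(DisparityRecord(eye_id, group, metric,
                                               row["strong"], row["weak"]))

    fw = fits.pivot_table(index=["eye_id", "group"], columns="meridian",
                          values=["threshold_cpd", "valid"], aggfunc="first")
    for (eye_id, group), row in fw.iterrows():
        if bool(row[("valid", "strong")]) and bool(row[("valid", "weak")]):
            records.append(DisparityRecord(eye_id, group, "svep_threshold",
                                           row[("threshold_cpd", "strong")],
                                           row[("threshold_cpd", "weak")]))

    if responses is not None:
        rw = responses.pivot_table(index=["eye_id", "group", "sf_cpd"],
                                   columns="meridian", values="amplitude_uv",
                                   aggfunc="first")
        for (eye_id, group, sf), row in rw.iterrows():
            records.append(DisparityRecord(
                eye_id, group, f"amplitude@{round(sf, 1)}cpd",
                row["strong"], row["weak"]))

    if thresholds is not None:
        conv = thresholds[thresholds["converged"]]
        tw = conv.pivot_table(index=["eye_id", "group", "sf_cpd"],
                              columns="meridian", values="threshold",
                              aggfunc="first")
        for (eye_id, group, sf), row in tw.iterrows():
            if np.isfinite(row.get("strong", np.nan)) and np.isfinite(row.get("weak", np.nan)):
                records.append(DisparityRecord(
                    eye_id, group, f"log_sensitivity@{sf}cpd",
                    -math.log10(row["strong"]), -math.log10(row["weak"])))
    return records


# ---------------------------------------------------------------------------
# full study and validation
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_study(config: RunConfig, output_dir) -> Path:
    """Run the whole simulated study and write all artifacts to ``output_dir``.

    Writes cohort.csv, trial_logs.csv, csf_thresholds.csv, csf_summaries.csv,
    svep_responses.csv, svep_fits.csv, disparity_report.csv, report.txt,
    group_contrasts.csv, config.yaml and manifest.json (seed, package
    version, per-file sha256 checksums).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = simulate_cohort_stage(config)
    cohort_df = pd.DataFrame([{
        "eye_id": e.eye_id, "group": e.group,
        "peak_gain_strong": e.observer.csf_strong.peak_gain,
        "peak_gain_weak": e.observer.csf_weak.peak_gain,
        "vep_threshold_strong": e.observer.vep_threshold_strong,
        "vep_threshold_weak": e.observer.vep_threshold_weak,
        "vep_peak_amplitude": e.observer.vep_peak_amplitude,
    } for e in cohort])

    trial_logs, thresholds = staircase_stage(config, cohort)
    summaries = csf_stage(config, thresholds)
    responses, fits = svep_stage(config, cohort)

    records = disparity_records(summaries, fits, responses, thresholds)
    report = build_disparity_report(records)

    contrasts = []
    group_names = [g.name for g in config.cohort.groups]
    if len(group_names) == 2:
        for metric in ("aulcsf", "csf_acuity", "sf_threshold_80",
                       "svep_threshold"):
            per_group = {
                g: [r.disparity for r in records
                    if r.group == g and r.metric == metric]
                for g in group_names
            }
            a, b = per_group[group_names[0]], per_group[group_names[1]]
            if len(a) >= 3 and len(b) >= 3:
                try:
                    c = group_contrast(b, a)  # second group minus first
                except ValueError:
                    continue
                contrasts.append({
                    "metric": metric,
                    "comparison": f"{group_names[1]}-{group_names[0]}",
                    "mean_diff": c.mean_diff, "se": c.se, "t": c.t_statistic,
                    "df": c.degrees_of_freedom, "p": c.p_value,
                })

    files = {
        "cohort.csv": cohort_df, "trial_logs.csv": trial_logs,
        "csf_thresholds.csv": thresholds, "csf_summaries.csv": summaries,
        "svep_responses.csv": responses, "svep_fits.csv": fits,
        "disparity_report.csv": report,
        "group_contrasts.csv": pd.DataFrame(contrasts),
    }
    for name, frame in files.items():
        frame.to_csv(out / name, index=False)
    (out / "report.txt").write_text(format_report(report))
    config.to_yaml(out / "config.yaml")

    manifest = {
        "package": "meridianvision",
        "version": __version__,
        "seed": config.seed,
        "n_eyes": len(cohort),
        "checksums": {name: _sha256(out / name)
                      for name in sorted([*files, "report.txt", "config.yaml"])},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _generative_crossing(csf, level: float) -> float:
    """log10 sf of the descending-limb crossing of a truncated log-parabola."""
    log_peak = math.log10(csf.peak_gain)
    if level > log_peak:
        raise ValueError("level above peak sensitivity")
    return (math.log10(csf.peak_sf)
            + csf.log_bandwidth * math.sqrt((log_peak - level) / _LOG_PARABOLA_K))


@dataclass
class ValidationReport:
    metrics: pd.DataFrame             # per eye x meridian, generative vs estimated
    contrast_thresholds: pd.DataFrame  # per eye x meridian x sf
    summary: dict                      # recovery-error summaries


def validate_pipeline(config: RunConfig) -> ValidationReport:
    """Parameter-recovery harness: run the pipeline with the generative truths
    retained and report (generative, estimated) pairs and error summaries."""
    cohort = simulate_cohort_stage(config)
    _, thresholds = staircase_stage(config, cohort)
    summaries = csf_stage(config, thresholds)
    _, fits = svep_stage(config, cohort)
    by_eye = {e.eye_id: e.observer for e in cohort}

    p_conv = 0.5 ** (1.0 / 3.0)  # 3-down-1-up convergence probability
    thr_rows = []
    for _, row in thresholds.iterrows():
        obs = by_eye[row["eye_id"]]
        gen = obs.contrast_threshold_at(p_conv, row["sf_cpd"], row["meridian"])
        thr_rows.append({
            "eye_id": row["eye_id"], "meridian": row["meridian"],
            "sf_cpd": row["sf_cpd"], "generative": gen,
            "estimated": row["threshold"], "converged": row["converged"],
            "log10_error": (math.log10(row["threshold"] / gen)
                            if row["converged"] else math.nan),
        })
    thr_frame = pd.DataFrame(thr_rows)

    met_rows = []
    for _, row in summaries.iterrows():
        obs = by_eye[row["eye_id"]]
        csf = obs.csf(row["meridian"])
        met_rows.append({
            "eye_id": row["eye_id"], "meridian": row["meridian"],
            "metric": "aulcsf", "generative": generative_aulcsf(csf),
            "estimated": row["aulcsf"],
        })
        met_rows.append({
            "eye_id": row["eye_id"], "meridian": row["meridian"],
            "metric": "csf_acuity",
            "generative": _generative_crossing(csf, 0.0),
            "estimated": row["csf_acuity"],
        })
        met_rows.append({
            "eye_id": row["eye_id"], "meridian": row["meridian"],
            "metric": "sf_threshold_80",
            "generative": 10.0 ** _generative_crossing(csf, math.log10(1 / 0.8)),
            "estimated": row["sf_threshold_80"],
        })
    for _, row in fits.iterrows():
        obs = by_eye[row["eye_id"]]
        met_rows.append({
            "eye_id": row["eye_id"], "meridian": row["meridian"],
            "metric": "svep_threshold",
            "generative": obs.vep_threshold(row["meridian"]),
            "estimated": row["threshold_cpd"] if row["valid"] else math.nan,
        })
    met_frame = pd.DataFrame(met_rows)
    met_frame["error"] = met_frame["estimated"] - met_frame["generative"]

    summary = {
        "median_abs_log10_contrast_error":
            float(thr_frame["log10_error"].abs().median()),
        "staircase_convergence_rate": float(thr_frame["converged"].mean()),
    }
    for metric, sub in met_frame.groupby("metric"):
        summary[f"median_abs_error_{metric}"] = float(sub["error"].abs().median())
    return ValidationReport(metrics=met_frame, contrast_thresholds=thr_frame,
                            summary=summary)
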