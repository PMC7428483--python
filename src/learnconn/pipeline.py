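"""End-to-end orchestration: inputs -> preprocessing -> graphs -> statistics.

A run is driven by a :class:`RunConfig` (readable from YAML).  Inputs come
from one of three modes: ``simulate`` (the synthetic cohort generator),
``roi-tsv`` (per-run node time-series tables) or ``nifti`` (4-D volumes plus
a node-coordinate table).  Every run is preprocessed (initial volumes
dropped, high-pass filtered), reduced to the correlation graph at the
configured link proportion, and summarized by the within-/between-network
statistics; the cohort is then analyzed with the nonparametric design and a
relation table in the style of the study's summary table is emitted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from learnconn import network, preprocess, stats, synthetic

_version = "0.1.0"

log = logging.getLogger("learnconn")

METRIC_FAMILIES = {
    "learning": synthetic.LEARNING_FAMILY,
    "test": synthetic.TEST_FAMILY,
}
METRIC_COLUMNS = ("within_DMN", "within_FPN", "between_DMN_FPN")


@dataclass
class RunConfig:
    """All pipeline settings; every analysis constant is a named key."""

    mode: str = "simulate"  # simulate | roi-tsv | nifti
    input_dir: str | None = None
    output_dir: str = "learnconn_out"
    threshold_p: float = network.DEFAULT_THRESHOLD_P
    ranking: str = "signed"
    drop_volumes: int = preprocess.DEFAULT_DROP_VOLUMES
    highpass_hz: float = preprocess.DEFAULT_HIGHPASS_HZ
    filter_order: int = 2
    roi_radius_mm: float = preprocess.DEFAULT_ROI_RADIUS_MM
    networks: tuple[str, ...] = ("DMN", "FPN")
    between_pairs: tuple[tuple[str, str], ...] = (("DMN", "FPN"),)
    alpha: float = stats.ALPHA
    seed: int = 0
    simulation: synthetic.SimulationConfig | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "roi-tsv", "nifti"):
            raise ValueError("mode must be simulate, roi-tsv or nifti")
        if not 0 < self.threshold_p <= 1:
            raise ValueError("threshold_p must lie in (0, 1]")
        if self.mode != "simulate" and not self.input_dir:
            raise ValueError(f"mode {self.mode!r} requires input_dir")
        if self.mode == "simulate" and self.simulation is None:
            self.simulation = synthetic.SimulationConfig(seed=self.seed)
        self.networks = tuple(self.networks)
        self.between_pairs = tuple(tuple(p) for p in self.between_pairs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = synthetic.SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class ValidationIssue:
    level: str  # "fatal" | "warning"
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.level == "fatal" for i in self.issues)

    def fatal(self, message: str) -> None:
        self.issues.append(ValidationIssue("fatal", message))

    def warning(self, message: str) -> None:
        self.issues.append(ValidationIssue("warning", message))


@dataclass
class RunReport:
    config: RunConfig
    metrics: pd.DataFrame
    score_test: stats.TestResult
    family_results: dict[tuple[str, str], stats.TestResult]
    pattern: pd.DataFrame
    behavior_diffs: pd.DataFrame | None
    behavior_result: stats.TestResult | None
    provenance: dict


def _load_roi_tsv_inputs(config: RunConfig):
    indir = Path(config.input_dir)
    parc = preprocess.Parcellation.from_tsv(indir / "parcellation.tsv")
    scores_path = indir / "scores.tsv"
    scores = pd.read_csv(scores_path, sep="\t") if scores_path.exists() else None
    series = {}
    for path in sorted(indir.glob("*_*.tsv")):
        if path.name in ("parcellation.tsv", "scores.tsv"):
            continue
        subject, condition = path.stem.split("_", 1)
        if condition not in synthetic.CONDITIONS:
            log.warning("skipping %s: unknown condition %r", path.name, condition)
            continue
        series[(subject, condition)] = preprocess.read_roi_tsv(path)
    if not series:
        raise FileNotFoundError(f"no run TSVs found under {indir}")
    return parc, series, scores


def validate_inputs(
    series: dict, parc: preprocess.Parcellation, conditions=None
) -> ValidationReport:
    """Shape, variance and design-completeness checks; reports, never raises."""
    report = ValidationReport()
    subjects = sorted({s for s, _ in series})
    seen_conditions = sorted({c for _, c in series})
    conditions = list(conditions or seen_conditions)
    extra = set(seen_conditions) - set(conditions)
    if extra:
        report.warning(f"unused conditions present: {sorted(extra)}")
    for subject in subjects:
        missing = [c for c in conditions if (subject, c) not in series]
        if missing:
            report.fatal(f"subject {subject} missing conditions {missing}")
    for key, ts in series.items():
        if ts.n_nodes != len(parc):
            report.fatal(
                f"run {key}: {ts.n_nodes} nodes vs parcellation {len(parc)}"
            )
            continue
        sd = ts.data.std(axis=0)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            names = [ts.node_ids[j] for j in dead[:3]]
            report.fatal(f"run {key}: zero-variance node(s) {names}")
    return report


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and write all artifacts to ``output_dir``."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    scores = None
    if config.mode == "simulate":
        cohort = synthetic.simulate_cohort(config.simulation)
        parc, series, scores = cohort.parcellation, cohort.series, cohort.scores
    elif config.mode == "roi-tsv":
        parc, series, scores = _load_roi_tsv_inputs(config)
    else:  # nifti
        indir = Path(config.input_dir)
        parc = preprocess.Parcellation.from_tsv(indir / "parcellation.tsv")
        scores_path = indir / "scores.tsv"
        scores = (
            pd.read_csv(scores_path, sep="\t") if scores_path.exists() else None
        )
        series = {}
        for path in sorted(indir.glob("*_*.nii*")):
            subject, condition = path.name.split(".", 1)[0].split("_", 1)
            vol = preprocess.Volume4D.from_nifti(path)
            series[(subject, condition)] = preprocess.extract_roi_timeseries(
                vol, parc, config.roi_radius_mm
            )

    conditions = sorted({c for _, c in series})
    validation = validate_inputs(series, parc, conditions)
    for issue in validation.issues:
        log.log(
            logging.ERROR if issue.level == "fatal" else logging.WARNING,
            "%s: %s", issue.level, issue.message,
        )
    if not validation.ok:
        raise ValueError(
            "input validation failed: "
            + "; ".join(i.message for i in validation.issues if i.level == "fatal")
        )

    processed = {}
    for key, ts in series.items():
        t_stage = time.time()
        ts = preprocess.drop_initial_volumes(ts, config.drop_volumes)
        ts = preprocess.highpass_filter(ts, config.highpass_hz, config.filter_order)
        processed[key] = ts
        log.info("preprocess %s: %d volumes (%.2fs)", key, ts.n_volumes,
                 time.time() - t_stage)

    metrics = network.subject_condition_metrics(
        processed,
        parc,
        p=config.threshold_p,
        labels=config.networks,
        between_pairs=config.between_pairs,
        ranking=config.ranking,
    )
    metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False)

    # behavioral contrast
    score_result = stats.TestResult("wilcoxon", float("nan"), float("nan"), 0, True)
    if scores is not None:
        score_result = stats.wilcoxon_signed_rank(
            scores["score_EL"].to_numpy(float), scores["score_TE"].to_numpy(float)
        )

    metric_cols = [c for c in METRIC_COLUMNS if c in metrics.columns]
    family_results: dict[tuple[str, str], stats.TestResult] = {}
    pattern_tables: dict[str, stats.CohortTable] = {}
    for family, fam_conditions in METRIC_FAMILIES.items():
        if not set(fam_conditions) <= set(conditions):
            continue
        for metric in metric_cols:
            table = stats.CohortTable.from_metrics(metrics, metric, fam_conditions)
            family_results[(family, metric)] = stats.posthoc_pairwise(table)
            pattern_tables[f"{family}:{metric}"] = table
    pattern = stats.pattern_summary(pattern_tables, config.alpha)
    if not pattern.empty:
        pattern.to_csv(outdir / "pattern.tsv", sep="\t", index=False)

    behavior_diffs = behavior_result = None
    if scores is not None and {"EL-learn", "TE-learn"} <= set(conditions):
        behavior_diffs, behavior_result = stats.brain_behavior_analysis(
            metrics, scores
        )
        behavior_diffs.to_csv(outdir / "behavior_diffs.tsv", sep="\t")

    provenance = {
        "version": _version,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "elapsed_s": round(time.time() - t0, 2),
        "n_runs": len(series),
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)

    # flat statistics table
    rows = []
    for (family, metric), result in family_results.items():
        rows.append(
            {"family": family, "metric": metric, "test": "friedman",
             "pair": "", "statistic": result.statistic, "p_raw": result.p_value,
             "p_corrected": result.p_value}
        )
        for comp in result.comparisons:
            rows.append(
                {"family": family, "metric": metric, "test": "wilcoxon",
                 "pair": f"{comp.pair[0]} vs {comp.pair[1]}",
                 "statistic": comp.statistic, "p_raw": comp.p_raw,
                 "p_corrected": comp.p_corrected}
            )
    if rows:
        pd.DataFrame(rows).to_csv(outdir / "stats.tsv", sep="\t", index=False)

    return RunReport(
        config=config,
        metrics=metrics,
        score_test=score_result,
        family_results=family_results,
        pattern=pattern,
        behavior_diffs=behavior_diffs,
        behavior_result=behavior_result,
        provenance=provenance,
    )


def relation_cell(pattern: pd.DataFrame, family: str, metric: str, a: str, b: str) -> str:
    """Look up one relation cell (e.g. learning/within_DMN, TE-learn vs rest)."""
    key = f"{family}:{metric}"
    row = pattern[
        (pattern["metric"] == key)
        & (pattern["pair"].isin([f"{a} vs {b}", f"{b} vs {a}"]))
    ]
    if row.empty:
        raise KeyError(f"no relation for {key} {a} vs {b}")
    return row.iloc[0]["relation"]
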