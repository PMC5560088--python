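"""End-to-end orchestration: simulate -> connect -> classify -> graph -> compare.

Each stage reads only its declared on-disk inputs and writes plain-text
artifacts into the run directory, so stages are independently rerunnable.
Every stage stamps its outputs' directory with the configuration hash and
seeds; a rerun with an identical configuration reproduces identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import connectivity as conn
from . import network as net
from . import stats as st
from . import synth

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Reproducible configuration for the full pipeline."""

    outdir: str = "run"
    cohort_csv: str | None = None  # if None, the simulate stage must run first
    timeseries_dir: str | None = None
    # simulate
    cohort: synth.CohortConfig = field(default_factory=synth.CohortConfig)
    # connectivity
    low_hz: float = conn.DEFAULT_LOW_HZ
    high_hz: float = conn.DEFAULT_HIGH_HZ
    tsnr_threshold: float = conn.DEFAULT_TSNR_THRESHOLD
    # classification
    top_k: int = clf.DEFAULT_TOP_K
    svm_c: float = 1.0
    cv: str = "loo"
    classify_n_perm: int = clf.DEFAULT_N_PERM
    classify_seed: int = 0
    nested_permutation: bool = True
    # network
    sparsity_grid: tuple[float, ...] = net.DEFAULT_SPARSITY_GRID
    n_nulls: int = net.DEFAULT_N_NULLS
    n_runs: int = net.DEFAULT_N_RUNS
    network_seed: int = 0
    # stats
    stats_n_perm: int = st.DEFAULT_N_PERM
    alpha: float = st.DEFAULT_ALPHA
    stats_seed: int = 0
    two_sided: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["sparsity_grid"] = [float(s) for s in self.sparsity_grid]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        conf_raw = cohort_raw.pop("confounds", {}) if cohort_raw else {}
        cohort_kwargs = dict(cohort_raw)
        if "module_sizes" in cohort_kwargs:
            cohort_kwargs["module_sizes"] = tuple(cohort_kwargs["module_sizes"])
        cohort = synth.CohortConfig(
            confounds=synth.ConfoundSpec(**conf_raw), **cohort_kwargs
        )
        if "sparsity_grid" in raw:
            raw["sparsity_grid"] = tuple(raw["sparsity_grid"])
        return cls(cohort=cohort, **raw)


def _stamp(outdir: Path, config: PipelineConfig, stage: str) -> None:
    stamp_file = outdir / "run_stamp.yaml"
    stamp = {"config_hash": config.config_hash(), "stages": []}
    if stamp_file.exists():
        stamp = yaml.safe_load(stamp_file.read_text())
    if stage not in stamp["stages"]:
        stamp["stages"].append(stage)
    stamp["config_hash"] = config.config_hash()
    stamp_file.write_text(yaml.safe_dump(stamp, sort_keys=False))


def stage_simulate(config: PipelineConfig) -> pd.DataFrame:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = synth.simulate_cohort(config.cohort)
    table = synth.write_cohort(records, config.cohort, outdir)
    logger.info("simulate: %d subjects written to %s", len(records), outdir)
    _stamp(outdir, config, "simulate")
    return table


def _load_cohort(config: PipelineConfig) -> tuple[pd.DataFrame, Path]:
    outdir = Path(config.outdir)
    cohort_csv = Path(config.cohort_csv) if config.cohort_csv else outdir / "cohort.csv"
    if not cohort_csv.exists():
        raise FileNotFoundError(f"cohort table {cohort_csv} not found; run simulate "
                                "or point cohort_csv at an existing table")
    table = pd.read_csv(cohort_csv)
    base = Path(config.timeseries_dir) if config.timeseries_dir else cohort_csv.parent
    return table, base


def stage_connect(config: PipelineConfig) -> pd.DataFrame:
    """tSNR gate + denoising + correlation for every subject in the cohort.

    Writes per-subject matrix CSVs, a wide feature table (one row per
    subject), and the exclusion list.  Returns the post-QC cohort table.
    """
    table, base = _load_cohort(config)
    outdir = Path(config.outdir)
    mat_dir = outdir / "connectivity"
    mat_dir.mkdir(parents=True, exist_ok=True)
    kept_rows = []
    exclusions = []
    feature_rows = []
    index_map = None
    for _, row in table.iterrows():
        panel = conn.read_panel_tsv(
            base / row["path"], tr=config.cohort.tr, subject_id=row["subject_id"]
        )
        matrix, report = conn.subject_connectivity(
            panel, config.low_hz, config.high_hz, config.tsnr_threshold
        )
        if matrix is None:
            exclusions.append(
                {"subject_id": row["subject_id"], "mean_tsnr": report.mean,
                 "threshold": report.threshold}
            )
            continue
        conn.write_matrix_csv(matrix, mat_dir / f"{row['subject_id']}.csv")
        fv = conn.vectorize_upper_triangle(matrix)
        index_map = fv.index_map
        feature_rows.append({"subject_id": row["subject_id"],
                             **{f"f{i}": v for i, v in enumerate(fv.values)}})
        kept_rows.append(row)
    kept = pd.DataFrame(kept_rows).reset_index(drop=True)
    kept.to_csv(outdir / "cohort_qc.csv", index=False)
    pd.DataFrame(exclusions).to_csv(outdir / "exclusions.csv", index=False)
    pd.DataFrame(feature_rows).to_csv(outdir / "features.csv", index=False)
    if index_map is not None:
        pd.DataFrame(index_map, columns=["roi_i", "roi_j"]).to_csv(
            outdir / "feature_index_map.csv", index=False
        )
    logger.info("connect: %d kept, %d excluded by tSNR", len(kept), len(exclusions))
    _stamp(outdir, config, "connect")
    return kept


def _load_feature_set(outdir: Path) -> clf.LabeledFeatureSet:
    feats = pd.read_csv(outdir / "features.csv")
    cohort = pd.read_csv(outdir / "cohort_qc.csv")
    merged = cohort[["subject_id", "group"]].merge(feats, on="subject_id")
    fcols = [c for c in merged.columns if c.startswith("f") and c[1:].isdigit()]
    imap_path = outdir / "feature_index_map.csv"
    index_map = None
    if imap_path.exists():
        imap = pd.read_csv(imap_path)
        index_map = list(zip(imap["roi_i"], imap["roi_j"]))
    return clf.LabeledFeatureSet(
        features=merged[fcols].to_numpy(),
        labels=merged["group"].to_numpy(),
        subject_ids=merged["subject_id"].tolist(),
        index_map=index_map,
    )


def stage_classify(config: PipelineConfig) -> dict:
    """Consensus-feature SVM with permutation test; writes a JSON report."""
    outdir = Path(config.outdir)
    dataset = _load_feature_set(outdir)
    sel = clf.consensus_features(dataset, config.top_k, config.cv,
                                 config.classify_seed)
    result = clf.permutation_test_accuracy(
        dataset, k=config.top_k, n_perm=config.classify_n_perm,
        seed=config.classify_seed, c=config.svm_c,
        nested=config.nested_permutation, cv=config.cv,
    )
    hist_counts, hist_edges = np.histogram(
        result.null_accuracies[np.isfinite(result.null_accuracies)],
        bins=20, range=(0.0, 1.0),
    )
    consensus_pairs = (
        [list(dataset.index_map[i]) for i in sel.consensus]
        if dataset.index_map
        else sel.consensus.tolist()
    )
    report = {
        "config_hash": config.config_hash(),
        "seed": config.classify_seed,
        "classes": list(result.classes),
        "n_subjects": dataset.n_subjects,
        "n_features": dataset.n_features,
        "top_k": config.top_k,
        "n_consensus_features": int(sel.consensus.size),
        "consensus_features": consensus_pairs,
        "per_subject_prediction": dict(
            zip(dataset.subject_ids, map(str, result.per_subject_prediction))
        ),
        "specificity": result.specificity,
        "sensitivity": result.sensitivity,
        "overall_accuracy": result.overall_accuracy,
        "permutation_p": result.permutation_p,
        "n_permutations": result.n_permutations,
        "null_histogram": {
            "counts": hist_counts.tolist(),
            "bin_edges": hist_edges.tolist(),
        },
    }
    (outdir / "classification.json").write_text(json.dumps(report, indent=2))
    logger.info("classify: accuracy %.3f, p = %.4g",
                result.overall_accuracy, result.permutation_p)
    _stamp(outdir, config, "classify")
    return report


def stage_graph(config: PipelineConfig) -> pd.DataFrame:
    """Topology profiles for every post-QC subject; writes metrics.csv."""
    outdir = Path(config.outdir)
    cohort = pd.read_csv(outdir / "cohort_qc.csv")
    matrices = [
        conn.read_matrix_csv(outdir / "connectivity" / f"{sid}.csv", sid)
        for sid in cohort["subject_id"]
    ]
    metrics = net.cohort_profiles(
        matrices, config.sparsity_grid, config.n_nulls, config.n_runs,
        config.network_seed, partition_dir=outdir / "partitions",
    )
    metrics.to_csv(outdir / "metrics.csv", index=False)
    with open(outdir / "graph_settings.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "sparsity_grid": [float(s) for s in config.sparsity_grid],
                "n_nulls": config.n_nulls,
                "n_runs": config.n_runs,
                "seed": config.network_seed,
                "config_hash": config.config_hash(),
            },
            fh, sort_keys=False,
        )
    logger.info("graph: %d subjects profiled", len(metrics))
    _stamp(outdir, config, "graph")
    return metrics


def stage_compare(config: PipelineConfig) -> pd.DataFrame:
    """Group statistics on the integrated metrics; writes results.csv."""
    outdir = Path(config.outdir)
    metrics = pd.read_csv(outdir / "metrics.csv")
    cohort = pd.read_csv(outdir / "cohort_qc.csv")
    table = st.group_metric_table(
        metrics[["subject_id", *net.METRIC_NAMES]],
        cohort,
        net.METRIC_NAMES,
        n_perm=config.stats_n_perm,
        alpha=config.alpha,
        seed=config.stats_seed,
        two_sided=config.two_sided,
    )
    table.to_csv(outdir / "results.csv", index=False)
    st.descriptives_table(cohort).to_csv(outdir / "descriptives.csv", index=False)
    logger.info("compare: %d metrics, %d FDR-significant",
                len(table), int(table["fdr_significant"].sum()))
    _stamp(outdir, config, "compare")
    return table


def run_pipeline(config: PipelineConfig, simulate: bool = True) -> Path:
    """Run all stages in order; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "pipeline_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    if simulate:
        stage_simulate(config)
    stage_connect(config)
    stage_classify(config)
    stage_graph(config)
    stage_compare(config)
    return outdir
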