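"""Synthetic resting-state cohorts with block-modular correlation structure.

The generator emulates the study design the rest of the package analyses:
two glioma groups (slow-growing "LGG" vs fast-growing "HGG"), 40 subjects
each, one hemisphere parcellated into 45 ROIs, 301 fMRI volumes at a
sampling interval of 1.5 s.  Each subject's ROI time series is drawn from a
multivariate normal whose correlation matrix is block-modular: ``intra_r``
within modules, ``inter_r`` between modules.  The two groups differ in how
segregated their networks are, which is the contrast the topology arm of
the pipeline is designed to detect.

Timepoints are temporally white: the downstream analysis operates on
correlation matrices, for which independent draws from the target
correlation structure suffice, and white generation keeps the sampling
distribution of every derived statistic analytically checkable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .connectivity import TimeSeriesPanel

logger = logging.getLogger(__name__)

GROUPS = ("LGG", "HGG")

#: truncation bounds for subject covariates (years, millimetres)
AGE_BOUNDS = (18.0, 90.0)
DIAMETER_BOUNDS = (5.0, 120.0)

_PSD_TOL = 1e-10


@dataclass(frozen=True)
class ConfoundSpec:
    """Amplitudes of the confounds injected into every ROI series.

    global_amp : amplitude of a shared white "global signal" component
    drift_amp  : amplitude of a linear drift spanning the scan
    spike_prob : per-timepoint probability of a motion-like spike
    spike_amp  : amplitude added to all ROIs at a spike timepoint
    """

    global_amp: float = 0.0
    drift_amp: float = 0.0
    spike_prob: float = 0.0
    spike_amp: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.spike_prob <= 1.0:
            raise ValueError(f"spike_prob must be in [0, 1], got {self.spike_prob}")
        for name in ("global_amp", "drift_amp", "spike_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for a two-group synthetic cohort.

    Defaults reproduce the study conditions: 40 subjects per group, 45 ROIs
    in three 15-ROI modules, 301 timepoints at TR = 1.5 s, and a group
    contrast in which the LGG-like group is less segregated (lower
    within-module, higher between-module correlation) than the HGG-like
    group.  Covariate moments follow the patient table of the study
    population (ages in years, maximum tumour diameter in mm).
    """

    n_per_group: int = 40
    n_rois: int = 45
    n_timepoints: int = 301
    tr: float = 1.5
    module_sizes: tuple[int, ...] = (15, 15, 15)
    intra_r: Mapping[str, float] = field(
        default_factory=lambda: {"LGG": 0.45, "HGG": 0.60}
    )
    inter_r: Mapping[str, float] = field(
        default_factory=lambda: {"LGG": 0.25, "HGG": 0.15}
    )
    noise_sd: float = 0.0
    baseline: float = 100.0
    confounds: ConfoundSpec = field(default_factory=ConfoundSpec)
    age_mean: Mapping[str, float] = field(
        default_factory=lambda: {"LGG": 38.79, "HGG": 51.28}
    )
    age_sd: Mapping[str, float] = field(
        default_factory=lambda: {"LGG": 10.77, "HGG": 13.10}
    )
    diameter_mean: Mapping[str, float] = field(
        default_factory=lambda: {"LGG": 55.0, "HGG": 48.0}
    )
    diameter_sd: Mapping[str, float] = field(
        default_factory=lambda: {"LGG": 19.0, "HGG": 16.0}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if sum(self.module_sizes) != self.n_rois:
            raise ValueError(
                f"module_sizes {self.module_sizes} must sum to n_rois={self.n_rois}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        self.confounds.validate()
        for g in GROUPS:
            intra, inter = self.intra_r[g], self.inter_r[g]
            if not 0.0 <= inter <= intra < 1.0:
                raise ValueError(
                    f"group {g}: need 0 <= inter_r <= intra_r < 1, "
                    f"got intra={intra}, inter={inter}"
                )

    @property
    def roi_names(self) -> list[str]:
        return [f"ROI{i + 1:02d}" for i in range(self.n_rois)]

    @property
    def module_labels(self) -> np.ndarray:
        """Planted module id per ROI (0-based)."""
        return np.repeat(np.arange(len(self.module_sizes)), self.module_sizes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["module_sizes"] = list(self.module_sizes)
        for k in ("intra_r", "inter_r", "age_mean", "age_sd", "diameter_mean", "diameter_sd"):
            d[k] = dict(d[k])
        return d


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    diameter: float
    panel: TimeSeriesPanel

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not (np.isfinite(self.age) and self.age > 0):
            raise ValueError("age must be finite and positive")
        if not (np.isfinite(self.diameter) and self.diameter > 0):
            raise ValueError("diameter must be finite and positive")


def make_modular_covariance(
    module_sizes: Sequence[int], intra_r: float, inter_r: float
) -> np.ndarray:
    """Block correlation matrix: ``intra_r`` within modules, ``inter_r`` between.

    The result has unit diagonal and is guaranteed positive semidefinite:
    if the raw block matrix is numerically indefinite its negative
    eigenvalues are clipped at zero and the matrix rescaled back to unit
    diagonal.
    """
    if not 0.0 <= inter_r <= intra_r < 1.0:
        raise ValueError(
            f"need 0 <= inter_r <= intra_r < 1, got intra_r={intra_r}, inter_r={inter_r}"
        )
    sizes = np.asarray(module_sizes, dtype=int)
    if sizes.size == 0 or np.any(sizes < 1):
        raise ValueError("module_sizes must be a non-empty list of positive counts")
    labels = np.repeat(np.arange(sizes.size), sizes)
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, intra_r, inter_r)
    np.fill_diagonal(cov, 1.0)
    min_eig = np.linalg.eigvalsh(cov)[0]
    if min_eig < -_PSD_TOL:
        logger.warning(
            "block matrix indefinite (min eigenvalue %.3e); repairing by clipping",
            min_eig,
        )
        w, v = np.linalg.eigh(cov)
        cov = (v * np.clip(w, 0.0, None)) @ v.T
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        np.fill_diagonal(cov, 1.0)
    return cov


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float]) -> float:
    # resampling is exact and cheap at these plausibility bounds
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if bounds[0] <= x <= bounds[1]:
            return float(x)
    return float(np.clip(mean, *bounds))


def simulate_subject(
    cfg: CohortConfig, group: str, rng_seed: int, subject_id: str | None = None
) -> SubjectRecord:
    """Draw one subject: ROI panel with the group's block covariance plus confounds.

    Deterministic given ``rng_seed``.  Injected confound components (global
    signal, drift ramp, spike indicator) are stored as regressor columns of
    the panel so the denoising stage can remove exactly what was added.
    """
    cfg.validate()
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    rng = np.random.default_rng(rng_seed)
    cov = make_modular_covariance(cfg.module_sizes, cfg.intra_r[group], cfg.inter_r[group])
    # sample via eigen-factor so clipped (rank-deficient) repairs still work
    w, v = np.linalg.eigh(cov)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    t, n = cfg.n_timepoints, cfg.n_rois
    data = rng.standard_normal((t, n)) @ factor.T
    if cfg.noise_sd > 0:
        data += cfg.noise_sd * rng.standard_normal((t, n))

    spec = cfg.confounds
    regs: list[np.ndarray] = []
    names: list[str] = []
    if spec.global_amp > 0:
        gs = rng.standard_normal(t)
        data += spec.global_amp * gs[:, None]
        regs.append(gs)
        names.append("global_signal")
    if spec.drift_amp > 0:
        ramp = np.linspace(-1.0, 1.0, t)
        data += spec.drift_amp * ramp[:, None]
        regs.append(ramp)
        names.append("drift")
    if spec.spike_prob > 0:
        spikes = (rng.random(t) < spec.spike_prob).astype(float)
        data += spec.spike_amp * spikes[:, None]
        regs.append(spikes)
        names.append("spikes")
    data += cfg.baseline

    confounds = np.column_stack(regs) if regs else np.empty((t, 0))
    sid = subject_id or f"{group}-{rng_seed % 10**6:06d}"
    panel = TimeSeriesPanel(
        data=data,
        tr=cfg.tr,
        roi_names=cfg.roi_names,
        confounds=confounds,
        confound_names=names,
        subject_id=sid,
    )
    age = _truncated_normal(rng, cfg.age_mean[group], cfg.age_sd[group], AGE_BOUNDS)
    diameter = _truncated_normal(
        rng, cfg.diameter_mean[group], cfg.diameter_sd[group], DIAMETER_BOUNDS
    )
    return SubjectRecord(sid, group, age, diameter, panel)


def subject_seeds(cfg: CohortConfig) -> np.ndarray:
    """Per-subject integer seeds spawned from the master seed (counter-based)."""
    n_total = 2 * cfg.n_per_group
    ss = np.random.SeedSequence(cfg.seed)
    return ss.generate_state(n_total, dtype=np.uint32)


def simulate_cohort(cfg: CohortConfig) -> list[SubjectRecord]:
    """Simulate the full two-group cohort; reproducible from ``cfg.seed``."""
    cfg.validate()
    seeds = subject_seeds(cfg)
    records: list[SubjectRecord] = []
    i = 0
    for group in GROUPS:
        for j in range(cfg.n_per_group):
            sid = f"{group}-{j + 1:03d}"
            records.append(simulate_subject(cfg, group, int(seeds[i]), subject_id=sid))
            i += 1
    return records


def cohort_table(records: Sequence[SubjectRecord]):
    """Subject table (ID, group, age, diameter) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "age": [r.age for r in records],
            "diameter": [r.diameter for r in records],
        }
    )


def write_cohort(records: Sequence[SubjectRecord], cfg: CohortConfig, outdir: str | Path):
    """Write per-subject TSV panels, the cohort CSV and a YAML config echo.

    Returns the cohort table with a ``path`` column pointing at each panel.
    """
    from .connectivity import write_panel_tsv

    outdir = Path(outdir)
    ts_dir = outdir / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    table = cohort_table(records)
    paths = []
    for rec in records:
        p = ts_dir / f"{rec.subject_id}.tsv"
        write_panel_tsv(rec.panel, p)
        paths.append(str(p.relative_to(outdir)))
    table["path"] = paths
    table.to_csv(outdir / "cohort.csv", index=False)
    with open(outdir / "cohort_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
    return table
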