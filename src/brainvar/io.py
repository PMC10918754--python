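"""File I/O and configuration for the end-to-end pipeline.

Canonical interchange is headered CSV/TSV text; every table round-trips to
full float precision (pandas writes repr-exact floats by default here via
float_format=None and reads them back bit-identically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import numpy as np
import yaml

from .labels import INDICATORS
from .variability import NetworkMap, RoiTimeSeries

__all__ = [
    "PipelineConfig",
    "read_timeseries_dir",
    "read_phenotypes",
    "read_network_map",
    "REQUIRED_PHENOTYPE_COLUMNS",
]

logger = logging.getLogger(__name__)

REQUIRED_PHENOTYPE_COLUMNS: tuple[str, ...] = (
    "subject_id", "age", "sex", "handedness", "education_years", "mean_fd",
) + INDICATORS

#: Subjects at or above this mean framewise displacement (mm) are excluded
#: (inclusion rule: mean FD strictly below 0.5 mm).
FD_EXCLUSION_MM = 0.5

MIN_TIMEPOINTS = 10


@dataclass
class PipelineConfig:
    """Everything run_pipeline needs; YAML-serializable, CLI-overridable."""

    out_dir: str = "brainvar_out"
    # simulation (used when timeseries_dir is None)
    simulate: bool = True
    cohort: dict = field(default_factory=dict)   # CohortSpec overrides
    write_timeseries: bool = True
    # pre-existing inputs (used when simulate is False)
    timeseries_dir: str | None = None
    network_map: str | None = None
    phenotypes: str | None = None
    tr: float = 1.4
    # variability options
    adjust: bool = True
    denominator: str = "n-1"
    # CFA options
    n_modifications: int = 4
    chi2_multiplier: str = "n-1"
    # regression options
    fdr_alpha: float = 0.05
    polynomial_degree: int = 2
    slope_ages: Sequence[float] | None = None
    # global
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.simulate:
            for name in ("timeseries_dir", "network_map", "phenotypes"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"config.{name} is required when "
                                     "simulate is false")
                if not Path(path).exists():
                    raise ValueError(f"config.{name} does not exist: {path}")
        if self.denominator not in ("n-1", "n-2"):
            raise ValueError("denominator must be 'n-1' or 'n-2'")
        if self.n_modifications < 0:
            raise ValueError("n_modifications must be >= 0")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.polynomial_degree < 1:
            raise ValueError("polynomial_degree must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")

    def to_yaml(self, path) -> None:
        d = dict(self.__dict__)
        if d["slope_ages"] is not None:
            d["slope_ages"] = list(d["slope_ages"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def read_timeseries_dir(path, tr: float = 1.4,
                        pattern: str = "*.csv") -> list[RoiTimeSeries]:
    """Load every per-subject ROI time-series matrix under ``path``.

    Files are headered delimited text, timepoint rows by ROI columns; the
    subject id is the file stem.  A consistent ROI label order is enforced
    across subjects (mismatched headers are an error naming the files).
    Subjects with non-finite values or fewer than 10 timepoints are skipped
    with a logged reason, echoing the study's QC-exclusion pattern.
    """
    root = Path(path)
    if not root.is_dir():
        raise ValueError(f"not a directory: {root}")
    files = sorted(root.glob(pattern))
    if not files:
        raise ValueError(f"no time-series files matching {pattern!r} in {root}")
    out: list[RoiTimeSeries] = []
    labels: list[str] | None = None
    first_file: Path | None = None
    from .variability import read_delimited

    for fp in files:
        frame = read_delimited(fp)
        cols = [str(c) for c in frame.columns]
        if labels is None:
            labels, first_file = cols, fp
        elif cols != labels:
            raise ValueError(f"ROI header mismatch between {first_file.name} "
                             f"and {fp.name}")
        data = frame.to_numpy(dtype=float).T
        if data.shape[1] < MIN_TIMEPOINTS:
            logger.warning("excluding %s: only %d timepoints (< %d)",
                           fp.stem, data.shape[1], MIN_TIMEPOINTS)
            continue
        if not np.all(np.isfinite(data)):
            logger.warning("excluding %s: non-finite values in time series",
                           fp.stem)
            continue
        out.append(RoiTimeSeries(subject_id=fp.stem, data=data,
                                 roi_labels=cols, tr=tr))
    return out


def read_phenotypes(path, fd_threshold: float = FD_EXCLUSION_MM,
                    require_scores: bool = True) -> pd.DataFrame:
    """Typed phenotype table with the motion inclusion rule applied.

    Requires subject_id, age, sex, handedness, education_years, mean_fd and
    (unless ``require_scores=False``) the 14 task score columns.  Subjects
    with mean FD >= 0.5 mm are excluded with a log line; duplicate subject
    ids are an error.
    """
    frame = pd.read_csv(path)
    required = REQUIRED_PHENOTYPE_COLUMNS if require_scores else \
        REQUIRED_PHENOTYPE_COLUMNS[:6]
    for col in required:
        if col not in frame.columns:
            raise ValueError(f"phenotype table is missing column {col!r}")
    if frame["subject_id"].duplicated().any():
        dup = frame.loc[frame["subject_id"].duplicated(), "subject_id"]
        raise ValueError(f"duplicate subject_id(s): {sorted(set(dup))[:5]}")
    for col in ("age", "education_years", "mean_fd"):
        frame[col] = pd.to_numeric(frame[col])
    high_motion = frame["mean_fd"] >= fd_threshold
    if high_motion.any():
        for sid in frame.loc[high_motion, "subject_id"]:
            logger.info("excluding %s: mean FD >= %.2f mm", sid, fd_threshold)
        frame = frame.loc[~high_motion]
    return frame.reset_index(drop=True)


def read_network_map(path) -> NetworkMap:
    return NetworkMap.from_tsv(path)
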