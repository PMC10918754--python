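"""Moment-to-moment BOLD signal variability (rMSSD) and its whole-brain
adjustment.

The per-region statistic is the root mean squared successive difference,

    delta_i = sqrt( sum_{t=2..n} (x_i(t-1) - x_i(t))^2 / (n - 1) ),

with n the number of timepoints.  Unlike the standard deviation it respects
temporal ordering and is less sensitive to slow trends and autocorrelation.
The denominator follows the study convention (n - 1, the timepoint count
minus one, even though there are n - 1 differences); ``denominator="n-2"``
divides by the number of differences instead.

The whole-brain adjustment mirrors global signal regression but operates on
successive differences: the mean difference series across all regions,
g(t), is regressed out of each region's difference series by OLS (with
intercept) before the rMSSD is computed, orthogonalizing network-specific
from global variability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .labels import ALL_NETWORK_GROUPS, NETWORKS, UNASSIGNED, WHOLE_BRAIN

__all__ = [
    "RoiTimeSeries",
    "NetworkMap",
    "VariabilityProfile",
    "rmssd",
    "successive_differences",
    "adjust_global_differences",
    "adjusted_rmssd",
    "raw_rmssd",
    "aggregate",
    "compute_profile",
    "residualize_motion",
    "network_correlation_matrix",
]

logger = logging.getLogger(__name__)

_DENOMS = ("n-1", "n-2")


def read_delimited(path) -> pd.DataFrame:
    """Headered CSV/TSV with exact (round-trip) float parsing."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") > first.count(",") else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def _check_denominator(denominator: str) -> None:
    if denominator not in _DENOMS:
        raise ValueError(f"denominator must be one of {_DENOMS}")


@dataclass
class RoiTimeSeries:
    """One subject's ROI x time signal matrix."""

    subject_id: str
    data: np.ndarray  # shape (n_rois, n_timepoints)
    roi_labels: list[str]
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D ROI x time matrix")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in time series of "
                             f"{self.subject_id!r}")
        if len(self.roi_labels) != self.data.shape[0]:
            raise ValueError("roi_labels must align with data rows")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("roi_labels must be unique")
        if not np.isfinite(self.tr) or self.tr <= 0:
            raise ValueError("tr must be a positive number of seconds")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def to_csv(self, path) -> None:
        """Write as timepoints-rows x ROI-columns with a label header.

        %.17g guarantees bit round-trip of float64 values.
        """
        pd.DataFrame(self.data.T, columns=self.roi_labels).to_csv(
            path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, subject_id: str | None = None,
                 tr: float = 1.4) -> "RoiTimeSeries":
        from pathlib import Path

        frame = read_delimited(path)
        sid = subject_id if subject_id is not None else Path(path).stem
        return cls(subject_id=sid, data=frame.to_numpy().T,
                   roi_labels=[str(c) for c in frame.columns], tr=tr)


@dataclass
class NetworkMap:
    """ROI label -> network label (five networks + unassigned)."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {net for net in self.mapping.values()
               if net not in ALL_NETWORK_GROUPS}
        if bad:
            raise ValueError(f"unknown network label(s): {sorted(bad)}")

    def __getitem__(self, roi: str) -> str:
        return self.mapping[roi]

    def networks_for(self, roi_labels: Iterable[str]) -> pd.Series:
        missing = [r for r in roi_labels if r not in self.mapping]
        if missing:
            raise KeyError(f"ROIs missing from network map: {missing[:5]}"
                           + ("..." if len(missing) > 5 else ""))
        return pd.Series({r: self.mapping[r] for r in roi_labels})

    def to_tsv(self, path) -> None:
        pd.DataFrame({"roi_label": list(self.mapping),
                      "network": list(self.mapping.values())}
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "NetworkMap":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        if not {"roi_label", "network"} <= set(frame.columns):
            raise ValueError("network map needs columns roi_label, network")
        return cls(dict(zip(frame["roi_label"], frame["network"])))


@dataclass
class VariabilityProfile:
    """Per-ROI, per-network, and whole-brain rMSSD for one subject."""

    subject_id: str
    delta_roi: pd.Series
    delta_network: pd.Series
    delta_whole_brain: float
    variant: str = "raw"  # raw | adjusted | motion_residualized


# ---------------------------------------------------------------------------
# core statistic

def rmssd(series, denominator: str = "n-1") -> float:
    """Root mean squared successive difference of one time series."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("rmssd expects a 1-D series; see raw_rmssd for matrices")
    if x.size < 2:
        raise ValueError("rmssd needs at least 2 timepoints")
    if not np.all(np.isfinite(x)):
        raise ValueError("rmssd input must be finite")
    _check_denominator(denominator)
    denom = x.size - 1 if denominator == "n-1" else x.size - 2
    if denom <= 0:
        raise ValueError("series too short for the requested denominator")
    d = x[:-1] - x[1:]
    return float(np.sqrt(np.sum(d * d) / denom))


def _rmssd_from_differences(d: np.ndarray, n_timepoints: int,
                            denominator: str) -> np.ndarray:
    _check_denominator(denominator)
    denom = n_timepoints - 1 if denominator == "n-1" else n_timepoints - 2
    if denom <= 0:
        raise ValueError("series too short for the requested denominator")
    return np.sqrt(np.sum(d * d, axis=-1) / denom)


def successive_differences(ts: RoiTimeSeries) -> np.ndarray:
    """Difference matrix d_i(t) = x_i(t-1) - x_i(t), shape ROI x (time-1)."""
    return ts.data[:, :-1] - ts.data[:, 1:]


def raw_rmssd(ts: RoiTimeSeries, denominator: str = "n-1") -> pd.Series:
    """Per-ROI rMSSD of the raw signal."""
    d = successive_differences(ts)
    return pd.Series(_rmssd_from_differences(d, ts.n_timepoints, denominator),
                     index=ts.roi_labels, name="delta")


def adjust_global_differences(ts: RoiTimeSeries) -> np.ndarray:
    """Residualize each ROI's successive-difference series on the global one.

    g(t) is the unweighted mean of all ROI difference series; each d_i is
    regressed on g by OLS with intercept and the residuals are returned
    (shape ROI x (time-1)).  Residuals have exactly zero sample covariance
    with g.  If g is constant (zero variance) the degenerate path
    mean-centers each d_i instead.
    """
    if ts.n_timepoints < 3:
        raise ValueError("adjustment needs at least 3 timepoints")
    d = successive_differences(ts)
    g = d.mean(axis=0)
    gc = g - g.mean()
    var_g = float(gc @ gc)
    if var_g <= 1e-30 * max(1.0, float(np.abs(d).max()) ** 2):
        logger.info("global difference series is constant for %s; "
                    "falling back to mean-centering", ts.subject_id)
        return d - d.mean(axis=1, keepdims=True)
    slope = (d @ gc) / var_g  # per-ROI OLS slope on centered g
    resid = d - d.mean(axis=1, keepdims=True) - slope[:, None] * gc[None, :]
    return resid


def adjusted_rmssd(ts: RoiTimeSeries, denominator: str = "n-1") -> pd.Series:
    """Per-ROI rMSSD of the globally adjusted difference series.

    Same denominator convention as the raw statistic (the residual series
    has one fewer element than the signal, as for raw differences).
    """
    resid = adjust_global_differences(ts)
    return pd.Series(_rmssd_from_differences(resid, ts.n_timepoints, denominator),
                     index=ts.roi_labels, name="delta_adjusted")


def aggregate(delta_roi: pd.Series, netmap: NetworkMap
              ) -> tuple[pd.Series, float]:
    """Unweighted network means and the whole-brain mean of per-ROI deltas.

    Unassigned ROIs count toward the whole-brain mean only.  Networks with
    no member ROIs are omitted with a logged warning.
    """
    nets = netmap.networks_for(delta_roi.index)
    grouped = delta_roi.groupby(nets).mean()
    present = [n for n in NETWORKS if n in grouped.index]
    for net in NETWORKS:
        if net not in grouped.index:
            logger.warning("network %s has no member ROIs; omitted", net)
    return grouped.loc[present], float(delta_roi.mean())


def compute_profile(ts: RoiTimeSeries, netmap: NetworkMap,
                    variant: str = "raw",
                    denominator: str = "n-1") -> VariabilityProfile:
    """Full per-subject profile for the raw or adjusted variant."""
    if variant == "raw":
        droi = raw_rmssd(ts, denominator)
    elif variant == "adjusted":
        droi = adjusted_rmssd(ts, denominator)
    else:
        raise ValueError("variant must be 'raw' or 'adjusted'")
    dnet, dwb = aggregate(droi, netmap)
    return VariabilityProfile(subject_id=ts.subject_id, delta_roi=droi,
                              delta_network=dnet, delta_whole_brain=dwb,
                              variant=variant)


def profiles_to_frame(profiles: Iterable[VariabilityProfile]) -> pd.DataFrame:
    """Subjects x (networks + whole_brain) summary table."""
    rows = []
    for p in profiles:
        row = {"subject_id": p.subject_id, **p.delta_network.to_dict(),
               WHOLE_BRAIN: p.delta_whole_brain}
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def residualize_motion(delta: pd.DataFrame, motion: pd.Series) -> pd.DataFrame:
    """OLS-residualize each summary column on mean FD across subjects.

    Residuals (which may be negative) have exactly zero sample correlation
    with motion.  Zero-variance motion degrades to mean-centering.
    """
    if len(delta) < 3:
        raise ValueError("motion residualization needs at least 3 subjects")
    m = motion.reindex(delta.index)
    if m.isna().any():
        raise ValueError("motion values missing for some subjects")
    if not np.all(np.isfinite(m.to_numpy())):
        raise ValueError("motion values must be finite")
    mc = m.to_numpy() - m.to_numpy().mean()
    var_m = float(mc @ mc)
    x = delta.to_numpy(dtype=float)
    xc = x - x.mean(axis=0, keepdims=True)
    if var_m <= 0:
        logger.info("motion has zero variance; residuals are mean-centered deltas")
        resid = xc
    else:
        slope = mc @ xc / var_m
        resid = xc - np.outer(mc, slope)
    return pd.DataFrame(resid, index=delta.index, columns=delta.columns)


def network_correlation_matrix(delta: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations across subjects of the network + whole-brain
    summaries (6 x 6, unit diagonal).  Zero-variance columns yield NaN
    entries and a warning rather than silent zeros."""
    if len(delta) < 3:
        raise ValueError("correlation matrix needs at least 3 subjects")
    cols = [c for c in list(NETWORKS) + [WHOLE_BRAIN] if c in delta.columns]
    sub = delta[cols]
    zero_var = sub.std(ddof=1) == 0
    if zero_var.any():
        warnings.warn("zero-variance column(s) "
                      f"{list(sub.columns[zero_var])}; correlations undefined",
                      RuntimeWarning, stacklevel=2)
    corr = sub.corr()
    np.fill_diagonal(corr.values, 1.0)
    if zero_var.any():
        for c in sub.columns[zero_var]:
            corr.loc[c, :] = np.nan
            corr.loc[:, c] = np.nan
            corr.loc[c, c] = 1.0
    return corr
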