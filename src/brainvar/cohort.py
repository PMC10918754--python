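"""Synthetic life-span cohort generator.

Emulates the structure of a large community resting-state fMRI study:
~724 participants aged 6-85, one ROI x time BOLD matrix per subject
(246 regions in five intrinsic networks plus unassigned subcortical
regions, ~423 volumes at TR = 1.4 s), demographic covariates, head
motion, and 14 executive-function task scores produced by a correlated
four-factor structure with age-moderated network-variability effects.

Signal model per subject: every ROI is a weighted sum of one shared
("global") AR(1) process and an ROI-specific AR(1) process,

    x_i(t) = w * G(t) + s_i * eps_i(t),

with amplitudes chosen so that the expected squared rMSSD of ROI i equals
a network- and age-dependent target.  The global component carries the
common life-span trend, a subject-level amplitude, and the motion
confound; network-specific variance targets are mixed-sign contrasts
around it whose ROI-size-weighted mean is ~constant in age and exactly
centered across subjects.  That composition is what makes whole-brain
variability, after the successive-difference adjustment, uncorrelated
with every network's adjusted variability - the qualitative contrast the
adjustment exists to produce.

Everything is deterministic given ``CohortSpec.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .labels import (
    ALL_NETWORK_GROUPS,
    FACTORS,
    FACTOR_PATTERN,
    INDICATORS,
    NETWORKS,
    TIMED_INDICATORS,
    UNASSIGNED,
    WHOLE_BRAIN,
)
from .variability import NetworkMap, RoiTimeSeries

__all__ = [
    "MotionModel",
    "CohortSpec",
    "GroundTruth",
    "generate_subject_timeseries",
    "generate_phenotypes",
    "generate_task_scores",
    "generate_cohort",
    "simulate_study",
    "default_network_map",
    "quadratic_age_curve",
]

_BURN_IN = 64  # AR(1) warm-up samples discarded before the recorded scan


def quadratic_age_curve(curvature: float, peak_age: float, age_mid: float
                        ) -> tuple[float, float, float]:
    """Coefficients (b0, b1, b2) of -curvature*(age - peak)^2 expressed in
    powers of the mid-centered age (age - age_mid)."""
    d = age_mid - peak_age
    return (-curvature * d * d, -2.0 * curvature * d, -curvature)


@dataclass(frozen=True)
class MotionModel:
    """U-shaped age -> mean framewise displacement curve plus noise.

    fd(age) = base + quad * (age - center)^2 + N(0, noise_sd^2), floored at
    0.02 mm.  ``reference`` is the FD value at which motion adds nothing to
    the global variance component.
    """

    base: float = 0.20
    quad: float = 1.0e-4
    center: float = 40.0
    noise_sd: float = 0.06
    reference: float = 0.25


def _default_loadings() -> dict[str, float]:
    return {
        "CST": 0.70, "LF": 0.75, "CF": 0.78, "TMT-B": 0.65, "CS": 0.60,
        "CWI-I": 0.80, "CWI-S": 0.82,
        "TMT-A": 0.72, "TMT-MS": 0.68, "RT": 0.60,
        "0-back": 0.55, "1-back": 0.75, "2-back": 0.78, "CPT": 0.50,
    }


def _default_noise_sd() -> dict[str, float]:
    return {k: math.sqrt(1.0 - v * v) for k, v in _default_loadings().items()}


def _default_age_curves() -> dict[str, tuple[float, float, float]]:
    mid = 45.5
    return {
        "cognitive_flexibility": quadratic_age_curve(3.0e-4, 38.0, mid),
        "inhibitory_control": quadratic_age_curve(3.0e-4, 40.0, mid),
        "processing_speed": quadratic_age_curve(4.0e-4, 32.0, mid),
        "working_memory": quadratic_age_curve(3.0e-4, 35.0, mid),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of the synthetic study (with study defaults)."""

    n_subjects: int = 724
    age_range: tuple[float, float] = (6.0, 85.0)
    n_rois: int = 246
    network_sizes: Mapping[str, int] = field(default_factory=lambda: {
        "CEN": 40, "DMN": 60, "SN": 30, "LN": 30, "DA": 30, UNASSIGNED: 56,
    })
    n_timepoints: int = 423  # 10-min scan at TR 1.4 s minus 5 dropped volumes
    tr: float = 1.4
    #: Variance share of the shared global component at the mean age.
    global_weight: float = 0.5
    ar_coefficient: float = 0.3
    #: Raw rMSSD target per network at the mid age (arbitrary signal units).
    network_delta_baseline: Mapping[str, float] = field(default_factory=lambda: {
        "CEN": 1.00, "DMN": 1.05, "SN": 0.95, "LN": 0.90, "DA": 1.00,
        UNASSIGNED: 1.00,
    })
    #: Raw rMSSD change per year of age.  Cortical association networks
    #: decline; the salience network, the subcortical/limbic nuclei (LN),
    #: and unassigned regions increase.  The ROI-size-weighted mean trend of
    #: the network-specific delta targets is ~0 (the common decline lives in
    #: the global component).
    network_delta_age_slope: Mapping[str, float] = field(default_factory=lambda: {
        "CEN": -0.0010, "DMN": -0.0010, "SN": 0.0008, "LN": 0.0006,
        "DA": -0.0005, UNASSIGNED: 0.0011883,
    })
    #: Lognormal sd of the per-subject global-amplitude multiplier.
    global_subject_sd: float = 0.12
    #: SD of per-subject, per-network deviations of the adjusted
    #: (network-specific) delta target, in delta units (weighted-centered
    #: across networks within subject so they cancel in the whole-brain mean).
    network_subject_sd: float = 0.06
    motion_model: MotionModel = field(default_factory=MotionModel)
    #: Coefficient of (FD - reference) on the global variance component.
    motion_delta_gain: float = 0.25
    factor_loadings: Mapping[str, float] = field(default_factory=_default_loadings)
    #: Per-factor (b0, b1, b2) quadratic in (age - mid(age_range)).
    factor_age_curve: Mapping[str, tuple[float, float, float]] = field(
        default_factory=_default_age_curves)
    #: Per-(factor, network) effect of adjusted network delta on the factor.
    gamma_main: Mapping[tuple[str, str], float] = field(default_factory=lambda: {
        (f, "LN"): -2.5 for f in FACTORS})
    #: Per-(factor, network) delta-by-age interaction effect.
    gamma_interaction: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            **{(f, "DMN"): 0.12 for f in FACTORS},
            **{(f, "CEN"): -0.12 for f in FACTORS},
        })
    factor_noise_sd: float = 0.9
    factor_noise_corr: float = 0.45
    indicator_noise_sd: Mapping[str, float] = field(default_factory=_default_noise_sd)
    #: Residual covariances between indicator errors (same task, same factor
    #: pairs), mirroring shared method variance within a battery.  Only
    #: pairs within factors of >= 3 indicators: a residual covariance
    #: between the sole two indicators of a factor is unidentified (it
    #: trades off against the loadings), so planting one would merely bias
    #: the generative loadings.
    indicator_residual_cov: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("LF", "CF"): 0.12,
            ("0-back", "1-back"): 0.08,
            ("1-back", "2-back"): 0.10,
        })
    timed_indicators: frozenset[str] = TIMED_INDICATORS
    seed: int = 0

    # -- derived helpers -------------------------------------------------
    @property
    def age_mid(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])

    def validate(self) -> None:
        def _finite(name: str, value: float) -> None:
            if not np.isfinite(value):
                raise ValueError(f"CohortSpec.{name} must be finite, got {value!r}")

        if self.n_subjects < 2:
            raise ValueError("CohortSpec.n_subjects must be >= 2")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("CohortSpec.age_range must satisfy min < max")
        for name in ("tr", "global_weight", "ar_coefficient",
                     "global_subject_sd", "network_subject_sd",
                     "motion_delta_gain", "factor_noise_sd",
                     "factor_noise_corr"):
            _finite(name, float(getattr(self, name)))
        _finite("age_range", self.age_range[0])
        _finite("age_range", self.age_range[1])
        if sum(self.network_sizes.values()) != self.n_rois:
            raise ValueError(
                "CohortSpec.network_sizes must sum to n_rois "
                f"({sum(self.network_sizes.values())} != {self.n_rois})")
        if not abs(self.ar_coefficient) < 1:
            raise ValueError("CohortSpec.ar_coefficient must lie in (-1, 1)")
        if not 0.0 <= self.global_weight <= 1.0:
            raise ValueError("CohortSpec.global_weight must lie in [0, 1]")
        if self.motion_model.noise_sd < 0:
            raise ValueError("CohortSpec.motion_model.noise_sd must be >= 0")
        if self.factor_noise_sd <= 0:
            raise ValueError("CohortSpec.factor_noise_sd must be > 0")
        for name, mapping in (("network_delta_baseline", self.network_delta_baseline),
                              ("network_delta_age_slope", self.network_delta_age_slope)):
            for grp in self.network_sizes:
                if grp not in mapping:
                    raise ValueError(f"CohortSpec.{name} missing entry for {grp!r}")
                _finite(f"{name}[{grp}]", mapping[grp])
        for ind, sd in self.indicator_noise_sd.items():
            if sd < 0:
                raise ValueError(
                    f"CohortSpec.indicator_noise_sd[{ind!r}] must be >= 0")
        unknown = set(self.timed_indicators) - set(INDICATORS)
        if unknown:
            raise ValueError(
                f"CohortSpec.timed_indicators contains unknown labels: {sorted(unknown)}")
        if self.seed < 0:
            raise ValueError("CohortSpec.seed must be a nonnegative integer")

    def with_(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "age_range": list(self.age_range),
            "n_rois": self.n_rois,
            "network_sizes": dict(self.network_sizes),
            "n_timepoints": self.n_timepoints,
            "tr": self.tr,
            "global_weight": self.global_weight,
            "ar_coefficient": self.ar_coefficient,
            "network_delta_baseline": dict(self.network_delta_baseline),
            "network_delta_age_slope": dict(self.network_delta_age_slope),
            "global_subject_sd": self.global_subject_sd,
            "network_subject_sd": self.network_subject_sd,
            "motion_model": {
                "base": self.motion_model.base,
                "quad": self.motion_model.quad,
                "center": self.motion_model.center,
                "noise_sd": self.motion_model.noise_sd,
                "reference": self.motion_model.reference,
            },
            "motion_delta_gain": self.motion_delta_gain,
            "factor_loadings": dict(self.factor_loadings),
            "factor_age_curve": {k: list(v) for k, v in self.factor_age_curve.items()},
            "gamma_main": {f"{f}|{n}": v for (f, n), v in self.gamma_main.items()},
            "gamma_interaction": {
                f"{f}|{n}": v for (f, n), v in self.gamma_interaction.items()},
            "factor_noise_sd": self.factor_noise_sd,
            "factor_noise_corr": self.factor_noise_corr,
            "indicator_noise_sd": dict(self.indicator_noise_sd),
            "indicator_residual_cov": {
                f"{a}|{b}": v for (a, b), v in self.indicator_residual_cov.items()},
            "timed_indicators": sorted(self.timed_indicators),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        kwargs = dict(d)
        if "age_range" in kwargs:
            kwargs["age_range"] = tuple(kwargs["age_range"])
        if "motion_model" in kwargs and isinstance(kwargs["motion_model"], Mapping):
            kwargs["motion_model"] = MotionModel(**kwargs["motion_model"])
        if "factor_age_curve" in kwargs:
            kwargs["factor_age_curve"] = {
                k: tuple(v) for k, v in kwargs["factor_age_curve"].items()}
        for key in ("gamma_main", "gamma_interaction"):
            if key in kwargs:
                kwargs[key] = {
                    tuple(k.split("|")): v for k, v in kwargs[key].items()}
        if "indicator_residual_cov" in kwargs:
            kwargs["indicator_residual_cov"] = {
                tuple(k.split("|")): v
                for k, v in kwargs["indicator_residual_cov"].items()}
        if "timed_indicators" in kwargs:
            kwargs["timed_indicators"] = frozenset(kwargs["timed_indicators"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Generative quantities stored alongside outputs for recovery tests."""

    spec: CohortSpec
    #: One row per subject: age, motion, global amplitude, per-network
    #: specific-variance targets and adjusted-delta targets.
    subjects: pd.DataFrame
    #: One row per subject: raw factor values (set by generate_task_scores).
    factors: pd.DataFrame | None = None

    def factor_sd(self) -> dict[str, float]:
        if self.factors is None:
            raise ValueError("task scores have not been generated yet")
        return {f: float(self.factors[f].std(ddof=1)) for f in FACTORS}


# ---------------------------------------------------------------------------
# internals

def _rng(spec: CohortSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec.seed, *key)))


def _groups(spec: CohortSpec) -> list[str]:
    return [g for g in ALL_NETWORK_GROUPS if g in spec.network_sizes]


def _network_arrays(spec: CohortSpec):
    groups = _groups(spec)
    sizes = np.array([spec.network_sizes[g] for g in groups], dtype=float)
    base = np.array([spec.network_delta_baseline[g] for g in groups])
    slope = np.array([spec.network_delta_age_slope[g] for g in groups])
    m0 = float(np.sum(sizes * base ** 2) / np.sum(sizes))
    return groups, sizes, base, slope, m0


def _subject_latents(spec: CohortSpec, age: float, subject_seed: int):
    """Per-subject latent draws: global amplitude, network deviations, FD."""
    rng = _rng(spec, 100, subject_seed)
    sg = spec.global_subject_sd
    g = float(np.exp(sg * rng.standard_normal() - 0.5 * sg * sg))
    groups, sizes, _, _, _ = _network_arrays(spec)
    dev = spec.network_subject_sd * rng.standard_normal(len(groups))
    dev = dev - float(np.sum(sizes * dev) / np.sum(sizes))  # zero weighted mean
    mm = spec.motion_model
    fd = mm.base + mm.quad * (age - mm.center) ** 2 \
        + mm.noise_sd * rng.standard_normal()
    fd = max(float(fd), 0.02)
    return g, dict(zip(groups, dev)), fd


def _variance_targets(spec: CohortSpec, age: float, g: float,
                      dev: Mapping[str, float], fd: float):
    """(global variance, per-group specific variance) of the squared rMSSD.

    The network-specific target is parameterized on the delta scale:
    A_net(age) = a0_net + slope_adj_net * (age - mid) + dev_net with
    a0_net = sqrt(baseline^2 - rho * m0) and slope_adj chosen so the raw
    rMSSD age slope at the mid age equals ``network_delta_age_slope``.
    Working on the delta scale (not the variance scale) means the
    weighted-centered deviations and the slope balance cancel in exactly
    the quantity the whole-brain summary averages, mean_i delta_i.
    """
    groups, _, base, slope, m0 = _network_arrays(spec)
    rho = spec.global_weight
    a0 = np.sqrt(np.clip(base ** 2 - rho * m0, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        slope_adj = np.where(a0 > 0, slope * base / np.where(a0 > 0, a0, 1.0), 0.0)
    a = a0 + slope_adj * (age - spec.age_mid) \
        + np.array([dev[grp] for grp in groups])
    specific = np.clip(a, 0.0, None) ** 2
    glob = max(rho * m0 * g
               + spec.motion_delta_gain * (fd - spec.motion_model.reference), 0.0)
    return glob, dict(zip(groups, specific))


def _ar1(rng: np.random.Generator, n_series: int, n_t: int, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) rows, burn-in discarded."""
    from scipy.signal import lfilter

    innov = rng.standard_normal((n_series, n_t + _BURN_IN))
    innov *= math.sqrt(max(1.0 - phi * phi, 0.0)) if abs(phi) < 1 else 1.0
    out = lfilter([1.0], [1.0, -phi], innov, axis=-1)
    return out[:, _BURN_IN:]


def roi_labels(spec: CohortSpec) -> list[str]:
    labels = []
    for grp in _groups(spec):
        labels.extend(f"{grp}_{i + 1:03d}" for i in range(spec.network_sizes[grp]))
    return labels


def default_network_map(spec: CohortSpec | None = None) -> NetworkMap:
    spec = spec or CohortSpec()
    mapping = {}
    for grp in _groups(spec):
        for i in range(spec.network_sizes[grp]):
            mapping[f"{grp}_{i + 1:03d}"] = grp
    return NetworkMap(mapping)


# ---------------------------------------------------------------------------
# public generators

def generate_subject_timeseries(spec: CohortSpec, age: float,
                                subject_seed: int) -> RoiTimeSeries:
    """One subject's ROI x time matrix, deterministic given (spec, seed)."""
    spec.validate()
    lo, hi = spec.age_range
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside age_range {spec.age_range}")
    g, dev, fd = _subject_latents(spec, age, subject_seed)
    glob, specific = _variance_targets(spec, age, g, dev, fd)
    kappa = 2.0 * (1.0 - spec.ar_coefficient)  # squared rMSSD of a unit AR(1)
    w = math.sqrt(glob / kappa)
    groups = _groups(spec)
    s = np.concatenate([
        np.full(spec.network_sizes[grp], math.sqrt(specific[grp] / kappa))
        for grp in groups])
    rng = _rng(spec, 101, subject_seed)
    series = _ar1(rng, spec.n_rois + 1, spec.n_timepoints, spec.ar_coefficient)
    shared, eps = series[0], series[1:]
    data = w * shared[None, :] + s[:, None] * eps
    return RoiTimeSeries(subject_id=f"sub-{subject_seed:04d}", data=data,
                         roi_labels=roi_labels(spec), tr=spec.tr)


def generate_phenotypes(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Demographics, motion, and generative per-network delta targets."""
    spec.validate()
    rng = _rng(spec, 1)
    n = spec.n_subjects
    lo, hi = spec.age_range
    ages = rng.uniform(lo, hi, n)
    sex = np.where(rng.random(n) < 0.57, "F", "M")  # study marginal: 57% female
    hand = np.where(rng.random(n) < 0.10, "L", "R")  # 10% left-handed
    edu = np.minimum(0.85 * (ages - 5.0), 13.5) + rng.normal(0.0, 2.0, n)
    edu = np.clip(edu, 0.0, 22.0)

    groups = _groups(spec)
    sizes = np.array([spec.network_sizes[grp] for grp in groups], dtype=float)
    rows = []
    for i in range(n):
        g, dev, fd = _subject_latents(spec, ages[i], i)
        glob, specific = _variance_targets(spec, ages[i], g, dev, fd)
        adj = {grp: math.sqrt(specific[grp]) for grp in groups}
        wb_adj = float(np.sum(sizes * np.array([adj[grp] for grp in groups]))
                       / np.sum(sizes))
        row = {"subject_id": f"sub-{i:04d}", "age": ages[i], "mean_fd": fd,
               "g_global": g, "global_variance": glob,
               f"delta_adj_{WHOLE_BRAIN}": wb_adj}
        row.update({f"dev_{grp}": dev[grp] for grp in groups})
        row.update({f"specific_var_{grp}": specific[grp] for grp in groups})
        row.update({f"delta_adj_{grp}": adj[grp] for grp in groups})
        rows.append(row)
    truth = GroundTruth(spec=spec, subjects=pd.DataFrame(rows))
    pheno = pd.DataFrame({
        "subject_id": truth.subjects["subject_id"],
        "age": ages, "sex": sex, "handedness": hand,
        "education_years": edu, "mean_fd": truth.subjects["mean_fd"],
    })
    return pheno, truth


def generate_task_scores(spec: CohortSpec, truth: GroundTruth,
                         adjusted_network_delta: pd.DataFrame | None = None
                         ) -> pd.DataFrame:
    """The 14 task scores from the four-factor structure.

    ``adjusted_network_delta`` (subject_id + one column per named network)
    defaults to the generative targets stored in ``truth`` so recovery tests
    have exact ground truth; pass re-estimated deltas for end-to-end runs.
    Factors: quadratic age trend + network-variability effects (main and
    age-interaction) + correlated noise.  Indicators: loading times factor
    plus (possibly covarying) error; timed scores are emitted sign-flipped
    (lower = better).  Ground-truth factor values are stored on ``truth``.
    """
    spec.validate()
    unknown = set(spec.timed_indicators) - set(INDICATORS)
    if unknown:
        raise ValueError(f"unknown indicator label(s) in timed_indicators: "
                         f"{sorted(unknown)}")
    if adjusted_network_delta is None:
        cols = {net: truth.subjects[f"delta_adj_{net}"].to_numpy()
                for net in NETWORKS}
        subject_id = truth.subjects["subject_id"]
        ages = truth.subjects["age"].to_numpy()
    else:
        adf = adjusted_network_delta.merge(
            truth.subjects[["subject_id", "age"]], on="subject_id")
        cols = {net: adf[net].to_numpy() for net in NETWORKS}
        subject_id = adf["subject_id"]
        ages = adf["age"].to_numpy()
    n = len(subject_id)
    agec = ages - float(np.mean(ages))
    age_mid_c = ages - spec.age_mid

    # correlated factor disturbances
    rho = spec.factor_noise_corr
    psi = spec.factor_noise_sd ** 2 * (
        (1.0 - rho) * np.eye(len(FACTORS)) + rho * np.ones((len(FACTORS),) * 2))
    lpsi = np.linalg.cholesky(psi)
    u = _rng(spec, 2).standard_normal((n, len(FACTORS))) @ lpsi.T

    f = np.zeros((n, len(FACTORS)))
    for k, fac in enumerate(FACTORS):
        b0, b1, b2 = spec.factor_age_curve.get(fac, (0.0, 0.0, 0.0))
        f[:, k] = b0 + b1 * age_mid_c + b2 * age_mid_c ** 2 + u[:, k]
        for (fac_g, net), gm in spec.gamma_main.items():
            if fac_g == fac:
                f[:, k] += gm * cols[net]
        for (fac_g, net), gi in spec.gamma_interaction.items():
            if fac_g == fac:
                # centered delta: the interaction moderates the slope without
                # injecting a spurious marginal age trend into the factor
                dnet = cols[net]
                f[:, k] += gi * (dnet - float(np.mean(dnet))) * agec

    # indicator errors with optional same-task residual covariances
    p = len(INDICATORS)
    idx = {ind: j for j, ind in enumerate(INDICATORS)}
    theta = np.diag([spec.indicator_noise_sd.get(ind, 0.0) ** 2
                     for ind in INDICATORS])
    for (a, b), cov in spec.indicator_residual_cov.items():
        if a not in idx or b not in idx:
            raise ValueError(f"unknown indicator pair in "
                             f"indicator_residual_cov: {(a, b)!r}")
        theta[idx[a], idx[b]] = theta[idx[b], idx[a]] = cov
    # cholesky of theta; allow exactly-zero noise via eigen fallback
    try:
        ltheta = np.linalg.cholesky(theta + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError as err:
        raise ValueError("indicator residual covariance matrix is not "
                         "positive semi-definite") from err
    e = _rng(spec, 3).standard_normal((n, p)) @ ltheta.T
    if np.allclose(theta, 0.0):
        e = np.zeros_like(e)

    scores = np.empty((n, p))
    for j, ind in enumerate(INDICATORS):
        lam = spec.factor_loadings.get(ind, 0.0)
        k = FACTORS.index(FACTOR_PATTERN[ind])
        scores[:, j] = lam * f[:, k] + e[:, j]
        if ind in spec.timed_indicators:
            scores[:, j] = -scores[:, j]

    truth.factors = pd.DataFrame(
        {"subject_id": subject_id.to_numpy(), **{fac: f[:, k] for k, fac in
                                                 enumerate(FACTORS)}})
    out = pd.DataFrame(scores, columns=list(INDICATORS))
    out.insert(0, "subject_id", subject_id.to_numpy())
    return out


def emulated_measured_variability(spec: CohortSpec, truth: GroundTruth
                                  ) -> pd.DataFrame:
    """Adjusted network/whole-brain summaries as the pipeline would measure
    them, without simulating time series.

    Adds to the generative targets the finite-scan rMSSD estimation noise:
    for an AR(1) process the successive differences have lag-1 correlation
    -(1 - phi)/2, giving a relative sd of the per-ROI rMSSD estimate of
    approximately sqrt((1 + 2 * ((1 - phi)/2)^2) / (2 (T - 1))); ROI noise
    is independent, so network means shrink it by sqrt(n_net) and the
    whole-brain mean by the corresponding weighted factor.  Deterministic
    given ``spec.seed``.
    """
    rel = math.sqrt((1.0 + 2.0 * ((1.0 - spec.ar_coefficient) / 2.0) ** 2)
                    / (2.0 * (spec.n_timepoints - 1)))
    rng = _rng(spec, 4)
    groups = _groups(spec)
    sizes = np.array([spec.network_sizes[grp] for grp in groups], dtype=float)
    n = len(truth.subjects)
    out = pd.DataFrame({"subject_id": truth.subjects["subject_id"]})
    for net in NETWORKS:
        a = truth.subjects[f"delta_adj_{net}"].to_numpy()
        noise = rel / math.sqrt(spec.network_sizes[net]) * a
        out[net] = a + noise * rng.standard_normal(n)
    a_groups = np.stack([truth.subjects[f"delta_adj_{grp}"].to_numpy()
                         for grp in groups])
    wb = truth.subjects[f"delta_adj_{WHOLE_BRAIN}"].to_numpy()
    wb_noise = rel * np.sqrt((sizes[:, None] * a_groups ** 2).sum(axis=0)) \
        / sizes.sum()
    out[WHOLE_BRAIN] = wb + wb_noise * rng.standard_normal(n)
    return out


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Phenotypes with task scores appended (generative-target pathway)."""
    pheno, truth = generate_phenotypes(spec)
    scores = generate_task_scores(spec, truth)
    return pheno.merge(scores, on="subject_id"), truth


def simulate_study(spec: CohortSpec, out_dir, write_timeseries: bool = True):
    """Write the full synthetic study to ``out_dir``.

    Produces one ``timeseries/<subject>.csv`` per subject (rows = timepoints,
    header = ROI labels), ``phenotypes.csv`` (demographics + 14 task scores),
    ``ground_truth.csv``, ``network_map.tsv``, and the spec echoed to
    ``cohort.yaml``.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pheno, truth = generate_cohort(spec)
    pheno.to_csv(out / "phenotypes.csv", index=False)
    truth.subjects.merge(truth.factors, on="subject_id").to_csv(
        out / "ground_truth.csv", index=False)
    default_network_map(spec).to_tsv(out / "network_map.tsv")
    spec.to_yaml(out / "cohort.yaml")
    if write_timeseries:
        ts_dir = out / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        ages = truth.subjects["age"].to_numpy()
        for i in range(spec.n_subjects):
            ts = generate_subject_timeseries(spec, float(ages[i]), i)
            ts.to_csv(ts_dir / f"{ts.subject_id}.csv")
    return pheno, truth
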