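"""Life-span regressions: executive-function factors on network variability.

One OLS model per (outcome factor, variability predictor) pair - separate
models rather than all six predictors jointly, because the unadjusted
predictors are collinear enough to make joint estimates unreliable.  Every
model includes sex, handedness, and years of education as covariates; the
interaction models add mean-centered age and the delta-by-age product.
Focal p values are Benjamini-Hochberg adjusted within families of six
predictors per (outcome x effect-type).  Significant interactions are
probed with conditional ("simple") slopes at the four cohort mean ages,
with delta-method standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .labels import COHORT_MEAN_AGES, FACTORS, NETWORKS, WHOLE_BRAIN

__all__ = [
    "ModerationSpec",
    "ModerationResult",
    "FamilyResults",
    "fit_model",
    "fdr_adjust",
    "simple_slopes",
    "age_polynomial",
    "run_model_family",
    "PREDICTORS",
]

logger = logging.getLogger(__name__)

#: The six variability predictors of the model family.
PREDICTORS: tuple[str, ...] = (WHOLE_BRAIN,) + NETWORKS

DEFAULT_COVARIATES: tuple[str, ...] = ("sex", "handedness", "education_years")


@dataclass(frozen=True)
class ModerationSpec:
    """One regression: outcome factor, delta predictor, optional delta-by-age
    interaction, plus the standard covariate trio."""

    outcome: str
    predictor: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    include_interaction: bool = False

    def __post_init__(self) -> None:
        if self.outcome not in FACTORS:
            raise ValueError(f"unknown outcome factor {self.outcome!r}")
        if self.predictor not in PREDICTORS:
            raise ValueError(f"unknown predictor {self.predictor!r}")

    @property
    def model_id(self) -> str:
        kind = "interaction" if self.include_interaction else "main"
        return f"{self.outcome}~{self.predictor}:{kind}"


@dataclass
class ModerationResult:
    """Coefficients, inference, and standardized effects for one model."""

    spec: ModerationSpec
    terms: pd.DataFrame          # index: term; columns b, se, t, p, beta
    cov_params: pd.DataFrame     # coefficient covariance (delta method input)
    df_resid: float
    n: int
    age_mean: float | None       # centering constant used for age

    @property
    def model_id(self) -> str:
        return self.spec.model_id

    @property
    def focal_term(self) -> str:
        if self.spec.include_interaction:
            return f"{self.spec.predictor}:age_c"
        return self.spec.predictor


def _encode_covariates(frame: pd.DataFrame, covariates: Sequence[str]
                       ) -> pd.DataFrame:
    """Sex/handedness as indicator columns, education left in years."""
    out = pd.DataFrame(index=frame.index)
    for cov in covariates:
        if cov == "sex":
            vals = frame["sex"]
            out["sex_female"] = (
                vals.astype(str).str.upper().isin(["F", "FEMALE", "1"])
            ).astype(float) if vals.dtype == object else vals.astype(float)
        elif cov == "handedness":
            vals = frame["handedness"]
            out["hand_left"] = (
                vals.astype(str).str.upper().isin(["L", "LEFT", "1"])
            ).astype(float) if vals.dtype == object else vals.astype(float)
        else:
            out[cov] = frame[cov].astype(float)
    return out


def _rank_check(x: pd.DataFrame) -> None:
    arr = x.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns from the QR diagonal
        _, rr = np.linalg.qr(arr)
        diag = np.abs(np.diag(rr))
        bad = [x.columns[i] for i in range(len(diag))
               if diag[i] < 1e-10 * max(diag.max(), 1.0)]
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"column(s): {bad or list(x.columns)}")


def fit_model(mspec: ModerationSpec, scores: pd.DataFrame,
              variability: pd.DataFrame, phenotypes: pd.DataFrame
              ) -> ModerationResult:
    """OLS of one factor score on one variability summary (+ covariates,
    optionally + age and delta-by-age).

    ``scores``: subject_id + factor columns. ``variability``: subject_id +
    predictor columns (adjusted, motion-residualized summaries).
    ``phenotypes``: subject_id + age/sex/handedness/education_years.
    Standardized betas come from a fully z-scored refit in which the
    interaction column is the product of the z-scored constituents.
    """
    merged = scores[["subject_id", mspec.outcome]].merge(
        variability[["subject_id", mspec.predictor]], on="subject_id").merge(
        phenotypes[["subject_id", "age", "sex", "handedness",
                    "education_years"]],
        on="subject_id")
    merged = merged.dropna()
    n = len(merged)
    if n < 20:
        raise ValueError(f"too few complete cases (n = {n}) for {mspec.model_id}")
    delta = merged[mspec.predictor].to_numpy(dtype=float)
    if np.std(delta) <= 1e-12 * max(1.0, float(np.abs(delta).max())):
        raise ValueError(f"predictor {mspec.predictor!r} has zero variance")
    y = merged[mspec.outcome].to_numpy(dtype=float)

    x = pd.DataFrame({"const": 1.0, mspec.predictor: delta},
                     index=merged.index)
    age_mean = None
    if mspec.include_interaction:
        age_mean = float(merged["age"].mean())
        age_c = merged["age"].to_numpy(dtype=float) - age_mean
        x["age_c"] = age_c
        x[f"{mspec.predictor}:age_c"] = delta * age_c
    x = pd.concat([x, _encode_covariates(merged, mspec.covariates)], axis=1)
    _rank_check(x)

    fit = sm.OLS(y, x).fit()

    # standardized effects from the z-scored refit
    sd_y = float(np.std(y, ddof=1))
    xz = pd.DataFrame({"const": 1.0}, index=x.index)
    for col in x.columns:
        if col in ("const", f"{mspec.predictor}:age_c"):
            continue
        v = x[col].to_numpy(dtype=float)
        sd = float(np.std(v, ddof=1))
        xz[col] = (v - v.mean()) / sd if sd > 0 else 0.0
    if mspec.include_interaction:
        xz[f"{mspec.predictor}:age_c"] = (
            xz[mspec.predictor].to_numpy() * xz["age_c"].to_numpy())
        xz = xz[list(x.columns)]
    fit_z = sm.OLS((y - y.mean()) / sd_y, xz).fit()

    terms = pd.DataFrame({
        "b": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues,
        "beta": fit_z.params,
    })
    terms.loc["const", "beta"] = np.nan
    return ModerationResult(
        spec=mspec, terms=terms,
        cov_params=pd.DataFrame(fit.cov_params(), index=x.columns,
                                columns=x.columns),
        df_resid=float(fit.df_resid), n=n, age_mean=age_mean)


def fdr_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q values within one family (capped at 1)."""
    arr = np.asarray(list(p), dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def simple_slopes(result: ModerationResult,
                  ages: Sequence[float] = COHORT_MEAN_AGES,
                  age_mean: float | None = None) -> pd.DataFrame:
    """Conditional slope of delta at chosen ages, with delta-method SEs.

    slope(a) = b_delta + a_c * b_int with a_c the age centered at the
    model's centering constant; Var = V_dd + a_c^2 V_ii + 2 a_c V_di.
    """
    mspec = result.spec
    if not mspec.include_interaction:
        raise ValueError("simple slopes require an interaction model")
    d_term, i_term = mspec.predictor, f"{mspec.predictor}:age_c"
    if i_term not in result.cov_params.index:
        raise ValueError("coefficient covariance for the interaction term "
                         "is missing")
    center = result.age_mean if age_mean is None else age_mean
    b_d = float(result.terms.loc[d_term, "b"])
    b_i = float(result.terms.loc[i_term, "b"])
    v_dd = float(result.cov_params.loc[d_term, d_term])
    v_ii = float(result.cov_params.loc[i_term, i_term])
    v_di = float(result.cov_params.loc[d_term, i_term])
    rows = []
    for age in ages:
        a = float(age) - center
        slope = b_d + a * b_i
        var = v_dd + a * a * v_ii + 2.0 * a * v_di
        se = float(np.sqrt(max(var, 0.0)))
        t = slope / se if se > 0 else np.nan
        p = 2.0 * float(sstats.t.sf(abs(t), result.df_resid))
        rows.append({"age": float(age), "slope": slope, "se": se,
                     "t": t, "p": p})
    return pd.DataFrame(rows)


def age_polynomial(scores: pd.DataFrame, phenotypes: pd.DataFrame,
                   degree: int = 2) -> dict[str, dict]:
    """Per-factor polynomial age curve fit on orthogonalized age powers.

    Returns, per factor: raw-basis coefficients on centered age powers,
    R^2, and (degree 2, concave) the peak age.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    merged = scores.merge(phenotypes[["subject_id", "age"]], on="subject_id")
    merged = merged.dropna(subset=["age"])
    n = len(merged)
    if degree >= n:
        raise ValueError(f"degree ({degree}) must be < number of subjects ({n})")
    age = merged["age"].to_numpy(dtype=float)
    age_mean = float(age.mean())
    ac = age - age_mean
    v = np.vander(ac, degree + 1, increasing=True)  # [1, ac, ac^2, ...]
    q, r = np.linalg.qr(v)
    out: dict[str, dict] = {}
    for fac in FACTORS:
        if fac not in merged.columns:
            continue
        y = merged[fac].to_numpy(dtype=float)
        mask = np.isfinite(y)
        qm, rm = (q[mask], r) if mask.all() else np.linalg.qr(v[mask])
        coef_q = qm.T @ y[mask]
        coef = np.linalg.solve(rm, coef_q)  # raw centered-power basis
        fitted = v[mask] @ coef
        ss_res = float(np.sum((y[mask] - fitted) ** 2))
        ss_tot = float(np.sum((y[mask] - y[mask].mean()) ** 2))
        entry = {
            "coefficients": coef.tolist(),
            "age_mean": age_mean,
            "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
            "n": int(mask.sum()),
        }
        if degree == 2 and coef[2] < 0:
            entry["peak_age"] = age_mean - coef[1] / (2.0 * coef[2])
        out[fac] = entry
    return out


@dataclass
class FamilyResults:
    """Everything run_model_family produces."""

    table: pd.DataFrame                # long, term-level
    slopes: pd.DataFrame               # simple slopes for surviving interactions
    results: Mapping[str, ModerationResult] = field(default_factory=dict)


def run_model_family(scores: pd.DataFrame, variability: pd.DataFrame,
                     phenotypes: pd.DataFrame,
                     alpha: float = 0.05,
                     slope_ages: Sequence[float] = COHORT_MEAN_AGES
                     ) -> FamilyResults:
    """All 4 outcomes x 6 predictors x {main, interaction} = 48 models.

    BH-FDR is applied to the focal term within each (outcome, effect-type)
    family of six predictors; simple slopes are computed for every
    interaction with q < alpha.
    """
    results: dict[str, ModerationResult] = {}
    rows = []
    for outcome in FACTORS:
        for kind in ("main", "interaction"):
            family = []
            for pred in PREDICTORS:
                mspec = ModerationSpec(outcome=outcome, predictor=pred,
                                       include_interaction=(kind == "interaction"))
                res = fit_model(mspec, scores, variability, phenotypes)
                results[res.model_id] = res
                family.append(res)
            focal_p = [float(r.terms.loc[r.focal_term, "p"]) for r in family]
            qvals = fdr_adjust(focal_p)
            for r, q in zip(family, qvals):
                for term, t_row in r.terms.iterrows():
                    rows.append({
                        "outcome": outcome, "predictor": r.spec.predictor,
                        "effect_type": kind, "term": term,
                        "b": t_row["b"], "se": t_row["se"], "t": t_row["t"],
                        "p": t_row["p"], "beta": t_row["beta"],
                        "q": q if term == r.focal_term else np.nan,
                        "focal": term == r.focal_term, "n": r.n,
                    })
    table = pd.DataFrame(rows)

    slope_rows = []
    focal = table[(table["effect_type"] == "interaction") & table["focal"]]
    for _, row in focal.iterrows():
        if row["q"] < alpha:
            res = results[f"{row['outcome']}~{row['predictor']}:interaction"]
            ss = simple_slopes(res, ages=slope_ages)
            ss.insert(0, "outcome", row["outcome"])
            ss.insert(1, "predictor", row["predictor"])
            slope_rows.append(ss)
    slopes = (pd.concat(slope_rows, ignore_index=True) if slope_rows
              else pd.DataFrame(columns=["outcome", "predictor", "age",
                                         "slope", "se", "t", "p"]))
    return FamilyResults(table=table, slopes=slopes, results=results)
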