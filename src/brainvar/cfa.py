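"""Correlated four-factor confirmatory factor analysis by maximum likelihood.

Model: Sigma(theta) = Lambda Phi Lambda' + Theta, with a prespecified
loading pattern over the 14 executive-function scores, unit-variance
factors (all loadings free - the only identification consistent with
df = 71 for the hypothesized model), free factor correlations, free
residual variances, and optionally freed residual covariances between
indicator pairs that share both the task battery and the latent factor.

The ML discrepancy

    F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p

is minimized with analytic gradients (L-BFGS-B, deterministic multistart).
chi^2 = (n - 1) F_ML at the optimum by default (configurable to n).  Fit
indices: CFI against the independence baseline, RMSEA, and SRMR over the
p(p+1)/2 unique standardized residuals.  Modification indices are proper
score tests computed from the expected information matrix.  Factor scores
use the regression method, W = Phi Lambda' Sigma^-1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize
from scipy import stats as sstats

from .labels import FACTOR_PATTERN, FACTORS, INDICATORS, TASK_OF, TIMED_INDICATORS

__all__ = [
    "FactorModelSpec",
    "FittedFactorModel",
    "model_df",
    "fit_ml",
    "fit_indices",
    "suggest_residual_covariances",
    "factor_scores",
    "reverse_code",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FactorModelSpec:
    """CFA structure: loading pattern, residual covariances, orientation."""

    indicators: tuple[str, ...] = INDICATORS
    loading_pattern: Mapping[str, str] = field(
        default_factory=lambda: dict(FACTOR_PATTERN))
    residual_covariances: tuple[tuple[str, str], ...] = ()
    reverse_coded: frozenset[str] = TIMED_INDICATORS
    task_of: Mapping[str, str] = field(default_factory=lambda: dict(TASK_OF))

    def __post_init__(self) -> None:
        if len(set(self.indicators)) != len(self.indicators):
            raise ValueError("indicators must be unique")
        missing = [i for i in self.indicators if i not in self.loading_pattern]
        if missing:
            raise ValueError(f"loading_pattern missing indicators: {missing}")
        for a, b in self.residual_covariances:
            for lbl in (a, b):
                if lbl not in self.indicators:
                    raise ValueError(f"residual covariance names unknown "
                                     f"indicator {lbl!r}")
            if a == b:
                raise ValueError("residual covariance pair must be distinct")

    @property
    def factors(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ind in self.indicators:
            seen.setdefault(self.loading_pattern[ind], None)
        return tuple(seen)

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    def eligible_residual_pairs(self) -> list[tuple[str, str]]:
        """Pairs sharing both the task and the factor, not yet freed."""
        freed = {frozenset(p) for p in self.residual_covariances}
        out = []
        for a, b in itertools.combinations(self.indicators, 2):
            if frozenset((a, b)) in freed:
                continue
            if (self.task_of.get(a) == self.task_of.get(b)
                    and self.loading_pattern[a] == self.loading_pattern[b]):
                out.append((a, b))
        return out

    def with_residual_covariances(self, pairs: Sequence[tuple[str, str]]
                                  ) -> "FactorModelSpec":
        eligible = {frozenset(p) for p in self.eligible_residual_pairs()}
        for pair in pairs:
            if frozenset(pair) not in eligible:
                raise ValueError(
                    f"pair {pair!r} is not an eligible same-task, "
                    "same-factor residual covariance")
        return replace(self, residual_covariances=(
            self.residual_covariances + tuple(tuple(p) for p in pairs)))


def model_df(spec: FactorModelSpec) -> int:
    """Degrees of freedom: unique covariance moments minus free parameters.

    Under unit-variance-factor identification the free parameters are all
    loadings, all residual variances, the factor correlations, and any
    freed residual covariances.
    """
    p = spec.n_indicators
    m = len(spec.factors)
    moments = p * (p + 1) // 2
    q = p + p + m * (m - 1) // 2 + len(spec.residual_covariances)
    df = moments - q
    if df < 0:
        raise ValueError(f"model is over-parameterized (df = {df})")
    return df


@dataclass
class FittedFactorModel:
    """ML estimates, fit indices, and factor-score weights."""

    spec: FactorModelSpec
    loadings: pd.DataFrame          # p x m
    factor_corr: pd.DataFrame       # m x m, unit diagonal
    residual_cov: pd.DataFrame      # p x p (diagonal + freed off-diagonals)
    means: pd.Series
    implied_cov: pd.DataFrame
    sample_cov: pd.DataFrame
    n: int
    fml: float
    chi2: float
    df: int
    pvalue: float
    cfi: float
    rmsea: float
    srmr: float
    converged: bool
    grad_norm: float
    heywood: bool
    chi2_multiplier: str = "n-1"

    @property
    def score_weights(self) -> pd.DataFrame:
        """Regression-method weights W = Phi Lambda' Sigma^-1 (m x p)."""
        lam = self.loadings.to_numpy()
        phi = self.factor_corr.to_numpy()
        sigma = self.implied_cov.to_numpy()
        w = phi @ lam.T @ np.linalg.inv(sigma)
        return pd.DataFrame(w, index=self.factor_corr.index,
                            columns=self.loadings.index)

    def to_dict(self) -> dict:
        return {
            "n": self.n, "fml": self.fml, "chi2": self.chi2, "df": self.df,
            "pvalue": self.pvalue, "cfi": self.cfi, "rmsea": self.rmsea,
            "srmr": self.srmr, "converged": self.converged,
            "heywood": self.heywood,
            "chi2_multiplier": self.chi2_multiplier,
            "residual_covariances": [list(p) for p in
                                     self.spec.residual_covariances],
            "loadings": {ind: {fac: float(self.loadings.loc[ind, fac])
                               for fac in self.loadings.columns
                               if self.loadings.loc[ind, fac] != 0.0}
                         for ind in self.loadings.index},
            "factor_corr": self.factor_corr.round(6).to_dict(),
        }


# ---------------------------------------------------------------------------
# parameter packing

class _Parameterization:
    """Free-parameter vector <-> (Lambda, Phi, Theta) for one spec."""

    def __init__(self, spec: FactorModelSpec):
        self.spec = spec
        self.p = spec.n_indicators
        self.facs = spec.factors
        self.m = len(self.facs)
        fidx = {f: k for k, f in enumerate(self.facs)}
        iidx = {ind: j for j, ind in enumerate(spec.indicators)}
        self.load_idx = [(iidx[ind], fidx[spec.loading_pattern[ind]])
                         for ind in spec.indicators]
        self.phi_idx = list(itertools.combinations(range(self.m), 2))
        self.cov_idx = [(iidx[a], iidx[b]) for a, b in spec.residual_covariances]
        self.n_free = (len(self.load_idx) + len(self.phi_idx) + self.p
                       + len(self.cov_idx))

    def unpack(self, theta: np.ndarray):
        p, m = self.p, self.m
        k = 0
        lam = np.zeros((p, m))
        for j, f in self.load_idx:
            lam[j, f] = theta[k]
            k += 1
        phi = np.eye(m)
        for a, b in self.phi_idx:
            phi[a, b] = phi[b, a] = theta[k]
            k += 1
        th = np.diag(theta[k:k + p].copy())
        k += p
        for j, l in self.cov_idx:
            th[j, l] = th[l, j] = theta[k]
            k += 1
        return lam, phi, th

    def pack(self, lam, phi, th) -> np.ndarray:
        out = [lam[j, f] for j, f in self.load_idx]
        out += [phi[a, b] for a, b in self.phi_idx]
        out += list(np.diag(th))
        out += [th[j, l] for j, l in self.cov_idx]
        return np.array(out)

    def bounds(self, var_floor: float) -> list[tuple[float | None, float | None]]:
        b: list[tuple[float | None, float | None]] = []
        b += [(None, None)] * len(self.load_idx)
        b += [(-0.995, 0.995)] * len(self.phi_idx)
        b += [(var_floor, None)] * self.p
        b += [(None, None)] * len(self.cov_idx)
        return b

    def dsigma(self, lam: np.ndarray, phi: np.ndarray) -> list[np.ndarray]:
        """d Sigma / d theta_k for every free parameter, in pack order."""
        p, m = self.p, self.m
        lp = lam @ phi  # p x m
        out = []
        for j, f in self.load_idx:
            d = np.zeros((p, p))
            d[j, :] += lp[:, f]
            d[:, j] += lp[:, f]
            out.append(d)
        for a, b in self.phi_idx:
            d = np.outer(lam[:, a], lam[:, b])
            out.append(d + d.T)
        for j in range(p):
            d = np.zeros((p, p))
            d[j, j] = 1.0
            out.append(d)
        for j, l in self.cov_idx:
            d = np.zeros((p, p))
            d[j, l] = d[l, j] = 1.0
            out.append(d)
        return out


def _discrepancy_and_grad(theta: np.ndarray, par: _Parameterization,
                          s: np.ndarray, logdet_s: float):
    lam, phi, th = par.unpack(theta)
    sigma = lam @ phi @ lam.T + th
    p = par.p
    try:
        cf = sla.cho_factor(sigma, lower=True, check_finite=False)
    except sla.LinAlgError:
        return 1e12, np.zeros_like(theta)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    sigma_inv = sla.cho_solve(cf, np.eye(p), check_finite=False)
    f = logdet - logdet_s + float(np.sum(sigma_inv * s)) - p
    a = sigma_inv - sigma_inv @ s @ sigma_inv  # symmetric
    grad = np.empty_like(theta)
    k = 0
    alp = a @ lam @ phi
    for j, fac in par.load_idx:
        grad[k] = 2.0 * alp[j, fac]
        k += 1
    lal = lam.T @ a @ lam
    for x, y in par.phi_idx:
        grad[k] = 2.0 * lal[x, y]
        k += 1
    for j in range(p):
        grad[k] = a[j, j]
        k += 1
    for j, l in par.cov_idx:
        grad[k] = 2.0 * a[j, l]
        k += 1
    return f, grad


def _start_values(par: _Parameterization, s: np.ndarray, scale: float,
                  phi0: float) -> np.ndarray:
    lam = np.zeros((par.p, par.m))
    for j, f in par.load_idx:
        lam[j, f] = np.sqrt(scale * s[j, j])
    phi = np.full((par.m, par.m), phi0)
    np.fill_diagonal(phi, 1.0)
    th = np.diag((1.0 - scale) * np.diag(s))
    return par.pack(lam, phi, th)


def fit_indices(sample_cov: np.ndarray, implied_cov: np.ndarray, n: int,
                df: int, chi2_multiplier: str = "n-1") -> dict[str, float]:
    """chi^2, CFI, RMSEA, SRMR from sample and implied covariances.

    Standalone so the identity case (implied == sample -> F = 0, chi2 = 0,
    RMSEA = 0, SRMR = 0, CFI = 1) and index formulas can be checked without
    running the optimizer.
    """
    s = np.asarray(sample_cov, float)
    sigma = np.asarray(implied_cov, float)
    p = s.shape[0]
    mult = (n - 1) if chi2_multiplier == "n-1" else n
    sign_s, logdet_s = np.linalg.slogdet(s)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise ValueError("covariance matrices must be positive definite")
    fml = float(logdet_m - logdet_s + np.trace(np.linalg.solve(sigma, s)) - p)
    fml = max(fml, 0.0)
    chi2 = mult * fml
    # independence baseline: Sigma_b = diag(S)
    f_base = float(np.sum(np.log(np.diag(s))) - logdet_s)
    chi2_base = mult * f_base
    df_base = p * (p - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2_base - df_base, chi2 - df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    rmsea = float(np.sqrt(num / (df * mult))) if df > 0 else 0.0
    dstd = np.sqrt(np.outer(np.diag(s), np.diag(s)))
    resid = (s - sigma) / dstd
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    pvalue = float(sstats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return {"fml": fml, "chi2": chi2, "cfi": cfi, "rmsea": rmsea,
            "srmr": srmr, "pvalue": pvalue}


def fit_ml(spec: FactorModelSpec,
           data: pd.DataFrame | None = None,
           sample_cov: pd.DataFrame | np.ndarray | None = None,
           n: int | None = None,
           means: pd.Series | None = None,
           chi2_multiplier: str = "n-1",
           resid_var_floor: float = 1e-6,
           heywood_floor: bool = True) -> FittedFactorModel:
    """Fit the CFA by minimizing the ML discrepancy.

    Either ``data`` (subjects x indicator scores; incomplete rows dropped
    listwise) or ``sample_cov`` with ``n`` must be supplied.  Deterministic
    multistart; non-convergence is reported on the result together with the
    gradient norm.  Residual variances hitting the floor are flagged as
    Heywood cases (with ``heywood_floor=False`` the fit is still returned,
    flagged, with the floor active - the floor is how boundary solutions
    are represented).
    """
    inds = list(spec.indicators)
    if data is not None:
        frame = data.loc[:, inds].dropna()
        nn = len(frame)
        if nn <= spec.n_indicators:
            raise ValueError(f"need more subjects ({nn}) than indicators "
                             f"({spec.n_indicators})")
        s = np.cov(frame.to_numpy(), rowvar=False, ddof=1)
        mu = frame.mean()
    else:
        if sample_cov is None or n is None:
            raise ValueError("supply either data or (sample_cov, n)")
        s = np.asarray(sample_cov, float)
        if s.shape != (len(inds), len(inds)):
            raise ValueError("sample_cov shape does not match indicators")
        nn = int(n)
        mu = means if means is not None else pd.Series(0.0, index=inds)
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError("sample covariance must be positive definite")

    par = _Parameterization(spec)
    bounds = par.bounds(resid_var_floor)
    best = None
    for scale, phi0 in ((0.5, 0.3), (0.3, 0.5), (0.7, 0.1)):
        x0 = _start_values(par, s, scale, phi0)
        res = optimize.minimize(
            _discrepancy_and_grad, x0, args=(par, s, logdet_s),
            method="L-BFGS-B", jac=True, bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
        if res.success and best.fun < 1e11:
            break
    assert best is not None
    # polishing pass from the best point
    res = optimize.minimize(
        _discrepancy_and_grad, best.x, args=(par, s, logdet_s),
        method="L-BFGS-B", jac=True, bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-10})
    if res.fun > best.fun:
        res = best
    fval, grad = _discrepancy_and_grad(res.x, par, s, logdet_s)
    # gradient entries at active bounds do not have to vanish
    at_bound = np.array([
        (lo is not None and abs(x - lo) < 1e-9) or
        (hi is not None and abs(x - hi) < 1e-9)
        for x, (lo, hi) in zip(res.x, bounds)])
    grad_norm = float(np.max(np.abs(np.where(at_bound, 0.0, grad))))
    converged = bool(grad_norm < 1e-4)
    if not converged:
        logger.warning("CFA did not fully converge: max|grad| = %.3g", grad_norm)

    lam, phi, th = par.unpack(res.x)
    heywood = bool(np.any(np.diag(th) <= resid_var_floor * 1.01))
    if heywood:
        logger.warning("Heywood case: residual variance at the floor "
                       "(%.1e)", resid_var_floor)
    sigma = lam @ phi @ lam.T + th
    df = model_df(spec)
    idx = fit_indices(s, sigma, nn, df, chi2_multiplier)

    facs = list(spec.factors)
    return FittedFactorModel(
        spec=spec,
        loadings=pd.DataFrame(lam, index=inds, columns=facs),
        factor_corr=pd.DataFrame(phi, index=facs, columns=facs),
        residual_cov=pd.DataFrame(th, index=inds, columns=inds),
        means=pd.Series(np.asarray(mu, float), index=inds),
        implied_cov=pd.DataFrame(sigma, index=inds, columns=inds),
        sample_cov=pd.DataFrame(s, index=inds, columns=inds),
        n=nn, fml=float(fval), chi2=idx["chi2"], df=df, pvalue=idx["pvalue"],
        cfi=idx["cfi"], rmsea=idx["rmsea"], srmr=idx["srmr"],
        converged=converged, grad_norm=grad_norm, heywood=heywood,
        chi2_multiplier=chi2_multiplier)


# ---------------------------------------------------------------------------
# modification indices

def suggest_residual_covariances(fit: FittedFactorModel, k: int
                                 ) -> list[tuple[tuple[str, str], float]]:
    """Rank eligible same-task, same-factor residual covariances by
    modification index (expected-information score test for freeing the
    parameter); returns the top ``k`` pairs with their MI.  Re-fitting with
    the chosen pairs freed is the caller's job."""
    if k < 0:
        raise ValueError("k must be >= 0")
    spec = fit.spec
    candidates = spec.eligible_residual_pairs()
    if k == 0 or not candidates:
        return []
    par = _Parameterization(spec)
    lam = fit.loadings.to_numpy()
    phi = fit.factor_corr.to_numpy()
    sigma = fit.implied_cov.to_numpy()
    s = fit.sample_cov.to_numpy()
    sigma_inv = np.linalg.inv(sigma)
    a = sigma_inv - sigma_inv @ s @ sigma_inv
    dsig_free = par.dsigma(lam, phi)
    iidx = {ind: j for j, ind in enumerate(spec.indicators)}
    mult = (fit.n - 1) if fit.chi2_multiplier == "n-1" else fit.n

    # expected information in the F_ML metric: H_ab = tr(S^-1 dS_a S^-1 dS_b)
    nf = len(dsig_free)
    h_ff = np.empty((nf, nf))
    si_d = [sigma_inv @ d for d in dsig_free]
    for i in range(nf):
        for j in range(i, nf):
            h_ff[i, j] = h_ff[j, i] = float(np.sum(si_d[i] * si_d[j].T))
    out = []
    for pair in candidates:
        j, l = iidx[pair[0]], iidx[pair[1]]
        d_c = np.zeros_like(sigma)
        d_c[j, l] = d_c[l, j] = 1.0
        g_c = 2.0 * a[j, l]  # dF/dtheta_c
        si_c = sigma_inv @ d_c
        h_cc = float(np.sum(si_c * si_c.T))
        h_cf = np.array([float(np.sum(si_c * d.T)) for d in si_d])
        try:
            schur = h_cc - h_cf @ np.linalg.solve(h_ff, h_cf)
        except np.linalg.LinAlgError:
            schur = h_cc
        if schur <= 1e-12:
            mi = 0.0
        else:
            mi = 0.5 * mult * g_c * g_c / schur
        out.append((pair, float(mi)))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out[:k]


# ---------------------------------------------------------------------------
# factor scores and orientation

def factor_scores(fit: FittedFactorModel, data: pd.DataFrame) -> pd.DataFrame:
    """Regression-method factor scores: (x - mu) W' with
    W = Phi Lambda' Sigma^-1."""
    inds = list(fit.spec.indicators)
    missing = [c for c in inds if c not in data.columns]
    if missing:
        raise ValueError(f"data is missing indicator columns: {missing}")
    sigma = fit.implied_cov.to_numpy()
    if np.linalg.cond(sigma) > 1e12:
        raise ValueError("implied covariance is singular; cannot compute "
                         "regression-method scores")
    frame = data.loc[:, inds].dropna()
    x = frame.to_numpy(dtype=float) - fit.means.to_numpy()
    w = fit.score_weights.to_numpy()
    scores = x @ w.T
    return pd.DataFrame(scores, index=frame.index,
                        columns=list(fit.spec.factors))


def reverse_code(data: pd.DataFrame,
                 reverse_coded: Sequence[str] | frozenset[str] = TIMED_INDICATORS
                 ) -> pd.DataFrame:
    """Negate timed-score columns so higher always means better.

    Guarded against double application via a frame attribute; unknown
    labels are rejected.
    """
    if data.attrs.get("reverse_coded", False):
        raise ValueError("reverse_code has already been applied to this table")
    unknown = [c for c in reverse_coded if c not in data.columns]
    if unknown:
        raise ValueError(f"unknown column(s) to reverse-code: {unknown}")
    out = data.copy()
    for c in reverse_coded:
        out[c] = -out[c]
    out.attrs["reverse_coded"] = True
    return out
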