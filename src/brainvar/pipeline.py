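"""End-to-end orchestration: simulate -> variability -> CFA -> regressions.

Every stage writes its artifacts under the configured output directory and
the whole run is reproducible from the config plus seed.  A stage failure
halts the run with the stage name and cause.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cfa as cfa_mod
from . import lifespan
from .cohort import CohortSpec, default_network_map, simulate_study
from .io import PipelineConfig, read_network_map, read_phenotypes, read_timeseries_dir
from .labels import COHORT_MEAN_AGES, INDICATORS, NETWORKS, WHOLE_BRAIN
from .variability import (
    NetworkMap,
    compute_profile,
    network_correlation_matrix,
    profiles_to_frame,
    residualize_motion,
)

__all__ = ["run_pipeline", "variability_stage", "cfa_stage", "regression_stage"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _run_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump(config.__dict__, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def variability_stage(timeseries, netmap: NetworkMap, phenotypes: pd.DataFrame,
                      denominator: str = "n-1", adjust: bool = True):
    """Raw, adjusted, and motion-residualized summary tables plus the
    before/after network correlation matrices."""
    raw = profiles_to_frame(
        compute_profile(ts, netmap, "raw", denominator) for ts in timeseries)
    out = {"raw": raw}
    if adjust:
        adj = profiles_to_frame(
            compute_profile(ts, netmap, "adjusted", denominator)
            for ts in timeseries)
        out["adjusted"] = adj
    basis = out.get("adjusted", raw)
    motion = phenotypes.set_index("subject_id")["mean_fd"]
    common = basis.index.intersection(motion.index)
    out["residualized"] = residualize_motion(basis.loc[common],
                                             motion.loc[common])
    out["corr_raw"] = network_correlation_matrix(raw)
    if adjust:
        out["corr_adjusted"] = network_correlation_matrix(out["adjusted"])
    return out


def cfa_stage(phenotypes: pd.DataFrame, n_modifications: int = 4,
              chi2_multiplier: str = "n-1"):
    """Reverse-code timed scores, fit the hypothesized model, apply the
    same-task residual-covariance modification when fit is suboptimal
    (CFI < 0.95, RMSEA > 0.08, or SRMR > 0.06), and extract regression-method
    factor scores from the final model."""
    spec = cfa_mod.FactorModelSpec()
    data = phenotypes.set_index("subject_id")[list(INDICATORS)]
    oriented = cfa_mod.reverse_code(data, spec.reverse_coded)
    base = cfa_mod.fit_ml(spec, data=oriented, chi2_multiplier=chi2_multiplier)
    final = base
    suboptimal = (base.cfi < 0.95 or base.rmsea > 0.08 or base.srmr > 0.06)
    if n_modifications > 0 and suboptimal:
        ranked = cfa_mod.suggest_residual_covariances(base, n_modifications)
        pairs = [pair for pair, _ in ranked]
        if pairs:
            final = cfa_mod.fit_ml(spec.with_residual_covariances(pairs),
                                   data=oriented,
                                   chi2_multiplier=chi2_multiplier)
    scores = cfa_mod.factor_scores(final, oriented)
    scores = scores.reset_index().rename(columns={"index": "subject_id"})
    return base, final, scores


def regression_stage(scores: pd.DataFrame, residualized: pd.DataFrame,
                     phenotypes: pd.DataFrame, alpha: float = 0.05,
                     slope_ages=None, polynomial_degree: int = 2):
    variability = residualized.reset_index()
    family = lifespan.run_model_family(
        scores, variability, phenotypes, alpha=alpha,
        slope_ages=slope_ages or COHORT_MEAN_AGES)
    curves = lifespan.age_polynomial(scores, phenotypes,
                                     degree=polynomial_degree)
    return family, curves


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a dict of the main in-memory artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)
    logger.info("run hash %s", _run_hash(config))
    config.to_yaml(out / "config.yaml")

    try:
        if config.simulate:
            spec = CohortSpec.from_dict({"seed": config.seed, **config.cohort})
            simulate_study(spec, out, write_timeseries=config.write_timeseries)
            netmap = default_network_map(spec)
            tr = spec.tr
        else:
            netmap = read_network_map(config.network_map)
            tr = config.tr
        phenotypes = read_phenotypes(out / "phenotypes.csv"
                                     if config.simulate else config.phenotypes)
        ts_dir = out / "timeseries" if config.simulate else Path(config.timeseries_dir)
        timeseries = read_timeseries_dir(ts_dir, tr=tr)
        keep = set(phenotypes["subject_id"])
        timeseries = [t for t in timeseries if t.subject_id in keep]
    except StageError:
        raise
    except Exception as err:
        raise StageError("ingest", err) from err

    try:
        var = variability_stage(timeseries, netmap, phenotypes,
                                denominator=config.denominator,
                                adjust=config.adjust)
        var["raw"].to_csv(out / "variability_raw.csv")
        if "adjusted" in var:
            var["adjusted"].to_csv(out / "variability_adjusted.csv")
        var["residualized"].to_csv(out / "variability_residualized.csv")
        var["corr_raw"].to_csv(out / "network_correlations_raw.csv")
        if "corr_adjusted" in var:
            var["corr_adjusted"].to_csv(out / "network_correlations_adjusted.csv")
    except Exception as err:
        raise StageError("variability", err) from err

    try:
        base, final, scores = cfa_stage(phenotypes, config.n_modifications,
                                        config.chi2_multiplier)
        with open(out / "cfa_fit.json", "w") as fp:
            json.dump({"base": base.to_dict(), "final": final.to_dict()},
                      fp, indent=2)
        scores.to_csv(out / "factor_scores.csv", index=False)
    except Exception as err:
        raise StageError("cfa", err) from err

    try:
        family, curves = regression_stage(
            scores, var["residualized"], phenotypes, alpha=config.fdr_alpha,
            slope_ages=config.slope_ages,
            polynomial_degree=config.polynomial_degree)
        family.table.to_csv(out / "table2_long.csv", index=False)
        family.slopes.to_csv(out / "simple_slopes.csv", index=False)
        with open(out / "age_curves.json", "w") as fp:
            json.dump(curves, fp, indent=2)
    except Exception as err:
        raise StageError("regress", err) from err

    try:
        _write_report(out, var, base, final, family, curves)
    except Exception as err:
        raise StageError("report", err) from err
    logging.getLogger().removeHandler(fh)
    fh.close()
    return {"phenotypes": phenotypes, "variability": var, "cfa_base": base,
            "cfa_final": final, "scores": scores, "family": family,
            "curves": curves}


def _write_report(out: Path, var, base, final, family, curves) -> None:
    lines = ["# brainvar run report", ""]
    lines += ["## Network variability correlations (raw)",
              var["corr_raw"].round(3).to_string(), ""]
    if "corr_adjusted" in var:
        lines += ["## Network variability correlations (adjusted)",
                  var["corr_adjusted"].round(3).to_string(), ""]
    for name, fit in (("hypothesized", base), ("final", final)):
        lines += [f"## CFA ({name} model)",
                  f"chi2({fit.df}) = {fit.chi2:.2f}, p = {fit.pvalue:.4g}, "
                  f"CFI = {fit.cfi:.3f}, RMSEA = {fit.rmsea:.3f}, "
                  f"SRMR = {fit.srmr:.3f}", ""]
    focal = family.table[family.table["focal"]]
    lines += ["## Regression models (focal terms)",
              focal[["outcome", "predictor", "effect_type", "b", "se", "p",
                     "q", "beta"]].round(4).to_string(index=False), ""]
    if len(family.slopes):
        lines += ["## Simple slopes (q < alpha interactions)",
                  family.slopes.round(4).to_string(index=False), ""]
    lines += ["## Age curves", json.dumps(curves, indent=2)]
    (out / "report.md").write_text("\n".join(lines))
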