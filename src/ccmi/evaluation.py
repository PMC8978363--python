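"""Scenario orchestration and simulation-study performance measures.

One replicate generates a cohort, induces covariate missingness, draws the
case-cohort sample with its weights, and analyses it with a complete-data
comparator, a complete-case analysis, and the seven MI strategies.  A
scenario executes replicates with deterministically split seeds, retains
the first ``nsim`` replicates on which every method converged, and
summarizes each method's relative bias, empirical and model-based SE, and
coverage, each with its Monte Carlo standard error (Morris–White–Crowther
conventions).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dgp import make_scenario_params
from .design import DegenerateSampleError, select_subcohort
from .estimation import EstimateRecord, cca_estimate, fit_ipw_glm, rubin_pool
from .imputation import STRATEGIES, ImputationConfig, impute
from .missingness import MissingnessParams, calibrate_intercepts, default_params, induce_missingness

__all__ = [
    "ScenarioConfig",
    "METHODS",
    "MI_METHODS",
    "run_replicate",
    "run_scenario",
    "performance_metrics",
    "coverage_mcse",
    "default_grid",
]

MI_METHODS = ("FCS-WO", "FCS-WX", "FCS-SS", "FCS-WM",
              "MVNI-WO", "MVNI-WX", "MVNI-SS")
METHODS = ("complete", "CCA") + MI_METHODS


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation grid plus execution parameters."""

    variant: str = "observed"
    association: str = "observed"
    estimand: str = "RR"
    mechanism: str = "independent"
    p: float = 15.0
    pi: float = 0.30
    n: int = 1000
    nsim: int = 2000
    buffer: int = 2200
    m: int = 30
    fcs_cycles: int = 10
    mvni_burnin: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.buffer < self.nsim:
            raise ValueError("buffer must be >= nsim")

    @property
    def scenario_id(self) -> str:
        return (f"{self.variant}-{self.association}-{self.estimand}-"
                f"{self.mechanism}-p{self.p:g}-pi{self.pi:g}")

    def imputation_config(self) -> ImputationConfig:
        return ImputationConfig(m=self.m, fcs_cycles=self.fcs_cycles,
                                mvni_burnin=self.mvni_burnin)

    def replicate_rng(self, k: int) -> np.random.Generator:
        """Deterministic per-replicate stream: (root seed, scenario id, k)."""
        tag = zlib.crc32(self.scenario_id.encode()) & 0x7FFFFFFF
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(tag, k))
        return np.random.default_rng(ss)


def default_grid(variant_extreme: bool = True) -> list[ScenarioConfig]:
    """The full default grid: 72 main scenarios plus 6 extreme ones."""
    grid = []
    for estimand in ("RR", "OR"):
        for association in ("observed", "enhanced"):
            for mechanism in ("independent", "DMO", "DME"):
                for p in (15.0, 30.0):
                    for pi in (0.20, 0.30, 0.40):
                        grid.append(ScenarioConfig(
                            variant="observed", association=association,
                            estimand=estimand, mechanism=mechanism,
                            p=p, pi=pi))
    if variant_extreme:
        for estimand in ("RR", "OR"):
            for pi in (0.20, 0.30, 0.40):
                grid.append(ScenarioConfig(
                    variant="extreme", association="enhanced",
                    estimand=estimand, mechanism="DME", p=30.0, pi=pi))
    return grid


def run_replicate(config: ScenarioConfig, mparams: MissingnessParams,
                  rng: np.random.Generator) -> dict[str, dict]:
    """One replicate: generate, mask, sample, analyse with every method.

    Returns {method: {"estimate", "se", "ci_low", "ci_high", "converged"}}.
    The complete-data comparator analyses the case-cohort sample using the
    pre-missingness covariate values; the MI methods each impute m datasets
    and pool with Rubin's rules.
    """
    from .dgp import generate_cohort

    params, spec = make_scenario_params(config.variant, config.association,
                                        config.estimand)
    family = "RR-poisson" if config.estimand == "RR" else "OR-logistic"
    imp_config = config.imputation_config()

    cohort = generate_cohort(params, spec, config.n, rng)
    masked = induce_missingness(cohort, mparams, rng)
    try:
        sample = select_subcohort(masked, config.pi, rng)
    except DegenerateSampleError:
        return {m: _failed() for m in METHODS}

    results: dict[str, dict] = {}

    # complete-data comparator: same analysed records, pre-missingness values
    complete_records = cohort.loc[sample.records.index].copy()
    complete_records["weight"] = sample.records["weight"].to_numpy()
    rec = fit_ipw_glm(complete_records, sample.weights, family)
    results["complete"] = _from_record(rec)

    try:
        results["CCA"] = _from_record(cca_estimate(sample, family))
    except ValueError:
        results["CCA"] = _failed()

    for label in MI_METHODS:
        strategy = STRATEGIES[label]
        completed = impute(sample, strategy, imp_config, rng)
        if not all(c.converged for c in completed):
            results[label] = _failed()
            continue
        fits = [fit_ipw_glm(c.data, c.data["weight"].to_numpy(dtype=float), family)
                for c in completed]
        if not all(f.converged for f in fits):
            results[label] = _failed()
            continue
        pooled = rubin_pool(fits)
        results[label] = {
            "estimate": pooled.estimate, "se": pooled.se,
            "ci_low": pooled.ci_low, "ci_high": pooled.ci_high,
            "converged": True,
        }
    return results


def _from_record(rec: EstimateRecord) -> dict:
    lo, hi = rec.ci()
    return {"estimate": rec.estimate, "se": rec.se, "ci_low": lo,
            "ci_high": hi, "converged": rec.converged}


def _failed() -> dict:
    return {"estimate": np.nan, "se": np.nan, "ci_low": np.nan,
            "ci_high": np.nan, "converged": False}


def run_scenario(config: ScenarioConfig,
                 mparams: MissingnessParams | None = None,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute a scenario and summarize per-method performance.

    Replicates run in fixed seed order until ``nsim`` replicates on which
    *all* methods converged have been retained, or the ``buffer`` is
    exhausted (in which case the summary is computed over the shortfall and
    flagged).  Convergence rates are reported over all executed replicates.
    Returns (summary table, per-replicate table).
    """
    params, spec = make_scenario_params(config.variant, config.association,
                                        config.estimand)
    if mparams is None:
        mparams = default_params(config.mechanism, config.p)
        if mparams.mechanism != "independent" and config.p > 0:
            calib_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(0xCA11B,)))
            mparams = calibrate_intercepts(params, spec, mparams, calib_rng)

    truth = spec.true_coef
    rows = []
    retained = 0
    executed = 0
    for k in range(config.buffer):
        rng = config.replicate_rng(k)
        res = run_replicate(config, mparams, rng)
        executed += 1
        all_ok = all(res[m]["converged"] for m in METHODS)
        if all_ok:
            retained += 1
        for method in METHODS:
            rows.append({"scenario": config.scenario_id, "replicate": k,
                         "method": method, "retained": all_ok, **res[method]})
        if retained >= config.nsim:
            break

    reps = pd.DataFrame(rows)
    shortfall = retained < config.nsim
    summary_rows = []
    for method in METHODS:
        sub = reps[reps["method"] == method]
        kept = sub[sub["retained"]]
        metrics = performance_metrics(
            kept["estimate"].to_numpy(), kept["se"].to_numpy(),
            kept["ci_low"].to_numpy(), kept["ci_high"].to_numpy(), truth)
        metrics.update({
            "scenario": config.scenario_id, "method": method,
            "convergence_rate_pct": 100.0 * sub["converged"].mean(),
            "replicates_executed": executed,
            "shortfall": shortfall,
        })
        summary_rows.append(metrics)
    cols = ["scenario", "method", "nsim", "mean_estimate", "relative_bias_pct",
            "relative_bias_mcse_pct", "empirical_se", "empirical_se_mcse",
            "model_se", "model_se_mcse", "coverage_pct", "coverage_mcse_pct",
            "convergence_rate_pct", "replicates_executed", "shortfall"]
    summary = pd.DataFrame(summary_rows)[[c for c in cols if c in summary_rows[0]]]
    return summary, reps


def performance_metrics(estimates: np.ndarray, ses: np.ndarray,
                        ci_low: np.ndarray, ci_high: np.ndarray,
                        truth: float) -> dict:
    """Simulation-study performance measures with Monte Carlo SEs.

    relative bias = 100 (mean - truth)/truth (absolute bias when truth is
    0); empirical SE = SD of the estimates; model SE = sqrt(mean squared
    estimated SE); coverage = percent of CIs containing the truth.  MCSEs:
    bias -> empSE/sqrt(nsim); empSE -> empSE/sqrt(2(nsim-1)); model SE ->
    delta-method on the mean of squared SEs; coverage -> binomial.
    """
    est = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    nsim = len(est)
    if nsim < 2:
        return {"nsim": nsim, "mean_estimate": float(est.mean()) if nsim else np.nan,
                "relative_bias_pct": np.nan, "relative_bias_mcse_pct": np.nan,
                "empirical_se": np.nan, "empirical_se_mcse": np.nan,
                "model_se": np.nan, "model_se_mcse": np.nan,
                "coverage_pct": np.nan, "coverage_mcse_pct": np.nan}
    mean_est = float(est.mean())
    bias = mean_est - truth
    emp_se = float(est.std(ddof=1))
    bias_mcse = emp_se / np.sqrt(nsim)
    if truth != 0:
        rel_bias = 100.0 * bias / truth
        rel_bias_mcse = 100.0 * bias_mcse / abs(truth)
    else:
        rel_bias = bias
        rel_bias_mcse = bias_mcse
    emp_se_mcse = emp_se / np.sqrt(2.0 * (nsim - 1))
    msq = ses ** 2
    model_se = float(np.sqrt(msq.mean()))
    model_se_mcse = float(np.sqrt(msq.var(ddof=1) / nsim) / (2.0 * model_se))
    covered = (ci_low <= truth) & (truth <= ci_high)
    cov = float(covered.mean())
    return {
        "nsim": nsim,
        "mean_estimate": mean_est,
        "relative_bias_pct": float(rel_bias),
        "relative_bias_mcse_pct": float(rel_bias_mcse),
        "empirical_se": emp_se,
        "empirical_se_mcse": float(emp_se_mcse),
        "model_se": model_se,
        "model_se_mcse": model_se_mcse,
        "coverage_pct": 100.0 * cov,
        "coverage_mcse_pct": coverage_mcse(cov, nsim),
    }


def coverage_mcse(coverage: float, nsim: int) -> float:
    """Monte Carlo SE of a coverage estimate, in percent."""
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be a proportion in [0, 1]")
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    return 100.0 * float(np.sqrt(coverage * (1.0 - coverage) / nsim))
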