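"""Multiple imputation engines: chained equations (FCS) and joint
multivariate-normal imputation (MVNI), with four ways of accommodating the
case-cohort weights in the imputation model.

The two incomplete covariates (``petown``, ``antevd``) are binary.  Under
FCS each is imputed from a logistic model fitted to the records where it is
observed, cycling petown -> antevd; coefficients are drawn from their
approximate normal posterior before each imputation draw (proper
imputation).  Under MVNI all variables enter a joint multivariate-normal
model sampled by data augmentation; imputed values are retained without
rounding.

Weight accommodations (the outcome is a perfect proxy for the weight
stratum in this design, since there are exactly two weight values):

* ``weight_only``   — outcome as a predictor, nothing else special;
* ``weight_interactions`` — adds outcome x analysis-variable interactions,
  recomputed within each cycle under FCS (passive) and included as "just
  another variable" under MVNI;
* ``stratum_specific`` — impute cases and non-cases separately, outcome
  excluded from the predictors;
* ``weighted_model`` — logistic fits maximize the weight-multiplied
  log-likelihood (FCS only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import expit

from .design import CaseCohortSample

__all__ = [
    "ImputationStrategy",
    "ImputationConfig",
    "CompletedDataset",
    "STRATEGIES",
    "build_imputation_design",
    "fcs_impute",
    "mvni_impute",
    "impute",
    "completed_to_csv",
    "posterior_draw_glm",
    "GlmFit",
    "FitError",
    "InvalidStrategyError",
]

INCOMPLETE_VARS = ("petown", "antevd")

#: analysis variables eligible for outcome interactions (WX)
_INTERACTABLE = ("vdi", "cauc", "hxfamall", "nsib1", "nsib2", "petown", "antevd")

#: absolute log-odds bound beyond which a logistic fit is treated as separated
SEPARATION_BOUND = 15.0


class InvalidStrategyError(ValueError):
    """Raised for strategy/framework combinations that are not defined."""


class FitError(RuntimeError):
    """A conditional-model fit failed (non-convergence, separation, singularity)."""


@dataclass(frozen=True)
class ImputationStrategy:
    """One MI approach: imputation framework plus weight accommodation."""

    framework: str
    accommodation: str
    label: str

    def __post_init__(self) -> None:
        if self.framework not in ("FCS", "MVNI"):
            raise InvalidStrategyError(f"unknown framework {self.framework!r}")
        if self.accommodation not in ("weight_only", "weight_interactions",
                                      "stratum_specific", "weighted_model"):
            raise InvalidStrategyError(f"unknown accommodation {self.accommodation!r}")
        if self.framework == "MVNI" and self.accommodation == "weighted_model":
            raise InvalidStrategyError(
                "a weighted imputation model is only defined within FCS")


#: the seven MI approaches under comparison
STRATEGIES: dict[str, ImputationStrategy] = {
    s.label: s for s in (
        ImputationStrategy("FCS", "weight_only", "FCS-WO"),
        ImputationStrategy("FCS", "weight_interactions", "FCS-WX"),
        ImputationStrategy("FCS", "stratum_specific", "FCS-SS"),
        ImputationStrategy("FCS", "weighted_model", "FCS-WM"),
        ImputationStrategy("MVNI", "weight_only", "MVNI-WO"),
        ImputationStrategy("MVNI", "weight_interactions", "MVNI-WX"),
        ImputationStrategy("MVNI", "stratum_specific", "MVNI-SS"),
    )
}


@dataclass(frozen=True)
class ImputationConfig:
    """Number of imputations and sampler effort per imputation.

    ``augment`` guards the conditional logistic fits against perfect
    prediction by adding a handful of small-weight pseudo-observations
    (the White–Daniel–Royston augmented-regression device used by
    mainstream chained-equations software); without it, sparse cells in
    small weight strata make quasi-separation frequent.
    """

    m: int = 30
    fcs_cycles: int = 10
    mvni_burnin: int = 200
    augment: bool = True

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("at least 2 imputations are required")
        if self.fcs_cycles < 1 or self.mvni_burnin < 1:
            raise ValueError("cycles and burn-in must be >= 1")


@dataclass
class CompletedDataset:
    """One completed copy of the analysed sample (imputation index 1..m)."""

    data: pd.DataFrame
    index: int
    converged: bool = True


# --------------------------------------------------------------------------
# Working representation: indicator-expanded columns
# --------------------------------------------------------------------------

def _expand(records: pd.DataFrame) -> pd.DataFrame:
    """Indicator-expanded numeric view of the analysed sample."""
    out = pd.DataFrame({
        "foodallergy": records["foodallergy"].astype(float).to_numpy(),
        "vdi": records["vdi"].astype(float).to_numpy(),
        "cauc": records["cauc"].astype(float).to_numpy(),
        "hxfamall": records["hxfamall"].astype(float).to_numpy(),
        "nsib1": (records["nsib"].to_numpy() == 1).astype(float),
        "nsib2": (records["nsib"].to_numpy() == 2).astype(float),
        "petown": records["petown"].astype(float).to_numpy(),
        "antevd": records["antevd"].astype(float).to_numpy(),
        "mage": records["mage"].astype(float).to_numpy(),
        "seifa1": (records["seifa"].to_numpy() == 1).astype(float),
        "seifa2": (records["seifa"].to_numpy() == 2).astype(float),
    })
    return out


def build_imputation_design(sample: CaseCohortSample,
                            strategy: ImputationStrategy) -> dict:
    """Predictor sets and fitting flags for each incomplete variable.

    The base predictor set contains the outcome, exposure, the other
    covariates (categoricals as indicator pairs), the other incomplete
    covariate, and the auxiliaries.  Accommodations modify it as described
    in the module docstring.
    """
    design: dict[str, dict] = {}
    for var in INCOMPLETE_VARS:
        other = "antevd" if var == "petown" else "petown"
        preds = ["foodallergy", "vdi", "cauc", "hxfamall", "nsib1", "nsib2",
                 other, "mage", "seifa1", "seifa2"]
        stratify = False
        weighted = False
        if strategy.accommodation == "weight_interactions":
            preds += [f"foodallergy:{x}" for x in _INTERACTABLE if x != var]
        elif strategy.accommodation == "stratum_specific":
            preds.remove("foodallergy")
            stratify = True
        elif strategy.accommodation == "weighted_model":
            if strategy.framework != "FCS":
                raise InvalidStrategyError(
                    "a weighted imputation model is only defined within FCS")
            weighted = True
        design[var] = {"predictors": preds, "stratify_by_outcome": stratify,
                       "weighted": weighted}
    return design


def _design_matrix(work: dict[str, np.ndarray], predictors: list[str],
                   rows: np.ndarray) -> np.ndarray:
    """Intercept + named columns; ``a:b`` denotes a product, built on the fly."""
    cols = [np.ones(int(rows.sum()) if rows.dtype == bool else len(rows))]
    for name in predictors:
        if ":" in name:
            a, b = name.split(":")
            v = work[a][rows] * work[b][rows]
        else:
            v = work[name][rows]
        cols.append(v)
    return np.column_stack(cols)


# --------------------------------------------------------------------------
# Logistic fitting and the approximate-posterior draw
# --------------------------------------------------------------------------

@dataclass
class GlmFit:
    """Point estimates and covariance from one conditional-model fit."""

    params: np.ndarray
    cov: np.ndarray
    converged: bool = True


def _logit_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray | None = None,
               max_iter: int = 60, tol: float = 1e-9) -> GlmFit:
    """Newton–Raphson logistic MLE, optionally maximizing a weighted log-likelihood.

    The covariance is the inverse (weighted) observed information, the
    model-based covariance of the fit.  Raises :class:`FitError` on
    separation or a singular information matrix.
    """
    n, k = X.shape
    if w is None:
        w = np.ones(n)
    beta = np.zeros(k)
    ybar = np.average(y, weights=w)
    if not 0.0 < ybar < 1.0:
        raise FitError("outcome constant in fitting sample")
    beta[0] = np.log(ybar / (1.0 - ybar))

    def loglik(b: np.ndarray) -> float:
        eta = X @ b
        # numerically stable w * (y*eta - log(1+exp(eta)))
        return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))

    ll = loglik(beta)
    for _ in range(max_iter):
        mu = expit(X @ beta)
        grad = X.T @ (w * (y - mu))
        wt = np.clip(w * mu * (1.0 - mu), 1e-12, None)
        H = (X * wt[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular information matrix") from exc
        # step-halving: Newton can overshoot badly on near-separated data
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise FitError("logistic fit: no likelihood-increasing step")
        converged = np.abs(scale * step).max() < tol or abs(ll_new - ll) < 1e-12
        beta, ll = cand, ll_new
        if converged:
            if np.abs(beta).max() > SEPARATION_BOUND:
                raise FitError("separation suspected (coefficient out of bounds)")
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError as exc:
                raise FitError("singular information matrix") from exc
            return GlmFit(beta, cov)
    raise FitError("logistic fit did not converge")


def _augment_against_separation(X: np.ndarray, y: np.ndarray,
                                w: np.ndarray | None):
    """Pseudo-observations that keep the logistic MLE finite.

    For every non-constant predictor and each outcome class, two rows are
    added at the predictor means with that predictor moved +-0.5 SD; the
    pseudo rows share a total weight of (#predictors + 1) spread evenly,
    so their influence vanishes as n grows.
    """
    n, kp1 = X.shape
    p = kp1 - 1
    means = X[:, 1:].mean(axis=0)
    sds = X[:, 1:].std(axis=0)
    rows, ys = [], []
    for j in range(p):
        if sds[j] == 0:
            continue
        for yy in (0.0, 1.0):
            for shift in (0.5, -0.5):
                r = np.concatenate([[1.0], means])
                r[1 + j] += shift * sds[j]
                rows.append(r)
                ys.append(yy)
    if not rows:
        return X, y, w
    Xa = np.vstack([X, np.array(rows)])
    ya = np.concatenate([y, np.array(ys)])
    w_obs = np.ones(n) if w is None else w
    w_pseudo = np.full(len(rows), (p + 1) / len(rows))
    return Xa, ya, np.concatenate([w_obs, w_pseudo])


def posterior_draw_glm(fit, rng: np.random.Generator) -> np.ndarray:
    """Approximate Bayesian coefficient draw: beta* ~ N(beta_hat, V_hat).

    Accepts a :class:`GlmFit` or any object exposing ``params`` and a
    covariance (``cov`` attribute or ``cov_params()`` method).  A zero
    covariance returns the point estimate; a non-positive-definite
    covariance raises :class:`FitError`.
    """
    beta = np.asarray(fit.params, dtype=float)
    if hasattr(fit, "cov"):
        cov = np.asarray(fit.cov, dtype=float)
    else:
        cov = np.asarray(fit.cov_params(), dtype=float)
    if not np.all(np.isfinite(cov)):
        raise FitError("non-finite posterior covariance")
    if np.allclose(cov, 0.0):
        return beta.copy()
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise FitError("posterior covariance not positive definite") from exc
    return beta + L @ rng.standard_normal(beta.shape[0])


# --------------------------------------------------------------------------
# FCS engine
# --------------------------------------------------------------------------

def fcs_impute(sample: CaseCohortSample, strategy: ImputationStrategy,
               config: ImputationConfig, rng: np.random.Generator,
               ) -> list[CompletedDataset]:
    """Chained-equations imputation: m independent repetitions.

    Per imputation, missing entries are initialized by resampling observed
    values, then ``fcs_cycles`` cycles visit petown then antevd: fit the
    (possibly weighted, possibly stratified) logistic model on the records
    where the variable is observed, draw coefficients from the approximate
    posterior, and draw imputed values Bernoulli(expit(x . beta*)).
    Interaction predictors are recomputed within every cycle.  A failed fit
    marks that imputation non-converged.
    """
    if strategy.framework != "FCS":
        raise InvalidStrategyError(f"{strategy.label} is not an FCS strategy")
    design = build_imputation_design(sample, strategy)
    base = _expand(sample.records)
    arrays = {c: base[c].to_numpy(dtype=float) for c in base.columns}
    weights = sample.weights
    masks = {v: np.isnan(arrays[v]) for v in INCOMPLETE_VARS}
    n_missing = sum(int(m.sum()) for m in masks.values())

    out: list[CompletedDataset] = []
    for b in range(config.m):
        if n_missing == 0:
            out.append(CompletedDataset(sample.records.copy(), b + 1, True))
            continue
        work = {c: v.copy() for c, v in arrays.items()}
        for v, mask in masks.items():
            obs = work[v][~mask]
            work[v][mask] = rng.choice(obs, size=int(mask.sum()), replace=True)
        converged = True
        for _cycle in range(config.fcs_cycles):
            for v in INCOMPLETE_VARS:
                mask = masks[v]
                if not mask.any():
                    continue
                spec_v = design[v]
                try:
                    _impute_one_var(work, v, mask, spec_v, weights, rng,
                                    augment=config.augment)
                except FitError:
                    converged = False
                    break
            if not converged:
                break
        completed = sample.records.copy()
        for v, mask in masks.items():
            vals = completed[v].to_numpy(dtype=float)
            vals[mask] = work[v][mask]
            completed[v] = vals
        out.append(CompletedDataset(completed, b + 1, converged))
    return out


def _impute_one_var(work: dict[str, np.ndarray], var: str, mask: np.ndarray,
                    spec: dict, weights: np.ndarray,
                    rng: np.random.Generator, augment: bool = True) -> None:
    """One FCS visit to one incomplete variable, in place."""
    y_all = work[var]
    if spec["stratify_by_outcome"]:
        strata = work["foodallergy"]
        for s in (0.0, 1.0):
            in_s = strata == s
            fit_rows = in_s & ~mask
            imp_rows = in_s & mask
            if not imp_rows.any():
                continue
            X = _design_matrix(work, spec["predictors"], fit_rows)
            yf, wf = y_all[fit_rows], None
            if augment:
                X, yf, wf = _augment_against_separation(X, yf, wf)
            fit = _logit_fit(X, yf, wf)
            beta = posterior_draw_glm(fit, rng)
            Xm = _design_matrix(work, spec["predictors"], imp_rows)
            p = expit(Xm @ beta)
            work[var][imp_rows] = (rng.random(int(imp_rows.sum())) < p).astype(float)
    else:
        fit_rows = ~mask
        X = _design_matrix(work, spec["predictors"], fit_rows)
        yf = y_all[fit_rows]
        wf = weights[fit_rows] if spec["weighted"] else None
        if augment:
            X, yf, wf = _augment_against_separation(X, yf, wf)
        fit = _logit_fit(X, yf, wf)
        beta = posterior_draw_glm(fit, rng)
        Xm = _design_matrix(work, spec["predictors"], mask)
        p = expit(Xm @ beta)
        work[var][mask] = (rng.random(int(mask.sum())) < p).astype(float)


# --------------------------------------------------------------------------
# MVNI engine: data augmentation under a joint normal model
# --------------------------------------------------------------------------

def mvni_impute(sample: CaseCohortSample, strategy: ImputationStrategy,
                config: ImputationConfig, rng: np.random.Generator,
                ) -> list[CompletedDataset]:
    """Joint multivariate-normal imputation by data augmentation.

    All variables (binaries as 0/1, categoricals as indicator columns, and
    under ``weight_interactions`` the outcome-by-variable products as
    additional "just another variable" columns) are modelled jointly
    normal.  Each imputation runs an independent chain: after
    ``mvni_burnin`` alternations of (mean, covariance) draws under the
    Jeffreys prior and conditional-normal draws of the missing entries, the
    chain state is the imputation.  Imputed values are retained unrounded.
    ``stratum_specific`` runs the sampler separately per outcome stratum
    with the outcome column dropped.
    """
    if strategy.framework != "MVNI":
        raise InvalidStrategyError(f"{strategy.label} is not an MVNI strategy")

    base = _expand(sample.records)
    columns = ["foodallergy", "vdi", "cauc", "hxfamall", "nsib1", "nsib2",
               "petown", "antevd", "mage", "seifa1", "seifa2"]
    jav: list[tuple[str, str]] = []
    if strategy.accommodation == "weight_interactions":
        jav = [("foodallergy", x) for x in _INTERACTABLE]

    Y = base[columns].to_numpy(dtype=float)
    names = list(columns)
    for a, b in jav:
        names.append(f"{a}:{b}")
        Y = np.column_stack([Y, base[a].to_numpy() * base[b].to_numpy()])
    miss = np.isnan(Y)
    n_missing = int(miss.sum())

    out: list[CompletedDataset] = []
    for b_idx in range(config.m):
        if n_missing == 0:
            out.append(CompletedDataset(sample.records.copy(), b_idx + 1, True))
            continue
        if strategy.accommodation == "stratum_specific":
            keep = [j for j, nm in enumerate(names) if nm != "foodallergy"]
            Ys = Y[:, keep].copy()
            ms = miss[:, keep]
            converged = True
            strata = base["foodallergy"].to_numpy()
            for s in (0.0, 1.0):
                rows = strata == s
                done, ok = _da_chain(Ys[rows], ms[rows], config.mvni_burnin, rng)
                Ys[rows] = done
                converged = converged and ok
            full = Y.copy()
            full[:, keep] = Ys
        else:
            full, converged = _da_chain(Y.copy(), miss, config.mvni_burnin, rng)
        completed = sample.records.copy()
        for v in INCOMPLETE_VARS:
            j = names.index(v)
            vals = completed[v].to_numpy(dtype=float)
            vals[miss[:, j]] = full[miss[:, j], j]
            completed[v] = vals
        out.append(CompletedDataset(completed, b_idx + 1, converged))
    return out


_TRIL_CACHE: dict[int, tuple] = {}


def _draw_inv_wishart(S: np.ndarray, df: int, rng: np.random.Generator,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Draw Sigma ~ InvWishart(df, S) by the Bartlett decomposition.

    Returns (Sigma, G) with G G' = Sigma, so the caller gets a factor for
    normal draws without an extra Cholesky.  With L = chol(S) and A the
    Bartlett factor, W = L^-T A A' L^-1 ~ Wishart(df, S^-1), and
    Sigma = W^-1 = G G' with G = L A^-T.
    """
    k = S.shape[0]
    if k not in _TRIL_CACHE:
        _TRIL_CACHE[k] = (np.tril_indices(k, -1), np.arange(k))
    (rows, cols), diag = _TRIL_CACHE[k]
    L = np.linalg.cholesky(S)
    A = np.zeros((k, k))
    A[rows, cols] = rng.standard_normal(rows.size)
    A[diag, diag] = np.sqrt(rng.chisquare(df - diag))
    G = L @ solve_triangular(A, np.eye(k), lower=True).T
    return G @ G.T, G


def _da_chain(Y: np.ndarray, miss: np.ndarray, burnin: int,
              rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """One data-augmentation chain; returns (completed data, converged)."""
    n, k = Y.shape
    # initialize missing entries by resampling observed values per column
    for j in range(k):
        mj = miss[:, j]
        if mj.any():
            obs = Y[~mj, j]
            Y[mj, j] = rng.choice(obs, size=int(mj.sum()), replace=True)

    # group rows by missingness pattern; observed blocks never change
    patt, inverse = np.unique(miss, axis=0, return_inverse=True)
    groups = []
    for g in range(len(patt)):
        if not patt[g].any():
            continue
        rows = np.where(inverse == g)[0]
        m_idx = np.where(patt[g])[0]
        o_idx = np.where(~patt[g])[0]
        groups.append({
            "m_idx": m_idx,
            "oo": np.ix_(o_idx, o_idx),
            "mo": np.ix_(m_idx, o_idx),
            "mm": np.ix_(m_idx, m_idx),
            "o_sel": o_idx,
            "set_at": np.ix_(rows, m_idx),
            "Yo": Y[np.ix_(rows, o_idx)].copy(),
            "nrows": len(rows),
        })

    sqrt_n = np.sqrt(n)
    ridge_used = False
    for _sweep in range(burnin):
        ybar = Y.mean(axis=0)
        R = Y - ybar
        S = R.T @ R
        try:
            sigma, G = _draw_inv_wishart(S, n - 1, rng)
        except np.linalg.LinAlgError:
            if ridge_used:
                return Y, False
            ridge_used = True
            S = S + 1e-6 * np.trace(S) / k * np.eye(k)
            try:
                sigma, G = _draw_inv_wishart(S, n - 1, rng)
            except np.linalg.LinAlgError:
                return Y, False
        mu = ybar + (G @ rng.standard_normal(k)) / sqrt_n
        # conditional distributions via the precision matrix:
        # cov(miss | obs) = inv(P_mm), mean shift = -inv(P_mm) P_mo (y_o - mu_o)
        Linv = solve_triangular(np.linalg.cholesky(sigma), np.eye(k), lower=True)
        P = Linv.T @ Linv

        for grp in groups:
            m_idx = grp["m_idx"]
            resid = grp["Yo"] - mu[grp["o_sel"]]
            shift = resid @ P[grp["mo"]].T
            if len(m_idx) == 1:
                c = 1.0 / P[grp["mm"]][0, 0]
                mean = mu[m_idx] - c * shift
                z = rng.standard_normal((grp["nrows"], 1))
                Y[grp["set_at"]] = mean + np.sqrt(c) * z
                continue
            try:
                C = np.linalg.inv(P[grp["mm"]])
                L = np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                return Y, False
            mean = mu[m_idx] - shift @ C.T
            z = rng.standard_normal((grp["nrows"], len(m_idx)))
            Y[grp["set_at"]] = mean + z @ L.T
    return Y, True


def impute(sample: CaseCohortSample, strategy: ImputationStrategy,
           config: ImputationConfig, rng: np.random.Generator,
           ) -> list[CompletedDataset]:
    """Dispatch to the framework-specific engine."""
    if strategy.framework == "FCS":
        return fcs_impute(sample, strategy, config, rng)
    return mvni_impute(sample, strategy, config, rng)


def completed_to_csv(completed: list[CompletedDataset], path) -> None:
    """Export completed datasets as one stacked (long-format) CSV.

    Rows carry an ``imputation`` index column (1..m) ahead of the record
    columns.
    """
    frames = []
    for c in completed:
        frame = c.data.copy()
        frame.insert(0, "imputation", c.index)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, na_rep="")
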