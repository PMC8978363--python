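"""Missingness induction in pet ownership and antenatal vitamin D use.

Two covariates, ``petown`` and ``antevd``, are made incomplete so that p% of
records have at least one missing value, with p/2% missing exactly one
covariate and p/2% missing both.  Three mechanisms are supported:

* ``independent`` — missingness assigned completely at random, with exact
  counts so realized proportions match the targets deterministically;
* ``DMO`` — dependent missingness, observed strength: logistic models for
  the indicators M_petown (on outcome, ethnicity, maternal age) and
  M_antevd (same predictors plus the realized M_petown);
* ``DME`` — dependent missingness, enhanced: the DMO slopes doubled.

Under the dependent mechanisms the intercepts (and the M_petown coefficient
in the antevd model) are calibrated by root finding on a large simulated
cohort so the expected proportions hit the targets; slopes are never touched
by calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .dgp import DGPParams, OutcomeSpec, ConfigurationError, generate_cohort

__all__ = [
    "MissingnessParams",
    "induce_independent",
    "induce_dependent",
    "induce_missingness",
    "calibrate_intercepts",
    "missingness_summary",
    "MECHANISMS",
]

MECHANISMS = ("independent", "DMO", "DME")

#: default dependent-mechanism slopes at observed (DMO) strength:
#: (outcome, cauc, mage); the enhanced mechanism (DME) doubles them
DEFAULT_DMO_SLOPES = (0.5, -0.3, 0.05)


class CalibrationError(RuntimeError):
    """Raised when intercept calibration cannot reach the target proportions."""


@dataclass(frozen=True)
class MissingnessParams:
    """Mechanism, target proportion p (percent), and indicator-model coefficients.

    ``nu`` = (nu0, outcome, cauc, mage) for M_petown; ``tau`` = (tau0,
    outcome, cauc, mage, M_petown) for M_antevd.  Intercepts nu0, tau0 and
    the coupling tau4 default to NaN until calibrated.
    """

    mechanism: str
    p: float
    nu: tuple[float, ...] = (float("nan"),) + DEFAULT_DMO_SLOPES
    tau: tuple[float, ...] = (float("nan"),) + DEFAULT_DMO_SLOPES + (float("nan"),)

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(f"unknown mechanism {self.mechanism!r}")
        if not 0.0 <= self.p < 100.0:
            raise ConfigurationError(f"p must be a percentage in [0,100), got {self.p}")
        if len(self.nu) != 4 or len(self.tau) != 5:
            raise ConfigurationError("nu needs 4 coefficients, tau needs 5")

    @property
    def calibrated(self) -> bool:
        return np.isfinite(self.nu[0]) and np.isfinite(self.tau[0]) and np.isfinite(self.tau[4])


def default_params(mechanism: str, p: float) -> MissingnessParams:
    """Default (uncalibrated) parameters; DME slopes are exactly 2x DMO."""
    if mechanism == "DME":
        s = tuple(2.0 * x for x in DEFAULT_DMO_SLOPES)
        return MissingnessParams("DME", p, nu=(np.nan,) + s, tau=(np.nan,) + s + (np.nan,))
    return MissingnessParams(mechanism, p)


# --------------------------------------------------------------------------
# Independent mechanism: exact-count assignment
# --------------------------------------------------------------------------

def induce_independent(cohort: pd.DataFrame, p: float,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Mask petown/antevd completely at random with exact target counts.

    p/2% of records lose both covariates and p/2% exactly one (split as
    evenly as possible between petown-only and antevd-only; petown gets the
    odd record).
    """
    n = len(cohort)
    n_inc = round(n * p / 100.0)
    if n_inc > n:
        raise ConfigurationError(f"p={p} implies {n_inc} incomplete records but n={n}")
    if n_inc == 0:
        return cohort.copy()
    n_both = round(n * p / 200.0)
    n_single = n_inc - n_both
    n_pet = (n_single + 1) // 2
    chosen = rng.choice(n, size=n_inc, replace=False)
    out = cohort.copy()
    both = chosen[:n_both]
    pet_only = chosen[n_both:n_both + n_pet]
    ant_only = chosen[n_both + n_pet:]
    cols = out.columns
    out.iloc[both, cols.get_loc("petown")] = np.nan
    out.iloc[both, cols.get_loc("antevd")] = np.nan
    out.iloc[pet_only, cols.get_loc("petown")] = np.nan
    out.iloc[ant_only, cols.get_loc("antevd")] = np.nan
    return out


# --------------------------------------------------------------------------
# Dependent mechanisms
# --------------------------------------------------------------------------

def _indicator_probs(cohort: pd.DataFrame, mparams: MissingnessParams):
    """Per-record P(M_petown=1) and P(M_antevd=1 | M_petown) pair."""
    y = cohort["foodallergy"].to_numpy(dtype=float)
    cauc = cohort["cauc"].to_numpy(dtype=float)
    mage = cohort["mage"].to_numpy(dtype=float)
    nu = mparams.nu
    tau = mparams.tau
    p_pet = expit(nu[0] + nu[1] * y + nu[2] * cauc + nu[3] * mage)
    lp_ant = tau[0] + tau[1] * y + tau[2] * cauc + tau[3] * mage
    return p_pet, expit(lp_ant), expit(lp_ant + tau[4])


def induce_dependent(cohort: pd.DataFrame, mparams: MissingnessParams,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Draw the two missingness indicators sequentially and mask values.

    M_petown is Bernoulli of a logistic in (outcome, cauc, mage); M_antevd
    is Bernoulli of a logistic in the same predictors plus the realized
    M_petown.
    """
    if not mparams.calibrated:
        raise CalibrationError("missingness parameters are not calibrated")
    p_pet, p_ant0, p_ant1 = _indicator_probs(cohort, mparams)
    m_pet = rng.random(len(cohort)) < p_pet
    p_ant = np.where(m_pet, p_ant1, p_ant0)
    m_ant = rng.random(len(cohort)) < p_ant
    out = cohort.copy()
    out.loc[m_pet, "petown"] = np.nan
    out.loc[m_ant, "antevd"] = np.nan
    return out


def induce_missingness(cohort: pd.DataFrame, mparams: MissingnessParams,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Dispatch on the mechanism; p = 0 returns the cohort unchanged."""
    if mparams.p == 0:
        return cohort.copy()
    if mparams.mechanism == "independent":
        return induce_independent(cohort, mparams.p, rng)
    return induce_dependent(cohort, mparams, rng)


# --------------------------------------------------------------------------
# Intercept calibration
# --------------------------------------------------------------------------

def calibrate_intercepts(
    dgp: DGPParams,
    spec: OutcomeSpec,
    mparams: MissingnessParams,
    rng: np.random.Generator,
    n_calib: int = 200_000,
    tol_pp: float = 0.25,
) -> MissingnessParams:
    """Choose nu0, tau0 and tau4 to hit the target missingness proportions.

    Targets on a large calibration cohort: P(M_petown) = P(M_antevd) = 3p/4
    percent and P(both) = p/2 percent, which yields p% of records with at
    least one missing covariate split equally between one-covariate and
    both-covariate patterns.  Root finding operates on *expected*
    proportions (means of per-record logistic probabilities), so the solve
    is deterministic given the calibration cohort.
    """
    if mparams.mechanism == "independent":
        return mparams
    p = mparams.p
    if p == 0:
        return replace(mparams, nu=(-np.inf,) + mparams.nu[1:],
                       tau=(-np.inf,) + mparams.tau[1:4] + (0.0,))
    t_marg = 0.75 * p / 100.0    # each indicator's marginal
    t_both = 0.5 * p / 100.0     # overlap

    cohort = generate_cohort(dgp, spec, n_calib, rng)
    y = cohort["foodallergy"].to_numpy(dtype=float)
    cauc = cohort["cauc"].to_numpy(dtype=float)
    mage = cohort["mage"].to_numpy(dtype=float)
    nu = mparams.nu
    tau = mparams.tau
    lp_pet = nu[1] * y + nu[2] * cauc + nu[3] * mage
    lp_ant = tau[1] * y + tau[2] * cauc + tau[3] * mage

    lo, hi = -30.0, 30.0
    nu0 = brentq(lambda c: expit(c + lp_pet).mean() - t_marg, lo, hi, xtol=1e-10)
    p_pet = expit(nu0 + lp_pet)

    def ant_marginal(tau0: float, tau4: float) -> float:
        return float(np.mean(p_pet * expit(tau0 + tau4 + lp_ant)
                             + (1 - p_pet) * expit(tau0 + lp_ant)))

    def overlap(tau0: float, tau4: float) -> float:
        return float(np.mean(p_pet * expit(tau0 + tau4 + lp_ant)))

    def tau0_for(tau4: float) -> float:
        return brentq(lambda c: ant_marginal(c, tau4) - t_marg, lo, hi, xtol=1e-10)

    def overlap_gap(tau4: float) -> float:
        return overlap(tau0_for(tau4), tau4) - t_both

    try:
        tau4 = brentq(overlap_gap, -20.0, 20.0, xtol=1e-10)
    except ValueError as exc:  # no sign change: overlap target unreachable
        raise CalibrationError(
            f"cannot reach both-missing target {t_both:.4f}: achievable overlap "
            f"range [{overlap(tau0_for(-20.0), -20.0):.4f}, "
            f"{overlap(tau0_for(20.0), 20.0):.4f}]"
        ) from exc
    tau0 = tau0_for(tau4)

    calibrated = replace(
        mparams,
        nu=(float(nu0),) + tuple(mparams.nu[1:]),
        tau=(float(tau0),) + tuple(mparams.tau[1:4]) + (float(tau4),),
    )
    # verify expected pattern proportions against the stated tolerance;
    # P(any missing) = P(Mp) + P(not Mp) * P(Ma | not Mp)
    p_pet_c, p_ant0, p_ant1 = _indicator_probs(cohort, calibrated)
    e_both = float(np.mean(p_pet_c * p_ant1))
    e_any = float(np.mean(p_pet_c + (1 - p_pet_c) * p_ant0))
    if abs(e_any * 100 - p) > tol_pp or abs(e_both * 100 - p / 2) > tol_pp:
        raise CalibrationError(
            f"calibration achieved {e_any*100:.3f}% incomplete / "
            f"{e_both*100:.3f}% both-missing against targets {p}% / {p/2}%"
        )
    return calibrated


def missingness_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of records by missingness pattern."""
    mp = cohort["petown"].isna().to_numpy()
    ma = cohort["antevd"].isna().to_numpy()
    n = len(cohort)
    counts = {
        "complete": int((~mp & ~ma).sum()),
        "petown_only": int((mp & ~ma).sum()),
        "antevd_only": int((~mp & ma).sum()),
        "both": int((mp & ma).sum()),
    }
    return pd.DataFrame({
        "pattern": list(counts),
        "count": list(counts.values()),
        "percent": [100.0 * c / n for c in counts.values()],
    })
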