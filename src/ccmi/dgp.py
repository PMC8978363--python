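"""Synthetic cohort generation.

Generates complete cohorts that emulate a birth-cohort food-allergy
investigation: a binary exposure (vitamin D insufficiency at birth, ``vdi``),
a binary outcome (food allergy at one year, ``foodallergy``), five
confounders (Caucasian ethnicity ``cauc``, antenatal vitamin D use
``antevd``, family history of allergy ``hxfamall``, number of siblings
``nsib`` as a 3-level categorical, pet ownership ``petown``) and two
auxiliary variables (maternal age ``mage``, continuous; socioeconomic
tertile ``seifa``).

Variables are drawn sequentially from conditional models that follow a
plausible causal ordering: ethnicity first, then maternal age, the
socioeconomic tertile, family history, number of siblings, pet ownership and
antenatal vitamin D use, the exposure, and finally the outcome.  Binary
variables use logistic models, the two 3-level categoricals use
baseline-category (multinomial) logits with category 0 as reference, and
maternal age is Gaussian given ethnicity.

The outcome is generated so that the target analysis is correctly specified:
under the risk-ratio (RR) estimand the event probability follows a log-link
model, under the odds-ratio (OR) estimand a logit-link model, both with the
linear predictor

    intercept + b1*vdi + b2*cauc + b3*petown + b4*[nsib=1] + b5*[nsib=2]
    + b6*antevd + b7*hxfamall

The default parameter registry is data, not code: slopes are modest effects
and every intercept was calibrated by Monte Carlo so that the simulated
marginals match the cohort the study emulates (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields

import numpy as np
import pandas as pd
import yaml

from scipy.special import expit

__all__ = [
    "DGPParams",
    "OutcomeSpec",
    "make_scenario_params",
    "generate_covariates",
    "generate_outcome",
    "generate_cohort",
    "outcome_linear_predictor",
    "save_params",
    "load_params",
    "cohort_to_csv",
    "VARIANTS",
    "ASSOCIATIONS",
    "ESTIMANDS",
]

VARIANTS = ("observed", "extreme")
ASSOCIATIONS = ("observed", "enhanced")
ESTIMANDS = ("RR", "OR")

#: columns of a complete cohort table, in generation order
COHORT_COLUMNS = [
    "id", "cauc", "mage", "seifa", "hxfamall", "nsib",
    "petown", "antevd", "vdi", "foodallergy",
]


class ConfigurationError(ValueError):
    """Raised for unknown scenario labels or invalid parameter values."""


@dataclass(frozen=True)
class DGPParams:
    """Coefficients of the sequential data-generating models.

    Coefficient ordering follows the linear predictors:

    * ``delta``: (intercept, cauc, sd) for maternal age.
    * ``zeta`` / ``eta``: (intercept, mage, cauc) for seifa=1 / seifa=2
      versus seifa=0.
    * ``iota``: (intercept, cauc) for family history.
    * ``kappa`` / ``lambda_``: (intercept, mage, cauc, [seifa=1], [seifa=2],
      hxfamall) for nsib=1 / nsib=2 versus nsib=0.
    * ``rho`` / ``phi``: (intercept, mage, cauc, [seifa=1], [seifa=2],
      hxfamall, [nsib=1], [nsib=2]) for pet ownership / antenatal vitamin D.
    * ``psi``: (intercept, mage, cauc, [seifa=1], [seifa=2], hxfamall,
      [nsib=1], [nsib=2], petown, antevd) for the exposure.
    """

    p_cauc: float
    delta: tuple[float, ...]
    zeta: tuple[float, ...]
    eta: tuple[float, ...]
    iota: tuple[float, ...]
    kappa: tuple[float, ...]
    lambda_: tuple[float, ...]
    rho: tuple[float, ...]
    phi: tuple[float, ...]
    psi: tuple[float, ...]

    _ARITY = {"delta": 3, "zeta": 3, "eta": 3, "iota": 2, "kappa": 6,
              "lambda_": 6, "rho": 8, "phi": 8, "psi": 10}

    def __post_init__(self) -> None:
        if not 0.0 < self.p_cauc < 1.0:
            raise ConfigurationError(f"p_cauc must be in (0,1), got {self.p_cauc}")
        if self.delta[2] < 0:
            raise ConfigurationError("maternal-age noise SD must be >= 0")
        for name, k in self._ARITY.items():
            v = getattr(self, name)
            if len(v) != k:
                raise ConfigurationError(f"{name} needs {k} coefficients, got {len(v)}")


@dataclass(frozen=True)
class OutcomeSpec:
    """Outcome-model specification.

    ``theta`` are the log-link (RR) coefficients, ``beta`` the logit-link
    (OR) ones; ``estimand`` selects which model generates the outcome.  The
    exposure coefficient (index 1) is log of the adjusted RR / OR.
    """

    estimand: str
    theta: tuple[float, ...]
    beta: tuple[float, ...]
    association: str = "observed"

    def __post_init__(self) -> None:
        if self.estimand not in ESTIMANDS:
            raise ConfigurationError(f"unknown estimand {self.estimand!r}")
        if self.association not in ASSOCIATIONS:
            raise ConfigurationError(f"unknown association {self.association!r}")
        if len(self.theta) != 8 or len(self.beta) != 8:
            raise ConfigurationError("outcome models need 8 coefficients each")

    @property
    def true_coef(self) -> float:
        """The generating log-RR or log-OR for the exposure."""
        return self.theta[1] if self.estimand == "RR" else self.beta[1]


# --------------------------------------------------------------------------
# Default parameter registry
#
# Slopes are modest a-priori effects; intercepts were calibrated by Monte
# Carlo (n = 1,000,000 cohorts, root finding on the mean event probability)
# so that simulated marginals match the emulated cohort:
#   cauc 0.721, mage ~ (32.1, 4.78), seifa (0.254, 0.194, 0.552),
#   hxfamall 0.861, nsib (0.422, 0.357, 0.222), petown 0.805, antevd 0.788,
#   vdi 0.445; outcome prevalence 8% (observed variant) and 20.4% RR /
#   18.4% OR (extreme variant).
# --------------------------------------------------------------------------

#: multiplier applied to the maternal-age slopes of the pet-ownership,
#: antenatal-vitamin-D and exposure models under the "extreme" variant
DEFAULT_STRENGTHENING_FACTOR = 2.0

_OBSERVED_DGP = dict(
    p_cauc=0.721,
    delta=(31.3800, 1.0, 4.7576),
    zeta=(-1.0305, 0.02, 0.2),
    eta=(-1.1766, 0.05, 0.5),
    iota=(1.6138, 0.3),
    kappa=(-1.2278, 0.03, -0.2, 0.1, 0.1, 0.2),
    lambda_=(-2.4273, 0.05, -0.3, 0.1, 0.2, 0.3),
    rho=(-0.0690, 0.03, 0.3, 0.1, -0.1, 0.2, 0.3, 0.4),
    phi=(-0.3530, 0.04, 0.3, 0.1, 0.3, 0.1, -0.1, -0.2),
    psi=(1.5890, -0.04, -0.4, 0.1, -0.2, 0.1, 0.1, 0.2, -0.1, -0.3),
)

#: non-intercept outcome slopes, shared by both links:
#: (vdi, cauc, petown, nsib1, nsib2, antevd, hxfamall)
_OUTCOME_SLOPES = (0.3, -0.2, -0.15, -0.3, -0.2, 0.4)
_RR_OBSERVED = float(np.log(1.16))
_OR_OBSERVED = float(np.log(1.18))
_ENHANCED = float(np.log(2.0))

#: calibrated outcome intercepts, keyed (variant, association, estimand)
_OUTCOME_INTERCEPTS = {
    ("observed", "observed", "RR"): -2.7464,
    ("observed", "observed", "OR"): -2.6661,
    ("observed", "enhanced", "RR"): -3.0439,
    ("observed", "enhanced", "OR"): -2.9462,
    ("extreme", "observed", "RR"): -1.7187,
    ("extreme", "observed", "OR"): -1.6119,
    ("extreme", "enhanced", "RR"): -1.8565,
    ("extreme", "enhanced", "OR"): -1.7292,
}


def make_scenario_params(
    variant: str = "observed",
    association: str = "observed",
    estimand: str = "RR",
    strengthening_factor: float = DEFAULT_STRENGTHENING_FACTOR,
) -> tuple[DGPParams, OutcomeSpec]:
    """Return the default parameter registry for one scenario family.

    ``variant="extreme"`` multiplies the maternal-age slopes of the
    pet-ownership, antenatal-vitamin-D and exposure models by
    ``strengthening_factor`` (the stress-test conditions); ``association``
    selects the exposure effect: log(1.16) RR / log(1.18) OR under
    ``observed`` versus log(2.0) under ``enhanced``.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}")
    if association not in ASSOCIATIONS:
        raise ConfigurationError(f"unknown association {association!r}")
    if estimand not in ESTIMANDS:
        raise ConfigurationError(f"unknown estimand {estimand!r}")

    params = DGPParams(**_OBSERVED_DGP)
    if variant == "extreme":
        def strengthen(v: tuple[float, ...]) -> tuple[float, ...]:
            v = list(v)
            v[1] *= strengthening_factor  # index 1 is the mage slope
            return tuple(v)
        params = replace(
            params,
            rho=strengthen(params.rho),
            phi=strengthen(params.phi),
            psi=strengthen(params.psi),
        )

    exposure_rr = _RR_OBSERVED if association == "observed" else _ENHANCED
    exposure_or = _OR_OBSERVED if association == "observed" else _ENHANCED
    theta = (_OUTCOME_INTERCEPTS[(variant, association, "RR")],
             exposure_rr, *_OUTCOME_SLOPES)
    beta = (_OUTCOME_INTERCEPTS[(variant, association, "OR")],
            exposure_or, *_OUTCOME_SLOPES)
    spec = OutcomeSpec(estimand=estimand, theta=theta, beta=beta,
                       association=association)
    return params, spec


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def _categorical3(lp1: np.ndarray, lp2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from a 3-category baseline-category logit (category 0 reference)."""
    denom = 1.0 + np.exp(lp1) + np.exp(lp2)
    p1 = np.exp(lp1) / denom
    p2 = np.exp(lp2) / denom
    u = rng.random(lp1.shape[0])
    return np.where(u < p1, 1, np.where(u < p1 + p2, 2, 0)).astype(np.int64)


def generate_covariates(params: DGPParams, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Generate `n` complete records of covariates, auxiliaries and exposure.

    Each variable is drawn from its conditional model given the previously
    generated variables; the outcome is added separately by
    :func:`generate_outcome`.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    cauc = (rng.random(n) < params.p_cauc).astype(np.int64)

    d0, d1, sd = params.delta
    mage = d0 + d1 * cauc + rng.normal(0.0, sd, n) if sd > 0 else d0 + d1 * cauc + np.zeros(n)

    z = params.zeta
    e = params.eta
    seifa = _categorical3(z[0] + z[1] * mage + z[2] * cauc,
                          e[0] + e[1] * mage + e[2] * cauc, rng)
    s1 = (seifa == 1).astype(np.int64)
    s2 = (seifa == 2).astype(np.int64)

    i0, i1 = params.iota
    hxfamall = (rng.random(n) < expit(i0 + i1 * cauc)).astype(np.int64)

    k = params.kappa
    l = params.lambda_
    base = np.column_stack([np.ones(n), mage, cauc, s1, s2, hxfamall])
    nsib = _categorical3(base @ np.asarray(k), base @ np.asarray(l), rng)
    n1 = (nsib == 1).astype(np.int64)
    n2 = (nsib == 2).astype(np.int64)

    ext = np.column_stack([np.ones(n), mage, cauc, s1, s2, hxfamall, n1, n2])
    petown = (rng.random(n) < expit(ext @ np.asarray(params.rho))).astype(np.int64)
    antevd = (rng.random(n) < expit(ext @ np.asarray(params.phi))).astype(np.int64)

    full = np.column_stack([ext, petown, antevd])
    vdi = (rng.random(n) < expit(full @ np.asarray(params.psi))).astype(np.int64)

    return pd.DataFrame({
        "id": np.arange(n, dtype=np.int64),
        "cauc": cauc, "mage": mage, "seifa": seifa, "hxfamall": hxfamall,
        "nsib": nsib, "petown": petown.astype(float),
        "antevd": antevd.astype(float), "vdi": vdi.astype(float),
    })


def outcome_linear_predictor(cohort: pd.DataFrame, coefs) -> np.ndarray:
    """Linear predictor of the outcome model at each record.

    Coefficient order: intercept, vdi, cauc, petown, [nsib=1], [nsib=2],
    antevd, hxfamall.
    """
    c = np.asarray(coefs, dtype=float)
    n1 = (cohort["nsib"].to_numpy() == 1).astype(float)
    n2 = (cohort["nsib"].to_numpy() == 2).astype(float)
    X = np.column_stack([
        np.ones(len(cohort)),
        cohort["vdi"].to_numpy(dtype=float),
        cohort["cauc"].to_numpy(dtype=float),
        cohort["petown"].to_numpy(dtype=float),
        n1, n2,
        cohort["antevd"].to_numpy(dtype=float),
        cohort["hxfamall"].to_numpy(dtype=float),
    ])
    return X @ c


class GenerationError(RuntimeError):
    """Raised when a log-link outcome model implies probabilities >= 1."""


def generate_outcome(cohort: pd.DataFrame, spec: OutcomeSpec,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Add a Bernoulli outcome to a complete cohort.

    Under the RR estimand the event probability is exp(linear predictor)
    (log link); any record with probability >= 1 aborts generation with a
    diagnostic naming the offending covariate pattern.  Under the OR
    estimand the logit link applies.
    """
    for col in ("vdi", "petown", "antevd"):
        if cohort[col].isna().any():
            raise ValueError("outcome generation requires a complete cohort")
    if spec.estimand == "RR":
        lp = outcome_linear_predictor(cohort, spec.theta)
        if np.any(lp >= 0):
            i = int(np.argmax(lp))
            bad = cohort.iloc[i][["vdi", "cauc", "petown", "nsib", "antevd", "hxfamall"]]
            raise GenerationError(
                "log-link outcome probability >= 1 for covariate pattern "
                f"{bad.to_dict()} (linear predictor {lp[i]:.3f})"
            )
        p = np.exp(lp)
    else:
        p = expit(outcome_linear_predictor(cohort, spec.beta))
    out = cohort.copy()
    out["foodallergy"] = (rng.random(len(cohort)) < p).astype(np.int64)
    return out


def generate_cohort(params: DGPParams, spec: OutcomeSpec, n: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Convenience wrapper: covariates then outcome, one call."""
    return generate_outcome(generate_covariates(params, n, rng), spec, rng)


# --------------------------------------------------------------------------
# Serialization: flat key -> numeric value, YAML text
# --------------------------------------------------------------------------

def _to_flat(obj) -> dict:
    flat: dict[str, float | str] = {"_class": type(obj).__name__}
    for f in fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, (tuple, list)):
            for i, x in enumerate(v):
                flat[f"{f.name}{i}"] = float(x)
        elif isinstance(v, str):
            flat[f.name] = v
        else:
            flat[f.name] = float(v)
    return flat


def _from_flat(flat: dict, cls):
    kwargs = {}
    for f in fields(cls):
        if f.name in flat:
            v = flat[f.name]
            kwargs[f.name] = v if isinstance(v, str) else float(v)
        else:
            seq = []
            while f"{f.name}{len(seq)}" in flat:
                seq.append(float(flat[f"{f.name}{len(seq)}"]))
            if not seq:
                raise ConfigurationError(f"missing key {f.name!r} in parameter file")
            kwargs[f.name] = tuple(seq)
    return cls(**kwargs)


def save_params(path, *objs) -> None:
    """Write one or more parameter objects to a plain-text YAML registry."""
    payload = [_to_flat(o) for o in objs]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_params(path) -> list:
    """Round-trip counterpart of :func:`save_params`."""
    from . import missingness  # local import to avoid a cycle

    registry = {"DGPParams": DGPParams, "OutcomeSpec": OutcomeSpec,
                "MissingnessParams": missingness.MissingnessParams}
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    out = []
    for flat in payload:
        cls = registry[flat.pop("_class")]
        out.append(_from_flat(flat, cls))
    return out


def cohort_to_csv(cohort: pd.DataFrame, path) -> None:
    """Export a cohort as CSV, missing values as empty fields."""
    cohort.to_csv(path, index=False, na_rep="")
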