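"""Case-cohort subsampling and inverse-probability (Borgan) weights.

A subcohort is drawn from the full cohort by independent Bernoulli sampling
with probability pi per record.  The analysed sample comprises all cases
plus the subcohort; the exposure is missing by design for everyone else.
Stratified-sampling weights follow Borgan: w = 1 for cases and n0/m0 for
non-case subcohort members, where n0 counts non-cases in the full cohort
and m0 non-cases in the subcohort, so the weights always sum exactly to the
full-cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CaseCohortSample", "select_subcohort", "compute_weights",
           "DegenerateSampleError", "SUBCOHORT_PROBS"]

#: default subcohort selection probabilities explored by the study
SUBCOHORT_PROBS = (0.20, 0.30, 0.40)


class DegenerateSampleError(RuntimeError):
    """Raised when the subcohort contains no non-cases (weights undefined)."""


@dataclass
class CaseCohortSample:
    """The analysed subset: all cases plus the subcohort, with IPW weights.

    ``records`` carries per-record ``in_subcohort`` and ``weight`` columns;
    ``n_full`` is the full-cohort size, ``n0``/``m0`` the non-case counts in
    the full cohort / subcohort.
    """

    records: pd.DataFrame
    pi: float
    n_full: int
    n0: int
    m0: int

    @property
    def weights(self) -> np.ndarray:
        return self.records["weight"].to_numpy(dtype=float)


def select_subcohort(cohort: pd.DataFrame, pi: float,
                     rng: np.random.Generator) -> CaseCohortSample:
    """Draw the subcohort and assemble the analysed case-cohort sample.

    Each record enters the subcohort independently with probability pi.
    The exposure is set missing for non-case records outside the subcohort
    (missing by design); those records are excluded from the analysed
    sample.  Weights are attached via :func:`compute_weights`.
    """
    if not 0.0 < pi <= 1.0:
        raise ValueError(f"pi must be in (0, 1], got {pi}")
    if "foodallergy" not in cohort.columns:
        raise ValueError("cohort must have a generated outcome")
    n = len(cohort)
    in_sub = rng.random(n) < pi
    is_case = cohort["foodallergy"].to_numpy() == 1
    n0 = int((~is_case).sum())
    m0 = int((in_sub & ~is_case).sum())

    frame = cohort.copy()
    frame["in_subcohort"] = in_sub
    # exposure missing by design outside the analysed sample
    frame.loc[~is_case & ~in_sub, "vdi"] = np.nan

    analysed = frame.loc[is_case | in_sub].copy()
    sample = CaseCohortSample(records=analysed, pi=pi, n_full=n, n0=n0, m0=m0)
    return compute_weights(sample)


def compute_weights(sample: CaseCohortSample) -> CaseCohortSample:
    """Attach Borgan weights: 1 for cases, n0/m0 for non-case subcohort members.

    Idempotent; cases sampled into the subcohort keep weight 1 (their
    selection probability is 1 by design).
    """
    if sample.m0 == 0:
        raise DegenerateSampleError(
            "no non-cases in the subcohort; weights n0/m0 undefined")
    is_case = sample.records["foodallergy"].to_numpy() == 1
    w = np.where(is_case, 1.0, sample.n0 / sample.m0)
    sample.records["weight"] = w
    return sample
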