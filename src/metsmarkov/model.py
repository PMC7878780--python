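"""Generator matrices and transition probabilities of the six-state model.

``build_generator`` evaluates the 6x6 intensity matrix Q(age, sex) under the
proportional-hazards parameterisation; ``transition_probability`` computes
P(t) = expm(Q t) with scipy's scaling-and-squaring matrix exponential. These
are the reference implementations; the fitting code uses an algebraically
equivalent fast path on the 3x3 living-metabolic block (see likelihood.py),
and the two are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .exceptions import ParameterError
from .params import IntensityParameters
from .states import N_STATES, TRANSITIONS, sex_to_male, transition_index

__all__ = [
    "build_generator",
    "metabolic_generator",
    "transition_probability",
    "intensity_for",
]

_ROWS = np.array([r - 1 for r, _ in TRANSITIONS])
_COLS = np.array([s - 1 for _, s in TRANSITIONS])

# Transitions whose source is a living metabolic state (rows of the 3x3 block).
_MET_MASK = _ROWS <= 2


def build_generator(params: IntensityParameters, age: float, sex) -> np.ndarray:
    """6x6 generator Q at the given covariates (per-year intensities).

    Off-diagonal entries are zero outside the allowed topology; each row sums
    to zero; the two death states are absorbing (zero rows).
    """
    rates = params.rates_at(age, sex_to_male(sex))
    Q = np.zeros((N_STATES, N_STATES))
    Q[_ROWS, _COLS] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def metabolic_generator(params: IntensityParameters, age: float, male: int) -> np.ndarray:
    """3x3 sub-generator on the living metabolic states {FMD, MMD, MetS}.

    Diagonal entries include the exits to CVD and other-cause death, so
    expm(A t) equals the corresponding block of expm(Q t): no path leaves the
    metabolic track and returns.
    """
    rates = params.rates_at(age, male)
    A = np.zeros((3, 3))
    for j, (r, s) in enumerate(TRANSITIONS):
        if r <= 3:
            A[r - 1, r - 1] -= rates[j]
            if s <= 3:
                A[r - 1, s - 1] += rates[j]
    return A


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition-probability matrix P(t) = expm(Q t).

    Entries are clipped into [0, 1] only within a 1e-8 numerical tolerance;
    anything worse raises, it is never silently repaired.
    """
    if t < 0:
        raise ParameterError(f"elapsed time must be non-negative, got {t}")
    Q = np.asarray(Q, dtype=float)
    P = expm(Q * float(t))
    if P.min() < -1e-8 or P.max() > 1 + 1e-8:
        raise ParameterError(
            f"matrix exponential left [0,1] beyond tolerance (min {P.min():g}, max {P.max():g})"
        )
    rowsum = P.sum(axis=1)
    if np.max(np.abs(rowsum - 1.0)) > 1e-8:
        raise ParameterError("transition-probability rows do not sum to 1 within tolerance")
    return np.clip(P, 0.0, 1.0)


def intensity_for(params: IntensityParameters, transition, age: float, sex) -> float:
    """Scalar intensity lambda_rs(age, sex), per year.

    Raises :class:`TopologyError` for a forbidden transition.
    """
    transition_index(transition)  # topology check with a clear error
    return params.intensity(transition, age, sex)
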