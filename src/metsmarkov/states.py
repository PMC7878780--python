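"""State space and transition topology of the six-state progression model.

The model tracks an adult screening participant through three metabolic
states defined by the refined MetS-related classification (RMRC) --
free of metabolic disorder (FMD, no positive criterion), mild metabolic
disorder (MMD, 1-2 criteria) and metabolic syndrome (MetS, >=3 criteria) --
and three prognostic states: incident cardiovascular disease (CVD),
death from CVD, and death from other causes (OCD).

Allowed instantaneous transitions (11 in total):

    FMD <-> MMD -> MetS          (entry into MetS only through MMD;
                                  no regression out of MetS)
    FMD/MMD/MetS -> CVD          (severity-specific CVD incidence)
    CVD -> CVD death             (case fatality)
    FMD/MMD/MetS/CVD -> OCD      (competing other-cause mortality)

CVD death and OCD are absorbing.
"""

from __future__ import annotations

import enum

from .exceptions import TopologyError


class StateCode(enum.IntEnum):
    """The six states, coded 1-6 as used in panel data files."""

    FMD = 1
    MMD = 2
    METS = 3
    CVD = 4
    CVD_DEATH = 5
    OCD = 6


class ObsKind(str, enum.Enum):
    """How an observation was made.

    ``panel``: RMRC state seen at a screening visit (interval-censored);
    ``exact_event``: registry-dated CVD onset or death;
    ``censor``: known alive and event-free at this time.
    """

    PANEL = "panel"
    EXACT = "exact_event"
    CENSOR = "censor"


#: Ordered allowed transitions; this ordering defines the parameter layout.
TRANSITIONS: tuple[tuple[int, int], ...] = (
    (1, 2),  # FMD -> MMD
    (2, 1),  # MMD -> FMD
    (2, 3),  # MMD -> MetS
    (1, 4),  # FMD -> CVD
    (2, 4),  # MMD -> CVD
    (3, 4),  # MetS -> CVD
    (4, 5),  # CVD -> CVD death
    (1, 6),  # FMD -> OCD
    (2, 6),  # MMD -> OCD
    (3, 6),  # MetS -> OCD
    (4, 6),  # CVD -> OCD
)

ALLOWED: frozenset[tuple[int, int]] = frozenset(TRANSITIONS)

#: Short names for the 11 transitions (used in parameter files and reports).
TRANSITION_NAMES: tuple[str, ...] = (
    "fmd_mmd",
    "mmd_fmd",
    "mmd_mets",
    "fmd_cvd",
    "mmd_cvd",
    "mets_cvd",
    "cvd_cvd_death",
    "fmd_ocd",
    "mmd_ocd",
    "mets_ocd",
    "cvd_ocd",
)

#: Covariate groups: each of the seven specific transitions carries its own
#: (age, sex) rate-ratio pair; the four OCD transitions share one pooled pair.
GROUP_NAMES: tuple[str, ...] = (
    "fmd_mmd",
    "mmd_fmd",
    "mmd_mets",
    "fmd_cvd",
    "mmd_cvd",
    "mets_cvd",
    "cvd_death",
    "ocd",
)

#: Covariate group index of each transition (parallel to TRANSITIONS).
TRANS_GROUP: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 7, 7, 7)

N_STATES = 6
N_TRANSITIONS = len(TRANSITIONS)
N_GROUPS = len(GROUP_NAMES)

LIVING_STATES = (1, 2, 3, 4)
METABOLIC_STATES = (1, 2, 3)
ABSORBING_STATES = (5, 6)

_TRANSITION_INDEX = {t: i for i, t in enumerate(TRANSITIONS)}
_NAME_INDEX = {n: i for i, n in enumerate(TRANSITION_NAMES)}


def transition_index(transition: tuple[int, int] | str) -> int:
    """Position of a transition in the canonical ordering.

    Accepts either an ``(r, s)`` state pair or a short name like ``"mmd_mets"``.
    Raises :class:`TopologyError` for forbidden transitions.
    """
    if isinstance(transition, str):
        try:
            return _NAME_INDEX[transition]
        except KeyError:
            raise TopologyError(f"unknown transition name {transition!r}") from None
    pair = (int(transition[0]), int(transition[1]))
    try:
        return _TRANSITION_INDEX[pair]
    except KeyError:
        raise TopologyError(
            f"transition {pair[0]}->{pair[1]} is not allowed by the six-state topology"
        ) from None


def sex_to_male(sex) -> int:
    """Normalise a sex value ('male'/'female', 'M'/'F', 0/1) to a 0/1 male flag."""
    if isinstance(sex, str):
        s = sex.strip().lower()
        if s in ("male", "m", "man", "men"):
            return 1
        if s in ("female", "f", "woman", "women"):
            return 0
        raise ValueError(f"unrecognised sex value {sex!r}")
    v = int(sex)
    if v not in (0, 1):
        raise ValueError(f"unrecognised sex value {sex!r}")
    return v
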