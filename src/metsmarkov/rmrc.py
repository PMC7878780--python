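"""Refined MetS-related classification (RMRC) from raw biomarkers.

The harmonised joint-scientific-statement criteria, with waist cutoffs for
Asian populations:

    central obesity        waist >= 80 cm (women) / >= 90 cm (men)
    hypertriglyceridemia   triglycerides >= 150 mg/dL
    low HDL cholesterol    HDL < 50 mg/dL (women) / < 40 mg/dL (men)
    elevated blood pressure  SBP >= 130 or DBP >= 85 mmHg
    hyperglycemia          fasting glucose >= 100 mg/dL

Subjects under treatment for hypertension, diabetes or hyperlipidemia count as
positive for the elevated-blood-pressure, hyperglycemia and
hypertriglyceridemia criteria respectively, regardless of the measured value.

Classification: 0 positive criteria -> FMD, 1-2 -> MMD, >= MET_S_MIN_CRITERIA
(3) -> MetS. Thresholds are applied exactly as written: values at a ">="
cutoff are positive, values at a "<" cutoff's boundary are negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .exceptions import DataError, MissingBiomarkerError
from .states import StateCode, sex_to_male

#: Number of positive criteria at or above which a subject is MetS.
MET_S_MIN_CRITERIA = 3

CRITERIA = ("central_obesity", "hypertriglyceridemia", "low_hdl", "high_bp", "hyperglycemia")

WAIST_CUTOFF = {"female": 80.0, "male": 90.0}
TG_CUTOFF = 150.0
HDL_CUTOFF = {"female": 50.0, "male": 40.0}
SBP_CUTOFF = 130.0
DBP_CUTOFF = 85.0
GLUCOSE_CUTOFF = 100.0


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class ScreenRecord:
    """One subject's biomarkers and treatment history at a screening visit."""

    subject_id: object
    sex: str
    age: float
    waist: float | None = None
    triglycerides: float | None = None
    hdl: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    fasting_glucose: float | None = None
    on_hypertension_treatment: bool = False
    on_diabetes_treatment: bool = False
    on_hyperlipidemia_treatment: bool = False
    screen_time: float = 0.0

    def __post_init__(self):
        if not (20.0 <= self.age <= 100.0):
            raise DataError(f"age {self.age} outside [20, 100] (subject {self.subject_id})")
        if self.screen_time < 0:
            raise DataError(f"screen_time must be >= 0 (subject {self.subject_id})")
        for name in ("waist", "triglycerides", "hdl", "sbp", "dbp", "fasting_glucose"):
            v = getattr(self, name)
            if not _missing(v) and v <= 0:
                raise DataError(f"{name}={v} must be strictly positive (subject {self.subject_id})")


@dataclass(frozen=True)
class CriteriaVector:
    """Flags for the five criteria plus their count."""

    central_obesity: bool
    hypertriglyceridemia: bool
    low_hdl: bool
    high_bp: bool
    hyperglycemia: bool

    @property
    def n_positive(self) -> int:
        return sum(
            (self.central_obesity, self.hypertriglyceridemia, self.low_hdl,
             self.high_bp, self.hyperglycemia)
        )

    @property
    def flags(self) -> tuple[bool, ...]:
        return (self.central_obesity, self.hypertriglyceridemia, self.low_hdl,
                self.high_bp, self.hyperglycemia)


def evaluate_criteria(
    record: ScreenRecord,
    *,
    permissive: bool = False,
    treatment_sets_low_hdl: bool = False,
) -> CriteriaVector:
    """Evaluate the five criteria for one screen.

    A missing biomarker raises :class:`MissingBiomarkerError` naming the
    criterion, unless a treatment flag covers it or ``permissive`` is set
    (in which case the unobserved criterion counts as negative; the caller is
    expected to flag such records). ``treatment_sets_low_hdl`` additionally
    maps hyperlipidemia treatment onto the low-HDL criterion.
    """
    sex = "male" if sex_to_male(record.sex) else "female"

    def need(value, criterion):
        if _missing(value):
            if permissive:
                return None
            raise MissingBiomarkerError(criterion, record.subject_id)
        return value

    # Central obesity: no treatment override exists.
    waist = need(record.waist, "central_obesity")
    obesity = waist is not None and waist >= WAIST_CUTOFF[sex]

    if record.on_hyperlipidemia_treatment:
        tg_flag = True
    else:
        tg = need(record.triglycerides, "hypertriglyceridemia")
        tg_flag = tg is not None and tg >= TG_CUTOFF

    if record.on_hyperlipidemia_treatment and treatment_sets_low_hdl:
        hdl_flag = True
    else:
        hdl = need(record.hdl, "low_hdl")
        hdl_flag = hdl is not None and hdl < HDL_CUTOFF[sex]

    if record.on_hypertension_treatment:
        bp_flag = True
    else:
        sbp = need(record.sbp, "high_bp")
        dbp = need(record.dbp, "high_bp")
        bp_flag = (sbp is not None and sbp >= SBP_CUTOFF) or (
            dbp is not None and dbp >= DBP_CUTOFF
        )

    if record.on_diabetes_treatment:
        glu_flag = True
    else:
        glu = need(record.fasting_glucose, "hyperglycemia")
        glu_flag = glu is not None and glu >= GLUCOSE_CUTOFF

    return CriteriaVector(obesity, tg_flag, hdl_flag, bp_flag, glu_flag)


def classify_rmrc(criteria: CriteriaVector, mets_min_criteria: int = MET_S_MIN_CRITERIA) -> StateCode:
    """Map a criteria vector to FMD / MMD / MetS."""
    n = criteria.n_positive
    if n == 0:
        return StateCode.FMD
    if n < mets_min_criteria:
        return StateCode.MMD
    return StateCode.METS


def classify_record(record: ScreenRecord, **kwargs) -> StateCode:
    """Convenience: evaluate criteria and classify in one call."""
    return classify_rmrc(evaluate_criteria(record, **kwargs))


# ---------------------------------------------------------------------------
# Tabular interface
# ---------------------------------------------------------------------------

#: Expected column names of a screens table; remap with ``column_map``.
SCREEN_COLUMNS = (
    "subject_id", "sex", "age", "waist", "triglycerides", "hdl", "sbp", "dbp",
    "fasting_glucose", "on_hypertension_treatment", "on_diabetes_treatment",
    "on_hyperlipidemia_treatment", "screen_time",
)


def classify_screens(
    df: pd.DataFrame,
    column_map: dict[str, str] | None = None,
    permissive: bool = False,
    treatment_sets_low_hdl: bool = False,
) -> pd.DataFrame:
    """Classify every row of a screens table.

    Returns a copy of the table with the five criterion flags, ``n_positive``,
    ``rmrc_state`` (1/2/3) appended, plus ``incomplete`` when ``permissive``.
    ``column_map`` maps the schema names above to the table's actual columns.
    """
    colmap = {c: c for c in SCREEN_COLUMNS}
    if column_map:
        colmap.update(column_map)
    missing_required = [c for c in ("subject_id", "sex", "age") if colmap[c] not in df.columns]
    if missing_required:
        raise DataError(f"screens table lacks required columns: {missing_required}")

    out = df.copy()
    results = {c: [] for c in CRITERIA}
    n_pos, state, incomplete = [], [], []
    for i, row in df.iterrows():
        def get(name, default=None):
            col = colmap[name]
            if col not in df.columns:
                return default
            v = row[col]
            return default if pd.isna(v) else v

        rec = ScreenRecord(
            subject_id=get("subject_id"),
            sex=str(get("sex")),
            age=float(get("age")),
            waist=get("waist"),
            triglycerides=get("triglycerides"),
            hdl=get("hdl"),
            sbp=get("sbp"),
            dbp=get("dbp"),
            fasting_glucose=get("fasting_glucose"),
            on_hypertension_treatment=bool(get("on_hypertension_treatment", False)),
            on_diabetes_treatment=bool(get("on_diabetes_treatment", False)),
            on_hyperlipidemia_treatment=bool(get("on_hyperlipidemia_treatment", False)),
            screen_time=float(get("screen_time", 0.0)),
        )
        try:
            crit = evaluate_criteria(
                rec, permissive=permissive, treatment_sets_low_hdl=treatment_sets_low_hdl
            )
            was_incomplete = False
        except MissingBiomarkerError as err:
            raise MissingBiomarkerError(err.criterion, f"{rec.subject_id} (row {i})") from None
        if permissive:
            # mark rows where any biomarker relevant to an uncovered criterion is absent
            was_incomplete = any(
                _missing(getattr(rec, b))
                for b, covered in (
                    ("waist", False),
                    ("triglycerides", rec.on_hyperlipidemia_treatment),
                    ("hdl", rec.on_hyperlipidemia_treatment and treatment_sets_low_hdl),
                    ("sbp", rec.on_hypertension_treatment),
                    ("dbp", rec.on_hypertension_treatment),
                    ("fasting_glucose", rec.on_diabetes_treatment),
                )
                if not covered
            )
        for c, v in zip(CRITERIA, crit.flags):
            results[c].append(bool(v))
        n_pos.append(crit.n_positive)
        state.append(int(classify_rmrc(crit)))
        incomplete.append(was_incomplete)

    for c in CRITERIA:
        out[c] = results[c]
    out["n_positive"] = n_pos
    out["rmrc_state"] = state
    if permissive:
        out["incomplete"] = incomplete
    return out


def classify_csv(path_in, path_out, **kwargs) -> pd.DataFrame:
    """Read a screens CSV, classify, write the augmented table; returns it."""
    df = pd.read_csv(path_in)
    out = classify_screens(df, **kwargs)
    out.to_csv(path_out, index=False)
    return out
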