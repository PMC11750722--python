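"""Scoring and validation of the fixed patient-reported instrument battery.

Instruments covered: Chalder fatigue scale (11 items), MRC dyspnea grade,
P4 pain rating scale (4 items), HADS (7 anxiety + 7 depression items),
EQ-5D (VAS + utility) and free-text symptom VAS ratings.  All instruments
are oriented so that higher = worse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

CORE_SYMPTOMS = ("fatigue", "breathlessness", "pain", "anxiety_depression")
SYMPTOM_LEVELS = CORE_SYMPTOMS + ("other",)

VISIT_MONTHS = (0, 3, 6, 12)


class ValidationError(ValueError):
    """Raised when a response violates an instrument's invariants."""


def _check_items(items: Sequence[int], n: int, lo: int, hi: int, name: str) -> tuple:
    items = tuple(items)
    if len(items) != n:
        raise ValidationError(f"{name}: expected {n} items, got {len(items)}")
    for i, v in enumerate(items):
        if v is None or not float(v) == int(v) or not lo <= int(v) <= hi:
            raise ValidationError(
                f"{name}: item {i + 1} value {v!r} outside {lo}..{hi}"
            )
    return tuple(int(v) for v in items)


@dataclass(frozen=True)
class ChalderResponse:
    """Eleven Likert-scored items, each 0..3. Items 1-7 physical, 8-11 mental."""

    items: Sequence[int]

    def __post_init__(self):
        object.__setattr__(self, "items", _check_items(self.items, 11, 0, 3, "chalder"))


@dataclass(frozen=True)
class ChalderScore:
    total: int
    physical: int
    mental: int

    def __post_init__(self):
        if self.total != self.physical + self.mental:
            raise ValidationError("chalder: total != physical + mental")


@dataclass(frozen=True)
class MRCDyspneaGrade:
    grade: int

    def __post_init__(self):
        if self.grade not in (1, 2, 3, 4, 5):
            raise ValidationError(f"mrc_dyspnea: grade {self.grade!r} outside 1..5")


@dataclass(frozen=True)
class P4PainResponse:
    """Four pain ratings, each 0..10; total is their sum (0..40)."""

    items: Sequence[int]

    def __post_init__(self):
        object.__setattr__(self, "items", _check_items(self.items, 4, 0, 10, "p4"))

    @property
    def total(self) -> int:
        return sum(self.items)


@dataclass(frozen=True)
class HADSResponse:
    """Seven anxiety and seven depression items, each 0..3.

    Anxiety and depression items are stored separately (the questionnaire
    interleaves them; the data schema keeps named columns to avoid layout
    ambiguity).
    """

    anxiety_items: Sequence[int]
    depression_items: Sequence[int]

    def __post_init__(self):
        object.__setattr__(
            self, "anxiety_items", _check_items(self.anxiety_items, 7, 0, 3, "hads_a")
        )
        object.__setattr__(
            self,
            "depression_items",
            _check_items(self.depression_items, 7, 0, 3, "hads_d"),
        )


@dataclass(frozen=True)
class HADSScore:
    anxiety: int
    depression: int
    total: int

    def __post_init__(self):
        if self.total != self.anxiety + self.depression:
            raise ValidationError("hads: total != anxiety + depression")


@dataclass(frozen=True)
class EQ5DRecord:
    vas: float
    utility: float

    def __post_init__(self):
        if not 0 <= self.vas <= 100:
            raise ValidationError(f"eq5d_vas: {self.vas!r} outside [0, 100]")
        if self.utility > 1:
            raise ValidationError(f"eq5d_utility: {self.utility!r} above 1")


def normalize_label(label: str) -> str:
    """Case/whitespace-normalize a free-text symptom label to a stable key."""
    key = " ".join(str(label).split()).lower()
    if not key:
        raise ValidationError("symptom label is empty")
    return key


@dataclass(frozen=True)
class SymptomVAS:
    """A named 'other' symptom rated on a 10-point visual analog scale."""

    label: str
    rating: float

    def __post_init__(self):
        object.__setattr__(self, "label", normalize_label(self.label))
        if not 0 <= self.rating <= 10:
            raise ValidationError(
                f"vas({self.label}): rating {self.rating!r} outside [0, 10]"
            )


def score_chalder(resp: ChalderResponse, method: str = "likert") -> ChalderScore:
    """Score the Chalder fatigue scale.

    ``likert`` sums raw 0-3 responses (total 0-33, physical 0-21, mental
    0-12); this is the scoring used throughout the pipeline. ``bimodal``
    (0/0/1/1 recoding, total 0-11) is exposed but unused downstream.
    """
    if method == "likert":
        vals = resp.items
    elif method == "bimodal":
        vals = tuple(1 if v >= 2 else 0 for v in resp.items)
    else:
        raise ValueError(f"unknown Chalder scoring method {method!r}")
    physical = sum(vals[:7])
    mental = sum(vals[7:])
    return ChalderScore(total=physical + mental, physical=physical, mental=mental)


def score_hads(resp: HADSResponse) -> HADSScore:
    """Sum the two HADS subscales; total = anxiety + depression."""
    anxiety = sum(resp.anxiety_items)
    depression = sum(resp.depression_items)
    return HADSScore(anxiety=anxiety, depression=depression, total=anxiety + depression)


def score_p4(resp: P4PainResponse) -> int:
    """Total P4 pain score: sum of the four 0-10 ratings (0..40)."""
    return resp.total


@dataclass
class VisitRecord:
    """One participant at one scheduled visit.

    Instruments not administered (or with any missing item: no proration)
    are ``None``, never zero. ``other_vas`` maps normalized symptom labels
    to VAS ratings.
    """

    participant_id: str
    visit_month: int
    chalder: Optional[ChalderResponse] = None
    hads: Optional[HADSResponse] = None
    p4: Optional[P4PainResponse] = None
    mrc_dyspnea: Optional[MRCDyspneaGrade] = None
    eq5d: Optional[EQ5DRecord] = None
    other_vas: dict = field(default_factory=dict)
    weight_kg: Optional[float] = None
    sbp_mmhg: Optional[float] = None
    dbp_mmhg: Optional[float] = None
    work_hours_missed: Optional[float] = None

    @property
    def chalder_total(self) -> Optional[int]:
        return score_chalder(self.chalder).total if self.chalder else None

    @property
    def hads_total(self) -> Optional[int]:
        return score_hads(self.hads).total if self.hads else None

    @property
    def p4_total(self) -> Optional[int]:
        return score_p4(self.p4) if self.p4 else None

    @property
    def mrc_grade(self) -> Optional[int]:
        return self.mrc_dyspnea.grade if self.mrc_dyspnea else None


_CHALDER_COLS = [f"chalder_{i:02d}" for i in range(1, 12)]
_HADS_A_COLS = [f"hads_a{i}" for i in range(1, 8)]
_HADS_D_COLS = [f"hads_d{i}" for i in range(1, 8)]
_P4_COLS = [f"p4_{i}" for i in range(1, 5)]

KNOWN_COLUMNS = frozenset(
    ["participant_id", "visit_month", "arm", "chosen_symptom", "mrc_dyspnea",
     "eq5d_vas", "eq5d_utility", "weight_kg", "sbp_mmhg", "dbp_mmhg",
     "work_hours_missed"]
    + _CHALDER_COLS + _HADS_A_COLS + _HADS_D_COLS + _P4_COLS
)


def _is_missing(v) -> bool:
    if v is None:
        return True
    try:
        return v != v  # NaN
    except TypeError:
        return False


def _gather(raw: Mapping, cols: Sequence[str]):
    """Return int items if every column is present, None if all are missing.

    A partially answered instrument counts as missing (no proration), but a
    warning is logged because data were discarded.
    """
    vals = [raw.get(c) for c in cols]
    missing = [_is_missing(v) for v in vals]
    if all(missing):
        return None
    if any(missing):
        logger.warning(
            "instrument %s partially missing for %s; treated as missing",
            cols[0].rsplit("_", 1)[0], raw.get("participant_id"),
        )
        return None
    return [int(v) for v in vals]


def score_table(df):
    """Vectorized scoring of a long-format participant-visit table.

    Input columns follow the shipped dictionary (``chalder_01..11``,
    ``hads_a1..7``/``hads_d1..7``, ``p4_1..4``, ``mrc_dyspnea``, ...).
    An instrument with any missing item is scored as missing. Returns a
    scored table with one row per input row and total/subscale columns.
    """
    import pandas as pd

    def _sum_if_complete(cols):
        block = df.reindex(columns=cols)
        s = block.sum(axis=1)
        s[block.isna().any(axis=1)] = float("nan")
        return s

    out = pd.DataFrame(index=df.index)
    for col in ("participant_id", "visit_month", "arm", "chosen_symptom"):
        if col in df.columns:
            out[col] = df[col]
    out["chalder_physical"] = _sum_if_complete(_CHALDER_COLS[:7])
    out["chalder_mental"] = _sum_if_complete(_CHALDER_COLS[7:])
    out["chalder_total"] = out["chalder_physical"] + out["chalder_mental"]
    out["hads_anxiety"] = _sum_if_complete(_HADS_A_COLS)
    out["hads_depression"] = _sum_if_complete(_HADS_D_COLS)
    out["hads_total"] = out["hads_anxiety"] + out["hads_depression"]
    out["p4_total"] = _sum_if_complete(_P4_COLS)
    for col in ("mrc_dyspnea", "eq5d_vas", "eq5d_utility", "weight_kg",
                "sbp_mmhg", "dbp_mmhg", "work_hours_missed"):
        if col in df.columns:
            out[col.replace("mrc_dyspnea", "mrc_grade")] = df[col]
    return out


def validate_visit(raw: Mapping, other_vas: Optional[Mapping[str, float]] = None) -> VisitRecord:
    """Build a validated :class:`VisitRecord` from one long-format CSV row.

    Unknown columns are ignored with a warning; bound violations raise
    :class:`ValidationError` naming the offending field. Missing instruments
    are recorded as absent. Re-validation is idempotent.
    """
    unknown = set(raw) - KNOWN_COLUMNS
    for col in sorted(unknown):
        logger.warning("unknown column %r ignored", col)

    visit_month = int(raw["visit_month"])
    if visit_month not in VISIT_MONTHS:
        raise ValidationError(f"visit_month {visit_month} not one of {VISIT_MONTHS}")

    chalder_items = _gather(raw, _CHALDER_COLS)
    hads_a = _gather(raw, _HADS_A_COLS)
    hads_d = _gather(raw, _HADS_D_COLS)
    p4_items = _gather(raw, _P4_COLS)
    mrc = raw.get("mrc_dyspnea")
    eq_vas, eq_util = raw.get("eq5d_vas"), raw.get("eq5d_utility")

    hads = None
    if hads_a is not None and hads_d is not None:
        hads = HADSResponse(anxiety_items=hads_a, depression_items=hads_d)
    elif (hads_a is None) != (hads_d is None):
        logger.warning("one HADS subscale missing for %s; HADS treated as missing",
                       raw.get("participant_id"))

    eq5d = None
    if not _is_missing(eq_vas) and not _is_missing(eq_util):
        eq5d = EQ5DRecord(vas=float(eq_vas), utility=float(eq_util))

    vas_map = {}
    if other_vas:
        for label, rating in other_vas.items():
            sv = SymptomVAS(label=label, rating=float(rating))
            vas_map[sv.label] = sv.rating

    def _opt_float(key):
        v = raw.get(key)
        return None if _is_missing(v) else float(v)

    return VisitRecord(
        participant_id=str(raw["participant_id"]),
        visit_month=visit_month,
        chalder=ChalderResponse(chalder_items) if chalder_items is not None else None,
        hads=hads,
        p4=P4PainResponse(p4_items) if p4_items is not None else None,
        mrc_dyspnea=MRCDyspneaGrade(int(mrc)) if not _is_missing(mrc) else None,
        eq5d=eq5d,
        other_vas=vas_map,
        weight_kg=_opt_float("weight_kg"),
        sbp_mmhg=_opt_float("sbp_mmhg"),
        dbp_mmhg=_opt_float("dbp_mmhg"),
        work_hours_missed=_opt_float("work_hours_missed"),
    )
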