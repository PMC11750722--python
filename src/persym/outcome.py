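"""Construction of the participant-respective primary outcome.

Each participant nominates at baseline the symptom they most want improved.
That symptom's instrument score is standardized — at every visit — using the
baseline mean and sample s.d. of the subgroup of participants who nominated
the same symptom, yielding a common dimensionless scale with mean 0 at
baseline and per-subgroup baseline s.d. exactly 1 (n-1 convention). Lower is
better for every instrument, so negative change over time means improvement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from persym.instruments import CORE_SYMPTOMS, VisitRecord, normalize_label

logger = logging.getLogger(__name__)

# scored-table column feeding the primary outcome, per chosen symptom
SCORE_COLUMN = {
    "fatigue": "chalder_total",
    "breathlessness": "mrc_grade",
    "pain": "p4_total",
    "anxiety_depression": "hads_total",
}

# instrument (lo, hi) ranges, used only by the non-paper degenerate fallback
INSTRUMENT_RANGE = {
    "fatigue": (0.0, 33.0),
    "breathlessness": (1.0, 5.0),
    "pain": (0.0, 40.0),
    "anxiety_depression": (0.0, 42.0),
    "other": (0.0, 10.0),
}


class DegenerateReferenceError(ValueError):
    """A standardization subgroup has n < 2 or zero baseline s.d."""


class ConfigurationError(ValueError):
    """Inconsistent outcome configuration (e.g. 'other' chooser without a label)."""


@dataclass(frozen=True)
class SubgroupReference:
    """Baseline mean/s.d. of one standardization stratum."""

    symptom: str
    baseline_mean: float
    baseline_sd: float
    n: int

    def __post_init__(self):
        if self.n < 2 or not (self.baseline_sd > 0) or not math.isfinite(self.baseline_sd):
            raise DegenerateReferenceError(
                f"subgroup {self.symptom!r}: n={self.n}, sd={self.baseline_sd} "
                "cannot support standardization"
            )


@dataclass(frozen=True)
class RecodeMap:
    """Mapping from 'other' symptom labels to one of the four core symptoms."""

    pairs: Mapping[str, str]

    def __post_init__(self):
        clean = {}
        for label, target in self.pairs.items():
            if target not in CORE_SYMPTOMS:
                raise ValueError(
                    f"recode target {target!r} is not a core symptom {CORE_SYMPTOMS}"
                )
            clean[normalize_label(label)] = target
        object.__setattr__(self, "pairs", clean)


def extract_chosen_raw(participant: Mapping, visit: VisitRecord):
    """Raw chosen-symptom score for one participant at one visit.

    Returns the Chalder total (fatigue), MRC grade (breathlessness), P4
    total (pain), HADS total (anxiety/depression), or — for 'other'
    choosers — the VAS rating of the main symptom label identified at
    baseline.  Returns ``None`` when the instrument/label is absent.
    """
    chosen = participant["chosen_symptom"]
    if chosen == "fatigue":
        return visit.chalder_total
    if chosen == "breathlessness":
        return visit.mrc_grade
    if chosen == "pain":
        return visit.p4_total
    if chosen == "anxiety_depression":
        return visit.hads_total
    if chosen == "other":
        label = participant.get("main_symptom_label")
        if label is None or (isinstance(label, float) and math.isnan(label)):
            raise ConfigurationError(
                f"participant {participant.get('participant_id')!r} chose 'other' "
                "but has no baseline main-symptom label"
            )
        return visit.other_vas.get(normalize_label(label))
    raise ValueError(f"unknown chosen symptom {chosen!r}")


def _chosen_raw_frame(cohort: pd.DataFrame, scored: pd.DataFrame,
                      other_long: Optional[pd.DataFrame]) -> pd.DataFrame:
    """One row per participant-visit with the raw chosen-symptom score.

    ``cohort``: participant_id, chosen_symptom, main_symptom_label (for
    'other' choosers). ``scored``: output of ``instruments.score_table``.
    ``other_long``: participant_id, visit_month, symptom_label, vas.
    """
    cols = ["participant_id", "chosen_symptom"]
    if "main_symptom_label" in cohort.columns:
        cols.append("main_symptom_label")
    merged = scored.merge(cohort[cols], on="participant_id", how="inner",
                          suffixes=("", "_cohort"))
    if "chosen_symptom_cohort" in merged.columns:
        merged["chosen_symptom"] = merged.pop("chosen_symptom_cohort")

    raw = pd.Series(np.nan, index=merged.index)
    for symptom, col in SCORE_COLUMN.items():
        mask = merged["chosen_symptom"] == symptom
        if mask.any():
            raw[mask] = pd.to_numeric(merged.loc[mask, col], errors="coerce")

    other_mask = merged["chosen_symptom"] == "other"
    if other_mask.any():
        if "main_symptom_label" not in merged.columns or (
            merged.loc[other_mask, "main_symptom_label"].isna().any()
        ):
            bad = merged.loc[other_mask]
            bad = bad[bad.get("main_symptom_label").isna()] if "main_symptom_label" in bad else bad
            raise ConfigurationError(
                "'other' choosers without a baseline main-symptom label: "
                f"{sorted(bad['participant_id'].unique())}"
            )
        if other_long is None or other_long.empty:
            raise ConfigurationError(
                "'other' choosers present but no other-symptom VAS table supplied"
            )
        ov = other_long.copy()
        ov["symptom_label"] = ov["symptom_label"].map(normalize_label)
        ov = ov.rename(columns={"symptom_label": "main_symptom_label", "vas": "_vas"})
        keys = merged.loc[other_mask, ["participant_id", "visit_month",
                                       "main_symptom_label"]].copy()
        keys["main_symptom_label"] = keys["main_symptom_label"].map(normalize_label)
        looked = keys.merge(
            ov[["participant_id", "visit_month", "main_symptom_label", "_vas"]],
            on=["participant_id", "visit_month", "main_symptom_label"], how="left",
        )
        raw[other_mask] = looked["_vas"].to_numpy()

    out = merged[["participant_id", "visit_month", "chosen_symptom"]].copy()
    if "main_symptom_label" in merged.columns:
        out["main_symptom_label"] = merged["main_symptom_label"]
    out["raw_score"] = raw
    return out


def _reference_key(symptom: str, label, per_label: bool):
    if symptom == "other" and per_label:
        return ("other", normalize_label(label))
    return symptom


def fit_references(
    baseline: pd.DataFrame,
    per_label_other: bool = False,
    on_degenerate: str = "error",
) -> Dict:
    """Fit baseline standardization references, one per chosen-symptom stratum.

    ``baseline`` needs columns ``chosen_symptom`` and ``raw_score`` (plus
    ``main_symptom_label`` when ``per_label_other``). References pool both
    arms. The 'other' stratum is pooled across labels by default (all share
    the 0-10 VAS scale); ``per_label_other=True`` fits one reference per
    label instead.

    ``on_degenerate``: ``"error"`` raises :class:`DegenerateReferenceError`
    for strata with n < 2 or zero s.d.; ``"fallback"`` substitutes the
    pooled min-max-rescaled s.d. of all other strata, mapped back to the
    stratum's instrument range — an explicitly non-paper stabilization.
    """
    if on_degenerate not in ("error", "fallback"):
        raise ValueError("on_degenerate must be 'error' or 'fallback'")
    if baseline["raw_score"].isna().any():
        missing = baseline.loc[baseline["raw_score"].isna(), "participant_id"]
        raise ValueError(
            f"baseline chosen score missing for participants {sorted(missing)}"
        )

    df = baseline.copy()
    df["_key"] = [
        _reference_key(s, df["main_symptom_label"].iloc[i] if "main_symptom_label" in df else None,
                       per_label_other)
        for i, s in enumerate(df["chosen_symptom"])
    ]

    stats = df.groupby("_key")["raw_score"].agg(["mean", "std", "count"])
    refs: Dict = {}
    degenerate = []
    for key, row in stats.iterrows():
        n, mean, sd = int(row["count"]), float(row["mean"]), float(row["std"])
        if n < 2 or not sd > 0:
            degenerate.append((key, n, sd))
        else:
            refs[key] = SubgroupReference(
                symptom=key if isinstance(key, str) else f"other:{key[1]}",
                baseline_mean=mean, baseline_sd=sd, n=n,
            )

    if degenerate:
        if on_degenerate == "error":
            raise DegenerateReferenceError(
                f"degenerate standardization subgroups: {degenerate}"
            )
        fallback_sd = _pooled_rescaled_sd(df, stats, per_label_other)
        for key, n, _sd in degenerate:
            symptom = key if isinstance(key, str) else "other"
            lo, hi = INSTRUMENT_RANGE[symptom]
            sd = fallback_sd * (hi - lo)
            mean = float(df.loc[df["_key"] == key, "raw_score"].mean())
            ref = SubgroupReference.__new__(SubgroupReference)
            object.__setattr__(ref, "symptom", key if isinstance(key, str) else f"other:{key[1]}")
            object.__setattr__(ref, "baseline_mean", mean)
            object.__setattr__(ref, "baseline_sd", sd)
            object.__setattr__(ref, "n", n)
            refs[key] = ref
            logger.warning(
                "subgroup %r degenerate (n=%d); borrowed rescaled pooled s.d. %.4g "
                "(non-paper fallback)", key, n, sd,
            )
    return refs


def _pooled_rescaled_sd(df: pd.DataFrame, stats: pd.DataFrame, per_label: bool) -> float:
    """Pooled s.d. of baseline scores after min-max rescaling to [0, 1]."""
    parts = []
    for key, row in stats.iterrows():
        if int(row["count"]) < 2 or not float(row["std"]) > 0:
            continue
        symptom = key if isinstance(key, str) else "other"
        lo, hi = INSTRUMENT_RANGE[symptom]
        vals = df.loc[df["_key"] == key, "raw_score"].to_numpy(dtype=float)
        parts.append((vals - lo) / (hi - lo))
    if not parts:
        raise DegenerateReferenceError("every standardization subgroup is degenerate")
    num = sum((len(p) - 1) * np.var(p, ddof=1) for p in parts)
    den = sum(len(p) - 1 for p in parts)
    return float(np.sqrt(num / den))


def standardize(raw: float, ref: SubgroupReference) -> float:
    """z = (raw - baseline mean) / baseline s.d. of the participant's stratum."""
    return (raw - ref.baseline_mean) / ref.baseline_sd


def build_primary_outcome(
    cohort: pd.DataFrame,
    scored_visits: pd.DataFrame,
    other_long: Optional[pd.DataFrame] = None,
    refs: Optional[Dict] = None,
    per_label_other: bool = False,
    on_degenerate: str = "error",
):
    """Respective primary-outcome table: one row per participant-visit.

    Returns ``(outcome, refs)`` where ``outcome`` has columns
    participant_id, visit_month, chosen_symptom, raw_score, z (rows with a
    missing chosen raw score are dropped), and ``refs`` are the baseline
    :class:`SubgroupReference` objects used (fitted here when not given).
    """
    raw = _chosen_raw_frame(cohort, scored_visits, other_long)
    if refs is None:
        base = raw[raw["visit_month"] == 0]
        refs = fit_references(base, per_label_other=per_label_other,
                              on_degenerate=on_degenerate)

    out = raw.dropna(subset=["raw_score"]).copy()
    keys = [
        _reference_key(s, out["main_symptom_label"].iloc[i] if "main_symptom_label" in out else None,
                       per_label_other)
        for i, s in enumerate(out["chosen_symptom"])
    ]
    means = np.array([refs[k].baseline_mean for k in keys])
    sds = np.array([refs[k].baseline_sd for k in keys])
    out["z"] = (out["raw_score"].to_numpy(dtype=float) - means) / sds
    cols = ["participant_id", "visit_month", "chosen_symptom", "raw_score", "z"]
    return out[cols].reset_index(drop=True), refs


def apply_recode(cohort: pd.DataFrame, recode: RecodeMap) -> pd.DataFrame:
    """Recode 'other' choosers whose main-symptom label maps to a core symptom.

    Returns a new cohort table; downstream standardization must refit
    references on it (the sensitivity dataset).
    """
    out = cohort.copy()
    if not recode.pairs:
        return out
    if "main_symptom_label" not in out.columns:
        return out
    mask = out["chosen_symptom"] == "other"
    labels = out.loc[mask, "main_symptom_label"].map(
        lambda x: normalize_label(x) if isinstance(x, str) else x
    )
    targets = labels.map(recode.pairs)
    hit = targets.notna()
    idx = targets.index[hit]
    out.loc[idx, "chosen_symptom"] = targets[hit]
    out.loc[idx, "main_symptom_label"] = None
    if len(idx):
        logger.info("recoded %d 'other' choosers onto core symptoms", len(idx))
    return out


def references_frame(refs: Dict) -> pd.DataFrame:
    """Tidy references table: symptom, n, baseline_mean, baseline_sd."""
    rows = [
        {"symptom": r.symptom, "n": r.n, "baseline_mean": r.baseline_mean,
         "baseline_sd": r.baseline_sd}
        for r in refs.values()
    ]
    return pd.DataFrame(rows, columns=["symptom", "n", "baseline_mean", "baseline_sd"])
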