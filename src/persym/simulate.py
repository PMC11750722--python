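"""Synthetic wait-list trial generator with known ground truth.

Emulates a two-arm remotely delivered trial with a participant-chosen
dominant-symptom primary outcome: cohort mix and demographics, minimization
allocation, baseline-correlated follow-up scores with standardized treatment
effects injected per visit, secondary outcomes with printed-magnitude arm
shifts, and monotone MAR attrition driven by arm and deprivation band.
Effects are injected on the standardized scale and mapped back through each
subgroup's generating s.d., so the target ANCOVA estimand equals the spec
value by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from persym.randomization import Minimizer, StratificationProfile

#: chosen-symptom instrument: mean, s.d., lower, upper, integer-valued
CORE_DISTS: Dict[str, Tuple[float, float, float, float, bool]] = {
    "fatigue": (22.0, 5.0, 0, 33, True),           # Chalder total (Likert)
    "breathlessness": (3.2, 0.9, 1, 5, True),      # MRC grade
    "pain": (20.0, 7.0, 0, 40, True),              # P4 total
    "anxiety_depression": (21.0, 8.0, 0, 42, True),  # HADS total
    "other": (6.0, 1.8, 0, 10, False),             # symptom VAS
}

SCORED_COLUMN = {
    "fatigue": "chalder_total",
    "breathlessness": "mrc_grade",
    "pain": "p4_total",
    "anxiety_depression": "hads_total",
}

#: secondary outcome: baseline (mean, sd, lo, hi) and per-visit per-arm change
SECONDARY_DEFAULTS = {
    "weight_kg": {
        "baseline": (101.9, 20.4, 55.0, 200.0),
        "change": {3: {"control": (-1.3, 4.7), "intervention": (-9.8, 6.0)},
                   6: {"control": (-0.7, 5.2), "intervention": (-10.3, 7.5)}},
    },
    "sbp_mmhg": {
        "baseline": (128.0, 14.0, 80.0, 220.0),
        "change": {3: {"control": (-1.5, 12.9), "intervention": (-4.0, 14.1)},
                   6: {"control": (-3.2, 12.9), "intervention": (-6.6, 14.1)}},
    },
    "dbp_mmhg": {
        "baseline": (82.0, 9.0, 40.0, 130.0),
        "change": {3: {"control": (-1.0, 9.1), "intervention": (-2.5, 9.0)},
                   6: {"control": (-1.8, 9.1), "intervention": (-4.7, 9.0)}},
    },
    "eq5d_vas": {
        "baseline": (55.0, 18.0, 0.0, 100.0),
        "change": {3: {"control": (1.0, 17.8), "intervention": (6.0, 18.2)},
                   6: {"control": (2.3, 17.8), "intervention": (10.9, 18.2)}},
    },
    "eq5d_utility": {
        "baseline": (0.60, 0.22, -0.3, 1.0),
        "change": {3: {"control": (0.0, 0.15), "intervention": (0.03, 0.15)},
                   6: {"control": (0.01, 0.15), "intervention": (0.06, 0.15)}},
    },
    "work_hours_missed": {
        "baseline": (9.0, 11.0, 0.0, 80.0),
        "change": {3: {"control": (-1.5, 14.0), "intervention": (-2.5, 14.0)},
                   6: {"control": (-2.34, 14.03), "intervention": (-3.38, 13.97)}},
    },
}

OTHER_LABELS = (
    "brain fog", "insomnia", "headache", "palpitations", "joint pain",
    "dizziness", "poor concentration", "muscle aches", "hair loss",
    "altered taste",
)


@dataclass
class SimulationSpec:
    """Full parameterization of one synthetic trial."""

    n: int = 234
    symptom_probs: Mapping[str, float] = field(default_factory=lambda: {
        "fatigue": 0.54, "breathlessness": 0.16, "pain": 0.12,
        "anxiety_depression": 0.01, "other": 0.17})
    sex_probs: Mapping[str, float] = field(default_factory=lambda: {
        "female": 0.85, "male": 0.14, "other": 0.01})
    age_mean: float = 46.3
    age_sd: float = 9.8
    ethnicity_probs: Mapping[str, float] = field(default_factory=lambda: {
        "white": 0.90, "south_asian": 0.04, "other": 0.06})
    imd_probs: Mapping[str, float] = field(default_factory=lambda: {
        "1-5": 0.53, "6-10": 0.47})
    core_dists: Mapping[str, Tuple[float, float, float, float, bool]] = field(
        default_factory=lambda: dict(CORE_DISTS))
    #: standardized between-arm effect injected at each follow-up month
    effects: Mapping[int, float] = field(default_factory=lambda: {3: -0.90, 6: -0.34})
    #: control-arm secular drift in s.d. units at each follow-up month
    control_drift: Mapping[int, float] = field(default_factory=lambda: {3: -0.45, 6: -0.83})
    baseline_followup_corr: float = 0.5
    visit_months: Tuple[int, ...] = (3, 6)
    #: per-visit dropout hazard: logit = b0 + b_arm*intervention + b_imd*deprived;
    #: defaults reproduce ~97/116 intervention and ~117/118 control retention
    #: at month 6 with the deprivation-skewed noncompletion
    dropout_intercept: float = -6.104
    dropout_arm_coef: float = 3.105
    dropout_imd_coef: float = 1.0
    other_symptom_rate: float = 3.5
    p_deterministic: float = 0.8
    include_secondary: bool = True
    item_level: bool = False
    seed: Optional[int] = None

    def __post_init__(self):
        for name, probs in (("symptom", self.symptom_probs), ("sex", self.sex_probs),
                            ("ethnicity", self.ethnicity_probs), ("imd", self.imd_probs)):
            total = sum(probs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{name} probabilities sum to {total}")
            if any(p < 0 or p > 1 for p in probs.values()):
                raise ValueError(f"{name} probabilities outside [0, 1]")
        if self.n < 1:
            raise ValueError("n must be positive")
        if not all(np.isfinite(v) for v in self.effects.values()):
            raise ValueError("effects must be finite")
        if not 0 <= self.baseline_followup_corr < 1:
            raise ValueError("baseline_followup_corr must be in [0, 1)")


def _draw_levels(rng, probs: Mapping[str, float], n: int) -> np.ndarray:
    levels = list(probs)
    return rng.choice(levels, size=n, p=[probs[k] for k in levels])


def _truncate(vals: np.ndarray, lo: float, hi: float, integer: bool) -> np.ndarray:
    out = np.clip(vals, lo, hi)
    return np.rint(out) if integer else np.round(out, 1)


def generate_cohort(spec: SimulationSpec,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw the participant table: profiles, baseline covariates, chosen symptom.

    'Other' choosers are given a named main symptom; baseline instrument
    totals are drawn per the spec's distributions (truncated to instrument
    ranges). Also carries the auxiliary covariates used as imputation
    predictors (BMI, education, physical activity, employment change).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n
    for sym, (mean, sd, lo, hi, _) in spec.core_dists.items():
        if not lo <= mean <= hi:
            raise ValueError(f"baseline mean for {sym!r} outside its range [{lo}, {hi}]")

    age = rng.normal(spec.age_mean, spec.age_sd, n).clip(18, 85)
    cohort = pd.DataFrame({
        "participant_id": [f"P{i + 1:04d}" for i in range(n)],
        "chosen_symptom": _draw_levels(rng, spec.symptom_probs, n),
        "sex": _draw_levels(rng, spec.sex_probs, n),
        "age": np.round(age, 1),
        "ethnicity": _draw_levels(rng, spec.ethnicity_probs, n),
        "imd_band": _draw_levels(rng, spec.imd_probs, n),
        "bmi": np.round(rng.normal(35.0, 5.5, n).clip(25.1, 60), 1),
        "education": rng.choice(["school", "college", "degree"], size=n,
                                p=[0.3, 0.3, 0.4]),
        "physical_activity": np.round(rng.gamma(2.0, 2.0, n), 1),
        "employment_change": rng.choice(["none", "reduced", "stopped"], size=n,
                                        p=[0.6, 0.25, 0.15]),
    })
    cohort["age_band"] = np.where(cohort["age"] < 50, "<50", "50+")

    other_mask = cohort["chosen_symptom"] == "other"
    labels = np.full(n, None, dtype=object)
    labels[other_mask] = rng.choice(OTHER_LABELS, size=int(other_mask.sum()))
    cohort["main_symptom_label"] = labels
    return cohort


def _profiles(cohort: pd.DataFrame) -> List[StratificationProfile]:
    return [
        StratificationProfile(symptom=r.chosen_symptom, sex=r.sex,
                              age_band=r.age_band, ethnicity=r.ethnicity,
                              imd_band=r.imd_band)
        for r in cohort.itertuples()
    ]


def allocate(cohort: pd.DataFrame, spec: SimulationSpec,
             rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Assign arms by minimization (80:20 by default); returns cohort + arm."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    minim = Minimizer(p_deterministic=spec.p_deterministic,
                      seed=int(rng.integers(2**63)))
    arms = minim.assign_all(_profiles(cohort), ids=list(cohort["participant_id"]))
    out = cohort.copy()
    out["arm"] = arms
    out.attrs["allocation_log"] = minim.log_frame()
    return out


def _core_baseline(cohort: pd.DataFrame, spec: SimulationSpec,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Baseline scored values for every core instrument, all participants."""
    n = len(cohort)
    scored = pd.DataFrame({
        "participant_id": cohort["participant_id"],
        "visit_month": 0,
    })
    for sym, col in SCORED_COLUMN.items():
        mean, sd, lo, hi, integer = spec.core_dists[sym]
        scored[col] = _truncate(rng.normal(mean, sd, n), lo, hi, integer)
    return scored


def generate_followup(
    cohort: pd.DataFrame,
    spec: SimulationSpec,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate scored visit records (baseline + follow-ups) and other-symptom VAS.

    ``cohort`` must carry an ``arm`` column. Follow-up scores are
    baseline-correlated draws with the control-arm drift plus, in the
    intervention arm, the spec's standardized effect converted to
    instrument units via the generating s.d. Secondary outcomes get
    arm-specific shifts of the configured magnitudes. Returns
    ``(scored_visits, other_long)``.
    """
    if "arm" not in cohort.columns:
        raise ValueError("cohort has no 'arm' column; allocate first")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = len(cohort)
    interv = (cohort["arm"] == "intervention").to_numpy(dtype=float)
    rho = spec.baseline_followup_corr
    resid = np.sqrt(1 - rho**2)

    base = _core_baseline(cohort, spec, rng)
    frames = []
    for sym, col in SCORED_COLUMN.items():
        mean, sd, lo, hi, integer = spec.core_dists[sym]
        z0 = (base[col].to_numpy(dtype=float) - mean) / sd
        for month in spec.visit_months:
            zt = (spec.control_drift.get(month, 0.0) + rho * z0
                  + resid * rng.standard_normal(n)
                  + spec.effects.get(month, 0.0) * interv)
            frames.append(pd.DataFrame({
                "participant_id": cohort["participant_id"],
                "visit_month": month,
                col: _truncate(mean + sd * zt, lo, hi, integer),
            }))
    visits = base
    for month in spec.visit_months:
        month_frames = [f for f in frames if f["visit_month"].iloc[0] == month]
        row = month_frames[0]
        for f in month_frames[1:]:
            row = row.merge(f, on=["participant_id", "visit_month"])
        visits = pd.concat([visits, row], ignore_index=True)

    if spec.include_secondary:
        for name, cfg in SECONDARY_DEFAULTS.items():
            bmean, bsd, lo, hi = cfg["baseline"]
            base_vals = np.clip(rng.normal(bmean, bsd, n), lo, hi)
            if name == "eq5d_utility":
                base_vals = np.round(base_vals, 3)
            else:
                base_vals = np.round(base_vals, 1)
            visits.loc[visits["visit_month"] == 0, name] = base_vals
            for month in spec.visit_months:
                ch = cfg["change"].get(month)
                if ch is None:
                    continue
                deltas = np.where(
                    interv == 1.0,
                    rng.normal(*ch["intervention"], n),
                    rng.normal(*ch["control"], n),
                )
                vals = np.clip(base_vals + deltas, lo, hi)
                vals = np.round(vals, 3 if name == "eq5d_utility" else 1)
                visits.loc[visits["visit_month"] == month, name] = vals

    other_long = _generate_other_symptoms(cohort, spec, rng)
    visits = visits.merge(cohort[["participant_id", "arm", "chosen_symptom"]],
                          on="participant_id")
    return visits.reset_index(drop=True), other_long


def _generate_other_symptoms(cohort: pd.DataFrame, spec: SimulationSpec,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Named 'other' symptoms tracked by VAS at every visit.

    Every participant reports a Poisson number of extra symptoms (trial-like
    mean ~3.5); 'other' choosers always include their main symptom. Once
    recorded, a symptom is rated at all subsequent visits.
    """
    mean, sd, lo, hi, _ = spec.core_dists["other"]
    rho = spec.baseline_followup_corr
    resid = np.sqrt(1 - rho**2)
    rows = []
    counts = rng.poisson(spec.other_symptom_rate, len(cohort))
    for i, r in enumerate(cohort.itertuples()):
        chosen = set()
        if r.chosen_symptom == "other":
            chosen.add(r.main_symptom_label)
        k = max(counts[i], len(chosen))
        pool = [s for s in OTHER_LABELS if s not in chosen]
        extra = rng.choice(pool, size=min(k - len(chosen), len(pool)), replace=False)
        labels = sorted(chosen) + list(extra)
        interv = 1.0 if r.arm == "intervention" else 0.0
        for label in labels:
            v0 = float(_truncate(np.array([rng.normal(mean, sd)]), lo, hi, False)[0])
            rows.append((r.participant_id, 0, label, v0))
            z0 = (v0 - mean) / sd
            for month in spec.visit_months:
                zt = (spec.control_drift.get(month, 0.0) + rho * z0
                      + resid * rng.standard_normal()
                      + spec.effects.get(month, 0.0) * interv)
                vt = float(_truncate(np.array([mean + sd * zt]), lo, hi, False)[0])
                rows.append((r.participant_id, month, label, vt))
    return pd.DataFrame(rows, columns=["participant_id", "visit_month",
                                       "symptom_label", "vas"])


def apply_attrition(
    visits: pd.DataFrame,
    cohort: pd.DataFrame,
    spec: SimulationSpec,
    rng: Optional[np.random.Generator] = None,
    other_long: Optional[pd.DataFrame] = None,
):
    """Impose monotone MAR dropout; returns masked tables + follow-up indicator.

    Per-visit loss hazard follows the spec's logit model in arm and
    deprivation band; once lost, a participant stays lost. Data columns at
    missed visits become NaN (rows are kept), and a ``followed_up`` column
    is emitted for the IPW sensitivity path. Returns
    ``(visits', other_long', followup)`` where ``followup`` has one row per
    participant-visit.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    interv = (cohort["arm"] == "intervention").to_numpy(dtype=float)
    deprived = (cohort["imd_band"] == "1-5").to_numpy(dtype=float)
    hazard = expit(spec.dropout_intercept + spec.dropout_arm_coef * interv
                   + spec.dropout_imd_coef * deprived)

    lost = np.zeros(len(cohort), dtype=bool)
    followed: Dict[int, np.ndarray] = {}
    for month in spec.visit_months:
        lost = lost | (rng.random(len(cohort)) < hazard)
        followed[month] = ~lost

    fu_rows = []
    for month in spec.visit_months:
        fu_rows.append(pd.DataFrame({
            "participant_id": cohort["participant_id"],
            "visit_month": month,
            "followed_up": followed[month],
        }))
    followup = pd.concat(fu_rows, ignore_index=True)

    out = visits.copy()
    meta = {"participant_id", "visit_month", "arm", "chosen_symptom"}
    data_cols = [c for c in out.columns if c not in meta]
    for month in spec.visit_months:
        lost_ids = set(cohort.loc[~followed[month], "participant_id"])
        mask = (out["visit_month"] == month) & out["participant_id"].isin(lost_ids)
        out.loc[mask, data_cols] = np.nan

    other_out = None
    if other_long is not None:
        other_out = other_long.copy()
        drop = pd.Series(False, index=other_out.index)
        for month in spec.visit_months:
            lost_ids = set(cohort.loc[~followed[month], "participant_id"])
            drop |= ((other_out["visit_month"] == month)
                     & other_out["participant_id"].isin(lost_ids))
        other_out = other_out[~drop].reset_index(drop=True)
    return out, other_out, followup


@dataclass
class TrialData:
    """One generated trial: tables plus the ground truth that made it."""

    cohort: pd.DataFrame
    visits: pd.DataFrame
    other_long: pd.DataFrame
    followup: pd.DataFrame
    allocation_log: pd.DataFrame
    ground_truth: Dict

    def ground_truth_json(self) -> str:
        return json.dumps(self.ground_truth, indent=2, default=str)


def generate_trial(spec: SimulationSpec,
                   seed: Optional[int] = None) -> TrialData:
    """Full pipeline: cohort -> minimization -> follow-up -> attrition."""
    if seed is not None:
        spec_seed = seed
    else:
        spec_seed = spec.seed
    rng = np.random.default_rng(spec_seed)
    cohort = generate_cohort(spec, rng)
    cohort = allocate(cohort, spec, rng)
    visits, other_long = generate_followup(cohort, spec, rng)
    visits, other_long, followup = apply_attrition(visits, cohort, spec, rng,
                                                   other_long)
    truth = {
        "effects": dict(spec.effects),
        "control_drift": dict(spec.control_drift),
        "dropout": {
            "intercept": spec.dropout_intercept,
            "arm_coef": spec.dropout_arm_coef,
            "imd_coef": spec.dropout_imd_coef,
        },
        "baseline_followup_corr": spec.baseline_followup_corr,
        "seed": spec_seed,
    }
    return TrialData(cohort=cohort, visits=visits, other_long=other_long,
                     followup=followup,
                     allocation_log=cohort.attrs.get("allocation_log"),
                     ground_truth=truth)


def expand_items(visits: pd.DataFrame, spec: SimulationSpec,
                 rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Back-fill item-level responses consistent with the scored totals.

    Each instrument total is distributed across its items by repeated
    random unit increments under the per-item cap, so items are exchangeable
    and every row round-trips through ``instruments.validate_visit``.
    Emits the long-format CSV schema consumed by the scoring layer.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)

    def split_total(total, n_items, cap):
        items = np.zeros(n_items, dtype=int)
        t = int(total)
        if t > n_items * cap:
            raise ValueError(f"total {t} infeasible for {n_items} items capped at {cap}")
        while t > 0:
            open_idx = np.flatnonzero(items < cap)
            items[open_idx[rng.integers(len(open_idx))]] += 1
            t -= 1
        return items

    rows = []
    for r in visits.itertuples():
        row = {"participant_id": r.participant_id, "visit_month": r.visit_month}
        for attr in ("arm", "chosen_symptom"):
            if hasattr(r, attr):
                row[attr] = getattr(r, attr)
        if pd.notna(r.chalder_total):
            for i, v in enumerate(split_total(r.chalder_total, 11, 3), 1):
                row[f"chalder_{i:02d}"] = v
        if pd.notna(r.hads_total):
            half = int(r.hads_total) // 2
            a_total = min(21, max(int(r.hads_total) - 21, half + int(rng.integers(-2, 3))))
            a_total = int(np.clip(a_total, max(0, int(r.hads_total) - 21), min(21, int(r.hads_total))))
            for i, v in enumerate(split_total(a_total, 7, 3), 1):
                row[f"hads_a{i}"] = v
            for i, v in enumerate(split_total(int(r.hads_total) - a_total, 7, 3), 1):
                row[f"hads_d{i}"] = v
        if pd.notna(r.p4_total):
            for i, v in enumerate(split_total(r.p4_total, 4, 10), 1):
                row[f"p4_{i}"] = v
        if pd.notna(r.mrc_grade):
            row["mrc_dyspnea"] = int(r.mrc_grade)
        for col in ("eq5d_vas", "eq5d_utility", "weight_kg", "sbp_mmhg",
                    "dbp_mmhg", "work_hours_missed"):
            if hasattr(r, col):
                row[col] = getattr(r, col)
        rows.append(row)
    return pd.DataFrame(rows)
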