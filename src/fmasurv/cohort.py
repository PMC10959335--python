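"""New-user cohort derivation from raw claims tables.

Applies the index, inclusion/exclusion, outcome-definition and censoring
rules of a new-user, active-comparator design to a :class:`ClaimsBundle`:

1. index = earliest qualifying DMT fill in the index window, arm = that drug;
2. proportion of days covered (PDC) for the index drug >= threshold over
   the post-index year;
3. continuous enrolment over the pre-index through post-index year, a
   single gap of up to 30 days allowed;
4. at least two MS diagnoses during the pre-index year;
5. age >= 18 at index;
6. exclusion of patients with any outcome diagnosis or any study-DMT fill
   during the pre-index year (prevalent disease / prior exposure).

Follow-up runs from index to the first of: outcome event, insurance
disenrollment (enrolment gap > 90 days), end of the study window and — in
on-treatment mode — discontinuation of the index drug.  Every step is
recorded in an attrition report that telescopes to the final cohort size.

Dates are handled as integer day offsets internally; enrolment spans are
inclusive of their end date; intervals are half-open [start, end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .synthetic import ClaimsBundle, default_code_vocabulary, DAYS_PER_YEAR

__all__ = [
    "StudyWindows",
    "CodeMap",
    "AttritionReport",
    "AmbiguousIndexError",
    "assign_index",
    "compute_pdc",
    "check_continuous_enrolment",
    "derive_outcome",
    "compute_followup",
    "apply_attrition",
    "impute_region",
]

logger = logging.getLogger(__name__)

OUTCOMES = ("t2d", "ahf", "atherosclerosis", "mi", "stroke", "cvd", "ckd", "composite")
_CVD_COMPONENTS = ("ahf", "atherosclerosis", "mi", "stroke")


class AmbiguousIndexError(ValueError):
    """Two different study DMTs filled on a patient's first qualifying date."""


@dataclass
class StudyWindows:
    index_start: str = "2013-01-01"
    index_end: str = "2018-12-31"
    pre_index_days: int = 365
    post_index_days: int = 365
    study_end: str = "2019-12-31"
    enrolment_gap_allowance: int = 30
    gap_mode: str = "per_gap"  # "per_gap" | "total"
    disenrollment_gap: int = 90
    pdc_threshold: float = 0.60
    pdc_includes_index_day: bool = True
    pre_index_includes_index_day: bool = False
    discontinuation_gap: int = 60

    def validate(self) -> None:
        if not 0.0 < self.pdc_threshold <= 1.0:
            raise ValueError("pdc_threshold must be in (0, 1]")
        if pd.Timestamp(self.index_end) > pd.Timestamp(self.study_end):
            raise ValueError("index window must lie within the study window")
        if self.gap_mode not in ("per_gap", "total"):
            raise ValueError("gap_mode must be 'per_gap' or 'total'")


@dataclass
class CodeMap:
    """Per-concept code sets; DMT drug codes keyed by arm label."""

    concepts: dict = field(default_factory=default_code_vocabulary)

    def __post_init__(self) -> None:
        dmt = self.concepts.get("dmt", {})
        classes = [frozenset(c) for c in dmt.values()]
        for key, codes in self.concepts.items():
            if key == "dmt":
                if any(not c for c in dmt.values()):
                    raise ValueError("empty DMT code set")
                continue
            if not codes:
                raise ValueError(f"empty code set for concept {key!r}")
        for i, a in enumerate(classes):
            for b in classes[i + 1 :]:
                if a & b:
                    raise ValueError("DMT drug-class code sets must be disjoint")

    def __getitem__(self, key: str) -> set:
        return self.concepts[key]

    @property
    def dmt(self) -> dict:
        return self.concepts["dmt"]

    def all_dmt_codes(self) -> set:
        return set().union(*self.dmt.values())

    def outcome_codes(self) -> set:
        out = set()
        for key in ("t2d", "ahf", "atherosclerosis", "mi", "stroke", "ckd"):
            out |= set(self.concepts[key])
        return out


@dataclass
class AttritionReport:
    steps: list = field(default_factory=list)  # dicts: rule, n_before, n_removed, n_after
    per_arm: dict = field(default_factory=dict)

    def add(self, rule: str, n_before: int, n_removed: int, per_arm: dict | None = None) -> None:
        self.steps.append(
            {
                "rule": rule,
                "n_before": int(n_before),
                "n_removed": int(n_removed),
                "n_after": int(n_before - n_removed),
            }
        )
        if per_arm is not None:
            self.per_arm[rule] = {k: int(v) for k, v in per_arm.items()}

    @property
    def final_n(self) -> int:
        return self.steps[-1]["n_after"] if self.steps else 0

    def removals(self) -> list:
        return [s["n_removed"] for s in self.steps]

    def to_dict(self) -> dict:
        return asdict(self)


def _days(dates) -> np.ndarray:
    """ISO dates / timestamps -> integer day offsets."""
    return (
        (pd.to_datetime(dates) - pd.Timestamp("1970-01-01")) // pd.Timedelta(days=1)
    )


# ---------------------------------------------------------------------------
# Index assignment
# ---------------------------------------------------------------------------

def assign_index(fills: pd.DataFrame, windows: StudyWindows, code_map: CodeMap) -> pd.DataFrame:
    """Earliest qualifying DMT fill in the index window per patient.

    Returns a frame indexed by patient_id with columns index_day (integer
    day offset), index_date and index_arm.  Patients without a qualifying
    fill are omitted; two *different* DMTs on the first date raise
    :class:`AmbiguousIndexError` listing the patients.
    """
    lo = int(_days(pd.Series([windows.index_start])).iloc[0])
    hi = int(_days(pd.Series([windows.index_end])).iloc[0])
    code_to_arm = {c: arm for arm, codes in code_map.dmt.items() for c in codes}
    f = fills[fills["code"].isin(code_to_arm)].copy()
    f["day"] = _days(f["date"])
    f = f[(f["day"] >= lo) & (f["day"] <= hi)]
    if f.empty:
        return pd.DataFrame(columns=["index_day", "index_date", "index_arm"])
    first_day = f.groupby("patient_id")["day"].transform("min")
    on_first = f[f["day"] == first_day]
    arms = on_first.groupby("patient_id")["code"].agg(lambda c: {code_to_arm[x] for x in c})
    ambiguous = arms[arms.map(len) > 1]
    if len(ambiguous):
        raise AmbiguousIndexError(
            "multiple DMTs on index date for patients: "
            + ", ".join(map(str, ambiguous.index.tolist()))
        )
    out = on_first.groupby("patient_id").agg(index_day=("day", "first"))
    out["index_date"] = pd.to_datetime(out["index_day"], unit="D")
    out["index_arm"] = arms.map(lambda s: next(iter(s)))
    return out


# ---------------------------------------------------------------------------
# Adherence and enrolment rules
# ---------------------------------------------------------------------------

def compute_pdc(
    fills: pd.DataFrame,
    index_day: int,
    post_index_days: int,
    drug_codes: set,
    include_index_day: bool = True,
) -> float:
    """Proportion of days covered by the index drug in the post-index year.

    Coverage is the union of [fill_day, fill_day + days_supply) intervals
    intersected with the post-index window; PDC = covered days / window
    length.
    """
    start = index_day if include_index_day else index_day + 1
    window = np.zeros(post_index_days, dtype=bool)
    f = fills[fills["code"].isin(drug_codes)]
    if (f["days_supply"] <= 0).any():
        raise ValueError("non-positive days_supply in fills")
    days = _days(f["date"]).to_numpy()
    for d, supply in zip(days, f["days_supply"].to_numpy()):
        a = max(int(d) - start, 0)
        b = min(int(d) + int(supply) - start, post_index_days)
        if b > a:
            window[a:b] = True
    return float(window.sum()) / post_index_days


def _merge_spans(starts: np.ndarray, ends_excl: np.ndarray) -> list:
    order = np.argsort(starts)
    merged: list[list[int]] = []
    for s, e in zip(starts[order], ends_excl[order]):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])
    return merged


def check_continuous_enrolment(
    enrolment: pd.DataFrame, index_day: int, windows: StudyWindows
) -> bool:
    """True iff the pre- through post-index window is continuously enrolled.

    Window is [index − pre_index_days, index + post_index_days); enrolment
    spans are inclusive of end_date.  In "per_gap" mode every uncovered gap
    must be <= the allowance; in "total" mode the summed gap days must be.
    """
    lo = index_day - windows.pre_index_days
    hi = index_day + windows.post_index_days  # exclusive
    starts = _days(enrolment["start_date"]).to_numpy()
    ends = _days(enrolment["end_date"]).to_numpy() + 1  # end inclusive
    merged = _merge_spans(starts, ends)
    gaps = []
    cursor = lo
    for s, e in merged:
        if e <= lo or s >= hi:
            continue
        if s > cursor:
            gaps.append(min(s, hi) - cursor)
        cursor = max(cursor, min(e, hi))
    if cursor < hi:
        gaps.append(hi - cursor)
    if not gaps:
        return True
    if windows.gap_mode == "total":
        return sum(gaps) <= windows.enrolment_gap_allowance
    return max(gaps) <= windows.enrolment_gap_allowance


# ---------------------------------------------------------------------------
# Outcome definitions
# ---------------------------------------------------------------------------

def derive_outcome(
    diagnoses: pd.DataFrame,
    fills: pd.DataFrame,
    code_map: CodeMap,
    outcome: str,
) -> pd.Series:
    """First date (integer day) each patient satisfies the outcome definition.

    T2D: two diagnosis codes, or one diagnosis plus one diabetes-medication
    fill (event dated at the second qualifying record).  CVD: earliest of
    AHF / atherosclerosis / MI / stroke (single diagnosis each).  CKD:
    single diagnosis.  Composite: earliest of T2D / CVD / CKD.
    """
    outcome = outcome.lower()
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")

    def first_dx(concept):
        d = diagnoses[diagnoses["code"].isin(code_map[concept])]
        if d.empty:
            return pd.Series(dtype=float)
        return d.assign(day=_days(d["date"])).groupby("patient_id")["day"].min()

    if outcome == "t2d":
        d = diagnoses[diagnoses["code"].isin(code_map["t2d"])]
        second_dx = pd.Series(dtype=float)
        if not d.empty:
            days = d.assign(day=_days(d["date"])).sort_values("day")
            second_dx = (
                days.groupby("patient_id")["day"]
                .apply(lambda s: s.iloc[1] if len(s) > 1 else np.nan)
                .dropna()
            )
        first_t2d_dx = first_dx("t2d")
        rx = fills[fills["code"].isin(code_map["diabetes_rx"])]
        first_rx = (
            rx.assign(day=_days(rx["date"])).groupby("patient_id")["day"].min()
            if not rx.empty
            else pd.Series(dtype=float)
        )
        mixed = pd.concat([first_t2d_dx, first_rx], axis=1, keys=["dx", "rx"]).dropna()
        mixed_day = mixed.max(axis=1) if not mixed.empty else pd.Series(dtype=float)
        return pd.concat([second_dx, mixed_day], axis=1).min(axis=1).dropna()
    if outcome in ("ahf", "atherosclerosis", "mi", "stroke", "ckd"):
        return first_dx(outcome)
    if outcome == "cvd":
        parts = [first_dx(c) for c in _CVD_COMPONENTS]
        return pd.concat(parts, axis=1).min(axis=1).dropna()
    # composite
    parts = [
        derive_outcome(diagnoses, fills, code_map, o) for o in ("t2d", "cvd", "ckd")
    ]
    return pd.concat(parts, axis=1).min(axis=1).dropna()


# ---------------------------------------------------------------------------
# Follow-up
# ---------------------------------------------------------------------------

def compute_followup(
    enrolment: pd.DataFrame,
    index_day: int,
    windows: StudyWindows,
    event_day: float | None = None,
    discontinuation_day: float | None = None,
    mode: str = "itt",
) -> tuple[float, int, str]:
    """(time_years, event_flag, censor_reason) for one patient.

    Follow-up ends at the first of: the outcome event, the first day of an
    enrolment gap longer than ``disenrollment_gap`` days after index, the
    study end and — in "on_treatment" mode — the discontinuation date.
    """
    if mode not in ("itt", "on_treatment"):
        raise ValueError("mode must be 'itt' or 'on_treatment'")
    study_end = int(_days(pd.Series([windows.study_end])).iloc[0])
    starts = _days(enrolment["start_date"]).to_numpy()
    ends = _days(enrolment["end_date"]).to_numpy() + 1
    merged = _merge_spans(starts, ends)

    disenroll = None
    cursor = index_day
    for s, e in merged:
        if e <= index_day:
            continue
        if s > cursor:
            if min(study_end + 1, s) - cursor > windows.disenrollment_gap:
                disenroll = cursor
                break
        cursor = max(cursor, e)
    if disenroll is None and cursor <= study_end:
        if study_end + 1 - cursor > windows.disenrollment_gap:
            disenroll = cursor

    candidates = {"study_end": study_end}
    if disenroll is not None:
        candidates["disenrollment"] = disenroll
    if mode == "on_treatment" and discontinuation_day is not None:
        candidates["discontinuation"] = int(discontinuation_day)
    reason, end_day = min(candidates.items(), key=lambda kv: (kv[1], kv[0]))
    if event_day is not None and event_day <= end_day:
        reason, end_day, flag = "event", int(event_day), 1
    else:
        flag = 0
    time_years = max(end_day - index_day, 0.5) / DAYS_PER_YEAR
    return float(time_years), int(flag), reason


def discontinuation_day(
    fills: pd.DataFrame, index_day: int, drug_codes: set, gap: int = 60
) -> float | None:
    """Day the index drug was discontinued: end of the last covered day
    followed by a supply gap longer than ``gap`` days (the tail after the
    final fill always counts as a gap)."""
    f = fills[fills["code"].isin(drug_codes)].copy()
    if f.empty:
        return None
    f["day"] = _days(f["date"])
    f = f[f["day"] >= index_day].sort_values("day")
    if f.empty:
        return None
    cover_end = None
    for d, supply in zip(f["day"].to_numpy(), f["days_supply"].to_numpy()):
        if cover_end is not None and d - cover_end > gap:
            return float(cover_end)
        cover_end = max(cover_end or 0, int(d) + int(supply))
    return float(cover_end)


# ---------------------------------------------------------------------------
# Region imputation
# ---------------------------------------------------------------------------

def impute_region(cohort: pd.DataFrame, column: str = "region") -> pd.DataFrame:
    """Fill missing region with the modal category (lexicographic tie-break)."""
    out = cohort.copy()
    col = out[column]
    missing = col.isna() | (col.astype(str) == "")
    if not missing.any():
        return out
    observed = col[~missing]
    if observed.empty:
        raise ValueError("region is missing for every patient; cannot impute")
    counts = observed.value_counts()
    top = counts[counts == counts.max()].index.tolist()
    mode = sorted(map(str, top))[0]
    if len(top) > 1:
        logger.info("region mode tie %s resolved lexicographically to %r", top, mode)
    logger.info("imputed %d missing region values as %r", int(missing.sum()), mode)
    out.loc[missing, column] = mode
    return out


# ---------------------------------------------------------------------------
# Full attrition pipeline
# ---------------------------------------------------------------------------

def apply_attrition(
    bundle: ClaimsBundle,
    windows: StudyWindows | None = None,
    code_map: CodeMap | None = None,
    outcome: str = "composite",
    mode: str = "itt",
) -> tuple[pd.DataFrame, AttritionReport]:
    """Derive the analysis cohort and its attrition audit trail.

    Applies, in order: index assignment, PDC >= threshold, continuous
    enrolment, >= 2 MS diagnoses pre-index, age >= 18 at index, and the
    prevalent-outcome / prior-DMT exclusion.  Returns the cohort table
    (one row per retained patient with covariates, follow-up time, event
    indicator and censoring reason) and the step-by-step report.
    """
    windows = windows or StudyWindows()
    windows.validate()
    code_map = code_map or CodeMap()
    for name, table in (
        ("enrolment", bundle.enrolment),
        ("diagnoses", bundle.diagnoses),
        ("fills", bundle.fills),
    ):
        if table is None:
            raise ValueError(f"missing required claims table {name!r}")

    report = AttritionReport()
    all_patients = bundle.enrolment["patient_id"].unique()
    n0 = len(all_patients)

    index = assign_index(bundle.fills, windows, code_map)
    report.add("index DMT fill in index window", n0, n0 - len(index))
    keep = index.index.to_numpy()

    enrol_by_pid = dict(tuple(bundle.enrolment.groupby("patient_id")))
    dx_by_pid = dict(tuple(bundle.diagnoses.groupby("patient_id")))
    fills_by_pid = dict(tuple(bundle.fills.groupby("patient_id")))
    empty_dx = bundle.diagnoses.iloc[0:0]
    empty_fills = bundle.fills.iloc[0:0]

    # PDC >= threshold
    ok = []
    for pid in keep:
        arm = index.loc[pid, "index_arm"]
        iday = int(index.loc[pid, "index_day"])
        pdc = compute_pdc(
            fills_by_pid.get(pid, empty_fills),
            iday,
            windows.post_index_days,
            code_map.dmt[arm],
            include_index_day=windows.pdc_includes_index_day,
        )
        if pdc >= windows.pdc_threshold:
            ok.append(pid)
    report.add(f"PDC >= {windows.pdc_threshold:.0%}", len(keep), len(keep) - len(ok))
    keep = np.asarray(ok)

    # continuous enrolment
    ok = [
        pid
        for pid in keep
        if check_continuous_enrolment(
            enrol_by_pid[pid], int(index.loc[pid, "index_day"]), windows
        )
    ]
    report.add("continuous enrolment (30-day gap allowed)", len(keep), len(keep) - len(ok))
    keep = np.asarray(ok)

    # >= 2 MS diagnoses pre-index
    def pre_window(iday):
        hi = iday + 1 if windows.pre_index_includes_index_day else iday
        return iday - windows.pre_index_days, hi  # [lo, hi)

    ok = []
    for pid in keep:
        iday = int(index.loc[pid, "index_day"])
        lo, hi = pre_window(iday)
        dx = dx_by_pid.get(pid, empty_dx)
        days = _days(dx["date"]).to_numpy()
        n_ms = int(
            (dx["code"].isin(code_map["ms"]).to_numpy() & (days >= lo) & (days < hi)).sum()
        )
        if n_ms >= 2:
            ok.append(pid)
    report.add(">= 2 MS diagnoses pre-index", len(keep), len(keep) - len(ok))
    keep = np.asarray(ok)

    # age >= 18 at index
    birth = bundle.enrolment.groupby("patient_id")["birth_year"].first()
    ok = []
    ages = {}
    for pid in keep:
        iday = int(index.loc[pid, "index_day"])
        year = pd.to_datetime(iday, unit="D").year
        age = year - int(birth.loc[pid])
        ages[pid] = age
        if age >= 18:
            ok.append(pid)
    report.add("age >= 18 at index", len(keep), len(keep) - len(ok))
    keep = np.asarray(ok)

    # prevalent outcome or prior DMT exposure pre-index
    out_codes = code_map.outcome_codes()
    dmt_codes = code_map.all_dmt_codes()
    ok = []
    for pid in keep:
        iday = int(index.loc[pid, "index_day"])
        lo, hi = pre_window(iday)
        dx = dx_by_pid.get(pid, empty_dx)
        ddays = _days(dx["date"]).to_numpy()
        prevalent = (dx["code"].isin(out_codes).to_numpy() & (ddays >= lo) & (ddays < hi)).any()
        fl = fills_by_pid.get(pid, empty_fills)
        fdays = _days(fl["date"]).to_numpy()
        prior = (fl["code"].isin(dmt_codes).to_numpy() & (fdays >= lo) & (fdays < iday)).any()
        if not (prevalent or prior):
            ok.append(pid)
    report.add("no prevalent outcome / prior DMT pre-index", len(keep), len(keep) - len(ok))
    keep = np.asarray(ok)

    arm_counts = (
        index.loc[keep, "index_arm"].value_counts().to_dict() if len(keep) else {}
    )
    report.per_arm["final"] = {k: int(v) for k, v in arm_counts.items()}

    # build cohort rows
    demo = bundle.enrolment.groupby("patient_id").first()
    rows = []
    baseline_flags = ("hypertension", "hyperlipidaemia", "tobacco", "mobility_aid")
    for pid in keep:
        iday = int(index.loc[pid, "index_day"])
        lo, hi = pre_window(iday)
        dx = dx_by_pid.get(pid, empty_dx)
        ddays = _days(dx["date"]).to_numpy()
        pre_mask = (ddays >= lo) & (ddays < hi)
        pre_dx = dx[pre_mask]
        fl = fills_by_pid.get(pid, empty_fills)
        fdays = _days(fl["date"]).to_numpy()
        post = fl[fdays >= iday]
        post_dx = dx[ddays >= iday]
        arm = index.loc[pid, "index_arm"]

        ev = derive_outcome(post_dx, post, code_map, outcome)
        ev_day = float(ev.loc[pid]) if pid in ev.index else None
        disc = (
            discontinuation_day(fl, iday, code_map.dmt[arm], windows.discontinuation_gap)
            if mode == "on_treatment"
            else None
        )
        t, e, reason = compute_followup(
            enrol_by_pid[pid], iday, windows, ev_day, disc, mode
        )
        row = {
            "patient_id": pid,
            "arm": arm,
            "age": ages[pid],
            "sex": demo.loc[pid, "sex"] if "sex" in demo else "",
            "region": demo.loc[pid, "region"] if "region" in demo else "",
            "payer": demo.loc[pid, "payer"] if "payer" in demo else "",
        }
        for flag in baseline_flags:
            row[flag] = int(pre_dx["code"].isin(code_map[flag]).any())
        row["charlson"] = int(pre_dx["code"].isin(code_map["charlson"]).sum())
        row.update({"time_years": t, "event": e, "censor_reason": reason})
        rows.append(row)

    cols = [
        "patient_id", "arm", "age", "sex", "region", "payer", "tobacco",
        "mobility_aid", "hyperlipidaemia", "hypertension", "charlson",
        "time_years", "event", "censor_reason",
    ]
    cohort = pd.DataFrame(rows, columns=cols)
    return cohort, report
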