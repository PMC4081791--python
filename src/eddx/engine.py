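"""Deterministic, auditable DSM-IV / DSM-5 eating-disorder rule engine.

Design notes
------------
Interview "regular" flags carry the interview's own twice-weekly/3-month
threshold (the DSM-IV level). The lower DSM-5 once-weekly criteria are met
either by the interview flag, or — as a fallback, recorded in provenance —
by a 28-day questionnaire count of at least 4 (four weeks x once weekly).
The fallback is never consulted when the interview already establishes the
behavior, and purging-disorder's exclusion of regular binges as well as its
"regular purging" requirement are interview-only: questionnaire counts
alone can neither create nor destroy a PD assignment.

"Significantly low weight" is operationalized as BMI < 18.5 throughout,
the same cut that gates PD from above. Atypical AN's "significant weight
loss" is unobservable at the item level, so its surrogate is the full AN
cognitive picture plus at least one regular restrictive/compensatory
behavior at BMI >= 18.5; the resulting overlap with PD is resolved purely
by category precedence.

Each category's pass/fail predicate is a function of the record alone
(never of the position of other categories in the precedence), so a
precedence permutation can only redistribute records among overlapping
categories — it can never change whether a record is diagnosed at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .labels import (DEFAULT_PRECEDENCE, Dsm4Label, Dsm5Label, REMISSION,
                     validate_precedence)
from .records import MONTH12, PatientRecord

#: 28-day questionnaire count establishing "at least once weekly".
WEEKLY_FALLBACK_COUNT = 4
#: Ordinal fasting-item band establishing at-least-weekly fasting.
WEEKLY_FASTING_SCORE = 2
#: Low-weight / normal-weight boundary (kg/m^2).
LOW_WEIGHT_BMI = 18.5

INTERVIEW = "interview"
EDEQ_FALLBACK = "edeq_fallback"
ANTHROPOMETRY = "anthropometry"
DERIVED = "derived"


@dataclass(slots=True)
class Criterion:
    met: bool
    source: str


class CriteriaProfile(dict):
    """Map criterion_id -> Criterion with convenience boolean access."""

    def met(self, criterion_id: str) -> bool:
        return self[criterion_id].met

    def source(self, criterion_id: str) -> str:
        return self[criterion_id].source


@dataclass(slots=True)
class DiagnosisResult:
    label: Dsm5Label
    trace: list = field(default_factory=list)
    precedence: tuple = DEFAULT_PRECEDENCE


def _weekly(profile: CriteriaProfile, name: str, regular: bool,
            fallback_met: bool) -> None:
    if regular:
        profile[name] = Criterion(True, INTERVIEW)
    elif fallback_met:
        profile[name] = Criterion(True, EDEQ_FALLBACK)
    else:
        profile[name] = Criterion(False, INTERVIEW)


def evaluate_criteria(record: PatientRecord) -> CriteriaProfile:
    """Evaluate every criterion any diagnostic rule consults, with provenance.

    Total on valid records; the questionnaire fallback is only recorded as
    the source when the interview flag alone did not establish the behavior.
    """
    iv, q = record.interview, record.edeq
    p = CriteriaProfile()

    _weekly(p, "weekly_obe", iv.regular_obe, q.obe_freq >= WEEKLY_FALLBACK_COUNT)
    _weekly(p, "weekly_sbe", iv.regular_sbe, q.sbe_freq >= WEEKLY_FALLBACK_COUNT)
    _weekly(p, "weekly_vomiting", iv.regular_vomiting,
            q.vomit_freq >= WEEKLY_FALLBACK_COUNT)
    _weekly(p, "weekly_laxatives", iv.regular_laxatives,
            q.laxative_freq >= WEEKLY_FALLBACK_COUNT)
    _weekly(p, "weekly_diuretics", iv.regular_diuretics,
            q.diuretic_freq >= WEEKLY_FALLBACK_COUNT)
    _weekly(p, "weekly_fasting", iv.regular_fasting,
            q.fasting_score >= WEEKLY_FASTING_SCORE)
    _weekly(p, "weekly_exercise", iv.regular_excess_exercise,
            q.exercise_freq >= WEEKLY_FALLBACK_COUNT)
    comp_ids = ("weekly_vomiting", "weekly_laxatives", "weekly_diuretics",
                "weekly_fasting", "weekly_exercise")
    p["weekly_compensation"] = Criterion(any(p.met(c) for c in comp_ids), DERIVED)

    # Interview-threshold (DSM-IV level) behaviors.
    p["regular_obe"] = Criterion(iv.regular_obe, INTERVIEW)
    p["regular_purging"] = Criterion(
        iv.regular_vomiting or iv.regular_laxatives or iv.regular_diuretics,
        INTERVIEW)
    p["regular_compensation"] = Criterion(
        p.met("regular_purging") or iv.regular_fasting
        or iv.regular_excess_exercise, INTERVIEW)
    p["regular_binge_or_purge"] = Criterion(
        iv.regular_obe or iv.regular_sbe or p.met("regular_purging"), DERIVED)

    p["low_weight"] = Criterion(record.bmi < LOW_WEIGHT_BMI, ANTHROPOMETRY)

    for name in ("weight_phobia", "undue_influence", "body_disturbance",
                 "denial_of_seriousness", "amenorrhea", "loss_of_control",
                 "binge_distress"):
        p[name] = Criterion(getattr(iv, name), INTERVIEW)

    # AN cognitive clusters: fear of weight gain (or persistent behavior that
    # interferes with weight gain) and the disturbed-experience cluster.
    p["an_fear"] = Criterion(
        iv.weight_phobia or p.met("regular_compensation"), DERIVED)
    p["an_body"] = Criterion(
        iv.body_disturbance or iv.undue_influence or iv.denial_of_seriousness,
        DERIVED)

    # Minimal-residual ("EDNOS other") symptom clusters. Behaviors count at
    # any frequency: an interview flag or a single questionnaire episode.
    p["ednos_psych"] = Criterion(
        iv.weight_phobia or iv.undue_influence or iv.body_disturbance
        or iv.denial_of_seriousness, DERIVED)
    p["ednos_behavioral"] = Criterion(
        iv.regular_obe or iv.regular_sbe or q.obe_freq >= 1 or q.sbe_freq >= 1
        or iv.loss_of_control
        or p.met("regular_purging") or q.vomit_freq >= 1
        or q.laxative_freq >= 1 or q.diuretic_freq >= 1
        or iv.regular_fasting or iv.regular_excess_exercise
        or q.fasting_score >= 1 or q.exercise_freq >= 1, DERIVED)
    p["ednos_physical"] = Criterion(
        p.met("low_weight") or iv.amenorrhea, DERIVED)

    # Sub-threshold binge/compensation presence at any frequency.
    p["obe_present"] = Criterion(iv.regular_obe or q.obe_freq >= 1, DERIVED)
    p["comp_present"] = Criterion(
        p.met("regular_compensation") or q.vomit_freq >= 1
        or q.laxative_freq >= 1 or q.diuretic_freq >= 1
        or q.exercise_freq >= 1 or q.fasting_score >= 1, DERIVED)

    return p


# ---------------------------------------------------------------------------
# Category predicates (order-free; precedence only selects the first pass).

def _an5(p: CriteriaProfile) -> bool:
    return p.met("low_weight") and p.met("an_fear") and p.met("an_body")


def _ran(p: CriteriaProfile) -> bool:
    return _an5(p) and not p.met("regular_binge_or_purge")


def _anbp(p: CriteriaProfile) -> bool:
    return _an5(p) and p.met("regular_binge_or_purge")


def _bn(p: CriteriaProfile) -> bool:
    return (p.met("weekly_obe") and p.met("weekly_compensation")
            and p.met("undue_influence") and not _an5(p))


def _bed(p: CriteriaProfile) -> bool:
    return (p.met("weekly_obe") and p.met("binge_distress")
            and not p.met("weekly_compensation") and not _an5(p))


def _pd(p: CriteriaProfile, bmi: float) -> bool:
    return (p.met("regular_purging") and bmi > LOW_WEIGHT_BMI
            and (p.met("undue_influence") or p.met("weight_phobia"))
            and not p.met("regular_obe"))


def _aan(p: CriteriaProfile) -> bool:
    return (p.met("an_fear") and p.met("an_body") and not p.met("low_weight")
            and p.met("regular_compensation") and not _bn(p) and not _bed(p))


def _subbn(p: CriteriaProfile) -> bool:
    return (p.met("obe_present") and p.met("comp_present")
            and p.met("undue_influence")
            and not (p.met("weekly_obe") and p.met("weekly_compensation"))
            and not _an5(p))


def _subbed(p: CriteriaProfile) -> bool:
    return (p.met("obe_present") and not p.met("weekly_obe")
            and p.met("binge_distress") and not p.met("comp_present")
            and not _an5(p))


def _category_passes(label: Dsm5Label, p: CriteriaProfile,
                     record: PatientRecord) -> bool:
    if label is Dsm5Label.RAN:
        return _ran(p)
    if label is Dsm5Label.ANBP:
        return _anbp(p)
    if label is Dsm5Label.BN:
        return _bn(p)
    if label is Dsm5Label.BED:
        return _bed(p)
    if label is Dsm5Label.PD:
        return _pd(p, record.bmi)
    if label is Dsm5Label.AAN:
        return _aan(p)
    if label is Dsm5Label.SUBBN:
        return _subbn(p)
    if label is Dsm5Label.SUBBED:
        return _subbed(p)
    raise ValueError(f"not a formal category: {label}")


def meets_ednos_other(record: PatientRecord,
                      profile: CriteriaProfile | None = None) -> bool:
    """Minimal symptom rule: >=1 psychological symptom plus >=1 behavioral
    or physical symptom."""
    p = profile if profile is not None else evaluate_criteria(record)
    return p.met("ednos_psych") and (p.met("ednos_behavioral")
                                     or p.met("ednos_physical"))


def diagnose_dsm5(record: PatientRecord,
                  precedence: Sequence = DEFAULT_PRECEDENCE,
                  profile: CriteriaProfile | None = None) -> DiagnosisResult:
    """Assign the first passing formal category in ``precedence``, falling
    back to the unspecified residual (UFED) via the minimal symptom rule,
    else NONE. The trace records each category tried and its verdict."""
    prec = validate_precedence(precedence)
    p = profile if profile is not None else evaluate_criteria(record)
    trace = []
    for label in prec:
        verdict = _category_passes(label, p, record)
        trace.append((label.value, verdict))
        if verdict:
            return DiagnosisResult(label, trace, prec)
    if meets_ednos_other(record, p):
        trace.append((Dsm5Label.UFED.value, True))
        return DiagnosisResult(Dsm5Label.UFED, trace, prec)
    trace.append((Dsm5Label.NONE.value, True))
    return DiagnosisResult(Dsm5Label.NONE, trace, prec)


def diagnose_dsm4(record: PatientRecord,
                  profile: CriteriaProfile | None = None) -> Dsm4Label:
    """DSM-IV diagnosis at the interview's twice-weekly thresholds.

    AN additionally requires amenorrhea; EDNOS is the residual for records
    failing full thresholds while still meeting the minimal symptom rule.
    Used by remission logic and the questionnaire-fallback gate.
    """
    p = profile if profile is not None else evaluate_criteria(record)
    an4 = (p.met("low_weight") and p.met("amenorrhea")
           and p.met("weight_phobia")
           and (p.met("body_disturbance") or p.met("undue_influence")))
    if an4:
        if p.met("regular_binge_or_purge"):
            return Dsm4Label.AN_BP
        return Dsm4Label.AN_R
    bn4 = (p.met("regular_obe") and p.met("regular_compensation")
           and p.met("undue_influence"))
    if bn4:
        if p.met("regular_purging"):
            return Dsm4Label.BN_P
        return Dsm4Label.BN_NP
    # Residual: the minimal symptom rule, or the binge-eating presentation
    # (a canonical DSM-IV EDNOS example, which carries no cognitive
    # criterion of its own).
    bed_pattern = (p.met("regular_obe") and p.met("binge_distress")
                   and not p.met("regular_compensation"))
    if bed_pattern or meets_ednos_other(record, p):
        return Dsm4Label.EDNOS
    return Dsm4Label.NONE


def classify_remission(record: PatientRecord) -> bool:
    """Remitted iff the follow-up record meets neither any DSM-IV ED rule
    nor the minimal residual symptom rule."""
    if record.timepoint != MONTH12:
        raise ValueError("remission is defined on 12-month follow-up records")
    p = evaluate_criteria(record)
    return diagnose_dsm4(record, p) is Dsm4Label.NONE and not meets_ednos_other(record, p)


def precedence_sensitivity(cohort: Iterable[PatientRecord],
                           orderings: Sequence[Sequence]) -> pd.DataFrame:
    """Label counts per precedence ordering (rows: ordering as a '>'-joined
    string; columns: labels). Only overlap-eligible records change column;
    the diagnosed total is invariant."""
    orderings = [validate_precedence(o) for o in orderings]
    if not orderings:
        raise ValueError("need at least one ordering")
    cohort = list(cohort)
    profiles = [evaluate_criteria(r) for r in cohort]
    rows = {}
    cols = [l.value for l in Dsm5Label]
    for prec in orderings:
        counts = dict.fromkeys(cols, 0)
        for rec, prof in zip(cohort, profiles):
            res = diagnose_dsm5(rec, prec, profile=prof)
            counts[res.label.value] += 1
        rows[" > ".join(l.value for l in prec)] = counts
    return pd.DataFrame.from_dict(rows, orient="index")[cols]
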