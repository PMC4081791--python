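"""Synthetic item-level patient cohorts with recoverable ground truth.

Each latent diagnosis label has a noise-free prototype that satisfies
exactly its defining criteria; generation draws per-label anthropometrics,
scale scores (truncated normal, instrument ranges respected), behavior
presence (Bernoulli at the published per-group prevalence) with 28-day
counts (right-truncated Poisson), and comorbidity flags, then flips only
*non-defining* interview indicators with a small noise probability so the
diagnostic engine can recover the latent label exactly when noise is zero.

Counts for behaviors whose regularity a label's rule forbids (objective
binges for purging disorder; compensation for BED) are drawn below the
weekly questionnaire-fallback threshold — mirroring clinical reality, where
such groups report the behavior occasionally but not regularly, and keeping
ground truth recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from . import calibration as cal
from .labels import REMISSION, Dsm5Label
from .records import (BASELINE, MONTH12, AxisIFlags, EdeqItems,
                      InterviewItems, PatientRecord, ScaleScores)

LABEL_ORDER = tuple(cal.COHORT_COUNTS)          # fixed generation order

_ALL_REGULAR = ("regular_obe", "regular_sbe", "regular_vomiting",
                "regular_laxatives", "regular_diuretics", "regular_fasting",
                "regular_excess_exercise")

#: Per-label interview-flag policy: defining-true ("on"), defining-false
#: ("off"); everything else is free and eligible for noise flips.
FLAG_POLICY: dict[str, dict[str, tuple[str, ...]]] = {
    "RAN": {
        "on": ("weight_phobia", "body_disturbance", "regular_fasting",
               "amenorrhea"),
        "off": ("regular_obe", "regular_sbe", "regular_vomiting",
                "regular_laxatives", "regular_diuretics"),
    },
    "ANBP": {
        "on": ("weight_phobia", "body_disturbance", "regular_obe",
               "loss_of_control", "regular_vomiting", "amenorrhea"),
        "off": (),
    },
    "BN": {
        "on": ("regular_obe", "loss_of_control", "regular_vomiting",
               "undue_influence"),
        "off": ("amenorrhea",),
    },
    "BED": {
        "on": ("regular_obe", "loss_of_control", "binge_distress"),
        "off": ("regular_vomiting", "regular_laxatives", "regular_diuretics",
                "regular_fasting", "regular_excess_exercise", "amenorrhea"),
    },
    "AAN": {
        "on": ("weight_phobia", "body_disturbance", "regular_fasting"),
        "off": ("regular_obe", "regular_sbe", "regular_vomiting",
                "regular_laxatives", "regular_diuretics", "amenorrhea"),
    },
    "PD": {
        "on": ("regular_vomiting", "weight_phobia", "undue_influence"),
        "off": ("regular_obe", "amenorrhea"),
    },
    "SUBBN": {
        "on": ("loss_of_control", "undue_influence"),
        "off": _ALL_REGULAR + ("amenorrhea",),
    },
    "SUBBED": {
        "on": ("loss_of_control", "binge_distress"),
        "off": _ALL_REGULAR + ("amenorrhea",),
    },
    "UFED": {
        "on": ("weight_phobia", "loss_of_control"),
        "off": _ALL_REGULAR + ("amenorrhea",),
    },
}

#: Per-label behavior-count constraints: behaviors forced present (the
#: label's sub-threshold pattern requires >=1 episode), forced absent, and
#: count ceilings (3 = below the weekly fallback threshold; 1 for the 0-6
#: ordinal fasting item).
_SUB_WEEKLY = 3
COUNT_CONSTRAINTS: dict[str, dict] = {
    "PD": {"max": {"obe": _SUB_WEEKLY}},
    "BED": {"max": {"vomiting": _SUB_WEEKLY, "laxatives": _SUB_WEEKLY,
                    "diuretics": _SUB_WEEKLY, "exercise": _SUB_WEEKLY,
                    "fasting": 1}},
    "SUBBN": {"present": ("obe", "vomiting"),
              "max": {"obe": _SUB_WEEKLY, "vomiting": _SUB_WEEKLY,
                      "laxatives": _SUB_WEEKLY, "diuretics": _SUB_WEEKLY,
                      "exercise": _SUB_WEEKLY, "fasting": 1}},
    "SUBBED": {"present": ("obe",),
               "zero": ("vomiting", "laxatives", "diuretics", "exercise",
                        "fasting"),
               "max": {"obe": _SUB_WEEKLY}},
}


@dataclass(slots=True)
class LatentAssignment:
    """Ground truth for one patient: intake label and 12-month target."""

    patient_id: str
    true_label: str
    true_followup_label: str        # a label value or REMISSION


@dataclass(slots=True)
class CohortConfig:
    """Generative parameters; defaults reproduce the calibration cohort."""

    n_patients: int = 2233
    mixture: dict = field(default_factory=lambda: dict(cal.DEFAULT_MIXTURE))
    score_params: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in cal.SCORE_PARAMS.items()})
    bmi_params: dict = field(default_factory=lambda: dict(cal.BMI_PARAMS))
    age_params: dict = field(default_factory=lambda: dict(cal.AGE_PARAMS))
    behavior_prevalence: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in cal.BEHAVIOR_PREVALENCE.items()})
    freq_params: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in cal.FREQ_PARAMS.items()})
    comorbidity: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in cal.COMORBIDITY.items()})
    transition: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in cal.DEFAULT_TRANSITION.items()})
    noise: float = 0.05
    retention: float = 1.0
    freq_cap: int = 56              # 28-day ceiling (2 episodes/day)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        known = set(LABEL_ORDER)
        unknown = set(self.mixture) - known
        if unknown:
            raise ValueError(f"unknown labels in mixture: {sorted(unknown)}")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture must sum to 1, got {total!r}")
        if any(p < 0 or p > 1 for p in self.mixture.values()):
            raise ValueError("mixture proportions must lie in [0, 1]")
        for row, cells in self.transition.items():
            s = sum(cells.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"transition row {row} sums to {s!r}, not 1")
            if any(p < 0 or p > 1 for p in cells.values()):
                raise ValueError(f"transition row {row} has invalid probability")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be a probability")
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError("retention must be a fraction in [0, 1]")
        for label, scales in self.score_params.items():
            for scale, (_, sd) in scales.items():
                if sd < 0:
                    raise ValueError(f"negative sd for {label}/{scale}")

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd <= 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def prototype_record(label, patient_id: str = "proto",
                     timepoint: str = BASELINE) -> PatientRecord:
    """Deterministic noise-free record satisfying exactly the defining
    criteria of ``label`` (purging-disorder prototypes also satisfy the
    atypical-AN pattern, so precedence decides between them)."""
    label = Dsm5Label(label)
    if label is Dsm5Label.NONE:
        raise ValueError("no prototype for NONE")
    name = label.value
    policy = FLAG_POLICY[name]
    iv = InterviewItems(**{f: True for f in policy["on"]})
    edeq = EdeqItems(global_score=cal.SCORE_PARAMS[name]["edeq_global"][0])
    cons = COUNT_CONSTRAINTS.get(name, {})
    for b in cons.get("present", ()):
        setattr(edeq, "fasting_score" if b == "fasting" else _FREQ_FIELD[b], 2)
    mean_bmi = float(np.clip(cal.BMI_PARAMS[name][0], *cal.BMI_BOUNDS[name]))
    sc = cal.SCORE_PARAMS[name]
    scales = ScaleScores(cia=sc["cia"][0], cprs=sc["cprs"][0],
                         sasb_affiliation=sc["sasb_affiliation"][0],
                         sasb_self_emancipation=sc["sasb_self_emancipation"][0],
                         sasb_self_control=sc["sasb_self_control"][0])
    return PatientRecord(patient_id=patient_id, timepoint=timepoint,
                         bmi=mean_bmi, age=cal.AGE_PARAMS[name][0],
                         interview=iv, edeq=edeq, scales=scales)


_FREQ_FIELD = {"obe": "obe_freq", "sbe": "sbe_freq", "vomiting": "vomit_freq",
               "laxatives": "laxative_freq", "diuretics": "diuretic_freq",
               "exercise": "exercise_freq"}


def _generate_block(label: str, ids, config: CohortConfig, rng,
                    timepoint: str):
    """Vectorized generation of all records sharing one latent label."""
    m = len(ids)
    policy = FLAG_POLICY[label]
    cons = COUNT_CONSTRAINTS.get(label, {})
    free = [f for f in InterviewItems.__dataclass_fields__
            if f not in policy["on"] and f not in policy["off"]]

    bmi = _truncnorm(rng, *config.bmi_params[label],
                     *cal.BMI_BOUNDS[label], m)
    age = _truncnorm(rng, *config.age_params[label], 18.0, 67.0, m)

    scores = {}
    for scale, (mean, sd) in config.score_params[label].items():
        lo, hi = cal.SCALE_BOUNDS[scale]
        scores[scale] = _truncnorm(rng, mean, sd, lo, hi, m)
    subscales = {
        s: np.clip(scores["edeq_global"] + rng.normal(0.0, 0.5, m), 0.0, 6.0)
        for s in ("restraint", "eating_concern", "shape_concern",
                  "weight_concern")
    }

    counts = {}
    for b in cal.BEHAVIORS:
        if b in cons.get("zero", ()):
            counts[b] = np.zeros(m, dtype=int)
            continue
        if b in cons.get("present", ()):
            present = np.ones(m, dtype=bool)
        else:
            present = rng.random(m) < config.behavior_prevalence[label][b]
        hi = cons.get("max", {}).get(b, 6 if b == "fasting" else config.freq_cap)
        draw = rng.poisson(config.freq_params[label][b], m)
        counts[b] = np.where(present, np.clip(draw, 1, hi), 0)

    flips = rng.random((m, len(free))) < config.noise
    com = {c: rng.random(m) < config.comorbidity[label][c]
           for c in ("mood", "anxiety", "substance")}

    records = []
    base_flags = {f: True for f in policy["on"]}
    for i, pid in enumerate(ids):
        flags = dict(base_flags)
        for j, f in enumerate(free):
            if flips[i, j]:
                flags[f] = True
        iv = InterviewItems(**flags)
        edeq = EdeqItems(
            obe_freq=int(counts["obe"][i]), sbe_freq=int(counts["sbe"][i]),
            vomit_freq=int(counts["vomiting"][i]),
            laxative_freq=int(counts["laxatives"][i]),
            diuretic_freq=int(counts["diuretics"][i]),
            exercise_freq=int(counts["exercise"][i]),
            fasting_score=int(counts["fasting"][i]),
            restraint=float(subscales["restraint"][i]),
            eating_concern=float(subscales["eating_concern"][i]),
            shape_concern=float(subscales["shape_concern"][i]),
            weight_concern=float(subscales["weight_concern"][i]),
            global_score=float(scores["edeq_global"][i]))
        sc = ScaleScores(
            cia=float(scores["cia"][i]), cprs=float(scores["cprs"][i]),
            sasb_affiliation=float(scores["sasb_affiliation"][i]),
            sasb_self_emancipation=float(scores["sasb_self_emancipation"][i]),
            sasb_self_control=float(scores["sasb_self_control"][i]))
        records.append(PatientRecord(
            patient_id=pid, timepoint=timepoint, bmi=float(bmi[i]),
            age=float(age[i]), interview=iv, edeq=edeq, scales=sc,
            comorbidity=AxisIFlags(mood=bool(com["mood"][i]),
                                   anxiety=bool(com["anxiety"][i]),
                                   substance=bool(com["substance"][i]))))
    return records


def _remitted_block(ids, baseline_by_id, rng):
    """Follow-up records with full remission: no interview symptoms, no
    behavior episodes, normal weight, low residual scores."""
    m = len(ids)
    bmi = _truncnorm(rng, 22.0, 2.0, 18.6, 30.0, m)
    scores = {s: _truncnorm(rng, mean, sd, *cal.SCALE_BOUNDS[s], m)
              for s, (mean, sd) in cal.REMITTED_SCORE_PARAMS.items()}
    sub = {s: np.clip(scores["edeq_global"] + rng.normal(0.0, 0.3, m), 0, 6)
           for s in ("restraint", "eating_concern", "shape_concern",
                     "weight_concern")}
    out = []
    for i, pid in enumerate(ids):
        base = baseline_by_id[pid]
        edeq = EdeqItems(
            restraint=float(sub["restraint"][i]),
            eating_concern=float(sub["eating_concern"][i]),
            shape_concern=float(sub["shape_concern"][i]),
            weight_concern=float(sub["weight_concern"][i]),
            global_score=float(scores["edeq_global"][i]))
        sc = ScaleScores(
            cia=float(scores["cia"][i]), cprs=float(scores["cprs"][i]),
            sasb_affiliation=float(scores["sasb_affiliation"][i]),
            sasb_self_emancipation=float(scores["sasb_self_emancipation"][i]),
            sasb_self_control=float(scores["sasb_self_control"][i]))
        out.append(PatientRecord(
            patient_id=pid, timepoint=MONTH12, bmi=float(bmi[i]),
            age=base.age + 1.0, interview=InterviewItems(), edeq=edeq,
            scales=sc, comorbidity=replace(base.comorbidity)))
    return out


def generate_cohort(config: CohortConfig):
    """Generate a baseline cohort plus latent ground truth.

    Returns ``(records, truths)`` with one entry per patient; records carry
    no label field. A fixed seed yields byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = [l for l in LABEL_ORDER if config.mixture.get(l, 0.0) > 0]
    probs = np.array([config.mixture[l] for l in labels])
    probs = probs / probs.sum()
    draw = rng.choice(len(labels), size=config.n_patients, p=probs)

    width = len(str(config.n_patients))
    ids = [f"P{i:0{width}d}" for i in range(config.n_patients)]

    # Follow-up targets drawn label-by-label from the transition rows.
    followup = [None] * config.n_patients
    for li, label in enumerate(labels):
        idx = np.flatnonzero(draw == li)
        if idx.size == 0:
            continue
        if label not in config.transition:
            raise KeyError(f"transition row missing for label {label}")
        row = config.transition[label]
        cols = list(row)
        targets = rng.choice(len(cols), size=idx.size,
                             p=np.array([row[c] for c in cols]))
        for j, t in zip(idx, targets):
            followup[j] = cols[t]

    records_by_id = {}
    for li, label in enumerate(labels):
        idx = np.flatnonzero(draw == li)
        if idx.size == 0:
            continue
        block = _generate_block(label, [ids[i] for i in idx], config, rng,
                                BASELINE)
        for rec in block:
            records_by_id[rec.patient_id] = rec

    records = [records_by_id[pid] for pid in ids]
    truths = [LatentAssignment(ids[i], labels[draw[i]], followup[i])
              for i in range(config.n_patients)]
    return records, truths


def generate_followup(cohort, truth, config: CohortConfig):
    """Materialize 12-month records from each patient's latent follow-up
    target, with missing-completely-at-random attrition at
    ``1 - config.retention``."""
    by_id = {r.patient_id: r for r in cohort}
    for t in truth:
        if t.patient_id not in by_id:
            raise KeyError(f"truth/cohort mismatch: {t.patient_id}")
    rng = np.random.default_rng([config.seed, 1])
    retained = [t for t in truth
                if config.retention >= 1.0 or rng.random() < config.retention]

    targets: dict[str, list[str]] = {}
    for t in retained:
        if t.true_followup_label != REMISSION \
                and t.true_followup_label not in FLAG_POLICY:
            raise KeyError(
                f"transition target unknown: {t.true_followup_label}")
        targets.setdefault(t.true_followup_label, []).append(t.patient_id)

    out_by_id = {}
    for target in list(cal.TRANSITION_COLUMNS) + ["SUBBN", "SUBBED"]:
        pids = targets.get(target, [])
        if not pids:
            continue
        if target == REMISSION:
            block = _remitted_block(pids, by_id, rng)
        else:
            block = _generate_block(target, pids, config, rng, MONTH12)
            for rec in block:
                rec.age = by_id[rec.patient_id].age + 1.0
        for rec in block:
            out_by_id[rec.patient_id] = rec
    return [out_by_id[t.patient_id] for t in retained]
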