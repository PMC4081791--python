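"""Published summary statistics of a large specialist-care adult female
eating-disorder cohort (N=2233 at intake, 530 with complete 12-month
follow-up), used as the generative calibration of the synthetic cohort and
as inputs to the reproduction utilities.

All structures are plain dicts keyed by DSM-5 label value so they can be
serialized into configs. The sub-threshold BED group (11 cases) has no
published scale/behavior rows of its own and reuses the BED parameters;
sub-threshold BN was absent from the cohort and gets zero mixture mass but
full generator support.
"""

from __future__ import annotations

from .labels import Dsm5Label as L
from .labels import REMISSION

# --- Intake diagnosis distribution (counts) -------------------------------
COHORT_COUNTS: dict[str, int] = {
    "RAN": 364, "ANBP": 295, "BN": 874, "BED": 124,
    "AAN": 310, "SUBBN": 0, "SUBBED": 11, "PD": 184, "UFED": 71,
}
COHORT_N = sum(COHORT_COUNTS.values())            # 2233

DEFAULT_MIXTURE: dict[str, float] = {
    k: v / COHORT_N for k, v in COHORT_COUNTS.items()
}

# --- Anthropometrics / age per group: (mean, sd) --------------------------
BMI_PARAMS: dict[str, tuple[float, float]] = {
    "RAN": (16.1, 1.6), "ANBP": (16.8, 1.4), "BN": (23.6, 4.3),
    "BED": (31.4, 7.7), "AAN": (22.7, 4.5), "SUBBN": (23.6, 4.3),
    "SUBBED": (30.2, 7.6), "PD": (21.9, 3.5), "UFED": (19.9, 6.7),
}
AGE_PARAMS: dict[str, tuple[float, float]] = {
    "RAN": (23.2, 6.6), "ANBP": (24.3, 7.1), "BN": (26.4, 8.0),
    "BED": (30.2, 10.2), "AAN": (26.0, 7.0), "SUBBN": (26.4, 8.0),
    "SUBBED": (34.4, 13.2), "PD": (25.4, 7.9), "UFED": (26.1, 9.1),
}

# BMI truncation bounds keeping each label's anthropometric gate satisfied.
BMI_BOUNDS: dict[str, tuple[float, float]] = {
    "RAN": (12.0, 18.4), "ANBP": (12.0, 18.4),
    "BN": (18.6, 50.0), "BED": (18.6, 55.0), "AAN": (18.6, 50.0),
    "SUBBN": (18.6, 50.0), "SUBBED": (18.6, 55.0), "PD": (18.6, 45.0),
    "UFED": (14.0, 50.0),
}

# --- Scale scores per group: (mean, sd) ------------------------------------
SCALES = ("edeq_global", "cia", "cprs", "sasb_affiliation",
          "sasb_self_emancipation", "sasb_self_control")

_T2 = {
    #           edeqG          cia           cprs         affil           emanc          control
    "RAN":    ((3.38, 1.36), (29.07, 11.4), (1.14, .51), (-10.98, 37.2), (30.4, 15.6), (62.1, 18.3)),
    "ANBP":   ((4.18, 1.18), (33.61, 9.9),  (1.34, .52), (-28.3, 31.4),  (31.2, 17.0), (59.8, 17.2)),
    "BN":     ((4.20, 0.95), (30.51, 9.3),  (1.14, .47), (-16.9, 33.0),  (32.0, 15.4), (54.8, 18.5)),
    "BED":    ((3.67, 1.08), (29.82, 9.2),  (1.14, .39), (-21.4, 33.4),  (35.1, 17.1), (49.5, 20.8)),
    "AAN":    ((3.64, 1.16), (26.39, 10.5), (1.08, .49), (-11.1, 35.2),  (31.2, 15.3), (57.0, 17.9)),
    "PD":     ((4.09, 0.97), (28.41, 9.5),  (1.14, .49), (-16.0, 34.5),  (30.6, 14.2), (53.7, 18.9)),
    "UFED":   ((1.72, 1.22), (19.19, 11.6), (0.76, .50), (17.3, 41.6),   (38.6, 18.6), (52.5, 19.7)),
}
_T2["SUBBED"] = _T2["BED"]
_T2["SUBBN"] = _T2["BN"]

SCORE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    label: dict(zip(SCALES, rows)) for label, rows in _T2.items()
}

# Instrument ranges used to truncate score draws.
SCALE_BOUNDS: dict[str, tuple[float, float]] = {
    "edeq_global": (0.0, 6.0), "cia": (0.0, 48.0), "cprs": (0.0, 3.0),
    "sasb_affiliation": (-100.0, 100.0),
    "sasb_self_emancipation": (0.0, 100.0),
    "sasb_self_control": (0.0, 100.0),
}

# Post-remission score levels (low residual pathology; a generator choice,
# no published per-scale remitted means exist).
REMITTED_SCORE_PARAMS: dict[str, tuple[float, float]] = {
    "edeq_global": (0.9, 0.7), "cia": (8.0, 6.0), "cprs": (0.4, 0.3),
    "sasb_affiliation": (25.0, 30.0), "sasb_self_emancipation": (33.0, 15.0),
    "sasb_self_control": (45.0, 18.0),
}

# --- Questionnaire behavior prevalences (% reporting >=1 episode/28 days) --
BEHAVIORS = ("obe", "sbe", "vomiting", "laxatives", "diuretics",
             "exercise", "fasting")

_T3_PREV = {
    #          obe  sbe  vom  lax  diu  exe  fast
    "RAN":    (25, 59, 7, 2, 1, 43, 58),
    "ANBP":   (55, 70, 78, 20, 10, 51, 77),
    "BN":     (74, 60, 71, 16, 5, 54, 66),
    "BED":    (83, 36, 6, 2, 1, 11, 36),
    "AAN":    (47, 58, 22, 2, 3, 49, 58),
    "PD":     (38, 66, 82, 18, 7, 55, 70),
    "UFED":   (34, 23, 30, 1, 1, 18, 18),
}
_T3_PREV["SUBBED"] = _T3_PREV["BED"]
_T3_PREV["SUBBN"] = (50, 60, 40, 10, 3, 50, 60)   # no published row

BEHAVIOR_PREVALENCE: dict[str, dict[str, float]] = {
    label: {b: v / 100.0 for b, v in zip(BEHAVIORS, row)}
    for label, row in _T3_PREV.items()
}

# --- Mean 28-day frequencies among reporters -------------------------------
# Missing published cells (UFED diuretics; single-case cells) filled with a
# small plausible mean of 2.0. The fasting entry is the 0-6 ordinal item.
_T4_FREQ = {
    "RAN":    (7.8, 11.3, 3.0, 2.0, 2.5, 15.9, 1.79),
    "ANBP":   (14.0, 12.0, 23.8, 9.6, 11.2, 15.7, 2.69),
    "BN":     (12.7, 10.9, 20.0, 11.5, 12.7, 13.2, 1.76),
    "BED":    (14.6, 11.3, 3.3, 1.0, 2.0, 6.7, 0.69),
    "AAN":    (8.1, 9.8, 15.1, 4.8, 4.6, 15.5, 1.68),
    "PD":     (8.8, 9.8, 14.0, 8.3, 10.4, 14.8, 2.10),
    "UFED":   (5.3, 6.1, 12.2, 4.0, 2.0, 14.3, 0.38),
}
_T4_FREQ["SUBBED"] = _T4_FREQ["BED"]
_T4_FREQ["SUBBN"] = (2.0, 8.0, 2.0, 2.0, 2.0, 10.0, 1.5)

FREQ_PARAMS: dict[str, dict[str, float]] = {
    label: dict(zip(BEHAVIORS, row)) for label, row in _T4_FREQ.items()
}

# --- Axis-I comorbidity prevalences ---------------------------------------
_T5 = {
    #          mood anx subst  (percent)
    "RAN":    (29, 13, 4),
    "ANBP":   (47, 18, 11),
    "BN":     (48, 16, 14),
    "BED":    (57, 17, 15),
    "AAN":    (37, 16, 10),
    "PD":     (36, 19, 11),
    "UFED":   (15, 8, 8),
}
_T5["SUBBED"] = _T5["BED"]
_T5["SUBBN"] = _T5["BN"]

COMORBIDITY: dict[str, dict[str, float]] = {
    label: {"mood": m / 100.0, "anxiety": a / 100.0, "substance": s / 100.0}
    for label, (m, a, s) in _T5.items()
}

# --- 12-month transition counts (rows: intake label; cols incl. remission) -
TRANSITION_COLUMNS = ("RAN", "ANBP", "BN", "BED", "AAN", "PD", "UFED",
                      REMISSION)
TRANSITION_COUNTS: dict[str, tuple[int, ...]] = {
    "RAN":  (29, 2, 2, 0, 17, 0, 18, 34),     # 102
    "ANBP": (6, 13, 6, 0, 7, 5, 11, 19),      # 67
    "BN":   (1, 3, 42, 2, 20, 5, 54, 92),     # 219
    "BED":  (0, 0, 4, 3, 2, 0, 6, 7),         # 22
    "AAN":  (0, 1, 6, 0, 13, 4, 14, 31),      # 69
    "PD":   (1, 1, 2, 0, 4, 6, 8, 17),        # 39
    "UFED": (1, 0, 1, 0, 0, 0, 4, 6),         # 12
}
TRANSITION_COUNTS["SUBBED"] = TRANSITION_COUNTS["BED"]   # no published row
TRANSITION_COUNTS["SUBBN"] = TRANSITION_COUNTS["BN"]

DEFAULT_TRANSITION: dict[str, dict[str, float]] = {
    row: {col: c / sum(counts) for col, c in zip(TRANSITION_COLUMNS, counts)}
    for row, counts in TRANSITION_COUNTS.items()
}

# --- Published categorical test inputs -------------------------------------
# Behavior presence counts with full-sample group denominators; some groups
# are excluded from a behavior's comparison when the behavior is definitional
# for (or incompatible with) the diagnosis.
BEHAVIOR_TEST_GROUPS: dict[str, tuple[str, ...]] = {
    "obe": ("ANBP", "BN", "BED", "AAN", "UFED"),
    "vomiting": ("ANBP", "BN", "AAN", "PD", "UFED"),
    "laxatives": ("ANBP", "BN", "AAN", "PD", "UFED"),
    "diuretics": ("ANBP", "BN", "AAN", "PD", "UFED"),
}
BEHAVIOR_YES_COUNTS: dict[str, dict[str, int]] = {
    "obe": {"RAN": 93, "ANBP": 163, "BN": 646, "BED": 103, "AAN": 146,
            "PD": 70, "UFED": 24},
    "vomiting": {"RAN": 27, "ANBP": 230, "BN": 621, "BED": 8, "AAN": 67,
                 "PD": 150, "UFED": 21},
    "laxatives": {"RAN": 8, "ANBP": 60, "BN": 138, "BED": 2, "AAN": 5,
                  "PD": 33, "UFED": 1},
    "diuretics": {"RAN": 4, "ANBP": 29, "BN": 46, "BED": 1, "AAN": 9,
                  "PD": 12, "UFED": 1},
}
COMORBIDITY_TEST_GROUPS = ("RAN", "ANBP", "BN", "BED", "AAN", "PD", "UFED")
COMORBIDITY_YES_COUNTS: dict[str, dict[str, int]] = {
    "mood": {"RAN": 104, "ANBP": 138, "BN": 417, "BED": 71, "AAN": 116,
             "PD": 66, "UFED": 11},
    "substance": {"RAN": 13, "ANBP": 31, "BN": 120, "BED": 19, "AAN": 32,
                  "PD": 21, "UFED": 6},
}
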