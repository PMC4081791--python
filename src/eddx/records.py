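"""Patient record model: one assessment of one adult patient.

The record mirrors the item-level data sources of a specialist
eating-disorder intake battery: a structured clinical interview (boolean
"regular behavior" and cognitive-criterion indicators, DSM-IV thresholded),
a self-report questionnaire with 28-day behavior frequency counts and 0-6
attitudinal subscales, anthropometrics, broadband symptom scales, and
Axis-I comorbidity screens. Instrument administration and psychometrics are
out of scope; the fields are the engine's input contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

BASELINE = "baseline"
MONTH12 = "month12"
TIMEPOINTS = (BASELINE, MONTH12)


@dataclass(slots=True)
class InterviewItems:
    """Interview indicators. ``regular_*`` flags encode the interview's own
    frequency threshold (at least twice weekly for three months)."""

    regular_obe: bool = False
    regular_sbe: bool = False
    loss_of_control: bool = False
    regular_vomiting: bool = False
    regular_laxatives: bool = False
    regular_diuretics: bool = False
    regular_fasting: bool = False
    regular_excess_exercise: bool = False
    weight_phobia: bool = False
    undue_influence: bool = False
    body_disturbance: bool = False
    denial_of_seriousness: bool = False
    amenorrhea: bool = False
    binge_distress: bool = False


INTERVIEW_FLAGS = tuple(f.name for f in fields(InterviewItems))

#: The four cognitive/psychological symptoms of the minimal residual rule.
PSYCH_FLAGS = ("weight_phobia", "undue_influence", "body_disturbance",
               "denial_of_seriousness")


@dataclass(slots=True)
class EdeqItems:
    """Questionnaire behavior counts over the last 28 days plus subscales."""

    obe_freq: int = 0
    sbe_freq: int = 0
    vomit_freq: int = 0
    laxative_freq: int = 0
    diuretic_freq: int = 0
    exercise_freq: int = 0
    fasting_score: int = 0          # ordinal 0-6 days-band item
    restraint: float = 0.0
    eating_concern: float = 0.0
    shape_concern: float = 0.0
    weight_concern: float = 0.0
    global_score: float = 0.0

    def __post_init__(self) -> None:
        for name in ("obe_freq", "sbe_freq", "vomit_freq", "laxative_freq",
                     "diuretic_freq", "exercise_freq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a non-negative count")
        if not 0 <= self.fasting_score <= 6:
            raise ValueError("fasting_score must be in 0..6")
        for name in ("restraint", "eating_concern", "shape_concern",
                     "weight_concern", "global_score"):
            if not 0.0 <= getattr(self, name) <= 6.0:
                raise ValueError(f"{name} must be in [0, 6]")


@dataclass(slots=True)
class ScaleScores:
    """Broadband scale scores: impairment (0-48), psychiatric distress index
    (0-3), and three self-image dimensions."""

    cia: float = 0.0
    cprs: float = 0.0
    sasb_affiliation: float = 0.0
    sasb_self_emancipation: float = 0.0
    sasb_self_control: float = 0.0


@dataclass(slots=True)
class AxisIFlags:
    mood: bool = False
    anxiety: bool = False
    substance: bool = False


@dataclass(slots=True)
class PatientRecord:
    patient_id: str
    timepoint: str = BASELINE
    bmi: float = 22.0
    age: float = 25.0
    interview: InterviewItems = field(default_factory=InterviewItems)
    edeq: EdeqItems = field(default_factory=EdeqItems)
    scales: ScaleScores = field(default_factory=ScaleScores)
    comorbidity: AxisIFlags = field(default_factory=AxisIFlags)

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        if not self.bmi > 0:
            raise ValueError("bmi must be positive")
        if self.age < 18:
            raise ValueError("cohort is adult: age must be >= 18")
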