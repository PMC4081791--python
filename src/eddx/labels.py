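"""Closed label sets for the diagnostic engine.

DSM-5 labels follow the operationalization used throughout the package:
full-syndrome anorexia nervosa restrictive (RAN) and binge/purge (ANBP)
subtypes, bulimia nervosa (BN), binge eating disorder (BED), then the
OSFED sub-categories — atypical AN (AAN), sub-threshold BN/BED (SUBBN,
SUBBED), purging disorder (PD) — the unspecified residual (UFED), and
NONE for records meeting no rule at all.
"""

from __future__ import annotations

from enum import Enum


class Dsm5Label(str, Enum):
    RAN = "RAN"
    ANBP = "ANBP"
    BN = "BN"
    BED = "BED"
    AAN = "AAN"
    SUBBN = "SUBBN"
    SUBBED = "SUBBED"
    PD = "PD"
    UFED = "UFED"
    NONE = "NONE"


class Dsm4Label(str, Enum):
    AN_R = "AN-R"
    AN_BP = "AN-BP"
    BN_P = "BN-P"
    BN_NP = "BN-NP"
    EDNOS = "EDNOS"
    NONE = "NONE"


#: Formal DSM-5 categories a precedence ordering permutes (UFED/NONE are
#: residuals and never part of the ordering).
FORMAL_LABELS: tuple[Dsm5Label, ...] = (
    Dsm5Label.RAN,
    Dsm5Label.ANBP,
    Dsm5Label.BN,
    Dsm5Label.BED,
    Dsm5Label.AAN,
    Dsm5Label.SUBBN,
    Dsm5Label.SUBBED,
    Dsm5Label.PD,
)

#: Default category precedence: the ordering that maximizes the purging
#: disorder group (PD tried before atypical AN), with AN always trumping BN.
DEFAULT_PRECEDENCE: tuple[Dsm5Label, ...] = (
    Dsm5Label.RAN,
    Dsm5Label.ANBP,
    Dsm5Label.BN,
    Dsm5Label.BED,
    Dsm5Label.PD,
    Dsm5Label.AAN,
    Dsm5Label.SUBBN,
    Dsm5Label.SUBBED,
)

#: Sentinel used in transition matrices / follow-up tables for full remission.
REMISSION = "REMISSION"

#: OSFED umbrella members used for composition arithmetic. The unspecified
#: residual is counted in the denominator: the cohort splits into full
#: syndromes (RAN/ANBP/BN/BED) versus everything sub-threshold or residual.
OSFED_LABELS: tuple[Dsm5Label, ...] = (
    Dsm5Label.AAN,
    Dsm5Label.SUBBN,
    Dsm5Label.SUBBED,
    Dsm5Label.PD,
    Dsm5Label.UFED,
)


def validate_precedence(precedence) -> tuple[Dsm5Label, ...]:
    """Validate a category ordering.

    Must be a permutation of the eight formal labels with both AN subtypes
    tried before BN (the AN-trumps-BN convention is structural, not a free
    choice).
    """
    prec = tuple(Dsm5Label(p) for p in precedence)
    if sorted(p.value for p in prec) != sorted(l.value for l in FORMAL_LABELS):
        raise ValueError(
            "precedence must be a permutation of the formal DSM-5 labels, got "
            f"{[p.value for p in prec]}"
        )
    bn = prec.index(Dsm5Label.BN)
    if prec.index(Dsm5Label.RAN) > bn or prec.index(Dsm5Label.ANBP) > bn:
        raise ValueError("AN subtypes must precede BN in any valid precedence")
    return prec
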