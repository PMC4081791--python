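"""Diagnosis distribution, 12-month cross-over/stability, remission rates,
and migration summaries.

Percentages are rounded half-up for display; machine output keeps raw
proportions. The residual-category share arithmetic treats the whole
non-full-syndrome remainder (atypical AN, sub-threshold BN/BED, purging
disorder, and the unspecified residual) as one denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .labels import OSFED_LABELS, REMISSION, Dsm5Label


def round_half_up(x: float, digits: int = 0) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(slots=True)
class TransitionTable:
    """Counts of intake label (rows) by follow-up outcome (columns,
    including a remission column)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if REMISSION not in self.counts.columns:
            raise ValueError("transition table needs a remission column")

    @classmethod
    def from_counts(cls, counts: dict, columns) -> "TransitionTable":
        df = pd.DataFrame.from_dict(counts, orient="index",
                                    columns=list(columns))
        return cls(df.astype(int))

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.values.sum())

    @property
    def row_percent(self) -> pd.DataFrame:
        return self.counts.div(self.row_totals, axis=0) * 100.0

    def stability(self) -> pd.Series:
        """Diagonal proportion per row (%): same label at both timepoints."""
        diag = pd.Series(
            [self.counts.at[r, r] if r in self.counts.columns else 0
             for r in self.counts.index], index=self.counts.index)
        return diag / self.row_totals * 100.0


@dataclass(slots=True)
class MigrationSummary:
    per_label_pct: dict
    excluded: frozenset
    mean_pct: float
    min_pct: float
    max_pct: float


def crossover_table(baseline_labels, followup_outcomes) -> TransitionTable:
    """Build the cross-over table from per-patient intake labels and
    follow-up outcomes (a label value, or the remission sentinel for
    patients remitted per the remission rule). Patients without follow-up
    are simply absent from ``followup_outcomes``."""
    missing = set(followup_outcomes) - set(baseline_labels)
    if missing:
        raise KeyError(f"follow-up ids not in baseline: {sorted(missing)[:5]}")
    rows = sorted({str(v) for v in baseline_labels.values()})
    cols = [l.value for l in Dsm5Label if l not in (Dsm5Label.NONE,)]
    cols.append(REMISSION)
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for pid, outcome in followup_outcomes.items():
        counts.at[str(baseline_labels[pid]), str(outcome)] += 1
    counts = counts.loc[counts.sum(axis=1) > 0]
    return TransitionTable(counts)


def remission_rates(table: TransitionTable):
    """Per-label and overall remission percentages (display-rounded),
    alongside raw proportions."""
    totals = table.row_totals
    if (totals == 0).any():
        raise ValueError("empty row in transition table")
    if table.grand_total == 0:
        raise ValueError("empty cohort")
    raw = table.counts[REMISSION] / totals
    overall = table.counts[REMISSION].sum() / table.grand_total
    pct = raw.map(lambda v: round_half_up(100.0 * v))
    return pd.DataFrame({"proportion": raw, "percent": pct}), overall


def migration_summary(table: TransitionTable,
                      excluded=(Dsm5Label.UFED, Dsm5Label.AAN)
                      ) -> MigrationSummary:
    """Per-row percentage of patients whose follow-up label is a diagnosis
    different from baseline and not in ``excluded``; the summary mean is
    the unweighted average across rows."""
    excluded = frozenset(e.value if isinstance(e, Dsm5Label) else str(e)
                         for e in excluded)
    dx_cols = [c for c in table.counts.columns if c != REMISSION]
    if not set(dx_cols) - excluded:
        raise ValueError("every diagnosis column excluded")
    per = {}
    for row in table.counts.index:
        moved = sum(int(table.counts.at[row, c]) for c in dx_cols
                    if c != row and c not in excluded)
        per[row] = 100.0 * moved / int(table.row_totals[row])
    vals = np.array(list(per.values()))
    return MigrationSummary(per, excluded, float(vals.mean()),
                            float(vals.min()), float(vals.max()))


@dataclass(slots=True)
class OsfedComposition:
    pd_cohort_share: float          # proportion of the whole cohort
    pd_osfed_share: float           # proportion of the residual umbrella
    top3_osfed_share: float         # PD + atypical AN + sub-BED share
    osfed_total: int
    cohort_total: int


def osfed_composition(distribution) -> OsfedComposition:
    """Composition of the residual ("other/unspecified") umbrella from a
    label -> count distribution over the closed label set."""
    counts = {Dsm5Label(k).value if not isinstance(k, str) else str(k): int(v)
              for k, v in dict(distribution).items()}
    cohort = sum(counts.values())
    osfed = sum(counts.get(l.value, 0) for l in OSFED_LABELS)
    if osfed == 0:
        raise ValueError("empty OSFED denominator")
    pd_n = counts.get(Dsm5Label.PD.value, 0)
    top3 = pd_n + counts.get(Dsm5Label.AAN.value, 0) \
        + counts.get(Dsm5Label.SUBBED.value, 0)
    return OsfedComposition(pd_n / cohort, pd_n / osfed, top3 / osfed,
                            osfed, cohort)
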