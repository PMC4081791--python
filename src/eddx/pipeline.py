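"""End-to-end pipeline: generate -> diagnose -> clean -> compare ->
longitudinal, with bit-stable report bundles, plus the recomputation of
every published-table quantity the package is calibrated against."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from .cohort import CohortConfig, generate_cohort, generate_followup
from .engine import classify_remission, diagnose_dsm5
from .io import write_cohort, write_truth
from .labels import DEFAULT_PRECEDENCE, REMISSION, validate_precedence
from .longitudinal import (TransitionTable, crossover_table,
                           migration_summary, osfed_composition,
                           remission_rates, round_half_up)
from .records import MONTH12
from .stats import (cap_and_gap_delete, chi_square, gated_contrasts,
                    select_omnibus)

#: Pre-defined plausible 28-day maxima for behavior-frequency items.
DEFAULT_CAPS: dict[str, float] = {
    "obe_freq": 56, "sbe_freq": 56, "vomit_freq": 84,
    "laxative_freq": 56, "diuretic_freq": 56, "exercise_freq": 56,
}

_BEHAVIOR_FIELD = {"obe": "obe_freq", "sbe": "sbe_freq",
                   "vomiting": "vomit_freq", "laxatives": "laxative_freq",
                   "diuretics": "diuretic_freq", "exercise": "exercise_freq"}
_SCALE_ATTR = {"edeq_global": ("edeq", "global_score"),
               "cia": ("scales", "cia"), "cprs": ("scales", "cprs"),
               "sasb_affiliation": ("scales", "sasb_affiliation"),
               "sasb_self_emancipation": ("scales", "sasb_self_emancipation"),
               "sasb_self_control": ("scales", "sasb_self_control")}


@dataclass(slots=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    precedence: tuple = DEFAULT_PRECEDENCE
    outdir: str = "eddx_reports"
    outlier_caps: dict = field(default_factory=lambda: dict(DEFAULT_CAPS))
    omnibus_alpha: float = 0.01
    categorical_alpha: float = 0.001
    gate_p: float = 0.01
    gate_d: float = 0.50

    def __post_init__(self) -> None:
        self.precedence = validate_precedence(self.precedence)
        for a in (self.omnibus_alpha, self.categorical_alpha):
            if not 0 < a < 1:
                raise ValueError("alpha levels must lie in (0, 1)")
        if self.gate_p <= 0 or self.gate_d <= 0:
            raise ValueError("gate thresholds must be positive")
        for k, v in self.outlier_caps.items():
            if v <= 0:
                raise ValueError(f"outlier cap for {k} must be positive")


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(
        {"cohort": config.cohort.to_dict(),
         "precedence": [p.value for p in config.precedence],
         "caps": config.outlier_caps,
         "alphas": [config.omnibus_alpha, config.categorical_alpha,
                    config.gate_p, config.gate_d]},
        sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Identical config and seed produce a byte-identical bundle. On stage
    failure, the partially written bundle is removed and the failing stage
    is named.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def emit(name, writer):
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    try:
        stage = "generate"
        records, truths = generate_cohort(config.cohort)
        followups = generate_followup(records, truths, config.cohort)
        emit("cohort.csv", lambda p: write_cohort(records, p))
        emit("followup.csv", lambda p: write_cohort(followups, p))
        emit("truth.json", lambda p: write_truth(truths, p))

        stage = "diagnose"
        labels = {r.patient_id: diagnose_dsm5(r, config.precedence).label.value
                  for r in records}
        outcomes = {}
        for r in followups:
            if classify_remission(r):
                outcomes[r.patient_id] = REMISSION
            else:
                outcomes[r.patient_id] = diagnose_dsm5(
                    r, config.precedence).label.value

        stage = "distribution"
        order = [l for l in cal.COHORT_COUNTS]
        dist_rows = []
        n_total = len(records)
        for lab in order + ["NONE"]:
            members = [r for r in records if labels[r.patient_id] == lab]
            if not members:
                if lab == "NONE":
                    continue
                dist_rows.append({"label": lab, "n": 0, "percent": 0.0,
                                  "bmi_mean": "", "bmi_sd": "",
                                  "age_mean": "", "age_sd": ""})
                continue
            bmis = np.array([m.bmi for m in members])
            ages = np.array([m.age for m in members])
            dist_rows.append({
                "label": lab, "n": len(members),
                "percent": round_half_up(100.0 * len(members) / n_total, 1),
                "bmi_mean": round(float(bmis.mean()), 2),
                "bmi_sd": round(float(bmis.std(ddof=1)), 2)
                if len(members) > 1 else "",
                "age_mean": round(float(ages.mean()), 2),
                "age_sd": round(float(ages.std(ddof=1)), 2)
                if len(members) > 1 else ""})
        emit("table1_distribution.csv",
             lambda p: pd.DataFrame(dist_rows).to_csv(p, index=False))

        stage = "scores"
        present = [l for l in order
                   if sum(1 for v in labels.values() if v == l) >= 2]
        score_rows = []
        for scale, (attr, sub) in _SCALE_ATTR.items():
            groups = {l: np.array([getattr(getattr(r, attr), sub)
                                   for r in records
                                   if labels[r.patient_id] == l])
                      for l in present}
            row = {"scale": scale}
            if len(groups) >= 2:
                omni = select_omnibus(groups)
                gated = gated_contrasts(groups)
                row.update(method=omni.method,
                           statistic=round(omni.statistic, 4),
                           p_value=float(f"{omni.p_value:.6g}"),
                           eta_p2=round(omni.effect, 4),
                           magnitude=omni.effect_magnitude,
                           significant_contrasts=";".join(
                               f"{c.group_a}>{c.group_b}" if c.mean_diff > 0
                               else f"{c.group_b}>{c.group_a}"
                               for c in gated))
            for l in present:
                row[f"{l}_mean"] = round(float(groups[l].mean()), 3)
                row[f"{l}_sd"] = round(float(groups[l].std(ddof=1)), 3)
            score_rows.append(row)
        emit("table2_scores.csv",
             lambda p: pd.DataFrame(score_rows).to_csv(p, index=False))

        stage = "behaviors"
        beh_rows = []
        for beh in cal.BEHAVIORS:
            fieldname = _BEHAVIOR_FIELD.get(beh)
            test_groups = cal.BEHAVIOR_TEST_GROUPS.get(
                beh, tuple(l for l in present))
            test_groups = [g for g in test_groups if g in present]
            yes, tot = [], []
            row = {"behavior": beh}
            for l in present:
                members = [r for r in records if labels[r.patient_id] == l]
                if beh == "fasting":
                    k = sum(1 for m in members if m.edeq.fasting_score >= 1)
                else:
                    k = sum(1 for m in members
                            if getattr(m.edeq, fieldname) >= 1)
                row[f"{l}_n"] = k
                row[f"{l}_pct"] = round_half_up(100.0 * k / len(members))
                if l in test_groups:
                    yes.append(k)
                    tot.append(len(members))
            if len(yes) >= 2 and min(tot) > 0:
                table = np.array([yes, [t - y for t, y in zip(tot, yes)]])
                if table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0:
                    omni = chi_square(table)
                    row.update(chi2=round(omni.statistic, 2),
                               df=omni.df[0], N=omni.n,
                               p_value=float(f"{omni.p_value:.6g}"))
            beh_rows.append(row)
        emit("table3_behaviors.csv",
             lambda p: pd.DataFrame(beh_rows).to_csv(p, index=False))

        stage = "outliers"
        clean_log_rows = []
        for beh, fieldname in _BEHAVIOR_FIELD.items():
            cap = config.outlier_caps.get(fieldname)
            if cap is None:
                continue
            by_group = {
                l: [getattr(r.edeq, fieldname) for r in records
                    if labels[r.patient_id] == l
                    and getattr(r.edeq, fieldname) >= 1]
                for l in present}
            by_group = {l: v for l, v in by_group.items() if len(v) >= 3}
            _, log = cap_and_gap_delete(by_group, cap)
            for group, action, value, count in log:
                clean_log_rows.append({"variable": fieldname, "group": group,
                                       "action": action, "value": value,
                                       "count": count})
        emit("outlier_log.csv", lambda p: pd.DataFrame(
            clean_log_rows,
            columns=["variable", "group", "action", "value", "count"]
        ).to_csv(p, index=False))

        stage = "comorbidity"
        com_rows = []
        for com in ("mood", "anxiety", "substance"):
            yes = [sum(1 for r in records if labels[r.patient_id] == l
                       and getattr(r.comorbidity, com)) for l in present]
            tot = [sum(1 for v in labels.values() if v == l) for l in present]
            row = {"disorder": com}
            for l, k, t in zip(present, yes, tot):
                row[f"{l}_n"] = k
                row[f"{l}_pct"] = round_half_up(100.0 * k / t)
            table = np.array([yes, [t - y for t, y in zip(tot, yes)]])
            if len(present) >= 2 and table.sum(axis=0).min() > 0 \
                    and table.sum(axis=1).min() > 0:
                omni = chi_square(table)
                row.update(chi2=round(omni.statistic, 2), df=omni.df[0],
                           N=omni.n, p_value=float(f"{omni.p_value:.6g}"))
            com_rows.append(row)
        emit("table5_comorbidity.csv",
             lambda p: pd.DataFrame(com_rows).to_csv(p, index=False))

        stage = "longitudinal"
        table = crossover_table(labels, outcomes)
        emit("table6_crossover.csv", lambda p: table.counts.to_csv(p))
        rem, overall = remission_rates(table)
        migration = migration_summary(table)
        try:
            comp = osfed_composition(
                pd.Series(list(labels.values())).value_counts().to_dict())
        except ValueError:      # cohort without any residual-category member
            comp = None
        metrics = {
            "n_baseline": len(records),
            "n_followup": len(followups),
            "remission_percent_by_label":
                {k: float(v) for k, v in rem["percent"].items()},
            "overall_remission_percent": round_half_up(100 * overall),
            "migration_mean_percent": round_half_up(migration.mean_pct),
            "migration_range_percent": [round_half_up(migration.min_pct),
                                        round_half_up(migration.max_pct)],
            "pd_cohort_share_percent":
                round_half_up(100 * comp.pd_cohort_share, 1)
                if comp else None,
            "pd_osfed_share_percent":
                round_half_up(100 * comp.pd_osfed_share) if comp else None,
            "pd_aan_subbed_osfed_share_percent":
                round_half_up(100 * comp.top3_osfed_share) if comp else None,
            "seed": config.cohort.seed,
            "config_hash": _config_hash(config),
        }
        emit("metrics.json", lambda p: _dump_json(metrics, p))
        emit("run.log", lambda p: p.write_text(
            f"seed={config.cohort.seed} config_hash={_config_hash(config)} "
            f"n={len(records)} followed={len(followups)}\n"))
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return metrics


def published_checks() -> dict:
    """Recompute every calibration-table statistic the package reproduces:
    chi-square tests from the published presence counts with full-sample
    group denominators, the residual-umbrella composition arithmetic, and
    the 12-month remission/cross-over/migration arithmetic."""
    out = {}
    for beh, groups in cal.BEHAVIOR_TEST_GROUPS.items():
        yes = [cal.BEHAVIOR_YES_COUNTS[beh][g] for g in groups]
        tot = [cal.COHORT_COUNTS[g] for g in groups]
        omni = chi_square(np.array([yes, [t - y for t, y in zip(tot, yes)]]))
        out[f"chi2_{beh}"] = {"value": round(omni.statistic, 2),
                              "df": omni.df[0], "n": omni.n}
    for com, counts in cal.COMORBIDITY_YES_COUNTS.items():
        groups = cal.COMORBIDITY_TEST_GROUPS
        yes = [counts[g] for g in groups]
        tot = [cal.COHORT_COUNTS[g] for g in groups]
        omni = chi_square(np.array([yes, [t - y for t, y in zip(tot, yes)]]))
        out[f"chi2_{com}"] = {"value": round(omni.statistic, 2),
                              "df": omni.df[0], "n": omni.n}

    comp = osfed_composition(cal.COHORT_COUNTS)
    out["pd_cohort_share_pct"] = round_half_up(100 * comp.pd_cohort_share, 1)
    out["pd_osfed_share_pct"] = round_half_up(100 * comp.pd_osfed_share)
    out["pd_aan_subbed_osfed_share_pct"] = round_half_up(
        100 * comp.top3_osfed_share)

    table = TransitionTable.from_counts(
        {k: cal.TRANSITION_COUNTS[k] for k in cal.TRANSITION_COUNTS
         if k not in ("SUBBN", "SUBBED")}, cal.TRANSITION_COLUMNS)
    rem, overall = remission_rates(table)
    out["pd_remission_pct"] = float(rem["percent"]["PD"])
    out["overall_remission_pct"] = round_half_up(100 * overall)
    mig = migration_summary(table)
    out["migration_mean_excl_pct"] = round_half_up(mig.mean_pct)
    out["migration_min_excl_pct"] = round_half_up(mig.min_pct)
    out["migration_max_excl_pct"] = round_half_up(mig.max_pct)
    mig_all = migration_summary(table, excluded=())
    out["pd_crossover_pct"] = round_half_up(mig_all.per_label_pct["PD"])
    out["migration_mean_incl_pct"] = round_half_up(mig_all.mean_pct)
    return out
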