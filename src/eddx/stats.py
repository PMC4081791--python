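"""Inferential protocol: outlier handling, omnibus tests with effect
sizes, dual-gated pairwise contrasts, categorical association with
standardized-residual post hocs, scale reliability, and residual gains.

Conventions: two-sided tests throughout; alpha 0.01 for omnibus and
pairwise mean contrasts, 0.001 for pairwise categorical tests; a mean
contrast is only reported when both p < 0.01 and |Cohen's d| >= 0.50 (the
dual significance gate); Pearson chi-square without continuity correction,
with Fisher's exact test substituted in 2x2 post hocs when any expected
cell falls below 5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

OMNIBUS_ALPHA = 0.01
GATE_P = 0.01
GATE_D = 0.50
CATEGORICAL_ALPHA = 0.001

#: Association-magnitude taxonomy (half-open bins on phi / Cramer's V).
MAGNITUDE_BINS = (
    (0.10, "negligible"),
    (0.20, "weak"),
    (0.40, "moderate"),
    (0.60, "relatively strong"),
    (0.80, "strong"),
    (math.inf, "very strong"),
)

# Partial eta-squared / Cohen's d descriptive thresholds.
ETA_SQ_THRESHOLDS = ((0.14, "large"), (0.06, "medium"), (0.01, "small"))
COHEN_D_THRESHOLDS = ((0.8, "large"), (0.5, "medium"), (0.2, "small"))


@dataclass(slots=True)
class OmnibusResult:
    statistic: float
    df: tuple
    p_value: float
    effect: float
    effect_name: str            # "eta_p2", "cramers_v", "phi"
    method: str                 # "anova" | "welch" | "chi2" | "fisher"
    n: int
    expected: np.ndarray | None = None
    std_residuals: np.ndarray | None = None

    @property
    def effect_magnitude(self) -> str:
        if self.effect_name == "eta_p2":
            return eta_squared_magnitude(self.effect)
        return association_magnitude(self.effect)


@dataclass(slots=True)
class ContrastResult:
    group_a: str
    group_b: str
    mean_diff: float
    p_value: float
    cohens_d: float
    method: str                 # "scheffe" | "games_howell"

    @property
    def passes_gate(self) -> bool:
        return self.p_value < GATE_P and abs(self.cohens_d) >= GATE_D


@dataclass(slots=True)
class CategoricalPosthoc:
    group_a: str
    group_b: str
    p_value: float
    phi: float
    method: str                 # "chi2" | "fisher"
    magnitude: str
    significant: bool
    omnibus_std_residuals: np.ndarray


def eta_squared_magnitude(eta: float) -> str:
    for thresh, name in ETA_SQ_THRESHOLDS:
        if eta >= thresh:
            return name
    return "negligible"


def cohen_d_magnitude(d: float) -> str:
    for thresh, name in COHEN_D_THRESHOLDS:
        if abs(d) >= thresh:
            return name
    return "negligible"


def association_magnitude(v: float) -> str:
    """Descriptive label for a phi / Cramer's V value (half-open bins)."""
    if v < 0:
        raise ValueError("association coefficient must be non-negative")
    for upper, name in MAGNITUDE_BINS:
        if v < upper:
            return name
    return "very strong"        # pragma: no cover (inf bin is exhaustive)


# ---------------------------------------------------------------------------
# Outliers

def cap_and_gap_delete(values_by_group, cap: float):
    """Two-step outlier rule applied independently within each group.

    Step 1 truncates values above the pre-defined plausible maximum ``cap``.
    Step 2 standardizes the group (sample SD, n-1) and repeatedly deletes
    the top distinct value (with ties) whenever its z-score exceeds the
    next-highest distinct value's z-score by more than 1; z-scores are
    recomputed after every deletion. Groups smaller than 3 are capped but
    skipped for deletion (SD too unstable), with a warning.

    Returns ``(cleaned, log)`` where log lists every change as
    ``(group, action, value, count)``.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    cleaned, log = {}, []
    for group, values in values_by_group.items():
        x = np.asarray(values, dtype=float)
        if x.size == 0:
            raise ValueError(f"group {group!r} is empty")
        n_over = int(np.sum(x > cap))
        if n_over:
            log.append((group, "capped", float(cap), n_over))
            x = np.minimum(x, cap)
        if x.size < 3:
            warnings.warn(f"group {group!r} has fewer than 3 values; "
                          "gap-deletion skipped")
            cleaned[group] = x
            continue
        while x.size >= 3:
            sd = x.std(ddof=1)
            if sd == 0:
                break
            distinct = np.unique(x)
            if distinct.size < 2:
                break
            top, nxt = distinct[-1], distinct[-2]
            if (top - nxt) / sd > 1.0:
                k = int(np.sum(x == top))
                log.append((group, "deleted", float(top), k))
                x = x[x != top]
            else:
                break
        cleaned[group] = x
    return cleaned, log


# ---------------------------------------------------------------------------
# Omnibus means tests

def _as_groups(groups):
    if isinstance(groups, dict):
        names = list(groups)
        arrays = [np.asarray(groups[g], dtype=float) for g in names]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        names = [str(i) for i in range(len(arrays))]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for name, a in zip(names, arrays):
        if a.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    return names, arrays


def one_way_anova(groups) -> OmnibusResult:
    """Classical one-way ANOVA with partial eta-squared
    (SS_between / (SS_between + SS_within))."""
    _, arrays = _as_groups(groups)
    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    ss_b = float(np.sum(ns * (means - grand) ** 2))
    ss_w = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b, df_w = k - 1, int(ns.sum()) - k
    if ss_w == 0 and ss_b == 0:
        f, p = 0.0, 1.0
    else:
        f = (ss_b / df_b) / (ss_w / df_w) if ss_w > 0 else math.inf
        p = float(sps.f.sf(f, df_b, df_w))
    eta = ss_b / (ss_b + ss_w) if (ss_b + ss_w) > 0 else 0.0
    return OmnibusResult(f, (df_b, df_w), p, eta, "eta_p2", "anova",
                         int(ns.sum()))


def welch_anova(groups) -> OmnibusResult:
    """Welch's heteroscedastic F with Welch-Satterthwaite denominator df."""
    _, arrays = _as_groups(groups)
    k = len(arrays)
    ns = np.array([a.size for a in arrays], dtype=float)
    means = np.array([a.mean() for a in arrays])
    var = np.array([a.var(ddof=1) for a in arrays])
    if np.all(var == 0):
        raise ValueError("Welch ANOVA undefined when every group variance is 0")
    w = ns / var
    mw = float(np.sum(w * means) / w.sum())
    num = float(np.sum(w * (means - mw) ** 2)) / (k - 1)
    lam = float(np.sum((1 - w / w.sum()) ** 2 / (ns - 1)))
    den = 1.0 + 2.0 * (k - 2) / (k * k - 1.0) * lam
    f = num / den
    df2 = (k * k - 1.0) / (3.0 * lam)
    p = float(sps.f.sf(f, k - 1, df2))
    # Effect size reported on the classical decomposition for comparability.
    eta = one_way_anova(groups).effect
    return OmnibusResult(f, (k - 1, df2), p, eta, "eta_p2", "welch",
                         int(ns.sum()))


def select_omnibus(groups, force: str | None = None,
                   levene_alpha: float = 0.05,
                   small_n: int = 30) -> OmnibusResult:
    """Welch trigger: heteroscedasticity (Levene p < 0.05) combined with a
    small group (min n < 30) selects Welch's ANOVA, else the classical one.
    ``force`` in {"anova", "welch"} overrides."""
    names, arrays = _as_groups(groups)
    if force == "anova":
        return one_way_anova(dict(zip(names, arrays)))
    if force == "welch":
        return welch_anova(dict(zip(names, arrays)))
    if force is not None:
        raise ValueError("force must be 'anova', 'welch', or None")
    _, lev_p = sps.levene(*arrays, center="median")
    if lev_p < levene_alpha and min(a.size for a in arrays) < small_n:
        return welch_anova(dict(zip(names, arrays)))
    return one_way_anova(dict(zip(names, arrays)))


# ---------------------------------------------------------------------------
# Pairwise contrasts

def cohens_d(a, b) -> float:
    """Pooled-SD standardized mean difference (n-1 pooling weights)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    pooled = math.sqrt(((a.size - 1) * a.var(ddof=1)
                        + (b.size - 1) * b.var(ddof=1))
                       / (a.size + b.size - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD: Cohen's d undefined")
    return float((a.mean() - b.mean()) / pooled)


def _pairwise_d(a, b):
    try:
        return cohens_d(a, b)
    except ValueError:
        return 0.0 if a.mean() == b.mean() else math.inf


def scheffe_contrasts(groups) -> list[ContrastResult]:
    """All pairwise Scheffe contrasts: the pairwise F is scaled by the
    omnibus numerator df, guaranteeing the post hoc is never more
    significant than the omnibus family allows."""
    names, arrays = _as_groups(groups)
    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    n_tot = int(ns.sum())
    ss_w = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_w = n_tot - k
    msw = ss_w / df_w
    out = []
    for i, j in combinations(range(k), 2):
        a, b = arrays[i], arrays[j]
        diff = float(a.mean() - b.mean())
        if msw == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            f_pair = diff ** 2 / (msw * (1.0 / a.size + 1.0 / b.size))
            p = float(sps.f.sf(f_pair / (k - 1), k - 1, df_w))
        out.append(ContrastResult(names[i], names[j], diff, p,
                                  _pairwise_d(a, b), "scheffe"))
    return out


def games_howell_contrasts(groups) -> list[ContrastResult]:
    """Games-Howell pairwise contrasts: studentized-range p-values with
    Welch-Satterthwaite per-pair df; robust to unequal variances."""
    names, arrays = _as_groups(groups)
    k = len(arrays)
    out = []
    for i, j in combinations(range(k), 2):
        a, b = arrays[i], arrays[j]
        va, vb = a.var(ddof=1), b.var(ddof=1)
        na, nb = a.size, b.size
        diff = float(a.mean() - b.mean())
        se2 = va / na + vb / nb
        if se2 == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / math.sqrt(se2)
            df = se2 ** 2 / ((va / na) ** 2 / (na - 1)
                             + (vb / nb) ** 2 / (nb - 1))
            q = abs(t) * math.sqrt(2.0)
            p = float(sps.studentized_range.sf(q, k, df))
        out.append(ContrastResult(names[i], names[j], diff, p,
                                  _pairwise_d(a, b), "games_howell"))
    return out


def gated_contrasts(groups, method: str = "auto") -> list[ContrastResult]:
    """Omnibus-then-pairwise procedure with the dual p/d gate.

    Runs the Welch-triggered omnibus at alpha 0.01; if it does not reject,
    no contrast is reported. Otherwise pairwise contrasts follow the
    omnibus family (Scheffe after classical ANOVA, Games-Howell after
    Welch) and only gate-passing contrasts are returned.
    """
    omni = select_omnibus(groups, force=None if method == "auto" else method)
    if omni.p_value >= OMNIBUS_ALPHA:
        return []
    contrasts = (games_howell_contrasts(groups) if omni.method == "welch"
                 else scheffe_contrasts(groups))
    return [c for c in contrasts if c.passes_gate]


# ---------------------------------------------------------------------------
# Categorical association

def chi_square(table) -> OmnibusResult:
    """Pearson chi-square without continuity correction, with expected
    counts and standardized residuals (O - E) / sqrt(E)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if (obs < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal row/column")
    chi2, p, df, expected = sps.chi2_contingency(obs, correction=False)
    n = int(round(obs.sum()))
    r, c = obs.shape
    if min(r, c) == 2:
        effect = math.sqrt(chi2 / n)
        name = "phi" if (r, c) == (2, 2) else "cramers_v"
    else:
        effect = math.sqrt(chi2 / (n * (min(r, c) - 1)))
        name = "cramers_v"
    resid = (obs - expected) / np.sqrt(expected)
    return OmnibusResult(float(chi2), (int(df),), float(p), float(effect),
                         name, "chi2", n, expected, resid)


def fisher_exact_2x2(table) -> float:
    obs = np.asarray(table)
    if obs.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    return float(sps.fisher_exact(obs)[1])


def pairwise_categorical(table, groups) -> list[CategoricalPosthoc]:
    """Pairwise 2x2 post hocs for a presence/absence x groups omnibus table.

    Fisher's exact test substitutes the chi-square when any expected cell
    of the pair's 2x2 falls below 5; phi is always sqrt(chi2 / N) of the
    pair; significance is judged at alpha 0.001. The omnibus table's
    standardized residuals are attached for inspection.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise ValueError("expected a 2 x k presence/absence table")
    if obs.shape[1] != len(groups):
        raise ValueError("group names must match table columns")
    if obs.shape[1] < 3:
        raise ValueError("pairwise post hocs need at least 3 groups")
    omni = chi_square(obs)
    out = []
    for i, j in combinations(range(obs.shape[1]), 2):
        sub = obs[:, [i, j]]
        if sub.sum(axis=0).min() == 0 or sub.sum(axis=1).min() == 0:
            raise ValueError(
                f"degenerate pair ({groups[i]}, {groups[j]}): zero marginal")
        n_pair = sub.sum()
        expected = np.outer(sub.sum(axis=1), sub.sum(axis=0)) / n_pair
        chi2_val = float(((sub - expected) ** 2 / expected).sum())
        phi = math.sqrt(chi2_val / n_pair)
        if expected.min() < 5:
            p, method = fisher_exact_2x2(sub.astype(int)), "fisher"
        else:
            p, method = float(sps.chi2.sf(chi2_val, 1)), "chi2"
        out.append(CategoricalPosthoc(
            groups[i], groups[j], p, phi, method,
            association_magnitude(phi), p < CATEGORICAL_ALPHA,
            omni.std_residuals))
    return out


# ---------------------------------------------------------------------------
# Change scores and reliability

def residual_gain(baseline, followup) -> np.ndarray:
    """Residuals from the pooled least-squares regression of follow-up on
    baseline: a change measure uncorrelated with initial severity."""
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(followup, dtype=float)
    if x.size != y.size:
        raise ValueError("baseline and follow-up must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if x.var(ddof=1) == 0:
        raise ValueError("zero baseline variance: slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return y - (slope * x + intercept)


def cronbach_alpha(item_matrix) -> float:
    """Internal-consistency reliability, k/(k-1) * (1 - sum(var_i)/var_tot)."""
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 3:
        raise ValueError("need >= 2 items and >= 3 respondents")
    k = m.shape[1]
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - m.var(axis=0, ddof=1).sum() / total_var))
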