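"""Cohort stratification and nonparametric marker statistics.

Three study groups: untreated OSA, CPAP-treated OSA, and controls without
OSA. Two stratification rules select analysis subjects:

* stratification 1 — all untreated kept; treated kept iff averaged CPAP
  usage >= 5 h/night;
* stratification 2 — a subject is kept iff AHI > 30, or (AHI > 10 and
  ESS > 10); treated additionally require CPAP >= 5 h/night. The AHI
  source is the visit value for untreated subjects and the diagnostic
  (pre-treatment) value for treated subjects. Controls pass
  unconditionally (the screening comparison uses the whole control
  group).

Legacy ODI-based variants of both rules (the earlier validation study's
criteria) are available via ``use_odi=True``.

Marker intensities in breath are right-skewed (non-normal by
Shapiro-Wilk), so between-group differences are tested with the
Mann-Whitney U test; the Shapiro-Wilk gate is reported, never used to
switch tests silently. Fold changes are ratios of group medians on the
TIC-normalized scale (z-scores destroy ratios). No multiple-testing
correction is applied by default (significant = p < alpha, unadjusted);
Benjamini-Hochberg is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import StatsError
from .panel import MatchTable
from .preprocess import IntensityMatrix

GROUPS = ("osa_untreated", "osa_treated", "control")


@dataclass
class SubjectRecord:
    """Clinical metadata for one subject."""

    subject_id: str
    group: str  # osa_untreated | osa_treated | control
    ahi_visit: Optional[float] = None  # events/h, at the study visit
    ahi_diagnosis: Optional[float] = None  # events/h, from the sleep report
    odi: Optional[float] = None  # events/h
    ess: Optional[float] = None  # Epworth score, points
    cpap_hours: Optional[float] = None  # h/night, treated only

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        for name in ("ahi_visit", "ahi_diagnosis", "odi", "ess", "cpap_hours"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cpap_hours is not None and self.group != "osa_treated":
            raise ValueError("cpap_hours only applies to treated subjects")


@dataclass
class StratificationRule:
    """Inclusion rule; ``rule_id`` is 'strat1' or 'strat2'."""

    rule_id: str
    cpap_min_hours: float = 5.0
    ahi_high: float = 30.0
    ahi_low: float = 10.0
    ess_min: float = 10.0
    use_odi: bool = False  # legacy ODI-based variant of the severity criterion

    def __post_init__(self) -> None:
        if self.rule_id not in ("strat1", "strat2"):
            raise ValueError(f"unknown rule {self.rule_id!r}")
        if min(self.cpap_min_hours, self.ahi_high, self.ahi_low, self.ess_min) <= 0:
            raise ValueError("thresholds must be positive")


STRAT1 = StratificationRule("strat1")
STRAT2 = StratificationRule("strat2")


def _severity_index(record: SubjectRecord, rule: StratificationRule) -> Optional[float]:
    if rule.use_odi:
        return record.odi
    # pre-treatment severity for treated subjects, visit AHI otherwise
    if record.group == "osa_treated":
        return record.ahi_diagnosis
    return record.ahi_visit


def apply_stratification(
    records: Sequence[SubjectRecord], rule: StratificationRule
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Included subject ids per group, plus per-subject exclusion reasons.

    Subjects missing a field the rule needs are excluded with a logged
    reason rather than failing the whole cohort.
    """
    included: dict[str, list[str]] = {g: [] for g in GROUPS}
    excluded: dict[str, str] = {}
    for rec in records:
        reason = _exclusion_reason(rec, rule)
        if reason is None:
            included[rec.group].append(rec.subject_id)
        else:
            excluded[rec.subject_id] = reason
    return included, excluded


def _exclusion_reason(rec: SubjectRecord, rule: StratificationRule) -> Optional[str]:
    if rec.group == "osa_treated":
        if rec.cpap_hours is None:
            return "missing cpap_hours"
        if rec.cpap_hours < rule.cpap_min_hours:
            return f"CPAP usage {rec.cpap_hours:g} < {rule.cpap_min_hours:g} h/night"
    if rule.rule_id == "strat1" or rec.group == "control":
        return None
    severity = _severity_index(rec, rule)
    if severity is None:
        return "missing AHI/ODI for severity criterion"
    if severity > rule.ahi_high:
        return None
    if rec.ess is None:
        return "missing ESS for severity criterion"
    if severity > rule.ahi_low and rec.ess > rule.ess_min:
        return None
    return (
        f"severity {severity:g} / ESS {rec.ess:g} fails "
        f"(> {rule.ahi_high:g}, or > {rule.ahi_low:g} with ESS > {rule.ess_min:g})"
    )


# ---------------------------------------------------------------------------
# tests


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U is the smaller of U1 and U2 (midrank
    ties). The p-value is the exact permutation p when n1 + n2 <= 12 and
    the pooled sample is tie-free, otherwise the normal approximation
    with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("empty sample")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    u1 = float(res.statistic)
    u = min(u1, x.size * y.size - u1)
    return u, float(res.pvalue)


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (3 <= n <= 5000, non-constant sample)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3 or values.size > 5000:
        raise StatsError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {values.size}")
    if np.ptp(values) == 0:
        raise StatsError("constant sample: Shapiro-Wilk undefined")
    w, p = sps.shapiro(values)
    return float(w), float(p)


@dataclass
class MarkerTestResult:
    """Between-group test result for one detected marker."""

    mz: float
    column: int
    u_statistic: float
    p_value: float
    fold_change: float  # median(group a) / median(group b), TIC-normalized
    direction: str  # "increased" | "decreased" (group a relative to b)
    normality_p_a: Optional[float] = None
    normality_p_b: Optional[float] = None
    p_adjusted: Optional[float] = None
    name: Optional[str] = None


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    n = pvals.size
    order = np.argsort(pvals)
    adj = np.empty(n)
    cummin = 1.0
    for rank_from_top in range(n - 1, -1, -1):
        i = order[rank_from_top]
        cummin = min(cummin, pvals[i] * n / (rank_from_top + 1))
        adj[i] = cummin
    return adj


def compare_groups(
    matrix: IntensityMatrix,
    matches: MatchTable,
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
    alpha: float = 0.05,
    adjust: bool = False,
) -> tuple[list[MarkerTestResult], list[MarkerTestResult]]:
    """Test every detected marker for a group-a vs group-b difference.

    The matrix should be in the auto-scaled state with the TIC-normalized
    snapshot retained (``tic_values``): ranks — and hence Mann-Whitney p
    — are identical on both scales (auto-scaling is a per-feature
    strictly increasing affine map), while fold changes are only
    meaningful on the TIC-normalized scale.

    Returns ``(all_results, significant)`` where significance is
    p < alpha, unadjusted unless ``adjust`` (Benjamini-Hochberg) is on.
    """
    ia = matrix.column_for(group_a_ids)
    ib = matrix.column_for(group_b_ids)
    if ia.size < 3 or ib.size < 3:
        raise StatsError("each group needs at least 3 subjects")
    fc_values = matrix.tic_values if matrix.tic_values is not None else matrix.values
    results: list[MarkerTestResult] = []
    for marker, col in zip(matches.panel.markers, matches.column):
        if col is None:
            continue
        xa = matrix.values[ia, col]
        xb = matrix.values[ib, col]
        u, p = mann_whitney_u(xa, xb)
        med_a = float(np.median(fc_values[ia, col]))
        med_b = float(np.median(fc_values[ib, col]))
        fc = med_a / med_b if med_b != 0 else math.inf
        results.append(
            MarkerTestResult(
                mz=marker.mz,
                column=col,
                u_statistic=u,
                p_value=p,
                fold_change=fc,
                direction="increased" if fc > 1 else "decreased",
                normality_p_a=_safe_shapiro(xa),
                normality_p_b=_safe_shapiro(xb),
                name=marker.name,
            )
        )
    if adjust and results:
        adj = _bh_adjust(np.array([r.p_value for r in results]))
        for r, a in zip(results, adj):
            r.p_adjusted = float(a)
        significant = [r for r in results if r.p_adjusted < alpha]
    else:
        significant = [r for r in results if r.p_value < alpha]
    return results, significant


def _safe_shapiro(values: np.ndarray) -> Optional[float]:
    try:
        return shapiro_wilk(values)[1]
    except StatsError:
        return None
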