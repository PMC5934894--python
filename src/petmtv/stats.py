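"""ROC, optimal cutoffs, diagnostic accuracy and associations.

The analysis layer: empirical ROC curves (AUC with DeLong confidence
intervals), the minimal-distance-to-(0,1) optimal cutoff, 2x2
diagnostic-accuracy tables with Clopper-Pearson exact intervals,
Mann-Whitney comparisons, saturated log-linear association z values,
and the stratified orchestration over a simulated or measured cohort.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import PatientRecord
from .features import FEATURE_NAMES, FeatureVector

__all__ = [
    "DiagnosticTable",
    "ROCResult",
    "AccuracyEstimate",
    "StratifiedReport",
    "roc_curve",
    "optimal_cutoff",
    "diagnostic_accuracy",
    "clopper_pearson",
    "round_half_up",
    "mann_whitney",
    "loglinear_association",
    "run_stratified_analysis",
    "reconstruct_from_subgroup_rates",
    "reconstruct_from_sens_spec",
    "INVERTED_FEATURES",
]

# features whose printed optimal cutoffs carry a "<" sign: low values
# predict inadequate response, so their ROC polarity is inverted
INVERTED_FEATURES = ("entropy", "contrast")


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero (toward +inf for positive x)."""
    factor = 10.0**decimals
    r = math.floor(x * factor + 0.5) / factor
    return int(r) if decimals == 0 else r


@dataclass(frozen=True)
class DiagnosticTable:
    """2x2 counts; test positive = biomarker beyond cutoff, condition = IR."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fn, self.fp, self.tn)
        if any(c < 0 for c in counts):
            raise ValueError(f"counts must be non-negative, got {counts}")
        if sum(counts) == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @staticmethod
    def from_predictions(
        values: Sequence[float], labels: Sequence[bool], cutoff: float
    ) -> "DiagnosticTable":
        v = np.asarray(values, dtype=float)
        y = np.asarray(labels, dtype=bool)
        pos = v > cutoff
        return DiagnosticTable(
            tp=int(np.sum(pos & y)),
            fn=int(np.sum(~pos & y)),
            fp=int(np.sum(pos & ~y)),
            tn=int(np.sum(~pos & ~y)),
        )


@dataclass
class ROCResult:
    """Empirical ROC curve with AUC, DeLong CI and the optimal cutoff."""

    thresholds: np.ndarray  # ascending; test positive = value > threshold
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    optimal_cutoff: float = math.nan
    optimal_d: float = math.nan


@dataclass(frozen=True)
class AccuracyEstimate:
    """One diagnostic proportion with its exact 95% interval."""

    successes: int
    trials: int
    point_pct: int  # half-up whole percent, as reported
    ci_pct: tuple[int, int]
    fraction: float  # raw, unrounded


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) two-sided confidence interval."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the empirical AUC (ties counted half)."""
    m, n = len(pos), len(neg)
    v10 = np.empty(m)
    for i, x in enumerate(pos):
        v10[i] = np.mean((neg < x) + 0.5 * (neg == x))
    v01 = np.empty(n)
    for j, y in enumerate(neg):
        v01[j] = np.mean((pos > y) + 0.5 * (pos == y))
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_curve(values: Sequence[float], labels: Sequence[bool]) -> ROCResult:
    """Empirical ROC of a biomarker against a binary condition.

    Test positive means value strictly above the threshold. The AUC is
    computed from midranks, making it identical to the Mann-Whitney U
    statistic divided by n1*n2 with ties counted one half; the 95% CI
    uses the DeLong variance with a normal approximation, clipped to
    [0, 1].
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape:
        raise ValueError("values and labels must have equal length")
    pos, neg = v[y], v[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC undefined: both classes must be present")

    ranks = sps.rankdata(v)
    auc = (ranks[y].sum() - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg))

    se = math.sqrt(_delong_variance(pos, neg))
    z = sps.norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))

    thresholds = np.concatenate(([-np.inf], np.unique(v)))
    sens = np.array([np.mean(pos > t) for t in thresholds])
    spec = np.array([np.mean(neg <= t) for t in thresholds])

    result = ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        auc_ci=ci,
    )
    result.optimal_cutoff, result.optimal_d = optimal_cutoff(result)
    return result


def optimal_cutoff(roc: ROCResult) -> tuple[float, float]:
    """Threshold minimizing d = sqrt((1-sens)^2 + (1-spec)^2).

    Ties are broken toward higher specificity, then higher threshold.
    """
    d = np.sqrt((1.0 - roc.sensitivity) ** 2 + (1.0 - roc.specificity) ** 2)
    best = None
    for i in range(len(d)):
        key = (round(d[i], 12), -roc.specificity[i], -roc.thresholds[i])
        if best is None or key < best[0]:
            best = (key, i)
    i = best[1]
    return float(roc.thresholds[i]), float(d[i])


def _estimate(k: int, n: int) -> Optional[AccuracyEstimate]:
    if n == 0:
        return None
    lo, hi = clopper_pearson(k, n)
    return AccuracyEstimate(
        successes=k,
        trials=n,
        point_pct=round_half_up(100.0 * k / n),
        ci_pct=(round_half_up(100.0 * lo), round_half_up(100.0 * hi)),
        fraction=k / n,
    )


def diagnostic_accuracy(table: DiagnosticTable) -> dict[str, Optional[AccuracyEstimate]]:
    """Sens/spec/PPV/NPV with exact 95% CIs, percentages rounded half-up.

    A metric with an empty denominator is reported as ``None``
    (undefined) rather than raising.
    """
    return {
        "sensitivity": _estimate(table.tp, table.tp + table.fn),
        "specificity": _estimate(table.tn, table.tn + table.fp),
        "ppv": _estimate(table.tp, table.tp + table.fp),
        "npv": _estimate(table.tn, table.tn + table.fn),
    }


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (midrank ties) with a two-sided p value.

    Uses exact enumeration when n1 + n2 <= 12 and the data are free of
    ties, otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def loglinear_association(counts: np.ndarray, delta: float = 0.5) -> dict[str, float]:
    """Interaction z values of the saturated log-linear model.

    Accepts a 2x2 or 2x2x2 contingency array. Effect coding (+1/-1 per
    axis level) gives closed-form estimates: each interaction term is
    the signed average of log counts, with variance the average of
    reciprocal counts over squared cell number. ``delta`` is added to
    every cell (0.5 by default) so zero cells stay finite. Axes are
    named A, B, C in order; returns z per two-way (and three-way) term.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape not in ((2, 2), (2, 2, 2)):
        raise ValueError(f"expected a 2x2 or 2x2x2 table, got shape {c.shape}")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    c = c + delta
    logc = np.log(c)
    k = c.ndim
    n_cells = c.size
    sign = np.array([1.0, -1.0])
    out: dict[str, float] = {}
    axis_names = "ABC"[:k]
    for size in range(2, k + 1):
        for axes in itertools.combinations(range(k), size):
            s = np.ones_like(c)
            for ax in axes:
                shape = [1] * k
                shape[ax] = 2
                s = s * sign.reshape(shape)
            est = float((s * logc).sum()) / n_cells
            var = float((1.0 / c).sum()) / n_cells**2
            out["".join(axis_names[a] for a in axes)] = est / math.sqrt(var)
    return out


# ---------------------------------------------------------------------------
# Stratified orchestration


@dataclass
class StratumFeatureResult:
    stratum: str
    feature: str
    direction: str  # ">" or "<" (reported polarity of the cutoff)
    roc: ROCResult
    cutoff: float  # on the original feature scale
    table: DiagnosticTable
    accuracy: dict[str, Optional[AccuracyEstimate]]


@dataclass
class StratifiedReport:
    strata: list[str]
    results: list[StratumFeatureResult] = field(default_factory=list)
    non_evaluable: list[str] = field(default_factory=list)

    def roc_table(self) -> pd.DataFrame:
        rows = [
            {
                "stratum": r.stratum,
                "feature": r.feature,
                "auc": r.roc.auc,
                "auc_ci_low": r.roc.auc_ci[0],
                "auc_ci_high": r.roc.auc_ci[1],
                "cutoff": r.cutoff,
                "direction": r.direction,
                "optimal_d": r.roc.optimal_d,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def accuracy_table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"stratum": r.stratum, "feature": r.feature}
            for metric, est in r.accuracy.items():
                if est is None:
                    row[metric] = None
                else:
                    row[metric] = est.point_pct
                    row[f"{metric}_ci_low"] = est.ci_pct[0]
                    row[f"{metric}_ci_high"] = est.ci_pct[1]
                    row[f"{metric}_fraction"] = est.fraction
            rows.append(row)
        return pd.DataFrame(rows)


def _strata_of(rec: PatientRecord, scheme: str) -> str:
    if scheme == "stage_groups":
        return rec.stage_group
    if scheme == "tg_tl":
        if rec.tg_tl is None:
            raise ValueError(f"patient {rec.id} lacks a TG/TL assignment")
        return f"TG/TL {rec.tg_tl}"
    raise ValueError(f"unknown stratification scheme {scheme!r}")


def run_stratified_analysis(
    cohort: Sequence[tuple[PatientRecord, FeatureVector]],
    strata: str = "stage_groups",
    features: Sequence[str] = FEATURE_NAMES,
) -> StratifiedReport:
    """Per-stratum, per-feature ROC + cutoff + diagnostic accuracy.

    Features in :data:`INVERTED_FEATURES` enter the ROC negated (low
    values predict IR); their cutoffs are reported back on the original
    scale with "<" polarity. Strata containing only one response class
    are listed as non-evaluable.
    """
    for rec, _ in cohort:
        if rec.response not in ("IR", "AR"):
            raise ValueError(f"patient {rec.id} has no response classification")

    labels_by_stratum: dict[str, list[bool]] = {}
    values_by_stratum: dict[str, list[FeatureVector]] = {}
    for rec, fv in cohort:
        s = _strata_of(rec, strata)
        labels_by_stratum.setdefault(s, []).append(rec.response == "IR")
        values_by_stratum.setdefault(s, []).append(fv)

    report = StratifiedReport(strata=sorted(labels_by_stratum))
    for stratum in report.strata:
        y = np.asarray(labels_by_stratum[stratum])
        if y.all() or not y.any():
            report.non_evaluable.append(stratum)
            continue
        for feat in features:
            raw = np.asarray([getattr(fv, feat) for fv in values_by_stratum[stratum]])
            inverted = feat in INVERTED_FEATURES
            v = -raw if inverted else raw
            roc = roc_curve(v, y)
            cutoff = -roc.optimal_cutoff if inverted else roc.optimal_cutoff
            table = DiagnosticTable.from_predictions(v, y, roc.optimal_cutoff)
            report.results.append(
                StratumFeatureResult(
                    stratum=stratum,
                    feature=feat,
                    direction="<" if inverted else ">",
                    roc=roc,
                    cutoff=cutoff,
                    table=table,
                    accuracy=diagnostic_accuracy(table),
                )
            )
    return report


# ---------------------------------------------------------------------------
# Integer 2x2 reconstruction from published summary percentages


def reconstruct_from_subgroup_rates(
    n_total: int,
    n_positive: int,
    rate_high_pct: float,
    rate_low_pct: float,
    decimals: int = 1,
) -> DiagnosticTable:
    """Recover the unique integer 2x2 table behind printed subgroup rates.

    Given the stratum size, the number of condition-positive patients,
    and the condition rates (in %) within the high- and low-biomarker
    subgroups, enumerates all integer splits and keeps the one whose
    rates round (half-up, ``decimals`` places) to the printed values.
    Raises if no split or more than one split matches.
    """
    matches = []
    for n_hi in range(1, n_total):
        n_lo = n_total - n_hi
        for k_hi in range(0, min(n_hi, n_positive) + 1):
            k_lo = n_positive - k_hi
            if not 0 <= k_lo <= n_lo:
                continue
            if (
                round_half_up(100.0 * k_hi / n_hi, decimals) == rate_high_pct
                and round_half_up(100.0 * k_lo / n_lo, decimals) == rate_low_pct
            ):
                matches.append(DiagnosticTable(tp=k_hi, fn=k_lo, fp=n_hi - k_hi, tn=n_lo - k_lo))
    if len(matches) != 1:
        raise ValueError(
            f"expected exactly one table for rates ({rate_high_pct}, {rate_low_pct}) "
            f"with n={n_total}, positives={n_positive}; found {len(matches)}"
        )
    return matches[0]


def reconstruct_from_sens_spec(
    n_total: int, n_positive: int, sens_pct: int, spec_pct: int
) -> DiagnosticTable:
    """Recover the integer 2x2 table behind whole-percent sens/spec."""
    n_negative = n_total - n_positive
    tps = [k for k in range(n_positive + 1)
           if round_half_up(100.0 * k / n_positive) == sens_pct]
    tns = [k for k in range(n_negative + 1)
           if round_half_up(100.0 * k / n_negative) == spec_pct]
    if len(tps) != 1 or len(tns) != 1:
        raise ValueError(
            f"sens/spec ({sens_pct}%, {spec_pct}%) do not pin a unique table "
            f"for n={n_total}, positives={n_positive}"
        )
    tp, tn = tps[0], tns[0]
    return DiagnosticTable(tp=tp, fn=n_positive - tp, fp=n_negative - tn, tn=tn)
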