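"""Cohort-level evaluation: ROC with DeLong CIs, Youden thresholds,
confusion statistics, t-tests, and Spearman correlation.

ROC orientation is fixed a priori for every predictor: a larger post-ectopic
increase points to a fluid responder.  The AUC is the Mann–Whitney statistic
(ties counted 1/2) and its confidence interval uses the DeLong structural-
component variance with normal quantiles, clipped to [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .deltas import VARIABLES

__all__ = [
    "RocResult",
    "YoudenResult",
    "ConfusionStats",
    "ClassificationResult",
    "GroupComparison",
    "roc_auc",
    "youden_threshold",
    "confusion_stats",
    "two_sample_t_pooled",
    "paired_t",
    "spearman_rho",
    "run_classification",
    "round_half_up",
]

_Z975 = sps.norm.ppf(0.975)


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (report style)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores contain non-finite values")
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    n_pos: int
    n_neg: int


def roc_auc(scores, labels, conf_level: float = 0.95) -> RocResult:
    """AUC with a DeLong confidence interval.

    ``labels`` truthy = responder; orientation is fixed (larger score =>
    responder).  With fewer than 2 members in a class the variance is
    degenerate and the CI collapses onto the point estimate.
    """
    pos, neg = _split(scores, labels)
    m, n = len(pos), len(neg)
    # placement values: psi(x, y) = 1[x>y] + 0.5*1[x==y]
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)  # per-responder placements
    v01 = cmp.mean(axis=0)  # per-non-responder placements
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    z = sps.norm.ppf(0.5 + conf_level / 2.0)
    lo = min(max(auc - z * se, 0.0), 1.0)
    hi = min(max(auc + z * se, 0.0), 1.0)
    return RocResult(auc=auc, ci_low=lo, ci_high=hi, se=se, n_pos=m, n_neg=n)


@dataclass
class YoudenResult:
    threshold: float
    sens_pct: float
    spec_pct: float
    youden_j: float
    degenerate: bool = False


def youden_threshold(scores, labels) -> YoudenResult:
    """Cut-point maximizing Youden's J = sens + spec − 1.

    Candidates are midpoints of adjacent sorted unique scores plus the two
    boundary cut-points (everything / nothing positive, both J = 0); the
    decision rule is positive iff score > threshold.  Ties in J are broken
    toward higher specificity, then toward the lower threshold.  With all
    scores identical the problem is degenerate (J = 0) and a warning is
    issued.
    """
    pos, neg = _split(scores, labels)
    uniq = np.unique(np.concatenate([pos, neg]))
    if len(uniq) == 1:
        warnings.warn("all scores identical: Youden threshold is degenerate")
        return YoudenResult(threshold=float(uniq[0]), sens_pct=0.0, spec_pct=100.0,
                            youden_j=0.0, degenerate=True)
    cands = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    best: Optional[YoudenResult] = None
    for thr in cands:
        sens = float(np.mean(pos > thr))
        spec = float(np.mean(neg <= thr))
        j = sens + spec - 1.0
        cur = YoudenResult(float(thr), 100.0 * sens, 100.0 * spec, j)
        if (
            best is None
            or j > best.youden_j + 1e-12
            or (abs(j - best.youden_j) <= 1e-12 and (cur.spec_pct, -cur.threshold) > (best.spec_pct, -best.threshold))
        ):
            best = cur
    return best


@dataclass
class ConfusionStats:
    tp: int
    fn: int
    fp: int
    tn: int
    sens_pct: Optional[float]
    spec_pct: Optional[float]
    ppv_pct: Optional[float]
    npv_pct: Optional[float]

    def rounded(self) -> dict:
        """Integer percentages as printed in reports (missing stays None)."""
        return {
            k: (None if v is None else round_half_up(v))
            for k, v in {
                "sens_pct": self.sens_pct,
                "spec_pct": self.spec_pct,
                "ppv_pct": self.ppv_pct,
                "npv_pct": self.npv_pct,
            }.items()
        }


def confusion_stats(tp: int, fn: int, fp: int, tn: int) -> ConfusionStats:
    """Sensitivity/specificity/PPV/NPV (%) from confusion counts.

    Ratios with zero denominator are reported missing (None).  PPV/NPV use
    the sample prevalence (no external prior).
    """
    for name, v in dict(tp=tp, fn=fn, fp=fp, tn=tn).items():
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")

    def ratio(num, den):
        return None if den == 0 else 100.0 * num / den

    return ConfusionStats(
        tp=tp, fn=fn, fp=fp, tn=tn,
        sens_pct=ratio(tp, tp + fn),
        spec_pct=ratio(tn, tn + fp),
        ppv_pct=ratio(tp, tp + fp),
        npv_pct=ratio(tn, tn + fn),
    )


def two_sample_t_pooled(
    m1: Optional[float] = None, s1: Optional[float] = None, n1: Optional[int] = None,
    m2: Optional[float] = None, s2: Optional[float] = None, n2: Optional[int] = None,
    x1: Optional[Sequence[float]] = None, x2: Optional[Sequence[float]] = None,
) -> tuple[float, int, float]:
    """Pooled-variance Student's t test (two-sided).

    Accepts either summary statistics (m, s, n per group — so printed group
    means/SDs are directly checkable) or raw vectors ``x1``/``x2``.  Returns
    (t, df, p) with t oriented as group2 − group1.
    """
    if x1 is not None or x2 is not None:
        if x1 is None or x2 is None:
            raise ValueError("provide both raw vectors or neither")
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        m1, s1, n1 = float(x1.mean()), float(x1.std(ddof=1)), len(x1)
        m2, s2, n2 = float(x2.mean()), float(x2.std(ddof=1)), len(x2)
    if None in (m1, s1, n1, m2, s2, n2):
        raise ValueError("summary statistics incomplete")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if not (s1 > 0 and s2 > 0):
        raise ValueError("group SDs must be positive")
    res = sps.ttest_ind_from_stats(m2, s2, n2, m1, s1, n1, equal_var=True)
    return float(res.statistic), int(n1 + n2 - 2), float(res.pvalue)


def paired_t(before: Sequence[float], after: Sequence[float]) -> tuple[float, float]:
    """Paired Student's t test (two-sided) on after − before.

    Zero-variance differences are degenerate: identical pairs give (0, 1);
    a constant nonzero shift gives p → 0 with a warning.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    if len(before) < 2:
        raise ValueError("need at least 2 pairs")
    d = after - before
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        warnings.warn("zero-variance nonzero differences: p reported as 0")
        return math.copysign(math.inf, d[0]), 0.0
    res = sps.ttest_rel(after, before)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), p by t-approximation.

    Returns (nan, nan) with a warning for a constant input vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-D vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined")
        return math.nan, math.nan
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Full classification grid
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    variable: str          # e.g. "sbp"
    scale: str             # "abs" | "rel"
    sv_threshold_pct: float
    auc: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    youden_threshold: Optional[float] = None
    sens_pct: Optional[float] = None
    spec_pct: Optional[float] = None
    ppv_pct: Optional[float] = None
    npv_pct: Optional[float] = None
    n_resp: int = 0
    n_nonresp: int = 0
    missing_reason: Optional[str] = None


@dataclass
class GroupComparison:
    variable: str
    scale: str
    mean_resp: float
    sd_resp: float
    mean_nonresp: float
    sd_nonresp: float
    n_resp: int
    n_nonresp: int
    t_stat: float
    p_two_sided: float


def run_classification(
    summaries: pd.DataFrame,
    sv_thresholds: Sequence[float] = (10.0, 15.0),
    scales: Sequence[str] = ("abs", "rel"),
) -> tuple[list[ClassificationResult], list[GroupComparison]]:
    """Evaluate every predictor (variable × scale) at each SV threshold.

    ``summaries`` is the patient-summary table (one row per patient with
    ``delta_abs_*``/``delta_rel_*`` columns and ``dsv_rel_pct``).  Group sizes
    are data-driven per variable: patients with a missing (QC-excluded) value
    drop out of that variable's rows only.  Rows whose labels collapse to a
    single class, or with fewer than 2 patients per class, are reported
    missing with a reason.  Group comparisons (means, SDs, pooled t) are
    computed at the first SV threshold.
    """
    results: list[ClassificationResult] = []
    comparisons: list[GroupComparison] = []
    for thr in sv_thresholds:
        labels_all = summaries["dsv_rel_pct"].to_numpy(dtype=float) >= thr
        for var in VARIABLES:
            for scale in scales:
                col = f"delta_{scale}_{var}"
                res = ClassificationResult(variable=var, scale=scale, sv_threshold_pct=float(thr))
                if col not in summaries.columns:
                    res.missing_reason = f"column {col} absent"
                    results.append(res)
                    continue
                scores = summaries[col].to_numpy(dtype=float)
                mask = np.isfinite(scores)
                sc, lb = scores[mask], labels_all[mask]
                res.n_resp = int(lb.sum())
                res.n_nonresp = int((~lb).sum())
                if res.n_resp < 2 or res.n_nonresp < 2:
                    res.missing_reason = "fewer than 2 patients in a class"
                    results.append(res)
                    continue
                roc = roc_auc(sc, lb)
                yt = youden_threshold(sc, lb)
                tp = int(np.sum(sc[lb] > yt.threshold))
                fn = res.n_resp - tp
                fp = int(np.sum(sc[~lb] > yt.threshold))
                tn = res.n_nonresp - fp
                conf = confusion_stats(tp, fn, fp, tn)
                res.auc, res.ci_low, res.ci_high = roc.auc, roc.ci_low, roc.ci_high
                res.youden_threshold = yt.threshold
                res.sens_pct, res.spec_pct = conf.sens_pct, conf.spec_pct
                res.ppv_pct, res.npv_pct = conf.ppv_pct, conf.npv_pct
                results.append(res)
                if thr == sv_thresholds[0]:
                    comparisons.append(
                        GroupComparison(
                            variable=var, scale=scale,
                            mean_resp=float(sc[lb].mean()), sd_resp=float(sc[lb].std(ddof=1)),
                            mean_nonresp=float(sc[~lb].mean()), sd_nonresp=float(sc[~lb].std(ddof=1)),
                            n_resp=res.n_resp, n_nonresp=res.n_nonresp,
                            t_stat=two_sample_t_pooled(x1=sc[~lb], x2=sc[lb])[0],
                            p_two_sided=two_sample_t_pooled(x1=sc[~lb], x2=sc[lb])[2],
                        )
                    )
    return results, comparisons


def format_report(results: list[ClassificationResult], comparisons: list[GroupComparison]) -> str:
    """Human-readable report (percentages as integers, p to 2 decimals)."""
    lines = ["Classification of fluid responsiveness by post-ectopic changes", ""]
    lines.append(f"{'predictor':<12}{'SV thr':>7}{'AUC':>7}{'CI':>16}{'thr':>9}{'sens':>6}{'spec':>6}{'ppv':>6}{'npv':>6}")
    for r in results:
        name = f"{r.variable}_{r.scale}"
        if r.missing_reason:
            lines.append(f"{name:<12}{r.sv_threshold_pct:>6.0f}%  missing ({r.missing_reason})")
            continue
        def pct(v):
            return "  na" if v is None else f"{round_half_up(v):>4d}"
        lines.append(
            f"{name:<12}{r.sv_threshold_pct:>6.0f}%{r.auc:>7.2f}"
            f"  [{r.ci_low:.2f}; {r.ci_high:.2f}]{r.youden_threshold:>9.3g}"
            f"{pct(r.sens_pct):>6}{pct(r.spec_pct):>6}{pct(r.ppv_pct):>6}{pct(r.npv_pct):>6}"
        )
    lines += ["", "Group comparison (responders vs non-responders, pooled t):"]
    for c in comparisons:
        lines.append(
            f"{c.variable}_{c.scale:<6} resp {c.mean_resp:7.2f} ({c.sd_resp:.2f}) n={c.n_resp}"
            f"  nonresp {c.mean_nonresp:7.2f} ({c.sd_nonresp:.2f}) n={c.n_nonresp}"
            f"  p={c.p_two_sided:.2f}"
        )
    return "\n".join(lines) + "\n"
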