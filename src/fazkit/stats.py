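"""Method-agreement and longitudinal statistics over FAZ measurement tables.

Two questions drive the analysis of a two-method FAZ study:

* Do the script-based and classifier-based areas agree?  Answered per
  plexus, pooling visits, with the Pearson correlation (Fisher-z 95% CI)
  and a Bland–Altman analysis (bias = mean paired difference,
  limits of agreement = bias ± 1.96 sd).
* Does the FAZ change across visits?  Answered per plexus and method with
  a repeated-measures ANOVA (additive subject + visit model on complete
  cases) followed by Tukey-adjusted pairwise visit comparisons via the
  studentized-range distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import MeasurementTable

__all__ = [
    "PearsonCI",
    "BlandAltman",
    "RMAnovaResult",
    "PairwiseComparison",
    "AgreementReport",
    "LongitudinalReport",
    "pearson_with_ci",
    "bland_altman",
    "rm_anova_matrix",
    "rm_anova",
    "tukey_pairwise_matrix",
    "tukey_pairwise",
    "studentized_range_cdf",
    "agreement_report",
    "longitudinal_report",
]


# ---------------------------------------------------------------------------
# correlation


@dataclass(frozen=True)
class PearsonCI:
    n: int
    r: float
    ci_low: float
    ci_high: float
    p_value: float


def pearson_with_ci(x, y, alpha: float = 0.05) -> PearsonCI:
    """Pearson correlation with a Fisher-z confidence interval.

    The CI is ``tanh(atanh(r) ± z_{1−α/2} / √(n−3))``; the two-sided p
    comes from the exact t reference distribution with n−2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 pairs, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    z = sps.norm.ppf(1 - alpha / 2)
    if abs(r) >= 1.0:
        lo, hi = r, r
    else:
        zr = np.arctanh(r)
        half = z / np.sqrt(n - 3)
        lo, hi = np.tanh(zr - half), np.tanh(zr + half)
    return PearsonCI(n=n, r=float(r), ci_low=float(lo), ci_high=float(hi), p_value=float(p))


# ---------------------------------------------------------------------------
# Bland–Altman


@dataclass(frozen=True)
class BlandAltman:
    n: int
    bias: float
    loa_low: float
    loa_high: float
    sd: float
    means: np.ndarray
    diffs: np.ndarray
    outlier_idx: tuple[int, ...]


def bland_altman(x, y) -> BlandAltman:
    """Paired-difference agreement analysis.

    Differences are x − y; bias is their mean and the 95% limits of
    agreement are bias ± 1.96 × sample sd (n−1).  Pairs falling outside
    the limits are flagged by index.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    n = len(x)
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    out = tuple(int(i) for i in np.nonzero((d < lo) | (d > hi))[0])
    return BlandAltman(
        n=n, bias=bias, loa_low=lo, loa_high=hi, sd=sd,
        means=(x + y) / 2.0, diffs=d, outlier_idx=out,
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


@dataclass(frozen=True)
class RMAnovaResult:
    F: float
    df1: int
    df2: int
    p_value: float
    n_subjects: int
    k: int
    ms_error: float
    group_means: np.ndarray
    n_dropped_incomplete: int = 0


def rm_anova_matrix(data: np.ndarray, n_dropped: int = 0) -> RMAnovaResult:
    """Repeated-measures ANOVA on a complete n-subjects × k-conditions matrix.

    Additive model ``y_ij = μ + subject_i + condition_j + ε_ij``; the F
    statistic for the condition effect has df1 = k−1, df2 = (n−1)(k−1).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be an n × k matrix")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 conditions, got {n} x {k}")
    grand = data.mean()
    subj_means = data.mean(axis=1)
    cond_means = data.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = max(ss_err, 0.0) / df2
    if ms_err == 0.0:
        f = 0.0 if ms_cond == 0.0 else np.inf
    else:
        f = ms_cond / ms_err
    p = 1.0 if f == 0.0 else float(sps.f.sf(f, df1, df2))
    return RMAnovaResult(
        F=float(f), df1=df1, df2=df2, p_value=p, n_subjects=n, k=k,
        ms_error=float(ms_err), group_means=cond_means, n_dropped_incomplete=n_dropped,
    )


def _visit_matrix(table: MeasurementTable, plexus: str, method: str) -> tuple[np.ndarray, int]:
    """Complete-case n × 4 visit matrix for one plexus and method."""
    df = table.records
    sel = df[(df["plexus"] == plexus) & (df["method"] == method)]
    wide = sel.pivot_table(
        index=["subject_id", "eye"], columns="visit", values="area_mm2", aggfunc="first"
    )
    wide = wide.reindex(columns=[1, 2, 3, 4])
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if len(complete) < 2:
        raise ValueError(
            f"need >= 2 subjects with all 4 visits for {plexus}/{method}; "
            f"have {len(complete)} ({n_dropped} incomplete dropped)"
        )
    return complete.to_numpy(), n_dropped


def rm_anova(table: MeasurementTable, plexus: str, method: str) -> RMAnovaResult:
    """Repeated-measures ANOVA of FAZ area across visits 1–4.

    Only eyes with all four visits contribute (complete-case analysis);
    the number of dropped incomplete eyes is reported on the result.
    """
    data, n_dropped = _visit_matrix(table, plexus, method)
    return rm_anova_matrix(data, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Tukey pairwise comparisons


@dataclass(frozen=True)
class PairwiseComparison:
    i: int
    j: int
    diff: float
    q: float
    p_adj: float


def studentized_range_cdf(q: float, k: int, df: int) -> float:
    """CDF of the studentized range Q(k, df) at q."""
    if k < 2 or df < 1:
        raise ValueError("need k >= 2 and df >= 1")
    if q < 0:
        raise ValueError("q must be nonnegative")
    if q == 0:
        return 0.0
    return float(sps.studentized_range.cdf(q, k, df))


def tukey_pairwise_matrix(
    data: np.ndarray, anova: RMAnovaResult | None = None
) -> list[PairwiseComparison]:
    """Tukey-adjusted all-pairs comparisons of condition means.

    For conditions i < j, ``q = |mean_i − mean_j| / √(MS_error / n)`` with
    MS_error and df2 from the repeated-measures ANOVA; the adjusted p is
    the studentized-range tail probability at q.
    """
    data = np.asarray(data, dtype=float)
    res = anova if anova is not None else rm_anova_matrix(data)
    n, k = data.shape
    se = np.sqrt(res.ms_error / n)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(res.group_means[i] - res.group_means[j])
            if se == 0.0:
                q = 0.0 if diff == 0.0 else np.inf
                p = 1.0 if diff == 0.0 else 0.0
            else:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, res.k, res.df2))
            out.append(PairwiseComparison(i=i + 1, j=j + 1, diff=diff, q=float(q), p_adj=p))
    return out


def tukey_pairwise(table: MeasurementTable, plexus: str, method: str) -> list[PairwiseComparison]:
    """Tukey-adjusted pairwise visit comparisons (all 6 visit pairs)."""
    data, _ = _visit_matrix(table, plexus, method)
    return tukey_pairwise_matrix(data)


# ---------------------------------------------------------------------------
# reports


@dataclass
class AgreementReport:
    """Cross-method agreement for one plexus, visits pooled."""

    plexus: str
    n: int
    pearson_r: float
    ci_low: float
    ci_high: float
    p_value: float
    bias: float
    loa_low: float
    loa_high: float
    outlier_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "plexus": self.plexus,
            "n": self.n,
            "pearson_r": self.pearson_r,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "outlier_ids": self.outlier_ids,
        }


def agreement_report(table: MeasurementTable, plexus: str) -> AgreementReport:
    """Script-vs-classifier agreement for one plexus, pooling all visits.

    Scans are paired by (subject, eye, visit); differences are
    script − ml in mm².
    """
    df = table.records
    sel = df[df["plexus"] == plexus]
    wide = sel.pivot_table(
        index=["subject_id", "eye", "visit"], columns="method", values="area_mm2", aggfunc="first"
    )
    if "script" not in wide.columns or "ml" not in wide.columns:
        raise ValueError(f"both methods required for agreement in plexus {plexus}")
    paired = wide.dropna(subset=["script", "ml"])
    x = paired["script"].to_numpy()
    y = paired["ml"].to_numpy()
    pc = pearson_with_ci(x, y)
    ba = bland_altman(x, y)
    ids = [
        f"{s}/{e}/v{v}" for (s, e, v) in (paired.index[i] for i in ba.outlier_idx)
    ]
    return AgreementReport(
        plexus=plexus,
        n=pc.n,
        pearson_r=pc.r,
        ci_low=pc.ci_low,
        ci_high=pc.ci_high,
        p_value=pc.p_value,
        bias=ba.bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        outlier_ids=ids,
    )


@dataclass
class LongitudinalReport:
    """Visit-effect analysis for one plexus and one method."""

    plexus: str
    method: str
    F: float
    df1: int
    df2: int
    p_value: float
    n_complete_subjects: int
    n_dropped_incomplete: int
    visit_means: list[float]
    pairwise: list[PairwiseComparison]

    def to_dict(self) -> dict:
        return {
            "plexus": self.plexus,
            "method": self.method,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p_value": self.p_value,
            "n_complete_subjects": self.n_complete_subjects,
            "n_dropped_incomplete": self.n_dropped_incomplete,
            "visit_means": self.visit_means,
            "pairwise": [
                {"visit_i": c.i, "visit_j": c.j, "diff": c.diff, "q": c.q, "p_adj": c.p_adj}
                for c in self.pairwise
            ],
        }


def longitudinal_report(table: MeasurementTable, plexus: str, method: str) -> LongitudinalReport:
    data, n_dropped = _visit_matrix(table, plexus, method)
    res = rm_anova_matrix(data, n_dropped=n_dropped)
    pairs = tukey_pairwise_matrix(data, anova=res)
    return LongitudinalReport(
        plexus=plexus,
        method=method,
        F=res.F,
        df1=res.df1,
        df2=res.df2,
        p_value=res.p_value,
        n_complete_subjects=res.n_subjects,
        n_dropped_incomplete=n_dropped,
        visit_means=[float(m) for m in res.group_means],
        pairwise=pairs,
    )
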