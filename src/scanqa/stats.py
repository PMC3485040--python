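"""Test-retest reliability statistics for metric tables.

A study produces a value for every (subject, condition, metric) cell.  Two
assessments quantify reproducibility across scanner conditions:

* one-way ANOVA across conditions — does the condition shift the group mean?
* the intraclass correlation ICC(3,1), the Shrout-Fleiss consistency form

      ICC = (BMS - EMS) / (BMS + (k - 1) * EMS)

  where BMS is the between-subject mean square and EMS the residual mean
  square of the two-way (subject x condition) decomposition and k the number
  of conditions.  ICC near 1 means between-subject variance dominates the
  condition error (good hardware reproducibility); near 0 means condition
  error dominates.

``anova_from_summary`` rebuilds a balanced one-way ANOVA from per-condition
means and standard errors alone, which lets published summary tables be
checked without the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MetricTable",
    "AnovaResult",
    "IccResult",
    "one_way_anova",
    "anova_from_summary",
    "icc_consistency",
    "paired_ttest",
    "metric_report",
]


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    mode: str = "one-way"


@dataclass
class IccResult:
    """ICC(3,1) with its variance components.

    ``icc`` is clipped to [0, 1] (the conventional reporting range);
    ``icc_raw`` keeps the unclipped value, which can be negative when the
    condition error exceeds the between-subject spread."""

    icc: float
    icc_raw: float
    bms: float
    ems: float
    k: int
    n_subjects: int
    defined: bool = True


@dataclass
class MetricTable:
    """Long-format (subject, condition, metric, value) container."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "condition", "metric", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"metric table missing columns: {sorted(missing)}")
        dup = self.data.duplicated(subset=["subject", "condition", "metric"])
        if dup.any():
            raise ValueError("duplicate (subject, condition, metric) cells")

    @property
    def metrics(self) -> list:
        return sorted(self.data["metric"].unique())

    @property
    def conditions(self) -> list:
        return sorted(self.data["condition"].unique())

    def wide(self, metric: str) -> pd.DataFrame:
        """subjects x conditions matrix for one metric (may contain NaN)."""
        sub = self.data[self.data["metric"] == metric]
        return sub.pivot(index="subject", columns="condition", values="value")


def one_way_anova(groups) -> AnovaResult:
    """Classic between/within sums-of-squares decomposition.

    ``groups`` is a sequence of 1D value arrays, one per condition; each must
    hold at least two values.  F is MSB/MSW with (k-1, N-k) degrees of
    freedom; if the within-group variance is zero and the means agree, F is 0
    (all data identical), otherwise infinite."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs at least 2 values")
    k = len(groups)
    ns = np.array([g.size for g in groups])
    n_total = int(ns.sum())
    grand = np.concatenate(groups).mean()
    ssb = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, groups)))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    dfb, dfw = k - 1, n_total - k
    msb, msw = ssb / dfb, ssw / dfw
    if msw == 0:
        f = 0.0 if msb == 0 else np.inf
    else:
        f = msb / msw
    p = float(sps.f.sf(f, dfb, dfw)) if np.isfinite(f) else 0.0
    if f == 0:
        p = 1.0
    return AnovaResult(f=float(f), df_between=dfb, df_within=dfw, p=p)


def anova_from_summary(means, ses, n_per_group: int) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group means and standard errors.

    For balanced groups the decomposition depends on the data only through
    the group means and variances: sd = se * sqrt(n), MSW = mean of group
    variances, MSB = n * sum((m_i - mbar)^2) / (k - 1)."""
    means = np.asarray(means, dtype=float).ravel()
    ses = np.asarray(ses, dtype=float).ravel()
    if means.size != ses.size:
        raise ValueError("means and ses must have equal length")
    if means.size < 2:
        raise ValueError("need at least 2 groups")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    k = means.size
    n = n_per_group
    variances = (ses * np.sqrt(n)) ** 2
    msw = float(variances.mean())
    msb = float(n * ((means - means.mean()) ** 2).sum() / (k - 1))
    f = msb / msw
    dfb, dfw = k - 1, k * (n - 1)
    p = float(sps.f.sf(f, dfb, dfw)) if f > 0 else 1.0
    return AnovaResult(f=f, df_between=dfb, df_within=dfw, p=p, mode="from-summary")


def icc_consistency(table) -> IccResult:
    """ICC(3,1) from a complete subjects x conditions matrix.

    Two-way mean squares: BMS over subjects (k values each), EMS the residual
    after removing subject and condition main effects.  An all-equal table
    has BMS = EMS = 0 and the ICC is flagged undefined."""
    x = np.asarray(
        table.values if isinstance(table, pd.DataFrame) else table, dtype=float
    )
    if x.ndim != 2:
        raise ValueError("table must be 2D (subjects x conditions)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if np.any(~np.isfinite(x)):
        raise ValueError("ICC requires a complete table (no missing cells)")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    cond_means = x.mean(axis=0)
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_cond
    bms = ss_subj / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if bms == 0 and ems == 0:
        return IccResult(np.nan, np.nan, 0.0, 0.0, k, n, defined=False)
    raw = (bms - ems) / (bms + (k - 1) * ems)
    return IccResult(
        icc=float(np.clip(raw, 0.0, 1.0)), icc_raw=float(raw),
        bms=float(bms), ems=float(ems), k=k, n_subjects=n,
    )


def paired_ttest(condition_a, condition_b) -> tuple[float, float]:
    """Paired t-test on the per-subject differences; two-sided p, n-1 df."""
    a = np.asarray(condition_a, dtype=float).ravel()
    b = np.asarray(condition_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero difference variance; paired t undefined")
    t = float(d.mean() / (sd / np.sqrt(d.size)))
    p = float(2 * sps.t.sf(abs(t), d.size - 1))
    return t, p


@dataclass
class MetricSummary:
    metric: str
    conditions: list
    means: list
    ses: list
    anova: AnovaResult | None
    icc: IccResult | None
    posthoc: dict = field(default_factory=dict)  # condition -> (t, p) vs reference
    warnings: list = field(default_factory=list)


def metric_report(
    table: MetricTable, reference_condition=None
) -> list[MetricSummary]:
    """Per-metric reproducibility summary across conditions.

    For each metric: per-condition mean and standard error, one-way ANOVA
    F/p, ICC(3,1) (skipped with a warning if the subject x condition table is
    incomplete), and optional paired-t post-hoc comparisons of every other
    condition against ``reference_condition``."""
    out = []
    for metric in table.metrics:
        wide = table.wide(metric)
        conds = list(wide.columns)
        means = [float(wide[c].mean()) for c in conds]
        ses = [
            float(wide[c].std(ddof=1) / np.sqrt(wide[c].count())) if wide[c].count() > 1 else np.nan
            for c in conds
        ]
        warnings_ = []
        anova = icc = None
        groups = [wide[c].dropna().values for c in conds]
        try:
            anova = one_way_anova(groups)
        except ValueError as exc:
            warnings_.append(f"ANOVA skipped: {exc}")
        if wide.isna().any().any():
            warnings_.append("ICC skipped: incomplete subject x condition table")
        elif len(conds) >= 2 and wide.shape[0] >= 2:
            icc = icc_consistency(wide)
            if not icc.defined:
                warnings_.append("ICC undefined: all cells equal")
        else:
            warnings_.append("ICC skipped: needs >= 2 subjects and conditions")
        posthoc = {}
        if reference_condition is not None and reference_condition in conds:
            ref = wide[reference_condition]
            for c in conds:
                if c == reference_condition:
                    continue
                paired = wide[[c, reference_condition]].dropna()
                try:
                    posthoc[c] = paired_ttest(paired[c].values, ref[paired.index].values)
                except ValueError as exc:
                    warnings_.append(f"post-hoc {c} vs {reference_condition} skipped: {exc}")
        out.append(
            MetricSummary(metric, conds, means, ses, anova, icc, posthoc, warnings_)
        )
    return out


__all__ += ["MetricSummary"]
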