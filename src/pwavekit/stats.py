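"""Cohort statistics for pre/post ablation P-wave parameters.

Implements the study's statistical pipeline on a patient table: paired
pre/post comparisons per group, comparison of changes between groups, a
univariable-screen Cox proportional-hazards analysis (covariates with
univariable p below a threshold enter a single multivariable model),
intraobserver variability summaries, and post hoc power.

Test selection follows the usual normality gate: Shapiro-Wilk at alpha
0.05 decides between the parametric test (paired/unpaired t) and its rank
alternative (Wilcoxon signed-rank / Mann-Whitney U).

The :class:`CohortAnalysis` model object wraps these operations in a
from_dataframe -> fit -> results -> summary() workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats as sst
from statsmodels.stats.power import TTestIndPower

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class PairedTestResult:
    mean_change: float
    statistic: float
    p_value: float
    test: str           # "paired_t", "wilcoxon", or "degenerate"
    n: int


@dataclass(frozen=True)
class GroupChangeResult:
    difference: float   # failure - success mean change
    statistic: float
    p_value: float
    test: str           # "unpaired_t" or "mann_whitney"
    n_success: int
    n_failure: int


def _is_normal(x: np.ndarray) -> bool:
    if np.ptp(x) == 0 or len(x) < 3:
        return False
    return sst.shapiro(x).pvalue > NORMALITY_ALPHA


def paired_change_test(pre, post) -> PairedTestResult:
    """Pre/post comparison of one parameter within one group.

    Uses the paired t-test when the within-patient changes pass the
    normality gate, the Wilcoxon signed-rank test otherwise. A fully
    degenerate comparison (all changes identical) is flagged: p = 1 when
    the common change is zero, p = 0 otherwise.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (same length)")
    if len(pre) < 3:
        raise ValueError("need at least 3 paired values")
    diff = post - pre
    mean_change = float(diff.mean())
    if np.ptp(diff) == 0:
        return PairedTestResult(mean_change, np.nan,
                                1.0 if mean_change == 0 else 0.0,
                                "degenerate", len(diff))
    if _is_normal(diff):
        res = sst.ttest_rel(post, pre)
        return PairedTestResult(mean_change, float(res.statistic),
                                float(res.pvalue), "paired_t", len(diff))
    res = sst.wilcoxon(post, pre)
    return PairedTestResult(mean_change, float(res.statistic),
                            float(res.pvalue), "wilcoxon", len(diff))


def between_group_change_test(changes_success, changes_failure) -> GroupChangeResult:
    """Compare parameter changes between the failure and success arms.

    The reported difference is failure minus success. Student's t when
    both groups pass the normality gate, Mann-Whitney U otherwise.
    """
    cs = np.asarray(changes_success, dtype=float)
    cf = np.asarray(changes_failure, dtype=float)
    if len(cs) < 3 or len(cf) < 3:
        raise ValueError("each group needs at least 3 values")
    diff = float(cf.mean() - cs.mean())
    if _is_normal(cs) and _is_normal(cf):
        res = sst.ttest_ind(cf, cs)
        return GroupChangeResult(diff, float(res.statistic), float(res.pvalue),
                                 "unpaired_t", len(cs), len(cf))
    res = sst.mannwhitneyu(cf, cs, alternative="two-sided")
    return GroupChangeResult(diff, float(res.statistic), float(res.pvalue),
                             "mann_whitney", len(cs), len(cf))


def cox_screen_and_fit(
    cohort: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time_months",
    event_col: str = "event",
    threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariable screen followed by one multivariable Cox model.

    Each candidate covariate is first fitted alone against the event
    process; covariates whose univariable p-value is below ``threshold``
    enter a single multivariable model together. Ties in the partial
    likelihood use lifelines' Efron handling (appropriate for the
    coarse, visit-binned event times of ablation follow-up).

    Returns ``(univariable, multivariable)`` tidy frames with columns
    ``term, hr, ci_low, ci_high, p, stage``; the multivariable frame is
    empty when no covariate survives the screen.
    """
    if cohort[event_col].sum() < 10:
        raise ValueError("need at least 10 events for Cox regression")
    uni_rows = []
    for cov in covariates:
        uni_rows.append(_fit_cox(cohort, [cov], duration_col, event_col, "univariable"))
    uni = pd.concat(uni_rows, ignore_index=True)
    selected = uni.loc[uni["p"] < threshold, "term"].tolist()
    if selected:
        multi = _fit_cox(cohort, selected, duration_col, event_col, "multivariable")
    else:
        multi = uni.iloc[0:0].copy()
    return uni, multi


def _fit_cox(df, covs, duration_col, event_col, stage) -> pd.DataFrame:
    sub = df[covs + [duration_col, event_col]].dropna()
    for cov in covs:
        if np.ptp(sub[cov].to_numpy(dtype=float)) == 0:
            raise ValueError(f"covariate {cov!r} is constant; cannot fit")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(sub, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise ValueError(
            f"Cox model did not converge for covariate(s) {covs}: {err}"
        ) from err
    s = cph.summary
    with np.errstate(over="ignore"):  # near-separated binaries give huge CIs
        lo = np.exp(s["coef lower 95%"].to_numpy())
        hi = np.exp(s["coef upper 95%"].to_numpy())
    return pd.DataFrame(
        {
            "term": s.index,
            "hr": s["exp(coef)"].to_numpy(),
            "ci_low": lo,
            "ci_high": hi,
            "p": s["p"].to_numpy(),
            "stage": stage,
        }
    )


def intraobserver_variability(
    pass1: pd.DataFrame, pass2: pd.DataFrame, parameters: list[str] | None = None
) -> pd.DataFrame:
    """Repeatability of duplicate measurement passes.

    Both tables must be indexed identically (same records in the same
    order, or a shared index). For each parameter the report gives the
    mean and SD of the absolute pass-to-pass differences and the percent
    variability, mean |difference| over the grand mean magnitude of the
    parameter across both passes.
    """
    if parameters is None:
        parameters = [c for c in pass1.columns if c in pass2.columns]
    if not pass1.index.equals(pass2.index):
        raise ValueError("measurement passes cover different records (mismatched keys)")
    rows = []
    for p in parameters:
        if p not in pass1.columns or p not in pass2.columns:
            raise ValueError(f"parameter {p!r} missing from one pass")
        a = pass1[p].to_numpy(dtype=float)
        b = pass2[p].to_numpy(dtype=float)
        d = np.abs(a - b)
        grand = abs(float(np.mean(np.concatenate([a, b]))))
        rows.append(
            dict(
                parameter=p,
                mean_abs_diff=float(d.mean()),
                sd_abs_diff=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
                percent_variability=(float(d.mean()) / grand * 100.0) if grand > 0 else np.nan,
            )
        )
    return pd.DataFrame(rows)


def posthoc_power(n1: int, n2: int, effect_size: float, alpha: float = 0.05) -> float:
    """Two-sample t-test power at a standardized mean difference (Cohen's d)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("both group sizes must be >= 2")
    power = TTestIndPower().power(
        effect_size=effect_size, nobs1=n1, ratio=n2 / n1, alpha=alpha,
        alternative="two-sided",
    )
    return float(power)


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

DEFAULT_PARAMETERS = ("pwdc_ms", "pwa_mv", "pwdisp_ms", "ptfv1_mm_s")


@dataclass
class CohortAnalysis:
    """The study's cohort analysis as a fittable model.

    Built from a tidy patient table carrying ``<param>_pre`` /
    ``<param>_post`` columns, a group label, the event flag and follow-up
    time, and any candidate Cox covariates. ``fit`` runs the paired
    pre/post tests per arm, the between-arm change tests, and the
    univariable-screen Cox regression, returning a
    :class:`CohortAnalysisResults`.
    """

    data: pd.DataFrame
    parameters: tuple[str, ...] = DEFAULT_PARAMETERS
    group_col: str = "group"
    duration_col: str = "time_months"
    event_col: str = "event"
    covariates: list[str] = field(default_factory=list)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        parameters: tuple[str, ...] = DEFAULT_PARAMETERS,
        group_col: str = "group",
        duration_col: str = "time_months",
        event_col: str = "event",
        covariates: list[str] | None = None,
    ) -> "CohortAnalysis":
        for p in parameters:
            for stage in ("pre", "post"):
                if f"{p}_{stage}" not in data.columns:
                    raise ValueError(f"missing column {p}_{stage}")
        if covariates is None:
            covariates = [c for c in (f"{p}_change" for p in parameters) if c in data.columns]
        return cls(data, parameters, group_col, duration_col, event_col, covariates)

    def fit(self, threshold: float = 0.05) -> "CohortAnalysisResults":
        df = self.data
        paired_rows = []
        between_rows = []
        for p in self.parameters:
            pre, post = f"{p}_pre", f"{p}_post"
            for grp, sub in df.groupby(self.group_col):
                r = paired_change_test(sub[pre], sub[post])
                paired_rows.append(
                    dict(parameter=p, group=grp, n=r.n,
                         mean_pre=float(sub[pre].mean()),
                         mean_post=float(sub[post].mean()),
                         mean_change=r.mean_change, p=r.p_value, test=r.test)
                )
            grps = dict(list(df.groupby(self.group_col)))
            if {"success", "failure"} <= set(grps):
                ch_s = grps["success"][post] - grps["success"][pre]
                ch_f = grps["failure"][post] - grps["failure"][pre]
                b = between_group_change_test(ch_s, ch_f)
                between_rows.append(
                    dict(parameter=p, difference=b.difference, p=b.p_value, test=b.test)
                )
        uni, multi = (pd.DataFrame(), pd.DataFrame())
        if self.covariates:
            uni, multi = cox_screen_and_fit(
                df, self.covariates, self.duration_col, self.event_col, threshold
            )
        return CohortAnalysisResults(
            model=self,
            paired=pd.DataFrame(paired_rows),
            between=pd.DataFrame(between_rows),
            cox_univariable=uni,
            cox_multivariable=multi,
            threshold=threshold,
        )


@dataclass
class CohortAnalysisResults:
    """Fitted cohort analysis: tidy tables plus a printable summary."""

    model: CohortAnalysis
    paired: pd.DataFrame
    between: pd.DataFrame
    cox_univariable: pd.DataFrame
    cox_multivariable: pd.DataFrame
    threshold: float

    def summary(self) -> str:
        lines = ["Cohort analysis", "=" * 60]
        n = len(self.model.data)
        ev = int(self.model.data[self.model.event_col].sum()) if self.model.event_col in self.model.data else 0
        lines.append(f"patients: {n}; events: {ev}; screen threshold p < {self.threshold:g}")
        lines.append("")
        lines.append("Paired pre/post comparisons")
        lines.append(self.paired.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        if len(self.between):
            lines.append("")
            lines.append("Change between arms (failure - success)")
            lines.append(self.between.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        if len(self.cox_univariable):
            lines.append("")
            lines.append("Cox regression (univariable screen -> multivariable)")
            both = pd.concat([self.cox_univariable, self.cox_multivariable], ignore_index=True)
            lines.append(both.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def to_tidy(self) -> pd.DataFrame:
        """All Cox terms in one tidy frame (term, stage, hr, ci, p)."""
        return pd.concat(
            [self.cox_univariable, self.cox_multivariable], ignore_index=True
        )
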