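"""Agreement metrics and subgroup hypothesis testing for age estimates.

Implements the evaluation battery for chronological vs estimated age:
MAE, RMSE, absolute-error range, Pearson R, coefficient of determination
(squared Pearson R by default; a variance-explained form is available),
Bland-Altman bias and 95% limits of agreement, and covariate-subgroup
comparisons with a normality/homoscedasticity gate choosing between the
independent t-test and the Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "EvaluationReport",
    "BlandAltman",
    "GroupComparison",
    "regression_metrics",
    "bland_altman",
    "compare_groups",
    "full_report",
]


@dataclass
class BlandAltman:
    """Bias and 95% limits of agreement of estimated - actual age.

    ``loa_low``/``loa_high`` are bias -/+ 1.96 * SD of the differences
    (sample SD, n-1); ``means``/``diffs`` support the classic plot.
    """

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


@dataclass
class EvaluationReport:
    """Agreement metrics between actual and estimated ages (years)."""

    n: int
    mae: float
    rmse: float
    error_range: tuple
    r: float | None
    r2: float | None
    bland_altman: BlandAltman | None = None

    def to_dict(self) -> dict:
        d = {"n": self.n, "mae": self.mae, "rmse": self.rmse,
             "error_min": self.error_range[0], "error_max": self.error_range[1],
             "r": self.r, "r2": self.r2}
        if self.bland_altman is not None:
            d.update({"ba_bias": self.bland_altman.bias,
                      "ba_sd": self.bland_altman.sd_diff,
                      "ba_loa_low": self.bland_altman.loa_low,
                      "ba_loa_high": self.bland_altman.loa_high})
        return d


@dataclass
class GroupComparison:
    """Two-group error comparison with the t / Mann-Whitney dispatch gate.

    The t-test is used iff both groups pass Shapiro-Wilk normality and the
    pair passes Levene's homogeneity of variance at the configured alpha;
    otherwise the Mann-Whitney U test is used.  Tests are two-sided.
    """

    labels: tuple
    reports: dict
    shapiro_p: dict
    levene_p: float
    chosen_test: str
    statistic: float
    p_value: float
    alpha: float = 0.05


def _check_pair(y_true, y_pred, min_n=1):
    y_true = np.asarray(y_true, dtype=float).reshape(-1)
    y_pred = np.asarray(y_pred, dtype=float).reshape(-1)
    if len(y_true) != len(y_pred):
        raise InputError("actual and estimated ages must have equal length")
    if len(y_true) < min_n:
        raise InputError(f"need at least {min_n} pairs, got {len(y_true)}")
    return y_true, y_pred


def regression_metrics(y_true, y_pred, r2_mode: str = "pearson"
                       ) -> EvaluationReport:
    """MAE, RMSE, |error| range, Pearson R and R^2.

    ``r2_mode='pearson'`` (default) squares the correlation coefficient;
    ``'variance'`` uses 1 - SSE/SST.  With fewer than two pairs or a
    constant series, R and R^2 are reported as missing with a warning.
    """
    y_true, y_pred = _check_pair(y_true, y_pred, min_n=1)
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    error_range = (float(np.abs(err).min()), float(np.abs(err).max()))
    r = r2 = None
    if len(y_true) >= 2 and np.std(y_true) > 0 and np.std(y_pred) > 0:
        r = float(sps.pearsonr(y_true, y_pred).statistic)
        if r2_mode == "pearson":
            r2 = r ** 2
        elif r2_mode == "variance":
            sst = float(np.sum((y_true - y_true.mean()) ** 2))
            r2 = 1.0 - float(np.sum(err ** 2)) / sst
        else:
            raise InputError(f"unknown r2_mode {r2_mode!r}")
    else:
        warnings.warn("R undefined for constant or single-point series")
    return EvaluationReport(n=len(y_true), mae=mae, rmse=rmse,
                            error_range=error_range, r=r, r2=r2)


def bland_altman(y_true, y_pred) -> BlandAltman:
    """Bland-Altman agreement of estimated vs actual age.

    Differences are estimated - actual; limits are bias +/- 1.96 * sample
    SD of the differences.
    """
    y_true, y_pred = _check_pair(y_true, y_pred, min_n=2)
    diffs = y_pred - y_true
    means = (y_pred + y_true) / 2.0
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltman(bias=bias, sd_diff=sd,
                       loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
                       means=means, diffs=diffs)


def compare_groups(values_a, values_b, labels=("group", "non-group"),
                   alpha: float = 0.05) -> GroupComparison:
    """Two-sided comparison of two samples (typically estimation errors).

    Dispatch: independent t-test iff Shapiro-Wilk normality holds in both
    groups AND Levene homogeneity holds across them at ``alpha``;
    otherwise Mann-Whitney U.
    """
    a = np.asarray(values_a, dtype=float).reshape(-1)
    b = np.asarray(values_b, dtype=float).reshape(-1)
    if len(a) < 3 or len(b) < 3:
        raise InputError("each group needs at least 3 values for the gate tests")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on near-ties
        sh_a = float(sps.shapiro(a).pvalue)
        sh_b = float(sps.shapiro(b).pvalue)
        lev = float(sps.levene(a, b).pvalue)
        if sh_a > alpha and sh_b > alpha and lev > alpha:
            res = sps.ttest_ind(a, b)
            chosen = "t"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            chosen = "mannwhitneyu"
    return GroupComparison(labels=tuple(labels),
                           reports={}, shapiro_p={labels[0]: sh_a,
                                                  labels[1]: sh_b},
                           levene_p=lev, chosen_test=chosen,
                           statistic=float(res.statistic),
                           p_value=float(res.pvalue), alpha=alpha)


def full_report(predictions: pd.DataFrame, manifest: pd.DataFrame,
                covariates=("hypertension", "diabetes", "alcohol", "smoking"),
                alpha: float = 0.05) -> pd.DataFrame:
    """Per-covariate-level metrics rows plus a Total row.

    ``predictions`` needs columns subject_id, age, predicted_age;
    ``manifest`` supplies the boolean covariate columns.  For each
    covariate with both levels present, the subgroup errors are also
    compared via the dispatch gate; the p-value is attached to both rows.
    Missing covariate columns are skipped with a note row omitted.
    """
    df = predictions.merge(manifest[["subject_id"] +
                                    [c for c in covariates
                                     if c in manifest.columns]],
                           on="subject_id", how="left")
    rows = []

    def metrics_row(sub: pd.DataFrame, dataset: str, group: str,
                    p_value=None) -> dict:
        rep = regression_metrics(sub["age"], sub["predicted_age"])
        ba = bland_altman(sub["age"], sub["predicted_age"]) if len(sub) >= 2 else None
        rep.bland_altman = ba
        row = {"dataset": dataset, "group": group, **rep.to_dict()}
        if p_value is not None:
            row["group_p_value"] = p_value
        return row

    for cov in covariates:
        if cov not in df.columns:
            continue
        pos = df[df[cov].astype(bool)]
        neg = df[~df[cov].astype(bool)]
        p_value = None
        if len(pos) >= 3 and len(neg) >= 3:
            cmp = compare_groups(pos["predicted_age"] - pos["age"],
                                 neg["predicted_age"] - neg["age"],
                                 labels=(cov, f"non-{cov}"), alpha=alpha)
            p_value = cmp.p_value
        if len(pos) >= 1:
            rows.append(metrics_row(pos, cov, cov, p_value))
        if len(neg) >= 1:
            rows.append(metrics_row(neg, cov, f"non-{cov}", p_value))
    rows.append(metrics_row(df, "total", "Total"))
    return pd.DataFrame(rows)


def render_report(report: pd.DataFrame) -> str:
    """Human-readable table of the metric rows."""
    cols = ["group", "n", "mae", "rmse", "error_min", "error_max", "r", "r2"]
    lines = [f"{'Group':<18}{'N':>6}{'MAE':>8}{'RMSE':>8}"
             f"{'ErrMin':>8}{'ErrMax':>8}{'R':>7}{'R2':>7}"]
    for _, row in report.iterrows():
        r = "" if row.get("r") is None or pd.isna(row.get("r")) else f"{row['r']:.2f}"
        r2 = "" if row.get("r2") is None or pd.isna(row.get("r2")) else f"{row['r2']:.2f}"
        lines.append(f"{row['group']:<18}{int(row['n']):>6}{row['mae']:>8.1f}"
                     f"{row['rmse']:>8.1f}{row['error_min']:>8.1f}"
                     f"{row['error_max']:>8.1f}{r:>7}{r2:>7}")
    return "\n".join(lines)
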