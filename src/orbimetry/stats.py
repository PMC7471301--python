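"""Agreement statistics for comparing proptosis measurement methods.

Implements the method-comparison protocol used when validating a new
exophthalmometry method against established ones: repeated-measures one-way
ANOVA with Bonferroni-corrected pairwise paired t-tests across methods,
Pearson correlation between modalities, Bland-Altman limits of agreement,
Cronbach's alpha for intra-observer (repeat) reliability, and intraclass
correlation coefficients ICC(2,1) / ICC(3,1) for inter-rater agreement.

All standard deviations use the n-1 denominator; the Bland-Altman multiplier
is fixed at 1.96.  "Interclass correlation coefficient" in clinical usage is
read as the intraclass correlation coefficient; the default form is
ICC(2,1) (two-way random effects, absolute agreement, single measurement).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MeasurementTable",
    "rm_anova_oneway",
    "bonferroni_pairwise",
    "paired_t",
    "pearson_r",
    "bland_altman",
    "cronbach_alpha",
    "icc",
    "method_summary",
]

REQUIRED_COLUMNS = ["subject_id", "eye", "method", "repeat", "rater", "value_mm", "group"]


@dataclass
class MeasurementTable:
    """Long-format subject x method x repeat x rater measurement records.

    Each eye is treated as an observational unit (a subject-eye pair), with
    the subject id retained; pivoted complete-case matrix views feed the
    statistics below.
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"measurement table missing columns: {missing}")
        if not np.all(np.isfinite(self.data["value_mm"].to_numpy(float))):
            raise ValueError("non-finite measurement values")
        if self.data[["subject_id", "eye"]].drop_duplicates().shape[0] < 2:
            raise ValueError("need at least 2 subject-eye units")

    @classmethod
    def from_csv(cls, path) -> "MeasurementTable":
        return cls(pd.read_csv(path))

    def _units(self, df: pd.DataFrame) -> pd.Series:
        return df["subject_id"].astype(str) + "/" + df["eye"].astype(str)

    def by_method(self, repeat: int = 1, rater: str | None = None, group: str | None = None) -> pd.DataFrame:
        """Complete-case unit x method matrix (one repeat, one rater)."""
        df = self.data[self.data["repeat"] == repeat]
        if rater is None:
            rater = sorted(df["rater"].unique())[0]
        df = df[df["rater"] == rater]
        if group is not None:
            df = df[df["group"] == group]
        wide = df.assign(unit=self._units(df)).pivot(index="unit", columns="method", values="value_mm")
        return wide.dropna()

    def by_repeat(self, method: str, rater: str | None = None) -> pd.DataFrame:
        """Complete-case unit x repeat matrix for one method (one rater)."""
        df = self.data[self.data["method"] == method]
        if rater is None:
            rater = sorted(df["rater"].unique())[0]
        df = df[df["rater"] == rater]
        wide = df.assign(unit=self._units(df)).pivot(index="unit", columns="repeat", values="value_mm")
        return wide.dropna()

    def by_rater(self, method: str, repeat: int = 1) -> pd.DataFrame:
        """Complete-case unit x rater matrix for one method (one repeat)."""
        df = self.data[(self.data["method"] == method) & (self.data["repeat"] == repeat)]
        wide = df.assign(unit=self._units(df)).pivot(index="unit", columns="rater", values="value_mm")
        return wide.dropna()


def _as_matrix(matrix) -> np.ndarray:
    m = np.asarray(matrix, dtype=float) if not isinstance(matrix, pd.DataFrame) else matrix.to_numpy(float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete subject x condition matrix with >= 2 rows and columns")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix has missing or non-finite entries; complete cases required")
    return m


@dataclass
class RMAnovaResult:
    F: float
    df_num: int
    df_den: int
    p: float
    degenerate: bool = False


def rm_anova_oneway(matrix) -> RMAnovaResult:
    """Repeated-measures one-way ANOVA on a subject x condition matrix.

    Classical within-subject decomposition: the condition effect is tested
    against the subject x condition residual, F = MS_cond / MS_error with
    df (k-1, (k-1)(n-1)).  No sphericity correction is applied.
    """
    m = _as_matrix(matrix)
    n, k = m.shape
    grand = m.mean()
    ss_cond = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_num, df_den = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    if ms_err <= 0:
        if ms_cond <= 0:
            return RMAnovaResult(F=0.0, df_num=df_num, df_den=df_den, p=1.0)
        return RMAnovaResult(F=np.inf, df_num=df_num, df_den=df_den, p=0.0, degenerate=True)
    F = ms_cond / ms_err
    p = float(sps.f.sf(F, df_num, df_den))
    return RMAnovaResult(F=float(F), df_num=df_num, df_den=df_den, p=p)


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    degenerate: bool = False


def paired_t(x, y) -> PairedTResult:
    """Two-sided paired t-test; d = x - y, sd with n-1 denominator."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired t-test needs two equal-length vectors, n >= 2")
    d = x - y
    n = len(d)
    md = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if md == 0:
            return PairedTResult(t=0.0, df=n - 1, p=1.0, mean_diff=0.0)
        return PairedTResult(
            t=np.inf if md > 0 else -np.inf, df=n - 1, p=0.0, mean_diff=float(md), degenerate=True
        )
    t = md / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return PairedTResult(t=float(t), df=n - 1, p=p, mean_diff=float(md))


def bonferroni_pairwise(matrix, labels=None) -> dict:
    """Paired t per condition pair, p multiplied by the number of pairs.

    Returns {(label_a, label_b): (raw_p, adjusted_p, mean_diff)} with the
    adjusted p capped at 1.  Pair count is k(k-1)/2.
    """
    if isinstance(matrix, pd.DataFrame) and labels is None:
        labels = list(matrix.columns)
    m = _as_matrix(matrix)
    k = m.shape[1]
    if labels is None:
        labels = list(range(k))
    n_pairs = k * (k - 1) // 2
    out = {}
    for a, b in combinations(range(k), 2):
        res = paired_t(m[:, a], m[:, b])
        out[(labels[a], labels[b])] = (res.p, min(1.0, res.p * n_pairs), res.mean_diff)
    return out


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("pearson_r needs two equal-length vectors, n >= 2")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def bland_altman(x, y) -> tuple:
    """Mean difference and 95% limits of agreement for two paired methods.

    Returns (mean_d, lower_loa, upper_loa) with d = x - y and
    LOA = mean_d -/+ 1.96 * sd(d) (n-1 denominator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("bland_altman needs two equal-length vectors, n >= 2")
    d = x - y
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return md, md - 1.96 * sd, md + 1.96 * sd


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha over a subject x repeat matrix.

    alpha = k/(k-1) * (1 - sum_i var_i / var_total) with per-column
    variances and the variance of per-subject sums, both n-1 denominator.
    """
    m = _as_matrix(matrix)
    k = m.shape[1]
    col_vars = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("no between-subject variance: alpha undefined")
    return float(k / (k - 1) * (1.0 - col_vars.sum() / total_var))


def icc(matrix, form: str = "icc2_1") -> float:
    """Intraclass correlation from a subject x rater matrix.

    Two-way ANOVA decomposition with rows = subjects (MS_R), columns =
    raters (MS_C), residual (MS_E):

    - ``icc2_1`` (two-way random, absolute agreement, single measurement):
      (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)
    - ``icc3_1`` (two-way mixed, consistency, single measurement):
      (MS_R - MS_E) / (MS_R + (k-1) MS_E)
    """
    if form not in ("icc2_1", "icc3_1"):
        raise ValueError("form must be 'icc2_1' or 'icc3_1'")
    m = _as_matrix(matrix)
    n, k = m.shape
    grand = m.mean()
    ss_rows = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if form == "icc3_1":
        denom = ms_r + (k - 1) * ms_e
    else:
        denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom <= 0:
        raise ValueError("degenerate variance structure: ICC undefined")
    return float((ms_r - ms_e) / denom)


def method_summary(table: MeasurementTable, group: str | None = None,
                   repeat: int = 1, rater: str | None = None) -> dict:
    """Per-method mean +/- SD and pairwise mean differences, mm (2 decimals).

    Returns ``{"per_method": {method: {"mean", "sd", "n"}},
    "pairwise_mean_diff": {(a, b): mean_a - mean_b}}``; with a single unit
    the SD is reported as None.
    """
    wide = table.by_method(repeat=repeat, rater=rater, group=group)
    if wide.shape[0] == 0:
        raise ValueError(f"no records for group {group!r}")
    per_method = {}
    for mcol in wide.columns:
        v = wide[mcol].to_numpy(float)
        per_method[mcol] = {
            "mean": round(float(v.mean()), 2),
            "sd": round(float(v.std(ddof=1)), 2) if len(v) > 1 else None,
            "n": int(len(v)),
        }
    pairwise = {}
    for a, b in combinations(list(wide.columns), 2):
        pairwise[(a, b)] = round(per_method[a]["mean"] - per_method[b]["mean"], 2)
    return {"per_method": per_method, "pairwise_mean_diff": pairwise}
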