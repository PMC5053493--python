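"""Longitudinal statistics with explicit missing-data handling.

The longitudinal matrix has one row per observation (a mouse eye) and one
column per month.  Months missing more than 25% of the observations are
eliminated, then observations missing more than 25% of the remaining months;
remaining gaps are filled assuming a linear local trend (interpolation
between the nearest observed neighbours in time, endpoints extrapolated from
the two nearest points).  The within-subject time effect is tested by a
one-way repeated-measures ANOVA with Bonferroni-corrected paired post hoc
comparisons against the baseline month; group comparisons use the
Mann-Whitney U test and associations the Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


def significance_stars(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class TestResult:
    """A named test statistic with p-value(s) and significance stars."""

    name: str
    statistic: float
    p_value: float
    df: tuple | None = None
    adjusted: dict = field(default_factory=dict)   # label -> adjusted p
    flags: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass
class LongitudinalMatrix:
    """Complete observations × months matrix after elimination and imputation."""

    data: pd.DataFrame                 # rows: eye id, columns: month (sorted)
    imputed: pd.DataFrame              # same shape, True where filled
    baseline: int | None = None        # baseline month (column label)
    dropped_columns: list = field(default_factory=list)
    dropped_rows: list = field(default_factory=list)

    @property
    def months(self) -> list:
        return list(self.data.columns)


def prepare_matrix(
    records: pd.DataFrame, max_missing: float = 0.25, baseline: int | None = None
) -> LongitudinalMatrix:
    """Eliminate, then impute, an incomplete observations × months table.

    Columns (months) with a missing fraction strictly above ``max_missing``
    are dropped first, then rows (eyes) by the same rule on the remaining
    columns.  Remaining gaps are linearly interpolated along the month axis
    using the month numbers as the time coordinate; endpoint gaps are
    extrapolated from the two nearest observed points.
    """
    df = records.copy()
    df = df[sorted(df.columns)]
    col_missing = df.isna().mean(axis=0)
    drop_cols = list(df.columns[col_missing > max_missing])
    df = df.drop(columns=drop_cols)
    row_missing = df.isna().mean(axis=1)
    drop_rows = list(df.index[row_missing > max_missing])
    df = df.drop(index=drop_rows)
    if df.empty or df.shape[1] == 0:
        raise ValueError("no data left after the elimination step")

    imputed = df.isna()
    t = np.asarray(df.columns, dtype=float)
    filled = df.to_numpy(dtype=float)
    for r in range(filled.shape[0]):
        row = filled[r]
        obs = np.isfinite(row)
        if obs.all():
            continue
        if obs.sum() < 2:
            raise ValueError(
                f"row {df.index[r]!r} has fewer than two observations to impute from"
            )
        interp = np.interp(t, t[obs], row[obs])
        ti, vi = t[obs], row[obs]
        first_slope = (vi[1] - vi[0]) / (ti[1] - ti[0])
        last_slope = (vi[-1] - vi[-2]) / (ti[-1] - ti[-2])
        before = t < ti[0]
        after = t > ti[-1]
        interp[before] = vi[0] + first_slope * (t[before] - ti[0])
        interp[after] = vi[-1] + last_slope * (t[after] - ti[-1])
        filled[r] = np.where(obs, row, interp)
    data = pd.DataFrame(filled, index=df.index, columns=df.columns)
    if baseline is not None and baseline not in data.columns:
        baseline = None
    if baseline is None and len(data.columns):
        baseline = data.columns[0]
    return LongitudinalMatrix(
        data=data, imputed=imputed, baseline=baseline,
        dropped_columns=drop_cols, dropped_rows=drop_rows,
    )


def rm_anova_bonferroni(
    matrix: LongitudinalMatrix, baseline: int | None = None
) -> TestResult:
    """One-way within-subject ANOVA with Bonferroni post hoc vs baseline.

    Sums of squares decompose into subjects, time and error;
    ``F = MS_time / MS_error`` on ``(k−1, (n−1)(k−1))`` degrees of freedom.
    Post hoc paired t-tests compare each month against the baseline with
    Bonferroni-adjusted ``p' = min(1, p·k_comparisons)``.
    """
    x = matrix.data.to_numpy(dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("repeated-measures ANOVA needs ≥2 subjects and ≥2 months")
    if not np.isfinite(x).all():
        raise ValueError("matrix must be complete; run prepare_matrix first")
    grand = x.mean()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_time = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_time
    df_time = k - 1
    df_err = (n - 1) * (k - 1)
    ms_time = ss_time / df_time
    ms_err = ss_err / df_err
    flags = []
    if ms_err <= 0:
        if ms_time == 0:
            f_stat, p = 0.0, 1.0
            flags.append("zero variance everywhere")
        else:
            f_stat, p = math.inf, 0.0
            flags.append("zero error variance; F infinite")
    else:
        f_stat = ms_time / ms_err
        p = float(sps.f.sf(f_stat, df_time, df_err))
    base = matrix.baseline if baseline is None else baseline
    adjusted = {}
    if base in matrix.data.columns:
        others = [c for c in matrix.data.columns if c != base]
        k_comp = len(others)
        for col in others:
            t_res = sps.ttest_rel(matrix.data[col], matrix.data[base])
            adjusted[f"{col} vs {base}"] = min(1.0, float(t_res.pvalue) * k_comp)
    return TestResult(
        name="repeated-measures ANOVA (time)",
        statistic=float(f_stat),
        p_value=float(p),
        df=(df_time, df_err),
        adjusted=adjusted,
        flags=flags,
        extra={
            "ss_subjects": ss_subj, "ss_time": ss_time, "ss_error": ss_err,
            "sphericity_correction": "none",
        },
    )


def _u_statistic(ranks_a: np.ndarray, n_a: int, n_b: int) -> float:
    u_a = ranks_a.sum() - n_a * (n_a + 1) / 2.0
    return min(u_a, n_a * n_b - u_a)


def mann_whitney_u(a, b, exact_max_n: int = 12) -> TestResult:
    """Mann-Whitney U with midrank ties.

    ``U = min(U_a, U_b)``.  For ``n_a + n_b ≤ exact_max_n`` the two-sided
    p-value is exact: the proportion of all group assignments of the pooled
    sample whose ``min(U_a, U_b)`` is at most the observed one (small values
    of the min statistic are extreme in either direction, so this tail is
    two-sided by construction).  Larger samples use the normal approximation
    with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_a], n_a, n_b)
    n = n_a + n_b
    if n <= exact_max_n:
        count = 0
        total = 0
        for idx in combinations(range(n), n_a):
            u = _u_statistic(ranks[list(idx)], n_a, n_b)
            count += u <= u_obs
            total += 1
        p = count / total
        method = "exact enumeration"
    else:
        mu = n_a * n_b / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            return TestResult(
                name="Mann-Whitney U", statistic=float(u_obs), p_value=1.0,
                flags=["all values tied"], extra={"method": "degenerate"},
            )
        z = (u_obs + 0.5 - mu) / math.sqrt(sigma2)
        p = min(1.0, 2.0 * sps.norm.cdf(z))
        method = "normal approximation with tie correction"
    return TestResult(
        name="Mann-Whitney U",
        statistic=float(u_obs),
        p_value=float(p),
        extra={"method": method, "n_a": n_a, "n_b": n_b},
    )


def pearson_r(x, y) -> TestResult:
    """Sample Pearson correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size ≥3")
    if np.std(x) == 0 or np.std(y) == 0:
        return TestResult(
            name="Pearson correlation", statistic=float("nan"), p_value=float("nan"),
            flags=["zero variance; correlation undefined"],
        )
    res = sps.pearsonr(x, y)
    return TestResult(
        name="Pearson correlation",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=(x.size - 2,),
    )


def report(results: list[TestResult]) -> str:
    """Human-readable multi-line report with significance stars."""
    lines = []
    for r in results:
        df_txt = f", df={r.df}" if r.df else ""
        lines.append(
            f"{r.name}: statistic={r.statistic:.4g}{df_txt}, "
            f"p={r.p_value:.4g} {r.stars}".rstrip()
        )
        for label, p_adj in r.adjusted.items():
            lines.append(
                f"  post hoc {label}: p_adj={p_adj:.4g} "
                f"{significance_stars(p_adj)}".rstrip()
            )
        for flag in r.flags:
            lines.append(f"  note: {flag}")
    return "\n".join(lines)
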