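"""Inferential statistics for the behavioral and network analyses.

Wraps the standard implementations (scipy, statsmodels, pingouin) behind
the small set of tests the study design needs: zero/two-sample/paired t
tests, the 2-group x 3-day mixed repeated-measures ANOVA, Pearson
correlation, Benjamini-Hochberg FDR, edge-wise group contrasts, and the
a-priori noncentral-F sample-size search for the within-between
interaction (G*Power convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestOutcome",
    "PowerSpec",
    "ttest_zero",
    "ttest_ind",
    "ttest_paired",
    "rm_anova_mixed",
    "pearson_corr",
    "fdr_bh",
    "edgewise_ttest",
    "power_rm_interaction",
    "sample_size_rm_anova",
]


@dataclass(frozen=True)
class TestOutcome:
    statistic: float
    df: float | tuple
    p_value: float
    effect: float  # mean difference (t tests) or r (correlation)


def _zero_var_outcome(df):
    warnings.warn("zero variance with zero effect; p = 1 by convention")
    return TestOutcome(0.0, df, 1.0, 0.0)


def ttest_zero(sample) -> TestOutcome:
    """One-sample t test against zero."""
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    if x.std(ddof=1) == 0:
        if x.mean() == 0:
            return _zero_var_outcome(x.size - 1)
        raise ValueError("zero variance with nonzero mean")
    t, p = sstats.ttest_1samp(x, 0.0)
    return TestOutcome(float(t), x.size - 1, float(p), float(x.mean()))


def ttest_ind(a, b, pooled: bool = True) -> TestOutcome:
    """Two-sample t test; pooled variance by default (SPSS-style)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per sample")
    diff = a.mean() - b.mean()
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if diff == 0:
            return _zero_var_outcome(a.size + b.size - 2)
        raise ValueError("zero variance with nonzero difference")
    t, p = sstats.ttest_ind(a, b, equal_var=pooled)
    df = (a.size + b.size - 2 if pooled
          else sstats.ttest_ind(a, b, equal_var=False).df)
    return TestOutcome(float(t), float(df), float(p), float(diff))


def ttest_paired(a, b) -> TestOutcome:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must match, n >= 2")
    d = a - b
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return _zero_var_outcome(d.size - 1)
        raise ValueError("zero variance with nonzero difference")
    t, p = sstats.ttest_rel(a, b)
    return TestOutcome(float(t), d.size - 1, float(p), float(d.mean()))


def rm_anova_mixed(data: pd.DataFrame, dv: str = "value",
                   within: str = "day", between: str = "group",
                   subject: str = "subject") -> pd.DataFrame:
    """Mixed-design repeated-measures ANOVA (subject as random factor).

    Requires a complete balanced design; sphericity is assumed (eps = 1),
    matching the convention the sample-size computation uses.  Returns a
    table with F, dfs and p for the between effect, the within effect and
    their interaction.
    """
    counts = data.groupby([subject, within], observed=True)[dv].count()
    n_cells = data[subject].nunique() * data[within].nunique()
    if len(counts) != n_cells or (counts != 1).any():
        raise ValueError("design must have exactly one value per "
                         "subject x within cell (no missing cells)")
    if data[dv].std(ddof=0) == 0:
        # no variance anywhere: every F is 0 by definition
        levels = ["group", "day", "interaction"]
        g = data[between].nunique()
        m = data[within].nunique()
        s = data[subject].nunique()
        df1 = [g - 1, m - 1, (g - 1) * (m - 1)]
        df2 = [s - g, (s - g) * (m - 1), (s - g) * (m - 1)]
        return pd.DataFrame({"effect": levels, "df1": df1, "df2": df2,
                             "F": 0.0, "p_value": 1.0})
    import pingouin as pg
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.mixed_anova(data=data, dv=dv, within=within,
                             between=between, subject=subject,
                             correction=False)
    out = res.rename(columns={"Source": "effect", "p_unc": "p_value",
                              "DF1": "df1", "DF2": "df2"})
    out["effect"] = out["effect"].replace({"Interaction": "interaction"})
    return out[["effect", "df1", "df2", "F", "p_value"]]


def pearson_corr(x, y) -> TestOutcome:
    """Pearson r with the two-sided t-transform p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = sstats.pearsonr(x, y)
    return TestOutcome(float(r), x.size - 2, float(p), float(r))


def fdr_bh(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: (rejected mask, adjusted p values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return rejected, adjusted


def edgewise_ttest(group_a: np.ndarray, group_b: np.ndarray,
                   alpha: float = 0.01, adjust: bool = False):
    """Independent-sample t test per edge.

    Inputs are (subjects x edges) matrices of per-subject edge summaries
    (mean Fisher z per edge across a period).  Returns a DataFrame with
    one row per edge (t, p, mean difference a-b, selected).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("need subjects x edges matrices on shared edges")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need n >= 2 subjects per group")
    t, p = sstats.ttest_ind(a, b, axis=0, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    if adjust:
        selected, p_eff = fdr_bh(p, alpha)
    else:
        selected, p_eff = p < alpha, p
    return pd.DataFrame({
        "edge": np.arange(a.shape[1]),
        "t": t, "p": p, "p_adjusted" if adjust else "p_raw": p_eff,
        "mean_diff": a.mean(axis=0) - b.mean(axis=0),
        "selected": selected,
    })


@dataclass(frozen=True)
class PowerSpec:
    effect_size_f: float = 0.25
    alpha: float = 0.05
    power: float = 0.8
    groups: int = 2
    measurements: int = 3
    rm_correlation: float = 0.5
    epsilon: float = 1.0

    def __post_init__(self):
        if self.effect_size_f <= 0:
            raise ValueError("effect size must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.groups < 2 or self.measurements < 2:
            raise ValueError("need >= 2 groups and >= 2 measurements")
        if not 0 <= self.rm_correlation < 1:
            raise ValueError("repeated-measures correlation must be in [0,1)")


def power_rm_interaction(n_total: int, spec: PowerSpec) -> float:
    """Noncentral-F power of the within-between interaction at total N.

    G*Power convention: lambda = f^2 N m eps / (1 - rho),
    df1 = (g-1)(m-1)eps, df2 = (N-g)(m-1)eps.
    """
    g, m = spec.groups, spec.measurements
    lam = (spec.effect_size_f ** 2 * n_total * m * spec.epsilon
           / (1 - spec.rm_correlation))
    df1 = (g - 1) * (m - 1) * spec.epsilon
    df2 = (n_total - g) * (m - 1) * spec.epsilon
    if df2 <= 0:
        return 0.0
    crit = sstats.f.ppf(1 - spec.alpha, df1, df2)
    return float(1 - sstats.ncf.cdf(crit, df1, df2, lam))


def sample_size_rm_anova(spec: PowerSpec = PowerSpec(),
                         n_max: int = 10 ** 6) -> int:
    """Smallest total N (equal groups) reaching the target power."""
    step = spec.groups
    start = spec.groups * 2
    n = start + (-start % step)
    while n <= n_max:
        if power_rm_interaction(n, spec) >= spec.power:
            return n
        n += step
    raise ValueError(f"target power unreachable within N <= {n_max}")
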