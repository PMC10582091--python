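"""The statistical layer: t-tests, repeated-measures / mixed ANOVA with
post hocs, Fisher's exact test, simple linear regression, and the
tail-probability utilities used to report (statistic, df, p) triplets.

Conventions:

* unpaired t-tests use the pooled-variance Student form (df = n1 + n2 − 2);
* repeated-measures ANOVAs report uncorrected df (no sphericity
  correction) and require balanced, complete designs;
* Tukey post hocs use the studentized-range distribution; Bonferroni
  multiplies raw p by the number of comparisons, capped at 1;
* Fisher's exact test is two-sided by the probability rule: the p-value is
  the sum of probabilities of all tables (margins fixed) no more probable
  than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sst


@dataclass
class StatResult:
    test_name: str
    statistic: float
    df: tuple
    p: float
    effect_label: str = ""
    correction: str = "none"

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p out of range: {self.p}")


@dataclass
class AnovaTable:
    rows: pd.DataFrame  # source, SS, df, MS, F, p
    design: str = ""

    def effect(self, source: str) -> StatResult:
        r = self.rows.set_index("source").loc[source]
        return StatResult("anova", float(r["F"]), (int(r["df"]), int(r["df_err"])),
                          float(r["p"]), effect_label=source)


# ---------------------------------------------------------------------------
# tail probabilities

def t_pvalue(t: float, df: int) -> float:
    """Two-sided Student-t tail probability."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * sst.t.sf(abs(t), df))


def f_pvalue(F: float, df1: int, df2: int) -> float:
    """Upper F tail probability."""
    if df1 < 1 or df2 < 1:
        raise ValueError("df must be >= 1")
    return float(sst.f.sf(F, df1, df2))


# ---------------------------------------------------------------------------
# t-tests

def t_test(x, y, paired: bool = False) -> StatResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if min(x.size, y.size) < 2:
        raise ValueError("need n >= 2 per sample")
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal n")
        d = x - y
        if np.all(d == d[0]) and d[0] == 0:
            return StatResult("t_paired", 0.0, (x.size - 1,), 1.0)
        res = sst.ttest_rel(x, y)
        return StatResult("t_paired", float(res.statistic), (x.size - 1,),
                          float(res.pvalue))
    if np.var(x) == 0 and np.var(y) == 0:
        raise ValueError("zero variance in both samples")
    res = sst.ttest_ind(x, y, equal_var=True)  # pooled-variance Student
    return StatResult("t_unpaired", float(res.statistic),
                      (x.size + y.size - 2,), float(res.pvalue))


# ---------------------------------------------------------------------------
# ANOVA (balanced designs, hand SS partition)

def _check_balanced(wide: pd.DataFrame) -> np.ndarray:
    arr = wide.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing cells: unbalanced/incomplete designs "
                         "are unsupported")
    return arr


def one_way_rm_anova(wide: pd.DataFrame) -> AnovaTable:
    """One-way repeated-measures ANOVA on a subjects × conditions table."""
    y = _check_balanced(wide)
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_subj = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_cond = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_cond
    df_cond, df_err = k - 1, (n - 1) * (k - 1)
    ms_cond, ms_err = ss_cond / df_cond, ss_err / df_err
    F = ms_cond / ms_err
    rows = pd.DataFrame([
        {"source": "condition", "SS": ss_cond, "df": df_cond, "MS": ms_cond,
         "F": F, "df_err": df_err, "p": f_pvalue(F, df_cond, df_err)},
        {"source": "subject", "SS": ss_subj, "df": n - 1, "MS": ss_subj / (n - 1),
         "F": np.nan, "df_err": np.nan, "p": np.nan},
        {"source": "error", "SS": ss_err, "df": df_err, "MS": ms_err,
         "F": np.nan, "df_err": np.nan, "p": np.nan},
    ])
    return AnovaTable(rows, design="one_way_rm")


def two_way_mixed_anova(data: pd.DataFrame, subject: str = "subject",
                        between: str = "group", within: str = "condition",
                        value: str = "value") -> AnovaTable:
    """Two-way mixed ANOVA: one between-subjects and one within-subjects
    factor, balanced design.  Long-format input."""
    piv = data.pivot_table(index=[between, subject], columns=within,
                           values=value, aggfunc="mean")
    y = _check_balanced(piv)
    groups = piv.index.get_level_values(0)
    glabels = groups.unique()
    g, k = len(glabels), y.shape[1]
    ns = [int((groups == gl).sum()) for gl in glabels]
    if len(set(ns)) != 1:
        raise ValueError("unequal group sizes: unbalanced designs unsupported")
    n = ns[0]
    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_of = np.concatenate([[i] * n for i in range(g)])
    group_means = np.array([y[group_of == i].mean() for i in range(g)])
    cond_means = y.mean(axis=0)
    cell_means = np.array([y[group_of == i].mean(axis=0) for i in range(g)])

    ss_total = ((y - grand) ** 2).sum()
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_group = n * k * ((group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_cond = g * n * ((cond_means - grand) ** 2).sum()
    ss_inter = n * ((cell_means - group_means[:, None] - cond_means[None, :]
                     + grand) ** 2).sum()
    ss_err = ss_total - ss_between_subj - ss_cond - ss_inter

    df_group, df_sw = g - 1, g * (n - 1)
    df_cond, df_inter, df_err = k - 1, (g - 1) * (k - 1), g * (n - 1) * (k - 1)
    ms = lambda ss, df: ss / df
    F_group = ms(ss_group, df_group) / ms(ss_subj_within, df_sw)
    F_cond = ms(ss_cond, df_cond) / ms(ss_err, df_err)
    F_inter = ms(ss_inter, df_inter) / ms(ss_err, df_err)
    rows = pd.DataFrame([
        {"source": between, "SS": ss_group, "df": df_group,
         "MS": ms(ss_group, df_group), "F": F_group, "df_err": df_sw,
         "p": f_pvalue(F_group, df_group, df_sw)},
        {"source": within, "SS": ss_cond, "df": df_cond,
         "MS": ms(ss_cond, df_cond), "F": F_cond, "df_err": df_err,
         "p": f_pvalue(F_cond, df_cond, df_err)},
        {"source": f"{between} x {within}", "SS": ss_inter, "df": df_inter,
         "MS": ms(ss_inter, df_inter), "F": F_inter, "df_err": df_err,
         "p": f_pvalue(F_inter, df_inter, df_err)},
        {"source": "subjects within groups", "SS": ss_subj_within, "df": df_sw,
         "MS": ms(ss_subj_within, df_sw), "F": np.nan, "df_err": np.nan, "p": np.nan},
        {"source": "error", "SS": ss_err, "df": df_err, "MS": ms(ss_err, df_err),
         "F": np.nan, "df_err": np.nan, "p": np.nan},
    ])
    return AnovaTable(rows, design="two_way_mixed")


def two_way_rm_anova(y: np.ndarray) -> AnovaTable:
    """Two-way fully repeated-measures ANOVA on subjects × A × B data.

    Each effect is tested against its own effect-by-subject error term.
    """
    y = np.asarray(y, float)
    if y.ndim != 3:
        raise ValueError("expect subjects x A x B array")
    n, a, b = y.shape
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_bs = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    resid = (y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - grand)
    ss_abs = (resid ** 2).sum()

    def row(src, ss, df, ss_e, df_e):
        F = (ss / df) / (ss_e / df_e)
        return {"source": src, "SS": ss, "df": df, "MS": ss / df, "F": F,
                "df_err": df_e, "p": f_pvalue(F, df, df_e)}

    rows = pd.DataFrame([
        row("A", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        row("B", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        row("A x B", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ])
    return AnovaTable(rows, design="two_way_rm")


# ---------------------------------------------------------------------------
# post hocs

def tukey_posthoc(groups: dict[str, np.ndarray]) -> list[StatResult]:
    """All-pairs Tukey HSD for independent groups (equal or unequal n,
    Tukey-Kramer), via the studentized-range distribution."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    names = list(groups)
    data = {k: np.asarray(v, float) for k, v in groups.items()}
    k = len(names)
    n_tot = sum(v.size for v in data.values())
    df_err = n_tot - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in data.values()) / df_err
    out = []
    for g1, g2 in combinations(names, 2):
        x, y = data[g1], data[g2]
        se = np.sqrt(mse / 2.0 * (1.0 / x.size + 1.0 / y.size))
        q = abs(x.mean() - y.mean()) / se
        p = float(sst.studentized_range.sf(q, k, df_err))
        out.append(StatResult("tukey", q, (k, df_err), min(p, 1.0),
                              effect_label=f"{g1} vs {g2}", correction="tukey"))
    return out


def bonferroni(p_values: list[float] | np.ndarray,
               m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values, capped at 1."""
    p = np.asarray(p_values, float)
    m = p.size if m is None else m
    return np.minimum(p * m, 1.0)


# ---------------------------------------------------------------------------
# Fisher's exact test

def fisher_exact(table) -> StatResult:
    """Two-sided Fisher's exact test on a 2×2 table (probability rule)."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    odds, p = sst.fisher_exact(t, alternative="two-sided")
    return StatResult("fisher_exact", float(odds), (1,), float(p))


# ---------------------------------------------------------------------------
# regression

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    F: float
    df: tuple
    p: float


def linregress(x, y) -> RegressionResult:
    """Simple least-squares regression with the F(1, n−2) omnibus test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]):
        raise ValueError("x is constant")
    res = sst.linregress(x, y)
    n = x.size
    r2 = res.rvalue ** 2
    if r2 >= 1.0:
        F, p = np.inf, np.finfo(float).tiny
    else:
        F = r2 * (n - 2) / (1.0 - r2)
        p = f_pvalue(F, 1, n - 2)
    return RegressionResult(float(res.slope), float(res.intercept), float(r2),
                            float(F), (1, n - 2), float(p))


def results_to_frame(results: list[StatResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        df1 = r.df[0] if len(r.df) > 0 else np.nan
        df2 = r.df[1] if len(r.df) > 1 else np.nan
        rows.append({"test_name": r.test_name, "effect": r.effect_label,
                     "statistic": r.statistic, "df1": df1, "df2": df2,
                     "p": r.p, "correction": r.correction})
    return pd.DataFrame(rows)
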