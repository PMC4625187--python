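"""The study's statistical battery with explicit contracts.

Nonparametric latency comparisons (Friedman with tie correction, paired
Wilcoxon, Mann-Whitney U with exact small-sample p-values), randomized-block
ANOVA with Tukey HSD on the block error term, balanced repeated-measures
ANOVA with up to two within-subject factors and an optional between-subjects
group factor (split-plot decomposition, optional Greenhouse-Geisser
correction), and paired t tests with Bonferroni adjustment.

The repeated-measures engine is a direct sums-of-squares decomposition on
subject-centered cell means: the within-subject space is split per factor
into effect, group-by-effect and subject-by-effect(error) strata, which is
exact for designs balanced over the within factors (unequal group sizes are
allowed).  Uncorrected degrees of freedom are reported by default;
``gg=True`` applies the Greenhouse-Geisser epsilon estimated from the
orthonormal contrast covariance pooled within groups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sstats

from .errors import DegenerateDataError, DesignError, ParameterError


@dataclass
class TestResult:
    """One statistical test: statistic, degrees of freedom, p-value."""

    name: str
    statistic: float
    df: Tuple[float, ...]
    p: float
    n: int
    method: str = ""
    correction: str = "none"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _as_matrix(values, min_rows: int, min_cols: int, what: str) -> np.ndarray:
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise DesignError(f"{what} requires a 2-D subjects-by-conditions table")
    if np.any(~np.isfinite(m)):
        raise DesignError(f"{what} has missing cells")
    if m.shape[0] < min_rows or m.shape[1] < min_cols:
        raise DesignError(
            f"{what} needs at least {min_rows} subjects and {min_cols} conditions, "
            f"got {m.shape}"
        )
    return m


# ---------------------------------------------------------------------------
# Nonparametric tests
# ---------------------------------------------------------------------------


def friedman_test(values) -> TestResult:
    """Friedman rank test over a subjects-by-days matrix (tie-corrected).

    Xr2 = [12 / (n k (k+1))] * sum(Rj^2) - 3 n (k+1), divided by the tie
    correction 1 - sum(t^3 - t) / (n k (k^2 - 1)); df = k - 1.
    """
    m = _as_matrix(values, 2, 2, "Friedman test")
    n, k = m.shape
    ranks = np.apply_along_axis(sstats.rankdata, 1, m)
    rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)
    tie_sum = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k * k - 1))
    if correction <= 0:  # every row fully tied: no information
        stat, p = 0.0, 1.0
    else:
        stat = stat / correction
        p = float(sstats.chi2.sf(stat, k - 1))
    return TestResult(
        name="Friedman",
        statistic=float(stat),
        df=(float(k - 1),),
        p=p,
        n=n,
        method="rank chi-square, mid-ranks with tie correction",
    )


def wilcoxon_paired(a, b) -> TestResult:
    """Paired Wilcoxon signed-rank test; exact null distribution for n <= 25
    (no ties/zeros), normal approximation otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DesignError("Wilcoxon needs two paired 1-D samples of equal length")
    if a.size < 2:
        raise DesignError("Wilcoxon needs n >= 2 pairs")
    d = a - b
    if np.all(d == 0):
        raise DegenerateDataError("all paired differences are zero")
    d_nz = d[d != 0]
    exact_ok = d_nz.size <= 25 and np.unique(np.abs(d_nz)).size == d_nz.size
    method = "exact" if exact_ok else "approx"
    res = sstats.wilcoxon(a, b, zero_method="wilcox", method=method, correction=not exact_ok)
    return TestResult(
        name="Wilcoxon signed-rank",
        statistic=float(res.statistic),
        df=(float("nan"),),
        p=float(res.pvalue),
        n=a.size,
        method=method,
    )


def mann_whitney(a, b) -> TestResult:
    """Mann-Whitney U, exact for n1, n2 <= 25 without ties, otherwise the
    normal approximation with tie correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise DesignError("Mann-Whitney needs two 1-D samples with n >= 2 each")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    exact_ok = (not has_ties) and max(a.size, b.size) <= 25
    method = "exact" if exact_ok else "asymptotic"
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        name="Mann-Whitney U",
        statistic=float(res.statistic),
        df=(float("nan"),),
        p=float(res.pvalue),
        n=a.size + b.size,
        method=method,
        extras={"U_other": float(a.size * b.size - res.statistic)},
    )


# ---------------------------------------------------------------------------
# Randomized-block ANOVA + Tukey HSD
# ---------------------------------------------------------------------------


def blocked_anova_tukey(values, labels: Optional[Sequence] = None) -> TestResult:
    """Randomized-block ANOVA (subjects as blocks) for a treatment effect,
    with Tukey HSD pairwise comparisons on the block error term.

    ``values`` is a complete blocks-by-treatments matrix.  The Tukey p-values
    use the studentized range with the block-design error degrees of freedom.
    """
    m = _as_matrix(values, 2, 2, "blocked ANOVA")
    b, k = m.shape
    labels = list(labels) if labels is not None else list(range(1, k + 1))
    if len(labels) != k:
        raise DesignError("labels length must match the number of treatments")
    grand = m.mean()
    treat_means = m.mean(axis=0)
    block_means = m.mean(axis=1)
    ss_total = float(np.sum((m - grand) ** 2))
    ss_treat = b * float(np.sum((treat_means - grand) ** 2))
    ss_block = k * float(np.sum((block_means - grand) ** 2))
    ss_err = ss_total - ss_treat - ss_block
    df_treat = k - 1
    df_err = (k - 1) * (b - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f_stat, p = (0.0, 1.0) if ss_treat <= 1e-300 else (float("inf"), 0.0)
    else:
        f_stat = (ss_treat / df_treat) / ms_err
        p = float(sstats.f.sf(f_stat, df_treat, df_err))
    rows = []
    se = math.sqrt(ms_err / b) if ms_err > 0 else 0.0
    for i, j in itertools.combinations(range(k), 2):
        diff = treat_means[j] - treat_means[i]
        if se > 0:
            q = abs(diff) / se
            p_ij = float(sstats.studentized_range.sf(q, k, df_err))
        else:
            q = 0.0 if diff == 0 else float("inf")
            p_ij = 1.0 if diff == 0 else 0.0
        rows.append(
            {
                "level_a": labels[i],
                "level_b": labels[j],
                "mean_diff": float(diff),
                "q": float(q),
                "p": p_ij,
                "reject": p_ij < 0.05,
            }
        )
    return TestResult(
        name="blocked ANOVA",
        statistic=float(f_stat),
        df=(float(df_treat), float(df_err)),
        p=p,
        n=b,
        method="randomized block F + Tukey HSD",
        extras={"tukey": pd.DataFrame(rows), "ms_error": ms_err},
    )


# ---------------------------------------------------------------------------
# Repeated-measures / split-plot ANOVA
# ---------------------------------------------------------------------------


def _pivot_design(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: Sequence[str],
    between: Optional[str],
) -> Tuple[np.ndarray, np.ndarray, List[Tuple], List]:
    """Return (cells, group codes, within level tuples, subjects).

    ``cells`` is (n_subjects, n_within_cells) with within cells ordered as
    the cartesian product of the sorted factor levels; completeness is
    validated cell by cell.
    """
    for col in [dv, subject, *within] + ([between] if between else []):
        if col not in data.columns:
            raise DesignError(f"column {col!r} missing from the data table")
    levels = [sorted(data[w].unique().tolist()) for w in within]
    cell_index = list(itertools.product(*levels))
    subjects = sorted(data[subject].unique().tolist())
    piv = data.pivot_table(index=subject, columns=list(within), values=dv, aggfunc="mean")
    missing = []
    for s in subjects:
        for cell in cell_index:
            key = cell[0] if len(cell) == 1 else cell
            if s not in piv.index or key not in piv.columns or pd.isna(piv.loc[s, key]):
                missing.append((s, cell))
    if missing:
        raise DesignError(f"unbalanced design; missing subject-cells: {missing[:10]}")
    cols = [c[0] if len(c) == 1 else c for c in cell_index]
    cells = piv.loc[subjects, cols].to_numpy(dtype=float)
    if between is not None:
        gmap = data.groupby(subject)[between].agg(lambda s: s.iloc[0])
        multi = data.groupby(subject)[between].nunique()
        if (multi > 1).any():
            raise DesignError("a subject appears in more than one between-group level")
        group_labels = sorted(gmap.unique().tolist())
        groups = np.array([group_labels.index(gmap[s]) for s in subjects])
    else:
        groups = np.zeros(len(subjects), dtype=int)
    return cells, groups, cell_index, subjects


def _gg_epsilon(scores: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from contrast scores (n x d), covariance
    pooled within groups."""
    d = scores.shape[1]
    if d <= 1:
        return 1.0
    resid = scores.astype(float).copy()
    for g in np.unique(groups):
        sel = groups == g
        resid[sel] -= resid[sel].mean(axis=0)
    dof = scores.shape[0] - np.unique(groups).size
    if dof < 1:
        return 1.0
    cov = resid.T @ resid / dof
    tr = np.trace(cov)
    tr2 = np.trace(cov @ cov)
    if tr2 <= 0:
        return 1.0
    eps = tr * tr / (d * tr2)
    return float(min(1.0, max(1.0 / d, eps)))


def _oneway_split(col: np.ndarray, groups: np.ndarray, ngroups: int):
    """Split a per-subject column into overall-mean, group-deviation and
    residual sums of squares (weighted means; exact one-way identity)."""
    n = col.shape[0]
    overall = col.mean(axis=0)
    ss_main = n * np.sum(overall**2)
    ss_group = 0.0
    ss_resid = 0.0
    for g in range(ngroups):
        sel = groups == g
        gm = col[sel].mean(axis=0)
        ss_group += sel.sum() * np.sum((gm - overall) ** 2)
        ss_resid += np.sum((col[sel] - gm) ** 2)
    return float(ss_main), float(ss_group), float(ss_resid)


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: Sequence[str],
    between: Optional[str] = None,
    gg: bool = False,
) -> Dict[str, TestResult]:
    """Repeated-measures ANOVA with one or two within factors and an
    optional between-subjects factor.

    Returns a dict of effects: within main effects (``"day"``), their
    interaction (``"day:frequency"``), and — when ``between`` is given —
    the group main effect and group to within-factor interactions, each
    tested against its own subject-level error stratum.  ``gg=True``
    replaces the p-values by Greenhouse-Geisser-corrected ones (the raw
    uncorrected p is kept in ``extras["p_uncorrected"]``).
    """
    within = list(within)
    if not 1 <= len(within) <= 2:
        raise DesignError("rm_anova supports one or two within-subject factors")
    cells, groups, cell_index, subjects = _pivot_design(data, dv, subject, within, between)
    n = len(subjects)
    ngroups = int(groups.max()) + 1
    if between is not None and ngroups < 2:
        raise DesignError("between factor has fewer than 2 levels")
    if n - ngroups < 1:
        raise DesignError("need more subjects than groups")
    shape = [len(sorted(set(c[i] for c in cell_index))) for i in range(len(within))]
    a = shape[0]
    b = shape[1] if len(within) == 2 else 1
    y = cells.reshape(n, a, b)

    subj_means = y.mean(axis=(1, 2))
    d = y - subj_means[:, None, None]  # subject-centered within-cell values

    results: Dict[str, TestResult] = {}

    # ---- between-subjects stratum ----
    if between is not None:
        overall = subj_means.mean()
        ss_g = 0.0
        ss_sg = 0.0
        for g in range(ngroups):
            sel = groups == g
            gm = subj_means[sel].mean()
            ss_g += sel.sum() * (gm - overall) ** 2
            ss_sg += np.sum((subj_means[sel] - gm) ** 2)
        ss_g *= a * b
        ss_sg *= a * b
        df_g, df_sg = ngroups - 1, n - ngroups
        f_g = (ss_g / df_g) / (ss_sg / df_sg) if ss_sg > 0 else float("inf")
        results["group"] = TestResult(
            name="group",
            statistic=float(f_g),
            df=(float(df_g), float(df_sg)),
            p=float(sstats.f.sf(f_g, df_g, df_sg)) if np.isfinite(f_g) else 0.0,
            n=n,
            method="split-plot between-subjects F",
        )

    # ---- within strata ----
    def contrasts(k: int) -> np.ndarray:
        if k == 1:
            return np.zeros((0, 1))
        return sla.helmert(k)  # (k-1, k) orthonormal rows

    ca, cb = contrasts(a), contrasts(b)

    strata = []
    if a > 1:
        profile_a = d.mean(axis=2)  # (n, a)
        strata.append((within[0], profile_a, b, ca, a - 1))
    if b > 1:
        profile_b = d.mean(axis=1)  # (n, b)
        strata.append((within[1], profile_b, a, cb, b - 1))
    if a > 1 and b > 1:
        inter = d - d.mean(axis=2, keepdims=True) - d.mean(axis=1, keepdims=True) + 0.0
        # note: d already has zero subject means, so the double-centering above
        # leaves exactly the within-subject interaction residual
        inter = inter.reshape(n, a * b)
        cab = np.kron(ca, cb)
        strata.append((f"{within[0]}:{within[1]}", inter, 1, cab, (a - 1) * (b - 1)))

    for name, profile, mult, cmat, df_eff in strata:
        ss_eff, ss_geff, ss_err = _oneway_split(profile, groups, ngroups)
        ss_eff *= mult
        ss_geff *= mult
        ss_err *= mult
        df_err = (n - ngroups) * df_eff
        ms_err = ss_err / df_err if df_err > 0 else 0.0
        # Greenhouse-Geisser epsilon from orthonormal contrast scores of the
        # subject profiles (contrasts annihilate the removed means)
        eps = _gg_epsilon(profile @ cmat.T, groups) if gg else 1.0

        def _ftest(label: str, ss: float, df1: float) -> TestResult:
            if ms_err <= 0:
                f_val = 0.0 if ss <= 1e-300 else float("inf")
                p_val = 1.0 if ss <= 1e-300 else 0.0
                p_unc = p_val
            else:
                f_val = (ss / df1) / ms_err
                p_unc = float(sstats.f.sf(f_val, df1, df_err))
                p_val = (
                    float(sstats.f.sf(f_val, eps * df1, eps * df_err)) if gg else p_unc
                )
            return TestResult(
                name=label,
                statistic=float(f_val),
                df=(float(df1), float(df_err)),
                p=p_val,
                n=n,
                method="repeated-measures F",
                correction=f"GG eps={eps:.3f}" if gg else "none",
                extras={"p_uncorrected": p_unc, "ss": ss, "ss_error": ss_err},
            )

        results[name] = _ftest(name, ss_eff, df_eff)
        if between is not None:
            results[f"group:{name}"] = _ftest(
                f"group:{name}", ss_geff, (ngroups - 1) * df_eff
            )
    return results


# ---------------------------------------------------------------------------
# Paired t with Bonferroni
# ---------------------------------------------------------------------------


def paired_t_bonferroni(
    comparisons: Sequence[Tuple[str, Sequence[float], Sequence[float]]],
    m: Optional[int] = None,
    alpha: float = 0.05,
) -> List[TestResult]:
    """Paired t per labelled comparison; Bonferroni-adjusted significance.

    Both the raw and the adjusted p (min(1, m*p)) are reported; comparisons
    with zero-variance differences are flagged degenerate instead of
    producing an infinite statistic.
    """
    if not comparisons:
        raise ParameterError("no comparisons supplied")
    m = m if m is not None else len(comparisons)
    if m < 1:
        raise ParameterError("number of tests m must be >= 1")
    out: List[TestResult] = []
    for label, a, b in comparisons:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape or a.ndim != 1 or a.size < 2:
            raise DesignError(f"comparison {label!r}: paired 1-D samples with n >= 2 required")
        diff = a - b
        if np.std(diff, ddof=1) == 0:
            out.append(
                TestResult(
                    name=f"paired t [{label}]",
                    statistic=float("nan"),
                    df=(float(a.size - 1),),
                    p=float("nan"),
                    n=a.size,
                    method="paired t",
                    correction=f"Bonferroni m={m}",
                    extras={"degenerate": True, "mean_diff": float(diff.mean())},
                )
            )
            continue
        res = sstats.ttest_rel(a, b)
        p_adj = min(1.0, m * float(res.pvalue))
        out.append(
            TestResult(
                name=f"paired t [{label}]",
                statistic=float(res.statistic),
                df=(float(a.size - 1),),
                p=float(res.pvalue),
                n=a.size,
                method="paired t",
                correction=f"Bonferroni m={m}",
                extras={
                    "degenerate": False,
                    "p_adjusted": p_adj,
                    "significant": p_adj < alpha,
                },
            )
        )
    return out


def pearson(a, b) -> TestResult:
    """Pearson correlation with the exact two-sided t-transform p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise DesignError("Pearson correlation needs paired samples with n >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise DegenerateDataError("correlation undefined for zero-variance input")
    res = sstats.pearsonr(a, b)
    return TestResult(
        name="Pearson r",
        statistic=float(res.statistic),
        df=(float(a.size - 2),),
        p=float(res.pvalue),
        n=a.size,
        method="exact t transform",
    )
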