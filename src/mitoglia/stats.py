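"""Group-comparison statistics for the per-cell metrics.

Test selection is gated on distributional checks: each group is tested for
normality (Shapiro–Wilk) and the groups jointly for equal variance (Levene).
Two groups: Student's t when both checks pass, Welch's t when normal but
heteroscedastic, otherwise the Wilcoxon rank-sum (Mann–Whitney) test.  Three
or more groups: one-way ANOVA with Tukey's HSD post-hoc when the gate passes,
otherwise Kruskal–Wallis with Conover's post-hoc test and Holm adjustment.
Sholl curves are compared with a linear mixed model (random intercept per
cell, sum-to-zero contrasts, type-III Wald test of the group main effect).

All tests are two-sided; alpha defaults to 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
import statsmodels.formula.api as smf

from .core_io import DomainError

ALPHA = 0.05


class InsufficientDataError(DomainError):
    pass


class DegenerateDataError(DomainError):
    pass


@dataclass
class TestReport:
    test_name: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None = None
    posthoc_method: str | None = None
    details: dict = field(default_factory=dict)


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, never below the raw p)."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]


def _normality_and_variance_gate(
    groups: list[np.ndarray], alpha: float
) -> tuple[bool, bool, dict]:
    """Shapiro per group; Levene across groups. Returns (normal, equal_var)."""
    shapiro_p = []
    for g in groups:
        if np.ptp(g) == 0:
            shapiro_p.append(0.0)  # a constant sample is treated as non-normal
        else:
            shapiro_p.append(float(sps.shapiro(g).pvalue))
    normal = all(p > alpha for p in shapiro_p)
    levene_p = float(sps.levene(*groups).pvalue)
    return normal, levene_p > alpha, {"shapiro_p": shapiro_p, "levene_p": levene_p}


def choose_two_sample_test(
    a: np.ndarray, b: np.ndarray, alpha: float = ALPHA
) -> TestReport:
    """Gate-selected two-sample comparison (two-sided).

    Both samples Shapiro-normal and Levene-homoscedastic at ``alpha`` →
    Student's t; normal but heteroscedastic → Welch's t; otherwise the
    Wilcoxon rank-sum test (exact for small samples without ties, normal
    approximation with continuity correction otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("each sample needs n >= 3")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise DegenerateDataError("all observations identical")
    normal, equal_var, gate = _normality_and_variance_gate([a, b], alpha)
    if normal and equal_var:
        res = sps.ttest_ind(a, b, equal_var=True)
        name = "student_t"
    elif normal:
        res = sps.ttest_ind(a, b, equal_var=False)
        name = "welch_t"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        name = "wilcoxon_rank_sum"
    return TestReport(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        details=gate,
    )


def conover_posthoc(groups: list[np.ndarray], labels: list[str] | None = None) -> pd.DataFrame:
    """Conover–Iman pairwise rank comparisons with Holm adjustment.

    The statistic for groups i, j is
    t = (R̄_i − R̄_j) / sqrt(S² (N−1−H)/(N−k) (1/n_i + 1/n_j)),
    with pooled rank variance S² = (Σ r² − N(N+1)²/4)/(N−1) and the
    tie-corrected Kruskal–Wallis H; p-values from t with N−k df, two-sided,
    Holm-adjusted over all pairs.  For k = 2 this reduces exactly to a
    two-sample t-test on the ranks.
    """
    k = len(groups)
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    sizes = np.array([len(g) for g in groups])
    N = int(sizes.sum())
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    mean_ranks = np.array([r.mean() for r in split])
    S2 = (np.sum(ranks**2) - N * (N + 1) ** 2 / 4.0) / (N - 1)
    if S2 <= 0:
        raise DegenerateDataError("all observations tied")
    H = float(sps.kruskal(*groups).statistic)
    denom_scale = S2 * (N - 1 - H) / (N - k)
    pairs, raw_p, tstats = [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(denom_scale * (1.0 / sizes[i] + 1.0 / sizes[j]))
            t = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.t.sf(abs(t), df=N - k)
            pairs.append((i, j))
            raw_p.append(min(p, 1.0))
            tstats.append(t)
    adj = holm_adjust(np.array(raw_p))
    mat = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    for (i, j), p in zip(pairs, adj):
        mat.iloc[i, j] = mat.iloc[j, i] = p
    mat.attrs["raw_p"] = {
        (labels[i], labels[j]): p for (i, j), p in zip(pairs, raw_p)
    }
    mat.attrs["t"] = {(labels[i], labels[j]): t for (i, j), t in zip(pairs, tstats)}
    return mat


def multigroup_test(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    parametric: bool | str = "auto",
    alpha: float = ALPHA,
) -> TestReport:
    """Omnibus comparison of ≥3 groups with the matching post-hoc.

    ``parametric='auto'`` applies the normality/equal-variance gate: pass →
    one-way ANOVA + Tukey HSD; fail → Kruskal–Wallis + Conover–Holm.  True or
    False forces the branch.  The full pairwise adjusted-p matrix is returned
    in ``posthoc``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise InsufficientDataError("need at least 3 groups (use choose_two_sample_test for 2)")
    if any(g.size < 3 for g in groups):
        raise InsufficientDataError("each group needs n >= 3")
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    if np.ptp(np.concatenate(groups)) == 0:
        raise DegenerateDataError("all observations identical across groups")
    details: dict = {}
    if parametric == "auto":
        normal, equal_var, details = _normality_and_variance_gate(groups, alpha)
        use_parametric = normal and equal_var
    else:
        use_parametric = bool(parametric)
    if use_parametric:
        res = sps.f_oneway(*groups)
        tk = sps.tukey_hsd(*groups)
        posthoc = pd.DataFrame(tk.pvalue, index=labels, columns=labels)
        return TestReport(
            test_name="anova_oneway",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            posthoc=posthoc,
            posthoc_method="tukey",
            details=details,
        )
    res = sps.kruskal(*groups)
    posthoc = conover_posthoc(groups, labels)
    return TestReport(
        test_name="kruskal_wallis",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        posthoc=posthoc,
        posthoc_method="holm_conover",
        details=details,
    )


def sholl_mixed_model(long_table: pd.DataFrame) -> TestReport:
    """Mixed-model comparison of Sholl curves between groups.

    Fits ``n_intersections ~ group + radius + group×radius`` with a random
    intercept and a random radius slope per cell and sum-to-zero contrasts
    for group, and reports the type-III Wald chi-square test of the group
    main effect.  The random slope is required: per-cell Sholl curves differ
    in tilt as well as level, and an intercept-only model underestimates the
    group-effect standard error (empirically ~5× the nominal type-I rate on
    null cohorts).  Because the group factor varies only between cells, the
    Wald statistic is referred to an F distribution with between-within
    denominator degrees of freedom (cells − groups) rather than the
    asymptotic chi-square, the standard small-sample correction when the
    effective sample size is the number of cells.  The input is a long table
    with columns cell_id, group, radius, n_intersections.
    """
    required = {"cell_id", "group", "radius", "n_intersections"}
    missing = required - set(long_table.columns)
    if missing:
        raise DomainError(f"long table missing columns: {sorted(missing)}")
    df = long_table.copy()
    df["group"] = df["group"].astype(str)
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    cells_per_group = df.groupby("group")["cell_id"].nunique()
    if (cells_per_group < 2).any():
        raise InsufficientDataError("each group needs at least 2 cells")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "n_intersections ~ C(group, Sum) * radius",
            data=df,
            groups=df["cell_id"],
            re_formula="~radius",
        )
        res = model.fit(reml=True)

    exog_names = model.exog_names
    idx = [
        i for i, name in enumerate(exog_names)
        if name.startswith("C(group, Sum)") and ":" not in name
    ]
    beta = np.asarray(res.fe_params)[idx]
    cov = np.asarray(res.cov_params())[np.ix_(idx, idx)]
    wald = float(beta @ np.linalg.solve(cov, beta))
    dof = len(idx)
    n_cells = df["cell_id"].nunique()
    df_denom = n_cells - len(groups)
    p = float(sps.f.sf(wald / dof, dof, df_denom))
    return TestReport(
        test_name="mixed_model",
        statistic=wald / dof,
        p_value=p,
        details={
            "df": (dof, df_denom),
            "formula": "n_intersections ~ C(group, Sum) * radius + (radius | cell_id)",
            "note": "random intercept and radius slope per cell; "
                    "type-III Wald test of the group main effect",
        },
    )


def compare_metric_table(
    metrics: pd.DataFrame, metric: str, group_col: str = "group", alpha: float = ALPHA
) -> TestReport:
    """Dispatch a per-cell metric to the two-sample or multi-group machinery."""
    sub = metrics[[group_col, metric]].dropna()
    labels = sorted(sub[group_col].astype(str).unique())
    groups = [sub.loc[sub[group_col].astype(str) == lab, metric].to_numpy() for lab in labels]
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    if len(groups) == 2:
        return choose_two_sample_test(groups[0], groups[1], alpha)
    return multigroup_test(groups, labels, alpha=alpha)
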