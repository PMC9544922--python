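"""Statistical battery for the longitudinal EMG measures, from first principles.

Implements the three designs the analysis needs:

* one-way ANOVA with Tukey, Bonferroni or Monte-Carlo Dunnett post-hocs
  (single-time-point comparisons);
* split-plot repeated-measures ANOVA (between factor: treatment group,
  within factor: week) with Greenhouse–Geisser sphericity correction,
  requiring a complete balanced panel;
* the exact two-sample Mann–Whitney U test, with mid-ranks for ties and a
  two-tailed p obtained by full enumeration of all group assignments —
  appropriate at the motor-neuron-mapping sample sizes (5 vs 3, 56
  assignments).

Only distribution functions (F, t, studentized range) are taken from
scipy; all sums of squares, statistics and enumeration are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sstats

ENUMERATION_GUARD = 1_000_000


@dataclass
class TestResult:
    method: str
    statistic: float
    df: tuple[float, ...]
    p: float
    effect_terms: dict[str, tuple[float, tuple[float, float], float]] = field(
        default_factory=dict
    )
    posthoc: list[tuple[tuple, float]] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# one-way ANOVA

def one_way_anova(groups: list[np.ndarray]) -> TestResult:
    """Classical between/within decomposition across independent groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least two values")
    k = len(groups)
    ns = np.array([g.size for g in groups])
    n = int(ns.sum())
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df1, df2 = k - 1, n - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return TestResult("one_way_anova", 0.0, (df1, df2), 1.0)
        return TestResult("one_way_anova", np.inf, (df1, df2), 0.0)
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sstats.f.sf(f, df1, df2))
    return TestResult("one_way_anova", float(f), (df1, df2), p)


def pairwise_posthoc(
    groups: list[np.ndarray],
    method: str = "tukey",
    control: int | None = None,
    seed: int | None = None,
    n_mc: int = 200_000,
) -> list[tuple[tuple[int, int], float]]:
    """Adjusted pairwise p-values following a one-way design.

    ``tukey`` uses the studentized-range distribution on all pairs;
    ``bonferroni`` multiplies pooled-variance pairwise t p-values by the
    number of comparisons (capped at 1); ``dunnett_mc`` compares every
    group to ``control`` with critical values from a seeded Monte-Carlo
    sample of the max-|t| null (so its p-values carry Monte-Carlo noise of
    order 1/sqrt(n_mc)).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.size for g in groups])
    df_w = int(ns.sum()) - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_w
    means = [g.mean() for g in groups]

    if method == "tukey":
        out = []
        for i, j in combinations(range(k), 2):
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se if se > 0 else (0.0 if means[i] == means[j] else np.inf)
            p = float(sstats.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
            out.append(((i, j), min(p, 1.0)))
        return out

    if method == "bonferroni":
        m = comb(k, 2)
        out = []
        for i, j in combinations(range(k), 2):
            se = np.sqrt(msw * (1.0 / ns[i] + 1.0 / ns[j]))
            t = (means[i] - means[j]) / se if se > 0 else (0.0 if means[i] == means[j] else np.inf)
            p_raw = 2.0 * float(sstats.t.sf(abs(t), df_w)) if np.isfinite(t) else 0.0
            out.append(((i, j), min(1.0, p_raw * m)))
        return out

    if method == "dunnett_mc":
        if control is None:
            raise ValueError("dunnett_mc requires a control group index")
        if seed is None:
            raise ValueError("dunnett_mc requires a seed for its Monte-Carlo null")
        rng = np.random.default_rng(seed)
        others = [i for i in range(k) if i != control]
        t_obs = {}
        for i in others:
            se = np.sqrt(msw * (1.0 / ns[i] + 1.0 / ns[control]))
            t_obs[i] = (means[i] - means[control]) / se if se > 0 else 0.0
        # null: group means ~ N(0, 1/n_i), shared variance estimate
        # s2 ~ chi2(df_w)/df_w, T_i = (m_i - m_c)/sqrt(s2 (1/n_i + 1/n_c))
        z = rng.standard_normal((n_mc, k)) / np.sqrt(ns)
        s2 = rng.chisquare(df_w, size=n_mc) / df_w
        tmat = np.abs(
            (z[:, others] - z[:, [control]])
            / np.sqrt(s2[:, None] * (1.0 / ns[others] + 1.0 / ns[control]))
        )
        max_t = tmat.max(axis=1)
        return [((i, control), float(np.mean(max_t >= abs(t_obs[i])))) for i in others]

    raise ValueError(f"unknown post-hoc method {method!r}")


# ---------------------------------------------------------------------------
# split-plot repeated-measures ANOVA

def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from a k x k within-subject covariance."""
    k = cov.shape[0]
    centred = (
        cov
        - cov.mean(axis=0, keepdims=True)
        - cov.mean(axis=1, keepdims=True)
        + cov.mean()
    )
    num = np.trace(centred) ** 2
    den = (k - 1) * np.sum(centred**2)
    if den <= 0:
        return 1.0
    return float(min(max(num / den, 1.0 / (k - 1)), 1.0))


def rm_anova_split_plot(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "week",
    subject: str = "animal_id",
    between: str = "group",
    gg_correction: bool = True,
) -> TestResult:
    """Two-way repeated-measures (split-plot) ANOVA.

    Between-subject factor ``between`` (g levels, n subjects each), within
    factor ``within`` (k levels, complete panel required).  Reports Time,
    Treatment (group) and Interaction F terms.  With ``gg_correction`` the
    within-factor degrees of freedom are multiplied by the
    Greenhouse–Geisser epsilon computed from the pooled within-group
    covariance of the repeated measures; the correction is applied
    unconditionally (no sphericity pre-test).
    """
    df = table[[subject, between, within, dv]].copy()
    wide = df.pivot_table(index=[between, subject], columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("unbalanced panel: every subject needs a value at every week")
    sizes = df.groupby(subject).size()
    if sizes.nunique() != 1:
        raise ValueError("unbalanced panel: unequal observations per subject")

    y = wide.to_numpy()  # subjects x weeks
    groups = wide.index.get_level_values(0).to_numpy()
    glabels = pd.unique(groups)
    g = len(glabels)
    n_total, k = y.shape
    n_per = np.array([(groups == lab).sum() for lab in glabels])
    if np.any(n_per < 2):
        raise ValueError("each group needs at least two subjects")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    week_means = y.mean(axis=0)
    group_means = np.array([y[groups == lab].mean() for lab in glabels])
    cell_means = np.vstack([y[groups == lab].mean(axis=0) for lab in glabels])

    ss_group = float(k * np.sum(n_per * (group_means - grand) ** 2))
    ss_subj_between = float(k * np.sum((subj_means - grand) ** 2))
    ss_subj_within = ss_subj_between - ss_group  # subjects within groups
    ss_time = float(n_total * np.sum((week_means - grand) ** 2))
    ss_inter = float(
        np.sum(
            n_per[:, None]
            * (cell_means - group_means[:, None] - week_means[None, :] + grand) ** 2
        )
    )
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_group - ss_subj_within - ss_time - ss_inter

    df_group, df_subj = g - 1, n_total - g
    df_time = k - 1
    df_inter = (g - 1) * (k - 1)
    df_err = (k - 1) * (n_total - g)

    f_group = (ss_group / df_group) / (ss_subj_within / df_subj)
    f_time = (ss_time / df_time) / (ss_err / df_err)
    f_inter = (ss_inter / df_inter) / (ss_err / df_err)

    # pooled within-group covariance of the repeated measures
    pooled = np.zeros((k, k))
    for lab in glabels:
        sub = y[groups == lab]
        pooled += (sub.shape[0] - 1) * np.cov(sub, rowvar=False)
    pooled /= n_total - g
    eps = gg_epsilon(pooled) if gg_correction else 1.0

    terms = {
        "treatment": (
            float(f_group),
            (float(df_group), float(df_subj)),
            float(sstats.f.sf(f_group, df_group, df_subj)),
        ),
        "time": (
            float(f_time),
            (eps * df_time, eps * df_err),
            float(sstats.f.sf(f_time, eps * df_time, eps * df_err)),
        ),
        "interaction": (
            float(f_inter),
            (eps * df_inter, eps * df_err),
            float(sstats.f.sf(f_inter, eps * df_inter, eps * df_err)),
        ),
    }
    tr = terms["treatment"]
    return TestResult(
        method="rm_anova_split_plot",
        statistic=tr[0],
        df=tr[1],
        p=tr[2],
        effect_terms=terms,
        extra={
            "epsilon": eps,
            "ss": {
                "treatment": ss_group,
                "subjects_within": ss_subj_within,
                "time": ss_time,
                "interaction": ss_inter,
                "error": ss_err,
            },
            "uncorrected_df": {
                "time": (float(df_time), float(df_err)),
                "interaction": (float(df_inter), float(df_err)),
            },
        },
    )


# ---------------------------------------------------------------------------
# exact Mann-Whitney U

def mann_whitney_exact(x, y) -> TestResult:
    """Two-sample Mann–Whitney U with exact enumeration p-value.

    U is computed from mid-ranks of the pooled sample.  The two-tailed p
    is the fraction of all C(n1+n2, n1) group assignments whose U deviates
    from the null mean n1*n2/2 by at least the observed deviation — the
    reflection rule, which for 5-vs-3 samples yields p-values in multiples
    of 2/56.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    total = comb(n, n1)
    if total > ENUMERATION_GUARD:
        raise ValueError(
            f"C({n},{n1}) = {total} assignments exceeds the exact-enumeration "
            "guard; use a normal-approximation test instead"
        )
    pooled = np.concatenate([x, y])
    ranks = sstats.rankdata(pooled)  # mid-ranks for ties
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    dev = abs(u1 - mean_u)

    hits = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mean_u) >= dev - 1e-9:
            hits += 1
    p = hits / total
    return TestResult(
        method="mann_whitney_exact",
        statistic=float(u1),
        df=(float(n1), float(n2)),
        p=float(p),
        extra={"n_assignments": total, "n_as_extreme": hits},
    )
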