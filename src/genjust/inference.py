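"""Pre-registered hypothesis tests.

The workhorse is a fully balanced within-subjects (repeated-measures) ANOVA
for an arbitrary set of within factors, computed through orthonormal contrast
scores.  For each effect E we build the Kronecker product of orthonormal
Helmert contrasts (for factors in E) and normalized averaging vectors (for
factors not in E), project each participant's cell-mean vector onto it, and
read off

    SS_E      = n * ||mean contrast score||^2
    SS_ExS    = total squared deviation of contrast scores from their mean
    F         = (SS_E / df_E) / (SS_ExS / ((n-1) df_E))
    eta_p^2   = SS_E / (SS_E + SS_ExS)
    epsilon   = tr(S)^2 / (df_E * tr(S^2)),   S = covariance of the scores,

the last being the Greenhouse-Geisser sphericity correction applied
multiplicatively to both degrees of freedom.  Because the contrast system
plus the grand-mean direction forms an orthonormal basis of the cell space,
the sums of squares of all effects, their error terms, and the
between-subjects term add up exactly to the total sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .design import ABSOLUTE_LEVELS, DANGER_LEVELS, RELATIVE_LEVELS

#: Canonical level orders for the study's factor columns.
CANONICAL_LEVELS = {
    "abs_level": list(ABSOLUTE_LEVELS),
    "rel_level": list(RELATIVE_LEVELS),
    "dangerous": [0, 1],
    "dangerousness": list(DANGER_LEVELS),
}

STUDY_WITHIN = ("abs_level", "rel_level", "dangerous")


@dataclass
class TTestResult:
    label: str
    t: float
    df: float
    p: float
    p_adj: float
    d: float


def _helmert(k: int) -> np.ndarray:
    """Orthonormal (k, k-1) contrast matrix."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


def gg_epsilon(cov: np.ndarray, contrast: np.ndarray | None = None) -> float:
    """Greenhouse-Geisser epsilon from a covariance matrix.

    Without a contrast, ``cov`` is the m x m covariance of the repeated
    measures and the classic double-centred (Box) formula is used; with an
    orthonormal contrast matrix (m x k), epsilon is computed on the k x k
    covariance of the contrast scores.  Both agree when the contrast spans
    the within-subject space.
    """
    S = np.asarray(cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be a square matrix")
    m = S.shape[0]
    if m < 2:
        raise ValueError("need at least 2 repeated measures")
    if contrast is None:
        C = np.eye(m) - np.full((m, m), 1.0 / m)
        S = C @ S @ C
        k = m - 1
    else:
        M = np.asarray(contrast, dtype=float)
        S = M.T @ S @ M
        k = S.shape[0]
    tr = np.trace(S)
    tr2 = np.trace(S @ S)
    if tr2 == 0:
        return 1.0
    return float(tr * tr / (k * tr2))


def cell_matrix(data: pd.DataFrame, dv: str = "rating",
                within: tuple[str, ...] = STUDY_WITHIN,
                subject: str = "participant_id"
                ) -> tuple[np.ndarray, list[tuple], pd.Index]:
    """Pivot long data to (n_subjects, n_cells); trials within a cell averaged.

    Cells are ordered by the Cartesian product of factor levels (canonical
    order for known study columns, sorted otherwise).  Raises on missing cells.
    """
    levels = [_levels_present(data, f) for f in within]
    piv = data.pivot_table(index=subject, columns=list(within), values=dv,
                           aggfunc="mean", observed=True)
    if len(within) > 1:
        full = pd.MultiIndex.from_product(levels, names=within)
    else:
        full = pd.Index(levels[0], name=within[0])
    piv = piv.reindex(columns=full)
    if piv.isna().any().any():
        raise ValueError("missing design cells: every participant must "
                         "contribute to every factor-level combination")
    cells = [c if isinstance(c, tuple) else (c,) for c in full]
    return piv.to_numpy(float), cells, piv.index


def _levels_present(data: pd.DataFrame, factor: str) -> list:
    present = set(data[factor].unique())
    canonical = CANONICAL_LEVELS.get(factor)
    if canonical is not None and present <= set(canonical):
        return [l for l in canonical if l in present]
    return sorted(present)


def _effect_contrasts(within: tuple[str, ...], n_levels: list[int]
                      ) -> dict[str, np.ndarray]:
    """Orthonormal contrast matrix (prod(levels), df_E) per effect."""
    out = {}
    for r in range(1, len(within) + 1):
        for combo in combinations(range(len(within)), r):
            mats = []
            for i, k in enumerate(n_levels):
                mats.append(_helmert(k) if i in combo
                            else np.full((k, 1), 1.0 / np.sqrt(k)))
            M = mats[0]
            for m2 in mats[1:]:
                M = np.kron(M, m2)
            out[":".join(within[i] for i in combo)] = M
    return out


def _effect_rows(Y: np.ndarray, contrasts: dict[str, np.ndarray],
                 covariate: np.ndarray | None = None) -> pd.DataFrame:
    """Per-effect ANOVA rows from the cell matrix (optionally ANCOVA-adjusted)."""
    n = Y.shape[0]
    rows = []
    for eff, M in contrasts.items():
        D = Y @ M
        k = D.shape[1]
        dbar = D.mean(axis=0)
        ss_eff = n * float(dbar @ dbar)
        resid = D - dbar
        err_df_per_contrast = n - 1
        if covariate is not None:
            x = covariate - covariate.mean()
            sxx = float(x @ x)
            b = (x @ resid) / sxx
            resid = resid - np.outer(x, b)
            err_df_per_contrast = n - 2
        ss_err = float((resid ** 2).sum())
        df1, df2 = k, err_df_per_contrast * k
        F = (ss_eff / df1) / (ss_err / df2)
        S = np.cov(Y @ M, rowvar=False).reshape(k, k) if covariate is None \
            else (resid.T @ resid) / (err_df_per_contrast)
        eps = gg_epsilon(S, contrast=np.eye(k)) if k > 1 else 1.0
        rows.append({
            "effect": eff,
            "F": F,
            "df1": df1 * eps,
            "df2": df2 * eps,
            "df1_uncorrected": df1,
            "df2_uncorrected": df2,
            "p": float(stats.f.sf(F, df1 * eps, df2 * eps)),
            "p_uncorrected": float(stats.f.sf(F, df1, df2)),
            "partial_eta_sq": ss_eff / (ss_eff + ss_err),
            "epsilon": eps,
            "ss_effect": ss_eff,
            "ss_error": ss_err,
        })
    return pd.DataFrame(rows).set_index("effect")


def rm_anova(data: pd.DataFrame, dv: str = "rating",
             within: tuple[str, ...] = STUDY_WITHIN,
             subject: str = "participant_id") -> pd.DataFrame:
    """Balanced repeated-measures ANOVA with GG-corrected dfs and partial eta^2.

    Returns one row per effect (all main effects and interactions) with
    columns F, df1, df2 (epsilon-corrected), p (GG), p_uncorrected,
    partial_eta_sq, epsilon, ss_effect, ss_error.  ``.attrs`` carry the
    subject and total sums of squares for conservation checks.
    """
    Y, cells, _ = cell_matrix(data, dv, within, subject)
    n_levels = [len(_levels_present(data, f)) for f in within]
    res = _effect_rows(Y, _effect_contrasts(within, n_levels))
    m = Y.shape[1]
    subj_means = Y.mean(axis=1)
    res.attrs["ss_subjects"] = m * float(((subj_means - subj_means.mean()) ** 2).sum())
    res.attrs["ss_total"] = float(((Y - Y.mean()) ** 2).sum())
    res.attrs["n_subjects"] = Y.shape[0]
    return res


def rm_ancova(data: pd.DataFrame, covariate: pd.Series, dv: str = "rating",
              within: tuple[str, ...] = STUDY_WITHIN,
              subject: str = "participant_id") -> pd.DataFrame:
    """Repeated-measures ANCOVA with a continuous between-subjects covariate.

    The mean-centred covariate and its interactions with the within effects
    are partialled out of each effect's error term; with a centred covariate
    the within-effect sums of squares are unchanged, so results reduce to
    :func:`rm_anova` when the covariate is uninformative.  A ``covariate``
    row reports the between-subjects regression on participant means.
    """
    Y, cells, subj_index = cell_matrix(data, dv, within, subject)
    x = pd.Series(covariate).reindex(subj_index).to_numpy(float)
    if np.isnan(x).any():
        raise ValueError("covariate missing for some participants")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    n_levels = [len(_levels_present(data, f)) for f in within]
    res = _effect_rows(Y, _effect_contrasts(within, n_levels), covariate=x)

    # between-subjects covariate effect on participant mean ratings
    n, m = Y.shape
    s = Y.mean(axis=1)
    xc = x - x.mean()
    b = float(xc @ (s - s.mean())) / float(xc @ xc)
    ss_cov = m * b * b * float(xc @ xc)
    ss_between = m * float(((s - s.mean()) ** 2).sum())
    ss_res = max(ss_between - ss_cov, 0.0)
    F = np.inf if ss_res == 0 else (ss_cov / 1) / (ss_res / (n - 2))
    cov_row = pd.DataFrame([{
        "effect": "covariate", "F": F, "df1": 1.0, "df2": float(n - 2),
        "df1_uncorrected": 1, "df2_uncorrected": n - 2,
        "p": float(stats.f.sf(F, 1, n - 2)),
        "p_uncorrected": float(stats.f.sf(F, 1, n - 2)),
        "partial_eta_sq": ss_cov / (ss_cov + ss_res),
        "epsilon": 1.0, "ss_effect": ss_cov, "ss_error": ss_res,
    }]).set_index("effect")
    out = pd.concat([res, cov_row])
    out.attrs["n_subjects"] = n
    return out


def paired_t_bonferroni(wide: pd.DataFrame,
                        comparisons: list[tuple] | None = None,
                        family_size: int | None = None) -> list[TTestResult]:
    """Bonferroni-corrected paired t-tests between columns of a wide frame.

    ``wide`` holds one column per level, one row per participant.  The
    adjusted p is the raw p times the family size (default: the number of
    comparisons), capped at 1; Cohen's d for a paired test is t / sqrt(n).
    """
    if len(wide) < 2:
        raise ValueError("need at least 2 participants")
    if comparisons is None:
        comparisons = list(combinations(wide.columns, 2))
    m = family_size if family_size is not None else len(comparisons)
    out = []
    for a, b in comparisons:
        n = len(wide)
        diffs = wide[a].to_numpy(float) - wide[b].to_numpy(float)
        if np.ptp(diffs) == 0 and diffs[0] == 0:
            t, p = 0.0, 1.0  # no difference anywhere
        else:
            res = stats.ttest_rel(wide[a], wide[b])
            t, p = float(res.statistic), float(res.pvalue)
        out.append(TTestResult(
            label=f"{a} vs {b}", t=t, df=float(n - 1), p=p,
            p_adj=min(1.0, p * m), d=t / np.sqrt(n)))
    return out


def welch_t(group_a, group_b, label: str = "", family_size: int = 1) -> TTestResult:
    """Welch's unequal-variance t-test with Satterthwaite df and pooled-SD d."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("both groups constant: t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = (va / len(a) + vb / len(b)) ** 2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1))
    sp = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2))
    d = float((a.mean() - b.mean()) / sp)
    return TTestResult(label=label, t=float(res.statistic), df=float(df),
                       p=float(res.pvalue),
                       p_adj=min(1.0, float(res.pvalue) * family_size), d=d)


def oneway_between_anova(groups: dict[str, np.ndarray] | list[np.ndarray]
                         ) -> pd.Series:
    """One-way between-subjects ANOVA (F, dfs, p, partial eta^2 = SSb/SStot)."""
    vals = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(vals) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 2 for v in vals):
        raise ValueError("each group needs at least 2 observations")
    all_y = np.concatenate([np.asarray(v, float) for v in vals])
    grand = all_y.mean()
    ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in vals)
    ss_total = float(((all_y - grand) ** 2).sum())
    ss_within = ss_total - ss_between
    k, N = len(vals), len(all_y)
    if ss_between == 0:
        F = 0.0
    else:
        F = (ss_between / (k - 1)) / (ss_within / (N - k))
    return pd.Series({
        "F": F, "df1": float(k - 1), "df2": float(N - k),
        "p": float(stats.f.sf(F, k - 1, N - k)),
        "partial_eta_sq": ss_between / ss_total if ss_total > 0 else 0.0,
    })
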