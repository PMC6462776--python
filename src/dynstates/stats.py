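"""Group-level non-parametric inference and demographics statistics.

Omnibus group effects on multivariate dynamic-connectivity measures use a
rank-based permutation MANOVA (Pillai-type trace on columnwise midranks,
p-value from label permutation).  Univariate follow-ups are Kruskal-Wallis
tests with Dunn's pairwise post-hocs under Benjamini-Hochberg FDR
correction; pairwise effect sizes are r^2 = (z/sqrt(n))^2.  Clinical
associations use Spearman rank correlations; medication subgroup contrasts
use Mann-Whitney U.  Demographics tables are reproduced with Pearson
chi-square (no continuity correction), pooled-variance t-tests and one-way
ANOVA computable directly from printed summary statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "kruskal_wallis",
    "dunn_posthoc",
    "nonparametric_manova",
    "effect_size_r2",
    "spearman_clinical",
    "mann_whitney",
    "chi_square",
    "t_from_summary",
    "anova_from_summary",
    "demographics_table",
    "ClinicalCorrelation",
]


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, int, float]:
    """Kruskal-Wallis H with midranks and tie correction.

    Returns (H, df, p).  If every value in every group is identical the
    statistic is 0 with p = 1 (not an error).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), df, float(p)


def dunn_posthoc(groups: list[np.ndarray], labels: list[str] | None = None,
                 method: str = "fdr_bh") -> pd.DataFrame:
    """Dunn's pairwise z tests from pooled midranks with tie correction,
    adjusted across the pairwise family (Benjamini-Hochberg by default).

    Returns a DataFrame with columns group_a, group_b, z, p, p_adj.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    k = len(groups)
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term: sum(t^3 - t) over tied groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    mean_ranks, sizes = [], []
    pos = 0
    for g in groups:
        mean_ranks.append(ranks[pos:pos + g.size].mean())
        sizes.append(g.size)
        pos += g.size
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "z": float(z), "p": min(1.0, float(p))})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"].to_numpy(), method=method)[1]
    return out


def _pillai_H(R: np.ndarray, group_slices: list[np.ndarray],
              grand: np.ndarray, Tinv: np.ndarray) -> float:
    p = R.shape[1]
    H = np.zeros((p, p))
    for idx in group_slices:
        d = R[idx].mean(axis=0) - grand
        H += idx.size * np.outer(d, d)
    return float(np.trace(H @ Tinv))


def nonparametric_manova(
    data: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Rank-based permutation MANOVA.

    Columns are midrank-transformed across subjects; the observed statistic
    is the Pillai-type trace tr(H (H+E)^-1) of a one-way MANOVA on the
    ranks, and the p-value is (1 + #{permuted >= observed}) / (n_perm + 1)
    under random relabeling of subjects.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be subjects x variables")
    n, p = X.shape
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if n < p + uniq.size:
        raise ValueError("too few subjects for the number of variables and groups")
    for j in range(p):
        if np.all(X[:, j] == X[0, j]):
            raise ValueError(f"constant column {j}: cannot rank-transform")
    R = np.column_stack([sps.rankdata(X[:, j]) for j in range(p)])
    grand = R.mean(axis=0)
    T = (R - grand).T @ (R - grand)
    Tinv = np.linalg.pinv(T)
    sizes = [int((labels == u).sum()) for u in uniq]
    slices = []
    start = 0
    for s in sizes:
        slices.append(np.arange(start, start + s))
        start += s
    # order rows by group so permutation = row shuffle against fixed slices
    order = np.concatenate([np.flatnonzero(labels == u) for u in uniq])
    R_ord = R[order]
    observed = _pillai_H(R_ord, slices, grand, Tinv)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _pillai_H(R_ord[perm], slices, grand, Tinv) >= observed - 1e-12:
            count += 1
    pval = (1.0 + count) / (n_perm + 1.0)
    return observed, pval


def effect_size_r2(z: float, n: int) -> float:
    """Pairwise effect size r^2 = (z / sqrt(n))^2 with n the total size of
    the two groups compared."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float((z / np.sqrt(n)) ** 2)


@dataclass
class ClinicalCorrelation:
    measure: str
    clinical_score: str
    rho: float
    p: float
    n: int
    p_adj: float | None = None


def spearman_clinical(
    measures: pd.DataFrame, clinical: pd.DataFrame, fdr: bool = False
) -> list[ClinicalCorrelation]:
    """Spearman rank correlations between every measure column and every
    clinical column, pairwise-complete.  Optionally BH-adjusted across the
    whole family."""
    out: list[ClinicalCorrelation] = []
    for m in measures.columns:
        for c in clinical.columns:
            x = measures[m].to_numpy(dtype=float)
            y = clinical[c].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                raise ValueError(f"fewer than 3 complete pairs for {m} vs {c}")
            if np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0]):
                raise ValueError(f"zero variance in {m} vs {c}")
            rho, p = sps.spearmanr(x[ok], y[ok])
            out.append(ClinicalCorrelation(m, c, float(rho), float(p), int(ok.sum())))
    if fdr and out:
        adj = multipletests([cc.p for cc in out], method="fdr_bh")[1]
        for cc, a in zip(out, adj):
            cc.p_adj = float(a)
    return out


def mann_whitney(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (midranks, tie-corrected).  Reports the smaller of the
    two U orientations; p is exact for small tie-free samples, otherwise the
    normal approximation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    u = min(float(res.statistic), a.size * b.size - float(res.statistic))
    return u, float(res.pvalue)


# ---------------------------------------------------------------------------
# Demographics-table statistics
# ---------------------------------------------------------------------------


def chi_square(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table, no continuity correction.
    Logs a warning (statistic still returned) if any expected cell < 1."""
    table = np.asarray(table, dtype=float)
    chi2, p, df, expected = sps.chi2_contingency(table, correction=False)
    if np.any(expected < 1):
        warnings.warn("expected cell count < 1; chi-square approximation is poor")
    return float(chi2), int(df), float(p)


def t_from_summary(mean1: float, sd1: float, n1: int,
                   mean2: float, sd2: float, n2: int) -> tuple[float, int, float]:
    """Two-sample pooled-variance (Student) t from group summaries;
    df = n1 + n2 - 2."""
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), n1 + n2 - 2, float(res.pvalue)


def anova_from_summary(means: list[float], sds: list[float],
                       ns: list[int]) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA F from per-group means, SDs and sizes."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    k = means.size
    N = int(ns.sum())
    grand = float((ns * means).sum() / N)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df1, df2 = k - 1, N - k
    F = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(F, df1, df2))
    return F, (df1, df2), p


def demographics_table(manifest: pd.DataFrame,
                       group_col: str = "group",
                       categorical: list[str] | None = None,
                       continuous: list[str] | None = None) -> pd.DataFrame:
    """Between-group demographic tests computed from a raw manifest:
    chi-square for categorical columns across all groups, one-way ANOVA for
    continuous columns across all groups."""
    groups = sorted(manifest[group_col].unique())
    rows = []
    for col in categorical or []:
        tab = pd.crosstab(manifest[col], manifest[group_col]).to_numpy()
        chi2, df, p = chi_square(tab)
        rows.append({"variable": col, "test": "chi-square",
                     "statistic": chi2, "df": df, "p": p})
    for col in continuous or []:
        means, sds, ns = [], [], []
        for g in groups:
            v = manifest.loc[manifest[group_col] == g, col].dropna()
            means.append(v.mean())
            sds.append(v.std(ddof=1))
            ns.append(v.size)
        F, (d1, d2), p = anova_from_summary(means, sds, ns)
        rows.append({"variable": col, "test": "one-way ANOVA",
                     "statistic": F, "df": f"{d1},{d2}", "p": p})
    return pd.DataFrame(rows)
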