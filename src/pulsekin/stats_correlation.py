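"""Correlation and differential-testing statistics on the joined matrices.

Implements the absolute (across genes, sample-averaged values), relative
(across genes, between-condition fold changes) and per-group (across
samples within one AS group) Spearman correlation analyses, the protein-CV
quintile analysis over the per-group correlation distribution, and the
differential expression/degradation tests (two-sided t-test with
Benjamini-Hochberg correction; ANOVA + Tukey HSD with a |log2 FC| >= 0.32
gate for multi-isoform genes).

Spearman p-values use the t-approximation t = rho * sqrt((n-2)/(1-rho^2))
with n-2 degrees of freedom; the printed significance cut |rho| > 0.576 at
n = 12, alpha = 0.05 follows from exactly this approximation.  An exact
permutation p-value is available for small n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

PAIRS = {
    "mRNA_kloss": ("mrna", "kloss"),
    "mRNA_protein": ("mrna", "protein"),
    "protein_kloss": ("protein", "kloss"),
}


@dataclass(frozen=True)
class GroupCorrelation:
    group_id: str
    pair: str
    rho: float
    p: float
    n: int


def spearman(x, y, exact: bool = False) -> tuple[float, float, int]:
    """Spearman rho with average-rank ties and its two-sided p-value.

    rho is the Pearson correlation of the rank vectors.  The p-value uses
    the t-approximation (default) or, with ``exact=True`` and n <= 8, full
    enumeration of rank permutations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return math.nan, math.nan, n
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact and n <= 8:
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += abs(r) >= obs - 1e-12
            total += 1
        return rho, count / total, n
    p = spearman_pvalue(rho, n)
    return rho, p, n


def spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p via the t-approximation with n-2 degrees of freedom."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def critical_rho(n: int, alpha: float = 0.05) -> float:
    """Smallest |rho| significant at the two-sided level alpha for n pairs,
    under the t-approximation (0.576 for n = 12, alpha = 0.05)."""
    if n < 3:
        raise ValueError("need n >= 3")
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(math.sqrt(tcrit**2 / (n - 2 + tcrit**2)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# correlation analyses
# ---------------------------------------------------------------------------

def absolute_correlation(matrix, pair: str) -> tuple[float, float, int]:
    """Across-gene Spearman correlation of sample-averaged layer values."""
    lx, ly = PAIRS[pair]
    rows = matrix.complete_rows((lx, ly))
    if len(rows) < 3:
        raise ValueError(f"need >= 3 complete rows, got {len(rows)}")
    x = matrix.layer(lx).loc[rows].mean(axis=1)
    y = matrix.layer(ly).loc[rows].mean(axis=1)
    return spearman(x, y)


def relative_correlation(
    matrix, condition_of: dict[str, str], pair: str
) -> tuple[float, float, int]:
    """Across-gene Spearman correlation of between-condition log2 fold
    changes (condition A minus condition B, per layer)."""
    lx, ly = PAIRS[pair]
    conds = sorted(set(condition_of.values()))
    if len(conds) != 2:
        raise ValueError("relative correlation requires exactly two conditions")
    a = [s for s in matrix.samples if condition_of[s] == conds[0]]
    b = [s for s in matrix.samples if condition_of[s] == conds[1]]
    rows = matrix.complete_rows((lx, ly))
    if len(rows) < 3:
        raise ValueError(f"need >= 3 complete rows, got {len(rows)}")

    def fc(layer):
        df = matrix.layer(layer).loc[rows]
        return df[a].mean(axis=1) - df[b].mean(axis=1)

    return spearman(fc(lx), fc(ly))


def per_group_correlation(matrix, pair: str) -> pd.DataFrame:
    """Per-AS-group Spearman correlation across the per-sample value pairs.

    Rows with an undefined coefficient (constant layer) are flagged with
    rho = NaN.  Returns a DataFrame (group_id, pair, rho, p, n).
    """
    lx, ly = PAIRS[pair]
    rows = matrix.complete_rows((lx, ly))
    x = matrix.layer(lx).loc[rows].to_numpy(dtype=float)
    y = matrix.layer(ly).loc[rows].to_numpy(dtype=float)
    n = x.shape[1]
    rx = stats.rankdata(x, axis=1)
    ry = stats.rankdata(y, axis=1)
    sx = rx.std(axis=1)
    sy = ry.std(axis=1)
    ok = (sx > 0) & (sy > 0)
    rho = np.full(len(rows), np.nan)
    num = ((rx - rx.mean(axis=1, keepdims=True)) * (ry - ry.mean(axis=1, keepdims=True))).mean(axis=1)
    rho[ok] = num[ok] / (sx[ok] * sy[ok])
    p = np.array([spearman_pvalue(r, n) if np.isfinite(r) else np.nan for r in rho])
    return pd.DataFrame(
        {"group_id": rows, "pair": pair, "rho": rho, "p": p, "n": n}
    ).set_index("group_id")


# ---------------------------------------------------------------------------
# CV quintiles
# ---------------------------------------------------------------------------

def cv_quintile_analysis(matrix, correlations: pd.DataFrame) -> dict:
    """Protein-abundance CV across five segments of the per-group
    correlation distribution.

    Groups are split into quintiles Q1..Q5 by ascending rho (stable
    tie-break on group id, segments equal in size +-1).  CV is computed on
    linear-scale protein intensities across samples.  A Kruskal-Wallis
    omnibus test and BH-corrected pairwise Wilcoxon rank-sum tests compare
    the segments.
    """
    common = correlations.index.intersection(matrix.protein.index)
    cors = correlations.loc[common].dropna(subset=["rho"])
    if len(cors) < 5:
        raise ValueError("need at least 5 groups with correlations")
    linear = 2.0 ** matrix.protein.loc[cors.index]
    cv = linear.std(axis=1, ddof=1) / linear.mean(axis=1)

    order = cors.assign(_gid=cors.index).sort_values(["rho", "_gid"], kind="stable").index
    labels = pd.Series(index=order, dtype=object)
    splits = np.array_split(np.arange(len(order)), 5)
    for qi, idx in enumerate(splits, start=1):
        labels.iloc[idx] = f"Q{qi}"

    df = pd.DataFrame({"cv": cv.loc[order], "quintile": labels})
    by_q = [df.loc[df["quintile"] == f"Q{i}", "cv"].to_numpy() for i in range(1, 6)]
    kw_p = float(stats.kruskal(*by_q).pvalue)

    pairs, pvals = [], []
    for i, j in itertools.combinations(range(1, 6), 2):
        res = stats.mannwhitneyu(by_q[i - 1], by_q[j - 1], alternative="two-sided")
        pairs.append((f"Q{i}", f"Q{j}"))
        pvals.append(float(res.pvalue))
    pairwise = pd.DataFrame(pairs, columns=["a", "b"])
    pairwise["p"] = pvals
    pairwise["q"] = bh_adjust(pvals)

    summary = df.groupby("quintile")["cv"].agg(["median", "mean", "size"])
    return {"per_group": df, "summary": summary, "kruskal_p": kw_p, "pairwise": pairwise}


# ---------------------------------------------------------------------------
# differential tests
# ---------------------------------------------------------------------------

def differential_test(
    values: pd.DataFrame, condition_of: dict[str, str]
) -> pd.DataFrame:
    """Per-row two-sided two-sample t-test on log2 values with BH correction.

    ``values`` is keys x samples (log2 scale).  Returns a DataFrame with
    log2_fc (condition A minus B), p, q and test columns; rows with zero
    variance in both groups get p = NaN and are excluded from correction.
    """
    conds = sorted(set(condition_of.values()))
    if len(conds) != 2:
        raise ValueError("differential_test requires exactly two conditions")
    a_cols = [s for s in values.columns if condition_of[s] == conds[0]]
    b_cols = [s for s in values.columns if condition_of[s] == conds[1]]
    a = values[a_cols].to_numpy(dtype=float)
    b = values[b_cols].to_numpy(dtype=float)
    fc = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (np.nanstd(a, axis=1) == 0) & (np.nanstd(b, axis=1) == 0)
    p[degenerate] = np.nan
    out = pd.DataFrame(
        {"log2_fc": fc, "p": p, "q": bh_adjust(p), "test": "t_test"},
        index=values.index,
    )
    out["flagged_zero_variance"] = degenerate
    return out


def isoform_differential(
    peptide_values: pd.DataFrame,
    p_threshold: float = 0.05,
    fc_threshold: float = 0.32,
) -> pd.DataFrame:
    """Differential splicing-isoform test within genes.

    ``peptide_values`` is a long table (gene_id, group_id, value) of
    peptide-level log2 quantities.  Genes with exactly two detected AS
    groups are tested by a two-sided t-test; genes with more use one-way
    ANOVA followed by Tukey HSD.  A gene is called differential only when
    the test is significant (p < ``p_threshold``) and at least one pairwise
    |mean log2 difference| >= ``fc_threshold``.  AS groups with fewer than
    two peptide values are excluded (logged in the output).
    """
    results = []
    for gene, sub in peptide_values.groupby("gene_id", sort=True):
        sizes = sub.groupby("group_id")["value"].size()
        kept = sizes.index[sizes >= 2]
        n_excluded = int((sizes < 2).sum())
        if len(kept) < 2:
            continue
        sub = sub[sub["group_id"].isin(kept)]
        groups = [g["value"].to_numpy(dtype=float) for _, g in sub.groupby("group_id")]
        means = sub.groupby("group_id")["value"].mean()
        if len(kept) == 2:
            p = float(stats.ttest_ind(groups[0], groups[1]).pvalue)
            max_fc = float(abs(means.iloc[0] - means.iloc[1]))
            called = p < p_threshold and max_fc >= fc_threshold
            test = "t_test"
        else:
            p = float(stats.f_oneway(*groups).pvalue)
            tukey = pairwise_tukeyhsd(
                sub["value"].to_numpy(dtype=float), sub["group_id"].to_numpy()
            )
            diffs = np.abs(tukey.meandiffs)
            reject = np.asarray(tukey.reject, dtype=bool)
            max_fc = float(diffs.max())
            called = p < p_threshold and bool(
                np.any(reject & (diffs >= fc_threshold))
            )
            test = "anova_tukey"
        results.append((gene, p, max_fc, called, test, n_excluded))
    out = pd.DataFrame(
        results,
        columns=["gene_id", "p", "max_abs_log2_fc", "called", "test",
                 "n_singleton_groups_excluded"],
    )
    if len(out):
        out["q"] = bh_adjust(out["p"])
    else:
        out["q"] = []
    return out.set_index("gene_id")
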