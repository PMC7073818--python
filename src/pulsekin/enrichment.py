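"""Rank-based 1D and 2D annotation enrichment.

For each annotation term the member scores are compared against the
non-member scores with a two-sided Mann-Whitney U test, and position is
summarized by the bounded rank score

    s = 2 * (mean rank of members - mean rank of non-members) / n

with average ranks for ties and n the total number of scored keys, so that
s lies in (-1, 1) and reaches +-1 exactly when the members occupy an
extreme block of the ranking.  2D enrichment computes the two axis scores
independently on the shared key set; joint significance is the larger
(conservative) of the two per-axis p-values, and terms are labeled by
quadrant (e.g. "upper right" = both scores positive: an mRNA-up, k_loss-up
buffering attempt).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .stats_correlation import bh_adjust


def _rank_score(ranks: np.ndarray, member_mask: np.ndarray) -> float:
    n = len(ranks)
    r_in = ranks[member_mask].mean()
    r_out = ranks[~member_mask].mean()
    return float(2.0 * (r_in - r_out) / n)


def enrich_1d(
    scores: pd.Series,
    annotations: dict[str, set],
    min_members: int = 10,
) -> pd.DataFrame:
    """1D enrichment of annotation terms along one numeric score.

    ``scores`` maps keys (e.g. AS group ids) to real values; ``annotations``
    maps term -> member key set.  Terms with fewer than ``min_members``
    scored members are skipped.  Returns a DataFrame indexed by term with
    columns s, p, q, n_members, sorted by q.
    """
    scores = scores.dropna()
    keys = scores.index
    vals = scores.to_numpy(dtype=float)
    ranks = stats.rankdata(vals)
    key_pos = {k: i for i, k in enumerate(keys)}

    rows = []
    for term, members in annotations.items():
        idx = [key_pos[k] for k in members if k in key_pos]
        if len(idx) < min_members or len(idx) == len(keys):
            continue
        mask = np.zeros(len(keys), dtype=bool)
        mask[idx] = True
        s = _rank_score(ranks, mask)
        p = float(
            stats.mannwhitneyu(vals[mask], vals[~mask], alternative="two-sided").pvalue
        )
        rows.append((term, s, p, int(mask.sum())))
    out = pd.DataFrame(rows, columns=["term", "s", "p", "n_members"]).set_index("term")
    out["q"] = bh_adjust(out["p"]) if len(out) else []
    return out.sort_values("q")[["s", "p", "q", "n_members"]]


def _quadrant(sx: float, sy: float) -> str:
    vert = "upper" if sy > 0 else "lower"
    horiz = "right" if sx > 0 else "left"
    return f"{vert} {horiz}"


def enrich_2d(
    scores_x: pd.Series,
    scores_y: pd.Series,
    annotations: dict[str, set],
    min_members: int = 10,
) -> pd.DataFrame:
    """2D enrichment on two score axes restricted to their shared keys.

    Per-axis scores and Mann-Whitney p-values are computed independently;
    the reported p is the larger of the two (conservative joint test), BH
    corrected across terms.  Each term is labeled with its quadrant.
    """
    common = scores_x.dropna().index.intersection(scores_y.dropna().index)
    ex = enrich_1d(scores_x.loc[common], annotations, min_members)
    ey = enrich_1d(scores_y.loc[common], annotations, min_members)
    terms = ex.index.intersection(ey.index)
    out = pd.DataFrame(
        {
            "s_x": ex.loc[terms, "s"],
            "s_y": ey.loc[terms, "s"],
            "p": np.maximum(ex.loc[terms, "p"], ey.loc[terms, "p"]),
            "n_members": ex.loc[terms, "n_members"],
        }
    )
    out["q"] = bh_adjust(out["p"]) if len(out) else []
    out["quadrant"] = [
        _quadrant(sx, sy) for sx, sy in zip(out["s_x"], out["s_y"])
    ]
    return out.sort_values("q")[["s_x", "s_y", "p", "q", "n_members", "quadrant"]]


def read_annotations(path) -> dict[str, set]:
    """Two-column TSV (term, key) -> term -> key set."""
    df = pd.read_csv(path, sep="\t", comment="#", header=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need two columns (term, key)")
    term_col, key_col = df.columns[:2]
    out: dict[str, set] = {}
    for term, sub in df.groupby(term_col):
        out[str(term)] = set(sub[key_col].astype(str))
    return out
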