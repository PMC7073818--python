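"""Alternative-splicing switch calling between two conditions.

A gene emits a switch event when its major (most abundant, mean FPKM)
isoform differs between the two conditions.  Genes must clear an expression
prefilter (non-zero FPKM in all replicate columns and FPKM > 1 in a minimum
number of columns, per transcript), a summed-expression threshold in a
minimum share of samples, and a dominance requirement (major / second
isoform ratio) in both conditions.  Events are classed by the ordered
biotype pair of the two majors (retained-intron vs protein-coding).

This is a simplified, declared re-specification of switch calling from
transcript dominance, not a port of any external caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SwitchConfig:
    gene_expression_threshold: float = 1.0  # summed FPKM a gene must exceed
    expression_breadth: float = 50.0  # percent of samples above the threshold
    dominance: float = 1.0  # min major / second-isoform FPKM ratio
    prefilter_min_expressed: int = 3  # columns with FPKM > 1 per transcript
    prefilter_nonzero_all: bool = True

    def __post_init__(self) -> None:
        for name in ("gene_expression_threshold", "expression_breadth", "dominance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SwitchEvent:
    gene_id: str
    major_A: str
    major_B: str
    dominance_A: float
    dominance_B: float
    cls: str  # RI_to_coding | coding_to_RI | coding_to_coding | other


def _classify(bio_a: str, bio_b: str) -> str:
    if bio_a == "retained_intron" and bio_b == "protein_coding":
        return "RI_to_coding"
    if bio_a == "protein_coding" and bio_b == "retained_intron":
        return "coding_to_RI"
    if bio_a == bio_b == "protein_coding":
        return "coding_to_coding"
    return "other"


def call_switches(
    expression: pd.DataFrame,
    transcripts: pd.DataFrame,
    condition_of: dict[str, str],
    config: SwitchConfig = SwitchConfig(),
) -> list[SwitchEvent]:
    """Call major-isoform switch events between exactly two conditions.

    ``condition_of`` maps sample -> condition label; the lexicographically
    smaller label is condition A.  Expression columns are (sample,
    replicate) pairs; replicates are pooled for breadth counting.
    """
    conds = sorted(set(condition_of.values()))
    if len(conds) != 2:
        raise ValueError(f"exactly two conditions required, got {conds}")
    cond_a, cond_b = conds

    gene_of = transcripts.set_index("transcript_id")["gene_id"]
    biotype_of = transcripts.set_index("transcript_id")["biotype"]

    expr = expression.copy()
    # per-transcript prefilter over all replicate columns
    if config.prefilter_nonzero_all:
        keep = (expr > 0).all(axis=1)
    else:
        keep = pd.Series(True, index=expr.index)
    keep &= (expr > 1.0).sum(axis=1) >= config.prefilter_min_expressed
    expr = expr[keep]

    col_cond = np.array([condition_of[s] for s, _ in expr.columns])
    a_cols = expr.columns[col_cond == cond_a]
    b_cols = expr.columns[col_cond == cond_b]

    genes = gene_of.reindex(expr.index)
    events: list[SwitchEvent] = []
    for gene, sub in expr.groupby(genes, sort=True):
        if len(sub) < 2:
            continue
        summed = sub.sum(axis=0)
        breadth = float((summed > config.gene_expression_threshold).mean() * 100.0)
        if breadth < config.expression_breadth:
            continue

        def major_and_dominance(cols):
            means = sub[cols].mean(axis=1).sort_values(ascending=False, kind="stable")
            major = means.index[0]
            second = means.iloc[1] if len(means) > 1 else 0.0
            dom = float(means.iloc[0] / second) if second > 0 else float("inf")
            return major, dom

        major_a, dom_a = major_and_dominance(a_cols)
        major_b, dom_b = major_and_dominance(b_cols)
        if dom_a < config.dominance or dom_b < config.dominance:
            continue
        if major_a == major_b:
            continue
        cls = _classify(biotype_of[major_a], biotype_of[major_b])
        events.append(SwitchEvent(gene, major_a, major_b, dom_a, dom_b, cls))
    return events


def events_frame(events: list[SwitchEvent]) -> pd.DataFrame:
    rows = [
        (e.gene_id, e.major_A, e.major_B, e.dominance_A, e.dominance_B, e.cls)
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "major_A", "major_B", "dominance_A", "dominance_B", "class"],
    )


def switch_consequences(
    events: list[SwitchEvent],
    protein_fc: pd.Series,
    kloss_fc: pd.Series | None = None,
    control_class: str = "coding_to_coding",
    min_values: int = 3,
) -> pd.DataFrame:
    """Protein / k_loss fold-change consequences of switch classes.

    ``protein_fc`` (and optionally ``kloss_fc``) are log2 fold changes
    (condition A over B) keyed by gene id.  Each class's distribution is
    compared to the ``control_class`` by a two-sided rank-sum test; classes
    with fewer than ``min_values`` matched values keep their summary but
    skip the test.
    """
    ev = events_frame(events)
    layers = {"protein": protein_fc}
    if kloss_fc is not None:
        layers["kloss"] = kloss_fc

    rows = []
    for layer, fc in layers.items():
        matched = ev.assign(fc=ev["gene_id"].map(fc)).dropna(subset=["fc"])
        control = matched.loc[matched["class"] == control_class, "fc"].to_numpy()
        for cls, sub in matched.groupby("class"):
            vals = sub["fc"].to_numpy()
            if cls == control_class:
                p = 1.0  # self-comparison contract
            elif len(vals) >= min_values and len(control) >= min_values:
                p = float(
                    stats.mannwhitneyu(vals, control, alternative="two-sided").pvalue
                )
            else:
                p = float("nan")
            rows.append((layer, cls, len(vals), float(np.median(vals)), p))
    return pd.DataFrame(
        rows, columns=["layer", "class", "n", "median_log2_fc", "p_vs_control"]
    )
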