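"""Joined per-(AS group, sample) matrices of protein, k_loss and mRNA.

The protein layer is built from peptide intensities: per peptide and sample
the median over replicate injections (at least two quantified replicates
required), peptides must be quantified in every sample ("full profiles"),
and member-peptide intensities are summed in linear scale before log2
(configurable log-space summing).  UQ groups take the FPKM of their single
transcript, SM groups that of their representative (major) transcript;
per-sample FPKM is the mean over replicates, log2-transformed with FPKM 0
mapped to missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LAYERS = ("protein", "kloss", "mrna")


@dataclass(frozen=True)
class AssemblyConfig:
    min_replicates: int = 2
    min_peptides: int = 2
    collapse: str = "sum_linear"  # or "sum_log"
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.collapse not in ("sum_linear", "sum_log"):
            raise ValueError("collapse must be 'sum_linear' or 'sum_log'")


@dataclass
class OmicsMatrix:
    """Aligned group x sample log2 matrices plus per-group metadata."""

    protein: pd.DataFrame  # log2 intensity
    kloss: pd.DataFrame  # log2 k_loss
    mrna: pd.DataFrame  # log2 FPKM
    meta: pd.DataFrame  # group_id-indexed: gene_id, class, representative

    @property
    def samples(self) -> list[str]:
        return list(self.protein.columns)

    def layer(self, name: str) -> pd.DataFrame:
        return {"protein": self.protein, "kloss": self.kloss, "mrna": self.mrna}[name]

    def complete_rows(self, layers=LAYERS) -> pd.Index:
        """Groups with no missing value in any requested layer."""
        ok = pd.Series(True, index=self.protein.index)
        for name in layers:
            ok &= self.layer(name).notna().all(axis=1)
        return ok.index[ok]


def peptide_intensity_from_psilac(precursors: pd.DataFrame) -> pd.DataFrame:
    """Total (L+H) peptide intensity per (sample, replicate).

    Under steady state L+H is constant over the labeling course, so the
    per-injection protein amount is the channel sum averaged over time
    points, summed over charge states.  Returns a long table (sample,
    replicate, peptide, intensity).
    """
    per_time = (
        precursors.groupby(
            ["sample", "replicate", "peptide", "charge", "time_h"], sort=False
        )["intensity"]
        .sum(min_count=1)
        .reset_index()
    )
    per_charge = (
        per_time.groupby(["sample", "replicate", "peptide", "charge"], sort=False)[
            "intensity"
        ]
        .mean()
        .reset_index()
    )
    out = (
        per_charge.groupby(["sample", "replicate", "peptide"], sort=False)["intensity"]
        .sum(min_count=1)
        .reset_index()
    )
    return out


def assemble_protein_matrix(
    peptide_intensities: pd.DataFrame,
    assignments: dict,
    groups: list,
    config: AssemblyConfig = AssemblyConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Group x sample log2 protein intensity matrix.

    ``peptide_intensities`` is a long table (sample, replicate, peptide,
    intensity) in linear scale.  Returns (matrix, log of exclusion counts).
    """
    log: dict[str, int] = {}
    df = peptide_intensities.copy()
    multi = {p for p, a in assignments.items() if a.cls == "multi_gene"}
    known = set(assignments)
    n0 = df["peptide"].nunique()
    df = df[df["peptide"].isin(known - multi)]
    log["multi_gene_or_unmapped_peptides"] = n0 - df["peptide"].nunique()

    g = df.dropna(subset=["intensity"]).groupby(["peptide", "sample"])["intensity"]
    med = g.median()
    nrep = g.size()
    med = med[nrep >= config.min_replicates]
    log["peptide_sample_below_min_replicates"] = int((nrep < config.min_replicates).sum())

    wide = med.unstack("sample")
    samples = sorted(df["sample"].unique())
    wide = wide.reindex(columns=samples)
    full = wide.dropna(axis=0, how="any")
    log["non_full_profile_peptides"] = len(wide) - len(full)

    rows = {}
    n_small = 0
    for grp in groups:
        members = sorted(set(grp.peptides) & set(full.index))
        if len(members) < config.min_peptides:
            n_small += 1
            continue
        vals = full.loc[members].to_numpy(dtype=float)
        if config.collapse == "sum_linear":
            rows[grp.group_id] = np.log2(vals.sum(axis=0))
        else:
            rows[grp.group_id] = np.log2(vals).sum(axis=0)
    log["groups_below_min_peptides"] = n_small
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    mat.index.name = "group_id"
    return mat, log


def join_omics(
    protein_matrix: pd.DataFrame,
    group_kloss: pd.DataFrame,
    expression: pd.DataFrame,
    groups: list,
    config: AssemblyConfig = AssemblyConfig(),
) -> OmicsMatrix:
    """Merge the three layers protein-centrically.

    Rows are the AS groups present in the protein matrix; ``group_kloss``
    already holds log2 k_loss per group and sample.  The mRNA value of a
    group is the log2 per-sample mean FPKM (over replicates) of its single
    (UQ) or representative major (SM) transcript.
    """
    by_id = {g.group_id: g for g in groups}
    samples = list(protein_matrix.columns)
    per_sample_fpkm = expression.T.groupby(level="sample").mean().T

    mrna_rows = {}
    meta_rows = {}
    for gid in protein_matrix.index:
        g = by_id.get(gid)
        if g is None:
            raise ValueError(f"protein matrix row {gid!r} has no AS group record")
        rep = g.representative_transcript
        if rep not in per_sample_fpkm.index:
            raise ValueError(f"group {gid!r}: representative transcript {rep!r} "
                             "absent from expression matrix")
        fpkm = per_sample_fpkm.loc[rep, samples].to_numpy(dtype=float)
        fpkm = fpkm + config.pseudocount
        with np.errstate(divide="ignore"):
            vals = np.where(fpkm > 0, np.log2(np.where(fpkm > 0, fpkm, 1.0)), np.nan)
        mrna_rows[gid] = vals
        meta_rows[gid] = (g.gene_id, g.cls, rep)

    mrna = pd.DataFrame.from_dict(mrna_rows, orient="index", columns=samples)
    meta = pd.DataFrame.from_dict(
        meta_rows, orient="index", columns=["gene_id", "class", "representative"]
    )
    kloss = group_kloss.reindex(index=protein_matrix.index, columns=samples)
    for df in (mrna, meta, kloss):
        df.index.name = "group_id"
    return OmicsMatrix(protein=protein_matrix, kloss=kloss, mrna=mrna, meta=meta)
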