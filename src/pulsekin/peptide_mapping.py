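"""In-silico tryptic digestion and peptide-to-isoform inference.

Peptides observed by MS are classified against an expression-filtered protein
database: *unique* peptides map to exactly one splicing isoform, *shared*
peptides map to several isoforms of the same gene, and peptides mapping to
more than one gene are excluded from all quantification.  Shared peptides
with an identical isoform footprint are assembled into one shared-major (SM)
AS group whose representative transcript is the isoform with the highest
average mRNA abundance; unique peptides form single-isoform (UQ) groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from pyteomics import parser as _pyt_parser

from .io_formats import is_valid_peptide

# cleave C-terminally of K/R unless followed by P (no WKP/MRP exceptions)
TRYPSIN_RULE = r"[KR](?!P)"


@dataclass(frozen=True)
class DigestConfig:
    """Tryptic digestion settings.

    missed_cleavages: maximum internal K/R sites left uncut (default 2).
    min_length/max_length: retained peptide length window, 7-30 residues by
    default (typical DIA detectability range).
    """

    missed_cleavages: int = 2
    min_length: int = 7
    max_length: int = 30

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


@dataclass(frozen=True)
class PeptideAssignment:
    peptide: str
    transcript_ids: frozenset
    gene_ids: frozenset
    cls: str  # unique | shared | multi_gene


@dataclass(frozen=True)
class ASGroup:
    """An isoform (UQ) or indistinguishable-isoform set (SM) of one gene."""

    group_id: str
    gene_id: str
    member_transcripts: frozenset
    cls: str  # UQ | SM
    representative_transcript: str
    peptides: frozenset = field(default_factory=frozenset)


def digest(protein_sequence: str, config: DigestConfig = DigestConfig()) -> set[str]:
    """Fully tryptic peptides of a protein within the configured constraints.

    Cleavage occurs C-terminal to K or R except before proline.  All
    fragments with at most ``missed_cleavages`` internal sites and length in
    ``[min_length, max_length]`` are returned.
    """
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    if not is_valid_peptide(protein_sequence):
        raise ValueError(f"illegal residue in sequence {protein_sequence[:20]!r}...")
    peps = _pyt_parser.cleave(
        protein_sequence,
        TRYPSIN_RULE,
        missed_cleavages=config.missed_cleavages,
        min_length=config.min_length,
    )
    return {p for p in peps if len(p) <= config.max_length}


def build_peptide_map(
    transcripts: pd.DataFrame, config: DigestConfig = DigestConfig()
) -> dict[str, set[str]]:
    """Digest every database entry; return peptide -> set of transcript ids."""
    mapping: dict[str, set[str]] = {}
    for row in transcripts.itertuples(index=False):
        if not row.protein_sequence:
            continue
        for pep in digest(row.protein_sequence, config):
            mapping.setdefault(pep, set()).add(row.transcript_id)
    return mapping


def classify_peptides(
    peptide_map: dict[str, set[str]], transcripts: pd.DataFrame
) -> dict[str, PeptideAssignment]:
    """Label every peptide unique / shared / multi_gene.

    multi_gene peptides are kept in the returned mapping (for reporting) but
    must be excluded from all downstream quantification.
    """
    gene_of = dict(zip(transcripts["transcript_id"], transcripts["gene_id"]))
    out: dict[str, PeptideAssignment] = {}
    for pep, tids in peptide_map.items():
        genes = frozenset(gene_of[t] for t in tids)
        if len(genes) > 1:
            cls = "multi_gene"
        elif len(tids) == 1:
            cls = "unique"
        else:
            cls = "shared"
        out[pep] = PeptideAssignment(pep, frozenset(tids), genes, cls)
    return out


def _mean_fpkm(expression: pd.DataFrame) -> pd.Series:
    """Average FPKM of each transcript over all samples and replicates."""
    return expression.mean(axis=1)


def assemble_as_groups(
    assignments: dict[str, PeptideAssignment], expression: pd.DataFrame
) -> list[ASGroup]:
    """Build UQ and SM AS groups from peptide assignments.

    Unique peptides of one transcript form a UQ group keyed by that
    transcript.  Shared peptides with identical transcript-id footprints form
    one SM group; its representative is the member transcript with the
    highest FPKM averaged over all samples (transcripts absent from the
    expression matrix count as 0), ties broken by lexicographically smallest
    transcript id.
    """
    avg = _mean_fpkm(expression)

    by_footprint: dict[tuple[str, frozenset], set[str]] = {}
    for a in assignments.values():
        if a.cls == "multi_gene":
            continue
        gene = next(iter(a.gene_ids))
        by_footprint.setdefault((gene, a.transcript_ids), set()).add(a.peptide)

    groups: list[ASGroup] = []
    for (gene, tids), peps in sorted(
        by_footprint.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1]))
    ):
        if len(tids) == 1:
            (tid,) = tids
            groups.append(
                ASGroup(f"UQ:{tid}", gene, tids, "UQ", tid, frozenset(peps))
            )
        else:
            rep = min(sorted(tids), key=lambda t: (-float(avg.get(t, 0.0)), t))
            gid = "SM:" + "+".join(sorted(tids))
            groups.append(ASGroup(gid, gene, tids, "SM", rep, frozenset(peps)))
    return groups


def assignments_frame(assignments: dict[str, PeptideAssignment]) -> pd.DataFrame:
    rows = [
        (
            a.peptide,
            ";".join(sorted(a.transcript_ids)),
            ";".join(sorted(a.gene_ids)),
            a.cls,
        )
        for a in assignments.values()
    ]
    return pd.DataFrame(
        rows, columns=["peptide", "transcript_ids", "gene_ids", "class"]
    ).sort_values("peptide", ignore_index=True)


def groups_frame(groups: list[ASGroup]) -> pd.DataFrame:
    rows = [
        (
            g.group_id,
            g.gene_id,
            ";".join(sorted(g.member_transcripts)),
            g.cls,
            g.representative_transcript,
            ";".join(sorted(g.peptides)),
        )
        for g in groups
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "group_id",
            "gene_id",
            "member_transcripts",
            "class",
            "representative_transcript",
            "peptides",
        ],
    )
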