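"""Readers and writers for the external text formats the pipeline touches.

All tabular data are tab-separated UTF-8 text with a header row; protein
sequences travel as FASTA with ``>transcript_id|gene_id|biotype`` headers.
Readers validate strictly and raise :class:`FormatError` (citing the offending
line where possible) rather than silently coercing malformed input.

Conventions
-----------
* Intensities of exactly 0 are stored as missing (below detection limit);
  DIA software exports use 0 and blank interchangeably.
* Output tables carry a provenance comment line ``# pulsekin <version>
  <command> <seed>`` which readers skip.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

# the 20 proteinogenic residues; B/J/O/U/X/Z are rejected
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_RE = re.compile(r"^[%s]+$" % AMINO_ACIDS)

PRECURSOR_COLUMNS = [
    "sample",
    "replicate",
    "time_h",
    "peptide",
    "charge",
    "channel",
    "intensity",
]
TRANSCRIPT_COLUMNS = ["gene_id", "transcript_id", "biotype", "protein_sequence"]
BIOTYPES = ("protein_coding", "retained_intron", "other")
CHANNELS = ("light", "heavy")


class FormatError(ValueError):
    """Malformed external input."""


def provenance_line(command: str = "", seed: int | None = None) -> str:
    seed_part = "" if seed is None else f" seed={seed}"
    return f"# pulsekin {__version__} {command}{seed_part}".rstrip()


def is_valid_peptide(seq: str) -> bool:
    return bool(_AA_RE.match(seq))


# ---------------------------------------------------------------------------
# precursor quantity tables
# ---------------------------------------------------------------------------

def read_precursor_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a long-format precursor quantity table.

    Parameters
    ----------
    path
        TSV file with a header naming at least the seven canonical columns
        (``sample, replicate, time_h, peptide, charge, channel, intensity``).
    column_map
        Optional ``{canonical_name: file_column}`` mapping so exports using
        different column names (e.g. a DIA software "report") can be adapted
        without editing the file.

    Returns
    -------
    DataFrame with the canonical columns; intensity is float with NaN for
    missing/zero/unparseable values.  The number of rows whose intensity
    could not be parsed is recorded in ``df.attrs["n_unparseable"]``.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in PRECURSOR_COLUMNS}
    missing = [column_map.get(c, c) for c in PRECURSOR_COLUMNS if column_map.get(c, c) not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = raw.rename(columns=rename)[PRECURSOR_COLUMNS].copy()

    bad_pep = ~df["peptide"].map(lambda s: isinstance(s, str) and is_valid_peptide(s))
    if bad_pep.any():
        i = int(np.flatnonzero(bad_pep)[0])
        raise FormatError(
            f"{path}: line {i + 2}: peptide {df['peptide'].iloc[i]!r} contains "
            "characters outside the amino-acid alphabet"
        )
    bad_chan = ~df["channel"].isin(CHANNELS)
    if bad_chan.any():
        i = int(np.flatnonzero(bad_chan)[0])
        raise FormatError(
            f"{path}: line {i + 2}: channel must be one of {CHANNELS}, got "
            f"{df['channel'].iloc[i]!r}"
        )

    for col, typ in (("replicate", int), ("charge", int)):
        try:
            df[col] = df[col].astype(typ)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: column {col!r} is not integer: {exc}") from None
    df["time_h"] = pd.to_numeric(df["time_h"], errors="raise").astype(float)
    if (df["time_h"] < 0).any():
        raise FormatError(f"{path}: negative labeling time")
    if (df["charge"] < 1).any():
        raise FormatError(f"{path}: charge must be positive")

    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    n_unparseable = int((intensity.isna() & df["intensity"].notna()).sum())
    if (intensity < 0).any():
        raise FormatError(f"{path}: negative intensity")
    # 0 == below detection limit -> missing
    df["intensity"] = intensity.mask(intensity == 0, np.nan)
    df.attrs["n_unparseable"] = n_unparseable

    key = ["sample", "replicate", "time_h", "peptide", "charge", "channel"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise FormatError(f"{path}: duplicate precursor key {tuple(first)}")
    return df


def write_precursor_table(
    df: pd.DataFrame, path: str | Path, command: str = "", seed: int | None = None
) -> None:
    _write_tsv(df[PRECURSOR_COLUMNS], path, command, seed, index=False)


# ---------------------------------------------------------------------------
# transcript annotation
# ---------------------------------------------------------------------------

def read_transcripts(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in TRANSCRIPT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df[TRANSCRIPT_COLUMNS].copy()
    df["protein_sequence"] = df["protein_sequence"].fillna("")
    if df["transcript_id"].duplicated().any():
        dup = df.loc[df["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise FormatError(f"{path}: duplicate transcript_id {dup!r}")
    bad = ~df["biotype"].isin(BIOTYPES)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise FormatError(
            f"{path}: line {i + 2}: unknown biotype {df['biotype'].iloc[i]!r}"
        )
    coding = df["biotype"] == "protein_coding"
    empty = df["protein_sequence"] == ""
    if (coding & empty).any():
        tid = df.loc[coding & empty, "transcript_id"].iloc[0]
        raise FormatError(f"{path}: protein_coding transcript {tid!r} lacks a sequence")
    nonempty = df.loc[~empty, "protein_sequence"]
    bad_seq = ~nonempty.map(is_valid_peptide)
    if bad_seq.any():
        tid = df.loc[nonempty.index[bad_seq], "transcript_id"].iloc[0]
        raise FormatError(f"{path}: transcript {tid!r}: illegal residue in sequence")
    return df


def write_transcripts(
    df: pd.DataFrame, path: str | Path, command: str = "", seed: int | None = None
) -> None:
    _write_tsv(df[TRANSCRIPT_COLUMNS], path, command, seed, index=False)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read an FPKM matrix: rows transcripts, columns ``sample:replicate``.

    Returns a DataFrame indexed by transcript_id whose columns are a
    two-level MultiIndex (sample, replicate).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.name != "transcript_id":
        raise FormatError(f"{path}: first column must be 'transcript_id'")
    cols = []
    for c in df.columns:
        if ":" not in c:
            raise FormatError(
                f"{path}: column {c!r} is not of the form 'sample:replicate'"
            )
        sample, rep = c.rsplit(":", 1)
        try:
            cols.append((sample, int(rep)))
        except ValueError:
            raise FormatError(f"{path}: non-integer replicate in column {c!r}") from None
    out = df.copy()
    out.columns = pd.MultiIndex.from_tuples(cols, names=["sample", "replicate"])
    vals = out.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise FormatError(f"{path}: missing FPKM value")
    if (vals < 0).any():
        r, c = map(int, np.argwhere(vals < 0)[0])
        raise FormatError(
            f"{path}: negative FPKM for transcript {out.index[r]!r} "
            f"in column {df.columns[c]!r}"
        )
    return out.astype(float)


def write_expression_matrix(
    df: pd.DataFrame, path: str | Path, command: str = "", seed: int | None = None
) -> None:
    flat = df.copy()
    flat.columns = [f"{s}:{r}" for s, r in df.columns]
    flat.index.name = "transcript_id"
    _write_tsv(flat, path, command, seed, index=True)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(transcripts: pd.DataFrame, path: str | Path) -> None:
    """Write protein sequences as FASTA, header ``>transcript_id|gene_id|biotype``."""
    records = []
    for row in transcripts.itertuples(index=False):
        if not row.protein_sequence:
            continue
        rid = f"{row.transcript_id}|{row.gene_id}|{row.biotype}"
        records.append(SeqRecord(Seq(row.protein_sequence), id=rid, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> pd.DataFrame:
    """Read a ``>transcript_id|gene_id|biotype`` FASTA back into a table."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise FormatError(
                f"{path}: header {rec.id!r} is not 'transcript_id|gene_id|biotype'"
            )
        tid, gid, biotype = parts
        seq = str(rec.seq)
        if not is_valid_peptide(seq):
            raise FormatError(f"{path}: record {tid!r}: illegal residue in sequence")
        rows.append((gid, tid, biotype, seq))
    return pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS)


# ---------------------------------------------------------------------------
# generic TSV with provenance
# ---------------------------------------------------------------------------

def _write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    command: str,
    seed: int | None,
    index: bool,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(provenance_line(command, seed) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    command: str = "",
    seed: int | None = None,
    index: bool = False,
) -> None:
    """Write any result table as TSV with the provenance comment line."""
    _write_tsv(df, path, command, seed, index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
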