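"""Reading and writing the external file formats.

Tables are tab-separated UTF-8 with a header row; lines starting with
``#`` are comments.  Sequences travel as FASTA via Biopython.  Residue
coordinates are 1-based inclusive everywhere in this package.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

MEDIA = ("selective", "permissive")

PLATE_COLUMNS = ["gene_id", "plate_id", "row", "col", "replicate", "medium", "size_px"]
PLATE_KEY = ["gene_id", "plate_id", "replicate", "medium"]


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence (gapped only inside alignments)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record needs a non-empty id")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a generic TSV table ('#' lines are comments)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_plate_table(path: str | Path, dialect: dict | None = None) -> pd.DataFrame:
    """Read and validate a long-form colony-size table.

    The expected columns are ``gene_id, plate_id, row, col, replicate,
    medium, size_px``; ``dialect`` may map external header names onto
    these (e.g. ``{"orf": "gene_id"}``) to adapt colony-quantification
    exports.

    Raises
    ------
    FormatError
        If a required column is missing, a size is non-numeric, a medium
        label is unknown, or a (gene, plate, replicate, medium) key is
        duplicated.
    """
    df = read_table(path)
    if dialect:
        df = df.rename(columns=dialect)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"plate table {path} is missing column(s): {', '.join(missing)}")
    df = df[PLATE_COLUMNS].copy()

    sizes = pd.to_numeric(df["size_px"], errors="coerce")
    bad = df.index[sizes.isna() | ~pd.Series(map(_finite, sizes), index=df.index)]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise FormatError(
            f"non-numeric or non-finite size_px at line {int(bad[0]) + 2} of {path}"
        )
    df["size_px"] = sizes.astype(float)
    if (df["size_px"] < 0).any():
        raise FormatError("size_px must be >= 0")

    unknown = set(df["medium"]) - set(MEDIA)
    if unknown:
        raise FormatError(f"unknown medium label(s): {sorted(unknown)}")

    for col in ("row", "col", "replicate"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
        if (df[col] < 1).any():
            raise FormatError(f"column {col!r} must be >= 1")

    dup = df.duplicated(subset=PLATE_KEY)
    if dup.any():
        key = df.loc[dup.idxmax(), PLATE_KEY].tolist()
        raise FormatError(f"duplicated (gene, plate, replicate, medium) key: {key}")
    return df


def write_plate_table(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df[PLATE_COLUMNS], path)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records in file order; uppercased, '*' stops stripped."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("*", "")
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta-2line")


def read_alignment(path: str | Path) -> list[SequenceRecord]:
    """Read an aligned FASTA; all records must have equal length."""
    records = read_fasta(path)
    lengths = {len(r) for r in records}
    if len(lengths) > 1:
        raise FormatError(f"ragged alignment in {path}: lengths {sorted(lengths)}")
    return records


def load_config(path: str | Path | None) -> dict:
    """Load a flat YAML config; absent path gives an empty mapping."""
    if path is None:
        return {}
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"config {path} must be a mapping")
    return data


def merge_config(config: dict, flags: dict) -> dict:
    """Merge CLI flags over a config file; explicit flags win."""
    merged = dict(config)
    merged.update({k: v for k, v in flags.items() if v is not None})
    return merged


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def as_records(pairs: Sequence[tuple[str, str]]) -> list[SequenceRecord]:
    """Convenience constructor used by tests and simulators."""
    return [SequenceRecord(id=i, sequence=s) for i, s in pairs]
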