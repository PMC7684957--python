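"""FASTA input and TSV/JSON report output.

All primary outputs are TSV with a header line preceded by '#'-prefixed
metadata, plus JSON sidecars for nested results, so re-running a command
with identical configuration produces byte-identical files.
"""

from __future__ import annotations

import gzip
import io as _io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

__all__ = ["FastaRecord", "read_fasta", "write_fasta", "write_tsv", "write_json"]


@dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str  # uppercased; ambiguity characters preserved


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read a (possibly gzipped) FASTA file into uppercase records.

    Raises with a line number when the file does not start with a '>'
    header, and explicitly on empty input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: malformed FASTA, line {lineno} precedes any '>' header"
                )
            break
        else:
            raise ValueError(f"{path}: empty FASTA input")
    with _open_text(path) as fh:
        records = [
            FastaRecord(id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(fh, "fasta")
        ]
    if not records:
        raise ValueError(f"{path}: empty FASTA input")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_tsv(path: str | Path, frame: pd.DataFrame, metadata: dict | None = None) -> None:
    """TSV with '#'-prefixed metadata lines above the header row."""
    buf = _io.StringIO()
    for key, val in (metadata or {}).items():
        buf.write(f"# {key}={val}\n")
    frame.to_csv(buf, sep="\t", index=False, float_format="%.10g")
    Path(path).write_text(buf.getvalue())


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
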