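"""File formats, run configuration and logging.

All genomic coordinates in files written by this package follow BED
conventions: 0-based, half-open intervals. FASTA/FASTQ I/O is gzip
transparent (by ``.gz`` suffix) and normalizes sequences to uppercase.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pydantic import BaseModel, ConfigDict

from . import __version__
from .errors import ConfigError, InputError, ParseError

logger = logging.getLogger("mpralocus")

DEFAULT_LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s %(message)s"

#: Fixed synthetic vector arms flanking the barcode in read 1 (20 nt each).
#: These stand in for the reporter vector's unpublished priming arms and are
#: part of this package's read-layout format.
ANCHOR_5 = "ACACGACGCTCTTCCGATCT"
ANCHOR_3 = "AGATCGGAAGAGCACACGTC"


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a basic stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(DEFAULT_LOG_FORMAT))
        logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

@dataclass
class FastqRecord:
    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise InputError(
                f"record {self.id}: sequence and quality lengths differ"
            )


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTA file as ``[(id, sequence), ...]``.

    Sequences are uppercased.
    """
    with _open_text(path, "r") as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
            fh,
            "fasta",
        )


def read_fastq(path: str | Path) -> list[FastqRecord]:
    """Read a (possibly gzipped) FASTQ file; sequences uppercased."""
    out: list[FastqRecord] = []
    with _open_text(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            out.append(FastqRecord(rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.quality}\n")


def iter_fastq_sequences(path: str | Path) -> Iterator[str]:
    """Stream just the sequences of a FASTQ file (uppercased)."""
    with _open_text(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


# ---------------------------------------------------------------------------
# bedGraph / BED
# ---------------------------------------------------------------------------

def write_bedgraph(
    values: Sequence[float],
    ref_id: str,
    path: str | Path,
    emit_zeros: bool = True,
) -> None:
    """Write a per-base track as bedGraph, merging runs of equal value.

    Intervals are 0-based half-open. With ``emit_zeros=False``, zero-valued
    runs are omitted from the data section.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise InputError("track contains non-finite values")
    with _open_text(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{ref_id}"\n')
        if arr.size == 0:
            return
        # run-length encode
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [arr.size]))
        for s, e in zip(starts, ends):
            v = arr[s]
            if v == 0 and not emit_zeros:
                continue
            fh.write(f"{ref_id}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str | Path, length: int | None = None) -> tuple[str, np.ndarray]:
    """Read a single-reference bedGraph back into a per-base array."""
    ref_id = None
    intervals: list[tuple[int, int, float]] = []
    with _open_text(path, "r") as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError("expected 4 bedGraph columns", line=i)
            try:
                s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ParseError(str(exc), line=i) from None
            if ref_id is None:
                ref_id = parts[0]
            elif parts[0] != ref_id:
                raise ParseError("multiple references in one bedGraph", line=i)
            intervals.append((s, e, v))
    if ref_id is None:
        raise ParseError("empty bedGraph")
    n = length if length is not None else max(e for _, e, _ in intervals)
    values = np.zeros(n, dtype=float)
    for s, e, v in intervals:
        values[s:e] = v
    return ref_id, values


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a 3–6 column BED file as ``[(ref, start, end, name), ...]``.

    Overlapping intervals are allowed; ``name`` defaults to ``"."``.
    """
    out: list[tuple[str, int, int, str]] = []
    with _open_text(path, "r") as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if not 3 <= len(parts) <= 6:
                raise ParseError("expected 3-6 BED columns", line=i)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(str(exc), line=i) from None
            if start >= end:
                raise ParseError("BED interval start >= end", line=i)
            name = parts[3] if len(parts) > 3 else "."
            out.append((parts[0], start, end, name))
    return out


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

class RunConfig(BaseModel):
    """Effective parameters of one pipeline invocation.

    Unknown keys are rejected; the effective config is echoed into the
    output directory so any run is reproducible from config + seed.
    """

    model_config = ConfigDict(extra="forbid")

    subcommand: str
    seed: int = 0
    version: str = __version__
    parameters: dict = {}

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            with open(path) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"invalid JSON config: {exc}") from None
        try:
            return cls(**data)
        except Exception as exc:  # pydantic ValidationError
            raise ConfigError(str(exc)) from None

    def echo(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "run_config.json"
        path.write_text(
            json.dumps(self.model_dump(), indent=2, sort_keys=True) + "\n"
        )
        return path
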