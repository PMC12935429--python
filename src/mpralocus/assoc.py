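"""Barcode-fragment association and the library coverage baseline.

The association library pairs each fragment barcode with the genomic
fragment it tags: read 1 carries the anchored barcode, read 2 the
fragment's 5' end. Grouping reads by barcode and requiring a concordant
fragment placement yields the barcode -> fragment map; stacking the kept
fragments gives the per-base coverage track that later normalizes the
cDNA signal.

The built-in fragment locator is an exact-seed + Hamming-extension
placement sufficient for desk-scale contigs; externally produced
alignments can be supplied instead of raw reads for real genomes.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .barcodes import reverse_complement
from .errors import InputError, ParseError
from .io import ANCHOR_3, ANCHOR_5, logger


@dataclass(frozen=True)
class Fragment:
    """A genomic interval (0-based, half-open) on a named reference."""

    ref_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise InputError(
                f"invalid fragment interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise InputError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class BarcodeAssociation:
    """The many-to-one barcode -> (fragment, read support) map, with an
    audit trail of dropped barcodes."""

    entries: dict[str, tuple[Fragment, int]] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.entries) & set(self.dropped)
        if overlap:
            raise InputError("entries and dropped must be disjoint")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CoverageTrack:
    """Per-base non-negative coverage over one reference."""

    ref_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InputError("coverage values must be one-dimensional")
        if self.values.size and self.values.min() < 0:
            raise InputError("coverage values must be >= 0")


# ---------------------------------------------------------------------------
# Barcode extraction
# ---------------------------------------------------------------------------

def extract_barcode(
    read: str,
    anchors: tuple[str, str] = (ANCHOR_5, ANCHOR_3),
    barcode_length: int = 24,
) -> str | None:
    """Pull the barcode out of an anchored read.

    Returns the ``barcode_length``-mer between the first exact occurrence
    of the 5' anchor and the immediately following 3' anchor, or ``None``
    when the anchors are absent or mis-spaced.
    """
    a5, a3 = anchors
    if not a5 or not a3:
        raise InputError("anchors must be non-empty")
    i = read.find(a5)
    if i < 0:
        return None
    start = i + len(a5)
    end = start + barcode_length
    if not read.startswith(a3, end):
        return None
    return read[start:end]


# ---------------------------------------------------------------------------
# Fragment location
# ---------------------------------------------------------------------------

class ReferenceIndex:
    """Exact-seed (default 20-mer) index over one reference for
    Hamming-extension read placement."""

    def __init__(self, reference: str, ref_id: str = "ref", seed_len: int = 20):
        if seed_len < 1:
            raise InputError("seed length must be >= 1")
        self.reference = reference
        self.ref_id = ref_id
        self.seed_len = seed_len
        self._index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(reference) - seed_len + 1):
            self._index[reference[i : i + seed_len]].append(i)

    def _candidates(self, read: str) -> list[tuple[int, int, str]]:
        """(mismatches, start, strand) for every seeded placement."""
        out: list[tuple[int, int, str]] = []
        ref = self.reference
        for strand, seq in (("+", read), ("-", reverse_complement(read))):
            seed = seq[: self.seed_len]
            for pos in self._index.get(seed, ()):
                if pos + len(seq) > len(ref):
                    continue
                window = ref[pos : pos + len(seq)]
                mm = sum(a != b for a, b in zip(seq, window))
                out.append((mm, pos, strand))
        return out

    def locate(
        self, read: str, max_mismatch_frac: float = 0.1
    ) -> Fragment | None:
        """Place a read; ``None`` when unmapped or ambiguous.

        A unique best placement (strictly fewer mismatches than any
        other) with mismatch fraction <= ``max_mismatch_frac`` is
        required.
        """
        if len(read) < self.seed_len:
            raise InputError(
                f"read shorter than seed length {self.seed_len}"
            )
        candidates = self._candidates(read)
        if not candidates:
            return None
        candidates.sort()
        best_mm, pos, strand = candidates[0]
        if best_mm > max_mismatch_frac * len(read):
            return None
        if len(candidates) > 1 and candidates[1][0] == best_mm:
            return None  # ambiguous: multiple equally good placements
        return Fragment(self.ref_id, pos, pos + len(read), strand)


def locate_fragment(
    read: str,
    reference: str,
    max_mismatch_frac: float = 0.1,
    seed_len: int = 20,
    ref_id: str = "ref",
) -> Fragment | None:
    """One-shot form of :meth:`ReferenceIndex.locate`."""
    return ReferenceIndex(reference, ref_id, seed_len).locate(
        read, max_mismatch_frac
    )


# ---------------------------------------------------------------------------
# Association building
# ---------------------------------------------------------------------------

@dataclass
class AssocParams:
    """Thresholds for barcode -> fragment consensus.

    ``fragment_end`` controls how the 3' end of the interval is set:
    ``"read_span"`` uses the mapped read span (appropriate for merged or
    full-length fragment reads); an integer uses a fixed expected
    fragment length from the library's size selection.
    """

    min_support: int = 1
    concordance_frac: float = 0.9
    slop: int = 5
    barcode_length: int = 24
    anchors: tuple[str, str] = (ANCHOR_5, ANCHOR_3)
    max_mismatch_frac: float = 0.1
    seed_len: int = 20
    fragment_end: str | int = "read_span"

    def __post_init__(self) -> None:
        if not 0 < self.concordance_frac <= 1:
            raise InputError("concordance_frac must lie in (0, 1]")
        if self.min_support < 1:
            raise InputError("min_support must be >= 1")


def build_association(
    read_pairs: Iterable[tuple[str, str]],
    reference: str,
    params: AssocParams | None = None,
    ref_id: str = "ref",
) -> BarcodeAssociation:
    """Group association reads by barcode and call a consensus fragment.

    A barcode is kept when it has >= ``min_support`` mapped reads and
    >= ``concordance_frac`` of them support one fragment interval
    (intervals equal within +/- ``slop`` bp); the consensus is the
    support-weighted modal interval. Everything else lands in
    ``dropped`` with a reason (``unmapped`` / ``low-support`` /
    ``ambiguous``).
    """
    params = params or AssocParams()
    index = ReferenceIndex(reference, ref_id, params.seed_len)

    groups: dict[str, list[Fragment | None]] = defaultdict(list)
    n_pairs = 0
    n_no_barcode = 0
    for r1, r2 in read_pairs:
        n_pairs += 1
        barcode = extract_barcode(r1, params.anchors, params.barcode_length)
        if barcode is None:
            n_no_barcode += 1
            continue
        placement = index.locate(r2, params.max_mismatch_frac)
        if placement is not None and params.fragment_end != "read_span":
            end = min(placement.start + int(params.fragment_end), len(reference))
            placement = Fragment(ref_id, placement.start, end, placement.strand)
        groups[barcode].append(placement)

    if n_pairs == 0:
        logger.warning("build_association: empty input")
        return BarcodeAssociation()

    entries: dict[str, tuple[Fragment, int]] = {}
    dropped: dict[str, str] = {}
    for barcode, placements in groups.items():
        mapped = [p for p in placements if p is not None]
        if not mapped:
            dropped[barcode] = "unmapped"
            continue
        if len(mapped) < params.min_support:
            dropped[barcode] = "low-support"
            continue
        consensus, support = _consensus_interval(mapped, params.slop)
        if support / len(mapped) < params.concordance_frac:
            dropped[barcode] = "ambiguous"
            continue
        if support < params.min_support:
            dropped[barcode] = "low-support"
            continue
        entries[barcode] = (consensus, support)

    logger.info(
        "build_association: %d pairs in, %d without barcode, "
        "%d barcodes kept, %d dropped",
        n_pairs, n_no_barcode, len(entries), len(dropped),
    )
    return BarcodeAssociation(entries=entries, dropped=dropped)


def _consensus_interval(
    placements: list[Fragment], slop: int
) -> tuple[Fragment, int]:
    """Support-weighted modal interval among placements, clustering
    intervals whose endpoints agree within +/- slop bp."""
    exact = Counter((p.start, p.end, p.strand) for p in placements)
    # cluster exact intervals around the most-supported representatives
    clusters: list[tuple[tuple[int, int, str], int]] = []
    for key, count in exact.most_common():
        for i, (rep, total) in enumerate(clusters):
            if abs(key[0] - rep[0]) <= slop and abs(key[1] - rep[1]) <= slop:
                clusters[i] = (rep, total + count)
                break
        else:
            clusters.append((key, count))
    (start, end, strand), support = max(clusters, key=lambda c: c[1])
    ref_id = placements[0].ref_id
    return Fragment(ref_id, start, end, strand), support


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def coverage_from_intervals(
    intervals: Iterable[tuple[int, int]],
    length: int,
    weights: Iterable[float] | None = None,
) -> np.ndarray:
    """Sum interval weights into a per-base array (difference-array
    accumulation, O(n + length))."""
    diff = np.zeros(length + 1, dtype=float)
    intervals = list(intervals)
    if weights is None:
        weights = [1.0] * len(intervals)
    for (start, end), w in zip(intervals, weights):
        if start < 0 or end > length:
            raise InputError("interval outside the reference")
        diff[start] += w
        diff[end] -= w
    return np.cumsum(diff[:-1])


def coverage_track(
    assoc: BarcodeAssociation,
    reference_length: int,
    weight: str = "barcode",
    ref_id: str = "ref",
) -> CoverageTrack:
    """Association-library coverage: each kept barcode adds its weight
    (1 per barcode, or its read support) to every base of its fragment."""
    if weight not in ("barcode", "read"):
        raise InputError('weight must be "barcode" or "read"')
    intervals = [frag.interval for frag, _ in assoc.entries.values()]
    weights = [
        1.0 if weight == "barcode" else float(support)
        for _, support in assoc.entries.values()
    ]
    values = coverage_from_intervals(intervals, reference_length, weights)
    return CoverageTrack(ref_id, values)


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

_TSV_HEADER = "barcode\tref\tstart\tend\tstrand\tsupport\tstatus"


def write_association(assoc: BarcodeAssociation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for barcode, (frag, support) in sorted(assoc.entries.items()):
            fh.write(
                f"{barcode}\t{frag.ref_id}\t{frag.start}\t{frag.end}\t"
                f"{frag.strand}\t{support}\tkept\n"
            )
        for barcode, reason in sorted(assoc.dropped.items()):
            fh.write(f"{barcode}\t.\t-1\t-1\t.\t0\t{reason}\n")


def read_association(path: str | Path) -> BarcodeAssociation:
    entries: dict[str, tuple[Fragment, int]] = {}
    dropped: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise ParseError("unexpected association table header", line=1)
        for i, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ParseError("expected 7 columns", line=i)
            barcode, ref, start, end, strand, support, status = parts
            if status == "kept":
                entries[barcode] = (
                    Fragment(ref, int(start), int(end), strand),
                    int(support),
                )
            else:
                dropped[barcode] = status
    return BarcodeAssociation(entries=entries, dropped=dropped)
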