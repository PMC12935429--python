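"""LS-MPRA quantification: cDNA barcode counting, per-base enrichment
tracks, interval AUC scores, replicate merging and QC flags.

The readout is E(x) = log2((C(x)+p) / (A(x)+p)) where C is the cDNA
barcode signal stacked over fragment intervals, A the association-library
coverage baseline, both scaled to counts-per-million of their library
totals, and p a pseudocount. Active regions appear as positive peaks;
regions depleted from the association library (e.g. around the
restriction site used in library construction) can create false peaks,
hence the restriction-site QC flag.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .assoc import BarcodeAssociation, coverage_from_intervals, extract_barcode
from .barcodes import Whitelist, reverse_complement
from .errors import InputError
from .io import ANCHOR_3, ANCHOR_5, logger

#: AscI recognition sequence (palindromic 8-cutter used in library assembly).
ASCI_MOTIF = "GGCGCGCC"


@dataclass
class EnrichmentTrack:
    """Per-base log2(cDNA / association) signal over one reference."""

    ref_id: str
    values: np.ndarray
    pseudocount: float = 1.0
    scale_factors: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise InputError("enrichment track must be finite everywhere")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class IntervalScore:
    """Trapezoidal AUC of a track over one interval, with replicates."""

    interval: tuple[int, int]
    auc: float
    replicate_values: list[float] = field(default_factory=list)
    mean: float = float("nan")
    sem: float = 0.0


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_cdna_barcodes(
    reads: Iterable[str],
    wl: Whitelist,
    anchors: tuple[str, str] = (ANCHOR_5, ANCHOR_3),
) -> tuple[dict[str, int], int]:
    """Extract, error-correct and count barcodes from cDNA reads.

    Returns (canonical barcode -> count, number of unmatched reads);
    unmatched covers missing anchors, off-whitelist and ambiguous
    barcodes.
    """
    counts: Counter[str] = Counter()
    unmatched = 0
    n = 0
    for read in reads:
        n += 1
        observed = extract_barcode(read, anchors, wl.length)
        canonical = wl.match(observed) if observed is not None else None
        if canonical is None:
            unmatched += 1
        else:
            counts[canonical] += 1
    logger.info(
        "count_cdna_barcodes: %d reads, %d counted, %d unmatched",
        n, n - unmatched, unmatched,
    )
    return dict(counts), unmatched


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def log2_ratio_track(
    numer_counts: dict[str, float],
    denom_counts: dict[str, float],
    assoc: BarcodeAssociation,
    reference_length: int,
    pseudocount: float = 1.0,
    depth_norm: str = "cpm",
    ref_id: str = "ref",
) -> EnrichmentTrack:
    """log2 ratio of two barcode-count layers stacked over fragments.

    Each layer's per-base signal is the sum of its barcode counts over
    the barcodes whose associated fragment covers the base; with
    ``depth_norm="cpm"`` each layer is scaled to counts-per-million of
    its own total before the ratio.
    """
    if pseudocount <= 0:
        raise InputError("pseudocount must be > 0")
    if depth_norm not in ("cpm", "none"):
        raise InputError('depth_norm must be "cpm" or "none"')
    if not assoc.entries:
        raise InputError("association is empty")

    def layer(counts: dict[str, float]) -> tuple[np.ndarray, float]:
        intervals, weights = [], []
        for barcode, value in counts.items():
            hit = assoc.entries.get(barcode)
            if hit is None:
                continue
            intervals.append(hit[0].interval)
            weights.append(float(value))
        total = float(sum(counts.values()))
        signal = coverage_from_intervals(intervals, reference_length, weights)
        return signal, total

    numer, numer_total = layer(numer_counts)
    denom, denom_total = layer(denom_counts)
    s_n = s_d = 1.0
    if depth_norm == "cpm":
        if numer_total <= 0 or denom_total <= 0:
            raise InputError("cannot CPM-scale an empty library")
        s_n = 1e6 / numer_total
        s_d = 1e6 / denom_total
    values = np.log2((numer * s_n + pseudocount) / (denom * s_d + pseudocount))
    return EnrichmentTrack(ref_id, values, pseudocount, (s_n, s_d))


def enrichment_track(
    cdna_counts: dict[str, int],
    assoc: BarcodeAssociation,
    reference_length: int,
    pseudocount: float = 1.0,
    depth_norm: str = "cpm",
    unique_barcodes: bool = False,
    ref_id: str = "ref",
) -> EnrichmentTrack:
    """The LS-MPRA enrichment readout.

    cDNA counts are normalized to library input: the association
    coverage (one unit per kept barcode) is the denominator. With
    ``unique_barcodes`` each detected barcode contributes once instead
    of its count (collision robustness check).
    """
    numer = {
        b: 1.0 if unique_barcodes else float(c)
        for b, c in cdna_counts.items()
        if c > 0
    }
    denom = {b: 1.0 for b in assoc.entries}
    return log2_ratio_track(
        numer, denom, assoc, reference_length, pseudocount, depth_norm, ref_id
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def auc_score(
    track: EnrichmentTrack,
    interval: tuple[int, int],
    replicates: Sequence[EnrichmentTrack] | None = None,
    normalize_to: float | None = None,
) -> IntervalScore:
    """Trapezoidal-rule AUC of the track over ``interval`` (unit base
    spacing). Per-replicate AUCs, their mean and SEM are reported when
    replicate tracks are given; ``normalize_to`` divides all values by a
    reference-condition AUC."""
    start, end = interval
    if not 0 <= start < end <= len(track):
        raise InputError(f"invalid interval [{start}, {end})")
    if end - start < 2:
        raise InputError("interval must span at least 2 bases")

    def one(t: EnrichmentTrack) -> float:
        value = float(np.trapezoid(t.values[start:end]))
        if normalize_to is not None:
            if normalize_to == 0:
                raise InputError("cannot normalize to a zero reference AUC")
            value /= normalize_to
        return value

    auc = one(track)
    rep_values = [one(t) for t in replicates] if replicates else []
    if rep_values:
        mean = float(np.mean(rep_values))
        sem = (
            float(np.std(rep_values, ddof=1) / np.sqrt(len(rep_values)))
            if len(rep_values) > 1
            else 0.0
        )
    else:
        mean, sem = auc, 0.0
    return IntervalScore((start, end), auc, rep_values, mean, sem)


def flag_restriction_sites(
    reference: str, motif: str = ASCI_MOTIF
) -> list[tuple[int, int]]:
    """Exact occurrences of a restriction motif on either strand.

    Sites where the association library is cut are depleted from the
    baseline and can masquerade as enrichment peaks; flag them for QC.
    Palindromic motifs are reported once per genomic interval.
    """
    if len(motif) < 4:
        raise InputError("motif length must be >= 4")
    found: set[tuple[int, int]] = set()
    for m in (motif, reverse_complement(motif)):
        i = reference.find(m)
        while i >= 0:
            found.add((i, i + len(m)))
            i = reference.find(m, i + 1)
    return sorted(found)


def merge_replicates(
    tracks: Sequence[EnrichmentTrack],
) -> tuple[EnrichmentTrack, np.ndarray]:
    """Position-wise mean track and SEM across experimental replicates."""
    if not tracks:
        raise InputError("no tracks to merge")
    ref_ids = {t.ref_id for t in tracks}
    lengths = {len(t) for t in tracks}
    if len(ref_ids) != 1 or len(lengths) != 1:
        raise InputError("replicate tracks must share reference and length")
    stack = np.stack([t.values for t in tracks])
    mean = stack.mean(axis=0)
    if len(tracks) > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(tracks))
    else:
        sem = np.zeros(stack.shape[1])
    merged = EnrichmentTrack(tracks[0].ref_id, mean, tracks[0].pseudocount)
    return merged, sem


def extract_intervals(
    track: EnrichmentTrack, threshold: float, min_width: int = 1
) -> list[tuple[int, int]]:
    """Contiguous runs of track values >= threshold, at least
    ``min_width`` bases wide. Convenience plumbing only — peaks in this
    assay are usually judged by inspection of the track."""
    above = track.values >= threshold
    out: list[tuple[int, int]] = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_width:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out
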