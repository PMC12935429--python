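"""Multiplexing-tag design, degenerate fragment barcodes and
error-correcting whitelists.

Library tags are short fixed sequences used to demultiplex pooled MPRA
libraries; they are designed so that every pair differs at a minimum
Hamming distance and each tag passes composition filters (no homopolymer
run of 3+, balanced GC, not self-reverse-complementary). Fragment
barcodes are longer degenerate oligos (default 24 nt of repeated ``SW``,
i.e. [GC][AT]) whose pattern keeps GC content moderate and forbids
homopolymers by construction.

Observed barcodes are decoded against a whitelist: the set of true
(canonical) barcodes plus every sequence within a Hamming radius that is
close to exactly one canonical. Sequences close to two or more canonicals
are ambiguous and never counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, prod

import numpy as np

from .errors import CapacityError, InputError

BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: IUPAC degenerate nucleotide classes.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length sequences."""
    if len(a) != len(b):
        raise InputError(
            f"hamming distance requires equal lengths ({len(a)} vs {len(b)})"
        )
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Tag design
# ---------------------------------------------------------------------------

def max_homopolymer_run(seq: str) -> int:
    run = best = 1 if seq else 0
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class TagFilters:
    """Composition filters applied to candidate library tags."""

    max_homopolymer: int = 2          # forbid runs of 3+
    gc_band: tuple[float, float] = (0.375, 0.625)
    forbid_self_revcomp: bool = True

    def passes(self, tag: str) -> bool:
        if max_homopolymer_run(tag) > self.max_homopolymer:
            return False
        lo, hi = self.gc_band
        if not lo <= gc_fraction(tag) <= hi:
            return False
        if self.forbid_self_revcomp and tag == reverse_complement(tag):
            return False
        return True


@dataclass(frozen=True)
class TagSet:
    """A set of same-length multiplexing tags with a guaranteed minimum
    pairwise Hamming distance."""

    tags: tuple[str, ...]
    length: int
    min_distance: int

    def __post_init__(self) -> None:
        if any(len(t) != self.length for t in self.tags):
            raise InputError("all tags must share the configured length")
        if len(self.tags) > 1:
            dmin = min(hamming(a, b) for a, b in combinations(self.tags, 2))
            if dmin < self.min_distance:
                raise InputError(
                    f"tag set violates min pairwise distance "
                    f"({dmin} < {self.min_distance})"
                )

    def min_pairwise_distance(self) -> int:
        if len(self.tags) < 2:
            return self.length
        return min(hamming(a, b) for a, b in combinations(self.tags, 2))


def design_tags(
    n: int,
    length: int = 8,
    min_distance: int = 5,
    filters: TagFilters | None = None,
    seed: int = 0,
    max_tries: int = 200_000,
) -> TagSet:
    """Randomized-greedy design of ``n`` library tags.

    Candidate tags are sampled uniformly, kept when they pass the
    composition filters and sit at Hamming distance >= ``min_distance``
    from every accepted tag. Reproducible under ``seed``.

    Raises :class:`CapacityError` when the request provably exceeds the
    code space (Singleton bound) or the search budget is exhausted.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if min_distance > length:
        raise CapacityError(
            f"min_distance {min_distance} exceeds tag length {length}"
        )
    if n > 4 ** (length - min_distance + 1):  # Singleton bound
        raise CapacityError(
            f"{n} tags of length {length} at distance {min_distance} "
            f"exceed the Singleton bound"
        )
    filters = filters or TagFilters()
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    for _ in range(max_tries):
        tag = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
        if not filters.passes(tag):
            continue
        if all(hamming(tag, t) >= min_distance for t in accepted):
            accepted.append(tag)
            if len(accepted) == n:
                return TagSet(tuple(accepted), length, min_distance)
    raise CapacityError(
        f"could not place {n} tags (length {length}, distance "
        f"{min_distance}) within the search budget; found {len(accepted)}"
    )


# ---------------------------------------------------------------------------
# Degenerate fragment barcodes
# ---------------------------------------------------------------------------

def pattern_space(pattern: str, length: int) -> int:
    """Number of distinct barcodes of ``length`` nt under a repeated
    degenerate ``pattern``."""
    classes = _expand_pattern(pattern, length)
    return prod(len(c) for c in classes)


def _expand_pattern(pattern: str, length: int) -> list[str]:
    if not pattern:
        raise InputError("empty degenerate pattern")
    for sym in pattern:
        if sym.upper() not in IUPAC:
            raise InputError(f"invalid IUPAC symbol {sym!r} in pattern")
    if length % len(pattern) != 0:
        raise InputError(
            f"length {length} not divisible by pattern period {len(pattern)}"
        )
    reps = length // len(pattern)
    return [IUPAC[sym.upper()] for sym in pattern] * reps


def generate_fragment_barcode(
    pattern: str = "SW",
    length: int = 24,
    rng: np.random.Generator | int | None = None,
) -> str:
    """Draw one barcode: each position uniform over its degenerate class.

    The default is twelve ``SW`` repeats, a 24-mer matching
    ``([GC][AT]){12}``.
    """
    classes = _expand_pattern(pattern, length)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sizes = np.array([len(c) for c in classes])
    picks = rng.integers(0, sizes)
    return "".join(c[i] for c, i in zip(classes, picks))


# ---------------------------------------------------------------------------
# Whitelists
# ---------------------------------------------------------------------------

def hamming_ball_size(length: int, max_dist: int) -> int:
    """|{sequences within Hamming distance d of one sequence}|."""
    return sum(comb(length, k) * 3 ** k for k in range(max_dist + 1))


def _ball(seq: str, max_dist: int):
    """Yield every sequence within ``max_dist`` substitutions of ``seq``."""
    L = len(seq)
    for k in range(max_dist + 1):
        for positions in combinations(range(L), k):
            yield from _mutate_at(seq, positions)


def _mutate_at(seq: str, positions: tuple[int, ...]):
    if not positions:
        yield seq
        return
    p, rest = positions[0], positions[1:]
    for alt in BASES:
        if alt == seq[p]:
            continue
        for tail in _mutate_at(seq, rest):
            yield tail[:p] + alt + tail[p + 1:]


_ENC = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i


def _encode(seqs: list[str]) -> np.ndarray:
    flat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return _ENC[flat].reshape(len(seqs), -1)


@dataclass
class Whitelist:
    """Canonical barcodes plus a Hamming-ball decoder.

    ``variant_map`` maps every unambiguous observed sequence within
    ``max_dist`` of a canonical to that canonical; it is enumerated
    eagerly when the ball volume is small and replaced by a neighbor
    search at match time otherwise (identical contract, bounded memory).
    """

    canonical: frozenset[str]
    max_dist: int
    variant_map: dict[str, str] | None = None
    _exact: dict[str, str] = field(default_factory=dict, repr=False)
    _matrix: np.ndarray | None = field(default=None, repr=False)
    _order: list[str] = field(default_factory=list, repr=False)

    @property
    def length(self) -> int:
        return len(next(iter(self.canonical)))

    def match(self, observed: str) -> str | None:
        """Decode one observed barcode; ``None`` when absent or ambiguous."""
        if len(observed) != self.length:
            return None
        if self.variant_map is not None:
            return self.variant_map.get(observed)
        hit = self._exact.get(observed)
        if hit is not None and self.max_dist == 0:
            return hit
        try:
            obs = _encode([observed])[0]
        except Exception:
            return None
        dists = (self._matrix != obs).sum(axis=1)
        close = np.flatnonzero(dists <= self.max_dist)
        if close.size != 1:
            return None
        return self._order[int(close[0])]


def build_whitelist(
    canonical: set[str] | list[str],
    max_dist: int | str = "auto",
    enumerate_limit: int = 2_000_000,
) -> Whitelist:
    """Build a Hamming-ball whitelist around a canonical barcode set.

    ``max_dist="auto"`` chooses ``floor((d_min - 1) / 2)`` where ``d_min``
    is the minimum pairwise Hamming distance of the canonical set — the
    largest radius at which balls cannot collide. Sequences within
    ``max_dist`` of two or more canonicals are excluded (ambiguous).
    """
    seqs = list(canonical)
    if not seqs:
        raise InputError("canonical set is empty")
    canon = list(dict.fromkeys(seqs))
    if len(canon) < len(seqs):
        raise InputError("duplicate canonical barcodes (d_min = 0)")
    L = len(canon[0])
    if any(len(c) != L for c in canon):
        raise InputError("canonical barcodes must share one length")

    if max_dist == "auto":
        if len(canon) == 1:
            d = 1
        else:
            d_min = min(hamming(a, b) for a, b in combinations(canon, 2))
            if d_min == 0:
                raise InputError("duplicate canonical barcodes (d_min = 0)")
            d = (d_min - 1) // 2
    else:
        d = int(max_dist)
        if d < 0:
            raise InputError("max_dist must be >= 0")

    wl = Whitelist(canonical=frozenset(canon), max_dist=d)
    wl._exact = {c: c for c in canon}
    wl._order = canon
    wl._matrix = _encode(canon)

    if hamming_ball_size(L, d) * len(canon) <= enumerate_limit:
        vmap: dict[str, str] = {}
        ambiguous: set[str] = set()
        for c in canon:
            for v in _ball(c, d):
                if v in ambiguous:
                    continue
                prev = vmap.get(v)
                if prev is None:
                    vmap[v] = c
                elif prev != c:
                    del vmap[v]
                    ambiguous.add(v)
        wl.variant_map = vmap
    return wl


def match_barcode(observed: str, wl: Whitelist) -> str | None:
    """Functional form of :meth:`Whitelist.match`."""
    return wl.match(observed)
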