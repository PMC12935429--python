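"""Synthetic MPRA data generation.

Emulates the generative process of a locus-specific MPRA (LS-MPRA) and a
degenerate MPRA (d-MPRA) so every downstream module can be exercised and
benchmarked without external sequencing data:

* random enzymatic fragmentation of a reference contig with uniform
  placement (digestion) and a uniform size range (gel size selection);
* unique degenerate barcoding of each fragment instance;
* a planted activity model — fragments overlapping an active region
  yield multinomially more transcripts than baseline fragments;
* read emission for the association and cDNA libraries with fixed
  20-nt vector anchor arms flanking the barcode and an optional
  independent per-base substitution sequencing-error model;
* error-prone-PCR point mutagenesis of a CRM (per-nucleotide rate in
  the assay's working range of ~0.02-0.2%) and per-site activator /
  repressor effect multipliers driving plasmid and cDNA clone counts.

All operations are reproducible under a seed; identical spec + seed
gives byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assoc import Fragment
from .barcodes import BASES, generate_fragment_barcode, pattern_space, reverse_complement
from .dmpra import MutationCall
from .errors import CapacityError, InputError
from .io import ANCHOR_3, ANCHOR_5, FastqRecord

#: Constant Phred+33 quality character for emitted reads.
QUALITY_CHAR = "I"


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def random_reference(length: int, rng: np.random.Generator | int | None = None) -> str:
    """A uniform-random nucleotide sequence, for desk-scale contigs."""
    rng = _as_rng(rng)
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


# ---------------------------------------------------------------------------
# Specifications and models
# ---------------------------------------------------------------------------

@dataclass
class SimSpec:
    """Parameters of one synthetic experiment.

    ``mutation_rate`` defaults to 0.001 per nucleotide, the midpoint of
    the error-prone-PCR working range (~0.02-0.2%). ``mutation_spectrum``
    is (substitution, deletion, insertion) proportions; the kit's true
    spectrum is unpublished, so the default (0.90, 0.08, 0.02) is a
    documented, configurable choice.
    """

    seed: int = 0
    n_fragments: int = 1000
    fragment_size_range: tuple[int, int] = (200, 500)
    barcode_length: int = 24
    barcode_pattern: str = "SW"
    read_length: int = 150
    association_reads_per_barcode: int = 5
    cdna_depth: int = 100_000
    plasmid_depth: int = 100_000
    sequencing_error_rate: float = 0.0
    mutation_rate: float = 0.001
    mutation_spectrum: tuple[float, float, float] = (0.90, 0.08, 0.02)

    def __post_init__(self) -> None:
        lo, hi = self.fragment_size_range
        if lo > hi or lo < 1:
            raise InputError("fragment_size_range must satisfy 1 <= min <= max")
        if self.n_fragments < 1:
            raise InputError("n_fragments must be >= 1")
        if self.barcode_length < 8:
            raise InputError("barcode_length must be >= 8")
        for name in ("sequencing_error_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must lie in [0, 1]")
        if any(p < 0 for p in self.mutation_spectrum) or not np.isclose(
            sum(self.mutation_spectrum), 1.0
        ):
            raise InputError("mutation_spectrum must be non-negative and sum to 1")


@dataclass
class ActivityModel:
    """Planted regulatory activity over a reference.

    Fragments are weighted by the strength of the active region covering
    the largest share of their span (ties to the leftmost region) or by
    ``baseline`` when they overlap no region. Active genomic regions then
    appear as peaks where the signals of overlapping fragments accumulate.
    """

    regions: list[tuple[int, int, float]] = field(default_factory=list)
    baseline: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise InputError("baseline multiplier must be > 0")
        for start, end, strength in self.regions:
            if start >= end:
                raise InputError("region interval start must be < end")
            if strength <= 0:
                raise InputError("region strengths must be > 0")
        ordered = sorted(self.regions)
        for (s1, e1, _), (s2, _, _) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise InputError("activity regions may not overlap")

    def validate_against(self, reference_length: int) -> None:
        for start, end, _ in self.regions:
            if start < 0 or end > reference_length:
                raise InputError("activity region outside the reference")

    def fragment_weight(self, fragment: Fragment) -> float:
        best_overlap = 0
        best: float = self.baseline
        for start, end, strength in sorted(self.regions):
            overlap = min(fragment.end, end) - max(fragment.start, start)
            if overlap > best_overlap:
                best_overlap = overlap
                best = strength
        return best


@dataclass
class MutantClone:
    """One error-prone-PCR clone of a CRM."""

    clone_id: str
    mutations: list[MutationCall]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise InputError("clone weight must be > 0")
        positions = [m.position for m in self.mutations]
        if len(positions) != len(set(positions)):
            raise InputError("mutation positions must be unique per clone")


# ---------------------------------------------------------------------------
# LS-MPRA generation
# ---------------------------------------------------------------------------

def fragment_reference(
    reference: str,
    spec: SimSpec,
    rng: np.random.Generator | int | None = None,
    ref_id: str = "ref",
) -> list[Fragment]:
    """Random fragmentation: uniform start positions, uniform lengths in
    the configured size range, uniform strands."""
    rng = _as_rng(spec.seed if rng is None else rng)
    L = len(reference)
    lo, hi = spec.fragment_size_range
    if L <= hi:
        raise InputError(
            f"reference length {L} must exceed max fragment size {hi}"
        )
    lengths = rng.integers(lo, hi + 1, size=spec.n_fragments)
    starts = rng.integers(0, L - lengths + 1)
    strands = rng.integers(0, 2, size=spec.n_fragments)
    return [
        Fragment(ref_id, int(s), int(s + ln), "+" if st == 0 else "-")
        for s, ln, st in zip(starts, lengths, strands)
    ]


def fragment_sequence(fragment: Fragment, reference: str) -> str:
    """The fragment's sequence in its own 5'->3' orientation."""
    seq = reference[fragment.start:fragment.end]
    return seq if fragment.strand == "+" else reverse_complement(seq)


def assign_barcodes(
    fragments: list[Fragment],
    spec: SimSpec,
    rng: np.random.Generator | int | None = None,
) -> dict[str, Fragment]:
    """Tag every fragment instance with a unique degenerate barcode.

    Fragments are instances: two fragments with the same interval still
    receive distinct barcodes.
    """
    rng = _as_rng(spec.seed if rng is None else rng)
    space = pattern_space(spec.barcode_pattern, spec.barcode_length)
    if len(fragments) > space:
        raise CapacityError(
            f"{len(fragments)} barcodes requested but the pattern space "
            f"holds only {space}"
        )
    assoc: dict[str, Fragment] = {}
    while len(assoc) < len(fragments):
        bc = generate_fragment_barcode(spec.barcode_pattern, spec.barcode_length, rng)
        if bc not in assoc:
            assoc[bc] = fragments[len(assoc)]
    return assoc


def simulate_expression(
    assoc: dict[str, Fragment],
    model: ActivityModel,
    depth: int,
    seed: np.random.Generator | int | None = None,
) -> dict[str, int]:
    """Multinomial transcript counts per barcode.

    Each barcode's probability is proportional to its fragment's activity
    weight; counts sum exactly to ``depth``.
    """
    if depth < 1:
        raise InputError("depth must be >= 1")
    rng = _as_rng(seed)
    barcodes = list(assoc)
    weights = np.array([model.fragment_weight(assoc[b]) for b in barcodes])
    counts = rng.multinomial(depth, weights / weights.sum())
    return {b: int(c) for b, c in zip(barcodes, counts)}


def _apply_sequencing_errors(
    seq: str, rate: float, rng: np.random.Generator
) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for p in positions:
        alts = [b for b in BASES if b != out[p]]
        out[p] = alts[rng.integers(0, 3)]
    return "".join(out)


def emit_reads(
    assoc: dict[str, Fragment],
    counts: dict[str, int],
    reference: str,
    spec: SimSpec,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[tuple[FastqRecord, FastqRecord]], list[FastqRecord]]:
    """Emit association read pairs and cDNA reads.

    Association mate 1 carries ``ANCHOR_5 + barcode + ANCHOR_3`` (padded
    with vector filler to the read length); mate 2 carries the fragment's
    5' end. cDNA reads carry the same anchored barcode layout, one read
    per transcript count. Deterministic under the seed.
    """
    rng = _as_rng(spec.seed if rng is None else rng)
    layout = len(ANCHOR_5) + spec.barcode_length + len(ANCHOR_3)
    if spec.read_length < layout:
        raise InputError(
            f"read_length {spec.read_length} shorter than anchor+barcode "
            f"layout ({layout})"
        )
    err = spec.sequencing_error_rate

    def read1_seq(barcode: str) -> str:
        core = ANCHOR_5 + barcode + ANCHOR_3
        pad = "A" * (spec.read_length - len(core))
        return core + pad

    assoc_pairs: list[tuple[FastqRecord, FastqRecord]] = []
    for i, (barcode, fragment) in enumerate(assoc.items()):
        frag_seq = fragment_sequence(fragment, reference)
        for j in range(spec.association_reads_per_barcode):
            rid = f"assoc:{i}:{j}"
            r1 = _apply_sequencing_errors(read1_seq(barcode), err, rng)
            r2 = _apply_sequencing_errors(frag_seq[: spec.read_length], err, rng)
            assoc_pairs.append(
                (
                    FastqRecord(rid + "/1", r1, QUALITY_CHAR * len(r1)),
                    FastqRecord(rid + "/2", r2, QUALITY_CHAR * len(r2)),
                )
            )

    cdna_reads: list[FastqRecord] = []
    for i, (barcode, n) in enumerate(counts.items()):
        for j in range(n):
            seq = _apply_sequencing_errors(read1_seq(barcode), err, rng)
            cdna_reads.append(
                FastqRecord(f"cdna:{i}:{j}", seq, QUALITY_CHAR * len(seq))
            )
    return assoc_pairs, cdna_reads


# ---------------------------------------------------------------------------
# d-MPRA generation
# ---------------------------------------------------------------------------

def mutagenize_crm(
    crm: str,
    n_clones: int,
    spec: SimSpec,
    rng: np.random.Generator | int | None = None,
) -> list[MutantClone]:
    """Error-prone-PCR clone library: every position of every clone
    mutates independently at ``spec.mutation_rate``; the mutation type is
    drawn from ``spec.mutation_spectrum``."""
    if not 0.0 <= spec.mutation_rate < 1.0:
        raise InputError("mutation_rate must lie in [0, 1)")
    rng = _as_rng(spec.seed if rng is None else rng)
    L = len(crm)
    n_mut = rng.binomial(L, spec.mutation_rate, size=n_clones)
    clones: list[MutantClone] = []
    p_sub, p_del, p_ins = spec.mutation_spectrum
    for i in range(n_clones):
        k = int(n_mut[i])
        mutations: list[MutationCall] = []
        if k:
            positions = np.sort(rng.choice(L, size=k, replace=False))
            kinds = rng.choice(3, size=k, p=[p_sub, p_del, p_ins])
            for p, kind in zip(positions, kinds):
                ref_base = crm[p]
                if kind == 0:
                    alts = [b for b in BASES if b != ref_base]
                    alt = alts[rng.integers(0, 3)]
                    mutations.append(MutationCall(int(p), "substitution", ref_base, alt))
                elif kind == 1:
                    mutations.append(MutationCall(int(p), "deletion", ref_base, None))
                else:
                    alt = BASES[rng.integers(0, 4)]
                    mutations.append(MutationCall(int(p), "insertion", ref_base, alt))
        clones.append(MutantClone(f"clone{i}", mutations))
    return clones


def mutant_sequence(crm: str, clone: MutantClone) -> str:
    """Apply a clone's mutations to the CRM reference.

    Insertions place the new base immediately before the recorded
    position; multi-event clones apply right-to-left so positions stay
    reference-anchored.
    """
    seq = list(crm)
    for m in sorted(clone.mutations, key=lambda m: m.position, reverse=True):
        if m.kind == "substitution":
            seq[m.position] = m.alt_base
        elif m.kind == "deletion":
            del seq[m.position]
        else:
            seq.insert(m.position, m.alt_base)
    return "".join(seq)


def clone_effect_weights(
    clones: list[MutantClone], site_effects: dict[int, float]
) -> np.ndarray:
    """Expected-expression multiplier per clone: the product of the
    per-site effect multipliers over its mutated positions (1 when a
    position carries no planted effect)."""
    if any(v <= 0 for v in site_effects.values()):
        raise InputError("site effect multipliers must be > 0")
    weights = np.empty(len(clones))
    for i, clone in enumerate(clones):
        w = clone.weight
        for m in clone.mutations:
            w *= site_effects.get(m.position, 1.0)
        weights[i] = w
    return weights


def simulate_dmpra_counts(
    clones: list[MutantClone],
    site_effects: dict[int, float],
    depths: tuple[int, int],
    seed: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Plasmid (uniform) and cDNA (effect-weighted) clone counts.

    Returns ``(plasmid_counts, cdna_counts)``; each sums exactly to its
    stated depth.
    """
    plasmid_depth, cdna_depth = depths
    if plasmid_depth < 1 or cdna_depth < 1:
        raise InputError("depths must be >= 1")
    rng = _as_rng(seed)
    n = len(clones)
    plasmid = rng.multinomial(plasmid_depth, np.full(n, 1.0 / n))
    weights = clone_effect_weights(clones, site_effects)
    cdna = rng.multinomial(cdna_depth, weights / weights.sum())
    return plasmid, cdna
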