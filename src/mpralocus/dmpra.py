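"""Degenerate-MPRA per-nucleotide mutation-effect profiling.

Each read is a full-length copy of a mutagenized CRM. Reads are globally
aligned to the CRM reference to call substitutions and deletions; reads
that do not span the whole contig, contain insertions, or carry a
deletion inside a homopolymer run are excluded. Per-position mutation
frequencies are normalized to the wild-type (zero-mutation) read count,
estimated with Monte-Carlo subsampling replicates, and turned into an
effect profile: log2(experimental / plasmid-control frequency),
median-baseline corrected, smoothed with a five-base sliding window
moving average, and trimmed of the assembly-constrained first 18 and
last 14 positions. Depletion of mutations in cDNA marks bases required
for activation; enrichment marks repressor-bound bases.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .errors import InputError

KINDS = ("substitution", "deletion", "insertion")
FAIL_REASONS = ("partial-span", "homopolymer-deletion", "insertion")


@dataclass(frozen=True)
class MutationCall:
    """One mutation at a reference-anchored CRM position."""

    position: int
    kind: str
    ref_base: str
    alt_base: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InputError(f"unknown mutation kind {self.kind!r}")
        if self.position < 0:
            raise InputError("mutation position must be >= 0")
        if self.kind == "substitution" and self.alt_base == self.ref_base:
            raise InputError("substitution alt base equals reference base")


@dataclass(frozen=True)
class ReadObservation:
    """Mutation calls of one read plus its filter status."""

    calls: tuple[MutationCall, ...]
    spans_full_contig: bool
    filter_status: str = "pass"

    def __post_init__(self) -> None:
        if self.filter_status != "pass" and self.filter_status not in FAIL_REASONS:
            raise InputError(f"unknown filter status {self.filter_status!r}")

    @property
    def passed(self) -> bool:
        return self.filter_status == "pass"

    @property
    def is_wildtype(self) -> bool:
        return self.passed and not self.calls


@dataclass
class PositionFrequencies:
    """Wild-type-normalized per-position mutation frequencies."""

    f: np.ndarray
    wt_count: int
    depth: int
    label: str = ""
    replicate: int = 0
    spread: np.ndarray | None = None  # SD across Monte-Carlo subsamples

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.size and self.f.min() < 0:
            raise InputError("frequencies must be >= 0")


# ---------------------------------------------------------------------------
# Mutation calling
# ---------------------------------------------------------------------------

def _left_normalize(run_start: int, run_end: int, crm: str) -> tuple[int, int]:
    # shift a deletion run leftmost within identical sequence context,
    # mirroring the leftmost-gap convention for indel placement
    while run_start > 0 and crm[run_start - 1] == crm[run_end - 1]:
        run_start -= 1
        run_end -= 1
    return run_start, run_end


def call_mutations(read: str, crm: str) -> ReadObservation:
    """Globally align one read to the CRM and extract mutation calls.

    Alignment uses unit mismatch/gap costs; deletion runs are
    left-normalized so gap placement is deterministic. Reads with
    insertions relative to the reference fail with ``insertion``; reads
    whose alignment leaves reference bases uncovered at either contig
    end fail with ``partial-span``. Multi-base deletions mark every
    deleted position.
    """
    if not read:
        raise InputError("empty read")
    result = edlib.align(read, crm, mode="NW", task="path")
    cigar = result["cigar"]

    calls: list[MutationCall] = []
    del_runs: list[tuple[int, int]] = []
    has_insertion = False
    q = t = 0
    ops: list[tuple[int, str]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    for n, op in ops:
        if op == "=":
            q += n
            t += n
        elif op == "X":
            for k in range(n):
                calls.append(
                    MutationCall(t + k, "substitution", crm[t + k], read[q + k])
                )
            q += n
            t += n
        elif op == "D":  # reference bases absent from the read
            del_runs.append((t, t + n))
            t += n
        elif op == "I":  # read bases absent from the reference
            has_insertion = True
            q += n
        else:
            raise InputError(f"unexpected alignment op {op!r}")

    spans = not (
        (ops and ops[0][1] == "D") or (ops and ops[-1][1] == "D")
    )
    for run_start, run_end in del_runs:
        run_start, run_end = _left_normalize(run_start, run_end, crm)
        for p in range(run_start, run_end):
            calls.append(MutationCall(p, "deletion", crm[p], None))
    calls.sort(key=lambda c: c.position)

    if not spans:
        status = "partial-span"
    elif has_insertion:
        status = "insertion"
    else:
        status = "pass"
    return ReadObservation(tuple(calls), spans, status)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def find_homopolymers(crm: str, min_run: int = 3) -> list[tuple[int, int]]:
    """Maximal single-base runs of length >= ``min_run`` as half-open
    intervals."""
    if min_run < 2:
        raise InputError("min_run must be >= 2")
    out: list[tuple[int, int]] = []
    i = 0
    while i < len(crm):
        j = i
        while j < len(crm) and crm[j] == crm[i]:
            j += 1
        if j - i >= min_run:
            out.append((i, j))
        i = j
    return out


def apply_filters(
    obs: ReadObservation, homopolymers: Sequence[tuple[int, int]]
) -> ReadObservation:
    """Fail a passing read whose deletions fall inside homopolymer runs.

    Substitutions inside homopolymers are retained; only deletion calls
    there are uninterpretable (gap placement is degenerate).
    """
    if not obs.passed:
        return obs
    for call in obs.calls:
        if call.kind == "deletion" and any(
            s <= call.position < e for s, e in homopolymers
        ):
            return ReadObservation(obs.calls, obs.spans_full_contig,
                                   "homopolymer-deletion")
    return obs


def process_reads(
    reads: Iterable[str], crm: str, min_homopolymer: int = 3
) -> list[ReadObservation]:
    """call_mutations + homopolymer filtering over a read collection."""
    homopolymers = find_homopolymers(crm, min_homopolymer)
    return [apply_filters(call_mutations(r, crm), homopolymers) for r in reads]


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def position_frequencies(
    observations: Iterable[ReadObservation],
    crm_length: int,
    label: str = "",
    replicate: int = 0,
) -> PositionFrequencies:
    """f(i) = (# passing reads mutated at i) / (# passing wild-type reads).

    The wild-type denominator makes frequencies comparable across
    libraries sequenced to different depths.
    """
    calls_per_read: list[tuple[int, ...]] = []
    for obs in observations:
        if obs.passed:
            calls_per_read.append(tuple(c.position for c in obs.calls))
    grouped = Counter(calls_per_read)
    positions = list(grouped.keys())
    counts = np.array([grouped[p] for p in positions], dtype=np.int64)
    return position_frequencies_from_counts(
        positions, counts, crm_length, label=label, replicate=replicate
    )


def position_frequencies_from_counts(
    call_positions: Sequence[tuple[int, ...]],
    counts: np.ndarray,
    crm_length: int,
    label: str = "",
    replicate: int = 0,
) -> PositionFrequencies:
    """Grouped form: identical reads collapsed to (mutated positions,
    multiplicity). Used directly by clone-level simulations."""
    counts = np.asarray(counts, dtype=np.int64)
    if len(call_positions) != counts.size:
        raise InputError("call_positions and counts must align")
    depth = int(counts.sum())
    wt = int(sum(c for p, c in zip(call_positions, counts) if not p))
    if wt == 0:
        raise InputError(
            "no passing wild-type reads: wild-type normalization undefined"
        )
    hits = np.zeros(crm_length, dtype=float)
    for pos_tuple, c in zip(call_positions, counts):
        for p in pos_tuple:
            if not 0 <= p < crm_length:
                raise InputError(f"call position {p} outside the CRM")
            hits[p] += c
    return PositionFrequencies(hits / wt, wt, depth, label, replicate)


def monte_carlo_frequencies(
    observations: Iterable[ReadObservation] | Sequence[tuple[int, ...]],
    crm_length: int,
    depth: int,
    n_reps: int = 10,
    seed: np.random.Generator | int | None = None,
    counts: np.ndarray | None = None,
    label: str = "",
) -> PositionFrequencies:
    """Monte-Carlo subsampled frequency estimate.

    Draws ``n_reps`` independent subsamples of ``depth`` passing reads
    without replacement, computes wild-type-normalized frequencies per
    subsample, and reports their position-wise mean with the SD across
    subsamples in ``spread``.

    ``observations`` is either an iterable of :class:`ReadObservation`
    or, with ``counts`` given, a grouped list of mutated-position tuples.
    """
    if counts is None:
        grouped = Counter(
            tuple(c.position for c in obs.calls)
            for obs in observations
            if obs.passed
        )
        call_positions = list(grouped.keys())
        counts = np.array([grouped[p] for p in call_positions], dtype=np.int64)
    else:
        call_positions = list(observations)  # type: ignore[arg-type]
        counts = np.asarray(counts, dtype=np.int64)

    total = int(counts.sum())
    if depth > total:
        raise InputError(f"subsample depth {depth} exceeds {total} passing reads")
    if depth < 1 or n_reps < 1:
        raise InputError("depth and n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    reps = np.empty((n_reps, crm_length))
    wt_counts = []
    for r in range(n_reps):
        sub = rng.multivariate_hypergeometric(counts, depth, method="marginals")
        pf = position_frequencies_from_counts(
            call_positions, sub, crm_length, label=label, replicate=r
        )
        reps[r] = pf.f
        wt_counts.append(pf.wt_count)
    spread = reps.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(crm_length)
    return PositionFrequencies(
        reps.mean(axis=0),
        wt_count=int(np.mean(wt_counts)),
        depth=depth,
        label=label,
        spread=spread,
    )


# ---------------------------------------------------------------------------
# Effect profiles
# ---------------------------------------------------------------------------

@dataclass
class EffectProfile:
    """Per-position mutation-effect profile of one replicate.

    ``raw_log2`` -> ``baseline_corrected`` (median-subtracted) ->
    ``smoothed`` (centered moving average, truncated at the array ends)
    -> ``trimmed`` (assembly-constrained edges removed).
    """

    raw_log2: np.ndarray
    baseline_corrected: np.ndarray
    smoothed: np.ndarray
    trimmed: np.ndarray
    window: int = 5
    trim: tuple[int, int] = (18, 14)
    epsilon: float = 0.0
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.window % 2 != 1:
            raise InputError("smoothing window must be odd")
        expected = self.raw_log2.size - sum(self.trim)
        if self.trimmed.size != expected:
            raise InputError(
                f"trimmed length {self.trimmed.size} != L - "
                f"{sum(self.trim)} = {expected}"
            )


def lower_median(values: np.ndarray) -> float:
    """Median with the lower-middle convention for even counts."""
    ordered = np.sort(np.asarray(values, dtype=float))
    if ordered.size == 0:
        raise InputError("median of empty array")
    return float(ordered[(ordered.size - 1) // 2])


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with a truncated (shrinking) window at
    the edges; preserves a constant array exactly."""
    if window % 2 != 1 or window < 1:
        raise InputError("window must be a positive odd integer")
    half = window // 2
    n = values.size
    csum = np.concatenate(([0.0], np.cumsum(values)))
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def effect_profile(
    exp: PositionFrequencies,
    ctrl: PositionFrequencies,
    window: int = 5,
    trim: tuple[int, int] = (18, 14),
    epsilon: float | None = None,
    replicate: int = 0,
) -> EffectProfile:
    """Experimental vs plasmid-control effect profile.

    raw(i) = log2((f_exp(i)+eps) / (f_ctrl(i)+eps)); the baseline is the
    median raw value (lower-middle convention), subtracted before a
    width-``window`` moving average; ``trim`` removes the first and last
    assembly-constrained positions. ``epsilon`` defaults to
    0.5 / min(wild-type count of the two libraries).
    """
    if exp.f.size != ctrl.f.size:
        raise InputError("experimental and control profiles differ in length")
    if epsilon is None:
        epsilon = 0.5 / min(exp.wt_count, ctrl.wt_count)
    if epsilon <= 0:
        raise InputError("epsilon must be > 0")
    t_left, t_right = trim
    L = exp.f.size
    if t_left + t_right >= L:
        raise InputError("trim removes the whole profile")
    raw = np.log2((exp.f + epsilon) / (ctrl.f + epsilon))
    corrected = raw - lower_median(raw)
    smoothed = moving_average(corrected, window)
    trimmed = smoothed[t_left : L - t_right]
    return EffectProfile(
        raw, corrected, smoothed, trimmed, window, trim, epsilon, replicate
    )


def aggregate_profiles(
    profiles: Sequence[EffectProfile],
) -> tuple[np.ndarray, np.ndarray]:
    """Position-wise mean and SD of trimmed profiles across replicates."""
    if not profiles:
        raise InputError("no profiles to aggregate")
    sizes = {p.trimmed.size for p in profiles}
    if len(sizes) != 1:
        raise InputError("profiles differ in trimmed length")
    stack = np.stack([p.trimmed for p in profiles])
    sd = stack.std(axis=0, ddof=1) if len(profiles) > 1 else np.zeros(stack.shape[1])
    return stack.mean(axis=0), sd


def permutation_band(
    profile: EffectProfile,
    n_perm: int = 200,
    seed: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation null for the trimmed profile.

    Shuffles the baseline-corrected values across positions, re-smooths
    and re-trims each permutation, and returns the position-wise
    (mean, SD) of the null ensemble — the +/-3 SD band flags positions
    incompatible with an exchangeable (no-effect) profile.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = profile.baseline_corrected.size
    t_left, t_right = profile.trim
    null = np.empty((n_perm, L - t_left - t_right))
    for i in range(n_perm):
        perm = rng.permutation(profile.baseline_corrected)
        null[i] = moving_average(perm, profile.window)[t_left : L - t_right]
    return null.mean(axis=0), null.std(axis=0, ddof=1)


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

def write_profile_tsv(
    path,
    profile: EffectProfile,
    replicates: Sequence[EffectProfile] | None = None,
) -> None:
    """Per-position profile table (position, raw, corrected, smoothed,
    trimmed flag, per-replicate trimmed values, mean, sd)."""
    import csv

    reps = list(replicates or [])
    t_left, t_right = profile.trim
    L = profile.raw_log2.size
    mean = sd = None
    if reps:
        mean, sd = aggregate_profiles(reps)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        header = ["position", "raw_log2", "corrected", "smoothed", "in_trimmed"]
        header += [f"rep{p.replicate}" for p in reps]
        if reps:
            header += ["mean", "sd"]
        writer.writerow(header)
        for i in range(L):
            in_trim = t_left <= i < L - t_right
            row = [
                i,
                f"{profile.raw_log2[i]:.6g}",
                f"{profile.baseline_corrected[i]:.6g}",
                f"{profile.smoothed[i]:.6g}",
                int(in_trim),
            ]
            j = i - t_left
            for p in reps:
                row.append(f"{p.trimmed[j]:.6g}" if in_trim else ".")
            if reps:
                row.append(f"{mean[j]:.6g}" if in_trim else ".")
                row.append(f"{sd[j]:.6g}" if in_trim else ".")
            writer.writerow(row)
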