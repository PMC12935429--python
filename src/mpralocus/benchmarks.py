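"""Seeded benchmark experiments on planted synthetic assays.

These routines run the full statistical chain of each pipeline on
synthetic data with known ground truth — a planted active region for the
LS-MPRA enrichment readout, planted activator/repressor sites for the
d-MPRA effect profile — and score whether the readout recovers the
plant. They work at the barcode/clone count level: the generative model
(fragmentation, barcoding, multinomial expression, mutagenesis,
effect-weighted counts) and the analysis (coverage baselines, CPM
log2-ratio tracks, wild-type-normalized Monte-Carlo frequencies,
median-corrected smoothed trimmed profiles) are exactly the production
code paths; only FASTQ serialization and re-parsing are bypassed, those
being covered by their own round-trip checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assoc import BarcodeAssociation
from .dmpra import (
    EffectProfile,
    effect_profile,
    find_homopolymers,
    monte_carlo_frequencies,
    permutation_band,
)
from .lsquant import auc_score, enrichment_track
from .simgen import (
    ActivityModel,
    MutantClone,
    SimSpec,
    assign_barcodes,
    fragment_reference,
    mutagenize_crm,
    random_reference,
    simulate_dmpra_counts,
    simulate_expression,
)


# ---------------------------------------------------------------------------
# LS-MPRA planted-peak recovery
# ---------------------------------------------------------------------------

@dataclass
class PeakRecoveryResult:
    argmax: int
    in_region: bool
    auc_region: float
    auc_background_max: float

    @property
    def auc_wins(self) -> bool:
        return self.auc_region > self.auc_background_max


def lsmpra_planted_peak_run(
    seed: int,
    reference_length: int = 10_000,
    n_fragments: int = 5_000,
    region: tuple[int, int] = (4_000, 4_500),
    strength: float = 8.0,
    depth: int = 100_000,
    fragment_size_range: tuple[int, int] = (200, 500),
) -> PeakRecoveryResult:
    """One seeded LS-MPRA simulation + quantification.

    Simulates a fragment library over a random reference with one planted
    active region, draws multinomial cDNA counts, builds the enrichment
    track against the ground-truth association, and reports whether the
    global argmax falls inside the planted region and whether the
    region's AUC beats every equal-length disjoint background interval.
    """
    rng = np.random.default_rng(seed)
    spec = SimSpec(
        seed=seed,
        n_fragments=n_fragments,
        fragment_size_range=fragment_size_range,
        cdna_depth=depth,
    )
    reference = random_reference(reference_length, rng)
    model = ActivityModel(regions=[(*region, strength)])
    model.validate_against(reference_length)
    fragments = fragment_reference(reference, spec, rng)
    association_map = assign_barcodes(fragments, spec, rng)
    counts = simulate_expression(association_map, model, depth, rng)

    truth = BarcodeAssociation(
        entries={b: (f, 1) for b, f in association_map.items()}
    )
    track = enrichment_track(counts, truth, reference_length)

    argmax = int(np.argmax(track.values))
    start, end = region
    width = end - start
    auc_region = auc_score(track, region).auc
    background = []
    for s in range(0, reference_length - width + 1, width):
        if s + width <= start or s >= end:
            background.append(auc_score(track, (s, s + width)).auc)
    return PeakRecoveryResult(
        argmax=argmax,
        in_region=start <= argmax < end,
        auc_region=auc_region,
        auc_background_max=max(background),
    )


# ---------------------------------------------------------------------------
# d-MPRA sign recovery and null flatness
# ---------------------------------------------------------------------------

def clone_read_groups(
    clones: list[MutantClone],
    counts: np.ndarray,
    crm: str,
    min_homopolymer: int = 3,
) -> tuple[list[tuple[int, ...]], np.ndarray]:
    """Apply the read filters to exact clone copies.

    Each sequenced read of a clone carries exactly the clone's mutations,
    so filtering happens per clone: clones with insertions fail, clones
    with a deletion inside a homopolymer run fail, the rest pass with
    their mutated positions as the call set. Returns grouped
    (positions, multiplicity) input for the frequency estimators.
    """
    homopolymers = find_homopolymers(crm, min_homopolymer)
    call_positions: list[tuple[int, ...]] = []
    kept_counts: list[int] = []
    for clone, n in zip(clones, counts):
        if n == 0:
            continue
        if any(m.kind == "insertion" for m in clone.mutations):
            continue
        if any(
            m.kind == "deletion" and any(s <= m.position < e for s, e in homopolymers)
            for m in clone.mutations
        ):
            continue
        call_positions.append(tuple(m.position for m in clone.mutations))
        kept_counts.append(int(n))
    return call_positions, np.asarray(kept_counts, dtype=np.int64)


@dataclass
class SignRecoveryResult:
    profile: EffectProfile
    activator_value: float
    repressor_value: float
    signs_correct: bool
    above_background: bool


def dmpra_sign_recovery_run(
    seed: int,
    crm_length: int = 300,
    n_clones: int = 50_000,
    mutation_rate: float = 0.001,
    activator_site: int = 100,
    activator_multiplier: float = 0.1,
    repressor_site: int = 200,
    repressor_multiplier: float = 10.0,
    depth: int = 100_000,
    mc_reps: int = 10,
) -> SignRecoveryResult:
    """One seeded d-MPRA simulation + effect profiling.

    Plants an activator site (mutations deplete expression) and a
    repressor site (mutations boost it), both well inside the trimmed
    window, and checks that the trimmed profile is negative at the
    activator, positive at the repressor, and that |profile| at both
    planted sites exceeds the 95th percentile of |profile| elsewhere.
    """
    rng = np.random.default_rng(seed)
    spec = SimSpec(seed=seed, mutation_rate=mutation_rate)
    crm = random_reference(crm_length, rng)
    clones = mutagenize_crm(crm, n_clones, spec, rng)
    site_effects = {
        activator_site: activator_multiplier,
        repressor_site: repressor_multiplier,
    }
    plasmid, cdna = simulate_dmpra_counts(
        clones, site_effects, (depth, depth), rng
    )

    groups = {
        "control": clone_read_groups(clones, plasmid, crm),
        "experimental": clone_read_groups(clones, cdna, crm),
    }
    mc_depth = min(int(c.sum()) for _, c in groups.values())
    freqs = {
        label: monte_carlo_frequencies(
            positions, crm_length, mc_depth, mc_reps, rng, counts=c, label=label
        )
        for label, (positions, c) in groups.items()
    }
    profile = effect_profile(freqs["experimental"], freqs["control"])

    t_left, t_right = profile.trim
    trimmed = profile.trimmed
    act_idx = activator_site - t_left
    rep_idx = repressor_site - t_left
    act_value = float(trimmed[act_idx])
    rep_value = float(trimmed[rep_idx])

    planted = set()
    half = profile.window // 2
    for site in (activator_site, repressor_site):
        planted.update(range(site - t_left - half, site - t_left + half + 1))
    background = np.abs(
        [v for i, v in enumerate(trimmed) if i not in planted]
    )
    cutoff = float(np.percentile(background, 95))
    return SignRecoveryResult(
        profile=profile,
        activator_value=act_value,
        repressor_value=rep_value,
        signs_correct=act_value < 0 < rep_value,
        above_background=abs(act_value) > cutoff and abs(rep_value) > cutoff,
    )


def dmpra_null_run(
    seed: int,
    crm_length: int = 300,
    n_clones: int = 50_000,
    mutation_rate: float = 0.001,
    depth: int = 100_000,
    mc_reps: int = 10,
    n_perm: int = 100,
) -> np.ndarray:
    """One no-effect d-MPRA simulation against its permutation band.

    Returns a boolean mask over trimmed positions marking where the
    profile leaves the +/-3 SD permutation null band.
    """
    rng = np.random.default_rng(seed)
    spec = SimSpec(seed=seed, mutation_rate=mutation_rate)
    crm = random_reference(crm_length, rng)
    clones = mutagenize_crm(crm, n_clones, spec, rng)
    plasmid, cdna = simulate_dmpra_counts(clones, {}, (depth, depth), rng)
    groups = {
        "control": clone_read_groups(clones, plasmid, crm),
        "experimental": clone_read_groups(clones, cdna, crm),
    }
    mc_depth = min(int(c.sum()) for _, c in groups.values())
    freqs = {
        label: monte_carlo_frequencies(
            positions, crm_length, mc_depth, mc_reps, rng, counts=c, label=label
        )
        for label, (positions, c) in groups.items()
    }
    profile = effect_profile(freqs["experimental"], freqs["control"])
    null_mean, null_sd = permutation_band(profile, n_perm=n_perm, seed=rng)
    return np.abs(profile.trimmed - null_mean) > 3.0 * null_sd
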