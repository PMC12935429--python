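"""Mutation calling, filtering, frequency estimation and effect profiles."""

import numpy as np
import pytest

from mpralocus import dmpra, simgen
from mpralocus.errors import InputError


class TestCallMutations:
    def test_single_substitution(self):
        obs = dmpra.call_mutations("ACGAACGT", "ACGTACGT")
        assert obs.passed
        assert len(obs.calls) == 1
        call = obs.calls[0]
        assert (call.position, call.kind, call.ref_base, call.alt_base) == (
            3, "substitution", "T", "A"
        )

    def test_wildtype_read(self):
        obs = dmpra.call_mutations("ACGTACGT", "ACGTACGT")
        assert obs.passed and not obs.calls
        assert obs.is_wildtype

    def test_partial_span_fails(self):
        obs = dmpra.call_mutations("ACGT", "ACGTACGT")
        assert obs.filter_status == "partial-span"
        assert not obs.spans_full_contig

    def test_leading_truncation_fails(self):
        obs = dmpra.call_mutations("TACGT", "ACGTACGT")
        assert obs.filter_status == "partial-span"

    def test_insertion_fails(self):
        obs = dmpra.call_mutations("ACGTTACGA", "ACGTACGA")
        assert obs.filter_status == "insertion"

    def test_internal_deletion_called(self):
        obs = dmpra.call_mutations("ACGACGT", "ACGTACGT")
        assert obs.passed
        dels = [c for c in obs.calls if c.kind == "deletion"]
        assert len(dels) == 1
        assert dels[0].position == 3

    def test_multi_base_deletion_marks_every_position(self):
        obs = dmpra.call_mutations("ACGGT", "ACGTAGGT")
        dels = sorted(c.position for c in obs.calls if c.kind == "deletion")
        assert len(dels) == 3

    def test_deletion_left_normalized_in_homopolymer(self):
        # deleting any C of CCC is equivalent; the call lands leftmost
        obs = dmpra.call_mutations("ACCGT", "ACCCGT")
        dels = [c for c in obs.calls if c.kind == "deletion"]
        assert len(dels) == 1
        assert dels[0].position == 1

    def test_empty_read_rejected(self):
        with pytest.raises(InputError):
            dmpra.call_mutations("", "ACGT")

    def test_recovers_simulated_clone_mutations(self):
        """Aligning an exact clone copy recovers the planted sub/del set."""
        crm = simgen.random_reference(200, 21)
        spec = simgen.SimSpec(mutation_rate=0.02,
                              mutation_spectrum=(0.8, 0.2, 0.0))
        clones = simgen.mutagenize_crm(crm, 60, spec, rng=4)
        checked = 0
        for clone in clones:
            # skip adjacent-mutation clones where call equivalence is
            # alignment-ambiguous by construction
            positions = sorted(m.position for m in clone.mutations)
            if any(b - a < 4 for a, b in zip(positions, positions[1:])):
                continue
            read = simgen.mutant_sequence(crm, clone)
            obs = dmpra.call_mutations(read, crm)
            hom = dmpra.find_homopolymers(crm)
            in_hom = lambda p: any(s <= p < e for s, e in hom)
            def left_normal(p):
                # a deletion in a repeat context is alignment-equivalent
                # to deleting the leftmost repeated base
                while p > 0 and crm[p - 1] == crm[p]:
                    p -= 1
                return p

            expected = {
                (left_normal(m.position) if m.kind == "deletion" else m.position,
                 m.kind)
                for m in clone.mutations
                if not (m.kind == "deletion" and in_hom(m.position))
            }
            got = {(c.position, c.kind) for c in obs.calls
                   if not (c.kind == "deletion" and in_hom(c.position))}
            assert got == expected
            checked += 1
        assert checked >= 30


class TestHomopolymers:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACGTTTGA", [(3, 6)]),
            ("ACGT", []),
            ("AAAAA", [(0, 5)]),
            ("AAATTTAA", [(0, 3), (3, 6)]),
        ],
    )
    def test_maximal_runs(self, seq, expected):
        assert dmpra.find_homopolymers(seq, 3) == expected

    def test_min_run_validation(self):
        with pytest.raises(InputError):
            dmpra.find_homopolymers("ACGT", 1)


class TestApplyFilters:
    HOM = [(3, 6)]

    def _obs(self, calls):
        return dmpra.ReadObservation(tuple(calls), True, "pass")

    def test_deletion_in_homopolymer_fails(self):
        obs = self._obs([dmpra.MutationCall(4, "deletion", "T")])
        out = dmpra.apply_filters(obs, self.HOM)
        assert out.filter_status == "homopolymer-deletion"

    def test_substitution_in_homopolymer_retained(self):
        obs = self._obs([dmpra.MutationCall(4, "substitution", "T", "C")])
        assert dmpra.apply_filters(obs, self.HOM).passed

    def test_deletion_outside_runs_passes(self):
        obs = self._obs([dmpra.MutationCall(7, "deletion", "A")])
        assert dmpra.apply_filters(obs, self.HOM).passed


class TestPositionFrequencies:
    def _obs(self, positions):
        calls = tuple(
            dmpra.MutationCall(p, "substitution", "A", "C") for p in positions
        )
        return dmpra.ReadObservation(calls, True, "pass")

    def test_wildtype_normalized_formula(self):
        observations = [self._obs([])] * 900 + [self._obs([5])] * 10
        pf = dmpra.position_frequencies(observations, 20)
        assert pf.wt_count == 900
        assert pf.depth == 910
        assert pf.f[5] == pytest.approx(10 / 900)
        assert pf.f[6] == 0.0

    def test_failed_reads_excluded(self):
        failed = dmpra.ReadObservation((), False, "partial-span")
        pf = dmpra.position_frequencies([self._obs([])] * 5 + [failed] * 5, 10)
        assert pf.depth == 5

    def test_no_wildtype_is_degenerate(self):
        with pytest.raises(InputError):
            dmpra.position_frequencies([self._obs([1])] * 3, 10)

    def test_simulated_rate_recovery(self):
        """At r=0.001 over a 100 bp CRM the wild-type-normalized mean
        frequency approximates the per-site rate (binomial oracle)."""
        L, r, n = 100, 0.001, 100_000
        rng = np.random.default_rng(10)
        k = rng.binomial(L, r, size=n)
        observations = []
        for ki in k:
            positions = rng.choice(L, size=ki, replace=False) if ki else []
            observations.append(self._obs(list(positions)))
        pf = dmpra.position_frequencies(observations, L)
        assert pf.f.mean() == pytest.approx(r, rel=0.2)


class TestMonteCarlo:
    def _library(self, seed=0, n=2000, L=50, r=0.01):
        rng = np.random.default_rng(seed)
        k = rng.binomial(L, r, size=n)
        groups = {}
        for ki in k:
            key = tuple(sorted(rng.choice(L, size=ki, replace=False))) if ki else ()
            groups[key] = groups.get(key, 0) + 1
        positions = list(groups)
        counts = np.array([groups[p] for p in positions])
        return positions, counts, L

    def test_full_depth_subsampling_is_degenerate(self):
        positions, counts, L = self._library()
        full = dmpra.position_frequencies_from_counts(positions, counts, L)
        mc = dmpra.monte_carlo_frequencies(
            positions, L, depth=int(counts.sum()), n_reps=10, seed=1,
            counts=counts,
        )
        assert np.allclose(mc.f, full.f)
        assert np.allclose(mc.spread, 0.0)

    def test_single_rep_mean_is_that_subsample(self):
        positions, counts, L = self._library()
        a = dmpra.monte_carlo_frequencies(
            positions, L, depth=500, n_reps=1, seed=7, counts=counts
        )
        b = dmpra.monte_carlo_frequencies(
            positions, L, depth=500, n_reps=1, seed=7, counts=counts
        )
        assert np.allclose(a.f, b.f)
        assert np.allclose(a.spread, 0.0)

    def test_depth_exceeding_reads_rejected(self):
        positions, counts, L = self._library()
        with pytest.raises(InputError):
            dmpra.monte_carlo_frequencies(
                positions, L, depth=int(counts.sum()) + 1, counts=counts
            )

    def test_mse_decreases_with_depth(self):
        positions, counts, L = self._library(seed=3, n=20_000)
        full = dmpra.position_frequencies_from_counts(positions, counts, L)
        total = int(counts.sum())
        mses = []
        for frac in (0.1, 0.5, 1.0):
            mc = dmpra.monte_carlo_frequencies(
                positions, L, depth=int(total * frac), n_reps=10, seed=5,
                counts=counts,
            )
            mses.append(float(np.mean((mc.f - full.f) ** 2)))
        assert mses[0] > mses[1] > mses[2]
        assert mses[2] == pytest.approx(0.0, abs=1e-18)

    def test_spread_scales_as_inverse_sqrt_depth(self):
        """SD across subsamples ~ depth^-1/2 (log-log slope in
        [-0.65, -0.35]) away from the without-replacement ceiling."""
        positions, counts, L = self._library(seed=11, n=200_000, r=0.02)
        depths = [1000, 4000, 16000]
        sds = []
        for d in depths:
            mc = dmpra.monte_carlo_frequencies(
                positions, L, depth=d, n_reps=10, seed=13, counts=counts
            )
            sds.append(float(mc.spread.mean()))
        slope = np.polyfit(np.log(depths), np.log(sds), 1)[0]
        assert -0.65 <= slope <= -0.35

    def test_observation_interface_matches_grouped(self):
        calls = [(), (3,), (), (3, 7), ()]
        observations = [
            dmpra.ReadObservation(
                tuple(dmpra.MutationCall(p, "substitution", "A", "C") for p in ps),
                True, "pass",
            )
            for ps in calls
        ]
        mc_obs = dmpra.monte_carlo_frequencies(observations, 10, depth=5,
                                               n_reps=3, seed=2)
        pf = dmpra.position_frequencies(observations, 10)
        assert np.allclose(mc_obs.f, pf.f)


class TestEffectProfile:
    def _pf(self, f, wt=1000):
        return dmpra.PositionFrequencies(np.asarray(f, dtype=float), wt, wt)

    def test_doubled_frequency_gives_flat_zero_profile(self):
        base = np.full(60, 0.01)
        profile = dmpra.effect_profile(
            self._pf(2 * base), self._pf(base), trim=(10, 10), epsilon=1e-12
        )
        assert np.allclose(profile.raw_log2, 1.0, atol=1e-6)
        assert np.allclose(profile.baseline_corrected, 0.0, atol=1e-6)
        assert np.allclose(profile.trimmed, 0.0, atol=1e-6)

    def test_smoothing_spike(self):
        smoothed = dmpra.moving_average(np.array([0, 0, 5, 0, 0.0]), 5)
        assert smoothed[2] == pytest.approx(1.0)

    def test_smoothing_preserves_constant(self):
        values = np.full(37, 2.5)
        assert np.allclose(dmpra.moving_average(values, 5), 2.5)

    def test_trimmed_length(self):
        f = np.abs(np.random.default_rng(0).normal(0.01, 0.001, 244))
        profile = dmpra.effect_profile(self._pf(f), self._pf(f))
        assert profile.trimmed.size == 244 - 18 - 14 == 212

    def test_median_correction_exactness(self):
        rng = np.random.default_rng(1)
        f1 = np.abs(rng.normal(0.01, 0.003, 101))
        f2 = np.abs(rng.normal(0.01, 0.003, 101))
        profile = dmpra.effect_profile(self._pf(f1), self._pf(f2), trim=(10, 10))
        assert dmpra.lower_median(profile.baseline_corrected) == 0.0

    def test_lower_median_convention(self):
        assert dmpra.lower_median(np.array([4.0, 1.0, 3.0, 2.0])) == 2.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            dmpra.effect_profile(self._pf(np.ones(10)), self._pf(np.ones(12)),
                                 trim=(2, 2))

    def test_default_epsilon_from_wildtype_counts(self):
        f = np.full(50, 0.01)
        profile = dmpra.effect_profile(
            self._pf(f, wt=200), self._pf(f, wt=400), trim=(5, 5)
        )
        assert profile.epsilon == pytest.approx(0.5 / 200)

    def test_aggregate_mean_and_sd(self):
        f = np.full(50, 0.01)
        profiles = []
        for shift, rep in ((0.0, 0), (0.002, 1)):
            profiles.append(
                dmpra.effect_profile(
                    self._pf(f + shift), self._pf(f), trim=(5, 5), replicate=rep
                )
            )
        mean, sd = dmpra.aggregate_profiles(profiles)
        assert mean.shape == sd.shape == (40,)
        assert np.all(sd >= 0)

    def test_permutation_band_contains_null_profile(self):
        rng = np.random.default_rng(8)
        f1 = np.abs(rng.normal(0.01, 0.001, 120))
        f2 = np.abs(rng.normal(0.01, 0.001, 120))
        profile = dmpra.effect_profile(self._pf(f1), self._pf(f2))
        mean, sd = dmpra.permutation_band(profile, n_perm=200, seed=0)
        frac_inside = np.mean(np.abs(profile.trimmed - mean) <= 3 * sd)
        assert frac_inside > 0.95


class TestProfileTsv:
    def test_written_table_has_all_positions(self, tmp_path):
        f = np.full(60, 0.01)
        pf = dmpra.PositionFrequencies(f, 100, 100)
        profile = dmpra.effect_profile(pf, pf, trim=(10, 10))
        path = tmp_path / "profile.tsv"
        dmpra.write_profile_tsv(path, profile, [profile])
        lines = path.read_text().splitlines()
        assert len(lines) == 61
        assert lines[0].split("\t")[:5] == [
            "position", "raw_log2", "corrected", "smoothed", "in_trimmed"
        ]
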