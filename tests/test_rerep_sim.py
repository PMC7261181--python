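"""Semiconservative labeling algebra, the opposed-nick digest, and pileup."""

import numpy as np
import pytest

from rerepseq import scenarios
from rerepseq.genome_io import GenomeDef
from rerepseq.rerep_sim import (
    DigestParams,
    DuplexMolecule,
    Fragment,
    FragmentBoundsError,
    LabelSchedule,
    OriginMap,
    Phase,
    ScheduleError,
    digest_molecule,
    double_labeled_fraction,
    fragments_to_track,
    replicate_population,
    simulate_sample,
    size_select,
)


@pytest.fixture
def tiny_genome():
    return GenomeDef([("chr1", 20_000), ("chrM", 2_000)], mito_name="chrM")


@pytest.fixture
def tiny_origins():
    return OriginMap({"chr1": [(0, 0.0)]}, fork_speed=1000.0)


class TestReplicatePopulation:
    def test_one_cycle_single_strand_labeled(self, tiny_genome, tiny_origins):
        mols = replicate_population(
            tiny_genome, tiny_origins, scenarios.multi_cycle_schedule(1),
            n_cells=1, mito_copies=1,
        )
        nuclear = [m for m in mols if m.chrom == "chr1"]
        assert len(nuclear) == 2
        for m in nuclear:
            one = m.top_labeled == [(0, 20_000)] and m.bottom_labeled == []
            other = m.bottom_labeled == [(0, 20_000)] and m.top_labeled == []
            assert one or other
        assert double_labeled_fraction(mols, tiny_genome) == 0.0

    @pytest.mark.parametrize("n_cycles,expected", [(1, 0.0), (2, 0.5), (3, 0.75)])
    def test_double_labeled_fraction_exact(self, tiny_genome, tiny_origins, n_cycles, expected):
        # population bookkeeping: fraction double-labeled = 1 - 2^(1-n)
        mols = replicate_population(
            tiny_genome, tiny_origins, scenarios.multi_cycle_schedule(n_cycles),
            n_cells=3, mito_copies=1,
        )
        assert double_labeled_fraction(mols, tiny_genome) == expected

    def test_fork_arithmetic_partial_sphase(self, tiny_genome, tiny_origins):
        """Single origin at 0, 1 kb/min, sampled at 10 min: label covers [0, 10 kb).

        Oracle: brute-force per-bp replication times, min over origins of
        firing_time + distance / fork_speed, thresholded at the sampling time.
        """
        pos = np.arange(20_000)
        t_rep = 0.0 + np.abs(pos - 0) / 1000.0
        # half-open convention: the interval end is the first unreplicated bp
        expected_bp = int((t_rep < 10.0).sum())
        sched = LabelSchedule((Phase(True, 10.0),))
        mols = replicate_population(tiny_genome, tiny_origins, sched, 1, mito_copies=1)
        nascent = [m.bottom_labeled or m.top_labeled for m in mols if m.chrom == "chr1"]
        for lab in nascent:
            assert lab == [(0, expected_bp)]

    def test_mito_always_double_labeled(self, tiny_genome, tiny_origins):
        mols = replicate_population(
            tiny_genome, tiny_origins, scenarios.multi_cycle_schedule(1),
            n_cells=2, mito_copies=5,
        )
        mito = [m for m in mols if m.chrom == "chrM"]
        assert len(mito) == 10
        assert all(m.is_fully_double_labeled() for m in mito)

    def test_zero_phase_schedule_rejected(self):
        with pytest.raises(ScheduleError):
            LabelSchedule(())

    def test_reproducible_given_seed(self, tiny_genome, tiny_origins):
        sched = LabelSchedule((Phase(True, "asynchronous"),))
        a = replicate_population(tiny_genome, tiny_origins, sched, 5, rng_seed=42, mito_copies=1)
        b = replicate_population(tiny_genome, tiny_origins, sched, 5, rng_seed=42, mito_copies=1)
        assert [(m.chrom, m.top_labeled, m.bottom_labeled) for m in a] == [
            (m.chrom, m.top_labeled, m.bottom_labeled) for m in b
        ]


class TestDigest:
    def test_unlabeled_molecule_single_terminal_fragment(self, rng):
        mol = DuplexMolecule("c", 0, 1000)
        frags = digest_molecule(mol, DigestParams(p_nick=1.0), rng)
        assert len(frags) == 1 and not frags[0].is_internal
        assert (frags[0].start, frags[0].end) == (0, 1000)

    @pytest.mark.parametrize("p_nick", [0.01, 0.2, 1.0])
    def test_single_strand_labeled_never_breaks(self, rng, p_nick):
        # opposed nicks are impossible with one labeled strand
        mol = DuplexMolecule("c", 0, 5000, top_labeled=[(0, 5000)])
        frags = digest_molecule(mol, DigestParams(p_nick=p_nick), rng)
        assert len(frags) == 1 and not frags[0].is_internal

    def test_deterministic_forced_nicks(self, rng):
        """Hand-enumerated pairing oracle: top {100,600}, bottom {105,590},
        offset 16 -> breaks at 102 and 595 -> three fragments."""
        mol = DuplexMolecule("c", 0, 1000, [(0, 1000)], [(0, 1000)])
        params = DigestParams(p_nick=1.0, dsb_max_offset=16)
        frags = digest_molecule(
            mol, params, rng, forced_top=[100, 600], forced_bottom=[105, 590]
        )
        assert [(f.start, f.end) for f in frags] == [(0, 102), (102, 595), (595, 1000)]
        assert [f.is_internal for f in frags] == [False, True, False]

    def test_nick_used_at_most_once(self, rng):
        # one top nick cannot pair with two bottom nicks
        mol = DuplexMolecule("c", 0, 1000, [(0, 1000)], [(0, 1000)])
        params = DigestParams(p_nick=1.0, dsb_max_offset=16)
        frags = digest_molecule(mol, params, rng, forced_top=[500], forced_bottom=[495, 505])
        assert sum(f.is_internal for f in frags) == 0  # one break -> two terminal pieces
        assert len(frags) == 2

    def test_double_labeled_yield_and_fragment_size(self, rng):
        params = scenarios.default_digest_params()
        mol = DuplexMolecule("c", 0, 200_000, [(0, 200_000)], [(0, 200_000)])
        frags = digest_molecule(mol, params, rng)
        internal = [f for f in frags if f.is_internal]
        assert len(internal) > 100
        mean_len = np.mean([f.length for f in internal])
        assert 300 <= mean_len <= 600

    def test_yield_monotone_in_p_nick(self, rng):
        mol = DuplexMolecule("c", 0, 100_000, [(0, 100_000)], [(0, 100_000)])
        yields = []
        for p in (0.01, 0.03, 0.1):
            counts = [
                len(size_select(digest_molecule(mol, DigestParams(p_nick=p), rng),
                                DigestParams(p_nick=p)))
                for _ in range(5)
            ]
            yields.append(np.mean(counts))
        assert yields[0] < yields[1] < yields[2]


class TestSizeSelect:
    def test_window_membership(self):
        params = DigestParams()
        frags = [
            Fragment("c", 0, 50, True, True),
            Fragment("c", 50, 550, True, True),
            Fragment("c", 550, 5550, True, True),
        ]
        kept = size_select(frags, params)
        assert [(f.start, f.end) for f in kept] == [(50, 550)]

    def test_empty_input(self):
        assert size_select([], DigestParams()) == []

    def test_terminal_fragments_excluded(self):
        frags = [
            Fragment("c", 0, 102, False, True),
            Fragment("c", 102, 595, True, True),
            Fragment("c", 595, 1000, True, False),
        ]
        kept = size_select(frags, DigestParams())
        assert [(f.start, f.end) for f in kept] == [(102, 595)]


class TestFragmentsToTrack:
    def test_single_fragment(self, tiny_genome):
        t = fragments_to_track([Fragment("chr1", 0, 100, True, True)], tiny_genome)
        assert t.intervals["chr1"] == [(0, 100, 1.0)]

    def test_overlap_pileup(self, tiny_genome):
        frags = [Fragment("chr1", 0, 100, True, True), Fragment("chr1", 50, 150, True, True)]
        t = fragments_to_track(frags, tiny_genome)
        assert t.intervals["chr1"] == [(0, 50, 1.0), (50, 100, 2.0), (100, 150, 1.0)]

    def test_empty(self, tiny_genome):
        assert fragments_to_track([], tiny_genome).total_mass() == 0

    def test_out_of_bounds_error(self, tiny_genome):
        with pytest.raises(FragmentBoundsError):
            fragments_to_track([Fragment("chr1", 0, 50_000, True, True)], tiny_genome)


class TestSimulateSample:
    def test_bit_reproducible(self, tiny_genome, tiny_origins):
        sched = scenarios.timing_course_schedule(5.0)
        params = DigestParams(p_nick=0.05, rng_seed=0)
        a = simulate_sample(tiny_genome, tiny_origins, sched, 10, params, rng_seed=9, mito_copies=3)
        b = simulate_sample(tiny_genome, tiny_origins, sched, 10, params, rng_seed=9, mito_copies=3)
        assert a[1] == b[1]
        assert a[0].intervals == b[0].intervals

    def test_mito_signal_present(self, tiny_genome, tiny_origins):
        sched = scenarios.timing_course_schedule(0.0)
        track, _ = simulate_sample(
            tiny_genome, tiny_origins, sched, 10,
            DigestParams(p_nick=0.05), rng_seed=1, mito_copies=5,
        )
        assert track.mass_on("chrM") > 0
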