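import copy

import numpy as np
import pytest

from kmerprimer import (PrimerCandidate, SpeciesSequenceSet,
                        SpecificityConfig, exact_match_screen,
                        local_align_screen, revcomp, screen_candidates)
from kmerprimer.specificity import ScreenIndex, _screen_one_by_one
from conftest import make_universe, random_seq
from oracles import longest_common_exact, max_alignment_length


def plant(universe, sp_idx, contig_idx, offset, block):
    cid, seq = universe[sp_idx].contigs[contig_idx]
    universe[sp_idx].contigs[contig_idx] = (
        cid, seq[:offset] + block + seq[offset + len(block):])


def planted_candidate(rng, universe, sp_idx=0, offset=50):
    """Plant a random 30-mer in one species and return its candidate."""
    marker = random_seq(rng, 30)
    plant(universe, sp_idx, 0, offset, marker)
    cid = universe[sp_idx].contigs[0][0]
    return PrimerCandidate(marker, universe[sp_idx].species_id, cid, offset)


class TestExactStage:
    def test_unique_candidate_survives(self, rng):
        universe = make_universe(rng)
        cand = planted_candidate(rng, universe)
        rep = exact_match_screen(cand, universe)
        assert rep.removal_reason is None

    def test_26_base_block_in_other_species_removes(self, rng):
        universe = make_universe(rng)
        cand = planted_candidate(rng, universe)
        plant(universe, 1, 0, 200, cand.sequence[:26])
        rep = exact_match_screen(cand, universe)
        assert rep.removal_reason == "OTHER_EXACT"
        # oracle: the longest exact shared substring really is >= 26
        other = universe[1].contigs[0][1]
        assert longest_common_exact(cand.sequence, other) >= 26

    def test_25_base_block_survives_exact_stage(self, rng):
        universe = make_universe(rng)
        cand = planted_candidate(rng, universe)
        block = cand.sequence[:25]
        plant(universe, 1, 0, 200, block)
        # force mismatching flanks so the shared run cannot extend by chance
        other = universe[1].contigs[0][1]
        nxt = cand.sequence[25]
        repl = "A" if nxt != "A" else "C"
        plant(universe, 1, 0, 225, repl)
        other = universe[1].contigs[0][1]
        assert longest_common_exact(cand.sequence, other) == 25
        rep = exact_match_screen(cand, universe)
        assert rep.removal_reason is None

    def test_second_full_length_copy_is_multimap(self, rng):
        universe = make_universe(rng)
        cand = planted_candidate(rng, universe)
        plant(universe, 0, 1, 100, cand.sequence)
        rep = exact_match_screen(cand, universe)
        assert rep.removal_reason == "SAME_MULTIMAP"

    def test_reverse_complement_copy_counts_as_multimap(self, rng):
        universe = make_universe(rng)
        cand = planted_candidate(rng, universe)
        plant(universe, 0, 1, 100, revcomp(cand.sequence))
        rep = exact_match_screen(cand, universe)
        assert rep.removal_reason == "SAME_MULTIMAP"
        cfg = SpecificityConfig(both_strands=False)
        rep2 = exact_match_screen(cand, ScreenIndex(universe, cfg))
        assert rep2.removal_reason is None


class TestLocalStage:
    def test_26_base_one_mismatch_in_other_species_removes(self, rng):
        universe = make_universe(rng)
        cand = planted_candidate(rng, universe)
        block = list(cand.sequence[:26])
        old = block[13]
        block[13] = {"A": "C", "C": "G", "G": "T", "T": "A"}[old]
        plant(universe, 1, 0, 200, "".join(block))
        repl = "A" if cand.sequence[26] != "A" else "C"
        plant(universe, 1, 0, 226, repl)  # block flank must not extend
        assert exact_match_screen(cand, universe).removal_reason is None
        rep = local_align_screen(cand, universe)
        assert rep.removal_reason == "OTHER_LOCAL"
        # oracle: optimal ungapped alignment against that contig spans 26
        other = universe[1].contigs[0][1]
        assert max_alignment_length(cand.sequence, other) == 26

    def test_second_same_species_24mer_triggers_same_extra(self, rng):
        universe = make_universe(rng)
        cand = planted_candidate(rng, universe)
        plant(universe, 0, 1, 120, cand.sequence[:24])
        own1 = universe[0].contigs[1][1]
        # avoid chance extension past 24
        repl = "A" if cand.sequence[24] != "A" else "C"
        plant(universe, 0, 1, 144, repl)
        own1 = universe[0].contigs[1][1]
        assert max_alignment_length(cand.sequence, own1) == 24
        rep = local_align_screen(cand, universe)
        assert rep.removal_reason == "SAME_EXTRA"

    def test_clean_candidate_reports_only_its_source(self, rng):
        universe = make_universe(rng)
        cand = planted_candidate(rng, universe)
        rep = local_align_screen(cand, universe)
        assert rep.removal_reason is None
        full = [h for h in rep.hits if h.match_len == 30
                and h.species_id == cand.species_id]
        assert len(full) == 1
        assert (full[0].contig_id, full[0].start) == (cand.contig_id, 50)

    def test_minus_strand_hit_detected(self, rng):
        universe = make_universe(rng)
        cand = planted_candidate(rng, universe)
        plant(universe, 1, 0, 200, revcomp(cand.sequence[:26]))
        rep = exact_match_screen(cand, universe)
        assert rep.removal_reason == "OTHER_EXACT"
        assert rep.hits[0].strand == "-"


class TestScreenCandidates:
    def test_empty_input(self, rng):
        universe = make_universe(rng)
        assert screen_candidates([], universe) == ([], [])

    @pytest.mark.parametrize("length,expected", [
        (24, None), (25, None), (26, "OTHER_EXACT"), (30, "OTHER_EXACT"),
    ])
    def test_boundary_block_lengths(self, rng, length, expected):
        universe = make_universe(rng)
        cand = planted_candidate(rng, universe)
        block = cand.sequence[:length]
        plant(universe, 1, 0, 200, block)
        if length < 30:
            repl = "A" if cand.sequence[length] != "A" else "C"
            plant(universe, 1, 0, 200 + length, repl)
        other = universe[1].contigs[0][1]
        assert longest_common_exact(cand.sequence, other) == length
        assert max_alignment_length(cand.sequence, other) == length
        survivors, reports = screen_candidates([cand], universe)
        if expected is None:
            assert survivors == [cand]
        else:
            assert survivors == [] and cand.removal_reason == expected

    def test_batch_equals_per_candidate_path(self, rng):
        """The vectorised batch screen and the reference per-candidate
        screen must agree hit-for-hit on a mixed fixture."""
        universe = make_universe(rng, n_species=3, n_contigs=2, length=500)
        cands = []
        c1 = planted_candidate(rng, universe, 0, 40)
        plant(universe, 1, 1, 100, c1.sequence[:26])
        cands.append(c1)
        c2 = planted_candidate(rng, universe, 1, 200)
        cands.append(c2)
        c3 = planted_candidate(rng, universe, 2, 300)
        plant(universe, 2, 1, 60, c3.sequence)  # multimap
        cands.append(c3)
        # plus every unique filter-passing window of sp1's first contig
        from kmerprimer import KmerParams, count_kmers, unique_kmers
        tables = [count_kmers(s, KmerParams()) for s in universe]
        cands.extend(unique_kmers(tables, "sp1")[:200])
        index = ScreenIndex(universe)
        got_s, got_r = screen_candidates(
            [copy.deepcopy(c) for c in cands], index)
        ref_cands = sorted([copy.deepcopy(c) for c in cands],
                           key=lambda c: (c.species_id, c.contig_id, c.offset))
        exp_s, exp_r = _screen_one_by_one(ref_cands, index)
        assert [c.id for c in got_s] == [c.id for c in exp_s]
        got_reasons = {r.candidate_id: r.removal_reason for r in got_r}
        exp_reasons = {r.candidate_id: r.removal_reason for r in exp_r}
        assert got_reasons == exp_reasons

    def test_invariant_under_contig_reverse_complement(self, rng):
        universe = make_universe(rng)
        cand = planted_candidate(rng, universe)
        plant(universe, 1, 0, 200, cand.sequence[:26])
        flipped = copy.deepcopy(universe)
        cid, seq = flipped[1].contigs[0]
        flipped[1].contigs[0] = (cid, revcomp(seq))
        r1 = screen_candidates([copy.deepcopy(cand)], universe)[0]
        r2 = screen_candidates([copy.deepcopy(cand)], flipped)[0]
        assert (r1 == []) == (r2 == [])

    def test_tightening_exact_threshold_shrinks_survivors(self, rng):
        universe = make_universe(rng)
        cand = planted_candidate(rng, universe)
        plant(universe, 1, 0, 200, cand.sequence[:24])
        loose = SpecificityConfig()
        tight = SpecificityConfig(exact_other_min=24)
        s_loose, _ = screen_candidates([copy.deepcopy(cand)],
                                       ScreenIndex(universe, loose), loose)
        s_tight, _ = screen_candidates([copy.deepcopy(cand)],
                                       ScreenIndex(universe, tight), tight)
        assert len(s_tight) <= len(s_loose)
        assert len(s_tight) == 0

    def test_survivors_subset_of_exact_stage(self, rng):
        universe = make_universe(rng, n_species=3, length=600)
        from kmerprimer import KmerParams, count_kmers, unique_kmers
        tables = [count_kmers(s, KmerParams()) for s in universe]
        cands = unique_kmers(tables, "sp1")[:300]
        index = ScreenIndex(universe)
        survivors, _ = screen_candidates(
            [copy.deepcopy(c) for c in cands], index)
        exact_ok = {c.id for c in cands
                    if exact_match_screen(c, index).removal_reason is None}
        assert {c.id for c in survivors} <= exact_ok
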