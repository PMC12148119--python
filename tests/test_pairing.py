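import numpy as np
import pytest

from kmerprimer import (Oligo, PairingConfig, PrimerCandidate, PrimerPair,
                        SpeciesSequenceSet, apply_filters, in_silico_pcr,
                        propose_partners, revcomp, validate_pair)
from conftest import random_seq

PASS30_A = "GCTGATTAGTTGTGCCGCAGCGAAGATGAC"  # composition-filter clean


def passing_30mer(rng):
    from kmerprimer import apply_filters
    while True:
        s = random_seq(rng, 30)
        if apply_filters(s).passed:
            return s


def simple_pair(fwd_seq, rev_seq, target="sp1", size=160):
    fwd = Oligo("F", fwd_seq, target, "c", 0, 0, "+")
    rev = Oligo("R", rev_seq, target, "c", 0, 0, "-")
    return PrimerPair(fwd, rev, target, size)


class TestInSilicoPcr:
    def build_template(self, rng, fwd, rev):
        """200-bp template: fwd at 10, revcomp(rev) occupying 150..169."""
        t = random_seq(rng, 200)
        t = t[:10] + fwd + t[10 + len(fwd):]
        site = revcomp(rev)
        t = t[:150] + site + t[150 + len(site):]
        return t

    def test_single_product_size_from_coordinates(self, rng):
        fwd, rev = random_seq(rng, 20), random_seq(rng, 20)
        t = self.build_template(rng, fwd, rev)
        universe = [SpeciesSequenceSet("sp1", [("c", t)])]
        preds = in_silico_pcr(simple_pair(fwd, rev), universe)
        assert len(preds) == 1
        assert preds[0].products == [("c", 10, 170, 160, 0, 0)]

    def test_three_prime_mismatch_abolishes_product(self, rng):
        fwd, rev = random_seq(rng, 20), random_seq(rng, 20)
        t = self.build_template(rng, fwd, rev)
        # mismatch at the forward primer's 3'-terminal base
        bad = fwd[:-1] + ("A" if fwd[-1] != "A" else "C")
        universe = [SpeciesSequenceSet("sp1", [("c", t)])]
        preds = in_silico_pcr(simple_pair(bad, rev), universe)
        assert preds[0].products == []

    def test_internal_mismatches_tolerated_up_to_limit(self, rng):
        fwd, rev = random_seq(rng, 20), random_seq(rng, 20)
        t = self.build_template(rng, fwd, rev)
        universe = [SpeciesSequenceSet("sp1", [("c", t)])]
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        two = flip[fwd[2]].join([fwd[:2], fwd[3:]])
        two = flip[two[5]].join([two[:5], two[6:]])
        preds = in_silico_pcr(simple_pair(two, rev), universe)
        assert preds[0].products == [("c", 10, 170, 160, 2, 0)]
        three = flip[two[8]].join([two[:8], two[9:]])
        preds3 = in_silico_pcr(simple_pair(three, rev), universe)
        assert preds3[0].products == []

    def test_divergent_orientation_yields_nothing(self, rng):
        fwd, rev = random_seq(rng, 20), random_seq(rng, 20)
        t = random_seq(rng, 200)
        # both sites in forward orientation: primers point the same way
        t = t[:10] + fwd + t[30:]
        t = t[:150] + rev + t[170:]
        universe = [SpeciesSequenceSet("sp1", [("c", t)])]
        preds = in_silico_pcr(simple_pair(fwd, rev), universe)
        assert preds[0].products == []

    def test_symmetric_under_role_swap(self, rng):
        fwd, rev = random_seq(rng, 20), random_seq(rng, 20)
        t = self.build_template(rng, fwd, rev)
        universe = [SpeciesSequenceSet("sp1", [("c", t)])]
        a = in_silico_pcr(simple_pair(fwd, rev), universe)
        b = in_silico_pcr(simple_pair(rev, fwd), universe)
        assert [p.products for p in a] == [
            [(c, s, e, sz, rm, fm) for c, s, e, sz, fm, rm in p.products]
            for p in b]

    def test_oversized_products_suppressed(self, rng):
        fwd, rev = random_seq(rng, 20), random_seq(rng, 20)
        t = self.build_template(rng, fwd, rev)
        universe = [SpeciesSequenceSet("sp1", [("c", t)])]
        cfg = PairingConfig(product_max=150)
        preds = in_silico_pcr(simple_pair(fwd, rev), universe, cfg)
        assert preds[0].products == []

    def test_empty_primer_rejected(self, rng):
        universe = [SpeciesSequenceSet("sp1", [("c", random_seq(rng, 50))])]
        with pytest.raises(ValueError):
            in_silico_pcr(simple_pair("", "ACGT" * 5), universe)


class TestValidatePair:
    def test_verdicts(self, rng):
        fwd, rev = random_seq(rng, 20), random_seq(rng, 20)
        t = random_seq(rng, 200)
        t = t[:10] + fwd + t[30:]
        t = t[:150] + revcomp(rev) + t[170:]
        target = SpeciesSequenceSet("sp1", [("c", t)])
        clean = SpeciesSequenceSet("sp2", [("c", random_seq(rng, 200))])
        assert validate_pair(simple_pair(fwd, rev), [target, clean])[0] \
            == "SPECIFIC"
        # conserved template in a second species -> NONSPECIFIC
        twin = SpeciesSequenceSet("sp3", [("c", t)])
        assert validate_pair(simple_pair(fwd, rev),
                             [target, twin])[0] == "NONSPECIFIC"
        assert validate_pair(simple_pair(fwd, rev), [clean])[0] \
            == "NO_AMPLIFICATION"


class TestProposePartners:
    def make_universe(self, rng, candidate_seq, partner_block,
                      cand_at=100, partner_at=500, length=1000):
        """Homopolymer sea with a planted candidate and one clean partner
        site; every other window fails the composition filter."""
        sea = "A" * length
        ctx = sea[:cand_at] + candidate_seq \
            + sea[cand_at + 30:partner_at] + partner_block \
            + sea[partner_at + len(partner_block):]
        sp1 = SpeciesSequenceSet("sp1", [("c1", ctx)])
        sp2 = SpeciesSequenceSet("sp2", [("c2", random_seq(rng, 400))])
        return ctx, [sp1, sp2]

    def test_single_clean_site_gives_expected_product(self, rng):
        cand_seq = passing_30mer(rng)
        ctx, universe = self.make_universe(rng, cand_seq, PASS30_A)
        cand = PrimerCandidate(cand_seq, "sp1", "c1", 100)
        pairs = propose_partners(cand, ctx, universe)
        assert pairs, "expected at least one proposal"
        for p in pairs:
            assert p.forward.sequence == cand_seq
            assert 400 <= p.expected_product <= 460
            # coordinate arithmetic: product spans fwd start..rev end
            assert p.expected_product == p.reverse.end - p.forward.start
            assert validate_pair(p, universe)[0] == "SPECIFIC"

    def test_all_windows_dirty_yields_empty(self, rng):
        cand_seq = passing_30mer(rng)
        sea = "A" * 1000
        ctx = sea[:100] + cand_seq + sea[130:]
        universe = [SpeciesSequenceSet("sp1", [("c1", ctx)]),
                    SpeciesSequenceSet("sp2", [("c2", random_seq(rng, 400))])]
        cand = PrimerCandidate(cand_seq, "sp1", "c1", 100)
        assert propose_partners(cand, ctx, universe) == []

    def test_candidate_near_three_prime_end_pairs_upstream(self, rng):
        cand_seq = passing_30mer(rng)
        sea = "A" * 300
        ctx = sea[:40] + PASS30_A + sea[70:250] + cand_seq + sea[280:]
        universe = [SpeciesSequenceSet("sp1", [("c1", ctx)]),
                    SpeciesSequenceSet("sp2", [("c2", random_seq(rng, 400))])]
        cand = PrimerCandidate(cand_seq, "sp1", "c1", 250)
        pairs = propose_partners(cand, ctx, universe)
        assert pairs
        for p in pairs:
            # candidate is the reverse primer; partner sits upstream
            assert p.reverse.sequence == revcomp(cand_seq)
            assert p.forward.start < 250
            assert p.expected_product == 280 - p.forward.start

    def test_context_shorter_than_product_min_is_empty(self, rng):
        cand_seq = passing_30mer(rng)
        ctx = cand_seq + "A" * 30
        universe = [SpeciesSequenceSet("sp1", [("c1", ctx)])]
        cand = PrimerCandidate(cand_seq, "sp1", "c1", 0)
        assert propose_partners(cand, ctx, universe) == []

    def test_candidate_must_map_to_context(self, rng):
        cand = PrimerCandidate(passing_30mer(rng), "sp1", "c1", 0)
        with pytest.raises(ValueError):
            propose_partners(cand, random_seq(rng, 500),
                             [SpeciesSequenceSet("sp1", [("c1", "A" * 500)])])
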