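"""Duplex alignment, seed scanning and target prediction."""

import numpy as np
import pytest

from ago2seed.errors import SequenceError
from ago2seed.sequences import MiRNASeq, UTRSeq, reverse_complement
from ago2seed.targets import (DEFAULT_PARAMS, ScoringParams, align_duplex,
                              predict_targets, seed_match_scan)
from oracles import best_local_duplex_score

RNG = np.random.default_rng(99)
BASES = np.array(list("ACGU"))


def random_rna(length, rng=RNG):
    return "".join(rng.choice(BASES, length))


def embed(utr_background: str, site: str, offset: int) -> str:
    return utr_background[:offset] + site + utr_background[offset + len(site):]


class TestSequenceTypes:
    def test_dna_is_canonicalized_to_rna(self):
        u = UTRSeq("g", "ACGTacgt")
        assert u.sequence == "ACGUACGU"

    def test_non_canonical_characters_rejected(self):
        with pytest.raises(SequenceError):
            MiRNASeq("m", "ACGUNACGUACGUACGUACGU")

    def test_mirna_length_bounds(self):
        with pytest.raises(SequenceError):
            MiRNASeq("m", "ACGU")

    def test_seed_is_positions_2_to_8(self):
        m = MiRNASeq("m", "UAGCAGCACGUAAAUAUUGGCG")  # miR-15a-like
        assert m.seed == "AGCAGCA"


class TestAlignDuplex:
    def test_perfect_duplex_scores_maximal(self):
        mirna = MiRNASeq("m", random_rna(22, np.random.default_rng(1)))
        site = reverse_complement(mirna.sequence)
        utr = UTRSeq("g", embed(random_rna(200, np.random.default_rng(2)), site, 90))
        sites = align_duplex(mirna, utr)
        assert sites
        best = sites[0]
        # all 22 positions Watson-Crick: 15 at x5 plus 7 seed at x10
        assert best.score >= 15 * 5 + 7 * 10
        assert best.seed_matched
        assert best.trace.count("|") >= 22

    def test_unpairable_sequences_give_no_sites(self):
        mirna = MiRNASeq("m", "A" * 22)
        utr = UTRSeq("g", "A" * 200)
        assert align_duplex(mirna, utr, ScoringParams(min_score=1)) == []

    def test_matches_exhaustive_dp_on_random_instances(self):
        rng = np.random.default_rng(5)
        params = ScoringParams(min_score=1e9)  # only compare best score
        for _ in range(50):
            mirna = MiRNASeq("m", random_rna(int(rng.integers(18, 27)), rng))
            utr = UTRSeq("g", random_rna(int(rng.integers(50, 301)), rng))
            oracle = best_local_duplex_score(mirna.sequence, utr.sequence)
            low = ScoringParams(min_score=0.5)
            sites = align_duplex(mirna, utr, low)
            got = sites[0].score if sites else 0.0
            assert got == pytest.approx(oracle, abs=1e-9)

    def test_score_equals_rescored_trace(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            mirna = MiRNASeq("m", random_rna(22, rng))
            utr = UTRSeq("g", random_rna(300, rng))
            for site in align_duplex(mirna, utr, ScoringParams(min_score=20)):
                assert site.rescore(DEFAULT_PARAMS, 22) == pytest.approx(site.score)

    def test_sites_are_non_overlapping_and_best_first(self):
        mirna = MiRNASeq("m", random_rna(22, np.random.default_rng(7)))
        site = reverse_complement(mirna.sequence)
        bg = random_rna(400, np.random.default_rng(8))
        utr = UTRSeq("g", embed(embed(bg, site, 50), site, 300))
        sites = align_duplex(mirna, utr)
        assert len(sites) >= 2
        scores = [s.score for s in sites]
        assert scores == sorted(scores, reverse=True)
        intervals = sorted((s.utr_start, s.utr_end) for s in sites)
        for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
            assert b1 <= a2

    def test_reversal_symmetry_with_mirrored_seed_weights(self):
        # reversing both sequences and mirroring the seed interval must give
        # the same best score (the DP has no directional bias)
        rng = np.random.default_rng(9)
        for _ in range(10):
            L = 22
            mirna = MiRNASeq("m", random_rna(L, rng))
            utr = UTRSeq("g", random_rna(150, rng))
            fwd = align_duplex(mirna, utr, ScoringParams(min_score=0.5))
            mirrored = ScoringParams(min_score=0.5, seed_start=L - 8 + 1,
                                     seed_end=L - 2 + 1)
            rev = align_duplex(MiRNASeq("m", mirna.sequence[::-1]),
                               UTRSeq("g", utr.sequence[::-1]), mirrored)
            f = fwd[0].score if fwd else 0.0
            r = rev[0].score if rev else 0.0
            assert f == pytest.approx(r)

    def test_flanking_background_never_lowers_best_score(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            mirna = MiRNASeq("m", random_rna(22, rng))
            core = random_rna(80, rng)
            padded = random_rna(40, rng) + core + random_rna(40, rng)
            p = ScoringParams(min_score=0.5)
            s_core = align_duplex(mirna, UTRSeq("g", core), p)
            s_pad = align_duplex(mirna, UTRSeq("g", padded), p)
            best_core = s_core[0].score if s_core else 0.0
            best_pad = s_pad[0].score if s_pad else 0.0
            assert best_pad >= best_core - 1e-9


class TestSeedScan:
    def test_planted_site_found_at_offset(self):
        mirna = MiRNASeq("m", "UAGCAGCACGUAAAUAUUGGCG")
        site = reverse_complement(mirna.seed)
        utr = UTRSeq("g", embed("A" * 100, site, 40))
        hits = seed_match_scan(mirna, utr)
        assert (40, "7mer") in hits

    def test_let7_family_seed_complement(self):
        # let-7 seed GAGGUAG pairs the UTR site CUACCUC
        mirna = MiRNASeq("let7", "UGAGGUAGUAGGUUGUAUAGUU")
        assert mirna.seed == "GAGGUAG"
        utr = UTRSeq("g", embed("G" * 60, "CUACCUC", 20))
        assert (20, "7mer") in seed_match_scan(mirna, utr)

    def test_7mer_a1_variant_detected(self):
        mirna = MiRNASeq("m", "UAGCAGCACGUAAAUAUUGGCG")
        site7 = reverse_complement(mirna.seed)
        variant = site7[1:] + "A"
        assert variant != site7  # guard against degenerate seeds
        utr = UTRSeq("g", embed("G" * 60, variant, 11))
        assert (11, "7mer-A1") in seed_match_scan(mirna, utr)

    def test_expected_hit_count_on_random_utrs(self):
        rng = np.random.default_rng(11)
        mirna = MiRNASeq("m", "UAGCAGCACGUAAAUAUUGGCG")
        L, n = 300, 1500
        count = 0
        for _ in range(n):
            utr = UTRSeq("g", random_rna(L, rng))
            count += sum(1 for _, kind in seed_match_scan(mirna, utr)
                         if kind == "7mer")
        expected = n * (L - 6) / 4 ** 7
        assert abs(count - expected) < 4 * np.sqrt(expected)


class TestPredictTargets:
    def test_planted_targets_predicted_decoys_absent(self, small_study):
        predicted = predict_targets(small_study.mirnas, small_study.utrs)
        truth = small_study.ledger.target_pairs
        hits = sum(1 for m, g in truth if g in predicted.get(m, []))
        assert hits >= 0.9 * len(truth)
        # genes with no planted site and no chance seed hit never appear
        with_sites = {g for g, _, _ in small_study.ledger.planted_sites}
        for m, genes in predicted.items():
            mirna = next(x for x in small_study.mirnas if x.id == m)
            for g in set(genes) - with_sites:
                utr = next(u for u in small_study.utrs if u.gene_id == g)
                assert seed_match_scan(mirna, utr)

    def test_threshold_above_maximum_gives_empty_sets(self, small_study):
        params = ScoringParams(min_score=1e6)
        predicted = predict_targets(small_study.mirnas[:1], small_study.utrs[:20],
                                    params)
        assert all(not genes for genes in predicted.values())

    def test_specificity_on_background_panels(self):
        # background-only UTRs: chance calls must be rare at default threshold
        rng = np.random.default_rng(12)
        mirnas = [MiRNASeq(f"m{i}", random_rna(22, rng)) for i in range(3)]
        utrs = [UTRSeq(f"g{i}", random_rna(500, rng)) for i in range(100)]
        predicted = predict_targets(mirnas, utrs)
        for m, genes in predicted.items():
            assert len(genes) <= 10  # specificity >= 0.9 on 100 genes
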