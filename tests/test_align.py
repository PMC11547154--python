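"""Smith-Waterman alignment, site enumeration, seed classification."""

from functools import lru_cache

import numpy as np
import pytest
from Bio import Align

from lncmeth.align import (
    ScoringScheme,
    classify_seed,
    clean_seq,
    enumerate_sites,
    revcomp,
    smith_waterman,
)

SCHEME = ScoringScheme()
ALPHA = np.array(list("ACGT"))


def rand_seq(rng, lo, hi):
    return "".join(rng.choice(ALPHA, size=rng.integers(lo, hi + 1)))


def brute_force_local_score(a, b, scheme=SCHEME):
    """Exhaustive local alignment score: best global alignment over every
    substring pair, by direct recursion (independent of the DP)."""

    @lru_cache(maxsize=None)
    def nw(x, y):
        if not x:
            return scheme.gap * len(y)
        if not y:
            return scheme.gap * len(x)
        sub = scheme.match if x[-1] == y[-1] else scheme.mismatch
        return max(
            nw(x[:-1], y[:-1]) + sub,
            nw(x[:-1], y) + scheme.gap,
            nw(x, y[:-1]) + scheme.gap,
        )

    best = 0.0
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            for k in range(len(b)):
                for l in range(k + 1, len(b) + 1):
                    best = max(best, nw(a[i:j], b[k:l]))
    return best


def biopython_local_score(a, b, scheme=SCHEME):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = scheme.gap
    aligner.extend_gap_score = scheme.gap
    return aligner.score(a, b)


class TestSmithWaterman:
    def test_perfect_duplex_full_length(self):
        a = "ACGTTGCAGGTCAATC"
        aln = smith_waterman(a, revcomp(a), mode="complementarity")
        assert aln.score == 2.0 * len(a)
        assert aln.matches == len(a)
        assert (aln.a_start, aln.a_end) == (0, len(a))

    def test_self_pairing_impossible(self):
        aln = smith_waterman("AAAA", "AAAA", mode="complementarity")
        assert aln.empty

    def test_illegal_character_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            smith_waterman("ACXT", "ACGT")

    @pytest.mark.parametrize("seed", range(25))
    def test_score_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rand_seq(rng, 3, 12), rand_seq(rng, 3, 12)
        aln = smith_waterman(a, b)
        assert aln.score == pytest.approx(brute_force_local_score(a, b))

    def test_score_matches_independent_aligner_on_200_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            a, b = rand_seq(rng, 5, 30), rand_seq(rng, 5, 30)
            assert smith_waterman(a, b).score == pytest.approx(
                biopython_local_score(a, b)
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_strand_duality(self, seed):
        """Identity alignment against revcomp(b) equals complementarity
        alignment against b, site for site."""
        rng = np.random.default_rng(seed)
        a, b = rand_seq(rng, 10, 40), rand_seq(rng, 10, 40)
        comp = smith_waterman(a, b, mode="complementarity")
        ident = smith_waterman(a, revcomp(b), mode="identity")
        assert comp.score == ident.score
        assert (comp.a_start, comp.a_end) == (ident.a_start, ident.a_end)
        assert (comp.b_start, comp.b_end) == (
            len(b) - ident.b_end, len(b) - ident.b_start
        )

    def test_u_mapped_to_t(self):
        aln = smith_waterman("ACGU", "ACGT")
        assert aln.score == 8.0


class TestEnumerateSites:
    def plant(self, rng, guest_len=32, subject_len=1231, pos=300):
        guest = "".join(rng.choice(ALPHA, size=guest_len))
        subject = list("".join(rng.choice(ALPHA, size=subject_len)))
        subject[pos:pos + guest_len] = revcomp(guest)
        return guest, "".join(subject)

    def test_planted_32nt_duplex_count_and_proportion(self):
        rng = np.random.default_rng(5)
        guest, subject = self.plant(rng)
        scheme = ScoringScheme(min_site_score=40)
        rep = enumerate_sites(guest, subject, scheme)
        assert rep.total_matched == 32
        assert rep.proportion == pytest.approx(32 / 1231)
        assert round(rep.proportion, 3) == 0.026
        (site,) = rep.sites
        assert (site.b_start, site.b_end) == (300, 332)

    def test_two_disjoint_sites_are_additive(self):
        rng = np.random.default_rng(11)
        g1 = "".join(rng.choice(ALPHA, size=10))
        g2 = "".join(rng.choice(ALPHA, size=15))
        query = g1 + "TTTT" + g2
        subject = list("".join(rng.choice(ALPHA, size=400)))
        subject[50:65] = revcomp(g2)
        subject[200:210] = revcomp(g1)
        scheme = ScoringScheme(min_site_score=18, min_site_length=5)
        rep = enumerate_sites(query, "".join(subject), scheme)
        assert rep.total_matched == 25
        assert len(rep.sites) == 2

    def test_sites_never_overlap_and_masking_is_idempotent(self):
        rng = np.random.default_rng(13)
        seg = "".join(rng.choice(ALPHA, size=20))
        query = seg + seg  # duplicated segment forces overlapping candidates
        subject = "CCCC" + revcomp(seg) + "CCCC"
        rep = enumerate_sites(query, subject, ScoringScheme(min_site_score=20))
        for s1 in rep.sites:
            for s2 in rep.sites:
                if s1 is s2:
                    continue
                assert s1.a_end <= s2.a_start or s2.a_end <= s1.a_start
                assert s1.b_end <= s2.b_start or s2.b_end <= s1.b_start
        # mask accepted footprints: re-running finds nothing further
        masked_q = list(query)
        masked_s = list(subject)
        for s in rep.sites:
            masked_q[s.a_start:s.a_end] = "N" * (s.a_end - s.a_start)
            masked_s[s.b_start:s.b_end] = "N" * (s.b_end - s.b_start)
        rerun = enumerate_sites(
            "".join(masked_q), "".join(masked_s), ScoringScheme(min_site_score=20)
        )
        assert rerun.sites == ()

    def test_raising_min_score_never_increases_total(self):
        rng = np.random.default_rng(17)
        a = "".join(rng.choice(ALPHA, size=150))
        b = "".join(rng.choice(ALPHA, size=150))
        totals = [
            enumerate_sites(a, b, ScoringScheme(min_site_score=s)).total_matched
            for s in (12, 16, 20, 30)
        ]
        assert totals == sorted(totals, reverse=True)


MIRNA = "TGGAGTGTGACAATGGTGTTTG"  # 22 nt


def seed_target(site):
    rng = np.random.default_rng(1)
    left = "".join(rng.choice(ALPHA, size=30))
    right = "".join(rng.choice(ALPHA, size=30))
    return left + site + right, len(left)


class TestClassifySeed:
    def test_8mer_by_construction(self):
        site = revcomp(MIRNA[1:8]) + "A"
        target, off = seed_target(site)
        hits = [s for s in classify_seed(MIRNA, target) if s.position >= off - 1]
        assert any(s.site_type == "8mer" and s.position == off for s in hits)

    def test_7mer_m8(self):
        site = revcomp(MIRNA[1:8]) + "C"
        target, off = seed_target(site)
        assert any(
            s.site_type == "7mer-m8" and s.position == off
            for s in classify_seed(MIRNA, target)
        )

    def test_7mer_a1(self):
        site = "T" + revcomp(MIRNA[1:7]) + "A"  # pos 8 unpaired, A opposite 1
        target, off = seed_target(site)
        assert any(
            s.site_type == "7mer-A1" and s.position == off + 1
            for s in classify_seed(MIRNA, target)
        )

    def test_6mer_only(self):
        site = "T" + revcomp(MIRNA[1:7]) + "C"
        target, off = seed_target(site)
        assert any(
            s.site_type == "6mer" and s.position == off + 1
            for s in classify_seed(MIRNA, target)
        )

    def test_g_bulged_variant(self):
        core7 = revcomp(MIRNA[1:8])
        site = core7[:3] + "G" + core7[3:] + "C"
        target, off = seed_target(site)
        assert any(
            s.site_type == "7mer-m8 g-bulged" and s.position == off
            for s in classify_seed(MIRNA, target)
        )

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            classify_seed("ACGTACG", "ACGTACGTACGT")

    def test_stronger_type_shadows_weaker(self):
        site = revcomp(MIRNA[1:8]) + "A"  # an 8mer site
        target, off = seed_target(site)
        hits = classify_seed(MIRNA, target)
        spans = [(s.position, s.end, s.site_type) for s in hits
                 if off - 1 <= s.position <= off + 1]
        assert ("6mer" not in {t for _, _, t in spans})


def test_clean_seq_rejects_and_maps():
    assert clean_seq("acgu") == "ACGT"
    with pytest.raises(ValueError, match="position 1"):
        clean_seq("A!CG")
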