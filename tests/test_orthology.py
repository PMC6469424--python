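"""Tests for contig filtering, ORF finding, alignment scoring and RBH."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from neotx.orthology import (
    Contig,
    HitRecord,
    OrthologTriplet,
    dedupe_exact,
    filter_contigs,
    find_longest_orf,
    local_align_score,
    reciprocal_best_hits,
    three_way_orthologs,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")
AA = "ARNDCQEGHILKMFPSTWYV"


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_longest_orf(seq, both_strands=True):
    """Exhaustive scan over all ATG/stop pairs in all six frames."""
    stops = {"TAA", "TAG", "TGA"}
    candidates = []
    strands = [("+", seq.upper())]
    if both_strands:
        strands.append(("-", str(Seq(seq.upper()).reverse_complement())))
    for strand_rank, (strand, s) in enumerate(strands):
        for frame in range(3):
            codons = [(i, s[i:i + 3]) for i in range(frame, len(s) - 2, 3)]
            valid = [(i, c) for i, c in codons if "N" not in c]
            for ai, (a_pos, a_c) in enumerate(valid):
                if a_c != "ATG":
                    continue
                for b_pos, b_c in valid[ai:]:
                    if b_c in stops:
                        # nearest stop; but only valid if no stop between
                        between = [c for i, c in valid if a_pos < i < b_pos]
                        if not any(c in stops for c in between):
                            candidates.append(
                                (-(b_pos + 3 - a_pos), strand_rank, frame, a_pos, b_pos + 3, strand)
                            )
                        break
    if not candidates:
        return None
    best = min(candidates)
    return best[5], best[2], best[3], best[4]


def sw_oracle(a, b, gap_open=11.0, gap_extend=1.0):
    """Independent affine-gap Smith-Waterman DP (gap of length L costs
    open + extend * L)."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s)
            Ix[i, j] = max(
                M[i - 1, j] - gap_open - gap_extend,
                Ix[i - 1, j] - gap_extend,
                Iy[i - 1, j] - gap_open - gap_extend,
            )
            Iy[i, j] = max(
                M[i, j - 1] - gap_open - gap_extend,
                Iy[i, j - 1] - gap_extend,
                Ix[i, j - 1] - gap_open - gap_extend,
            )
            best = max(best, M[i, j])
    return best


def brute_force_best(hits, cutoff):
    best = {}
    for h in hits:
        if h.evalue > cutoff:
            continue
        key = (h.evalue, -h.score, h.subject_id)
        if h.query_id not in best or key < best[h.query_id][0]:
            best[h.query_id] = (key, h.subject_id)
    return {q: s for q, (_, s) in best.items()}


def brute_force_rbh(hits_ab, hits_ba, cutoff):
    fa = brute_force_best(hits_ab, cutoff)
    fb = brute_force_best(hits_ba, cutoff)
    return {(a, b) for a, b in fa.items() if fb.get(b) == a}


def random_hit_tables(rng, n_query=200, n_subject=150, density=3.0):
    hits = []
    for q in range(n_query):
        for s in rng.choice(n_subject, size=rng.poisson(density), replace=False):
            hits.append(
                HitRecord(
                    f"a{q}", f"b{s}",
                    score=float(np.round(rng.uniform(20, 400), 1)),
                    evalue=float(10 ** rng.uniform(-60, -5)),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# filter_contigs / dedupe_exact
# ---------------------------------------------------------------------------

class TestFilterContigs:
    def test_strict_length_boundary(self):
        short = Contig("a", "A" * 249)
        exact = Contig("b", "A" * 250)
        assert filter_contigs([short, exact]) == [exact]

    def test_empty_input(self):
        assert filter_contigs([]) == []

    def test_idempotent(self, rng):
        contigs = [
            Contig(f"c{i}", "".join(rng.choice(list("ACGT"), size=rng.integers(100, 500))))
            for i in range(50)
        ]
        once = filter_contigs(contigs)
        assert filter_contigs(once) == once


class TestDedupeExact:
    def test_identical_sequences_keep_lexicographic_id(self):
        out = dedupe_exact([Contig("b", "ACGTACGT"), Contig("a", "ACGTACGT")])
        assert [c.id for c in out] == ["a"]

    def test_substring_absorbed_by_superstring(self):
        out = dedupe_exact([Contig("sub", "GTAC"), Contig("full", "ACGTACGT")])
        assert [c.id for c in out] == ["full"]

    def test_random_distinct_sequences_match_quadratic_oracle(self, rng):
        contigs = [
            Contig(f"c{i:03d}", "".join(rng.choice(list("ACGT"), size=rng.integers(30, 80))))
            for i in range(100)
        ]
        got = {c.id for c in dedupe_exact(contigs)}
        # quadratic oracle: drop c if its sequence is a substring of a longer
        # (or equal, lower-id) retained sequence
        expect = set()
        ranked = sorted(contigs, key=lambda c: (-len(c.sequence), c.id))
        kept = []
        for c in ranked:
            if not any(c.sequence in k.sequence for k in kept):
                kept.append(c)
                expect.add(c.id)
        assert got == expect


# ---------------------------------------------------------------------------
# find_longest_orf
# ---------------------------------------------------------------------------

class TestFindLongestOrf:
    def test_hand_checkable_minimal_orf(self):
        rec = find_longest_orf(Contig("c", "ATGAAATAA"))
        assert (rec.strand, rec.frame, rec.start, rec.end) == ("+", 0, 0, 9)
        assert rec.aa_length == 2
        assert rec.peptide == "MK"

    def test_no_start_codon_returns_none(self):
        assert find_longest_orf(Contig("c", "CCCCCC")) is None

    def test_n_invalidates_start_and_stop(self):
        # ATN is not a start; TNA is not a stop
        assert find_longest_orf(Contig("c", "ATNAAATAA"), both_strands=False) is None

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04],
                                     size=2000))
            rec = find_longest_orf(Contig("c", seq))
            expect = brute_force_longest_orf(seq)
            if expect is None:
                assert rec is None
            else:
                assert (rec.strand, rec.frame, rec.start, rec.end) == expect
                assert (rec.end - rec.start) % 3 == 0

    def test_plus_strand_only_flag(self, rng):
        seq = str(Seq("ATGAAACCCGGGTAA").reverse_complement())
        assert find_longest_orf(Contig("c", seq), both_strands=False) is None
        rec = find_longest_orf(Contig("c", seq), both_strands=True)
        assert rec.strand == "-"


# ---------------------------------------------------------------------------
# local_align_score
# ---------------------------------------------------------------------------

class TestLocalAlignScore:
    def test_self_alignment_is_diagonal_sum(self):
        pep = "MKWVTFISLLLF"
        score, proxy = local_align_score(pep, pep)
        assert score == sum(BLOSUM62[c, c] for c in pep)
        assert proxy == pytest.approx(np.exp(-score))

    def test_dissimilar_peptides_floor_at_zero(self):
        score, proxy = local_align_score("WWWW", "GGGG")
        assert score == 0.0
        assert proxy == 1.0

    def test_evalue_proxy_monotone_decreasing(self):
        s1, e1 = local_align_score("MKWVTFISLL", "MKWVTFISLL")
        s2, e2 = local_align_score("MKWVTFISLL", "MKWV")
        assert s1 > s2
        assert e1 < e2

    def test_unknown_residue_uses_neutral_score(self):
        score, _ = local_align_score("MKJM", "MKJM", unknown_residue_score=0.0)
        # J maps to X scored 0: diagonal sum skips it
        assert score == BLOSUM62["M", "M"] * 2 + BLOSUM62["K", "K"]

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        for k in range(50):
            a = "".join(rng.choice(list(AA), size=rng.integers(8, 35)))
            b = "".join(rng.choice(list(AA), size=rng.integers(8, 35)))
            if k % 3 == 0:  # include related pairs with indels
                b = a[: len(a) // 2] + b[:6] + a[len(a) // 2 :]
            score, _ = local_align_score(a, b)
            assert score == sw_oracle(a, b)


# ---------------------------------------------------------------------------
# reciprocal_best_hits / three_way_orthologs
# ---------------------------------------------------------------------------

class TestReciprocalBestHits:
    def test_mutual_best_pair_kept(self):
        ab = [HitRecord("a", "b", 100, 1e-30)]
        ba = [HitRecord("b", "a", 100, 1e-30)]
        assert reciprocal_best_hits(ab, ba) == [("a", "b")]

    def test_non_reciprocal_excluded(self):
        ab = [HitRecord("a", "b", 100, 1e-30)]
        ba = [HitRecord("b", "a2", 200, 1e-40), HitRecord("b", "a", 100, 1e-30)]
        assert reciprocal_best_hits(ab, ba) == []

    def test_evalue_cutoff_applied_both_directions(self):
        ab = [HitRecord("a", "b", 100, 1e-30)]
        ba = [HitRecord("b", "a", 100, 1e-10)]
        assert reciprocal_best_hits(ab, ba, evalue_cutoff=1e-20) == []

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(5):
            ab = random_hit_tables(rng)
            ba = random_hit_tables(rng, n_query=150, n_subject=200)
            ba = [HitRecord(h.query_id.replace("a", "b"),
                            h.subject_id.replace("b", "a"), h.score, h.evalue)
                  for h in ba]
            got = set(reciprocal_best_hits(ab, ba, 1e-10))
            assert got == brute_force_rbh(ab, ba, 1e-10)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        ab = random_hit_tables(rng, n_query=30, n_subject=25)
        ba = [HitRecord(f"b{i}", f"a{j}", float(np.round(rng.uniform(20, 400), 1)),
                        float(10 ** rng.uniform(-60, -5)))
              for i in range(25) for j in rng.choice(30, rng.poisson(2), replace=False)]
        fwd = set(reciprocal_best_hits(ab, ba))
        rev = {(a, b) for b, a in reciprocal_best_hits(ba, ab)}
        assert fwd == rev

    def test_no_id_occurs_twice(self, rng):
        ab = random_hit_tables(rng)
        ba = [HitRecord(h.subject_id, h.query_id, h.score, h.evalue) for h in ab]
        pairs = reciprocal_best_hits(ab, ba, 1e-10)
        lefts = [a for a, _ in pairs]
        rights = [b for _, b in pairs]
        assert len(lefts) == len(set(lefts))
        assert len(rights) == len(set(rights))


class TestThreeWayOrthologs:
    def test_consistent_triangle(self):
        out = three_way_orthologs([("a", "b")], [("a", "c")], [("b", "c")])
        assert out == [OrthologTriplet("a", "b", "c")]

    def test_inconsistent_triangle_rejected(self):
        out = three_way_orthologs([("a", "b")], [("a", "c")], [("b", "c2")])
        assert out == []

    def test_matches_brute_force(self, rng):
        def rand_pairs(n):
            perm = rng.permutation(n)
            return [(f"x{i}", f"y{perm[i]}") for i in rng.choice(n, n // 2, replace=False)]

        r12 = [(f"a{i}", f"b{j}") for i, j in enumerate(rng.permutation(40))]
        r13 = [(f"a{i}", f"c{j}") for i, j in enumerate(rng.permutation(40)) if i % 3]
        r23 = [(f"b{i}", f"c{j}") for i, j in enumerate(rng.permutation(40)) if i % 2]
        got = {(t.id_species1, t.id_species2, t.id_species3)
               for t in three_way_orthologs(r12, r13, r23)}
        expect = {
            (a, b, c)
            for (a, b) in r12
            for (a2, c) in r13
            if a == a2 and (b, c) in set(r23)
        }
        assert got == expect
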