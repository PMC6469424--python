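"""Three-species ortholog matching.

The stage reduces per-species transcript sets to a table of matched ortholog
triplets:

1. length filtering (contigs shorter than 250 bp are discarded);
2. exact-duplicate / exact-substring removal, keeping the longest
   representative;
3. longest-ORF selection per contig over six reading frames;
4. all-vs-all peptide similarity (Smith-Waterman local alignment with affine
   gaps, via Biopython's PairwiseAligner) or externally supplied BLAST
   tabular hits;
5. reciprocal-best-hit (RBH) pairing per species pair at an e-value cutoff;
6. intersection of the three pairwise RBH sets into consistent triangles.

The in-repo aligner reports an ``evalue_proxy = exp(-score)``: a monotone
decreasing transform of the alignment score used only for thresholding.  It
is never a calibrated BLAST e-value; externally computed BLAST tabular hits
can be substituted wherever ``HitRecord`` lists are consumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "Contig",
    "OrfRecord",
    "HitRecord",
    "OrthologTriplet",
    "filter_contigs",
    "dedupe_exact",
    "find_longest_orf",
    "local_align_score",
    "all_vs_all_hits",
    "reciprocal_best_hits",
    "three_way_orthologs",
    "orthologs_from_contigs",
]

_STOPS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class Contig:
    """A transcript contig: id plus nucleotide sequence over {A,C,G,T,N}."""

    id: str
    sequence: str


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame on a contig.

    Coordinates are 0-based half-open on the reported strand (for ``-`` they
    refer to the reverse-complemented sequence).  ``end`` includes the stop
    codon; ``aa_length`` excludes it.
    """

    contig_id: str
    strand: str  # '+' or '-'
    frame: int  # 0, 1, 2
    start: int
    end: int
    aa_length: int
    peptide: str


@dataclass(frozen=True)
class HitRecord:
    """One similarity hit (query vs subject) with a score and an e-value."""

    query_id: str
    subject_id: str
    score: float
    evalue: float


@dataclass(frozen=True)
class OrthologTriplet:
    id_species1: str
    id_species2: str
    id_species3: str


# ---------------------------------------------------------------------------
# Contig filtering
# ---------------------------------------------------------------------------

def filter_contigs(contigs: Sequence[Contig], min_length: int = 250) -> list[Contig]:
    """Drop contigs strictly shorter than ``min_length`` bases, keeping order."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    return [c for c in contigs if len(c.sequence) >= min_length]


def dedupe_exact(contigs: Sequence[Contig]) -> list[Contig]:
    """Remove exact duplicates and exact substrings of longer contigs.

    The longest representative survives; among equal sequences the
    lexicographically smallest id wins.  Output preserves input order.
    """
    # process longest first so every earlier-kept contig can absorb later ones
    order = sorted(contigs, key=lambda c: (-len(c.sequence), c.id))
    kept: list[Contig] = []
    kept_ids: set[str] = set()
    for cand in order:
        if any(cand.sequence in k.sequence for k in kept):
            continue
        kept.append(cand)
        kept_ids.add(cand.id)
    return [c for c in contigs if c.id in kept_ids]


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

def _frame_orfs(seq: str, frame: int) -> Iterable[tuple[int, int]]:
    """Yield (start, end) of ATG-initiated, stop-terminated ORFs in one frame.

    For each stop codon, the leftmost valid ATG after the previous in-frame
    stop is yielded (the longest ORF terminating at that stop).  A codon
    containing N is neither a valid start nor a valid stop.
    """
    n = len(seq)
    pending_start: int | None = None
    for pos in range(frame, n - 2, 3):
        codon = seq[pos : pos + 3]
        if "N" in codon:
            continue
        if codon in _STOPS:
            if pending_start is not None:
                yield pending_start, pos + 3
            pending_start = None
        elif codon == "ATG" and pending_start is None:
            pending_start = pos


def find_longest_orf(contig: Contig, both_strands: bool = True) -> OrfRecord | None:
    """Return the longest ATG..stop ORF over the searched frames, or None.

    Ties break by strand (``+`` before ``-``), then lower frame, then lower
    start.  Coordinates refer to the reported strand.
    """
    if not contig.sequence:
        raise ValueError("contig sequence must be non-empty")
    seq_fwd = contig.sequence.upper()
    strands = [("+", seq_fwd)]
    if both_strands:
        strands.append(("-", str(Seq(seq_fwd).reverse_complement())))

    best: tuple[int, int, int, int] | None = None  # (-len, strand_rank, frame, start)
    best_info: tuple[str, int, int, int, str] | None = None
    for strand_rank, (strand, seq) in enumerate(strands):
        for frame in range(3):
            for start, end in _frame_orfs(seq, frame):
                key = (-(end - start), strand_rank, frame, start)
                if best is None or key < best:
                    best = key
                    best_info = (strand, frame, start, end, seq)
    if best_info is None:
        return None
    strand, frame, start, end, seq = best_info
    peptide = str(Seq(seq[start : end - 3]).translate())
    return OrfRecord(
        contig_id=contig.id,
        strand=strand,
        frame=frame,
        start=start,
        end=end,
        aa_length=(end - start) // 3 - 1,
        peptide=peptide,
    )


# ---------------------------------------------------------------------------
# Peptide similarity
# ---------------------------------------------------------------------------

def _make_aligner(
    substitution_matrix: str | object = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    unknown_residue_score: float | None = None,
) -> PairwiseAligner:
    if isinstance(substitution_matrix, str):
        matrix = substitution_matrices.load(substitution_matrix)
    else:
        matrix = substitution_matrix
    if unknown_residue_score is not None and "X" in matrix.alphabet:
        matrix = matrix.copy()
        matrix[:, "X"] = unknown_residue_score
        matrix["X", :] = unknown_residue_score
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # a gap of length L costs gap_open + gap_extend * L (BLAST convention)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _sanitize(peptide: str, alphabet: str) -> str:
    return "".join(ch if ch in alphabet else "X" for ch in peptide.upper())


def local_align_score(
    peptide_a: str,
    peptide_b: str,
    substitution_matrix: str | object = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    unknown_residue_score: float | None = None,
) -> tuple[float, float]:
    """Smith-Waterman local alignment score and its e-value proxy.

    Residues absent from the matrix alphabet are mapped to ``X``; pass
    ``unknown_residue_score`` to overwrite the matrix's X row/column with a
    neutral value.  Returns ``(score, exp(-score))``; the proxy is monotone
    decreasing in score and used only for thresholding.
    """
    if not peptide_a or not peptide_b:
        raise ValueError("peptides must be non-empty")
    aligner = _make_aligner(
        substitution_matrix, gap_open, gap_extend, unknown_residue_score
    )
    alphabet = str(aligner.substitution_matrix.alphabet)
    score = float(
        aligner.score(_sanitize(peptide_a, alphabet), _sanitize(peptide_b, alphabet))
    )
    return score, math.exp(-score) if score < 700 else 0.0


def all_vs_all_hits(
    queries: dict[str, str],
    subjects: dict[str, str],
    substitution_matrix: str | object = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[HitRecord]:
    """Score every query peptide against every subject peptide.

    A hit is emitted for every pair with positive score; the caller's
    e-value cutoff does the thresholding.
    """
    aligner = _make_aligner(substitution_matrix, gap_open, gap_extend)
    alphabet = str(aligner.substitution_matrix.alphabet)
    q_clean = {k: _sanitize(v, alphabet) for k, v in queries.items()}
    s_clean = {k: _sanitize(v, alphabet) for k, v in subjects.items()}
    hits = []
    for qid, qseq in q_clean.items():
        for sid, sseq in s_clean.items():
            score = float(aligner.score(qseq, sseq))
            if score > 0:
                evalue = math.exp(-score) if score < 700 else 0.0
                hits.append(HitRecord(qid, sid, score, evalue))
    return hits


# ---------------------------------------------------------------------------
# Reciprocal best hits and triangles
# ---------------------------------------------------------------------------

def _best_hits(hits: Iterable[HitRecord], evalue_cutoff: float) -> dict[str, str]:
    """Best subject per query: lowest evalue, then highest score, then
    lexicographically smallest subject id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.evalue > evalue_cutoff:
            continue
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, -h.score, h.subject_id) < (
            cur.evalue,
            -cur.score,
            cur.subject_id,
        ):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def reciprocal_best_hits(
    hits_ab: Iterable[HitRecord],
    hits_ba: Iterable[HitRecord],
    evalue_cutoff: float = 1e-20,
) -> list[tuple[str, str]]:
    """Pairs (a, b) where b is a's best hit A->B and a is b's best hit B->A.

    Both directions must pass the e-value cutoff.  Best-hit ties resolve by
    lowest e-value, then highest score, then lexicographic subject id, making
    the output deterministic regardless of hit-table order.
    """
    best_ab = _best_hits(hits_ab, evalue_cutoff)
    best_ba = _best_hits(hits_ba, evalue_cutoff)
    pairs = [
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    ]
    return sorted(pairs)


def three_way_orthologs(
    rbh_12: Iterable[tuple[str, str]],
    rbh_13: Iterable[tuple[str, str]],
    rbh_23: Iterable[tuple[str, str]],
) -> list[OrthologTriplet]:
    """Consistent triangles: (a,b,c) with (a,b), (a,c) and (b,c) all RBH pairs.

    Because RBH pairs are one-to-one per species pair, every transcript id
    appears in at most one triplet.
    """
    map_12 = dict(rbh_12)
    map_13 = dict(rbh_13)
    set_23 = set(rbh_23)
    triplets = []
    for a in sorted(map_12):
        b = map_12[a]
        c = map_13.get(a)
        if c is not None and (b, c) in set_23:
            triplets.append(OrthologTriplet(a, b, c))
    return triplets


def orthologs_from_contigs(
    contigs_by_species: dict[str, Sequence[Contig]],
    min_length: int = 250,
    evalue_cutoff: float = 1e-20,
    both_strands: bool = True,
) -> tuple[list[OrthologTriplet], dict[str, dict[str, OrfRecord]]]:
    """Full orthology stage from raw contigs to matched triplets.

    Filters and dedupes each species' contigs, takes the longest ORF per
    contig, scores all peptide pairs between species, applies RBH per species
    pair and intersects the pairwise sets into triangles.  Species keys are
    used in sorted order as species 1..3.
    """
    if len(contigs_by_species) != 3:
        raise ValueError("exactly three species are required")
    species = sorted(contigs_by_species)
    peptides: dict[str, dict[str, str]] = {}
    orfs: dict[str, dict[str, OrfRecord]] = {}
    for sp in species:
        clean = dedupe_exact(filter_contigs(contigs_by_species[sp], min_length))
        orfs[sp] = {}
        peptides[sp] = {}
        for contig in clean:
            rec = find_longest_orf(contig, both_strands=both_strands)
            if rec is not None:
                orfs[sp][contig.id] = rec
                peptides[sp][contig.id] = rec.peptide

    def rbh(sp_a: str, sp_b: str) -> list[tuple[str, str]]:
        ab = all_vs_all_hits(peptides[sp_a], peptides[sp_b])
        ba = [HitRecord(h.subject_id, h.query_id, h.score, h.evalue) for h in ab]
        return reciprocal_best_hits(ab, ba, evalue_cutoff)

    s1, s2, s3 = species
    triplets = three_way_orthologs(rbh(s1, s2), rbh(s1, s3), rbh(s2, s3))
    return triplets, orfs
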