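"""Seeded local-alignment search with BLAST-like statistics.

The engine stands in for the blastp/blastn/read-mapping screens of the
pipeline: a query/subject pair is considered only if it shares an exact
seed word (11 nt in nucleotide mode, 4 residues in protein mode); a seeded
pair is then scored with an optimal affine-gap Smith-Waterman alignment.
Running the full optimal local alignment on seeded pairs (rather than a
banded extension) makes the engine agree exactly with an unseeded
Smith-Waterman whenever the optimal alignment contains a seed word.

Bit scores and e-values follow Karlin-Altschul statistics with fixed
(lambda, K) per scoring scheme:

    bit_score = (lambda * raw - ln K) / ln 2
    e_value   = K * m * n * exp(-lambda * raw)

with m the query length and n the total subject length searched.  Any
fixed, consistent pair preserves the ranking semantics used by the
pipeline's thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align

from .seqio import AnnotatedSequence, SeqKind, reverse_complement

NT_WORD_SIZE = 11
AA_WORD_SIZE = 4


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters plus Karlin-Altschul constants.

    Nucleotide defaults are the classic megablast-like +2/-3 with affine
    gap penalties 5/2 and (lambda, K) = (0.625, 0.41); protein mode uses a
    named substitution matrix (BLOSUM62) with its published gapped values.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    aa_matrix: str = "BLOSUM62"
    lam: float = 0.625
    K: float = 0.41

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are nonnegative magnitudes")

    @classmethod
    def nucleotide(cls) -> "ScoringScheme":
        return cls()

    @classmethod
    def protein(cls) -> "ScoringScheme":
        # BLOSUM62 gapped (11,1-equivalent) published constants
        return cls(aa_matrix="BLOSUM62", lam=0.267, K=0.041)

    def bit_score(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.K)) / math.log(2)

    def e_value(self, raw: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * raw)


@dataclass(frozen=True)
class HomologyHit:
    """One local-alignment match; coordinates are 0-based half-open.

    ``aligned_length`` counts alignment columns including gap columns;
    ``identity_pct`` = 100 * matches / aligned_length.  For minus-strand
    nucleotide hits the subject coordinates refer to the original
    (plus-strand) subject sequence.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    aligned_length: int
    identity_pct: float
    raw_score: int
    bit_score: float
    e_value: float
    strand: str = "+"

    def __post_init__(self):
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be positive")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct outside [0,100]")
        if self.q_end - self.q_start > self.aligned_length:
            raise ValueError("query span exceeds aligned length")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")


@lru_cache(maxsize=8)
def _aligner(mode: SeqKind, scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if mode is SeqKind.NT:
        aligner.match_score = scheme.match
        aligner.mismatch_score = scheme.mismatch
    else:
        aligner.substitution_matrix = Align.substitution_matrices.load(
            scheme.aa_matrix
        )
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


@lru_cache(maxsize=8192)
def _words(seq: str, k: int) -> frozenset[str]:
    """Exact seed words of a sequence (cached: references recur across searches)."""
    ambiguous = "N" if k == NT_WORD_SIZE else "X"
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if ambiguous not in w and "-" not in w:
            out.add(w)
    return frozenset(out)


def _align_pair(
    query: str,
    subject: str,
    mode: SeqKind,
    scheme: ScoringScheme,
    m: int,
    total_n: int,
    evalue_cutoff: float,
):
    """Return (raw, evalue, alignment) for the best local alignment, or None."""
    aligner = _aligner(mode, scheme)
    score = aligner.score(query, subject)
    raw = int(round(score))
    if raw <= 0:
        return None
    evalue = scheme.e_value(raw, m, total_n)
    if evalue > evalue_cutoff:
        return None
    alignment = aligner.align(query, subject)[0]
    return raw, evalue, alignment


def _hit_from_alignment(
    query_id: str,
    subject_id: str,
    alignment,
    raw: int,
    evalue: float,
    scheme: ScoringScheme,
    strand: str,
    subject_len: int,
) -> HomologyHit:
    counts = alignment.counts()
    aligned_length = counts.gaps + counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / aligned_length
    q_blocks, s_blocks = alignment.aligned[0], alignment.aligned[1]
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    s_start, s_end = int(s_blocks[0][0]), int(s_blocks[-1][1])
    if strand == "-":
        # alignment was computed against the reverse complement; report
        # coordinates on the original subject
        s_start, s_end = subject_len - s_end, subject_len - s_start
    return HomologyHit(
        query_id=query_id,
        subject_id=subject_id,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        aligned_length=int(aligned_length),
        identity_pct=identity,
        raw_score=raw,
        bit_score=scheme.bit_score(raw),
        e_value=evalue,
        strand=strand,
    )


def search(
    query: AnnotatedSequence,
    subjects: Sequence[AnnotatedSequence],
    mode: SeqKind | str,
    evalue_cutoff: float = 10.0,
    scheme: ScoringScheme | None = None,
) -> list[HomologyHit]:
    """Search a query against subjects; NT mode searches both strands.

    Only pairs sharing an exact seed word are aligned.  Every returned hit
    has ``e_value <= evalue_cutoff``.
    """
    mode = SeqKind(mode)
    if scheme is None:
        scheme = ScoringScheme.nucleotide() if mode is SeqKind.NT else ScoringScheme.protein()
    if query.kind is not mode or any(s.kind is not mode for s in subjects):
        raise ValueError("query and subjects must all match the search mode")
    if not subjects:
        return []

    k = NT_WORD_SIZE if mode is SeqKind.NT else AA_WORD_SIZE
    q_seq = query.ungapped
    q_words = _words(q_seq, k)
    m = len(q_seq)
    total_n = sum(len(s.ungapped) for s in subjects)

    hits: list[HomologyHit] = []
    for subject in subjects:
        s_seq = subject.ungapped
        s_words = _words(s_seq, k)
        if q_words & s_words:
            result = _align_pair(q_seq, s_seq, mode, scheme, m, total_n, evalue_cutoff)
            if result is not None:
                raw, ev, aln = result
                hits.append(
                    _hit_from_alignment(
                        query.id, subject.id, aln, raw, ev, scheme, "+", len(s_seq)
                    )
                )
        if mode is SeqKind.NT:
            rc = reverse_complement(s_seq)
            if q_words & _words(rc, k):
                result = _align_pair(q_seq, rc, mode, scheme, m, total_n, evalue_cutoff)
                if result is not None:
                    raw, ev, aln = result
                    hits.append(
                        _hit_from_alignment(
                            query.id, subject.id, aln, raw, ev, scheme, "-", len(s_seq)
                        )
                    )
    hits.sort(key=_hit_order_key)
    return hits


def _hit_order_key(hit: HomologyHit):
    return (-hit.bit_score, hit.e_value, -hit.identity_pct, hit.subject_id)


def best_hit(hits: Sequence[HomologyHit]) -> HomologyHit | None:
    """Best hit under (bit score desc, e-value asc, identity desc, subject id).

    All hits must share one query; returns None for empty input.
    """
    if not hits:
        return None
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits from multiple queries: {sorted(queries)}")
    return min(hits, key=_hit_order_key)


def passes_similarity_filter(
    hit: HomologyHit, min_identity_pct: float, min_length: int
) -> bool:
    """Inclusive thresholds on percent identity and aligned length."""
    return hit.identity_pct >= min_identity_pct and hit.aligned_length >= min_length


def write_hits_tsv(hits: Iterable[HomologyHit], path):
    """Tabular hits mirroring 12-column BLAST outfmt-6 ordering.

    Coordinates are 0-based half-open (noted in the header comment).
    Mismatch/gap-open columns are derived from the alignment summary.
    """
    with open(path, "w") as fh:
        fh.write(
            "# qid\tsid\tpident\tlength\tmismatches\tgapopens\tqstart\tqend"
            "\tsstart\tsend\tevalue\tbitscore  (coords 0-based half-open)\n"
        )
        for h in hits:
            matches = round(h.identity_pct * h.aligned_length / 100.0)
            q_cov = h.q_end - h.q_start
            s_cov = abs(h.s_end - h.s_start)
            gaps = 2 * h.aligned_length - q_cov - s_cov - h.aligned_length
            mism = h.aligned_length - matches - max(gaps, 0)
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity_pct:.2f}\t"
                f"{h.aligned_length}\t{max(mism, 0)}\t{max(gaps, 0)}\t"
                f"{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t"
                f"{h.e_value:.3g}\t{h.bit_score:.1f}\n"
            )
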