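"""Pre-design orthogroup filtering.

Implements the design-time filters applied before any bait is tiled:
taxon-representation, anchoring to reference-genome gene models,
removal of non-cnidarian (holobiont contaminant) transcripts by best
local-alignment hit, and binning of each orthogroup to the reference
genome of its best gene-model hit.

Contaminant-database records carry a ``source=`` header tag with value
``cnidarian`` or ``non-cnidarian``; untagged records default to cnidarian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .seqio import SCLERACTINIAN_CLADES, AnnotatedSequence, Clade, SeqKind
from .similarity import (
    HomologyHit,
    ScoringScheme,
    best_hit,
    passes_similarity_filter,
    search,
)


@dataclass(frozen=True)
class Orthogroup:
    """A named set of taxon-annotated AA members with parallel coding sequences.

    AA and NT members correspond 1:1 by record id; the NT sequence is the
    (ungapped) coding sequence of the AA member, optionally with a trailing
    stop codon.  AA members may carry alignment gaps.
    """

    id: str
    aa_members: tuple[AnnotatedSequence, ...]
    nt_members: tuple[AnnotatedSequence, ...]
    bin: str | None = None
    reference_gene: str | None = None

    def __post_init__(self):
        aa_ids = [m.id for m in self.aa_members]
        nt_by_id = {m.id: m for m in self.nt_members}
        if sorted(aa_ids) != sorted(nt_by_id):
            raise ValueError(f"orthogroup {self.id}: AA/NT members do not match 1:1")
        for aa in self.aa_members:
            nt = nt_by_id[aa.id]
            n_aa = len(aa.ungapped)
            n_nt = len(nt.ungapped)
            if n_nt not in (3 * n_aa, 3 * n_aa + 3):
                raise ValueError(
                    f"orthogroup {self.id}, member {aa.id}: "
                    f"CDS length {n_nt} does not match {n_aa} residues"
                )

    def nt_member(self, member_id: str) -> AnnotatedSequence:
        for m in self.nt_members:
            if m.id == member_id:
                return m
        raise KeyError(member_id)

    def scleractinian_taxa(self) -> set[str]:
        return {m.taxon for m in self.aa_members if m.clade in SCLERACTINIAN_CLADES}

    def drop_members(self, member_ids: set[str]) -> "Orthogroup":
        return replace(
            self,
            aa_members=tuple(m for m in self.aa_members if m.id not in member_ids),
            nt_members=tuple(m for m in self.nt_members if m.id not in member_ids),
        )


def representation_filter(
    og: Orthogroup, min_taxa: int = 6, min_per_clade: int = 2
) -> bool:
    """True iff the orthogroup has enough distinct scleractinian taxa.

    Requires >= min_taxa distinct scleractinian taxa overall and
    >= min_per_clade distinct taxa from EACH of the Robust and Complex
    clades (set min_per_clade=0 to disable the per-clade condition).
    Distinctness counts taxon labels, not sequences, so upstream paralogs
    do not inflate counts.
    """
    taxa_by_clade: dict[Clade, set[str]] = {Clade.ROBUST: set(), Clade.COMPLEX: set()}
    for m in og.aa_members:
        if m.clade in taxa_by_clade:
            taxa_by_clade[m.clade].add(m.taxon)
    n_scleractinian = len(taxa_by_clade[Clade.ROBUST] | taxa_by_clade[Clade.COMPLEX])
    return (
        n_scleractinian >= min_taxa
        and len(taxa_by_clade[Clade.ROBUST]) >= min_per_clade
        and len(taxa_by_clade[Clade.COMPLEX]) >= min_per_clade
    )


def _degapped_aa(member: AnnotatedSequence) -> AnnotatedSequence:
    if "-" not in member.residues:
        return member
    return AnnotatedSequence(
        id=member.id,
        residues=member.ungapped,
        kind=member.kind,
        taxon=member.taxon,
        clade=member.clade,
        tags=dict(member.tags),
    )


def _all_model_hits(
    og: Orthogroup,
    gene_models: Mapping[str, Sequence[AnnotatedSequence]],
    evalue: float,
    scheme: ScoringScheme,
) -> list[tuple[str, HomologyHit]]:
    """(genome_id, hit) pairs for every member x gene-model hit."""
    out: list[tuple[str, HomologyHit]] = []
    for member in og.aa_members:
        query = _degapped_aa(member)
        for genome_id in sorted(gene_models):
            models = gene_models[genome_id]
            for hit in search(query, list(models), SeqKind.AA, evalue, scheme):
                out.append((genome_id, hit))
    return out


def genome_anchor(
    og: Orthogroup,
    gene_models: Mapping[str, Sequence[AnnotatedSequence]],
    min_bit_score: float = 50.0,
    evalue: float = 1e-6,
    scheme: ScoringScheme | None = None,
) -> bool:
    """True iff any member hits any gene model with bit score >= threshold."""
    if not gene_models:
        raise ValueError("gene_models must be nonempty")
    scheme = scheme or ScoringScheme.protein()
    for member in og.aa_members:
        query = _degapped_aa(member)
        for genome_id in sorted(gene_models):
            for hit in search(query, list(gene_models[genome_id]), SeqKind.AA, evalue, scheme):
                if hit.bit_score >= min_bit_score:
                    return True
    return False


def assign_bin(
    og: Orthogroup,
    gene_models: Mapping[str, Sequence[AnnotatedSequence]],
    evalue: float = 1e-6,
    scheme: ScoringScheme | None = None,
) -> Orthogroup:
    """Bin the orthogroup to the genome of its best member x model hit.

    Ordering follows the best-hit sort (bit score desc, e-value asc,
    identity desc, subject id asc).  Also records the best-hit gene model
    id for downstream exon projection.
    """
    scheme = scheme or ScoringScheme.protein()
    pairs = _all_model_hits(og, gene_models, evalue, scheme)
    if not pairs:
        raise ValueError(f"orthogroup {og.id}: no gene-model hits; anchor first")
    genome_id, top = min(
        pairs,
        key=lambda gh: (
            -gh[1].bit_score,
            gh[1].e_value,
            -gh[1].identity_pct,
            gh[1].subject_id,
        ),
    )
    return replace(og, bin=genome_id, reference_gene=top.subject_id)


def anchor_and_bin(
    og: Orthogroup,
    gene_models: Mapping[str, Sequence[AnnotatedSequence]],
    min_bit_score: float = 50.0,
    evalue: float = 1e-6,
    scheme: ScoringScheme | None = None,
) -> Orthogroup | None:
    """Anchor check and bin assignment with one pass over member x model hits.

    Equivalent to ``genome_anchor`` followed by ``assign_bin`` (the best
    hit carries the maximal bit score, so anchoring reduces to checking it)
    but without searching twice.  Returns None when the orthogroup fails
    the anchor threshold.
    """
    if not gene_models:
        raise ValueError("gene_models must be nonempty")
    scheme = scheme or ScoringScheme.protein()
    pairs = _all_model_hits(og, gene_models, evalue, scheme)
    if not pairs:
        return None
    genome_id, top = min(
        pairs,
        key=lambda gh: (
            -gh[1].bit_score,
            gh[1].e_value,
            -gh[1].identity_pct,
            gh[1].subject_id,
        ),
    )
    if top.bit_score < min_bit_score:
        return None
    return replace(og, bin=genome_id, reference_gene=top.subject_id)


def remove_contaminant_transcripts(
    og: Orthogroup,
    noncnidarian_db: Sequence[AnnotatedSequence],
    min_identity: float = 80.0,
    min_len: int = 100,
    evalue: float = 1e-6,
    min_taxa: int = 6,
    scheme: ScoringScheme | None = None,
) -> tuple[Orthogroup | None, list[tuple[str, HomologyHit]]]:
    """Remove members whose single best database hit is non-cnidarian.

    Only the best hit per transcript (best-hit order) is evaluated; it must
    be a non-cnidarian record and pass the similarity filter
    (>= min_identity % over >= min_len columns) for the member to be
    removed.  Returns (surviving orthogroup or None, removal evidence);
    None when the survivors cover fewer than ``min_taxa`` distinct
    scleractinian taxa.
    """
    scheme = scheme or ScoringScheme.nucleotide()
    db = list(noncnidarian_db)
    noncnid_ids = {
        rec.id
        for rec in db
        if rec.tags.get("source", "cnidarian").lower() == "non-cnidarian"
    }
    removed: list[tuple[str, HomologyHit]] = []
    for member in og.nt_members:
        hits = search(member, db, SeqKind.NT, evalue, scheme)
        top = best_hit(hits)
        if top is None or top.subject_id not in noncnid_ids:
            continue
        if passes_similarity_filter(top, min_identity, min_len):
            removed.append((member.id, top))

    removed_ids = {member_id for member_id, _ in removed}
    survivor = og.drop_members(removed_ids) if removed_ids else og
    if len(survivor.scleractinian_taxa()) < min_taxa:
        return None, removed
    return survivor, removed
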