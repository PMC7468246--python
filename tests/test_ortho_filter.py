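"""Representation, genome-anchoring, contaminant-removal and binning filters."""

import pytest

from coralbaits.ortho_filter import (
    Orthogroup,
    anchor_and_bin,
    assign_bin,
    genome_anchor,
    remove_contaminant_transcripts,
    representation_filter,
)
from coralbaits.seqio import AnnotatedSequence, Clade, SeqKind, translate_cds
from coralbaits.similarity import ScoringScheme


def _random_cds(rng, n_codons):
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons:
        c = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
        if c not in stops:
            codons.append(c)
    return "".join(codons)


def _mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[rng.integers(4)]
    s = "".join(out)
    return "".join(
        c[:2] + "C" if c in {"TAA", "TAG", "TGA"} else c
        for c in (s[i : i + 3] for i in range(0, len(s), 3))
    )


def make_og(cds_by_member, clades, og_id="OG1"):
    aa, nt = [], []
    for member, cds in cds_by_member.items():
        clade = clades.get(member, Clade.OTHER)
        aa.append(
            AnnotatedSequence(
                id=member, residues=translate_cds(cds), kind=SeqKind.AA,
                taxon=member, clade=clade,
            )
        )
        nt.append(
            AnnotatedSequence(
                id=member, residues=cds, kind=SeqKind.NT, taxon=member, clade=clade
            )
        )
    return Orthogroup(id=og_id, aa_members=tuple(aa), nt_members=tuple(nt))


@pytest.fixture(scope="module")
def base_og(rng):
    root = _random_cds(rng, 120)
    members = {}
    clades = {}
    for i in range(3):
        members[f"R{i}"] = _mutate(rng, root, 0.05)
        clades[f"R{i}"] = Clade.ROBUST
    for i in range(3):
        members[f"C{i}"] = _mutate(rng, root, 0.05)
        clades[f"C{i}"] = Clade.COMPLEX
    return root, members, clades


def test_representation_rules(base_og):
    root, members, clades = base_og
    og = make_og(members, clades)
    assert representation_filter(og, min_taxa=6, min_per_clade=2)  # 3R + 3C

    # five taxa total fails the overall minimum
    five = {k: members[k] for k in list(members)[:5]}
    assert not representation_filter(make_og(five, clades), 6, 2)

    # 5 Robust + 1 Complex fails the each-clade reading
    skew_clades = dict(clades)
    for i, k in enumerate(members):
        skew_clades[k] = Clade.ROBUST if i < 5 else Clade.COMPLEX
    assert not representation_filter(make_og(members, skew_clades), 6, 2)
    # ... but passes when the per-clade condition is disabled
    assert representation_filter(make_og(members, skew_clades), 6, 0)


def test_representation_monotone_in_taxa(base_og, rng):
    root, members, clades = base_og
    og = make_og(members, clades)
    assert representation_filter(og, 6, 2)
    extra = dict(members)
    extra_clades = dict(clades)
    extra["R9"] = _mutate(rng, root, 0.05)
    extra_clades["R9"] = Clade.ROBUST
    assert representation_filter(make_og(extra, extra_clades), 6, 2)


def test_representation_counts_distinct_taxa_not_sequences(base_og):
    root, members, clades = base_og
    og = make_og(members, clades)
    # two paralogous sequences from one taxon: ids differ, taxon equal
    dup_aa = og.aa_members[0]
    para = AnnotatedSequence(
        id="R0b", residues=dup_aa.residues, kind=SeqKind.AA,
        taxon=dup_aa.taxon, clade=dup_aa.clade,
    )
    para_nt = AnnotatedSequence(
        id="R0b", residues=og.nt_members[0].residues, kind=SeqKind.NT,
        taxon=dup_aa.taxon, clade=dup_aa.clade,
    )
    bigger = Orthogroup(
        id="OG1", aa_members=og.aa_members + (para,), nt_members=og.nt_members + (para_nt,)
    )
    five = {k for k in list(bigger.scleractinian_taxa())}
    assert len(five) == 6  # paralog did not add a taxon
    assert not representation_filter(bigger, min_taxa=7, min_per_clade=2)


def test_genome_anchor_and_threshold_inclusivity(base_og, rng):
    root, members, clades = base_og
    og = make_og(members, clades)
    model = AnnotatedSequence(id="g1", residues=translate_cds(root), kind=SeqKind.AA)
    gene_models = {"G1": [model]}
    assert genome_anchor(og, gene_models, min_bit_score=50.0)

    # the >= comparison is inclusive: anchoring at exactly the best bit score
    binned = anchor_and_bin(og, gene_models, min_bit_score=0.0)
    from coralbaits.similarity import search, best_hit

    best_bits = max(
        best_hit(
            search(m, [model], SeqKind.AA, 1e-6, ScoringScheme.protein())
        ).bit_score
        for m in og.aa_members
    )
    assert anchor_and_bin(og, gene_models, min_bit_score=best_bits) is not None
    assert anchor_and_bin(og, gene_models, min_bit_score=best_bits + 1e-6) is None

    # unrelated random sequence set: nothing reaches 50 bits
    noise = make_og(
        {f"X{i}": _random_cds(rng, 80) for i in range(6)},
        {f"X{i}": Clade.ROBUST for i in range(6)},
    )
    assert not genome_anchor(noise, gene_models, min_bit_score=50.0)


def test_assign_bin_picks_best_genome(base_og, rng):
    root, members, clades = base_og
    og = make_og(members, clades)
    close = AnnotatedSequence(id="g_close", residues=translate_cds(root), kind=SeqKind.AA)
    far = AnnotatedSequence(
        id="g_far", residues=translate_cds(_mutate(rng, root, 0.30)), kind=SeqKind.AA
    )
    binned = assign_bin(og, {"G1": [far], "G2": [close]})
    assert binned.bin == "G2"
    assert binned.reference_gene == "g_close"

    single = assign_bin(og, {"G1": [close]})
    assert single.bin == "G1"

    with pytest.raises(ValueError, match="no gene-model hits"):
        assign_bin(
            make_og({"X0": _random_cds(rng, 70)}, {"X0": Clade.ROBUST}),
            {"G1": [far]},
        )


@pytest.fixture(scope="module")
def contaminant_setup(rng):
    root = _random_cds(rng, 150)
    backbone = _random_cds(rng, 150)  # the non-cnidarian source
    members, clades = {}, {}
    for i in range(4):
        members[f"R{i}"] = _mutate(rng, root, 0.05)
        clades[f"R{i}"] = Clade.ROBUST
    for i in range(3):
        members[f"C{i}"] = _mutate(rng, root, 0.05)
        clades[f"C{i}"] = Clade.COMPLEX
    members["C2"] = _mutate(rng, backbone, 0.05)  # planted foreign transcript
    db = [
        AnnotatedSequence(
            id="cnid", residues=root, kind=SeqKind.NT, tags={"source": "cnidarian"}
        ),
        AnnotatedSequence(
            id="noncnid", residues=backbone, kind=SeqKind.NT,
            tags={"source": "non-cnidarian"},
        ),
    ]
    return make_og(members, clades), db


def test_contaminant_member_removed(contaminant_setup):
    og, db = contaminant_setup
    survivor, removed = remove_contaminant_transcripts(og, db, 80.0, 100, 1e-6, 6)
    assert [m for m, _ in removed] == ["C2"]
    assert survivor is not None
    assert "C2" not in {m.id for m in survivor.aa_members}
    evidence = removed[0][1]
    assert evidence.subject_id == "noncnid"
    assert evidence.identity_pct >= 80.0 and evidence.aligned_length >= 100


def test_cnidarian_best_hit_protects_member(contaminant_setup):
    og, db = contaminant_setup
    survivor, removed = remove_contaminant_transcripts(og, db, 80.0, 100, 1e-6, 6)
    kept = {m.id for m in survivor.aa_members}
    assert {"R0", "R1", "R2", "R3", "C0", "C1"} <= kept


def test_locus_dropped_when_below_min_taxa(contaminant_setup):
    og, db = contaminant_setup
    survivor, removed = remove_contaminant_transcripts(og, db, 80.0, 100, 1e-6, 7)
    assert survivor is None  # 6 surviving scleractinians < 7
    assert [m for m, _ in removed] == ["C2"]


def test_contaminant_removal_idempotent(contaminant_setup):
    og, db = contaminant_setup
    once, _ = remove_contaminant_transcripts(og, db, 80.0, 100, 1e-6, 6)
    twice, removed2 = remove_contaminant_transcripts(once, db, 80.0, 100, 1e-6, 6)
    assert removed2 == []
    assert {m.id for m in twice.aa_members} == {m.id for m in once.aa_members}
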