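"""Symbiont screening, region pruning, duplicate and self-hyb removal."""

import pytest

from coralbaits.bait_design import Bait, BaitRegion
from coralbaits.bait_filter import (
    RemovalReason,
    dedup,
    mapping_criterion,
    prune_regions,
    run_screen,
    self_hyb_screen,
    symbiont_screen,
)
from coralbaits.seqio import AnnotatedSequence, SeqKind, reverse_complement
from coralbaits.similarity import HomologyHit

from .oracles import rc_flags


def random_bait(rng, bait_id, region="r1", tile=0):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
    return Bait(bait_id=bait_id, region_ref=region, tile_index=tile,
                source_taxon="t", sequence=seq)


def region_of(baits, locus="L1", start=0, end=240):
    return BaitRegion(
        locus_id=locus, window_start=start, window_end=end,
        n_tiles=7, baits=list(baits),
    )


def _hit(identity, q_span):
    return HomologyHit(
        query_id="b", subject_id="sym", q_start=0, q_end=q_span,
        s_start=0, s_end=q_span, aligned_length=max(q_span, 1),
        identity_pct=identity, raw_score=10, bit_score=20.0, e_value=1.0,
    )


@pytest.mark.parametrize(
    "identity,span,expected",
    [(70.0, 84, True), (69.9, 84, False), (70.0, 83, False), (100.0, 84, True)],
)
def test_mapping_criterion_inclusive_boundaries(identity, span, expected):
    assert mapping_criterion(_hit(identity, span), 70.0, 84) is expected


def test_symbiont_screen_flags_verbatim_copy(rng):
    baits = [random_bait(rng, f"b{i}") for i in range(5)]
    ref_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
    ref_seq = ref_seq[:400] + baits[2].sequence + ref_seq[520:]
    refs = [AnnotatedSequence(id="sym1", residues=ref_seq, kind=SeqKind.NT)]
    flagged = symbiont_screen(baits, refs)
    assert set(flagged) == {"b2"}
    assert flagged["b2"] is RemovalReason.SYMBIONT_MAP


def test_symbiont_screen_ignores_unrelated_baits(rng):
    baits = [random_bait(rng, f"b{i}") for i in range(10)]
    refs = [
        AnnotatedSequence(
            id=f"sym{j}",
            residues="".join("ACGT"[i] for i in rng.integers(0, 4, 2000)),
            kind=SeqKind.NT,
        )
        for j in range(3)
    ]
    assert symbiont_screen(baits, refs) == {}


def test_prune_regions_rules(rng):
    seven = [random_bait(rng, f"s{i}", tile=i) for i in range(7)]
    two = [random_bait(rng, f"d{i}", tile=i) for i in range(2)]

    # >= 3 flagged: whole region removed
    survivors, bait_log, region_log = prune_regions(
        [region_of(seven)], {f"s{i}": RemovalReason.SYMBIONT_MAP for i in range(3)}
    )
    assert survivors == [] and len(region_log) == 1
    assert len(bait_log) == 7  # every bait accounted for

    # 2 flagged of 7: region kept with 5
    survivors, bait_log, region_log = prune_regions(
        [region_of(seven)], {f"s{i}": RemovalReason.SYMBIONT_MAP for i in range(2)}
    )
    assert len(survivors) == 1 and len(survivors[0].baits) == 5
    assert region_log == []

    # 1 flagged of 2: only one bait would remain -> region removed
    survivors, bait_log, region_log = prune_regions(
        [region_of(two)], {"d0": RemovalReason.SYMBIONT_BLAST}
    )
    assert survivors == [] and len(region_log) == 1


def test_prune_monotone_in_flags(rng):
    seven = [random_bait(rng, f"m{i}", tile=i) for i in range(7)]
    flags = {f"m{i}": RemovalReason.SYMBIONT_MAP for i in range(3)}
    removed_before = prune_regions([region_of(seven)], flags)[2]
    flags["m3"] = RemovalReason.SYMBIONT_MAP
    removed_after = prune_regions([region_of(seven)], flags)[2]
    assert {r for r, _ in removed_before} <= {r for r, _ in removed_after}


def test_dedup_keeps_first_and_is_idempotent(rng):
    a = random_bait(rng, "a")
    b = random_bait(rng, "b")
    copy = Bait(bait_id="c", region_ref="r2", tile_index=1,
                source_taxon="t", sequence=a.sequence)
    kept, removed = dedup([a, b, copy])
    assert [x.bait_id for x in kept] == ["a", "b"]
    assert removed == [("c", RemovalReason.DUPLICATE)]
    kept2, removed2 = dedup(kept)
    assert kept2 == kept and removed2 == []

    unique, removed3 = dedup([a, b])
    assert [x.bait_id for x in unique] == ["a", "b"] and removed3 == []


def test_self_hyb_flags_later_of_rc_pair(rng):
    a = random_bait(rng, "a")
    rc_copy = Bait(bait_id="z", region_ref="r", tile_index=0, source_taxon="t",
                   sequence=reverse_complement(a.sequence))
    others = [random_bait(rng, f"o{i}") for i in range(5)]
    flagged = self_hyb_screen([a, *others, rc_copy], min_rc_match=21)
    assert flagged == {"z"}


def test_self_hyb_matches_bruteforce_oracle(rng):
    baits = [random_bait(rng, f"b{i:02d}") for i in range(20)]
    # plant one rc pair and one partial (25 nt) rc overlap
    baits[7] = Bait(bait_id="b07", region_ref="r", tile_index=0, source_taxon="t",
                    sequence=reverse_complement(baits[3].sequence))
    partial = reverse_complement(baits[5].sequence[40:65])
    host = list(baits[11].sequence)
    host[10:35] = partial
    baits[11] = Bait(bait_id="b11", region_ref="r", tile_index=0, source_taxon="t",
                     sequence="".join(host))
    expected = rc_flags([(b.bait_id, b.sequence) for b in baits], 21)
    assert self_hyb_screen(baits, min_rc_match=21) == expected
    assert {"b07", "b11"} <= expected


def test_unrelated_baits_not_flagged(rng):
    baits = [random_bait(rng, f"u{i}") for i in range(30)]
    assert self_hyb_screen(baits, min_rc_match=21) == set()


def _planted_regions(rng):
    regions = []
    for r in range(4):
        baits = [random_bait(rng, f"r{r}b{i}", region=f"L{r}:0-240", tile=i)
                 for i in range(7)]
        regions.append(BaitRegion(locus_id=f"L{r}", window_start=0, window_end=240,
                                  n_tiles=7, baits=baits))
    return regions


def test_run_screen_conserves_counts(rng):
    regions = _planted_regions(rng)
    # symbiont ref carrying one region's bait verbatim three times over
    sym = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    for k, b in enumerate(regions[1].baits[:3]):
        sym = sym[: 200 * (k + 1)] + b.sequence + sym[200 * (k + 1) + 120 :]
    refs = [AnnotatedSequence(id="sym", residues=sym, kind=SeqKind.NT)]

    n_input = sum(len(r.baits) for r in regions)
    survivors, report = run_screen(regions, refs)
    assert report.n_input == n_input
    assert report.n_surviving + report.n_removed == n_input
    assert {r.locus_id for r in survivors} == {"L0", "L2", "L3"}
    removed_ids = [b for b, _ in report.removed_baits]
    assert len(removed_ids) == len(set(removed_ids))  # each bait ledgered once


def test_run_screen_idempotent(rng):
    regions = _planted_regions(rng)
    refs = [AnnotatedSequence(
        id="sym",
        residues=regions[0].baits[0].sequence + "".join(
            "ACGT"[i] for i in rng.integers(0, 4, 500)
        ),
        kind=SeqKind.NT,
    )]
    survivors, first = run_screen(regions, refs)
    again, second = run_screen(survivors, refs)
    assert second.n_removed == 0
    assert second.removed_regions == []
    assert [b.bait_id for r in again for b in r.baits] == [
        b.bait_id for r in survivors for b in r.baits
    ]
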