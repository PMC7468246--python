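"""Tiling arithmetic, exon-aware window search and bait generation."""

import pytest

from coralbaits.bait_design import (
    BaitLabel,
    TilingScheme,
    best_region_per_locus,
    column_identity_scores,
    design_barcode_baits,
    design_regions,
    find_window,
    make_region,
    project_exons,
    tile_positions,
)
from coralbaits.codon_align import CodonAlignment
from coralbaits.seqio import ExonMap

from .oracles import enumerate_windows

REF = "__ref__"


@pytest.mark.parametrize("window,n", [(240, 7), (200, 5), (160, 3), (120, 1)])
def test_tile_counts_match_design_rule(window, n):
    positions = tile_positions(window)
    assert len(positions) == n
    assert positions[0] == 0 and positions[-1] == window - 120
    assert all(b - a == 20 for a, b in zip(positions, positions[1:]))


def test_tile_positions_rejects_short_window():
    with pytest.raises(ValueError):
        tile_positions(100)


def test_tiling_scheme_validation():
    with pytest.raises(ValueError):
        TilingScheme(window_lengths=(240, 250))
    with pytest.raises(ValueError):
        TilingScheme(window_lengths=(240, 130))  # (130-120) % 20 != 0
    with pytest.raises(ValueError):
        TilingScheme(bait_length=200, window_lengths=(160,))


def _aln(rows, locus="L1"):
    return CodonAlignment(locus_id=locus, rows=dict(rows), aa_rows={})


def _random_rows(rng, n_rows, n_cols, diversity=0.1):
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, n_cols))
    rows = {}
    for r in range(n_rows):
        row = list(base)
        for i in range(n_cols):
            if rng.random() < diversity:
                row[i] = "ACGT"[rng.integers(4)]
        rows[f"t{r}"] = "".join(row)
    return rows


def test_single_exon_gap_free_gets_240_window(rng):
    rows = _random_rows(rng, 4, 300)
    rows[REF] = rows.pop("t0")
    aln = _aln(rows)
    exons = ExonMap(gene_id="g", exons=((0, 300),))
    found = find_window(aln, exons, reference_row=REF)
    assert found is not None
    (start, end), length = found
    assert length == 240 and end - start == 240


def test_short_exons_fall_back_to_120(rng):
    # projected exon lengths 132 and 150: no exon hosts a 160 window
    rows = _random_rows(rng, 4, 282)
    rows[REF] = rows.pop("t0")
    aln = _aln(rows)
    exons = ExonMap(gene_id="g", exons=((0, 132), (132, 282)))
    found = find_window(aln, exons, reference_row=REF)
    assert found is not None
    assert found[1] == 120


def test_all_gap_columns_yield_none(rng):
    rows = _random_rows(rng, 3, 240)
    rows["t1"] = "-" * 240  # one row makes every column fail the strict rule
    rows[REF] = rows.pop("t0")
    aln = _aln(rows)
    exons = ExonMap(gene_id="g", exons=((0, 240),))
    assert find_window(aln, exons, reference_row=REF) is None


def test_window_matches_bruteforce_oracle(rng):
    for trial in range(5):
        n_cols = int(rng.integers(260, 400)) // 3 * 3
        rows = _random_rows(rng, 5, n_cols, diversity=0.15)
        # plant some gap columns
        for name in list(rows)[1:3]:
            row = list(rows[name])
            start = int(rng.integers(0, n_cols - 30))
            for c in range(start, start + 30):
                row[c] = "-"
            rows[name] = "".join(row)
        split = int(rng.integers(60, n_cols - 60))
        exons = ExonMap(gene_id="g", exons=((0, split), (split, n_cols)))
        ref = rows.pop("t0")
        member_rows = dict(rows)
        rows = {REF: ref, **member_rows}
        aln = _aln(rows)
        found = find_window(aln, exons, reference_row=REF)

        exon_ids = [0 if c < split else 1 for c in range(n_cols)]
        expected = enumerate_windows(list(member_rows.values()), exon_ids)
        if expected is None:
            assert found is None
        else:
            assert found is not None
            assert found[0] == expected


def test_window_invariant_under_row_permutation(rng):
    rows = _random_rows(rng, 6, 300)
    ref = rows.pop("t0")
    exons = ExonMap(gene_id="g", exons=((0, 300),))
    fwd = find_window(_aln({REF: ref, **rows}), exons, reference_row=REF)
    rev = find_window(
        _aln({REF: ref, **dict(reversed(list(rows.items())))}), exons, reference_row=REF
    )
    assert fwd == rev


def test_window_never_crosses_exon_boundary(rng):
    rows = _random_rows(rng, 4, 600)
    rows[REF] = rows.pop("t0")
    split = 300
    exons = ExonMap(gene_id="g", exons=((0, split), (split, 600)))
    found = find_window(_aln(rows), exons, reference_row=REF)
    (start, end), _ = found
    assert end <= split or start >= split


def test_exon_projection_through_reference_gaps():
    # reference row with a 3-column insertion between its two exons
    ref = "AAA" * 10 + "---" + "CCC" * 10
    exons = ExonMap(gene_id="g", exons=((0, 30), (30, 60)))
    ids = project_exons(ref, exons)
    assert list(ids[:30]) == [0] * 30
    assert list(ids[30:33]) == [0] * 3  # insertion inherits preceding exon
    assert list(ids[33:]) == [1] * 30


def test_make_region_dedup_and_variants(rng):
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 240))
    # two identical rows: one bait per tile
    aln = _aln({REF: base, "a": base, "b": base})
    region = make_region(aln, (0, 240), reference_row=REF)
    assert region.n_tiles == 7 and len(region.baits) == 7

    # rows differing inside every tile: two variants per tile
    variant = list(base)
    for pos in range(10, 240, 20):  # a difference in every 120-mer
        variant[pos] = "A" if base[pos] != "A" else "C"
    aln2 = _aln({REF: base, "a": base, "b": "".join(variant)})
    region2 = make_region(aln2, (0, 240), reference_row=REF)
    assert len(region2.baits) == 14

    # a row with a central gap contributes nothing to overlapping tiles
    gapped = base[:118] + "---" + base[121:]
    aln3 = _aln({REF: base, "a": base, "b": gapped})
    region3 = make_region(aln3, (0, 240), reference_row=REF)
    tiles_from_b = {b.tile_index for b in region3.baits if b.source_taxon == "b"}
    assert tiles_from_b == set()  # every tile overlaps columns 118-120
    assert {b.tile_index for b in region3.baits} == set(range(7))


def test_emitted_baits_are_clean(study_workspace):
    from coralbaits.seqio import SeqKind, read_fasta

    baits = read_fasta(study_workspace["outdir"] / "design" / "baits.fasta", SeqKind.NT)
    assert baits
    for rec in baits:
        assert len(rec.residues) == 120
        assert set(rec.residues) <= set("ACGT")


def test_best_region_selection(rng):
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    aln = _aln({REF: base, "a": base, "b": base})
    long = make_region(aln, (0, 240), reference_row=REF)
    short = make_region(aln, (0, 160), reference_row=REF)
    assert best_region_per_locus([short, long]) is long

    noisy = list(base)
    for c in range(0, 240, 5):
        noisy[c] = "A" if base[c] != "A" else "G"
    aln_low = _aln({REF: base, "a": base, "b": "".join(noisy)})
    low_ident = make_region(aln_low, (0, 240), reference_row=REF)
    assert best_region_per_locus([low_ident, long]) is long
    assert best_region_per_locus([long]) is long
    with pytest.raises(ValueError):
        best_region_per_locus([])


def test_multi_region_design_one_window_per_exon(rng):
    rows = _random_rows(rng, 4, 600, diversity=0.05)
    rows[REF] = rows.pop("t0")
    exons = ExonMap(gene_id="g", exons=((0, 300), (300, 600)))
    regions = design_regions(
        _aln(rows), exons, reference_row=REF, multi_region=True
    )
    assert len(regions) == 2
    sides = sorted((r.window_start, r.window_end) for r in regions)
    assert sides[0][1] <= 300 <= sides[1][0]


def test_barcode_tiling_spans_whole_gene(rng):
    gene = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
    region = design_barcode_baits({"x": gene}, BaitLabel.COI)
    assert region.n_tiles == 25  # floor((600-120)/20)+1
    assert len(region.baits) == 25
    assert all(b.label is BaitLabel.COI for b in region.baits)

    short = gene[:130]
    region2 = design_barcode_baits({"x": short}, BaitLabel.H3)
    starts = sorted({b.sequence == short[t:t+120] for t, b in zip((0, 10), region2.baits)})
    assert region2.n_tiles == 2
    assert [b.bait_id.split("|")[2] for b in region2.baits] == ["tile0", "tile1"]
    assert region2.baits[1].sequence == short[10:130]

    divergent = {"x": gene, "y": gene[:300] + gene[300:][::-1]}
    region3 = design_barcode_baits(divergent, BaitLabel.COI)
    assert len(region3.baits) > region3.n_tiles  # divergent tiles carry variants

    with pytest.raises(ValueError):
        design_barcode_baits({"x": gene[:100]}, BaitLabel.COI)
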