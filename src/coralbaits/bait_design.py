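"""Exon-aware bait-window search and 120 bp tiled bait generation.

A locus is scanned for the longest window (240 -> 200 -> 160 -> 120 nt)
that (i) lies wholly inside a single exon of the reference gene model
projected onto alignment columns and (ii) satisfies the gap rule.  Within
the chosen window length, the window maximising mean pairwise identity
wins (ties -> leftmost); the window is then tiled with 120 bp baits every
20 bp and each distinct gap-free 120-mer among member rows becomes a bait.

Windows never cross projected exon boundaries, so baits remain contiguous
on the genome and capture efficiency does not suffer from intron breaks.
Barcode genes (COI, histone H3) are tiled across their entire length
instead, with the last tile anchored at the end of the gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .codon_align import CodonAlignment
from .seqio import ExonMap


class BaitLabel(str, Enum):
    TARGET = "target"
    COI = "coi"
    H3 = "h3"


@dataclass(frozen=True)
class TilingScheme:
    """Bait length, tiling offset and the iterative window lengths."""

    bait_length: int = 120
    offset: int = 20
    window_lengths: tuple[int, ...] = (240, 200, 160, 120)

    def __post_init__(self):
        if self.bait_length > min(self.window_lengths):
            raise ValueError("bait_length exceeds the smallest window")
        if list(self.window_lengths) != sorted(self.window_lengths, reverse=True):
            raise ValueError("window_lengths must be strictly decreasing")
        if len(set(self.window_lengths)) != len(self.window_lengths):
            raise ValueError("window_lengths must be strictly decreasing")
        for w in self.window_lengths:
            if (w - self.bait_length) % self.offset != 0:
                raise ValueError(f"window {w}: (W - bait_length) not divisible by offset")


@dataclass(frozen=True)
class Bait:
    """A single 120 bp probe sequence extracted from an alignment tile."""

    bait_id: str
    region_ref: str
    tile_index: int
    source_taxon: str
    sequence: str
    label: BaitLabel = BaitLabel.TARGET

    def __post_init__(self):
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"bait {self.bait_id}: alphabet must be ACGT only")


@dataclass
class BaitRegion:
    """A tiled window on a locus alignment plus its baits."""

    locus_id: str
    window_start: int
    window_end: int
    n_tiles: int
    baits: list[Bait]
    source_bin: str = ""
    mean_identity: float = 1.0
    label: BaitLabel = BaitLabel.TARGET

    @property
    def window_length(self) -> int:
        return self.window_end - self.window_start

    @property
    def region_id(self) -> str:
        return f"{self.locus_id}:{self.window_start}-{self.window_end}"


def tile_positions(window_length: int, scheme: TilingScheme | None = None) -> list[int]:
    """Start offsets of the tiled baits within a window.

    A 240 bp window yields 7 baits, 200 -> 5, 160 -> 3, 120 -> 1.
    """
    scheme = scheme or TilingScheme()
    if window_length < scheme.bait_length:
        raise ValueError(f"window {window_length} shorter than a bait")
    return list(range(0, window_length - scheme.bait_length + 1, scheme.offset))


def project_exons(reference_row: str, exon_map: ExonMap) -> np.ndarray:
    """Exon index for every alignment column, projected through the reference row.

    Reference (non-gap) columns inherit the exon of their coding-sequence
    position; insertion columns (reference gaps) inherit the preceding
    reference position's exon, leading insertions the first exon.
    """
    cds_len = len(reference_row.replace("-", ""))
    if cds_len != exon_map.total_length:
        raise ValueError(
            f"{exon_map.gene_id}: reference row has {cds_len} coding positions "
            f"but the exon map covers {exon_map.total_length}"
        )
    starts = np.array([s for s, _ in exon_map.exons])
    out = np.zeros(len(reference_row), dtype=np.int64)
    pos = -1
    for col, ch in enumerate(reference_row):
        if ch != "-":
            pos += 1
        cds_pos = max(pos, 0)
        out[col] = int(np.searchsorted(starts, cds_pos, side="right") - 1)
    return out


def column_identity_scores(rows: Sequence[str]) -> np.ndarray:
    """Per-column mean pairwise identity over non-gap characters.

    The mean pairwise identity of a window equals the mean of this score
    over its columns (identity averaged per column then per pair commutes).
    Columns with fewer than two non-gap characters score 0.
    """
    if not rows:
        return np.zeros(0)
    mat = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    n_cols = mat.shape[1]
    scores = np.zeros(n_cols)
    gap = ord("-")
    letters = np.unique(mat)
    nongap = (mat != gap).sum(axis=0)
    eq_pairs = np.zeros(n_cols)
    for letter in letters:
        if letter == gap:
            continue
        n = (mat == letter).sum(axis=0)
        eq_pairs += n * (n - 1) / 2.0
    total_pairs = nongap * (nongap - 1) / 2.0
    mask = total_pairs > 0
    scores[mask] = eq_pairs[mask] / total_pairs[mask]
    return scores


def _gap_valid_columns(rows: Sequence[str], gap_mode: str, max_gap_frac: float) -> np.ndarray:
    mat = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    gap_count = (mat == ord("-")).sum(axis=0)
    if gap_mode == "strict":
        return gap_count == 0
    if gap_mode == "tolerant":
        return gap_count / len(rows) <= max_gap_frac
    raise ValueError(f"unknown gap_mode {gap_mode!r}")


def find_window(
    locus: CodonAlignment,
    exon_map: ExonMap,
    scheme: TilingScheme | None = None,
    reference_row: str | None = None,
    gap_mode: str = "strict",
    max_gap_frac: float = 0.5,
    exon_index: int | None = None,
) -> tuple[tuple[int, int], int] | None:
    """Locate the best bait window, trying window lengths longest-first.

    Returns ((start, end), window_length) in alignment columns, or None
    when no window of any length is valid.  ``exon_index`` restricts the
    search to one projected exon (used for multi-exon design).
    """
    scheme = scheme or TilingScheme()
    if reference_row is None or reference_row not in locus.rows:
        raise ValueError("find_window needs the reference row name")
    exon_ids = project_exons(locus.rows[reference_row], exon_map)
    members = [row for name, row in locus.rows.items() if name != reference_row]
    if not members:
        return None
    valid = _gap_valid_columns(members, gap_mode, max_gap_frac)
    scores = column_identity_scores(members)
    n_cols = len(valid)

    bad_prefix = np.concatenate([[0], np.cumsum(~valid)])
    score_prefix = np.concatenate([[0.0], np.cumsum(scores)])

    for w in scheme.window_lengths:
        if w > n_cols:
            continue
        starts = np.arange(0, n_cols - w + 1)
        ok = bad_prefix[starts + w] - bad_prefix[starts] == 0
        # exon ids are monotone along columns: same id at both ends means
        # the window sits wholly inside one exon
        ok &= exon_ids[starts] == exon_ids[starts + w - 1]
        if exon_index is not None:
            ok &= exon_ids[starts] == exon_index
        if not ok.any():
            continue
        window_scores = (score_prefix[starts + w] - score_prefix[starts]) / w
        window_scores[~ok] = -np.inf
        best = int(np.argmax(window_scores))  # argmax takes the leftmost max
        return (int(starts[best]), int(starts[best]) + w), w
    return None


def make_region(
    locus: CodonAlignment,
    window: tuple[int, int],
    scheme: TilingScheme | None = None,
    reference_row: str | None = None,
    source_bin: str = "",
    label: BaitLabel = BaitLabel.TARGET,
) -> BaitRegion:
    """Tile a validated window and emit one bait per distinct gap-free 120-mer.

    Duplicates within a tile collapse to the first contributing taxon in
    input order; a row with a gap (or N) inside a tile simply contributes
    no bait for that tile.
    """
    scheme = scheme or TilingScheme()
    start, end = window
    w = end - start
    positions = tile_positions(w, scheme)
    members = [(name, row) for name, row in locus.rows.items() if name != reference_row]
    scores = column_identity_scores([row for _, row in members])
    mean_identity = float(scores[start:end].mean()) if end > start else 0.0

    baits: list[Bait] = []
    region_id = f"{locus.locus_id}:{start}-{end}"
    for k, offset in enumerate(positions):
        tile_start = start + offset
        seen: set[str] = set()
        for taxon, row in members:
            sub = row[tile_start : tile_start + scheme.bait_length]
            if "-" in sub or "N" in sub or sub in seen:
                continue
            seen.add(sub)
            baits.append(
                Bait(
                    bait_id=f"{locus.locus_id}|{start}-{end}|tile{k}|{taxon}",
                    region_ref=region_id,
                    tile_index=k,
                    source_taxon=taxon,
                    sequence=sub,
                    label=label,
                )
            )
    return BaitRegion(
        locus_id=locus.locus_id,
        window_start=start,
        window_end=end,
        n_tiles=len(positions),
        baits=baits,
        source_bin=source_bin,
        mean_identity=mean_identity,
        label=label,
    )


def best_region_per_locus(regions: Sequence[BaitRegion]) -> BaitRegion:
    """Single best region: longest window, then highest identity, then leftmost."""
    if not regions:
        raise ValueError("no candidate regions")
    return min(
        regions,
        key=lambda r: (-r.window_length, -r.mean_identity, r.window_start),
    )


def design_regions(
    locus: CodonAlignment,
    exon_map: ExonMap,
    scheme: TilingScheme | None = None,
    reference_row: str | None = None,
    source_bin: str = "",
    gap_mode: str = "strict",
    max_gap_frac: float = 0.5,
    multi_region: bool = False,
) -> list[BaitRegion]:
    """Design bait regions for one locus.

    With ``multi_region`` the best window of each projected exon is kept
    independently (mirroring the observed multiplicity of exon regions per
    locus); otherwise a single best window for the locus is returned.
    """
    scheme = scheme or TilingScheme()
    if multi_region:
        exon_ids = sorted(
            set(project_exons(locus.rows[reference_row], exon_map).tolist())
        )
        regions = []
        for exon_index in exon_ids:
            found = find_window(
                locus, exon_map, scheme, reference_row, gap_mode, max_gap_frac,
                exon_index=exon_index,
            )
            if found is not None:
                regions.append(
                    make_region(locus, found[0], scheme, reference_row, source_bin)
                )
        return regions
    found = find_window(locus, exon_map, scheme, reference_row, gap_mode, max_gap_frac)
    if found is None:
        return []
    return [make_region(locus, found[0], scheme, reference_row, source_bin)]


def design_barcode_baits(
    rows: Mapping[str, str],
    label: BaitLabel,
    scheme: TilingScheme | None = None,
    locus_id: str | None = None,
) -> BaitRegion:
    """Tile 120 bp baits across the entire length of a barcode gene alignment.

    Tiles advance by the scheme offset; if the alignment length is not
    offset-aligned the final tile is anchored at length - 120 so the whole
    gene is covered.  Distinct gap-free variants per tile become baits.
    """
    scheme = scheme or TilingScheme()
    if not rows:
        raise ValueError("no barcode sequences")
    length = len(next(iter(rows.values())))
    if any(len(r) != length for r in rows.values()):
        raise ValueError("barcode rows are not aligned (unequal lengths)")
    if length < scheme.bait_length:
        raise ValueError(f"barcode alignment of {length} columns is shorter than a bait")
    locus_id = locus_id or label.value
    positions = list(range(0, length - scheme.bait_length + 1, scheme.offset))
    last = length - scheme.bait_length
    if positions[-1] != last:
        positions.append(last)

    scores = column_identity_scores(list(rows.values()))
    baits: list[Bait] = []
    region_id = f"{locus_id}:0-{length}"
    for k, tile_start in enumerate(positions):
        seen: set[str] = set()
        for taxon, row in rows.items():
            sub = row[tile_start : tile_start + scheme.bait_length]
            if "-" in sub or "N" in sub or sub in seen:
                continue
            seen.add(sub)
            baits.append(
                Bait(
                    bait_id=f"{locus_id}|0-{length}|tile{k}|{taxon}",
                    region_ref=region_id,
                    tile_index=k,
                    source_taxon=taxon,
                    sequence=sub,
                    label=label,
                )
            )
    return BaitRegion(
        locus_id=locus_id,
        window_start=0,
        window_end=length,
        n_tiles=len(positions),
        baits=baits,
        mean_identity=float(scores.mean()),
        label=label,
    )
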