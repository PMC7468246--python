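"""Concatenation of curated loci into a partitioned supermatrix.

Gaps (``-``) and absent-locus padding (``?``) both count as missing data
when summarising the matrix; a column is parsimony-informative when at
least two distinct non-missing states each occur in at least two rows.
The trimming step is a transparent per-column gap-fraction rule standing
in for external alignment-trimming heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

MISSING = frozenset("-?NX")


@dataclass
class Supermatrix:
    """Concatenated per-locus alignments, partitioned by locus.

    Partitions are 0-based half-open on the concatenation and tile
    [0, length) exactly; a taxon absent from a locus carries ``?`` across
    that partition.
    """

    taxa: list[str]
    partitions: list[tuple[str, int, int]]
    cells: dict[str, str]

    def __post_init__(self):
        lengths = {len(row) for row in self.cells.values()}
        if len(lengths) > 1:
            raise ValueError("matrix rows differ in length")
        expected = 0
        for _, start, end in self.partitions:
            if start != expected:
                raise ValueError("partitions do not tile the matrix")
            expected = end
        if self.partitions and lengths and expected != lengths.pop():
            raise ValueError("partition span does not match matrix length")

    @property
    def length(self) -> int:
        return len(self.cells[self.taxa[0]]) if self.taxa else 0


def trim_alignment(
    rows: Mapping[str, str], max_gap_frac: float = 0.8
) -> dict[str, str] | None:
    """Remove columns whose gap fraction exceeds the threshold.

    Row order is preserved.  Returns None when trimming removes every
    column (the locus should then be dropped, with a log entry upstream).
    """
    names = list(rows)
    if not names:
        return {}
    mat = np.frombuffer("".join(rows.values()).encode(), dtype=np.uint8)
    mat = mat.reshape(len(names), -1)
    gap_frac = ((mat == ord("-")) | (mat == ord("?"))).mean(axis=0)
    keep = gap_frac <= max_gap_frac
    if not keep.any():
        return None
    trimmed = mat[:, keep]
    return {
        name: trimmed[i].tobytes().decode() for i, name in enumerate(names)
    }


def concatenate(
    loci: Sequence[tuple[str, Mapping[str, str]]],
    taxon_universe: Sequence[str] | None = None,
) -> Supermatrix:
    """Concatenate per-locus alignments; missing taxa are padded with ``?``.

    ``loci`` is an ordered sequence of (locus_id, {taxon: aligned row}).
    """
    if taxon_universe is None:
        seen: list[str] = []
        for _, rows in loci:
            for taxon in rows:
                if taxon not in seen:
                    seen.append(taxon)
        taxon_universe = seen
    taxa = list(taxon_universe)

    partitions: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    offset = 0
    for locus_id, rows in loci:
        if len(rows) != len(set(rows)):
            raise ValueError(f"{locus_id}: duplicate taxon")
        lengths = {len(r) for r in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"{locus_id}: rows are not aligned")
        width = lengths.pop()
        for taxon in taxa:
            chunks[taxon].append(rows.get(taxon, "?" * width))
        partitions.append((locus_id, offset, offset + width))
        offset += width
    return Supermatrix(
        taxa=taxa,
        partitions=partitions,
        cells={t: "".join(chunks[t]) for t in taxa},
    )


def _char_matrix(rows: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)


def parsimony_informative_sites(rows: Sequence[str]) -> int:
    """Count columns with >= 2 distinct non-missing states each in >= 2 rows."""
    if not rows:
        return 0
    mat = _char_matrix(rows)
    missing = np.zeros(mat.shape, dtype=bool)
    for ch in MISSING:
        missing |= mat == ord(ch)
    counted = np.zeros(mat.shape[1], dtype=np.int64)
    for letter in np.unique(mat):
        if chr(letter) in MISSING:
            continue
        counted += ((mat == letter).sum(axis=0) >= 2).astype(np.int64)
    return int((counted >= 2).sum())


def matrix_stats(m: Supermatrix) -> dict:
    """Missing-data %, parsimony-informative sites and per-locus lengths.

    missing_pct counts both ``?`` (absent locus) and ``-`` (alignment gap)
    cells; PI sites are counted matrix-wide over the concatenation.
    """
    rows = [m.cells[t] for t in m.taxa]
    mat = _char_matrix(rows) if rows else np.zeros((0, 0), dtype=np.uint8)
    n_cells = mat.size
    missing = np.zeros(mat.shape, dtype=bool)
    for ch in "-?":
        missing |= mat == ord(ch)
    missing_pct = 100.0 * missing.sum() / n_cells if n_cells else 0.0

    n_pi = parsimony_informative_sites(rows)
    lengths = np.array([end - start for _, start, end in m.partitions], dtype=float)
    per_locus = {
        "mean": float(lengths.mean()) if lengths.size else 0.0,
        "sd": float(lengths.std(ddof=1)) if lengths.size > 1 else None,
        "min": int(lengths.min()) if lengths.size else 0,
        "max": int(lengths.max()) if lengths.size else 0,
    }
    return {
        "n_taxa": len(m.taxa),
        "n_loci": len(m.partitions),
        "length": m.length,
        "missing_pct": missing_pct,
        "n_pi_sites": n_pi,
        "pi_pct": 100.0 * n_pi / m.length if m.length else 0.0,
        "locus_length": per_locus,
    }


def write_partitions(m: Supermatrix, path):
    """RAxML-style partition file, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for locus_id, start, end in m.partitions:
            fh.write(f"DNA, {locus_id} = {start + 1}-{end}\n")


def read_partitions(path) -> list[tuple[str, int, int]]:
    """Parse a RAxML-style partition file back to 0-based half-open spans."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            _, rest = line.split(",", 1)
            name, span = rest.split("=")
            start, end = span.strip().split("-")
            out.append((name.strip(), int(start) - 1, int(end)))
    return out


def write_matrix_fasta(m: Supermatrix, path):
    with open(path, "w") as fh:
        for taxon in m.taxa:
            fh.write(f">{taxon}\n")
            row = m.cells[taxon]
            for i in range(0, len(row), 80):
                fh.write(row[i : i + 80] + "\n")


def write_matrix_phylip(m: Supermatrix, path):
    """Relaxed PHYLIP (name, two spaces, full row)."""
    with open(path, "w") as fh:
        fh.write(f"{len(m.taxa)} {m.length}\n")
        for taxon in m.taxa:
            fh.write(f"{taxon}  {m.cells[taxon]}\n")
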