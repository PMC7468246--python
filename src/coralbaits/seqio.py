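"""Readers and writers for the on-disk formats the pipeline touches.

All coordinates are 0-based half-open.  FASTA headers may carry
``key=value;key=value`` tags after the record id (e.g. ``taxon=`` and
``clade=``); files remain plain FASTA for external tools.  Residues are
parsed case-insensitively and stored uppercase.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table


class Clade(str, Enum):
    ROBUST = "ROBUST"
    COMPLEX = "COMPLEX"
    OUTGROUP = "OUTGROUP"
    OTHER = "OTHER"


class SeqKind(str, Enum):
    NT = "NT"
    AA = "AA"


#: scleractinian corals split into the two deep primary lineages
SCLERACTINIAN_CLADES = frozenset({Clade.ROBUST, Clade.COMPLEX})

NT_ALPHABET = frozenset("ACGTN-")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX-")

_RC = str.maketrans("ACGTN", "TGCAN")

CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)


class FormatError(ValueError):
    """Raised for malformed input files or records."""


@dataclass(frozen=True)
class AnnotatedSequence:
    """One FASTA record with taxon and clade annotation.

    ``residues`` is the uppercase sequence; ``tags`` holds any further
    header key-value pairs (unknown tags are preserved, not interpreted).
    """

    id: str
    residues: str
    kind: SeqKind
    taxon: str = ""
    clade: Clade = Clade.OTHER
    tags: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"record id {self.id!r} is empty or has whitespace")
        if not self.residues:
            raise FormatError(f"record {self.id}: empty sequence")
        if not self.taxon:
            object.__setattr__(self, "taxon", self.id)
        alphabet = NT_ALPHABET if self.kind is SeqKind.NT else AA_ALPHABET
        for pos, ch in enumerate(self.residues):
            if ch not in alphabet:
                raise FormatError(
                    f"record {self.id}: illegal {self.kind.value} residue "
                    f"{ch!r} at position {pos + 1}"
                )

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ExonMap:
    """Exon coordinates on a gene-model coding sequence (0-based half-open)."""

    gene_id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        prev_end = 0
        for start, end in self.exons:
            if end - start < 1:
                raise ValueError(f"{self.gene_id}: empty exon ({start},{end})")
            if start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end

    @property
    def total_length(self) -> int:
        return self.exons[-1][1] if self.exons else 0


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_header(line: str) -> tuple[str, str, Clade, dict]:
    parts = line[1:].strip().split(None, 1)
    if not parts:
        raise FormatError("FASTA header with no id")
    rec_id = parts[0]
    taxon, clade, tags = "", Clade.OTHER, {}
    if len(parts) == 2:
        for item in parts[1].split(";"):
            item = item.strip()
            if not item or "=" not in item:
                continue
            key, value = item.split("=", 1)
            key = key.strip().lower()
            value = value.strip()
            if key == "taxon":
                taxon = value
            elif key == "clade":
                try:
                    clade = Clade(value.upper())
                except ValueError:
                    raise FormatError(
                        f"record {rec_id}: unknown clade {value!r}"
                    ) from None
            else:
                tags[key] = value
    return rec_id, taxon, clade, tags


def read_fasta(path, kind: SeqKind | str) -> list[AnnotatedSequence]:
    """Parse a FASTA file into :class:`AnnotatedSequence` records.

    Headers may carry ``taxon=...;clade=...`` tags after the id; untagged
    records get ``clade=OTHER`` and ``taxon=id``.
    """
    kind = SeqKind(kind)
    records: list[AnnotatedSequence] = []
    header: tuple | None = None
    chunks: list[str] = []

    def _flush():
        if header is None:
            return
        rec_id, taxon, clade, tags = header
        records.append(
            AnnotatedSequence(
                id=rec_id,
                residues="".join(chunks).upper(),
                kind=kind,
                taxon=taxon,
                clade=clade,
                tags=tags,
            )
        )

    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = _parse_header(line)
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}: sequence data before first header")
                chunks.append(line.strip())
    _flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Sequence[AnnotatedSequence], path, line_width: int = 80):
    """Write records as FASTA, encoding taxon/clade tags in the header."""
    if not records:
        raise FormatError("nothing to write: empty record set")
    if line_width < 1:
        raise ValueError("line_width must be positive")
    seen: set[str] = set()
    with _open_text(path, "wt") as fh:
        for rec in records:
            if rec.id in seen:
                raise FormatError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            tags = []
            if rec.taxon != rec.id:
                tags.append(f"taxon={rec.taxon}")
            if rec.clade is not Clade.OTHER:
                tags.append(f"clade={rec.clade.value}")
            for key in sorted(rec.tags):
                tags.append(f"{key}={rec.tags[key]}")
            header = ">" + rec.id + (" " + ";".join(tags) if tags else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), line_width):
                fh.write(rec.residues[i : i + line_width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    up = seq.upper()
    if not set(up) <= NT_ALPHABET - {"-"}:
        bad = sorted(set(up) - (NT_ALPHABET - {"-"}))
        raise FormatError(f"non-nucleotide characters in sequence: {bad}")
    return up.translate(_RC)[::-1]


def read_coverage_table(path) -> dict[str, float]:
    """Read a per-contig coverage TSV with header ``contig_id<TAB>coverage``."""
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
    if list(df.columns) != ["contig_id", "coverage"]:
        raise FormatError(
            f"{path}: expected header 'contig_id\\tcoverage', got {list(df.columns)}"
        )
    if df["contig_id"].duplicated().any():
        dup = df.loc[df["contig_id"].duplicated(), "contig_id"].iloc[0]
        raise FormatError(f"{path}: duplicate contig id {dup!r}")
    cov = pd.to_numeric(df["coverage"], errors="raise")
    if (cov < 0).any():
        bad = df.loc[cov < 0, "contig_id"].iloc[0]
        raise FormatError(f"{path}: negative coverage for {bad!r}")
    return dict(zip(df["contig_id"], cov.astype(float)))


def read_exon_maps(path) -> dict[str, ExonMap]:
    """Read BED-like exon maps: ``gene_id<TAB>start<TAB>end`` (0-based half-open)."""
    by_gene: dict[str, list[tuple[int, int]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab fields")
            gene, start, end = fields[0], int(fields[1]), int(fields[2])
            by_gene.setdefault(gene, []).append((start, end))
    return {
        gene: ExonMap(gene_id=gene, exons=tuple(sorted(exons)))
        for gene, exons in by_gene.items()
    }


def write_exon_maps(maps: Iterable[ExonMap], path):
    with _open_text(path, "wt") as fh:
        for em in maps:
            for start, end in em.exons:
                fh.write(f"{em.gene_id}\t{start}\t{end}\n")


def translate_cds(nt: str) -> str:
    """Translate an in-frame coding sequence; N-containing codons give X.

    A trailing stop codon is rendered as ``*``-free: it is the caller's job
    to strip stops; an internal stop raises.
    """
    if len(nt) % 3 != 0:
        raise FormatError(f"CDS length {len(nt)} not a multiple of 3")
    out = []
    n_codons = len(nt) // 3
    for i in range(n_codons):
        codon = nt[3 * i : 3 * i + 3].upper()
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                break  # trailing stop: stop translating, do not emit
            raise FormatError(f"internal stop codon {codon} at codon {i}")
        out.append(CODON_TO_AA.get(codon, "X"))
    return "".join(out)
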