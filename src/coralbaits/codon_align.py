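"""Codon-level nucleotide alignments from amino-acid alignments.

``back_translate`` expands each aligned amino-acid residue to its source
codon (and each gap to ``---``), so the nucleotide alignment always has
exactly three times the columns of the protein alignment and degapping a
row recovers the original coding sequence.  A translation mismatch aborts
rather than auto-correcting: a silent frame error would corrupt every
bait designed downstream.

The protein alignment itself is pluggable: pre-aligned input is accepted
as-is, and :func:`align_amino_acids` can shell out to mafft when rows
still need aligning.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .seqio import (
    STOP_CODONS,
    AnnotatedSequence,
    FormatError,
    SeqKind,
    read_fasta,
    translate_cds,
    write_fasta,
)


@dataclass
class CodonAlignment:
    """Aligned coding sequences for one locus (NT rows parallel to AA rows)."""

    locus_id: str
    rows: dict[str, str]
    aa_rows: dict[str, str]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.locus_id}: NT rows differ in length")
        aa_lengths = {len(r) for r in self.aa_rows.values()}
        if len(aa_lengths) > 1:
            raise ValueError(f"{self.locus_id}: AA rows differ in length")
        if lengths and aa_lengths and lengths.pop() != 3 * aa_lengths.pop():
            raise ValueError(f"{self.locus_id}: NT columns != 3 x AA columns")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)


def _strip_trailing_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:].upper() in STOP_CODONS:
        return cds[:-3]
    return cds


def back_translate(
    aa_alignment: Mapping[str, str],
    cds: Mapping[str, str],
    locus_id: str = "locus",
) -> CodonAlignment:
    """Expand a gapped AA alignment to its codon-level NT alignment.

    For each row, the ungapped AA length times three must equal the CDS
    length (after stripping a trailing stop codon) and the CDS must
    translate to the ungapped row under the standard code (X is tolerated
    at N-containing codons).
    """
    nt_rows: dict[str, str] = {}
    for taxon, aa_row in aa_alignment.items():
        if taxon not in cds:
            raise FormatError(f"{locus_id}: no coding sequence for {taxon}")
        coding = _strip_trailing_stop(cds[taxon].upper().replace("-", ""))
        aa_ungapped = aa_row.replace("-", "")
        if 3 * len(aa_ungapped) != len(coding):
            raise FormatError(
                f"{locus_id}, {taxon}: CDS length {len(coding)} does not match "
                f"{len(aa_ungapped)} aligned residues"
            )
        codons = [coding[3 * i : 3 * i + 3] for i in range(len(coding) // 3)]
        out = []
        idx = 0
        for aa in aa_row:
            if aa == "-":
                out.append("---")
                continue
            codon = codons[idx]
            expected = translate_cds(codon)
            observed = expected[0] if expected else "X"
            if observed != aa.upper() and not (aa.upper() == "X" and "N" in codon):
                raise FormatError(
                    f"{locus_id}, {taxon}: codon {idx} ({codon}) translates to "
                    f"{observed!r}, alignment has {aa!r}"
                )
            out.append(codon)
            idx += 1
        nt_rows[taxon] = "".join(out)
    return CodonAlignment(locus_id=locus_id, rows=nt_rows, aa_rows=dict(aa_alignment))


def is_aligned(rows: Mapping[str, str]) -> bool:
    return len({len(r) for r in rows.values()}) <= 1


def align_amino_acids(
    seqs: Mapping[str, str], method: str = "mafft"
) -> dict[str, str]:
    """Align AA sequences, preserving input row order.

    ``method='none'`` validates that rows are already equal length and
    returns them unchanged; ``method='mafft'`` shells out to the mafft
    executable (``--auto --quiet``).
    """
    if method == "none":
        if not is_aligned(seqs):
            raise FormatError("rows are not pre-aligned (unequal lengths)")
        return dict(seqs)
    if method != "mafft":
        raise ValueError(f"unknown alignment method {method!r}")
    records = [
        AnnotatedSequence(id=name, residues=seq.replace("-", ""), kind=SeqKind.AA)
        for name, seq in seqs.items()
    ]
    with tempfile.TemporaryDirectory() as tmp:
        in_path = Path(tmp) / "in.fasta"
        write_fasta(records, in_path)
        proc = subprocess.run(
            ["mafft", "--auto", "--quiet", str(in_path)],
            capture_output=True,
            text=True,
            check=True,
        )
        out_path = Path(tmp) / "out.fasta"
        out_path.write_text(proc.stdout)
        aligned = read_fasta(out_path, SeqKind.AA)
    result = {rec.id: rec.residues for rec in aligned}
    return {name: result[name] for name in seqs}
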