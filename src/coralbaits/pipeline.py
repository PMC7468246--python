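"""The two end-to-end workflows: design-time and post-capture.

``run_design``: orthogroup filtering -> codon alignment -> exon-aware bait
tiling -> bait screening, emitting the final probe FASTA (targets plus
coi/h3 barcode baits), a region manifest, the screen ledger and a
run-summary JSON with counts at every stage.

``run_postcapture``: barcode QC -> gene-tree curation -> supermatrix,
refusing to build the matrix when a sample looks misidentified unless
forced.

Workspace layout (as produced by :mod:`coralbaits.fixtures`):
``orthogroups/<locus>.{aa,nt}.fasta``, ``genomes/<G>.models.fasta`` +
``<G>.cds.fasta`` + ``<G>.exons.tsv``, ``contaminant_db.fasta``,
``symbiont_refs.fasta``, ``barcode_refs.fasta``, ``clades.tsv``, and
``postcapture/`` with ``samples.tsv``, ``samples/``, ``trees/``,
``loci/``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import bait_filter, qc_barcode
from .bait_design import (
    BaitLabel,
    BaitRegion,
    TilingScheme,
    design_barcode_baits,
    design_regions,
    best_region_per_locus,
)
from .codon_align import back_translate, CodonAlignment
from .genetree_filter import Criterion, curate_locus, read_gene_tree
from .ortho_filter import (
    Orthogroup,
    anchor_and_bin,
    remove_contaminant_transcripts,
    representation_filter,
)
from .seqio import (
    AnnotatedSequence,
    Clade,
    SeqKind,
    read_coverage_table,
    read_exon_maps,
    read_fasta,
    write_fasta,
)
from .supermatrix import (
    concatenate,
    matrix_stats,
    trim_alignment,
    write_matrix_fasta,
    write_matrix_phylip,
    write_partitions,
)

REF_ROW = "__ref__"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class QCFailure(RuntimeError):
    """A sample failed barcode identity verification."""


@dataclass
class DesignParams:
    min_taxa: int = 6
    min_per_clade: int = 2
    min_bit_score: float = 50.0
    anchor_evalue: float = 1e-6
    contaminant_identity: float = 80.0
    contaminant_length: int = 100
    contaminant_evalue: float = 1e-6
    gap_mode: str = "strict"
    max_gap_frac: float = 0.5
    multi_region: bool = True
    map_identity: float = 70.0
    map_length_frac: float = 0.70
    blast_evalue: float = 1e-4
    max_removed: int = 3
    min_remaining: int = 2
    min_rc_match: int = 21
    final_recheck: bool = True


@dataclass
class PostcaptureParams:
    barcode_min_identity: float = 98.0
    barcode_min_len: int = 200
    coverage_fold: float = 100.0
    min_support: float = 10.0
    long_branch_factor: float = 5.0
    min_scleractinians: int = 3
    min_pi_sites: int = 1
    trim_max_gap_frac: float = 0.8


def _load_orthogroups(workspace: Path) -> list[Orthogroup]:
    og_dir = workspace / "orthogroups"
    groups = []
    for aa_path in sorted(og_dir.glob("*.aa.fasta")):
        locus_id = aa_path.name[: -len(".aa.fasta")]
        nt_path = og_dir / f"{locus_id}.nt.fasta"
        if not nt_path.exists():
            raise StageError("load", f"{locus_id}: missing CDS file {nt_path.name}")
        groups.append(
            Orthogroup(
                id=locus_id,
                aa_members=tuple(read_fasta(aa_path, SeqKind.AA)),
                nt_members=tuple(read_fasta(nt_path, SeqKind.NT)),
            )
        )
    if not groups:
        raise StageError("load", f"no input loci under {og_dir}")
    return groups


def _load_genomes(workspace: Path):
    genome_dir = workspace / "genomes"
    gene_models: dict[str, list[AnnotatedSequence]] = {}
    model_cds: dict[str, str] = {}
    exon_maps = {}
    for models_path in sorted(genome_dir.glob("*.models.fasta")):
        genome = models_path.name[: -len(".models.fasta")]
        gene_models[genome] = read_fasta(models_path, SeqKind.AA)
        for rec in read_fasta(genome_dir / f"{genome}.cds.fasta", SeqKind.NT):
            model_cds[rec.id] = rec.residues
        exon_maps.update(read_exon_maps(genome_dir / f"{genome}.exons.tsv"))
    if not gene_models:
        raise StageError("load", f"no reference genomes under {genome_dir}")
    return gene_models, model_cds, exon_maps


def run_design(
    workspace: Path | str,
    outdir: Path | str,
    params: DesignParams | None = None,
    scheme_nt=None,
    scheme_aa=None,
) -> dict:
    """Execute the design workflow; returns (and writes) the run summary."""
    workspace, outdir = Path(workspace), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or DesignParams()

    groups = _load_orthogroups(workspace)
    gene_models, model_cds, exon_maps = _load_genomes(workspace)
    contaminant_db = read_fasta(workspace / "contaminant_db.fasta", SeqKind.NT)
    symbiont_refs = read_fasta(workspace / "symbiont_refs.fasta", SeqKind.NT)

    summary: dict = {"stage_counts": {"input_loci": len(groups)}}
    audit: list[dict] = []

    represented = []
    for og in groups:
        if representation_filter(og, params.min_taxa, params.min_per_clade):
            represented.append(og)
        else:
            audit.append({"locus": og.id, "action": "drop", "reason": "representation"})
    summary["stage_counts"]["represented"] = len(represented)

    anchored = []
    for og in represented:
        binned = anchor_and_bin(
            og, gene_models, params.min_bit_score, params.anchor_evalue, scheme_aa
        )
        if binned is None:
            audit.append({"locus": og.id, "action": "drop", "reason": "no_genome_anchor"})
        else:
            anchored.append(binned)
    summary["stage_counts"]["anchored"] = len(anchored)

    clean: list[Orthogroup] = []
    contaminant_removals: list[tuple[str, str]] = []
    for og in anchored:
        survivor, removed = remove_contaminant_transcripts(
            og,
            contaminant_db,
            params.contaminant_identity,
            params.contaminant_length,
            params.contaminant_evalue,
            params.min_taxa,
            scheme_nt,
        )
        for member_id, hit in removed:
            contaminant_removals.append((og.id, member_id))
            audit.append(
                {
                    "locus": og.id,
                    "action": "remove_member",
                    "reason": "non_cnidarian_best_hit",
                    "member": member_id,
                    "subject": hit.subject_id,
                    "identity_pct": round(hit.identity_pct, 2),
                    "aligned_length": hit.aligned_length,
                }
            )
        if survivor is None:
            audit.append({"locus": og.id, "action": "drop", "reason": "below_min_taxa"})
        else:
            clean.append(survivor)
    summary["stage_counts"]["post_contaminant"] = len(clean)
    summary["contaminant_removals"] = sorted(contaminant_removals)

    scheme = TilingScheme()
    regions: list[BaitRegion] = []
    for og in clean:
        aa_rows = {m.id: m.residues for m in og.aa_members}
        cds = {m.id: m.ungapped for m in og.nt_members}
        try:
            locus = back_translate(aa_rows, cds, locus_id=og.id)
        except Exception as exc:  # translation/frame error: skip with audit entry
            audit.append({"locus": og.id, "action": "drop", "reason": f"codon_align: {exc}"})
            continue
        ref_cds = model_cds.get(og.reference_gene)
        if ref_cds is None or len(ref_cds) != locus.length:
            audit.append(
                {"locus": og.id, "action": "drop", "reason": "reference_length_mismatch"}
            )
            continue
        rows = {REF_ROW: ref_cds, **locus.rows}
        aligned = CodonAlignment(locus_id=og.id, rows=rows, aa_rows={})
        locus_regions = design_regions(
            aligned,
            exon_maps[og.reference_gene],
            scheme,
            reference_row=REF_ROW,
            source_bin=og.bin,
            gap_mode=params.gap_mode,
            max_gap_frac=params.max_gap_frac,
            multi_region=params.multi_region,
        )
        if not locus_regions:
            audit.append({"locus": og.id, "action": "drop", "reason": "no_bait_window"})
            continue
        if not params.multi_region:
            locus_regions = [best_region_per_locus(locus_regions)]
        regions.extend(locus_regions)

    summary["stage_counts"]["loci_with_regions"] = len({r.locus_id for r in regions})
    summary["stage_counts"]["regions_designed"] = len(regions)

    barcode_path = workspace / "barcode_refs.fasta"
    if barcode_path.exists():
        barcode_refs = read_fasta(barcode_path, SeqKind.NT)
        for label in (BaitLabel.COI, BaitLabel.H3):
            rows = {
                r.taxon: r.residues
                for r in barcode_refs
                if r.tags.get("locus", "").lower() == label.value
            }
            if rows:
                regions.append(design_barcode_baits(rows, label, scheme))
    summary["stage_counts"]["baits_designed"] = sum(len(r.baits) for r in regions)

    surviving, report = bait_filter.run_screen(
        regions,
        symbiont_refs,
        params.map_identity,
        params.map_length_frac,
        params.blast_evalue,
        params.max_removed,
        params.min_remaining,
        params.min_rc_match,
        params.final_recheck,
        scheme_nt,
    )
    summary["stage_counts"]["baits_retained"] = report.n_surviving
    summary["stage_counts"]["regions_retained"] = len(surviving)
    summary["screen"] = {
        "n_input": report.n_input,
        "removed_by_reason": report.counts_by_reason(),
        "surviving_by_label": dict(sorted(report.surviving_by_label.items())),
    }
    symbiont_flagged = sorted(
        {
            bait_id.split("|", 1)[0]
            for bait_id, reason in report.removed_baits
            if reason in (bait_filter.RemovalReason.SYMBIONT_MAP,
                          bait_filter.RemovalReason.SYMBIONT_BLAST)
        }
        - {BaitLabel.COI.value, BaitLabel.H3.value}
    )
    summary["symbiont_flagged_loci"] = symbiont_flagged

    final_baits = [
        AnnotatedSequence(
            id=f"{b.bait_id}|{b.label.value}", residues=b.sequence, kind=SeqKind.NT
        )
        for r in surviving
        for b in r.baits
    ]
    if final_baits:
        write_fasta(final_baits, outdir / "baits.fasta")
    with open(outdir / "regions.tsv", "w") as fh:
        fh.write(
            "locus\tbin\twindow_start\twindow_end\twindow_length\tn_tiles"
            "\tn_baits\tmean_identity\tlabel\n"
        )
        for r in surviving:
            fh.write(
                f"{r.locus_id}\t{r.source_bin}\t{r.window_start}\t{r.window_end}"
                f"\t{r.window_length}\t{r.n_tiles}\t{len(r.baits)}"
                f"\t{r.mean_identity:.4f}\t{r.label.value}\n"
            )
    with open(outdir / "screen_ledger.tsv", "w") as fh:
        fh.write("kind\tid\treason\n")
        for bait_id, reason in report.removed_baits:
            fh.write(f"bait\t{bait_id}\t{reason.value}\n")
        for region_id, reason in report.removed_regions:
            fh.write(f"region\t{region_id}\t{reason.value}\n")
    pd.DataFrame(audit).to_csv(outdir / "audit_log.tsv", sep="\t", index=False)
    (outdir / "design_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )
    return summary


def _read_clades(path) -> dict[str, Clade]:
    df = pd.read_csv(path, sep="\t")
    return {row.taxon: Clade(row.clade) for row in df.itertuples()}


def run_postcapture(
    workspace: Path | str,
    outdir: Path | str,
    params: PostcaptureParams | None = None,
    force: bool = False,
) -> dict:
    """Execute the post-capture workflow; returns (and writes) the summary.

    Refuses to build the supermatrix when any sample is a misidentification
    suspect, unless ``force`` is set (the summary then carries a warning
    banner).
    """
    workspace, outdir = Path(workspace), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or PostcaptureParams()
    post = workspace / "postcapture"
    expected_clades = _read_clades(workspace / "clades.tsv")
    barcode_refs = read_fasta(workspace / "barcode_refs.fasta", SeqKind.NT)

    samples = pd.read_csv(post / "samples.tsv", sep="\t")
    reports = []
    coverage_rows = []
    for row in samples.itertuples():
        contigs = read_fasta(post / "samples" / f"{row.sample_id}.contigs.fasta", SeqKind.NT)
        coverages = read_coverage_table(post / "samples" / f"{row.sample_id}.coverage.tsv")
        for cid, cov in coverages.items():
            label = "COI" if cid.startswith("coi") else "H3" if cid.startswith("h3") else "TARGET"
            coverage_rows.append({"sample": row.sample_id, "label": label, "coverage": cov})
        for locus_label in ("coi", "h3"):
            refs = [r for r in barcode_refs if r.tags.get("locus") == locus_label]
            if not refs:
                continue
            reports.append(
                qc_barcode.barcode_check(
                    row.sample_id,
                    row.expected_taxon,
                    contigs,
                    coverages,
                    refs,
                    locus=locus_label,
                    min_identity=params.barcode_min_identity,
                    min_len=params.barcode_min_len,
                    coverage_fold=params.coverage_fold,
                )
            )

    suspects = [
        r for r in reports if r.verdict is qc_barcode.Verdict.MISIDENTIFIED_SUSPECT
    ]
    summary: dict = {
        "barcode_reports": [r.to_dict() for r in reports],
        "coverage_summary": qc_barcode.coverage_summary(pd.DataFrame(coverage_rows)),
        "warnings": [],
    }
    if suspects:
        names = sorted({f"{r.sample_id}/{r.locus}" for r in suspects})
        if not force:
            (outdir / "postcapture_summary.json").write_text(
                json.dumps(summary, indent=1, sort_keys=True)
            )
            raise QCFailure(f"misidentification suspects: {', '.join(names)}")
        summary["warnings"].append(
            f"FORCED past misidentification suspects: {', '.join(names)}"
        )

    removals: list[dict] = []
    dropped: list[dict] = []
    curated_loci = []
    for tree_path in sorted((post / "trees").glob("*.nwk")):
        locus_id = tree_path.stem
        tree = read_gene_tree(tree_path)
        seqs = {
            rec.id: rec.residues
            for rec in read_fasta(post / "loci" / f"{locus_id}.fasta", SeqKind.NT)
        }
        curated, log, drop_reason = curate_locus(
            locus_id,
            tree,
            seqs,
            expected_clades,
            params.min_support,
            params.long_branch_factor,
            params.min_scleractinians,
            params.min_pi_sites,
        )
        for tip, criterion in log:
            removals.append({"locus": locus_id, "tip": tip, "criterion": criterion.value})
        if curated is None:
            dropped.append({"locus": locus_id, "reason": drop_reason.value})
        else:
            curated_loci.append(curated)

    summary["removals"] = removals
    summary["dropped_loci"] = dropped
    summary["n_curated_loci"] = len(curated_loci)

    trimmed = []
    for locus in curated_loci:
        rows = trim_alignment(locus.sequences, params.trim_max_gap_frac)
        if rows is None:
            dropped.append({"locus": locus.locus_id, "reason": "TRIMMED_EMPTY"})
            continue
        trimmed.append((locus.locus_id, rows))

    taxa_universe = sorted(expected_clades)
    matrix = concatenate(trimmed, taxa_universe)
    stats = matrix_stats(matrix)
    summary["matrix_stats"] = stats
    write_matrix_fasta(matrix, outdir / "supermatrix.fasta")
    write_matrix_phylip(matrix, outdir / "supermatrix.phy")
    write_partitions(matrix, outdir / "partitions.txt")
    with open(outdir / "removal_log.tsv", "w") as fh:
        fh.write("locus\ttip\tcriterion\n")
        for entry in removals:
            fh.write(f"{entry['locus']}\t{entry['tip']}\t{entry['criterion']}\n")
    (outdir / "postcapture_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )
    return summary
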