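"""Deterministic synthetic-data generator with planted ground truth.

Emulates the pipeline's entire input universe at desk scale: orthogroup
alignments across a ((Robust),(Complex),Outgroup) taxon set evolved under
an equal-rates substitution model (no indels within coding positions; gap
structure arises from lineage-specific exon presence), reference-genome
gene models with exon maps, a labelled contaminant-screen database,
symbiont references, barcode references, and the post-capture inputs
(per-sample contigs with coverages, gene trees, per-locus alignments).

Every planted anomaly — non-cnidarian transcripts, symbiont-derived
segments, gene-tree misplacements, taxon-local paralog copies, a barcode
cross-contaminant — is listed exactly once in the truth ledger, and
recovery by the pipeline is measured against that ledger.

Planted symbiont segments span 80 codons (240 nt): a full-window verbatim
block pins the bait-window search (mean pairwise identity exactly 1
inside it), so detection by the symbiont screen is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .seqio import (
    STOP_CODONS,
    AnnotatedSequence,
    Clade,
    SeqKind,
    translate_cds,
    write_exon_maps,
    write_fasta,
    ExonMap,
)

BASES = "ACGT"
CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)


@dataclass
class FixtureConfig:
    """All knobs of the synthetic study; the seed fixes every random draw."""

    seed: int = 42
    n_robust: int = 8
    n_complex: int = 8
    n_outgroup: int = 4
    n_loci: int = 60
    locus_length_range: tuple[int, int] = (60, 200)  # codons
    tree_depth: float = 0.10  # expected substitutions/site, root -> clade
    within_clade_depth: float = 0.03
    outgroup_depth_factor: float = 1.5
    contaminant_fraction: float = 0.10
    contaminant_divergence: float = 0.05
    symbiont_insert_fraction: float = 0.10
    symbiont_insert_codons: int = 80
    paralog_fraction: float = 0.10
    exon_break_prob: float = 0.01  # per codon junction
    long_exon_fraction: float = 0.7
    exon_dropout_prob: float = 0.15
    n_genomes: int = 3
    n_symbiont_refs: int = 6
    symbiont_ref_length: int = 3000
    dropout: float = 0.10  # per taxon per locus at capture
    n_misplaced: int = 3
    cross_contam_ratio: float = 150.0
    barcode_divergence: float = 0.06
    low_support_prob: float = 0.05

    def __post_init__(self):
        for name in (
            "contaminant_fraction",
            "symbiont_insert_fraction",
            "paralog_fraction",
            "dropout",
            "exon_dropout_prob",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if min(self.n_robust, self.n_complex, self.n_outgroup, self.n_loci) < 0:
            raise ValueError("counts must be nonnegative")

    def taxa(self) -> dict[str, Clade]:
        out: dict[str, Clade] = {}
        for i in range(self.n_robust):
            out[f"Rob{i + 1:02d}"] = Clade.ROBUST
        for i in range(self.n_complex):
            out[f"Com{i + 1:02d}"] = Clade.COMPLEX
        for i in range(self.n_outgroup):
            out[f"Out{i + 1:02d}"] = Clade.OUTGROUP
        return out


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(CODONS), size=n_codons)
    return "".join(CODONS[i] for i in idx)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _repair_stops(seq: str) -> str:
    # TAA/TAG -> TAC, TGA -> TGC: setting the third base to C removes every stop
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    return "".join(c[:2] + "C" if c in STOP_CODONS else c for c in codons)


def _mutate(rng: np.random.Generator, seq: str, rate: float, coding: bool = True) -> str:
    arr = list(seq)
    for i in np.flatnonzero(rng.random(len(arr)) < rate):
        choices = [b for b in BASES if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    out = "".join(arr)
    return _repair_stops(out) if coding else out


def _exon_breaks(rng, n_codons: int, break_prob: float, ensure_long: bool) -> list[int]:
    """Codon-junction break positions; optionally guarantee an exon >= 85 codons."""
    breaks = [j for j in range(1, n_codons) if rng.random() < break_prob]
    if ensure_long and breaks:
        spans = np.diff([0, *breaks, n_codons])
        if spans.max() < 85:
            breaks = [b for b in breaks if b >= 85]
    return breaks


@dataclass
class _Locus:
    """Internal bookkeeping for one simulated locus."""

    locus_id: str
    n_codons: int
    root: str
    genome: str
    gene_id: str
    model: str
    exon_bounds: list[int]  # codon boundaries incl. 0 and n_codons
    member_genes: dict[str, str] = field(default_factory=dict)  # full genes
    missing_exons: dict[str, set[int]] = field(default_factory=dict)  # clade -> exon idx
    contaminant_member: str | None = None
    contaminant_backbone: str | None = None
    insert: tuple[int, int] | None = None  # codon span of symbiont insert

    @property
    def exon_spans_codons(self) -> list[tuple[int, int]]:
        return list(zip(self.exon_bounds[:-1], self.exon_bounds[1:]))

    def missing_for(self, clade: Clade) -> set[int]:
        return self.missing_exons.get(clade.value, set())

    def aligned_nt_row(self, taxon: str, clade: Clade, gene: str | None = None) -> str:
        gene = gene if gene is not None else self.member_genes[taxon]
        missing = self.missing_for(clade)
        out = []
        for e_idx, (cs, ce) in enumerate(self.exon_spans_codons):
            if e_idx in missing:
                out.append("-" * (3 * (ce - cs)))
            else:
                out.append(gene[3 * cs : 3 * ce])
        return "".join(out)

    def cds(self, taxon: str, clade: Clade) -> str:
        return self.aligned_nt_row(taxon, clade).replace("-", "")

    def aligned_aa_row(self, taxon: str, clade: Clade) -> str:
        aa_full = translate_cds(self.member_genes[taxon])
        missing = self.missing_for(clade)
        out = []
        for e_idx, (cs, ce) in enumerate(self.exon_spans_codons):
            if e_idx in missing:
                out.append("-" * (ce - cs))
            else:
                out.append(aa_full[cs:ce])
        return "".join(out)


def simulate_orthogroups(cfg: FixtureConfig, outdir: Path | str) -> dict:
    """Write the design-time workspace; returns the truth ledger (also saved).

    Layout under ``outdir``: ``orthogroups/`` (per-locus AA alignment +
    CDS FASTA), ``genomes/`` (per-genome protein/CDS FASTA + exon TSV),
    ``contaminant_db.fasta``, ``symbiont_refs.fasta``,
    ``barcode_refs.fasta``, ``clades.tsv``, ``truth.json``.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(cfg.seed)
    taxa = cfg.taxa()
    scler = [t for t, c in taxa.items() if c in (Clade.ROBUST, Clade.COMPLEX)]

    lo, hi = cfg.locus_length_range
    loci: list[_Locus] = []
    for i in range(cfg.n_loci):
        locus_id = f"OG{i:04d}"
        n_codons = int(rng.integers(lo, hi + 1))
        root = _random_cds(rng, n_codons)
        genome = f"G{i % cfg.n_genomes + 1}"
        model = _mutate(rng, root, 0.02)
        ensure_long = bool(rng.random() < cfg.long_exon_fraction)
        breaks = _exon_breaks(rng, n_codons, cfg.exon_break_prob, ensure_long)
        bounds = [0, *breaks, n_codons]

        locus = _Locus(
            locus_id=locus_id,
            n_codons=n_codons,
            root=root,
            genome=genome,
            gene_id=f"g{i:04d}",
            model=model,
            exon_bounds=bounds,
        )

        anc = {
            Clade.ROBUST: _mutate(rng, root, cfg.tree_depth),
            Clade.COMPLEX: _mutate(rng, root, cfg.tree_depth),
            Clade.OUTGROUP: _mutate(rng, root, cfg.tree_depth * cfg.outgroup_depth_factor),
        }
        for taxon, clade in taxa.items():
            locus.member_genes[taxon] = _mutate(rng, anc[clade], cfg.within_clade_depth)

        # lineage-specific exon absence (never the largest exon, so the
        # best bait window of the locus is always fully present)
        spans = locus.exon_spans_codons
        if len(spans) >= 2 and rng.random() < cfg.exon_dropout_prob:
            largest = max(range(len(spans)), key=lambda k: spans[k][1] - spans[k][0])
            candidates = [k for k in range(len(spans)) if k != largest]
            clade = [Clade.ROBUST, Clade.COMPLEX, Clade.OUTGROUP][rng.integers(3)]
            locus.missing_exons[clade.value] = {candidates[rng.integers(len(candidates))]}
        loci.append(locus)

    perm = [int(j) for j in rng.permutation(cfg.n_loci)]
    n_cont = int(cfg.contaminant_fraction * cfg.n_loci)
    n_sym = int(cfg.symbiont_insert_fraction * cfg.n_loci)

    contaminants = []
    for j in perm[:n_cont]:
        locus = loci[j]
        victim = scler[rng.integers(len(scler))]
        backbone = _random_cds(rng, locus.n_codons)
        locus.contaminant_member = victim
        locus.contaminant_backbone = backbone
        locus.member_genes[victim] = _mutate(rng, backbone, cfg.contaminant_divergence)
        contaminants.append({"locus": locus.locus_id, "member": victim})

    k = cfg.symbiont_insert_codons
    symbiont_loci = []
    pool = [
        j
        for j in perm[n_cont:]
        if _insert_position(loci[j], k) is not None
    ]
    for j in pool[:n_sym]:
        locus = loci[j]
        start = _insert_position(locus, k)
        insert = _random_cds(rng, k)
        for taxon in locus.member_genes:
            gene = locus.member_genes[taxon]
            locus.member_genes[taxon] = gene[: 3 * start] + insert + gene[3 * (start + k) :]
        locus.insert = (start, start + k)
        symbiont_loci.append(
            {
                "locus": locus.locus_id,
                "insert_start": 3 * start,
                "insert_end": 3 * (start + k),
                "insert": insert,
            }
        )

    _write_design_workspace(cfg, outdir, rng, taxa, loci, symbiont_loci)

    truth = {
        "config": asdict(cfg),
        "taxa": {t: c.value for t, c in taxa.items()},
        "genome_of_locus": {l.locus_id: l.genome for l in loci},
        "reference_gene": {l.locus_id: l.gene_id for l in loci},
        "contaminants": contaminants,
        "symbiont_loci": symbiont_loci,
        "loci": [l.locus_id for l in loci],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    # keep internal state for simulate_capture without re-deriving
    truth["_loci_objects"] = loci
    truth["_rng"] = rng
    return truth


def _largest_exon(locus: _Locus) -> int:
    return max(ce - cs for cs, ce in locus.exon_spans_codons)


#: codons of contiguous native sequence that must survive a symbiont
#: insertion so the locus still anchors to its gene model
_MIN_NATIVE_RUN = 55


def _insert_position(locus: _Locus, k: int) -> int | None:
    """Codon start for a symbiont insert, or None if the locus is unsuitable.

    The insert must sit wholly inside the largest exon and is placed flush
    against the exon end that leaves the longest contiguous run of native
    codons (so members still anchor to the gene model after replacement).
    """
    spans = locus.exon_spans_codons
    e_idx = max(range(len(spans)), key=lambda q: spans[q][1] - spans[q][0])
    cs, ce = spans[e_idx]
    if ce - cs < k:
        return None
    n = locus.n_codons
    candidates = {cs, ce - k}
    best = max(candidates, key=lambda s: max(s, n - s - k))
    if max(best, n - best - k) < _MIN_NATIVE_RUN:
        return None
    return best


def _write_design_workspace(cfg, outdir, rng, taxa, loci, symbiont_loci):
    og_dir = outdir / "orthogroups"
    genome_dir = outdir / "genomes"
    og_dir.mkdir(parents=True, exist_ok=True)
    genome_dir.mkdir(parents=True, exist_ok=True)

    for locus in loci:
        aa_records, nt_records = [], []
        for taxon, clade in taxa.items():
            aa_records.append(
                AnnotatedSequence(
                    id=taxon,
                    residues=locus.aligned_aa_row(taxon, clade),
                    kind=SeqKind.AA,
                    taxon=taxon,
                    clade=clade,
                )
            )
            nt_records.append(
                AnnotatedSequence(
                    id=taxon,
                    residues=locus.cds(taxon, clade),
                    kind=SeqKind.NT,
                    taxon=taxon,
                    clade=clade,
                )
            )
        write_fasta(aa_records, og_dir / f"{locus.locus_id}.aa.fasta")
        write_fasta(nt_records, og_dir / f"{locus.locus_id}.nt.fasta")

    by_genome: dict[str, list[_Locus]] = {}
    for locus in loci:
        by_genome.setdefault(locus.genome, []).append(locus)
    for genome in sorted(by_genome):
        models_aa, models_nt, exon_maps = [], [], []
        for locus in by_genome[genome]:
            models_aa.append(
                AnnotatedSequence(
                    id=locus.gene_id, residues=translate_cds(locus.model), kind=SeqKind.AA
                )
            )
            models_nt.append(
                AnnotatedSequence(id=locus.gene_id, residues=locus.model, kind=SeqKind.NT)
            )
            exon_maps.append(
                ExonMap(
                    gene_id=locus.gene_id,
                    exons=tuple(
                        (3 * cs, 3 * ce) for cs, ce in locus.exon_spans_codons
                    ),
                )
            )
        write_fasta(models_aa, genome_dir / f"{genome}.models.fasta")
        write_fasta(models_nt, genome_dir / f"{genome}.cds.fasta")
        write_exon_maps(exon_maps, genome_dir / f"{genome}.exons.tsv")

    db_records = []
    for locus in loci:
        db_records.append(
            AnnotatedSequence(
                id=f"db_{locus.locus_id}_cnid",
                residues=locus.root,
                kind=SeqKind.NT,
                tags={"source": "cnidarian"},
            )
        )
        if locus.contaminant_backbone is not None:
            db_records.append(
                AnnotatedSequence(
                    id=f"db_{locus.locus_id}_noncnid",
                    residues=locus.contaminant_backbone,
                    kind=SeqKind.NT,
                    tags={"source": "non-cnidarian"},
                )
            )
    write_fasta(db_records, outdir / "contaminant_db.fasta")

    refs = [_random_nt(rng, cfg.symbiont_ref_length) for _ in range(cfg.n_symbiont_refs)]
    for j, entry in enumerate(symbiont_loci):
        insert = entry["insert"]
        r = j % len(refs)
        pos = int(rng.integers(0, cfg.symbiont_ref_length - len(insert)))
        refs[r] = refs[r][:pos] + insert + refs[r][pos + len(insert) :]
    write_fasta(
        [
            AnnotatedSequence(id=f"sym{r + 1}", residues=refs[r], kind=SeqKind.NT)
            for r in range(len(refs))
        ],
        outdir / "symbiont_refs.fasta",
    )

    barcode_records = []
    for locus_name, length in (("coi", 660), ("h3", 360)):
        root = _random_nt(rng, length)
        for taxon in taxa:
            barcode_records.append(
                AnnotatedSequence(
                    id=f"{locus_name}_{taxon}",
                    residues=_mutate(rng, root, cfg.barcode_divergence, coding=False),
                    kind=SeqKind.NT,
                    taxon=taxon,
                    tags={"locus": locus_name},
                )
            )
    write_fasta(barcode_records, outdir / "barcode_refs.fasta")

    with open(outdir / "clades.tsv", "w") as fh:
        fh.write("taxon\tclade\n")
        for taxon, clade in taxa.items():
            fh.write(f"{taxon}\t{clade.value}\n")


# ---------------------------------------------------------------------------
# post-capture inputs


def _subtree_newick(tips, rng, cfg) -> str:
    if len(tips) == 1:
        return f"{tips[0]}:{rng.uniform(0.02, 0.08):.4f}"
    split = int(rng.integers(1, len(tips)))
    left = _subtree_newick(tips[:split], rng, cfg)
    right = _subtree_newick(tips[split:], rng, cfg)
    if rng.random() < cfg.low_support_prob:
        support = int(rng.integers(0, 10))
    else:
        support = int(rng.integers(60, 101))
    return f"({left},{right}){support}:{rng.uniform(0.01, 0.05):.4f}"


def _clade_newick(tips, rng, cfg) -> str:
    tips = [tips[i] for i in rng.permutation(len(tips))]
    if len(tips) == 1:
        return f"{tips[0]}:{rng.uniform(0.02, 0.08):.4f}"
    split = max(int(rng.integers(1, len(tips))), 1)
    left = _subtree_newick(tips[:split], rng, cfg)
    right = _subtree_newick(tips[split:], rng, cfg)
    return f"({left},{right})100:{rng.uniform(0.04, 0.08):.4f}"


def simulate_capture(cfg: FixtureConfig, outdir: Path | str, truth: dict) -> dict:
    """Write post-capture inputs; extends and re-saves the truth ledger.

    Per-sample contig FASTA + coverage TSV (with one planted barcode
    cross-contaminant), per-locus gene trees with planted misplacements
    and paralog copies, per-locus alignments, and the sample sheet.
    """
    outdir = Path(outdir)
    loci: list[_Locus] = truth["_loci_objects"]
    rng: np.random.Generator = truth["_rng"]
    taxa = cfg.taxa()
    scler = [t for t, c in taxa.items() if c in (Clade.ROBUST, Clade.COMPLEX)]

    post = outdir / "postcapture"
    (post / "samples").mkdir(parents=True, exist_ok=True)
    (post / "trees").mkdir(parents=True, exist_ok=True)
    (post / "loci").mkdir(parents=True, exist_ok=True)

    planted_so_far = {e["locus"] for e in truth["contaminants"]} | {
        e["locus"] for e in truth["symbiont_loci"]
    }
    free = [l for l in loci if l.locus_id not in planted_so_far]
    order = [int(i) for i in rng.permutation(len(free))]

    misplaced = []
    for j in order[: cfg.n_misplaced]:
        locus = free[j]
        taxon = scler[rng.integers(len(scler))]
        misplaced.append({"locus": locus.locus_id, "taxon": taxon})
    misplaced_by_locus = {e["locus"]: e["taxon"] for e in misplaced}

    n_paralog = int(cfg.paralog_fraction * cfg.n_loci)
    paralogs = []
    for idx, j in enumerate(order[cfg.n_misplaced : cfg.n_misplaced + n_paralog]):
        locus = free[j]
        taxon = scler[rng.integers(len(scler))]
        tags = ("main", "0.0") if idx % 2 == 0 else ("0.0", "0.1")
        paralogs.append(
            {
                "locus": locus.locus_id,
                "taxon": taxon,
                "kept": f"{taxon}.{tags[0]}",
                "removed": [f"{taxon}.{tags[1]}"],
            }
        )
    paralog_by_locus = {e["locus"]: e for e in paralogs}

    captured: dict[str, list[str]] = {}
    for locus in loci:
        protected = set()
        if locus.locus_id in misplaced_by_locus:
            protected.add(misplaced_by_locus[locus.locus_id])
        if locus.locus_id in paralog_by_locus:
            protected.add(paralog_by_locus[locus.locus_id]["taxon"])
        present = [
            t for t in taxa if t in protected or rng.random() >= cfg.dropout
        ]
        # keep each major clade readable in the gene tree: top up to at
        # least three captured taxa per scleractinian clade
        for clade in (Clade.ROBUST, Clade.COMPLEX):
            have = [t for t in present if taxa[t] is clade]
            missing = [t for t in taxa if taxa[t] is clade and t not in present]
            while len(have) < 3 and missing:
                pick = missing.pop(int(rng.integers(len(missing))))
                present.append(pick)
                have.append(pick)
        present = [t for t in taxa if t in present]

        tips: list[str] = []
        rows: dict[str, str] = {}
        par = paralog_by_locus.get(locus.locus_id)
        for taxon in present:
            clade = taxa[taxon]
            row = locus.aligned_nt_row(taxon, clade)
            if par and taxon == par["taxon"]:
                second = _mutate(rng, locus.member_genes[taxon], 0.01)
                tips.extend([par["kept"], par["removed"][0]])
                rows[par["kept"]] = row
                rows[par["removed"][0]] = locus.aligned_nt_row(taxon, clade, gene=second)
            else:
                tips.append(taxon)
                rows[taxon] = row
        captured[locus.locus_id] = tips

        rec = [
            AnnotatedSequence(id=tip, residues=rows[tip], kind=SeqKind.NT)
            for tip in tips
        ]
        write_fasta(rec, post / "loci" / f"{locus.locus_id}.fasta")

        robust = [t for t in tips if taxa[parse_base(t)] is Clade.ROBUST]
        complx = [t for t in tips if taxa[parse_base(t)] is Clade.COMPLEX]
        outg = [t for t in tips if taxa[parse_base(t)] is Clade.OUTGROUP]
        bad = misplaced_by_locus.get(locus.locus_id)
        if bad is not None:
            wrong = complx if taxa[bad] is Clade.ROBUST else robust
            right = robust if taxa[bad] is Clade.ROBUST else complx
            right.remove(bad)
            wrong.append(bad)
            rng.shuffle(wrong)
        parts = [
            _clade_newick(group, rng, cfg)
            for group in (robust, complx, outg)
            if group
        ]
        (post / "trees" / f"{locus.locus_id}.nwk").write_text(
            "(" + ",".join(parts) + ");\n"
        )

    # barcode references were written by simulate_orthogroups; reload taxa refs
    from .seqio import read_fasta

    barcode_refs = read_fasta(outdir / "barcode_refs.fasta", SeqKind.NT)
    ref_by_key = {(r.tags["locus"], r.taxon): r.residues for r in barcode_refs}

    contaminated_sample = scler[rng.integers(len(scler))]
    donors = [t for t in scler if t != contaminated_sample]
    donor = donors[rng.integers(len(donors))]
    barcode_contaminant = {
        "sample": contaminated_sample,
        "donor": donor,
        "locus": "coi",
        "ratio": cfg.cross_contam_ratio,
    }

    with open(post / "samples.tsv", "w") as fh:
        fh.write("sample_id\texpected_taxon\n")
        for taxon in taxa:
            fh.write(f"{taxon}\t{taxon}\n")

    for taxon, clade in taxa.items():
        contigs = []
        coverages: dict[str, float] = {}
        coi_cov = float(np.round(rng.uniform(2500, 3500), 1))
        h3_cov = float(np.round(rng.uniform(2500, 3500), 1))
        contigs.append(
            AnnotatedSequence(
                id="coi_self", residues=ref_by_key[("coi", taxon)], kind=SeqKind.NT
            )
        )
        coverages["coi_self"] = coi_cov
        contigs.append(
            AnnotatedSequence(
                id="h3_self", residues=ref_by_key[("h3", taxon)], kind=SeqKind.NT
            )
        )
        coverages["h3_self"] = h3_cov
        if taxon == contaminated_sample:
            contigs.append(
                AnnotatedSequence(
                    id="coi_contam",
                    residues=ref_by_key[("coi", donor)],
                    kind=SeqKind.NT,
                )
            )
            coverages["coi_contam"] = float(
                np.round(coi_cov / cfg.cross_contam_ratio, 3)
            )
        for locus in loci:
            tips = captured[locus.locus_id]
            if taxon not in tips:
                continue
            cid = f"t_{locus.locus_id}"
            contigs.append(
                AnnotatedSequence(
                    id=cid, residues=locus.cds(taxon, clade), kind=SeqKind.NT
                )
            )
            coverages[cid] = float(np.round(max(rng.normal(2200, 600), 100.0), 1))
        write_fasta(contigs, post / "samples" / f"{taxon}.contigs.fasta")
        with open(post / "samples" / f"{taxon}.coverage.tsv", "w") as fh:
            fh.write("contig_id\tcoverage\n")
            for cid, cov in coverages.items():
                fh.write(f"{cid}\t{cov}\n")

    truth["misplaced"] = misplaced
    truth["paralogs"] = paralogs
    truth["barcode_contaminant"] = barcode_contaminant
    truth["captured"] = captured

    persisted = {k: v for k, v in truth.items() if not k.startswith("_")}
    (outdir / "truth.json").write_text(json.dumps(persisted, indent=1, sort_keys=True))
    return truth


def parse_base(tip: str) -> str:
    return tip.split(".", 1)[0]


def make_workspace(cfg: FixtureConfig, outdir: Path | str) -> dict:
    """Materialise a complete test workspace (design + post-capture inputs)."""
    truth = simulate_orthogroups(cfg, outdir)
    return simulate_capture(cfg, outdir, truth)


def load_truth(workspace: Path | str) -> dict:
    return json.loads((Path(workspace) / "truth.json").read_text())


def _prf(expected: set, found: set) -> dict[str, float]:
    tp = len(expected & found)
    precision = tp / len(found) if found else (1.0 if not expected else 0.0)
    recall = tp / len(expected) if expected else 1.0
    return {"precision": precision, "recall": recall, "n_expected": len(expected), "n_found": len(found)}


def evaluate_design(truth: dict, design_summary: dict) -> dict:
    """Planted-anomaly recovery scores for the design workflow."""
    expected_cont = {(e["locus"], e["member"]) for e in truth["contaminants"]}
    found_cont = {tuple(x) for x in design_summary["contaminant_removals"]}
    expected_sym = {e["locus"] for e in truth["symbiont_loci"]}
    found_sym = set(design_summary["symbiont_flagged_loci"])
    return {
        "contaminants": _prf(expected_cont, found_cont),
        "symbiont_loci": _prf(expected_sym, found_sym),
    }


def evaluate_postcapture(truth: dict, post_summary: dict) -> dict:
    """Planted-anomaly recovery scores for the post-capture workflow."""
    expected_mis = {(e["locus"], e["taxon"]) for e in truth["misplaced"]}
    found_mis = {
        (entry["locus"], parse_base(entry["tip"]))
        for entry in post_summary["removals"]
        if entry["criterion"] == "CRIT_B"
    }
    expected_par = {
        (e["locus"], tip) for e in truth["paralogs"] for tip in e["removed"]
    }
    found_par = {
        (entry["locus"], entry["tip"])
        for entry in post_summary["removals"]
        if entry["criterion"] == "PARALOG_RESOLVED"
    }
    verdicts = {
        (r["sample_id"], r["locus"]): r["verdict"] for r in post_summary["barcode_reports"]
    }
    bc = truth["barcode_contaminant"]
    contaminated = [
        r
        for r in post_summary["barcode_reports"]
        if r["sample_id"] == bc["sample"] and r["locus"] == bc["locus"]
    ]
    contaminant_entries = (
        [
            h
            for h in contaminated[0]["hits"]
            if h["status"] == "CONTAMINANT_DETECTED"
        ]
        if contaminated
        else []
    )
    return {
        "misplaced": _prf(expected_mis, found_mis),
        "paralogs": _prf(expected_par, found_par),
        "all_verified": all(v == "VERIFIED" for v in verdicts.values()),
        "n_verified": sum(1 for v in verdicts.values() if v == "VERIFIED"),
        "n_reports": len(verdicts),
        "contaminant_entries": contaminant_entries,
    }
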