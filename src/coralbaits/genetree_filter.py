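"""Gene-tree-based curation of captured loci.

Tip labels are ``<taxon>`` or ``<taxon>.<tag>`` where the tag marks
assembler paralog copies (``main``, ``0.0``, ``0.1``, ...).  Curation
proceeds per locus: low-support branches are collapsed to polytomies,
loci showing type II paralogy (a duplication deeper than the taxon level)
are dropped whole, taxon-local (type I) paralogs are resolved by keeping
the ``.main`` copy (else ``0.0``, else the untagged copy), and three
contamination criteria prune individual tips:

(a) a paralogous taxon with copies observed in different major clades
    loses the copy outside its expected clade;
(b) a single-copy taxon observed in the wrong major clade is removed;
(c) a tip with a pendant branch longer than ``factor`` times the median
    pendant branch is removed (computed on the pre-removal tree).

A tip's *observed* major clade is read from the smallest enclosing clade
with at least three other tips — an algorithmic stand-in for reading the
neighbourhood off a plotted tree.  The call is made only when the
scleractinian neighbours are unanimous: a tip truly nested in a foreign
clade is surrounded by it, whereas a tip that merely sits with a small
party of its own clade (e.g. low locus occupancy) has a mixed
neighbourhood and stays unjudged (kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from statistics import median
from typing import Mapping, Sequence

import dendropy

from .seqio import Clade, SCLERACTINIAN_CLADES


class Criterion(str, Enum):
    PARALOG_TYPE2_LOCUS = "PARALOG_TYPE2_LOCUS"
    PARALOG_RESOLVED = "PARALOG_RESOLVED"
    CRIT_A = "CRIT_A"
    CRIT_B = "CRIT_B"
    CRIT_C = "CRIT_C"
    LOW_TAXA = "LOW_TAXA"
    UNINFORMATIVE = "UNINFORMATIVE"


@dataclass
class CuratedLocus:
    """Per-locus taxon -> sequence map after curation, plus the removal log."""

    locus_id: str
    sequences: dict[str, str]
    removal_log: list[tuple[str, Criterion]] = field(default_factory=list)


def parse_tip(label: str) -> tuple[str, str | None]:
    """Split a tip label into (taxon, paralog tag)."""
    if "." in label:
        taxon, tag = label.split(".", 1)
        return taxon, tag
    return label, None


def read_gene_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def _support_of(node) -> float | None:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def collapse_low_support(tree: dendropy.Tree, min_support: float = 10.0) -> dendropy.Tree:
    """Contract internal edges with support below the threshold to polytomies.

    Absent support keeps the edge.  The tip set is unchanged; the input
    tree is not modified.
    """
    out = tree.clone(depth=1)
    to_collapse = []
    for node in out.preorder_internal_node_iter(exclude_seed_node=True):
        support = _support_of(node)
        if support is not None and support < min_support:
            to_collapse.append(node.edge)
    for edge in to_collapse:
        edge.collapse()
    return out


def resolve_type1_paralogs(
    sequences: Mapping[str, str],
    strict: bool = True,
) -> tuple[dict[str, str], list[tuple[str, Criterion]]]:
    """Keep one copy per taxon: ``.main``, else ``.0.0``, else untagged.

    Returns ({taxon: kept tip label}, removal log).  A taxon with copies
    but none of those three forms is ill-formed input under ``strict``;
    with ``strict=False`` (used after contamination pruning, which may
    have removed the preferred copy) the lexicographically smallest
    remaining tag is kept instead.
    """
    by_taxon: dict[str, dict[str | None, str]] = {}
    order: list[str] = []
    for label in sequences:
        taxon, tag = parse_tip(label)
        if taxon not in by_taxon:
            order.append(taxon)
        by_taxon.setdefault(taxon, {})[tag] = label

    kept: dict[str, str] = {}
    removed: list[tuple[str, Criterion]] = []
    for taxon in order:
        copies = by_taxon[taxon]
        for preferred in ("main", "0.0", None):
            if preferred in copies:
                kept[taxon] = copies[preferred]
                break
        else:
            if strict:
                raise ValueError(
                    f"taxon {taxon}: copies {sorted(filter(None, copies))} include "
                    "neither '.main', '.0.0' nor an untagged copy"
                )
            kept[taxon] = copies[min(copies, key=str)]
        for tag, label in copies.items():
            if label != kept[taxon]:
                removed.append((label, Criterion.PARALOG_RESOLVED))
    return kept, removed


def _leaf_labels(node) -> list[str]:
    return [leaf.taxon.label for leaf in node.leaf_iter()]


def flag_type2_paralogy(tree: dendropy.Tree) -> bool:
    """True when a duplication deeper than the taxon level is visible.

    Operationalised as: some internal edge has at least two multi-copy
    taxa with copies on both of its sides, i.e. the copies partition into
    two clades that each span multiple taxa.
    """
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(leaves) < 4:
        return False
    copies_per_taxon: dict[str, int] = {}
    for label in leaves:
        taxon, _ = parse_tip(label)
        copies_per_taxon[taxon] = copies_per_taxon.get(taxon, 0) + 1
    multi = {t for t, n in copies_per_taxon.items() if n >= 2}
    if len(multi) < 2:
        return False
    total = {t: n for t, n in copies_per_taxon.items()}
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        inside: dict[str, int] = {}
        for label in _leaf_labels(node):
            taxon, _ = parse_tip(label)
            inside[taxon] = inside.get(taxon, 0) + 1
        straddling = sum(
            1 for t in multi if 0 < inside.get(t, 0) < total[t]
        )
        if straddling >= 2:
            return True
    return False


def _rooted_copy(tree: dendropy.Tree, expected_clades: Mapping[str, Clade]) -> dendropy.Tree:
    out = tree.clone(depth=1)
    out.is_rooted = True
    outgroup = [
        leaf
        for leaf in out.leaf_node_iter()
        if expected_clades.get(parse_tip(leaf.taxon.label)[0]) is Clade.OUTGROUP
    ]
    try:
        if outgroup:
            mrca = out.mrca(taxa=[l.taxon for l in outgroup])
            if mrca is not out.seed_node:
                out.reroot_at_edge(mrca.edge, update_bipartitions=False)
        else:
            out.reroot_at_midpoint(update_bipartitions=False)
    except (ValueError, AssertionError):
        pass  # degenerate trees keep their input rooting
    return out


def observed_clades(
    tree: dendropy.Tree,
    expected_clades: Mapping[str, Clade],
    neighborhood: int = 3,
) -> dict[str, Clade | None]:
    """Observed major clade per tip via the enclosing-clade consensus rule.

    For each tip, take the smallest enclosing clade with at least
    ``neighborhood`` other tips; the observed clade is called only when
    every scleractinian neighbour (Robust/Complex; paralog copies count
    as their taxon's clade) agrees.  Mixed or all-outgroup
    neighbourhoods give None (no call).
    """
    rooted = _rooted_copy(tree, expected_clades)
    result: dict[str, Clade | None] = {}
    for leaf in rooted.leaf_node_iter():
        label = leaf.taxon.label
        node = leaf.parent_node
        chosen: list[str] | None = None
        while node is not None:
            others = [l for l in _leaf_labels(node) if l != label]
            if len(others) >= neighborhood:
                chosen = others
                break
            node = node.parent_node
        if chosen is None:
            result[label] = None
            continue
        votes = {
            expected_clades.get(parse_tip(other)[0])
            for other in chosen
        } & SCLERACTINIAN_CLADES
        result[label] = votes.pop() if len(votes) == 1 else None
    return result


def apply_contamination_criteria(
    tree: dendropy.Tree,
    expected_clades: Mapping[str, Clade],
    long_branch_factor: float = 5.0,
) -> list[tuple[str, Criterion]]:
    """Removal set for criteria (a), (b) and (c) on one gene tree.

    (c) is evaluated on the pre-removal tree, so the criteria commute for
    disjoint removals.  Trees with fewer than four tips skip (a) and (b).
    """
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    removals: list[tuple[str, Criterion]] = []

    # (c): unusually long pendant branches, relative scale-free rule
    pendant = {
        l.taxon.label: l.edge.length
        for l in tree.leaf_node_iter()
        if l.edge.length is not None
    }
    if len(pendant) >= 2:
        med = median(pendant.values())
        if med > 0:
            for label, length in pendant.items():
                if length > long_branch_factor * med:
                    removals.append((label, Criterion.CRIT_C))

    if len(leaves) < 4:
        return removals

    observed = observed_clades(tree, expected_clades)
    flagged_c = {label for label, _ in removals}
    copies: dict[str, list[str]] = {}
    for label in leaves:
        copies.setdefault(parse_tip(label)[0], []).append(label)

    for taxon, labels in copies.items():
        expected = expected_clades.get(taxon)
        if expected not in SCLERACTINIAN_CLADES:
            continue
        judged = {l: observed[l] for l in labels if observed.get(l) is not None}
        if len(labels) >= 2:
            # (a): copies of one taxon in different observed clades
            if len({c for c in judged.values()}) >= 2:
                for label, clade in judged.items():
                    if clade is not expected and label not in flagged_c:
                        removals.append((label, Criterion.CRIT_A))
        else:
            # (b): single-copy taxon in the wrong major clade
            label = labels[0]
            clade = judged.get(label)
            if clade is not None and clade is not expected and label not in flagged_c:
                removals.append((label, Criterion.CRIT_B))
    return removals


def count_scleractinians(
    taxa: Sequence[str], expected_clades: Mapping[str, Clade]
) -> int:
    return sum(1 for t in taxa if expected_clades.get(t) in SCLERACTINIAN_CLADES)


def locus_level_filter(
    curated: CuratedLocus,
    expected_clades: Mapping[str, Clade],
    min_scleractinians: int = 3,
    min_pi_sites: int = 1,
) -> tuple[bool, Criterion | None]:
    """Keep/drop decision on the curated locus.

    Drops loci with fewer than three scleractinian taxa (LOW_TAXA) or with
    fewer parsimony-informative sites than required (UNINFORMATIVE).
    """
    from .supermatrix import parsimony_informative_sites

    if count_scleractinians(list(curated.sequences), expected_clades) < min_scleractinians:
        return False, Criterion.LOW_TAXA
    rows = list(curated.sequences.values())
    if min_pi_sites > 0:
        if len({len(r) for r in rows}) != 1:
            raise ValueError(f"{curated.locus_id}: rows must be aligned for the PI filter")
        if parsimony_informative_sites(rows) < min_pi_sites:
            return False, Criterion.UNINFORMATIVE
    return True, None


def curate_locus(
    locus_id: str,
    tree: dendropy.Tree,
    sequences: Mapping[str, str],
    expected_clades: Mapping[str, Clade],
    min_support: float = 10.0,
    long_branch_factor: float = 5.0,
    min_scleractinians: int = 3,
    min_pi_sites: int = 1,
) -> tuple[CuratedLocus | None, list[tuple[str, Criterion]], Criterion | None]:
    """Full curation of one locus.

    Returns (curated locus or None, tip removal log, locus-level drop
    reason or None).  Sequence ids must equal tree tip labels.
    """
    collapsed = collapse_low_support(tree, min_support)

    if flag_type2_paralogy(collapsed):
        log = [(label, Criterion.PARALOG_TYPE2_LOCUS) for label in sorted(sequences)]
        return None, log, Criterion.PARALOG_TYPE2_LOCUS

    log: list[tuple[str, Criterion]] = []
    removals = apply_contamination_criteria(collapsed, expected_clades, long_branch_factor)
    removed_labels = {label for label, _ in removals}
    log.extend(removals)

    surviving = {l: s for l, s in sequences.items() if l not in removed_labels}
    kept_by_taxon, paralog_log = resolve_type1_paralogs(surviving, strict=False)
    log.extend(paralog_log)

    curated = CuratedLocus(
        locus_id=locus_id,
        sequences={taxon: surviving[label] for taxon, label in kept_by_taxon.items()},
        removal_log=log,
    )
    keep, reason = locus_level_filter(
        curated, expected_clades, min_scleractinians, min_pi_sites
    )
    if not keep:
        return None, log, reason
    return curated, log, None
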