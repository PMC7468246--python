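"""Post-design screening of the bait set.

Order of the screens is fixed: symbiont cross-hybridization, region
pruning, exact-duplicate removal, self-hybridization removal, and a final
region-prune re-check (so the region invariant survives dedup/self-hyb
losses).  Every removal is written to a ledger and counts are conserved at
every stage: input baits = survivors + removals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .bait_design import Bait, BaitRegion
from .seqio import AnnotatedSequence, SeqKind, reverse_complement
from .similarity import HomologyHit, ScoringScheme, best_hit, search


class RemovalReason(str, Enum):
    SYMBIONT_MAP = "SYMBIONT_MAP"
    SYMBIONT_BLAST = "SYMBIONT_BLAST"
    DUPLICATE = "DUPLICATE"
    SELF_HYB = "SELF_HYB"
    REGION_PRUNED = "REGION_PRUNED"


@dataclass
class ScreenReport:
    """Ledger of one screening run; counts conserve at every stage."""

    n_input: int = 0
    removed_baits: list[tuple[str, RemovalReason]] = field(default_factory=list)
    removed_regions: list[tuple[str, RemovalReason]] = field(default_factory=list)
    surviving_by_label: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return len(self.removed_baits)

    @property
    def n_surviving(self) -> int:
        return sum(self.surviving_by_label.values())

    def counts_by_reason(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.removed_baits:
            out[reason.value] = out.get(reason.value, 0) + 1
        return out


def mapping_criterion(
    hit: HomologyHit, min_identity: float = 70.0, min_query_cov: int = 84
) -> bool:
    """Read-mapper-style criterion: identity and aligned bait positions.

    '70% length' is read as >= 70% of the 120 bp bait aligned, i.e. the
    query span must cover >= 84 bait positions (inclusive thresholds).
    """
    return hit.identity_pct >= min_identity and (hit.q_end - hit.q_start) >= min_query_cov


def symbiont_screen(
    baits: Sequence[Bait],
    symbiont_refs: Sequence[AnnotatedSequence],
    map_identity: float = 70.0,
    map_length_frac: float = 0.70,
    blast_evalue: float = 1e-4,
    scheme: ScoringScheme | None = None,
) -> dict[str, RemovalReason]:
    """Flag baits that map to or blast-match symbiont references.

    A bait is flagged if its best hit satisfies the mapping criterion
    (identity >= 70% over >= 0.70 x 120 = 84 bait positions) or if any hit
    has e-value <= blast_evalue.  Returns {bait_id: reason}, preferring
    the mapping reason when both trigger.
    """
    scheme = scheme or ScoringScheme.nucleotide()
    refs = list(symbiont_refs)
    flagged: dict[str, RemovalReason] = {}
    for bait in baits:
        query = AnnotatedSequence(id=bait.bait_id, residues=bait.sequence, kind=SeqKind.NT)
        min_cov = int(round(map_length_frac * len(bait.sequence)))
        # permissive cutoff so mapping-criterion hits with weak e-values
        # are still seen; the blast criterion applies its own cutoff
        hits = search(query, refs, SeqKind.NT, evalue_cutoff=10.0, scheme=scheme)
        if not hits:
            continue
        top = best_hit(hits)
        if mapping_criterion(top, map_identity, min_cov):
            flagged[bait.bait_id] = RemovalReason.SYMBIONT_MAP
        elif any(h.e_value <= blast_evalue for h in hits):
            flagged[bait.bait_id] = RemovalReason.SYMBIONT_BLAST
    return flagged


def prune_regions(
    regions: Sequence[BaitRegion],
    flagged: Mapping[str, RemovalReason] | Iterable[str],
    max_removed: int = 3,
    min_remaining: int = 2,
) -> tuple[list[BaitRegion], list[tuple[str, RemovalReason]], list[tuple[str, RemovalReason]]]:
    """Drop whole regions that lost too many baits.

    A region is removed when >= max_removed of its baits are flagged or
    fewer than min_remaining baits would survive; otherwise only the
    flagged baits are dropped.  Returns (surviving regions, removed-bait
    ledger entries, removed-region ledger entries).
    """
    if not isinstance(flagged, Mapping):
        flagged = {bait_id: RemovalReason.REGION_PRUNED for bait_id in flagged}
    survivors: list[BaitRegion] = []
    bait_entries: list[tuple[str, RemovalReason]] = []
    region_entries: list[tuple[str, RemovalReason]] = []
    for region in regions:
        hit_ids = [b.bait_id for b in region.baits if b.bait_id in flagged]
        remaining = [b for b in region.baits if b.bait_id not in flagged]
        if len(hit_ids) >= max_removed or len(remaining) < min_remaining:
            region_entries.append((region.region_id, RemovalReason.REGION_PRUNED))
            for b in region.baits:
                reason = flagged.get(b.bait_id, RemovalReason.REGION_PRUNED)
                bait_entries.append((b.bait_id, reason))
        else:
            for bait_id in hit_ids:
                bait_entries.append((bait_id, flagged[bait_id]))
            survivors.append(replace(region, baits=remaining))
    return survivors, bait_entries, region_entries


def dedup(baits: Sequence[Bait]) -> tuple[list[Bait], list[tuple[str, RemovalReason]]]:
    """Collapse exact-sequence duplicates to the first occurrence in input order."""
    seen: set[str] = set()
    kept: list[Bait] = []
    removed: list[tuple[str, RemovalReason]] = []
    for bait in baits:
        if bait.sequence in seen:
            removed.append((bait.bait_id, RemovalReason.DUPLICATE))
        else:
            seen.add(bait.sequence)
            kept.append(bait)
    return kept, removed


def self_hyb_screen(baits: Sequence[Bait], min_rc_match: int = 21) -> set[str]:
    """Flag baits sharing a reverse-complementary exact run with another bait.

    For every ordered pair (earlier, later in input order) whose sequences
    share a reverse-complementary run >= min_rc_match, the later bait is
    flagged; a palindromic bait (reverse-complementary to itself) is also
    flagged.  Equivalent to an all-pairs rc-substring scan via a k-mer
    index.
    """
    word_index: dict[str, bool] = {}
    flagged: set[str] = set()
    k = min_rc_match
    for bait in baits:
        seq = bait.sequence
        rc = reverse_complement(seq)
        rc_words = {rc[i : i + k] for i in range(len(rc) - k + 1)}
        own_words = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        if any(w in word_index for w in rc_words) or (rc_words & own_words):
            flagged.add(bait.bait_id)
        for w in own_words:
            word_index[w] = True
    return flagged


def _region_total(regions: Sequence[BaitRegion]) -> int:
    return sum(len(r.baits) for r in regions)


def run_screen(
    regions: Sequence[BaitRegion],
    symbiont_refs: Sequence[AnnotatedSequence],
    map_identity: float = 70.0,
    map_length_frac: float = 0.70,
    blast_evalue: float = 1e-4,
    max_removed: int = 3,
    min_remaining: int = 2,
    min_rc_match: int = 21,
    final_recheck: bool = True,
    scheme: ScoringScheme | None = None,
) -> tuple[list[BaitRegion], ScreenReport]:
    """Full screening pipeline over bait regions.

    symbiont screen -> region prune -> duplicate removal -> self-hyb
    removal -> final region-prune re-check.  The re-check compares each
    region's cumulative losses in this run against the pruning rule.
    """
    report = ScreenReport(n_input=_region_total(regions))
    original_sizes = {r.region_id: len(r.baits) for r in regions}

    all_baits = [b for r in regions for b in r.baits]
    flagged = symbiont_screen(
        all_baits, symbiont_refs, map_identity, map_length_frac, blast_evalue, scheme
    )
    regions, bait_entries, region_entries = prune_regions(
        regions, flagged, max_removed, min_remaining
    )
    report.removed_baits.extend(bait_entries)
    report.removed_regions.extend(region_entries)

    surviving_baits = [b for r in regions for b in r.baits]
    kept, dup_entries = dedup(surviving_baits)
    report.removed_baits.extend(dup_entries)
    kept_ids = {b.bait_id for b in kept}

    hyb_flagged = self_hyb_screen(kept, min_rc_match)
    report.removed_baits.extend(
        (bait_id, RemovalReason.SELF_HYB) for bait_id in sorted(hyb_flagged)
    )
    kept_ids -= hyb_flagged

    pruned: list[BaitRegion] = []
    for region in regions:
        remaining = [b for b in region.baits if b.bait_id in kept_ids]
        n_lost = original_sizes[region.region_id] - len(remaining)
        if final_recheck and (n_lost >= max_removed or len(remaining) < min_remaining):
            report.removed_regions.append((region.region_id, RemovalReason.REGION_PRUNED))
            already = {bid for bid, _ in report.removed_baits}
            for b in remaining:
                if b.bait_id not in already:
                    report.removed_baits.append((b.bait_id, RemovalReason.REGION_PRUNED))
        else:
            pruned.append(replace(region, baits=remaining))

    for region in pruned:
        for b in region.baits:
            label = b.label.value
            report.surviving_by_label[label] = report.surviving_by_label.get(label, 0) + 1
    return pruned, report
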