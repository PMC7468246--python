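"""Gene-tree curation: support collapsing, paralog handling, contamination
criteria and locus-level filters."""

import dendropy
import pytest

from coralbaits.genetree_filter import (
    Criterion,
    apply_contamination_criteria,
    collapse_low_support,
    curate_locus,
    flag_type2_paralogy,
    locus_level_filter,
    observed_clades,
    resolve_type1_paralogs,
    CuratedLocus,
)
from coralbaits.seqio import Clade


def tree_of(newick):
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


CLADES = {
    **{f"R{i}": Clade.ROBUST for i in range(1, 7)},
    **{f"C{i}": Clade.COMPLEX for i in range(1, 7)},
    **{f"O{i}": Clade.OUTGROUP for i in range(1, 3)},
    "A": Clade.ROBUST, "B": Clade.COMPLEX, "X": Clade.ROBUST,
}


def n_internal(tree):
    return sum(1 for _ in tree.preorder_internal_node_iter(exclude_seed_node=True))


def test_collapse_low_support():
    fully = tree_of("((A:1,B:1)95:1,(R1:1,C1:1)80:1);")
    out = collapse_low_support(fully, 10)
    assert n_internal(out) == n_internal(fully)

    weak = tree_of("((A:1,B:1)5:1,(R1:1,C1:1)80:1);")
    out = collapse_low_support(weak, 10)
    assert n_internal(out) == n_internal(weak) - 1
    assert len(out.leaf_nodes()) == 4  # tips preserved

    star = tree_of("(A:1,B:1,R1:1,C1:1);")
    assert n_internal(collapse_low_support(star, 10)) == 0

    unlabelled = tree_of("((A:1,B:1):1,(R1:1,C1:1)80:1);")
    assert n_internal(collapse_low_support(unlabelled, 10)) == n_internal(unlabelled)


def test_resolve_type1_preference_order():
    kept, removed = resolve_type1_paralogs({"X.main": "AA", "X.0.0": "CC"})
    assert kept == {"X": "X.main"}
    assert removed == [("X.0.0", Criterion.PARALOG_RESOLVED)]

    kept, _ = resolve_type1_paralogs({"X.0.0": "AA", "X.0.1": "CC"})
    assert kept == {"X": "X.0.0"}

    kept, removed = resolve_type1_paralogs({"X": "AA"})
    assert kept == {"X": "X"} and removed == []

    with pytest.raises(ValueError):
        resolve_type1_paralogs({"X.0.1": "AA", "X.0.2": "CC"})
    # non-strict mode falls back to the smallest remaining tag
    kept, _ = resolve_type1_paralogs({"X.0.1": "AA", "X.0.2": "CC"}, strict=False)
    assert kept == {"X": "X.0.1"}


def test_type2_paralogy_detection():
    deep = tree_of("((A.0.0:1,B.0.0:1)90:1,(A.0.1:1,B.0.1:1)90:1);")
    assert flag_type2_paralogy(deep)

    taxon_local = tree_of("(((A.main:1,A.0.0:1)90:1,B:1)90:1,(C1:1,C2:1)90:1);")
    assert not flag_type2_paralogy(taxon_local)

    single_copy = tree_of("((A:1,B:1)90:1,(C1:1,C2:1)90:1);")
    assert not flag_type2_paralogy(single_copy)


WRONG_CLADE = (
    "(((R1:0.05,R2:0.04)90:0.03,(R3:0.05,R4:0.04)85:0.03)100:0.05,"
    "(((C1:0.05,X:0.04)90:0.03,C2:0.05)88:0.02,(C3:0.04,C4:0.05)91:0.03)100:0.05,"
    "(O1:0.06,O2:0.07)100:0.06);"
)


def test_criterion_b_removes_misplaced_single_copy():
    removals = apply_contamination_criteria(tree_of(WRONG_CLADE), CLADES)
    assert removals == [("X", Criterion.CRIT_B)]


def test_criterion_a_removes_wrong_clade_paralog_copy():
    newick = (
        "(((R1:0.05,X.main:0.04)90:0.03,(R3:0.05,R4:0.04)85:0.03)100:0.05,"
        "(((C1:0.05,X.0.0:0.04)90:0.03,C2:0.05)88:0.02,(C3:0.04,C4:0.05)91:0.03)100:0.05,"
        "(O1:0.06,O2:0.07)100:0.06);"
    )
    removals = apply_contamination_criteria(tree_of(newick), CLADES)
    assert removals == [("X.0.0", Criterion.CRIT_A)]  # the COMPLEX-placed copy


def test_criterion_c_long_branch():
    newick = (
        "((R1:0.05,R2:0.04)90:0.03,(C1:0.05,C2:0.6)88:0.02,"
        "(O1:0.06,O2:0.07)100:0.06);"
    )
    removals = apply_contamination_criteria(tree_of(newick), CLADES, long_branch_factor=5.0)
    assert ("C2", Criterion.CRIT_C) in removals  # 0.6 > 5 x median(~0.055)
    assert all(c is Criterion.CRIT_C for _, c in removals)


def test_mixed_small_party_is_not_flagged():
    """A clade reduced to a small party sister to the other clade stays:
    its neighbourhood is mixed, not a foreign nesting."""
    newick = (
        "(((R1:0.05,R2:0.04)90:0.03,R3:0.05)100:0.05,"
        "((C1:0.05,C2:0.04)90:0.03,(C3:0.04,(C4:0.05,C5:0.04)80:0.02)91:0.03)100:0.05,"
        "(O1:0.06,O2:0.07)100:0.06);"
    )
    removals = apply_contamination_criteria(tree_of(newick), CLADES)
    assert removals == []


def test_observed_clades_calls():
    observed = observed_clades(tree_of(WRONG_CLADE), CLADES)
    assert observed["X"] is Clade.COMPLEX  # unanimously foreign surroundings
    assert all(observed[f"R{i}"] is Clade.ROBUST for i in range(1, 5))
    # Complex tips see the contaminant in their neighbourhood: no call
    assert all(observed[f"C{i}"] is None for i in range(1, 5))
    assert observed["O1"] is None  # outgroup neighbourhood carries no vote


def test_small_trees_skip_clade_criteria():
    newick = "(X:0.05,C1:0.05,C2:0.05);"
    removals = apply_contamination_criteria(tree_of(newick), CLADES)
    assert all(c is Criterion.CRIT_C for _, c in removals)


def test_locus_level_filter():
    clades = {"R1": Clade.ROBUST, "C1": Clade.COMPLEX, "C2": Clade.COMPLEX,
              "O1": Clade.OUTGROUP}
    low = CuratedLocus("L", {"R1": "ACGT", "C1": "ACGT"})
    keep, reason = locus_level_filter(low, clades, min_scleractinians=3)
    assert not keep and reason is Criterion.LOW_TAXA

    flat = CuratedLocus("L", {"R1": "AAAA", "C1": "AAAA", "C2": "AAAA"})
    keep, reason = locus_level_filter(flat, clades, min_pi_sites=1)
    assert not keep and reason is Criterion.UNINFORMATIVE

    good = CuratedLocus("L", {"R1": "AACC", "C1": "AATT", "C2": "GGCC", "O1": "GGTT"})
    keep, reason = locus_level_filter(good, clades, min_pi_sites=1)
    assert keep and reason is None


def test_curate_locus_full_path():
    seqs = {
        "R1": "AAAACCCC", "R2": "AAAACCCC", "R3": "AAAATTTT", "R4": "AAAATTTT",
        "C1": "GGGGCCCC", "X.main": "GGGGCCCA", "C2": "GGGGCCCC",
        "C3": "GGGGTTTT", "C4": "GGGGTTTT", "O1": "GGAACCTT", "O2": "GGAACCTT",
    }
    curated, log, reason = curate_locus(
        "L1", tree_of(WRONG_CLADE.replace("X:", "X.main:")), seqs, CLADES
    )
    assert reason is None
    assert ("X.main", Criterion.CRIT_B) in log
    assert "X" not in curated.sequences
    assert set(curated.sequences) == {"R1", "R2", "R3", "R4", "C1", "C2", "C3", "C4",
                                      "O1", "O2"}

    # removal log and survivors partition the input tips
    removed_tips = {tip for tip, _ in log}
    survivor_tips = {tip for tip in seqs if tip not in removed_tips}
    assert removed_tips | survivor_tips == set(seqs)
    assert not removed_tips & survivor_tips


def test_curate_locus_drops_type2_locus():
    newick = "((A.0.0:1,B.0.0:1)90:1,(A.0.1:1,B.0.1:1)90:1);"
    seqs = {"A.0.0": "ACGT", "B.0.0": "ACGT", "A.0.1": "ACGT", "B.0.1": "ACGT"}
    curated, log, reason = curate_locus("L1", tree_of(newick), seqs, CLADES)
    assert curated is None
    assert reason is Criterion.PARALOG_TYPE2_LOCUS
    assert {tip for tip, _ in log} == set(seqs)
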