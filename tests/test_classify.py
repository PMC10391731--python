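import numpy as np
import pytest
from Bio.Seq import reverse_complement

from _oracles import infix_distance
import umiquant as uq
from umiquant import Allele, AlleleReference, assign_allele, classify_reads, extract_umi
from umiquant.classify import CATEGORIES
from umiquant.preprocess import SequencedRead
from umiquant.references import UMI_CONSTANT_PREFIX


def make_read(bases):
    return SequencedRead("r", bases, "I" * len(bases))


class TestExtractUmi:
    def test_planted_umi(self):
        read = make_read(UMI_CONSTANT_PREFIX + "ACGTACGTACGT" + "GGGTTTAAACCC")
        umi, insert = extract_umi(read)
        assert umi == "ACGTACGTACGT"
        assert insert == "GGGTTTAAACCC"

    def test_one_prefix_mismatch_tolerated(self):
        prefix = "T" + UMI_CONSTANT_PREFIX[1:]
        read = make_read(prefix + "ACGTACGTACGT" + "GGGTTTAAACCC")
        umi, insert = extract_umi(read)
        assert umi == "ACGTACGTACGT"

    def test_two_mismatches_rejected(self):
        prefix = "TT" + UMI_CONSTANT_PREFIX[2:]
        read = make_read(prefix + "ACGTACGTACGT" + "GGGTTTAAACCC")
        assert extract_umi(read) is None

    def test_reverse_complement_orientation_normalized(self):
        forward = UMI_CONSTANT_PREFIX + "ACGTACGTACGT" + "GGGTTTAAACCC"
        read = make_read(reverse_complement(forward))
        umi, insert = extract_umi(read)
        assert umi == "ACGTACGTACGT"
        assert insert == "GGGTTTAAACCC"

    def test_zero_error_umis_equal_planted(self, refs, zero_error_run):
        molecules, reads = zero_error_run
        planted = {m.molecule_id: m.umi for m in molecules}
        checked = 0
        for read in reads[:1000]:
            umi, _ = extract_umi(read)
            assert umi == planted[read.truth]
            checked += 1
        assert checked == 1000


class TestAssignAllele:
    def test_exact_reference_insert(self, refs):
        call, best, second = assign_allele(refs[Allele.CA_ACTIVE].sequence, refs)
        assert call == "ca_active"
        assert best == 0
        assert second > 20

    def test_equidistant_insert_unclassified(self):
        tiny = {
            Allele.WT: AlleleReference(Allele.WT, "A" * 20, 20),
            Allele.CA_NATIVE: AlleleReference(Allele.CA_NATIVE, "A" * 14 + "C" * 6, 20),
            Allele.CA_ACTIVE: AlleleReference(Allele.CA_ACTIVE, "G" * 20, 20),
        }
        insert = "A" * 17 + "C" * 3
        assert infix_distance(insert, tiny[Allele.WT].sequence) == infix_distance(
            insert, tiny[Allele.CA_NATIVE].sequence
        )
        call, best, second = assign_allele(insert, tiny)
        assert call == "unclassified"
        assert best == second

    def test_margin_rule_blocks_near_ties(self):
        tiny = {
            Allele.WT: AlleleReference(Allele.WT, "A" * 20, 20),
            Allele.CA_NATIVE: AlleleReference(Allele.CA_NATIVE, "A" * 18 + "C" * 2, 20),
            Allele.CA_ACTIVE: AlleleReference(Allele.CA_ACTIVE, "G" * 20, 20),
        }
        call, best, second = assign_allele("A" * 20, tiny, min_margin=3)
        assert (best, second) == (0, 2)
        assert call == "unclassified"
        call2, _, _ = assign_allele("A" * 20, tiny, min_margin=2)
        assert call2 == "wt"

    def test_two_substitutions_still_called_with_oracle_distance(self, refs):
        rng = np.random.default_rng(4)
        wt = list(refs[Allele.WT].sequence)
        pos = rng.choice(len(wt), size=2, replace=False)
        for p in pos:
            wt[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[wt[p]]
        insert = "".join(wt)
        call, best, second = assign_allele(insert, refs)
        assert call == "wt"
        assert best == 2
        assert best == infix_distance(insert, refs[Allele.WT].sequence)

    def test_empty_insert_rejected(self, refs):
        with pytest.raises(ValueError):
            assign_allele("", refs)

    def test_distance_fraction_cap(self, refs):
        call, *_ = assign_allele("ACGT" * 40, refs, max_dist_fraction=0.1)
        assert call == "unclassified"


def test_category_counts_partition_reads(default_run):
    counts = default_run.category_counts
    assert set(counts) == set(CATEGORIES)
    assert sum(counts.values()) == default_run.preprocess_log.passed
    assert len(default_run.classified) == sum(
        counts[c] for c in ("wt", "ca_native", "ca_active", "unclassified")
    )


def test_zero_error_reads_all_match_truth_allele(refs, zero_error_run):
    molecules, reads = zero_error_run
    passed, _ = uq.preprocess_reads(reads)
    classified, counts = classify_reads(passed, refs)
    assert counts["no_anchor"] == 0 and counts["dropped"] == 0
    truth_allele = {m.molecule_id: m.allele_id.value for m in molecules}
    assert (
        classified["allele_call"] == classified["truth"].map(truth_allele)
    ).all()


def test_native_vs_active_misclassification_rate(default_run):
    """At 0.5% per-base sequencing error the two CA forms are never confused."""
    classified = default_run.classified
    truth_allele = {m.molecule_id: m.allele_id.value for m in default_run.truth}
    truth = classified["truth"].map(truth_allele)
    ca_reads = classified[truth.isin(["ca_native", "ca_active"])]
    swapped = (
        (truth.loc[ca_reads.index] == "ca_native")
        & (ca_reads["allele_call"] == "ca_active")
    ).sum() + (
        (truth.loc[ca_reads.index] == "ca_active")
        & (ca_reads["allele_call"] == "ca_native")
    ).sum()
    assert len(ca_reads) > 1000
    assert swapped / len(ca_reads) < 1e-3
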