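"""UMI extraction and per-read allele assignment.

The UMI is the 12-nt stretch immediately following the constant tail of the
barcoding primer at the read start (one mismatch tolerated in the tail;
reads matching in reverse complement are flipped first).  The remaining
insert is compared with the three allele references by unit-cost edit
distance with free end-gaps on the reference, and called for the nearest
reference only when the distance is small relative to the insert and the
second-best reference is clearly farther away (a best-vs-second-best margin
rule); anything else is left unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import pandas as pd
from Bio.Seq import reverse_complement

from .preprocess import SequencedRead
from .references import UMI_CONSTANT_PREFIX, Allele, AlleleReference

#: Per-read outcome categories; every preprocessed read lands in exactly one.
CATEGORIES = ("wt", "ca_native", "ca_active", "unclassified", "no_anchor", "dropped")


@dataclass
class ClassifiedRead:
    read_id: str
    umi: str
    allele_call: str  # one of wt / ca_native / ca_active / unclassified
    edit_distance_best: int
    edit_distance_second: int
    truth: str | None = None


def _hamming_at_most(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def extract_umi(
    read: SequencedRead,
    constant_prefix: str = UMI_CONSTANT_PREFIX,
    umi_length: int = 12,
    max_prefix_mismatch: int = 1,
) -> tuple[str, str] | None:
    """Locate the constant prefix and split off (umi, insert).

    Returns None when the prefix is absent (within tolerance) in both
    orientations — the read is counted as anchorless by the caller.
    """
    k = len(constant_prefix)
    if len(read.bases) < k + umi_length:
        return None
    bases = read.bases
    if not bases.startswith(constant_prefix) and not _hamming_at_most(
        bases[:k], constant_prefix, max_prefix_mismatch
    ):
        flipped = reverse_complement(bases)
        if len(flipped) >= k + umi_length and _hamming_at_most(
            flipped[:k], constant_prefix, max_prefix_mismatch
        ):
            bases = flipped
        else:
            return None
    return bases[k : k + umi_length], bases[k + umi_length :]


def assign_allele(
    insert: str,
    refs: dict[Allele, AlleleReference],
    max_dist_fraction: float = 0.1,
    min_margin: int = 3,
) -> tuple[str, int, int]:
    """Call the nearest reference, or unclassified.

    Distance is unit-cost Levenshtein with free end-gaps on the reference
    (the insert must be explained end to end; unaligned reference flanks are
    free).  The nearest allele is called iff its distance is at most
    ``max_dist_fraction`` of the insert length and the runner-up is at least
    ``min_margin`` edits farther.

    Returns ``(call, best_distance, second_best_distance)``.
    """
    if not insert:
        raise ValueError("insert must be non-empty")
    dists = sorted(
        (
            edlib.align(insert, ref.sequence, mode="HW", task="distance")[
                "editDistance"
            ],
            allele,
        )
        for allele, ref in refs.items()
    )
    (best, allele), (second, _) = dists[0], dists[1]
    if best <= max_dist_fraction * len(insert) and second - best >= min_margin:
        return allele.value, best, second
    return "unclassified", best, second


def classify_reads(
    reads: list[SequencedRead],
    refs: dict[Allele, AlleleReference],
    constant_prefix: str = UMI_CONSTANT_PREFIX,
    umi_length: int = 12,
    max_prefix_mismatch: int = 1,
    max_dist_fraction: float = 0.1,
    min_margin: int = 3,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every read; return the per-read table and category counts.

    Category counts partition the input: wt / ca_native / ca_active /
    unclassified / no_anchor (prefix not found) / dropped (N in the UMI).
    Only the first four categories appear in the returned table.
    """
    rows: list[ClassifiedRead] = []
    counts = dict.fromkeys(CATEGORIES, 0)
    for read in reads:
        extracted = extract_umi(read, constant_prefix, umi_length, max_prefix_mismatch)
        if extracted is None:
            counts["no_anchor"] += 1
            continue
        umi, insert = extracted
        if set(umi) - set("ACGT"):
            counts["dropped"] += 1
            continue
        if not insert:
            counts["no_anchor"] += 1
            continue
        call, best, second = assign_allele(insert, refs, max_dist_fraction, min_margin)
        counts[call] += 1
        rows.append(ClassifiedRead(read.read_id, umi, call, best, second, read.truth))
    df = pd.DataFrame(
        {
            "read_id": [r.read_id for r in rows],
            "umi": [r.umi for r in rows],
            "allele_call": [r.allele_call for r in rows],
            "edit_distance_best": [r.edit_distance_best for r in rows],
            "edit_distance_second": [r.edit_distance_second for r in rows],
            "truth": [r.truth for r in rows],
        }
    )
    return df, counts
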