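"""Read preprocessing: 3' adapter trimming and the all-bases quality filter.

Both steps are implemented directly rather than delegated to an external
trimmer so their behaviour is fully specified: a 3' adapter occurrence (full,
or a prefix of the adapter running off the read end) is located allowing up
to 10% mismatches of the matched length, and a read passes quality filtering
only if the required fraction of its bases (by default all of them, matching
a ``fastq_quality_filter -q 20 -Q33 -p 100`` configuration) reaches the
Phred threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .references import READTHROUGH_ADAPTER, UMI_CONSTANT_PREFIX

PHRED_OFFSET = 33


@dataclass
class SequencedRead:
    """A FASTQ record, optionally linked to the simulated molecule it came from."""

    read_id: str
    bases: str
    qualities: str
    truth: str | None = None  # molecule_id of the founding template, if known

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: bases ({len(self.bases)}) and qualities "
                f"({len(self.qualities)}) differ in length"
            )
        if self.qualities and min(self.qualities) < "!":
            raise ValueError(f"{self.read_id}: quality string is not Phred+33")

    def phred(self) -> np.ndarray:
        """Per-base Phred scores as an integer array."""
        return (
            np.frombuffer(self.qualities.encode(), dtype=np.uint8).astype(np.int32)
            - PHRED_OFFSET
        )

    def __len__(self) -> int:
        return len(self.bases)


def _adapter_match_offset(
    bases: str, adapter: str, min_overlap: int, max_error_rate: float
) -> int | None:
    """Leftmost offset where the adapter starts, or None.

    A match at offset ``j`` compares ``adapter[:k]`` with ``bases[j:j+k]``
    where ``k = min(len(adapter), len(bases) - j)`` — i.e. the occurrence
    either covers the whole adapter (read-through) or runs off the 3' end of
    the read.  Valid if ``k >= min_overlap`` and mismatches <= 10% of ``k``.
    """
    n, a = len(bases), len(adapter)
    if n == 0:
        return None
    exact = bases.find(adapter)
    read = np.frombuffer(bases.encode(), dtype=np.uint8)
    ad = np.frombuffer(adapter.encode(), dtype=np.uint8)
    limit = exact if exact >= 0 else n  # a mismatched hit can only be earlier
    mism = np.zeros(min(n, limit + 1), dtype=np.int32)
    for i in range(a):
        span = min(len(mism), n - i)
        if span <= 0:
            break
        mism[:span] += read[i : i + span] != ad[i]
    offsets = np.arange(len(mism))
    k = np.minimum(a, n - offsets)
    valid = (k >= min_overlap) & (mism <= np.floor(max_error_rate * k))
    hits = np.nonzero(valid)[0]
    if hits.size:
        return int(hits[0])
    return exact if exact >= 0 else None


def trim_adapter(
    read: SequencedRead,
    adapter: str = READTHROUGH_ADAPTER,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
) -> SequencedRead:
    """Trim a 3' adapter occurrence from a read.

    Bases and qualities are truncated at the match start (0-based, half-open);
    a read with no acceptable occurrence is returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    j = _adapter_match_offset(read.bases, adapter, min_overlap, max_error_rate)
    if j is None:
        return read
    return replace(read, bases=read.bases[:j], qualities=read.qualities[:j])


def _batch_match_offsets(
    reads: list[SequencedRead],
    adapter: str,
    min_overlap: int,
    max_error_rate: float,
) -> list[int | None]:
    """Adapter match offsets for many reads at once.

    Semantically identical to :func:`_adapter_match_offset` per read, but
    reads of equal length are processed as one matrix, which is much faster
    for the length-homogeneous output of amplicon sequencing.
    """
    from collections import defaultdict

    ad = np.frombuffer(adapter.encode(), dtype=np.uint8)
    a = len(ad)
    offsets: list[int | None] = [None] * len(reads)
    by_len: dict[int, list[int]] = defaultdict(list)
    for idx, read in enumerate(reads):
        if len(read.bases) > 0:
            by_len[len(read.bases)].append(idx)
    for L, idxs in by_len.items():
        mat = np.frombuffer(
            "".join(reads[i].bases for i in idxs).encode(), dtype=np.uint8
        ).reshape(len(idxs), L)
        mism = np.zeros((len(idxs), L), dtype=np.int16)
        for i in range(min(a, L)):
            mism[:, : L - i] += mat[:, i:] != ad[i]
        k = np.minimum(a, L - np.arange(L))
        allowed = np.floor(max_error_rate * k).astype(np.int16)
        valid = (k >= min_overlap)[None, :] & (mism <= allowed[None, :])
        any_valid = valid.any(axis=1)
        first = valid.argmax(axis=1)
        for row, idx in enumerate(idxs):
            if any_valid[row]:
                offsets[idx] = int(first[row])
    return offsets


def quality_filter(
    read: SequencedRead, min_q: int = 20, min_fraction: float = 1.0
) -> bool:
    """True iff at least ``min_fraction`` of bases have Phred >= ``min_q``.

    The defaults require every base to reach Q20.  Empty reads fail.
    """
    if len(read) == 0:
        return False
    return float(np.mean(read.phred() >= min_q)) >= min_fraction


#: Reads shorter than this after trimming cannot carry a classifiable insert
#: (constant prefix + UMI + a minimal gene-specific stub).
def min_classifiable_length(umi_length: int = 12) -> int:
    return len(UMI_CONSTANT_PREFIX) + umi_length + 10


@dataclass
class PreprocessLog:
    """Per-sample preprocessing counters."""

    reads_in: int = 0
    trimmed: int = 0
    failed_quality: int = 0
    too_short: int = 0
    passed: int = 0
    counters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reads_in": self.reads_in,
            "trimmed": self.trimmed,
            "failed_quality": self.failed_quality,
            "too_short": self.too_short,
            "passed": self.passed,
        }


def preprocess_reads(
    reads: list[SequencedRead],
    adapter: str = READTHROUGH_ADAPTER,
    min_q: int = 20,
    min_fraction: float = 1.0,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
    umi_length: int = 12,
) -> tuple[list[SequencedRead], PreprocessLog]:
    """Trim adapters, drop too-short reads, then apply the quality filter."""
    log = PreprocessLog(reads_in=len(reads))
    min_len = min_classifiable_length(umi_length)
    offsets = _batch_match_offsets(reads, adapter, min_overlap, max_error_rate)
    passed: list[SequencedRead] = []
    for read, j in zip(reads, offsets):
        trimmed = (
            read if j is None else replace(read, bases=read.bases[:j], qualities=read.qualities[:j])
        )
        if len(trimmed) < len(read):
            log.trimmed += 1
        if len(trimmed) < min_len:
            log.too_short += 1
            continue
        if not quality_filter(trimmed, min_q=min_q, min_fraction=min_fraction):
            log.failed_quality += 1
            continue
        passed.append(trimmed)
    log.passed = len(passed)
    return passed, log
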