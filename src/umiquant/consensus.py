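"""Barcode-family construction, consensus calling and noise suppression.

Reads sharing a UMI form a barcode family.  Families with fewer than three
reads are treated as PCR/sequencing artifacts and discarded; a retained
family is called for the allele holding a clear plurality of its read votes.
After counting consensus families per allele class, any class with six or
fewer families is suppressed as residual background noise (its raw count is
kept alongside for inspection).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .references import Allele

ALLELE_ORDER = (Allele.WT.value, Allele.CA_NATIVE.value, Allele.CA_ACTIVE.value)
DISCARDED = "discarded"

#: Minimum reads for a barcode family to count as a genuine molecule.
DEFAULT_FAMILY_MIN_READS = 3

#: Family counts at or below this per allele class are background noise.
DEFAULT_MAX_NOISE_FAMILIES = 6


@dataclass
class UmiFamily:
    """Reads sharing one UMI, with allele votes and the consensus call."""

    umi: str
    n_reads: int
    votes: dict[str, int]
    consensus: str  # allele value or "discarded"


def consensus_allele(
    votes: dict[str, int], min_vote_fraction: float = 0.6
) -> str:
    """Plurality consensus over allele votes.

    Unclassified reads contribute no allele vote.  The plurality allele is
    returned iff it is unique and holds at least ``min_vote_fraction`` of
    the allele votes; ties, low shares and vote-free families are discarded.
    """
    allele_votes = {a: votes.get(a, 0) for a in ALLELE_ORDER}
    total = sum(allele_votes.values())
    if total == 0:
        return DISCARDED
    top = max(allele_votes.values())
    winners = [a for a, v in allele_votes.items() if v == top]
    if len(winners) > 1 or top / total < min_vote_fraction:
        return DISCARDED
    return winners[0]


def build_families(
    classified: pd.DataFrame,
    family_min_reads: int = DEFAULT_FAMILY_MIN_READS,
    min_vote_fraction: float = 0.6,
    merge_hamming1: bool = False,
) -> pd.DataFrame:
    """Group classified reads into barcode families and call each one.

    One family per distinct UMI (exact string match; optional merging of
    UMIs one substitution apart into their larger neighbour).  Families with
    fewer than ``family_min_reads`` reads are discarded; otherwise the
    consensus vote rule applies.  Returns a table with columns umi, n_reads,
    one vote column per category, and consensus.
    """
    if classified.empty:
        cols = ["umi", "n_reads"] + [f"votes_{a}" for a in ALLELE_ORDER]
        return pd.DataFrame(columns=cols + ["votes_unclassified", "consensus"])
    pivot = (
        classified.groupby(["umi", "allele_call"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    for cat in (*ALLELE_ORDER, "unclassified"):
        if cat not in pivot.columns:
            pivot[cat] = 0
    if merge_hamming1:
        pivot = _merge_umis_hamming1(pivot)
    fam = pd.DataFrame(index=pivot.index)
    fam["n_reads"] = pivot[[*ALLELE_ORDER, "unclassified"]].sum(axis=1)
    for a in ALLELE_ORDER:
        fam[f"votes_{a}"] = pivot[a]
    fam["votes_unclassified"] = pivot["unclassified"]
    votes = pivot[list(ALLELE_ORDER)].to_numpy()
    total = votes.sum(axis=1)
    top = votes.max(axis=1)
    n_top = (votes == top[:, None]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, top / np.maximum(total, 1), 0.0)
    ok = (
        (fam["n_reads"].to_numpy() >= family_min_reads)
        & (total > 0)
        & (n_top == 1)
        & (share >= min_vote_fraction)
    )
    winner = np.array(ALLELE_ORDER)[votes.argmax(axis=1)]
    fam["consensus"] = np.where(ok, winner, DISCARDED)
    return fam.reset_index()


def _merge_umis_hamming1(pivot: pd.DataFrame) -> pd.DataFrame:
    """Directionally merge each UMI into a strictly larger neighbour at
    Hamming distance 1 (largest families absorb first)."""
    sizes = pivot.sum(axis=1)
    order = sizes.sort_values(ascending=False, kind="mergesort").index
    target: dict[str, str] = {}
    seen: dict[str, str] = {}
    for umi in order:
        merged_into = None
        for i in range(len(umi)):
            for b in "ACGT":
                if b == umi[i]:
                    continue
                neighbour = umi[:i] + b + umi[i + 1 :]
                if neighbour in seen and sizes[seen[neighbour]] > sizes[umi]:
                    merged_into = seen[neighbour]
                    break
            if merged_into:
                break
        if merged_into:
            target[umi] = merged_into
        else:
            seen[umi] = umi
    if not target:
        return pivot
    grouper = [target.get(u, u) for u in pivot.index]
    merged = pivot.groupby(grouper).sum()
    merged.index.name = "umi"
    return merged


@dataclass
class AlleleFamilyCounts:
    """Per-sample consensus-family tallies, raw and after noise suppression."""

    sample_id: str
    raw: dict[str, int]
    reported: dict[str, int] = field(default_factory=dict)
    suppressed: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.raw.values()):
            raise ValueError("family counts must be non-negative")
        if not self.reported:
            self.reported = dict(self.raw)
        if not self.suppressed:
            self.suppressed = dict.fromkeys(self.raw, False)

    @property
    def families_wt(self) -> int:
        return self.reported[Allele.WT.value]

    @property
    def families_native(self) -> int:
        return self.reported[Allele.CA_NATIVE.value]

    @property
    def families_active(self) -> int:
        return self.reported[Allele.CA_ACTIVE.value]

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "raw": dict(self.raw),
            "reported": dict(self.reported),
            "suppressed": dict(self.suppressed),
        }


def count_families(families: pd.DataFrame, sample_id: str) -> AlleleFamilyCounts:
    """Tally consensus families per allele class (discarded families excluded)."""
    raw = {
        a: int((families["consensus"] == a).sum()) if len(families) else 0
        for a in ALLELE_ORDER
    }
    return AlleleFamilyCounts(sample_id=sample_id, raw=raw)


def apply_noise_floor(
    counts: AlleleFamilyCounts, max_noise_families: int = DEFAULT_MAX_NOISE_FAMILIES
) -> AlleleFamilyCounts:
    """Suppress allele classes whose family count is within the noise floor.

    A class with at most ``max_noise_families`` consensus families is
    reported as 0 and flagged; the raw count is preserved.
    """
    reported = {}
    suppressed = {}
    for allele, n in counts.raw.items():
        if n <= max_noise_families:
            reported[allele] = 0
            suppressed[allele] = True
        else:
            reported[allele] = n
            suppressed[allele] = False
    return replace(counts, reported=reported, suppressed=suppressed)
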