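"""Reference amplicons for the three Braf allele classes.

The assay distinguishes three amplifiable alleles in a heterozygous
``Braf^CA/+`` animal:

* ``wt`` — the wildtype *Braf* allele (185 bp amplicon),
* ``ca_native`` — the conditional knock-in allele before Cre recombination
  (308 bp),
* ``ca_active`` — the same allele after Cre excises the conditional cassette
  and switches it to express BRAF(V600E) (335 bp).

The published murine amplicon sequences are not available, so references are
built as random sequences of the correct lengths that share, verbatim, the
two gene-specific primer segments as flanks.  Every step of the pipeline is
sequence-agnostic: only the lengths, the shared flanks and the large mutual
edit distance of the three references matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import edlib
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord


class Allele(str, Enum):
    """The three allele classes resolved by the assay."""

    WT = "wt"
    CA_NATIVE = "ca_native"
    CA_ACTIVE = "ca_active"


#: Constant 5' tail of the reverse barcoding primer; reads begin with this
#: segment, immediately followed by the 12-nt UMI.
UMI_CONSTANT_PREFIX = "GGACACTCTTTCCCTACACGACGCTCTTCCGATCT"

#: Gene-specific segment of the reverse barcoding primer (follows the UMI).
REVERSE_GENE_FLANK = "ATGGGAAAGAGTGTCCCTCTGCTGGGAAAGCGG"

#: Constant 5' tail of the forward barcoding primer.
FORWARD_TAIL = "GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"

#: Gene-specific segment of the forward barcoding primer.
FORWARD_GENE_FLANK = "TGAGTATTTTTGTGGCAACTGC"

#: Adapter sequence observed when sequencing reads through the far end of the
#: amplicon (reverse complement of the forward primer tail) — the 3' adapter
#: the preprocessing stage trims.
READTHROUGH_ADAPTER = reverse_complement(FORWARD_TAIL)

#: Published amplicon lengths in bp.
DEFAULT_LENGTHS: dict[Allele, int] = {
    Allele.WT: 185,
    Allele.CA_NATIVE: 308,
    Allele.CA_ACTIVE: 335,
}

#: Combined length of the two gene-specific flanks shared by all references.
FLANK_LENGTH = len(REVERSE_GENE_FLANK) + len(FORWARD_GENE_FLANK)

#: Required minimum edit distance between any two references.
MIN_PAIRWISE_DISTANCE = 20

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class AlleleReference:
    """One amplicon reference: allele class, sequence and expected length."""

    allele_id: Allele
    sequence: str
    expected_length: int

    def __post_init__(self) -> None:
        if len(self.sequence) != self.expected_length:
            raise ValueError(
                f"{self.allele_id.value}: sequence length {len(self.sequence)} "
                f"!= expected {self.expected_length}"
            )


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def pairwise_distance(a: str, b: str) -> int:
    """Global (Needleman-Wunsch) unit-cost edit distance between two strings."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def make_references(
    seed: int = 0,
    lengths: tuple[int, int, int] = (185, 308, 335),
) -> dict[Allele, AlleleReference]:
    """Build the three allele references.

    Each reference reads, in the orientation of the UMI-bearing read:
    gene-specific reverse flank, random interior, reverse complement of the
    gene-specific forward flank.  All three share both flanks verbatim.

    Parameters
    ----------
    seed
        Seed for the interior sequences; the same seed reproduces the same
        references byte for byte.
    lengths
        Amplicon lengths for (wt, ca_native, ca_active); defaults to the
        assay's 185/308/335 bp.

    Raises
    ------
    ValueError
        If any requested length cannot hold both primer flanks.
    """
    alleles = (Allele.WT, Allele.CA_NATIVE, Allele.CA_ACTIVE)
    for allele, length in zip(alleles, lengths):
        if length <= FLANK_LENGTH:
            raise ValueError(
                f"{allele.value}: amplicon length {length} bp cannot hold the "
                f"two primer flanks ({FLANK_LENGTH} bp combined)"
            )
    tail = reverse_complement(FORWARD_GENE_FLANK)
    for attempt in range(32):
        rng = np.random.default_rng([seed % 2**31, attempt])
        refs = {}
        for allele, length in zip(alleles, lengths):
            interior = _random_dna(rng, length - FLANK_LENGTH)
            refs[allele] = AlleleReference(
                allele, REVERSE_GENE_FLANK + interior + tail, length
            )
        dmin = min(
            pairwise_distance(refs[a].sequence, refs[b].sequence)
            for i, a in enumerate(alleles)
            for b in alleles[i + 1 :]
        )
        if dmin > MIN_PAIRWISE_DISTANCE:
            return refs
    raise RuntimeError(
        "could not generate references with sufficient mutual edit distance"
    )  # pragma: no cover - random sequences essentially never collide


def write_references_fasta(refs: dict[Allele, AlleleReference], path) -> None:
    records = [
        SeqRecord(
            Seq(ref.sequence),
            id=ref.allele_id.value,
            description=f"expected_length={ref.expected_length}",
        )
        for ref in refs.values()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_references_fasta(path) -> dict[Allele, AlleleReference]:
    refs = {}
    for record in SeqIO.parse(str(path), "fasta"):
        allele = Allele(record.id)
        seq = str(record.seq).upper()
        refs[allele] = AlleleReference(allele, seq, len(seq))
    missing = set(Allele) - set(refs)
    if missing:
        raise ValueError(
            "reference FASTA is missing alleles: "
            + ", ".join(sorted(a.value for a in missing))
        )
    return refs
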