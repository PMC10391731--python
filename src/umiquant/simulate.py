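"""Simulation of a UMI-tagged Braf amplicon sequencing library.

The generative model mirrors the barcoded amplicon protocol:

1.  A population of heterozygous cells each carries one wildtype template
    and one conditional-allele template; a small fraction of cells has the
    recombined (activated) form of the conditional allele.
2.  A low-cycle barcoding PCR attaches a random 12-nt UMI to each captured
    template molecule (capture efficiency ``templates_per_allele_per_cell``).
3.  Exponential amplification (barcoding + adapter PCR cycles) copies each
    molecule along a branching lineage, with an independent per-base
    substitution probability at every copying event — so errors arising in
    early cycles are shared by the descendant reads of that branch.
4.  Sequencing draws a Poisson number of reads per molecule and applies
    per-base errors whose probabilities are exactly the ones encoded in the
    emitted Phred+33 quality string.

Every read is the full amplicon in the orientation of the UMI-bearing
primer: constant prefix, UMI, allele sequence, then the read-through adapter
(the reverse complement of the opposite primer tail).  A truth sidecar links
every read to its founding molecule for end-to-end validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import SequencedRead
from .references import (
    READTHROUGH_ADAPTER,
    UMI_CONSTANT_PREFIX,
    Allele,
    AlleleReference,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

#: Quality assigned when the sequencing channel is error-free.
MAX_QUALITY = 41


@dataclass
class SampleModel:
    """Parameters of one simulated sample.

    Defaults describe the non-induced regime: ~10,000 cells of which 0.5%
    carry the activated allele, capture efficiency and depth calibrated so a
    sample yields on the order of 10^4 reads with tens of activated reads.
    """

    n_cells: int = 10_000
    activated_cell_fraction: float = 0.005
    templates_per_allele_per_cell: float = 0.16
    umi_length: int = 12
    barcoding_cycles: int = 3
    adapter_cycles: int = 28
    pcr_error_rate: float = 1e-5
    seq_error_rate: float = 0.005
    low_quality_prob: float = 0.0002
    mean_reads_per_molecule: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.activated_cell_fraction <= 1.0:
            raise ValueError("activated_cell_fraction must be in [0, 1]")
        if not 0.0 < self.templates_per_allele_per_cell <= 1.0:
            raise ValueError(
                "templates_per_allele_per_cell (capture efficiency) must be in (0, 1]"
            )
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.mean_reads_per_molecule <= 0:
            raise ValueError("mean_reads_per_molecule must be positive")
        for name in ("pcr_error_rate", "seq_error_rate", "low_quality_prob"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.umi_length < 1:
            raise ValueError("umi_length must be positive")

    @property
    def total_cycles(self) -> int:
        return self.barcoding_cycles + self.adapter_cycles


@dataclass
class TruthRecord:
    """Ground truth for one tagged template molecule."""

    molecule_id: str
    allele_id: Allele
    umi: str
    n_reads: int = 0


def simulate_sample(
    refs: dict[Allele, AlleleReference], model: SampleModel
) -> list[TruthRecord]:
    """Draw the tagged template molecules of one sample.

    Each cell contributes one wildtype and one conditional-allele template;
    each template is captured independently with probability
    ``templates_per_allele_per_cell``; every captured molecule receives an
    independent UMI drawn uniformly from the 4^umi_length space.
    """
    rng = np.random.default_rng([model.seed % 2**31, 0])
    n = model.n_cells
    t = model.templates_per_allele_per_cell
    activated = rng.random(n) < model.activated_cell_fraction
    wt_captured = rng.random(n) < t
    ca_captured = rng.random(n) < t
    alleles: list[Allele] = [Allele.WT] * int(wt_captured.sum())
    alleles += [
        Allele.CA_ACTIVE if act else Allele.CA_NATIVE
        for act, cap in zip(activated, ca_captured)
        if cap
    ]
    n_mol = len(alleles)
    umis = _BASES[rng.integers(0, 4, size=(n_mol, model.umi_length))]
    return [
        TruthRecord(f"M{i:06d}", allele, umis[i].tobytes().decode())
        for i, allele in enumerate(alleles)
    ]


def _phred_char(q: int) -> str:
    return chr(q + 33)


def _lineage_mutations(
    rng: np.random.Generator,
    cache: dict,
    path_bits: np.ndarray,
    length: int,
    rate: float,
) -> dict[int, int]:
    """Substitutions accumulated along one amplification lineage.

    A lineage is a root-to-leaf path through the (abstract) PCR copy tree,
    encoded as branch bits; mutation sets are cached per tree node so reads
    sharing an ancestral branch share its errors.
    """
    muts: dict[int, int] = {}
    key = 1  # leading sentinel bit makes the encoding prefix-unique
    for bit in path_bits:
        key = (key << 1) | int(bit)
        node = cache.get(key)
        if node is None:
            k = rng.poisson(length * rate)
            if k:
                pos = rng.integers(0, length, size=k)
                shift = rng.integers(1, 4, size=k)
                node = list(zip(pos.tolist(), shift.tolist()))
            else:
                node = ()
            cache[key] = node
        for pos, shift in node:
            # net shift 0 after repeated hits is a genuine back-mutation
            muts[pos] = (muts.get(pos, 0) + shift) % 4
    return muts


def sequence_reads(
    molecules: list[TruthRecord],
    refs: dict[Allele, AlleleReference],
    model: SampleModel,
) -> list[SequencedRead]:
    """Emit sequencing reads for the tagged molecules.

    Read counts per molecule are Poisson(``mean_reads_per_molecule``).
    Updates ``n_reads`` on each :class:`TruthRecord` in place and returns the
    reads in a fixed deterministic order.
    """
    rng = np.random.default_rng([model.seed % 2**31, 1])
    seq_err = model.seq_error_rate
    if seq_err > 0:
        q_hi = int(np.clip(round(-10 * math.log10(seq_err)), 2, MAX_QUALITY))
    else:
        q_hi = MAX_QUALITY
    reads: list[SequencedRead] = []
    n_reads_per_mol = rng.poisson(model.mean_reads_per_molecule, size=len(molecules))
    for mol, n_reads in zip(molecules, n_reads_per_mol):
        mol.n_reads = int(n_reads)
        if n_reads == 0:
            continue
        template = (
            UMI_CONSTANT_PREFIX
            + mol.umi
            + refs[mol.allele_id].sequence
            + READTHROUGH_ADAPTER
        )
        tarr = np.frombuffer(template.encode(), dtype=np.uint8)
        L = len(tarr)
        lineage_cache: dict = {}
        for j in range(n_reads):
            arr = tarr.copy()
            if model.pcr_error_rate > 0:
                bits = rng.integers(0, 2, size=model.total_cycles)
                for pos, shift in _lineage_mutations(
                    rng, lineage_cache, bits, L, model.pcr_error_rate
                ).items():
                    arr[pos] = _BASES[(_BASE_INDEX[arr[pos]] + shift) % 4]
            # emitted qualities define the per-base error probabilities used
            qual = np.full(L, q_hi, dtype=np.int32)
            if model.low_quality_prob > 0:
                n_low = rng.binomial(L, model.low_quality_prob)
                if n_low:
                    low_pos = rng.choice(L, size=n_low, replace=False)
                    qual[low_pos] = rng.integers(2, 16, size=n_low)
            if seq_err > 0:
                err_p = 10.0 ** (-qual / 10.0)
                hit = np.nonzero(rng.random(L) < err_p)[0]
                if hit.size:
                    shift = rng.integers(1, 4, size=hit.size)
                    arr[hit] = _BASES[(_BASE_INDEX[arr[hit]] + shift) % 4]
            reads.append(
                SequencedRead(
                    read_id=f"{mol.molecule_id}:r{j}",
                    bases=arr.tobytes().decode(),
                    qualities=(qual + 33).astype(np.uint8).tobytes().decode(),
                    truth=mol.molecule_id,
                )
            )
    return reads


def write_fastq(reads: list[SequencedRead], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.bases}\n+\n{read.qualities}\n")


def read_fastq(path) -> list[SequencedRead]:
    """Load a Phred+33 FASTQ file; read ids of the form M...:r... keep truth links."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    reads = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            read_id = title.split()[0]
            truth = read_id.rsplit(":r", 1)[0] if ":r" in read_id else None
            reads.append(SequencedRead(read_id, seq, qual, truth=truth))
    return reads


def write_truth(molecules: list[TruthRecord], path) -> None:
    pd.DataFrame(
        {
            "molecule_id": [m.molecule_id for m in molecules],
            "allele_id": [m.allele_id.value for m in molecules],
            "umi": [m.umi for m in molecules],
            "n_reads": [m.n_reads for m in molecules],
        }
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"umi": str})
    return [
        TruthRecord(row.molecule_id, Allele(row.allele_id), row.umi, int(row.n_reads))
        for row in df.itertuples()
    ]


def truth_table(molecules: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "molecule_id": [m.molecule_id for m in molecules],
            "allele_id": [m.allele_id.value for m in molecules],
            "umi": [m.umi for m in molecules],
            "n_reads": [m.n_reads for m in molecules],
        }
    )
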