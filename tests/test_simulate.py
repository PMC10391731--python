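import numpy as np
import pytest

import umiquant as uq
from umiquant import Allele, SampleModel, sequence_reads, simulate_sample


def small_model(**kw):
    base = dict(
        n_cells=200,
        activated_cell_fraction=0.2,
        templates_per_allele_per_cell=1.0,
        pcr_error_rate=0.0,
        seq_error_rate=0.0,
        low_quality_prob=0.0,
        mean_reads_per_molecule=5.0,
        seed=3,
    )
    base.update(kw)
    return SampleModel(**base)


def test_fraction_boundaries(refs):
    none = simulate_sample(refs, small_model(activated_cell_fraction=0.0))
    assert not any(m.allele_id is Allele.CA_ACTIVE for m in none)
    every = simulate_sample(refs, small_model(activated_cell_fraction=1.0))
    assert not any(m.allele_id is Allele.CA_NATIVE for m in every)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        small_model(activated_cell_fraction=1.5)
    with pytest.raises(ValueError):
        small_model(activated_cell_fraction=-0.1)
    with pytest.raises(ValueError):
        small_model(mean_reads_per_molecule=0.0)
    with pytest.raises(ValueError):
        small_model(templates_per_allele_per_cell=0.0)


def test_activated_share_matches_binomial_sampling():
    """Across 50 seeds the activated share of CA molecules tracks the cell fraction."""
    refs = uq.make_references()
    ratios = []
    for seed in range(50):
        mols = simulate_sample(
            refs,
            SampleModel(
                n_cells=10_000,
                activated_cell_fraction=0.005,
                templates_per_allele_per_cell=0.16,
                seed=seed,
            ),
        )
        active = sum(m.allele_id is Allele.CA_ACTIVE for m in mols)
        native = sum(m.allele_id is Allele.CA_NATIVE for m in mols)
        ratios.append(active / (active + native))
    mean = np.mean(ratios)
    se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
    assert abs(mean - 0.005) <= 3 * se


def test_expected_molecule_count(refs):
    mols = simulate_sample(
        refs, small_model(n_cells=5000, templates_per_allele_per_cell=0.5)
    )
    expected = 2 * 5000 * 0.5
    assert abs(len(mols) - expected) < 4 * np.sqrt(expected)


def test_umi_collisions_within_birthday_bound(refs):
    """Duplicate UMIs stay within 10x the n(n-1)/2 / 4^12 expectation."""
    total_pairs = 0
    collisions = 0
    for seed in range(3):
        mols = simulate_sample(
            refs,
            small_model(n_cells=10_000, templates_per_allele_per_cell=1.0, seed=seed),
        )
        n = len(mols)
        total_pairs += n * (n - 1) / 2
        collisions += n - len({m.umi for m in mols})
    bound = 10 * total_pairs / 4**12
    assert collisions <= max(bound, 1)


def test_zero_noise_reads_identical_to_template(refs, zero_error_run):
    molecules, reads = zero_error_run
    by_id = {m.molecule_id: m for m in molecules}
    for read in reads[:500]:
        mol = by_id[read.truth]
        expected = (
            uq.references.UMI_CONSTANT_PREFIX
            + mol.umi
            + refs[mol.allele_id].sequence
            + uq.references.READTHROUGH_ADAPTER
        )
        assert read.bases == expected


def test_read_count_distribution(refs):
    mols = simulate_sample(
        refs, small_model(n_cells=500, mean_reads_per_molecule=10.0)
    )
    reads = sequence_reads(mols, refs, small_model(n_cells=500, mean_reads_per_molecule=10.0))
    total_expected = len(mols) * 10.0
    # total is Poisson(n * mean); 3 sd band
    assert abs(len(reads) - total_expected) <= 3 * np.sqrt(total_expected)
    assert sum(m.n_reads for m in mols) == len(reads)


def test_truth_conservation(zero_error_run):
    molecules, reads = zero_error_run
    ids = {m.molecule_id for m in molecules}
    assert all(r.truth in ids for r in reads)


def test_zero_error_umi_allele_multiset_matches_truth(zero_error_run, refs):
    molecules, reads = zero_error_run
    prefix_len = len(uq.references.UMI_CONSTANT_PREFIX)
    observed = {
        (r.bases[prefix_len : prefix_len + 12], len(r.bases)) for r in reads
    }
    expected = {
        (m.umi, prefix_len + 12 + refs[m.allele_id].expected_length + 34)
        for m in molecules
        if m.n_reads > 0
    }
    assert observed == expected


def test_simulation_reproducible_from_seed(refs):
    m = small_model(seq_error_rate=0.005, pcr_error_rate=1e-4, low_quality_prob=0.001)
    mols1 = simulate_sample(refs, m)
    reads1 = sequence_reads(mols1, refs, m)
    mols2 = simulate_sample(refs, m)
    reads2 = sequence_reads(mols2, refs, m)
    assert [(r.read_id, r.bases, r.qualities) for r in reads1] == [
        (r.read_id, r.bases, r.qualities) for r in reads2
    ]


def test_fastq_format(refs, tmp_path, zero_error_run):
    _, reads = zero_error_run
    path = tmp_path / "out.fastq"
    uq.write_fastq(reads, path)
    lines = path.read_text().splitlines()
    assert len(lines) == 4 * len(reads)
    back = uq.read_fastq(path)
    assert [(r.read_id, r.bases, r.qualities) for r in back] == [
        (r.read_id, r.bases, r.qualities) for r in reads
    ]
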