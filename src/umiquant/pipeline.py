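"""End-to-end driver: preprocess -> classify -> consensus -> quantify.

The pipeline can be run on existing FASTQ files with a reference FASTA, or
entirely from a simulation specification; either way a single seed in the
configuration makes the run byte-for-byte reproducible.  Configuration is a
flat YAML document::

    seed: 1
    references: {fasta: refs.fasta}          # or {seed: 1, lengths: [185, 308, 335]}
    thresholds:
      min_q: 20
      min_fraction: 1.0
      family_min_reads: 3
      max_noise_families: 6
    samples:
      - id: lung_1
        fastq: lung_1.fastq                  # or simulate: {n_cells: ..., ...}
    out_dir: results/run1                    # optional; TSV/JSON artifacts
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from . import classify as _classify
from . import consensus as _consensus
from . import preprocess as _preprocess
from . import simulate as _simulate
from .quantify import AlleleQuantModel, AlleleQuantResults
from .references import (
    Allele,
    AlleleReference,
    make_references,
    read_references_fasta,
    write_references_fasta,
)

DEFAULT_THRESHOLDS = {
    "adapter": _preprocess.READTHROUGH_ADAPTER,
    "min_q": 20,
    "min_fraction": 1.0,
    "min_overlap": 3,
    "max_error_rate": 0.1,
    "umi_length": 12,
    "max_prefix_mismatch": 1,
    "max_dist_fraction": 0.1,
    "min_margin": 3,
    "family_min_reads": _consensus.DEFAULT_FAMILY_MIN_READS,
    "min_vote_fraction": 0.6,
    "merge_hamming1": False,
    "max_noise_families": _consensus.DEFAULT_MAX_NOISE_FAMILIES,
}


class PipelineError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclasses.dataclass
class SampleResult:
    """Everything the pipeline derives from one sample."""

    results: AlleleQuantResults
    preprocess_log: _preprocess.PreprocessLog
    category_counts: dict[str, int]
    classified: pd.DataFrame
    families: pd.DataFrame
    truth: list[_simulate.TruthRecord] | None = None
    n_reads_in: int = 0


def quantify_sample(
    reads: list[_preprocess.SequencedRead],
    refs: dict[Allele, AlleleReference],
    sample_id: str,
    thresholds: dict | None = None,
    truth: list[_simulate.TruthRecord] | None = None,
) -> SampleResult:
    """Run the analysis stages on in-memory reads for one sample."""
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    if not reads:
        raise PipelineError("preprocess", f"sample {sample_id}: no input reads")
    passed, log = _preprocess.preprocess_reads(
        reads,
        adapter=th["adapter"],
        min_q=th["min_q"],
        min_fraction=th["min_fraction"],
        min_overlap=th["min_overlap"],
        max_error_rate=th["max_error_rate"],
        umi_length=th["umi_length"],
    )
    classified, categories = _classify.classify_reads(
        passed,
        refs,
        umi_length=th["umi_length"],
        max_prefix_mismatch=th["max_prefix_mismatch"],
        max_dist_fraction=th["max_dist_fraction"],
        min_margin=th["min_margin"],
    )
    families = _consensus.build_families(
        classified,
        family_min_reads=th["family_min_reads"],
        min_vote_fraction=th["min_vote_fraction"],
        merge_hamming1=th["merge_hamming1"],
    )
    model = AlleleQuantModel.from_families(
        families,
        sample_id,
        max_noise_families=th["max_noise_families"],
        thresholds={
            k: th[k]
            for k in ("min_q", "min_fraction", "family_min_reads", "min_vote_fraction")
        },
    )
    return SampleResult(
        results=model.fit(),
        preprocess_log=log,
        category_counts=categories,
        classified=classified,
        families=families,
        truth=truth,
        n_reads_in=len(reads),
    )


def simulate_and_quantify(
    refs: dict[Allele, AlleleReference],
    model: _simulate.SampleModel,
    sample_id: str,
    thresholds: dict | None = None,
) -> SampleResult:
    """Simulate one sample and push it through the full pipeline."""
    molecules = _simulate.simulate_sample(refs, model)
    reads = _simulate.sequence_reads(molecules, refs, model)
    return quantify_sample(reads, refs, sample_id, thresholds, truth=molecules)


def _load_references(spec: dict) -> dict[Allele, AlleleReference]:
    if "fasta" in spec:
        return read_references_fasta(spec["fasta"])
    lengths = tuple(spec.get("lengths", (185, 308, 335)))
    return make_references(seed=spec.get("seed", 0), lengths=lengths)


def run_pipeline(config: dict | str | Path, out_dir=None) -> list[SampleResult]:
    """Execute the pipeline for every sample in a configuration.

    ``config`` is a mapping or the path of a YAML file.  When ``out_dir``
    (or the config's ``out_dir``) is set, per-sample TSV artifacts and a
    machine-readable ``report.json`` are written there.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    try:
        seed = int(config["seed"])
    except KeyError as exc:
        raise PipelineError("config", "a seed is mandatory") from exc
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    try:
        refs = _load_references(config.get("references", {"seed": seed}))
    except (OSError, ValueError) as exc:
        raise PipelineError("references", str(exc)) from exc

    results: list[SampleResult] = []
    samples = config.get("samples")
    if not samples:
        raise PipelineError("config", "no samples defined")
    for i, sample in enumerate(samples):
        sample_id = str(sample.get("id", f"sample_{i}"))
        if "fastq" in sample:
            try:
                reads = _simulate.read_fastq(sample["fastq"])
            except OSError as exc:
                raise PipelineError("preprocess", str(exc)) from exc
            truth = (
                _simulate.read_truth(sample["truth"]) if sample.get("truth") else None
            )
            results.append(
                quantify_sample(reads, refs, sample_id, thresholds, truth=truth)
            )
        elif "simulate" in sample:
            spec = dict(sample["simulate"])
            spec.setdefault("seed", (seed * 1009 + i) % 2**31)
            sim_model = _simulate.SampleModel(**spec)
            results.append(
                simulate_and_quantify(refs, sim_model, sample_id, thresholds)
            )
        else:
            raise PipelineError(
                "config", f"sample {sample_id}: needs 'fastq' or 'simulate'"
            )

    out_dir = out_dir or config.get("out_dir")
    if out_dir:
        write_run_artifacts(results, refs, Path(out_dir))
    return results


def write_run_artifacts(
    results: list[SampleResult],
    refs: dict[Allele, AlleleReference],
    out_dir: Path,
) -> None:
    """Write per-sample TSVs and the versioned machine-readable report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_references_fasta(refs, out_dir / "references.fasta")
    report = {"schema": "umiquant-report/1", "samples": []}
    for res in results:
        sid = res.results.sample_id
        res.classified.to_csv(out_dir / f"{sid}.classified.tsv", sep="\t", index=False)
        res.families.to_csv(out_dir / f"{sid}.families.tsv", sep="\t", index=False)
        pd.DataFrame([res.preprocess_log.to_dict()]).to_csv(
            out_dir / f"{sid}.preprocess.tsv", sep="\t", index=False
        )
        pd.DataFrame([res.category_counts]).to_csv(
            out_dir / f"{sid}.categories.tsv", sep="\t", index=False
        )
        if res.truth is not None:
            _simulate.write_truth(res.truth, out_dir / f"{sid}.truth.tsv")
        report["samples"].append(res.results.to_dict())
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
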