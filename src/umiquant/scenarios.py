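"""Study-arm scenarios binding the simulator to testable regimes.

Three scenarios mirror the experimental arms:

* ``null`` — no recombination at all (activated-cell fraction 0);
* ``non_induced`` — spontaneous (leaky) Cre activity in a small minority of
  cells (fraction 0.005, under the sub-1% regime), calibrated so a sample
  yields roughly 10^4 total reads with tens of activated reads;
* ``induced`` — tamoxifen-induced recombination in a large minority of
  cells (fraction 0.3).

Each scenario can be materialized to disk (FASTQ, reference FASTA, truth
TSV, expected-summary JSON) or run straight through the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

from . import simulate as _simulate
from .pipeline import SampleResult, simulate_and_quantify
from .references import Allele, make_references, write_references_fasta
from .simulate import SampleModel

REGIMES = ("null", "non_induced", "induced")

#: Prevalence cut points separating regimes: exactly 0 -> null, below 1% ->
#: non-induced leak, at or above 10% -> induced.
NON_INDUCED_MAX_PREVALENCE = 0.01
INDUCED_MIN_PREVALENCE = 0.10


@dataclass
class Scenario:
    name: str
    expected_regime: str
    sample_models: list[SampleModel]

    def __post_init__(self) -> None:
        if self.expected_regime not in REGIMES:
            raise ValueError(f"unknown regime {self.expected_regime!r}")
        for m in self.sample_models:
            f = m.activated_cell_fraction
            if self.expected_regime == "null" and f != 0:
                raise ValueError("null scenarios require fraction 0")
            if self.expected_regime == "non_induced" and not 0 < f < 0.01:
                raise ValueError("non-induced scenarios require fraction in (0, 0.01)")
            if self.expected_regime == "induced" and f <= 0.1:
                raise ValueError("induced scenarios require fraction > 0.1")


def _base_model(seed: int) -> SampleModel:
    return SampleModel(seed=seed)


def default_scenarios(seed: int, n_samples: int = 1) -> list[Scenario]:
    """The three study-arm scenarios with per-sample seeds derived from ``seed``."""

    def models(fraction: float, offset: int) -> list[SampleModel]:
        return [
            replace(
                _base_model((seed * 100003 + offset * 1000 + i) % 2**31),
                activated_cell_fraction=fraction,
            )
            for i in range(n_samples)
        ]

    return [
        Scenario("null", "null", models(0.0, 0)),
        Scenario("non_induced", "non_induced", models(0.005, 1)),
        Scenario("induced", "induced", models(0.3, 2)),
    ]


def classify_regime(prevalence: float | None) -> str:
    """Map a raw activation prevalence onto a regime label."""
    if prevalence is None or prevalence == 0:
        return "null"
    if prevalence < NON_INDUCED_MAX_PREVALENCE:
        return "non_induced"
    if prevalence >= INDUCED_MIN_PREVALENCE:
        return "induced"
    return "intermediate"


def run_scenario(
    scenario: Scenario, refs=None, thresholds: dict | None = None
) -> list[SampleResult]:
    """Simulate every sample of a scenario and run the pipeline on each."""
    refs = refs or make_references()
    return [
        simulate_and_quantify(refs, model, f"{scenario.name}_{i}", thresholds)
        for i, model in enumerate(scenario.sample_models)
    ]


def make_scenarios(out_dir, seed: int, n_samples: int = 1) -> list[Path]:
    """Write the scenario suite to disk, one directory per scenario.

    Each directory holds the shared references, per-sample FASTQ and truth
    sidecar, and an ``expected_summary.json`` with the scenario's regime and
    per-sample truth tallies.
    """
    out_dir = Path(out_dir)
    refs = make_references()
    written = []
    for scenario in default_scenarios(seed, n_samples=n_samples):
        sdir = out_dir / scenario.name
        sdir.mkdir(parents=True, exist_ok=True)
        write_references_fasta(refs, sdir / "references.fasta")
        summary = {"name": scenario.name, "expected_regime": scenario.expected_regime,
                   "samples": []}
        for i, model in enumerate(scenario.sample_models):
            molecules = _simulate.simulate_sample(refs, model)
            reads = _simulate.sequence_reads(molecules, refs, model)
            _simulate.write_fastq(reads, sdir / f"sample_{i}.fastq")
            _simulate.write_truth(molecules, sdir / f"sample_{i}.truth.tsv")
            tally = {a.value: 0 for a in Allele}
            for mol in molecules:
                tally[mol.allele_id.value] += 1
            summary["samples"].append(
                {
                    "sample_id": f"sample_{i}",
                    "seed": model.seed,
                    "activated_cell_fraction": model.activated_cell_fraction,
                    "n_molecules": tally,
                    "n_reads": len(reads),
                }
            )
        with open(sdir / "expected_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(sdir)
    return written
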