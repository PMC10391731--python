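"""Estimators over barcode-family counts, statsmodels-style.

:class:`AlleleQuantModel` wraps the consensus family counts of one sample;
``fit()`` returns an :class:`AlleleQuantResults` carrying the two sample
estimates with 95% intervals:

* activation prevalence — activated families divided by total
  (native + activated) conditional-allele families, with a Wilson score
  interval;
* mutant cell fraction — activated families divided by wildtype families.
  Under the heterozygous model every cell contributes one wildtype template,
  so this ratio estimates the proportion of cells carrying the recombined
  oncogene.  Its interval propagates the Wilson bounds of the underlying
  proportion through the odds transform.

Group comparison uses the Welch (unequal-variance) two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .consensus import (
    DEFAULT_FAMILY_MIN_READS,
    DEFAULT_MAX_NOISE_FAMILIES,
    AlleleFamilyCounts,
    apply_noise_floor,
    build_families,
    count_families,
)


@dataclass(frozen=True)
class Estimate:
    """A point estimate with a 95% interval, or a missing value with a reason."""

    value: float | None
    ci_low: float | None
    ci_high: float | None
    n: int
    reason: str | None = None

    @property
    def missing(self) -> bool:
        return self.value is None

    def __str__(self) -> str:
        if self.missing:
            return f"NA ({self.reason})"
        return f"{self.value:.6g} [{self.ci_low:.6g}, {self.ci_high:.6g}]"


def _wilson(count: int, nobs: int) -> tuple[float, float]:
    low, high = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(low), float(high)


def activation_prevalence(
    counts: AlleleFamilyCounts, use_reported: bool = True
) -> Estimate:
    """Activated / (native + activated) conditional-allele families."""
    src = counts.reported if use_reported else counts.raw
    active = src["ca_active"]
    denom = active + src["ca_native"]
    if denom == 0:
        return Estimate(None, None, None, 0, reason="no conditional-allele families")
    low, high = _wilson(active, denom)
    return Estimate(active / denom, low, high, denom)


def mutant_cell_fraction(
    counts: AlleleFamilyCounts, use_reported: bool = True
) -> Estimate:
    """Activated families per wildtype family (proportion of mutant cells)."""
    src = counts.reported if use_reported else counts.raw
    active, wt = src["ca_active"], src["wt"]
    if wt == 0:
        return Estimate(None, None, None, 0, reason="no wildtype families")
    low, high = _wilson(active, active + wt)
    return Estimate(
        active / wt,
        max(low / (1.0 - low), 0.0),
        high / (1.0 - high) if high < 1.0 else math.inf,
        active + wt,
    )


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample comparison, or the degenerate exact-equality report."""

    difference: float
    t: float | None
    p: float | None
    df: float | None
    degenerate: bool = False
    equal: bool | None = None


def compare_groups(group1, group2) -> GroupComparison:
    """Welch t-test between two groups of per-sample estimates.

    Zero-variance degenerate groups (no within-group spread anywhere) fall
    back to an exact-equality report rather than an undefined t statistic.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two samples")
    diff = float(x.mean() - y.mean())
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        return GroupComparison(diff, None, None, None, degenerate=True, equal=diff == 0)
    res = stats.ttest_ind(x, y, equal_var=False)
    return GroupComparison(diff, float(res.statistic), float(res.pvalue), float(res.df))


class AlleleQuantModel:
    """Quantification model for one sample's barcode-family counts.

    Parameters
    ----------
    counts
        Raw consensus-family counts per allele class.
    max_noise_families
        Noise floor applied at ``fit`` time (class counts at or below it are
        reported as zero).
    thresholds
        Free-form record of the upstream thresholds, carried into results.
    """

    def __init__(
        self,
        counts: AlleleFamilyCounts,
        max_noise_families: int = DEFAULT_MAX_NOISE_FAMILIES,
        thresholds: dict | None = None,
    ):
        self.counts = counts
        self.max_noise_families = max_noise_families
        self.thresholds = dict(thresholds or {})

    @classmethod
    def from_families(
        cls,
        families,
        sample_id: str,
        max_noise_families: int = DEFAULT_MAX_NOISE_FAMILIES,
        thresholds: dict | None = None,
    ) -> "AlleleQuantModel":
        """Build from a families table (output of :func:`build_families`)."""
        return cls(
            count_families(families, sample_id),
            max_noise_families=max_noise_families,
            thresholds=thresholds,
        )

    @classmethod
    def from_classified_reads(
        cls,
        classified,
        sample_id: str,
        family_min_reads: int = DEFAULT_FAMILY_MIN_READS,
        min_vote_fraction: float = 0.6,
        max_noise_families: int = DEFAULT_MAX_NOISE_FAMILIES,
        merge_hamming1: bool = False,
    ) -> "AlleleQuantModel":
        """Build from a per-read classification table."""
        families = build_families(
            classified,
            family_min_reads=family_min_reads,
            min_vote_fraction=min_vote_fraction,
            merge_hamming1=merge_hamming1,
        )
        thresholds = {
            "family_min_reads": family_min_reads,
            "min_vote_fraction": min_vote_fraction,
            "max_noise_families": max_noise_families,
        }
        return cls.from_families(
            families, sample_id, max_noise_families, thresholds=thresholds
        )

    def fit(self) -> "AlleleQuantResults":
        floored = apply_noise_floor(self.counts, self.max_noise_families)
        return AlleleQuantResults(
            sample_id=self.counts.sample_id,
            counts=floored,
            activation_prevalence=activation_prevalence(floored),
            mutant_cell_fraction=mutant_cell_fraction(floored),
            raw_activation_prevalence=activation_prevalence(floored, use_reported=False),
            raw_mutant_cell_fraction=mutant_cell_fraction(floored, use_reported=False),
            thresholds={
                **self.thresholds,
                "max_noise_families": self.max_noise_families,
            },
        )


@dataclass
class AlleleQuantResults:
    """Per-sample quantification results.

    ``activation_prevalence`` and ``mutant_cell_fraction`` use the
    noise-suppressed (reported) counts — the sample's detection calls; the
    ``raw_*`` twins use unsuppressed counts and are what simulation-recovery
    comparisons should use, since suppression deliberately biases small
    signals to zero.
    """

    sample_id: str
    counts: AlleleFamilyCounts
    activation_prevalence: Estimate
    mutant_cell_fraction: Estimate
    raw_activation_prevalence: Estimate
    raw_mutant_cell_fraction: Estimate
    thresholds: dict

    def to_dict(self) -> dict:
        def est(e: Estimate) -> dict:
            return {
                "value": e.value,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n": e.n,
                "reason": e.reason,
            }

        return {
            "sample_id": self.sample_id,
            "counts": self.counts.to_dict(),
            "activation_prevalence": est(self.activation_prevalence),
            "mutant_cell_fraction": est(self.mutant_cell_fraction),
            "raw_activation_prevalence": est(self.raw_activation_prevalence),
            "raw_mutant_cell_fraction": est(self.raw_mutant_cell_fraction),
            "thresholds": dict(self.thresholds),
        }

    def summary(self) -> str:
        c = self.counts
        lines = [
            f"Allele quantification — sample {self.sample_id}",
            "=" * 54,
            f"{'allele class':<14}{'raw families':>14}{'reported':>12}{'suppressed':>12}",
        ]
        for allele in ("wt", "ca_native", "ca_active"):
            lines.append(
                f"{allele:<14}{c.raw[allele]:>14}{c.reported[allele]:>12}"
                f"{str(c.suppressed[allele]):>12}"
            )
        lines += [
            "-" * 54,
            f"activation prevalence : {self.activation_prevalence}",
            f"mutant cell fraction  : {self.mutant_cell_fraction}",
            f"  (raw prevalence     : {self.raw_activation_prevalence})",
            f"  (raw cell fraction  : {self.raw_mutant_cell_fraction})",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar chart of raw vs reported family counts per allele class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 3))
        alleles = ("wt", "ca_native", "ca_active")
        x = np.arange(len(alleles))
        ax.bar(x - 0.2, [self.counts.raw[a] for a in alleles], 0.4, label="raw")
        ax.bar(
            x + 0.2, [self.counts.reported[a] for a in alleles], 0.4, label="reported"
        )
        ax.set_xticks(x, alleles)
        ax.set_ylabel("barcode families")
        ax.set_title(self.sample_id)
        ax.legend()
        return ax
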