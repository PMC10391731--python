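# Methods

## Model of the assay

A heterozygous `Braf^CA/+` cell carries one wildtype *Braf* allele and one
conditional knock-in allele; Cre recombination switches the conditional
allele from its native (308 bp amplicon) to its activated (335 bp) form,
while the wildtype amplicon is 185 bp. A barcoding PCR attaches a 12-nt
random UMI to each captured template via the reverse primer (constant
35-nt tail, 12 N positions, 33-nt gene-specific segment); a second PCR adds
sequencing adapters. Reads are collapsed into barcode families by UMI, each
family is called for one allele, and two per-sample quantities follow:

* **activation prevalence** `p = F_active / (F_native + F_active)` — the
  fraction of conditional-allele molecules that recombined;
* **mutant cell fraction** `m = F_active / F_wt` — since every cell
  contributes exactly one wildtype template, wildtype families count cells,
  and activated families count recombined cells.

Both are estimated on barcode families rather than reads: families are
molecule counts, invariant (beyond threshold effects) to amplification
depth. Read-level tallies are also emitted for comparison.

## Reference construction

The murine amplicon sequences are not published, so references are random
sequences at the correct lengths sharing the two gene-specific primer
segments verbatim as flanks. The pipeline depends only on lengths, flanks
and mutual distinguishability; generated triples are required to be more
than 20 edits apart pairwise (random interiors are far above this), so an
error-free read is never ambiguous.

## Simulator

* **Cells and capture.** Each of `n_cells` cells holds one wildtype and one
  conditional template; the conditional template is activated with
  probability `activated_cell_fraction`. Each template is captured
  independently with probability `templates_per_allele_per_cell` (a
  Bernoulli thinning; values are restricted to (0, 1] because a cell has
  only one template per allele). Captured molecules get i.i.d. uniform
  UMIs from the 4^12 space.
* **PCR errors.** Amplification runs 3 barcoding + 28 adapter cycles. Each
  read descends through a lineage of copy events, encoded as a random
  branch path through the per-molecule copy tree; every tree node draws
  Poisson(L · `pcr_error_rate`) substitutions, and nodes are cached so reads
  sharing an ancestral branch share its errors. Default rate 1e-5 per base
  per cycle (proofreading-polymerase regime); no indels or chimeras.
* **Sequencing.** Reads per molecule are Poisson(`mean_reads_per_molecule`).
  Every read is the full amplicon, single-end, in the UMI-primer
  orientation: constant tail + UMI + allele sequence + read-through
  adapter (the reverse complement of the opposite primer tail). Base
  qualities are `Q = round(-10·log10(seq_error_rate))` (default 0.005 →
  Q23), except a small fraction `low_quality_prob` (default 2e-4) of bases
  drawn at Q2–15; each base is then substituted with probability exactly
  `10^(-Q/10)`, so emitted quality strings encode the error channel
  actually used. `seq_error_rate = 0` is a true zero-error channel emitted
  at Q41 (the conventional "no error observed" cap).
* **Determinism.** All randomness flows from the single `seed` through two
  stage-keyed NumPy generators (molecule sampling, read emission); a fixed
  seed reproduces FASTQ bytes exactly.

### Default study conditions

The defaults describe the non-induced (leaky-Cre) regime: 10,000 cells,
activated-cell fraction 0.005, capture efficiency 0.16, mean 4 reads per
molecule. These were chosen so one sample yields ≈ 12,800 total reads (the
reported 5,000–15,000 per-sample band), tens of activated reads, ≈ 1,100
wildtype families and an activated-family count with Poisson mean ≈ 6 —
i.e. a signal sitting deliberately at the noise floor, as in the tissue
data. The induced arm uses fraction 0.3; the null arm fraction 0.

### What the simulator does not model

Paired-end reads and merging, indels, chimeric amplicons, index hopping,
instrument-specific quality profiles, and template-strand UMI families
(each molecule has one UMI, not one per strand). Passing tests therefore
demonstrate the correctness of the counting and estimation logic under a
substitution-dominant error model, not robustness to structural artifacts
in real libraries.

## Pipeline stages and numerical choices

1. **Trimming.** The 3' adapter (a configuration item; default the
   read-through adapter above) is located at the leftmost offset where the
   adapter — or a prefix of it running off the read end, at least
   `min_overlap = 3` bases — matches with at most 10% mismatches of the
   matched length. Coordinates are 0-based half-open. A batched
   equal-length fast path is verified equivalent to the per-read
   implementation and to a brute-force scan.
2. **Quality filter.** Pass iff at least `min_fraction` (default 1.0) of
   bases reach `min_q` (default 20), Phred+33. Reads shorter than
   prefix + UMI + 10 bases after trimming are discarded as unclassifiable.
3. **UMI extraction.** The 35-nt constant tail must match the read start
   with ≤ 1 mismatch (reads are reverse-complemented first if that
   orientation matches); the next 12 bases are the UMI (reads with N
   dropped and counted), the remainder is the insert. Failures are counted
   as anchorless; all category counts partition the input exactly.
4. **Allele assignment.** Unit-cost edit distance (edlib) from the insert
   to each reference with free end-gaps on the reference. The nearest
   allele is called iff distance ≤ 0.1 × insert length and the runner-up is
   ≥ 3 edits farther; ties and near-ties are unclassified. With references
   > 20 edits apart, confusing the two conditional forms would need > 10
   coordinated errors — effectively impossible at the default error rates.
5. **Families and consensus.** Families are exact-UMI groups (optional
   directional merging of UMIs one substitution apart into strictly larger
   neighbours is available but off by default, since the protocol treats
   UMIs as exact). Families with < 3 reads are discarded. A retained family
   is called for the unique plurality allele holding ≥ 0.6 of its allele
   votes (unclassified reads count toward family size but not votes); ties
   and low shares are discarded.
6. **Noise floor.** Applied per allele class per sample: a class with ≤ 6
   consensus families reports 0 with a suppressed flag; raw counts are
   always retained. Reported (post-floor) counts are the sample's
   *detection* calls; recovery/consistency analyses use the raw counts,
   because the floor deliberately biases small true signals to zero.
7. **Intervals.** Wilson score at 95% for the prevalence proportion; the
   cell-fraction ratio `a/w` maps Wilson bounds on `a/(a+w)` through
   `p/(1-p)` (lower bound clamped at 0). Degenerate zero-variance group
   comparisons return an exact-equality report instead of a t statistic.

## Problem sizes in the test suite

Stochastic checks run at sizes chosen to keep each check's Monte-Carlo
error well inside its assertion band: 20 seeds per arm at the default
non-induced conditions (~13k reads/sample) for the sub-1% and
null-specificity checks, and 20 seeds × 4 activation fractions at a
deep-coverage setting (800 cells, capture 1.0, mean 12 reads/molecule) for
estimator consistency. Depth 12 is used there because ≥ 3-read family
recovery saturates (≥ 99.9%): at shallow depth, recovery is
length-dependent — longer amplicons lose marginally more reads to the
all-bases-Q20 filter — which visibly (≈ 1–2%) depresses the
activated-to-wildtype family ratio. That shallow-depth bias is a genuine
property of this class of assay worth remembering when comparing samples
sequenced at different depths.

## Known limitations

* UMI collisions (two molecules drawing the same 12-mer) merge families;
  at 10^4–10^5 molecules per sample the expected number of colliding pairs
  is ≪ 1% of families and is ignored.
* The noise floor is a hard threshold, not an error-rate model; samples
  whose true activated-family count is near 6 are reported as zero by
  design.
* Group comparison implements only the two-group Welch test; multi-group
  designs should be analysed elsewhere.
* Morphometry consumes measurement tables; image segmentation is out of
  scope. Outputs carry the units of their inputs.
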