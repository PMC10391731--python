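# umiquant

Ultrasensitive quantification of Cre-recombined *Braf* alleles from
UMI-barcoded amplicon sequencing, with a ground-truthed library simulator
and the accompanying organ-morphometry formulas.

## The problem

Tamoxifen-inducible CreER(T2) drivers are slightly leaky: even without
induction, a small fraction of cells in a `Braf^CA/+` mouse spontaneously
recombines the conditional allele and starts expressing oncogenic
BRAF(V600E). Measuring how small that fraction is requires counting
*molecules*, not reads: raw read counts are dominated by PCR amplification
noise. The barcoded-amplicon strategy attaches a random 12-nt unique
molecular identifier (UMI) to each template during a 3-cycle barcoding PCR,
amplifies, sequences, and then collapses reads back into **barcode
families** (reads sharing a UMI). Three amplicons are distinguishable by
sequence and length: wildtype *Braf* (185 bp), the native (unrecombined)
conditional allele (308 bp) and the activated (recombined) allele (335 bp).

The analysis rules implemented here are:

* quality filtering: every base of a read must reach Q20
  (the `-q 20 -Q33 -p 100` configuration), after 3' adapter trimming;
* per-read allele assignment by edit distance against the three references,
  with a best-vs-second-best margin rule;
* barcode families require **≥ 3 reads** with the same UMI;
* an allele class with **≤ 6 families** in a sample is background noise and
  reported as zero (raw counts are kept alongside);
* two estimators per sample, each with a 95% interval:
  * activation prevalence
    `p = F_active / (F_native + F_active)` (Wilson score interval),
  * mutant cell fraction `m = F_active / F_wt` — each cell contributes one
    wildtype template under the heterozygous model, so this estimates the
    proportion of cells carrying the recombined oncogene (Wilson bounds
    propagated through the odds transform);
* Welch's unequal-variance t-test for two-group comparisons;
* thyroid lobe volumetry `V = h·w·d·π/6` (width substitutes a missing
  depth) and pooled lung tumor burden `Σ tumor area / Σ total area`.

Because real reads are not bundled here, a first-class simulator generates
libraries with known ground truth (per-molecule UMIs, allele identities and
read counts), including a branching-lineage PCR substitution-error model
and sequencing errors consistent with the emitted quality strings.

## Worked example

```python
import umiquant as uq

refs = uq.make_references()                      # 185 / 308 / 335 bp references
model = uq.SampleModel(seed=7)                   # non-induced defaults: 10,000 cells,
                                                 # 0.5% activated
result = uq.simulate_and_quantify(refs, model, "demo")
print(result.results.summary())
```

prints

```
Allele quantification — sample demo
======================================================
allele class    raw families    reported  suppressed
wt                      1078        1078       False
ca_native               1056        1056       False
ca_active                  4           0        True
------------------------------------------------------
activation prevalence : 0 [0, 0.00362456]
mutant cell fraction  : 0 [0, 0.00356351]
  (raw prevalence     : 0.00377358 [0.00146842, 0.00966243])
  (raw cell fraction  : 0.00371058 [0.00144062, 0.00955726])
```

Reading this: the sample yielded 1078 wildtype and 1060 conditional-allele
barcode families; 4 activated families fall at or below the 6-family noise
floor, so the *detection* calls (reported columns, top block) are zero,
while the raw estimates put the mutant cell fraction near the simulated
truth of 0.5% — well under 1% of cells, with the Wilson interval excluding
anything above ~1%.

The same run is available from the shell:

```bash
umiquant simulate --out scratch/demo --seed 7
umiquant quantify --config config.yaml
umiquant scenarios --out scratch/scenarios --seed 1
```

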