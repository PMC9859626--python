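# varlod

Somatic SNV/indel calling for cancer NGS data, in tumor-only or
tumor–normal paired mode.

Clinical variant interpretation needs callers that are simultaneously
sensitive to low-frequency somatic mutations (down to ~1% allele
fraction in ctDNA and deep targeted panels) and faithful in how they
*represent* what they find: two adjacent substitutions on the same DNA
molecule are one multi-nucleotide variant (CA→AG), and a deletion with a
nearby substitution on the same reads is one complex allele (GG→A) — not
two or three separate records that downstream annotation will
misinterpret. `varlod` combines a Bayesian-classifier likelihood-ratio
score with Fisher's exact test against the matched normal, phases
adjacent events through single-read co-occurrence, and reports
PCR-duplicate-collapsed allele frequencies behind a configurable filter
ledger.

## The model in brief

At a candidate site with base observations b_i and error probabilities
e_i = 10^(−q_i/10), the mutant-vs-reference log odds is

    LOD = Σ_i log10[ f̂·P(b_i|alt) + (1−f̂)·P(b_i|ref) ] − Σ_i log10 P(b_i|ref),
    P(b|a) = 1−e  if b = a,  e/3 otherwise,

with f̂ the duplicate-collapsed alternate fraction; candidates need
LOD ≥ 3.9. With a matched normal, a candidate is emitted when the normal
is clean (or single-stranded), or its normal-sample LOD is weak, or the
one-sided Fisher exact test on the 2×2 table

    (n1, n0; c1, c0) = (normal var, normal ref; tumor var, tumor ref)

gives p ≤ 0.05 — all behind normal-frequency gates (normal VAF < 2%
absolute or < 0.2× the tumor VAF). VAF = 100 × supporting duplicate
groups / informative duplicate groups; a group of duplicate reads counts
once and supports only when > 80% of its members carry the allele. See
`docs/methods.md` for the full cascade, merging rules, and defaults.

## Worked example

Simulate a 10% SNV at 400× on a synthetic contig and call it:

```bash
varlod simulate --out-dir demo --contig c1 --length 500 \
    --variant 241:G:A:10 --depth 400 --seed 7
varlod call demo/sim.bam demo/sim.bed demo/sim.fa -o demo/calls.vcf
```

The output VCF contains one PASS record (positions are 1-based):

```
c1  241  .  G  A  .  PASS  DP=377;AD=348,29;AF=0.0769231;TLOD=69.1;TYPE=SNV;STR=14,15;ORIGIN=unknown
```

Reading it: the site had 377 duplicate-collapsed informative read
groups (`DP`), 29 of which supported the variant (`AD` ref,var), for a
called allele fraction of 7.7% (`AF`) against the 10% simulated truth —
within binomial sampling noise at this depth. `TLOD` is the
likelihood-ratio score (far above the 3.9 emission threshold),
`STR` shows support balanced across strands (14 forward, 15 reverse),
and `ORIGIN` is `unknown` because no population-frequency or hotspot
sites files were supplied to classify germline vs somatic in tumor-only
mode. In paired mode (`varlod somatic tumor.bam normal.bam ...`) records
instead carry `NDP`/`NAD`, the normal LOD (`NLOD`) and the exact-test
p-value (`FETP`).

`varlod evaluate calls.vcf sim.truth.tsv sim.fa` scores a call set
against the simulator's ground truth and prints tp/fp/fn, precision,
sensitivity, and both F1 conventions (harmonic and product).

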