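# Methods

`varlod` is a somatic SNV/indel caller for targeted and whole-genome NGS
data that works in two modes: tumor-only (output includes germline and
somatic variants, with an origin annotation) and tumor–normal paired
(output is somatic variants surviving a normal-sample cascade). This note
documents the statistical model, the decision cascade, the merging rules
for multi-nucleotide and complex alleles, the quantification conventions,
the synthetic-data generator, and the numerical/design choices that were
genuinely open.

## Candidate scoring: the Bayesian-classifier LOD

At each pileup site the caller compares two models for the retained base
observations b_1..b_n with Phred qualities q_1..q_n (e_i = 10^(−q_i/10)):
a mutant model in which an alternate allele is present at fraction f, and
a reference-only model (f = 0). Per observation,

    P(b_i | allele) = 1 − e_i   if b_i equals the allele
                      e_i / 3   otherwise,

and the score is the log10 likelihood ratio

    LOD = Σ_i log10[ f·P(b_i|alt) + (1−f)·P(b_i|ref) ] − Σ_i log10 P(b_i|ref),

evaluated at f = f̂, the duplicate-collapsed alternate-allele fraction.
A candidate is kept when LOD ≥ 3.9 (`lod_threshold`). The sums are
computed in log space; probabilities are clamped at 1e−300 before the
logarithm, and f̂ = 0 short-circuits to LOD = 0 exactly. Using the
collapsed fraction for f̂ keeps the score coherent with the reported VAF
(both describe molecules, not raw reads); observations themselves are not
collapsed, so duplicate reads still contribute independent base-quality
evidence.

Reads carrying three or more quality-passing mismatches are removed from
SNV evidence before scoring (`max_mismatches_per_read`, default 3): dense
mismatch runs on a single read are overwhelmingly alignment artifacts.
The indel path deliberately keeps these reads — a genuine complex allele
(e.g. a 15→3 bp replacement) mismatches heavily by construction.

## Paired cascade

For each tumor candidate with a matched normal, in order:

1. **Frequency gates.** The normal VAF must be below `nf` (default .02,
   as an allele fraction) OR below `normal_ratio` (default .2) times the
   tumor VAF; otherwise reject. The OR is deliberate — either bound
   suffices.
2. **Clean or single-stranded normal.** Zero normal support, or normal
   support confined to one strand (an artifact signature), emits
   directly.
3. **Normal LOD gate.** When the normal VAF is below
   `normal_lod_gate_ratio` (default .5) times the tumor VAF, the same LOD
   statistic is evaluated on the normal pileup: a weak normal signal
   (LOD < 3.9) emits the variant; a strong one falls through to the exact
   test.
4. **Fisher's exact test.** On the 2×2 table (normal variant/reference
   vs tumor variant/reference counts, duplicate-collapsed), emit iff
   p ≤ `fet_p_threshold` (default .05).

The point probability of a table is the hypergeometric term

    p = (n1+n0)! (c1+c0)! (c1+n1)! (c0+n0)!
        / [ n1! n0! c1! c0! (n1+n0+c1+c0)! ],

computed in log-gamma space (relative error ≤ 1e−10 against exact
factorial arithmetic for tables up to N = 200, verified in the test
suite). Because a lone point probability is not a valid p-value, the
default p sums the one-sided tail toward tumor enrichment (tables with
fewer normal variant reads at fixed margins); `fet_mode="point"` is
available for the literal point term. Zero normal coverage at a candidate
site rejects the candidate with an explicit `no_normal_coverage` label —
absence of evidence in the normal is not treated as evidence of absence.

Indel and complex alleles have no per-base error model, so the cascade
skips gate 3 for them and goes straight from the frequency gates to the
exact test, which is the statistic designed for count data of this kind.

## MNV and complex merging

**Adjacent SNVs.** Two SNV candidates at consecutive positions merge into
one block substitution (CA→AG) when they co-occur on the same reads: at
least `mnv_cooccurrence_fraction` (default .9) of the reads supporting
the lower-support member must also support the other. Exact set equality
would be brittle under sequencing error, hence the 90% rule. Runs merge
transitively; non-adjacent same-read SNVs never merge. Merging happens
after per-site classification, so a neighbor that failed the somatic test
in the normal (a germline het riding next to a somatic SNV) is never
absorbed — the somatic SNV is emitted alone as a single-base record.
A merged record's support, depth, and VAF are recomputed against the full
haplotype (a read must spell the complete alternate block to count); its
LOD is the minimum of the component LODs and its exact-test p the maximum
of the component p-values, a deliberately conservative aggregation.

**Same-read gaps and SNVs.** Per read, insertion/deletion events come
straight from the CIGAR; reads with more than two gap/ins events are
dropped from indel evidence. Two gap/ins events on one read merge when
fewer than 10 reference bases separate their inner edges (`d < 10`,
strict, matching the "less than" phrasing); an SNV on the same read is
absorbed when its distance to the nearest event edge is at most 5
(`d ≤ 5`, inclusive, matching the "within" phrasing). Distances are
measured edge-to-edge in reference coordinates with adjacency = 1 for the
SNV rule and 0 intervening bases for adjacent gaps; the sources that
motivated these rules do not define the measurement, so the least
ambiguous convention was chosen and frozen. The merged allele's reference
sequence is read off the reference over the merged span and its alternate
off the read's component events, yielding block records such as GG→A or
AATTAAGAGAAGCAA→TTC. Events on different reads are never merged.
Component SNVs of an emitted complex allele are suppressed from the SNV
output (a GG→A call would otherwise also emit its G→A component); the
suppression rule drops an SNV whose position falls inside an emitted
complex/indel span when at least half of its supporting reads carry that
complex allele.

## Quantification

Reads sharing an alignment signature — contig, start, end, strand, and
mate start when present — are presumed PCR copies of one molecule and
form a duplicate group. Depth is the number of groups informative at the
site; a group supports the variant only when strictly more than
`dup_support_fraction` (default .8) of its informative members carry the
allele (exactly 4 of 5 does not support). VAF = 100 × supporting groups /
informative groups. For indel/complex alleles only reads spanning the
entire reference span of the allele enter the denominator. The site's
base quality is the maximum base quality among variant-supporting
observations. The filter ledger (support ≥ 2, depth ≥ 8, VAF ≥ floor,
site quality ≥ 13, optional strand screen, off by default) is a set of
labels; only label-free candidates reach the output. An optional
end-of-read distance screen (`end_distance_filter`, default 0 = off)
drops base observations within N positions of either read end, for
libraries whose read ends are error-prone.

**The VAF floor default is 0.5%.** The floor exists to suppress
error-pile artifacts, and at base quality 30 with the LOD and support
screens in front of it, 0.5% already makes error-driven calls vanishingly
rare at clinical depths (an error pile must reach ~10 same-base reads at
2000×). A floor at 1% would sit *on top of* the lowest allele fractions
this class of assay is expected to report (panel variants at 1.1–1.5%
are routine), and binomial sampling at 2000× then drops roughly one in
five such variants below the cut — an unacceptable sensitivity loss for
a threshold whose job is artifact control, not sensitivity definition.
The floor is configurable (`--min-vaf`, in percent).

## Region chunking

The target intervals are split into `threads` chunks of near-equal total
bases (regions split mid-interval where a quota boundary falls). A
variant belongs to the chunk containing its (normalized) start; every
chunk fetches reads with 300 bp of padding and evaluates candidates over
the padded window, so merging decisions near a boundary are made
identically by both neighboring chunks and the merged output is invariant
to the chunk count. This is verified byte-for-byte in the tests.

## Variant representation

Internal coordinates are 0-based half-open; all emitted coordinates are
1-based. MNV and complex records are written as block substitutions with
no anchor base (REF=GG, ALT=A); pure insertions/deletions are
left-aligned against the reference and carry a single left anchor base
per VCF 4.2. Normalization (suffix trim, prefix trim, left shift,
re-anchor) is idempotent, and evaluation matches call and truth sets only
after normalizing both sides, so representation shifts cannot manufacture
false positives or negatives.

## Synthetic-data generator

The simulator emits pre-aligned reads with exact CIGARs; no aligner is
involved, so truth placement is known by construction. A haplotype is
built by applying the truth variants to a random (or supplied) contig;
each fragment is drawn from a variant haplotype with probability equal to
the target VAF, and its CIGAR is derived from the reference/haplotype
alignment chain (block substitutions become mismatch runs, length
differences become I/D ops; insertions clipped at read edges become soft
clips). Defaults: depth as specified per experiment, read length 100,
base quality 30 (uniform), sequencing error rate 1e−3 (uniform random
substitutions, consistent with q30), duplicate rate 0.1 (a duplicate
copies its fragment's placement and draws independent sequencing errors),
strand balance 0.5, and fragment-length jitter ±20% around the read
length. The jitter emulates the fragment-size diversity of real
libraries; without it, fixed-length single-end fragments admit so few
distinct alignment signatures that coordinate-based duplicate collapsing
would merge unrelated molecules wholesale at high depth — a simulator
artifact, not a property of real data. All randomness flows from a single
seed; per-contig sub-seeds are drawn deterministically from it.

What the generator does **not** model: platform-specific error spectra
and quality-score variation, soft-clipping of variant-spanning read ends,
mapping ambiguity, GC/coverage bias, and contamination. Passing tests
therefore demonstrate the correctness of the decision logic and
arithmetic under idealized noise, not robustness to alignment artifacts —
the screens that target those artifacts (mismatch-dense read removal,
strand checks, the normal cascade) are exercised with constructed
fixtures instead.

The packaged proficiency-panel table (`data/eqa2017_variants.tsv`, 94
variants) keeps genomic coordinates as contig *labels* only; each variant
is embedded at a fixed offset (240) of its own 500 bp synthetic contig,
so the caller is exercised end-to-end without any reference genome. The
panel-recovery experiment simulates each contig at 2000× (mean coverage
at the variant), read length 100, q30, and calls in tumor-only mode with
default thresholds; these sizes keep the whole experiment within minutes
on one core while leaving multiple-sigma margins above every decision
floor for the lowest-frequency panel members (1.17%).

## Evaluation metrics

Precision = TP/(TP+FP), sensitivity = TP/(TP+FN) after normalization and
exact (contig, pos, ref, alt) matching. Two F1 conventions circulate in
caller comparisons: the harmonic mean 2PS/(P+S) and the plain product
P·S. The evaluator computes and labels **both** and never silently picks
one; they agree only at P = S = 1.

## Known limitations

- No local realignment: variants at read ends that aligners soft-clip are
  invisible, and reported VAFs can be slightly deflated for such sites.
- Single-read phasing only: alleles spanning more than one read length
  cannot be assembled.
- No tumor purity/ploidy adjustment, no UMI-aware deduplication, no
  contamination estimation, no panel-of-normals.
- Multi-allelic sites are emitted as independent records per alternate
  allele; no joint genotyping.
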