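# Methods

## Signal model

A diploid Sanger trace is the superposition of two haplotype signals. At
chromatogram position `j`, haplotype 1 contributes its base with area
`allele_fraction * peak_mean` and haplotype 2 the complement; identical
bases merge into a single peak. Downstream of a heterozygous indel of
size `s` the haplotypes are out of register, so every position shows two
comparable peaks whose identities are offset copies of one another. This
offset-copy structure is the entire detection signal; no per-scan-point
waveform is modelled.

## The caller

**Homozygous scan.** The primary-base string is aligned globally to its
reference window (match +1, mismatch −1, gap open −2, gap extend −1;
reference end-overhangs free, since a read covers a sub-interval of its
amplicon). The alignment is delegated to Biopython's `PairwiseAligner`;
its score is verified in the test suite against an independently coded
affine-gap dynamic program. Mismatch columns without a qualifying
secondary peak become homozygous SNVs; gap runs become homozygous
indels. Alignment-gap regions are excluded from the phase-shift search so
no position is reported by both mechanisms.

**Two vectors.** `v1[j]` is the largest-area base at read position `j`;
`v2[j]` is the second-largest unless its area is *less than*
`rho = 0.10` of the primary area, in which case the primary base is
copied into both vectors. The comparison is strict (`area >= rho *
primary` keeps the secondary), and this is the only place `rho` enters.

**Phase-shift search.** For every position `p` and size
`1 <= |s| <= max_shift`, the score is the fraction of window positions
`j` (those in `[p, L-1-max(s,0)]` with `j+s >= 0`) where
`v2[j] == v1[j+s]`. Sign convention: `s > 0` means the minor allele's
downstream content arrives `s` positions early — a deletion on that
allele; `s < 0` is an insertion of `|s|` bases, read out of `v2` over the
divergent rows. (For insertions, anchoring positions `p < |s|` duplicate
the `p = |s|` window and are skipped.) The best hypothesis — ties broken
toward higher score, smaller `|s|`, smaller `p`, deletions before
insertions — is called when

* `score >= theta` (default 0.90),
* `window >= min_window` (default 10),
* `score` exceeds the unshifted match fraction from `p` by at least
  `delta` (default 0.20).

`max_shift` defaults to 30 with a hard cap of 99: the method targets
short (&lt;100 bp) indels only. All five thresholds are configuration-
exposed. At most one heterozygous indel is called per read; a read
carrying two is outside the model and the second one is missed.

Matching is by base identity, not weighted by peak area or quality: the
observed quantity the score explains is the base content of the two
vectors. Shifts are inserted into `v2` only; shifting `v1` by `-s` is
the mirror hypothesis and adds nothing.

**Coordinates and normalization.** Indel calls are anchored VCF-style on
the last unchanged reference base and left-normalized. In repetitive
sequence several placements describe the same edit; the simulator's truth
tables are normalized the same way, so placement ambiguity cannot produce
spurious disagreements.

**Heterozygous SNVs** are reported at isolated vector disagreements
(clean flanking positions, one of the two bases equal to the reference);
they are deliberately simple and carry no genotype likelihoods.

## Somatic classification and annotation

A variant's identity is its (reference, position, ref, alt, kind) tuple;
zygosity is not part of the match. Labels: **somatic** — present in both
independently amplified tumor replicates and absent from the matched
normal; **germline** — present in the normal; **unconfirmed** — in one
replicate only (this package's addition; a strictness flag can accept
single-replicate support); **known_snp** — removed by catalog lookup of
(reference, position, alt) before classification. A variant present in
the normal is never labelled somatic, regardless of flags.

Coding changes use `c.<ref><pos><alt>` with 1-based CDS positions; the
codon number is `ceil(pos/3)`; protein changes are
`p.<refAA><codon><altAA>` with `X` for stop. Indels are typed frameshift
when the net length change is not a multiple of three, inframe
otherwise. Splice-proximity flagging (±2 bp of a supplied exon boundary)
is available but no splicing model is attempted.

## Exact co-occurrence test

The two-tailed Fisher's exact test uses the probability-mass convention:
with margins fixed, sum the hypergeometric probability of every table no
more likely than the observed one. Probabilities are computed from
log-factorials (`lgamma`); a relative tie tolerance of 1e-7 guards the
"equally likely" boundary against floating-point jitter. A table with
any zero margin returns p = 1 by convention. This convention is what
reproduces the printed p-values on the packaged co-occurrence tables
(0.0011 for the 2/2/0/103 table, 0.0102 for 2/2/3/100); the test suite
cross-checks against an exact-fraction enumeration oracle and against
`scipy.stats.fisher_exact`, neither of which is used by the
implementation.

Discovery-screen power is `1 − (1 − X)^n` for a gene mutated in a
fraction `X` of tumors, `n = 24` screened by default.

## Simulator design

`SimulationConfig` defaults: `peak_mean = 1000` (arbitrary fluorescence
units), `allele_fraction = 0.5` (balanced diploid amplification),
`noise_sd = 30` (3% of a full peak, additive Gaussian truncated at zero),
`cross_talk = 0.05` (one spurious peak per position at 5% of a full
peak, modelling dye cross-talk and baseline wobble), `read_length = 240`
on 258-bp amplicons. The noise model is deliberately minimal — one
tunable width, no PCR artifacts, no base-quality simulation, no
per-scan waveform.

The cohort generator mirrors an amplicon-based tumor/normal screen: per
case, one normal sample (germline variants only) and two tumor
replicates (germline + somatic, same variants, fresh noise), with
exactly one planted variant per amplicon so the one-indel-per-read
limitation never confounds the benchmark. Defaults plant 3 somatic
(SNV, insertion, deletion) and 2 germline variants per case at interior
positions (at least 50 positions from the read start, 60 from the end),
indel sizes 1–10. On exactly tied peak areas the renderer takes
haplotype 1's base as primary; under noise, ties have measure zero.

**What passing tests do and do not show.** With `allele_fraction = 0.5`
the two allele peaks are exactly balanced, so under any noise the
primary/secondary ranking flips randomly from row to row and the
identity-matched score of a true indel collapses toward the background
match rate — balanced heterozygous indels are detectable only in nearly
noise-free traces. This is a property of the identity-matching score,
not of the simulator. Sensitivity under noise requires allele imbalance:
the monotone-degradation benchmark therefore runs at
`allele_fraction = 0.6`, where recovery falls gradually (1.00 at
`noise_sd` 0 to 0.00 by `noise_sd` 240 in the seeded sweep). Specificity
is unaffected: on 1,000 variant-free reads at 5% noise plus cross-talk,
the default thresholds produce no false heterozygous-indel call. Real
chromatograms additionally contain mobility shifts, dye blobs and
quality decay that the generator does not emulate; passing benchmarks
bound algorithmic behaviour, not wet-lab performance.

## Packaged fixtures

* `table2_mutations.tsv` — the cohort mutation table: 9 nonsynonymous
  somatic mutations across 6 distinct cases (two cases carry two
  mutations each; one case carries two *MRE11A* mutations). External
  impact predictions (Mutation Assessor / SIFT / PolyPhen-2) are carried
  as free-text columns and never computed.
* `cds_synthetic.fa` — synthetic mini coding sequences whose codons are
  exactly those implied by the printed c./p. pairs; real transcripts are
  not shipped. Filler codons are alanine (GCT), with ATG start and TAA
  stop.
* `gene_status_synthetic.tsv` — 107 cases × 4 genes with the published
  marginal counts (45/20/42 histotypes; 4/2/2/5 mutated cases;
  co-occurrence cells 2/2/0/103 and 2/2/3/100). Mutated cases and their
  histotypes are as published; the filler case ids and the specific
  identity of ATAD5-only overlaps are synthetic — any assignment with
  the same margins yields identical statistics.

## Benchmark problem sizes

Noiseless recovery: 60 reads (indel sizes 1–10 × {insertion, deletion} ×
3 interior positions) on a 300-bp reference. Specificity: 1,000
variant-free 240-bp reads. Search-equivalence: reads ≤ 30 bp against an
exhaustive oracle with `max_shift = 3`. End-to-end: 10 cases × 5
amplicons × 3 samples. These sizes keep the whole suite and the
acceptance script in the tens of seconds while exercising every code
path; all are set in the tests and scale linearly if enlarged.

## Known limitations

* One heterozygous indel per read; compound heterozygotes and
  multi-indel reads are out of scope.
* Balanced-allele indels are not detectable under realistic noise (see
  above); an allele-fraction sweep is advised when tuning for real
  traces.
* Strand is carried but unused ('+' only in the simulator); no
  bidirectional-confirmation requirement is enforced beyond replicate
  concordance.
* No ABI/SCF chromatogram parsing, no SAM/BAM/VCF emission, no
  base-quality model, no multiple-testing correction in the cohort
  statistics.
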