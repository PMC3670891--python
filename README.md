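# dipscan

Somatic mutation screening by Sanger sequencing runs into a blind spot:
heterozygous insertions and deletions. Downstream of a heterozygous indel
the two allele sequences fall out of register, so every chromatogram
position carries two comparable-area peaks and ordinary base calling
degrades into apparent noise. `dipscan` implements a trace-level caller
that turns this failure mode into the detection signal, together with the
tumor/normal verification and cohort statistics used in candidate-gene
mutation screens (the packaged fixtures describe a screen of
chromosome-instability / sister-chromatid-cohesion genes — *ESCO1*,
*CHTF18*, *MRE11A*, *ATAD5* — in endometrial carcinoma).

It is aimed at anyone analysing diploid Sanger traces for short
(&lt;100 bp) indels and at reproducing cohort-level screen statistics:
per-gene case frequencies, exact co-occurrence tests, and discovery-screen
power.

## Method

From each read's per-position peak table (primary and secondary base with
fluorescence areas), two base vectors are formed: `v1[j]` is the
largest-area base at position `j`, and `v2[j]` is the second-largest —
unless its area is less than 10% of the primary (`rho = 0.10`), in which
case the primary base is copied into both vectors. A heterozygous indel
of size `s` announces itself as a phase shift: from its position `p`
onward, `v2` equals `v1` displaced by `s`. The caller scores every
hypothesis `(p, s)` by the match fraction

```
score(p, s) = #{ j >= p : v2[j] == v1[j+s] } / window(p, s)
```

and calls the best hypothesis as a heterozygous deletion (`s > 0`) or
insertion (`s < 0`) when `score >= theta` (0.90), the window covers at
least `min_window` (10) positions, and the score improves on the
unshifted match fraction by at least `delta` (0.20). Homozygous variants
are read off a global alignment of the primary-base string beforehand;
isolated vector disagreements become heterozygous SNVs.

Around the caller sit:

* a **synthetic diploid-trace generator** that renders haplotype pairs
  into peak tables with known ground truth (the only way to benchmark the
  caller, since raw chromatograms for the original screen were never
  deposited),
* **somatic classification**: a variant is somatic only if reproduced in
  two independently amplified tumor replicates and absent from the
  matched normal; known polymorphisms are removed against a SNP catalog,
* **coding annotation** in `c.G1012T` / `p.E338X` notation with
  `ceil(pos/3)` codon arithmetic,
* **cohort statistics**: distinct-case gene frequencies by histotype, a
  hand-implemented two-tailed Fisher's exact test (probability-mass
  convention, summed from log-factorial hypergeometric probabilities),
  discovery-screen power `1 - (1 - X)^n`, and oncoprint export.

## Worked example

```python
from dipscan.cohort_stats import (CohortSpec, build_contingency,
    discovery_power, fisher_exact_two_tailed, gene_case_frequency)
from dipscan.fixtures import load_gene_status_fixture, load_table2_mutations

records = load_table2_mutations()
cohort = CohortSpec()                      # 45 serous / 20 clear cell / 42 endometrioid
k, n, f = gene_case_frequency(records, cohort, "ESCO1", "all")
print(f"ESCO1: {k}/{n} = {100*f:.1f}%")

t = build_contingency(load_gene_status_fixture(), "ESCO1", "CHTF18")
print("table:", (t.a, t.b, t.c, t.d))
print(f"P = {fisher_exact_two_tailed(t):.4f}")
print(f"power at 5%: {100*discovery_power(0.05, 24):.0f}%")
```

prints

```
ESCO1: 4/107 = 3.7%
table: (2, 2, 0, 103)
P = 0.0011
power at 5%: 71%
```

i.e. *ESCO1* is mutated in 4 of 107 distinct cases (3.7%), its
co-occurrence with *CHTF18* mutations is significant under the two-tailed
exact test (P = 0.0011 on the 2/2/0/103 table), and a 24-tumor discovery
screen has 71% power to catch a gene mutated in 5% of tumors.

The pipeline end-to-end, on a simulated cohort:

```
dipscan run --config cfg.yaml --out outdir/
```

writes `references.fa`, `traces.tsv`, `truth.tsv`, `calls.tsv`,
`variant_status.tsv`, `mutations.tsv`, `stats.tsv` and
`truth_comparison.tsv`; on a noiseless cohort every planted somatic and
germline variant is recovered with the correct label. The subcommands
`simulate`, `detect`, `somatic` and `stats` run the stages individually.

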