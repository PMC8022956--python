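# crestmap

Fine-mapping toolkit for the chicken *Crest* locus — the mutation on
chromosome 33 that replaces the small head feathers of wild-type chickens
with large, dorsal-type crest feathers. The causal change is a **197 bp
tandem duplication** in the intron of *HOXC10* (GalGal6
Chr33:7,587,588–7,587,784), discoverable as the single variant inside a
1.9 kb identity-by-descent (IBD) interval that is carried by every crested
bird and by no wild-type bird.

The package is aimed at people studying monogenic traits in livestock who
want a self-contained, fully synthetic re-creation of that discovery logic:
it simulates a candidate-region WGS cohort, scans it for the shared
haplotype, detects the duplication from read-level evidence, classifies the
allele series, and reproduces the PCR/KASP diagnostic assay.

## The model

Five haplotypes segregate at the locus:

| allele           | copies of the 197 bp unit | base at g.7,587,629 | TG repeat at g.7,587,694 |
|------------------|---------------------------|---------------------|--------------------------|
| *cr^WT^*         | 1                         | C                   | (TG)₇                    |
| *Cr1*            | 2                         | C / C               | (TG)₇ / (TG)₇            |
| *Cr2*            | 2                         | C / **A** (3′ copy) | (TG)₇ / (TG)₇            |
| *Cr3*            | 2                         | C / C               | **(TG)₈** (5′ copy) / (TG)₇ |
| back-mutant      | 1                         | **A**               | (TG)₇                    |

The analysis pipeline mirrors the study logic:

1. **IBD scan** — under the assumption that all crested birds inherit the
   mutation from one ancestor, find maximal runs of consecutive polymorphic
   sites at which every case is homozygous for the same allele (case pools
   ≥ 95 % fixed). The top run is the IBD interval.
2. **Concordance filter** — keep the in-interval variants whose non-reference
   allele is carried by *all* cases and *zero* controls.
3. **SV detection** — call the duplication from split reads (exact
   breakpoints, left-aligned through microhomology), everted read pairs, and
   the unit/flank depth ratio (~1.5 het, ~2.0 hom).
4. **Diagnostics** — in-silico PCR with primers Cr_197_F1/R1 (241 bp product
   on single-copy haplotypes, 438 bp on duplicated ones), per-haplotype
   sequence classification of 438 bp samples, and a KASP-style base call at
   g.7,587,629 for 241-only samples.

No real sequence data are downloaded: a seeded pseudo-random reference
preserves the true coordinates and planted locus features, so every
coordinate-level claim is checkable offline.

## Worked example

```python
import crestmap as cm
from crestmap import locus
from crestmap.synthetic_cohort import default_design, generate_cohort
from crestmap.ibd_scan import shared_interval_scan, concordance_filter

ref = cm.build_reference(seed=1)
cohort = generate_cohort(ref, default_design(), seed=1)   # 219 samples
top = shared_interval_scan(cohort.matrix, locus.CANDIDATE_REGION)[0]
print(top.interval, top.length)
candidates = concordance_filter(cohort.matrix, top.interval)
print([(c.variant.vtype, c.variant.pos) for c in candidates])
```

prints

```
chr33:7585881-7587784 1904
[('DUP', 7587588)]
```

i.e. the scan recovers the 1.9 kb shared interval and the filter reduces the
five in-interval case-haplotype changes (four SNVs plus the duplication) to
the duplication alone. The same run from the shell:

```bash
crestmap run --seed 1 --out-dir run1            # writes run1/manifest.json
crestmap simulate --seed 1 --design tiny --out-dir sim1
crestmap scan --vcf sim1/truth.vcf --samples sim1/sample_sheet.tsv
```

The run manifest also records the detector output on a simulated 20×
homozygote — one call, `unit_length: 197`, genotype `hom`, breakpoints
`chr33:7587588-7587784` — and a breed × genotype diagnostic table with zero
discordance against the generator's truth.

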