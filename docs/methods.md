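# Methods

## Scope and model

`crestmap` re-creates, on fully synthetic data, the discovery and diagnostic
logic for the chicken *Crest* mutation: a 197 bp tandem duplication at
Chr33:7,587,588–7,587,784 (GalGal6) inside a 1.9 kb identity-by-descent
(IBD) interval (Chr33:7,585,881–7,587,784) shared by crested birds. The
package treats the locus geometry — the duplication unit, the C>A site at
g.7,587,629 (unit offset 42), the TG microsatellite at g.7,587,694 (unit
offset 107), the four interval SNVs, and the diagnostic primer pair — as
fixed constants (`crestmap.locus`); everything else is simulated.

## The reference model

`build_reference(seed)` draws a uniform random A/C/G/T sequence over
chr33:7,500,000–7,820,000 and plants:

* the unit-internal features (C at offset 42; a maximal (TG)₇ run at offset
  107, guarded on both sides so it cannot extend);
* the forward primer ending 3 bp before the unit and the reverse-complement
  of the reverse primer starting 3 bp after it, which makes the wild-type
  amplicon exactly 241 bp. The duplication amplicon is therefore an
  *emergent* 241 + 197 = 438 bp, not a hard-coded constant;
* a guard that the base before the unit differs from the unit's last base,
  so the planted junction is already the left-aligned (canonical)
  representation.

A scrubbing pass then removes chance occurrences of either primer (both
strands, genome-wide) and of (TG)≥₆ runs within 5 kb of the unit, avoiding
the planted footprints. Construction is deterministic per seed; the unit's
30 bp flanks are asserted unique so they can anchor classification.

Real GalGal6 sequence is deliberately not used: only the coordinates and
planted features carry information, which keeps every coordinate-level claim
testable without downloads. Consequences for interpretation: background
sequence composition, repeats and mappability artefacts of the real genome
are absent, so passing tests demonstrate correctness of the algorithms under
the modeled signal, not robustness to real-genome noise.

## Haplotypes and the coordinate map

`build_allele` composes each of the five alleles from reference pieces and
records, for every haplotype base, its reference origin as a list of
colinear segments (insertions carry no origin). The 2 bp TG expansion is
inserted at the 3′ end of the run of the 5′ copy; the C>A edit is a
substitution and does not perturb the map. Background SNVs are applied
through the map (a substitution inside the unit would propagate to both
copies of a duplicated allele).

## Cohort generation

`generate_cohort` expands a `CohortDesign` (per-breed rows: phenotype,
count, diploid genotype, individual or pool) into haplotypes and a truth
genotype matrix. Three stock designs exist: `wgs_panel` (22 crest samples —
18 individuals + 4 pools of 10 birds — across eight crested breeds, plus 197
non-crested individuals), `table1` (the published diagnostic-cohort
composition: 68 crested and 433 non-crested individuals), and `tiny` for
quick runs.

Construction guarantees the study-logic geometry:

* the four IBD SNVs ride on every duplication haplotype, and on
  `max(1, round(0.05 × n))` of the control wild-type haplotypes — so they are
  shared by all cases yet rejected by the control filter. The floor of one
  carrier keeps the modeled logic intact in small cohorts, where a binomial
  draw could otherwise leave the SNVs control-free;
* a boundary marker at 7,585,881 where controls segregate (~30 % allele
  frequency) while every case haplotype is reference — this is what pins the
  printed interval start, since no variant is reported there;
* planted case-discordant sites immediately outside the interval (7,585,731
  and 7,587,942) bound the scan;
* no random background variation inside 7,585,600–7,588,100, so within the
  interval the case haplotype differs from the reference at exactly the four
  SNVs plus the duplication, and the primer/flank anchors stay intact.

Background sites elsewhere are placed at 3 × 10⁻³ per bp (one segregating
site per ~330 bp, a WGS-like between-breed density) with per-site alternate
allele frequencies uniform on [0.1, 0.5], shared by case and control
haplotypes alike. The density matters: it keeps any chance run of
case-concordant background sites far shorter than the 1.9 kb interval, so
the scan's top hit is the modeled interval essentially always. Pool samples
contribute alternate-allele frequencies over their 2 × 10 member haplotypes
instead of genotypes.

A design requesting a crested bird with no duplication allele (e.g. a
homozygous back-mutant crest) is rejected as contradicting the model.

## Read simulation

`simulate_alignments` draws a Poisson number of fragments per haplotype
(total coverage split evenly; default 20×, read length 100, fragment length
N(350, 50²) truncated at 200, substitution errors optional, default off) and
places each read analytically through the coordinate map — no aligner runs.
A read whose origins jump backwards in reference space (the tandem junction)
is emitted as a primary plus supplementary split alignment with exact clip
lengths; split parts shorter than 12 aligned bases are soft-clipped only.
Fragments straddling the junction yield everted pair orientations naturally.
Output is importable directly or as coordinate-sorted SAM via pysam.

## SV calling

`collect_evidence` accumulates per-base depth, exact split junctions
(suffix-part start ≤ prefix-part end), and everted pairs.
`call_tandem_dup` left-aligns junctions through microhomology when a
reference accessor is available (shifting while `base(start−1) ==
base(end)`, the VCF convention), merges identical junctions, requires
`split + everted ≥ 3` (a conventional small-cohort minimum), and genotypes
from the unit/flank depth ratio with boundaries 1.25/1.75 over 2 kb flanks.
At 20× over a 197 bp unit the ratio has a relative standard error of roughly
10 %, so genotype boundaries are wide and the property tests average over
seeds; breakpoints, by contrast, are exact whenever ≥ 3 junction reads
exist, which at 20× fails in well under 5 % of runs.

## IBD scan and concordance filter

A site is case-concordant (default `homozygous_ibd` mode) when one allele
exists for which every case individual is homozygous and every case pool is
≥ 95 % fixed; `dominant_carrier` relaxes this to carrying one copy. Missing
genotypes break concordance under the default `strict` policy ("permissive"
treats them as compatible — real pipelines rarely have complete calls; the
choice is exposed because the right answer is data-dependent). Maximal runs
of consecutive concordant polymorphic sites become intervals
[first site, last site] — using END for symbolic duplications — sorted by
length. The filter then keeps in-interval variants whose alternate allele is
carried by 100 % of cases (pools ≥ 95 %) and 0 % of controls (control pools
exactly 0). The scan is verified against an exhaustive oracle on small
matrices, and the filter is monotone: adding a control can only shrink the
candidate list.

## Allele classification and diagnostics

Classification anchors on the unique 30 bp unit flanks, splits the
inter-flank stack into copies by minimizing summed edlib edit distance to
the unit over candidate cut points (tolerance 3 edits per copy — the real
allele edits are 1–2 bp), reads the offset-42 base and the maximal TG run
per copy, and applies the decision table (5′/3′ identity is positional).
More than two copies, or a diverged copy, yields `unknown`.

The diagnostic assay models PCR as exact primer matching on both strands
(the primers are given and templates synthetic, so no mismatch tolerance),
gel reading with ±3 bp tolerance, and KASP as a direct base read of the
3′-most copy at offset 42 — mirroring where the *Cr2* substitution sits.
Samples with a duplication-sized fragment are routed to per-haplotype
sequence classification; 241-only samples to the KASP call, whose C/A
outcome is what identifies back-mutant carriers. Fragment pattern and
classification must agree or the sample fails with a rule trace.

## Expression module

`relative_expression` implements the comparative-Ct method with
amplification efficiency fixed at 2: replicates averaged, ΔCt against a
reference gene, scaled to a named calibrator sample (fold 1 by
construction). miRNA normalization against a small-RNA reference is the
same computation.

## Problem sizes and determinism

Default problem sizes are desk-scale by design: a 320 kb region, 219- or
501-sample cohorts, 20× read simulation (~32,000 fragments per genome).
Every stochastic step takes an explicit seed; pipeline runs derive child
seeds from one master seed via `numpy.random.SeedSequence`, and a (config,
seed) pair reproduces a run's manifest exactly.

## Known limitations

* Sequencing errors are uniform substitutions; no indel errors or quality
  scores, so diagnostic discordance is exactly zero on default (error-free)
  data — the zero-discordance checks validate logic, not noise robustness.
* Only tandem-duplication signatures are modeled; the detector is not a
  general SV caller.
* Pool handling (frequency thresholds 0.95/0.0) is a modeling choice; the
  original study's pool treatment is not described at this level.
* Whether all crested WGS samples were homozygous is not stated in the
  study; the generator defaults to homozygous (crested breeds are fixed for
  their alleles) and exposes heterozygous designs through `CohortDesign`.
* The printed IBD start has no reported variant; modeling it as a
  case-concordant reference-allele marker reproduces both the printed
  interval and the count of five in-interval changes, but is an inference,
  not a documented fact.
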