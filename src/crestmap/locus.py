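"""Fixed facts about the chicken *Crest* locus (GalGal6, chromosome 33).

The mutant alleles at this locus carry a 197 bp tandem duplication in the
*HOXC10* intron; the duplication unit also contains the C>A substitution that
distinguishes *Cr2* and the TG microsatellite whose expansion distinguishes
*Cr3*.  Everything downstream (generator, scan, detector, classifier, assay)
derives its coordinates from these constants.
"""

from .io_formats import GenomicInterval

CHROM = "chr33"

#: modeled reference window around the locus
REGION = GenomicInterval(CHROM, 7_500_000, 7_820_000)

#: linkage-defined candidate interval: 7.57 Mb to the distal end at 7.82 Mb
CANDIDATE_REGION = GenomicInterval(CHROM, 7_570_000, 7_820_000)

#: the 197 bp tandem duplication unit
DUP_START = 7_587_588
DUP_END = 7_587_784
UNIT_LENGTH = DUP_END - DUP_START + 1  # 197

#: C>A substitution carried by the 3' copy in Cr2 (single-copy numbering)
SNP_POS = 7_587_629
SNP_UNIT_OFFSET = SNP_POS - DUP_START + 1  # 42, 1-based within the unit

#: TG microsatellite; (TG)7 in the reference, (TG)8 in the Cr3 5' copy
TG_POS = 7_587_694
TG_UNIT_OFFSET = TG_POS - DUP_START + 1  # 107, 1-based within the unit
TG_WT_REPEATS = 7

#: shared (identity-by-descent) interval across crested samples
IBD_START = 7_585_881
IBD_END = DUP_END
IBD_INTERVAL = GenomicInterval(CHROM, IBD_START, IBD_END)

#: the four single-nucleotide variants inside the IBD interval
IBD_SNV_POSITIONS = (7_586_870, 7_586_999, 7_587_089, 7_587_313)

#: diagnostic PCR primers (Cr_197_F1 / Cr_197_R1) and the wild-type fragment
PRIMER_F = "ACCAAACCGCTTCGATGTGT"
PRIMER_R = "CGTCCCATTGGCATCACC"
WT_FRAGMENT = 241

ALLELE_NAMES = ("crWT", "Cr1", "Cr2", "Cr3", "Cr2_backmutant")
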