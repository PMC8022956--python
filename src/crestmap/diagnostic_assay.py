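"""The *Crest* diagnostic test, in silico.

The wet-lab assay combines three steps: PCR with primers flanking the
duplication unit (a duplication-free haplotype yields a 241 bp fragment, a
duplication haplotype a 438 bp one), Sanger sequencing of every 438 bp
product to resolve which duplication allele it is, and a KASP assay on
241-only samples for the C>A base at g.7,587,629 -- which is what reveals
the single-copy back-mutant haplotype in non-crested birds.

Here PCR is exact-match primer search on the template, Sanger
interpretation is the allele classifier, and KASP is a direct biallelic
base read at the SNP (competitive fluorescence chemistry is wet-lab detail
with no computational content).  ``diagnose_individual`` mirrors the routing
logic and records the rules it fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from . import locus
from .allele_classify import classify_allele, count_unit_copies, FLANK_LENGTH
from .io_formats import SampleSheetRow
from .synthetic_cohort import Cohort, Haplotype, ReferenceModel

#: canonical column order of the published summary table
GENOTYPE_COLUMNS = ("Cr1/Cr1", "Cr2/Cr2", "Cr2/Cr3", "Cr3/Cr3", "crWT/crWT")


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    name: str = ""

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if not seq or set(seq) - set("ACGT"):
                raise ValueError("primers must be non-empty ACGT sequences")


CR197_PRIMERS = PrimerPair(locus.PRIMER_F, locus.PRIMER_R, name="Cr_197")


@dataclass
class DiagnosticResult:
    sample_id: str
    fragment_lengths: tuple[int, ...]
    kasp_call: str  # C/C | C/A | A/A | NA
    final_genotype: str
    rule_trace: list[str] = field(default_factory=list)


def insilico_pcr(template: str, primers: PrimerPair = CR197_PRIMERS,
                 max_product: int = 5000,
                 return_sequences: bool = False):
    """Exact-match in-silico PCR product lengths (and optionally sequences).

    Each pairing of a forward-primer site with a downstream
    reverse-complemented reverse-primer site within ``max_product`` yields a
    product; the length counts both primer footprints.
    """
    rc_reverse = str(Seq(primers.reverse).reverse_complement())

    def sites(needle: str) -> list[int]:
        out, start = [], 0
        while (i := template.find(needle, start)) != -1:
            out.append(i)
            start = i + 1
        return out

    products = []
    for f in sites(primers.forward):
        for r in sites(rc_reverse):
            end = r + len(rc_reverse)
            length = end - f
            if f < end and length <= max_product:
                products.append((length, template[f:end]))
    products.sort()
    if return_sequences:
        return products
    return [length for length, _ in products]


def fragment_interpret(lengths: Iterable[int],
                       tolerance: int = 3,
                       wt_length: int = locus.WT_FRAGMENT,
                       dup_length: int = locus.WT_FRAGMENT + locus.UNIT_LENGTH
                       ) -> str:
    """Gel-pattern interpretation: {hom_dup, het, hom_wt, fail}.

    Lengths within ``tolerance`` bp of the expected fragments are accepted
    (gel resolution); any unexplained fragment, or no fragment, fails.
    """
    has_wt = has_dup = False
    for length in lengths:
        if abs(length - wt_length) <= tolerance:
            has_wt = True
        elif abs(length - dup_length) <= tolerance:
            has_dup = True
        else:
            return "fail"
    if has_wt and has_dup:
        return "het"
    if has_dup:
        return "hom_dup"
    if has_wt:
        return "hom_wt"
    return "fail"


def _kasp_base(ref: ReferenceModel, haplotype: str) -> str | None:
    """The diagnostic base read by KASP: the 3'-most unit copy's offset-42 base."""
    try:
        _, intervals = count_unit_copies(
            haplotype, ref.unit_sequence,
            (ref.left_flank(FLANK_LENGTH), ref.right_flank(FLANK_LENGTH)),
        )
    except ValueError:
        return None
    a, b = intervals[-1]
    idx = a - 1 + locus.SNP_UNIT_OFFSET - 1
    if idx >= b:
        return None
    base = haplotype[idx]
    return base if base in "CA" else None


def kasp_genotype(ref: ReferenceModel, hap_a: str, hap_b: str) -> str:
    """Diploid base call at g.7,587,629 ('NA' when a base cannot be resolved)."""
    bases = [_kasp_base(ref, h) for h in (hap_a, hap_b)]
    if any(b is None for b in bases):
        return "NA"
    bases.sort(key=lambda b: 0 if b == "C" else 1)  # reference base first
    return f"{bases[0]}/{bases[1]}"


_KASP_TO_GENOTYPE = {
    "C/C": "crWT/crWT",
    "C/A": "Cr2_backmutant/crWT",
    "A/A": "Cr2_backmutant/Cr2_backmutant",
}

_DUP_ALLELES = {"Cr1", "Cr2", "Cr3"}


def diagnose_individual(ref: ReferenceModel,
                        hap_a: Haplotype | str, hap_b: Haplotype | str,
                        sample_id: str = "",
                        tolerance: int = 3) -> DiagnosticResult:
    """Run the full diagnostic decision flow on one individual.

    Samples showing a duplication-sized fragment are routed to per-haplotype
    sequence classification; 241-only samples are routed to the KASP call.
    Contradictions between the fragment pattern and the classification fail
    with a trace.
    """
    seqs = [h.sequence if isinstance(h, Haplotype) else h
            for h in (hap_a, hap_b)]
    fragments = tuple(
        sorted(length for s in seqs for length in insilico_pcr(s))
    )
    trace = [f"pcr: fragments {list(fragments)}"]
    dup_state = fragment_interpret(fragments, tolerance=tolerance)
    trace.append(f"fragment_interpret: {dup_state}")
    kasp_call = "NA"
    if dup_state == "fail":
        final = "fail"
    elif dup_state in ("hom_dup", "het"):
        calls = [classify_allele(s, ref) for s in seqs]
        trace.append(
            "sanger_classify: " + "/".join(c.allele for c in calls)
        )
        if any(c.allele == "unknown" for c in calls):
            final = "fail"
        else:
            n_dup = sum(c.allele in _DUP_ALLELES for c in calls)
            expected = 2 if dup_state == "hom_dup" else 1
            if n_dup != expected:
                trace.append(
                    f"inconsistent: {n_dup} duplication alleles vs "
                    f"fragment pattern {dup_state}"
                )
                final = "fail"
            else:
                final = "/".join(sorted(c.allele for c in calls))
    else:  # hom_wt: 241-only, KASP route
        kasp_call = kasp_genotype(ref, *seqs)
        trace.append(f"kasp: {kasp_call}")
        final = _KASP_TO_GENOTYPE.get(kasp_call, "fail")
    return DiagnosticResult(sample_id=sample_id, fragment_lengths=fragments,
                            kasp_call=kasp_call, final_genotype=final,
                            rule_trace=trace)


def diagnose_cohort(cohort: Cohort) -> list[DiagnosticResult]:
    """Diagnose every individual sample of a generated cohort (pools have no
    single diploid genotype and are skipped)."""
    results = []
    for sid in cohort.haplotype_specs:
        hap_a, hap_b = cohort.haplotypes(sid)
        results.append(
            diagnose_individual(cohort.reference, hap_a, hap_b, sample_id=sid)
        )
    return results


def cohort_summary(results: Sequence[DiagnosticResult],
                   sheet: Sequence[SampleSheetRow]) -> pd.DataFrame:
    """Breed x genotype count table in the style of the published summary."""
    by_id: Mapping[str, SampleSheetRow] = {s.sample_id: s for s in sheet}
    if not results:
        return pd.DataFrame(columns=["phenotype"])
    rows: dict[str, dict[str, int]] = {}
    phenotype: dict[str, str] = {}
    breed_order: list[str] = []
    for res in results:
        sample = by_id[res.sample_id]
        if sample.breed not in rows:
            rows[sample.breed] = {}
            phenotype[sample.breed] = sample.phenotype
            breed_order.append(sample.breed)
        counts = rows[sample.breed]
        counts[res.final_genotype] = counts.get(res.final_genotype, 0) + 1
    genotypes = list(GENOTYPE_COLUMNS) + sorted(
        {g for counts in rows.values() for g in counts}
        - set(GENOTYPE_COLUMNS)
    )
    table = pd.DataFrame(
        [
            [phenotype[b]] + [rows[b].get(g, 0) for g in genotypes]
            for b in breed_order
        ],
        index=pd.Index(breed_order, name="breed"),
        columns=["phenotype"] + genotypes,
    )
    return table
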