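"""Synthetic stand-in for the WGS study panel at the *Crest* locus.

The generator builds a seeded pseudo-random reference window that preserves
only the real GalGal6 coordinates and the planted locus features (the 197 bp
duplication unit with its internal C base and (TG)7 run, and the diagnostic
primer sites spaced so the wild-type amplicon is 241 bp).  On top of it the
five locus haplotypes are constructed, diploid case/control cohorts are
sampled (with both individual and pooled samples), and paired-end alignments
are simulated analytically from the haplotype->reference coordinate map, so
junction-spanning reads come out as split alignments and junction-straddling
fragments as everted pairs without running an aligner.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import locus
from .io_formats import (
    GenomicInterval,
    GenotypeMatrix,
    SampleSheetRow,
    VariantRecord,
    write_fasta,
    write_sample_sheet,
    write_vcf,
)
from .sv_detect import AlignedReadPair, ReadAlignment

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: background variants are kept out of this window so the IBD interval, the
#: primer footprints and the classification flanks stay exactly as planted
_BACKGROUND_EXCLUSION = GenomicInterval(locus.CHROM, 7_585_600, 7_588_100)

#: planted case-discordant sites immediately flanking the IBD interval
DISCORDANT_LEFT = 7_585_731
DISCORDANT_RIGHT = 7_587_942

#: planted boundary marker: controls segregate, every case haplotype is REF
BOUNDARY_MARKER = locus.IBD_START


# ---------------------------------------------------------------------------
# allele specifications


@dataclass(frozen=True)
class AlleleSpec:
    """Structure of one *Crest*-locus haplotype.

    ``copy_snp_bases`` / ``copy_tg_repeats`` are per unit copy, 5' to 3'
    (one entry for single-copy alleles, two for duplicated ones).
    """

    name: str
    has_duplication: bool
    copy_snp_bases: tuple[str, ...]
    copy_tg_repeats: tuple[int, ...]

    def __post_init__(self) -> None:
        n = 2 if self.has_duplication else 1
        if len(self.copy_snp_bases) != n or len(self.copy_tg_repeats) != n:
            raise ValueError(f"{self.name}: expected {n} per-copy entries")


ALLELE_SPECS: dict[str, AlleleSpec] = {
    "crWT": AlleleSpec("crWT", False, ("C",), (7,)),
    "Cr1": AlleleSpec("Cr1", True, ("C", "C"), (7, 7)),
    "Cr2": AlleleSpec("Cr2", True, ("C", "A"), (7, 7)),
    "Cr3": AlleleSpec("Cr3", True, ("C", "C"), (8, 7)),
    "Cr2_backmutant": AlleleSpec("Cr2_backmutant", False, ("A",), (7,)),
}


# ---------------------------------------------------------------------------
# reference model


@dataclass
class ReferenceModel:
    """Seeded pseudo-sequence of the candidate window with planted features."""

    interval: GenomicInterval
    sequence: str
    primer_forward_site: GenomicInterval
    primer_reverse_site: GenomicInterval  # footprint of revcomp(reverse) on +
    seed: int

    def offset(self, pos: int) -> int:
        """1-based genomic position -> 0-based index into ``sequence``."""
        if not self.interval.contains(pos):
            raise ValueError(f"{pos} outside {self.interval}")
        return pos - self.interval.start

    def base(self, pos: int) -> str:
        return self.sequence[self.offset(pos)]

    def subseq(self, start: int, end: int) -> str:
        return self.sequence[self.offset(start) : self.offset(end) + 1]

    @property
    def unit_sequence(self) -> str:
        return self.subseq(locus.DUP_START, locus.DUP_END)

    def left_flank(self, n: int = 30) -> str:
        return self.subseq(locus.DUP_START - n, locus.DUP_START - 1)

    def right_flank(self, n: int = 30) -> str:
        return self.subseq(locus.DUP_END + 1, locus.DUP_END + n)


def _scrub(seq: bytearray, region_start: int, protected: set[int],
           rng: np.random.Generator) -> None:
    """Remove unintended primer-site and long-TG occurrences.

    Spurious exact primer matches are destroyed genome-wide; (TG)>=6 runs are
    destroyed within 5 kb of the duplication unit (elsewhere they are
    harmless to every operation in the pipeline).
    """
    primers = [locus.PRIMER_F, str(Seq(locus.PRIMER_F).reverse_complement()),
               locus.PRIMER_R, str(Seq(locus.PRIMER_R).reverse_complement())]
    tg_lo = locus.DUP_START - 5000 - region_start
    tg_hi = locus.DUP_END + 5000 - region_start
    for _ in range(50):
        text = seq.decode()
        hits: list[tuple[int, int]] = []
        for p in primers:
            start = 0
            while (i := text.find(p, start)) != -1:
                hits.append((i, i + len(p)))
                start = i + 1
        for m in re.finditer("(?:TG){6,}", text[max(0, tg_lo) : tg_hi]):
            hits.append((m.start() + max(0, tg_lo), m.end() + max(0, tg_lo)))
        hits = [
            (a, b) for a, b in hits
            if any((a + k) not in protected for k in range(b - a))
        ]
        # drop hits that are entirely the planted features themselves
        hits = [
            (a, b) for a, b in hits
            if not all((a + k) in protected for k in range(b - a))
        ]
        if not hits:
            return
        for a, b in hits:
            editable = [a + k for k in range(b - a) if (a + k) not in protected]
            i = editable[len(editable) // 2]
            current = seq[i]
            choices = [c for c in b"ACGT" if c != current]
            seq[i] = choices[int(rng.integers(len(choices)))]
    raise RuntimeError("could not scrub reference of spurious motifs")


def build_reference(seed: int, interval: GenomicInterval = locus.REGION) -> ReferenceModel:
    """Deterministic reference window with the locus features planted."""
    rng = np.random.default_rng(seed)
    n = interval.length()
    seq = bytearray(_BASES[rng.integers(0, 4, size=n)].tobytes())
    start = interval.start

    def put(pos: int, s: str) -> None:
        i = pos - start
        seq[i : i + len(s)] = s.encode()

    put(locus.SNP_POS, "C")
    put(locus.TG_POS, "TG" * locus.TG_WT_REPEATS)
    # guards so the planted run is maximal at exactly (TG)7
    put(locus.TG_POS - 1, "A")
    put(locus.TG_POS + 2 * locus.TG_WT_REPEATS, "A")

    f_start = locus.DUP_START - 3 - len(locus.PRIMER_F)
    put(f_start, locus.PRIMER_F)
    rc_r = str(Seq(locus.PRIMER_R).reverse_complement())
    r_start = locus.DUP_END + 4
    put(r_start, rc_r)
    forward_site = GenomicInterval(interval.chrom, f_start,
                                   f_start + len(locus.PRIMER_F) - 1)
    reverse_site = GenomicInterval(interval.chrom, r_start,
                                   r_start + len(rc_r) - 1)
    # wild-type amplicon spans both primer footprints and the unit
    assert reverse_site.end - forward_site.start + 1 == locus.WT_FRAGMENT

    # keep the planted junction left-aligned: no microhomology across it
    if seq[locus.DUP_START - 1 - start] == seq[locus.DUP_END - start]:
        current = seq[locus.DUP_END - start]
        seq[locus.DUP_START - 1 - start] = next(
            c for c in b"ACGT" if c != current
        )

    protected: set[int] = {locus.SNP_POS - start, locus.DUP_START - 1 - start}
    for pos in range(locus.TG_POS - 1, locus.TG_POS + 2 * locus.TG_WT_REPEATS + 1):
        protected.add(pos - start)
    for iv in (forward_site, reverse_site):
        protected.update(range(iv.start - start, iv.end - start + 1))
    _scrub(seq, start, protected, rng)

    ref = ReferenceModel(interval=interval, sequence=seq.decode(),
                         primer_forward_site=forward_site,
                         primer_reverse_site=reverse_site, seed=seed)
    for flank in (ref.left_flank(), ref.right_flank()):
        if ref.sequence.count(flank) != 1:
            raise RuntimeError("unit flank is not unique in the reference")
    return ref


# ---------------------------------------------------------------------------
# haplotypes


@dataclass(frozen=True)
class Segment:
    """One colinear piece of the haplotype->reference coordinate map.

    ``ref_start is None`` marks bases with no reference origin (insertions).
    """

    hap_start: int  # 1-based
    length: int
    ref_start: int | None


@dataclass
class Haplotype:
    allele: str
    sequence: str
    segments: tuple[Segment, ...]
    snvs: dict[int, str] = field(default_factory=dict)  # ref pos -> alt base

    @property
    def length(self) -> int:
        return len(self.sequence)

    def hap_positions(self, ref_pos: int) -> list[int]:
        """All haplotype positions whose reference origin is ``ref_pos``."""
        out = []
        for seg in self.segments:
            if seg.ref_start is not None and (
                seg.ref_start <= ref_pos < seg.ref_start + seg.length
            ):
                out.append(seg.hap_start + (ref_pos - seg.ref_start))
        return out

    def hap_range(self, region: GenomicInterval) -> tuple[int, int]:
        """Smallest haplotype window covering all bases originating in ``region``."""
        lo, hi = None, None
        for seg in self.segments:
            if seg.ref_start is None:
                continue
            a = max(seg.ref_start, region.start)
            b = min(seg.ref_start + seg.length - 1, region.end)
            if a > b:
                continue
            h0 = seg.hap_start + (a - seg.ref_start)
            h1 = seg.hap_start + (b - seg.ref_start)
            lo = h0 if lo is None else min(lo, h0)
            hi = h1 if hi is None else max(hi, h1)
        if lo is None:
            raise ValueError(f"haplotype has no bases in {region}")
        return lo, hi


def _edited_unit(unit: str, snp_base: str, tg_repeats: int) -> str:
    s = unit
    if snp_base != "C":
        i = locus.SNP_UNIT_OFFSET - 1
        s = s[:i] + snp_base + s[i + 1 :]
    if tg_repeats != locus.TG_WT_REPEATS:
        extra = tg_repeats - locus.TG_WT_REPEATS
        if extra < 0:
            raise ValueError("TG contraction not modeled")
        i = locus.TG_UNIT_OFFSET - 1 + 2 * locus.TG_WT_REPEATS  # end of run
        s = s[:i] + "TG" * extra + s[i:]
    return s


def build_allele(ref: ReferenceModel, spec: AlleleSpec | str,
                 snvs: dict[int, str] | None = None) -> Haplotype:
    """Haplotype sequence + coordinate map for one allele.

    Duplicated alleles insert the second tandem copy immediately after the
    unit; copy-specific edits (the C>A base, the TG expansion) are applied per
    the allele specification.  ``snvs`` (reference position -> alternate base)
    adds background
    substitutions; a position inside the unit would be written into every
    copy.
    """
    if isinstance(spec, str):
        try:
            spec = ALLELE_SPECS[spec]
        except KeyError:
            raise KeyError(f"unknown allele name {spec!r}") from None
    region_start = ref.interval.start
    unit = ref.unit_sequence
    off0 = ref.offset(locus.DUP_START)
    off1 = ref.offset(locus.DUP_END) + 1

    # (sequence piece, reference start or None)
    pieces: list[tuple[str, int | None]] = [(ref.sequence[:off0], region_start)]
    for snp_base, tg in zip(spec.copy_snp_bases, spec.copy_tg_repeats):
        copy = _edited_unit(unit, snp_base, tg)
        if tg == locus.TG_WT_REPEATS:
            pieces.append((copy, locus.DUP_START))
        else:  # split around the inserted repeat units
            cut = locus.TG_UNIT_OFFSET - 1 + 2 * locus.TG_WT_REPEATS
            extra = 2 * (tg - locus.TG_WT_REPEATS)
            pieces.append((copy[:cut], locus.DUP_START))
            pieces.append((copy[cut : cut + extra], None))
            pieces.append((copy[cut + extra :], locus.DUP_START + cut))
    pieces.append((ref.sequence[off1:], locus.DUP_END + 1))

    segments: list[Segment] = []
    parts: list[str] = []
    hap_pos = 1
    for piece, ref_start in pieces:
        if not piece:
            continue
        segments.append(Segment(hap_pos, len(piece), ref_start))
        parts.append(piece)
        hap_pos += len(piece)
    hap = Haplotype(allele=spec.name, sequence="".join(parts),
                    segments=tuple(segments))
    if snvs:
        buf = bytearray(hap.sequence.encode())
        for pos, alt in snvs.items():
            for hp in hap.hap_positions(pos):
                buf[hp - 1] = ord(alt)
        hap.sequence = buf.decode()
        hap.snvs = dict(snvs)
    return hap


# ---------------------------------------------------------------------------
# cohort design


@dataclass(frozen=True)
class ReadParams:
    coverage: float = 20.0
    read_length: int = 100
    fragment_mean: float = 350.0
    fragment_sd: float = 50.0
    error_rate: float = 0.0


@dataclass(frozen=True)
class DesignRow:
    breed: str
    phenotype: str
    n: int
    genotype: tuple[str, str]
    sample_kind: str = "individual"
    pool_size: int = 10

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for a in self.genotype:
            if a not in ALLELE_SPECS:
                raise ValueError(f"unknown allele {a!r}")


@dataclass(frozen=True)
class CohortDesign:
    rows: tuple[DesignRow, ...]
    background_density: float = 3e-3  # segregating sites per bp
    maf_range: tuple[float, float] = (0.1, 0.5)
    wt_ibd_block_fraction: float = 0.05
    marker_control_freq: float = 0.3
    reads: ReadParams = ReadParams()

    def __post_init__(self) -> None:
        for row in self.rows:
            crested = row.phenotype != "non_crested"
            has_dup = any(ALLELE_SPECS[a].has_duplication for a in row.genotype)
            if crested and not has_dup:
                raise ValueError(
                    f"{row.breed}: a crested bird without a duplication allele "
                    f"({row.genotype[0]}/{row.genotype[1]}) contradicts the model"
                )


def default_design(reads: ReadParams = ReadParams()) -> CohortDesign:
    """WGS-panel emulation: 22 crest samples (18 individuals + 4 pools)
    across eight crested breeds, plus 197 non-crested individuals."""
    rows = (
        DesignRow("Beijing You", "crested_small", 1, ("Cr1", "Cr1")),
        DesignRow("Silkie", "crested_small", 4, ("Cr1", "Cr1")),
        DesignRow("Silkie", "crested_small", 1, ("Cr1", "Cr1"), "pool"),
        DesignRow("Crested Dutch", "crested_large", 1, ("Cr2", "Cr2")),
        DesignRow("Crevecoeur", "crested_large", 1, ("Cr2", "Cr2")),
        DesignRow("Houdan", "crested_large", 3, ("Cr2", "Cr2")),
        DesignRow("Houdan", "crested_large", 1, ("Cr2", "Cr2"), "pool"),
        DesignRow("Polish", "crested_large", 2, ("Cr2", "Cr2")),
        DesignRow("Polish", "crested_large", 1, ("Cr2", "Cr3")),
        DesignRow("Polish", "crested_large", 1, ("Cr3", "Cr3")),
        DesignRow("Polish", "crested_large", 1, ("Cr2", "Cr2"), "pool"),
        DesignRow("Dutch-Polish", "crested_large", 1, ("Cr2", "Cr2")),
        DesignRow("Dutch-Polish", "crested_large", 1, ("Cr3", "Cr3"), "pool"),
        DesignRow("Sultan", "crested_large", 1, ("Cr2", "Cr2")),
        DesignRow("Appenzeller", "crested_upward", 1, ("Cr2", "Cr2")),
        DesignRow("Schijndelaar", "crested_upward", 1, ("Cr2", "Cr3")),
        DesignRow("Other breeds", "non_crested", 197, ("crWT", "crWT")),
    )
    return CohortDesign(rows=rows, reads=reads)


def table1_design(reads: ReadParams = ReadParams()) -> CohortDesign:
    """Per-breed counts and genotypes of the published genotyping summary."""
    rows = (
        DesignRow("Beijing You", "crested_small", 1, ("Cr1", "Cr1")),
        DesignRow("Silkie", "crested_small", 22, ("Cr1", "Cr1")),
        DesignRow("Crested Dutch", "crested_large", 1, ("Cr2", "Cr2")),
        DesignRow("Crevecoeur", "crested_large", 1, ("Cr2", "Cr2")),
        DesignRow("Dutch-Polish", "crested_large", 3, ("Cr2", "Cr2")),
        DesignRow("Dutch-Polish", "crested_large", 1, ("Cr2", "Cr3")),
        DesignRow("Dutch-Polish", "crested_large", 4, ("Cr3", "Cr3")),
        DesignRow("Houdan", "crested_large", 8, ("Cr2", "Cr2")),
        DesignRow("Polish", "crested_large", 11, ("Cr2", "Cr2")),
        DesignRow("Polish", "crested_large", 2, ("Cr2", "Cr3")),
        DesignRow("Polish", "crested_large", 1, ("Cr3", "Cr3")),
        DesignRow("Sultan", "crested_large", 5, ("Cr2", "Cr2")),
        DesignRow("Sultan", "crested_large", 2, ("Cr3", "Cr3")),
        DesignRow("Appenzeller", "crested_upward", 4, ("Cr2", "Cr2")),
        DesignRow("Schijndelaar", "crested_upward", 1, ("Cr2", "Cr2")),
        DesignRow("Schijndelaar", "crested_upward", 1, ("Cr2", "Cr3")),
        DesignRow("Other breeds", "non_crested", 433, ("crWT", "crWT")),
    )
    return CohortDesign(rows=rows, reads=reads)


def tiny_design(reads: ReadParams = ReadParams()) -> CohortDesign:
    """Small cohort for quick end-to-end runs."""
    rows = (
        DesignRow("Silkie", "crested_small", 3, ("Cr1", "Cr1")),
        DesignRow("Houdan", "crested_large", 2, ("Cr2", "Cr2")),
        DesignRow("Silkie", "crested_small", 1, ("Cr1", "Cr1"), "pool"),
        DesignRow("Other breeds", "non_crested", 8, ("crWT", "crWT")),
    )
    return CohortDesign(rows=rows, reads=reads)


DESIGNS = {"wgs_panel": default_design, "table1": table1_design,
           "tiny": tiny_design}


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class HapSpec:
    """Lightweight haplotype description: allele + background substitutions."""

    allele: str
    snv_positions: frozenset[int]


@dataclass
class Cohort:
    design: CohortDesign
    reference: ReferenceModel
    sheet: list[SampleSheetRow]
    matrix: GenotypeMatrix
    truth_variants: list[VariantRecord]
    haplotype_specs: dict[str, tuple[HapSpec, HapSpec]]  # individuals
    pool_members: dict[str, list[tuple[HapSpec, HapSpec]]]
    site_alt_base: dict[int, str]

    def haplotypes(self, sample_id: str) -> tuple[Haplotype, Haplotype]:
        """Materialize the two haplotype sequences of an individual."""
        a, b = self.haplotype_specs[sample_id]
        return (self._materialize(a), self._materialize(b))

    def _materialize(self, spec: HapSpec) -> Haplotype:
        snvs = {p: self.site_alt_base[p] for p in spec.snv_positions}
        return build_allele(self.reference, spec.allele, snvs=snvs)

    def write(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": str(outdir / "reference.fa"),
            "sample_sheet": str(outdir / "sample_sheet.tsv"),
            "truth_vcf": str(outdir / "truth.vcf"),
        }
        write_fasta({self.reference.interval.chrom: self.reference.sequence},
                    paths["reference"])
        write_sample_sheet(self.sheet, paths["sample_sheet"])
        if self.matrix.variants:
            write_vcf(self.matrix, paths["truth_vcf"])
        else:
            Path(paths["truth_vcf"]).write_text(
                "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL"
                "\tFILTER\tINFO\n"
            )
        return paths


def _breed_code(breed: str) -> str:
    return "".join(w[:3].upper() for w in re.split(r"[\s-]+", breed))


def generate_cohort(ref: ReferenceModel, design: CohortDesign,
                    seed: int) -> Cohort:
    """Sample a diploid cohort and its truth genotype matrix.

    The construction guarantees the study-logic geometry: the four IBD SNVs
    ride on every duplication haplotype (and on a small minority of control
    haplotypes), the boundary marker at the IBD start is reference on every
    case haplotype while controls segregate, the sites immediately flanking
    the IBD interval are case-discordant, and inside the interval the case
    haplotype differs from the reference at exactly the four SNVs plus the
    duplication.
    """
    rng = np.random.default_rng(seed)

    # --- samples and haplotypes -------------------------------------------
    sheet: list[SampleSheetRow] = []
    hap_owner: list[tuple[str, int]] = []  # (sample_id, hap index in sample)
    hap_allele: list[str] = []
    counters: dict[str, int] = {}
    individual_ids: list[str] = []
    pool_ids: list[str] = []
    sample_hap_slices: dict[str, slice] = {}
    for row in design.rows:
        for _ in range(row.n):
            code = _breed_code(row.breed)
            counters[code] = counters.get(code, 0) + 1
            suffix = "P" if row.sample_kind == "pool" else ""
            sid = f"{code}{suffix}{counters[code]:03d}"
            sheet.append(SampleSheetRow(sid, row.breed, row.phenotype,
                                        row.sample_kind))
            n_haps = 2 * (row.pool_size if row.sample_kind == "pool" else 1)
            start = len(hap_allele)
            for k in range(n_haps):
                hap_owner.append((sid, k))
                hap_allele.append(row.genotype[k % 2])
            sample_hap_slices[sid] = slice(start, start + n_haps)
            (pool_ids if row.sample_kind == "pool" else individual_ids).append(sid)
    n_haps = len(hap_allele)
    if n_haps == 0:
        empty = pd.DataFrame()
        matrix = GenotypeMatrix(variants=[], samples=[], calls=empty)
        return Cohort(design, ref, [], matrix, [], {}, {}, {})

    is_dup_hap = np.array(
        [ALLELE_SPECS[a].has_duplication for a in hap_allele], dtype=bool
    )
    case_ids = {s.sample_id for s in sheet if s.is_case}
    is_case_hap = np.array(
        [sid in case_ids for sid, _ in hap_owner], dtype=bool
    )
    is_control_wt_hap = (~is_case_hap) & (~is_dup_hap)

    # --- site placement ----------------------------------------------------
    region = ref.interval
    n_bg = int(round(design.background_density * region.length()))
    candidates = rng.choice(
        np.arange(region.start, region.end + 1), size=min(n_bg * 2, region.length()),
        replace=False,
    )
    special = {BOUNDARY_MARKER, DISCORDANT_LEFT, DISCORDANT_RIGHT,
               *locus.IBD_SNV_POSITIONS, locus.DUP_START}
    background = [
        int(p) for p in candidates
        if not _BACKGROUND_EXCLUSION.contains(int(p)) and int(p) not in special
    ][:n_bg]
    snv_positions = sorted(
        background + [BOUNDARY_MARKER, DISCORDANT_LEFT, DISCORDANT_RIGHT,
                      *locus.IBD_SNV_POSITIONS]
    )
    site_alt_base: dict[int, str] = {}
    for pos in snv_positions:
        ref_base = ref.base(pos)
        alts = [b for b in "ACGT" if b != ref_base]
        site_alt_base[pos] = alts[int(rng.integers(3))]

    # --- per-haplotype alt allocation -------------------------------------
    alt = np.zeros((len(snv_positions), n_haps), dtype=bool)
    pos_index = {p: i for i, p in enumerate(snv_positions)}
    for pos in background:
        p = rng.uniform(*design.maf_range)
        alt[pos_index[pos]] = rng.random(n_haps) < p

    i_marker = pos_index[BOUNDARY_MARKER]
    controls = np.flatnonzero(~is_case_hap)
    alt[i_marker] = False
    if controls.size:
        alt[i_marker, controls] = rng.random(controls.size) < design.marker_control_freq
        if not alt[i_marker, controls].any():
            alt[i_marker, controls[0]] = True

    for pos in (DISCORDANT_LEFT, DISCORDANT_RIGHT):
        i = pos_index[pos]
        alt[i] = rng.random(n_haps) < 0.3
        # force discordance among cases: first case individual made 0/1
        first_case = next((sid for sid in individual_ids if sid in case_ids), None)
        if first_case is not None:
            sl = sample_hap_slices[first_case]
            alt[i, sl.start] = True
            alt[i, sl.start + 1] = False

    for pos in locus.IBD_SNV_POSITIONS:
        i = pos_index[pos]
        alt[i] = is_dup_hap.copy()
    wt_controls = np.flatnonzero(is_control_wt_hap)
    if wt_controls.size:
        k = max(1, int(round(design.wt_ibd_block_fraction * wt_controls.size)))
        block = rng.choice(wt_controls, size=k, replace=False)
        for pos in locus.IBD_SNV_POSITIONS:
            alt[pos_index[pos], block] = True

    # --- variant records and calls ----------------------------------------
    variants: list[VariantRecord] = []
    rows_alt: list[np.ndarray] = []
    for pos in snv_positions:
        variants.append(
            VariantRecord(GenomicInterval(region.chrom, pos, pos), "SNV",
                          ref.base(pos), site_alt_base[pos])
        )
        rows_alt.append(alt[pos_index[pos]])
    dup_record = VariantRecord(
        GenomicInterval(region.chrom, locus.DUP_START, locus.DUP_START),
        "DUP", ref.base(locus.DUP_START), "<DUP>", dup_end=locus.DUP_END,
    )
    insert_at = next(
        (i for i, v in enumerate(variants) if v.pos > locus.DUP_START),
        len(variants),
    )
    variants.insert(insert_at, dup_record)
    rows_alt.insert(insert_at, is_dup_hap)

    calls: dict[str, list] = {}
    for s in sheet:
        sl = sample_hap_slices[s.sample_id]
        col: list = []
        for row_alt in rows_alt:
            haps = row_alt[sl]
            if s.sample_kind == "pool":
                col.append(float(haps.mean()))
            else:
                a, b = int(haps[0]), int(haps[1])
                col.append(f"{min(a, b)}/{max(a, b)}")
        calls[s.sample_id] = col

    matrix = GenotypeMatrix(
        variants=variants, samples=sheet,
        calls=pd.DataFrame(calls, columns=[s.sample_id for s in sheet]),
    )

    # --- haplotype specs ----------------------------------------------------
    def spec_for(h: int) -> HapSpec:
        carried = frozenset(
            p for p in snv_positions if alt[pos_index[p], h]
        )
        return HapSpec(allele=hap_allele[h], snv_positions=carried)

    haplotype_specs = {
        sid: (spec_for(sample_hap_slices[sid].start),
              spec_for(sample_hap_slices[sid].start + 1))
        for sid in individual_ids
    }
    pool_members = {
        sid: [
            (spec_for(h), spec_for(h + 1))
            for h in range(sample_hap_slices[sid].start,
                           sample_hap_slices[sid].stop, 2)
        ]
        for sid in pool_ids
    }
    return Cohort(design=design, reference=ref, sheet=sheet, matrix=matrix,
                  truth_variants=variants, haplotype_specs=haplotype_specs,
                  pool_members=pool_members, site_alt_base=site_alt_base)


# ---------------------------------------------------------------------------
# read simulation


def _chunk_ops(ops: list[tuple[str, int, int | None]]):
    """Group walk ops into locally colinear chunks (new chunk at a ref jump)."""
    chunks: list[list[tuple[str, int, int | None]]] = []
    expected: int | None = None
    current: list[tuple[str, int, int | None]] = []
    for op, n, ref_start in ops:
        if op == "I":
            if current:
                current.append((op, n, None))
            else:
                current = [(op, n, None)]
            continue
        if current and expected is not None and ref_start != expected:
            chunks.append(current)
            current = [(op, n, ref_start)]
        else:
            current.append((op, n, ref_start))
        expected = ref_start + n
    if current:
        chunks.append(current)
    return chunks


def _place_read(hap: Haplotype, a: int, b: int, qname: str, is_read1: bool,
                is_reverse: bool, seq: str,
                min_segment: int = 12) -> tuple[ReadAlignment, list[ReadAlignment]]:
    """Analytic alignment of haplotype interval [a, b] onto the reference."""
    ops: list[tuple[str, int, int | None]] = []
    for seg in hap.segments:
        lo = max(a, seg.hap_start)
        hi = min(b, seg.hap_start + seg.length - 1)
        if lo > hi:
            continue
        if seg.ref_start is None:
            ops.append(("I", hi - lo + 1, None))
        else:
            ops.append(("M", hi - lo + 1, seg.ref_start + (lo - seg.hap_start)))
    chunks = _chunk_ops(ops)

    # read offsets of each chunk, then strip edge insertions into clips
    infos = []
    offset = 0
    for chunk in chunks:
        length = sum(n for _, n, _ in chunk)
        start = offset
        offset += length
        while chunk and chunk[0][0] == "I":
            start += chunk[0][1]
            chunk = chunk[1:]
        end = start + sum(n for _, n, _ in chunk)
        if not chunk:
            continue
        infos.append((start, end, chunk))

    read_len = b - a + 1
    aligned = [sum(n for op, n, _ in chunk if op == "M") for _, _, chunk in infos]
    primary_idx = int(np.argmax(aligned))
    alignments: list[ReadAlignment | None] = []
    for i, (start, end, chunk) in enumerate(infos):
        if i != primary_idx and aligned[i] < min_segment:
            alignments.append(None)
            continue
        cigar: list[tuple[str, int]] = []
        if start > 0:
            cigar.append(("S", start))
        for op, n, _ in chunk:
            if cigar and cigar[-1][0] == op:
                cigar[-1] = (op, cigar[-1][1] + n)
            else:
                cigar.append((op, n))
        if read_len - end > 0:
            cigar.append(("S", read_len - end))
        alignments.append(
            ReadAlignment(
                qname=qname, chrom=locus.CHROM,
                pos=chunk[0][2], is_reverse=is_reverse, is_read1=is_read1,
                is_supplementary=(i != primary_idx),
                cigar=tuple(cigar), seq=seq,
            )
        )
    primary = alignments[primary_idx]
    supplementary = [x for i, x in enumerate(alignments)
                     if x is not None and i != primary_idx]
    return primary, supplementary


def simulate_alignments(ref: ReferenceModel,
                        haplotypes: tuple[Haplotype, Haplotype],
                        params: ReadParams, seed: int,
                        region: GenomicInterval | None = None,
                        sample_id: str = "sim") -> list[AlignedReadPair]:
    """Simulate paired-end alignments for one diploid individual.

    Fragments are drawn along each haplotype and every read's reference
    placement is computed from the coordinate map: junction-spanning reads
    become primary + supplementary split alignments with exact clip lengths,
    and fragments straddling the junction yield everted pair orientations.
    Deterministic per seed.
    """
    if params.coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    rl = params.read_length
    pairs: list[AlignedReadPair] = []
    frag_counter = 0
    for hap in haplotypes:
        if region is None:
            lo, hi = 1, hap.length
        else:
            lo, hi = hap.hap_range(region)
        window = hi - lo + 1
        lam = (params.coverage / 2.0) * window / (2 * rl)
        n_frag = int(rng.poisson(lam))
        for _ in range(n_frag):
            flen = int(round(rng.normal(params.fragment_mean,
                                        params.fragment_sd)))
            flen = max(2 * rl, min(flen, window))
            start = int(rng.integers(lo, hi - flen + 2))
            qname = f"{sample_id}_frag{frag_counter:06d}"
            frag_counter += 1
            reads = []
            for is_read1, (a, b), is_reverse in (
                (True, (start, start + rl - 1), False),
                (False, (start + flen - rl, start + flen - 1), True),
            ):
                seq = hap.sequence[a - 1 : b]
                if params.error_rate > 0:
                    seq = _add_errors(seq, params.error_rate, rng)
                reads.append(_place_read(hap, a, b, qname, is_read1,
                                         is_reverse, seq))
            (r1, s1), (r2, s2) = reads
            r1.mate_pos, r1.mate_reverse = r2.pos, r2.is_reverse
            r2.mate_pos, r2.mate_reverse = r1.pos, r1.is_reverse
            pairs.append(AlignedReadPair(qname=qname, r1=r1, r2=r2,
                                         supplementaries=s1 + s2))
    return pairs


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    buf = bytearray(seq.encode())
    for i in np.flatnonzero(rng.random(len(buf)) < rate):
        current = buf[i]
        choices = [c for c in b"ACGT" if c != current]
        buf[i] = choices[int(rng.integers(3))]
    return buf.decode()
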