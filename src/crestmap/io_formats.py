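"""Shared genomic types and readers/writers for the formats the pipeline touches.

All public coordinates are 1-based inclusive, the convention used for the
locus throughout (e.g. a duplication "spanning 7,587,588-7,587,784" includes
both endpoints).  The only sanctioned conversion to 0-based half-open
(BED, internal arrays) is the :func:`to_zero_based` / :func:`from_zero_based`
pair, which composes to the identity.

VCF and SAM I/O are thin layers over :mod:`pysam`; FASTA goes through
:mod:`Bio.SeqIO`.  Only the subset of VCF the pipeline produces is supported:
``GT`` for individual samples, a pool alternate-allele frequency in a
dedicated ``AF`` FORMAT field, and symbolic ``<DUP>`` records carrying
``END``/``SVTYPE``/``SVLEN``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PHENOTYPES = frozenset(
    {"crested_large", "crested_small", "crested_upward", "non_crested"}
)
SAMPLE_KINDS = frozenset({"individual", "pool"})
MISSING_GT = "./."


# ---------------------------------------------------------------------------
# coordinates


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Closed interval [start, end] on ``chrom``, 1-based inclusive."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")

    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def __str__(self) -> str:  # chr33:7,587,588-7,587,784 style without commas
        return f"{self.chrom}:{self.start}-{self.end}"


def to_zero_based(interval: GenomicInterval) -> tuple[str, int, int]:
    """1-based inclusive -> (chrom, start, end) 0-based half-open (BED)."""
    return interval.chrom, interval.start - 1, interval.end


def from_zero_based(chrom: str, start: int, end: int) -> GenomicInterval:
    """(chrom, start, end) 0-based half-open (BED) -> 1-based inclusive."""
    return GenomicInterval(chrom, start + 1, end)


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chr33:7570000-7820000`` (commas tolerated)."""
    chrom, _, span = text.partition(":")
    if not span:
        raise ValueError(f"cannot parse region {text!r}")
    lo, _, hi = span.replace(",", "").partition("-")
    return GenomicInterval(chrom, int(lo), int(hi))


# ---------------------------------------------------------------------------
# variants


@dataclass(frozen=True)
class VariantRecord:
    """A single variant: SNV, insertion, or symbolic tandem duplication.

    For ``DUP`` records ``interval.start`` is the first duplicated base and
    ``dup_end`` the last one (the span style used for the locus); ``alt_allele``
    is the symbolic ``<DUP>``.
    """

    interval: GenomicInterval
    vtype: str  # SNV | INS | DUP
    ref_allele: str
    alt_allele: str
    dup_end: int | None = None

    def __post_init__(self) -> None:
        if self.vtype == "SNV":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("SNV alleles must have length 1")
        elif self.vtype == "DUP":
            if self.dup_end is None or self.dup_end <= self.interval.start:
                raise ValueError("DUP requires dup_end > interval.start")
        elif self.vtype == "INS":
            if len(self.alt_allele) <= len(self.ref_allele):
                raise ValueError("INS alt must be longer than ref")
        else:
            raise ValueError(f"unknown variant type {self.vtype!r}")

    @property
    def pos(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        """Last reference base affected (END for DUPs)."""
        return self.dup_end if self.vtype == "DUP" else self.interval.end


def dup_to_insertion(dup: VariantRecord, unit_seq: str, anchor_base: str) -> VariantRecord:
    """Equivalent explicit-insertion representation of a tandem duplication.

    A tandem duplication of [start, end] is the insertion of the unit
    sequence immediately after ``end``; ``anchor_base`` is the reference base
    at ``end``.
    """
    if dup.vtype != "DUP":
        raise ValueError("expected a DUP record")
    return VariantRecord(
        interval=GenomicInterval(dup.interval.chrom, dup.dup_end, dup.dup_end),
        vtype="INS",
        ref_allele=anchor_base,
        alt_allele=anchor_base + unit_seq,
    )


def apply_variant(sequence: str, region_start: int, record: VariantRecord,
                  unit_seq: str | None = None) -> str:
    """Apply one variant to a reference slice starting at ``region_start``.

    Used to check that the symbolic-DUP and explicit-insertion encodings
    describe the same event.
    """
    i = record.pos - region_start  # 0-based offset
    if record.vtype == "SNV":
        return sequence[:i] + record.alt_allele + sequence[i + 1 :]
    if record.vtype == "INS":
        return sequence[: i + len(record.ref_allele)] + record.alt_allele[
            len(record.ref_allele) :
        ] + sequence[i + len(record.ref_allele) :]
    if record.vtype == "DUP":
        j = record.dup_end - region_start + 1
        unit = sequence[i:j] if unit_seq is None else unit_seq
        return sequence[:j] + unit + sequence[j:]
    raise ValueError(record.vtype)


# ---------------------------------------------------------------------------
# sample sheet


@dataclass(frozen=True)
class SampleSheetRow:
    sample_id: str
    breed: str
    phenotype: str
    sample_kind: str = "individual"

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"phenotype {self.phenotype!r} not in {sorted(PHENOTYPES)}"
            )
        if self.sample_kind not in SAMPLE_KINDS:
            raise ValueError(f"sample_kind {self.sample_kind!r}")

    @property
    def is_case(self) -> bool:
        return self.phenotype != "non_crested"


def write_sample_sheet(rows: Sequence[SampleSheetRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.sample_id, r.breed, r.phenotype, r.sample_kind)
            for r in rows
        ],
        columns=["sample_id", "breed", "phenotype", "sample_kind"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> list[SampleSheetRow]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    rows = [
        SampleSheetRow(r.sample_id, r.breed, r.phenotype, r.sample_kind)
        for r in df.itertuples()
    ]
    ids = [r.sample_id for r in rows]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in sample sheet")
    return rows


# ---------------------------------------------------------------------------
# genotype matrix


@dataclass
class GenotypeMatrix:
    """Variants x samples call container.

    ``calls`` is a pandas DataFrame (rows aligned with ``variants``, columns
    are sample ids).  Entries are diploid genotype strings (``0/0``, ``0/1``,
    ``1/1``, ``./.``) for individual samples and alternate-allele frequencies
    (floats in [0, 1]) for pool samples.
    """

    variants: list[VariantRecord]
    samples: list[SampleSheetRow]
    calls: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.calls.columns) != ids:
            raise ValueError("calls columns do not match sample sheet order")
        if len(self.calls) != len(self.variants):
            raise ValueError("calls rows do not match variant count")
        positions = [v.pos for v in self.variants]
        if positions != sorted(positions):
            raise ValueError("variants must be sorted by position")
        kinds = {s.sample_id: s.sample_kind for s in self.samples}
        for sid, col in self.calls.items():
            for value in col:
                if kinds[sid] == "pool":
                    if not isinstance(value, float) or not 0.0 <= value <= 1.0:
                        raise ValueError(
                            f"pool sample {sid} needs frequencies in [0,1]"
                        )
                elif not isinstance(value, str):
                    raise ValueError(f"individual sample {sid} needs GT strings")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.variants), len(self.samples)

    @property
    def case_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.is_case]

    @property
    def control_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if not s.is_case]

    def sample(self, sample_id: str) -> SampleSheetRow:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def calls_at(self, variant_index: int) -> dict[str, str | float]:
        return dict(self.calls.iloc[variant_index])

    def variants_in(self, interval: GenomicInterval) -> list[int]:
        return [
            i
            for i, v in enumerate(self.variants)
            if v.interval.chrom == interval.chrom
            and interval.start <= v.pos <= interval.end
        ]


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(s), id=name, description="") for name, s in records.items()
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(samples: Sequence[SampleSheetRow], contig: str,
                contig_length: int) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Length of structural variant")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AF", 1, "Float", "Pool alternate allele frequency")
    header.add_line('##ALT=<ID=DUP,Description="Tandem duplication">')
    for s in samples:
        header.add_sample(s.sample_id)
    return header


def write_vcf(matrix: GenotypeMatrix, path: str | Path,
              contig_length: int = 7_820_000) -> None:
    contig = matrix.variants[0].interval.chrom if matrix.variants else "chr33"
    header = _vcf_header(matrix.samples, contig, contig_length)
    kinds = {s.sample_id: s.sample_kind for s in matrix.samples}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, var in enumerate(matrix.variants):
            alt = "<DUP>" if var.vtype == "DUP" else var.alt_allele
            kwargs = {}
            if var.vtype == "DUP":
                # htslib re-derives END as POS + SVLEN for symbolic records;
                # the reader below recovers dup_end from SVLEN
                kwargs["stop"] = var.dup_end
            rec = out.new_record(
                contig=var.interval.chrom,
                start=var.pos - 1,
                alleles=(var.ref_allele, alt),
                **kwargs,
            )
            if var.vtype == "DUP":
                rec.info["SVTYPE"] = "DUP"
                rec.info["SVLEN"] = var.dup_end - var.pos + 1
            row = matrix.calls.iloc[i]
            for sid in matrix.calls.columns:
                if kinds[sid] == "pool":
                    rec.samples[sid]["GT"] = (None, None)
                    rec.samples[sid]["AF"] = float(row[sid])
                else:
                    gt = row[sid]
                    if gt == MISSING_GT:
                        rec.samples[sid]["GT"] = (None, None)
                    else:
                        a, b = gt.split("/")
                        rec.samples[sid]["GT"] = (int(a), int(b))
            out.write(rec)


def read_vcf(path: str | Path, samples: Sequence[SampleSheetRow]) -> GenotypeMatrix:
    """Read a VCF produced by this pipeline into a :class:`GenotypeMatrix`.

    ``samples`` (the sample sheet) decides which columns are pools; a VCF
    sample absent from the sheet is an error naming the sample.
    """
    by_id = {s.sample_id: s for s in samples}
    variants: list[VariantRecord] = []
    columns: dict[str, list] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for sid in vcf.header.samples:
            if sid not in by_id:
                raise ValueError(f"sample {sid!r} missing from sample sheet")
            columns[sid] = []
        sheet = [by_id[sid] for sid in vcf.header.samples]
        for line_no, rec in enumerate(vcf, start=1):
            if len(rec.alts or ()) != 1:
                raise ValueError(f"record {line_no}: expected exactly one ALT")
            alt = rec.alts[0]
            chrom, pos = rec.contig, rec.pos
            if alt == "<DUP>":
                svlen = rec.info.get("SVLEN")
                dup_end = (pos + abs(int(svlen)) - 1 if svlen is not None
                           else rec.stop)
                var = VariantRecord(
                    GenomicInterval(chrom, pos, pos), "DUP", rec.ref, alt,
                    dup_end=dup_end,
                )
            elif len(alt) > len(rec.ref):
                var = VariantRecord(
                    GenomicInterval(chrom, pos, pos + len(rec.ref) - 1),
                    "INS", rec.ref, alt,
                )
            else:
                var = VariantRecord(
                    GenomicInterval(chrom, pos, pos), "SNV", rec.ref, alt
                )
            variants.append(var)
            for sid in vcf.header.samples:
                sample = rec.samples[sid]
                if by_id[sid].sample_kind == "pool":
                    af = sample.get("AF")
                    columns[sid].append(float(af) if af is not None else 0.0)
                else:
                    gt = sample.get("GT")
                    if gt is None or all(a is None for a in gt):
                        columns[sid].append(MISSING_GT)
                        continue
                    # htslib maps out-of-range allele indexes to None, so a
                    # half-missing tuple here means a malformed GT
                    if any(a not in (0, 1) for a in gt):
                        raise ValueError(
                            f"record {line_no}: malformed GT {gt} for {sid}"
                        )
                    columns[sid].append(f"{min(gt)}/{max(gt)}")
    calls = pd.DataFrame(columns, columns=list(columns))
    order = sorted(range(len(variants)), key=lambda i: variants[i].pos)
    variants = [variants[i] for i in order]
    calls = calls.iloc[order].reset_index(drop=True)
    return GenotypeMatrix(variants=variants, samples=sheet, calls=calls)


# ---------------------------------------------------------------------------
# SAM

_CIGAR_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5}
_CODE_CIGAR = {v: k for k, v in _CIGAR_CODE.items()}


def _cigar_string(cigar: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def write_sam(pairs: Iterable["AlignedReadPair"], path: str | Path,
              ref_name: str = "chr33", ref_length: int = 7_820_000) -> None:
    """Write read pairs (with supplementary split segments) as coordinate-sorted SAM."""
    from .sv_detect import AlignedReadPair, ReadAlignment  # noqa: F401

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref_name, "LN": ref_length}],
    }
    out = pysam.AlignmentFile(str(path), "w", header=header)
    segments: list[pysam.AlignedSegment] = []

    def sa_tag(alns) -> str:
        return "".join(
            f"{a.chrom},{a.pos},{'-' if a.is_reverse else '+'},"
            f"{_cigar_string(a.cigar)},60,0;"
            for a in alns
        )

    for pair in pairs:
        by_read = {True: [], False: []}
        for aln in (pair.r1, pair.r2, *pair.supplementaries):
            if aln is not None:
                by_read[aln.is_read1].append(aln)
        for aln in (pair.r1, pair.r2, *pair.supplementaries):
            if aln is None:
                continue
            seg = pysam.AlignedSegment(header=out.header)
            seg.query_name = aln.qname
            seg.reference_id = 0
            seg.reference_start = aln.pos - 1
            seg.mapping_quality = 60
            seg.cigartuples = [(_CIGAR_CODE[op], n) for op, n in aln.cigar]
            seg.query_sequence = aln.seq
            flag = 0x1  # paired
            flag |= 0x40 if aln.is_read1 else 0x80
            if aln.is_reverse:
                flag |= 0x10
            if aln.mate_reverse:
                flag |= 0x20
            if aln.is_supplementary:
                flag |= 0x800
            seg.flag = flag
            if aln.mate_pos is not None:
                seg.next_reference_id = 0
                seg.next_reference_start = aln.mate_pos - 1
            mates = by_read[aln.is_read1]
            others = [a for a in mates if a is not aln]
            if others:
                seg.set_tag("SA", sa_tag(others))
            segments.append(seg)
    segments.sort(key=lambda s: s.reference_start)
    for seg in segments:
        out.write(seg)
    out.close()


def read_sam(path: str | Path) -> Iterator["AlignedReadPair"]:
    """Stream aligned read pairs from a coordinate-sorted SAM.

    Yields :class:`crestmap.sv_detect.AlignedReadPair` objects with any
    supplementary split segments attached.  Orphan mates are skipped with a
    warning; unsorted input is an error.
    """
    from .sv_detect import AlignedReadPair, ReadAlignment

    af = pysam.AlignmentFile(str(path), "r", check_sq=False)
    so = (af.header.to_dict().get("HD") or {}).get("SO")
    if so != "coordinate":
        raise ValueError(f"SAM must be coordinate-sorted (SO={so!r})")
    groups: dict[str, list[ReadAlignment]] = {}
    last_pos = -1
    for seg in af:
        if seg.reference_start < last_pos:
            raise ValueError("SAM records are not coordinate-sorted")
        last_pos = seg.reference_start
        aln = ReadAlignment(
            qname=seg.query_name,
            chrom=seg.reference_name,
            pos=seg.reference_start + 1,
            is_reverse=seg.is_reverse,
            is_read1=seg.is_read1,
            is_supplementary=seg.is_supplementary,
            cigar=tuple((_CODE_CIGAR[c], n) for c, n in seg.cigartuples or ()),
            seq=seg.query_sequence,
            mate_pos=(seg.next_reference_start + 1
                      if seg.next_reference_start >= 0 else None),
            mate_reverse=seg.mate_is_reverse,
        )
        groups.setdefault(seg.query_name, []).append(aln)
    af.close()
    for qname, alns in groups.items():
        r1 = next((a for a in alns if a.is_read1 and not a.is_supplementary), None)
        r2 = next((a for a in alns if not a.is_read1 and not a.is_supplementary), None)
        if r1 is None or r2 is None:
            warnings.warn(f"orphan mate for fragment {qname}; pair skipped")
            continue
        supp = [a for a in alns if a.is_supplementary]
        yield AlignedReadPair(qname=qname, r1=r1, r2=r2, supplementaries=supp)
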