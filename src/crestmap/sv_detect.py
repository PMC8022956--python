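"""Tandem-duplication detection from read-level evidence.

A tandem duplication leaves three signatures in paired-end alignments:

* **split reads** — a read crossing the junction between the two copies
  aligns in two parts: a prefix ending at the last base of the unit and a
  suffix starting again at its first base.  These give base-pair-exact
  breakpoints.
* **everted pairs** — a fragment straddling the junction maps with its
  forward-strand mate to the *right* of its reverse-strand mate, the mates
  pointing away from each other.
* **read depth** — the duplicated unit is covered twice per mutant
  haplotype, so depth inside the unit relative to the flanks tends to 1.5
  (heterozygote) or 2.0 (homozygote).

The caller clusters identical split junctions, left-aligns them through any
microhomology (the VCF convention of reporting the leftmost equivalent
breakpoints), and genotypes the call from the unit/flank depth ratio.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import GenomicInterval

_REF_CONSUMING = {"M": True, "D": True, "N": True, "I": False, "S": False, "H": False}
_READ_CONSUMING = {"M": True, "I": True, "S": True, "D": False, "N": False, "H": False}


@dataclass
class ReadAlignment:
    """One aligned segment of one read (primary or supplementary)."""

    qname: str
    chrom: str
    pos: int  # 1-based leftmost aligned base
    is_reverse: bool
    is_read1: bool
    is_supplementary: bool
    cigar: tuple[tuple[str, int], ...]
    seq: str | None = None
    mate_pos: int | None = None
    mate_reverse: bool | None = None

    @property
    def ref_end(self) -> int:
        """1-based rightmost aligned reference base."""
        span = sum(n for op, n in self.cigar if _REF_CONSUMING[op])
        return self.pos + span - 1

    @property
    def clip_left(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] in "SH" else 0

    @property
    def clip_right(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] in "SH" else 0

    @property
    def aligned_length(self) -> int:
        return sum(n for op, n in self.cigar if op == "M")


@dataclass
class AlignedReadPair:
    """A fragment's two primary alignments plus any supplementary segments."""

    qname: str
    r1: ReadAlignment
    r2: ReadAlignment
    supplementaries: list[ReadAlignment] = field(default_factory=list)

    @property
    def is_everted(self) -> bool:
        """Mates on opposite strands pointing away from each other."""
        a, b = self.r1, self.r2
        if a.is_reverse == b.is_reverse:
            return False
        fwd, rev = (a, b) if not a.is_reverse else (b, a)
        return fwd.pos > rev.pos

    def overlaps(self, region: GenomicInterval) -> bool:
        lo = min(self.r1.pos, self.r2.pos)
        hi = max(self.r1.ref_end, self.r2.ref_end)
        return self.r1.chrom == region.chrom and lo <= region.end and hi >= region.start


@dataclass
class Evidence:
    """Everted-pair clusters, split-read junctions and a depth profile."""

    region: GenomicInterval
    depth: np.ndarray  # per-base, index 0 == region.start
    junctions: Counter  # (dup_start, dup_end) -> split-read count
    everted: list[AlignedReadPair]

    def depth_at(self, interval: GenomicInterval) -> np.ndarray:
        lo = max(interval.start, self.region.start) - self.region.start
        hi = min(interval.end, self.region.end) - self.region.start + 1
        return self.depth[lo:hi]


@dataclass
class DupCall:
    interval: GenomicInterval  # duplicated unit, 1-based inclusive
    unit_length: int
    genotype: str  # het | hom
    pe_support: int
    sr_support: int
    depth_ratio: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.unit_length != self.interval.end - self.interval.start + 1:
            raise ValueError("unit_length inconsistent with interval")


def collect_evidence(pairs: Iterable[AlignedReadPair],
                     region: GenomicInterval) -> Evidence:
    """Scan read pairs for duplication signatures inside ``region``."""
    depth = np.zeros(region.length(), dtype=np.int32)
    junctions: Counter = Counter()
    everted: list[AlignedReadPair] = []
    for pair in pairs:
        if not pair.overlaps(region):
            continue
        alns = [pair.r1, pair.r2, *pair.supplementaries]
        for aln in alns:
            ref = aln.pos
            for op, n in aln.cigar:
                if op == "M":
                    lo = max(ref, region.start) - region.start
                    hi = min(ref + n - 1, region.end) - region.start + 1
                    if hi > lo:
                        depth[lo:hi] += 1
                if _REF_CONSUMING[op]:
                    ref += n
        if pair.is_everted:
            everted.append(pair)
        for is_read1 in (True, False):
            parts = [a for a in alns if a.is_read1 == is_read1]
            if len(parts) < 2:
                continue
            parts.sort(key=lambda a: a.clip_left)  # read-offset order
            for prefix, suffix in zip(parts, parts[1:]):
                s, e = suffix.pos, prefix.ref_end
                if s <= e:  # backward jump: tandem-duplication junction
                    junctions[(s, e)] += 1
    return Evidence(region=region, depth=depth, junctions=junctions,
                    everted=everted)


def depth_ratio(evidence: Evidence, unit: GenomicInterval,
                flank: int = 2000) -> float:
    """Mean depth inside ``unit`` divided by mean depth over both flanks."""
    inside = evidence.depth_at(unit)
    left = evidence.depth_at(
        GenomicInterval(unit.chrom, max(evidence.region.start, unit.start - flank),
                        max(evidence.region.start, unit.start - 1))
    )
    right = evidence.depth_at(
        GenomicInterval(unit.chrom, min(evidence.region.end, unit.end + 1),
                        min(evidence.region.end, unit.end + flank))
    )
    flank_depth = np.concatenate([left, right])
    if flank_depth.size == 0 or flank_depth.mean() == 0:
        raise ValueError("zero flank depth; cannot normalize")
    return float(inside.mean() / flank_depth.mean())


def left_align_junction(start: int, end: int, base_at) -> tuple[int, int]:
    """Shift a (start, end) duplication junction through microhomology.

    Duplicating [start, end] and [start-1, end-1] produce the same sequence
    whenever base(start-1) == base(end); report the leftmost representation.
    ``base_at`` maps a 1-based reference position to its base (or None when
    outside the known sequence).
    """
    while True:
        prev = base_at(start - 1)
        if prev is None or prev != base_at(end):
            return start, end
        start -= 1
        end -= 1


def call_tandem_dup(evidence: Evidence, min_support: int = 3,
                    het_low: float = 1.25, hom_low: float = 1.75,
                    flank: int = 2000, base_at=None) -> list[DupCall]:
    """Call tandem duplications from an evidence bundle.

    Breakpoints come from the modal split-read junction (left-aligned when a
    reference accessor ``base_at`` is supplied); the genotype comes from the
    unit/flank depth ratio (het for ratio in [het_low, hom_low), hom above).
    Calls overlapping another call are flagged rather than suppressed.
    """
    aligned: Counter = Counter()
    for (s, e), n in evidence.junctions.items():
        if base_at is not None:
            s, e = left_align_junction(s, e, base_at)
        aligned[(s, e)] += n
    calls: list[DupCall] = []
    for (s, e), sr in aligned.items():
        pe = sum(
            1
            for pair in evidence.everted
            if _everted_supports(pair, s, e)
        )
        if sr + pe < min_support:
            continue
        unit = GenomicInterval(evidence.region.chrom, s, e)
        ratio = depth_ratio(evidence, unit, flank=flank)
        if ratio >= hom_low:
            genotype = "hom"
        else:
            genotype = "het"
        calls.append(
            DupCall(interval=unit, unit_length=e - s + 1, genotype=genotype,
                    pe_support=pe, sr_support=sr, depth_ratio=ratio)
        )
    calls.sort(key=lambda c: c.sr_support + c.pe_support, reverse=True)
    for i, a in enumerate(calls):
        for b in calls[i + 1 :]:
            if a.interval.overlaps(b.interval):
                a.flagged = b.flagged = True
    return calls


def _everted_supports(pair: AlignedReadPair, s: int, e: int,
                      slack: int = 10) -> bool:
    fwd, rev = (
        (pair.r1, pair.r2) if not pair.r1.is_reverse else (pair.r2, pair.r1)
    )
    return rev.pos >= s - slack and fwd.ref_end <= e + slack


def dup_calls_to_matrix_records(calls: Sequence[DupCall]):
    """Symbolic <DUP> VariantRecords for the calls (for VCF export)."""
    from .io_formats import VariantRecord

    records = []
    for c in calls:
        records.append(
            VariantRecord(
                interval=GenomicInterval(c.interval.chrom, c.interval.start,
                                         c.interval.start),
                vtype="DUP", ref_allele="N", alt_allele="<DUP>",
                dup_end=c.interval.end,
            )
        )
    return records
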