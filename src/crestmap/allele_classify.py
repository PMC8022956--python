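"""Classify a resolved *Crest*-locus sequence into one of the five alleles.

This reproduces the Sanger-interpretation logic at the sequence level: count
tandem copies of the 197 bp unit between its unique flanking anchors, read
the diagnostic base at unit offset 42 (g.7,587,629) in each copy, type the TG
microsatellite at unit offset 107 (g.7,587,694), and apply the decision
table:

====================  =========================================
allele                structure
====================  =========================================
crWT                  1 copy, C, (TG)7
Cr2_backmutant        1 copy, A  (the *Cr2*-derived single copy)
Cr1                   2 copies, C/C, (TG)7/(TG)7
Cr2                   2 copies, A in the 3' copy
Cr3                   2 copies, (TG)8 in the 5' copy
====================  =========================================

Copy identity (5' vs 3') is positional.  Unit matching is near-exact
(edlib edit distance, tolerance 3 by default, since the real allele edits
are 1-2 bp); a sequence outside the table classifies as ``unknown``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from . import locus
from .synthetic_cohort import ReferenceModel

FLANK_LENGTH = 30


@dataclass
class AlleleCall:
    allele: str  # crWT | Cr1 | Cr2 | Cr3 | Cr2_backmutant | unknown
    copy_count: int
    snp_bases: tuple[str, ...]
    tg_counts: tuple[int, ...]
    copy_intervals: tuple[tuple[int, int], ...]  # 1-based within input seq
    note: str = ""


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def count_unit_copies(seq: str, unit_seq: str,
                      flanks: tuple[str, str]) -> tuple[int, list[tuple[int, int]]]:
    """Count tandem copies of ``unit_seq`` between the two flank anchors.

    Both flanks must occur exactly once.  Returns the copy count and the
    1-based (start, end) interval of each copy within ``seq``, ordered
    5' to 3'.  Copies are delimited by minimizing the summed edit distance
    to the unit over candidate split points, tolerating the small
    copy-specific edits.
    """
    left, right = flanks
    for name, flank in (("left", left), ("right", right)):
        count = seq.count(flank)
        if count == 0:
            raise ValueError(f"not the Crest locus: {name} flank absent")
        if count > 1:
            raise ValueError(f"{name} flank occurs {count} times")
    i = seq.index(left) + len(left)
    j = seq.index(right)
    if j < i:
        raise ValueError("not the Crest locus: flanks out of order")
    region_len = j - i
    unit_len = len(unit_seq)
    n = max(1, int(round(region_len / unit_len)))
    if abs(region_len - n * unit_len) > 4 * n:
        raise ValueError(
            f"inter-flank span {region_len} bp is not a plausible copy stack"
        )
    region = seq[i:j]
    if n == 1:
        return 1, [(i + 1, j)]
    # split the stack copy by copy, choosing each cut to minimize edit distance
    intervals: list[tuple[int, int]] = []
    offset = 0
    for copy_idx in range(n - 1):
        remaining = region_len - offset
        target = remaining - (n - 1 - copy_idx) * unit_len  # nominal cut
        best_cut, best_cost = None, None
        for cut in range(max(1, target - 6), min(remaining, target + 6) + 1):
            cost = _edit_distance(region[offset : offset + cut], unit_seq)
            if best_cost is None or cost < best_cost:
                best_cut, best_cost = cut, cost
        intervals.append((i + offset + 1, i + offset + best_cut))
        offset += best_cut
    intervals.append((i + offset + 1, j))
    return n, intervals


def count_tg_repeats(copy_seq: str, anchor_offset: int = locus.TG_UNIT_OFFSET) -> int:
    """Length, in repeat units, of the maximal perfect TG run containing the
    1-based ``anchor_offset``.  Returns 0 if the anchor base is not T or G."""
    idx = anchor_offset - 1
    if idx < 0 or idx >= len(copy_seq) or copy_seq[idx] not in "TG":
        return 0
    for m in re.finditer("(?:TG)+", copy_seq):
        if m.start() <= idx < m.end():
            return (m.end() - m.start()) // 2
    return 0


def classify_allele(seq: str, ref: ReferenceModel,
                    max_edits: int = 3) -> AlleleCall:
    """Classify one haplotype sequence spanning the locus with both flanks."""
    unit = ref.unit_sequence
    flanks = (ref.left_flank(FLANK_LENGTH), ref.right_flank(FLANK_LENGTH))
    n, intervals = count_unit_copies(seq, unit, flanks)
    copies = [seq[a - 1 : b] for a, b in intervals]
    snp_bases = tuple(
        c[locus.SNP_UNIT_OFFSET - 1] if len(c) >= locus.SNP_UNIT_OFFSET else "N"
        for c in copies
    )
    tg_counts = tuple(count_tg_repeats(c) for c in copies)
    call = AlleleCall(allele="unknown", copy_count=n, snp_bases=snp_bases,
                      tg_counts=tg_counts,
                      copy_intervals=tuple(intervals))
    if n > 2:
        call.note = f"{n} unit copies: outside the known allele series"
        return call
    if any(_edit_distance(c, unit) > max_edits for c in copies):
        call.note = "a unit copy diverges from the reference beyond tolerance"
        return call
    if n == 1:
        base = snp_bases[0]
        if base == "C":
            call.allele = "crWT"
        elif base == "A":
            call.allele = "Cr2_backmutant"
        return call
    b5, b3 = snp_bases
    t5, t3 = tg_counts
    if b3 == "A" and b5 == "C":
        call.allele = "Cr2"
    elif t5 == locus.TG_WT_REPEATS + 1 and t3 == locus.TG_WT_REPEATS \
            and b5 == b3 == "C":
        call.allele = "Cr3"
    elif b5 == b3 == "C" and t5 == t3 == locus.TG_WT_REPEATS:
        call.allele = "Cr1"
    return call


def classify_diploid(seq_a: str, seq_b: str, ref: ReferenceModel,
                     max_edits: int = 3) -> str:
    """Alphabetically ordered diploid genotype label, e.g. ``Cr2/Cr3``."""
    labels = []
    for seq in (seq_a, seq_b):
        try:
            labels.append(classify_allele(seq, ref, max_edits=max_edits).allele)
        except ValueError:
            labels.append("unknown")
    if "unknown" in labels:
        return "unknown"
    return "/".join(sorted(labels))
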