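"""Shared-haplotype (identity-by-descent) scanning and concordance filtering.

Crested chickens are assumed to have inherited the causal mutation from a
common ancestor, so within the candidate region there must be an interval
over which every crested sample carries the same haplotype.  The scan finds
maximal runs of consecutive polymorphic sites at which all case samples are
concordant (by default: homozygous for one and the same allele, with case
pools effectively fixed for it), and reports each run as an interval bounded
by its outermost concordant sites -- using the END coordinate for symbolic
duplication records.

The concordance filter then reduces the in-interval variants to those whose
non-reference allele is carried by every case and by no control, the
pattern expected of the causal change itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .io_formats import (
    MISSING_GT,
    GenomicInterval,
    GenotypeMatrix,
    VariantRecord,
    to_zero_based,
)

MODES = ("homozygous_ibd", "dominant_carrier")


@dataclass
class IbdInterval:
    interval: GenomicInterval
    n_support_sites: int
    flanking_discordant: tuple[int | None, int | None]

    def __post_init__(self) -> None:
        if self.n_support_sites < 1:
            raise ValueError("an IBD interval needs at least one support site")

    @property
    def length(self) -> int:
        return self.interval.length()


@dataclass
class CandidateVariant:
    variant: VariantRecord
    case_carrier_fraction: float
    control_carrier_fraction: float


def _allele_ok_individual(gt: str, allele: str, mode: str,
                          missing_policy: str) -> bool | None:
    """None means 'missing under permissive policy' (compatible)."""
    if gt == MISSING_GT:
        return None if missing_policy == "permissive" else False
    if mode == "homozygous_ibd":
        return gt == f"{allele}/{allele}"
    return allele in gt.split("/")


def _allele_freq(af: float, allele: str) -> float:
    return af if allele == "1" else 1.0 - af


def site_concordance(calls_at_site: Mapping[str, str | float],
                     case_ids: Sequence[str],
                     mode: str = "homozygous_ibd",
                     pool_fix_threshold: float = 0.95,
                     missing_policy: str = "strict") -> tuple[bool, str | None]:
    """Is this site compatible with all cases sharing one allele?

    Returns ``(is_concordant, shared_allele)`` where the shared allele is
    ``"ref"`` or ``"alt"``.  Individual calls are genotype strings, pool
    calls are alternate-allele frequencies; a pool counts as sharing an
    allele when its frequency for that allele is at least
    ``pool_fix_threshold``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if not case_ids:
        raise ValueError("no case samples")
    for allele, label in (("1", "alt"), ("0", "ref")):
        ok = True
        for sid in case_ids:
            call = calls_at_site[sid]
            if isinstance(call, float):
                if mode == "homozygous_ibd":
                    if _allele_freq(call, allele) < pool_fix_threshold:
                        ok = False
                        break
                elif _allele_freq(call, allele) <= 0.0:
                    ok = False
                    break
            else:
                verdict = _allele_ok_individual(call, allele, mode,
                                                missing_policy)
                if verdict is False:
                    ok = False
                    break
        if ok:
            return True, label
    return False, None


def _is_polymorphic(calls_at_site: Mapping[str, str | float]) -> bool:
    for call in calls_at_site.values():
        if isinstance(call, float):
            if call > 0.0:
                return True
        elif "1" in call:
            return True
    return False


def shared_interval_scan(matrix: GenotypeMatrix,
                         candidate: GenomicInterval,
                         mode: str = "homozygous_ibd",
                         pool_fix_threshold: float = 0.95,
                         missing_policy: str = "strict") -> list[IbdInterval]:
    """Maximal case-concordant runs inside ``candidate``, longest first.

    Each run is reported as [position of first concordant site, position of
    last concordant site (its END for DUP records)], together with the
    nearest discordant site on either side.
    """
    case_ids = matrix.case_ids
    if not case_ids:
        raise ValueError("no case samples in matrix")
    idx = matrix.variants_in(candidate)
    sites = []
    for i in idx:
        calls = matrix.calls_at(i)
        if not _is_polymorphic(calls):
            continue
        concordant, _ = site_concordance(
            calls, case_ids, mode=mode, pool_fix_threshold=pool_fix_threshold,
            missing_policy=missing_policy,
        )
        sites.append((matrix.variants[i], concordant))
    intervals: list[IbdInterval] = []
    run: list[VariantRecord] = []
    left_disc: int | None = None
    for variant, concordant in sites + [(None, False)]:
        if concordant:
            run.append(variant)
            continue
        if run:
            intervals.append(
                IbdInterval(
                    interval=GenomicInterval(
                        candidate.chrom, run[0].pos,
                        max(v.end for v in run),
                    ),
                    n_support_sites=len(run),
                    flanking_discordant=(
                        left_disc, variant.pos if variant is not None else None
                    ),
                )
            )
            run = []
        if variant is not None:
            left_disc = variant.pos
    intervals.sort(key=lambda iv: (-iv.length, iv.interval.start))
    return intervals


def _carrier_fractions(matrix: GenotypeMatrix, i: int,
                       pool_fix_threshold: float) -> tuple[float, float]:
    calls = matrix.calls_at(i)
    kinds = {s.sample_id: s for s in matrix.samples}

    def carries(sid: str, case: bool) -> bool:
        call = calls[sid]
        if isinstance(call, float):
            return call >= pool_fix_threshold if case else call > 0.0
        return "1" in call

    cases = matrix.case_ids
    controls = matrix.control_ids
    case_frac = (
        sum(carries(s, True) for s in cases) / len(cases) if cases else 0.0
    )
    control_frac = (
        sum(carries(s, False) for s in controls) / len(controls)
        if controls else 0.0
    )
    return case_frac, control_frac


def shared_case_variants(matrix: GenotypeMatrix, interval: GenomicInterval,
                         pool_fix_threshold: float = 0.95) -> list[CandidateVariant]:
    """Variants inside ``interval`` whose alternate allele rides on every case.

    This is the 'sequence changes carried by the shared case haplotype'
    accounting, before any control-based filtering.
    """
    out = []
    for i in matrix.variants_in(interval):
        case_frac, control_frac = _carrier_fractions(matrix, i,
                                                     pool_fix_threshold)
        if case_frac == 1.0:
            out.append(CandidateVariant(matrix.variants[i], case_frac,
                                        control_frac))
    return out


def concordance_filter(matrix: GenotypeMatrix, interval: GenomicInterval,
                       pool_fix_threshold: float = 0.95) -> list[CandidateVariant]:
    """Variants in ``interval`` present in all cases and absent from all controls.

    Case pools must be effectively fixed (frequency >= threshold); control
    pools must show a frequency of exactly zero.
    """
    return [
        cv for cv in shared_case_variants(matrix, interval, pool_fix_threshold)
        if cv.control_carrier_fraction == 0.0
    ]


def write_intervals_bed(intervals: Sequence[IbdInterval],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end = to_zero_based(iv.interval)
            fh.write(f"{chrom}\t{start}\t{end}\tsupport={iv.n_support_sites}\n")
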