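"""Concordance logic, shared-interval scan vs brute force, candidate filter."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crestmap import locus
from crestmap.ibd_scan import (
    concordance_filter,
    shared_case_variants,
    shared_interval_scan,
    site_concordance,
)
from crestmap.io_formats import (
    GenomicInterval,
    GenotypeMatrix,
    SampleSheetRow,
    VariantRecord,
)


def toy_matrix(genotype_rows, case_flags, positions=None, pool_flags=None):
    """Build a GenotypeMatrix from per-site lists of calls."""
    n_samples = len(case_flags)
    pool_flags = pool_flags or [False] * n_samples
    positions = positions or [100 * (i + 1) for i in range(len(genotype_rows))]
    samples = [
        SampleSheetRow(
            f"s{j}", "b", "crested_large" if case_flags[j] else "non_crested",
            "pool" if pool_flags[j] else "individual",
        )
        for j in range(n_samples)
    ]
    variants = [
        VariantRecord(GenomicInterval("chr33", p, p), "SNV", "A", "T")
        for p in positions
    ]
    calls = pd.DataFrame(
        {s.sample_id: [row[j] for row in genotype_rows]
         for j, s in enumerate(samples)}
    )
    return GenotypeMatrix(variants=variants, samples=samples, calls=calls)


class TestSiteConcordance:
    def test_identical_homozygous_cases_concordant_for_alt(self):
        calls = {f"c{i}": "1/1" for i in range(5)}
        calls.update({"k0": "0/1", "k1": "0/0"})
        assert site_concordance(calls, [f"c{i}" for i in range(5)]) == \
               (True, "alt")

    def test_single_heterozygous_case_breaks_homozygous_mode(self):
        calls = {"c0": "1/1", "c1": "0/1"}
        concordant, _ = site_concordance(calls, ["c0", "c1"])
        assert not concordant

    def test_heterozygous_cases_pass_dominant_carrier_mode(self):
        calls = {"c0": "1/1", "c1": "0/1"}
        assert site_concordance(calls, ["c0", "c1"],
                                mode="dominant_carrier") == (True, "alt")

    def test_case_pool_above_fixation_threshold_counts(self):
        calls = {"c0": "1/1", "c1": "1/1", "p0": 0.97}
        assert site_concordance(calls, ["c0", "c1", "p0"],
                                pool_fix_threshold=0.95) == (True, "alt")
        calls["p0"] = 0.90
        assert site_concordance(calls, ["c0", "c1", "p0"])[0] is False

    def test_no_cases_is_an_error(self):
        with pytest.raises(ValueError, match="no case"):
            site_concordance({"s": "0/0"}, [])

    def test_missing_genotype_policy(self):
        calls = {"c0": "1/1", "c1": "./."}
        assert site_concordance(calls, ["c0", "c1"])[0] is False
        assert site_concordance(calls, ["c0", "c1"],
                                missing_policy="permissive") == (True, "alt")


def brute_force_scan(matrix, candidate, **kwargs):
    """Oracle: test every contiguous run of polymorphic sites exhaustively."""
    from crestmap.ibd_scan import _is_polymorphic

    case_ids = matrix.case_ids
    idx = [
        i for i in matrix.variants_in(candidate)
        if _is_polymorphic(matrix.calls_at(i))
    ]
    conc = [
        site_concordance(matrix.calls_at(i), case_ids, **kwargs)[0]
        for i in idx
    ]
    best = []
    for a in range(len(idx)):
        for b in range(a, len(idx)):
            if all(conc[a : b + 1]):
                maximal = (a == 0 or not conc[a - 1]) and (
                    b == len(idx) - 1 or not conc[b + 1]
                )
                if maximal:
                    best.append(
                        (matrix.variants[idx[a]].pos,
                         max(matrix.variants[idx[i]].end
                             for i in range(a, b + 1)),
                         b - a + 1)
                    )
    best.sort(key=lambda t: (-(t[1] - t[0] + 1), t[0]))
    return best


@st.composite
def small_matrices(draw):
    n_sites = draw(st.integers(1, 12))
    n_samples = draw(st.integers(1, 8))
    case_flags = draw(
        st.lists(st.booleans(), min_size=n_samples, max_size=n_samples)
    )
    if not any(case_flags):
        case_flags[0] = True
    rows = [
        draw(st.lists(st.sampled_from(["0/0", "0/1", "1/1"]),
                      min_size=n_samples, max_size=n_samples))
        for _ in range(n_sites)
    ]
    return toy_matrix(rows, case_flags)


class TestSharedIntervalScan:
    @given(matrix=small_matrices())
    def test_matches_exhaustive_oracle(self, matrix):
        candidate = GenomicInterval("chr33", 1, 10_000)
        got = [
            (iv.interval.start, iv.interval.end, iv.n_support_sites)
            for iv in shared_interval_scan(matrix, candidate)
        ]
        assert got == brute_force_scan(matrix, candidate)

    def test_all_discordant_yields_empty(self):
        matrix = toy_matrix(
            [["0/1", "0/0"], ["1/1", "0/1"]], [True, True]
        )
        assert shared_interval_scan(matrix,
                                    GenomicInterval("chr33", 1, 1000)) == []

    def test_recovers_printed_interval_on_default_cohort(self, wgs_cohort):
        intervals = shared_interval_scan(wgs_cohort.matrix,
                                         locus.CANDIDATE_REGION)
        top = intervals[0]
        assert (top.interval.start, top.interval.end) == (
            locus.IBD_START, locus.IBD_END
        )
        assert top.n_support_sites == 6
        assert top.flanking_discordant == (7_585_731, 7_587_942)

    def test_dup_end_extends_interval(self):
        samples = [SampleSheetRow("c0", "b", "crested_large")]
        variants = [
            VariantRecord(GenomicInterval("chr33", 100, 100), "SNV", "A", "T"),
            VariantRecord(GenomicInterval("chr33", 300, 300), "DUP", "A",
                          "<DUP>", dup_end=500),
        ]
        calls = pd.DataFrame({"c0": ["1/1", "1/1"]})
        matrix = GenotypeMatrix(variants=variants, samples=samples, calls=calls)
        [iv] = shared_interval_scan(matrix, GenomicInterval("chr33", 1, 1000))
        assert (iv.interval.start, iv.interval.end) == (100, 500)


class TestConcordanceFilter:
    def test_default_cohort_reduces_to_single_dup(self, wgs_cohort):
        interval = locus.IBD_INTERVAL
        shared = shared_case_variants(wgs_cohort.matrix, interval)
        assert len(shared) == 5
        candidates = concordance_filter(wgs_cohort.matrix, interval)
        assert len(candidates) == 1
        assert candidates[0].variant.vtype == "DUP"

    def test_variant_carried_by_one_control_excluded(self):
        matrix = toy_matrix([["1/1", "1/1", "0/1", "0/0"]],
                            [True, True, False, False])
        assert concordance_filter(matrix,
                                  GenomicInterval("chr33", 1, 1000)) == []

    def test_variant_carried_by_everyone_excluded(self):
        matrix = toy_matrix([["1/1", "1/1", "1/1", "1/1"]],
                            [True, True, False, False])
        assert concordance_filter(matrix,
                                  GenomicInterval("chr33", 1, 1000)) == []

    def test_control_pool_must_be_exactly_zero(self):
        matrix = toy_matrix([["1/1", "1/1", 0.05]], [True, True, False],
                            pool_flags=[False, False, True])
        assert concordance_filter(matrix,
                                  GenomicInterval("chr33", 1, 1000)) == []

    @given(matrix=small_matrices(),
           extra=st.lists(st.sampled_from(["0/0", "0/1", "1/1"]),
                          min_size=1, max_size=12))
    def test_adding_a_control_never_grows_candidates(self, matrix, extra):
        candidate = GenomicInterval("chr33", 1, 10_000)
        if len(extra) < len(matrix.variants):
            extra = extra * len(matrix.variants)
        before = {
            cv.variant.pos for cv in concordance_filter(matrix, candidate)
        }
        samples = matrix.samples + [
            SampleSheetRow("new_control", "b", "non_crested")
        ]
        calls = matrix.calls.copy()
        calls["new_control"] = extra[: len(matrix.variants)]
        bigger = GenotypeMatrix(variants=matrix.variants, samples=samples,
                                calls=calls)
        after = {
            cv.variant.pos for cv in concordance_filter(bigger, candidate)
        }
        assert after <= before

    def test_candidates_lie_inside_a_reported_interval(self, wgs_cohort):
        intervals = shared_interval_scan(wgs_cohort.matrix,
                                         locus.CANDIDATE_REGION)
        top = intervals[0]
        for cv in concordance_filter(wgs_cohort.matrix, top.interval):
            assert top.interval.contains(cv.variant.pos)
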