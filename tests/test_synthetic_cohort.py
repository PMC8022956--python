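"""Reference model, allele construction, cohort sampling, read simulation."""

import numpy as np
import pytest

import crestmap as cm
from crestmap import locus
from crestmap.io_formats import GenomicInterval
from crestmap.synthetic_cohort import (
    ALLELE_SPECS,
    AlleleSpec,
    CohortDesign,
    DesignRow,
    ReadParams,
    build_allele,
    build_reference,
    default_design,
    generate_cohort,
    simulate_alignments,
    tiny_design,
)


class TestReferenceModel:
    def test_unit_extraction_is_197_bp(self, reference):
        assert len(reference.unit_sequence) == 197

    def test_planted_snp_and_microsatellite(self, reference):
        assert reference.base(locus.SNP_POS) == "C"
        run = reference.subseq(locus.TG_POS, locus.TG_POS + 13)
        assert run == "TG" * 7
        # the run is maximal: neither side extends it
        assert reference.subseq(locus.TG_POS - 2, locus.TG_POS - 1) != "TG"
        assert reference.subseq(locus.TG_POS + 14, locus.TG_POS + 15) != "TG"

    def test_seeded_build_is_reproducible(self):
        assert build_reference(4).sequence == build_reference(4).sequence
        assert build_reference(4).sequence != build_reference(5).sequence

    def test_primer_spacing_gives_wild_type_amplicon(self, reference):
        span = (reference.primer_reverse_site.end
                - reference.primer_forward_site.start + 1)
        assert span == locus.WT_FRAGMENT

    def test_primers_and_long_tg_unique_near_unit(self, reference):
        seq = reference.sequence
        assert seq.count(locus.PRIMER_F) == 1
        window = reference.subseq(locus.DUP_START - 5000, locus.DUP_END + 5000)
        assert window.count("TG" * 6) == 1  # only the planted run

    def test_no_microhomology_across_planted_junction(self, reference):
        assert reference.base(locus.DUP_START - 1) != reference.base(locus.DUP_END)

    def test_unit_flanks_unique(self, reference):
        assert reference.sequence.count(reference.left_flank()) == 1
        assert reference.sequence.count(reference.right_flank()) == 1


class TestBuildAllele:
    def test_wild_type_is_reference_slice(self, reference, alleles):
        assert alleles["crWT"].sequence == reference.sequence

    @pytest.mark.parametrize("name,delta", [
        ("Cr1", 197), ("Cr2", 197), ("Cr3", 199), ("Cr2_backmutant", 0),
    ])
    def test_length_deltas(self, alleles, name, delta):
        assert alleles[name].length - alleles["crWT"].length == delta

    def test_cr3_minus_cr1_is_two_bp(self, alleles):
        assert alleles["Cr3"].length - alleles["Cr1"].length == 2

    def test_cr2_substitution_sits_in_three_prime_copy(self, reference, alleles):
        hap = alleles["Cr2"]
        positions = hap.hap_positions(locus.SNP_POS)
        assert len(positions) == 2  # one per copy
        five_p, three_p = sorted(positions)
        assert hap.sequence[five_p - 1] == "C"
        assert hap.sequence[three_p - 1] == "A"

    def test_coordinate_map_identity_outside_duplication(self, reference, alleles):
        hap = alleles["Cr1"]
        assert hap.hap_positions(7_550_000) == [7_550_000 - reference.interval.start + 1]
        # positions downstream of the unit shift by one unit length
        [down] = hap.hap_positions(locus.DUP_END + 100)
        assert down == (locus.DUP_END + 100 - reference.interval.start + 1
                        + locus.UNIT_LENGTH)

    def test_unknown_allele_name_rejected(self, reference):
        with pytest.raises(KeyError, match="unknown allele"):
            build_allele(reference, "Cr9")

    def test_background_snv_written_into_both_copies_when_inside_unit(
        self, reference
    ):
        pos = locus.DUP_START + 10
        ref_base = reference.base(pos)
        alt = "A" if ref_base != "A" else "G"
        hap = build_allele(reference, "Cr1", snvs={pos: alt})
        assert [hap.sequence[p - 1] for p in hap.hap_positions(pos)] == [alt, alt]


class TestGenerateCohort:
    def test_truth_contains_five_case_changes_in_ibd_interval(self, wgs_cohort):
        matrix = wgs_cohort.matrix
        case = matrix.case_ids
        changes = []
        for i in matrix.variants_in(locus.IBD_INTERVAL):
            calls = matrix.calls_at(i)
            carried = all(
                (calls[s] >= 0.95) if isinstance(calls[s], float)
                else "1" in calls[s]
                for s in case
            )
            if carried:
                changes.append(matrix.variants[i])
        assert len(changes) == 5
        assert sorted(v.pos for v in changes) == sorted(
            [*locus.IBD_SNV_POSITIONS, locus.DUP_START]
        )
        assert sum(v.vtype == "DUP" for v in changes) == 1

    def test_empty_design_gives_empty_outputs(self, reference):
        cohort = generate_cohort(reference, CohortDesign(rows=()), seed=1)
        assert cohort.matrix.shape == (0, 0)
        assert cohort.truth_variants == []

    def test_fixed_pool_has_alt_frequency_one_at_duplication(self, reference):
        design = CohortDesign(rows=(
            DesignRow("Silkie", "crested_small", 1, ("Cr1", "Cr1"), "pool",
                      pool_size=20),
            DesignRow("Other breeds", "non_crested", 2, ("crWT", "crWT")),
        ))
        cohort = generate_cohort(reference, design, seed=2)
        matrix = cohort.matrix
        [i] = [k for k, v in enumerate(matrix.variants) if v.vtype == "DUP"]
        pool_id = next(s.sample_id for s in cohort.sheet
                       if s.sample_kind == "pool")
        assert matrix.calls.iloc[i][pool_id] == 1.0

    def test_crested_bird_without_duplication_allele_rejected(self):
        with pytest.raises(ValueError, match="contradicts"):
            CohortDesign(rows=(
                DesignRow("Ameraucana", "crested_small", 1,
                          ("Cr2_backmutant", "Cr2_backmutant")),
            ))

    def test_matrix_agrees_with_built_haplotypes(self, reference):
        cohort = generate_cohort(reference, tiny_design(), seed=4)
        matrix = cohort.matrix
        for sid, (spec_a, spec_b) in cohort.haplotype_specs.items():
            hap_a, hap_b = cohort.haplotypes(sid)
            for i, var in enumerate(matrix.variants):
                gt = matrix.calls.iloc[i][sid]
                if var.vtype == "DUP":
                    expected = sum(
                        ALLELE_SPECS[s.allele].has_duplication
                        for s in (spec_a, spec_b)
                    )
                else:
                    expected = sum(
                        h.sequence[p - 1] == var.alt_allele
                        for h in (hap_a, hap_b)
                        for p in h.hap_positions(var.pos)[:1]
                    )
                assert gt.count("1") == expected, (sid, var.pos)

    def test_ibd_snvs_ride_on_a_minority_of_control_haplotypes(self, wgs_cohort):
        matrix = wgs_cohort.matrix
        controls = matrix.control_ids
        for pos in locus.IBD_SNV_POSITIONS:
            [i] = [k for k, v in enumerate(matrix.variants) if v.pos == pos]
            carriers = sum(
                "1" in matrix.calls.iloc[i][s] for s in controls
            )
            assert 0 < carriers < len(controls) / 2

    def test_boundary_marker_reference_in_all_cases(self, wgs_cohort):
        matrix = wgs_cohort.matrix
        [i] = [k for k, v in enumerate(matrix.variants)
               if v.pos == locus.IBD_START]
        for s in matrix.case_ids:
            call = matrix.calls.iloc[i][s]
            assert call == "0/0" if isinstance(call, str) else call == 0.0
        assert any(
            "1" in matrix.calls.iloc[i][s] for s in matrix.control_ids
            if isinstance(matrix.calls.iloc[i][s], str)
        )


class TestSimulateAlignments:
    WINDOW = GenomicInterval("chr33", 7_580_000, 7_595_000)

    def test_wild_type_has_no_split_reads(self, reference, alleles):
        from crestmap.sv_detect import collect_evidence

        pairs = simulate_alignments(
            reference, (alleles["crWT"], alleles["crWT"]),
            ReadParams(coverage=20), seed=1, region=self.WINDOW,
        )
        evidence = collect_evidence(pairs, self.WINDOW)
        assert not evidence.junctions
        assert not evidence.everted

    def test_junction_split_read_count_near_binomial_expectation(
        self, reference, alleles
    ):
        from crestmap.sv_detect import collect_evidence

        coverage, read_length, min_seg = 20, 100, 12
        pairs = simulate_alignments(
            reference, (alleles["Cr1"], alleles["Cr1"]),
            ReadParams(coverage=coverage), seed=1, region=self.WINDOW,
        )
        evidence = collect_evidence(pairs, self.WINDOW)
        [(junction, count)] = evidence.junctions.most_common(1)
        assert junction == (locus.DUP_START, locus.DUP_END)
        # reads starting within (read_length - 2*min_seg) of the junction
        # split into two reportable parts, on both haplotypes
        per_base_read_rate = coverage / (2 * read_length)  # per haplotype
        expected = 2 * per_base_read_rate * (read_length - 2 * min_seg + 1)
        assert abs(count - expected) <= 3 * np.sqrt(expected)

    def test_unit_depth_doubles_for_homozygote(self, reference, alleles):
        from crestmap.sv_detect import collect_evidence, depth_ratio

        ratios = []
        for seed in (1, 2, 3):
            pairs = simulate_alignments(
                reference, (alleles["Cr1"], alleles["Cr1"]),
                ReadParams(coverage=20), seed=seed, region=self.WINDOW,
            )
            evidence = collect_evidence(pairs, self.WINDOW)
            unit = GenomicInterval("chr33", locus.DUP_START, locus.DUP_END)
            ratios.append(depth_ratio(evidence, unit))
        assert abs(np.mean(ratios) - 2.0) <= 0.3  # 15%

    def test_error_free_reads_match_their_haplotype(self, reference, alleles):
        hap = alleles["Cr3"]
        pairs = simulate_alignments(
            reference, (hap, hap), ReadParams(coverage=2), seed=9,
            region=self.WINDOW,
        )
        assert pairs
        for pair in pairs:
            for aln in (pair.r1, pair.r2):
                assert aln.seq in hap.sequence

    def test_errors_introduced_at_requested_rate(self, reference, alleles):
        hap = alleles["crWT"]
        rate = 0.01
        pairs = simulate_alignments(
            reference, (hap, hap), ReadParams(coverage=10, error_rate=rate),
            seed=3, region=self.WINDOW,
        )
        mism = total = 0
        for pair in pairs:
            for aln in (pair.r1, pair.r2):
                true = hap.sequence  # compare against placement-free origin
                # plain-M reads only, compare to reference-of-origin bases
                if aln.cigar == (("M", 100),):
                    origin = reference.subseq(aln.pos, aln.pos + 99)
                    mism += sum(a != b for a, b in zip(aln.seq, origin))
                    total += 100
        assert total > 0
        observed = mism / total
        assert abs(observed - rate) <= 3 * np.sqrt(rate / total)

    def test_deterministic_per_seed(self, reference, alleles):
        a = simulate_alignments(reference, (alleles["Cr1"], alleles["crWT"]),
                                ReadParams(coverage=5), seed=6,
                                region=self.WINDOW)
        b = simulate_alignments(reference, (alleles["Cr1"], alleles["crWT"]),
                                ReadParams(coverage=5), seed=6,
                                region=self.WINDOW)
        assert [(p.r1.pos, p.r1.cigar) for p in a] == \
               [(p.r1.pos, p.r1.cigar) for p in b]

    def test_nonpositive_coverage_rejected(self, reference, alleles):
        with pytest.raises(ValueError, match="coverage"):
            simulate_alignments(reference, (alleles["crWT"], alleles["crWT"]),
                                ReadParams(coverage=0), seed=1)


class TestClassifierRoundTrip:
    def test_classify_of_built_allele_recovers_spec_over_seeds(self):
        from crestmap.allele_classify import classify_allele

        for seed in range(5):
            ref = build_reference(seed)
            for name in ALLELE_SPECS:
                hap = build_allele(ref, name)
                assert classify_allele(hap.sequence, ref).allele == name
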