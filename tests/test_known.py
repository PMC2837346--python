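"""Known-miRNA annotation: arm assignment, isomiRs, ratios, presence."""

import pytest

from mirkit.align import Hit
from mirkit.known import (
    KnownMiRNARecord,
    assign_tag,
    compute_arm_ratio,
    tally_presence,
)
from mirkit.tags import UniqueTag

# precursor: 5 nt flank, 20 nt mature arm, 10 nt loop, 20 nt star arm, 5 nt flank
PRE = "AAAAA" + "G" * 20 + "T" * 10 + "C" * 20 + "AAAAA"
REC = KnownMiRNARecord("mir-1", PRE, (5, 25), (35, 55))


def _tag(seq="X"):
    return UniqueTag(seq if seq != "X" else "G" * 20, 10, "lib")


class TestAssignTag:
    def test_exact_mature_has_zero_offsets(self):
        a = assign_tag(_tag(), Hit("mir-1", 5, 25, "+"), REC)
        assert a.region == "mature"
        assert (a.five_prime_offset, a.three_prime_offset) == (0, 0)

    def test_three_prime_shift_within_tolerance_is_mature_isomir(self):
        a = assign_tag(_tag(), Hit("mir-1", 5, 27, "+"), REC)
        assert a.region == "mature"
        assert (a.five_prime_offset, a.three_prime_offset) == (0, 2)

    def test_loop_centred_tag_is_hairpin_region(self):
        a = assign_tag(_tag(), Hit("mir-1", 24, 42, "+"), REC)
        assert a.region == "hairpin_region"

    def test_star_arm_assignment(self):
        a = assign_tag(_tag(), Hit("mir-1", 36, 55, "+"), REC)
        assert a.region == "star"
        assert (a.five_prime_offset, a.three_prime_offset) == (1, 0)

    def test_precursor_without_star_falls_to_hairpin_region(self):
        rec = KnownMiRNARecord("mir-2", PRE, (5, 25), None)
        a = assign_tag(_tag(), Hit("mir-2", 36, 55, "+"), rec)
        assert a.region == "hairpin_region"

    def test_offset_beyond_tolerance_is_hairpin_region(self):
        a = assign_tag(_tag(), Hit("mir-1", 5, 31, "+"), REC)  # 3' offset +6
        assert a.region == "hairpin_region"


class TestArmRatio:
    @pytest.mark.parametrize(
        "mature,star,ratio,cls",
        [
            (100, 100, 1.0, "equivalent"),
            (75, 100, 0.75, "equivalent"),       # lower bin edge inclusive
            (220, 100, 2.2, "equivalent"),       # upper bin edge inclusive
            (50, 100, 0.5, "star_dominant"),
            (74, 100, 0.74, "star_dominant"),
            (221, 100, 2.21, "mature_dominant"),
            (242000, 1, 242000.0, "mature_dominant"),
        ],
    )
    def test_bins(self, mature, star, ratio, cls):
        r = compute_arm_ratio("m", mature, star)
        assert r.ratio == pytest.approx(ratio)
        assert r.ratio_class == cls

    def test_zero_star_count_is_undefined_without_pseudocount(self):
        r = compute_arm_ratio("m", 10, 0)
        assert r.ratio is None and r.ratio_class == "undefined"

    def test_both_zero_is_undefined(self):
        assert compute_arm_ratio("m", 0, 0).ratio_class == "undefined"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_arm_ratio("m", -1, 5)


class TestPresence:
    def test_single_library_sets_coincide(self):
        t = tally_presence({"L1": {"a": 3, "b": 0, "c": 1}})
        assert t.common_to_all == {"a", "c"}
        assert t.unique_to_one == {"a", "c"}

    def test_three_libraries_sharing_two(self):
        t = tally_presence({
            "L1": {"a": 1, "b": 1, "x": 1},
            "L2": {"a": 2, "b": 1},
            "L3": {"a": 1, "b": 9, "y": 4},
        })
        assert t.common_to_all == {"a", "b"}
        assert t.unique_to_one == {"x", "y"}

    def test_no_library_is_an_error(self):
        with pytest.raises(ValueError):
            tally_presence({})


class TestStudyRecovery:
    def test_counts_conserved_per_precursor(self, study):
        """mature + star + hairpin counts equal all tag counts hitting it."""
        for lib, buckets in study.buckets.items():
            expected = {}
            tag_by_seq = {t.sequence: t for t in study.tags[lib]}
            for seq, hits in buckets.known_hits.items():
                for h in hits:
                    expected[h.ref_name] = (
                        expected.get(h.ref_name, 0) + tag_by_seq[seq].count
                    )
            for mir_id, rec in study.known_records.items():
                got = (
                    rec.mature_counts.get(lib, 0)
                    + rec.star_counts.get(lib, 0)
                    + rec.hairpin_counts.get(lib, 0)
                )
                assert got == expected.get(mir_id, 0)

    def test_configured_arm_ratio_classes_recovered(self, study, study_configs):
        """>= 95% of known loci with both arms well covered get the right class."""
        from mirkit.known import compute_arm_ratio

        cfg = study_configs[0]
        checked = correct = 0
        for mir_id, rec in study.known_records.items():
            r = cfg.arm_ratio[mir_id]
            expected_total = sum(
                t.expected_counts.get(mir_id, 0.0)
                for t in study.ground_truth.values()
            )
            exp_mature = expected_total * r / (1 + r)
            exp_star = expected_total / (1 + r)
            if min(exp_mature, exp_star) < 50:
                continue
            checked += 1
            expected_cls = compute_arm_ratio(mir_id, exp_mature, exp_star).ratio_class
            got = study.arm_ratios[mir_id].ratio_class
            correct += got == expected_cls
        assert checked >= 3
        assert correct >= 0.95 * checked

    def test_isomir_three_prime_mass_exceeds_five_prime(self, study):
        """Recovered isomiR spectra show the configured 3' > 5' heterogeneity."""
        three = five = 0
        for isomirs in study.isomirs.values():
            for iso in isomirs:
                if iso.three_prime_offset != 0:
                    three += iso.count
                if iso.five_prime_offset != 0:
                    five += iso.count
        assert three > five > 0
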