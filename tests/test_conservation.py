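"""Contact mapping, scoring regions and conservation factors."""

import math

import pytest

from agerank.config import LogisticParams
from agerank.conservation import (
    AlignedFamily,
    BindingSiteContacts,
    ContactMappingError,
    DomainAnnotation,
    SpeciesAbsentError,
    binding_site_conservation,
    contacts_to_columns,
    domain_conservation,
    global_identity,
    scoring_regions,
    select_homologue,
    site_identity,
)
from agerank.grantham import EmptyRegionError

YH_SIM = 1 - 83 / 215  # conservative Tyr<->His substitution


def contacts(positions, structure="S1", het="AAA"):
    return BindingSiteContacts(structure, het, list(positions))


def flat_family(ref: str, others: dict[str, tuple[str, str]]) -> AlignedFamily:
    seqs = {"REF": ref}
    species = {"REF": "hsapiens"}
    for member, (seq, sp) in others.items():
        seqs[member] = seq
        species[member] = sp
    return AlignedFamily("F", "REF", seqs, species)


class TestContactsToColumns:
    def test_gap_shifts_columns(self, toy_family):
        # residue 3 (D) of the reference sits right of the gap, column 4
        assert contacts_to_columns(toy_family, contacts([3])) == {4}

    def test_gapless_is_identity(self):
        fam = flat_family("ACDEF", {"M": ("ACDEF", "celegans")})
        assert contacts_to_columns(fam, contacts([1, 5])) == {1, 5}

    def test_empty_contacts(self, toy_family):
        assert contacts_to_columns(toy_family, contacts([])) == set()

    def test_position_beyond_reference_raises(self, toy_family):
        with pytest.raises(ContactMappingError):
            contacts_to_columns(toy_family, contacts([10]))  # ref has 9 residues


class TestScoringRegions:
    def test_contacts_inside_domain_take_whole_domain(self):
        regions = scoring_regions(
            contacts([10, 20]), DomainAnnotation([(1, 100)]), seq_length=300
        )
        assert regions == [(1, 100)]

    def test_orphan_contact_gets_window(self):
        regions = scoring_regions(
            contacts([200]), DomainAnnotation([]), seq_length=300
        )
        assert regions == [(150, 250)]

    def test_window_clipped_at_bounds(self):
        regions = scoring_regions(
            contacts([10]), DomainAnnotation([]), seq_length=30
        )
        assert regions == [(1, 30)]

    def test_domain_and_window_union(self):
        regions = scoring_regions(
            contacts([30, 400]), DomainAnnotation([(1, 50)]), seq_length=500
        )
        assert regions == [(1, 50), (350, 450)]

    def test_adjacent_intervals_merge(self):
        regions = scoring_regions(
            contacts([51, 160]), DomainAnnotation([(1, 100), (101, 200)]),
            seq_length=300,
        )
        assert regions == [(1, 200)]

    def test_idempotent_and_order_invariant(self):
        doms = DomainAnnotation([(40, 90)])
        a = scoring_regions(contacts([50, 200, 310]), doms, seq_length=400)
        b = scoring_regions(contacts([310, 50, 200]), doms, seq_length=400)
        assert a == b
        # regions are already disjoint and sorted
        assert all(a[i][1] + 1 < a[i + 1][0] for i in range(len(a) - 1))

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            scoring_regions(contacts([5]), DomainAnnotation([]), 100, window=-1)


class TestDomainConservation:
    def test_identical_member_hits_logistic_ceiling(self):
        fam = flat_family("A" * 40, {"M": ("A" * 40, "celegans")})
        value = domain_conservation(fam, "M", [(1, 40)])
        assert value == pytest.approx(1 / (1 + math.exp(-4)), abs=1e-12)

    def test_all_gap_member_hits_logistic_floor(self):
        fam = flat_family("A" * 40, {"M": ("-" * 40, "celegans")})
        value = domain_conservation(fam, "M", [(1, 40)])
        assert value == pytest.approx(1 / (1 + math.exp(6)), abs=1e-12)

    def test_midpoint_parameters(self):
        # one Y->H change among few residues; value must follow the
        # logistic of the exact region similarity
        fam = flat_family("YAAA", {"M": ("HAAA", "celegans")})
        sim = (YH_SIM + 3) / 4
        value = domain_conservation(fam, "M", [(1, 4)])
        assert value == pytest.approx(
            1 / (1 + math.exp(-(sim - 0.6) / 0.1)), abs=1e-12
        )

    def test_monotone_in_region_similarity(self):
        better = flat_family("Y" * 10, {"M": ("Y" * 9 + "H", "celegans")})
        worse = flat_family("Y" * 10, {"M": ("H" * 10, "celegans")})
        assert domain_conservation(better, "M", [(1, 10)]) > domain_conservation(
            worse, "M", [(1, 10)]
        )

    def test_empty_regions_raise(self):
        fam = flat_family("AAAA", {"M": ("AAAA", "celegans")})
        with pytest.raises(EmptyRegionError):
            domain_conservation(fam, "M", [])


class TestBindingSiteConservation:
    def test_fully_conserved_site(self):
        fam = flat_family("ACDEFGHIKL", {"M": ("ACDEFGHIKL", "celegans")})
        assert binding_site_conservation(fam, "M", range(1, 11)) == 1.0

    def test_lowest_half_average(self):
        # 4 site columns: two identical (sim 1), one Y->H, one F->Y
        fam = flat_family("AYFA", {"M": ("AHYA", "celegans")})
        fy = 1 - 22 / 215
        expected = (YH_SIM + fy) / 2  # k = 2 lowest of [yh, fy, 1, 1]
        assert binding_site_conservation(fam, "M", [1, 2, 3, 4]) == pytest.approx(
            expected, abs=1e-12
        )

    def test_eleven_residue_site_single_change(self):
        """One conservative Y->H change in an 11-residue site gives ~0.92,
        the value reported for the dorsomorphin site in the worm."""
        ref = "Y" + "A" * 10
        fam = flat_family(ref, {"M": ("H" + "A" * 10, "celegans")})
        value = binding_site_conservation(fam, "M", range(1, 12))
        assert value == pytest.approx((YH_SIM + 4) / 5, abs=1e-12)
        assert round(value, 2) == 0.92

    def test_single_residue_site_uses_k_one(self):
        fam = flat_family("Y", {"M": ("H", "celegans")})
        assert binding_site_conservation(fam, "M", [1]) == pytest.approx(YH_SIM)

    def test_ceil_rounding_mode(self):
        ref = "YYA"
        fam = flat_family(ref, {"M": ("HHA", "celegans")})
        floor_v = binding_site_conservation(fam, "M", [1, 2, 3], k_rounding="floor")
        ceil_v = binding_site_conservation(fam, "M", [1, 2, 3], k_rounding="ceil")
        assert floor_v == pytest.approx(YH_SIM)
        assert ceil_v == pytest.approx(YH_SIM)  # mean of two equal lows

    def test_never_exceeds_full_site_mean(self):
        from agerank.conservation import site_similarities
        fam = flat_family("YAFKDE", {"M": ("HGYKDA", "celegans")})
        cols = range(1, 7)
        sims = site_similarities(fam, "M", cols)
        assert binding_site_conservation(fam, "M", cols) <= sum(sims) / len(sims)

    def test_empty_site_raises(self):
        fam = flat_family("AAAA", {"M": ("AAAA", "celegans")})
        with pytest.raises(EmptyRegionError):
            binding_site_conservation(fam, "M", [])


class TestSelectHomologue:
    def test_fewest_site_gaps_wins(self, toy_family):
        cols = contacts_to_columns(toy_family, contacts([4, 5]))  # E, F
        # WORM2 has a gap at the F column
        assert select_homologue(toy_family, "celegans", cols) == "WORM1"

    def test_similarity_breaks_gap_ties(self):
        fam = flat_family(
            "YYYY",
            {"M1": ("HHHH", "celegans"), "M2": ("YHHH", "celegans")},
        )
        assert select_homologue(fam, "celegans", [1, 2, 3, 4]) == "M2"

    def test_lexicographic_last_resort(self):
        fam = flat_family(
            "YYYY",
            {"B": ("YYYY", "celegans"), "A": ("YYYY", "celegans")},
        )
        assert select_homologue(fam, "celegans", [1, 2]) == "A"

    def test_single_member(self, toy_family):
        cols = contacts_to_columns(toy_family, contacts([1, 2]))
        assert select_homologue(toy_family, "dmelanogaster", cols) == "FLY1"

    def test_absent_species_raises(self, toy_family):
        with pytest.raises(SpeciesAbsentError):
            select_homologue(toy_family, "rnorvegicus", {1})

    def test_input_order_invariance(self):
        members = {
            f"M{i}": ("YHYH" if i % 2 else "YYHH", "celegans") for i in range(6)
        }
        fam1 = flat_family("YYYY", members)
        fam2 = flat_family("YYYY", dict(reversed(list(members.items()))))
        cols = [1, 2, 3, 4]
        assert select_homologue(fam1, "celegans", cols) == select_homologue(
            fam2, "celegans", cols
        )


class TestIdentityPercents:
    def test_identical_member_is_100(self):
        fam = flat_family("ACDEF", {"M": ("ACDEF", "celegans")})
        assert global_identity(fam, "M") == 100
        assert site_identity(fam, "M", [1, 2, 3]) == 100

    def test_one_mismatch_in_ten_site_columns(self):
        fam = flat_family("A" * 10, {"M": ("A" * 9 + "C", "celegans")})
        assert site_identity(fam, "M", range(1, 11)) == 90

    def test_reference_gaps_excluded_from_global(self, toy_family):
        # reference has 9 residues; WORM1 matches all of them
        assert global_identity(toy_family, "WORM1") == 100
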