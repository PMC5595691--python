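"""Factor transforms, losses, bonuses and the composite score."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agerank.config import RankingConfig
from agerank.scoring import (
    CompoundRecord,
    EvidenceAnnotation,
    FactorSet,
    ScoreBreakdown,
    affinity_factor,
    aggregate_targets,
    aging_implication,
    approval_bonus,
    bioavailability_factor,
    composite_score,
    go_evidence_score,
    lipinski_loss,
    lipinski_violations,
    log_affinity_from_kd,
    logistic,
    promiscuity_loss,
    purchase_bonus,
    tailored_score,
)

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestLogistic:
    @pytest.mark.parametrize(
        "x,l,s,expected",
        [
            (0.6, 0.6, 0.1, 0.5),
            (7.0, 7.0, 1.0, 0.5),
            (7.0, 5.0, 1.0, 1 / (1 + math.exp(-2))),
            (1.0, 0.6, 0.1, 1 / (1 + math.exp(-4))),
        ],
    )
    def test_values(self, x, l, s, expected):
        assert logistic(x, l, s) == pytest.approx(expected, abs=1e-12)

    def test_strictly_increasing(self):
        xs = [logistic(x / 10, 0.6, 0.1) for x in range(11)]
        assert all(a < b for a, b in zip(xs, xs[1:]))

    @pytest.mark.parametrize("s", [0.0, -1.0])
    def test_nonpositive_scale_rejected(self, s):
        with pytest.raises(ValueError):
            logistic(1.0, 0.0, s)

    def test_extreme_arguments_saturate(self):
        assert logistic(-1e6, 0.0, 1.0) == 0.0
        assert logistic(1e6, 0.0, 1.0) == 1.0


class TestEvidence:
    @pytest.mark.parametrize(
        "category,via,expected",
        [
            ("experimental", False, 0.01),
            ("experimental", True, 0.02),
            ("computational", False, 0.15),
            ("computational", True, 0.16),
            ("author_curator", False, 0.16),
            ("author_curator", True, 0.16),
            ("automatic_or_none", False, 0.28),
            ("automatic_or_none", True, 0.29),
        ],
    )
    def test_category_scores(self, category, via, expected):
        ann = EvidenceAnnotation("P1", category=category, via_orthologue=via)
        assert go_evidence_score(ann) == expected

    def test_genage_forces_strongest_score(self):
        ann = EvidenceAnnotation(
            "P1", category="automatic_or_none", via_orthologue=True, genage=True
        )
        assert go_evidence_score(ann) == 0.01

    def test_invalid_category_rejected(self):
        with pytest.raises(ValueError):
            EvidenceAnnotation("P1", category="hearsay")


class TestAgingImplication:
    @pytest.mark.parametrize(
        "ev,m,expected",
        [(0.0, 0, 1.0), (0.01, 0, 0.995), (0.01, 1, 0.945), (0.28, 2, 0.76)],
    )
    def test_default_reading(self, ev, m, expected):
        assert aging_implication(ev, m) == pytest.approx(expected, abs=1e-12)

    def test_alternative_reading(self):
        cfg = RankingConfig(aging_formula="half_mappings")
        assert aging_implication(0.01, 1, cfg) == pytest.approx(1 - 0.01 - 0.05)

    def test_floored_at_zero(self):
        assert aging_implication(1.0, 50) == 0.0


class TestAffinity:
    @pytest.mark.parametrize(
        "kd_nm,cell",
        [(100, 0.88), (23, 0.93), (35, 0.92), (63, 0.9), (120, 0.87)],
    )
    def test_reported_affinity_cells(self, kd_nm, cell):
        """The five nanomolar affinities quoted for the top compounds must
        reproduce their two-decimal table cells."""
        factor = affinity_factor(log_affinity_from_kd(kd_nm * 1e-9))
        assert round(factor, 2) == cell

    def test_closed_form_millimolar(self):
        assert affinity_factor(log_affinity_from_kd(1e-3)) == pytest.approx(
            1 / (1 + math.exp(2)), abs=1e-12
        )

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            log_affinity_from_kd(0.0)

    def test_decreasing_in_kd(self):
        kds = [1e-9, 1e-8, 1e-7, 1e-6, 1e-3]
        vals = [affinity_factor(log_affinity_from_kd(k)) for k in kds]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestBioavailability:
    def test_fly_constant(self):
        assert bioavailability_factor("dmelanogaster") == 0.9

    def test_worm_midpoint(self):
        assert bioavailability_factor("celegans", burns_score=4.0) == pytest.approx(
            0.6
        )

    def test_worm_saturates_at_one(self):
        assert bioavailability_factor("celegans", burns_score=1e4) == pytest.approx(
            1.0
        )

    def test_worm_floor_is_point_two(self):
        assert bioavailability_factor("celegans", burns_score=-1e4) == pytest.approx(
            0.2
        )

    def test_missing_predictor_score_raises(self):
        with pytest.raises(ValueError):
            bioavailability_factor("celegans")


class TestLipinskiAndTerms:
    @pytest.mark.parametrize(
        "descr,expected",
        [
            ((400, 3, 2, 5), 0),
            ((600, 6, 6, 11), 4),
            ((500, 5, 5, 10), 1),  # only the MW rule fires at the boundary
        ],
    )
    def test_violation_count(self, descr, expected):
        assert lipinski_violations(*descr) == expected

    @pytest.mark.parametrize("n,expected", [(0, 0.0), (2, -0.1), (3, -0.15)])
    def test_lipinski_loss(self, n, expected):
        assert lipinski_loss(n) == pytest.approx(expected)

    def test_promiscuity_loss(self):
        assert promiscuity_loss(7) == pytest.approx(-0.1)
        assert promiscuity_loss(1) == pytest.approx(
            -logistic(1, 7, 1) / 5, abs=1e-15
        )
        assert promiscuity_loss(10**6) == pytest.approx(-0.2)

    def test_bonuses(self):
        assert purchase_bonus(True) == 0.1
        assert purchase_bonus(False) == 0.0
        assert approval_bonus("chembl_drug") == 0.1
        assert approval_bonus("drugbank_only") == 0.075
        assert approval_bonus("none") == 0.0
        with pytest.raises(ValueError):
            approval_bonus("fda")

    def test_compound_record_violations_fallback(self):
        rec = CompoundRecord("AAA", lipinski_descriptors=(600, 6, 6, 11))
        assert rec.violation_count() == 4
        rec2 = CompoundRecord("BBB", lipinski_violations=2)
        assert rec2.violation_count() == 2
        with pytest.raises(ValueError):
            CompoundRecord("CCC").violation_count()


class TestAggregation:
    def test_single_target_unchanged(self):
        assert aggregate_targets([(0.9, 0.8, 0.7)]) == (0.9, 0.8, 0.7)

    def test_elementwise_max_and_commutativity(self):
        a = [(0.9, 0.8, 0.7), (0.8, 0.9, 0.9)]
        assert aggregate_targets(a) == (0.9, 0.9, 0.9)
        assert aggregate_targets(list(reversed(a))) == (0.9, 0.9, 0.9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_targets([])


class TestComposite:
    def test_top_fly_compound_clips_to_one(self):
        """A perfect kinase inhibitor row: product 0.8208 plus both
        bonuses exceeds 1 and clips."""
        bd = composite_score(
            FactorSet(1.0, 0.96, 1.0, 0.95, 0.9), purchase=0.1, approval=0.1
        )
        assert bd.final == 1.0

    def test_mid_table_worm_compound(self):
        bd = composite_score(
            FactorSet(1.0, 0.95, 0.95, 0.93, 0.81), purchase=0.1, approval=0.08
        )
        assert round(bd.final, 2) == 0.86

    def test_neutral_inputs(self):
        assert composite_score(FactorSet(1, 1, 1, 1, 1)).final == 1.0

    def test_out_of_range_factor_rejected(self):
        with pytest.raises(ValueError):
            FactorSet(1.2, 1, 1, 1, 1)
        with pytest.raises(ValueError):
            composite_score(FactorSet(1, 1, 1, 1, 1), lipinski=0.1)

    def test_serialization_round_trip_preserves_final(self):
        bd = composite_score(
            FactorSet(0.995, 0.97, 0.92, 0.88, 0.6),
            lipinski=-0.05,
            promiscuity=promiscuity_loss(2),
            purchase=0.1,
            approval=0.075,
        )
        restored = ScoreBreakdown.from_dict(bd.to_dict())
        assert restored == bd
        recomputed = composite_score(
            restored.factors,
            restored.lipinski_loss,
            restored.promiscuity_loss,
            restored.purchase_bonus,
            restored.approval_bonus,
        )
        assert recomputed.final == bd.final

    @given(
        factors=st.tuples(unit, unit, unit, unit, unit),
        lip=st.integers(min_value=0, max_value=4),
        n_targets=st.integers(min_value=0, max_value=200),
        buy=st.booleans(),
        appr=st.sampled_from(["chembl_drug", "drugbank_only", "none"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_final_always_in_unit_interval(self, factors, lip, n_targets, buy, appr):
        bd = composite_score(
            FactorSet(*factors),
            lipinski=lipinski_loss(lip),
            promiscuity=promiscuity_loss(n_targets),
            purchase=purchase_bonus(buy),
            approval=approval_bonus(appr),
        )
        assert 0.0 <= bd.final <= 1.0

    @given(
        factors=st.tuples(unit, unit, unit, unit, unit),
        idx=st.integers(min_value=0, max_value=4),
        bump=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_each_factor(self, factors, idx, bump):
        raised = list(factors)
        raised[idx] = min(1.0, raised[idx] + bump)
        low = composite_score(FactorSet(*factors), lipinski=-0.1)
        high = composite_score(FactorSet(*raised), lipinski=-0.1)
        assert high.final >= low.final


class TestTailoredScore:
    def _bd(self):
        return composite_score(
            FactorSet(0.9, 0.95, 0.92, 0.88, 0.6),
            lipinski=-0.05,
            promiscuity=-0.01,
            purchase=0.1,
            approval=0.075,
        )

    def test_unit_weights_reproduce_composite(self):
        bd = self._bd()
        assert tailored_score(bd) == bd.final

    def test_zero_weight_excludes_factor(self):
        bd = self._bd()
        excl = tailored_score(bd, factor_weights={"bioavailability": 0.0})
        neutral = composite_score(
            FactorSet(0.9, 0.95, 0.92, 0.88, 1.0),
            lipinski=-0.05,
            promiscuity=-0.01,
            purchase=0.1,
            approval=0.075,
        )
        assert excl == pytest.approx(neutral.final, abs=1e-12)

    def test_all_zero_weights_clip_to_one(self):
        bd = self._bd()
        value = tailored_score(
            bd,
            factor_weights={k: 0.0 for k in ("aging", "domain_cons", "site_cons", "affinity", "bioavailability")},
            term_weights={k: 0.0 for k in ("lipinski_loss", "promiscuity_loss", "purchase_bonus", "approval_bonus")},
        )
        assert value == 1.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            tailored_score(self._bd(), factor_weights={"aging": -1.0})
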