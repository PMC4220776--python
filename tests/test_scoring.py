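"""FACT-G scoring, rescaling, tariff evaluation and descriptive statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from utilmap.scoring import (
    DEFAULT_REVERSED_ITEMS,
    DOMAIN_ITEMS,
    DOMAIN_MAX,
    ITEM_CODES,
    AggregateTerm,
    DomainScores,
    HealthStateProfile,
    ItemResponseSet,
    TariffSpec,
    apply_tariff,
    describe_scores,
    inverse_rescale,
    load_tariff,
    rescale_scores,
    score_factg,
)

ALL_DIRECT = frozenset()


def make_items(value=0, reversed_items=ALL_DIRECT, skip=()):
    responses = {c: value for c in ITEM_CODES if c not in skip}
    return ItemResponseSet("p1", responses, reversed_items=reversed_items)


class TestScoreFactg:
    def test_floor_case_all_zero_direct(self):
        scores = score_factg(make_items(0))
        assert scores.pwb == scores.swb == scores.ewb == scores.fwb == 0
        assert scores.global_score == 0

    def test_reversed_pwb_items_contribute_four_minus_response(self):
        items = make_items(0, reversed_items=frozenset(DOMAIN_ITEMS["pwb"]))
        assert score_factg(items).pwb == 28  # (4 - 0) x 7

    def test_proration_scales_answered_sum(self):
        # 6 of 7 PWB items answered with reversed contributions summing to 18
        responses = {c: 0 for c in ITEM_CODES}
        contribs = [4, 4, 4, 3, 3, 0]
        for code, contrib in zip(DOMAIN_ITEMS["pwb"][:6], contribs):
            responses[code] = 4 - contrib
        del responses["GP7"]
        items = ItemResponseSet(
            "p1", responses, reversed_items=frozenset(DOMAIN_ITEMS["pwb"])
        )
        assert score_factg(items).pwb == pytest.approx(18 * 7 / 6)  # = 21

    def test_domain_invalid_when_half_or_fewer_answered(self):
        # 3 of 7 FWB answered (< majority) -> invalid; global also invalid
        skip = DOMAIN_ITEMS["fwb"][3:]
        scores = score_factg(make_items(2, skip=skip))
        assert math.isnan(scores.fwb)
        assert math.isnan(scores.global_score)

    def test_global_needs_80pct_of_all_items(self):
        # drop 3 items from each of PWB/SWB (domains stay valid: 4/7 answered)
        skip = DOMAIN_ITEMS["pwb"][:3] + DOMAIN_ITEMS["swb"][:3]
        scores = score_factg(make_items(2, skip=skip))
        assert not math.isnan(scores.pwb) and not math.isnan(scores.swb)
        assert math.isnan(scores.global_score)  # 21/27 < 80%

    @pytest.mark.parametrize("bad", [-1, 5, 2.5])
    def test_out_of_range_response_rejected(self, bad):
        with pytest.raises(ValueError):
            ItemResponseSet("p1", {"GP1": bad})

    def test_unknown_item_code_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ItemResponseSet("p1", {"XX1": 1})

    @given(
        st.lists(st.integers(min_value=0, max_value=4), min_size=27, max_size=27)
    )
    @settings(max_examples=50, deadline=None)
    def test_complete_direct_scoring_is_plain_sum(self, values):
        responses = dict(zip(ITEM_CODES, values))
        scores = score_factg(ItemResponseSet("p", responses, ALL_DIRECT))
        for domain, codes in DOMAIN_ITEMS.items():
            assert getattr(scores, domain) == sum(responses[c] for c in codes)
        assert scores.global_score == sum(values)


class TestRescale:
    def test_endpoints(self):
        zero = DomainScores(0, 0, 0, 0, 0)
        full = DomainScores(28, 28, 24, 28, 108)
        assert rescale_scores(zero)["global"] == 0
        assert rescale_scores(full)["global"] == 100
        assert all(v == 100 for v in rescale_scores(full).values())

    def test_study_mean_global(self):
        ds = DomainScores(
            math.nan, math.nan, math.nan, math.nan, 78.87
        )
        assert rescale_scores(ds)["global"] == pytest.approx(73.03, abs=0.005)

    def test_ewb_midpoint(self):
        ds = DomainScores(math.nan, math.nan, 12, math.nan, math.nan)
        assert rescale_scores(ds)["ewb"] == 50.0

    def test_raw_above_maximum_rejected(self):
        with pytest.raises(ValueError):
            DomainScores(29, 0, 0, 0, math.nan)

    @given(
        pwb=st.integers(0, 28), swb=st.integers(0, 28),
        ewb=st.integers(0, 24), fwb=st.integers(0, 28),
    )
    @settings(max_examples=50, deadline=None)
    def test_rescale_inverse_roundtrip(self, pwb, swb, ewb, fwb):
        ds = DomainScores(pwb, swb, ewb, fwb, pwb + swb + ewb + fwb)
        back = inverse_rescale(rescale_scores(ds))
        for name in ("pwb", "swb", "ewb", "fwb", "global_score"):
            assert getattr(back, name) == pytest.approx(
                getattr(ds, name), abs=1e-12
            )

    def test_global_must_equal_domain_sum(self):
        with pytest.raises(ValueError, match="sum"):
            DomainScores(10, 10, 10, 10, 50)


TOY_TARIFF = TariffSpec(
    name="toy",
    dimensions=("a", "b"),
    level_counts=(3, 3),
    decrements=((0.0, 0.1, 0.3), (0.0, 0.1, 0.3)),
)


class TestTariff:
    def test_all_ones_profile_yields_intercept(self):
        profile = HealthStateProfile("custom", (1, 1), level_counts=(3, 3))
        assert apply_tariff(profile, TOY_TARIFF) == 1.0

    def test_hand_sum(self):
        profile = HealthStateProfile("custom", (2, 3), level_counts=(3, 3))
        assert apply_tariff(profile, TOY_TARIFF) == pytest.approx(0.6)

    def test_aggregate_term_subtracted(self):
        tariff = TariffSpec(
            name="toy+",
            dimensions=("a", "b"),
            level_counts=(3, 3),
            decrements=((0.0, 0.1, 0.3), (0.0, 0.1, 0.3)),
            aggregate_terms=(AggregateTerm("any_at_worst", 0.05),),
        )
        profile = HealthStateProfile("custom", (2, 3), level_counts=(3, 3))
        assert apply_tariff(profile, tariff) == pytest.approx(0.55)

    def test_dimension_mismatch_rejected(self):
        profile = HealthStateProfile("custom", (1, 1, 1), level_counts=(3, 3, 3))
        with pytest.raises(ValueError, match="level counts"):
            apply_tariff(profile, TOY_TARIFF)

    def test_out_of_range_result_warns_not_errors(self):
        tariff = TariffSpec(
            name="tight", dimensions=("a",), level_counts=(2,),
            decrements=((0.0, 0.9),), utility_range=(0.5, 1.0),
        )
        profile = HealthStateProfile("custom", (2,), level_counts=(2,))
        with pytest.warns(UserWarning, match="outside declared range"):
            assert apply_tariff(profile, tariff) == pytest.approx(0.1)

    def test_eq5d_enumeration_has_243_distinct_states(self):
        counts = (3, 3, 3, 3, 3)
        tariff = TariffSpec(
            name="eq5d-toy",
            dimensions=tuple("mobility selfcare usual pain anxiety".split()),
            level_counts=counts,
            decrements=tuple((0.0, 0.05 * (d + 1), 0.11 * (d + 1))
                             for d in range(5)),
        )
        utilities = set()
        for levels in itertools.product(*(range(1, c + 1) for c in counts)):
            profile = HealthStateProfile("EQ5D3L", levels)
            utilities.add(round(apply_tariff(profile, tariff), 10))
        assert len(utilities) > 1
        n_states = len(
            list(itertools.product(*(range(1, c + 1) for c in counts)))
        )
        assert n_states == 243

    def test_sf6d_state_space_is_product_of_level_counts(self):
        from utilmap.scoring import INSTRUMENT_LEVELS

        counts = INSTRUMENT_LEVELS["SF6D"]
        assert int(np.prod(counts)) == 18000
        # boundary profiles validate without error
        HealthStateProfile("SF6D", tuple(counts))
        HealthStateProfile("SF6D", (1,) * 6)
        with pytest.raises(ValueError):
            HealthStateProfile("SF6D", (7, 1, 1, 1, 1, 1))

    def test_level1_decrement_must_be_zero(self):
        with pytest.raises(ValueError, match="level-1"):
            TariffSpec("bad", ("a",), (2,), ((0.1, 0.2),))

    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        cfg = {
            "name": "toy",
            "dimensions": ["a", "b"],
            "level_counts": [3, 3],
            "decrements": [[0.0, 0.1, 0.3], [0.0, 0.1, 0.3]],
            "aggregate_terms": [{"kind": "any_at_worst", "coefficient": 0.05}],
        }
        path = tmp_path / "tariff.yaml"
        path.write_text(yaml.safe_dump(cfg))
        tariff = load_tariff(path)
        profile = HealthStateProfile("custom", (2, 3), level_counts=(3, 3))
        assert apply_tariff(profile, tariff) == pytest.approx(0.55)


class TestDescribeScores:
    def test_ceiling_share(self):
        out = describe_scores([1.0, 1.0, 0.8, 0.6], maximum=1.0)
        assert out["ceiling_pct"] == 50.0

    def test_constant_vector_flags_skewness(self):
        out = describe_scores([0.5, 0.5, 0.5])
        assert out["sd"] == 0.0
        assert not out["skewness_defined"]

    def test_symmetric_vector(self):
        out = describe_scores([0.2, 0.4, 0.6, 0.8, 1.0])
        assert out["mean"] == pytest.approx(0.6)
        assert out["median"] == pytest.approx(0.6)
        assert out["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            describe_scores([float("nan")] * 3)
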