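"""Scoring operations: eligibility, competition windows, order index,
repetitive matings, standardization and assortative counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from polyprec import (
    assortative_count,
    competition_start_day,
    eligible_females,
    order_day_scores,
    order_index,
    paternity_share,
    repetitive_count,
    score_vial,
    standardize,
)
from polyprec.errors import DegenerateInputError, NoDataError

from conftest import build_vial


class TestEligibility:
    @pytest.mark.parametrize(
        "events, expected",
        [
            ([(1, 1, "m1", "f1")], set()),  # focal only
            ([(1, 1, "m2", "f1"), (2, 1, "m3", "f1")], set()),  # rivals only
            ([(1, 1, "m1", "f1"), (3, 1, "m2", "f1")], {"f1"}),  # focal d1 + rival d3
            (
                [(1, 1, "m2", "f1"), (2, 1, "m1", "f1"), (1, 2, "m1", "f2")],
                {"f1"},
            ),
        ],
    )
    def test_eligibility_rules(self, events, expected):
        ds = build_vial(events=events)
        assert eligible_females(ds, "V1") == expected

    @pytest.mark.parametrize(
        "events, expected_day",
        [
            ([(1, 1, "m1", "f1"), (3, 1, "m2", "f1")], 3),  # focal d1, rival d3
            ([(1, 1, "m2", "f1"), (2, 1, "m1", "f1")], 2),  # rival d1, focal d2
            ([(1, 1, "m1", "f1"), (1, 2, "m2", "f1")], 1),  # both on day 1
        ],
    )
    def test_competition_start_day(self, events, expected_day):
        ds = build_vial(events=events)
        assert competition_start_day(ds, "V1", "f1") == expected_day

    def test_start_day_none_for_ineligible(self):
        ds = build_vial(events=[(1, 1, "m1", "f1")])
        assert competition_start_day(ds, "V1", "f1") is None

    def test_missing_vial_raises(self):
        ds = build_vial()
        with pytest.raises(NoDataError):
            eligible_females(ds, "nope")


class TestPaternityShare:
    def test_pooled_counts_within_window(self):
        # eligible from day 1; window batches (6,2) and (0,2) pool to 6/10
        ds = build_vial(
            events=[(1, 1, "m1", "f1"), (1, 2, "m2", "f1")],
            offspring=[("f1", 1, 6, 2), ("f1", 2, 0, 2)],
        )
        assert paternity_share(ds, "V1") == pytest.approx(0.6)

    def test_window_excludes_pre_competition_lay_days(self):
        # focal d1, rival d3: lay days 1-2 excluded, 3-4 counted
        ds = build_vial(
            events=[(1, 1, "m1", "f1"), (3, 1, "m2", "f1")],
            offspring=[
                ("f1", 1, 10, 0),
                ("f1", 2, 10, 0),
                ("f1", 3, 1, 3),
                ("f1", 4, 1, 3),
            ],
        )
        assert paternity_share(ds, "V1") == pytest.approx(2 / 8)

    def test_all_wildtype_gives_one(self):
        ds = build_vial(
            events=[(1, 1, "m1", "f1"), (1, 2, "m2", "f1")],
            offspring=[("f1", 2, 7, 0)],
        )
        assert paternity_share(ds, "V1") == pytest.approx(1.0)

    def test_per_female_mean_differs_from_pooled(self):
        ds = build_vial(
            events=[
                (1, 1, "m1", "f1"),
                (1, 2, "m2", "f1"),
                (1, 3, "m1", "f2"),
                (1, 4, "m2", "f2"),
            ],
            offspring=[("f1", 1, 9, 1), ("f2", 1, 0, 10)],
        )
        assert paternity_share(ds, "V1", pooling="pooled") == pytest.approx(9 / 20)
        assert paternity_share(ds, "V1", pooling="per_female_mean") == pytest.approx(
            (0.9 + 0.0) / 2
        )

    def test_undefined_without_window_offspring(self):
        ds = build_vial(events=[(1, 1, "m1", "f1"), (2, 1, "m2", "f1")],
                        offspring=[("f1", 1, 5, 5)])  # lay day 1 < start day 2
        assert paternity_share(ds, "V1") is None


class TestOrderIndex:
    def test_carry_forward_scores_one_for_days_2_to_4(self):
        # rival day 1, focal day 2, no further matings -> 1 on days 2, 3, 4
        ds = build_vial(events=[(1, 1, "m2", "f1"), (2, 1, "m1", "f1")])
        scores = order_day_scores(ds, "V1")
        assert list(scores["day"]) == [2, 3, 4]
        assert list(scores["indicator"]) == [1, 1, 1]
        assert order_index(ds, "V1") == pytest.approx(1.0)

    def test_symmetric_case_scores_zero(self):
        # focal day 1, rival day 2, no further matings -> 0 on days 2, 3, 4
        ds = build_vial(events=[(1, 1, "m1", "f1"), (2, 1, "m2", "f1")])
        scores = order_day_scores(ds, "V1")
        assert list(scores["indicator"]) == [0, 0, 0]
        assert order_index(ds, "V1") == pytest.approx(0.0)

    def test_mean_over_two_females(self):
        ds = build_vial(
            events=[
                (1, 1, "m2", "f1"),
                (2, 1, "m1", "f1"),  # f1: focal last from day 2 on
                (1, 2, "m1", "f2"),
                (2, 2, "m2", "f2"),  # f2: rival last from day 2 on
            ]
        )
        assert order_index(ds, "V1") == pytest.approx(0.5)

    def test_same_day_competition_uses_seq_order(self):
        ds = build_vial(events=[(1, 1, "m2", "f1"), (1, 2, "m1", "f1")])
        scores = order_day_scores(ds, "V1")
        assert list(scores["day"]) == [1, 2, 3, 4]
        assert list(scores["indicator"]) == [1, 1, 1, 1]
        ds2 = build_vial(events=[(1, 1, "m1", "f1"), (1, 2, "m2", "f1")])
        assert order_index(ds2, "V1") == pytest.approx(0.0)

    def test_prestart_option_scores_from_first_mating(self):
        # focal d1, rival d3: default scores days 3-4; option scores days 1-4
        ds = build_vial(events=[(1, 1, "m1", "f1"), (3, 1, "m2", "f1")])
        assert list(order_day_scores(ds, "V1")["day"]) == [3, 4]
        early = order_day_scores(ds, "V1", prestart="from_first_mating")
        assert list(early["day"]) == [1, 2, 3, 4]
        assert list(early["indicator"]) == [1, 1, 0, 0]

    def test_undefined_when_focal_never_mates(self):
        ds = build_vial(events=[(1, 1, "m2", "f1")])
        assert order_index(ds, "V1") is None
        assert repetitive_count(ds, "V1") == 0


class TestRepetitiveAndAssortative:
    def test_total_counts_focal_matings_with_eligible_partners(self):
        ds = build_vial(
            events=[
                (1, 1, "m1", "f1"),
                (2, 1, "m1", "f1"),
                (3, 1, "m1", "f1"),
                (3, 2, "m2", "f1"),
            ]
        )
        assert repetitive_count(ds, "V1") == 3
        assert repetitive_count(ds, "V1", convention="rematings") == 2

    def test_two_partners_sum(self):
        ds = build_vial(
            events=[
                (1, 1, "m1", "f1"),
                (2, 1, "m1", "f1"),
                (2, 2, "m2", "f1"),
                (1, 2, "m1", "f2"),
                (3, 1, "m3", "f2"),
            ]
        )
        assert repetitive_count(ds, "V1", convention="total") == 3
        assert repetitive_count(ds, "V1", convention="rematings") == 1

    def test_ineligible_partners_do_not_count(self):
        ds = build_vial(events=[(1, 1, "m1", "f1"), (2, 1, "m1", "f1")])
        assert repetitive_count(ds, "V1") == 0

    @pytest.mark.parametrize(
        "female_sizes, expected",
        [(("large",) * 4, 3), (("small",) * 4, 0)],
    )
    def test_assortative_extremes(self, female_sizes, expected):
        events = [(1, 1, "m1", "f1"), (2, 1, "m1", "f2"), (3, 1, "m1", "f1")]
        ds = build_vial(events=events, female_sizes=female_sizes)
        assert assortative_count(ds, "V1") == expected

    def test_assortative_matches_event_by_event_count(self):
        rng = np.random.default_rng(5)
        sizes = tuple(rng.choice(["large", "small"], size=4))
        events = []
        seq = {d: 0 for d in range(1, 5)}
        for _ in range(20):
            d = int(rng.integers(1, 5))
            seq[d] += 1
            events.append(
                (d, seq[d], f"m{rng.integers(1, 5)}", f"f{rng.integers(1, 5)}")
            )
        ds = build_vial(events=events, female_sizes=sizes)
        brute = sum(
            1
            for d, s, m, f in events
            if m == "m1" and sizes[int(f[1]) - 1] == "large"
        )
        assert assortative_count(ds, "V1") == brute


class TestStandardize:
    def test_closed_form(self):
        assert standardize([1, 2, 3]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_moments(self):
        z = standardize(np.random.default_rng(0).normal(5, 3, size=40))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12

    def test_constant_vector_raises(self):
        with pytest.raises(DegenerateInputError):
            standardize([2.0, 2.0, 2.0])

    @given(
        hst.lists(
            hst.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=3,
            max_size=30,
        ).filter(lambda v: np.std(v) > 1e-6)
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotence(self, values):
        once = standardize(values)
        twice = standardize(once)
        assert np.allclose(once, twice, atol=1e-9)


class TestInvariances:
    def _scores(self, ds):
        row = score_vial(ds, "V1")
        return {
            k: row[k]
            for k in (
                "paternity_share",
                "order_index",
                "repetitive_count",
                "n_eligible_females",
            )
        }

    def test_event_row_permutation_is_irrelevant(self):
        events = [
            (1, 1, "m2", "f1"),
            (1, 2, "m1", "f1"),
            (2, 1, "m1", "f2"),
            (3, 1, "m3", "f2"),
            (4, 1, "m1", "f1"),
        ]
        offspring = [("f1", 2, 4, 4), ("f2", 3, 1, 5)]
        base = self._scores(build_vial(events=events, offspring=offspring))
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ds = build_vial(
                events=[events[i] for i in rng.permutation(len(events))],
                offspring=offspring,
            )
            assert self._scores(ds) == base

    def test_ineligible_female_matings_change_nothing(self):
        events = [(1, 1, "m2", "f1"), (2, 1, "m1", "f1")]
        offspring = [("f1", 2, 3, 1)]
        base = self._scores(build_vial(events=events, offspring=offspring))
        # f4 mates only rivals: never eligible
        extra = events + [(1, 2, "m3", "f4"), (3, 1, "m4", "f4")]
        assert self._scores(build_vial(events=extra, offspring=offspring)) == base

    def test_scores_in_unit_interval(self, sim_fm_scores):
        ps = sim_fm_scores["paternity_share"].dropna()
        oi = sim_fm_scores["order_index"].dropna()
        assert ((ps >= 0) & (ps <= 1)).all()
        assert ((oi >= 0) & (oi <= 1)).all()
        assert (
            sim_fm_scores["repetitive_count"] >= sim_fm_scores["n_eligible_females"]
        ).all()
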