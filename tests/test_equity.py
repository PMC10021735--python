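"""Workforce weights, availability terms and the equity index."""

import numpy as np
import pytest
from shapely.geometry import Point

from archaccess import (
    Facility,
    StaffingStandard,
    availability_terms,
    equity_index,
    rank_districts,
    standard_weights,
    weighted_workforce,
)
from archaccess.equity import EquityScore


class TestStandardWeights:
    @pytest.mark.parametrize(
        "standard, expected",
        [
            ((2500, 1000, 855), (2.92, 1.17, 1.0)),
            ((855, 855, 855), (1.0, 1.0, 1.0)),
            ((1710, 855, 855), (2.0, 1.0, 1.0)),
        ],
    )
    def test_normalised_to_nurse_standard(self, standard, expected):
        assert standard_weights(StaffingStandard(*standard)) == expected

    def test_nonpositive_standard_rejected(self):
        with pytest.raises(ValueError):
            standard_weights(StaffingStandard(0, 1000, 855))


class TestWeightedWorkforce:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((1, 0, 0), 2.92),  # one physician
            ((0, 0, 0), 0.0),
            ((2, 3, 4), 13.35),  # 2·2.92 + 3·1.17 + 4·1
        ],
    )
    def test_linear_combination(self, counts, expected):
        physicians, midwives, nurses = counts
        assert weighted_workforce(physicians, midwives, nurses) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            weighted_workforce(-1, 0, 0)


class TestAvailabilityTerms:
    def _pk(self, mu_ish_staff):
        phys, midw, nur = mu_ish_staff
        return Facility("p", "puskesmas", "d", Point(0, 0), phys, nur, midw)

    def test_per_thousand(self):
        # 50 weighted workers over 100,000 people -> 0.5 per 1,000
        f = Facility("p", "puskesmas", "d", Point(0, 0), physicians=0, nurses=50, midwives=0)
        x, y = availability_terms(100_000, [f])
        assert x == pytest.approx(0.5)
        assert y == 0.0

    def test_no_hospitals_gives_zero_y(self):
        f = Facility("p", "puskesmas", "d", Point(0, 0), nurses=10)
        assert availability_terms(1000, [f])[1] == 0.0

    def test_scale_invariance(self):
        f1 = Facility("p", "puskesmas", "d", Point(0, 0), nurses=10)
        f2 = Facility("p", "puskesmas", "d", Point(0, 0), nurses=20)
        assert availability_terms(1000, [f1])[0] == pytest.approx(
            availability_terms(2000, [f2])[0]
        )

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ValueError):
            availability_terms(0, [])


class TestEquityIndex:
    def test_direct_arithmetic(self):
        assert equity_index(10.0, 2.0, 2.0) == pytest.approx(5.0)

    def test_zero_distance_is_best(self):
        assert equity_index(0.0, 1.0, 3.0) == 0.0

    def test_homogeneity(self):
        base = equity_index(10.0, 2.0, 4.0)
        assert equity_index(20.0, 2.0, 4.0) == pytest.approx(2 * base)
        assert equity_index(10.0, 4.0, 8.0) == pytest.approx(base / 2)

    def test_no_workforce_rejected(self):
        with pytest.raises(ValueError, match="no workforce"):
            equity_index(5.0, 0.0, 0.0)

    def test_forms_agree_on_ordering_when_x_equals_y(self):
        rows = [(10.0, 2.0), (3.0, 5.0), (40.0, 1.0), (8.0, 8.0)]
        avail = [equity_index(z, v, v, form="availability") for z, v in rows]
        ratio = [equity_index(z, v, v, form="ratio") for z, v in rows]
        assert np.argsort(avail).tolist() == np.argsort(ratio).tolist()

    def test_monotonicity_under_random_perturbations(self, rng):
        """Adding any worker never worsens equity; more distance never
        improves it (50 random configurations)."""
        weights = standard_weights()
        for _ in range(50):
            pop = float(rng.integers(10_000, 300_000))
            staff_p = rng.integers(0, 20, size=3)
            staff_h = rng.integers(0, 40, size=3)
            z = float(rng.uniform(1, 200))
            fp = Facility("p", "puskesmas", "d", Point(0, 0), *map(int, staff_p))
            fh = Facility("h", "hospital", "d", Point(0, 0), *map(int, staff_h))
            x, y = availability_terms(pop, [fp, fh], weights)
            if x + y == 0:
                continue
            base = equity_index(z, x, y)
            # one extra worker of a random type at a random facility
            which = int(rng.integers(0, 2))
            attr = ("physicians", "nurses", "midwives")[int(rng.integers(0, 3))]
            staff = [fp, fh]
            f = staff[which]
            staff[which] = Facility(
                f.id, f.kind, f.district_id, f.location,
                f.physicians + (attr == "physicians"),
                f.nurses + (attr == "nurses"),
                f.midwives + (attr == "midwives"),
            )
            x2, y2 = availability_terms(pop, staff, weights)
            assert equity_index(z, x2, y2) <= base + 1e-12
            assert equity_index(z * rng.uniform(1.0, 3.0), x, y) >= base - 1e-12

    def test_unit_invariance_of_ranking(self, rng):
        zs = rng.uniform(1, 100, size=6)
        xs = rng.uniform(0.1, 5, size=6)
        ys = rng.uniform(0.1, 5, size=6)
        base = [equity_index(z, x, y) for z, x, y in zip(zs, xs, ys)]
        miles = [equity_index(z * 0.621, x, y) for z, x, y in zip(zs, xs, ys)]
        assert np.argsort(base).tolist() == np.argsort(miles).tolist()


class TestRankDistricts:
    def _score(self, did, value):
        return EquityScore(did, did.upper(), 1.0, 1.0, 1.0, value)

    def test_ascending_order(self):
        ranked = rank_districts([self._score(d, v) for d, v in [("a", 1), ("b", 2), ("c", 3)]])
        assert [s.district_id for s in ranked] == ["a", "b", "c"]
        assert [s.rank for s in ranked] == [1, 2, 3]

    def test_permutation_invariance(self):
        scores = [self._score(d, v) for d, v in [("a", 3), ("b", 1), ("c", 2)]]
        fwd = rank_districts(scores)
        rev = rank_districts(list(reversed(scores)))
        assert [s.district_id for s in fwd] == [s.district_id for s in rev] == ["b", "c", "a"]

    def test_ties_break_alphabetically(self):
        ranked = rank_districts([self._score("zz", 1.0), self._score("aa", 1.0)])
        assert [s.district_id for s in ranked] == ["aa", "zz"]

    def test_best_workforce_and_distance_ranks_first(self, small_results):
        """In a fitted region the rank-1 district has the lowest equity value."""
        scores = small_results.bundle.equity_scores
        assert scores[0].rank == 1
        assert scores[0].equity_value == min(s.equity_value for s in scores)
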