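import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clmfca import (
    DEFAULT_SPEC,
    ChoiceModelSpec,
    ChoiceRecord,
    DemandPoint,
    Hospital,
    TravelTimeMatrix,
    catchment_sets,
    choice_probabilities,
    fit,
    odds_ratio,
    utility,
)
from conftest import random_instance


class TestUtility:
    def test_all_reference_levels_give_zero(self):
        h = Hospital("h", 0, 0, 1.0, level="Low", urbanization="Metro", n_specialists=0)
        assert utility(h, 0.0) == 0.0

    def test_high_tier_alone_gives_its_coefficient(self):
        h = Hospital("h", 0, 0, 1.0, level="High", urbanization="Metro", n_specialists=0)
        assert utility(h, 0.0) == pytest.approx(-1.072)

    def test_hand_computed_combination(self):
        # -0.862 (rural) + 5*0.151 - 30*0.064 = -2.027
        h = Hospital("h", 0, 0, 1.0, level="Low", urbanization="Rural", n_specialists=5)
        assert utility(h, 30.0) == pytest.approx(-2.027)

    def test_negative_travel_time_rejected(self):
        h = Hospital("h", 0, 0, 1.0)
        with pytest.raises(ValueError):
            utility(h, -1.0)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "coef, expected, digits",
        [(-1.072, 0.34, 2), (0.0, 1.0, 12), (0.151, 1.163, 3)],
    )
    def test_values(self, coef, expected, digits):
        assert round(odds_ratio(coef), digits) == pytest.approx(expected)


class TestChoiceProbabilities:
    def _landscape(self, hospitals, tau_row):
        demand = [DemandPoint("d", 0, 0, 100.0)]
        tt = TravelTimeMatrix(
            np.array([tau_row], dtype=float), ("d",), tuple(h.id for h in hospitals)
        )
        cat = catchment_sets(tt, 60.0)
        return demand, tt, cat

    def test_singleton_choice_set_is_certain(self):
        hs = [Hospital("h1", 0, 0, 1.0), Hospital("h2", 0, 0, 1.0)]
        demand, tt, cat = self._landscape(hs, [10.0, 90.0])
        p = choice_probabilities(demand, hs, tt, cat)
        np.testing.assert_allclose(p.probs[0], [1.0, 0.0])

    def test_identical_hospitals_split_evenly(self):
        hs = [Hospital("h1", 0, 0, 1.0), Hospital("h2", 0, 0, 1.0)]
        demand, tt, cat = self._landscape(hs, [20.0, 20.0])
        p = choice_probabilities(demand, hs, tt, cat)
        np.testing.assert_allclose(p.probs[0], [0.5, 0.5])

    def test_softmax_of_tier_gap(self):
        # V = (0, -1.072) -> P = (0.7450, 0.2550)
        hs = [
            Hospital("h1", 0, 0, 1.0, level="Low"),
            Hospital("h2", 0, 0, 1.0, level="High"),
        ]
        demand, tt, cat = self._landscape(hs, [0.0, 0.0])
        p = choice_probabilities(demand, hs, tt, cat)
        np.testing.assert_allclose(p.probs[0], [0.7450, 0.2550], atol=5e-5)

    def test_empty_choice_set_gives_zero_row(self):
        hs = [Hospital("h1", 0, 0, 1.0)]
        demand, tt, cat = self._landscape(hs, [90.0])
        p = choice_probabilities(demand, hs, tt, cat)
        assert p.probs[0, 0] == 0.0

    def test_extreme_utilities_do_not_overflow(self):
        hs = [Hospital("h1", 0, 0, 1.0, n_specialists=10000),
              Hospital("h2", 0, 0, 1.0)]
        demand, tt, cat = self._landscape(hs, [0.0, 0.0])
        p = choice_probabilities(demand, hs, tt, cat)
        assert np.all(np.isfinite(p.probs))
        np.testing.assert_allclose(p.probs[0], [1.0, 0.0], atol=1e-12)

    def test_global_convention_normalizes_over_all_hospitals(self):
        hs = [Hospital("h1", 0, 0, 1.0), Hospital("h2", 0, 0, 1.0)]
        demand, tt, cat = self._landscape(hs, [10.0, 90.0])
        p = choice_probabilities(demand, hs, tt, cat, choice_set="global")
        assert p.probs[0].sum() == pytest.approx(1.0, abs=1e-12)
        assert p.probs[0, 1] > 0  # out-of-catchment hospital still chosen sometimes

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rows_normalize_and_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        demand, hospitals, tt = random_instance(rng, n_demand=8, n_hospitals=5)
        cat = catchment_sets(tt, 60.0)
        spec = ChoiceModelSpec(*rng.normal(0, 1, 5))
        p = choice_probabilities(demand, hospitals, tt, cat, spec)
        sums = p.probs.sum(axis=1)
        nonempty = cat.within.any(axis=1)
        np.testing.assert_allclose(sums[nonempty], 1.0, atol=1e-9)
        np.testing.assert_allclose(sums[~nonempty], 0.0)
        # adding a constant to every utility of one demand point changes nothing:
        # equivalent to shifting all utilities via a common additive term
        shifted = ChoiceModelSpec(*(spec.as_array() + np.array([0, 0, 0, 0, 0.0])))
        tt2 = TravelTimeMatrix(tt.times + 7.5, tt.demand_ids, tt.hospital_ids)
        cat2 = catchment_sets(tt2, 60.0 + 7.5)
        if np.array_equal(cat.within, cat2.within):
            p2 = choice_probabilities(demand, hospitals, tt2, cat2, shifted)
            np.testing.assert_allclose(p.probs, p2.probs, atol=1e-9)

    def test_monotone_in_specialists(self, small_landscape):
        demand, hospitals, tt, cat, probs = small_landscape
        target = 3
        boosted = list(hospitals)
        h = hospitals[target]
        boosted[target] = Hospital(h.id, h.x, h.y, h.capacity, h.level,
                                   h.urbanization, h.n_specialists + 2)
        p2 = choice_probabilities(demand, boosted, tt, cat)
        # strict gain wherever the patient actually has a choice
        reach = cat.within[:, target] & (cat.within.sum(axis=1) >= 2)
        assert np.all(p2.probs[reach, target] > probs.probs[reach, target])
        singleton = cat.within[:, target] & (cat.within.sum(axis=1) == 1)
        np.testing.assert_array_equal(p2.probs[singleton, target], 1.0)
        others = np.ones(len(hospitals), dtype=bool)
        others[target] = False
        assert np.all(p2.probs[:, others] <= probs.probs[:, others] + 1e-15)


def _simulate_records(rng, demand, hospitals, tt, cat, spec, n_choices):
    """Draw observed choices from the model within catchment option sets."""
    probs = choice_probabilities(demand, hospitals, tt, cat, spec)
    pops = np.array([d.population for d in demand])
    valid = cat.within.sum(axis=1) >= 2
    weights = np.where(valid, pops, 0.0)
    weights = weights / weights.sum()
    picks = rng.choice(len(demand), size=n_choices, p=weights)
    records = []
    for i in picks:
        opts = np.flatnonzero(cat.within[i])
        row = probs.probs[i, opts]
        chosen = rng.choice(opts, p=row / row.sum())
        records.append(
            ChoiceRecord(demand[i].id, hospitals[chosen].id,
                         tuple(hospitals[k].id for k in opts))
        )
    return records


class TestFit:
    def test_chosen_must_be_in_option_set(self):
        with pytest.raises(ValueError):
            ChoiceRecord("d", "h9", ("h1", "h2"))

    def test_rejects_singleton_option_sets(self, small_landscape):
        demand, hospitals, tt, cat, probs = small_landscape
        rec = ChoiceRecord(demand[0].id, hospitals[0].id, (hospitals[0].id,))
        with pytest.raises(ValueError):
            fit([rec], hospitals, tt)

    def test_null_model_recovery(self, small_landscape):
        """Choices simulated uniformly (beta = 0) give estimates within 3 SE of 0."""
        demand, hospitals, tt, cat, _ = small_landscape
        rng = np.random.default_rng(7)
        zero = ChoiceModelSpec(0, 0, 0, 0, 0)
        records = _simulate_records(rng, demand, hospitals, tt, cat, zero, 5000)
        result = fit(records, hospitals, tt)
        assert result.converged
        assert np.all(np.abs(result.spec.as_array()) <= 3 * result.standard_errors)
        # likelihood at the optimum is no worse than at the zero start
        n_eff = sum(np.log(len(r.option_ids)) for r in records)
        assert result.log_likelihood >= -n_eff

    def test_recovers_generating_coefficients(self, small_landscape):
        demand, hospitals, tt, cat, _ = small_landscape
        rng = np.random.default_rng(21)
        records = _simulate_records(rng, demand, hospitals, tt, cat, DEFAULT_SPEC, 6000)
        result = fit(records, hospitals, tt)
        err = np.abs(result.spec.as_array() - DEFAULT_SPEC.as_array())
        assert np.all(err <= 3 * result.standard_errors)

    def test_matches_statsmodels_conditional_logit(self, small_landscape):
        """Independent cross-check against the grouped conditional-logit MLE."""
        sm_clogit = pytest.importorskip(
            "statsmodels.discrete.conditional_models"
        ).ConditionalLogit
        from clmfca.choice import _stack_records

        demand, hospitals, tt, cat, _ = small_landscape
        rng = np.random.default_rng(3)
        records = _simulate_records(rng, demand, hospitals, tt, cat, DEFAULT_SPEC, 800)
        mine = fit(records, hospitals, tt)

        z, mask, chosen_pos = _stack_records(records, hospitals, tt)
        rows, y, groups = [], [], []
        for n, rec in enumerate(records):
            m = len(rec.option_ids)
            for k in range(m):
                rows.append(z[n, k])
                y.append(1 if k == chosen_pos[n] else 0)
                groups.append(n)
        res = sm_clogit(np.array(y), np.array(rows), groups=np.array(groups)).fit(disp=0)
        np.testing.assert_allclose(mine.spec.as_array(), res.params, atol=1e-4)
        np.testing.assert_allclose(mine.standard_errors, res.bse, rtol=1e-3)
        assert mine.log_likelihood == pytest.approx(res.llf, rel=1e-6)

    def test_two_alternative_fit_equals_binary_logit_on_differences(self):
        """With 2 options per set, conditional logit reduces to a binary logit
        on the covariate differences (no intercept)."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        hospitals = [
            Hospital(f"h{j}", 0, 0, 1.0,
                     level=rng.choice(["High", "Low"]),
                     urbanization=rng.choice(["Metro", "City", "Rural"]),
                     n_specialists=int(rng.integers(0, 8)))
            for j in range(12)
        ]
        demand = [DemandPoint(f"d{i}", 0, 0, 1.0) for i in range(40)]
        tt = TravelTimeMatrix(rng.uniform(0, 60, (40, 12)),
                              tuple(d.id for d in demand),
                              tuple(h.id for h in hospitals))
        from clmfca.choice import utility_matrix

        util = utility_matrix(hospitals, tt, DEFAULT_SPEC)
        records = []
        for _ in range(2000):
            i = int(rng.integers(0, 40))
            a, b = rng.choice(12, size=2, replace=False)
            pa = 1.0 / (1.0 + np.exp(util[i, b] - util[i, a]))
            chosen = a if rng.random() < pa else b
            records.append(ChoiceRecord(demand[i].id, hospitals[chosen].id,
                                        (hospitals[a].id, hospitals[b].id)))
        mine = fit(records, hospitals, tt)

        from clmfca.choice import _stack_records

        z, mask, chosen_pos = _stack_records(records, hospitals, tt)
        x_diff = np.array([zz[0] - zz[1] for zz in z])
        y = (chosen_pos == 0).astype(int)
        res = sm.Logit(y, x_diff).fit(disp=0)
        np.testing.assert_allclose(mine.spec.as_array(), res.params, atol=1e-5)

    def test_separation_is_flagged(self):
        """Choices that always take the nearest option separate perfectly on
        travel time; the fit warns and flags its estimates as unstable."""
        rng = np.random.default_rng(13)
        hospitals = [
            Hospital(f"h{j}", 0, 0, 1.0,
                     level=rng.choice(["High", "Low"]),
                     urbanization=rng.choice(["Metro", "City", "Rural"]),
                     n_specialists=int(rng.integers(0, 6)))
            for j in range(8)
        ]
        demand = [DemandPoint(f"d{i}", 0, 0, 1.0) for i in range(20)]
        tt = TravelTimeMatrix(rng.uniform(0, 60, (20, 8)),
                              tuple(d.id for d in demand),
                              tuple(h.id for h in hospitals))
        records = []
        for _ in range(200):
            i = int(rng.integers(0, 20))
            opts = rng.choice(8, size=3, replace=False)
            nearest = opts[np.argmin(tt.times[i, opts])]
            records.append(ChoiceRecord(demand[i].id, hospitals[nearest].id,
                                        tuple(hospitals[k].id for k in opts)))
        with pytest.warns(RuntimeWarning):
            result = fit(records, hospitals, tt)
        assert result.unstable
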