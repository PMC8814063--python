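"""Deterministic availability chain: worked values, validation, invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from samplecast import (
    Scenario,
    TimeModel,
    UndefinedProbabilityError,
    ValidationError,
    annual_cases,
    availability_probability,
    distribute_to_hospitals,
    evaluate_scenario,
    hour_sweep,
    per_hospital_availability,
    refine,
    stratify,
)

# strategies over valid scenario space; bounded so continuous values stay finite
populations = st.integers(min_value=0, max_value=2_000_000_000)
prevalences = st.floats(min_value=0, max_value=100, allow_nan=False)
hospitals = st.integers(min_value=1, max_value=10_000)
strata = st.integers(min_value=1, max_value=50)
hours = st.floats(min_value=0.25, max_value=24, allow_nan=False)


def scenarios():
    return st.builds(
        lambda n, pr, x, xp, h: Scenario(
            population_size=n,
            prevalence_pct=pr,
            hospital_count=x,
            strata_count=xp,
            time_model=TimeModel(sampling_hours=h),
        ),
        populations,
        prevalences,
        hospitals,
        strata,
        hours,
    )


class TestChainSteps:
    @pytest.mark.parametrize(
        ("n", "pr", "pc", "expected"),
        [
            (58_746_995, 3, 100, 1_762_409.85),
            (0, 12, 100, 0.0),
            (12_300_000, 12, 100, 1_476_000.0),
        ],
    )
    def test_annual_cases_examples(self, n, pr, pc, expected):
        assert annual_cases(n, pr, pc) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        ("s", "x", "expected"),
        [
            (1_762_409.85, 100, 17_624.0985),
            (1_476_000.0, 100, 14_760.0),
            (123.456, 1, 123.456),
        ],
    )
    def test_distribute_examples(self, s, x, expected):
        assert distribute_to_hospitals(s, x) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        ("u", "xp", "expected"),
        [
            (17_624.0985, 5, 3_524.8197),
            (14_760.0, 5, 2_952.0),
            (99.9, 1, 99.9),
        ],
    )
    def test_stratify_examples(self, u, xp, expected):
        assert stratify(u, xp) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        ("scenario_kwargs", "expected"),
        [
            (dict(population_size=58_746_995, prevalence_pct=3), 3_524.8197),
            (dict(population_size=1_000_000, prevalence_pct=0), 0.0),
            (dict(population_size=12_300_000, prevalence_pct=15), 3_690.0),
        ],
    )
    def test_closed_form_examples(self, scenario_kwargs, expected):
        assert per_hospital_availability(Scenario(**scenario_kwargs)) == pytest.approx(
            expected, rel=1e-12, abs=1e-12
        )

    @pytest.mark.parametrize(
        ("a", "h", "expected"),
        [
            (3_524.8197, 1, 130.37),
            (0.0, 7, 0.0),
            (2_952.0, 3, 327.55),
        ],
    )
    def test_refine_examples(self, a, h, expected):
        r = refine(a, TimeModel(sampling_hours=h))
        assert r == pytest.approx(expected, abs=0.01)

    def test_probability_examples(self):
        assert availability_probability(130.37, 3_524.8197) == pytest.approx(0.03699, abs=1e-4)
        # R == A -> P = 1
        assert availability_probability(42.0, 42.0) == pytest.approx(1.0)

    def test_probability_undefined_at_zero_availability(self):
        with pytest.raises(UndefinedProbabilityError):
            availability_probability(0.0, 0.0)


class TestValidation:
    @pytest.mark.parametrize(
        ("call", "field_name"),
        [
            (lambda: annual_cases(-1, 3), "population_size"),
            (lambda: annual_cases(100, 120), "prevalence_pct"),
            (lambda: annual_cases(100, 3, 0), "pct_base"),
            (lambda: distribute_to_hospitals(10.0, 0), "hospital_count"),
            (lambda: stratify(10.0, 0), "strata_count"),
            (lambda: TimeModel(sampling_hours=0), "sampling_hours"),
            (lambda: TimeModel(sampling_hours=25), "sampling_hours"),
            (lambda: TimeModel(working_days_per_month=32), "working_days_per_month"),
            (lambda: TimeModel(working_days_per_month=31, months_per_year=12), "days_per_year"),
            (lambda: Scenario(population_size=-5, prevalence_pct=3), "population_size"),
        ],
    )
    def test_errors_name_offending_field(self, call, field_name):
        with pytest.raises(ValidationError, match=field_name):
            call()

    def test_degenerate_zero_inputs_are_valid(self):
        assert evaluate_scenario(Scenario(population_size=0, prevalence_pct=12)).predicted == 0
        assert evaluate_scenario(Scenario(population_size=10**6, prevalence_pct=0)).predicted == 0

    def test_nondefault_pct_base_warns(self):
        with pytest.warns(UserWarning, match="pct_base"):
            Scenario(population_size=100, prevalence_pct=3, pct_base=50)


class TestEvaluateScenario:
    @pytest.mark.parametrize(
        ("n", "pr", "wst", "predicted"),
        [
            (58_746_995, 3, 651, 130),
            (58_746_995, 17, 3693, 738),
            (12_300_000, 12, 545, 109),
        ],
    )
    def test_published_integer_reports(self, n, pr, wst, predicted):
        result = evaluate_scenario(Scenario(population_size=n, prevalence_pct=pr))
        assert result.predicted_without_stratification == wst
        assert result.predicted == predicted

    def test_result_fields_consistent(self, three_pct_scenario):
        r = evaluate_scenario(three_pct_scenario)
        assert r.per_hospital * 100 == pytest.approx(r.annual_cases, rel=1e-9)
        assert r.per_stratum * 5 == pytest.approx(r.per_hospital, rel=1e-9)
        assert 0 <= r.probability <= 1
        assert r.predicted <= r.predicted_without_stratification


class TestHourSweep:
    def test_migraine_sweep(self, migraine_scenario):
        results = hour_sweep(migraine_scenario, [1, 2, 3, 4, 5])
        assert [r.predicted for r in results] == [109, 218, 327, 436, 545]

    def test_three_pct_sweep(self, three_pct_scenario):
        results = hour_sweep(three_pct_scenario, [1, 2, 3])
        assert [r.predicted for r in results] == [130, 260, 391]

    def test_refined_strictly_increasing(self, kidney_scenario):
        refined = [r.refined for r in hour_sweep(kidney_scenario, [1, 2, 4, 8, 16, 24])]
        assert all(b > a for a, b in zip(refined, refined[1:]))

    def test_full_time_limit_recovers_availability(self):
        # with dM*dY = Yd and h = Hd the refinement factor is exactly 1
        tm = TimeModel(days_per_year=360, working_days_per_month=30, sampling_hours=24)
        sc = Scenario(population_size=10**7, prevalence_pct=5, time_model=tm)
        (result,) = hour_sweep(sc, [24])
        assert result.predicted == math.floor(per_hospital_availability(sc))

    def test_empty_hours_rejected(self, migraine_scenario):
        with pytest.raises(ValidationError):
            hour_sweep(migraine_scenario, [])


class TestProperties:
    @settings(max_examples=200, derandomize=True)
    @given(scenarios())
    def test_conservation_and_chain_equivalence(self, sc):
        s = annual_cases(sc.population_size, sc.prevalence_pct, sc.pct_base)
        u = distribute_to_hospitals(s, sc.hospital_count)
        sp = stratify(u, sc.strata_count)
        assert u * sc.hospital_count == pytest.approx(s, rel=1e-9, abs=1e-9)
        assert sp * sc.strata_count * sc.hospital_count == pytest.approx(s, rel=1e-9, abs=1e-9)
        assert per_hospital_availability(sc) == pytest.approx(sp, rel=1e-12, abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(min_value=0, max_value=1e7, allow_nan=False), st.integers(min_value=1, max_value=24))
    def test_refine_linear_in_hours(self, a, h):
        tm1 = TimeModel(sampling_hours=1)
        tmh = TimeModel(sampling_hours=h)
        assert refine(a, tmh) == h * refine(a, tm1)  # bit-exact by construction

    @settings(max_examples=100, derandomize=True)
    @given(scenarios())
    def test_probability_bounded_and_population_invariant(self, sc):
        result = evaluate_scenario(sc)
        if result.per_stratum > 0:
            h = sc.time_model.sampling_hours
            expected_p = h * 27 * 12 / (365 * 24)
            assert 0 <= result.probability <= 1
            assert result.probability == pytest.approx(expected_p, rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(scenarios(), st.integers(min_value=1, max_value=1000))
    def test_scale_invariance_in_population(self, sc, k):
        base = evaluate_scenario(sc)
        scaled = evaluate_scenario(
            Scenario(
                population_size=sc.population_size * k,
                prevalence_pct=sc.prevalence_pct,
                hospital_count=sc.hospital_count,
                strata_count=sc.strata_count,
                time_model=sc.time_model,
            )
        )
        assert scaled.refined == pytest.approx(base.refined * k, rel=1e-12, abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(scenarios())
    def test_floor_counts_monotone(self, sc):
        base = evaluate_scenario(sc)
        more_prev = evaluate_scenario(
            Scenario(
                population_size=sc.population_size,
                prevalence_pct=min(sc.prevalence_pct * 1.5, 100),
                hospital_count=sc.hospital_count,
                strata_count=sc.strata_count,
                time_model=sc.time_model,
            )
        )
        more_hosp = evaluate_scenario(
            Scenario(
                population_size=sc.population_size,
                prevalence_pct=sc.prevalence_pct,
                hospital_count=sc.hospital_count + 1,
                strata_count=sc.strata_count,
                time_model=sc.time_model,
            )
        )
        more_strata = evaluate_scenario(
            Scenario(
                population_size=sc.population_size,
                prevalence_pct=sc.prevalence_pct,
                hospital_count=sc.hospital_count,
                strata_count=sc.strata_count + 1,
                time_model=sc.time_model,
            )
        )
        assert more_prev.predicted >= base.predicted
        assert more_hosp.predicted <= base.predicted
        assert more_strata.predicted <= base.predicted
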