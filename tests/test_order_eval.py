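"""The order-appropriateness decision cascade and its aggregations."""

import numpy as np
import pytest

from obesitydosing import (
    DataIntegrityError,
    GroupKey,
    GrowthChart,
    MedicationOrder,
    NotGovernedError,
    OrderDoseUnit,
    OrderEvaluation,
    Phase,
    Reason,
    Status,
    UndefinedRateError,
    WeightKind,
    aggregate_proportions,
    evaluate_batch,
    evaluate_order,
    event_rate,
    pareto_decomposition,
)

from conftest import lean_assessment, make_patient, obese_assessment, weights_of


def order(**kwargs):
    defaults = dict(
        order_id="o1",
        patient_id="p1",
        drug="acetaminophen",
        dose_amount=500.0,
        dose_unit=OrderDoseUnit.MG,
    )
    defaults.update(kwargs)
    return MedicationOrder(**defaults)


class TestEvaluateOrder:
    def test_max_dose_carve_out(self, formulary):
        # 1000 mg flat acetaminophen at adjusted weight 70 kg: 14.3 mg/kg,
        # exactly the max dose -> appropriate via the max-dose rule
        ev = evaluate_order(
            order(dose_amount=1000.0),
            make_patient(),
            obese_assessment(),
            weights_of(actual=100.0, ideal=50.0, adjusted=70.0),
            formulary,
        )
        assert ev.status is Status.APPROPRIATE
        assert ev.reason is Reason.MAX_DOSE_RULE
        assert ev.computed_per_kg == pytest.approx(1000.0 / 70.0)

    def test_max_dose_below_heavy_threshold_inappropriate(self, formulary):
        # adjusted weight 60 kg: 1000 mg is 16.7 mg/kg > 15 -> inappropriate
        ev = evaluate_order(
            order(dose_amount=1000.0),
            make_patient(),
            obese_assessment(),
            weights_of(actual=90.0, ideal=40.0, adjusted=60.0),
            formulary,
        )
        assert ev.status is Status.INAPPROPRIATE
        assert ev.reason is Reason.FLAT_DOSE_OUT_OF_RANGE

    def test_flat_dose_in_range(self, formulary):
        # 600 mg over adjusted 52 kg = 11.5 mg/kg, inside 10-15
        ev = evaluate_order(
            order(dose_amount=600.0),
            make_patient(),
            obese_assessment(),
            weights_of(),
            formulary,
        )
        assert (ev.status, ev.reason) == (Status.APPROPRIATE, Reason.FLAT_DOSE_IN_RANGE)

    def test_per_kg_order_with_actual_weight_mismatch(self, formulary):
        # acyclovir recommends ideal body weight
        ev = evaluate_order(
            order(drug="acyclovir", dose_amount=10.0,
                  dose_unit=OrderDoseUnit.MG_PER_KG,
                  weight_kind_used=WeightKind.ACTUAL, weight_used_kg=70.0),
            make_patient(),
            obese_assessment(),
            weights_of(),
            formulary,
        )
        assert (ev.status, ev.reason) == (Status.INAPPROPRIATE, Reason.WEIGHT_KIND_MISMATCH)
        assert ev.computed_per_kg is None

    def test_per_kg_order_matching_kind(self, formulary):
        ev = evaluate_order(
            order(drug="acyclovir", dose_amount=10.0,
                  dose_unit=OrderDoseUnit.MG_PER_KG,
                  weight_kind_used=WeightKind.IDEAL, weight_used_kg=40.0),
            make_patient(),
            obese_assessment(),
            weights_of(),
            formulary,
        )
        assert (ev.status, ev.reason) == (Status.APPROPRIATE, Reason.WEIGHT_KIND_MATCH)

    def test_rate_order_judged_by_weight_kind_only(self, formulary):
        ev = evaluate_order(
            order(drug="dexmedetomidine", dose_amount=0.7,
                  dose_unit=OrderDoseUnit.MCG_PER_KG_PER_HR,
                  weight_kind_used=WeightKind.ADJUSTED, weight_used_kg=52.0),
            make_patient(),
            obese_assessment(),
            weights_of(),
            formulary,
        )
        assert (ev.status, ev.reason) == (Status.APPROPRIATE, Reason.WEIGHT_KIND_MATCH)

    def test_level_based_aminoglycoside_excluded(self, formulary):
        ev = evaluate_order(
            order(drug="gentamicin", dose_amount=120.0, level_based=True),
            make_patient(),
            obese_assessment(),
            weights_of(),
            formulary,
        )
        assert (ev.status, ev.reason) == (Status.EXCLUDED, Reason.EXCLUDED_LEVEL_BASED)

    def test_level_based_per_kg_order_not_excluded(self, formulary):
        # the exclusion covers flat mg doses only
        ev = evaluate_order(
            order(drug="gentamicin", dose_amount=2.5,
                  dose_unit=OrderDoseUnit.MG_PER_KG, level_based=True,
                  weight_kind_used=WeightKind.ADJUSTED, weight_used_kg=52.0),
            make_patient(),
            obese_assessment(),
            weights_of(),
            formulary,
        )
        assert ev.status is Status.APPROPRIATE

    def test_level_based_acetaminophen_not_excluded(self, formulary):
        # acetaminophen is not level-monitored; the flag is ignored
        ev = evaluate_order(
            order(dose_amount=600.0, level_based=True),
            make_patient(),
            obese_assessment(),
            weights_of(),
            formulary,
        )
        assert ev.status is Status.APPROPRIATE

    def test_non_cdc_growth_chart_excluded(self, formulary):
        patient = make_patient(growth_chart_id=GrowthChart.OTHER)
        ev = evaluate_order(order(), patient, None, None, formulary)
        assert (ev.status, ev.reason) == (Status.EXCLUDED, Reason.EXCLUDED_GROWTH_CHART)

    def test_under_two_years_excluded(self, formulary):
        ev = evaluate_order(order(), make_patient(age_months=20), None, None, formulary)
        assert (ev.status, ev.reason) == (Status.EXCLUDED, Reason.EXCLUDED_GROWTH_CHART)

    def test_not_obese_actual_or_no_weight_ok(self, formulary):
        for kwargs in (
            dict(dose_amount=5000.0),  # any flat dose
            dict(dose_amount=20.0, dose_unit=OrderDoseUnit.MG_PER_KG,
                 weight_kind_used=WeightKind.ACTUAL, weight_used_kg=70.0),
        ):
            ev = evaluate_order(
                order(**kwargs), make_patient(), lean_assessment(), weights_of(), formulary
            )
            assert (ev.status, ev.reason) == (Status.APPROPRIATE, Reason.NOT_OBESE_ACTUAL_OK)

    def test_not_obese_alternative_weight_inappropriate(self, formulary):
        ev = evaluate_order(
            order(dose_amount=12.0, dose_unit=OrderDoseUnit.MG_PER_KG,
                  weight_kind_used=WeightKind.IDEAL, weight_used_kg=40.0),
            make_patient(),
            lean_assessment(),
            weights_of(),
            formulary,
        )
        assert (ev.status, ev.reason) == (Status.INAPPROPRIATE, Reason.WEIGHT_KIND_MISMATCH)

    def test_unknown_drug_raises_not_governed(self, formulary):
        with pytest.raises(NotGovernedError):
            evaluate_order(
                order(drug="vancomycin"), make_patient(), obese_assessment(),
                weights_of(), formulary,
            )


class TestCascadeProperties:
    def test_every_order_maps_to_exactly_one_reason(self, formulary):
        """Randomized orders: cascade exhaustive, exclusive, and the
        excluded status appears iff the reason is an exclusion code."""
        rng = np.random.default_rng(2024)
        drugs = formulary.drugs()
        kinds = [None, WeightKind.ACTUAL, WeightKind.IDEAL, WeightKind.ADJUSTED]
        for i in range(500):
            drug = drugs[rng.integers(len(drugs))]
            unit = [OrderDoseUnit.MG, OrderDoseUnit.MG_PER_KG,
                    OrderDoseUnit.MCG_PER_KG_PER_HR][rng.integers(3)]
            kind = kinds[rng.integers(1, 4)] if unit is not OrderDoseUnit.MG \
                else kinds[rng.integers(4)]
            o = order(
                order_id=f"r{i}", drug=drug,
                dose_amount=float(rng.uniform(0.1, 2000.0)),
                dose_unit=unit, weight_kind_used=kind,
                weight_used_kg=None if kind is None else 50.0,
                level_based=bool(rng.random() < 0.3),
            )
            patient = make_patient(
                age_months=int(rng.integers(12, 300)),
                growth_chart_id=(GrowthChart.OTHER if rng.random() < 0.2
                                 else GrowthChart.CDC_2_20),
            )
            classifiable = (patient.growth_chart_id is GrowthChart.CDC_2_20
                            and patient.age_months >= 24)
            assessment = (obese_assessment() if rng.random() < 0.5 else lean_assessment()) \
                if classifiable else None
            weights = weights_of() if classifiable else None
            ev = evaluate_order(o, patient, assessment, weights, formulary)
            assert isinstance(ev.reason, Reason)
            assert (ev.status is Status.EXCLUDED) == (
                ev.reason in (Reason.EXCLUDED_LEVEL_BASED, Reason.EXCLUDED_GROWTH_CHART)
            )

    @pytest.mark.parametrize("drug", ["acetaminophen", "acyclovir", "amikacin",
                                      "gentamicin", "tobramycin", "voriconazole"])
    def test_flat_dose_boundary_equals_brute_force(self, formulary, drug):
        """The appropriate/inappropriate flat-dose boundary equals
        recommended-weight x per-kg bounds plus the max-dose point."""
        rule = formulary.lookup(drug)
        w = weights_of(actual=80.0, ideal=38.0, adjusted=54.8)
        alt = w.weight_of_kind(rule.recommended_weight_kind)
        for dose in np.linspace(1.0, 2500.0, 400):
            dose = float(dose)
            ev = evaluate_order(
                order(drug=drug, dose_amount=dose),
                make_patient(), obese_assessment(), w, formulary,
            )
            oracle = (rule.per_kg_low * alt <= dose <= rule.per_kg_high * alt) or (
                rule.max_dose_mg is not None
                and dose == rule.max_dose_mg
                and dose <= rule.per_kg_high * alt
            )
            assert (ev.status is Status.APPROPRIATE) == oracle, (drug, dose)

    def test_appropriate_flat_doses_form_interval_plus_max_point(self, formulary):
        # adjusted weight 120 kg: guideline interval is [1200, 1800] mg and
        # the 1000 mg max dose sits below it (8.3 mg/kg) yet is appropriate
        rule = formulary.lookup("acetaminophen")
        w = weights_of(actual=180.0, ideal=80.0, adjusted=120.0)
        doses = np.arange(1.0, 2000.0, 0.5)
        ok = [
            evaluate_order(
                order(dose_amount=float(d)), make_patient(),
                obese_assessment(), w, formulary,
            ).status
            is Status.APPROPRIATE
            for d in doses
        ]
        ok_doses = doses[np.array(ok)]
        in_interval = ok_doses[(ok_doses >= rule.per_kg_low * 120.0 - 1e-9)
                               & (ok_doses <= rule.per_kg_high * 120.0 + 1e-9)]
        extras = set(np.round(ok_doses, 6)) - set(np.round(in_interval, 6))
        assert extras == {1000.0}  # the max-dose carve-out point
        # and the interval itself is contiguous on the grid
        assert np.all(np.diff(np.where(np.isin(doses, in_interval))[0]) == 1)


class TestEvaluateBatch:
    def test_empty_orders_empty_result(self, formulary, lms):
        res = evaluate_batch([], [], formulary, lms)
        assert res.evaluations == [] and res.rejects == [] and res.not_governed == []

    def test_conservation_and_rejects(self, formulary, lms):
        patients = [make_patient(patient_id="known", weight_kg=60.0)]
        orders = [
            order(order_id="a", patient_id="known"),
            order(order_id="b", patient_id="ghost"),
            order(order_id="c", patient_id="known", drug="vancomycin"),
        ]
        res = evaluate_batch(orders, patients, formulary, lms)
        assert len(res.evaluations) == 1
        assert res.rejects == [("b", "unknown patient 'ghost'")]
        assert res.not_governed == ["c"]
        assert len(orders) == len(res.evaluations) + len(res.rejects) + len(res.not_governed)

    def test_order_independent(self, formulary, lms):
        patients = [make_patient(patient_id=f"p{i}", weight_kg=30.0 + i) for i in range(5)]
        orders = [order(order_id=f"o{i}", patient_id=f"p{i % 5}",
                        dose_amount=100.0 + 37 * i) for i in range(20)]
        fwd = evaluate_batch(orders, patients, formulary, lms)
        rev = evaluate_batch(list(reversed(orders)), patients, formulary, lms)
        assert {e.order_id: (e.status, e.reason) for e in fwd.evaluations} == \
               {e.order_id: (e.status, e.reason) for e in rev.evaluations}


def _ev(order_id, status, drug="acetaminophen", month="2021-01",
        department="ED", phase=Phase.PRE):
    reason = {
        Status.APPROPRIATE: Reason.NOT_OBESE_ACTUAL_OK,
        Status.INAPPROPRIATE: Reason.WEIGHT_KIND_MISMATCH,
        Status.EXCLUDED: Reason.EXCLUDED_LEVEL_BASED,
    }[status]
    return OrderEvaluation(
        order_id=order_id, status=status, reason=reason,
        drug=drug, department=department, month=month, phase=phase, age_band="6-11y",
    )


class TestAggregation:
    def test_single_group_counts(self):
        evs = [_ev(f"o{i}", Status.APPROPRIATE if i < 5 else Status.INAPPROPRIATE)
               for i in range(10)]
        [sub] = aggregate_proportions(evs, GroupKey.MONTH)
        assert (sub.n, sub.successes) == (10, 5)

    def test_excluded_leave_the_denominator(self):
        evs = [_ev(f"a{i}", Status.EXCLUDED) for i in range(3)] + \
              [_ev(f"b{i}", Status.APPROPRIATE) for i in range(7)]
        [sub] = aggregate_proportions(evs, GroupKey.MONTH)
        assert (sub.n, sub.successes) == (7, 7)

    def test_counts_conserved_across_groups(self):
        rng = np.random.default_rng(5)
        evs = [
            _ev(f"o{i}",
                Status.APPROPRIATE if rng.random() < 0.6 else Status.INAPPROPRIATE,
                month=f"2021-{int(rng.integers(1, 13)):02d}",
                department=["ED", "PICU", "CTICU"][rng.integers(3)])
            for i in range(200)
        ]
        for key in (GroupKey.MONTH, GroupKey.DEPARTMENT, GroupKey.DRUG):
            assert sum(s.n for s in aggregate_proportions(evs, key)) == 200

    def test_all_excluded_yields_empty(self):
        evs = [_ev(f"o{i}", Status.EXCLUDED) for i in range(4)]
        assert aggregate_proportions(evs, GroupKey.MONTH) == []


class TestPareto:
    def test_hand_worked_decomposition(self):
        evs = (
            [_ev(f"a{i}", Status.INAPPROPRIATE, department="A") for i in range(6)]
            + [_ev(f"b{i}", Status.INAPPROPRIATE, department="B") for i in range(3)]
            + [_ev("c0", Status.INAPPROPRIATE, department="C")]
            + [_ev("x0", Status.APPROPRIATE, department="A")]
        )
        rows = pareto_decomposition(evs, GroupKey.DEPARTMENT)
        assert [(r[0], r[1]) for r in rows] == [("A", 6), ("B", 3), ("C", 1)]
        assert [r[2] for r in rows] == pytest.approx([60.0, 90.0, 100.0])

    def test_single_category(self):
        rows = pareto_decomposition([_ev("o", Status.INAPPROPRIATE)], GroupKey.DRUG)
        assert rows == [("acetaminophen", 1, 100.0)]

    def test_ties_broken_lexicographically(self):
        evs = [_ev("o1", Status.INAPPROPRIATE, department="zeta"),
               _ev("o2", Status.INAPPROPRIATE, department="alpha")]
        rows = pareto_decomposition(evs, GroupKey.DEPARTMENT)
        assert [r[0] for r in rows] == ["alpha", "zeta"]

    def test_no_inappropriate_empty(self):
        assert pareto_decomposition([_ev("o", Status.APPROPRIATE)], GroupKey.DRUG) == []


class TestEventRate:
    @pytest.mark.parametrize(
        "events, reports, expected",
        [(1, 2613, 0.000383), (6, 4611, 0.001301), (0, 1000, 0.0)],
    )
    def test_rounded_rates(self, events, reports, expected):
        assert event_rate(events, reports) == expected

    def test_zero_reports_undefined(self):
        with pytest.raises(UndefinedRateError):
            event_rate(0, 0)

    def test_events_exceeding_reports_rejected(self):
        with pytest.raises(DataIntegrityError):
            event_rate(5, 3)
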