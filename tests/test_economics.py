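import numpy as np
import pytest

from nsclc_cea import units
from nsclc_cea.config import chemo_regimen, nivo_regimen
from nsclc_cea.economics import (
    AdverseEvent,
    AdverseEventProfile,
    ArmResult,
    DosingRegimen,
    DrugComponent,
    EconomicInputs,
    InfusionVisit,
    PatientProfile,
    accumulate,
    administration_cost_per_cycle,
    compute_icer,
    drug_cost_per_cycle,
    one_time_ae_burden,
    subsequent_therapy_cost,
)
from nsclc_cea.markov import CohortTrace, ModelSettings

PRICES = {
    "nivolumab": 29.345,
    "ipilimumab": 161.70,
    "pemetrexed": 7.3766,
    "cisplatin": 0.2010,
    "gemcitabine": 4.331 / 200.0,
}
PROFILE = PatientProfile(weight_kg=70.0, bsa_m2=1.86)


def econ(**kw):
    return EconomicInputs(prices_per_mg=PRICES, **kw)


class TestDrugCost:
    def test_weight_based_antibody_cost(self):
        # nivolumab 3 mg/kg x 70 kg x $29.345/mg x 3 doses per 6-week cycle
        reg = DosingRegimen((DrugComponent("nivolumab", 3.0, "per_kg", 2.0),))
        cost = drug_cost_per_cycle(reg, PROFILE, econ(), 0)
        assert cost == pytest.approx(210 * 29.345 * 3, rel=1e-12)  # 18,487.35

    def test_six_weekly_component_once_per_cycle(self):
        reg = DosingRegimen((DrugComponent("ipilimumab", 1.0, "per_kg", 6.0),))
        cost = drug_cost_per_cycle(reg, PROFILE, econ(), 5)
        assert cost == pytest.approx(70 * 161.70, rel=1e-12)  # 11,319.00

    def test_zero_dose_costs_nothing(self):
        reg = DosingRegimen((DrugComponent("nivolumab", 0.0, "per_kg", 2.0),))
        assert drug_cost_per_cycle(reg, PROFILE, econ(), 0) == 0.0

    def test_missing_price_raises(self):
        reg = DosingRegimen((DrugComponent("docetaxel", 75.0, "per_m2", 3.0),))
        with pytest.raises(KeyError):
            drug_cost_per_cycle(reg, PROFILE, econ(), 0)

    def test_induction_cap_and_maintenance_switch(self):
        reg = chemo_regimen(squamous_fraction=0.0)
        # cycles 0-1: pemetrexed+cisplatin doublet (2 doses each)
        c0 = drug_cost_per_cycle(reg, PROFILE, econ(), 0)
        doublet = 2 * (930 * 7.3766 + 139.5 * 0.2010)
        assert c0 == pytest.approx(doublet, rel=1e-12)
        # cycle 2 onward: pemetrexed maintenance only
        c2 = drug_cost_per_cycle(reg, PROFILE, econ(), 2)
        assert c2 == pytest.approx(2 * 930 * 7.3766, rel=1e-12)

    def test_squamous_mix_weights_components(self):
        all_sq = drug_cost_per_cycle(chemo_regimen(1.0), PROFILE, econ(), 0)
        no_sq = drug_cost_per_cycle(chemo_regimen(0.0), PROFILE, econ(), 0)
        mixed = drug_cost_per_cycle(chemo_regimen(0.3), PROFILE, econ(), 0)
        assert mixed == pytest.approx(0.3 * all_sq + 0.7 * no_sq, rel=1e-12)


class TestAdministrationCost:
    def test_one_hour_infusion_bills_first_hour(self):
        reg = DosingRegimen((), visits=(InfusionVisit(1.0, 6.0),))
        assert administration_cost_per_cycle(reg, econ(), 0) == pytest.approx(143.08)

    def test_two_hour_infusion_adds_additional_hour(self):
        reg = DosingRegimen((), visits=(InfusionVisit(2.0, 6.0),))
        got = administration_cost_per_cycle(reg, econ(), 0)
        assert got == pytest.approx(143.08 + 30.99)  # 174.07

    def test_no_visits_costs_nothing(self):
        reg = DosingRegimen(())
        assert administration_cost_per_cycle(reg, econ(), 0) == 0.0


class TestAdverseEventBurden:
    def test_zero_incidence_is_free(self):
        profile = AdverseEventProfile(
            (AdverseEvent("diarrhea", 0.0, 16510.0, -0.32),)
        )
        assert one_time_ae_burden(profile, units.CYCLE_YEARS) == (0.0, 0.0)

    def test_expected_cost_is_incidence_weighted(self):
        profile = AdverseEventProfile(
            (AdverseEvent("diarrhea", 0.170, 16510.0, -0.32),)
        )
        cost, _ = one_time_ae_burden(profile, units.CYCLE_YEARS)
        assert cost == pytest.approx(2806.70, rel=1e-9)

    def test_linearity_in_incidence(self):
        single = AdverseEventProfile(
            (AdverseEvent("nausea", 0.10, 2586.0, -0.25),)
        )
        double = AdverseEventProfile(
            (AdverseEvent("nausea", 0.20, 2586.0, -0.25),)
        )
        c1, q1 = one_time_ae_burden(single, units.CYCLE_YEARS)
        c2, q2 = one_time_ae_burden(double, units.CYCLE_YEARS)
        assert c2 == pytest.approx(2 * c1) and q2 == pytest.approx(2 * q1)


class TestSubsequentTherapy:
    def test_no_progression_no_cost(self):
        e = econ(subsequent_cost=8448.0, subsequent_proportion=0.56)
        assert subsequent_therapy_cost(e, 0.0) == 0.0

    def test_chemo_arm_uptake_weighting(self):
        e = econ(subsequent_cost=8448.0, subsequent_proportion=0.56)
        assert subsequent_therapy_cost(e, 0.10) == pytest.approx(473.088, rel=1e-9)

    def test_intervention_arm_uptake_weighting(self):
        e = econ(subsequent_cost=1858.0, subsequent_proportion=0.44)
        assert subsequent_therapy_cost(e, 0.10) == pytest.approx(81.752, rel=1e-9)


def _toy_trace(n_boundaries=3):
    t = np.arange(n_boundaries, dtype=float) * units.CYCLE_MONTHS
    pfs = np.array([1.0, 0.5, 0.25][:n_boundaries])
    dead = 1.0 - pfs
    return CohortTrace(t, pfs, np.zeros(n_boundaries), dead)


NO_AE = AdverseEventProfile(())
NO_DRUGS = DosingRegimen(())


class TestAccumulate:
    def test_hand_computed_toy_cohort(self):
        # two cycles, PFS occupancy 1.0 -> 0.5 -> 0.25, utility 0.71, no
        # discounting: effective occupancy (0.75, 0.375) x cycle length
        settings = ModelSettings(discount_rate=0.0, horizon_years=2 * units.CYCLE_YEARS)
        res = accumulate(_toy_trace(), econ(utility_pfs=0.71), NO_AE, NO_DRUGS, settings)
        expected_ly = (0.75 + 0.375) * units.CYCLE_YEARS
        assert res.life_years == pytest.approx(expected_ly, abs=1e-9)
        assert res.qalys == pytest.approx(0.71 * expected_ly, abs=1e-9)

    def test_zero_utilities_zero_qalys(self):
        settings = ModelSettings(discount_rate=0.0, horizon_years=2 * units.CYCLE_YEARS)
        res = accumulate(
            _toy_trace(), econ(utility_pfs=0.0, utility_pd=0.0), NO_AE, NO_DRUGS, settings
        )
        assert res.qalys == 0.0
        assert res.life_years > 0.0

    def test_full_utilities_no_discount_gives_qaly_equal_ly(self):
        settings = ModelSettings(discount_rate=0.0, horizon_years=2 * units.CYCLE_YEARS)
        res = accumulate(
            _toy_trace(), econ(utility_pfs=1.0, utility_pd=1.0), NO_AE, NO_DRUGS, settings
        )
        assert res.qalys == pytest.approx(res.life_years, abs=1e-12)

    def test_everything_free_costs_nothing(self):
        settings = ModelSettings(horizon_years=2 * units.CYCLE_YEARS)
        zero_prices = EconomicInputs(prices_per_mg={k: 0.0 for k in PRICES},
                                     admin_first_hour=0.0, admin_additional_hour=0.0)
        res = accumulate(_toy_trace(), zero_prices, NO_AE, nivo_regimen(), settings)
        assert res.cost == 0.0

    def test_higher_pfs_utility_raises_qalys(self):
        settings = ModelSettings(horizon_years=2 * units.CYCLE_YEARS)
        lo = accumulate(_toy_trace(), econ(utility_pfs=0.6), NO_AE, NO_DRUGS, settings)
        hi = accumulate(_toy_trace(), econ(utility_pfs=0.8), NO_AE, NO_DRUGS, settings)
        assert hi.qalys > lo.qalys

    def test_costs_scale_linearly_in_prices(self):
        settings = ModelSettings(horizon_years=2 * units.CYCLE_YEARS)
        single = accumulate(_toy_trace(), econ(), NO_AE, nivo_regimen(), settings)
        doubled_prices = {k: 2 * v for k, v in PRICES.items()}
        double = accumulate(
            _toy_trace(),
            EconomicInputs(prices_per_mg=doubled_prices, admin_first_hour=0.0,
                           admin_additional_hour=0.0),
            NO_AE,
            nivo_regimen(),
            settings,
        )
        drug_single = single.breakdown["drug"]
        assert double.breakdown["drug"] == pytest.approx(2 * drug_single, rel=1e-12)


class TestICER:
    def test_simple_ratio(self):
        a = ArmResult(200_000.0, 2.5, 2.0)
        b = ArmResult(100_000.0, 1.5, 1.0)
        res = compute_icer(a, b)
        assert res.icer_per_qaly == pytest.approx(100_000.0)
        assert res.dominance == ""

    def test_identical_arms_flagged_indeterminate(self):
        a = ArmResult(100_000.0, 1.5, 1.0)
        res = compute_icer(a, a)
        assert res.icer_per_qaly is None
        assert res.dominance == "indeterminate"

    def test_published_rounded_increments(self):
        # rounded incremental cost 65,218 over 0.62 QALYs
        a = ArmResult(236_795.0, 3.12, 1.88)
        b = ArmResult(171_577.0, 2.01, 1.26)
        res = compute_icer(a, b)
        assert res.icer_per_qaly == pytest.approx(105_190, rel=2e-3)

    def test_dominant_when_cheaper_and_better(self):
        a = ArmResult(90_000.0, 2.0, 1.5)
        b = ArmResult(100_000.0, 1.5, 1.0)
        assert compute_icer(a, b).dominance == "intervention_dominant"

    def test_icer_invariant_to_shared_cost_offset(self):
        a = ArmResult(200_000.0, 2.5, 2.0)
        b = ArmResult(100_000.0, 1.5, 1.0)
        shift = 25_000.0
        shifted = compute_icer(
            ArmResult(a.cost + shift, a.life_years, a.qalys),
            ArmResult(b.cost + shift, b.life_years, b.qalys),
        )
        assert shifted.icer_per_qaly == pytest.approx(compute_icer(a, b).icer_per_qaly)

    def test_qaly_cannot_exceed_life_years(self):
        with pytest.raises(ValueError):
            ArmResult(0.0, 1.0, 1.5)
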