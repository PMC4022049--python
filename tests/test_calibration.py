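"""Calibration: competing-risk incidence, the median-time rule, utility and
cost estimators, and the full registry-to-parameters orchestration."""

import numpy as np
import pandas as pd
import pytest

from gdcea.calibration import (
    CENSORED,
    DEATH,
    TRANSITION_PREFIX,
    CalibrationError,
    EmptyCurveError,
    IncidenceCurve,
    InsufficientDataError,
    Registry,
    annual_ert_cost,
    annual_hospital_cost,
    annual_outpatient_cost,
    annual_production_loss,
    annualize_transition,
    calibrate,
    cumulative_incidence_all,
    cumulative_incidence_competing,
    kaplan_meier_naive,
    mean_state_utility,
    read_registry,
    transition_summary,
    write_registry,
)
from gdcea.params import DiseaseState

S = DiseaseState.SIGNS_SYMPTOMS
BONE = TRANSITION_PREFIX + "bone_complication"
SPLEN = TRANSITION_PREFIX + "splenectomy"


def episodes_frame(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "state", "start_age", "end_age", "end_event"]
    )


class TestCumulativeIncidence:
    def test_no_competition_reduces_to_empirical_cdf(self):
        rows = [(i, S.value, 0.0, i + 1.0, BONE) for i in range(4)]
        rows += [(i, S.value, 0.0, 10.0, CENSORED) for i in range(4, 10)]
        curve = cumulative_incidence_competing(
            episodes_frame(rows), S, DiseaseState.BONE_COMPLICATION
        )
        assert curve.cif[np.searchsorted(curve.times, 4.0)] == pytest.approx(0.4)

    def test_hand_computed_competing_oracle(self):
        # 10 at risk; year 1: one competing event; year 2: one event of interest
        rows = [(0, S.value, 0.0, 1.0, SPLEN), (1, S.value, 0.0, 2.0, BONE)]
        rows += [(i, S.value, 0.0, 5.0, CENSORED) for i in range(2, 10)]
        curve = cumulative_incidence_competing(
            episodes_frame(rows), S, DiseaseState.BONE_COMPLICATION
        )
        # CIF_interest(2) = S(1) * 1/9 = (9/10) * (1/9) = 0.10
        j = np.searchsorted(curve.times, 2.0)
        assert curve.cif[j] == pytest.approx(0.10, abs=1e-12)

    def test_all_censored_gives_zero_curve(self):
        rows = [(i, S.value, 0.0, 3.0, CENSORED) for i in range(5)]
        curve = cumulative_incidence_competing(
            episodes_frame(rows), S, DiseaseState.BONE_COMPLICATION
        )
        assert np.all(curve.cif == 0.0)

    def test_no_episodes_signals_empty_curve(self):
        with pytest.raises(EmptyCurveError):
            cumulative_incidence_competing(
                episodes_frame([]), S, DiseaseState.BONE_COMPLICATION
            )

    def test_mass_conservation(self, rng):
        # destination CIFs plus the event-free fraction partition the cohort
        causes = [BONE, SPLEN, DEATH, CENSORED]
        rows = [
            (i, S.value, 0.0, float(rng.integers(1, 15)), causes[rng.integers(4)])
            for i in range(200)
        ]
        frame = episodes_frame(rows)
        curves = cumulative_incidence_all(frame, S)
        any_curve = next(iter(curves.values()))
        total = any_curve.event_free.copy()
        for curve in curves.values():
            total = total + curve.cif
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_matches_lifelines_aalen_johansen(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 120
        # unique event times: lifelines jitters ties, which would spoil
        # an exact comparison
        durations = np.sort(rng.uniform(0.5, 12.0, size=n))
        codes = rng.integers(0, 3, size=n)  # 0 censored, 1 interest, 2 competing
        cause = np.where(codes == 1, BONE, np.where(codes == 2, SPLEN, CENSORED))
        rows = [(i, S.value, 0.0, durations[i], cause[i]) for i in range(n)]
        curve = cumulative_incidence_competing(
            episodes_frame(rows), S, DiseaseState.BONE_COMPLICATION
        )
        ajf = lifelines.AalenJohansenFitter(calculate_variance=False)
        ajf.fit(durations, codes, event_of_interest=1)
        expected = ajf.cumulative_density_.iloc[:, 0]
        for t, value in zip(curve.times, curve.cif):
            assert value == pytest.approx(
                float(expected.loc[:t].iloc[-1]), abs=1e-9
            )

    def test_naive_km_overstates_competing_incidence(self):
        rows = [(0, S.value, 0.0, 1.0, SPLEN), (1, S.value, 0.0, 2.0, BONE)]
        rows += [(i, S.value, 0.0, 5.0, CENSORED) for i in range(2, 10)]
        frame = episodes_frame(rows)
        corrected = cumulative_incidence_competing(
            frame, S, DiseaseState.BONE_COMPLICATION
        )
        naive = kaplan_meier_naive(frame, S, DiseaseState.BONE_COMPLICATION)
        assert naive.cif[-1] > corrected.cif[-1]


def make_curve(times, cif, at_risk, n_start=None):
    times = np.asarray(times, dtype=float)
    cif = np.asarray(cif, dtype=float)
    return IncidenceCurve(
        times=times,
        cif=cif,
        event_free=1 - cif,
        at_risk=np.asarray(at_risk, dtype=float),
        n_start=n_start or int(at_risk[0]),
        cause=BONE,
    )


class TestTransitionSummary:
    def test_median_rule_at_exact_half(self):
        curve = make_curve([2, 4, 6, 8], [0.1, 0.3, 0.5, 0.6], [20, 15, 10, 5])
        read = transition_summary(curve)
        assert (read.p_cum, read.t_ref) == (0.5, 6.0)
        assert read.rule == "median"

    def test_median_rule_interpolates_jumps(self):
        curve = make_curve([2, 4, 6], [0.1, 0.4, 0.6], [20, 15, 10])
        read = transition_summary(curve)
        # crossing between (4, 0.4) and (6, 0.6): t = 4 + 0.5*2
        assert read.t_ref == pytest.approx(5.0)
        assert read.p_cum == 0.5

    def test_four_at_risk_rule(self):
        curve = make_curve([3, 6, 9, 12], [0.1, 0.2, 0.3, 0.3], [20, 10, 4, 2])
        read = transition_summary(curve)
        assert (read.p_cum, read.t_ref) == (0.3, 9.0)
        assert read.rule == "at_risk_4"

    def test_zero_curve_reads_zero(self):
        curve = make_curve([1, 5], [0.0, 0.0], [10, 6])
        read = transition_summary(curve)
        assert read.p_cum == 0.0
        assert annualize_transition(read.p_cum, read.t_ref) == 0.0

    def test_insufficient_risk_set(self):
        curve = make_curve([1, 2], [0.1, 0.2], [3, 2])
        with pytest.raises(InsufficientDataError):
            transition_summary(curve)


class TestAnnualize:
    @pytest.mark.parametrize(
        "p_cum,t,expected",
        [
            (0.0, 7.0, 0.0),
            (0.75, 2.0, 0.5),
            (0.5, 3.0, 1 - 0.5 ** (1 / 3)),
        ],
    )
    def test_closed_form(self, p_cum, t, expected):
        assert annualize_transition(p_cum, t) == pytest.approx(expected, abs=1e-12)

    def test_exact_inverse_of_compounding(self, rng):
        for _ in range(1000):
            p_cum = rng.uniform(0.0, 0.999)
            t = rng.uniform(1.0, 40.0)  # at least one cycle
            p = annualize_transition(p_cum, t)
            assert 1 - (1 - p) ** t == pytest.approx(p_cum, abs=1e-12)

    def test_instantaneous_transition_warns(self):
        with pytest.warns(UserWarning):
            assert annualize_transition(1.0, 5.0) == 1.0

    def test_zero_time_rejected(self):
        with pytest.raises(CalibrationError):
            annualize_transition(0.2, 0.0)


def eq5d_frame(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "age", "state", "utility", "tariff"]
    )


class TestMeanStateUtility:
    def test_single_patient_mean(self):
        frame = eq5d_frame(
            [(1, 10.0, S.value, 0.8, "UK"), (1, 10.25, S.value, 0.9, "UK")]
        )
        spec = mean_state_utility(frame, S, bootstrap_reps=0)
        assert spec.mean_u == pytest.approx(0.85)
        assert spec.lcl is None and spec.ucl is None  # CI unavailable, N = 1

    def test_two_stage_averaging_ignores_observation_counts(self):
        rows = [(1, 10 + i / 4, S.value, 0.8, "UK") for i in range(10)]
        rows += [(2, 20.0, S.value, 0.88, "UK"), (2, 20.25, S.value, 0.92, "UK")]
        spec = mean_state_utility(eq5d_frame(rows), S, bootstrap_reps=0)
        assert spec.mean_u == pytest.approx(0.85)  # not the pooled mean 0.82

    def test_duplicating_a_patients_observations_changes_nothing(self):
        rows = [(1, 10.0, S.value, 0.7, "UK"), (2, 11.0, S.value, 0.9, "UK")]
        base = mean_state_utility(eq5d_frame(rows), S, bootstrap_reps=0).mean_u
        doubled = mean_state_utility(
            eq5d_frame(rows + [(1, 10.25, S.value, 0.7, "UK")] * 3),
            S,
            bootstrap_reps=0,
        ).mean_u
        assert doubled == pytest.approx(base)

    def test_bca_interval_brackets_truth(self, rng):
        # simulation oracle: repeated cohorts from a known mean
        truth = 0.85
        hits = 0
        reps = 40
        for r in range(reps):
            rows = []
            for pid in range(25):
                mu = truth + rng.normal(0, 0.05)
                for k in range(4):
                    rows.append((pid, 10 + k / 4, S.value, mu + rng.normal(0, 0.03), "UK"))
            spec = mean_state_utility(
                eq5d_frame(rows), S, bootstrap_reps=500,
                rng=np.random.default_rng(1000 + r),
            )
            if spec.lcl is not None and spec.lcl <= truth <= spec.ucl:
                hits += 1
        assert hits / reps >= 0.8  # ~95% nominal coverage, small-sample slack


def dose_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "state", "episode_start_age", "episode_end_age",
            "vials_per_month",
        ],
    )


class TestErtCost:
    def test_constant_dose_arithmetic(self):
        frame = dose_frame([(1, S.value, 20.0, 21.0, 6.0)])
        vials, cost = annual_ert_cost(frame, S, 1985.0)
        assert vials == pytest.approx(72.0)
        assert cost == pytest.approx(142_920.0)

    def test_episode_length_weighting(self):
        frame = dose_frame(
            [(1, S.value, 20.0, 20.5, 4.0), (1, S.value, 20.5, 21.0, 8.0)]
        )
        vials, cost = annual_ert_cost(frame, S, 1985.0)
        assert vials == pytest.approx(72.0)
        assert cost == pytest.approx(142_920.0)

    def test_unequal_lengths_weighted(self):
        frame = dose_frame(
            [(1, S.value, 0.0, 3.0, 4.0), (1, S.value, 3.0, 4.0, 8.0)]
        )
        vials, _ = annual_ert_cost(frame, S, 1985.0)
        assert vials == pytest.approx(12 * (3 * 4 + 1 * 8) / 4)

    def test_zero_length_patient_excluded_with_warning(self):
        frame = dose_frame(
            [(1, S.value, 20.0, 20.0, 6.0), (2, S.value, 20.0, 21.0, 4.0)]
        )
        with pytest.warns(UserWarning, match="zero total"):
            vials, _ = annual_ert_cost(frame, S, 1985.0)
        assert vials == pytest.approx(48.0)


class TestHospitalAndOutpatientCosts:
    def test_product_sum_single_year(self):
        episodes = episodes_frame([(1, S.value, 10.0, 11.0, CENSORED)])
        procedures = pd.DataFrame(
            [
                (1, 10.2, S.value, 500.0, 1),
                (1, 10.7, S.value, 970.0, 1),
            ],
            columns=["patient_id", "age", "state", "unit_cost", "count"],
        )
        spec = annual_hospital_cost(procedures, episodes, S, bootstrap_reps=0)
        assert spec.mean_annual_cost == pytest.approx(1470.0)

    def test_annualization_over_two_years(self):
        episodes = episodes_frame([(1, S.value, 10.0, 12.0, CENSORED)])
        procedures = pd.DataFrame(
            [(1, 10.5, S.value, 2000.0, 1)],
            columns=["patient_id", "age", "state", "unit_cost", "count"],
        )
        spec = annual_hospital_cost(procedures, episodes, S, bootstrap_reps=0)
        assert spec.mean_annual_cost == pytest.approx(1000.0)

    def test_matches_brute_force_double_mean(self, rng):
        episodes, procedures = [], []
        expected = []
        for pid in range(12):
            years = float(rng.integers(1, 6))
            episodes.append((pid, S.value, 0.0, years, CENSORED))
            total = 0.0
            for _ in range(int(rng.integers(0, 8))):
                cost = float(rng.integers(50, 2000))
                procedures.append((pid, 0.5, S.value, cost, int(rng.integers(1, 3))))
                total += cost * procedures[-1][4]
            expected.append(total / years)
        spec = annual_hospital_cost(
            pd.DataFrame(
                procedures,
                columns=["patient_id", "age", "state", "unit_cost", "count"],
            ),
            episodes_frame(episodes),
            S,
            bootstrap_reps=0,
        )
        assert spec.mean_annual_cost == pytest.approx(np.mean(expected))

    def test_outpatient_times_four_rule(self):
        frame = pd.DataFrame(
            [(1, S.value, 10.0, 1, 28.0)],
            columns=["patient_id", "state", "quarter_age", "visits", "unit_cost"],
        )
        spec = annual_outpatient_cost(frame, S, bootstrap_reps=0)
        assert spec.mean_annual_cost == pytest.approx(112.0)

    def test_outpatient_zero_visits(self):
        frame = pd.DataFrame(
            [(1, S.value, 10.0, 0, 28.0), (2, S.value, 11.0, 0, 36.0)],
            columns=["patient_id", "state", "quarter_age", "visits", "unit_cost"],
        )
        spec = annual_outpatient_cost(frame, S, bootstrap_reps=0)
        assert spec.mean_annual_cost == 0.0


def work_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "state", "employed", "disabled_due_to_gd",
            "hours_per_workday", "workdays_per_week", "sick_days_per_fortnight",
        ],
    )


class TestProductionLoss:
    def test_not_employed_not_disabled_is_zero(self):
        frame = work_frame([(1, S.value, False, False, 0.0, 0.0, 0.0)])
        spec = annual_production_loss(frame, S, bootstrap_reps=0)
        assert spec.mean_annual_cost == 0.0

    def test_sick_leave_formula(self):
        frame = work_frame([(1, S.value, True, False, 8.0, 5.0, 1.0)])
        spec = annual_production_loss(frame, S, hourly_cost=30.0, bootstrap_reps=0)
        assert spec.mean_annual_cost == pytest.approx(26 * 8 * 30)

    def test_full_disability_formula(self):
        frame = work_frame(
            [
                (1, S.value, True, False, 8.0, 5.0, 0.0),
                (2, S.value, False, True, 0.0, 0.0, 0.0),
            ]
        )
        spec = annual_production_loss(frame, S, hourly_cost=30.0, bootstrap_reps=0)
        # disabled patient loses 52 * 5 * 8 * 30; employed one loses nothing
        assert spec.mean_annual_cost == pytest.approx(62_400.0 / 2)


class TestCalibrateOrchestration:
    def test_empty_registry_flags_everything_missing(self):
        result = calibrate(Registry.empty(), "no_ert", bootstrap_reps=0)
        assert not result.transitions
        assert not result.utilities
        assert len(result.missing) > 0

    def test_single_patient_registry(self):
        registry = Registry.empty()
        registry.episodes = episodes_frame([(1, S.value, 10.0, 14.0, CENSORED)])
        registry.eq5d = eq5d_frame([(1, 10.0, S.value, 0.82, "UK")])
        result = calibrate(registry, "no_ert", bootstrap_reps=200)
        spec = next(u for u in result.utilities if u.state is S)
        assert spec.mean_u == pytest.approx(0.82)
        assert spec.lcl is None  # CI flagged unavailable

    def test_registry_roundtrip(self, tmp_path, strategies, life_table):
        from gdcea.synthetic_data import SyntheticCohortSpec, simulate_registry

        spec = SyntheticCohortSpec(
            n_patients=30, truth=strategies["ert_base"], life_table=life_table,
            follow_up_years=20, seed=3,
        )
        registry, _ = simulate_registry(spec)
        write_registry(registry, tmp_path)
        back = read_registry(tmp_path)
        for name in ("episodes", "eq5d", "doses", "procedures", "outpatient", "work"):
            pd.testing.assert_frame_equal(
                getattr(registry, name).reset_index(drop=True),
                getattr(back, name).reset_index(drop=True),
                check_dtype=False,
            )
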