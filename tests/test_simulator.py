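"""Coupled simulation: path equivalence, conservation, metrics, scoring."""

import numpy as np
import pytest

from oxsa.breathing import BreathingSpec, EventAnnotation, build_pattern
from oxsa.errors import CFLError, ParameterValidationError
from oxsa.simulator import (
    SolverOptions,
    ahi_from_result,
    compute_metrics,
    run_scenario,
    run_simulation,
    scored_events,
)

NORMAL = dict(V_T=0.5, V_D=0.15, V_End=2.3, b_r=12.0)


class TestLoopEquivalence:
    def test_compiled_and_python_paths_agree(self, params):
        # the numba kernel must reproduce the reference module ops step
        # for step; short run with an apnea to exercise both regimes
        spec = BreathingSpec(
            **NORMAL,
            events=(EventAnnotation("apnea", 10.0, 10.0),),
            total_duration=30.0,
            stabilization_time=0.0,
        )
        res_py = run_scenario(spec, params, options=SolverOptions(loop="python"))
        res_nb = run_scenario(spec, params, options=SolverOptions(loop="compiled"))
        assert res_nb.P_A == pytest.approx(res_py.P_A, abs=1e-10)
        for tag in ("sa", "sv", "pv"):
            assert res_nb.compartments[tag].C_T == pytest.approx(
                res_py.compartments[tag].C_T, abs=1e-12
            )
        assert res_nb.uptake_rate == pytest.approx(res_py.uptake_rate, abs=1e-15)

    def test_curve_constants_shared_between_paths(self):
        from oxsa import _kernels, hemoglobin

        assert _kernels._ODC_A == hemoglobin.ODC_A
        assert _kernels._ODC_B == hemoglobin.ODC_B


class TestRunSimulation:
    def test_result_traces_aligned_and_finite(self, normal_result):
        n = normal_result.times.size
        assert normal_result.P_A.shape == (n,)
        for tr in normal_result.compartments.values():
            assert tr.C_d.shape == (n,)
            assert np.all((tr.S >= 0) & (tr.S <= 1))
            assert np.all(np.isfinite(tr.C_T))

    def test_near_zero_ventilation_declines_monotonically(self, params):
        # breathing with vanishing alveolar ventilation is pure consumption
        spec = BreathingSpec(V_T=0.1501, V_D=0.15, V_End=2.3, b_r=12.0,
                             total_duration=120.0, stabilization_time=0.0)
        pattern = build_pattern(spec, 0.005, include_stabilization=False)
        res = run_simulation(pattern, params)
        assert res.P_A[-1] < res.P_A[0] - 20.0
        smooth = np.convolve(res.P_A, np.ones(1000) / 1000, mode="valid")
        assert np.all(np.diff(smooth) <= 1e-9)
        sa = res.compartments["sa"].C_d
        assert sa[-1] < sa[0] * 0.7

    def test_cfl_checked_before_run(self, params):
        pattern = build_pattern(
            BreathingSpec(**NORMAL, total_duration=10.0, stabilization_time=0.0),
            dt=0.05,
            include_stabilization=False,
        )
        with pytest.raises(CFLError):
            run_simulation(pattern, params, options=SolverOptions(dt=0.05))

    def test_global_conservation_in_steady_cycle(
        self, normal_result, steady_cycle_mask, params
    ):
        # lung O2 uptake per unit time equals metabolic consumption (1%)
        mean_uptake = np.mean(normal_result.uptake_rate[steady_cycle_mask])
        assert mean_uptake == pytest.approx(params.MR_O2, rel=0.01)

    def test_snapshots_recorded_on_python_path(self, params):
        spec = BreathingSpec(**NORMAL, total_duration=20.0, stabilization_time=0.0)
        res = run_scenario(
            spec, params, options=SolverOptions(snapshot_times=(5.0, 15.0))
        )
        assert len(res.snapshots) == 2
        z, P = res.snapshots[0].z_m, res.snapshots[0].P_mmHg
        assert z.shape == P.shape == (res.options.n_slices,)
        assert np.all(np.diff(z) > 0)

    def test_heart_rate_series_accepted(self, params):
        spec = BreathingSpec(**NORMAL, total_duration=30.0, stabilization_time=0.0)
        pattern = build_pattern(spec, 0.005, include_stabilization=False)
        hr_t = np.linspace(0, 30, 31)
        hr_v = np.full(31, 80.0)
        res = run_simulation(pattern, params, hr=(hr_t, hr_v))
        assert res.Q == pytest.approx(80.0 * params.stroke_volume / 60.0)

    def test_dataframe_round_trip(self, severe_result, tmp_path):
        df = severe_result.to_dataframe()
        path = tmp_path / "ts.csv"
        df.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        assert list(back.columns) == list(df.columns)
        assert back["S_sa"].to_numpy() == pytest.approx(
            df["S_sa"].to_numpy(), abs=1e-12
        )


class TestComputeMetrics:
    def test_normal_run_has_zero_severity(self, normal_result):
        m = compute_metrics(normal_result)
        assert m.pct_decrease_saturation["sa"] == pytest.approx(0.0, abs=0.5)
        assert m.pct_reduction_mass_transfer == pytest.approx(0.0, abs=1.5)

    def test_event_minima_and_recovery_reported(self, sim_metrics):
        m = sim_metrics["mild_normal_recovery"]
        assert len(m.per_event) == 2
        for em in m.per_event:
            assert em.min_S_sa < m.normal_avg["S_sa"]
            assert em.reoxygenation_time_s > 60.0
            assert not em.overshoot

    def test_hyperventilation_recovery_faster_with_overshoot(self, sim_metrics):
        m1 = sim_metrics["mild_normal_recovery"]
        m2 = sim_metrics["mild_hyperventilation_recovery"]
        assert (
            m2.per_event[0].reoxygenation_time_s
            < 0.5 * m1.per_event[0].reoxygenation_time_s
        )
        assert m2.per_event[0].overshoot and not m1.per_event[0].overshoot

    def test_empty_normal_window_rejected(self, normal_result):
        with pytest.raises(ParameterValidationError):
            compute_metrics(normal_result, normal_window=(1e6, 2e6))

    def test_percent_decreases_positive_under_desaturation(self, sim_metrics):
        m = sim_metrics["moderate_long_apneas"]
        for key in ("sa", "sv"):
            assert m.pct_decrease_saturation[key] > 0
            assert m.pct_decrease_dissolved[key] > 0
        assert m.pct_reduction_mass_transfer > 0

    def test_metrics_serializable(self, sim_metrics):
        import json

        doc = sim_metrics["mild_normal_recovery"].to_dict()
        json.dumps(doc)


class TestEventScoring:
    def test_short_apneas_unscored(self, params):
        spec = BreathingSpec(
            **NORMAL,
            events=(
                EventAnnotation("apnea", 50.0, 20.0),
                EventAnnotation("apnea", 150.0, 5.0),
            ),
            total_duration=300.0,
        )
        res = run_scenario(spec, params)
        m = compute_metrics(res)
        scored = scored_events(m)
        assert [e.duration for e in scored] == [20.0]
        assert ahi_from_result(res, m) == pytest.approx(1 / (300 / 3600))

    def test_mild_hypopneas_fail_desaturation_criterion(self, params):
        # 50%-airflow hypopneas that desaturate < 4% score an AHI of 0
        spec = BreathingSpec(
            **NORMAL,
            events=(EventAnnotation("hypopnea", 50.0, 25.0, airflow_fraction=0.5),),
            total_duration=300.0,
        )
        res = run_scenario(spec, params)
        m = compute_metrics(res)
        assert m.per_event[0].saturation_decrease_pct < 4.0
        assert ahi_from_result(res, m) == 0.0


@pytest.fixture(scope="module")
def short_normal():
    return BreathingSpec(**NORMAL, total_duration=60.0, stabilization_time=120.0)


class TestConvergence:
    def steady_outputs(self, spec, params, **opts):
        res = run_scenario(spec, params, options=SolverOptions(**opts))
        t = res.times
        mask = (t >= 130.0) & (t <= 175.0)
        sa = res.compartments["sa"]
        return np.array(
            [np.mean(res.P_A[mask]), np.mean(sa.C_d[mask]), np.mean(sa.S[mask])]
        )

    def test_halving_dt_changes_outputs_under_0p2_percent(self, short_normal, params):
        a = self.steady_outputs(short_normal, params, dt=0.005)
        b = self.steady_outputs(short_normal, params, dt=0.0025)
        assert np.max(np.abs(b / a - 1)) < 0.002

    def test_doubling_slices_changes_outputs_under_0p5_percent(
        self, short_normal, params
    ):
        a = self.steady_outputs(short_normal, params, n_slices=40)
        b = self.steady_outputs(short_normal, params, n_slices=80)
        assert np.max(np.abs(b / a - 1)) < 0.005
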