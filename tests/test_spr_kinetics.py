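"""1:1 Langmuir simulation vs ODE oracle, global fit recovery, table I/O."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fcbind.spr_kinetics import (
    InjectionSchedule,
    LangmuirModel,
    Sensorgram,
    doubling_dilutions,
    fit_langmuir,
    kd_from_rates,
    read_sensorgram_table,
    simulate_sensorgram,
    write_sensorgram_table,
)

HEXA_FC_RATES = dict(kon=6.68e2, koff=8.39e-4)  # micromolar-KD lectin interaction


def _ode_response(model, concentration, times, t_switch):
    """Independent oracle: stiff-safe numerical integration of dR/dt."""

    def rhs(t, r):
        c = concentration if t <= t_switch else 0.0
        return model.kon * c * (model.rmax - r[0]) - model.koff * r[0]

    out = np.empty_like(times, dtype=float)
    assoc = times[times <= t_switch]
    sol_a = solve_ivp(rhs, (0, t_switch), [0.0], t_eval=assoc, rtol=1e-10, atol=1e-12)
    out[: len(assoc)] = sol_a.y[0]
    r_switch = solve_ivp(rhs, (0, t_switch), [0.0], rtol=1e-10, atol=1e-12).y[0, -1]
    dissoc = times[times > t_switch]
    if len(dissoc):
        sol_d = solve_ivp(
            lambda t, r: [-model.koff * r[0]],
            (t_switch, times[-1]),
            [r_switch],
            t_eval=dissoc,
            rtol=1e-10,
            atol=1e-12,
        )
        out[len(assoc):] = sol_d.y[0]
    return out


@pytest.mark.parametrize(
    "kon, koff, conc_factor",
    [
        (6.68e2, 8.39e-4, 10.0),
        (3.6e4, 1.58e-4, 1.0),
        (1e5, 1e-2, 0.25),
    ],
)
def test_analytic_solution_matches_ode_integration(kon, koff, conc_factor):
    model = LangmuirModel(kon=kon, koff=koff, rmax=100.0)
    conc = conc_factor * model.kd
    times = np.arange(0.0, 601.0, 5.0)
    analytic = model.response(times, conc, t_switch=300.0)
    numeric = _ode_response(model, conc, times, t_switch=300.0)
    scale = max(analytic.max(), 1e-12)
    assert np.max(np.abs(analytic - numeric)) / scale < 1e-3


def test_equilibrium_response_limits():
    model = LangmuirModel(rmax=80.0, **HEXA_FC_RATES)
    assert model.response(np.array([1e7]), model.kd, t_switch=2e7)[0] == pytest.approx(40.0, rel=1e-6)
    assert np.allclose(model.response(np.arange(0, 100.0), 0.0, t_switch=300.0), 0.0)


def test_req_monotone_in_concentration_and_bounded_by_rmax():
    model = LangmuirModel(rmax=100.0, **HEXA_FC_RATES)
    concs = np.geomspace(0.01 * model.kd, 100 * model.kd, 25)
    reqs = [model.req(c) for c in concs]
    assert all(b > a for a, b in zip(reqs, reqs[1:]))
    assert all(0 < r < 100.0 for r in reqs)


def test_dissociation_phase_strictly_decreasing_when_koff_positive():
    model = LangmuirModel(rmax=100.0, **HEXA_FC_RATES)
    sched = InjectionSchedule(concentrations=(10 * model.kd,), t_switch=300, t_end=600)
    (curve,) = simulate_sensorgram(model, sched)
    dissoc = curve.responses[curve.times > 300.0]
    assert np.all(np.diff(dissoc) < 0)


def test_noiseless_global_fit_recovers_rates_to_a_tenth_of_a_percent():
    model = LangmuirModel(rmax=100.0, **HEXA_FC_RATES)
    sched = InjectionSchedule(
        concentrations=doubling_dilutions(16 * model.kd, 6), t_switch=300, t_end=600
    )
    fit = fit_langmuir(simulate_sensorgram(model, sched), sched)
    assert fit.converged
    assert fit.kon == pytest.approx(model.kon, rel=1e-3)
    assert fit.koff == pytest.approx(model.koff, rel=1e-3)
    assert fit.rmax == pytest.approx(model.rmax, rel=1e-3)
    assert fit.kd == fit.koff / fit.kon  # derived, never independently fitted


def test_fit_of_no_dissociation_data_returns_negligible_koff():
    model = LangmuirModel(kon=1e4, koff=0.0, rmax=50.0)
    sched = InjectionSchedule(concentrations=(1e-6, 5e-7), t_switch=300, t_end=600)
    fit = fit_langmuir(simulate_sensorgram(model, sched), sched)
    assert fit.koff <= 1e-6


def test_joint_concentration_and_capacity_scaling_leaves_rates_unchanged():
    model = LangmuirModel(rmax=100.0, **HEXA_FC_RATES)
    sched = InjectionSchedule(
        concentrations=doubling_dilutions(8 * model.kd, 5), t_switch=300, t_end=600
    )
    fit1 = fit_langmuir(simulate_sensorgram(model, sched), sched)
    model2 = LangmuirModel(rmax=200.0, **HEXA_FC_RATES)
    sched2 = InjectionSchedule(
        concentrations=tuple(2 * c for c in sched.concentrations), t_switch=300, t_end=600
    )
    fit2 = fit_langmuir(simulate_sensorgram(model2, sched2), sched2)
    assert fit2.kon == pytest.approx(fit1.kon, rel=1e-6)
    assert fit2.koff == pytest.approx(fit1.koff, rel=1e-6)


def test_degenerate_all_zero_responses_raise():
    t = np.arange(0.0, 10.0)
    curve = Sensorgram(times=t, responses=np.zeros_like(t), concentration=1e-6)
    with pytest.raises(ValueError, match="degenerate"):
        fit_langmuir([curve])


def test_kd_from_rates_values_and_errors():
    assert kd_from_rates(1.0, 1.0) == 1.0
    assert kd_from_rates(6.68e2, 8.39e-4) == pytest.approx(1.26e-6, rel=5e-3)
    with pytest.raises(ValueError):
        kd_from_rates(0.0, 1.0)
    with pytest.raises(ValueError):
        kd_from_rates(1.0, -1.0)


def test_invalid_model_and_schedule_parameters_raise():
    with pytest.raises(ValueError):
        LangmuirModel(kon=-1.0, koff=1e-3, rmax=10.0)
    with pytest.raises(ValueError):
        InjectionSchedule(concentrations=(1e-6, 1e-6))
    with pytest.raises(ValueError):
        simulate_sensorgram(
            LangmuirModel(kon=1e3, koff=1e-3, rmax=10.0),
            InjectionSchedule(concentrations=(1e-6,)),
            noise_sd=-1.0,
        )


def test_sensorgram_table_round_trip(tmp_path):
    model = LangmuirModel(rmax=100.0, **HEXA_FC_RATES)
    sched = InjectionSchedule(concentrations=doubling_dilutions(1e-5, 3), t_switch=300, t_end=450, dt=5)
    curves = simulate_sensorgram(model, sched, noise_sd=0.5, seed=1)
    path = tmp_path / "curves.tsv"
    write_sensorgram_table(curves, path)
    back = read_sensorgram_table(path)
    assert len(back) == len(curves)
    by_conc = {c.concentration: c for c in back}
    for c in curves:
        assert np.allclose(by_conc[c.concentration].responses, c.responses, rtol=1e-9)


def test_table_with_unequal_time_grids_kept_per_curve(tmp_path):
    path = tmp_path / "mixed.tsv"
    path.write_text(
        "time_s\tresponse_RU\tconcentration_M\n"
        "0\t0.0\t1e-06\n1\t1.0\t1e-06\n2\t1.5\t1e-06\n"
        "0\t0.0\t2e-06\n5\t2.0\t2e-06\n"
    )
    curves = read_sensorgram_table(path)
    assert sorted(len(c.times) for c in curves) == [2, 3]


def test_empty_or_malformed_table_raises(tmp_path):
    empty = tmp_path / "empty.tsv"
    empty.write_text("")
    with pytest.raises(ValueError, match="empty"):
        read_sensorgram_table(empty)
    missing = tmp_path / "missing.tsv"
    missing.write_text("time_s\tresponse_RU\n0\t1.0\n")
    with pytest.raises(ValueError, match="concentration_M"):
        read_sensorgram_table(missing)
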