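"""Structural-model unit and property tests: fraction algebra, transit
kinetics, allometry, rate-matrix structure, mass balance and solver
agreement."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clopk.model import (
    CompartmentLayout,
    DoseEvent,
    DoseFractions,
    StructuralParams,
    allometric_scale,
    apparent_half_life,
    build_rate_matrix,
    default_params,
    fractions_from_fr,
    ktr_from_mtt,
    predict_amounts,
    predict_concentrations,
    scale_to_weight,
    terminal_half_life,
)
from clopk._analytic import fraction_arrays

DOSE = [DoseEvent(0.0, 150.0)]


# ---------------------------------------------------------------------------
# Fraction algebra
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "fr1, f_am, f_iam_pct",
    [(119.0, 0.12, 87.27), (76.8, 0.12, 86.87)],
)
def test_fraction_algebra_reference_values(fr1, f_am, f_iam_pct):
    fr = fractions_from_fr(fr1, f_am)
    assert round(100.0 * fr.F_iaM, 2) == f_iam_pct
    assert fr.F_aM == pytest.approx(f_am, abs=1e-12)


def test_fr2_solved_from_fixed_active_fraction():
    # FR2 = F_aM (1+FR1)/(1−F_aM) = 0.12·120/0.88, worked by hand
    fr = fractions_from_fr(119.0, 0.12)
    assert fr.FR2 == pytest.approx(0.12 * 120.0 / 0.88, rel=1e-12)
    assert fr.FR2 == pytest.approx(16.3636, abs=5e-4)


def test_symmetric_logit_limit():
    fr = fractions_from_fr(1.0, 1e-12)
    assert fr.F_iaM == pytest.approx(0.5, abs=1e-9)
    assert fr.F_P == pytest.approx(0.5, abs=1e-9)
    assert fr.F_aM == pytest.approx(0.0, abs=1e-9)


def test_fraction_normalization_over_random_draws(rng):
    fr1 = np.exp(rng.uniform(np.log(1e-3), np.log(1e4), size=10_000))
    f_am = rng.uniform(0.001, 0.999, size=10_000)
    F_iaM, F_aM, F_P, FR2 = fraction_arrays(fr1, f_am)
    total = F_iaM + F_aM + F_P
    assert np.max(np.abs(total - 1.0)) < 1e-12
    assert np.all((F_iaM > 0) & (F_iaM < 1))
    assert np.all((F_P > 0) & (F_P < 1))
    assert np.all(FR2 > 0)


@pytest.mark.parametrize("fr1, f_am", [(0.0, 0.12), (-1.0, 0.12),
                                       (119.0, 0.0), (119.0, 1.0)])
def test_fraction_domain_errors(fr1, f_am):
    with pytest.raises(ValueError):
        fractions_from_fr(fr1, f_am)


def test_dose_fractions_invariant_enforced():
    with pytest.raises(ValueError):
        DoseFractions(F_iaM=0.5, F_aM=0.3, F_P=0.1, FR2=1.0)  # sums to 0.9


# ---------------------------------------------------------------------------
# Transit rate, allometry, half-life
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "mtt, n, expected, tol",
    [(0.470, 2, 6.38, 0.01), (0.410, 2, 7.32, 0.01), (3.0, 2, 1.0, 1e-12)],
)
def test_transit_rate_from_mean_transit_time(mtt, n, expected, tol):
    assert ktr_from_mtt(mtt, n) == pytest.approx(expected, abs=tol)


def test_transit_rate_domain_error():
    with pytest.raises(ValueError):
        ktr_from_mtt(0.0, 2)


@pytest.mark.parametrize(
    "value, weight, exponent, expected",
    [
        (89.5, 70.0, 0.75, 89.5),
        (89.5, 140.0, 0.75, 89.5 * 2.0**0.75),  # = 150.52 to 2 dp
        (218.0, 35.0, 1.0, 109.0),
    ],
)
def test_allometric_scaling(value, weight, exponent, expected):
    assert allometric_scale(value, weight, exponent) == pytest.approx(expected)


def test_allometric_scaling_reference_rounding():
    assert round(allometric_scale(89.5, 140.0, 0.75), 2) == 150.52


def test_allometric_domain_error():
    with pytest.raises(ValueError):
        allometric_scale(89.5, -1.0, 0.75)


def test_scale_to_weight_exponents():
    p = scale_to_weight(default_params(1), 140.0)
    assert p.CL_P == pytest.approx(89.5 * 2**0.75)
    assert p.V_cP == pytest.approx(218.0 * 2.0)
    assert p.V_h == pytest.approx(1.5 * 2.0)
    assert p.Q_h == 50.0  # fixed physiological flow, not scaled


@pytest.mark.parametrize(
    "cl, v, expected, tol",
    [(89.5, 218.0, 1.69, 0.01), (89.5, 188.0, 1.46, 0.01),
     (89.5, 248.0, 1.92, 0.01), (1.0, 1.0, math.log(2.0), 1e-12)],
)
def test_apparent_half_life(cl, v, expected, tol):
    assert apparent_half_life(cl, v) == pytest.approx(expected, abs=tol)


def test_apparent_half_life_domain_error():
    with pytest.raises(ValueError):
        apparent_half_life(-1.0, 218.0)


def test_terminal_slope_close_to_apparent_half_life():
    # The recycled parent fraction F_P is <1%, so the exact terminal
    # eigenvalue half-life stays within ~2% of ln2·V/CL.
    p = default_params(1)
    assert terminal_half_life(p) == pytest.approx(
        apparent_half_life(p.CL_P, p.V_cP), rel=0.02
    )


def test_structural_params_validation():
    with pytest.raises(ValueError):
        StructuralParams(CL_P=-1.0)
    with pytest.raises(ValueError):
        StructuralParams(F_aM_fixed=1.5)
    with pytest.raises(ValueError):
        DoseEvent(0.0, -5.0)


# ---------------------------------------------------------------------------
# Rate matrix structure
# ---------------------------------------------------------------------------


def test_rate_matrix_generator_properties():
    p = default_params(1)
    A = build_rate_matrix(p)
    lay = CompartmentLayout(p.n_transit)
    off = A - np.diag(np.diag(A))
    assert np.all(off >= 0)
    assert np.all(np.diag(A) <= 0)
    # Mass accounting: excluding the cumulative-formation tracker row, every
    # column loses at most what the molecular-weight conversion removes.
    rows = [i for i in range(lay.n_states) if i != lay.sink_inactive_formed]
    colsums = A[rows, :].sum(axis=0)
    assert np.all(colsums <= 1e-12)
    fr = fractions_from_fr(p.FR1, p.F_aM_fixed)
    expected_liver_deficit = -(1.0 - p.mw_scale) * fr.F_iaM * p.Q_h / p.V_h
    assert colsums[lay.liver] == pytest.approx(expected_liver_deficit)


def test_liver_outflow_split_matches_fractions():
    p = default_params(1)
    fr = fractions_from_fr(p.FR1, p.F_aM_fixed)
    A = build_rate_matrix(p, fr)
    lay = CompartmentLayout(p.n_transit)
    kh = p.Q_h / p.V_h
    assert A[lay.central_parent, lay.liver] == pytest.approx(fr.F_P * kh)
    assert A[lay.central_metab, lay.liver] == pytest.approx(
        p.mw_scale * fr.F_iaM * kh
    )
    assert A[lay.sink_active, lay.liver] == pytest.approx(fr.F_aM * kh)
    # systemic parent returns to the liver at clearance CL_P
    assert A[lay.liver, lay.central_parent] == pytest.approx(p.CL_P / p.V_cP)


def test_ultimate_metabolite_fate():
    # With every liver passage split F_iaM:F_aM:F_P and the escaped parent
    # recycling, the ultimate metabolised split is F_iaM : F_aM.
    p = default_params(1)
    fr = fractions_from_fr(p.FR1, p.F_aM_fixed)
    amounts = predict_amounts(p, fr, DOSE, [3000.0])[0]
    lay = CompartmentLayout(p.n_transit)
    total = fr.F_iaM + fr.F_aM
    assert amounts[lay.sink_active] == pytest.approx(
        150.0 * fr.F_aM / total, rel=1e-6
    )
    assert amounts[lay.sink_inactive_formed] == pytest.approx(
        150.0 * p.mw_scale * fr.F_iaM / total, rel=1e-6
    )
    assert np.sum(amounts[lay.transient]) < 1e-6  # transients have emptied


def test_negligible_inactive_path_gives_negligible_metabolite():
    p = dataclasses.replace(default_params(1), FR1=1e-8)
    _, cm = predict_concentrations(p, None, DOSE, np.linspace(0.5, 24, 20))
    assert np.max(cm) < 1e-6  # F_iaM ~ 1e-8 of the dose


# ---------------------------------------------------------------------------
# Mass balance and non-negativity
# ---------------------------------------------------------------------------


def _conservation_error(p, fr, amounts, lay, dose=150.0):
    parent_units = (
        amounts[:, lay.depot]
        + amounts[:, lay.transit].sum(axis=1)
        + amounts[:, lay.liver]
        + amounts[:, lay.central_parent]
    )
    metab_parent_units = (
        amounts[:, lay.central_metab]
        + amounts[:, lay.peripheral_metab]
        + amounts[:, lay.sink_metab_eliminated]
    ) / p.mw_scale
    total = (
        parent_units + metab_parent_units + amounts[:, lay.sink_active]
        + amounts[:, lay.sink_other]
    )
    return np.max(np.abs(total - p.F_ref * dose) / (p.F_ref * dose))


def test_mass_balance_closes_to_1e8(rng):
    times = np.array([0.1, 0.5, 1.0, 2.0, 6.0, 12.0, 48.0, 240.0])
    for k in range(12):
        p = default_params(1)
        if k > 0:
            mult = {
                f: np.exp(rng.uniform(-np.log(3), np.log(3)))
                for f in ("CL_P", "V_cP", "MTT", "FR1", "CL_iaM", "V_c_iaM",
                          "Q_iaM", "V_p_iaM")
            }
            p = dataclasses.replace(
                p, **{f: getattr(p, f) * m for f, m in mult.items()}
            )
        fr = fractions_from_fr(p.FR1, p.F_aM_fixed)
        lay = CompartmentLayout(p.n_transit)
        amounts = predict_amounts(p, fr, DOSE, times)
        assert np.all(amounts >= -1e-10)
        assert _conservation_error(p, fr, amounts, lay) < 1e-8
        # the other-elimination slot carries no flux in this topology
        assert np.max(np.abs(amounts[:, lay.sink_other])) == 0.0
        # cumulative-formation tracker equals the metabolite system total
        tracker = amounts[:, lay.sink_inactive_formed]
        system = (
            amounts[:, lay.central_metab] + amounts[:, lay.peripheral_metab]
            + amounts[:, lay.sink_metab_eliminated]
        )
        assert np.max(np.abs(tracker - system)) < 1e-8 * 150.0


def test_mass_balance_long_time_limits():
    p = default_params(2)
    fr = fractions_from_fr(p.FR1, p.F_aM_fixed)
    lay = CompartmentLayout(p.n_transit)
    amounts = predict_amounts(p, fr, DOSE, [5000.0])[0]
    assert np.sum(amounts[lay.transient][: lay.central_metab]) < 1e-9
    expected_ca = p.mw_scale * fr.F_iaM / (1.0 - fr.F_P) * 150.0
    assert amounts[lay.sink_metab_eliminated] == pytest.approx(
        expected_ca, rel=1e-8
    )


# ---------------------------------------------------------------------------
# Solver agreement and closed-form oracles
# ---------------------------------------------------------------------------


def _perturbed(rng, study=1):
    p = default_params(study)
    mult = {
        f: np.exp(rng.uniform(-np.log(3), np.log(3)))
        for f in ("CL_P", "V_cP", "MTT", "FR1", "CL_iaM", "V_c_iaM", "Q_iaM",
                  "V_p_iaM")
    }
    return dataclasses.replace(p, **{f: getattr(p, f) * m for f, m in mult.items()})


def _assert_close(a, b, rtol):
    floor = rtol * max(np.max(np.abs(b)), 1e-12)
    assert np.max(np.abs(a - b) / np.maximum(np.abs(b), floor)) < rtol


def test_analytic_matches_matrix_exponential_over_perturbations(rng):
    times = np.array([0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0])
    for k in range(100):
        p = default_params(1) if k == 0 else _perturbed(rng)
        cp_e, cm_e = predict_concentrations(p, None, DOSE, times)
        cp_a, cm_a = predict_concentrations(p, None, DOSE, times, method="analytic")
        _assert_close(cp_a, cp_e, 1e-6)
        _assert_close(cm_a, cm_e, 1e-6)


def test_ode_matches_matrix_exponential(rng):
    times = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0])
    for k in range(10):
        p = default_params(2) if k == 0 else _perturbed(rng, study=2)
        cp_e, cm_e = predict_concentrations(p, None, DOSE, times)
        cp_o, cm_o = predict_concentrations(p, None, DOSE, times, method="ode")
        _assert_close(cp_o, cp_e, 1e-6)
        _assert_close(cm_o, cm_e, 1e-6)


def test_erlang_depot_chain_closed_form():
    # Pure chain: amount in transit stage k is D·(Ktr t)^k e^{−Ktr t}/k!,
    # hence the liver input rate is D·Ktr³ t² e^{−Ktr t}/2.
    p = default_params(1)
    lay = CompartmentLayout(p.n_transit)
    ktr = ktr_from_mtt(p.MTT, p.n_transit)
    times = np.linspace(0.05, 2.0, 15)
    amounts = predict_amounts(p, None, DOSE, times)
    for k, idx in enumerate([lay.depot, *lay.transit]):
        expected = 150.0 * (ktr * times) ** k * np.exp(-ktr * times) / math.factorial(k)
        np.testing.assert_allclose(amounts[:, idx], expected, rtol=1e-8)


def test_fast_liver_limit_matches_bateman_erlang_form():
    # With Q_h→∞, V_h→0 the liver becomes an instantaneous splitter and the
    # parent reduces to one-compartment kinetics with Erlang input of
    # F_P·D and elimination rate ke = (CL_P/V_cP)(1−F_P).
    p = dataclasses.replace(default_params(1), Q_h=2e6, V_h=1e-4)
    fr = fractions_from_fr(p.FR1, p.F_aM_fixed)
    ktr = ktr_from_mtt(p.MTT, p.n_transit)
    ke = p.CL_P / p.V_cP * (1.0 - fr.F_P)
    times = np.linspace(0.1, 12.0, 25)
    a = ktr - ke
    conv = (
        np.exp(-ke * times) / a**3
        - np.exp(-ktr * times)
        * (1.0 / a**3 + times / a**2 + times**2 / (2.0 * a))
    )
    expected_amount = fr.F_P * 150.0 * ktr**3 * conv
    expected_ng_ml = expected_amount / p.V_cP * 1000.0
    cp, _ = predict_concentrations(p, fr, DOSE, times)
    np.testing.assert_allclose(cp, expected_ng_ml, rtol=2e-4)


def test_auc_monotonicity():
    times = np.linspace(0.01, 400.0, 4000)
    parent_aucs, metab_aucs = [], []
    for clp in [40.0, 89.5, 160.0, 300.0]:
        p = dataclasses.replace(default_params(1), CL_P=clp)
        cp, _ = predict_concentrations(p, None, DOSE, times, method="analytic")
        parent_aucs.append(np.trapezoid(cp, times))
    for fr1 in [20.0, 76.8, 119.0, 400.0]:
        p = dataclasses.replace(default_params(1), FR1=fr1)
        _, cm = predict_concentrations(p, None, DOSE, times, method="analytic")
        metab_aucs.append(np.trapezoid(cm, times))
    assert np.all(np.diff(parent_aucs) < 0)
    assert np.all(np.diff(metab_aucs) > 0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    clp=st.floats(20.0, 300.0), vcp=st.floats(50.0, 600.0),
    mtt=st.floats(0.15, 2.0), fr1=st.floats(5.0, 500.0),
)
def test_concentrations_nonnegative(clp, vcp, mtt, fr1):
    p = dataclasses.replace(
        default_params(1), CL_P=clp, V_cP=vcp, MTT=mtt, FR1=fr1
    )
    times = np.linspace(0.05, 96.0, 40)
    cp, cm = predict_concentrations(p, None, DOSE, times, method="analytic")
    assert np.all(cp >= -1e-12)
    assert np.all(cm >= -1e-12)


def test_predict_interface_contracts():
    p = default_params(1)
    with pytest.raises(ValueError):
        predict_concentrations(p, None, DOSE, [2.0, 1.0])
    with pytest.raises(ValueError):
        predict_concentrations(p, None, DOSE, [1.0], method="nope")
    cp, cm = predict_concentrations(p, None, [], [1.0, 2.0])
    assert np.all(cp == 0.0) and np.all(cm == 0.0)


def test_multiple_doses_superpose():
    p = default_params(1)
    doses = [DoseEvent(0.0, 150.0), DoseEvent(12.0, 150.0, "generic")]
    times = np.array([1.0, 6.0, 13.0, 20.0, 36.0])
    cp_e, cm_e = predict_concentrations(p, None, doses, times)
    cp_a, cm_a = predict_concentrations(p, None, doses, times, method="analytic")
    np.testing.assert_allclose(cp_a, cp_e, rtol=1e-9)
    np.testing.assert_allclose(cm_a, cm_e, rtol=1e-9)
    # the generic dose carries relative bioavailability F_gen
    single, _ = predict_concentrations(p, None, DOSE, times)
    assert cp_e[0] == pytest.approx(single[0])
    assert np.all(cp_e[2:] > single[2:])
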