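"""Structural joint parent–metabolite PK model of clopidogrel (CLO) and its
inactive carboxylic-acid metabolite (CLO-CA).

The model is linear and time-invariant between dose events:

* oral depot followed by a chain of ``n_transit`` transit compartments, all
  with the same rate constant ``K_tr = (n_transit + 1) / MTT`` (Erlang-type
  absorption delay);
* a hepatic (liver) compartment of volume ``V_h`` emptied at the plasma-flow
  rate ``Q_h / V_h``.  Its outflow is partitioned by the dose fractions:
  ``F_P`` continues as systemic parent drug, ``F_iaM`` forms CLO-CA (scaled
  by the metabolite/parent molecular-weight ratio ``mw_scale``), and ``F_aM``
  forms the active thiol metabolite, which is tracked only as a cumulative
  sink.  Systemic parent drug returns to the liver at clearance ``CL_P``, so
  every parent molecule is ultimately metabolised and the terminal parent
  slope is close to ``CL_P / V_cP``;
* one-compartment disposition for the parent, two-compartment disposition
  (central + peripheral) with linear elimination for CLO-CA.

Amounts are carried in mg (parent-mass units upstream of metabolite
formation, metabolite-mass units after the ``mw_scale`` conversion).  Parent
concentrations are reported in ng/mL and metabolite concentrations in µg/mL,
matching the assay units of the bioequivalence studies the model describes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.integrate import solve_ivp

__all__ = [
    "StructuralParams",
    "DoseFractions",
    "DoseEvent",
    "CompartmentLayout",
    "fractions_from_fr",
    "ktr_from_mtt",
    "allometric_scale",
    "scale_to_weight",
    "apparent_half_life",
    "terminal_half_life",
    "build_rate_matrix",
    "predict_concentrations",
    "predict_amounts",
    "default_params",
]

# Fixed physiological / assay constants (per-70-kg reference scale).
Q_H_FIXED = 50.0  # liver plasma flow, L/h
V_H_FIXED = 1.5  # liver volume, L per 70 kg
MW_SCALE = 0.9565  # CLO-CA / CLO molecular-weight ratio applied to formation
F_AM_FIXED = 0.12  # fraction of metabolised dose forming the active thiol
REF_WEIGHT = 70.0  # kg


@dataclass(frozen=True)
class StructuralParams:
    """Population (or individual) fixed-effect parameters.

    Clearances are L/h per 70 kg, volumes L per 70 kg unless already scaled
    to an individual weight via :func:`scale_to_weight`.
    """

    CL_P: float = 89.5  # parent clearance (fixed in estimation)
    V_cP: float = 218.0  # parent central volume
    MTT: float = 0.470  # mean absorption transit time, h
    n_transit: int = 2  # number of transit compartments
    F_ref: float = 1.0  # reference-product bioavailability (fixed)
    F_gen: float = 1.08  # generic-product relative bioavailability
    FR1: float = 119.0  # logit-normal fraction parameter (inactive path)
    F_aM_fixed: float = F_AM_FIXED  # active-metabolite fraction (fixed)
    CL_iaM: float = 8.70  # metabolite clearance
    V_c_iaM: float = 23.7  # metabolite central volume
    Q_iaM: float = 10.8  # metabolite intercompartmental clearance
    V_p_iaM: float = 61.3  # metabolite peripheral volume
    Q_h: float = Q_H_FIXED  # liver plasma flow, L/h (not weight-scaled)
    V_h: float = V_H_FIXED  # liver volume, L per 70 kg
    mw_scale: float = MW_SCALE

    def __post_init__(self) -> None:
        positive = (
            "CL_P V_cP MTT F_ref F_gen FR1 CL_iaM V_c_iaM Q_iaM V_p_iaM "
            "Q_h V_h mw_scale".split()
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (isinstance(self.n_transit, (int, np.integer)) and self.n_transit >= 0):
            raise ValueError("n_transit must be a non-negative integer")
        if not 0.0 < self.F_aM_fixed < 1.0:
            raise ValueError("F_aM_fixed must lie in (0, 1)")


@dataclass(frozen=True)
class DoseFractions:
    """Partition of the metabolised dose: inactive / active / parent-escape.

    ``F_iaM + F_aM + F_P = 1``; ``FR2`` is the auxiliary logit parameter
    implied by fixing ``F_aM``.
    """

    F_iaM: float
    F_aM: float
    F_P: float
    FR2: float

    def __post_init__(self) -> None:
        for name in ("F_iaM", "F_aM", "F_P"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not self.FR2 > 0:
            raise ValueError("FR2 must be positive")
        if abs(self.F_iaM + self.F_aM + self.F_P - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")


@dataclass(frozen=True)
class DoseEvent:
    """Instantaneous oral dose into the depot compartment."""

    time: float  # h
    amount: float  # mg
    formulation: Literal["reference", "generic"] = "reference"

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise ValueError("dose amount must be positive")
        if self.time < 0:
            raise ValueError("dose time must be non-negative")


def fractions_from_fr(FR1: float, F_aM_fixed: float = F_AM_FIXED) -> DoseFractions:
    """Dose fractions from the logit parameter ``FR1`` with ``F_aM`` fixed.

    ``FR2`` is solved from ``F_aM = FR2/(1 + FR1 + FR2)``, then

    .. math::

        F_{iaM} = \\frac{FR_1}{1 + FR_1 + FR_2},\\quad
        F_{aM} = \\frac{FR_2}{1 + FR_1 + FR_2},\\quad
        F_P = \\frac{1}{1 + FR_1 + FR_2}.
    """
    if not FR1 > 0:
        raise ValueError("FR1 must be strictly positive")
    if not 0.0 < F_aM_fixed < 1.0:
        raise ValueError("F_aM_fixed must lie in (0, 1)")
    FR2 = F_aM_fixed * (1.0 + FR1) / (1.0 - F_aM_fixed)
    denom = 1.0 + FR1 + FR2
    return DoseFractions(
        F_iaM=FR1 / denom, F_aM=FR2 / denom, F_P=1.0 / denom, FR2=FR2
    )


def ktr_from_mtt(MTT: float, n_transit: int = 2) -> float:
    """Transit rate constant ``(n_transit + 1)/MTT`` in 1/h."""
    if not MTT > 0:
        raise ValueError("MTT must be strictly positive")
    if n_transit < 0:
        raise ValueError("n_transit must be non-negative")
    return (n_transit + 1) / MTT


def allometric_scale(value_70: float, weight: float, exponent: float) -> float:
    """Scale a per-70-kg parameter to ``weight`` kg: ``value·(WT/70)^exp``."""
    if not weight > 0:
        raise ValueError("weight must be strictly positive")
    return value_70 * (weight / REF_WEIGHT) ** exponent


def scale_to_weight(p: StructuralParams, weight: float) -> StructuralParams:
    """Apply allometric scaling: exponent 0.75 for clearances, 1 for volumes.

    ``Q_h`` is a fixed physiological flow and is left unscaled.
    """
    return replace(
        p,
        CL_P=allometric_scale(p.CL_P, weight, 0.75),
        CL_iaM=allometric_scale(p.CL_iaM, weight, 0.75),
        Q_iaM=allometric_scale(p.Q_iaM, weight, 0.75),
        V_cP=allometric_scale(p.V_cP, weight, 1.0),
        V_c_iaM=allometric_scale(p.V_c_iaM, weight, 1.0),
        V_p_iaM=allometric_scale(p.V_p_iaM, weight, 1.0),
        V_h=allometric_scale(p.V_h, weight, 1.0),
    )


def apparent_half_life(CL: float, V: float) -> float:
    """Headline apparent half-life ``ln2·V/CL`` (h).

    This is the reporting convention for the parent drug (CL and V being the
    parent clearance and central volume); the exact terminal slope of the
    full system, which also reflects the small recycled fraction ``F_P``, is
    available from :func:`terminal_half_life`.
    """
    if not (CL > 0 and V > 0):
        raise ValueError("CL and V must be strictly positive")
    return math.log(2.0) * V / CL


def terminal_half_life(p: StructuralParams, fr: DoseFractions | None = None) -> float:
    """Half-life of the slowest eigenvalue of the parent disposition block."""
    if fr is None:
        fr = fractions_from_fr(p.FR1, p.F_aM_fixed)
    kh = p.Q_h / p.V_h
    kret = p.CL_P / p.V_cP
    # roots of s^2 + (kh+kret) s + kh*kret*(1-F_P)
    b = kh + kret
    c = kh * kret * (1.0 - fr.F_P)
    slow = (b - math.sqrt(b * b - 4.0 * c)) / 2.0
    return math.log(2.0) / slow


# ---------------------------------------------------------------------------
# Compartment layout and rate matrix
# ---------------------------------------------------------------------------


class CompartmentLayout:
    """Index map for the state vector of the linear system.

    Transient compartments: depot, ``n_transit`` transit compartments, liver,
    parent central, metabolite central, metabolite peripheral.  Bookkeeping
    states: cumulative inactive-metabolite formed (metabolite-mass units),
    active-metabolite sink, an other-elimination sink (zero flux under the
    implemented topology; kept so alternative liver wirings remain
    expressible), and cumulative metabolite eliminated.
    """

    def __init__(self, n_transit: int = 2):
        self.n_transit = int(n_transit)
        self.depot = 0
        self.transit = list(range(1, 1 + self.n_transit))
        self.liver = 1 + self.n_transit
        self.central_parent = self.liver + 1
        self.central_metab = self.liver + 2
        self.peripheral_metab = self.liver + 3
        self.sink_inactive_formed = self.liver + 4
        self.sink_active = self.liver + 5
        self.sink_other = self.liver + 6
        self.sink_metab_eliminated = self.liver + 7
        self.n_states = self.liver + 8
        self.transient = list(range(self.liver + 4))


def build_rate_matrix(p: StructuralParams, fr: DoseFractions | None = None) -> np.ndarray:
    """First-order rate matrix ``A`` with ``dx/dt = A·x`` between doses.

    Off-diagonal entries are non-negative and diagonal entries non-positive
    (generator property on the transient block).  The liver outflow
    ``Q_h/V_h`` is split by the dose fractions; the inactive-metabolite flux
    is multiplied by ``mw_scale`` on entry into the metabolite central
    compartment (and into its cumulative-formation tracker).
    """
    if fr is None:
        fr = fractions_from_fr(p.FR1, p.F_aM_fixed)
    lay = CompartmentLayout(p.n_transit)
    A = np.zeros((lay.n_states, lay.n_states))
    ktr = ktr_from_mtt(p.MTT, p.n_transit)

    chain = [lay.depot, *lay.transit, lay.liver]
    for src, dst in zip(chain[:-1], chain[1:]):
        A[src, src] -= ktr
        A[dst, src] += ktr

    kh = p.Q_h / p.V_h
    A[lay.liver, lay.liver] -= kh
    A[lay.central_parent, lay.liver] += fr.F_P * kh
    A[lay.central_metab, lay.liver] += p.mw_scale * fr.F_iaM * kh
    A[lay.sink_inactive_formed, lay.liver] += p.mw_scale * fr.F_iaM * kh
    A[lay.sink_active, lay.liver] += fr.F_aM * kh

    kret = p.CL_P / p.V_cP
    A[lay.central_parent, lay.central_parent] -= kret
    A[lay.liver, lay.central_parent] += kret

    k20 = p.CL_iaM / p.V_c_iaM
    k23 = p.Q_iaM / p.V_c_iaM
    k32 = p.Q_iaM / p.V_p_iaM
    A[lay.central_metab, lay.central_metab] -= k20 + k23
    A[lay.peripheral_metab, lay.central_metab] += k23
    A[lay.central_metab, lay.peripheral_metab] += k32
    A[lay.peripheral_metab, lay.peripheral_metab] -= k32
    A[lay.sink_metab_eliminated, lay.central_metab] += k20
    return A


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def _dose_bioavailability(p: StructuralParams, dose: DoseEvent) -> float:
    if dose.formulation == "reference":
        return p.F_ref
    if dose.formulation == "generic":
        return p.F_gen
    raise ValueError(f"unknown formulation {dose.formulation!r}")


def predict_amounts(
    p: StructuralParams,
    fr: DoseFractions | None,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    method: Literal["matrix_exp", "ode"] = "matrix_exp",
) -> np.ndarray:
    """Amounts in every compartment at ``times`` (rows: time, cols: state).

    Doses are instantaneous depot inputs of ``F·amount``; ``times`` must be
    sorted and non-negative.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    if times.size and times[0] < 0:
        raise ValueError("times must be non-negative")
    if fr is None:
        fr = fractions_from_fr(p.FR1, p.F_aM_fixed)
    lay = CompartmentLayout(p.n_transit)
    A = build_rate_matrix(p, fr)

    events = sorted(doses, key=lambda d: d.time)
    out = np.zeros((times.size, lay.n_states))

    if method == "matrix_exp":
        x = np.zeros(lay.n_states)
        t_cur = 0.0
        ei = 0
        for j, t in enumerate(times):
            while ei < len(events) and events[ei].time <= t:
                dt = events[ei].time - t_cur
                if dt > 0:
                    x = expm(A * dt) @ x
                x[lay.depot] += _dose_bioavailability(p, events[ei]) * events[ei].amount
                t_cur = events[ei].time
                ei += 1
            dt = t - t_cur
            if dt > 0:
                x = expm(A * dt) @ x
                t_cur = t
            out[j] = x
        return out
    if method == "ode":
        x = np.zeros(lay.n_states)
        t_cur = 0.0
        ei = 0

        def rhs(t, y):
            return A @ y

        def advance(x, t0, t1):
            if t1 <= t0:
                return x
            sol = solve_ivp(
                rhs, (t0, t1), x, method="LSODA", rtol=1e-12, atol=1e-16
            )
            if not sol.success:  # pragma: no cover - LSODA on linear systems
                raise RuntimeError(f"ODE integration failed: {sol.message}")
            return sol.y[:, -1]

        for j, t in enumerate(times):
            while ei < len(events) and events[ei].time <= t:
                x = advance(x, t_cur, events[ei].time)
                x[lay.depot] += _dose_bioavailability(p, events[ei]) * events[ei].amount
                t_cur = max(t_cur, events[ei].time)
                ei += 1
            x = advance(x, t_cur, t)
            t_cur = max(t_cur, t)
            out[j] = x
        return out
    raise ValueError(f"unknown method {method!r}")


def predict_concentrations(
    p: StructuralParams,
    fr: DoseFractions | None,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    method: Literal["matrix_exp", "ode", "analytic"] = "matrix_exp",
) -> tuple[np.ndarray, np.ndarray]:
    """Parent (ng/mL) and metabolite (µg/mL) concentration series.

    Parent: ``A_central_parent / V_cP`` in mg/L (= µg/mL) × 1000 → ng/mL.
    Metabolite: ``A_central_metab / V_c_iaM`` in mg/L = µg/mL.
    """
    if method == "analytic":
        from ._analytic import predict_concentrations_analytic

        return predict_concentrations_analytic(p, fr, doses, times)
    amounts = predict_amounts(p, fr, doses, times, method=method)
    lay = CompartmentLayout(p.n_transit)
    parent_ng_ml = amounts[:, lay.central_parent] / p.V_cP * 1000.0
    metab_ug_ml = amounts[:, lay.central_metab] / p.V_c_iaM
    return parent_ng_ml, metab_ug_ml


def default_params(study: int = 1) -> StructuralParams:
    """Package default population parameters for each study arm."""
    if study == 1:
        return StructuralParams()
    if study == 2:
        return StructuralParams(MTT=0.410, F_gen=0.960, FR1=76.8)
    raise ValueError("study must be 1 or 2")
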