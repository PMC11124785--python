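"""Nonlinear mixed-effects estimation for the joint parent–metabolite model.

The marginal likelihood of each subject's data over their random effects is
approximated by the Laplace method at the empirical-Bayes mode (exact
finite-difference eta Hessian, 2π constants included), and the resulting
objective function value (OFV = −2 log marginal likelihood) is minimised
over the population parameters on a log-transformed scale.

Random effects per subject (diagonal covariance):

====  =================  ======================================
idx   effect             applies to
====  =================  ======================================
0     eta_V_cP           parent central volume (IIV)
1     eta_V_c_iaM        metabolite central volume (IIV)
2     eta_FR1            fraction parameter (IIV, study-specific SD)
3     eta_F              bioavailability (IIV, study-specific SD)
4,5   kappa_F[occ]       bioavailability (IOV per occasion)
6,7   kappa_MTT[occ]     mean transit time (IOV per occasion)
====  =================  ======================================

Every likelihood evaluation is vectorised over a batch of parameter/eta
variants, so finite-difference gradients and Hessians cost a single call to
the closed-form prediction engine.  During outer gradient, covariance and
SIR evaluations the empirical-Bayes modes are frozen at their current
values (they are refreshed at every objective evaluation), the usual
approximation in FOCE-type implementations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from ._analytic import unit_bolus_profiles

__all__ = [
    "ParameterSpec",
    "FitResult",
    "SubjectData",
    "default_parameter_spec",
    "build_subjects",
    "subject_loglik",
    "ebe",
    "ofv_laplace",
    "fit",
    "THETA_NAMES",
    "OMEGA_NAMES",
    "SIGMA_NAMES",
    "FIXED_DEFAULTS",
    "ETA_NAMES",
]

THETA_NAMES = [
    "V_cP", "CL_iaM", "V_c_iaM", "Q_iaM", "V_p_iaM",
    "MTT_st1", "MTT_st2", "F_gen_st1", "F_gen_st2", "FR1_st1", "FR1_st2",
]
OMEGA_NAMES = [
    "om_V_cP", "om_V_c_iaM", "om_FR1_st1", "om_FR1_st2",
    "om_F_st1", "om_F_st2", "ov_F_st1", "ov_F_st2",
    "ov_MTT_st1", "ov_MTT_st2",
]
SIGMA_NAMES = ["sigma_st1", "sigma_st2"]
FIXED_DEFAULTS = {
    "CL_P": 89.5, "Q_h": 50.0, "V_h": 1.5, "F_aM": 0.12, "F_ref": 1.0,
    "mw_scale": 0.9565,
}
DEFAULT_ESTIMATES = {
    "V_cP": 218.0, "CL_iaM": 8.70, "V_c_iaM": 23.7, "Q_iaM": 10.8,
    "V_p_iaM": 61.3, "MTT_st1": 0.470, "MTT_st2": 0.410,
    "F_gen_st1": 1.08, "F_gen_st2": 0.960, "FR1_st1": 119.0,
    "FR1_st2": 76.8,
    "om_V_cP": 0.4582, "om_V_c_iaM": 0.2506, "om_FR1_st1": 0.7280,
    "om_FR1_st2": 0.2786, "om_F_st1": 0.4266, "om_F_st2": 0.2588,
    "ov_F_st1": 0.0883, "ov_F_st2": 0.2324, "ov_MTT_st1": 0.2544,
    "ov_MTT_st2": 0.2748, "sigma_st1": 0.4195, "sigma_st2": 0.2939,
}
PARAM_ORDER = THETA_NAMES + OMEGA_NAMES + SIGMA_NAMES
ETA_NAMES = [
    "eta_V_cP", "eta_V_c_iaM", "eta_FR1", "eta_F",
    "kappa_F_occ1", "kappa_F_occ2", "kappa_MTT_occ1", "kappa_MTT_occ2",
]
N_ETA = len(ETA_NAMES)
_MIN_SD = 1e-10  # SDs below this are treated as structurally absent effects
_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Parameter specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterSpec:
    """Initial values, fixed mask and transforms for the estimation problem."""

    values: dict
    fixed: frozenset = frozenset(FIXED_DEFAULTS)
    transforms: dict = field(default_factory=dict)  # name -> "log" | "none"

    def __post_init__(self) -> None:
        for name in PARAM_ORDER:
            if name not in self.values:
                raise ValueError(f"missing initial value for {name}")
            if not np.isfinite(self.values[name]):
                raise ValueError(f"non-finite initial value for {name}")
        for name in FIXED_DEFAULTS:
            if name not in self.values:
                raise ValueError(f"missing fixed value for {name}")

    @property
    def free_names(self) -> list:
        return [n for n in PARAM_ORDER if n not in self.fixed]

    def _tf(self, name: str) -> str:
        return self.transforms.get(name, "log")

    def _scale(self, name: str) -> float:
        # native-scale entries are optimised in units of their initial value
        # so the problem stays well conditioned
        v = abs(self.values[name])
        return v if v > 0 else 1.0

    def pack(self, values: Mapping[str, float]) -> np.ndarray:
        out = []
        for n in self.free_names:
            v = values[n]
            out.append(np.log(v) if self._tf(n) == "log" else v / self._scale(n))
        return np.asarray(out)

    def unpack(self, x: np.ndarray) -> dict:
        vals = dict(self.values)
        for n, xi in zip(self.free_names, x):
            vals[n] = (
                float(np.exp(xi)) if self._tf(n) == "log"
                else float(xi * self._scale(n))
            )
        return vals

    def bounds(self) -> list:
        return [
            (None, None) if self._tf(n) == "log"
            else (1e-10 / self._scale(n), None)
            for n in self.free_names
        ]


def default_parameter_spec(
    jitter: float = 0.0,
    seed: int | None = None,
    extra_fixed: Iterable[str] = (),
    overrides: Mapping[str, float] | None = None,
) -> ParameterSpec:
    """Spec with package default initial values, optionally jittered ±``jitter``.

    ``extra_fixed`` can pin additional entries (e.g. all omegas and sigmas
    for a pooled, variability-free fit); ``overrides`` replaces initial
    values after jittering.
    """
    values = dict(DEFAULT_ESTIMATES)
    fixed = frozenset(FIXED_DEFAULTS) | frozenset(extra_fixed)
    if jitter:
        rng = np.random.default_rng(seed)
        for n in PARAM_ORDER:
            if n not in fixed:
                values[n] *= 1.0 + rng.uniform(-jitter, jitter)
    if overrides:
        values.update(overrides)
    values.update({k: values.get(k, v) for k, v in FIXED_DEFAULTS.items()})
    for k, v in FIXED_DEFAULTS.items():
        values.setdefault(k, v)
    return ParameterSpec(values=values, fixed=fixed)


# ---------------------------------------------------------------------------
# Dataset preparation
# ---------------------------------------------------------------------------


@dataclass
class OccasionData:
    form: str  # 'R' or 'T'
    dose_mg: float
    times: np.ndarray  # observation times (h), both analytes interleaved
    dv: np.ndarray
    dvid: np.ndarray  # 1 parent, 2 metabolite


@dataclass
class SubjectData:
    subject_id: int
    study: int
    weight: float
    occasions: list

    @property
    def n_obs(self) -> int:
        return sum(o.times.size for o in self.occasions)


def build_subjects(dataset: pd.DataFrame) -> list:
    """Group retained observations into per-subject, per-occasion arrays."""
    subjects = []
    obs = dataset[(dataset["EVID"] == 0) & (dataset["MDV"] == 0)]
    for (sid,), grp in obs.groupby(["ID"])[obs.columns]:
        study = int(grp["STUDY"].iloc[0])
        weight = float(grp["WT"].iloc[0])
        occasions = []
        for occ in sorted(grp["OCC"].unique()):
            g = grp[grp["OCC"] == occ].sort_values(["TIME", "DVID"])
            dose_rows = dataset[
                (dataset["ID"] == sid) & (dataset["OCC"] == occ)
                & (dataset["EVID"] == 1)
            ]
            if len(dose_rows) != 1:
                raise ValueError(
                    f"subject {sid} occasion {occ}: expected exactly one dose row"
                )
            occasions.append(
                OccasionData(
                    form=str(g["FORM"].iloc[0]),
                    dose_mg=float(dose_rows["AMT"].iloc[0]),
                    times=g["TIME"].to_numpy(dtype=float),
                    dv=g["DV"].to_numpy(dtype=float),
                    dvid=g["DVID"].to_numpy(dtype=int),
                )
            )
        subjects.append(SubjectData(int(sid), study, weight, occasions))
    return subjects


# ---------------------------------------------------------------------------
# Random-effect bookkeeping
# ---------------------------------------------------------------------------


def omega_sd_vector(values: Mapping[str, float], study: int) -> np.ndarray:
    """Diagonal SDs of the 8 random effects for a subject of ``study``."""
    s = f"st{study}"
    return np.array([
        values["om_V_cP"], values["om_V_c_iaM"], values[f"om_FR1_{s}"],
        values[f"om_F_{s}"], values[f"ov_F_{s}"], values[f"ov_F_{s}"],
        values[f"ov_MTT_{s}"], values[f"ov_MTT_{s}"],
    ])


def _study_suffixed(values: Mapping, name: str, study: int):
    return values[f"{name}_st{study}"]


# ---------------------------------------------------------------------------
# Batched conditional likelihood
# ---------------------------------------------------------------------------


def _as_batch(v, B: int) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    return np.broadcast_to(a, (B,)) if a.ndim == 0 else a


def _predict_subject(values_b: Mapping, subj: SubjectData, eta: np.ndarray):
    """Model predictions for every retained observation of ``subj``.

    ``values_b`` maps parameter names to scalars or (B,) arrays; ``eta`` is
    (B, 8).  Returns (B, n_obs) predictions in observation units.
    """
    eta = np.atleast_2d(eta)
    B = max(eta.shape[0], max(
        (np.size(v) for v in values_b.values() if np.ndim(v) > 0), default=1
    ))
    eta = np.broadcast_to(eta, (B, N_ETA))
    st = subj.study
    wv = subj.weight / 70.0
    wc = wv ** 0.75
    parts = []
    for o, occ in enumerate(subj.occasions):
        F_form = (
            _as_batch(values_b["F_ref"], B)
            if occ.form == "R"
            else _as_batch(_study_suffixed(values_b, "F_gen", st), B)
        )
        F_i = F_form * np.exp(eta[:, 3] + eta[:, 4 + o])
        pars = {
            "dose": F_i * occ.dose_mg,
            "CL_P": _as_batch(values_b["CL_P"], B) * wc,
            "V_cP": _as_batch(values_b["V_cP"], B) * np.exp(eta[:, 0]) * wv,
            "MTT": _as_batch(_study_suffixed(values_b, "MTT", st), B)
                   * np.exp(eta[:, 6 + o]),
            "FR1": _as_batch(_study_suffixed(values_b, "FR1", st), B)
                   * np.exp(eta[:, 2]),
            "F_aM": _as_batch(values_b["F_aM"], B),
            "CL_iaM": _as_batch(values_b["CL_iaM"], B) * wc,
            "V_c_iaM": _as_batch(values_b["V_c_iaM"], B) * np.exp(eta[:, 1]) * wv,
            "Q_iaM": _as_batch(values_b["Q_iaM"], B) * wc,
            "V_p_iaM": _as_batch(values_b["V_p_iaM"], B) * wv,
            "Q_h": _as_batch(values_b["Q_h"], B),
            "V_h": _as_batch(values_b["V_h"], B) * wv,
            "mw_scale": _as_batch(values_b["mw_scale"], B),
        }
        cp, cm = unit_bolus_profiles(pars, occ.times)
        parts.append(np.where(occ.dvid[None, :] == 1, cp, cm))
    return np.hstack(parts)


def _g_batch(values_b: Mapping, subj: SubjectData, eta: np.ndarray) -> np.ndarray:
    """−2·(conditional log-likelihood + eta log-prior), batched → (B,).

    Proportional residual error: Var = (sigma_study · f)².  Random-effect
    dimensions whose SD is structurally zero contribute no prior term.
    """
    eta = np.atleast_2d(eta)
    pred = _predict_subject(values_b, subj, eta)
    B = pred.shape[0]
    y = np.hstack([o.dv for o in subj.occasions])[None, :]
    sigma = _as_batch(_study_suffixed(values_b, "sigma", subj.study), B)[:, None]
    f = np.maximum(pred, 1e-12)
    var = (sigma * f) ** 2
    g = np.sum((y - pred) ** 2 / var + np.log(var) + _LOG2PI, axis=1)

    omega_cols = np.stack(
        [
            _as_batch(v, B)
            for v in _omega_columns(values_b, subj.study)
        ],
        axis=1,
    )
    active = omega_cols > _MIN_SD
    with np.errstate(divide="ignore", invalid="ignore"):
        prior = np.where(
            active,
            (np.broadcast_to(eta, (B, N_ETA)) / np.where(active, omega_cols, 1.0)) ** 2
            + 2.0 * np.log(np.where(active, omega_cols, 1.0))
            + _LOG2PI,
            0.0,
        )
    g = g + prior.sum(axis=1)
    return np.where(np.isfinite(g), g, 1e12)


def _omega_columns(values_b: Mapping, study: int) -> list:
    s = f"st{study}"
    return [
        values_b["om_V_cP"], values_b["om_V_c_iaM"], values_b[f"om_FR1_{s}"],
        values_b[f"om_F_{s}"], values_b[f"ov_F_{s}"], values_b[f"ov_F_{s}"],
        values_b[f"ov_MTT_{s}"], values_b[f"ov_MTT_{s}"],
    ]


def subject_loglik(
    subj: SubjectData, values: Mapping[str, float], eta: np.ndarray
) -> float:
    """Conditional log-likelihood of one subject's data plus the eta prior."""
    return -0.5 * float(_g_batch(values, subj, np.asarray(eta, dtype=float))[0])


# ---------------------------------------------------------------------------
# Empirical Bayes estimates and Laplace OFV
# ---------------------------------------------------------------------------


def _active_mask(values: Mapping[str, float], study: int) -> np.ndarray:
    return omega_sd_vector(values, study) > _MIN_SD


def ebe(
    subj: SubjectData,
    values: Mapping[str, float],
    eta0: np.ndarray | None = None,
    gtol: float = 1e-5,
    multistart: bool = False,
) -> tuple[np.ndarray, dict]:
    """Mode of the penalized conditional likelihood over the subject's etas.

    Quasi-Newton (BFGS) with batched forward-difference gradients, started
    from zero (and from ``eta0`` when supplied; with ``multistart`` also
    from a small deterministic off-zero point as a local-minimum guard).
    Returns the full 8-vector (inactive dimensions zero) and solver info.
    """
    mask = _active_mask(values, subj.study)
    d = int(mask.sum())
    if d == 0:
        return np.zeros(N_ETA), {"converged": True, "nit": 0, "g": float(_g_batch(values, subj, np.zeros((1, N_ETA)))[0])}
    h = 1e-5

    def fun_grad(x: np.ndarray):
        etas = np.zeros((2 * d + 1, N_ETA))
        etas[:, mask] = x[None, :]
        etas[1:1 + d, mask] += np.eye(d) * h
        etas[1 + d:, mask] -= np.eye(d) * h
        vals = _g_batch(values, subj, etas)
        return vals[0], (vals[1:1 + d] - vals[1 + d:]) / (2.0 * h)

    starts = [np.zeros(d)]
    if eta0 is not None and np.any(eta0):
        starts.insert(0, np.asarray(eta0)[mask])
    if multistart:
        starts.append(np.full(d, 0.3))
    best = None
    for x0 in starts:
        res = optimize.minimize(
            fun_grad, x0, jac=True, method="BFGS",
            options={"gtol": gtol, "maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not best.success and best.fun >= 1e12:  # pragma: no cover
        warnings.warn(f"EBE search failed for subject {subj.subject_id}")
    eta_hat = np.zeros(N_ETA)
    eta_hat[mask] = best.x
    # status 2 (precision loss) means the iterate reached the noise floor of
    # the finite-difference gradient, which is convergence for our purposes
    converged = bool(best.success) or getattr(best, "status", None) == 2
    return eta_hat, {"converged": converged, "nit": int(best.nit),
                     "g": float(best.fun)}


def _hessian_offsets(d: int, h) -> tuple[np.ndarray, list]:
    """Evaluation offsets for a central-difference Hessian in d dimensions.

    ``h`` may be a scalar or a per-dimension step vector.
    """
    h = np.broadcast_to(np.asarray(h, dtype=float), (d,))
    pts = [np.zeros(d)]
    for i in range(d):
        for s in (h[i], -h[i]):
            e = np.zeros(d); e[i] = s
            pts.append(e)
    pairs = []
    for i in range(d):
        for j in range(i + 1, d):
            pairs.append((i, j))
            for si, sj in ((h[i], h[j]), (h[i], -h[j]),
                           (-h[i], h[j]), (-h[i], -h[j])):
                e = np.zeros(d); e[i] = si; e[j] = sj
                pts.append(e)
    return np.array(pts), pairs


def _assemble_hessian(vals: np.ndarray, d: int, h, pairs: list) -> np.ndarray:
    h = np.broadcast_to(np.asarray(h, dtype=float), (d,))
    H = np.empty((d, d))
    base = vals[0]
    for i in range(d):
        fp, fm = vals[1 + 2 * i], vals[2 + 2 * i]
        H[i, i] = (fp - 2.0 * base + fm) / h[i]**2
    off = 1 + 2 * d
    for idx, (i, j) in enumerate(pairs):
        fpp, fpm, fmp, fmm = vals[off + 4 * idx: off + 4 * idx + 4]
        H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _logdet_psd(H: np.ndarray, label: str = "eta Hessian") -> float:
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        evals = np.linalg.eigvalsh(H)
        ridge = abs(evals.min()) + 1e-6
        warnings.warn(f"singular/indefinite {label}; ridge-regularized")
        sign, logdet = np.linalg.slogdet(H + ridge * np.eye(H.shape[0]))
    return logdet


def _stencil_eval(
    values_b: Mapping, subj: SubjectData, centers: np.ndarray,
    full_offsets: np.ndarray,
) -> np.ndarray:
    """Evaluate g on a per-variant stencil: centers (V, 8) + offsets (n_pts, 8)."""
    V = centers.shape[0]
    n_pts = full_offsets.shape[0]
    etas = np.repeat(centers, n_pts, axis=0) + np.tile(full_offsets, (V, 1))
    vb = {
        k: (np.repeat(np.asarray(v, dtype=float), n_pts) if np.ndim(v) > 0 else v)
        for k, v in values_b.items()
    }
    return _g_batch(vb, subj, etas).reshape(V, n_pts)


def _grad_offsets(d: int, h: float) -> np.ndarray:
    pts = [np.zeros(d)]
    for i in range(d):
        for s in (h, -h):
            e = np.zeros(d)
            e[i] = s
            pts.append(e)
    return np.array(pts)


def _subject_ofv_batch(
    values_b: Mapping, subj: SubjectData, eta_hat: np.ndarray,
    hess_h: float = 1e-3, refine: int = 1, H0: np.ndarray | None = None,
    return_hessian: bool = False,
):
    """Laplace −2·log marginal likelihood contributions for V parameter variants.

    ``values_b`` maps names to (V,) arrays (or scalars).  Starting from the
    shared mode ``eta_hat``, each variant's mode is re-centred by ``refine``
    Newton steps (gradient and Hessian come from the same finite-difference
    stencil as the Laplace determinant), and a final second-order correction
    ``−½ ∇gᵀH⁻¹∇g`` absorbs any residual mode offset.  This keeps parameter
    gradients of the OFV accurate without a per-variant inner optimisation.
    When a base-mode Hessian ``H0`` is supplied, the first re-centring pass
    uses a cheap gradient-only stencil with that Hessian.
    """
    V = max((np.size(v) for v in values_b.values() if np.ndim(v) > 0), default=1)
    base_vals = {k: (np.asarray(v).reshape(-1)[0] if np.ndim(v) > 0 else v)
                 for k, v in values_b.items()}
    mask = _active_mask(base_vals, subj.study)
    d = int(mask.sum())
    if d == 0:
        eta_b = np.broadcast_to(eta_hat, (V, N_ETA))
        out = _g_batch(values_b, subj, eta_b)
        return (out, None) if return_hessian else out

    offsets, pairs = _hessian_offsets(d, hess_h)
    full_offsets = np.zeros((offsets.shape[0], N_ETA))
    full_offsets[:, mask] = offsets
    centers = np.tile(eta_hat, (V, 1))

    if H0 is not None and refine >= 1:
        goff = _grad_offsets(d, hess_h)
        fullg = np.zeros((goff.shape[0], N_ETA))
        fullg[:, mask] = goff
        vals_g = _stencil_eval(values_b, subj, centers, fullg)
        grads_g = (vals_g[:, 1::2] - vals_g[:, 2::2]) / (2.0 * hess_h)
        try:
            steps = -np.linalg.solve(H0, grads_g.T).T
        except np.linalg.LinAlgError:  # pragma: no cover
            steps = np.zeros_like(grads_g)
        norms = np.linalg.norm(steps, axis=1)
        too_big = norms > 0.5
        if np.any(too_big):
            steps[too_big] *= (0.5 / norms[too_big])[:, None]
        centers[:, mask] += steps
        refine -= 1

    for it in range(refine + 1):
        vals = _stencil_eval(values_b, subj, centers, full_offsets)
        grads = (vals[:, 1:1 + 2 * d:2] - vals[:, 2:2 + 2 * d:2]) / (2.0 * hess_h)
        Hs = [_assemble_hessian(vals[v], d, hess_h, pairs) for v in range(V)]
        steps = np.empty((V, d))
        for v in range(V):
            try:
                steps[v] = -np.linalg.solve(Hs[v], grads[v])
            except np.linalg.LinAlgError:
                steps[v] = 0.0
        norms = np.linalg.norm(steps, axis=1)
        too_big = norms > 0.5  # keep re-centring conservative
        if np.any(too_big):
            steps[too_big] *= (0.5 / norms[too_big])[:, None]
        if it < refine and np.max(np.abs(steps)) > 1e-9:
            centers[:, mask] += steps
            continue
        break

    out = np.empty(V)
    for v in range(V):
        # g = −2·l_pen, so Hess(−l_pen) = Hess(g)/2 and
        # −2·log∫exp(l_pen) ≈ g(mode) − d·log(2π) + log|Hess(g)| − d·log 2,
        # with g(mode) ≈ g(center) − ½ ∇gᵀ H⁻¹ ∇g.
        H = Hs[v]
        logdet = _logdet_psd(H)
        try:
            corr = 0.5 * float(grads[v] @ np.linalg.solve(H, grads[v]))
        except np.linalg.LinAlgError:  # pragma: no cover
            corr = 0.0
        out[v] = (
            vals[v, 0] - corr - d * _LOG2PI + logdet - d * np.log(2.0)
        )
    if return_hessian:
        return out, Hs[0]
    return out


def laplace_neg2_marginal(g_fn, mode: np.ndarray, h: float = 1e-3) -> float:
    """Generic Laplace approximation of ``−2·log ∫ exp(−g(η)/2) dη``.

    ``g_fn`` maps a batch (B, d) to (B,) values of −2× the integrand's log;
    ``mode`` should be (near) the minimiser of g.  Uses the same
    finite-difference stencil, determinant and second-order mode correction
    as the per-subject marginal-likelihood machinery; exact for quadratic g.
    """
    mode = np.asarray(mode, dtype=float)
    d = mode.size
    offsets, pairs = _hessian_offsets(d, h)
    vals = np.asarray(g_fn(mode[None, :] + offsets), dtype=float)
    H = _assemble_hessian(vals, d, h, pairs)
    grad = (vals[1:1 + 2 * d:2] - vals[2:2 + 2 * d:2]) / (2.0 * h)
    logdet = _logdet_psd(H)
    corr = 0.5 * float(grad @ np.linalg.solve(H, grad))
    return float(vals[0] - corr - d * _LOG2PI + logdet - d * np.log(2.0))


def ofv_laplace(
    data: pd.DataFrame | Sequence[SubjectData],
    values: Mapping[str, float],
    ebes: Mapping[int, np.ndarray] | None = None,
    reoptimize: bool = True,
) -> float:
    """Laplace objective function value over all subjects.

    With ``reoptimize`` the EBE mode is recomputed (warm-started from
    ``ebes`` when given); otherwise the supplied modes are used as-is.
    """
    subjects = data if not isinstance(data, pd.DataFrame) else build_subjects(data)
    total = 0.0
    for subj in subjects:
        eta0 = None if ebes is None else ebes.get(subj.subject_id)
        if reoptimize or eta0 is None:
            eta_hat, _ = ebe(subj, values, eta0=eta0)
        else:
            eta_hat = eta0
        total += float(_subject_ofv_batch(values, subj, eta_hat)[0])
    return total


# ---------------------------------------------------------------------------
# Fit
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates, uncertainty and diagnostics from one estimation run."""

    values: dict  # all parameter values (estimated + fixed), natural scale
    spec: ParameterSpec
    ofv: float
    aic: float
    bic: float
    n_obs: int
    n_free: int
    se: dict | None
    rse_percent: dict | None
    cov: np.ndarray | None  # covariance on the transformed (log) scale
    ebes: pd.DataFrame
    convergence: dict

    @property
    def theta(self) -> dict:
        return {n: self.values[n] for n in THETA_NAMES}

    def fraction_estimates(self, study: int) -> dict:
        from .model import fractions_from_fr
        fr = fractions_from_fr(self.values[f"FR1_st{study}"], self.values["F_aM"])
        return {"F_iaM": fr.F_iaM, "F_aM": fr.F_aM, "F_P": fr.F_P, "FR2": fr.FR2}

    def ebe_dict(self) -> dict:
        return {
            int(r["ID"]): np.array([r[n] for n in ETA_NAMES])
            for _, r in self.ebes.iterrows()
        }

    def to_json(self, path=None) -> str:
        payload = {
            "values": self.values,
            "fixed": sorted(self.spec.fixed),
            "ofv": self.ofv, "aic": self.aic, "bic": self.bic,
            "n_obs": self.n_obs, "n_free_parameters": self.n_free,
            "se": self.se, "rse_percent": self.rse_percent,
            "convergence": self.convergence,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _frozen_ofv_factory(
    subjects: Sequence[SubjectData], spec: ParameterSpec,
    ebes: Mapping[int, np.ndarray],
) -> Callable[[np.ndarray], float]:
    """OFV as a function of the transformed free vector, EBEs frozen."""

    def ofv_x(x: np.ndarray) -> float:
        values = spec.unpack(np.asarray(x))
        return sum(
            float(_subject_ofv_batch(values, s, ebes[s.subject_id])[0])
            for s in subjects
        )

    return ofv_x


def _ofv_gradient(
    subjects, spec, x, ebes, H_cache=None, h: float = 1e-4,
    central: bool = False,
) -> np.ndarray:
    """Batched finite-difference OFV gradient with per-variant mode re-centring."""
    p = x.size
    hs = h * np.maximum(1.0, np.abs(x))  # relative steps for unscaled spaces
    if central:
        variants = np.tile(x, (2 * p, 1))
        for i in range(p):
            variants[2 * i, i] += hs[i]
            variants[2 * i + 1, i] -= hs[i]
    else:
        variants = np.vstack([x[None, :], x[None, :] + np.diag(hs)])
    value_arrays = _values_for_variants(spec, variants)
    totals = np.zeros(variants.shape[0])
    for subj in subjects:
        H0 = None if H_cache is None else H_cache.get(subj.subject_id)
        totals += _subject_ofv_batch(
            value_arrays, subj, ebes[subj.subject_id], H0=H0
        )
    if central:
        return (totals[0::2] - totals[1::2]) / (2.0 * hs)
    return (totals[1:] - totals[0]) / hs


def _values_for_variants(spec: ParameterSpec, variants: np.ndarray) -> dict:
    """Expand a (V, p) transformed matrix into name → (V,) natural arrays."""
    out = {}
    for j, n in enumerate(spec.free_names):
        col = variants[:, j]
        out[n] = np.exp(col) if spec._tf(n) == "log" else col * spec._scale(n)
    for n in PARAM_ORDER:
        if n in spec.fixed:
            out[n] = spec.values[n]
    for n, v in FIXED_DEFAULTS.items():
        out.setdefault(n, spec.values.get(n, v))
    return out


def _ofv_hessian(
    subjects, spec, x, ebes, H_cache=None, h: float = 1e-4, chunk: int = 64
) -> np.ndarray:
    """Central-difference Hessian of the OFV (for standard errors)."""
    p = x.size
    h = h * np.maximum(1.0, np.abs(x))
    offsets, pairs = _hessian_offsets(p, h)
    variants = x[None, :] + offsets
    totals = np.zeros(variants.shape[0])
    for lo in range(0, variants.shape[0], chunk):
        sl = slice(lo, min(lo + chunk, variants.shape[0]))
        value_arrays = _values_for_variants(spec, variants[sl])
        for subj in subjects:
            H0 = None if H_cache is None else H_cache.get(subj.subject_id)
            totals[sl] += _subject_ofv_batch(
                value_arrays, subj, ebes[subj.subject_id], H0=H0
            )
    return _assemble_hessian(totals, p, h, pairs)


def fit(
    dataset: pd.DataFrame | Sequence[SubjectData],
    spec: ParameterSpec | None = None,
    n_starts: int = 1,
    start_jitter: float = 0.2,
    maxiter: int = 100,
    se: bool = True,
    seed: int = 0,
    gtol: float = 1e-3,
    ftol: float = 1e-8,
    grad_method: str = "forward",
    verbose: bool = False,
) -> FitResult:
    """Maximum (approximate marginal) likelihood fit of the joint model.

    Minimises the Laplace OFV over the free parameters on the transformed
    scale with L-BFGS-B; objective evaluations refresh the per-subject EBE
    modes (warm-started), gradients hold them frozen.  ``n_starts > 1`` adds
    deterministic jittered restarts (±``start_jitter``, seeded) and keeps
    the best minimum.
    """
    if spec is None:
        spec = default_parameter_spec()
    subjects = (
        build_subjects(dataset) if isinstance(dataset, pd.DataFrame) else list(dataset)
    )
    if not subjects:
        raise ValueError("dataset contains no retained observations")
    n_obs = sum(s.n_obs for s in subjects)
    if any(s.n_obs == 0 for s in subjects):
        raise ValueError("every subject must have at least one retained observation")

    starts = [spec.pack(spec.values)]
    rng = np.random.default_rng(seed)
    for _ in range(n_starts - 1):
        jit = default_parameter_spec(
            jitter=start_jitter, seed=int(rng.integers(2**31 - 1))
        )
        vals = dict(spec.values)
        for n in spec.free_names:
            vals[n] = jit.values.get(n, vals[n])
        starts.append(spec.pack(vals))

    best = None
    for x0 in starts:
        ebes_store: dict = {}
        H_cache: dict = {}
        nfev = [0]

        def objective(x):
            values = spec.unpack(x)
            total = 0.0
            for subj in subjects:
                eta_hat, _ = ebe(subj, values, eta0=ebes_store.get(subj.subject_id))
                ebes_store[subj.subject_id] = eta_hat
                contrib, H = _subject_ofv_batch(
                    values, subj, eta_hat, return_hessian=True
                )
                H_cache[subj.subject_id] = H
                total += float(contrib[0])
            nfev[0] += 1
            if verbose:
                print(f"  OFV eval {nfev[0]}: {total:.3f}")
            return total

        def gradient(x):
            return _ofv_gradient(
                subjects, spec, np.asarray(x), ebes_store, H_cache,
                central=(grad_method == "central"),
            )

        res = optimize.minimize(
            objective, x0, jac=gradient, method="L-BFGS-B",
            bounds=spec.bounds(),
            options={"maxiter": maxiter, "gtol": gtol, "ftol": ftol},
        )
        if best is None or res.fun < best[0].fun:
            best = (res, dict(ebes_store))

    res, ebes_store = best
    x_hat = np.asarray(res.x)
    values = spec.unpack(x_hat)
    # Final EBE refresh at the optimum.
    H_cache = {}
    ofv = 0.0
    for subj in subjects:
        eta_hat, _ = ebe(subj, values, eta0=ebes_store.get(subj.subject_id))
        ebes_store[subj.subject_id] = eta_hat
        contrib, H = _subject_ofv_batch(values, subj, eta_hat, return_hessian=True)
        H_cache[subj.subject_id] = H
        ofv += float(contrib[0])
    p = len(spec.free_names)
    aic = ofv + 2.0 * p
    bic = ofv + p * np.log(n_obs)

    se_dict = rse_dict = None
    cov = None
    if se:
        H = _ofv_hessian(subjects, spec, x_hat, ebes_store, H_cache)
        try:
            cov = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:  # pragma: no cover
            warnings.warn("singular OFV Hessian; standard errors unavailable")
        if cov is not None:
            dvar = np.diag(cov)
            if np.any(dvar <= 0):
                warnings.warn("non-positive variance in covariance matrix")
            se_x = np.sqrt(np.maximum(dvar, 0.0))
            se_dict, rse_dict = {}, {}
            for n, xi, si in zip(spec.free_names, x_hat, se_x):
                est = values[n]
                # delta method back to natural scale for log-transformed entries
                se_nat = est * si if spec._tf(n) == "log" else si
                se_dict[n] = float(se_nat)
                rse_dict[n] = float(100.0 * se_nat / abs(est)) if est else np.nan

    ebes_df = pd.DataFrame(
        [
            {"ID": s.subject_id, "STUDY": s.study,
             **dict(zip(ETA_NAMES, ebes_store[s.subject_id]))}
            for s in subjects
        ]
    )
    gradient_final = _ofv_gradient(
        subjects, spec, x_hat, ebes_store, H_cache, central=True
    )
    convergence = {
        "success": bool(res.success),
        "message": str(res.message),
        "iterations": int(res.nit),
        "n_objective_evals": int(res.nfev),
        "max_gradient": float(np.max(np.abs(gradient_final))),
        "n_starts": n_starts,
    }
    if not res.success:
        warnings.warn(f"optimizer did not report convergence: {res.message}")
    return FitResult(
        values=values, spec=spec, ofv=float(ofv), aic=float(aic),
        bic=float(bic), n_obs=int(n_obs), n_free=p, se=se_dict,
        rse_percent=rse_dict, cov=cov, ebes=ebes_df, convergence=convergence,
    )
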