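"""Model evaluation: conditional weighted residuals, visual predictive
checks, and sampling importance resampling.

All three procedures operate on a fitted (or known) parameter set expressed
as the flat name→value mapping used by :mod:`clopk.estimate`, so they can be
run both after an estimation and directly under the generating model of a
simulation study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._analytic import unit_bolus_profiles
from .estimate import (
    N_ETA,
    SubjectData,
    _active_mask,
    _predict_subject,
    _study_suffixed,
    _subject_ofv_batch,
    _values_for_variants,
    build_subjects,
    ebe,
    omega_sd_vector,
)

__all__ = [
    "cwres",
    "gof_table",
    "vpc",
    "VPCResult",
    "sir",
    "sir_from_ofv",
    "SIRResult",
]


# ---------------------------------------------------------------------------
# CWRES and goodness of fit
# ---------------------------------------------------------------------------


def _eta_sensitivity(
    values: Mapping[str, float], subj: SubjectData, eta_hat: np.ndarray,
    mask: np.ndarray, h: float = 1e-4,
) -> np.ndarray:
    """Central-difference sensitivity G = df/d(eta) (n_obs, d) at the mode."""
    d = int(mask.sum())
    etas = np.tile(eta_hat, (2 * d, 1))
    idx = np.where(mask)[0]
    for j, i in enumerate(idx):
        etas[2 * j, i] += h
        etas[2 * j + 1, i] -= h
    preds = _predict_subject(values, subj, etas)
    return ((preds[0::2] - preds[1::2]) / (2.0 * h)).T


def _resolve_ebes(dataset, values, fit=None, ebes=None):
    subjects = (
        build_subjects(dataset) if isinstance(dataset, pd.DataFrame) else list(dataset)
    )
    eta_map = {}
    if fit is not None and ebes is None:
        ebes = fit.ebe_dict()
    for s in subjects:
        if ebes is not None and s.subject_id in ebes:
            eta_map[s.subject_id] = np.asarray(ebes[s.subject_id])
        else:
            eta_map[s.subject_id], _ = ebe(s, values)
    return subjects, eta_map


def _fit_values(fit_or_values) -> dict:
    if isinstance(fit_or_values, Mapping):
        return dict(fit_or_values)
    return dict(fit_or_values.values)


def cwres(
    dataset: pd.DataFrame | Sequence[SubjectData],
    fit_or_values,
    ebes: Mapping[int, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Conditional weighted residuals from a first-order expansion at the EBEs.

    Per subject, with G the eta-sensitivity of the predictions at the mode
    η̂, Ω the diagonal random-effect covariance and proportional residual
    variance diag((σ·f̂)²):

        CWRES = Cov^(−1/2) · (y − f(θ, η̂) + G·η̂),  Cov = G·Ω·Gᵀ + diag((σ·f̂)²)

    Under a correctly specified model these are approximately standard
    normal and mutually decorrelated within subject.
    """
    values = _fit_values(fit_or_values)
    fit = None if isinstance(fit_or_values, Mapping) else fit_or_values
    subjects, eta_map = _resolve_ebes(dataset, values, fit=fit, ebes=ebes)
    frames = []
    for s in subjects:
        eta_hat = eta_map[s.subject_id]
        mask = _active_mask(values, s.study)
        f_hat = _predict_subject(values, s, eta_hat[None, :])[0]
        y = np.hstack([o.dv for o in s.occasions])
        sigma = float(_study_suffixed(values, "sigma", s.study))
        res_var = (sigma * np.maximum(f_hat, 1e-12)) ** 2
        if mask.any():
            G = _eta_sensitivity(values, s, eta_hat, mask)
            omega2 = omega_sd_vector(values, s.study)[mask] ** 2
            cov = (G * omega2[None, :]) @ G.T + np.diag(res_var)
            resid = y - f_hat + G @ eta_hat[mask]
        else:
            cov = np.diag(res_var)
            resid = y - f_hat
        evals, evecs = np.linalg.eigh(cov)
        if evals.min() <= 0:  # pragma: no cover - guards degenerate designs
            warnings.warn("singular CWRES covariance; ridge-regularized")
            evals = np.maximum(evals, 1e-10)
        w = evecs @ np.diag(evals**-0.5) @ evecs.T
        cw = w @ resid
        n_occ = [o.times.size for o in s.occasions]
        frames.append(pd.DataFrame({
            "ID": s.subject_id, "STUDY": s.study,
            "OCC": np.repeat([i + 1 for i in range(len(n_occ))], n_occ),
            "TIME": np.hstack([o.times for o in s.occasions]),
            "DVID": np.hstack([o.dvid for o in s.occasions]),
            "DV": y, "IPRED": f_hat, "CWRES": cw,
        }))
    return pd.concat(frames, ignore_index=True)


def gof_table(
    dataset: pd.DataFrame | Sequence[SubjectData],
    fit_or_values,
    ebes: Mapping[int, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Observation-level table driving the four standard GOF panels.

    PRED is the population prediction (η = 0, individual weight and
    formulation retained), IPRED the empirical-Bayes individual prediction;
    TAD is time after the period's dose.
    """
    values = _fit_values(fit_or_values)
    fit = None if isinstance(fit_or_values, Mapping) else fit_or_values
    table = cwres(dataset, fit_or_values, ebes=ebes)
    subjects, _ = _resolve_ebes(dataset, values, fit=fit, ebes={})
    pred = {
        s.subject_id: _predict_subject(values, s, np.zeros((1, N_ETA)))[0]
        for s in subjects
    }
    table["PRED"] = np.hstack([pred[s.subject_id] for s in subjects])
    table["TAD"] = table["TIME"]
    return table[["ID", "STUDY", "OCC", "TIME", "TAD", "DVID", "DV",
                  "PRED", "IPRED", "CWRES"]]


# ---------------------------------------------------------------------------
# Visual predictive check
# ---------------------------------------------------------------------------


@dataclass
class VPCResult:
    """Binned observed percentiles with simulation-based confidence bands."""

    table: pd.DataFrame
    n_sim: int

    def coverage(self) -> float:
        """Fraction of (bin × percentile) checks where the observed
        percentile falls inside its simulated 95% CI."""
        t = self.table
        hits = 0
        total = 0
        for q in (5, 50, 95):
            obs = t[f"obs_p{q}"]
            ok = (obs >= t[f"sim_p{q}_lo"]) & (obs <= t[f"sim_p{q}_hi"])
            valid = obs.notna() & t[f"sim_p{q}_lo"].notna()
            hits += int((ok & valid).sum())
            total += int(valid.sum())
        return hits / total if total else float("nan")


def _design_meta(dataset: pd.DataFrame) -> pd.DataFrame:
    doses = dataset[dataset["EVID"] == 1]
    return doses[["ID", "STUDY", "OCC", "FORM", "WT", "AMT"]].reset_index(drop=True)


def _simulate_replicates(
    meta: pd.DataFrame, values: Mapping[str, float], times: np.ndarray,
    n_sim: int, rng: np.random.Generator, chunk: int = 200,
) -> np.ndarray:
    """Simulated DV array (n_sim, n_subject_occasions, T, 2 analytes)."""
    study = int(meta["STUDY"].iloc[0])
    sd = omega_sd_vector(values, study)
    sigma = float(_study_suffixed(values, "sigma", study))
    subj_ids = meta["ID"].to_numpy()
    uniq, subj_idx = np.unique(subj_ids, return_inverse=True)
    occ = meta["OCC"].to_numpy(dtype=int) - 1
    wt = meta["WT"].to_numpy(dtype=float)
    form = meta["FORM"].to_numpy()
    amt = meta["AMT"].to_numpy(dtype=float)
    n_rows = len(meta)
    out = np.empty((n_sim, n_rows, times.size, 2))
    wv = wt / 70.0
    wc = wv**0.75
    f_base = np.where(
        form == "R", values["F_ref"],
        _study_suffixed(values, "F_gen", study),
    ).astype(float)
    for lo in range(0, n_sim, chunk):
        ns = min(chunk, n_sim - lo)
        eta_subj = rng.normal(0.0, sd[:4], size=(ns, uniq.size, 4))
        kap_F = rng.normal(0.0, sd[4], size=(ns, uniq.size, 2))
        kap_MTT = rng.normal(0.0, sd[6], size=(ns, uniq.size, 2))
        e = eta_subj[:, subj_idx, :]  # (ns, n_rows, 4)
        kF = kap_F[:, subj_idx, :][np.arange(ns)[:, None], np.arange(n_rows)[None, :], occ[None, :]]
        kM = kap_MTT[:, subj_idx, :][np.arange(ns)[:, None], np.arange(n_rows)[None, :], occ[None, :]]
        pars = {
            "dose": (f_base * amt)[None, :] * np.exp(e[:, :, 3] + kF),
            "CL_P": values["CL_P"] * wc[None, :] * np.ones((ns, 1)),
            "V_cP": values["V_cP"] * np.exp(e[:, :, 0]) * wv[None, :],
            "MTT": _study_suffixed(values, "MTT", study) * np.exp(kM),
            "FR1": _study_suffixed(values, "FR1", study) * np.exp(e[:, :, 2]),
            "F_aM": values["F_aM"],
            "CL_iaM": values["CL_iaM"] * wc[None, :] * np.ones((ns, 1)),
            "V_c_iaM": values["V_c_iaM"] * np.exp(e[:, :, 1]) * wv[None, :],
            "Q_iaM": values["Q_iaM"] * wc[None, :] * np.ones((ns, 1)),
            "V_p_iaM": values["V_p_iaM"] * wv[None, :] * np.ones((ns, 1)),
            "Q_h": values["Q_h"], "V_h": values["V_h"] * wv[None, :] * np.ones((ns, 1)),
            "mw_scale": values["mw_scale"],
        }
        cp, cm = unit_bolus_profiles(pars, times)
        cp = cp.reshape(ns, n_rows, times.size)
        cm = cm.reshape(ns, n_rows, times.size)
        eps = rng.normal(0.0, sigma, size=(ns, n_rows, times.size, 2))
        out[lo:lo + ns, :, :, 0] = cp * (1.0 + eps[..., 0])
        out[lo:lo + ns, :, :, 1] = cm * (1.0 + eps[..., 1])
    return out


def vpc(
    dataset: pd.DataFrame,
    fit_or_values,
    n_sim: int = 1000,
    seed: int = 0,
    lloq_parent: float = 0.5,
    lloq_metab: float = 0.1,
    min_bin_obs: int = 3,
    bins: Mapping[int, Sequence[Sequence[float]]] | None = None,
) -> VPCResult:
    """Visual predictive check against ``n_sim`` simulated study replicates.

    Replicates reuse the original design (subjects, weights, formulations,
    doses and the nominal schedule inferred from the dataset's observation
    rows) and apply the same LLOQ exclusion rule as the analysis.  Bins are
    nominal sampling times; times with fewer than ``min_bin_obs`` retained
    observations are merged into their left neighbour (with a warning), or
    custom per-study bins may be supplied.
    """
    values = _fit_values(fit_or_values)
    rng = np.random.default_rng(seed)
    obs = dataset[(dataset["EVID"] == 0) & (dataset["MDV"] == 0)]
    rows = []
    for study in sorted(obs["STUDY"].unique()):
        sobs = obs[obs["STUDY"] == study]
        meta = _design_meta(dataset[dataset["STUDY"] == study])
        times = np.unique(sobs["TIME"].to_numpy(dtype=float))
        sims = _simulate_replicates(meta, values, times, n_sim, rng)
        lloqs = {1: lloq_parent, 2: lloq_metab}
        for dvid in (1, 2):
            aobs = sobs[sobs["DVID"] == dvid]
            sim = sims[:, :, :, dvid - 1].copy()
            sim[sim < lloqs[dvid]] = np.nan
            if bins is not None and study in bins:
                groups = [np.asarray(b, dtype=float) for b in bins[study]]
            else:
                groups = _merge_bins(aobs, times, min_bin_obs)
            for grp in groups:
                in_bin = np.isin(times, grp)
                ov = aobs[aobs["TIME"].isin(grp)]["DV"].to_numpy()
                sv = sim[:, :, in_bin].reshape(n_sim, -1)
                row = {
                    "STUDY": study, "DVID": dvid,
                    "bin_lo": grp.min(), "bin_hi": grp.max(),
                    "n_obs": ov.size,
                }
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    for q in (5, 50, 95):
                        row[f"obs_p{q}"] = (
                            np.percentile(ov, q) if ov.size else np.nan
                        )
                        rep = np.nanpercentile(sv, q, axis=1)
                        row[f"sim_p{q}_med"] = np.nanmedian(rep)
                        row[f"sim_p{q}_lo"] = np.nanpercentile(rep, 2.5)
                        row[f"sim_p{q}_hi"] = np.nanpercentile(rep, 97.5)
                rows.append(row)
    return VPCResult(table=pd.DataFrame(rows), n_sim=n_sim)


def _merge_bins(aobs: pd.DataFrame, times: np.ndarray, min_bin_obs: int):
    counts = aobs.groupby("TIME").size()
    groups: list[list[float]] = []
    for t in times:
        n = int(counts.get(t, 0))
        if groups and sum(int(counts.get(x, 0)) for x in groups[-1]) < min_bin_obs:
            groups[-1].append(t)
        elif n < min_bin_obs and groups:
            groups[-1].append(t)
            warnings.warn(
                f"sparse bin at t={t} merged with neighbour", stacklevel=2
            )
        else:
            groups.append([t])
    if groups and sum(int(counts.get(x, 0)) for x in groups[-1]) < min_bin_obs \
            and len(groups) > 1:
        last = groups.pop()
        groups[-1].extend(last)
    return [np.asarray(g) for g in groups]


# ---------------------------------------------------------------------------
# Sampling importance resampling
# ---------------------------------------------------------------------------


@dataclass
class SIRResult:
    """Resampled parameter uncertainty summary."""

    summary: pd.DataFrame  # per parameter: estimate, median, 2.5/97.5 perc.
    samples: pd.DataFrame  # resampled vectors, natural scale
    ess: float
    n_proposals: int
    n_resamples: int


def sir_from_ofv(
    ofv_fn: Callable[[np.ndarray], np.ndarray],
    center: np.ndarray,
    cov: np.ndarray,
    M: int = 5000,
    m: int = 1000,
    seed: int | np.random.Generator = 0,
    inflation: float = 1.5,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Core SIR step on an arbitrary OFV surface.

    Proposals ~ MVN(center, inflation·cov); importance weight ∝
    exp(−ΔOFV/2)/proposal density; ``m`` resamples without replacement.
    Returns (resampled draws, normalized weights, effective sample size).
    """
    if m > M:
        raise ValueError("m must not exceed M")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = center.size
    prop_cov = inflation * 0.5 * (cov + cov.T)
    evals = np.linalg.eigvalsh(prop_cov)
    if evals.min() <= 0:
        warnings.warn(
            "proposal covariance not positive definite; flooring eigenvalues"
        )
        ev, evec = np.linalg.eigh(prop_cov)
        ev = np.maximum(ev, 1e-8 * max(ev.max(), 1e-8))
        prop_cov = evec @ np.diag(ev) @ evec.T
    L = np.linalg.cholesky(prop_cov)
    draws = center[None, :] + rng.standard_normal((M, p)) @ L.T
    logq = stats.multivariate_normal(mean=center, cov=prop_cov).logpdf(draws)
    ofv = np.asarray(ofv_fn(draws), dtype=float)
    logw = -0.5 * (ofv - np.nanmin(ofv)) - logq
    logw -= logw.max()
    w = np.exp(logw)
    w[~np.isfinite(w)] = 0.0
    w /= w.sum()
    ess = 1.0 / np.sum(w**2)
    if ess < 0.1 * m:
        warnings.warn(
            f"SIR effective sample size {ess:.0f} < 0.1·m; consider a "
            "different proposal inflation"
        )
    if int((w > 0).sum()) >= m:
        idx = rng.choice(M, size=m, replace=False, p=w)
    else:  # too few usable proposals to resample without replacement
        warnings.warn(
            "fewer positive-weight proposals than resamples; "
            "falling back to resampling with replacement"
        )
        idx = rng.choice(M, size=m, replace=True, p=w)
    return draws[idx], w, float(ess)


def sir(
    dataset: pd.DataFrame | Sequence[SubjectData],
    fit,
    M: int = 5000,
    m: int = 1000,
    seed: int = 0,
    inflation: float = 1.5,
    chunk: int = 32,
) -> SIRResult:
    """Parameter-uncertainty assessment of a fit by single-iteration SIR.

    The OFV of each proposal is evaluated with the empirical-Bayes modes
    re-centred from the fit's values (two Newton passes), on the transformed
    scale; resampled vectors are reported on the natural scale.
    """
    if fit.cov is None:
        raise ValueError("fit must carry a covariance matrix (fit with se=True)")
    spec = fit.spec
    subjects = (
        build_subjects(dataset) if isinstance(dataset, pd.DataFrame) else list(dataset)
    )
    ebes = fit.ebe_dict()
    x_hat = spec.pack(fit.values)

    def ofv_fn(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        out = np.zeros(X.shape[0])
        for lo in range(0, X.shape[0], chunk):
            sl = slice(lo, min(lo + chunk, X.shape[0]))
            value_arrays = _values_for_variants(spec, X[sl])
            for s in subjects:
                out[sl] += _subject_ofv_batch(
                    value_arrays, s, ebes[s.subject_id], refine=2
                )
        return out

    draws, w, ess = sir_from_ofv(
        ofv_fn, x_hat, fit.cov, M=M, m=m, seed=seed, inflation=inflation
    )
    names = spec.free_names
    nat = np.stack([
        [fit.spec.unpack(x)[n] for n in names] for x in draws
    ])
    samples = pd.DataFrame(nat, columns=names)
    summary = pd.DataFrame({
        "parameter": names,
        "estimate": [fit.values[n] for n in names],
        "median": np.median(nat, axis=0),
        "p2.5": np.percentile(nat, 2.5, axis=0),
        "p97.5": np.percentile(nat, 97.5, axis=0),
    })
    return SIRResult(
        summary=summary, samples=samples, ess=ess,
        n_proposals=M, n_resamples=m,
    )
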