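"""Synthetic two-study crossover bioequivalence data generator.

The generator emulates the structure of the data the joint model is built
for: two independent 2x2 crossover studies in healthy volunteers (24 and 26
subjects), a single 150 mg oral dose per period, rich sampling (14 samples
per period to 48 h, 17 samples per period to 36 h), body weight drawn from a
truncated normal, log-normal inter-individual variability (IIV) on selected
parameters, inter-occasion variability (IOV) on the absorption parameters,
study-specific proportional residual error, and LLOQ censoring (0.5 ng/mL
for the parent, 0.1 µg/mL for the metabolite, excluded per the M1 rule).

Records use the conventional long pharmacometric dialect: one dose row
(EVID=1) per subject-period plus one observation row per analyte per nominal
time (EVID=0, DVID 1=parent ng/mL, 2=metabolite µg/mL).  TIME is time after
the period's dose; washout between periods is assumed complete (parent
half-life ~1.7 h), so occasions are simulated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import StructuralParams, default_params, scale_to_weight

__all__ = [
    "StudyDesign",
    "VariabilityModel",
    "SubjectRealization",
    "study_design",
    "default_variability",
    "sample_covariates",
    "sample_individual_params",
    "generate_study",
    "generate_dataset",
    "apply_lloq",
    "scheduled_sample_count",
    "DATASET_COLUMNS",
]

DATASET_COLUMNS = [
    "ID", "STUDY", "OCC", "SEQ", "FORM", "TIME", "EVID", "AMT", "CMT",
    "DVID", "DV", "WT", "MDV", "BLQ",
]

# Body weight distribution of the pooled healthy-volunteer population.
WEIGHT_MEAN = 74.1
WEIGHT_SD = 13.56
WEIGHT_LO = 47.0
WEIGHT_HI = 100.0

_TIMES_STUDY1 = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0,
                 12.0, 24.0, 48.0)
_TIMES_STUDY2 = (0.17, 0.33, 0.5, 0.67, 0.83, 1.0, 1.25, 1.5, 2.0, 2.5, 3.0,
                 4.0, 6.0, 8.0, 12.0, 24.0, 36.0)


@dataclass(frozen=True)
class StudyDesign:
    """Layout of one 2x2 crossover study."""

    study_id: int
    n_subjects: int
    sampling_times: tuple[float, ...]
    n_periods: int = 2
    dose_mg: float = 150.0
    lloq_parent: float = 0.5  # ng/mL
    lloq_metab: float = 0.1  # µg/mL

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_periods <= 0:
            raise ValueError("n_subjects and n_periods must be positive")
        if self.dose_mg <= 0:
            raise ValueError("dose_mg must be positive")
        times = np.asarray(self.sampling_times)
        if times.size == 0 or np.any(np.diff(times) <= 0) or times[0] <= 0:
            raise ValueError("sampling_times must be positive and increasing")

    @property
    def samples_per_period(self) -> int:
        return len(self.sampling_times)

    @property
    def horizon(self) -> float:
        return max(self.sampling_times)


@dataclass(frozen=True)
class VariabilityModel:
    """Random-effect magnitudes for one study (log-scale SDs).

    The reported CV% convention is ``100·sd`` (the usual shorthand for
    exponential random-effect models); the exact lognormal transform
    ``100·sqrt(exp(sd²)−1)`` is available via :meth:`cv_percent`.
    """

    iiv_V_cP: float = 0.4582
    iiv_V_c_iaM: float = 0.2506
    iiv_FR1: float = 0.7280
    iiv_F: float = 0.4266
    iov_F: float = 0.0883
    iov_MTT: float = 0.2544
    sigma_prop: float = 0.4195

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def cv_percent(self, name: str, convention: str = "sd") -> float:
        sd = getattr(self, name)
        if convention == "sd":
            return 100.0 * sd
        if convention == "lognormal":
            return 100.0 * np.sqrt(np.expm1(sd**2))
        raise ValueError(f"unknown CV convention {convention!r}")


@dataclass(frozen=True)
class SubjectRealization:
    """One subject's covariates, sequence and random-effect draws."""

    subject_id: int
    study_id: int
    weight: float
    sequence: str  # "RT" or "TR"
    eta: dict = field(default_factory=dict)  # IIV draws (log scale)
    kappa: tuple = ((0.0, 0.0), (0.0, 0.0))  # per-occasion (kappa_F, kappa_MTT)


def study_design(study: int = 1) -> StudyDesign:
    """Default design for study 1 (24 subjects, 14x48 h) or 2 (26, 17x36 h)."""
    if study == 1:
        return StudyDesign(study_id=1, n_subjects=24, sampling_times=_TIMES_STUDY1)
    if study == 2:
        return StudyDesign(study_id=2, n_subjects=26, sampling_times=_TIMES_STUDY2)
    raise ValueError("study must be 1 or 2")


def default_variability(study: int = 1) -> VariabilityModel:
    """Default random-effect magnitudes per study arm."""
    if study == 1:
        return VariabilityModel()
    if study == 2:
        return VariabilityModel(
            iiv_FR1=0.2786, iiv_F=0.2588, iov_F=0.2324, iov_MTT=0.2748,
            sigma_prop=0.2939,
        )
    raise ValueError("study must be 1 or 2")


def scheduled_sample_count(design: StudyDesign) -> int:
    """Blood samples scheduled by protocol (each assayed for both analytes)."""
    return design.n_subjects * design.n_periods * design.samples_per_period


def _sequences(n_subjects: int) -> list[str]:
    # Balanced assignment: alternate RT / TR.
    return ["RT" if i % 2 == 0 else "TR" for i in range(n_subjects)]


def sample_covariates(
    design: StudyDesign, seed: int | np.random.Generator
) -> list[SubjectRealization]:
    """Draw body weights (truncated normal) and assign balanced sequences."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = (WEIGHT_LO - WEIGHT_MEAN) / WEIGHT_SD
    b = (WEIGHT_HI - WEIGHT_MEAN) / WEIGHT_SD
    weights = stats.truncnorm.rvs(
        a, b, loc=WEIGHT_MEAN, scale=WEIGHT_SD, size=design.n_subjects,
        random_state=rng,
    )
    seqs = _sequences(design.n_subjects)
    base = 0 if design.study_id == 1 else 100
    return [
        SubjectRealization(
            subject_id=base + i + 1, study_id=design.study_id,
            weight=float(w), sequence=s,
        )
        for i, (w, s) in enumerate(zip(weights, seqs))
    ]


def sample_individual_params(
    pop: StructuralParams,
    var: VariabilityModel,
    subject: SubjectRealization,
    seed: int | np.random.Generator,
    n_occasions: int = 2,
) -> tuple[SubjectRealization, list[StructuralParams]]:
    """Draw the subject's random effects and build per-occasion parameters.

    IIV enters multiplicatively (``P_i = P_pop·exp(η)``) on V_cP, V_c_iaM,
    FR1 and bioavailability; IOV adds ``exp(κ_occ)`` on bioavailability and
    MTT.  Allometric weight scaling is applied afterwards.  Bioavailability
    deviations are stored on ``F_ref``/``F_gen`` jointly so the formulation
    ratio is preserved within subject-occasion.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    eta = {
        "V_cP": rng.normal(0.0, var.iiv_V_cP),
        "V_c_iaM": rng.normal(0.0, var.iiv_V_c_iaM),
        "FR1": rng.normal(0.0, var.iiv_FR1),
        "F": rng.normal(0.0, var.iiv_F),
    }
    kappa = tuple(
        (rng.normal(0.0, var.iov_F), rng.normal(0.0, var.iov_MTT))
        for _ in range(n_occasions)
    )
    subject = replace(subject, eta=eta, kappa=kappa)
    occasions = []
    for kF, kMTT in kappa:
        f_mult = np.exp(eta["F"] + kF)
        ind = replace(
            pop,
            V_cP=pop.V_cP * np.exp(eta["V_cP"]),
            V_c_iaM=pop.V_c_iaM * np.exp(eta["V_c_iaM"]),
            FR1=pop.FR1 * np.exp(eta["FR1"]),
            F_ref=pop.F_ref * f_mult,
            F_gen=pop.F_gen * f_mult,
            MTT=pop.MTT * np.exp(kMTT),
        )
        occasions.append(scale_to_weight(ind, subject.weight))
    return subject, occasions


def generate_study(
    design: StudyDesign,
    pop: StructuralParams | None = None,
    var: VariabilityModel | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one study as a long-format dataset (before LLOQ handling).

    Each subject-period gets one dose row and one observation row per
    analyte per nominal time; DV = prediction·(1+ε) with study-specific
    proportional error.
    """
    from ._analytic import unit_bolus_profiles

    if pop is None:
        pop = default_params(design.study_id)
    if var is None:
        var = default_variability(design.study_id)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    subjects = sample_covariates(design, rng)
    times = np.asarray(design.sampling_times)
    rows: list[dict] = []
    for subj in subjects:
        subj, occ_params = sample_individual_params(pop, var, subj, rng)
        for occ in range(design.n_periods):
            form = subj.sequence[occ]  # 'R' reference, 'T' test/generic
            ind = occ_params[occ]
            f_dose = ind.F_ref if form == "R" else ind.F_gen
            pars = {
                "dose": f_dose * design.dose_mg,
                "CL_P": ind.CL_P, "V_cP": ind.V_cP, "MTT": ind.MTT,
                "FR1": ind.FR1, "F_aM": ind.F_aM_fixed,
                "CL_iaM": ind.CL_iaM, "V_c_iaM": ind.V_c_iaM,
                "Q_iaM": ind.Q_iaM, "V_p_iaM": ind.V_p_iaM,
                "Q_h": ind.Q_h, "V_h": ind.V_h, "mw_scale": ind.mw_scale,
            }
            cp, cm = unit_bolus_profiles(pars, times)
            cp, cm = cp[0], cm[0]
            eps = rng.normal(0.0, var.sigma_prop, size=(2, times.size))
            dv_p = cp * (1.0 + eps[0])
            dv_m = cm * (1.0 + eps[1])
            common = dict(
                ID=subj.subject_id, STUDY=design.study_id, OCC=occ + 1,
                SEQ=subj.sequence, FORM=form, WT=subj.weight,
            )
            rows.append(dict(common, TIME=0.0, EVID=1, AMT=design.dose_mg,
                             CMT=1, DVID=0, DV=np.nan, MDV=1, BLQ=0))
            for j, t in enumerate(times):
                rows.append(dict(common, TIME=t, EVID=0, AMT=0.0, CMT=5,
                                 DVID=1, DV=dv_p[j], MDV=0, BLQ=0))
                rows.append(dict(common, TIME=t, EVID=0, AMT=0.0, CMT=6,
                                 DVID=2, DV=dv_m[j], MDV=0, BLQ=0))
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    return df


def generate_dataset(
    designs: Sequence[StudyDesign] | None = None,
    pops: Sequence[StructuralParams] | None = None,
    vars_: Sequence[VariabilityModel] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate both studies with independent sub-streams of ``seed``."""
    if designs is None:
        designs = [study_design(1), study_design(2)]
    if pops is None:
        pops = [default_params(d.study_id) for d in designs]
    if vars_ is None:
        vars_ = [default_variability(d.study_id) for d in designs]
    streams = np.random.SeedSequence(seed).spawn(len(designs))
    frames = [
        generate_study(d, p, v, np.random.default_rng(s))
        for d, p, v, s in zip(designs, pops, vars_, streams)
    ]
    return pd.concat(frames, ignore_index=True)


def apply_lloq(
    ds: pd.DataFrame,
    lloq_parent: float = 0.5,
    lloq_metab: float = 0.1,
    policy: str = "exclude",
) -> pd.DataFrame:
    """Flag observations strictly below the analyte LLOQ and apply a policy.

    ``exclude`` (the M1 rule) drops flagged rows; ``flag`` keeps them with
    BLQ=1 and MDV=1.  Values exactly at the LLOQ are retained.  Negative
    simulated concentrations are likewise flagged.
    """
    if policy not in ("exclude", "flag"):
        raise ValueError(f"unknown LLOQ policy {policy!r}")
    ds = ds.copy()
    obs = ds["EVID"] == 0
    lloq = np.where(ds["DVID"] == 1, lloq_parent, lloq_metab)
    blq = obs & (ds["DV"].to_numpy() < lloq)
    ds.loc[blq, "BLQ"] = 1
    if policy == "exclude":
        return ds.loc[~blq].reset_index(drop=True)
    ds.loc[blq, "MDV"] = 1
    return ds
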