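"""Dataset reading/writing/validation, run configuration and the pipeline.

The dataset dialect is the conventional long pharmacometric CSV: mandatory
header, one row per dose or observation, missing DV encoded as ``"."``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import simulate
from .simulate import DATASET_COLUMNS, apply_lloq, study_design

__all__ = [
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "DatasetError",
    "RunConfig",
    "load_config",
    "run_pipeline",
]

log = logging.getLogger("clopk")

_NUMERIC = ["ID", "STUDY", "OCC", "TIME", "EVID", "AMT", "CMT", "DVID",
            "DV", "WT", "MDV", "BLQ"]


class DatasetError(ValueError):
    """Raised when a dataset fails validation; carries the itemized report."""

    def __init__(self, problems: list):
        self.problems = list(problems)
        super().__init__(
            "dataset validation failed:\n" + "\n".join(f"- {p}" for p in problems)
        )


def write_dataset(ds: pd.DataFrame, path) -> None:
    ds.to_csv(path, index=False, na_rep=".")


def read_dataset(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["."])
    return validate_dataset(df)


def validate_dataset(ds: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Check the dataset dialect and record-level invariants.

    Returns the (type-coerced) dataset or raises :class:`DatasetError`
    listing every violation found.
    """
    if not isinstance(ds, pd.DataFrame):
        ds = pd.read_csv(ds, na_values=["."])
    problems: list[str] = []
    missing = [c for c in DATASET_COLUMNS if c not in ds.columns]
    if missing:
        raise DatasetError([f"missing column {c}" for c in missing])
    ds = ds.copy()
    for c in _NUMERIC:
        ds[c] = pd.to_numeric(ds[c], errors="coerce")
        bad = ds[c].isna() & (c not in ("DV",))
        if c != "DV" and bad.any():
            problems.append(f"column {c}: {int(bad.sum())} non-numeric entries")
    if problems:
        raise DatasetError(problems)

    if (ds["TIME"] < 0).any():
        problems.append("negative TIME values")
    if (ds["WT"] <= 0).any():
        problems.append("non-positive body weight")
    dose = ds[ds["EVID"] == 1]
    obs = ds[ds["EVID"] == 0]
    bad_amt = dose[dose["AMT"] <= 0]
    for i in bad_amt.index:
        problems.append(f"row {i}: dose row with non-positive AMT")
    for i in dose[dose["DV"].notna()].index:
        problems.append(f"row {i}: dose row carries a DV")
    for i in obs[obs["AMT"] > 0].index:
        problems.append(f"row {i}: observation row with AMT>0")
    missing_dv = obs[(obs["MDV"] == 0) & obs["DV"].isna()]
    for i in missing_dv.index:
        problems.append(f"row {i}: observation row with MDV=0 but missing DV")
    unknown_evid = ds[~ds["EVID"].isin([0, 1])]
    for i in unknown_evid.index:
        problems.append(f"row {i}: EVID must be 0 or 1")
    counts = dose.groupby(["ID", "OCC"]).size()
    for (sid, occ), n in counts.items():
        if n != 1:
            problems.append(
                f"subject {int(sid)} occasion {int(occ)}: {n} dose rows (expected 1)"
            )
    if problems:
        raise DatasetError(problems)
    return ds


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline settings (generate → fit → diagnose → report)."""

    seed: int = 1
    n_subjects: dict = field(default_factory=lambda: {1: 24, 2: 26})
    variability_scale: float = 1.0  # multiplies all random-effect/error SDs
    lloq_policy: str = "exclude"
    fit_maxiter: int = 100
    fit_starts: int = 1
    fit_se: bool = True
    vpc_n_sim: int = 1000
    sir_proposals: int = 5000
    sir_resamples: int = 1000
    make_plots: bool = False
    output_dir: str = "clopk_run"

    def __post_init__(self) -> None:
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        for k in self.n_subjects:
            if int(k) not in (1, 2):
                raise ValueError(f"unknown study {k}")
        if self.fit_maxiter <= 0 or self.vpc_n_sim <= 0:
            raise ValueError("iteration/simulation counts must be positive")
        if self.variability_scale < 0:
            raise ValueError("variability_scale must be non-negative")
        if self.sir_resamples > self.sir_proposals:
            raise ValueError("sir_resamples must not exceed sir_proposals")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "n_subjects" in raw:
        raw["n_subjects"] = {int(k): int(v) for k, v in raw["n_subjects"].items()}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _designs(cfg: RunConfig) -> list:
    out = []
    for study, n in sorted(cfg.n_subjects.items()):
        base = study_design(int(study))
        out.append(dataclasses.replace(base, n_subjects=int(n)))
    return out


def run_pipeline(cfg: RunConfig, spec=None) -> Path:
    """Run generate → LLOQ exclusion → fit → GOF/CWRES → VPC → SIR.

    Writes dataset.csv, fit.json, ebes.csv, gof.csv, vpc.csv, sir.csv and
    run.log into the configured output directory and returns its path.
    """
    from .diagnostics import gof_table, sir, vpc
    from .estimate import default_parameter_spec, fit

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        import clopk

        log.info("clopk %s; seed %d", clopk.__version__, cfg.seed)
        designs = _designs(cfg)
        vars_ = [simulate.default_variability(d.study_id) for d in designs]
        if cfg.variability_scale != 1.0:
            vars_ = [
                dataclasses.replace(v, **{
                    f: getattr(v, f) * cfg.variability_scale
                    for f in v.__dataclass_fields__
                })
                for v in vars_
            ]
        ds_full = simulate.generate_dataset(designs, vars_=vars_, seed=cfg.seed)
        write_dataset(ds_full, out / "dataset_full.csv")
        ds = apply_lloq(ds_full, policy=cfg.lloq_policy)
        write_dataset(ds, out / "dataset.csv")
        log.info("generated %d rows (%d retained observations)",
                 len(ds_full), int((ds["EVID"] == 0).sum()))

        if spec is None:
            if cfg.variability_scale == 0.0:
                # variability-free data: pooled fit with sigma pinned small
                from .estimate import OMEGA_NAMES, SIGMA_NAMES

                overrides = {n: 0.0 for n in OMEGA_NAMES}
                overrides.update({n: 0.01 for n in SIGMA_NAMES})
                spec = default_parameter_spec(
                    extra_fixed=tuple(OMEGA_NAMES) + tuple(SIGMA_NAMES),
                    overrides=overrides,
                )
            else:
                spec = default_parameter_spec()
        result = fit(
            ds, spec, maxiter=cfg.fit_maxiter, n_starts=cfg.fit_starts,
            se=cfg.fit_se, seed=cfg.seed,
        )
        result.to_json(out / "fit.json")
        result.ebes.to_csv(out / "ebes.csv", index=False)
        log.info("fit: OFV %.3f AIC %.3f BIC %.3f", result.ofv, result.aic,
                 result.bic)

        gof = gof_table(ds, result)
        gof.to_csv(out / "gof.csv", index=False)
        vr = vpc(ds, result, n_sim=cfg.vpc_n_sim, seed=cfg.seed + 1)
        vr.table.to_csv(out / "vpc.csv", index=False)
        log.info("vpc coverage %.3f over %d bins", vr.coverage(), len(vr.table))

        if cfg.fit_se and result.cov is not None:
            sr = sir(
                ds, result, M=cfg.sir_proposals, m=cfg.sir_resamples,
                seed=cfg.seed + 2,
            )
            sr.summary.to_csv(out / "sir.csv", index=False)
            log.info("sir ESS %.0f of %d proposals", sr.ess, sr.n_proposals)
        if cfg.make_plots:
            _write_plots(out, gof, vr)
        log.info("pipeline complete")
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _write_plots(out: Path, gof: pd.DataFrame, vr) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for dvid, color in ((1, "tab:purple"), (2, "tab:green")):
        sub = gof[gof["DVID"] == dvid]
        axes[0, 0].loglog(sub["PRED"], sub["DV"], ".", ms=3, color=color)
        axes[0, 1].loglog(sub["IPRED"], sub["DV"], ".", ms=3, color=color)
        axes[1, 0].semilogx(sub["PRED"], sub["CWRES"], ".", ms=3, color=color)
        axes[1, 1].plot(sub["TAD"], sub["CWRES"], ".", ms=3, color=color)
    for ax, (xl, yl) in zip(axes.ravel(), [("PRED", "DV"), ("IPRED", "DV"),
                                           ("PRED", "CWRES"), ("TAD", "CWRES")]):
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
    fig.tight_layout()
    fig.savefig(out / "gof.png", dpi=120)
    plt.close(fig)

    t = vr.table
    fig, axes = plt.subplots(2, 2, figsize=(9, 8), sharex=False)
    for i, study in enumerate(sorted(t["STUDY"].unique())):
        for j, dvid in enumerate((1, 2)):
            ax = axes[i, j]
            sub = t[(t["STUDY"] == study) & (t["DVID"] == dvid)]
            x = 0.5 * (sub["bin_lo"] + sub["bin_hi"])
            for q, style in ((5, "--"), (50, "-"), (95, "--")):
                ax.fill_between(x, sub[f"sim_p{q}_lo"], sub[f"sim_p{q}_hi"],
                                alpha=0.25, color="tab:red")
                ax.plot(x, sub[f"obs_p{q}"], style, color="tab:blue")
            ax.set_yscale("log")
            ax.set_title(f"study {study}, {'parent' if dvid == 1 else 'metabolite'}")
            ax.set_xlabel("time (h)")
    fig.tight_layout()
    fig.savefig(out / "vpc.png", dpi=120)
    plt.close(fig)
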