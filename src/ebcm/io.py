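"""CSV/JSON readers and writers plus the end-to-end pipeline.

All CSVs are comma-separated UTF-8 with mandatory headers and '.' decimals.
Files written by this package carry a leading ``# ebcm ...`` comment line
embedding the package version and the master seed; readers skip comment
lines, so write-then-read round-trips are lossless.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes_regression import MCMCConfig, WeightedBayesLinearModel
from .datasets import default_model, load_knots
from .fitting import (
    DEFAULT_AGE_MAX,
    RECENT_ONSET_CUTOFF_MONTHS,
    AlphaDemandModel,
    AutopsyRecord,
)
from .physiology import PhysiologyModel
from .residuals import (
    CpeptideAggregate,
    PairedObservation,
    ResidualPoint,
    SmoothedSeries,
    align_with_cpeptide,
    moving_average,
    residual_series,
)
from .synthetic_data import (
    SyntheticCohortConfig,
    SyntheticStudyConfig,
    generate_autopsy_cohort,
    generate_cpeptide_aggregates,
)

__all__ = [
    "read_autopsy_csv",
    "write_autopsy_csv",
    "read_cpeptide_csv",
    "write_cpeptide_csv",
    "write_residuals_csv",
    "read_residuals_csv",
    "write_pairs_csv",
    "read_pairs_csv",
    "read_model_json",
    "write_model_json",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_AUTOPSY_COLS = {
    "patient_id",
    "study",
    "age_years",
    "months_since_diagnosis",
}
_CPEP_COLS = {
    "study",
    "months_since_diagnosis",
    "mean_nmol_per_L",
    "se_nmol_per_L",
    "n",
}


def _stamp(seed: int | None) -> str:
    tag = f"# ebcm v{__version__}"
    if seed is not None:
        tag += f" seed={seed}"
    return tag + "\n"


def _write_df(df: pd.DataFrame, path, seed: int | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_stamp(seed))
        # %.17g keeps float round-trips lossless
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_df(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def read_autopsy_csv(path) -> list[AutopsyRecord]:
    """Read autopsy records; either islet counts or observed_ebcm per row.

    Rows failing validation are reported together with their line numbers.
    """
    try:
        df = _read_df(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file, expected autopsy CSV header")
    missing = _AUTOPSY_COLS - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    has_fraction = "observed_ebcm" in df.columns
    has_counts = {"islets_deficient", "islets_total"} <= set(df.columns)
    if not (has_fraction or has_counts):
        raise ValueError(
            f"{path}: need either observed_ebcm or islets_deficient+islets_total"
        )
    records, errors = [], []
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after header
        try:
            frac = row.get("observed_ebcm", np.nan)
            deficient = row.get("islets_deficient", np.nan)
            total = row.get("islets_total", np.nan)
            counts_ok = has_counts and np.isfinite(deficient) and np.isfinite(total)
            if not np.isfinite(frac):
                if not counts_ok:
                    raise ValueError("no observed_ebcm and no usable islet counts")
                frac = float(deficient) / float(total)
            records.append(
                AutopsyRecord(
                    patient_id=str(row["patient_id"]),
                    study=str(row["study"]),
                    age=float(row["age_years"]),
                    time_since_diagnosis=float(row["months_since_diagnosis"]),
                    observed_ebcm=float(frac),
                    islets_insulin_deficient=int(deficient) if counts_ok else None,
                    islets_total=int(total) if counts_ok else None,
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError(f"{path}: {len(errors)} invalid row(s): " + "; ".join(errors))
    return records


def write_autopsy_csv(records, path, seed: int | None = None) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "study": [r.study for r in records],
            "age_years": [r.age for r in records],
            "months_since_diagnosis": [r.time_since_diagnosis for r in records],
            "islets_deficient": [r.islets_insulin_deficient for r in records],
            "islets_total": [r.islets_total for r in records],
            "observed_ebcm": [r.observed_ebcm for r in records],
        }
    )
    _write_df(df, path, seed)


def read_cpeptide_csv(path) -> list[CpeptideAggregate]:
    df = _read_df(path)
    missing = _CPEP_COLS - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return [
        CpeptideAggregate(
            study=str(row["study"]),
            time_since_diagnosis=float(row["months_since_diagnosis"]),
            mean=float(row["mean_nmol_per_L"]),
            se=float(row["se_nmol_per_L"]),
            n=int(row["n"]),
            stratum=str(row.get("stratum", "mixed")),
            sampling=str(row.get("sampling", "fasting")),
        )
        for _, row in df.iterrows()
    ]


def write_cpeptide_csv(aggregates, path, seed: int | None = None) -> None:
    df = pd.DataFrame(
        {
            "study": [a.study for a in aggregates],
            "months_since_diagnosis": [a.time_since_diagnosis for a in aggregates],
            "mean_nmol_per_L": [a.mean for a in aggregates],
            "se_nmol_per_L": [a.se for a in aggregates],
            "n": [a.n for a in aggregates],
            "stratum": [a.stratum for a in aggregates],
            "sampling": [a.sampling for a in aggregates],
        }
    )
    _write_df(df, path, seed)


def write_residuals_csv(points, path, seed: int | None = None) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in points],
            "months_since_diagnosis": [p.time_since_diagnosis for p in points],
            "delta_ebcm": [p.delta_ebcm for p in points],
        }
    )
    _write_df(df, path, seed)


def read_residuals_csv(path) -> list[ResidualPoint]:
    df = _read_df(path)
    return [
        ResidualPoint(
            time_since_diagnosis=float(r["months_since_diagnosis"]),
            delta_ebcm=float(r["delta_ebcm"]),
            patient_id=str(r["patient_id"]),
        )
        for _, r in df.iterrows()
    ]


def write_pairs_csv(pairs, path, seed: int | None = None) -> None:
    df = pd.DataFrame(
        {
            "study": [p.study for p in pairs],
            "months_since_diagnosis": [p.time_since_diagnosis for p in pairs],
            "x": [p.x for p in pairs],
            "x_sd": [p.x_sd for p in pairs],
            "y": [p.y for p in pairs],
            "y_se": [p.y_se for p in pairs],
            "weight": [p.weight for p in pairs],
        }
    )
    _write_df(df, path, seed)


def read_pairs_csv(path) -> list[PairedObservation]:
    df = _read_df(path)
    return [
        PairedObservation(
            x=float(r["x"]),
            x_sd=float(r["x_sd"]),
            y=float(r["y"]),
            y_se=float(r["y_se"]),
            weight=float(r["weight"]),
            time_since_diagnosis=float(r.get("months_since_diagnosis", np.nan)),
            study=str(r.get("study", "")),
        )
        for _, r in df.iterrows()
    ]


def read_model_json(path) -> PhysiologyModel:
    """Build a :class:`PhysiologyModel` from a JSON parameter file.

    Schema: ``{"alpha": ..., "gamma": ..., "qmax": ..., "kclr": ...,
    "rho": ..., "curves": {"weight": path-or-null, "bcm": path-or-null}}``;
    missing curve paths fall back to the packaged fixture curves.
    """
    with open(path, encoding="utf-8") as fh:
        cfg = json.load(fh)
    params = {
        k: float(cfg[k]) for k in ("alpha", "gamma", "qmax", "kclr", "rho") if k in cfg
    }
    curves = cfg.get("curves") or {}
    if curves.get("weight") and curves.get("bcm"):
        from .curves import fit_cubic_spline

        weight = fit_cubic_spline(load_knots(curves["weight"]))
        bcm = fit_cubic_spline(load_knots(curves["bcm"]))
        alpha = params.pop("alpha", 499.0)
        return PhysiologyModel(alpha=alpha, weight_curve=weight, bcm_curve=bcm, **params)
    return default_model(**params)


def write_model_json(model: PhysiologyModel, path, seed: int | None = None) -> None:
    payload = {
        "alpha": model.alpha,
        "gamma": model.gamma,
        "qmax": model.qmax,
        "kclr": model.kclr,
        "rho": model.rho,
        "version": __version__,
    }
    if seed is not None:
        payload["seed"] = seed
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


# -- end-to-end pipeline ------------------------------------------------------


@dataclass
class PipelineConfig:
    """Configuration for the chained simulate -> ... -> regress pipeline.

    When ``autopsy_csv``/``cpeptide_csv`` are unset the synthetic
    generators supply the inputs (seeded).
    """

    outdir: str = "ebcm-out"
    seed: int = 42
    alpha: float = 499.0
    window: int = 9
    age_max: float = DEFAULT_AGE_MAX
    onset_cutoff_months: float = RECENT_ONSET_CUTOFF_MONTHS
    autopsy_csv: str | None = None
    cpeptide_csv: str | None = None
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    cohort: SyntheticCohortConfig | None = None
    studies: SyntheticStudyConfig | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "outdir",
            "seed",
            "alpha",
            "window",
            "age_max",
            "onset_cutoff_months",
            "autopsy_csv",
            "cpeptide_csv",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "mcmc" in raw:
            kwargs["mcmc"] = MCMCConfig(**raw["mcmc"])
        if "cohort" in raw:
            kwargs["cohort"] = SyntheticCohortConfig(**raw["cohort"])
        if "studies" in raw:
            kwargs["studies"] = SyntheticStudyConfig(**raw["studies"])
        return cls(**kwargs)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis chain and write all artifacts to ``cfg.outdir``.

    Stages: load/simulate inputs -> fit the demand parameter alpha on the
    recent-onset under-``age_max`` subset -> residual series for the whole
    cohort under the fitted alpha -> 9-point smoothing -> pairing with
    C-peptide timepoints -> weighted Bayesian regression.  Returns the
    report dict (also written as ``report.json``).
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed
    t0 = time.perf_counter()

    def stage(msg: str) -> None:
        logger.info("[%6.2fs] %s", time.perf_counter() - t0, msg)

    model0 = default_model(alpha=cfg.alpha)

    if cfg.autopsy_csv:
        records = read_autopsy_csv(cfg.autopsy_csv)
        stage(f"loaded {len(records)} autopsy records from {cfg.autopsy_csv}")
    else:
        cohort_cfg = cfg.cohort or SyntheticCohortConfig(seed=seed)
        records = generate_autopsy_cohort(cohort_cfg, model0)
        write_autopsy_csv(records, out / "autopsy.csv", seed=seed)
        stage(f"simulated {len(records)} autopsy records")

    if cfg.cpeptide_csv:
        aggregates = read_cpeptide_csv(cfg.cpeptide_csv)
        stage(f"loaded {len(aggregates)} C-peptide timepoints from {cfg.cpeptide_csv}")
    else:
        study_cfg = cfg.studies or SyntheticStudyConfig(seed=seed + 1)
        aggregates = generate_cpeptide_aggregates(study_cfg, model0)
        write_cpeptide_csv(aggregates, out / "cpeptide.csv", seed=seed)
        stage(f"simulated {len(aggregates)} C-peptide timepoints")

    alpha_model = AlphaDemandModel(
        records,
        model0.weight_curve,
        model0.bcm_curve,
        age_max=cfg.age_max,
        onset_cutoff_months=cfg.onset_cutoff_months,
    )
    alpha_res = alpha_model.fit(method="wls")
    stage(
        f"alpha fit on {alpha_res.estimate.n_used} recent-onset records: "
        f"{alpha_res.alpha_hat:.1f}"
    )

    model = model0.with_alpha(alpha_res.alpha_hat)
    resid = residual_series(records, model)
    write_residuals_csv(resid, out / "residuals.csv", seed=seed)
    smoothed = moving_average(resid, window=cfg.window)
    stage(f"{len(resid)} residuals -> {smoothed.times.size} smoothed windows")

    pairs = align_with_cpeptide(smoothed, aggregates)
    write_pairs_csv(pairs, out / "pairs.csv", seed=seed)
    stage(f"{len(pairs)} paired observations")

    mcmc = MCMCConfig(**{**cfg.mcmc.__dict__, "seed": seed})
    result = WeightedBayesLinearModel.from_pairs(pairs).fit(mcmc)
    stage(
        f"regression done: P(slope>0) = {result.p_slope_positive:.4f}, "
        f"PSRF = {result.psrf.round(4).tolist()}"
    )

    posterior = result.to_dict() | {"version": __version__}
    (out / "posterior.json").write_text(json.dumps(posterior, indent=2))

    report = {
        "version": __version__,
        "seed": seed,
        "n_autopsy_records": len(records),
        "n_recent_onset_used": alpha_res.estimate.n_used,
        "alpha_hat": alpha_res.alpha_hat,
        "alpha_ci95": list(alpha_res.conf_int()),
        "n_pairs": len(pairs),
        "slope_mean": posterior["slope_mean"],
        "intercept_mean": posterior["intercept_mean"],
        "psrf": posterior["psrf"],
        "acceptance_fraction": posterior["acceptance_fraction"],
        "p_slope_positive": posterior["p_slope_positive"],
        "significant": posterior["significant"],
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    stage("report written")
    return report
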