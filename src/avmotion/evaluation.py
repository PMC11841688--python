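"""Model-versus-data comparison tables.

Predictions from the three cue-combination models are scored against the
empirical audio-visual fits three ways: squared errors of precision and
bias per (condition, model) with cohort mean +/- SD, percentile bootstrap
CIs of prediction-minus-empirical differences per participant, and RMSE of
each model-implied psychometric curve against the observed response
proportions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cue_models import Model, Prediction
from .exceptions import ValidationError
from .kinematics import VelocityDistribution
from .psychometrics import (
    AcrossTrialFit,
    BinnedData,
    PsychFit,
    model_implied_curve,
    rmse,
)

__all__ = [
    "ErrorTable",
    "DifferenceCI",
    "RmseTable",
    "squared_errors",
    "bootstrap_difference_ci",
    "model_rmse_table",
    "rank_models",
    "report",
]

logger = logging.getLogger(__name__)

#: Models scored on bias; ICI predicts 0 by definition and is excluded.
BIAS_MODELS = (Model.BCI, Model.BCI_PLUS)


@dataclass(frozen=True)
class ErrorTable:
    """Per-participant squared errors plus cohort summaries."""

    per_participant: pd.DataFrame  # participant, condition, model, sq_err_*

    def summary(self, parameter: str) -> pd.DataFrame:
        """Cohort mean and SD of squared error by (condition, model).

        ``parameter`` is 'precision' or 'bias'; the bias table excludes ICI.
        """
        col = {"precision": "sq_err_sigma", "bias": "sq_err_pse"}[parameter]
        df = self.per_participant
        if parameter == "bias":
            df = df[df["model"].isin([m.value for m in BIAS_MODELS])]
        out = (df.groupby(["condition", "model"], sort=True)[col]
                 .agg(["mean", "std", "count"]).reset_index())
        return out.rename(columns={"count": "n_participants"})


@dataclass(frozen=True)
class DifferenceCI:
    """Percentile CI of prediction-minus-empirical replicate differences."""

    parameter: str  # 'precision' or 'bias'
    lower: float
    upper: float
    contains_zero: bool
    n_boot: int
    warning: str = ""

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValidationError("lower must be <= upper")


@dataclass(frozen=True)
class RmseTable:
    """Per-participant model-curve RMSEs plus cohort summaries."""

    per_participant: pd.DataFrame  # participant, condition, model, rmse

    def summary(self) -> pd.DataFrame:
        out = (self.per_participant
               .groupby(["condition", "model"], sort=True)["rmse"]
               .agg(["mean", "sem", "count"]).reset_index())
        return out.rename(columns={"count": "n_participants"})


def squared_errors(
    predictions: Mapping[tuple[str, str, Model], Prediction],
    empirical_fits: Mapping[tuple[str, str], PsychFit],
) -> ErrorTable:
    """Squared prediction errors for every (participant, condition, model).

    Every prediction key must have a matching empirical audio-visual fit.
    Bias errors are recorded as NaN for ICI (zero-bias by definition).
    """
    rows = []
    for (pid, condition, model), pred in predictions.items():
        if (pid, condition) not in empirical_fits:
            raise ValidationError(
                f"no empirical fit for participant {pid!r}, "
                f"condition {condition!r}"
            )
        emp = empirical_fits[(pid, condition)]
        sq_sigma = (pred.sigma_av - emp.sigma) ** 2
        sq_pse = ((pred.pse_av - emp.alpha) ** 2
                  if model in BIAS_MODELS else np.nan)
        rows.append((pid, condition, model.value, sq_sigma, sq_pse))
    df = pd.DataFrame(
        rows,
        columns=["participant", "condition", "model",
                 "sq_err_sigma", "sq_err_pse"],
    ).sort_values(["participant", "condition", "model"]).reset_index(drop=True)
    return ErrorTable(df)


def bootstrap_difference_ci(
    pred_samples: np.ndarray,
    emp_samples: np.ndarray,
    level: float = 0.95,
    parameter: str = "precision",
) -> DifferenceCI:
    """Percentile CI of index-paired (prediction - empirical) replicates."""
    p = np.asarray(pred_samples, dtype=float)
    e = np.asarray(emp_samples, dtype=float)
    if p.shape != e.shape or p.ndim != 1:
        raise ValidationError("replicate vectors must be paired 1-D arrays")
    warning = ""
    if p.size < 100:
        warning = f"only {p.size} retained replicates"
    diff = p - e
    lo = (1.0 - level) / 2.0
    lower, upper = float(np.quantile(diff, lo)), float(np.quantile(diff, 1 - lo))
    return DifferenceCI(parameter, lower, upper,
                        contains_zero=(lower <= 0.0 <= upper),
                        n_boot=p.size, warning=warning)


def model_rmse_table(
    av_datasets: Mapping[tuple[str, str], BinnedData],
    predictions: Mapping[tuple[str, str, Model], Prediction],
    head_dists: Mapping[tuple[str, str], VelocityDistribution] | None = None,
    lapse: float = 0.0,
) -> RmseTable:
    """RMSE of each model-implied curve against the observed proportions.

    Each predicted (pse, sigma) pair is mapped to a response curve via the
    standard model, or the head-speed-marginalized model when a head-speed
    distribution is supplied for that (participant, condition).
    """
    rows = []
    for (pid, condition, model), pred in predictions.items():
        key = (pid, condition)
        if key not in av_datasets:
            raise ValidationError(f"no binned data for {key}")
        data = av_datasets[key]
        if head_dists is not None and key in head_dists:
            hd = head_dists[key]
            fit: PsychFit | AcrossTrialFit = AcrossTrialFit(
                pred.pse_av, pred.sigma_av * hd.mean, lapse, hd,
                loglik=np.nan, converged=True,
            )
        else:
            fit = PsychFit(pred.pse_av, pred.sigma_av, lapse,
                           loglik=np.nan, converged=True)
        curve = model_implied_curve(fit, data.gain)
        rows.append((pid, condition, model.value,
                     rmse(curve, data.proportions)))
    df = pd.DataFrame(
        rows, columns=["participant", "condition", "model", "rmse"]
    ).sort_values(["participant", "condition", "model"]).reset_index(drop=True)
    return RmseTable(df)


def rank_models(table: ErrorTable | RmseTable | pd.DataFrame,
                column: str | None = None) -> pd.DataFrame:
    """Order models by cohort mean error and count per-case wins.

    Returns one row per model with its cohort mean and the number of
    (participant, condition) cases where it is the strict-minimum model;
    ties count for no model and set the ``tied`` flag on those cases' rows.
    """
    if isinstance(table, ErrorTable):
        df, column = table.per_participant, column or "sq_err_sigma"
    elif isinstance(table, RmseTable):
        df, column = table.per_participant, column or "rmse"
    else:
        df = table
        if column is None:
            raise ValidationError("column required for a raw DataFrame")
    df = df.dropna(subset=[column])
    means = df.groupby("model", sort=True)[column].mean()
    wins = {m: 0 for m in means.index}
    n_cases = 0
    n_ties = 0
    for _, grp in df.groupby(["participant", "condition"], sort=True):
        n_cases += 1
        vals = grp.set_index("model")[column]
        lo = vals.min()
        winners = vals.index[vals == lo]
        if len(winners) == 1:
            wins[winners[0]] += 1
        else:
            n_ties += 1
    out = pd.DataFrame({
        "model": means.index,
        "mean_error": means.to_numpy(),
        "best_in_n_cases": [wins[m] for m in means.index],
    })
    out["n_cases"] = n_cases
    out["n_tied_cases"] = n_ties
    return out.sort_values(
        ["mean_error", "model"]).reset_index(drop=True)


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def report(
    out_dir: str | Path,
    error_table: ErrorTable | None = None,
    rmse_table: RmseTable | None = None,
    config: Mapping | None = None,
    seeds: Mapping | None = None,
    make_plots: bool = False,
) -> dict:
    """Write CSV tables and a JSON summary; returns the summary dict.

    The summary embeds a config hash and the seeds used so a run can be
    reproduced exactly. Plotting is best-effort: a missing backend logs and
    is skipped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config_hash": config_hash(config or {}),
        "seeds": dict(seeds or {}),
        "tables": {},
    }
    if error_table is not None:
        error_table.per_participant.to_csv(out / "error_table.csv", index=False)
        summary["tables"]["error_table"] = "error_table.csv"
        for param in ("precision", "bias"):
            s = error_table.summary(param)
            s.to_csv(out / f"squared_error_{param}_summary.csv", index=False)
            summary[f"squared_error_{param}"] = {
                f"{r.condition}/{r.model}": round(float(r["mean"]), 10)
                for _, r in s.iterrows()
            }
    if rmse_table is not None:
        rmse_table.per_participant.to_csv(out / "rmse_table.csv", index=False)
        summary["tables"]["rmse_table"] = "rmse_table.csv"
        s = rmse_table.summary()
        s.to_csv(out / "rmse_summary.csv", index=False)
        summary["rmse"] = {
            f"{r.condition}/{r.model}": round(float(r["mean"]), 10)
            for _, r in s.iterrows()
        }
    if make_plots:
        try:
            _write_plots(out, error_table, rmse_table)
        except Exception as exc:  # plotting is optional
            logger.warning("plots skipped: %s", exc)
            summary["plots_skipped"] = str(exc)
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True))
    return summary


def _write_plots(out: Path, error_table: ErrorTable | None,
                 rmse_table: RmseTable | None) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if error_table is not None:
        s = error_table.summary("precision")
        fig, ax = plt.subplots(figsize=(7, 4))
        for model, grp in s.groupby("model"):
            ax.bar([f"{c}\n{model}" for c in grp["condition"]], grp["mean"],
                   label=model)
        ax.set_ylabel("squared error (precision)")
        fig.tight_layout()
        fig.savefig(out / "squared_error_precision.png", dpi=120)
        plt.close(fig)
    if rmse_table is not None:
        s = rmse_table.summary()
        fig, ax = plt.subplots(figsize=(7, 4))
        for model, grp in s.groupby("model"):
            ax.plot(grp["condition"], grp["mean"], marker="o", label=model)
        ax.set_ylabel("RMSE")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "rmse.png", dpi=120)
        plt.close(fig)
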