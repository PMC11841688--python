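"""End-to-end simulate -> fit -> predict -> evaluate runs.

Glue used by the CLI, the tests, and the acceptance script. A simulated
participant is run through exactly the analysis a real trial table would
see; the only simulation-side shortcut is that the shared-noise variance is
taken from the generative truth (standing in for the separate
self-movement-precision experiment that measures it empirically).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cue_models import (
    Model,
    Modality,
    Prediction,
    SharedNoise,
    UnimodalEstimate,
    predict_all,
)
from .evaluation import ErrorTable, RmseTable, model_rmse_table, squared_errors
from .psychometrics import BinnedData, PsychFit, bin_responses, fit_cumulative_gaussian
from .synthetic_data import (
    TABLE1_CONDITIONS,
    Condition,
    ObserverParams,
    canonical_gain_grid,
    condition_label,
    make_schedule,
    simulate_trials,
)

AV_NAMES = {
    (False, False): "no_jitter",
    (False, True): "visual_jitter",
    (True, False): "audio_jitter",
    (True, True): "audio_visual_jitter",
}


@dataclass
class ParticipantResult:
    participant_id: str
    trials: pd.DataFrame
    fits: dict[Condition, PsychFit]
    binned: dict[Condition, BinnedData]
    estimates: dict[tuple[Modality, bool], UnimodalEstimate]
    predictions: dict[tuple[str, Model], Prediction]
    av_fits: dict[str, PsychFit]
    av_binned: dict[str, BinnedData]


def true_shared_noise(params: ObserverParams) -> SharedNoise:
    """Generative shared-noise variance in gain units."""
    return SharedNoise((params.sigma_sm / params.head_mu) ** 2, reps_used=3)


def fit_all_conditions(
    trials: pd.DataFrame, n_starts: int = 5
) -> tuple[dict[Condition, PsychFit], dict[Condition, BinnedData]]:
    fits: dict[Condition, PsychFit] = {}
    binned: dict[Condition, BinnedData] = {}
    for (mod, aj, vj), grp in trials.groupby(
        ["modality", "audio_jitter", "visual_jitter"], sort=True
    ):
        cond = Condition(Modality(mod), bool(aj), bool(vj))
        data = bin_responses(grp)
        binned[cond] = data
        fits[cond] = fit_cumulative_gaussian(data, n_starts=n_starts)
    return fits, binned


def unimodal_estimates(
    fits: dict[Condition, PsychFit]
) -> dict[tuple[Modality, bool], UnimodalEstimate]:
    out: dict[tuple[Modality, bool], UnimodalEstimate] = {}
    for cond, fit in fits.items():
        if cond.modality is Modality.AUDIO_VISUAL:
            continue
        jit = (cond.audio_jitter if cond.modality is Modality.AUDIO
               else cond.visual_jitter)
        out[(cond.modality, jit)] = UnimodalEstimate(
            cond.modality, jit, fit.alpha, fit.sigma)
    return out


def run_participant(
    params: ObserverParams,
    seed: int,
    participant_id: str = "sim",
    n_reps: int = 30,
    gains: np.ndarray | None = None,
    shared: SharedNoise | None = None,
    n_starts: int = 5,
) -> ParticipantResult:
    """Simulate one observer and run the full single-participant analysis."""
    if gains is None:
        gains = canonical_gain_grid()
    schedule = make_schedule(n_reps, gains, TABLE1_CONDITIONS, seed)
    trials = simulate_trials(params, schedule, seed + 1, participant_id)
    fits, binned = fit_all_conditions(trials, n_starts=n_starts)
    estimates = unimodal_estimates(fits)
    if shared is None:
        shared = true_shared_noise(params)
    predictions = predict_all(estimates, shared)
    av_fits: dict[str, PsychFit] = {}
    av_binned: dict[str, BinnedData] = {}
    for cond, fit in fits.items():
        if cond.modality is Modality.AUDIO_VISUAL:
            name = AV_NAMES[(cond.audio_jitter, cond.visual_jitter)]
            av_fits[name] = fit
            av_binned[name] = binned[cond]
    return ParticipantResult(participant_id, trials, fits, binned, estimates,
                             predictions, av_fits, av_binned)


def run_cohort(
    params_list: list[ObserverParams],
    seed: int,
    n_reps: int = 30,
    n_starts: int = 3,
) -> tuple[ErrorTable, RmseTable, list[ParticipantResult]]:
    """Simulate and evaluate a cohort; one ObserverParams per participant."""
    results = []
    predictions: dict[tuple[str, str, Model], Prediction] = {}
    emp_fits: dict[tuple[str, str], PsychFit] = {}
    av_data: dict[tuple[str, str], BinnedData] = {}
    for i, params in enumerate(params_list):
        pid = f"p{i + 1}"
        res = run_participant(params, seed + 1000 * i, pid, n_reps=n_reps,
                              n_starts=n_starts)
        results.append(res)
        for (cond_name, model), pred in res.predictions.items():
            predictions[(pid, cond_name, model)] = pred
        for cond_name, fit in res.av_fits.items():
            emp_fits[(pid, cond_name)] = fit
            av_data[(pid, cond_name)] = res.av_binned[cond_name]
    error_table = squared_errors(predictions, emp_fits)
    rmse_table = model_rmse_table(av_data, predictions)
    return error_table, rmse_table, results
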