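"""Cue-combination predictions for audio-visual motion judgments.

Three model variants predict the audio-visual psychometric parameters (bias
and precision, both in stimulus-gain units) from the unimodal fits:

* ``bci_predict`` -- reliability-weighted fusion of body-centered cues,
  ignoring any noise shared between them.
* ``bci_plus_predict`` -- the same fusion corrected for the correlation
  ``rho`` induced by a self-movement noise source common to both cues.
* ``ici_predict`` -- fusion of the raw image signals after the shared
  self-movement variance has been subtracted out; predicts zero bias.

The shared-noise variance is never a free parameter: it is estimated from
matched condition pairs via the variance sum law (``variance_sum_law`` /
``estimate_sigma_sm``) and converted to a correlation with ``compute_rho``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .exceptions import (
    InconsistentSharedNoiseError,
    NegativeImageVarianceError,
    ValidationError,
)

__all__ = [
    "Modality",
    "Model",
    "UnimodalEstimate",
    "SharedNoise",
    "Prediction",
    "bci_predict",
    "compute_rho",
    "bci_plus_predict",
    "variance_sum_law",
    "estimate_sigma_sm",
    "ici_predict",
    "predict_all",
    "propagate_bootstrap",
]


class Modality(str, Enum):
    AUDIO = "audio"
    VISUAL = "visual"
    AUDIO_VISUAL = "audio_visual"


class Model(str, Enum):
    BCI = "BCI"
    BCI_PLUS = "BCI_plus"
    ICI = "ICI"


@dataclass(frozen=True)
class UnimodalEstimate:
    """Fitted psychometric parameters of one predicting condition.

    ``pse`` and ``sigma`` are in stimulus-gain units. ``bootstrap`` may hold
    an ``(n, 2)`` array of replicate ``(pse, sigma)`` pairs.
    """

    modality: Modality
    jitter: bool
    pse: float
    sigma: float
    bootstrap: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.modality not in (Modality.AUDIO, Modality.VISUAL):
            raise ValidationError("unimodal estimate must be audio or visual")
        if not self.sigma > 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class SharedNoise:
    """Self-movement noise variance estimate (gain units squared).

    ``excluded`` marks the case where every repetition produced a negative
    variance and no estimate exists.
    """

    sigma_sm_sq: float
    reps_used: int
    reps_excluded: int = 0
    excluded: bool = False

    def __post_init__(self) -> None:
        if not self.excluded:
            if self.reps_used < 1:
                raise ValidationError("a valid estimate needs reps_used >= 1")
            if not self.sigma_sm_sq >= 0:
                raise ValidationError("sigma_sm_sq must be >= 0")


@dataclass(frozen=True)
class Prediction:
    """Model-predicted audio-visual bias and precision."""

    model: Model
    pse_av: float
    sigma_av: float
    w_a: float
    w_v: float
    rho: float = 0.0
    vetoed: Modality | None = None


def bci_predict(a: UnimodalEstimate, v: UnimodalEstimate) -> Prediction:
    """Standard reliability-weighted fusion of the two unimodal estimates.

    Weights are proportional to the inverse variances; the predicted
    precision is the usual harmonic combination, which never exceeds the
    better unimodal sigma.
    """
    _check_pair(a, v)
    rel_a = 1.0 / a.sigma**2
    rel_v = 1.0 / v.sigma**2
    w_a = rel_a / (rel_a + rel_v)
    w_v = rel_v / (rel_a + rel_v)
    pse_av = w_a * a.pse + w_v * v.pse
    sigma_av = math.sqrt(
        (a.sigma**2 * v.sigma**2) / (a.sigma**2 + v.sigma**2)
    )
    return Prediction(Model.BCI, pse_av, sigma_av, w_a, w_v, rho=0.0)


def compute_rho(shared: SharedNoise, sigma_a: float, sigma_v: float) -> float:
    """Correlation between the compensated cues: sigma_SM^2 / (sigma_a * sigma_v).

    Raises :class:`InconsistentSharedNoiseError` if the implied correlation
    is >= 1 (shared noise at least as large as one cue's total noise).
    """
    if shared.excluded:
        raise ValidationError("shared-noise estimate was excluded entirely")
    if not (sigma_a > 0 and sigma_v > 0):
        raise ValidationError("sigmas must be > 0")
    if shared.sigma_sm_sq < 0:
        raise ValidationError("sigma_sm_sq must be >= 0")
    rho = shared.sigma_sm_sq / (sigma_a * sigma_v)
    if rho >= 1.0:
        raise InconsistentSharedNoiseError(
            f"shared noise implies rho = {rho:.4g} >= 1"
        )
    return rho


def bci_plus_predict(
    a: UnimodalEstimate, v: UnimodalEstimate, rho: float
) -> Prediction:
    """Correlation-adjusted fusion of the two unimodal estimates.

    The adjusted reliabilities are ``1/sigma_m^2 - rho/(sigma_a sigma_v)``.
    If one of them is negative the corresponding cue is vetoed: its
    reliability is clamped to 0 (the other cue captures the decision) and
    the returned prediction carries ``vetoed`` naming the clamped modality.
    At ``rho = 0`` the result equals :func:`bci_predict` exactly.
    """
    _check_pair(a, v)
    if not (0.0 <= rho < 1.0):
        raise ValidationError(f"rho must be in [0, 1), got {rho}")
    cross = rho / (a.sigma * v.sigma)
    rel_a = 1.0 / a.sigma**2 - cross
    rel_v = 1.0 / v.sigma**2 - cross
    vetoed: Modality | None = None
    if rel_a < 0.0:
        rel_a, vetoed = 0.0, a.modality
    elif rel_v < 0.0:
        rel_v, vetoed = 0.0, v.modality
    w_a = rel_a / (rel_a + rel_v)
    w_v = rel_v / (rel_a + rel_v)
    pse_av = w_a * a.pse + w_v * v.pse
    rel_av = (1.0 / a.sigma**2 + 1.0 / v.sigma**2 - 2.0 * cross) / (
        1.0 - rho**2
    )
    sigma_av = 1.0 / math.sqrt(rel_av)
    return Prediction(Model.BCI_PLUS, pse_av, sigma_av, w_a, w_v, rho=rho,
                      vetoed=vetoed)


def variance_sum_law(sigma_total_sq: float, sigma_other_sq: float) -> float:
    """Subtract one variance component from a total variance.

    The result may be negative; callers decide policy
    (:func:`estimate_sigma_sm` excludes, :func:`ici_predict` errors).
    """
    if sigma_total_sq < 0 or sigma_other_sq < 0:
        raise ValidationError("variances must be >= 0")
    return sigma_total_sq - sigma_other_sq


def estimate_sigma_sm(rep_estimates: Sequence[float]) -> SharedNoise:
    """Combine up to three per-repetition sigma_SM^2 values.

    Negative repetitions are excluded; the estimate is the mean of the
    remainder. If every repetition is negative the returned object has
    ``excluded=True`` and no usable variance.
    """
    vals = [float(x) for x in rep_estimates]
    if not 1 <= len(vals) <= 3:
        raise ValidationError("expected 1-3 repetition estimates")
    kept = [x for x in vals if x >= 0.0]
    n_excl = len(vals) - len(kept)
    if not kept:
        return SharedNoise(math.nan, 0, n_excl, excluded=True)
    return SharedNoise(float(np.mean(kept)), len(kept), n_excl)


def ici_predict(
    a: UnimodalEstimate, v: UnimodalEstimate, shared: SharedNoise
) -> Prediction:
    """Fusion of image-only noises after removing the shared variance.

    The shared variance is subtracted from both unimodal variances and the
    standard harmonic combination applied to what remains; the predicted
    bias is exactly 0 (image cues are assumed internally consistent).
    """
    _check_pair(a, v)
    if shared.excluded:
        raise ValidationError("shared-noise estimate was excluded entirely")
    var_a_im = variance_sum_law(a.sigma**2, shared.sigma_sm_sq)
    var_v_im = variance_sum_law(v.sigma**2, shared.sigma_sm_sq)
    if var_a_im <= 0 or var_v_im <= 0:
        raise NegativeImageVarianceError(
            "shared variance >= a unimodal total variance"
        )
    rel_a = 1.0 / var_a_im
    rel_v = 1.0 / var_v_im
    w_a = rel_a / (rel_a + rel_v)
    w_v = rel_v / (rel_a + rel_v)
    sigma_av = math.sqrt(var_a_im * var_v_im / (var_a_im + var_v_im))
    return Prediction(Model.ICI, 0.0, sigma_av, w_a, w_v, rho=0.0)


# (audio_jitter, visual_jitter) of each AV condition -> jitter flag of the
# audio and visual predicting conditions. Each AV condition is predicted by
# the unimodal conditions with matching jitter flags.
AV_PREDICTING_PAIRS: dict[tuple[bool, bool], tuple[bool, bool]] = {
    (False, False): (False, False),
    (False, True): (False, True),
    (True, False): (True, False),
    (True, True): (True, True),
}

AV_CONDITION_NAMES: dict[tuple[bool, bool], str] = {
    (False, False): "no_jitter",
    (False, True): "visual_jitter",
    (True, False): "audio_jitter",
    (True, True): "audio_visual_jitter",
}


def predict_all(
    estimates: Mapping[tuple[Modality, bool], UnimodalEstimate],
    shared: SharedNoise,
) -> dict[tuple[str, Model], Prediction]:
    """All three model predictions for each of the four AV conditions.

    ``estimates`` maps ``(modality, jitter)`` to the fitted unimodal
    estimate. Raises if a required predicting condition is missing or if an
    estimate's own (modality, jitter) tags disagree with its key.
    """
    for key, est in estimates.items():
        if (est.modality, est.jitter) != key:
            raise ValidationError(
                f"estimate tagged {(est.modality.value, est.jitter)} stored "
                f"under key {(key[0].value, key[1])}"
            )
    out: dict[tuple[str, Model], Prediction] = {}
    for av_key, (a_jit, v_jit) in AV_PREDICTING_PAIRS.items():
        name = AV_CONDITION_NAMES[av_key]
        try:
            a = estimates[(Modality.AUDIO, a_jit)]
            v = estimates[(Modality.VISUAL, v_jit)]
        except KeyError as exc:
            raise ValidationError(
                f"missing predicting condition {exc.args[0]} for AV "
                f"condition {name!r}"
            ) from None
        rho = compute_rho(shared, a.sigma, v.sigma)
        out[(name, Model.BCI)] = bci_predict(a, v)
        out[(name, Model.BCI_PLUS)] = bci_plus_predict(a, v, rho)
        out[(name, Model.ICI)] = ici_predict(a, v, shared)
    return out


def propagate_bootstrap(
    model: Model,
    a_boot: np.ndarray,
    v_boot: np.ndarray,
    a_meta: tuple[Modality, bool] = (Modality.AUDIO, False),
    v_meta: tuple[Modality, bool] = (Modality.VISUAL, False),
    sigma_sm_sq_boot: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Apply a model's equations to paired bootstrap replicates.

    ``a_boot``/``v_boot`` are ``(n, 2)`` arrays of ``(pse, sigma)``
    replicates, paired by index; ``sigma_sm_sq_boot`` (required for BCI+ and
    ICI) is a length-``n`` vector of per-replicate shared variances, NaN
    where the replicate's estimate was excluded entirely.

    Returns an ``(m, 2)`` array of predicted ``(pse, sigma)`` for the ``m``
    replicates that produced a valid prediction, and the number dropped.
    """
    a_boot = np.asarray(a_boot, dtype=float)
    v_boot = np.asarray(v_boot, dtype=float)
    if a_boot.shape != v_boot.shape or a_boot.ndim != 2:
        raise ValidationError("replicate arrays must have matching (n, 2) shape")
    n = a_boot.shape[0]
    if model in (Model.BCI_PLUS, Model.ICI):
        if sigma_sm_sq_boot is None:
            raise ValidationError(f"{model.value} needs sigma_sm_sq replicates")
        sm = np.asarray(sigma_sm_sq_boot, dtype=float)
        if sm.shape != (n,):
            raise ValidationError("sigma_sm_sq_boot length mismatch")
    preds: list[tuple[float, float]] = []
    dropped = 0
    for i in range(n):
        try:
            a = UnimodalEstimate(*a_meta, a_boot[i, 0], a_boot[i, 1])
            v = UnimodalEstimate(*v_meta, v_boot[i, 0], v_boot[i, 1])
            if model is Model.BCI:
                p = bci_predict(a, v)
            else:
                if not np.isfinite(sm[i]) or sm[i] < 0:
                    dropped += 1
                    continue
                shared = SharedNoise(float(sm[i]), 1)
                if model is Model.BCI_PLUS:
                    rho = compute_rho(shared, a.sigma, v.sigma)
                    p = bci_plus_predict(a, v, rho)
                else:
                    p = ici_predict(a, v, shared)
        except ValidationError:
            dropped += 1
            continue
        preds.append((p.pse_av, p.sigma_av))
    return np.asarray(preds, dtype=float).reshape(-1, 2), dropped


def _check_pair(a: UnimodalEstimate, v: UnimodalEstimate) -> None:
    if a.modality is not Modality.AUDIO or v.modality is not Modality.VISUAL:
        raise ValidationError(
            "bimodal prediction needs one audio and one visual estimate, "
            f"got ({a.modality.value}, {v.modality.value})"
        )
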