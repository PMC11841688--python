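"""Generative observer for gain-coded left/right motion judgments.

The simulated experiment presents an auditory, visual, or audio-visual
stimulus whose velocity is a signed proportion (*gain*) of the observer's
concurrent head velocity. The observer compensates each modality's image
motion for self-movement using a noisy, shared self-movement signal, and
judges whether the stimulus moved with or against the head.

Per-trial decision variable for modality ``m``::

    D_m = (gain - (1 - r_m)) * h + eps_m + eps_SM

where ``h`` is the trial's head speed, ``r_m`` the modality's compensation
gain (``1`` = perfect compensation, giving zero bias), ``eps_m`` the
modality's image noise (inflated when the stimulus is jittered), and
``eps_SM`` a single self-movement noise draw shared by both modalities
within a trial. All noises are in amplitude units (deg/s): judgments are
coded as motion amplitude, and dividing by head speed yields the gain-unit
psychometric parameters. Audio-visual trials combine the two decision
variables with reliability weights adjusted for the shared-noise
correlation (the BCI+ observer); a flag switches to plain uncorrelated
weighting for model-discrimination experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cue_models import Modality, SharedNoise, UnimodalEstimate, bci_plus_predict, bci_predict, compute_rho
from .exceptions import NotApplicableError, ValidationError

__all__ = [
    "Condition",
    "ObserverParams",
    "TABLE1_CONDITIONS",
    "canonical_gain_grid",
    "condition_label",
    "make_schedule",
    "draw_head_velocity",
    "decision_variables",
    "simulate_response",
    "simulate_trials",
    "analytic_psychometric",
    "generate_stimulus_trace",
    "gate_stimulus_level",
]

GAIN_MAX = 0.5
JITTER_HALF_WIDTH_DEG = 7.5
JITTER_RATE_HZ = 5.0
DEFAULT_HEAD_FLOOR = 15.0


@dataclass(frozen=True)
class Condition:
    """One of the eight interleaved stimulus conditions.

    Jitter flags may only be set on modalities that are present.
    """

    modality: Modality
    audio_jitter: bool = False
    visual_jitter: bool = False

    def __post_init__(self) -> None:
        if self.modality is Modality.VISUAL and self.audio_jitter:
            raise ValidationError("visual-only condition cannot jitter audio")
        if self.modality is Modality.AUDIO and self.visual_jitter:
            raise ValidationError("audio-only condition cannot jitter visual")


#: The eight constructible conditions, in canonical order.
TABLE1_CONDITIONS: tuple[Condition, ...] = (
    Condition(Modality.VISUAL, visual_jitter=False),
    Condition(Modality.VISUAL, visual_jitter=True),
    Condition(Modality.AUDIO, audio_jitter=False),
    Condition(Modality.AUDIO, audio_jitter=True),
    Condition(Modality.AUDIO_VISUAL, False, False),
    Condition(Modality.AUDIO_VISUAL, False, True),
    Condition(Modality.AUDIO_VISUAL, True, False),
    Condition(Modality.AUDIO_VISUAL, True, True),
)


def condition_label(cond: Condition) -> str:
    bits = [cond.modality.value]
    if cond.audio_jitter:
        bits.append("aj")
    if cond.visual_jitter:
        bits.append("vj")
    return "+".join(bits)


def canonical_gain_grid(n_steps: int = 7, max_gain: float = GAIN_MAX) -> np.ndarray:
    """Gain levels 0 to +/-max_gain: ``n_steps`` magnitudes (0 included)
    mirrored to both directions, 2*n_steps - 1 distinct values."""
    mags = np.linspace(0.0, max_gain, n_steps)
    return np.unique(np.concatenate([-mags, mags]))


@dataclass(frozen=True)
class ObserverParams:
    """Generative truth for one simulated participant.

    Image-noise SDs (``sigma_img_*``), the shared self-movement noise SD
    (``sigma_sm``) and head-speed parameters are all in deg/s; compensation
    gains ``r_audio``/``r_visual`` are dimensionless (1 = unbiased).
    """

    sigma_img_audio: float
    sigma_img_visual: float
    sigma_img_audio_jitter: float
    sigma_img_visual_jitter: float
    sigma_sm: float
    r_audio: float = 1.0
    r_visual: float = 1.0
    head_mu: float = 80.0
    head_sd: float = 0.0
    head_floor: float = DEFAULT_HEAD_FLOOR
    lapse: float = 0.0
    bci_plus_observer: bool = True

    def __post_init__(self) -> None:
        for name in ("sigma_img_audio", "sigma_img_visual",
                     "sigma_img_audio_jitter", "sigma_img_visual_jitter",
                     "sigma_sm", "head_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.head_mu > self.head_floor >= 0:
            raise ValidationError("need head_mu > head_floor >= 0")
        if not 0.0 <= self.lapse <= 0.02:
            raise ValidationError("lapse must be in [0, 0.02]")

    @classmethod
    def from_gain_units(
        cls,
        sigma_audio: float,
        sigma_visual: float,
        sigma_audio_jitter: float,
        sigma_visual_jitter: float,
        sigma_sm: float,
        head_mu: float = 80.0,
        **kwargs,
    ) -> "ObserverParams":
        """Build from gain-unit noise SDs (multiplied by ``head_mu``)."""
        return cls(
            sigma_img_audio=sigma_audio * head_mu,
            sigma_img_visual=sigma_visual * head_mu,
            sigma_img_audio_jitter=sigma_audio_jitter * head_mu,
            sigma_img_visual_jitter=sigma_visual_jitter * head_mu,
            sigma_sm=sigma_sm * head_mu,
            head_mu=head_mu,
            **kwargs,
        )

    def sigma_img(self, modality: Modality, jitter: bool) -> float:
        if modality is Modality.AUDIO:
            return self.sigma_img_audio_jitter if jitter else self.sigma_img_audio
        if modality is Modality.VISUAL:
            return self.sigma_img_visual_jitter if jitter else self.sigma_img_visual
        raise ValidationError("image noise is per unimodal modality")

    def compensation(self, modality: Modality) -> float:
        return self.r_audio if modality is Modality.AUDIO else self.r_visual


def make_schedule(
    n_reps: int,
    gains: Sequence[float],
    conditions: Sequence[Condition],
    seed: int,
) -> pd.DataFrame:
    """Fully crossed, seeded-interleaved trial schedule.

    Every (condition, gain) cell appears exactly ``n_reps`` times; rows are
    shuffled into a random presentation order reproducible from ``seed``.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    gains = [float(g) for g in gains]
    if not gains or len(set(gains)) != len(gains):
        raise ValidationError("gains must be nonempty and distinct")
    conditions = list(conditions)
    if not conditions or len(set(conditions)) != len(conditions):
        raise ValidationError("conditions must be nonempty and distinct")
    for g in gains:
        if not -GAIN_MAX <= g <= GAIN_MAX:
            raise ValidationError(f"gain {g} outside [-{GAIN_MAX}, {GAIN_MAX}]")
    rows = [
        (cond.modality.value, cond.audio_jitter, cond.visual_jitter, g)
        for cond in conditions
        for g in gains
        for _ in range(n_reps)
    ]
    df = pd.DataFrame(
        rows, columns=["modality", "audio_jitter", "visual_jitter", "gain"]
    )
    rng = np.random.default_rng(seed)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df["sweep_index"] = 3
    return df


def draw_head_velocity(
    params: ObserverParams, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Per-trial median head speeds: Normal(head_mu, head_sd^2) truncated
    below at head_floor, via rejection sampling."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if params.head_sd == 0:
        return np.full(n, params.head_mu)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(params.head_mu, params.head_sd, size=2 * (n - filled))
        keep = draw[draw >= params.head_floor][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def _av_weights(params: ObserverParams, condition: Condition) -> tuple[float, float]:
    """True-noise integration weights for the audio-visual observer."""
    sig_a = math.hypot(params.sigma_img(Modality.AUDIO, condition.audio_jitter),
                       params.sigma_sm)
    sig_v = math.hypot(params.sigma_img(Modality.VISUAL, condition.visual_jitter),
                       params.sigma_sm)
    if params.bci_plus_observer and params.sigma_sm > 0:
        rho = params.sigma_sm**2 / (sig_a * sig_v)
        rel_a = max(1.0 / sig_a**2 - rho / (sig_a * sig_v), 0.0)
        rel_v = max(1.0 / sig_v**2 - rho / (sig_a * sig_v), 0.0)
    else:
        rel_a, rel_v = 1.0 / sig_a**2, 1.0 / sig_v**2
    return rel_a / (rel_a + rel_v), rel_v / (rel_a + rel_v)


def decision_variables(
    gain: float,
    condition: Condition,
    head_velocity: np.ndarray | float,
    params: ObserverParams,
    rng: np.random.Generator,
) -> dict[Modality, np.ndarray]:
    """Noisy per-trial amplitude estimates, one shared self-movement draw
    per trial. Vectorized over trials (``head_velocity`` may be an array)."""
    h = np.atleast_1d(np.asarray(head_velocity, dtype=float))
    if np.any(np.abs(h) < params.head_floor):
        raise ValidationError("head speed below floor")
    n = h.size
    eps_sm = rng.normal(0.0, params.sigma_sm, size=n) if params.sigma_sm > 0 else np.zeros(n)
    out: dict[Modality, np.ndarray] = {}
    modalities = (
        [Modality.AUDIO, Modality.VISUAL]
        if condition.modality is Modality.AUDIO_VISUAL
        else [condition.modality]
    )
    for m in modalities:
        jit = condition.audio_jitter if m is Modality.AUDIO else condition.visual_jitter
        sig = params.sigma_img(m, jit)
        eps = rng.normal(0.0, sig, size=n) if sig > 0 else np.zeros(n)
        bias = 1.0 - params.compensation(m)
        out[m] = (gain - bias) * h + eps + eps_sm
    return out


def simulate_response(
    gain: float,
    condition: Condition,
    head_velocity: np.ndarray | float,
    params: ObserverParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean with-the-head responses for one (gain, condition) cell."""
    dvs = decision_variables(gain, condition, head_velocity, params, rng)
    if condition.modality is Modality.AUDIO_VISUAL:
        w_a, w_v = _av_weights(params, condition)
        d = w_a * dvs[Modality.AUDIO] + w_v * dvs[Modality.VISUAL]
    else:
        d = dvs[condition.modality]
    resp = d > 0
    if params.lapse > 0:
        lapsed = rng.random(d.size) < params.lapse
        resp = np.where(lapsed, rng.random(d.size) < 0.5, resp)
    return resp


def simulate_trials(
    params: ObserverParams,
    schedule: pd.DataFrame,
    seed: int,
    participant_id: str = "sim",
) -> pd.DataFrame:
    """Complete a schedule into a trial table with head speeds and responses.

    Columns follow the on-disk convention: participant_id, modality,
    audio_jitter, visual_jitter, gain, response ('with'/'against'),
    head_velocity, sweep_index.
    """
    rng = np.random.default_rng(seed)
    df = schedule.copy().reset_index(drop=True)
    df["head_velocity"] = draw_head_velocity(params, len(df), rng)
    responses = np.empty(len(df), dtype=bool)
    # group by cell for vectorized draws; order within the table is preserved
    for (mod, aj, vj, gain), idx in df.groupby(
        ["modality", "audio_jitter", "visual_jitter", "gain"], sort=True
    ).groups.items():
        cond = Condition(Modality(mod), bool(aj), bool(vj))
        idx = np.asarray(idx)
        responses[idx] = simulate_response(
            float(gain), cond, df.loc[idx, "head_velocity"].to_numpy(), params, rng
        )
    df["response"] = np.where(responses, "with", "against")
    df.insert(0, "participant_id", participant_id)
    return df[
        ["participant_id", "modality", "audio_jitter", "visual_jitter",
         "gain", "response", "head_velocity", "sweep_index"]
    ]


def analytic_psychometric(
    params: ObserverParams, condition: Condition
) -> tuple[float, float]:
    """Closed-form (PSE, sigma) in gain units; requires a fixed head speed.

    Unimodal: PSE = 1 - r_m, sigma = sqrt(sigma_img^2 + sigma_sm^2)/head_mu.
    Audio-visual: the correlation-adjusted (or plain, per the observer flag)
    combination of the two unimodal values.
    """
    if params.head_sd != 0:
        raise NotApplicableError("closed form requires head_sd = 0")
    if condition.modality is not Modality.AUDIO_VISUAL:
        m = condition.modality
        jit = condition.audio_jitter if m is Modality.AUDIO else condition.visual_jitter
        sigma = math.hypot(params.sigma_img(m, jit), params.sigma_sm) / params.head_mu
        return 1.0 - params.compensation(m), sigma

    a = UnimodalEstimate(
        Modality.AUDIO, condition.audio_jitter,
        1.0 - params.r_audio,
        math.hypot(params.sigma_img(Modality.AUDIO, condition.audio_jitter),
                   params.sigma_sm) / params.head_mu,
    )
    v = UnimodalEstimate(
        Modality.VISUAL, condition.visual_jitter,
        1.0 - params.r_visual,
        math.hypot(params.sigma_img(Modality.VISUAL, condition.visual_jitter),
                   params.sigma_sm) / params.head_mu,
    )
    if params.bci_plus_observer and params.sigma_sm > 0:
        shared = SharedNoise((params.sigma_sm / params.head_mu) ** 2, 1)
        pred = bci_plus_predict(a, v, compute_rho(shared, a.sigma, v.sigma))
    else:
        pred = bci_predict(a, v)
        if params.sigma_sm > 0:
            # plain weights, but the shared noise still correlates the cues:
            # Var = w_a^2 s_a^2 + w_v^2 s_v^2 + 2 w_a w_v sigma_sm^2
            sm2 = (params.sigma_sm / params.head_mu) ** 2
            var = (pred.w_a**2 * a.sigma**2 + pred.w_v**2 * v.sigma**2
                   + 2 * pred.w_a * pred.w_v * sm2)
            pred = replace(pred, sigma_av=math.sqrt(var))
    return pred.pse_av, pred.sigma_av


def generate_stimulus_trace(
    head_position: np.ndarray,
    rate: float,
    gain: float,
    jitter: bool,
    seed: int | np.random.Generator = 0,
    jitter_rate: float = JITTER_RATE_HZ,
    jitter_half_width: float = JITTER_HALF_WIDTH_DEG,
) -> np.ndarray:
    """World-frame stimulus positions for a head-position trace.

    Position is ``gain`` times the head displacement from its first sample,
    plus (when ``jitter``) a piecewise-constant uniform offset redrawn at
    ``jitter_rate``.
    """
    head = np.asarray(head_position, dtype=float)
    pos = gain * (head - head[0])
    if jitter:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        dwell = max(int(round(rate / jitter_rate)), 1)
        n_seg = int(np.ceil(head.size / dwell))
        offsets = rng.uniform(-jitter_half_width, jitter_half_width, size=n_seg)
        pos = pos + np.repeat(offsets, dwell)[: head.size]
    return pos


def gate_stimulus_level(
    head_speed: np.ndarray, threshold: float, decay: float = 0.5
) -> np.ndarray:
    """Leaky stimulus amplitude gate.

    Level starts at 1, is multiplied by ``1 - decay`` on every frame spent
    below ``threshold``, and resets to 1 when speed recovers.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    if not 0 < decay <= 1:
        raise ValidationError("decay must be in (0, 1]")
    speed = np.asarray(head_speed, dtype=float)
    level = np.ones_like(speed)
    cur = 1.0
    for i, s in enumerate(speed):
        cur = cur * (1.0 - decay) if s < threshold else 1.0
        level[i] = cur
    return level
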