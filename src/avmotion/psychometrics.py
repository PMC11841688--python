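"""Psychometric function fitting for gain-coded left/right judgments.

Two response models are fit by maximum likelihood:

* standard cumulative Gaussian with a symmetric lapse rate,
  ``P(with | g) = lapse + (1 - 2 lapse) * Phi((g - alpha) / sigma)``;
* an across-trial-noise variant in which the judgment is made on motion
  *amplitude* so trial-to-trial head-speed variability enters the decision
  variable,
  ``P(with | g) = lapse + (1 - 2 lapse) * E_h[Phi((g - g0) h / sigma_amp)]``
  with the expectation over a truncated-Gaussian head-speed distribution.

Precision is reported as the fitted standard deviation (inverse slope);
bias as the 50% point (alpha / g0). Standard errors come from a
nonparametric bootstrap stratified by gain level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .exceptions import UnidentifiableDataError, ValidationError
from .kinematics import VelocityDistribution
from .synthetic_data import DEFAULT_HEAD_FLOOR

__all__ = [
    "BinnedData",
    "PsychFit",
    "AcrossTrialFit",
    "BootstrapResult",
    "bin_responses",
    "fit_cumulative_gaussian",
    "bootstrap_fit",
    "fit_across_trial_model",
    "model_implied_curve",
    "rmse",
]

LAPSE_MAX_DEFAULT = 0.02
_N_STARTS = 5


@dataclass(frozen=True)
class BinnedData:
    """Per-gain with-the-head counts."""

    gain: np.ndarray
    n_with: np.ndarray
    n_total: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=float)
        k = np.asarray(self.n_with, dtype=int)
        n = np.asarray(self.n_total, dtype=int)
        object.__setattr__(self, "gain", g)
        object.__setattr__(self, "n_with", k)
        object.__setattr__(self, "n_total", n)
        if not (g.shape == k.shape == n.shape) or g.ndim != 1:
            raise ValidationError("gain/n_with/n_total must be equal-length 1-D")
        if g.size == 0:
            raise ValidationError("empty binned data")
        if np.unique(g).size != g.size:
            raise ValidationError("gains must be distinct")
        if np.any(k < 0) or np.any(k > n):
            raise ValidationError("need 0 <= n_with <= n_total")

    @property
    def proportions(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.n_total > 0, self.n_with / self.n_total, np.nan)

    def drop_empty(self) -> "BinnedData":
        keep = self.n_total > 0
        if not keep.all():
            warnings.warn("dropping gain levels with zero trials")
        return BinnedData(self.gain[keep], self.n_with[keep], self.n_total[keep])


@dataclass(frozen=True)
class PsychFit:
    """Cumulative-Gaussian fit: bias ``alpha``, precision ``sigma``
    (inverse slope), symmetric lapse."""

    alpha: float
    sigma: float
    lapse: float
    loglik: float
    converged: bool


@dataclass(frozen=True)
class AcrossTrialFit:
    """Amplitude-coded fit marginalized over head-speed variability."""

    g0: float
    sigma_amp: float
    lapse: float
    head_dist: VelocityDistribution
    loglik: float
    converged: bool
    head_floor: float = DEFAULT_HEAD_FLOOR


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate parameter tuples (alpha, sigma, lapse) per row."""

    samples: np.ndarray
    n_requested: int
    n_retained: int
    warning: str = ""

    def se(self) -> tuple[float, float]:
        """Bootstrap SEs of (alpha, sigma)."""
        return (float(self.samples[:, 0].std(ddof=1)),
                float(self.samples[:, 1].std(ddof=1)))

    def percentile_ci(self, col: int, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        return (float(np.quantile(self.samples[:, col], lo)),
                float(np.quantile(self.samples[:, col], 1.0 - lo)))


def bin_responses(trials: pd.DataFrame) -> BinnedData:
    """Count with-the-head responses per gain for a single-condition table."""
    if len(trials) == 0:
        raise ValidationError("no trials to bin")
    cond_cols = ["modality", "audio_jitter", "visual_jitter"]
    if trials[cond_cols].drop_duplicates().shape[0] != 1:
        raise ValidationError("trials span more than one condition")
    with_head = _with_head_mask(trials)
    grouped = trials.assign(_with=with_head).groupby("gain", sort=True)["_with"]
    agg = grouped.agg(["sum", "count"])
    return BinnedData(agg.index.to_numpy(float),
                      agg["sum"].to_numpy(int),
                      agg["count"].to_numpy(int))


def _with_head_mask(trials: pd.DataFrame) -> np.ndarray:
    resp = trials["response"]
    if resp.dtype == bool:
        return resp.to_numpy()
    vals = set(resp.unique())
    if not vals <= {"with", "against"}:
        raise ValidationError(f"unrecognized response codes: {vals}")
    return (resp == "with").to_numpy()


def _nll_and_grad(theta: np.ndarray, g: np.ndarray, k: np.ndarray,
                  n: np.ndarray) -> tuple[float, np.ndarray]:
    alpha, log_sigma, lapse = theta
    sigma = math.exp(log_sigma)
    z = (g - alpha) / sigma
    phi_cdf = ndtr(z)
    p = lapse + (1.0 - 2.0 * lapse) * phi_cdf
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    nll = -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))
    dl_dp = k / p - (n - k) / (1.0 - p)
    pdf = norm.pdf(z)
    dp_da = -(1.0 - 2.0 * lapse) * pdf / sigma
    dp_dls = -(1.0 - 2.0 * lapse) * pdf * z
    dp_dl = 1.0 - 2.0 * phi_cdf
    grad = -np.array([
        np.sum(dl_dp * dp_da),
        np.sum(dl_dp * dp_dls),
        np.sum(dl_dp * dp_dl),
    ])
    return nll, grad


def _probit_init(data: BinnedData) -> tuple[float, float]:
    """Weighted probit-regression starting values for (alpha, sigma)."""
    n = data.n_total
    p = np.clip(data.proportions, 1.0 / (2 * n.max() + 2),
                1.0 - 1.0 / (2 * n.max() + 2))
    z = ndtri(p)
    w = n.astype(float)
    gbar = np.average(data.gain, weights=w)
    zbar = np.average(z, weights=w)
    cov = np.average((data.gain - gbar) * (z - zbar), weights=w)
    var = np.average((data.gain - gbar) ** 2, weights=w)
    slope = cov / var if var > 0 else 1.0
    slope = max(slope, 1e-6)
    sigma = 1.0 / slope
    alpha = gbar - zbar * sigma
    return alpha, sigma


def fit_cumulative_gaussian(
    data: BinnedData,
    lapse_max: float = LAPSE_MAX_DEFAULT,
    n_starts: int = _N_STARTS,
    seed: int = 0,
    init: tuple[float, float, float] | None = None,
) -> PsychFit:
    """Maximum-likelihood cumulative-Gaussian fit with bounded lapse.

    Multi-start bounded quasi-Newton optimization: a probit-regression
    start plus jittered restarts; ties broken by log-likelihood then by
    smaller sigma. Raises :class:`UnidentifiableDataError` when the data
    carry no slope information (all responses identical).
    """
    data = data.drop_empty()
    if data.gain.size < 3:
        raise ValidationError("need >= 3 gain levels with trials")
    total_with = int(data.n_with.sum())
    if total_with == 0 or total_with == int(data.n_total.sum()):
        raise UnidentifiableDataError("all responses identical")

    g, k, n = data.gain, data.n_with, data.n_total
    span = float(g.max() - g.min())
    bounds = [(g.min() - 2 * span, g.max() + 2 * span),
              (math.log(span * 1e-4), math.log(span * 50)),
              (0.0, lapse_max)]
    a0, s0 = _probit_init(data) if init is None else init[:2]
    s0 = float(np.clip(s0, span * 2e-4, span * 25))
    a0 = float(np.clip(a0, bounds[0][0], bounds[0][1]))
    l0 = lapse_max / 2 if init is None else init[2]
    starts = [np.array([a0, math.log(s0), l0])]
    rng = np.random.default_rng(seed)
    for _ in range(max(n_starts - 1, 0)):
        starts.append(np.array([
            np.clip(a0 + rng.normal(0, 0.3 * span), *bounds[0]),
            np.clip(math.log(s0) + rng.normal(0, 0.7), *bounds[1]),
            rng.uniform(0, lapse_max),
        ]))

    best: tuple[float, float, PsychFit] | None = None
    for x0 in starts:
        res = minimize(_nll_and_grad, x0, args=(g, k, n), jac=True,
                       method="L-BFGS-B", bounds=bounds)
        fit = PsychFit(float(res.x[0]), float(math.exp(res.x[1])),
                       float(res.x[2]), -float(res.fun), bool(res.success))
        key = (-fit.loglik, fit.sigma)
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], fit)
    assert best is not None
    return best[2]


def bootstrap_fit(
    data: BinnedData,
    n: int = 2000,
    seed: int = 0,
    lapse_max: float = LAPSE_MAX_DEFAULT,
    point_fit: PsychFit | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap stratified by gain level.

    Each replicate redraws every gain level's with-count from a binomial at
    the empirical proportion and refits (single start at the point
    estimate). Replicates whose refit fails are dropped and counted; a
    warning string is set when more than 20% fail.
    """
    data = data.drop_empty()
    if point_fit is None:
        point_fit = fit_cumulative_gaussian(data, lapse_max=lapse_max)
    rng = np.random.default_rng(seed)
    p_hat = data.proportions
    samples: list[tuple[float, float, float]] = []
    failures = 0
    init = (point_fit.alpha, point_fit.sigma, point_fit.lapse)
    for _ in range(n):
        k_rep = rng.binomial(data.n_total, p_hat)
        rep = BinnedData(data.gain, k_rep, data.n_total)
        try:
            fit = fit_cumulative_gaussian(rep, lapse_max=lapse_max,
                                          n_starts=1, init=init)
        except (UnidentifiableDataError, ValidationError):
            failures += 1
            continue
        if not fit.converged:
            failures += 1
            continue
        samples.append((fit.alpha, fit.sigma, fit.lapse))
    warning = ""
    if failures > 0.2 * n:
        warning = f"{failures}/{n} bootstrap replicates failed"
    return BootstrapResult(np.asarray(samples, dtype=float).reshape(-1, 3),
                           n, len(samples), warning)


def _truncnorm_nodes(
    head_dist: VelocityDistribution,
    floor: float,
    n_nodes: int = 96,
) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights for the truncated head-speed density."""
    sd = math.sqrt(head_dist.variance)
    if sd == 0:
        return np.array([head_dist.mean]), np.array([1.0])
    lo = max(floor, head_dist.mean - 8 * sd)
    hi = head_dist.mean + 8 * sd
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    h = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    dens = norm.pdf(h, head_dist.mean, sd) * w
    return h, dens / dens.sum()


def _across_trial_p(theta: np.ndarray, g: np.ndarray, h: np.ndarray,
                    w: np.ndarray) -> np.ndarray:
    g0, log_sig, lapse = theta
    sig = math.exp(log_sig)
    z = np.outer(g - g0, h) / sig
    inner = ndtr(z) @ w
    return lapse + (1.0 - 2.0 * lapse) * inner


def fit_across_trial_model(
    data: BinnedData,
    head_dist: VelocityDistribution,
    lapse_max: float = LAPSE_MAX_DEFAULT,
    head_floor: float = DEFAULT_HEAD_FLOOR,
    n_nodes: int = 96,
    n_starts: int = _N_STARTS,
    seed: int = 0,
) -> AcrossTrialFit:
    """Fit the head-speed-marginalized psychometric model.

    The expectation over head speed uses fixed Gauss-Legendre quadrature
    (``n_nodes`` nodes) against the truncated-Gaussian density. With zero
    head variance this reduces to the standard model with
    ``sigma = sigma_amp / mean``.
    """
    data = data.drop_empty()
    if head_dist.mean <= 0:
        raise ValidationError("head-speed mean must be > 0")
    if data.gain.size < 3:
        raise ValidationError("need >= 3 gain levels with trials")
    total_with = int(data.n_with.sum())
    if total_with == 0 or total_with == int(data.n_total.sum()):
        raise UnidentifiableDataError("all responses identical")
    g, k, n = data.gain, data.n_with, data.n_total
    h, w = _truncnorm_nodes(head_dist, head_floor, n_nodes)

    def nll(theta: np.ndarray) -> float:
        p = np.clip(_across_trial_p(theta, g, h, w), 1e-12, 1 - 1e-12)
        return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    a0, s0 = _probit_init(data)
    span = float(g.max() - g.min())
    bounds = [(g.min() - 2 * span, g.max() + 2 * span),
              (math.log(span * head_dist.mean * 1e-4),
               math.log(span * head_dist.mean * 50)),
              (0.0, lapse_max)]
    s0_amp = float(np.clip(s0 * head_dist.mean,
                           math.exp(bounds[1][0]) * 2, math.exp(bounds[1][1]) / 2))
    starts = [np.array([a0, math.log(s0_amp), lapse_max / 2])]
    rng = np.random.default_rng(seed)
    for _ in range(max(n_starts - 1, 0)):
        starts.append(np.array([
            np.clip(a0 + rng.normal(0, 0.3 * span), *bounds[0]),
            np.clip(math.log(s0_amp) + rng.normal(0, 0.7), *bounds[1]),
            rng.uniform(0, lapse_max),
        ]))
    best: tuple[tuple[float, float], AcrossTrialFit] | None = None
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        fit = AcrossTrialFit(float(res.x[0]), float(math.exp(res.x[1])),
                             float(res.x[2]), head_dist, -float(res.fun),
                             bool(res.success), head_floor)
        key = (-fit.loglik, fit.sigma_amp)
        if best is None or key < best[0]:
            best = (key, fit)
    assert best is not None
    return best[1]


def model_implied_curve(fit: PsychFit | AcrossTrialFit,
                        gains: np.ndarray) -> np.ndarray:
    """P(with | gain) under a fitted (or constructed) response model."""
    gains = np.asarray(gains, dtype=float)
    if isinstance(fit, PsychFit):
        z = (gains - fit.alpha) / fit.sigma
        return fit.lapse + (1.0 - 2.0 * fit.lapse) * ndtr(z)
    if isinstance(fit, AcrossTrialFit):
        h, w = _truncnorm_nodes(fit.head_dist, fit.head_floor)
        theta = np.array([fit.g0, math.log(fit.sigma_amp), fit.lapse])
        return _across_trial_p(theta, gains, h, w)
    raise ValidationError(f"unsupported fit type {type(fit).__name__}")


def rmse(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Root mean squared difference of two equal-length vectors."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValidationError("length mismatch")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def binned_loglik(fit: PsychFit | AcrossTrialFit, data: BinnedData) -> float:
    """Binomial log-likelihood of binned data under a fitted model."""
    p = np.clip(model_implied_curve(fit, data.gain), 1e-12, 1 - 1e-12)
    return float(np.sum(data.n_with * np.log(p)
                        + (data.n_total - data.n_with) * np.log1p(-p)))
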