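"""Observation error model, likelihood and fit-comparison diagnostics.

The assay error is a linear polynomial in the observed concentration,
SD(Y) = C0 + C1*Y per output channel, inflated by a single multiplicative
scalar gamma shared across channels. Observations are treated as
independent Gaussians on the concentration scale centred at the model
prediction, which makes each subject's -2 log-likelihood a weighted
sum of squares plus a data-dependent constant.

Model comparison uses AIC = -2LL + 2p with p = number of active
structural parameters + 1 for gamma, and predictive performance is
summarized by weighted bias, bias-adjusted imprecision and the R^2 of
an observed-versus-predicted regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from . import reference
from .models import (
    CSF,
    PLASMA,
    PKParams,
    Propagator,
    SubjectRecord,
    get_structure,
)

__all__ = [
    "ErrorPolynomial",
    "GammaScale",
    "ErrorModel",
    "ChannelDiagnostics",
    "FitDiagnostics",
    "default_error_model",
    "observation_sd",
    "subject_neg2ll",
    "subject_neg2ll_stacked",
    "model_aic",
    "n_fitted_params",
    "predictive_diagnostics",
    "UndefinedLikelihoodError",
]

_LOG_2PI = math.log(2.0 * math.pi)


class UndefinedLikelihoodError(ValueError):
    """A likelihood was requested for a subject with no usable observations."""


@dataclass(frozen=True)
class ErrorPolynomial:
    """SD(Y) = c0 + c1*Y for one output channel (ug/ml)."""

    c0: float
    c1: float
    applies_to: str = PLASMA

    def __post_init__(self) -> None:
        if self.c0 < 0 or self.c1 < 0:
            raise ValueError("error polynomial coefficients must be >= 0")

    def sd(self, value) -> np.ndarray:
        return self.c0 + self.c1 * np.asarray(value, dtype=float)


@dataclass(frozen=True)
class GammaScale:
    """Multiplicative error inflation shared across output channels."""

    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


@dataclass(frozen=True)
class ErrorModel:
    """Per-channel error polynomials plus the shared gamma scalar."""

    polynomials: dict[str, ErrorPolynomial] = field(default_factory=dict)
    gamma: GammaScale = GammaScale(1.0)

    def polynomial(self, output: str) -> ErrorPolynomial:
        try:
            return self.polynomials[output]
        except KeyError:
            raise KeyError(f"no error polynomial defined for channel {output!r}") from None

    def sd(self, output: str, value) -> np.ndarray:
        return observation_sd(value, self.polynomial(output), self.gamma)

    def with_gamma(self, gamma: float) -> "ErrorModel":
        return ErrorModel(self.polynomials, GammaScale(gamma))


def default_error_model(gamma: float = 1.0) -> ErrorModel:
    """The assay polynomials reported for this drug (plasma and CSF)."""
    return ErrorModel(
        {
            PLASMA: ErrorPolynomial(*reference.PLASMA_ERROR_POLY, applies_to=PLASMA),
            CSF: ErrorPolynomial(*reference.CSF_ERROR_POLY, applies_to=CSF),
        },
        GammaScale(gamma),
    )


def observation_sd(value, poly: ErrorPolynomial, gamma: GammaScale | float = 1.0):
    """Observation SD in ug/ml: (c0 + c1*Y) * gamma."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("observation value must be >= 0")
    g = gamma.gamma if isinstance(gamma, GammaScale) else float(gamma)
    out = poly.sd(arr) * g
    return float(out) if np.isscalar(value) else out


def _subject_channels(subject: SubjectRecord, error_model: ErrorModel):
    """Group a subject's usable observations by channel.

    Returns (times, values, base sds) per channel with >=1 observation.
    """
    groups = {}
    for out in (PLASMA, CSF):
        obs = subject.active_observations(out)
        if not obs:
            continue
        t = np.array([o.time for o in obs])
        y = np.array([o.value for o in obs])
        sd0 = error_model.polynomial(out).sd(y)
        groups[out] = (t, y, sd0)
    if not groups:
        raise UndefinedLikelihoodError(
            f"subject {subject.id!r} has no non-excluded observations"
        )
    return groups


def subject_residual_terms(
    theta, subject: SubjectRecord, structure, error_model: ErrorModel
):
    """Gamma-independent likelihood pieces for stacked parameter vectors.

    Returns ``(rss, log_sd_sum, n_obs)`` where for each parameter vector
    ``rss`` is sum((y - f)/sd0)^2, ``log_sd_sum`` is sum(log sd0) (a
    scalar, prediction-independent) and ``n_obs`` the observation count.
    The -2LL at inflation gamma is then
    ``n*log(2*pi) + 2*log_sd_sum + 2*n*log(gamma) + rss/gamma^2``.
    """
    structure = get_structure(structure)
    groups = _subject_channels(subject, error_model)
    if isinstance(theta, Propagator):
        prop = theta
    elif isinstance(theta, PKParams):
        prop = Propagator(theta.to_vector(structure)[None, :], structure)
    else:
        prop = Propagator(np.atleast_2d(np.asarray(theta, dtype=float)), structure)
    # one segment walk for both channels
    all_times = np.concatenate([t for t, _, _ in groups.values()])
    amounts = prop.amounts(subject.doses, all_times)
    rss = 0.0
    log_sd_sum = 0.0
    n_obs = 0
    offset = 0
    for out, (t, y, sd0) in groups.items():
        state_idx, vol_name = structure.output_index(out)
        vols = prop.theta[:, structure.active_params.index(vol_name)]
        pred = amounts[:, offset : offset + len(t), state_idx] / vols[:, None]
        offset += len(t)
        rss = rss + np.sum(((y[None, :] - pred) / sd0[None, :]) ** 2, axis=1)
        log_sd_sum += float(np.sum(np.log(sd0)))
        n_obs += len(y)
    return rss, log_sd_sum, n_obs


def neg2ll_from_terms(rss, log_sd_sum: float, n_obs: int, gamma: float = 1.0):
    return (
        n_obs * _LOG_2PI
        + 2.0 * log_sd_sum
        + 2.0 * n_obs * math.log(gamma)
        + np.asarray(rss) / gamma**2
    )


def subject_neg2ll_stacked(
    theta, subject: SubjectRecord, structure, error_model: ErrorModel | None = None
) -> np.ndarray:
    """-2 log-likelihood of one subject for stacked parameter vectors."""
    error_model = error_model or default_error_model()
    rss, log_sd_sum, n_obs = subject_residual_terms(
        theta, subject, structure, error_model
    )
    return neg2ll_from_terms(rss, log_sd_sum, n_obs, error_model.gamma.gamma)


def subject_neg2ll(
    params, subject: SubjectRecord, structure, error_model: ErrorModel | None = None
) -> float:
    """-2 log-likelihood contribution of one subject.

    Independent Gaussian observations centred at the model prediction
    with SD from the channel's error polynomial evaluated at the
    *observed* value, times gamma. Excluded observations are skipped.
    """
    structure = get_structure(structure)
    if isinstance(params, PKParams):
        params = params.to_vector(structure)
    return float(subject_neg2ll_stacked(params, subject, structure, error_model)[0])


def n_fitted_params(structure) -> int:
    """AIC parameter count: active structural parameters plus gamma."""
    return len(get_structure(structure).active_params) + 1


def model_aic(neg2ll: float, n_params: int) -> float:
    """Akaike information criterion, -2LL + 2p."""
    if n_params < 1:
        raise ValueError(f"n_params must be >= 1, got {n_params}")
    return neg2ll + 2.0 * n_params


@dataclass(frozen=True)
class ChannelDiagnostics:
    """Observed-versus-predicted summary for one output channel."""

    bias: float  # weighted mean prediction error, ug/ml
    imprecision: float  # bias-adjusted weighted mean squared error, (ug/ml)^2
    r2: float  # R^2 of predicted regressed on observed, with intercept
    n: int


@dataclass(frozen=True)
class FitDiagnostics:
    """Fit-level diagnostics: -2LL, AIC and per-channel performance."""

    neg2ll: float
    aic: float
    channels: dict[str, ChannelDiagnostics] = field(default_factory=dict)


def predictive_diagnostics(
    observed: Sequence[float],
    predicted: Sequence[float],
    sds: Sequence[float] | None = None,
    weighting: str = "inverse_variance",
    n_label: int | None = None,
) -> ChannelDiagnostics:
    """Bias, imprecision and R^2 of observed-versus-predicted pairs.

    bias = weighted mean of (pred - obs); imprecision = weighted mean of
    (pred - obs)^2 minus bias^2. Weights are 1/sd^2 by default or unit
    weights with ``weighting="unit"``. R^2 comes from an ordinary
    least-squares regression of predicted on observed with intercept.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-d of equal length")
    if len(obs) < 2:
        raise ValueError("need at least 2 observed/predicted pairs")
    if weighting == "inverse_variance":
        if sds is None:
            raise ValueError("inverse-variance weighting requires sds")
        sd = np.asarray(sds, dtype=float)
        if sd.shape != obs.shape or np.any(sd <= 0):
            raise ValueError("sds must be positive and match the data length")
        w = 1.0 / sd**2
    elif weighting == "unit":
        w = np.ones_like(obs)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if np.ptp(obs) == 0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    w = w / w.sum()
    err = pred - obs
    bias = float(np.sum(w * err))
    imprecision = float(np.sum(w * err**2) - bias**2)
    r = stats.linregress(obs, pred)
    return ChannelDiagnostics(
        bias=bias,
        imprecision=max(imprecision, 0.0),
        r2=float(r.rvalue**2),
        n=n_label if n_label is not None else len(obs),
    )
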