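"""Nonparametric population estimation on an adaptive support-point grid.

The between-subject parameter distribution is represented as a discrete
mixture of support points (parameter vectors) with probabilities. A fit
alternates: (a) evaluate each subject's log-likelihood at every point,
(b) maximize the mixture likelihood over the probability simplex with
monotone EM multiplicative updates, (c) condense away negligible-weight
points, (d) expand by perturbing the leading support points along each axis by
a fraction of the (log-scale) search box that shrinks whenever a cycle
stalls, keeping the enlarged support only when it improves -2LL. Adding candidate points can never
worsen the optimal mixture likelihood, so the -2LL trajectory across
accepted cycles is non-increasing by construction.

Per-subject maximum a posteriori (MAP) Bayesian posteriors follow by
discrete Bayes: posterior_j proportional to prior_j * L(subject | j).
Posterior concentration profiles on a regular grid aggregate the
support-point predictions with the posterior-weighted median (the
posterior-weighted mean and the single best point are options).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from .likelihood import (
    ErrorModel,
    FitDiagnostics,
    UndefinedLikelihoodError,
    default_error_model,
    model_aic,
    n_fitted_params,
    neg2ll_from_terms,
    predictive_diagnostics,
    subject_residual_terms,
)
from .models import (
    PKParams,
    Propagator,
    SubjectRecord,
    get_structure,
    predict_concentrations_stacked,
)
from . import reference

__all__ = [
    "SupportPoint",
    "ParamBounds",
    "PopulationModel",
    "NPAG",
    "FitError",
    "default_bounds",
    "initialize_grid",
    "fit_population",
    "bayesian_posterior",
    "posterior_profile",
    "population_diagnostics",
    "weighted_median",
    "weighted_quantile",
]


class FitError(RuntimeError):
    """Population fit could not proceed (e.g. no finite-likelihood point)."""


@dataclass(frozen=True)
class SupportPoint:
    """One candidate parameter vector with its population probability."""

    params: PKParams
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0 + 1e-12:
            raise ValueError(f"probability must be in [0,1], got {self.probability}")


@dataclass(frozen=True)
class ParamBounds:
    """Per-parameter search box, 0 < lower < upper."""

    lower: dict[str, float]
    upper: dict[str, float]

    def __post_init__(self) -> None:
        for name in self.lower:
            lo, hi = self.lower[name], self.upper.get(name)
            if hi is None:
                raise ValueError(f"missing upper bound for {name!r}")
            if not (0 < lo < hi):
                raise ValueError(
                    f"require 0 < lower < upper for {name!r}, got ({lo}, {hi})"
                )

    def arrays(self, structure: ModelStructure) -> tuple[np.ndarray, np.ndarray]:
        names = structure.active_params
        try:
            lo = np.array([self.lower[n] for n in names])
            hi = np.array([self.upper[n] for n in names])
        except KeyError as e:
            raise ValueError(f"bounds missing for parameter {e.args[0]!r}") from None
        return lo, hi


def default_bounds(
    structure="four_compartment_lag",
    medians: PKParams | None = None,
    span: float = 10.0,
) -> ParamBounds:
    """[median/span, median*span] box around the reported medians."""
    structure = get_structure(structure)
    medians = medians or reference.REFERENCE_MEDIANS
    lo, hi = {}, {}
    for name in structure.active_params:
        m = medians.get(name)
        if m is None:
            raise ValueError(f"no median available for parameter {name!r}")
        lo[name] = m / span
        hi[name] = m * span
    return ParamBounds(lo, hi)


def _sobol_grid(
    lo: np.ndarray, hi: np.ndarray, n_points: int, seed: int
) -> np.ndarray:
    """Scrambled-Sobol fill of the box, uniform on the log scale."""
    k = len(lo)
    sampler = qmc.Sobol(d=k, scramble=True, rng=np.random.default_rng(seed))
    with warnings.catch_warnings():
        # balance is irrelevant here; any n is a valid space-filling start
        warnings.simplefilter("ignore", UserWarning)
        u = sampler.random(n_points)
    return np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))


def initialize_grid(
    bounds: ParamBounds,
    n_points: int,
    seed: int,
    structure="four_compartment_lag",
) -> list[SupportPoint]:
    """Equal-weight low-discrepancy starting grid inside the box."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    structure = get_structure(structure)
    lo, hi = bounds.arrays(structure)
    theta = _sobol_grid(lo, hi, n_points, seed)
    w = 1.0 / n_points
    return [
        SupportPoint(PKParams.from_vector(row, structure), w) for row in theta
    ]


def weighted_quantile(values, weights, q: float) -> float:
    """Lower weighted quantile: smallest v with cumulative weight >= q."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1 or len(v) == 0:
        raise ValueError("values and weights must be equal-length 1-d, nonempty")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    order = np.argsort(v, kind="stable")
    cw = np.cumsum(w[order]) / w.sum()
    idx = int(np.searchsorted(cw, q, side="left"))
    idx = min(idx, len(v) - 1)
    return float(v[order][idx])


def weighted_median(values, weights) -> float:
    return weighted_quantile(values, weights, 0.5)


@dataclass
class PopulationModel:
    """A fitted nonparametric population model.

    Support points with probabilities, the error model used, fit
    diagnostics and the cycle-by-cycle -2LL log.
    """

    structure: str
    support_points: list[SupportPoint]
    error_model: ErrorModel
    neg2ll: float
    aic: float
    cycle_log: list[dict] = field(default_factory=list)
    diagnostics: FitDiagnostics | None = None
    bounds: ParamBounds | None = None

    def __post_init__(self) -> None:
        if not self.support_points:
            raise ValueError("population model needs at least one support point")
        total = sum(p.probability for p in self.support_points)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"support-point weights sum to {total}, not 1")

    @property
    def gamma(self) -> float:
        return self.error_model.gamma.gamma

    def theta_matrix(self) -> np.ndarray:
        structure = get_structure(self.structure)
        return np.vstack(
            [p.params.to_vector(structure) for p in self.support_points]
        )

    def weights(self) -> np.ndarray:
        return np.array([p.probability for p in self.support_points])

    def weighted_median_params(self) -> PKParams:
        """Per-parameter weighted medians of the population distribution."""
        structure = get_structure(self.structure)
        theta = self.theta_matrix()
        w = self.weights()
        med = [weighted_median(theta[:, j], w) for j in range(theta.shape[1])]
        return PKParams.from_vector(med, structure)

    def parameter_cv_pct(self) -> dict[str, float]:
        """Weighted CV% (100*SD/mean) per parameter."""
        structure = get_structure(self.structure)
        theta = self.theta_matrix()
        w = self.weights()
        out = {}
        for j, name in enumerate(structure.active_params):
            mean = float(np.sum(w * theta[:, j]))
            var = float(np.sum(w * (theta[:, j] - mean) ** 2))
            out[name] = 100.0 * math.sqrt(max(var, 0.0)) / mean
        return out

    def to_json(self, path) -> None:
        structure = get_structure(self.structure)
        payload = {
            "structure": self.structure,
            "gamma": self.gamma,
            "neg2ll": self.neg2ll,
            "aic": self.aic,
            "param_names": list(structure.active_params),
            "support_points": [
                {"params": p.params.as_dict(), "probability": p.probability}
                for p in self.support_points
            ],
            "error_polynomials": {
                ch: {"c0": poly.c0, "c1": poly.c1}
                for ch, poly in self.error_model.polynomials.items()
            },
            "cycle_log": self.cycle_log,
            "diagnostics": _diagnostics_payload(self.diagnostics),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PopulationModel":
        with open(path) as fh:
            payload = json.load(fh)
        from .likelihood import ErrorPolynomial, GammaScale

        polys = {
            ch: ErrorPolynomial(d["c0"], d["c1"], applies_to=ch)
            for ch, d in payload["error_polynomials"].items()
        }
        em = ErrorModel(polys, GammaScale(payload["gamma"]))
        pts = [
            SupportPoint(PKParams(**d["params"]), d["probability"])
            for d in payload["support_points"]
        ]
        return cls(
            structure=payload["structure"],
            support_points=pts,
            error_model=em,
            neg2ll=payload["neg2ll"],
            aic=payload["aic"],
            cycle_log=payload.get("cycle_log", []),
        )


def _diagnostics_payload(diag: FitDiagnostics | None):
    if diag is None:
        return None
    return {
        "neg2ll": diag.neg2ll,
        "aic": diag.aic,
        "channels": {ch: asdict(c) for ch, c in diag.channels.items()},
    }


def _optimize_weights(
    loglik: np.ndarray,
    w0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 50000,
) -> tuple[np.ndarray, float]:
    """Maximize sum_i log(sum_j w_j L_ij) over the probability simplex.

    EM multiplicative updates, monotone from any interior start; stops
    at simplex-gradient (KKT) tolerance ``tol``. Returns (weights,
    -2LL). ``loglik`` is the (n_subjects, n_points) log-likelihood
    matrix.
    """
    N, P = loglik.shape
    a = np.max(loglik, axis=1, keepdims=True)
    if not np.all(np.isfinite(a)):
        raise FitError(
            "a subject has no finite-likelihood support point; widen the "
            "search bounds or check the dataset"
        )
    M = np.exp(loglik - a)  # row-scaled likelihoods, max 1 per row
    w = np.full(P, 1.0 / P) if w0 is None else np.asarray(w0, dtype=float).copy()
    w = np.clip(w, 1e-300, None)
    w /= w.sum()
    for _ in range(max_iter):
        mix = M @ w
        g = (M / mix[:, None]).mean(axis=0)  # simplex gradient; KKT: g<=1
        w *= g
        w /= w.sum()
        if np.max(g) - 1.0 < tol:
            break
    mix = M @ w
    neg2ll = -2.0 * float(np.sum(a[:, 0] + np.log(mix)))
    return w, neg2ll


class NPAG(BaseEstimator):
    """Nonparametric adaptive-grid population PK estimator.

    Parameters
    ----------
    structure : name of the compartmental structure to fit.
    bounds : ParamBounds search box; default [median/10, median*10]
        around the reported population medians.
    n_init : size of the scrambled-Sobol starting grid (log-uniform in
        the box).
    condense_tol : support points below this probability are dropped.
    convergence_tol : stop when a cycle improves -2LL by less than this.
    max_cycles : hard cycle cap.
    expansion_fraction : initial per-axis perturbation as a fraction of
        the log-box width; halved whenever a cycle fails to improve
        -2LL, down to ``min_expansion`` (then the fit stops).
    error_model : observation ErrorModel; default the packaged assay
        polynomials with gamma = 1.
    optimize_gamma : if True, refit the shared gamma scalar once per
        cycle by 1-d likelihood maximization.
    profile_aggregate : "weighted_median" (default), "weighted_mean" or
        "map" - how posterior profiles pool support-point predictions.
    seed : required; drives grid initialization (the only stochastic
        step).

    Attributes (after ``fit``)
    --------------------------
    model_ : PopulationModel with support points and diagnostics.
    support_, weights_ : support matrix (P, k) and probabilities.
    neg2ll_, aic_, gamma_, cycle_log_, n_cycles_, converged_.
    """

    def __init__(
        self,
        structure: str = "four_compartment_lag",
        bounds: ParamBounds | None = None,
        n_init: int = 2048,
        condense_tol: float = 1e-8,
        convergence_tol: float = 0.01,
        max_cycles: int = 100,
        expansion_fraction: float = 0.2,
        min_expansion: float = 1e-3,
        expand_max_points: int = 200,
        polish: bool = True,
        polish_max_points: int = 30,
        polish_maxfev: int = 300,
        polish_method: str = "lbfgsb",
        error_model: ErrorModel | None = None,
        optimize_gamma: bool = False,
        profile_aggregate: str = "weighted_median",
        seed: int | None = None,
    ):
        self.structure = structure
        self.bounds = bounds
        self.n_init = n_init
        self.condense_tol = condense_tol
        self.convergence_tol = convergence_tol
        self.max_cycles = max_cycles
        self.expansion_fraction = expansion_fraction
        self.min_expansion = min_expansion
        self.expand_max_points = expand_max_points
        self.polish = polish
        self.polish_max_points = polish_max_points
        self.polish_maxfev = polish_maxfev
        self.polish_method = polish_method
        self.error_model = error_model
        self.optimize_gamma = optimize_gamma
        self.profile_aggregate = profile_aggregate
        self.seed = seed

    # -- likelihood bookkeeping -------------------------------------------

    def _subject_terms(self, theta: np.ndarray):
        """rss (N,P) matrix plus per-subject constants for stacked points."""
        prop = Propagator(theta, self._structure)
        rss = np.empty((len(self._subjects), theta.shape[0]))
        for i, sub in enumerate(self._subjects):
            r, _, _ = subject_residual_terms(
                prop, sub, self._structure, self._error_model
            )
            rss[i] = r
        return rss

    def _loglik(self, rss: np.ndarray, gamma: float) -> np.ndarray:
        const = np.array(
            [
                -0.5 * (n * _LOG2PI + 2.0 * s + 2.0 * n * math.log(gamma))
                for (s, n) in self._subject_consts
            ]
        )
        return const[:, None] - 0.5 * rss / gamma**2

    # -- fitting ------------------------------------------------------------

    def fit(self, X: Sequence[SubjectRecord], y=None) -> "NPAG":
        """Fit the population model to a sequence of SubjectRecord."""
        if self.seed is None:
            raise ValueError("NPAG requires an explicit integer seed")
        subjects = [s for s in X]
        usable = [s for s in subjects if len(s.active_observations()) >= 1]
        if not any(len(s.active_observations()) >= 2 for s in usable):
            raise FitError("need at least one subject with >= 2 observations")
        self._subjects = usable
        self._structure = get_structure(self.structure)
        self._error_model = self.error_model or default_error_model()
        bounds = self.bounds or default_bounds(self._structure)
        lo, hi = bounds.arrays(self._structure)
        log_lo, log_hi = np.log(lo), np.log(hi)

        # gamma-independent constants per subject
        probe = np.exp((log_lo + log_hi) / 2.0)[None, :]
        self._subject_consts = []
        for sub in usable:
            _, log_sd_sum, n_obs = subject_residual_terms(
                probe, sub, self._structure, self._error_model
            )
            self._subject_consts.append((log_sd_sum, n_obs))

        gamma = self._error_model.gamma.gamma
        theta = _sobol_grid(lo, hi, self.n_init, self.seed)
        rss = self._subject_terms(theta)
        ll0 = self._loglik(rss, gamma)
        best = np.max(ll0, axis=1)
        if np.any(best < -700.0):  # density underflows to zero everywhere
            worst = [usable[i].id for i in np.where(best < -700.0)[0]]
            raise FitError(
                f"no support point has nonzero likelihood for subject(s) "
                f"{worst}: predictions are wildly off the observations; "
                f"widen the search bounds or check the dataset units"
            )
        w, neg2ll = _optimize_weights(ll0)
        theta, rss, w = self._condense(theta, rss, w)
        cycle_log = [
            {"cycle": 0, "neg2ll": neg2ll, "n_support": len(w), "expansion": None}
        ]

        frac = self.expansion_fraction
        converged = False
        for cycle in range(1, self.max_cycles + 1):
            if self.optimize_gamma:
                gamma = self._refit_gamma(rss, w, gamma)
            cand = self._expand(
                self._expansion_subset(theta, w), log_lo, log_hi, frac
            )
            if self.polish:
                moved = self._polish_points(
                    theta, rss, w, gamma, log_lo, log_hi
                )
                if len(moved):
                    cand = np.vstack([cand, moved]) if len(cand) else moved
            if len(cand):
                rss_cand = self._subject_terms(cand)
                theta_all = np.vstack([theta, cand])
                rss_all = np.hstack([rss, rss_cand])
                w_start = np.concatenate(
                    [w, np.full(len(cand), 1.0 / max(len(cand), 1))]
                )
                w_start /= w_start.sum()
            else:
                theta_all, rss_all, w_start = theta, rss, w
            # intermediate cycles use a capped EM (the accept gate below
            # keeps the -2LL trajectory monotone regardless); the final
            # weights are re-polished to full tolerance after the loop
            w_new, neg2ll_new = _optimize_weights(
                self._loglik(rss_all, gamma), w0=w_start, max_iter=2000
            )
            if neg2ll_new <= neg2ll + 1e-9:
                theta, rss, w = self._condense(theta_all, rss_all, w_new)
                improvement = neg2ll - neg2ll_new
                neg2ll = min(neg2ll, neg2ll_new)
            else:  # numerical regression; keep previous support
                improvement = 0.0
            cycle_log.append(
                {
                    "cycle": cycle,
                    "neg2ll": neg2ll,
                    "n_support": len(w),
                    "expansion": frac,
                    "gamma": gamma,
                }
            )
            if improvement < self.convergence_tol:
                # a stalled cycle means the current step cannot improve the
                # support; refine the perturbation until it bottoms out
                if frac <= self.min_expansion:
                    converged = True
                    break
                frac /= 2.0

        # final weight polish at full simplex-gradient tolerance
        w_fin, neg2ll_fin = _optimize_weights(self._loglik(rss, gamma), w0=w)
        if neg2ll_fin <= neg2ll:
            theta, rss, w = self._condense(theta, rss, w_fin)
            neg2ll = neg2ll_fin
            if cycle_log:
                cycle_log[-1]["neg2ll"] = neg2ll

        self._error_model = self._error_model.with_gamma(gamma)
        aic = model_aic(neg2ll, n_fitted_params(self._structure))
        pts = [
            SupportPoint(PKParams.from_vector(row, self._structure), float(p))
            for row, p in zip(theta, w / w.sum())
        ]
        self.model_ = PopulationModel(
            structure=self._structure.name,
            support_points=pts,
            error_model=self._error_model,
            neg2ll=neg2ll,
            aic=aic,
            cycle_log=cycle_log,
            bounds=bounds,
        )
        self.support_ = theta
        self.weights_ = w / w.sum()
        self.neg2ll_ = neg2ll
        self.aic_ = aic
        self.gamma_ = gamma
        self.cycle_log_ = cycle_log
        self.n_cycles_ = cycle_log[-1]["cycle"]
        self.converged_ = converged
        self.model_.diagnostics = population_diagnostics(
            self.model_, usable, aggregate=self.profile_aggregate
        )
        return self

    def _condense(self, theta, rss, w):
        w = np.asarray(w, dtype=float)
        keep = w >= self.condense_tol * w.sum()
        if not np.any(keep):
            keep = w == w.max()
        theta, rss, w = theta[keep], rss[:, keep], w[keep]
        # merge numerically identical points left by clipped expansions
        _, idx = np.unique(np.round(np.log(theta), 10), axis=0, return_index=True)
        if len(idx) < len(w):
            merged_w = np.zeros(len(idx))
            key = np.round(np.log(theta), 10)
            uniq = key[np.sort(idx)]
            lookup = {tuple(r): i for i, r in enumerate(uniq)}
            for j in range(len(w)):
                merged_w[lookup[tuple(key[j])]] += w[j]
            sel = np.sort(idx)
            theta, rss, w = theta[sel], rss[:, sel], merged_w
        return theta, rss, w / w.sum()

    def _expansion_subset(self, theta, w):
        """Highest-weight points covering essentially all mixing mass.

        Flat likelihood ridges leave many small-weight near-duplicates in
        the support; perturbing every one of them makes the candidate set
        explode without adding information, so expansion works from the
        top ``expand_max_points`` points (covering >= 1 - 1e-6 of mass).
        """
        if len(w) <= self.expand_max_points:
            return theta
        order = np.argsort(w)[::-1]
        cum = np.cumsum(w[order])
        n_cover = int(np.searchsorted(cum, 1.0 - 1e-6)) + 1
        n_keep = min(max(n_cover, 1), self.expand_max_points)
        return theta[order[:n_keep]]

    def _expand(self, theta, log_lo, log_hi, frac):
        if frac <= 0:
            return np.empty((0, theta.shape[1]))
        step = frac * (log_hi - log_lo)
        logt = np.log(theta)
        cands = []
        for j in range(theta.shape[1]):
            for sgn in (+1.0, -1.0):
                c = logt.copy()
                c[:, j] = np.clip(c[:, j] + sgn * step[j], log_lo[j], log_hi[j])
                cands.append(c)
        cand = np.unique(np.round(np.vstack(cands), 12), axis=0)
        # drop candidates that coincide with existing support
        existing = {tuple(r) for r in np.round(logt, 12)}
        cand = np.array([r for r in cand if tuple(r) not in existing])
        return np.exp(cand) if len(cand) else np.empty((0, theta.shape[1]))

    def _polish_points(self, theta, rss, w, gamma, log_lo, log_hi):
        """EM M-step relocation of the leading support points.

        Each point is moved to (locally) maximize its responsibility-
        weighted log-likelihood - the M-step of EM for a point-mass
        mixture. Axis-aligned expansion alone cannot follow correlated
        likelihood ridges (moving one rate constant is only favourable
        if others move with it); a local multivariate search can. The
        relocated points enter the candidate pool and are kept only if
        the mixture -2LL improves, so monotonicity is unaffected.
        """
        from scipy.optimize import minimize

        ll = self._loglik(rss, gamma)
        a = np.max(ll, axis=1, keepdims=True)
        M = np.exp(ll - a)
        mix = M @ w
        resp = (M * w[None, :]) / mix[:, None]  # responsibilities (N, P)
        order = np.argsort(w)[::-1][: self.polish_max_points]
        moved = []
        for j in order:
            subs = np.where(resp[:, j] > 1e-8)[0]
            if len(subs) == 0:
                continue
            rw = resp[subs, j]
            subjects = [self._subjects[i] for i in subs]

            def objective(u):
                th = np.exp(u)[None, :]
                prop = Propagator(th, self._structure)
                tot = 0.0
                for wk, sub in zip(rw, subjects):
                    r, _, _ = subject_residual_terms(
                        prop, sub, self._structure, self._error_model
                    )
                    tot += wk * float(r[0])
                return tot

            if self.polish_method == "powell":
                res = minimize(
                    objective,
                    np.clip(np.log(theta[j]), log_lo, log_hi),
                    method="Powell",
                    bounds=list(zip(log_lo, log_hi)),
                    options={"maxfev": self.polish_maxfev, "xtol": 1e-4, "ftol": 1e-7},
                )
            else:
                res = minimize(
                    objective,
                    np.clip(np.log(theta[j]), log_lo, log_hi),
                    method="L-BFGS-B",
                    bounds=list(zip(log_lo, log_hi)),
                    options={"maxfun": self.polish_maxfev, "eps": 1e-6},
                )
            u = np.clip(res.x, log_lo, log_hi)
            moved.append(np.exp(u))
        return np.array(moved) if moved else np.empty((0, theta.shape[1]))

    def _refit_gamma(self, rss, w, gamma0):
        from scipy.optimize import minimize_scalar

        def total_neg2ll(log_g):
            g = math.exp(log_g)
            _, n2 = _optimize_weights(self._loglik(rss, g), w0=w, max_iter=200)
            return n2

        res = minimize_scalar(
            total_neg2ll,
            bracket=(math.log(gamma0) - 0.5, math.log(gamma0) + 0.5),
            options={"xtol": 1e-3},
            method="brent",
        )
        return float(math.exp(res.x))

    # -- posterior interface -------------------------------------------------

    def posterior(self, subject: SubjectRecord) -> np.ndarray:
        self._check_fitted()
        return bayesian_posterior(subject, self.model_)

    def predict_profile(self, subject, grid_step=0.2, horizon=24.0, outputs=None):
        self._check_fitted()
        return posterior_profile(
            subject,
            self.model_,
            grid_step=grid_step,
            horizon=horizon,
            outputs=outputs,
            aggregate=self.profile_aggregate,
        )

    def score(self, X, y=None) -> float:
        """Mean per-subject log-likelihood under the fitted mixture."""
        self._check_fitted()
        total = 0.0
        for sub in X:
            theta = self.model_.theta_matrix()
            r, s, n = subject_residual_terms(
                theta, sub, self._structure, self.model_.error_model
            )
            ll = -0.5 * neg2ll_from_terms(r, s, n, self.model_.gamma)
            a = ll.max()
            total += a + math.log(
                float(np.sum(self.model_.weights() * np.exp(ll - a)))
            )
        return total / len(list(X))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("NPAG instance is not fitted yet; call fit first")


_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class Profile:
    """A posterior concentration-time profile on a regular grid."""

    times: np.ndarray
    concentrations: dict[str, np.ndarray]

    def channel(self, output: str) -> np.ndarray:
        return self.concentrations[output]


def _posterior_log_weights(subject, model: PopulationModel):
    structure = get_structure(model.structure)
    theta = model.theta_matrix()
    prior = model.weights()
    try:
        rss, log_sd_sum, n_obs = subject_residual_terms(
            theta, subject, structure, model.error_model
        )
    except UndefinedLikelihoodError:
        warnings.warn(
            f"subject {subject.id!r} has no observations; posterior equals prior",
            stacklevel=3,
        )
        with np.errstate(divide="ignore"):
            return np.log(prior)
    ll = -0.5 * neg2ll_from_terms(rss, log_sd_sum, n_obs, model.gamma)
    with np.errstate(divide="ignore"):
        return np.log(prior) + ll


def bayesian_posterior(subject: SubjectRecord, model: PopulationModel) -> np.ndarray:
    """Posterior support-point weights for one subject (discrete Bayes)."""
    logw = _posterior_log_weights(subject, model)
    a = np.max(logw)
    if not np.isfinite(a):
        raise FitError(
            f"subject {subject.id!r} has zero posterior mass everywhere"
        )
    w = np.exp(logw - a)
    return w / w.sum()


def posterior_profile(
    subject: SubjectRecord,
    model: PopulationModel,
    grid_step: float = 0.2,
    horizon: float = 24.0,
    outputs: Sequence[str] | None = None,
    aggregate: str = "weighted_median",
) -> Profile:
    """Posterior predicted concentrations on a regular time grid.

    The grid is {0, grid_step, ..., horizon} inclusive (121 points for
    24 h at 12-min steps). Each time's value pools the support-point
    predictions with the subject's posterior weights using the requested
    aggregator.
    """
    n_steps = horizon / grid_step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("horizon must be a multiple of grid_step")
    structure = get_structure(model.structure)
    if outputs is None:
        outputs = sorted(structure.outputs)
    times = np.linspace(0.0, horizon, int(round(n_steps)) + 1)
    post = bayesian_posterior(subject, model)
    theta = model.theta_matrix()
    mask = post > 0
    theta_eff, post_eff = theta[mask], post[mask]
    conc = {}
    for out in outputs:
        pred = predict_concentrations_stacked(
            theta_eff, structure, subject.doses, times, out
        )
        if aggregate == "weighted_median":
            conc[out] = np.array(
                [weighted_median(pred[:, t], post_eff) for t in range(len(times))]
            )
        elif aggregate == "weighted_mean":
            conc[out] = post_eff @ pred
        elif aggregate == "map":
            conc[out] = pred[int(np.argmax(post_eff))]
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
    return Profile(times=times, concentrations=conc)


def population_diagnostics(
    model: PopulationModel,
    dataset: Sequence[SubjectRecord],
    weighting: str = "inverse_variance",
    aggregate: str = "weighted_median",
) -> FitDiagnostics:
    """Observed-versus-posterior-predicted diagnostics per channel."""
    structure = get_structure(model.structure)
    pooled: dict[str, list[tuple[float, float, float]]] = {
        ch: [] for ch in structure.outputs
    }
    theta = model.theta_matrix()
    for sub in dataset:
        try:
            post = bayesian_posterior(sub, model)
        except UndefinedLikelihoodError:
            continue
        mask = post > 0
        for ch in structure.outputs:
            obs = sub.active_observations(ch)
            if not obs:
                continue
            t = np.array([o.time for o in obs])
            y = np.array([o.value for o in obs])
            pred = predict_concentrations_stacked(
                theta[mask], structure, sub.doses, t, ch
            )
            if aggregate == "weighted_mean":
                yhat = post[mask] @ pred
            elif aggregate == "map":
                yhat = pred[int(np.argmax(post[mask]))]
            else:
                yhat = np.array(
                    [weighted_median(pred[:, i], post[mask]) for i in range(len(t))]
                )
            sd = model.error_model.sd(ch, y)
            pooled[ch].extend(zip(y, yhat, np.atleast_1d(sd)))
    channels = {}
    for ch, triples in pooled.items():
        if len(triples) < 2:
            continue
        y, yhat, sd = (np.array(v) for v in zip(*triples))
        channels[ch] = predictive_diagnostics(y, yhat, sd, weighting=weighting)
    return FitDiagnostics(neg2ll=model.neg2ll, aic=model.aic, channels=channels)


def fit_population(
    dataset: Sequence[SubjectRecord],
    structure: str = "four_compartment_lag",
    bounds: ParamBounds | None = None,
    seed: int | None = None,
    **settings,
) -> PopulationModel:
    """Functional wrapper over the NPAG estimator; returns the fitted model."""
    est = NPAG(structure=structure, bounds=bounds, seed=seed, **settings)
    est.fit(dataset)
    return est.model_
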