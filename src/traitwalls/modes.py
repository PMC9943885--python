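"""Likelihoods, ML fitting and AICc selection for evolutionary-mode models.

Four classic tempo-and-mode models for a time series of sample means with
known sampling error:

* ``GRW`` — general (directional) random walk: increments per unit time are
  normal with mean ``mu_step`` and variance ``sigma2_step``.
* ``URW`` — unbiased random walk: GRW with ``mu_step = 0``.
* ``Stasis`` — samples independently normal around a steady mean ``theta``
  with variance ``omega2``.
* ``StrictStasis`` — stasis with ``omega2 = 0``; only sampling noise remains.

Two parameterizations are provided. ``Joint`` treats the observed sample
means as one multivariate-normal draw: for the random walks the mean is
``anc + mu_step * t`` and the covariance is
``sigma2_step * min(t_i, t_j) + delta_ij * v_i / n_i`` (ages rebased to
t_1 = 0); for stasis the covariance is ``omega2 * I + diag(v_i / n_i)``.
``AD`` (ancestor–descendant) treats successive differences as independent
normals. Model support is compared by the small-sample-corrected Akaike
criterion, AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1), and Akaike weights.

Fitting exploits the fact that for every model the mean-structure
parameters are generalized-least-squares solvable given the single
variance parameter, so maximization reduces to a one-dimensional profile
likelihood in log-variance (coarse grid scan plus bounded refinements) —
deterministic and free of optimizer restarts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .config import FitSettings, PipelineConfig
from .series import SampleSeries, to_sample_series

MODELS = ("GRW", "URW", "Stasis", "StrictStasis")
K_PARAMS = {"GRW": 3, "URW": 2, "Stasis": 2, "StrictStasis": 1}
_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class ModeParams:
    """Parameters of an evolutionary-mode model; only the fields relevant
    to a given model are populated."""

    anc: float | None = None        # inferred trait value at the first sample
    mu_step: float | None = None    # mean step per unit time
    sigma2_step: float | None = None  # step variance per unit time
    theta: float | None = None      # stasis long-term mean
    omega2: float | None = None     # stasis variance around theta


@dataclass
class ModelFit:
    model: str
    params: ModeParams
    loglik: float
    k_params: int
    n: int
    aicc: float = float("nan")
    akaike_weight: float = float("nan")
    converged: bool = True


def aicc(loglik: float, k: int, n: int) -> float:
    """Bias-corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        return float("inf")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs) -> np.ndarray:
    """Normalized Akaike weights; invariant to a constant shift in AICc."""
    a = np.asarray(aiccs, dtype=float)
    finite = np.isfinite(a)
    w = np.zeros_like(a)
    if finite.any():
        d = a[finite] - a[finite].min()
        ew = np.exp(-0.5 * d)
        w[finite] = ew / ew.sum()
    return w


def _mvn_loglik(resid: np.ndarray, cov: np.ndarray) -> float:
    try:
        chol = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError:
        return -np.inf
    diag = np.diag(chol)
    if np.any(diag <= 0):
        return -np.inf
    z = linalg.solve_triangular(chol, resid, lower=True)
    return float(-0.5 * (len(resid) * _LOG2PI) - np.sum(np.log(diag)) - 0.5 * z @ z)


def _rw_cov(t: np.ndarray, eps: np.ndarray, sigma2: float) -> np.ndarray:
    return sigma2 * np.minimum.outer(t, t) + np.diag(eps)


def _norm_logpdf_sum(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> float:
    if np.any(var <= 0):
        return -np.inf
    return float(np.sum(-0.5 * (_LOG2PI + np.log(var) + (x - mean) ** 2 / var)))


def loglik(model: str, params: ModeParams, series: SampleSeries,
           method: str = "Joint") -> float:
    """Exact log density of the observed sample means under ``model``.

    A singular covariance (all sampling variances zero together with a
    zero process variance) yields ``-inf`` rather than an exception.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    t = series.ages - series.ages[0]
    x = series.means
    eps = series.sampling_variances
    if method == "Joint":
        if model in ("GRW", "URW"):
            mu = params.mu_step if model == "GRW" else 0.0
            mean = params.anc + mu * t
            cov = _rw_cov(t, eps, params.sigma2_step)
            return _mvn_loglik(x - mean, cov)
        omega2 = params.omega2 if model == "Stasis" else 0.0
        var = omega2 + eps
        return _norm_logpdf_sum(x, np.full_like(x, params.theta), var)
    if method == "AD":
        if model in ("GRW", "URW"):
            mu = params.mu_step if model == "GRW" else 0.0
            d = np.diff(x)
            dt = np.diff(t)
            var = params.sigma2_step * dt + eps[:-1] + eps[1:]
            return _norm_logpdf_sum(d, mu * dt, var)
        omega2 = params.omega2 if model == "Stasis" else 0.0
        var = omega2 + eps[1:]
        return _norm_logpdf_sum(x[1:], np.full(len(x) - 1, params.theta), var)
    raise ValueError(f"unknown method {method!r} (expected 'Joint' or 'AD')")


# ---------------------------------------------------------------------------
# profile likelihood machinery

def _gls(X: np.ndarray, y: np.ndarray, cov: np.ndarray):
    """GLS coefficients and the profiled MVN log-likelihood."""
    try:
        chol = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError:
        return None, -np.inf
    Xw = linalg.solve_triangular(chol, X, lower=True)
    yw = linalg.solve_triangular(chol, y, lower=True)
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    ll = float(-0.5 * len(y) * _LOG2PI - np.sum(np.log(np.diag(chol))) - 0.5 * resid @ resid)
    return beta, ll


def _profile_maximize(profile, scale: float, settings: FitSettings):
    """Maximize a 1-D profile log-likelihood over a variance parameter.

    Scans a log-spaced grid from the variance floor up to well past the
    data scale, then refines around the best few grid points with bounded
    scalar optimization.
    """
    floor = settings.variance_floor
    hi = max(scale * 1e3, floor * 1e6)
    grid = np.exp(np.linspace(math.log(floor), math.log(hi), settings.grid_points))
    vals = np.array([profile(v) for v in grid])
    if not np.isfinite(vals).any():
        return floor, -np.inf, False
    order = np.argsort(vals)[::-1]
    best_v = float(grid[order[0]])
    best_ll = float(vals[order[0]])
    for idx in order[: settings.restarts]:
        lo = grid[max(idx - 1, 0)]
        up = grid[min(idx + 1, len(grid) - 1)]
        if lo >= up:
            continue
        res = optimize.minimize_scalar(
            lambda lv: -profile(math.exp(lv)),
            bounds=(math.log(lo), math.log(up)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if np.isfinite(res.fun) and -res.fun > best_ll:
            best_ll = float(-res.fun)
            best_v = float(math.exp(res.x))
    return best_v, best_ll, np.isfinite(best_ll)


def _rw_scale(series: SampleSeries) -> float:
    d = np.diff(series.means)
    dt = np.diff(series.ages)
    s = float(np.median(d * d / dt)) if len(d) else 0.0
    return max(s, float(np.var(series.means)), 1e-8)


def fit_model(model: str, series: SampleSeries, method: str = "Joint",
              settings: FitSettings | None = None) -> ModelFit:
    """Maximum-likelihood fit of one model to a sample series.

    Variance parameters are optimized on a log scale above the configured
    floor; mean-structure parameters (``anc``, ``mu_step``, ``theta``) are
    profiled out by GLS at each variance value.
    """
    if settings is None:
        settings = FitSettings()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    k = K_PARAMS[model]
    n_eff = len(series) if method == "Joint" else len(series) - 1
    if len(series) < k + 2:
        raise ValueError(f"series too short ({len(series)}) to fit {model} (needs >= {k + 2})")

    t = series.ages - series.ages[0]
    x = series.means
    eps = series.sampling_variances

    if model == "StrictStasis":
        target = x if method == "Joint" else x[1:]
        e = eps if method == "Joint" else eps[1:]
        if np.all(e > 0):
            w = 1.0 / e
            theta = float(np.sum(w * target) / np.sum(w))
            params = ModeParams(theta=theta, omega2=0.0)
            ll = loglik(model, params, series, method)
            ok = np.isfinite(ll)
        else:
            # zero sampling variance makes the strict-stasis density singular
            theta = float(np.mean(target))
            params = ModeParams(theta=theta, omega2=0.0)
            ll = -np.inf
            ok = False
        return ModelFit(model=model, params=params, loglik=ll, k_params=k,
                        n=n_eff, aicc=aicc(ll, k, n_eff), converged=ok)

    if model == "Stasis":
        target = x if method == "Joint" else x[1:]
        e = eps if method == "Joint" else eps[1:]

        def profile(omega2: float) -> float:
            var = omega2 + e
            if np.any(var <= 0):
                return -np.inf
            w = 1.0 / var
            theta = np.sum(w * target) / np.sum(w)
            return _norm_logpdf_sum(target, np.full_like(target, theta), var)

        scale = max(float(np.var(target)), 1e-8)
        omega2, ll, ok = _profile_maximize(profile, scale, settings)
        var = omega2 + e
        w = 1.0 / var
        theta = float(np.sum(w * target) / np.sum(w))
        params = ModeParams(theta=theta, omega2=omega2)
        return ModelFit(model=model, params=params, loglik=ll, k_params=k,
                        n=n_eff, aicc=aicc(ll, k, n_eff), converged=ok)

    # random-walk models
    if method == "Joint":
        X = np.column_stack([np.ones_like(t), t]) if model == "GRW" else np.ones((len(t), 1))

        def profile(sigma2: float) -> float:
            _, ll = _gls(X, x, _rw_cov(t, eps, sigma2))
            return ll

        sigma2, ll, ok = _profile_maximize(profile, _rw_scale(series), settings)
        beta, _ = _gls(X, x, _rw_cov(t, eps, sigma2))
        if beta is None:
            beta = np.array([x[0], 0.0])
            ok = False
        anc = float(beta[0])
        mu = float(beta[1]) if model == "GRW" else 0.0
    else:  # AD: differences are independent; weighted LS for mu
        d = np.diff(x)
        dt = np.diff(t)
        se = eps[:-1] + eps[1:]

        def profile(sigma2: float) -> float:
            var = sigma2 * dt + se
            if np.any(var <= 0):
                return -np.inf
            if model == "GRW":
                w = 1.0 / var
                mu = np.sum(w * d * dt) / np.sum(w * dt * dt)
            else:
                mu = 0.0
            return _norm_logpdf_sum(d, mu * dt, var)

        sigma2, ll, ok = _profile_maximize(profile, _rw_scale(series), settings)
        var = sigma2 * dt + se
        if model == "GRW" and np.all(var > 0):
            w = 1.0 / var
            mu = float(np.sum(w * d * dt) / np.sum(w * dt * dt))
        else:
            mu = 0.0
        anc = float(x[0])
    params = ModeParams(anc=anc, mu_step=mu if model == "GRW" else 0.0, sigma2_step=sigma2)
    return ModelFit(model=model, params=params, loglik=ll, k_params=k,
                    n=n_eff, aicc=aicc(ll, k, n_eff), converged=ok)


def fit_four_models(series: SampleSeries, method: str = "Joint",
                    settings: FitSettings | None = None) -> list[ModelFit]:
    """Fit all four modes, attach AICc and Akaike weights, sort by AICc.

    The lowest-AICc model is the best supported; weights give the
    probability each model is best within the candidate set.
    """
    fits = [fit_model(m, series, method, settings) for m in MODELS]
    weights = akaike_weights([f.aicc for f in fits])
    for f, w in zip(fits, weights):
        f.akaike_weight = float(w)
    return sorted(fits, key=lambda f: (f.aicc, f.model))


@dataclass
class ModelFitTable:
    """Per-phase model-fit results plus phases skipped as too short."""

    frames: list = field(default_factory=list)   # (phase_index, start, end, fits)
    skipped: list = field(default_factory=list)  # (phase_index, reason)

    def best_by_phase(self) -> dict:
        return {idx: fits[0] for idx, _, _, fits in self.frames}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for idx, start, end, fits in self.frames:
            for f in fits:
                p = f.params
                rows.append({
                    "phase_index": idx,
                    "start_year": start,
                    "end_year": end,
                    "model": f.model,
                    "loglik": f.loglik,
                    "k": f.k_params,
                    "n": f.n,
                    "aicc": f.aicc,
                    "akaike_weight": round(f.akaike_weight, 3),
                    "anc": p.anc,
                    "mu_step": p.mu_step,
                    "sigma2_step": p.sigma2_step,
                    "theta": p.theta,
                    "omega2": p.omega2,
                    "converged": f.converged,
                })
        return pd.DataFrame(rows)


def fit_by_phase(summaries: pd.DataFrame, phases, method: str = "Joint",
                 config: PipelineConfig | None = None) -> ModelFitTable:
    """Fit the four-model set within each year phase.

    Phases contributing fewer usable years than the configured minimum
    (default 6; the four-model set spends up to 3 parameters) are reported
    as skipped rather than fitted.
    """
    if config is None:
        config = PipelineConfig()
    table = ModelFitTable()
    min_n = config.fit.min_phase_samples
    for idx, phase in enumerate(phases):
        sub = summaries[(summaries["year"] >= phase.start_year)
                        & (summaries["year"] <= phase.end_year)]
        if len(sub) < min_n:
            table.skipped.append(
                (idx, f"phase {phase.start_year}-{phase.end_year} has only "
                      f"{len(sub)} sampled years (< {min_n})"))
            continue
        series = to_sample_series(sub.reset_index(drop=True), "mean", config)
        fits = fit_four_models(series, method, config.fit)
        table.frames.append((idx, phase.start_year, phase.end_year, fits))
    return table
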