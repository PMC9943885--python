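"""One-predictor multivariate adaptive regression splines (MARS).

A from-scratch implementation of the pieces a changepoint analysis of a
yearly trait series needs: a greedy forward pass adding reflected hinge
pairs max(0, x-k) / max(0, k-x) at observed knot candidates, a backward
pruning pass scored by generalized cross-validation (GCV), k-fold
cross-validated choice of the retained knot count, and conversion of the
selected knots into contiguous year phases with per-phase OLS lines.

With a single predictor the model space is piecewise-linear continuous
functions of the year, so the base model carries an intercept and a global
linear term and every hinge pair contributes one slope change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import MARSSettings

_RSS_EPS = 1e-12


@dataclass
class HingeModel:
    """A fitted hinge-function model.

    ``basis`` holds (knot, sign) pairs: sign +1 denotes max(0, x - knot),
    sign -1 denotes max(0, knot - x). ``coef`` aligns with the design
    matrix [1, x, *basis]. ``gcv`` and ``cv_r2`` are filled by the pruning
    and cross-validation stages.
    """

    basis: tuple
    coef: np.ndarray
    rss: float
    gcv: float = float("nan")
    cv_r2: float = float("nan")

    @property
    def knots(self) -> list:
        return sorted({k for k, _ in self.basis})

    @property
    def n_knots(self) -> int:
        return len({k for k, _ in self.basis})

    @property
    def n_coef(self) -> int:
        return len(self.coef)

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        cols = [np.ones_like(x), x]
        for knot, sign in self.basis:
            cols.append(np.maximum(0.0, sign * (x - knot)))
        return np.column_stack(cols)

    def predict(self, x) -> np.ndarray:
        return self.design(np.asarray(x, dtype=float)) @ self.coef


def _fit_basis(x: np.ndarray, y: np.ndarray, basis: tuple) -> HingeModel:
    model = HingeModel(basis=basis, coef=np.zeros(2 + len(basis)), rss=float("inf"))
    X = model.design(x)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    model.coef = coef
    model.rss = float(resid @ resid)
    return model


def candidate_knots(x: np.ndarray, end_span: int = 3) -> np.ndarray:
    """Observed x-values eligible as knots, excluding ``end_span``
    observations at each end to avoid degenerate hinges."""
    x = np.asarray(x, dtype=float)
    if end_span > 0:
        inner = x[end_span:len(x) - end_span]
    else:
        inner = x
    return np.unique(inner)


def forward_pass(x, y, max_terms: int, end_span: int = 3) -> list[HingeModel]:
    """Greedy forward selection of reflected hinge pairs.

    Starting from the intercept+linear base model, repeatedly adds the
    hinge pair at the candidate knot minimizing RSS (earliest year wins
    ties), up to ``max_terms`` pairs. Returns the full nested sequence,
    base model first; stops early when the fit is numerically exact or no
    candidate improves it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal lengths")
    if len(x) < 10:
        raise ValueError(f"forward_pass needs at least 10 points, got {len(x)}")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    if max_terms < 1:
        raise ValueError("max_terms must be >= 1")

    scale = max(float(np.sum((y - y.mean()) ** 2)), 1.0)
    models = [_fit_basis(x, y, basis=())]
    used: set = set()
    cands = candidate_knots(x, end_span)
    for _ in range(max_terms):
        current = models[-1]
        if current.rss <= _RSS_EPS * scale:
            break
        best = None
        for knot in cands:
            if knot in used:
                continue
            trial = _fit_basis(x, y, current.basis + ((knot, 1), (knot, -1)))
            if best is None or trial.rss < best.rss - _RSS_EPS * scale:
                best = trial
        if best is None or best.rss >= current.rss - _RSS_EPS * scale:
            break
        used.add(best.basis[-1][0])
        models.append(best)
    return models


def _gcv(rss: float, n: int, n_coef: int, n_knots: int, penalty: float) -> float:
    c = n_coef + penalty * n_knots
    if c >= n:
        return float("inf")
    return (rss / n) / (1.0 - c / n) ** 2


def prune_path(x, y, full: HingeModel, penalty: float) -> list[HingeModel]:
    """Backward deletion path from ``full`` down to the base model.

    At each step the single basis function whose removal minimizes RSS is
    deleted; every model along the path gets its GCV score. Returned
    largest-first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    current = full
    path = []
    while True:
        current.gcv = _gcv(current.rss, n, current.n_coef, current.n_knots, penalty)
        path.append(current)
        if not current.basis:
            break
        best = None
        for i in range(len(current.basis)):
            reduced = current.basis[:i] + current.basis[i + 1:]
            trial = _fit_basis(x, y, reduced)
            if best is None or trial.rss < best.rss:
                best = trial
        current = best
    return path


def backward_prune(x, y, models: list[HingeModel], penalty: float = 2.0) -> HingeModel:
    """Prune the largest forward-pass model, returning the min-GCV submodel.

    Models whose effective parameter count reaches the sample size have
    undefined GCV and are rejected from consideration; ties favor the
    smaller model.
    """
    if not models:
        raise ValueError("backward_prune requires a nonempty model sequence")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    path = prune_path(x, y, models[-1], penalty)
    finite = [m for m in path if np.isfinite(m.gcv)]
    if not finite:
        raise ValueError("GCV undefined for every model on the pruning path")
    best = min(m.gcv for m in finite)
    # GCV values within float fuzz of the minimum are ties; prefer the
    # smallest model among them
    tol = 1e-9 * (float(np.var(y)) + best) + 1e-12
    tied = [m for m in finite if m.gcv <= best + tol]
    return min(tied, key=lambda m: (m.n_knots, m.n_coef))


def _assign_folds(n: int, k_folds: int, rng: np.random.Generator,
                  scheme: str = "stratified") -> np.ndarray:
    folds = np.empty(n, dtype=int)
    if scheme == "blocks":
        folds[:] = (np.arange(n) * k_folds) // n
        return folds
    # stratified along the time axis: permute fold labels within each
    # consecutive block of k points, so every fold samples all eras
    labels = np.arange(k_folds)
    for start in range(0, n, k_folds):
        stop = min(start + k_folds, n)
        chunk = rng.permutation(labels)[: stop - start]
        folds[start:stop] = chunk
    return folds


def _path_model_for_count(path: list[HingeModel], m: int) -> HingeModel | None:
    """Smallest-RSS model on the path with exactly m knots (or the largest
    available count below m when the path never reaches m)."""
    exact = [mod for mod in path if mod.n_knots == m]
    if exact:
        return min(exact, key=lambda mod: mod.rss)
    smaller = [mod for mod in path if mod.n_knots < m]
    if smaller:
        best_count = max(mod.n_knots for mod in smaller)
        return min((mod for mod in smaller if mod.n_knots == best_count),
                   key=lambda mod: mod.rss)
    return None


@dataclass
class CVResult:
    """Selected model plus the per-knot-count cross-validation trace."""

    model: HingeModel
    knot_counts: np.ndarray
    cv_r2: np.ndarray
    gcv: np.ndarray
    knots_by_count: list

    def path_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "knot_count": self.knot_counts,
            "knots": [";".join(f"{k:g}" for k in ks) for ks in self.knots_by_count],
            "gcv": self.gcv,
            "cv_r2": self.cv_r2,
        })


def select_knots_cv(
    x,
    y,
    settings: MARSSettings | None = None,
    rng: np.random.Generator | None = None,
) -> CVResult:
    """Choose the retained knot count by k-fold cross-validation.

    For each knot count m along the pruned path, the mean out-of-fold R²
    over k folds is computed by re-running the forward/backward passes on
    each training split. The smallest m whose CV-R² comes within
    ``cv_tolerance`` of the maximum — the R² asymptote — is selected and
    refit on all data.
    """
    if settings is None:
        settings = MARSSettings()
    if rng is None:
        rng = np.random.default_rng(0)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < settings.k_folds:
        raise ValueError(f"need n >= k_folds ({settings.k_folds}), got n={n}")

    folds = _assign_folds(n, settings.k_folds, rng, settings.fold_scheme)
    counts = np.arange(settings.max_knots + 1)
    sse = np.zeros((settings.k_folds, len(counts)))
    sst = np.zeros(settings.k_folds)
    y_bar = y.mean()
    for f in range(settings.k_folds):
        test = folds == f
        if not test.any():
            continue
        xt, yt = x[~test], y[~test]
        fwd = forward_pass(xt, yt, settings.max_knots, settings.end_span)
        path = prune_path(xt, yt, fwd[-1], settings.gcv_penalty) + fwd
        sst[f] = float(np.sum((y[test] - y_bar) ** 2))
        for j, m in enumerate(counts):
            mod = _path_model_for_count(path, m)
            pred = mod.predict(x[test])
            sse[f, j] = float(np.sum((y[test] - pred) ** 2))
    valid = sst > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r2_folds = 1.0 - sse[valid] / sst[valid, None]
    cv_r2 = r2_folds.mean(axis=0)

    best = float(np.max(cv_r2))
    selected = int(counts[np.argmax(cv_r2 >= best - settings.cv_tolerance)])

    fwd_all = forward_pass(x, y, settings.max_knots, settings.end_span)
    path_all = prune_path(x, y, fwd_all[-1], settings.gcv_penalty) + fwd_all
    gcv_by_count = []
    knots_by_count = []
    for m in counts:
        mod = _path_model_for_count(path_all, m)
        mod.gcv = _gcv(mod.rss, n, mod.n_coef, mod.n_knots, settings.gcv_penalty)
        gcv_by_count.append(mod.gcv)
        knots_by_count.append(mod.knots)
    chosen = _path_model_for_count(path_all, selected)
    chosen.cv_r2 = float(cv_r2[selected])
    return CVResult(
        model=chosen,
        knot_counts=counts,
        cv_r2=cv_r2,
        gcv=np.asarray(gcv_by_count),
        knots_by_count=knots_by_count,
    )


@dataclass
class Phase:
    """A contiguous year segment with its OLS trend line."""

    start_year: int
    end_year: int
    slope: float = float("nan")
    intercept: float = float("nan")
    slope_ci_low: float = float("nan")
    slope_ci_high: float = float("nan")
    n: int = 0


@dataclass
class PhaseSet:
    phases: list = field(default_factory=list)
    knots: list = field(default_factory=list)

    def __len__(self):
        return len(self.phases)

    def __iter__(self):
        return iter(self.phases)

    def __getitem__(self, i):
        return self.phases[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "phase_index": i,
            "start_year": p.start_year,
            "end_year": p.end_year,
            "slope": p.slope,
            "intercept": p.intercept,
            "slope_ci_low": p.slope_ci_low,
            "slope_ci_high": p.slope_ci_high,
            "n": p.n,
        } for i, p in enumerate(self.phases)])


def _phase_ols(years: np.ndarray, values: np.ndarray, ci_level: float) -> tuple:
    n = len(years)
    if n < 2 or np.ptp(years) == 0:
        return float("nan"), float("nan"), float("nan"), float("nan")
    res = stats.linregress(years, values)
    if n > 2 and np.isfinite(res.stderr) and res.stderr > 0:
        tcrit = stats.t.ppf(0.5 + ci_level / 2, n - 2)
        lo, hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
    elif n > 2:  # perfectly collinear
        lo = hi = res.slope
    else:
        lo, hi = -np.inf, np.inf
    return float(res.slope), float(res.intercept), float(lo), float(hi)


def phases_from_knots(
    knots,
    year_start: int,
    year_end: int,
    summaries: pd.DataFrame,
    statistic: str = "mean",
    ci_level: float = 0.95,
) -> PhaseSet:
    """Partition [year_start, year_end] at the knot years.

    A knot year closes its phase: phase i ends at knot i and the next
    phase begins at knot i + 1. Each phase carries an OLS line of
    ``statistic`` against year with a t-based confidence interval on the
    slope.
    """
    knots = sorted(int(round(k)) for k in knots)
    for k in knots:
        if not (year_start < k < year_end):
            raise ValueError(f"knot {k} outside the open interval ({year_start}, {year_end})")
    starts = [year_start] + [k + 1 for k in knots]
    ends = list(knots) + [year_end]
    phases = []
    for s, e in zip(starts, ends):
        sub = summaries[(summaries["year"] >= s) & (summaries["year"] <= e)]
        slope, intercept, lo, hi = _phase_ols(
            sub["year"].to_numpy(dtype=float),
            sub[statistic].to_numpy(dtype=float),
            ci_level,
        )
        phases.append(Phase(start_year=s, end_year=e, slope=slope, intercept=intercept,
                            slope_ci_low=lo, slope_ci_high=hi, n=len(sub)))
    return PhaseSet(phases=phases, knots=knots)
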