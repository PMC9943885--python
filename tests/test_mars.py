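import numpy as np
import pandas as pd
import pytest

from traitwalls import (
    MARSSettings,
    backward_prune,
    forward_pass,
    phases_from_knots,
    select_knots_cv,
)
from traitwalls.mars import candidate_knots, prune_path


def exhaustive_knot_search(x, y, n_knots):
    """Independent oracle: brute-force RSS minimization over all single or
    double knot placements of a continuous piecewise-linear fit."""
    from itertools import combinations
    cands = candidate_knots(x)

    def rss_for(knots):
        cols = [np.ones_like(x), x] + [np.maximum(0.0, x - k) for k in knots]
        X = np.column_stack(cols)
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)

    best = None
    for knots in combinations(cands, n_knots):
        r = rss_for(knots)
        if best is None or r < best[1] - 1e-10:
            best = (knots, r)
    return sorted(best[0]), best[1]


def piecewise(x, breaks, slopes, start=0.0):
    """Continuous piecewise-linear ground truth built by integrating the
    segment slopes."""
    edges = [x[0]] + list(breaks) + [x[-1]]
    y = np.empty_like(x, dtype=float)
    for i, xi in enumerate(x):
        val = start
        for slope, (lo, hi) in zip(slopes, zip(edges[:-1], edges[1:])):
            step = min(xi, hi) - lo
            if step > 0:
                val += slope * step
            if xi <= hi:
                break
        y[i] = val
    return y


class TestForwardPass:
    def test_linear_data_needs_no_knot(self):
        x = np.arange(1.0, 101.0)
        models = forward_pass(x, 2 * x + 1, max_terms=5)
        assert models[0].rss == pytest.approx(0.0, abs=1e-9)
        assert len(models) == 1  # no knot improves an exact fit

    def test_single_kink_matches_exhaustive_oracle(self):
        x = np.arange(1.0, 101.0)
        y = np.abs(x - 50)
        models = forward_pass(x, y, max_terms=3)
        oracle_knots, oracle_rss = exhaustive_knot_search(x, y, 1)
        assert models[1].knots == oracle_knots == [50.0]
        assert models[1].rss == pytest.approx(oracle_rss, abs=1e-8)
        assert models[1].rss == pytest.approx(0.0, abs=1e-8)

    def test_two_breaks_match_exhaustive_oracle(self):
        """Forward selection overshoots, but pruning lands on the same
        two knots as brute-force search over all placements."""
        x = np.arange(1.0, 61.0)
        y = piecewise(x, breaks=[20.0, 40.0], slopes=[1.0, 0.0, 2.0])
        models = forward_pass(x, y, max_terms=6)
        assert models[-1].rss == pytest.approx(0.0, abs=1e-8)
        pruned = backward_prune(x, y, models)
        oracle_knots, _ = exhaustive_knot_search(x, y, 2)
        assert pruned.knots == oracle_knots == [20.0, 40.0]
        assert pruned.rss == pytest.approx(0.0, abs=1e-8)

    def test_rss_is_non_increasing_along_the_pass(self):
        rng = np.random.default_rng(2)
        x = np.arange(0.0, 80.0)
        y = np.sin(x / 10) + rng.normal(0, 0.3, size=80)
        models = forward_pass(x, y, max_terms=6)
        rss = [m.rss for m in models]
        assert all(a >= b - 1e-9 for a, b in zip(rss, rss[1:]))

    def test_fit_is_continuous_piecewise_linear(self):
        rng = np.random.default_rng(4)
        x = np.arange(0.0, 60.0)
        y = piecewise(x, [25.0], [0.5, -1.0]) + rng.normal(0, 0.1, size=60)
        model = forward_pass(x, y, max_terms=3)[-1]
        for k in model.knots:
            left = model.predict([k - 1e-7])[0]
            right = model.predict([k + 1e-7])[0]
            assert left == pytest.approx(right, abs=1e-5)
        # second differences vanish away from knots (piecewise linearity)
        grid = np.array([g for g in np.linspace(5, 55, 201)
                         if all(abs(g - k) > 0.5 for k in model.knots)])
        pred = model.predict(grid)
        d2 = np.diff(pred) / np.diff(grid)
        # slopes are locally constant between consecutive off-knot points
        jumps = np.abs(np.diff(d2))
        assert np.sum(jumps > 1e-6) <= len(model.knots)

    def test_preconditions(self):
        x = np.arange(1.0, 11.0)
        with pytest.raises(ValueError, match="max_terms"):
            forward_pass(x, x, max_terms=0)
        with pytest.raises(ValueError, match="at least 10"):
            forward_pass(x[:5], x[:5], max_terms=1)


class TestBackwardPrune:
    def test_noiseless_kink_survives_pruning(self):
        x = np.arange(1.0, 101.0)
        y = np.abs(x - 50)
        models = forward_pass(x, y, max_terms=5)
        pruned = backward_prune(x, y, models, penalty=2.0)
        assert pruned.knots == [50.0]

    def test_single_model_returned_unchanged(self):
        x = np.arange(1.0, 101.0)
        y = 2 * x
        models = forward_pass(x, y, max_terms=3)
        assert len(models) == 1
        pruned = backward_prune(x, y, models)
        assert pruned.basis == models[0].basis

    def test_pure_noise_is_pruned_back(self):
        """With no structure, GCV pruning should retain at most one knot in
        the vast majority of replicates."""
        x = np.arange(60.0)
        keep = 0
        for rep in range(100):
            y = np.random.default_rng(rep).normal(size=60)
            pruned = backward_prune(x, y, forward_pass(x, y, max_terms=10))
            keep += pruned.n_knots <= 1
        assert keep >= 90

    def test_gcv_matches_hand_computation_on_two_model_path(self):
        x = np.arange(1.0, 101.0)
        y = np.abs(x - 50)
        models = forward_pass(x, y, max_terms=1)
        path = prune_path(x, y, models[-1], penalty=2.0)
        for m in path:
            c = m.n_coef + 2.0 * m.n_knots
            expected = (m.rss / 100) / (1 - c / 100) ** 2
            assert m.gcv == pytest.approx(expected)


class TestSelectKnotsCV:
    def test_noiseless_two_break_data_recovers_truth(self):
        x = np.arange(1.0, 61.0)
        y = piecewise(x, [20.0, 40.0], [1.0, 0.0, 2.0])
        res = select_knots_cv(x, y, MARSSettings(), np.random.default_rng(0))
        assert res.model.knots == [20.0, 40.0]

    def test_linear_with_small_noise_selects_zero_knots(self):
        rng = np.random.default_rng(1)
        x = np.arange(1.0, 101.0)
        y = 0.5 * x + rng.normal(0, 0.5, size=100)
        res = select_knots_cv(x, y, MARSSettings(), np.random.default_rng(0))
        assert res.model.n_knots == 0

    def test_same_fold_stream_reproduces_the_selection(self):
        rng = np.random.default_rng(9)
        x = np.arange(0.0, 70.0)
        y = piecewise(x, [30.0], [0.2, 1.5]) + rng.normal(0, 0.5, size=70)
        a = select_knots_cv(x, y, MARSSettings(), np.random.default_rng(42))
        b = select_knots_cv(x, y, MARSSettings(), np.random.default_rng(42))
        assert a.model.knots == b.model.knots
        assert np.allclose(a.cv_r2, b.cv_r2)

    def test_needs_at_least_k_points(self):
        with pytest.raises(ValueError, match="k_folds"):
            select_knots_cv(np.arange(5.0), np.arange(5.0), MARSSettings(k_folds=10))


class TestPhasesFromKnots:
    def _summaries(self, years, values):
        return pd.DataFrame({"year": years, "mean": values})

    def test_knot_year_closes_its_phase(self):
        years = np.arange(1829, 1965)
        ps = phases_from_knots([1881, 1945], 1829, 1964,
                               self._summaries(years, np.arange(136.0)))
        spans = [(p.start_year, p.end_year) for p in ps]
        assert spans == [(1829, 1881), (1882, 1945), (1946, 1964)]

    def test_no_knots_gives_single_full_phase(self):
        years = np.arange(1829, 1965)
        ps = phases_from_knots([], 1829, 1964, self._summaries(years, np.arange(136.0)))
        assert [(p.start_year, p.end_year) for p in ps] == [(1829, 1964)]

    def test_constant_phase_has_zero_slope_ci_containing_zero(self):
        years = np.arange(1900, 1930)
        ps = phases_from_knots([], 1900, 1929, self._summaries(years, np.full(30, 5.0)))
        p = ps[0]
        assert p.slope == pytest.approx(0.0, abs=1e-12)
        assert p.slope_ci_low <= 0.0 <= p.slope_ci_high

    def test_phases_partition_the_range(self):
        years = np.arange(1829, 1965)
        ps = phases_from_knots([1860, 1900, 1940], 1829, 1964,
                               self._summaries(years, np.arange(136.0)))
        for a, b in zip(ps.phases, ps.phases[1:]):
            assert b.start_year == a.end_year + 1
        assert ps[0].start_year == 1829 and ps[-1].end_year == 1964

    def test_out_of_range_knot_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            phases_from_knots([1829], 1829, 1964,
                              self._summaries(np.arange(1829, 1965), np.arange(136.0)))
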