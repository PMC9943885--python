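"""Synthetic trait data emulating competition-driven extinction.

Two generators:

* :func:`simulate_mode_series` draws a :class:`~traitwalls.series.SampleSeries`
  directly from one of the four evolutionary-mode models, for estimator
  tests (parameter recovery, model-selection consistency).
* :func:`simulate_design_records` builds a design-level record table for a
  whole scenario: a latent performance frontier drifts as a random walk —
  neutrally before any competitor appears, directionally afterwards —
  reflected below a fixed upper ("right") wall, while the feasible lower
  bound (the "left" wall) stays put until a late exclusion onset, after
  which it rises and truncates the lower tail. Each year a Poisson number
  of new designs draws trait values from the band between the walls.

Default scenario conditions: a 136-year span with a single competitor
appearing in year 60, drift sized so the frontier first strikes the right
wall near year 90, and lower-tail exclusion beginning in year 100 —
together with a design intensity of ~120 new designs per year, matching
the density of the historical record the pipeline is modeled on. Trait
units are dimensionless (walls at 1 and 100); every statistic downstream
is scale-free.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import substream
from .records import EventRecord
from .series import SampleSeries


@dataclass
class ScenarioConfig:
    """Generative scenario for a design-level record table."""

    years: int = 136
    start_year: int = 1
    left_wall: float = 1.0
    right_wall: float = 100.0
    frontier_start: float = 10.0
    baseline_step_sd: float = 0.8
    competitor_years: tuple = (60,)
    #: drift (trait units / yr) added to the frontier walk at each
    #: competitor onset; scalar applies to every competitor
    post_competitor_drift: float | tuple = 3.0
    exclusion_onset_year: int | None = 100
    exclusion_rate: float = 1.0
    designs_per_year_rate: float = 120.0
    #: minimum width of the trait band; the frontier is clamped (and the
    #: year flagged) if the rising lower bound would squeeze it thinner
    within_year_spread: float = 0.5
    #: "triangular" places the within-year mode below the mean, at this
    #: fraction of the band; "uniform" is available for sensitivity checks
    band_shape: str = "triangular"
    triangular_mode_frac: float = 0.6
    disturbance_years: tuple = ()
    disturbance_magnitudes: tuple = ()
    disturbance_duration: int = 2
    seed: int = 0

    def validate(self) -> "ScenarioConfig":
        if self.years < 3:
            raise ValueError("scenario needs at least 3 years")
        if self.right_wall <= self.left_wall:
            raise ValueError("right_wall must exceed left_wall")
        if self.exclusion_rate < 0 or self.baseline_step_sd <= 0:
            raise ValueError("rates must be nonnegative, step sd positive")
        if self.designs_per_year_rate <= 0 or self.within_year_spread <= 0:
            raise ValueError("designs_per_year_rate and within_year_spread must be positive")
        last = self.start_year + self.years - 1
        for cy in self.competitor_years:
            if not (self.start_year <= cy <= last):
                raise ValueError(f"competitor year {cy} outside scenario span")
        if self.exclusion_onset_year is not None and not (
            self.start_year <= self.exclusion_onset_year <= last
        ):
            raise ValueError("exclusion_onset_year outside scenario span")
        if self.band_shape not in ("triangular", "uniform"):
            raise ValueError(f"unknown band_shape {self.band_shape!r}")
        if len(self.disturbance_magnitudes) not in (0, len(self.disturbance_years)):
            raise ValueError("disturbance_magnitudes must match disturbance_years")
        return self

    def drifts(self) -> list:
        d = self.post_competitor_drift
        if np.isscalar(d):
            return [float(d)] * len(self.competitor_years)
        if len(d) != len(self.competitor_years):
            raise ValueError("post_competitor_drift must be scalar or match competitor_years")
        return [float(v) for v in d]


@dataclass
class GroundTruth:
    """Bookkeeping truth for a simulated scenario."""

    seed: int
    competitor_onset_years: list
    detachment_year: int | None
    wall_contact_year: int | None
    years: list = field(default_factory=list)
    n: list = field(default_factory=list)
    mean: list = field(default_factory=list)
    max: list = field(default_factory=list)
    min: list = field(default_factory=list)
    frontier: list = field(default_factory=list)
    lower_bound: list = field(default_factory=list)
    gap_years: list = field(default_factory=list)
    clamped_years: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def simulate_mode_series(
    model: str,
    params,
    n_samples: int,
    sizes,
    within_sample_var: float,
    seed: int,
    ages=None,
) -> SampleSeries:
    """Draw a sample series exactly from one evolutionary-mode model.

    Latent means follow the generating process (random-walk increments or
    independent stasis draws); observed means add sampling noise with
    variance ``within_sample_var / size``. The recorded variances and
    sizes are the true ones.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    if within_sample_var < 0:
        raise ValueError("within_sample_var must be nonnegative")
    rng = np.random.default_rng(seed)
    sizes = np.full(n_samples, sizes, dtype=int) if np.isscalar(sizes) \
        else np.asarray(sizes, dtype=int)
    ages = np.arange(n_samples, dtype=float) if ages is None \
        else np.asarray(ages, dtype=float)
    dt = np.diff(ages)

    if model in ("GRW", "URW"):
        mu = params.mu_step if model == "GRW" else 0.0
        sigma2 = params.sigma2_step
        if sigma2 is None or sigma2 < 0:
            raise ValueError("random-walk models need sigma2_step >= 0")
        steps = rng.normal(mu * dt, np.sqrt(sigma2 * dt))
        latent = params.anc + np.concatenate([[0.0], np.cumsum(steps)])
    elif model in ("Stasis", "StrictStasis"):
        omega2 = params.omega2 if model == "Stasis" else 0.0
        if omega2 is None or omega2 < 0:
            raise ValueError("stasis needs omega2 >= 0")
        latent = rng.normal(params.theta, np.sqrt(omega2), size=n_samples)
    else:
        raise ValueError(f"unknown model {model!r}")

    noise_sd = np.sqrt(within_sample_var / sizes)
    observed = latent + rng.normal(0.0, 1.0, size=n_samples) * noise_sd
    return SampleSeries(
        ages=ages,
        means=observed,
        variances=np.full(n_samples, float(within_sample_var)),
        sizes=sizes,
    )


def _disturbance_factor(sc: ScenarioConfig, year: int) -> float:
    factor = 1.0
    mags = sc.disturbance_magnitudes or (1.0,) * len(sc.disturbance_years)
    for dy, mag in zip(sc.disturbance_years, mags):
        if dy <= year <= dy + sc.disturbance_duration - 1:
            factor *= mag
    return factor


def simulate_design_records(sc: ScenarioConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a full design-level record table plus its ground truth.

    The latent frontier walks with the current drift, reflecting off the
    right wall (so post-contact maxima can "bounce"); yearly trait values
    are drawn between the current lower bound and the frontier. The truth
    object records the first wall contact, the exclusion onset, per-year
    realized summaries, and any years where the band collapsed and the
    frontier had to be clamped.
    """
    sc.validate()
    rng = substream(sc.seed, "simulation")
    drifts = sc.drifts()
    truth = GroundTruth(
        seed=sc.seed,
        competitor_onset_years=list(sc.competitor_years),
        detachment_year=sc.exclusion_onset_year if sc.exclusion_rate > 0 else None,
        wall_contact_year=None,
    )
    frontier = sc.frontier_start
    rows = []
    last = sc.start_year + sc.years - 1
    for year in range(sc.start_year, last + 1):
        drift = sum(d for cy, d in zip(sc.competitor_years, drifts) if year >= cy)
        frontier += rng.normal(drift, sc.baseline_step_sd)
        if frontier > sc.right_wall:
            frontier = 2.0 * sc.right_wall - frontier  # reflect, not absorb
            if truth.wall_contact_year is None:
                truth.wall_contact_year = year
        lower = sc.left_wall
        if sc.exclusion_onset_year is not None and year >= sc.exclusion_onset_year:
            lower += sc.exclusion_rate * (year - sc.exclusion_onset_year)
        if frontier < lower + sc.within_year_spread:
            frontier = lower + sc.within_year_spread
            truth.clamped_years.append(year)

        rate = sc.designs_per_year_rate * _disturbance_factor(sc, year)
        n_designs = int(rng.poisson(rate))
        if n_designs == 0:
            truth.gap_years.append(year)
            truth.frontier.append(float(frontier))
            truth.lower_bound.append(float(lower))
            continue
        if sc.band_shape == "triangular":
            mode = lower + sc.triangular_mode_frac * (frontier - lower)
            values = rng.triangular(lower, mode, frontier, size=n_designs)
        else:
            values = rng.uniform(lower, frontier, size=n_designs)
        for j, v in enumerate(values):
            rows.append((f"D{year:04d}-{j:04d}", year, float(v)))
        truth.years.append(year)
        truth.n.append(n_designs)
        truth.mean.append(float(values.mean()))
        truth.max.append(float(values.max()))
        truth.min.append(float(values.min()))
        truth.frontier.append(float(frontier))
        truth.lower_bound.append(float(lower))
    records = pd.DataFrame(rows, columns=["design_id", "year", "trait_value"])
    return records, truth


def ground_truth_report(sc: ScenarioConfig) -> GroundTruth:
    """Deterministic truth for a scenario: same seed, same report."""
    _, truth = simulate_design_records(sc)
    return truth


def scenario_events(sc: ScenarioConfig) -> list[EventRecord]:
    """Event records (competitors + disturbances) implied by a scenario."""
    events = [EventRecord(name=f"competitor_{i + 1}", year=int(cy), kind="competitor")
              for i, cy in enumerate(sc.competitor_years)]
    events += [EventRecord(name=f"disturbance_{i + 1}", year=int(dy), kind="disturbance")
               for i, dy in enumerate(sc.disturbance_years)]
    return sorted(events, key=lambda e: e.year)
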