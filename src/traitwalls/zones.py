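"""Safe / danger / extinction zone classification.

Operationalizes a graphical model of competition-driven extinction as
explicit decision rules over the annual summaries, MARS phases, mode fits
and the event table:

* **safe zone** — before any competition signal: the incumbent's mean
  trait drifts neutrally away from the lower ("left") wall.
* **danger zone** — begins when the best-supported evolutionary mode
  switches from an unbiased walk or stasis to a positive directional walk
  at a phase boundary coinciding (within a configurable window) with a
  competitor first appearance: character displacement.
* **extinction zone** — begins when the yearly minimum detaches from the
  left wall (a sustained, significantly positive minimum trend), meaning
  no population remains shielded from competition.

A collision of the yearly maximum with the upper ("right") wall — the
series levelling off or bouncing at its peak — is recorded as supporting
evidence, not a zone boundary. All thresholds are explicit, configurable
stand-ins for a qualitative picture, and are echoed in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig, ZoneSettings, substream
from .mars import PhaseSet, _phase_ols, phases_from_knots, select_knots_cv
from .modes import ModelFitTable

RW_LIKE = ("URW", "Stasis", "StrictStasis")


@dataclass
class Zone:
    zone: str
    start_year: int
    end_year: int


@dataclass
class ZoneReport:
    zones: list = field(default_factory=list)
    directional_shift_year: int | None = None
    right_wall_year: int | None = None
    left_wall_detach_year: int | None = None
    evidence: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "zone": z.zone, "start_year": z.start_year, "end_year": z.end_year,
        } for z in self.zones])


def detect_directional_shift(
    fit_table: ModelFitTable,
    events,
    window: int = 5,
) -> tuple[int | None, dict | None]:
    """First phase boundary where the best mode switches to directional.

    Scans consecutive fitted phases for a switch from {URW, Stasis,
    StrictStasis} to GRW with a positive mean step, and accepts it only if
    the boundary (knot) year lies within ``window`` years of a competitor
    first appearance. Returns (year, evidence) or (None, None).
    """
    competitor_years = [e.year for e in events if e.kind == "competitor"]
    if not competitor_years or len(fit_table.frames) < 2:
        return None, None
    frames = sorted(fit_table.frames, key=lambda f: f[1])
    for (i1, s1, e1, fits1), (i2, s2, e2, fits2) in zip(frames, frames[1:]):
        if s2 != e1 + 1:
            continue  # a skipped phase breaks the chain
        best1, best2 = fits1[0], fits2[0]
        if best1.model in RW_LIKE and best2.model == "GRW" \
                and (best2.params.mu_step or 0.0) > 0:
            knot = e1
            near = [c for c in competitor_years if abs(knot - c) <= window]
            if near:
                return knot, {
                    "rule": "directional_shift",
                    "knot_year": knot,
                    "best_model_before": best1.model,
                    "best_model_after": best2.model,
                    "mu_step_after": best2.params.mu_step,
                    "matched_competitor_year": near[0],
                }
    return None, None


def detect_right_wall(
    years,
    max_values,
    settings: ZoneSettings | None = None,
) -> tuple[int | None, dict | None]:
    """Year the yearly-maximum series hits its upper wall, if it does.

    The candidate year is the first year entering a tolerance band
    (``peak_tolerance_frac`` of the series range) below the global
    maximum — the peak itself for a rise-and-fall ("bounce") series, the
    plateau onset when the series levels off at the wall. The call is
    accepted when at least ``post_peak_fraction`` of the series follows
    the candidate and the post-candidate OLS slope, including its CI upper
    bound, stays below a small positive threshold.
    """
    if settings is None:
        settings = ZoneSettings()
    years = np.asarray(years, dtype=float)
    vals = np.asarray(max_values, dtype=float)
    n = len(years)
    if n < settings.min_series_points:
        raise ValueError(f"right-wall detection needs >= {settings.min_series_points} yearly maxima")
    rng_span = float(np.ptp(vals))
    if rng_span == 0:
        return None, None
    tol = settings.peak_tolerance_frac * rng_span
    cand_idx = int(np.argmax(vals >= vals.max() - tol))
    post = slice(cand_idx + 1, n)
    n_post = n - cand_idx - 1
    if n_post < max(3, int(np.ceil(settings.post_peak_fraction * n))):
        return None, None
    slope, _, _, ci_high = _phase_ols(years[post], vals[post], settings.ci_level)
    threshold = settings.wall_slope_threshold_frac * rng_span
    if np.isfinite(slope) and slope < threshold and ci_high < threshold:
        year = int(years[cand_idx])
        return year, {
            "rule": "right_wall",
            "peak_year": year,
            "peak_value": float(vals[cand_idx]),
            "post_peak_slope": slope,
            "post_peak_slope_ci_high": ci_high,
            "slope_threshold": threshold,
            "post_peak_fraction": n_post / n,
        }
    return None, None


def detect_left_wall_detachment(
    years,
    min_values,
    config: PipelineConfig | None = None,
) -> tuple[int | None, dict | None]:
    """Year the yearly-minimum series detaches from the lower wall.

    Runs the MARS changepoint search on the minimum series and returns the
    last knot whose following phase has a significantly positive OLS slope
    (95% CI excluding zero); None when the minimum never takes off.
    """
    if config is None:
        config = PipelineConfig()
    years = np.asarray(years, dtype=float)
    vals = np.asarray(min_values, dtype=float)
    if len(years) < config.zones.min_series_points:
        raise ValueError(
            f"left-wall detection needs >= {config.zones.min_series_points} yearly minima")
    rng = substream(config.seed, "mars-cv-min")
    result = select_knots_cv(years, vals, config.mars, rng)
    if not result.model.knots:
        return None, None
    frame = pd.DataFrame({"year": years.astype(int), "min": vals})
    phases = phases_from_knots(result.model.knots, int(years[0]), int(years[-1]),
                               frame, statistic="min", ci_level=config.zones.ci_level)
    for phase, knot in zip(reversed(phases.phases[1:]), reversed(phases.knots)):
        if np.isfinite(phase.slope) and phase.slope > 0 and phase.slope_ci_low > 0:
            return int(knot), {
                "rule": "left_wall_detachment",
                "knot_year": int(knot),
                "following_slope": phase.slope,
                "following_slope_ci": [phase.slope_ci_low, phase.slope_ci_high],
            }
    return None, None


def classify_zones(
    summaries: pd.DataFrame,
    phases: PhaseSet,
    fit_table: ModelFitTable,
    events,
    config: PipelineConfig | None = None,
) -> ZoneReport:
    """Assemble the safe/danger/extinction report from all component analyses.

    Safe runs from the series start to the directional-shift year (the
    whole series if no competition signal fires); danger runs from the
    shift to left-wall detachment (or the series end); extinction runs
    from detachment to the end. The right-wall year is recorded as
    evidence only. Degenerate inputs yield a single safe zone with a note.
    """
    if config is None:
        config = PipelineConfig()
    report = ZoneReport()
    first = int(summaries["year"].min())
    last = int(summaries["year"].max())
    zs = config.zones

    shift, shift_ev = detect_directional_shift(fit_table, events, zs.event_window_years)
    report.directional_shift_year = shift
    if shift_ev:
        report.evidence["danger"] = [shift_ev]

    if len(summaries) >= zs.min_series_points:
        rw, rw_ev = detect_right_wall(summaries["year"], summaries["max"], zs)
        report.right_wall_year = rw
        if rw_ev:
            report.evidence.setdefault("danger", []).append(rw_ev)
        det, det_ev = detect_left_wall_detachment(summaries["year"], summaries["min"], config)
        report.left_wall_detach_year = det
        if det_ev:
            report.evidence["extinction"] = [det_ev]
    else:
        report.notes.append("series too short for wall detectors")

    disturbances = [e for e in events if e.kind == "disturbance"]
    if disturbances:
        report.notes.append(
            "disturbance events annotated but excluded from rule triggers: "
            + ", ".join(f"{e.name} ({e.year})" for e in disturbances))

    if shift is None:
        report.zones = [Zone("safe", first, last)]
        report.notes.append("no competition detected")
        return report

    det = report.left_wall_detach_year
    if det is not None and det <= shift:
        report.notes.append(
            f"left-wall detachment year {det} does not follow the directional shift; "
            "treated as evidence only")
        det = None
    zones = []
    if shift > first:
        zones.append(Zone("safe", first, shift - 1))
    if det is not None:
        zones.append(Zone("danger", max(shift, first), det - 1))
        zones.append(Zone("extinction", det, last))
    else:
        zones.append(Zone("danger", max(shift, first), last))
    report.zones = zones
    return report
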