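"""Per-year distributional summaries of a trait-record table.

Collapses design-level records into one row per calendar year — sample
size, mean, sample variance, maximum, minimum, a kernel-density modal
proxy and the interquartile range — and repackages the result as the
(mean, variance, n, age) quadruples the evolutionary-mode likelihoods
consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import KDESettings, PipelineConfig

SUMMARY_COLUMNS = [
    "year", "n", "mean", "variance", "max", "min", "mode", "iqr_low", "iqr_high",
]


def _nrd0_bandwidth(values: np.ndarray) -> float:
    # Silverman rule-of-thumb as implemented by R's bw.nrd0, including its
    # fallbacks for degenerate spread.
    n = len(values)
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    lo = min(sd, iqr / 1.34) if iqr > 0 else sd
    if lo == 0:
        lo = sd or abs(float(values[0])) or 1.0
    return 0.9 * lo * n ** (-0.2)


def kde_mode(values, kde: KDESettings | None = None) -> float:
    """Grid argmax of a Gaussian kernel density estimate.

    The peak of the estimated density serves as a modal proxy for a
    continuous trait. For a single value the value itself is returned;
    ties break toward the smallest grid point.
    """
    if kde is None:
        kde = KDESettings()
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("kde_mode requires at least one value")
    if values.size == 1 or np.ptp(values) == 0:
        return float(values[0])
    bw = _nrd0_bandwidth(values)
    lo = values.min() - kde.tail_bandwidths * bw
    hi = values.max() + kde.tail_bandwidths * bw
    grid = np.linspace(lo, hi, kde.grid_size)
    # density up to a constant factor; argmax is what matters
    z = (grid[:, None] - values[None, :]) / bw
    density = np.exp(-0.5 * z * z).sum(axis=1)
    return float(grid[int(np.argmax(density))])


def build_summary_series(
    records: pd.DataFrame, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, list[int]]:
    """Collapse a record table into one summary row per observed year.

    Returns the summary frame (columns :data:`SUMMARY_COLUMNS`) and the
    list of gap years — years inside the observed span with no records,
    which are omitted from the series rather than interpolated.
    """
    if config is None:
        config = PipelineConfig()
    if len(records) == 0:
        raise ValueError("cannot summarize an empty record table")
    rows = []
    for year, grp in records.groupby("year"):
        v = grp["trait_value"].to_numpy(dtype=float)
        n = len(v)
        q25, q75 = np.percentile(v, [25, 75])  # linear-interpolation (type 7)
        mode = kde_mode(v, config.kde)
        rows.append({
            "year": int(year),
            "n": n,
            "mean": float(v.mean()),
            "variance": float(v.var(ddof=1)) if n > 1 else 0.0,
            "max": float(v.max()),
            "min": float(v.min()),
            # the KDE grid extends past the data range; clip the modal
            # proxy back into [min, max] so summary invariants hold
            "mode": float(np.clip(mode, v.min(), v.max())),
            "iqr_low": float(q25),
            "iqr_high": float(q75),
        })
    summaries = pd.DataFrame(rows).sort_values("year").reset_index(drop=True)
    observed = set(summaries["year"])
    gaps = [y for y in range(summaries["year"].min(), summaries["year"].max() + 1)
            if y not in observed]
    return summaries, gaps


@dataclass
class SampleSeries:
    """Fit-ready series of (age, mean, variance, n) quadruples.

    Ages are rebased so the first sample sits at 0; they must be strictly
    increasing. ``imputed`` flags samples whose variance was replaced by
    the pooled within-year variance (singleton years).
    """

    ages: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    sizes: np.ndarray
    imputed: np.ndarray = field(default=None)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=int)
        if self.imputed is None:
            self.imputed = np.zeros(len(self.ages), dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)
        n = len(self.ages)
        if not (len(self.means) == len(self.variances) == len(self.sizes) == n):
            raise ValueError("SampleSeries fields must have equal lengths")
        # likelihood evaluation is defined from 2 samples; fitting
        # enforces its own stricter minimum
        if n < 2:
            raise ValueError("SampleSeries needs at least 2 samples")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("SampleSeries ages must be strictly increasing")
        if np.any(self.variances < 0):
            raise ValueError("SampleSeries variances must be nonnegative")
        if np.any(self.sizes < 1):
            raise ValueError("SampleSeries sizes must be positive")

    def __len__(self) -> int:
        return len(self.ages)

    @property
    def sampling_variances(self) -> np.ndarray:
        """Per-sample sampling variance of the mean, v_i / n_i."""
        return self.variances / self.sizes


def pooled_variance(summaries: pd.DataFrame) -> float:
    """Pooled within-year variance over all years with n >= 2."""
    multi = summaries[summaries["n"] > 1]
    if len(multi) == 0:
        return 0.0
    w = (multi["n"] - 1).to_numpy(dtype=float)
    return float(np.sum(w * multi["variance"].to_numpy()) / np.sum(w))


def to_sample_series(
    summaries: pd.DataFrame,
    statistic: str = "mean",
    config: PipelineConfig | None = None,
) -> SampleSeries:
    """Convert a summary frame into a :class:`SampleSeries` on ``statistic``.

    Only the yearly mean carries the variance/sample-size structure the
    mode likelihoods require, so any other statistic is rejected.
    Singleton years (n = 1) receive the pooled within-year variance and
    are flagged as imputed.
    """
    if statistic != "mean":
        raise ValueError(
            f"sample series require the 'mean' statistic (got {statistic!r}); "
            "max/min/mode series lack the within-year variance structure"
        )
    if len(summaries) < 3:
        raise ValueError(f"need at least 3 summarized years, got {len(summaries)}")
    years = summaries["year"].to_numpy(dtype=float)
    variances = summaries["variance"].to_numpy(dtype=float).copy()
    singleton = summaries["n"].to_numpy() == 1
    if singleton.any():
        variances[singleton] = pooled_variance(summaries)
    return SampleSeries(
        ages=years - years[0],
        means=summaries["mean"].to_numpy(dtype=float),
        variances=variances,
        sizes=summaries["n"].to_numpy(dtype=int),
        imputed=singleton,
    )
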