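"""Plot-level ΔAGB aggregation and weighted statistics for permanent plots.

Permanent plots (old-growth and managed/logged forests) each carry one
or more census-interval ΔAGB rates.  A plot's rate is the plain mean
across its censuses.  Within a category, plot rates are weighted by
plot area × total monitoring period — larger, longer-monitored plots
measure net change with less sampling noise — unless every plot in the
category shares the same area and monitoring period, in which case
weighting is moot and unit weights are used.  Uncertainty for the
weighted category mean comes from a percentile bootstrap over plots
(the independent sampling units), resampling rate–weight pairs jointly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import CensusRate, PermanentPlot, PlotStatus, UsageError, ValidationError

__all__ = [
    "WeightingScheme",
    "WeightedRate",
    "DEFAULT_BOOTSTRAP_SEED",
    "plot_mean_rate",
    "plot_weight",
    "category_weighted_rates",
    "weighted_mean",
    "weighted_sd",
    "bootstrap_ci",
    "weighted_rates_to_frame",
]

#: Default seed for the category bootstrap (the derivation is meant to
#: be bit-reproducible end to end).
DEFAULT_BOOTSTRAP_SEED = 20190816


class WeightingScheme(str, Enum):
    AREA_X_YEARS = "area_x_years"
    AREA_ONLY = "area_only"
    YEARS_ONLY = "years_only"
    EQUAL = "equal"


@dataclass(frozen=True)
class WeightedRate:
    """A plot-mean ΔAGB rate with its category weight."""

    plot_id: str
    rate: float
    weight: float
    status: PlotStatus

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValidationError(f"plot {self.plot_id!r}: negative weight")


def plot_mean_rate(censuses: Sequence[CensusRate]) -> float:
    """Mean ΔAGB rate across a plot's census intervals (unweighted)."""
    if not censuses:
        raise UsageError("plot has no census intervals")
    return float(np.mean([c.rate for c in censuses]))


def plot_weight(
    area_ha: float,
    monitoring_years: float,
    scheme: WeightingScheme = WeightingScheme.AREA_X_YEARS,
) -> float:
    """Weight of one plot under the given scheme."""
    if not area_ha > 0 or not monitoring_years > 0:
        raise ValidationError(
            f"area ({area_ha}) and monitoring period ({monitoring_years}) must be positive"
        )
    if scheme is WeightingScheme.AREA_X_YEARS:
        return area_ha * monitoring_years
    if scheme is WeightingScheme.AREA_ONLY:
        return area_ha
    if scheme is WeightingScheme.YEARS_ONLY:
        return monitoring_years
    return 1.0


def category_weighted_rates(
    plots: Sequence[PermanentPlot],
    scheme: WeightingScheme = WeightingScheme.AREA_X_YEARS,
) -> list[WeightedRate]:
    """Plot-mean rates with weights for one category of permanent plots.

    If every plot in the category has identical area and monitoring
    period the weights collapse to 1.
    """
    if not plots:
        return []
    areas = {p.area_ha for p in plots}
    years = {p.monitoring_years for p in plots}
    uniform = len(areas) == 1 and len(years) == 1
    out = []
    for p in plots:
        w = 1.0 if uniform else plot_weight(p.area_ha, p.monitoring_years, scheme)
        out.append(
            WeightedRate(
                plot_id=p.plot_id,
                rate=plot_mean_rate(p.censuses),
                weight=w,
                status=p.status,
            )
        )
    return out


def _check_weights(rates: np.ndarray, weights: np.ndarray) -> None:
    if rates.shape != weights.shape:
        raise UsageError("rates and weights must have equal length")
    if np.any(weights < 0):
        raise ValidationError("weights must be nonnegative")
    if weights.sum() <= 0:
        raise ValidationError("weights must not all be zero")


def weighted_mean(rates: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted mean Σwᵢxᵢ / Σwᵢ."""
    x = np.asarray(rates, dtype=float)
    w = np.asarray(weights, dtype=float)
    _check_weights(x, w)
    return float(np.sum(w * x) / np.sum(w))


def weighted_sd(rates: Sequence[float], weights: Sequence[float]) -> float:
    """Frequency-style weighted standard deviation.

    sqrt( Σwᵢ(xᵢ − x̄_w)² / ((M−1)/M · Σwᵢ) ) with M the number of
    plots carrying nonzero weight; reduces to the ordinary sample SD
    under equal weights, and to 0 when only one plot has weight.
    """
    x = np.asarray(rates, dtype=float)
    w = np.asarray(weights, dtype=float)
    _check_weights(x, w)
    m = int(np.count_nonzero(w))
    if m <= 1:
        return 0.0
    xbar = np.sum(w * x) / np.sum(w)
    return float(np.sqrt(np.sum(w * (x - xbar) ** 2) / ((m - 1) / m * np.sum(w))))


def bootstrap_ci(
    rates: Sequence[float],
    weights: Sequence[float],
    reps: int = 1000,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the weighted mean, resampling plots.

    Plots (rate, weight) pairs are resampled jointly with replacement,
    ``reps`` times, at the original sample size; the interval is the
    ((1−level)/2, 1−(1−level)/2) percentile pair of the replicate
    weighted means.  Deterministic for a given seed.
    """
    x = np.asarray(rates, dtype=float)
    w = np.asarray(weights, dtype=float)
    _check_weights(x, w)
    n = x.size
    if n < 2:
        raise UsageError("bootstrap needs at least 2 plots")
    if reps < 1:
        raise UsageError("reps must be >= 1")
    if not 0 < level < 1:
        raise UsageError("level must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    xw = (x * w)[idx].sum(axis=1)
    ws = w[idx].sum(axis=1)
    # A replicate drawing only zero-weight plots falls back to its
    # unweighted mean (possible only when some weights are exactly 0).
    zero = ws == 0
    means = np.empty(reps)
    means[~zero] = xw[~zero] / ws[~zero]
    if zero.any():
        means[zero] = x[idx[zero]].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def weighted_rates_to_frame(
    plots: Sequence[PermanentPlot],
    scheme: WeightingScheme = WeightingScheme.AREA_X_YEARS,
) -> pd.DataFrame:
    """Plot-rate table: one row per permanent plot."""
    wrs = category_weighted_rates(plots, scheme)
    return pd.DataFrame(
        [
            {
                "plot_id": p.plot_id,
                "continent": p.continent.value,
                "ecozone": p.ecozone.value,
                "status": p.status.value,
                "rate": wr.rate,
                "weight": wr.weight,
                "n_censuses": len(p.censuses),
                "monitoring_years": p.monitoring_years,
            }
            for p, wr in zip(plots, wrs)
        ]
    )
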