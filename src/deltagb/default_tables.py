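"""Assembly of category-level default ΔAGB rates (the Tier 1 table).

Site- or plot-level rates are pooled per continent × ecozone × forest
type.  Secondary-forest categories (younger/older) get an unweighted
mean, median, sample SD and a z-based 95% CI; old-growth categories
get a weighted mean, weighted SD and a percentile-bootstrap CI.
Managed/logged plot rates, where present, are pooled into the
older-secondary category.  A category needs at least two sites or
plots; emptier cells are filled by a deterministic recommendation
ladder (donor continent → best-aligned of two donors → user-supplied
2006 Tier 1 fallback values, for which older-secondary and old-growth
collapse back into a single ">20 years" class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import Continent, Ecozone, ForestType, UsageError
from .permanent_plot_rates import (
    DEFAULT_BOOTSTRAP_SEED,
    WeightedRate,
    bootstrap_ci,
    weighted_mean,
    weighted_sd,
)

__all__ = [
    "CiMethod",
    "CellStatus",
    "CategoryEstimate",
    "GapFillError",
    "CellKey",
    "normal_ci",
    "estimate_secondary_category",
    "estimate_og_category",
    "pool_managed_into_os",
    "cell_universe",
    "fill_gaps",
    "render_table",
    "round_half_away",
]

#: Deterministic orderings used throughout rendering and tie-breaking.
CONTINENT_ORDER = (Continent.AFRICA, Continent.AMERICAS, Continent.ASIA)
FOREST_TYPE_ORDER = (
    ForestType.YOUNGER_SECONDARY,
    ForestType.OLDER_SECONDARY,
    ForestType.OLD_GROWTH,
)
ECOZONE_ORDER = tuple(Ecozone)

MIN_SITES_PER_CATEGORY = 2

CellKey = tuple[Ecozone, Continent, ForestType]


class CiMethod(str, Enum):
    ANALYTIC_Z = "analytic_z"
    BOOTSTRAP = "bootstrap"


class CellStatus(str, Enum):
    DERIVED = "derived"
    RECOMMENDED_FROM_DONOR = "recommended_from_donor"
    IPCC2006_FALLBACK = "ipcc2006_fallback"


class GapFillError(ValueError):
    """A fallback cell has no 2006 Tier 1 value configured."""


@dataclass(frozen=True)
class CategoryEstimate:
    """One row of the default-rate table."""

    continent: Continent
    ecozone: Ecozone
    forest_type: ForestType
    mean: float
    median: float | None
    sd: float | None
    ci_low: float | None
    ci_high: float | None
    n_sites: int
    ci_method: CiMethod | None
    status: CellStatus
    donor: Continent | None = None

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if self.ci_low > self.ci_high:
                raise ValueError("ci_low must not exceed ci_high")
        if self.status is CellStatus.DERIVED and self.n_sites < MIN_SITES_PER_CATEGORY:
            raise ValueError("derived categories need >= 2 sites")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of the table)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def normal_ci(
    mean: float, sd: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """z-based confidence interval mean ± z·sd/√n."""
    if n < 2:
        raise UsageError(f"normal_ci needs n >= 2, got {n}")
    if sd < 0:
        raise UsageError("sd must be nonnegative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * sd / math.sqrt(n)
    return mean - half, mean + half


def estimate_secondary_category(
    site_rates: Sequence[float],
    continent: Continent,
    ecozone: Ecozone,
    forest_type: ForestType,
    level: float = 0.95,
) -> CategoryEstimate | None:
    """Unweighted category statistics for secondary-forest rates.

    Returns ``None`` when fewer than two site rates are available; the
    cell then goes to the gap-filling ladder.
    """
    rates = np.asarray(site_rates, dtype=float)
    if rates.size < MIN_SITES_PER_CATEGORY:
        return None
    mean = float(rates.mean())
    sd = float(rates.std(ddof=1))
    lo, hi = normal_ci(mean, sd, rates.size, level)
    return CategoryEstimate(
        continent=continent,
        ecozone=ecozone,
        forest_type=forest_type,
        mean=mean,
        median=float(np.median(rates)),
        sd=sd,
        ci_low=lo,
        ci_high=hi,
        n_sites=int(rates.size),
        ci_method=CiMethod.ANALYTIC_Z,
        status=CellStatus.DERIVED,
    )


def estimate_og_category(
    weighted_rates: Sequence[WeightedRate],
    continent: Continent,
    ecozone: Ecozone,
    reps: int = 1000,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
    level: float = 0.95,
) -> CategoryEstimate | None:
    """Weighted category statistics for old-growth plot rates.

    Weighted mean and SD, unweighted median, percentile-bootstrap CI
    over plots.  Returns ``None`` below two plots.
    """
    if len(weighted_rates) < MIN_SITES_PER_CATEGORY:
        return None
    rates = [wr.rate for wr in weighted_rates]
    weights = [wr.weight for wr in weighted_rates]
    lo, hi = bootstrap_ci(rates, weights, reps=reps, seed=seed, level=level)
    return CategoryEstimate(
        continent=continent,
        ecozone=ecozone,
        forest_type=ForestType.OLD_GROWTH,
        mean=weighted_mean(rates, weights),
        median=float(np.median(rates)),
        sd=weighted_sd(rates, weights),
        ci_low=lo,
        ci_high=hi,
        n_sites=len(weighted_rates),
        ci_method=CiMethod.BOOTSTRAP,
        status=CellStatus.DERIVED,
    )


def pool_managed_into_os(
    os_site_rates: Sequence[float],
    managed_plot_rates: Sequence[float],
) -> list[float]:
    """Pool managed/logged plot-mean rates into the older-secondary set.

    Each managed plot contributes its plot-mean rate as one additional
    (unweighted) site-level observation.
    """
    return list(os_site_rates) + list(managed_plot_rates)


def cell_universe(
    ecozones: Iterable[Ecozone],
    continents: Iterable[Continent] = CONTINENT_ORDER,
    masked: Iterable[tuple[Ecozone, Continent]] = (),
) -> list[CellKey]:
    """All continent × ecozone × forest-type cells the table must cover.

    ``masked`` pairs (ecozone absent from a continent) are omitted.
    """
    masked = set(masked)
    cells = []
    for ez in sorted(set(ecozones), key=ECOZONE_ORDER.index):
        for co in sorted(set(continents), key=CONTINENT_ORDER.index):
            if (ez, co) in masked:
                continue
            for ft in FOREST_TYPE_ORDER:
                cells.append((ez, co, ft))
    return cells


def _donor_alignment(
    donor: CategoryEstimate,
    target_other_means: Sequence[float],
) -> float:
    if not target_other_means:
        return math.inf  # no basis for alignment: fall to the tie-breaks
    return float(np.mean([abs(donor.mean - m) for m in target_other_means]))


def _ipcc2006_value(
    ipcc2006: Mapping, continent: Continent, ecozone: Ecozone, forest_type: ForestType
) -> float:
    # Older-secondary and old-growth share the 2006 ">20 years" class.
    cls = "secondary_le20" if forest_type is ForestType.YOUNGER_SECONDARY else "gt20"
    try:
        return float(ipcc2006[continent.value][ecozone.value][cls])
    except (KeyError, TypeError):
        raise GapFillError(
            "no 2006 Tier 1 fallback value configured for cell "
            f"({ecozone.value}, {continent.value}, {forest_type.value}; class {cls!r})"
        ) from None


def fill_gaps(
    table: Mapping[CellKey, CategoryEstimate | None],
    ipcc2006: Mapping | None = None,
    cells: Sequence[CellKey] | None = None,
) -> dict[CellKey, CategoryEstimate]:
    """Fill empty cells by the recommendation ladder.

    1. one donor continent has a derived value for the same ecozone ×
       forest type → copy it (status ``recommended_from_donor``);
    2. two donors → take the donor whose mean is closest (mean absolute
       difference) to the derived means of the other forest types in
       the target's own continent × ecozone; ties go to the donor with
       more sites, then to the fixed continent order;
    3. no donor on any continent → the user-supplied 2006 Tier 1 value
       (status ``ipcc2006_fallback``); a missing config entry for such
       a cell is a hard error.

    Derived cells are never overwritten; the operation is idempotent.
    """
    if cells is None:
        cells = list(table.keys())
    out: dict[CellKey, CategoryEstimate] = {
        k: v for k, v in table.items() if v is not None
    }
    for key in cells:
        if out.get(key) is not None:
            continue
        ez, co, ft = key
        donors = [
            out[(ez, donor_co, ft)]
            for donor_co in CONTINENT_ORDER
            if donor_co != co
            and out.get((ez, donor_co, ft)) is not None
            and out[(ez, donor_co, ft)].status is CellStatus.DERIVED
        ]
        if donors:
            if len(donors) == 1:
                chosen = donors[0]
            else:
                other_means = [
                    out[(ez, co, other_ft)].mean
                    for other_ft in FOREST_TYPE_ORDER
                    if other_ft != ft
                    and out.get((ez, co, other_ft)) is not None
                    and out[(ez, co, other_ft)].status is CellStatus.DERIVED
                ]
                chosen = min(
                    donors,
                    key=lambda d: (
                        _donor_alignment(d, other_means),
                        -d.n_sites,
                        CONTINENT_ORDER.index(d.continent),
                    ),
                )
            out[key] = replace(
                chosen,
                continent=co,
                ecozone=ez,
                forest_type=ft,
                status=CellStatus.RECOMMENDED_FROM_DONOR,
                donor=chosen.continent,
            )
        else:
            value = _ipcc2006_value(ipcc2006 or {}, co, ez, ft)
            out[key] = CategoryEstimate(
                continent=co,
                ecozone=ez,
                forest_type=ft,
                mean=value,
                median=None,
                sd=None,
                ci_low=None,
                ci_high=None,
                n_sites=0,
                ci_method=None,
                status=CellStatus.IPCC2006_FALLBACK,
            )
    return out


_FT_LABEL = {
    ForestType.YOUNGER_SECONDARY: "YS",
    ForestType.OLDER_SECONDARY: "OS",
    ForestType.OLD_GROWTH: "OG",
}


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return f"{round_half_away(x) + 0.0:.1f}"  # + 0.0 normalises -0.0


def render_table(
    table: Mapping[CellKey, CategoryEstimate],
) -> tuple[pd.DataFrame, str]:
    """Render the default-rate table.

    Returns a DataFrame (full precision) and a fixed-width text
    rendering with all rates rounded half-away-from-zero to one
    decimal.  Rows are ordered ecozone, then continent, then forest
    type (YS, OS, OG).
    """
    keys = sorted(
        table.keys(),
        key=lambda k: (
            ECOZONE_ORDER.index(k[0]),
            CONTINENT_ORDER.index(k[1]),
            FOREST_TYPE_ORDER.index(k[2]),
        ),
    )
    rows = []
    for key in keys:
        est = table[key]
        rows.append(
            {
                "ecozone": est.ecozone.value,
                "continent": est.continent.value,
                "forest_type": _FT_LABEL[est.forest_type],
                "mean": est.mean,
                "median": est.median,
                "sd": est.sd,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n": est.n_sites,
                "ci_method": est.ci_method.value if est.ci_method else "",
                "status": est.status.value,
                "donor": est.donor.value if est.donor else "",
            }
        )
    df = pd.DataFrame(rows)
    display = df.copy()
    for col in ("mean", "median", "sd", "ci_low", "ci_high"):
        display[col] = [_fmt(v) for v in df[col]]
    text = display.to_string(index=False)
    return df, text
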