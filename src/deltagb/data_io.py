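"""Reading, validation and classification of plot-level forest data.

Two kinds of input table are supported:

* chronosequence plots — static AGB observations of secondary-forest
  stands of known age, one row per plot;
* permanent plots — repeated-census net biomass change (``ΔAGB``) rates
  of old-growth or managed/logged stands, one row per census interval.

Besides parsing, this module applies the compilation rules of the
Tier 1 default-rate derivation: conversion of carbon values to dry
biomass, the younger/older-secondary age cut-offs, the exclusion
filters (continental United States, stands older than 100 years) and
the grouping of proximate chronosequence sites in Africa and Asia.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "Continent",
    "Ecozone",
    "ForestType",
    "PlotStatus",
    "Intervention",
    "PlotRecord",
    "Chronosequence",
    "CensusRate",
    "PermanentPlot",
    "FilterReport",
    "ValidationError",
    "ClassificationError",
    "UsageError",
    "IPCC_CARBON_FRACTION",
    "PROXIMITY_THRESHOLD_DEG",
    "convert_to_agb",
    "classify_forest_type",
    "apply_inclusion_filters",
    "group_proximate_sites",
    "read_chronosequence_csv",
    "read_permanent_plot_csv",
]

#: IPCC default carbon fraction of aboveground dry biomass.
IPCC_CARBON_FRACTION = 0.47

#: Grouping radius (decimal degrees) for proximate chronosequence sites.
#: Sites closer than this, in the same ecozone, are pooled into a single
#: chronosequence.  The Americas have no grouping rule; there, only
#: chronosequences with at least three plots are retained.
PROXIMITY_THRESHOLD_DEG: Mapping[str, float] = {"Africa": 1.5, "Asia": 4.0}

#: Secondary stands at or below this age count as younger secondary.
YOUNGER_SECONDARY_MAX_AGE = 20.0
#: Secondary stands above this age are out of scope (treated as mature).
SECONDARY_MAX_AGE = 100.0
#: Years without recorded anthropogenic disturbance that qualify a
#: stand as old-growth.
OLD_GROWTH_MIN_YEARS = 100.0


class ValidationError(ValueError):
    """An input record violates a field-level constraint."""


class ClassificationError(ValueError):
    """Forest-type metadata are contradictory or insufficient."""


class UsageError(ValueError):
    """An operation was called outside its contract (caller bug)."""


class Continent(str, Enum):
    AFRICA = "Africa"
    AMERICAS = "NorthSouthAmerica"
    ASIA = "Asia"


class Ecozone(str, Enum):
    """FAO global ecological zones in the tropical/subtropical domain."""

    TROPICAL_RAINFOREST = "tropical_rainforest"
    TROPICAL_MOIST_FOREST = "tropical_moist_forest"
    TROPICAL_DRY_FOREST = "tropical_dry_forest"
    TROPICAL_SHRUBLAND = "tropical_shrubland"
    TROPICAL_MOUNTAIN_SYSTEM = "tropical_mountain_system"
    SUBTROPICAL_HUMID_FOREST = "subtropical_humid_forest"
    SUBTROPICAL_DRY_FOREST = "subtropical_dry_forest"
    SUBTROPICAL_STEPPE = "subtropical_steppe"
    SUBTROPICAL_MOUNTAIN_SYSTEM = "subtropical_mountain_system"


class ForestType(str, Enum):
    YOUNGER_SECONDARY = "younger_secondary"
    OLDER_SECONDARY = "older_secondary"
    OLD_GROWTH = "old_growth"
    MANAGED_LOGGED = "managed_logged"


class PlotStatus(str, Enum):
    OLD_GROWTH = "old_growth"
    MANAGED_LOGGED = "managed_logged"


class Intervention(str, Enum):
    NONE = "none"
    PARTIAL_DISTURBANCE = "partial_disturbance"


@dataclass(frozen=True)
class PlotRecord:
    """One chronosequence observation: AGB of a stand of known age.

    ``abg_value`` is aboveground dry biomass in Mg/ha after any carbon
    conversion has been applied (see :func:`convert_to_agb`).
    """

    record_id: str
    site_id: str
    continent: Continent
    ecozone: Ecozone
    latitude: float
    longitude: float
    stand_age: float
    abg_value: float
    in_continental_us: bool = False

    def __post_init__(self) -> None:
        if not self.stand_age > 0:
            raise ValidationError(
                f"record {self.record_id!r}: stand_age must be > 0, got {self.stand_age}"
            )
        if not self.abg_value >= 0 or math.isnan(self.abg_value):
            raise ValidationError(
                f"record {self.record_id!r}: AGB must be >= 0, got {self.abg_value}"
            )
        if abs(self.latitude) > 90:
            raise ValidationError(f"record {self.record_id!r}: |latitude| > 90")
        if abs(self.longitude) > 180:
            raise ValidationError(f"record {self.record_id!r}: |longitude| > 180")


@dataclass(frozen=True)
class Chronosequence:
    """A (possibly grouped) site with its AGB–stand age observations."""

    chrono_id: str
    continent: Continent
    ecozone: Ecozone
    plots: tuple[PlotRecord, ...]
    member_site_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.plots:
            raise ValidationError(f"chronosequence {self.chrono_id!r} has no plots")
        for p in self.plots:
            if p.continent != self.continent or p.ecozone != self.ecozone:
                raise ValidationError(
                    f"chronosequence {self.chrono_id!r}: plot {p.record_id!r} "
                    "does not share the chronosequence continent/ecozone"
                )
            if p.stand_age > SECONDARY_MAX_AGE:
                raise ValidationError(
                    f"chronosequence {self.chrono_id!r}: plot {p.record_id!r} "
                    f"older than {SECONDARY_MAX_AGE:.0f} years"
                )
        if self.continent is Continent.AMERICAS and len(self.plots) < 3:
            raise ValidationError(
                f"chronosequence {self.chrono_id!r}: American chronosequences "
                "require >= 3 plots"
            )

    @property
    def ages(self) -> tuple[float, ...]:
        return tuple(p.stand_age for p in self.plots)

    @property
    def min_age(self) -> float:
        return min(self.ages)

    @property
    def max_age(self) -> float:
        return max(self.ages)

    def n_distinct_ages(self) -> int:
        return len({p.stand_age for p in self.plots})


@dataclass(frozen=True)
class CensusRate:
    """ΔAGB over one census interval of a permanent plot."""

    interval_years: float
    rate: float  # Mg ha⁻¹ yr⁻¹, may be negative

    def __post_init__(self) -> None:
        if not self.interval_years > 0:
            raise ValidationError(
                f"census interval must be > 0 years, got {self.interval_years}"
            )


@dataclass(frozen=True)
class PermanentPlot:
    """A repeatedly censused plot in old-growth or managed/logged forest."""

    plot_id: str
    continent: Continent
    ecozone: Ecozone
    status: PlotStatus
    area_ha: float
    censuses: tuple[CensusRate, ...]
    monitoring_years: float

    def __post_init__(self) -> None:
        if not self.area_ha > 0:
            raise ValidationError(
                f"plot {self.plot_id!r}: area must be > 0 ha, got {self.area_ha}"
            )
        if not self.censuses:
            raise ValidationError(f"plot {self.plot_id!r}: no census intervals")
        if not self.monitoring_years > 0:
            raise ValidationError(
                f"plot {self.plot_id!r}: monitoring_years must be > 0"
            )


def convert_to_agb(
    value: float,
    is_carbon: bool,
    cf: float | None = None,
    record_id: str = "<unknown>",
) -> float:
    """Convert a biomass or carbon quantity to aboveground dry biomass.

    Carbon values are divided by the carbon fraction cited in the
    original source when available, otherwise by the IPCC default of
    0.47.  Biomass values pass through unchanged.

    Parameters
    ----------
    value : float
        Quantity in Mg/ha (stocks) or Mg ha⁻¹ yr⁻¹ (rates).
    is_carbon : bool
        Whether ``value`` is expressed as carbon.
    cf : float, optional
        Source-specific carbon fraction, in (0, 1].
    record_id : str
        Used only in error messages.
    """
    if value < 0 or math.isnan(value):
        raise ValidationError(f"record {record_id!r}: value must be >= 0, got {value}")
    if not is_carbon:
        return value
    if cf is None:
        cf = IPCC_CARBON_FRACTION
    if not (0 < cf <= 1):
        raise ValidationError(
            f"record {record_id!r}: carbon fraction must be in (0, 1], got {cf}"
        )
    return value / cf


def classify_forest_type(
    stand_age: float | None = None,
    last_disturbance: float | None = None,
    intervention: Intervention | None = None,
) -> ForestType:
    """Assign a stand to one of the four forest types.

    Rules, in order of precedence:

    1. a partial-disturbance intervention (selective logging,
       silviculture) makes the stand managed/logged — unless the stand
       is simultaneously documented as undisturbed for >= 100 years,
       which is contradictory;
    2. no recorded anthropogenic disturbance for >= 100 years makes it
       old-growth;
    3. stand age (or, failing that, time since last disturbance)
       <= 20 years is younger secondary, (20, 100] years is older
       secondary, and > 100 years is treated as old-growth.
    """
    if stand_age is None and last_disturbance is None and intervention is None:
        raise ClassificationError("no stand metadata provided")
    partial = intervention is Intervention.PARTIAL_DISTURBANCE
    undisturbed = last_disturbance is not None and last_disturbance >= OLD_GROWTH_MIN_YEARS
    if partial and undisturbed:
        raise ClassificationError(
            "contradictory metadata: partial disturbance recorded for a stand "
            f"undisturbed for {last_disturbance} years"
        )
    if partial:
        return ForestType.MANAGED_LOGGED
    if undisturbed:
        return ForestType.OLD_GROWTH
    age = stand_age if stand_age is not None else last_disturbance
    if age is None:
        raise ClassificationError(
            "intervention 'none' alone does not determine a forest type"
        )
    if age <= 0:
        raise ClassificationError(f"stand age must be positive, got {age}")
    if age <= YOUNGER_SECONDARY_MAX_AGE:
        return ForestType.YOUNGER_SECONDARY
    if age <= SECONDARY_MAX_AGE:
        return ForestType.OLDER_SECONDARY
    return ForestType.OLD_GROWTH


@dataclass
class FilterReport:
    """Counts of records dropped per inclusion rule."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, rule: str, n: int = 1) -> None:
        self.counts[rule] = self.counts.get(rule, 0) + n

    @property
    def total_dropped(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict[str, int]:
        return dict(sorted(self.counts.items()))


def apply_inclusion_filters(
    records: Sequence[PlotRecord],
) -> tuple[list[PlotRecord], FilterReport]:
    """Apply the compilation exclusion rules to chronosequence records.

    Drops records from sites in the continental United States and
    secondary stands older than 100 years.  Returns the retained
    records together with a report of counts dropped per rule; an
    empty result is legal.
    """
    report = FilterReport(counts={"continental_us": 0, "age_over_100": 0})
    kept: list[PlotRecord] = []
    for rec in records:
        if rec.in_continental_us:
            report.add("continental_us")
        elif rec.stand_age > SECONDARY_MAX_AGE:
            report.add("age_over_100")
        else:
            kept.append(rec)
    return kept, report


def _site_coordinate(records: Sequence[PlotRecord]) -> tuple[float, float]:
    lat = sum(r.latitude for r in records) / len(records)
    lon = sum(r.longitude for r in records) / len(records)
    return lat, lon


def _degree_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    # Euclidean distance on (lat, lon) in decimal degrees; the grouping
    # radius is itself quoted in degrees.
    return math.hypot(a[0] - b[0], a[1] - b[1])


def _great_circle_degrees(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Central angle between two points, in degrees."""
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    h = (
        math.sin((lat2 - lat1) / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
    )
    return math.degrees(2 * math.asin(min(1.0, math.sqrt(h))))


_METRICS = {"euclidean_degrees": _degree_distance, "great_circle": _great_circle_degrees}


def group_proximate_sites(
    records: Sequence[PlotRecord],
    continent: Continent,
    thresholds: Mapping[str, float] | None = None,
    metric: str = "euclidean_degrees",
    min_plots_americas: int = 3,
    min_distinct_ages: int = 2,
) -> tuple[list[Chronosequence], FilterReport]:
    """Build chronosequences from plot records of one continent.

    In Africa and Asia, sites in the same ecozone whose coordinates lie
    within the continental radius are pooled into a single
    chronosequence.  Pooling is by single linkage: any chain of
    below-threshold pairs merges, i.e. the connected components of the
    proximity graph.  Grouped chronosequences still need at least
    ``min_distinct_ages`` distinct stand ages to support a growth
    curve.  In the Americas no pooling is done and chronosequences with
    fewer than ``min_plots_americas`` plots are excluded.

    Returns the chronosequences (deterministically ordered by id) and
    a report of sites/chronosequences dropped by the size rules.
    """
    if thresholds is None:
        thresholds = PROXIMITY_THRESHOLD_DEG
    try:
        dist = _METRICS[metric]
    except KeyError:
        raise UsageError(f"unknown distance metric {metric!r}") from None
    for rec in records:
        if rec.continent != continent:
            raise UsageError(
                f"record {rec.record_id!r} is on {rec.continent.value}, "
                f"not {continent.value}: group one continent at a time"
            )

    report = FilterReport()
    by_site: dict[tuple[Ecozone, str], list[PlotRecord]] = {}
    for rec in records:
        by_site.setdefault((rec.ecozone, rec.site_id), []).append(rec)

    chronos: list[Chronosequence] = []
    if continent is Continent.AMERICAS:
        for (ecozone, site_id), recs in sorted(by_site.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
            if len(recs) < min_plots_americas:
                report.add("americas_fewer_than_3_plots")
                continue
            chronos.append(
                Chronosequence(
                    chrono_id=site_id,
                    continent=continent,
                    ecozone=ecozone,
                    plots=tuple(sorted(recs, key=lambda r: (r.stand_age, r.record_id))),
                    member_site_ids=frozenset({site_id}),
                )
            )
        return chronos, report

    radius = thresholds[continent.value]
    by_ecozone: dict[Ecozone, list[str]] = {}
    for ecozone, site_id in by_site:
        by_ecozone.setdefault(ecozone, []).append(site_id)

    for ecozone in sorted(by_ecozone, key=lambda e: e.value):
        site_ids = sorted(by_ecozone[ecozone])
        coords = {
            s: _site_coordinate(by_site[(ecozone, s)]) for s in site_ids
        }
        graph = nx.Graph()
        graph.add_nodes_from(site_ids)
        for i, a in enumerate(site_ids):
            for b in site_ids[i + 1 :]:
                if dist(coords[a], coords[b]) < radius:
                    graph.add_edge(a, b)
        for component in nx.connected_components(graph):
            members = sorted(component)
            recs = [r for s in members for r in by_site[(ecozone, s)]]
            if len({r.stand_age for r in recs}) < min_distinct_ages:
                report.add("fewer_than_2_distinct_ages")
                continue
            chronos.append(
                Chronosequence(
                    chrono_id="+".join(members),
                    continent=continent,
                    ecozone=ecozone,
                    plots=tuple(sorted(recs, key=lambda r: (r.stand_age, r.record_id))),
                    member_site_ids=frozenset(members),
                )
            )
    chronos.sort(key=lambda c: (c.ecozone.value, c.chrono_id))
    return chronos, report


_CHRONO_COLUMNS = {
    "record_id",
    "site_id",
    "continent",
    "ecozone",
    "lat",
    "lon",
    "stand_age",
    "value",
    "value_type",
    "carbon_fraction",
    "in_continental_us",
}
_PLOT_COLUMNS = {
    "plot_id",
    "continent",
    "ecozone",
    "status",
    "area_ha",
    "interval_years",
    "rate",
    "value_type",
    "carbon_fraction",
}


def _warn_unknown_columns(df: pd.DataFrame, known: set[str], what: str) -> None:
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"ignoring unknown {what} columns: {unknown}", stacklevel=3)


def _opt_float(x) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return None
    return float(x)


def read_chronosequence_csv(path) -> list[PlotRecord]:
    """Read a chronosequence plot table.

    Expected columns: ``record_id,site_id,continent,ecozone,lat,lon,
    stand_age,value,value_type{agb|carbon},carbon_fraction,
    in_continental_us``.  Carbon values are converted to AGB on read.
    Unknown columns are ignored with a warning.
    """
    df = pd.read_csv(path)
    _warn_unknown_columns(df, _CHRONO_COLUMNS, "chronosequence")
    missing = {"record_id", "site_id", "continent", "ecozone", "lat", "lon", "stand_age", "value", "value_type"} - set(df.columns)
    if missing:
        raise ValidationError(f"chronosequence CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        value_type = str(row.value_type).strip().lower()
        if value_type not in {"agb", "carbon"}:
            raise ValidationError(
                f"record {row.record_id!r}: value_type must be 'agb' or 'carbon'"
            )
        cf = _opt_float(getattr(row, "carbon_fraction", None))
        agb = convert_to_agb(
            float(row.value), value_type == "carbon", cf, record_id=str(row.record_id)
        )
        in_us = bool(getattr(row, "in_continental_us", False))
        records.append(
            PlotRecord(
                record_id=str(row.record_id),
                site_id=str(row.site_id),
                continent=Continent(row.continent),
                ecozone=Ecozone(row.ecozone),
                latitude=float(row.lat),
                longitude=float(row.lon),
                stand_age=float(row.stand_age),
                abg_value=agb,
                in_continental_us=in_us,
            )
        )
    return records


def read_permanent_plot_csv(path) -> list[PermanentPlot]:
    """Read a permanent-plot table (one row per census interval).

    Expected columns: ``plot_id,continent,ecozone,status{old_growth|
    managed_logged},area_ha,interval_years,rate,value_type,
    carbon_fraction``.  ΔC rates are converted to ΔAGB on read.  The
    plot's monitoring period is the sum of its census intervals.
    """
    df = pd.read_csv(path)
    _warn_unknown_columns(df, _PLOT_COLUMNS, "permanent-plot")
    missing = {"plot_id", "continent", "ecozone", "status", "area_ha", "interval_years", "rate", "value_type"} - set(df.columns)
    if missing:
        raise ValidationError(f"permanent-plot CSV missing columns: {sorted(missing)}")
    plots: list[PermanentPlot] = []
    for plot_id, group in df.groupby("plot_id", sort=True):
        first = group.iloc[0]
        censuses = []
        for row in group.itertuples(index=False):
            value_type = str(row.value_type).strip().lower()
            rate = float(row.rate)
            if value_type == "carbon":
                cf = _opt_float(getattr(row, "carbon_fraction", None))
                if cf is None:
                    cf = IPCC_CARBON_FRACTION
                if not (0 < cf <= 1):
                    raise ValidationError(
                        f"plot {plot_id!r}: carbon fraction must be in (0, 1], got {cf}"
                    )
                rate = rate / cf
            elif value_type != "agb":
                raise ValidationError(
                    f"plot {plot_id!r}: value_type must be 'agb' or 'carbon'"
                )
            censuses.append(CensusRate(interval_years=float(row.interval_years), rate=rate))
        plots.append(
            PermanentPlot(
                plot_id=str(plot_id),
                continent=Continent(first["continent"]),
                ecozone=Ecozone(first["ecozone"]),
                status=PlotStatus(first["status"]),
                area_ha=float(first["area_ha"]),
                censuses=tuple(censuses),
                monitoring_years=float(sum(c.interval_years for c in censuses)),
            )
        )
    return plots
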