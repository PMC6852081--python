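"""Synthetic chronosequence and permanent-plot data with known truth.

The real plot networks behind tropical forest-carbon syntheses are not
redistributable, so every stage of the pipeline is exercised on
generated data whose ground truth is known exactly.

Chronosequences are drawn from the same generative model the analysis
fits: site intercept/slope pairs from a bivariate normal around the
stratum fixed effects, AGB linear in ln(stand age) plus Gaussian
residual noise, floored at zero (biomass cannot be negative; the floor
count is reported so tests can detect distortion).  Permanent plots
draw a true plot rate around a category mean, census rates around the
plot truth, and heterogeneous plot areas and monitoring lengths.

Every generator is deterministic given its seed, and returns a truth
ledger holding the analytic site-level rates implied by the noiseless
curves, against which the fitting pipeline can be checked.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .data_io import (
    CensusRate,
    Continent,
    Ecozone,
    PermanentPlot,
    PlotRecord,
    PlotStatus,
    ValidationError,
)

__all__ = [
    "ChronoSimParams",
    "PlotSimParams",
    "ChronoTruth",
    "simulate_chronosequences",
    "simulate_permanent_plots",
    "StudyFixture",
    "make_study_fixture",
    "write_study_fixture",
]

YS_ANCHOR_AGE = 20.0


@dataclass(frozen=True)
class ChronoSimParams:
    """Generative settings for one stratum of chronosequences.

    Defaults describe a data-rich tropical-rainforest-like stratum:
    AGB reaching ~115 Mg/ha at 20 years, moderate between-site spread
    and ~10 Mg/ha residual scatter around each site's curve.
    """

    n_sites: int = 30
    plots_per_site: int | tuple[int, int] = 8
    age_range: tuple[float, float] = (2.0, 80.0)
    beta0: float = 10.0  # Mg/ha at age 1 yr (ln age = 0)
    beta1: float = 35.0  # Mg/ha per unit ln(years)
    sd_b0: float = 10.0
    sd_b1: float = 5.0
    corr_b0b1: float = 0.0
    sd_resid: float = 10.0
    continent: Continent = Continent.AMERICAS
    ecozone: Ecozone = Ecozone.TROPICAL_RAINFOREST
    seed: int = 0
    age_sampling: str = "uniform"  # or "log_uniform" (skew toward young stands)
    site_spacing_deg: float = 6.0
    site_prefix: str = "site"

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")
        if min(self.sd_b0, self.sd_b1, self.sd_resid) < 0:
            raise ValidationError("standard deviations must be >= 0")
        if abs(self.corr_b0b1) > 1:
            raise ValidationError("|corr_b0b1| must be <= 1")
        lo, hi = self.age_range
        if not (0 < lo <= hi <= 100):
            raise ValidationError("age_range must satisfy 0 < min <= max <= 100")
        if self.age_sampling not in ("uniform", "log_uniform"):
            raise ValidationError(f"unknown age_sampling {self.age_sampling!r}")


@dataclass(frozen=True)
class PlotSimParams:
    """Generative settings for one category of permanent plots.

    Defaults emulate an old-growth category: a small positive mean net
    change with plot-to-plot spread comparable to published old-growth
    SDs (~2 Mg ha⁻¹ yr⁻¹) and noisier individual census intervals.
    Negative category means are allowed (declining stands).
    """

    n_plots: int = 30
    mu_rate: float = 1.0
    sd_plot: float = 2.0
    sd_census: float = 1.5
    censuses_per_plot: int | tuple[int, int] = (1, 5)
    area_range: tuple[float, float] = (0.25, 4.0)
    years_range: tuple[float, float] = (5.0, 30.0)
    status: PlotStatus = PlotStatus.OLD_GROWTH
    continent: Continent = Continent.AMERICAS
    ecozone: Ecozone = Ecozone.TROPICAL_RAINFOREST
    seed: int = 0
    plot_prefix: str = "plot"

    def __post_init__(self) -> None:
        if self.n_plots < 1:
            raise ValidationError("n_plots must be >= 1")
        if min(self.sd_plot, self.sd_census) < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.area_range[0] <= 0 or self.years_range[0] <= 0:
            raise ValidationError("area and monitoring ranges must be positive")
        if self.area_range[0] > self.area_range[1] or self.years_range[0] > self.years_range[1]:
            raise ValidationError("ranges must be (min, max) with min <= max")


@dataclass
class ChronoTruth:
    """Ground truth of a simulated chronosequence stratum."""

    params: dict[str, Any]
    sites: dict[str, dict[str, float]]  # per-site coefficients and rates
    n_floored: int


def _count(spec: int | tuple[int, int], rng: np.random.Generator) -> int:
    if isinstance(spec, tuple):
        lo, hi = spec
        return int(rng.integers(lo, hi + 1))
    return int(spec)


def _site_coords(i: int, spacing: float) -> tuple[float, float]:
    # Synthetic grid points, spaced beyond any grouping radius so that
    # simulated sites stay distinct chronosequences by default.
    per_row = max(1, int(340 // spacing))
    lat = -20.0 + spacing * (i // per_row)
    lon = -170.0 + spacing * (i % per_row)
    return lat, lon


def simulate_chronosequences(
    params: ChronoSimParams,
) -> tuple[list[PlotRecord], ChronoTruth]:
    """Draw one stratum of chronosequence plot records.

    The truth ledger records, per site, the realised intercept and
    slope and the analytic younger-secondary rate
    ``(β0+b0 + (β1+b1)·ln 20)/20`` together with the older-secondary
    chord between the site's realised age anchors.
    """
    rng = np.random.default_rng(params.seed)
    cov = np.array(
        [
            [params.sd_b0**2, params.corr_b0b1 * params.sd_b0 * params.sd_b1],
            [params.corr_b0b1 * params.sd_b0 * params.sd_b1, params.sd_b1**2],
        ]
    )
    deviations = rng.multivariate_normal(
        np.zeros(2), cov, size=params.n_sites, check_valid="ignore", method="svd"
    )
    records: list[PlotRecord] = []
    sites: dict[str, dict[str, float]] = {}
    n_floored = 0
    lo, hi = params.age_range
    for i in range(params.n_sites):
        site_id = f"{params.site_prefix}{i:03d}"
        b0, b1 = float(deviations[i, 0]), float(deviations[i, 1])
        a0, a1 = params.beta0 + b0, params.beta1 + b1
        n_plots = _count(params.plots_per_site, rng)
        if params.age_sampling == "log_uniform":
            ages = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_plots))
        else:
            ages = rng.uniform(lo, hi, size=n_plots)
        noise = rng.normal(0.0, params.sd_resid, size=n_plots) if params.sd_resid > 0 else np.zeros(n_plots)
        agb = a0 + a1 * np.log(ages) + noise
        floored = agb < 0
        n_floored += int(floored.sum())
        agb = np.where(floored, 0.0, agb)
        lat, lon = _site_coords(i, params.site_spacing_deg)
        for j in range(n_plots):
            records.append(
                PlotRecord(
                    record_id=f"{site_id}_p{j:02d}",
                    site_id=site_id,
                    continent=params.continent,
                    ecozone=params.ecozone,
                    latitude=lat,
                    longitude=lon,
                    stand_age=float(ages[j]),
                    abg_value=float(agb[j]),
                )
            )
        min_age, max_age = float(ages.min()), float(ages.max())
        anchor_low = YS_ANCHOR_AGE if min_age <= YS_ANCHOR_AGE else min_age
        entry = {
            "b0": b0,
            "b1": b1,
            "intercept": a0,
            "slope": a1,
            "ys_rate": (a0 + a1 * np.log(YS_ANCHOR_AGE)) / YS_ANCHOR_AGE,
            "min_age": min_age,
            "max_age": max_age,
        }
        if max_age > anchor_low:
            entry["os_anchor_low"] = anchor_low
            entry["os_rate"] = (
                a1 * (np.log(max_age) - np.log(anchor_low)) / (max_age - anchor_low)
            )
        sites[site_id] = {k: float(v) for k, v in entry.items()}
    truth = ChronoTruth(
        params={
            **{k: (v.value if hasattr(v, "value") else v) for k, v in asdict(params).items()}
        },
        sites=sites,
        n_floored=n_floored,
    )
    return records, truth


def simulate_permanent_plots(
    params: PlotSimParams,
) -> tuple[list[PermanentPlot], dict[str, Any]]:
    """Draw one category of permanent plots with census-level noise."""
    rng = np.random.default_rng(params.seed)
    plots: list[PermanentPlot] = []
    truths: dict[str, float] = {}
    for i in range(params.n_plots):
        plot_id = f"{params.plot_prefix}{i:03d}"
        true_rate = float(rng.normal(params.mu_rate, params.sd_plot)) if params.sd_plot > 0 else params.mu_rate
        k = _count(params.censuses_per_plot, rng)
        monitoring = float(rng.uniform(*params.years_range))
        interval = monitoring / k
        if params.sd_census > 0:
            census_rates = rng.normal(true_rate, params.sd_census, size=k)
        else:
            census_rates = np.full(k, true_rate)
        area = float(rng.uniform(*params.area_range))
        plots.append(
            PermanentPlot(
                plot_id=plot_id,
                continent=params.continent,
                ecozone=params.ecozone,
                status=params.status,
                area_ha=area,
                censuses=tuple(
                    CensusRate(interval_years=interval, rate=float(r))
                    for r in census_rates
                ),
                monitoring_years=monitoring,
            )
        )
        truths[plot_id] = true_rate
    ledger = {
        "params": {
            **{k: (v.value if hasattr(v, "value") else v) for k, v in asdict(params).items()}
        },
        "mu_rate": params.mu_rate,
        "plots": truths,
    }
    return plots, ledger


# --------------------------------------------------------------------------
# End-to-end study fixture


@dataclass
class StudyFixture:
    """A complete two-file synthetic study with its truth ledger.

    ``chrono_frame`` and ``plots_frame`` follow the CSV schemas that
    :mod:`deltagb.data_io` reads; ``ipcc2006`` is the fallback config
    for cells no continent can inform; ``truth`` documents generator
    parameters and the gap cells the fixture creates on purpose.
    """

    chrono_frame: pd.DataFrame
    plots_frame: pd.DataFrame
    ipcc2006: dict
    ecozones: list[Ecozone]
    truth: dict = field(default_factory=dict)


def _chrono_rows(records: list[PlotRecord], value_type: str = "agb") -> list[dict]:
    rows = []
    for r in records:
        value = r.abg_value if value_type == "agb" else r.abg_value * 0.47
        rows.append(
            {
                "record_id": r.record_id,
                "site_id": r.site_id,
                "continent": r.continent.value,
                "ecozone": r.ecozone.value,
                "lat": r.latitude,
                "lon": r.longitude,
                "stand_age": r.stand_age,
                "value": value,
                "value_type": value_type,
                "carbon_fraction": "",
                "in_continental_us": False,
            }
        )
    return rows


def _plot_rows(plots: list[PermanentPlot]) -> list[dict]:
    return [
        {
            "plot_id": p.plot_id,
            "continent": p.continent.value,
            "ecozone": p.ecozone.value,
            "status": p.status.value,
            "area_ha": p.area_ha,
            "interval_years": c.interval_years,
            "rate": c.rate,
            "value_type": "agb",
            "carbon_fraction": "",
        }
        for p in plots
        for c in p.censuses
    ]


#: Fallback Tier 1 values supplied with the fixture, one pair per
#: continent × ecozone (younger-secondary class and the single
#: ">20 years" class).  These are configuration inputs, not estimates.
_FIXTURE_IPCC2006 = {
    co: {
        ez: {"secondary_le20": le20, "gt20": gt20}
        for ez, le20, gt20 in (
            ("tropical_rainforest", 7.0, 2.0),
            ("tropical_moist_forest", 4.0, 1.5),
            ("tropical_dry_forest", 2.4, 1.8),
        )
    }
    for co in ("Africa", "NorthSouthAmerica", "Asia")
}


def make_study_fixture(seed: int = 0) -> StudyFixture:
    """Generate a small end-to-end study across three continents.

    Composition (tropical rainforest, moist forest and dry forest):

    * rainforest: chronosequences and old-growth plots on every
      continent, plus managed/logged plots in the Americas and Africa;
    * moist forest: full data in Africa and Asia, but American
      chronosequences only in stands ≤ 20 years (so the American
      older-secondary cell is empty and must be recommended from the
      better-aligned of two donors) and old-growth plots only in
      Africa (so the other two old-growth cells take the single-donor
      rung);
    * dry forest: no data anywhere — all its cells fall through to the
      supplied 2006 Tier 1 values;
    * one chronosequence record in the continental United States and
      one with stand age 101 years, both of which the inclusion
      filters must drop, and one chronosequence reported in carbon
      units.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(16) % (2**31)]
    RF, MO = Ecozone.TROPICAL_RAINFOREST, Ecozone.TROPICAL_MOIST_FOREST
    AF, NA, AS = Continent.AFRICA, Continent.AMERICAS, Continent.ASIA

    chrono_rows: list[dict] = []
    truth: dict[str, Any] = {"seed": seed, "strata": {}}

    def add_chrono(tag: str, params: ChronoSimParams, value_type: str = "agb") -> None:
        records, t = simulate_chronosequences(params)
        chrono_rows.extend(_chrono_rows(records, value_type))
        truth["strata"][tag] = {"params": t.params, "sites": t.sites, "n_floored": t.n_floored}

    add_chrono("Africa/rainforest", ChronoSimParams(
        n_sites=7, plots_per_site=(4, 8), beta0=12, beta1=38, sd_b0=8, sd_b1=4,
        corr_b0b1=0.3, sd_resid=10, continent=AF, ecozone=RF, seed=seeds[0],
        site_prefix="af_rf_"))
    add_chrono("NorthSouthAmerica/rainforest", ChronoSimParams(
        n_sites=10, plots_per_site=(4, 9), beta0=10, beta1=35, sd_b0=8, sd_b1=4,
        corr_b0b1=0.3, sd_resid=10, continent=NA, ecozone=RF, seed=seeds[1],
        site_prefix="na_rf_"))
    add_chrono("Asia/rainforest", ChronoSimParams(
        n_sites=8, plots_per_site=(3, 7), beta0=8, beta1=20, sd_b0=6, sd_b1=3,
        corr_b0b1=0.3, sd_resid=8, continent=AS, ecozone=RF, seed=seeds[2],
        site_prefix="as_rf_"))
    add_chrono("Africa/moist", ChronoSimParams(
        n_sites=5, plots_per_site=(3, 7), beta0=5, beta1=17, sd_b0=5, sd_b1=2.5,
        corr_b0b1=0.3, sd_resid=7, continent=AF, ecozone=MO, seed=seeds[3],
        site_prefix="af_mo_"), value_type="carbon")
    # American moist-forest stands are all young: the older-secondary
    # cell stays empty and must be filled by the two-donor rung.
    add_chrono("NorthSouthAmerica/moist", ChronoSimParams(
        n_sites=6, plots_per_site=(4, 7), age_range=(2.0, 18.0), beta0=8, beta1=33,
        sd_b0=6, sd_b1=3, corr_b0b1=0.3, sd_resid=8, continent=NA, ecozone=MO,
        seed=seeds[4], site_prefix="na_mo_"))
    add_chrono("Asia/moist", ChronoSimParams(
        n_sites=6, plots_per_site=(3, 7), beta0=4, beta1=14, sd_b0=4, sd_b1=2,
        corr_b0b1=0.3, sd_resid=6, continent=AS, ecozone=MO, seed=seeds[5],
        site_prefix="as_mo_"))

    # Two proximate single-plot African rainforest sites <1.5° apart:
    # they must be pooled into one grouped chronosequence.
    rng = np.random.default_rng(seeds[6])
    for sid, (lat, lon), age in (
        ("af_rf_near_a", (2.0, 20.0), 6.0),
        ("af_rf_near_b", (2.9, 20.7), 34.0),
    ):
        agb = 12 + 38 * np.log(age) + rng.normal(0, 10)
        chrono_rows.append({
            "record_id": f"{sid}_p00", "site_id": sid, "continent": AF.value,
            "ecozone": RF.value, "lat": lat, "lon": lon, "stand_age": age,
            "value": max(agb, 0.0), "value_type": "agb", "carbon_fraction": "",
            "in_continental_us": False,
        })

    # Records the inclusion filters must drop.
    chrono_rows.append({
        "record_id": "us_excl_p00", "site_id": "us_excl", "continent": NA.value,
        "ecozone": RF.value, "lat": 29.0, "lon": -82.0, "stand_age": 15.0,
        "value": 80.0, "value_type": "agb", "carbon_fraction": "",
        "in_continental_us": True,
    })
    chrono_rows.append({
        "record_id": "too_old_p00", "site_id": "na_rf_000", "continent": NA.value,
        "ecozone": RF.value, "lat": -20.0, "lon": -170.0, "stand_age": 101.0,
        "value": 260.0, "value_type": "agb", "carbon_fraction": "",
        "in_continental_us": False,
    })

    plot_rows: list[dict] = []

    def add_plots(tag: str, params: PlotSimParams) -> None:
        plots, ledger = simulate_permanent_plots(params)
        plot_rows.extend(_plot_rows(plots))
        truth["strata"][tag] = ledger

    add_plots("Africa/rainforest/OG", PlotSimParams(
        n_plots=18, mu_rate=1.3, sd_plot=2.0, sd_census=1.5, continent=AF,
        ecozone=RF, seed=seeds[7], plot_prefix="af_rf_og_"))
    add_plots("NorthSouthAmerica/rainforest/OG", PlotSimParams(
        n_plots=24, mu_rate=1.0, sd_plot=2.0, sd_census=1.5, continent=NA,
        ecozone=RF, seed=seeds[8], plot_prefix="na_rf_og_"))
    add_plots("Asia/rainforest/OG", PlotSimParams(
        n_plots=14, mu_rate=0.7, sd_plot=2.2, sd_census=1.5, continent=AS,
        ecozone=RF, seed=seeds[9], plot_prefix="as_rf_og_"))
    add_plots("Africa/moist/OG", PlotSimParams(
        n_plots=10, mu_rate=0.4, sd_plot=2.0, sd_census=1.5, continent=AF,
        ecozone=MO, seed=seeds[10], plot_prefix="af_mo_og_"))
    add_plots("NorthSouthAmerica/rainforest/ML", PlotSimParams(
        n_plots=8, mu_rate=2.8, sd_plot=1.5, sd_census=1.2,
        status=PlotStatus.MANAGED_LOGGED, continent=NA, ecozone=RF,
        seed=seeds[11], plot_prefix="na_rf_ml_"))
    add_plots("Africa/rainforest/ML", PlotSimParams(
        n_plots=4, mu_rate=5.0, sd_plot=1.5, sd_census=1.2,
        status=PlotStatus.MANAGED_LOGGED, continent=AF, ecozone=RF,
        seed=seeds[12], plot_prefix="af_rf_ml_"))

    truth["expected_gap_cells"] = {
        "two_donor": ["tropical_moist_forest/NorthSouthAmerica/OS"],
        "single_donor": [
            "tropical_moist_forest/NorthSouthAmerica/OG",
            "tropical_moist_forest/Asia/OG",
        ],
        "ipcc2006": ["tropical_dry_forest/*"],
    }
    return StudyFixture(
        chrono_frame=pd.DataFrame(chrono_rows),
        plots_frame=pd.DataFrame(plot_rows),
        ipcc2006=_FIXTURE_IPCC2006,
        ecozones=[RF, MO, Ecozone.TROPICAL_DRY_FOREST],
        truth=truth,
    )


def write_study_fixture(fixture: StudyFixture, out_dir) -> dict[str, Path]:
    """Write the fixture as chrono.csv, plots.csv, ipcc2006.yaml, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrono": out / "chrono.csv",
        "plots": out / "plots.csv",
        "ipcc2006": out / "ipcc2006.yaml",
        "truth": out / "truth.json",
    }
    fixture.chrono_frame.to_csv(paths["chrono"], index=False)
    fixture.plots_frame.to_csv(paths["plots"], index=False)
    with open(paths["ipcc2006"], "w") as fh:
        yaml.safe_dump(
            {
                "ipcc2006": fixture.ipcc2006,
                "ecozones": [e.value for e in fixture.ecozones],
            },
            fh,
            sort_keys=True,
        )
    with open(paths["truth"], "w") as fh:
        json.dump(fixture.truth, fh, indent=1, sort_keys=True)
    return paths
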