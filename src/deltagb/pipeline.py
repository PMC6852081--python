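"""End-to-end derivation: plot tables in, default-rate table out.

Wires the stages together: validation and inclusion filters, proximity
grouping per continent, one mixed-effects growth-curve fit per
continent × ecozone stratum, site-level younger/older-secondary rates,
weighted old-growth category statistics with bootstrap CIs, pooling of
managed/logged plots into older-secondary cells, gap filling and
rendering.  The whole derivation is deterministic for a given seed:
per-category bootstrap seeds are spawned from the base seed and the
cell's fixed position in the table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .chronosequence_rates import (
    RankDeficiencyError,
    SiteRate,
    fit_growth_model,
    rates_to_frame,
    site_rates,
)
from .data_io import (
    Chronosequence,
    Continent,
    Ecozone,
    ForestType,
    PermanentPlot,
    PlotStatus,
    apply_inclusion_filters,
    group_proximate_sites,
    read_chronosequence_csv,
    read_permanent_plot_csv,
    PROXIMITY_THRESHOLD_DEG,
)
from .default_tables import (
    CONTINENT_ORDER,
    ECOZONE_ORDER,
    CategoryEstimate,
    CellKey,
    CellStatus,
    cell_universe,
    estimate_og_category,
    estimate_secondary_category,
    fill_gaps,
    pool_managed_into_os,
    render_table,
)
from .permanent_plot_rates import (
    DEFAULT_BOOTSTRAP_SEED,
    WeightingScheme,
    category_weighted_rates,
    plot_mean_rate,
    weighted_rates_to_frame,
)

__all__ = ["DeriveConfig", "DeriveResult", "derive_rates", "derive_rates_files"]


@dataclass(frozen=True)
class DeriveConfig:
    """Tunable settings of the derivation."""

    weighting_scheme: WeightingScheme = WeightingScheme.AREA_X_YEARS
    ci_level: float = 0.95
    reps: int = 1000
    seed: int = DEFAULT_BOOTSTRAP_SEED
    proximity_thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(PROXIMITY_THRESHOLD_DEG)
    )
    ecozones: tuple[Ecozone, ...] | None = None  # None: those observed in inputs
    masked_cells: frozenset[tuple[Ecozone, Continent]] = frozenset()
    ipcc2006: Mapping = field(default_factory=dict)


@dataclass
class DeriveResult:
    """Everything the derivation produces."""

    table: dict[CellKey, CategoryEstimate]
    frame: pd.DataFrame
    text: str
    site_rate_frame: pd.DataFrame
    plot_rate_frame: pd.DataFrame
    report: dict[str, Any]


def _cell_seed(base_seed: int, ecozone: Ecozone, continent: Continent) -> int:
    ss = np.random.SeedSequence(
        [base_seed, ECOZONE_ORDER.index(ecozone), CONTINENT_ORDER.index(continent)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def derive_rates(
    chrono_records: Sequence,
    permanent_plots: Sequence[PermanentPlot],
    config: DeriveConfig = DeriveConfig(),
) -> DeriveResult:
    """Run the full derivation on validated in-memory inputs."""
    report: dict[str, Any] = {}

    records, filter_report = apply_inclusion_filters(list(chrono_records))
    report["inclusion_filters"] = filter_report.to_dict()

    chronos: list[Chronosequence] = []
    grouping: dict[str, dict[str, int]] = {}
    for continent in CONTINENT_ORDER:
        cont_records = [r for r in records if r.continent is continent]
        if not cont_records:
            continue
        cont_chronos, group_report = group_proximate_sites(
            cont_records, continent, thresholds=config.proximity_thresholds
        )
        chronos.extend(cont_chronos)
        grouping[continent.value] = group_report.to_dict()
    report["grouping"] = grouping

    # One growth-model fit per continent × ecozone stratum.
    strata: dict[tuple[Continent, Ecozone], list[Chronosequence]] = {}
    for c in chronos:
        strata.setdefault((c.continent, c.ecozone), []).append(c)

    all_site_rates: list[SiteRate] = []
    fitted, skipped = [], []
    for (continent, ecozone) in sorted(
        strata, key=lambda k: (CONTINENT_ORDER.index(k[0]), ECOZONE_ORDER.index(k[1]))
    ):
        group = [c for c in strata[(continent, ecozone)] if c.n_distinct_ages() >= 2]
        n_dropped = len(strata[(continent, ecozone)]) - len(group)
        if len(group) < 2:
            skipped.append(
                {
                    "continent": continent.value,
                    "ecozone": ecozone.value,
                    "reason": "fewer than 2 usable chronosequences",
                }
            )
            continue
        fit = fit_growth_model(group)
        all_site_rates.extend(site_rates(fit))
        fitted.append(
            {
                "continent": continent.value,
                "ecozone": ecozone.value,
                "n_chronosequences": len(group),
                "n_single_age_dropped": n_dropped,
                "fit_method": fit.fit_method.value,
            }
        )
    report["strata_fitted"] = fitted
    report["strata_skipped"] = skipped

    # Permanent plots, split by status and cell.
    og_plots: dict[tuple[Ecozone, Continent], list[PermanentPlot]] = {}
    ml_plots: dict[tuple[Ecozone, Continent], list[PermanentPlot]] = {}
    for p in permanent_plots:
        target = og_plots if p.status is PlotStatus.OLD_GROWTH else ml_plots
        target.setdefault((p.ecozone, p.continent), []).append(p)

    observed = (
        {r.ecozone for r in records}
        | {p.ecozone for p in permanent_plots}
    )
    ecozones = config.ecozones if config.ecozones is not None else sorted(
        observed, key=ECOZONE_ORDER.index
    )
    cells = cell_universe(ecozones, masked=config.masked_cells)

    table: dict[CellKey, CategoryEstimate | None] = {k: None for k in cells}
    for (ez, co, ft) in cells:
        if ft is ForestType.OLD_GROWTH:
            plots = og_plots.get((ez, co), [])
            wrs = category_weighted_rates(plots, config.weighting_scheme)
            table[(ez, co, ft)] = estimate_og_category(
                wrs,
                continent=co,
                ecozone=ez,
                reps=config.reps,
                seed=_cell_seed(config.seed, ez, co),
                level=config.ci_level,
            )
        else:
            rates = [
                r.rate
                for r in all_site_rates
                if r.continent is co and r.ecozone is ez and r.forest_type is ft
            ]
            if ft is ForestType.OLDER_SECONDARY:
                managed = [
                    plot_mean_rate(p.censuses)
                    for p in ml_plots.get((ez, co), [])
                ]
                rates = pool_managed_into_os(rates, managed)
            table[(ez, co, ft)] = estimate_secondary_category(
                rates, continent=co, ecozone=ez, forest_type=ft, level=config.ci_level
            )

    filled = fill_gaps(table, ipcc2006=config.ipcc2006, cells=cells)
    frame, text = render_table(filled)
    report["cells"] = {
        f"{ez.value}/{co.value}/{ft.value}": filled[(ez, co, ft)].status.value
        for (ez, co, ft) in cells
    }

    all_plots_sorted = sorted(permanent_plots, key=lambda p: p.plot_id)
    return DeriveResult(
        table=filled,
        frame=frame,
        text=text,
        site_rate_frame=rates_to_frame(all_site_rates),
        plot_rate_frame=weighted_rates_to_frame(
            all_plots_sorted, config.weighting_scheme
        ),
        report=report,
    )


def derive_rates_files(
    chrono_csv,
    plots_csv,
    out_csv,
    ipcc2006_yaml=None,
    log_json=None,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
    reps: int = 1000,
    weighting: WeightingScheme = WeightingScheme.AREA_X_YEARS,
    ci_level: float = 0.95,
) -> DeriveResult:
    """File-level wrapper around :func:`derive_rates`.

    Reads the two input CSVs and optionally a YAML config carrying the
    ``ipcc2006`` fallback table and, if the table should cover more
    cells than the data inform, ``ecozones`` and ``masked_cells``
    (pairs of ecozone and continent absent from each other).  Writes
    the rendered table CSV and a JSON run report.  Output bytes are
    reproducible for fixed inputs and seed.
    """
    records = read_chronosequence_csv(chrono_csv)
    plots = read_permanent_plot_csv(plots_csv)
    ipcc2006: Mapping = {}
    ecozones = None
    masked: frozenset[tuple[Ecozone, Continent]] = frozenset()
    if ipcc2006_yaml is not None:
        with open(ipcc2006_yaml) as fh:
            loaded = yaml.safe_load(fh) or {}
        ipcc2006 = loaded.get("ipcc2006", loaded)
        if "ecozones" in loaded:
            ecozones = tuple(Ecozone(e) for e in loaded["ecozones"])
        if "masked_cells" in loaded:
            masked = frozenset(
                (Ecozone(e), Continent(c)) for e, c in loaded["masked_cells"]
            )
    config = DeriveConfig(
        weighting_scheme=weighting,
        ci_level=ci_level,
        reps=reps,
        seed=seed,
        ecozones=ecozones,
        masked_cells=masked,
        ipcc2006=ipcc2006,
    )
    result = derive_rates(records, plots, config)

    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    rendered = result.frame.copy()
    for col in ("mean", "median", "sd", "ci_low", "ci_high"):
        rendered[col] = [
            "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.10g}"
            for v in rendered[col]
        ]
    rendered.to_csv(out_csv, index=False)
    if log_json is not None:
        with open(log_json, "w") as fh:
            json.dump(result.report, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return result
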