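# deltagb

Derivation of IPCC Tier 1 default **aboveground net biomass change
(ΔAGB)** rates for tropical and subtropical natural forests, from
plot-level data to a per-continent × ecozone × forest-type default
table with uncertainty.

Countries without dense national forest inventories report forest
carbon sinks with Tier 1 default ΔAGB rates — single values per FAO
global ecological zone ("ecozone") and continent, split into younger
secondary (≤ 20 yr), older secondary (> 20 yr, up to 100 yr) and
old-growth forest. `deltagb` implements the full statistical pipeline
that produces such a table from two kinds of field data:

* **chronosequences** — sets of secondary-forest plots of different
  stand ages under similar conditions (a space-for-time substitute
  for long-term monitoring), each contributing AGB (Mg/ha) at a known
  age;
* **permanent plots** — repeatedly censused old-growth or
  managed/logged stands, each contributing one ΔAGB rate
  (Mg ha⁻¹ yr⁻¹) per census interval.

## The model and statistics

For each continent × ecozone stratum, plot AGB is modelled on
log stand age with chronosequence-level random effects
(REML, via statsmodels `MixedLM`):

    AGB_ij = (β0 + b0_i) + (β1 + b1_i)·ln(age_ij) + ε_ij,
    (b0_i, b1_i) ~ N(0, Σ),  ε_ij ~ N(0, σ²)

Site-specific curves (fixed effects + BLUPs) give two slopes per
site: the **younger-secondary rate** AGB(20)/20 (linear accumulation
assumed over the first two decades) and the **older-secondary rate**
(AGB(t_max) − AGB(20)) / (t_max − 20), never extrapolating past the
oldest observed age. Old-growth plot rates (mean across censuses) are
pooled per category with weights = plot area × monitoring period;
the category gets a weighted mean, weighted SD and a 95% percentile
bootstrap CI (1,000 resamples over plots). Secondary categories get
an unweighted mean, sample SD and a z-based CI (mean ± 1.96·SD/√n).
Managed/logged plot rates are pooled into the older-secondary
category. Categories with fewer than two sites are filled by a
deterministic recommendation ladder: copy the single donor
continent → choose the better-aligned of two donors → fall back to
user-supplied IPCC 2006 values (for which older-secondary and
old-growth collapse back into one "> 20 years" class).

Because the underlying plot networks are not redistributable, the
package ships a synthetic-data generator with known ground truth
(`deltagb.synthetic_data`) that emulates both data kinds, and keeps
the published refined default-rate table as a regression fixture
(`deltagb.reference`).

## Worked example

Generate a synthetic three-continent study and derive its table:

```sh
deltagb simulate --kind fixture --seed 1 --out study/
deltagb derive-rates --chrono study/chrono.csv --plots study/plots.csv \
    --ipcc2006 study/ipcc2006.yaml --seed 1 --out study/table.csv
```

which prints (excerpt):

```
              ecozone         continent forest_type mean median  sd ci_low ci_high  n  ci_method                 status  donor
  tropical_rainforest            Africa          YS  7.0    6.4 1.1    6.3     7.7  8 analytic_z                derived
  tropical_rainforest            Africa          OS  2.9    1.3 2.9    1.3     4.6 12 analytic_z                derived
  tropical_rainforest            Africa          OG  1.4    1.4 2.7    0.2     2.7 18  bootstrap                derived
...
tropical_moist_forest NorthSouthAmerica          OS  0.6    0.6 0.2    0.4     0.7  5 analytic_z recommended_from_donor Africa
  tropical_dry_forest            Africa          YS  2.4                            0                 ipcc2006_fallback
```

Each row is one category: mean/median/SD and 95% CI in
Mg ha⁻¹ yr⁻¹ (rounded to one decimal), `n` the number of
chronosequences and/or permanent plots, `ci_method` showing the
analytic z interval (secondary) or the plot bootstrap (old-growth),
and `status`/`donor` recording provenance — here the American
moist-forest older-secondary cell had fewer than two sites and was
recommended from Africa, while the dry-forest ecozone (no data in
this synthetic study) fell back to the supplied 2006 values.

The JSON report written via `--log` records the inclusion-filter
counts (continental-US and over-age records dropped), the proximity
grouping per continent (< 1.5° in Africa, < 4.0° in Asia, single
linkage), the fit method per stratum and the status of every cell.

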