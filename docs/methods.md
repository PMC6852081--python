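# Methods

## Scope and data model

`deltagb` turns plot-level observations of tropical and subtropical
natural forests into category-level default net biomass change rates
(ΔAGB, Mg dry biomass ha⁻¹ yr⁻¹), one category being a continent ×
FAO ecozone × forest type cell. Forest types follow the succession
stages used in Tier 1 greenhouse-gas reporting: younger secondary
(stand age ≤ 20 yr), older secondary (> 20 and ≤ 100 yr) and
old-growth (no recorded anthropogenic disturbance for ≥ 100 yr);
stands with partial disturbance (selective logging, silviculture)
form a managed/logged group that is pooled into older-secondary
categories. Carbon-denominated inputs are converted to dry biomass by
the source's carbon fraction or, absent that, the IPCC default 0.47.

Compilation rules applied before any statistics: records from the
continental United States and secondary stands older than 100 years
are excluded (both counted in a filter report); in Africa and Asia,
chronosequence sites in the same ecozone closer than 1.5° / 4.0° are
pooled into single chronosequences (single linkage, i.e. connected
components of the below-threshold graph); in the Americas no pooling
is done and chronosequences need at least three plots.

## Secondary forests: growth curves on log age

Within one continent × ecozone stratum the AGB of chronosequence
plots is modelled as

    AGB_ij = (β0 + b0_i) + (β1 + b1_i)·ln(age_ij) + ε_ij

with correlated site-level random intercepts and slopes and Gaussian
residuals, fitted by REML (statsmodels `MixedLM`). The log transform
captures decelerating biomass accumulation through succession.
Site-specific curves are the fixed effects plus the shrunken
random-effect predictions (BLUPs); shrinkage means fitted site slopes
vary no more than independent per-site OLS slopes, a property the
test suite checks empirically.

Rates are chords of the fitted curves:

* younger secondary: AGB(20)/20 — biomass growth treated as linear
  over the first two decades, an assumption that yields unbiased
  20-year averages in a bookkeeping context even where instantaneous
  rates differ;
* older secondary: (AGB(t_max) − AGB(a)) / (t_max − a), with
  a = 20 yr or the youngest observed age if the whole site is older,
  and t_max the oldest age observed at the site. Curves are never
  extrapolated beyond t_max; sites without a plot ≤ 20 yr contribute
  no younger-secondary rate, sites without one > 20 yr no
  older-secondary rate. Negative predictions and rates are retained
  and flagged, never clamped.

One model is fitted per continent × ecozone stratum, since rates are
subsequently pooled within exactly that stratum.

### Convergence ladder

Variance components near a boundary can defeat the full model, so
the fit degrades in a fixed, recorded order: REML with correlated
random intercept and slope → REML with independent random effects
(diagonal covariance, via a constrained parameter pattern) → REML
with random intercept only → ML with the full structure → per-site
ordinary least squares (site coefficients fitted independently;
"fixed effects" are then their unweighted means). A fit is accepted
only if the optimizer converged with finite estimates and a positive
semidefinite random-effect covariance. The accepted method is stored
on the fit object and propagated into the site-rate table. In the
noiseless limit all mixed rungs are degenerate and the OLS rung
reproduces the generative curves exactly, which the tests exploit.

## Permanent plots: weighted category statistics

A plot's rate is the plain mean of its census-interval rates.
Within an old-growth category, plots are weighted by
area (ha) × total monitoring period (yr) — larger, longer-monitored
plots estimate net change with less sampling noise — except that a
category in which every plot shares one area and one monitoring
period uses unit weights. Alternative schemes (area only, years
only, equal) are selectable where source-specific weights are more
appropriate. Category statistics are the weighted mean, the
frequency-style weighted SD

    sqrt( Σw(x − x̄_w)² / ((M−1)/M · Σw) ),  M = #{w > 0},

which reduces to the ordinary sample SD at equal weights, an
unweighted median, and a 95% percentile bootstrap CI: plots —
the independent sampling units — are resampled with replacement
(rate and weight jointly) 1,000 times at the original sample size
and the 2.5/97.5 percentiles of the replicate weighted means taken.
The bootstrap is deterministic given its seed (default 20190816);
the pipeline spawns one seed per table cell from the run seed, so a
whole derivation is byte-reproducible.

Secondary categories use the unweighted mean, sample SD and the
analytic z interval mean ± 1.959964·SD/√n. The z form (not t) is
normative here: it reproduces all 22 published secondary-category
CIs at one-decimal rounding, which a t interval does not.

## Default-table assembly

Categories need ≥ 2 chronosequences or plots. Empty cells are filled
by a deterministic ladder: (1) a single donor continent with a
derived value for the same ecozone and forest type is copied, with
provenance recorded; (2) with two candidate donors, the donor whose
mean lies closest (mean absolute difference) to the derived means of
the *other* forest types in the target's own continent × ecozone
wins — ties go to the donor with more sites, then to the fixed
continent order Africa, Americas, Asia; if the target cell has no
derived other-type mean the tie-breaks decide directly; (3) with no
donor anywhere, the user-supplied IPCC 2006 value is recommended,
older-secondary and old-growth sharing the 2006 "> 20 years" class —
a missing config entry for such a cell is a hard error rather than a
silent blank. Derived cells are never overwritten and the operation
is idempotent.

The cell universe defaults to the ecozones observed in the input
(all three continents, three forest types); a config file may widen
it or mask ecozone–continent pairs that do not exist geographically.
Rounding to the table's one-decimal precision (ties away from zero)
happens only at rendering; the pipeline carries full precision.

## Synthetic data

The generator draws from exactly the model the analysis assumes —
bivariate-normal site effects, AGB linear in ln(age), Gaussian
residuals, uniform (optionally log-uniform, emulating the real skew
toward young stands) ages — plus permanent plots with a true rate
per plot, noisier census rates around it, and heterogeneous areas
and monitoring lengths. Defaults describe a data-rich
rainforest-like stratum: β0 = 10, β1 = 35 (AGB ≈ 115 Mg/ha at
20 yr), sd(b0) = 10, sd(b1) = 5, σ = 10 Mg/ha, 30 sites × 8 plots,
ages 2–80 yr; old-growth categories use mean rate 1.0, between-plot
SD 2.0, census SD 1.5 Mg ha⁻¹ yr⁻¹, 1–5 censuses, areas 0.25–4 ha
and 5–30 yr of monitoring, matching the magnitudes typical of
tropical inventory networks. Negative AGB draws are floored at zero
with the count reported, so tests can detect distortion of the
noiseless identities. Every generator is byte-reproducible given its
seed, and a truth ledger records each site's analytic
younger/older-secondary rates and each plot's true rate.

What the generator does **not** emulate: real geography (coordinates
are grid points spaced beyond the grouping radii), allometric
measurement error, temporal autocorrelation between censuses,
heavy-tailed disturbance losses, and any dependence of a plot's
precision on its area or monitoring length. Passing tests therefore
demonstrate correctness of the statistical machinery under the
stated generative model, not unbiasedness on real plot networks.

`make_study_fixture` assembles a complete small study (three
continents; rainforest, moist and dry forest; ~40 chronosequences
and ~80 permanent plots including managed/logged subsets) whose
construction guarantees that every inclusion filter, the proximity
grouping, the managed/logged pooling and every rung of the
gap-filling ladder is exercised in one end-to-end run.

## Numerical choices and degenerate inputs

* Proximity is Euclidean distance on (lat, lon) in decimal degrees,
  matching the unit in which the radii are quoted; a great-circle
  metric is available as an option.
* ln is the natural logarithm throughout.
* Age exactly 20 yr classifies as younger secondary; stand age over
  100 yr with no other metadata classifies as old-growth.
* A chronosequence whose plots all share one age is rank-deficient
  and rejected; grouped African/Asian chronosequences need two
  distinct ages to support a slope.
* Weighted SD of a single effectively-weighted plot is 0 by
  convention; a bootstrap replicate drawing only zero-weight plots
  falls back to its unweighted mean.
* Bootstrap percentiles use numpy's default (linear-interpolation)
  quantile; alternative conventions change coverage negligibly.
* Rendering rounds half away from zero and normalises −0.0 to 0.0.

## Known limitations

* Chronosequences substitute space for time; site-specific rates
  inherit that assumption, and older-secondary rates carry an upward
  bias where old stands are scarce.
* Category CIs reflect site-rate dispersion only; uncertainty from
  the mixed-model fit itself is not propagated, matching the
  published derivation.
* The percentile bootstrap under-covers slightly at category sizes
  around 30 plots, and strong area × years weight heterogeneity
  lowers the effective sample size further, so measured coverage of
  the nominal 95% interval sits a little below nominal under the
  default generator conditions (the acceptance checks compute the
  empirical value). BCa or studentised intervals would narrow the
  gap but are deliberately out of scope; the simple percentile
  interval is the documented, reproducible convention here.
* Gap-filled cells copy a donor's dispersion statistics verbatim;
  they describe the donor, not the target, and are labelled as such.
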