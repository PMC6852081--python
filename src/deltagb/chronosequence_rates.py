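"""Growth-curve fitting and site-level ΔAGB rates for secondary forests.

Within one continent × ecozone stratum, plot AGB is modelled as a
linear function of ln(stand age) with chronosequence-level random
intercepts and slopes:

    AGB_ij = (β0 + b0_i) + (β1 + b1_i) · ln(age_ij) + ε_ij

with (b0_i, b1_i) bivariate normal and ε_ij ~ N(0, σ²).  The log
transform captures the decelerating accumulation of biomass during
succession.  Site-specific curves (fixed effects plus the shrunken
random-effect predictions, i.e. BLUPs) yield two slopes per site:

* younger secondary (≤ 20 yr): predicted AGB at 20 years divided by
  20, i.e. the chord from the origin — biomass accumulation is
  assumed linear over the first two decades;
* older secondary (> 20 yr): the chord of the fitted curve between
  20 years (or the youngest age after 20) and the oldest age observed
  at the site.  No extrapolation beyond the observed maximum age.

Restricted maximum likelihood is used for estimation.  When the full
model does not converge the fit degrades in a documented order:
uncorrelated random effects, then random intercept only, then maximum
likelihood, and finally independent per-site ordinary least squares.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLMParams

from .data_io import Chronosequence, Continent, Ecozone, ForestType, UsageError

__all__ = [
    "FitMethod",
    "VarComponents",
    "GrowthModelFit",
    "SiteRate",
    "RankDeficiencyError",
    "fit_growth_model",
    "predict_site_agb",
    "ys_rate",
    "os_rate",
    "site_rates",
    "rates_to_frame",
]

logger = logging.getLogger(__name__)

YS_ANCHOR_AGE = 20.0


class RankDeficiencyError(ValueError):
    """The design matrix cannot identify a slope (no age variation)."""


class FitMethod(str, Enum):
    REML = "REML"
    ML = "ML"
    FALLBACK_PER_SITE_OLS = "fallback_per_site_OLS"


class VarComponents(NamedTuple):
    sd_b0: float
    sd_b1: float
    corr_b0b1: float
    sd_resid: float


@dataclass(frozen=True)
class GrowthModelFit:
    """Fitted AGB–ln(age) model for one continent × ecozone stratum."""

    continent: Continent
    ecozone: Ecozone
    beta0: float
    beta1: float
    site_effects: dict[str, tuple[float, float]]  # chrono_id -> (b0_i, b1_i)
    var_components: VarComponents
    converged: bool
    fit_method: FitMethod
    site_age_range: dict[str, tuple[float, float]]  # chrono_id -> (min, max)

    def site_coefficients(self, chrono_id: str) -> tuple[float, float]:
        """Return the site-specific (intercept, slope)."""
        try:
            b0, b1 = self.site_effects[chrono_id]
        except KeyError:
            raise KeyError(
                f"chronosequence {chrono_id!r} was not part of this fit"
            ) from None
        return self.beta0 + b0, self.beta1 + b1


@dataclass(frozen=True)
class SiteRate:
    """A site-level ΔAGB rate derived from the fitted growth curve."""

    chrono_id: str
    continent: Continent
    ecozone: Ecozone
    forest_type: ForestType
    rate: float  # Mg ha⁻¹ yr⁻¹
    anchor_low_age: float
    anchor_high_age: float
    predicted_agb_low: float
    predicted_agb_high: float
    fit_method: FitMethod


def _stack(chronosequences: Sequence[Chronosequence]) -> pd.DataFrame:
    rows = [
        {"chrono_id": c.chrono_id, "age": p.stand_age, "agb": p.abg_value}
        for c in chronosequences
        for p in c.plots
    ]
    df = pd.DataFrame(rows)
    df["ln_age"] = np.log(df["age"])
    return df


def _result_ok(res) -> bool:
    params = np.concatenate([np.atleast_1d(res.fe_params), np.ravel(res.cov_re)])
    if not np.all(np.isfinite(params)) or not np.isfinite(res.scale):
        return False
    eigvals = np.linalg.eigvalsh(np.atleast_2d(np.asarray(res.cov_re)))
    if np.any(eigvals < -1e-8):
        return False
    return bool(res.converged)


def _extract(res, continent, ecozone, age_range, method: FitMethod) -> GrowthModelFit:
    fe = np.asarray(res.fe_params)
    beta0, beta1 = float(fe[0]), float(fe[1])
    cov = np.atleast_2d(np.asarray(res.cov_re))
    sd_b0 = math.sqrt(max(cov[0, 0], 0.0))
    if cov.shape[0] > 1:
        sd_b1 = math.sqrt(max(cov[1, 1], 0.0))
        corr = float(cov[0, 1] / (sd_b0 * sd_b1)) if sd_b0 > 0 and sd_b1 > 0 else 0.0
        corr = max(-1.0, min(1.0, corr))
    else:
        sd_b1, corr = 0.0, 0.0
    effects = {}
    for gid, re in res.random_effects.items():
        vals = np.asarray(re, dtype=float)
        b0 = float(vals[0])
        b1 = float(vals[1]) if vals.size > 1 else 0.0
        effects[str(gid)] = (b0, b1)
    return GrowthModelFit(
        continent=continent,
        ecozone=ecozone,
        beta0=beta0,
        beta1=beta1,
        site_effects=effects,
        var_components=VarComponents(sd_b0, sd_b1, corr, math.sqrt(max(res.scale, 0.0))),
        converged=True,
        fit_method=method,
        site_age_range=age_range,
    )


def _per_site_ols(df, continent, ecozone, age_range) -> GrowthModelFit:
    # Independent OLS lines per site; "fixed effects" are the unweighted
    # means of the site coefficients, so site effects remain deviations.
    coefs = {}
    for gid, g in df.groupby("chrono_id"):
        slope, intercept = np.polyfit(g["ln_age"].to_numpy(), g["agb"].to_numpy(), 1)
        coefs[str(gid)] = (float(intercept), float(slope))
    beta0 = float(np.mean([c[0] for c in coefs.values()]))
    beta1 = float(np.mean([c[1] for c in coefs.values()]))
    effects = {gid: (c[0] - beta0, c[1] - beta1) for gid, c in coefs.items()}
    resid_var = 0.0
    n = 0
    for gid, g in df.groupby("chrono_id"):
        b0, b1 = coefs[str(gid)]
        r = g["agb"].to_numpy() - (b0 + b1 * g["ln_age"].to_numpy())
        resid_var += float(np.sum(r**2))
        n += len(g)
    sd_resid = math.sqrt(resid_var / n) if n else 0.0
    b0s = [c[0] for c in coefs.values()]
    b1s = [c[1] for c in coefs.values()]
    sd_b0 = float(np.std(b0s, ddof=1)) if len(b0s) > 1 else 0.0
    sd_b1 = float(np.std(b1s, ddof=1)) if len(b1s) > 1 else 0.0
    return GrowthModelFit(
        continent=continent,
        ecozone=ecozone,
        beta0=beta0,
        beta1=beta1,
        site_effects=effects,
        var_components=VarComponents(sd_b0, sd_b1, 0.0, sd_resid),
        converged=True,
        fit_method=FitMethod.FALLBACK_PER_SITE_OLS,
        site_age_range=age_range,
    )


def fit_growth_model(
    chronosequences: Sequence[Chronosequence],
) -> GrowthModelFit:
    """Fit the random-intercept-and-slope AGB–ln(age) model.

    Requires at least two chronosequences, each with at least two plots
    at distinct ages, all from the same continent × ecozone stratum.
    Raises :class:`RankDeficiencyError` when no site shows age
    variation.
    """
    if len(chronosequences) < 2:
        raise UsageError("fit_growth_model needs >= 2 chronosequences")
    strata = {(c.continent, c.ecozone) for c in chronosequences}
    if len(strata) > 1:
        raise UsageError(
            "all chronosequences must share one continent × ecozone stratum"
        )
    (continent, ecozone) = strata.pop()
    for c in chronosequences:
        if c.n_distinct_ages() < 2:
            raise RankDeficiencyError(
                f"chronosequence {c.chrono_id!r} has plots at a single stand "
                "age; its slope is unidentifiable"
            )
    df = _stack(chronosequences)
    age_range = {c.chrono_id: (c.min_age, c.max_age) for c in chronosequences}

    free_diag = MixedLMParams.from_components(
        fe_params=np.ones(2), cov_re=np.eye(2)
    )
    attempts = (
        (FitMethod.REML, "~ln_age", True, None),   # correlated intercept+slope
        (FitMethod.REML, "~ln_age", True, free_diag),  # drop the correlation
        (FitMethod.REML, "~1", True, None),        # drop the random slope
        (FitMethod.ML, "~ln_age", False, None),    # last resort before OLS
    )
    for method, re_formula, reml, free in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM.from_formula(
                    "agb ~ ln_age",
                    groups="chrono_id",
                    re_formula=re_formula,
                    data=df,
                )
                res = model.fit(reml=reml, free=free, method=["lbfgs", "bfgs"])
            if _result_ok(res):
                fit = _extract(res, continent, ecozone, age_range, method)
                if free is not None or re_formula == "~1":
                    logger.info(
                        "stratum %s/%s: degraded fit (%s, re=%s)",
                        continent.value, ecozone.value, method.value, re_formula,
                    )
                return fit
        except (np.linalg.LinAlgError, ValueError):
            continue
    logger.info(
        "stratum %s/%s: mixed model did not converge, using per-site OLS",
        continent.value, ecozone.value,
    )
    return _per_site_ols(df, continent, ecozone, age_range)


def predict_site_agb(fit: GrowthModelFit, chrono_id: str, age: float) -> float:
    """Predict AGB (Mg/ha) at ``age`` years from the site-specific curve.

    Negative predictions are possible at very young ages; they are
    returned as-is (downstream code flags rather than clamps them).
    """
    if not age > 0:
        raise UsageError(f"age must be > 0 years, got {age}")
    a0, a1 = fit.site_coefficients(chrono_id)
    return a0 + a1 * math.log(age)


def ys_rate(fit: GrowthModelFit, chrono_id: str) -> SiteRate | None:
    """Younger-secondary ΔAGB rate: predicted AGB at 20 years over 20.

    Sites with no plot at or below 20 years contribute no
    younger-secondary rate; ``None`` is returned and the skip logged.
    """
    min_age, _ = fit.site_age_range[chrono_id]
    if min_age > YS_ANCHOR_AGE:
        logger.info(
            "site %s: no plot <= %.0f yr, skipping younger-secondary rate",
            chrono_id, YS_ANCHOR_AGE,
        )
        return None
    agb20 = predict_site_agb(fit, chrono_id, YS_ANCHOR_AGE)
    return SiteRate(
        chrono_id=chrono_id,
        continent=fit.continent,
        ecozone=fit.ecozone,
        forest_type=ForestType.YOUNGER_SECONDARY,
        rate=agb20 / YS_ANCHOR_AGE,
        anchor_low_age=0.0,
        anchor_high_age=YS_ANCHOR_AGE,
        predicted_agb_low=0.0,
        predicted_agb_high=agb20,
        fit_method=fit.fit_method,
    )


def os_rate(
    fit: GrowthModelFit,
    chrono_id: str,
    max_age: float,
    youngest_age: float,
) -> SiteRate | None:
    """Older-secondary ΔAGB rate: chord of the curve beyond 20 years.

    The lower anchor is 20 years, or the youngest observed age when the
    whole site is older than 20.  The upper anchor is the oldest age
    observed at the site; the curve is never extrapolated past it.
    Sites whose oldest plot is not older than the lower anchor
    contribute no older-secondary rate.
    """
    anchor_low = YS_ANCHOR_AGE if youngest_age <= YS_ANCHOR_AGE else youngest_age
    if max_age <= anchor_low:
        logger.info(
            "site %s: max age %.1f <= anchor %.1f, skipping older-secondary rate",
            chrono_id, max_age, anchor_low,
        )
        return None
    agb_low = predict_site_agb(fit, chrono_id, anchor_low)
    agb_high = predict_site_agb(fit, chrono_id, max_age)
    return SiteRate(
        chrono_id=chrono_id,
        continent=fit.continent,
        ecozone=fit.ecozone,
        forest_type=ForestType.OLDER_SECONDARY,
        rate=(agb_high - agb_low) / (max_age - anchor_low),
        anchor_low_age=anchor_low,
        anchor_high_age=max_age,
        predicted_agb_low=agb_low,
        predicted_agb_high=agb_high,
        fit_method=fit.fit_method,
    )


def site_rates(fit: GrowthModelFit) -> list[SiteRate]:
    """All younger- and older-secondary rates derivable from a fit."""
    out: list[SiteRate] = []
    for chrono_id in sorted(fit.site_effects):
        min_age, max_age = fit.site_age_range[chrono_id]
        ys = ys_rate(fit, chrono_id)
        if ys is not None:
            out.append(ys)
        os_ = os_rate(fit, chrono_id, max_age=max_age, youngest_age=min_age)
        if os_ is not None:
            out.append(os_)
    return out


def rates_to_frame(rates: Iterable[SiteRate]) -> pd.DataFrame:
    """Site-rate table: one row per site and forest type."""
    return pd.DataFrame(
        [
            {
                "chrono_id": r.chrono_id,
                "continent": r.continent.value,
                "ecozone": r.ecozone.value,
                "forest_type": r.forest_type.value,
                "rate": r.rate,
                "anchor_low_age": r.anchor_low_age,
                "anchor_high_age": r.anchor_high_age,
                "predicted_agb_low": r.predicted_agb_low,
                "predicted_agb_high": r.predicted_agb_high,
                "fit_method": r.fit_method.value,
            }
            for r in rates
        ]
    )
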