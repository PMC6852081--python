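"""Published Tier 1 default ΔAGB rates (2019 IPCC Refinement).

The refined default-rate table for tropical and subtropical natural
forests, as printed in the 2019 Refinement derivation, kept here as a
regression fixture: the analytic-CI and rate-identity consistency
checks verify that this package's formulas reproduce the printed
bounds.  The underlying plot databases are not redistributable, so
these numbers are reference inputs, never something this package
re-estimates from raw data.

Units are Mg dry biomass ha⁻¹ yr⁻¹ (AGB stocks in Mg/ha); values carry
the table's one-decimal precision.
"""

from __future__ import annotations

from typing import NamedTuple

from .data_io import Continent, Ecozone, ForestType

__all__ = ["PublishedRate", "PUBLISHED_DEFAULT_RATES", "PUBLISHED_AGB_AT_20"]


class PublishedRate(NamedTuple):
    ecozone: Ecozone
    continent: Continent
    forest_type: ForestType
    mean: float
    median: float
    sd: float
    ci_low: float
    ci_high: float
    n: int


_RF = Ecozone.TROPICAL_RAINFOREST
_MO = Ecozone.TROPICAL_MOIST_FOREST
_DR = Ecozone.TROPICAL_DRY_FOREST
_MT = Ecozone.TROPICAL_MOUNTAIN_SYSTEM
_SH = Ecozone.SUBTROPICAL_HUMID_FOREST
_SM = Ecozone.SUBTROPICAL_MOUNTAIN_SYSTEM
_AF, _NA, _AS = Continent.AFRICA, Continent.AMERICAS, Continent.ASIA
_YS = ForestType.YOUNGER_SECONDARY
_OS = ForestType.OLDER_SECONDARY
_OG = ForestType.OLD_GROWTH

#: All rows of the published refined default-rate table.
PUBLISHED_DEFAULT_RATES: tuple[PublishedRate, ...] = (
    PublishedRate(_RF, _AF, _YS, 7.6, 3.5, 5.9, 4.6, 10.6, 15),
    PublishedRate(_RF, _AF, _OS, 3.5, 1.9, 3.3, 1.5, 5.5, 10),
    PublishedRate(_RF, _AF, _OG, 1.3, 1.7, 3.5, 0.5, 2.1, 77),
    PublishedRate(_RF, _NA, _YS, 5.9, 5.0, 2.5, 5.1, 6.7, 42),
    PublishedRate(_RF, _NA, _OS, 2.3, 2.1, 1.1, 2.0, 2.6, 39),
    PublishedRate(_RF, _NA, _OG, 1.0, 0.9, 2.0, 0.6, 1.4, 248),
    PublishedRate(_RF, _AS, _YS, 3.4, 2.1, 3.9, 0.5, 6.3, 7),
    PublishedRate(_RF, _AS, _OS, 2.7, 2.7, 3.1, -1.6, 7.0, 2),
    PublishedRate(_RF, _AS, _OG, 0.7, 0.8, 2.2, 0.1, 1.3, 66),
    PublishedRate(_MO, _AF, _YS, 2.9, 2.9, 1.0, 1.5, 4.3, 2),
    PublishedRate(_MO, _AF, _OS, 0.9, 0.9, 0.7, -0.1, 1.9, 2),
    PublishedRate(_MO, _NA, _YS, 5.2, 4.5, 2.3, 4.2, 6.2, 21),
    PublishedRate(_MO, _NA, _OS, 2.7, 2.2, 1.7, 1.9, 3.5, 18),
    PublishedRate(_MO, _NA, _OG, 0.4, 0.8, 2.1, -0.7, 1.5, 19),
    PublishedRate(_MO, _AS, _YS, 2.4, 2.4, 0.3, 2.0, 2.8, 2),
    PublishedRate(_DR, _NA, _YS, 3.9, 3.1, 2.4, 2.0, 5.8, 6),
    PublishedRate(_DR, _NA, _OS, 1.6, 1.5, 1.1, 0.6, 2.6, 5),
    PublishedRate(_MT, _AF, _YS, 5.5, 5.5, 6.8, -3.9, 14.9, 2),
    PublishedRate(_MT, _NA, _YS, 4.4, 4.0, 1.6, 3.1, 5.7, 6),
    PublishedRate(_MT, _NA, _OS, 1.8, 1.5, 0.8, 1.0, 2.6, 4),
    PublishedRate(_MT, _NA, _OG, 0.5, 0.1, 1.9, -0.9, 1.9, 6),
    PublishedRate(_MT, _AS, _YS, 2.9, 2.9, 0.1, 2.8, 3.0, 5),
    PublishedRate(_MT, _AS, _OS, 1.1, 1.2, 0.4, 0.7, 1.5, 5),
    PublishedRate(_MT, _AS, _OG, -0.7, -0.3, 3.1, -3.2, 1.8, 5),
    PublishedRate(_SH, _AS, _YS, 2.5, 2.2, 0.8, 1.7, 3.3, 4),
    PublishedRate(_SH, _AS, _OS, 1.0, 0.7, 0.9, 0.4, 1.6, 8),
    PublishedRate(_SM, _AS, _YS, 2.5, 2.5, 0.03, 2.5, 2.5, 2),
    PublishedRate(_SM, _AS, _OS, 0.5, 0.4, 0.3, 0.3, 0.7, 12),
)

#: Ecozone-level fitted AGB at 20 years (Mg/ha) reported alongside the
#: table; dividing by 20 gives the corresponding younger-secondary
#: default rate.
PUBLISHED_AGB_AT_20: dict[tuple[Continent, Ecozone], float] = {
    (_NA, _RF): 118.9,
    (_NA, _MT): 88.7,
    (_AF, _RF): 151.2,
    (_AF, _MO): 57.3,
    (_AS, _RF): 68.8,
    (_AS, _MO): 47.1,
}
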