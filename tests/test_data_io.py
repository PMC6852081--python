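"""Validation, carbon conversion, classification, filters and grouping."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from deltagb.data_io import (
    Chronosequence,
    ClassificationError,
    Continent,
    Ecozone,
    ForestType,
    Intervention,
    PlotRecord,
    UsageError,
    ValidationError,
    apply_inclusion_filters,
    classify_forest_type,
    convert_to_agb,
    group_proximate_sites,
    read_chronosequence_csv,
    read_permanent_plot_csv,
)


def make_record(record_id="r", site_id="s", continent=Continent.AFRICA,
                ecozone=Ecozone.TROPICAL_RAINFOREST, lat=0.0, lon=0.0,
                age=10.0, agb=50.0, in_us=False):
    return PlotRecord(
        record_id=record_id, site_id=site_id, continent=continent,
        ecozone=ecozone, latitude=lat, longitude=lon, stand_age=age,
        abg_value=agb, in_continental_us=in_us,
    )


class TestConvertToAgb:
    @pytest.mark.parametrize(
        "value,is_carbon,cf,expected",
        [
            (47.0, True, None, 100.0),   # IPCC default carbon fraction
            (80.0, False, None, 80.0),   # biomass passes through
            (25.0, True, 0.5, 50.0),     # source-specific fraction wins
            (0.0, True, None, 0.0),
        ],
    )
    def test_examples(self, value, is_carbon, cf, expected):
        assert convert_to_agb(value, is_carbon, cf) == pytest.approx(expected)

    @pytest.mark.parametrize("value,cf", [(-1.0, None), (10.0, 0.0), (10.0, 1.5)])
    def test_invalid_inputs_name_the_record(self, value, cf):
        with pytest.raises(ValidationError, match="rec7"):
            convert_to_agb(value, True, cf, record_id="rec7")

    @given(
        agb=st.floats(0, 1e4, allow_nan=False),
        cf=st.floats(0.01, 1.0, allow_nan=False),
    )
    @settings(derandomize=True, deadline=None)
    def test_inverts_carbon_multiplication(self, agb, cf):
        assert convert_to_agb(agb * cf, True, cf) == pytest.approx(agb, rel=1e-9)


class TestClassifyForestType:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(stand_age=20.0), ForestType.YOUNGER_SECONDARY),   # boundary inclusive
            (dict(stand_age=20.5), ForestType.OLDER_SECONDARY),
            (dict(stand_age=100.0), ForestType.OLDER_SECONDARY),
            (dict(stand_age=101.0), ForestType.OLD_GROWTH),
            (dict(last_disturbance=150.0), ForestType.OLD_GROWTH),
            (dict(last_disturbance=100.0), ForestType.OLD_GROWTH),
            (dict(last_disturbance=15.0), ForestType.YOUNGER_SECONDARY),
            (
                dict(stand_age=40.0, intervention=Intervention.PARTIAL_DISTURBANCE),
                ForestType.MANAGED_LOGGED,
            ),
        ],
    )
    def test_rules(self, kwargs, expected):
        assert classify_forest_type(**kwargs) is expected

    def test_contradictory_metadata_rejected(self):
        with pytest.raises(ClassificationError):
            classify_forest_type(
                last_disturbance=150.0,
                intervention=Intervention.PARTIAL_DISTURBANCE,
            )

    def test_no_metadata_rejected(self):
        with pytest.raises(ClassificationError):
            classify_forest_type()

    def test_total_and_single_valued_on_precondition_domain(self):
        """Every admissible metadata combination yields exactly one type."""
        ages = [None, 1.0, 20.0, 21.0, 99.0, 101.0]
        dists = [None, 5.0, 99.0, 100.0, 200.0]
        intervs = [None, Intervention.NONE, Intervention.PARTIAL_DISTURBANCE]
        for age, dist, interv in itertools.product(ages, dists, intervs):
            if age is None and dist is None and interv in (None, Intervention.NONE):
                continue  # outside the precondition
            contradictory = (
                interv is Intervention.PARTIAL_DISTURBANCE
                and dist is not None and dist >= 100
            )
            if contradictory:
                with pytest.raises(ClassificationError):
                    classify_forest_type(age, dist, interv)
            else:
                assert classify_forest_type(age, dist, interv) in ForestType


class TestInclusionFilters:
    def test_us_records_dropped_and_counted(self):
        records = [make_record(record_id=f"r{i}") for i in range(4)]
        records.append(make_record(record_id="us", in_us=True))
        kept, report = apply_inclusion_filters(records)
        assert len(kept) == 4
        assert report.counts["continental_us"] == 1

    def test_overage_secondary_dropped(self):
        records = [make_record(age=101.0), make_record(record_id="ok", age=100.0)]
        kept, report = apply_inclusion_filters(records)
        assert [r.record_id for r in kept] == ["ok"]
        assert report.counts["age_over_100"] == 1

    def test_empty_input(self):
        kept, report = apply_inclusion_filters([])
        assert kept == [] and report.total_dropped == 0

    @given(st.lists(st.tuples(st.booleans(), st.floats(1.0, 150.0)), max_size=30))
    @settings(derandomize=True, deadline=None)
    def test_dropped_counts_sum_to_size_difference(self, flags):
        records = [
            make_record(record_id=f"r{i}", age=age, in_us=in_us)
            for i, (in_us, age) in enumerate(flags)
        ]
        kept, report = apply_inclusion_filters(records)
        assert report.total_dropped == len(records) - len(kept)


class TestGroupProximateSites:
    def _africa_site(self, site_id, lat, lon, ages=(5.0, 30.0)):
        return [
            make_record(record_id=f"{site_id}_{i}", site_id=site_id,
                        lat=lat, lon=lon, age=a)
            for i, a in enumerate(ages)
        ]

    def test_nearby_african_sites_merge(self):
        records = self._africa_site("a", 0.0, 0.0) + self._africa_site("b", 1.4, 0.0)
        chronos, _ = group_proximate_sites(records, Continent.AFRICA)
        assert len(chronos) == 1
        assert chronos[0].member_site_ids == {"a", "b"}

    def test_distant_african_sites_stay_separate(self):
        records = self._africa_site("a", 0.0, 0.0) + self._africa_site("b", 1.6, 0.0)
        chronos, _ = group_proximate_sites(records, Continent.AFRICA)
        assert len(chronos) == 2

    def test_single_linkage_chain_matches_brute_force(self):
        # A-B and B-C are 3° apart (< 4° Asia radius), A-C is 6°: one
        # chained chronosequence, confirmed by brute-force transitive
        # closure over all below-threshold pairs.
        sites = {"A": (0.0, 0.0), "B": (0.0, 3.0), "C": (0.0, 6.0)}
        records = []
        for sid, (lat, lon) in sites.items():
            records += [
                make_record(record_id=f"{sid}{i}", site_id=sid,
                            continent=Continent.ASIA, lat=lat, lon=lon, age=a)
                for i, a in enumerate((5.0, 30.0))
            ]
        chronos, _ = group_proximate_sites(records, Continent.ASIA)

        # brute-force oracle: repeatedly merge any two groups containing
        # a below-threshold pair until a fixed point
        groups = [{s} for s in sites]
        changed = True
        while changed:
            changed = False
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    close = any(
                        ((sites[x][0] - sites[y][0]) ** 2
                         + (sites[x][1] - sites[y][1]) ** 2) ** 0.5 < 4.0
                        for x in groups[i]
                        for y in groups[j]
                    )
                    if close:
                        groups[i] |= groups[j]
                        del groups[j]
                        changed = True
                        break
                if changed:
                    break
        expected = {frozenset(g) for g in groups}
        assert {frozenset(c.member_site_ids) for c in chronos} == expected
        assert expected == {frozenset({"A", "B", "C"})}

    def test_americas_small_chronosequences_excluded(self):
        records = [
            make_record(record_id=f"big{i}", site_id="big",
                        continent=Continent.AMERICAS, age=float(i + 1))
            for i in range(3)
        ] + [
            make_record(record_id="small0", site_id="small",
                        continent=Continent.AMERICAS, age=4.0),
            make_record(record_id="small1", site_id="small",
                        continent=Continent.AMERICAS, age=9.0),
        ]
        chronos, report = group_proximate_sites(records, Continent.AMERICAS)
        assert [c.chrono_id for c in chronos] == ["big"]
        assert report.counts["americas_fewer_than_3_plots"] == 1

    def test_grouped_sites_need_two_distinct_ages(self):
        records = self._africa_site("a", 0.0, 0.0, ages=(12.0,)) + self._africa_site(
            "b", 0.5, 0.0, ages=(12.0,)
        )
        chronos, report = group_proximate_sites(records, Continent.AFRICA)
        assert chronos == []
        assert report.counts["fewer_than_2_distinct_ages"] == 1

    def test_mixed_continents_rejected(self):
        records = self._africa_site("a", 0.0, 0.0) + [
            make_record(record_id="x", site_id="x", continent=Continent.ASIA,
                        age=5.0)
        ]
        with pytest.raises(UsageError):
            group_proximate_sites(records, Continent.AFRICA)

    def test_idempotent(self):
        records = (
            self._africa_site("a", 0.0, 0.0)
            + self._africa_site("b", 1.2, 0.3)
            + self._africa_site("c", 10.0, 10.0)
        )
        first, _ = group_proximate_sites(records, Continent.AFRICA)
        again, _ = group_proximate_sites(
            [p for c in first for p in c.plots], Continent.AFRICA
        )
        assert {frozenset(c.member_site_ids) for c in first} == {
            frozenset(c.member_site_ids) for c in again
        }


class TestRecordValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(age=0.0), dict(age=-3.0), dict(agb=-1.0), dict(lat=95.0), dict(lon=190.0)],
    )
    def test_invalid_records_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            make_record(**kwargs)

    def test_american_chronosequence_needs_three_plots(self):
        plots = tuple(
            make_record(record_id=f"r{i}", continent=Continent.AMERICAS, age=float(i + 1))
            for i in range(2)
        )
        with pytest.raises(ValidationError):
            Chronosequence(
                chrono_id="c", continent=Continent.AMERICAS,
                ecozone=Ecozone.TROPICAL_RAINFOREST, plots=plots,
                member_site_ids=frozenset({"s"}),
            )


class TestCsvReaders:
    def test_chronosequence_round_trip_with_conversion(self, tmp_path):
        df = pd.DataFrame(
            {
                "record_id": ["r1", "r2"],
                "site_id": ["s1", "s1"],
                "continent": ["Africa", "Africa"],
                "ecozone": ["tropical_rainforest"] * 2,
                "lat": [1.0, 1.0],
                "lon": [2.0, 2.0],
                "stand_age": [10.0, 30.0],
                "value": [47.0, 120.0],
                "value_type": ["carbon", "agb"],
                "carbon_fraction": ["", ""],
                "in_continental_us": [False, False],
                "extraneous": ["x", "y"],
            }
        )
        path = tmp_path / "chrono.csv"
        df.to_csv(path, index=False)
        with pytest.warns(UserWarning, match="extraneous"):
            records = read_chronosequence_csv(path)
        assert records[0].abg_value == pytest.approx(100.0)
        assert records[1].abg_value == pytest.approx(120.0)

    def test_permanent_plots_grouped_by_id(self, tmp_path):
        df = pd.DataFrame(
            {
                "plot_id": ["p1", "p1", "p2"],
                "continent": ["Asia"] * 3,
                "ecozone": ["tropical_rainforest"] * 3,
                "status": ["old_growth"] * 3,
                "area_ha": [1.0, 1.0, 0.5],
                "interval_years": [5.0, 7.0, 4.0],
                "rate": [1.0, 2.0, -0.5],
                "value_type": ["agb"] * 3,
                "carbon_fraction": ["", "", ""],
            }
        )
        path = tmp_path / "plots.csv"
        df.to_csv(path, index=False)
        plots = read_permanent_plot_csv(path)
        assert [p.plot_id for p in plots] == ["p1", "p2"]
        assert plots[0].monitoring_years == pytest.approx(12.0)
        assert len(plots[0].censuses) == 2
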