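"""Semantic search, unit conversion, harmonization, climate binning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oceanpack import (
    AttributeQuery,
    ClimateZone,
    Injection,
    LoadedPackage,
    Predicate,
    UnitRegistry,
    build_harmonized_table,
    attach_env_context,
    climate_zone,
    convert_value,
    filter_samples,
    generate_package,
    search_attributes,
)
from oceanpack.errors import ColumnError, IncompatibleUnitsError, UnknownTermError
from oceanpack.harmonize import MICROMOLAR, MICROMOLE_PER_KG


NITRATE = "ENVO:3100022"
PHOSPHATE = "TEMP:0000001"
LATITUDE = "PMO:00000076"


class TestUnits:
    def test_metric_prefix_chain(self, registry):
        assert convert_value(1.0, "UO:0000064", "UO:0000065", registry) == 1000.0
        assert convert_value(1.0, "UO:0000062", "UO:0000065", registry) == 1e9

    def test_offset_conversion(self, registry):
        assert convert_value(25.0, "UO:0000027", "UO:0000012", registry) == 298.15

    def test_identity(self, registry):
        assert convert_value(3.5, "UO:0000064", "UO:0000064", registry) == 3.5

    def test_disjoint_dimensions_need_bridge(self, registry):
        with pytest.raises(IncompatibleUnitsError):
            convert_value(1.0, MICROMOLE_PER_KG, "UO:0000027", registry)
        with pytest.raises(IncompatibleUnitsError):
            convert_value(1.0, MICROMOLAR, MICROMOLE_PER_KG, registry)

    def test_density_bridge(self):
        reg = UnitRegistry()
        reg.add_unit(MICROMOLE_PER_KG)
        reg.add_unit(MICROMOLAR)
        reg.add_density_bridge(1.025)
        assert convert_value(1.025, MICROMOLAR, MICROMOLE_PER_KG, reg) == \
            pytest.approx(1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.sampled_from(["UO:0000062", "UO:0000063", "UO:0000064",
                            "UO:0000065", "UO:0000027", "UO:0000012"]),
           st.sampled_from(["UO:0000062", "UO:0000063", "UO:0000064",
                            "UO:0000065", "UO:0000027", "UO:0000012"]),
           st.floats(-1e6, 1e6, allow_nan=False))
    def test_round_trip(self, registry, a, b, v):
        if not registry.convertible(a, b):
            return
        back = convert_value(convert_value(v, a, b, registry), b, a, registry)
        assert back == pytest.approx(v, rel=1e-9, abs=1e-9)


class TestSearch:
    @pytest.fixture
    def packages(self, tmp_path):
        pkg, _ = generate_package(tmp_path / "p", n_samples=3, seed=8)
        # annotate phosphate with the *specific* chlorophyll-a term to
        # exercise subsumption: a field typed with a descendant concept
        from oceanpack import OntologyTermRef
        pkg.resource("chemistry").field("phosphate").rdf_type = \
            OntologyTermRef("ENVO:3100008")
        return [pkg]

    def test_descendant_query_finds_specific_field(self, packages, graph):
        hits = search_attributes(
            packages, graph,
            AttributeQuery("ENVO:3100036", include_descendants=True))
        assert [(m.field, m.exact) for m in hits] == [("phosphate", False)]

    def test_exact_query_misses_specific_field(self, packages, graph):
        hits = search_attributes(
            packages, graph,
            AttributeQuery("ENVO:3100036", include_descendants=False))
        assert hits == []

    def test_subsumption_superset_of_exact(self, packages, graph):
        for term in (NITRATE, "ENVO:3100036", "TEMP:0000022"):
            exact = set(search_attributes(
                packages, graph, AttributeQuery(term)))
            sub = set(search_attributes(
                packages, graph,
                AttributeQuery(term, include_descendants=True)))
            assert {(m.package, m.field) for m in exact} <= \
                {(m.package, m.field) for m in sub}

    def test_empty_package_list(self, graph):
        assert search_attributes([], graph, AttributeQuery(NITRATE)) == []

    def test_unknown_term_raises(self, packages, graph):
        with pytest.raises(UnknownTermError):
            search_attributes(packages, graph, AttributeQuery("ENVO:000nope"))


class TestHarmonize:
    def test_two_packages_single_unit_column(self, tmp_path, graph, registry):
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        generate_package(a_dir, n_samples=6, seed=21, name="pkg-a")
        generate_package(b_dir, n_samples=6, seed=22, name="pkg-b")
        loaded = [LoadedPackage.from_dir(a_dir), LoadedPackage.from_dir(b_dir)]
        # express package b's nitrate in nanomolar
        lb = loaded[1]
        from oceanpack import OntologyTermRef
        nit = lb.descriptor.resource("chemistry").field("nitrate")
        nit.unit_rdf_type = OntologyTermRef("UO:0000065")
        i = lb.tables["chemistry"].columns.index("nitrate")
        lb.tables["chemistry"].rows = [
            tuple(c * 1000.0 if j == i and isinstance(c, float) else c
                  for j, c in enumerate(row))
            for row in lb.tables["chemistry"].rows
        ]
        table = build_harmonized_table(loaded, graph, [NITRATE], registry)
        assert table.units[NITRATE] == MICROMOLAR
        pkgs_seen = {p.package for p in table.provenance.values()}
        assert pkgs_seen == {"pkg-a", "pkg-b"}
        # nanomolar values were converted back onto the micromolar scale
        vals = table.values[NITRATE].dropna()
        assert float(vals.max()) < 100.0

    def test_samples_missing_from_one_package_get_nulls(
            self, loaded_clean_package, graph, registry):
        lp, manifest = loaded_clean_package
        table = build_harmonized_table([lp], graph, [NITRATE, PHOSPHATE],
                                       registry)
        for sid, truth in manifest.sample_truth.items():
            for attr, key in ((NITRATE, "nitrate"), (PHOSPHATE, "phosphate")):
                cell = table.values.loc[sid, attr]
                if truth[key] is None:
                    assert np.isnan(cell)
                else:
                    assert cell == pytest.approx(truth[key])

    def test_conservation_of_contributed_values(
            self, loaded_clean_package, graph, registry):
        lp, manifest = loaded_clean_package
        table = build_harmonized_table([lp], graph, [NITRATE, PHOSPHATE],
                                       registry)
        contributed = sum(
            (v["nitrate"] is not None) + (v["phosphate"] is not None)
            for v in manifest.sample_truth.values())
        non_null = int(table.values.notna().sum().sum())
        assert non_null == contributed - len(table.conflicts)

    def test_provenance_rebuild_reproduces_values(
            self, loaded_clean_package, graph, registry):
        lp, _ = loaded_clean_package
        t1 = build_harmonized_table([lp], graph, [NITRATE], registry)
        t2 = build_harmonized_table([lp], graph, [NITRATE], registry)
        assert t1.values.equals(t2.values)
        assert t1.provenance == t2.provenance

    def test_env_context_attached(self, loaded_clean_package, graph, registry):
        lp, _ = loaded_clean_package
        table = build_harmonized_table([lp], graph, [NITRATE], registry)
        attach_env_context(table, [lp], graph)
        row = table.context.iloc[0]
        assert row["biome"].label == "marine biome"
        assert row["feature"].label == "sea surface layer"
        assert row["material"].label == "liquid water"
        assert table.context_flags == []

    def test_device_heterogeneity_surfaced(self, loaded_clean_package, graph,
                                           registry):
        lp, _ = loaded_clean_package
        table = build_harmonized_table([lp], graph, [NITRATE, PHOSPHATE],
                                       registry)
        devices = table.device_summary()
        assert devices[NITRATE] == ["OBI:0400115"]
        assert devices[PHOSPHATE] == ["OBI:0001057"]


class TestFilter:
    def test_non_null_co_selection_matches_manifest(
            self, loaded_clean_package, graph, registry):
        lp, manifest = loaded_clean_package
        table = build_harmonized_table([lp], graph, [NITRATE, PHOSPHATE],
                                       registry)
        out, removed = filter_samples(table, [
            Predicate(NITRATE, non_null=True),
            Predicate(PHOSPHATE, non_null=True),
        ])
        expected = [sid for sid, v in manifest.sample_truth.items()
                    if v["nitrate"] is not None and v["phosphate"] is not None]
        assert sorted(out.samples) == sorted(expected)
        assert removed == len(table.samples) - len(expected)

    def test_empty_predicates_is_identity(self, loaded_clean_package, graph,
                                          registry):
        lp, _ = loaded_clean_package
        table = build_harmonized_table([lp], graph, [NITRATE], registry)
        out, removed = filter_samples(table, [])
        assert removed == 0 and out.values.equals(table.values)

    def test_contradictory_predicate_rejected(self):
        with pytest.raises(ColumnError):
            Predicate(NITRATE, minimum=5, maximum=1)

    def test_unknown_attribute_rejected(self, loaded_clean_package, graph,
                                        registry):
        lp, _ = loaded_clean_package
        table = build_harmonized_table([lp], graph, [NITRATE], registry)
        with pytest.raises(ColumnError):
            filter_samples(table, [Predicate("ENVO:3100036", non_null=True)])


class TestClimateZone:
    @pytest.mark.parametrize("lat,zone", [
        (22.75, ClimateZone.TROPICAL),
        (0.0, ClimateZone.TROPICAL),
        (23.5, ClimateZone.TEMPERATE),   # boundary goes poleward
        (-45.0, ClimateZone.TEMPERATE),
        (66.5, ClimateZone.POLAR),
        (-70.0, ClimateZone.POLAR),
        (90.0, ClimateZone.POLAR),
    ])
    def test_binning(self, lat, zone):
        assert climate_zone(lat) is zone

    def test_zone_terms(self):
        assert ClimateZone.TROPICAL.term.curie == "ENVO:01000204"
        assert ClimateZone.TEMPERATE.term.curie == "ENVO:01000206"
        assert ClimateZone.POLAR.term.curie == "ENVO:01000238"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            climate_zone(90.5)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.floats(-90, 90, allow_nan=False))
    def test_partition_no_gaps_no_overlaps(self, lat):
        zones = [z for z in ClimateZone if climate_zone(lat) is z]
        assert len(zones) == 1
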