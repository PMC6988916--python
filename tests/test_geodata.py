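"""Unit ingestion, joining, projection and measurement."""

import json
import sqlite3

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Polygon, mapping

from forestspat import crs, geodata
from forestspat.geodata import (SampleId, area_weighted_mean,
                                project_and_measure, read_units)

from conftest import make_unit


def geographic_square(zone_spec: str, cx: float, cy: float, side: float
                      ) -> Polygon:
    """A square of the given side [m] centred at projected (cx, cy),
    expressed in geographic coordinates."""
    zone = crs.parse_zone(zone_spec)
    h = side / 2
    xs = np.array([cx - h, cx + h, cx + h, cx - h])
    ys = np.array([cy - h, cy - h, cy + h, cy + h])
    lon, lat = crs.utm_to_geographic(xs, ys, zone)
    return Polygon(zip(lon, lat))


def write_geojson(path, features):
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [
            {"type": "Feature", "properties": props,
             "geometry": mapping(geom)} for props, geom in features
        ]}, fh)


def attr_frame(ids):
    return pd.DataFrame({
        "unit_id": ids,
        "A_TOT": 200.0, "FA": 50.0, "FA_pot": 100.0, "P_TOT": 1000.0,
        "R_TOT": 4.0, "FL_TOT": 120.0, "CSI": 40.0,
    })


class TestReadUnits:
    def test_identity_join_populates_fields(self, tmp_path):
        sq = geographic_square("35S", 500_000, 8_400_000, 1000)
        write_geojson(tmp_path / "b.geojson", [({"unit_id": "a"}, sq)])
        attr_frame(["a"]).to_csv(tmp_path / "a.csv", index=False)
        units, rejects = read_units(tmp_path / "b.geojson", tmp_path / "a.csv",
                                    "unit_id", country="ZAM", level="micro")
        assert len(units) == 1 and rejects.empty
        u = units[0]
        assert (u.unit_id, u.country, u.A_TOT, u.CSI) == ("a", "ZAM", 200.0, 40.0)
        assert u.CY is None
        assert u.geometry is not None

    def test_unmatched_attribute_row_goes_to_rejects(self, tmp_path):
        sq = geographic_square("35S", 500_000, 8_400_000, 1000)
        write_geojson(tmp_path / "b.geojson", [({"unit_id": "a"}, sq)])
        attr_frame(["a", "ghost"]).to_csv(tmp_path / "a.csv", index=False)
        units, rejects = read_units(tmp_path / "b.geojson", tmp_path / "a.csv",
                                    "unit_id", country="ZAM", level="micro")
        assert [u.unit_id for u in units] == ["a"]
        assert rejects.unit_id.tolist() == ["ghost"]
        assert rejects.reason.iloc[0] == "no matching polygon"

    def test_unmatched_polygon_goes_to_rejects(self, tmp_path):
        sq = geographic_square("35S", 500_000, 8_400_000, 1000)
        sq2 = geographic_square("35S", 600_000, 8_400_000, 1000)
        write_geojson(tmp_path / "b.geojson",
                      [({"unit_id": "a"}, sq), ({"unit_id": "orphan"}, sq2)])
        attr_frame(["a"]).to_csv(tmp_path / "a.csv", index=False)
        _, rejects = read_units(tmp_path / "b.geojson", tmp_path / "a.csv",
                                "unit_id", country="ZAM", level="micro")
        assert rejects.unit_id.tolist() == ["orphan"]

    def test_duplicate_join_key_is_hard_error(self, tmp_path):
        sq = geographic_square("35S", 500_000, 8_400_000, 1000)
        write_geojson(tmp_path / "b.geojson", [({"unit_id": "a"}, sq)])
        attr_frame(["a", "a"]).to_csv(tmp_path / "a.csv", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_units(tmp_path / "b.geojson", tmp_path / "a.csv", "unit_id")

    def test_excel_attributes(self, tmp_path):
        sq = geographic_square("35S", 500_000, 8_400_000, 1000)
        write_geojson(tmp_path / "b.geojson", [({"unit_id": "a"}, sq)])
        attr_frame(["a"]).to_excel(tmp_path / "a.xlsx", index=False)
        units, _ = read_units(tmp_path / "b.geojson", tmp_path / "a.xlsx",
                              "unit_id", country="ZAM", level="micro")
        assert units[0].A_TOT == 200.0

    def test_wkt_csv_boundaries(self, tmp_path):
        sq = geographic_square("35S", 500_000, 8_400_000, 1000)
        pd.DataFrame({"unit_id": ["a"], "geometry": [sq.wkt]}).to_csv(
            tmp_path / "b.csv", index=False)
        attr_frame(["a"]).to_csv(tmp_path / "a.csv", index=False)
        units, _ = read_units(tmp_path / "b.csv", tmp_path / "a.csv",
                              "unit_id", country="ZAM", level="micro")
        assert units[0].geometry.equals_exact(sq, 1e-12)


def make_gpkg(path, features, layer="units"):
    """Minimal GeoPackage writer for test fixtures (header + ISO WKB)."""
    con = sqlite3.connect(path)
    con.execute("CREATE TABLE gpkg_contents "
                "(table_name TEXT, data_type TEXT)")
    con.execute("INSERT INTO gpkg_contents VALUES (?, 'features')", (layer,))
    con.execute("CREATE TABLE gpkg_geometry_columns "
                "(table_name TEXT, column_name TEXT)")
    con.execute("INSERT INTO gpkg_geometry_columns VALUES (?, 'geom')",
                (layer,))
    con.execute(f'CREATE TABLE "{layer}" (unit_id TEXT, geom BLOB)')
    import struct
    for props, geom in features:
        header = b"GP" + bytes([0, 0b00000001]) + struct.pack("<i", 4326)
        blob = header + shapely.to_wkb(geom)
        con.execute(f'INSERT INTO "{layer}" VALUES (?, ?)',
                    (props["unit_id"], blob))
    con.commit()
    con.close()


def test_geopackage_reader(tmp_path):
    sq = geographic_square("35S", 500_000, 8_400_000, 1000)
    make_gpkg(tmp_path / "b.gpkg", [({"unit_id": "a"}, sq)])
    attr_frame(["a"]).to_csv(tmp_path / "a.csv", index=False)
    units, rejects = read_units(tmp_path / "b.gpkg", tmp_path / "a.csv",
                                "unit_id", country="ZAM", level="micro")
    assert rejects.empty
    assert units[0].geometry.equals_exact(sq, 1e-9)


class TestProjectAndMeasure:
    def test_square_km_measures_100_ha(self):
        sq = geographic_square("35S", 500_000, 8_400_000, 1000)
        unit = make_unit(A_TOT=np.nan)
        unit.geometry = sq
        out = project_and_measure([unit], crs_spec="35S", set_area=True)[0]
        assert out.A_TOT == pytest.approx(100.0, rel=1e-6)

    def test_centroid_of_symmetric_square_is_its_centre(self):
        sq = geographic_square("35S", 512_345, 8_433_000, 2000)
        unit = make_unit()
        unit.geometry = sq
        out = project_and_measure([unit], crs_spec="35S")[0]
        assert out.centroid[0] == pytest.approx(512_345, abs=1e-3)
        assert out.centroid[1] == pytest.approx(8_433_000, abs=1e-3)

    def test_country_default_matches_explicit_zone(self):
        sq = geographic_square("35S", 500_000, 8_400_000, 1000)
        unit = make_unit(country="ZAM")
        unit.geometry = sq
        by_default = project_and_measure([unit])[0]
        by_spec = project_and_measure([unit], crs_spec="35S")[0]
        assert by_default.centroid == by_spec.centroid

    def test_degenerate_geometry_raises_with_unit_name(self):
        unit = make_unit(unit_id="flatland")
        unit.geometry = Polygon([(27, -14), (27, -14.001), (27, -14)])
        with pytest.raises(ValueError, match="flatland"):
            project_and_measure([unit], crs_spec="35S")

    def test_total_area_invariant_under_ordering(self, rng):
        units = []
        for i in range(8):
            u = make_unit(unit_id=f"u{i}")
            u.geometry = geographic_square(
                "35S", 450_000 + 20_000 * i, 8_380_000, 1000 * (i + 1))
            units.append(u)
        fwd = project_and_measure(units, crs_spec="35S", set_area=True)
        perm = [units[i] for i in rng.permutation(8)]
        rev = project_and_measure(perm, crs_spec="35S", set_area=True)
        assert sum(u.A_TOT for u in fwd) == pytest.approx(
            sum(u.A_TOT for u in rev), rel=1e-12)


class TestAreaWeightedMean:
    def test_constant_values(self):
        assert area_weighted_mean([(10, 1), (10, 99)]) == 10

    def test_symmetry(self):
        assert area_weighted_mean([(0, 1), (100, 1)]) == 50

    def test_matches_direct_summation(self, rng):
        pairs = list(zip(rng.normal(50, 10, 100), rng.uniform(0.1, 5, 100)))
        num = sum(v * a for v, a in pairs)
        den = sum(a for _, a in pairs)
        assert area_weighted_mean(pairs) == pytest.approx(num / den, rel=1e-12)

    def test_zero_total_area_raises(self):
        with pytest.raises(ValueError):
            area_weighted_mean([(1.0, 0.0), (2.0, 0.0)])


def test_unit_table_round_trip(tmp_path):
    units = [make_unit(unit_id=f"u{i}", A_TOT=200.0 + i * np.pi,
                       CY=None if i % 2 else 5.5e6 + i,
                       centroid=(1000.0 * i, 2000.0 * i + 0.123456789))
             for i in range(10)]
    geodata.write_units(units, tmp_path / "units.csv")
    back = geodata.read_unit_table(tmp_path / "units.csv")
    assert len(back) == 10
    for a, b in zip(units, back):
        assert a.unit_id == b.unit_id
        assert a.A_TOT == b.A_TOT
        assert a.CY == b.CY
        assert a.centroid == b.centroid


def test_sample_id_validation():
    assert str(SampleId("PAN", "meso")) == "PAN:meso"
    assert SampleId.parse("zam:MICRO") == SampleId("ZAM", "micro")
    with pytest.raises(ValueError):
        SampleId("USA", "macro")
    with pytest.raises(ValueError):
        SampleId("ZAM", "nano")
    assert len(geodata.ALL_SAMPLES) == 12


def test_unit_record_invariants():
    with pytest.raises(ValueError, match="FA"):
        make_unit(FA=150.0, FA_pot=100.0).validate()
    with pytest.raises(ValueError, match="CSI"):
        make_unit(CSI=140.0).validate()
    make_unit().validate()
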