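import json

import numpy as np
import pytest

from metalmap import (
    Annotation,
    AnnotationSet,
    PlanarTransform,
    parse_asap_xml,
    parse_geojson,
    rasterize,
    transform_annotations,
    write_geojson,
)
from metalmap.annotate import polygon_area


def point_in_polygon_evenodd(x, y, rings):
    """Independent even-odd (crossing number) oracle over all rings."""
    crossings = 0
    for ring in rings:
        v = np.asarray(ring, dtype=float)
        n = len(v)
        for i in range(n):
            x1, y1 = v[i]
            x2, y2 = v[(i + 1) % n]
            if (y1 > y) != (y2 > y):
                xc = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
                if x < xc:
                    crossings += 1
    return crossings % 2 == 1


def square(label, x0, y0, side, frame="wsi"):
    ext = [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]
    return Annotation(label=label, exterior=np.array(ext, float), frame_id=frame)


def geojson_doc(features):
    return {"type": "FeatureCollection", "features": features}


def polygon_feature(coords, classification=None, name=None, gtype="Polygon"):
    props = {}
    if classification:
        props["classification"] = {"name": classification}
    if name:
        props["name"] = name
    return {
        "type": "Feature",
        "geometry": {"type": gtype, "coordinates": coords},
        "properties": props,
    }


class TestGeoJSON:
    def test_single_square_classified(self, tmp_path):
        doc = geojson_doc(
            [polygon_feature([[[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]]],
                             classification="Tumor")]
        )
        p = tmp_path / "a.geojson"
        p.write_text(json.dumps(doc))
        aset = parse_geojson(p, pixel_size_um=0.25)
        assert len(aset) == 1
        assert aset.annotations[0].label == "Tumor"
        # pixel -> µm conversion applied
        assert aset.annotations[0].exterior.max() == pytest.approx(2.5)

    def test_unclassified_fallback(self, tmp_path):
        doc = geojson_doc(
            [polygon_feature([[[0, 0], [4, 0], [4, 4], [0, 4], [0, 0]]])]
        )
        p = tmp_path / "b.geojson"
        p.write_text(json.dumps(doc))
        assert parse_geojson(p, 1.0).annotations[0].label == "unclassified"

    def test_multipolygon_split(self, tmp_path):
        coords = [
            [[[0, 0], [4, 0], [4, 4], [0, 4], [0, 0]]],
            [[[10, 10], [14, 10], [14, 14], [10, 14], [10, 10]]],
        ]
        doc = geojson_doc(
            [polygon_feature(coords, classification="Fat", gtype="MultiPolygon")]
        )
        p = tmp_path / "c.geojson"
        p.write_text(json.dumps(doc))
        aset = parse_geojson(p, 1.0)
        assert len(aset) == 2
        assert aset.labels == ["Fat", "Fat"]

    def test_non_polygon_skipped_with_warning(self, tmp_path):
        doc = geojson_doc(
            [
                polygon_feature([[[0, 0], [4, 0], [4, 4], [0, 4], [0, 0]]]),
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [1, 1]},
                    "properties": {},
                },
            ]
        )
        p = tmp_path / "d.geojson"
        p.write_text(json.dumps(doc))
        with pytest.warns(UserWarning, match="skipped 1"):
            aset = parse_geojson(p, 1.0)
        assert len(aset) == 1

    def test_malformed_json_raises(self, tmp_path):
        p = tmp_path / "bad.geojson"
        p.write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            parse_geojson(p, 1.0)

    def test_round_trip_preserves_labels_vertices_and_unicode(self, tmp_path, rng):
        anns = []
        for label in ["Tumor", "Normal Fibrous Stroma", "Stromä-µ区"]:
            v = rng.uniform(0, 1000, (6, 2))
            v = v[np.argsort(np.arctan2(*(v - v.mean(0)).T[::-1]))]  # simple polygon
            anns.append(Annotation(label=label, exterior=v, frame_id="wsi"))
        aset = AnnotationSet(anns, frame_id="wsi")
        p = tmp_path / "rt.geojson"
        write_geojson(aset, p, pixel_size_um=0.25)
        back = parse_geojson(p, pixel_size_um=0.25)
        assert back.labels == aset.labels
        for a, b in zip(aset.annotations, back.annotations):
            np.testing.assert_allclose(a.exterior, b.exterior, atol=1e-9)

    def test_holes_survive_round_trip(self, tmp_path):
        a = Annotation(
            "Duct",
            np.array([[0.0, 0], [100, 0], [100, 100], [0, 100]]),
            holes=[np.array([[40.0, 40], [60, 40], [60, 60], [40, 60]])],
            frame_id="wsi",
        )
        p = tmp_path / "h.geojson"
        write_geojson(AnnotationSet([a]), p, 1.0)
        back = parse_geojson(p, 1.0)
        assert len(back.annotations[0].holes) == 1
        np.testing.assert_allclose(back.annotations[0].holes[0], a.holes[0],
                                   atol=1e-9)

    def test_empty_set_valid_featurecollection(self, tmp_path):
        p = tmp_path / "empty.geojson"
        write_geojson(AnnotationSet([], frame_id="wsi"), p, 1.0)
        doc = json.loads(p.read_text())
        assert doc["type"] == "FeatureCollection"
        assert doc["features"] == []
        assert len(parse_geojson(p, 1.0)) == 0


ASAP_DOC = """<?xml version="1.0"?>
<ASAP_Annotations>
  <Annotations>
    <Annotation Name="Annotation 0" Type="Polygon" PartOfGroup="Stroma">
      <Coordinates>
        <Coordinate Order="2" X="10" Y="10"/>
        <Coordinate Order="0" X="0" Y="0"/>
        <Coordinate Order="3" X="0" Y="10"/>
        <Coordinate Order="1" X="10" Y="0"/>
      </Coordinates>
    </Annotation>
  </Annotations>
</ASAP_Annotations>
"""


class TestASAP:
    def test_polygon_with_group(self, tmp_path):
        p = tmp_path / "a.xml"
        p.write_text(ASAP_DOC)
        aset = parse_asap_xml(p, pixel_size_um=1.0)
        assert len(aset) == 1
        a = aset.annotations[0]
        assert a.label == "Stroma"
        assert len(a.exterior) == 4

    def test_vertices_ordered_by_order_attribute(self, tmp_path):
        p = tmp_path / "a.xml"
        p.write_text(ASAP_DOC)
        a = parse_asap_xml(p, 1.0).annotations[0]
        np.testing.assert_array_equal(
            a.exterior, [[0, 0], [10, 0], [10, 10], [0, 10]]
        )

    def test_empty_document(self, tmp_path):
        p = tmp_path / "e.xml"
        p.write_text("<ASAP_Annotations><Annotations/></ASAP_Annotations>")
        assert len(parse_asap_xml(p, 1.0)) == 0

    def test_non_polygon_skipped(self, tmp_path):
        doc = """<ASAP_Annotations><Annotations>
        <Annotation Name="dot" Type="Dot" PartOfGroup="None">
          <Coordinates><Coordinate Order="0" X="1" Y="1"/></Coordinates>
        </Annotation></Annotations></ASAP_Annotations>"""
        p = tmp_path / "d.xml"
        p.write_text(doc)
        with pytest.warns(UserWarning, match="skipped"):
            assert len(parse_asap_xml(p, 1.0)) == 0

    def test_malformed_xml_raises(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<ASAP_Annotations><unclosed>")
        with pytest.raises(ValueError, match="malformed"):
            parse_asap_xml(p, 1.0)


class TestTransformAnnotations:
    def test_identity(self):
        aset = AnnotationSet([square("Tumor", 0, 0, 10)], frame_id="wsi")
        out = transform_annotations(aset, PlanarTransform.identity("wsi"))
        np.testing.assert_array_equal(
            out.annotations[0].exterior, aset.annotations[0].exterior
        )

    def test_scale_two_quadruples_area(self):
        aset = AnnotationSet([square("Tumor", 0, 0, 10)], frame_id="wsi")
        T = PlanarTransform([[2.0, 0, 0], [0, 2.0, 0]],
                            source_frame_id="wsi", target_frame_id="big")
        out = transform_annotations(aset, T)
        assert out.annotations[0].area == pytest.approx(400.0)
        assert out.frame_id == "big"

    def test_frame_mismatch_rejected(self):
        aset = AnnotationSet([square("Tumor", 0, 0, 10)], frame_id="wsi")
        T = PlanarTransform.identity("elemental")
        with pytest.raises(ValueError, match="frame"):
            transform_annotations(aset, T)

    def test_area_covariance_shoelace_oracle(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            A = rng.normal(0, 2, (2, 2))
            while abs(np.linalg.det(A)) < 0.1:
                A = rng.normal(0, 2, (2, 2))
            T = PlanarTransform(np.column_stack([A, rng.normal(0, 50, 2)]),
                                source_frame_id="wsi", target_frame_id="x")
            v = rng.uniform(0, 100, (8, 2))
            hull_order = np.argsort(np.arctan2(*(v - v.mean(0)).T[::-1]))
            poly = Annotation("r", v[hull_order], frame_id="wsi")
            out = transform_annotations(AnnotationSet([poly]), T).annotations[0]
            want = abs(np.linalg.det(A)) * abs(polygon_area(poly.exterior))
            got = abs(polygon_area(out.exterior))
            assert got == pytest.approx(want, rel=1e-9)


class TestRasterize:
    def test_empty_set_all_zero(self):
        lm = rasterize(AnnotationSet([], frame_id="elemental"), (5, 5), 1.0)
        assert (lm.labels == 0).all()

    def test_square_covering_four_centers(self):
        # centers at integer µm; square (0.5,0.5)-(2.5,2.5) contains 4 of them
        a = Annotation("Tumor", np.array([[0.5, 0.5], [2.5, 0.5],
                                          [2.5, 2.5], [0.5, 2.5]]),
                       frame_id="elemental")
        lm = rasterize(AnnotationSet([a], frame_id="elemental"), (4, 4), 1.0)
        assert lm.labels.sum() == 4
        assert (lm.labels[1:3, 1:3] == 1).all()

    def test_overlap_last_drawn_wins_both_orders(self):
        a = square("A", 0, 0, 4, frame="elemental")
        b = square("B", 2, 2, 4, frame="elemental")
        ab = rasterize(AnnotationSet([a, b], frame_id="elemental"), (8, 8), 1.0)
        ba = rasterize(AnnotationSet([b, a], frame_id="elemental"), (8, 8), 1.0)
        # overlap zone (strictly inside both): center at (3, 3)
        assert ab.labels[3, 3] == [k for k, v in ab.label_table.items() if v == "B"][0]
        assert ba.labels[3, 3] == [k for k, v in ba.label_table.items() if v == "A"][0]

    def test_matches_point_in_polygon_oracle(self, rng):
        for _ in range(5):
            v = rng.uniform(2, 48, (7, 2))
            v = v[np.argsort(np.arctan2(*(v - v.mean(0)).T[::-1]))]
            hole = v.mean(0) + (v - v.mean(0)) * 0.25
            a = Annotation("R", v, holes=[hole], frame_id="elemental")
            lm = rasterize(AnnotationSet([a], frame_id="elemental"), (50, 50), 1.0)
            rings = [a.exterior, a.holes[0]]
            for r in range(50):
                for c in range(50):
                    want = point_in_polygon_evenodd(float(c), float(r), rings)
                    assert (lm.labels[r, c] != 0) == want, (r, c)

    def test_labelled_area_converges_with_resolution(self):
        a = square("R", 3.0, 3.0, 40.0, frame="elemental")
        true_area = 1600.0
        perimeter = 160.0
        for ps in (4.0, 2.0, 1.0):
            n = int(np.ceil(50 / ps))
            lm = rasterize(AnnotationSet([a], frame_id="elemental"), (n, n), ps)
            raster_area = (lm.labels > 0).sum() * ps * ps
            assert abs(raster_area - true_area) <= 2 * perimeter * ps

    def test_region_mask_lookup(self):
        a = square("Tumor", 0.5, 0.5, 2, frame="elemental")
        lm = rasterize(AnnotationSet([a], frame_id="elemental"), (5, 5), 1.0)
        assert lm.region_mask("Tumor").sum() == (lm.labels > 0).sum()
        with pytest.raises(KeyError):
            lm.region_mask("Nope")
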