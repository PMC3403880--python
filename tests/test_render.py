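"""Color rules, depiction providers, and image composition."""

import xml.etree.ElementTree as ET

import pytest
from hypothesis import given, settings, strategies as st

from moleculecloud.layout import CloudItem, LayoutConfig, greedy_place
from moleculecloud.render import (CLASS_PALETTE, BoxColor, ColorRule,
                                  MockProvider, RDKitProvider, activity_color,
                                  class_color, compose, compose_png,
                                  record_color)
from moleculecloud.substructure import Kind, SubstructureRecord

SVG_NS = "{http://www.w3.org/2000/svg}"


class TestActivityColor:
    rule = ColorRule(scheme="activity_intensity")

    def test_zero_ratio_means_no_box(self):
        assert activity_color(0.0, self.rule) is None

    def test_full_ratio_is_saturated_magenta(self):
        c = activity_color(1.0, self.rule)
        assert c == BoxColor("#FF00FF", 1.0)

    def test_opacity_is_linear(self):
        half = activity_color(0.5, self.rule)
        full = activity_color(1.0, self.rule)
        assert half.opacity == pytest.approx(full.opacity / 2)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            activity_color(1.5, self.rule)


class TestClassColor:
    rule = ColorRule(scheme="target_class")

    def test_dominant_kinase_is_blue(self):
        assert class_color({"kinase": 0.9, "GPCR": 0.1}, self.rule) \
            == BoxColor(CLASS_PALETTE["kinase"])

    def test_split_activity_is_uncolored(self):
        assert class_color({"kinase": 0.5, "GPCR": 0.5}, self.rule) is None

    def test_threshold_is_inclusive(self):
        assert class_color({"protease": 0.70}, self.rule) \
            == BoxColor(CLASS_PALETTE["protease"])

    def test_unknown_class_raises_with_accepted_labels(self):
        with pytest.raises(ValueError, match="GPCR"):
            class_color({"martian": 1.0}, self.rule)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=6))
    @settings(derandomize=True, max_examples=80)
    def test_colored_iff_exactly_one_class_reaches_threshold(self, raw):
        labels = list(CLASS_PALETTE)[:len(raw)]
        total = sum(raw)
        fractions = {c: (v / total if total > 1 else v)
                     for c, v in zip(labels, raw)}
        winners = [c for c, f in fractions.items() if f >= 0.70]
        got = class_color(fractions, self.rule)
        if len(winners) == 1:
            assert got == BoxColor(CLASS_PALETTE[winners[0]])
        else:
            assert got is None

    def test_threshold_must_demand_majority(self):
        with pytest.raises(ValueError):
            ColorRule(scheme="target_class", class_threshold=0.4)


def _records_and_items(provider, smiles_list, scheme="none", ratios=None,
                       fractions=None):
    rule = ColorRule(scheme=scheme)
    records, items = {}, []
    for k, smi in enumerate(smiles_list):
        rec = SubstructureRecord(
            smi, Kind.SCAFFOLD, 10 - k,
            activity_ratio=(ratios or {}).get(smi),
            class_fractions=(fractions or {}).get(smi, {}))
        mol = provider.parse(smi)
        w, h = provider.extent(mol)
        records[smi] = rec
        items.append(CloudItem(smi, w, h))
    return records, items, rule


class TestCompose:
    cfg = LayoutConfig(canvas_width=600, canvas_height=400, grid_nx=20,
                       grid_ny=14)

    def test_empty_item_list_is_blank_canvas(self):
        doc = compose([], {}, MockProvider(), ColorRule(), self.cfg)
        root = ET.fromstring(doc)
        assert root.get("width") == "600"
        assert not [g for g in root.iter(SVG_NS + "g")]

    def test_single_structure_centered(self):
        provider = MockProvider()
        records, items, rule = _records_and_items(provider, ["c1ccccc1"])
        placed = greedy_place(items, self.cfg)
        doc = compose(placed, records, provider, rule, self.cfg)
        root = ET.fromstring(doc)
        groups = [g for g in root.iter(SVG_NS + "g")
                  if g.get("class") == "structure"]
        assert len(groups) == 1
        assert "translate(" in groups[0].get("transform")

    def test_group_count_and_no_boxes_without_scheme(self):
        provider = MockProvider()
        records, items, rule = _records_and_items(
            provider, ["c1ccccc1", "c1ccncc1", "C1CCNCC1"])
        placed = greedy_place(items, self.cfg)
        doc = compose(placed, records, provider, rule, self.cfg)
        root = ET.fromstring(doc)
        groups = [g for g in root.iter(SVG_NS + "g")
                  if g.get("class") == "structure"]
        assert len(groups) == 3
        for g in groups:
            fills = {r.get("fill") for r in g.iter(SVG_NS + "rect")}
            assert fills <= {"none"}

    def test_activity_boxes_present_with_ratio(self):
        provider = MockProvider()
        records, items, rule = _records_and_items(
            provider, ["c1ccncc1", "C1CCNCC1"], scheme="activity_intensity",
            ratios={"c1ccncc1": 0.8, "C1CCNCC1": 0.0})
        placed = greedy_place(items, self.cfg)
        doc = compose(placed, records, provider, rule, self.cfg)
        assert doc.count('fill="#FF00FF"') == 1
        assert 'fill-opacity="0.800"' in doc

    def test_depiction_failure_skips_structure(self):
        provider = MockProvider()
        records, items, rule = _records_and_items(provider, ["c1ccccc1"])
        bad = SubstructureRecord("has space", Kind.SCAFFOLD, 1)
        records["bad"] = bad
        items.append(CloudItem("bad", 30, 20))
        placed = greedy_place(items, self.cfg)
        warnings = []
        doc = compose(placed, records, provider, rule, self.cfg,
                      warnings=warnings)
        root = ET.fromstring(doc)
        groups = [g for g in root.iter(SVG_NS + "g")
                  if g.get("class") == "structure"]
        assert len(groups) == 1 and len(warnings) == 1

    def test_compose_is_deterministic(self):
        provider = MockProvider()
        records, items, rule = _records_and_items(
            provider, ["c1ccccc1", "c1ccncc1"])
        placed = greedy_place(items, self.cfg)
        a = compose(placed, records, provider, rule, self.cfg)
        b = compose(placed, records, provider, rule, self.cfg)
        assert a == b


class TestRDKitProvider:
    def test_extent_and_drawing_aspect_agree(self):
        provider = RDKitProvider()
        mol = provider.parse("c1ccc(-c2ccccc2)cc1")
        w, h = provider.extent(mol)
        assert w > h  # biphenyl is wide
        doc = provider.draw_svg(mol, w, h)
        root = ET.fromstring(doc)
        dw = float(root.get("width").replace("px", ""))
        dh = float(root.get("height").replace("px", ""))
        assert dw / dh == pytest.approx(w / h, rel=0.05)

    def test_parse_failure_raises(self):
        with pytest.raises(ValueError):
            RDKitProvider().parse(")(")

    def test_canonical_matches_aggregation_key(self):
        provider = RDKitProvider()
        from moleculecloud.substructure import canonicalize
        assert provider.canonical(provider.parse("C1=CC=CC=C1")) \
            == canonicalize("c1ccccc1")

    def test_png_composition(self):
        provider = RDKitProvider()
        cfg = LayoutConfig(canvas_width=300, canvas_height=200, grid_nx=10,
                           grid_ny=8)
        records, items, rule = _records_and_items(provider, ["c1ccccc1"])
        placed = greedy_place(items, cfg)
        img = compose_png(placed, records, provider, rule, cfg)
        assert img.size == (300, 200)
        # the molecule must actually have been drawn (non-white pixels)
        assert img.convert("L").getextrema()[0] < 255


def test_record_color_dispatch():
    rec = SubstructureRecord("c1ccccc1", Kind.SCAFFOLD, 5, activity_ratio=0.3,
                             class_fractions={"GPCR": 0.9})
    assert record_color(rec, ColorRule(scheme="none")) is None
    assert record_color(rec, ColorRule(scheme="activity_intensity")).opacity \
        == pytest.approx(0.3)
    assert record_color(rec, ColorRule(scheme="target_class")).hex \
        == CLASS_PALETTE["GPCR"]
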