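"""Depiction and composition of the final cloud image.

Chemistry enters the pipeline only through a :class:`DepictionProvider` —
the pluggable contract any toolkit must satisfy (parse, canonicalize,
measure, draw).  The default provider binds to RDKit; a toolkit-free mock
provider (labelled boxes sized by text length) keeps the whole pipeline
testable without any depiction engine.

Color coding carries extra information on a structure's background box:
*activity intensity* renders the box in magenta whose opacity equals the
fraction of bioactive molecules containing the scaffold, and *target class*
colors the box by protein target family when at least 70% of the molecules
containing the scaffold hit a single class (mixed-activity scaffolds stay
uncolored).
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

from .layout import CloudItem, LayoutConfig
from .substructure import SubstructureRecord

__all__ = [
    "DepictionProvider",
    "RDKitProvider",
    "MockProvider",
    "BoxColor",
    "ColorRule",
    "CLASS_PALETTE",
    "activity_color",
    "class_color",
    "record_color",
    "compose",
    "compose_png",
]


@runtime_checkable
class DepictionProvider(Protocol):
    """What a chemistry toolkit must supply to render a cloud."""

    def parse(self, smiles: str):
        """Parse SMILES to a toolkit molecule; raise ValueError on failure."""

    def canonical(self, mol) -> str:
        """Canonical SMILES of a parsed molecule."""

    def extent(self, mol) -> tuple[float, float]:
        """Natural (width, height) of the depiction at unit scale, in canvas units."""

    def draw_svg(self, mol, width: float, height: float) -> str:
        """Standalone SVG document of the molecule, transparent background."""

    def draw_png(self, mol, width: int, height: int):
        """PIL image (RGBA, transparent background) of the molecule."""


class RDKitProvider:
    """Default provider on the RDKit drawing engine.

    ``px_per_angstrom`` sets the natural size of a depiction from its 2D
    coordinate bounding box; ``margin`` pads it so bond labels never touch
    the frame.
    """

    def __init__(self, px_per_angstrom: float = 22.0, margin: float = 14.0):
        self.px_per_angstrom = px_per_angstrom
        self.margin = margin

    def parse(self, smiles: str):
        from rdkit import Chem
        from rdkit.Chem import rdDepictor

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        rdDepictor.Compute2DCoords(mol)
        return mol

    def canonical(self, mol) -> str:
        from rdkit import Chem

        return Chem.MolToSmiles(mol)

    def extent(self, mol) -> tuple[float, float]:
        conf = mol.GetConformer()
        xs = [conf.GetAtomPosition(i).x for i in range(mol.GetNumAtoms())]
        ys = [conf.GetAtomPosition(i).y for i in range(mol.GetNumAtoms())]
        dx = (max(xs) - min(xs)) if xs else 1.0
        dy = (max(ys) - min(ys)) if ys else 1.0
        return (dx * self.px_per_angstrom + 2 * self.margin,
                dy * self.px_per_angstrom + 2 * self.margin)

    def _drawer(self, cls, width: int, height: int):
        d = cls(width, height)
        opts = d.drawOptions()
        opts.clearBackground = False
        opts.padding = 0.08
        return d

    def draw_svg(self, mol, width: float, height: float) -> str:
        from rdkit.Chem.Draw import rdMolDraw2D

        d = self._drawer(rdMolDraw2D.MolDraw2DSVG, int(round(width)), int(round(height)))
        rdMolDraw2D.PrepareAndDrawMolecule(d, mol)
        d.FinishDrawing()
        return d.GetDrawingText()

    def draw_png(self, mol, width: int, height: int):
        from PIL import Image
        from rdkit.Chem.Draw import rdMolDraw2D

        d = self._drawer(rdMolDraw2D.MolDraw2DCairo, width, height)
        rdMolDraw2D.PrepareAndDrawMolecule(d, mol)
        d.FinishDrawing()
        return Image.open(io.BytesIO(d.GetDrawingText())).convert("RGBA")


class MockProvider:
    """Toolkit-free stand-in: each structure is a labelled box whose width
    grows with the SMILES length.  Lets every pipeline stage run and be
    tested without a chemistry toolkit."""

    char_width = 8.0
    line_height = 26.0

    def parse(self, smiles: str):
        if not smiles or " " in smiles:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        return smiles

    def canonical(self, mol) -> str:
        return str(mol)

    def extent(self, mol) -> tuple[float, float]:
        return (len(str(mol)) * self.char_width + 10, self.line_height)

    def draw_svg(self, mol, width: float, height: float) -> str:
        label = _xml_escape(str(mol))
        return (f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:g}" '
                f'height="{height:g}"><rect x="0" y="0" width="{width:g}" '
                f'height="{height:g}" fill="none" stroke="black"/>'
                f'<text x="{width / 2:g}" y="{height * 0.7:g}" font-size="{height * 0.55:g}" '
                f'text-anchor="middle">{label}</text></svg>')

    def draw_png(self, mol, width: int, height: int):
        from PIL import Image, ImageDraw

        img = Image.new("RGBA", (width, height), (0, 0, 0, 0))
        d = ImageDraw.Draw(img)
        d.rectangle([0, 0, width - 1, height - 1], outline=(0, 0, 0, 255))
        d.text((4, height // 4), str(mol), fill=(0, 0, 0, 255))
        return img


def _xml_escape(s: str) -> str:
    return (s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
            .replace('"', "&quot;"))


# --- color coding -----------------------------------------------------------

@dataclass(frozen=True)
class BoxColor:
    """Background box fill: hex color + opacity in [0, 1]."""

    hex: str
    opacity: float = 1.0


#: Fixed palette for the six protein target classes.
CLASS_PALETTE: dict[str, str] = {
    "GPCR": "#FF00FF",            # magenta
    "kinase": "#3050F8",          # blue
    "protease": "#E00000",        # red
    "other_enzyme": "#20A020",    # green
    "nuclear_receptor": "#8B5A2B",  # brown
    "ion_channel": "#F0D000",     # yellow
}

INTENSITY_HUE = "#FF00FF"  # magenta, as used for bioactivity shading


@dataclass(frozen=True)
class ColorRule:
    """Which color scheme applies and with what parameters.

    ``class_threshold`` is the minimum fraction of a scaffold's molecules
    that must hit one target class for the box to take that class's color;
    it must exceed 0.5 so the class is unique.
    """

    scheme: str = "none"  # none | activity_intensity | target_class
    class_palette: dict[str, str] = field(default_factory=lambda: dict(CLASS_PALETTE))
    class_threshold: float = 0.70
    intensity_hue: str = INTENSITY_HUE

    def __post_init__(self) -> None:
        if self.scheme not in ("none", "activity_intensity", "target_class"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not (0.5 < self.class_threshold <= 1.0):
            raise ValueError("class_threshold must be in (0.5, 1.0]")


def activity_color(activity_ratio: float, rule: ColorRule) -> BoxColor | None:
    """Magenta box whose opacity equals the bioactive fraction; no box at 0."""
    if not (0.0 <= activity_ratio <= 1.0):
        raise ValueError(f"activity_ratio {activity_ratio} outside [0, 1]")
    if activity_ratio == 0.0:
        return None
    return BoxColor(rule.intensity_hue, activity_ratio)


def class_color(class_fractions: dict[str, float], rule: ColorRule) -> BoxColor | None:
    """Palette color of the single target class reaching the threshold
    (inclusive); None when no class, or more than one, qualifies."""
    unknown = sorted(set(class_fractions) - set(rule.class_palette))
    if unknown:
        raise ValueError(f"unknown target class(es) {unknown}; accepted: "
                         f"{sorted(rule.class_palette)}")
    winners = [c for c, f in class_fractions.items() if f >= rule.class_threshold]
    if len(winners) != 1:
        return None
    return BoxColor(rule.class_palette[winners[0]])


def record_color(record: SubstructureRecord, rule: ColorRule) -> BoxColor | None:
    """Apply the configured scheme to one record."""
    if rule.scheme == "activity_intensity":
        return activity_color(record.activity_ratio or 0.0, rule)
    if rule.scheme == "target_class":
        return class_color(record.class_fractions, rule)
    return None


# --- composition ------------------------------------------------------------

_SVG_OPEN_RE = re.compile(r"<svg\b[^>]*>", re.DOTALL)


def _svg_inner(doc: str) -> str:
    """Strip the XML prolog and outer <svg> element from a standalone SVG."""
    m = _SVG_OPEN_RE.search(doc)
    if m is None:
        raise ValueError("provider did not return an SVG document")
    body = doc[m.end():]
    end = body.rfind("</svg>")
    return body[:end] if end >= 0 else body


def compose(items: list[CloudItem], records: dict[str, SubstructureRecord],
            provider: DepictionProvider, rule: ColorRule, cfg: LayoutConfig,
            box_padding: float = 0.05, warnings: list | None = None) -> str:
    """Assemble the final cloud as a standalone SVG document.

    Structures are drawn in ascending frame area, so the largest are painted
    last and never fully hidden.  Each structure sits in a group translated
    to its layout position, optionally over a rounded background box (5%
    padding).  Records that fail to depict are skipped with a warning; the
    document is deterministic for fixed inputs.
    """
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{cfg.canvas_width:g}" height="{cfg.canvas_height:g}" '
        f'viewBox="0 0 {cfg.canvas_width:g} {cfg.canvas_height:g}">',
        f'<rect x="0" y="0" width="{cfg.canvas_width:g}" '
        f'height="{cfg.canvas_height:g}" fill="white"/>',
    ]
    for it in sorted(items, key=lambda q: (q.area, q.id)):
        rec = records[it.id]
        try:
            mol = provider.parse(rec.canonical_smiles)
            inner = _svg_inner(provider.draw_svg(mol, it.width, it.height))
        except Exception as exc:  # depiction failure: skip, keep composing
            if warnings is not None:
                warnings.append(f"depiction failed for {rec.canonical_smiles!r}: {exc}")
            continue
        x0, y0 = it.x - it.width / 2, it.y - it.height / 2
        parts.append(f'<g class="structure" data-id="{_xml_escape(it.id)}" '
                     f'transform="translate({x0:.2f},{y0:.2f})">')
        color = record_color(rec, rule)
        if color is not None:
            pad = box_padding * min(it.width, it.height)
            parts.append(
                f'<rect x="{-pad:.2f}" y="{-pad:.2f}" '
                f'width="{it.width + 2 * pad:.2f}" height="{it.height + 2 * pad:.2f}" '
                f'rx="{3 * pad:.2f}" fill="{color.hex}" '
                f'fill-opacity="{color.opacity:.3f}"/>')
        parts.append(inner)
        parts.append("</g>")
    parts.append("</svg>")
    return "\n".join(parts)


def compose_png(items: list[CloudItem], records: dict[str, SubstructureRecord],
                provider: DepictionProvider, rule: ColorRule, cfg: LayoutConfig,
                box_padding: float = 0.05, dpi_scale: float = 1.0,
                warnings: list | None = None):
    """Rasterized counterpart of :func:`compose`; returns a PIL image."""
    from PIL import Image, ImageDraw

    s = dpi_scale
    W, H = int(round(cfg.canvas_width * s)), int(round(cfg.canvas_height * s))
    canvas = Image.new("RGBA", (W, H), (255, 255, 255, 255))
    draw = ImageDraw.Draw(canvas, "RGBA")
    for it in sorted(items, key=lambda q: (q.area, q.id)):
        rec = records[it.id]
        try:
            mol = provider.parse(rec.canonical_smiles)
            w, h = max(1, int(round(it.width * s))), max(1, int(round(it.height * s)))
            tile = provider.draw_png(mol, w, h)
        except Exception as exc:
            if warnings is not None:
                warnings.append(f"depiction failed for {rec.canonical_smiles!r}: {exc}")
            continue
        x0 = int(round((it.x - it.width / 2) * s))
        y0 = int(round((it.y - it.height / 2) * s))
        color = record_color(rec, rule)
        if color is not None:
            pad = int(round(box_padding * min(it.width, it.height) * s))
            rgb = tuple(int(color.hex[k:k + 2], 16) for k in (1, 3, 5))
            draw.rounded_rectangle(
                [x0 - pad, y0 - pad, x0 + w + pad, y0 + h + pad],
                radius=3 * pad, fill=rgb + (int(round(255 * color.opacity)),))
        canvas.alpha_composite(tile, (x0, y0))
    return canvas.convert("RGB")
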