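"""Priority decision-tree fusion of thematic layers into categorical maps.

Six binary layers (water, forest, cropland, early/middle/late rice) are
fused with a fixed priority: water first, then forest, then rice — and a
rice label additionally requires the pixel to be cropland (rice can only
grow on cropland, which removes spurious rice detections over water edges
and settlements).  Middle rice is tested before early rice: middle rice can
be confused for early rice in the early-rice enhancement, but not the
reverse, so giving middle rice priority resolves the overlap.  Early and
late rice coincide spatially (double cropping), so they are mapped on two
separate products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import Grid2D, Unit, check_coregistered
from .classify import ClassLayer

#: Label dictionary shared by both categorical products.
LEGEND: dict[int, str] = {
    0: "other",
    1: "water",
    2: "forest",
    3: "middle_rice",
    4: "early_rice",
    5: "late_rice",
}
LABEL_OF = {name: code for code, name in LEGEND.items()}


@dataclass
class CategoricalMap:
    """Complete single-label partition of the valid pixels."""

    labels: Grid2D
    legend: dict[int, str] = field(default_factory=lambda: dict(LEGEND))

    def __post_init__(self) -> None:
        valid = self.labels.valid_values()
        if valid.size and not np.isin(valid, list(self.legend)).all():
            raise ValueError("labels outside legend")

    def mask_of(self, class_name: str) -> np.ndarray:
        return (self.labels.values == LABEL_OF[class_name]) & self.labels.valid_mask

    def area_km2(self, class_name: str) -> float:
        px = self.labels.pixel_size
        return float(self.mask_of(class_name).sum()) * px * px / 1e6


def _binary(layer: ClassLayer) -> np.ndarray:
    return (layer.mask.values == 1) & layer.mask.valid_mask


def _fuse(layers: list[ClassLayer], rules: list[tuple[np.ndarray, int]]) -> CategoricalMap:
    check_coregistered(*(l.mask for l in layers))
    template = layers[0].mask
    nodata = np.zeros(template.shape, dtype=bool)
    for l in layers:
        nodata |= l.mask.nodata_mask
    out = np.full(template.shape, LABEL_OF["other"], dtype=np.int16)
    assigned = np.zeros(template.shape, dtype=bool)
    for condition, code in rules:
        hit = condition & ~assigned
        out[hit] = code
        assigned |= hit
    out[nodata] = -1
    grid = Grid2D(np.where(nodata, LABEL_OF["other"], out), Unit.LABEL,
                  template.transform, nodata_mask=nodata)
    return CategoricalMap(grid)


def fuse_early_middle(water: ClassLayer, forest: ClassLayer,
                      cropland: ClassLayer, middle: ClassLayer,
                      early: ClassLayer) -> CategoricalMap:
    """Early+middle rice product: water > forest > middle > early > other.

    Rice rules are gated on the cropland layer; first matching rule wins and
    later layers cannot change an assigned pixel.
    """
    w, f, c = _binary(water), _binary(forest), _binary(cropland)
    m, e = _binary(middle), _binary(early)
    return _fuse(
        [water, forest, cropland, middle, early],
        [
            (w, LABEL_OF["water"]),
            (f, LABEL_OF["forest"]),
            (c & m, LABEL_OF["middle_rice"]),
            (c & e, LABEL_OF["early_rice"]),
        ],
    )


def fuse_late(water: ClassLayer, forest: ClassLayer, cropland: ClassLayer,
              late: ClassLayer) -> CategoricalMap:
    """Late-rice product: water > forest > (cropland and late rice) > other."""
    w, f, c, l = _binary(water), _binary(forest), _binary(cropland), _binary(late)
    return _fuse(
        [water, forest, cropland, late],
        [
            (w, LABEL_OF["water"]),
            (f, LABEL_OF["forest"]),
            (c & l, LABEL_OF["late_rice"]),
        ],
    )


def double_crop_area(early_map: CategoricalMap, late_map: CategoricalMap,
                     pixel_size: float | None = None) -> float:
    """Area (km²) planted to both early and late rice in the same year."""
    check_coregistered(early_map.labels, late_map.labels)
    if pixel_size is None:
        pixel_size = early_map.labels.pixel_size
    both = early_map.mask_of("early_rice") & late_map.mask_of("late_rice")
    return float(both.sum()) * pixel_size * pixel_size / 1e6
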