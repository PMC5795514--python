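"""Synthetic study scenes with the temporal signatures of a double-cropping
rice plain.

Generates co-registered SAR VH backscatter time series, optical red/NIR
pairs, an auxiliary water layer and per-pixel truth so that every pipeline
stage is testable without satellite downloads.  Temporal means follow the
field-observed pattern: water is flat near -24 dB, forest/built-up flat
near -10 dB, and rice dips to a flooded-transplanting trough (about -20 dB)
before peaking at canopy closure (about -11 dB); double-cropped early+late
fields show two troughs.  NDVI is high in season and low in winter over
cropland, high year-round over evergreen forest, and negative over water.

Only the two flat dB anchors (-24 water, -10 forest/built-up) are
field-reported values; the remaining profile numbers are generator
parameters chosen to reproduce the stated relations, not measurements.
"""

from __future__ import annotations

import datetime as dt
import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .classify import ClassLayer
from .fusion import LABEL_OF, LEGEND, CategoricalMap
from .grids import Grid2D, Transform, Unit
from .optical import OpticalPair
from .temporal import AcquisitionStack

#: Generator land-cover classes (integer codes in truth rasters).
GEN_CLASSES = (
    "water",
    "forest_builtup",
    "cropland_early_late",
    "cropland_middle",
    "cropland_other",
    "other",
)
GEN_CODE = {name: i for i, name in enumerate(GEN_CLASSES)}

#: Piecewise-linear backscatter profiles, (day-of-year, dB) anchor points.
#: Flat covers are single-valued; rice classes encode trough -> peak ->
#: decline, with a second trough/peak pair for the double crop.
_PROFILE_ANCHORS: dict[str, list[tuple[int, float]]] = {
    "water": [(1, -24.0), (366, -24.0)],
    "forest_builtup": [(1, -10.0), (366, -10.0)],
    "other": [(1, -13.0), (366, -13.0)],
    "cropland_other": [(1, -14.0), (366, -14.0)],
    # early rice: trough mid-Apr, peak mid-Jun, harvest, then late-rice
    # trough late Jul and peak early Sep (double crop on one field)
    "cropland_early_late": [
        (60, -14.0), (80, -14.0), (95, -20.0), (110, -20.0), (132, -12.0),
        (160, -11.0), (175, -11.5), (190, -13.5), (200, -15.0), (205, -20.0),
        (220, -20.0), (240, -14.0), (258, -11.0), (272, -11.5), (290, -14.0),
        (306, -15.0),
    ],
    # middle rice: trough mid-May to early Jun, peak mid-Jul
    "cropland_middle": [
        (60, -14.0), (110, -14.0), (130, -20.0), (160, -20.0), (185, -13.0),
        (200, -11.0), (215, -12.0), (240, -15.0), (306, -15.0),
    ],
}

#: Mean NDVI by class and season tag.
_NDVI_MEANS: dict[str, dict[str, float]] = {
    "water": {"growing": -0.3, "winter": -0.3},
    "forest_builtup": {"growing": 0.8, "winter": 0.7},
    "cropland_early_late": {"growing": 0.7, "winter": 0.15},
    "cropland_middle": {"growing": 0.7, "winter": 0.15},
    "cropland_other": {"growing": 0.7, "winter": 0.15},
    "other": {"growing": 0.2, "winter": 0.2},
}


def default_sar_dates() -> list[dt.date]:
    """12-day acquisition cadence, 31 March to 21 October 2016 (18 dates)."""
    start = dt.date(2016, 3, 31)
    return [start + dt.timedelta(days=12 * k) for k in range(18)]


def default_growing_dates() -> list[dt.date]:
    return [dt.date(2016, 6, 23), dt.date(2016, 7, 25), dt.date(2016, 9, 27)]


def default_winter_dates() -> list[dt.date]:
    return [dt.date(2016, 2, 16), dt.date(2016, 12, 16)]


def temporal_profile(cls: str, date: dt.date) -> float:
    """Noise-free mean VH backscatter (dB) of a class on a date."""
    if cls not in _PROFILE_ANCHORS:
        raise ValueError(f"unknown generator class {cls!r}")
    anchors = _PROFILE_ANCHORS[cls]
    doys = [a[0] for a in anchors]
    vals = [a[1] for a in anchors]
    return float(np.interp(date.timetuple().tm_yday, doys, vals))


def ndvi_profile(cls: str, date_tag: str) -> float:
    """Noise-free mean NDVI of a class for a 'growing' or 'winter' date."""
    if cls not in _NDVI_MEANS:
        raise ValueError(f"unknown generator class {cls!r}")
    if date_tag not in ("growing", "winter"):
        raise ValueError(f"date_tag must be 'growing' or 'winter', got {date_tag!r}")
    return _NDVI_MEANS[cls][date_tag]


@dataclass
class SceneConfig:
    """Study-condition parameters of a synthetic scene."""

    shape: tuple[int, int] = (200, 200)
    pixel_size: float = 30.0
    class_fractions: dict[str, float] = field(default_factory=lambda: {
        "water": 0.15,
        "forest_builtup": 0.20,
        "cropland_early_late": 0.25,
        "cropland_middle": 0.10,
        "cropland_other": 0.15,
        "other": 0.15,
    })
    sar_dates: list[dt.date] = field(default_factory=default_sar_dates)
    missing_dates: list[dt.date] = field(default_factory=list)
    growing_dates: list[dt.date] = field(default_factory=default_growing_dates)
    winter_dates: list[dt.date] = field(default_factory=default_winter_dates)
    noise_sd_db: float = 1.0        # matches the +/-1 dB spreads of flat covers
    noise_sd_ndvi: float = 0.05
    sar_unit: str = "dB"            # or "linear-power" to exercise dB conversion
    n_seed_patches: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_fractions) - set(GEN_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in fractions: {sorted(unknown)}")
        vals = np.array(list(self.class_fractions.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("class fractions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {vals.sum()}")
        dates = self.sar_dates
        if any(a >= b for a, b in zip(dates, dates[1:])):
            raise ValueError("sar_dates must be strictly increasing")
        if self.sar_unit not in ("dB", "linear-power"):
            raise ValueError(f"sar_unit must be 'dB' or 'linear-power'")

    def effective_sar_dates(self) -> list[dt.date]:
        drop = set(self.missing_dates)
        return [d for d in self.sar_dates if d not in drop]

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "pixel_size": self.pixel_size,
            "class_fractions": dict(self.class_fractions),
            "sar_dates": [d.isoformat() for d in self.sar_dates],
            "missing_dates": [d.isoformat() for d in self.missing_dates],
            "growing_dates": [d.isoformat() for d in self.growing_dates],
            "winter_dates": [d.isoformat() for d in self.winter_dates],
            "noise_sd_db": self.noise_sd_db,
            "noise_sd_ndvi": self.noise_sd_ndvi,
            "sar_unit": self.sar_unit,
            "n_seed_patches": self.n_seed_patches,
            "seed": self.seed,
        }


@dataclass
class SceneTruth:
    """Per-pixel generator classes plus the derived reference products."""

    class_labels: Grid2D          # GEN_CODE values
    transform: Transform

    def mask_of(self, cls: str) -> np.ndarray:
        return self.class_labels.values == GEN_CODE[cls]

    @property
    def early_mask(self) -> np.ndarray:
        return self.mask_of("cropland_early_late")

    @property
    def middle_mask(self) -> np.ndarray:
        return self.mask_of("cropland_middle")

    @property
    def late_mask(self) -> np.ndarray:
        return self.mask_of("cropland_early_late")

    @property
    def double_crop_mask(self) -> np.ndarray:
        return self.early_mask & self.late_mask

    def _reference(self, assignments: dict[str, str]) -> CategoricalMap:
        out = np.full(self.class_labels.shape, LABEL_OF["other"], dtype=np.int16)
        for gen_cls, map_cls in assignments.items():
            out[self.mask_of(gen_cls)] = LABEL_OF[map_cls]
        grid = Grid2D(out, Unit.LABEL, self.transform)
        return CategoricalMap(grid, dict(LEGEND))

    def reference_early_middle(self) -> CategoricalMap:
        """Truth in the legend of the early+middle rice product."""
        return self._reference({
            "water": "water",
            "forest_builtup": "forest",
            "cropland_early_late": "early_rice",
            "cropland_middle": "middle_rice",
        })

    def reference_late(self) -> CategoricalMap:
        """Truth in the legend of the late-rice product."""
        return self._reference({
            "water": "water",
            "forest_builtup": "forest",
            "cropland_early_late": "late_rice",
        })


@dataclass
class SyntheticScene:
    """Everything the pipeline consumes, plus truth."""

    sar: AcquisitionStack
    optical: list[OpticalPair]
    water_layer: ClassLayer
    truth: SceneTruth
    config: SceneConfig


def _grow_regions(shape: tuple[int, int], fractions: dict[str, float],
                  n_seed_patches: int, rng: np.random.Generator) -> np.ndarray:
    """Contiguous class patches by competitive multi-seed region growth.

    Class pixel quotas follow the largest-remainder rule, so empirical
    fractions match the configured ones to within one pixel of rounding.
    """
    rows, cols = shape
    n = rows * cols
    names = [c for c in GEN_CLASSES if fractions.get(c, 0.0) > 0]
    fr = np.array([fractions[c] for c in names])
    quotas = np.floor(fr * n).astype(int)
    remainder = n - quotas.sum()
    order = np.argsort(-(fr * n - quotas))
    quotas[order[:remainder]] += 1

    labels = np.full(shape, -1, dtype=np.int16)
    counts = np.zeros(len(names), dtype=int)
    frontiers: list[deque] = [deque() for _ in names]

    n_seeds = [max(1, int(round(fractions[c] * n_seed_patches))) for c in names]
    cells = rng.choice(n, size=sum(n_seeds), replace=False)
    pos = 0
    for k in range(len(names)):
        for cell in cells[pos:pos + n_seeds[k]]:
            frontiers[k].append((int(cell) // cols, int(cell) % cols))
        pos += n_seeds[k]

    def reseed(k: int) -> None:
        free = np.flatnonzero(labels.ravel() == -1)
        cell = int(rng.choice(free))
        frontiers[k].append((cell // cols, cell % cols))

    active = set(range(len(names)))
    while active:
        for k in sorted(active):
            if counts[k] >= quotas[k]:
                active.discard(k)
                continue
            placed = False
            while frontiers[k] and not placed:
                r, c = frontiers[k].popleft()
                if labels[r, c] != -1:
                    continue
                labels[r, c] = GEN_CODE[names[k]]
                counts[k] += 1
                placed = True
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and labels[rr, cc] == -1:
                        frontiers[k].append((rr, cc))
            if not placed:
                if counts[k] >= quotas[k] or (labels == -1).sum() == 0:
                    active.discard(k)
                else:
                    reseed(k)
    return labels


def generate_scene(config: SceneConfig | None = None) -> SyntheticScene:
    """Generate a fully reproducible synthetic scene from the config seed."""
    config = config or SceneConfig()
    rows, cols = config.shape
    transform = Transform(0.0, 0.0, config.pixel_size)
    rng = np.random.default_rng(config.seed)

    labels = _grow_regions(config.shape, config.class_fractions,
                           config.n_seed_patches, rng)
    truth = SceneTruth(Grid2D(labels, Unit.LABEL, transform), transform)

    class_masks = {c: labels == GEN_CODE[c] for c in GEN_CLASSES}

    # SAR stack: per-date mean profile per class + Gaussian noise (dB space)
    dates = config.effective_sar_dates()
    grids = []
    for date in dates:
        mean = np.zeros(config.shape)
        for cls, mask in class_masks.items():
            mean[mask] = temporal_profile(cls, date)
        db = mean + rng.normal(0.0, config.noise_sd_db, size=config.shape)
        if config.sar_unit == "dB":
            grids.append(Grid2D(db, Unit.DB, transform))
        else:
            grids.append(Grid2D(np.power(10.0, db / 10.0),
                                Unit.LINEAR_POWER, transform))
    sar = AcquisitionStack(dates, grids)

    # Optical pairs: draw the target NDVI (mean + noise) and invert it to
    # red/NIR reflectances with a fixed band sum, so ndvi() recovers it.
    optical = []
    band_sum = 0.4
    for date, tag in sorted(
        [(d, "growing") for d in config.growing_dates]
        + [(d, "winter") for d in config.winter_dates]
    ):
        target = np.zeros(config.shape)
        for cls, mask in class_masks.items():
            target[mask] = ndvi_profile(cls, tag)
        target = np.clip(
            target + rng.normal(0.0, config.noise_sd_ndvi, size=config.shape),
            -0.95, 0.95,
        )
        nir = band_sum * (1.0 + target) / 2.0
        red = band_sum * (1.0 - target) / 2.0
        optical.append(OpticalPair(
            red=Grid2D(red, Unit.REFLECTANCE, transform),
            nir=Grid2D(nir, Unit.REFLECTANCE, transform),
            date=date,
        ))

    # Auxiliary water layer emulating an external water-extent product
    water_mask = class_masks["water"].astype(np.int16)
    water_layer = ClassLayer(Grid2D(water_mask, Unit.LABEL, transform), "water")

    return SyntheticScene(sar, optical, water_layer, truth, config)


def write_manifest(path, config: SceneConfig) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
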