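"""End-to-end orchestration: enhance -> classify -> fuse -> assess.

Chains the stage modules in the operational order: SAR preprocessing
(dB + despeckle), phenology-window enhancement per rice type, NDVI
cropland enhancement, K-Means classification of each enhanced product,
cluster merging into thematic layers, priority decision fusion into the
two categorical maps, and design-based accuracy/area assessment against a
reference map via a stratified per-map-class sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .accuracy import ErrorMatrix, StratifiedAreaEstimator, build_error_matrix
from .classify import (ClassLayer, auto_assign_clusters, kmeans_classify,
                       merge_clusters)
from .fusion import CategoricalMap, double_crop_area, fuse_early_middle, fuse_late
from .grids import Grid2D, Unit
from .optical import build_cropland_image, ndvi
from .radiometry import despeckle_median, to_decibel
from .synthetic import SyntheticScene
from .temporal import AcquisitionStack, PhenologyCalendar, RICE_TYPES


@dataclass
class PipelineParams:
    """Classifier and assessment settings for one run."""

    k: int = 10
    max_iter: int = 20
    seed: int = 0
    despeckle_window: int = 5
    samples_per_stratum: int = 100
    calendar: PhenologyCalendar = field(default_factory=PhenologyCalendar)


@dataclass
class AssessmentResult:
    """Design-based assessment of one categorical product."""

    error_matrix: ErrorMatrix
    estimator: StratifiedAreaEstimator
    pixel_agreement: float        # plain full-map fraction of matching pixels


@dataclass
class PipelineResult:
    rice_layers: dict[str, ClassLayer]
    cropland_layer: ClassLayer
    forest_layer: ClassLayer
    water_layer: ClassLayer
    early_middle_map: CategoricalMap
    late_map: CategoricalMap
    double_crop_km2: float
    assessments: dict[str, AssessmentResult]
    cluster_mappings: dict[str, dict[int, str]]


def preprocess_sar(stack: AcquisitionStack, window: int = 5) -> AcquisitionStack:
    """Convert to dB if needed and despeckle each acquisition."""
    grids = []
    for g in stack.grids:
        if g.unit == Unit.LINEAR_POWER:
            g = to_decibel(g)
        g.require_unit(Unit.DB)
        grids.append(despeckle_median(g, window))
    return AcquisitionStack(list(stack.dates), grids)


def _empty_layer(template: Grid2D, class_name: str) -> ClassLayer:
    zeros = template.with_values(np.zeros(template.shape, dtype=np.int16),
                                 unit=Unit.LABEL)
    return ClassLayer(zeros, class_name)


def classify_rice_layers(stack: AcquisitionStack, params: PipelineParams,
                         mappings_out: dict | None = None) -> dict[str, ClassLayer]:
    """One binary rice layer per rice type from its enhanced image."""
    from .temporal import build_enhanced_image
    layers: dict[str, ClassLayer] = {}
    for i, rice_type in enumerate(RICE_TYPES):
        image = build_enhanced_image(stack, params.calendar, rice_type)
        clusters = kmeans_classify(image, k=params.k, max_iter=params.max_iter,
                                   seed=params.seed + i)
        class_name = f"{rice_type}_rice"
        mapping = auto_assign_clusters(clusters, "rice_enhanced",
                                       rice_class=class_name)
        if mappings_out is not None:
            mappings_out[class_name] = mapping
        merged = merge_clusters(clusters, mapping)
        layer = next((l for l in merged if l.class_name == class_name), None)
        layers[class_name] = layer or _empty_layer(stack.grids[0], class_name)
    return layers


def classify_cropland_layers(optical_pairs, growing_dates, winter_dates,
                             params: PipelineParams,
                             mappings_out: dict | None = None
                             ) -> tuple[ClassLayer, ClassLayer]:
    """(cropland, forest) binary layers from the NDVI cropland image."""
    growing = [ndvi(p) for p in optical_pairs if p.date in set(growing_dates)]
    winter = [ndvi(p) for p in optical_pairs if p.date in set(winter_dates)]
    image = build_cropland_image(growing, winter)
    clusters = kmeans_classify(image, k=params.k, max_iter=params.max_iter,
                               seed=params.seed + 7)
    mapping = auto_assign_clusters(clusters, "cropland_image")
    if mappings_out is not None:
        mappings_out["cropland_image"] = mapping
    merged = merge_clusters(clusters, mapping)
    template = optical_pairs[0].red
    cropland = next((l for l in merged if l.class_name == "cropland"), None)
    forest = next((l for l in merged if l.class_name == "forest"), None)
    return (cropland or _empty_layer(template, "cropland"),
            forest or _empty_layer(template, "forest"))


def stratified_sample_mask(map_labels: CategoricalMap, per_stratum: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Random per-map-class sample of pixels for accuracy assessment."""
    mask = np.zeros(map_labels.labels.shape, dtype=bool)
    values = map_labels.labels.values
    valid = map_labels.labels.valid_mask
    for code in np.unique(values[valid]):
        flat = np.flatnonzero((values == code) & valid)
        take = min(per_stratum, flat.size)
        chosen = rng.choice(flat, size=take, replace=False)
        mask.ravel()[chosen] = True
    return mask


def assess_map(mapped: CategoricalMap, reference: CategoricalMap,
               legend: list[str], per_stratum: int,
               rng: np.random.Generator) -> AssessmentResult:
    sample = stratified_sample_mask(mapped, per_stratum, rng)
    em = build_error_matrix(mapped, reference, legend, sample_mask=sample)
    est = StratifiedAreaEstimator().fit(em)
    both = mapped.labels.valid_mask & reference.labels.valid_mask
    agreement = float(
        (mapped.labels.values[both] == reference.labels.values[both]).mean()
    )
    return AssessmentResult(em, est, agreement)


def run_pipeline(scene: SyntheticScene,
                 params: PipelineParams | None = None) -> PipelineResult:
    """Full chain on a scene; assessment uses the scene's truth rasters."""
    params = params or PipelineParams()
    mappings: dict[str, dict[int, str]] = {}

    stack = preprocess_sar(scene.sar, params.despeckle_window)
    rice_layers = classify_rice_layers(stack, params, mappings)
    cropland, forest = classify_cropland_layers(
        scene.optical, scene.config.growing_dates, scene.config.winter_dates,
        params, mappings,
    )
    water = scene.water_layer

    early_middle = fuse_early_middle(water, forest, cropland,
                                     rice_layers["middle_rice"],
                                     rice_layers["early_rice"])
    late = fuse_late(water, forest, cropland, rice_layers["late_rice"])
    double_km2 = double_crop_area(early_middle, late)

    rng = np.random.default_rng(params.seed + 1000)
    legend_em = ["water", "forest", "middle_rice", "early_rice", "other"]
    legend_late = ["water", "forest", "late_rice", "other"]
    assessments = {
        "early_middle": assess_map(early_middle,
                                   scene.truth.reference_early_middle(),
                                   legend_em, params.samples_per_stratum, rng),
        "late": assess_map(late, scene.truth.reference_late(),
                           legend_late, params.samples_per_stratum, rng),
    }

    return PipelineResult(
        rice_layers=rice_layers,
        cropland_layer=cropland,
        forest_layer=forest,
        water_layer=water,
        early_middle_map=early_middle,
        late_map=late,
        double_crop_km2=double_km2,
        assessments=assessments,
        cluster_mappings=mappings,
    )
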