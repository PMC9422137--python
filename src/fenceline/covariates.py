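"""Per-candidate covariates: feature crossings, distances, land cover, caps.

Crossing counts are transversal intersections between a step line and the
polylines of one configuration class; distances are point-to-nearest-feature,
capped at 1000 m. Crossing counts are capped at the (nearest-rank) 98th
percentile of the pooled used+available counts, per tactic and class, which
is what keeps the conditional-logistic fits away from separation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely import STRtree
from shapely.geometry import LineString, Point

from .features import ConfigClass, FeatureLayer
from .geoio import CategoricalRaster

logger = logging.getLogger(__name__)

DISTANCE_CAP_M = 1000.0
CAP_PERCENTILE = 98.0
CORRELATION_THRESHOLD = 0.7

LANDCOVER_CATEGORIES = ("NATIVE", "ANNUAL_CROP", "PERENNIAL", "OTHER")
LANDCOVER_REFERENCE = "ANNUAL_CROP"

#: Raw land-cover classes collapsed to the four analysis categories:
#: native prairie/shrub/wetland -> NATIVE; tree covers, exposed, developed
#: and water -> OTHER.
DEFAULT_RECLASS = {
    "native_prairie": "NATIVE",
    "shrub": "NATIVE",
    "wetland": "NATIVE",
    "annual_crop": "ANNUAL_CROP",
    "perennial": "PERENNIAL",
    "deciduous_tree": "OTHER",
    "coniferous_tree": "OTHER",
    "mixed_tree": "OTHER",
    "exposed": "OTHER",
    "developed": "OTHER",
    "water": "OTHER",
}


class LayerIndex:
    """Spatial index over one configuration class's polylines."""

    def __init__(self, layer: FeatureLayer):
        self.config_class = layer.config_class
        self.lines = np.asarray(layer.geometries, dtype=object)
        self.tree = STRtree(list(self.lines)) if len(self.lines) else None


def _count_pieces(geom) -> int:
    """Crossing count contributed by one segment-polyline intersection.

    Each transversal intersection point counts once; a collinear overlap
    stretch counts once; an endpoint merely touching a line also counts once
    (measure-zero contact, fixed convention).
    """
    if geom.is_empty:
        return 0
    t = geom.geom_type
    if t == "Point":
        return 1
    if t in ("LineString", "LinearRing"):
        return 1
    if t in ("MultiPoint", "MultiLineString"):
        return len(geom.geoms)
    if t == "GeometryCollection":
        return sum(_count_pieces(g) for g in geom.geoms)
    return 0


def count_crossings(step_line: LineString, layer: FeatureLayer | LayerIndex) -> int:
    """Number of times a step segment crosses the layer's polylines."""
    index = layer if isinstance(layer, LayerIndex) else LayerIndex(layer)
    if step_line.length == 0 or index.tree is None:
        return 0
    total = 0
    for idx in index.tree.query(step_line, predicate="intersects"):
        total += _count_pieces(step_line.intersection(index.lines[idx]))
    return total


def count_crossings_bulk(
    starts: np.ndarray, ends: np.ndarray, index: LayerIndex
) -> np.ndarray:
    """Crossing counts for many segments at once (shared with the simulator)."""
    starts = np.asarray(starts, dtype=float)
    ends = np.asarray(ends, dtype=float)
    n = len(starts)
    counts = np.zeros(n, dtype=int)
    if index.tree is None or n == 0:
        return counts
    coords = np.stack([starts, ends], axis=1)
    segs = shapely.linestrings(coords)
    nonzero = shapely.length(segs) > 0
    seg_idx, line_idx = index.tree.query(segs, predicate="intersects")
    for si, li in zip(seg_idx, line_idx):
        if nonzero[si]:
            counts[si] += _count_pieces(segs[si].intersection(index.lines[li]))
    return counts


def distance_to_feature(
    point: Point | tuple[float, float],
    layer: FeatureLayer | LayerIndex,
    cap: float = DISTANCE_CAP_M,
) -> float:
    """Distance (m) from a point to the nearest polyline of a layer, capped."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    index = layer if isinstance(layer, LayerIndex) else LayerIndex(layer)
    if index.tree is None:
        logger.warning("distance_to_feature: empty %s layer, returning cap", index.config_class)
        return float(cap)
    p = Point(point) if not isinstance(point, Point) else point
    nearest = index.tree.nearest(p)
    return float(min(p.distance(index.lines[nearest]), cap))


def distance_to_feature_bulk(
    xy: np.ndarray, index: LayerIndex, cap: float = DISTANCE_CAP_M
) -> np.ndarray:
    xy = np.asarray(xy, dtype=float)
    if index.tree is None:
        logger.warning("distance bulk: empty %s layer, returning cap", index.config_class)
        return np.full(len(xy), float(cap))
    pts = shapely.points(xy)
    nearest = index.tree.nearest(pts)
    d = shapely.distance(pts, index.lines[nearest])
    return np.minimum(d, cap)


class StackedLayerIndex:
    """One spatial index over all four configuration classes.

    Used by both the analysis covariate path and the movement simulator, so
    the two compute crossings through literally the same code.
    """

    def __init__(self, layers: dict[ConfigClass, FeatureLayer]):
        self.classes = list(layers.keys())
        lines: list = []
        labels: list[int] = []
        for i, cc in enumerate(self.classes):
            for g in layers[cc].geometries:
                lines.append(g)
                labels.append(i)
        self.lines = np.asarray(lines, dtype=object)
        self.labels = np.asarray(labels, dtype=int)
        self.tree = STRtree(list(self.lines)) if len(self.lines) else None
        self.per_class = {cc: LayerIndex(layers[cc]) for cc in self.classes}

    def count_crossings_by_class(
        self, starts: np.ndarray, ends: np.ndarray
    ) -> dict[ConfigClass, np.ndarray]:
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        n = len(starts)
        counts = {cc: np.zeros(n, dtype=int) for cc in self.classes}
        if self.tree is None or n == 0:
            return counts
        segs = shapely.linestrings(np.stack([starts, ends], axis=1))
        nonzero = shapely.length(segs) > 0
        seg_idx, line_idx = self.tree.query(segs, predicate="intersects")
        for si, li in zip(seg_idx, line_idx):
            if nonzero[si]:
                cc = self.classes[self.labels[li]]
                counts[cc][si] += _count_pieces(segs[si].intersection(self.lines[li]))
        return counts

    def distances_by_class(
        self, xy: np.ndarray, cap: float = DISTANCE_CAP_M
    ) -> dict[ConfigClass, np.ndarray]:
        return {
            cc: distance_to_feature_bulk(xy, idx, cap) for cc, idx in self.per_class.items()
        }


@dataclass
class CapRule:
    """Nearest-rank percentile cap on a crossing-count covariate."""

    config_class: ConfigClass
    percentile: float
    cap_value: int
    constant: bool = False  # all-zero counts: covariate degenerates

    def apply(self, x):
        return np.minimum(np.asarray(x), self.cap_value)


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Classic nearest-rank percentile: the ceil(p/100 * n)-th order statistic."""
    v = np.sort(np.asarray(values))
    if len(v) == 0:
        raise ValueError("empty values")
    rank = max(1, math.ceil(percentile / 100.0 * len(v)))
    return float(v[min(rank, len(v)) - 1])


def fit_caps(
    counts_by_class: dict[ConfigClass, np.ndarray],
    percentile: float = CAP_PERCENTILE,
) -> dict[ConfigClass, CapRule]:
    """Percentile caps from pooled used+available crossing counts, per class."""
    rules = {}
    for cc, counts in counts_by_class.items():
        counts = np.asarray(counts)
        if len(counts) == 0:
            raise ValueError(f"no counts for {cc}")
        cap = int(round(nearest_rank_percentile(counts, percentile)))
        constant = bool(np.all(counts == 0))
        if constant:
            logger.warning("crossing covariate %s is all-zero; cap 0, constant", cc.value)
        rules[cc] = CapRule(cc, percentile, cap, constant)
    return rules


#: running count of land-cover lookups that fell back to OTHER (off-map/unmapped)
landcover_fallback_counter = {"count": 0}


def landcover_at(
    xy: np.ndarray,
    raster: CategoricalRaster,
    reclass: dict[str, str] | None = None,
) -> np.ndarray:
    """Four-category land cover at points; off-map or unknown classes -> OTHER."""
    reclass = DEFAULT_RECLASS if reclass is None else reclass
    xy = np.asarray(xy, dtype=float)
    codes = np.atleast_1d(raster.code_at(xy[..., 0], xy[..., 1]))
    # code -> category lookup table; unknown/off-map codes fall back to OTHER
    max_code = max([c for c in raster.legend] + [0])
    lut = np.full(max_code + 2, "OTHER", dtype=object)
    known = np.zeros(max_code + 2, dtype=bool)
    for code, raw in raster.legend.items():
        if 0 <= code <= max_code and raw in reclass:
            lut[code] = reclass[raw]
            known[code] = True
    idx = np.where((codes >= 0) & (codes <= max_code), codes, max_code + 1)
    out = lut[idx]
    n_fallback = int((~known[idx]).sum())
    if n_fallback:
        landcover_fallback_counter["count"] += n_fallback
        logger.debug("landcover_at: %d point(s) off-map or unmapped -> OTHER", n_fallback)
    return out


@dataclass
class ScreenReport:
    """Pairwise Pearson correlations over model covariates."""

    r_matrix: pd.DataFrame
    threshold: float
    flagged: list[tuple[str, str, float]] = field(default_factory=list)
    undefined: list[tuple[str, str]] = field(default_factory=list)


def screen_collinearity(
    design: pd.DataFrame, threshold: float = CORRELATION_THRESHOLD
) -> ScreenReport:
    """Flag covariate pairs with |r| strictly above the threshold.

    Zero-variance covariates yield undefined correlations, reported as such;
    flagged pairs are warned about, never auto-dropped.
    """
    if design.shape[1] < 2 or design.shape[0] < 3:
        raise ValueError("need >=2 covariates and >=3 rows")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = design.corr(method="pearson")
    np.fill_diagonal(r.values, 1.0)
    flagged, undefined = [], []
    cols = list(design.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            val = r.loc[a, b]
            if np.isnan(val):
                undefined.append((a, b))
            elif abs(val) > threshold:
                flagged.append((a, b, float(val)))
    for a, b, val in flagged:
        logger.warning("collinearity: |r(%s, %s)| = %.3f > %.2f", a, b, abs(val), threshold)
    return ScreenReport(r_matrix=r, threshold=threshold, flagged=flagged, undefined=undefined)


def crossing_covariate_columns() -> list[str]:
    return [f"n_cross_{cc.value}" for cc in ConfigClass]


def distance_covariate_columns() -> list[str]:
    return [f"dist_{cc.value}" for cc in ConfigClass]


def _as_stacked(layers) -> StackedLayerIndex:
    return layers if isinstance(layers, StackedLayerIndex) else StackedLayerIndex(layers)


def compute_crossing_covariates(
    strata: pd.DataFrame,
    layers: dict[ConfigClass, FeatureLayer] | StackedLayerIndex,
    raster: CategoricalRaster,
    reclass: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Append uncapped crossing counts (per class) and endpoint land cover."""
    stacked = _as_stacked(layers)
    out = strata.copy()
    starts = out[["anchor_x", "anchor_y"]].to_numpy()
    ends = out[["x", "y"]].to_numpy()
    for cc, counts in stacked.count_crossings_by_class(starts, ends).items():
        out[f"n_cross_{cc.value}"] = counts
    out["landcover"] = landcover_at(ends, raster, reclass)
    return out


def compute_proximity_covariates(
    strata: pd.DataFrame,
    layers: dict[ConfigClass, FeatureLayer] | StackedLayerIndex,
    raster: CategoricalRaster,
    reclass: dict[str, str] | None = None,
    cap: float = DISTANCE_CAP_M,
) -> pd.DataFrame:
    """Append capped distance-to-feature (per class) and land cover."""
    stacked = _as_stacked(layers)
    out = strata.copy()
    xy = out[["x", "y"]].to_numpy()
    for cc, dists in stacked.distances_by_class(xy, cap).items():
        out[f"dist_{cc.value}"] = dists
    out["landcover"] = landcover_at(xy, raster, reclass)
    return out


def apply_crossing_caps(
    table: pd.DataFrame, rules: dict[ConfigClass, CapRule]
) -> pd.DataFrame:
    out = table.copy()
    for cc, rule in rules.items():
        col = f"n_cross_{cc.value}"
        if col in out.columns:
            out[col] = rule.apply(out[col].to_numpy())
    return out
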