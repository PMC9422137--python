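"""Linear-feature configuration layers.

Fences and roads are combined into four mutually exclusive configuration
classes: pasture fence (FENCE), road with no fence (RNF), road fenced on one
side (R1F), and road fenced on both sides (R2F). Roads are partitioned into
short subsegments; fence presence is tested independently on the left and
right side of each subsegment within the road class's right-of-way buffer,
and adjacent subsegments with the same class are merged back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from shapely import STRtree
from shapely.geometry import LineString, Polygon
from shapely.ops import substring, unary_union

from .geoio import CRSError, _looks_geographic


class RoadClass(str, Enum):
    paved_divided = "paved_divided"
    paved_undivided = "paved_undivided"
    gravel = "gravel"


class ConfigClass(str, Enum):
    FENCE = "FENCE"
    RNF = "RNF"
    R1F = "R1F"
    R2F = "R2F"


#: Right-of-way half-widths (m) used to test whether a road is fenced:
#: 40 m for paved roads, 20 m for unpaved (county) roads.
ROAD_BUFFER_M = {
    RoadClass.paved_divided: 40.0,
    RoadClass.paved_undivided: 40.0,
    RoadClass.gravel: 20.0,
}


def buffer_width_for(road_class: RoadClass | str) -> float:
    """Right-of-way half-width in meters for a road class."""
    try:
        return ROAD_BUFFER_M[RoadClass(road_class)]
    except (ValueError, KeyError):
        raise ValueError(f"unknown road class: {road_class!r}") from None


def _validate_line(geom: LineString, what: str) -> None:
    if geom.geom_type != "LineString" or len(geom.coords) < 2:
        raise ValueError(f"{what}: geometry must be a LineString with >=2 vertices")
    if not np.all(np.isfinite(np.asarray(geom.coords))):
        raise ValueError(f"{what}: geometry has non-finite coordinates")


@dataclass
class RoadRecord:
    geometry: LineString
    road_class: RoadClass

    def __post_init__(self) -> None:
        _validate_line(self.geometry, "RoadRecord")
        self.road_class = RoadClass(self.road_class)


@dataclass
class FenceRecord:
    geometry: LineString

    def __post_init__(self) -> None:
        _validate_line(self.geometry, "FenceRecord")


@dataclass
class FeatureLayer:
    """Polylines of one configuration class."""

    config_class: ConfigClass
    geometries: list[LineString] = field(default_factory=list)

    @property
    def total_length_m(self) -> float:
        return float(sum(g.length for g in self.geometries))

    @property
    def total_length_km(self) -> float:
        return self.total_length_m / 1000.0


#: a side counts as fenced when fences run alongside at least this fraction
#: of the subsegment's along-track extent (a fence merely crossing the road
#: contributes ~zero along-track coverage and is not a roadside fence)
SIDE_COVERAGE_FRACTION = 0.5


def _interval_union(spans: list[tuple[float, float]]) -> float:
    total = 0.0
    last_end = -math.inf
    for a, b in sorted(spans):
        if b <= last_end:
            continue
        total += b - max(a, last_end)
        last_end = b
    return total


def _fence_sides(
    subseg: LineString,
    fence_tree: STRtree,
    fences: list[LineString],
    width: float,
) -> tuple[bool, bool]:
    """Which sides (left, right) of ``subseg`` are fenced.

    A side is fenced when the fences falling in that side's buffer rectangle
    cover at least SIDE_COVERAGE_FRACTION of the subsegment's length when
    projected onto its axis. Subsegments are treated via their chord, which
    is exact for straight roads and a close approximation at 50-m splits.
    """
    (x0, y0), (x1, y1) = subseg.coords[0], subseg.coords[-1]
    dx, dy = x1 - x0, y1 - y0
    seg_len = math.hypot(dx, dy)
    if seg_len == 0:
        return False, False
    ux, uy = dx / seg_len, dy / seg_len
    nx, ny = -uy, ux  # left normal
    sides = []
    for sgn in (1.0, -1.0):  # left, right
        rect = Polygon(
            [
                (x0, y0),
                (x1, y1),
                (x1 + sgn * nx * width, y1 + sgn * ny * width),
                (x0 + sgn * nx * width, y0 + sgn * ny * width),
            ]
        )
        spans: list[tuple[float, float]] = []
        for idx in fence_tree.query(rect, predicate="intersects"):
            clipped = fences[idx].intersection(rect)
            if clipped.is_empty:
                continue
            parts = getattr(clipped, "geoms", [clipped])
            for part in parts:
                coords = np.asarray(getattr(part, "coords", []))
                if len(coords) == 0:
                    continue
                proj = (coords[:, 0] - x0) * ux + (coords[:, 1] - y0) * uy
                spans.append((float(proj.min()), float(proj.max())))
        covered = _interval_union(spans)
        sides.append(covered >= SIDE_COVERAGE_FRACTION * seg_len)
    return sides[0], sides[1]


def classify_road_segments(
    roads: list[RoadRecord],
    fences: list[FenceRecord],
    split_step: float = 50.0,
) -> dict[ConfigClass, FeatureLayer]:
    """Partition road centerlines by fence configuration.

    Each road is split into subsegments of at most ``split_step`` meters;
    fence presence on each side is evaluated per subsegment within the road
    class's buffer width; runs of equal class are merged. Fence stretches
    that fall inside any road buffer are consumed by the road classification
    and removed from the FENCE layer so one physical fence is never counted
    twice.
    """
    if split_step <= 0:
        raise ValueError("split_step must be positive")
    road_lines = [r.geometry for r in roads]
    fence_lines = [f.geometry for f in fences]
    if _looks_geographic(road_lines + fence_lines):
        raise CRSError("input coordinates look like lon/lat degrees; projected meters required")

    layers = {cc: FeatureLayer(cc) for cc in ConfigClass}
    fence_tree = STRtree(fence_lines) if fence_lines else None

    road_buffers = []
    for road in roads:
        width = buffer_width_for(road.road_class)
        line = road.geometry
        road_buffers.append(line.buffer(width, quad_segs=4))
        n = max(1, math.ceil(line.length / split_step))
        breaks = np.linspace(0.0, line.length, n + 1)
        classes: list[ConfigClass] = []
        for d0, d1 in zip(breaks[:-1], breaks[1:]):
            sub = substring(line, d0, d1)
            if fence_tree is None:
                classes.append(ConfigClass.RNF)
                continue
            left, right = _fence_sides(sub, fence_tree, fence_lines, width)
            n_sides = int(left) + int(right)
            classes.append([ConfigClass.RNF, ConfigClass.R1F, ConfigClass.R2F][n_sides])
        # merge runs of identical class back into maximal substrings
        i = 0
        while i < n:
            j = i
            while j + 1 < n and classes[j + 1] == classes[i]:
                j += 1
            layers[classes[i]].geometries.append(substring(line, breaks[i], breaks[j + 1]))
            i = j + 1

    # remaining pasture fences: whatever lies outside every road buffer
    if fence_lines:
        buffer_union = unary_union(road_buffers) if road_buffers else None
        for fence in fence_lines:
            residue = fence if buffer_union is None else fence.difference(buffer_union)
            if residue.is_empty:
                continue
            parts = residue.geoms if residue.geom_type == "MultiLineString" else [residue]
            for part in parts:
                if part.geom_type == "LineString" and part.length > 1e-9:
                    layers[ConfigClass.FENCE].geometries.append(part)
    return layers


def clip_layers(
    layers: dict[ConfigClass, FeatureLayer], study_area: Polygon
) -> dict[ConfigClass, FeatureLayer]:
    """Clip every layer to a study-area polygon."""
    out: dict[ConfigClass, FeatureLayer] = {}
    for cc, layer in layers.items():
        clipped = FeatureLayer(cc)
        for g in layer.geometries:
            inter = g.intersection(study_area)
            if inter.is_empty:
                continue
            parts = inter.geoms if inter.geom_type in ("MultiLineString", "GeometryCollection") else [inter]
            for part in parts:
                if part.geom_type == "LineString" and part.length > 0:
                    clipped.geometries.append(part)
        out[cc] = clipped
    return out
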