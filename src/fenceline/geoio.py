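"""Lightweight geospatial I/O: GeoJSON line layers and categorical ASCII-grid rasters.

All geometries live in a single projected metric CRS (planar coordinates in
meters). GeoJSON is used purely as a container for projected polylines; a
heuristic guard rejects layers that look like unprojected lon/lat degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import LineString, mapping, shape


class CRSError(ValueError):
    """Raised when input coordinates do not look like projected meters."""


def _looks_geographic(lines: list[LineString]) -> bool:
    # Degrees-range coordinates on a multi-feature layer are almost certainly
    # lon/lat; a genuine metric study area of a few points near the origin is
    # indistinguishable, so only layers with some spatial spread are rejected.
    xs, ys = [], []
    for ln in lines:
        c = np.asarray(ln.coords)
        xs.extend(c[:, 0])
        ys.extend(c[:, 1])
    if not xs:
        return False
    xs, ys = np.asarray(xs), np.asarray(ys)
    in_deg_range = (
        xs.min() >= -180 and xs.max() <= 180 and ys.min() >= -90 and ys.max() <= 90
    )
    return bool(in_deg_range and (np.ptp(xs) > 0.001 or np.ptp(ys) > 0.001))


def read_line_layer(
    path: str | Path, *, properties: list[str] | None = None, allow_geographic: bool = False
) -> tuple[list[LineString], list[dict]]:
    """Read a GeoJSON FeatureCollection of LineStrings.

    Returns (geometries, per-feature property dicts). MultiLineStrings are
    exploded into their parts (properties duplicated).
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    lines: list[LineString] = []
    props: list[dict] = []
    for feat in gj.get("features", []):
        geom = shape(feat["geometry"])
        p = feat.get("properties") or {}
        if properties is not None:
            p = {k: p.get(k) for k in properties}
        if geom.geom_type == "LineString":
            parts = [geom]
        elif geom.geom_type == "MultiLineString":
            parts = list(geom.geoms)
        else:
            raise ValueError(f"{path}: unsupported geometry type {geom.geom_type}")
        for part in parts:
            lines.append(part)
            props.append(dict(p))
    if not allow_geographic and _looks_geographic(lines):
        raise CRSError(
            f"{path}: coordinates fall in lon/lat degree ranges; a projected "
            "metric CRS is required (pass allow_geographic=True to override)"
        )
    return lines, props


def write_line_layer(
    path: str | Path, lines: list[LineString], props: list[dict] | None = None
) -> None:
    """Write polylines (plus optional per-feature properties) as GeoJSON."""
    if props is None:
        props = [{} for _ in lines]
    features = [
        {"type": "Feature", "geometry": mapping(ln), "properties": p}
        for ln, p in zip(lines, props, strict=True)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


@dataclass
class CategoricalRaster:
    """A categorical grid in projected coordinates.

    ``values[row, col]`` holds integer class codes; row 0 is the NORTH edge
    (ESRI ASCII grid convention). ``legend`` maps codes to raw class names.
    """

    values: np.ndarray  # 2-D int array
    x0: float  # west edge
    y0: float  # south edge
    cell: float  # cell size in meters
    legend: dict[int, str] = field(default_factory=dict)
    nodata: int = -1

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def code_at(self, x, y):
        """Class code at point(s) (x, y); ``nodata`` off-map. Vectorized."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell).astype(int)
        row = (self.nrows - 1) - np.floor((y - self.y0) / self.cell).astype(int)
        ok = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        out = np.full(np.broadcast(x, y).shape, self.nodata, dtype=int)
        out[ok] = self.values[row[ok], col[ok]]
        return out if out.ndim else int(out)

    def name_at(self, x: float, y: float) -> str | None:
        code = self.code_at(x, y)
        return self.legend.get(int(code))

    def write_ascii(self, path: str | Path) -> None:
        """Write as ESRI ASCII grid; the legend goes to a JSON sidecar."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.x0}\n")
            fh.write(f"yllcorner {self.y0}\n")
            fh.write(f"cellsize {self.cell}\n")
            fh.write(f"NODATA_value {self.nodata}\n")
            for row in self.values:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
        with open(path.with_suffix(path.suffix + ".legend.json"), "w") as fh:
            json.dump({str(k): v for k, v in self.legend.items()}, fh)

    @classmethod
    def read_ascii(cls, path: str | Path) -> "CategoricalRaster":
        path = Path(path)
        header: dict[str, float] = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
                ):
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([int(v) for v in parts])
        values = np.asarray(rows, dtype=int)
        legend_path = path.with_suffix(path.suffix + ".legend.json")
        legend: dict[int, str] = {}
        if legend_path.exists():
            with open(legend_path) as fh:
                legend = {int(k): v for k, v in json.load(fh).items()}
        return cls(
            values=values,
            x0=header["xllcorner"],
            y0=header["yllcorner"],
            cell=header["cellsize"],
            legend=legend,
            nodata=int(header.get("nodata_value", -1)),
        )
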