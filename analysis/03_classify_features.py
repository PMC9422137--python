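"""Classify raw road/fence polylines into the four configuration layers.

Reads the raw layers written by 01_build_landscape.py, partitions each road
into RNF / R1F / R2F stretches by testing fence presence on each side within
the class's right-of-way buffer (40 m paved, 20 m unpaved), keeps leftover
fences as FENCE, and — because the generator also wrote the ground truth —
reports how much road length the classifier assigns to the correct class.

Outputs: classified_<CLASS>.geojson and classification_summary.csv.
"""

import argparse
from pathlib import Path

import pandas as pd
from shapely.ops import unary_union

from fenceline import geoio
from fenceline.features import (
    ConfigClass,
    FenceRecord,
    RoadClass,
    RoadRecord,
    classify_road_segments,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--split-step", type=float, default=50.0)
    args = ap.parse_args()
    lsdir = args.out_dir / "landscape"

    road_lines, road_props = geoio.read_line_layer(lsdir / "roads.geojson")
    fence_lines, _ = geoio.read_line_layer(lsdir / "fences.geojson")
    roads = [
        RoadRecord(g, RoadClass(p["road_class"]))
        for g, p in zip(road_lines, road_props)
    ]
    fences = [FenceRecord(g) for g in fence_lines]

    layers = classify_road_segments(roads, fences, split_step=args.split_step)

    rows = []
    total_road = sum(r.geometry.length for r in roads)
    agree_len = 0.0
    for cc in ConfigClass:
        geoio.write_line_layer(
            args.out_dir / f"classified_{cc.value}.geojson",
            layers[cc].geometries,
            [{"config_class": cc.value}] * len(layers[cc].geometries),
        )
        truth_path = lsdir / f"truth_{cc.value}.geojson"
        truth_km = None
        if truth_path.exists():
            truth_lines, _ = geoio.read_line_layer(truth_path)
            truth_km = sum(g.length for g in truth_lines) / 1000.0
            if cc is not ConfigClass.FENCE:
                truth_buf = unary_union([g.buffer(0.5) for g in truth_lines])
                agree_len += unary_union(layers[cc].geometries).intersection(truth_buf).length
        rows.append((cc.value, layers[cc].total_length_km, truth_km))
    table = pd.DataFrame(rows, columns=["config_class", "classified_km", "truth_km"])
    table.to_csv(args.out_dir / "classification_summary.csv", index=False)

    road_out = sum(
        layers[cc].total_length_m for cc in (ConfigClass.RNF, ConfigClass.R1F, ConfigClass.R2F)
    )
    print(table.to_string(index=False))
    print(f"road length conserved to {abs(road_out - total_road) / total_road:.2e} (relative)")
    print(f"road length in the ground-truth class: {100 * agree_len / total_road:.2f}%")


if __name__ == "__main__":
    main()
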