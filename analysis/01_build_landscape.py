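"""Generate the synthetic study landscape and report feature densities.

Builds a 30 x 30 km landscape shaped like a fenced rangeland system — a grid
of pasture fences, a sparser road grid whose stretches are unfenced, fenced on
one side, or fenced on both sides, and patchy land cover — then writes the raw
and ground-truth layers plus a per-class density table.

Outputs (under --out-dir, default results/):
    landscape/roads.geojson, fences.geojson   raw inputs for the classifier
    landscape/truth_<CLASS>.geojson           ground-truth configuration layers
    landscape/landcover.asc (+ legend)        categorical land cover
    feature_densities.csv                     km and km/km^2 per class
"""

import argparse
from pathlib import Path

from shapely.geometry import box

from fenceline import geoio, synth
from fenceline.pipeline import summarize_features


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    config = synth.LandscapeConfig(seed=args.seed)
    land = synth.gen_landscape(config)

    out = args.out_dir / "landscape"
    out.mkdir(parents=True, exist_ok=True)
    geoio.write_line_layer(
        out / "roads.geojson",
        [r.geometry for r in land.roads],
        [{"road_class": r.road_class.value} for r in land.roads],
    )
    geoio.write_line_layer(out / "fences.geojson", [f.geometry for f in land.fences])
    for cc, layer in land.true_layers.items():
        geoio.write_line_layer(
            out / f"truth_{cc.value}.geojson",
            layer.geometries,
            [{"config_class": cc.value}] * len(layer.geometries),
        )
    land.landcover.write_ascii(out / "landcover.asc")

    table = summarize_features(land.true_layers, box(*land.extent))
    table.to_csv(args.out_dir / "feature_densities.csv", index=False)
    print(f"landscape seed {args.seed}, extent {land.extent}")
    print(table.to_string(index=False))
    print(f"wrote layers to {out}/")


if __name__ == "__main__":
    main()
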