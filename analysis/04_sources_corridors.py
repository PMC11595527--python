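"""Identify ecological sources and least-cost corridors.

Runs morphological spatial pattern analysis on the habitat map, keeps
core patches of at least 35 km2 as ecological sources, converts the
ensemble suitability surface into a 1-100 resistance surface, and maps
least-cost corridors (with 20,000-unit cost-weighted swaths) between
adjacent sources. Outputs land in results/04_corridors/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from corridorscape.corridors import build_network, resistance_from_suitability
from corridorscape.mspa import CLASS_CODES, mspa_classify, select_sources
from corridorscape.pipeline import _json_default, corridors_to_geojson, sources_to_geojson
from corridorscape.raster import read_raster, write_raster

ROOT = Path(__file__).resolve().parents[1] / "results"
IN, OUT = ROOT / "02_sdm", ROOT / "04_corridors"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    habitat = read_raster(IN / "habitat.asc")
    suitability = read_raster(IN / "suitability.asc")

    class_map = mspa_classify(habitat, edge_width_s=1)
    summary = class_map.summary()
    print("MSPA classes (cells):")
    print(summary[summary["cells"] > 0].to_string(index=False))

    sources = select_sources(class_map, min_area_km2=35.0)
    print(f"{sources.count} ecological sources >= 35 km2, "
          f"total {sources.total_area_km2:.1f} km2 "
          f"(core cells overall: {class_map.count('core')})")

    resistance = resistance_from_suitability(suitability, r_min=1.0, r_max=100.0)
    network = build_network(sources, resistance, cutoff=20000.0, drop_above_cutoff=False)
    stats = network.stats()
    print(f"{stats['count']} corridors; length mean {stats['mean_length_m']:.0f} m "
          f"(range {stats['min_length_m']:.0f}-{stats['max_length_m']:.0f} m)"
          if stats["count"] else "no corridors")
    for c in network.corridors:
        print(f"  sources {c.source_pair}: cost-weighted distance {c.lcp_cost:.0f}, "
              f"length {c.length_m:.0f} m, swath {int(c.swath.sum())} cells")

    write_raster(class_map.classes, OUT / "mspa_classes.asc")
    summary.to_csv(OUT / "mspa_summary.csv", index=False)
    grid = habitat.grid
    (OUT / "sources.geojson").write_text(
        json.dumps(sources_to_geojson(sources, grid), default=_json_default))
    (OUT / "corridors.geojson").write_text(
        json.dumps(corridors_to_geojson(network, grid), default=_json_default))
    (OUT / "network_stats.json").write_text(json.dumps(stats, indent=2, default=_json_default))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
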