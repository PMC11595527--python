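"""Rank sources and corridors into four importance levels.

Sources are ranked by dPC (higher = more critical to overall
connectivity), corridors by standardized cost-weighted distance (lower
cost = more important). Also recomputes, with the same percent-decline
arithmetic the package applies to its own outputs, the published
habitat-area and corridor-count declines. Outputs land in
results/05_priorities/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from corridorscape.corridors import Corridor, CorridorNetwork
from corridorscape.prioritize import percent_decline, rank_corridors, rank_sources

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "05_priorities"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    patches = pd.read_csv(ROOT / "03_connectivity" / "patches.csv")
    src_rank = rank_sources(pd.Series(patches["dPC_1000m"].to_numpy(),
                                      index=patches["patch_id"]))
    src_rank.to_csv(OUT / "source_ranking.csv", index=False)
    n_top = (src_rank["importance_class"] == 4).sum()
    print(f"{len(src_rank)} patches ranked by dPC; {n_top} in the top importance class")

    corridors_geo = json.loads((ROOT / "04_corridors" / "corridors.geojson").read_text())
    feats = corridors_geo["features"]
    if feats:
        network = CorridorNetwork([
            Corridor(
                source_pair=(f["properties"]["source_a"], f["properties"]["source_b"]),
                path=np.empty((0, 2), int),
                lcp_cost=f["properties"]["lcp_cost"],
                length_m=f["properties"]["length_m"],
                swath=np.zeros((1, 1), bool),
                cutoff=20000.0,
            )
            for f in feats
        ])
        cor_rank = rank_corridors(network)
        cor_rank.to_csv(OUT / "corridor_ranking.csv", index=False)
        print("corridor ranking (lower standardized cost = more important):")
        print(cor_rank.to_string(index=False))

    declines = {
        "habitat_1995_to_2020_pct": percent_decline(91571.0, 15436.0),
        "habitat_1995_to_2050_pct": percent_decline(91571.0, 10002.0),
        "corridors_1995_to_2050_pct": percent_decline(332.0, 38.0),
    }
    (OUT / "published_declines.json").write_text(json.dumps(declines, indent=2))
    print("published-scale declines recomputed from the printed values:")
    for k, v in declines.items():
        print(f"  {k}: {v}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
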