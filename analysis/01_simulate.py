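"""Generate the synthetic study landscape.

Builds the default fragmented landscape (three plateau habitat blocks,
two stepping-stone islets, faint inter-block ridges on a 60x60 km grid
of 300 m cells), its covariate stack (3 informative + 1 engineered
collinear layer), and 200 presence + 200 background points, and writes
everything under results/01_landscape/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from corridorscape.raster import write_raster
from corridorscape.synthland import (
    default_landscape,
    make_covariates,
    make_suitability,
    sample_occurrences,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "01_landscape"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = default_landscape(seed=SEED)
    truth = make_suitability(spec)
    covariates = make_covariates(
        truth, n_informative=3, n_collinear=1, noise_sd=0.05, seed=SEED + 1
    )
    occurrences = sample_occurrences(truth, n_presence=200, seed=SEED + 2)

    write_raster(truth, OUT / "latent_suitability.asc")
    for name, layer in covariates.items():
        write_raster(layer, OUT / f"{name}.asc")
    occurrences.to_csv(OUT / "occurrences.csv", index=False)

    habitat_km2 = (truth.data >= 0.5).sum() * truth.grid.cell_area_km2
    print(f"landscape: {spec.width}x{spec.height} cells at {spec.cell_size:.0f} m "
          f"({truth.grid.extent_area_km2:.0f} km2)")
    print(f"latent habitat (suitability >= 0.5): {habitat_km2:.1f} km2")
    print(f"covariate layers: {', '.join(covariates)}")
    print(f"occurrences: {len(occurrences)} points "
          f"({(occurrences['label'] == 'presence').sum()} presences)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
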