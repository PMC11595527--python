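"""Fit the ensemble habitat suitability model.

Reads the simulated occurrences and covariates, thins presences to 1 km,
screens covariates by VIF (< 10), splits 75/25, fits the three learner
families, gates them at AUC >= 0.8 and TSS >= 0.7, averages survivors
with (AUC - 0.5)^2 weights, reports jackknife variable importance, and
binarizes the ensemble surface at the max-TSS threshold. Outputs land in
results/02_sdm/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from corridorscape import sdm
from corridorscape.learners import default_learners, maxent_learner
from corridorscape.raster import read_raster, write_raster

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"
IN, OUT = ROOT / "01_landscape", ROOT / "02_sdm"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    occurrences = pd.read_csv(IN / "occurrences.csv")
    stack = {
        p.stem: read_raster(p) for p in sorted(IN.glob("*.asc"))
        if p.stem != "latent_suitability"
    }
    truth = read_raster(IN / "latent_suitability.asc")

    thinned = sdm.thin_occurrences(occurrences, min_distance=1000.0)
    print(f"thinning: {int((occurrences['label'] == 'presence').sum())} presences -> "
          f"{int((thinned['label'] == 'presence').sum())}")

    retained, vif_trace = sdm.vif_screen(stack, thinned, threshold=10.0)
    dropped = [n for n in stack if n not in retained]
    print(f"VIF screen: kept {retained}, dropped {dropped}")
    vif_trace.to_csv(OUT / "vif_trace.csv", index=False)

    train, test = sdm.split_train_test(thinned, train_fraction=0.75, seed=SEED + 3)
    X_train = sdm.sample_stack(stack, train, retained)
    y_train = (train["label"] == "presence").to_numpy()
    X_test = sdm.sample_stack(stack, test, retained)
    y_test = (test["label"] == "presence").to_numpy()

    fits, scores = {}, []
    for learner in default_learners(seed=SEED + 4):
        learner.fit(X_train, y_train)
        fits[learner.learner_id] = learner
        ev = sdm.evaluate(learner, X_test, y_test)
        scores.append((learner.learner_id, ev))
        print(f"  {learner.learner_id}: AUC = {ev.auc:.3f}, TSS = {ev.tss:.3f}")

    result = sdm.gate_and_weight(scores, auc_min=0.8, tss_min=0.7)
    for lid, reason in result.excluded:
        print(f"  excluded {lid}: {reason}")
    for lid, raw, w in result.retained:
        print(f"  retained {lid}: raw weight {raw:.4f}, normalized {w:.3f}")

    suitability = sdm.ensemble_predict(fits, result, stack, retained)
    corr = float(np.corrcoef(truth.data.ravel(), suitability.data.ravel())[0, 1])
    print(f"ensemble vs latent truth: Pearson r = {corr:.3f}")

    importance = sdm.jackknife_importance(
        lambda: maxent_learner(seed=SEED + 4), X_train, y_train, X_test, y_test, retained
    )
    importance.to_csv(OUT / "jackknife_importance.csv", index=False)
    top = importance.loc[importance["contribution_pct"].idxmax()]
    print(f"jackknife: {top['variable']} contributes most ({top['contribution_pct']:.1f}%)")

    ens_scores = np.zeros(len(y_test))
    for lid, _, w in result.retained:
        ens_scores += w * fits[lid].predict_score(X_test)
    habitat, threshold = sdm.binarize_habitat(suitability, ens_scores, y_test)
    area = habitat.data.sum() * habitat.grid.cell_area_km2
    print(f"binarized at max-TSS threshold {threshold:.3f}: {area:.1f} km2 habitat")

    write_raster(suitability, OUT / "suitability.asc")
    write_raster(habitat, OUT / "habitat.asc")
    (OUT / "sdm_report.json").write_text(json.dumps({
        "per_learner": {lid: {"auc": ev.auc, "tss": ev.tss} for lid, ev in result.scores.items()},
        "weights": {lid: w for lid, _, w in result.retained},
        "truth_correlation": corr,
        "binarization_threshold": threshold,
        "habitat_area_km2": area,
    }, indent=2))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
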