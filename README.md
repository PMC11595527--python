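# corridorscape

Habitat suitability, graph-theoretic connectivity, and least-cost
corridor analysis for fragmented landscapes, built around the workflow
used to assess the declining habitat network of Reeves's pheasant
(*Syrmaticus reevesii*) in central China: ensemble species distribution
modeling, connectivity indices at species dispersal distances,
morphological delineation of ecological sources, corridor mapping over a
resistance surface, and four-level conservation prioritization.

The package is aimed at spatial ecologists and conservation planners who
want each of those stages as a tested, scriptable Python function rather
than a chain of GIS tool clicks — and at anyone who needs a synthetic
landscape generator with known ground truth to validate such a pipeline.

## The pipeline

1. **Occurrence preparation** — presence records are spatially thinned
   (default 1 km) against pseudoreplication; covariates are screened by
   iterative variance inflation factor (drop the worst layer while any
   VIF ≥ 10).
2. **Ensemble suitability model** — three learner families (smooth
   additive, random forest, maximum-entropy-style logistic) are fitted
   on a stratified 75/25 presence/background split. Each is scored on
   the held-out set by AUC (Mann–Whitney rank statistic) and TSS
   (max over thresholds of sensitivity + specificity − 1); learners with
   AUC < 0.8 or TSS < 0.7 are excluded, survivors averaged with weights
   `w_m ∝ (AUC_m − 0.5)²`. Jackknife (leave-one-variable-out AUC drop)
   gives percent variable contributions. The surface is binarized at the
   max-TSS threshold.
3. **Connectivity** — habitat patches (8-connected components, areas
   `a_i`, landscape area `A_L`) enter the landscape graph with links at
   dispersal distance `d*` and dispersal probabilities
   `p_ij = exp(−α·d_ij)`, `α = ln 2 / d*`:

   - `IIC = Σ_i Σ_j a_i a_j / (1 + nl_ij) / A_L²` (topological links),
   - `PC = Σ_i Σ_j a_i a_j P*_ij / A_L²` (max-product path probability),
   - `dPC_k = (PC − PC′_k) / PC × 100` (index drop when patch k is removed),

   evaluated at 500 m (average) and 1000 m (maximum) movement distances.
4. **Ecological sources** — morphological spatial pattern analysis
   (core / islet / perforation / edge / loop / bridge / branch) on the
   binary habitat map; core patches ≥ 35 km² become sources.
5. **Corridors** — suitability `H` maps linearly to resistance
   `R = 1 + 99 (1 − H)`; cost-weighted distance (CWD) over the
   8-neighbor grid graph yields least-cost paths between CWD-allocation-
   adjacent sources and corridor swaths `CWD_a + CWD_b − lcp ≤ 20,000`.
6. **Prioritization** — sources ranked by dPC, corridors by standardized
   cost-weighted distance, each binned at percentile 25/50/75 into four
   importance levels.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
package's synthetic landscape (three plateau habitat blocks, stepping
stones and faint ridges on a 60 × 60 km grid of 300 m cells):

```bash
python analysis/01_simulate.py
python analysis/02_suitability_model.py
python analysis/03_connectivity.py
python analysis/04_sources_corridors.py
python analysis/05_prioritize.py
```

`02_suitability_model.py` prints:

```
thinning: 200 presences -> 109
VIF screen: kept ['env2', 'env3'], dropped ['collin1', 'env1']
  additive: AUC = 0.904, TSS = 0.749
  forest: AUC = 0.882, TSS = 0.729
  maxent: AUC = 0.879, TSS = 0.729
  retained additive: raw weight 0.1630, normalized 0.360
  retained forest: raw weight 0.1461, normalized 0.323
  retained maxent: raw weight 0.1433, normalized 0.317
ensemble vs latent truth: Pearson r = 0.829
binarized at max-TSS threshold 0.559: 423.5 km2 habitat
```

The engineered collinear covariate (`collin1`) is caught by the VIF
screen, all three learners clear the quality gates, and the weighted
ensemble reconstructs the latent suitability field (r = 0.83).
`03_connectivity.py` then reports IIC and PC rising from the 500 m to
the 1000 m dispersal distance (0.00366 → 0.00393 and 0.00390 → 0.00417
here), `04_sources_corridors.py` finds the three ≥ 35 km² sources and
the three least-cost corridors linking them (mean length ≈ 22 km), and
`05_prioritize.py` bins patches and corridors into the four importance
levels and recomputes the published-scale declines (83.14% habitat loss
1995→2020; 88.55% corridor loss 1995→2050).

The same pipeline runs in one call on user data or synthetic data via
the CLI:

```bash
corridorscape run-all --out runs/demo --seed 1
corridorscape connectivity --habitat runs/demo/habitat.asc --distances 500,1000 --out report.json
```

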