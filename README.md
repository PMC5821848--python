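# bioregionize

Beta-diversity bioregionalization of gridded species assemblages, with driver
attribution.

Given a grid-cell × species presence–absence matrix, the package answers two
questions that recur throughout historical biogeography — *how many
compositionally distinct regions does a biota fall into, and where are they?*
and *what explains the boundaries: climate, topography, dispersal barriers
such as large rivers, or vegetation structure?* The motivating application is
the regionalization of species-rich tropical faunas (e.g. Amazonian anurans on
a 50 × 50 km grid), where large rivers are candidate dispersal barriers and
strong climate gradients shape range limits.

## Method

1. **Turnover.** Pairwise dissimilarity between cells uses the Simpson
   turnover index. With `a` species shared by two cells, `b` private to the
   neighboring cell and `c` private to the focal cell,

   βsim = min(b, c) / (a + min(b, c)),

   i.e. one minus the Simpson similarity `a/(a + min(b, c))`. Nested
   assemblages score 0, so richness gradients do not masquerade as regional
   boundaries; only species replacement counts.

2. **Consensus Ward regionalization.** Turnover matrices carry many tied and
   zero values, so the Ward dendrogram topology depends on the input order of
   the cells. The scan builds Ward trees (Lance–Williams update on raw
   dissimilarities, order-determined tie-breaks) for many random orderings of
   the cells, cuts each at k = 2..K_max, and scores every partition by
   **explained dissimilarity** (share of total pairwise dissimilarity falling
   between clusters) and **mean silhouette width**. The cluster count is
   chosen by a dual criterion: the smallest k whose explained dissimilarity
   reaches 0.90, advanced while the silhouette still increases. Replicate
   partitions at the chosen k are condensed into one region map by Ward
   clustering of the co-classification frequency matrix.

3. **Driver attribution.** Each predictor family (current climate,
   topography, vegetation percentages) is reduced to two standardized PCA
   axes; historical-climate predictors are current minus Last Glacial Maximum
   temperature and precipitation (circulation models averaged first); river
   banks enter as a categorical term. Multinomial logistic regressions of
   region membership are fitted on **every subset** of the nine terms, ranked
   by AICc with Akaike weights and percent deviance explained (%DE), and the
   best model's %DE is decomposed into unique and shared fractions of the
   climate / topography / rivers / vegetation groups by inclusion–exclusion.

4. **Synthetic landscapes.** Because real range-map compilations are rarely
   redistributable, a generator produces lattice landscapes with known ground
   truth: river polylines partition the grid into blocks, environmental
   gradients provide predictors, and species ranges grow by a spreading-dye
   process with a river-crossing penalty and optional climatic niche
   filtering. Planted-region recovery validates the whole chain.

## Worked example

The dual-criterion rule applied to a published cluster-quality series for
Amazonian anurans (577 species), and Akaike weights recomputed from the
published ΔAICc values of the six top driver models:

```python
>>> from bioregionize import select_k, akaike_weights
>>> from bioregionize.datasets import amazonian_anuran_scan, AMAZONIAN_DRIVER_DELTA_AICC
>>> select_k(amazonian_anuran_scan(), threshold=0.90)
7
>>> akaike_weights(AMAZONIAN_DRIVER_DELTA_AICC).round(4)
array([9.534e-01, 3.720e-02, 8.600e-03, 8.000e-04, 0.000e+00, 0.000e+00])
```

Explained dissimilarity first reaches 0.90 at k = 6 (0.909); the silhouette
rises from 0.313 to 0.336 at k = 7 and falls back to 0.334 at k = 8, so seven
regions are selected. The best driver model carries essentially all the
weight of evidence (0.95).

An end-to-end synthetic run — two rivers cut a 10 × 10 lattice into four
blocks, 30 endemic species seeded per block, crossing probability 0.02:

```python
>>> from bioregionize import PipelineConfig, run_pipeline
>>> cfg = PipelineConfig.from_dict(dict(
...     seed=7,
...     simulation=dict(rows=10, cols=10,
...                     rivers=[{"type": "horizontal", "at": 5},
...                             {"type": "vertical", "at": 5}],
...                     n_species=120, range_size=["uniform", 10, 20],
...                     crossing_probability=0.02, balanced_origins=True),
...     k_max=8, n_reorder=10, ridge_lambda=1e-3, out_dir="demo_out"))
>>> manifest = run_pipeline(cfg)
>>> manifest["stages"]["regionalize"]
{'chosen_k': 4}
>>> manifest["stages"]["ground_truth"]
{'ari_vs_truth': 1.0, 'true_n_blocks': 4}
>>> manifest["stages"]["drivers"]["best_terms"]
['RIVERS']
```

The scan recovers exactly the four planted blocks (adjusted Rand index 1.0
against ground truth) and the AICc ranking identifies the river category as
the dominant driver. Output CSVs (region scan, region labels, cell
summaries, model ranking, deviance partition) and a JSON manifest land in
`demo_out/`.

The same workflow is available from the shell:

```bash
bioregionize simulate --rows 10 --cols 10 --n-species 120 --seed 7 --out-dir demo
bioregionize pipeline --config config.yaml --seed 7 --out-dir demo_out
bioregionize sweep --config config.yaml --thresholds 0,1,2,3 --out-dir sweep_out
```

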