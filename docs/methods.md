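# Methods

This note records the models, conventions and design choices behind
`bioregionize`, in the spirit of a statistical supplement: what is computed,
under which assumptions, and where the genuinely open choices were made.

## Simpson turnover

For cells with species sets X (focal) and Y (neighboring), a = |X ∩ Y|,
b = |Y \ X|, c = |X \ Y|, the dissimilarity is

    βsim(X, Y) = min(b, c) / (a + min(b, c)) = 1 − a / (a + min(b, c)).

Properties relied on downstream: symmetric; zero on the diagonal and for
nested pairs; 1 for disjoint pairs; bounded in [0, 1]; insensitive to
richness differences because only the *smaller* private-species count enters.
The index is undefined for empty cells, which are therefore dropped (not
imputed) before the pairwise computation. Values are kept at full floating
precision — ties in βsim are real features of presence–absence data and are
handled downstream by the randomized-order consensus, not by rounding.

The pairwise computation is vectorized (a = X·Xᵀ over the 0/1 matrix); a
per-pair (a, b, c) component table can be retained for diagnostics.

## Ward clustering with order-determined tie-breaks

Agglomeration follows the Lance–Williams recurrence

    d(uv, w) = ((n_u + n_w) d(u, w) + (n_v + n_w) d(v, w) − n_w d(u, v))
               / (n_u + n_v + n_w),

applied by default to the raw dissimilarities (the legacy "ward.D"
convention of the R ecosystem in which this analysis style originated; the
squared-input "ward.D2"/scipy convention is available via
`variant="ward.D2"`, and is cross-checked against scipy in the tests).
Heights are recorded exactly as produced; monotonicity is not assumed, and a
cut at k is defined combinatorially — undo the last k − 1 merges — rather
than by a height threshold, so non-monotone height sequences cannot corrupt
partitions.

Ties are broken deterministically toward the smallest pair indices under the
supplied cell ordering: active clusters are kept sorted by their minimal leaf
position in the permutation, and the first minimal entry of the upper
triangle (row-major) is merged. Different input orders can therefore produce
different trees on tied input. This is deliberate: it is the mechanism the
randomized-reorder scan uses to expose topology uncertainty caused by the
many ties and zeros of turnover matrices.

## Scan, selection rule, consensus

`scan_regions` draws `n_reorder` random permutations (default 50) from a
single seeded generator, builds one dendrogram per permutation, cuts each at
k = 2..min(K_max, n−1) (default K_max = 50), and averages two quality
metrics per k across replicates:

- **Explained dissimilarity**: Σ d(i, j) over between-cluster unordered
  pairs divided by Σ d(i, j) over all unordered pairs. Non-decreasing over
  nested cuts of one tree (refining a partition only moves pairs from within
  to between), 0 at k = 1, 1 for all-singletons.
- **Mean silhouette width**: mean over cells of
  (b(i) − a(i)) / max(a(i), b(i)), with a(i) the mean dissimilarity to
  own-cluster co-members and b(i) the smallest mean dissimilarity to another
  cluster; singletons contribute 0 by convention. Range [−1, 1].

`select_k` finds the smallest k whose mean explained dissimilarity reaches
the threshold (default 0.90, the conventional "suitable tree cut" level),
then advances while the mean silhouette *strictly* increases, returning the
k where it stops increasing. On the bundled published Amazonian anuran
series this yields k = 7 (explained dissimilarity crosses 0.90 at k = 6; the
silhouette rises 0.313 → 0.336 into k = 7 and drops to 0.334 at k = 8). If
the silhouette still rises at the largest scanned k, that k is returned with
a warning. "Strictly increases" is this package's operationalization of
"stops increasing"; the alternative (non-strict) reading would select the
same k on every series we examined, but the strict form makes the stopping
condition unambiguous for flat stretches.

How n replicate membership matrices become one final region map is genuinely
open; this package uses co-classification consensus: the fraction of
replicates placing each cell pair together is computed, and 1 − frequency is
Ward-clustered with the identity ordering and cut at the chosen k. This is
invariant to replicate label permutations and returns unanimous partitions
unchanged. Per-k metrics are reported as arithmetic means over replicates.

## Driver models

Predictors are reduced per family: separate PCAs (on standardized variables,
so correlation-structure PCAs) of the six current-climate variables, the six
topographic-heterogeneity variables, and the vegetation-type percentages;
the first two axes of each enter the models (CURE.PC1/2, TOPO.PC1/2,
VEGE.PC1/2). Axis signs follow the convention that the largest-magnitude
loading is positive. Historical-climate predictors HDT and HDP are current
minus LGM annual mean temperature / annual precipitation, with the LGM
circulation models averaged *before* differencing so inter-model noise
cancels. The river category (RIVERS) enters as a categorical with treatment
contrasts against its most frequent level. Pearson correlations (with
two-sided t-based p, no multiplicity correction) document which raw
variables each axis tracks.

Region membership is modeled by multinomial logistic regression with a
designated reference class (the most frequent region; the choice affects
coefficients, not deviance or AICc). The log-likelihood is maximized by
L-BFGS with an analytic gradient; an optional L2 ridge on non-intercept
coefficients (pipeline default 1e−6) guarantees finite estimates under
(quasi-)separation — which arises by construction whenever a river category
perfectly predicts regions. The reported log-likelihood, deviance and %DE
always come from the *unpenalized* likelihood evaluated at the (possibly
penalized) optimum, keeping AICc comparable across models. The parameter
count is the full coefficient structure, (K−1) × (1 + continuous terms +
Σ(levels−1)); a seven-region model with six continuous terms and a ten-level
categorical therefore has df = 96. Standard errors come from the observed
information (unpenalized Hessian) at the estimate.

Model ranking fits all 2^t term subsets (t = 9 in the standard analysis),
ranks by AICc = −2ℓ + 2k + 2k(k+1)/(n − k − 1) with n = number of grid cells
(cells are the modeled units; no spatial autocorrelation correction is
applied, matching the analysis style this implements), and attaches ΔAICc,
Akaike weights normalized over *all* fitted subsets, and %DE = 100 × (null
deviance − model deviance)/null deviance. Ties in AICc break toward fewer
terms, then the lexicographic term string.

Deviance partitioning fits all non-empty unions of the predictor groups
C (current + historical climate), T (topography), R (rivers), V (vegetation)
restricted to the best model's terms, and solves for unique/shared fractions
by inclusion–exclusion: f(S) = Σ_{B⊆S} (−1)^{|S|−|B|} [R(G) − R(G∖B)], where
R(A) is the %DE of the union of groups in A. The fractions sum exactly to
the full model's %DE; shared fractions may be negative (suppression). If the
best model spans fewer than two groups, the pipeline partitions the full
group set instead so the output stays defined.

## Synthetic landscapes

The generator emulates the statistical structure of a gridded range-map
analysis, with known ground truth:

- **Lattice and rivers.** An abstract n_rows × n_cols integer grid (no
  geodesy — the analysis needs only topology). Rivers are polylines over
  lattice corners, validated to run along grid lines and terminate on the
  boundary; severed 4-adjacencies define blocks via connected components.
  The river-bank category defaults to the block label, and the number of
  rivers/blocks is fully configurable (the real-world category count is
  analysis-dependent).
- **Environment.** Each field is a deterministic gradient (row, column or
  radial) plus seeded Gaussian noise; defaults emulate a tropical lowland
  biome (precipitation ~1400–3000 mm/yr falling eastward, temperature rising
  southward, relief concentrated in one quadrant, LGM fields cooler by 4 °C
  and drier by 500 mm with per-model noise, vegetation softmax-normalized
  percentages dominated by moist forest). TOPOMAX = TOPOMIN + non-negative
  relief by construction.
- **Species.** Spreading dye: each species seeds at a uniform cell
  (optionally within a prescribed block) and repeatedly occupies a uniformly
  drawn unoccupied 4-neighbor of its range until the drawn range size is
  reached. A candidate reachable only across a river is accepted with
  probability `crossing_probability`; a candidate outside the species'
  climatic niche (|field − niche center| > breadth, default field APRE,
  default breadth infinite) is never admissible; growth stops early when no
  admissible neighbor remains. Spreading dye is the standard macroecological
  range model and produces contiguous ranges with controllable size. Range
  sizes draw from fixed/uniform/lognormal specs (default lognormal, mean 25
  cells, σ = 0.75, at the default 20 × 20 lattice with 577 species —
  mirroring the species count of the motivating fauna); sizes exceeding the
  lattice are capped with a warning.
- **Randomness.** One master seed; species s uses the independent substream
  `default_rng([seed, s])`, so outputs are byte-identical across runs and
  robust to execution-order changes.

What the generator does **not** emulate: real geometry and projections,
spatially autocorrelated noise fields, range fragmentation, taxonomic error,
or observer effort. Passing planted-recovery tests therefore demonstrates
the *method chain* is correct and well-calibrated on clean structure, not
that any empirical dataset satisfies its assumptions.

## Problem sizes and validation conditions

Planted-recovery studies use 10 × 10 lattices cut by two full-span rivers
into four 25-cell blocks, 30 endemic species per block (120 species),
crossing probability 0.02, uniform range sizes 10–20 cells, scans to
K_max = 8 over 10 reorderings, across 20 seeds — sizes chosen so the full
suite and the acceptance script run comfortably on a laptop while leaving
the recovery problem non-trivial (within-block turnover is substantial;
cross-block turnover is near-complete). Under these conditions the
selection rule returns the true k = 4 and the consensus partition reaches
adjusted Rand ≥ 0.9 in ≈ 90% of seeds; failures are k = 5 solutions that
split one block, an expected consequence of tie-rich turnover structure.
Driver-recovery studies use n = 240 cells with a four-level river category
and noise predictors (rivers-only signal), and n = 2000 for coefficient
recovery.

## Numerical conventions and degenerate inputs

- Tie comparisons in agglomeration use exact float equality; ties arise from
  identical arithmetic on identical inputs, which is the relevant case.
- `explained_dissimilarity` raises on all-zero dissimilarity (a degenerate
  landscape with one composition).
- `mean_silhouette` raises for k = 1; singleton clusters score 0.
- Constant columns are dropped from PCAs with a warning; constant continuous
  predictors raise in the multinomial design.
- L-BFGS occasionally reports line-search failure within float precision of
  the optimum; convergence is therefore additionally accepted when the final
  gradient norm is negligible. Genuine non-convergence (unpenalized fits
  under separation) is flagged, and the dredge excludes failed fits from the
  Akaike weights with a log record.
- AICc is undefined when n − k − 1 ≤ 0 and raises.

## Known limitations

- Raw-dissimilarity Ward ("ward.D") can produce non-monotone merge heights;
  dendrogram *heights* should not be read as an ultrametric.
- The co-classification consensus is one defensible aggregation among
  several; with few reorderings on heavily tied matrices it can differ from,
  e.g., majority-vote relabeling approaches.
- All-subsets fitting is exponential in the term count (2^9 = 512 fits in
  the standard analysis); `max_terms` bounds the enumeration if needed.
- Cells are treated as independent observations in the multinomial models;
  no spatial autocorrelation correction is offered.
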