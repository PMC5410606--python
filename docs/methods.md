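# Methods

## The model of the data

The package operates on preprocessed, spatially registered 4D images and on
binary region masks that are taken as authoritative inputs: no motion
correction, filtering, registration, ICA or mask trimming is performed
here. Within a network of `N ≥ 3` regions, every voxel contributes one BOLD
series; all computation happens on 0-based voxel indices in the image's own
grid (world coordinates are carried in the affine but never used — node
distances are reported in voxel units).

## Node identification

For each ordered region pair `(x, y)` the node `V_xy` is the voxel of `x`
maximising the thresholded total correlation to `y`: the sum of its Pearson
correlations to every voxel of `y`, keeping only values strictly greater
than the threshold `tau`.

* **`tau` (default 0.25, dimensionless).** The conventional cutoff of
  global-brain-connectivity analyses. Sub-threshold correlations contribute
  exactly zero rather than their signed value; with `tau ≥ 0` this also
  removes all negative correlations, so no separate sign handling is
  needed.
* **Strict inequality.** A correlation exactly at `tau` is excluded.
* **All-sub-threshold fallback.** If no correlation anywhere passes `tau`,
  the voxel with the largest unthresholded sum is selected and the node is
  flagged (`suprathreshold=False`). This keeps the node table at its full
  `N(N−1)` shape; flags propagate into the pipeline's `flags.tsv` report.
* **Ties.** Exact score ties resolve to the lowest linearised voxel index.
  Because optimised matrix products can differ in the last ulp between
  bit-identical rows, candidates within a relative `1e-9` of the maximum are
  re-scored with sequential dot products before the tie rule is applied;
  this makes the selection exactly reproducible across BLAS
  implementations.
* **Constant series.** Zero-variance voxels are retained (removing them
  would shift voxel indexing) and all their correlations are defined as 0:
  a flat series carries no connectivity evidence.
* **Nuisance regression.** When regressors (e.g. white-matter/CSF signals)
  are supplied, every voxel series is replaced by its least-squares
  residual against an intercept plus the regressors before any correlation
  is computed; correlations of residuals equal partial correlations
  controlling for the regressors.

The same voxel may be selected as the node towards several targets; this is
permitted (the duplicated pair then correlates at exactly 1) but counted
and reported, since it inflates intra-regional connectivity.

## Connectivity measures

In the context of region pair `{a, b}` the `(N−1)²` node pairs between the
regions split into primary (1 edge), primary-secondary (`2(N−2)`) and
secondary (`(N−2)²`) classes; `R1` is the primary edge value and `R12`/`R2`
are means over their classes. `RI(a)` summarises the `(N−1)(N−2)/2` pairs
among region `a`'s own nodes.

Design choices where the definitions were genuinely open:

* `R12` and `R2` are implemented as means over **explicitly enumerated edge
  sets** rather than via nested summation indices with skip rules; the
  class cardinalities (`2(N−2)`, `(N−2)²`) fix the intended sets
  unambiguously, and the subtraction form of `R2` (total inter-region sum
  minus primary and primary-secondary sums, divided by `(N−2)²`) is kept as
  an internal cross-check — the two agree to machine precision by
  construction.
* `RI` defaults to the **mean** over intra pairs so that all four measures
  share the [−1, 1] scale; the literal raw sum is available via
  `RunConfig(ri_mode="raw_sum")`.
* Per-region profiles average **pair-level** measure values over the `N−1`
  pairs containing the region (rather than pooling edges directly); for
  `RI` the profile is the region's own value.
* Edges between nodes of different networks appear in the full node-by-node
  matrix but carry no label and enter no measure: the taxonomy is defined
  within a network only.
* Network-level values are unweighted means over pairs (regions for `RI`).

Edge labels are a function of the network alone — independent of subject
and of data — and an edge belonging to context `{a, b}` carries no label in
any other context.

## Group statistics

Between-group comparison uses Welch's unequal-variance t-test with
Satterthwaite degrees of freedom and two-sided p-values, both edgewise (per
off-diagonal matrix entry) and on network-level measures. Multiple testing
is controlled with Benjamini–Hochberg step-up FDR applied *within
families*: all upper-triangle edges form one family for a matrix
comparison; each measure type (R1, R12, R2, RI) forms one family across its
comparisons. Edgewise results report an uncorrected `p < 0.001` mask
alongside the FDR mask (`alpha = 0.05` by default). With three or more
groups a one-way ANOVA omnibus test precedes pairwise Welch post-hoc tests,
BH-corrected within the declared family; both raw and adjusted p-values are
reported. Degenerate inputs are explicit: two constant equal samples are an
error; constant unequal samples yield `p = 0` with a warning.

## Mask perturbation

To emulate the variability of ICA-derived regions, masks are eroded or
inflated by standard binary morphology (structuring element of face (6),
edge (18) or corner (26) connectivity; face adjacency is the default, and
iteration counts — not target sizes — parameterise the variants), or
"adjusted" by seeded boundary jitter: `round(fraction·size)` boundary
voxels are swapped for an equal number of outside neighbours, preserving
total size while moving up to `2·fraction` of the membership.
Externally supplied masks (e.g. from an independent ICA) are a fourth
variant kind. Reproducibility is quantified by correlating each node's
series under variant masks with its series under the originals — matched
by `(source, target)` key, per subject, then aggregated as mean ± sd per
source region and overall. The comparison is on series, not coordinates: a
variant that selects a different voxel with an identical series scores 1.

## The synthetic-data generator

Each network has a network-wide latent `g` and one pairwise latent `c_ab`
per unordered region pair, all AR(1) with unit stationary variance
(`phi = 0.4` by default — mild temporal autocorrelation). Voxel `v` of
region `a` is

```
y_v = lam_global·g + Σ_{b≠a} [lam_bg + (lam_hub − lam_bg)·1(v = hub_ab)]·c_ab + sigma·eps_v
```

with iid standard-normal noise. One hub per ordered pair is drawn uniformly
and independently, so duplicate hubs occur naturally with probability about
`(N−2)/voxels_per_region`. A group's coupling `kappa ∈ (0, 1]` multiplies
`lam_bg` and `lam_hub` (not `lam_global`) of designated networks, emulating
attenuated within-network coupling in a patient group. Defaults:
`voxels_per_region = 60`, `T = 150` (a typical resting-state run length),
`lam_global = 0.5`, `lam_bg = 0.3`, `lam_hub = 1.0`, `sigma = 1`. Regions
are disjoint near-cubic cuboids on a small shared grid; optional Gaussian
smoothing (`smooth_sigma`, off by default) produces spatially smooth data
for mask-perturbation studies, in which case the inter-region gap should
exceed the kernel width so perturbed masks cannot bleed into a neighbouring
region (the mask experiments use `gap = 4` with `smooth_sigma = 1`).

What the generator does *not* emulate: hemodynamic response shapes, head
motion, physiological noise spectra, spatial heterogeneity of SNR, or
anatomically shaped regions. Passing tests therefore demonstrate the
correctness and calibration of the *algorithms*, not performance on real
fMRI.

### Identifiability at the default settings

The planted hub is the **population** argmax of the selection score: its
expected correlation to the target region (≈ 0.30 under the defaults)
exceeds the background's (≈ 0.238). Two features make finite-sample
recovery imperfect, however. First, the unscaled network-wide latent lifts
*all* inter-regional correlations to just below the 0.25 threshold, so with
`T = 150` (sampling error ≈ 0.08 per correlation) threshold passes are
nearly coin-flips for background voxels. Second, the hub's own variance
(`lam_hub² + …`) dilutes its correlations, leaving a thin margin over the
maximum of ~59 competing voxels. Single-run recovery at the defaults is
therefore around 0.4–0.5 — far above chance (1/60) but not near 1; it
approaches 1 as `T` grows (the score's sampling error shrinks as
`T^(−1/2)`) or as `lam_global` shrinks. `scripts/acceptance.py` computes
the realised rate.

The same structure bounds what group differences are detectable: because
`kappa` leaves `lam_global` untouched — the global latent models residual
shared signal that real pipelines remove with global-signal regression,
which is out of scope here — secondary edges share mostly global variance,
and their population decrease under `kappa = 0.5` is small (~0.03 on R12)
relative to between-subject variability at n = 20. `R1`, computed between
the two voxels selected for the pair itself, carries the coupling signal
directly and detects reliably. In-sample node selection also introduces a
winner's-curse bias: with weakly identifiable hubs, selections align with
noise, duplicate nodes become more frequent, and intra-regional values can
be inflated in the *weaker*-coupling group. These are properties of the
method under this data model, and the acceptance outputs report them as
measured.

## Numerical conventions

* Correlations are computed as dot products of centred, unit-norm rows and
  clipped to [−1, 1]; exactly constant rows give 0.
* Node-by-node matrices are symmetrised (`(M + Mᵀ)/2`) with unit diagonal;
  TSV serialisation uses `%.17g`, so round-trips are exact and repeated
  runs are byte-identical.
* All randomness flows from explicit integer seeds (subject seeds are
  `base_seed + index`); identical seeds give bit-identical data.

## Known limitations

* Node identification and measure computation use the same data, so
  selection bias inflates measures in absolute terms; between-group
  contrasts are only partially protected (both groups share the bias only
  where selection quality is comparable).
* Duplicate nodes contribute unit edges to `RI` by design; the report in
  `flags.tsv` should be consulted when `RI` is interpreted.
* Between-network connectivity is computed but intentionally unlabelled and
  unmeasured.
* The mask jitter model moves only boundary voxels; it does not emulate
  topological changes (splits, holes) that a genuinely different ICA
  decomposition could produce — supply external masks for that case.
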