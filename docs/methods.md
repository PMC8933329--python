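# Methods

## The VR-thresholding model

Deterministic tractography with a fractional anisotropy stopping threshold
(FAT) and a fiber length threshold (FLT) defines, for every streamline, the
largest FAT at which the fiber is still tracked with length ≥ FLT. Sweeping
the FAT upward from 0 in steps of 0.01 assigns each fiber its **fa_max**;
the subject-level maximum is **FAT_max**, and each fiber's **visualized
ratio** is VR = fa_max / FAT_max × 100 %. Thresholding the tractogram at
VR ≥ 25 % and VR ≥ 50 % yields two nested fiber sets per subject that are
comparable across subjects with different absolute FA levels (e.g. tumor-
depressed hemispheres).

Two implementations of fa_max coexist:

1. **Sweep** (`famax_by_sweep`, the production path): the largest grid
   threshold t such that some contiguous run of fiber points with FA ≥ t
   has arc length ≥ FLT. The qualification predicate is monotone in t, so a
   binary search over the integer grid is exact. Thresholds are held as
   integer hundredths internally; results lie exactly on the 0.01 grid.
2. **Retracking** (`famax_by_retracking`, the test oracle): rerun the
   tracker at every grid threshold and record the largest threshold at
   which each seed still yields a surviving streamline — the literal
   repeated-threshold procedure.

The two differ semantically: the sweep scores the best run anywhere on the
fiber, retracking the run containing the seed. On the run through the seed
they agree exactly (the tracker is deterministic, so the point sets are
identical). The acceptance comparison therefore uses a validation phantom
whose within-tube FA roughness (jitter SD 0.005) is below the grid step:
under that condition the agreement is 100 % of ~1,700 seeds; with roughness
of two grid steps the best-run/seed-run gap alone drives disagreement on
~16 % of peripheral seeds. The cohort generator keeps the rougher, more
realistic jitter (0.02) — the semantics gap is a property of the published
procedure's ambiguity, documented rather than hidden.

The minimal tracker follows the voxelwise principal direction from every
seed in both orientations with a fixed 1 mm step, stopping when the
interpolated FA falls below the threshold, the turning angle exceeds 60°,
the direction field vanishes, or the volume edge is reached. These tracker
constants are conventional choices (the procedure they instantiate does not
prescribe them); only the test oracle depends on them.

## Networks and metrics

Fibers selected at a VR threshold are mapped to region pairs by their two
endpoints (nearest-voxel label lookup); fibers with a background endpoint or
both endpoints in one region are dropped and tallied. Pass-through counting
(every region pair a fiber's points visit) exists behind a flag for
sensitivity analysis only — it inflates hub connectivity. A pair with
**strictly more than 3** fibers is connected ("more than three" read
strictly: count 3 → no edge, count 4 → edge). Graphs are undirected,
unweighted, without self-loops.

Five matrices per subject and threshold: whole (90 nodes), left/right
hemisphere (45 each), and POS/NEG networks induced on the subject's
stimulation-mapped region sets (variable size; group summaries average the
per-subject metrics). Metrics:

- AD = 2E/N;
- EG = mean of 1/d(i,j) over ordered pairs, 1/∞ = 0 for disconnected pairs
  (Latora–Marchiori); 0 when N < 2;
- EL = mean over nodes of EG of the subgraph induced on each node's
  neighbors; nodes with < 2 neighbors contribute 0;
- AD/EG/EL-diff = value(25 %) − value(50 %). Edge nestedness across
  thresholds makes AD-diff and EG-diff non-negative; EL is not monotone
  under edge addition and its diff may take either sign.

Matrices of 0 or 1 nodes have all metrics defined as 0. Shortest paths run
through `scipy.sparse.csgraph`; the test suite pins all three metrics to a
definitional brute-force oracle (Floyd–Warshall + neighborhood subgraphs)
and to networkx at 1e-12 on hundreds of random graphs.

## Stimulation-site mapping

Stimulation points (world mm, POS = naming error, NEG = no error) take the
label of their containing voxel; background points snap to the nearest
labeled voxel center within 5 mm (ties to the smallest region id),
reflecting cortical sites that land just outside labeled gray matter after
registration; farther points are dropped with a logged count. A region may
be both POS and NEG for one subject by default; `pos_precedence` removes
POS regions from the NEG set (the counts in the emulated study do not
disambiguate the two conventions, so both are provided). Intragroup
mapping proportions are reported per region, group and polarity, with a
highlight flag at a configurable subject count (default 20).

## Statistics

- **ANCOVA**: OLS of metric on intercept + GIA indicator + tumor size;
  reported statistic is the group coefficient's t with n − 3 df (matching
  the convention of reporting T-values), the one-df F alongside. A constant
  covariate is rejected as rank-deficient; a constant *outcome* is reported
  as t = 0, p = 1 (no detectable difference).
- **Nonparametric test** for mapping counts: Mann-Whitney U (two-sided;
  exact for small tie-free samples).
- **Correlation** with aphasia level: Spearman by default (the level is
  ordinal); Pearson available.
- **FDR**: Benjamini-Hochberg within each output table (45 comparisons:
  5 kinds × 3 metrics × {25 %, 50 %, DIFF}); the family definition is a
  package choice since alternatives were not specified.
- α = 0.05 throughout.

## The synthetic cohort: study conditions

The generator emulates, at desk scale, a 30 + 30 two-group study:

| parameter | default | meaning |
|---|---|---|
| `n_regions` | 90 (45 + 45) | bilateral block parcellation, 2 mm voxels |
| bundles | 4 inter + 12 intra per hemisphere | complete-graph wiring over 6 hub regions per hemisphere |
| `peak_fa_min/max` | 0.16 / 0.53 | per-bundle tube FA; one interhemispheric anchor at 0.53 |
| `fa_jitter` | 0.02 | voxelwise tube FA roughness (SD) |
| `fatmax_scale_sd` | 0.12 | relative subject FA scaling, so FAT_max ≈ 0.52 ± 0.05 |
| `base_keep` | 0.92 | per-subject bundle retention (both groups) |
| `left_deficit` | 0.75 | GIA keeps each left intra bundle with this probability |
| tumor size | NA 2.4 ± 2.6, GIA 4.7 ± 4.3 cm³ | truncated normal at 0 |
| POS/NEG probabilities | means ≈ 8–9 POS, ≈ 16–17 NEG regions/subject | left hemisphere only; POS rarer than NEG |
| contrast regions | 2, POS prob. (0.13, 0.43) NA vs (0.40, 0.70) GIA | group-differential positive mapping |

Geometry: each hemisphere's intra bundles bow into the interhemispheric gap
at distinct depths (quadratic Bézier arcs), which (a) separates the FA
tubes in space so each keeps its per-bundle FA identity, and (b) lets every
bundle exceed the 30 mm FLT regardless of chord length. Tubes are
rasterized in ascending peak-FA order, so where tubes cross, the higher-FA
tube keeps its voxels and lower tubes acquire harmless high-FA spikes
(spikes cannot extend a contiguous ≥ FLT run). The hub wiring gives the
networks triangles, hence nonzero local efficiency. The FA anchor bundle is
interhemispheric so FAT_max does not depend on which left bundles a GIA
subject retains; consequently per-fiber VR ≈ bundle peak / 0.53
independently of the subject FA scale, as the VR construction intends.
Realized FAT_max averages ≈ 0.52, slightly below the 0.53 anchor, because
fa_max is a run minimum over a jittered tube.

Aphasia level (ordinal 0–5; 0 = none, fixed for NA): each GIA subject's
latent severity is the standardized count of deficit-induced left-bundle
drops times a signal weight (1.5) plus unit noise; levels 1–5 are assigned
by within-group latent quintiles. Under the null configuration
(`left_deficit = 1`) there are no deficit drops and the latent is pure
noise, so severity is independent of connectivity and the correlation test
stays calibrated; under an effect the level is negatively linked to
realized left connectivity by construction. The numeric coding and the
strength of the link are modeling choices for recovery testing, not claims
about any clinical instrument.

Tumor size is a covariate only — it is not geometrically embedded in the
phantom by default; `apply_lesion` can zero FA in a sphere to stress-test
tracking.

What the generator does **not** emulate: DWI signal formation and CSD,
registration error, curved/crossing-fiber anatomy beyond single-tangent
tubes, spatially realistic atlas geometry, lesion mass effects, or any
quantitative aphasia instrument. Passing tests therefore demonstrate that
the pipeline recovers the structure it is told to generate — correctness
and calibration of the machinery — not clinical validity on real data.

## Problem sizes and runtime choices

Replicate studies use deliberately small conditions so hundreds of
end-to-end cohorts run on one CPU: statistical calibration uses 200 null
cohorts of 30 + 30 subjects on a reduced 20-region configuration
(`small_config`); effect recovery uses 100 default-configuration 90-region
cohorts restricted to the left-hemisphere matrices it tests. The default
connectome (~28 bundles, ~170 fibers/subject) is far sparser than a real
90-region connectome, so absolute AD/EG/EL values are smaller than clinical
ones; all comparisons in the package are within- or between-group on the
same conditions, where scale cancels.

## Numerical and degenerate-case conventions

- Thresholds as integer hundredths; VR comparisons inclusive (≥), so the
  FAT_max fiber is retained at every threshold and boundaries are
  deterministic.
- World mm (RAS) everywhere; world → voxel by inverse affine; trilinear
  interpolation for FA, nearest voxel for labels; out-of-bounds FA samples
  are 0.
- A subject with no fiber clearing the FLT yields all-zero matrices and
  metrics with a warning (FAT_max undefined); `compute_vr` on such a
  subject raises.
- FA and label volumes must be pre-co-registered; a shape/affine mismatch
  is a hard error. No resampling or reorientation is performed.
- Every random draw descends from one root seed through named substreams
  (per subject index), so cohorts are bit-identical under a fixed seed and
  per-subject data are independent of cohort ordering; reruns produce
  byte-identical CSVs and manifests.

## Known limitations

- The fa_max sweep/retracking equivalence is exact only up to the best-run
  vs seed-run semantics discussed above; on rough FA fields the sweep is an
  upper bound.
- The Mann-Whitney calibration on small integer counts is conservative
  (observed rejection ≈ 2 % at nominal 5 %) because of heavy ties.
- POS/NEG networks of fewer than two mapped-and-wired regions carry zero
  metrics, which dilutes group contrasts in the pos/neg strata at desk
  scale.
- The tracker is intentionally minimal (single tensor-like direction per
  voxel, no interpolation of directions); it exists to realize the literal
  threshold-sweep procedure on phantoms, not to process clinical DWI.
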