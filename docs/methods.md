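# Methods

## Model and procedure

The package operationalizes a food-fish model: a causal-link scoring scheme
between functional feeding morphology and the capacity to exploit aquatic
food resources.

1. **Ingestion and filtering.** A measurement table (CSV/XLSX; one row per
   fish: species, native/alien status, standard length SL in mm, 22 raw
   trait values) is parsed with case-insensitive header matching and an
   optional alias map. Missing values are represented as absent entries,
   never as 0, because 0 is a legal presence/absence value. Only specimens
   with SL > 0 and a value for every schema trait are analysed; removals are
   logged per species.
2. **Size scaling.** Metric lengths are divided by SL, areas by SL²; ratios,
   angles and binary traits pass through. This removes isometric size
   effects (the scaled matrix is invariant under inflating a specimen's SL
   and all its metric lengths by c and areas by c²); allometry is not
   modelled.
3. **Standardization.** Every trait column is z-scored across specimens, and
   every FSP trait column is z-scored across food types, so each variable
   has mean 0 and SD 1 and carries equal weight. The FSP axis choice
   (per trait, across food types) is deliberate: it gives each trait
   comparable leverage in the cross-trait ranking that the rank correlation
   sees. The SD uses the sample (n−1) convention throughout; it is a
   parameter (`ddof`) because either convention is defensible, and the
   z-scores it yields differ only by a common factor, which rank
   correlation ignores.
4. **Optimum-type traits.** Velocity suction capacity (HyL/LJSL), relative
   gape area (OGAr/BAr) and body depth (BD) peak at intermediate values.
   For a food type on which such a trait has a nonzero effect, the
   specimen's z is replaced by −|z − z_opt| before correlating. The optimum
   values are not observable from data shipped here; the default z_opt = 0
   (the standardized sample mean) is configurable per trait. No dead-zone
   around the optimum is modelled.
5. **Trophic profiles.** TP(i, f) = Kendall tau-b between the specimen's
   (optimum-transformed) z-vector and food type f's standardized effect row.
   Tau-b (tie-corrected) rather than tau-a is essential: effect rows take at
   most five distinct values, so ties are pervasive and untied tau would cap
   |TP| well below 1 and distort the scale. Constant vectors make tau
   undefined and raise; the zero-variance policy (below) must remove them
   first.
6. **Ordination.** Covariance PCA of the standardized trait matrix
   (equivalent to correlation PCA of the raw traits) and of the raw TP
   matrix (tau values are already commensurate in [−1, 1]; no
   re-standardization). Component signs are arbitrary; each loading vector
   is flipped so its largest-magnitude entry is positive, making output
   deterministic without implying any particular published orientation.
7. **Clustering.** Mean TPs per species are clustered by species (rows) and
   by food type (columns) with Ward's minimum-variance criterion on
   unsquared Euclidean distances (the ward.D2 variant; scipy's
   `linkage(method="ward")`). Leaves are sorted lexicographically before
   linkage so merge ties break deterministically. Clade support is the plain
   bootstrap probability: the feature dimension (columns when clustering
   rows, and vice versa) is resampled with replacement `n_boot` times
   (default 10,000), the tree is rebuilt, and each original clade's support
   is the fraction of replicates containing its exact leaf set. The
   multiscale-bootstrap AU approximation is intentionally not implemented;
   plain BP is the contract here.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `ddof` | 1 | SD convention for all standardization and summaries |
| `zero_variance` | `"error"` | constant columns: raise, or `"drop"` from both the trait and FSP matrices (keeping the trait sets aligned) |
| `optima` | z = 0 per optimum trait | optimum z-values for HyL/LJSL, OGAr/BAr, BD |
| `n_boot` | 10,000 | bootstrap replicates for clade support |
| `seed` | — | controls all resampling; fixed seed ⇒ bit-identical output |

## Synthetic data: what it emulates, what it does not

`ffm.simulate` generates the study conditions end-to-end. The default
community has nine species with the reference per-species specimen counts
(10, 8, 9, 6, 10, 13, 9, 10, 10 = 85) and SL means/SDs, and continuous
traits drawn on the scaled scale (equicorrelated normals, within-species CV
8%, between-species correlation 0.3) then multiplied back by SL or SL², so
the generator encodes exact isometry and size scaling inverts the
construction. Species trait means encode three ecological groups — a
barbelled small-gape group (with oral teeth absent), a large-gape
large-head group, and a deep-bodied long-gut group — plus one average
species, loosely on the scale of real benthic freshwater fish. Binary traits
are Bernoulli per species.

The shipped default FSP (ten food resources × 22 traits) is a hand-written
**synthetic** fixture built from plausible functional-morphology reasoning
(e.g. pursuit piscivores: large gape and eye, short gut, shallow body); it
is not a transcription of any published profile set. `generate_fsp` draws
random integer matrices with configurable sparsity, rejecting draws with
all-zero food rows or constant trait columns (which standardization cannot
handle).

Consequently, passing tests demonstrate that the *pipeline* behaves
correctly under the assumed data structure (isometric scaling, multivariate
normal scaled traits, species clusters, integer profiles); they do not
validate any real community's trait values, allometric growth, measurement
error structure, or the ecological correctness of real specialist profiles.

`exact_moment_lengths` materializes an SL sample with exactly a printed
n/min/max/mean/SD (extremes at the range ends, interior points solved in a
symmetric two-point design), used to round-trip published summary tables
through `summarize_species`.

`plant_specialist` returns a *standardized* trait vector (a strictly
increasing map z + z³/4 of a food type's standardized effects, plus normal
jitter) rather than a raw record: a z-vector is defined only relative to a
sample, so no single raw specimen could carry it. It drives the
parameter-recovery checks: at zero noise and tie-free effects the planted
food's TP entry is exactly 1; at noise SD 0.1 the planted food is the argmax
in ≥ 95% of seeds; at very high noise the entry is statistically
indistinguishable from 0.

## Numerical choices and degenerate inputs

- Tau-b agrees with an explicit O(n²) pair-counting oracle to < 1e-12;
  constant vectors raise rather than return NaN.
- Standardized columns satisfy |mean| < 1e-9 and |SD − 1| < 1e-9; violations
  of the zero-variance policy raise with the offending columns listed.
- PCA explained fractions are non-increasing, sum to 1 over all components,
  and are invariant to row permutations; rank-0 input raises.
- Single-specimen species report SD = 0 by default (configurable to NaN).
- Dendrogram heights are non-decreasing; Newick branch lengths are parent
  height minus node height, with support values as internal node labels.

## Problem sizes

The test suite and acceptance script run the full pipeline at the study
scale (85 specimens × 22 traits × 10 food types), the tau oracle on 1,000
random pairs of lengths 3–22, specialist recovery over 100 seeds, and clade
support with 1,000 bootstrap replicates on a planted two-group matrix
(pipeline default remains 10,000); these sizes give stable statistics while
keeping a full run in seconds.

## Known limitations

- Effects are inputs: the package does not infer FSP values from diet data,
  nor validate TPs against stomach contents.
- No allometric scaling, no landmark morphometrics, no taxonomic validation.
- Optimum values and any tolerance band around them are assumptions, not
  estimates.
- Bootstrap probabilities are known to be conservative for large clades;
  the AU correction is out of scope.
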