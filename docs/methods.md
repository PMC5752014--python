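# Methods

This note documents the models, conventions and numerical choices behind each
analysis stage, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Morphometric preprocessing and BGA

Specimens with standard length (SL) below `min_sl` (default 20 mm) are
excluded; the boundary value is retained ("smaller than" semantics).
Missing cells are imputed per (population, variable) by ordinary least squares
of the variable on SL, requiring at least two observed rows; there is no
fallback for smaller groups because a one-point regression is undefined — the
error names the offending group and variable. Imputed meristic counts are
snapped back to their half-unit grid to preserve the counting invariant.
If a population's SL values are numerically constant the regression degenerates
and the group mean is used (slope 0).

Morphometric variables are transformed to log(value/SL) and log(SL) itself is
retained as a size variable; the natural log is the default (`log_base`
configurable) since the choice only rescales columns that are subsequently
reduced. Variables flagged as head-length ratios keep their flag as
provenance, but standardization always divides by SL — the study design this
emulates standardizes every measurement by SL. Meristic counts enter raw.
Every column is centred and scaled by its population (1/n) standard
deviation, the convention under which a correlation PCA's total inertia
equals the column count.

The between-group analysis is the eigen-decomposition of
B = Σ_k (n_k/n)·m_k m_kᵀ, where m_k is the group-mean row of the
centred-reduced matrix. The observed statistic is
X_obs = trace(B)/total inertia ∈ [0, 1]. The permutation test shuffles rows
(equivalently labels), keeps group sizes fixed, and reports the add-one
estimator p = (#{X_perm ≥ X_obs} + 1)/(n_perm + 1); ties count as exceedances
(conservative), and the attainable minimum is 1/(n_perm + 1). Specimen scores
are projections of individual rows on the between-class axes; axis signs are
fixed by making the first non-negligible loading positive.

## K2P barcoding

The Kimura two-parameter distance uses pairwise deletion: a site contributes
only when both sequences carry an unambiguous A/C/G/T; ambiguity codes never
partially match. When 1−2P−Q ≤ 0 or 1−2Q ≤ 0 (saturation) or no comparable
site remains, the distance is undefined, propagates as NaN, and is excluded
from all summaries with a warning count.

The threshold-optimization rule, frozen here so the implementation is
self-contained: at threshold t an individual's neighbour set is every other
individual within distance t. Individuals without conspecifics are true
negatives with an empty neighbour set, otherwise false positives; individuals
with conspecifics are false negatives (empty set), true positives (only
conspecifics) or false positives (any heterospecific neighbour). The default
grid is 0.001–0.10 in steps of 0.001; all minimizers of
false positives + false negatives are reported, smallest first.

## Ordinations

PCA and PCoA use uniform row weights 1/n. PCoA double-centres −½D² (Gower);
eigenvalues within 1e−8 (relative) of zero are truncated and at most n−1 axes
are reported. The Cailliez constant is the largest real eigenvalue of the
2n×2n companion matrix [[0, 2·G(D²)], [−I, −4·G(D)]]; it is added to every
off-diagonal dissimilarity before re-analysis, after which the row scores
reproduce D + c pairwise. Geographic distances are great-circle (haversine)
on a sphere of mean radius 6,371,008.8 m; an ellipsoidal geodesic differs by
under 0.6%, immaterial for an ordination of the resulting matrix. Patristic
distances sum branch lengths along tip-to-tip paths; polytomy resolution
inserts zero-length branches (deterministic ladder by default, seeded random
available) and therefore never changes them.

## RV tests and MCOA

RV = trace(XXᵀYYᵀ)/√(trace((XXᵀ)²)·trace((YYᵀ)²)) on column-centred tables;
the permutation test shuffles rows of one table, with the same add-one
estimator as the BGA test.

MCOA axis r maximizes Σ_k w_k·Cov²(X_k u_k, v) over a unit-variance synthetic
variable v and per-table unit-norm loadings u_k, computed as the leading
eigenvector of (1/n)·Σ_k w_k X_k X_kᵀ. Before the next axis every table is
deflated by orthogonal projection of its columns onto the complement of its
own normed score, and the summed operator is restricted to the orthocomplement
of the previous synthetic variables, making compromise axes orthonormal in the
1/n metric. Axis signs follow the first table's score. Criterion weights
default to uniform; inverse-first-eigenvalue and inverse-total-inertia
schemes are available. With a single table the criterion degenerates to PCA
(pseudo-eigenvalues equal the PCA eigenvalues), a useful exactness check.

In the integrative pipeline the three preliminary score tables (population-
mean morphometric PCA, Cailliez PCoA of patristic distances, PCoA of
geographic distances) are each rescaled to total inertia 1 before MCOA.
Without this the geographic table — in meters squared — would dominate the
criterion by ten orders of magnitude; with it the Inertia/Co-Inertia/Cos²/Cov²
blocks are unit-free and comparable across tables. Morphometric
within-population variability is removed by replacing specimens with their
population means, replicated back to individuals so the three tables stay
row-conformable.

## DEC and DEC+j

The state space contains all nonempty subsets of the areas up to
`max_range_size`, plus the null range kept as an absorbing CTMC state but
excluded from tip observations and from the root prior (uniform over non-null
states). Anagenetic rates: expansion to one new area at |R|·d (uniform area
adjacency — no inter-basin distance matrix is assumed), contraction at e per
occupied area, size-1 ranges contracting to null. Cladogenetic ordered
daughter pairs and base weights: sympatry (size-1 copy), subset sympatry,
vicariance with one size-1 daughter — all weighted (3−j)/3 — and jumps to a
single outside area weighted j, normalized per ancestor state; j = 0 recovers
plain DEC exactly (verified to 1e−10).

The likelihood uses Felsenstein pruning with dense `scipy.linalg.expm`
transition matrices cached per unique branch length, per-node rescaling of
conditional likelihoods to avoid underflow, and the cladogenetic mixture at
internal nodes (including the root, whose prior applies after its event).
Ancestral-range marginals come from a standard outside (preorder) pass and are
reported at each internal node immediately before its cladogenesis.

Fitting maximizes the log-likelihood with L-BFGS-B under bounds
d, e ∈ [1e−6, 5] and j ∈ [0, 2.99999], from 5 seeded Latin-grid starts
(log-uniform in d and e). The DEC/DEC+j comparison uses D = 2ΔlnL against
χ²(1); because j = 0 lies on the boundary of its parameter space the true
null distribution is a ½χ²₀+½χ²₁ mixture, so the nominal 5% test is
conservative — simulated type-I rejection rates run at or below the nominal
level.

### Identifiability of e

In parameter-recovery simulations (50-tip pure-birth trees, 5 areas,
d = 0.1, e = 0.02) the dispersal rate is recovered with ~10% median relative
error, but the extirpation rate is routinely driven to its lower bound. Two
effects compound: e is weakly identified in DEC generally (contraction
followed by re-expansion is nearly invisible in tip ranges, and published DEC
fits often sit on an e bound), and the forward simulator conditions on
survival (histories with an extinct tip are rejected) while the inference
does not, biasing ê downward. Users should treat ê point estimates with
caution and prefer likelihood-ratio comparisons.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
group-structured morphometric means with allometric scaling on SL, lognormal
measurement noise (default SD 0.04 on the log scale, of the order of
measurement repeatability), half-unit meristic counts, missing-at-random
cells (default 2%, matching a plausible rate of broken-fin-ray gaps),
sequences evolved under the exact two-parameter substitution process
(transition/transversion ratio κ = 4, a typical mitochondrial value) so the
K2P metric is the correct estimator by construction, per-basin clustered GPS
points, and tip ranges evolved forward under DEC with known (d, e, j). One
global seed fans out to independent per-stream child seeds so stages can be
regenerated in isolation; regeneration from the same seed is byte-identical.

The three-species preset separates species by a factor 1.25/0.8 in
morphometric slopes and by deep (0.1–0.25 substitutions/site) stem branches —
a clean-cut case. What passing tests on it show is that each stage recovers
structure that is unambiguously present; they do not show robustness to the
hard features of real data (overlapping morphologies, introgression,
incomplete lineage sorting, uneven sampling), which the preset deliberately
does not emulate. The pure-birth tree simulator stops one exponential waiting
time after the n-th speciation, so its expected root-to-tip depth is
(1/b)·Σ_{k=2..n} 1/k, and no pendant edge has zero length. DEC recovery
experiments use 50-tip trees at birth rate 0.3 (total tree length of a few
hundred units), chosen so both event types occur O(10) times tree-wide.

## Degenerate inputs and tie-breaks

Zero-variance columns after transformation are an error (a column equal to SL
produces an all-zero log-ratio). A group of size one is allowed in barcoding
summaries (it contributes no within-group distances and is reported as a
singleton) but is an error in imputation. Permutation-test ties count as
exceedances. Eigenvector signs everywhere follow the first-non-negligible-
entry-positive rule so results are deterministic across LAPACK builds.

## Limitations

Alignment construction, tree inference and map rendering are out of scope —
alignments and trees are consumed, not built. The DEC implementation uses
dense matrix exponentials: fine for 11 areas capped at range size 4
(562 states), but not for much larger state spaces. No time-stratified
dispersal matrices or alternative cladogenesis models (BayArea/DIVA-like) are
provided.
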