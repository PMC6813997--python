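# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not emulate.

## Trees and covariance structure

Input phylogenies are rooted, time-calibrated, with branch lengths in time
units and mandatory lengths on every non-root edge; internal labels are
ignored and polytomies preserved.  A tree is treated as ultrametric when
the spread of root-to-tip depths is at most 1e-6 of the depth; OU fitting
requires ultrametry (its covariance formula assumes contemporaneous tips),
Brownian-motion fitting does not.  Pruning keeps the original root even
when it becomes unary, so root-to-tip depths — and hence all covariances —
of the retained tips are unchanged; unary nodes below the root are
suppressed with branch lengths summed.

Two matrices drive everything: `C[i,j] = s_ij`, the shared root-to-MRCA
path length, and the patristic distance `d_ij = depth_i + depth_j −
2 s_ij`.

## Procrustes alignment and sliding

GPA centres each specimen, scales it to unit centroid size, rotates it
onto the running consensus (proper rotations only, determinant +1 — the
alignment never introduces reflections, so left/right chirality must be
standardised upstream), and re-estimates the consensus until it moves by
less than 1e-8 (root sum of squares) or 100 iterations.  The reported
consensus is the arithmetic mean of the aligned specimens.

Semilandmark sliding minimises the Procrustes distance to the consensus
(not bending energy).  Each non-anchored point moves only along its local
tangent — the chord between its curve neighbours — to the closed-form 1-D
projection of the consensus point.  The outer loop alternates a GPA (to
re-estimate the consensus) with a sliding pass, three times by default.
One deliberate choice: sliding is applied in each specimen's **original**
coordinate frame, with the consensus carried back through the inverse
Procrustes transform.  This keeps anchored endpoints bit-identical through
the whole operation and makes the slide a pure within-specimen
repositioning; alignment happens when the caller runs GPA on the slid set.
A zero tangent (coincident neighbours, relative to centroid size) is an
error naming the curve and position.

Shape PCA is an SVD of the centred flattened coordinates; components with
eigenvalues below 1e-12 of the leading one are dropped; each component's
sign is fixed so its largest-magnitude loading is positive, which makes
scores deterministic across BLAS implementations.

## K_mult

With `C` the phylogenetic covariance, `a` the GLS phylogenetic mean and
`Yc = Y − a`:

    K_mult = [ Σ_i ||Yc_i||² / tr(Ycᵀ C⁻¹ Yc) ] / [ (tr C − N/1ᵀC⁻¹1) / (N−1) ]

On a star phylogeny the two bracketed factors cancel exactly, giving
K_mult = 1 for any data; under BM its expectation is 1.  Constant traits
return 0 by convention.  The permutation test shuffles tip rows; the
observed statistic counts as a member of its own null set, so the smallest
attainable p is 1/(n_perm+1); the default 999 permutations give a floor of
0.001.

## Multi-peak OU (Hansen) model and the stepwise search

Traits are modelled independently (per-trait α, σ², θ_r; model AICc is
the per-trait sum with k = 2 + #regimes per trait).  The expectation of a
tip is `W θ`, where the weight a lineage gives regime *r* accumulates
`e^{−α(T−t_end)} − e^{−α(T−t_start)}` over its time segments in *r*, and
the residual `e^{−αT}` goes to the root-regime column (root state anchored
at the root-regime optimum); rows of `W` sum to 1.  The covariance is
`V_ij = σ²/(2α) · e^{−α d_ij} (1 − e^{−2α s_ij})`.  σ² and θ are profiled
out analytically (GLS); α is maximised on a log scale over
[1e-8, 1e3/T] with an 8-point grid and bounded Brent refinement
(xatol 1e-3 on log α), a range whose ends recover the BM and white-noise
limits.  A regime whose design column has (numerically) zero weight, or a
collinear design — e.g. shifts on both root-child branches jointly
covering every tip — is rejected as non-identifiable.

The forward phase starts from one regime, tries a brand-new regime at the
origin of every non-root branch without a shift, accepts the largest
strict AICc improvement (pre-order position breaks ties), and stops when
none improves.  The backward phase tries every unordered pair of regimes
(including the root regime — a lineage may revert to the ancestral peak),
rewrites one label into the other, refits, accepts the best strict
improvement, and repeats; shifts made vacuous by a merge are absorbed.
Bookkeeping on the final painting: shifts k are branches where the regime
changes (the root origin is not a shift); a regime entered by ≥ 2 shifts
is convergent; the convergence fraction is (shifts into convergent
regimes)/k.  This counting is the only one consistent with a model that
has, say, 8 shifts, 5 regimes, 3 convergent regimes and 6 convergent
shifts at once — it requires allowing shifts back into the root regime.

Known limitation: greedy AICc forward searches overfit — extra shifts
absorb phylogenetic covariance, which inflates α̂ and so shrinks the
apparent uncertainty of the optima; occasionally this makes the backward
phase keep two planted convergent regimes separate even though they share
a true optimum.  This is a property of the search strategy, not of the
implementation.

## C-metrics

Ancestral states are the BM maximum-likelihood (GLS) reconstruction: each
internal node is the conditional expectation of the joint Gaussian given
the tips, with the root at the phylogenetic mean.  For a focal pair,
D_max is the maximum distance between reconstructed states across the two
lineages back to and including their MRCA, **excluding** the contemporary
tip-vs-tip pair; D_tip is that tip distance.  Excluding the tip pair is
what lets C1 = 1 − D_tip/D_max go negative when lineages have diverged
beyond any ancestral separation — a diagnostic of divergence rather than
convergence.  C2 = D_max − D_tip; C3 and C4 divide C2 by the summed
phenotypic branch lengths (distances between reconstructed parent/child
states) of the MRCA's clade and of the whole tree, each computed per pair
and averaged over unordered focal pairs (equal weights; identities
C2 = C1·D_max and C3·L_clade = C4·L_tree = C2 hold per pair).

Significance: the trait rate matrix is the GLS estimator
`R = (Y−a)ᵀC⁻¹(Y−a)/N`; `n_sim` BM datasets are simulated with rate `R`
and the metrics recomputed for the same focal set.  The reported p is the
raw proportion of simulations at or above the observed value — it can be
0, matching common printed practice — and the protected estimate
(s+1)/(n_sim+1) is carried in metadata for downstream use.

## Wheatsheaf index

Trait columns are standardised (PC scores have wildly unequal variances;
configurable off); Euclidean distances are corrected with the
multiplicative kernel `d′_ij = d_ij (1 + s_ij/T)`, bounded in [1, 2]:
close relatives' distances are inflated so relatedness-driven similarity
does not mimic convergence, and no singularity arises for sister tips (a
patristic-distance division would blow up there).  The kernel is passed as
a function and can be swapped for any other correction.  The index is the
all-pairs mean over the focal-pairs mean; identical focal phenotypes give
+∞ with a warning.  Confidence intervals are percentile 2.5/97.5 of
leave-one-tip-out replicates; deleting one member of a two-species focal
group leaves no focal pair, so that replicate — and hence the upper bound
— is infinite (percentiles propagate infinities rather than producing
NaN).  The bootstrap p resamples tip rows with replacement, reassigns them
to tips, and counts replicate indices ≥ observed; the raw proportion is
reported with the protected (s+1)/(n+1) value alongside.

## Ecological association

Membership is tested one regime at a time (in-regime vs all others).
Species belonging to several categories of a factor are handled by
assignment variants: variant *v* fixes every species to its *v*-th listed
category (clamped to its own list), one factor at a time, so a factor with
at most two listed categories per species yields two tests.  The
Bonferroni correction multiplies each raw p by the number of tests
actually run for that regime — the realised count is derived from the
data's ambiguity structure rather than hard-coded.  No Yates continuity
correction is applied.  Categories with an empty margin are dropped (noted
in the result); a table left with fewer than two categories is recorded as
skipped.  The ANOVA of ln-transformed masses is computed from explicit
between/within sums of squares so SST = SSB + SSW holds by construction.

## Synthetic data

Defaults are desk-scale versions of the motivating study system: 32 tips
(48 available by argument) on a pure-birth tree rescaled to depth 36 time
units, 2 traits for the regime search, more (up to 30) for the
distance-based metrics, and 20-landmark schemes standing in for the
371-landmark real protocol.  Trait generators sample exact Gaussian
transitions branch by branch (BM increments with covariance t·R; OU
transitions with mean pulled toward the branch's regime optimum and
variance σ²/(2α)(1−e^{−2αt})), so simulated covariances match the
analytic forms used by the likelihoods — a cross-check the test suite
performs.  Landmark sets are smooth helix-like template curves plus
group-specific low-frequency deformation fields, coordinate noise, and
random rigid motion + scale for the alignment to undo.  Ecology tables
draw each species' category from its regime's preferred category with a
given strength, add multi-valued cells with probability 0.2(1−strength),
and draw masses log-normally per regime.

Planted-shift placement enforces two conditions: shifted clades never
jointly cover all tips (identifiability of the root regime), and — for the
convergence datasets used in recovery experiments — shift branches
originate in the older half of the tree, so planted regimes have had time
to approach their optima (α · adaptation-time well above 1); a regime born
just before the present would carry no expressible signal and would not
constitute a strong planted shift.

What the generators do **not** emulate: realistic cochlear geometry,
fossil (non-contemporaneous) tips, measurement error, correlated trait
evolution (the OU generator matches the fitted model's independence
assumption), and missing data.  Passing tests therefore demonstrate
correctness of the machinery and its behaviour under the model's own
assumptions, not robustness to their violation in real morphometric data.

## Problem sizes and reproducibility

Monte-Carlo defaults are 999 permutations (K_mult), 1000 simulations
(C-metric p-values) and 1000 bootstraps (Wheatsheaf); the test suite and
the acceptance script scale these to 99–1000 and use 16–64-tip trees,
sizes chosen to keep the full verification runs comfortable on a single
CPU while leaving the Monte-Carlo resolution adequate for the calibration
bands they check.  Every stochastic entry point takes a seed; dataset- and
pipeline-level seeds spawn per-stage substreams via `SeedSequence`, so a
given configuration is bit-reproducible, and pipeline outputs are written
with fixed float formatting so re-runs are byte-identical.
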