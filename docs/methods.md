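# Methods

`gimmesub` organizes heterogeneous samples into data-driven subgroups from
directed resting-state functional connectivity.  This note documents the
models, algorithms, parameter choices, and numerical conventions the package
implements, and what its validation does and does not establish.

## The unified SEM (structural VAR of order 1)

Each individual's p-variate ROI series is modeled as

    y_t = A y_t + Φ y_{t−1} + ζ_t,     ζ_t ~ N(0, Ψ),  Ψ diagonal,

where A holds contemporaneous directed paths (zero diagonal) and Φ the lag-1
paths, with autoregressive effects on its diagonal.  The reduced form is
y_t = (I−A)⁻¹(Φ y_{t−1} + ζ_t); a valid model requires (I−A) invertible and
spectral radius of (I−A)⁻¹Φ below 1 for stationarity.

**Estimation.**  The model is fit by maximum likelihood on the lag-embedded
observations [y_{t−1}, y_t].  The lagged block is treated as saturated
(exogenous), which reduces the 2p-dimensional covariance-structure
discrepancy

    F = ln|Σ(θ)| − ln|S| + tr(S Σ(θ)⁻¹) − 2p

to the conditional Gaussian deviance of y_t given y_{t−1}.  Writing
C = I − A and S_e(θ) for the model residual second-moment matrix, the
residual variances are profiled out analytically (ψ̂_i equals the i-th
diagonal of S_e), leaving

    F_p(A, Φ) = Σ_i ln S_e,ii − 2 ln|C| − ln|S_res|,

with S_res the saturated conditional residual covariance.  F_p is minimized
by L-BFGS over the free elements of (A, Φ) with closed-form gradients
(∂F_p/∂A = 2C⁻ᵀ − 2D⁻¹(C S_yy − Φ S_yxᵀ), D = diag(S_e); analogously for
Φ).  Convergence: relative change below 1e−12 or gradient norm below 1e−8,
at most 500 iterations; a singular C during search returns a quadratic
barrier value that pushes the step back.  χ² = (n−1)·F̂ over the n retained
lag pairs; df = p² + p(p+1)/2 − (free parameters + p).  Standard errors come
from the inverse finite-difference Hessian of F_p (profile-likelihood
covariance).  For recursive (lower-triangular A) patterns the ML solution
coincides with per-equation least squares; the test suite enforces agreement
to 1e−4.

**Missing frames.**  Rows of NaN are placeholders that preserve scan order;
the lag embedding keeps only pairs whose two frames are both complete, and
refuses to fit when fewer than 10·p pairs remain.

**Scaling.**  Series are mean-centered implicitly (all moments are
covariances).  Per-ROI z-scoring is available (`standardize=True`) but off
by default: path weights are regressions of one ROI signal on another, so an
individual's global signal scale already cancels, while z-scoring
multiplies every beta by a ratio of sample standard deviations.  With
realistic series lengths those ratios are noisy — and shift with genuinely
individual-specific connections — which contaminates the between-individual
beta comparisons the subgrouping step depends on.  Fitting on the observed
scale keeps betas comparable whenever ROIs share acquisition units, which
holds for ROI-averaged BOLD and for the simulation.

**Fit indices.**  Relative to an AR-only null model: RMSEA
(√(max(χ²−df,0)/(df(n−1)))), SRMR (RMS standardized residual over the
modeled y-y and y-x blocks), CFI, and NNFI.  A model "fits excellently" when
at least two of {RMSEA ≤ .05, SRMR ≤ .05, CFI ≥ .95, NNFI ≥ .95} hold
(configurable).  A saturated model (df = 0) flags RMSEA/CFI/NNFI undefined.

**Modification indices.**  For every fixed off-diagonal A element and fixed
Φ element, the MI is the score-test estimate of the χ² drop from freeing
that one element: MI = (n−1)·g²/(2h), where g is the gradient of F_p at the
restricted optimum and h the Schur complement of that element's curvature
with respect to the free parameters (finite differences of the analytic
gradient).  MIs match refitting exactly in the near-null regime and track
the true χ² drop within ~20% for moderate omitted effects; for very strong
omitted paths the score test overshoots the likelihood-ratio drop, which is
harmless for ranking candidates.

## The GIMME search

**Group stage.**  All AR (Φ diagonal) paths are freed a priori and never
pruned.  Iteratively, each individual is fit and the candidate path whose MI
exceeds the Bonferroni-corrected χ²(1) critical value (α = .05 over the
current candidate count) for the most individuals is freed — provided that
count reaches γ·N with γ = 0.75 (ties: larger summed MI).  The search stops
when no candidate reaches the criterion.  Afterwards, any added group path
whose estimate is non-significant (two-sided z, α) for more than (1−γ)·N
individuals is removed, worst first, refitting between removals.
Individuals that fail to converge are excluded with a logged warning and N
is adjusted.

**Individual stage.**  Per individual, starting from the group map, the
largest-MI candidate above the Bonferroni critical value is freed until the
excellent-fit rule is met or no candidate qualifies; steps producing a
singular (I−A) are rejected and the next candidate is tried.  Finally,
non-significant individual-level paths (never group-level paths) are pruned,
least significant first.  One consequence of the excellent-fit stopping rule
is worth knowing: in larger models whose group map already fits well, a
single true individual path can be skipped because global fit indices barely
register one omitted element among ~p(2p−1) modeled moments.  This is the
standard trade-off of fit-guided search and accounts for the recovery rate
sitting slightly below 100%.

**Recovery scoring.**  Against simulation ground truth, a true directed path
counts as recovered when exactly that element (same direction, same lag) is
free in the individual's final model; the rate pools all true paths across
individuals.

## Similarity subgrouping with data-driven thresholding

Individuals are represented by the vector of their contemporaneous
group-path betas (individual-level and lagged paths are excluded: they are
too heterogeneous, while group paths are estimated for everyone and
approximately normally distributed across individuals).  The N×N similarity
matrix X holds Pearson correlations of these vectors; zero-variance vectors
are flagged and their similarities set undefined.

X is binarized at threshold r: A_ij = 1 iff X_ij ≥ r (closed boundary,
i ≠ j); with the grid restricted to r ∈ [0, 1], negatively correlated pairs
are never connected.  For each r in 0, .01, …, 1.00 the package runs the
modularity maximizer 100 times, recording all Q values, their standard
deviation (the stability criterion), and the graph's mean reachability (for
each individual, the size of its connected component minus one, averaged).

**Modularity maximizer.**  Newman's Q is maximized by a Louvain-style
algorithm: randomized-order local node moves, community aggregation,
repeated over levels, followed by a Kernighan–Lin-style refinement pass over
the original nodes.  Node visit order is randomized per run, so runs can
land in different local maxima — precisely the run-to-run variability the
stability criterion measures.  On all ≤8-node graphs in the test suite the
best-of-runs Q equals the exhaustive-search optimum; an edgeless graph
yields singleton communities with Q = 0 and a warning.  The hot loop is
numba-compiled (run time ≈ 1 ms at N = 100).

**Threshold selection.**  A chord is drawn from the first to the last point
of the mean-reachability curve and the drop index is the grid point at
maximum perpendicular distance from it (ties → smallest index; a flat or
linear curve returns the last index with a warning).  Among thresholds
strictly before the drop whose graphs have edges, the one with minimal
std(Q) wins; ties break to the highest r, then the highest mean Q.  A
numerical subtlety matters here: when all 100 runs find the identical
partition, their Q values can still differ by ~1e−16 because the summation
order follows the randomized node order, so std(Q) below 1e−10 is snapped
to zero before comparison — otherwise the tie-break can be decided by
floating-point noise instead of genuine stability.  The
final partition at r* is the modal partition across that threshold's 100
runs (after canonical relabeling), ties broken by highest Q.

**Accuracy scoring.**  Detected communities are matched one-to-one to true
subgroups by Hungarian assignment on the contingency table; members of
unmatched communities count as errors.

## Perturbation robustness

The binarized network at r* is rewired by double-edge swaps, each of which
removes an edge and relocates it between two other nodes while a paired edge
compensates, so every node's degree is exactly preserved and no self-loops
or multi-edges arise.  Perturbation level α performs round(α·m) swaps on an
m-edge network: α = 0 leaves the network untouched and α = 1 touches on the
order of every edge, i.e. an essentially random degree-matched graph.
Graphs too sparse to swap are returned unchanged with a warning.

At each level (0 to 1 in .025 steps by default, 100 replicates each),
community detection is re-run directly on the perturbed binary graph — no
re-thresholding, since the input is already binary — and compared with the
original partition by Meilă's variation of information
VI = H(P) + H(P′) − 2I(P;P′) in bits (configurable base; VI ≤ log₂N), and by
the fraction of vertices whose maximum-overlap-matched community changed.
Each perturbed network's partition is consolidated exactly the way the main
pipeline consolidates its final solution: the modal partition across
`detection_runs` = 100 randomized modularity runs.  This matters: single
runs on a half-rewired network disagree with each other on ~40% of labels,
so without consolidation the curve measures optimizer noise rather than the
perturbation's effect.  The baseline comparison uses an Erdős–Rényi graph
with matched node and edge counts.

## Subgroup comparison

Per group path, a one-way ANOVA tests any difference across subgroups, and
per (path, subgroup) a two-sample t contrasts the subgroup against all other
individuals pooled (the "average of the others"); equal variances are
assumed, matching the ANOVA decomposition.  FDR control applies jointly
across all path×subgroup contrasts — the most conservative family — using
Storey q-values with the smoother π₀ estimate (cubic spline over
λ = .05, …, .95, evaluated at λ = .95; π₀ falls back to 1 for families
smaller than 20).  Benjamini–Hochberg is selectable.  Verdicts at α = .05:
`higher`/`lower` by the sign of the mean difference when q ≤ α, `similar`
otherwise, `untestable` for singleton subgroups.  A traditional two-group
diagnostic comparison (per-path t with FDR across paths) is included for
reference.

## The synthetic-data generator

The generator emulates a subgroup-structured resting-state sample: 100
individuals in 4 equal subgroups, 10 ROIs, 200 scans each.  All individuals
share autoregressive effects of 0.60 and 9 contemporaneous group paths of
weight 0.50; within each subgroup 3 of the 9 paths deviate by ±0.20, and one
subgroup-specific path (weight 0.50, not a group path) is present per
individual with probability 0.5 (Bernoulli), adding individual-level
heterogeneity.  Innovations are i.i.d. Gaussian (sd 1.0 — the scale is
immaterial to betas); series start at zero and 200 burn-in samples are
discarded.  Every subgroup's system, with and without its unique path, must
pass the stationarity check or the design is rejected with a diagnostic
naming the subgroup.

Choices the design leaves open were fixed as follows and are configurable:

- **Group paths:** a chain ROI_i → ROI_{i+1} (i = 0…8).  A recursive
  pattern keeps every system trivially stable and identifiable.
- **Deviant triples:** stride-2 windows of 3 over the 9 paths —
  {0,1,2}, {2,3,4}, {4,5,6}, {6,7,8} — with sign pattern (+,−,+), so
  consecutive subgroups share one same-signed deviant path.  Fully disjoint
  or anti-correlated triples make subgroups unrealistically separable (the
  similarity network becomes near-block-diagonal, thresholds select around
  0.4, and subgrouping is trivially perfect); the overlapping layout
  reproduces the intended operating regime, with selected thresholds around
  0.5–0.6 and near-ceiling but not degenerate recovery.  Triples must be
  pairwise distinct or the design is rejected.
- **Unique paths:** (0→5), (1→6), (2→7), (3→8), weight 0.50.
- **Subgroup count/sizes:** 4 × 25, configurable.

**What the generator does not emulate:** hemodynamic response convolution,
scanner/physiological noise spectra, temporal filtering artifacts, spatial
structure or atlas misregistration, head motion (motion scrubbing is
exercised with synthetic realignment parameters instead), and unequal or
unknown subgroup counts.  Passing the validation therefore shows that the
estimation and subgrouping machinery recovers the structure this generative
family produces — not that real fMRI preprocessing pipelines deliver data of
this cleanliness.

## Validation scale and determinism

The validation study runs 10 seeded replicates of the full design
(≈ 30 s each on one core: the GIMME search dominates, the 101-threshold ×
100-run scan adds a few seconds).  Robustness quantities use 100
perturbation replicates at the levels of interest on one replicate's
network.  Every stage draws from independent streams spawned from a single
master seed; repeated runs are bit-identical.  Smaller two-subgroup designs
(N = 24, T = 150) are used in unit tests where full scale adds nothing.

## Known limitations

- The score-test MI overshoots the LR χ² drop for large omitted effects;
  ranking is unaffected.
- The excellent-fit stopping rule can skip weak individual-level paths in
  well-fitting large models (see above).
- Louvain-style maximization is exact only on the small graphs where the
  suite checks it against enumeration; at N = 100 it is a high-quality
  heuristic, which is precisely what the stability criterion expects.
- Storey's π₀ estimate is unstable for very small families and falls back
  to π₀ = 1 (BH-equivalent behavior) below 20 tests.
- Threshold selection assumes the reachability curve has an elbow; a
  network that never fragments over the grid triggers the no-drop warning
  path and selection among all stable thresholds.
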