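# Methods

## The model

`tfanet` reconstructs a three-layer regulatory network in which the
regulating activity of each transcription factor is a hidden variable. Let
M be the number of samples, Q ∈ ℝ^{K×M} the observed mRNA of the K
regulators (the L TFs first, then K−L candidate modulators), P ∈ ℝ^{L×M}
the hidden activities, and E ∈ ℝ^{N×M} the expression of N target genes.
Conditional on its parents, every node is Gaussian with a linear mean:

    p_l | pa(p_l) ~ N( Σ_{k∈pa} β_lk q_k ,  σ²_{P_l} )        l = 1…L
    e_n | pa(e_n) ~ N( Σ_{l∈pa} α_nl p_l ,  σ²_{E_n} )        n = 1…N

B = (β_lk) is the modulation-strength matrix (each TF's own mRNA is always
one of its activity's parents), A = (α_nl) the regulation-strength matrix.
The support of A and B is not learned freely: it is fixed to a draft
network assembled from two information-theoretic screens, and the fit only
estimates the coefficient values on that support (plus an L1 penalty that
can zero them).

Rows of Q and E are z-scored (population sd) before fitting. The marginal
Gaussian factors of the regulator mRNA then carry no information about
(A, B, P, σ²) and are dropped from the objective, which is the penalized
negative log-likelihood

    J(Θ) = Σ_l [ M/2·log(2πσ²_{P_l}) + ‖p_l − B_l Q‖²/(2σ²_{P_l}) ]
         + Σ_n [ M/2·log(2πσ²_{E_n}) + ‖e_n − A_n P‖²/(2σ²_{E_n}) ]
         + λ(‖A‖₁ + ‖B‖₁).

## Step 1 — pairwise screening

MI between two expression vectors is estimated by a product-Gaussian-kernel
density estimator evaluated at the observed points: with per-variable
Silverman bandwidths h = 1.06·sd·n^(−1/5), the estimate is the sample
average of log[ f̂(x,y) / (f̂₁(x)·f̂₂(y)) ], which reduces to
mean_i log( n·Σ_j K_x(i,j)K_y(i,j) / (Σ_j K_x(i,j)·Σ_j K_y(i,j)) ) — the
kernel normalisation constants cancel. Units are nats (a bits flag exists);
small negative estimates are clamped to zero; densities are floored at
1e−300 before logs. On bivariate Gaussian data at n = 2000 the estimator is
within a few hundredths of a nat of −½·ln(1−ρ²).

Screening computes MI for every TF × candidate-target pair, fits a
location-scale Student-t to the pooled values by maximum likelihood
(method-of-moments with ν = 5 as a logged fallback), and keeps pairs whose
upper-tail probability is below the cutoff (default 10⁻⁴). The t-null is
deliberately fitted to *all* pairs — with realistic TF counts the planted
signal is a small contamination of a heavy-tailed null, and the procedure
controls the selected fraction on pure-noise matrices to ≲ the cutoff
order. With very few pairs (< 50) the fit is refused.

## Step 2 — modulator detection

The conditional-MI score of a TF–target pair (x, y) given a candidate
modulator m is the difference of subset MIs

    CMI(x, y | m) = MI(x, y | m ∈ top 35%) − MI(x, y | m ∈ bottom 35%),

where the splits take the floor(0.35·M) largest/smallest samples of m
(stable sort; ties resolved by sample position). The null distribution is
obtained by permuting the modulator; because a permutation only relabels
which samples fall in the two groups, the implementation draws the
permuted splits directly on m's rank ordering. This makes p-values
deterministic under a fixed seed and *exactly* invariant to any sample
permutation applied jointly to x, y and m (for tie-free m). The p-value
uses the add-one formula p = (1 + #{CMI_perm ≥ CMI_obs})/(1 + n_perm), so
p ≥ 1/(n_perm+1) and the test is valid at finite n_perm. The comparison is
one-sided on the signed CMI (a *gain* of dependency at high modulator
levels); a loss-of-dependency modulator can be probed by negating m.

A cofactor (restricted to the TF's functional-linkage neighbours) is
called a modulator when its per-target p-values fall below the cutoff
(default 10⁻³) for at least 50% of the TF's Step-1 targets. One set of
permuted splits is shared across a cofactor's targets within a call — the
permutation acts on the modulator alone, so it induces the same split for
every target; this is statistically identical to independent draws per
target and an order of magnitude cheaper. The subset-MI kernel is batched
and chunked (≈8M-element tensors), with the TF-side kernel reused across
targets.

## Step 3 — hard-assignment EM

Given Θ = (A, B, σ²), the activities maximizing the complete-data
likelihood solve the L×L system C·P = D with

    C = Aᵀ diag(1/σ²_E) A + diag(1/σ²_P)
    D = diag(1/σ²_P)·B·Q + Aᵀ diag(1/σ²_E)·E,

solved once per fit iteration for all M columns by Cholesky factorisation
(C ⪰ diag(1/σ²_P) ≻ 0 thanks to the variance floor). The M-step is
separable across rows of A and B. Each row solves a support-restricted
lasso; the row's L1 weight is scaled by 2σ² of that row, which makes the
row solve the *exact* minimizer of its term of J(Θ) (and coincides with
the plain ‖E−AP‖² + ‖P−BQ‖² + λ(‖A‖₁+‖B‖₁) objective when variances are
equal). Solver: ADMM with over-relaxation 1.5, absolute/relative
tolerances 1e−6/1e−4, ≤500 iterations, ρ initialised at 1.0 with standard
residual balancing (ρ doubled/halved when primal and dual residuals
diverge by 10×) — without balancing, fixed ρ = 1 stalls when 2ΦᵀΦ is
large. The ADMM output is polished by an exact solve on its active set
when the KKT sign pattern is consistent, and a per-row safeguard keeps the
previous iterate's row whenever the new row would score worse, so EM
descent holds to machine precision despite the iterative inner solver.
λ = 0 bypasses ADMM entirely (restricted least squares; equivalently the
row-wise pseudo-inverse update, for which a dense `m_step_dense` with
explicit rank checks is also provided). Variances update to the mean
squared residuals, floored at 1e−8.

Two initialisation/scheduling choices matter and were made deliberately:

* **Initialisation.** P⁽⁰⁾ = each TF's own z-scored mRNA, B⁽⁰⁾ = identity
  on self-edges, A⁽⁰⁾ = restricted least squares of E on P⁽⁰⁾. Target
  variances start from the initial residuals, but σ²_P starts at 1: the
  self-edge construction makes the latent-layer residual exactly zero at
  init, and starting σ²_P at the floor would give the prior a 10⁸ : 1
  precision advantage and pin the activities to the mRNA forever.
* **Variance warm-up.** Per-node variance updates are deferred for the
  first half of the iteration budget; during warm-up the fit is pure
  alternating least squares at the frozen variances. Updating variances
  from the very first residuals lets one latent variance collapse to the
  floor before B is learned — a self-reinforcing degenerate attractor of
  hard EM (observed on noiseless data, where one activity row is
  immediately explained perfectly). Every warm-up step is still exact
  coordinate descent on J at the frozen σ², and the first variance update
  is the exact σ²-minimizer, so the recorded objective trace is
  non-increasing across both phases.

Convergence is declared when the relative change of J falls below `tol`
(default 1e−6) in the variance-update phase, or at `max_iter` (default
100). The fit is fully deterministic; the `seed` argument exists for
interface symmetry only.

**Identifiability.** The likelihood is invariant to scaling an activity
row by c while dividing the corresponding A column and multiplying the B
row by c. Activity estimates are therefore meaningful up to per-TF scale
(correlation-based evaluation is scale-free), and exact coefficient
recovery on noiseless data holds after fixing the gauge via the forced
self-edge. Hard EM on a non-convex objective finds local optima; the
structured initialisation above recovers the generator's activities with
median |correlation| ≈ 1.0 on the standard preset.

**Active triplets.** After the fit, a draft triplet (m, t, g) is retained
iff |β_{t,m}| and |α_{g,t}| both exceed 1e−10 (exact zeros are produced by
the soft-thresholding step, so the tolerance only guards round-off). The
default λ = 300 was fixed once by a pilot on the standard preset with a
decoy-augmented draft (true support plus Bernoulli(0.2) spurious edges),
chosen so roughly half of that draft survives — the regime in which the
penalty prunes spurious edges while keeping true ones. With the exact true
support, near-100% survival is the correct outcome at any sensible λ,
because generator weights are bounded away from zero.

## Downstream analyses

* **Three-layer assembly**: a directed multigraph with `regulation`
  (TF → target) and `modulation` (modulator → TF) edge types; nodes carry
  role sets (a gene may be modulator, TF and target at once); duplicate
  (source, target, type) edges are collapsed.
* **Betweenness**: unnormalized shortest-path betweenness via networkx,
  directed by default (edge semantics are directed), optionally on the
  TF-core induced subgraph; validated against a hand-written BFS
  path-counting oracle on all graphs ≤ 30 nodes.
* **MI-improvement test**: bootstrap over samples (with replacement,
  both MI scores recomputed jointly per replicate); p is the add-one
  fraction of replicates where the activity's MI with the target fails to
  exceed the mRNA's, ties counting one half so exchangeable inputs give
  p ≈ 0.5. Degenerate resamples (a constant vector) count against
  improvement.
* **Rewiring analysis**: samples sorted by the modulator and cut into 10
  equal bins (remainder to the last bin); Pearson correlation per bin
  (degenerate bins recorded as 0 with a warning); the 10 correlations
  categorised low/high by 1-D 2-means with deterministic min/max centroid
  initialisation; significance from the Step-2 CMI permutation test
  (default 10,000 permutations, one-sided gain).

## Synthetic data

The generator realizes exactly the structure the method assumes, which is
the point: passing tests certify the machinery (estimators, optimizers,
calibration), not robustness to real-data pathologies. Q rows are i.i.d.
standard normal; B has forced self-edges plus off-support entries at a
given density; A is Bernoulli at the same density; nonzero weights are
uniform on ±[0.5, 1.5] — bounded away from zero so "nonzero support" is
unambiguous in recovery tests. P = BQ + ε, E = AP + ε with Gaussian noise.
The standard preset is L=5, K=20, N=60, M=400, density 0.2, noise sd 0.1.
Gated triplets for Step-2 testing use y = gate·x·1[m > median(m)] + ε; the
generator gates at the median even though detection splits at 35% tails —
detection is not told the generator's split. Not modeled: microarray noise
shapes, batch effects, tissue covariance structure, time ordering.

## Test and acceptance problem sizes

Statistical checks run at sizes chosen to keep the full suite fast while
leaving comfortable margins: MI accuracy at n = 2000; E-step oracle on 100
random (L=3, K=4, N=5, M=10) instances; ADMM vs coordinate-descent lasso
on 20 (20×8) instances; EM descent across 50 fits at (L=3, K=8, N=15,
M=80); recovery at the standard preset with noise monotonicity over sd ∈
{0.5, 0.2, 0.1} in the median over 5 seeds; modulator calibration with
2000 null permutation tests (n_perm = 1000) and gated detection across 10
seeds at n = 500. `scripts/acceptance.py` re-derives the same quantities
at slightly reduced replicate counts (noted in its JSON output as `n`).

## Known limitations

* The resubstitution kernel-MI estimator has a small positive bias under
  independence and a small negative bias at high dependence; comparisons
  are meaningful within a dataset, not across sample sizes.
* The Step-1 t-null is contaminated by true signal; with a large planted
  fraction the tail fit becomes conservative.
* Hard EM provides point activities only — no posterior uncertainty.
* Per-TF activity scale (and sign, when a TF's self-edge is not sign-
  constrained) is a gauge freedom; report correlations, not raw scales.
* The modulator majority rule inherits Step-1's target list; a TF with no
  significant targets yields no modulator calls by construction.
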