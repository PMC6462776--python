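# Methods

`dynstates` implements a sliding-window dynamic functional-connectivity
(dFC) analysis for per-subject network time courses — the kind of data
produced by group-ICA + dual regression of resting-state fMRI, after all
image-level processing is done.  The package operates entirely on flat
text (TSV/CSV/JSON): one T x N matrix per subject (T time points, N
network signals, sampling interval TR) plus a subject manifest.

## Generative model of the synthetic cohort

Because the pipeline's validity claims are made on synthetic data, the
generator is first-class, tested code.  Each subject's signal is a
hidden-Markov switching multivariate Gaussian:

* a latent state sequence s_1..s_T follows a first-order Markov chain
  (initial distribution = the chain's stationary distribution);
* the emission at time t is y_t ~ N(0, Sigma_{s_t}), with each Sigma a
  unit-diagonal symmetric positive-definite (SPD) matrix on the
  correlation scale;
* optional nuisance components are added: polynomial trends of orders
  1–3 (coefficients U(−c, c) per network, default c = 0.5), sparse
  additive spikes (default rate 0.002 per cell, amplitude 6), and white
  noise (default SD 0.3).

State covariances are two-factor models Sigma = L L' + psi I normalized
to unit diagonal, with blockwise loadings over five functional modules
(motor, visual, default-mode, attention, cognitive-control).  State s
loads a rotating pair of modules positively, one module negatively
(anticorrelation) and one more on an independent second factor, so
successive states carry genuinely distinct signed correlation patterns —
not scaled copies of one pattern, which k-means could not tell apart at
realistic window noise.  The factor form is SPD by construction for
loadings < 1 (a shrink-toward-identity step remains as a safety net).
Per-state magnitudes default to a ladder from 1.0 down to 0.35: state 1
is the "strong" state (largest positive and negative correlations) and
the last state is the "sparse" state with only faint structure.  No
quantitative state-separation scale exists to calibrate against, so
`strength` (peak loading = 0.9 x strength) is a free scenario parameter:
0.6 in the study-shaped cohort; the "well-separated" recovery scenario
uses 0.9 with all per-state scales at 1.0.

The study-shaped default cohort is 31 HC / 29 AD-like / 31 DLB-like
subjects, T = 128, TR = 3 s, N = 27.  Group effects are encoded **only**
through the Markov dynamics (never the emission covariances), so any
detected group difference is a pure dynamics effect: controls split time
roughly evenly over the three states, both patient-like groups enter
state 1 less and leave it faster, and the DLB-like group lingers in the
sparse state 2.  Covariate columns (age, gender, study membership, and
optional clinical scores) are drawn from per-group distributions shaped
like the reference cohort's demographics table.

What the generator does **not** emulate: hemodynamic autocorrelation,
scanner noise spectra, motion, spatial structure, non-Gaussian marginals,
and gradual (non-instantaneous) state transitions.  Passing recovery
tests therefore demonstrate internal consistency of the pipeline under
the switching-Gaussian model, not performance on real fMRI.

## Postprocessing

Cleaning order is detrend → despike → low-pass.

* **Detrend**: least-squares projection onto an orthonormal polynomial
  basis up to order 3 (intercept included); exact and idempotent.
* **Despike**: deviations from a running median (window 11 points) are
  compared with a local MAD scale (x1.4826, floored at the column's
  global deviation MAD); points beyond 4 robust SDs are replaced by a
  cubic spline fitted through the clean points.  A flagged point must
  additionally exceed twice the column's overall robust SD — without
  this amplitude floor, noiseless smooth oscillations (whose
  running-median deviations are tiny but structured) would be flagged.
  The reference despiking tool's exact parameters are not published, so
  threshold and window are exposed in the config; defaults are chosen to
  flag only gross outliers at T = 128.
* **Low-pass**: fifth-order Butterworth at 0.15 Hz applied
  forward-backward (zero phase, reflective padding of 3 x order).  The
  cutoff must lie below the Nyquist frequency 1/(2 TR) ≈ 0.167 Hz at
  TR = 3 s.  Zero-phase filtering squares the transfer function, so the
  effective gain at the cutoff is 1/2 rather than 1/sqrt(2); we accept
  this in exchange for not phase-shifting the windowed correlations.

## Sliding-window connectivity

* **Taper**: rectangle of w = 22 TR convolved with a Gaussian of sigma =
  3 TR, truncated to the central w samples and renormalized.  Truncation
  to exactly w samples keeps the window count at T − w + 1 = 107 for
  T = 128.  Step = 1 TR; w is swept over 18–28 in robustness checks.
* **Windowed covariance**: taper-weighted, weighted mean removed per
  window, normalized by 1 − Σ w_i² (reduces to 1/(w−1) for a uniform
  taper).
* **Graphical LASSO**: per-window L1-penalized precision estimation
  (off-diagonal penalty), solved by scikit-learn's coordinate-descent
  solver behind the module's own surface.  The penalty lambda is chosen
  per subject by 20-fold cross-validation over windows: folds are
  contiguous blocks of window indices (contiguous rather than
  interleaved to limit sample sharing between train and test windows);
  for each fold and lambda one model is fitted to the pooled (averaged)
  training-window covariance and scored by the mean Gaussian
  log-likelihood of the held-out windows' sample covariances.  The
  library default grid is 30 log-spaced values in [1e-3, 1]; the
  standing experiments use 6 log-spaced values in [0.05, 0.5], since for
  22-sample windows of 27 networks the per-window problem is
  rank-deficient and penalties below ~0.05 are numerically meaningless
  there.  Solver notes: sporadic coordinate-descent breakdowns on
  rank-deficient windows are retried with a small diagonal loading
  (1e-6, then 1e-4 of the mean variance); a slow final dual gap on an
  otherwise SPD solution is accepted at the default tolerance 1e-4.
* **Fisher z**: regularized covariance → correlation → atanh; diagonal
  excluded (set to 0).  |r| = 1 off-diagonal is an error.
* **Residualization**: for each (connection, window) cell, ordinary
  least squares across subjects on centered covariates (age; gender and
  study coded 0/1) plus intercept; the cell is replaced by residual +
  intercept so the grand level survives for clustering.
* **Variability**: SD over windows per connection (W−1 denominator),
  computed on the residualized z scale (the SD step follows the
  z-transform in the processing order; an r-scale mode exists via the
  correlation helper).  Per-network mean over its N−1 connections and
  the overall mean over N(N−1)/2 connections summarize whole-brain
  dynamics.

## Connectivity states

Features are the residualized Fisher-z upper triangles of all windows of
all subjects (no exemplar subsampling).  Clustering is k-means under the
Manhattan (L1) distance: assignment to the nearest centroid (ties to the
lowest index), centroid update = componentwise median (the minimizer of
summed L1 distance), convergence when assignments stop changing
(max 100 iterations), best of `n_init` random-row initializations
(library default 500; 50–100 in the standing experiments, 8 inside
replicated power studies).  An emptied cluster is re-seeded at the row
farthest from its centroid.  The z-scale feature choice (rather than raw
covariance) keeps features scale-comparable across subjects; a
raw-covariance mode is available by passing unconverted matrices.

k is selected by the elbow of the cluster-validity curve
(within-cluster / between-cluster mean L1 distance over k = 2..8): both
axes are normalized to [0, 1] and the k farthest from the chord joining
the curve's endpoints is taken; a near-linear curve returns the smallest
k with an explicit "no elbow" flag.

Reported states are relabeled by descending total occupancy so labels
are comparable across runs.  Per-subject dynamics metrics: frequency
(proportion of windows per state), mean dwell time (mean maximal-run
length per state; runs touching the scan edges are included — a flagless
choice since truncated runs bias all groups equally), intertransition
interval (W / number of runs), number of transitions (runs − 1).
Stability is assessed by split-half (subjects halved, halves clustered,
centroids matched one-to-one by Hungarian assignment on correlations)
and bootstrap (subjects resampled with replacement, compared to the
full-data centroids) resampling.

## Network dynamics

Each window's |z| matrix is binarized by keeping the m largest
off-diagonal magnitudes, m = round(density × N(N−1)/2); ties at the
cutoff break by (row, column) order, so thresholding is deterministic,
and |r| and |z| rank identically so the scale choice cannot affect the
graph.  The density grid spans 3.7%–39.3% (13..138 edges for N = 27);
the grid step is not prescribed anywhere, so the default takes every
integer edge count in that range, and the analysis scripts thin it to
~26 levels for runtime.  Global efficiency is the mean inverse BFS
shortest-path length over ordered node pairs (disconnected pairs
contribute 0; no largest-component restriction); local efficiency of a
node is the global efficiency of its neighbor-induced subgraph (< 2
neighbors scores 0).  BFS runs level-synchronously for all sources at
once as boolean matrix products, which makes the 27-node graphs cheap; a
Floyd-Warshall triple loop serves as the independent oracle in tests.
Per window, both measures are averaged over the density grid
("integration" = arithmetic mean); the SD over windows (W−1) is the
dynamics summary, and a static counterpart uses the whole-time-course
correlation matrix.

## Statistics

* **Omnibus**: the cited non-parametric MANOVA variant is not
  recoverable from its citation, so the package implements a declared
  substitute: columnwise midrank transform, Pillai-type trace
  tr(H (H+E)^{-1}) of the one-way decomposition on ranks, p-value by
  label permutation, p = (1 + #{permuted ≥ observed}) / (n_perm + 1).
  Because H + E is permutation-invariant on ranks, only H is recomputed
  per permutation.  The substitute is validated by calibration (type-I
  error within [0.03, 0.07] at alpha = 0.05 over 1000 null simulations),
  not by matching any published F values.
* **Univariate**: Kruskal-Wallis (midranks, tie-corrected) with Dunn's
  pairwise z tests from pooled midranks, Benjamini-Hochberg FDR within
  each measure's pairwise family; pairwise effect sizes r² = (z/√n)².
* **Clinical**: Spearman rank correlations, pairwise-complete, optional
  BH adjustment; Mann-Whitney U (midranks; exact p for small tie-free
  samples) for two-group medication-style splits.
* **Demographics**: Pearson chi-square without continuity correction
  (the no-correction form reproduces the reference cohort table's
  printed values; a corrected mode is a one-line change at the call
  site), pooled-variance Student t (df = n1+n2−2, matching the printed
  t_58 for 29+31 subjects), and one-way ANOVA — all computable from
  printed group summaries (means, SDs, sizes) as well as raw manifests.

## Standing experiments and problem sizes

All experiment sizes are the package's own choices, stated here:

* **State recovery**: 30 subjects, strength 0.9 with all three states at
  full magnitude (equally strong, distinctly structured patterns),
  balanced self-transitions 0.97 (mean dwell ≈ 33 TR = 1.5 x the window
  length, so most windows are state-pure — together these are the
  intended meaning of "well-separated" here), noise SD 0.2, no
  trend/spike nuisance.
  Ground-truth window labels are taper-weighted majority latent labels;
  accuracy is maximized over state permutations (Hungarian matching of
  the confusion matrix).  k-means uses 50 restarts at k = 3 and 10 per k
  in the elbow sweep.
* **Dynamics-effect power**: two groups of 30 differing only in the
  state-1 self-transition probability (0.92 vs 0.80, freed mass
  redistributed proportionally); 20 replicates; per replicate the
  estimated-state path runs unregularized windowed correlations →
  Fisher z → L1 k-means (8 restarts, k = 3) → metrics → KW + Dunn.
  Regularization is omitted inside replicates because per-replicate
  lambda CV would multiply runtime ~50-fold while the clustering
  operates on (monotone transforms of) correlations either way; the
  regularized path is exercised end-to-end in the recovery experiment.
* **Null calibration**: identical dynamics in both groups, 1000
  replicates, metrics computed from latent window-majority labels — the
  KW test's null behavior is a property of the metric vectors and group
  labels, not of how state sequences were estimated, and the cheap path
  is what makes 1000 replicates affordable.
* **MANOVA calibration**: 1000 null simulations of 30 subjects x 3
  variables, 199 permutations each (alpha = 0.05 is exactly attainable
  with 199).

## Numerical choices and degenerate inputs

* All randomness flows through numpy `SeedSequence` hierarchies; every
  run artifact records the seed and a config hash, and identical seeds
  reproduce byte-identical outputs.
* Constant columns: zero covariance rows in a window are tolerated at
  the covariance stage and rejected (with the network named) at the
  correlation/static-efficiency stages; constant columns fail the MANOVA
  rank transform explicitly.
* Ties: L1 k-means assignment ties go to the lowest centroid index;
  threshold ties to lexicographically first (row, col); rank ties use
  midranks with standard tie corrections throughout.
* A despiked column must retain ≥ 4 clean points to support the cubic
  spline; otherwise the subject errors out with the network named.

## Known limitations

* The switching-Gaussian generator is the model the pipeline assumes;
  recovery results are upper bounds relative to real fMRI.
* The permutation MANOVA is a calibrated substitute for an unspecified
  published variant; its statistic values are not comparable across
  implementations, only its decisions.
* Lambda cross-validation scores a pooled training fit against held-out
  windows; with long stationary stretches the pooled covariance is
  well-estimated and the CV tends toward small penalties — the grid's
  lower bound is the effective regularizer in that regime.
* Windows spanning state transitions carry mixed covariance; with dwell
  times near the window length, label accuracy is intrinsically capped
  below 100% regardless of estimator quality.
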