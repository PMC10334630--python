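# Methods

## Model

A mass spectrum is a finite set `M = {(x_1, s_1), …, (x_q, s_q)}` with
strictly ascending m/z positions and nonnegative intensities, read as a
sampled curve `f(x_j) = s_j`. Path-connectivity inside an upper-level set
`M_a = {x : f(x) ≥ a}` is realized as contiguity of grid indices whose
intensity clears `a` — the unique faithful discretization of a
one-dimensional curve. Zero-dimensional topological features are the
connected components of `M_a`; sweeping `a` downward, a component is born
at each local maximum (birth `a* = f(x)`) and dies when it becomes
connected to a component led by a taller peak (death `a+`). The global
maximum never merges and receives the global minimum as its death. The
persistence transformation stores `t(x) = (x, a*, a+)` per peak, the
reduced form `t̃(x) = (x, a* − a+)`; projecting away the position recovers
the classical persistence diagram of the upper-level-set filtration.

Conventions, all deterministic:

- **Plateaus.** Runs of equal consecutive intensities collapse to one
  point represented by the leftmost index; a constant spectrum has exactly
  one feature with birth = death.
- **Boundaries.** Grid endpoints may be local maxima.
- **Elder rule ties.** Components with equal birth are ordered by the
  induced order of the m/z axis: the smaller index is elder. When the two
  merge candidates tie, the merge-tree parent is the smaller-index one.
- **Tie comparison.** Floating-point equality is exact, no epsilon: ties
  in real data are exact duplicates produced by intensity quantization.
- **k% extraction.** `ceil(k/100 · m)` features are retained (at least
  one for every valid `k ∈ (0, 100]`), ties at the cutoff resolved toward
  the smaller index. Because the global feature attains the maximal
  persistence `max − min` and, among equally persistent features, the
  smallest index, it is always retained.

With tied intensities, several equal-height global peaks may each span the
full intensity range; the *unique* global feature is then identified as
the merge-tree root (elder of all).

## Algorithm

Indices of the plateau-collapsed sequence are processed in descending
intensity order (stable sort, so equal values go left to right). Active
components are maintained as index intervals with O(1) endpoint
bookkeeping and an elder record per interval; activating an index either
founds a component (a birth), extends one, or merges two — recording the
death and merge parent of the younger elder. The sweep is iterative, so
recursion depth never bounds the spectrum length; total cost is the sort,
`O(q log q)`. Spectra with ~10⁵ points transform in milliseconds and
runtime grows near-linearly in `q` (measured exponent ≈ 1 in the
acceptance script).

Correctness is established against two independent routes: (i) a
brute-force reference (`topoms.reference`) that replays the filtration
literally — descending threshold sweep on the raw grid with a
scipy disjoint set, births at isolated activations, elder-rule merges,
with transient zero-persistence births of non-peak plateaus filtered —
and (ii) a directional-barrier rule evaluated per peak (death = the larger
of the two path-minimum barriers to the nearest taller point, where on the
left "taller" includes equal height, since a tied left component is
elder). Both agree exactly with the sweep implementation, including merge
parents, on randomized corpora with heavy ties.

## Classification

The persistence matrix `Z` (one row per spectrum, persistences scattered
to their m/z indices, zeros elsewhere; extraction applied per spectrum) is
fed to:

- **Logistic regression**, logit link, no penalty, lbfgs with tolerance
  1e-8 and an iteration cap of 1000. Sparse persistence features can be
  linearly separable; the cap then stops the fit with a logged warning.
  Class 1 is predicted iff the fitted probability strictly exceeds
  `c = 0.5`.
- **Random forest** in its original form: 1000 CART trees on bootstrap
  samples of size `n`, Gini impurity, `floor(sqrt(q))` candidate
  covariates per split, minimum leaf size 1, majority vote, seed 1234.

Evaluation is balanced accuracy, `(recall_0 + recall_1)/2`, under
cross-validation grouped at the TMA level (leave-one-group-out in
ascending group order, or a two-way split of groups), so no group ever
straddles train and test. Summary statistics over folds are mean, min,
max, median and the sample standard deviation (n−1 denominator). A test
fold containing a single class is an error naming the fold. Hyperparameter
search is deliberately out of scope.

## Synthetic data generator

`simulate_image` emulates the structure of ground-truth MS images used in
noise studies: a pixel grid whose top-left quadrant holds a circle
(radius `min(h,w)/5`) and whose bottom-right quadrant holds a square
(side `0.4·min(h,w)`), on an m/z axis of 1000 bins spanning 500–2000
(the much finer grid of the original simulation tooling is intentionally
not replicated). Fifty true peaks are placed uniformly with a minimum
separation of 12 m/z (6× the default Gaussian profile sigma of 2 m/z), so
distinct peaks remain resolvable as distinct local maxima — as distinct
molecular species are. Each peak is assigned to circle-only, square-only,
or both (40% shared by default); amplitudes are log-normal with median 100
and sigma 0.2; a pixel's spectrum is a constant baseline (0, 5 or 15 in
the studied range) plus the profiles of the peaks active in its region.

Contamination is additive: Gaussian `N(0, sd²)` clamped at zero (MALDI
intensities are nonnegative), or Poisson with rate λ per bin — at large λ
the noise peaks rival the signal. Rendering uses the mean-spectrum
convention; the denoised image is, per pixel, the mean of the dense vector
of retained k%-persistence values.

`simulate_labeled_spectra` produces two classes sharing `n_shared` peaks
and owning `n_exclusive` exclusive peaks each on a 300-bin axis (profile
sigma 6 m/z, minimum separation 24 m/z), with a log-normal per-spectrum
intensity scale (sigma 0.1) and additive clamped Gaussian noise (default
sd 10, i.e. 10% of the mean amplitude 100); group ids are assigned
round-robin so every group contains both classes.

What the generator does *not* model: isotope patterns, correlated
(pink/structured) noise, baseline drift and TIC-normalization artifacts,
peak-position jitter across spectra, and spatial correlation between
neighbouring pixels. Passing tests therefore demonstrate correctness of
the topological machinery and sensible behaviour under idealized noise,
not performance on real acquisitions.

## Problem sizes and numerical choices

The randomized cross-check corpus is 1000 spectra of lengths 2–500, half
continuous, half quantized to small integers to exercise tie handling
heavily. Denoising studies use 30×30 (and 60×60 for timing) images with
1000 bins; the classification study uses n = 200 spectra, 4 groups,
k = 30% extraction. The stability check perturbs by ε = 0.05 in sup-norm
and requires every feature with persistence > 2ε to match injectively
within ε in birth and death (feasibility matching via linear assignment);
a formal stability theorem for the transformation is an open question, and
the check is a numerical proxy on random instances only.

The Poisson contrast study uses λ = 30 — large enough that noise maxima
(≈ 20–45) dot every background pixel, small enough that signal
persistences (≈ 100) survive — rendered at k = 1%.

## Limitations

- Per-spectrum k% extraction is a design choice; a dataset-global
  extraction variant is intentionally not implemented.
- The oracle-style per-pixel k used in the recovery statistic requires
  knowing the number of active true peaks and is available only in
  simulation; background pixels (no active peaks) are excluded from the
  statistic since no retention fraction is defined for them.
- Only 0-dimensional homology applies: spectra are curves, so no higher-
  dimensional features exist. Sublevel-set filtrations and bottleneck
  distances are out of scope.
- imzML ingestion is optional and read-only; the canonical interchange
  format is the delimited-text matrix.
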