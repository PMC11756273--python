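# Methods

This note records the models implemented, the conventions and numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the design decisions taken where more than one reasonable
definition existed.

## Substitution models

All models are continuous-time reversible Markov chains on the 20 amino
acids, ordered `ARNDCQEGHILKMFPSTWYV` throughout the package.  A rate
matrix is assembled from a symmetric exchangeability matrix `s` and an
equilibrium profile `π` as `Q_ij = s_ij π_j` (i ≠ j), diagonal set so rows
sum to zero, and scaled so `−Σ_i π_i Q_ii = 1` (branch lengths are
expected substitutions per site).  Two exchangeability presets ship:
Poisson (all off-diagonals equal) and the empirical LG matrix with its
published frequencies, bundled as a text data file so no network access is
ever needed.

Transition probabilities use the symmetrized eigendecomposition
`B = D^{1/2} Q D^{-1/2}` (D = diag(π)), which is exact for reversible Q
and numerically stable; `P(t) = D^{-1/2} U e^{Λt} U^T D^{1/2}`.  For
simulation, P rows are clipped to [0, 1] and renormalized to absorb
last-ulp negatives; for likelihoods the raw reconstruction is used.

**Profile regularization.**  A zero equilibrium frequency makes the chain
non-ergodic, so profiles entering a rate matrix are floored at ε = 1e−10
and renormalized.  `build_rate_matrix` rejects profiles containing exact
zeros rather than silently fixing them; the regularization is an explicit
call (and is applied automatically where profiles are generated or read
from files).  Flooring at 1e−10 leaves any entry above the floor bitwise
unchanged, so well-formed profiles pass through untouched.

**Discrete gamma rates.**  K equiprobable categories with the category
rate equal to the conditional mean of the mean-one gamma density over its
quantile bin (computed with regularized incomplete gamma functions, then
rescaled so the weighted mean is exactly 1).  Means, not medians: this is
the convention of the major ML phylogenetics programs.  The gamma shape α
is never optimized here — it is a user- or fixture-supplied parameter,
recorded in every report (default 1.0 in the pipeline and fixtures).

**Model flavours.**  Homogeneous (one profile), finite mixture (k class
profiles, weights summing to 1, one shared exchangeability matrix), and
site-specific profiles (one profile per column — the PMSF form).  The
empirical C10–C60 class-profile tables are not bundled; mixtures read
their class profiles from a small text file (one line per class, 20
frequencies with an optional leading weight).

## Simulation

Each site is independent.  Per site: a gamma category is drawn uniformly
over the K categories (equal category weights), a mixture class is drawn
by weight where applicable, the root state is drawn from the governing
profile, and states propagate down the tree using rate-scaled transition
probabilities per edge.  The root is the tree's internal seed node; by
reversibility the sampling distribution is invariant to that choice
(checked by the root-invariance likelihood test).

**Reproducibility scheme.**  Site j of a request with seed s (an int or a
tuple) consumes uniforms from `numpy.random.default_rng((*s, offset + j))`
in a fixed order: class, category, root state, then one per edge in
preorder.  Because every site owns a counter-based substream, simulating
sites one at a time (with `site_offset = i`) and concatenating the columns
is bit-identical to the batch run — the property that makes site-by-site
PMSF simulation reproducible.  Replicate r of an adequacy test uses
substream `(seed, r)`.

**Missing data.**  Real matrices are gappy, and div is sensitive to
per-column sample size, so by default the adequacy pipeline copies the
observed alignment's gap-plus-ambiguity mask onto every replicate
(`gap_mode="copy"`); `"none"` simulates complete matrices.  Whether
replicates should inherit the real missingness pattern is genuinely open —
both behaviors are exposed and the active flag is recorded in reports.
Indels are not simulated.

## The adequacy test

div(A) is the mean over columns of the number of distinct canonical
residues observed; gaps and ambiguity codes (`X B Z J * .`) are treated as
unobserved, and all-unobserved columns are excluded from the mean rather
than counted as zero — they carry no compositional information (recorded
in the report metadata).  The Z-score uses the sample SD (n−1).

**Sign convention.**  Z = (mean of replicates − observed) / SD: a model
that overproduces per-site diversity — the characteristic failure of
site-homogeneous models on heterogeneous data — gets a positive Z.  The
convention matches the way such tests are conventionally tabulated (the
negative of the naive (obs − mean)/SD deviate); a `negate` flag flips it.
The verdict band is fixed at −2 < Z < 2, with the caveat that the band
reads as a 95% statement only under normality — hence the replicate
distributions are always written out for inspection.

## Likelihoods and PMSF

Site likelihoods use the standard postorder pruning recursion over
20-state conditional likelihood vectors.  Underflow control: after each
internal node the site's vector is divided by its maximum and the log of
the factor accumulated per site, so hundreds of taxa are safe in double
precision.  Gap/ambiguous leaves contribute all-ones partials (an all-gap
column has log-likelihood exactly 0).  Gamma categories are averaged with
weight 1/K; mixture classes with their weights (log-sum-exp).  Pattern
compression is not performed; linearity over repeated columns is tested
instead.

The PMSF step computes, per site, the posterior probability of each
mixture class with the gamma categories summed out *inside* each class
(the joint class-by-rate posterior marginalized over rates), then takes
the posterior-weighted average of the class profiles as the site's
profile.  The output is therefore always a convex combination of the
class profiles, and reuses the mixture's exchangeabilities and gamma
model.  A site with zero likelihood under every class is an error (it
cannot occur after profile regularization).

**Profile files.**  The IQ-TREE-style site-frequency dialect is one line
per site (index + 20 frequencies).  The Phylobayes-style dialect is pinned
to the block format shipped in this repository's fixtures (residue header
line, `sample <n>` block headers, one row per site); the upstream tool's
exact layout is not reproduced anywhere authoritative, so the reader is
dialect-configurable and validated against the fixture format.  Posterior
samples are combined by per-site arithmetic mean followed by
renormalization — the natural "posterior mean" reading of profile export;
other combinations can be applied upstream of the writer if needed.
Row sums are tolerated up to 1e−2 from 1 (input rounding) and renormalized
on read.

## Curation filters

Order: gap/length filter → paralogue resolution → iterated long-branch
removal.  Each filter is a no-op on its own output except the long-branch
filter, which owns an internal pass count.

* **Gap/length**: drop sequences with gap fraction strictly above 0.25
  (gap characters only, not ambiguities); exclude families whose
  alignments are not strictly longer than 50 columns or that retain fewer
  than two sequences.
* **Long branch** (2 passes, threshold mean + 2·SD): statistics are
  computed over *all* branch lengths of the current gene tree (internal +
  terminal; a terminal-only pool is available via `pool="terminal"`), with
  the sample SD; removal applies to leaves via their terminal branch.
  Trees are pruned, not re-inferred, between passes.  Iterating matters
  because one extreme branch inflates the SD enough to shield a second
  outlier; the two-outlier construction in the tests demonstrates the
  pass-2 catch.  A pass that would leave fewer than four leaves is
  skipped and flagged.
* **Paralogues**: a taxon's multiple copies are in-paralogues when they
  form one side of a bipartition of the unrooted gene tree (no rooting
  rule is assumed); then the copy with the shortest terminal branch — the
  only per-copy length available — is kept.  Any non-monophyletic copy set
  excludes the whole family.

Every removal is logged once with a reason; replaying a log against the
input family reproduces the filtered output exactly.

## Synthetic data

Fixture trees come in four shapes (balanced, pectinate, star, and a
coalescent-like shape built by uniformly random pairwise joins) with
branch lengths drawn i.i.d. from an exponential (default mean 0.1) or
uniform distribution.  Site profiles are Dirichlet draws: concentration
0.1 gives sparse profiles (typically fewer than six residues above 5%
frequency per site), emulating the strong per-site preferences an
infinite-mixture analysis recovers from real proteins; 0.5 is a milder
regime; `uniform` is the homogeneous control.  Eight named 9-leaf
topology fixtures (competing hypotheses of ecdysozoan relationships, with
synthetic branch lengths) ship as package data for experiments of the
shape "profiles estimated under topology X".

What the generator does **not** emulate: among-branch compositional
drift, indel processes, alignment/trimming error, model misspecification
of the exchangeabilities, and linked sites.  Tests passing on these
fixtures show the machinery is correct and the statistic behaves as
designed under its own assumptions — not that any particular empirical
dataset is well described by any particular model.

## Problem sizes

The full-scale protocol (scripts/acceptance.py) uses 100 taxa × 2,000
sites × 100 replicates × 10 seeds, the regime where the div statistic's
self-consistency and discrimination behavior is cleanly separated
(|Z| ≲ 1.5 under the true model vs Z ≈ 40–55 for the homogeneous model on
sparse-profile data).  The test suite runs the same protocols at 40 taxa ×
500 sites × 60 replicates, which preserves both behaviors; the bootstrap
Z under the true model is approximately pivotal, so the calibration does
not depend on the problem size.

## Known limitations

* No ML optimization: branch lengths, gamma shape, exchangeabilities and
  mixture weights are inputs, not estimates.
* div is the only adequacy statistic shipped (the interface accepts any
  alignment→scalar function internally, but only div is exposed).
* The Z band at ±2 is a convention, not a calibrated size; for skewed
  replicate distributions, inspect the distribution files.
* Newick support covers the common dialect (lengths after `:`, bracket
  comments ignored, unquoted labels with underscores preserved).
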