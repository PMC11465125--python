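# Methods

This note documents the models and procedures `irisphylo` implements,
the parameters that matter, what the synthetic-data generators emulate,
and the numerical and design choices made where the design was open.

## Color categorization

An iris image is reduced to its per-channel arithmetic mean (rounded
half-up to integers, matching how printed RGB triples are integer),
encoded `#RRGGBB`, matched against a color-name table, and assigned to
one of eleven basic categories: white, black, red, green, yellow, blue,
brown, purple, pink, orange, gray. "Hazel" counts as green and "beige"
as yellow. A name resolves to a category through its own hue token when
it has one (the *last* hue word, following descriptor conventions in
which the final noun is the hue); otherwise through an ISCC-NBS-style
descriptor ("Burnt Coffee" → "moderate brown" → brown). Names with
neither raise an explicit error rather than guessing.

The packaged color-name table (`colornames.py`) is a curated fixture of
~70 records standing in for the tens-of-thousands-entry open-source
color-name databases; because it is a subset, `name_color` falls back
from exact hex match to the nearest entry in Euclidean RGB distance
(ties broken lexicographically by name). With a full database the
fallback is nearly always an exact or near-exact hit; with the fixture
it is the normal path. Transparent pixels are excluded on load —
transparency is the programmatic stand-in for manual iris cropping.

Most-common colors use predominance thresholds evaluated in order:
four categories each >20%, else three each >26.6%, else two each >40%,
else the single plurality category. The thresholds are strict
inequalities; a 60/40 split therefore yields a single most-common
color, not two.

## Polymorphism statistics

Pixel-level PCA is computed on centered, unscaled RGB values (the three
channels share units, so correlation scaling would distort the
dark–light axis). Components are sign-fixed (largest-magnitude loading
element positive) so downstream results are deterministic. With three
channels the three components always capture 100% of the variance;
what matters is which color contrast each axis encodes, visualized by
averaging pixels in 20 equally spaced score bins (last bin
right-closed; empty bins are reported as missing, never zero).

The category effect on each component is tested with a linear mixed
model: score ~ category with random intercepts for taxon and for image
nested in taxon, so pseudo-replicated pixels cannot masquerade as
independent evidence. The omnibus category test is a Wald chi-square on
the category coefficients with Bonferroni correction across the three
components; at the pixel counts involved (tens of thousands) this is
numerically indistinguishable from a Satterthwaite-type F test, which
the statistical backend (statsmodels MixedLM) does not provide.
Significant omnibus tests are followed by all-pairs contrasts with a
studentized-range (Tukey-style) adjustment. Singular fits are flagged
in the result rather than raised. Per-species tests along PC2 use
Kruskal–Wallis (midranks, standard tie correction) with Bonferroni over
species, followed when significant by two-sided pairwise Mann–Whitney
tests (exact for groups of ≤8) with Bonferroni over pairs; adjusted
p-values are capped at 1.

## Shade extraction

Irises are rarely homogeneous — central heterochromia puts a darker
pigment near the pupil and a lighter one in the periphery — so each
taxon × color group is summarized by 2–4 shades:

1. **Embedding.** Per image, pixels are reduced to 2-D. The default in
   analyses is UMAP (15 neighbors, min_dist 0.1, Euclidean, fixed seed;
   deterministic in single-threaded mode) for its preservation of local
   structure; a PCA projection is provided as a fully deterministic,
   fast alternative and is what the test suite exercises.
2. **Cluster count.** k is selected per image by an automated elbow on
   the k-means SSE curve over k in [1, 6]. The criterion is the largest
   *relative* SSE drop, SSE(k−1)/SSE(k) — the discrete curvature of the
   log-SSE curve. The curvature of the raw SSE curve was considered and
   rejected: for equally spaced, well-separated shades it provably
   peaks at k=2 regardless of the true count (the first drop dominates
   the second difference), whereas the scale-free form recovers planted
   counts of 2, 3 and 4. A vanishing SSE wins outright; ties go to the
   smaller k; all-identical pixels give k=1. A single noisy shade may
   read as 2 under this criterion — in the intended data every eye has
   at least two shades, and the consensus step damps per-image noise.
3. **Consensus and re-clustering.** Per-image k values are averaged and
   rounded half-up; every image is re-clustered at the consensus k
   (k-means on the embedding, 10 restarts, best inertia; cluster mean
   RGB computed in original space over member pixels). Images with
   fewer distinct embedded points than the consensus k cannot be
   matched cluster-for-cluster and are dropped from the merge.
4. **Matching and merging.** Clusters are matched to a reference image
   (the one with the most pixels — the choice the data most rewards,
   since images are deliberately not resized and pixel count weights
   the merge) by exhaustive search over all k! assignments for the
   minimum summed squared RGB distance; ties take the lexicographically
   smallest permutation. Merged shade RGBs are pixel-count-weighted
   means; prevalence ranks by total pixel count, ties to the darker
   shade.
5. **Tiers.** Three shades are slotted dark/medium/light by increasing
   Euclidean distance from black (0, 0, 0). Two shades each take the
   nearest of the reference tier averages — by default the global mean
   dark/medium/light over all three-shade profiles in the current run
   (global rather than per color group, so sparse groups still get a
   reference) — and the vacant tier is filled: missing dark or light
   duplicates medium; missing medium averages dark and light. One shade
   is duplicated into all tiers. Four shades first merge the two
   closest (count-weighted) and proceed as three. Every profile
   therefore exposes exactly three tiers, making eyes with different
   shade counts comparable.
6. **Stability.** The profile is recomputed on image prefixes of
   growing size; convergence means the largest per-channel change over
   the last step is below 5 channel units (~2% of the scale). Curves
   that level off indicate the sample has overcome lighting noise.

## Discrete ancestral reconstruction

Presence/absence of each color evolves under a continuous-time Markov
model; the likelihood is computed by Felsenstein's pruning algorithm
with per-node rescaling (the inner loop is numba-compiled; transition
matrices come from the eigendecomposition of the generator, falling
back to a scipy matrix exponential when the eigenbasis is
ill-conditioned). Impossible data yield an explicit −inf, never a
sentinel. Missing tips enter as uninformative partials.

Fourteen model variants are compared: ER and ARD versions of the plain
Mk model; of a gamma edge-rate Mk model (each edge's rate integrated
over K=4 equal-probability discrete-gamma categories with mean one,
category rates by the mean-of-interval convention, edges independent);
of hidden-rates models with 2 and 3 rate classes (flip rates per class
plus a ladder of class switches — symmetric one-rate for ER,
directional for ARD; simultaneous observed+class transitions have rate
zero); of one-sided hidden-rates models with a hidden class only when
the color is present, or only when absent (the single-class observed
state connects to every class of the other); plus irreversible
gain-only and loss-only Mk models. "2 and 3 rate classes" reads the
four/six-state phrasing as total expanded states for a binary
character. Free-parameter counts follow from the parameterization
(ER Mk 1, ARD Mk 2, …); AIC = 2k − 2logL, Akaike weights
w ∝ exp(−ΔAIC/2), AIC ties resolved toward fewer parameters.

Rates are estimated by multi-start L-BFGS-B on log rates, bounds
[1e-8, 1e3], first start at 1/tree-height, 10 restarts by default,
seeded; non-convergence is flagged with the best point returned, and
fits within a factor ~2 of the box bounds are flagged `boundary`. The
root prior defaults to equal over expanded states (configurable to
stationary or custom).

Marginal ancestral probabilities combine tipward and rootward partial
likelihoods at the MLE — valid for arbitrary generators, including
irreversible and hidden-state models — with hidden classes summed out.
A color is called present above 0.5 strictly; an exact 0.5 is called
absent and flagged. Agreement with exhaustive joint-state enumeration
is verified to 1e-8 on random ≤6-tip trees. A utility enumerates the
2⁵ − 1 = 31 non-empty color combinations of the five-color polymorphic
state space.

## Quantitative ancestral reconstruction

For each (node, color) called present, a subset tree retains exactly
the tips reachable from the node through an unbroken chain of
present-called nodes. A tip below any absent-called node is excluded
even if itself present: its color re-arose independently and carries no
information about the focal ancestor's shade. Pruning removes degree-2
nodes and sums their branch lengths, so retained pairwise path lengths
are unchanged.

On the subset tree, each of the 9 channel × tier combinations is
reconstructed under Brownian motion. The estimate at a node is the
generalized-least-squares root estimate of the tree rerooted at that
node — computed directly from the rerooted tip covariance
C_x[i,j] = (d(x,i) + d(x,j) − d(i,j))/2 — with variance
σ̂²/(1ᵀC_x⁻¹1) and CI95 = estimate ± 1.96·sd; σ² is the ML estimate at
the root (residual quadratic form divided by the number of tips). A
1e-12 ridge guards near-singular covariances; a tip at distance zero
from the evaluation node pins the estimate to that tip. The two-tip
equal-branch case reduces to the arithmetic midpoint, estimates are
affine-equivariant, and simulated 95% CI coverage is 95% ± 3%.
Estimates outside [0, 255] are flagged, never clipped; display values
round half-up with raw floats retained. Tiers filled upstream by
duplication contribute their filled values, by design. Presence calls
feeding the subsetting come from the single best (lowest-AIC) model,
not a model average.

Shade counts (1–4) and primary/secondary tier identities are
reconstructed as unordered multistate characters (ER and ARD fits,
AIC-selected — "unordered" because nothing forces, say, dark→light
changes through medium); a single observed state short-circuits to a
degenerate certainty reconstruction.

## Trait correlation

Two binary traits evolve jointly on {(0,0), (0,1), (1,0), (1,1)} with
simultaneous double transitions forbidden. The independent model has 4
free rates (each trait's gain/loss unaffected by the other's state);
the dependent model has 8. Both are fitted by maximum likelihood
through the Mk machinery. The comparison is summarized by a log Bayes
factor operationalized as 2·(logL_dep − logL_indep) — with ML fits this
likelihood-ratio form is the only computable analog of the Bayes-factor
convention — computed per replicate from fresh random starts and
averaged (default 100 replicates), significant above 2. Replicate
averaging mirrors the optimizer stochasticity of the original
procedure. No multiple-testing correction is applied across pairs;
the threshold-2 rule is the only filter.

A caution established by this package's own simulations: because
2·ΔlogL between nested models with 4 constraints has null expectation
near 4, the logBF>2 rule is permissive — on 100-tip trees with
independently evolving traits it flags roughly a quarter to a half of
pairs depending on rates. Self-comparisons (a trait against itself) are
the positive control: they come out significant with tetrachoric +1.

Tetrachoric correlation: thresholds from the margins of a latent
bivariate standard normal, correlation by bounded scalar ML over the
quadrant multinomial. Boundary tables return exactly ±1 with the sign
of the association (empty concordant cell → −1, empty discordant cell
→ +1); constant-margin tables are degenerate and raise. Continuous
shade averages are discretized by exact Jenks natural breaks (O(kn²)
dynamic programming over prefix sums; boundaries reported as class
maxima; default 2 classes) with the lighter class coded 1, so a
positive association reads "associated with lighter shades". Multistate
traits (activity, region, habitat, coat pattern, nose color) expand to
one indicator per category, and a taxon may carry several categories at
once.

## Trees

Trees are rooted, with unique tip labels and nonnegative branch
lengths in arbitrary consistent time units; zero-length edges are
permitted but discoverable. Newick I/O, pruning and clade extraction
are backed by dendropy; underscores in labels are preserved verbatim.
Taxa missing from a reference tree are grafted as polytomies at the
anchor's parent with pendant length equal to the anchor's own branch —
a deliberate overestimate of divergence that never rescales existing
edges, so grafted trees may be non-ultrametric (the ultrametricity
check reports the maximum root-to-tip deviation). When the anchor is a
clade, its stem branch length is used. Internal nodes are named by
Newick label when present, else `N<postorder index>`; these names key
all per-node outputs.

## Synthetic data

The generators define the study conditions and are all bit-reproducible
under a fixed seed, recording complete node-level truth:

- **Irises** (`gen_iris`): 1–4 shade centroids with proportions summing
  to 1; pixel counts by largest-remainder allocation (deterministic);
  per-pixel iid Gaussian channel noise, clipped to [0, 255] and rounded.
  The `rings` layout keeps shades contiguous (equal-area concentric
  annuli in the PNG rendering, emulating central heterochromia);
  `mixed` shuffles. Real pixel noise is uncharacterized, so `noise_sd`
  is an exposed parameter; 5 channel units is the default working value
  in tests. No camera, lighting or specular effects are simulated, so
  passing recoveries demonstrate the pipeline's correctness on its own
  model, not robustness to photographic artifacts.
- **Trees** (`gen_tree`): pure-birth (Yule), conditioned on n tips with
  the proper final Exp(n·λ) waiting time appended (the raw simulator
  stops at the n-th birth, leaving zero-length pendant edges), scaled
  to unit height by default — rates are therefore per unit tree depth.
- **Characters**: `sim_mk` draws states edge-by-edge from the matrix
  exponential; `sim_bm` adds Normal(0, σ²t) increments; `sim_pagel`
  evolves the joint 4-state chain with double transitions forbidden.

## Problem sizes in the checked runs

The simulation studies in the test suite use the sizes the methods are
documented with: 100 random ≤6-tip trees for enumeration agreement, 50
replicates of 300-tip trees for Mk rate recovery (median q̂ within
[0.4, 0.6] of the generating 0.5), 1000 node draws on 100-tip trees for
CI coverage, 500 independent and 60 strongly dependent trait pairs on
100-tip trees (2 replicate refits, 1 restart each) for the logBF rule's
error rates, planted 2–4-shade irises of 2000 pixels for shade
recovery, and 100 random arrays (n ≤ 12, k ≤ 4) against exhaustive
partition search for Jenks. The full suite runs in a few minutes on one
CPU.

## Known limitations

- The color-name fixture is small; nearest-neighbor naming is coarser
  than the full open-source databases it stands in for.
- The logBF>2 dependence rule has the permissive null behavior noted
  above; treat flagged pairs as candidates, not conclusions.
- Shade reconstruction is per color: taxa near a category border
  contribute to only one color's reconstruction.
- No Ornstein–Uhlenbeck or rate-shift continuous models; Brownian
  motion only. No Bayesian stochastic mapping; marginal (not joint)
  discrete reconstruction only.
- Automated elbow selection can differ from a human reading of an
  elbow plot on ambiguous SSE curves.
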