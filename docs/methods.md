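# Methods

## Substitution models

All models are continuous-time Markov generators Q over the nucleotides in
fixed order A, C, G, T (U is a synonym of T on input): off-diagonal entries
are non-negative and rows sum to zero.

* **GTR** is parameterized by six exchangeabilities (a..f) and equilibrium
  frequencies π, with q_ij = r_ij π_j and symmetric r, so detailed balance
  π_i q_ij = π_j q_ji holds by construction and π is stationary.
* **NREV6** constrains each substitution to share a rate with its strand
  complement: q_AC = q_TG, q_AG = q_TC, q_AT = q_TA, q_CG = q_GC,
  q_CT = q_GA, q_GT = q_CA. The constructor applies these equalities to the
  raw rates with no frequency factors; Q is then invariant under the
  relabelling A↔T, C↔G, from which complement symmetry of the stationary
  distribution (π_A = π_T, π_C = π_G) follows as a theorem — the test suite
  asserts it rather than imposing it. An alternative convention would
  multiply rows by frequency factors, but that breaks the stated rate
  equalities unless π is already complement-symmetric, so the pure-rate
  convention was adopted.
* **NREV12** (the UNREST convention) places twelve unconstrained rates on
  the off-diagonals. Its equilibrium frequencies are not free parameters:
  they are the stationary distribution obtained by solving πQ = 0 (null
  space of Qᵀ, refined by a constrained least-squares solve; residual
  tolerance 1e-10). Frequency-factor parameterizations of a 12-rate model
  are circular once π must itself satisfy πQ = 0, which is why the pure
  rate convention is used here too.

For identifiability during fitting one reference rate is fixed at 1 (the
A→G rate, matching the convention in which ladder rate tables are
expressed); for branch-length interpretation a generator can additionally
be normalized so −Σ_i π_i q_ii = 1, i.e. one expected substitution per
site per unit time.

Transition probabilities P(t) = exp(Qt) are computed by eigendecomposition
of the (generally non-symmetric) generator with an `expm` fallback when
the eigenvector matrix is ill-conditioned (condition number > 1e8); tiny
negative entries from roundoff are clipped and rows renormalized.

Among-site rate variation uses the standard equal-probability discrete
gamma: ncat quantile bins of a Gamma(α, 1/α) density, each represented by
its conditional mean, so the mixture has mean rate exactly 1. Default
ncat = 4; ncat = 1 disables heterogeneity.

## Likelihood and optimization

The likelihood is Felsenstein pruning over a rooted tree with per-node
rescaling of partial likelihoods (log-scale accumulators) so long
alignments do not underflow. Alignment columns are compressed to unique
site patterns, and the postorder pass runs as a numba-compiled kernel
(with a pure-NumPy fallback) since it sits inside every optimizer
evaluation. Gaps and N are fully ambiguous observations; IUPAC codes
become indicator partial likelihoods. Because NREV6/NREV12 are not
reversible, the likelihood genuinely depends on the root position; the
pulley principle holds only for reversible models rooted at stationarity
(both facts are asserted in tests).

Root-state distributions: empirical base composition for GTR, stationary
π of the fitted generator for NREV6/NREV12 (empirical available as an
option), and three free parameters (softmax-parameterized) for NREV12+F.

Maximization alternates two blocks until the relative log-likelihood gain
falls below 1e-6 (at most 8 rounds):

1. substitution parameters (log-rates, log-α, root logits) by bounded
   L-BFGS-B, with the generator normalized to unit expected rate inside
   the objective — without this normalization the reference-rate
   convention creates a flat ridge between overall rate scale and total
   tree length along which block descent zigzags badly;
2. branch lengths coordinate-wise by bounded scalar minimization, using
   the up/down decomposition so one full sweep costs about two tree
   traversals; lengths are bounded to [0, 20] expected substitutions/site
   to keep exp(Qt) well-behaved.

Restarts with jittered initial parameters are available (`n_restarts`);
the default is a single deterministic start, which proved stable at the
problem sizes used here because the objective is initialized from
equal rates and the input tree's branch lengths. Warm starts
(`init_rates`, `init_alpha`) let a nested fit seed its generalization,
which both speeds up NREV12 fits and guarantees the likelihood ordering
required by nested-model tests.

Topology search is NNI hill climbing with the fitted model frozen: every
nearest-neighbour interchange of the current tree is scored by
re-optimizing only the branch lengths the swap touches, the best
candidate receives a full branch sweep and is accepted while the
log-likelihood improves, and the free parameters are refitted once on
the final topology (rearrangements of NNI magnitude barely move the rate
estimates, so per-move refits buy almost nothing at several times the
cost). Accepted-move rounds are capped (default 50; the simulation study
uses 6) because on near-saturated data hill climbing otherwise wanders
on an essentially flat surface. The root position is kept where the
starting tree put it; for reversible models this is equivalent to an
unrooted search. The search is deterministic given its seed, and the
returned log-likelihood never falls below the starting fit's.

## Model selection

AIC-c = −2logL + 2k + 2k(k+1)/(n−k−1) with n = number of alignment
columns. k counts substitution parameters + gamma shape + branch lengths,
structured identically across families so AIC-c differences reduce to
substitution-parameter differences: GTR 5 exchangeabilities + 3 free
frequencies = 8, NREV6 5, NREV12 11, NREV12+F 14. Akaike weights are
exp(−Δ_i/2) normalized over the fitted families. LRTs use
χ² with d = difference in substitution free parameters: GTR→NREV12 d = 3,
NREV6→NREV12 d = 6. Whether empirical GTR frequencies "should" count as
free parameters is a judgement call; counting them keeps the GTR⊂NREV12
nesting arithmetic consistent (8 + 3 = 11).

## Quantifying non-reversibility

For each unordered nucleotide pair with forward rate m and reverse rate
n, the pair DNR is |m − n|; the mean DNR averages the six pairs. DNR is
convention-dependent (doubling all rates doubles it); rates are expressed
with the A→G rate fixed at 1, the same convention the ladder tables use,
and reports record the convention tag.

The irreversibility indices implement the Kolmogorov cycle criterion: a
stationary chain is reversible iff around every cycle the clockwise and
anticlockwise rate products agree. On four states the three triangles
through A are an independent cycle basis, so IRI1–3 are the log ratios of
the two products around {A,C,G}, {A,C,T}, {A,G,T}; all three vanish iff Q
is reversible, they are invariant to rescaling Q, and the fourth
triangle's ratio is the signed combination IRI1 − IRI2 + IRI3 (asserted
numerically). Closed-form cycle ratios were chosen over flux- or
entropy-based measures for scale invariance and an exact zero under
reversibility.

## Simulation study

The DNR ladder starts from a reversible baseline rate set (relative rates
A↔C 0.166, A↔G 1, A↔T 0.14, C↔G 0.131, G↔T 0.118, C↔T 1.101) and adds an
offset d to exactly the six designated forward substitutions C→A, G→A,
A→T, G→C, T→G, C→T, leaving the reverse rates untouched; the mean DNR of
the result is d exactly. (One published rendering of the baseline matrix
prints the G↔T entry as 0.188; the ladder table value 0.118 is used
throughout, and the two agree on every DNR statistic since the baseline
is symmetric either way.)

The ladder matrices are used on their printed relative-rate scale: the
offset raises the overall substitution rate (≈3× the baseline at d = 2,
≈9× at d = 8, ≈21× at d = 20), so on a fixed true tree higher-DNR
datasets are genuinely more diverged. This is the effect the accuracy
study measures — inferred branch lengths outgrow the fixed true tree
while DNR rises — and normalizing every level to one substitution per
unit time would erase it. For the study the whole ladder is divided by
the baseline's expected rate (`study_matrix`), a pure unit choice that
makes true-tree branch lengths read as expected substitutions/site at
DNR = 0 (so the DNR = 0 cell gives unbiased branch-length inference and
the model comparison there measures pure noise) while preserving the
d-dependent divergence ratios.

Alignments are simulated column-independently: root states drawn i.i.d.
from the stationary π of the generator, then propagated down each branch
through exp(Q r_c t) with the site's gamma multiplier r_c. This makes
the process stationary along the whole tree (π e^{Qt} = π), which the
suite verifies by a χ² goodness-of-fit of a tip sequence's base
composition. Gamma heterogeneity is off by default in simulations.

True trees are seeded Yule topologies (default 20 taxa, exponential
branch lengths) standing in for a fixed empirical tree that is not
publicly tabulated; the study's logic only requires fixed true trees.
Each tree is rescaled by a single factor, found by bisection against
calibration simulations (5 × 2000 sites), so the average pairwise
identity (API) of simulated alignments hits a target level (75–95%,
tolerance 1 percentage point). API is the mean over sequence pairs of
identical columns among mutually ungapped columns; simulated data are
gapless, so gap handling matters only for empirical inputs.

The full factorial design is 5 API levels × 11 DNR levels (0, 2, …, 20)
× 100 replicates = 5500 alignments, with a per-dataset seed derived
stably from the master seed. The default alignment length is 2000 sites
(the source study does not state one; 2000 keeps wRF variance low at
desk scale).

## Accuracy scoring

Inferred trees are compared to the truth with the weighted
Robinson-Foulds distance: both trees are unrooted (the two root edges
merge), and the distance sums |w₁ − w₂| over the union of bipartitions,
including pendant edges, with weight 0 where a split is absent. The
distance is unnormalized; wRF with unit weights equals the plain RF
symmetric-difference count on nontrivial splits. Unrooting is necessary
because non-reversible inference returns rooted trees while GTR inference
cannot place a root.

Per dataset, trees are inferred under GTR and NREV12 by NNI search from a
common neighbor-joining start (Jukes-Cantor distances, midpoint-rooted) —
a deliberately model-neutral common starting point. Per (API, DNR) cell a
two-sided paired t-test compares the models' wRF values (degenerate
all-zero differences give p = 1), and p-values are Holm-adjusted across
the DNR levels of each API panel (the adjustment method is recorded in
the output metadata so Bonferroni/BH can be swapped in).

## Problem sizes used in the shipped checks

The acceptance-style tests run the study end to end at sizes chosen to
keep the whole suite comfortably reproducible on a single CPU: parameter
recovery uses 10 replicates of 5000 sites on a 20-taxon tree; LRT
calibration uses 200 GTR replicates of 1000 sites on 10 taxa; the
accuracy trend uses 2 true trees (API ≈ 95% and ≈ 85%, 20 taxa as in the
default design), DNR ∈ {0, 8, 20}, 20 replicates of 1000 sites. At these
sizes the qualitative results — exact ladder DNR, calibrated type-I
error, wRF increasing with DNR, NREV12 no worse than GTR at extreme DNR
in the high-API panels — are stable; absolute wRF magnitudes depend on
the unpublished empirical true tree and are out of scope.

## What the synthetic data do not emulate

No indels (alignments are simulated gapless and assumed correct), no
heterotachy or branch-specific rate variation, no recombination, no
codon structure or selection. Passing tests therefore demonstrate the
correctness and calibration of the inference machinery under the stated
generating process, not robustness to alignment error or to model
violations beyond non-reversibility itself.

## Known limitations

* NNI search explores locally; for very poor starting trees an SPR/TBR
  search would be more robust.
* The NREV12 root position is inherited from the starting tree rather
  than optimized over placements, so the rooting information in
  non-reversible models is exploited only partially.
* AIC-c parameter counts include branch lengths; other conventions exist
  and would shift all models' scores by the same structure.
* DNR values are only comparable across datasets under a shared
  reference-rate convention.
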