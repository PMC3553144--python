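# Methods

This note records the models behind each stage, the defaults that
matter, what the synthetic generators do and do not emulate, and the
design choices made where the design was genuinely open.  Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sequence comparison

Global alignment is Needleman–Wunsch with affine gaps through
`Bio.Align.PairwiseAligner`, defaulting to BLOSUM62 with gap open 10.0
and gap extend 0.5 (the EMBOSS needle convention: a gap of length k
costs `open + (k−1)·extend`, terminal gaps included).  Identity and
similarity percentages are taken over the full alignment length
including gap columns; a substituted column counts as similar when its
matrix score is positive.  `X` is neutralized (score 0 against
everything) and never counts as identical — a conservative treatment of
unknown residues.  The homolog filter applies the family-survey rules
as stated: ungapped length strictly inside the per-subfamily window and
identity to the query strictly above the threshold (35% default).

PEST detection follows the Rogers–Wells–Rechsteiner formulation used by
ePESTfind.  Candidates are maximal stretches between positive residues
(K/R/H, or the termini) of length ≥ 12 containing at least one D/E, one
P and one S/T.  The score combines the mass percent of D/E/P/S/T —
after subtracting one equivalent each of (D or E), P and (S or T),
taking the heaviest residue of each kind present — with the
mole-fraction-weighted Kyte–Doolittle hydropathy rescaled to 0–90
(`hp = 10·KD + 45`): `score = 0.55·DEPST − 0.5·hydro`, valid at ≥ +5.
No installed package provides this scorer, so it is implemented here
and pinned by an independent in-test recomputation of the formula.

## Distances, neighbor joining, bootstrap

Protein Jukes–Cantor uses the 20-state correction
`d = −(19/20)·ln(1 − (20/19)p)` with pairwise deletion: for each pair,
only columns where both rows carry a standard residue (no gap, X or ?)
enter `p`.  Observed proportions at or beyond the 19/20 saturation
point are flagged and clamped to a ceiling (default 5.0
substitutions/site) rather than returning infinity, keeping bootstrap
replicates usable.  A pair with zero comparable columns is an error
naming the pair.

Neighbor joining is Saitou–Nei with the Studier–Keppler Q-criterion.
Ties in Q are broken by the first (i, j) pair in the current node
ordering, making the output deterministic; negative branch-length
estimates are clamped to zero with the deficit moved to the sibling
edge so that additive inputs are still reproduced exactly.  The
unrooted result is represented with a trifurcating root.  Bootstrap
supports resample columns with replacement from a single seeded
generator (indices drawn replicate-major), rebuild distance + NJ per
replicate, and attach to each internal edge of the point-estimate tree
the percentage of replicates containing its bipartition.  Replicates
that degenerate (e.g. a pair loses all comparable columns) are skipped
and counted.  Outgroup rooting bisects the subtending edge 50/50.

## Type I functional divergence

Between two disjoint monophyletic clusters (each ≥ 4 taxa), per-column
substitution counts on each cluster's subtree are obtained by Fitch
parsimony; gaps and X are excluded from leaf state sets, and a column
with no informative residue in a cluster is masked.  Parsimony
undercounts on long branches, so fitted rate scales are effective
(parsimony-visible) scales — this attenuates θ̂ on deep trees but does
not bias the null.

The estimator is the two-state rate mixture: with probability 1−θ a
site's rate λ is shared by the clusters, with probability θ each
cluster draws independently; λ ~ Gamma(α) with mean 1, and counts are
Poisson(λ·T_cluster).  Both marginals are negative binomial and the
shared-rate joint has a closed bivariate negative-binomial form, so the
log likelihood is exact and fast.  Free parameters (θ, α, T_A, T_B) are
fitted by L-BFGS-B on `[0, 1−10⁻⁶] × log[0.05, 50] × log[10⁻⁴, 100]²`
with random restarts.  **Pooled shape:** the gamma shape is shared
between clusters.  A shared/independent mixture with cluster-specific
shapes has no symmetric definition of the shared component, and
swapping the cluster labels must leave θ̂, the LRT and the candidate
sites unchanged — a contract the tests enforce — so pooling is the
coherent choice; the fitted shape is reported for both clusters.

Because θ = 0 lies on the boundary, the LRT reference is the 50:50
mixture of a point mass at zero and χ²(1); significance is declared at
p ≤ 0.05.  In finite samples this test is mildly conservative (more
than half the null LRTs are exactly zero), which the null-calibration
check quantifies.  The standard error of θ̂ comes from the curvature of
the profiled negative log likelihood in θ.  Per-site posteriors of
rate-shift membership follow from Bayes' rule at the fitted parameters;
candidate sites use the strict `posterior > 0.85` rule, optionally
mapped into a named reference row's ungapped numbering.

`sample_counts` draws directly from this generative model (the sampler
used for recovery and calibration experiments); the sequence-level
route (`simulate_family` → `fitch_counts` → `estimate_type1`) exercises
the same estimator under model mismatch.

## Type II functional divergence

The signal class is sites conserved within each cluster but fixed for
different residues between them.  Cluster consensuses are strict
majorities; ties exclude the column (logged).  The mixture has a
background class — shared gamma rate λ governing both the within-
cluster counts and, through `1 − exp(−λ·T_m)`, the chance of a
between-cluster consensus difference — and a divergent class whose
consensus difference is certain regardless of rate.  θ_II is the fitted
weight of the divergent class.  Each differing column receives the
posterior **odds ratio** of the divergent class against the background.
The conventional cut-off on this statistic (> 17) is an odds scale, not
a probability — a quantity above 1 cannot be a probability, and this
package documents it as odds.  Sites above the cut-off whose cluster
consensuses fall in different biochemical classes (+ = K/R/H,
− = D/E, hydrophobic = A/V/L/I/M/F/W, hydrophilic = the rest) are
reported as radical.

## Ka/Ks

Nei–Gojobori (1986) counting: per codon, each position contributes the
fraction of its three single-nucleotide changes that are synonymous
(changes to stops count as nonsynonymous), so synonymous +
nonsynonymous sites sum to 3 per codon.  Differences between codons
differing at k positions are averaged over all k! minimal pathways,
excluding pathways through stop codons (falling back to all pathways in
the rare case every one is blocked).  Both proportions get the
nucleotide Jukes–Cantor correction `d = −(3/4)·ln(1 − (4/3)p)`;
proportions ≥ 3/4 are saturated and reported NA, as is ω when Ks = 0.
Site-wise estimates pool the query row against every other row per
codon column; classes are purifying/neutral/positive with a ±0.1
neutral band around ω = 1.  Codon maximum-likelihood site models
(M8-type random effects) are deliberately out of scope: the counting
estimator answers the qualitative question — which regime — that the
pipeline consumes.

## Anisotropic network model

Cα nodes within 15 Å (inclusive, the conventional ARD cutoff) are
joined by springs of uniform constant γ = 1; kT = 1.  The off-diagonal
3×3 superblock for a connected pair is `−γ (r⊗r)/|r|²` with r the
equilibrium separation; diagonal superblocks enforce zero row sums.
Symmetry, translation invariance and positive semidefiniteness are
asserted on every build, and the spring network's connectivity is
checked explicitly (a disconnected network carries a warning and is
expected to show more than six near-zero modes).  The dense symmetric
eigendecomposition classifies eigenvalues below `10⁻⁸·λ_max` as
rigid-body — a scale-free tolerance — and requires exactly six on a
connected chain.  Mean-square fluctuations are
`msf_i = Σ_k |U_k[3i:3i+3]|²/λ_k` over non-rigid modes; with all modes
this equals the trace of the i-th diagonal superblock of the Hessian
pseudo-inverse, which the tests verify independently.  Theoretical
B-factors are `(8π²/3)·msf`, least-squares scaled onto the experimental
column, with the Pearson correlation reported (NA for a constant
column).

## Ensemble PCA and mode overlap

Heterogeneous structures are matched to a reference (first structure
unless named) through global sequence alignment; members matching under
40% of reference positions are excluded, and reference positions
observed in fewer than 90% of members are dropped ensemble-wide, the
remaining holes being masked and imputed from the per-position observed
mean — imputation from the mean adds no covariance, which keeps the
spectrum honest without inventing geometry.  Iterative superposition
alternates Kabsch fits (proper rotations; reflection case
sign-corrected) onto the running mean until the mean moves less than
10⁻⁵ Å (at most 100 iterations), recording per-member RMSD to the mean.
PCA eigendecomposes the covariance of flattened coordinate deviations
(divisor M−1); fractions are λ_i/Σλ and conformer projections are the
deviation dot products.  Mode overlap against an ANM mode set is the
absolute cosine of unit eigenvectors (eigenvector sign is arbitrary);
the projection correlation is the Pearson correlation, over conformers,
of scores along the paired axes.  Group structure in (PC1, PC2) is
summarized by centroids, spreads and a silhouette score
(scikit-learn).

## Synthetic generators: what they emulate, and what not

`make_ankyrin_calpha` builds an ideal-geometry repeat stack: two
antiparallel helical segments per repeat (rise 1.5 Å/residue,
100°/residue, radius 2.3 Å) joined by arc-shaped turns and finger
loops placed so consecutive Cα distances stay near 3.8 Å, repeats
translated 10 Å along the stacking axis.  It reproduces the topology
and connectivity that the ANM needs — not real side-chain packing,
repeat irregularity or sequence-structure correlation.  ANM/PCA results
on it validate the linear algebra and the mode machinery, not claims
about any particular protein.

`make_ensemble` displaces the base chain along q orthonormal 3N
directions with chosen variances plus small isotropic jitter
(σ = 0.01 Å by default, kept well below the planted standard
deviations so the planted subspace dominates the spectrum, as the
generator's contract requires), optionally scrambling members by random
rigid transforms that superposition must remove.  Random directions are
drawn orthogonal to the rigid-body subspace so planted variance cannot
leak into (and be consumed by) the superposition step.

`simulate_family` evolves sites independently down a known tree under a
Poisson equal-exchangeability model with Gamma(α) site rates (mean 1);
a planted fraction θ of sites draws an independent, `shift_factor`-
scaled rate inside one clade (stem included).  This realizes exactly
the rate-decoupling structure the type I estimator models — by design,
so recovery is interpretable — and omits exchangeability structure,
indels and alignment error; gap handling is therefore tested with
hand-made fixtures, and passing recovery tests demonstrates estimator
correctness under the stated model, not robustness to misalignment.
Amino-acid exchangeabilities (JTT and kin) are deliberately absent: the
divergence estimator models rates, not exchangeabilities, and the
pipeline's distance stage is likewise exchangeability-free.

`simulate_codons` is GY94-like over the 61 sense codons with uniform
frequencies and per-site ω; transition/transversion ratio κ defaults to
1, the minimal model under which ω is identifiable for a counting
estimator that assumes unbiased mutation (NG86 is known to be biased
under strong transition bias, and κ is exposed for studying exactly
that).  Each generator's rate matrix is normalized to one expected
substitution per unit branch length.  Calibration runs use a balanced
8-taxon tree with branches of 0.15 substitutions/codon and 300 codons —
moderate, unsaturated divergence.

Study-condition sizes used by the tests and the acceptance script:
type I recovery at α = 0.5, L = 1000, cluster scales T = 2.0
substitutions/site (a realistic within-subfamily subtree length), 20
seeds per planted θ; null calibration at L = 500 over 200 simulations;
NJ recovery on 8-taxon trees with branches 0.02–0.1 at L = 2000 over 20
replicates; PCA recovery at M = 200/500 on a 66-residue chain.  These
sizes make every check run in seconds to a couple of minutes while
leaving the estimators' asymptotic behavior visible.

## Numerical choices and degenerate inputs

- Likelihood optimizations work in log-parameters with explicit bounds
  and random restarts; an alternative fit that lands below its own null
  is replaced by the null (LRT 0) rather than reported negative.
- Mixture site likelihoods are combined with `logaddexp`; the type II
  background probability of a consensus difference uses a clipped
  `log1p(−exp(·))` to stay finite for extreme parameters.
- Zero-length branches are legal everywhere (they simply transmit the
  parent state); zero distances in NJ resolve by the deterministic
  tie-break, so topologies among identical taxa are arbitrary but
  reproducible.
- PDB coordinates round-trip at the format's 10⁻³ Å precision; residues
  with missing CA are skipped and counted, duplicate (chain, resseq) CA
  records are an error.
- `-0.0` branch lengths are normalized on Newick output so write→read→
  write is bit-identical.

## Known limitations

- Fitch counting underestimates multiple hits; θ̂ from deep-tree
  sequence data is attenuated relative to the generative-model route.
  The boundary LRT is finite-sample conservative.
- The type II mixture is a deliberately small model (one between-
  cluster divergence scale); it ranks sites and calibrates the odds
  cut-off but is not a full codon- or ancestor-aware reconstruction.
- NG86 counting cannot reproduce site calls from random-effects codon
  ML; it targets regime-level conclusions.
- Ensemble PCA imputes masked coordinates from the mean, which shrinks
  the apparent variance of poorly covered positions.
- The Bayesian tree inference, MSA construction, homology modelling and
  molecular-dynamics stages of the wider workflow this package mirrors
  are intentionally out of scope; trees and alignments are consumed as
  inputs.
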