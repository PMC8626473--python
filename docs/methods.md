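# Methods

This note documents the models, estimators, and design choices behind each
stage of the pipeline, and what the synthetic-data tests do and do not show
about real data.

## Coalescent model and units

All simulation time is in coalescent units (2N generations).  Within a
species-tree branch carrying k gene lineages, the waiting time to the next
coalescence is Exponential with rate k(k−1)/2 and a uniformly chosen pair
merges; lineages remaining at the root coalesce in an unbounded ancestral
branch.  On a network, each lineage reaching a reticulate node follows a
parent edge independently with that edge's inheritance probability γ; the
degenerate values γ ∈ {0, 1} are accepted and routed deterministically
(without consuming a random draw), so a γ = 1 network reproduces, draw for
draw, the tree obtained by deleting the unused edge.  Emitted branch
lengths are durations × `mutation_scale` (default 1.0, i.e. coalescent
units); the classifier and the mixture test are scale-equivariant, so this
choice affects only the interpretation of λ̂.

For a rooted triplet with internal branch t, the probability that a gene
tree is discordant is (2/3)e^(−t), split equally between the two minor
resolutions — the closed form the simulator is tested against at
30,000 trees per branch length.

## Topology census

Classification is by *diagnostic clade presence*, not by requiring every
focal group to be monophyletic: a tree is Type I/II/III when it contains a
clade comprising exactly the tips of the corresponding two focal groups
(after pruning away all species outside the three groups).  Group monophyly
is reported as a separate per-type statistic.  The three diagnostic tip
sets pairwise intersect without nesting, so at most one can be a clade of
any tree (clades form a laminar family); the code asserts this on every
tree it classifies.

The bootstrap filter applies to the single branch subtending the diagnostic
clade.  Two conventions required a decision:

* when pruning merges a path of edges, the merged edge carries the minimum
  of the non-missing supports along the path (conservative);
* a diagnostic branch with *no* support value passes the filter, so
  topology-only trees remain classifiable (simulated supports default to
  100, which keeps the filter inert on synthetic data).

Trees missing the outgroup or a focal group are skipped with a logged
warning in batch mode.  Gene trees are rooted by the outgroup before
classification: on the edge separating outgroup from ingroup tips when the
outgroup is monophyletic, otherwise on the edge maximizing the separation,
with the result flagged `outgroup_non_monophyletic`.

The chromosome homogeneity check is a Pearson chi-square test (no
continuity correction) on the type × chromosome contingency table, with
empty categories dropped.

## Triplet exponential-mixture test

Observations are internal branch lengths of gene-tree triplets, obtained by
restricting each rooted tree to three species (multi-copy species are
represented by the copy with the smallest total nodal distance to the other
two species' tips).  For each triplet × topology:

* one-component model: f₁(t) = (1/λ)e^(−t/λ);
* two-component model: π(1/λ)e^(−(t−K)/λ)·[t ≥ K] + (1−π)(1/λ)e^(−t/λ),
  with a shared λ (the standard assumption for this family of tests).

K is profiled on a 200-point grid from 0 to the 99th percentile of the
data, with EM on (π, λ) at each K.  Because the two components share λ, the
likelihood ratio between them is the constant e^(K/λ) for every t ≥ K, so
the E-step collapses to prefix sums and each EM iteration costs O(1) per
grid point after sorting — the full profile is a handful of vectorized
array operations.  Initialization uses five spread starting weights
π₀ ∈ {0.1, 0.3, 0.5, 0.7, 0.9}; with a closed-form M-step and a smooth
profiled likelihood these deterministic starts dominate random restarts and
keep the fit fully reproducible.  The grid includes K = 0, where the
mixture collapses to the exponential, which guarantees logL₂ ≥ logL₁.

Model choice uses BIC₁ = −2logL₁ + ln N against BIC₂ = −2logL₂ + 3 ln N and
calls "mixture" when ΔBIC = BIC₁ − BIC₂ > 10.  At N = 500 this threshold
demands a log-likelihood gain of about 11, so the type-I error under pure
exponential data is far below the 5% bound the calibration suite checks.
Fits require N ≥ 20 observations.

The subsampling protocol repeats the fits on runs of `trees_per_run` trees
sampled without replacement (defaults 100 × 500, matching large-scale
practice; per-run sub-seeds derive from the master seed).  Only *discordant*
topologies — those uniting a species pair that is not a cherry of the
species tree for that triplet — probe hybridization.  The literature
reports an "average ILS/hybridization ratio" without a formula, so the
aggregation here is defined explicitly: each fit contributes a non-ILS rate
of π̂ when called mixture and 0 otherwise; the per-pair rate is the mean
over runs × triplets, and a pair is flagged when it exceeds 0.1.  Both the
raw π̂ and the ratio (1−π̂)/π̂ of called fits are emitted.

## ABBA-BABA D-statistic

Counting is at the haploid genotype level (one 0/1 derived-allele code per
taxon per site), the error-free equivalent of read-sampling estimators;
sites with a derived outgroup allele or non-biallelic codes are skipped.
D = (ΣnABBA − ΣnBABA)/(ΣnABBA + ΣnBABA); the SE is the delete-one block
jackknife SE = sqrt((m−1)/m · Σ(D₍ᵢ₎ − D̄)²) over m blocks, and |Z| > 3 is
the default call (configurable).  Blocks are fixed site-count windows for
simulated (unlinked) sites; real-coordinate blocking can be supplied via a
precomputed block table.  The quartet-conformity filter marks results whose
(((P1,P2),P3),O) arrangement contradicts the species tree.

The site simulator draws one genealogy per unlinked site under the 4-taxon
MSC, with probability γ that the P2 lineage jumps into P3's branch at the
introgression time (default: half the P1–P2 split height) — a single pulse,
matching the pulse interpretation of D.  One mutation is placed uniformly
on the genealogy (infinite sites), so the ABBA (BABA) probability of a site
is the relative length of the branch subtending exactly {P2,P3} ({P1,P3}).
The per-site sampler is numba-compiled, which is what makes the
1,000-replicate null calibration (200 blocks × 250 sites each) affordable.

## Node-weighted Ks and age dating

A family of n paralogs yields n(n−1)/2 pairwise Ks estimates for n−1
duplication events.  Given the family tree, every internal node with child
clades L and R contributes its m = |L|·|R| cross-pairs at weight 1/m, so
the weights of each duplication node sum to exactly 1 and a family
contributes total weight n−1 — both enforced as exact invariants in the
test suite.  Families outside 1 < n < 5 are rejected (the low-copy filter
that keeps redundancy manageable).

When no family tree is supplied, one is built by UPGMA on the pairwise Ks
matrix with deterministic lexicographic tie-breaking — Ks is approximately
ultrametric across duplication nodes and family size ≤ 4 bounds the
topology risk; callers may supply their own trees.

Pairwise Ks uses Nei–Gojobori (1986) counting: per-codon synonymous site
fractions averaged over both sequences, synonymous/nonsynonymous
differences averaged with equal weight over mutational pathways (pathways
through stop codons are excluded; changes *to* stop codons count as
nonsynonymous), Jukes–Cantor correction Ks = −(3/4)ln(1 − (4/3)pS), and a
saturation guard at pS ≥ 0.75.  This counting estimator is a deliberate
design choice over maximum-likelihood codon models: it is exact,
dependency-free, and adequate for peak location, though it is known to run
slightly below ML estimates at high divergence.

The peak is the argmax of a weighted Gaussian KDE (Silverman bandwidth on
the weighted sample by default) on a 0.005 grid over (0.05, 2.0]; the lower
cut excludes the allelic/recent-duplicate spike, and multiple local maxima
trigger a warning.  Ages follow T = K/(2r) with
r = 1.51 × 10⁻⁹ substitutions/site/year by default (a magnoliid-calibrated
rate); the same equation dates LTR insertions from 5'/3' terminal-repeat
divergence.  Converting a Ks peak into an absolute WGD age inherits the
full uncertainty of r and of rate variation across lineages; no
cross-lineage calibration or confidence interval is attempted here.

## Synthetic-data generators

* **Gene trees** — network MSC as above; simulated supports default to a
  constant 100 (optionally 100·Beta(a,b) noise).
* **Site patterns** — 4-taxon MSC with a pulse introgression edge,
  infinite-sites mutation, fixed-size blocks.
* **Ks families** — sizes drawn from {2, 3, 4} with probabilities
  (0.5, 0.3, 0.2) (curated low-copy sets are dominated by small families;
  chosen once, not tuned); random rooted topologies by sequential pair
  merging; each duplication node is WGD-derived with probability
  `wgd_fraction` (true Ks = `wgd_ks`) or background with true Ks ~
  Uniform(0.05, 2.0); node ages are sorted so deeper nodes carry larger Ks;
  observed values multiply the truth by LogNormal(0, σ) noise.  Families
  retain their true trees and true Ks for oracle tests.
* **LTR divergences** — Normal(burst, sd) truncated at zero.

What these generators do *not* emulate: sequence-level evolution (no
alignment error, no rate variation among sites or lineages), linkage within
loci, gene-tree estimation error beyond the optional support noise,
multiple overlapping WGD cohorts, and fractionation bias.  Passing tests
therefore demonstrate correctness of the estimators under their stated
models, not robustness to the full error structure of genome data.

## False-positive control

Replicates simulate gene trees under a reticulation-free species tree and
re-run the triplet protocol (and optionally the census); the control passes
when ≥ 90% of replicates produce no hybridization flag among the focal
pairs.  "Flag-free" is judged on the triplet test — the D-statistic's null
behavior is calibrated separately in its own suite.  The report also pools
the two minor census types across replicates and tests their symmetry
(exact binomial against 1/2), the prediction whose violation on real data
argues against ILS as the sole cause of discordance.  Analyses are per
replicate; pooling a single resample across replicates would only shrink
the variance of an already-null quantity.

## Problem sizes and defaults

The built-in 18-taxon example tree places deep within-clade splits and a
single 0.3-coalescent-unit branch at the contentious node, yielding ~45%
typed trees and near-symmetric minor types under ILS.  The end-to-end
control in the test suite runs 10 replicates of 500 trees with 3 protocol
runs of 400 trees over 8 clade representatives — sizes chosen so the whole
suite, including the 1,000-replicate D-statistic calibration and the
30,000-tree closed-form checks, completes in a few minutes; the protocol
defaults themselves remain 100 runs × 500 trees.  All randomness descends
from one master seed through named SHA-256 sub-streams, so adding a stage
never perturbs another stage's draws and every artifact is byte-for-byte
reproducible.

## Known limitations

* The triplet test's per-pair aggregation is one reasonable formalization
  of a verbally-described statistic; alternative weightings across triplets
  would change the numeric rate (not the calls on clear signals).
* NG86 Ks saturates near pS = 0.75 and is refused there rather than
  extrapolated.
* Diffuse introgression (low γ, short donor-sharing window) produces small
  shifts K that the ΔBIC > 10 rule will not call at moderate N — the rule
  is deliberately conservative, trading power for a controlled false-call
  rate.
* The D-statistic implementation targets haploid genotype input; population
  allele frequencies and genotype likelihoods are out of scope.
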