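# Methods

## Overview

`parsimotif` infers transcription-factor binding motifs de novo from sets of
unaligned DNA sequences (e.g. ChIP-seq peak sequences) using inhomogeneous
parsimonious Markov models (PMMs). The central modeling question is how much
intra-motif dependency — a base's distribution depending on the preceding one to
four bases — the data actually support, and the central algorithmic problem is
performing that model selection while the binding-site locations themselves are
unobserved.

## The motif model

A motif of width W assigns position ℓ a conditional distribution over {A,C,G,T}
given up to d preceding bases *within the site*. Instead of the 4^d parameter
vectors of a full inhomogeneous Markov model, each position carries a
*parsimonious context tree* (PCT): a rooted balanced tree of depth d whose non-root
nodes are labeled by non-empty subsets of the alphabet, the children of any node
partitioning it. Each leaf's root path defines a *context* — a subset of the 4^d
context strings — and all strings in one context share one probability vector. The
PCT space interpolates between the PWM (one all-merging context per position) and
the full order-d Markov model (4^d singleton contexts). The first d−1 positions of
the motif have no full context inside the site; they use the effective order
min(d, ℓ−1), the standard convention for inhomogeneous Markov models.

Positions ℓ count their context toward offsets −1 … −d: the children of the PCT
root condition on the directly preceding base, the deepest level on the base d
positions back. Context strings are encoded base-4 big-endian with the proximal
base as the least significant digit; all count tables, leaf-index maps, and
likelihood scans share this encoding.

## Structure learning and parameter estimation

Given aligned sites, the PCT at each position is chosen by exact maximization of
the BIC structure score

    S_BIC(τ) = Σ_{c∈τ} Σ_a N_ca ln(N_ca / N_c·) − ½ |τ| (|𝒜|−1) ln N,

with natural logarithms (scores are therefore base-dependent; they are only ever
compared to each other). Cells with N_ca = 0 contribute nothing; an empty context
contributes nothing to the likelihood but its leaf still counts in the penalty —
the structure spends those parameters regardless of whether data reach them. The
score is a per-leaf sum, which the maximizer exploits: a bottom-up recursion
reduces the count table along each candidate subset label, solves the subtree
below it, and selects the children of every node by maximizing over all 15 set
partitions of the alphabet. For d ≤ 4 over DNA this is exact and fast; correctness
is defined (and tested) as agreement with brute-force enumeration of all
structures on instances small enough to enumerate (15 structures at d=1 over four
symbols; 6 at d=2 over two; 205 at d=2 over three). Score ties are broken toward
fewer leaves, then by canonical ordering of the subset partition, so results are
reproducible and parsimonious.

Conditional probabilities are estimated per context by the factorized sequential
normalized maximum likelihood (fsNML) estimator

    θ_a = e(N_a)(N_a+1) / Σ_b e(N_b)(N_b+1),   e(N) = ((N+1)/N)^N, e(0) = 1,

which is hyperparameter-free, strictly positive, and reduces to the uniform
distribution on empty counts. e(N) is evaluated in log space (N·ln(1+1/N)) so
large counts cannot overflow. An order-0 model is exactly a PWM with
fsNML-smoothed columns, which the tests verify as a likelihood identity.

## The latent-variable model and discovery algorithm

Sequences follow the one-occurrence-per-sequence (OOPS) model: exactly one motif
instance per sequence at unknown start v and strand s, flanked by a homogeneous
Markov model (order 2 by default — enough to absorb mono- and dinucleotide repeat
structure that otherwise distracts discovery). Conditional on (v, s) the sequence
likelihood factorizes into prefix flank, motif window (reverse-complemented for
the reverse strand), and suffix flank; each flanking segment is scored from a
fresh start with its own initial distributions, exactly matching that
factorization — nothing is conditioned across the motif boundary. Priors over v
and s are uniform, the standard OOPS choice; they make the strand-marginalized
joint P(x, v) well defined, and the tests verify by brute-force enumeration over
all 4^L sequences that the resulting marginal distribution normalizes exactly.

Discovery seeks the latent configuration whose extracted site set maximizes the
summed per-position BIC score. The search is a stochastic EM variant:

1. initialize (v, s) uniformly at random;
2. refit the motif *exactly* from the current sites (BIC-optimal PCTs, fsNML
   parameters) and record the structure score;
3. resample (v, s) per sequence from the categorical distribution proportional to
   the conditional sequence likelihood over all (position, strand) pairs,
   normalized in log space;
4. repeat from 2.

The loop order (init → fit → {resample → refit}) is fixed here as a design
choice. Each of R restarts runs at least T iterations and terminates only after
T′ consecutive iterations without score improvement (absolute tolerance 1e−9);
defaults are T=50, T′=10, R=10. The best (score, latents) pair across all
iterations and restarts is kept, and the final model is refit from those latents,
so the returned score always equals an independent recomputation from the
returned latents. The flanking model is estimated once before the loop and held
fixed: the objective involves only the motif's structure score, and under a fixed
flanking model the per-sequence sampling distribution is proportional to the
motif-versus-background ratio, so sampling from the full conditional likelihood
and sampling from that ratio are the same operation. One master seed drives
per-restart child streams (`SeedSequence(seed, spawn_key=(r,))`), making runs
reproducible and restart-count-extensible without reshuffling earlier restarts.

In synthetic experiments the chain typically spends tens of iterations on a
diffuse plateau before locking onto a planted motif, which is why the minimum
iteration count matters more than the patience; R=10 restarts make the overall
failure probability small, and the best-score selection reliably picks a
locked-on restart because its score is far above the plateau.

## Binding-site prediction

The strand-marginalized joint is computed for every window of every sequence by a
vectorized scan (cumulative fresh-start prefix scores, suffix scores with per-
start initial-distribution corrections, and per-position context-code lookups;
the reverse strand reuses the forward scan on the reverse complement). Scanning
the negative set gives an empirical null; the threshold Z is the smallest scanned
value such that at most a fraction α = 10⁻⁴ of negative windows score strictly
above it. This is deliberately read as an upper-tail criterion — the negatives
set the significance level — because the literal lower-quantile reading would
call essentially every window; the direction is nevertheless a configuration
switch. No interpolation between list values is used, and the rule guarantees by
construction that on background the expected called fraction is ≤ α. Predicted
windows are annotated with the argmax strand (the joint itself is strand-
marginalized) purely so that the output forms an orientation-aligned site set for
logos and demixing; overlapping windows are all reported.

## Multiple-motif detection

A dependency-aware model can absorb two co-occurring motifs into one. Predicted
site sets are therefore clustered with a two-component PWM mixture (EM: 20 random
Dirichlet initializations, log-likelihood tolerance 1e−6, pseudocount 0.1 in
M-steps — the clustering backend is standard machinery, and these settings are
package choices, all configurable). The weighted Jensen–Shannon divergence
between the component columns, summed over positions and averaged over the
predictions of orders 1–4, quantifies how different the two clusters are; below
0.18 the set is categorized as one motif (A), otherwise as a putative mixture
(B), with the boundary assigned to B. Natural logs are used, so one column
contributes at most ln 2 ≈ 0.693.

The 0.18 operating point is scale-dependent: a maximum-likelihood two-component
fit always splits finite single-motif data somewhat, and that noise-driven
aggregate JSD decays roughly like W/N. It falls safely below 0.18 only once the
site set reaches the scale of real predicted binding-site collections (thousands
of sites); the separation suite therefore exercises the single-motif case at
N = 5000. Small site sets inflate the statistic and should not be categorized
with this threshold.

## Fragment-based classification

Motif models are compared without ground-truth site locations by a two-class
generative classifier: the OOPS model (flanking part fit on training positives
plus negatives, motif found by discovery on training positives) against the
flanking model alone. Test fragments are scored by the log-likelihood ratio, with
the OOPS side marginalizing over (v, s); a max-over-windows variant is available
as a flag. Ten-fold cross-validation (positives and negatives split
independently) yields per-fold AUCs, the improvement score
Ψ_d = log₂((1−AUC₀)/(1−AUC_d)), and pairwise two-sided Wilcoxon signed-rank
p-values across orders. AUC uses the rank statistic with ties counted one half
(delegated to scikit-learn and cross-checked in tests against a brute-force
pairwise count); the signed-rank test is delegated to SciPy.

## Synthetic benchmarks

The generator emulates the structure of a ChIP-seq study: N positive sequences of
length L, each a homogeneous Markov background (order 2 by default, uniform
conditionals unless a background model is supplied) with exactly one motif
instance planted at a uniform start, reverse-complemented with probability 0.5;
negatives are pure background at two per positive, length-matched. Defaults are
N=200, L=100. Two presets cover the regimes the package targets: `strong_pwm`, a
width-8 order-0 motif with probability 0.9 on a fixed consensus (TGACGTCA — note
this consensus is its own reverse complement, so strand is deliberately
unidentifiable and recovery is judged on positions); and `order2`, a width-8
motif with an anchored start and near-deterministic second-order conditionals
(probability 0.85 on a base determined by the two preceding ones), whose marginal
column frequencies are far less informative than its conditionals — exactly the
regime where dependency-aware models should win, which the classification suite
confirms in direction.

What the generator does *not* emulate: peak-calling artifacts, positional bias of
sites toward peak centers, sequence composition heterogeneity, repeats, or
multiple/zero occurrences per sequence. Passing recovery tests therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not performance on real ChIP-seq data.

## Problem sizes and numerical choices

Test-suite study sizes were chosen so the whole suite exercises every claim at
realistic-but-small scale: localization uses the default benchmark (N=200, L=100,
W=8) with the default discovery settings; the order-comparison study uses N=200,
L=60 with a reduced discovery budget (T=50, T′=10, R=4) per fold, which suffices
for reliable locking on the anchored order-2 motif. All likelihood work is done
in log space with log-sum-exp for strand mixing; count tables are exact integers;
fsNML and flanking conditionals are strictly positive by construction, so no
likelihood is ever −∞ for valid DNA input.

## Known limitations

- Exact PCT maximization enumerates the 15 set partitions per node; it is exact
  for DNA up to d≈4 but not intended for large alphabets.
- The OOPS assumption is taken at face value: sequences without a site, or with
  several, are still assigned exactly one.
- The demixing threshold 0.18 is a fixed operating point on the aggregate JSD
  scale for width-20 motifs; site sets at the borderline (e.g. motifs with a
  common variable-length core) can fall on either side.
- Discovery optimizes a stochastic search over an intractable discrete space;
  with too small a restart or iteration budget it can return a locally optimal
  alignment of background, recognizable by a structure score far below typical
  locked-on values.
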