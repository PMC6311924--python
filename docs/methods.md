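# Methods

## Model

`bermix` models a case-control microbiome study as a finite mixture in which
an unobserved sample group drives both community composition and disease
status. For sample *n* with taxon counts *w<sub>n</sub>* (totals
*M<sub>n</sub>* over *K* taxa) and binary label *y<sub>n</sub>*:

* *z<sub>n</sub>* ~ Multinomial(1, φ) — the latent cluster, mixing weights
  φ on the *L*-simplex;
* *y<sub>n</sub>* | *z<sub>n</sub>=l* ~ Bernoulli(ρ<sub>l</sub>) — each
  cluster has its own disease risk;
* *w<sub>n</sub>* | *z<sub>n</sub>=l* ~ Multinomial(M<sub>n</sub>,
  p<sub>l</sub>) — each cluster has its own composition row
  p<sub>l</sub> on the *K*-simplex;
* p<sub>l</sub> ~ Dirichlet(α, …, α), a symmetric prior written throughout
  as the offset γ = α − 1 ≥ 0.

The complete-data joint factorizes over samples, and every quantity the
package computes — responsibilities, disease probabilities, hard labels —
is a ratio of such joints, so the multinomial coefficient
M<sub>n</sub>!/∏<sub>k</sub>w<sub>nk</sub>! is dropped everywhere and
objective values are reported up to an additive constant.

Compared with per-taxon tests or zero-inflation approaches, the mixture
attributes excess zeros and taxon co-occurrence to between-group
heterogeneity: a taxon can be structurally absent in one community type and
abundant in another without any per-taxon zero machinery. The Dirichlet
offset γ acts as a pseudo-count inside the M-step rather than on the raw
data, so a taxon unobserved in a cluster keeps a small positive appearance
probability and new samples containing it are not assigned probability zero.

## Estimation: annealed EM

Parameters (φ, ρ, P) are MAP-estimated by expectation–maximization with
deterministic annealing. At inverse temperature β ∈ (0, 1] the E-step
computes tempered responsibilities z<sub>nl</sub> ∝ f(y<sub>n</sub>,
w<sub>n</sub>, l)<sup>β</sup> (log-domain, max-shifted exponentiation); the
M-step is in closed form:

* φ<sub>l</sub> = (1/N) Σ<sub>n</sub> z<sub>nl</sub>
* ρ<sub>l</sub> = Σ<sub>n</sub> z<sub>nl</sub> y<sub>n</sub> /
  Σ<sub>n</sub> z<sub>nl</sub>
* p<sub>lk</sub> = (Σ<sub>n</sub> z<sub>nl</sub> w<sub>nk</sub> + γ) /
  (Σ<sub>n</sub> z<sub>nl</sub> M<sub>n</sub> + Kγ)

With γ = 0 the composition update is the weighted-count maximum-likelihood
ratio. β is stepped up a ladder ending at exactly 1, where the updates are
standard EM; at each rung the free energy β·(expected complete-data log
posterior) + entropy is monotone over sweeps and is used for convergence
(relative change below `inner_tol`, default 1e-8, or 500 sweeps).

**Annealing ladder.** The default ladder is geometric:
{0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0}. The scale matters: per-cluster
log-likelihood differences grow linearly in the read depth, so at
M<sub>n</sub> ≈ 10⁴ they are O(10³–10⁴) nats and any β ≳ 0.1 already yields
effectively hard assignments — a ladder confined to high β performs no
smoothing and inherits plain EM's local optima (in our recovery experiments
it merged clusters in roughly a third of replicates). Starting three decades
down restores genuine annealing; starting much lower (β ≈ 10⁻⁵) is harmful,
because a near-uniform posterior erases the initial symmetry breaking and
the mixture can freeze in a collapsed state. Users fitting shallow data
(M<sub>n</sub> in the tens) can pass a higher-starting ladder via
`AnnealingSchedule(betas=...)`.

**Initialization and restarts.** Initial responsibilities are flat-Dirichlet
draws per sample (seeded; drawn in sample-id-sorted order and scattered
back, so the fit is invariant to row order), followed by one M-step.
`n_restarts` independent runs are performed and the best final objective
wins, ties to the earliest restart; the default is 5, although with proper
annealing restarts rarely disagree. An optional k-means-style warm start was
evaluated and gave no improvement over the annealed random start.

**Degeneracies.** Risks are clipped to [1e-12, 1−1e-12] before logs (the
M-step yields exact 0/1 in small pure clusters). Empty clusters
(Σ<sub>n</sub> z<sub>nl</sub> = 0) get ρ<sub>l</sub> = overall prevalence;
with γ = 0 their composition row is re-seeded from the pooled composition
and φ floored at 1/N, with a warning. Responsibilities below 1e-250 are
flushed to exact zeros (denormal weights otherwise combine with mixing
weights that underflow to exactly zero and produce −∞ objectives). A sample
with zero probability under every cluster raises an error naming the sample
rather than emitting NaN.

**Label switching.** Fitted clusters are always relabeled so ρ̂ is
non-decreasing; cluster 1 is the lowest-risk group by convention.

## Prediction

For a count vector *w*, the disease probability is the posterior
ρ̃ = Σ<sub>l</sub> r<sub>l</sub> ρ̂<sub>l</sub> with label-free weights
r<sub>l</sub> ∝ φ̂<sub>l</sub> ∏<sub>k</sub> p̂<sub>lk</sub><sup>w_k</sup>
— a convex combination of cluster risks, never using an observed label.
Hard assignment takes the argmax of the posterior responsibilities, either
conditioning on the observed label (in-sample classification) or
marginalizing it (new samples); ties break to the lowest index.

## Choosing L

Repeated stratified K-fold cross-validation (default 10 folds) scores each
candidate L by the held-out log-loss
−Σ<sub>j</sub>[y<sub>j</sub> log ρ̃<sub>j</sub> +
(1−y<sub>j</sub>) log(1−ρ̃<sub>j</sub>)], with probabilities clipped at
1e-12. Per-fold sums are divided by the fold size so folds of unequal size
are comparable (raw sums are stored too); the mean and standard error are
taken over all repeat × fold values, and the L with the smallest mean wins.
Ties are assessed with a small numerical tolerance (1e-9 relative): when
superfluous clusters collapse into exact duplicates the per-L losses agree
to float precision, and parsimony rather than rounding noise should decide.
Single CV passes are noisy — the mean loss differences between candidate L
values are often far smaller than one fold's spread — so `n_repeats`
(default 20) independent fold assignments are averaged; raise it when the
loss curve is flat. A fold whose fit fails is recorded and skipped; at
least 80% of folds must succeed for an L to be eligible.

The held-out loss is a prediction criterion, not a clustering criterion: an
extra cluster that duplicates an existing one leaves predictions unchanged,
so the criterion is flat (not increasing) beyond the true L, and in finite
samples an extra cluster can eke out a genuinely lower held-out loss by
absorbing realized heterogeneity. Selection toward slightly larger L is
therefore an inherent feature of log-loss CV at high separation, and
neighbouring values of the selected L should be inspected.

## Synthetic data and the recovery study

`simulate.generate` draws datasets exactly from the generative model;
composition rows come from a symmetric Dirichlet(α) with α = 1 by default
(the flat case). The canonical recovery configuration
(`default_study_config`) uses N = 700 samples, M<sub>n</sub> = 10 000 reads,
L = 7 equally likely clusters with risks 0.3, 0.4, …, 0.9, γ = 10⁻⁹, and
K = 20 taxa. K is a free knob: separability — and with it the
classification accuracy below — depends on it, since the taxon count and
the Dirichlet concentration control how distinct two random composition
rows are.

`run_simulation_study` generates replicates, fits each at the true L (two
restarts in the harness; annealing makes more redundant), sorts clusters by
estimated risk, and tabulates the mean and across-replicate standard
deviation of ρ̂ and φ̂ per cluster, the mean hard-classification accuracy,
and true-vs-estimated composition pairs. The default is 200 replicates; the
study table is insensitive to raising it further. Two alignment conventions
are exposed: the risk-ascending convention (default) compares cluster
labels after sorting both sides by risk, so two clusters whose *estimated*
risks swap order count as misclassified even when the partition is correct;
best-permutation (Hungarian) alignment is immune to such swaps. At the
canonical configuration the fitted partitions are essentially exact
(best-permutation accuracy ≈ 1.0) and the risk-aligned accuracy ≈ 0.89
reflects adjacent-risk order swaps, whose rate is set by the risk spacing
(0.1) relative to the sampling error of ρ̂ (≈ 0.03–0.05 at ~100 samples per
cluster). Composition scatter pairs are matched by partition overlap
(Hungarian on the confusion matrix) so order swaps do not scramble them;
their correlation with the truth exceeds 0.99.

What the generator does *not* emulate: overdispersion beyond multinomial
sampling, zero inflation, covariates, compositional correlations between
clusters, or uneven read depth (unless a per-sample M vector is supplied).
Passing recovery tests on this generator shows the estimator inverts its
own generative model — it does not certify performance on real microbiome
data, where the model is at best an approximation.

## Numerical and design choices

* All likelihood math in natural logs; responsibilities via max-shifted
  log-sum-exp (raw products underflow at M<sub>n</sub> = 10⁴).
* Internal indexing is 0-based; user-facing cluster labels are 1-based.
* γ defaults to 10⁻⁹ (weakly informative prior) in the CLI and study
  harness.
* CV folds are stratified by label by default (preserves the case/control
  ratio in small folds), with seeded shuffling; fold seeds are derived
  deterministically from the user seed so identical runs are bit-identical.
* Parameter files are JSON at full float precision; tables are TSV.
* BIOM ingestion is out of scope; convert to TSV/CSV upstream.

## Limitations

* Single symmetric Dirichlet offset γ; no asymmetric priors and no
  data-driven γ estimation.
* No acceleration for very large N × K (the E-step is a dense N × L
  matrix product per sweep).
* The CV criterion selects for label prediction, not cluster recovery; see
  above.
* Real 16S/metagenomic preprocessing (OTU picking, taxonomy mapping) is
  upstream of this package.
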