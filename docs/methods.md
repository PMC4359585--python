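# Methods

## Model

Each microbiome sample n is a bag of N_n tokens, one per observed sequence
read of an OTU. A token carries three coupled draws: a factor assignment
X ~ Categorical(pi_n), an assemblage assignment Z ~ Categorical(theta_X) and
the observed OTU W ~ Categorical(phi_Z). The mixture rows carry symmetric
Dirichlet priors with concentrations alpha_pi, alpha_theta, alpha_phi.
Supervision enters through the sample's allowed factor set: pi_n is a
Dirichlet over only the factors known to contribute to sample n, and every
other factor has exactly zero probability — a hard constraint, not a prior
preference. Multi-label designs (e.g. host x body site) are encoded either
as column-qualified factor values with multi-element allowed sets, or as one
pre-combined label column; both are supported and the combined convention is
the default documented one.

The unit of sampling is the token, not the distinct OTU: abundance
information flows through token multiplicity, and the complete likelihood is
a product over i = 1..N_n of single-token draws. Tokenization is exactly
invertible to the count matrix.

## Collapsed inference

pi, theta and phi are integrated out analytically. The collapsed state is
three count tables — C_wl (OTU x assemblage), C_kl (factor x assemblage),
C_nk (sample x factor) — and the joint P(W, Z, X | alpha) is a product of
Dirichlet-multinomial normalizers: one per assemblage over OTU counts, one
per factor over assemblage counts, one per sample over factor counts
restricted to its allowed set. The Gibbs full conditional for one token is
the familiar product of three smoothed ratios; the pair (k, l) is drawn
jointly from one categorical over allowed-factors x assemblages, and counts
are updated immediately after each draw. Tokens are visited in a freshly
randomized order every sweep.

Restricting the pi term's denominator (and its alpha_pi multiplicity) to the
allowed set makes pi_n a Dirichlet over exactly the sample's known factors,
which is what the zero-mass supervision constraint requires. Because the
allowed-set total equals N_n (every token has some factor), this denominator
is constant within a token update and drops out of the normalized
conditional.

Correctness is validated two independent ways in the test suite: the summed
collapsed joint over all assignments of a tiny instance equals a Monte-Carlo
Dirichlet integral of the uncollapsed likelihood, and single-token joint
ratios equal conditional-weight ratios exhaustively on small instances.
Sampler output is checked against brute-force enumeration of all (K·L)^n
assignments on instances small enough to enumerate.

## Hyperparameter learning

After each sweep, each concentration is updated by one Metropolis step: a
symmetric Gaussian random walk on log(alpha) (default step 0.5), a flat
prior on log(alpha) within (1e-6, 100) enforced by rejection, and acceptance
probability min(1, exp(delta collapsed joint)). Only the joint term the
given alpha touches is recomputed. All chains start at alpha = 0.01. With a
flat prior on log(alpha) and a log-space symmetric proposal the proposal
Jacobian cancels, so the acceptance ratio is the bare joint ratio; this is
the one place where two natural conventions (flat on alpha vs flat on
log alpha) disagree, and we chose flat on log alpha as scale-free.
`hp_update_after` optionally holds the concentrations at 0.01 for the first
sweeps so assemblage structure consolidates before the priors adapt —
without it, a chain that transiently spreads one true assemblage across
several identical copies can drive alpha_theta upward and lock the diffuse
explanation in.

## Mixing: why token-level Gibbs is not enough, and what we add

Single-token updates mix poorly across assemblage *decompositions*: once
counts are entrenched, moving a coherent block of OTU tokens between
assemblages requires passing through states the sampler essentially never
visits (the first token to move faces a near-zero smoothed ratio). In
experiments on simulated data this traps chains in local decompositions
whose collapsed log probability is hundreds of nats below the dominant mode,
even over tens of thousands of sweeps.

Two optional Metropolis moves, both exact (they leave the collapsed
posterior invariant) and both off by default, address this:

- **Split–merge** (`McmcConfig.split_merge_moves` proposals per sweep): two
  anchor tokens are drawn; if they share an assemblage, its members are
  split into the assemblage and a currently empty one via sequentially
  allocated restricted Gibbs (five launch scans refine a random initial
  split, and the final scan's transition probability enters the acceptance
  ratio); if they differ, the two assemblages are merged, with the reverse
  split's probability computed by a forced dry run. Factor assignments never
  change, so supervision is untouched. Splits require an empty assemblage,
  so this move is most effective when the model is run with one or two
  spare assemblages beyond the expected structure.
- **OTU-block swap** (`McmcConfig.block_swap_proposals` per OTU per sweep):
  all tokens of one OTU within one factor are exchanged between a random
  assemblage pair — an involution with symmetric selection probability, so
  acceptance is min(1, exp(delta joint)). This relocates whole OTU columns
  that single-token updates cannot shift.

Both moves are validated against enumeration: interleaving them with sweeps
on tiny instances leaves the sampled marginals within Monte-Carlo error of
the exact posterior.

With multiple chains (`n_chains > 1`), `run_training` returns the chain with
the highest mean retained collapsed log probability and computes a
concordance score (mean matched cosine similarity of phi estimates across
chains after optimal assemblage assignment, Hungarian matching); a score
below 0.9 raises a warning to run longer, mirroring how non-concordant
chains are handled in practice.

## Schedules and estimates

Training defaults: 2,000 sweeps, the first 200 discarded, snapshots every
100 — 18 retained snapshots. Prediction defaults: 1,000 sweeps, 50 burn-in,
snapshots every 50 — 19 retained. Snapshots store full count tables
(lossless; estimates can be recomputed under any smoothing). Posterior-mean
mixtures are computed per snapshot as smoothed ratios, e.g.
theta_kl = (C_kl + a_theta)/(Σ C_kl' + L a_theta), then averaged over
snapshots; pi rows are zero outside allowed sets. An assemblage with no
tokens gets the prior-mean (uniform) OTU row.

Prediction folds each test sample in independently: a per-sample copy of the
frozen training C_wl/C_kl (which the sample's own tokens do update during
its chain, then discard), C_nk starting at zero, all K factors allowed, and
hyperparameters frozen at their posterior-mean training values. Per-sample
sub-seeds are derived from the master seed and the sample identifier, so
batch composition and order cannot affect results. Empty samples fall back
to the uniform prior and are flagged.

## Synthetic data

The generator draws from the model's own generative process, so it emulates
compositional count data with a true two-level mixture structure — and
nothing else: no sequencing error, chimeras, copy-number variation or
compositional artifacts of real amplicon pipelines. Passing tests therefore
demonstrate correct inference under the model's assumptions, not robustness
to real-data violations of them. Default scenario: 200 samples (the scale of
a typical simulation condition here), with K, L, T, depth and the
concentration triplet as the scenario knobs; `DEFAULT_SCENARIO_GRID` spans
K in {2,4,8} x L in {5,20} x T in {50,500} x depth in {100,1000} x a sparse
and a diffuse concentration regime as this package's own illustrative grid
of easy-to-hard conditions. Ground truth (mixtures and every token's latent
assignments) is always emitted.

`draw_identifiable_parameters` rejects truth draws — on truth-only criteria,
never on inference output — whose decomposition could not be recovered even
in principle: with single-label samples the likelihood sees only the K
factor-level OTU distributions theta @ phi, so for K < L recovery requires
nearly non-overlapping assemblage profiles (pairwise phi cosine <= 0.08),
substantial use of every assemblage (max_k theta_kl >= 0.15) and
non-proportional usage columns (pairwise column cosine <= 0.93; proportional
columns make two assemblages indistinguishable from one merged one).

## Reference benchmarks

`biomico.benchmarks` packages the standard self-checks:

- **Parameter recovery** (K=3, L=5, T=50, N=60, 500 tokens/sample): the
  usage matrix is a fixed design (`RECOVERY_THETA`) with all entries
  positive (every factor touches every assemblage, keeping token moves
  fluid), every assemblage a substantial component of some factor, and
  pairwise non-proportional columns — the properties the K < L rank
  deficiency requires for the decomposition to be pinned by the sparse
  priors. OTU profiles are per-seed sparse Dirichlet(0.02) draws redrawn
  until pairwise cosine <= 0.05. Training runs 5 chains x 6,000 sweeps
  (4,000 burn-in) with split–merge and block-swap moves and keeps the best
  chain by retained log probability. Scored by matched per-row L1 error of
  phi and each factor's theta mass on its true assemblages.
- **Held-out classification**: two factors with disjoint assemblage blocks;
  an `overlap` knob linearly interpolates each factor's assemblage mixture
  toward uniform (0 = fully separated, 1 = identical factors), so accuracy
  should degrade from near-perfect toward chance as overlap grows.
- **Hyperparameter direction**: data generated with
  alpha_phi = alpha_theta = 0.01 (six factors over four assemblages, so each
  assemblage has a distinctive usage signature and the consolidated sparse
  explanation dominates); learned alpha_phi, alpha_theta should remain well
  below 1, matching the sub-unity estimates the model family reports on real
  communities.

Problem sizes in the benchmarks (tens of samples, hundreds of tokens,
thousands of sweeps) are chosen so the full suite runs on a laptop-class
single core in minutes while remaining large enough for the statistical
assertions to be meaningful.

## Numerical choices and degenerate inputs

Conditional weights are computed in linear space (counts are bounded by
token totals; no underflow at these scales); joint probabilities in
log-gamma space. Classification ties break toward the lower factor index;
support-set ties at the cutoff boundary break toward the lower item index;
the "inflection" rule for predominant OTUs takes the prefix before the
largest consecutive ratio drop of the sorted distribution, falling back to
the full set (with a warning) when no drop exists — the inflection notion is
this package's operationalization of an informal convention. Zero-count
assemblages estimate to the prior mean. All-zero samples are rejected at
tokenization; empty test samples predict the uniform prior. Relative
abundances are rejected rather than rescaled, because N_n must count real
observations for the token-level model to be meaningful. Test OTUs absent
from the training vocabulary are dropped with a report (phi has no support
for them); training OTUs absent from a test sample contribute zero counts.

## Known limitations

- L is fixed by the user (100 by default, following common practice for this
  model family); no automatic selection. One or two spare assemblages help
  the split–merge move; heavily overcomplete L can fragment profiles.
- At K < L with single-label samples, the factor-level data constrain only a
  rank-K projection of (theta, phi); recovery of individual assemblages
  leans on the sparse priors, and posterior mass on alternative
  decompositions is a genuine feature of the model, not a sampler artifact.
  The recovery benchmark's truth is designed to be identifiable; arbitrary
  truths need not be.
- Equal-weight splits of a factor's private assemblages with disjoint OTU
  blocks are not identifiable at all (any repartition fits); the
  classification benchmarks therefore score factor-level quantities.
- The MH proposal scale (0.5) and the alpha bounds (1e-6, 100) are pragmatic
  defaults; no adaptation is implemented.
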