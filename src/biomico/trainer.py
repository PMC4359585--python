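"""Training-phase MCMC: Gibbs sweeps, Metropolis-within-Gibbs hyperparameter
updates, burn-in/thinning, and multi-chain concordance.

The default schedule discards the first 200 sweeps as burn-in, runs 2,000
sweeps in total and retains a count-table snapshot every 100 sweeps, giving
18 posterior snapshots per chain. Hyperparameters start at 0.01 and are
resampled once per sweep (after all token updates) by a symmetric log-scale
Gaussian random walk accepted against the collapsed joint probability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _gibbs
from ._splitmerge import block_swap_pass, split_merge_move
from .data_io import TokenizedDataset
from .model_core import (
    AssignmentState,
    CountTables,
    Dimensions,
    Hyperparameters,
    collapsed_joint_log_prob,
    estimate_mixtures,
    init_state,
    log_prob_phi_term,
    log_prob_pi_term,
    log_prob_theta_term,
)

__all__ = [
    "McmcConfig",
    "RetainedSample",
    "TrainedModel",
    "dimensions_for",
    "build_allowed_mask",
    "gibbs_sweep",
    "mh_update_hyperparameters",
    "run_training",
    "run_training_chains",
    "estimate_theta",
    "estimate_phi",
    "estimate_pi",
    "chain_concordance",
]

HP_BOUNDS = (1e-6, 100.0)
CONCORDANCE_THRESHOLD = 0.9


@dataclass(frozen=True)
class McmcConfig:
    """MCMC schedule and chain bookkeeping.

    Snapshots are retained at sweeps ``burn_in + thin, burn_in + 2*thin, ...``
    up to ``total_iterations``, so a chain keeps
    ``floor((total_iterations - burn_in) / thin)`` snapshots.
    """

    burn_in: int = 200
    total_iterations: int = 2000
    thin: int = 100
    n_chains: int = 1
    seed: int = 0
    hp_update: bool = True
    hp_step: float = 0.5
    hp_update_after: int = 0
    split_merge_moves: int = 0
    block_swap_proposals: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if not (self.total_iterations >= self.thin >= 1):
            raise ValueError("need total_iterations >= thin >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @classmethod
    def training_defaults(cls, **overrides) -> "McmcConfig":
        return cls(**{"burn_in": 200, "total_iterations": 2000, "thin": 100, **overrides})

    @classmethod
    def testing_defaults(cls, **overrides) -> "McmcConfig":
        return cls(
            **{
                "burn_in": 50,
                "total_iterations": 1000,
                "thin": 50,
                "hp_update": False,
                **overrides,
            }
        )

    @property
    def n_retained(self) -> int:
        return (self.total_iterations - self.burn_in) // self.thin


@dataclass
class RetainedSample:
    """One posterior snapshot: count tables plus the hyperparameters in force."""

    counts: CountTables
    hp: Hyperparameters


@dataclass
class TrainedModel:
    """Everything prediction and interpretation need from a training run."""

    dims: Dimensions
    factor_names: list[str]
    otu_ids: list[str]
    sample_ids: list[str]
    allowed_factors: list[frozenset[int]]
    config: McmcConfig
    final_counts: CountTables
    final_hp: Hyperparameters
    snapshots: list[RetainedSample]
    hp_trace: np.ndarray
    log_prob_trace: np.ndarray
    concordance: float | None = field(default=None, compare=False)

    def mean_hp(self) -> Hyperparameters:
        """Posterior-mean hyperparameters over retained snapshots."""
        arr = np.stack([s.hp.as_array() for s in self.snapshots]).mean(axis=0)
        return Hyperparameters(alpha_pi=arr[0], alpha_theta=arr[1], alpha_phi=arr[2])


def dimensions_for(data: TokenizedDataset, n_assemblages: int, n_factors: int | None = None) -> Dimensions:
    """Build Dimensions from a tokenized dataset and a chosen number of assemblages."""
    if n_factors is None:
        if data.factor_names:
            n_factors = len(data.factor_names)
        else:
            n_factors = 1 + max(max(a) for a in data.allowed_factors)
    return Dimensions(
        n_samples=data.n_samples,
        n_factors=n_factors,
        n_assemblages=n_assemblages,
        n_otus=data.n_otus,
        tokens_per_sample=data.tokens_per_sample(),
    )


def build_allowed_mask(allowed_factors: list, n_factors: int) -> np.ndarray:
    """N x K boolean supervision mask (True where the factor may contribute)."""
    mask = np.zeros((len(allowed_factors), n_factors), dtype=np.bool_)
    for n, allowed in enumerate(allowed_factors):
        for k in allowed:
            if k >= n_factors:
                raise ValueError(f"factor index {k} out of range (K={n_factors})")
            mask[n, k] = True
    return mask


def gibbs_sweep(
    state: AssignmentState,
    counts: CountTables,
    allowed_mask: np.ndarray,
    hp: Hyperparameters,
    rng: np.random.Generator,
) -> None:
    """One collapsed Gibbs sweep: every token resampled once, in random order.

    Each token is removed from the count tables, a joint (factor, assemblage)
    pair is drawn from the collapsed conditional, and the tables are updated
    immediately. Operates in place.
    """
    _gibbs.sweep(state, counts, allowed_mask, hp, rng)


def _propose_log_walk(value: float, step: float, rng: np.random.Generator) -> float:
    return value * math.exp(rng.normal(0.0, step))


def mh_update_hyperparameters(
    counts: CountTables,
    hp: Hyperparameters,
    allowed_sets: list,
    rng: np.random.Generator,
    step: float = 0.5,
) -> tuple[Hyperparameters, dict]:
    """Metropolis updates of the three Dirichlet concentrations.

    Each concentration gets an independent symmetric Gaussian random walk on
    the log scale (flat prior on log alpha within (1e-6, 100), enforced by
    rejection), accepted with probability min(1, exp(delta collapsed joint)).
    Only the joint term a given alpha touches is recomputed.
    """
    terms = {
        "alpha_phi": lambda a: log_prob_phi_term(counts, Hyperparameters(1, 1, a)),
        "alpha_theta": lambda a: log_prob_theta_term(counts, Hyperparameters(1, a, 1)),
        "alpha_pi": lambda a: log_prob_pi_term(counts, Hyperparameters(a, 1, 1), allowed_sets),
    }
    new_values = {}
    accepted = {}
    for name in ("alpha_pi", "alpha_theta", "alpha_phi"):
        current = getattr(hp, name)
        proposal = _propose_log_walk(current, step, rng)
        if not (HP_BOUNDS[0] < proposal < HP_BOUNDS[1]):
            new_values[name] = current
            accepted[name] = False
            continue
        log_ratio = terms[name](proposal) - terms[name](current)
        if math.log(rng.random()) < log_ratio:
            new_values[name] = proposal
            accepted[name] = True
        else:
            new_values[name] = current
            accepted[name] = False
    return Hyperparameters(**new_values), accepted


def _run_single_chain(
    data: TokenizedDataset,
    dims: Dimensions,
    config: McmcConfig,
    chain_index: int,
) -> TrainedModel:
    rng = np.random.default_rng([config.seed, chain_index])
    state, counts = init_state(data, dims, rng)
    mask = build_allowed_mask(data.allowed_factors, dims.n_factors)
    allowed_sets = data.allowed_factors
    hp = Hyperparameters()  # all concentrations start at 0.01
    snapshots: list[RetainedSample] = []
    hp_trace = np.empty((config.total_iterations, 3))
    log_prob_trace = np.empty(config.total_iterations)
    for it in range(1, config.total_iterations + 1):
        gibbs_sweep(state, counts, mask, hp, rng)
        for _ in range(config.split_merge_moves):
            split_merge_move(state, counts, hp, rng)
        if config.block_swap_proposals:
            block_swap_pass(state, counts, hp, rng, config.block_swap_proposals)
        if config.hp_update and it > config.hp_update_after:
            hp, _ = mh_update_hyperparameters(counts, hp, allowed_sets, rng, config.hp_step)
        hp_trace[it - 1] = hp.as_array()
        log_prob_trace[it - 1] = collapsed_joint_log_prob(counts, hp, allowed_sets)
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            snapshots.append(RetainedSample(counts=counts.copy(), hp=hp))
    if not snapshots:
        raise ValueError(
            "MCMC schedule retains no snapshots "
            f"(burn_in={config.burn_in}, total={config.total_iterations}, thin={config.thin})"
        )
    return TrainedModel(
        dims=dims,
        factor_names=list(data.factor_names) or [f"factor_{k}" for k in range(dims.n_factors)],
        otu_ids=[f"otu_{t}" for t in range(dims.n_otus)],
        sample_ids=list(data.sample_ids),
        allowed_factors=list(data.allowed_factors),
        config=config,
        final_counts=counts,
        final_hp=hp,
        snapshots=snapshots,
        hp_trace=hp_trace,
        log_prob_trace=log_prob_trace,
    )


def run_training_chains(
    data: TokenizedDataset,
    dims: Dimensions,
    config: McmcConfig,
    otu_ids: list[str] | None = None,
) -> list[TrainedModel]:
    """Run ``config.n_chains`` independent chains from distinct sub-seeds."""
    if data.n_samples == 0:
        raise ValueError("no samples to train on")
    if dims.n_assemblages < 1:
        raise ValueError("need at least one assemblage")
    models = []
    for c in range(config.n_chains):
        model = _run_single_chain(data, dims, config, c)
        if otu_ids is not None:
            model.otu_ids = list(otu_ids)
        models.append(model)
    return models


def run_training(
    data: TokenizedDataset,
    dims: Dimensions,
    config: McmcConfig,
    otu_ids: list[str] | None = None,
) -> TrainedModel:
    """Train the model; with multiple chains, return the best one by log probability.

    Independent chains may settle in different assemblage decompositions; the
    chain with the highest mean retained collapsed joint log probability is
    returned. If the assemblage posteriors of the chains are not concordant
    (mean matched cosine similarity of the phi estimates < 0.9), a warning is
    raised suggesting a longer run.
    """
    models = run_training_chains(data, dims, config, otu_ids=otu_ids)
    best = models[0]
    if len(models) > 1:
        scores = [m.log_prob_trace[config.burn_in:].mean() for m in models]
        best = models[int(np.argmax(scores))]
        score, flagged = chain_concordance(models)
        best.concordance = score
        if flagged:
            warnings.warn(
                f"chains are not concordant (score {score:.3f} < {CONCORDANCE_THRESHOLD}); "
                "consider running longer chains"
            )
    return best


def _snapshot_estimates(model: TrainedModel):
    for snap in model.snapshots:
        yield estimate_mixtures(snap.counts, snap.hp, model.allowed_factors)


def estimate_theta(model: TrainedModel) -> np.ndarray:
    """Posterior-mean factor->assemblage mixture (K x L), averaged over snapshots."""
    if not model.snapshots:
        raise ValueError("model has no retained snapshots")
    return np.mean([theta for _, theta, _ in _snapshot_estimates(model)], axis=0)


def estimate_phi(model: TrainedModel) -> np.ndarray:
    """Posterior-mean assemblage->OTU mixture (L x T), averaged over snapshots."""
    if not model.snapshots:
        raise ValueError("model has no retained snapshots")
    return np.mean([phi for _, _, phi in _snapshot_estimates(model)], axis=0)


def estimate_pi(model: TrainedModel) -> np.ndarray:
    """Posterior-mean sample->factor mixture (N x K); zero outside allowed sets."""
    if not model.snapshots:
        raise ValueError("model has no retained snapshots")
    return np.mean([pi for pi, _, _ in _snapshot_estimates(model)], axis=0)


def chain_concordance(models: list[TrainedModel]) -> tuple[float, bool]:
    """Mean matched cosine similarity of phi estimates across chain pairs.

    Assemblage labels are arbitrary (label switching), so chains are compared
    after an optimal one-to-one assemblage assignment. Returns the mean
    matched similarity over all chain pairs and a flag that is True when the
    score falls below 0.9.
    """
    from .summaries import match_assemblages

    if len(models) < 2:
        raise ValueError("concordance needs at least two chains")
    shapes = {(m.dims.n_assemblages, m.dims.n_otus) for m in models}
    if len(shapes) != 1:
        raise ValueError("chains have mismatched dimensions")
    phis = [estimate_phi(m) for m in models]
    scores = []
    for a in range(len(phis)):
        for b in range(a + 1, len(phis)):
            _, sims = match_assemblages(phis[a], phis[b])
            scores.append(float(np.mean(sims)))
    score = float(np.mean(scores))
    return score, score < CONCORDANCE_THRESHOLD
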