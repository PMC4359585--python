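"""Folding unlabeled samples into a trained model to predict factor posteriors.

Each test sample is processed independently: the training-phase OTU-assemblage
and factor-assemblage count tables are carried forward (a per-sample working
copy that the sample's own tokens update during its chain), the sample's
factor counts start at zero, and a short Gibbs run (default: 1,000 sweeps,
the first 50 discarded, snapshots every 50 -> 19 snapshots) samples its token
assignments with all K factors allowed. Marginalizing the assemblage
assignments in each snapshot gives the posterior probability of each factor;
snapshots are averaged into the reported posterior.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .data_io import SampleLabels, TokenizedDataset
from .model_core import AssignmentState, CountTables, Hyperparameters
from .trainer import McmcConfig, TrainedModel, build_allowed_mask, gibbs_sweep

__all__ = [
    "FactorPosterior",
    "Classification",
    "run_prediction",
    "classify_max_posterior",
    "classification_accuracy",
    "median_label_prediction",
]


@dataclass
class FactorPosterior:
    """Posterior factor probabilities for a set of test samples.

    ``probabilities[i]`` is a length-K vector summing to 1 for
    ``sample_ids[i]``; ``empty_sample[i]`` marks samples with no tokens, whose
    posterior is the symmetric prior (uniform over K).
    """

    sample_ids: list[str]
    factor_names: list[str]
    probabilities: np.ndarray
    empty_sample: np.ndarray


@dataclass(frozen=True)
class Classification:
    """Maximum-posterior factor calls, one per sample."""

    sample_ids: list[str]
    factor_names: list[str]
    predicted: np.ndarray
    max_posterior: np.ndarray

    def predicted_names(self) -> list[str]:
        return [self.factor_names[k] for k in self.predicted]


def _sample_seed(master_seed: int, sample_id: str) -> list[int]:
    """Deterministic per-sample seed independent of batch composition/order."""
    return [int(master_seed) % (2**31), zlib.crc32(sample_id.encode()) % (2**31)]


def _predict_one(
    model: TrainedModel,
    sample_id: str,
    tokens: np.ndarray,
    hp: Hyperparameters,
    config: McmcConfig,
    allowed: frozenset[int],
) -> np.ndarray:
    n_factors = model.dims.n_factors
    n_assemblages = model.dims.n_assemblages
    rng = np.random.default_rng(_sample_seed(config.seed, sample_id))
    allowed_arr = np.asarray(sorted(allowed), dtype=np.int64)
    m = tokens.shape[0]
    state = AssignmentState(
        token_otu=np.asarray(tokens, dtype=np.int64),
        token_sample=np.zeros(m, dtype=np.int64),
        x=allowed_arr[rng.integers(0, allowed_arr.size, size=m)],
        z=rng.integers(0, n_assemblages, size=m),
    )
    # working copy: frozen training c_wl/c_kl plus this sample's own tokens
    counts = CountTables(
        c_wl=model.final_counts.c_wl.copy(),
        c_kl=model.final_counts.c_kl.copy(),
        c_nk=np.zeros((1, n_factors), dtype=np.int64),
    )
    np.add.at(counts.c_wl, (state.token_otu, state.z), 1)
    np.add.at(counts.c_kl, (state.x, state.z), 1)
    np.add.at(counts.c_nk, (np.zeros(m, dtype=np.int64), state.x), 1)
    counts.assemblage_totals = counts.c_wl.sum(axis=0)
    counts.factor_totals = counts.c_kl.sum(axis=1)
    counts.sample_totals = counts.c_nk.sum(axis=1)
    mask = build_allowed_mask([allowed], n_factors)
    k_eff = allowed_arr.size
    posterior = np.zeros(n_factors)
    n_kept = 0
    for it in range(1, config.total_iterations + 1):
        gibbs_sweep(state, counts, mask, hp, rng)
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            posterior[allowed_arr] += (counts.c_nk[0, allowed_arr] + hp.alpha_pi) / (
                m + k_eff * hp.alpha_pi
            )
            n_kept += 1
    if n_kept == 0:
        raise ValueError("test MCMC schedule retains no snapshots")
    return posterior / n_kept


def run_prediction(
    model: TrainedModel,
    test: TokenizedDataset,
    config: McmcConfig | None = None,
    allowed: frozenset[int] | None = None,
) -> FactorPosterior:
    """Posterior factor probabilities for unlabeled, vocabulary-aligned samples.

    ``test`` must be tokenized against the model's OTU vocabulary (see
    :func:`biomico.data_io.align_test_table`). All K factors are allowed for
    every sample unless ``allowed`` restricts them. Samples are folded in one
    at a time with per-sample sub-seeds, so batch composition does not affect
    results. Empty samples fall back to the uniform prior and are flagged.
    Hyperparameters are frozen at their posterior-mean training values.
    """
    if config is None:
        config = McmcConfig.testing_defaults(seed=model.config.seed)
    if allowed is None:
        allowed = frozenset(range(model.dims.n_factors))
    hp = model.mean_hp()
    n_factors = model.dims.n_factors
    probs = np.zeros((test.n_samples, n_factors))
    empty = np.zeros(test.n_samples, dtype=bool)
    for i, (sid, tokens) in enumerate(zip(test.sample_ids, test.tokens)):
        if len(tokens) == 0:
            probs[i] = 1.0 / n_factors
            empty[i] = True
            continue
        if len(tokens) and int(np.max(tokens)) >= model.dims.n_otus:
            raise ValueError(f"sample {sid!r} has OTU indices outside the model vocabulary")
        probs[i] = _predict_one(model, sid, tokens, hp, config, allowed)
    return FactorPosterior(
        sample_ids=list(test.sample_ids),
        factor_names=list(model.factor_names),
        probabilities=probs,
        empty_sample=empty,
    )


def classify_max_posterior(posterior: FactorPosterior) -> Classification:
    """Call each sample's factor by maximum posterior probability.

    Exact ties are broken toward the lowest factor index.
    """
    if posterior.probabilities.shape[0] == 0:
        raise ValueError("empty posterior table")
    predicted = np.argmax(posterior.probabilities, axis=1)  # argmax takes first maximum
    max_post = posterior.probabilities[np.arange(len(predicted)), predicted]
    return Classification(
        sample_ids=list(posterior.sample_ids),
        factor_names=list(posterior.factor_names),
        predicted=predicted,
        max_posterior=max_post,
    )


def classification_accuracy(
    predictions: Classification, truth: list[SampleLabels]
) -> float:
    """Percent of test samples whose predicted factor is among their true values."""
    if len(predictions.sample_ids) == 0:
        raise ValueError("no predictions to score")
    truth_map = {t.sample_id: t.factor_values for t in truth}
    correct = 0
    for sid, pred in zip(predictions.sample_ids, predictions.predicted):
        if sid not in truth_map:
            raise ValueError(f"no truth label for sample {sid!r}")
        if int(pred) in truth_map[sid]:
            correct += 1
    return 100.0 * correct / len(predictions.sample_ids)


def median_label_prediction(
    posterior: FactorPosterior, groups: dict[str, str]
) -> Classification:
    """Group-level factor calls: majority vote over a group's sample-level calls.

    ``groups`` maps sample id -> group key (e.g. the individual a time series
    belongs to). Ties go to the lower factor index. The returned
    ``max_posterior`` is the winning factor's vote fraction within the group.
    """
    calls = classify_max_posterior(posterior)
    by_group: dict[str, list[int]] = {}
    for sid, pred in zip(calls.sample_ids, calls.predicted):
        if sid not in groups:
            raise ValueError(f"sample {sid!r} has no group key")
        by_group.setdefault(groups[sid], []).append(int(pred))
    group_ids = sorted(by_group)
    n_factors = len(posterior.factor_names)
    predicted = np.empty(len(group_ids), dtype=np.int64)
    vote_frac = np.empty(len(group_ids))
    for g, gid in enumerate(group_ids):
        votes = np.bincount(by_group[gid], minlength=n_factors)
        predicted[g] = int(np.argmax(votes))  # first maximum = lower index on ties
        vote_frac[g] = votes[predicted[g]] / votes.sum()
    return Classification(
        sample_ids=group_ids,
        factor_names=list(posterior.factor_names),
        predicted=predicted,
        max_posterior=vote_frac,
    )
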