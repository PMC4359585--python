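"""Reference simulation benchmarks with known ground truth.

These procedures define the package's standard self-checks: parameter
recovery on a sparse, identifiable truth; held-out factor classification on
block-structured two-factor communities with a tunable overlap; and the
direction of learned hyperparameters under sparse generative concentrations.
They are used by the test suite and the reproduction script, and are callable
directly for exploration.
"""

from __future__ import annotations

import numpy as np

from .predictor import classification_accuracy, classify_max_posterior, run_prediction
from .simulator import (
    SimulationScenario,
    draw_model_parameters,
    generate_dataset,
    separated_two_factor_params,
    train_test_split,
)
from .summaries import match_assemblages, support_set
from .trainer import (
    McmcConfig,
    dimensions_for,
    estimate_phi,
    estimate_theta,
    run_training,
)

__all__ = [
    "RECOVERY_THETA",
    "recovery_truth",
    "run_parameter_recovery",
    "run_classification_benchmark",
    "run_hyperparameter_direction",
]

# Fixed assemblage-usage structure for the recovery benchmark. With K < L
# the K factor-level OTU distributions constrain only a rank-K projection of
# (theta, phi), so recovery requires a truth whose decomposition is pinned
# by the sparse priors: all entries positive (every factor touches every
# assemblage, keeping token moves fluid), every assemblage a substantial
# component of at least one factor, and pairwise non-proportional usage
# columns (each assemblage has a distinct cross-factor signature).
RECOVERY_THETA = np.array(
    [
        [0.40, 0.40, 0.08, 0.06, 0.06],
        [0.04, 0.16, 0.40, 0.33, 0.07],
        [0.16, 0.04, 0.06, 0.22, 0.52],
    ]
)


def recovery_truth(seed: int, n_otus: int = 50, alpha_phi: float = 0.02,
                   max_phi_cosine: float = 0.05, max_draws: int = 10000):
    """Sparse assemblage OTU profiles for the recovery benchmark.

    phi rows are symmetric Dirichlet(alpha_phi) draws, redrawn until all
    pairwise cosine similarities are below ``max_phi_cosine`` so the
    assemblages are distinguishable in principle (a truth-only condition).
    """
    rng = np.random.default_rng([int(seed) % (2**31), 101])
    L = RECOVERY_THETA.shape[1]
    for _ in range(max_draws):
        phi = rng.dirichlet(np.full(n_otus, alpha_phi), size=L)
        u = phi / np.maximum(np.linalg.norm(phi, axis=1, keepdims=True), 1e-300)
        gram = u @ u.T
        np.fill_diagonal(gram, 0.0)
        if gram.max() <= max_phi_cosine:
            return phi
    raise RuntimeError("could not draw well-separated assemblage profiles")


def run_parameter_recovery(
    seed: int,
    n_samples: int = 60,
    n_otus: int = 50,
    depth: int = 500,
    config: McmcConfig | None = None,
) -> dict:
    """Simulate from sparse truth, train, and score recovery of phi and theta.

    Returns matched per-row L1 errors of the phi estimate, the mean matched
    cosine similarity, and each factor's estimated mass on its true
    assemblages (the 90% support set of the true theta row).
    """
    K, L = RECOVERY_THETA.shape
    phi = recovery_truth(seed, n_otus=n_otus)
    scenario = SimulationScenario(
        n_samples=n_samples, n_factors=K, n_assemblages=L, n_otus=n_otus,
        tokens_per_sample=depth, seed=int(seed) % (2**31),
    )
    ds = generate_dataset(scenario, theta=RECOVERY_THETA, phi=phi)
    data = ds.tokenized()
    if config is None:
        config = McmcConfig(
            burn_in=4000, total_iterations=6000, thin=100, n_chains=5,
            seed=int(seed) % (2**31), split_merge_moves=3, block_swap_proposals=10,
        )
    model = run_training(data, dimensions_for(data, L), config)
    phi_hat = estimate_phi(model)
    theta_hat = estimate_theta(model)
    perm, sims = match_assemblages(ds.params.phi, phi_hat)
    l1 = np.abs(ds.params.phi - phi_hat[perm]).sum(axis=1)
    matched_theta = theta_hat[:, perm]
    mass = np.array(
        [
            matched_theta[k, support_set(RECOVERY_THETA[k], 0.9).items].sum()
            for k in range(K)
        ]
    )
    return {
        "phi_l1": l1,
        "mean_phi_l1": float(l1.mean()),
        "matched_cosine": sims,
        "theta_mass_on_true": mass,
        "model": model,
        "dataset": ds,
    }


def run_classification_benchmark(
    seed: int,
    overlap: float = 0.0,
    n_samples: int = 40,
    depth: int = 200,
    train_config: McmcConfig | None = None,
    test_config: McmcConfig | None = None,
) -> float:
    """Held-out classification accuracy (%) on a two-factor block scenario.

    ``overlap`` interpolates each factor's assemblage mixture toward uniform:
    0 gives fully separated factors, 1 identical ones.
    """
    theta, phi = separated_two_factor_params(2, 4, 40, overlap=overlap)
    scenario = SimulationScenario(
        n_samples=n_samples, n_factors=2, n_assemblages=4, n_otus=40,
        tokens_per_sample=depth, seed=int(seed) % (2**31),
    )
    ds = generate_dataset(scenario, theta=theta, phi=phi)
    train_idx, test_idx = train_test_split(ds, 0.5, seed=int(seed) % (2**31))
    data = ds.tokenized(train_idx)
    if train_config is None:
        train_config = McmcConfig(
            burn_in=200, total_iterations=800, thin=50, seed=int(seed) % (2**31)
        )
    model = run_training(data, dimensions_for(data, 4), train_config)
    if test_config is None:
        test_config = McmcConfig.testing_defaults(seed=int(seed) % (2**31))
    test = ds.tokenized(test_idx, unlabeled=True)
    posterior = run_prediction(model, test, test_config)
    calls = classify_max_posterior(posterior)
    return classification_accuracy(calls, [ds.labels[n] for n in test_idx])


def run_hyperparameter_direction(
    seed: int,
    n_samples: int = 36,
    depth: int = 200,
    config: McmcConfig | None = None,
) -> dict:
    """Train on data generated with alpha_phi = alpha_theta = 0.01.

    Returns the posterior-mean concentrations; on such sparse data the learned
    alpha_phi and alpha_theta should stay well below 1. Six factors over four
    assemblages give each assemblage a distinct usage signature, so the
    consolidated (sparse) explanation dominates diffuse ones.
    """
    scenario = SimulationScenario(
        n_samples=n_samples, n_factors=6, n_assemblages=4, n_otus=50,
        tokens_per_sample=depth, alpha_theta=0.01, alpha_phi=0.01,
        seed=int(seed) % (2**31),
    )
    ds = generate_dataset(scenario)
    data = ds.tokenized()
    if config is None:
        config = McmcConfig(
            burn_in=400, total_iterations=1200, thin=50,
            seed=int(seed) % (2**31),
            hp_update_after=200, split_merge_moves=2, block_swap_proposals=4,
        )
    model = run_training(data, dimensions_for(data, 4), config)
    hp = model.mean_hp()
    return {
        "alpha_phi": float(hp.alpha_phi),
        "alpha_theta": float(hp.alpha_theta),
        "alpha_pi": float(hp.alpha_pi),
        "model": model,
    }
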