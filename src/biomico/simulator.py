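"""Synthetic microbiome data drawn from the model's own generative process.

A scenario fixes the problem sizes (N samples, K factors, L assemblages,
T OTUs, sequencing depth) and the symmetric Dirichlet concentrations from
which the true mixtures are drawn. For every token of every sample the
generator draws a factor X ~ Categorical(pi_n), an assemblage
Z ~ Categorical(theta_X) and an OTU W ~ Categorical(phi_Z), then aggregates
tokens into a count table. The latent truth (pi, theta, phi, and per-token
X, Z) is always returned alongside the data so training and prediction can be
scored against known parameters.

``DEFAULT_SCENARIO_GRID`` spans K in {2,4,8} x L in {5,20} x T in {50,500}
x depth in {100,1000} x two concentration regimes; it is this package's own
illustrative grid for mapping easy and hard inference regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np

from .data_io import OtuTable, SampleLabels, TokenizedDataset

__all__ = [
    "SimulationScenario",
    "GenerativeParams",
    "SimulatedDataset",
    "draw_model_parameters",
    "generate_sample",
    "generate_dataset",
    "train_test_split",
    "separated_two_factor_params",
    "DEFAULT_SCENARIO_GRID",
]


@dataclass(frozen=True)
class SimulationScenario:
    """One simulation condition; everything reproducible from ``seed``.

    ``factors_per_sample`` controls the size of each sample's allowed set
    (factor membership is assigned round-robin so all K factors are used).
    """

    n_samples: int = 200
    n_factors: int = 2
    n_assemblages: int = 5
    n_otus: int = 50
    tokens_per_sample: int = 500
    alpha_pi: float = 1.0
    alpha_theta: float = 0.1
    alpha_phi: float = 0.05
    factors_per_sample: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_factors, self.n_assemblages, self.n_otus) < 1:
            raise ValueError("scenario dimensions must be >= 1")
        if self.tokens_per_sample < 0:
            raise ValueError("tokens_per_sample must be >= 0")
        if not (1 <= self.factors_per_sample <= self.n_factors):
            raise ValueError("factors_per_sample must be in [1, n_factors]")


@dataclass
class GenerativeParams:
    """Ground-truth mixtures used to generate a dataset."""

    theta: np.ndarray  # K x L, row-stochastic
    phi: np.ndarray  # L x T, row-stochastic
    pi: np.ndarray  # N x K, row-stochastic, zero outside allowed sets
    allowed_factors: list[frozenset[int]]
    scenario: SimulationScenario


@dataclass
class SimulatedDataset:
    """A generated dataset plus the truth needed for recovery tests."""

    table: OtuTable
    labels: list[SampleLabels]
    factor_names: list[str]
    params: GenerativeParams
    latent_w: list[np.ndarray]
    latent_x: list[np.ndarray]
    latent_z: list[np.ndarray]

    def tokenized(self, samples: list[int] | None = None, unlabeled: bool = False) -> TokenizedDataset:
        """Tokenize (a subset of) the dataset; ``unlabeled`` opens all factors."""
        idx = list(range(self.table.n_samples)) if samples is None else list(samples)
        all_factors = frozenset(range(len(self.factor_names)))
        tokens = [
            np.repeat(np.arange(self.table.n_otus, dtype=np.int64), self.table.counts[n])
            for n in idx
        ]
        allowed = [
            all_factors if unlabeled else self.labels[n].factor_values for n in idx
        ]
        return TokenizedDataset(
            sample_ids=[self.table.sample_ids[n] for n in idx],
            tokens=tokens,
            allowed_factors=allowed,
            n_otus=self.table.n_otus,
            factor_names=list(self.factor_names),
        )


def _assign_allowed_sets(scenario: SimulationScenario, rng: np.random.Generator) -> list[frozenset[int]]:
    """Round-robin primary factor, plus random extras for multi-factor samples."""
    allowed = []
    for n in range(scenario.n_samples):
        primary = n % scenario.n_factors
        extra = [k for k in range(scenario.n_factors) if k != primary]
        chosen = {primary}
        if scenario.factors_per_sample > 1:
            chosen.update(
                rng.choice(extra, size=scenario.factors_per_sample - 1, replace=False).tolist()
            )
        allowed.append(frozenset(int(k) for k in chosen))
    return allowed


def draw_model_parameters(
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
    theta: np.ndarray | None = None,
    phi: np.ndarray | None = None,
) -> GenerativeParams:
    """Draw (or accept) the true mixtures for a scenario.

    theta rows ~ Dirichlet(alpha_theta * 1_L), phi rows ~ Dirichlet(alpha_phi
    * 1_T), and each pi_n ~ Dirichlet(alpha_pi) over the sample's allowed set
    (zeros elsewhere). Explicit ``theta``/``phi`` matrices override the draws.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    K, L, T = scenario.n_factors, scenario.n_assemblages, scenario.n_otus
    if theta is None:
        theta = rng.dirichlet(np.full(L, scenario.alpha_theta), size=K)
    if phi is None:
        phi = rng.dirichlet(np.full(T, scenario.alpha_phi), size=L)
    theta = np.asarray(theta, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    if theta.shape != (K, L) or phi.shape != (L, T):
        raise ValueError("explicit theta/phi have wrong shape for the scenario")
    allowed = _assign_allowed_sets(scenario, rng)
    pi = np.zeros((scenario.n_samples, K))
    for n, aset in enumerate(allowed):
        idx = np.asarray(sorted(aset), dtype=np.int64)
        pi[n, idx] = rng.dirichlet(np.full(idx.size, scenario.alpha_pi))
    return GenerativeParams(theta=theta, phi=phi, pi=pi, allowed_factors=allowed, scenario=scenario)


def generate_sample(
    params: GenerativeParams,
    sample_index: int,
    depth: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one sample's tokens: (otu tokens, true X, true Z), each length ``depth``."""
    pi_n = params.pi[sample_index]
    K, L = params.theta.shape
    T = params.phi.shape[1]
    x = rng.choice(K, size=depth, p=pi_n)
    z = np.empty(depth, dtype=np.int64)
    w = np.empty(depth, dtype=np.int64)
    for k in np.unique(x):
        sel = x == k
        z[sel] = rng.choice(L, size=int(sel.sum()), p=params.theta[k])
    for l in np.unique(z):
        sel = z == l
        w[sel] = rng.choice(T, size=int(sel.sum()), p=params.phi[l])
    return w, x.astype(np.int64), z


def draw_identifiable_parameters(
    scenario: SimulationScenario,
    min_top_usage: float = 0.15,
    max_phi_cosine: float = 0.08,
    max_usage_cosine: float = 0.93,
    max_draws: int = 20000,
) -> GenerativeParams:
    """Draw truth from the scenario's Dirichlet regime, conditioned on identifiability.

    With single-label samples the likelihood sees only the K factor-level OTU
    distributions theta @ phi, so for K < L the (theta, phi) decomposition is
    identifiable only when the truth is genuinely sparse and well used:
    assemblage OTU profiles must be nearly non-overlapping (pairwise cosine
    similarity of phi rows <= ``max_phi_cosine``), every assemblage must
    contribute substantially to at least one factor (max_k theta_kl >=
    ``min_top_usage``), and assemblages must be used in distinguishable ratios
    across factors (pairwise cosine of theta columns <= ``max_usage_cosine``;
    proportional usage columns make two assemblages indistinguishable from one
    merged assemblage). Draws are rejected on these truth-only conditions
    until all hold — never on inference results.
    """
    rng = np.random.default_rng(scenario.seed)
    for _ in range(max_draws):
        params = draw_model_parameters(scenario, rng=rng)
        top_usage = params.theta.max(axis=0)
        if top_usage.min() < min_top_usage:
            continue
        cols = params.theta / np.maximum(
            np.linalg.norm(params.theta, axis=0, keepdims=True), 1e-300
        )
        col_gram = cols.T @ cols
        np.fill_diagonal(col_gram, 0.0)
        if col_gram.max() > max_usage_cosine:
            continue
        u = params.phi / np.maximum(np.linalg.norm(params.phi, axis=1, keepdims=True), 1e-300)
        gram = u @ u.T
        np.fill_diagonal(gram, 0.0)
        if gram.max() <= max_phi_cosine:
            return params
    raise RuntimeError(
        f"no identifiable truth found in {max_draws} draws; "
        "relax the conditions or change the concentration regime"
    )


def generate_dataset(
    scenario: SimulationScenario,
    theta: np.ndarray | None = None,
    phi: np.ndarray | None = None,
    params: GenerativeParams | None = None,
) -> SimulatedDataset:
    """Generate a full dataset (count table, labels, truth) from a scenario.

    Truth is drawn from the scenario's priors unless explicit ``theta``/``phi``
    matrices or a complete ``params`` (e.g. from
    :func:`draw_identifiable_parameters`) are supplied.
    """
    rng = np.random.default_rng(scenario.seed)
    if params is None:
        params = draw_model_parameters(scenario, rng=rng, theta=theta, phi=phi)
    else:
        # keep token draws decoupled from however many prior draws truth took
        rng = np.random.default_rng([scenario.seed, 1])
    counts = np.zeros((scenario.n_samples, scenario.n_otus), dtype=np.int64)
    latent_w: list[np.ndarray] = []
    latent_x: list[np.ndarray] = []
    latent_z: list[np.ndarray] = []
    labels: list[SampleLabels] = []
    factor_names = [f"factor_{k}" for k in range(scenario.n_factors)]
    for n in range(scenario.n_samples):
        w, x, z = generate_sample(params, n, scenario.tokens_per_sample, rng)
        np.add.at(counts[n], w, 1)
        latent_w.append(w)
        latent_x.append(x)
        latent_z.append(z)
        labels.append(
            SampleLabels(sample_id=f"sample_{n}", factor_values=params.allowed_factors[n])
        )
    table = OtuTable(
        sample_ids=[f"sample_{n}" for n in range(scenario.n_samples)],
        otu_ids=[f"otu_{t}" for t in range(scenario.n_otus)],
        counts=counts,
    )
    return SimulatedDataset(
        table=table,
        labels=labels,
        factor_names=factor_names,
        params=params,
        latent_w=latent_w,
        latent_x=latent_x,
        latent_z=latent_z,
    )


def train_test_split(
    dataset: SimulatedDataset, test_fraction: float = 0.5, seed: int = 0
) -> tuple[list[int], list[int]]:
    """Split sample indices into train/test, stratified by primary factor."""
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_factor: dict[int, list[int]] = {}
    for n, lab in enumerate(dataset.labels):
        by_factor.setdefault(min(lab.factor_values), []).append(n)
    train: list[int] = []
    test: list[int] = []
    for _, members in sorted(by_factor.items()):
        members = np.asarray(members)
        rng.shuffle(members)
        n_test = max(1, int(round(test_fraction * members.size)))
        test.extend(members[:n_test].tolist())
        train.extend(members[n_test:].tolist())
    return sorted(train), sorted(test)


def separated_two_factor_params(
    n_factors: int = 2,
    n_assemblages: int = 4,
    n_otus: int = 40,
    overlap: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Explicit block-structured (theta, phi) with tunable factor overlap.

    Each factor owns a disjoint block of assemblages and each assemblage a
    disjoint block of OTUs; ``overlap`` in [0, 1] linearly mixes each factor's
    assemblage distribution toward the uniform distribution, so 0 gives fully
    separated factors and 1 makes all factors identical.
    """
    if not (0 <= overlap <= 1):
        raise ValueError("overlap must be in [0, 1]")
    if n_assemblages % n_factors or n_otus % n_assemblages:
        raise ValueError("need n_factors | n_assemblages | n_otus for clean blocks")
    per_factor = n_assemblages // n_factors
    per_assemblage = n_otus // n_assemblages
    theta = np.zeros((n_factors, n_assemblages))
    for k in range(n_factors):
        theta[k, k * per_factor : (k + 1) * per_factor] = 1.0 / per_factor
    theta = (1 - overlap) * theta + overlap / n_assemblages
    phi = np.zeros((n_assemblages, n_otus))
    for l in range(n_assemblages):
        phi[l, l * per_assemblage : (l + 1) * per_assemblage] = 1.0 / per_assemblage
    return theta, phi


def _grid() -> list[SimulationScenario]:
    base = SimulationScenario()
    regimes = [
        {"alpha_theta": 0.1, "alpha_phi": 0.05},  # sparse, well-separated structure
        {"alpha_theta": 1.0, "alpha_phi": 0.5},  # diffuse, harder structure
    ]
    grid = []
    for K, L, T, depth, regime in product((2, 4, 8), (5, 20), (50, 500), (100, 1000), regimes):
        grid.append(
            replace(
                base,
                n_factors=K,
                n_assemblages=L,
                n_otus=T,
                tokens_per_sample=depth,
                **regime,
            )
        )
    return grid


DEFAULT_SCENARIO_GRID: list[SimulationScenario] = _grid()
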