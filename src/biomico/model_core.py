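"""Collapsed latent-state representation of the hierarchical mixed-membership model.

Each microbiome sample is modeled as a mixture over K known *factors*
(body site, host, season, ...), each factor as a mixture over L latent OTU
*assemblages*, and each assemblage as a multinomial over the T OTUs. Symmetric
Dirichlet priors (concentrations ``alpha_pi``, ``alpha_theta``, ``alpha_phi``)
sit on the three mixture levels. Integrating the mixture weights out
analytically leaves a state of per-token discrete assignments (X = factor,
Z = assemblage) whose sufficient statistics are three count tables; this
module owns those tables, the collapsed full conditional a Gibbs sampler
draws from, and the collapsed joint probability used for hyperparameter
learning and validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "Hyperparameters",
    "Dimensions",
    "AssignmentState",
    "CountTables",
    "init_state",
    "conditional_assignment_distribution",
    "remove_token",
    "add_token",
    "collapsed_joint_log_prob",
    "estimate_mixtures",
]


@dataclass(frozen=True)
class Hyperparameters:
    """Symmetric Dirichlet concentrations for the three mixture levels.

    ``alpha_pi`` governs factor mixing within samples, ``alpha_theta``
    assemblage mixing within factors, ``alpha_phi`` OTU mixing within
    assemblages. All must be strictly positive.
    """

    alpha_pi: float = 0.01
    alpha_theta: float = 0.01
    alpha_phi: float = 0.01

    def __post_init__(self) -> None:
        for name in ("alpha_pi", "alpha_theta", "alpha_phi"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"{name} must be strictly positive, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha_pi, self.alpha_theta, self.alpha_phi])


@dataclass(frozen=True)
class Dimensions:
    """Problem sizes: N samples, K factors, L assemblages, T OTU types.

    ``tokens_per_sample`` holds N_n, the number of count units in sample n.
    """

    n_samples: int
    n_factors: int
    n_assemblages: int
    n_otus: int
    tokens_per_sample: np.ndarray

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_factors, self.n_assemblages, self.n_otus) < 1:
            raise ValueError("all dimensions must be >= 1")
        tps = np.asarray(self.tokens_per_sample)
        if tps.shape != (self.n_samples,):
            raise ValueError("tokens_per_sample must have one entry per sample")
        object.__setattr__(self, "tokens_per_sample", tps.astype(np.int64))


@dataclass
class AssignmentState:
    """Per-token factor (X) and assemblage (Z) assignments, flattened.

    ``token_otu[i]`` and ``token_sample[i]`` identify token i; ``x[i]`` is its
    factor in 0..K-1 and ``z[i]`` its assemblage in 0..L-1. During training
    every x[i] lies in its sample's allowed-factor set.
    """

    token_otu: np.ndarray
    token_sample: np.ndarray
    x: np.ndarray
    z: np.ndarray

    @property
    def n_tokens(self) -> int:
        return self.token_otu.shape[0]


@dataclass
class CountTables:
    """Sufficient statistics of the collapsed state, with cached marginals.

    ``c_wl[w, l]``: tokens of OTU w assigned to assemblage l (T x L).
    ``c_kl[k, l]``: tokens assigned to factor k and assemblage l (K x L).
    ``c_nk[n, k]``: tokens of sample n assigned to factor k (N x K).
    The cached marginals are the assemblage totals (sum_w c_wl), factor totals
    (sum_l c_kl) and sample totals (sum_k c_nk, which always equals N_n).
    """

    c_wl: np.ndarray
    c_kl: np.ndarray
    c_nk: np.ndarray
    assemblage_totals: np.ndarray = field(default=None)  # type: ignore[assignment]
    factor_totals: np.ndarray = field(default=None)  # type: ignore[assignment]
    sample_totals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.assemblage_totals is None:
            self.assemblage_totals = self.c_wl.sum(axis=0)
        if self.factor_totals is None:
            self.factor_totals = self.c_kl.sum(axis=1)
        if self.sample_totals is None:
            self.sample_totals = self.c_nk.sum(axis=1)

    @classmethod
    def zeros(cls, n_samples: int, n_factors: int, n_assemblages: int, n_otus: int) -> "CountTables":
        return cls(
            c_wl=np.zeros((n_otus, n_assemblages), dtype=np.int64),
            c_kl=np.zeros((n_factors, n_assemblages), dtype=np.int64),
            c_nk=np.zeros((n_samples, n_factors), dtype=np.int64),
        )

    @classmethod
    def from_state(cls, state: AssignmentState, dims: Dimensions) -> "CountTables":
        """Recount the three tables from scratch (the histogram definition)."""
        tables = cls.zeros(dims.n_samples, dims.n_factors, dims.n_assemblages, dims.n_otus)
        np.add.at(tables.c_wl, (state.token_otu, state.z), 1)
        np.add.at(tables.c_kl, (state.x, state.z), 1)
        np.add.at(tables.c_nk, (state.token_sample, state.x), 1)
        tables.assemblage_totals = tables.c_wl.sum(axis=0)
        tables.factor_totals = tables.c_kl.sum(axis=1)
        tables.sample_totals = tables.c_nk.sum(axis=1)
        return tables

    def copy(self) -> "CountTables":
        return CountTables(
            c_wl=self.c_wl.copy(),
            c_kl=self.c_kl.copy(),
            c_nk=self.c_nk.copy(),
            assemblage_totals=self.assemblage_totals.copy(),
            factor_totals=self.factor_totals.copy(),
            sample_totals=self.sample_totals.copy(),
        )

    @property
    def total_tokens(self) -> int:
        return int(self.c_wl.sum())

    def check_consistency(self) -> None:
        """Raise if the tables violate conservation or non-negativity."""
        for name, tab in (("c_wl", self.c_wl), ("c_kl", self.c_kl), ("c_nk", self.c_nk)):
            if (tab < 0).any():
                raise RuntimeError(f"negative count in {name}")
        totals = {self.c_wl.sum(), self.c_kl.sum(), self.c_nk.sum()}
        if len(totals) != 1:
            raise RuntimeError(f"token totals disagree across tables: {totals}")
        if not np.array_equal(self.assemblage_totals, self.c_wl.sum(axis=0)):
            raise RuntimeError("stale assemblage totals")
        if not np.array_equal(self.factor_totals, self.c_kl.sum(axis=1)):
            raise RuntimeError("stale factor totals")
        if not np.array_equal(self.sample_totals, self.c_nk.sum(axis=1)):
            raise RuntimeError("stale sample totals")


def init_state(
    data,
    dims: Dimensions,
    seed,
) -> tuple[AssignmentState, CountTables]:
    """Draw a uniform-random initial assignment respecting supervision.

    Each token's factor is drawn uniformly from its sample's allowed set and
    its assemblage uniformly from 1..L. Returns the state plus count tables
    built from it. ``data`` is a :class:`~biomico.data_io.TokenizedDataset`.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(seed)
    token_otu = []
    token_sample = []
    x = []
    z = []
    for n, (tokens, allowed) in enumerate(zip(data.tokens, data.allowed_factors)):
        allowed_arr = np.asarray(sorted(allowed), dtype=np.int64)
        if allowed_arr.size == 0:
            raise ValueError(f"sample {data.sample_ids[n]!r} has an empty allowed-factor set")
        m = len(tokens)
        token_otu.append(np.asarray(tokens, dtype=np.int64))
        token_sample.append(np.full(m, n, dtype=np.int64))
        x.append(allowed_arr[rng.integers(0, allowed_arr.size, size=m)])
        z.append(rng.integers(0, dims.n_assemblages, size=m))
    state = AssignmentState(
        token_otu=np.concatenate(token_otu) if token_otu else np.empty(0, dtype=np.int64),
        token_sample=np.concatenate(token_sample) if token_sample else np.empty(0, dtype=np.int64),
        x=np.concatenate(x) if x else np.empty(0, dtype=np.int64),
        z=np.concatenate(z) if z else np.empty(0, dtype=np.int64),
    )
    return state, CountTables.from_state(state, dims)


def conditional_assignment_distribution(
    otu: int,
    sample: int,
    counts: CountTables,
    hp: Hyperparameters,
    allowed: set[int] | np.ndarray,
) -> np.ndarray:
    """Collapsed full conditional over joint (factor, assemblage) assignments.

    ``counts`` must already exclude the token being resampled. Returns a K x L
    table of probabilities summing to 1, with rows of disallowed factors
    identically zero. The (k, l) weight is the product of three smoothed
    ratios: the OTU's share of assemblage l, assemblage l's share of factor k,
    and factor k's share of the sample (the latter restricted to the sample's
    allowed factors, over which pi_n is defined).
    """
    n_otus, n_assemblages = counts.c_wl.shape
    n_factors = counts.c_kl.shape[0]
    allowed_idx = np.asarray(sorted(allowed), dtype=np.int64)
    if allowed_idx.size == 0:
        raise ValueError("allowed factor set is empty")
    if (counts.c_wl[otu] < 0).any() or (counts.c_nk[sample] < 0).any():
        raise RuntimeError("negative count in conditional computation")

    phi_term = (counts.c_wl[otu] + hp.alpha_phi) / (
        counts.assemblage_totals + n_otus * hp.alpha_phi
    )  # (L,)
    theta_term = (counts.c_kl + hp.alpha_theta) / (
        counts.factor_totals[:, None] + n_assemblages * hp.alpha_theta
    )  # (K, L)
    pi_denom = counts.c_nk[sample, allowed_idx].sum() + allowed_idx.size * hp.alpha_pi
    pi_term = np.zeros(n_factors)
    pi_term[allowed_idx] = (counts.c_nk[sample, allowed_idx] + hp.alpha_pi) / pi_denom

    weights = pi_term[:, None] * theta_term * phi_term[None, :]
    total = weights.sum()
    if not (total > 0 and np.isfinite(total)):
        raise RuntimeError("degenerate conditional distribution")
    return weights / total


def remove_token(counts: CountTables, otu: int, sample: int, k: int, l: int) -> None:
    """Subtract one token with assignment (k, l) from all three tables in place."""
    if counts.c_wl[otu, l] <= 0 or counts.c_kl[k, l] <= 0 or counts.c_nk[sample, k] <= 0:
        raise RuntimeError(
            f"cannot remove token (otu={otu}, sample={sample}, k={k}, l={l}): count already zero"
        )
    counts.c_wl[otu, l] -= 1
    counts.c_kl[k, l] -= 1
    counts.c_nk[sample, k] -= 1
    counts.assemblage_totals[l] -= 1
    counts.factor_totals[k] -= 1
    counts.sample_totals[sample] -= 1


def add_token(counts: CountTables, otu: int, sample: int, k: int, l: int) -> None:
    """Add one token with assignment (k, l) to all three tables in place."""
    counts.c_wl[otu, l] += 1
    counts.c_kl[k, l] += 1
    counts.c_nk[sample, k] += 1
    counts.assemblage_totals[l] += 1
    counts.factor_totals[k] += 1
    counts.sample_totals[sample] += 1


def _log_dirichlet_multinomial(row_counts: np.ndarray, alpha: float) -> float:
    """log [ B(counts + alpha*1) / B(alpha*1) ] for one Dirichlet-multinomial row."""
    counts = np.asarray(row_counts, dtype=np.float64)
    dim = counts.shape[-1]
    num = gammaln(counts + alpha).sum(axis=-1) - gammaln(counts.sum(axis=-1) + dim * alpha)
    den = dim * gammaln(alpha) - gammaln(dim * alpha)
    return float(np.sum(num - den))


def log_prob_phi_term(counts: CountTables, hp: Hyperparameters) -> float:
    """Collapsed contribution of P(W | Z): one DM normalizer per assemblage."""
    return _log_dirichlet_multinomial(counts.c_wl.T, hp.alpha_phi)


def log_prob_theta_term(counts: CountTables, hp: Hyperparameters) -> float:
    """Collapsed contribution of P(Z | X): one DM normalizer per factor."""
    return _log_dirichlet_multinomial(counts.c_kl, hp.alpha_theta)


def log_prob_pi_term(
    counts: CountTables, hp: Hyperparameters, allowed_sets: list
) -> float:
    """Collapsed contribution of P(X): per sample, a DM over its allowed factors."""
    out = 0.0
    for n, allowed in enumerate(allowed_sets):
        idx = np.asarray(sorted(allowed), dtype=np.int64)
        out += _log_dirichlet_multinomial(counts.c_nk[n, idx], hp.alpha_pi)
    return out


def collapsed_joint_log_prob(
    counts: CountTables,
    hp: Hyperparameters,
    allowed_sets: list,
) -> float:
    """log P(W, Z, X | alpha) with pi, theta, phi integrated out.

    A product of Dirichlet-multinomial normalizers: one per assemblage (OTU
    counts), one per factor (assemblage counts), and one per sample
    (factor counts, restricted to the sample's allowed set). Zero tokens give
    log-probability 0 (an empty product).
    """
    lp = (
        log_prob_phi_term(counts, hp)
        + log_prob_theta_term(counts, hp)
        + log_prob_pi_term(counts, hp, allowed_sets)
    )
    if not np.isfinite(lp):
        raise FloatingPointError("non-finite collapsed joint log probability")
    return lp


def estimate_mixtures(
    counts: CountTables,
    hp: Hyperparameters,
    allowed_sets: list | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior-mean pi (N x K), theta (K x L), phi (L x T) for one count state.

    Each row is the mean of the Dirichlet posterior implied by the counts:
    e.g. theta_kl = (C_kl + a_theta) / (sum_l' C_kl' + L*a_theta). pi rows are
    zero outside the allowed set when ``allowed_sets`` is given.
    """
    n_otus, n_assemblages = counts.c_wl.shape
    n_samples, n_factors = counts.c_nk.shape
    theta = (counts.c_kl + hp.alpha_theta) / (
        counts.factor_totals[:, None] + n_assemblages * hp.alpha_theta
    )
    phi = (counts.c_wl.T + hp.alpha_phi) / (
        counts.assemblage_totals[:, None] + n_otus * hp.alpha_phi
    )
    pi = np.zeros((n_samples, n_factors))
    if allowed_sets is None:
        allowed_sets = [range(n_factors)] * n_samples
    for n, allowed in enumerate(allowed_sets):
        idx = np.asarray(sorted(allowed), dtype=np.int64)
        denom = counts.c_nk[n, idx].sum() + idx.size * hp.alpha_pi
        pi[n, idx] = (counts.c_nk[n, idx] + hp.alpha_pi) / denom
    return pi, theta, phi
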