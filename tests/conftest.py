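"""Shared fixtures and independent oracles for the test suite.

The enumeration oracles here weight every possible joint assignment of a tiny
instance by the collapsed joint probability; they are deliberately simple and
independent of the samplers they validate.
"""

import itertools

import numpy as np
import pytest

from biomico.data_io import OtuTable, SampleLabels, TokenizedDataset
from biomico.model_core import (
    AssignmentState,
    CountTables,
    Dimensions,
    collapsed_joint_log_prob,
)


@pytest.fixture
def tiny_table():
    return OtuTable(
        sample_ids=["s1", "s2"],
        otu_ids=["otuA", "otuB", "otuC"],
        counts=np.array([[1, 0, 2], [0, 4, 0]]),
    )


@pytest.fixture
def tiny_labels():
    return [
        SampleLabels("s1", frozenset({0})),
        SampleLabels("s2", frozenset({1})),
    ]


@pytest.fixture
def tiny_tokenized():
    """Two samples, two tokens each, partial supervision on sample 2."""
    return TokenizedDataset(
        sample_ids=["s0", "s1"],
        tokens=[np.array([0, 1]), np.array([1, 1])],
        allowed_factors=[frozenset({0, 1}), frozenset({1})],
        n_otus=2,
        factor_names=["envA", "envB"],
    )


def enumerate_train_posterior(tok_otu, tok_sample, allowed, dims, hp):
    """Exact token-level marginals P(X_i=k), P(Z_i=l) by full enumeration.

    Every joint assignment of all tokens is weighted by
    exp(collapsed_joint_log_prob); supervision-violating assignments get
    weight zero.
    """
    n_tok = len(tok_otu)
    K, L = dims.n_factors, dims.n_assemblages
    pairs = list(itertools.product(range(K), range(L)))
    marg_x = np.zeros((n_tok, K))
    marg_z = np.zeros((n_tok, L))
    total = 0.0
    for assign in itertools.product(pairs, repeat=n_tok):
        x = np.array([a[0] for a in assign])
        z = np.array([a[1] for a in assign])
        if not all(x[t] in allowed[tok_sample[t]] for t in range(n_tok)):
            continue
        state = AssignmentState(np.asarray(tok_otu), np.asarray(tok_sample), x, z)
        counts = CountTables.from_state(state, dims)
        w = np.exp(collapsed_joint_log_prob(counts, hp, allowed))
        total += w
        for t in range(n_tok):
            marg_x[t, x[t]] += w
            marg_z[t, z[t]] += w
    return marg_x / total, marg_z / total, total


def enumerate_test_posterior(train_c_wl, train_c_kl, test_tokens, hp):
    """Exact factor posterior of one folded-in test sample by enumeration.

    Training counts are frozen; each joint assignment of the test tokens is
    weighted by the collapsed joint of the combined counts; the reported
    posterior is the expectation of the smoothed factor proportions
    (C_nk + alpha_pi) / (N_n + K * alpha_pi).
    """
    n_otus, n_assemblages = train_c_wl.shape
    n_factors = train_c_kl.shape[0]
    m = len(test_tokens)
    allowed = [frozenset(range(n_factors))]
    pairs = list(itertools.product(range(n_factors), range(n_assemblages)))
    post = np.zeros(n_factors)
    total = 0.0
    for assign in itertools.product(pairs, repeat=m):
        c_wl = train_c_wl.copy()
        c_kl = train_c_kl.copy()
        c_nk = np.zeros((1, n_factors), dtype=np.int64)
        for t, (k, l) in enumerate(assign):
            c_wl[test_tokens[t], l] += 1
            c_kl[k, l] += 1
            c_nk[0, k] += 1
        counts = CountTables(c_wl=c_wl, c_kl=c_kl, c_nk=c_nk)
        w = np.exp(collapsed_joint_log_prob(counts, hp, allowed))
        total += w
        post += w * (c_nk[0] + hp.alpha_pi) / (m + n_factors * hp.alpha_pi)
    return post / total


def make_dims(data: TokenizedDataset, n_assemblages: int) -> Dimensions:
    return Dimensions(
        n_samples=data.n_samples,
        n_factors=data.n_factors or (1 + max(max(a) for a in data.allowed_factors)),
        n_assemblages=n_assemblages,
        n_otus=data.n_otus,
        tokens_per_sample=data.tokens_per_sample(),
    )
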