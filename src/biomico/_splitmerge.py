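"""Split-merge Metropolis-Hastings move over assemblage assignments.

Single-token Gibbs updates mix poorly across alternative assemblage
decompositions: moving a coherent group of OTU tokens between assemblages
requires passing through low-probability intermediate states. The
sequentially-allocated split-merge move proposes reorganizing entire
assemblages at once: two anchor tokens are drawn; if they share an assemblage
its members are split into two (one of which must be a currently empty
assemblage), and if they differ the two assemblages are merged. Proposals are
built by restricted Gibbs allocation between the two candidate assemblages -
several launch scans refine a random initial split, and the transition
probability of one final scan enters the Metropolis-Hastings ratio, with the
collapsed joint probability supplying the target ratio. The move is exact
(leaves the collapsed posterior invariant) and complements the token-level
sweeps; it never changes factor assignments, so supervision constraints are
untouched.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit
from scipy.special import gammaln

__all__ = ["split_merge_move", "block_swap_pass"]

_N_LAUNCH_SCANS = 5


@njit(cache=True)
def _restricted_scans(
    tok_w,
    tok_k,
    side,
    c_w1,
    c_w2,
    c_k1,
    c_k2,
    a_phi,
    a_theta,
    n_otus,
    uniforms,
    forced,
    n_scans,
):  # pragma: no cover - exercised via split_merge_move()
    """Run restricted Gibbs scans reassigning each token between two assemblages.

    ``side[t]`` is 0/1 for assemblage one/two; counts include all of S plus the
    two anchors (anchor counts never move). The final scan's realized
    transition log-probability is returned; earlier scans only refine the
    state. When ``forced`` is true the final scan is forced to reproduce
    ``side`` as given on entry (the dry run for a merge's reverse move), and
    earlier scans operate on a scratch copy ending at that state.
    """
    m = tok_w.shape[0]
    t1 = c_w1.sum()
    t2 = c_w2.sum()
    log_q = 0.0
    u_idx = 0
    for scan in range(n_scans):
        last = scan == n_scans - 1
        for t in range(m):
            w = tok_w[t]
            k = tok_k[t]
            # remove token t from its current side
            if side[t] == 0:
                c_w1[w] -= 1
                c_k1[k] -= 1
                t1 -= 1
            else:
                c_w2[w] -= 1
                c_k2[k] -= 1
                t2 -= 1
            w1 = (c_w1[w] + a_phi) / (t1 + n_otus * a_phi) * (c_k1[k] + a_theta)
            w2 = (c_w2[w] + a_phi) / (t2 + n_otus * a_phi) * (c_k2[k] + a_theta)
            p2 = w2 / (w1 + w2)
            if last and forced:
                pick = side[t]
            else:
                pick = 1 if uniforms[u_idx] < p2 else 0
                u_idx += 1
            if last:
                log_q += np.log(p2 if pick == 1 else 1.0 - p2)
            side[t] = pick
            if pick == 0:
                c_w1[w] += 1
                c_k1[k] += 1
                t1 += 1
            else:
                c_w2[w] += 1
                c_k2[k] += 1
                t2 += 1
    return log_q


def _column_term(c_w: np.ndarray, c_k: np.ndarray, a_phi: float, a_theta: float) -> float:
    """Collapsed-joint contribution that depends on one assemblage column."""
    n_otus = c_w.shape[0]
    return float(
        gammaln(c_w + a_phi).sum()
        - gammaln(c_w.sum() + n_otus * a_phi)
        + gammaln(c_k + a_theta).sum()
    )


def _rebuild_columns(state, counts, cols) -> None:
    for l in cols:
        members = state.z == l
        cw = np.bincount(state.token_otu[members], minlength=counts.c_wl.shape[0])
        ck = np.bincount(state.x[members], minlength=counts.c_kl.shape[0])
        counts.c_wl[:, l] = cw
        counts.c_kl[:, l] = ck
        counts.assemblage_totals[l] = cw.sum()
        counts.factor_totals[:] = counts.c_kl.sum(axis=1)


def split_merge_move(state, counts, hp, rng: np.random.Generator) -> bool:
    """Propose one split or merge of assemblages; returns True if accepted."""
    n = state.n_tokens
    if n < 2:
        return False
    n_otus, n_assemblages = counts.c_wl.shape
    n_factors = counts.c_kl.shape[0]
    i, j = rng.choice(n, size=2, replace=False)
    li, lj = int(state.z[i]), int(state.z[j])
    a_phi, a_theta = float(hp.alpha_phi), float(hp.alpha_theta)

    if li == lj:
        empties = np.flatnonzero(counts.assemblage_totals == 0)
        if empties.size == 0:
            return False
        l_new = int(empties[rng.integers(empties.size)])
        members = np.flatnonzero(state.z == li)
        S = members[(members != i) & (members != j)]
        tok_w = state.token_otu[S].astype(np.int64)
        tok_k = state.x[S].astype(np.int64)
        side = (rng.random(S.size) < 0.5).astype(np.int8)
        c_w1 = np.zeros(n_otus, dtype=np.float64)
        c_w2 = np.zeros(n_otus, dtype=np.float64)
        c_k1 = np.zeros(n_factors, dtype=np.float64)
        c_k2 = np.zeros(n_factors, dtype=np.float64)
        c_w1[state.token_otu[i]] += 1
        c_k1[state.x[i]] += 1
        c_w2[state.token_otu[j]] += 1
        c_k2[state.x[j]] += 1
        np.add.at(c_w1, tok_w[side == 0], 1)
        np.add.at(c_k1, tok_k[side == 0], 1)
        np.add.at(c_w2, tok_w[side == 1], 1)
        np.add.at(c_k2, tok_k[side == 1], 1)
        uniforms = rng.random(S.size * (_N_LAUNCH_SCANS + 1))
        log_q = _restricted_scans(
            tok_w, tok_k, side, c_w1, c_w2, c_k1, c_k2,
            a_phi, a_theta, n_otus, uniforms, False, _N_LAUNCH_SCANS + 1,
        )
        old = _column_term(
            counts.c_wl[:, li].astype(np.float64),
            counts.c_kl[:, li].astype(np.float64),
            a_phi, a_theta,
        ) + _column_term(
            np.zeros(n_otus), np.zeros(n_factors), a_phi, a_theta
        )
        new = _column_term(c_w1, c_k1, a_phi, a_theta) + _column_term(
            c_w2, c_k2, a_phi, a_theta
        )
        log_acc = (new - old) - log_q + np.log(empties.size)
        if np.log(rng.random()) < log_acc:
            state.z[S[side == 1]] = l_new
            state.z[j] = l_new
            _rebuild_columns(state, counts, (li, l_new))
            return True
        return False

    # merge lj into li; the reverse move is a split of the merged assemblage
    mem_i = np.flatnonzero(state.z == li)
    mem_j = np.flatnonzero(state.z == lj)
    S = np.concatenate([mem_i[mem_i != i], mem_j[mem_j != j]])
    tok_w = state.token_otu[S].astype(np.int64)
    tok_k = state.x[S].astype(np.int64)
    target = (state.z[S] == lj).astype(np.int8)
    side = (rng.random(S.size) < 0.5).astype(np.int8)
    c_w1 = np.zeros(n_otus, dtype=np.float64)
    c_w2 = np.zeros(n_otus, dtype=np.float64)
    c_k1 = np.zeros(n_factors, dtype=np.float64)
    c_k2 = np.zeros(n_factors, dtype=np.float64)
    c_w1[state.token_otu[i]] += 1
    c_k1[state.x[i]] += 1
    c_w2[state.token_otu[j]] += 1
    c_k2[state.x[j]] += 1
    np.add.at(c_w1, tok_w[side == 0], 1)
    np.add.at(c_k1, tok_k[side == 0], 1)
    np.add.at(c_w2, tok_w[side == 1], 1)
    np.add.at(c_k2, tok_k[side == 1], 1)
    uniforms = rng.random(S.size * _N_LAUNCH_SCANS)
    if _N_LAUNCH_SCANS > 0:
        _restricted_scans(
            tok_w, tok_k, side, c_w1, c_w2, c_k1, c_k2,
            a_phi, a_theta, n_otus, uniforms, False, _N_LAUNCH_SCANS,
        )
    # forced final scan reproducing the current split, from the launch state
    log_q_rev = _forced_final_scan(
        tok_w, tok_k, side.copy(), target, c_w1, c_w2, c_k1, c_k2,
        a_phi, a_theta, n_otus,
    )
    old = _column_term(
        counts.c_wl[:, li].astype(np.float64),
        counts.c_kl[:, li].astype(np.float64),
        a_phi, a_theta,
    ) + _column_term(
        counts.c_wl[:, lj].astype(np.float64),
        counts.c_kl[:, lj].astype(np.float64),
        a_phi, a_theta,
    )
    merged_w = (counts.c_wl[:, li] + counts.c_wl[:, lj]).astype(np.float64)
    merged_k = (counts.c_kl[:, li] + counts.c_kl[:, lj]).astype(np.float64)
    new = _column_term(merged_w, merged_k, a_phi, a_theta) + _column_term(
        np.zeros(n_otus), np.zeros(n_factors), a_phi, a_theta
    )
    n_empty_after = int((counts.assemblage_totals == 0).sum()) + 1
    log_acc = (new - old) + log_q_rev - np.log(n_empty_after)
    if np.log(rng.random()) < log_acc:
        state.z[state.z == lj] = li
        _rebuild_columns(state, counts, (li, lj))
        return True
    return False


@njit(cache=True)
def _block_swap_kernel(
    otu_ptr,
    otu_tok,
    x,
    z,
    c_wl,
    c_kl,
    assemblage_totals,
    a_phi,
    a_theta,
    otus,
    ks,
    l1s,
    l2s,
    log_us,
):  # pragma: no cover - exercised via block_swap_pass()
    n_otus = c_wl.shape[0]
    n_acc = 0
    for p in range(otus.shape[0]):
        w = otus[p]
        k = ks[p]
        l1 = l1s[p]
        l2 = l2s[p]
        a = 0
        b = 0
        for j in range(otu_ptr[w], otu_ptr[w + 1]):
            t = otu_tok[j]
            if x[t] == k:
                if z[t] == l1:
                    a += 1
                elif z[t] == l2:
                    b += 1
        if a == 0 and b == 0:
            continue
        d = b - a
        c1 = c_wl[w, l1]
        c2 = c_wl[w, l2]
        t1 = assemblage_totals[l1]
        t2 = assemblage_totals[l2]
        k1 = c_kl[k, l1]
        k2 = c_kl[k, l2]
        dlp = (
            _lgamma(c1 + d + a_phi) - _lgamma(c1 + a_phi)
            + _lgamma(c2 - d + a_phi) - _lgamma(c2 + a_phi)
            - _lgamma(t1 + d + n_otus * a_phi) + _lgamma(t1 + n_otus * a_phi)
            - _lgamma(t2 - d + n_otus * a_phi) + _lgamma(t2 + n_otus * a_phi)
            + _lgamma(k1 + d + a_theta) - _lgamma(k1 + a_theta)
            + _lgamma(k2 - d + a_theta) - _lgamma(k2 + a_theta)
        )
        if log_us[p] < dlp:
            n_acc += 1
            for j in range(otu_ptr[w], otu_ptr[w + 1]):
                t = otu_tok[j]
                if x[t] == k:
                    if z[t] == l1:
                        z[t] = l2
                    elif z[t] == l2:
                        z[t] = l1
            c_wl[w, l1] += d
            c_wl[w, l2] -= d
            assemblage_totals[l1] += d
            assemblage_totals[l2] -= d
            c_kl[k, l1] += d
            c_kl[k, l2] -= d
    return n_acc


@njit(cache=True)
def _lgamma(v):  # pragma: no cover
    return math.lgamma(v)


def block_swap_pass(state, counts, hp, rng: np.random.Generator, proposals_per_otu: int = 4) -> int:
    """Metropolis pass of OTU-block swaps between assemblage pairs.

    Each proposal picks an OTU w, a factor k and an assemblage pair (l1, l2)
    and exchanges *all* of w's tokens assigned to (k, l1) with those assigned
    to (k, l2). The move is an involution with a symmetric selection
    probability, so acceptance is min(1, exp(delta collapsed joint log prob));
    the pi term is unaffected (factor assignments do not change). These
    coordinated moves relocate whole OTU columns that single-token updates
    cannot shift once counts are entrenched.
    """
    n_otus, n_assemblages = counts.c_wl.shape
    n_factors = counts.c_kl.shape[0]
    if n_assemblages < 2:
        return 0
    # CSR index of tokens by OTU; token_otu never changes, so cache it
    cache = getattr(state, "_otu_index_cache", None)
    if cache is None or cache[2] is not state.token_otu:
        order = np.argsort(state.token_otu, kind="stable").astype(np.int64)
        ptr = np.zeros(n_otus + 1, dtype=np.int64)
        np.cumsum(
            np.bincount(state.token_otu, minlength=n_otus), out=ptr[1:]
        )
        cache = (ptr, order, state.token_otu)
        state._otu_index_cache = cache
    otu_ptr, otu_tok, _ = cache
    n_props = n_otus * proposals_per_otu
    otus = rng.integers(0, n_otus, size=n_props)
    ks = rng.integers(0, n_factors, size=n_props)
    l1s = rng.integers(0, n_assemblages, size=n_props)
    shift = rng.integers(1, n_assemblages, size=n_props)
    l2s = (l1s + shift) % n_assemblages
    log_us = np.log(rng.random(n_props))
    return int(
        _block_swap_kernel(
            otu_ptr,
            otu_tok,
            state.x,
            state.z,
            counts.c_wl,
            counts.c_kl,
            counts.assemblage_totals,
            float(hp.alpha_phi),
            float(hp.alpha_theta),
            otus,
            ks,
            l1s,
            l2s,
            log_us,
        )
    )


@njit(cache=True)
def _forced_final_scan(
    tok_w,
    tok_k,
    side,
    target,
    c_w1,
    c_w2,
    c_k1,
    c_k2,
    a_phi,
    a_theta,
    n_otus,
):  # pragma: no cover - exercised via split_merge_move()
    """One restricted Gibbs scan forced to land on ``target``; returns its log-prob."""
    m = tok_w.shape[0]
    t1 = c_w1.sum()
    t2 = c_w2.sum()
    log_q = 0.0
    for t in range(m):
        w = tok_w[t]
        k = tok_k[t]
        if side[t] == 0:
            c_w1[w] -= 1
            c_k1[k] -= 1
            t1 -= 1
        else:
            c_w2[w] -= 1
            c_k2[k] -= 1
            t2 -= 1
        w1 = (c_w1[w] + a_phi) / (t1 + n_otus * a_phi) * (c_k1[k] + a_theta)
        w2 = (c_w2[w] + a_phi) / (t2 + n_otus * a_phi) * (c_k2[k] + a_theta)
        p2 = w2 / (w1 + w2)
        pick = target[t]
        log_q += np.log(p2 if pick == 1 else 1.0 - p2)
        side[t] = pick
        if pick == 0:
            c_w1[w] += 1
            c_k1[k] += 1
            t1 += 1
        else:
            c_w2[w] += 1
            c_k2[k] += 1
            t2 += 1
    return log_q
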