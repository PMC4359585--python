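"""Compiled inner loop of the collapsed Gibbs sampler.

One sweep resamples every token's joint (factor, assemblage) assignment from
the collapsed full conditional, updating the count tables immediately so each
draw conditions on all previous ones. All randomness (visit order, uniform
variates for the categorical draws) is generated by the caller's
``numpy.random.Generator`` and passed in, keeping the kernel deterministic
given its inputs.

The pi-term denominator is constant across candidate (k, l) pairs for a fixed
token (the sample's token total is fixed), so it is omitted from the
unnormalized weights.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sweep"]


@njit(cache=True)
def _sweep_kernel(
    token_otu,
    token_sample,
    x,
    z,
    allowed_mask,
    c_wl,
    c_kl,
    c_nk,
    assemblage_totals,
    factor_totals,
    sample_totals,
    alpha_pi,
    alpha_theta,
    alpha_phi,
    order,
    uniforms,
):  # pragma: no cover - exercised via sweep()
    n_otus, n_assemblages = c_wl.shape
    n_factors = c_kl.shape[0]
    weights = np.empty((n_factors, n_assemblages), dtype=np.float64)
    t_alpha_phi = n_otus * alpha_phi
    l_alpha_theta = n_assemblages * alpha_theta
    for pos in range(order.shape[0]):
        i = order[pos]
        w = token_otu[i]
        n = token_sample[i]
        k0 = x[i]
        l0 = z[i]
        # remove the token from the state
        c_wl[w, l0] -= 1
        c_kl[k0, l0] -= 1
        c_nk[n, k0] -= 1
        assemblage_totals[l0] -= 1
        factor_totals[k0] -= 1
        sample_totals[n] -= 1
        # unnormalized joint conditional over (k, l)
        total = 0.0
        for k in range(n_factors):
            if allowed_mask[n, k]:
                pi_w = c_nk[n, k] + alpha_pi
                theta_denom = factor_totals[k] + l_alpha_theta
                for l in range(n_assemblages):
                    val = (
                        pi_w
                        * (c_kl[k, l] + alpha_theta)
                        / theta_denom
                        * (c_wl[w, l] + alpha_phi)
                        / (assemblage_totals[l] + t_alpha_phi)
                    )
                    weights[k, l] = val
                    total += val
            else:
                for l in range(n_assemblages):
                    weights[k, l] = 0.0
        # categorical draw via a single uniform
        r = uniforms[pos] * total
        acc = 0.0
        new_k = -1
        new_l = -1
        done = False
        for k in range(n_factors):
            if done or not allowed_mask[n, k]:
                continue
            for l in range(n_assemblages):
                acc += weights[k, l]
                if acc >= r:
                    new_k = k
                    new_l = l
                    done = True
                    break
        if not done:
            # numerical tail: fall back to the last allowed pair
            for k in range(n_factors):
                if allowed_mask[n, k]:
                    new_k = k
            new_l = n_assemblages - 1
        # add the token back with its new assignment
        x[i] = new_k
        z[i] = new_l
        c_wl[w, new_l] += 1
        c_kl[new_k, new_l] += 1
        c_nk[n, new_k] += 1
        assemblage_totals[new_l] += 1
        factor_totals[new_k] += 1
        sample_totals[n] += 1


def sweep(state, counts, allowed_mask: np.ndarray, hp, rng: np.random.Generator) -> None:
    """Run one full Gibbs sweep in place over ``state`` and ``counts``.

    Tokens are visited in a freshly randomized order drawn from ``rng``.
    """
    n_tokens = state.n_tokens
    if n_tokens == 0:
        return
    order = rng.permutation(n_tokens).astype(np.int64)
    uniforms = rng.random(n_tokens)
    _sweep_kernel(
        state.token_otu,
        state.token_sample,
        state.x,
        state.z,
        allowed_mask,
        counts.c_wl,
        counts.c_kl,
        counts.c_nk,
        counts.assemblage_totals,
        counts.factor_totals,
        counts.sample_totals,
        hp.alpha_pi,
        hp.alpha_theta,
        hp.alpha_phi,
        order,
        uniforms,
    )
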