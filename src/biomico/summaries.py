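"""Post-hoc interpretation of trained models.

Support sets (the minimal highest-probability items reaching a posterior-
density cutoff, 95% by convention), predominant-OTU extraction by top-n or by
the largest relative drop in the sorted distribution, factor-level OTU
profiles (assemblage-marginalized), and label-switching-aware matching of
assemblages between runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "SupportSet",
    "support_set",
    "predominant_otus",
    "factor_otu_profile",
    "match_assemblages",
]


@dataclass(frozen=True)
class SupportSet:
    """Items (assemblages or OTUs) ranked by probability, with their cumulative mass."""

    items: np.ndarray
    probabilities: np.ndarray
    cumulative: float
    cutoff: float

    def __len__(self) -> int:
        return len(self.items)


def _check_probability_vector(p: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a one-dimensional, non-empty probability vector")
    if (p < -tol).any():
        raise ValueError("negative probabilities")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"probabilities sum to {p.sum():.6f}, not 1")
    return np.clip(p, 0.0, None)


def support_set(probabilities: np.ndarray, cutoff: float = 0.95) -> SupportSet:
    """Minimal set of highest-probability items whose mass reaches ``cutoff``.

    Items are taken in descending probability order (ties broken toward the
    lower index) until the cumulative probability first reaches the cutoff, so
    dropping the last item would fall below it.
    """
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must be in (0, 1)")
    p = _check_probability_vector(probabilities)
    # stable sort on -p keeps lower indices first among ties
    order = np.argsort(-p, kind="stable")
    csum = np.cumsum(p[order])
    n_items = int(np.searchsorted(csum, cutoff - 1e-12) + 1)
    n_items = min(n_items, p.size)
    return SupportSet(
        items=order[:n_items],
        probabilities=p[order[:n_items]],
        cumulative=float(csum[n_items - 1]),
        cutoff=cutoff,
    )


def predominant_otus(
    phi_marginal: np.ndarray, rule: str = "inflection", n: int | None = None
) -> SupportSet:
    """Extract the predominant OTUs of a posterior OTU distribution.

    ``rule='top_n'`` returns the ``n`` highest-probability OTUs.
    ``rule='inflection'`` returns the prefix of the sorted distribution before
    the largest relative drop (the maximum ratio p_(i)/p_(i+1)); on a flat
    distribution no drop exists and the full set is returned with a warning.
    The reported cutoff is the cumulative density captured.
    """
    p = _check_probability_vector(phi_marginal)
    order = np.argsort(-p, kind="stable")
    sorted_p = p[order]
    if rule == "top_n":
        if n is None:
            raise ValueError("top_n rule requires n")
        if n > p.size:
            raise ValueError(f"n={n} exceeds the number of OTUs ({p.size})")
        cut = n
    elif rule == "inflection":
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(sorted_p[1:] > 0, sorted_p[:-1] / sorted_p[1:], np.inf)
        finite_drop = ratios[np.isfinite(ratios)]
        positive = sorted_p[:-1] > 0
        ratios = np.where(positive, ratios, 1.0)
        if p.size < 2 or np.allclose(ratios, 1.0) or (finite_drop.size and np.all(np.isclose(finite_drop, 1.0)) and not np.isinf(ratios).any()):
            warnings.warn("no inflection point in a flat distribution; returning all OTUs")
            cut = p.size
        else:
            cut = int(np.argmax(ratios) + 1)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    cumulative = float(sorted_p[:cut].sum())
    return SupportSet(
        items=order[:cut],
        probabilities=sorted_p[:cut],
        cumulative=cumulative,
        cutoff=cumulative,
    )


def factor_otu_profile(theta_k: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """OTU mixing probabilities of one factor, marginalized over assemblages.

    Returns sum_l theta_kl * phi_l (a length-T probability vector).
    """
    theta_k = np.asarray(theta_k, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    if theta_k.ndim != 1 or phi.ndim != 2 or theta_k.size != phi.shape[0]:
        raise ValueError("theta_k must have one weight per phi row")
    return theta_k @ phi


def match_assemblages(
    phi_a: np.ndarray, phi_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one assemblage matching between two phi matrices.

    Maximizes the summed cosine similarity of matched rows (Hungarian
    assignment). Returns ``perm`` with ``phi_b[perm[l]]`` matched to
    ``phi_a[l]``, and the per-pair similarities. Zero rows match with
    similarity 0.
    """
    phi_a = np.asarray(phi_a, dtype=np.float64)
    phi_b = np.asarray(phi_b, dtype=np.float64)
    if phi_a.shape != phi_b.shape:
        raise ValueError("phi matrices must have identical shapes")
    norm_a = np.linalg.norm(phi_a, axis=1, keepdims=True)
    norm_b = np.linalg.norm(phi_b, axis=1, keepdims=True)
    ua = np.divide(phi_a, norm_a, out=np.zeros_like(phi_a), where=norm_a > 0)
    ub = np.divide(phi_b, norm_b, out=np.zeros_like(phi_b), where=norm_b > 0)
    sim = ua @ ub.T
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(phi_a.shape[0], dtype=np.int64)
    perm[rows] = cols
    return perm, sim[rows, cols]
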