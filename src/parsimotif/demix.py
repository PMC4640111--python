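"""Multiple-motif detection: two-PWM mixture fitting and Jensen-Shannon divergence.

A dependency-aware motif model can absorb two distinct motifs co-occurring in one
data set into a single "motif" with strong apparent dependencies. To flag this, the
predicted binding sites are clustered with a two-component mixture of PWMs (EM). The
per-column Jensen-Shannon divergence between the two components, weighted by the
cluster weights, is summed over all columns; if the average of this aggregate over
model orders 1-4 stays below 0.18 the site set is categorized as a single motif
(category A), otherwise as a putative mixture of motifs (category B). Natural
logarithms throughout, so one column contributes at most ln 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .seqdata import ALPHABET_SIZE, SiteSet

JSD_THRESHOLD = 0.18


@dataclass
class MixtureFit:
    """Converged two-component PWM mixture: weights, components, final log-likelihood."""

    weights: np.ndarray  # (2,)
    components: np.ndarray  # (2, W, 4)
    log_likelihood: float
    n_iter: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9 or np.any(self.weights < 0):
            raise ValueError("mixture weights must be a distribution")


def fit_two_pwm_mixture(
    sites: SiteSet,
    restarts: int = 20,
    tol: float = 1e-6,
    seed: int | None = None,
    pseudocount: float = 0.1,
    max_iter: int = 500,
) -> MixtureFit:
    """EM for a two-component product-multinomial (PWM) mixture over aligned sites.

    Components are initialized from per-column Dirichlet draws; the best of
    ``restarts`` runs by final log-likelihood wins. M-steps add ``pseudocount`` to
    every cell so no column ever collapses to zero probability. Identical inputs are
    handled gracefully: both components converge to the common PWM.
    """
    if len(sites) < 2:
        raise ValueError("mixture fitting needs at least two sites")
    enc = sites.encoded().astype(np.int64)
    n, w = enc.shape
    onehot = np.eye(ALPHABET_SIZE)[enc]  # (n, w, 4)
    cols = np.arange(w)
    rng = np.random.default_rng(seed)
    best: MixtureFit | None = None
    for _ in range(restarts):
        comps = rng.dirichlet(np.ones(ALPHABET_SIZE), size=(2, w))
        weights = np.array([0.5, 0.5])
        prev_ll = -np.inf
        for it in range(1, max_iter + 1):
            with np.errstate(divide="ignore"):
                logc = np.log(comps)
                logw = np.log(weights)
            site_ll = np.stack([logc[k][cols, enc].sum(axis=1) for k in range(2)], axis=1)
            joint = site_ll + logw
            norm = logsumexp(joint, axis=1)
            ll = float(norm.sum())
            resp = np.exp(joint - norm[:, None])
            weights = resp.sum(axis=0) / n
            counts = np.einsum("ik,ija->kja", resp, onehot) + pseudocount
            comps = counts / counts.sum(axis=2, keepdims=True)
            if ll - prev_ll < tol and it > 1:
                break
            prev_ll = ll
        if best is None or ll > best.log_likelihood:
            best = MixtureFit(weights, comps, ll, it)
    assert best is not None
    return best


def kld(p, q) -> float:
    """Kullback-Leibler divergence ``sum_i p_i ln(p_i/q_i)``; 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    mask = p > 0
    if np.any(q[mask] == 0):
        raise ValueError("KLD undefined: q has zero mass where p does not")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def column_jsd(p1, p2, w1: float, w2: float) -> float:
    """Weighted Jensen-Shannon divergence of one PWM column pair; in [0, ln 2]."""
    if abs(w1 + w2 - 1.0) > 1e-9 or w1 < 0 or w2 < 0:
        raise ValueError("weights must be non-negative and sum to 1")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    mix = w1 * p1 + w2 * p2
    out = 0.0
    if w1 > 0:
        out += w1 * kld(p1, mix)
    if w2 > 0:
        out += w2 * kld(p2, mix)
    return out


def motif_jsd(fit: MixtureFit) -> float:
    """Aggregate JSD of a fitted mixture: sum of the column JSDs over all positions."""
    w1, w2 = fit.weights
    return float(
        sum(
            column_jsd(fit.components[0][j], fit.components[1][j], w1, w2)
            for j in range(fit.components.shape[1])
        )
    )


def categorize(jsd_values, threshold: float = JSD_THRESHOLD) -> str:
    """Average the supplied per-order JSD values and map to category 'A' or 'B'.

    Strictly below the threshold means a single motif (A); the boundary value is
    assigned to B, since only "smaller" divergences qualify as single-motif.
    """
    values = np.asarray(list(jsd_values), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one JSD value")
    return "A" if values.mean() < threshold else "B"
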