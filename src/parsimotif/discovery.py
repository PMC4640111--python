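"""Stochastic de novo motif discovery by latent-variable sampling + exact refitting.

The discovery objective is the latent configuration ``(v, s)`` whose extracted site
set maximizes the summed per-position BIC structure score. The search interleaves two
steps: (i) given latents, the motif model is refit *exactly* (BIC-optimal PCTs,
fsNML parameters); (ii) given the model, a new latent configuration is sampled per
sequence from the categorical distribution proportional to the conditional sequence
likelihood over all (position, strand) pairs — a Gibbs-sampler-style move that lets
the chain escape local optima a deterministic EM would be trapped in.

Each of R restarts begins from uniformly random latents, runs at least T iterations,
and stops once T' consecutive iterations pass without score improvement. The best
(score, latents) pair across all iterations and restarts wins, and the final model is
refit from those latents, so the reported model, score, and latents are mutually
consistent. All randomness flows from one master seed through per-restart streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .oops import FlankingModel, OOPSModel, fit_flanking, scan_sequence
from .pmm import fit_motif
from .seqdata import LatentConfig, SequenceSet, extract_sites

SCORE_TOL = 1e-9
MAX_ITER = 1000


@dataclass
class DiscoveryConfig:
    width: int = 20
    order: int = 2
    min_iter: int = 50  # T
    patience: int = 10  # T'
    restarts: int = 10  # R
    seed: int | None = None
    flank_order: int = 2

    def __post_init__(self) -> None:
        if self.min_iter < 1 or self.patience < 1 or self.restarts < 1:
            raise ValueError("min_iter, patience, and restarts must all be >= 1")
        if self.width < 1 or self.order < 0:
            raise ValueError("width must be >= 1 and order >= 0")


@dataclass
class DiscoveryResult:
    model: OOPSModel
    latents: LatentConfig
    score: float
    restart: int
    iteration: int


def _check_lengths(data: SequenceSet, width: int) -> None:
    for sid, L in zip(data.ids, data.lengths):
        if L < width:
            raise ValueError(f"sequence {sid!r} (length {L}) is shorter than width {width}")


def init_latents(data: SequenceSet, width: int, rng: np.random.Generator) -> LatentConfig:
    """Uniformly random start positions and strands."""
    _check_lengths(data, width)
    v = np.array([rng.integers(1, L - width + 2) for L in data.lengths])
    s = np.where(rng.random(len(data)) < 0.5, "F", "R")
    return LatentConfig(v, s)


def sample_latents(
    model: OOPSModel, data: SequenceSet, rng: np.random.Generator
) -> LatentConfig:
    """Draw ``(v_i, s_i)`` per sequence proportional to the conditional likelihood.

    Probabilities are normalized in log space, so arbitrarily small likelihoods
    cannot underflow the categorical draw.
    """
    vs, ss = [], []
    for x in data.encoded():
        cond_f, cond_r, _ = scan_sequence(model, x)
        logp = np.concatenate((cond_f, cond_r))
        logp = logp - logp.max()
        p = np.exp(logp)
        p /= p.sum()
        k = rng.choice(len(p), p=p)
        n_win = len(cond_f)
        vs.append(k % n_win + 1)
        ss.append("F" if k < n_win else "R")
    return LatentConfig(np.array(vs), np.array(ss))


def discover(
    data: SequenceSet, config: DiscoveryConfig, flanking: FlankingModel | None = None
) -> DiscoveryResult:
    """Run the full stochastic discovery and return the best-scoring solution.

    The flanking model is estimated once from ``data`` (or taken from the caller,
    e.g. when it was fit on positives plus negatives) and held fixed: the objective
    concerns only the motif's structure score, and under a fixed flanking model the
    sampling distribution over latents is unaffected by this choice.
    """
    _check_lengths(data, config.width)
    if flanking is None:
        flanking = fit_flanking(data, config.flank_order)
    best: tuple[float, LatentConfig, int, int] | None = None
    for r in range(config.restarts):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=0 if config.seed is None else config.seed,
                                   spawn_key=(r,))
        )
        latents = init_latents(data, config.width, rng)
        restart_best = -np.inf
        stale = 0
        for t in range(1, MAX_ITER + 1):
            sites = extract_sites(data, latents, config.width)
            model, score = fit_motif(sites, config.order)
            if score > restart_best + SCORE_TOL:
                restart_best = score
                stale = 0
            else:
                stale += 1
            if best is None or score > best[0] + SCORE_TOL:
                best = (score, latents, r, t)
            if t >= config.min_iter and stale >= config.patience:
                break
            latents = sample_latents(OOPSModel(model, flanking), data, rng)
    assert best is not None
    score, latents, restart, iteration = best
    sites = extract_sites(data, latents, config.width)
    final_model, final_score = fit_motif(sites, config.order)
    assert abs(final_score - score) < 1e-6
    return DiscoveryResult(OOPSModel(final_model, flanking), latents, final_score, restart, iteration)
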