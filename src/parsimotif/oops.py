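"""The one-occurrence-per-sequence (OOPS) latent-variable model.

Each input sequence is assumed to contain exactly one motif instance at an unknown
start ``v`` on an unknown strand ``s``. Conditional on ``(v, s)`` the sequence
factorizes into a prefix flank, the motif window (reverse-complemented for the R
strand), and a suffix flank. Flanks are scored by a homogeneous Markov model of order
``h`` (default 2); each flanking segment restarts from the model's initial
distributions, exactly matching the factorized conditional likelihood — nothing is
conditioned across the motif.

Priors over the latent variables are uniform: ``P(v) = 1/(L-W+1)`` and ``P(s) = 1/2``,
the standard OOPS choice. The strand-marginalized joint ``P(x, v)`` is the quantity
scanned during binding-site prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .pmm import MotifModel, motif_log_likelihood
from .seqdata import ALPHABET_SIZE, SequenceSet, encode, reverse_complement

LOG_HALF = float(np.log(0.5))


@dataclass
class FlankingModel:
    """Homogeneous Markov model of order ``h`` for background / flanking segments.

    ``initial[k]`` (shape ``(4**k, 4)``) is the conditional distribution of a
    segment's ``(k+1)``-th symbol given its first ``k`` symbols, for ``k < h``;
    ``trans`` (shape ``(4**h, 4)``) applies from segment position ``h+1`` onward.
    """

    order: int
    initial: list[np.ndarray]
    trans: np.ndarray
    _logs: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("flanking order must be >= 0")
        if len(self.initial) != self.order:
            raise ValueError(f"need {self.order} initial distribution blocks")
        self.trans = np.asarray(self.trans, dtype=float)
        if self.trans.shape != (ALPHABET_SIZE**self.order, ALPHABET_SIZE):
            raise ValueError(f"transition table has shape {self.trans.shape}")
        blocks = [np.asarray(b, dtype=float) for b in self.initial]
        for k, b in enumerate(blocks):
            if b.shape != (ALPHABET_SIZE**k, ALPHABET_SIZE):
                raise ValueError(f"initial block {k} has shape {b.shape}")
        for b in blocks + [self.trans]:
            if np.any(b < 0) or np.any(np.abs(b.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("flanking distributions must be normalized")
        self.initial = blocks

    @classmethod
    def uniform(cls, order: int) -> "FlankingModel":
        initial = [np.full((ALPHABET_SIZE**k, ALPHABET_SIZE), 0.25) for k in range(order)]
        return cls(order, initial, np.full((ALPHABET_SIZE**order, ALPHABET_SIZE), 0.25))

    def logs(self) -> tuple[list[np.ndarray], np.ndarray]:
        if self._logs is None:
            with np.errstate(divide="ignore"):
                self._logs = ([np.log(b) for b in self.initial], np.log(self.trans))
        return self._logs

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "initial": [b.tolist() for b in self.initial],
            "trans": self.trans.tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FlankingModel":
        return cls(
            data["order"],
            [np.asarray(b, dtype=float) for b in data["initial"]],
            np.asarray(data["trans"], dtype=float),
        )


def fit_flanking(data: SequenceSet, order: int = 2) -> FlankingModel:
    """Estimate a homogeneous Markov model from pooled counts with add-one smoothing.

    Full-order conditionals come from every position with a complete context;
    the initial distributions of orders ``0 .. h-1`` come from pooled sequence
    prefixes. Add-one smoothing keeps every conditional strictly positive, which
    matters only for short or skewed inputs.
    """
    if len(data) == 0:
        raise ValueError("cannot fit a flanking model on empty data")
    h = order
    init_counts = [np.zeros((ALPHABET_SIZE**k, ALPHABET_SIZE)) for k in range(h)]
    trans_counts = np.zeros((ALPHABET_SIZE**h, ALPHABET_SIZE))
    for x in data.encoded():
        x = x.astype(np.int64)
        for k in range(min(h, len(x))):
            ctx = 0
            for u in range(k):  # prefix x[0:k], big-endian
                ctx = ctx * ALPHABET_SIZE + x[u]
            init_counts[k][ctx, x[k]] += 1
        if len(x) > h:
            codes = np.zeros(len(x) - h, dtype=np.int64)
            for u in range(h):
                codes += x[u : len(x) - h + u] * ALPHABET_SIZE ** (h - 1 - u)
            np.add.at(trans_counts, (codes, x[h:]), 1)
    initial = [(b + 1.0) / (b + 1.0).sum(axis=1, keepdims=True) for b in init_counts]
    trans = (trans_counts + 1.0) / (trans_counts + 1.0).sum(axis=1, keepdims=True)
    return FlankingModel(h, initial, trans)


def _segment_log_prob(model: FlankingModel, x: np.ndarray) -> float:
    h = model.order
    log_init, log_trans = model.logs()
    total = 0.0
    ctx = 0
    for t in range(len(x)):
        if t < h:
            total += log_init[t][ctx, x[t]]
            ctx = ctx * ALPHABET_SIZE + x[t]
        else:
            total += log_trans[ctx, x[t]]
            ctx = (ctx * ALPHABET_SIZE + x[t]) % (ALPHABET_SIZE**h)
    return float(total)


def flanking_log_prob(model: FlankingModel, segment: str) -> float:
    """Log-probability of a segment scored from a fresh start; empty segment -> 0."""
    if segment == "":
        return 0.0
    return _segment_log_prob(model, encode(segment).astype(np.int64))


@dataclass
class OOPSModel:
    """Motif model plus flanking model; the full generative sequence model."""

    motif: MotifModel
    flanking: FlankingModel

    @property
    def width(self) -> int:
        return self.motif.width

    def to_dict(self) -> dict:
        return {"motif": self.motif.to_dict(), "flanking": self.flanking.to_dict()}

    @classmethod
    def from_dict(cls, data: dict) -> "OOPSModel":
        return cls(MotifModel.from_dict(data["motif"]), FlankingModel.from_dict(data["flanking"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "OOPSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# -- vectorized scanning --------------------------------------------------------


def _prefix_scores(model: FlankingModel, x: np.ndarray) -> np.ndarray:
    """``P[k] = log P_f(x[:k])`` for k = 0..L (cumulative fresh-start prefix)."""
    h = model.order
    L = len(x)
    log_init, log_trans = model.logs()
    terms = np.zeros(L)
    ctx = 0
    for t in range(min(h, L)):
        terms[t] = log_init[t][ctx, x[t]]
        ctx = ctx * ALPHABET_SIZE + x[t]
    if L > h:
        codes = np.zeros(L - h, dtype=np.int64)
        for u in range(h):
            codes += x[u : L - h + u] * ALPHABET_SIZE ** (h - 1 - u)
        terms[h:] = log_trans[codes, x[h:]]
    return np.concatenate(([0.0], np.cumsum(terms)))


def _suffix_scores(model: FlankingModel, x: np.ndarray) -> np.ndarray:
    """``S[u] = log P_f(x[u:])`` for u = 0..L, each suffix scored from a fresh start."""
    h = model.order
    L = len(x)
    log_init, log_trans = model.logs()
    # full-order terms, valid for absolute positions t >= h
    full = np.zeros(L)
    if L > h:
        codes = np.zeros(L - h, dtype=np.int64)
        for u in range(h):
            codes += x[u : L - h + u] * ALPHABET_SIZE ** (h - 1 - u)
        full[h:] = log_trans[codes, x[h:]]
    tail = np.concatenate((np.cumsum(full[::-1])[::-1], [0.0]))  # tail[t] = sum_{t'>=t}
    S = np.zeros(L + 1)
    for u in range(L):
        s = tail[min(u + h, L)]
        ctx = 0
        for j in range(min(h, L - u)):
            s += log_init[j][ctx, x[u + j]]
            ctx = ctx * ALPHABET_SIZE + x[u + j]
        S[u] = s
    return S


def scan_sequence(model: OOPSModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Conditional and joint log-likelihoods for every window of one sequence.

    Returns ``(cond_F, cond_R, joint)``, each of length ``L - W + 1`` indexed by the
    0-based window start. ``cond_*[j] = log P(x | v=j+1, s=*)`` and
    ``joint[j] = log P(x, v=j+1)`` with the strand marginalized under uniform priors.
    """
    x = np.asarray(x, dtype=np.int64)
    W = model.width
    L = len(x)
    if L < W:
        raise ValueError(f"sequence of length {L} shorter than motif width {W}")
    pre = _prefix_scores(model.flanking, x)
    suf = _suffix_scores(model.flanking, x)
    motif_f = model.motif.window_log_likelihoods(x)
    xrc = (ALPHABET_SIZE - 1 - x)[::-1]
    motif_on_rc = model.motif.window_log_likelihoods(xrc)
    n_win = L - W + 1
    flank = pre[:n_win] + suf[W : W + n_win]
    cond_f = flank + motif_f
    cond_r = flank + motif_on_rc[::-1]  # window j of x maps to window L-W-j of rc(x)
    joint = -np.log(n_win) + LOG_HALF + np.logaddexp(cond_f, cond_r)
    return cond_f, cond_r, joint


def conditional_log_likelihood(model: OOPSModel, seq: str, v: int, s: str) -> float:
    """``log P(x | v, s, Theta)``: prefix flank + motif window (rc for R) + suffix flank."""
    W = model.width
    L = len(seq)
    if L < W:
        raise ValueError(f"sequence of length {L} shorter than motif width {W}")
    if not (1 <= v <= L - W + 1):
        raise ValueError(f"start {v} out of range for length {L} and width {W}")
    if s not in ("F", "R"):
        raise ValueError("strand must be 'F' or 'R'")
    window = seq[v - 1 : v - 1 + W]
    if s == "R":
        window = reverse_complement(window)
    return (
        flanking_log_prob(model.flanking, seq[: v - 1])
        + flanking_log_prob(model.flanking, seq[v - 1 + W :])
        + motif_log_likelihood(model.motif, window)
    )


def joint_log_likelihood(model: OOPSModel, seq: str, v: int) -> float:
    """``log P(x, v)`` with the strand summed out under uniform (v, s) priors."""
    L = len(seq)
    n_win = L - model.width + 1
    if not (1 <= v <= n_win):
        raise ValueError(f"start {v} out of range for length {L}")
    f = conditional_log_likelihood(model, seq, v, "F")
    r = conditional_log_likelihood(model, seq, v, "R")
    return float(-np.log(n_win) + LOG_HALF + np.logaddexp(f, r))


def oops_log_marginal(model: OOPSModel, seq: str) -> float:
    """Full-sequence OOPS likelihood: ``log sum_v P(x, v)``."""
    _, _, joint = scan_sequence(model, encode(seq))
    return float(logsumexp(joint))


def sequence_log_prob(model: FlankingModel, seq: str) -> float:
    """Whole sequence scored by the flanking (background) model alone."""
    return flanking_log_prob(model, seq)
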