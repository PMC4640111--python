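"""Inhomogeneous parsimonious Markov motif models with fsNML parameters.

A motif model of width W and maximal order d carries one PCT per position (of
effective depth ``min(d, position-1)``) and one conditional probability vector per
PCT context. Structures are selected by exact BIC maximization and parameters by the
factorized sequential normalized maximum likelihood (fsNML) estimator, which is
hyperparameter-free:

    theta_a = e(N_a) (N_a + 1) / sum_b e(N_b) (N_b + 1),   e(N) = ((N+1)/N)^N, e(0) = 1.

An order-0 model is exactly a PWM with fsNML-smoothed columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pct import PCT, ScoredPCT, aggregate_counts, bic_score, maximize_bic
from .seqdata import ALPHABET_SIZE, SiteSet, context_counts, effective_depth, encode

MODEL_FORMAT_VERSION = 1


def fsnml_estimate(counts: np.ndarray) -> np.ndarray:
    """fsNML probability estimate from a vector of non-negative counts.

    Strictly positive and normalized for any input, including all zeros (uniform).
    ``e(N)`` is evaluated in log space as ``N log((N+1)/N)`` so arbitrarily large
    counts cannot overflow.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_e = np.where(counts > 0, counts * np.log1p(1.0 / np.where(counts > 0, counts, 1.0)), 0.0)
    log_w = log_e + np.log(counts + 1.0)
    log_w -= log_w.max()
    w = np.exp(log_w)
    return w / w.sum()


@dataclass
class MotifModel:
    """Width-W PMM: per-position PCTs plus per-context probability vectors."""

    width: int
    order: int
    pcts: list[PCT]
    thetas: list[np.ndarray]  # thetas[l] has shape (n_leaves of pcts[l], 4)
    _log_tables: list[np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.pcts) != self.width or len(self.thetas) != self.width:
            raise ValueError("need one PCT and one theta block per motif position")
        for pos, (pct, theta) in enumerate(zip(self.pcts, self.thetas), start=1):
            d_eff = effective_depth(pos, self.order)
            if pct.depth != d_eff:
                raise ValueError(
                    f"PCT at position {pos} has depth {pct.depth}, expected {d_eff}"
                )
            theta = np.asarray(theta, dtype=float)
            if theta.shape != (pct.n_leaves, ALPHABET_SIZE):
                raise ValueError(f"theta block at position {pos} has shape {theta.shape}")
            if np.any(theta < 0) or np.any(np.abs(theta.sum(axis=1) - 1.0) > 1e-12):
                raise ValueError(f"theta rows at position {pos} must be distributions")
            self.thetas[pos - 1] = theta

    def log_tables(self) -> list[np.ndarray]:
        """Per position: ``(4**d_eff, 4)`` table of log theta indexed by context code."""
        if self._log_tables is None:
            tables = []
            for pct, theta in zip(self.pcts, self.thetas):
                with np.errstate(divide="ignore"):
                    tables.append(np.log(theta)[pct.leaf_index()])
            self._log_tables = tables
        return self._log_tables

    # -- likelihood -------------------------------------------------------------

    def site_log_likelihoods(self, enc: np.ndarray) -> np.ndarray:
        """Log-likelihood of each row of an ``(N, W)`` encoded site matrix."""
        enc = np.atleast_2d(np.asarray(enc, dtype=np.int64))
        if enc.shape[1] != self.width:
            raise ValueError(f"sites of width {enc.shape[1]} scored by width-{self.width} model")
        out = np.zeros(enc.shape[0])
        tables = self.log_tables()
        for pos in range(1, self.width + 1):
            d_eff = self.pcts[pos - 1].depth
            code = np.zeros(enc.shape[0], dtype=np.int64)
            for k in range(1, d_eff + 1):
                code += enc[:, pos - 1 - k] * ALPHABET_SIZE ** (k - 1)
            out += tables[pos - 1][code, enc[:, pos - 1]]
        return out

    def window_log_likelihoods(self, x: np.ndarray) -> np.ndarray:
        """Motif log-likelihood of every width-W window of an encoded sequence."""
        x = np.asarray(x, dtype=np.int64)
        n_win = len(x) - self.width + 1
        if n_win < 1:
            raise ValueError("sequence shorter than motif width")
        starts = np.arange(n_win)
        out = np.zeros(n_win)
        tables = self.log_tables()
        for pos in range(1, self.width + 1):
            d_eff = self.pcts[pos - 1].depth
            code = np.zeros(n_win, dtype=np.int64)
            for k in range(1, d_eff + 1):
                code += x[starts + pos - 1 - k] * ALPHABET_SIZE ** (k - 1)
            out += tables[pos - 1][code, x[starts + pos - 1]]
        return out

    # -- persistence ------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "width": self.width,
            "order": self.order,
            "positions": [
                {"pct": pct.to_text(), "theta": theta.tolist()}
                for pct, theta in zip(self.pcts, self.thetas)
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MotifModel":
        if data.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {data.get('format_version')!r}")
        pcts = [PCT.from_text(p["pct"]) for p in data["positions"]]
        thetas = [np.asarray(p["theta"], dtype=float) for p in data["positions"]]
        return cls(data["width"], data["order"], pcts, thetas)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MotifModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def motif_log_likelihood(model: MotifModel, sites: SiteSet | str) -> float:
    """Total log-likelihood of one site or a SiteSet under the PMM (natural log)."""
    if isinstance(sites, str):
        enc = encode(sites)[None, :]
    else:
        if sites.width != model.width:
            raise ValueError(f"site width {sites.width} != model width {model.width}")
        enc = sites.encoded()
    if enc.shape[1] != model.width:
        raise ValueError(f"site width {enc.shape[1]} != model width {model.width}")
    return float(model.site_log_likelihoods(enc).sum())


def fit_position(sites: SiteSet, position: int, order: int) -> tuple[ScoredPCT, np.ndarray]:
    """BIC-optimal PCT and fsNML parameters for one motif position."""
    if len(sites) == 0:
        raise ValueError("cannot fit a position on an empty SiteSet")
    d_eff = effective_depth(position, order)
    raw = context_counts(sites, position, order)
    scored = maximize_bic(raw, d_eff, len(sites))
    agg = aggregate_counts(raw, scored.pct)
    theta = np.stack([fsnml_estimate(row) for row in agg])
    return scored, theta


def fit_motif(sites: SiteSet, order: int) -> tuple[MotifModel, float]:
    """Fit a width-|sites| PMM of maximal order ``order``; return (model, score).

    The structure score is the sum over positions of the BIC scores of the selected
    PCTs — the inner objective of the latent-variable discovery problem.
    """
    if len(sites) == 0:
        raise ValueError("cannot fit a motif on an empty SiteSet")
    pcts, thetas, total = [], [], 0.0
    for pos in range(1, sites.width + 1):
        scored, theta = fit_position(sites, pos, order)
        pcts.append(scored.pct)
        thetas.append(theta)
        total += scored.score
    return MotifModel(sites.width, order, pcts, thetas), float(total)


def fit_with_structure(sites: SiteSet, order: int, pcts: list[PCT]) -> tuple[MotifModel, float]:
    """fsNML parameters (and summed BIC score) for fixed, caller-supplied PCTs."""
    if len(sites) == 0:
        raise ValueError("cannot fit on an empty SiteSet")
    thetas, total = [], 0.0
    for pos, pct in enumerate(pcts, start=1):
        raw = context_counts(sites, pos, order)
        agg = aggregate_counts(raw, pct)
        thetas.append(np.stack([fsnml_estimate(row) for row in agg]))
        total += bic_score(pct, raw, len(sites))
    return MotifModel(sites.width, order, list(pcts), thetas), float(total)
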