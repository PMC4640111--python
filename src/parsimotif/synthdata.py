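"""Synthetic ChIP-seq-like benchmarks with known ground truth.

Positives emulate peak sequences: homogeneous Markov background (order 2 by default,
matching the flanking model used for real data) with exactly one motif instance
planted per sequence at a uniform position, reverse-complemented with a configurable
strand probability. Negatives are pure background of matched lengths at a
configurable ratio (two per positive by default). The generator records the true
latent configuration and the planted sites, so every downstream stage — discovery,
prediction, demixing, classification — can be validated against ground truth.

Built-in motif presets:

``strong_pwm``
    An order-0 motif (width 8) with a fixed consensus and probability 0.9 on the
    consensus base per position — a high-information motif typical of strongly
    sequence-specific factors.
``order2``
    A width-8 order-2 motif with two anchored positions followed by near-
    deterministic second-order conditionals (the next base is a function of the two
    preceding ones with probability 0.85). Its marginal base frequencies are much
    less informative than its conditionals, which is precisely the regime where
    dependency-aware models pay off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .oops import FlankingModel
from .pct import PCT
from .pmm import MotifModel
from .seqdata import (
    ALPHABET,
    ALPHABET_SIZE,
    LatentConfig,
    SequenceSet,
    SiteSet,
    decode,
    reverse_complement,
)


def consensus_pwm(consensus: str, strength: float = 0.9) -> MotifModel:
    """Order-0 motif putting ``strength`` on each consensus base."""
    w = len(consensus)
    thetas = []
    for ch in consensus:
        theta = np.full(ALPHABET_SIZE, (1.0 - strength) / 3.0)
        theta[ALPHABET.index(ch)] = strength
        thetas.append(theta[None, :])
    return MotifModel(w, 0, [PCT((),) for _ in range(w)], thetas)


def order2_motif(width: int = 8, strength: float = 0.85) -> MotifModel:
    """Order-2 motif: anchored start, then each base determined by the previous two."""
    if width < 3:
        raise ValueError("order-2 preset needs width >= 3")

    def concentrated(target: int) -> np.ndarray:
        theta = np.full(ALPHABET_SIZE, (1.0 - strength) / 3.0)
        theta[target] = strength
        return theta

    pcts, thetas = [], []
    for pos in range(1, width + 1):
        d_eff = min(2, pos - 1)
        pct = PCT.maximal(d_eff)
        pcts.append(pct)
        rows = []
        for chain in pct.leaf_chains():
            if d_eff == 0:
                rows.append(concentrated(2))  # anchor: G
            elif d_eff == 1:
                b = chain[0][0]  # symbol at offset -1
                rows.append(concentrated((b + 1) % ALPHABET_SIZE))
            else:
                b, a = chain[0][0], chain[1][0]  # offsets -1 and -2
                rows.append(concentrated((a + b) % ALPHABET_SIZE))
        thetas.append(np.stack(rows))
    return MotifModel(width, 2, pcts, thetas)


def motif_preset(name: str, width: int = 8) -> MotifModel:
    if name == "strong_pwm":
        consensus = ("TGACGTCA" * ((width + 7) // 8))[:width]
        return consensus_pwm(consensus, 0.9)
    if name == "order2":
        return order2_motif(width)
    raise ValueError(f"unknown motif preset {name!r}")


def sample_motif_sites(motif: MotifModel, n: int, rng: np.random.Generator) -> SiteSet:
    """Draw n i.i.d. sites: per position, the base comes from the matching context."""
    tables = [np.exp(t) for t in motif.log_tables()]  # (4**d_eff, 4) per position
    sites = np.zeros((n, motif.width), dtype=np.int64)
    for pos in range(1, motif.width + 1):
        d_eff = motif.pcts[pos - 1].depth
        code = np.zeros(n, dtype=np.int64)
        for k in range(1, d_eff + 1):
            code += sites[:, pos - 1 - k] * ALPHABET_SIZE ** (k - 1)
        u = rng.random(n)
        cdf = np.cumsum(tables[pos - 1][code], axis=1)
        sites[:, pos - 1] = (u[:, None] > cdf).sum(axis=1)
    return SiteSet(motif.width, [decode(row) for row in sites])


def sample_background(model: FlankingModel, length: int, rng: np.random.Generator) -> str:
    """One background sequence from the homogeneous Markov chain (fresh start)."""
    h = model.order
    out = np.zeros(length, dtype=np.int64)
    ctx = 0
    for t in range(length):
        dist = model.initial[t][ctx] if t < h else model.trans[ctx]
        a = int(rng.choice(ALPHABET_SIZE, p=dist))
        out[t] = a
        ctx = (ctx * ALPHABET_SIZE + a) % (ALPHABET_SIZE ** max(h, 1)) if h else 0
    return decode(out)


@dataclass
class BenchmarkSpec:
    """Parameters of a synthetic benchmark; defaults mirror the study conditions."""

    n_pos: int = 200
    length: int | list[int] = 100
    motif: MotifModel | str = "strong_pwm"
    motif_width: int = 8
    background_order: int = 2
    background: FlankingModel | None = None  # default: uniform chain of that order
    strand_prob: float = 0.5
    neg_ratio: int = 2
    seed: int | None = None
    second_motif: MotifModel | str | None = None
    second_weight: float = 0.0

    def resolved_motif(self) -> MotifModel:
        return motif_preset(self.motif, self.motif_width) if isinstance(self.motif, str) else self.motif

    def resolved_second(self) -> MotifModel | None:
        if self.second_motif is None:
            return None
        if isinstance(self.second_motif, str):
            return motif_preset(self.second_motif, self.motif_width)
        return self.second_motif

    def lengths(self) -> list[int]:
        L = self.length
        lens = [L] * self.n_pos if isinstance(L, int) else list(L)
        if len(lens) != self.n_pos:
            raise ValueError("length list must have n_pos entries")
        w = self.resolved_motif().width
        if min(lens) < w:
            raise ValueError("all sequence lengths must be >= motif width")
        return lens

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkSpec":
        raw = yaml.safe_load(Path(path).read_text())
        motif = raw.get("motif", "strong_pwm")
        if isinstance(motif, dict):
            if "consensus" in motif:
                motif = consensus_pwm(motif["consensus"], motif.get("strength", 0.9))
            else:
                motif = motif_preset(motif["preset"], motif.get("width", raw.get("motif_width", 8)))
        kwargs = {
            k: raw[k]
            for k in (
                "n_pos",
                "length",
                "motif_width",
                "background_order",
                "strand_prob",
                "neg_ratio",
                "seed",
                "second_weight",
            )
            if k in raw
        }
        return cls(motif=motif, second_motif=raw.get("second_motif"), **kwargs)


@dataclass
class Benchmark:
    positives: SequenceSet
    negatives: SequenceSet
    truth: LatentConfig
    sites: SiteSet  # planted sites, motif orientation
    origins: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def truth_table(self) -> pd.DataFrame:
        """Same schema as prediction TSVs, for direct comparison."""
        return pd.DataFrame(
            {
                "seq_id": self.positives.ids,
                "start": self.truth.v,
                "strand": self.truth.s,
                "site": self.sites.sites,
                "log_likelihood": np.nan,
            }
        )


def make_benchmark(spec: BenchmarkSpec) -> Benchmark:
    """Generate positives (one planted site each), matched negatives, and the truth."""
    if not (0.0 <= spec.strand_prob <= 1.0):
        raise ValueError("strand_prob must lie in [0, 1]")
    if spec.neg_ratio < 0:
        raise ValueError("neg_ratio must be >= 0")
    rng = np.random.default_rng(spec.seed)
    motif = spec.resolved_motif()
    second = spec.resolved_second()
    background = spec.background or FlankingModel.uniform(spec.background_order)
    lengths = spec.lengths()
    W = motif.width
    if second is not None and second.width != W:
        raise ValueError("both motifs must have the same width")

    pos_seqs, vs, ss, planted, origins = [], [], [], [], []
    for L in lengths:
        origin = 1 if (second is not None and rng.random() < spec.second_weight) else 0
        site = sample_motif_sites(second if origin else motif, 1, rng).sites[0]
        bg = sample_background(background, L, rng)
        v = int(rng.integers(1, L - W + 2))
        strand = "R" if rng.random() < spec.strand_prob else "F"
        inserted = site if strand == "F" else reverse_complement(site)
        pos_seqs.append(bg[: v - 1] + inserted + bg[v - 1 + W :])
        vs.append(v)
        ss.append(strand)
        planted.append(site)
        origins.append(origin)

    positives = SequenceSet(pos_seqs, [f"pos_{i}" for i in range(spec.n_pos)])
    n_neg = spec.neg_ratio * spec.n_pos
    neg_lengths = [lengths[i % len(lengths)] for i in range(n_neg)]
    negatives = SequenceSet(
        [sample_background(background, L, rng) for L in neg_lengths],
        [f"neg_{i}" for i in range(n_neg)],
    )
    return Benchmark(
        positives,
        negatives,
        LatentConfig(np.array(vs), np.array(ss)),
        SiteSet(W, planted),
        np.array(origins, dtype=int),
    )
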