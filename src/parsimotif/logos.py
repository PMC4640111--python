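"""Sequence logos and conditional sequence logos as structured data.

A logo column shows nucleotide relative frequencies scaled by the column's
information content ``IC_j = 2 + sum_a p_ja log2 p_ja`` (bits, in [0, 2]). A
*conditional* logo refines one motif position: for each context of that position's
PCT it shows the conditional nucleotide frequencies, with a stack-width class
reflecting how many sites fall in the context — full width above 50 % coverage, half
width for 5-50 %, quarter width below 5 %.

Logos are emitted as JSON/TSV-friendly structures; an optional matplotlib renderer
draws them when a figure is explicitly requested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pmm import MotifModel
from .seqdata import ALPHABET, ALPHABET_SIZE, SiteSet, context_counts


@dataclass
class LogoMatrix:
    freqs: np.ndarray  # (W, 4) relative frequencies
    info: np.ndarray  # (W,) information content in bits

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    def stack_heights(self) -> np.ndarray:
        """(W, 4) letter heights: frequency times column information content."""
        return self.freqs * self.info[:, None]

    def to_dict(self) -> dict:
        return {
            "alphabet": ALPHABET,
            "frequencies": self.freqs.tolist(),
            "information_bits": self.info.tolist(),
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _information_bits(freqs: np.ndarray) -> np.ndarray:
    nz = np.where(freqs > 0, freqs, 1.0)
    return 2.0 + np.sum(freqs * np.log2(nz), axis=-1)


def logo_matrix(sites: SiteSet) -> LogoMatrix:
    """Mononucleotide logo of an aligned site set."""
    if len(sites) == 0:
        raise ValueError("cannot build a logo from an empty SiteSet")
    enc = sites.encoded()
    counts = np.stack(
        [np.bincount(enc[:, j], minlength=ALPHABET_SIZE) for j in range(sites.width)]
    ).astype(float)
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return LogoMatrix(freqs, _information_bits(freqs))


def width_class(coverage: float) -> float:
    """Stack-width class for a context: 1 above 50 %, 1/2 for 5-50 %, 1/4 below 5 %."""
    if coverage > 0.5:
        return 1.0
    if coverage >= 0.05:
        return 0.5
    return 0.25


@dataclass
class ContextStack:
    context: list[str]  # member context strings
    freqs: np.ndarray  # (4,) conditional frequencies
    coverage: float
    width: float


@dataclass
class ConditionalLogo:
    position: int
    stacks: list[ContextStack]

    def to_dict(self) -> dict:
        return {
            "position": self.position,
            "alphabet": ALPHABET,
            "contexts": [
                {
                    "members": s.context,
                    "frequencies": s.freqs.tolist(),
                    "coverage": s.coverage,
                    "width": s.width,
                }
                for s in self.stacks
            ],
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def conditional_logo(model: MotifModel, sites: SiteSet, position: int) -> ConditionalLogo:
    """Per-context frequency stacks at one motif position, from observed sites.

    Coverage fractions are the shares of sites whose context falls in each PCT
    context; they sum to one across the position's contexts.
    """
    if not (1 <= position <= model.width):
        raise ValueError(f"position {position} outside motif of width {model.width}")
    if sites.width != model.width:
        raise ValueError("sites and model have different widths")
    if len(sites) == 0:
        raise ValueError("cannot build a conditional logo from an empty SiteSet")
    pct = model.pcts[position - 1]
    raw = context_counts(sites, position, model.order)
    idx = pct.leaf_index()
    agg = np.zeros((pct.n_leaves, ALPHABET_SIZE))
    np.add.at(agg, idx, raw.astype(float))
    totals = agg.sum(axis=1)
    n = totals.sum()
    stacks = []
    for leaf, members in enumerate(pct.contexts()):
        cov = float(totals[leaf] / n)
        freqs = agg[leaf] / totals[leaf] if totals[leaf] > 0 else np.full(ALPHABET_SIZE, 0.25)
        stacks.append(ContextStack(sorted(members), freqs, cov, width_class(cov)))
    return ConditionalLogo(position, stacks)


def render_logo(matrix: LogoMatrix, path: str | Path) -> None:
    """Minimal graphical rendering (stacked letter bars) via matplotlib, if present."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    fig, ax = plt.subplots(figsize=(0.5 * matrix.width + 1, 2.5))
    heights = matrix.stack_heights()
    for j in range(matrix.width):
        bottom = 0.0
        for a in np.argsort(heights[j]):
            h = heights[j, a]
            if h <= 0:
                continue
            ax.bar(j + 1, h, bottom=bottom, color=colors[ALPHABET[a]], width=0.9)
            if h > 0.12:
                ax.text(j + 1, bottom + h / 2, ALPHABET[a], ha="center", va="center", fontsize=8)
            bottom += h
    ax.set_xlim(0.5, matrix.width + 0.5)
    ax.set_ylim(0, 2)
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)
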