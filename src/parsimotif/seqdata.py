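"""Sequence containers, FASTA I/O, reverse complement, site extraction, context counting.

DNA sequences are plain upper-case strings over the alphabet ``ACGT``. Binding-site
start positions are 1-based and inclusive throughout, so a site planted at ``v`` in a
sequence of length ``L`` occupies positions ``v .. v+W-1`` with ``1 <= v <= L-W+1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
ALPHABET_SIZE = 4

_SYM_TO_IDX = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to an int8 array with A,C,G,T -> 0,1,2,3."""
    try:
        return np.fromiter((_SYM_TO_IDX[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"invalid DNA symbol {exc.args[0]!r} in sequence") from None


def decode(arr: Iterable[int]) -> str:
    return "".join(ALPHABET[i] for i in arr)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; an involution on {A,C,G,T}*."""
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(f"invalid DNA symbol(s) {sorted(bad)!r} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceSet:
    """An ordered collection of DNA sequences with unique identifiers."""

    sequences: list[str]
    ids: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) == 0:
            raise ValueError("no sequences: a SequenceSet must contain at least one record")
        if len(self.sequences) != len(self.ids):
            raise ValueError("sequences and ids must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        for sid, s in zip(self.ids, self.sequences):
            bad = set(s) - set(ALPHABET)
            if bad:
                raise ValueError(f"sequence {sid!r} contains invalid symbol(s) {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.sequences], dtype=int)

    def encoded(self) -> list[np.ndarray]:
        return [encode(s) for s in self.sequences]

    def subset(self, indices: Sequence[int]) -> "SequenceSet":
        return SequenceSet([self.sequences[i] for i in indices], [self.ids[i] for i in indices])


@dataclass
class SiteSet:
    """Aligned fixed-width sequences, e.g. extracted or predicted binding sites."""

    width: int
    sites: list[str]
    _encoded: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("site width must be >= 1")
        for s in self.sites:
            if len(s) != self.width:
                raise ValueError(f"site {s!r} does not have width {self.width}")
            bad = set(s) - set(ALPHABET)
            if bad:
                raise ValueError(f"site {s!r} contains invalid symbol(s) {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def encoded(self) -> np.ndarray:
        """(N, W) int8 matrix of the sites; cached after the first call."""
        if self._encoded is None:
            if len(self.sites) == 0:
                self._encoded = np.zeros((0, self.width), dtype=np.int8)
            else:
                self._encoded = np.stack([encode(s) for s in self.sites])
        return self._encoded


@dataclass
class LatentConfig:
    """Per-sequence motif start position (1-based) and strand ('F' or 'R')."""

    v: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=int)
        self.s = np.asarray(self.s, dtype="<U1")
        if self.v.shape != self.s.shape:
            raise ValueError("v and s must have equal length")
        if not np.all(np.isin(self.s, ["F", "R"])):
            raise ValueError("strand flags must be 'F' or 'R'")

    def __len__(self) -> int:
        return len(self.v)


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Records are upper-cased and taken in file order. Sequences containing ``N`` or any
    other ambiguous symbol are rejected: the study design excludes ambiguous
    nucleotides from both positive and negative sets.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    seqs, ids = [], []
    for rec in records:
        s = str(rec.seq).upper()
        if "N" in s:
            raise ValueError(
                f"record {rec.id!r} contains ambiguous nucleotide 'N'; "
                "ambiguous sequences are excluded from analysis"
            )
        bad = set(s) - set(ALPHABET)
        if bad:
            raise ValueError(f"record {rec.id!r} contains invalid symbol(s) {sorted(bad)!r}")
        seqs.append(s)
        ids.append(rec.id)
    return SequenceSet(seqs, ids)


def write_fasta(data: SequenceSet, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for s, i in zip(data.sequences, data.ids)]
    SeqIO.write(records, str(path), "fasta")


def read_sites(path: str | Path) -> SiteSet:
    """Read aligned sites from FASTA or from plain one-site-per-line text."""
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        data = read_fasta(path)
        sites = list(data.sequences)
    else:
        sites = [line.strip().upper() for line in text.splitlines() if line.strip()]
    if not sites:
        raise ValueError(f"no sites found in {path}")
    widths = {len(s) for s in sites}
    if len(widths) != 1:
        raise ValueError(f"sites have unequal widths {sorted(widths)}")
    return SiteSet(widths.pop(), sites)


def write_sites(sites: SiteSet, path: str | Path, fasta: bool = False) -> None:
    if fasta:
        data = SequenceSet(list(sites.sites), [f"site_{k}" for k in range(len(sites))])
        write_fasta(data, path)
    else:
        Path(path).write_text("\n".join(sites.sites) + "\n")


def extract_sites(data: SequenceSet, latents: LatentConfig, width: int) -> SiteSet:
    """Cut the width-``width`` windows named by ``latents`` out of ``data``.

    Forward-strand records yield the window itself; reverse-strand records yield its
    reverse complement, so the output is orientation-aligned with the motif model.
    """
    if len(latents) != len(data):
        raise ValueError("latent configuration length does not match number of sequences")
    sites = []
    for seq, sid, v, strand in zip(data.sequences, data.ids, latents.v, latents.s):
        if not (1 <= v <= len(seq) - width + 1):
            raise ValueError(
                f"start {v} out of range for sequence {sid!r} (length {len(seq)}, width {width})"
            )
        window = seq[v - 1 : v - 1 + width]
        sites.append(window if strand == "F" else reverse_complement(window))
    return SiteSet(width, sites)


def effective_depth(position: int, depth: int) -> int:
    """Context order actually available at 1-based motif position ``position``.

    The first ``depth`` positions of a motif lack a full-length context inside the
    site, so the effective order there is ``position - 1``.
    """
    if position < 1:
        raise ValueError("motif positions are 1-based")
    return min(depth, position - 1)


def context_counts(sites: SiteSet, position: int, depth: int) -> np.ndarray:
    """Count symbol occurrences at ``position`` per length-``d_eff`` context.

    Returns a ``(4**d_eff, 4)`` integer table where ``d_eff = min(depth, position-1)``.
    Row index encodes the context string big-endian (most distal symbol first), i.e.
    the symbol at ``position-1`` is the least significant digit.
    """
    if not (1 <= position <= sites.width):
        raise ValueError(f"position {position} outside motif of width {sites.width}")
    d_eff = effective_depth(position, depth)
    table = np.zeros((ALPHABET_SIZE**d_eff, ALPHABET_SIZE), dtype=np.int64)
    enc = sites.encoded()
    if enc.shape[0] == 0:
        return table
    sym = enc[:, position - 1].astype(np.int64)
    code = np.zeros(enc.shape[0], dtype=np.int64)
    for k in range(1, d_eff + 1):
        code += enc[:, position - 1 - k].astype(np.int64) * ALPHABET_SIZE ** (k - 1)
    np.add.at(table, (code, sym), 1)
    return table
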