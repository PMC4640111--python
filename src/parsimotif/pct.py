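"""Parsimonious context trees: structure, BIC scoring, exact maximization.

A parsimonious context tree (PCT) of depth ``d`` is a rooted, balanced tree whose
non-root nodes carry non-empty subset labels of the alphabet; the labels of the
children of any node form a partition of the alphabet. The cross product of the labels
along a leaf-to-root path is a *context*: a set of length-``d`` context strings that
share one conditional probability vector. The contexts of all leaves partition the set
of all length-``d`` strings. A depth-0 PCT is the bare root (one empty context), which
corresponds to a single PWM column.

Level convention: the children of the root condition on the symbol directly preceding
the modeled position (offset -1); the deepest level conditions on offset ``-d``.
Context strings are written left-to-right from offset ``-d`` to offset ``-1`` and
encoded big-endian, so the offset ``-1`` symbol is the least significant base-``m``
digit — the same encoding used by :func:`parsimotif.seqdata.context_counts`.

BIC scores use the natural logarithm throughout.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .seqdata import ALPHABET

DEFAULT_ALPHABET_SIZE = 4


def set_partitions(items: tuple[int, ...]) -> Iterator[list[tuple[int, ...]]]:
    """Yield all partitions of ``items`` into non-empty blocks (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        # first joins an existing block, or starts its own
        for i in range(len(part)):
            yield part[:i] + [tuple(sorted((first,) + part[i]))] + part[i + 1 :]
        yield [(first,)] + part


def _canonical(partition) -> list[tuple[int, ...]]:
    return sorted(tuple(sorted(b)) for b in partition)


def all_partitions(m: int) -> list[list[tuple[int, ...]]]:
    parts = [_canonical(p) for p in set_partitions(tuple(range(m)))]
    parts.sort()
    return parts


@dataclass(frozen=True)
class PCTNode:
    label: tuple[int, ...]  # sorted symbol indices
    children: tuple["PCTNode", ...]


class PCT:
    """A parsimonious context tree over an alphabet of size ``m`` (default DNA)."""

    def __init__(self, children: tuple[PCTNode, ...] = (), m: int = DEFAULT_ALPHABET_SIZE):
        self.m = m
        self.children = tuple(children)
        self.validate()

    # -- construction helpers ---------------------------------------------------

    @classmethod
    def minimal(cls, depth: int, m: int = DEFAULT_ALPHABET_SIZE) -> "PCT":
        """The fully merged PCT: one node labeled by the whole alphabet per level.

        Its single context contains every length-``depth`` string, so the model at
        this position degenerates to a PWM column regardless of ``depth``.
        """
        node: tuple[PCTNode, ...] = ()
        for _ in range(depth):
            node = (PCTNode(tuple(range(m)), node),)
        return cls(node, m=m)

    @classmethod
    def maximal(cls, depth: int, m: int = DEFAULT_ALPHABET_SIZE) -> "PCT":
        """The fully split PCT: singleton labels, one context per context string."""

        def build(d: int) -> tuple[PCTNode, ...]:
            if d == 0:
                return ()
            return tuple(PCTNode((a,), build(d - 1)) for a in range(m))

        return cls(build(depth), m=m)

    # -- structure --------------------------------------------------------------

    def validate(self) -> None:
        depths = set()

        def walk(children: tuple[PCTNode, ...], depth: int) -> None:
            if not children:
                depths.add(depth)
                return
            seen: list[int] = []
            for node in children:
                if not node.label:
                    raise ValueError("PCT node labels must be non-empty")
                if tuple(sorted(node.label)) != tuple(node.label):
                    raise ValueError("PCT node labels must be sorted symbol tuples")
                seen.extend(node.label)
            if sorted(seen) != list(range(self.m)):
                raise ValueError("child labels must form a partition of the alphabet")
            for node in children:
                walk(node.children, depth + 1)

        walk(self.children, 0)
        if len(depths) != 1:
            raise ValueError("all leaves of a PCT must lie at the same depth")
        self._depth = depths.pop()

    @property
    def depth(self) -> int:
        return self._depth

    @property
    def n_leaves(self) -> int:
        return max(1, len(self.leaf_chains()))

    def leaf_chains(self) -> list[tuple[tuple[int, ...], ...]]:
        """Root-to-leaf label chains; level 1 (first entry) conditions on offset -1."""
        chains: list[tuple[tuple[int, ...], ...]] = []

        def walk(children: tuple[PCTNode, ...], prefix: tuple) -> None:
            if not children:
                if prefix:
                    chains.append(prefix)
                return
            for node in children:
                walk(node.children, prefix + (node.label,))

        walk(self.children, ())
        return chains if chains else [()]

    def contexts(self) -> list[frozenset[str]]:
        """The leaf contexts as sets of length-``depth`` strings; a partition of A^d."""
        alpha = ALPHABET[: self.m]
        if self.depth == 0:
            return [frozenset({""})]
        out = []
        for chain in self.leaf_chains():
            # chain[k-1] constrains the symbol at offset -k, i.e. string index d-k
            members = []
            for combo in itertools.product(*reversed(chain)):
                members.append("".join(alpha[a] for a in combo))
            out.append(frozenset(members))
        return out

    def leaf_index(self) -> np.ndarray:
        """Array of length ``m**depth`` mapping encoded context -> leaf number."""
        d, m = self.depth, self.m
        idx = np.full(m**d, -1, dtype=np.int64)
        for leaf, chain in enumerate(self.leaf_chains()):
            if not chain:
                idx[:] = 0
                break
            codes = [0]
            for k, label in enumerate(chain, start=1):  # offset -k has weight m**(k-1)
                codes = [c + a * m ** (k - 1) for c in codes for a in label]
            idx[codes] = leaf
        if d == 0:
            idx = np.zeros(1, dtype=np.int64)
        assert (idx >= 0).all()
        return idx

    # -- serialization ----------------------------------------------------------

    def to_text(self) -> str:
        alpha = ALPHABET[: self.m]

        def render(node: PCTNode) -> str:
            lab = "".join(alpha[a] for a in node.label)
            if not node.children:
                return lab
            return lab + "(" + "|".join(render(c) for c in node.children) + ")"

        return "(" + "|".join(render(c) for c in self.children) + ")"

    @classmethod
    def from_text(cls, text: str, m: int = DEFAULT_ALPHABET_SIZE) -> "PCT":
        alpha = ALPHABET[:m]
        pos = 0

        def parse_children() -> tuple[PCTNode, ...]:
            nonlocal pos
            assert text[pos] == "("
            pos += 1
            nodes = []
            while text[pos] != ")":
                start = pos
                while text[pos] not in "(|)":
                    pos += 1
                label = tuple(sorted(alpha.index(ch) for ch in text[start:pos]))
                children: tuple[PCTNode, ...] = ()
                if text[pos] == "(":
                    children = parse_children()
                nodes.append(PCTNode(label, children))
                if text[pos] == "|":
                    pos += 1
            pos += 1
            return tuple(nodes)

        text = text.strip()
        if text == "()":
            return cls((), m=m)
        children = parse_children()
        if pos != len(text):
            raise ValueError(f"trailing characters in PCT text {text!r}")
        return cls(children, m=m)

    def to_dict(self) -> dict:
        def conv(node: PCTNode) -> dict:
            return {"label": list(node.label), "children": [conv(c) for c in node.children]}

        return {"m": self.m, "depth": self.depth, "children": [conv(c) for c in self.children]}

    @classmethod
    def from_dict(cls, data: dict) -> "PCT":
        def conv(d: dict) -> PCTNode:
            return PCTNode(tuple(sorted(d["label"])), tuple(conv(c) for c in d["children"]))

        return cls(tuple(conv(c) for c in data["children"]), m=data.get("m", DEFAULT_ALPHABET_SIZE))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "PCT":
        return cls.from_dict(json.loads(text))

    # -- dunder -----------------------------------------------------------------

    def __eq__(self, other) -> bool:
        return isinstance(other, PCT) and self.m == other.m and self.children == other.children

    def __hash__(self) -> int:
        return hash((self.m, self.children))

    def __repr__(self) -> str:
        return f"PCT({self.to_text()!r}, m={self.m})"


@dataclass
class ScoredPCT:
    pct: PCT
    score: float


def aggregate_counts(raw: np.ndarray, pct: PCT) -> np.ndarray:
    """Sum a raw ``(m**d, m)`` count table over the contexts of ``pct``.

    Row order follows the PCT's leaf order; column sums are conserved.
    """
    raw = np.asarray(raw)
    if raw.shape != (pct.m**pct.depth, pct.m):
        raise ValueError(
            f"count table shape {raw.shape} does not match depth {pct.depth} over "
            f"alphabet size {pct.m}"
        )
    idx = pct.leaf_index()
    out = np.zeros((pct.n_leaves, pct.m), dtype=raw.dtype)
    np.add.at(out, idx, raw)
    return out


def _leaf_log_likelihood(counts: np.ndarray) -> float:
    """Maximum log-likelihood contribution of one context: sum n*ln(n/total)."""
    total = counts.sum()
    if total == 0:
        return 0.0
    nz = counts[counts > 0].astype(float)
    return float(np.sum(nz * (np.log(nz) - np.log(total))))


def bic_score(pct: PCT, raw: np.ndarray, n: int) -> float:
    """BIC structure score: penalized maximum log-likelihood, natural log.

    ``sum_c sum_a N_ca ln(N_ca / N_c.) - 0.5 |tau| (m-1) ln N`` where ``|tau|`` is the
    number of leaves. Zero cells contribute nothing to the likelihood; empty contexts
    contribute nothing either but still count toward the parameter penalty.
    """
    if n <= 0:
        raise ValueError("BIC score undefined for sample size 0")
    raw = np.asarray(raw)
    if int(raw.sum()) != int(n):
        raise ValueError(f"sample size {n} does not equal table total {int(raw.sum())}")
    agg = aggregate_counts(raw, pct)
    ll = sum(_leaf_log_likelihood(row) for row in agg)
    penalty = 0.5 * pct.n_leaves * (pct.m - 1) * np.log(n)
    return float(ll - penalty)


def _reduce(table: np.ndarray, block: tuple[int, ...], m: int) -> np.ndarray:
    """Constrain the least significant context digit to ``block`` and sum it out."""
    t3 = table.reshape(-1, m, m)  # (remaining contexts, constrained digit, symbol)
    return t3[:, list(block), :].sum(axis=1)


def maximize_bic(
    raw: np.ndarray, depth: int, n: int, m: int = DEFAULT_ALPHABET_SIZE
) -> ScoredPCT:
    """Exact global maximization of the BIC structure score over depth-``depth`` PCTs.

    Bottom-up recursion: for each node, counts are aggregated along the chain of
    subset labels on its root path, the optimal subtree below each candidate label is
    computed from the reduced table, and the children are chosen by maximizing over
    all set partitions of the alphabet. Ties are broken toward fewer leaves, then by
    canonical (lexicographic) ordering of the partition.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if n <= 0:
        raise ValueError("sample size must be >= 1")
    raw = np.asarray(raw, dtype=np.int64)
    if raw.shape != (m**depth, m):
        raise ValueError(f"count table shape {raw.shape} does not match depth {depth}")
    leaf_pen = 0.5 * (m - 1) * np.log(n)
    partitions = all_partitions(m)
    subsets = sorted({b for p in partitions for b in p})

    def leaf_score(counts: np.ndarray) -> float:
        return _leaf_log_likelihood(counts) - leaf_pen

    def best_children(table: np.ndarray, r: int) -> tuple[float, int, tuple[PCTNode, ...]]:
        """Optimal child forest of a node whose subtree spans ``r`` more levels."""
        per_subset: dict[tuple[int, ...], tuple[float, int, PCTNode]] = {}
        for block in subsets:
            reduced = _reduce(table, block, m)
            if r == 1:
                per_subset[block] = (leaf_score(reduced[0]), 1, PCTNode(block, ()))
            else:
                s, leaves, kids = best_children(reduced, r - 1)
                per_subset[block] = (s, leaves, PCTNode(block, kids))
        best: tuple[float, int, tuple[PCTNode, ...]] | None = None
        for part in partitions:  # canonical ascending order; first best wins ties
            score = sum(per_subset[b][0] for b in part)
            leaves = sum(per_subset[b][1] for b in part)
            if best is None or score > best[0] or (score == best[0] and leaves < best[1]):
                best = (score, leaves, tuple(per_subset[b][2] for b in part))
        assert best is not None
        return best

    if depth == 0:
        counts = raw.reshape(m)
        return ScoredPCT(PCT((), m=m), leaf_score(counts))
    score, _, children = best_children(raw, depth)
    return ScoredPCT(PCT(children, m=m), float(score))


def count_pcts(depth: int, m: int = DEFAULT_ALPHABET_SIZE) -> int:
    """Number of distinct PCT structures of exactly depth ``depth``."""
    if depth == 0:
        return 1
    sizes = [len(p) for p in all_partitions(m)]
    c = 1
    for _ in range(depth):
        c = sum(c**k for k in sizes)
    return c


def enumerate_pcts(
    depth: int, m: int = DEFAULT_ALPHABET_SIZE, cap: int = 100_000
) -> Iterator[PCT]:
    """Yield every valid PCT structure exactly once (brute-force oracle).

    Refuses instances with more than ``cap`` structures.
    """
    total = count_pcts(depth, m)
    if total > cap:
        raise ValueError(f"{total} structures of depth {depth} exceed cap {cap}")
    partitions = all_partitions(m)

    def forests(d: int) -> Iterator[tuple[PCTNode, ...]]:
        if d == 0:
            yield ()
            return
        for part in partitions:
            for combo in itertools.product(*(forests(d - 1) for _ in part)):
                yield tuple(PCTNode(b, kids) for b, kids in zip(part, combo))

    if depth == 0:
        yield PCT((), m=m)
        return
    for children in forests(depth):
        yield PCT(children, m=m)
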