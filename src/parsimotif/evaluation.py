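"""Fragment-based classification: 10-fold CV, AUC, and the Psi improvement score.

Motif models are compared without known binding-site locations by how well a
two-class generative classifier separates motif-bearing (ChIP-positive) fragments
from background (negative) fragments. Class one is the OOPS model (motif found by de
novo discovery on training positives); class two is the homogeneous flanking Markov
model fit on the union of training positives and negatives. A test fragment is
scored by the log-likelihood ratio of the two class models; the AUC over the test
fold measures separation.

The improvement of an order-d model over the PWM (order 0) is summarized by

    Psi_d = log2((1 - AUC_0) / (1 - AUC_d)),

the base-2 log of the ratio of distances to perfect classification: Psi_d = 1 means
the order-d model halves the distance to a perfect classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.metrics import roc_auc_score

from .discovery import DiscoveryConfig, discover
from .oops import fit_flanking, oops_log_marginal, scan_sequence, sequence_log_prob
from .seqdata import SequenceSet


def psi(auc0: float, aucd: float) -> float:
    """Distance-to-perfect improvement score, base-2 log; positive iff aucd > auc0."""
    if not (0.0 <= auc0 < 1.0):
        raise ValueError("auc0 must lie in [0, 1)")
    if not (0.0 <= aucd < 1.0):
        raise ValueError("aucd must lie in [0, 1); a perfect AUC gives an infinite score")
    return float(np.log2((1.0 - auc0) / (1.0 - aucd)))


def auc(pos_scores, neg_scores) -> float:
    """Rank-statistic area under the ROC curve; ties count one half."""
    pos = np.asarray(list(pos_scores), dtype=float)
    neg = np.asarray(list(neg_scores), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be nonempty")
    labels = np.concatenate((np.ones(pos.size), np.zeros(neg.size)))
    return float(roc_auc_score(labels, np.concatenate((pos, neg))))


@dataclass
class FoldSplit:
    fold: int
    train_pos: SequenceSet
    train_neg: SequenceSet
    test_pos: SequenceSet
    test_neg: SequenceSet


def cv_split(
    pos: SequenceSet, neg: SequenceSet, k: int = 10, seed: int | None = None
) -> list[FoldSplit]:
    """Seeded k-fold split; positives and negatives are partitioned independently."""
    if len(pos) < k or len(neg) < k:
        raise ValueError(f"need at least {k} sequences per class for {k}-fold CV")
    rng = np.random.default_rng(seed)

    def folds(data: SequenceSet) -> list[np.ndarray]:
        idx = rng.permutation(len(data))
        return [chunk for chunk in np.array_split(idx, k)]

    pos_folds, neg_folds = folds(pos), folds(neg)
    out = []
    for f in range(k):
        train_p = np.concatenate([pos_folds[j] for j in range(k) if j != f])
        train_n = np.concatenate([neg_folds[j] for j in range(k) if j != f])
        out.append(
            FoldSplit(
                f,
                pos.subset(train_p),
                neg.subset(train_n),
                pos.subset(pos_folds[f]),
                neg.subset(neg_folds[f]),
            )
        )
    return out


@dataclass
class ClassificationConfig:
    width: int = 20
    orders: tuple[int, ...] = (0, 1, 2, 3, 4)
    folds: int = 10
    seed: int | None = None
    flank_order: int = 2
    score: str = "marginal"  # or "max": best single window instead of the OOPS sum
    discovery: DiscoveryConfig | None = None  # template; width/order/seed are overridden

    def discovery_config(self, order: int, seed: int) -> DiscoveryConfig:
        base = self.discovery or DiscoveryConfig()
        return DiscoveryConfig(
            width=self.width,
            order=order,
            min_iter=base.min_iter,
            patience=base.patience,
            restarts=base.restarts,
            seed=seed,
            flank_order=self.flank_order,
        )


def _class_score(model, flanking, seq: str, mode: str) -> float:
    if mode == "marginal":
        fg = oops_log_marginal(model, seq)
    elif mode == "max":
        from .seqdata import encode

        _, _, joint = scan_sequence(model, encode(seq))
        fg = float(joint.max())
    else:
        raise ValueError(f"unknown scoring mode {mode!r}")
    return fg - sequence_log_prob(flanking, seq)


def fragment_classify(
    pos: SequenceSet, neg: SequenceSet, config: ClassificationConfig
) -> pd.DataFrame:
    """Cross-validated fragment classification for several model orders.

    Per fold: the flanking model is fit on training positives plus negatives, de
    novo discovery runs on training positives for each order, and every test
    fragment is scored by the class log-likelihood ratio. Returns a DataFrame with
    columns fold, order, auc, psi (psi relative to the order-0 AUC of the same fold;
    NaN when order 0 is not among the requested orders or an AUC is exactly 1).
    """
    rows = []
    splits = cv_split(pos, neg, config.folds, config.seed)
    base_seed = 0 if config.seed is None else config.seed
    for split in splits:
        union = SequenceSet(
            split.train_pos.sequences + split.train_neg.sequences,
            [f"p{i}" for i in range(len(split.train_pos))]
            + [f"n{i}" for i in range(len(split.train_neg))],
        )
        flanking = fit_flanking(union, config.flank_order)
        fold_auc = {}
        for order in config.orders:
            dconf = config.discovery_config(
                order, seed=base_seed + 1000 * split.fold + order
            )
            result = discover(split.train_pos, dconf, flanking=flanking)
            ps = [_class_score(result.model, flanking, s, config.score) for s in split.test_pos]
            ns = [_class_score(result.model, flanking, s, config.score) for s in split.test_neg]
            fold_auc[order] = auc(ps, ns)
        for order in config.orders:
            a = fold_auc[order]
            if 0 in fold_auc and fold_auc[0] < 1.0 and a < 1.0:
                p = psi(fold_auc[0], a)
            else:
                p = np.nan
            rows.append({"fold": split.fold, "order": order, "auc": a, "psi": p})
    return pd.DataFrame(rows)


def compare_orders(auc_by_order: dict[int, list[float]]) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon signed-rank p-values over paired AUC lists.

    Entry (i, j) is the p-value for orders i vs j; the diagonal is NaN, and fully
    tied pairs (all differences zero) are reported as p = 1.
    """
    orders = sorted(auc_by_order)
    n = {o: len(auc_by_order[o]) for o in orders}
    if len(set(n.values())) != 1:
        raise ValueError(f"AUC lists must be paired (equal length); got {n}")
    mat = pd.DataFrame(np.nan, index=orders, columns=orders)
    for i in orders:
        for j in orders:
            if i >= j:
                continue
            d = np.asarray(auc_by_order[i]) - np.asarray(auc_by_order[j])
            if np.all(d == 0):
                p = 1.0
            else:
                p = float(wilcoxon(auc_by_order[i], auc_by_order[j], zero_method="wilcox").pvalue)
            mat.loc[i, j] = p
            mat.loc[j, i] = p
    return mat
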