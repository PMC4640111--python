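"""Binding-site prediction: likelihood scanning and negative-set thresholding.

The strand-marginalized joint log-likelihood ``log P(x_i, v_i = j)`` is computed for
every window of every sequence. Scanning the *negative* set yields an empirical null
distribution from which a threshold Z is taken as the smallest scanned value such
that at most a fraction ``alpha`` (default 1e-4) of negative windows score strictly
above it — an upper-tail quantile rule, so that on background alone the expected
fraction of windows called is at most alpha. All windows of the positive set scoring
above Z are then reported as binding sites; overlapping windows are all kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .oops import OOPSModel, scan_sequence
from .seqdata import SequenceSet, SiteSet, reverse_complement


def likelihood_scan(model: OOPSModel, data: SequenceSet) -> pd.DataFrame:
    """Joint log-likelihood of every valid window: columns seq_id, start, log_likelihood.

    ``start`` is 1-based; one row per (sequence, start), totalling
    ``sum_i (L_i - W + 1)`` rows.
    """
    rows = []
    for sid, x in zip(data.ids, data.encoded()):
        _, _, joint = scan_sequence(model, x)
        rows.append(
            pd.DataFrame(
                {"seq_id": sid, "start": np.arange(1, len(joint) + 1), "log_likelihood": joint}
            )
        )
    return pd.concat(rows, ignore_index=True)


def threshold_from_negatives(values, alpha: float = 1e-4, tail: str = "upper") -> float:
    """Threshold from the empirical distribution of negative-window scores.

    With ``tail="upper"`` (the default, used for prediction): the smallest listed
    value such that the fraction of values strictly greater than it is <= alpha, so
    that on background at most a fraction alpha of windows would be called. With
    ``tail="lower"``: the plain empirical alpha-quantile (smallest value with at
    least a fraction alpha of values at or below it) — provided for completeness,
    but note it admits nearly every window as a "site". No interpolation between
    list values is performed. ``alpha = 1`` returns the minimum under the
    upper-tail rule.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute a threshold from an empty list")
    srt = np.sort(values)
    n = srt.size
    if tail == "upper":
        # fraction strictly greater than srt[i] is (n - searchsorted_right) / n
        exceed = (n - np.searchsorted(srt, srt, side="right")) / n
        return float(srt[np.nonzero(exceed <= alpha)[0][0]])
    if tail == "lower":
        at_or_below = np.searchsorted(srt, srt, side="right") / n
        return float(srt[np.nonzero(at_or_below >= alpha)[0][0]])
    raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")


@dataclass
class PredictionSet:
    """Predicted binding sites with their scores; backed by a DataFrame.

    Columns: seq_id, start (1-based), strand, site (orientation-aligned, i.e.
    reverse-complemented for R records), log_likelihood.
    """

    width: int
    records: pd.DataFrame

    def site_set(self) -> SiteSet:
        return SiteSet(self.width, list(self.records["site"]))

    def __len__(self) -> int:
        return len(self.records)

    def save_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def predict_sites(model: OOPSModel, positives: SequenceSet, z: float) -> PredictionSet:
    """All windows of the positive set with joint log-likelihood strictly above ``z``.

    The joint itself is strand-marginalized; each record is additionally annotated
    with the argmax strand so the reported site strings form an aligned SiteSet
    usable for logos and demixing.
    """
    if not np.isfinite(z) and z > 0:
        raise ValueError("threshold must be finite or -inf")
    W = model.width
    rows = []
    for sid, seq, x in zip(positives.ids, positives.sequences, positives.encoded()):
        cond_f, cond_r, joint = scan_sequence(model, x)
        hits = np.nonzero(joint > z)[0]
        for j in hits:
            strand = "F" if cond_f[j] >= cond_r[j] else "R"
            window = seq[j : j + W]
            rows.append(
                {
                    "seq_id": sid,
                    "start": int(j) + 1,
                    "strand": strand,
                    "site": window if strand == "F" else reverse_complement(window),
                    "log_likelihood": float(joint[j]),
                }
            )
    records = pd.DataFrame(
        rows, columns=["seq_id", "start", "strand", "site", "log_likelihood"]
    )
    return PredictionSet(W, records)
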