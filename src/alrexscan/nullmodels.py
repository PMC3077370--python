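"""Random-PSSM null models and ROC ranking.

Null motifs have each column drawn independently from a Dirichlet
distribution whose concentration vector equals the background nucleotide
frequencies (total concentration 1, so columns are sparse/peaked — matching
the information-rich motifs being benchmarked). A motif's discriminative
power for 5UI absence is summarized by its ROC over per-sequence maximum
scores: TPR is the fraction of 5UI- sequences called motif-containing at a
threshold, FPR the same fraction for 5UI+ sequences, classification rule
max score >= t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pssm import PSSM, SCAN_REGION, encode_sequence

log = logging.getLogger(__name__)


@dataclass
class ROCCurve:
    """Threshold-swept (TPR, FPR) pairs, thresholds descending.

    Includes the (0, 0) and (1, 1) endpoints via +/- infinity sentinel
    thresholds.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        self.fpr = np.asarray(self.fpr, dtype=float)
        if np.any(np.diff(self.tpr) < 0) or np.any(np.diff(self.fpr) < 0):
            raise ValueError("TPR/FPR must be non-decreasing as threshold falls")

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))

    def tpr_at_fpr(self, f: float) -> float:
        """TPR at the smallest threshold whose FPR <= f (step interpolation)."""
        idx = int(np.searchsorted(self.fpr, f, side="right")) - 1
        return float(self.tpr[max(idx, 0)])


@dataclass
class NullRanking:
    """Target-vs-null TPR comparison on a fixed FPR grid.

    ``percentile`` is the fraction of null motifs with TPR strictly below
    the target's at each grid FPR; ``percentile_mid`` additionally credits
    half of exact ties (used for calibration checks, where strict ranking
    is sub-uniform on discrete TPR grids).
    """

    fpr_grid: np.ndarray
    target_tpr: np.ndarray
    null_tpr_median: np.ndarray
    percentile: np.ndarray
    percentile_mid: np.ndarray
    n_null: int

    @property
    def min_percentile(self) -> float:
        return float(self.percentile.min())

    def to_dict(self) -> dict:
        return {
            "fpr_grid": self.fpr_grid.tolist(),
            "target_tpr": self.target_tpr.tolist(),
            "null_tpr_median": self.null_tpr_median.tolist(),
            "percentile": self.percentile.tolist(),
            "percentile_mid": self.percentile_mid.tolist(),
            "n_null": self.n_null,
            "min_percentile": self.min_percentile,
        }


def sample_random_pssm(
    length: int,
    background: Sequence[float],
    seed: int | np.random.Generator | None = 0,
    name: str = "null",
) -> PSSM:
    """Draw a random PSSM with independent Dirichlet(background) columns."""
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be 4 positive frequencies summing to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = rng.dirichlet(bg, size=length).T  # (4, length)
    return PSSM(probs=probs, background=bg, name=name)


def empirical_background(seqs: Sequence[str], region: int = SCAN_REGION) -> np.ndarray:
    """Base frequencies of the pooled first-``region``-nt prefixes."""
    counts = np.zeros(4)
    for s in seqs:
        enc = encode_sequence(s[:region])
        counts += np.bincount(enc, minlength=4)
    if counts.sum() == 0:
        raise ValueError("no sequence content")
    return counts / counts.sum()


def build_roc(
    max_scores_pos: Sequence[float], max_scores_neg: Sequence[float]
) -> ROCCurve:
    """ROC over the union of observed per-sequence maximum scores."""
    pos = np.asarray(list(max_scores_pos), dtype=float)
    neg = np.asarray(list(max_scores_neg), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    thr = np.concatenate(
        [[np.inf], np.unique(np.concatenate([pos, neg]))[::-1], [-np.inf]]
    )
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # count of scores >= t via searchsorted on ascending arrays
    tpr = 1.0 - np.searchsorted(pos_sorted, thr, side="left") / pos.size
    fpr = 1.0 - np.searchsorted(neg_sorted, thr, side="left") / neg.size
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr)


class SequenceScanPool:
    """Encoded first-``region``-nt prefixes with fast max-score evaluation."""

    def __init__(self, seqs: Sequence[str], region: int = SCAN_REGION):
        if any(len(s) < region for s in seqs):
            raise ValueError(f"all sequences must be >= {region} nt")
        self.region = region
        self.encoded = np.stack([encode_sequence(s[:region]) for s in seqs])
        self._windows: dict[int, np.ndarray] = {}

    def _window_view(self, L: int) -> np.ndarray:
        if L not in self._windows:
            self._windows[L] = np.lib.stride_tricks.sliding_window_view(
                self.encoded, L, axis=1
            )
        return self._windows[L]

    def max_scores(self, pssm: PSSM) -> np.ndarray:
        """Maximum window log-odds score per sequence."""
        L = pssm.length
        if self.region < L:
            raise ValueError("scan region shorter than motif")
        W = self._window_view(L)  # (n, n_win, L)
        lo = pssm.log_odds
        scores = lo[W[:, :, 0], 0]
        for j in range(1, L):
            scores = scores + lo[W[:, :, j], j]
        return scores.max(axis=1)


def rank_against_null(
    target: PSSM,
    pos_seqs: Sequence[str],
    neg_seqs: Sequence[str],
    n_null: int = 1000,
    fpr_grid: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
    seed: int = 0,
    region: int = SCAN_REGION,
    background: Sequence[float] | None = None,
) -> NullRanking:
    """Rank a target motif against Dirichlet random PSSMs of equal length.

    Every sequence is scanned threshold-free with the target and each null;
    TPR-at-FPR is evaluated by step interpolation on each curve. The null
    background defaults to the empirical base frequencies of the pooled
    positive + negative prefixes.
    """
    fpr_grid = np.asarray(list(fpr_grid), dtype=float)
    if np.any(fpr_grid <= 0) or np.any(fpr_grid >= 1):
        raise ValueError("fpr_grid values must be in (0, 1)")
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    pool_pos = SequenceScanPool(pos_seqs, region)
    pool_neg = SequenceScanPool(neg_seqs, region)
    bg = (
        np.asarray(background, float)
        if background is not None
        else empirical_background(list(pos_seqs) + list(neg_seqs), region)
    )
    target_roc = build_roc(pool_pos.max_scores(target), pool_neg.max_scores(target))
    target_tpr = np.array([target_roc.tpr_at_fpr(f) for f in fpr_grid])

    rng = np.random.default_rng(seed)
    null_tpr = np.empty((n_null, fpr_grid.size))
    for i in range(n_null):
        null = sample_random_pssm(target.length, bg, rng, name=f"null_{i}")
        roc = build_roc(pool_pos.max_scores(null), pool_neg.max_scores(null))
        null_tpr[i] = [roc.tpr_at_fpr(f) for f in fpr_grid]

    below = (null_tpr < target_tpr[None, :] - 1e-12).mean(axis=0)
    equal = (np.abs(null_tpr - target_tpr[None, :]) <= 1e-12).mean(axis=0)
    return NullRanking(
        fpr_grid=fpr_grid,
        target_tpr=target_tpr,
        null_tpr_median=np.median(null_tpr, axis=0),
        percentile=below,
        percentile_mid=below + 0.5 * equal,
        n_null=n_null,
    )


def select_threshold_tprime(
    target_roc: ROCCurve, null_rocs: Sequence[ROCCurve]
) -> float:
    """Threshold maximizing target TPR minus null-median TPR at matched FPR.

    Candidates are the target curve's thresholds; ties go to the larger
    (more stringent) threshold.
    """
    if not null_rocs:
        raise ValueError("need at least one null ROC curve")
    best_t = None
    best_delta = -np.inf
    for t, tpr, fpr in zip(target_roc.thresholds, target_roc.tpr, target_roc.fpr):
        null_median = float(np.median([nc.tpr_at_fpr(fpr) for nc in null_rocs]))
        delta = tpr - null_median
        # thresholds iterate in descending order; strict > keeps the largest t
        if delta > best_delta + 1e-15:
            best_delta = delta
            best_t = float(t)
    assert best_t is not None
    return best_t
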