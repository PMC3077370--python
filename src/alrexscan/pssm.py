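"""PSSM motif machinery.

Windows of motif width inside the first 99 nt of each CDS are scored with a
log-odds (bits) position-specific scoring matrix; overlapping windows are
disambiguated by greedy non-maximum suppression so that retained hits never
mutually overlap. Downstream analyses (threshold selection, occurrence and
frame statistics, multiplicity) all reuse the same threshold-free scan.

The discriminative degenerate k-mer scan is a deliberately simple,
exhaustive stand-in for external discriminative motif discovery tools: it
ranks every k-mer over {A,C,G,T,S,W} by the enrichment (greater-tail
hypergeometric) of its presence among positive versus negative sequences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .stats import ContingencyTable2x2, TestResult, hypergeom_tail, wilcoxon_rank_sum

log = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: scan region at the 5' end of the CDS (nt), wide enough to contain any
#: signal peptide in its entirety
SCAN_REGION = 99

#: degenerate nucleotide codes used by the k-mer scan
DEGENERATE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "S": "CG", "W": "AT",
}
# which degenerate letters (over ACGTSW) match a given concrete base
_MATCHING_LETTERS = {
    "A": ("A", "W"), "C": ("C", "S"), "G": ("G", "S"), "T": ("T", "W"),
}


@dataclass
class PSSM:
    """Per-position nucleotide probability matrix with background.

    ``probs`` has shape (4, length), rows ordered A, C, G, T; every column
    sums to one. Scores are log2(p / background) summed over positions.
    """

    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    name: str = "motif"

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4 or self.probs.shape[1] < 4:
            raise ValueError("probs must be 4 x length with length >= 4")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PSSM columns must each sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """(4, length) matrix of log2(p/background); -inf where p = 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background[:, None])


@dataclass(frozen=True)
class MotifHit:
    transcript_id: str
    position: int  # 0-based CDS offset of the window start
    score: float

    @property
    def frame(self) -> int:
        return self.position % 3


@dataclass
class ThresholdSelection:
    t_star: float
    fisher_p: float
    table_at_t: ContingencyTable2x2


def pssm_from_sites(
    sites: Sequence[str], pseudocount: float = 0.5,
    background: Sequence[float] | None = None, name: str = "motif",
) -> PSSM:
    """Estimate a PSSM from aligned equal-length forward-strand sites."""
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    L = len(sites[0])
    if any(len(s) != L for s in sites):
        raise ValueError("sites must have identical lengths")
    counts = np.zeros((4, L))
    for s in sites:
        for j, b in enumerate(s.upper()):
            counts[BASE_INDEX[b], j] += 1
    probs = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PSSM(probs=probs, background=bg, name=name)


def pssm_from_consensus(
    consensus: str, smoothing: float = 0.04,
    background: Sequence[float] | None = None, name: str | None = None,
) -> PSSM:
    """Build a PSSM from a degenerate consensus (codes A,C,G,T,S,W).

    Allowed bases at each position share 1 - smoothing of the probability
    mass; the remainder is spread over the disallowed bases so that
    log-odds scores stay finite.
    """
    consensus = consensus.upper()
    L = len(consensus)
    probs = np.empty((4, L))
    for j, letter in enumerate(consensus):
        allowed = DEGENERATE.get(letter)
        if allowed is None:
            raise ValueError(f"unsupported consensus code: {letter}")
        n_allowed = len(allowed)
        col = np.full(4, smoothing / (4 - n_allowed) if n_allowed < 4 else 0.0)
        for b in allowed:
            col[BASE_INDEX[b]] = (1.0 - smoothing) / n_allowed
        probs[:, j] = col
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PSSM(probs=probs, background=bg, name=name or consensus)


# ---------------------------------------------------------------------------
# simple text formats

def write_pssm(pssm: PSSM, path: str | Path) -> None:
    """Four labeled rows (A/C/G/T), whitespace-separated probabilities."""
    with open(path, "w") as fh:
        fh.write(f"# PSSM {pssm.name}\n")
        fh.write("# background " + " ".join(f"{v:.6f}" for v in pssm.background) + "\n")
        for i, b in enumerate(BASES):
            fh.write(b + " " + " ".join(f"{v:.6f}" for v in pssm.probs[i]) + "\n")


def read_pssm(path: str | Path, name: str | None = None) -> PSSM:
    rows: dict[str, list[float]] = {}
    background = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "background":
                    background = [float(v) for v in parts[1:5]]
                continue
            parts = line.split()
            if parts[0].upper() in BASE_INDEX:
                rows[parts[0].upper()] = [float(v) for v in parts[1:]]
    if set(rows) != set(BASES):
        raise ValueError(f"PSSM file must have rows A,C,G,T; got {sorted(rows)}")
    probs = np.array([rows[b] for b in BASES])
    # renormalize columns to absorb printed rounding
    probs = probs / probs.sum(axis=0, keepdims=True)
    bg = np.asarray(background, float) if background else np.full(4, 0.25)
    bg = bg / bg.sum()
    return PSSM(probs=probs, background=bg, name=name or Path(path).stem)


def read_meme_minimal(path: str | Path) -> list[PSSM]:
    """Parse motifs from MEME minimal format (letter-probability matrices)."""
    motifs: list[PSSM] = []
    background = np.full(4, 0.25)
    name = None
    matrix: list[list[float]] = []
    expecting = 0

    def flush():
        nonlocal matrix, name
        if matrix:
            probs = np.array(matrix).T
            probs = probs / probs.sum(axis=0, keepdims=True)
            motifs.append(PSSM(probs=probs, background=background.copy(),
                               name=name or f"motif_{len(motifs) + 1}"))
        matrix = []

    with open(path) as fh:
        lines = iter(fh)
        for line in lines:
            stripped = line.strip()
            if stripped.startswith("Background letter frequencies"):
                freq_line = next(lines).split()
                vals = {freq_line[i]: float(freq_line[i + 1])
                        for i in range(0, len(freq_line), 2)}
                background = np.array([vals.get(b, 0.25) for b in BASES])
                background = background / background.sum()
            elif stripped.startswith("MOTIF"):
                flush()
                name = stripped.split()[1] if len(stripped.split()) > 1 else None
            elif stripped.startswith("letter-probability matrix"):
                expecting = 1
            elif expecting and stripped and stripped[0] in "0123456789.":
                matrix.append([float(v) for v in stripped.split()[:4]])
            elif expecting and not stripped:
                expecting = 0
    flush()
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs


# ---------------------------------------------------------------------------
# scanning

def encode_sequence(seq: str) -> np.ndarray:
    try:
        return np.array([BASE_INDEX[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"sequence contains non-ACGT base {exc}") from exc


def window_scores(pssm: PSSM, cds: str, region: int = SCAN_REGION) -> np.ndarray:
    """Log-odds score of every window start in [0, region - length]."""
    L = pssm.length
    if region < L:
        raise ValueError(f"scan region {region} shorter than motif length {L}")
    if len(cds) < region:
        raise ValueError(
            f"sequence length {len(cds)} shorter than scan region {region}"
        )
    enc = encode_sequence(cds[:region])
    lo = pssm.log_odds
    n_win = region - L + 1
    scores = np.zeros(n_win)
    for j in range(L):
        scores += lo[enc[j : j + n_win], j]
    return scores


def _greedy_nms(scores: np.ndarray, length: int) -> list[int]:
    """Keep best-scoring windows, suppressing all overlapping ones.

    Order: score descending, ties broken leftmost. Retained starts are
    pairwise >= length apart.
    """
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= length for j in kept):
            kept.append(i)
    return sorted(kept)


def scan_sequence(
    pssm: PSSM, cds: str, region: int = SCAN_REGION, transcript_id: str = ""
) -> list[MotifHit]:
    """Score all windows in the first ``region`` nt and collapse overlaps.

    No threshold is applied here; hits are filtered downstream so the t*
    and t' analyses share one scan.
    """
    scores = window_scores(pssm, cds, region)
    kept = _greedy_nms(scores, pssm.length)
    return [
        MotifHit(transcript_id=transcript_id, position=i, score=float(scores[i]))
        for i in kept
    ]


def max_window_score(pssm: PSSM, cds: str, region: int = SCAN_REGION) -> float:
    return float(window_scores(pssm, cds, region).max())


# ---------------------------------------------------------------------------
# threshold selection (t*)

def select_threshold_tstar(
    max_scores_pos: Sequence[float], max_scores_neg: Sequence[float]
) -> ThresholdSelection:
    """Pick the score threshold maximizing enrichment of the positive set.

    Each sequence contributes its maximum retained window score; candidate
    thresholds are the distinct observed maxima. A sequence is
    motif-containing iff its maximum >= t. Returns the t with the smallest
    greater-tail hypergeometric p; ties go to the larger (more stringent) t.
    """
    pos = np.asarray(list(max_scores_pos), dtype=float)
    neg = np.asarray(list(max_scores_neg), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    candidates = np.unique(np.concatenate([pos, neg]))[::-1]  # descending
    best: ThresholdSelection | None = None
    for t in candidates:
        a = int((pos >= t).sum())
        b = int((neg >= t).sum())
        table = ContingencyTable2x2(a=a, b=b, c=pos.size - a, d=neg.size - b)
        p = hypergeom_tail(table, "greater")
        # strict < keeps the first (largest) t among ties
        if best is None or p < best.fisher_p:
            best = ThresholdSelection(t_star=float(t), fisher_p=p, table_at_t=table)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# occurrence statistics

@dataclass
class GroupOccurrence:
    n_sequences: int
    n_with_ge1: int
    n_with_ge2: int
    frame_counts: tuple[int, int, int]
    frame_chi2_p: float | None
    positions: list[int]
    median_position: float | None

    @property
    def frac_ge1(self) -> float:
        return self.n_with_ge1 / self.n_sequences if self.n_sequences else 0.0

    @property
    def frac_ge2(self) -> float:
        return self.n_with_ge2 / self.n_sequences if self.n_sequences else 0.0

    @property
    def frame_fractions(self) -> tuple[float, float, float]:
        total = sum(self.frame_counts)
        if total == 0:
            return (0.0, 0.0, 0.0)
        return tuple(c / total for c in self.frame_counts)  # type: ignore

    def to_dict(self) -> dict:
        return {
            "n_sequences": self.n_sequences,
            "frac_ge1": self.frac_ge1,
            "frac_ge2": self.frac_ge2,
            "frame_counts": list(self.frame_counts),
            "frame_fractions": list(self.frame_fractions),
            "frame_chi2_p": self.frame_chi2_p,
            "median_position": self.median_position,
        }


@dataclass
class OccurrenceReport:
    """Occurrence/frame/position summary per 5UI group.

    Positions are 0-based window starts within the CDS; the positive group
    is the 5UI-lacking one, mirroring the discriminative setup.
    """

    positive: GroupOccurrence  # 5UI- sequences
    negative: GroupOccurrence  # 5UI+ sequences
    positional_test: TestResult | None

    def to_dict(self) -> dict:
        return {
            "position_convention": "0-based window start",
            "positive_5ui_minus": self.positive.to_dict(),
            "negative_5ui_plus": self.negative.to_dict(),
            "positional_test": (
                self.positional_test.to_dict() if self.positional_test else None
            ),
        }


def _group_occurrence(hit_lists: list[list[int]]) -> GroupOccurrence:
    n = len(hit_lists)
    ge1 = sum(1 for h in hit_lists if len(h) >= 1)
    ge2 = sum(1 for h in hit_lists if len(h) >= 2)
    positions = [p for h in hit_lists for p in h]
    frames = [0, 0, 0]
    for p in positions:
        frames[p % 3] += 1
    chi2_p = None
    if positions:
        chi2_p = float(sps.chisquare(frames).pvalue)
    return GroupOccurrence(
        n_sequences=n,
        n_with_ge1=ge1,
        n_with_ge2=ge2,
        frame_counts=tuple(frames),  # type: ignore
        frame_chi2_p=chi2_p,
        positions=positions,
        median_position=float(np.median(positions)) if positions else None,
    )


def occurrence_stats(
    hits_by_id: Mapping[str, Sequence[MotifHit] | Sequence[int]],
    labels: Mapping[str, bool],
) -> OccurrenceReport:
    """Summarize thresholded hits by 5UI status.

    ``hits_by_id`` maps transcript id to its retained (already thresholded)
    hits — MotifHit objects or bare positions; ids present in ``labels`` but
    absent from ``hits_by_id`` count as zero-hit sequences. ``labels`` maps
    id to has_5ui.
    """
    pos_lists: list[list[int]] = []
    neg_lists: list[list[int]] = []
    for tid, has_5ui in labels.items():
        hits = hits_by_id.get(tid, ())
        positions = [h.position if isinstance(h, MotifHit) else int(h) for h in hits]
        (neg_lists if has_5ui else pos_lists).append(positions)
    positive = _group_occurrence(pos_lists)
    negative = _group_occurrence(neg_lists)
    positional_test = None
    if positive.positions and negative.positions:
        positional_test = wilcoxon_rank_sum(
            positive.positions, negative.positions, mode="normal_approx"
        )
    return OccurrenceReport(
        positive=positive, negative=negative, positional_test=positional_test
    )


# ---------------------------------------------------------------------------
# exhaustive discriminative degenerate k-mer scan (stand-in for external
# discriminative motif discovery)

@dataclass
class KmerResult:
    pattern: str
    pos_present: int
    neg_present: int
    p_value: float
    p_bonferroni: float


def _present_patterns(seq: str, k: int, region: int) -> set[str]:
    """All degenerate k-mers over {A,C,G,T,S,W} matching somewhere in seq."""
    prefix = seq[:region].upper()
    patterns: set[str] = set()
    for i in range(len(prefix) - k + 1):
        word = prefix[i : i + k]
        if set(word) - set(BASES):
            continue
        options = [_MATCHING_LETTERS[b] for b in word]
        patterns.update("".join(p) for p in product(*options))
    return patterns


def discriminative_kmer_scan(
    pos_seqs: Sequence[str],
    neg_seqs: Sequence[str],
    k: int = 6,
    region: int = SCAN_REGION,
    top: int | None = None,
) -> list[KmerResult]:
    """Rank all degenerate k-mers by presence enrichment in pos vs neg.

    Presence is per sequence within the first ``region`` nt; the p-value is
    the greater-tail hypergeometric of the overlap between positive
    sequences and pattern-containing sequences, Bonferroni-adjusted over
    the full 6^k enumeration. k > 8 is refused.
    """
    if k > 8:
        raise ValueError("k > 8 refused (6^k enumeration would be excessive)")
    if any(len(s) < k for s in list(pos_seqs) + list(neg_seqs)):
        raise ValueError("all sequences must be at least k nt long")
    n_pos, n_neg = len(pos_seqs), len(neg_seqs)
    pos_counts: dict[str, int] = {}
    neg_counts: dict[str, int] = {}
    for seq in pos_seqs:
        for pat in _present_patterns(seq, k, region):
            pos_counts[pat] = pos_counts.get(pat, 0) + 1
    for seq in neg_seqs:
        for pat in _present_patterns(seq, k, region):
            neg_counts[pat] = neg_counts.get(pat, 0) + 1
    n_tests = len(DEGENERATE) ** k
    results = []
    for pat in set(pos_counts) | set(neg_counts):
        cp = pos_counts.get(pat, 0)
        cn = neg_counts.get(pat, 0)
        table = ContingencyTable2x2(a=cp, b=cn, c=n_pos - cp, d=n_neg - cn)
        p = hypergeom_tail(table, "greater")
        results.append(
            KmerResult(
                pattern=pat, pos_present=cp, neg_present=cn,
                p_value=p, p_bonferroni=min(1.0, p * n_tests),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.pattern))
    return results[:top] if top else results


def write_hits_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    """TSV hit report; positions are 1-based in this human-facing output."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tposition_1based\tframe\tscore_bits\n")
        for h in hits:
            fh.write(f"{h.transcript_id}\t{h.position + 1}\t{h.frame}\t{h.score:.6f}\n")
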