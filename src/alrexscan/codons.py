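"""Leader-window codon composition features.

The first 69 nt of each CDS (the leader window, long enough to cover
essentially all signal peptides) are compared against the rest of the open
reading frame. Features: adenine content, leucine:isoleucine and
arginine:lysine usage, and the ratio of adenine-lacking to adenine-containing
codons over the seven amino acids that have both kinds (L, V, A, P, S, G, R),
plus the analogous thymine ratio over its nine amino acids
(A, T, P, H, N, D, R, S, G).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .ingest import LEADER_WINDOW, TranscriptRecord
from .stats import (
    ContingencyTable2x2,
    TestResult,
    bootstrap_median_se,
    fisher_exact_2x2,
    wilcoxon_rank_sum,
)

log = logging.getLogger(__name__)

CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)

#: amino acids possessing both adenine-lacking and adenine-containing codons
ADENINE_AMINO_ACIDS = frozenset("LVAPSGR")
#: amino acids possessing both thymine-lacking and thymine-containing codons
THYMINE_AMINO_ACIDS = frozenset("ATPHNDRSG")

FEATURES = (
    "adenine_percent",
    "leu_ile",
    "arg_lys",
    "adenine_codons",
    "thymine_codons",
)


@dataclass
class CodonFeatureVector:
    adenine_count: int
    window_length: int
    aa_counts: Counter
    adenineless_codons: int
    adenineful_codons: int
    thymineless_codons: int
    thymineful_codons: int
    window: str = "first69"

    @property
    def adenine_percent(self) -> float:
        return 100.0 * self.adenine_count / self.window_length


def partition_cds(record: TranscriptRecord | str) -> tuple[str, str]:
    """Split a CDS into the 69-nt leader window and the rest of the ORF."""
    cds = record.cds if isinstance(record, TranscriptRecord) else record
    if len(cds) % 3 != 0 or len(cds) < 150:
        raise ValueError(
            f"CDS must be a multiple of 3 and >= 150 nt, got {len(cds)}"
        )
    return cds[:LEADER_WINDOW], cds[LEADER_WINDOW:]


def codon_feature_vector(seq: str, window: str = "first69") -> CodonFeatureVector:
    """Compute composition features of an in-frame nucleotide string.

    Stop codons contribute to nucleotide counts but not to amino-acid
    tallies. A codon is adenine-lacking iff none of its three bases is A,
    counted only for the seven amino acids that have both codon kinds;
    thymine analogously over its nine.
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    if set(seq) - set("ACGT"):
        raise ValueError("sequence contains ambiguous bases")
    aa_counts: Counter = Counter()
    a_less = a_full = t_less = t_full = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            continue
        aa = CODON_TO_AA[codon]
        aa_counts[aa] += 1
        if aa in ADENINE_AMINO_ACIDS:
            if "A" in codon:
                a_full += 1
            else:
                a_less += 1
        if aa in THYMINE_AMINO_ACIDS:
            if "T" in codon:
                t_full += 1
            else:
                t_less += 1
    return CodonFeatureVector(
        adenine_count=seq.count("A"),
        window_length=len(seq),
        aa_counts=aa_counts,
        adenineless_codons=a_less,
        adenineful_codons=a_full,
        thymineless_codons=t_less,
        thymineful_codons=t_full,
        window=window,
    )


def feature_table(records: Iterable[TranscriptRecord]) -> pd.DataFrame:
    """One row per transcript x window with all composition features."""
    rows = []
    for rec in records:
        first69, rest = partition_cds(rec)
        for window, seq in (("first69", first69), ("rest", rest)):
            v = codon_feature_vector(seq, window)
            rows.append(
                {
                    "transcript_id": rec.transcript_id,
                    "window": window,
                    "leader_class": rec.leader_class.value,
                    "has_5ui": rec.has_5ui,
                    "adenine_count": v.adenine_count,
                    "adenine_percent": v.adenine_percent,
                    "L": v.aa_counts.get("L", 0),
                    "I": v.aa_counts.get("I", 0),
                    "R": v.aa_counts.get("R", 0),
                    "K": v.aa_counts.get("K", 0),
                    "adenineless_codons": v.adenineless_codons,
                    "adenineful_codons": v.adenineful_codons,
                    "thymineless_codons": v.thymineless_codons,
                    "thymineful_codons": v.thymineful_codons,
                }
            )
    return pd.DataFrame(rows)


_RATIO_PAIRS = {
    "leu_ile": ("L", "I"),
    "arg_lys": ("R", "K"),
}
_CLASS_PAIRS = {
    "adenine_codons": ("adenineless_codons", "adenineful_codons"),
    "thymine_codons": ("thymineless_codons", "thymineful_codons"),
}


@dataclass
class GroupComparison:
    feature: str
    test: TestResult
    group1: dict = field(default_factory=dict)
    group2: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "test": self.test.to_dict(),
            "group1": self.group1,
            "group2": self.group2,
        }


def _pair_counts(vec: CodonFeatureVector, feature: str) -> tuple[int, int]:
    if feature in _RATIO_PAIRS:
        num, den = _RATIO_PAIRS[feature]
        return vec.aa_counts.get(num, 0), vec.aa_counts.get(den, 0)
    num, den = _CLASS_PAIRS[feature]
    return getattr(vec, num), getattr(vec, den)


def compare_groups(
    group1: Sequence[CodonFeatureVector],
    group2: Sequence[CodonFeatureVector],
    feature: str,
    bootstrap_B: int = 1000,
    seed: int = 0,
) -> GroupComparison:
    """Compare a composition feature between two transcript groups.

    adenine_percent: Wilcoxon rank-sum on per-sequence values, with group
    medians and bootstrap SEs. Count ratios (leu_ile, arg_lys,
    adenine_codons, thymine_codons): Fisher's exact test on pooled counts —
    the only construction that yields the odds-ratio confidence intervals
    the per-group ratio summaries are reported with. Per-gene mean ratios
    are emitted alongside, dropping genes with a zero denominator (count
    logged).
    """
    if not group1 or not group2:
        raise ValueError("both groups must be non-empty")
    if feature == "adenine_percent":
        x = [v.adenine_percent for v in group1]
        y = [v.adenine_percent for v in group2]
        test = wilcoxon_rank_sum(x, y, mode="normal_approx")
        g1 = {
            "n": len(x),
            "median": float(np.median(x)),
            "median_se": bootstrap_median_se(x, B=bootstrap_B, seed=seed),
        }
        g2 = {
            "n": len(y),
            "median": float(np.median(y)),
            "median_se": bootstrap_median_se(y, B=bootstrap_B, seed=seed + 1),
        }
        return GroupComparison(feature=feature, test=test, group1=g1, group2=g2)

    if feature not in _RATIO_PAIRS and feature not in _CLASS_PAIRS:
        raise ValueError(f"unknown feature: {feature}")

    def summarize(group, label):
        num = sum(_pair_counts(v, feature)[0] for v in group)
        den = sum(_pair_counts(v, feature)[1] for v in group)
        per_gene = []
        dropped = 0
        for v in group:
            a, b = _pair_counts(v, feature)
            if b == 0:
                dropped += 1
            else:
                per_gene.append(a / b)
        if dropped:
            log.info("%s %s: %d genes with zero denominator dropped from "
                     "per-gene ratios", feature, label, dropped)
        return {
            "n": len(group),
            "pooled_num": num,
            "pooled_den": den,
            "pooled_ratio": num / den if den else float("nan"),
            "mean_per_gene_ratio": float(np.mean(per_gene)) if per_gene else float("nan"),
            "per_gene_dropped": dropped,
        }

    g1 = summarize(group1, "group1")
    g2 = summarize(group2, "group2")
    table = ContingencyTable2x2(
        a=g1["pooled_num"], b=g1["pooled_den"],
        c=g2["pooled_num"], d=g2["pooled_den"],
    )
    test = fisher_exact_2x2(table, tail="two_sided")
    return GroupComparison(feature=feature, test=test, group1=g1, group2=g2)
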