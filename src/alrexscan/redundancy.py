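"""Sequence redundancy reduction before motif analysis.

The first 99 nt of every CDS is locally aligned against all others
(match +1 / mismatch -1 / gap -2); pairs reaching the identity threshold
over a sufficient aligned span are linked and single-linkage connected
components form clusters, from each of which one seeded-random
representative is kept. The thresholds (identity >= 0.9 over >= 60 aligned
columns) are chosen to merge only near-duplicate leaders so closely related
sequences do not overweight downstream motif statistics.

A k-mer prescreen skips pairs that cannot reach the identity threshold: at
>= 90% identity over >= 60 ungapped columns the pigeonhole principle forces
a shared exact 8-mer, so only pairs sharing one are aligned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from .ingest import TranscriptRecord
from .pssm import SCAN_REGION

log = logging.getLogger(__name__)

_PRESCREEN_K = 8


@dataclass
class SimilarityCluster:
    member_ids: list[str]
    representative_id: str

    def __post_init__(self):
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a cluster member")


def _make_aligner(match: float = 1.0, mismatch: float = -1.0,
                  gap: float = -2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def _similar(aligner, s1: str, s2: str, min_identity: float,
             min_overlap: int) -> bool:
    aln = aligner.align(s1, s2)[0]
    counts = aln.counts()
    span = counts.identities + counts.mismatches + counts.gaps
    if span < min_overlap:
        return False
    return counts.identities / span >= min_identity


def _candidate_pairs(prefixes: Sequence[str]) -> Iterable[tuple[int, int]]:
    """Pairs of indices sharing at least one exact 8-mer in their prefixes."""
    by_kmer: dict[str, list[int]] = {}
    for idx, seq in enumerate(prefixes):
        for i in range(len(seq) - _PRESCREEN_K + 1):
            by_kmer.setdefault(seq[i : i + _PRESCREEN_K], []).append(idx)
    pairs: set[tuple[int, int]] = set()
    for ids in by_kmer.values():
        uniq = sorted(set(ids))
        if len(uniq) < 2:
            continue
        for a_i in range(len(uniq)):
            for b_i in range(a_i + 1, len(uniq)):
                pairs.add((uniq[a_i], uniq[b_i]))
    return sorted(pairs)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_first99(
    records: Sequence[TranscriptRecord],
    min_identity: float = 0.9,
    min_overlap: int = 60,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> list[SimilarityCluster]:
    """Single-linkage clusters of similar first-99-nt prefixes.

    The placeholder representative is the lexicographically smallest member;
    use :func:`pick_representatives` for the seeded-random choice.
    """
    for rec in records:
        if len(rec.cds) < SCAN_REGION:
            raise ValueError(
                f"{rec.transcript_id}: CDS shorter than {SCAN_REGION} nt"
            )
    prefixes = [rec.cds[:SCAN_REGION] for rec in records]
    aligner = _make_aligner(match, mismatch, gap)
    uf = _UnionFind(len(records))
    for i, j in _candidate_pairs(prefixes):
        if _similar(aligner, prefixes[i], prefixes[j], min_identity, min_overlap):
            uf.union(i, j)
    components: dict[int, list[int]] = {}
    for idx in range(len(records)):
        components.setdefault(uf.find(idx), []).append(idx)
    clusters = []
    for indices in components.values():
        ids = sorted(records[i].transcript_id for i in indices)
        clusters.append(SimilarityCluster(member_ids=ids, representative_id=ids[0]))
    clusters.sort(key=lambda c: c.member_ids[0])
    return clusters


def pick_representatives(
    clusters: Sequence[SimilarityCluster],
    records: Sequence[TranscriptRecord],
    seed: int = 0,
) -> list[TranscriptRecord]:
    """One seeded-random representative per cluster (deterministic per seed)."""
    by_id = {r.transcript_id: r for r in records}
    rng = np.random.default_rng(seed)
    chosen = []
    for cluster in sorted(clusters, key=lambda c: c.member_ids[0]):
        members = sorted(cluster.member_ids)
        pick = members[int(rng.integers(len(members)))]
        cluster.representative_id = pick
        chosen.append(by_id[pick])
    return sorted(chosen, key=lambda r: r.transcript_id)


def write_cluster_report(
    clusters: Sequence[SimilarityCluster], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\trepresentative_id\tmember_count\tmember_ids\n")
        for i, c in enumerate(clusters):
            fh.write(
                f"{i}\t{c.representative_id}\t{len(c.member_ids)}\t"
                + ",".join(c.member_ids)
                + "\n"
            )
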