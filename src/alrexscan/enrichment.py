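"""Category enrichment of 5UI status.

Per-term Fisher's exact test with a log10 odds-ratio (LOD) effect size,
Westfall-Young min-p resampling adjustment (label permutations preserve the
dependency structure between overlapping terms), and a stratified
Cochran-Mantel-Haenszel control for the 5'UTR-length confound.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.contingency_tables import StratifiedTable

from .ingest import LeaderClass, TranscriptRecord
from .stats import ContingencyTable2x2, TestResult, fisher_exact_2x2

log = logging.getLogger(__name__)


@dataclass
class CategoryAnnotation:
    term_id: str
    member_ids: frozenset[str]

    def __post_init__(self):
        self.member_ids = frozenset(self.member_ids)
        if not self.member_ids:
            raise ValueError(f"term {self.term_id} has no members")


@dataclass
class EnrichmentRow:
    term_id: str
    n_term: int
    k_term_5ui: int
    n_total: int
    k_total_5ui: int
    lod: float
    p_raw: float
    p_adj: float | None = None

    def to_dict(self) -> dict:
        return {
            "term_id": self.term_id,
            "n_term": self.n_term,
            "k_term_5ui": self.k_term_5ui,
            "n_total": self.n_total,
            "k_total_5ui": self.k_total_5ui,
            "lod": self.lod,
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
        }


def read_category_annotations(path: str | Path) -> list[CategoryAnnotation]:
    """Two-column TSV (term_id, transcript_id); '#' comments allowed."""
    members: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            term, tid = line.split("\t")[:2]
            members.setdefault(term, set()).add(tid)
    return [CategoryAnnotation(t, frozenset(m)) for t, m in sorted(members.items())]


def write_enrichment_tsv(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    pd.DataFrame([r.to_dict() for r in rows]).to_csv(path, sep="\t", index=False)


def _lod(a: int, b: int, c: int, d: int) -> float:
    """log10 odds ratio with Haldane +0.5 applied only on zero cells."""
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return math.log10((a * d) / (b * c))


def term_enrichment(
    annotations: Sequence[CategoryAnnotation],
    labels: Mapping[str, bool],
    sort: str = "abs_lod",
) -> list[EnrichmentRow]:
    """Fisher enrichment of 5UI status per category term.

    ``labels`` maps every transcript id in the universe to has_5ui. The 2x2
    per term is (in-term x 5UI+); LOD > 0 means the term is enriched for
    5UI-containing genes, LOD < 0 depleted. sort: 'abs_lod' (descending
    magnitude), 'lod' (ascending — depletion view) or 'p'.
    """
    universe = set(labels)
    n_total = len(universe)
    k_total = sum(bool(v) for v in labels.values())
    rows = []
    for ann in annotations:
        unknown = ann.member_ids - universe
        if unknown:
            raise ValueError(
                f"term {ann.term_id} has unlabeled ids, e.g. {sorted(unknown)[0]}"
            )
        n_term = len(ann.member_ids)
        k_term = sum(1 for tid in ann.member_ids if labels[tid])
        a = k_term                      # in-term, 5UI+
        b = n_term - k_term             # in-term, 5UI-
        c = k_total - k_term            # out-of-term, 5UI+
        d = (n_total - n_term) - c      # out-of-term, 5UI-
        res = fisher_exact_2x2(ContingencyTable2x2(a=a, b=b, c=c, d=d), "two_sided")
        rows.append(
            EnrichmentRow(
                term_id=ann.term_id,
                n_term=n_term,
                k_term_5ui=k_term,
                n_total=n_total,
                k_total_5ui=k_total,
                lod=_lod(a, b, c, d),
                p_raw=res.p_value,
            )
        )
    if sort == "abs_lod":
        rows.sort(key=lambda r: (-abs(r.lod), r.p_raw, r.term_id))
    elif sort == "lod":
        rows.sort(key=lambda r: (r.lod, r.p_raw, r.term_id))
    elif sort == "p":
        rows.sort(key=lambda r: (r.p_raw, r.term_id))
    else:
        raise ValueError(f"unknown sort: {sort}")
    return rows


class _FisherLookup:
    """Two-sided Fisher p for every possible in-term 5UI+ count of a term."""

    def __init__(self, n_total: int, k_total: int):
        self.n_total = n_total
        self.k_total = k_total
        self._cache: dict[int, np.ndarray] = {}

    def table(self, n_term: int) -> np.ndarray:
        if n_term not in self._cache:
            ps = np.empty(n_term + 1)
            for k in range(n_term + 1):
                a = k
                b = n_term - k
                c = self.k_total - k
                d = (self.n_total - n_term) - c
                if min(c, d) < 0:
                    ps[k] = np.nan
                    continue
                ps[k] = fisher_exact_2x2(
                    ContingencyTable2x2(a=a, b=b, c=c, d=d), "two_sided"
                ).p_value
            self._cache[n_term] = ps
        return self._cache[n_term]


def resampling_adjust(
    rows: Sequence[EnrichmentRow],
    annotations: Sequence[CategoryAnnotation],
    labels: Mapping[str, bool],
    n_resamples: int = 10000,
    seed: int = 0,
) -> list[EnrichmentRow]:
    """Westfall-Young min-p adjusted p-values by label resampling.

    Labels are permuted over transcripts preserving the number of 5UI+
    genes; per permutation the minimum raw p over all terms is recorded and
    p_adj(term) = (1 + #{min p <= p_raw}) / (1 + n_resamples), with add-one
    smoothing and monotone (step-down) enforcement in p_raw order.
    """
    universe = sorted(labels)
    index = {tid: i for i, tid in enumerate(universe)}
    n_total = len(universe)
    k_total = sum(bool(labels[t]) for t in universe)
    ann_by_id = {a.term_id: a for a in annotations}
    term_matrix = np.zeros((len(rows), n_total), dtype=float)
    for r_i, row in enumerate(rows):
        for tid in ann_by_id[row.term_id].member_ids:
            term_matrix[r_i, index[tid]] = 1.0
    sizes = term_matrix.sum(axis=1).astype(int)
    lookup = _FisherLookup(n_total, k_total)
    p_tables = [lookup.table(s) for s in sizes]

    rng = np.random.default_rng(seed)
    base = np.zeros(n_total)
    base[:k_total] = 1.0
    min_ps = np.empty(n_resamples)
    batch = 200
    done = 0
    while done < n_resamples:
        nb = min(batch, n_resamples - done)
        perms = np.stack([rng.permutation(base) for _ in range(nb)], axis=1)
        counts = term_matrix @ perms  # (n_terms, nb)
        counts = np.rint(counts).astype(int)
        for j in range(nb):
            min_ps[done + j] = min(
                p_tables[t][counts[t, j]] for t in range(len(rows))
            )
        done += nb

    out = []
    for row in rows:
        hits = int((min_ps <= row.p_raw + 1e-15).sum())
        p_adj = (1 + hits) / (1 + n_resamples)
        out.append(
            EnrichmentRow(**{**row.to_dict(), "p_adj": max(p_adj, row.p_raw)})
        )
    # monotone enforcement in raw-p order
    order = sorted(range(len(out)), key=lambda i: out[i].p_raw)
    running = 0.0
    for i in order:
        running = max(running, out[i].p_adj)
        out[i].p_adj = running
    return out


def length_matched_association(
    records: Sequence[TranscriptRecord],
    leader: LeaderClass = LeaderClass.SSCR,
    n_strata: int = 10,
) -> tuple[TestResult, list[dict]]:
    """5'UTR-length-matched test of leader-class x 5UI association.

    Stratifies transcripts into 5'UTR-length quantile bins and runs the
    Cochran-Mantel-Haenszel common odds-ratio test of (leader-class
    membership x 5UI presence) across strata; strata with a zero margin are
    dropped with a warning. Returns the test and per-stratum 2x2 audit
    tables.
    """
    recs = [r for r in records if r.leader_class in (leader, LeaderClass.OTHER)]
    if not recs:
        raise ValueError("no records for requested leader class")
    lengths = pd.Series([r.utr5_length for r in recs])
    strata = pd.qcut(lengths, q=min(n_strata, lengths.nunique()), duplicates="drop")
    tables = []
    audit = []
    for level in strata.cat.categories:
        members = [r for r, s in zip(recs, strata) if s == level]
        a = sum(1 for r in members if r.leader_class == leader and r.has_5ui)
        b = sum(1 for r in members if r.leader_class == leader and not r.has_5ui)
        c = sum(1 for r in members if r.leader_class != leader and r.has_5ui)
        d = sum(1 for r in members if r.leader_class != leader and not r.has_5ui)
        entry = {"stratum": str(level), "a": a, "b": b, "c": c, "d": d}
        if min(a + b, c + d, a + c, b + d) == 0:
            log.warning("dropping stratum %s with zero margin", level)
            entry["dropped"] = True
        else:
            entry["dropped"] = False
            tables.append(np.array([[a, b], [c, d]], dtype=float))
        audit.append(entry)
    if not tables:
        raise ValueError("no usable strata for CMH test")
    st = StratifiedTable(tables)
    res = st.test_null_odds(correction=True)
    result = TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect=float(st.oddsratio_pooled),
        tail="two_sided",
        method="cochran_mantel_haenszel",
    )
    return result, audit
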