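"""PSSM construction, scanning with overlap disambiguation, t*, k-mer scan."""

from __future__ import annotations

import numpy as np
import pytest

from alrexscan.pssm import (
    BASE_INDEX,
    MotifHit,
    _greedy_nms,
    discriminative_kmer_scan,
    max_window_score,
    occurrence_stats,
    pssm_from_consensus,
    pssm_from_sites,
    read_meme_minimal,
    read_pssm,
    scan_sequence,
    select_threshold_tstar,
    window_scores,
    write_pssm,
)
from alrexscan.stats import ContingencyTable2x2, hypergeom_tail

from conftest import random_cds


def brute_force_scan(pssm, seq, region=99):
    """Independent O(L^2) reference: per-base scoring + iterative argmax
    suppression of overlapping windows."""
    L = pssm.length
    lo = pssm.log_odds
    scores = []
    for start in range(region - L + 1):
        s = 0.0
        for j in range(L):
            s += lo[BASE_INDEX[seq[start + j]], j]
        scores.append(s)
    remaining = set(range(len(scores)))
    kept = []
    while remaining:
        best = min(remaining, key=lambda i: (-scores[i], i))
        kept.append(best)
        remaining = {i for i in remaining if abs(i - best) >= L}
    return sorted(kept), scores


class TestPssmConstruction:
    def test_identical_sites_give_unit_columns(self):
        p = pssm_from_sites(["CGCCGC"] * 10, pseudocount=0.0)
        assert np.allclose(p.probs.max(axis=0), 1.0)

    def test_direct_counts(self):
        p = pssm_from_sites(["CGCG", "CGGC"], pseudocount=0.0)
        assert np.allclose(p.probs[:, 2], [0, 0.5, 0.5, 0])

    def test_pseudocount_formula(self):
        sites = ["ACGT", "AAGT", "ACGT", "TCGT"]
        p = pssm_from_sites(sites, pseudocount=0.5)
        # column 0: A appears 3 times of 4 sites
        assert p.probs[BASE_INDEX["A"], 0] == pytest.approx((3 + 0.5) / (4 + 2))
        assert p.probs[BASE_INDEX["T"], 0] == pytest.approx((1 + 0.5) / (4 + 2))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pssm_from_sites(["ACGT", "ACG"])

    def test_consensus_pssm_prefers_allowed_bases(self):
        p = pssm_from_consensus("CGSSGC")
        assert p.probs[BASE_INDEX["C"], 0] > 0.9
        assert p.probs[BASE_INDEX["C"], 2] == pytest.approx(
            p.probs[BASE_INDEX["G"], 2]
        )
        assert np.allclose(p.probs.sum(axis=0), 1.0)

    def test_simple_format_round_trip(self, tmp_path):
        p = pssm_from_sites(["ACGTAC", "ACGGAC", "TCGTAC"], pseudocount=0.5)
        path = tmp_path / "m.pssm"
        write_pssm(p, path)
        q = read_pssm(path)
        assert np.allclose(p.probs, q.probs, atol=1e-5)

    def test_meme_minimal_parse(self, tmp_path):
        text = """MEME version 4

ALPHABET= ACGT

Background letter frequencies
A 0.2 C 0.3 G 0.3 T 0.2

MOTIF CGSSGC
letter-probability matrix: alength= 4 w= 4 nsites= 20 E= 0
0.05 0.85 0.05 0.05
0.05 0.05 0.85 0.05
0.05 0.45 0.45 0.05
0.05 0.85 0.05 0.05
"""
        path = tmp_path / "m.meme"
        path.write_text(text)
        motifs = read_meme_minimal(path)
        assert len(motifs) == 1
        m = motifs[0]
        assert m.name == "CGSSGC" and m.length == 4
        assert m.background[0] == pytest.approx(0.2)
        assert m.probs[BASE_INDEX["C"], 0] == pytest.approx(0.85)


class TestScanSequence:
    def test_single_match_dominates_and_suppresses(self, rng):
        target = pssm_from_consensus("ACGT", smoothing=0.04)
        seq = "CC" * 60
        seq = seq[:12] + "ACGT" + seq[16:]
        hits = scan_sequence(target, seq[:120])
        by_pos = {h.position: h for h in hits}
        assert 12 in by_pos
        top = max(hits, key=lambda h: h.score)
        assert top.position == 12
        for h in hits:
            if h is not top:
                assert abs(h.position - top.position) >= 4

    def test_middle_of_three_overlapping_windows_survives(self):
        assert _greedy_nms(np.array([5.0, 7.0, 6.0]), length=4) == [1]

    def test_tie_broken_leftmost(self):
        assert _greedy_nms(np.array([7.0, 7.0, 3.0]), length=2) == [0, 2]

    def test_matches_brute_force_reference(self, rng):
        for _ in range(50):
            L = int(rng.integers(4, 9))
            probs = rng.dirichlet(np.ones(4), size=L).T
            p = pssm_from_sites(["ACGT" * 2] * 2)  # placeholder, replaced below
            p.probs = probs
            seq = random_cds(rng, n_codons=40)
            hits = scan_sequence(p, seq)
            kept, scores = brute_force_scan(p, seq)
            assert [h.position for h in hits] == kept
            for h in hits:
                assert h.score == pytest.approx(scores[h.position], abs=1e-10)

    def test_retained_hits_never_overlap(self, rng):
        p = pssm_from_consensus("CGSSGC")
        for _ in range(20):
            seq = random_cds(rng, n_codons=40)
            hits = scan_sequence(p, seq)
            pos = [h.position for h in hits]
            for i in range(len(pos)):
                for j in range(i + 1, len(pos)):
                    assert abs(pos[i] - pos[j]) >= p.length

    def test_region_shorter_than_motif_rejected(self):
        p = pssm_from_consensus("CGSSGC")
        with pytest.raises(ValueError):
            window_scores(p, "ACGT" * 30, region=4)

    def test_sequence_shorter_than_region_rejected(self):
        p = pssm_from_consensus("CGSSGC")
        with pytest.raises(ValueError):
            scan_sequence(p, "ACGT" * 10)


class TestSelectThresholdTstar:
    def brute_force(self, pos, neg):
        cands = sorted(set(pos) | set(neg), reverse=True)
        best = None
        for t in cands:
            a = sum(1 for v in pos if v >= t)
            b = sum(1 for v in neg if v >= t)
            table = ContingencyTable2x2(a, b, len(pos) - a, len(neg) - b)
            p = hypergeom_tail(table, "greater")
            if best is None or p < best[1]:
                best = (t, p)
        return best

    def test_perfect_separation(self):
        pos = [5.0, 6.0, 7.0]
        neg = [1.0, 2.0, 3.0]
        sel = select_threshold_tstar(pos, neg)
        assert sel.t_star == 5.0
        full = ContingencyTable2x2(3, 0, 0, 3)
        assert sel.fisher_p == pytest.approx(hypergeom_tail(full, "greater"))

    def test_identical_lists_no_discrimination(self):
        scores = [1.0, 2.0, 3.0]
        sel = select_threshold_tstar(scores, scores)
        _, p_bf = self.brute_force(scores, scores)
        assert sel.fisher_p == pytest.approx(p_bf, abs=1e-12)
        assert sel.fisher_p >= 0.5  # no discrimination possible
        assert sel.t_star == 3.0  # ties on p resolve to the most stringent t

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(30):
            pos = rng.choice(np.linspace(0, 5, 12), size=40)
            neg = rng.choice(np.linspace(0, 5, 12), size=40)
            sel = select_threshold_tstar(pos, neg)
            t_bf, p_bf = self.brute_force(list(pos), list(neg))
            assert sel.fisher_p == pytest.approx(p_bf, abs=1e-12)
            assert sel.t_star == t_bf


class TestOccurrenceStats:
    def test_codon_aligned_hits_fill_frame_zero(self):
        hits = {"a": [0, 3, 6], "b": [9, 12]}
        labels = {"a": False, "b": False, "c": True}
        rep = occurrence_stats(hits, labels)
        assert rep.positive.frame_fractions[0] == 1.0
        assert rep.positive.frac_ge1 == 1.0 and rep.positive.frac_ge2 == 1.0
        assert rep.negative.frac_ge1 == 0.0

    def test_empty_hits_give_zero_counts_no_tests(self):
        rep = occurrence_stats({}, {"a": False, "b": True})
        assert rep.positive.n_with_ge1 == 0
        assert rep.positive.frame_chi2_p is None
        assert rep.positional_test is None

    def test_serializable(self):
        rep = occurrence_stats({"a": [1, 8]}, {"a": False, "b": True})
        d = rep.to_dict()
        assert d["positive_5ui_minus"]["frac_ge2"] == 1.0


class TestDiscriminativeKmerScan:
    def test_no_discrimination_when_sets_identical(self, rng):
        seqs = [random_cds(rng, n_codons=40) for _ in range(20)]
        results = discriminative_kmer_scan(seqs, list(seqs), k=4)
        assert all(r.p_value >= 0.5 for r in results)
        assert all(r.p_bonferroni == 1.0 for r in results)

    def test_k_guard(self):
        with pytest.raises(ValueError):
            discriminative_kmer_scan(["ACGTACGTA" * 12], ["ACGTACGTA" * 12], k=9)

    def test_recovers_planted_consensus(self, medium_dataset):
        cfg, records, ledger = medium_dataset
        pos = [r.cds for r in records
               if ledger.group_of[r.transcript_id] == "pos"]
        neg = [r.cds for r in records
               if ledger.group_of[r.transcript_id] == "neg"]
        results = discriminative_kmer_scan(pos, neg, k=6, top=5)

        def specializes(pattern, consensus="CGSSGC"):
            expand = {"S": "CG", "W": "AT", "A": "A", "C": "C", "G": "G", "T": "T"}
            return all(
                set(expand[p]) <= set(expand[c]) for p, c in zip(pattern, consensus)
            )

        assert any(specializes(r.pattern) for r in results)
        assert results[0].p_bonferroni < 0.05


def test_kmer_scan_null_behavior_under_label_shuffles(medium_dataset):
    """Shuffling group labels destroys the planted signal: across 20
    shuffles, no k-mer passes Bonferroni 0.05 in at least 90% of them."""
    from alrexscan.pssm import _present_patterns
    from alrexscan.stats import ContingencyTable2x2, hypergeom_tail

    _, records, _ = medium_dataset
    seqs = [r.cds for r in records]
    n = len(seqs)
    n_pos = sum(1 for r in records if not r.has_5ui)
    pattern_seqs: dict[str, list[int]] = {}
    for i, s in enumerate(seqs):
        for pat in _present_patterns(s, 6, 99):
            pattern_seqs.setdefault(pat, []).append(i)
    n_tests = 6**6
    rng = np.random.default_rng(77)
    cache: dict[tuple[int, int], float] = {}
    shuffles_with_hit = 0
    for _ in range(20):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_pos, replace=False)] = True
        min_p = 1.0
        for pat, idx in pattern_seqs.items():
            total = len(idx)
            k = int(perm[idx].sum())
            key = (total, k)
            if key not in cache:
                cache[key] = hypergeom_tail(
                    ContingencyTable2x2(k, total - k, n_pos - k,
                                        (n - n_pos) - (total - k)),
                    "greater",
                )
            min_p = min(min_p, cache[key])
        if min_p * n_tests < 0.05:
            shuffles_with_hit += 1
    assert shuffles_with_hit <= 2  # >= 90% of shuffles clean


def test_max_window_score_consistent_with_scan(rng):
    p = pssm_from_consensus("CGSSGC")
    for _ in range(10):
        seq = random_cds(rng, n_codons=40)
        assert max_window_score(p, seq) == pytest.approx(
            max(h.score for h in scan_sequence(p, seq)), abs=1e-12
        )
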