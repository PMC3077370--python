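"""Transcript ingestion.

Parses CDS FASTA files and refGene-style annotation tables, derives 5'UTR
length and 5'UTR-intron (5UI) status in transcript orientation, assigns
leader classes (SSCR / MSCR / other) from user-provided id lists, applies the
CDS sanity filters (length a multiple of 3 and >= 150 nt) and collapses
splice variants to a single seeded-random representative.

Coordinates follow the UCSC convention throughout: 0-based, half-open
genomic intervals. An intron counts as a 5'UTR intron only when it lies
entirely 5' of the CDS start in transcript orientation.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: minimum CDS length retained by :func:`apply_cds_filters` (nt)
MIN_CDS_LENGTH = 150
#: leader window analysed downstream (nt)
LEADER_WINDOW = 69


class LeaderClass(str, Enum):
    """N-terminal leader type of the encoded protein."""

    SSCR = "SSCR"  # signal sequence coding region (ER-targeted)
    MSCR = "MSCR"  # mitochondrial-targeting sequence coding region
    OTHER = "OTHER"


@dataclass
class TranscriptRecord:
    """One coding transcript with its 5'UTR-derived attributes.

    ``utr5_splice_pattern`` is an opaque hashable key describing the splice
    structure of the 5'UTR (used only for variant deduplication).
    """

    transcript_id: str
    cds: str
    utr5_length: int = 0
    utr5_intron_count: int = 0
    leader_class: LeaderClass = LeaderClass.OTHER
    non_utr5_intron_total: int | None = None
    utr5_splice_pattern: tuple | None = None

    @property
    def has_5ui(self) -> bool:
        return self.utr5_intron_count > 0

    def validate(self) -> None:
        """Check the type invariants; raises ``ValueError`` on violation."""
        if len(self.cds) % 3 != 0 or len(self.cds) < MIN_CDS_LENGTH:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(self.cds)} violates "
                f"multiple-of-3 / >= {MIN_CDS_LENGTH} nt invariant"
            )
        if set(self.cds) - VALID_BASES:
            raise ValueError(f"{self.transcript_id}: CDS has non-ACGT characters")
        if self.utr5_length < 0 or self.utr5_intron_count < 0:
            raise ValueError(f"{self.transcript_id}: negative 5'UTR attribute")
        if not isinstance(self.leader_class, LeaderClass):
            raise ValueError(f"{self.transcript_id}: bad leader_class")


@dataclass(frozen=True)
class AnnotationRow:
    """One refGene-like annotation row (0-based half-open coordinates)."""

    transcript_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    chrom: str = "chrSim"

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty/negative exon ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e
        if not self.cds_start < self.cds_end:
            raise ValueError(f"{self.transcript_id}: empty CDS interval")


@dataclass
class ParseResult:
    records: list[tuple[str, str]]
    rejected: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class FilterReport:
    not_multiple_of_3: int = 0
    too_short: int = 0

    @property
    def removed(self) -> int:
        return self.not_multiple_of_3 + self.too_short


def parse_cds_fasta(path: str | Path) -> ParseResult:
    """Parse a CDS FASTA file.

    Sequences are uppercased. Records containing characters outside
    {A,C,G,T,N} — or any N at all — are rejected individually with a logged
    reason; a duplicate id is fatal.
    """
    path = Path(path)
    result = ParseResult(records=[])
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES - {"N"}
        if bad:
            reason = f"non-nucleotide characters {sorted(bad)}"
        elif "N" in seq:
            reason = "ambiguous base N"
        else:
            result.records.append((rec.id, seq))
            continue
        log.warning("rejecting %s: %s", rec.id, reason)
        result.rejected.append((rec.id, reason))
    return result


def write_cds_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=tid, description="") for tid, seq in records
    ]
    SeqIO.write(seqrecs, str(Path(path)), "fasta")


_REFGENE_COLUMNS = (
    "name chrom strand txStart txEnd cdsStart cdsEnd exonCount exonStarts exonEnds"
).split()


def read_annotation_table(path: str | Path) -> list[AnnotationRow]:
    """Read a tab-delimited refGene-like annotation table.

    Expected columns: name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts, exonEnds (coordinate lists comma-separated, as in
    UCSC table dumps). Lines starting with '#' are skipped.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ValueError(f"annotation row has {len(parts)} fields, need 10")
            (name, chrom, strand, _tx_s, _tx_e, cds_s, cds_e, n_ex, ex_s, ex_e) = parts[:10]
            starts = [int(x) for x in ex_s.rstrip(",").split(",")]
            ends = [int(x) for x in ex_e.rstrip(",").split(",")]
            if len(starts) != int(n_ex) or len(ends) != int(n_ex):
                raise ValueError(f"{name}: exonCount does not match coordinate lists")
            row = AnnotationRow(
                transcript_id=name,
                strand=strand,
                exons=tuple(zip(starts, ends)),
                cds_start=int(cds_s),
                cds_end=int(cds_e),
                chrom=chrom,
            )
            row.validate()
            rows.append(row)
    return rows


def write_annotation_table(rows: Iterable[AnnotationRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_REFGENE_COLUMNS) + "\n")
        for r in rows:
            starts = ",".join(str(s) for s, _ in r.exons) + ","
            ends = ",".join(str(e) for _, e in r.exons) + ","
            fh.write(
                "\t".join(
                    [
                        r.transcript_id,
                        r.chrom,
                        r.strand,
                        str(r.exons[0][0]),
                        str(r.exons[-1][1]),
                        str(r.cds_start),
                        str(r.cds_end),
                        str(len(r.exons)),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


def derive_utr5(row: AnnotationRow) -> tuple[int, int]:
    """Return (5'UTR exonic length in nt, number of 5'UTR introns).

    Both quantities are taken in transcript orientation: the 5'UTR consists of
    exonic bases strictly 5' of the CDS start, and an intron is a 5UI only if
    it lies entirely within that region.
    """
    row.validate()
    exons = row.exons
    introns = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
    if row.strand == "+":
        anchor = row.cds_start
        if not any(s <= anchor < e for s, e in exons):
            raise ValueError(
                f"inconsistent annotation: cds_start of {row.transcript_id} "
                "outside exon union"
            )
        length = sum(min(e, anchor) - s for s, e in exons if s < anchor)
        count = sum(1 for _s, i_end in introns if i_end <= anchor)
    else:
        anchor = row.cds_end  # first coding base is cds_end - 1 on minus strand
        if not any(s <= anchor - 1 < e for s, e in exons):
            raise ValueError(
                f"inconsistent annotation: cds_end of {row.transcript_id} "
                "outside exon union"
            )
        length = sum(e - max(s, anchor) for s, e in exons if e > anchor)
        count = sum(1 for i_start, _e in introns if i_start >= anchor)
    return length, count


def utr5_splice_pattern(row: AnnotationRow) -> tuple:
    """Hashable key describing the 5'UTR splice structure of a variant."""
    exons = row.exons
    introns = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
    if row.strand == "+":
        utr_introns = tuple(iv for iv in introns if iv[1] <= row.cds_start)
    else:
        utr_introns = tuple(iv for iv in introns if iv[0] >= row.cds_end)
    return (row.chrom, row.strand, utr_introns)


def non_utr5_intron_total(row: AnnotationRow) -> int:
    """Total length (nt) of introns not in the 5'UTR."""
    exons = row.exons
    introns = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
    if row.strand == "+":
        body = [iv for iv in introns if not iv[1] <= row.cds_start]
    else:
        body = [iv for iv in introns if not iv[0] >= row.cds_end]
    return sum(e - s for s, e in body)


def read_id_list(path: str | Path) -> set[str]:
    """One transcript id per line; '#' starts a comment."""
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.add(line)
    return ids


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(ids):
            fh.write(tid + "\n")


def assign_leader_class(
    records: Iterable[TranscriptRecord],
    sscr_ids: set[str],
    mscr_ids: set[str],
) -> list[TranscriptRecord]:
    """Assign SSCR/MSCR/OTHER from precomputed id lists (ids may not overlap)."""
    both = sscr_ids & mscr_ids
    if both:
        raise ValueError(f"ids present in both leader lists: {sorted(both)[:5]}")
    out = []
    for rec in records:
        if rec.transcript_id in sscr_ids:
            cls = LeaderClass.SSCR
        elif rec.transcript_id in mscr_ids:
            cls = LeaderClass.MSCR
        else:
            cls = LeaderClass.OTHER
        out.append(replace(rec, leader_class=cls))
    return out


def apply_cds_filters(
    records: Sequence[TranscriptRecord],
) -> tuple[list[TranscriptRecord], FilterReport]:
    """Drop CDSs whose length is not a multiple of 3 or is < 150 nt.

    A CDS failing both rules is counted once, under not_multiple_of_3
    (checked first).
    """
    report = FilterReport()
    kept = []
    for rec in records:
        n = len(rec.cds)
        if n % 3 != 0:
            report.not_multiple_of_3 += 1
        elif n < MIN_CDS_LENGTH:
            report.too_short += 1
        else:
            kept.append(rec)
    return kept, report


def dedup_splice_variants(
    records: Sequence[TranscriptRecord],
    mode: str = "identical_leader69",
    seed: int = 0,
) -> list[TranscriptRecord]:
    """Collapse groups of equivalent splice variants to one representative.

    mode 'identical_leader69' groups records sharing their first 69 CDS nt;
    mode 'identical_utr_splicing' groups records with identical 5'UTR splice
    patterns (requires ``utr5_splice_pattern`` to be populated). Within each
    group one representative is chosen by a seeded uniform draw; the result
    is deterministic for a fixed seed regardless of input order.
    """
    if mode == "identical_leader69":
        keyfn = lambda r: r.cds[:LEADER_WINDOW]
    elif mode == "identical_utr_splicing":
        def keyfn(r):
            if r.utr5_splice_pattern is None:
                raise ValueError(f"{r.transcript_id}: missing utr5_splice_pattern")
            return r.utr5_splice_pattern
    else:
        raise ValueError(f"unknown dedup mode: {mode}")

    groups: dict = {}
    for rec in records:
        groups.setdefault(keyfn(rec), []).append(rec)
    rng = random.Random(seed)
    reps = []
    # iterate groups in a canonical order so the draw sequence is stable
    for key in sorted(groups, key=repr):
        members = sorted(groups[key], key=lambda r: r.transcript_id)
        reps.append(rng.choice(members))
    return sorted(reps, key=lambda r: r.transcript_id)


def build_transcript_records(
    fasta_records: Sequence[tuple[str, str]],
    annotation: Sequence[AnnotationRow],
    sscr_ids: set[str] | None = None,
    mscr_ids: set[str] | None = None,
) -> list[TranscriptRecord]:
    """Join parsed CDS sequences with annotation-derived 5'UTR attributes."""
    ann_by_id = {r.transcript_id: r for r in annotation}
    out = []
    for tid, cds in fasta_records:
        row = ann_by_id.get(tid)
        if row is None:
            log.warning("no annotation for %s; skipping", tid)
            continue
        length, count = derive_utr5(row)
        out.append(
            TranscriptRecord(
                transcript_id=tid,
                cds=cds,
                utr5_length=length,
                utr5_intron_count=count,
                non_utr5_intron_total=non_utr5_intron_total(row),
                utr5_splice_pattern=utr5_splice_pattern(row),
            )
        )
    if sscr_ids is not None or mscr_ids is not None:
        out = assign_leader_class(out, sscr_ids or set(), mscr_ids or set())
    return out
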