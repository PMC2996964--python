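"""Contig-to-gene annotation from tabular BLAST output.

Parses 12-column tabular alignments (BLAST ``-outfmt 6`` dialect:
qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore), applies an e-value cutoff, selects one best hit per
contig (minimum e-value, then maximum aligned length), partitions off
contigs whose best hit identifies them as contamination, computes per-gene
coverage, and flags alignment gaps indicative of splice variants.

Coordinates are 1-based inclusive internally (the BLAST tabular
convention); :func:`gaps_to_bed` converts to 0-based half-open for export.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

DEFAULT_EVALUE_CUTOFF = 1e-10
DEFAULT_MIN_GAP = 15

OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class AlignmentHit:
    """One tabular alignment row, spans normalised to start <= end."""

    query_id: str
    subject_id: str
    percent_identity: float
    aligned_length: int
    mismatches: int
    gap_opens: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    evalue: float
    bitscore: float
    subject_reverse: bool = False  # original sstart > send

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")
        if self.aligned_length <= 0:
            raise ValueError("aligned length must be positive")
        for lo, hi in (self.query_span, self.subject_span):
            if lo > hi:
                raise ValueError("span start must be <= end")


@dataclass(frozen=True)
class GeneAssignment:
    """A contig assigned to the gene of its best below-cutoff hit."""

    contig_id: str
    gene_id: str
    best_hit: AlignmentHit


def parse_tabular_alignments(
    path, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> list[AlignmentHit]:
    """Read a 12-column tabular alignment file, keeping hits with
    ``evalue <= evalue_cutoff`` (inclusive, the BLAST community norm).

    Spans with start > end (minus-strand subject coordinates) are
    normalised and flagged via ``subject_reverse``.  Malformed lines raise
    ``ValueError`` naming the 1-based line number.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                length = int(fields[3])
                mismatch = int(fields[4])
                gapopen = int(fields[5])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric field ({exc})"
                ) from None
            if evalue > evalue_cutoff:
                continue
            q_rev = qstart > qend
            s_rev = sstart > send
            if q_rev:
                qstart, qend = qend, qstart
            if s_rev:
                sstart, send = send, sstart
            hits.append(
                AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=pident,
                    aligned_length=length,
                    mismatches=mismatch,
                    gap_opens=gapopen,
                    query_span=(qstart, qend),
                    subject_span=(sstart, send),
                    evalue=evalue,
                    bitscore=bitscore,
                    subject_reverse=s_rev != q_rev,
                )
            )
    return hits


def select_best_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit:
    """The single best hit for one query: minimum e-value, ties broken by
    maximum aligned length, remaining ties by lexicographic subject id.

    Deterministic and invariant to the order of ``hits``.
    """
    if not hits:
        raise ValueError("empty hit list")
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    return min(hits, key=lambda h: (h.evalue, -h.aligned_length, h.subject_id))


def assign_genes(hits: Iterable[AlignmentHit]) -> dict[str, GeneAssignment]:
    """Best-hit gene assignment for every query appearing in ``hits``."""
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    return {
        q: GeneAssignment(q, best.subject_id, best)
        for q, qhits in by_query.items()
        for best in [select_best_hit(qhits)]
    }


def flag_contaminants(
    assignments: Mapping[str, GeneAssignment],
    contaminant_subject_ids: Iterable[str],
) -> tuple[dict[str, GeneAssignment], pd.DataFrame]:
    """Partition assignments into (clean, removal report).

    A contig is contamination iff its *best* hit's subject is in the
    contaminant set (e.g. subjects from a foreign-taxon reference).  The
    report lists contig id, offending subject and e-value, one row per
    removed contig.
    """
    contaminants = set(contaminant_subject_ids)
    clean: dict[str, GeneAssignment] = {}
    removed = []
    for contig, a in assignments.items():
        if a.gene_id in contaminants:
            removed.append(
                {
                    "contig_id": contig,
                    "subject_id": a.gene_id,
                    "evalue": a.best_hit.evalue,
                }
            )
        else:
            clean[contig] = a
    report = pd.DataFrame(removed, columns=["contig_id", "subject_id", "evalue"])
    return clean, report


def compute_gene_coverage(gene_length: int, contig_lengths: Sequence[int]) -> float:
    """Percent of a gene covered by its assigned contigs.

    ``100 * sum(contig lengths) / gene_length``, capped at 100 when
    overlapping contigs push the total past the gene length.  Returns a
    value in (0, 100].
    """
    if gene_length <= 0:
        raise ValueError("gene length must be positive")
    if len(contig_lengths) == 0:
        raise ValueError("at least one contig required")
    if any(c <= 0 for c in contig_lengths):
        raise ValueError("contig lengths must be positive")
    return min(100.0, 100.0 * sum(contig_lengths) / gene_length)


@dataclass
class GapReport:
    """Result of splice-gap screening for one query/reference pair."""

    has_splice_gap: bool
    #: (gap_start, gap_end, gap_length) per inter-segment gap, 1-based
    #: inclusive reference coordinates of the uncovered stretch.
    gaps: list[tuple[int, int, int]]
    #: pairs of overlapping input segments, reported rather than merged.
    overlaps: list[tuple[tuple[int, int], tuple[int, int]]]


def detect_alignment_gaps(
    segments: Sequence[tuple[int, int]], min_gap: int = DEFAULT_MIN_GAP
) -> GapReport:
    """Screen aligned segments on a reference for splice-variant gaps.

    A gap is the stretch of reference positions between consecutive
    segments (coordinates 1-based inclusive); the splice flag is raised
    iff some gap is *strictly* longer than ``min_gap`` bases.  Used both
    for read-vs-contig alignments (contigs mixing isoforms) and
    contig-vs-gene-model alignments (novel isoforms).

    Overlapping segments are listed in the report, never silently merged.
    """
    if len(segments) == 0:
        raise ValueError("at least one aligned segment required")
    segs = sorted((int(a), int(b)) for a, b in segments)
    for a, b in segs:
        if a > b:
            raise ValueError(f"segment start > end: {(a, b)}")
    gaps: list[tuple[int, int, int]] = []
    overlaps: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for prev, cur in zip(segs, segs[1:]):
        gap_len = cur[0] - prev[1] - 1
        if gap_len < 0:
            overlaps.append((prev, cur))
        elif gap_len > 0:
            gaps.append((prev[1] + 1, cur[0] - 1, gap_len))
    flag = any(g[2] > min_gap for g in gaps)
    return GapReport(flag, gaps, overlaps)


def gaps_to_bed(gaps, chrom: str) -> pd.DataFrame:
    """Convert 1-based inclusive gap intervals to BED (0-based half-open)."""
    return pd.DataFrame(
        [(chrom, start - 1, end, f"gap_{i}", length)
         for i, (start, end, length) in enumerate(gaps, start=1)],
        columns=["chrom", "start", "end", "name", "gap_length"],
    )


def assignments_to_frame(
    assignments: Mapping[str, GeneAssignment]
) -> pd.DataFrame:
    """Tabular view of assignments (contig_id, gene_id, evalue, length)."""
    rows = [
        {
            "contig_id": a.contig_id,
            "gene_id": a.gene_id,
            "evalue": a.best_hit.evalue,
            "aligned_length": a.best_hit.aligned_length,
        }
        for a in assignments.values()
    ]
    return pd.DataFrame(
        rows, columns=["contig_id", "gene_id", "evalue", "aligned_length"]
    )
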