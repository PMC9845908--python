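"""Post-discovery miRNA locus curation and seed-aware homolog matching.

Candidate precursor-mature records (one row per sample x precursor, as a
quantifier would emit) are filtered on quality (no rRNA/tRNA, at least five
reads on both mature and star strands, hairpin-folding randfold p < 0.05),
novel precursors surviving in any sample are compiled into a composite
reference, and precursors with identical mature sequences are merged into
one locus when their genomic intervals overlap (transitively) on the same
chromosome and strand — identical matures at disjoint locations stay
separate loci.  Homologs are accepted only above 90% identity with at most
two mismatches, none of them inside the seed region (positions 2-7 from
the 5' end).

Genomic intervals are 0-based half-open in memory (GFF3 on disk is 1-based
closed; conversion lives in provisio.io).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEED_START = 2  # 1-based, inclusive
SEED_END = 7

_RNA_ALPHABET = set("ACGU")


@dataclass(frozen=True)
class MiRNALocus:
    locus_id: str
    mature_seq: str
    members: tuple[str, ...]  # precursor IDs
    chrom: str
    start: int  # 0-based half-open hull of member intervals
    end: int
    strand: str


@dataclass(frozen=True)
class HomologMatch:
    query: str
    subject: str
    identity: float  # matches / query length
    mismatch_positions: tuple[int, ...]  # 1-based from the 5' end
    accepted: bool


# ---------------------------------------------------------------------------
# quality filtering
# ---------------------------------------------------------------------------


def filter_precursor_pairs(
    records: pd.DataFrame,
    min_reads: int = 5,
    randfold_alpha: float = 0.05,
) -> pd.DataFrame:
    """Records passing the precursor-mature quality filters, in input order.

    Keep iff not rRNA/tRNA, mature and star read counts both >= min_reads,
    and randfold p strictly below randfold_alpha.
    """
    keep = (
        ~records["rrna_trna"].astype(bool)
        & (records["mature_count"] >= min_reads)
        & (records["star_count"] >= min_reads)
        & (records["randfold_p"] < randfold_alpha)
    )
    return records[keep]


def compile_novel_precursors(
    passing_novel: pd.DataFrame | pd.Series,
    known: list[str] | pd.Series,
) -> list[str]:
    """Composite precursor reference: known first, then novel lexicographic.

    Novel sequences surviving filtering in any sample are deduplicated;
    duplicates of known sequences collapse to the known entry.
    """
    if isinstance(passing_novel, pd.DataFrame):
        novel_seqs = passing_novel["mature_seq"]
    else:
        novel_seqs = passing_novel
    known_list = list(known)
    known_set = set(known_list)
    novel = sorted(set(novel_seqs) - known_set)
    return known_list + novel


# ---------------------------------------------------------------------------
# locus merging
# ---------------------------------------------------------------------------


def _connected_components(intervals: list[tuple[int, int, int]]) -> list[list[int]]:
    """Overlap-connected components of (start, end, idx) on one chrom+strand."""
    intervals = sorted(intervals)
    comps: list[list[int]] = []
    cur: list[int] = []
    cur_end = -1
    for start, end, idx in intervals:
        if cur and start < cur_end:  # >= 1 bp overlap in half-open coords
            cur.append(idx)
            cur_end = max(cur_end, end)
        else:
            if cur:
                comps.append(cur)
            cur = [idx]
            cur_end = end
    if cur:
        comps.append(cur)
    return comps


def merge_loci(records: pd.DataFrame) -> list[MiRNALocus]:
    """Merge precursors with identical mature sequences and overlapping spans.

    Records are grouped by exact mature sequence; within a group, precursors
    on the same chromosome and strand whose intervals overlap (taking the
    transitive closure, so a chain A-B-C with A and C disjoint still merges)
    form one locus.  The result is independent of record order and
    idempotent.  Each precursor's interval is taken from its first record;
    per-sample read counts are handled by :func:`mirna_count_table`.
    """
    pre = (
        records[["precursor", "chrom", "start", "end", "strand", "mature_seq"]]
        .drop_duplicates(subset="precursor")
        .sort_values("precursor")
    )
    multi = records.groupby(["sample", "precursor"]).size()
    if (multi > 1).any():
        logger.warning("some precursors appear more than once within a sample")

    loci: list[MiRNALocus] = []
    for (mature, chrom, strand), grp in pre.groupby(["mature_seq", "chrom", "strand"], sort=True):
        ivals = [(int(r.start), int(r.end), i) for i, r in enumerate(grp.itertuples(index=False))]
        rows = list(grp.itertuples(index=False))
        for comp in _connected_components(ivals):
            members = tuple(sorted(rows[i].precursor for i in comp))
            loci.append(
                MiRNALocus(
                    locus_id="",  # assigned after global ordering
                    mature_seq=mature,
                    members=members,
                    chrom=chrom,
                    start=min(rows[i].start for i in comp),
                    end=max(rows[i].end for i in comp),
                    strand=strand,
                )
            )
    loci.sort(key=lambda l: (l.chrom, l.start, l.end, l.strand, l.mature_seq))
    return [
        MiRNALocus(f"locus{i + 1:03d}", l.mature_seq, l.members, l.chrom, l.start,
                   l.end, l.strand)
        for i, l in enumerate(loci)
    ]


def mirna_count_table(loci: list[MiRNALocus], records: pd.DataFrame) -> pd.DataFrame:
    """Locus x sample mature-count matrix, summing merged members."""
    by_pre = {}
    for l in loci:
        for p in l.members:
            by_pre[p] = l.locus_id
    known = records["precursor"].isin(by_pre)
    sub = records[known].copy()
    missing = {p for l in loci for p in l.members} - set(records["precursor"])
    if missing:
        raise ValueError(f"loci reference absent precursors: {sorted(missing)[:5]}")
    sub["locus"] = sub["precursor"].map(by_pre)
    table = (
        sub.pivot_table(index="locus", columns="sample", values="mature_count",
                        aggfunc="sum", fill_value=0)
        .astype(np.int64)
    )
    order = [l.locus_id for l in loci]
    table = table.reindex(order, fill_value=0)
    table.index.name = "feature"
    table.columns.name = None
    return table


# ---------------------------------------------------------------------------
# homolog matching
# ---------------------------------------------------------------------------


def _validate_rna(seq: str, name: str) -> str:
    s = seq.upper().replace("T", "U")
    if set(s) - _RNA_ALPHABET:
        raise ValueError(f"{name} contains non-RNA characters: {seq!r}")
    return s


def _best_gapless_overlap(query: str, subject: str) -> tuple[float, tuple[int, ...]]:
    """Best gapless equal-length comparison, sliding the shorter sequence.

    Identity = matches / query length; mismatch positions are 1-based from
    the query's 5' end.  Overhanging query positions (when the subject is
    shorter) count as mismatches.
    """
    lq, ls = len(query), len(subject)
    best_matches = -1
    best_mm: tuple[int, ...] = ()
    if ls >= lq:
        for off in range(ls - lq + 1):
            window = subject[off:off + lq]
            mm = tuple(i + 1 for i in range(lq) if query[i] != window[i])
            if lq - len(mm) > best_matches:
                best_matches = lq - len(mm)
                best_mm = mm
    else:
        for off in range(lq - ls + 1):
            mm = tuple(
                i + 1
                for i in range(lq)
                if not (off <= i < off + ls and query[i] == subject[i - off])
            )
            if lq - len(mm) > best_matches:
                best_matches = lq - len(mm)
                best_mm = mm
    return best_matches / lq, best_mm


def match_homologs(
    queries: dict[str, str],
    database: dict[str, str],
    min_identity: float = 0.90,
    max_mismatches: int = 2,
    seed_start: int = SEED_START,
    seed_end: int = SEED_END,
) -> list[HomologMatch]:
    """Best database hit per query under seed-aware homology rules.

    A hit is accepted iff identity strictly exceeds ``min_identity``, there
    are at most ``max_mismatches`` mismatches, and no mismatch falls inside
    the seed region (positions seed_start..seed_end from the 5' end).
    """
    out = []
    for qname, qseq in queries.items():
        q = _validate_rna(qseq, qname)
        if len(q) < 8:
            raise ValueError(f"query {qname} shorter than 8 nt")
        best = None
        for sname in sorted(database):
            s = _validate_rna(database[sname], sname)
            ident, mm = _best_gapless_overlap(q, s)
            if best is None or ident > best[0]:
                best = (ident, mm, sname)
        if best is None:
            continue  # empty database: no hit to report
        ident, mm, sname = best
        seed_hit = any(seed_start <= pos <= seed_end for pos in mm)
        accepted = ident > min_identity and len(mm) <= max_mismatches and not seed_hit
        out.append(
            HomologMatch(
                query=qname,
                subject=sname,
                identity=ident,
                mismatch_positions=mm,
                accepted=accepted,
            )
        )
    return out
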