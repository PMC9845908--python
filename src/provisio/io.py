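"""Reading and writing the plain-text formats used throughout the pipeline.

Counts and metadata travel as TSV, precursor intervals as GFF3 (1-based,
closed intervals on disk; 0-based half-open in memory), mature sequences as
FASTA, and summaries as JSON.  Every writer/reader pair is a lossless
round trip for the columns it owns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------------------
# counts / metadata / generic tables
# ---------------------------------------------------------------------------


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a feature x sample integer count matrix as TSV.

    The first column holds feature identifiers, the header row sample IDs.
    """
    counts.to_csv(path, sep="\t", index_label="feature")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate feature identifiers in {path}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample identifiers in {path}")
    if (df.values < 0).any():
        raise ValueError(f"negative counts in {path}")
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if meta.index.has_duplicates:
        raise ValueError(f"duplicate sample identifiers in {path}")
    return meta


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_partition(labels: Mapping[str, int] | pd.Series, path: str | Path) -> None:
    """Write a gene -> module-label assignment as a two-column TSV."""
    s = pd.Series(labels, name="module")
    s.index.name = "gene"
    s.to_csv(path, sep="\t")


def read_partition(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df["module"].astype(int)


# ---------------------------------------------------------------------------
# GFF3 intervals
# ---------------------------------------------------------------------------

_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def write_gff3(intervals: pd.DataFrame, path: str | Path,
               feature_type: str = "pre_miRNA", source: str = "provisio") -> None:
    """Write intervals held 0-based half-open as 1-based closed GFF3.

    ``intervals`` needs columns chrom/start/end/strand and an ``id`` column;
    any other columns become extra ``key=value`` attributes.
    """
    extra = [c for c in intervals.columns if c not in {"chrom", "start", "end", "strand", "id"}]
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in intervals.itertuples(index=False):
            attrs = [f"ID={getattr(row, 'id')}"]
            for c in extra:
                attrs.append(f"{c}={getattr(row, c)}")
            fields = [
                str(getattr(row, "chrom")), source, feature_type,
                str(int(getattr(row, "start")) + 1),  # to 1-based closed
                str(int(getattr(row, "end"))),
                ".", str(getattr(row, "strand")), ".", ";".join(attrs),
            ]
            fh.write("\t".join(fields) + "\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read GFF3 intervals back to 0-based half-open coordinates."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(item.split("=", 1) for item in parts[8].split(";") if item)
            start1, end1 = int(parts[3]), int(parts[4])
            if start1 < 1 or end1 < start1:
                raise ValueError(f"invalid GFF3 coordinates: {line!r}")
            row = {
                "chrom": parts[0],
                "start": start1 - 1,  # to 0-based half-open
                "end": end1,
                "strand": parts[6],
                "id": attrs.pop("ID", None),
                "type": parts[2],
            }
            row.update(attrs)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# JSON summaries
# ---------------------------------------------------------------------------


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    try:
        import numpy as np

        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
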