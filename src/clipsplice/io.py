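"""Shared readers and writers: FASTA, GTF, GMT, BED6, TSV, run manifests.

SAM is read with pysam inside :mod:`clipsplice.crosslink`; everything else
funnels through here. All coordinate conversions go through
:mod:`clipsplice.coords` at the format boundary.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import coords

PACKAGE_VERSION = "0.1.0"


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    seq_records = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

GTF_COLUMNS = [
    "contig", "source", "feature", "start", "end",
    "score", "strand", "frame", "gene_id", "transcript_id",
]


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Parse a GTF into a DataFrame (one row per feature, 1-based inclusive
    ``start``/``end`` preserved as in the file).

    Uses :mod:`gffutils` with an in-memory database; malformed lines raise
    with the offending file named.
    """
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # pragma: no cover - error path
        raise ValueError(f"failed to parse GTF {path}: {exc}") from exc
    rows = []
    for feat in db.all_features(order_by=("seqid", "start")):
        rows.append({
            "contig": feat.seqid,
            "source": feat.source,
            "feature": feat.featuretype,
            "start": feat.start,
            "end": feat.end,
            "score": feat.score,
            "strand": feat.strand,
            "frame": feat.frame,
            "gene_id": feat.attributes.get("gene_id", [""])[0],
            "transcript_id": feat.attributes.get("transcript_id", [""])[0],
        })
    if not rows:
        raise ValueError(f"no features found in GTF {path}")
    return pd.DataFrame(rows, columns=GTF_COLUMNS)


def write_gtf(df: pd.DataFrame, path: str | Path, source: str = "clipsplice") -> None:
    """Write a feature DataFrame (columns per :data:`GTF_COLUMNS`, 1-based
    inclusive coordinates) as 9-column GTF text."""
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}"; transcript_id "{row.transcript_id}";'
            fh.write(
                f"{row.contig}\t{getattr(row, 'source', source) or source}\t{row.feature}\t"
                f"{row.start}\t{row.end}\t{row.score or '.'}\t{row.strand}\t"
                f"{row.frame or '.'}\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: one named gene set per line, tab-separated,
    second column is a (ignored) description."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[fields[0]] = {g for g in fields[2:] if g}
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "."] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# BED6 (crosslink tags)
# ---------------------------------------------------------------------------

def write_tags_bed6(tag_counts: pd.DataFrame, path: str | Path) -> None:
    """Write per-position tag counts as BED6.

    ``tag_counts`` columns: reference, position (0-based), evidence, count.
    BED is 0-based half-open, so each single-nucleotide tag spans
    ``[position, position + 1)``; name carries the evidence class and score
    the tag count.
    """
    with open(path, "w") as fh:
        for row in tag_counts.itertuples(index=False):
            fh.write(
                f"{row.reference}\t{row.position}\t{row.position + 1}\t"
                f"{row.evidence}\t{row.count}\t+\n"
            )


def read_tags_bed6(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED fields")
            start, end = int(fields[1]), int(fields[2])
            if end != start + 1:
                raise ValueError(f"{path}:{lineno}: tag records must span one nucleotide")
            rows.append({
                "reference": fields[0], "position": start,
                "evidence": fields[3], "count": int(fields[4]),
            })
    return pd.DataFrame(rows, columns=["reference", "position", "evidence", "count"])


# ---------------------------------------------------------------------------
# Profiles as TSV (1-based positions at the interface)
# ---------------------------------------------------------------------------

def write_profile_tsv(profile_df: pd.DataFrame, path: str | Path) -> None:
    """``profile_df`` columns: reference, position (0-based), truncation_count,
    deletion_count. Written with 1-based positions per the TSV contract."""
    out = profile_df.copy()
    out["position_1based"] = out["position"].map(coords.zero_pos_to_one_based)
    out[["reference", "position_1based", "truncation_count", "deletion_count"]].to_csv(
        path, sep="\t", index=False
    )


def read_profile_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["position"] = df["position_1based"].map(coords.one_based_pos_to_zero)
    return df[["reference", "position", "truncation_count", "deletion_count"]]


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def file_checksum(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, *, subcommand: str, config: Mapping,
                   seed: int | None, inputs: Iterable[str | Path] = ()) -> None:
    """Machine-readable record of a run: config, seed, software version and
    input checksums, enabling byte-level reproduction claims."""
    manifest = {
        "tool": "clipsplice",
        "version": PACKAGE_VERSION,
        "python": sys.version.split()[0],
        "subcommand": subcommand,
        "seed": seed,
        "config": dict(config),
        "input_checksums": {str(p): file_checksum(p) for p in inputs if Path(p).exists()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
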