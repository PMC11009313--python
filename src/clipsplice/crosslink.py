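"""iCLIP crosslink evidence from aligned reads.

Truncation evidence: cDNAs truncate at the crosslinked nucleotide, so each
read contributes one truncation tag at the position immediately 5' of its
alignment start (reads starting at reference position 0 are dropped and
counted). Deletion evidence: reverse transcription reading through a
crosslink can instead skip the crosslinked nucleotide, so every reference
position deleted in a read's CIGAR contributes one deletion tag. The two
evidence classes are tallied separately and never mixed: binding profiles
use truncation tags, while the crosslinked-nucleotide analysis uses the
fraction of covering reads carrying a deletion at a position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

from . import coords

logger = logging.getLogger(__name__)

_CIGAR_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X
_CIGAR_DELETION = 2


class CrosslinkTag(NamedTuple):
    reference: str
    position: int      # 0-based
    evidence: str      # truncation | deletion
    sample: str


@dataclass
class AlignedRead:
    """Minimal sense-strand alignment record (0-based start, pysam-style
    CIGAR tuples)."""
    query_name: str
    reference: str
    start: int
    cigartuples: list[tuple[int, int]]

    def reference_span(self) -> int:
        return sum(n for op, n in self.cigartuples if op in _CIGAR_REF_CONSUMING)

    def deleted_positions(self) -> list[int]:
        out = []
        cursor = self.start
        for op, n in self.cigartuples:
            if op == _CIGAR_DELETION:
                out.extend(range(cursor, cursor + n))
            if op in _CIGAR_REF_CONSUMING:
                cursor += n
        return out


@dataclass
class SamLibrary:
    reads: list[AlignedRead]
    reference_lengths: dict[str, int]
    n_antisense_discarded: int


def load_sam(path: str | Path) -> SamLibrary:
    """Read SAM text with pysam. Antisense alignments are discarded with a
    logged count (iCLIP reads are sense to their snRNA references);
    unmapped records are skipped."""
    reads: list[AlignedRead] = []
    n_antisense = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as af:
        ref_lengths = dict(zip(af.references, af.lengths))
        for seg in af.fetch(until_eof=True):
            if seg.is_unmapped:
                continue
            if seg.is_reverse:
                n_antisense += 1
                continue
            if seg.cigartuples is None:
                raise ValueError(f"read {seg.query_name!r} has no CIGAR")
            reads.append(AlignedRead(
                query_name=seg.query_name,
                reference=seg.reference_name,
                start=seg.reference_start,
                cigartuples=list(seg.cigartuples),
            ))
    if n_antisense:
        logger.info("discarded %d antisense alignments from %s", n_antisense, path)
    return SamLibrary(reads, ref_lengths, n_antisense)


# ---------------------------------------------------------------------------
# Tag calling
# ---------------------------------------------------------------------------

@dataclass
class CrosslinkCalls:
    tags: list[CrosslinkTag]
    n_reads: int
    n_dropped_start_zero: int

    def truncation_tags(self) -> list[CrosslinkTag]:
        return [t for t in self.tags if t.evidence == "truncation"]

    def deletion_tags(self) -> list[CrosslinkTag]:
        return [t for t in self.tags if t.evidence == "deletion"]


def call_crosslinks(
    reads: Iterable[AlignedRead],
    references: Mapping[str, int],
    sample: str,
) -> CrosslinkCalls:
    """One truncation tag per read at the nucleotide immediately 5' of its
    start (reads starting at position 0 dropped and counted); one deletion
    tag per CIGAR-deleted reference nucleotide. Tag conservation: truncation
    tags + dropped reads = total reads."""
    tags: list[CrosslinkTag] = []
    n_reads = 0
    n_dropped = 0
    for read in reads:
        n_reads += 1
        if read.reference not in references:
            raise ValueError(
                f"read {read.query_name!r} aligned to unknown reference {read.reference!r}"
            )
        ref_len = references[read.reference]
        end = read.start + read.reference_span()
        if not 0 <= read.start < end <= ref_len:
            raise ValueError(
                f"read {read.query_name!r}: malformed CIGAR/position "
                f"(span [{read.start}, {end}) outside reference of length {ref_len})"
            )
        if read.start == 0:
            n_dropped += 1
        else:
            tags.append(CrosslinkTag(read.reference, read.start - 1, "truncation", sample))
        for pos in read.deleted_positions():
            tags.append(CrosslinkTag(read.reference, pos, "deletion", sample))
    return CrosslinkCalls(tags=tags, n_reads=n_reads, n_dropped_start_zero=n_dropped)


# ---------------------------------------------------------------------------
# Per-nucleotide profiles
# ---------------------------------------------------------------------------

@dataclass
class NucleotideProfile:
    reference: str
    sample: str
    truncation_counts: np.ndarray
    deletion_counts: np.ndarray
    library_size: int
    condition: str | None = None

    def total_tags(self) -> int:
        return int(self.truncation_counts.sum())

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        """Positionwise table; with ``normalized`` the counts are also
        emitted scaled per million library reads (both normalisations are
        reported because raw-vs-scaled is an analysis choice)."""
        df = pd.DataFrame({
            "reference": self.reference,
            "position": np.arange(len(self.truncation_counts)),
            "truncation_count": self.truncation_counts,
            "deletion_count": self.deletion_counts,
        })
        if normalized and self.library_size > 0:
            scale = 1e6 / self.library_size
            df["truncation_per_million"] = df["truncation_count"] * scale
            df["deletion_per_million"] = df["deletion_count"] * scale
        return df


def build_profile(
    tags: Iterable[CrosslinkTag],
    sample: str,
    reference: str,
    reference_length: int,
    library_size: int | None = None,
    condition: str | None = None,
) -> NucleotideProfile:
    """Positionwise tally of one sample's tags on one reference; conserves
    tag counts and keeps truncation and deletion evidence separate."""
    trunc = np.zeros(reference_length, dtype=np.int64)
    dele = np.zeros(reference_length, dtype=np.int64)
    n = 0
    for tag in tags:
        if tag.sample != sample or tag.reference != reference:
            continue
        if not 0 <= tag.position < reference_length:
            raise ValueError(f"tag position {tag.position} outside {reference!r}")
        n += 1
        if tag.evidence == "truncation":
            trunc[tag.position] += 1
        elif tag.evidence == "deletion":
            dele[tag.position] += 1
        else:
            raise ValueError(f"unknown evidence class {tag.evidence!r}")
    return NucleotideProfile(
        reference=reference, sample=sample,
        truncation_counts=trunc, deletion_counts=dele,
        library_size=library_size if library_size is not None else n,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# Deletion-fraction estimation (crosslinked-nucleotide analysis)
# ---------------------------------------------------------------------------

@dataclass
class CrosslinkSite:
    reference: str
    position: int
    coverage: int
    deletion_reads: int
    defined: bool

    @property
    def deletion_fraction(self) -> float:
        return self.deletion_reads / self.coverage if self.defined else float("nan")


def deletion_fraction(
    reads: Iterable[AlignedRead],
    reference: str,
    position: int,
) -> CrosslinkSite:
    """Fraction of reads overlapping ``position`` whose alignment deletes
    that nucleotide. Zero coverage yields an undefined (flagged) result,
    never 0."""
    coverage = 0
    deleted = 0
    for read in reads:
        if read.reference != reference:
            continue
        if read.start <= position < read.start + read.reference_span():
            coverage += 1
            if position in read.deleted_positions():
                deleted += 1
    return CrosslinkSite(
        reference=reference, position=position,
        coverage=coverage, deletion_reads=deleted, defined=coverage > 0,
    )


def mean_deletion_fraction(sites: Sequence[CrosslinkSite]) -> float:
    """Across-sample average: unweighted mean of per-sample fractions,
    skipping undefined (zero-coverage) samples."""
    fractions = [s.deletion_fraction for s in sites if s.defined]
    if not fractions:
        raise ValueError("no sample has coverage at this site")
    return float(np.mean(fractions))


# ---------------------------------------------------------------------------
# Windowed region summaries
# ---------------------------------------------------------------------------

@dataclass
class RegionSummary:
    reference: str
    window_1based: tuple[int, int]   # inclusive, reporting convention
    sample: str
    proportion_of_total_hits: float
    defined: bool
    condition: str | None = None


def region_proportion(profile: NucleotideProfile, window_1based: tuple[int, int]) -> RegionSummary:
    """Truncation-tag count inside the (1-based inclusive) window divided by
    the reference's total truncation tags — 'proportion of total hits' is
    per-reference, so proportions over a disjoint exhaustive partition sum
    to 1."""
    start0, end0 = coords.one_based_to_zero_half_open(*window_1based)
    if end0 > len(profile.truncation_counts):
        raise ValueError(
            f"window {window_1based} extends past reference "
            f"{profile.reference!r} of length {len(profile.truncation_counts)}"
        )
    total = profile.truncation_counts.sum()
    if total == 0:
        return RegionSummary(profile.reference, window_1based, profile.sample,
                             float("nan"), defined=False, condition=profile.condition)
    prop = float(profile.truncation_counts[start0:end0].sum() / total)
    return RegionSummary(profile.reference, window_1based, profile.sample,
                         prop, defined=True, condition=profile.condition)


# ---------------------------------------------------------------------------
# Per-RNA abundance with biotype roll-up
# ---------------------------------------------------------------------------

def transcript_abundance(
    tags: Iterable[CrosslinkTag],
    biotypes: Mapping[str, str],
    library_size: int | None = None,
    evidence: str = "truncation",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-RNA tag counts and CPM (count * 1e6 / library size), with a
    biotype roll-up by summation. Tags on RNAs missing from the biotype
    annotation land in an explicit 'unassigned' bucket rather than being
    dropped silently."""
    counts: dict[str, int] = {}
    n_used = 0
    for tag in tags:
        if tag.evidence != evidence:
            continue
        n_used += 1
        counts[tag.reference] = counts.get(tag.reference, 0) + 1
    lib = library_size if library_size is not None else n_used
    if lib <= 0:
        raise ValueError("library size must be positive")
    rows = []
    for rna in sorted(counts):
        biotype = biotypes.get(rna, "unassigned")
        rows.append({
            "rna": rna, "biotype": biotype, "count": counts[rna],
            "cpm": counts[rna] * 1e6 / lib,
        })
    per_rna = pd.DataFrame(rows, columns=["rna", "biotype", "count", "cpm"])
    rollup = (
        per_rna.groupby("biotype", as_index=False)[["count", "cpm"]].sum()
        if not per_rna.empty else pd.DataFrame(columns=["biotype", "count", "cpm"])
    )
    return per_rna, rollup


def tags_to_count_frame(tags: Iterable[CrosslinkTag]) -> pd.DataFrame:
    """Collapse tags into the (reference, position, evidence, count) frame
    consumed by the BED6 writer."""
    counter: dict[tuple, int] = {}
    for t in tags:
        key = (t.reference, t.position, t.evidence)
        counter[key] = counter.get(key, 0) + 1
    rows = [
        {"reference": r, "position": p, "evidence": e, "count": c}
        for (r, p, e), c in sorted(counter.items())
    ]
    return pd.DataFrame(rows, columns=["reference", "position", "evidence", "count"])
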