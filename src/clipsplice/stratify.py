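"""Splice-site-centric stratification of crosslink evidence.

Maps crosslink tags to annotated exon/intron boundaries, extracts
strand-corrected donor 9-mers (last 3 exonic + first 6 intronic nt) and
acceptor 23-mers (last 20 intronic + 3 exonic nt) for maxent scoring,
partitions boundary fold changes by weak/intermediate/strong splice-site
strength, tests gene-set enrichment of differentially bound sites with
Fisher's exact test (BH-adjusted per direction), and contrasts the
nucleotide composition of up- versus down-regulated exon sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import diffbind, io, maxent
from .crosslink import CrosslinkTag

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 10
DONOR_EXONIC = 3   # exonic nt in the donor window
DONOR_INTRONIC = 6
ACCEPTOR_INTRONIC = 20
ACCEPTOR_EXONIC = 3


@dataclass
class BoundarySite:
    gene: str
    transcript: str
    contig: str
    side: str            # donor | acceptor
    strand: str
    boundary: int        # 0-based genomic coordinate of the last exonic nt at the junction
    window: str          # 9-mer (donor) or 23-mer (acceptor), transcription orientation
    score: float | None = None
    category: str | None = None
    tag_counts: dict[str, int] = field(default_factory=dict)  # per condition

    @property
    def site_id(self) -> str:
        return f"{self.transcript}:{self.side}:{self.contig}:{self.boundary + 1}:{self.strand}"


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def extract_boundary_windows(
    gtf: pd.DataFrame | str,
    genome: Mapping[str, str] | str,
) -> list[BoundarySite]:
    """Donor and acceptor windows for every internal exon boundary of every
    transcript, strand-corrected (minus-strand windows are
    reverse-complemented). Windows that would run past the contig end, or
    whose intron is too short to supply the intronic part, are skipped
    with a logged warning."""
    if isinstance(gtf, str):
        gtf = io.read_gtf(gtf)
    if isinstance(genome, str):
        genome = io.read_fasta(genome)
    exons = gtf[gtf["feature"] == "exon"]
    sites: list[BoundarySite] = []
    n_skipped = 0
    for (tx, gene_id, contig, strand), group in exons.groupby(
        ["transcript_id", "gene_id", "contig", "strand"], sort=True
    ):
        seq = genome.get(contig)
        if seq is None:
            raise ValueError(f"contig {contig!r} missing from genome FASTA")
        bounds = sorted(
            (int(r.start) - 1, int(r.end)) for r in group.itertuples()
        )  # 0-based half-open, genomic order
        for (s0, e0), (s1, e1) in zip(bounds, bounds[1:]):
            if s1 <= e0:
                raise ValueError(f"overlapping exons within transcript {tx!r}")
            intron_len = s1 - e0
            if strand == "+":
                donor = _plus_donor(seq, e0, intron_len)
                acceptor = _plus_acceptor(seq, s1, intron_len)
                donor_pos, acceptor_pos = e0 - 1, s1
            else:
                # transcription right-to-left: the downstream exon (genomic
                # right) donates, the upstream exon accepts
                donor = _minus_donor(seq, s1, intron_len)
                acceptor = _minus_acceptor(seq, e0, intron_len)
                donor_pos, acceptor_pos = s1, e0 - 1
            for side, window, pos in (
                ("donor", donor, donor_pos),
                ("acceptor", acceptor, acceptor_pos),
            ):
                if window is None:
                    n_skipped += 1
                    continue
                sites.append(BoundarySite(
                    gene=gene_id, transcript=tx, contig=contig, side=side,
                    strand=strand, boundary=pos, window=window,
                ))
    if n_skipped:
        logger.warning("skipped %d boundary windows extending past a contig/intron end",
                       n_skipped)
    return sites


def _plus_donor(seq: str, e0: int, intron_len: int) -> str | None:
    if e0 < DONOR_EXONIC or e0 + DONOR_INTRONIC > len(seq) or intron_len < DONOR_INTRONIC:
        return None
    return seq[e0 - DONOR_EXONIC:e0 + DONOR_INTRONIC]


def _plus_acceptor(seq: str, s1: int, intron_len: int) -> str | None:
    if s1 < ACCEPTOR_INTRONIC or s1 + ACCEPTOR_EXONIC > len(seq) or intron_len < ACCEPTOR_INTRONIC:
        return None
    return seq[s1 - ACCEPTOR_INTRONIC:s1 + ACCEPTOR_EXONIC]


def _minus_donor(seq: str, s1: int, intron_len: int) -> str | None:
    if s1 < DONOR_INTRONIC or s1 + DONOR_EXONIC > len(seq) or intron_len < DONOR_INTRONIC:
        return None
    return io.reverse_complement(seq[s1 - DONOR_INTRONIC:s1 + DONOR_EXONIC])


def _minus_acceptor(seq: str, e0: int, intron_len: int) -> str | None:
    if e0 < ACCEPTOR_EXONIC or e0 + ACCEPTOR_INTRONIC > len(seq) or intron_len < ACCEPTOR_INTRONIC:
        return None
    return io.reverse_complement(seq[e0 - ACCEPTOR_EXONIC:e0 + ACCEPTOR_INTRONIC])


def score_boundaries(
    sites: Iterable[BoundarySite],
    donor_model: maxent.MaxEntModel | None = None,
    acceptor_model: maxent.MaxEntModel | None = None,
    donor_background: maxent.MaxEntModel | None = None,
    acceptor_background: maxent.MaxEntModel | None = None,
    weak_threshold: float = maxent.WEAK_THRESHOLD,
    strong_threshold: float = maxent.STRONG_THRESHOLD,
) -> list[BoundarySite]:
    """Attach maxent5/maxent3 scores and weak/intermediate/strong categories
    to boundary sites in place (and return them)."""
    sites = list(sites)
    for side, model, background in (
        ("donor", donor_model, donor_background),
        ("acceptor", acceptor_model, acceptor_background),
    ):
        if model is None:
            continue
        subset = [s for s in sites if s.side == side]
        if not subset:
            continue
        scored = maxent.score_batch(
            model, [s.window for s in subset], background, side,
            weak_threshold, strong_threshold,
        )
        for site, sc in zip(subset, scored):
            site.score = sc.score
            site.category = sc.category
    return sites


# ---------------------------------------------------------------------------
# Tag-to-boundary assignment
# ---------------------------------------------------------------------------

@dataclass
class AssignmentStats:
    n_tags: int
    n_assigned: int
    n_unassigned: int
    n_double_assigned: int


def assign_tags_to_boundaries(
    tags: Iterable[CrosslinkTag],
    boundaries: Sequence[BoundarySite],
    flank: int = DEFAULT_FLANK,
    condition_of_sample: Mapping[str, str] | None = None,
) -> AssignmentStats:
    """Assign each tag to its nearest boundary within ±flank nt of the
    junction; a tag exactly equidistant to two boundaries supports both
    (double assignments are counted and reported). Counts accumulate into
    each boundary's per-condition ``tag_counts``."""
    by_contig: dict[str, list[BoundarySite]] = {}
    for b in boundaries:
        by_contig.setdefault(b.contig, []).append(b)
    coord_arrays = {
        contig: np.array([b.boundary for b in bs])
        for contig, bs in by_contig.items()
    }
    n_tags = n_assigned = n_unassigned = n_double = 0
    for tag in tags:
        n_tags += 1
        bs = by_contig.get(tag.reference)
        if bs is None:
            n_unassigned += 1
            continue
        dist = np.abs(coord_arrays[tag.reference] - tag.position)
        dmin = dist.min()
        if dmin > flank:
            n_unassigned += 1
            continue
        hits = np.flatnonzero(dist == dmin)
        if len(hits) > 1:
            n_double += 1
        n_assigned += 1
        condition = (condition_of_sample or {}).get(tag.sample, tag.sample)
        for h in hits:
            b = bs[h]
            b.tag_counts[condition] = b.tag_counts.get(condition, 0) + 1
    return AssignmentStats(n_tags, n_assigned, n_unassigned, n_double)


# ---------------------------------------------------------------------------
# Strength-stratified fold changes
# ---------------------------------------------------------------------------

def stratified_fold_changes(
    boundaries: Sequence[BoundarySite],
    case_condition: str,
    control_condition: str,
    library_sizes: Mapping[str, float] | None = None,
    pseudocount: float = diffbind.DEFAULT_PSEUDOCOUNT,
    fc_cutoff: float = diffbind.DEFAULT_FC_CUTOFF,
    min_coverage: int = diffbind.DEFAULT_MIN_COVERAGE,
    kurtosis_seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, diffbind.FoldChangeSummary | None]]:
    """Per-boundary log2 fold changes partitioned by splice-site strength
    category; empty categories are reported empty, not as errors.

    Returns the per-site table (site, gene, side, category, counts, CPMs,
    log2fc, direction) and a per-category excess-kurtosis summary (None
    where a category has fewer than 4 sites)."""
    rows = []
    for b in boundaries:
        c_case = b.tag_counts.get(case_condition, 0)
        c_ctrl = b.tag_counts.get(control_condition, 0)
        if c_case + c_ctrl < min_coverage:
            continue
        lib_case = library_sizes[case_condition] if library_sizes else 1e6
        lib_ctrl = library_sizes[control_condition] if library_sizes else 1e6
        cpm_case = c_case * 1e6 / lib_case
        cpm_ctrl = c_ctrl * 1e6 / lib_ctrl
        site = diffbind.log2_fold_change(cpm_case, cpm_ctrl, b.site_id, pseudocount, fc_cutoff)
        rows.append({
            "site": b.site_id, "gene": b.gene, "side": b.side,
            "category": b.category, "score": b.score,
            "count_case": c_case, "count_control": c_ctrl,
            "cpm_case": cpm_case, "cpm_control": cpm_ctrl,
            "log2fc": site.log2fc, "direction": site.direction,
        })
    table = pd.DataFrame(rows, columns=[
        "site", "gene", "side", "category", "score", "count_case",
        "count_control", "cpm_case", "cpm_control", "log2fc", "direction",
    ])
    summaries: dict[str, diffbind.FoldChangeSummary | None] = {}
    for category in ("weak", "intermediate", "strong"):
        sub = table[table["category"] == category]
        if len(sub) >= 4 and sub["log2fc"].nunique() > 1:
            summaries[category] = diffbind.excess_kurtosis(
                sub["log2fc"].to_numpy(), label=category, seed=kurtosis_seed,
            )
        else:
            summaries[category] = None
    return table, summaries


# ---------------------------------------------------------------------------
# Fisher gene-set enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    gene_set: str
    table: tuple[int, int, int, int]  # (in&sel, in&not, out&sel, out&not)
    odds_ratio: float
    p: float
    p_adj: float
    direction: str


def fisher_enrichment(
    selected: set[str],
    background: set[str],
    gene_sets: Mapping[str, set[str]],
    direction: str = "up",
) -> list[EnrichmentResult]:
    """Two-sided Fisher exact test per gene set, BH-adjusted across the
    sets tested within this direction stratum. Odds ratios use the Haldane
    0.5 correction when a table cell is zero. Gene sets with no member in
    the background are dropped."""
    if not background:
        raise ValueError("empty background")
    if not selected <= background:
        raise ValueError("selected genes must be a subset of the background")
    results = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & background
        if not members:
            continue
        a = len(members & selected)
        b = len(members - selected)
        c = len(selected - members)
        d = len(background) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orat = (a * d) / (b * c)
        results.append(EnrichmentResult(name, (a, b, c, d), float(orat), float(p),
                                        np.nan, direction))
    if results:
        adj = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r.p_adj = float(q)
    return results


# ---------------------------------------------------------------------------
# Nucleotide-composition contrast
# ---------------------------------------------------------------------------

@dataclass
class CompositionContrast:
    per_position: pd.DataFrame | None   # position, base, freq_up, freq_down, diff, log_odds
    aggregate: pd.DataFrame             # base (T, C), frac_up, frac_down, diff + bootstrap CIs


def _base_fractions(seqs: Sequence[str], base: str) -> np.ndarray:
    return np.array([s.count(base) / len(s) for s in seqs])


def composition_contrast(
    up_seqs: Sequence[str],
    down_seqs: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
) -> CompositionContrast:
    """Per-position and aggregate nucleotide-frequency differences between
    up- and down-regulated sequence sets.

    Per-position output requires all sequences to share one length (emitted
    as None otherwise); the aggregate thymidine/cytidine fractions with
    bootstrap CIs are computed regardless. Both the raw frequency
    difference and a pseudocounted log-odds are emitted per position."""
    if not up_seqs or not down_seqs:
        raise ValueError("both sequence sets must be non-empty")
    lengths = {len(s) for s in list(up_seqs) + list(down_seqs)}
    per_position = None
    if len(lengths) == 1:
        L = lengths.pop()
        rows = []
        up_mat = np.array([list(s) for s in up_seqs])
        down_mat = np.array([list(s) for s in down_seqs])
        for pos in range(L):
            for base in "ACGT":
                fu = float((up_mat[:, pos] == base).mean())
                fd = float((down_mat[:, pos] == base).mean())
                lo = np.log2(((up_mat[:, pos] == base).sum() + 0.5)
                             / ((down_mat[:, pos] == base).sum() + 0.5)
                             * (len(down_seqs) + 1.0) / (len(up_seqs) + 1.0))
                rows.append({"position": pos, "base": base, "freq_up": fu,
                             "freq_down": fd, "diff": fu - fd, "log_odds": float(lo)})
        per_position = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    agg_rows = []
    for base in ("T", "C"):
        fu = _base_fractions(up_seqs, base)
        fd = _base_fractions(down_seqs, base)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            bu = fu[rng.integers(0, len(fu), len(fu))].mean()
            bd = fd[rng.integers(0, len(fd), len(fd))].mean()
            boots[i] = bu - bd
        lo, hi = np.percentile(boots, [2.5, 97.5])
        agg_rows.append({
            "base": base, "frac_up": float(fu.mean()), "frac_down": float(fd.mean()),
            "diff": float(fu.mean() - fd.mean()),
            "ci_low": float(lo), "ci_high": float(hi),
        })
    return CompositionContrast(per_position=per_position, aggregate=pd.DataFrame(agg_rows))
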