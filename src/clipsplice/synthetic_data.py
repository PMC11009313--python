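"""Synthetic data generators with recorded ground truth.

Every input the analysis stages consume can be generated here: aligned
iCLIP-style reads whose truncation and deletion evidence concentrates at
chosen nucleotides of short RNA references, exon-junction count tables with
group-specific PSI means and dispersions, signal/decoy splice-site sequence
sets with tunable per-position information content, and toy gene annotations
with planted unannotated (cryptic) junctions. All randomness flows from a
single integer seed, hierarchically split per consumer and per sample, and
every generator is byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io
from .splicing import Junction

_ALPHABET = np.array(list("ACGT"))

# substream labels appended to the global seed so consumers never share a stream
_STREAM_CLIP = 0
_STREAM_JUNCTIONS = 1
_STREAM_SPLICE_SITES = 2
_STREAM_ANNOTATION = 3


@dataclass
class SimulationTruth:
    """Full generative ground truth for a simulated experiment.

    Parameters
    ----------
    seed
        Global integer seed; all generators derive per-sample substreams
        from it.
    references
        ``(name, sequence)`` pairs for the short RNA references (e.g. a
        106-nt U6 snRNA).
    binding_profile
        Per-reference vector of crosslink probabilities per nucleotide;
        each sums to 1. The final nucleotide must carry zero mass because
        a crosslink there leaves no room for a truncated read 3' of it.
    deletion_sites
        Per-reference 0-based positions designated as the actual
        crosslinked nucleotides; reads covering one carry a deletion there
        with probability ``deletion_prob``.
    deletion_prob
        Per-read, per-site deletion probability in [0, 1].
    psi_truth
        ``{event_id: {condition: (mean_psi, dispersion)}}`` with mean in
        [0, 1] and beta-binomial overdispersion rho in (0, 1).
    planted_cryptic
        Junctions guaranteed absent from any emitted annotation.
    """

    seed: int
    references: list[tuple[str, str]] = field(default_factory=list)
    binding_profile: dict[str, np.ndarray] = field(default_factory=dict)
    deletion_sites: dict[str, list[int]] = field(default_factory=dict)
    deletion_prob: float = 0.0
    read_length: int = 30
    n_reads_per_sample: int = 10_000
    samples: list[tuple[str, str]] = field(default_factory=list)
    reference_weights: dict[str, float] | None = None
    psi_truth: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    event_types: dict[str, str] = field(default_factory=dict)
    planted_cryptic: list[Junction] = field(default_factory=list)

    def validate(self) -> None:
        ref_lengths = {name: len(seq) for name, seq in self.references}
        for name, profile in self.binding_profile.items():
            if name not in ref_lengths:
                raise ValueError(f"binding profile for unknown reference {name!r}")
            profile = np.asarray(profile, dtype=float)
            if len(profile) != ref_lengths[name]:
                raise ValueError(f"profile length mismatch for {name!r}")
            if (profile < 0).any():
                raise ValueError(f"negative crosslink probability for {name!r}")
            if abs(profile.sum() - 1.0) > 1e-9:
                raise ValueError(f"binding profile for {name!r} does not sum to 1")
            if profile[-1] != 0:
                raise ValueError(
                    f"binding profile for {name!r} places mass on the final "
                    "nucleotide; a crosslink there leaves no room for a read"
                )
        if not 0.0 <= self.deletion_prob <= 1.0:
            raise ValueError("deletion_prob must lie in [0, 1]")
        for name, sites in self.deletion_sites.items():
            for pos in sites:
                if not 0 <= pos < ref_lengths.get(name, 0):
                    raise ValueError(f"deletion site {pos} outside reference {name!r}")
        for event, per_cond in self.psi_truth.items():
            for cond, (mean, rho) in per_cond.items():
                if not 0.0 <= mean <= 1.0:
                    raise ValueError(f"mean PSI for {event}/{cond} outside [0, 1]")
                if rho <= 0.0 or rho >= 1.0:
                    raise ValueError(f"dispersion for {event}/{cond} must be in (0, 1)")

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for _, cond in self.samples:
            if cond not in seen:
                seen.append(cond)
        return seen


def _substream(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, index]))


# ---------------------------------------------------------------------------
# iCLIP read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedClip:
    sam_paths: dict[str, Path]
    truth_tags: pd.DataFrame  # sample, read_id, reference, crosslink_pos, deleted_positions


def _sam_header(references: Sequence[tuple[str, str]], sample: str) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, seq in references:
        lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
    lines.append(f"@RG\tID:{sample}")
    return "\n".join(lines) + "\n"


def _cigar_and_query(ref_seq: str, start: int, span: int, deleted: list[int]) -> tuple[str, str]:
    """Build CIGAR/query for a read consuming ``span`` reference nt from
    ``start``, with the reference positions in ``deleted`` absent from the
    query. Adjacent deletions merge into a single D operation."""
    if not deleted:
        return f"{span}M", ref_seq[start:start + span]
    deleted = sorted(deleted)
    ops: list[tuple[int, str]] = []
    query_parts: list[str] = []
    cursor = start
    i = 0
    while i < len(deleted):
        j = i
        while j + 1 < len(deleted) and deleted[j + 1] == deleted[j] + 1:
            j += 1
        if deleted[i] > cursor:
            ops.append((deleted[i] - cursor, "M"))
            query_parts.append(ref_seq[cursor:deleted[i]])
        ops.append((j - i + 1, "D"))
        cursor = deleted[j] + 1
        i = j + 1
    end = start + span
    if cursor < end:
        ops.append((end - cursor, "M"))
        query_parts.append(ref_seq[cursor:end])
    cigar = "".join(f"{n}{op}" for n, op in ops)
    return cigar, "".join(query_parts)


def simulate_clip_reads(truth: SimulationTruth, out_dir: str | Path) -> SimulatedClip:
    """Emit per-sample SAM files of pre-aligned iCLIP-style reads plus a
    ground-truth tag table.

    For each read a crosslink nucleotide is drawn from the reference's
    binding profile and the read starts one nucleotide 3' of it (the iCLIP
    truncation convention). Reads covering a designated crosslink site
    carry a 1-2 nt deletion there with probability ``deletion_prob``,
    encoded as a CIGAR D operation. Reads are truncated at the reference
    3' end when necessary; the exact read count is conserved.
    """
    truth.validate()
    if not truth.samples:
        raise ValueError("truth.samples is empty")
    ref_seqs = dict(truth.references)
    for name, seq in truth.references:
        if truth.read_length > len(seq):
            raise ValueError(
                f"read_length {truth.read_length} exceeds reference {name!r} "
                f"length {len(seq)}"
            )
    ref_names = [name for name, _ in truth.references if name in truth.binding_profile]
    weights = np.array(
        [1.0 if truth.reference_weights is None else truth.reference_weights[n] for n in ref_names],
        dtype=float,
    )
    weights = weights / weights.sum()

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sam_paths: dict[str, Path] = {}
    truth_rows: list[dict] = []

    for s_idx, (sample, _condition) in enumerate(truth.samples):
        rng = _substream(truth.seed, _STREAM_CLIP, s_idx)
        n_per_ref = rng.multinomial(truth.n_reads_per_sample, weights)
        lines: list[str] = []
        read_no = 0
        for name, n_reads in zip(ref_names, n_per_ref):
            seq = ref_seqs[name]
            profile = np.asarray(truth.binding_profile[name], dtype=float)
            xlink = rng.choice(len(seq), size=n_reads, p=profile)
            xlink.sort(kind="stable")
            sites = sorted(truth.deletion_sites.get(name, []))
            for pos in xlink:
                start = int(pos) + 1
                span = min(truth.read_length, len(seq) - start)
                covered = [d for d in sites if start <= d < start + span]
                deleted = [d for d in covered
                           if truth.deletion_prob > 0 and rng.random() < truth.deletion_prob]
                cigar, query = _cigar_and_query(seq, start, span, deleted)
                qname = f"{sample}.r{read_no:06d}"
                read_no += 1
                lines.append(
                    f"{qname}\t0\t{name}\t{start + 1}\t255\t{cigar}\t*\t0\t0\t"
                    f"{query}\t*\tRG:Z:{sample}"
                )
                truth_rows.append({
                    "sample": sample, "read_id": qname, "reference": name,
                    "crosslink_pos": int(pos),
                    "deleted_positions": ",".join(map(str, deleted)),
                })
        path = out_dir / f"{sample}.sam"
        with open(path, "w") as fh:
            fh.write(_sam_header(truth.references, sample))
            fh.write("\n".join(lines))
            if lines:
                fh.write("\n")
        sam_paths[sample] = path

    truth_df = pd.DataFrame(
        truth_rows,
        columns=["sample", "read_id", "reference", "crosslink_pos", "deleted_positions"],
    )
    truth_df.to_csv(out_dir / "tags_truth.tsv", sep="\t", index=False)
    return SimulatedClip(sam_paths=sam_paths, truth_tags=truth_df)


# ---------------------------------------------------------------------------
# Junction-count simulation (beta-binomial PSI)
# ---------------------------------------------------------------------------

def beta_binomial_params(mean: float, rho: float) -> tuple[float, float]:
    """Convert (mean, overdispersion rho) to Beta(a, b) shape parameters.

    rho is the intraclass correlation: Var(PSI_latent) = mean(1-mean)*rho.
    """
    if rho <= 0.0 or rho >= 1.0:
        raise ValueError("dispersion rho must be in (0, 1)")
    scale = (1.0 - rho) / rho
    return mean * scale, (1.0 - mean) * scale


def simulate_junction_counts(
    truth: SimulationTruth, depth: int, out_path: str | Path | None = None
) -> pd.DataFrame:
    """Draw per-event, per-sample inclusion/skipping junction counts from a
    beta-binomial with the condition's mean PSI and dispersion.

    Totals per event and sample equal ``depth`` exactly. Boundary means
    (0 or 1) produce degenerate draws with zero variance.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not truth.psi_truth:
        raise ValueError("truth.psi_truth is empty")
    rows = []
    for s_idx, (sample, condition) in enumerate(truth.samples):
        rng = _substream(truth.seed, _STREAM_JUNCTIONS, s_idx)
        for event_id in sorted(truth.psi_truth):
            per_cond = truth.psi_truth[event_id]
            if condition not in per_cond:
                raise ValueError(f"no PSI truth for event {event_id!r} in condition {condition!r}")
            mean, rho = per_cond[condition]
            if mean <= 0.0:
                incl = 0
            elif mean >= 1.0:
                incl = depth
            else:
                a, b = beta_binomial_params(mean, rho)
                p = rng.beta(a, b)
                incl = int(rng.binomial(depth, p))
            rows.append({
                "event_id": event_id,
                "event_type": truth.event_types.get(event_id, "SE"),
                "sample": sample,
                "condition": condition,
                "inclusion_count": incl,
                "skipping_count": depth - incl,
            })
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# Splice-site sequence sets with tunable information content
# ---------------------------------------------------------------------------

def _consensus_prob_for_bits(bits: float) -> float:
    """Solve for the consensus-base probability q giving per-position
    information content ``bits`` under a (q, r, r, r) composition."""
    if bits < 0 or bits > 2.0:
        raise ValueError(f"information content {bits} bits/position unreachable (max 2)")
    if bits == 0:
        return 0.25
    if bits >= 2.0 - 1e-12:
        return 1.0

    def info(q: float) -> float:
        r = (1.0 - q) / 3.0
        h = -q * math.log2(q)
        if r > 0:
            h -= 3.0 * r * math.log2(r)
        return 2.0 - h

    lo, hi = 0.25, 1.0 - 1e-12
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if info(mid) < bits:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_splice_site_sets(
    info_content: Sequence[float],
    n_signal: int,
    n_decoy: int,
    seed: int,
    consensus: str | None = None,
    signal_path: str | Path | None = None,
    decoy_path: str | Path | None = None,
) -> tuple[list[str], list[str]]:
    """Draw signal windows from a position-specific model with the requested
    per-position information content (bits), and decoys uniformly.

    ``consensus`` optionally fixes the consensus base at each position
    (e.g. ``...GT...`` with 2 bits at the GT positions for a canonical
    donor); otherwise consensus bases are drawn once from the seed stream.
    Window length must be 9 (donor) or 23 (acceptor).
    """
    L = len(info_content)
    if L not in (9, 23):
        raise ValueError(f"window length must be 9 (donor) or 23 (acceptor), got {L}")
    rng = _substream(seed, _STREAM_SPLICE_SITES)
    if consensus is None:
        consensus_idx = rng.integers(0, 4, size=L)
    else:
        if len(consensus) != L:
            raise ValueError("consensus length mismatch")
        lookup = {b: i for i, b in enumerate("ACGT")}
        consensus_idx = np.array([lookup[b] for b in consensus.upper()])

    pwm = np.empty((L, 4))
    for i, bits in enumerate(info_content):
        q = _consensus_prob_for_bits(float(bits))
        pwm[i] = (1.0 - q) / 3.0
        pwm[i, consensus_idx[i]] = q

    sig_idx = np.stack(
        [rng.choice(4, size=n_signal, p=pwm[i]) for i in range(L)], axis=1
    ) if n_signal else np.empty((0, L), dtype=int)
    signal = ["".join(_ALPHABET[row]) for row in sig_idx]
    dec_idx = rng.integers(0, 4, size=(n_decoy, L))
    decoy = ["".join(_ALPHABET[row]) for row in dec_idx]

    if signal_path is not None:
        io.write_fasta({f"signal_{i:05d}": s for i, s in enumerate(signal)}, signal_path)
    if decoy_path is not None:
        io.write_fasta({f"decoy_{i:05d}": s for i, s in enumerate(decoy)}, decoy_path)
    return signal, decoy


# ---------------------------------------------------------------------------
# Toy annotation with planted cryptic junctions
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTruth:
    gtf: pd.DataFrame
    genome: dict[str, str]
    annotated_junctions: list[Junction]
    cryptic_junctions: list[Junction]
    contig: str = "chrSim"


def simulate_annotation(
    n_genes: int,
    exons_per_gene: int,
    planted_cryptic: int | Sequence[Junction],
    seed: int,
    exon_length_range: tuple[int, int] = (80, 160),
    intron_length_range: tuple[int, int] = (80, 200),
    gtf_path: str | Path | None = None,
    fasta_path: str | Path | None = None,
) -> AnnotationTruth:
    """Emit a toy genome FASTA and matching GTF with known junction truth.

    Genes alternate strand along a single contig; introns carry canonical
    GT...AG dinucleotides (strand-corrected). ``planted_cryptic`` is either
    an explicit junction list or a count of cryptic junctions to derive by
    shifting annotated donors into the intron; planted junctions are
    guaranteed absent from the emitted GTF.
    """
    if n_genes < 1 or exons_per_gene < 2:
        raise ValueError("need at least 1 gene with 2 exons")
    lo_e, hi_e = exon_length_range
    lo_i, hi_i = intron_length_range
    if lo_e < 3:
        raise ValueError("exon lengths must be >= 3 for donor/acceptor windows")
    if lo_i < 30:
        raise ValueError("intron lengths must be >= 30 for acceptor windows")
    rng = _substream(seed, _STREAM_ANNOTATION)
    contig = "chrSim"
    gap = 300

    genome_parts: list[np.ndarray] = []
    rows: list[dict] = []
    annotated: list[Junction] = []
    cursor = 0  # 0-based genomic cursor

    for g in range(n_genes):
        strand = "+" if g % 2 == 0 else "-"
        gene_id = f"gene{g + 1:03d}"
        tx_id = f"tx{g + 1:03d}"
        lead = int(rng.integers(gap // 2, gap))
        genome_parts.append(rng.integers(0, 4, size=lead))
        cursor += lead
        exon_bounds: list[tuple[int, int]] = []  # 0-based half-open, genomic order
        for e in range(exons_per_gene):
            e_len = int(rng.integers(lo_e, hi_e + 1))
            exon_seq = rng.integers(0, 4, size=e_len)
            genome_parts.append(exon_seq)
            exon_bounds.append((cursor, cursor + e_len))
            cursor += e_len
            if e < exons_per_gene - 1:
                i_len = int(rng.integers(lo_i, hi_i + 1))
                intron_seq = rng.integers(0, 4, size=i_len)
                if strand == "+":
                    intron_seq[0:2] = [2, 3]       # GT
                    intron_seq[-2:] = [0, 2]       # AG
                else:
                    intron_seq[0:2] = [1, 3]       # CT = revcomp(AG)
                    intron_seq[-2:] = [0, 1]       # AC = revcomp(GT)
                genome_parts.append(intron_seq)
                cursor += i_len
        for s0, e0 in exon_bounds:
            if not s0 < e0:
                raise ValueError(f"overlapping or empty exon in {tx_id}")
        for (_, a_end), (b_start, _) in zip(exon_bounds, exon_bounds[1:]):
            if b_start <= a_end:
                raise ValueError(f"overlapping exons within transcript {tx_id}")
        gene_start0, gene_end0 = exon_bounds[0][0], exon_bounds[-1][1]
        rows.append({
            "contig": contig, "source": "clipsplice", "feature": "gene",
            "start": gene_start0 + 1, "end": gene_end0, "score": ".",
            "strand": strand, "frame": ".", "gene_id": gene_id, "transcript_id": tx_id,
        })
        rows.append({**rows[-1], "feature": "transcript"})
        for s0, e0 in exon_bounds:
            rows.append({
                "contig": contig, "source": "clipsplice", "feature": "exon",
                "start": s0 + 1, "end": e0, "score": ".",
                "strand": strand, "frame": ".", "gene_id": gene_id, "transcript_id": tx_id,
            })
        # junctions in transcription order (1-based exonic boundary coordinates)
        if strand == "+":
            for (_, a_end), (b_start, _) in zip(exon_bounds, exon_bounds[1:]):
                annotated.append(Junction(contig, a_end, b_start + 1, "+"))
        else:
            for (_, a_end), (b_start, _) in zip(exon_bounds, exon_bounds[1:]):
                # transcription right-to-left: donor is the downstream exon's
                # genomic start, acceptor the upstream exon's genomic end
                annotated.append(Junction(contig, b_start + 1, a_end, "-"))

    genome_parts.append(rng.integers(0, 4, size=gap))
    genome = "".join(_ALPHABET[np.concatenate(genome_parts)])
    gtf = pd.DataFrame(rows, columns=io.GTF_COLUMNS)

    donors = {(j.contig, j.strand, j.donor) for j in annotated}
    acceptors = {(j.contig, j.strand, j.acceptor) for j in annotated}
    if isinstance(planted_cryptic, int):
        n_cryptic = planted_cryptic
        if n_cryptic > len(annotated):
            raise ValueError("cannot plant more cryptic junctions than annotated ones")
        cryptic: list[Junction] = []
        picks = rng.choice(len(annotated), size=n_cryptic, replace=False)
        for k in sorted(picks):
            j = annotated[k]
            step = 1 if j.strand == "+" else -1
            for shift in range(5, 25):
                new_donor = j.donor + step * shift
                if (j.contig, j.strand, new_donor) not in donors:
                    cryptic.append(Junction(j.contig, new_donor, j.acceptor, j.strand))
                    break
            else:  # pragma: no cover - 20 candidate shifts always suffice
                raise RuntimeError("could not derive a cryptic donor")
    else:
        cryptic = list(planted_cryptic)
        for j in cryptic:
            if (j.contig, j.strand, j.donor) in donors and (j.contig, j.strand, j.acceptor) in acceptors:
                raise ValueError(f"planted junction {j} is fully annotated")

    if gtf_path is not None:
        io.write_gtf(gtf, gtf_path)
    if fasta_path is not None:
        io.write_fasta({contig: genome}, fasta_path)
    return AnnotationTruth(
        gtf=gtf, genome={contig: genome},
        annotated_junctions=annotated, cryptic_junctions=cryptic, contig=contig,
    )
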