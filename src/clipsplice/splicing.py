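"""PSI quantification, PSI-variability testing, differential alternative
splicing, and annotated-vs-cryptic junction classification.

PSI (percent spliced in) for an event is the mean of its inclusion-junction
counts divided by that mean plus the skipping-junction count. Variability
between conditions is assessed per event with a two-sided F test on PSI
variances and globally with an independent two-sample t test on per-event
PSI standard deviations. Differential events are called with a binomial
likelihood-ratio test on pooled counts, BH-adjusted, and filtered on
adjusted p < alpha together with an absolute PSI difference above
``min_delta``. A junction is cryptic when either its donor or its acceptor
coordinate is absent from the annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "RI", "MXE", "A3SS", "A5SS")


class Junction(NamedTuple):
    """A splice junction: 1-based genomic coordinates of the last exonic
    nucleotide on the donor side and the first exonic nucleotide on the
    acceptor side, in transcription order (donor > acceptor genomically on
    the minus strand)."""

    contig: str
    donor: int
    acceptor: int
    strand: str

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        upstream = self.donor < self.acceptor if self.strand == "+" else self.donor > self.acceptor
        if not upstream:
            raise ValueError(
                f"donor must lie strictly upstream of acceptor in transcription "
                f"order: {self}"
            )


@dataclass
class SplicingEvent:
    """Junction-count-backed alternative splicing event."""

    event_id: str
    event_type: str
    inclusion_counts: np.ndarray  # (n_inclusion_junctions, n_samples)
    skipping_counts: np.ndarray   # (n_samples,)
    samples: list[str]
    conditions: list[str]
    junctions: list[Junction] | None = None
    cryptic: bool | None = None

    def __post_init__(self) -> None:
        self.inclusion_counts = np.atleast_2d(np.asarray(self.inclusion_counts, dtype=float))
        self.skipping_counts = np.asarray(self.skipping_counts, dtype=float)
        if (self.inclusion_counts < 0).any() or (self.skipping_counts < 0).any():
            raise ValueError(f"negative junction counts in event {self.event_id!r}")
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")

    def psi(self) -> np.ndarray:
        return compute_psi(self.inclusion_counts, self.skipping_counts)


def compute_psi(inclusion_counts, skipping_counts) -> np.ndarray:
    """Per-sample PSI = mean(inclusion counts) / (mean(inclusion) + skipping).

    Returns NaN (undefined, to be excluded downstream) where the total
    supporting evidence is zero; raises on negative counts.
    """
    incl = np.atleast_2d(np.asarray(inclusion_counts, dtype=float))
    skip = np.asarray(skipping_counts, dtype=float)
    if (incl < 0).any() or (skip < 0).any():
        raise ValueError("negative junction counts")
    mean_incl = incl.mean(axis=0)
    total = mean_incl + skip
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total > 0, mean_incl / total, np.nan)
    return psi


# ---------------------------------------------------------------------------
# PSI variability: per-event F test + global t test on per-event SDs
# ---------------------------------------------------------------------------

def f_variance_test(psi_case: Sequence[float], psi_control: Sequence[float]) -> tuple[float, float]:
    """Two-sided variance-ratio F test for one event.

    F = var(case)/var(control) with (n_case-1, n_control-1) degrees of
    freedom; returns (F, p). NaN PSI values are dropped; zero control
    variance yields (inf/nan, nan) and is excluded from global summaries.
    """
    a = np.asarray(psi_case, dtype=float)
    b = np.asarray(psi_control, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 defined PSI values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0.0:
        return (np.inf if va > 0 else np.nan), np.nan
    f = va / vb
    dist = stats.f(len(a) - 1, len(b) - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0))


@dataclass
class VariabilityResult:
    per_event: pd.DataFrame      # event_id, sd_case, sd_control, F, p
    global_t: float
    global_p: float
    n_excluded_zero_variance: int


def psi_variability_test(
    psi_case: np.ndarray,
    psi_control: np.ndarray,
    event_ids: Sequence[str] | None = None,
    welch: bool = False,
) -> VariabilityResult:
    """Per-event F tests plus the global independent t test comparing the
    two groups' per-event PSI standard deviations.

    ``psi_case``/``psi_control`` are (n_events, n_samples) arrays. Events
    whose control variance is zero are flagged (p = NaN) and excluded from
    the global test with a logged count.
    """
    psi_case = np.atleast_2d(np.asarray(psi_case, dtype=float))
    psi_control = np.atleast_2d(np.asarray(psi_control, dtype=float))
    if psi_case.shape[0] != psi_control.shape[0]:
        raise ValueError("event dimension mismatch between groups")
    n_events = psi_case.shape[0]
    ids = list(event_ids) if event_ids is not None else [f"event{i}" for i in range(n_events)]

    rows = []
    for i in range(n_events):
        f, p = f_variance_test(psi_case[i], psi_control[i])
        rows.append({
            "event_id": ids[i],
            "sd_case": float(np.nanstd(psi_case[i], ddof=1)),
            "sd_control": float(np.nanstd(psi_control[i], ddof=1)),
            "F": f, "p": p,
        })
    per_event = pd.DataFrame(rows)
    ok = ~per_event["p"].isna()
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("excluded %d events with zero control variance from global test", n_excluded)
    usable = per_event[ok]
    if len(usable) < 2:
        raise ValueError("too few events with defined F tests for the global comparison")
    t, p_global = stats.ttest_ind(usable["sd_case"], usable["sd_control"], equal_var=not welch)
    return VariabilityResult(per_event, float(t), float(p_global), n_excluded)


# ---------------------------------------------------------------------------
# Differential ASE calling: binomial LRT + BH + effect-size filter
# ---------------------------------------------------------------------------

def _binom_loglik(k: float, n: float, p: float) -> float:
    if n == 0:
        return 0.0
    p = min(max(p, 1e-12), 1 - 1e-12)
    return k * np.log(p) + (n - k) * np.log(1.0 - p)


def binomial_lrt(incl_case: float, tot_case: float, incl_ctrl: float, tot_ctrl: float) -> float:
    """Likelihood-ratio test of a common inclusion proportion against
    group-specific proportions on pooled counts (chi-square, df = 1)."""
    if min(tot_case, tot_ctrl) <= 0:
        return np.nan
    p0 = (incl_case + incl_ctrl) / (tot_case + tot_ctrl)
    ll0 = _binom_loglik(incl_case, tot_case, p0) + _binom_loglik(incl_ctrl, tot_ctrl, p0)
    ll1 = (_binom_loglik(incl_case, tot_case, incl_case / tot_case)
           + _binom_loglik(incl_ctrl, tot_ctrl, incl_ctrl / tot_ctrl))
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    return float(stats.chi2.sf(lrt, df=1))


def differential_ase(
    events: Iterable[SplicingEvent],
    case_condition: str,
    control_condition: str,
    alpha: float = 0.05,
    min_delta: float = 0.05,
) -> pd.DataFrame:
    """Call differential alternative splicing events.

    Per event, a binomial LRT on counts pooled within condition yields p;
    BH adjustment across events yields p_adj; an event is significant when
    p_adj < alpha AND |delta PSI| > min_delta (delta = mean case PSI minus
    mean control PSI). Returns the full per-event table with a
    ``significant`` flag and, as attrs, counts per event type.
    """
    rows = []
    for ev in events:
        cond = np.asarray(ev.conditions)
        psi = ev.psi()
        is_case = cond == case_condition
        is_ctrl = cond == control_condition
        if not is_case.any() or not is_ctrl.any():
            raise ValueError(f"event {ev.event_id!r} lacks samples in one condition")
        mean_incl = ev.inclusion_counts.mean(axis=0)
        total = mean_incl + ev.skipping_counts
        p = binomial_lrt(
            mean_incl[is_case].sum(), total[is_case].sum(),
            mean_incl[is_ctrl].sum(), total[is_ctrl].sum(),
        )
        delta = float(np.nanmean(psi[is_case]) - np.nanmean(psi[is_ctrl]))
        rows.append({
            "event_id": ev.event_id, "event_type": ev.event_type,
            "psi_case": float(np.nanmean(psi[is_case])),
            "psi_control": float(np.nanmean(psi[is_ctrl])),
            "delta_psi": delta, "p": p,
            "cryptic": ev.cryptic,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no events supplied")
    ok = ~df["p"].isna()
    df["p_adj"] = np.nan
    if ok.any():
        df.loc[ok, "p_adj"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    df["significant"] = (df["p_adj"] < alpha) & (df["delta_psi"].abs() > min_delta)
    counts = (
        df[df["significant"]].groupby("event_type")["event_id"].count()
        .reindex(EVENT_TYPES, fill_value=0).to_dict()
    )
    df.attrs["significant_by_type"] = counts
    df.attrs["alpha"] = alpha
    df.attrs["min_delta"] = min_delta
    return df


# ---------------------------------------------------------------------------
# Cryptic classification
# ---------------------------------------------------------------------------

def annotated_site_sets(annotated_junctions: Iterable[Junction]):
    """Build strand-aware donor and acceptor coordinate sets plus the contig
    universe from an annotated junction collection."""
    donors, acceptors, contigs = set(), set(), set()
    for j in annotated_junctions:
        donors.add((j.contig, j.strand, j.donor))
        acceptors.add((j.contig, j.strand, j.acceptor))
        contigs.add(j.contig)
    return donors, acceptors, contigs


def classify_cryptic(
    junctions: Iterable[Junction],
    annotated_junctions: Iterable[Junction],
) -> pd.DataFrame:
    """Label each junction annotated or cryptic.

    A junction is cryptic iff its donor OR its acceptor coordinate
    (strand-aware) is absent from the annotated site sets. Pure set
    membership: deterministic and permutation-invariant.
    """
    donors, acceptors, contigs = annotated_site_sets(annotated_junctions)
    rows = []
    for j in junctions:
        j.validate()
        if j.contig not in contigs:
            raise ValueError(f"junction on unknown contig {j.contig!r}")
        donor_known = (j.contig, j.strand, j.donor) in donors
        acceptor_known = (j.contig, j.strand, j.acceptor) in acceptors
        rows.append({
            "contig": j.contig, "donor": j.donor, "acceptor": j.acceptor,
            "strand": j.strand, "annotated_donor": donor_known,
            "annotated_acceptor": acceptor_known,
            "classification": "annotated" if donor_known and acceptor_known else "cryptic",
        })
    return pd.DataFrame(
        rows,
        columns=["contig", "donor", "acceptor", "strand",
                 "annotated_donor", "annotated_acceptor", "classification"],
    )


# ---------------------------------------------------------------------------
# Table I/O helpers
# ---------------------------------------------------------------------------

def events_from_count_table(df: pd.DataFrame) -> list[SplicingEvent]:
    """Build events from a long-format count table with columns event_id,
    event_type, sample, condition, inclusion_count, skipping_count (the
    format :func:`clipsplice.synthetic_data.simulate_junction_counts`
    emits)."""
    events = []
    for event_id, group in df.groupby("event_id", sort=True):
        group = group.sort_values("sample")
        events.append(SplicingEvent(
            event_id=str(event_id),
            event_type=str(group["event_type"].iloc[0]),
            inclusion_counts=group["inclusion_count"].to_numpy()[None, :],
            skipping_counts=group["skipping_count"].to_numpy(),
            samples=group["sample"].tolist(),
            conditions=group["condition"].tolist(),
        ))
    return events
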