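"""Maximum-entropy splice-site strength models (maxent5 / maxent3).

A model is the maximum-entropy distribution over fixed-length sequence
windows subject to matching a set of empirical marginals of the training
(signal) set. Donor models use 9-mers (last 3 exonic + first 6 intronic
nucleotides), acceptor models 23-mers (last 20 intronic + 3 exonic). The
default constraint set is all single-position marginals plus all
adjacent-pair marginals; fitting is by iterative proportional fitting (IPF)
over the fully enumerated sequence space when that space is small enough
(4^9 for donors), and by the exactly-computable first-order Markov chain
factorisation otherwise (23-mer acceptors). A window's score is

    maxent = log2 p_signal(window) - log2 p_background(window)

with a uniform background unless a decoy-trained model is supplied. Scores
are stratified into weak (< 3), intermediate ([3, 8]) and strong (> 8)
splice sites; the thresholds are configurable because a re-trained model's
scale need not match any published scorer's.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

DONOR_WINDOW = 9
ACCEPTOR_WINDOW = 23
WEAK_THRESHOLD = 3.0
STRONG_THRESHOLD = 8.0
DEFAULT_PSEUDOCOUNT = 0.5
_MAX_TABLE_CELLS = 1 << 20  # enumerate up to ~10 positions over ACGT


def default_constraints(window_length: int) -> list[tuple[int, ...]]:
    """Single-position marginals plus all adjacent-pair marginals."""
    singles = [(i,) for i in range(window_length)]
    pairs = [(i, i + 1) for i in range(window_length - 1)]
    return singles + pairs


def _encode(seqs: Sequence[str], alphabet: str) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(alphabet)}
    out = np.empty((len(seqs), len(seqs[0])), dtype=np.int64)
    for si, seq in enumerate(seqs):
        for pi, ch in enumerate(seq):
            try:
                out[si, pi] = lookup[ch]
            except KeyError:
                raise ValueError(
                    f"sequence {si} ({seq!r}) has non-{alphabet} character "
                    f"{ch!r} at position {pi}"
                ) from None
    return out


def empirical_marginals(
    encoded: np.ndarray,
    constraint_set: Sequence[tuple[int, ...]],
    k: int,
    pseudocount: float,
) -> dict[tuple[int, ...], np.ndarray]:
    """Smoothed empirical marginal tables, one per constrained position
    subset.

    The Laplace pseudocount is applied per cell of each *maximal*
    constrained subset; targets for subsets contained in a larger
    constrained subset are derived by marginalising the covering subset's
    smoothed table. Deriving rather than re-smoothing keeps the whole
    constraint family mutually consistent, which IPF requires to
    converge (independently smoothed single and pair tables would imply
    slightly different single-position marginals).
    """
    subsets = [tuple(s) for s in constraint_set]
    maximal = [s for s in subsets
               if not any(s != t and set(s) <= set(t) for t in subsets)]
    marginals: dict[tuple[int, ...], np.ndarray] = {}
    for subset in maximal:
        shape = (k,) * len(subset)
        counts = np.full(shape, pseudocount, dtype=float)
        cols = encoded[:, list(subset)]
        np.add.at(counts, tuple(cols.T), 1.0)
        marginals[subset] = counts / counts.sum()
    for subset in subsets:
        if subset in marginals:
            continue
        cover = next(t for t in maximal if set(subset) <= set(t))
        axes = tuple(i for i, pos in enumerate(cover) if pos not in subset)
        marginals[subset] = marginals[cover].sum(axis=axes)
    return marginals


@dataclass
class MaxEntModel:
    """Fitted maximum-entropy distribution over sequence windows.

    ``kind`` is ``"table"`` (explicit probability table over the enumerated
    space, fitted by IPF) or ``"chain"`` (adjacent-pairwise Markov chain
    factorisation, exact for the single+adjacent-pair constraint set).
    """

    window_length: int
    alphabet: str
    constraint_set: list[tuple[int, ...]]
    signal_marginals: dict[tuple[int, ...], np.ndarray]
    kind: str
    pseudocount: float
    table: np.ndarray | None = None            # kind == "table"
    pair_probs: list[np.ndarray] | None = None  # kind == "chain"
    metadata: dict = field(default_factory=dict)

    # -- probability ------------------------------------------------------
    def log2prob(self, sequence: str) -> float:
        return self.log2prob_batch([sequence])[0]

    def log2prob_batch(self, sequences: Sequence[str]) -> np.ndarray:
        enc = _encode(list(sequences), self.alphabet)
        if enc.shape[1] != self.window_length:
            raise ValueError(
                f"sequence length {enc.shape[1]} does not match model window "
                f"{self.window_length}"
            )
        if self.kind == "table":
            probs = self.table[tuple(enc.T)]
            return np.log2(probs)
        # chain: p(x) = p01(x0,x1) * prod_i p_{i,i+1}(x_i,x_{i+1}) / s_i(x_i)
        logp = np.log2(self.pair_probs[0][enc[:, 0], enc[:, 1]])
        for i in range(1, self.window_length - 1):
            pair = self.pair_probs[i]
            single = pair.sum(axis=1)  # marginal of position i, consistent across pairs
            logp += np.log2(pair[enc[:, i], enc[:, i + 1]]) - np.log2(single[enc[:, i]])
        return logp

    # -- diagnostics ------------------------------------------------------
    def fitted_marginal(self, subset: tuple[int, ...]) -> np.ndarray:
        subset = tuple(sorted(subset))
        if self.kind == "table":
            axes = tuple(i for i in range(self.window_length) if i not in subset)
            return self.table.sum(axis=axes)
        if len(subset) == 1:
            (i,) = subset
            pair = self.pair_probs[min(i, self.window_length - 2)]
            return pair.sum(axis=1) if i < self.window_length - 1 else pair.sum(axis=0)
        if len(subset) == 2 and subset[1] == subset[0] + 1:
            return self.pair_probs[subset[0]]
        raise ValueError(f"chain models only expose single/adjacent-pair marginals, not {subset}")

    def max_marginal_deviation(self) -> float:
        return max(
            float(np.abs(self.fitted_marginal(s) - m).max())
            for s, m in self.signal_marginals.items()
        )

    def entropy_bits(self) -> float:
        """Shannon entropy of the fitted distribution in bits (table models
        only)."""
        if self.kind != "table":
            raise ValueError("entropy over the full support requires a table model")
        p = self.table[self.table > 0]
        return float(-(p * np.log2(p)).sum())

    # -- serialisation ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "clipsplice-maxent-1",
            "window_length": self.window_length,
            "alphabet": self.alphabet,
            "kind": self.kind,
            "pseudocount": self.pseudocount,
            "constraint_set": [list(s) for s in self.constraint_set],
            "signal_marginals": {
                ",".join(map(str, s)): m.tolist() for s, m in self.signal_marginals.items()
            },
            "pair_probs": [p.tolist() for p in self.pair_probs] if self.pair_probs else None,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MaxEntModel":
        with open(path) as fh:
            payload = json.load(fh)
        marginals = {
            tuple(int(x) for x in key.split(",")): np.array(val)
            for key, val in payload["signal_marginals"].items()
        }
        constraint_set = [tuple(s) for s in payload["constraint_set"]]
        if payload["kind"] == "chain":
            return cls(
                window_length=payload["window_length"], alphabet=payload["alphabet"],
                constraint_set=constraint_set, signal_marginals=marginals,
                kind="chain", pseudocount=payload["pseudocount"],
                pair_probs=[np.array(p) for p in payload["pair_probs"]],
                metadata=payload.get("metadata", {}),
            )
        # table models are refitted from their stored marginals: IPF is
        # deterministic, so this reproduces the distribution without
        # serialising the full 4^9 table
        model = _fit_table(
            payload["window_length"], payload["alphabet"], constraint_set,
            marginals, payload["pseudocount"],
        )
        model.metadata = payload.get("metadata", {})
        return model


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _expand_to_full(arr: np.ndarray, subset: tuple[int, ...], L: int) -> np.ndarray:
    """Broadcast a marginal table (axes in sorted subset order) to the full
    L-dimensional shape."""
    full_shape = [1] * L
    for axis, pos in enumerate(subset):
        full_shape[pos] = arr.shape[axis]
    return arr.reshape(full_shape)


def _fit_table(
    window_length: int,
    alphabet: str,
    constraint_set: Sequence[tuple[int, ...]],
    marginals: Mapping[tuple[int, ...], np.ndarray],
    pseudocount: float,
    tol: float = 1e-6,
    max_sweeps: int = 500,
) -> MaxEntModel:
    k = len(alphabet)
    L = window_length
    table = np.full((k,) * L, 1.0 / k**L)
    sweeps = 0
    max_dev = np.inf
    # subsets are stored sorted, so summing out the complement axes leaves
    # the marginal's axes already in subset order
    while sweeps < max_sweeps:
        sweeps += 1
        for subset in constraint_set:
            target = marginals[tuple(subset)]
            axes = tuple(i for i in range(L) if i not in subset)
            current = table.sum(axis=axes)
            ratio = np.where(current > 0, target / np.where(current > 0, current, 1.0), 0.0)
            table = table * _expand_to_full(ratio, tuple(subset), L)
        devs = []
        for subset in constraint_set:
            target = marginals[tuple(subset)]
            axes = tuple(i for i in range(L) if i not in subset)
            devs.append(np.abs(table.sum(axis=axes) - target).max())
        max_dev = float(max(devs))
        if max_dev < tol:
            break
    table /= table.sum()
    return MaxEntModel(
        window_length=L, alphabet=alphabet, constraint_set=list(map(tuple, constraint_set)),
        signal_marginals=dict(marginals), kind="table", pseudocount=pseudocount,
        table=table,
        metadata={
            "fit": "iterative proportional fitting over the enumerated space",
            "sweeps": sweeps, "max_marginal_deviation": max_dev,
            "constraint_note": (
                "single-position plus adjacent-pair marginals; not the full "
                "MaxEntScan constraint hierarchy"
            ),
        },
    )


def fit_maxent(
    signal_seqs: Sequence[str],
    constraint_set: Sequence[tuple[int, ...]] | None = None,
    window_length: int | None = None,
    alphabet: str = "ACGT",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    tol: float = 1e-6,
    max_sweeps: int = 500,
) -> MaxEntModel:
    """Fit the maximum-entropy distribution matching the training set's
    marginals on ``constraint_set``.

    Uses IPF over the enumerated sequence space when |alphabet|^L is small
    enough (donor 9-mers: 4^9); otherwise the constraint set must be the
    single+adjacent-pair family and the exact Markov-chain factorisation is
    used (acceptor 23-mers).
    """
    signal_seqs = list(signal_seqs)
    if not signal_seqs:
        raise ValueError("empty training set")
    L = len(signal_seqs[0])
    if window_length is not None and window_length != L:
        raise ValueError(f"window_length {window_length} != sequence length {L}")
    if any(len(s) != L for s in signal_seqs):
        raise ValueError("training sequences have unequal lengths")
    encoded = _encode(signal_seqs, alphabet)
    k = len(alphabet)
    if constraint_set is None:
        constraint_set = default_constraints(L)
    constraint_set = [tuple(sorted(s)) for s in constraint_set]
    marginals = empirical_marginals(encoded, constraint_set, k, pseudocount)

    if k**L <= _MAX_TABLE_CELLS:
        return _fit_table(L, alphabet, constraint_set, marginals, pseudocount,
                          tol=tol, max_sweeps=max_sweeps)

    adjacent = set(default_constraints(L))
    if not set(constraint_set) <= adjacent:
        raise ValueError(
            "window too long to enumerate; only single-position and "
            "adjacent-pair constraints are supported for chain models"
        )
    pair_probs = [marginals.get((i, i + 1)) for i in range(L - 1)]
    if any(p is None for p in pair_probs):
        raise ValueError("chain models require all adjacent-pair constraints")
    return MaxEntModel(
        window_length=L, alphabet=alphabet, constraint_set=list(constraint_set),
        signal_marginals=marginals, kind="chain", pseudocount=pseudocount,
        pair_probs=pair_probs,
        metadata={
            "fit": "exact adjacent-pairwise Markov chain factorisation",
            "constraint_note": (
                "single-position plus adjacent-pair marginals; not the full "
                "MaxEntScan constraint hierarchy"
            ),
        },
    )


def fit_background(
    decoy_seqs: Sequence[str] | None,
    window_length: int,
    alphabet: str = "ACGT",
    **kwargs,
) -> MaxEntModel | None:
    """Background model: maxent fit to the decoy set when given, else None
    (interpreted as uniform by :func:`score`)."""
    if decoy_seqs is None:
        return None
    return fit_maxent(decoy_seqs, window_length=window_length, alphabet=alphabet, **kwargs)


# ---------------------------------------------------------------------------
# Scoring and classification
# ---------------------------------------------------------------------------

@dataclass
class SpliceSiteScore:
    sequence: str
    score: float
    side: str        # donor | acceptor
    category: str    # weak | intermediate | strong


def classify_splice_site(
    score: float,
    side: str = "donor",
    weak_threshold: float = WEAK_THRESHOLD,
    strong_threshold: float = STRONG_THRESHOLD,
) -> str:
    """weak iff score < weak_threshold; strong iff score > strong_threshold;
    boundary values are intermediate. Raises on non-finite scores."""
    if side not in ("donor", "acceptor"):
        raise ValueError(f"side must be donor or acceptor, got {side!r}")
    if not math.isfinite(score):
        raise ValueError(f"non-finite maxent score {score!r}")
    if score < weak_threshold:
        return "weak"
    if score > strong_threshold:
        return "strong"
    return "intermediate"


def score(
    model: MaxEntModel,
    sequence: str,
    background: MaxEntModel | None = None,
    side: str = "donor",
    weak_threshold: float = WEAK_THRESHOLD,
    strong_threshold: float = STRONG_THRESHOLD,
) -> SpliceSiteScore:
    """maxent score = log2 p_signal(seq) - log2 p_background(seq); the
    background is uniform when no decoy model is supplied."""
    return score_batch(model, [sequence], background, side,
                       weak_threshold, strong_threshold)[0]


def score_batch(
    model: MaxEntModel,
    sequences: Sequence[str],
    background: MaxEntModel | None = None,
    side: str = "donor",
    weak_threshold: float = WEAK_THRESHOLD,
    strong_threshold: float = STRONG_THRESHOLD,
) -> list[SpliceSiteScore]:
    logp = model.log2prob_batch(sequences)
    if background is None:
        logq = np.full(len(sequences), -model.window_length * math.log2(len(model.alphabet)))
    else:
        if background.window_length != model.window_length:
            raise ValueError("background window length does not match signal model")
        logq = background.log2prob_batch(sequences)
    scores = logp - logq
    return [
        SpliceSiteScore(
            sequence=seq, score=float(s), side=side,
            category=classify_splice_site(float(s), side, weak_threshold, strong_threshold),
        )
        for seq, s in zip(sequences, scores)
    ]


# ---------------------------------------------------------------------------
# Score-distribution shape (biphasic diagnostics)
# ---------------------------------------------------------------------------

@dataclass
class ScoreDistribution:
    bin_edges: np.ndarray
    density: np.ndarray
    grid: np.ndarray
    kde_density: np.ndarray
    maxima: list[float]
    minima: list[float]


def score_distribution(
    scores: Sequence[float],
    bandwidth: float | str | None = None,
    n_bins: int = 50,
    n_grid: int = 512,
) -> ScoreDistribution:
    """Histogram plus kernel-smoothed density with its local maxima and
    minima — the diagnostic for a biphasic (two-maximum) score
    distribution. Order-invariant; requires at least 10 scores."""
    values = np.sort(np.asarray(scores, dtype=float))
    if len(values) < 10:
        raise ValueError(f"need >= 10 scores for a distribution summary, got {len(values)}")
    if np.ptp(values) == 0.0:
        v = float(values[0])
        edges = np.array([v - 0.5, v + 0.5])
        return ScoreDistribution(
            bin_edges=edges, density=np.array([1.0]),
            grid=np.array([v]), kde_density=np.array([np.inf]),
            maxima=[v], minima=[],
        )
    density, edges = np.histogram(values, bins=n_bins, density=True)
    kde = stats.gaussian_kde(values, bw_method=bandwidth)
    bw = kde.covariance_factor() * values.std(ddof=1)
    grid = np.linspace(values[0] - 3 * bw, values[-1] + 3 * bw, n_grid)
    smooth = kde(grid)
    interior = np.arange(1, n_grid - 1)
    is_max = (smooth[interior] > smooth[interior - 1]) & (smooth[interior] >= smooth[interior + 1])
    is_min = (smooth[interior] < smooth[interior - 1]) & (smooth[interior] <= smooth[interior + 1])
    return ScoreDistribution(
        bin_edges=edges, density=density, grid=grid, kde_density=smooth,
        maxima=[float(grid[i]) for i in interior[is_max]],
        minima=[float(grid[i]) for i in interior[is_min]],
    )


# ---------------------------------------------------------------------------
# Oracle helper (used by the test-suite's independent cross-check)
# ---------------------------------------------------------------------------

def enumerate_windows(window_length: int, alphabet: str = "ACGT") -> list[str]:
    """All |alphabet|^L windows in lexicographic order (desk-scale only)."""
    return ["".join(t) for t in itertools.product(alphabet, repeat=window_length)]
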