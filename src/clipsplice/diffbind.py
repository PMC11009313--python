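"""Differential binding between conditions.

Counts are normalised to counts-per-million, condition replicates are
summarised by mean CPM, and fold changes are log2((cpm_case + c) /
(cpm_control + c)) with pseudocount c = 0.5 so zero counts stay finite.
Sites move into the 'up'/'down' selection at |log2FC| > 1. Distribution
shape is summarised by Fisher excess kurtosis (population moments, with a
bias-corrected alternative) plus a seeded bootstrap CI, and windowed region
differences are assessed with a label-permutation test on per-sample
region proportions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .crosslink import NucleotideProfile, region_proportion

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_FC_CUTOFF = 1.0
DEFAULT_MIN_COVERAGE = 10


@dataclass
class DifferentialSite:
    feature: str
    cpm_case: float
    cpm_control: float
    log2fc: float
    direction: str  # up | down | unchanged


@dataclass
class FoldChangeSummary:
    label: str
    n: int
    excess_kurtosis: float
    bootstrap_ci: tuple[float, float]


# ---------------------------------------------------------------------------
# Normalisation and fold changes
# ---------------------------------------------------------------------------

def normalize_cpm(
    counts: pd.DataFrame,
    library_sizes: Sequence[float] | pd.Series,
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """CPM per feature per sample (columns = samples); with ``conditions``
    given per sample, replicate columns are additionally summarised by
    their mean CPM in ``<condition>`` columns of the returned frame's
    ``attrs['condition_means']``."""
    libs = np.asarray(library_sizes, dtype=float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    if len(libs) != counts.shape[1]:
        raise ValueError("one library size per sample column required")
    cpm = counts * (1e6 / libs)
    if conditions is not None:
        cond = np.asarray(conditions)
        means = {c: cpm.loc[:, cond == c].mean(axis=1) for c in dict.fromkeys(conditions)}
        cpm.attrs["condition_means"] = pd.DataFrame(means)
    return cpm


def log2_fold_change(
    cpm_case: float,
    cpm_control: float,
    feature: str = "",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
) -> DifferentialSite:
    """log2((cpm_case + c)/(cpm_control + c)); direction is 'up' above the
    cutoff, 'down' below its negative, else 'unchanged'. Swapping case and
    control negates the value exactly."""
    if cpm_case < 0 or cpm_control < 0:
        raise ValueError("CPM values must be non-negative")
    # difference of logs (not log of ratio) so that swapping case and
    # control negates the value bit-exactly
    fc = math.log2(cpm_case + pseudocount) - math.log2(cpm_control + pseudocount)
    if fc > fc_cutoff:
        direction = "up"
    elif fc < -fc_cutoff:
        direction = "down"
    else:
        direction = "unchanged"
    return DifferentialSite(feature, cpm_case, cpm_control, fc, direction)


def fold_change_table(
    cpm_case: pd.Series,
    cpm_control: pd.Series,
    count_case: pd.Series | None = None,
    count_control: pd.Series | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Vectorised fold changes for a feature-indexed CPM pair. Features
    whose combined raw coverage falls below ``min_coverage`` are dropped
    (noise-driven extreme fold changes) when raw counts are supplied."""
    df = pd.DataFrame({"cpm_case": cpm_case, "cpm_control": cpm_control})
    if count_case is not None and count_control is not None:
        keep = (count_case + count_control) >= min_coverage
        df = df[keep]
    df["log2fc"] = np.log2(df["cpm_case"] + pseudocount) - np.log2(df["cpm_control"] + pseudocount)
    df["direction"] = np.select(
        [df["log2fc"] > fc_cutoff, df["log2fc"] < -fc_cutoff],
        ["up", "down"], default="unchanged",
    )
    return df


# ---------------------------------------------------------------------------
# Kurtosis
# ---------------------------------------------------------------------------

def excess_kurtosis(
    values: Sequence[float],
    label: str = "",
    bias_corrected: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> FoldChangeSummary:
    """Fisher excess kurtosis m4/m2^2 - 3 on population moments (the
    default, appropriate at the large n of fold-change sets), with a
    seeded bootstrap 95% CI. ``bias_corrected`` switches to the
    small-sample unbiased estimator."""
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 values for kurtosis")
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance: kurtosis undefined for constant input")
    point = float(stats.kurtosis(x, fisher=True, bias=not bias_corrected))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant resamples yield NaN kurtosis
        boots = stats.kurtosis(x[idx], axis=1, fisher=True, bias=not bias_corrected)
    boots = boots[np.isfinite(boots)]
    if len(boots) == 0:
        raise ValueError("all bootstrap resamples degenerate; cannot form a CI")
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return FoldChangeSummary(label=label, n=len(x), excess_kurtosis=point,
                             bootstrap_ci=(float(lo), float(hi)))


# ---------------------------------------------------------------------------
# Label-permutation test for windowed region differences
# ---------------------------------------------------------------------------

@dataclass
class RegionTestResult:
    observed: float
    p_value: float
    n_case: int
    n_control: int
    n_permutations: int
    exact: bool
    alternative: str


def permutation_proportion_test(
    props_case: Sequence[float],
    props_control: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> RegionTestResult:
    """Label-permutation test on per-sample region proportions.

    Statistic: mean(case) - mean(control). When the number of distinct
    case/control label assignments is at most ``n_perm`` the test
    enumerates them all and the observed assignment counts itself (the
    exact analogue of the add-one convention, so p >= 1/N and never 0);
    otherwise ``n_perm`` random relabelings are drawn and
    p = (1 + #{permuted at least as extreme}) / (1 + n_perm).
    ``alternative`` is 'two-sided' (by absolute value), 'greater' or
    'less'.
    """
    a = np.asarray(props_case, dtype=float)
    b = np.asarray(props_control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per condition for a permutation test")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    n, n_case = len(pooled), len(a)
    observed = a.mean() - b.mean()

    n_distinct = math.comb(n, n_case)
    if n_distinct <= n_perm:
        idx = np.array(list(itertools.combinations(range(n), n_case)))
        case_sums = pooled[idx].sum(axis=1)
        stats_perm = case_sums / n_case - (pooled.sum() - case_sums) / (n - n_case)
        k = _count_extreme(stats_perm, observed, alternative)
        return RegionTestResult(float(observed), k / n_distinct, n_case, len(b),
                                n_distinct, True, alternative)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        s = perm[:n_case].mean() - perm[n_case:].mean()
        count += _is_extreme(s, observed, alternative)
    p = (1 + count) / (1 + n_perm)
    return RegionTestResult(float(observed), float(p), n_case, len(b),
                            n_perm, False, alternative)


def _count_extreme(stats_perm: np.ndarray, observed: float, alternative: str) -> int:
    if alternative == "two-sided":
        return int((np.abs(stats_perm) >= abs(observed) - 1e-12).sum())
    if alternative == "greater":
        return int((stats_perm >= observed - 1e-12).sum())
    return int((stats_perm <= observed + 1e-12).sum())


def _is_extreme(s: float, observed: float, alternative: str) -> bool:
    if alternative == "two-sided":
        return abs(s) >= abs(observed) - 1e-12
    if alternative == "greater":
        return s >= observed - 1e-12
    return s <= observed + 1e-12


def region_difference_test(
    profiles_case: Sequence[NucleotideProfile],
    profiles_control: Sequence[NucleotideProfile],
    window_1based: tuple[int, int],
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> RegionTestResult:
    """Permutation test of the 'proportion of total hits' in a window
    between conditions, computed from per-sample nucleotide profiles."""
    props_case = [region_proportion(p, window_1based).proportion_of_total_hits
                  for p in profiles_case]
    props_control = [region_proportion(p, window_1based).proportion_of_total_hits
                     for p in profiles_control]
    if any(math.isnan(x) for x in props_case + props_control):
        raise ValueError("a sample has no tags on this reference; proportion undefined")
    return permutation_proportion_test(props_case, props_control, n_perm, seed, alternative)
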