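"""Population-level statistics on per-cell count tables.

ON fractions (strict count thresholds), knockout percent reductions, Pearson
correlations, nearest-producer distances in the monolayer, and conditional
invariance of transcription-factor distributions across cytokine strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "AnalysisConfig",
    "on_fraction",
    "percent_reduction",
    "pearson",
    "nearest_producer_distance",
    "distance_correlation_check",
    "conditional_invariance",
    "timecourse_fraction_tf_correlation",
]


@dataclass
class AnalysisConfig:
    """Thresholds and filters of the count-table analysis.

    A cell is an Ifng producer above 20 transcripts and an Il4 producer above
    50 (strict inequalities); cells with polar radius r < 10 are excluded
    from θ statistics; counts at or beyond 200 are extrapolated from
    fluorescence.
    """

    ifng_on_threshold: int = 20
    il4_on_threshold: int = 50
    r_min: float = 10.0
    resolvable_max: int = 200
    no_correlation_cut: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ifng_on_threshold < 0 or self.il4_on_threshold < 0:
            raise ValueError("thresholds must be >= 0")


def on_fraction(counts: np.ndarray, threshold: float) -> float:
    """Fraction of cells strictly above ``threshold`` transcripts (a cell at
    exactly the threshold is OFF)."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("counts must be nonempty")
    return float(np.mean(counts > threshold))


def percent_reduction(mean_ref: float, mean_test: float, rounded: bool = True) -> float:
    """Percent reduction of a mean relative to a reference:
    100·(1 − mean_test/mean_ref), rounded to the nearest integer for
    reporting (e.g. 33 → 1.6 is a 95% reduction)."""
    if mean_ref <= 0:
        raise ValueError("mean_ref must be positive")
    pct = 100.0 * (1.0 - mean_test / mean_ref)
    return float(round(pct)) if rounded else float(pct)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("inputs must be nonconstant")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def nearest_producer_distance(
    positions_um: np.ndarray, counts: np.ndarray, threshold: float
) -> np.ndarray:
    """Distance (µm) from each cell's centroid to the nearest producer
    centroid, a producer being a cell with count > threshold.  Producers get
    distance 0 (they are their own nearest producer)."""
    positions_um = np.asarray(positions_um, dtype=float)
    counts = np.asarray(counts)
    producers = counts > threshold
    if not producers.any():
        raise ValueError("no producer cells above threshold")
    tree = cKDTree(positions_um[producers])
    d, _ = tree.query(positions_um)
    d = np.asarray(d, dtype=float)
    d[producers] = 0.0
    return d


def distance_correlation_check(
    tf_counts: np.ndarray, distances: np.ndarray, no_correlation_cut: float = 0.1
) -> dict:
    """Pearson correlation of TF count vs distance to the nearest producer,
    with a boolean 'no correlation' flag (|R| below the cut).

    A flat profile indicates the cytokine milieu is well mixed: diffusion
    from rare source cells is not rate-limiting."""
    r, p = pearson(tf_counts, distances)
    return {"R": r, "p": p, "no_correlation": bool(abs(r) < no_correlation_cut)}


DEFAULT_STRATA_EDGES = (1.0, 20.0, 100.0, 1000.0, np.inf)


def conditional_invariance(
    tf_counts: np.ndarray,
    cytokine_counts: np.ndarray,
    strata_edges: tuple = DEFAULT_STRATA_EDGES,
    min_stratum: int = 20,
    include_off_stratum: bool = True,
) -> dict:
    """Test whether the TF distribution is invariant across cytokine strata.

    Cells are binned by cytokine count into right-open strata between
    consecutive edges (a leading [0, first_edge) OFF stratum is included by
    default); all stratum pairs are compared by two-sample KS on the TF
    counts with Bonferroni adjustment.  Strata below ``min_stratum`` cells
    are dropped with a warning.

    Returns max D, min adjusted p, and the per-pair table.
    """
    tf_counts = np.asarray(tf_counts, dtype=float)
    cytokine_counts = np.asarray(cytokine_counts, dtype=float)
    edges = list(strata_edges)
    if include_off_stratum and edges[0] > 0:
        edges = [0.0] + edges
    strata = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (cytokine_counts >= lo) & (cytokine_counts < hi)
        if sel.sum() < min_stratum:
            if sel.sum() > 0:
                warnings.warn(
                    f"stratum [{lo}, {hi}) has {int(sel.sum())} < {min_stratum} cells; dropped",
                    stacklevel=2,
                )
            continue
        strata.append(((lo, hi), tf_counts[sel]))
    if len(strata) < 2:
        raise ValueError("need at least two adequately populated strata")

    pairs = []
    n_tests = len(list(combinations(range(len(strata)), 2)))
    for (ia, a), (ib, b) in combinations(enumerate(strata), 2):
        res = stats.ks_2samp(a[1], b[1], method="asymp")
        pairs.append(
            {
                "stratum_a": a[0],
                "stratum_b": b[0],
                "D": float(res.statistic),
                "p_adj": float(min(1.0, res.pvalue * n_tests)),
            }
        )
    return {
        "max_D": max(p["D"] for p in pairs),
        "min_p_adj": min(p["p_adj"] for p in pairs),
        "pairs": pairs,
        "invariant": bool(min(p["p_adj"] for p in pairs) > 0.01),
    }


def timecourse_fraction_tf_correlation(
    fractions_by_time: np.ndarray, mean_tf_by_time: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation over time points of the cytokine ON-fraction with
    the mean TF level (per-time-point means)."""
    f = np.asarray(fractions_by_time, dtype=float)
    m = np.asarray(mean_tf_by_time, dtype=float)
    if f.size < 3:
        raise ValueError("need >= 3 time points")
    return pearson(f, m)
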