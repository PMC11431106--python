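"""Information-theoretic pattern separation measures.

Three estimators operating on spike-time ensembles:

* estimated mutual information, a nearest-neighbor
  (Kozachenko-Leonenko-style) estimator over Wasserstein distances
  between equal-duration pattern segments;
* transfer entropy, a plug-in conditional-mutual-information estimate on
  the binned binary representation;
* relative redundancy reduction, the change in within-pattern redundancy
  between two patterns normalized by their estimated mutual information.

All estimators are deterministic functions of their inputs and the
:class:`EstimatorConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import wasserstein_distance

from .indices_classic import IndexValue
from .patterns import BinaryPattern, SpikeTrainEnsemble

__all__ = [
    "EstimatorConfig",
    "SegmentedPattern",
    "segment_pattern",
    "wasserstein_segment_distance",
    "segment_distance_table",
    "estimated_mi",
    "mi_from_tables",
    "transfer_entropy",
    "binarize",
    "redundancy",
    "redundancy_reduction",
]


@dataclass(frozen=True)
class EstimatorConfig:
    """Tunables of the information-theoretic estimators.

    n_periods
        Number N of equal-duration segments each pattern is cut into for
        the nearest-neighbor mutual-information estimator.
    h
        Smoothing integer, the nearest-neighbor order (1 <= h < N).
    k
        Transfer-entropy history length in bins.
    log_base
        Base of the logarithm for the mutual-information estimate
        ("e" for nats, 2 for bits).  Transfer entropy is always in bits.
    """

    n_periods: int = 50
    h: int = 3
    k: int = 1
    log_base: float | str = "e"

    def __post_init__(self):
        if not 1 <= self.h < self.n_periods:
            raise ValueError("smoothing parameter must satisfy 1 <= h < N")
        if self.k < 1:
            raise ValueError("history length k must be >= 1")

    def _log(self, x: np.ndarray) -> np.ndarray:
        if self.log_base in ("e", math.e):
            return np.log(x)
        return np.log(x) / math.log(float(self.log_base))


@dataclass(frozen=True)
class SegmentedPattern:
    """A spike ensemble cut into N consecutive equal-duration periods.

    ``segments[i][p]`` holds neuron i's spike times in period p,
    re-referenced to the period start; concatenating the periods (with
    offsets restored) recovers the original ensemble.
    """

    segments: tuple[tuple[np.ndarray, ...], ...]
    period_length: float

    @property
    def n_periods(self) -> int:
        return len(self.segments[0])

    @property
    def n_neurons(self) -> int:
        return len(self.segments)


def segment_pattern(ens: SpikeTrainEnsemble, n_periods: int) -> SegmentedPattern:
    """Cut each train into ``n_periods`` equal periods of tau / N ms."""
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    length = ens.tau / n_periods
    per_neuron = []
    for train in ens.trains:
        idx = np.minimum((train / length).astype(int), n_periods - 1)
        per_neuron.append(
            tuple(train[idx == p] - p * length for p in range(n_periods))
        )
    return SegmentedPattern(tuple(per_neuron), length)


def wasserstein_segment_distance(
    a: np.ndarray, b: np.ndarray, period_length: float
) -> float:
    """W1 distance between the spike-time empirical measures of two segments.

    Each train carries unit total mass (1/n per spike); for equal counts
    this is the mean absolute difference of the sorted times.  An empty
    segment against a non-empty one is assigned the maximal displacement,
    the period length; two empty segments are at distance 0.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 and b.size == 0:
        return 0.0
    if a.size == 0 or b.size == 0:
        return float(period_length)
    if a.size == b.size:
        return float(np.abs(a - b).mean())  # monotone matching of sorted lists
    return float(wasserstein_distance(a, b))


def segment_distance_table(seg: SegmentedPattern) -> np.ndarray:
    """Pairwise N x N segment distances, summed over neurons."""
    n = seg.n_periods
    table = np.zeros((n, n))
    for neuron in seg.segments:
        for i in range(n):
            for j in range(i + 1, n):
                d = wasserstein_segment_distance(
                    neuron[i], neuron[j], seg.period_length
                )
                table[i, j] += d
                table[j, i] += d
    return table


def _neighborhoods(table: np.ndarray, h: int) -> list[set[int]]:
    """Per segment: itself plus its h-1 nearest other segments.

    Ordering is lexicographic in (distance, segment index), which breaks
    the exact ties that bin-center spike times make common; the h-th
    entry of that ordering is the h-th nearest-neighbor distance
    delta_h.  Including the segment itself keeps the pair count C >= 1,
    so the estimator never diverges, and makes identical patterns give
    exactly log(N / h).
    """
    n = table.shape[0]
    hoods = []
    for i in range(n):
        others = np.delete(np.arange(n), i)
        order = others[np.lexsort((others, table[i, others]))]
        hoods.append({i, *order[: h - 1].tolist()})
    return hoods


def mi_from_tables(
    d1: np.ndarray, d2: np.ndarray, cfg: EstimatorConfig
) -> float:
    """Nearest-neighbor MI estimate from two segment-distance tables.

    C_i counts the segments j lying in the joint h-neighborhood of
    segment i in both patterns (self-pair included); the estimate is the
    average of log(N * C_i / h^2).
    """
    n = d1.shape[0]
    if n < 2:
        raise ValueError("need at least 2 periods")
    q1 = _neighborhoods(d1, cfg.h)
    q2 = _neighborhoods(d2, cfg.h)
    counts = np.array([len(a & b) for a, b in zip(q1, q2)], float)
    return float(np.mean(cfg._log(n * counts / cfg.h**2)))


def estimated_mi(
    t1: SpikeTrainEnsemble, t2: SpikeTrainEnsemble, cfg: EstimatorConfig
) -> float:
    """Estimated mutual information between two patterns.

    Both patterns are segmented into N periods; segment distances are
    per-neuron Wasserstein distances summed over neurons, so multi-neuron
    ensembles are treated jointly.  The estimator is biased but exactly
    symmetric in its arguments, and bounded above by log(N^2 / h^2).
    """
    s1 = segment_pattern(t1, cfg.n_periods)
    s2 = segment_pattern(t2, cfg.n_periods)
    return mi_from_tables(
        segment_distance_table(s1), segment_distance_table(s2), cfg
    )


# --- transfer entropy -------------------------------------------------------

def binarize(ens: SpikeTrainEnsemble, n_bins: int) -> BinaryPattern:
    """Bin a spike ensemble: a bin is active if it contains any spike."""
    width = ens.tau / n_bins
    m = np.zeros((ens.n_neurons, n_bins), dtype=np.int8)
    for i, train in enumerate(ens.trains):
        idx = np.minimum((train / width).astype(int), n_bins - 1)
        m[i, idx] = 1
    return BinaryPattern(m)


def _symbols(p: BinaryPattern) -> np.ndarray:
    """Per-bin joint state of the pattern as an integer code."""
    weights = 1 << np.arange(p.n_neurons)
    return (weights[:, None] * p.matrix).sum(axis=0)


def _entropy_bits(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    f = counts / counts.sum()
    return float(-(f * np.log2(f)).sum())


def transfer_entropy(
    source, target, cfg: EstimatorConfig, n_bins: int | None = None
) -> float:
    """Plug-in transfer entropy source -> target, in bits.

    Works on the binned binary representation: for each time bin t the
    joint empirical frequencies of (target state at t, target history of
    k bins, source history of k bins) give

        dT = H(Y_t | Y_hist) - H(Y_t | Y_hist, X_hist).

    Directional: swapping the arguments changes the value.  Inputs may be
    binary patterns/arrays or spike ensembles (then ``n_bins`` is
    required to bin them).  Always non-negative, as a plug-in conditional
    mutual information.
    """

    def to_pattern(x):
        if isinstance(x, SpikeTrainEnsemble):
            if n_bins is None:
                raise ValueError("n_bins required to bin spike ensembles")
            return binarize(x, n_bins)
        if isinstance(x, BinaryPattern):
            return x
        return BinaryPattern(np.atleast_2d(np.asarray(x, dtype=np.int8)))

    ps, pt = to_pattern(source), to_pattern(target)
    if ps.n_bins != pt.n_bins:
        raise ValueError("source and target must share Nbins")
    k = cfg.k
    if ps.n_bins <= k:
        raise ValueError("Nbins must exceed the history length k")
    xs, ys = _symbols(ps), _symbols(pt)
    base = int(max(xs.max(), ys.max())) + 1

    def hist_codes(sym):
        # code of the k-bin history ending just before t, for t = k..T-1
        n = sym.size - k
        code = np.zeros(n, dtype=np.int64)
        for lag in range(1, k + 1):
            code = code * base + sym[k - lag : k - lag + n]
        return code

    y_now = ys[k:].astype(np.int64)
    y_hist = hist_codes(ys)
    x_hist = hist_codes(xs)
    span = int(max(y_hist.max(), x_hist.max())) + 1
    h_y_given_own = _entropy_bits(y_now * span + y_hist) - _entropy_bits(y_hist)
    joint_hist = y_hist * span + x_hist
    h_y_given_both = _entropy_bits(
        y_now * span * span + joint_hist
    ) - _entropy_bits(joint_hist)
    return max(h_y_given_own - h_y_given_both, 0.0)


# --- redundancy --------------------------------------------------------------

def redundancy(t: SpikeTrainEnsemble, cfg: EstimatorConfig) -> float:
    """Within-pattern redundancy R(T) = min_i MI(T without i, T_i)."""
    if t.n_neurons < 2:
        raise ValueError("redundancy needs at least 2 neurons")
    seg = segment_pattern(t, cfg.n_periods)
    tables = [
        segment_distance_table(
            SegmentedPattern((neuron,), seg.period_length)
        )
        for neuron in seg.segments
    ]
    total = sum(tables)
    vals = []
    for i in range(t.n_neurons):
        rest = total - tables[i]  # ensemble with neuron i removed
        vals.append(mi_from_tables(rest, tables[i], cfg))
    return float(min(vals))


def redundancy_reduction(
    t1: SpikeTrainEnsemble, t2: SpikeTrainEnsemble, cfg: EstimatorConfig
) -> IndexValue:
    """Relative redundancy reduction (R(T1) - R(T2)) / MI(T1, T2).

    Undefined (invalid flag) when the estimated mutual information in the
    denominator is zero.
    """
    denom = estimated_mi(t1, t2, cfg)
    if denom == 0.0:
        return IndexValue("rr", math.nan, valid=False)
    num = redundancy(t1, cfg) - redundancy(t2, cfg)
    return IndexValue("rr", num / denom)
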