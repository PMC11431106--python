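"""Non-information-theoretic spike-pattern similarity indices.

Five indices commonly used in pattern-separation research:

* Pearson correlation and cosine similarity of the vectorized binary
  patterns (range [-1, 1] and [0, 1] on binary data);
* scaling factor, the ratio of the two vector norms;
* a time-resolved Hamming distance, the mean absolute bin-wise
  difference over all neurons and bins (inactive rows are kept);
* SPIKE similarity, one minus the time average of the Kreuz bivariate
  dissimilarity profile D(t), averaged over neurons.

Undefined cases (zero variance, zero norm) return an IndexValue with the
``valid`` flag cleared rather than raising, so sweep aggregation can skip
them explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .patterns import BinaryPattern, SpikeTrainEnsemble

__all__ = [
    "IndexValue",
    "pearson",
    "cosine",
    "scaling_factor",
    "hamming",
    "spike_similarity",
    "spike_dissimilarity_profile",
]


@dataclass(frozen=True)
class IndexValue:
    """A named scalar index with an explicit validity flag."""

    name: str
    value: float
    valid: bool = True

    def __float__(self) -> float:
        return self.value


def _as_vec(x) -> np.ndarray:
    v = np.asarray(x, float).reshape(-1)
    return v


def pearson(x1, x2) -> IndexValue:
    """Pearson correlation of two equal-length vectors (sample moments).

    Expectations are plain means over entries; a zero-variance input makes
    the index undefined (invalid flag).
    """
    a, b = _as_vec(x1), _as_vec(x2)
    if a.size != b.size or a.size < 2:
        raise ValueError("inputs must share a length of at least 2")
    va = np.mean(a * a) - np.mean(a) ** 2
    vb = np.mean(b * b) - np.mean(b) ** 2
    if va <= 0 or vb <= 0:
        return IndexValue("pearson", math.nan, valid=False)
    cov = np.mean(a * b) - np.mean(a) * np.mean(b)
    return IndexValue("pearson", float(cov / math.sqrt(va * vb)))


def cosine(x1, x2) -> IndexValue:
    """Normalized dot product of two equal-length vectors."""
    a, b = _as_vec(x1), _as_vec(x2)
    if a.size != b.size:
        raise ValueError("inputs must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return IndexValue("cosine", math.nan, valid=False)
    return IndexValue("cosine", float(a @ b / (na * nb)))


def scaling_factor(x1, x2) -> IndexValue:
    """Ratio of Euclidean norms ||x1|| / ||x2||."""
    a, b = _as_vec(x1), _as_vec(x2)
    if a.size != b.size:
        raise ValueError("inputs must have equal length")
    nb = np.linalg.norm(b)
    if nb == 0:
        return IndexValue("scaling", math.nan, valid=False)
    return IndexValue("scaling", float(np.linalg.norm(a) / nb))


def hamming(p1: BinaryPattern, p2: BinaryPattern) -> IndexValue:
    """Mean absolute bin-wise difference over all neurons and bins.

    Permanently inactive rows are never removed, so the value is always
    the raw disagreement fraction in [0, 1].
    """
    if p1.matrix.shape != p2.matrix.shape:
        raise ValueError("patterns must have matching shapes")
    d = np.abs(p1.matrix.astype(int) - p2.matrix.astype(int)).mean()
    return IndexValue("hamming", float(d))


# --- SPIKE similarity ------------------------------------------------------

def _augment(train: np.ndarray, tau: float) -> np.ndarray:
    """Add auxiliary spikes at 0 and tau (deduplicated).

    The bivariate profile needs a preceding and following spike at every
    observation time; edge spikes are the convention of the original
    SPIKE-distance literature and make empty trains well defined.
    """
    return np.unique(np.concatenate(([0.0], train, [tau])))


def _nearest_dist(spikes: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Distance from each time in t to the nearest element of spikes."""
    idx = np.searchsorted(spikes, t)
    left = spikes[np.clip(idx - 1, 0, spikes.size - 1)]
    right = spikes[np.clip(idx, 0, spikes.size - 1)]
    return np.minimum(np.abs(t - left), np.abs(right - t))


def spike_dissimilarity_profile(
    a: np.ndarray, b: np.ndarray, tau: float, t: np.ndarray
) -> np.ndarray:
    """Kreuz bivariate dissimilarity profile D(t) for two spike trains.

    Both trains are augmented with edge spikes at 0 and tau.  At each
    observation time the preceding/following spikes give the local
    interval x_ISI, the offsets x_P, x_F, and the distances dt_P, dt_F
    from those corner spikes to the nearest spike of the other train;

        S^(n) = (dt_P x_F + dt_F x_P) / x_ISI
        D = (S^(1) x_ISI^(2) + S^(2) x_ISI^(1)) / (2 <x_ISI>^2)

    with <x_ISI> the mean of the two instantaneous intervals.  D vanishes
    identically for identical trains.
    """
    aa, bb = _augment(np.asarray(a, float), tau), _augment(np.asarray(b, float), tau)
    out = []
    for mine, other in ((aa, bb), (bb, aa)):
        # preceding spike: max{s <= t}; following: min{s > t}
        ip = np.searchsorted(mine, t, side="right") - 1
        ip = np.clip(ip, 0, mine.size - 2)
        tp, tf = mine[ip], mine[ip + 1]
        x_isi = tf - tp
        x_p, x_f = t - tp, tf - t
        dt_p = _nearest_dist(other, tp)
        dt_f = _nearest_dist(other, tf)
        s = (dt_p * x_f + dt_f * x_p) / x_isi
        out.append((s, x_isi))
    (s1, isi1), (s2, isi2) = out
    mean_isi = 0.5 * (isi1 + isi2)
    return (s1 * isi2 + s2 * isi1) / (2.0 * mean_isi**2)


def spike_similarity(
    t1: SpikeTrainEnsemble,
    t2: SpikeTrainEnsemble,
    n_grid: int = 16000,
) -> IndexValue:
    """SPIKE similarity averaged over neurons.

    Per neuron, 1 - (1/tau) * integral of D(t) over [0, tau]; the
    integral uses the midpoint rule on a uniform grid of ``n_grid``
    points, which avoids evaluating D exactly at spike times (D is
    piecewise smooth between spikes).  Identical ensembles give exactly 1;
    a pair of empty trains likewise (their profiles vanish).
    """
    if t1.n_neurons != t2.n_neurons:
        raise ValueError("ensembles must have the same neuron count")
    if abs(t1.tau - t2.tau) > 1e-9:
        raise ValueError("ensembles must share the observation window")
    tau = t1.tau
    t = (np.arange(n_grid) + 0.5) * (tau / n_grid)
    vals = []
    for a, b in zip(t1.trains, t2.trains):
        d = spike_dissimilarity_profile(a, b, tau, t)
        vals.append(1.0 - float(d.mean()))
    return IndexValue("spike", float(np.mean(vals)))
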