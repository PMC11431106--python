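"""Pattern sampling, representations and sweep construction.

A sampled neural pattern is a 2 x Nbins binary matrix: each column is one
time bin drawn i.i.d. from the categorical law {q00, q10, q01, q11}.
Patterns convert to spike-time ensembles by placing one timestamp per
active bin inside a [0, tau] ms observation window (tau = 16 ms by
default, matching the evaluation protocol).

The two sweep constructors build the control/comparison distribution
pairs used in the index-evaluation experiments:

* the d_theta sweep holds both marginals fixed (eta2 = 1 - eta1) and
  moves probability mass between the coincident outcomes (00, 11) and the
  single-neuron outcomes (10, 01), spanning near-maximal anti-correlation
  to near-maximal correlation;
* the d_eta2 sweep holds theta = 0 (independent neurons, q11 = eta1*eta2)
  and raises neuron 2's marginal rate from a sparse 0.1 baseline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .manifold import Coordinates, JointLaw, law_of, theta_of

__all__ = [
    "BinaryPattern",
    "SpikeTrainEnsemble",
    "PatternPair",
    "SweepSpec",
    "DEFAULT_TAU_MS",
    "DEFAULT_N_BINS",
    "DEFAULT_N_TRIALS",
    "sample_pattern",
    "vectorize",
    "to_spike_times",
    "sample_pair",
    "build_dtheta_sweep",
    "build_deta_sweep",
    "read_spike_trains",
    "write_spike_trains",
    "read_pattern_csv",
    "write_pattern_csv",
]

DEFAULT_TAU_MS = 16.0
DEFAULT_N_BINS = 1000
DEFAULT_N_TRIALS = 10

#: q11 kept this far inside its feasible interval at the sweep ends
SWEEP_EDGE = 1e-2


@dataclass(frozen=True)
class BinaryPattern:
    """Binary activity matrix, neurons as rows, time bins as columns."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.int8)
        if m.ndim != 2 or m.shape[1] < 1:
            raise ValueError("pattern must be a 2-D matrix with >= 1 bin")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("pattern entries must be 0/1")
        object.__setattr__(self, "matrix", m)

    @property
    def n_neurons(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class SpikeTrainEnsemble:
    """Per-neuron ordered spike times (ms) within an observation window."""

    trains: tuple[np.ndarray, ...]
    tau: float = DEFAULT_TAU_MS

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("window length tau must be positive")
        clean = []
        for t in self.trains:
            t = np.asarray(t, float)
            if t.ndim != 1:
                raise ValueError("each train must be a 1-D array of times")
            if t.size and (np.any(np.diff(t) <= 0)):
                raise ValueError("spike times must be strictly increasing")
            if t.size and (t[0] < 0 or t[-1] > self.tau):
                raise ValueError(f"spike times must lie in [0, {self.tau}]")
            clean.append(t)
        object.__setattr__(self, "trains", tuple(clean))

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    def counts(self) -> list[int]:
        return [t.size for t in self.trains]


@dataclass(frozen=True)
class PatternPair:
    """A control/comparison draw with the coordinates that generated it."""

    control: BinaryPattern
    comparison: BinaryPattern
    control_coords: Coordinates
    comparison_coords: Coordinates
    tau: float = DEFAULT_TAU_MS

    def __post_init__(self):
        if self.control.n_bins != self.comparison.n_bins:
            raise ValueError("pair members must share Nbins")

    def spike_ensembles(self) -> tuple[SpikeTrainEnsemble, SpikeTrainEnsemble]:
        return (
            to_spike_times(self.control, self.tau),
            to_spike_times(self.comparison, self.tau),
        )


@dataclass(frozen=True)
class SweepSpec:
    """One sweep experiment: a control law and a grid of comparisons."""

    kind: str  # "dtheta" | "deta2"
    eta1: float
    control: Coordinates
    comparisons: tuple[Coordinates, ...]
    increments: tuple[float, ...]  # d_theta or d_eta2 per grid point
    n_bins: int = DEFAULT_N_BINS
    n_trials: int = DEFAULT_N_TRIALS
    tau: float = DEFAULT_TAU_MS
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("dtheta", "deta2"):
            raise ValueError(f"unknown sweep kind {self.kind!r}")
        if len(self.comparisons) != len(self.increments):
            raise ValueError("one increment per comparison point required")
        for c in self.comparisons:
            law_of(c)  # raises if any grid point is infeasible

    def trial_seed(self, point: int, trial: int) -> int:
        """Deterministic child seed for one (grid point, trial) draw.

        Derived through numpy's SeedSequence spawning so any single trial
        is reproducible in isolation from (seed, point, trial).
        """
        ss = np.random.SeedSequence(self.seed, spawn_key=(point, trial))
        return int(ss.generate_state(1, np.uint32)[0])

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "eta1": self.eta1,
                "control": json.loads(self.control.to_json()),
                "comparisons": [
                    json.loads(c.to_json()) for c in self.comparisons
                ],
                "increments": list(self.increments),
                "n_bins": self.n_bins,
                "n_trials": self.n_trials,
                "tau": self.tau,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "SweepSpec":
        d = json.loads(s)
        return cls(
            kind=d["kind"],
            eta1=d["eta1"],
            control=Coordinates(**d["control"]),
            comparisons=tuple(Coordinates(**c) for c in d["comparisons"]),
            increments=tuple(d["increments"]),
            n_bins=d["n_bins"],
            n_trials=d["n_trials"],
            tau=d["tau"],
            seed=d["seed"],
        )


def sample_pattern(
    q: JointLaw, n_bins: int, rng_seed: int | np.random.Generator
) -> BinaryPattern:
    """Draw a 2 x n_bins pattern, each column i.i.d. categorical under q."""
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    # outcome order (00, 10, 01, 11): bit 1 = neuron 1, bit 2 = neuron 2
    outcome = rng.choice(4, size=n_bins, p=q.as_array())
    x1 = np.isin(outcome, (1, 3)).astype(np.int8)
    x2 = np.isin(outcome, (2, 3)).astype(np.int8)
    return BinaryPattern(np.vstack([x1, x2]))


def vectorize(p: BinaryPattern) -> np.ndarray:
    """Flatten to [x_11..x_1Nbins, x_21..x_2Nbins, ...] (vec of the transpose)."""
    return p.matrix.reshape(-1).copy()


def to_spike_times(
    p: BinaryPattern, tau: float = DEFAULT_TAU_MS, placement: str = "center"
) -> SpikeTrainEnsemble:
    """Convert active bins to timestamps inside [0, tau].

    Each active bin j contributes one spike at the bin center
    (j + 0.5) * tau / Nbins (or the left edge j * tau / Nbins with
    placement="edge").
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if placement not in ("center", "edge"):
        raise ValueError("placement must be 'center' or 'edge'")
    width = tau / p.n_bins
    off = 0.5 * width if placement == "center" else 0.0
    trains = tuple(
        np.flatnonzero(row).astype(float) * width + off for row in p.matrix
    )
    return SpikeTrainEnsemble(trains, tau=tau)


def sample_pair(
    control: Coordinates,
    comparison: Coordinates,
    n_bins: int,
    rng_seed: int | np.random.Generator,
    tau: float = DEFAULT_TAU_MS,
) -> PatternPair:
    """Draw one fresh control/comparison pattern pair."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return PatternPair(
        control=sample_pattern(law_of(control), n_bins, rng),
        comparison=sample_pattern(law_of(comparison), n_bins, rng),
        control_coords=control,
        comparison_coords=comparison,
        tau=tau,
    )


def build_dtheta_sweep(
    eta1: float,
    grid_size: int = 21,
    n_bins: int = DEFAULT_N_BINS,
    n_trials: int = DEFAULT_N_TRIALS,
    tau: float = DEFAULT_TAU_MS,
    seed: int = 0,
) -> SweepSpec:
    """Correlation sweep at fixed marginals (eta2 = 1 - eta1 >= eta1).

    The control law is the independent one (theta = 0); comparisons shift
    mass dq11 from the single-neuron outcomes onto both coincident
    outcomes (q00 and q11 move together because eta1 + eta2 = 1), leaving
    the marginals untouched.  The grid spans q11 in
    [SWEEP_EDGE, eta1 - SWEEP_EDGE]: the lower end is nearly maximal
    anti-correlation (q11 = q00 = 0.01), the upper end nearly maximal
    correlation (q10 = q01 = 0.01).
    """
    if not 0 < eta1 <= 0.5:
        raise ValueError(
            "eta1 must lie in (0, 0.5] so that eta2 = 1 - eta1 >= eta1"
        )
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    eta2 = 1.0 - eta1
    control = Coordinates(eta1, eta2, 0.0)
    lo, hi = SWEEP_EDGE, eta1 - SWEEP_EDGE
    if hi <= lo:
        raise ValueError(f"eta1 = {eta1} leaves no feasible q11 grid")
    comparisons, increments = [], []
    for q11 in np.linspace(lo, hi, grid_size):
        q10 = eta1 - q11
        q01 = eta2 - q11
        q00 = 1.0 - eta1 - eta2 + q11
        law = JointLaw(q00, q10, q01, q11)
        dtheta = theta_of(law)  # control theta is 0
        comparisons.append(Coordinates(eta1, eta2, dtheta))
        increments.append(dtheta)
    return SweepSpec(
        kind="dtheta",
        eta1=eta1,
        control=control,
        comparisons=tuple(comparisons),
        increments=tuple(increments),
        n_bins=n_bins,
        n_trials=n_trials,
        tau=tau,
        seed=seed,
    )


def build_deta_sweep(
    eta1: float,
    grid: np.ndarray | int = 17,
    eta2_base: float = 0.1,
    n_bins: int = DEFAULT_N_BINS,
    n_trials: int = DEFAULT_N_TRIALS,
    tau: float = DEFAULT_TAU_MS,
    seed: int = 0,
) -> SweepSpec:
    """Rate sweep of neuron 2 at theta = 0 (independent neurons).

    Control is (eta1, eta2_base, 0); comparisons raise eta2 by d_eta2.
    An integer ``grid`` requests that many evenly spaced d_eta2 values in
    [0, 0.8]; an array gives the increments directly.
    """
    if not 0 < eta1 < 1:
        raise ValueError("eta1 must lie in (0, 1)")
    if isinstance(grid, (int, np.integer)):
        grid = np.linspace(0.0, 0.8, int(grid))
    grid = np.asarray(grid, float)
    if np.any(eta2_base + grid >= 1.0) or np.any(eta2_base + grid <= 0.0):
        raise ValueError("eta2_base + d_eta2 must stay inside (0, 1)")
    control = Coordinates(eta1, eta2_base, 0.0)
    comparisons = tuple(
        Coordinates(eta1, eta2_base + d, 0.0) for d in grid
    )
    return SweepSpec(
        kind="deta2",
        eta1=eta1,
        control=control,
        comparisons=comparisons,
        increments=tuple(float(d) for d in grid),
        n_bins=n_bins,
        n_trials=n_trials,
        tau=tau,
        seed=seed,
    )


# --- plain-text I/O -------------------------------------------------------

def write_spike_trains(ens: SpikeTrainEnsemble, path: str | Path) -> None:
    """One line per neuron: whitespace-separated ascending times in ms."""
    lines = [" ".join(f"{t:.10g}" for t in train) for train in ens.trains]
    Path(path).write_text("\n".join(lines) + "\n")


def read_spike_trains(
    path: str | Path, tau: float = DEFAULT_TAU_MS
) -> SpikeTrainEnsemble:
    trains = []
    for line in Path(path).read_text().splitlines():
        vals = np.array([float(v) for v in line.split()], float)
        trains.append(vals)
    if not trains:
        raise ValueError(f"no spike trains found in {path}")
    inferred = max((t[-1] for t in trains if t.size), default=0.0)
    return SpikeTrainEnsemble(tuple(trains), tau=max(tau, inferred))


def write_pattern_csv(p: BinaryPattern, path: str | Path) -> None:
    """CSV of 0/1 with neurons as rows."""
    np.savetxt(path, p.matrix, fmt="%d", delimiter=",")


def read_pattern_csv(path: str | Path) -> BinaryPattern:
    m = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
    return BinaryPattern(m)
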