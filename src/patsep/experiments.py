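"""Sweep experiments: apply all eight indices to sampled pattern pairs.

For every grid point of a sweep, ``run_sweep`` draws ``n_trials``
independent control/comparison pattern pairs (the control is re-sampled
each trial, so both members carry trial-to-trial variability), computes
the eight indices on each pair, and aggregates mean and standard error
of the mean per index.  ``summarize_trends`` then condenses a sweep into
one rank correlation (with a permutation p-value) per index, which is how
the qualitative claims — classic indices flat in d_theta, Hamming rising
and SPIKE/scaling falling in d_eta2 — are checked.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import indices_classic as ic
from . import indices_info as ii
from .indices_info import EstimatorConfig
from .patterns import (
    PatternPair,
    SweepSpec,
    sample_pair,
    to_spike_times,
    vectorize,
)

__all__ = [
    "INDEX_NAMES",
    "SweepResult",
    "run_sweep",
    "compute_pair_indices",
    "write_results",
    "read_results",
    "summarize_trends",
]

logger = logging.getLogger("patsep")

#: canonical index order: classic indices then information-theoretic ones
INDEX_NAMES = (
    "pearson",
    "cosine",
    "hamming",
    "spike",
    "scaling",
    "mi",
    "te",
    "rr",
)


@dataclass(frozen=True)
class SweepResult:
    """Aggregated sweep output.

    ``table`` has one row per grid point with columns ``kind``, ``eta1``,
    ``increment`` and, per index, ``<name>_mean``, ``<name>_sem``,
    ``<name>_n`` (valid-trial count).  ``provenance`` records the sweep
    spec and estimator configuration needed to regenerate it.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def compute_pair_indices(
    pair: PatternPair, cfg: EstimatorConfig, n_grid: int | None = None
) -> dict[str, ic.IndexValue]:
    """All eight indices for one control/comparison pattern pair.

    The expensive per-neuron segment-distance tables are built once per
    pattern and shared between the mutual-information, redundancy and
    redundancy-reduction estimates.
    """
    v1, v2 = vectorize(pair.control), vectorize(pair.comparison)
    t1 = to_spike_times(pair.control, pair.tau)
    t2 = to_spike_times(pair.comparison, pair.tau)
    if n_grid is None:
        n_grid = 16 * pair.control.n_bins

    out = {
        "pearson": ic.pearson(v1, v2),
        "cosine": ic.cosine(v1, v2),
        "scaling": ic.scaling_factor(v1, v2),
        "hamming": ic.hamming(pair.control, pair.comparison),
        "spike": ic.spike_similarity(t1, t2, n_grid=n_grid),
    }

    # shared per-neuron distance tables
    def neuron_tables(ens):
        seg = ii.segment_pattern(ens, cfg.n_periods)
        return [
            ii.segment_distance_table(
                ii.SegmentedPattern((neuron,), seg.period_length)
            )
            for neuron in seg.segments
        ]

    tabs1, tabs2 = neuron_tables(t1), neuron_tables(t2)
    total1, total2 = sum(tabs1), sum(tabs2)
    mi = ii.mi_from_tables(total1, total2, cfg)
    out["mi"] = ic.IndexValue("mi", mi)
    out["te"] = ic.IndexValue(
        "te", ii.transfer_entropy(pair.control, pair.comparison, cfg)
    )

    def redundancy_from(tabs, total):
        return min(
            ii.mi_from_tables(total - t, t, cfg) for t in tabs
        )

    if mi == 0.0:
        out["rr"] = ic.IndexValue("rr", float("nan"), valid=False)
    else:
        r1 = redundancy_from(tabs1, total1)
        r2 = redundancy_from(tabs2, total2)
        out["rr"] = ic.IndexValue("rr", (r1 - r2) / mi)
    return out


def run_sweep(
    spec: SweepSpec, cfg: EstimatorConfig | None = None
) -> SweepResult:
    """Run one sweep experiment; deterministic given the sweep's seed.

    Invalid index evaluations (undefined Pearson/cosine/scaling on
    degenerate draws, zero-MI denominators) are excluded from the
    aggregates with the valid-trial count decremented and a warning
    logged — never silently imputed.
    """
    cfg = cfg or EstimatorConfig()
    rows = []
    n_invalid = 0
    for p_idx, (comparison, inc) in enumerate(
        zip(spec.comparisons, spec.increments)
    ):
        samples: dict[str, list[float]] = {k: [] for k in INDEX_NAMES}
        for trial in range(spec.n_trials):
            pair = sample_pair(
                spec.control,
                comparison,
                spec.n_bins,
                spec.trial_seed(p_idx, trial),
                tau=spec.tau,
            )
            for name, val in compute_pair_indices(pair, cfg).items():
                if val.valid:
                    samples[name].append(val.value)
                else:
                    n_invalid += 1
                    logger.warning(
                        "invalid %s at point %d trial %d (excluded)",
                        name,
                        p_idx,
                        trial,
                    )
        row = {"kind": spec.kind, "eta1": spec.eta1, "increment": inc}
        for name in INDEX_NAMES:
            vals = np.array(samples[name])
            n = vals.size
            row[f"{name}_mean"] = float(vals.mean()) if n else float("nan")
            row[f"{name}_sem"] = (
                float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            )
            row[f"{name}_n"] = n
        rows.append(row)
    if n_invalid:
        logger.warning("%d invalid index evaluations excluded", n_invalid)
    provenance = {
        "spec": json.loads(spec.to_json()),
        "estimator": {
            "n_periods": cfg.n_periods,
            "h": cfg.h,
            "k": cfg.k,
            "log_base": str(cfg.log_base),
        },
        "indices": list(INDEX_NAMES),
    }
    return SweepResult(pd.DataFrame(rows), provenance)


def write_results(result: SweepResult, path: str | Path) -> None:
    """CSV of the aggregate table plus a JSON provenance sidecar."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    result.table.to_csv(path, index=False)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(result.provenance, indent=2)
    )


def read_results(path: str | Path) -> SweepResult:
    path = Path(path)
    table = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return SweepResult(table, provenance)


def summarize_trends(
    result: SweepResult, n_permutations: int = 5000, seed: int = 0
) -> pd.DataFrame:
    """Rank correlation of each index mean against the sweep increment.

    Returns one row per index with the Spearman rank correlation and a
    two-sided permutation p-value (increment order shuffled).  A constant
    index column is flagged undefined rather than given a correlation.
    """
    table = result.table
    if len(table) < 3:
        raise ValueError("need at least 3 grid points to summarize trends")
    rng = np.random.default_rng(seed)
    inc = table["increment"].to_numpy()
    rows = []
    for name in INDEX_NAMES:
        means = table[f"{name}_mean"].to_numpy()
        ok = np.isfinite(means)
        if ok.sum() < 3 or np.ptp(means[ok]) == 0:
            rows.append(
                {"index": name, "rho": float("nan"), "p_value": float("nan"),
                 "defined": False}
            )
            continue
        rho = spearmanr(inc[ok], means[ok]).statistic
        null = np.empty(n_permutations)
        m = means[ok]
        x = inc[ok]
        for b in range(n_permutations):
            null[b] = spearmanr(x, rng.permutation(m)).statistic
        p = float((np.abs(null) >= abs(rho) - 1e-12).mean())
        rows.append({"index": name, "rho": float(rho), "p_value": p,
                     "defined": True})
    return pd.DataFrame(rows).set_index("index")
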