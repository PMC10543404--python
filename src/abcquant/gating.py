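"""Fluorescence gating: per-channel positive/negative calls and joint
probe-pattern counts.

Auto-thresholding uses an exact two-center 1-D partitioning per channel
(the optimal k=2 split of the sorted intensities, found by minimizing
within-cluster sum of squares) with the threshold at the midpoint of the two
cluster centers.  Channels whose two candidate centers are not separated by
at least 3 pooled within-cluster standard deviations are degenerate
(single-cluster) and are called all-negative when the cluster sits at the
chip's baseline, all-positive otherwise.  Calls are strict: a partition is
positive iff its intensity exceeds the threshold, so exact ties gate
negative (conservative for drop-off detection).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from abcquant.panel import ProbePanel

#: minimum partitions for data-driven thresholding
MIN_PARTITIONS_AUTO = 100

#: center separation (in pooled within-cluster sd) below which a channel is
#: treated as a single cluster
DEGENERATE_SEPARATION = 3.0


def _best_split_1d(x: np.ndarray) -> tuple[float, float, float]:
    """Optimal two-cluster split of 1-D data by within-SS minimization.

    Returns (lower center, upper center, pooled within-cluster sd).  Exact
    and deterministic: every split point of the sorted data is scored via
    prefix sums, unlike iterative k-means this cannot mis-converge when one
    cluster holds a tiny fraction of points.
    """
    xs = np.sort(x)
    n = len(xs)
    c1 = np.cumsum(xs)
    c2 = np.cumsum(xs**2)
    k = np.arange(1, n)  # size of the lower cluster
    sum1, sum2 = c1[k - 1], c1[-1] - c1[k - 1]
    sq1, sq2 = c2[k - 1], c2[-1] - c2[k - 1]
    ss = (sq1 - sum1**2 / k) + (sq2 - sum2**2 / (n - k))
    i = int(np.argmin(ss))
    lo_mean = sum1[i] / k[i]
    hi_mean = sum2[i] / (n - k[i])
    pooled_sd = math.sqrt(max(ss[i], 0.0) / max(n - 2, 1))
    return lo_mean, hi_mean, pooled_sd


def call_thresholds(
    table: pd.DataFrame,
    dyes,
    method: str = "auto",
    manual_values: dict | None = None,
) -> dict:
    """Per-dye gating thresholds for one chip.

    auto: two-center 1-D partitioning per channel, threshold at the midpoint
    of the centers; degenerate channels get +inf (all-negative) when their
    intensities sit near the chip-wide baseline percentile, -inf otherwise.
    manual: values passed through (every panel dye required).
    """
    dyes = list(dyes)
    if method == "manual":
        manual_values = manual_values or {}
        missing = [d for d in dyes if d not in manual_values]
        if missing:
            raise ValueError(f"manual thresholds missing dyes: {missing}")
        return {d: float(manual_values[d]) for d in dyes}
    if method != "auto":
        raise ValueError(f"unknown thresholding method {method!r}")

    for d in dyes:
        if d not in table.columns:
            raise ValueError(f"partition table missing dye column {d!r}")
        if not np.isfinite(table[d].to_numpy(dtype=float)).all():
            raise ValueError(f"non-finite intensities in channel {d!r}")
    if len(table) < MIN_PARTITIONS_AUTO:
        raise ValueError(f"auto thresholding requires >= {MIN_PARTITIONS_AUTO} partitions, got {len(table)}")

    # chip-wide baseline anchor for degenerate (single-cluster) channels
    all_intens = table[dyes].to_numpy(dtype=float)
    chip_baseline = np.percentile(all_intens, 1)

    thresholds = {}
    for d in dyes:
        x = table[d].to_numpy(dtype=float)
        lo, hi, pooled_sd = _best_split_1d(x)
        if hi - lo < DEGENERATE_SEPARATION * pooled_sd or pooled_sd == 0 and hi == lo:
            center = float(np.median(x))
            near_baseline = center <= chip_baseline + DEGENERATE_SEPARATION * max(np.std(x), 1e-12)
            thresholds[d] = math.inf if near_baseline else -math.inf
        else:
            thresholds[d] = (lo + hi) / 2.0
    return thresholds


@dataclass
class GateResult:
    """Boolean call matrix plus per-channel counts for one chip."""

    chip_id: str
    thresholds: dict
    calls: pd.DataFrame  # partitions x dyes, boolean
    n_pos: dict
    n_neg: dict

    @property
    def n_partitions(self) -> int:
        return len(self.calls)

    @property
    def dyes(self) -> tuple[str, ...]:
        return tuple(self.calls.columns)

    def to_csv(self, path) -> None:
        out = self.calls.copy()
        out.insert(0, "partition_index", np.arange(len(out)))
        out.to_csv(path, index=False)


def gate(table: pd.DataFrame, thresholds: dict) -> GateResult:
    """Apply thresholds: call = intensity > threshold, strict."""
    dyes = list(thresholds)
    missing = [d for d in dyes if d not in table.columns]
    if missing:
        raise ValueError(f"partition table missing dye columns: {missing}")
    calls = pd.DataFrame(
        {d: table[d].to_numpy(dtype=float) > thresholds[d] for d in dyes}
    )
    n_pos = {d: int(calls[d].sum()) for d in dyes}
    n_neg = {d: int(len(calls) - n_pos[d]) for d in dyes}
    chip_id = str(table["chip_id"].iloc[0]) if "chip_id" in table.columns and len(table) else "chip"
    return GateResult(chip_id=chip_id, thresholds=dict(thresholds), calls=calls, n_pos=n_pos, n_neg=n_neg)


@dataclass
class PatternCounts:
    """Counts of the 2^k joint dye states over the panel dyes.

    ``counts`` maps a tuple of booleans (in ``dyes`` order) to a partition
    count; ``dropoff_marginals`` gives, per drop-off dye, the count of
    partitions that are reference-positive but negative for that dye --
    the drop-off product cluster of the 2-D scatterplots.
    """

    dyes: tuple
    counts: dict
    n_partitions: int
    dropoff_marginals: dict

    def pattern_label(self, pattern: tuple) -> str:
        return "/".join(f"{d}{'+' if v else '-'}" for d, v in zip(self.dyes, pattern))

    def to_dict(self) -> dict:
        return {
            "dyes": list(self.dyes),
            "n_partitions": self.n_partitions,
            "counts": {self.pattern_label(p): c for p, c in sorted(self.counts.items())},
            "dropoff_marginals": dict(self.dropoff_marginals),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def pattern_counts(gr: GateResult, panel: ProbePanel) -> PatternCounts:
    """Joint probe-pattern counts over the panel dyes.

    Patterns are mutually exclusive and exhaustive, so their counts sum to
    the number of partitions.
    """
    dyes = panel.dyes
    missing = [d for d in dyes if d not in gr.calls.columns]
    if missing:
        raise ValueError(f"gated calls missing panel dyes: {missing}")
    mat = gr.calls[list(dyes)].to_numpy(dtype=bool)
    # encode each partition's joint state as an integer
    weights = 1 << np.arange(len(dyes))
    codes = mat @ weights
    uniq, cnt = np.unique(codes, return_counts=True)
    counts = {}
    for code, c in zip(uniq, cnt):
        pattern = tuple(bool(code >> i & 1) for i in range(len(dyes)))
        counts[pattern] = int(c)
    ref = panel.reference_dye
    ref_idx = dyes.index(ref)
    marginals = {}
    for probe in panel.dropoff_probes:
        j = dyes.index(probe.dye)
        marginals[probe.dye] = int(np.sum(mat[:, ref_idx] & ~mat[:, j]))
    return PatternCounts(
        dyes=dyes, counts=counts, n_partitions=len(mat), dropoff_marginals=marginals
    )
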