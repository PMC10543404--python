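"""Ordered-alternative trend analysis for inducer dose series.

Drop-off fractions measured across increasing doxycycline doses are tested
for a monotone increasing trend with the Jonckheere-Terpstra statistic:
the sum over ordered group pairs (i < j) of Mann-Whitney counts
#{x_i < x_j} + 1/2 #{x_i = x_j}.  Doses are ordinal and group sizes tiny,
so the null is taken by exact enumeration of label assignments when the
total sample size is at most 8, and by label permutation otherwise.  The
statistic is rank-based, hence invariant under strictly monotone transforms
of the observations.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: largest total n for which the exact enumeration null is used
EXACT_ENUMERATION_LIMIT = 8


@dataclass
class DoseSeries:
    """Replicate measurements grouped by strictly ordered dose.

    ``doses`` are the ordered dose labels (e.g. ng/mL doxycycline);
    ``groups`` the replicate values per dose.  Biological-by-technical
    layouts can be pre-pooled or averaged per biological replicate before
    construction (see ``from_table``).
    """

    doses: tuple
    groups: tuple  # tuple of 1-D float arrays, parallel to doses

    def __post_init__(self) -> None:
        self.doses = tuple(self.doses)
        self.groups = tuple(np.asarray(g, dtype=float).ravel() for g in self.groups)
        if len(self.doses) < 2:
            raise ValueError("at least 2 dose groups required")
        if len(self.doses) != len(self.groups):
            raise ValueError("doses and groups must be parallel")
        if any(len(g) < 1 for g in self.groups):
            raise ValueError("every dose group needs at least 1 replicate")
        d = [float(x) for x in self.doses]
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("doses must be strictly increasing")

    @property
    def n_total(self) -> int:
        return sum(len(g) for g in self.groups)

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        probe: str | None = None,
        value_col: str = "value",
        pooling: str = "pooled",
    ) -> "DoseSeries":
        """Build from a long table with columns dose, replicate, probe, value.

        pooling="pooled" uses every measurement as a replicate;
        pooling="by_replicate" first averages technical measurements within
        each (dose, replicate) pair, treating ``replicate`` as the
        biological unit.
        """
        df = table.copy()
        if probe is not None:
            df = df[df["probe"] == probe]
        if df.empty:
            raise ValueError("no rows for the requested probe")
        if pooling == "by_replicate":
            df = df.groupby(["dose", "replicate"], as_index=False)[value_col].mean()
        elif pooling != "pooled":
            raise ValueError(f"unknown pooling mode {pooling!r}")
        doses = sorted(df["dose"].unique())
        groups = [df.loc[df["dose"] == d, value_col].to_numpy(dtype=float) for d in doses]
        return cls(doses=tuple(doses), groups=tuple(groups))


def jt_statistic(groups) -> float:
    """Jonckheere-Terpstra statistic with the 1/2 tie convention."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    stat = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a = groups[i][:, None]
            b = groups[j][None, :]
            stat += np.sum(b > a) + 0.5 * np.sum(b == a)
    return float(stat)


def max_jt(groups) -> float:
    """Maximum attainable statistic: sum of n_i * n_j over ordered pairs."""
    sizes = [len(g) for g in groups]
    return float(sum(a * b for a, b in itertools.combinations(sizes, 2)))


@dataclass(frozen=True)
class JTResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "permutation"
    n_perm: int
    max_statistic: float
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "n_perm": self.n_perm,
            "max_statistic": self.max_statistic,
            "seed": self.seed,
        }


def jonckheere_terpstra(
    series: DoseSeries,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> JTResult:
    """One-sided (increasing) Jonckheere-Terpstra trend test.

    Exact null by full enumeration of the n! value-to-slot assignments when
    n_total <= 8 (duplicate orderings count with their natural multiplicity,
    which matches the multiset distribution); Monte-Carlo label permutation
    with the add-one convention otherwise.
    """
    sizes = [len(g) for g in series.groups]
    pooled = np.concatenate(series.groups)
    bounds = np.cumsum(sizes)[:-1]
    obs = jt_statistic(series.groups)

    if series.n_total <= EXACT_ENUMERATION_LIMIT:
        hits = total = 0
        for perm in itertools.permutations(pooled):
            g = np.split(np.asarray(perm), bounds)
            total += 1
            if jt_statistic(g) >= obs - 1e-12:
                hits += 1
        return JTResult(
            statistic=obs, p_value=hits / total, method="exact",
            n_perm=total, max_statistic=max_jt(series.groups), seed=seed,
        )

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        g = np.split(perm, bounds)
        if jt_statistic(g) >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return JTResult(
        statistic=obs, p_value=p, method="permutation",
        n_perm=n_perm, max_statistic=max_jt(series.groups), seed=seed,
    )


def trend_summary(series: DoseSeries) -> dict:
    """Per-dose mean +/- SEM, fold change vs the lowest dose, monotonicity.

    SEM is undefined (NaN) for single-replicate groups; fold changes are
    relative to the lowest-dose mean (NaN when that mean is 0); the monotone
    flag marks non-decreasing sample means across doses.
    """
    rows = []
    means = []
    for dose, g in zip(series.doses, series.groups):
        k = len(g)
        mean = float(np.mean(g))
        sem = float(np.std(g, ddof=1) / math.sqrt(k)) if k > 1 else math.nan
        rows.append({"dose": dose, "n": k, "mean": mean, "sem": sem})
        means.append(mean)
    base = means[0]
    for r, m in zip(rows, means):
        r["fold_vs_lowest"] = m / base if base != 0 else math.nan
    monotone = all(b >= a for a, b in zip(means, means[1:]))
    return {"per_dose": rows, "monotone_increasing": monotone}


def trend_report(series: DoseSeries, n_perm: int = 10_000, seed: int | None = None) -> dict:
    """Combined JSON-ready report: summary plus the trend test."""
    jt = jonckheere_terpstra(series, n_perm=n_perm, seed=seed)
    out = trend_summary(series)
    out["jonckheere_terpstra"] = jt.to_dict()
    return out
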