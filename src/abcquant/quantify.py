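"""Poisson-corrected dPCR quantification.

Partition occupancy is Poisson, so the mean copies per partition follows
from the negative fraction alone: lambda = -ln(N_neg / N_total), and the
concentration is lambda / partition_volume = lambda * n_partitions /
(reaction_volume * analyzed_fraction), in copies/uL.

Drop-off (mutant) quantification must correct for co-encapsulation: a
partition holding both a mutant and a wild-type template lights every
probe, so the naive count of (reference+, probe-) partitions under-counts
mutants as loading increases.  Two estimators are provided:

* difference (default): lambda_mut = lambda_ref - lambda_probe, each
  channel Poisson-corrected independently;
* joint: solves the two-species occupancy model from the probe-negative
  fraction and the (reference+, probe-) pattern frequency,
  P(ref+, probe-) = (1 - e^{-lambda_mut}) * e^{-lambda_intact}.

Both are exactly consistent under the model; the joint estimator serves as
the cross-check.  Confidence intervals on lambda come from Clopper-Pearson
bounds on the negative fraction transformed through -ln; intervals on
ratios (drop-off fraction, CNV ratio) come from a partition-resampling
bootstrap, implemented as a multinomial resample of the joint pattern
counts (equivalent to resampling partitions with replacement).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from abcquant.gating import GateResult, PatternCounts, pattern_counts
from abcquant.panel import ProbePanel
from abcquant.simulate import ChipSpec


@dataclass(frozen=True)
class LambdaEstimate:
    """Poisson mean copies per partition with Clopper-Pearson-derived CI."""

    lam: float
    ci_low: float
    ci_high: float
    n_neg: int
    n_total: int
    ci_level: float = 0.95
    saturated: bool = False  # no negative partitions: only a lower bound

    def scaled(self, factor: float) -> "LambdaEstimate":
        return LambdaEstimate(
            lam=self.lam * factor,
            ci_low=self.ci_low * factor,
            ci_high=self.ci_high * factor,
            n_neg=self.n_neg,
            n_total=self.n_total,
            ci_level=self.ci_level,
            saturated=self.saturated,
        )


def lambda_from_negatives(n_neg: int, n_total: int, ci_level: float = 0.95) -> LambdaEstimate:
    """Poisson correction of a negative-partition count.

    lambda = -ln(n_neg / n_total); the CI maps the Clopper-Pearson interval
    for the negative fraction through -ln (monotone decreasing, so bounds
    swap).  n_neg == 0 is saturated: the point estimate is undefined
    (reported as +inf) and only the lower bound is meaningful.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= n_neg <= n_total):
        raise ValueError("n_neg must satisfy 0 <= n_neg <= n_total")
    alpha = 1.0 - ci_level
    # Clopper-Pearson bounds on the negative fraction
    p_lo = stats.beta.ppf(alpha / 2, n_neg, n_total - n_neg + 1) if n_neg > 0 else 0.0
    p_hi = stats.beta.ppf(1 - alpha / 2, n_neg + 1, n_total - n_neg) if n_neg < n_total else 1.0
    lam_low = -math.log(p_hi) if p_hi > 0 else math.inf
    lam_high = -math.log(p_lo) if p_lo > 0 else math.inf
    if n_neg == 0:
        return LambdaEstimate(
            lam=math.inf, ci_low=lam_low, ci_high=math.inf,
            n_neg=n_neg, n_total=n_total, ci_level=ci_level, saturated=True,
        )
    lam = -math.log(n_neg / n_total)
    return LambdaEstimate(
        lam=lam, ci_low=lam_low, ci_high=lam_high,
        n_neg=n_neg, n_total=n_total, ci_level=ci_level,
    )


def concentration(est: LambdaEstimate, chip: ChipSpec) -> LambdaEstimate:
    """Convert copies/partition to copies/uL: C = lambda / partition_volume."""
    if est.lam < 0 and not est.saturated:
        raise ValueError("lambda must be >= 0")
    return est.scaled(1.0 / chip.partition_volume)


@dataclass
class ChannelQuant:
    """Per-dye quantification: lambda and concentration, each with CI."""

    dye: str
    lam: LambdaEstimate
    conc: LambdaEstimate

    def to_dict(self) -> dict:
        return {
            "dye": self.dye,
            "n_neg": self.lam.n_neg,
            "n_total": self.lam.n_total,
            "lambda": self.lam.lam,
            "lambda_ci": [self.lam.ci_low, self.lam.ci_high],
            "copies_per_ul": self.conc.lam,
            "copies_per_ul_ci": [self.conc.ci_low, self.conc.ci_high],
            "saturated": self.lam.saturated,
        }


@dataclass
class DropoffQuant:
    """Per drop-off probe: mutant concentration and drop-off fraction."""

    dye: str
    lam_mut: float
    conc_mut: float
    conc_mut_ci: tuple
    fraction: float
    fraction_ci: tuple
    floored: bool = False  # negative raw estimate floored at 0
    fraction_exceeds_one: bool = False

    def to_dict(self) -> dict:
        return {
            "dye": self.dye,
            "lambda_mut": self.lam_mut,
            "copies_per_ul_mut": self.conc_mut,
            "copies_per_ul_mut_ci": list(self.conc_mut_ci),
            "dropoff_fraction": self.fraction,
            "dropoff_fraction_ci": list(self.fraction_ci),
            "floored": self.floored,
            "fraction_exceeds_one": self.fraction_exceeds_one,
        }


@dataclass
class QuantResult:
    """Full quantification of one chip (or one pooled pseudo-chip)."""

    chip_id: str
    method: str
    channels: dict  # dye -> ChannelQuant
    dropoffs: dict  # dye -> DropoffQuant
    patterns: PatternCounts
    chip: ChipSpec
    reference_dye: str
    ci_level: float = 0.95
    n_boot: int = 1000
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "chip_id": self.chip_id,
            "method": self.method,
            "reference_dye": self.reference_dye,
            "ci_level": self.ci_level,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "channels": {d: c.to_dict() for d, c in self.channels.items()},
            "dropoffs": {d: q.to_dict() for d, q in self.dropoffs.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_rows(self) -> list:
        """Flat rows (one per probe) for TSV export."""
        rows = []
        ref = self.channels[self.reference_dye]
        for dye, q in self.dropoffs.items():
            rows.append(
                {
                    "chip_id": self.chip_id,
                    "probe_dye": dye,
                    "method": self.method,
                    "copies_per_ul_ref": ref.conc.lam,
                    "copies_per_ul_probe": self.channels[dye].conc.lam,
                    "copies_per_ul_mut": q.conc_mut,
                    "dropoff_fraction": q.fraction,
                    "fraction_ci_low": q.fraction_ci[0],
                    "fraction_ci_high": q.fraction_ci[1],
                }
            )
        return rows


def _neg_counts_from_patterns(pc: PatternCounts) -> dict:
    """Per-dye negative-partition counts derived from joint pattern counts."""
    n_neg = {d: 0 for d in pc.dyes}
    for pattern, c in pc.counts.items():
        for d, state in zip(pc.dyes, pattern):
            if not state:
                n_neg[d] += c
    return n_neg


def _lam_mut_difference(lam_ref: float, lam_probe: float) -> tuple[float, bool]:
    raw = lam_ref - lam_probe
    return (max(raw, 0.0), raw < 0.0)


def _lam_mut_joint(pc: PatternCounts, ref_dye: str, probe_dye: str) -> tuple[float, bool]:
    """Solve lambda_mut from P(ref+, probe-) = (1 - e^-lam_mut) e^-lam_intact."""
    n = pc.n_partitions
    n_probe_neg = _neg_counts_from_patterns(pc)[probe_dye]
    if n_probe_neg == 0:
        return (math.inf, False)
    p_intact_neg = n_probe_neg / n
    p_pat = pc.dropoff_marginals[probe_dye] / n
    inner = 1.0 - p_pat / p_intact_neg
    if inner <= 0:
        return (math.inf, False)
    return (max(-math.log(inner), 0.0), False)


def dropoff_quantify_from_patterns(
    pc: PatternCounts,
    panel: ProbePanel,
    chip: ChipSpec,
    method: str = "difference",
    ci_level: float = 0.95,
    n_boot: int = 1000,
    seed: int | None = None,
    chip_id: str = "chip",
) -> QuantResult:
    """Quantify per-channel and drop-off concentrations from pattern counts.

    Operating on joint pattern counts (rather than the call matrix) lets
    replicate chips be pooled by summing counts before quantification, and
    makes the bootstrap a multinomial resample.
    """
    if method not in ("difference", "joint"):
        raise ValueError(f"unknown method {method!r}")
    ref_dye = panel.reference_dye
    n = pc.n_partitions
    neg = _neg_counts_from_patterns(pc)

    if neg[ref_dye] == 0:
        raise ValueError("reference channel saturated (no negative partitions): quantification refused")

    channels = {}
    for dye in pc.dyes:
        lam = lambda_from_negatives(neg[dye], n, ci_level)
        channels[dye] = ChannelQuant(dye=dye, lam=lam, conc=concentration(lam, chip))

    lam_ref = channels[ref_dye].lam.lam
    pv = chip.partition_volume

    def estimate_all(pat_counts: PatternCounts) -> dict:
        """lam_mut and fraction per drop-off dye from one set of pattern counts."""
        negs = _neg_counts_from_patterns(pat_counts)
        if negs[ref_dye] == 0:
            return {}
        l_ref = -math.log(negs[ref_dye] / pat_counts.n_partitions)
        out = {}
        for probe in panel.dropoff_probes:
            d = probe.dye
            if method == "difference":
                if negs[d] == 0:
                    out[d] = (math.nan, math.nan, False)
                    continue
                l_probe = -math.log(negs[d] / pat_counts.n_partitions)
                l_mut, floored = _lam_mut_difference(l_ref, l_probe)
            else:
                l_mut, floored = _lam_mut_joint(pat_counts, ref_dye, d)
            frac = l_mut / l_ref if l_ref > 0 else (0.0 if l_mut == 0 else math.inf)
            out[d] = (l_mut, frac, floored)
        return out

    point = estimate_all(pc)

    # partition-resampling bootstrap via multinomial over joint patterns
    rng = np.random.default_rng(seed)
    patterns = sorted(pc.counts)
    probs = np.array([pc.counts[p] for p in patterns], dtype=float)
    probs /= probs.sum()
    boot = {probe.dye: [] for probe in panel.dropoff_probes}
    if n_boot > 0:
        draws = rng.multinomial(n, probs, size=n_boot)
        for row in draws:
            bc = PatternCounts(
                dyes=pc.dyes,
                counts=dict(zip(patterns, (int(v) for v in row))),
                n_partitions=n,
                dropoff_marginals=_marginals_from_counts(pc.dyes, patterns, row, ref_dye, panel),
            )
            est = estimate_all(bc)
            for d, vals in est.items():
                boot[d].append(vals)

    alpha = 1.0 - ci_level
    dropoffs = {}
    for probe in panel.dropoff_probes:
        d = probe.dye
        l_mut, frac, floored = point[d]
        if boot[d]:
            arr = np.array([(lm, fr) for lm, fr, _ in boot[d]], dtype=float)
            finite = np.isfinite(arr).all(axis=1)
            arr = arr[finite]
        else:
            arr = np.empty((0, 2))
        if len(arr):
            lm_ci = tuple(np.quantile(arr[:, 0], [alpha / 2, 1 - alpha / 2]) / pv)
            fr_ci = tuple(np.quantile(arr[:, 1], [alpha / 2, 1 - alpha / 2]))
        else:
            lm_ci = (math.nan, math.nan)
            fr_ci = (math.nan, math.nan)
        dropoffs[d] = DropoffQuant(
            dye=d,
            lam_mut=l_mut,
            conc_mut=l_mut / pv,
            conc_mut_ci=lm_ci,
            fraction=frac,
            fraction_ci=fr_ci,
            floored=floored,
            fraction_exceeds_one=bool(frac > 1.0),
        )

    return QuantResult(
        chip_id=chip_id,
        method=method,
        channels=channels,
        dropoffs=dropoffs,
        patterns=pc,
        chip=chip,
        reference_dye=ref_dye,
        ci_level=ci_level,
        n_boot=n_boot,
        seed=seed,
    )


def _marginals_from_counts(dyes, patterns, counts_row, ref_dye, panel) -> dict:
    ref_idx = list(dyes).index(ref_dye)
    marg = {}
    for probe in panel.dropoff_probes:
        j = list(dyes).index(probe.dye)
        marg[probe.dye] = int(
            sum(c for p, c in zip(patterns, counts_row) if p[ref_idx] and not p[j])
        )
    return marg


def dropoff_quantify(
    gr: GateResult,
    panel: ProbePanel,
    chip: ChipSpec,
    method: str = "difference",
    ci_level: float = 0.95,
    n_boot: int = 1000,
    seed: int | None = None,
) -> QuantResult:
    """Quantify one gated chip (see dropoff_quantify_from_patterns)."""
    pc = pattern_counts(gr, panel)
    return dropoff_quantify_from_patterns(
        pc, panel, chip, method=method, ci_level=ci_level,
        n_boot=n_boot, seed=seed, chip_id=gr.chip_id,
    )


def pool_pattern_counts(pcs) -> PatternCounts:
    """Sum joint pattern counts across replicate chips (partition pooling)."""
    pcs = list(pcs)
    if not pcs:
        raise ValueError("no pattern counts to pool")
    dyes = pcs[0].dyes
    if any(pc.dyes != dyes for pc in pcs):
        raise ValueError("pattern counts have mismatched dye sets")
    counts: dict = {}
    marg: dict = {}
    n = 0
    for pc in pcs:
        n += pc.n_partitions
        for p, c in pc.counts.items():
            counts[p] = counts.get(p, 0) + c
        for d, c in pc.dropoff_marginals.items():
            marg[d] = marg.get(d, 0) + c
    return PatternCounts(dyes=dyes, counts=counts, n_partitions=n, dropoff_marginals=marg)


@dataclass
class CNVCall:
    """Reference:drop-off concentration ratios and the resulting CNV call.

    ``hemizygous-reference`` fires only when every per-probe bootstrap CI
    excludes 1 and contains 0.5 (the reference-probe site lost on one
    homolog); ``euploid`` when every CI contains 1; otherwise ``other``.
    """

    ratios: dict  # probe dye -> ratio Chat_ref / Chat_probe
    ratio_cis: dict
    call: str
    total_copies_per_ul: dict  # per-dye concentration (the 4-probe verification)
    n_boot: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "ratios": dict(self.ratios),
            "ratio_cis": {d: list(ci) for d, ci in self.ratio_cis.items()},
            "call": self.call,
            "total_copies_per_ul": dict(self.total_copies_per_ul),
            "n_boot": self.n_boot,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def cnv_ratio(q: QuantResult, n_boot: int = 2000, seed: int | None = None) -> CNVCall:
    """Copy-number inference from probe-concentration ratios.

    For each drop-off probe, r = C_ref / C_probe with a partition-resampling
    bootstrap CI.  A halved reference signal (r ~= 0.5 on every probe) marks
    loss of the reference binding site on one homolog.
    """
    ref_dye = q.reference_dye
    pc = q.patterns
    n = pc.n_partitions
    neg = _neg_counts_from_patterns(pc)
    for dye in pc.dyes:
        if neg[dye] == 0:
            raise ValueError(f"channel {dye} saturated: CNV ratio refused")
        if q.channels[dye].conc.lam <= 0:
            raise ValueError(f"channel {dye} has zero concentration: CNV ratio undefined")

    probe_dyes = [d for d in pc.dyes if d != ref_dye]
    lam_ref = -math.log(neg[ref_dye] / n)
    ratios = {d: lam_ref / -math.log(neg[d] / n) for d in probe_dyes}

    rng = np.random.default_rng(seed)
    patterns = sorted(pc.counts)
    probs = np.array([pc.counts[p] for p in patterns], dtype=float)
    probs /= probs.sum()
    draws = rng.multinomial(n, probs, size=n_boot)
    # per-dye negative counts for each bootstrap replicate
    neg_masks = {d: np.array([not p[list(pc.dyes).index(d)] for p in patterns]) for d in pc.dyes}
    boot_ratios = {d: [] for d in probe_dyes}
    for row in draws:
        nn = {d: int(row[neg_masks[d]].sum()) for d in pc.dyes}
        if nn[ref_dye] == 0 or any(nn[d] == 0 for d in probe_dyes):
            continue
        l_ref = -math.log(nn[ref_dye] / n)
        for d in probe_dyes:
            l_probe = -math.log(nn[d] / n)
            if l_probe > 0:
                boot_ratios[d].append(l_ref / l_probe)

    cis = {}
    for d in probe_dyes:
        arr = np.asarray(boot_ratios[d])
        cis[d] = tuple(np.quantile(arr, [0.025, 0.975])) if len(arr) else (math.nan, math.nan)

    def ci_contains(ci, v):
        return ci[0] <= v <= ci[1]

    if all(not ci_contains(cis[d], 1.0) and ci_contains(cis[d], 0.5) for d in probe_dyes):
        call = "hemizygous-reference"
    elif all(ci_contains(cis[d], 1.0) for d in probe_dyes):
        call = "euploid"
    else:
        call = "other"

    totals = {d: q.channels[d].conc.lam for d in pc.dyes}
    return CNVCall(
        ratios=ratios, ratio_cis=cis, call=call,
        total_copies_per_ul=totals, n_boot=n_boot, seed=seed,
    )


def aggregate_quant_results(results) -> dict:
    """Replicate aggregation across chips: mean +/- SEM per drop-off probe.

    Mirrors how figure panels report "mean values +/- SEM" over replicate
    reactions, for both copies/uL and drop-off fraction.
    """
    results = list(results)
    if not results:
        raise ValueError("no quantification results to aggregate")
    dyes = list(results[0].dropoffs)
    out = {}
    for d in dyes:
        fracs = np.array([r.dropoffs[d].fraction for r in results], dtype=float)
        concs = np.array([r.dropoffs[d].conc_mut for r in results], dtype=float)
        k = len(results)
        out[d] = {
            "n_chips": k,
            "mean_fraction": float(fracs.mean()),
            "sem_fraction": float(fracs.std(ddof=1) / math.sqrt(k)) if k > 1 else math.nan,
            "mean_copies_per_ul": float(concs.mean()),
            "sem_copies_per_ul": float(concs.std(ddof=1) / math.sqrt(k)) if k > 1 else math.nan,
        }
    return out


def naive_dropoff_fraction(pc: PatternCounts, panel: ProbePanel) -> dict:
    """Uncorrected estimator: (ref+, probe-) count / ref+ count.

    Ignores co-encapsulation (a partition holding both a mutant and a
    wild-type template lights every probe and is missed), so it is biased
    low at high loading.  Kept as the comparison baseline for the corrected
    estimators.
    """
    ref_dye = panel.reference_dye
    ref_idx = list(pc.dyes).index(ref_dye)
    n_ref_pos = sum(c for p, c in pc.counts.items() if p[ref_idx])
    out = {}
    for probe in panel.dropoff_probes:
        out[probe.dye] = (
            pc.dropoff_marginals[probe.dye] / n_ref_pos if n_ref_pos else math.nan
        )
    return out
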