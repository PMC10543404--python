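"""Per-position indel profiling of amplicon alignments and CpG-motif analysis.

Profiles count insertion/deletion events at each reference position of a
single amplicon, from SAM alignments.  Motif scanning covers the AID
deamination preference hierarchy (WGCW >>> WRC > RCG, with the CpG
dinucleotide as the common core), and a depth-weighted permutation test asks
whether indel events concentrate near CpG sites, the hallmark of an AID
break cluster.

Coordinates are 0-based half-open throughout; profile positions are relative
to the amplicon start.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pysam

_MOTIF_PATTERNS = {
    "CpG": "CG",
    "RCG": "[AG]CG",
    "WRC": "[AT][AG]C",
    "WGCW": "[AT]GC[AT]",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class AmpliconRef:
    """An amplicon reference: sequence plus genomic anchor and annotation.

    ``abc_intervals`` are amplicon-local sub-intervals annotated as the AID
    break cluster proper; ``cpg_positions`` are amplicon-local indices of the
    C of each CpG dinucleotide (derived from the sequence when omitted).
    """

    name: str
    chrom: str
    start: int
    end: int
    sequence: str
    abc_intervals: tuple[tuple[int, int], ...] = ()
    cpg_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) != self.end - self.start:
            raise ValueError(
                f"amplicon {self.name!r}: sequence length {len(seq)} != span {self.end - self.start}"
            )
        if not self.cpg_positions:
            object.__setattr__(self, "cpg_positions", tuple(scan_motifs(seq, "CpG")))
        else:
            for p in self.cpg_positions:
                if seq[p : p + 2] != "CG":
                    raise ValueError(f"amplicon {self.name!r}: position {p} is not a CpG")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class IndelProfile:
    """Per-position indel event counts over one amplicon.

    ``del_cov[p]`` counts reads whose deletion spans position p;
    ``del_start[p]`` counts deletion events starting at p (one per event);
    ``ins_count[p]`` counts insertion events assigned to p (the reference
    position immediately after the insertion point); ``depth[p]`` is the
    number of reads whose reference footprint (deletions included) covers p.
    """

    ref_name: str
    depth: np.ndarray
    del_cov: np.ndarray
    del_start: np.ndarray
    ins_count: np.ndarray
    n_reads: int = 0
    n_skipped: int = 0
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if np.any(self.del_cov > self.depth):
            raise ValueError("deletion coverage exceeds depth")

    @property
    def n_positions(self) -> int:
        return len(self.depth)

    def event_counts(self) -> np.ndarray:
        """Indel events per position: deletion starts plus insertions."""
        return self.del_start + self.ins_count

    def frequencies(self):
        """Per-position deletion/insertion frequencies as a DataFrame."""
        import pandas as pd

        with np.errstate(divide="ignore", invalid="ignore"):
            del_freq = np.where(self.depth > 0, self.del_cov / np.maximum(self.depth, 1), 0.0)
            ins_freq = np.where(self.depth > 0, self.ins_count / np.maximum(self.depth, 1), 0.0)
        return pd.DataFrame(
            {
                "pos": np.arange(self.n_positions),
                "depth": self.depth,
                "del_count": self.del_cov,
                "ins_count": self.ins_count,
                "del_freq": del_freq,
                "ins_freq": ins_freq,
            }
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of the indel-to-CpG proximity permutation test."""

    window: int
    n_events: int
    observed_fraction: float
    null_mean: float
    fold_enrichment: float
    p_value: float
    n_perm: int
    seed: int | None = None
    evaluable: bool = True
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "window": self.window,
            "n_events": self.n_events,
            "observed_fraction": self.observed_fraction,
            "null_mean": self.null_mean,
            "fold_enrichment": self.fold_enrichment,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "evaluable": self.evaluable,
            "reason": self.reason,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def scan_motifs(sequence: str, motif: str, both_strands: bool = True) -> list[int]:
    """Return sorted 0-based start positions of motif matches.

    Motifs: ``CpG`` (CG), ``RCG``, ``WRC``, ``WGCW`` with IUPAC W={A,T},
    R={A,G}; ``N`` never matches.  With ``both_strands``, matches on the
    reverse complement are projected back onto forward-strand start
    coordinates and de-duplicated (CG is its own reverse complement, so the
    CpG set is strand-symmetric by construction).
    """
    if motif not in _MOTIF_PATTERNS:
        raise ValueError(f"unknown motif {motif!r}; expected one of {sorted(_MOTIF_PATTERNS)}")
    seq = sequence.upper()
    if not re.fullmatch("[ACGTN]*", seq):
        raise ValueError("sequence must be over the alphabet {A,C,G,T,N}")
    pat = re.compile(f"(?=({_MOTIF_PATTERNS[motif]}))")
    width = len(_MOTIF_PATTERNS[motif].replace("[AG]", "R").replace("[AT]", "W"))
    hits = {m.start() for m in pat.finditer(seq)}
    if both_strands:
        rc = seq.translate(_COMPLEMENT)[::-1]
        for m in pat.finditer(rc):
            hits.add(len(seq) - m.start() - width)
    return sorted(hits)


def _footprint(aln: pysam.AlignedSegment) -> tuple[int, int]:
    """Reference footprint [start, end) of an alignment, deletions included."""
    return aln.reference_start, aln.reference_end


def parse_alignments(sam_path, ref: AmpliconRef) -> IndelProfile:
    """Build an IndelProfile from SAM alignments against one amplicon.

    A deletion of length L starting at reference position p increments
    ``del_cov`` at p..p+L-1 (and ``del_start`` at p); an insertion between
    reference positions p-1 and p increments ``ins_count`` at p.
    Substitutions are ignored.  Unmapped, secondary and supplementary records
    are skipped (counted in ``n_skipped``); records whose reference footprint
    exceeds the amplicon are rejected (``n_rejected``).
    """
    L = len(ref)
    depth = np.zeros(L, dtype=np.int64)
    del_cov = np.zeros(L, dtype=np.int64)
    del_start = np.zeros(L, dtype=np.int64)
    ins_count = np.zeros(L, dtype=np.int64)
    n_reads = n_skipped = n_rejected = 0

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                n_skipped += 1
                continue
            rs, re_ = _footprint(aln)
            if rs < 0 or re_ is None or re_ > L:
                n_rejected += 1
                continue
            depth[rs:re_] += 1
            pos = rs
            ok = True
            for op, length in aln.cigartuples or ():
                if op in (0, 7, 8):  # M, =, X
                    pos += length
                elif op == 2:  # D
                    if pos + length > L:
                        ok = False
                        break
                    del_cov[pos : pos + length] += 1
                    del_start[pos] += 1
                    pos += length
                elif op == 1:  # I: assigned to the following reference position
                    ins_count[min(pos, L - 1)] += 1
                elif op in (4, 5):  # soft/hard clip: no reference advance
                    continue
                elif op == 3:  # N
                    pos += length
            if not ok:
                n_rejected += 1
                depth[rs:re_] -= 1
                continue
            n_reads += 1

    return IndelProfile(
        ref_name=ref.name,
        depth=depth,
        del_cov=del_cov,
        del_start=del_start,
        ins_count=ins_count,
        n_reads=n_reads,
        n_skipped=n_skipped,
        n_rejected=n_rejected,
    )


def proximity_enrichment(
    profile: IndelProfile,
    cpg_positions,
    window: int = 8,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Permutation test for indel concentration near CpG sites.

    The observed statistic is the fraction of indel events (deletion starts
    plus insertions) lying within ±``window`` bp of any CpG.  The null
    re-places the same number of events over covered positions with
    probability proportional to read depth; because proximity is a binary
    property of position, the null fraction is Binomial(n_events, p_near)
    with p_near the depth-weighted proximity mass.  p-value uses the
    add-one permutation convention.
    """
    cpgs = np.asarray(sorted(cpg_positions), dtype=np.int64)
    events = profile.event_counts()
    n_events = int(events.sum())
    if n_events == 0 or cpgs.size == 0:
        return EnrichmentResult(
            window=window,
            n_events=n_events,
            observed_fraction=float("nan"),
            null_mean=float("nan"),
            fold_enrichment=float("nan"),
            p_value=float("nan"),
            n_perm=n_perm,
            seed=seed,
            evaluable=False,
            reason="no indel events" if n_events == 0 else "no CpG sites",
        )

    positions = np.arange(profile.n_positions)
    near = np.zeros(profile.n_positions, dtype=bool)
    for c in cpgs:
        lo, hi = max(0, c - window), min(profile.n_positions, c + window + 1)
        near[lo:hi] = True

    observed = float(events[near].sum() / n_events)

    covered = profile.depth > 0
    weights = np.where(covered, profile.depth, 0).astype(float)
    weights /= weights.sum()
    p_near = float(weights[near].sum())

    rng = np.random.default_rng(seed)
    null = rng.binomial(n_events, p_near, size=n_perm) / n_events
    null_mean = float(null.mean())
    fold = observed / null_mean if null_mean > 0 else float("inf")
    p = float((1 + np.sum(null >= observed)) / (n_perm + 1))
    return EnrichmentResult(
        window=window,
        n_events=n_events,
        observed_fraction=observed,
        null_mean=null_mean,
        fold_enrichment=fold,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )


def probe_window_dropoff(sam_path, probe_intervals, ref: AmpliconRef) -> dict:
    """Sequence-level analog of the dPCR drop-off readout.

    For each probe interval (amplicon-local, 0-based half-open), the
    predicted drop-off fraction is the fraction of reads carrying at least
    one indel overlapping the interval, among reads whose reference footprint
    fully spans it.  An insertion at position p overlaps [p-1, p+1).

    Returns ``{probe_name: {"fraction": f, "n_dropped": k, "n_spanning": n}}``.
    """
    L = len(ref)
    intervals = []
    for name, start, end in probe_intervals:
        if start < 0 or end > L or start >= end:
            raise ValueError(f"probe {name!r} interval [{start}, {end}) outside amplicon of length {L}")
        intervals.append((name, start, end))

    denom = {name: 0 for name, _, _ in intervals}
    numer = {name: 0 for name, _, _ in intervals}

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            rs, re_ = aln.reference_start, aln.reference_end
            indel_spans = []
            pos = rs
            for op, length in aln.cigartuples or ():
                if op in (0, 7, 8, 3):
                    pos += length
                elif op == 2:
                    indel_spans.append((pos, pos + length))
                    pos += length
                elif op == 1:
                    indel_spans.append((pos - 1, pos + 1))
            for name, start, end in intervals:
                if rs <= start and re_ >= end:
                    denom[name] += 1
                    if any(s < end and e > start for s, e in indel_spans):
                        numer[name] += 1

    out = {}
    for name, _, _ in intervals:
        n = denom[name]
        out[name] = {
            "fraction": numer[name] / n if n else float("nan"),
            "n_dropped": numer[name],
            "n_spanning": n,
        }
    return out


def plot_profile(profile: IndelProfile, path, ref: AmpliconRef | None = None) -> None:
    """Bar plot of per-position deletion (blue) vs insertion (green) frequency."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = profile.frequencies()
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.bar(df["pos"], df["del_freq"], width=1.0, color="tab:blue", label="deletions")
    ax.bar(df["pos"], -df["ins_freq"], width=1.0, color="tab:green", label="insertions")
    if ref is not None:
        for c in ref.cpg_positions:
            ax.axvline(c, color="red", lw=0.5, alpha=0.6)
    ax.set_xlabel("amplicon position (bp)")
    ax.set_ylabel("indel frequency")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
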