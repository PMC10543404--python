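"""Synthetic-data generators: dPCR chip simulator and amplicon read simulator.

The chip simulator emulates a microchamber array digital PCR run: template
molecules of each allele species distribute over partitions independently
and Poisson; a dye channel is truly positive in a partition iff at least one
template of a species whose probe site is intact for that dye is present;
fluorescence intensities are then drawn from a two-component Gaussian noise
model with optional "rain" (intermediate-intensity positives).

The read simulator emulates amplicon sequencing of an AID break cluster:
each read is independently edited with some probability, the edit lands near
a CpG hotspot (Gaussian kernel around weighted hotspot centers), deletions
dominate insertions, and lengths are 1 + Geometric.  Reads are emitted as
FASTQ plus SAM alignments whose CIGARs encode the introduced edits exactly,
together with a ground-truth record for recovery testing.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from abcquant.indels import AmpliconRef
from abcquant.panel import ProbePanel, canonical_dye

#: human haploid genome mass, picograms; converts gDNA input mass to copies
PG_PER_HAPLOID_GENOME = 3.3


def gdna_concentration(mass_ng: float, reaction_volume_ul: float = 9.0) -> float:
    """Haploid genome copies/uL of reaction for a given gDNA input mass.

    10 ng in a 9 uL reaction -> 10_000 pg / 3.3 pg / 9 uL ~= 336.7 copies/uL.
    """
    if mass_ng < 0 or reaction_volume_ul <= 0:
        raise ValueError("mass must be >= 0 and reaction volume > 0")
    return mass_ng * 1000.0 / PG_PER_HAPLOID_GENOME / reaction_volume_ul


@dataclass(frozen=True)
class ChipSpec:
    """Geometry of one dPCR chip.

    Defaults model a 20,480-microchamber array running a 9 uL reaction with
    the full volume analyzed.  ``partition_volume`` (uL) is derived so that
    partition_volume * n_partitions == reaction_volume * analyzed_fraction.
    """

    n_partitions: int = 20_480
    reaction_volume: float = 9.0
    analyzed_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_partitions < 1:
            raise ValueError("n_partitions must be >= 1")
        if self.reaction_volume <= 0:
            raise ValueError("reaction_volume must be > 0")
        if not (0 < self.analyzed_fraction <= 1):
            raise ValueError("analyzed_fraction must be in (0, 1]")

    @property
    def partition_volume(self) -> float:
        return self.reaction_volume * self.analyzed_fraction / self.n_partitions


@dataclass(frozen=True)
class AlleleSpecies:
    """One allele species on the chip.

    ``binding_profile`` maps dye -> True when that probe's binding site is
    intact on this species (the probe lights up in partitions containing it).
    """

    name: str
    concentration: float  # copies/uL of reaction
    binding_profile: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.concentration) or self.concentration < 0:
            raise ValueError(f"species {self.name!r}: concentration must be finite and >= 0")
        object.__setattr__(
            self, "binding_profile", {canonical_dye(d): bool(v) for d, v in self.binding_profile.items()}
        )


@dataclass(frozen=True)
class NoiseModel:
    """Two-component Gaussian fluorescence model with optional rain.

    Each field may be a scalar (applied to every dye) or a mapping
    dye -> value.  ``rain_fraction`` of truly positive partitions draw their
    intensity from an intermediate "rain" cluster (late/partial
    amplification) centered at ``rain_position`` of the way from baseline to
    positive.  Real rain lies between the clusters but overwhelmingly still
    gates positive -- a drop-off assay with a ~1e-4 false-positive floor
    could not work otherwise -- so the default position (0.7) keeps rain
    above a midpoint threshold while still stressing cluster separation.
    """

    baseline_mean: float | dict = 1000.0
    baseline_sd: float | dict = 50.0
    positive_mean: float | dict = 5000.0
    positive_sd: float | dict = 200.0
    rain_fraction: float = 0.01
    rain_position: float = 0.7

    def __post_init__(self) -> None:
        if not (0 <= self.rain_fraction < 1):
            raise ValueError("rain_fraction must be in [0, 1)")
        if not (0 < self.rain_position < 1):
            raise ValueError("rain_position must be in (0, 1)")

    def _get(self, param, dye: str) -> float:
        return float(param[dye]) if isinstance(param, dict) else float(param)

    def params_for(self, dye: str) -> tuple[float, float, float, float]:
        b = self._get(self.baseline_mean, dye)
        bs = self._get(self.baseline_sd, dye)
        p = self._get(self.positive_mean, dye)
        ps = self._get(self.positive_sd, dye)
        if p <= b + 4 * max(bs, ps):
            raise ValueError(f"dye {dye}: positive and baseline clusters are not separable")
        return b, bs, p, ps


@dataclass
class ChipTruth:
    """Ground truth emitted by the chip simulator."""

    chip_id: str
    lam: dict  # species name -> true mean copies/partition
    counts: dict  # species name -> per-partition template counts
    true_state: dict  # dye -> per-partition true positivity (bool array)
    dropoff_fraction: dict  # drop-off dye -> true mutant fraction among ref-bound templates

    def to_json(self, path) -> None:
        payload = {
            "chip_id": self.chip_id,
            "lam": self.lam,
            "dropoff_fraction": self.dropoff_fraction,
            "counts": {k: np.asarray(v).tolist() for k, v in self.counts.items()},
            "true_state": {k: np.asarray(v).astype(int).tolist() for k, v in self.true_state.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def make_editing_species(
    panel: ProbePanel,
    total_conc: float,
    dropoff_fraction: float,
    affected_dyes,
) -> list[AlleleSpecies]:
    """Split a locus concentration into intact and edited allele species.

    The edited species carries an indel that abolishes binding of
    ``affected_dyes`` (drop-off probes only; the reference site is by
    definition never disrupted by editing).  Concentrations sum to
    ``total_conc`` exactly.
    """
    if not (0 <= dropoff_fraction <= 1):
        raise ValueError("dropoff_fraction must be in [0, 1]")
    affected = {canonical_dye(d) for d in affected_dyes}
    if panel.reference_dye in affected:
        raise ValueError("the reference probe site cannot be an editing target")
    unknown = affected - set(panel.dyes)
    if unknown:
        raise ValueError(f"affected dyes not in panel: {sorted(unknown)}")
    intact = AlleleSpecies(
        name="intact",
        concentration=(1.0 - dropoff_fraction) * total_conc,
        binding_profile={d: True for d in panel.dyes},
    )
    edited = AlleleSpecies(
        name="edited",
        concentration=dropoff_fraction * total_conc,
        binding_profile={d: d not in affected for d in panel.dyes},
    )
    return [intact, edited]


def make_cnv_species(panel: ProbePanel, total_conc: float) -> list[AlleleSpecies]:
    """Two equal-concentration homologs, one missing the reference-probe site.

    Models a hemizygous deletion of the reference binding site: drop-off
    channels see both homologs while the reference channel sees only one,
    so the reference:drop-off concentration ratio is 1/2.
    """
    if total_conc < 0:
        raise ValueError("total_conc must be >= 0")
    half = total_conc / 2.0
    intact = AlleleSpecies(
        name="homolog_intact",
        concentration=half,
        binding_profile={d: True for d in panel.dyes},
    )
    ref_del = AlleleSpecies(
        name="homolog_ref_deleted",
        concentration=half,
        binding_profile={d: d != panel.reference_dye for d in panel.dyes},
    )
    return [intact, ref_del]


def simulate_chip(
    panel: ProbePanel,
    chip: ChipSpec,
    species,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    chip_id: str = "chip0",
) -> tuple[pd.DataFrame, ChipTruth]:
    """Simulate one dPCR chip.

    Per partition, the template count of each species is Poisson(lambda_s)
    with lambda_s = concentration_s * partition_volume; a dye channel is
    truly positive iff >=1 template of any species binding that dye is
    present; intensities are drawn from the noise model conditional on the
    true state.  Returns the partition fluorescence table (one row per
    microchamber, one intensity column per dye) and the ground truth.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    panel_dyes = set(panel.dyes)
    for s in species:
        extra = set(s.binding_profile) - panel_dyes
        if extra:
            raise ValueError(f"species {s.name!r}: dyes {sorted(extra)} not in panel")
        missing = panel_dyes - set(s.binding_profile)
        if missing:
            raise ValueError(f"species {s.name!r}: binding profile missing dyes {sorted(missing)}")

    n = chip.n_partitions
    pv = chip.partition_volume
    counts = {}
    lam = {}
    for s in species:
        lam_s = s.concentration * pv
        lam[s.name] = lam_s
        counts[s.name] = rng.poisson(lam_s, size=n)

    table = pd.DataFrame({"chip_id": chip_id, "partition_index": np.arange(n)})
    true_state = {}
    for dye in panel.dyes:
        pos = np.zeros(n, dtype=bool)
        for s in species:
            if s.binding_profile[dye]:
                pos |= counts[s.name] > 0
        true_state[dye] = pos
        b, bs, p, ps = noise.params_for(dye)
        intens = rng.normal(b, bs, size=n)
        n_pos = int(pos.sum())
        if n_pos:
            pos_int = rng.normal(p, ps, size=n_pos)
            if noise.rain_fraction > 0:
                is_rain = rng.random(n_pos) < noise.rain_fraction
                n_rain = int(is_rain.sum())
                if n_rain:
                    rain_mean = b + noise.rain_position * (p - b)
                    pos_int[is_rain] = rng.normal(rain_mean, ps, size=n_rain)
            intens[pos] = pos_int
        table[dye] = intens

    ref_dye = panel.reference_dye
    ref_total = sum(s.concentration for s in species if s.binding_profile[ref_dye])
    dropoff_fraction = {}
    for probe in panel.dropoff_probes:
        mut = sum(
            s.concentration
            for s in species
            if s.binding_profile[ref_dye] and not s.binding_profile[probe.dye]
        )
        dropoff_fraction[probe.dye] = mut / ref_total if ref_total > 0 else 0.0

    truth = ChipTruth(
        chip_id=chip_id,
        lam=lam,
        counts=counts,
        true_state=true_state,
        dropoff_fraction=dropoff_fraction,
    )
    return table, truth


# --------------------------------------------------------------------------
# amplicon read simulation


@dataclass(frozen=True)
class EditModel:
    """Editing model for the amplicon read simulator.

    ``hotspot_centers`` are amplicon-local positions (CpG sites) with
    ``hotspot_weights`` summing to 1; an edited read's position is a weighted
    hotspot center plus a discretized Gaussian(0, kernel_sd) offset.  A small
    kernel_sd reproduces the focal indel peaks seen in Nalm6 cells, a larger
    one the spread-out Reh-like pattern.  Deletions occur with probability
    ``deletion_prob`` (default 0.8: deletions dominate insertions); lengths
    are 1 + Geometric.
    """

    p_edit: float = 0.1
    hotspot_centers: tuple[int, ...] = ()
    hotspot_weights: tuple[float, ...] = ()
    kernel_sd: float = 3.0
    deletion_prob: float = 0.8
    del_length_geom_p: float = 0.4
    ins_length_geom_p: float = 0.6

    def __post_init__(self) -> None:
        if not (0 <= self.p_edit <= 1):
            raise ValueError("p_edit must be in [0, 1]")
        if not (0 <= self.deletion_prob <= 1):
            raise ValueError("deletion_prob must be in [0, 1]")
        for p in (self.del_length_geom_p, self.ins_length_geom_p):
            if not (0 < p <= 1):
                raise ValueError("geometric length parameters must be in (0, 1]")
        if not self.hotspot_centers:
            raise ValueError("at least one hotspot center is required")
        if self.hotspot_weights:
            if len(self.hotspot_weights) != len(self.hotspot_centers):
                raise ValueError("hotspot_weights must match hotspot_centers")
            if abs(sum(self.hotspot_weights) - 1.0) > 1e-9:
                raise ValueError("hotspot weights must sum to 1")
        else:
            k = len(self.hotspot_centers)
            object.__setattr__(self, "hotspot_weights", tuple(1.0 / k for _ in range(k)))


@dataclass(frozen=True)
class ReadEdit:
    """One introduced edit: position is amplicon-local; for insertions it is
    the reference position immediately after the insertion point."""

    position: int
    kind: str  # "del" | "ins"
    length: int
    inserted: str = ""


@dataclass
class ReadTruth:
    """Ground truth for a simulated read set: per-read edits (empty list for
    unedited reads) plus counts of skipped placements."""

    ref_name: str
    edits: list  # list[list[ReadEdit]], parallel to reads
    n_reads: int = 0
    n_skipped_edits: int = 0

    def deletion_start_counts(self, n_positions: int) -> np.ndarray:
        out = np.zeros(n_positions, dtype=np.int64)
        for per_read in self.edits:
            for e in per_read:
                if e.kind == "del":
                    out[e.position] += 1
        return out

    def deletion_cov_counts(self, n_positions: int) -> np.ndarray:
        out = np.zeros(n_positions, dtype=np.int64)
        for per_read in self.edits:
            for e in per_read:
                if e.kind == "del":
                    out[e.position : e.position + e.length] += 1
        return out

    def insertion_counts(self, n_positions: int) -> np.ndarray:
        out = np.zeros(n_positions, dtype=np.int64)
        for per_read in self.edits:
            for e in per_read:
                if e.kind == "ins":
                    out[e.position] += 1
        return out

    def to_json(self, path) -> None:
        payload = {
            "ref_name": self.ref_name,
            "n_reads": self.n_reads,
            "n_skipped_edits": self.n_skipped_edits,
            "edits": [
                [
                    {"position": e.position, "kind": e.kind, "length": e.length, "inserted": e.inserted}
                    for e in per_read
                ]
                for per_read in self.edits
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


_BASES = np.array(list("ACGT"))
_MAX_PLACEMENT_RETRIES = 20


def _draw_edit(rng: np.random.Generator, model: EditModel, L: int) -> ReadEdit | None:
    """Draw one edit; None if no valid placement within the retry budget."""
    centers = np.asarray(model.hotspot_centers)
    weights = np.asarray(model.hotspot_weights)
    for _ in range(_MAX_PLACEMENT_RETRIES):
        center = int(rng.choice(centers, p=weights))
        pos = center + int(round(rng.normal(0.0, model.kernel_sd)))
        if rng.random() < model.deletion_prob:
            # numpy's geometric has support {1, 2, ...}: lengths are 1 + Geom(p)
            length = int(rng.geometric(model.del_length_geom_p))
            # keep at least one aligned base on each side of the deletion
            if pos < 1 or pos + length > L - 1:
                continue
            return ReadEdit(position=pos, kind="del", length=length)
        length = int(rng.geometric(model.ins_length_geom_p))
        if pos < 1 or pos > L - 1:
            continue
        ins_seq = "".join(rng.choice(_BASES, size=length))
        return ReadEdit(position=pos, kind="ins", length=length, inserted=ins_seq)
    return None


def simulate_reads(
    ref: AmpliconRef,
    n_reads: int,
    model: EditModel,
    seed: int | None = None,
    fastq_path=None,
    sam_path=None,
    truth_path=None,
) -> ReadTruth:
    """Simulate amplicon reads with CpG-proximal indels.

    Each read covers the full amplicon and is independently edited with
    probability ``model.p_edit`` (at most one indel per read, matching a
    single NHEJ repair scar per allele).  FASTQ carries constant Q30
    qualities; SAM records encode the edits via exact CIGARs against the
    amplicon reference.  Files are written when paths are given; the truth
    record is always returned.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    L = len(ref)
    for c in model.hotspot_centers:
        if not (0 <= c < L):
            raise ValueError(f"hotspot center {c} outside amplicon of length {L}")
    rng = np.random.default_rng(seed)
    seq = ref.sequence

    edits: list[list[ReadEdit]] = []
    records = []  # (name, read_seq, cigar)
    n_skipped = 0
    edited_flags = rng.random(n_reads) < model.p_edit
    for i in range(n_reads):
        name = f"read{i:06d}"
        per_read: list[ReadEdit] = []
        if edited_flags[i]:
            edit = _draw_edit(rng, model, L)
            if edit is None:
                n_skipped += 1
                warnings.warn("edit placement failed after bounded retries; read left unedited")
            else:
                per_read.append(edit)
        if per_read:
            e = per_read[0]
            if e.kind == "del":
                read_seq = seq[: e.position] + seq[e.position + e.length :]
                cigar = f"{e.position}M{e.length}D{L - e.position - e.length}M"
            else:
                read_seq = seq[: e.position] + e.inserted + seq[e.position :]
                cigar = f"{e.position}M{e.length}I{L - e.position}M"
        else:
            read_seq = seq
            cigar = f"{L}M"
        edits.append(per_read)
        records.append((name, read_seq, cigar))

    truth = ReadTruth(ref_name=ref.name, edits=edits, n_reads=n_reads, n_skipped_edits=n_skipped)

    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            for name, read_seq, _ in records:
                fh.write(f"@{name}\n{read_seq}\n+\n{'?' * len(read_seq)}\n")
    if sam_path is not None:
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "unsorted"},
                "SQ": [{"SN": ref.name, "LN": L}],
            }
        )
        with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam:
            for name, read_seq, cigar in records:
                a = pysam.AlignedSegment(header)
                a.query_name = name
                a.query_sequence = read_seq
                a.flag = 0
                a.reference_id = 0
                a.reference_start = 0
                a.mapping_quality = 60
                a.cigarstring = cigar
                a.query_qualities = pysam.qualitystring_to_array("?" * len(read_seq))
                sam.write(a)
    if truth_path is not None:
        truth.to_json(truth_path)
    return truth
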