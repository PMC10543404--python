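"""Readers, writers and run configuration for the dPCR/AmpSeq pipeline.

File contracts
--------------
* Partition table CSV: ``chip_id, partition_index, FAM, TAMRA, Cy5, HEX``
  (one row per microchamber; ``SUN`` accepted as an alias column for HEX).
* Probe panel JSON: ``{"name": ..., "probes": [{"name", "dye", "role",
  "chrom", "start", "end", "cpg_positions"}]}`` with 0-based half-open
  intervals.
* BED (0-based half-open), FASTA and SAM v1.6 via pandas/Biopython/pysam.
* RunConfig YAML round-trips losslessly; all randomness flows from its
  explicit seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from abcquant.indels import AmpliconRef
from abcquant.panel import KNOWN_DYES, Probe, ProbePanel, canonical_dye

DEFAULT_DYES = ("FAM", "TAMRA", "Cy5", "HEX")


def read_partition_csv(path, dyes=DEFAULT_DYES) -> pd.DataFrame:
    """Read and validate a partition fluorescence table.

    Requires one numeric, finite intensity column per requested dye; unknown
    columns are preserved but ignored downstream.  Errors name the offending
    column and row.
    """
    df = pd.read_csv(path)
    df = df.rename(columns={"SUN": "HEX"})
    for d in dyes:
        if d not in df.columns:
            raise ValueError(f"{path}: missing dye column {d!r}")
        col = pd.to_numeric(df[d], errors="coerce")
        bad = col.index[~np.isfinite(col.to_numpy(dtype=float))]
        if len(bad):
            raise ValueError(f"{path}: non-numeric or non-finite intensity in column {d!r}, row {bad[0]}")
        df[d] = col
    if "partition_index" not in df.columns:
        df.insert(0, "partition_index", np.arange(len(df)))
    if "chip_id" not in df.columns:
        df.insert(0, "chip_id", Path(str(path)).stem)
    return df


def write_partition_csv(table: pd.DataFrame, path) -> None:
    cols = ["chip_id", "partition_index"] + [c for c in table.columns if c not in ("chip_id", "partition_index")]
    table[cols].to_csv(path, index=False, float_format="%.4f")


def read_panel(path) -> ProbePanel:
    """Read a probe panel from JSON; panel invariants are enforced on load."""
    with open(path) as fh:
        data = json.load(fh)
    probes = []
    for p in data["probes"]:
        dye = canonical_dye(p["dye"])
        if dye not in KNOWN_DYES:
            raise ValueError(f"{path}: probe {p.get('name')!r} has unsupported dye {p['dye']!r}")
        probes.append(
            Probe(
                name=p["name"],
                dye=dye,
                role=p["role"],
                chrom=p.get("chrom", ""),
                start=int(p.get("start", 0)),
                end=int(p.get("end", 0)),
                cpg_positions=tuple(p.get("cpg_positions", ())),
            )
        )
    return ProbePanel(name=data.get("name", Path(str(path)).stem), probes=tuple(probes))


def write_panel(panel: ProbePanel, path) -> None:
    data = {
        "name": panel.name,
        "probes": [
            {
                "name": p.name,
                "dye": p.dye,
                "role": p.role,
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "cpg_positions": list(p.cpg_positions),
            }
            for p in panel.probes
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


def read_bed(path) -> list:
    """Read a BED file (0-based half-open) into (chrom, start, end, name) tuples."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED record needs >= 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end < start:
                raise ValueError(f"{path}:{ln}: end < start")
            name = parts[3] if len(parts) > 3 else f"region{ln}"
            out.append((chrom, start, end, name))
    return out


def write_bed(records, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_amplicon_fasta(path, name: str | None = None, chrom: str = "", start: int = 0) -> AmpliconRef:
    """Read one amplicon reference from FASTA (first record unless named)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    rec = records[0]
    if name is not None:
        matches = [r for r in records if r.id == name]
        if not matches:
            raise ValueError(f"{path}: no record named {name!r}")
        rec = matches[0]
    seq = str(rec.seq).upper()
    return AmpliconRef(name=rec.id, chrom=chrom or rec.id, start=start, end=start + len(seq), sequence=seq)


def write_amplicon_fasta(ref: AmpliconRef, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{ref.name}\n")
        for i in range(0, len(ref.sequence), 70):
            fh.write(ref.sequence[i : i + 70] + "\n")


def validate_panel_against_amplicon(panel: ProbePanel, amp: AmpliconRef) -> None:
    """Cross-validation: every probe interval must lie within the amplicon span."""
    for p in panel.probes:
        if p.chrom and amp.chrom and p.chrom != amp.chrom:
            raise ValueError(f"probe {p.name!r}: chromosome {p.chrom} != amplicon {amp.chrom}")
        if p.start < amp.start or p.end > amp.end:
            raise ValueError(
                f"probe {p.name!r}: interval [{p.start}, {p.end}) outside amplicon "
                f"[{amp.start}, {amp.end})"
            )


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; round-trips losslessly via YAML."""

    n_partitions: int = 20_480
    reaction_volume: float = 9.0
    analyzed_fraction: float = 1.0
    gdna_ng: float = 10.0
    dropoff_fraction: float = 0.10
    affected_dyes: tuple = ("TAMRA",)
    n_chips: int = 3
    method: str = "difference"
    ci_level: float = 0.95
    n_boot: int = 1000
    n_perm: int = 10_000
    seed: int = 7
    cnv: bool = False
    panel: str = "crlf2"  # bundled panel name or path to a panel JSON
    out_dir: str = "results"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["affected_dyes"] = list(self.affected_dyes)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["affected_dyes"] = tuple(data.get("affected_dyes", ("TAMRA",)))
        return cls(**data)


def load_panel(name_or_path: str) -> ProbePanel:
    from abcquant import fixtures

    if name_or_path == "crlf2":
        return fixtures.crlf2_panel()
    if name_or_path == "bcl2":
        return fixtures.bcl2_panel()
    return read_panel(name_or_path)


def run_pipeline(config: RunConfig, stages=("simulate", "gate", "quantify")) -> dict:
    """Config-driven simulate -> gate -> quantify (-> cnv) pipeline.

    Deterministic given the config seed: chip i uses seed + i for simulation
    and seed + 10_000 + i for the quantification bootstrap.  Returns a
    JSON-ready report; per-stage outputs are written under ``out_dir``.
    """
    from abcquant.gating import call_thresholds, gate
    from abcquant.quantify import aggregate_quant_results, cnv_ratio, dropoff_quantify
    from abcquant.simulate import (
        ChipSpec,
        gdna_concentration,
        make_cnv_species,
        make_editing_species,
        simulate_chip,
    )

    panel = load_panel(config.panel)
    chip = ChipSpec(config.n_partitions, config.reaction_volume, config.analyzed_fraction)
    total_conc = gdna_concentration(config.gdna_ng, config.reaction_volume)
    if config.cnv:
        species = make_cnv_species(panel, total_conc)
    else:
        species = make_editing_species(panel, total_conc, config.dropoff_fraction, config.affected_dyes)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "config": config.as_dict(),
        "panel": panel.name,
        "true_concentration_total": total_conc,
        "chips": [],
    }
    quants = []
    for i in range(config.n_chips):
        chip_id = f"chip{i:02d}"
        table, truth = simulate_chip(panel, chip, species, seed=config.seed + i, chip_id=chip_id)
        thresholds = call_thresholds(table, panel.dyes)
        gr = gate(table, thresholds)
        q = dropoff_quantify(
            gr, panel, chip, method=config.method, ci_level=config.ci_level,
            n_boot=config.n_boot, seed=config.seed + 10_000 + i,
        )
        quants.append(q)
        entry = {
            "chip_id": chip_id,
            "seed": config.seed + i,
            "n_partitions": chip.n_partitions,
            "true_dropoff_fraction": truth.dropoff_fraction,
            "quant": q.to_dict(),
        }
        if config.cnv:
            cnv = cnv_ratio(q, n_boot=config.n_boot, seed=config.seed + 20_000 + i)
            entry["cnv"] = cnv.to_dict()
        report["chips"].append(entry)

    report["aggregate"] = aggregate_quant_results(quants)
    rows = [r for q in quants for r in q.to_rows()]
    pd.DataFrame(rows).to_csv(out_dir / "quant_per_chip.tsv", sep="\t", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
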