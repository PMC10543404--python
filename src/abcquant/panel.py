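"""Probe-panel model for multiplexed drop-off dPCR assays.

A panel is one amplicon interrogated by up to four hydrolysis probes, each
read on its own dye channel.  Exactly one probe is the *reference* probe: it
binds a stretch of the amplicon where no breaks have been mapped, so it
lights up in every partition that received at least one template molecule.
The remaining probes are *drop-off* probes sitting directly on mutation-prone
sites (typically CpGs): an indel under the probe abolishes binding, so mutant
amplicons are reference-positive but drop-off-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

KNOWN_DYES = ("FAM", "TAMRA", "Cy5", "HEX")

#: accepted aliases for the reference channel dye
DYE_ALIASES = {"SUN": "HEX"}


def canonical_dye(dye: str) -> str:
    """Map dye aliases (SUN -> HEX) onto canonical channel names."""
    return DYE_ALIASES.get(dye, dye)


@dataclass(frozen=True)
class Probe:
    """One hydrolysis probe of the panel.

    Coordinates are 0-based half-open genomic intervals (hg38 anchors for the
    bundled fixtures).  ``cpg_positions`` lists the genomic coordinates of
    the CpG site(s) the probe covers; empty for the reference probe.
    """

    name: str
    dye: str
    role: str  # "reference" | "dropoff"
    chrom: str = ""
    start: int = 0
    end: int = 0
    cpg_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "dye", canonical_dye(self.dye))
        if self.role not in ("reference", "dropoff"):
            raise ValueError(f"probe {self.name!r}: role must be 'reference' or 'dropoff', got {self.role!r}")
        if self.dye not in KNOWN_DYES:
            raise ValueError(f"probe {self.name!r}: unknown dye {self.dye!r}; expected one of {KNOWN_DYES}")
        if self.end < self.start:
            raise ValueError(f"probe {self.name!r}: interval end < start")


@dataclass(frozen=True)
class ProbePanel:
    """The assay design: exactly one reference probe plus >=1 drop-off probes."""

    name: str
    probes: tuple[Probe, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "probes", tuple(self.probes))
        refs = [p for p in self.probes if p.role == "reference"]
        drops = [p for p in self.probes if p.role == "dropoff"]
        if len(refs) != 1:
            raise ValueError(f"panel {self.name!r}: exactly one reference probe required, found {len(refs)}")
        if not drops:
            raise ValueError(f"panel {self.name!r}: at least one drop-off probe required")
        dyes = [p.dye for p in self.probes]
        if len(set(dyes)) != len(dyes):
            raise ValueError(f"panel {self.name!r}: dyes must be unique, got {dyes}")

    @property
    def reference(self) -> Probe:
        return next(p for p in self.probes if p.role == "reference")

    @property
    def dropoff_probes(self) -> tuple[Probe, ...]:
        return tuple(p for p in self.probes if p.role == "dropoff")

    @property
    def dyes(self) -> tuple[str, ...]:
        """Panel dyes in probe order (reference dye included)."""
        return tuple(p.dye for p in self.probes)

    @property
    def reference_dye(self) -> str:
        return self.reference.dye

    def probe_by_dye(self, dye: str) -> Probe:
        dye = canonical_dye(dye)
        for p in self.probes:
            if p.dye == dye:
                return p
        raise KeyError(f"panel {self.name!r} has no probe on dye {dye!r}")
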