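"""Synthetic assay fixtures: deterministic amplicons and probe panels.

These are synthetic stand-ins for the real assay designs (whose primer and
probe sequences are not public): amplicon sequences are generated from a
fixed seed with CpG dinucleotides placed only at designed hotspot positions,
and probe intervals are laid over them the way the real panels are laid out.

The CRLF2-like design mirrors the published geometry of that AID break
cluster: three drop-off probes (FAM, TAMRA, Cy5), each over a CpG, with two
proximal CpGs 23 bp apart and a third distal CpG ~150 bp away, plus a HEX
(SUN) reference probe over a break-free stretch.  The BCL2-like design has
two drop-off probes (FAM, Cy5) plus the reference.  Genomic anchors are
hg38-style placeholders on the true loci.
"""

from __future__ import annotations

import numpy as np

from abcquant.indels import AmpliconRef
from abcquant.panel import Probe, ProbePanel

_FIXTURE_SEED = 20480  # fixed: fixtures are designs, not random draws


def _synthetic_sequence(length: int, cpg_sites, seed: int) -> str:
    """Random sequence with CpG dinucleotides only at the given positions."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=length)
    # remove accidental CGs so the designed sites are the only CpGs
    for _ in range(4):
        s = "".join(seq)
        for i in range(length - 1):
            if s[i] == "C" and s[i + 1] == "G":
                seq[i + 1] = "A"
            s = "".join(seq)
    for p in cpg_sites:
        seq[p] = "C"
        seq[p + 1] = "G"
        # avoid creating an upstream CG run
        if p > 0 and seq[p - 1] == "C":
            seq[p - 1] = "T"
        if p + 2 < length and seq[p + 2] == "G" and seq[p + 1] == "C":
            seq[p + 2] = "A"
    return "".join(seq)


def crlf2_amplicon(length: int = 320) -> AmpliconRef:
    """CRLF2-like amplicon: CpGs at 100, 123 (proximal pair) and 250 (distal)."""
    cpgs = (100, 123, 250)
    seq = _synthetic_sequence(length, cpgs, _FIXTURE_SEED)
    start = 1_212_750  # placeholder anchor in the X/Y pseudoautosomal region
    return AmpliconRef(
        name="CRLF2_ABC_synthetic",
        chrom="chrX",
        start=start,
        end=start + length,
        sequence=seq,
        abc_intervals=((90, 260),),
        cpg_positions=cpgs,
    )


def crlf2_panel() -> ProbePanel:
    """CRLF2-like 4-plex: FAM/TAMRA/Cy5 drop-off probes on the CpGs, HEX reference."""
    amp = crlf2_amplicon()
    g = amp.start
    return ProbePanel(
        name="CRLF2_ABC_synthetic",
        probes=(
            Probe("CRLF2_ref", "HEX", "reference", amp.chrom, g + 20, g + 45),
            Probe("CRLF2_cpg1", "FAM", "dropoff", amp.chrom, g + 92, g + 112, (g + 100,)),
            Probe("CRLF2_cpg2", "TAMRA", "dropoff", amp.chrom, g + 115, g + 135, (g + 123,)),
            Probe("CRLF2_cpg3", "Cy5", "dropoff", amp.chrom, g + 242, g + 262, (g + 250,)),
        ),
    )


def bcl2_amplicon(length: int = 300) -> AmpliconRef:
    """BCL2-MBR-like amplicon: two probed CpG sites."""
    cpgs = (110, 200)
    seq = _synthetic_sequence(length, cpgs, _FIXTURE_SEED + 1)
    start = 63_123_400  # placeholder anchor in the BCL2 3' UTR / MBR
    return AmpliconRef(
        name="BCL2_MBR_synthetic",
        chrom="chr18",
        start=start,
        end=start + length,
        sequence=seq,
        abc_intervals=((100, 215),),
        cpg_positions=cpgs,
    )


def bcl2_panel() -> ProbePanel:
    """BCL2-like 3-plex: FAM and Cy5 drop-off probes plus HEX reference."""
    amp = bcl2_amplicon()
    g = amp.start
    return ProbePanel(
        name="BCL2_MBR_synthetic",
        probes=(
            Probe("BCL2_ref", "HEX", "reference", amp.chrom, g + 15, g + 40),
            Probe("BCL2_cpg1", "FAM", "dropoff", amp.chrom, g + 102, g + 122, (g + 110,)),
            Probe("BCL2_cpg2", "Cy5", "dropoff", amp.chrom, g + 192, g + 212, (g + 200,)),
        ),
    )


def probe_intervals_local(panel: ProbePanel, amp: AmpliconRef) -> list:
    """Panel probe intervals projected onto amplicon-local coordinates."""
    out = []
    for p in panel.probes:
        out.append((p.name, p.start - amp.start, p.end - amp.start))
    return out
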