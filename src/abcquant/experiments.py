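"""Study-condition workflows: simulated counterparts of the assay experiments.

Each function runs the full pipeline (chip simulation -> auto gating ->
Poisson drop-off quantification) under the conditions of one experiment and
returns the quantities the experiment reports.  The module-level constants
encode the study conditions: chip geometry (20,480 microchambers, 9 uL
reaction), template load (10 ng gDNA), the CRISPR editing levels at the
TAMRA site (~10% drop-off for the efficient guide, 5-fold less for the
weaker guide, 1000-fold less for the unedited baseline).
"""

from __future__ import annotations

import numpy as np

from abcquant.fixtures import crlf2_panel
from abcquant.gating import call_thresholds, gate, pattern_counts
from abcquant.quantify import (
    aggregate_quant_results,
    cnv_ratio,
    dropoff_quantify_from_patterns,
    pool_pattern_counts,
)
from abcquant.simulate import (
    ChipSpec,
    gdna_concentration,
    make_cnv_species,
    make_editing_species,
    simulate_chip,
)

#: TAMRA-site drop-off fraction induced by the efficient guide (sgCRLF2-1 level)
SG1_DROPOFF_FRACTION = 0.10
#: the weaker guide (sgCRLF2-3) produces 5-fold less drop-off
SG3_FOLD_LESS = 5.0
#: unedited baseline sits 1000-fold below the edited level
BASELINE_FOLD = 1000.0
#: gDNA input per reaction, ng
GDNA_NG = 10.0
#: replicate chips for the editing-recovery experiments
N_CHIPS_EDITING = 24
#: chips pooled per condition for the baseline-fold experiment (few mutant
#: events per chip, so partitions are pooled before Poisson quantification)
N_CHIPS_BASELINE = 100

DEFAULT_CHIP = ChipSpec(n_partitions=20_480, reaction_volume=9.0, analyzed_fraction=1.0)


def _subseeds(seed: int, n: int, salt: int = 0) -> list[int]:
    """Deterministic sub-seeds (< 2^31) derived from one master seed."""
    ss = np.random.SeedSequence([seed, salt])
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def simulate_sample(
    fraction: float,
    n_chips: int,
    seed: int,
    affected_dyes=("TAMRA",),
    chip: ChipSpec = DEFAULT_CHIP,
    gdna_ng: float = GDNA_NG,
    salt: int = 0,
):
    """Simulate replicate chips of one sample; return their pattern counts."""
    panel = crlf2_panel()
    conc = gdna_concentration(gdna_ng, chip.reaction_volume)
    species = make_editing_species(panel, conc, fraction, affected_dyes)
    pcs = []
    for s in _subseeds(seed, n_chips, salt=salt):
        table, _ = simulate_chip(panel, chip, species, seed=s)
        gr = gate(table, call_thresholds(table, panel.dyes))
        pcs.append(pattern_counts(gr, panel))
    return panel, pcs


def editing_recovery(
    fraction: float = SG1_DROPOFF_FRACTION,
    n_chips: int = N_CHIPS_EDITING,
    seed: int = 1,
    chip: ChipSpec = DEFAULT_CHIP,
    salt: int = 0,
) -> dict:
    """Per-chip drop-off quantification at one editing level.

    Returns the mean estimated TAMRA drop-off fraction and mutant
    concentration (copies/uL) over replicate chips.
    """
    panel, pcs = simulate_sample(fraction, n_chips, seed, chip=chip, salt=salt)
    quants = [
        dropoff_quantify_from_patterns(pc, panel, chip, n_boot=0, chip_id=f"chip{i:02d}")
        for i, pc in enumerate(pcs)
    ]
    agg = aggregate_quant_results(quants)["TAMRA"]
    return {
        "true_fraction": fraction,
        "n_chips": n_chips,
        "mean_fraction": agg["mean_fraction"],
        "sem_fraction": agg["sem_fraction"],
        "mean_copies_per_ul": agg["mean_copies_per_ul"],
        "sem_copies_per_ul": agg["sem_copies_per_ul"],
        "per_chip_fraction": [q.dropoffs["TAMRA"].fraction for q in quants],
    }


def guide_comparison(seed: int = 1) -> dict:
    """Efficient vs weak guide: ratio of estimated drop-off fractions."""
    strong = editing_recovery(SG1_DROPOFF_FRACTION, seed=seed, salt=1)
    weak = editing_recovery(SG1_DROPOFF_FRACTION / SG3_FOLD_LESS, seed=seed, salt=2)
    return {
        "strong": strong,
        "weak": weak,
        "fold_ratio": strong["mean_fraction"] / weak["mean_fraction"],
        "true_fold": SG3_FOLD_LESS,
    }


def baseline_fold(seed: int = 1, n_chips: int = N_CHIPS_BASELINE) -> dict:
    """Edited vs unedited baseline, pooling partitions across chips.

    The baseline's true fraction is 1000-fold below the edited level, so a
    single chip holds only a handful of mutant templates; pattern counts are
    pooled across chips before Poisson quantification.
    """
    chip = DEFAULT_CHIP
    panel, pcs_edit = simulate_sample(SG1_DROPOFF_FRACTION, n_chips, seed, salt=3)
    _, pcs_base = simulate_sample(SG1_DROPOFF_FRACTION / BASELINE_FOLD, n_chips, seed, salt=4)
    q_edit = dropoff_quantify_from_patterns(
        pool_pattern_counts(pcs_edit), panel, chip, n_boot=0, chip_id="edited_pool"
    )
    q_base = dropoff_quantify_from_patterns(
        pool_pattern_counts(pcs_base), panel, chip, n_boot=0, chip_id="baseline_pool"
    )
    f_edit = q_edit.dropoffs["TAMRA"].fraction
    f_base = q_base.dropoffs["TAMRA"].fraction
    return {
        "n_chips_per_condition": n_chips,
        "edited_fraction": f_edit,
        "baseline_fraction": f_base,
        "fold_increase": f_edit / f_base if f_base > 0 else float("inf"),
        "true_fold": BASELINE_FOLD,
    }


def cnv_experiment(seed: int = 1, n_boot: int = 2000, chip: ChipSpec = DEFAULT_CHIP) -> dict:
    """Hemizygous reference-site deletion: probe ratios and the CNV call."""
    panel = crlf2_panel()
    conc = gdna_concentration(GDNA_NG, chip.reaction_volume)
    species = make_cnv_species(panel, conc)
    [s] = _subseeds(seed, 1, salt=5)
    table, _ = simulate_chip(panel, chip, species, seed=s)
    gr = gate(table, call_thresholds(table, panel.dyes))
    pc = pattern_counts(gr, panel)
    q = dropoff_quantify_from_patterns(pc, panel, chip, n_boot=0)
    call = cnv_ratio(q, n_boot=n_boot, seed=s)
    return {
        "ratios": call.ratios,
        "ratio_cis": {d: list(ci) for d, ci in call.ratio_cis.items()},
        "call": call.call,
        "mean_ratio": float(np.mean(list(call.ratios.values()))),
        "total_copies_per_ul": call.total_copies_per_ul,
    }
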