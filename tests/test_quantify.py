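"""Poisson correction, drop-off estimation, co-encapsulation bias, CNV."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from abcquant import (
    ChipSpec,
    aggregate_quant_results,
    cnv_ratio,
    concentration,
    dropoff_quantify,
    dropoff_quantify_from_patterns,
    lambda_from_negatives,
    make_cnv_species,
    make_editing_species,
    pool_pattern_counts,
    pattern_counts,
)
from abcquant.quantify import naive_dropoff_fraction
from tests.conftest import simulate_truth_gate


class TestLambdaFromNegatives:
    def test_all_negative_gives_zero(self):
        est = lambda_from_negatives(20_000, 20_000)
        assert est.lam == 0.0
        assert est.ci_low == 0.0 and est.ci_high > 0

    def test_poisson_correction_value(self):
        # -ln(7358/20000) ~= 1.0
        est = lambda_from_negatives(7358, 20_000)
        assert est.lam == pytest.approx(0.99997, abs=1e-4)
        assert est.ci_low < est.lam < est.ci_high

    def test_saturated_reports_lower_bound_only(self):
        est = lambda_from_negatives(0, 20_000)
        assert est.saturated
        assert math.isinf(est.lam) and math.isinf(est.ci_high)
        assert 0 < est.ci_low < math.inf

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            lambda_from_negatives(21, 20)

    @given(st.integers(min_value=1, max_value=999))
    def test_monotone_decreasing_in_negatives(self, n_neg):
        n = 1000
        a = lambda_from_negatives(n_neg, n).lam
        b = lambda_from_negatives(n_neg + 1, n).lam
        assert b < a

    def test_ci_coverage_at_default_load(self):
        """Clopper-Pearson-derived lambda CI covers the truth ~95% of the
        time at lambda = 0.15 on a 20,480-partition chip."""
        lam, n = 0.15, 20_480
        rng = np.random.default_rng(42)
        n_neg = rng.binomial(n, math.exp(-lam), size=1000)
        covered = 0
        for k in n_neg:
            est = lambda_from_negatives(int(k), n)
            covered += est.ci_low <= lam <= est.ci_high
        assert 0.93 <= covered / 1000 <= 0.97


class TestConcentration:
    def test_zero_lambda(self, default_chip):
        est = lambda_from_negatives(100, 100)
        assert concentration(est, default_chip).lam == 0.0

    def test_default_chip_scale(self, default_chip):
        # 0.148 copies/partition on 20,480 partitions in 9 uL ~= 336.8 copies/uL
        from abcquant.quantify import LambdaEstimate

        est = LambdaEstimate(lam=0.148, ci_low=0.14, ci_high=0.156, n_neg=0, n_total=1)
        conc = concentration(est, default_chip)
        assert conc.lam == pytest.approx(0.148 * 20_480 / 9, rel=1e-12)
        assert conc.lam == pytest.approx(336.8, abs=0.2)

    def test_analyzed_fraction_scaling(self):
        from abcquant.quantify import LambdaEstimate

        est = LambdaEstimate(lam=0.2, ci_low=0.19, ci_high=0.21, n_neg=0, n_total=1)
        full = concentration(est, ChipSpec(analyzed_fraction=1.0)).lam
        half = concentration(est, ChipSpec(analyzed_fraction=0.5)).lam
        assert half == pytest.approx(2 * full)

    def test_units_scale_with_chip_geometry(self):
        from abcquant.quantify import LambdaEstimate

        est = LambdaEstimate(lam=0.3, ci_low=0.29, ci_high=0.31, n_neg=0, n_total=1)
        base = concentration(est, ChipSpec(n_partitions=20_480, reaction_volume=9.0)).lam
        double_vol = concentration(est, ChipSpec(n_partitions=20_480, reaction_volume=18.0)).lam
        double_n = concentration(est, ChipSpec(n_partitions=40_960, reaction_volume=9.0)).lam
        assert double_vol == pytest.approx(base / 2)
        assert double_n == pytest.approx(base * 2)


class TestDropoffQuantify:
    def test_no_editing_fraction_zero(self, crlf2_panel, default_chip, total_conc):
        species = make_editing_species(crlf2_panel, total_conc, 0.0, ["TAMRA"])
        gr, _ = simulate_truth_gate(crlf2_panel, default_chip, species, seed=21)
        q = dropoff_quantify(gr, crlf2_panel, default_chip, n_boot=200, seed=1)
        dq = q.dropoffs["TAMRA"]
        assert dq.fraction == pytest.approx(0.0, abs=0.02)
        assert dq.fraction_ci[0] <= 0.0 <= dq.fraction_ci[1] + 1e-12

    def test_ten_percent_editing_recovered(self, crlf2_panel, default_chip, total_conc):
        """lam_ref ~ 0.148, 10% edited -> f ~ 0.10 and C_mut ~ 33.7 copies/uL."""
        species = make_editing_species(crlf2_panel, total_conc, 0.10, ["TAMRA"])
        gr, _ = simulate_truth_gate(crlf2_panel, default_chip, species, seed=22)
        q = dropoff_quantify(gr, crlf2_panel, default_chip, n_boot=200, seed=2)
        dq = q.dropoffs["TAMRA"]
        assert dq.fraction == pytest.approx(0.10, abs=0.02)
        assert dq.conc_mut == pytest.approx(33.7, rel=0.2)
        # untargeted probes show no drop-off
        assert q.dropoffs["FAM"].fraction == pytest.approx(0.0, abs=0.02)

    def test_reference_saturated_refused(self, crlf2_panel, default_chip):
        pv = default_chip.partition_volume
        species = make_editing_species(crlf2_panel, 20.0 / pv, 0.1, ["TAMRA"])
        gr, _ = simulate_truth_gate(crlf2_panel, default_chip, species, seed=23)
        with pytest.raises(ValueError, match="saturated"):
            dropoff_quantify(gr, crlf2_panel, default_chip, n_boot=0)

    @pytest.mark.parametrize("lam_ref", [0.05, 0.15, 0.5, 1.5])
    def test_difference_and_joint_estimators_agree(
        self, crlf2_panel, default_chip, lam_ref
    ):
        """The two co-encapsulation-corrected estimators agree within the
        bootstrap CI across template loads."""
        f = 0.1
        conc = lam_ref / default_chip.partition_volume
        species = make_editing_species(crlf2_panel, conc, f, ["TAMRA"])
        gr, _ = simulate_truth_gate(crlf2_panel, default_chip, species, seed=int(lam_ref * 1000))
        qd = dropoff_quantify(gr, crlf2_panel, default_chip, method="difference", n_boot=300, seed=3)
        qj = dropoff_quantify(gr, crlf2_panel, default_chip, method="joint", n_boot=0)
        d, j = qd.dropoffs["TAMRA"], qj.dropoffs["TAMRA"]
        lo, hi = d.fraction_ci
        assert lo - 0.01 <= j.fraction <= hi + 0.01
        assert d.fraction == pytest.approx(f, abs=0.03)
        assert j.fraction == pytest.approx(f, abs=0.03)

    @pytest.mark.parametrize("f", [0.001, 0.01, 0.1, 0.5])
    @pytest.mark.parametrize("lam_ref", [0.05, 0.15, 1.5])
    def test_estimator_consistency(self, crlf2_panel, default_chip, f, lam_ref):
        """Mean bias of f-hat is within Monte-Carlo error across the grid."""
        conc = lam_ref / default_chip.partition_volume
        species = make_editing_species(crlf2_panel, conc, f, ["TAMRA"])
        n_rep = 30
        ests = []
        for r in range(n_rep):
            gr, _ = simulate_truth_gate(
                crlf2_panel, default_chip, species, seed=10_000 + 100 * r + int(lam_ref * 10)
            )
            q = dropoff_quantify(gr, crlf2_panel, default_chip, n_boot=0)
            ests.append(q.dropoffs["TAMRA"].fraction)
        ests = np.asarray(ests)
        sem = ests.std(ddof=1) / math.sqrt(n_rep)
        assert abs(ests.mean() - f) < 3.5 * sem + 1e-4

    def test_naive_estimator_biased_at_high_load(self, crlf2_panel, default_chip):
        """The uncorrected (ref+, probe-)/(ref+) estimator under-counts
        mutants when co-encapsulation is common; the correction does not."""
        f, lam_ref = 0.5, 1.5
        conc = lam_ref / default_chip.partition_volume
        species = make_editing_species(crlf2_panel, conc, f, ["TAMRA"])
        naive, corrected = [], []
        for r in range(20):
            gr, _ = simulate_truth_gate(crlf2_panel, default_chip, species, seed=30_000 + r)
            pc = pattern_counts(gr, crlf2_panel)
            naive.append(naive_dropoff_fraction(pc, crlf2_panel)["TAMRA"])
            q = dropoff_quantify_from_patterns(pc, crlf2_panel, default_chip, n_boot=0)
            corrected.append(q.dropoffs["TAMRA"].fraction)
        naive, corrected = np.asarray(naive), np.asarray(corrected)
        # expected naive value: (1 - e^-lam_mut) e^-lam_intact / (1 - e^-lam_ref)
        assert naive.mean() < 0.40  # far below the true 0.5
        assert corrected.mean() == pytest.approx(0.5, abs=0.02)

    def test_floored_negative_estimate_flagged(self, crlf2_panel, default_chip, total_conc):
        """When the probe channel carries more templates than the reference
        (reference-site deletion), the raw difference is negative; the
        estimate is floored at zero and flagged, never reported negative."""
        species = make_cnv_species(crlf2_panel, total_conc)
        gr, _ = simulate_truth_gate(crlf2_panel, default_chip, species, seed=40_000)
        q = dropoff_quantify(gr, crlf2_panel, default_chip, n_boot=0)
        for d in ("FAM", "TAMRA", "Cy5"):
            dq = q.dropoffs[d]
            assert dq.fraction == 0.0
            assert dq.floored

    def test_pooling_patterns_across_chips(self, crlf2_panel, default_chip, total_conc):
        species = make_editing_species(crlf2_panel, total_conc, 0.1, ["TAMRA"])
        pcs = []
        for r in range(5):
            gr, _ = simulate_truth_gate(crlf2_panel, default_chip, species, seed=50_000 + r)
            pcs.append(pattern_counts(gr, crlf2_panel))
        pooled = pool_pattern_counts(pcs)
        assert pooled.n_partitions == 5 * default_chip.n_partitions
        q = dropoff_quantify_from_patterns(pooled, crlf2_panel, default_chip, n_boot=0)
        assert q.dropoffs["TAMRA"].fraction == pytest.approx(0.1, abs=0.01)

    def test_aggregate_mean_sem(self, crlf2_panel, default_chip, total_conc):
        species = make_editing_species(crlf2_panel, total_conc, 0.1, ["TAMRA"])
        qs = []
        for r in range(3):
            gr, _ = simulate_truth_gate(crlf2_panel, default_chip, species, seed=60_000 + r)
            qs.append(dropoff_quantify(gr, crlf2_panel, default_chip, n_boot=0))
        agg = aggregate_quant_results(qs)
        assert agg["TAMRA"]["n_chips"] == 3
        assert agg["TAMRA"]["mean_fraction"] == pytest.approx(0.1, abs=0.02)
        assert agg["TAMRA"]["sem_fraction"] >= 0


class TestCNV:
    def test_euploid_ratio_one(self, crlf2_panel, default_chip, total_conc):
        species = make_editing_species(crlf2_panel, total_conc, 0.0, ["TAMRA"])
        gr, _ = simulate_truth_gate(crlf2_panel, default_chip, species, seed=71)
        q = dropoff_quantify(gr, crlf2_panel, default_chip, n_boot=0)
        call = cnv_ratio(q, n_boot=500, seed=5)
        for d, r in call.ratios.items():
            assert r == pytest.approx(1.0, abs=0.05)
        assert call.call == "euploid"

    def test_hemizygous_reference_half_ratio(self, crlf2_panel, default_chip, total_conc):
        """Reference-site deletion on one homolog halves the reference
        signal relative to every drop-off probe."""
        species = make_cnv_species(crlf2_panel, total_conc)
        gr, _ = simulate_truth_gate(crlf2_panel, default_chip, species, seed=72)
        q = dropoff_quantify(gr, crlf2_panel, default_chip, n_boot=0)
        call = cnv_ratio(q, n_boot=1000, seed=6)
        for d in ("FAM", "TAMRA", "Cy5"):
            assert call.ratios[d] == pytest.approx(0.5, abs=0.03)
            lo, hi = call.ratio_cis[d]
            assert lo <= 0.5 <= hi and not (lo <= 1.0 <= hi)
        assert call.call == "hemizygous-reference"
        # total-copies verification: drop-off channels see the full load
        assert call.total_copies_per_ul["TAMRA"] == pytest.approx(total_conc, rel=0.05)
        assert call.total_copies_per_ul["HEX"] == pytest.approx(total_conc / 2, rel=0.05)

    def test_bootstrap_ci_coverage(self, crlf2_panel, default_chip, total_conc):
        """~95% of bootstrap CIs cover the true ratio 0.5 over replicate chips."""
        species = make_cnv_species(crlf2_panel, total_conc)
        covered = 0
        n_rep = 120
        for r in range(n_rep):
            gr, _ = simulate_truth_gate(crlf2_panel, default_chip, species, seed=80_000 + r)
            q = dropoff_quantify(gr, crlf2_panel, default_chip, n_boot=0)
            call = cnv_ratio(q, n_boot=400, seed=r)
            lo, hi = call.ratio_cis["TAMRA"]
            covered += lo <= 0.5 <= hi
        assert 0.89 <= covered / n_rep <= 0.99
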