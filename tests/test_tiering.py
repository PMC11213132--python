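"""Anchor positions, anchor scenarios, clonality and tier assignment."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neotier import (
    AnchorMatrix,
    AnchorScenario,
    Clonality,
    InvalidArgumentError,
    PeptidePair,
    Tier,
    TierConfig,
    VariantMeasurements,
    assign_tier,
    classify_clonality,
    compute_allele_expr,
    determine_anchor_positions,
    evaluate_anchor_scenario,
    retier,
)
from neotier.report import AggregateRow

from conftest import make_allele_summary, make_summary


class TestAlleleExpr:
    @pytest.mark.parametrize("expr,vaf,expected", [(10, 0.5, 5), (7, 0, 0), (0, 0.9, 0)])
    def test_product(self, expr, vaf, expected):
        assert compute_allele_expr(expr, vaf) == expected

    def test_missing_vaf_propagates(self):
        assert compute_allele_expr(10, None) is None

    def test_vaf_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compute_allele_expr(10, 1.5)


class TestAnchorPositions:
    def test_two_symmetric_anchors(self):
        m = AnchorMatrix("A", 4, (0.45, 0.05, 0.05, 0.45))
        assert determine_anchor_positions(m, 0.8) == {1, 4}

    def test_uniform_needs_all_positions_at_full_threshold(self):
        m = AnchorMatrix("A", 9, tuple([1 / 9] * 9))
        assert determine_anchor_positions(m, 1.0) == set(range(1, 10))

    def test_single_dominant_position_suffices(self):
        m = AnchorMatrix("A", 4, (0.05, 0.85, 0.05, 0.05))
        assert determine_anchor_positions(m, 0.8) == {2}

    def test_ties_broken_by_lower_index(self):
        m = AnchorMatrix("A", 4, (0.25, 0.25, 0.25, 0.25))
        assert determine_anchor_positions(m, 0.5) == {1, 2}

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        length=st.integers(8, 11),
        seed=st.integers(0, 10_000),
        threshold=st.floats(0.1, 1.0),
    )
    def test_greedy_set_reaches_threshold_and_is_minimal(self, length, seed, threshold):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(length))
        m = AnchorMatrix("A", length, tuple(probs / probs.sum()))
        chosen = determine_anchor_positions(m, threshold)
        mass = sum(m.probabilities[p - 1] for p in chosen)
        assert mass >= threshold - 1e-9
        # dropping the least probable chosen position must break the bound
        weakest = min(chosen, key=lambda p: (m.probabilities[p - 1], -p))
        assert mass - m.probabilities[weakest - 1] < threshold

    def test_malformed_matrix_rejected(self):
        with pytest.raises(InvalidArgumentError):
            AnchorMatrix("A", 4, (0.5, 0.5, 0.5, 0.5))


def _pair(positions, length=9):
    return PeptidePair(
        mt_peptide="A" * length, wt_peptide="C" * length, length=length,
        mutation_positions=frozenset(positions),
    )


class TestAnchorScenario:
    def test_mutation_off_anchor_accepts(self):
        assert evaluate_anchor_scenario(_pair({4}), {2, 9}, wt_ic50=50) == AnchorScenario.ACCEPT

    def test_anchor_mutation_with_binding_wt_rejects(self):
        assert (
            evaluate_anchor_scenario(_pair({2}), {2, 9}, wt_ic50=50)
            == AnchorScenario.REJECT_ANCHOR
        )

    def test_anchor_mutation_with_nonbinding_wt_accepts(self):
        assert evaluate_anchor_scenario(_pair({2}), {2, 9}, wt_ic50=5000) == AnchorScenario.ACCEPT

    def test_anchor_mutation_without_wt_measurement_is_unknown(self):
        assert evaluate_anchor_scenario(_pair({2}), {2, 9}, wt_ic50=None) == AnchorScenario.UNKNOWN

    def test_mixed_anchor_and_non_anchor_positions_accept(self):
        assert (
            evaluate_anchor_scenario(_pair({2, 5}), {2, 9}, wt_ic50=50) == AnchorScenario.ACCEPT
        )

    def test_empty_anchor_set_rejected(self):
        with pytest.raises(InvalidArgumentError):
            evaluate_anchor_scenario(_pair({2}), set(), wt_ic50=50)


class TestClonality:
    def test_boundary_vaf_is_founding(self):
        assert classify_clonality(0.25, tumor_purity=1.0) == Clonality.FOUNDING

    def test_low_vaf_is_subclonal(self):
        assert classify_clonality(0.10, tumor_purity=1.0) == Clonality.SUBCLONAL

    def test_cohort_max_vaf_reference(self):
        assert classify_clonality(0.2, cohort_max_vaf=0.4) == Clonality.FOUNDING
        assert classify_clonality(0.19, cohort_max_vaf=0.4) == Clonality.SUBCLONAL

    def test_no_reference_is_unknown(self):
        assert classify_clonality(0.2) == Clonality.UNKNOWN


def _meas(**kw):
    defaults = dict(
        gene="G", dna_vaf=0.3, rna_vaf=0.5, rna_depth=50, gene_expr=10.0, tsl=1,
        tumor_purity=0.8,
    )
    defaults.update(kw)
    return VariantMeasurements(**defaults)


def _passing_summary(ic50=100.0, wt_ic50=None):
    return make_summary("AAAAAAAAA", {"A": make_allele_summary(ic50, wt_ic50=wt_ic50)})


class TestAssignTier:
    def test_everything_passing_is_pass(self):
        r = assign_tier(
            _passing_summary(), _meas(), AnchorScenario.ACCEPT, Clonality.FOUNDING
        )
        assert r.tier == Tier.PASS
        assert r.failing_criteria == ()

    def test_zero_allele_expression_is_noexpr(self):
        r = assign_tier(
            _passing_summary(), _meas(rna_vaf=0.0), AnchorScenario.ACCEPT, Clonality.FOUNDING
        )
        assert r.tier == Tier.NOEXPR

    def test_sole_anchor_failure_is_anchor(self):
        r = assign_tier(
            _passing_summary(), _meas(), AnchorScenario.REJECT_ANCHOR, Clonality.FOUNDING
        )
        assert r.tier == Tier.ANCHOR
        assert r.failing_criteria == ("anchor",)

    def test_sole_subclonality_is_subclonal(self):
        r = assign_tier(_passing_summary(), _meas(), AnchorScenario.ACCEPT, Clonality.SUBCLONAL)
        assert r.tier == Tier.SUBCLONAL

    def test_low_expression_is_lowexpr(self):
        r = assign_tier(
            _passing_summary(), _meas(gene_expr=2.0), AnchorScenario.ACCEPT, Clonality.FOUNDING
        )
        assert r.tier == Tier.LOWEXPR

    def test_binding_failure_is_poor_and_all_criteria_listed(self):
        r = assign_tier(
            _passing_summary(ic50=900.0), _meas(gene_expr=2.0),
            AnchorScenario.ACCEPT, Clonality.SUBCLONAL,
        )
        assert r.tier == Tier.POOR
        assert set(r.failing_criteria) == {"binding", "low_expression", "subclonal"}

    def test_multiple_named_categories_fail_to_poor(self):
        r = assign_tier(
            _passing_summary(), _meas(), AnchorScenario.REJECT_ANCHOR, Clonality.SUBCLONAL
        )
        assert r.tier == Tier.POOR

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        ic50=st.floats(10, 5000),
        gene_expr=st.floats(0, 20),
        rna_vaf=st.floats(0, 1),
        subclonal=st.booleans(),
        reject=st.booleans(),
        tsl=st.integers(1, 5),
        improvement=st.sampled_from(["ic50", "expr", "clonality", "scenario"]),
    )
    def test_single_criterion_improvement_never_worsens_tier(
        self, ic50, gene_expr, rna_vaf, subclonal, reject, tsl, improvement
    ):
        meas = _meas(gene_expr=gene_expr, rna_vaf=rna_vaf, tsl=tsl)
        clon = Clonality.SUBCLONAL if subclonal else Clonality.FOUNDING
        scen = AnchorScenario.REJECT_ANCHOR if reject else AnchorScenario.ACCEPT
        before = assign_tier(_passing_summary(ic50=ic50), meas, scen, clon)
        if improvement == "ic50":
            after = assign_tier(_passing_summary(ic50=ic50 / 100), meas, scen, clon)
        elif improvement == "expr":
            after = assign_tier(
                _passing_summary(ic50=ic50), _meas(gene_expr=gene_expr + 50, rna_vaf=max(rna_vaf, 0.5), tsl=tsl),
                scen, clon,
            )
        elif improvement == "clonality":
            after = assign_tier(_passing_summary(ic50=ic50), meas, scen, Clonality.FOUNDING)
        else:
            after = assign_tier(_passing_summary(ic50=ic50), meas, AnchorScenario.ACCEPT, clon)
        assert after.tier.order <= before.tier.order


def _row(**kw):
    defaults = dict(
        variant_id="chr1-100-A-T", gene="G", aa_change="p.A1V", pos_in_peptide="5",
        best_peptide="AAAAAAAAA", best_wt_peptide="CAAAAAAAA", hla_allele="A",
        ic50_mt=100.0, ic50_wt=None, lowest_ic50_mt=80.0, percentile_mt=0.5,
        gene_expr=10.0, rna_vaf=0.5, allele_expr=5.0, rna_depth=50, dna_vaf=0.3,
        tsl=1, n_passing_peptides=2, anchor_overlap="none", tier=Tier.PASS,
    )
    defaults.update(kw)
    return AggregateRow(**defaults)


class TestRetier:
    def test_raising_expression_threshold_demotes_to_lowexpr(self):
        rows = retier([_row()], TierConfig(allele_expr_threshold=7.5), tumor_purity=0.8)
        assert rows[0].tier == Tier.LOWEXPR

    def test_identical_config_is_idempotent(self):
        cfg = TierConfig()
        once = retier([_row()], cfg, tumor_purity=0.8)
        twice = retier(once, cfg, tumor_purity=0.8)
        assert [r.tier for r in once] == [r.tier for r in twice]

    def test_lowering_ic50_threshold_demotes_marginal_binders(self):
        rows = [_row(ic50_mt=100.0), _row(variant_id="chr1-200-A-T", ic50_mt=5.0)]
        out = retier(rows, TierConfig(ic50_threshold=10.0), tumor_purity=0.8)
        assert out[0].tier == Tier.POOR
        assert out[1].tier == Tier.PASS

    def test_purity_change_flips_clonality(self):
        row = _row(dna_vaf=0.1)
        high = retier([row], TierConfig(), tumor_purity=0.2)  # ref 0.1, keep founding
        low = retier([row], TierConfig(), tumor_purity=0.9)  # ref 0.45 -> subclonal
        assert high[0].tier == Tier.PASS
        assert low[0].tier == Tier.SUBCLONAL

    def test_evaluations_preserved(self):
        from neotier import Evaluation

        row = _row(evaluation=Evaluation.ACCEPT)
        out = retier([row], TierConfig(allele_expr_threshold=7.5), tumor_purity=0.8)
        assert out[0].evaluation == Evaluation.ACCEPT
        assert row.tier == Tier.PASS  # input untouched

    def test_anchor_scenario_rederived_from_overlap_and_wt(self):
        row = _row(anchor_overlap="all", ic50_wt=50.0)
        out = retier([row], TierConfig(), tumor_purity=0.8)
        assert out[0].tier == Tier.ANCHOR
        out2 = retier([row], TierConfig(wt_ic50_threshold=10.0), tumor_purity=0.8)
        assert out2[0].tier == Tier.PASS
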