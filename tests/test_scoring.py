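"""Concordance classification and the integrative driver score."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from omidriver import (
    GeneEvidence,
    TargetMap,
    ValidationError,
    aggregate_mirna,
    classify_concordance,
    integrative_score,
    score_genes,
    select_candidates,
    table1_evidence,
    table1_fixture,
)
from omidriver.datamodel import Layer
from omidriver.differential import DifferentialRecord


def mirna_rec(mid, effect, significant=True):
    return DifferentialRecord(mid, Layer.MIRNA, effect, 0.0, 0.001, 0.01, 0.5, significant)


class TestAggregateMirna:
    TARGETS = TargetMap(entries={"miR-1": frozenset({"G1"}), "miR-2": frozenset({"G1"}),
                                 "miR-3": frozenset({"G1", "G2"})})

    def test_sum_of_opposing_regulators(self):
        recs = [mirna_rec("miR-1", 3.1), mirna_rec("miR-2", 2.4), mirna_rec("miR-3", 2.53)]
        assert aggregate_mirna("G1", recs, self.TARGETS, -1) == pytest.approx(8.03)

    def test_same_direction_mirnas_do_not_count(self):
        recs = [mirna_rec("miR-1", 2.0)]
        assert aggregate_mirna("G1", recs, self.TARGETS, +1) is None

    def test_non_targeting_or_non_significant_ignored(self):
        recs = [mirna_rec("miR-1", 3.0, significant=False), mirna_rec("miR-9", 3.0)]
        assert aggregate_mirna("G1", recs, self.TARGETS, -1) is None
        assert aggregate_mirna("G9", recs, self.TARGETS, -1) is None


class TestConcordance:
    def test_down_gene_with_loss_and_opposing_mirna(self):
        # hypomethylation alongside downexpression is discordant
        e = GeneEvidence("AR", ge_fc=-4.84, cna_lr=-0.35, me_fc=-1.38, mirna_fc=8.01)
        p = classify_concordance(e)
        assert (p.cna_concordant, p.me_concordant, p.mirna_concordant) == (True, False, True)
        assert p.n_other == 2

    def test_fully_concordant_down_gene(self):
        e = GeneEvidence("IL17RD", ge_fc=-2.71, cna_lr=-0.33, me_fc=1.62, mirna_fc=8.03)
        assert classify_concordance(e).n_other == 3

    def test_absent_layers_never_concordant(self):
        assert classify_concordance(GeneEvidence("G", ge_fc=1.0)).n_other == 0

    def test_zero_expression_change_rejected(self):
        with pytest.raises(ValidationError, match="not differentially expressed"):
            classify_concordance(GeneEvidence("G", ge_fc=0.0))


class TestIntegrativeScore:
    @pytest.mark.parametrize("gene,expected", [
        ("AR", 79.20), ("FGFR2", 52.24), ("PML", 60.78),
    ])
    def test_published_rows_reproduce_exactly(self, gene, expected):
        ev = {e.gene_id: e for e in table1_evidence()}[gene]
        s = integrative_score(ev, meets_frequency=True)
        assert s.score == pytest.approx(expected, abs=1e-9)

    def test_degenerate_no_other_layers(self):
        s = integrative_score(GeneEvidence("G", ge_fc=1.0), meets_frequency=False)
        assert s.alpha == 1 and s.beta == 1 and s.score == pytest.approx(1.0)

    def test_alpha_beta_bonus_ratio(self):
        # same evidence: (alpha=2, beta=4) vs (alpha=1, beta=3) = 8/3
        e_full = GeneEvidence("G", ge_fc=-2.0, cna_lr=-0.4, me_fc=1.0, mirna_fc=3.0)
        hi = integrative_score(e_full, meets_frequency=True)
        base = (abs(e_full.ge_fc) + 0.4 + 1.0 + 3.0)
        assert hi.score == pytest.approx(base * 2 * 4)
        lo_e = GeneEvidence("G", ge_fc=-2.0, cna_lr=-0.4, me_fc=1.0, mirna_fc=None)
        lo = integrative_score(lo_e, meets_frequency=False)
        assert lo.beta == 3
        assert hi.score / lo.score == pytest.approx((8 / 3) * (base / (base - 3.0)))

    def test_discordant_layer_contributes_nothing(self):
        with_disc = GeneEvidence("G", ge_fc=2.0, cna_lr=0.5, me_fc=1.0, mirna_fc=-3.0)
        without = GeneEvidence("G", ge_fc=2.0, cna_lr=0.5, me_fc=None, mirna_fc=-3.0)
        assert integrative_score(with_disc).score == integrative_score(without).score

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(ge=st.floats(0.1, 10), cna=st.floats(0.05, 2), me=st.floats(0.05, 5),
           mi=st.floats(0.05, 10), sign=st.sampled_from([1.0, -1.0]))
    def test_sign_symmetry_and_concordant_monotonicity(self, ge, cna, me, mi, sign):
        e = GeneEvidence("G", ge_fc=sign * ge, cna_lr=sign * cna,
                         me_fc=-sign * me, mirna_fc=-sign * mi, cna_fraction=0.5)
        mirrored = GeneEvidence("G", ge_fc=-sign * ge, cna_lr=-sign * cna,
                                me_fc=sign * me, mirna_fc=sign * mi, cna_fraction=0.5)
        s = integrative_score(e)
        assert s.score == pytest.approx(integrative_score(mirrored).score)
        # adding a concordant layer never decreases the score
        fewer = GeneEvidence("G", ge_fc=sign * ge, cna_lr=sign * cna,
                             me_fc=-sign * me, mirna_fc=None, cna_fraction=0.5)
        assert s.score >= integrative_score(fewer).score
        # increasing a concordant magnitude strictly increases it
        bigger = GeneEvidence("G", ge_fc=sign * ge, cna_lr=sign * (cna + 0.1),
                              me_fc=-sign * me, mirna_fc=-sign * mi, cna_fraction=0.5)
        assert integrative_score(bigger).score > s.score


class TestTable1Oracle:
    def test_all_printed_scores_reproduce_within_rounding(self):
        fx = table1_fixture().set_index("gene")
        scored = {s.gene_id: s for s in score_genes(table1_evidence(), meets_frequency=True)}
        devs = [abs(scored[g].score - fx.score[g]) for g in fx.index]
        assert len(devs) == 47
        assert max(devs) <= 0.1

    def test_every_row_is_a_driver_at_published_cutoff(self):
        scored = score_genes(table1_evidence(), meets_frequency=True)
        drivers, passengers = select_candidates(scored, cutoff=48.72)
        assert len(drivers) == 47 and not passengers


class TestSelectCandidates:
    def scored(self, scores, n_other=2):
        out = []
        for i, sc in enumerate(scores):
            e = GeneEvidence(f"G{i}", ge_fc=1.0, cna_lr=0.2,
                             me_fc=-1.0 if n_other >= 2 else None, cna_fraction=1.0)
            s = integrative_score(e)
            s.score = sc
            out.append(s)
        return out

    def test_midpoint_cutoff(self):
        drivers, passengers = select_candidates(self.scored([10.0, 90.0]), cutoff="midpoint")
        assert drivers == {"G1"} and passengers == {"G0"}

    def test_numeric_cutoff_overrides(self):
        drivers, _ = select_candidates(self.scored([10.0, 90.0]), cutoff=5.0)
        assert drivers == {"G0", "G1"}

    def test_all_ineligible_warns_and_returns_empty(self, caplog):
        import logging
        scored = self.scored([10.0], n_other=1)
        with caplog.at_level(logging.WARNING, logger="omidriver"):
            drivers, passengers = select_candidates(scored, min_other_layers=2)
        assert drivers == set() == passengers
        assert scored[0].klass == "ineligible"
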