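"""Fold-change relevance classes, per-pair consistency scoring, the
printed-table tallies, and qPCR log2 fold changes."""

import numpy as np
import pandas as pd
import pytest

from glvnet.consensus import InteractionPair
from glvnet.models import AbundanceTable
from glvnet.validation import (
    classify_fold_change,
    expression_log2fc,
    fold_changes,
    score_consistency,
    summarize_validation,
)


def _pair(a, b, ptype, sign_ab, sign_ba):
    return InteractionPair(
        taxon_a=a, taxon_b=b, type=ptype,
        sign_ab=sign_ab, sign_ba=sign_ba,
        support_ab=0.9 if sign_ab is not None else 0.0,
        support_ba=0.9 if sign_ba is not None else 0.0,
    )


class TestFoldChangeClassification:
    @pytest.mark.parametrize(
        "fc,expected",
        [
            (10.0, "increase"),
            (9.88, "increase"),      # administered genus, single-strain trial
            (2.01, "increase"),
            (2.0, "no-difference"),  # boundary is strict
            (1.91, "no-difference"), # partner fold change in the mixed trial
            (0.5, "no-difference"),  # boundary is strict
            (0.49, "decrease"),
            (0.09, "decrease"),
        ],
    )
    def test_threshold_boundaries(self, fc, expected):
        assert classify_fold_change(fc) == expected


class TestFoldChanges:
    def test_ratio_of_group_means(self):
        treat = AbundanceTable(
            counts=pd.DataFrame({"t1": [20, 80], "t2": [20, 80]}, index=["A", "B"]))
        ctrl = AbundanceTable(
            counts=pd.DataFrame({"c1": [2, 98], "c2": [2, 98]}, index=["A", "B"]))
        records, excluded = fold_changes(treat, ctrl, group="G1")
        by = {r.taxon: r for r in records}
        assert by["A"].fold_change == pytest.approx(10.0)
        assert by["A"].relevance == "increase"
        assert not excluded

    def test_zero_abundance_taxon_excluded_and_listed(self):
        treat = AbundanceTable(
            counts=pd.DataFrame({"t1": [10, 0], "t2": [12, 0]}, index=["A", "B"]))
        ctrl = AbundanceTable(
            counts=pd.DataFrame({"c1": [10, 5], "c2": [9, 6]}, index=["A", "B"]))
        records, excluded = fold_changes(treat, ctrl)
        assert excluded == ["B"]
        assert [r.taxon for r in records] == ["A"]

    def test_swapping_groups_inverts_fold_changes(self):
        rng = np.random.default_rng(0)
        counts_a = pd.DataFrame(rng.integers(1, 200, (3, 4)), index=list("XYZ"))
        counts_b = pd.DataFrame(rng.integers(1, 200, (3, 4)), index=list("XYZ"))
        fwd, _ = fold_changes(AbundanceTable(counts=counts_a), AbundanceTable(counts=counts_b))
        rev, _ = fold_changes(AbundanceTable(counts=counts_b), AbundanceTable(counts=counts_a))
        for f, r in zip(fwd, rev):
            assert f.fold_change == pytest.approx(1 / r.fold_change)

    def test_empty_evaluable_set_raises(self):
        treat = AbundanceTable(counts=pd.DataFrame({"t1": [0, 5], "t2": [0, 6]}, index=["A", "B"]))
        ctrl = AbundanceTable(counts=pd.DataFrame({"c1": [3, 0], "c2": [4, 0]}, index=["A", "B"]))
        with pytest.raises(ValueError, match="no evaluable"):
            fold_changes(treat, ctrl)


class TestScoreConsistency:
    def _records(self, fc_by_taxon, group="G1"):
        from glvnet.validation import FoldChangeRecord, classify_fold_change

        return [
            FoldChangeRecord(
                taxon=t, group=group, fold_change=fc, dispersion=0.1,
                relevance=classify_fold_change(fc), wilcoxon_p=0.03,
            )
            for t, fc in fc_by_taxon.items()
        ]

    def test_rule_table(self):
        """Mutual partner up -> consistent; competitive partner up ->
        conflict; competitive partner flat -> no-difference."""
        pairs = [
            _pair("P", "Q", "mutual", 1, 1),
            _pair("P", "R", "competitive", -1, -1),
            _pair("P", "S", "competitive", -1, -1),
        ]
        scores = score_consistency(
            pairs, self._records({"Q": 3.0, "R": 3.0, "S": 1.2}), ["P"]
        )
        by = scores.set_index("partner")["consistency"]
        assert by["Q"] == "consistent"
        assert by["R"] == "conflict"
        assert by["S"] == "no-difference"

    def test_commensal_direction_matters(self):
        # P benefits Q: expectation applies; Q benefits P: partner untested
        toward_q = [_pair("P", "Q", "commensal", 1, None)]
        toward_p = [_pair("P", "Q", "commensal", None, 1)]
        rec = self._records({"Q": 5.0})
        assert score_consistency(toward_q, rec, ["P"])["consistency"].tolist() == ["consistent"]
        assert score_consistency(toward_p, rec, ["P"]).empty

    def test_multi_strain_group_scored_per_focal_genus(self):
        pairs = [
            _pair("P", "Q", "mutual", 1, 1),
            _pair("B", "Q", "competitive", -1, -1),
            _pair("P", "B", "mutual", 1, 1),  # between administered genera: skipped
        ]
        scores = score_consistency(pairs, self._records({"Q": 4.0}), ["P", "B"])
        assert len(scores) == 2
        assert set(scores["focal"]) == {"P", "B"}
        assert scores.set_index("focal")["consistency"].to_dict() == {
            "P": "consistent", "B": "conflict"
        }

    def test_missing_administered_genus_raises(self):
        with pytest.raises(KeyError):
            score_consistency([_pair("P", "Q", "mutual", 1, 1)], [], ["Z"])


class TestSummarizeValidation:
    def _scores(self, focal, group, consistent, conflict, nodiff):
        rows = (
            [{"focal": focal, "group": group, "consistency": "consistent"}] * consistent
            + [{"focal": focal, "group": group, "consistency": "conflict"}] * conflict
            + [{"focal": focal, "group": group, "consistency": "no-difference"}] * nodiff
        )
        return pd.DataFrame(rows)

    def test_single_strain_trial_percentages(self):
        """Percentages recompute from the printed per-genus counts of the
        first trial group at one-decimal rounding."""
        scores = pd.concat(
            [
                self._scores("Lactococcus", "G1", 34, 15, 16),     # of 65
                self._scores("Corynebacterium", "G1", 27, 18, 12),  # of 57
                self._scores("Bacillus", "G1", 24, 18, 10),         # of 52
            ],
            ignore_index=True,
        )
        summary = summarize_validation(scores)
        t = summary.table.set_index("focal")
        assert t.loc["Lactococcus", "consistent_pct"] == 52.3
        assert t.loc["Lactococcus", "conflict_pct"] == 23.1
        assert t.loc["Corynebacterium", "consistent_pct"] == 47.4
        assert t.loc["Bacillus", "consistent_pct"] == 46.2
        pooled = summary.pooled.set_index("group").loc["G1"]
        assert pooled["n_evaluable"] == 174
        assert pooled["consistent"] == 85
        assert pooled["consistent_pct"] == 48.9
        assert pooled["conflict"] == 51
        assert pooled["conflict_pct"] == 29.3

    def test_counts_partition_evaluable_total(self):
        scores = self._scores("X", "G2", 5, 3, 2)
        t = summarize_validation(scores).table.iloc[0]
        assert t["consistent"] + t["conflict"] + t["no_difference"] == t["n_evaluable"]

    def test_empty_scores_give_empty_summary(self):
        summary = summarize_validation(pd.DataFrame(columns=["focal", "group", "consistency"]))
        assert summary.table.empty


class TestExpressionLog2FC:
    def test_identical_groups_are_zero(self):
        dct = np.array([5.0, 6.0, 7.0, 8.0])
        fc, sd, p = expression_log2fc(dct, dct)
        assert fc == 0.0
        assert p == 1.0

    def test_two_cycles_lower_is_fourfold(self):
        ctrl = np.array([6.0, 7.0, 5.0, 6.5])
        fc, _, _ = expression_log2fc(ctrl - 2.0, ctrl)
        assert fc == pytest.approx(2.0)

    def test_constructed_sets_reproduce_reported_magnitude(self):
        """Delta-Ct sets whose means differ by -2.34 cycles give the
        log2 fold change reported for the single-strain spore trial."""
        ctrl = np.array([7.1, 6.4, 8.0, 6.9])
        treat = ctrl - 2.34 + np.array([0.05, -0.05, 0.1, -0.1])
        fc, sd, p = expression_log2fc(treat, ctrl)
        assert fc == pytest.approx(2.34, abs=1e-9)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            expression_log2fc([1.0], [2.0])
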