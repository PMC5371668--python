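"""Scoring probiotic-trial outcomes against an inferred interaction network.

For each taxon the trial fold change is the ratio of mean relative
abundance in the treatment group to the control group.  A fold change is
*relevant* only when strictly above 2 (increase) or strictly below 0.5
(decrease); anything in between — including exactly 2 or exactly 0.5 —
is "no-difference".

Consistency of an interaction pair {P, Q} (P administered) is judged by
the retained directed edge P -> Q: a positive effect predicts Q should
increase, a negative effect predicts a decrease.  The observed relevance
class then yields "consistent" (matches the prediction), "conflict"
(opposite relevant class), or "no-difference".  This operational rule is
an interpretation — the relevance thresholds combined with a three-way
split — and is stated as such in the docs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import InteractionPair
from .models import AbundanceTable

__all__ = [
    "FoldChangeRecord",
    "ValidationSummary",
    "fold_changes",
    "classify_fold_change",
    "score_consistency",
    "summarize_validation",
    "expression_log2fc",
]

logger = logging.getLogger(__name__)

INCREASE_THRESHOLD = 2.0
DECREASE_THRESHOLD = 0.5


@dataclass(frozen=True)
class FoldChangeRecord:
    taxon: str
    group: str
    fold_change: float
    dispersion: float  # sd of per-animal ratios to the control mean
    relevance: str  # increase | decrease | no-difference
    wilcoxon_p: float


@dataclass
class ValidationSummary:
    """Per-focal-genus consistency tallies with one-decimal percentages.

    ``table`` columns: focal, group, n_evaluable, consistent, conflict,
    no_difference and the matching ``*_pct``.  ``pooled`` aggregates the
    counts across focal genera per group.
    """

    table: pd.DataFrame
    pooled: pd.DataFrame


def classify_fold_change(fc: float) -> str:
    """Strict relevance thresholds: > 2 increase, < 0.5 decrease."""
    if fc > INCREASE_THRESHOLD:
        return "increase"
    if fc < DECREASE_THRESHOLD:
        return "decrease"
    return "no-difference"


def _relative(table: AbundanceTable) -> pd.DataFrame:
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero total count")
    return table.counts / totals


def fold_changes(
    treatment: AbundanceTable,
    control: AbundanceTable,
    taxa: list[str] | None = None,
    group: str = "",
) -> tuple[list[FoldChangeRecord], list[str]]:
    """Per-taxon treatment/control fold changes with Wilcoxon rank-sum p.

    Taxa whose counts are zero across all samples of either group are
    excluded and returned in the second element.  The test is the
    two-sided rank-sum on per-animal relative abundances (exact null for
    the small group sizes typical of feeding trials, mid-ranks on ties).
    """
    if treatment.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    rel_t = _relative(treatment)
    rel_c = _relative(control)
    if taxa is None:
        taxa = [t for t in treatment.taxa if t in set(control.taxa)]
    records: list[FoldChangeRecord] = []
    excluded: list[str] = []
    for taxon in taxa:
        if taxon not in rel_t.index or taxon not in rel_c.index:
            excluded.append(taxon)
            continue
        t_vals = rel_t.loc[taxon].to_numpy()
        c_vals = rel_c.loc[taxon].to_numpy()
        mean_t, mean_c = t_vals.mean(), c_vals.mean()
        if mean_t == 0 or mean_c == 0:
            excluded.append(taxon)
            continue
        fc = mean_t / mean_c
        try:
            p = float(
                stats.mannwhitneyu(t_vals, c_vals, alternative="two-sided").pvalue
            )
        except ValueError:
            p = 1.0
        records.append(
            FoldChangeRecord(
                taxon=taxon,
                group=group,
                fold_change=fc,
                dispersion=float((t_vals / mean_c).std(ddof=1)),
                relevance=classify_fold_change(fc),
                wilcoxon_p=p,
            )
        )
    if not records:
        raise ValueError("no evaluable taxa left after zero-abundance exclusions")
    return records, excluded


def score_consistency(
    iips: list[InteractionPair],
    fold_change_records: list[FoldChangeRecord],
    administered: list[str],
) -> pd.DataFrame:
    """Class each evaluable partner of the administered genera.

    Returns a frame with columns focal, partner, pair_type, expected,
    observed, consistency.  A pair contributes one row per administered
    genus it touches (multi-strain groups are evaluated per focal genus).
    Partners with no retained edge directed at them are skipped and
    logged.
    """
    fc_by_taxon = {r.taxon: r for r in fold_change_records}
    iip_taxa = {t for p in iips for t in (p.taxon_a, p.taxon_b)}
    missing = [g for g in administered if g not in iip_taxa]
    if missing:
        raise KeyError(f"administered genera absent from the IIP set: {missing}")
    rows = []
    for focal in administered:
        for pair in iips:
            if not pair.touches(focal):
                continue
            partner = pair.partner_of(focal)
            if partner in administered:
                continue  # co-administered genera are perturbed, not read-outs
            record = fc_by_taxon.get(partner)
            if record is None:
                continue  # excluded (zero abundance) or not measured
            effect = pair.effect_on(partner)
            if effect is None:
                logger.info(
                    "pair (%s, %s): no retained edge toward %s; skipped",
                    pair.taxon_a,
                    pair.taxon_b,
                    partner,
                )
                continue
            expected = "increase" if effect > 0 else "decrease"
            observed = record.relevance
            if observed == expected:
                consistency = "consistent"
            elif observed == "no-difference":
                consistency = "no-difference"
            else:
                consistency = "conflict"
            rows.append(
                {
                    "focal": focal,
                    "partner": partner,
                    "pair_type": pair.type,
                    "expected": expected,
                    "observed": observed,
                    "consistency": consistency,
                    "fold_change": record.fold_change,
                    "wilcoxon_p": record.wilcoxon_p,
                    "group": record.group,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "focal",
            "partner",
            "pair_type",
            "expected",
            "observed",
            "consistency",
            "fold_change",
            "wilcoxon_p",
            "group",
        ],
    )


def summarize_validation(scores: pd.DataFrame) -> ValidationSummary:
    """Tally consistency classes per focal genus x group, with pooled rows.

    Percentages are rounded to one decimal and recompute from the counts.
    """
    classes = ["consistent", "conflict", "no-difference"]
    if scores.empty:
        empty = pd.DataFrame(
            columns=["focal", "group", "n_evaluable"]
            + [c.replace("-", "_") for c in classes]
            + [c.replace("-", "_") + "_pct" for c in classes]
        )
        return ValidationSummary(table=empty, pooled=empty.drop(columns=["focal"], errors="ignore"))

    def tally(frame: pd.DataFrame) -> dict[str, float]:
        n = len(frame)
        out: dict[str, float] = {"n_evaluable": n}
        for cls in classes:
            count = int((frame["consistency"] == cls).sum())
            key = cls.replace("-", "_")
            out[key] = count
            out[key + "_pct"] = round(100.0 * count / n, 1) if n else 0.0
        return out

    rows = []
    for (focal, group), sub in scores.groupby(["focal", "group"], sort=False):
        rows.append({"focal": focal, "group": group, **tally(sub)})
    table = pd.DataFrame(rows)

    pooled_rows = []
    for group, sub in scores.groupby("group", sort=False):
        pooled_rows.append({"group": group, **tally(sub)})
    pooled = pd.DataFrame(pooled_rows)
    return ValidationSummary(table=table, pooled=pooled)


def expression_log2fc(
    delta_ct_treatment: np.ndarray,
    delta_ct_control: np.ndarray,
    paired: bool = True,
) -> tuple[float, float, float]:
    """Log2 expression fold change from housekeeping-normalized Ct values.

    Follows the ddCt convention: with dCt = Ct(target) - Ct(housekeeping)
    per animal, log2FC = -(mean dCt_treatment - mean dCt_control).  Returns
    (log2FC, sd, p) where sd is across per-animal ddCt values (paired) or
    propagated group sds (unpaired), and p is from a two-sided paired or
    two-sample t-test.
    """
    t = np.asarray(delta_ct_treatment, dtype=float)
    c = np.asarray(delta_ct_control, dtype=float)
    if len(t) < 2 or len(c) < 2:
        raise ValueError("need n >= 2 per group")
    log2fc = -(t.mean() - c.mean())
    if paired:
        if len(t) != len(c):
            raise ValueError("paired analysis needs equal group sizes")
        ddct = -(t - c)
        sd = float(ddct.std(ddof=1))
        if np.allclose(t, c):
            p = 1.0
        else:
            p = float(stats.ttest_rel(t, c).pvalue)
    else:
        sd = float(np.sqrt(t.var(ddof=1) + c.var(ddof=1)))
        p = float(stats.ttest_ind(t, c).pvalue)
    return float(log2fc), sd, p
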