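"""Alpha diversity, Bray-Curtis dissimilarity, rarefaction and
between-time-point tests.

Shannon entropy is reported in nats; "Simpson index" means the
Gini-Simpson index 1 - sum(p^2), so the inverse Simpson index satisfies
``inverse_simpson = 1 / (1 - simpson)`` and the Hill ordering
``exp(shannon) >= inverse_simpson`` holds for every composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis as _scipy_braycurtis

__all__ = [
    "DiversityRecord",
    "alpha_diversity",
    "bray_curtis",
    "compare_timepoints",
    "rarefaction_curve",
    "diversity_table",
]


@dataclass(frozen=True)
class DiversityRecord:
    label: str
    richness: int
    shannon: float
    simpson: float
    inverse_simpson: float


def alpha_diversity(proportions: np.ndarray, label: str = "") -> DiversityRecord:
    """Richness, Shannon (nats), Gini-Simpson and inverse Simpson indices."""
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportions must sum to 1, got {p.sum()}")
    nz = p[p > 0]
    shannon = float(-(nz * np.log(nz)).sum())
    sum_sq = float((nz**2).sum())
    return DiversityRecord(
        label=label,
        richness=int((p > 0).sum()),
        shannon=shannon,
        simpson=1.0 - sum_sq,
        inverse_simpson=1.0 / sum_sq,
    )


def bray_curtis(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum_a + sum_b), in [0, 1]."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples must share one taxon set")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("values must be non-negative")
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero samples")
    return float(_scipy_braycurtis(a, b))


def compare_timepoints(
    values_a: np.ndarray, values_b: np.ndarray, test: str = "student"
) -> tuple[float, float]:
    """Two-sided two-sample t-test between two groups of per-animal values.

    ``student`` pools variances (the classical two-sample test);
    ``welch`` drops the equal-variance assumption.  Two degenerate
    zero-variance groups with equal means are reported as (t=0, p=1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if test not in ("student", "welch"):
        raise ValueError("test must be 'student' or 'welch'")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    res = stats.ttest_ind(a, b, equal_var=(test == "student"))
    return float(res.statistic), float(res.pvalue)


def rarefaction_curve(
    counts: np.ndarray, depths: list[int], reps: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Mean observed taxa under subsampling without replacement.

    Each replicate draws a multivariate-hypergeometric subsample of the
    requested depth from the full count vector and counts the taxa seen.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    rng = np.random.default_rng(seed)
    records = []
    for depth in depths:
        if depth > total:
            raise ValueError(f"depth {depth} exceeds sample total {total}")
        observed = np.empty(reps)
        for r in range(reps):
            sub = rng.multivariate_hypergeometric(counts, depth)
            observed[r] = (sub > 0).sum()
        records.append((depth, observed.mean(), observed.std(ddof=0)))
    return pd.DataFrame(records, columns=["depth", "mean_observed", "sd_observed"])


def diversity_table(props: pd.DataFrame, times: pd.Series | None = None) -> pd.DataFrame:
    """Per-sample alpha-diversity records, with per-time mean +/- se when
    ``times`` is given (one value per sample column)."""
    rows = []
    for sample in props.columns:
        rec = alpha_diversity(props[sample].to_numpy(), label=str(sample))
        rows.append(
            {
                "sample": rec.label,
                "richness": rec.richness,
                "shannon": rec.shannon,
                "simpson": rec.simpson,
                "inverse_simpson": rec.inverse_simpson,
            }
        )
    table = pd.DataFrame(rows).set_index("sample")
    if times is None:
        return table
    table["time"] = np.asarray(times, dtype=float)
    grouped = table.groupby("time")
    summary = grouped.mean()
    n = grouped.size()
    se = grouped.std(ddof=1).div(np.sqrt(n), axis=0)
    se.columns = [f"{c}_se" for c in se.columns]
    return summary.join(se)
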