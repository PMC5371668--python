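"""Consensus network construction and interaction-type classification.

The inference is replicated on bootstrap resamples of the regression
intervals; in each replicate only the strongest fraction of directed
relationships (by absolute coefficient, global rank) is retained, and a
directed edge enters the consensus network only if it survives in at
least ``cutoff`` of the replicates with a stable majority sign.

Unordered pairs with at least one retained edge are classified into the
ecological types: (+,+) mutual, (-,-) competitive, (+, absent)
commensal, (-, absent) amensal.  Opposite-sign pairs (+,-) are
exploitative and reported as a separate fifth class outside the
four-type tally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glv import choose_lambda, fit_glv
from .models import RegressionSystem, TimeSeriesProfile

__all__ = [
    "EdgeTallies",
    "ConsensusNetwork",
    "InteractionPair",
    "replicate_inference",
    "build_consensus",
    "classify_pairs",
    "partner_subnetwork",
    "type_counts",
]

logger = logging.getLogger(__name__)

FOUR_TYPES = ("commensal", "amensal", "mutual", "competitive")


@dataclass
class EdgeTallies:
    """Per-directed-edge bookkeeping across inference replicates."""

    taxa: list[str]
    replicates: int
    # (source, target) -> [retained, positive, negative, coefficient sum]
    counts: dict[tuple[str, str], list[float]] = field(default_factory=dict)

    def record(self, source: str, target: str, coeff: float) -> None:
        entry = self.counts.setdefault((source, target), [0, 0, 0, 0.0])
        entry[0] += 1
        if coeff > 0:
            entry[1] += 1
        elif coeff < 0:
            entry[2] += 1
        entry[3] += coeff


@dataclass
class ConsensusNetwork:
    """Directed signed edges that survived the support cutoff.

    ``edges`` columns: source, target, sign (+1/-1), support (fraction of
    replicates), mean_coeff.  Edge source->target means "source affects
    target".
    """

    taxa: list[str]
    edges: pd.DataFrame
    replicates: int

    def __post_init__(self) -> None:
        required = {"source", "target", "sign", "support", "mean_coeff"}
        missing = required - set(self.edges.columns)
        if missing:
            raise ValueError(f"edges frame missing columns: {sorted(missing)}")

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str, int, float, float]],
        taxa: list[str] | None = None,
        replicates: int = 1,
    ) -> "ConsensusNetwork":
        frame = pd.DataFrame(
            edges, columns=["source", "target", "sign", "support", "mean_coeff"]
        )
        if taxa is None:
            taxa = sorted(set(frame["source"]) | set(frame["target"]))
        return cls(taxa=taxa, edges=frame, replicates=replicates)

    def edge_lookup(self) -> dict[tuple[str, str], tuple[int, float]]:
        return {
            (r.source, r.target): (int(r.sign), float(r.support))
            for r in self.edges.itertuples()
        }


@dataclass(frozen=True)
class InteractionPair:
    """An unordered taxon pair with its directed signs and ecological type."""

    taxon_a: str
    taxon_b: str
    type: str
    sign_ab: int | None  # effect of a on b (edge a->b), None if absent
    sign_ba: int | None
    support_ab: float
    support_ba: float

    def effect_on(self, taxon: str) -> int | None:
        """Sign of the retained edge pointing at ``taxon``, if any."""
        if taxon == self.taxon_b:
            return self.sign_ab
        if taxon == self.taxon_a:
            return self.sign_ba
        raise KeyError(f"{taxon!r} not in pair ({self.taxon_a}, {self.taxon_b})")

    def partner_of(self, taxon: str) -> str:
        if taxon == self.taxon_a:
            return self.taxon_b
        if taxon == self.taxon_b:
            return self.taxon_a
        raise KeyError(f"{taxon!r} not in pair ({self.taxon_a}, {self.taxon_b})")

    def touches(self, taxon: str) -> bool:
        return taxon in (self.taxon_a, self.taxon_b)


_TYPE_SIGNS = {
    "mutual": (1, 1),
    "competitive": (-1, -1),
    "commensal": (1, None),
    "amensal": (-1, None),
    "exploitative": (1, -1),
}


def network_from_type_counts(
    counts: dict[str, int],
    focal: str | None = None,
    support: float = 1.0,
) -> ConsensusNetwork:
    """A synthetic consensus network realizing exact per-type pair counts.

    With ``focal`` set, every pair joins the focal taxon to a fresh
    partner (a star, for partner-breakdown bookkeeping); otherwise pairs
    are laid out over a pool of fresh taxa.  Useful for checks whose
    expected values are pure tallies of a known composition.
    """
    edges: list[tuple[str, str, int, float, float]] = []
    k = 0
    for ptype, n in counts.items():
        s_ab, s_ba = _TYPE_SIGNS[ptype]
        for _ in range(n):
            if focal is not None:
                a, b = focal, f"partner_{k:05d}"
            else:
                a, b = f"taxon_{2 * k:05d}", f"taxon_{2 * k + 1:05d}"
            k += 1
            edges.append((a, b, s_ab, support, float(s_ab)))
            if s_ba is not None:
                edges.append((b, a, s_ba, support, float(s_ba)))
    return ConsensusNetwork.from_edges(edges)


def _retain_top(interactions: np.ndarray, top_fraction: float) -> np.ndarray:
    """Boolean mask of off-diagonal entries in the top |a| fraction (global rank)."""
    n = interactions.shape[0]
    off = ~np.eye(n, dtype=bool)
    mags = np.abs(interactions[off])
    m = mags.size
    k = min(m, max(1, int(np.floor(top_fraction * m + 1e-9))))
    threshold = np.sort(mags)[::-1][k - 1]
    mask = (np.abs(interactions) >= threshold) & off
    # Ties at the threshold could overfill; trim deterministically by magnitude.
    if mask.sum() > k:
        idx = np.argwhere(mask)
        order = np.argsort(-np.abs(interactions[mask]), kind="stable")
        mask = np.zeros_like(mask)
        for row in idx[order[:k]]:
            mask[row[0], row[1]] = True
    return mask


def replicate_inference(
    profile: TimeSeriesProfile | RegressionSystem,
    R: int = 100,
    top_fraction: float = 0.25,
    seed: int = 0,
    lam: float | None = None,
    jitter_lambda: bool = False,
) -> EdgeTallies:
    """Bootstrap the gradient-matching fit and tally surviving edges.

    Each replicate resamples regression intervals with replacement, refits
    the gLV coefficients, and keeps the ``top_fraction`` of directed
    relationships by absolute coefficient.  ``lam=None`` selects the ridge
    penalty once by leave-one-interval-out cross-validation;
    ``jitter_lambda`` additionally varies it +/-25% per replicate.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    from .glv import build_regression_system

    if isinstance(profile, TimeSeriesProfile):
        system = build_regression_system(profile)
    else:
        system = profile
    if lam is None:
        lam = choose_lambda(system)

    rng = np.random.default_rng(seed)
    taxa = system.taxa
    m = system.n_intervals
    tallies = EdgeTallies(taxa=list(taxa), replicates=R)
    for _ in range(R):
        idx = rng.integers(0, m, size=m)
        if len(np.unique(idx)) == 1:
            logger.warning("degenerate bootstrap replicate: all intervals identical")
        boot = RegressionSystem(
            taxa=list(taxa),
            design=system.design[idx],
            responses=system.responses[:, idx],
            dt=system.dt[idx],
        )
        lam_r = lam * rng.uniform(0.75, 1.25) if jitter_lambda else lam
        try:
            with warnings.catch_warnings():
                # bootstrap resamples routinely lose self-limitation; the
                # clamp inside fit_glv is expected here, not noteworthy
                warnings.simplefilter("ignore", UserWarning)
                model = fit_glv(boot, lam=max(lam_r, 1e-12))
        except np.linalg.LinAlgError:
            continue
        mask = _retain_top(model.interactions, top_fraction)
        for i, j in np.argwhere(mask):
            # a[i, j]: j affects i, so the directed edge is j -> i
            tallies.record(taxa[j], taxa[i], model.interactions[i, j])
    return tallies


def build_consensus(
    tallies: EdgeTallies, cutoff: float = 0.5, R: int | None = None
) -> ConsensusNetwork:
    """Keep edges with support >= cutoff and a stable majority sign.

    Support is the fraction of replicates retaining the edge; an exact
    tie between positive and negative retentions drops the edge (a
    consensus edge must have an interpretable sign).
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must be in (0, 1]")
    if R is None:
        R = tallies.replicates
    rows = []
    for (source, target), (kept, pos, neg, coeff_sum) in tallies.counts.items():
        support = kept / R
        if support < cutoff:
            continue
        if pos == neg:
            logger.info("sign tie for edge %s->%s; dropped", source, target)
            continue
        sign = 1 if pos > neg else -1
        rows.append((source, target, sign, support, coeff_sum / kept))
    frame = pd.DataFrame(
        rows, columns=["source", "target", "sign", "support", "mean_coeff"]
    )
    return ConsensusNetwork(taxa=list(tallies.taxa), edges=frame, replicates=R)


def classify_pairs(network: ConsensusNetwork) -> list[InteractionPair]:
    """Type every unordered pair with at least one retained directed edge."""
    lookup = network.edge_lookup()
    pairs: dict[tuple[str, str], InteractionPair] = {}
    seen = {tuple(sorted(key)) for key in lookup}
    for a, b in sorted(seen):
        sign_ab, support_ab = lookup.get((a, b), (None, 0.0))
        sign_ba, support_ba = lookup.get((b, a), (None, 0.0))
        signs = {sign_ab, sign_ba}
        if signs == {1}:
            ptype = "mutual"
        elif signs == {-1}:
            ptype = "competitive"
        elif signs == {1, -1}:
            ptype = "exploitative"
        elif 1 in signs:
            ptype = "commensal"
        else:
            ptype = "amensal"
        pairs[(a, b)] = InteractionPair(
            taxon_a=a,
            taxon_b=b,
            type=ptype,
            sign_ab=sign_ab,
            sign_ba=sign_ba,
            support_ab=support_ab,
            support_ba=support_ba,
        )
    return list(pairs.values())


def type_counts(pairs: list[InteractionPair]) -> dict[str, int]:
    counts = {t: 0 for t in FOUR_TYPES + ("exploitative",)}
    for p in pairs:
        counts[p.type] += 1
    return counts


def partner_subnetwork(
    pairs: list[InteractionPair], focal: list[str]
) -> tuple[list[InteractionPair], pd.DataFrame]:
    """Pairs touching any focal taxon, plus a per-focal type breakdown."""
    all_taxa = {t for p in pairs for t in (p.taxon_a, p.taxon_b)}
    unknown = [f for f in focal if f not in all_taxa]
    if unknown:
        raise KeyError(f"focal taxa not in network: {unknown}")
    subset = [p for p in pairs if any(p.touches(f) for f in focal)]
    rows = []
    for f in focal:
        counts = type_counts([p for p in subset if p.touches(f)])
        counts["focal"] = f
        counts["total"] = sum(v for k, v in counts.items() if k != "focal")
        rows.append(counts)
    breakdown = pd.DataFrame(rows).set_index("focal")
    return subset, breakdown


def pairs_to_frame(pairs: list[InteractionPair]) -> pd.DataFrame:
    """IIP table: taxonA, taxonB, type, directed signs and supports."""
    return pd.DataFrame(
        [
            {
                "taxon_a": p.taxon_a,
                "taxon_b": p.taxon_b,
                "type": p.type,
                "sign_a_to_b": p.sign_ab,
                "sign_b_to_a": p.sign_ba,
                "support_a_to_b": p.support_ab,
                "support_b_to_a": p.support_ba,
            }
            for p in pairs
        ]
    )
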