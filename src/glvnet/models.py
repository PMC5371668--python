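"""Core containers shared across the pipeline.

Conventions used throughout:

* The interaction matrix ``A`` stores ``a[i, j]``, the per-unit-abundance
  effect of taxon *j* on taxon *i* (units: 1/day per relative-abundance
  unit).  A directed edge ``j -> i`` therefore corresponds to ``a[i, j]``.
* Abundance profiles are compositional: every time column sums to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GLVModel",
    "TimeSeriesProfile",
    "AbundanceTable",
    "TrialDesign",
    "RegressionSystem",
]


@dataclass
class GLVModel:
    """A generalized Lotka-Volterra community model.

    dx_i/dt = x_i * (b_i + sum_j a_ij x_j)

    Parameters
    ----------
    taxa
        Ordered taxon labels.
    growth_rates
        Intrinsic per-capita growth rates ``b_i`` (1/day).
    interactions
        Square matrix with ``a[i, j]`` = effect of taxon ``j`` on taxon
        ``i``.  Diagonal entries must be strictly negative
        (self-limitation).
    """

    taxa: list[str]
    growth_rates: np.ndarray
    interactions: np.ndarray

    def __post_init__(self) -> None:
        self.growth_rates = np.asarray(self.growth_rates, dtype=float)
        self.interactions = np.asarray(self.interactions, dtype=float)
        n = len(self.taxa)
        if self.interactions.shape != (n, n):
            raise ValueError(
                f"interaction matrix shape {self.interactions.shape} does not "
                f"match {n} taxa"
            )
        if self.growth_rates.shape != (n,):
            raise ValueError("growth_rates length must match taxa")
        if not np.all(np.isfinite(self.interactions)) or not np.all(
            np.isfinite(self.growth_rates)
        ):
            raise ValueError("model parameters must be finite")
        if np.any(np.diag(self.interactions) >= 0):
            raise ValueError("diagonal interaction entries must be strictly negative")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def to_edge_frame(self) -> pd.DataFrame:
        """Flatten the interaction matrix to a (source, target, coefficient) table."""
        rows = []
        for i, target in enumerate(self.taxa):
            for j, source in enumerate(self.taxa):
                if i == j:
                    continue
                rows.append((source, target, self.interactions[i, j]))
        return pd.DataFrame(rows, columns=["source", "target", "coefficient"])


@dataclass
class TimeSeriesProfile:
    """Relative-abundance trajectory of a community.

    ``abundances`` is taxa x times; every column sums to one.
    """

    taxa: list[str]
    times: np.ndarray
    abundances: np.ndarray
    #: False marks an absolute-abundance trajectory (simulation diagnostics);
    #: the inference path always works on normalized profiles.
    normalized: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (len(self.taxa), len(self.times)):
            raise ValueError("abundances must be (n_taxa, n_times)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")
        if self.normalized:
            sums = self.abundances.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValueError("each time column must sum to 1 (within 1e-9)")

    @property
    def n_times(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundances, index=self.taxa, columns=self.times)


@dataclass
class AbundanceTable:
    """Taxa-by-sample count table with optional per-sample metadata.

    ``counts`` rows are indexed by taxon label (a rank-prefixed lineage
    string before genus collapse, a bare genus name after), columns by
    sample label.  ``metadata``, when present, is indexed by sample label
    and covers every sample (columns such as ``time`` or ``group``).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate taxon labels: {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample labels: {dups}")
        if (self.counts.to_numpy() < 0).any():
            bad = np.argwhere(self.counts.to_numpy() < 0)[0]
            raise ValueError(
                f"negative count at taxon {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )
        if self.metadata is not None:
            missing = set(self.counts.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(f"metadata missing for samples: {sorted(missing)}")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class TrialDesign:
    """Layout of a probiotic feeding trial.

    ``administered`` maps each group label to the list of genera dosed in
    that group; the control group maps to an empty list.
    """

    groups: list[str]
    administered: dict[str, list[str]]
    n_per_group: int = 4
    boost: float = 15.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        controls = [g for g in self.groups if not self.administered.get(g)]
        if not controls:
            raise ValueError("design needs a control group with no administered genera")

    @property
    def control_group(self) -> str:
        return next(g for g in self.groups if not self.administered.get(g))


@dataclass
class RegressionSystem:
    """Gradient-matching regression layout for one profile.

    For consecutive sampling intervals ``(t_k, t_{k+1})`` the per-taxon
    response is the log-abundance growth rate
    ``y_i(k) = (ln x_i(t_{k+1}) - ln x_i(t_k)) / (t_{k+1} - t_k)``
    and the shared design row is ``[1, x_1(t_k), ..., x_n(t_k)]``.
    """

    taxa: list[str]
    design: np.ndarray  # (n_intervals, n_taxa + 1), leading intercept column
    responses: np.ndarray  # (n_taxa, n_intervals)
    dt: np.ndarray  # (n_intervals,) interval widths in days

    def __post_init__(self) -> None:
        n_int = self.design.shape[0]
        if self.responses.shape != (len(self.taxa), n_int):
            raise ValueError("responses must be (n_taxa, n_intervals)")
        if self.design.shape[1] != len(self.taxa) + 1:
            raise ValueError("design must have n_taxa + 1 columns")
        if self.dt.shape != (n_int,):
            raise ValueError("dt must have one entry per interval")

    @property
    def n_intervals(self) -> int:
        return self.design.shape[0]
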