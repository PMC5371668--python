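"""Ground-truth community generators.

Everything downstream of the raw-read pipeline is testable against data
built here: a random gLV system with a known mixture of pairwise
interaction types, its simulated time series under multiplicative noise,
multinomial read counts at a configurable sequencing depth, and
probiotic-trial count tables whose fold-change structure follows the
ground-truth network.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import AbundanceTable, GLVModel, TimeSeriesProfile, TrialDesign

__all__ = [
    "PAIR_TYPES",
    "DEFAULT_TIMES",
    "sample_interaction_matrix",
    "simulate_glv",
    "counts_from_profile",
    "generate_trial",
    "expected_trial_composition",
    "sample_planted_matrix",
    "planted_fanin_graph",
    "write_ground_truth_edges",
]

#: Pairwise ecological types and the joint sign pattern (effect on A, effect on B)
#: they impose on the two directed coefficients of an unordered pair.
PAIR_TYPES = ("mutual", "competitive", "commensal", "amensal", "none")

_SIGNS = {
    "mutual": (1, 1),
    "competitive": (-1, -1),
    "commensal": (1, 0),
    "amensal": (-1, 0),
    "none": (0, 0),
}

#: Sampling schedule of the emulated study: 12 points over 15 days with a
#: long pre-perturbation gap, then 6 h and 12 h spacing.
DEFAULT_TIMES = np.array(
    [1.0, 11.0, 11.25, 11.5, 11.75, 12.0, 12.5, 13.0, 13.5, 14.0, 14.5, 15.0]
)

EXTINCTION_FLOOR = 1e-8
OVERFLOW_GUARD = 1e6


def _allocate_pair_counts(n_pairs: int, mixture: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of pair types so counts are exact."""
    raw = {t: mixture.get(t, 0.0) * n_pairs for t in PAIR_TYPES}
    counts = {t: int(math.floor(v)) for t, v in raw.items()}
    short = n_pairs - sum(counts.values())
    by_rem = sorted(PAIR_TYPES, key=lambda t: raw[t] - counts[t], reverse=True)
    for t in by_rem[:short]:
        counts[t] += 1
    return counts


def sample_interaction_matrix(
    n_taxa: int,
    type_mixture: dict[str, float],
    magnitude_range: tuple[float, float] = (0.3, 1.0),
    seed: int = 0,
    growth_rate_range: tuple[float, float] = (0.2, 0.8),
    self_limitation_range: tuple[float, float] = (1.0, 2.0),
    taxa: list[str] | None = None,
) -> GLVModel:
    """Draw a gLV model whose pair types realize ``type_mixture`` exactly.

    Unordered pairs are assigned to types by permutation (largest-remainder
    apportionment of the requested proportions over C(n,2) pairs), so the
    realized type counts match the request exactly rather than in
    expectation.  Coefficient magnitudes are uniform on
    ``magnitude_range``; which member of the pair receives the nonzero
    effect in asymmetric types (commensal/amensal) is randomized.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    unknown = set(type_mixture) - set(PAIR_TYPES)
    if unknown:
        raise ValueError(f"unknown interaction types: {sorted(unknown)}")
    weights = np.array([type_mixture.get(t, 0.0) for t in PAIR_TYPES], dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(
            "type_mixture proportions must be non-negative and sum to 1; got "
            f"{dict(type_mixture)}"
        )
    lo, hi = magnitude_range
    if not (0 < lo <= hi):
        raise ValueError("magnitude_range must satisfy 0 < lo <= hi")

    rng = np.random.default_rng(seed)
    if taxa is None:
        taxa = [f"genus_{k:02d}" for k in range(n_taxa)]

    pairs = [(i, j) for i in range(n_taxa) for j in range(i + 1, n_taxa)]
    counts = _allocate_pair_counts(len(pairs), type_mixture)
    labels = [t for t in PAIR_TYPES for _ in range(counts[t])]
    rng.shuffle(pairs)

    a = np.zeros((n_taxa, n_taxa))
    for (i, j), label in zip(pairs, labels):
        s_on_i, s_on_j = _SIGNS[label]
        if rng.random() < 0.5:  # randomize which member gets which role
            s_on_i, s_on_j = s_on_j, s_on_i
        a[i, j] = s_on_i * rng.uniform(lo, hi)
        a[j, i] = s_on_j * rng.uniform(lo, hi)
    np.fill_diagonal(a, -rng.uniform(*self_limitation_range, size=n_taxa))

    b = rng.uniform(*growth_rate_range, size=n_taxa)
    return GLVModel(taxa=list(taxa), growth_rates=b, interactions=a)


def _glv_rhs(t: float, x: np.ndarray, b: np.ndarray, a: np.ndarray) -> np.ndarray:
    return x * (b + a @ x)


def _overflow_event(t: float, x: np.ndarray, b: np.ndarray, a: np.ndarray) -> float:
    return OVERFLOW_GUARD - float(np.max(np.abs(x)))


_overflow_event.terminal = True  # type: ignore[attr-defined]


def simulate_glv(
    model: GLVModel,
    x0: np.ndarray,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    extinction_floor: float = EXTINCTION_FLOOR,
    renormalize: bool = True,
    noise_mode: str = "observation",
) -> TimeSeriesProfile:
    """Integrate the gLV ODE and sample it at ``times``.

    The trajectory is integrated with an adaptive high-order scheme
    (tight tolerances), sampled at the requested times, perturbed with
    multiplicative log-normal noise of scale ``noise_sd``, clamped at the
    extinction floor, and renormalized to relative abundance per column.
    ``renormalize=False`` returns the absolute trajectory instead (used
    for diagnostics and parameter-recovery checks, where normalization
    would decouple the data from the generating coefficients).

    ``noise_mode`` controls where stochasticity enters: ``"observation"``
    perturbs only the sampled values (measurement error), while
    ``"process"`` kicks the community state at every sampling time and
    lets the kick propagate through the subsequent dynamics
    (environmental stochasticity; keeps a community near equilibrium
    persistently excited).
    """
    x0 = np.asarray(x0, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(x0 <= 0):
        raise ValueError("x0 must be strictly positive")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if noise_mode not in ("observation", "process"):
        raise ValueError("noise_mode must be 'observation' or 'process'")

    if noise_mode == "process" and noise_sd > 0:
        rng = np.random.default_rng(seed)
        traj = np.empty((len(x0), len(times)))
        cur = x0.copy()
        traj[:, 0] = cur
        for k in range(len(times) - 1):
            sol = solve_ivp(
                _glv_rhs,
                (times[k], times[k + 1]),
                cur,
                args=(model.growth_rates, model.interactions),
                method="LSODA",
                rtol=1e-9,
                atol=1e-12,
                events=_overflow_event,
            )
            if not sol.success or (sol.t_events and len(sol.t_events[0])):
                raise RuntimeError(f"gLV integration diverged before t={times[k + 1]}")
            cur = sol.y[:, -1] * np.exp(rng.normal(0.0, noise_sd, size=len(cur)))
            cur = np.clip(cur, extinction_floor, None)
            if np.any(cur > OVERFLOW_GUARD):
                raise RuntimeError(
                    f"gLV trajectory exceeded overflow guard at t={times[k + 1]}"
                )
            traj[:, k + 1] = cur
    else:
        sol = solve_ivp(
            _glv_rhs,
            (times[0], times[-1]),
            x0,
            t_eval=times,
            args=(model.growth_rates, model.interactions),
            method="LSODA",
            rtol=1e-9,
            atol=1e-12,
            events=_overflow_event,
        )
        if not sol.success or sol.y.shape[1] < len(times):
            n_ok = sol.y.shape[1]
            bad_t = times[n_ok] if n_ok < len(times) else times[-1]
            raise RuntimeError(f"gLV integration diverged before t={bad_t}")
        traj = sol.y
        if np.any(np.abs(traj) > OVERFLOW_GUARD) or not np.all(np.isfinite(traj)):
            bad = np.argwhere(~np.isfinite(traj) | (np.abs(traj) > OVERFLOW_GUARD))
            raise RuntimeError(
                f"gLV trajectory exceeded overflow guard at t={times[bad[0, 1]]}"
            )
        if noise_sd > 0:
            rng = np.random.default_rng(seed)
            traj = traj * np.exp(rng.normal(0.0, noise_sd, size=traj.shape))
    traj = np.clip(traj, extinction_floor, None)
    if not renormalize:
        return TimeSeriesProfile(
            taxa=list(model.taxa), times=times, abundances=traj, normalized=False
        )
    traj = traj / traj.sum(axis=0, keepdims=True)
    return TimeSeriesProfile(taxa=list(model.taxa), times=times, abundances=traj)


def counts_from_profile(
    profile: TimeSeriesProfile | pd.DataFrame,
    depth: int = 5000,
    seed: int = 0,
    sample_names: list[str] | None = None,
    metadata: pd.DataFrame | None = None,
) -> AbundanceTable:
    """Multinomial read counts at a fixed sequencing depth per sample."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(profile, TimeSeriesProfile):
        props = profile.abundances
        taxa = profile.taxa
        if sample_names is None:
            sample_names = [f"t{t:g}" for t in profile.times]
        if metadata is None:
            metadata = pd.DataFrame({"time": profile.times}, index=sample_names)
    else:
        props = profile.to_numpy(dtype=float)
        taxa = list(profile.index)
        if sample_names is None:
            sample_names = list(profile.columns)
    counts = np.column_stack(
        [rng.multinomial(depth, props[:, k] / props[:, k].sum()) for k in range(props.shape[1])]
    )
    frame = pd.DataFrame(counts, index=taxa, columns=sample_names)
    return AbundanceTable(counts=frame, metadata=metadata)


def _propagate_perturbation(
    model: GLVModel,
    baseline: np.ndarray,
    perturbed: np.ndarray,
    dt: float,
    administered_idx: list[int],
) -> np.ndarray:
    """One gLV response step around a baseline treated as equilibrium.

    At equilibrium the intrinsic terms cancel, so the community response
    to a perturbation is driven by the interaction terms alone:
    ``y_i = p_i * exp(dt * sum_j a_ij (p_j - x_j))``.  The administered
    taxa themselves are held at their dosed level — the boost encodes
    the observed colonization outcome, not a free-running state.
    """
    drive = model.interactions @ (perturbed - baseline)
    out = perturbed * np.exp(dt * drive)
    out[administered_idx] = perturbed[administered_idx]
    return out


def generate_trial(
    model: GLVModel,
    baseline: np.ndarray,
    design: TrialDesign,
    seed: int = 0,
    depth: int = 5000,
    response_dt: float = 14.0,
    animal_sd: float = 0.3,
) -> dict[str, AbundanceTable]:
    """Simulate one probiotic trial per group in ``design``.

    The administered genus is boosted ``design.boost``-fold above
    baseline, the rest of the community responds through one gLV
    interaction step spanning the trial duration (``response_dt`` days;
    default 14, a two-week trial), per-animal log-normal variation of
    scale ``animal_sd`` is applied, and multinomial counts are drawn at
    ``depth`` reads per sample.  The control group is drawn from the
    unperturbed baseline.
    """
    baseline = np.asarray(baseline, dtype=float)
    baseline = baseline / baseline.sum()
    index = {t: i for i, t in enumerate(model.taxa)}
    for group in design.groups:
        for genus in design.administered.get(group, []):
            if genus not in index:
                raise KeyError(
                    f"unknown genus {genus!r}; valid labels: {model.taxa}"
                )

    rng = np.random.default_rng(seed)
    tables: dict[str, AbundanceTable] = {}
    for group in design.groups:
        dosed = design.administered.get(group, [])
        perturbed = baseline.copy()
        for genus in dosed:
            perturbed[index[genus]] *= design.boost
        if dosed:
            expected = _propagate_perturbation(
                model, baseline, perturbed, response_dt, [index[g] for g in dosed]
            )
        else:
            expected = baseline.copy()
        animals = []
        for _ in range(design.n_per_group):
            comp = expected * np.exp(rng.normal(0.0, animal_sd, size=len(expected)))
            comp = comp / comp.sum()
            animals.append(rng.multinomial(depth, comp))
        names = [f"{group}_a{k + 1}" for k in range(design.n_per_group)]
        frame = pd.DataFrame(np.column_stack(animals), index=model.taxa, columns=names)
        meta = pd.DataFrame({"group": group}, index=names)
        tables[group] = AbundanceTable(counts=frame, metadata=meta)
    return tables


def expected_trial_composition(
    model: GLVModel,
    baseline: np.ndarray,
    administered: list[str],
    boost: float,
    response_dt: float = 14.0,
) -> np.ndarray:
    """Noise-free expected composition of a treatment group (unnormalized)."""
    baseline = np.asarray(baseline, dtype=float)
    baseline = baseline / baseline.sum()
    perturbed = baseline.copy()
    index = {t: i for i, t in enumerate(model.taxa)}
    for genus in administered:
        perturbed[index[genus]] *= boost
    if not administered:
        return baseline
    return _propagate_perturbation(
        model, baseline, perturbed, response_dt, [index[g] for g in administered]
    )


def sample_stable_community(
    n_taxa: int,
    type_mixture: dict[str, float],
    magnitude_range: tuple[float, float] = (0.3, 1.0),
    equilibrium_range: tuple[float, float] = (0.1, 0.4),
    seed: int = 0,
) -> tuple[GLVModel, np.ndarray]:
    """An interaction model guaranteed a feasible, locally stable fixed point.

    The interaction matrix is drawn as in :func:`sample_interaction_matrix`,
    an interior equilibrium ``x*`` is drawn from ``equilibrium_range``,
    growth rates are set to ``b = -A x*``, and self-limitation is
    strengthened until the fixed point is stable — so trajectories from
    any positive start converge instead of diverging, for every seed.
    """
    model = sample_interaction_matrix(
        n_taxa, type_mixture, magnitude_range=magnitude_range, seed=seed
    )
    rng = np.random.default_rng(seed + 1)
    x_star = rng.uniform(*equilibrium_range, size=n_taxa)
    a = model.interactions
    for _ in range(60):
        if np.linalg.eigvals(np.diag(x_star) @ a).real.max() < -0.01:
            break
        a[np.diag_indices(n_taxa)] *= 1.2
    else:
        raise RuntimeError("could not stabilize the sampled community")
    model.growth_rates = -a @ x_star
    return model, x_star


def sample_planted_matrix(
    n_taxa: int = 10,
    n_planted: int = 5,
    strong_range: tuple[float, float] = (0.45, 0.7),
    background_range: tuple[float, float] = (0.02, 0.06),
    equilibrium_range: tuple[float, float] = (0.5, 1.5),
    seed: int = 0,
) -> tuple[GLVModel, list[tuple[str, str, str]], np.ndarray]:
    """A stable community with strong planted pairs over a weak background.

    Planted pairs alternate mutual / competitive with coefficient
    magnitudes drawn from ``strong_range`` (at least five-fold above the
    background range, so they dominate any magnitude ranking); every
    other pair gets weak background coefficients.  A random interior
    equilibrium ``x*`` is drawn from ``equilibrium_range`` and growth
    rates are set to ``b = -A x*``, so the community is guaranteed a
    feasible fixed point; self-limitation is strengthened as needed
    until that fixed point is locally stable.

    Returns (model, planted pair list as (taxon_a, taxon_b, type), x*).
    """
    if strong_range[0] < 5 * background_range[1]:
        raise ValueError("planted coefficients must be >= 5x background")
    rng = np.random.default_rng(seed)
    mixture = {"mutual": 0.3, "competitive": 0.3, "commensal": 0.2, "amensal": 0.2}
    model = sample_interaction_matrix(
        n_taxa,
        mixture,
        magnitude_range=background_range,
        seed=seed,
        self_limitation_range=(0.9, 1.1),
    )
    pairs = [(i, j) for i in range(n_taxa) for j in range(i + 1, n_taxa)]
    chosen = [pairs[k] for k in rng.choice(len(pairs), size=n_planted, replace=False)]
    planted = []
    a = model.interactions
    for k, (i, j) in enumerate(chosen):
        ptype = "mutual" if k % 2 == 0 else "competitive"
        s = 1 if ptype == "mutual" else -1
        a[i, j] = s * rng.uniform(*strong_range)
        a[j, i] = s * rng.uniform(*strong_range)
        planted.append((model.taxa[i], model.taxa[j], ptype))
    x_star = rng.uniform(*equilibrium_range, size=n_taxa)
    for _ in range(40):  # strong mutualism can destabilize; firm up the diagonal
        if np.linalg.eigvals(np.diag(x_star) @ a).real.max() < -0.05:
            break
        a[np.diag_indices(n_taxa)] *= 1.15
    else:
        raise RuntimeError("could not stabilize the planted community")
    model.growth_rates = -a @ x_star
    return model, planted, x_star


def planted_fanin_graph(
    n_targets: int = 60,
    n_hubs: int = 10,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """A directed graph with guaranteed fan-in enrichment.

    Hub nodes form one directed cycle (so each hub has in-degree 1 and
    consecutive hubs are adjacent); every target receives exactly two
    edges from a non-consecutive — hence never adjacent — hub pair, so
    each target contributes one clean fan-in triad.  Degree-preserving
    rewiring reassigns the co-pointing hub pairs at random, and the
    fraction landing on adjacent (consecutive) hubs spoils those triads:
    the null mean falls below the observed count by construction.
    """
    if n_hubs < 5:
        raise ValueError("need at least 5 hubs for non-adjacent pairs")
    rng = np.random.default_rng(seed)
    hubs = [f"h{k}" for k in range(n_hubs)]
    edges: set[tuple[str, str]] = set()
    for k in range(n_hubs):
        edges.add((hubs[k], hubs[(k + 1) % n_hubs]))
    for t in range(n_targets):
        while True:
            u, v = rng.choice(n_hubs, size=2, replace=False)
            if (u - v) % n_hubs not in (1, n_hubs - 1):
                break
        edges.add((hubs[u], f"t{t}"))
        edges.add((hubs[v], f"t{t}"))
    return sorted(edges)


def write_ground_truth_edges(model: GLVModel, path: str) -> None:
    """Export the true interaction matrix as a (source, target, coefficient) TSV."""
    frame = model.to_edge_frame()
    with open(path, "w") as fh:
        fh.write("# ground-truth gLV interactions; edge source->target is a_[target,source]\n")
        frame.to_csv(fh, sep="\t", index=False)
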