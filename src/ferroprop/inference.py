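"""Transmission inference on event tables and contact graphs.

``fit_spread_probability`` recovers the per-contact conversion probability
of the chain-binomial process by maximum likelihood: at every step each
alive, unconverted cell with k contact neighbours that died in that step is
one Bernoulli trial with success probability 1 - (1 - p)**k.

``propagation_test`` combines the Hopkins cluster tendency of the dead-cell
pattern with the distance-permutation null into a single
propagating / random / inconclusive verdict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import spatial_stats

__all__ = ["SpreadFit", "fit_spread_probability", "PropagationReport", "propagation_test"]


@dataclass
class SpreadFit:
    """Chain-binomial MLE of the per-contact spread probability.

    ``profile`` is the log-likelihood on ``p_grid``; ``n_exposures`` counts
    Bernoulli trials and ``n_conversions`` successes; ``dt`` is the
    attribution clock in minutes.
    """

    p_hat: float
    p_grid: np.ndarray
    profile: np.ndarray
    n_exposures: int
    n_conversions: int
    dt: float


def _exposure_trials(events: pd.DataFrame, graph: nx.Graph, dt: float):
    """Enumerate per-step (k, success) Bernoulli trials from an event table.

    Death times are binned to the dt grid; a cell is susceptible until its
    oxidation onset (or death/censoring). Each step in which a susceptible
    cell has k newly dead contact neighbours is one trial. The conversion
    step itself is not observed (the onset trails it by a delay), so a
    converting cell's conversion is attributed to its *last* exposure step
    at or before the onset; its earlier exposures, and every exposure of
    never-converting or right-censored cells, count as failures. Pooling a
    cell's exposures into a single trial would be misspecified — conversion
    stops the exposure process, so the pooled count is outcome-dependent —
    hence the sequential per-step form.
    """
    ids = events["id"].to_numpy()
    idx = {c: i for i, c in enumerate(ids)}
    n = len(ids)
    nbrs = [np.array([idx[j] for j in graph.neighbors(c)], int) if c in graph else np.empty(0, int) for c in ids]

    bleb = events["blebbing_time"].to_numpy(dtype=float)
    onset = events["ox_onset_time"].to_numpy(dtype=float)
    # infectious step of each dead cell (ceil to the grid: a death in
    # (t-dt, t] is "newly dead" at step t). Only ferroptotic deaths spread;
    # they are recognisable by a preceding oxidation onset, so deaths
    # without one (background toxicity) are not treated as infectious.
    dead = ~np.isnan(bleb)
    ferroptotic = dead & ~np.isnan(onset)
    death_step = np.full(n, -1, dtype=int)
    death_step[ferroptotic] = np.ceil(bleb[ferroptotic] / dt - 1e-9).astype(int)
    onset_step = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    has_onset = ~np.isnan(onset)
    onset_step[has_onset] = np.ceil(onset[has_onset] / dt - 1e-9).astype(int)

    trials = []  # (k, success)
    for i in range(n):
        if len(nbrs[i]) == 0:
            continue
        nd_steps = death_step[nbrs[i]]
        nd_steps = nd_steps[nd_steps > 0]
        if len(nd_steps) == 0:
            continue
        # exposures while susceptible: step <= onset_step (inclusive — the
        # conversion step itself is an exposure) and before own death if
        # it died without observed onset (background death)
        limit = onset_step[i]
        if not has_onset[i] and death_step[i] >= 0:
            limit = min(limit, death_step[i])
        steps, counts = np.unique(nd_steps[nd_steps <= limit], return_counts=True)
        if len(steps) == 0:
            continue
        converted = bool(has_onset[i] and onset[i] > 0)  # onset 0 = opto seed
        for k in counts[:-1]:
            trials.append((int(k), False))
        trials.append((int(counts[-1]), converted))
    return trials


def fit_spread_probability(
    events: pd.DataFrame,
    graph: nx.Graph,
    dt: float,
    grid_size: int = 201,
) -> SpreadFit:
    """Maximum-likelihood per-contact spread probability.

    Maximises the product of trial likelihoods over p in [0, 1] by
    golden-section search, and returns the log-likelihood profile on a
    uniform grid alongside. Raises if the table yields no exposure
    opportunities (p is unidentifiable).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    trials = _exposure_trials(events, graph, dt)
    if not trials:
        raise ValueError("no exposure opportunities; spread probability unidentifiable")
    ks = np.array([k for k, _ in trials], dtype=float)
    succ = np.array([s for _, s in trials], dtype=bool)

    def nll(p):
        p = min(max(p, 0.0), 1.0)
        q = 1.0 - p
        with np.errstate(divide="ignore"):
            log_fail = ks * np.log(q) if q > 0 else np.full_like(ks, -np.inf)
            conv = 1.0 - q**ks
            log_succ = np.where(conv > 0, np.log(np.maximum(conv, 1e-300)), -np.inf)
        ll = np.where(succ, log_succ, log_fail)
        return -np.sum(ll)

    grid = np.linspace(0.0, 1.0, grid_size)
    profile = np.array([-nll(p) for p in grid])

    if not succ.any():
        p_hat = 0.0
    elif succ.all() and np.all(ks >= 1):
        # boundary check: with every trial a success the MLE is 1
        p_hat = 1.0
    else:
        res = minimize_scalar(nll, bounds=(1e-9, 1.0 - 1e-9), method="bounded",
                              options={"xatol": 1e-6})
        p_hat = float(res.x)
        # guard against a flat interior: compare with grid optimum
        if -nll(p_hat) < profile.max():
            p_hat = float(grid[np.argmax(profile)])
    return SpreadFit(
        p_hat=p_hat,
        p_grid=grid,
        profile=profile,
        n_exposures=len(trials),
        n_conversions=int(succ.sum()),
        dt=dt,
    )


@dataclass
class PropagationReport:
    """Composite propagation-vs-random decision.

    verdict: "propagating" iff the permutation p-value < alpha AND
    Hopkins H_mean > h_threshold; "random" iff p >= alpha; otherwise
    "inconclusive" (short distances without cluster tendency).
    """

    hopkins_mean: float
    observed_median_nn: float
    permutation_p: float
    verdict: str
    alpha: float
    h_threshold: float


def propagation_test(
    events: pd.DataFrame,
    cells: pd.DataFrame,
    reps: int = 999,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    h_threshold: float = 0.5,
    min_dead: int = 5,
) -> PropagationReport:
    """Decide whether observed deaths look contact-propagated or random.

    Computes (i) the Hopkins statistic of all dead-cell coordinates within
    the full-population bounding box and (ii) the observed median dead
    bystander → dead transfected nearest-neighbour distance against its
    label-permutation null. Requires at least ``min_dead`` dead cells per
    population.
    """
    merged = cells.merge(events, on="id")
    dead = merged[~merged["draq7_time"].isna() | ~merged["blebbing_time"].isna()]
    dead_by = dead[dead["population"] == "bystander"]
    dead_tr = dead[dead["population"] == "transfected"]
    if len(dead_by) < min_dead or len(dead_tr) < min_dead:
        raise ValueError(
            f"need >= {min_dead} dead cells per population "
            f"(got {len(dead_tr)} transfected, {len(dead_by)} bystander)"
        )
    pattern = spatial_stats.PointPattern.from_cells(cells, subset=dead.index.to_numpy())
    # cells.merge preserves cells' positional index when ids align
    xy_by = dead_by[["x", "y"]].to_numpy()
    xy_tr = dead_tr[["x", "y"]].to_numpy()
    observed = float(np.median(spatial_stats.nearest_neighbor_distances(xy_by, xy_tr)))

    hop = spatial_stats.hopkins(pattern, seed=seed)
    null = spatial_stats.distance_permutation_null(
        cells,
        n_dead_source=len(dead_by),
        n_dead_target=len(dead_tr),
        reps=reps,
        seed=seed,
        observed=observed,
    )
    if null.p_value < alpha and hop.H_mean > h_threshold:
        verdict = "propagating"
    elif null.p_value >= alpha:
        verdict = "random"
    else:
        verdict = "inconclusive"
    return PropagationReport(
        hopkins_mean=hop.H_mean,
        observed_median_nn=observed,
        permutation_p=null.p_value,
        verdict=verdict,
        alpha=alpha,
        h_threshold=h_threshold,
    )
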