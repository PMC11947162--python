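"""Point-pattern statistics on dead-cell coordinates.

Implements the Hopkins cluster-tendency statistic, within- and
cross-population nearest-neighbour distances, equivalent-circle diameter
estimation, and a label-permutation null for cross-population distance
medians. Distances are Euclidean, centroid-to-centroid, with no edge
correction (raw vector lengths; near-boundary distances are biased upward
for sparse patterns — documented, not corrected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "PointPattern",
    "HopkinsResult",
    "hopkins",
    "nearest_neighbor_distances",
    "estimate_cell_diameter",
    "distance_permutation_null",
    "PermutationNullResult",
]


@dataclass
class PointPattern:
    """Planar points (µm) inside an axis-aligned rectangular window.

    ``window`` is (xmin, xmax, ymin, ymax). The window is the sampling
    frame — for monolayer analyses use the bounding box of *all* cells,
    not only the dead ones, to avoid biasing the Hopkins statistic.
    """

    points: np.ndarray
    window: tuple

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        xmin, xmax, ymin, ymax = self.window
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("window must have positive area")
        if len(self.points):
            x, y = self.points[:, 0], self.points[:, 1]
            if (x < xmin).any() or (x > xmax).any() or (y < ymin).any() or (y > ymax).any():
                raise ValueError("all points must lie inside the window")

    @classmethod
    def from_cells(cls, cells: pd.DataFrame, subset: Optional[np.ndarray] = None) -> "PointPattern":
        """Pattern of (a subset of) cell centroids with the full-population
        bounding box as window."""
        xy = cells[["x", "y"]].to_numpy(dtype=float)
        window = (xy[:, 0].min(), xy[:, 0].max(), xy[:, 1].min(), xy[:, 1].max())
        pts = xy if subset is None else xy[np.asarray(subset)]
        return cls(pts, window)

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class HopkinsResult:
    """Hopkins statistic H = Σu^d / (Σu^d + Σw^d) summarised over replicates.

    u_i: nearest-event distance from a uniform random location;
    w_i: nearest-neighbour distance of a sampled event (self excluded);
    m: sample count per replicate; d: distance exponent. H ≈ 0.5 under
    complete spatial randomness, → 1 for clustered patterns, < 0.5 for
    regular ones.
    """

    H_mean: float
    H_sd: float
    H_values: np.ndarray
    m: int
    d: float
    seed: Optional[int] = None


def hopkins(
    pattern: PointPattern,
    m: Optional[int] = None,
    d: float = 2.0,
    reps: int = 100,
    seed: Optional[int] = None,
) -> HopkinsResult:
    """Hopkins cluster-tendency statistic, mean ± sd over ``reps`` replicates.

    Per replicate: draw ``m`` uniform locations in the window and record
    each one's distance to the nearest event (u_i); sample ``m`` events
    without replacement and record each one's distance to its nearest other
    event (w_i); H = Σu_i^d / (Σu_i^d + Σw_i^d).

    ``m`` defaults to max(5, round(0.1 n)), clamped to n - 1. Requires
    n >= 5 and 1 <= m <= n - 1.
    """
    n = pattern.n
    if n < 5:
        raise ValueError("hopkins requires at least 5 events")
    if m is None:
        m = min(max(5, int(round(0.1 * n))), n - 1)
    if not 1 <= m <= n - 1:
        raise ValueError(f"m must be in [1, {n - 1}], got {m}")
    xmin, xmax, ymin, ymax = pattern.window

    rng = np.random.default_rng(seed)
    tree = cKDTree(pattern.points)
    H = np.empty(reps)
    for r in range(reps):
        locs = np.column_stack(
            [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
        )
        u, _ = tree.query(locs, k=1)
        sample_idx = rng.choice(n, size=m, replace=False)
        w, _ = tree.query(pattern.points[sample_idx], k=2)
        w = w[:, 1]  # nearest *other* event
        num = np.sum(u**d)
        den = num + np.sum(w**d)
        H[r] = 1.0 if den == 0 else num / den
    return HopkinsResult(
        H_mean=float(H.mean()),
        H_sd=float(H.std(ddof=1)) if reps > 1 else 0.0,
        H_values=H,
        m=m,
        d=d,
        seed=seed,
    )


def nearest_neighbor_distances(
    source: np.ndarray | PointPattern,
    target: Optional[np.ndarray | PointPattern] = None,
) -> np.ndarray:
    """One distance (µm) per source point.

    With ``target``: distance from each source point to its nearest target
    point (cross-population mode, e.g. dead bystander → dead transfected).
    Without: distance to the nearest *other* point within ``source``
    (self excluded). Ties in the neighbour search resolve to the
    lowest-index point; the returned distance is unaffected.
    """
    src = source.points if isinstance(source, PointPattern) else np.asarray(source, float).reshape(-1, 2)
    if len(src) == 0:
        raise ValueError("source pattern is empty")
    if target is not None:
        tgt = target.points if isinstance(target, PointPattern) else np.asarray(target, float).reshape(-1, 2)
        if len(tgt) == 0:
            raise ValueError("target pattern is empty")
        dist, _ = cKDTree(tgt).query(src, k=1)
        return np.asarray(dist, dtype=float)
    if len(src) < 2:
        raise ValueError("within-pattern distances require at least 2 points")
    dist, _ = cKDTree(src).query(src, k=2)
    return np.asarray(dist[:, 1], dtype=float)


def estimate_cell_diameter(areas) -> tuple[float, float]:
    """Mean and sd of equivalent-circle diameters 2·sqrt(area/π).

    ``areas`` may be an iterable of areas in µm², or a LabelMap-style
    object exposing ``.areas``.
    """
    if hasattr(areas, "areas"):
        areas = areas.areas
    a = np.asarray(list(areas) if not isinstance(areas, np.ndarray) else areas, dtype=float)
    if a.size == 0:
        raise ValueError("no cells provided")
    if (a <= 0).any():
        raise ValueError("areas must be positive")
    diam = 2.0 * np.sqrt(a / np.pi)
    sd = float(diam.std(ddof=1)) if diam.size > 1 else 0.0
    return float(diam.mean()), sd


@dataclass
class PermutationNullResult:
    """Null distribution of the median cross-NN distance under random
    death-label assignment, with an add-one permutation p-value."""

    null_medians: np.ndarray
    observed: Optional[float]
    p_value: Optional[float]
    n_dead_source: int
    n_dead_target: int
    seed: Optional[int] = None


def distance_permutation_null(
    cells: pd.DataFrame,
    n_dead_source: int,
    n_dead_target: int,
    reps: int = 999,
    seed: Optional[int] = None,
    observed: Optional[float] = None,
    source_population: str = "bystander",
    target_population: str = "transfected",
) -> PermutationNullResult:
    """Resampling null for the median source→target nearest-neighbour distance.

    Holds the monolayer geometry fixed and, per replicate, samples which
    cells died uniformly within each population (``n_dead_source`` from
    ``source_population``, ``n_dead_target`` from ``target_population``),
    then records the median cross-NN distance. If ``observed`` is given,
    p = (1 + #{null <= observed}) / (reps + 1) — a one-sided test for
    *shorter-than-random* distances, the signature of contact propagation.
    """
    pop = cells["population"].to_numpy()
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    src_idx = np.flatnonzero(pop == source_population)
    tgt_idx = np.flatnonzero(pop == target_population)
    if n_dead_source < 1 or n_dead_source > len(src_idx):
        raise ValueError(
            f"n_dead_source={n_dead_source} infeasible ({len(src_idx)} {source_population} cells)"
        )
    if n_dead_target < 1 or n_dead_target > len(tgt_idx):
        raise ValueError(
            f"n_dead_target={n_dead_target} infeasible ({len(tgt_idx)} {target_population} cells)"
        )
    rng = np.random.default_rng(seed)
    medians = np.empty(reps)
    for r in range(reps):
        s = rng.choice(src_idx, size=n_dead_source, replace=False)
        t = rng.choice(tgt_idx, size=n_dead_target, replace=False)
        medians[r] = np.median(nearest_neighbor_distances(xy[s], xy[t]))
    p = None
    if observed is not None:
        p = (1 + int(np.sum(medians <= observed))) / (reps + 1)
    return PermutationNullResult(
        null_medians=medians,
        observed=observed,
        p_value=p,
        n_dead_source=n_dead_source,
        n_dead_target=n_dead_target,
        seed=seed,
    )
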