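"""Ground-truth generators: monolayers, contact graphs, death propagation,
rendered time-lapse stacks, GUV transfer traces, and lipidomics tables.

The simulator is a discrete-time chain-binomial on a hard-disc monolayer.
Opto-activated cells die with truncated-normal timing; at every step each
alive, unconverted cell with ``k`` contact neighbours that died *in that
step* converts with probability ``1 - (1 - p_eff)**k``. Converted cells show
lipid oxidation after a lognormal delay and die a truncated-normal interval
later. Perturbations (Fer-1, iron chelation, contact ablation, bilayer
bridges) act multiplicatively on ``p_eff`` or open an extra distance-decayed
exposure channel — see :class:`ferroprop.config.Modifiers`.

All tables are pandas DataFrames; the contact graph is a networkx Graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .config import GUVPairConfig, ImagingConfig, LipidSimConfig, SimulationConfig

__all__ = [
    "FrameStack",
    "generate_monolayer",
    "build_contact_graph",
    "simulate_propagation",
    "render_frames",
    "simulate_guv_pair",
    "simulate_lipidomics",
    "PackingError",
]

CELL_COLUMNS = ["id", "x", "y", "diameter", "population", "illuminated"]
EVENT_COLUMNS = ["id", "ox_onset_time", "blebbing_time", "draq7_time", "cause"]


class PackingError(RuntimeError):
    """Raised when random sequential adsorption cannot reach the target
    confluency; carries the achieved area fraction."""

    def __init__(self, achieved: float, target: float):
        self.achieved = achieved
        self.target = target
        super().__init__(
            f"packing stalled at area fraction {achieved:.3f} "
            f"(target {target:.3f} +/- 0.05)"
        )


@dataclass
class FrameStack:
    """A rendered multi-channel time-lapse.

    ``data`` is indexed (time, channel, row, col); ``frame_times`` are in
    minutes and ``pixel_size`` in µm/px. ``channels`` names axis 1.
    """

    data: np.ndarray
    frame_times: np.ndarray
    channels: tuple
    pixel_size: float

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("FrameStack data must be (T, C, H, W)")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel names do not match data shape")
        if len(self.frame_times) != self.data.shape[0]:
            raise ValueError("frame_times do not match data shape")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channels.index(name)]


# ---------------------------------------------------------------------------
# monolayer geometry
# ---------------------------------------------------------------------------

def generate_monolayer(config: SimulationConfig) -> pd.DataFrame:
    """Pack hard discs into a square field by random sequential adsorption.

    Disc diameters are truncated-normal (positive); centres are uniform
    proposals rejected on overlap (centres closer than
    ``(1 - overlap_tolerance) * (r_i + r_j)``) or field overhang. Packing
    stops when the realised disc-area fraction reaches the target; if the
    attempt budget is exhausted more than 0.05 below target a
    :class:`PackingError` is raised. Population labels are i.i.d. Bernoulli
    with ``transfected_fraction``; exactly ``n_illuminated`` transfected
    cells are marked illuminated.

    Returns a CellTable with columns id, x, y, diameter, population,
    illuminated. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.field_size
    target = config.target_confluency
    field_area = L * L

    # spatial hash grid for O(1) neighbourhood overlap queries
    cell_size = max(config.diameter_mean + 4 * config.diameter_sd, 1e-6)
    n_bins = max(int(L / cell_size), 1)
    bin_w = L / n_bins
    grid: dict = {}

    xs: list = []
    ys: list = []
    ds: list = []
    covered = 0.0
    tol = 1.0 - config.overlap_tolerance

    # attempt budget scales with the number of discs the field can hold
    approx_n = max(int(target * field_area / (math.pi * (config.diameter_mean / 2) ** 2)), 1)
    max_attempts = 400 * approx_n

    attempts = 0
    while covered / field_area < target and attempts < max_attempts:
        attempts += 1
        d = -1.0
        while d <= 0:
            d = rng.normal(config.diameter_mean, config.diameter_sd)
        r = d / 2
        if 2 * r >= L:
            continue
        x = rng.uniform(r, L - r)
        y = rng.uniform(r, L - r)
        bi, bj = int(x / bin_w), int(y / bin_w)
        ok = True
        for ii in range(max(bi - 1, 0), min(bi + 2, n_bins)):
            for jj in range(max(bj - 1, 0), min(bj + 2, n_bins)):
                for k in grid.get((ii, jj), ()):
                    dx = x - xs[k]
                    dy = y - ys[k]
                    lim = tol * (r + ds[k] / 2)
                    if dx * dx + dy * dy < lim * lim:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        grid.setdefault((bi, bj), []).append(len(xs))
        xs.append(x)
        ys.append(y)
        ds.append(d)
        covered += math.pi * r * r

    realized = covered / field_area
    if realized < target - 0.05:
        raise PackingError(realized, target)

    n = len(xs)
    transfected = rng.random(n) < config.transfected_fraction
    population = np.where(transfected, "transfected", "bystander")
    illuminated = np.zeros(n, dtype=bool)
    if config.n_illuminated > 0:
        t_idx = np.flatnonzero(transfected)
        if len(t_idx) < config.n_illuminated:
            raise ValueError(
                f"n_illuminated={config.n_illuminated} exceeds the "
                f"{len(t_idx)} transfected cells present"
            )
        chosen = rng.choice(t_idx, size=config.n_illuminated, replace=False)
        illuminated[chosen] = True

    return pd.DataFrame(
        {
            "id": np.arange(n, dtype=int),
            "x": np.asarray(xs),
            "y": np.asarray(ys),
            "diameter": np.asarray(ds),
            "population": population,
            "illuminated": illuminated,
        }
    )


def build_contact_graph(cells: pd.DataFrame, kappa: float = 1.2) -> nx.Graph:
    """Contact graph: edge (i, j) iff centroid distance <= kappa * (d_i + d_j)/2.

    ``kappa`` rescales the touching criterion (1.0 = discs exactly tangent);
    values slightly above 1 absorb the packing tolerance and membrane reach.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    g = nx.Graph(kappa=kappa)
    ids = cells["id"].to_numpy()
    g.add_nodes_from(ids.tolist())
    if len(cells) < 2:
        return g
    xy = cells[["x", "y"]].to_numpy()
    diam = cells["diameter"].to_numpy()
    tree = cKDTree(xy)
    max_reach = kappa * diam.max()
    pairs = tree.query_pairs(r=max_reach, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        thresh = kappa * (diam[pairs[:, 0]] + diam[pairs[:, 1]]) / 2
        keep = pairs[d <= thresh]
        g.add_edges_from(zip(ids[keep[:, 0]].tolist(), ids[keep[:, 1]].tolist()))
    return g


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_propagation(
    cells: pd.DataFrame, graph: nx.Graph, config: SimulationConfig
) -> pd.DataFrame:
    """Run the chain-binomial contact-death process on a monolayer.

    Returns an EventTable (one row per cell) with ox_onset_time,
    blebbing_time, draq7_time (NaN = censored at ``t_end``) and cause in
    {opto, propagated, background, none}.

    Model per step of length ``dt`` (see module docstring): only ferroptotic
    deaths (cause opto/propagated) are infectious, and only during the step
    in which they occur; the effective per-contact probability is
    ``p_spread * iron_factor * fer1(t) * contacts_enabled``. Background
    death is a memoryless per-minute hazard applied to alive, unconverted
    cells and is not infectious.
    """
    config.validate()
    mods = config.modifiers
    n = len(cells)
    ids = cells["id"].to_numpy()
    id_to_idx = {cid: i for i, cid in enumerate(ids)}
    for u in graph.nodes:
        if u not in id_to_idx:
            raise ValueError(f"graph node {u!r} missing from CellTable")

    # adjacency in index space, CSR-style
    import scipy.sparse as sp

    rows, cols = [], []
    for u, v in graph.edges:
        iu, iv = id_to_idx[u], id_to_idx[v]
        rows += [iu, iv]
        cols += [iv, iu]
    A = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )

    rng = np.random.default_rng(config.seed)

    ox_onset = np.full(n, np.nan)
    bleb = np.full(n, np.nan)
    cause = np.array(["none"] * n, dtype=object)
    converted = np.zeros(n, dtype=bool)
    infectious_bleb = np.full(n, np.inf)  # ferroptotic death times driving spread

    illum = (cells["illuminated"].to_numpy().astype(bool)) & (
        cells["population"].to_numpy() == "transfected"
    )
    if cells["illuminated"].to_numpy().astype(bool).sum() != illum.sum():
        raise ValueError("illuminated cells must be transfected")
    idx_illum = np.flatnonzero(illum)
    if len(idx_illum):
        ox_onset[idx_illum] = 0.0
        t_death = _truncnorm(
            rng,
            config.opto_death_mean,
            config.opto_death_sd,
            config.opto_death_min,
            config.opto_death_max,
            len(idx_illum),
        )
        bleb[idx_illum] = t_death
        infectious_bleb[idx_illum] = t_death
        cause[idx_illum] = "opto"
        converted[idx_illum] = True

    xy = cells[["x", "y"]].to_numpy()
    tree = cKDTree(xy) if mods.bilayer_range is not None else None

    dt = config.dt
    n_steps = int(round(config.t_end / dt))
    p_bg_step = 1.0 - (1.0 - config.background_hazard) ** dt

    for step in range(1, n_steps + 1):
        t = step * dt
        newly = (infectious_bleb > t - dt) & (infectious_bleb <= t)
        susceptible = (~converted) & (np.isnan(bleb) | (bleb > t))

        fer1 = 1.0
        if mods.fer1_time is not None and t >= mods.fer1_time:
            fer1 = mods.fer1_efficacy
        p_eff = (
            config.p_spread
            * mods.iron_factor
            * fer1
            * (1.0 if mods.contacts_enabled else 0.0)
        )

        if newly.any():
            k = A @ newly.astype(np.int8)
            exposed = np.flatnonzero(susceptible & (k > 0))
            if len(exposed):
                # draw in index order so modifier-null runs consume the
                # same stream as p_spread = 0
                u = rng.random(len(exposed))
                p_conv = 1.0 - (1.0 - p_eff) ** k[exposed]
                new_conv = exposed[u < p_conv]
                _convert(new_conv, t, rng, config, ox_onset, bleb, cause,
                         converted, infectious_bleb)
                susceptible[new_conv] = False

            if mods.bilayer_range is not None:
                R = mods.bilayer_range
                src = np.flatnonzero(newly)
                cand: dict = {}
                for s in src:
                    near = tree.query_ball_point(xy[s], R)
                    for j in near:
                        if j == s or not susceptible[j]:
                            continue
                        if A[s, j]:
                            continue  # contact channel already handled
                        dist = float(np.linalg.norm(xy[j] - xy[s]))
                        p_j = p_eff * max(0.0, 1.0 - dist / R)
                        cand[j] = 1.0 - (1.0 - cand.get(j, 0.0)) * (1.0 - p_j)
                if cand:
                    targets = np.array(sorted(cand), dtype=int)
                    u = rng.random(len(targets))
                    hit = targets[u < np.array([cand[j] for j in targets])]
                    _convert(hit, t, rng, config, ox_onset, bleb, cause,
                             converted, infectious_bleb)
                    susceptible[hit] = False

        if config.background_hazard > 0:
            alive_unconv = np.flatnonzero(susceptible)
            if len(alive_unconv):
                u = rng.random(len(alive_unconv))
                bg = alive_unconv[u < p_bg_step]
                bleb[bg] = t
                cause[bg] = "background"
                converted[bg] = True  # removed from the susceptible pool

    # censor at t_end
    t_end = config.t_end
    draq7 = bleb + mods.draq7_lag
    ox_out = np.where(np.isnan(ox_onset) | (ox_onset > t_end), np.nan, ox_onset)
    bleb_out = np.where(np.isnan(bleb) | (bleb > t_end), np.nan, bleb)
    draq7_out = np.where(np.isnan(draq7) | (draq7 > t_end), np.nan, draq7)
    cause_out = cause.copy()
    unobserved = np.isnan(ox_out) & np.isnan(bleb_out)
    cause_out[unobserved] = "none"

    return pd.DataFrame(
        {
            "id": ids,
            "ox_onset_time": ox_out,
            "blebbing_time": bleb_out,
            "draq7_time": draq7_out,
            "cause": cause_out,
        }
    )


def _convert(idx, t, rng, config, ox_onset, bleb, cause, converted, infectious_bleb):
    """Mark cells converted at time t; draw their onset and death times."""
    if len(idx) == 0:
        return
    delay = rng.lognormal(
        config.onset_delay_meanlog, config.onset_delay_sdlog, size=len(idx)
    )
    onset = t + delay
    interval = _truncnorm(
        rng, config.onset_to_death_mean, config.onset_to_death_sd,
        0.0, np.inf, len(idx),
    )
    ox_onset[idx] = onset
    bleb[idx] = onset + interval
    infectious_bleb[idx] = onset + interval
    cause[idx] = "propagated"
    converted[idx] = True


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_frames(
    cells: pd.DataFrame,
    events: pd.DataFrame,
    imaging: ImagingConfig,
    field_size: float,
    t_end: Optional[float] = None,
):
    """Render a four-channel time-lapse plus a ground-truth label map.

    Each cell is an isotropic Gaussian blob of sigma ``diameter/4``
    (convolved with the PSF in quadrature). The marker channel is constant
    for transfected cells; DRAQ7 steps on at frames >= ``draq7_time``;
    BODIPY green/red exchange linearly over ``ox_rise_minutes`` after
    ``ox_onset_time`` with green + red conserved per cell. Additive
    Gaussian noise of sd ``noise_sd`` is applied to every pixel.

    Returns ``(FrameStack, label_map)`` where ``label_map`` is an (H, W)
    integer image (0 = background) of the true disc footprints, labelled by
    cell id + 1.
    """
    imaging.validate()
    npx = int(round(field_size / imaging.pixel_size))
    if npx < 4:
        raise ValueError("pixel field too small to contain cells")
    diam_px = cells["diameter"].to_numpy() / imaging.pixel_size if len(cells) else np.array([])
    if len(cells) and (diam_px.max() > npx):
        raise ValueError("pixel field too small to contain cells")

    if t_end is None:
        finite = events[["ox_onset_time", "blebbing_time", "draq7_time"]].to_numpy()
        t_end = float(np.nanmax(finite)) if np.isfinite(finite).any() else 0.0
    frame_times = np.arange(0.0, t_end + 1e-9, imaging.frame_interval)
    if len(frame_times) == 0:
        frame_times = np.array([0.0])

    ch = ImagingConfig.CHANNELS
    T = len(frame_times)
    data = np.zeros((T, 4, npx, npx), dtype=np.float32)
    for c, name in enumerate(ch):
        data[:, c] += imaging.offsets[name]

    ev = events.set_index("id")
    rng = np.random.default_rng(imaging.seed)

    for _, cell in cells.iterrows():
        cx = cell.x / imaging.pixel_size
        cy = cell.y / imaging.pixel_size
        sigma = math.hypot(cell.diameter / 4.0 / imaging.pixel_size, imaging.psf_sigma)
        half = int(math.ceil(4 * sigma))
        r0 = max(int(cy) - half, 0)
        r1 = min(int(cy) + half + 1, npx)
        c0 = max(int(cx) - half, 0)
        c1 = min(int(cx) + half + 1, npx)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        blob = np.exp(-(((xx - cx) ** 2) + ((yy - cy) ** 2)) / (2 * sigma**2)).astype(
            np.float32
        )

        row = ev.loc[cell.id]
        ox_t = row["ox_onset_time"]
        draq_t = row["draq7_time"]

        if cell.population == "transfected":
            data[:, 0, r0:r1, c0:c1] += imaging.gains["marker"] * blob

        if not np.isnan(draq_t):
            on = frame_times >= draq_t
            data[on, 1, r0:r1, c0:c1] += imaging.gains["draq7"] * blob

        # oxidised fraction per frame: linear ramp after onset
        if np.isnan(ox_t):
            frac = np.zeros(T, dtype=np.float32)
        else:
            rise = max(imaging.ox_rise_minutes, 1e-9)
            frac = np.clip((frame_times - ox_t) / rise, 0.0, 1.0).astype(np.float32)
        g_gain = imaging.gains["bodipy_green"]
        r_gain = imaging.gains["bodipy_red"]
        data[:, 2, r0:r1, c0:c1] += g_gain * frac[:, None, None] * blob
        data[:, 3, r0:r1, c0:c1] += r_gain * (1.0 - frac[:, None, None]) * blob

    if imaging.noise_sd > 0:
        data += rng.normal(0.0, imaging.noise_sd, size=data.shape).astype(np.float32)

    # ground-truth label map: disc footprints, later ids overwrite overlaps
    label_map = np.zeros((npx, npx), dtype=np.int32)
    for _, cell in cells.iterrows():
        cx = cell.x / imaging.pixel_size
        cy = cell.y / imaging.pixel_size
        r = cell.diameter / 2.0 / imaging.pixel_size
        half = int(math.ceil(r))
        r0 = max(int(cy) - half, 0)
        r1 = min(int(cy) + half + 1, npx)
        c0 = max(int(cx) - half, 0)
        c1 = min(int(cx) + half + 1, npx)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        mask = ((xx - cx) ** 2 + (yy - cy) ** 2) <= r * r
        label_map[r0:r1, c0:c1][mask] = int(cell.id) + 1

    stack = FrameStack(
        data=data,
        frame_times=frame_times,
        channels=ch,
        pixel_size=imaging.pixel_size,
    )
    return stack, label_map


# ---------------------------------------------------------------------------
# GUV pair
# ---------------------------------------------------------------------------

def simulate_guv_pair(config: GUVPairConfig) -> pd.DataFrame:
    """Two-compartment oxidation-transfer kinetics for a donor/acceptor GUV pair.

    Solves ``dx_d/dt = k_act (1 - x_d)`` and
    ``dx_a/dt = contact * k0 * iron * x_d * (1 - x_a)`` numerically
    (LSODA, tight tolerances) and maps oxidised fractions to measured
    ratios ``r = baseline + (1 - baseline) x``. Returns a DataFrame with
    columns time, donor_ratio, acceptor_ratio.
    """
    config.validate()
    from scipy.integrate import solve_ivp

    c = (1.0 if config.contact else 0.0) * config.k0 * config.iron_conc

    def rhs(_t, y):
        xd, xa = y
        return [config.k_act * (1.0 - xd), c * xd * (1.0 - xa)]

    times = np.arange(0.0, config.t_end + 1e-12, config.dt)
    sol = solve_ivp(
        rhs, (0.0, float(times[-1])), [0.0, 0.0], t_eval=times,
        method="LSODA", rtol=1e-10, atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"GUV ODE integration failed: {sol.message}")
    b = config.baseline_ratio
    return pd.DataFrame(
        {
            "time": times,
            "donor_ratio": b + (1.0 - b) * sol.y[0],
            "acceptor_ratio": b + (1.0 - b) * sol.y[1],
        }
    )


# ---------------------------------------------------------------------------
# lipidomics
# ---------------------------------------------------------------------------

def simulate_lipidomics(config: LipidSimConfig) -> pd.DataFrame:
    """Peak-area table with known fold-change truth.

    Control-condition normalised level of species s is ``base_level``;
    illuminated is ``base_level * true_fold_change``. Raw areas are
    reconstructed as ``level * IS_area * protein_ug`` with multiplicative
    lognormal noise of the configured CV, so the lipidomics module's
    normalise -> fold-change path recovers the truth exactly at CV = 0.

    Columns: species, condition, replicate, area, is_name, is_area,
    protein_ug, true_fold_change.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sigma = math.sqrt(math.log(1.0 + config.cv**2)) if config.cv > 0 else 0.0
    rows = []
    for rep in range(1, config.n_replicates + 1):
        for sp in config.species:
            for cond in ("control", "illuminated"):
                level = sp.base_level * (sp.true_fold_change if cond == "illuminated" else 1.0)
                is_area = config.standard_areas[sp.standard]
                noise = rng.lognormal(-sigma**2 / 2, sigma) if sigma > 0 else 1.0
                rows.append(
                    {
                        "species": sp.name,
                        "condition": cond,
                        "replicate": rep,
                        "area": level * is_area * config.protein_ug * noise,
                        "is_name": sp.standard,
                        "is_area": is_area,
                        "protein_ug": config.protein_ug,
                        "true_fold_change": sp.true_fold_change,
                    }
                )
    return pd.DataFrame(rows)
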