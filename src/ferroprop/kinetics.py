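"""Population-level death kinetics: %positive curves, %AUC, time-to-event
summaries and routine one-way ANOVA / Tukey group comparison."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PopulationCurve",
    "AUCResult",
    "population_curves",
    "pct_auc",
    "time_to_event_summary",
    "compare_groups",
]


@dataclass
class PopulationCurve:
    """%positive-over-time curves, one column per population.

    ``values`` is a DataFrame indexed by time (minutes) with one column per
    population. In ``fraction_of_population`` mode values are percentages of
    the population's *initial* size (denominators fixed at t0, bounded
    [0, 100]); in ``count_per_confluency`` mode values are positive-object
    counts divided by the confluency fraction, in arbitrary units and
    unbounded.
    """

    values: pd.DataFrame
    mode: str
    population_sizes: dict

    @property
    def times(self) -> np.ndarray:
        return self.values.index.to_numpy(dtype=float)


@dataclass
class AUCResult:
    pct_auc: float
    span: float  # minutes


def population_curves(
    death_times: pd.Series | dict,
    populations: pd.Series | dict,
    frame_times,
    mode: str = "fraction_of_population",
    confluency: Optional[np.ndarray] = None,
) -> PopulationCurve:
    """Cumulative %positive curves per population at the given frame times.

    ``death_times``: per-cell event time, NaN for censored cells.
    ``populations``: per-cell population label over the same cell ids.
    Fraction mode: value(t, pop) = 100 * #{pop cells with event <= t} /
    initial pop size. Count-per-confluency mode needs a ``confluency``
    fraction per frame and returns total positives / confluency.
    """
    death_times = pd.Series(death_times, dtype=float)
    populations = pd.Series(populations)
    frame_times = np.asarray(frame_times, dtype=float)
    if len(frame_times) == 0 or np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame_times must be non-empty and strictly increasing")
    if not death_times.index.equals(populations.index):
        populations = populations.reindex(death_times.index)
    if populations.isna().any():
        raise ValueError("every cell needs a population label")

    if mode == "fraction_of_population":
        cols = {}
        sizes = {}
        for pop, idx in populations.groupby(populations).groups.items():
            times = death_times.loc[idx].to_numpy()
            n0 = len(idx)
            if n0 == 0:
                raise ValueError(f"population {pop!r} is empty")
            dead = times[~np.isnan(times)]
            cols[pop] = 100.0 * np.searchsorted(np.sort(dead), frame_times, side="right") / n0
            sizes[pop] = n0
        values = pd.DataFrame(cols, index=pd.Index(frame_times, name="time"))
        return PopulationCurve(values=values, mode=mode, population_sizes=sizes)
    elif mode == "count_per_confluency":
        if confluency is None:
            raise ValueError("count_per_confluency mode requires a confluency trace")
        confluency = np.asarray(confluency, dtype=float)
        if confluency.shape != frame_times.shape or (confluency <= 0).any():
            raise ValueError("confluency must be positive, one value per frame")
        dead = death_times.to_numpy()
        dead = np.sort(dead[~np.isnan(dead)])
        counts = np.searchsorted(dead, frame_times, side="right")
        values = pd.DataFrame(
            {"all": counts / confluency}, index=pd.Index(frame_times, name="time")
        )
        return PopulationCurve(values=values, mode=mode, population_sizes={"all": len(death_times)})
    raise ValueError(f"unknown mode {mode!r}")


def pct_auc(curve: PopulationCurve | pd.Series, population: Optional[str] = None) -> AUCResult:
    """%AUC: trapezoidal area under a %positive curve, normalised by the
    maximal attainable area (100% over the full span), times 100.

    A curve pinned at 100% scores 100, a flat zero curve scores 0, a linear
    0→100% ramp scores 50. Defined for fraction-mode curves with at least
    two time points.
    """
    if isinstance(curve, PopulationCurve):
        if curve.mode != "fraction_of_population":
            raise ValueError("%AUC is defined for fraction-mode curves")
        if population is None:
            if curve.values.shape[1] != 1:
                raise ValueError("specify which population to summarise")
            series = curve.values.iloc[:, 0]
        else:
            series = curve.values[population]
    else:
        series = curve
    t = series.index.to_numpy(dtype=float)
    v = series.to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("%AUC requires at least two time points")
    span = t[-1] - t[0]
    auc = np.trapezoid(v, t)
    return AUCResult(pct_auc=float(auc / (100.0 * span) * 100.0), span=float(span))


def time_to_event_summary(times) -> dict:
    """Mean/min/max of uncensored event times plus the censored count.

    ``times``: array-like with NaN marking censored cells. Censored cells
    are counted and reported, never imputed. If everything is censored the
    summary carries ``all_censored=True`` and no moments.
    """
    t = np.asarray(pd.Series(times, dtype=float))
    if t.size == 0:
        raise ValueError("empty group")
    obs = t[~np.isnan(t)]
    n_cens = int(np.isnan(t).sum())
    if obs.size == 0:
        return {"all_censored": True, "n_censored": n_cens, "n_events": 0}
    return {
        "all_censored": False,
        "mean": float(obs.mean()),
        "min": float(obs.min()),
        "max": float(obs.max()),
        "n_events": int(obs.size),
        "n_censored": n_cens,
    }


def compare_groups(groups: dict) -> dict:
    """One-way ANOVA with Tukey-HSD pairwise adjusted p-values.

    ``groups`` maps condition name → array of values (each with >= 2
    values). Returns {"F", "p", "tukey": {(a, b): p_adj}, "degenerate"}.
    If within-group variance is zero everywhere the F statistic is
    undefined and flagged rather than reported as a number.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, a in zip(names, arrays):
        if a.size < 2:
            raise ValueError(f"group {g!r} needs at least two values")
    within_var = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if within_var == 0:
        return {"F": np.nan, "p": np.nan, "tukey": {}, "degenerate": True}
    F, p = stats.f_oneway(*arrays)
    tk = stats.tukey_hsd(*arrays)
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairwise[(names[i], names[j])] = float(tk.pvalue[i, j])
    return {"F": float(F), "p": float(p), "tukey": pairwise, "degenerate": False}
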