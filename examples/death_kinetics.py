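"""Population death kinetics and %AUC summaries.

Computes %DRAQ7-positive curves per population (denominator = initial
population size), summarises each curve as %AUC, and compares conditions
with one-way ANOVA + Tukey.
"""

import numpy as np
import pandas as pd

import ferroprop as fp
from ferroprop.config import Modifiers

aucs = {"activated": [], "bystander": [], "bystander_fer1": []}
for seed in range(5):
    cfg = fp.SimulationConfig(seed=seed)
    cells = fp.generate_monolayer(cfg)
    graph = fp.build_contact_graph(cells)
    events = fp.simulate_propagation(cells, graph, cfg)
    fer1 = fp.simulate_propagation(
        cells, graph,
        fp.SimulationConfig(seed=seed,
                            modifiers=Modifiers(fer1_time=0.0, fer1_efficacy=0.0)))
    t_grid = np.arange(0.0, cfg.t_end + 1, 6.0)
    pops = cells.set_index("id").population

    def pct_auc_of(ev, ids):
        deaths = ev.set_index("id").draq7_time.loc[ids]
        curve = fp.population_curves(deaths, pd.Series("g", index=ids),
                                     frame_times=t_grid)
        return fp.pct_auc(curve, population="g").pct_auc

    aucs["activated"].append(pct_auc_of(events, cells.loc[cells.illuminated, "id"]))
    aucs["bystander"].append(pct_auc_of(events, pops[pops == "bystander"].index))
    aucs["bystander_fer1"].append(pct_auc_of(fer1, pops[pops == "bystander"].index))

for name, vals in aucs.items():
    print(f"%AUC {name:15s} {np.mean(vals):6.2f} +/- {np.std(vals):.2f}")

res = fp.compare_groups(aucs)
print(f"one-way ANOVA: F = {res['F']:.1f}, p = {res['p']:.2e}")
for pair, p in res["tukey"].items():
    print(f"  Tukey {pair[0]} vs {pair[1]}: p = {p:.3g}")
# Activated cells die almost immediately (%AUC near 100); bystanders die
# later and partially; Fer-1 reduces bystander death to background.
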