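"""Lipidomics normalisation and illuminated/control fold changes.

Simulates a peak-area table with known fold-change truth (internal
standards, protein content, multiplicative noise), then recovers the truth
through the normalise -> fold-change path.
"""

import ferroprop as fp

cfg = fp.LipidSimConfig(cv=0.1, seed=0)
table = fp.simulate_lipidomics(cfg)
norm = fp.normalize_areas(table, per_protein=True)
fc = fp.fold_changes(norm)

print("species                mean FC   truth")
for sp in cfg.species:
    got = fc.loc[fc.species == sp.name, "mean_fold_change"].iloc[0]
    print(f"{sp.name:22s} {got:7.2f} {sp.true_fold_change:7.1f}")
# With 10% CV and 3 replicates the replicate-mean fold change sits close
# to the configured truth; at cv=0 the recovery is exact.
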