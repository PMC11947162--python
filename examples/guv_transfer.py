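"""Donor-to-acceptor oxidation transfer between vesicle pairs.

Integrates the two-compartment GUV model under four conditions and prints
the final acceptor oxidation ratios: transfer requires both membrane
contact and external iron.
"""

import ferroprop as fp

conditions = {
    "contact + iron": fp.GUVPairConfig(),
    "no contact": fp.GUVPairConfig(contact=False),
    "no iron": fp.GUVPairConfig(iron_conc=0.0),
    "high iron": fp.GUVPairConfig(iron_conc=2.0),
}
for name, cfg in conditions.items():
    tr = fp.simulate_guv_pair(cfg)
    mid = tr.iloc[(tr.time - 15.0).abs().idxmin()]
    print(f"{name:15s} acceptor ratio at 15 min {mid.acceptor_ratio:.3f}, "
          f"at 60 min {tr.acceptor_ratio.iloc[-1]:.3f} "
          f"(baseline {cfg.baseline_ratio})")
# The acceptor only departs from baseline when coupled (contact AND iron);
# more iron accelerates the transfer (higher ratio at 15 min).
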