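"""Generate a synthetic stress-tolerance assay with known true LD values.

The generator draws negative binomial colony counts around a
shoulder-shaped survival curve: survival stays near 1 up to the shoulder
dose, then declines exponentially — the phenotype of radiation-resistant
bacteria.  Because the curve family has (near) closed-form LD values, the
printed ground truth lets you judge any downstream estimate.
"""

import lethaldose as ld

cfg = ld.default_config(seed=42)
ds = ld.simulate_dataset(cfg)

print(ds.frame.head(10).to_string(index=False))
print(f"... {len(ds)} rows: 2 strains x 2 experiments x 8 doses x 2 plates")

for name, params in cfg.strains:
    ld50 = ld.true_ld(params, 0.5)
    ld10 = ld.true_ld(params, 0.1)
    print(f"{name}: true LD50 = {ld50:.3f}, true LD10 = {ld10:.3f} "
          f"(shoulder {params.shoulder}, decay rate {params.decay_rate})")
# The LD50 is the dose at which the expected count falls to half the
# unexposed baseline; LD10 the dose at which 10% survive.
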