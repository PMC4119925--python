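"""Minimum inhibitory concentration from a growth/no-growth plate ladder.

The MIC is the smallest tested concentration at and above which no growth
is observed; growth at every tested level yields a right-censored call
("MIC > max tested").
"""

import numpy as np

import lethaldose as ld

conc = np.array([0.1, 0.3, 0.5, 1.0, 2.0, 4.0, 8.0])  # mM
table = ld.MICTable(
    agent="AsO4",
    concentrations=conc,
    growth={
        "isolateA": np.array([1, 1, 1, 1, 1, 1, 0], bool),   # inhibited only at 8 mM
        "control": np.array([1, 1, 1, 0, 0, 0, 0], bool),  # inhibited from 1 mM
        "hardy": np.ones(7, bool),                      # never inhibited
    },
)

for strain in table.growth:
    print(ld.compute_mic(table, strain))
# "MIC(isolateA, AsO4) = 8 mM" reads: 8 mM is the lowest tested concentration
# that fully blocks growth; the censored strain would need higher doses.
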