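"""Threshold sweep of small-world metrics on a subject-average network.

The subject's trial-averaged PLV matrix is binarized over the threshold
grid; at each T the clustering coefficient C and characteristic path length
L are compared against 20 edge-count-matched uniform random networks to
form gamma = C/Cr, lambda = L/Lr and the small-world index S = gamma/lambda.
"""

import numpy as np

from eegfc import (
    BANDS, CoupledPair, CouplingSpec, generate_epochs, mean_matrix,
    plv_matrix, sweep_table, threshold_sweep,
)

# a ring of coupled neighbours produces lattice-like (clustered) structure
n_ch = 16
pairs = tuple(CoupledPair(i, (i + 1) % n_ch, 0.8) for i in range(n_ch))
spec = CouplingSpec(band=BANDS["alpha"], pairs=pairs, noise_sd=0.2)
rec = generate_epochs(spec, n_epochs=8, epoch_len_s=6.0, fs=250.0,
                      n_channels=n_ch, seed=5)

avg = mean_matrix(plv_matrix(rec, BANDS["alpha"]))
sweep = threshold_sweep(avg, n_random=20, seed=0)
table = sweep_table(sweep).dropna()

print(table.iloc[::6].to_string(index=False,
                                float_format=lambda v: f"{v:.3f}"))
defined = table[table["S"].notna()]
best = defined.loc[defined["S"].idxmax()]
print(f"\nmax S = {best['S']:.3f} at T = {best['T']:.3f} "
      f"(gamma = {best['gamma']:.3f}, lambda = {best['lambda']:.3f}): "
      "at mid thresholds the coupled ring is more clustered than a random "
      "network of the same density at a comparable path length.")
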