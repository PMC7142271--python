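"""Compute the four functional-connectivity metrics on a coupled recording.

One channel pair (0, 1) is coupled with a quarter-cycle phase lag; the pair
(2, 3) is independent.  Coherence and PLV see the coupling regardless of the
lag; PLI sees it *because* the lag is nonzero (zero-lag coupling is invisible
to PLI by construction); time-domain correlation is nearly blind to this
particular coupling because a quarter-cycle shift makes narrowband signals
orthogonal.
"""

import numpy as np

from eegfc import BANDS, CoupledPair, CouplingSpec, generate_epochs, subject_connectivity

spec = CouplingSpec(band=BANDS["alpha"],
                    pairs=(CoupledPair(0, 1, 0.9, np.pi / 2),), noise_sd=0.2)
rec = generate_epochs(spec, n_epochs=5, epoch_len_s=6.0, fs=250.0,
                      n_channels=4, seed=3)

print(f"{rec.n_trials} trials x {rec.n_channels} channels, alpha band (8-13 Hz)")
print(f"{'metric':<12} {'coupled (0,1)':>14} {'independent (2,3)':>18}")
for metric in ("coherence", "correlation", "plv", "pli"):
    mats = subject_connectivity(rec, metric, BANDS["alpha"])
    coupled = np.mean([m.values[0, 1] for m in mats])
    indep = np.mean([m.values[2, 3] for m in mats])
    print(f"{metric:<12} {coupled:>14.3f} {indep:>18.3f}")
# Coherence/PLV/PLI approach 1 on the coupled pair while independent pairs
# sit at the finite-sample null level (not 0: narrowband phases are
# autocorrelated, so 6 s of signal contains far fewer than 1500 independent
# phase samples).  Correlation stays near 0 on the coupled pair: the pi/2
# lag decorrelates the waveforms even though their phases are locked.
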