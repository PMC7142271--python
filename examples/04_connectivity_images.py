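"""Encode connectivity matrices as square images and stack three bands as RGB.

The strictly-upper triangle of the symmetric matrix is read row by row and
refilled into the largest square that fits; the short tail is dropped.  For
128 channels that is 8,128 values -> a 90 x 90 image with a 28-value tail
consisting exactly of the pairs among channels E121-E128.
"""

import numpy as np

from eegfc import (
    BANDS, ConnectivityMatrix, discarded_pairs, matrix_to_image, rank_bands,
    stack_three_bands, upper_triangle_vector,
)

rng = np.random.default_rng(0)
m = rng.uniform(0, 1, (128, 128))
m = (m + m.T) / 2
np.fill_diagonal(m, 1.0)

vec = upper_triangle_vector(m)
img = matrix_to_image(ConnectivityMatrix(m, "coherence", BANDS["delta"]))
tail = discarded_pairs(128)
print(f"upper triangle: {vec.size} values -> image {img.pixels.shape}, "
      f"{vec.size - img.side**2} discarded")
print(f"discarded pairs all among the last 8 channels: "
      f"{all(i >= 120 for i, _ in tail)} (n={len(tail)})")

# stack the three best bands (by single-band CV accuracy) as R, G, B
accuracy_by_band = {"delta": 0.78, "theta": 0.76, "alpha": 0.69,
                    "beta": 0.76, "gamma": 0.75}
order = rank_bands(accuracy_by_band)
imgs = {b: matrix_to_image(ConnectivityMatrix(m, "coherence", BANDS[b]))
        for b in order}
rgb = stack_three_bands(*(imgs[b] for b in order))
print(f"three-channel image {rgb.pixels.shape}, band order R,G,B = {rgb.bands}")
# The channel order is descending single-band accuracy: the red channel
# carries the most discriminative band.
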