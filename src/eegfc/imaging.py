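"""Encode connectivity matrices as square images for the CNN.

Only the strictly-upper triangle of a symmetric ``n x n`` connectivity
matrix is informative (the diagonal is the self-connectivity).  Its
``n(n-1)/2`` values are read line by line (row-major) and refilled, line by
line, into the largest square that fits; the short tail that does not fit
is discarded.  For 128 channels: 8,128 off-diagonal values -> a 90 x 90
image with a 28-element tail, and because the enumeration is row-major the
discarded tail is exactly the set of pairs among the last eight channels
(E121-E128) — for the Geodesic net these sit on the face and carry the most
myogenic/ocular contamination.

Three single-band images can be stacked as the red, green and blue
channels of a three-channel image; by convention the channel order is
descending single-band classification accuracy (red = best band).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isqrt
from typing import Mapping, Sequence

import numpy as np

from .connectivity import ConnectivityMatrix


@dataclass
class ConnectivityImage:
    """Square image (side x side, optionally x 3) from connectivity values."""

    pixels: np.ndarray
    metric: str = ""
    bands: tuple[str, ...] = ()
    subject_id: str = "S000"
    trial_index: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim == 2:
            ok = p.shape[0] == p.shape[1]
        elif p.ndim == 3:
            ok = p.shape[0] == p.shape[1] and p.shape[2] in (1, 3)
        else:
            ok = False
        if not ok:
            raise ValueError(f"pixels must be side x side (x 1|3), got {p.shape}")
        self.pixels = p

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_img_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


def upper_triangle_vector(m: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Strictly-above-diagonal elements in row-major order, length n(n-1)/2."""
    v = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {v.shape}")
    return v[np.triu_indices(v.shape[0], k=1)]


def image_side(vector_length: int) -> int:
    """Largest integer side with ``side**2 <= vector_length``."""
    return isqrt(vector_length)


def discarded_pairs(n_channels: int) -> list[tuple[int, int]]:
    """(i, j) channel pairs whose values fall off the end of the square.

    With row-major enumeration these are always pairs among the
    highest-numbered channels; for n = 128 exactly the 28 pairs among
    channels 121-128 (0-based indices 120-127).
    """
    iu = np.triu_indices(n_channels, k=1)
    side = image_side(len(iu[0]))
    return list(zip(iu[0][side * side :].tolist(), iu[1][side * side :].tolist()))


def vector_to_square(
    vec: np.ndarray,
    metric: str = "",
    bands: tuple[str, ...] = (),
    subject_id: str = "S000",
    trial_index: int = 0,
) -> ConnectivityImage:
    """Fill the first ``side**2`` elements row by row; discard the tail."""
    vec = np.asarray(vec).ravel()
    if vec.size < 4:
        raise ValueError("need at least 4 elements to form a square image")
    side = image_side(vec.size)
    return ConnectivityImage(
        vec[: side * side].reshape(side, side),
        metric=metric,
        bands=bands,
        subject_id=subject_id,
        trial_index=trial_index,
    )


def matrix_to_image(m: ConnectivityMatrix | np.ndarray) -> ConnectivityImage:
    """Connectivity matrix -> single-channel square image.

    Deterministic and order-preserving; note the encoding is keyed to the
    channel numbering, so renumbering channels changes the image (electrode
    locations are deliberately not represented).
    """
    vec = upper_triangle_vector(m)
    if isinstance(m, ConnectivityMatrix):
        return vector_to_square(
            vec,
            metric=m.metric,
            bands=(m.band.name,),
            subject_id=m.subject_id,
            trial_index=m.trial_index,
        )
    return vector_to_square(vec)


def stack_three_bands(
    img_r: ConnectivityImage, img_g: ConnectivityImage, img_b: ConnectivityImage
) -> ConnectivityImage:
    """RGB stack of three single-band images of one metric.

    Callers order the inputs by descending single-band accuracy (red =
    best); :func:`rank_bands` derives that order from an accuracy table.
    """
    imgs = (img_r, img_g, img_b)
    sides = {im.side for im in imgs}
    if len(sides) != 1:
        raise ValueError(f"mismatched image sides: {sorted(sides)}")
    if any(im.pixels.ndim != 2 for im in imgs):
        raise ValueError("inputs must be single-channel images")
    metrics = {im.metric for im in imgs}
    if len(metrics) != 1:
        raise ValueError(f"images mix metrics: {sorted(metrics)}")
    bands = tuple(im.bands[0] if im.bands else "" for im in imgs)
    if len(set(bands)) != 3:
        raise ValueError(f"three distinct bands required, got {bands}")
    return ConnectivityImage(
        np.stack([im.pixels for im in imgs], axis=-1),
        metric=img_r.metric,
        bands=bands,
        subject_id=img_r.subject_id,
        trial_index=img_r.trial_index,
    )


def rank_bands(accuracy_by_band: Mapping[str, float], top: int = 3) -> tuple[str, ...]:
    """Bands sorted by descending classification accuracy (ties by name)."""
    ordered = sorted(accuracy_by_band.items(), key=lambda kv: (-kv[1], kv[0]))
    return tuple(name for name, _ in ordered[:top])
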