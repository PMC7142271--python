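"""Functional-connectivity matrices: coherence, correlation, PLV and PLI.

One symmetric ``n_channels x n_channels`` matrix per trial, per metric,
per frequency band.

Estimator conventions
---------------------
coherence
    ``|<S_xy(f)>| / sqrt(<S_xx(f)> <S_yy(f)>)`` with cross-spectra averaged
    over Hann-tapered windows (default 1 s, 50% overlap) *within* the trial,
    then averaged over the FFT bins whose centres fall in ``[f_lo, f_hi)``.
    A single window would make coherence identically 1, so at least two
    averaging windows are required.
correlation
    Pearson correlation of the band-filtered time series within the trial.
    The matrix carries absolute values (thresholding and image pixels are
    defined on [0, 1]); the signed matrix is retained in ``signed_values``.
plv
    ``|mean_k exp(i (phi_x[k] - phi_y[k]))|`` over time samples within the
    trial, phases from the analytic signal (Hilbert transform) of the
    band-filtered series.  Phase estimates near the epoch edges are
    unreliable, so half a second at each end is trimmed by default.
pli
    ``|mean_k sign(wrap(phi_x[k] - phi_y[k]))|`` with differences wrapped to
    ``(-pi, pi]`` and ``sign(0) = 0``; blind to zero-lag (volume-conduction
    -like) coupling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.signal import hilbert

from .preprocessing import BandDefinition, EpochedRecording, bandpass

METRICS = ("coherence", "correlation", "plv", "pli")


@dataclass
class ConnectivityMatrix:
    """Symmetric connectivity matrix for one (subject, trial, metric, band)."""

    values: np.ndarray
    metric: str
    band: BandDefinition
    subject_id: str = "S000"
    trial_index: int = 0
    signed_values: np.ndarray | None = None  # correlation only

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {v.shape}")
        asym = np.max(np.abs(v - v.T)) if v.size else 0.0
        if asym > 1e-10:
            raise ValueError(f"matrix asymmetry {asym:.2e} exceeds 1e-10")
        lo = -1.0 if self.metric == "correlation" else 0.0
        if v.min() < lo - 1e-9 or v.max() > 1.0 + 1e-9:
            raise ValueError(
                f"{self.metric} values outside [{lo}, 1]: "
                f"range [{v.min():.4f}, {v.max():.4f}]"
            )
        self.values = np.clip(v, lo, 1.0)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def _trial_iter(rec: EpochedRecording):
    for t in range(rec.n_trials):
        yield t, rec.data[t]


def _band_phases(
    rec: EpochedRecording, band: BandDefinition, edge_trim_s: float
) -> np.ndarray:
    """Instantaneous phases, trials x channels x samples, edges trimmed."""
    filtered = bandpass(rec, band)
    phases = np.angle(hilbert(filtered.data, axis=-1))
    trim = int(round(edge_trim_s * rec.fs))
    if 2 * trim >= rec.n_samples:
        raise ValueError("edge trim leaves no samples; reduce edge_trim_s")
    return phases[..., trim : rec.n_samples - trim] if trim else phases


# ---------------------------------------------------------------------------
# the four estimators
# ---------------------------------------------------------------------------

def coherence_matrix(
    rec: EpochedRecording,
    band: BandDefinition,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> list[ConnectivityMatrix]:
    """Magnitude-squared-free coherence per trial, averaged over band bins."""
    nperseg = int(round(window_s * rec.fs))
    step = max(1, int(round(nperseg * (1 - overlap))))
    if nperseg > rec.n_samples:
        raise ValueError("window longer than trial")
    n_win = 1 + (rec.n_samples - nperseg) // step
    if n_win < 2:
        raise ValueError(
            "coherence needs at least 2 averaging windows per trial "
            "(a single window gives coherence identically 1)"
        )
    win = sps.get_window("hann", nperseg)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / rec.fs)
    band_bins = np.flatnonzero((freqs >= band.f_lo) & (freqs < band.f_hi))
    if band_bins.size == 0:
        raise ValueError(f"no FFT bins inside band {band.name!r}")

    out = []
    for t, x in _trial_iter(rec):
        # windows: channels x n_win x nperseg
        segs = np.lib.stride_tricks.sliding_window_view(x, nperseg, axis=-1)[:, ::step, :]
        segs = segs - segs.mean(axis=-1, keepdims=True)
        X = np.fft.rfft(segs * win, axis=-1)[:, :, band_bins]
        sxy = np.einsum("ikf,jkf->ijf", X, np.conj(X)) / X.shape[1]
        idx = np.arange(sxy.shape[0])
        auto = np.real(sxy[idx, idx])  # channels x band_bins
        denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            coh_f = np.abs(sxy) / denom
        coh = np.nanmean(coh_f, axis=-1)
        coh = 0.5 * (coh + coh.T)
        np.fill_diagonal(coh, 1.0)
        out.append(
            ConnectivityMatrix(
                np.clip(coh, 0.0, 1.0), "coherence", band, rec.subject_id, t
            )
        )
    return out


def correlation_matrix(
    rec: EpochedRecording, band: BandDefinition
) -> list[ConnectivityMatrix]:
    """Pearson correlation of band-filtered series; |r| stored, signed kept."""
    filtered = bandpass(rec, band)
    out = []
    for t, x in _trial_iter(filtered):
        sd = x.std(axis=-1)
        if np.any(sd == 0):
            ch = int(np.flatnonzero(sd == 0)[0])
            raise ValueError(
                f"zero-variance channel {rec.channel_labels[ch]!r} in trial {t}: "
                "correlation undefined"
            )
        r = np.corrcoef(x)
        r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        out.append(
            ConnectivityMatrix(
                np.abs(r), "correlation", band, rec.subject_id, t, signed_values=r
            )
        )
    return out


def plv_matrix(
    rec: EpochedRecording, band: BandDefinition, edge_trim_s: float = 0.5
) -> list[ConnectivityMatrix]:
    """Phase-locking value per trial from analytic-signal phases."""
    phases = _band_phases(rec, band, edge_trim_s)
    out = []
    for t in range(rec.n_trials):
        z = np.exp(1j * phases[t])
        plv = np.abs(z @ np.conj(z.T)) / z.shape[1]
        plv = 0.5 * (plv + plv.T)
        np.fill_diagonal(plv, 1.0)
        out.append(
            ConnectivityMatrix(np.clip(plv, 0, 1), "plv", band, rec.subject_id, t)
        )
    return out


def wrap_phase(d: np.ndarray) -> np.ndarray:
    """Wrap phase differences to the interval ``(-pi, pi]``."""
    w = np.mod(d, 2 * np.pi)
    w = np.where(w > np.pi, w - 2 * np.pi, w)
    return w


def plv_from_phases(phi_x: np.ndarray, phi_y: np.ndarray) -> float:
    """PLV of two instantaneous-phase series: |mean unit phasor of the difference|."""
    return float(np.abs(np.mean(np.exp(1j * (np.asarray(phi_x) - np.asarray(phi_y))))))


def pli_from_phases(phi_x: np.ndarray, phi_y: np.ndarray) -> float:
    """PLI of two phase series: |mean sign of the wrapped difference|, sign(0)=0."""
    return float(np.abs(np.mean(np.sign(wrap_phase(np.asarray(phi_x) - np.asarray(phi_y))))))


def pli_matrix(
    rec: EpochedRecording, band: BandDefinition, edge_trim_s: float = 0.5
) -> list[ConnectivityMatrix]:
    """Phase-lag index per trial: |mean sign of wrapped phase differences|."""
    phases = _band_phases(rec, band, edge_trim_s)
    n_ch = rec.n_channels
    out = []
    for t in range(rec.n_trials):
        p = phases[t]
        pli = np.empty((n_ch, n_ch))
        for i in range(n_ch):  # row-wise to bound memory at n_ch x n_samples
            pli[i] = np.abs(np.mean(np.sign(wrap_phase(p[i] - p)), axis=-1))
        pli = 0.5 * (pli + pli.T)
        np.fill_diagonal(pli, 0.0)
        out.append(
            ConnectivityMatrix(np.clip(pli, 0, 1), "pli", band, rec.subject_id, t)
        )
    return out


_DISPATCH = {
    "coherence": coherence_matrix,
    "correlation": correlation_matrix,
    "plv": plv_matrix,
    "pli": pli_matrix,
}


def subject_connectivity(
    rec: EpochedRecording, metric: str, band: BandDefinition, **kwargs
) -> list[ConnectivityMatrix]:
    """One connectivity matrix per trial for the named metric."""
    if metric not in _DISPATCH:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    return _DISPATCH[metric](rec, band, **kwargs)


def mean_matrix(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Average of a subject's per-trial matrices (one network per subject)."""
    if not matrices:
        raise ValueError("no matrices to average")
    m0 = matrices[0]
    stack = np.stack([m.values for m in matrices])
    return ConnectivityMatrix(
        stack.mean(axis=0), m0.metric, m0.band, m0.subject_id, trial_index=-1
    )
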