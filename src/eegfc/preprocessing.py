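"""Epoched-recording container, canonical frequency bands, filtering and segmentation.

The container holds one subject's epoched multichannel EEG as a dense
``trials x channels x samples`` array plus the metadata every downstream
stage needs (sampling rate, channel labels, per-trial block labels, group
label).  Filtering uses 4th-order Butterworth sections applied
forward-backward (zero-phase), the standard choice when instantaneous
phase is extracted later: a causal filter would add a frequency-dependent
phase shift and bias PLV/PLI.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency interval, half-open ``[f_lo, f_hi)`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got "
                f"[{self.f_lo}, {self.f_hi})"
            )


#: Canonical EEG rhythm bands (Hz).
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 70.0),
}


def default_channel_labels(n_channels: int) -> list[str]:
    """Geodesic-net style labels ``E1 .. En``."""
    return [f"E{i + 1}" for i in range(n_channels)]


@dataclass
class EpochedRecording:
    """One subject's epoched EEG: ``data[trial, channel, sample]``."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = "S000"
    group_label: str | None = None
    block_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be trials x channels x samples, got shape {self.data.shape}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[1]} channels"
            )
        bad = ~np.isfinite(self.data)
        if bad.any():
            t, c, s = (int(v[0]) for v in np.nonzero(bad))
            raise ValueError(
                f"non-finite sample in subject {self.subject_id!r}: trial {t}, "
                f"channel {self.channel_labels[c]!r} (index {c}), sample {s}"
            )
        if self.block_labels is not None and len(self.block_labels) != self.data.shape[0]:
            raise ValueError("block_labels must have one entry per trial")

    # -- convenience ------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray) -> "EpochedRecording":
        """Copy of this recording with the signal array replaced."""
        return replace(self, data=data)


# ---------------------------------------------------------------------------
# container I/O: one .npz per subject + JSON sidecar with the metadata
# ---------------------------------------------------------------------------

def write_recording(rec: EpochedRecording, path: str | Path) -> Path:
    """Write ``<path>.npz`` (data) and ``<path>.json`` (metadata)."""
    path = Path(path)
    if path.suffix == ".npz":
        path = path.with_suffix("")
    np.savez(path.with_suffix(".npz"), data=rec.data)
    meta = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "subject_id": rec.subject_id,
        "group_label": rec.group_label,
        "block_labels": rec.block_labels,
    }
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path.with_suffix(".npz")


def _read_container(path: Path) -> EpochedRecording:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta or "channel_labels" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks fs or channel_labels")
    with np.load(path) as npz:
        data = npz["data"]
    return EpochedRecording(
        data=data,
        fs=float(meta["fs"]),
        channel_labels=list(meta["channel_labels"]),
        subject_id=meta.get("subject_id", path.stem),
        group_label=meta.get("group_label"),
        block_labels=meta.get("block_labels"),
    )


def _read_edf(path: Path) -> EpochedRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()  # channels x samples, continuous
    # continuous input: returned unsegmented, as a single trial
    return EpochedRecording(
        data=data[np.newaxis, :, :],
        fs=fs,
        channel_labels=list(raw.ch_names),
        subject_id=path.stem,
    )


def read_recording(path: str | Path, format: str = "auto") -> EpochedRecording:
    """Read a recording from the package container (``.npz``) or EDF.

    Continuous EDF input is returned unsegmented (one trial spanning the
    whole record); use :func:`segment` afterwards.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = {".npz": "container", ".edf": "edf"}.get(path.suffix.lower(), "")
    if format == "container":
        return _read_container(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown recording format {format!r} for {path}")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _sos_bandpass(lo: float, hi: float, fs: float, order: int = 4):
    if hi >= fs / 2:
        raise ValueError(
            f"upper cutoff {hi} Hz must be below the Nyquist frequency {fs / 2} Hz"
        )
    if lo <= 0:
        raise ValueError("lower cutoff must be positive")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def broadband_filter(
    rec: EpochedRecording, lo: float = 0.5, hi: float = 70.0
) -> EpochedRecording:
    """Zero-phase broadband filter (defaults 0.5–70 Hz), per channel per trial."""
    sos = _sos_bandpass(lo, hi, rec.fs)
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=-1))


def bandpass(rec: EpochedRecording, band: BandDefinition) -> EpochedRecording:
    """Zero-phase band-pass restricted to ``band`` (half-open [f_lo, f_hi))."""
    sos = _sos_bandpass(band.f_lo, band.f_hi, rec.fs)
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=-1))


def select_block(rec: EpochedRecording, block: str) -> EpochedRecording:
    """Trials belonging to one task block (e.g. "Neu" or "Emo")."""
    if rec.block_labels is None:
        raise ValueError("recording has no block labels")
    idx = [i for i, b in enumerate(rec.block_labels) if b == block]
    if not idx:
        raise ValueError(f"no trials in block {block!r}")
    return replace(rec, data=rec.data[idx],
                   block_labels=[rec.block_labels[i] for i in idx])


def clean(
    rec: EpochedRecording,
    cleaner: Callable[[EpochedRecording], EpochedRecording] | None = None,
) -> EpochedRecording:
    """Pluggable artifact-removal hook.

    Artifact rejection (ocular ICA, amplitude criteria, ...) is deliberately
    delegated: pass any callable mapping recording -> recording.  The default
    is the identity, appropriate for synthetic data.
    """
    return rec if cleaner is None else cleaner(rec)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment(
    continuous: np.ndarray | EpochedRecording,
    fs: float | None = None,
    epoch_len_s: float = 6.0,
    marks: Sequence[int] | None = None,
    channel_labels: Sequence[str] | None = None,
) -> EpochedRecording:
    """Cut a continuous multichannel signal into fixed-length epochs.

    Parameters
    ----------
    continuous
        ``channels x samples`` array, or a single-trial
        :class:`EpochedRecording` (e.g. fresh from an EDF read).
    marks
        Trial-onset sample indices.  Without marks the signal is tiled
        uniformly; the partial tail is discarded.  A mark closer than one
        epoch length to the end drops that epoch with a warning.
    """
    if isinstance(continuous, EpochedRecording):
        if continuous.n_trials != 1:
            raise ValueError("segment() expects a continuous (single-trial) recording")
        fs = continuous.fs
        channel_labels = continuous.channel_labels
        sig = continuous.data[0]
        subject_id = continuous.subject_id
        group_label = continuous.group_label
    else:
        if fs is None:
            raise ValueError("fs is required when passing a bare array")
        sig = np.atleast_2d(np.asarray(continuous, dtype=np.float64))
        subject_id, group_label = "S000", None
    n_ch, n_samp = sig.shape
    n_ep = int(round(epoch_len_s * fs))
    if n_ep <= 0:
        raise ValueError("epoch length must span at least one sample")

    if marks is None:
        starts = list(range(0, n_samp - n_ep + 1, n_ep))
    else:
        starts, dropped = [], []
        for m in marks:
            (starts if m + n_ep <= n_samp else dropped).append(int(m))
        if dropped:
            warnings.warn(
                f"dropped {len(dropped)} mark(s) closer than one epoch "
                f"({n_ep} samples) to the end of the signal: {dropped}",
                stacklevel=2,
            )
    if not starts:
        warnings.warn("signal shorter than one epoch: zero epochs produced", stacklevel=2)
        epochs = np.empty((0, n_ch, n_ep))
    else:
        epochs = np.stack([sig[:, s : s + n_ep] for s in starts])
    labels = (
        list(channel_labels) if channel_labels is not None else default_channel_labels(n_ch)
    )
    return EpochedRecording(
        data=epochs,
        fs=float(fs),
        channel_labels=labels,
        subject_id=subject_id,
        group_label=group_label,
    )
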