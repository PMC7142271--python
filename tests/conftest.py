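import numpy as np
import pytest

from eegfc import BANDS, CoupledPair, CouplingSpec, generate_epochs


@pytest.fixture
def make_recording():
    """Factory for small coupled synthetic recordings."""

    def _make(
        pairs=((0, 1, 1.0, 0.0),),
        noise_sd=0.0,
        band=BANDS["alpha"],
        n_epochs=3,
        n_channels=4,
        fs=250.0,
        epoch_len_s=6.0,
        seed=7,
        amplitude_corr=False,
    ):
        spec = CouplingSpec(
            band=band,
            pairs=tuple(CoupledPair(*p) for p in pairs),
            noise_sd=noise_sd,
            amplitude_corr=amplitude_corr,
        )
        return generate_epochs(
            spec, n_epochs=n_epochs, epoch_len_s=epoch_len_s, fs=fs,
            n_channels=n_channels, seed=seed,
        )

    return _make


def write_minimal_edf(path, data, fs):
    """Tiny EDF writer (int16, 1-second records) used only as a test fixture."""
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    fs = int(fs)
    n_records = int(np.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samp] = data
    pmin, pmax = float(padded.min() - 1), float(padded.max() + 1)
    dmin, dmax = -32768, 32767

    def f(s, n):
        return str(s)[:n].ljust(n).encode("ascii")

    hdr = b"".join([
        f("0", 8), f("X", 80), f("X", 80),
        f("01.01.20", 8), f("00.00.00", 8),
        f(256 * (1 + n_ch), 8), f("", 44),
        f(n_records, 8), f(1, 8), f(n_ch, 4),
    ])
    hdr += b"".join(f(f"EEG E{i + 1}", 16) for i in range(n_ch))
    hdr += b"".join(f("", 80) for _ in range(n_ch))
    hdr += b"".join(f("uV", 8) for _ in range(n_ch))
    hdr += b"".join(f(f"{pmin:.3f}", 8) for _ in range(n_ch))
    hdr += b"".join(f(f"{pmax:.3f}", 8) for _ in range(n_ch))
    hdr += b"".join(f(dmin, 8) for _ in range(n_ch))
    hdr += b"".join(f(dmax, 8) for _ in range(n_ch))
    hdr += b"".join(f("", 80) for _ in range(n_ch))
    hdr += b"".join(f(fs, 8) for _ in range(n_ch))
    hdr += b"".join(f("", 32) for _ in range(n_ch))
    scale = (dmax - dmin) / (pmax - pmin)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            chunk = padded[:, r * fs : (r + 1) * fs]
            dig = np.round((chunk - pmin) * scale + dmin).astype("<i2")
            fh.write(dig.tobytes())
    return path
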