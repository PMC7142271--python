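"""Synthetic multichannel EEG with controllable phase coupling.

Every downstream stage of the pipeline (connectivity estimation, graph
analysis, image encoding, classification) is exercised on signals whose
coupling structure is known by construction.  The signal model uses
band-centred stochastic oscillators — narrowband-filtered Gaussian noise
carriers — rather than pure sinusoids, so that coherence and PLV take
nontrivial values (< 1) at intermediate coupling strengths instead of
saturating.

Coupling between a pair of channels is realised by mixing a shared
narrowband carrier into both channels with weight equal to the coupling
strength; the stated phase lag is applied by rotating the carrier's
analytic signal, which gives direct control of the downstream PLV/PLI
ground truth:

* strength 1, lag 0, no noise  ->  PLV = 1, PLI = 0 (zero-lag coupling)
* strength 1, lag pi/2         ->  PLI = 1 (all phase differences one-sided)
* strength 0                   ->  channels independent; PLV at the
  finite-sample null level for the number of samples used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .preprocessing import (
    BandDefinition,
    BANDS,
    EpochedRecording,
    default_channel_labels,
    write_recording,
    read_recording,
)

#: default group labels for two-group cohorts
GROUPS = ("control", "depressed")


@dataclass(frozen=True)
class CoupledPair:
    """One coupled channel pair: indices, mixing weight and phase lag."""

    i: int
    j: int
    strength: float
    phase_lag: float = 0.0

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("a channel cannot be coupled to itself")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError(f"coupling strength must lie in [0, 1], got {self.strength}")


@dataclass(frozen=True)
class CouplingSpec:
    """Band-specific coupling structure injected into a synthetic recording."""

    band: BandDefinition
    pairs: tuple[CoupledPair, ...] = ()
    noise_sd: float = 0.2
    amplitude_corr: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        # normalize plain tuples into CoupledPair
        pairs = tuple(
            p if isinstance(p, CoupledPair) else CoupledPair(*p) for p in self.pairs
        )
        object.__setattr__(self, "pairs", pairs)

    def validate_for(self, fs: float, n_channels: int) -> None:
        if self.band.f_hi > fs / 2:
            raise ValueError(
                f"band {self.band.name!r} upper edge {self.band.f_hi} Hz exceeds "
                f"the Nyquist frequency {fs / 2} Hz"
            )
        for p in self.pairs:
            if not (0 <= p.i < n_channels and 0 <= p.j < n_channels):
                raise ValueError(f"pair ({p.i}, {p.j}) outside 0..{n_channels - 1}")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort layout; defaults emulate a 48-subject, 128-channel study."""

    n_per_group: int = 24
    n_epochs: int = 30
    epoch_len_s: float = 6.0
    fs: float = 250.0
    n_channels: int = 128
    base: CouplingSpec = field(
        default_factory=lambda: CouplingSpec(band=BANDS["alpha"])
    )
    group_effect: Mapping[str, CouplingSpec] | None = None
    group_names: tuple[str, str] = GROUPS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        n = self.n_epochs * self.epoch_len_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("n_epochs * epoch_len_s * fs must be an integer sample count")


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _narrowband_analytic(
    rng: np.random.Generator, n: int, fs: float, band: BandDefinition
) -> np.ndarray:
    """Unit-RMS analytic (positive-frequency) narrowband Gaussian noise."""
    spec = np.fft.fft(rng.standard_normal(n))
    f = np.fft.fftfreq(n, d=1.0 / fs)
    mask = (f >= band.f_lo) & (f < band.f_hi)  # positive frequencies only
    spec[~mask] = 0.0
    z = 2.0 * np.fft.ifft(spec)
    rms = np.sqrt(np.mean(z.real**2))
    return z / rms if rms > 0 else z


def generate_epochs(
    spec: CouplingSpec | Sequence[CouplingSpec],
    n_epochs: int,
    epoch_len_s: float,
    fs: float,
    n_channels: int,
    seed: int,
    subject_id: str = "S000",
    group_label: str | None = None,
    block_labels: Sequence[str] | None = None,
) -> EpochedRecording:
    """Generate epoched multichannel signals realizing the coupling spec(s).

    Each epoch draws fresh carriers, so the baseline phase is random per
    epoch while coupled pairs share phase up to the stated lag within each
    epoch.  Deterministic for a fixed seed.
    """
    specs = [spec] if isinstance(spec, CouplingSpec) else list(spec)
    for s in specs:
        s.validate_for(fs, n_channels)
    n_samp = int(round(epoch_len_s * fs))
    rng = np.random.default_rng(seed)
    data = np.zeros((n_epochs, n_channels, n_samp))

    for ep in range(n_epochs):
        for s in specs:
            contrib = np.empty((n_channels, n_samp))
            # independent narrowband background for every channel
            for c in range(n_channels):
                contrib[c] = _narrowband_analytic(rng, n_samp, fs, s.band).real
            env = None
            if s.amplitude_corr:
                # shared slow Rayleigh-like envelope -> amplitude correlation
                # without phase locking (multiplying by a positive envelope
                # leaves instantaneous phase untouched)
                slow = _narrowband_analytic(
                    rng, n_samp, fs, BandDefinition("env", 0.1, 1.0)
                )
                env = np.abs(slow)
                env /= env.mean()
            for p in s.pairs:
                carrier = _narrowband_analytic(rng, n_samp, fs, s.band)
                xi = p.strength * carrier.real + (1 - p.strength) * contrib[p.i]
                lagged = (carrier * np.exp(-1j * p.phase_lag)).real
                xj = p.strength * lagged + (1 - p.strength) * contrib[p.j]
                contrib[p.i], contrib[p.j] = xi, xj
            if env is not None:
                idx = sorted({k for p in s.pairs for k in (p.i, p.j)})
                contrib[idx] *= env
            data[ep] += contrib
        noise_sd = max((s.noise_sd for s in specs), default=0.0)
        if noise_sd > 0:
            data[ep] += noise_sd * rng.standard_normal((n_channels, n_samp))

    return EpochedRecording(
        data=data,
        fs=fs,
        channel_labels=default_channel_labels(n_channels),
        subject_id=subject_id,
        group_label=group_label,
        block_labels=list(block_labels) if block_labels is not None else None,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def subject_seed(master_seed: int, subject_index: int) -> int:
    """Deterministic, well-separated per-subject seed."""
    ss = np.random.SeedSequence([int(master_seed), int(subject_index)])
    return int(ss.generate_state(1)[0])


def _merge(base: CouplingSpec, delta: CouplingSpec | None) -> CouplingSpec:
    """Group-effect merge: delta pairs replace/extend base pairs for its band."""
    if delta is None:
        return base
    merged = {(p.i, p.j): p for p in base.pairs}
    for p in delta.pairs:
        merged[(p.i, p.j)] = p
    return dataclasses.replace(delta, pairs=tuple(merged.values()))


def generate_cohort(spec: CohortSpec) -> list[EpochedRecording]:
    """Generate a labeled two-group cohort of epoched recordings.

    Per-subject seeds derive deterministically from the master seed; the
    group effect applies only to the designated group(s).  With an empty
    group effect the two groups are exchangeable by construction.
    """
    effect = dict(spec.group_effect or {})
    unknown = set(effect) - set(spec.group_names)
    if unknown:
        raise ValueError(f"group_effect refers to unknown group(s): {sorted(unknown)}")
    half_blocks = spec.n_epochs // 2
    block_labels = ["Neu"] * half_blocks + ["Emo"] * (spec.n_epochs - half_blocks)
    cohort: list[EpochedRecording] = []
    idx = 0
    for group in spec.group_names:
        coupling = _merge(spec.base, effect.get(group))
        for k in range(spec.n_per_group):
            rec = generate_epochs(
                coupling,
                n_epochs=spec.n_epochs,
                epoch_len_s=spec.epoch_len_s,
                fs=spec.fs,
                n_channels=spec.n_channels,
                seed=subject_seed(spec.seed, idx),
                subject_id=f"S{idx:03d}",
                group_label=group,
                block_labels=block_labels,
            )
            cohort.append(rec)
            idx += 1
    return cohort


def write_cohort(cohort: Sequence[EpochedRecording], outdir: str | Path) -> list[Path]:
    """One container file per subject under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return [write_recording(rec, outdir / rec.subject_id) for rec in cohort]


def read_cohort(indir: str | Path) -> list[EpochedRecording]:
    indir = Path(indir)
    return [read_recording(p) for p in sorted(indir.glob("*.npz"))]
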