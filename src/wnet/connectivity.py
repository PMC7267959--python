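"""Windowed-Fourier cross-spectra and weighted phase lag index (WPLI).

The WPLI of a channel pair is

    WPLI = |E[I(X) sgn(I(X))]| / E[|I(X)|] = |E[I(X)]| / E[|I(X)|]

where X is the cross-spectrum of the two signals, I(X) its imaginary part
and E the expectation over observations (epochs x time windows x in-band
frequency bins). Weighting the phase-lag sign by |I(X)| suppresses
near-zero-lag contributions, which on scalp EEG are dominated by volume
conduction. WPLI is bounded in [0, 1]: 0 for no consistent lagged phase
relation, 1 for a constant nonzero lag.

Time-frequency decomposition uses a windowed Fourier transform on a 0.5 Hz
grid with an adaptive window of 3 cycles at the band's low edge ramping
linearly to 10 cycles at the high edge, Hann-tapered, windows sliding at
50% overlap within each epoch.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, InvalidArgumentError
from .synthetic import BANDS, Recording

FREQ_STEP = 0.5  # Hz
MIN_CYCLES, MAX_CYCLES = 3.0, 10.0
_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class CrossSpectrumSet:
    """Pooled complex cross-spectrum observations for all channel pairs.

    values[k, p] is the cross-spectrum of pair p (upper-triangle order) at
    observation k; each observation is one (epoch, window, frequency-bin)
    triple. freqs, epoch_index give the provenance of each observation.
    """

    values: np.ndarray  # complex, (n_obs, n_pairs)
    freqs: np.ndarray  # (n_obs,)
    epoch_index: np.ndarray  # (n_obs,)
    labels: tuple[str, ...]
    band: str
    power: np.ndarray | None = None  # (n_obs, n_channels), taper-windowed auto-spectra

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def pair_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return np.triu_indices(self.n_channels, k=1)

    @classmethod
    def from_pair_observations(cls, values, labels=("ch1", "ch2"), band="alpha"):
        """Wrap raw cross-spectrum observations for a single channel pair."""
        v = np.asarray(values, dtype=complex).reshape(-1, 1)
        return cls(values=v, freqs=np.zeros(len(v)), epoch_index=np.zeros(len(v), dtype=int),
                   labels=tuple(labels), band=band)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric per-band WPLI matrix with channel labels."""

    wpli: np.ndarray
    band: str
    labels: tuple[str, ...]
    n_epochs_used: int

    def __post_init__(self):
        w = self.wpli
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidArgumentError("wpli must be square")
        if w.shape[0] != len(self.labels):
            raise InvalidArgumentError("labels must match matrix size")
        if not np.allclose(w, w.T, atol=1e-9):
            raise InvalidArgumentError("wpli must be symmetric")
        if np.any(np.diag(w) != 0):
            raise InvalidArgumentError("wpli diagonal must be zero")
        if w.min() < -1e-12 or w.max() > 1 + 1e-9:
            raise InvalidArgumentError("wpli entries must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return len(self.labels)


def band_frequency_grid(band: str) -> np.ndarray:
    lo, hi = BANDS[band]
    return np.arange(lo, hi + FREQ_STEP / 2, FREQ_STEP)


def cycles_for(freq: float, band: str) -> float:
    """Adaptive cycle count: 3 at the band's low edge, 10 at the high edge."""
    lo, hi = BANDS[band]
    frac = 0.0 if hi == lo else (freq - lo) / (hi - lo)
    return MIN_CYCLES + (MAX_CYCLES - MIN_CYCLES) * float(np.clip(frac, 0.0, 1.0))


def window_length(freq: float, band: str, epoch_duration: float) -> float:
    """Window length in seconds at one frequency, clipped to the epoch."""
    return min(cycles_for(freq, band) / freq, epoch_duration)


def tfr_windowed_fourier(recording: Recording, band: str) -> CrossSpectrumSet:
    """Windowed-Fourier cross-spectra of all channel pairs in one band."""
    if band not in BANDS:
        raise InvalidArgumentError(f"unknown band {band!r}")
    fs = recording.fs
    lo, hi = BANDS[band]
    if hi > fs / 2:
        raise InvalidArgumentError(f"band {band} exceeds Nyquist ({fs / 2} Hz)")
    n_epochs, n_ch, n_samp = recording.epochs.shape
    duration = n_samp / fs
    freqs = band_frequency_grid(band)
    # precondition: the minimum cycle count must fit the epoch
    for f in freqs:
        if MIN_CYCLES / f > duration + 1e-12:
            raise InvalidArgumentError(
                f"epoch of {duration:.3f} s too short for {MIN_CYCLES:g} cycles at {f:g} Hz"
            )
    iu, ju = np.triu_indices(n_ch, k=1)
    vals, fobs, eobs, pows = [], [], [], []
    t = np.arange(n_samp) / fs
    for f in freqs:
        w_samp = max(2, int(round(window_length(f, band, duration) * fs)))
        w_samp = min(w_samp, n_samp)
        hop = max(1, w_samp // 2)
        starts = np.arange(0, n_samp - w_samp + 1, hop)
        taper = np.hanning(w_samp)
        # normalise to amplitude units so coefficients are comparable
        # across the frequency-dependent window lengths
        carrier = np.exp(-2j * np.pi * f * t[:w_samp]) * taper / (taper.sum() / 2.0)
        for e in range(n_epochs):
            # complex Fourier coefficient per (window, channel)
            seg = np.stack([recording.epochs[e, :, s:s + w_samp] for s in starts])
            coef = seg @ carrier  # (n_windows, n_channels)
            cross = coef[:, iu] * np.conj(coef[:, ju])
            vals.append(cross)
            pows.append((coef * np.conj(coef)).real)
            fobs.append(np.full(len(starts), f))
            eobs.append(np.full(len(starts), e, dtype=int))
    return CrossSpectrumSet(
        values=np.concatenate(vals, axis=0),
        freqs=np.concatenate(fobs),
        epoch_index=np.concatenate(eobs),
        labels=recording.layout.labels,
        band=band,
        power=np.concatenate(pows, axis=0),
    )


def _wpli_from_imag(imag: np.ndarray) -> np.ndarray:
    """|E[I(X)]| / E[|I(X)|] along axis 0, with the zero-denominator -> 0
    convention (an identically real cross-spectrum signals lack of lagged
    connectivity, not an undefined one)."""
    num = np.abs(imag.mean(axis=0))
    den = np.abs(imag).mean(axis=0)
    out = np.zeros_like(den)
    ok = den > _ZERO_TOL
    out[ok] = num[ok] / den[ok]
    return np.clip(out, 0.0, 1.0)


def wpli(cs: CrossSpectrumSet, pooling: str = "joint") -> ConnectivityMatrix:
    """WPLI matrix from a cross-spectrum observation set.

    pooling="joint" (default) takes the expectation over all observations
    at once; pooling="per_epoch" computes a WPLI per epoch and averages the
    per-epoch values — exposed for sensitivity analysis.
    """
    if cs.values.shape[0] == 0:
        raise DegenerateInputError("empty cross-spectrum observation set")
    if pooling not in ("joint", "per_epoch"):
        raise InvalidArgumentError(f"unknown pooling {pooling!r}")
    imag = np.imag(cs.values)
    if pooling == "joint":
        pair_vals = _wpli_from_imag(imag)
    else:
        epochs = np.unique(cs.epoch_index)
        pair_vals = np.mean(
            [_wpli_from_imag(imag[cs.epoch_index == e]) for e in epochs], axis=0
        )
    n = cs.n_channels
    m = np.zeros((n, n))
    iu, ju = cs.pair_indices
    m[iu, ju] = pair_vals
    m[ju, iu] = pair_vals
    return ConnectivityMatrix(
        wpli=m, band=cs.band, labels=cs.labels,
        n_epochs_used=int(len(np.unique(cs.epoch_index))),
    )


def band_matrices(
    recording: Recording,
    bands: tuple[str, ...] = ("theta", "alpha", "beta"),
    pooling: str = "joint",
) -> dict[str, ConnectivityMatrix]:
    """One WPLI matrix per frequency band, expectation pooled over epochs."""
    return {b: wpli(tfr_windowed_fourier(recording, b), pooling=pooling) for b in bands}
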