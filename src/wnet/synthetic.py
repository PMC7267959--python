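"""Synthetic EEG cohorts with planted band-specific connectivity effects.

The generator emulates eyes-closed sensor-space recordings: each channel
carries band-limited oscillations plus broadband noise, and selected channel
pairs share an oscillatory carrier at a controlled phase lag so that
phase-lag-based connectivity (WPLI) can detect them. Groups differ by
multiplicative attenuation of the planted coupling per band, mimicking the
reduced alpha/beta-band synchronisation reported in dementia cohorts, and a
clinical-score table can be generated with an approximate planted rank
correlation against each subject's realised mean coupling.

The signal model is deliberately minimal — a shared sinusoidal carrier mixed
into the lagged channel plus independent per-channel oscillators and white
noise — because its WPLI limits are analytic: unit coupling at lag pi/2 with
no noise gives WPLI exactly 1, and zero coupling gives no systematic phase
relation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import rng_for
from .exceptions import InvalidArgumentError

#: Canonical band edges in Hz (theta, alpha, beta).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.5),
    "alpha": (8.0, 13.5),
    "beta": (14.0, 20.5),
}

#: Scalp region tags.
REGIONS = ("frontal", "lateral", "central", "posterior")

_HEAD_RADIUS_MM = 87.5  # max inter-electrode distance 2R = 175 mm <= 227 mm


@dataclass(frozen=True)
class SensorLayout:
    """Electrode montage: labels, 3-D positions (mm) and scalp regions."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3) in mm
    region: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) != self.positions.shape[0] or len(self.region) != len(self.labels):
            raise InvalidArgumentError("labels, positions and region must align")
        for r in self.region:
            if r not in REGIONS:
                raise InvalidArgumentError(f"unknown region tag {r!r}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def pairwise_distances(self) -> np.ndarray:
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((d**2).sum(-1))


@dataclass(frozen=True)
class CouplingSpec:
    """Planted phase coupling within one frequency band.

    edge_list pairs share a sinusoidal carrier; coupling_strength mixes the
    (lagged) shared carrier into the second channel; phase_lag must be
    nonzero for the coupling to survive a phase-lag-index estimator.
    """

    band: str
    edge_list: tuple[tuple[int, int], ...] = ()
    coupling_strength: tuple[float, ...] = ()
    phase_lag: tuple[float, ...] = ()
    noise_sd: float = 0.2
    amplitude: float = 1.0

    def __post_init__(self):
        if self.band not in BANDS:
            raise InvalidArgumentError(f"unknown band {self.band!r}; expected one of {list(BANDS)}")
        ne = len(self.edge_list)
        if len(self.coupling_strength) != ne or len(self.phase_lag) != ne:
            raise InvalidArgumentError("edge_list, coupling_strength and phase_lag must have equal length")
        for c in self.coupling_strength:
            if not 0.0 <= c <= 1.0:
                raise InvalidArgumentError(f"coupling_strength {c} outside [0, 1]")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: size, per-band coupling attenuation and clinical scores."""

    name: str
    n_subjects: int
    attenuation: dict = field(default_factory=dict)  # band -> factor in [0, 1]
    clinical_means: dict = field(default_factory=dict)  # score -> mean
    clinical_sds: dict = field(default_factory=dict)  # score -> sd
    planted_rho: dict = field(default_factory=dict)  # score -> target Spearman rho
    subject_jitter: float = 0.15  # relative half-width of per-subject coupling jitter

    def __post_init__(self):
        if self.n_subjects < 2:
            raise InvalidArgumentError("each group needs n_subjects >= 2")
        for band, a in self.attenuation.items():
            if band not in BANDS:
                raise InvalidArgumentError(f"unknown band {band!r} in attenuation")
            if not 0.0 <= a <= 1.0:
                raise InvalidArgumentError("attenuation factors must lie in [0, 1]")


@dataclass(frozen=True)
class Recording:
    """One subject's epoched multichannel signal."""

    subject_id: str
    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)
    fs: float
    layout: SensorLayout

    def __post_init__(self):
        if self.epochs.ndim != 3:
            raise InvalidArgumentError("epochs must be (n_epochs, n_channels, n_samples)")
        if self.epochs.shape[1] != self.layout.n_channels:
            raise InvalidArgumentError("channel count does not match layout")
        if not np.all(np.isfinite(self.epochs)):
            raise InvalidArgumentError("epochs contain non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_duration(self) -> float:
        return self.epochs.shape[2] / self.fs


def _assign_region(pos: np.ndarray) -> str:
    # Quadrant rule on head-relative coordinates: +y anterior, +x right.
    x, y = pos[0], pos[1]
    if y > 0.30 * _HEAD_RADIUS_MM:
        return "frontal"
    if y < -0.30 * _HEAD_RADIUS_MM:
        return "posterior"
    if abs(x) > 0.45 * _HEAD_RADIUS_MM:
        return "lateral"
    return "central"


def generate_layout(n_channels: int, seed: int) -> SensorLayout:
    """Deterministic quasi-uniform scalp montage on a head-sized sphere.

    Electrodes are laid out on a Fibonacci spiral over the upper portion of
    a sphere of radius 87.5 mm (roughly a 10-5-density montage at 128
    channels), with a small seeded angular jitter so distinct seeds give
    distinct montages. Regions follow a coordinate quadrant rule: anterior
    -> frontal, posterior -> posterior, midline band -> central, temporal
    band -> lateral.
    """
    if n_channels < 8:
        raise InvalidArgumentError("need at least 8 channels for a meaningful montage")
    rng = rng_for(seed, "layout", n_channels)
    idx = np.arange(n_channels)
    # z spans the scalp cap from slightly below the equator to the vertex
    z = -0.25 + (1.0 + 0.25) * (idx + 0.5) / n_channels
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * idx + rng.uniform(-0.02, 0.02, size=n_channels)
    r_xy = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pos = np.column_stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z]) * _HEAD_RADIUS_MM
    labels = tuple(f"E{i + 1:03d}" for i in idx)
    region = tuple(_assign_region(p) for p in pos)
    return SensorLayout(labels=labels, positions=pos, region=region)


def _check_specs(spec_list, n_channels, fs):
    bands = [s.band for s in spec_list]
    if len(set(bands)) != len(bands):
        raise InvalidArgumentError("overlapping/duplicate bands in spec_list")
    hi = max(BANDS[s.band][1] for s in spec_list) if spec_list else 0.0
    if spec_list and fs < 4 * hi:
        raise InvalidArgumentError(f"fs={fs} Hz too low; need >= 4x the highest band edge ({4 * hi} Hz)")
    for s in spec_list:
        for i, j in s.edge_list:
            if not (0 <= i < n_channels and 0 <= j < n_channels) or i == j:
                raise InvalidArgumentError(f"bad edge ({i}, {j}) for {n_channels} channels")


def generate_recording(
    layout: SensorLayout,
    spec_list: list[CouplingSpec],
    n_epochs: int = 10,
    fs: float = 256.0,
    seed: int = 0,
    epoch_duration: float = 2.0,
    subject_id: str = "S000",
) -> Recording:
    """Simulate one subject's epoched recording from coupling specs.

    Every channel receives, per band spec, an independent sinusoid at an
    epoch-jittered in-band frequency with a random phase. For each planted
    edge (i, j) with strength c and lag phi, channel j's band component is
    ``c * carrier_i(t - phi) + (1 - c) * own oscillator``, so c=1 with zero
    noise reproduces a constant-lag sinusoid pair and c=0 leaves the pair
    phase-independent.
    """
    if n_epochs < 1:
        raise InvalidArgumentError("n_epochs must be >= 1")
    _check_specs(spec_list, layout.n_channels, fs)
    rng = rng_for(seed, "recording", subject_id)
    n_ch = layout.n_channels
    n_samp = int(round(epoch_duration * fs))
    t = np.arange(n_samp) / fs
    epochs = np.zeros((n_epochs, n_ch, n_samp))
    for e in range(n_epochs):
        for spec in spec_list:
            lo, hi = BANDS[spec.band]
            span = hi - lo
            # jittered carrier frequencies in the central 80% of the band
            freqs = rng.uniform(lo + 0.1 * span, hi - 0.1 * span, size=n_ch)
            phases = rng.uniform(0, 2 * np.pi, size=n_ch)
            osc = spec.amplitude * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
            comp = osc.copy()
            for (i, j), c, lag in zip(spec.edge_list, spec.coupling_strength, spec.phase_lag):
                shared = spec.amplitude * np.sin(2 * np.pi * freqs[i] * t + phases[i] - lag)
                comp[j] = c * shared + (1.0 - c) * osc[j]
            epochs[e] += comp
            if spec.noise_sd > 0:
                epochs[e] += rng.normal(0.0, spec.noise_sd, size=(n_ch, n_samp))
    return Recording(subject_id=subject_id, epochs=epochs, fs=fs, layout=layout)


def generate_cohort(
    groups: list[GroupSpec],
    layout: SensorLayout,
    base_specs: list[CouplingSpec],
    seed: int,
    n_epochs: int = 10,
    fs: float = 256.0,
) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate a multi-group cohort plus its clinical-score table.

    Each subject's coupling strengths are the base strengths scaled by the
    group's per-band attenuation and a per-subject multiplicative jitter
    (clipped to [0, 1]); the jittered mean strength is the latent trait that
    planted clinical correlations are generated against. All randomness
    derives deterministically from the master seed.
    """
    if len(groups) < 2:
        raise InvalidArgumentError("need at least 2 groups")
    recordings: list[Recording] = []
    rows = []
    for g in groups:
        traits = np.empty(g.n_subjects)
        subj_ids = []
        for s in range(g.n_subjects):
            sid = f"{g.name}-{s + 1:03d}"
            subj_ids.append(sid)
            jit_rng = rng_for(seed, "jitter", g.name, s)
            specs = []
            strengths = []
            for spec in base_specs:
                att = g.attenuation.get(spec.band, 1.0)
                jit = 1.0 + g.subject_jitter * jit_rng.uniform(-1.0, 1.0)
                new_strengths = tuple(
                    float(np.clip(c * att * jit, 0.0, 1.0)) for c in spec.coupling_strength
                )
                strengths.extend(new_strengths)
                specs.append(replace(spec, coupling_strength=new_strengths))
            traits[s] = np.mean(strengths) if strengths else 0.0
            recordings.append(
                generate_recording(
                    layout, specs, n_epochs=n_epochs, fs=fs,
                    seed=rng_for(seed, "subject", g.name, s).integers(2**31 - 1),
                    subject_id=sid,
                )
            )
        score_rng = rng_for(seed, "clinical", g.name)
        scores = {}
        for name, mean in g.clinical_means.items():
            sd = g.clinical_sds.get(name, 1.0)
            rho = g.planted_rho.get(name)
            if rho is None:
                scores[name] = score_rng.normal(mean, sd, size=g.n_subjects)
            else:
                # Gaussian mixing against the latent trait approximates the
                # target rank correlation (exact rho not guaranteed).
                tz = traits - traits.mean()
                tsd = tz.std()
                tz = tz / tsd if tsd > 0 else np.zeros_like(tz)
                z = rho * tz + np.sqrt(max(0.0, 1 - rho**2)) * score_rng.normal(size=g.n_subjects)
                scores[name] = mean + sd * z
        for s, sid in enumerate(subj_ids):
            rows.append({"subject_id": sid, "group": g.name,
                         **{k: float(v[s]) for k, v in scores.items()}})
    return recordings, pd.DataFrame(rows)
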