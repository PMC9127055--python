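"""Ground-truth synthetic EEG groups with planted networks and dose arithmetic.

The generator emulates a sham-controlled stimulation study: each subject
contributes one *active* and one *sham* session of 64-channel eyes-closed
EEG covering a 2-min baseline, an 8-min stimulation block (split into two
4-min halves) and a 3-min recovery.  Every planted network is a fixed scalp
topography driven by band-limited Gaussian noise; in the active condition
only, a network's per-band source variance is multiplied by its effect
scaling inside the specified protocol segments.  Spatially white 1/f sensor
noise is added on top.

Also provides the optical dose arithmetic of the stimulation protocol
(irradiance, energy, fluence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import signal

from .core import (
    CONDITIONS,
    DEFAULT_PROTOCOL,
    N_CHANNELS,
    SUPPORTED_RATES,
    EEGRecording,
    Montage,
    ProtocolSpec,
    make_montage,
)
from .spectral import DEFAULT_BANDS

__all__ = [
    "NetworkSpec",
    "default_networks",
    "simulate_group",
    "iter_group",
    "inject_artifacts",
    "irradiance",
    "fluence",
]


@dataclass(frozen=True)
class NetworkSpec:
    """One planted spatiotemporal network.

    ``topography`` is the 64-channel relative-potential pattern (unit
    Euclidean norm); ``band_profile`` gives the fraction of source variance
    in each frequency band; ``power`` scales the network's total source
    variance; ``effects`` maps band -> segment -> multiplicative power
    scaling applied in the active condition only.
    """

    topography: np.ndarray
    band_profile: Mapping[str, float]
    power: float = 1.0
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        topo = np.asarray(self.topography, dtype=float)
        if topo.shape != (N_CHANNELS,):
            raise ValueError(f"topography must have {N_CHANNELS} entries")
        nrm = np.linalg.norm(topo)
        if not np.isfinite(nrm) or nrm == 0:
            raise ValueError("topography must be finite and nonzero")
        object.__setattr__(self, "topography", topo / nrm)
        if any(v < 0 for v in self.band_profile.values()):
            raise ValueError("band fractions must be nonnegative")
        if self.power <= 0:
            raise ValueError("network power must be > 0")
        for band, segs in self.effects.items():
            if any(s <= 0 for s in segs.values()):
                raise ValueError("effect scalings must be > 0")


# Dominant-band rotation used for the default networks. Posterior resting
# networks are alpha-heavy, so alpha leads the cycle.
_DOMINANT_CYCLE = ("alpha", "theta", "beta", "delta", "gamma")
# Broadband floor shared by every network (1/f-flavored: low bands heavier).
_FLOOR = {"delta": 0.40, "theta": 0.25, "alpha": 0.15, "beta": 0.12, "gamma": 0.08}


def _smooth_patterns(montage: Montage, n: int, rng: np.random.Generator) -> np.ndarray:
    """Random smooth scalp patterns, then orthonormalized (64 x n)."""
    pos = montage.positions
    pats = np.empty((N_CHANNELS, n))
    for k in range(n):
        centers = rng.standard_normal((3, 3))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        amps = rng.standard_normal(3)
        d2 = ((pos[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        pats[:, k] = (amps * np.exp(-d2 / (2 * 0.6**2))).sum(-1)
    # QR orthonormalization keeps early patterns smooth and makes the set
    # exactly recoverable by an SVD of the mixed signal.
    q, _ = np.linalg.qr(pats)
    return q


def _balance_rows(W: np.ndarray, powers: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """Orthonormal columns with uniform power-weighted row norms.

    Alternates row rescaling toward equal planted channel power
    ``sum_k p_k W[ch, k]^2`` with column re-orthonormalization.  Uniform
    planted power across channels keeps per-channel z-standardization from
    systematically rotating the group SVD basis away from the planted
    topographies, so the generator's networks are identifiable.
    """
    W = W.copy()
    for _ in range(n_iter):
        r = (W**2 * powers).sum(axis=1)
        W *= np.sqrt(r.mean() / np.maximum(r, 1e-12))[:, None]
        W, _ = np.linalg.qr(W)
    return W


def default_networks(
    n_networks: int = 11,
    montage: Montage | None = None,
    *,
    power_decay: float = 0.8,
    dominant_fraction: float = 0.6,
    alpha_effect: float = 1.5,
    gamma_effect: float = 0.7,
    topography_seed: int = 20220510,
) -> list[NetworkSpec]:
    """Construct the default planted-network set.

    Eleven networks by default, mutually orthonormal smooth topographies,
    total source power decaying geometrically with rank (ratio
    ``power_decay``), each dominated by one band (fraction
    ``dominant_fraction``) on top of a shared 1/f-flavored floor.  Two
    stimulation effects are planted in the active condition during both
    stimulation segments: an alpha power increase (x ``alpha_effect``) on
    the first alpha-dominant network and a gamma power decrease
    (x ``gamma_effect``) on the first gamma-dominant network.
    """
    if n_networks < 1:
        raise ValueError("need at least one network")
    montage = montage or make_montage()
    rng = np.random.default_rng(topography_seed)
    powers = power_decay ** np.arange(n_networks)
    topos = _balance_rows(_smooth_patterns(montage, n_networks, rng), powers)
    floor_total = sum(_FLOOR.values())
    stim_segments = ("stim1", "stim2")
    alpha_done = gamma_done = False
    nets: list[NetworkSpec] = []
    for k in range(n_networks):
        dom = _DOMINANT_CYCLE[k % len(_DOMINANT_CYCLE)]
        profile = {
            b: (1 - dominant_fraction) * f / floor_total for b, f in _FLOOR.items()
        }
        profile[dom] += dominant_fraction
        effects: dict[str, dict[str, float]] = {}
        if dom == "alpha" and not alpha_done and alpha_effect != 1.0:
            effects["alpha"] = {s: alpha_effect for s in stim_segments}
            alpha_done = True
        if dom == "gamma" and not gamma_done and gamma_effect != 1.0:
            effects["gamma"] = {s: gamma_effect for s in stim_segments}
            gamma_done = True
        nets.append(
            NetworkSpec(
                topography=topos[:, k],
                band_profile=profile,
                power=power_decay**k,
                effects=effects,
            )
        )
    return nets


def _band_sos(band: tuple[float, float], rate: float):
    lo, hi = band
    hi = min(hi, 0.999 * rate / 2)
    return signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")


def _simulate_recording(
    networks: Sequence[NetworkSpec],
    protocol: ProtocolSpec,
    rate: float,
    noise_level: float,
    montage: Montage,
    subject_id: str,
    condition: str,
    rng: np.random.Generator,
    gains: np.ndarray,
) -> EEGRecording:
    n = protocol.n_samples(rate)
    seg_slices = protocol.segment_slices(rate)
    bands = DEFAULT_BANDS.intervals
    n_nets = len(networks)

    # Per-band, per-network band-limited unit-variance sources.
    sources = np.zeros((n_nets, n))
    for bname, band in bands.items():
        white = rng.standard_normal((n_nets, n))
        x = signal.sosfilt(_band_sos(band, rate), white, axis=-1)
        x /= x.std(axis=-1, keepdims=True)
        for k, net in enumerate(networks):
            frac = net.band_profile.get(bname, 0.0)
            if frac <= 0:
                continue
            amp = np.sqrt(net.power * frac)
            xb = x[k]
            segs = net.effects.get(bname)
            if segs and condition == "active":
                xb = xb.copy()
                for seg, scale in segs.items():
                    xb[seg_slices[seg]] *= np.sqrt(scale)
            sources[k] += amp * xb

    mixing = np.stack([net.topography for net in networks], axis=1) * gains
    data = mixing @ sources

    # Spatially white sensor noise with a 1/f power spectrum (flat below 1 Hz).
    sig_rms = np.sqrt(np.mean(data**2))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    noise = np.fft.irfft(np.fft.rfft(rng.standard_normal((N_CHANNELS, n)), axis=-1) * shape, n=n, axis=-1)
    noise *= (noise_level * sig_rms) / noise.std()
    data += noise

    return EEGRecording(
        data=data,
        rate=rate,
        montage=montage,
        subject_id=subject_id,
        condition=condition,
        segment_markers=protocol.segment_markers(rate),
    )


def iter_group(
    n_subjects: int,
    networks: Sequence[NetworkSpec],
    protocol: ProtocolSpec = DEFAULT_PROTOCOL,
    rate: float = 256,
    noise_level: float = 0.3,
    seed: int = 0,
    montage: Montage | None = None,
) -> Iterator[tuple[EEGRecording, EEGRecording]]:
    """Yield (active, sham) recording pairs one subject at a time.

    Memory-friendly counterpart of :func:`simulate_group`; identical
    arguments and seed produce identical recordings in either.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not networks:
        raise ValueError("need at least one network")
    if rate not in SUPPORTED_RATES:
        raise ValueError(f"rate must be one of {SUPPORTED_RATES}")
    if noise_level <= 0:
        raise ValueError("noise level must be > 0")
    montage = montage or make_montage()
    width = len(str(n_subjects))
    for m in range(n_subjects):
        sid = f"S{m + 1:0{width}d}"
        # Subject anatomy: log-normal channel-by-network gains shared by
        # both conditions of the same subject.
        rng_subj = np.random.default_rng([int(seed), m, 999])
        gains = np.exp(0.2 * rng_subj.standard_normal((N_CHANNELS, len(networks))))
        pair = []
        for ci, cond in enumerate(CONDITIONS):
            rng = np.random.default_rng([int(seed), m, ci])
            pair.append(
                _simulate_recording(
                    networks, protocol, rate, noise_level, montage, sid, cond, rng, gains
                )
            )
        yield tuple(pair)


def simulate_group(
    n_subjects: int,
    networks: Sequence[NetworkSpec],
    protocol: ProtocolSpec = DEFAULT_PROTOCOL,
    rate: float = 256,
    noise_level: float = 0.3,
    seed: int = 0,
    montage: Montage | None = None,
) -> list[tuple[EEGRecording, EEGRecording]]:
    """Simulate a full group; returns a list of (active, sham) pairs."""
    return list(
        iter_group(n_subjects, networks, protocol, rate, noise_level, seed, montage)
    )


def inject_artifacts(
    rec: EEGRecording,
    spike_rate: float,
    amplitude: float = 20.0,
    seed: int = 0,
) -> EEGRecording:
    """Add sparse high-amplitude transients (motion/jaw-clench surrogates).

    ``spike_rate`` is events per minute; ``amplitude`` is the transient peak
    in multiples of each affected channel's standard deviation.  Each event
    hits a random channel subset with a half-sine bump of 0.1-0.3 s.  With
    ``spike_rate == 0`` the recording is returned unchanged.
    """
    if spike_rate < 0:
        raise ValueError("spike rate must be >= 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if spike_rate == 0:
        return rec
    rng = np.random.default_rng(seed)
    duration_min = rec.n_samples / rec.rate / 60.0
    n_events = rng.poisson(spike_rate * duration_min)
    data = rec.data.copy()
    ch_sd = data.std(axis=1)
    for _ in range(n_events):
        width = int(rng.uniform(0.1, 0.3) * rec.rate)
        t0 = rng.integers(0, max(1, rec.n_samples - width))
        chans = np.flatnonzero(rng.random(N_CHANNELS) < 0.25)
        if chans.size == 0:
            chans = rng.integers(0, N_CHANNELS, size=1)
        bump = np.sin(np.linspace(0, np.pi, width))
        sign = rng.choice([-1.0, 1.0], size=chans.size)
        data[np.ix_(chans, range(t0, t0 + width))] += (
            sign[:, None] * amplitude * ch_sd[chans, None] * bump[None, :]
        )
    return rec.copy_with(data=data)


def irradiance(power: float, area: float) -> float:
    """Irradiance in mW/cm^2 from laser power (W) and aperture area (cm^2).

    Reported to one decimal, the precision of a bench power meter.
    """
    if area <= 0:
        raise ValueError("aperture area must be > 0")
    return round(1000.0 * power / area, 1)


def fluence(power: float, duration: float, area: float) -> tuple[float, float]:
    """Delivered energy (J) and fluence (J/cm^2) of one stimulation session."""
    if area <= 0:
        raise ValueError("aperture area must be > 0")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    energy = power * duration
    return round(energy, 1), round(energy / area, 1)
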