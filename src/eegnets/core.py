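"""Shared domain containers: montage, recordings, stimulation protocol.

The package works with eyes-closed resting EEG recorded on a 64-electrode
10-10 cap before, during, and after an 8-minute active or sham stimulation
block.  A recording is a plain ``channels x samples`` array annotated with
its sampling rate, its montage, and the sample indices of the protocol
segment boundaries (baseline / first stimulation half / second half /
recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

N_CHANNELS = 64
SUPPORTED_RATES = (256, 512)
CONDITIONS = ("active", "sham")
SEGMENT_NAMES = ("baseline", "stim1", "stim2", "recovery")


@dataclass(frozen=True)
class Montage:
    """64 electrode labels with head-centered 3D positions.

    Positions are normalized so the scalp is the unit sphere, which is the
    convention the spherical forward model in :mod:`eegnets.eloreta` expects.
    """

    labels: tuple[str, ...]
    positions: np.ndarray  # (64, 3), unit-sphere radius

    def __post_init__(self) -> None:
        if len(self.labels) != N_CHANNELS:
            raise ValueError(f"montage needs {N_CHANNELS} labels, got {len(self.labels)}")
        if len(set(self.labels)) != N_CHANNELS:
            raise ValueError("montage labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (N_CHANNELS, 3):
            raise ValueError(f"positions must be ({N_CHANNELS}, 3), got {pos.shape}")
        r = np.linalg.norm(pos, axis=1)
        if np.any(r > 1.0 + 1e-9):
            raise ValueError("montage positions must lie on or inside the unit sphere")
        object.__setattr__(self, "positions", pos)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Montage):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.positions, other.positions)


_MONTAGE_CACHE: dict[int, Montage] = {}


def make_montage(n_channels: int = N_CHANNELS) -> Montage:
    """Return the standard Biosemi 64-channel 10-10 montage on the unit sphere.

    Deterministic: every call returns an identical montage.  Only 64 channels
    are supported; any other count raises ``ValueError``.
    """
    if n_channels != N_CHANNELS:
        raise ValueError(f"only {N_CHANNELS}-channel montages are supported, got {n_channels}")
    if n_channels not in _MONTAGE_CACHE:
        import mne

        std = mne.channels.make_standard_montage("biosemi64")
        ch_pos = std.get_positions()["ch_pos"]
        labels = tuple(std.ch_names)
        pos = np.array([ch_pos[ch] for ch in labels], dtype=float)
        # project onto the unit sphere (biosemi64 template is a 9.5 cm sphere)
        pos /= np.linalg.norm(pos, axis=1, keepdims=True)
        _MONTAGE_CACHE[n_channels] = Montage(labels=labels, positions=pos)
    return _MONTAGE_CACHE[n_channels]


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing and optical dose parameters of one stimulation session.

    ``boundaries_min`` are the protocol boundaries in minutes relative to
    stimulation onset: baseline start, stimulation onset, stimulation
    midpoint, stimulation end, end of recording.  The default is the
    2-min baseline / 8-min stimulation (split 4+4) / 3-min recovery session.
    """

    boundaries_min: tuple[float, float, float, float, float] = (-2.0, 0.0, 4.0, 8.0, 11.0)
    power_w: float = 3.5
    aperture_cm2: float = 13.6
    stim_duration_s: float = 480.0

    def __post_init__(self) -> None:
        b = self.boundaries_min
        if len(b) != 5 or any(b[i] >= b[i + 1] for i in range(4)):
            raise ValueError("protocol boundaries must be 5 strictly increasing minutes")
        if self.power_w < 0:
            raise ValueError("laser power must be >= 0")
        if self.aperture_cm2 <= 0:
            raise ValueError("aperture area must be > 0")

    @property
    def duration_min(self) -> float:
        return self.boundaries_min[-1] - self.boundaries_min[0]

    def n_samples(self, rate: float) -> int:
        return int(round(self.duration_min * 60.0 * rate))

    def segment_markers(self, rate: float) -> tuple[int, int, int]:
        """Sample indices of the three interior boundaries."""
        t0 = self.boundaries_min[0]
        return tuple(
            int(round((b - t0) * 60.0 * rate)) for b in self.boundaries_min[1:4]
        )

    def segment_slices(self, rate: float) -> dict[str, slice]:
        t0 = self.boundaries_min[0]
        edges = [int(round((b - t0) * 60.0 * rate)) for b in self.boundaries_min]
        return {
            name: slice(edges[i], edges[i + 1])
            for i, name in enumerate(SEGMENT_NAMES)
        }

    def scaled(self, factor: float) -> "ProtocolSpec":
        """Uniformly shrink/stretch all boundaries (same 4-segment structure)."""
        return replace(self, boundaries_min=tuple(b * factor for b in self.boundaries_min),
                       stim_duration_s=self.stim_duration_s * factor)


DEFAULT_PROTOCOL = ProtocolSpec()


@dataclass
class EEGRecording:
    """One subject/condition multichannel EEG time series.

    ``data`` is channels x samples; microvolts for real data, unitless for
    synthetic or standardized data.  ``segment_markers`` are the sample
    indices of the three interior protocol boundaries (stim onset, stim
    midpoint, stim end).
    """

    data: np.ndarray
    rate: float
    montage: Montage
    subject_id: str
    condition: str
    segment_markers: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] != N_CHANNELS:
            raise ValueError(f"data must be ({N_CHANNELS}, n_samples), got {self.data.shape}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        m = tuple(int(x) for x in self.segment_markers)
        if any(m[i] >= m[i + 1] for i in range(len(m) - 1)):
            raise ValueError("segment markers must be strictly increasing")
        if m and (m[0] < 0 or m[-1] > self.n_samples):
            raise ValueError("segment markers must lie within the recording")
        self.segment_markers = m

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.condition)

    def copy_with(self, **kw) -> "EEGRecording":
        out = EEGRecording(
            data=kw.get("data", self.data),
            rate=kw.get("rate", self.rate),
            montage=self.montage,
            subject_id=self.subject_id,
            condition=self.condition,
            segment_markers=kw.get("segment_markers", self.segment_markers),
        )
        return out


def stage_seed(seed: int, stage: str) -> list[int]:
    """Fan a global seed out to an independent per-stage seed sequence.

    Uses a CRC32 hash of the stage name so stages can be rerun in isolation
    with reproducible streams.  Suitable for ``np.random.default_rng``.
    """
    import zlib

    return [int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode()) & 0x7FFFFFFF]
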