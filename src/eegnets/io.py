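"""File formats: EDF and delimited recordings, montage tables, manifests.

Recordings are exchanged either as EDF (16-bit, the common clinical
interchange format; read back through mne) or as tab-delimited numeric
matrices (one row per channel, full float precision, lossless).  A group
manifest is a YAML file listing subject ID, condition, file path, format
and sampling rate for every session, plus the montage table and protocol.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import numpy as np
import yaml

from .core import N_CHANNELS, EEGRecording, Montage, ProtocolSpec, make_montage

__all__ = [
    "write_edf",
    "read_edf",
    "write_delimited",
    "read_delimited",
    "write_recording",
    "read_recording",
    "write_montage",
    "read_montage",
    "write_manifest",
    "read_manifest",
    "load_manifest_recordings",
]

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as a minimal EDF file (16-bit, 1-s data records).

    EDF stores integer-second records; trailing samples beyond the last
    whole second are zero-padded.  Amplitudes are quantized to the 16-bit
    grid spanned by each channel's data range (physical dimension uV).
    """
    path = Path(path)
    rate = int(round(rec.rate))
    n_rec = int(np.ceil(rec.n_samples / rate))
    data = np.zeros((N_CHANNELS, n_rec * rate))
    data[:, : rec.n_samples] = rec.data
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    scale = (pmax - pmin) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    digital = np.round((data - pmin[:, None]) / scale[:, None] + _EDF_DIG_MIN)
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    now = datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad(f"{rec.subject_id} {rec.condition}", 80),
            _pad("eegnets synthetic", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 + N_CHANNELS * 256), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),  # record duration, seconds
            _pad(str(N_CHANNELS), 4),
        ]
    )
    labels = rec.montage.labels
    sig = b"".join(_pad(lab, 16) for lab in labels)
    sig += b"".join(_pad("AgAgCl electrode", 80) for _ in labels)
    sig += b"".join(_pad("uV", 8) for _ in labels)
    sig += b"".join(_pad(f"{v:.6g}"[:8], 8) for v in pmin)
    sig += b"".join(_pad(f"{v:.6g}"[:8], 8) for v in pmax)
    sig += b"".join(_pad(str(_EDF_DIG_MIN), 8) for _ in labels)
    sig += b"".join(_pad(str(_EDF_DIG_MAX), 8) for _ in labels)
    sig += b"".join(_pad("", 80) for _ in labels)
    sig += b"".join(_pad(str(rate), 8) for _ in labels)
    sig += b"".join(_pad("", 32) for _ in labels)

    with open(path, "wb") as fh:
        fh.write(header + sig)
        # data records: per record, channel-major int16
        for r in range(n_rec):
            fh.write(digital[:, r * rate : (r + 1) * rate].tobytes())


def read_edf(
    path: str | Path,
    subject_id: str = "",
    condition: str = "active",
    montage: Montage | None = None,
    segment_markers: tuple[int, ...] = (),
    n_samples: int | None = None,
) -> EEGRecording:
    """Read an EDF recording (via mne); requires exactly 64 channels.

    ``n_samples`` trims zero-padding introduced by whole-second records.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne rescales uV to volts; undo
    if data.shape[0] != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} channels, file has {data.shape[0]}")
    if n_samples is not None:
        data = data[:, :n_samples]
    return EEGRecording(
        data=data,
        rate=float(raw.info["sfreq"]),
        montage=montage or make_montage(),
        subject_id=subject_id,
        condition=condition,
        segment_markers=segment_markers,
    )


def write_delimited(rec: EEGRecording, path: str | Path) -> None:
    """Tab-delimited matrix, one row per channel, full float precision."""
    np.savetxt(path, rec.data, fmt="%.17g", delimiter="\t")


def read_delimited(
    path: str | Path,
    rate: float,
    subject_id: str = "",
    condition: str = "active",
    montage: Montage | None = None,
    segment_markers: tuple[int, ...] = (),
) -> EEGRecording:
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    if data.shape[0] != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} channels, file has {data.shape[0]}")
    return EEGRecording(
        data=data,
        rate=rate,
        montage=montage or make_montage(),
        subject_id=subject_id,
        condition=condition,
        segment_markers=segment_markers,
    )


def write_recording(rec: EEGRecording, path: str | Path, fmt: str = "edf") -> None:
    if fmt == "edf":
        write_edf(rec, path)
    elif fmt == "delimited":
        write_delimited(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_recording(path: str | Path, fmt: str = "edf", **kw) -> EEGRecording:
    if fmt == "edf":
        return read_edf(path, **kw)
    if fmt == "delimited":
        return read_delimited(path, **kw)
    raise ValueError(f"unknown format {fmt!r}")


def write_montage(montage: Montage, path: str | Path) -> None:
    """Tab-separated electrode table: label, x, y, z."""
    with open(path, "w") as fh:
        fh.write("label\tx\ty\tz\n")
        for lab, (x, y, z) in zip(montage.labels, montage.positions):
            fh.write(f"{lab}\t{x:.17g}\t{y:.17g}\t{z:.17g}\n")


def read_montage(path: str | Path) -> Montage:
    labels, pos = [], []
    with open(path) as fh:
        next(fh)
        for line in fh:
            parts = line.split("\t")
            labels.append(parts[0])
            pos.append([float(v) for v in parts[1:4]])
    return Montage(labels=tuple(labels), positions=np.array(pos))


def write_manifest(
    entries: list[dict],
    path: str | Path,
    montage_path: str | None = None,
    protocol: ProtocolSpec | None = None,
) -> None:
    """Write a group manifest (YAML): one entry per session.

    Each entry needs keys subject, condition, path, format, rate; the
    manifest optionally records the montage table path and the protocol
    boundaries so a run is fully described by one file.
    """
    doc: dict = {"recordings": entries}
    if montage_path is not None:
        doc["montage"] = montage_path
    if protocol is not None:
        doc["protocol"] = {
            "boundaries_min": list(protocol.boundaries_min),
            "power_w": protocol.power_w,
            "aperture_cm2": protocol.aperture_cm2,
            "stim_duration_s": protocol.stim_duration_s,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_manifest(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "protocol" in doc:
        doc["protocol"] = ProtocolSpec(
            boundaries_min=tuple(doc["protocol"]["boundaries_min"]),
            power_w=doc["protocol"].get("power_w", 3.5),
            aperture_cm2=doc["protocol"].get("aperture_cm2", 13.6),
            stim_duration_s=doc["protocol"].get("stim_duration_s", 480.0),
        )
    return doc


def load_manifest_recordings(path: str | Path) -> tuple[list[EEGRecording], ProtocolSpec | None]:
    """Load every session listed in a manifest."""
    doc = read_manifest(path)
    base = Path(path).parent
    montage = read_montage(base / doc["montage"]) if "montage" in doc else make_montage()
    protocol = doc.get("protocol")
    recs = []
    for e in doc["recordings"]:
        p = Path(e["path"])
        if not p.is_absolute():
            p = base / p
        rate = float(e["rate"])
        markers = (
            tuple(protocol.segment_markers(rate)) if protocol is not None else ()
        )
        kw = dict(
            subject_id=str(e["subject"]),
            condition=e["condition"],
            montage=montage,
            segment_markers=markers,
        )
        if e.get("format", "edf") == "edf":
            n_samples = protocol.n_samples(rate) if protocol is not None else None
            recs.append(read_edf(p, n_samples=n_samples, **kw))
        else:
            recs.append(read_delimited(p, rate=rate, **kw))
    return recs, protocol
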