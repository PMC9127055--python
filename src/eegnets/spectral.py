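"""Segmenting component time courses, Welch PSD, and band-power indices.

Powers are quantified per frequency band i, component j, subject m, and
period t.  ``nP = P / P(baseline)`` normalizes each power by the same
session's own pre-stimulation baseline, removing between-subject amplitude
variation; ``dnP = nP(active) - nP(sham)`` then removes any within-session
drift common to both conditions, leaving the stimulation-specific power
change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .core import ProtocolSpec

__all__ = [
    "BandScheme",
    "DEFAULT_BANDS",
    "segment",
    "welch_psd",
    "band_power",
    "normalize_power",
    "sham_subtract",
    "PowerTable",
    "compute_power_table",
    "screen_outlier_subjects",
]

PERIODS = ("stim1", "stim2", "recovery")


@dataclass(frozen=True)
class BandScheme:
    """Named contiguous frequency bands covering [1, 70] Hz.

    Intervals are half-open ``[lo, hi)`` except the last band, which is
    closed on the right so the scheme covers 70 Hz without double-counting
    the shared integer edges.
    """

    intervals: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        items = list(self.intervals.items())
        if not items:
            raise ValueError("band scheme cannot be empty")
        for (_, (lo1, hi1)), (_, (lo2, _)) in zip(items, items[1:]):
            if hi1 != lo2:
                raise ValueError("bands must be contiguous and non-overlapping")
            if lo1 >= hi1:
                raise ValueError("band edges must be increasing")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.intervals)

    @property
    def span(self) -> tuple[float, float]:
        vals = list(self.intervals.values())
        return vals[0][0], vals[-1][1]

    def mask(self, freqs: np.ndarray, band: str) -> np.ndarray:
        lo, hi = self.intervals[band]
        if band == self.names[-1]:
            return (freqs >= lo) & (freqs <= hi)
        return (freqs >= lo) & (freqs < hi)


DEFAULT_BANDS = BandScheme(
    intervals={
        "delta": (1.0, 4.0),
        "theta": (4.0, 8.0),
        "alpha": (8.0, 13.0),
        "beta": (13.0, 30.0),
        "gamma": (30.0, 70.0),
    }
)


def segment(
    timecourse: np.ndarray, protocol: ProtocolSpec, rate: float
) -> dict[str, np.ndarray]:
    """Split a component time course into the four protocol segments.

    Returns baseline / stim1 / stim2 / recovery slices (views).  The time
    course must cover the full protocol exactly.
    """
    x = np.asarray(timecourse)
    n_expected = protocol.n_samples(rate)
    if x.shape[0] != n_expected:
        raise ValueError(
            f"time course has {x.shape[0]} samples, protocol needs {n_expected}"
        )
    return {name: x[sl] for name, sl in protocol.segment_slices(rate).items()}


def welch_psd(
    x: np.ndarray, rate: float, window_s: float = 4.0, overlap: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged-periodogram (Welch) density with Hann windows.

    4-s windows give 0.25 Hz resolution, adequate for 1-Hz band edges.
    Returns (frequencies, density); the density integrates to the signal
    variance (one-sided).
    """
    x = np.asarray(x)
    nperseg = int(round(window_s * rate))
    if x.shape[-1] < nperseg:
        raise ValueError("segment shorter than one Welch window")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    freqs, psd = signal.welch(
        x,
        fs=rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return freqs, psd


def band_power(
    freqs: np.ndarray,
    density: np.ndarray,
    band: str,
    scheme: BandScheme = DEFAULT_BANDS,
) -> float | np.ndarray:
    """Mean PSD over the band's bins times the band width in Hz."""
    m = scheme.mask(np.asarray(freqs), band)
    if not m.any():
        raise ValueError(f"no frequency bins fall inside band {band!r}")
    lo, hi = scheme.intervals[band]
    return np.asarray(density)[..., m].mean(axis=-1) * (hi - lo)


def normalize_power(P, baselineP):
    """Baseline-normalized power nP = P / P(baseline of the same session)."""
    baselineP = np.asarray(baselineP, dtype=float)
    if np.any(baselineP <= 0):
        raise ValueError("baseline power must be > 0")
    return np.asarray(P, dtype=float) / baselineP


def sham_subtract(nP_active, nP_sham):
    """Sham-subtracted index dnP = nP(active) - nP(sham), elementwise."""
    a = np.asarray(nP_active, dtype=float)
    s = np.asarray(nP_sham, dtype=float)
    if a.shape != s.shape:
        raise ValueError("active and sham nP shapes do not match")
    return a - s


@dataclass
class PowerTable:
    """Long-format band powers with their normalized and sham-subtracted forms.

    ``table`` columns: band, component, subject, period, condition, P, nP
    (periods include 'baseline', where nP == 1 by construction).
    ``dnp`` columns: band, component, subject, period, dnP for the three
    post-onset periods.
    """

    table: pd.DataFrame
    dnp: pd.DataFrame
    bands: BandScheme = field(default=DEFAULT_BANDS)

    @property
    def components(self) -> list:
        return sorted(self.table["component"].unique())

    @property
    def subjects(self) -> list:
        return sorted(self.table["subject"].unique())

    def dnp_values(self, band: str, component, period: str) -> np.ndarray:
        """Per-subject dnP vector for one (band, component, period) cell."""
        sel = self.dnp[
            (self.dnp["band"] == band)
            & (self.dnp["component"] == component)
            & (self.dnp["period"] == period)
        ].sort_values("subject")
        return sel["dnP"].to_numpy()


def compute_power_table(
    timecourses: Mapping[tuple[str, str], np.ndarray],
    protocol: ProtocolSpec,
    rate: float,
    components: Sequence | None = None,
    scheme: BandScheme = DEFAULT_BANDS,
    window_s: float = 4.0,
    overlap: float = 0.5,
) -> PowerTable:
    """Band powers P, nP and dnP for every component of every subject.

    ``timecourses`` maps (subject, condition) to a samples x components
    array (one column per selected component), e.g. the output of
    :func:`eegnets.gsvd.component_timecourses`.
    """
    rows = []
    for (subject, condition), tc in timecourses.items():
        tc = np.atleast_2d(np.asarray(tc).T).T  # ensure (samples, K)
        if components is None:
            comp_labels = list(range(tc.shape[1]))
        else:
            comp_labels = list(components)
        segs = {
            name: tc[sl, :] for name, sl in protocol.segment_slices(rate).items()
        }
        psd = {}
        for name, block in segs.items():
            freqs, dens = welch_psd(block.T, rate, window_s, overlap)
            psd[name] = dens  # (K, n_freqs)
        for j, comp in enumerate(comp_labels):
            for bname in scheme.names:
                base = band_power(freqs, psd["baseline"][j], bname, scheme)
                for per in ("baseline",) + PERIODS:
                    P = band_power(freqs, psd[per][j], bname, scheme)
                    rows.append(
                        {
                            "band": bname,
                            "component": comp,
                            "subject": subject,
                            "period": per,
                            "condition": condition,
                            "P": float(P),
                            "nP": float(normalize_power(P, base)),
                        }
                    )
    table = pd.DataFrame(rows)
    wide = table[table["period"] != "baseline"].pivot_table(
        index=["band", "component", "subject", "period"],
        columns="condition",
        values="nP",
    )
    if not {"active", "sham"} <= set(wide.columns):
        raise ValueError("need both active and sham sessions to form dnP")
    dnp = wide.reset_index()
    dnp["dnP"] = sham_subtract(dnp["active"].to_numpy(), dnp["sham"].to_numpy())
    dnp = dnp[["band", "component", "subject", "period", "dnP"]]
    dnp.columns.name = None
    return PowerTable(table=table, dnp=dnp, bands=scheme)


def screen_outlier_subjects(pt: PowerTable, z_limit: float = 4.0) -> tuple[PowerTable, list[str]]:
    """Optionally drop subjects with extreme component powers.

    A subject is excluded when, for any component, their total power
    (summed over bands, periods and conditions) deviates from the group
    mean by more than ``z_limit`` standard deviations.
    """
    totals = (
        pt.table.groupby(["component", "subject"])["P"].sum().reset_index()
    )
    bad: set[str] = set()
    for comp, grp in totals.groupby("component"):
        mu, sd = grp["P"].mean(), grp["P"].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            continue
        z = (grp["P"] - mu).abs() / sd
        bad |= set(grp.loc[z > z_limit, "subject"])
    if not bad:
        return pt, []
    keep_t = pt.table[~pt.table["subject"].isin(bad)].reset_index(drop=True)
    keep_d = pt.dnp[~pt.dnp["subject"].isin(bad)].reset_index(drop=True)
    return PowerTable(table=keep_t, dnp=keep_d, bands=pt.bands), sorted(bad)
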