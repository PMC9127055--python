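"""Group singular value decomposition of concatenated multi-subject EEG.

Every subject's cleaned 64-channel series is z-standardized per channel
(so no subject's amplitude dominates), both conditions of every subject
are stacked into one tall samples x channels matrix B, and an economy SVD
``B = U S V^T`` is taken.  Columns of V are the group's spatial
topographies (relative electrical potential, rEP), the matching columns
of U are their time courses, and the singular values rank the components
by root-mean-square contribution.  Components decaying less than 90% from
the top singular value are kept; their per-subject time courses are the
U-column rows of that subject's block.

For very tall group matrices the decomposition is done from the 64 x 64
Gram matrix ``B^T B`` (one pass of blockwise accumulation), which avoids
materializing U; time courses are then reconstructed per block as
``B_block V / S``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .core import CONDITIONS, N_CHANNELS, EEGRecording

__all__ = [
    "zstandardize",
    "GroupMatrix",
    "concatenate_group",
    "SVDResult",
    "group_svd",
    "select_components",
    "weight_fraction",
    "component_timecourses",
    "pairwise_pcc",
    "match_topographies",
    "reproducibility_check",
]

# above this many matrix entries, group_svd switches to the Gram route
_EXACT_SIZE_LIMIT = 2 * 10**8
_BLOCK_ROWS = 1_000_000


def zstandardize(rec: EEGRecording) -> EEGRecording:
    """Standardize each channel to temporal mean 0 and SD 1.

    Uses the population (divide-by-n) standard deviation.  Flat channels
    cannot be standardized and raise ``ValueError``.
    """
    data = np.asarray(rec.data, dtype=float)
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        flat = [rec.montage.labels[i] for i in np.flatnonzero(sd[:, 0] == 0)]
        raise ValueError(f"flat (zero-SD) channels cannot be standardized: {flat}")
    return rec.copy_with(data=(data - mu) / sd)


def _sort_key(key: tuple[str, str]) -> tuple[str, int]:
    return (key[0], CONDITIONS.index(key[1]))


@dataclass
class GroupMatrix:
    """Concatenated samples x channels matrix with its block index.

    ``index_map`` maps (subject_id, condition) to the half-open row range
    occupied by that session; the ranges partition the rows exactly.
    """

    B: np.ndarray
    index_map: dict[tuple[str, str], tuple[int, int]]
    rate: float | None = None

    @classmethod
    def allocate(
        cls,
        block_lengths: Mapping[tuple[str, str], int],
        dtype=np.float64,
        rate: float | None = None,
    ) -> "GroupMatrix":
        """Preallocate for streaming assembly (blocks filled via set_block)."""
        keys = sorted(block_lengths, key=_sort_key)
        index_map = {}
        start = 0
        for k in keys:
            index_map[k] = (start, start + block_lengths[k])
            start += block_lengths[k]
        return cls(B=np.empty((start, N_CHANNELS), dtype=dtype), index_map=index_map, rate=rate)

    def set_block(self, key: tuple[str, str], data: np.ndarray) -> None:
        """Insert one session (channels x samples; stored transposed)."""
        start, end = self.index_map[key]
        if data.shape != (N_CHANNELS, end - start):
            raise ValueError(f"block {key} has shape {data.shape}, expected ({N_CHANNELS}, {end - start})")
        self.B[start:end] = data.T

    def block(self, key: tuple[str, str]) -> np.ndarray:
        start, end = self.index_map[key]
        return self.B[start:end]

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.index_map})


def concatenate_group(recs: Sequence[EEGRecording], dtype=np.float64) -> GroupMatrix:
    """Stack z-standardized sessions into one group matrix.

    Blocks are ordered by subject ID, active before sham, so the stacking
    is deterministic; ``index_map`` inverts it exactly.  All recordings
    must share the sampling rate, and no (subject, condition) may repeat.
    """
    if not recs:
        raise ValueError("no recordings to concatenate")
    rates = {r.rate for r in recs}
    if len(rates) != 1:
        raise ValueError(f"mixed sampling rates {sorted(rates)}; downsample first")
    keys = [r.key for r in recs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (subject, condition) recordings")
    lengths = {r.key: r.n_samples for r in recs}
    G = GroupMatrix.allocate(lengths, dtype=dtype, rate=recs[0].rate)
    for r in recs:
        G.set_block(r.key, r.data)
    return G


@dataclass
class SVDResult:
    """Economy SVD of the group matrix.

    ``U`` is samples x 64 (may be None when the decomposition was computed
    from the Gram matrix; time courses are then reconstructed on demand),
    ``S`` the 64 singular values in descending order, ``V`` the 64 x 64
    spatial topographies (one rEP map per column).
    """

    S: np.ndarray
    V: np.ndarray
    U: np.ndarray | None = None

    @property
    def topographies(self) -> np.ndarray:
        return self.V


def _fix_signs(V: np.ndarray, U: np.ndarray | None) -> None:
    """Make each topography's largest-magnitude entry positive (in place)."""
    idx = np.abs(V).argmax(axis=0)
    flip = V[idx, np.arange(V.shape[1])] < 0
    V[:, flip] *= -1.0
    if U is not None:
        U[:, flip] *= -1.0


def group_svd(G: GroupMatrix, method: str = "auto") -> SVDResult:
    """Economy-size SVD of the group matrix.

    ``method='exact'`` runs LAPACK on B directly (U materialized);
    ``'gram'`` accumulates the 64 x 64 Gram matrix blockwise and
    eigendecomposes it, leaving U implicit.  ``'auto'`` picks by size.
    Component signs follow the largest-entry-positive convention; ties in
    S keep the original column order.
    """
    B = G.B
    if B.shape[0] <= B.shape[1]:
        raise ValueError("group matrix must have more rows than columns")
    if method == "auto":
        method = "exact" if B.size <= _EXACT_SIZE_LIMIT else "gram"
    if method == "exact":
        if not np.all(np.isfinite(B)):
            raise ValueError("group matrix contains non-finite entries")
        U, S, Vt = scipy.linalg.svd(np.asarray(B, dtype=np.float64), full_matrices=False)
        V = Vt.T
        _fix_signs(V, U)
        return SVDResult(S=S, V=V, U=U)
    if method == "gram":
        C = np.zeros((N_CHANNELS, N_CHANNELS))
        for start in range(0, B.shape[0], _BLOCK_ROWS):
            blk = np.asarray(B[start : start + _BLOCK_ROWS], dtype=np.float64)
            if not np.all(np.isfinite(blk)):
                raise ValueError("group matrix contains non-finite entries")
            C += blk.T @ blk
        w, vecs = np.linalg.eigh(C)
        S = np.sqrt(np.clip(w[::-1], 0.0, None))
        V = vecs[:, ::-1].copy()
        _fix_signs(V, None)
        return SVDResult(S=S, V=V, U=None)
    raise ValueError(f"unknown method {method!r}")


def select_components(S: np.ndarray, decay_threshold: float = 0.9) -> list[int]:
    """Indices of components decaying less than ``decay_threshold`` from the top.

    Keeps every component with ``S[k] > (1 - decay_threshold) * S[0]``
    (strict: a weight exactly at the cutoff is excluded).
    """
    S = np.asarray(S, dtype=float)
    if S.size == 0:
        raise ValueError("empty singular value array")
    if S[0] <= 0:
        raise ValueError("leading singular value must be positive")
    cutoff = (1.0 - decay_threshold) * S[0]
    # strict inequality up to float round-off of the cutoff product
    return [int(k) for k in np.flatnonzero(S > cutoff * (1.0 + 1e-12))]


def weight_fraction(S: np.ndarray, selected: Sequence[int]) -> float:
    """Share of total singular-value weight carried by the selection."""
    S = np.asarray(S, dtype=float)
    if len(selected) == 0:
        raise ValueError("selection is empty")
    return float(S[list(selected)].sum() / S.sum())


def component_timecourses(
    R: SVDResult,
    G: GroupMatrix,
    selected: Sequence[int],
) -> dict[tuple[str, str], np.ndarray]:
    """Per-session time courses of the selected components.

    For each (subject, condition) block, returns the rows of the selected
    U columns inside that block (samples x K).  When U was not
    materialized, the identity ``U = B V / S`` is applied per block.
    """
    sel = list(selected)
    out: dict[tuple[str, str], np.ndarray] = {}
    for key in G.index_map:
        start, end = G.index_map[key]
        if R.U is not None:
            out[key] = R.U[start:end][:, sel].copy()
        else:
            blk = np.asarray(G.B[start:end], dtype=np.float64)
            out[key] = (blk @ R.V[:, sel]) / R.S[sel]
    return out


@dataclass
class CorrelationMatrix:
    """Group-averaged pairwise Pearson correlations between component
    time courses; the diagonal (self-correlation) is not applicable and
    stored as NaN."""

    values: np.ndarray
    components: tuple = ()

    @property
    def max_abs_offdiag(self) -> float:
        off = self.values[~np.eye(self.values.shape[0], dtype=bool)]
        return float(np.nanmax(np.abs(off)))


def pairwise_pcc(
    timecourses: Mapping[tuple[str, str], np.ndarray],
    components: Sequence | None = None,
) -> CorrelationMatrix:
    """Average per-session component-pair Pearson correlations.

    For every session the full-recording correlation matrix of its
    component time courses is computed, then averaged across sessions.
    A zero-variance time course raises ``ValueError``.
    """
    mats = []
    for key, tc in timecourses.items():
        tc = np.asarray(tc, dtype=float)
        if tc.ndim != 2 or tc.shape[1] < 2:
            raise ValueError("need at least 2 component time courses per session")
        if np.any(tc.std(axis=0) == 0):
            raise ValueError(f"zero-variance time course in session {key}")
        mats.append(np.corrcoef(tc.T))
    avg = np.mean(mats, axis=0)
    np.fill_diagonal(avg, np.nan)
    comps = tuple(components) if components is not None else tuple(range(avg.shape[0]))
    return CorrelationMatrix(values=avg, components=comps)


def match_topographies(reference: np.ndarray, candidate: np.ndarray) -> np.ndarray:
    """Sign-invariant one-to-one cosine matching of topography sets.

    Both arguments are 64 x K column sets.  Components are paired by
    maximizing total |cosine similarity| (one-to-one assignment); returns
    the matched |cosine| per reference column.
    """
    from scipy.optimize import linear_sum_assignment

    ref = reference / np.linalg.norm(reference, axis=0, keepdims=True)
    cand = candidate / np.linalg.norm(candidate, axis=0, keepdims=True)
    cos = np.abs(ref.T @ cand)
    rows, cols = linear_sum_assignment(-cos)
    out = np.zeros(ref.shape[1])
    out[rows] = cos[rows, cols]
    return out


def _baseline_slice(rec: EEGRecording) -> EEGRecording:
    if not rec.segment_markers:
        raise ValueError("recording has no segment markers")
    stop = rec.segment_markers[0]
    return rec.copy_with(data=rec.data[:, :stop], segment_markers=())


def reproducibility_check(
    recs: Sequence[EEGRecording],
    strategy: str = "random-half",
    seed: int = 0,
    decay_threshold: float = 0.9,
    n_components: int | None = None,
) -> np.ndarray:
    """Topography stability of the group decomposition under subsetting.

    Reruns standardize -> concatenate -> SVD on a subset of the data
    (``baseline-only``, ``active-only``, ``sham-only``, ``random-half`` of
    subjects, or ``full``) and reports each full-run topography's matched
    |cosine similarity| against the subset run (sign-invariant,
    one-to-one).  Values near 1 mean the spatial patterns do not depend on
    which sessions entered the decomposition.
    """
    subjects = sorted({r.subject_id for r in recs})
    if len(subjects) < 4:
        raise ValueError("need at least 4 subjects for a reproducibility check")

    def decompose(rs: Sequence[EEGRecording]) -> tuple[SVDResult, list[int]]:
        G = concatenate_group([zstandardize(r) for r in rs])
        if G.B.shape[0] <= N_CHANNELS:
            raise ValueError("subset too small for a 64-column SVD")
        R = group_svd(G)
        sel = (
            list(range(n_components))
            if n_components is not None
            else select_components(R.S, decay_threshold)
        )
        return R, sel

    R_full, sel_full = decompose(recs)

    if strategy == "full":
        subset = list(recs)
    elif strategy == "random-half":
        rng = np.random.default_rng(seed)
        half = sorted(rng.choice(subjects, size=len(subjects) // 2, replace=False))
        subset = [r for r in recs if r.subject_id in half]
    elif strategy in ("active-only", "sham-only"):
        cond = strategy.split("-")[0]
        subset = [r for r in recs if r.condition == cond]
    elif strategy == "baseline-only":
        subset = [_baseline_slice(r) for r in recs]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    R_sub, _ = decompose(subset)
    k = len(sel_full)
    return match_topographies(R_full.V[:, sel_full], R_sub.V[:, :k])
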