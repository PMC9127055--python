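"""Spherical-head forward model and the eLORETA inverse solution.

The forward model is the classical three-shell concentric-sphere head
(brain / skull / scalp) with the scalp as the unit sphere.  Potentials of
a current dipole are computed from the Legendre-series expansion, with the
radial transfer coefficient of each harmonic obtained from a small
per-degree linear system enforcing potential and radial-current continuity
across shells and zero current through the scalp.

eLORETA (exact low-resolution electromagnetic tomography) is a weighted
minimum-norm inverse whose voxel weights are chosen by a fixed-point
iteration so that the resulting resolution matrix has exact localization:
a noiseless scalp pattern generated by any single grid dipole produces a
current-density magnitude map whose maximum is at the generating voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Montage

__all__ = [
    "SourceGrid",
    "make_source_grid",
    "LeadField",
    "spherical_leadfield",
    "ELORETAConfig",
    "ELORETATransform",
    "eloreta_transform",
    "SourceMap",
    "localize",
    "threshold_map",
]

DEFAULT_RADII = (0.87, 0.92, 1.0)  # brain, skull, scalp (scalp = unit sphere)
DEFAULT_CONDUCTIVITIES = (1.0, 0.0125, 1.0)  # relative; skull ~80x less conductive


@dataclass(frozen=True)
class SourceGrid:
    """Regular lattice of candidate source locations inside the brain shell."""

    positions: np.ndarray  # (V, 3)
    spacing: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] == 0:
            raise ValueError("grid positions must be a nonempty (V, 3) array")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        object.__setattr__(self, "positions", pos)

    @property
    def n_voxels(self) -> int:
        return self.positions.shape[0]


def make_source_grid(
    spacing: float = 0.15, radius: float = DEFAULT_RADII[0], margin: float = 0.03
) -> SourceGrid:
    """Half-spacing-offset cubic lattice strictly inside the brain shell.

    Units are normalized head radii (scalp = 1).  The default 0.15 spacing
    (~13 mm on a 9 cm head) keeps the grid below a thousand voxels, which
    is plenty for the smooth current-density maps the inverse produces.
    The half-spacing offset avoids a voxel exactly at the head center,
    where the dipole expansion's radial direction is undefined.
    """
    rmax = radius - margin
    k = int(np.ceil(rmax / spacing)) + 1
    axis = (np.arange(-k, k) + 0.5) * spacing
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= rmax]
    return SourceGrid(positions=pts, spacing=spacing)


@dataclass
class LeadField:
    """Forward gain: scalp potential per unit dipole moment.

    ``gain`` has shape (channels, voxels, 3); every column is
    average-referenced (channel mean zero).
    """

    gain: np.ndarray
    montage: Montage
    grid: SourceGrid
    radii: tuple[float, float, float] = DEFAULT_RADII
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES

    @property
    def matrix(self) -> np.ndarray:
        """Gain flattened to (channels, voxels * 3)."""
        return self.gain.reshape(self.gain.shape[0], -1)


def _radial_transfer(n_max: int, radii, conductivities) -> np.ndarray:
    """Per-degree transfer from the primary harmonic potential at the
    innermost interface to the scalp-surface potential.

    For each Legendre degree n the potential in shell j is
    ``a_j (r/q_j)^n + b_j (r/p_j)^(-(n+1))`` with [p_j, q_j] the shell's
    radial extent; this scaling keeps every matrix entry at most 1 in
    magnitude so the solve stays well conditioned at high degree.
    """
    radii = tuple(float(r) for r in radii)
    cond = tuple(float(c) for c in conductivities)
    L = len(radii)
    if L != len(cond):
        raise ValueError("radii and conductivities must have equal length")
    if any(radii[i] >= radii[i + 1] for i in range(L - 1)):
        raise ValueError("shell radii must be strictly increasing")
    t = np.empty(n_max + 1)
    t[0] = 0.0
    n_unknown = 2 * L - 1  # a_1, then (a_j, b_j) for j >= 2
    for n in range(1, n_max + 1):
        A = np.zeros((n_unknown, n_unknown))
        rhs = np.zeros(n_unknown)

        def a_idx(j):  # 1-based layer
            return 0 if j == 1 else 2 * j - 3

        def b_idx(j):
            return 2 * j - 2

        row = 0
        for j in range(1, L):  # interface at radius radii[j-1]
            r = radii[j - 1]
            p_in = radii[j - 2] if j >= 2 else None
            # layer j evaluated at its outer radius r:
            #   a_j * (r/q_j)^n with q_j = r  -> coefficient 1
            #   b_j * (r/p_j)^-(n+1)  (j>=2)
            # layer j+1 evaluated at its inner radius r:
            #   a_{j+1} * (r/q_{j+1})^n, b_{j+1} * (r/p_{j+1})^-(n+1) with p=r -> 1
            ratio_out = (r / radii[j]) ** n
            b_j_coef = (r / p_in) ** (-(n + 1)) if j >= 2 else 0.0
            # potential continuity
            A[row, a_idx(j)] = 1.0
            if j >= 2:
                A[row, b_idx(j)] = b_j_coef
            A[row, a_idx(j + 1)] = -ratio_out
            A[row, b_idx(j + 1)] = -1.0
            if j == 1:
                rhs[row] = -1.0  # primary potential (r/r1)^-(n+1) at r1
            row += 1
            # radial current continuity (times r/sigma scalings kept explicit)
            A[row, a_idx(j)] = cond[j - 1] * n
            if j >= 2:
                A[row, b_idx(j)] = -cond[j - 1] * (n + 1) * b_j_coef
            A[row, a_idx(j + 1)] = -cond[j] * n * ratio_out
            A[row, b_idx(j + 1)] = cond[j] * (n + 1)
            if j == 1:
                rhs[row] = cond[0] * (n + 1)
            row += 1
        # no current through the scalp surface
        rL = radii[-1]
        A[row, a_idx(L)] = n
        A[row, b_idx(L)] = -(n + 1) * (rL / radii[-2]) ** (-(n + 1))
        sol = np.linalg.solve(A, rhs)
        t[n] = sol[a_idx(L)] + sol[b_idx(L)] * (rL / radii[-2]) ** (-(n + 1))
    return t


def spherical_leadfield(
    montage: Montage,
    grid: SourceGrid,
    radii: tuple[float, float, float] = DEFAULT_RADII,
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES,
    n_terms: int | None = None,
) -> LeadField:
    """Analytic concentric-shell dipole potentials at the montage electrodes.

    Electrodes are taken radially at the scalp radius.  The Legendre series
    is truncated adaptively (term magnitude ~ n (b/r1)^(n-1)) unless
    ``n_terms`` is given.  Columns are average-referenced.
    """
    pos = grid.positions
    b = np.linalg.norm(pos, axis=1)
    r1 = radii[0]
    if np.any(b >= r1):
        raise ValueError("all grid voxels must lie strictly inside the innermost shell")
    if np.any(b < 1e-12):
        raise ValueError("grid voxels must not sit exactly at the head center")
    e_hat = montage.positions / np.linalg.norm(montage.positions, axis=1, keepdims=True)
    v_hat = pos / b[:, None]

    fmax = float(b.max() / r1)
    if n_terms is None:
        n_terms = 30
        while n_terms < 400 and (n_terms + 1) * fmax ** max(n_terms - 1, 1) > 1e-12:
            n_terms += 10
    t = _radial_transfer(n_terms, radii, conductivities)

    c = np.clip(v_hat @ e_hat.T, -1.0, 1.0)  # (V, E)
    s = np.sqrt(np.clip(1.0 - c**2, 0.0, None))
    tang = e_hat[None, :, :] - c[:, :, None] * v_hat[:, None, :]
    safe = s > 1e-9
    tang = np.where(safe[:, :, None], tang / np.where(safe, s, 1.0)[:, :, None], 0.0)

    sigma1 = conductivities[0]
    f = (b / r1)[:, None]  # (V, 1)
    base = 1.0 / (4.0 * np.pi * sigma1 * r1**2)

    # Legendre recurrences accumulated on the fly
    A_rad = np.zeros_like(c)
    A_tan = np.zeros_like(c)
    P_nm1 = np.ones_like(c)  # P_0
    P_n = c.copy()  # P_1
    Q_nm1 = np.zeros_like(c)  # P_0^1
    Q_n = s.copy()  # P_1^1
    f_pow = np.ones_like(f)  # f^(n-1) at n=1
    for n in range(1, n_terms + 1):
        coef = base * t[n] * f_pow
        A_rad += coef * n * P_n
        A_tan += coef * Q_n
        # advance recurrences to degree n+1
        P_np1 = ((2 * n + 1) * c * P_n - n * P_nm1) / (n + 1)
        Q_np1 = ((2 * n + 1) * c * Q_n - (n + 1) * Q_nm1) / n
        P_nm1, P_n = P_n, P_np1
        Q_nm1, Q_n = Q_n, Q_np1
        f_pow = f_pow * f

    # gain[e, v, k] = A_rad[v, e] * v_hat[v, k] + A_tan[v, e] * tang[v, e, k]
    gain = (
        A_rad.T[:, :, None] * v_hat[None, :, :]
        + A_tan.T[:, :, None] * tang.transpose(1, 0, 2)
    )
    gain -= gain.mean(axis=0, keepdims=True)
    return LeadField(gain=gain, montage=montage, grid=grid, radii=tuple(radii),
                     conductivities=tuple(conductivities))


@dataclass(frozen=True)
class ELORETAConfig:
    regularization: float = 1.0
    max_iter: int = 100
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")


@dataclass
class ELORETATransform:
    """Converged inverse operator: ``transform`` maps an average-referenced
    64-channel topography to per-voxel dipole moments (V, 3)."""

    transform: np.ndarray  # (V, 3, E)
    weights: np.ndarray  # (V, 3, 3)
    iterations: int
    converged: bool
    config: ELORETAConfig
    leadfield: LeadField


def _batch_sym_inv(W: np.ndarray) -> np.ndarray:
    w, vec = np.linalg.eigh(W)
    floor = np.maximum(w[..., -1:] * 1e-12, 1e-300)
    inv = 1.0 / np.maximum(w, floor)
    return np.einsum("vik,vk,vjk->vij", vec, inv, vec)


def _batch_sym_sqrt(S: np.ndarray) -> np.ndarray:
    w, vec = np.linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    return np.einsum("vik,vk,vjk->vij", vec, np.sqrt(w), vec)


def eloreta_transform(L: LeadField, cfg: ELORETAConfig = ELORETAConfig()) -> ELORETATransform:
    """Compute the eLORETA inverse operator by the standard fixed-point
    iteration on symmetric 3x3 voxel weight blocks.

    Each sweep forms ``C = K W^-1 K^T``, regularizes it with
    ``alpha * mean-sensor-variance`` times the average-reference centering
    operator, and updates every block to the symmetric square root of
    ``K_v^T C^+ K_v``; iteration stops when the relative weight change
    drops below ``cfg.tol``.  The stated regularization is scale-free: it
    multiplies the mean of C's diagonal, so ``regularization=1`` means a
    ridge the size of the average sensor variance of the gain gram.
    """
    K = np.asarray(L.gain, dtype=float)  # (E, V, 3)
    if not np.all(np.isfinite(K)):
        raise ValueError("leadfield must be finite")
    E, V, _ = K.shape
    H = np.eye(E) - 1.0 / E
    W = np.broadcast_to(np.eye(3), (V, 3, 3)).copy()
    alpha = cfg.regularization
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        Winv = _batch_sym_inv(W)
        C = np.einsum("avi,vij,bvj->ab", K, Winv, K, optimize=True)
        alpha_eff = alpha * np.trace(C) / E
        M = np.linalg.pinv(C + alpha_eff * H, hermitian=True, rcond=1e-12)
        S = np.einsum("avi,ab,bvj->vij", K, M, K, optimize=True)
        W_new = _batch_sym_sqrt(S)
        num = np.linalg.norm(W_new - W)
        den = np.linalg.norm(W)
        W = W_new
        if num / den < cfg.tol:
            converged = True
            break
    Winv = _batch_sym_inv(W)
    Kt = K.transpose(1, 2, 0)  # (V, 3, E)
    C = np.einsum("avi,vij,bvj->ab", K, Winv, K, optimize=True)
    alpha_eff = alpha * np.trace(C) / E
    M = np.linalg.pinv(C + alpha_eff * H, hermitian=True, rcond=1e-12)
    T = np.einsum("vij,vje,ef->vif", Winv, Kt, M, optimize=True)
    return ELORETATransform(
        transform=T, weights=W, iterations=it, converged=converged, config=cfg, leadfield=L
    )


@dataclass
class SourceMap:
    """Per-voxel current-density magnitudes (relative units) with an
    optional binary mask of the dominant voxels."""

    grid: SourceGrid
    values: np.ndarray  # (V,)
    moments: np.ndarray | None = None  # (V, 3)
    mask: np.ndarray | None = None
    threshold: float | None = None


def localize(topography: np.ndarray, transform: ELORETATransform) -> SourceMap:
    """Project a 64-channel topography into source space.

    The topography is re-centered to the average reference first; the
    per-voxel magnitude is the Euclidean norm of the estimated dipole
    moment, i.e. an orientation-free current-density map.
    """
    topo = np.asarray(topography, dtype=float).ravel()
    if topo.shape[0] != transform.transform.shape[2]:
        raise ValueError(
            f"topography has {topo.shape[0]} channels, leadfield expects "
            f"{transform.transform.shape[2]}"
        )
    topo = topo - topo.mean()
    J = np.einsum("vie,e->vi", transform.transform, topo)
    return SourceMap(
        grid=transform.leadfield.grid, values=np.linalg.norm(J, axis=1), moments=J
    )


def threshold_map(
    smap: SourceMap, fraction: float = 0.75, method: str = "fraction-of-max"
) -> SourceMap:
    """Binarize a source map, keeping its dominant voxels.

    ``fraction-of-max`` keeps voxels strictly above ``fraction`` times the
    map maximum (the default, fraction 0.75 -> the ">75% of maximum"
    rendering rule); ``percentile`` keeps voxels above the ``fraction``
    rank quantile instead.
    """
    vals = np.asarray(smap.values, dtype=float)
    vmax = vals.max()
    if vmax <= 0:
        raise ValueError("cannot threshold an all-zero source map")
    if method == "fraction-of-max":
        cut = fraction * vmax
    elif method == "percentile":
        cut = float(np.quantile(vals, fraction))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return SourceMap(
        grid=smap.grid,
        values=vals,
        moments=smap.moments,
        mask=vals > cut,
        threshold=cut,
    )
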