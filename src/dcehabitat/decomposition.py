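"""NMF decomposition of prostate signal-time curves.

The prostate voxels' baseline-corrected curves form a non-negative matrix
``D`` (P voxels x T frames) which is factorized as ``D ~ W x S`` with
``W >= 0`` and ``S >= 0``: the rows of ``S`` are k temporal contrast
signatures and the columns of ``W`` their per-voxel weights.  The
well-perfused pattern is the signature with the largest trapezoidal area
under the curve over the first 90 s; its weight column, mapped back to 3D,
is the ``W_wp`` intensity map of suspicious perfusion that the
segmentation stage thresholds.

Patterns are normalized to unit maximum with the weights rescaled so the
product ``W x S`` is unchanged; all downstream logic is invariant to this
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import NMF

from .io_core import DceSeries, MaskVolume, TimeGrid

__all__ = [
    "CurveMatrix",
    "NmfResult",
    "build_curve_matrix",
    "estimate_k",
    "run_nmf",
    "select_wp",
    "decompose",
    "save_nmf",
    "load_nmf",
]

DEFAULT_K = 3
_K_MIN, _K_MAX = 2, 5


@dataclass
class CurveMatrix:
    """Baseline-corrected prostate voxel curves, P x T, with coordinates."""

    D: np.ndarray  # P x T, non-negative
    coords: np.ndarray  # P x 3 voxel indices
    shape: tuple[int, int, int]
    grid: TimeGrid

    @property
    def n_voxels(self) -> int:
        return self.D.shape[0]


@dataclass
class NmfResult:
    """Factorization ``D ~ W x S`` plus the selected well-perfused pattern."""

    W: np.ndarray  # P x k
    S: np.ndarray  # k x T
    coords: np.ndarray
    shape: tuple[int, int, int]
    grid: TimeGrid
    residual: float  # relative Frobenius residual ||D - WS|| / ||D||
    converged: bool = True
    wp_index: int | None = None

    @property
    def k(self) -> int:
        return self.W.shape[1]

    def weight_map(self, m: int) -> np.ndarray:
        """3D volume of the weights of pattern ``m`` (zero outside prostate)."""
        vol = np.zeros(self.shape, dtype=float)
        vol[tuple(self.coords.T)] = self.W[:, m]
        return vol

    @property
    def W_wp(self) -> np.ndarray:
        if self.wp_index is None:
            raise ValueError("well-perfused pattern not selected yet")
        return self.weight_map(self.wp_index)

    @property
    def prostate_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        mask[tuple(self.coords.T)] = True
        return mask


def build_curve_matrix(series: DceSeries, prostate: MaskVolume) -> CurveMatrix:
    """Extract prostate voxel curves, subtract the pre-contrast baseline.

    Each row is the voxel's time course minus the mean of its ``n_pre``
    pre-contrast frames; negatives are clipped to zero to satisfy the
    non-negativity the factorization requires.
    """
    if not prostate.data.any():
        raise ValueError("prostate mask is empty")
    coords = np.argwhere(prostate.data)
    rows = series.data[prostate.data]  # P x T
    baseline = rows[:, : series.grid.n_pre].mean(axis=1, keepdims=True)
    D = np.clip(rows - baseline, 0.0, None)
    return CurveMatrix(D=D, coords=coords, shape=series.shape3d, grid=series.grid)


def estimate_k(cm: CurveMatrix, k_min: int = _K_MIN, k_max: int = _K_MAX) -> int:
    """Estimate the number of significant components of ``D``.

    Uses the minimum of the Malinowski factor-indicator function computed
    from the PCA eigenspectrum of D, clamped to ``[k_min, k_max]``.  The
    default pipeline uses a fixed k = 3; this estimator is available for
    data-driven rank selection.
    """
    D = cm.D
    P, T = D.shape
    if P <= T:
        raise ValueError("need more voxels than frames to estimate rank")
    # eigenvalues of D^T D (squared singular values)
    g = np.linalg.svd(D, compute_uv=False) ** 2
    g = np.concatenate([g, np.zeros(T - g.size)])
    # eigenvalues at float round-off level are exact zeros of the model
    g[g < g[0] * 1e-12] = 0.0
    ind = np.full(T - 1, np.inf)
    for n in range(1, T):
        rsd = np.sqrt(max(g[n:].sum(), 0.0) / (P * (T - n)))
        ind[n - 1] = rsd / (T - n) ** 2
    n_best = int(np.argmin(ind)) + 1
    if n_best < k_min:
        warnings.warn(
            f"estimated rank {n_best} below floor; clamping to {k_min}"
        )
    return int(np.clip(n_best, k_min, k_max))


def run_nmf(
    cm: CurveMatrix,
    k: int = DEFAULT_K,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-10,
    init: str = "nndsvda",
) -> NmfResult:
    """Non-negative factorization of the curve matrix.

    Multiplicative updates on the Frobenius loss with a deterministic
    NNDSVD-based initialization, so identical inputs give identical
    factors; ``seed`` only matters when ``init='random'`` is requested.

    Multiplicative updates stay close to the NNDSVD basin, which keeps
    the temporal patterns tissue-separated; faster solvers that chase the
    global Frobenius optimum tend to rotate the patterns into mixtures
    (the factorization of overlapping smooth curves is near-degenerate),
    which would defeat the purity segmentation downstream.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    D = cm.D
    norm_D = np.linalg.norm(D)
    if norm_D == 0:
        W = np.zeros((D.shape[0], k))
        S = np.zeros((k, D.shape[1]))
        return NmfResult(
            W=W, S=S, coords=cm.coords, shape=cm.shape, grid=cm.grid,
            residual=0.0,
        )
    model = NMF(
        n_components=k,
        init=init,
        solver="mu",
        beta_loss="frobenius",
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(D)
    S = model.components_
    converged = model.n_iter_ < max_iter
    if not converged:
        warnings.warn("NMF did not converge; returning best iterate")
    # unit-maximum pattern normalization, W rescaled so W x S is unchanged
    peaks = S.max(axis=1)
    for m in range(k):
        if peaks[m] > 0:
            S[m] /= peaks[m]
            W[:, m] *= peaks[m]
    residual = float(np.linalg.norm(D - W @ S) / norm_D)
    return NmfResult(
        W=W, S=S, coords=cm.coords, shape=cm.shape, grid=cm.grid,
        residual=residual, converged=converged,
    )


def auc_0_90(pattern: np.ndarray, grid: TimeGrid, t_max: float = 90.0) -> float:
    """Trapezoidal AUC of a pattern over the frames with t <= ``t_max``."""
    sel = grid.times <= t_max
    return float(np.trapezoid(pattern[sel], grid.times[sel]))


def select_wp(S: np.ndarray, grid: TimeGrid) -> int:
    """Index of the well-perfused pattern: argmax of AUC over [0, 90] s.

    If 90 s falls between frames the integral stops at the last frame
    before it (no extrapolation).  Exact ties are broken by the lowest
    pattern index, with a warning.
    """
    aucs = np.array([auc_0_90(S[m], grid) for m in range(S.shape[0])])
    best = int(np.argmax(aucs))
    if np.sum(aucs == aucs[best]) > 1:
        warnings.warn("AUC tie between patterns; selecting the lowest index")
    return best


def decompose(
    series: DceSeries,
    prostate: MaskVolume,
    k: int | None = DEFAULT_K,
    seed: int = 0,
) -> NmfResult:
    """Full stage: curve matrix -> NMF -> well-perfused pattern selection.

    ``k=None`` triggers data-driven rank estimation.
    """
    cm = build_curve_matrix(series, prostate)
    if k is None:
        k = estimate_k(cm)
    res = run_nmf(cm, k=k, seed=seed)
    res.wp_index = select_wp(res.S, series.grid)
    return res


# ---------------------------------------------------------------------------
# Persistence: compressed-array bundle (documented npz + embedded metadata)


def save_nmf(res: NmfResult, path: str | Path) -> None:
    np.savez_compressed(
        Path(path),
        W=res.W,
        S=res.S,
        coords=res.coords,
        shape=np.asarray(res.shape),
        times=res.grid.times,
        n_pre=np.asarray(res.grid.n_pre),
        residual=np.asarray(res.residual),
        wp_index=np.asarray(-1 if res.wp_index is None else res.wp_index),
        converged=np.asarray(res.converged),
    )


def load_nmf(path: str | Path) -> NmfResult:
    with np.load(Path(path)) as z:
        wp = int(z["wp_index"])
        return NmfResult(
            W=z["W"],
            S=z["S"],
            coords=z["coords"],
            shape=tuple(int(v) for v in z["shape"]),
            grid=TimeGrid(times=z["times"], n_pre=int(z["n_pre"])),
            residual=float(z["residual"]),
            converged=bool(z["converged"]),
            wp_index=None if wp < 0 else wp,
        )
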