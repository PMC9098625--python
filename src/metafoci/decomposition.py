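"""Decomposition of a set of statistical brain maps.

The maps (e.g. thresholded ALE maps, one per task paradigm) are vectorized
over a common brain mask into a maps x voxels matrix.  Inter-map structure
is summarised three ways:

* metric MDS on the 1 - r correlation-distance matrix, stress-majorization
  (SMACOF) initialised from PCA scores, goodness-of-fit by Kruskal's
  standardized stress;
* PCA over the maps dimension: loadings (map coefficients) and voxel
  score maps, with explained-variance ratios;
* spatial ICA (FastICA, log-cosh contrast) at a component count chosen
  from the PCA, with components re-ordered and sign-flipped to match the
  principal components.

Sampling adequacy of the map correlation matrix is reported via the
Kaiser-Meyer-Olkin index and Bartlett's sphericity test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA, FastICA
from sklearn.manifold import smacof

from .foci_io import BrainGrid, Volume

logger = logging.getLogger(__name__)

__all__ = [
    "MapMatrix",
    "Embedding",
    "Decomposition",
    "vectorize_maps",
    "correlation_distance",
    "classical_mds_init",
    "mds_embed",
    "kruskal_stress",
    "pca_decompose",
    "ica_decompose",
    "align_components",
    "sampling_adequacy",
]


@dataclass
class MapMatrix:
    """maps x voxels matrix of map values over the in-mask voxels."""

    names: list[str]
    values: np.ndarray  # (n_maps, n_voxels)
    grid: BrainGrid

    @property
    def n_maps(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def zero_variance_maps(self) -> list[str]:
        sd = self.values.std(axis=1)
        return [n for n, s in zip(self.names, sd) if s == 0.0]


@dataclass
class Embedding:
    coordinates: np.ndarray  # (n_maps, dims)
    stress: float  # Kruskal standardized stress
    dims: int
    names: list[str]


@dataclass
class Decomposition:
    method: str  # "pca" | "ica"
    loadings: np.ndarray  # (n_maps, k) map coefficients
    scores: np.ndarray  # (n_voxels, k) voxel projections
    names: list[str]
    grid: BrainGrid
    explained_variance_ratio: np.ndarray | None = None
    order: np.ndarray | None = None  # permutation applied by align_components
    signs: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def score_volumes(self) -> list[Volume]:
        out = []
        for c in range(self.k):
            data = np.zeros(self.grid.shape)
            data[self.grid.mask] = self.scores[:, c]
            out.append(Volume(self.grid, data, name=f"{self.method}-{c + 1}"))
        return out


def vectorize_maps(volumes: list[Volume], grid: BrainGrid) -> MapMatrix:
    """Stack map volumes into a maps x voxels matrix over the brain mask."""
    if not volumes:
        raise ValueError("no volumes given")
    rows, names = [], []
    for v in volumes:
        if v.grid.shape != grid.shape:
            raise ValueError(f"volume {v.name!r} is on a different grid")
        rows.append(v.data[grid.mask])
        names.append(v.name or f"map{len(names) + 1}")
    m = MapMatrix(names=names, values=np.vstack(rows), grid=grid)
    zv = m.zero_variance_maps()
    if zv:
        logger.warning("zero-variance maps: %s", ", ".join(zv))
    return m


def correlation_distance(m: MapMatrix) -> np.ndarray:
    """Pairwise dissimilarity d_ij = 1 - r_ij (Pearson) between maps."""
    if m.n_maps < 2:
        raise ValueError("need at least two maps")
    zv = m.zero_variance_maps()
    if zv:
        raise ValueError(f"zero-variance map(s): {', '.join(zv)}")
    r = np.corrcoef(m.values)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return d


def classical_mds_init(d: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson double-centring coordinates: the PCA of a distance matrix.

    Used as the deterministic starting configuration for the iterative
    embedding, so repeated runs give identical solutions and the first
    ``dims`` columns are nested across dimensionalities.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:dims]
    w = np.clip(w[order], 0.0, None)
    coords = v[:, order] * np.sqrt(w)
    # deterministic sign convention: largest-magnitude element positive
    for c in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, c]))
        if coords[i, c] < 0:
            coords[:, c] *= -1
    return coords


def kruskal_stress(d: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal standardized stress of an embedding.

    S = sqrt( sum_{i<j} (D_ij - dhat_ij)^2 / sum_{i<j} D_ij^2 ) with dhat
    the embedded Euclidean distances.
    """
    d = np.asarray(d, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if d.shape[0] != coords.shape[0]:
        raise ValueError("distance matrix and coordinates disagree in size")
    iu = np.triu_indices(d.shape[0], k=1)
    denom = (d[iu] ** 2).sum()
    if denom == 0:
        raise ValueError("all-zero distance matrix")
    dhat = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    num = ((d[iu] - dhat[iu]) ** 2).sum()
    return float(np.sqrt(num / denom))


def mds_embed(
    d: np.ndarray,
    dims: int = 3,
    init: np.ndarray | None = None,
    names: list[str] | None = None,
    max_iter: int = 3000,
    eps: float = 1e-9,
) -> Embedding:
    """Metric MDS by stress majorization from a given initialization.

    With ``init=None`` the classical (Torgerson) solution is used, which
    makes the embedding deterministic and nested across ``dims``.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if dims >= n:
        raise ValueError(f"dims={dims} must be < number of points ({n})")
    if init is None:
        init = classical_mds_init(d, dims)
    init = np.asarray(init, dtype=float)
    if init.shape != (n, dims):
        raise ValueError(f"init shape {init.shape} != ({n}, {dims})")
    coords, _ = smacof(
        d,
        metric=True,
        n_components=dims,
        init=init,
        n_init=1,
        max_iter=max_iter,
        eps=eps,
        normalized_stress=False,
    )
    s = kruskal_stress(d, coords)
    return Embedding(
        coordinates=coords,
        stress=s,
        dims=dims,
        names=names or [f"map{i + 1}" for i in range(n)],
    )


def pca_decompose(m: MapMatrix, k: int) -> Decomposition:
    """PCA over the maps dimension of a maps x voxels matrix.

    Each map is mean-centred over voxels (no variance scaling: the maps
    share a common statistic scale).  Loadings are the map coefficients of
    each component; scores are the voxel projections.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m.n_maps:
        raise ValueError(f"k={k} exceeds the number of maps ({m.n_maps})")
    x = m.values.T  # voxels x maps; PCA variables = maps
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # maps x k
    # deterministic sign convention
    for c in range(k):
        i = np.argmax(np.abs(loadings[:, c]))
        if loadings[i, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return Decomposition(
        method="pca",
        loadings=loadings,
        scores=scores,
        names=list(m.names),
        grid=m.grid,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def ica_decompose(
    m: MapMatrix, k: int, seed: int | None = 0, max_iter: int = 1000, tol: float = 1e-6
) -> Decomposition:
    """Spatial ICA of the maps x voxels matrix.

    The voxels x maps matrix is whitened to ``k`` dimensions and rotated to
    maximise non-Gaussianity of the voxel scores (FastICA, log-cosh
    contrast).  Component order and sign are indeterminate; use
    :func:`align_components` to match a PCA of the same data.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m.n_maps:
        raise ValueError(f"k={k} exceeds the number of maps ({m.n_maps})")
    x = m.values.T  # voxels x maps
    ica = FastICA(
        n_components=k,
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    scores = ica.fit_transform(x)  # voxels x k
    if ica.n_iter_ >= max_iter:
        raise RuntimeError(
            "FastICA did not converge; try another seed or component count"
        )
    loadings = ica.mixing_  # maps x k
    return Decomposition(
        method="ica",
        loadings=loadings,
        scores=scores,
        names=list(m.names),
        grid=m.grid,
    )


def align_components(ica: Decomposition, pca: Decomposition) -> Decomposition:
    """Reorder/sign-flip ICA components to match PCA components.

    Greedy one-to-one assignment on |Pearson correlation| of the voxel
    scores, highest first; ties resolved in favour of the lower PC index.
    The matched correlation is made positive by flipping the IC sign (the
    loading is flipped with it, leaving the reconstruction unchanged).
    """
    if ica.k != pca.k:
        raise ValueError("component counts differ")
    k = ica.k
    r = np.corrcoef(pca.scores.T, ica.scores.T)[:k, k:]  # (pc, ic)
    order = np.full(k, -1, dtype=int)
    signs = np.ones(k)
    used_pc: set[int] = set()
    used_ic: set[int] = set()
    flat = sorted(
        ((abs(r[p, i]), p, i) for p in range(k) for i in range(k)),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    for _, p, i in flat:
        if p in used_pc or i in used_ic:
            continue
        order[p] = i
        signs[p] = 1.0 if r[p, i] >= 0 else -1.0
        used_pc.add(p)
        used_ic.add(i)
        if len(used_pc) == k:
            break
    return Decomposition(
        method="ica",
        loadings=ica.loadings[:, order] * signs,
        scores=ica.scores[:, order] * signs,
        names=list(ica.names),
        grid=ica.grid,
        order=order,
        signs=signs,
    )


def sampling_adequacy(m: MapMatrix) -> tuple[float, float, int, float]:
    """KMO index and Bartlett sphericity test of the map correlation matrix.

    Returns ``(kmo, chi2, df, p)``.  Bartlett's n is the in-mask voxel
    count; note voxels are spatially dependent, so the effective n is
    smaller and the chi-square p-value is anti-conservative.
    """
    if m.n_maps < 3:
        raise ValueError("need at least three maps")
    r = np.corrcoef(m.values)
    p_vars = r.shape[0]
    n = m.n_voxels

    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("singular correlation matrix")
    chi2 = -(n - 1 - (2 * p_vars + 5) / 6.0) * logdet
    df = p_vars * (p_vars - 1) // 2
    p_value = float(stats.chi2.sf(chi2, df))

    try:
        r_inv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix") from exc
    d = np.sqrt(np.outer(np.diag(r_inv), np.diag(r_inv)))
    partial = -r_inv / d
    off = ~np.eye(p_vars, dtype=bool)
    kmo = float((r[off] ** 2).sum() / ((r[off] ** 2).sum() + (partial[off] ** 2).sum()))
    return kmo, float(chi2), int(df), p_value
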