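"""Activation likelihood estimation (ALE) with cluster-level FWE and fail-safe.

Each experiment's foci are modelled as 3-D isotropic Gaussian probability
kernels whose spatial uncertainty shrinks with the number of subjects:

    sd(n) = sqrt(sigma_template^2 + sigma_subject^2 / n)
    FWHM(n) = sqrt(8 ln 2) * sd(n)

The per-experiment modelled-activation (MA) map takes, at every voxel, the
maximum over that experiment's kernels (each a unit-mass probability
kernel, so MA is the per-voxel probability that the experiment's true
activation lies there) — non-additive, so within-experiment focus
clusters do not inflate evidence.
Experiments combine by probabilistic union:

    ALE(v) = 1 - prod_e (1 - MA_e(v)).

Voxel-wise inference uses an analytic null obtained by convolving the
experiments' in-brain MA value histograms under the same union formula
(equivalent to relocating each experiment's activation independently and
uniformly within the brain).  Cluster-level FWE control compares observed
supra-threshold cluster sizes against the null distribution of the maximum
cluster size over Monte-Carlo datasets with uniformly redrawn foci.

The fail-safe (file-drawer) analysis appends a stated proportion of pure
noise experiments — uniform foci, focus/subject counts resampled from the
observed experiments — and checks which clusters survive re-analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .foci_io import (
    BrainGrid,
    Experiment,
    FociDataset,
    Focus,
    Volume,
    foci_voxel_indices,
)

logger = logging.getLogger(__name__)

GAUSS_FWHM = math.sqrt(8.0 * math.log(2.0))
MIN_RECOMMENDED_EXPERIMENTS = 17

# face connectivity (6 neighbours)
CONNECTIVITY_6 = ndimage.generate_binary_structure(3, 1)

__all__ = [
    "KernelSpec",
    "AleResult",
    "FailsafeResult",
    "fwhm_from_subjects",
    "modeled_activation",
    "ale_map",
    "AleNull",
    "voxel_null",
    "cluster_fwe",
    "failsafe",
]


@dataclass(frozen=True)
class KernelSpec:
    """Spatial uncertainty model of the ALE kernel.

    sigma_template : between-template sd (mm), irreducible registration
        uncertainty shared by all experiments.
    sigma_subject : between-subject sd (mm); its contribution shrinks with
        1/sqrt(n).  Defaults put FWHM in the 9-12 mm range for typical
        sample sizes (n = 5-30).
    """

    sigma_template: float = 3.5
    sigma_subject: float = 8.0

    def __post_init__(self) -> None:
        if self.sigma_template < 0 or self.sigma_subject < 0:
            raise ValueError("kernel sds must be non-negative")

    def sd(self, n_subjects: int) -> float:
        if n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        return math.sqrt(
            self.sigma_template**2 + self.sigma_subject**2 / n_subjects
        )

    def fwhm(self, n_subjects: int) -> float:
        return GAUSS_FWHM * self.sd(n_subjects)


def fwhm_from_subjects(n_subjects: int, spec: KernelSpec) -> float:
    """Kernel FWHM (mm) for an experiment with ``n_subjects`` subjects."""
    return spec.fwhm(n_subjects)


# ---------------------------------------------------------------------------
# Modelled activation


_PATCH_CACHE: dict[tuple, np.ndarray] = {}


def _kernel_patch(sd: float, voxel_sizes: tuple[float, ...], trunc: float = 1e-6) -> np.ndarray:
    """Gaussian probability kernel sampled at voxel centres.

    Normalised to unit mass over the lattice, so a focus contributes its
    maximum (the per-voxel probability of the true activation) at its own
    voxel and the union statistic stays strictly below one.  Truncated
    where the kernel falls below ``trunc`` of its peak.
    """
    key = (round(sd, 9), tuple(round(v, 9) for v in voxel_sizes), trunc)
    patch = _PATCH_CACHE.get(key)
    if patch is not None:
        return patch
    r_mm = sd * math.sqrt(-2.0 * math.log(trunc))
    radii = [int(math.ceil(r_mm / v)) for v in voxel_sizes]
    axes = [np.arange(-r, r + 1) * v for r, v in zip(radii, voxel_sizes)]
    d2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    patch = np.exp(-d2 / (2.0 * sd * sd))
    patch[patch < trunc] = 0.0
    patch /= patch.sum()
    _PATCH_CACHE[key] = patch
    return patch


def _ma_array(
    foci_ijk: np.ndarray, grid: BrainGrid, sd: float
) -> np.ndarray:
    """MA field from voxel-snapped foci: max of shifted Gaussian patches."""
    out = np.zeros(grid.shape, dtype=float)
    patch = _kernel_patch(sd, tuple(grid.voxel_sizes))
    radii = [(s - 1) // 2 for s in patch.shape]
    for ijk in foci_ijk:
        src, dst = [], []
        for ax in range(3):
            c, r, n = int(ijk[ax]), radii[ax], grid.shape[ax]
            lo, hi = c - r, c + r + 1
            dst.append(slice(max(lo, 0), min(hi, n)))
            src.append(slice(max(lo, 0) - lo, patch.shape[ax] - (hi - min(hi, n))))
        dst, src = tuple(dst), tuple(src)
        np.maximum(out[dst], patch[src], out=out[dst])
    return out


def modeled_activation(
    experiment: Experiment, grid: BrainGrid, spec: KernelSpec
) -> Volume:
    """Modelled-activation map of one experiment.

    Foci are snapped to their nearest voxel centre; the map value at a
    voxel is the maximum over the experiment's kernels (values in [0, 1]).
    Out-of-grid foci are dropped with a warning; an experiment with no
    in-grid focus is an error.
    """
    ijk, _ = foci_voxel_indices(grid, experiment.foci)
    if len(ijk) == 0:
        raise ValueError(
            f"experiment {experiment.study!r}: all foci fall outside the grid"
        )
    sd = spec.sd(experiment.n_subjects)
    return Volume(grid, _ma_array(ijk, grid, sd), name=f"MA:{experiment.study}")


def ale_map(ma_volumes: list[Volume]) -> Volume:
    """Union-combine MA maps: ALE = 1 - prod(1 - MA)."""
    if not ma_volumes:
        raise ValueError("need at least one MA volume")
    grid = ma_volumes[0].grid
    for v in ma_volumes[1:]:
        if v.grid is not grid and (
            v.grid.shape != grid.shape or not np.allclose(v.grid.affine, grid.affine)
        ):
            raise ValueError("MA volumes are on different grids")
    acc = np.ones(grid.shape, dtype=float)
    for v in ma_volumes:
        acc *= 1.0 - v.data
    return Volume(grid, 1.0 - acc, name="ALE")


# ---------------------------------------------------------------------------
# Analytic voxel-wise null


class AleNull:
    """Null distribution of the ALE statistic under uniform focus relocation.

    Stores the pmf of ALE values discretised to bins of width ``bin_width``
    (bin i represents the value i * bin_width) and exposes the exceedance
    probability P(ALE >= a).
    """

    def __init__(self, pmf: np.ndarray, bin_width: float):
        self.bin_width = float(bin_width)
        self.pmf = np.asarray(pmf, dtype=float)
        # survival[i] = P(ALE >= i * bin_width)
        self.survival = self.pmf[::-1].cumsum()[::-1]

    def exceedance(self, a) -> np.ndarray | float:
        """P(ALE >= a) for scalar or array ``a``."""
        a = np.asarray(a, dtype=float)
        idx = np.ceil(a / self.bin_width - 1e-9).astype(int)
        idx = np.clip(idx, 0, len(self.survival) - 1)
        out = self.survival[idx]
        out = np.where(a > (len(self.survival) - 1) * self.bin_width, 0.0, out)
        return float(out) if out.ndim == 0 else out

    def threshold(self, p: float) -> float:
        """Smallest ALE value a with P(ALE >= a) <= p (inf if unattainable)."""
        below = np.nonzero(self.survival <= p)[0]
        if len(below) == 0:
            return float("inf")
        return float(below[0] * self.bin_width)


def voxel_null(
    ma_volumes: list[Volume],
    mask: np.ndarray,
    bin_width: float = 1e-5,
) -> AleNull:
    """Analytic ALE null by successive histogram convolution.

    For each experiment the in-brain MA values are histogrammed; the
    experiment histograms are combined one at a time under the union
    formula, each bin weighted by its in-brain frequency.  This is the
    distribution of the ALE value at a single voxel when every experiment's
    activation pattern is relocated uniformly within the brain.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if not ma_volumes:
        raise ValueError("need at least one MA volume")
    if len(ma_volumes) < MIN_RECOMMENDED_EXPERIMENTS:
        logger.warning(
            "ALE on %d experiments; at least %d are recommended for a "
            "statistically sound meta-analysis",
            len(ma_volumes),
            MIN_RECOMMENDED_EXPERIMENTS,
        )
    mask = np.asarray(mask, dtype=bool)
    n_bins = int(math.ceil(1.0 / bin_width)) + 1

    def hist_of(values: np.ndarray) -> np.ndarray:
        idx = np.floor(values / bin_width + 0.5).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        h = np.bincount(idx, minlength=n_bins).astype(float)
        return h / h.sum()

    pmf = hist_of(ma_volumes[0].data[mask])
    vals = np.arange(n_bins) * bin_width
    for vol in ma_volumes[1:]:
        h = hist_of(vol.data[mask])
        nz_a = np.nonzero(pmf)[0]
        nz_m = np.nonzero(h)[0]
        new = np.zeros(n_bins)
        # chunk over current-pmf support to bound the outer-product memory
        chunk = max(1, int(4e6 / max(len(nz_m), 1)))
        one_minus_m = 1.0 - vals[nz_m]
        w_m = h[nz_m]
        for s in range(0, len(nz_a), chunk):
            blk = nz_a[s : s + chunk]
            a_vals = vals[blk]
            w_a = pmf[blk]
            combo = 1.0 - np.outer(1.0 - a_vals, one_minus_m)
            idx = np.floor(combo / bin_width + 0.5).astype(int)
            np.clip(idx, 0, n_bins - 1, out=idx)
            weights = np.outer(w_a, w_m)
            new += np.bincount(idx.ravel(), weights=weights.ravel(), minlength=n_bins)
        pmf = new
    return AleNull(pmf, bin_width)


# ---------------------------------------------------------------------------
# Cluster-level FWE


@dataclass
class AleResult:
    ale: Volume
    p: Volume
    forming_threshold_ale: float
    forming_threshold_p: float
    cluster_size_threshold: int
    clusters: Volume  # integer labels, 0 = background
    cluster_table: pd.DataFrame  # label, size, peak_x/y/z (mm), peak_ale
    null: AleNull = field(repr=False, default=None)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_table)

    def cluster_mask(self) -> np.ndarray:
        return self.clusters.data > 0


def _label_clusters(supra: np.ndarray) -> tuple[np.ndarray, int]:
    return ndimage.label(supra, structure=CONNECTIVITY_6)


def _max_cluster_size(supra: np.ndarray) -> int:
    labels, n = _label_clusters(supra)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def _draw_uniform_experiment(
    rng: np.random.Generator, n_foci: int, mask_idx: np.ndarray
) -> np.ndarray:
    sel = rng.integers(0, len(mask_idx), size=n_foci)
    return mask_idx[sel]


def _perm_max_sizes(
    dataset_counts: list[tuple[int, float]],
    grid: BrainGrid,
    forming_ale: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null max-cluster-size distribution under uniform focus relocation."""
    mask_idx = grid.mask_indices()
    sizes = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        acc = np.ones(grid.shape)
        for n_foci, sd in dataset_counts:
            ijk = _draw_uniform_experiment(rng, n_foci, mask_idx)
            acc *= 1.0 - _ma_array(ijk, grid, sd)
        ale = 1.0 - acc
        supra = (ale >= forming_ale) & grid.mask
        sizes[i] = _max_cluster_size(supra)
    return sizes


def _size_threshold(max_sizes: np.ndarray, alpha: float) -> int:
    """Smallest cluster size whose null exceedance probability is <= alpha.

    Equivalent to the ceiling of the (1 - alpha) quantile of the null
    maximum-cluster-size distribution, stepped to the next attainable
    integer size.
    """
    s = 1
    ms = np.sort(np.asarray(max_sizes))
    n = len(ms)
    while (n - np.searchsorted(ms, s, side="left")) / n > alpha:
        s += 1
    return s


def cluster_fwe(
    dataset: FociDataset,
    grid: BrainGrid,
    spec: KernelSpec,
    cfp: float = 0.001,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = 0,
    bin_width: float = 1e-5,
) -> AleResult:
    """Full ALE analysis with cluster-forming and cluster-extent FWE thresholds.

    Parameters
    ----------
    dataset : merged dataset (one experiment per subject group).
    cfp : cluster-forming voxel-wise p threshold (default 0.001).
    alpha : cluster-level FWE rate (default 0.05).
    n_perm : Monte-Carlo datasets for the max-cluster-size null (>= 100).
    bin_width : ALE-histogram resolution of the analytic voxel null.
    """
    if not (0 < cfp < 1):
        raise ValueError("cfp must be in (0, 1)")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    exps = list(dataset.experiments)
    if not exps:
        raise ValueError("empty dataset")

    ma = [modeled_activation(e, grid, spec) for e in exps]
    ale = ale_map(ma)
    null = voxel_null(ma, grid.mask, bin_width=bin_width)
    forming_ale = null.threshold(cfp)

    p_data = np.ones(grid.shape)
    p_data[grid.mask] = null.exceedance(ale.data[grid.mask])
    p_vol = Volume(grid, p_data, name="ALE-p")

    empty_table = pd.DataFrame(
        columns=["label", "size", "peak_x", "peak_y", "peak_z", "peak_ale"]
    )
    if not np.isfinite(forming_ale):
        logger.info("no attainable ALE value passes the forming threshold")
        return AleResult(
            ale, p_vol, forming_ale, cfp, 0,
            Volume(grid, np.zeros(grid.shape)), empty_table, null,
        )

    supra = (ale.data >= forming_ale) & grid.mask
    labels, n_lab = _label_clusters(supra)
    if n_lab == 0:
        logger.info("no voxel passes the cluster-forming threshold")
        return AleResult(
            ale, p_vol, forming_ale, cfp, 0,
            Volume(grid, np.zeros(grid.shape)), empty_table, null,
        )

    rng = np.random.default_rng(seed)
    counts = [(e.n_foci, spec.sd(e.n_subjects)) for e in exps]
    max_sizes = _perm_max_sizes(counts, grid, forming_ale, n_perm, rng)
    k_thr = _size_threshold(max_sizes, alpha)

    sizes = np.bincount(labels.ravel())
    out_labels = np.zeros(grid.shape, dtype=int)
    rows = []
    new_label = 0
    order = np.argsort(-sizes[1:]) + 1  # largest first
    for lab in order:
        if sizes[lab] < k_thr:
            continue
        new_label += 1
        sel = labels == lab
        out_labels[sel] = new_label
        vox = np.argwhere(sel)
        vals = ale.data[sel]
        peak = vox[np.argmax(vals)]
        peak_mm = grid.voxel_to_mm(peak)
        rows.append(
            {
                "label": new_label,
                "size": int(sizes[lab]),
                "peak_x": float(peak_mm[0]),
                "peak_y": float(peak_mm[1]),
                "peak_z": float(peak_mm[2]),
                "peak_ale": float(vals.max()),
            }
        )
    table = pd.DataFrame(rows) if rows else empty_table
    return AleResult(
        ale,
        p_vol,
        float(forming_ale),
        cfp,
        int(k_thr),
        Volume(grid, out_labels.astype(float), name="clusters"),
        table,
        null,
    )


# ---------------------------------------------------------------------------
# Fail-safe (file-drawer) analysis


@dataclass
class FailsafeResult:
    original: AleResult
    augmented: AleResult
    proportion: float
    n_noise_experiments: int
    retained: dict[int, bool]  # original cluster label -> peak still significant
    noise_experiments: list[Experiment] = field(default_factory=list)

    @property
    def all_retained(self) -> bool:
        return all(self.retained.values()) if self.retained else True


def failsafe(
    dataset: FociDataset,
    proportion: float,
    grid: BrainGrid,
    spec: KernelSpec,
    seed: int | None = 0,
    cfp: float = 0.001,
    alpha: float = 0.05,
    n_perm: int = 1000,
    bin_width: float = 1e-5,
    original: AleResult | None = None,
) -> FailsafeResult:
    """Robustness to the file-drawer effect.

    Appends ``round(proportion * n_experiments)`` noise experiments with
    uniformly placed foci; their (n_foci, n_subjects) pairs are resampled
    jointly with replacement from the original experiments.  The analysis
    is re-run and each original surviving cluster is checked for a peak
    that is still inside the augmented surviving clusters (its peak voxel
    or a face neighbour of it).
    """
    if proportion < 0:
        raise ValueError("proportion must be >= 0")
    if original is None:
        original = cluster_fwe(
            dataset, grid, spec, cfp=cfp, alpha=alpha, n_perm=n_perm,
            seed=seed, bin_width=bin_width,
        )
    n_noise = int(round(proportion * len(dataset.experiments)))
    if n_noise == 0:
        return FailsafeResult(
            original, original, proportion, 0,
            {int(r["label"]): True for _, r in original.cluster_table.iterrows()},
        )

    noise_rng = np.random.default_rng(None if seed is None else seed + 104729)
    mask_idx = grid.mask_indices()
    pairs = [(e.n_foci, e.n_subjects) for e in dataset.experiments]
    noise_exps = []
    for i in range(n_noise):
        n_foci, n_subj = pairs[noise_rng.integers(0, len(pairs))]
        ijk = _draw_uniform_experiment(noise_rng, n_foci, mask_idx)
        mm = np.atleast_2d(grid.voxel_to_mm(ijk.astype(float)))
        noise_exps.append(
            Experiment(
                study=f"noise-{i:03d}",
                contrast="failsafe",
                n_subjects=int(n_subj),
                foci=[Focus(*row) for row in mm],
                paradigm="noise",
                group=f"noise-{i:03d}",
            )
        )
    augmented_ds = FociDataset(
        experiments=list(dataset.experiments) + noise_exps, space=dataset.space
    )
    augmented = cluster_fwe(
        augmented_ds, grid, spec, cfp=cfp, alpha=alpha, n_perm=n_perm,
        seed=seed, bin_width=bin_width,
    )


    surv = augmented.cluster_mask()
    surv_dil = ndimage.binary_dilation(surv, structure=CONNECTIVITY_6)
    retained = {}
    for _, row in original.cluster_table.iterrows():
        peak_ijk, _ = foci_voxel_indices(
            grid, np.array([[row["peak_x"], row["peak_y"], row["peak_z"]]])
        )
        i, j, k = peak_ijk[0]
        retained[int(row["label"])] = bool(surv_dil[i, j, k])
    return FailsafeResult(
        original, augmented, proportion, n_noise, retained, noise_exps
    )
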