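"""Synthetic foci databases, ROI masks, and gradient volumes with known truth.

Emulates the structure of a curated coordinate database: experiments
labelled with paradigm classes, each with a subject count and a set of 3-D
activation foci.  Designated "signal" paradigms concentrate a fraction of
their foci around planted activation centres inside the brain; the rest of
the foci — and all foci of background paradigms — are uniform over the
brain mask.  Ground truth (centres, the designated network-associated
paradigm subset, gradient mixing matrix) is returned alongside, so every
downstream stage can be tested for recovery.

Count models: foci per experiment follow a shifted negative binomial
(heavy-tailed, mean about 10, matching typical per-paradigm totals of
roughly ten foci per experiment in published databases); subject counts
follow a discretised log-normal with median about 15.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .foci_io import BrainGrid, Experiment, FociDataset, Focus, Volume

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "generate_database",
    "generate_masks",
    "generate_gradients",
    "generate_all",
    "default_config",
]


@dataclass
class SynthConfig:
    # grid
    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size: float = 4.0
    # database structure
    n_paradigms: int = 10
    experiments_per_paradigm: int = 30
    foci_mean: float = 10.0
    foci_dispersion: float = 2.0  # negative-binomial size parameter
    subjects_median: float = 15.0
    subjects_log_sd: float = 0.4
    # planted signal
    planted_centers: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=dict
    )
    jitter_sd: float = 8.0  # mm, isotropic Gaussian around a planted centre
    background: float = 0.3  # fraction of a signal paradigm's foci that are uniform
    # masks
    roi_center: tuple[float, float, float] = (0.0, -20.0, 20.0)
    roi_fraction: float = 0.1
    roi_offsets: tuple[tuple[float, float, float], ...] = (
        (0.0, 0.0, 0.0),
        (6.0, 4.0, -4.0),
        (-6.0, 6.0, 4.0),
    )
    n_rsn_labels: int = 5
    # gradients
    n_gradients: int = 2
    gradient_mixing: np.ndarray | None = None
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "voxel_size",
            "foci_mean",
            "foci_dispersion",
            "subjects_median",
            "subjects_log_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if not (0.0 <= self.background <= 1.0):
            raise ValueError("background fraction must lie in [0, 1]")
        if self.roi_fraction >= 1.0 or self.roi_fraction <= 0.0:
            raise ValueError("roi_fraction must lie in (0, 1)")
        if self.n_paradigms < max(1, len(self.planted_centers)):
            raise ValueError("n_paradigms smaller than the planted paradigm count")
        if self.experiments_per_paradigm < 1:
            raise ValueError("experiments_per_paradigm must be >= 1")

    def make_grid(self) -> BrainGrid:
        return BrainGrid.create(self.grid_shape, self.voxel_size)

    def paradigm_names(self) -> list[str]:
        names = list(self.planted_centers)
        i = 1
        while len(names) < self.n_paradigms:
            cand = f"Background-{i:02d}"
            if cand not in names:
                names.append(cand)
            i += 1
        return names

    def effective_mixing(self) -> np.ndarray:
        if self.gradient_mixing is not None:
            return np.asarray(self.gradient_mixing, dtype=float)
        return np.eye(self.n_gradients, _N_BASIS)[:, :_N_BASIS]


@dataclass
class SynthTruth:
    centers: dict[str, list[tuple[float, float, float]]]
    dmn_paradigms: list[str]  # the designated network-associated subset
    center_mask_membership: dict[str, list[list[bool]]]  # paradigm -> per-centre per-mask
    mixing: np.ndarray

    def __post_init__(self) -> None:
        if not self.dmn_paradigms:
            raise ValueError("designated paradigm subset must be non-empty")


def default_config(**overrides) -> SynthConfig:
    """Study-like defaults: four network-associated paradigms with centres
    planted inside the ROI neighbourhood, plus background paradigms."""
    # centres sit on voxel centres of the default 4 mm grid, inside the
    # ROI neighbourhood around roi_center, so the designated paradigms are
    # recoverable by the ROI-association stage
    centers = {
        "Social-Inference": [(2.0, -22.0, 26.0), (2.0, 10.0, 14.0)],
        "Episodic-Recall": [(-6.0, -26.0, 22.0)],
        "Self-Reflection": [(6.0, -2.0, 30.0)],
        "Rest-Deactivation": [(2.0, -18.0, 26.0), (-2.0, 6.0, 18.0)],
    }
    cfg = SynthConfig(planted_centers=centers)
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# Database


def _draw_n_foci(rng: np.random.Generator, cfg: SynthConfig, size: int) -> np.ndarray:
    # shifted negative binomial: 1 + NB(r, p) with mean foci_mean
    mean_excess = max(cfg.foci_mean - 1.0, 1e-9)
    r = cfg.foci_dispersion
    p = r / (r + mean_excess)
    return 1 + rng.negative_binomial(r, p, size=size)


def _draw_n_subjects(rng: np.random.Generator, cfg: SynthConfig, size: int) -> np.ndarray:
    raw = rng.lognormal(mean=math.log(cfg.subjects_median), sigma=cfg.subjects_log_sd, size=size)
    return np.maximum(1, np.round(raw).astype(int))


def _uniform_foci(rng: np.random.Generator, grid: BrainGrid, n: int) -> np.ndarray:
    """Uniform in-brain foci at voxel centres, as (n, 3) mm coordinates."""
    idx = grid.mask_indices()
    sel = rng.integers(0, len(idx), size=n)
    return np.atleast_2d(grid.voxel_to_mm(idx[sel].astype(float)))


def _planted_focus(
    rng: np.random.Generator,
    grid: BrainGrid,
    centers: np.ndarray,
    jitter_sd: float,
) -> np.ndarray:
    c = centers[rng.integers(0, len(centers))]
    if jitter_sd == 0.0:
        return c.copy()
    for _ in range(200):
        mm = c + rng.normal(0.0, jitter_sd, size=3)
        vox = np.floor(grid.mm_to_voxel_continuous(mm) + 0.5).astype(int)
        if grid.in_grid(vox[None, :])[0] and grid.mask[tuple(vox)]:
            return mm
    return c.copy()  # extremely tight mask: fall back to the centre itself


def generate_database(config: SynthConfig) -> tuple[FociDataset, SynthTruth]:
    """Generate a labelled foci database with planted activation centres.

    Deterministic given ``config.seed``.  Signal paradigms draw each focus
    from a planted centre plus isotropic Gaussian jitter with probability
    ``1 - background``, otherwise uniformly over the brain mask.
    """
    config.validate()
    grid = config.make_grid()
    for par, centers in config.planted_centers.items():
        for c in centers:
            vox = np.floor(grid.mm_to_voxel_continuous(np.asarray(c, float)) + 0.5).astype(int)
            if not grid.in_grid(vox[None, :])[0] or not grid.mask[tuple(vox)]:
                raise ValueError(
                    f"planted centre {c} of paradigm {par!r} is outside the brain mask"
                )

    rng = np.random.default_rng(config.seed)
    experiments: list[Experiment] = []
    names = config.paradigm_names()
    for par in names:
        centers = np.asarray(config.planted_centers.get(par, []), dtype=float)
        is_signal = len(centers) > 0
        n_exp = config.experiments_per_paradigm
        n_foci_arr = _draw_n_foci(rng, config, n_exp)
        n_subj_arr = _draw_n_subjects(rng, config, n_exp)
        for i in range(n_exp):
            n_foci = int(n_foci_arr[i])
            mm_rows = []
            for _ in range(n_foci):
                if is_signal and rng.random() >= config.background:
                    mm_rows.append(_planted_focus(rng, grid, centers, config.jitter_sd))
                else:
                    mm_rows.append(_uniform_foci(rng, grid, 1)[0])
            study = f"{par} study {i + 1:03d}, 2020"
            experiments.append(
                Experiment(
                    study=study,
                    contrast="main effect",
                    n_subjects=int(n_subj_arr[i]),
                    foci=[Focus(*row) for row in mm_rows],
                    paradigm=par,
                    group=study,
                )
            )

    dataset = FociDataset(experiments=experiments, space="Talairach")
    _, rois, _ = generate_masks(config)
    membership = {
        par: [
            [bool(r.data[tuple(np.floor(grid.mm_to_voxel_continuous(np.asarray(c, float)) + 0.5).astype(int))] > 0) for r in rois]
            for c in centers
        ]
        for par, centers in config.planted_centers.items()
    }
    truth = SynthTruth(
        centers={k: list(v) for k, v in config.planted_centers.items()},
        dmn_paradigms=list(config.planted_centers) or ["none"],
        center_mask_membership=membership,
        mixing=config.effective_mixing(),
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Masks and parcellation


def generate_masks(config: SynthConfig) -> tuple[Volume, list[Volume], Volume]:
    """Brain mask, three partially overlapping ROI masks, and a parcellation.

    The three ROIs are balls of identical volume (``roi_fraction`` of the
    brain) centred at ``roi_center`` plus the three configured offsets —
    three imperfectly agreeing definitions of the same network.  The
    parcellation assigns every in-brain voxel to one of ``n_rsn_labels``
    synthetic networks by nearest-seed (Voronoi) labelling.
    """
    config.validate()
    grid = config.make_grid()
    brain = Volume(grid, grid.mask.astype(float), name="brain")

    vol_brain_mm = grid.n_mask_voxels * float(np.prod(grid.voxel_sizes))
    radius = (3.0 * config.roi_fraction * vol_brain_mm / (4.0 * math.pi)) ** (1.0 / 3.0)
    mm = np.atleast_2d(grid.voxel_to_mm(grid.mask_indices().astype(float)))

    rois = []
    for i, off in enumerate(config.roi_offsets):
        c = np.asarray(config.roi_center, float) + np.asarray(off, float)
        inside = ((mm - c) ** 2).sum(axis=1) <= radius**2
        data = np.zeros(grid.shape)
        data[grid.mask] = inside.astype(float)
        rois.append(Volume(grid, data, name=f"roi{i + 1}"))

    rng = np.random.default_rng(config.seed + 1)
    seeds = mm[rng.choice(len(mm), size=config.n_rsn_labels, replace=False)]
    d2 = ((mm[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1) + 1
    lab_data = np.zeros(grid.shape)
    lab_data[grid.mask] = labels.astype(float)
    parcellation = Volume(grid, lab_data, name="rsn_labels")
    return brain, rois, parcellation


# ---------------------------------------------------------------------------
# Gradient volumes


_N_BASIS = 4


def _basis_fields(grid: BrainGrid) -> np.ndarray:
    """Low-order polynomial fields over the mask: zero mean, unit variance."""
    mm = np.atleast_2d(grid.voxel_to_mm(grid.mask_indices().astype(float)))
    half = np.abs(mm).max(axis=0)
    half[half == 0] = 1.0
    u = mm / half  # normalised coordinates in [-1, 1]
    fields = [u[:, 0], u[:, 2], u[:, 1] ** 2, u[:, 0] * u[:, 1]]
    out = []
    for f in fields:
        f = f - f.mean()
        sd = f.std()
        if sd == 0:
            raise ValueError("degenerate basis field (zero variance)")
        out.append(f / sd)
    return np.vstack(out)  # (_N_BASIS, n_voxels)


def mix_basis_fields(fields: np.ndarray, mixing: np.ndarray, grid: BrainGrid) -> list[Volume]:
    """Mix flat basis fields into gradient volumes; zero-mean over the mask."""
    fields = np.asarray(fields, dtype=float)
    if np.any(fields.std(axis=1) == 0):
        raise ValueError("constant basis field (zero variance)")
    mixed = np.asarray(mixing, dtype=float) @ fields
    vols = []
    for g in range(mixed.shape[0]):
        row = mixed[g] - mixed[g].mean()
        data = np.zeros(grid.shape)
        data[grid.mask] = row
        vols.append(Volume(grid, data, name=f"gradient{g + 1}"))
    return vols


def generate_gradients(config: SynthConfig) -> list[Volume]:
    """Smooth synthetic gradient volumes (mixed low-order polynomials)."""
    config.validate()
    grid = config.make_grid()
    mixing = config.effective_mixing()
    if mixing.shape[1] != _N_BASIS:
        raise ValueError(f"mixing matrix must have {_N_BASIS} columns")
    return mix_basis_fields(_basis_fields(grid), mixing, grid)


# ---------------------------------------------------------------------------


@dataclass
class SynthBundle:
    config: SynthConfig
    grid: BrainGrid
    dataset: FociDataset
    truth: SynthTruth
    brain: Volume
    rois: list[Volume]
    parcellation: Volume
    gradients: list[Volume]


def generate_all(config: SynthConfig) -> SynthBundle:
    dataset, truth = generate_database(config)
    brain, rois, parcellation = generate_masks(config)
    gradients = generate_gradients(config)
    return SynthBundle(
        config=config,
        grid=config.make_grid(),
        dataset=dataset,
        truth=truth,
        brain=brain,
        rois=rois,
        parcellation=parcellation,
        gradients=gradients,
    )
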