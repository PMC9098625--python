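"""Foci databases, the voxel-grid data model, and Sleuth text I/O.

The meta-analytic unit is the :class:`Experiment`: a labelled set of peak
activation coordinates (foci, in mm, Talairach-like space) reported by one
contrast of one study, together with the number of subjects scanned.  A
:class:`FociDataset` collects experiments; :class:`BrainGrid` and
:class:`Volume` carry everything voxel-wise (masks, ALE maps, component
score maps, gradients) on a regular isotropic grid with a NIfTI-style
affine.

Sleuth dialect
--------------
Plain text, comment lines start ``// ``::

    // Reference=Talairach
    // Smith, 2009: Task minus rest
    // Subjects=12
    -42.0 22.0 -8.0
    ...
    <blank line between experiment blocks>

Subject-group identity is carried by the study id (``Author, Year``):
contrasts of the same study are treated as measurements of the same group
and merged by :func:`merge_by_group` before ALE, so that one group of
subjects contributes a single set of foci.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Focus",
    "Experiment",
    "FociDataset",
    "BrainGrid",
    "Volume",
    "SleuthParseError",
    "read_sleuth",
    "write_sleuth",
    "merge_by_group",
    "mm_to_voxel",
    "voxel_to_mm",
    "foci_voxel_indices",
]


@dataclass(frozen=True)
class Focus:
    """A peak coordinate in millimetres."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Experiment:
    study: str
    contrast: str
    n_subjects: int
    foci: list[Focus]
    paradigm: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if not self.group:
            self.group = self.study
        if self.n_subjects < 1:
            raise ValueError(
                f"experiment {self.study!r}/{self.contrast!r}: n_subjects must be >= 1"
            )
        if len(self.foci) < 1:
            raise ValueError(
                f"experiment {self.study!r}/{self.contrast!r}: needs at least one focus"
            )

    @property
    def n_foci(self) -> int:
        return len(self.foci)

    def foci_array(self) -> np.ndarray:
        """Foci as an (n, 3) float array of mm coordinates."""
        return np.array([[f.x, f.y, f.z] for f in self.foci], dtype=float)


@dataclass
class FociDataset:
    experiments: list[Experiment] = field(default_factory=list)
    space: str = "Talairach"

    def __post_init__(self) -> None:
        keys = [(e.study, e.contrast) for e in self.experiments]
        if len(set(keys)) != len(keys):
            seen, dups = set(), set()
            for k in keys:
                (dups if k in seen else seen).add(k)
            raise ValueError(f"duplicate (study, contrast) pairs: {sorted(dups)}")

    def __len__(self) -> int:
        return len(self.experiments)

    def __iter__(self):
        return iter(self.experiments)

    @property
    def n_foci(self) -> int:
        return sum(e.n_foci for e in self.experiments)

    def paradigms(self) -> list[str]:
        """Distinct paradigm labels, in first-appearance order."""
        out: list[str] = []
        for e in self.experiments:
            if e.paradigm not in out:
                out.append(e.paradigm)
        return out

    def subset(self, paradigm: str) -> "FociDataset":
        exps = [e for e in self.experiments if e.paradigm == paradigm]
        return FociDataset(experiments=exps, space=self.space)


class BrainGrid:
    """A regular voxel grid with affine and boolean brain mask.

    Voxel indices are 0-based; mm space is authoritative.  The affine maps
    homogeneous voxel indices to mm, NIfTI convention.
    """

    def __init__(self, shape: tuple[int, int, int], affine: np.ndarray, mask: np.ndarray):
        self.shape = tuple(int(s) for s in shape)
        self.affine = np.asarray(affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        self.inv_affine = np.linalg.inv(self.affine)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.shape:
            raise ValueError("mask shape does not match grid shape")
        if not mask.any():
            raise ValueError("brain mask is empty")
        self.mask = mask

    @classmethod
    def create(
        cls,
        shape: tuple[int, int, int] = (40, 48, 40),
        voxel_size: float = 4.0,
        mask: np.ndarray | None = None,
    ) -> "BrainGrid":
        """Build a centred isotropic grid; default mask = inscribed ellipsoid."""
        shape = tuple(int(s) for s in shape)
        affine = np.eye(4)
        affine[0, 0] = affine[1, 1] = affine[2, 2] = float(voxel_size)
        # centre of the grid sits at mm (0, 0, 0)
        centre_vox = (np.array(shape) - 1) / 2.0
        affine[:3, 3] = -centre_vox * voxel_size
        if mask is None:
            idx = np.indices(shape).reshape(3, -1).T
            semi = np.array(shape) / 2.0
            mask = (((idx - centre_vox) / semi) ** 2).sum(axis=1) <= 1.0
            mask = mask.reshape(shape)
        return cls(shape, affine, mask)

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    def mask_indices(self) -> np.ndarray:
        """(n, 3) integer indices of in-mask voxels, C order."""
        return np.argwhere(self.mask)

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        mm = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return mm.squeeze()

    def mm_to_voxel_continuous(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        vox = xyz @ self.inv_affine[:3, :3].T + self.inv_affine[:3, 3]
        return vox.squeeze()

    def in_grid(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk))
        ok = np.ones(len(ijk), dtype=bool)
        for ax in range(3):
            ok &= (ijk[:, ax] >= 0) & (ijk[:, ax] < self.shape[ax])
        return ok

    def new_volume(self, data: np.ndarray | None = None) -> "Volume":
        if data is None:
            data = np.zeros(self.shape, dtype=float)
        return Volume(self, data)


class Volume:
    """One scalar per voxel on a :class:`BrainGrid`."""

    def __init__(self, grid: BrainGrid, data: np.ndarray, name: str = ""):
        data = np.asarray(data, dtype=float)
        if data.shape != grid.shape:
            raise ValueError(f"data shape {data.shape} != grid shape {grid.shape}")
        if not np.isfinite(data[grid.mask]).all():
            raise ValueError("non-finite values inside the brain mask")
        self.grid = grid
        self.data = data
        self.name = name

    def masked(self) -> np.ndarray:
        """In-mask values as a flat vector (C order of mask indices)."""
        return self.data[self.grid.mask]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float64), self.grid.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, grid: BrainGrid | None = None, name: str = "") -> "Volume":
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        if grid is None:
            grid = BrainGrid(data.shape, img.affine, np.isfinite(data))
        return cls(grid, data, name=name)


# ---------------------------------------------------------------------------
# Sleuth text format


class SleuthParseError(ValueError):
    pass


def read_sleuth(stream, paradigm: str = "") -> FociDataset:
    """Parse a Sleuth text export into a :class:`FociDataset`.

    ``stream`` may be a file-like object or a string.  All experiments get
    the given paradigm label (Sleuth exports are one file per query).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    space = "Talairach"
    experiments: list[Experiment] = []
    header: tuple[str, str] | None = None
    n_subjects: int | None = None
    coords: list[Focus] = []

    def flush(lineno: int) -> None:
        nonlocal header, n_subjects, coords
        if header is None and not coords:
            return
        if header is None:
            raise SleuthParseError(f"coordinate rows without a header near line {lineno}")
        study, contrast = header
        if n_subjects is None:
            raise SleuthParseError(
                f"block {study!r}: {contrast!r} has no '// Subjects=N' line"
            )
        if not coords:
            raise SleuthParseError(f"block {study!r}: {contrast!r} has no coordinates")
        experiments.append(
            Experiment(
                study=study,
                contrast=contrast,
                n_subjects=n_subjects,
                foci=coords,
                paradigm=paradigm,
            )
        )
        header, n_subjects, coords = None, None, []

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            flush(lineno)
            continue
        if line.startswith("//"):
            body = line[2:].strip()
            if body.startswith("Reference="):
                space = body.split("=", 1)[1].strip()
            elif body.startswith("Subjects="):
                try:
                    n_subjects = int(body.split("=", 1)[1].strip())
                except ValueError as exc:
                    raise SleuthParseError(
                        f"line {lineno}: malformed Subjects line: {line!r}"
                    ) from exc
            else:
                if header is not None:
                    flush(lineno)
                if ":" in body:
                    study, contrast = body.split(":", 1)
                    header = (study.strip(), contrast.strip())
                else:
                    header = (body, "")
        else:
            parts = line.split()
            if len(parts) != 3:
                raise SleuthParseError(
                    f"line {lineno}: expected 'x y z', got {line!r}"
                )
            try:
                x, y, z = (float(p) for p in parts)
            except ValueError as exc:
                raise SleuthParseError(
                    f"line {lineno}: non-numeric coordinate row {line!r}"
                ) from exc
            coords.append(Focus(x, y, z))
    flush(-1)
    return FociDataset(experiments=experiments, space=space)


def _fmt(v: float) -> str:
    # fixed two decimals: round-trips exactly through float parsing
    return f"{v:.2f}"


def write_sleuth(dataset: FociDataset, stream=None) -> str:
    """Serialize a dataset to Sleuth text; returns the text.

    ``write_sleuth(read_sleuth(t)) == t`` for text produced by this writer.
    """
    lines = [f"// Reference={dataset.space}", ""]
    for e in dataset.experiments:
        lines.append(f"// {e.study}: {e.contrast}" if e.contrast else f"// {e.study}")
        lines.append(f"// Subjects={e.n_subjects}")
        for f in e.foci:
            lines.append(f"{_fmt(f.x)} {_fmt(f.y)} {_fmt(f.z)}")
        lines.append("")
    text = "\n".join(lines)
    if not text.endswith("\n"):
        text += "\n"
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# Group merging


def merge_by_group(dataset: FociDataset) -> FociDataset:
    """Merge contrasts computed on the same subject group into one experiment.

    Foci are concatenated (duplicates kept); the merged experiment keeps the
    group's subject count.  Idempotent; conserves the total focus count.
    """
    order: list[str] = []
    by_group: dict[str, list[Experiment]] = {}
    for e in dataset.experiments:
        if e.group not in by_group:
            by_group[e.group] = []
            order.append(e.group)
        by_group[e.group].append(e)

    merged: list[Experiment] = []
    for g in order:
        exps = by_group[g]
        ns = {e.n_subjects for e in exps}
        if len(ns) > 1:
            raise ValueError(
                f"group {g!r} has conflicting subject counts {sorted(ns)}"
            )
        if len(exps) == 1:
            merged.append(exps[0])
            continue
        foci = [f for e in exps for f in e.foci]
        contrast = " + ".join(e.contrast for e in exps)
        merged.append(
            Experiment(
                study=exps[0].study,
                contrast=contrast,
                n_subjects=exps[0].n_subjects,
                foci=foci,
                paradigm=exps[0].paradigm,
                group=g,
            )
        )
    return FociDataset(experiments=merged, space=dataset.space)


# ---------------------------------------------------------------------------
# mm <-> voxel


def mm_to_voxel(grid: BrainGrid, focus: Focus | np.ndarray) -> tuple[int, int, int]:
    """Nearest-voxel index of a mm coordinate (half-up rounding on ties)."""
    xyz = focus.as_array() if isinstance(focus, Focus) else np.asarray(focus, float)
    cont = grid.mm_to_voxel_continuous(xyz)
    ijk = np.floor(cont + 0.5).astype(int)
    return (int(ijk[0]), int(ijk[1]), int(ijk[2]))


def voxel_to_mm(grid: BrainGrid, ijk) -> np.ndarray:
    return grid.voxel_to_mm(np.asarray(ijk, dtype=float))


def foci_voxel_indices(
    grid: BrainGrid, foci: list[Focus] | np.ndarray
) -> tuple[np.ndarray, int]:
    """Map foci to voxel indices, dropping out-of-grid foci with a warning.

    Returns ``(indices, n_dropped)`` where indices is (n_kept, 3) int.
    """
    if isinstance(foci, np.ndarray):
        mm = np.atleast_2d(foci)
    else:
        mm = np.array([[f.x, f.y, f.z] for f in foci], dtype=float)
    cont = np.atleast_2d(grid.mm_to_voxel_continuous(mm))
    ijk = np.floor(cont + 0.5).astype(int)
    ok = grid.in_grid(ijk)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%d focus/foci outside the grid were dropped", n_dropped)
    return ijk[ok], n_dropped
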