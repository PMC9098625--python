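"""Paradigm-ROI association testing.

Given the foci of one task paradigm and a region of interest (ROI), the
question is whether the paradigm's reported activations are denser inside
the ROI than expected if they were spread uniformly across the brain.
Under that uniform null the in-ROI focus count k is Binomial(N, p) with
p the ROI's share of in-brain voxels, and the density statistic is the
normal-approximation z-score

    z = (k - N p) / sqrt(N p (1 - p)),

one-sided: large z means denser than chance.  Profiles over all paradigms
are thresholded at a Bonferroni-style cutoff (default z* = 3.3), and a
consensus rule keeps the paradigms significant for at least k of several
alternative ROI definitions of the same network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .foci_io import BrainGrid, FociDataset, Focus, foci_voxel_indices

logger = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = 3.3

__all__ = [
    "ParadigmProfile",
    "roi_density_z",
    "paradigm_profile",
    "consensus_paradigms",
    "DEFAULT_Z_THRESHOLD",
]


@dataclass
class ParadigmProfile:
    """Per-paradigm density z-scores for one ROI, sorted by descending z."""

    roi_name: str
    table: pd.DataFrame  # columns: paradigm, k, N, z, significant
    z_threshold: float

    def significant_paradigms(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "paradigm"])

    @classmethod
    def from_scores(
        cls,
        roi_name: str,
        scores: list[tuple[str, float]],
        z_threshold: float = DEFAULT_Z_THRESHOLD,
    ) -> "ParadigmProfile":
        """Build a profile from externally published (paradigm, z) rows.

        Count columns are not available in that case and are set to -1.
        """
        df = pd.DataFrame(
            {
                "paradigm": [s[0] for s in scores],
                "k": -1,
                "N": -1,
                "z": [float(s[1]) for s in scores],
            }
        )
        df["significant"] = df["z"] > z_threshold
        df = df.sort_values("z", ascending=False, kind="stable").reset_index(drop=True)
        return cls(roi_name=roi_name, table=df, z_threshold=z_threshold)

    def save(self, path) -> None:
        df = self.table.copy()
        df.insert(0, "roi", self.roi_name)
        df.to_csv(path, sep="\t", index=False)


def _count_in_mask(grid: BrainGrid, foci, mask: np.ndarray) -> tuple[int, int]:
    """(in-mask count, in-brain count) for a list/array of foci."""
    ijk, _ = foci_voxel_indices(grid, foci)
    if len(ijk) == 0:
        return 0, 0
    in_brain = grid.mask[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
    ijk = ijk[in_brain]
    if len(ijk) == 0:
        return 0, 0
    k = int(mask[ijk[:, 0], ijk[:, 1], ijk[:, 2]].sum())
    return k, len(ijk)


def roi_density_z(
    foci,
    roi_mask: np.ndarray,
    grid: BrainGrid,
    continuity_correction: bool = False,
) -> float:
    """Density z-score of a focus set inside an ROI versus the uniform null.

    Parameters
    ----------
    foci : list of Focus or (n, 3) mm array
    roi_mask : boolean array on the grid; must be a subset of the brain mask.
    continuity_correction : subtract 0.5 from the count deviation (off by
        default so that k = Np gives exactly z = 0).

    Foci falling outside the brain mask are excluded from both k and N.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != grid.shape:
        raise ValueError("ROI mask shape does not match grid")
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    if (roi_mask & ~grid.mask).any():
        raise ValueError("ROI mask extends outside the brain mask")
    n_roi = int(roi_mask.sum())
    n_brain = grid.n_mask_voxels
    p = n_roi / n_brain
    if p >= 1.0:
        raise ValueError("ROI covers the whole brain mask; null is degenerate")
    k, n = _count_in_mask(grid, foci, roi_mask)
    if n == 0:
        raise ValueError("no in-brain foci")
    dev = k - n * p
    if continuity_correction:
        dev -= 0.5 * np.sign(dev)
    return float(dev / np.sqrt(n * p * (1.0 - p)))


def paradigm_profile(
    dataset: FociDataset,
    roi_mask: np.ndarray,
    grid: BrainGrid,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    roi_name: str = "roi",
    continuity_correction: bool = False,
) -> ParadigmProfile:
    """Density z for every paradigm class in the dataset against one ROI."""
    paradigms = dataset.paradigms()
    if not paradigms:
        raise ValueError("dataset has no paradigms")
    rows = []
    for par in paradigms:
        foci = [f for e in dataset.subset(par) for f in e.foci]
        roi_arr = np.asarray(roi_mask, dtype=bool)
        k, n = _count_in_mask(grid, foci, roi_arr)
        z = roi_density_z(foci, roi_arr, grid, continuity_correction)
        rows.append({"paradigm": par, "k": k, "N": n, "z": z})
    df = pd.DataFrame(rows)
    df["significant"] = df["z"] > z_threshold
    df = df.sort_values("z", ascending=False, kind="stable").reset_index(drop=True)
    return ParadigmProfile(roi_name=roi_name, table=df, z_threshold=z_threshold)


def consensus_paradigms(profiles: list[ParadigmProfile], k: int = 2) -> list[str]:
    """Paradigms significant in at least ``k`` of the given profiles.

    Returned deduplicated, ordered by the maximum z reached across profiles
    (descending; ties broken by label for stability).
    """
    if k < 1 or k > len(profiles):
        raise ValueError(f"k={k} out of range for {len(profiles)} profiles")
    counts: dict[str, int] = {}
    max_z: dict[str, float] = {}
    for prof in profiles:
        for _, row in prof.table.iterrows():
            lab = row["paradigm"]
            z = float(row["z"])
            max_z[lab] = max(max_z.get(lab, -np.inf), z)
            if row["significant"]:
                counts[lab] = counts.get(lab, 0) + 1
    hits = [lab for lab, c in counts.items() if c >= k]
    return sorted(hits, key=lambda lab: (-max_z[lab], lab))
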