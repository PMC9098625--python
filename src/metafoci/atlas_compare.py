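"""Comparison of result maps with parcellations and gradient volumes.

Covers: per-map resting-state-network (RSN) voxel proportions against a
label parcellation, Jaccard overlap between binary maps, brain-masked
Pearson correlation with gradient volumes, a one-tailed Welch t-test of
gradient values inside versus outside a map's positive support, percentage
of positive-map voxels overlapping the gradient's positive voxels, and the
correlation between an MDS axis and the maps' gradient correlations.

Voxel-wise tests carry no spatial-autocorrelation correction; with tens of
thousands of spatially smooth voxels the nominal p-values are
anti-conservative and should be read as descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .foci_io import BrainGrid, Volume

__all__ = [
    "ComparisonReport",
    "rsn_proportions",
    "jaccard",
    "masked_correlation",
    "positive_part_ttest",
    "positive_overlap_percent",
    "axis_gradient_correlation",
    "compare_maps",
]


def rsn_proportions(binary_map: np.ndarray, parcellation: np.ndarray) -> dict:
    """Fraction of a binary map's positive voxels falling in each label.

    Label 0 is treated as outside the parcellation; its share is reported
    under the key ``"unassigned"``.
    """
    binary_map = np.asarray(binary_map, dtype=bool)
    labels = np.asarray(parcellation)
    if binary_map.shape != labels.shape:
        raise ValueError("map and parcellation are on different grids")
    n = int(binary_map.sum())
    if n == 0:
        raise ValueError("empty map")
    vals = labels[binary_map].astype(int)
    out: dict = {}
    for lab in np.unique(vals):
        frac = float((vals == lab).sum()) / n
        out["unassigned" if lab == 0 else int(lab)] = frac
    return out


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary voxel sets."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("shapes differ")
    union = (a | b).sum()
    if union == 0:
        raise ValueError("both sets are empty")
    return float((a & b).sum() / union)


def masked_correlation(map_vol: Volume, gradient: Volume, mask: np.ndarray) -> float:
    """Pearson r between two volumes over the in-mask voxels only."""
    mask = np.asarray(mask, dtype=bool)
    x = map_vol.data[mask]
    y = gradient.data[mask]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance inside the mask")
    return float(np.corrcoef(x, y)[0, 1])


def positive_part_ttest(
    map_vol: Volume, gradient: Volume, mask: np.ndarray
) -> tuple[float, float]:
    """Welch t-test: gradient inside vs outside the map's positive support.

    One-tailed alternative 'inside > outside'.  The positive support must
    be a non-empty proper subset of the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    pos = (map_vol.data > 0) & mask
    if not pos.any():
        raise ValueError("map has no positive voxels inside the mask")
    rest = mask & ~pos
    if not rest.any():
        raise ValueError("map is positive over the whole mask")
    inside = gradient.data[pos]
    outside = gradient.data[rest]
    if inside.std() == 0 and outside.std() == 0:
        raise ValueError("gradient has zero variance in both groups")
    res = stats.ttest_ind(inside, outside, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def positive_overlap_percent(map_vol: Volume, gradient: Volume) -> float:
    """Percent of the map's positive voxels where the gradient is positive."""
    pos_map = map_vol.data > 0
    n = int(pos_map.sum())
    if n == 0:
        raise ValueError("map has no positive voxels")
    overlap = int((pos_map & (gradient.data > 0)).sum())
    return 100.0 * overlap / n


def axis_gradient_correlation(
    axis_coordinates: np.ndarray,
    map_gradient_correlations: np.ndarray,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Correlation between maps' MDS-axis coordinates and their gradient r.

    p-value from the t transform t = r * sqrt((n-2)/(1-r^2)) with n-2 df;
    ``alternative`` in {"two-sided", "greater", "less"} sets the tail.
    """
    x = np.asarray(axis_coordinates, dtype=float)
    y = np.asarray(map_gradient_correlations, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need at least three paired values")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    if alternative == "two-sided":
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    elif alternative == "greater":
        p = stats.t.sf(t, n - 2)
    elif alternative == "less":
        p = stats.t.cdf(t, n - 2)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return r, float(p)


@dataclass
class ComparisonReport:
    """Bundle of map-vs-atlas and map-vs-gradient summaries."""

    rsn_table: pd.DataFrame  # map, label, proportion
    jaccard_table: pd.DataFrame  # map, label, jaccard
    gradient_table: pd.DataFrame  # map, gradient, r, t, p_one_tailed, overlap_pct
    axis_results: dict = field(default_factory=dict)
    caveats: list[str] = field(
        default_factory=lambda: [
            "voxel-wise tests assume independent voxels; spatial smoothness "
            "makes nominal p-values anti-conservative"
        ]
    )

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.rsn_table.to_csv(d / "rsn_proportions.tsv", sep="\t", index=False)
        self.jaccard_table.to_csv(d / "jaccard.tsv", sep="\t", index=False)
        self.gradient_table.to_csv(d / "gradient_comparison.tsv", sep="\t", index=False)


def compare_maps(
    maps: dict[str, Volume],
    parcellation: Volume,
    gradients: dict[str, Volume],
    grid: BrainGrid,
) -> ComparisonReport:
    """Run the full comparison suite on a named set of maps."""
    rsn_rows, jac_rows, grad_rows = [], [], []
    labels = parcellation.data.astype(int)
    for name, vol in maps.items():
        pos = (vol.data > 0) & grid.mask
        if pos.any():
            for lab, frac in rsn_proportions(pos, labels).items():
                rsn_rows.append({"map": name, "label": lab, "proportion": frac})
            for lab in np.unique(labels[labels > 0]):
                jac_rows.append(
                    {
                        "map": name,
                        "label": int(lab),
                        "jaccard": jaccard(pos, (labels == lab) & grid.mask),
                    }
                )
        for gname, gvol in gradients.items():
            r = masked_correlation(vol, gvol, grid.mask)
            try:
                t, p = positive_part_ttest(vol, gvol, grid.mask)
            except ValueError:
                t, p = np.nan, np.nan
            try:
                pct = positive_overlap_percent(vol, gvol)
            except ValueError:
                pct = np.nan
            grad_rows.append(
                {
                    "map": name,
                    "gradient": gname,
                    "r": r,
                    "t": t,
                    "p_one_tailed": p,
                    "overlap_pct": pct,
                }
            )
    return ComparisonReport(
        rsn_table=pd.DataFrame(rsn_rows),
        jaccard_table=pd.DataFrame(jac_rows),
        gradient_table=pd.DataFrame(grad_rows),
    )
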