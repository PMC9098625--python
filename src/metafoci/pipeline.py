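"""End-to-end orchestration of the meta-analytic study replica.

Stages: synthetic database generation -> paradigm-ROI association profiles
for three network masks -> multi-mask consensus -> per-paradigm ALE with
cluster-level FWE -> fail-safe robustness -> decomposition of the map set
(MDS, PCA, ICA) -> comparison with the parcellation and gradient volumes.
Every stochastic stage has its own explicit seed; given one configuration
the run is bit-reproducible and every intermediate artifact is written to
the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ale import AleResult, KernelSpec, cluster_fwe, failsafe
from .atlas_compare import axis_gradient_correlation, compare_maps, masked_correlation
from .decomposition import (
    correlation_distance,
    ica_decompose,
    align_components,
    mds_embed,
    pca_decompose,
    sampling_adequacy,
    vectorize_maps,
)
from .foci_io import FociDataset, Volume, merge_by_group, write_sleuth
from .paradigm_analysis import consensus_paradigms, paradigm_profile
from .synthetic_data import SynthConfig, default_config, generate_all

logger = logging.getLogger(__name__)

MIN_EXPERIMENTS = 17

__all__ = ["PipelineConfig", "run_pipeline", "min_experiment_guard"]


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=default_config)
    consensus_k: int = 2
    z_threshold: float = 3.3
    kernel: KernelSpec = field(default_factory=KernelSpec)
    cfp: float = 0.001
    alpha: float = 0.05
    n_perm: int = 200
    bin_width: float = 1e-5
    failsafe_proportions: tuple[float, ...] = (0.06, 0.60)
    decomposition_k: int = 4
    mds_dims: int = 3
    drop_smallest_check: bool = False
    seed_ale: int = 11
    seed_failsafe: int = 12
    seed_ica: int = 13

    def validate(self) -> None:
        self.synth.validate()
        if not (0 < self.cfp < 1) or not (0 < self.alpha <= 1):
            raise ValueError("thresholds must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**{
            **raw.pop("synth", {}),
        }) if "synth" in raw else default_config()
        if synth.planted_centers:
            synth.planted_centers = {
                k: [tuple(c) for c in v] for k, v in synth.planted_centers.items()
            }
        kernel = KernelSpec(**raw.pop("kernel", {}))
        cfg = cls(synth=synth, kernel=kernel)
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown pipeline option {k!r}")
            setattr(cfg, k, tuple(v) if isinstance(v, list) else v)
        cfg.validate()
        return cfg


def min_experiment_guard(dataset: FociDataset, minimum: int = MIN_EXPERIMENTS) -> list[str]:
    """Flag paradigms whose merged experiment count is below ``minimum``.

    The analysis proceeds for flagged paradigms; the warning propagates to
    the report.
    """
    warnings = []
    for par in dataset.paradigms():
        n = len(dataset.subset(par))
        if n == 0:
            logger.error("paradigm %r has no experiments; skipped", par)
            warnings.append(f"{par}: 0 experiments (skipped)")
        elif n < minimum:
            msg = f"{par}: only {n} merged experiments (< {minimum} recommended)"
            logger.warning(msg)
            warnings.append(msg)
    return warnings


def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", name).strip("_")


def _config_dict(cfg: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    return convert(cfg)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages and write a report bundle; returns a summary dict."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "warnings": []}

    # --- stage 1: synthetic data -------------------------------------------
    bundle = generate_all(config.synth)
    grid = bundle.grid
    ds_dir = out / "dataset"
    ds_dir.mkdir(exist_ok=True)
    for par in bundle.dataset.paradigms():
        (ds_dir / f"{_slug(par)}.txt").write_text(
            write_sleuth(bundle.dataset.subset(par))
        )
    mask_dir = out / "masks"
    mask_dir.mkdir(exist_ok=True)
    bundle.brain.save(mask_dir / "brain.nii")
    for i, roi in enumerate(bundle.rois):
        roi.save(mask_dir / f"roi{i + 1}.nii")
    bundle.parcellation.save(mask_dir / "rsn_labels.nii")
    grad_dir = out / "gradients"
    grad_dir.mkdir(exist_ok=True)
    for i, g in enumerate(bundle.gradients):
        g.save(grad_dir / f"gradient{i + 1}.nii")
    truth_rows = [
        {"paradigm": par, "x": c[0], "y": c[1], "z": c[2]}
        for par, cs in bundle.truth.centers.items()
        for c in cs
    ]
    pd.DataFrame(truth_rows).to_csv(out / "truth_centers.tsv", sep="\t", index=False)

    # --- stage 2: merge + paradigm analysis --------------------------------
    merged = merge_by_group(bundle.dataset)
    prof_dir = out / "profiles"
    prof_dir.mkdir(exist_ok=True)
    profiles = []
    for i, roi in enumerate(bundle.rois):
        prof = paradigm_profile(
            merged,
            roi.data > 0,
            grid,
            z_threshold=config.z_threshold,
            roi_name=f"roi{i + 1}",
        )
        prof.save(prof_dir / f"roi{i + 1}.tsv")
        profiles.append(prof)

    consensus = consensus_paradigms(profiles, k=config.consensus_k)
    (out / "consensus.txt").write_text("\n".join(consensus) + "\n")
    summary["consensus"] = consensus
    if not consensus:
        logger.warning("empty consensus: no paradigm is significant in "
                       ">= %d masks; stopping after paradigm analysis",
                       config.consensus_k)
        summary["warnings"].append("empty consensus; downstream stages skipped")
        _write_manifest(out, config, summary)
        return summary

    summary["warnings"] += min_experiment_guard(
        FociDataset(
            [e for e in merged if e.paradigm in consensus], space=merged.space
        )
    )

    # --- stage 3: per-paradigm ALE + fail-safe ------------------------------
    ale_dir = out / "ale"
    ale_dir.mkdir(exist_ok=True)
    results: dict[str, AleResult] = {}
    failsafe_rows = []
    for idx, par in enumerate(consensus):
        sub = merged.subset(par)
        if len(sub) == 0:
            continue
        res = cluster_fwe(
            sub, grid, config.kernel,
            cfp=config.cfp, alpha=config.alpha, n_perm=config.n_perm,
            seed=config.seed_ale + idx, bin_width=config.bin_width,
        )
        results[par] = res
        pdir = ale_dir / _slug(par)
        pdir.mkdir(exist_ok=True)
        res.ale.save(pdir / "ale.nii")
        res.p.save(pdir / "p.nii")
        res.clusters.save(pdir / "clusters.nii")
        res.cluster_table.to_csv(pdir / "clusters.tsv", sep="\t", index=False)
        for prop in config.failsafe_proportions:
            fs = failsafe(
                sub, prop, grid, config.kernel,
                seed=config.seed_failsafe + idx,
                cfp=config.cfp, alpha=config.alpha, n_perm=config.n_perm,
                bin_width=config.bin_width, original=res,
            )
            for lab, kept in fs.retained.items():
                failsafe_rows.append(
                    {"paradigm": par, "proportion": prop, "cluster": lab,
                     "retained": bool(kept)}
                )
    if failsafe_rows:
        pd.DataFrame(failsafe_rows).to_csv(
            out / "failsafe_retention.tsv", sep="\t", index=False
        )
    summary["n_surviving_clusters"] = {
        par: res.n_clusters for par, res in results.items()
    }

    # --- stage 4: decomposition --------------------------------------------
    thresholded: dict[str, Volume] = {}
    for par, res in results.items():
        data = res.ale.data * res.cluster_mask()
        if data[grid.mask].std() > 0:
            thresholded[par] = Volume(grid, data, name=par)
        else:
            logger.warning("paradigm %r has an empty thresholded map; "
                           "excluded from decomposition", par)
    dec_dir = out / "decomposition"
    dec_dir.mkdir(exist_ok=True)
    if len(thresholded) < 3:
        logger.warning("fewer than 3 non-empty significant maps; "
                       "decomposition skipped")
        summary["warnings"].append("decomposition skipped (<3 usable maps)")
        _write_manifest(out, config, summary)
        return summary

    matrix = vectorize_maps(list(thresholded.values()), grid)
    d = correlation_distance(matrix)
    pd.DataFrame(d, index=matrix.names, columns=matrix.names).to_csv(
        dec_dir / "distance.tsv", sep="\t"
    )
    k = min(config.decomposition_k, matrix.n_maps)
    embeddings = {}
    for dims in sorted({2, config.mds_dims}):
        if dims >= matrix.n_maps:
            continue
        emb = mds_embed(d, dims=dims, names=matrix.names)
        embeddings[dims] = emb
        pd.DataFrame(
            emb.coordinates,
            index=matrix.names,
            columns=[f"axis{i + 1}" for i in range(dims)],
        ).to_csv(dec_dir / f"mds_{dims}d.tsv", sep="\t")
    pd.DataFrame(
        [{"dims": dims, "stress": emb.stress} for dims, emb in embeddings.items()]
    ).to_csv(dec_dir / "stress.tsv", sep="\t", index=False)
    summary["mds_stress"] = {dims: emb.stress for dims, emb in embeddings.items()}

    pca = pca_decompose(matrix, k)
    ica = align_components(ica_decompose(matrix, k, seed=config.seed_ica), pca)
    pd.DataFrame(
        pca.loadings, index=matrix.names,
        columns=[f"PC{i + 1}" for i in range(k)],
    ).to_csv(dec_dir / "pca_loadings.tsv", sep="\t")
    pd.DataFrame(
        ica.loadings, index=matrix.names,
        columns=[f"IC{i + 1}" for i in range(k)],
    ).to_csv(dec_dir / "ica_loadings.tsv", sep="\t")
    pd.DataFrame(
        {"component": [f"PC{i + 1}" for i in range(k)],
         "explained_variance_ratio": pca.explained_variance_ratio},
    ).to_csv(dec_dir / "explained_variance.tsv", sep="\t", index=False)
    for vol in pca.score_volumes() + ica.score_volumes():
        vol.save(dec_dir / f"{_slug(vol.name)}.nii")
    kmo, chi2, dof, p_b = sampling_adequacy(matrix)
    pd.DataFrame(
        [{"kmo": kmo, "bartlett_chi2": chi2, "df": dof, "p": p_b}]
    ).to_csv(dec_dir / "kmo_bartlett.tsv", sep="\t", index=False)
    summary["kmo"] = kmo
    summary["pca_explained_4"] = float(
        pca.explained_variance_ratio[: min(4, k)].sum()
    )

    if config.drop_smallest_check and matrix.n_maps > 3:
        sizes = {par: len(merged.subset(par)) for par in thresholded}
        drop = min(sizes, key=sizes.get)
        kept = [v for n, v in thresholded.items() if n != drop]
        sub_matrix = vectorize_maps(kept, grid)
        sub_pca = pca_decompose(sub_matrix, min(k, sub_matrix.n_maps))
        pd.DataFrame(
            sub_pca.loadings, index=sub_matrix.names,
            columns=[f"PC{i + 1}" for i in range(sub_pca.k)],
        ).to_csv(dec_dir / f"pca_loadings_without_{_slug(drop)}.tsv", sep="\t")

    # --- stage 5: comparison -----------------------------------------------
    ic_maps = {
        f"IC{i + 1}": vol for i, vol in enumerate(ica.score_volumes())
    }
    gradients = {g.name: g for g in bundle.gradients}
    report = compare_maps(
        {**thresholded, **ic_maps}, bundle.parcellation, gradients, grid
    )
    report.save(out / "compare")
    axis_rows = []
    emb = embeddings.get(config.mds_dims) or next(iter(embeddings.values()))
    for gname, gvol in gradients.items():
        rs = [
            masked_correlation(thresholded[n], gvol, grid.mask)
            for n in matrix.names
        ]
        r, p = axis_gradient_correlation(
            emb.coordinates[:, 0], np.array(rs), alternative="two-sided"
        )
        axis_rows.append({"gradient": gname, "r": r, "p": p})
    pd.DataFrame(axis_rows).to_csv(
        out / "compare" / "axis_correlation.tsv", sep="\t", index=False
    )
    summary["axis_correlation"] = {
        row["gradient"]: row["r"] for row in axis_rows
    }

    _write_manifest(out, config, summary)
    return summary


def _write_manifest(out: Path, config: PipelineConfig, summary: dict) -> None:
    manifest = {
        "package": "metafoci",
        "version": __version__,
        "config": _config_dict(config),
        "summary": {k: v for k, v in summary.items() if k != "version"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
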