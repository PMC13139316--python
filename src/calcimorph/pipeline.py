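"""Pipeline orchestration: simulate → segment → features → analyze.

Each stage reads and writes plain artifacts (NIfTI volumes, CSV tables)
under an output directory and records its parameters, seeds and input
digests in ``manifest.json`` so any run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import DependencyError
from .grids import ClusterLabelMap
from .io import (
    config_to_dict,
    read_label_map,
    read_volume,
    sha256_digest,
    write_label_map,
    write_volume,
)
from .morphometry import aggregate_plaques, compute_cluster_features
from .phantoms import CohortConfig, generate_cohort
from .segmentation import (
    label_components,
    morphological_clean,
    normalize_intensity,
    threshold_calcium,
)
from .stats import (
    DEFAULT_FEATURES,
    compare_fragmentation,
    correlation_matrix,
    fit_rcs_model,
    group_comparisons_frame,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

MODES = ("simulate", "segment", "features", "analyze", "all")


@dataclasses.dataclass
class SegmentationParams:
    clip_lo: float = -1024.0
    clip_hi: float = 3071.0
    threshold_hu: float = 130.0
    connectivity: int = 26
    min_volume_mm3: float = 1.0
    opening_radius_voxels: int = 0


@dataclasses.dataclass
class AnalysisParams:
    features: tuple[str, ...] = tuple(DEFAULT_FEATURES)
    n_boot: int = 1000
    knot_quantiles: tuple[float, float, float] = (0.10, 0.50, 0.90)
    influence_screen: bool = True
    seed: int = 7
    rcs_pairs: tuple[tuple[str, str], ...] = (
        ("eccentricity", "volume_mm3"),
        ("mu_hu", "volume_mm3"),
        ("compactness", "mu_hu"),
        ("eccentricity", "mu_hu"),
    )


@dataclasses.dataclass
class PipelineConfig:
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    segmentation: SegmentationParams = dataclasses.field(default_factory=SegmentationParams)
    analysis: AnalysisParams = dataclasses.field(default_factory=AnalysisParams)


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage '{stage}' needs {path.name}; run '{produced_by}' first"
        )
    return path


def run_pipeline(
    config: PipelineConfig | None = None,
    mode: str = "all",
    outdir: str | Path = "calcimorph_out",
    seed: int | None = None,
) -> dict:
    """Execute pipeline stages in order; returns the run manifest.

    ``seed`` overrides both the cohort seed (simulate) and the analysis
    seed, giving one knob for full reproducibility.  ``all`` on a
    synthetic configuration needs no external input.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    config = config if config is not None else PipelineConfig()
    if seed is not None:
        config = dataclasses.replace(
            config,
            cohort=dataclasses.replace(config.cohort, seed=int(seed)),
            analysis=dataclasses.replace(config.analysis, seed=int(seed)),
        )
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "calcimorph",
        "version": __version__,
        "mode": mode,
        "started": _now(),
        "seeds": {
            "cohort": config.cohort.seed,
            "analysis": config.analysis.seed,
        },
        "config": {
            "cohort": config_to_dict(config.cohort),
            "segmentation": dataclasses.asdict(config.segmentation),
            "analysis": dataclasses.asdict(config.analysis),
        },
        "stages": {},
        "input_digests": {},
    }
    stages = [mode] if mode != "all" else ["simulate", "segment", "features", "analyze"]
    for stage in stages:
        logger.info("running stage %s", stage)
        _STAGE_FUNCS[stage](config, out, manifest)
    manifest["finished"] = _now()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _volume_paths(out: Path) -> list[Path]:
    return sorted((out / "volumes").glob("*.nii*"))


def _stage_simulate(config: PipelineConfig, out: Path, manifest: dict) -> None:
    volumes, truth = generate_cohort(config.cohort)
    vol_dir = out / "volumes"
    vol_dir.mkdir(exist_ok=True)
    plaque_ids = truth["plaque_id"].unique()
    for pid, vol in zip(plaque_ids, volumes):
        write_volume(vol, vol_dir / f"{pid}.nii.gz")
    truth.to_csv(out / "ground_truth.csv", index=False)
    manifest["stages"]["simulate"] = {
        "n_plaques": len(volumes),
        "n_clusters": len(truth),
        "seed": config.cohort.seed,
    }


def _stage_segment(config: PipelineConfig, out: Path, manifest: dict) -> None:
    paths = _volume_paths(out)
    if not paths:
        raise DependencyError(
            "stage 'segment' found no volumes under volumes/; run 'simulate' "
            "first or place NIfTI volumes there"
        )
    seg = config.segmentation
    lab_dir = out / "labels"
    lab_dir.mkdir(exist_ok=True)
    n_clusters = 0
    for path in paths:
        vol = read_volume(path)
        vol = normalize_intensity(vol, seg.clip_lo, seg.clip_hi)
        mask = threshold_calcium(vol, seg.threshold_hu)
        mask = morphological_clean(mask, seg.min_volume_mm3, seg.opening_radius_voxels)
        labels = label_components(mask, seg.connectivity)
        n_clusters += labels.n_clusters
        stem = path.name.split(".")[0]
        write_label_map(labels, lab_dir / f"{stem}_labels.nii.gz")
        manifest["input_digests"][path.name] = sha256_digest(path)
    manifest["stages"]["segment"] = {**dataclasses.asdict(seg), "n_clusters": n_clusters}


def _stage_features(config: PipelineConfig, out: Path, manifest: dict) -> None:
    paths = _volume_paths(out)
    if not paths:
        raise DependencyError("stage 'features' needs volumes/; run 'simulate' first")
    seg = config.segmentation
    frames = []
    for path in paths:
        stem = path.name.split(".")[0]
        lab_path = _require(
            out / "labels" / f"{stem}_labels.nii.gz", "features", "segment"
        )
        labels = read_label_map(lab_path, connectivity=seg.connectivity)
        volume = read_volume(path)
        frames.append(compute_cluster_features(labels, volume, plaque_id=stem))
    features = pd.concat(frames, ignore_index=True)
    features.to_csv(out / "features.csv", index=False)
    plaques = aggregate_plaques(features)
    plaques.to_csv(out / "plaques.csv", index=False)
    manifest["stages"]["features"] = {
        "n_clusters": len(features),
        "n_plaques": len(plaques),
    }


def _stage_analyze(config: PipelineConfig, out: Path, manifest: dict) -> None:
    feat_path = _require(out / "features.csv", "analyze", "features")
    plq_path = _require(out / "plaques.csv", "analyze", "features")
    features = pd.read_csv(feat_path)
    plaques = pd.read_csv(plq_path)
    ana = config.analysis
    feats = [f for f in ana.features if f in features.columns]

    corr = correlation_matrix(
        features, feats, partial=False, n_boot=ana.n_boot, seed=ana.seed
    )
    corr.to_csv(out / "correlations.csv", index=False)
    partial = correlation_matrix(
        features, feats, partial=True, n_boot=ana.n_boot, seed=ana.seed + 1
    )
    partial.to_csv(out / "partial_correlations.csv", index=False)

    rcs_rows, pred_frames = [], []
    for outcome, exposure in ana.rcs_pairs:
        covs = [f for f in feats if f not in (outcome, exposure)]
        fit = fit_rcs_model(
            features[outcome],
            features[exposure],
            features[covs] if covs else None,
            knot_quantiles=ana.knot_quantiles,
            influence_screen=ana.influence_screen,
            outcome=outcome,
            exposure=exposure,
        )
        rcs_rows.append(
            {
                "outcome": outcome,
                "exposure": exposure,
                "knot1": fit.knots[0],
                "knot2": fit.knots[1],
                "knot3": fit.knots[2],
                "beta_linear": fit.coefficients["rcs_linear"],
                "se_linear": fit.standard_errors["rcs_linear"],
                "beta_nonlinear": fit.coefficients["rcs_nonlinear"],
                "se_nonlinear": fit.standard_errors["rcs_nonlinear"],
                "wald_chi2": fit.wald_chi2,
                "p_nonlinear": fit.p_nonlinear,
                "n_used": fit.n_used,
                "n_excluded": len(fit.excluded_indices),
            }
        )
        grid = np.linspace(
            float(features[exposure].min()), float(features[exposure].max()), 50
        )
        fitted, lo, hi = fit.predict(grid)
        pred_frames.append(
            pd.DataFrame(
                {
                    "outcome": outcome,
                    "exposure": exposure,
                    "x": grid,
                    "fitted": fitted,
                    "ci_lo": lo,
                    "ci_hi": hi,
                }
            )
        )
    pd.DataFrame(rcs_rows).to_csv(out / "rcs_fits.csv", index=False)
    pd.concat(pred_frames, ignore_index=True).to_csv(
        out / "rcs_predictions.csv", index=False
    )

    comparisons = compare_fragmentation(plaques)
    group_comparisons_frame(comparisons).to_csv(
        out / "group_comparisons.csv", index=False
    )
    manifest["stages"]["analyze"] = {
        "n_boot": ana.n_boot,
        "seed": ana.seed,
        "n_significant_couplings_q05": int((corr["q_value"] < 0.05).sum()),
        "input_digests": {
            "features.csv": sha256_digest(feat_path),
            "plaques.csv": sha256_digest(plq_path),
        },
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "features": _stage_features,
    "analyze": _stage_analyze,
}
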