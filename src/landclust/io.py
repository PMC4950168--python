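"""NIfTI input/output, run configuration and report generation.

Conventions: voxel indices are 0-based everywhere (internal structures
and CSV outputs); mm coordinates computed through the NIfTI affine are
reported alongside. Every output volume carries the input affine
unchanged.
"""

from __future__ import annotations

import dataclasses
import glob as _glob
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .clustering import ClusteringConfig
from .evaluate import evaluate_simulations
from .permutation import InferenceResult, infer
from .simulate import SimulationScenario, make_region
from .stats import SubjectStack

__all__ = [
    "RunConfig",
    "load_subject_stack",
    "run_group_analysis",
    "run_simulation_study",
    "scenario_from_yaml",
]

log = logging.getLogger("landclust")


@dataclass
class RunConfig:
    """Configuration of one group analysis run."""

    subjects: list[str] | str
    mask: str | None
    out_dir: str
    n_permutations: int = 100
    alpha: float = 0.05
    connectivity: int = 26
    seed: int = 0
    pre_threshold: float | None = None
    two_sided: bool = True

    def clustering_config(self) -> ClusteringConfig:
        return ClusteringConfig(
            connectivity=self.connectivity, pre_threshold=self.pre_threshold
        )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _expand_subjects(subjects: list[str] | str) -> list[str]:
    if isinstance(subjects, str):
        paths = sorted(_glob.glob(subjects)) or [subjects]
    else:
        paths = list(subjects)
    return paths


def load_subject_stack(subjects: list[str] | str, mask: str | None = None) -> SubjectStack:
    """Load a 4D NIfTI (or a list/glob of 3D NIfTIs) plus an optional mask.

    Voxel sizes come from the NIfTI header; the affine of the first
    image is carried through to all outputs. With no mask, every voxel
    is in-mask. All volumes must share one shape, and the mask must
    match it.
    """
    paths = _expand_subjects(subjects)
    imgs = [nib.load(p) for p in paths]
    if len(imgs) == 1 and imgs[0].ndim == 4:
        data4 = np.asanyarray(imgs[0].dataobj, dtype=np.float64)
        data = np.moveaxis(data4, -1, 0)
        ref = imgs[0]
    else:
        vols = []
        for p, img in zip(paths, imgs):
            if img.ndim != 3:
                raise ValueError(f"{p}: expected a 3D volume in a multi-file stack")
            vols.append(np.asanyarray(img.dataobj, dtype=np.float64))
        data = np.stack(vols, axis=0)
        ref = imgs[0]
    shape = data.shape[1:]
    if mask is not None:
        mask_img = nib.load(mask)
        mask_arr = np.asanyarray(mask_img.dataobj) != 0
        if mask_arr.shape != shape:
            raise ValueError(
                f"mask geometry {mask_arr.shape} does not match subject volumes {shape}"
            )
    else:
        mask_arr = np.ones(shape, dtype=bool)
    voxel_size = np.asarray(ref.header.get_zooms()[:3], dtype=np.float64)
    return SubjectStack(data, mask_arr, voxel_size, affine=np.asarray(ref.affine))


def _save_volume(arr: np.ndarray, affine: np.ndarray | None, path: Path) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(arr), affine), str(path))


def _cluster_table_with_mm(result: InferenceResult, affine: np.ndarray | None) -> pd.DataFrame:
    table = result.cluster_table()
    if affine is None:
        affine = np.eye(4)
    vox = table[["peak_x", "peak_y", "peak_z"]].to_numpy(dtype=float)
    if len(table):
        mm = nib.affines.apply_affine(affine, vox)
    else:
        mm = np.empty((0, 3))
    table["peak_mm_x"], table["peak_mm_y"], table["peak_mm_z"] = mm.T if len(table) else (
        [],
        [],
        [],
    )
    return table


def run_group_analysis(config: RunConfig) -> dict[str, Path]:
    """Run the full group analysis and write the output bundle.

    Writes the landscape map, integer cluster-label map and significance
    mask as NIfTI (input geometry preserved), the cluster table and null
    max-score distribution as CSV, and the resolved configuration with
    the seed as YAML. Returns the paths, keyed by artifact name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack = load_subject_stack(config.subjects, config.mask)
    log.info(
        "group analysis: %d subjects, grid %s, %d permutations, alpha %g, seed %d",
        stack.n_subjects,
        stack.shape,
        config.n_permutations,
        config.alpha,
        config.seed,
    )
    result = infer(
        stack,
        n_permutations=config.n_permutations,
        seed=config.seed,
        alpha=config.alpha,
        config=config.clustering_config(),
        two_sided=config.two_sided,
    )
    cs = result.cluster_set
    paths = {
        "landscape": out / "landscape.nii.gz",
        "cluster_labels": out / "cluster_labels.nii.gz",
        "significance_mask": out / "significance_mask.nii.gz",
        "clusters": out / "clusters.csv",
        "null_distribution": out / "null_distribution.csv",
        "config": out / "config.yaml",
    }
    affine = stack.affine
    _save_volume(cs.landscape.values, affine, paths["landscape"])
    _save_volume(cs.label_grid.astype(np.int32), affine, paths["cluster_labels"])
    _save_volume(result.significance_mask.astype(np.uint8), affine, paths["significance_mask"])
    table = _cluster_table_with_mm(result, affine)
    table.to_csv(paths["clusters"], index=False)
    pd.DataFrame(
        {"permutation": np.arange(1, config.n_permutations + 1), "max_score": result.null.max_scores}
    ).to_csv(paths["null_distribution"], index=False)
    resolved = config.as_dict()
    resolved["criterion"] = float(result.criterion)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=False)
    log.info(
        "criterion %.4f; %d/%d clusters significant",
        result.criterion,
        int(result.significant.sum()),
        cs.n_clusters,
    )
    return paths


def scenario_from_yaml(path: str | Path) -> tuple[SimulationScenario, dict]:
    """Build a SimulationScenario from a YAML file.

    Recognized keys: grid_shape, voxel_size, region_center,
    region_radii, n_subjects, effect_size, fwhm, seed, rescale_noise,
    plus study-level keys (n_simulations, n_permutations, alpha,
    pre_threshold, connectivity, baseline) returned in the second item.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    grid_shape = tuple(raw.get("grid_shape", (48, 48, 48)))
    region = make_region(
        grid_shape,
        tuple(raw["region_center"]) if "region_center" in raw else None,
        tuple(raw.get("region_radii", (4.0, 3.8, 3.4))),
    )
    scenario = SimulationScenario(
        grid_shape=grid_shape,
        voxel_size=tuple(raw.get("voxel_size", (2.0, 2.0, 2.0))),
        region=region,
        n_subjects=int(raw.get("n_subjects", 32)),
        effect_size=float(raw.get("effect_size", 0.8)),
        fwhm=float(raw.get("fwhm", 4.0)),
        seed=int(raw.get("seed", 0)),
        rescale_noise=bool(raw.get("rescale_noise", True)),
    )
    study = {
        "n_simulations": int(raw.get("n_simulations", 100)),
        "n_permutations": int(raw.get("n_permutations", 100)),
        "alpha": float(raw.get("alpha", 0.05)),
        "pre_threshold": raw.get("pre_threshold", 0.05),
        "connectivity": int(raw.get("connectivity", 26)),
        "baseline": bool(raw.get("baseline", False)),
    }
    return scenario, study


def run_simulation_study(
    scenario: SimulationScenario,
    study: dict,
    out_dir: str | Path,
    progress: bool = False,
) -> dict[str, Path]:
    """Run the simulation study and write summary + per-cluster CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = ClusteringConfig(
        connectivity=study.get("connectivity", 26),
        pre_threshold=study.get("pre_threshold", 0.05),
    )
    methods = ["landscape"] + (["baseline"] if study.get("baseline") else [])
    summaries = []
    paths: dict[str, Path] = {"summary": out / "summary.csv"}
    for method in methods:
        summary, detail = evaluate_simulations(
            scenario,
            n_simulations=study["n_simulations"],
            n_permutations=study["n_permutations"],
            seed=scenario.seed if isinstance(scenario.seed, int) else 0,
            method=method,
            config=config,
            alpha=study.get("alpha", 0.05),
            progress=progress,
        )
        row = {"method": method, **summary.as_row()}
        summaries.append(row)
        detail_path = out / f"details_{method}.csv"
        detail.to_csv(detail_path, index=False)
        paths[f"details_{method}"] = detail_path
        log.info("%s: %s", method, json.dumps(row))
    pd.DataFrame(summaries).to_csv(paths["summary"], index=False)
    return paths
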