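"""End-to-end orchestration: simulate -> reconstruct -> segment -> score -> report.

Every stage writes its artifacts under the output directory and registers
them in a manifest (JSON) with their SHA-256 checksums and the seeds that
produced them, so two runs with the same configuration are byte-identical
and fully auditable.  Warnings raised by the stages (clipping, threshold
fallbacks) are collected into the manifest as machine-readable strings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as vio
from .config import PipelineConfig
from .phantom import (
    BranchingSpec,
    FlatFieldModel,
    NoiseModel,
    ProjectionSet,
    build_vessel_tree,
    project,
    voxelize,
)
from .quantify import SamplingScheme, angiographic_score, sample_rois
from .recon import reconstruct_volume
from .segment import RoiGrid, binarize_blocks, morph_open
from .stats import GROUP_ORDER, compare_pairwise, plot_scores, summarize

__all__ = ["run_pipeline", "run_twin_modes", "simulate_groups", "score_projections"]


def _seed_for(master: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    h = hashlib.sha256(f"{master}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Stage: simulate
# ---------------------------------------------------------------------------

def simulate_groups(config: PipelineConfig) -> tuple[list[ProjectionSet], dict]:
    """Build the vessel tree and acquire each vertical stage group.

    The tree is projected analytically per group (the rays of a group only
    see the z range of that group), producing ``n_groups`` projection sets
    labeled CT1..CT4 from the fundus end upward.  Returns the sets plus the
    ground truth (tree and voxelized lumen phantom).
    """
    ph_cfg, acq = config.phantom, config.acquisition
    pitch = acq.pixel_pitch_um
    nz, ny, nx = ph_cfg.extent_px
    spec = BranchingSpec(
        diameters_um=ph_cfg.diameters_um,
        n_children=ph_cfg.n_children,
        lengths_um=ph_cfg.lengths_um,
        branch_angle_deg=ph_cfg.branch_angle_deg,
        root_start=(0.0, 0.0, 2 * pitch),
        root_direction=(0.0, 0.0, 1.0),
    )
    tree = build_vessel_tree(spec, seed=_seed_for(config.seed, "tree"),
                             contrast_per_um=ph_cfg.contrast_per_um)
    truth = voxelize(tree, pitch, (nz, ny, nx))

    angles = np.arange(acq.n_angles) * (180.0 / acq.n_angles)
    step_rows = max(1, int(round(acq.step_um / pitch)))
    flat = FlatFieldModel()
    noise = NoiseModel(photons=acq.photons, read_sd=acq.read_noise)
    sets = []
    for g in range(acq.n_groups):
        z0 = g * acq.step_um
        ps = project(
            tree, angles_deg=angles, mode=acq.mode, flat=flat, noise=noise,
            seed=_seed_for(config.seed, "project", g),
            pixel_pitch_um=pitch, detector_shape=(step_rows, nx), z0_um=z0,
            axis_offset_px=acq.axis_offset_px,
            phase_strength_px2=acq.phase_strength_px2,
            group_id=f"CT{g + 1}",
            meta={"energy_kev": acq.energy_kev, "distance_mm": acq.distance_mm},
        )
        sets.append(ps)
    return sets, {"tree": tree, "truth": truth}


# ---------------------------------------------------------------------------
# Stage: score
# ---------------------------------------------------------------------------

def score_projections(pset: ProjectionSet, config: PipelineConfig,
                      seed: int, bbox=None) -> list:
    """Sample the scheme's ROIs on a group's films and score each one.

    Films are flat-field-corrected intensity images (vessels dark); each ROI
    is binarized block-wise and (optionally) opened before counting.
    """
    sc, seg = config.scoring, config.segment
    scheme = SamplingScheme(tuple(sc.angles_deg), sc.films_per_angle,
                            sc.areas_per_film)
    roi = (seg.roi_size, seg.roi_size)
    block = (seg.block_size, seg.block_size)
    samples = sample_rois(pset, scheme, roi_size=roi, block=block,
                          seed=seed, bbox=bbox)
    i0 = pset.mean_background()
    for s in samples:
        # re-derive the film image exactly as sample_rois did
        film_ids = _film_ids(scheme, pset.angles_deg, s.angle_deg)
        image = pset.images[film_ids[s.film_idx]] / i0
        roi_img = s.roi.extract(image)
        mask = binarize_blocks(
            roi_img, RoiGrid(size=roi, block=block),
            polarity=seg.polarity_projections, clamp=seg.clamp,
            min_contrast_frac=seg.min_contrast_frac,
            noise_floor_k=seg.noise_floor_k,
        )
        if seg.opening:
            mask = morph_open(mask)
        s.score = angiographic_score(mask)
    return samples


def _film_ids(scheme: SamplingScheme, available: np.ndarray, nominal: float) -> list[int]:
    from .quantify import _film_angles
    return _film_angles(scheme, available, nominal)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class _Manifest:
    config: dict
    seed: int
    stages: dict
    warnings: list

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "seed": self.seed,
             "stages": self.stages, "warnings": self.warnings},
            indent=1,
        )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all five stages and write a checksummed manifest.

    Artifacts per stage: projections (TIFF+JSON per group) and ground truth;
    slice volumes; one segmented mid-slice mask per group; the score table
    (CSV); the summary/comparison report (CSV/JSON/PNG).  Any stage failure
    aborts with the stage name attached.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, list[str]] = {}
    warnings_log: list[str] = []

    def register(stage: str, path: Path) -> None:
        stages.setdefault(stage, []).append(path.name)

    # --- simulate ---------------------------------------------------------
    try:
        sets, truth = simulate_groups(config)
        p = vio.write_tree(truth["tree"], out / "tree.json")
        register("simulate", p)
        p = vio.write_voxel_mask(truth["truth"], out / "lumen_mask.tif")
        register("simulate", p)
        for ps in sets:
            p = vio.write_projections(ps, out / f"projections_{ps.group_id}.tif")
            register("simulate", p)
            register("simulate", p.with_name(p.stem + "_background.tif"))
            register("simulate", p.with_suffix(".json"))
            warnings_log.extend(f"{ps.group_id}: {w}" for w in ps.log)
        warnings_log.extend(truth["truth"].log)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    # --- reconstruct ------------------------------------------------------
    volumes = []
    try:
        for ps in sets:
            vol = reconstruct_volume(ps, rows=config.recon.rows,
                                     filter_name=config.recon.filter_name,
                                     floor=config.recon.floor,
                                     equalize=config.recon.equalize)
            volumes.append(vol)
            p = vio.write_slices(vol, out / f"slices_{ps.group_id}.tif")
            register("reconstruct", p)
            register("reconstruct", p.with_suffix(".json"))
            warnings_log.extend(f"{ps.group_id}: {w}" for w in vol.log)
    except Exception as exc:
        raise RuntimeError(f"stage 'reconstruct' failed: {exc}") from exc

    # --- segment (one mid-stack slice per group, central ROI) -------------
    try:
        seg = config.segment
        for ps, vol in zip(sets, volumes):
            sl = vol.slices[len(vol.slices) // 2]
            size = min(seg.roi_size, (min(sl.shape) // seg.block_size) * seg.block_size)
            size = max(size, seg.block_size)
            r0 = (sl.shape[0] - size) // 2
            c0 = (sl.shape[1] - size) // 2
            grid = RoiGrid(origin=(r0, c0), size=(size, size),
                           block=(seg.block_size, seg.block_size))
            mask = binarize_blocks(grid.extract(sl), grid,
                                   polarity=seg.polarity_slices,
                                   clamp=seg.clamp,
                                   min_contrast_frac=seg.min_contrast_frac,
                                   noise_floor_k=seg.noise_floor_k)
            if seg.opening:
                mask = morph_open(mask)
            p = vio.write_mask(mask, out / f"mask_{ps.group_id}.png")
            register("segment", p)
            register("segment", p.with_suffix(".json"))
            warnings_log.extend(f"{ps.group_id}: {w}" for w in mask.log)
    except Exception as exc:
        raise RuntimeError(f"stage 'segment' failed: {exc}") from exc

    # --- score ------------------------------------------------------------
    try:
        all_samples = []
        for g, ps in enumerate(sets):
            all_samples.extend(
                score_projections(ps, config, seed=_seed_for(config.seed, "rois", g))
            )
        p = vio.write_scores(all_samples, out / "scores.csv")
        register("score", p)
    except Exception as exc:
        raise RuntimeError(f"stage 'score' failed: {exc}") from exc

    # --- report -----------------------------------------------------------
    try:
        order = tuple(f"CT{g + 1}" for g in range(config.acquisition.n_groups))
        groups = {
            g: np.array([s.score for s in all_samples if s.group == g])
            for g in order
        }
        summary = summarize(groups, order=order)
        summary.to_csv(out / "summary.csv")
        register("report", out / "summary.csv")
        if all(len(v) >= 2 for v in groups.values()) and len(order) >= 2:
            cm = compare_pairwise(groups, order=order)
            (out / "comparisons.json").write_text(json.dumps({
                "test": cm.test_name,
                "groups": list(cm.groups),
                "p_values": cm.p_values.tolist(),
                "stars": cm.stars().tolist(),
            }, indent=1))
            register("report", out / "comparisons.json")
            warnings_log.extend(cm.log)
        plot_scores(summary, out / "scores.png")
        register("report", out / "scores.png")
    except Exception as exc:
        raise RuntimeError(f"stage 'report' failed: {exc}") from exc

    # --- manifest ---------------------------------------------------------
    checksums = {
        name: _sha256(out / name)
        for names in stages.values() for name in names
    }
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "mode": config.acquisition.mode,
        "stages": stages,
        "checksums": checksums,
        "warnings": warnings_log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def run_twin_modes(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run matched absorption/phase twins and a mode-comparison report.

    Both runs share the configuration and master seed, so they see identical
    noise draws; only the contrast mode differs.  The comparison report
    lists the per-group mean scores under each mode and their differences.
    """
    import dataclasses as dc

    out = Path(out_dir)
    results = {}
    for mode in ("absorption", "phase"):
        cfg = dc.replace(config, acquisition=dc.replace(config.acquisition, mode=mode))
        results[mode] = run_pipeline(cfg, out / mode)
    comparison = {}
    for mode in results:
        import pandas as pd
        summary = pd.read_csv(out / mode / "summary.csv").set_index("group")
        comparison[mode] = summary["mean"].to_dict()
    delta = {
        g: comparison["phase"][g] - comparison["absorption"][g]
        for g in comparison["absorption"]
    }
    report = {"mean_scores": comparison, "phase_minus_absorption": delta}
    (out / "mode_comparison.json").write_text(json.dumps(report, indent=1))
    return report
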