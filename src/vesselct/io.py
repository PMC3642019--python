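"""Reading and writing the pipeline's on-disk formats.

Interchange contract: projection stacks and slice volumes are multi-page
TIFFs (one page per angle or slice) with a JSON sidecar carrying the
numeric metadata; masks are 8-bit PNG/TIFF (0/255); score tables are CSV;
vessel trees are JSON.  Float image data round-trips bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .phantom import ProjectionSet, VesselTree, VoxelPhantom
from .recon import SliceVolume
from .segment import BinaryMask

__all__ = [
    "write_projections", "read_projections",
    "write_slices", "read_slices",
    "write_mask", "read_mask",
    "write_tree", "read_tree",
    "write_voxel_mask",
    "write_scores", "read_scores",
]

_SIDECAR_KEYS = ("angles_deg", "pixel_pitch_um", "mode")


def _sidecar_path(stack_path: Path) -> Path:
    return stack_path.with_suffix(".json")


def write_projections(pset: ProjectionSet, path: str | Path) -> Path:
    """Write a projection stack as multi-page TIFF + JSON sidecar.

    The background frames go to ``<stem>_background.tif``.
    """
    path = Path(path)
    tifffile.imwrite(path, pset.images, photometric="minisblack")
    tifffile.imwrite(path.with_name(path.stem + "_background.tif"),
                     pset.background, photometric="minisblack")
    sidecar = {
        "angles_deg": pset.angles_deg.tolist(),
        "pixel_pitch_um": pset.pixel_pitch_um,
        "mode": pset.mode,
        "group_id": pset.group_id,
        "normalized": pset.normalized,
        "meta": _jsonable(pset.meta),
        "log": pset.log,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_projections(path: str | Path) -> ProjectionSet:
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    missing = [k for k in _SIDECAR_KEYS if k not in sidecar]
    if missing:
        raise ValueError(f"sidecar {sidecar_file} missing keys: {', '.join(missing)}")
    images = tifffile.imread(path)
    background = tifffile.imread(path.with_name(path.stem + "_background.tif"))
    return ProjectionSet(
        images=images,
        angles_deg=np.array(sidecar["angles_deg"]),
        background=background,
        pixel_pitch_um=sidecar["pixel_pitch_um"],
        mode=sidecar["mode"],
        group_id=sidecar.get("group_id"),
        normalized=sidecar.get("normalized", False),
        meta=sidecar.get("meta", {}),
        log=sidecar.get("log", []),
    )


def write_slices(vol: SliceVolume, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, vol.slices.astype(np.float32),
                     photometric="minisblack")
    sidecar = {
        "voxel_size_um": vol.voxel_size_um,
        "rows": list(vol.rows),
        "background_gray": vol.background_gray,
        "axis_offset": vol.axis_offset,
        "filter_name": vol.filter_name,
        "provenance": vol.provenance,
        "log": vol.log,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_slices(path: str | Path) -> SliceVolume:
    path = Path(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    slices = tifffile.imread(path)
    if slices.ndim == 2:
        slices = slices[None]
    return SliceVolume(
        slices=slices,
        voxel_size_um=sidecar["voxel_size_um"],
        rows=sidecar.get("rows", []),
        background_gray=sidecar.get("background_gray", 0.5),
        axis_offset=sidecar.get("axis_offset", 0.0),
        filter_name=sidecar.get("filter_name", "ramlak"),
        provenance=sidecar.get("provenance"),
        log=sidecar.get("log", []),
    )


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a binary mask as 8-bit image (vessel = 255)."""
    path = Path(path)
    iio.imwrite(path, (mask.data * 255).astype(np.uint8))
    sidecar = {
        "global_threshold": mask.global_threshold,
        "block_thresholds": None if mask.block_thresholds is None
        else np.where(np.isnan(mask.block_thresholds), None,
                      mask.block_thresholds).tolist(),
        "opened": mask.opened,
        "log": mask.log,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_mask(path: str | Path) -> BinaryMask:
    path = Path(path)
    data = (np.asarray(iio.imread(path)) > 127).astype(np.uint8)
    mask = BinaryMask(data)
    sidecar_file = _sidecar_path(path)
    if sidecar_file.exists():
        sidecar = json.loads(sidecar_file.read_text())
        mask.global_threshold = sidecar.get("global_threshold")
        bt = sidecar.get("block_thresholds")
        if bt is not None:
            mask.block_thresholds = np.array(
                [[np.nan if v is None else v for v in row] for row in bt]
            )
        mask.opened = sidecar.get("opened", False)
        mask.log = sidecar.get("log", [])
    return mask


def write_tree(tree: VesselTree, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(tree.to_dict(), indent=1))
    return path


def read_tree(path: str | Path) -> VesselTree:
    return VesselTree.from_dict(json.loads(Path(path).read_text()))


def write_voxel_mask(phantom: VoxelPhantom, path: str | Path) -> Path:
    """Ground-truth lumen mask (multi-page TIFF, 0/255 per z slice)."""
    path = Path(path)
    tifffile.imwrite(path, ((phantom.grid > 0) * 255).astype(np.uint8),
                     photometric="minisblack")
    return path


_SCORE_COLUMNS = ["group", "angle_deg", "film_idx", "area_idx",
                  "roi_row", "roi_col", "score"]


def write_scores(samples: list, path: str | Path) -> Path:
    """ScoreSample table as CSV (one row per ROI)."""
    rows = [
        {
            "group": s.group, "angle_deg": s.angle_deg, "film_idx": s.film_idx,
            "area_idx": s.area_idx, "roi_row": s.roi.origin[0],
            "roi_col": s.roi.origin[1], "score": s.score,
        }
        for s in samples
    ]
    df = pd.DataFrame(rows, columns=_SCORE_COLUMNS)
    df.to_csv(path, index=False)
    return Path(path)


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {', '.join(sorted(missing))}")
    return df


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.integer, np.floating)):
            v = v.item()
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        out[k] = v
    return out
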