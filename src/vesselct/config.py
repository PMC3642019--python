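"""Pipeline configuration: the acquisition geometry and processing knobs.

Defaults reproduce the emulated experiment: 9 um detector pitch, 180
projections in 1 degree steps over 180 degrees, four acquisition groups
stepped 4 mm vertically, a 200x200 scoring ROI in 25 blocks of 40x40, and
27 scores per group (3 angles x 3 films x 3 areas).  Beam energy (22 keV)
and propagation distance (700 mm) are carried as metadata only; the
phase-contrast model is phenomenological and does not consume them.

Configurations round-trip losslessly through YAML.  Seeds are explicit and
mandatory — nothing in the pipeline draws from wall-clock entropy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = [
    "PhantomConfig",
    "AcquisitionConfig",
    "ReconConfig",
    "SegmentConfig",
    "ScoringConfig",
    "PipelineConfig",
]


@dataclass
class PhantomConfig:
    """Vessel-tree generation parameters (diameters in um, root first)."""

    diameters_um: list[float] = field(
        default_factory=lambda: [200.0, 110.0, 95.0, 80.0, 40.0]
    )
    n_children: int = 2
    lengths_um: list[float] | None = None
    branch_angle_deg: float = 35.0
    contrast_per_um: float = 2.0e-3
    extent_px: list[int] = field(default_factory=lambda: [256, 256, 256])  # z, y, x


@dataclass
class AcquisitionConfig:
    """Scan geometry, contrast mode, flat-field and noise settings."""

    n_angles: int = 180
    pixel_pitch_um: float = 9.0
    n_groups: int = 4
    step_um: float = 4000.0
    group_overlap_um: float = 0.0
    mode: str = "absorption"  # or "phase"
    phase_strength_px2: float = 1.0
    photons: float | None = 50000.0
    read_noise: float = 0.002
    axis_offset_px: float = 0.0
    energy_kev: float = 22.0   # metadata only
    distance_mm: float = 700.0  # metadata only


@dataclass
class ReconConfig:
    """Reconstruction filter and slice selection."""

    filter_name: str = "ramlak"
    rows: list[int] | None = None  # None = all detector rows
    floor: float | None = 0.0
    equalize: bool = True


@dataclass
class SegmentConfig:
    """ROI grid geometry and thresholding behaviour."""

    roi_size: int = 200
    block_size: int = 40
    clamp: float = 0.1
    min_contrast_frac: float = 0.1
    noise_floor_k: float = 1.5
    polarity_projections: str = "dark"
    polarity_slices: str = "bright"
    opening: bool = True


@dataclass
class ScoringConfig:
    """The 27-sample scheme: angles x films x areas."""

    angles_deg: list[float] = field(default_factory=lambda: [0.0, 90.0, 179.0])
    films_per_angle: int = 3
    areas_per_film: int = 3


@dataclass
class PipelineConfig:
    """Full end-to-end configuration with a mandatory master seed."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            phantom=PhantomConfig(**d.get("phantom", {})),
            acquisition=AcquisitionConfig(**d.get("acquisition", {})),
            recon=ReconConfig(**d.get("recon", {})),
            segment=SegmentConfig(**d.get("segment", {})),
            scoring=ScoringConfig(**d.get("scoring", {})),
            seed=d.get("seed", 0),
        )

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str) -> "PipelineConfig":
        """Load from a YAML string or a path to a YAML file."""
        try:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        except (OSError, ValueError):
            d = yaml.safe_load(source)
        return cls.from_dict(d)

    @classmethod
    def small(cls, seed: int = 0) -> "PipelineConfig":
        """A fast 64^3 configuration for tests and demonstrations.

        Keeps the full pipeline structure (4 groups, both flat-field and
        noise models, the block grid) at a fraction of the runtime: a
        3-level tree in a 64-px field, 60 angles, 80x80 scoring ROIs in
        40x40 blocks.
        """
        return cls(
            phantom=PhantomConfig(
                diameters_um=[72.0, 45.0, 27.0],
                lengths_um=[800.0, 400.0, 250.0],
                extent_px=[192, 64, 64],
            ),
            acquisition=AcquisitionConfig(
                n_angles=60, n_groups=4, step_um=432.0, photons=50000.0,
            ),
            recon=ReconConfig(rows=[12, 24, 36]),
            segment=SegmentConfig(roi_size=40, block_size=20),
            scoring=ScoringConfig(areas_per_film=1),
            seed=seed,
        )
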