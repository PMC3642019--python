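"""Angiographic scoring and sub-pixel vessel diameter measurement.

The angiographic score is the microvessel-density statistic: the number of
vessel pixels divided by the total number of pixels in a region of
interest.  Scores are sampled under a fixed scheme — three turntable angles
(0, 90 and the 180-equivalent), three films per angle, three randomly
placed ROIs per film — giving 27 scores per acquisition group, summarized
as mean +/- sample SD.

Vessel diameters are measured from gray-level line profiles crossing a
vessel: the width is the full width at half depth between the local
background level and the profile extremum, with linear interpolation at the
two half-depth crossings, which yields fractional pixel counts (e.g. 7.8
pixels at a 9 um pitch ~= 70 um).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import ndimage

from .phantom import (
    DEFAULT_PIXEL_PITCH_UM,
    NoiseModel,
    ProjectionSet,
    VesselSegment,
    VesselTree,
    project,
)
from .segment import BinaryMask, RoiGrid, binarize_blocks

__all__ = [
    "ScoreSample",
    "LineProfile",
    "DiameterMeasurement",
    "SamplingScheme",
    "angiographic_score",
    "sample_rois",
    "score_group",
    "extract_profile",
    "measure_diameter",
    "format_diameter_um",
    "min_detectable_diameter",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ScoreSample:
    """One ROI's angiographic score with its sampling labels."""

    group: str | None
    angle_deg: float
    film_idx: int
    area_idx: int
    roi: RoiGrid
    score: float | None = None

    def __post_init__(self) -> None:
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


@dataclass
class LineProfile:
    """Gray values sampled along a straight line segment of an image."""

    positions: np.ndarray  # pixel units along the line, strictly increasing
    values: np.ndarray
    orientation: tuple[float, float]  # (row, col) unit direction
    source: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class DiameterMeasurement:
    """A vessel width in fractional pixels and micrometres."""

    pixel_count: float
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    method: str = "fwhm"

    def __post_init__(self) -> None:
        if self.pixel_count < 0:
            raise ValueError("pixel count must be non-negative")

    @property
    def diameter_um(self) -> float:
        return self.pixel_count * self.pixel_pitch_um


def format_diameter_um(m: DiameterMeasurement) -> float:
    """Diameter rounded to two significant figures (reporting convention)."""
    d = m.diameter_um
    if d == 0:
        return 0.0
    exp = math.floor(math.log10(abs(d)))
    return round(d, -exp + 1)


# ---------------------------------------------------------------------------
# Angiographic score
# ---------------------------------------------------------------------------

def angiographic_score(mask: BinaryMask | np.ndarray) -> float:
    """Vessel-pixel fraction of a binary mask: (# ones) / (# pixels).

    Computed with exact rational arithmetic before float conversion, so the
    score equals the counting ratio to the last bit.
    """
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask)
    if data.size == 0:
        raise ValueError("empty mask")
    if not np.isin(data, (0, 1)).all():
        raise ValueError("mask values must be 0 or 1")
    return float(Fraction(int(data.sum()), int(data.size)))


# ---------------------------------------------------------------------------
# ROI sampling scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingScheme:
    """Turntable angles and film/area multiplicities of the scoring design.

    The 180 degree position maps to the 179 degree projection (no 180 degree
    frame exists when angles run 0..179).  Only one projection exists per
    angle, so the "films" of an angle are the projection at the nominal
    angle and its immediate angular neighbors (e.g. 89, 90, 91 for 90),
    which keeps the per-group sample count while averaging out small angular
    differences.
    """

    angles_deg: tuple[float, ...] = (0.0, 90.0, 179.0)
    films_per_angle: int = 3
    areas_per_film: int = 3

    @property
    def n_samples(self) -> int:
        return len(self.angles_deg) * self.films_per_angle * self.areas_per_film


def _film_angles(scheme: SamplingScheme, available: np.ndarray, nominal: float) -> list[int]:
    """Indices of the projections serving as films for one nominal angle."""
    base = int(np.abs(available - nominal).argmin())
    n = len(available)
    half = scheme.films_per_angle // 2
    return [(base + k) % n for k in range(-half, -half + scheme.films_per_angle)]


def sample_rois(image_set: ProjectionSet | list,
                scheme: SamplingScheme | None = None,
                roi_size: tuple[int, int] = (200, 200),
                block: tuple[int, int] | None = None,
                seed: int | None = 0,
                bbox: tuple[int, int, int, int] | None = None,
                group: str | None = None) -> list[ScoreSample]:
    """Place the scheme's ROIs (score stubs) on a set of films.

    ``image_set`` is a :class:`ProjectionSet` (films are projections chosen
    per the scheme's film rule) or an explicit list of ``(label, image)``
    pairs (each entry is a film; the scheme's angles then index into it
    cyclically).  Placements are uniformly random within ``bbox``
    (``(row_lo, col_lo, row_hi, col_hi)``, default the full frame) and
    non-overlapping within a film; placement is deterministic given
    ``seed``.  Raises if a film cannot hold the requested number of
    non-overlapping ROIs, reporting the maximum feasible count.
    """
    scheme = scheme or SamplingScheme()
    rng = np.random.default_rng(seed)
    if isinstance(image_set, ProjectionSet):
        films = []
        for a in scheme.angles_deg:
            for f, idx in enumerate(_film_angles(scheme, image_set.angles_deg, a)):
                films.append((a, f, image_set.images[idx]))
        group = group or image_set.group_id
    else:
        films = []
        for ai, a in enumerate(scheme.angles_deg):
            for f in range(scheme.films_per_angle):
                label, image = image_set[(ai * scheme.films_per_angle + f) % len(image_set)]
                films.append((a, f, image))

    h, w = roi_size
    block = block or (h, w)
    samples: list[ScoreSample] = []
    for angle, film_idx, image in films:
        r_lo, c_lo, r_hi, c_hi = bbox or (0, 0, image.shape[0], image.shape[1])
        if r_hi - r_lo < h or c_hi - c_lo < w:
            raise ValueError("image too small for the requested ROI size")
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < scheme.areas_per_film:
            r = int(rng.integers(r_lo, r_hi - h + 1))
            c = int(rng.integers(c_lo, c_hi - w + 1))
            if all(abs(r - pr) >= h or abs(c - pc) >= w for pr, pc in placed):
                placed.append((r, c))
            attempts += 1
            if attempts > 2000:
                cap = ((r_hi - r_lo) // h) * ((c_hi - c_lo) // w)
                raise ValueError(
                    f"cannot place {scheme.areas_per_film} non-overlapping "
                    f"{h}x{w} ROIs; at most {cap} fit"
                )
        for area_idx, (r, c) in enumerate(placed):
            samples.append(ScoreSample(
                group=group, angle_deg=angle, film_idx=film_idx,
                area_idx=area_idx,
                roi=RoiGrid(origin=(r, c), size=(h, w), block=block),
            ))
    return samples


def score_group(samples: list[ScoreSample] | np.ndarray) -> tuple[float, float, int]:
    """Arithmetic mean and sample SD (n-1 denominator) of a group's scores."""
    if samples and isinstance(samples[0], ScoreSample):
        scores = np.array([s.score for s in samples], dtype=float)
    else:
        scores = np.asarray(samples, dtype=float)
    n = len(scores)
    if n < 2:
        raise ValueError("at least 2 scores are required")
    return float(scores.mean()), float(scores.std(ddof=1)), n


# ---------------------------------------------------------------------------
# Line profiles and diameter measurement
# ---------------------------------------------------------------------------

def extract_profile(image: np.ndarray, start: tuple[float, float],
                    end: tuple[float, float], sampling: float = 1.0,
                    source: str | None = None) -> LineProfile:
    """Bilinearly interpolated gray values along a line segment.

    ``start``/``end`` are (row, col) positions; samples are spaced
    ``sampling`` pixels apart along the segment (endpoints included).
    """
    image = np.asarray(image, dtype=float)
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    length = float(np.hypot(*(end - start)))
    if length == 0:
        raise ValueError("zero-length line")
    for p in (start, end):
        if not (0 <= p[0] <= image.shape[0] - 1 and 0 <= p[1] <= image.shape[1] - 1):
            raise ValueError("profile endpoints must lie inside the image")
    n = int(np.floor(length / sampling)) + 1
    pos = sampling * np.arange(n)
    direction = (end - start) / length
    coords = start[None, :] + pos[:, None] * direction[None, :]
    values = ndimage.map_coordinates(image, coords.T, order=1, mode="nearest")
    return LineProfile(pos, values, orientation=(direction[0], direction[1]),
                       source=source)


def measure_diameter(profile: LineProfile,
                     pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
                     method: str = "fwhm",
                     polarity: str = "auto",
                     background_frac: float = 0.2,
                     noise_floor: float | None = None) -> DiameterMeasurement:
    """Full width at half depth of the vessel crossing a line profile.

    The local background is the median of the outer ``background_frac`` of
    the profile (both ends).  The vessel is the dominant extremum relative
    to that background — a minimum for dark vessels on projections, a
    maximum for bright cross-sections on slices (``polarity='auto'`` picks
    the larger deviation).  The width is measured between the two
    half-depth crossings nearest the extremum, each located by linear
    interpolation, giving fractional pixel counts.  ``noise_floor`` (same
    units as the profile; default three robust noise SDs of the background
    samples) rejects profiles without a genuine vessel.
    """
    if method != "fwhm":
        raise ValueError("only the 'fwhm' method is implemented")
    pos, val = profile.positions, profile.values
    k = max(1, int(round(background_frac * len(val) / 2)))
    bg_samples = np.concatenate([val[:k], val[-k:]])
    background = float(np.median(bg_samples))
    if noise_floor is None:
        mad = float(np.median(np.abs(bg_samples - background)))
        noise_floor = max(3.0 * 1.4826 * mad, 1e-12)

    dev = val - background
    if polarity == "dark":
        extremum_idx = int(dev.argmin())
    elif polarity == "bright":
        extremum_idx = int(dev.argmax())
    elif polarity == "auto":
        extremum_idx = int(np.abs(dev).argmax())
    else:
        raise ValueError("polarity must be 'dark', 'bright' or 'auto'")
    depth = dev[extremum_idx]
    if abs(depth) <= noise_floor:
        raise ValueError("no vessel on profile (extremum within noise floor)")

    half = depth / 2.0
    # walk outward from the extremum to the first half-depth crossings
    sign = 1.0 if depth > 0 else -1.0
    d = sign * dev  # vessel now a positive bump; half-depth = |half|
    target = sign * half

    def _crossing(direction: int) -> float:
        i = extremum_idx
        while 0 < i < len(d) - 1:
            j = i + direction
            if d[j] < target:
                # linear interpolation between samples j and i
                frac = (d[i] - target) / (d[i] - d[j])
                return float(pos[i] + frac * (pos[j] - pos[i]))
            i = j
        return float(pos[i])

    left = _crossing(-1)
    right = _crossing(+1)
    width_px = abs(right - left)
    return DiameterMeasurement(width_px, pixel_pitch_um, method="fwhm")


# ---------------------------------------------------------------------------
# Minimum detectable diameter (contrast-mode comparison)
# ---------------------------------------------------------------------------

def min_detectable_diameter(diameters_um: list[float],
                            cnr: float = 5.0,
                            seed: int | None = 0,
                            mode: str = "absorption",
                            contrast_per_um: float = 2.0e-3,
                            pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
                            phase_strength_px2: float = 1.0,
                            n_rows: int = 48,
                            recall_target: float = 0.5) -> float:
    """Smallest tube diameter whose segmentation recovers >= 50% of lumen rays.

    For each diameter in the ascending sweep, a single vertical tube is
    projected at 0 degrees with photon noise calibrated so that a 36 um
    (4 px) reference tube has the requested peak contrast-to-noise ratio,
    the log-projection is segmented block-wise (vessels dark), and the
    recall of the rays passing through the lumen is evaluated.  Detectability
    is judged on the thresholded mask *before* morphological opening: a 3x3
    opening would erase any 2-px-wide vessel outright, whereas minimum
    visible calibers are assessed on the gray images, not on the cleaned
    density masks.

    Returns the first diameter meeting ``recall_target``, or ``inf`` (with a
    warning) if none does.  Twin absorption/phase calls with the same seed
    see identical noise draws, isolating the contrast-mode effect.
    """
    if sorted(diameters_um) != list(diameters_um):
        raise ValueError("diameter sweep must be sorted ascending")
    ref_contrast = contrast_per_um * 4 * pixel_pitch_um  # 36 um reference tube
    photons = None if not np.isfinite(cnr) else (cnr / ref_contrast) ** 2
    ncol = 72
    # 24-px-wide blocks keep the centred tube inside the middle block at a
    # modest vessel fraction for the whole sweep
    grid = RoiGrid(size=(n_rows, ncol), block=(n_rows, 24))
    height = n_rows * pixel_pitch_um
    for d in diameters_um:
        tree = VesselTree(
            [VesselSegment([0, 0, 0], [0, 0, height], d / 2.0, 0)],
            contrast_per_um=contrast_per_um,
        )
        ps = project(
            tree, angles_deg=[0.0], mode=mode,
            flat=np.ones((n_rows, ncol)),
            noise=NoiseModel(photons=photons),
            seed=seed, pixel_pitch_um=pixel_pitch_um,
            detector_shape=(n_rows, ncol), z0_um=0.0,
            phase_strength_px2=phase_strength_px2,
        )
        # films are intensity images: vessels absorb, so they are dark
        ratio = ps.images[0] / ps.mean_background()
        mask = binarize_blocks(ratio, grid, polarity="dark").data.astype(bool)
        c0 = (ncol - 1) / 2.0
        x_um = (np.arange(ncol) - c0) * pixel_pitch_um
        lumen = np.broadcast_to(np.abs(x_um) < d / 2.0, (n_rows, ncol))
        if lumen.sum() == 0:
            continue
        recall = (mask & lumen).sum() / lumen.sum()
        if recall >= recall_target:
            return float(d)
    warnings.warn("no diameter in the sweep was detectable; returning inf")
    return float("inf")
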