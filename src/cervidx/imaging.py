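"""Cytology-image morphometry pipeline (phase 2).

From an 8-bit RGB micrograph of stained endocervical cells the pipeline
extracts four image-level features:

* ``dn`` — mean nucleus area in pixels,
* ``tn`` — mean nucleus staining (darker = more hyperchromatic = higher),
* ``hn`` — mean nucleus eccentricity (0 round .. 1 elongated),
* ``pn`` — total count of nucleoli (small dark spots inside nuclei).

Steps: optional level enhancement -> green-channel thresholding (nuclei are
darkest in the green channel of hematoxylin-type stains) -> morphological
cleanup -> connected-component labeling with region moments -> per-nucleus
nucleolus spot detection -> feature averaging.

Staining convention: raw image intensity decreases with stain uptake, while
the model's staining universe places "dark" at high values.  ``tn`` is
therefore computed on an inverted grayscale rescaled to [0, 150]
(``(255 - luminance) * 150/255``); the raw-intensity convention is a
configuration switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import color, measure, morphology
from skimage.filters import threshold_otsu

from .fuzzy import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterError",
    "NoNucleiError",
    "PipelineParams",
    "NucleusRegion",
    "FeatureVector",
    "enhance_levels",
    "split_channels",
    "to_grayscale",
    "staining_raster",
    "threshold_nuclei",
    "morph_cleanup",
    "label_nuclei",
    "detect_nucleoli",
    "compute_features",
    "extract_features",
    "regions_to_table",
]

TN_SCALE = 150.0 / 255.0


class ParameterError(ValueError):
    """Invalid pipeline parameter."""


class NoNucleiError(RuntimeError):
    """The segmentation found no nucleus; features are undefined."""


@dataclass(frozen=True)
class PipelineParams:
    """Tunable pipeline parameters (all defaults documented in the docs).

    ``nucleolus_k``: a spot must be darker than the nucleus mean by ``k``
    region standard deviations.  ``nucleolus_min_spot`` / ``max_frac`` bound
    the admissible spot area in pixels / as a fraction of the nucleus area.
    """

    gain: float = 1.0
    offset: float = 0.0
    stretch: tuple[float, float] | None = None   # percentile pair, e.g. (1, 99)
    emboss: bool = False                          # optional, feature-neutral
    threshold_method: str = "otsu"                # otsu | manual
    manual_value: float | None = None
    morph_radius: int = 2
    min_area: int = 50
    nucleolus_k: float = 2.0
    nucleolus_min_spot: int = 12
    nucleolus_max_frac: float = 0.5
    tn_mode: str = "inverted"                     # inverted | raw
    hn_mode: str = "mean"                         # mean | irregular_fraction
    hn_irregular_cut: float = 0.75


@dataclass
class NucleusRegion:
    """One labeled nucleus with its morphometric descriptors."""

    id: int
    area: int
    perimeter: float
    centroid: tuple[float, float]     # (row, col), 0-based
    eccentricity: float
    mean_staining: float = float("nan")
    nucleolus_count: int = 0
    coords: np.ndarray = field(repr=False, default=None)  # (n, 2) row/col


@dataclass(frozen=True)
class FeatureVector:
    """Image-level inputs to the injury-resolution model."""

    dn: float          # mean nucleus area, px
    tn: float          # mean staining, staining-channel units
    hn: float          # mean eccentricity
    pn: int            # total nucleolus count
    n_nuclei: int

    def as_dict(self) -> dict:
        return {
            "dn": self.dn, "tn": self.tn, "hn": self.hn,
            "pn": self.pn, "n_nuclei": self.n_nuclei,
        }


# ---------------------------------------------------------------------------
# Pixel-level steps
# ---------------------------------------------------------------------------


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError(f"expected an RGB image (H, W, 3), got shape {image.shape}")
    return image


def enhance_levels(image: np.ndarray, params: PipelineParams | None = None) -> np.ndarray:
    """Brightness/contrast adjustment: linear gain/offset or percentile stretch."""
    params = params or PipelineParams()
    image = _check_rgb(image).astype(float)
    if params.stretch is not None:
        p_lo, p_hi = params.stretch
        lo, hi = np.percentile(image, [p_lo, p_hi])
        if hi <= lo:
            raise ParameterError(
                f"degenerate percentile stretch: p{p_lo}={lo} >= p{p_hi}={hi}"
            )
        image = (image - lo) / (hi - lo) * 255.0
    else:
        image = image * params.gain + params.offset
    if params.emboss:
        # By-name-only legacy step; kept as an explicit no-op so configs can
        # toggle it without changing features.
        logger.info("emboss requested: feature-neutral no-op")
    return np.clip(image, 0, 255).astype(np.uint8)


def split_channels(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lossless split into (red, green, blue) single-channel rasters."""
    image = _check_rgb(image)
    return image[..., 0].copy(), image[..., 1].copy(), image[..., 2].copy()


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance raster in [0, 255] (float)."""
    image = _check_rgb(image)
    return color.rgb2gray(image) * 255.0


def staining_raster(gray: np.ndarray, mode: str = "inverted") -> np.ndarray:
    """Staining channel: inverted grayscale rescaled to [0, 150] by default,
    so darker (hyperchromatic) nuclei score higher."""
    gray = np.asarray(gray, dtype=float)
    if mode == "inverted":
        return (255.0 - gray) * TN_SCALE
    if mode == "raw":
        return gray
    raise ParameterError(f"unknown staining mode {mode!r}")


def threshold_nuclei(
    green: np.ndarray,
    method: str = "otsu",
    manual_value: float | None = None,
) -> np.ndarray:
    """Binary mask of nucleus candidates: the darker class of the green channel."""
    green = np.asarray(green)
    if method == "manual":
        if manual_value is None:
            raise ParameterError("manual thresholding requires a value")
        t = manual_value
    elif method == "otsu":
        if np.ptp(green) == 0:
            logger.warning("uniform raster: no contrast, returning empty mask")
            return np.zeros(green.shape, dtype=bool)
        t = threshold_otsu(green)
    else:
        raise ParameterError(f"unknown threshold method {method!r}")
    # <= so that the dark mode itself is foreground on exactly two-valued
    # rasters, where Otsu returns the lower level
    return green <= t


def morph_cleanup(mask: np.ndarray, radius: int = 2, min_area: int = 50) -> np.ndarray:
    """Opening then closing with a disk element, hole filling, and removal of
    components smaller than ``min_area``."""
    if radius < 0 or min_area < 0:
        raise ParameterError("radius and min_area must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius > 0:
        selem = morphology.disk(radius)
        mask = morphology.opening(mask, selem)
        mask = morphology.closing(mask, selem)
        mask = ndi.binary_fill_holes(mask)
    if min_area > 0:
        # removes components strictly smaller than min_area
        mask = morphology.remove_small_objects(mask, max_size=min_area - 1)
    return np.asarray(mask, dtype=bool)


# ---------------------------------------------------------------------------
# Region-level steps
# ---------------------------------------------------------------------------


def label_nuclei(mask: np.ndarray) -> list[NucleusRegion]:
    """8-connected component labeling; eccentricity comes from the region's
    second-order central moments (best-fit ellipse)."""
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    regions = []
    for rp in measure.regionprops(labels):
        regions.append(
            NucleusRegion(
                id=int(rp.label),
                area=int(rp.area),
                perimeter=float(rp.perimeter),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                eccentricity=float(rp.eccentricity),
                coords=rp.coords,
            )
        )
    return regions


def detect_nucleoli(
    staining: np.ndarray,
    regions: list[NucleusRegion],
    k: float = 2.0,
    min_spot: int = 12,
    max_frac: float = 0.5,
) -> list[int]:
    """Count dark interior spots per nucleus.

    ``staining`` uses the darker-is-higher convention, so within each
    nucleus the spot threshold is ``region mean + k * region std``; 8-connected
    spots with area in ``[min_spot, max_frac * nucleus_area]`` are counted.
    Also fills each region's ``mean_staining`` and ``nucleolus_count``.
    """
    staining = np.asarray(staining, dtype=float)
    counts = []
    for region in regions:
        rows, cols = region.coords[:, 0], region.coords[:, 1]
        vals = staining[rows, cols]
        region.mean_staining = float(vals.mean())
        thr = vals.mean() + k * vals.std()
        spot_pixels = vals > thr
        count = 0
        if spot_pixels.any():
            # rebuild a local mask to measure spot connectivity
            r0, c0 = rows.min(), cols.min()
            local = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=bool)
            local[rows[spot_pixels] - r0, cols[spot_pixels] - c0] = True
            spot_labels = measure.label(local, connectivity=2)
            hi = max_frac * region.area
            for sp in measure.regionprops(spot_labels):
                if min_spot <= sp.area <= hi:
                    count += 1
        region.nucleolus_count = count
        counts.append(count)
    return counts


def compute_features(staining: np.ndarray, regions: list[NucleusRegion]) -> FeatureVector:
    """Average the per-region descriptors into the image-level features.

    dn and tn are arithmetic means over nuclei (sum of areas / n, sum of
    region mean stainings / n); hn is the mean eccentricity; pn is the total
    nucleolus count.
    """
    if not regions:
        raise NoNucleiError("no nuclei detected; image features are undefined")
    staining = np.asarray(staining, dtype=float)
    for region in regions:
        if not np.isfinite(region.mean_staining):
            vals = staining[region.coords[:, 0], region.coords[:, 1]]
            region.mean_staining = float(vals.mean())
    n = len(regions)
    return FeatureVector(
        dn=sum(r.area for r in regions) / n,
        tn=sum(r.mean_staining for r in regions) / n,
        hn=sum(r.eccentricity for r in regions) / n,
        pn=int(sum(r.nucleolus_count for r in regions)),
        n_nuclei=n,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def extract_features(
    image: np.ndarray,
    params: PipelineParams | None = None,
) -> tuple[FeatureVector, list[NucleusRegion], np.ndarray]:
    """Run the whole pipeline on an RGB image.

    Returns the feature vector, the per-nucleus regions, and the final
    binary mask (for QC overlays).
    """
    params = params or PipelineParams()
    image = _check_rgb(image)
    enhanced = enhance_levels(image, params)
    _, green, _ = split_channels(enhanced)
    mask = threshold_nuclei(green, params.threshold_method, params.manual_value)
    mask = morph_cleanup(mask, params.morph_radius, params.min_area)
    regions = label_nuclei(mask)
    gray = to_grayscale(enhanced)
    stain = staining_raster(gray, params.tn_mode)
    # spot detection always works on the darker-is-higher raster, whatever
    # convention tn is reported in
    stain_inv = stain if params.tn_mode == "inverted" else staining_raster(gray)
    detect_nucleoli(
        stain_inv, regions,
        k=params.nucleolus_k,
        min_spot=params.nucleolus_min_spot,
        max_frac=params.nucleolus_max_frac,
    )
    if not regions:
        raise NoNucleiError("no nuclei detected; image features are undefined")
    if params.tn_mode != "inverted":
        for r in regions:
            r.mean_staining = float("nan")
    fv = compute_features(stain, regions)
    if params.hn_mode == "irregular_fraction":
        frac = sum(r.eccentricity >= params.hn_irregular_cut for r in regions) / len(regions)
        fv = replace(fv, hn=frac)
    elif params.hn_mode != "mean":
        raise ParameterError(f"unknown hn mode {params.hn_mode!r}")
    return fv, regions, mask


def regions_to_table(regions: list[NucleusRegion]):
    """Per-region table (pandas DataFrame) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "id": r.id,
                "area": r.area,
                "perimeter": r.perimeter,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "eccentricity": r.eccentricity,
                "mean_staining": r.mean_staining,
                "nucleolus_count": r.nucleolus_count,
            }
            for r in regions
        ]
    )
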