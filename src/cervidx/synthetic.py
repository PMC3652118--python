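"""Synthetic cytology fields and clinical cohorts with ground truth.

The generator renders stained-smear-like RGB frames: dark elliptical nuclei
(darkest in the green channel, as with hematoxylin-type stains) on a
lighter cytoplasm/background, optionally with small darker interior spots
standing in for nucleoli, plus Gaussian pixel noise.  Every nucleus carries
pixel-exact ground truth (label mask, rasterized area, analytic
eccentricity, target staining, planted nucleolus count), so the whole
morphometry pipeline is testable without any external data.

Area regimes mirror the per-condition statistics the published system was
calibrated on (small ~3537 px, medium ~7658 px, large ~13747 px mean
nucleus areas with the corresponding population variances); see
``REGIMES``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from skimage import draw

from .fuzzy import InputError
from .imaging import TN_SCALE
from .risk import ClinicalRecord, build_risk_model

logger = logging.getLogger(__name__)

__all__ = [
    "GenerationError",
    "ImageSpec",
    "NucleusTruth",
    "GroundTruth",
    "REGIMES",
    "COHORT_PROFILES",
    "generate_image",
    "generate_cohort",
]

# luminance weights used by the grayscale conversion (ITU-R 601, as in
# skimage.color.rgb2gray)
_WR, _WG, _WB = 0.2125, 0.7154, 0.0721
_GREEN_DIP = 12.0                       # how much darker green is vs luminance
_RB_LIFT = _GREEN_DIP * _WG / (_WR + _WB)


class GenerationError(RuntimeError):
    """Nucleus placement infeasible for the requested spec."""


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of one synthetic cytology field.

    ``area_dist``, ``eccentricity_dist`` and ``staining_dist`` are
    (mean, sd) Gaussians, clamped to valid ranges; staining is expressed on
    the model's staining universe (50-150, darker = higher).
    ``nucleoli_per_nucleus`` plants that many dark spots inside every
    nucleus.
    """

    width: int = 512
    height: int = 512
    n_nuclei: int = 12
    area_dist: tuple[float, float] = (3536.71, 1269.27)
    eccentricity_dist: tuple[float, float] = (0.62, 0.04)
    staining_dist: tuple[float, float] = (65.0, 4.0)
    nucleoli_per_nucleus: int = 0
    nucleolus_radius: int = 3
    nucleolus_contrast: float = 35.0    # extra staining units for spots
    background_rgb: tuple[int, int, int] = (225, 210, 220)
    noise_sd: float = 6.0
    separation: float = 8.0   # min gap between nuclei, px; must exceed the
                              # bridging distance of downstream closing
    seed: int = 0


@dataclass(frozen=True)
class NucleusTruth:
    label: int
    area: int                  # rasterized pixel count
    eccentricity: float        # analytic sqrt(1 - (b/a)^2)
    staining: float            # target staining (50-150 scale)
    nucleolus_count: int
    centroid: tuple[float, float]


@dataclass(frozen=True)
class GroundTruth:
    labels: np.ndarray = field(repr=False)   # int raster, 0 = background
    nuclei: tuple[NucleusTruth, ...]

    @property
    def dn(self) -> float:
        return float(np.mean([n.area for n in self.nuclei]))

    @property
    def hn(self) -> float:
        return float(np.mean([n.eccentricity for n in self.nuclei]))

    @property
    def pn(self) -> int:
        return int(sum(n.nucleolus_count for n in self.nuclei))


# The three area regimes (mean, population sd) with renders that land in the
# clear/media/dark staining bands and regular/irregular shape bands.
REGIMES: dict[str, ImageSpec] = {
    "normal": ImageSpec(
        area_dist=(3536.71, math.sqrt(1_611_045.74)),
        staining_dist=(65.0, 4.0),
        eccentricity_dist=(0.62, 0.04),
        nucleoli_per_nucleus=0,
    ),
    "agc": ImageSpec(
        width=640, height=640,
        area_dist=(7658.24, math.sqrt(2_283_910.70)),
        staining_dist=(84.5, 1.0),
        eccentricity_dist=(0.86, 0.03),
        nucleoli_per_nucleus=1,
    ),
    "positive": ImageSpec(
        width=860, height=860,
        area_dist=(13747.13, math.sqrt(17_225_203.65)),
        staining_dist=(105.0, 5.0),
        eccentricity_dist=(0.86, 0.03),
        nucleoli_per_nucleus=0,
    ),
}


def _nucleus_rgb(staining: float) -> tuple[float, float, float]:
    """RGB triple whose luminance matches the target staining and whose
    green channel is the darkest."""
    g0 = 255.0 - staining / TN_SCALE
    return (g0 + _RB_LIFT, g0 - _GREEN_DIP, g0 + _RB_LIFT)


def generate_image(spec: ImageSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one field; fully reproducible from ``spec.seed``.

    Nuclei are placed by rejection sampling with a 2-px separation margin
    (no touching components).  Raises :class:`GenerationError` when the
    requested total nucleus area exceeds 30% of the frame or placement
    fails after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    if spec.n_nuclei < 0:
        raise InputError("n_nuclei must be >= 0")
    if spec.n_nuclei * spec.area_dist[0] > 0.30 * w * h:
        raise GenerationError(
            f"expected nucleus area {spec.n_nuclei * spec.area_dist[0]:.0f} px "
            f"exceeds 30% of the {w}x{h} frame"
        )

    image = np.empty((h, w, 3), dtype=float)
    image[..., 0] = spec.background_rgb[0]
    image[..., 1] = spec.background_rgb[1]
    image[..., 2] = spec.background_rgb[2]
    labels = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)

    nuclei: list[NucleusTruth] = []
    for idx in range(1, spec.n_nuclei + 1):
        area = max(200.0, rng.normal(*spec.area_dist))
        ecc = float(np.clip(rng.normal(*spec.eccentricity_dist), 0.0, 0.95))
        staining = float(np.clip(rng.normal(*spec.staining_dist), 50.0, 145.0))
        ratio = math.sqrt(1.0 - ecc**2)          # b / a
        a_rad = math.sqrt(area / (math.pi * ratio))
        b_rad = a_rad * ratio
        theta = rng.uniform(0.0, math.pi)

        placed = False
        sep = spec.separation
        for _ in range(300):
            margin = a_rad + sep + 1
            if 2 * margin >= min(h, w):
                break
            # integer centers keep rasterized circles symmetric
            r0 = float(rng.integers(int(margin), int(h - margin) + 1))
            c0 = float(rng.integers(int(margin), int(w - margin) + 1))
            # candidate footprint expanded to enforce the separation gap
            rr2, cc2 = draw.ellipse(r0, c0, a_rad + sep, b_rad + sep,
                                    shape=(h, w), rotation=theta)
            if occupied[rr2, cc2].any():
                continue
            rr, cc = draw.ellipse(r0, c0, a_rad, b_rad,
                                  shape=(h, w), rotation=theta)
            occupied[rr, cc] = True
            labels[rr, cc] = idx
            image[rr, cc, :] = _nucleus_rgb(staining)

            n_spots = _plant_nucleoli(
                image, rng, spec, (r0, c0), (a_rad, b_rad), theta, staining
            )
            nuclei.append(
                NucleusTruth(
                    label=idx,
                    area=int(len(rr)),
                    eccentricity=ecc,
                    staining=staining,
                    nucleolus_count=n_spots,
                    centroid=(float(rr.mean()), float(cc.mean())),
                )
            )
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place nucleus {idx}/{spec.n_nuclei} after 300 tries "
                f"in a {w}x{h} frame"
            )

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return image, GroundTruth(labels=labels, nuclei=tuple(nuclei))


def _plant_nucleoli(image, rng, spec, center, radii, theta, staining) -> int:
    """Stamp the requested dark spots well inside the ellipse; returns the
    number actually planted (placement failures are silently dropped — the
    stored count reflects the render)."""
    if spec.nucleoli_per_nucleus <= 0:
        return 0
    r0, c0 = center
    a_rad, b_rad = radii
    sr = spec.nucleolus_radius
    spot_rgb = _nucleus_rgb(staining + spec.nucleolus_contrast)
    placed_centers: list[tuple[float, float]] = []
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    for _ in range(spec.nucleoli_per_nucleus):
        for _try in range(100):
            # uniform position inside the 0.55-scaled ellipse keeps spots
            # clear of the rim
            ang = rng.uniform(0.0, 2.0 * math.pi)
            frac = 0.55 * math.sqrt(rng.uniform())
            dr_e = frac * a_rad * math.cos(ang)
            dc_e = frac * b_rad * math.sin(ang)
            # rotate into image frame (same convention as draw.ellipse)
            dr = dr_e * cos_t - dc_e * sin_t
            dc = dr_e * sin_t + dc_e * cos_t
            rs, cs = r0 + dr, c0 + dc
            if all(
                (rs - pr) ** 2 + (cs - pc) ** 2 >= (2 * sr + 2) ** 2
                for pr, pc in placed_centers
            ):
                rr, cc = draw.disk((rs, cs), sr, shape=image.shape[:2])
                image[rr, cc, :] = spot_rgb
                placed_centers.append((rs, cs))
                break
    return len(placed_centers)


# ---------------------------------------------------------------------------
# Clinical cohorts
# ---------------------------------------------------------------------------

COHORT_PROFILES: dict[str, dict] = {
    "low_risk": {
        "age": "adult", "sexual_onset": "adult", "partners": "few",
        "pregnancies": "few", "first_pregnancy_age": "adult",
        "std_history": False, "lesions": False,
    },
    "high_risk": {
        "age": "young", "sexual_onset": "young", "partners": "many",
        "pregnancies": "null", "first_pregnancy_age": "young",
        "std_history": False, "lesions": False,
    },
}


def _plateau(variable, label) -> tuple[float, float]:
    s = variable.set_by_label(label)
    bp = s.breakpoints
    return bp[1], bp[2]


def generate_cohort(
    n: int,
    profile: str | Mapping = "low_risk",
    seed: int = 0,
) -> list[ClinicalRecord]:
    """Sample ``n`` clinical records uniformly from the plateaus of the
    fuzzy sets named by ``profile`` (a preset name or a field->label map).

    Record invariants (age >= sexual onset, first pregnancy >= sexual
    onset) are enforced by rejection; a profile whose plateaus make them
    unsatisfiable raises an input error.
    """
    if isinstance(profile, str):
        try:
            profile = COHORT_PROFILES[profile]
        except KeyError:
            raise InputError(
                f"unknown cohort profile {profile!r} "
                f"(presets: {sorted(COHORT_PROFILES)})"
            ) from None
    rng = np.random.default_rng(seed)
    model = build_risk_model()
    var = {v.name: v for v in model.inputs}

    age_lo, age_hi = _plateau(var["age"], profile["age"])
    ivsa_lo, ivsa_hi = _plateau(var["sexual_onset"], profile["sexual_onset"])
    ps_lo, ps_hi = _plateau(var["partners"], profile["partners"])
    ng_label = var["pregnancies"].canonical(profile["pregnancies"])
    pg_lo, pg_hi = _plateau(var["first_pregnancy_age"], profile["first_pregnancy_age"])
    if ivsa_lo > age_hi:
        raise InputError("profile forces sexual onset after current age")
    if ng_label != "null" and pg_hi < ivsa_lo:
        raise InputError("profile forces first pregnancy before sexual onset")

    records = []
    for _ in range(n):
        for _try in range(200):
            age = rng.uniform(age_lo, age_hi)
            ivsa = rng.uniform(ivsa_lo, ivsa_hi)
            if ivsa > age:
                continue
            ps = int(rng.integers(math.ceil(ps_lo), math.floor(ps_hi) + 1))
            if ng_label == "null":
                ng, pg = 0, None
            else:
                ng_lo, ng_hi = _plateau(var["pregnancies"], ng_label)
                ng = max(1, int(rng.integers(math.ceil(ng_lo), math.floor(ng_hi) + 1)))
                pg = rng.uniform(pg_lo, pg_hi)
                if pg < ivsa or pg > age:
                    continue
            rec = ClinicalRecord(
                age=round(age, 1), ivsa=round(ivsa, 1), ps=ps, ng=ng,
                pg=None if pg is None else round(pg, 1),
                ets=bool(profile["std_history"]), le=bool(profile["lesions"]),
            )
            rec.validate()
            records.append(rec)
            break
        else:
            raise InputError(
                "could not satisfy record invariants under this profile"
            )
    return records
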