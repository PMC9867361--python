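"""Synthetic radiograph phantoms and cohorts with known ground truth.

The clinical X-rays behind the study are not publicly deposited, so every
image-facing stage is exercised on phantoms: a bright, smoothly curved
chain of vertebra-like Gaussian blobs on a noisy dark background, with
controllable end-tangent angles, chord area, texture granularity and an
optional scan-line stripe artifact.  The blob centres lie on a single
cubic Bezier whose end tangents are set directly from the requested
angles, so the geometric ground truth is analytic.

A companion generator draws tabular cohorts with the class-conditional
feature structure the analysis assumes (painful necks: larger curve
angle and enclosed area, lower image contrast of the normal group is
reversed — contrast runs higher in pain-free subjects), truncated to the
observed feature ranges so validation bounds always hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from .cohort import ABNORMAL, NORMAL, FEATURE_BOUNDS, PatientRecord
from .geometry import LandmarkSet
from .preprocess import GrayImage


@dataclass
class PhantomSpec:
    image_size: tuple = (512, 640)      # (width, height) pixels
    n_vertebrae: int = 7
    end_angle_c7: float = 90.0          # target angle_1, degrees
    end_angle_c1: float = 90.0          # target angle_2, degrees
    blob_radius: float = 18.0           # pixels
    background_noise_sd: float = 8.0    # gray levels
    texture_granularity: float = 2.0    # correlation length, pixels
    stripe_amplitude: float = 0.0       # gray levels; scan-line artifact
    stripe_period: float = 8.0          # pixels
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.end_angle_c7 < 180 and 0 < self.end_angle_c1 < 180):
            raise ValueError("end angles must lie in (0, 180) degrees")
        if self.n_vertebrae < 3:
            raise ValueError("need at least 3 vertebrae")
        if self.background_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def _bezier(p0, p1, p2, p3, t):
    t = np.asarray(t, dtype=float)[:, None]
    return ((1 - t) ** 3 * p0 + 3 * (1 - t) ** 2 * t * p1
            + 3 * (1 - t) * t ** 2 * p2 + t ** 3 * p3)


def _control_points(spec: PhantomSpec):
    """Cubic Bezier whose end tangents realise the requested angles.

    Image coordinates (y down): a direction with upright angle theta
    against the horizontal is (cos theta, -sin theta).  C1 sits near the
    top of the frame, C7 near the bottom.
    """
    w, h = spec.image_size
    p0 = np.array([w / 2.0, 0.18 * h])      # C1
    p3 = np.array([w / 2.0, 0.82 * h])      # C7
    chord = np.linalg.norm(p3 - p0)
    hnd = chord / 3.0
    t1 = np.deg2rad(spec.end_angle_c7)
    t2 = np.deg2rad(spec.end_angle_c1)
    p1 = p0 + hnd * np.array([-np.cos(t2), np.sin(t2)])   # heads down-curve
    p2 = p3 + hnd * np.array([np.cos(t1), -np.sin(t1)])   # heads up-curve
    return p0, p1, p2, p3


def _shoelace(poly):
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def true_chord_area(spec: PhantomSpec, n: int = 20001) -> float:
    """Area (px^2) between the generating Bezier and its C1-C7 chord."""
    cps = _control_points(spec)
    poly = _bezier(*cps, np.linspace(0, 1, n))
    return float(_shoelace(poly))


def generate_radiograph(spec: PhantomSpec) -> tuple[GrayImage, LandmarkSet]:
    """Render a phantom radiograph and return it with exact blob centres.

    The pixel noise depends on the seed; the landmark geometry does not.
    Raises if any blob would fall outside the frame.
    """
    w, h = spec.image_size
    cps = _control_points(spec)
    t_marks = np.linspace(0.0, 1.0, spec.n_vertebrae)
    marks = _bezier(*cps, t_marks)
    margin = 2.0 * spec.blob_radius
    if (marks[:, 0].min() < margin or marks[:, 0].max() > w - margin
            or marks[:, 1].min() < margin or marks[:, 1].max() > h - margin):
        raise ValueError(
            "phantom spec rejected: vertebra blobs would fall outside the frame"
        )

    rng = np.random.default_rng(spec.seed)
    img = np.full((h, w), 30.0)
    if spec.background_noise_sd > 0:
        noise = rng.normal(0.0, 1.0, (h, w))
        if spec.texture_granularity > 0:
            noise = ndimage.gaussian_filter(noise, spec.texture_granularity)
            noise /= max(noise.std(), 1e-12)
        img += spec.background_noise_sd * noise
    if spec.stripe_amplitude > 0:
        rows = np.arange(h)[:, None]
        img += spec.stripe_amplitude * np.sin(2 * np.pi * rows / spec.stripe_period)

    yy, xx = np.mgrid[0:h, 0:w]
    sigma = spec.blob_radius / 1.5
    for cx, cy in marks:
        img += 170.0 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    # darker inter-vertebral gaps between consecutive bodies
    gaps = 0.5 * (marks[:-1] + marks[1:])
    gsig = sigma / 2.5
    for cx, cy in gaps:
        img -= 60.0 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * gsig**2))

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    gray = GrayImage(pixels, provenance=["phantom"])
    return gray, LandmarkSet(marks)


# ---------------------------------------------------------------------------
# tabular cohort simulation


#: overall cohort mean/SD per feature (the study's descriptive statistics)
FEATURE_MOMENTS = {
    "age": (36.89, 8.28),
    "angle_1": (79.56, 13.81),
    "angle_2": (54.19, 9.87),
    "area": (1007.35, 178.30),
    "contrast": (0.55, 0.52),
    "homogeneity": (0.90, 0.05),
    "correlation": (0.80, 0.11),
    "energy": (0.41, 0.13),
}

#: class-conditional mean offsets in SD units, applied with + to the
#: abnormal class and - to the normal class.  Signs follow the observed
#: feature-vs-class correlations: painful necks run to larger angle_1 and
#: area, pain-free subjects to higher image contrast.
DEFAULT_CLASS_OFFSETS = {"angle_1": +0.45, "area": +0.45, "contrast": -0.45}

#: per-class probabilities over the five usage bands (band 5, >9 h, is
#: unobserved in the study and defaults to zero mass)
DEFAULT_BAND_PROBS = {
    NORMAL: (0.50, 0.20, 0.15, 0.15, 0.0),
    ABNORMAL: (0.15, 0.15, 0.35, 0.35, 0.0),
}

_BAND_HOUR_RANGES = {1: (0.5, 2.0), 2: (2.0, 3.0), 3: (3.0, 6.0),
                     4: (6.0, 9.0), 5: (9.0, 12.0)}


@dataclass
class CohortSimSpec:
    n_patients: int = 46
    prevalence_abnormal: float = 38 / 46
    feature_moments: dict = field(default_factory=lambda: dict(FEATURE_MOMENTS))
    class_offsets: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_OFFSETS))
    band_probs: dict = field(default_factory=lambda: dict(DEFAULT_BAND_PROBS))
    misscore_rate: float = 4 / 46   # chance the simulated model score lands wrong
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.prevalence_abnormal <= 1:
            raise ValueError("prevalence must lie in [0, 1]")
        for name, (_, sd) in self.feature_moments.items():
            if sd <= 0:
                raise ValueError(f"SD for {name} must be positive")


def _draw_truncnorm(rng, mean, sd, lo, hi, size):
    if mean < lo - 6 * sd or mean > hi + 6 * sd:
        raise ValueError(
            f"infeasible truncation: mean {mean} more than 6 SD outside [{lo}, {hi}]"
        )
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSimSpec) -> list[PatientRecord]:
    """Draw a synthetic cohort with the configured class structure.

    Features come from class-conditional normals truncated to the
    observed cohort bounds; hours come from the per-class band model; a
    surrogate model score lands on the correct side of 0.5 except with
    probability ``misscore_rate``.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    classes = (rng.random(n) < spec.prevalence_abnormal).astype(int)
    classes = np.where(classes == 1, ABNORMAL, NORMAL)

    cols = {}
    for name, (mean, sd) in spec.feature_moments.items():
        lo, hi, _ = FEATURE_BOUNDS[name]
        off = spec.class_offsets.get(name, 0.0) * sd
        mu = np.where(classes == ABNORMAL, mean + off, mean - off)
        vals = np.empty(n)
        for k, m in enumerate(mu):
            vals[k] = _draw_truncnorm(rng, m, sd, lo, hi, 1)[0]
        cols[name] = vals

    hours = np.empty(n)
    for k, cls in enumerate(classes):
        probs = np.asarray(spec.band_probs[int(cls)], dtype=float)
        band = int(rng.choice(np.arange(1, 6), p=probs / probs.sum()))
        lo, hi = _BAND_HOUR_RANGES[band]
        hours[k] = round(rng.uniform(lo, hi), 1)

    records = []
    for k in range(n):
        cls = int(classes[k])
        wrong = rng.random() < spec.misscore_rate
        target = cls if not wrong else 1 - cls
        gep_h = rng.uniform(0.5, 1.0) if target == NORMAL else rng.uniform(0.0, 0.5 - 1e-9)
        records.append(PatientRecord(
            patient_id=k + 1,
            gender="male" if rng.random() < 19 / 46 else "female",
            age=int(np.rint(cols["age"][k])),
            h_mean=float(hours[k]),
            angle_1=float(cols["angle_1"][k]),
            angle_2=float(cols["angle_2"][k]),
            area=float(cols["area"][k]),
            contrast=float(cols["contrast"][k]),
            homogeneity=float(cols["homogeneity"][k]),
            correlation=float(cols["correlation"][k]),
            energy=float(cols["energy"][k]),
            input_class=cls,
            gep_h=float(round(gep_h, 3)),
            predicted_class=int(gep_h >= 0.5),
        ))
    return records
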