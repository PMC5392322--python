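"""Synthetic stained-section phantoms and synthetic patient cohorts.

Two generators make every downstream stage testable without patient data:

* :func:`generate_phantom` renders an RGB image of DAB-brown tumor islands
  of known area on a white or hematoxylin-tinted background, using the same
  Beer-Lambert optics the segmentation inverts, and returns exact per-island
  ground truth (achieved pixel areas and bud/artifact status).
* :func:`simulate_cohort` draws per-patient covariates mimicking an
  early-stage oral squamous cell carcinoma cohort, a Bernoulli nodal
  outcome from a logistic model, and exponential proportional-hazards
  survival with uniform administrative censoring.
* :func:`cohort_with_target_auc` builds a one-score cohort whose
  Bayes-optimal discrimination equals a requested AUC exactly, via the
  binormal identity AUC = Phi(delta / sqrt(2)).

All randomness flows through a single integer seed per spec; identical
specs yield bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.special import expit, logit
from scipy.stats import norm

from .bud_counting import ARTIFACT_MIN_UM2, BudParams
from .image_io import CalibratedImage, ROIPolygon, ROISet

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "PhantomCapacityError",
    "generate_phantom",
    "save_phantom",
    "simulate_cohort",
    "cohort_with_target_auc",
    "COHORT_COLUMNS",
]


class PhantomCapacityError(RuntimeError):
    """Islands could not be placed without overlap; use a larger canvas."""


# DAB optical-density direction used for rendering; identical to the
# segmentation default so a phantom of concentration c deconvolves to c.
from .stain_segmentation import RUIFROK_HDAB  # noqa: E402

_DAB_VEC = RUIFROK_HDAB[1]
_HEMA_VEC = RUIFROK_HDAB[0]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and optics of a stained-tissue phantom.

    ``island_areas_um2`` are target areas of bud-candidate islands;
    ``artifact_areas_um2`` are sub-150-um^2 specks.  Shapes are drawn
    uniformly from ``shapes``.  Total island area must not exceed 30% of
    the canvas so rejection-sampled placement terminates.
    """

    height_px: int = 512
    width_px: int = 512
    microns_per_pixel: float = 1.0
    island_areas_um2: tuple[float, ...] = ()
    artifact_areas_um2: tuple[float, ...] = ()
    shapes: tuple[str, ...] = ("disc", "ellipse", "blob")
    dab_concentration: float = 1.0
    background: str = "white"  # "white" | "hematoxylin"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ValueError("canvas must be at least 1 x 1")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be > 0")
        if any(a <= 0 for a in self.island_areas_um2):
            raise ValueError("island areas must be > 0")
        if any(a >= ARTIFACT_MIN_UM2 for a in self.artifact_areas_um2):
            raise ValueError("artifact areas must be < 150 um^2")
        if self.background not in ("white", "hematoxylin"):
            raise ValueError("background must be 'white' or 'hematoxylin'")
        if self.dab_concentration <= 0:
            raise ValueError("dab_concentration must be > 0")
        total_px = sum(self.island_areas_um2 + self.artifact_areas_um2) / self.microns_per_pixel**2
        if total_px > 0.3 * self.height_px * self.width_px:
            raise ValueError("total island area exceeds 30% of the canvas")


def _footprint(shape: str, area_px: float, rng: np.random.Generator) -> np.ndarray:
    """Rasterize one island footprint with pixel count close to area_px."""
    r0 = max(np.sqrt(area_px / np.pi), 0.6)
    if shape == "ellipse":
        aspect = rng.uniform(1.3, 2.2)
        theta = rng.uniform(0, np.pi)
    elif shape == "blob":
        k = rng.integers(3, 6)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.15, 0.3)
    cx, cy = rng.uniform(-0.5, 0.5, size=2)

    def raster(scale: float) -> np.ndarray:
        r = r0 * scale
        half = int(np.ceil(r * 2.5)) + 2
        yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
        yy -= cy
        xx -= cx
        if shape == "disc":
            return xx**2 + yy**2 <= r**2
        if shape == "ellipse":
            a = r * np.sqrt(aspect)
            b = r / np.sqrt(aspect)
            xr = xx * np.cos(theta) + yy * np.sin(theta)
            yr = -xx * np.sin(theta) + yy * np.cos(theta)
            return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        # blob: sinusoidally wobbled radius
        rho = np.hypot(xx, yy)
        ang = np.arctan2(yy, xx)
        # normalize so the mean squared radius stays ~r^2
        wob = 1.0 + amp * np.sin(k * ang + phase)
        return rho <= r * wob / np.sqrt(1 + amp**2 / 2)

    # tune the scale so the achieved pixel count is closest to the target
    scales = np.linspace(0.75, 1.3, 56)
    counts = np.array([int(raster(s).sum()) for s in scales])
    best = int(np.argmin(np.abs(counts - area_px)))
    fp = raster(scales[best])
    # trim empty margins
    rows = np.any(fp, axis=1)
    cols = np.any(fp, axis=0)
    return fp[rows][:, cols]


_SEP_STRUCT = np.ones((5, 5), dtype=bool)  # 2-px separation guard


def _place(
    fp: np.ndarray,
    occupancy: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 500,
) -> tuple[int, int]:
    """Find a top-left offset where the dilated footprint misses occupancy."""
    h, w = occupancy.shape
    fh, fw = fp.shape
    if fh > h or fw > w:
        raise PhantomCapacityError("island footprint larger than canvas")
    guard = ndimage.binary_dilation(np.pad(fp, 2), structure=_SEP_STRUCT)
    gh, gw = guard.shape
    for _ in range(max_tries):
        y = int(rng.integers(0, h - fh + 1))
        x = int(rng.integers(0, w - fw + 1))
        y0, x0 = max(y - 2, 0), max(x - 2, 0)
        gy, gx = y - 2, x - 2
        sl = occupancy[y0 : gy + gh, x0 : gx + gw]
        gsl = guard[y0 - gy : y0 - gy + sl.shape[0], x0 - gx : x0 - gx + sl.shape[1]]
        if not np.any(sl & gsl):
            return y, x
    raise PhantomCapacityError(
        "could not place island without overlap; use a larger canvas"
    )


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[CalibratedImage, ROISet, pd.DataFrame]:
    """Render a phantom and its exact ground truth.

    Returns (image, rois, truth).  ``truth`` has one row per placed object
    with its achieved pixel count, achieved area in um^2, and status under
    the default classifier: ``artifact`` (< 150 um^2), ``bud`` (>= 150 and
    < 950 um^2) or ``large`` (>= 950 um^2).  Achieved — not target — areas
    define the truth, so it stays exact under rasterization.

    Islands are rendered by Beer-Lambert mixing: each stained pixel gets
    optical density ``concentration x DAB vector`` and intensity
    ``255 x 10^(-OD) - 1`` per channel, the exact inverse of the
    segmentation's OD transform (up to 8-bit rounding).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    occupancy = np.zeros((h, w), dtype=bool)
    conc = np.zeros((h, w), dtype=float)
    params = BudParams()

    targets = [(a, "island") for a in spec.island_areas_um2] + [
        (a, "artifact") for a in spec.artifact_areas_um2
    ]
    # place large objects first: helps rejection sampling converge
    targets.sort(key=lambda t: -t[0])
    rows = []
    for target_um2, kind in targets:
        area_px = target_um2 / spec.microns_per_pixel**2
        shape = "disc" if kind == "artifact" else str(rng.choice(list(spec.shapes)))
        fp = _footprint(shape, area_px, rng)
        y, x = _place(fp, occupancy, rng)
        occupancy[y : y + fp.shape[0], x : x + fp.shape[1]] |= fp
        conc[y : y + fp.shape[0], x : x + fp.shape[1]] += fp * spec.dab_concentration
        achieved_px = int(fp.sum())
        achieved_um2 = achieved_px * spec.microns_per_pixel**2
        if achieved_um2 < params.artifact_min_um2:
            status = "artifact"
        elif achieved_um2 < params.bud_max_um2:
            status = "bud"
        else:
            status = "large"
        rows.append(
            {
                "target_um2": target_um2,
                "shape": shape,
                "pixel_count": achieved_px,
                "area_um2": achieved_um2,
                "status": status,
            }
        )

    od = conc[..., None] * _DAB_VEC
    if spec.background == "hematoxylin":
        od = od + 0.08 * _HEMA_VEC  # faint counterstain everywhere
    intensity = 255.0 * 10.0 ** (-od) - 1.0
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=intensity.shape)
    pixels = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)

    image = CalibratedImage(
        pixels=pixels,
        microns_per_pixel=spec.microns_per_pixel,
        source_id=f"phantom(seed={spec.seed})",
    )
    roi = ROISet(
        polygons=(
            ROIPolygon(
                name="canvas",
                role="include",
                vertices=(
                    (-0.5, -0.5),
                    (w - 0.5, -0.5),
                    (w - 0.5, h - 0.5),
                    (-0.5, h - 0.5),
                ),
            ),
        )
    )
    truth = pd.DataFrame(
        rows, columns=["target_um2", "shape", "pixel_count", "area_um2", "status"]
    )
    return image, roi, truth


def save_phantom(
    image: CalibratedImage,
    rois: ROISet,
    truth: pd.DataFrame,
    stem: str | Path,
) -> None:
    """Write a phantom as TIFF + GeoJSON ROI + JSON ground truth."""
    stem = Path(stem)
    res = 1.0 / (image.microns_per_pixel / 10_000.0)  # px per cm
    tifffile.imwrite(
        stem.with_suffix(".tiff"),
        image.pixels,
        resolution=(res, res),
        resolutionunit="CENTIMETER",
    )
    features = [
        {
            "type": "Feature",
            "properties": {"name": p.name, "role": p.role},
            "geometry": {
                "type": "Polygon",
                "coordinates": [[list(v) for v in p.vertices] + [list(p.vertices[0])]],
            },
        }
        for p in rois.polygons
    ]
    stem.with_suffix(".geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
    stem.with_suffix(".truth.json").write_text(truth.to_json(orient="records"))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: Column dictionary of the simulated cohort table.
COHORT_COLUMNS: dict[str, str] = {
    "id": "patient identifier",
    "dtbc": "digital tumor bud count (negative-binomial draw)",
    "dtbc_tertile": "DTBC tertile (1 = lower, 3 = upper)",
    "depth_mm": "absolute tumor invasive depth, mm (lognormal)",
    "depth_gt4": "1 if invasive depth > 4 mm",
    "grade": "differentiation grade: well / moderate / poor",
    "front": "invasive front: cohesive / non_cohesive",
    "pni": "perineural invasion (0/1)",
    "ct_stage": "clinical T stage: cT1 / cT2",
    "site": "tumor subsite: floor / tongue / other",
    "age": "age at diagnosis, years",
    "sex": "male / female",
    "smoking": "smoking exposure: high / low",
    "node_status": "nodal status: N0 / ITC-micro / macro",
    "node_binary": "1 if any nodal metastasis (node_status != N0)",
    "os_time": "overall-survival follow-up, years",
    "os_event": "1 if death observed",
    "pfs_time": "progression-free-survival follow-up, years",
    "pfs_event": "1 if progression or death observed",
}


@dataclass(frozen=True)
class CohortSpec:
    """Distributional spec of a synthetic early-OSCC cohort.

    Defaults mirror a 222-patient early-stage cohort: ~34% node-positive,
    median age 64, right-skewed bud counts mostly between 0 and 1000 per
    section, roughly half of tumors deeper than 4 mm.

    ``node_model`` maps design-column names to log-odds coefficients
    (key ``intercept`` for the intercept); ``os_loghr`` / ``pfs_loghr``
    map the same names to log hazard ratios.  Available design columns:
    ``dtbc_z`` (standardized log1p bud count), ``depth_z``, ``age_z``,
    ``pni``, ``ct2``, ``male``, ``smoking_high``, ``noncohesive``,
    ``grade_moderate``, ``grade_poor``, ``node_binary``.
    """

    n_patients: int = 222
    dtbc_mean: float = 600.0
    dtbc_dispersion: float = 1.2  # NB size parameter; var = m + m^2/size
    depth_log_mean: float = float(np.log(4.0))  # median 4 mm
    depth_log_sd: float = 0.6
    grade_probs: tuple[float, float, float] = (0.263, 0.590, 0.147)  # well/mod/poor
    front_noncohesive_prob: float = 0.60
    pni_prob: float = 0.29
    ct2_prob: float = 0.35
    site_probs: tuple[float, float, float] = (0.47, 0.42, 0.11)  # floor/tongue/other
    age_mean: float = 64.0
    age_sd: float = 12.0
    sex_male_prob: float = 0.57
    smoking_high_prob: float = 0.78
    node_model: Mapping[str, float] = field(
        default_factory=lambda: {
            "intercept": float(logit(0.34)),
            "dtbc_z": 0.9,
            "depth_z": 0.5,
            "pni": 0.4,
        }
    )
    macro_frac: float = 0.6  # macrometastases among node-positive
    os_baseline_rate: float = 0.08  # events per year
    os_loghr: Mapping[str, float] = field(
        default_factory=lambda: {"dtbc_z": 0.5, "age_z": 0.35, "node_binary": 0.5}
    )
    pfs_baseline_rate: float = 0.055
    pfs_loghr: Mapping[str, float] = field(
        default_factory=lambda: {"dtbc_z": 0.8, "node_binary": 0.4}
    )
    censor_years: float = 8.0  # uniform administrative window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for probs in (self.grade_probs, self.site_probs):
            if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1) > 1e-9:
                raise ValueError("categorical probabilities must lie in [0,1] and sum to 1")
        if self.censor_years < 0:
            raise ValueError("censor_years must be >= 0")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _linear_predictor(
    design: pd.DataFrame, model: Mapping[str, float]
) -> np.ndarray:
    lp = np.full(len(design), float(model.get("intercept", 0.0)))
    for name, coef in model.items():
        if name == "intercept":
            continue
        if name not in design.columns:
            raise KeyError(f"unknown model term {name!r}")
        lp = lp + float(coef) * design[name].to_numpy(dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictor")
    return lp


def simulate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort table (see :data:`COHORT_COLUMNS`).

    Node status is Bernoulli(logistic(linear predictor)); event times are
    exponential with rate ``baseline x exp(linear hazard predictor)``;
    observed time is the minimum of the event time and a uniform
    administrative censoring draw, with the event flag set accordingly.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    # negative binomial via gamma-Poisson mixture
    size = spec.dtbc_dispersion
    lam = rng.gamma(shape=size, scale=spec.dtbc_mean / size, size=n)
    dtbc = rng.poisson(lam)
    depth = rng.lognormal(spec.depth_log_mean, spec.depth_log_sd, size=n)
    grade = rng.choice(["well", "moderate", "poor"], size=n, p=spec.grade_probs)
    front = np.where(
        rng.random(n) < spec.front_noncohesive_prob, "non_cohesive", "cohesive"
    )
    pni = (rng.random(n) < spec.pni_prob).astype(int)
    ct_stage = np.where(rng.random(n) < spec.ct2_prob, "cT2", "cT1")
    site = rng.choice(["floor", "tongue", "other"], size=n, p=spec.site_probs)
    age = rng.normal(spec.age_mean, spec.age_sd, size=n)
    sex = np.where(rng.random(n) < spec.sex_male_prob, "male", "female")
    smoking = np.where(rng.random(n) < spec.smoking_high_prob, "high", "low")

    design = pd.DataFrame(
        {
            "dtbc_z": _zscore(np.log1p(dtbc.astype(float))),
            "depth_z": _zscore(np.log(depth)),
            "age_z": _zscore(age),
            "pni": pni.astype(float),
            "ct2": (ct_stage == "cT2").astype(float),
            "male": (sex == "male").astype(float),
            "smoking_high": (smoking == "high").astype(float),
            "noncohesive": (front == "non_cohesive").astype(float),
            "grade_moderate": (grade == "moderate").astype(float),
            "grade_poor": (grade == "poor").astype(float),
        }
    )

    node_p = expit(_linear_predictor(design, spec.node_model))
    node_binary = (rng.random(n) < node_p).astype(int)
    macro = rng.random(n) < spec.macro_frac
    node_status = np.where(
        node_binary == 1, np.where(macro, "macro", "ITC-micro"), "N0"
    )
    design["node_binary"] = node_binary.astype(float)

    def _survival(base_rate: float, loghr: Mapping[str, float]):
        rate = base_rate * np.exp(_linear_predictor(design, loghr))
        event_time = rng.exponential(1.0 / np.maximum(rate, 1e-300))
        censor = rng.uniform(0.0, spec.censor_years, size=n) if spec.censor_years > 0 else np.zeros(n)
        time = np.minimum(event_time, censor)
        event = (event_time <= censor).astype(int)
        return time, event

    os_time, os_event = _survival(spec.os_baseline_rate, spec.os_loghr)
    pfs_time, pfs_event = _survival(spec.pfs_baseline_rate, spec.pfs_loghr)

    from .survival_analysis import assign_tertiles

    try:
        tertile = assign_tertiles(dtbc)
    except ValueError:  # fewer than 3 distinct counts: degenerate but legal
        tertile = np.ones(n, dtype=int)

    return pd.DataFrame(
        {
            "id": [f"P{i:04d}" for i in range(n)],
            "dtbc": dtbc,
            "dtbc_tertile": tertile,
            "depth_mm": depth,
            "depth_gt4": (depth > 4.0).astype(int),
            "grade": grade,
            "front": front,
            "pni": pni,
            "ct_stage": ct_stage,
            "site": site,
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "node_status": node_status,
            "node_binary": node_binary,
            "os_time": os_time,
            "os_event": os_event,
            "pfs_time": pfs_time,
            "pfs_event": pfs_event,
        }
    )


def cohort_with_target_auc(
    n_patients: int,
    target_auc: float,
    prevalence: float = 0.34,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort with a single composite score of known discrimination.

    Labels are Bernoulli(prevalence); the score is N(0, 1) for negatives
    and N(delta, 1) for positives with ``delta = sqrt(2) * Phi^-1(AUC)``,
    so the Bayes-optimal AUC of the score equals ``target_auc`` exactly
    (binormal identity).  The implied logistic model has slope delta on
    the score.
    """
    if not 0.5 < target_auc < 1.0:
        raise ValueError("target_auc must lie in (0.5, 1)")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    delta = np.sqrt(2.0) * norm.ppf(target_auc)
    y = (rng.random(n_patients) < prevalence).astype(int)
    score = rng.normal(0.0, 1.0, size=n_patients) + delta * y
    return pd.DataFrame(
        {
            "id": [f"S{i:05d}" for i in range(n_patients)],
            "score": score,
            "node_binary": y,
        }
    )
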