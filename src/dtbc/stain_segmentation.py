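"""H-DAB stain separation and thresholding of the brown (DAB) signal.

Cytokeratin IHC produces a brown DAB precipitate over a hematoxylin
counterstain.  Under the Beer-Lambert law the optical density (OD) of a
pixel is linear in stain concentration, so the RGB image is mapped to OD
space, unmixed with the published Ruifrok-Johnstone H-DAB vectors, and the
DAB channel is thresholded.  Segmentation runs at a reduced analysis
magnification: the scan is block-mean downsampled by an integer factor
(default 4, i.e. a 20x scan analyzed at 5x) before thresholding, which
also rescales the pixel calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .image_io import AnalysisMask, CalibratedImage

__all__ = [
    "RUIFROK_HDAB",
    "StainParams",
    "StainMask",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "segment_dab",
    "load_stain_params",
]


def _hdab_matrix() -> np.ndarray:
    # Ruifrok & Johnstone H-DAB optical-density vectors (rows: hematoxylin,
    # DAB, residual); the residual is the unit cross product of the first two.
    h = np.array([0.650, 0.704, 0.286])
    d = np.array([0.269, 0.568, 0.778])
    r = np.cross(h, d)
    m = np.vstack([h, d, r])
    return m / np.linalg.norm(m, axis=1, keepdims=True)


RUIFROK_HDAB: np.ndarray = _hdab_matrix()


class StainConfigError(ValueError):
    """Invalid stain-separation parameters."""


@dataclass(frozen=True)
class StainParams:
    """Parameters of the DAB segmentation step.

    od_matrix
        3x3 matrix whose rows are unit-norm stain OD vectors
        (hematoxylin, DAB, residual).  Defaults to the Ruifrok-Johnstone
        H-DAB values.
    dab_od_threshold
        Minimum DAB concentration (OD units) for a pixel to count as
        stained.  Default 0.15.
    analysis_scale_factor
        Integer block-downsampling factor from scan to analysis
        resolution.  Default 4 (20x scan -> 5x analysis).
    """

    od_matrix: np.ndarray = field(default_factory=lambda: RUIFROK_HDAB.copy())
    dab_od_threshold: float = 0.15
    analysis_scale_factor: int = 4

    def __post_init__(self) -> None:
        m = np.asarray(self.od_matrix, dtype=float)
        if m.shape != (3, 3):
            raise StainConfigError("od_matrix must be 3x3")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise StainConfigError("od_matrix rows must have unit Euclidean norm")
        if abs(np.linalg.det(m)) < 1e-12:
            raise StainConfigError("od_matrix is singular")
        if not self.dab_od_threshold > 0:
            raise StainConfigError("dab_od_threshold must be > 0")
        if int(self.analysis_scale_factor) != self.analysis_scale_factor or self.analysis_scale_factor < 1:
            raise StainConfigError("analysis_scale_factor must be an integer >= 1")
        object.__setattr__(self, "od_matrix", m)


@dataclass(frozen=True)
class StainMask:
    """Thresholded DAB mask at analysis resolution."""

    mask: np.ndarray  # h x w bool
    microns_per_pixel: float  # analysis-resolution calibration
    params_used: StainParams


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Beer-Lambert transform: OD_c = -log10((I_c + 1) / 255).

    The +1 offset keeps the transform finite at zero intensity; at full
    intensity (255) the OD is slightly negative (-log10(256/255), about
    -1.7e-3) and is clipped to zero.
    """
    intens = np.asarray(pixels, dtype=float)
    od = -np.log10((intens + 1.0) / 255.0)
    return np.maximum(od, 0.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (returns float intensities in [0, 255])."""
    return np.clip(255.0 * 10.0 ** (-np.asarray(od, dtype=float)) - 1.0, 0.0, 255.0)


def deconvolve(od: np.ndarray, params: StainParams | None = None) -> np.ndarray:
    """Unmix per-pixel OD vectors into (hematoxylin, DAB, residual) concentrations.

    Solves ``od = concentrations @ od_matrix`` for the concentrations; the
    round trip ``deconvolve(od) @ od_matrix`` reconstructs ``od`` to
    numerical precision.
    """
    params = params or StainParams()
    inv = np.linalg.inv(params.od_matrix)
    return np.asarray(od, dtype=float) @ inv


def _block_mean(arr: np.ndarray, f: int) -> np.ndarray:
    """Mean over f x f blocks; ragged edge blocks average their own pixels."""
    if f == 1:
        return np.asarray(arr, dtype=float)
    h, w = arr.shape[:2]
    row_idx = np.arange(0, h, f)
    col_idx = np.arange(0, w, f)
    a = np.asarray(arr, dtype=float)
    summed = np.add.reduceat(np.add.reduceat(a, row_idx, axis=0), col_idx, axis=1)
    row_n = np.diff(np.append(row_idx, h))
    col_n = np.diff(np.append(col_idx, w))
    counts = np.outer(row_n, col_n)
    if a.ndim == 3:
        counts = counts[..., None]
    return summed / counts


def segment_dab(
    image: CalibratedImage,
    mask: AnalysisMask,
    params: StainParams | None = None,
) -> StainMask:
    """Threshold the DAB channel inside the analysis mask.

    The RGB image is block-mean downsampled by ``analysis_scale_factor``,
    converted to OD, unmixed, and the DAB concentration compared against
    ``dab_od_threshold`` (inclusive).  The analysis mask is downsampled by
    block majority so a coarse pixel is scored when more than half of its
    source pixels were inside the ROI.
    """
    params = params or StainParams()
    f = int(params.analysis_scale_factor)
    h, w = image.shape
    if f > h or f > w:
        raise ValueError(
            f"analysis_scale_factor {f} exceeds image extent {h}x{w}"
        )
    if mask.mask.shape != (h, w):
        raise ValueError("image and mask dimensions disagree")

    rgb_small = _block_mean(image.pixels, f)
    mask_small = _block_mean(mask.mask.astype(float), f) > 0.5
    conc = deconvolve(rgb_to_od(rgb_small), params)
    dab = conc[..., 1]
    stained = (dab >= params.dab_od_threshold) & mask_small
    return StainMask(
        mask=stained,
        microns_per_pixel=image.microns_per_pixel * f,
        params_used=params,
    )


def load_stain_params(path: str | Path) -> StainParams:
    """Read :class:`StainParams` from a YAML/TOML-style key-value file.

    Recognized keys: ``dab_od_threshold``, ``analysis_scale_factor``,
    ``od_matrix`` (nested 3x3 list).  Missing keys keep their defaults.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs = {}
    if "dab_od_threshold" in doc:
        kwargs["dab_od_threshold"] = float(doc["dab_od_threshold"])
    if "analysis_scale_factor" in doc:
        kwargs["analysis_scale_factor"] = int(doc["analysis_scale_factor"])
    if "od_matrix" in doc:
        kwargs["od_matrix"] = np.asarray(doc["od_matrix"], dtype=float)
    return StainParams(**kwargs)
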