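"""Pixel-wise gray-to-dilution calibration and dilution-factor maps.

Transmitted-light gray values inside a droplet report the z-averaged
local dye concentration. Stacks of stationary droplets at known dye
fractions are frame-averaged into one reference image per fraction;
an ordinary least-squares line fitted per pixel (fraction against
averaged gray) then converts any measured gray value into a local
z-averaged dye fraction, analogous to applying the Beer–Lambert law
in its linearised small-absorbance regime. Integrating such a map over
the intradroplet pixels yields the overall dilution factor
``DF = C_pre / C_post``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .gating import to_grayscale
from .stacks import ImageStack, Roi

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationModel",
    "DilutionMap",
    "fit_calibration",
    "segment_droplet",
    "map_dilution",
    "overall_dilution",
]


@dataclasses.dataclass
class CalibrationModel:
    """Per-pixel linear map from gray value to z-averaged dye fraction.

    ``fraction = slope * gray + intercept`` wherever the model is
    defined; pixels outside every calibration droplet mask, or with a
    singular fit, hold NaN coefficients.
    """

    slope: np.ndarray
    intercept: np.ndarray
    fit_residual: np.ndarray
    n_frames_averaged: int
    fractions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.slope.shape != self.intercept.shape or self.slope.shape != self.fit_residual.shape:
            raise ValueError("slope, intercept and fit_residual must share one shape")

    @property
    def domain(self) -> np.ndarray:
        """Boolean mask of pixels where the model is defined."""
        return np.isfinite(self.slope) & np.isfinite(self.intercept)

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        planes = np.stack([self.slope, self.intercept, self.fit_residual]).astype(np.float32)
        tifffile.imwrite(directory / "calibration_model.tif", planes, photometric="minisblack")
        meta = {
            "planes": ["slope", "intercept", "fit_residual"],
            "n_frames_averaged": self.n_frames_averaged,
            "fractions": list(self.fractions),
        }
        (directory / "calibration_model.json").write_text(json.dumps(meta, indent=1))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "CalibrationModel":
        directory = Path(directory)
        planes = np.asarray(tifffile.imread(directory / "calibration_model.tif"), dtype=float)
        meta = json.loads((directory / "calibration_model.json").read_text())
        return cls(
            slope=planes[0],
            intercept=planes[1],
            fit_residual=planes[2],
            n_frames_averaged=int(meta["n_frames_averaged"]),
            fractions=tuple(meta.get("fractions", ())),
        )


@dataclasses.dataclass
class DilutionMap:
    """Per-pixel z-averaged dye fraction relative to the unwashed level."""

    fraction: np.ndarray
    mask: np.ndarray
    clipped_count: int

    def __post_init__(self) -> None:
        if self.fraction.shape != self.mask.shape:
            raise ValueError("fraction and mask must share one shape")


def segment_droplet(
    frame: np.ndarray,
    roi: Roi,
    wall_exclusion: float = 0.0,
    threshold: float | str = "otsu",
) -> np.ndarray:
    """Threshold-segment the intradroplet region, excluding wall rows.

    Returns a full-frame boolean mask of intradroplet pixels (dye is
    darker than background). The top and bottom ``wall_exclusion``
    fraction of the ROI rows are removed because pixels adjacent to the
    channel walls suffer optical aberrations in real devices.
    """
    if not 0.0 <= wall_exclusion <= 0.4:
        raise ValueError(f"wall_exclusion must lie in [0, 0.4], got {wall_exclusion}")
    gray = to_grayscale(frame)
    sub = roi.crop(gray)
    if threshold == "otsu":
        from skimage.filters import threshold_otsu

        if np.ptp(sub) == 0:
            raise ValueError("cannot segment a droplet in a flat frame (empty mask)")
        thresh = threshold_otsu(sub)
    else:
        thresh = float(threshold)
    foreground = sub < thresh
    n_excl = int(round(wall_exclusion * roi.height))
    if n_excl:
        foreground[:n_excl, :] = False
        foreground[roi.height - n_excl :, :] = False
    if not foreground.any():
        raise ValueError("droplet mask is empty after thresholding and wall exclusion")
    mask = np.zeros(gray.shape, dtype=bool)
    mask[roi.row_start : roi.row_stop, roi.col_start : roi.col_stop] = foreground
    return mask


def fit_calibration(
    stacks: list[ImageStack],
    fractions: list[float],
    roi: Roi | None = None,
    wall_exclusion: float = 0.0,
) -> CalibrationModel:
    """Fit the per-pixel linear gray-to-fraction calibration.

    Each stack (one per known dye fraction, co-registered stationary
    droplets) is grayscale-converted and frame-averaged into a single
    reference image. The droplet mask is segmented on the reference with
    the highest dye fraction — the strongest-contrast image — and shared
    across fractions, which is exact for co-registered stationary
    droplets. Per pixel inside the mask, ordinary least squares of
    fraction against averaged gray across the references yields the
    slope and intercept; pixels whose gray does not vary across
    fractions are marked undefined (NaN), not fatal.
    """
    if len(stacks) != len(fractions):
        raise ValueError("need exactly one stack per calibration fraction")
    if len(set(map(float, fractions))) < 2:
        raise ValueError("need at least 2 distinct calibration fractions")
    fracs = np.asarray(fractions, dtype=float)

    references = []
    for stack in stacks:
        frames = stack.frames
        if frames.ndim == 4:
            frames = frames.mean(axis=-1)  # RGB -> gray, unweighted mean
        references.append(np.asarray(frames, dtype=float).mean(axis=0))
    refs = np.stack(references)  # (m, h, w)

    shape = refs.shape[1:]
    if roi is None:
        roi = Roi(0, shape[0], 0, shape[1])
    mask = segment_droplet(refs[int(np.argmax(fracs))], roi, wall_exclusion=wall_exclusion)

    gbar = refs.mean(axis=0)
    ybar = fracs.mean()
    dg = refs - gbar[None]
    dy = fracs - ybar
    sxx = np.einsum("mhw,mhw->hw", dg, dg)
    sxy = np.einsum("m,mhw->hw", dy, dg)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 1e-18, sxy / sxx, np.nan)
    intercept = ybar - slope * gbar
    predicted = slope[None] * refs + intercept[None]
    residual = np.sqrt(np.mean((fracs[:, None, None] - predicted) ** 2, axis=0))

    outside = ~mask
    slope = slope.copy()
    intercept = intercept.copy()
    residual = residual.copy()
    slope[outside] = np.nan
    intercept[outside] = np.nan
    residual[outside] = np.nan
    n_singular = int(np.sum(mask & ~np.isfinite(slope)))
    if n_singular:
        logger.warning("%d intradroplet pixels had a singular calibration fit", n_singular)
    return CalibrationModel(
        slope=slope,
        intercept=intercept,
        fit_residual=residual,
        n_frames_averaged=min(s.n_frames for s in stacks),
        fractions=tuple(float(f) for f in fractions),
    )


def map_dilution(
    frame: np.ndarray,
    model: CalibrationModel,
    mask: np.ndarray | None = None,
) -> DilutionMap:
    """Convert a gray frame into a z-averaged dye-fraction map.

    The per-pixel linear model is applied on ``mask`` (default: the
    model domain); values are clipped into the physical range [0, 1]
    with the clip count recorded, and pixels where the model is
    undefined are excluded from the output mask.
    """
    gray = np.asarray(to_grayscale(frame), dtype=float)
    if gray.shape != model.slope.shape:
        raise ValueError(
            f"frame shape {gray.shape} does not match calibration shape {model.slope.shape}"
        )
    effective = model.domain if mask is None else (np.asarray(mask, dtype=bool) & model.domain)
    if not effective.any():
        raise ValueError("mask and calibration-model domain are disjoint")
    raw = model.slope * gray + model.intercept
    clipped = np.clip(raw, 0.0, 1.0)
    clipped_count = int(np.sum((raw != clipped) & effective))
    fraction = np.where(effective, clipped, np.nan)
    return DilutionMap(fraction=fraction, mask=effective, clipped_count=clipped_count)


def overall_dilution(dmap: DilutionMap) -> float:
    """Integrate a dilution map into one overall dilution factor.

    ``DF = 1 / mean(fraction)`` with an unweighted mean over the
    intradroplet mask. A zero mean (complete washing, below detection)
    is reported as ``inf`` with a warning rather than an exception.
    """
    if not dmap.mask.any():
        raise ValueError("dilution map has an empty mask")
    mean_fraction = float(np.mean(dmap.fraction[dmap.mask]))
    if mean_fraction == 0.0:
        warnings.warn("mean dye fraction is zero; dilution factor is infinite", stacklevel=2)
        return float("inf")
    return 1.0 / mean_fraction
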