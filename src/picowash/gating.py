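"""Retrospective gating: reorder randomly-phased frames by droplet position.

A fast periodic process (a droplet transiting a washer in ~0.5 ms) can
be reconstructed from many asynchronously captured short-exposure
frames by estimating, per frame, the position of a reference droplet
and sorting the frames by that position — the droplet-microfluidic
analogue of retrospectively gated cardiac imaging.

Two localizers are provided: intensity-threshold segmentation followed
by the centroid of the largest dark component, and exhaustive
sum-square-difference (SSD) template matching of a reference droplet
patch. Positions are reported as absolute frame columns; the SSD
candidate position ``x`` is the leftmost column of the compared
subimage (0-based).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from skimage import measure

from .stacks import ImageStack, Roi

logger = logging.getLogger(__name__)

__all__ = [
    "ReferencePatch",
    "SSDProfile",
    "DropletLocalization",
    "ReconstructedSequence",
    "to_grayscale",
    "locate_centroid",
    "ssd_profile",
    "locate_template",
    "reconstruct_sequence",
]


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Collapse an RGB frame to gray by the unweighted R-G-B mean.

    Already-gray input is returned unchanged.
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[-1] == 3:
        return frame.mean(axis=-1)
    raise ValueError(f"expected a gray (h, w) or RGB (h, w, 3) frame, got shape {frame.shape}")


@dataclasses.dataclass(frozen=True)
class ReferencePatch:
    """Cropped reference droplet image used for template matching."""

    G_ref: np.ndarray
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        patch = np.asarray(self.G_ref, dtype=float)
        if patch.ndim != 2 or patch.size == 0:
            raise ValueError("reference patch must be a non-empty 2-D gray image")
        object.__setattr__(self, "G_ref", patch)

    @property
    def shape(self) -> tuple[int, int]:
        return self.G_ref.shape

    @classmethod
    def from_frame(cls, frame: np.ndarray, roi: Roi) -> "ReferencePatch":
        return cls(G_ref=roi.crop(to_grayscale(frame)), origin=(roi.row_start, roi.col_start))


@dataclasses.dataclass(frozen=True)
class SSDProfile:
    """Sum-square difference E(x) over candidate patch positions.

    ``E[i]`` corresponds to absolute frame column ``x = x_min + i`` (the
    leftmost column of the subimage); ``valid_range = (x_min, x_max)``
    is half-open.
    """

    E: np.ndarray
    valid_range: tuple[int, int]

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=float)
        lo, hi = self.valid_range
        if E.shape != (hi - lo,):
            raise ValueError("E length must equal the valid range extent")
        object.__setattr__(self, "E", E)

    def at(self, x: int) -> float:
        lo, hi = self.valid_range
        if not lo <= x < hi:
            raise ValueError(f"position {x} outside valid range [{lo}, {hi})")
        return float(self.E[x - lo])


@dataclasses.dataclass(frozen=True)
class DropletLocalization:
    """Estimated reference-droplet position in one frame."""

    frame_index: int
    x_ref: float
    method: str
    valid: bool


@dataclasses.dataclass(frozen=True)
class ReconstructedSequence:
    """Frames reordered by reference position (ascending)."""

    ordering: np.ndarray
    positions: np.ndarray
    pseudo_times_ms: np.ndarray | None
    n_dropped: int


def locate_centroid(
    frame: np.ndarray,
    roi: Roi,
    threshold: float | str = "otsu",
    min_area: int = 1,
    frame_index: int = -1,
) -> DropletLocalization:
    """Locate a droplet as the centroid column of the largest dark blob.

    Pixels darker than ``threshold`` (dye absorbs light) inside the ROI
    form the foreground; ``x_ref`` is the intensity-unweighted centroid
    column of the largest connected component, in absolute frame
    columns. ``valid`` is False when no component reaches ``min_area``.
    """
    gray = to_grayscale(frame)
    sub = roi.crop(gray)
    if threshold == "otsu":
        from skimage.filters import threshold_otsu

        if np.ptp(sub) == 0:
            return DropletLocalization(frame_index, np.nan, "centroid", False)
        thresh = threshold_otsu(sub)
    else:
        thresh = float(threshold)
    foreground = sub < thresh
    if not foreground.any():
        return DropletLocalization(frame_index, np.nan, "centroid", False)
    labels = measure.label(foreground)
    regions = measure.regionprops(labels)
    largest = max(regions, key=lambda r: r.area)
    if largest.area < min_area:
        return DropletLocalization(frame_index, np.nan, "centroid", False)
    x_ref = largest.centroid[1] + roi.col_start
    return DropletLocalization(frame_index, float(x_ref), "centroid", True)


def ssd_profile(frame: np.ndarray, roi: Roi, ref: ReferencePatch) -> SSDProfile:
    """Exhaustive SSD of a reference patch against every column offset.

    For each candidate ``x`` the subimage whose leftmost column is ``x``
    (and whose rows are the top ``patch_rows`` rows of the ROI) is
    compared to the patch by ``E(x) = sum_k (g_k(x) - G_ref,k)**2`` over
    all pixel pairs; every position in the valid range is evaluated.
    """
    gray = to_grayscale(frame)
    sub = roi.crop(gray)
    ph, pw = ref.shape
    if ph > roi.height or pw > roi.width:
        raise ValueError(
            f"patch shape {ref.shape} exceeds ROI shape ({roi.height}, {roi.width})"
        )
    band = np.ascontiguousarray(sub[:ph, :], dtype=float)
    windows = np.lib.stride_tricks.sliding_window_view(band, (ph, pw))[0]
    diff = windows - ref.G_ref[None]
    E = np.einsum("xij,xij->x", diff, diff)
    lo = roi.col_start
    return SSDProfile(E=E, valid_range=(lo, lo + E.shape[0]))


def locate_template(
    frame: np.ndarray,
    roi: Roi,
    ref: ReferencePatch,
    bounds: tuple[int, int] | None = None,
    mismatch_ceiling: float = np.inf,
    frame_index: int = -1,
) -> DropletLocalization:
    """Locate a droplet as the SSD argmin within position bounds.

    ``bounds`` (absolute columns, half-open) defaults to the central
    third of the ROI so that exactly one droplet of a periodic train can
    occupy it. Ties take the smallest ``x``; a minimum above
    ``mismatch_ceiling`` marks the frame invalid (no droplet in bounds).
    """
    profile = ssd_profile(frame, roi, ref)
    lo, hi = profile.valid_range
    if bounds is None:
        third = roi.width // 3
        bounds = (roi.col_start + third, roi.col_start + 2 * third)
    b_lo, b_hi = int(bounds[0]), int(bounds[1])
    b_lo, b_hi = max(b_lo, lo), min(b_hi, hi)
    if b_hi <= b_lo:
        raise ValueError(f"empty template-search bounds [{bounds[0]}, {bounds[1]}) "
                         f"within evaluable range [{lo}, {hi})")
    window = profile.E[b_lo - lo : b_hi - lo]
    idx = int(np.argmin(window))  # argmin takes the first (smallest x) on ties
    if np.count_nonzero(window == window[idx]) > 1:
        logger.debug("frame %d: SSD tie within bounds, keeping smallest x", frame_index)
    x_ref = b_lo + idx
    valid = bool(window[idx] <= mismatch_ceiling)
    return DropletLocalization(frame_index, float(x_ref), "template", valid)


def reconstruct_sequence(
    stack: ImageStack | None,
    localizations: list[DropletLocalization],
    velocity_um_per_ms: float | None = None,
    px_size: float | None = None,
) -> ReconstructedSequence:
    """Sort frames by localized reference position to rebuild the motion.

    Invalid frames are dropped (counted); remaining frames are sorted
    ascending by ``x_ref`` with ties broken by original frame index.
    When a velocity is supplied, pseudo-times are assigned as
    ``(x_ref - min x_ref) * px_size / velocity``.
    """
    valid = [loc for loc in localizations if loc.valid]
    n_dropped = len(localizations) - len(valid)
    if n_dropped:
        logger.info("dropped %d frames without a localized droplet", n_dropped)
    if len(valid) < 2:
        raise ValueError(f"need at least 2 valid localizations, got {len(valid)}")
    order = sorted(valid, key=lambda loc: (loc.x_ref, loc.frame_index))
    ordering = np.array([loc.frame_index for loc in order], dtype=int)
    positions = np.array([loc.x_ref for loc in order], dtype=float)
    pseudo_times = None
    if velocity_um_per_ms is not None:
        if px_size is None:
            px_size = stack.px_size if stack is not None else 1.0
        pseudo_times = (positions - positions[0]) * px_size / velocity_um_per_ms
    return ReconstructedSequence(
        ordering=ordering,
        positions=positions,
        pseudo_times_ms=pseudo_times,
        n_dropped=n_dropped,
    )
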