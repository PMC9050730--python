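"""Washing-efficiency quantification from long-exposure streak images.

Long exposures (much longer than a droplet transit) average the
fluorescence of dye-laden droplets into a streak whose intensity at a
channel position is proportional to the droplet duty fraction
``p_droplet = L_drop / (L_drop + L_space)`` times the intradroplet dye
concentration. Three aligned images — device operating (``I_wash``),
device idle (``I_cntl``) and dropletless background (``I_back``) — give
the normalized profile

    I(x) = (I_wash(x) - I_back(x)) / (I_cntl(x) - I_back(x))

and the dilution factor follows from segment averages of I(x) before
and after the washer, corrected for any plug-geometry change:

    DF = [<I_pre> * duty_post] / [<I_post> * duty_pre]

The unknown proportionality constant between intensity and
concentration cancels in the ratio, so no absolute concentration is
ever reported from long-exposure data.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .stacks import ImageStack, Roi

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityProfile",
    "PlugGeometry",
    "WashResult",
    "SerialDilutionResult",
    "column_profile",
    "normalize_profile",
    "plug_geometry",
    "dilution_factor",
    "serial_dilution",
    "bead_retention",
]


@dataclasses.dataclass(frozen=True)
class IntensityProfile:
    """Per-column intensities along the emulsion channel and their
    normalized ratio I(x); columns with a near-zero denominator are
    flagged invalid and never enter downstream averages."""

    x: np.ndarray
    I_wash: np.ndarray
    I_cntl: np.ndarray
    I_back: np.ndarray
    I_norm: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        n = self.x.shape[0]
        for name in ("I_wash", "I_cntl", "I_back", "I_norm", "valid"):
            if getattr(self, name).shape != (n,):
                raise ValueError("profile vectors must share one length")


@dataclasses.dataclass(frozen=True)
class PlugGeometry:
    """Plug-train geometry statistics measured from imagery."""

    L_drop: float
    L_space: float
    cv_drop: float = 0.0
    n_measured: int = 0

    def __post_init__(self) -> None:
        if self.L_drop <= 0:
            raise ValueError(f"L_drop must be positive, got {self.L_drop}")
        if self.cv_drop < 0:
            raise ValueError("cv_drop must be non-negative")
        if not 0.0 < self.duty_fraction <= 1.0:
            raise ValueError(f"duty fraction must lie in (0, 1], got {self.duty_fraction}")

    @property
    def duty_fraction(self) -> float:
        return self.L_drop / (self.L_drop + self.L_space)

    @property
    def cv_percent(self) -> float:
        """Coefficient of variation of plug length, SD/mean in percent."""
        return 100.0 * self.cv_drop


@dataclasses.dataclass(frozen=True)
class WashResult:
    """Dilution factor of one washing stage with its inputs."""

    I_pre_mean: float
    I_post_mean: float
    geom_pre: PlugGeometry
    geom_post: PlugGeometry
    DF: float
    segment_bounds: tuple[tuple[float, float], tuple[float, float]]


@dataclasses.dataclass(frozen=True)
class SerialDilutionResult:
    """Per-stage and overall dilution factors of washers in series."""

    stages: tuple[WashResult, ...]
    overall: WashResult
    segment_means: tuple[float, ...]

    @property
    def stage_dfs(self) -> tuple[float, ...]:
        return tuple(s.DF for s in self.stages)

    @property
    def overall_df(self) -> float:
        return self.overall.DF


def column_profile(image: np.ndarray, roi: Roi) -> np.ndarray:
    """Integrate gray values over the channel cross-section per column."""
    if roi.height < 1:
        raise ValueError("ROI must span at least one channel row")
    sub = roi.crop(np.asarray(image, dtype=float))
    return sub.sum(axis=0)


def normalize_profile(
    I_wash: np.ndarray,
    I_cntl: np.ndarray,
    I_back: np.ndarray,
    x: np.ndarray | None = None,
    eps: float | None = None,
) -> IntensityProfile:
    """Compute I(x) = (I_wash - I_back) / (I_cntl - I_back).

    ``eps`` defaults to 1e-6 times the dynamic range of the denominator;
    columns with ``|I_cntl - I_back| <= eps`` are flagged invalid and
    excluded from every downstream average (never zero-filled).
    """
    I_wash = np.asarray(I_wash, dtype=float)
    I_cntl = np.asarray(I_cntl, dtype=float)
    I_back = np.asarray(I_back, dtype=float)
    if not I_wash.shape == I_cntl.shape == I_back.shape:
        raise ValueError("the three intensity profiles must share one length")
    denom = I_cntl - I_back
    if eps is None:
        eps = 1e-6 * float(np.max(np.abs(denom)))
    valid = np.abs(denom) > eps
    if not valid.any():
        raise ValueError("every column has a vanishing control-minus-background denominator")
    I_norm = np.full_like(denom, np.nan)
    I_norm[valid] = (I_wash[valid] - I_back[valid]) / denom[valid]
    if x is None:
        x = np.arange(I_wash.shape[0], dtype=float)
    return IntensityProfile(
        x=np.asarray(x, dtype=float),
        I_wash=I_wash,
        I_cntl=I_cntl,
        I_back=I_back,
        I_norm=I_norm,
        valid=valid,
    )


def plug_geometry(
    stack: ImageStack,
    roi: Roi,
    threshold: float | str = "otsu",
    min_droplets: int = 5,
) -> PlugGeometry:
    """Measure plug length, spacing and length CV from short-exposure frames.

    Per frame, a column is counted as intradroplet when its darkest ROI
    pixel falls below the threshold (the plug's mid-row reaches its full
    nominal extent, so the rounded end caps bias the measured length by
    under a pixel). Runs of consecutive plug columns give individual
    plugs; runs touching the ROI edges are excluded as partially
    visible. Spacing is the mean gap between consecutive plug centers
    minus the mean plug length.
    """
    frames = stack.frames
    if frames.ndim == 4:
        frames = frames.mean(axis=-1)
    if threshold == "otsu":
        from skimage.filters import threshold_otsu

        thresh = threshold_otsu(roi.crop(np.asarray(frames, dtype=float)))
    else:
        thresh = float(threshold)

    lengths_px: list[float] = []
    periods_px: list[float] = []
    for frame in frames:
        sub = roi.crop(np.asarray(frame, dtype=float))
        dark = sub.min(axis=0) < thresh
        # run extraction: starts where dark turns on, stops where it turns off
        padded = np.concatenate(([False], dark, [False]))
        changes = np.flatnonzero(np.diff(padded.astype(np.int8)))
        run_starts, run_stops = changes[0::2], changes[1::2]
        centers = []
        for s, e in zip(run_starts, run_stops):
            if s == 0 or e == dark.size:
                continue  # partial plug at the ROI edge
            lengths_px.append(float(e - s))
            centers.append((s + e) / 2.0)
        periods_px.extend(np.diff(centers).tolist())

    n = len(lengths_px)
    if n < min_droplets:
        raise ValueError(f"only {n} fully visible droplets measured; need >= {min_droplets}")
    lengths_um = np.asarray(lengths_px) * stack.px_size
    mean_len = float(lengths_um.mean())
    cv = float(lengths_um.std(ddof=1) / mean_len) if n > 1 else 0.0
    if periods_px:
        mean_period = float(np.mean(periods_px)) * stack.px_size
        spacing = max(mean_period - mean_len, 0.0)
    else:
        raise ValueError("no consecutive plug pairs visible; cannot estimate spacing")
    return PlugGeometry(L_drop=mean_len, L_space=spacing, cv_drop=cv, n_measured=n)


def dilution_factor(
    I_pre_mean: float,
    I_post_mean: float,
    geom_pre: PlugGeometry,
    geom_post: PlugGeometry,
) -> float:
    """Dilution factor from segment-averaged normalized intensities.

    ``DF = [<I_pre> * duty_post] / [<I_post> * duty_pre]`` where the
    duty fractions account for plug length/spacing changes across the
    washer. The unknown intensity-to-concentration constant cancels.
    """
    if I_post_mean < 0:
        raise ValueError(f"invalid negative post-washer intensity {I_post_mean}")
    if I_post_mean == 0:
        raise ValueError(
            "post-washer normalized intensity is zero: dye fully washed below "
            "detection; the dilution factor is unbounded"
        )
    return (I_pre_mean * geom_post.duty_fraction) / (I_post_mean * geom_pre.duty_fraction)


def _segment_mean(
    profile: IntensityProfile, lo: float, hi: float, name: str, min_columns: int = 10
) -> float:
    select = (profile.x >= lo) & (profile.x < hi) & profile.valid
    n = int(select.sum())
    if n < min_columns:
        raise ValueError(
            f"segment {name!r} spanning x in [{lo}, {hi}) has {n} valid columns; "
            f"need >= {min_columns}"
        )
    return float(profile.I_norm[select].mean())


def serial_dilution(
    profile: IntensityProfile,
    washer_ranges: list[tuple[float, float]],
    geoms: PlugGeometry | list[PlugGeometry],
    guard: float | None = None,
    min_columns: int = 10,
) -> SerialDilutionResult:
    """Per-stage and overall dilution factors for washers in series.

    The profile is split into segments before the first washer, between
    consecutive washers, and after the last. Stage-k DF uses the
    segment means flanking washer k; the overall DF uses the first and
    last segments. A guard band of one plug length (of the adjacent
    segment's geometry, override with ``guard`` in x units) is excluded
    around each washer because dye removal ramps over a finite distance.
    Under constant geometry the stage DFs multiply exactly to the
    overall DF.
    """
    if not washer_ranges:
        raise ValueError("need at least one washer range")
    ranges = [(float(lo), float(hi)) for lo, hi in washer_ranges]
    for (lo, hi) in ranges:
        if hi <= lo:
            raise ValueError(f"washer range [{lo}, {hi}) is empty")
    for (a, b), (c, d) in zip(ranges, ranges[1:]):
        if c < b:
            raise ValueError("washer ranges must be ordered and non-overlapping")
    n_segments = len(ranges) + 1
    if isinstance(geoms, PlugGeometry):
        geoms = [geoms] * n_segments
    if len(geoms) != n_segments:
        raise ValueError(f"need {n_segments} plug geometries (one per segment), got {len(geoms)}")

    x_lo, x_hi = float(profile.x[0]), float(profile.x[-1]) + 1.0
    bounds: list[tuple[float, float]] = []
    for k in range(n_segments):
        lo = x_lo if k == 0 else ranges[k - 1][1]
        hi = x_hi if k == len(ranges) else ranges[k][0]
        g_lo = guard if guard is not None else (geoms[k].L_drop if k > 0 else 0.0)
        g_hi = guard if guard is not None else (geoms[k].L_drop if k < len(ranges) else 0.0)
        bounds.append((lo + (g_lo if k > 0 else 0.0), hi - (g_hi if k < len(ranges) else 0.0)))

    names = (
        ["before washer 1"]
        + [f"between washers {k} and {k + 1}" for k in range(1, len(ranges))]
        + ["after last washer"]
    )
    means = tuple(
        _segment_mean(profile, lo, hi, name, min_columns)
        for (lo, hi), name in zip(bounds, names)
    )

    stages = tuple(
        WashResult(
            I_pre_mean=means[k],
            I_post_mean=means[k + 1],
            geom_pre=geoms[k],
            geom_post=geoms[k + 1],
            DF=dilution_factor(means[k], means[k + 1], geoms[k], geoms[k + 1]),
            segment_bounds=(bounds[k], bounds[k + 1]),
        )
        for k in range(len(ranges))
    )
    overall = WashResult(
        I_pre_mean=means[0],
        I_post_mean=means[-1],
        geom_pre=geoms[0],
        geom_post=geoms[-1],
        DF=dilution_factor(means[0], means[-1], geoms[0], geoms[-1]),
        segment_bounds=(bounds[0], bounds[-1]),
    )
    return SerialDilutionResult(stages=stages, overall=overall, segment_means=means)


def bead_retention(
    prop_pre: float,
    prop_post: float,
    n_pre: int | None = None,
    n_post: int | None = None,
) -> float:
    """Bead retention across the washer, as a percentage.

    The proportion of fully formed droplets containing a microparticle
    downstream of the washer divided by the proportion upstream. Values
    above 100% are possible under sampling noise and are flagged with a
    warning, not rejected. ``n_pre``/``n_post`` are droplet counts for
    reporting only.
    """
    if not 0.0 < prop_pre <= 1.0:
        raise ValueError(f"prop_pre must lie in (0, 1], got {prop_pre}")
    if not 0.0 <= prop_post <= 1.0:
        raise ValueError(f"prop_post must lie in [0, 1], got {prop_post}")
    retention = 100.0 * prop_post / prop_pre
    if retention > 100.0:
        logger.warning(
            "bead retention %.1f%% exceeds 100%% (sampling noise; n_pre=%s, n_post=%s)",
            retention, n_pre, n_post,
        )
    return retention
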