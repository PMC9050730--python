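"""Synthetic droplet-channel scene generation with known ground truth.

The generator emulates a transmitted-light view of a water-in-oil plug
train moving through a rectangular microchannel past one or more
on-chip washing units. Each washing unit reduces the intradroplet dye
concentration by a known fold factor ("stage dilution") over a short
spatial ramp, so every downstream analysis stage — retrospective
gating, pixel-wise calibration, long-exposure dilution quantification —
can be validated against an imposed ground truth.

Rendering model
---------------
* Coordinates: ``x`` is the flow axis (columns, increasing downstream),
  ``y`` runs across the channel (rows); 0-based, half-open pixel
  intervals. All lengths are stored in micrometers and converted to
  pixels only at render time.
* Droplets are rectangular plugs with rounded ends approximated by a
  half-disc cap of radius half the imaged channel breadth.
* Transmitted-light attenuation is linear in the local z-averaged dye
  fraction: ``gray = background_gray - attenuation_gray * fraction``
  inside a plug, plus additive Gaussian noise. This linearised
  absorbance keeps the downstream per-pixel linear calibration exactly
  identifiable.
* The plug train is periodic with period ``L_drop + L_space``; a frame's
  *phase* is the position offset of the train (μm), drawn uniformly at
  random for short-exposure frames to mimic asynchronous acquisition of
  a fast periodic process.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .stacks import ImageStack

__all__ = [
    "ChannelSpec",
    "PlugTrain",
    "WasherEvent",
    "Scene",
    "TransitTime",
    "build_scene",
    "transit_time",
    "dye_fraction_profile",
    "render_short_exposure",
    "render_long_exposure",
    "render_calibration_series",
    "scene_to_dict",
    "scene_from_dict",
]

#: μm³ per millilitre
_UM3_PER_ML = 1e12
#: milliseconds per hour
_MS_PER_H = 3.6e6

LONG_EXPOSURE_MODES = ("wash", "control", "background")


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value}")


@dataclasses.dataclass(frozen=True)
class ChannelSpec:
    """Geometry and flow of the emulsion channel.

    ``length_px`` columns along the flow axis and ``height_px`` rows
    across the channel define the rendered image; ``width_um`` (in-plane
    width, y) and ``height_um`` (out-of-plane depth, z) define the
    physical cross-section used for the mean flow velocity
    ``v = Q / A`` with volumetric flow ``flow_rate`` in mL/h.
    """

    length_px: int = 600
    height_px: int = 50
    px_size: float = 1.0
    width_um: float = 50.0
    height_um: float = 60.0
    flow_rate: float = 2.0

    def __post_init__(self) -> None:
        for name in ("length_px", "height_px", "px_size", "width_um", "height_um"):
            _require_positive(name, getattr(self, name))
        if self.flow_rate < 0:
            raise ValueError(f"flow_rate must be non-negative, got {self.flow_rate}")

    @property
    def length_um(self) -> float:
        return self.length_px * self.px_size

    @property
    def breadth_um(self) -> float:
        """Imaged channel breadth (row span) in μm."""
        return self.height_px * self.px_size

    @property
    def cross_section_um2(self) -> float:
        return self.width_um * self.height_um

    @property
    def velocity_um_per_ms(self) -> float:
        """Mean plug velocity Q/A in μm/ms."""
        if self.flow_rate == 0:
            raise ValueError("velocity undefined at zero flow rate")
        q_um3_per_ms = self.flow_rate * _UM3_PER_ML / _MS_PER_H
        return q_um3_per_ms / self.cross_section_um2


@dataclasses.dataclass(frozen=True)
class PlugTrain:
    """Periodic droplet plug train: plug length, spacing, dye load."""

    L_drop: float = 85.0
    L_space: float = 85.0
    n_droplets: int = 5
    dye_fraction_pre: float = 1.0

    def __post_init__(self) -> None:
        _require_positive("L_drop", self.L_drop)
        if self.L_space < 0:
            raise ValueError(f"L_space must be non-negative, got {self.L_space}")
        _require_positive("n_droplets", self.n_droplets)
        if not 0.0 <= self.dye_fraction_pre <= 1.0:
            raise ValueError(f"dye_fraction_pre must lie in [0, 1], got {self.dye_fraction_pre}")

    @property
    def period_um(self) -> float:
        return self.L_drop + self.L_space

    @property
    def duty_fraction(self) -> float:
        """Fraction of time a droplet occupies a given channel position."""
        return self.L_drop / self.period_um


@dataclasses.dataclass(frozen=True)
class WasherEvent:
    """Ground-truth washing stage at one channel position.

    ``stage_dilution`` is the fold reduction of intradroplet dye applied
    downstream; the reduction ramps linearly over ``gradient_span_um``
    columns centred at ``position_um``.
    """

    position_um: float
    stage_dilution: float
    gradient_span_um: float = 30.0

    def __post_init__(self) -> None:
        if self.stage_dilution < 1.0:
            raise ValueError(f"stage_dilution must be >= 1, got {self.stage_dilution}")
        if self.gradient_span_um < 0:
            raise ValueError("gradient_span_um must be non-negative")


@dataclasses.dataclass(frozen=True)
class Scene:
    """Complete synthetic scene: geometry, train, washers, noise, seed."""

    channel: ChannelSpec = dataclasses.field(default_factory=ChannelSpec)
    train: PlugTrain = dataclasses.field(default_factory=PlugTrain)
    washers: tuple[WasherEvent, ...] = ()
    noise_sd: float = 0.0
    background_gray: float = 200.0
    attenuation_gray: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "washers", tuple(self.washers))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        max_signal = self.attenuation_gray * self.train.dye_fraction_pre
        if not self.background_gray > max_signal >= 0:
            raise ValueError(
                "background_gray must exceed attenuation_gray * dye_fraction_pre "
                f"(got background {self.background_gray}, peak attenuation {max_signal})"
            )
        for w in self.washers:
            if not 0 <= w.position_um <= self.channel.length_um:
                raise ValueError(
                    f"washer position {w.position_um} μm outside channel "
                    f"[0, {self.channel.length_um}] μm"
                )


# ---------------------------------------------------------------------------
# construction

_CHANNEL_KEYS = {f.name for f in dataclasses.fields(ChannelSpec)}
_TRAIN_KEYS = {f.name for f in dataclasses.fields(PlugTrain)}
_WASHER_KEYS = {f.name for f in dataclasses.fields(WasherEvent)}
_SCENE_KEYS = {"channel", "train", "washers", "noise_sd", "background_gray", "attenuation_gray"}


def _check_keys(mapping: Mapping[str, Any], allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown {context} keys: {sorted(unknown)}; allowed: {sorted(allowed)}")


def build_scene(config: Mapping[str, Any] | None = None, seed: int = 0) -> Scene:
    """Build a validated :class:`Scene` from a nested parameter mapping.

    Unknown keys are rejected so configuration typos fail loudly.
    Identical ``(config, seed)`` pairs yield identical scenes.
    """
    config = dict(config or {})
    _check_keys(config, _SCENE_KEYS, "scene")
    channel_cfg = dict(config.get("channel", {}))
    _check_keys(channel_cfg, _CHANNEL_KEYS, "channel")
    train_cfg = dict(config.get("train", {}))
    _check_keys(train_cfg, _TRAIN_KEYS, "train")
    washers = []
    for i, w in enumerate(config.get("washers", [])):
        w = dict(w)
        _check_keys(w, _WASHER_KEYS, f"washers[{i}]")
        washers.append(WasherEvent(**w))
    return Scene(
        channel=ChannelSpec(**channel_cfg),
        train=PlugTrain(**train_cfg),
        washers=tuple(washers),
        noise_sd=float(config.get("noise_sd", 0.0)),
        background_gray=float(config.get("background_gray", 200.0)),
        attenuation_gray=float(config.get("attenuation_gray", 150.0)),
        seed=int(seed),
    )


def scene_to_dict(scene: Scene) -> dict[str, Any]:
    return {
        "channel": dataclasses.asdict(scene.channel),
        "train": dataclasses.asdict(scene.train),
        "washers": [dataclasses.asdict(w) for w in scene.washers],
        "noise_sd": scene.noise_sd,
        "background_gray": scene.background_gray,
        "attenuation_gray": scene.attenuation_gray,
        "seed": scene.seed,
    }


def scene_from_dict(data: Mapping[str, Any]) -> Scene:
    data = dict(data)
    seed = int(data.pop("seed", 0))
    return build_scene(data, seed=seed)


# ---------------------------------------------------------------------------
# transit time

def round_to_sig(value: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures (for display with a "~")."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round(value, sig - 1 - exponent)


@dataclasses.dataclass(frozen=True)
class TransitTime:
    """Washing timescale estimate: time to advance one plug length."""

    duration_ms: float
    min_field_frequency_khz: float

    @property
    def duration_display(self) -> str:
        return f"~{round_to_sig(self.duration_ms):g} ms"

    @property
    def frequency_display(self) -> str:
        return f"{round_to_sig(self.min_field_frequency_khz):g} kHz"


def transit_time(scene: Scene) -> TransitTime:
    """Estimate the washing timescale and minimum AC field frequency.

    The washing duration is the time a plug needs to advance one plug
    length at the mean velocity Q/A; the destabilising AC field must
    oscillate faster than the reciprocal of that duration so every
    passing droplet experiences a field maximum.
    """
    if scene.channel.flow_rate <= 0:
        raise ValueError("transit time requires a positive flow rate")
    duration_ms = scene.train.L_drop / scene.channel.velocity_um_per_ms
    return TransitTime(duration_ms=duration_ms, min_field_frequency_khz=1.0 / duration_ms)


# ---------------------------------------------------------------------------
# rendering

def dye_fraction_profile(scene: Scene, x_um: np.ndarray) -> np.ndarray:
    """Ground-truth z-averaged dye fraction as a function of channel position.

    Starts at ``dye_fraction_pre``; each washer multiplies by a factor
    ramping linearly from 1 to ``1/stage_dilution`` over its gradient
    span.
    """
    x_um = np.asarray(x_um, dtype=float)
    fraction = np.full_like(x_um, scene.train.dye_fraction_pre)
    for washer in scene.washers:
        half = washer.gradient_span_um / 2.0
        factor = np.interp(
            x_um,
            [washer.position_um - half, washer.position_um + half],
            [1.0, 1.0 / washer.stage_dilution],
        )
        fraction *= factor
    return fraction


def _column_centers_um(channel: ChannelSpec) -> np.ndarray:
    return (np.arange(channel.length_px) + 0.5) * channel.px_size


def _row_insets_um(channel: ChannelSpec) -> np.ndarray:
    """Per-row end-cap inset: how far the rounded plug end recedes from
    the plug's nominal extent at each row."""
    radius = channel.breadth_um / 2.0
    y = (np.arange(channel.height_px) + 0.5) * channel.px_size
    chord = np.sqrt(np.maximum(radius**2 - (y - radius) ** 2, 0.0))
    return radius - chord


def _occupancy_mask(scene: Scene, phase_um: float) -> np.ndarray:
    """Boolean (rows, cols) mask of intradroplet pixels at a given phase.

    Phase is the train offset: plug leading (left) edges sit at
    ``phase + k * period`` along x.
    """
    x = _column_centers_um(scene.channel)
    inset = _row_insets_um(scene.channel)
    rel = np.mod(x - phase_um, scene.train.period_um)
    return (rel[None, :] >= inset[:, None]) & (
        rel[None, :] < (scene.train.L_drop - inset)[:, None]
    )


def render_short_exposure(
    scene: Scene,
    n_frames: int,
    seed: int | None = None,
    phases: Sequence[float] | None = None,
) -> ImageStack:
    """Render randomly-phased short-exposure frames of the plug train.

    Each frame freezes the train at an independently uniform random
    phase (or at the caller-supplied ``phases``, e.g. a linear sweep).
    Ground-truth phases are recorded on the returned stack.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(scene.seed if seed is None else seed)
    total_extent = scene.train.n_droplets * scene.train.period_um
    if phases is None:
        phase_arr = rng.uniform(0.0, total_extent, size=n_frames)
    else:
        phase_arr = np.asarray(phases, dtype=float)
        if phase_arr.shape != (n_frames,):
            raise ValueError("phases must supply one value per frame")

    x = _column_centers_um(scene.channel)
    fraction = dye_fraction_profile(scene, x)
    frames = np.empty((n_frames, scene.channel.height_px, scene.channel.length_px), dtype=np.float32)
    for i, phase in enumerate(phase_arr):
        occ = _occupancy_mask(scene, phase)
        gray = scene.background_gray - scene.attenuation_gray * fraction[None, :] * occ
        if scene.noise_sd > 0:
            gray = gray + rng.normal(0.0, scene.noise_sd, size=gray.shape)
            gray = np.maximum(gray, 0.0)
        frames[i] = gray
    return ImageStack(
        frames=frames,
        exposure="short",
        px_size=scene.channel.px_size,
        phases=phase_arr,
        meta={"scene": scene_to_dict(scene)},
    )


def render_long_exposure(scene: Scene, mode: str = "wash") -> np.ndarray:
    """Analytic long-exposure (time-averaged) image of the moving train.

    With the phase uniformly distributed, the expected gray value at a
    pixel is ``background - attenuation * p(row) * fraction(x)`` where
    ``p(row)`` is the per-row occupancy duty fraction (plug length minus
    end-cap insets, over the train period). ``mode="control"`` disables
    all washers; ``mode="background"`` returns the dropletless baseline.
    """
    if mode not in LONG_EXPOSURE_MODES:
        raise ValueError(f"unknown mode {mode!r}; valid modes: {LONG_EXPOSURE_MODES}")
    shape = (scene.channel.height_px, scene.channel.length_px)
    if mode == "background":
        return np.full(shape, scene.background_gray, dtype=float)
    x = _column_centers_um(scene.channel)
    if mode == "control":
        fraction = np.full_like(x, scene.train.dye_fraction_pre)
    else:
        fraction = dye_fraction_profile(scene, x)
    inset = _row_insets_um(scene.channel)
    duty = np.maximum(scene.train.L_drop - 2.0 * inset, 0.0) / scene.train.period_um
    return scene.background_gray - scene.attenuation_gray * duty[:, None] * fraction[None, :]


def render_calibration_series(
    scene: Scene,
    fractions: Iterable[float],
    n_frames: int = 500,
    seed: int | None = None,
) -> list[ImageStack]:
    """Render stacks of stationary droplets at known uniform dye fractions.

    One stack per fraction; the droplet is parked at the channel centre
    (no field, no flow) and only the additive noise varies between
    frames, emulating the acquisition of reference images for the
    per-pixel gray-to-dilution calibration.
    """
    fractions = [float(f) for f in fractions]
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ValueError("calibration fractions must lie in [0, 1]")
    if len(set(fractions)) < 2:
        raise ValueError(
            "need at least 2 distinct dye fractions to constrain a linear calibration"
        )
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")

    # park one plug centred in the channel
    phase = scene.channel.length_um / 2.0 - scene.train.L_drop / 2.0
    occ = _occupancy_mask(scene, phase)
    seq = np.random.SeedSequence(scene.seed if seed is None else seed)
    stacks = []
    for fraction, child in zip(fractions, seq.spawn(len(fractions))):
        rng = np.random.default_rng(child)
        base = scene.background_gray - scene.attenuation_gray * fraction * occ
        frames = np.broadcast_to(
            base.astype(np.float32), (n_frames, *base.shape)
        ).copy()
        if scene.noise_sd > 0:
            frames = frames + rng.normal(0.0, scene.noise_sd, size=frames.shape).astype(np.float32)
            frames = np.maximum(frames, 0.0)
        stacks.append(
            ImageStack(
                frames=frames,
                exposure="calibration",
                px_size=scene.channel.px_size,
                meta={"scene": scene_to_dict(scene), "fraction": fraction},
            )
        )
    return stacks
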