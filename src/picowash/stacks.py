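"""Shared image containers and TIFF/JSON input/output.

The toolkit exchanges imagery as multi-page TIFF stacks with a JSON
sidecar carrying acquisition metadata (exposure class, pixel size,
per-frame ground-truth phases when the stack is synthetic). PNG is
accepted read-only for single frames.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile


@dataclasses.dataclass(frozen=True)
class Roi:
    """Half-open rectangular region of interest, 0-based pixel indices.

    Rows run across the channel, columns along the flow axis.
    """

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError("ROI start indices must be non-negative")
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError(
                "ROI must have positive extent: "
                f"rows [{self.row_start}, {self.row_stop}), "
                f"cols [{self.col_start}, {self.col_stop})"
            )

    @property
    def height(self) -> int:
        return self.row_stop - self.row_start

    @property
    def width(self) -> int:
        return self.col_stop - self.col_start

    def validate_within(self, shape: tuple[int, ...]) -> None:
        h, w = shape[-2], shape[-1]
        if self.row_stop > h or self.col_stop > w:
            raise ValueError(f"ROI {self} exceeds image shape ({h}, {w})")

    def crop(self, image: np.ndarray) -> np.ndarray:
        self.validate_within(image.shape)
        return image[..., self.row_start : self.row_stop, self.col_start : self.col_stop]

    @classmethod
    def from_string(cls, text: str) -> "Roi":
        """Parse ``"r0:r1,c0:c1"`` (e.g. ``"0:60,100:500"``)."""
        try:
            rows, cols = text.split(",")
            r0, r1 = (int(v) for v in rows.split(":"))
            c0, c1 = (int(v) for v in cols.split(":"))
        except ValueError as exc:
            raise ValueError(f"cannot parse ROI string {text!r}; expected 'r0:r1,c0:c1'") from exc
        return cls(r0, r1, c0, c1)

    def to_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ImageStack:
    """Ordered stack of co-registered frames.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)`` (grayscale) or
        ``(n_frames, rows, cols, 3)`` (RGB), gray values in arbitrary
        camera units.
    exposure
        Exposure class: ``"short"`` (droplets frozen at a random phase),
        ``"long"`` (time-averaged streaks) or ``"calibration"``
        (stationary droplets of known dye fraction).
    px_size
        Micrometers per pixel.
    phases
        Optional per-frame ground-truth plug-train phase (μm), recorded
        by the synthetic generator.
    meta
        Free-form metadata (scene description, dye fraction, ...).
    """

    frames: np.ndarray
    exposure: str = "short"
    px_size: float = 1.0
    phases: np.ndarray | None = None
    meta: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (n, rows, cols) or (n, rows, cols, 3)")
        if self.exposure not in ("short", "long", "calibration"):
            raise ValueError(f"unknown exposure class {self.exposure!r}")
        if self.px_size <= 0:
            raise ValueError("px_size must be positive")
        if self.phases is not None:
            self.phases = np.asarray(self.phases, dtype=float)
            if self.phases.shape != (self.n_frames,):
                raise ValueError("phases must hold one value per frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def save(self, path: str | Path, bitdepth: int = 16) -> Path:
        """Write a multi-page TIFF plus a ``.json`` sidecar.

        ``bitdepth`` of 8 or 16 selects the integer sample format; 32
        writes float32 without quantisation.
        """
        path = Path(path)
        if bitdepth == 8:
            data = np.clip(np.rint(self.frames), 0, 255).astype(np.uint8)
        elif bitdepth == 16:
            data = np.clip(np.rint(self.frames), 0, 65535).astype(np.uint16)
        elif bitdepth == 32:
            data = self.frames.astype(np.float32)
        else:
            raise ValueError("bitdepth must be 8, 16 or 32")
        tifffile.imwrite(path, data, photometric="minisblack")
        sidecar = {
            "exposure": self.exposure,
            "px_size": self.px_size,
            "phases": None if self.phases is None else self.phases.tolist(),
            "meta": self.meta,
        }
        sidecar_path = path.with_suffix(path.suffix + ".json")
        sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ImageStack":
        """Read a TIFF stack (or a single PNG frame) and its sidecar if present."""
        path = Path(path)
        if path.suffix.lower() == ".png":
            import imageio.v3 as iio

            frame = np.asarray(iio.imread(path), dtype=np.float32)
            frames = frame[None]
        else:
            frames = np.asarray(tifffile.imread(path), dtype=np.float32)
            if frames.ndim == 2:
                frames = frames[None]
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            phases = sidecar.get("phases")
            return cls(
                frames=frames,
                exposure=sidecar.get("exposure", "short"),
                px_size=float(sidecar.get("px_size", 1.0)),
                phases=None if phases is None else np.asarray(phases, dtype=float),
                meta=sidecar.get("meta", {}),
            )
        return cls(frames=frames)
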