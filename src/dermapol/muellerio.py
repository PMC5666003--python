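"""Containers and file I/O for Mueller matrix images and MMT parameter maps.

A :class:`MuellerImage` holds a per-pixel 4×4 Mueller matrix as an
``(H, W, 4, 4)`` float array.  On disk it is a 16-page 32-bit float TIFF in
channel order m11, m12, …, m44 (row-major) plus a JSON sidecar with the
acquisition metadata (pixel size, wavelength, normalization flag, stage
label, optional mask).  The default analysis grid is 400×400 pixels covering
0.8 × 0.8 cm².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from . import polcore

DEFAULT_SIZE = 400
DEFAULT_PIXEL_SIZE_CM = 0.8 / 400.0


@dataclass
class MuellerImage:
    """Per-pixel Mueller matrices with acquisition metadata."""

    elements: np.ndarray  # (H, W, 4, 4)
    pixel_size_cm: float = DEFAULT_PIXEL_SIZE_CM
    wavelength_nm: float = 632.0
    normalized: bool = True
    stage_label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=np.float64)
        if self.elements.ndim != 4 or self.elements.shape[2:] != (4, 4):
            raise ValueError("elements must have shape (H, W, 4, 4)")

    @property
    def height(self) -> int:
        return self.elements.shape[0]

    @property
    def width(self) -> int:
        return self.elements.shape[1]

    def normalize(self) -> "MuellerImage":
        """Return a copy with every pixel normalized by its m11 element."""
        return MuellerImage(
            polcore.normalize_by_m11(self.elements),
            pixel_size_cm=self.pixel_size_cm,
            wavelength_nm=self.wavelength_nm,
            normalized=True,
            stage_label=self.stage_label,
            metadata=dict(self.metadata),
        )

    def mmt(self) -> "MMTMaps":
        """Compute per-pixel MMT anisotropy/orientation maps."""
        el = self.elements if self.normalized else polcore.normalize_by_m11(self.elements)
        return MMTMaps(
            A_map=np.asarray(polcore.mmt_A(el)),
            alpha_map=np.asarray(polcore.mmt_alpha(el)),
            stage_label=self.stage_label,
        )


@dataclass
class MMTMaps:
    """MMT parameter maps: A ∈ [0,1], α ∈ (−90°, 90°] (NaN = no orientation)."""

    A_map: np.ndarray
    alpha_map: np.ndarray
    stage_label: str = ""

    @property
    def orientation_x(self) -> np.ndarray:
        """Fibre orientation x = α/4 in degrees (defined modulo 45°)."""
        return self.alpha_map / 4.0

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.alpha_map)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_mueller_image(path: str | Path, image: MuellerImage) -> None:
    """Write a 16-page float32 TIFF plus JSON metadata sidecar."""
    path = Path(path)
    pages = image.elements.reshape(image.height, image.width, 16)
    pages = np.moveaxis(pages, -1, 0).astype(np.float32)
    tifffile.imwrite(path, pages)
    meta = {
        "pixel_size_cm": image.pixel_size_cm,
        "wavelength_nm": image.wavelength_nm,
        "normalized": image.normalized,
        "stage_label": image.stage_label,
        **image.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_mueller_image(path: str | Path) -> MuellerImage:
    """Read a Mueller image container written by :func:`write_mueller_image`."""
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] != 16:
        raise ValueError(f"expected a 16-page TIFF, got shape {pages.shape}")
    elements = np.moveaxis(pages, 0, -1).reshape(pages.shape[1], pages.shape[2], 4, 4)
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return MuellerImage(
        elements.astype(np.float64),
        pixel_size_cm=meta.pop("pixel_size_cm", DEFAULT_PIXEL_SIZE_CM),
        wavelength_nm=meta.pop("wavelength_nm", 632.0),
        normalized=meta.pop("normalized", True),
        stage_label=meta.pop("stage_label", ""),
        metadata=meta,
    )


def write_frame_stack(path: str | Path, frames: np.ndarray, schedule: dict) -> None:
    """Write a (n_frames, H, W) intensity stack + JSON schedule sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))
    _sidecar_path(path).write_text(json.dumps(schedule, indent=2))


def read_frame_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    frames = tifffile.imread(path).astype(np.float64)
    sidecar = _sidecar_path(path)
    schedule = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return frames, schedule
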