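"""Geometric and intensity preprocessing for CTA-like volumes.

Every volume entering training or inference is brought to a fixed cubic shape
and a fixed Hounsfield-unit window of interest.  The clinical-scale geometry is
320x320x320 voxels; the desk-scale default used throughout the synthetic
experiments is 64x64x64.  The HU window is centred at 100 HU with width
700 HU, i.e. [-250, 450]; voxels outside the window are saturated to its
bounds.  Resize happens before windowing.

Interpolation is trilinear for intensities and nearest-neighbour for label
maps, so resampling can never invent label values.  Anisotropic inputs are
stretched to the cubic target without aspect-ratio preservation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateAxisError
from .volume_io import IntensityVolume, LabelVolume

DESK_SHAPE = (64, 64, 64)
CLINICAL_SHAPE = (320, 320, 320)


@dataclass
class PreprocessConfig:
    """Target geometry and HU window.

    Parameters
    ----------
    target_shape : output grid shape; each entry must be >= 8.
    hu_center, hu_width : window centre and width in HU; the window is
        ``[hu_center - hu_width/2, hu_center + hu_width/2]``.
    """

    target_shape: tuple[int, int, int] = DESK_SHAPE
    hu_center: float = 100.0
    hu_width: float = 700.0

    def __post_init__(self):
        self.target_shape = tuple(int(n) for n in self.target_shape)
        if len(self.target_shape) != 3 or any(n < 8 for n in self.target_shape):
            raise ValueError(f"target_shape entries must be >= 8, got {self.target_shape}")
        if self.hu_width <= 0:
            raise ValueError("hu_width must be positive")

    @property
    def hu_min(self) -> float:
        return self.hu_center - self.hu_width / 2.0

    @property
    def hu_max(self) -> float:
        return self.hu_center + self.hu_width / 2.0


def _zoom_factors(old_shape, new_shape):
    return [n / o for o, n in zip(old_shape, new_shape)]


def resize_volume(vol: IntensityVolume, cfg: PreprocessConfig) -> IntensityVolume:
    """Trilinearly resample a volume to ``cfg.target_shape``.

    Spacing is rescaled by old_shape/new_shape per axis so physical extent is
    preserved.  Endpoints map to endpoints (corner-aligned sampling), so a
    linear ramp keeps its end values under resizing.
    """
    old = vol.shape
    if any(n < 2 for n in old):
        raise DegenerateAxisError(f"cannot resize axis of length < 2, shape {old}")
    new = cfg.target_shape
    if tuple(old) == new:
        return IntensityVolume(vol.data.copy(), vol.spacing)
    out = _resample(vol.data.astype(np.float64), new, order=1)
    spacing = tuple(s * o / n for s, o, n in zip(vol.spacing, old, new))
    return IntensityVolume(out.astype(np.float32), spacing)


def resize_labels(lv: LabelVolume, cfg: PreprocessConfig) -> LabelVolume:
    """Nearest-neighbour resample of a label map to ``cfg.target_shape``."""
    old = lv.shape
    new = cfg.target_shape
    if tuple(old) == new:
        return LabelVolume(lv.data.copy(), lv.spacing)
    out = _resample(lv.data.astype(np.float64), new, order=0)
    spacing = tuple(s * o / n for s, o, n in zip(lv.spacing, old, new))
    return LabelVolume(out.astype(np.uint8), spacing)


def _resample(data: np.ndarray, new_shape, order: int) -> np.ndarray:
    """Corner-aligned resampling onto a regular grid of ``new_shape``."""
    coords = np.meshgrid(
        *[
            np.linspace(0.0, o - 1.0, n) if n > 1 else np.array([(o - 1.0) / 2.0])
            for o, n in zip(data.shape, new_shape)
        ],
        indexing="ij",
    )
    return ndimage.map_coordinates(
        data, np.stack(coords), order=order, mode="nearest"
    )


def hu_window(vol: IntensityVolume, cfg: PreprocessConfig) -> IntensityVolume:
    """Saturate intensities to the HU window; idempotent by construction."""
    out = np.clip(vol.data, cfg.hu_min, cfg.hu_max)
    return IntensityVolume(out, vol.spacing)


def to_unit_range(vol: IntensityVolume, cfg: PreprocessConfig) -> IntensityVolume:
    """Map the HU window affinely onto [0, 1] for network input.

    Assumes ``vol`` has already been windowed; values outside the window are
    clipped again so the output is always in [0, 1].
    """
    out = (vol.data - cfg.hu_min) / (cfg.hu_max - cfg.hu_min)
    return IntensityVolume(np.clip(out, 0.0, 1.0), vol.spacing)


def preprocess_volume(vol: IntensityVolume, cfg: PreprocessConfig) -> IntensityVolume:
    """Resize, then window: the standard path from raw volume to analysis grid."""
    return hu_window(resize_volume(vol, cfg), cfg)
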