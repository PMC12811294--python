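"""Calibrated image frames.

A :class:`Frame` is a single 2-D intensity image with its physical pixel
size attached, so every downstream measurement (areas, lengths, speeds)
can be reported in micrometre-based units. Stacks are plain lists of
frames ordered by time; multichannel data is a dict keyed by channel tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Pixel sizes (µm/px) of the three standard magnifications used for
#: long-term viability imaging (10×), neurite morphology (20×) and
#: high-resolution organelle imaging (40×).
PIXEL_SIZE_BY_MAGNIFICATION: dict[int, float] = {10: 0.69, 20: 0.345, 40: 0.1725}

STANDARD_PIXEL_SIZES = tuple(PIXEL_SIZE_BY_MAGNIFICATION.values())


@dataclass
class Frame:
    """One calibrated 2-D intensity image.

    Parameters
    ----------
    data:
        2-D float array of non-negative intensities.
    pixel_size_um:
        Physical side of one pixel in µm.
    channel:
        Channel tag, e.g. ``"egfp"``, ``"hoechst"``, ``"tmrm"``, ``"tdp43"``.
    timepoint:
        Acquisition time in ``time_unit`` units (days for longitudinal
        imaging, minutes or seconds for acute imaging).
    time_unit:
        One of ``"days"``, ``"min"``, ``"s"``.
    """

    data: np.ndarray
    pixel_size_um: float
    channel: str = ""
    timepoint: float = 0.0
    time_unit: str = "days"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"Frame data must be 2-D, got shape {self.data.shape}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Frame intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("Frame intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def field_size_um(self) -> tuple[float, float]:
        """Physical extent (height, width) of the frame in µm."""
        return (self.shape[0] * self.pixel_size_um, self.shape[1] * self.pixel_size_um)

    def with_data(self, data: np.ndarray) -> "Frame":
        """Copy of this frame carrying new pixel data, same calibration."""
        return replace(self, data=np.asarray(data, dtype=float))

    def um_to_px(self, um: float) -> float:
        return um / self.pixel_size_um

    def px_to_um(self, px: float) -> float:
        return px * self.pixel_size_um
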