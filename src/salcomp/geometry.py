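"""Screen geometry shared by the stimulus, saliency and gaze modules.

All spatial quantities are expressed in degrees of visual angle, with the
origin at the screen centre, x increasing rightward and y increasing
downward.  Pixel (row, col) centres map to degrees via
``x = (col - (W - 1) / 2) * degrees_per_px`` so that the coordinate grid is
mirror-symmetric about the vertical midline for any frame width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ScreenGeometry:
    """Pixel grid and its angular calibration.

    Parameters
    ----------
    width_px, height_px
        Frame size in pixels.
    degrees_per_px
        Angular size of one pixel (assumed isotropic).
    central_exclusion_deg
        Half-width of the vertical band around the midline that is excluded
        from hemifield statistics (both salience and gaze), in degrees.
    """

    width_px: int = 128
    height_px: int = 96
    degrees_per_px: float = 0.1875
    central_exclusion_deg: float = 2.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen dimensions must be strictly positive")
        if self.degrees_per_px <= 0:
            raise ValueError("degrees_per_px must be strictly positive")
        if self.central_exclusion_deg <= 0:
            raise ValueError("central_exclusion_deg must be strictly positive")

    @property
    def horizontal_span_deg(self) -> float:
        return self.width_px * self.degrees_per_px

    @property
    def vertical_span_deg(self) -> float:
        return self.height_px * self.degrees_per_px

    def x_coords_deg(self) -> np.ndarray:
        """Horizontal coordinate (degrees) of each pixel column centre."""
        cols = np.arange(self.width_px, dtype=float)
        return (cols - (self.width_px - 1) / 2.0) * self.degrees_per_px

    def y_coords_deg(self) -> np.ndarray:
        rows = np.arange(self.height_px, dtype=float)
        return (rows - (self.height_px - 1) / 2.0) * self.degrees_per_px

    def deg_to_px(self, x_deg: float, y_deg: float) -> tuple[float, float]:
        """Map degree coordinates to fractional (col, row) pixel coordinates."""
        col = x_deg / self.degrees_per_px + (self.width_px - 1) / 2.0
        row = y_deg / self.degrees_per_px + (self.height_px - 1) / 2.0
        return col, row


DEFAULT_GEOMETRY = ScreenGeometry()
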