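"""Dorsal-cortex atlas geometry: brain mask, midline, registration landmarks.

The atlas is a pixel grid covering the dorsal mouse skull field of view
(~1 cm^2 after 4x4 on-camera binning, i.e. 128x128 pixels at ~78 um/px).
Coordinates are 0-based, row-major, origin top-left; x = column; the midline
is a vertical column and anterior is toward row 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LANDMARK_NAMES = ("anterior_vessel_junction", "midline_suture_point", "lambda")


@dataclass(frozen=True)
class AtlasSpec:
    """Common imaging space shared by all mice.

    landmarks map name -> (row, col) pixel coordinates of the skull fiducials
    used for registration: the junction of the coronal vessel separating the
    olfactory bulb from cortex (anterior midline), a point on the sagittal
    suture, and lambda (posterior midline).
    """

    width: int
    height: int
    brain_mask: np.ndarray
    midline_col: float
    landmarks: dict = field(default_factory=dict)
    pixel_size: float = 0.078  # mm per pixel

    @property
    def shape(self):
        return (self.height, self.width)

    def mask_area_mm2(self) -> float:
        return float(self.brain_mask.sum()) * self.pixel_size ** 2

    def hemisphere_of(self, col) -> str:
        return "left" if col < self.midline_col else "right"


def make_atlas(width: int = 128, height: int = 128,
               pixel_size: float = 0.078) -> AtlasSpec:
    """Build a left-right symmetric dorsal-cortex atlas.

    The brain mask is the union of two mirrored elliptical hemispheres
    (rounded anteriorly, slightly flattened at the midline), symmetric about
    the central column. Landmarks sit on the midline at fixed fractional
    depths. Deterministic: no randomness.
    """
    if width < 32 or height < 32:
        raise ValueError("atlas must be at least 32x32 pixels to place landmarks")
    midline = (width - 1) / 2.0
    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    # single ellipse centered on midline -> exactly mirror-symmetric mask
    cy, cx = (height - 1) / 2.0, midline
    ry, rx = 0.46 * height, 0.42 * width
    mask = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0
    top = int(np.ceil(cy - ry)) if cy - ry > 0 else 0
    bot = int(np.floor(cy + ry))
    landmarks = {
        "anterior_vessel_junction": (float(max(top + 1, 1)), midline),
        "midline_suture_point": (float(cy), midline),
        "lambda": (float(min(bot - 1, height - 2)), midline),
    }
    for name, (r, c) in landmarks.items():
        if not (0 <= r < height and 0 <= c < width):
            raise ValueError(f"landmark {name} falls outside the image")
    return AtlasSpec(width=width, height=height, brain_mask=mask,
                     midline_col=midline, landmarks=landmarks,
                     pixel_size=pixel_size)
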