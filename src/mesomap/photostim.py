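"""Photostimulus-evoked effective connectivity and the global inhibition index.

Optogenetic photostimulation sessions (10 Hz hemodynamic sampling) are block
averaged and baseline subtracted; the mean evoked time course within a small
disc at the stimulation target is correlated with every pixel's evoked
trace. Pixels anticorrelated with the driven seed (r < 0, strict) are
counted to form a per-session global inhibition index; a magnitude-weighted
mode (sum of |r| over anticorrelated pixels) is also provided since either
reading of "summing anticorrelated pixels" is defensible.

Block averaging itself is the denoiser here: no additional band-pass is
applied to the averaged stimulus traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evoked import BlockStack, block_average, extract_blocks
from .rsfc import _pearson_vs_all
from .spectroscopy import HemoMovie
from .synthetic import StimParadigm

#: stimulation-site disc radius in pixels (about 310 um at 78 um/px)
TARGET_RADIUS_PX = 4.0


@dataclass(frozen=True)
class StimTarget:
    """Photostimulation site: disc of pixels around the targeted location."""

    center: tuple                 # (row, col), atlas pixels
    radius: float = TARGET_RADIUS_PX
    laser: dict = field(default_factory=lambda: {
        "wavelength_nm": 473, "power_mw": 0.5, "pulse_hz": 10,
        "pulse_ms": 20})

    def disc(self, shape) -> np.ndarray:
        rows = np.arange(shape[0])[:, None]
        cols = np.arange(shape[1])[None, :]
        d = np.hypot(rows - self.center[0], cols - self.center[1])
        return d <= self.radius


@dataclass
class InhibitionIndex:
    """Count (and |r|-sum) of pixels anticorrelated with the driven seed."""

    value: int
    magnitude_sum: float
    area_mm2: float
    map: np.ndarray
    subject: str = ""
    session: str = ""


def photostim_block_average(movie: HemoMovie, paradigm: StimParadigm) -> np.ndarray:
    """Baseline-subtracted block average of a photostimulation session.

    Shares the block-extraction/averaging code path with the electrical
    evoked analysis.
    """
    stack = extract_blocks(movie, paradigm)
    return block_average(stack)


def target_seed_trace(avg: np.ndarray, target: StimTarget,
                      mask: np.ndarray) -> np.ndarray:
    """Mean evoked time course within the target disc (inside the mask)."""
    disc = target.disc(avg.shape[1:]) & mask
    if not disc.any():
        raise ValueError("target disc does not intersect the brain mask")
    return avg[:, disc].mean(axis=1)


def effective_connectivity_map(avg: np.ndarray, seed: np.ndarray,
                               mask: np.ndarray) -> np.ndarray:
    """Pearson r of the driven seed trace vs every pixel's evoked trace.

    Raw r (no Fisher transform): the downstream threshold at 0 is purely
    sign-based. Zero-variance pixels are NaN.
    """
    r = _pearson_vs_all(np.asarray(seed, float), avg[:, mask])
    out = np.full(mask.shape, np.nan)
    out[mask] = r
    return out


def inhibition_index(r_map: np.ndarray, mask: np.ndarray,
                     pixel_size_mm: float = 0.078,
                     subject: str = "", session: str = "") -> InhibitionIndex:
    """Global inhibition index: pixels with r < 0 (strict) inside the mask.

    ``value`` is the pixel count (anticorrelated area); ``magnitude_sum``
    is sum(|r|) over the same pixels for the weighted reading.
    """
    vals = r_map[mask]
    neg = vals < 0  # strict: r == 0 does not count
    count = int(np.nansum(neg))
    mag = float(np.nansum(np.abs(vals[neg & np.isfinite(vals)])))
    return InhibitionIndex(value=count, magnitude_sum=mag,
                           area_mm2=count * pixel_size_mm ** 2,
                           map=r_map, subject=subject, session=session)


def session_inhibition(movie: HemoMovie, paradigm: StimParadigm,
                       target: StimTarget, pixel_size_mm: float = 0.078,
                       subject: str = "", session: str = "") -> InhibitionIndex:
    """Full per-session path: block average -> seed trace -> r map -> index."""
    avg = photostim_block_average(movie, paradigm)
    seed = target_seed_trace(avg, target, movie.mask)
    r_map = effective_connectivity_map(avg, seed, movie.mask)
    return inhibition_index(r_map, movie.mask, pixel_size_mm,
                            subject=subject, session=session)
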