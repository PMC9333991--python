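"""Block-design evoked response mapping.

Stimulation blocks are cut from the hemoglobin movie, baseline-subtracted
(mean over 1-5 s before onset), averaged, and reduced to a peak-response
map (mean over a window around stimulus offset). Activation magnitude and
area use a single group threshold: 75% of the maximum of the group-mean
baseline peak map, reused for every mouse and session so that weak
post-stroke responses are measured against a common yardstick. Mouse-level
T-maps (one-sample t across blocks) feed group effect-size (Cohen's D)
maps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectroscopy import HemoMovie
from .synthetic import StimParadigm

log = logging.getLogger(__name__)

#: peak window half-width around stimulus offset, seconds
PEAK_WINDOW_S = 2.0


@dataclass
class BlockStack:
    """Per-block HbT segments: (n_blocks, T_block, H, W)."""

    blocks: np.ndarray
    block_onsets_s: np.ndarray  # onset of stimulation within movie, s
    paradigm: StimParadigm
    frame_rate: float
    mask: np.ndarray

    @property
    def n_blocks(self) -> int:
        return self.blocks.shape[0]

    def frames(self, t0: float, t1: float) -> slice:
        """Frame slice for the half-open within-block window [t0, t1) s."""
        return slice(int(round(t0 * self.frame_rate)),
                     int(round(t1 * self.frame_rate)))


@dataclass
class EvokedMap:
    """Peak map plus threshold-based response metrics.

    magnitude is NaN ("missing") when no pixel reaches threshold; area is
    then 0. Normalized values are fractions of the group's mean baseline
    magnitude/area.
    """

    peak: np.ndarray
    threshold: float
    magnitude: float
    area: int
    magnitude_norm: float = float("nan")
    area_norm: float = float("nan")
    subject: str = ""
    session: str = ""


@dataclass
class TMap:
    """Per-pixel one-sample t of block peak responses vs 0."""

    t: np.ndarray
    dof: int
    undefined: np.ndarray  # pixels with zero block variance


@dataclass
class EffectSizeMap:
    d: np.ndarray
    inclusion_mask: np.ndarray


def extract_blocks(movie: HemoMovie, paradigm: StimParadigm) -> BlockStack:
    """Slice the movie into per-block segments [onset - pre, onset + stim + post).

    Blocks whose end would overrun the movie are dropped with a warning.
    """
    fs = movie.frame_rate
    block_len = int(round(paradigm.block_s * fs))
    onsets = paradigm.onsets_s()
    segments, kept_onsets = [], []
    for onset in onsets:
        start = int(round((onset - paradigm.pre_s) * fs))
        if start + block_len > movie.n_frames:
            warnings.warn(f"dropping truncated block at t={onset:g}s",
                          stacklevel=2)
            continue
        segments.append(movie.hbt[start:start + block_len])
        kept_onsets.append(onset)
    blocks = (np.stack(segments) if segments
              else np.empty((0, block_len) + movie.hbt.shape[1:]))
    if not segments:
        warnings.warn("no complete stimulation blocks found", stacklevel=2)
    return BlockStack(blocks=blocks, block_onsets_s=np.asarray(kept_onsets),
                      paradigm=paradigm, frame_rate=fs, mask=movie.mask)


def _baseline_window(stack: BlockStack) -> slice:
    """Baseline frames: [onset - 5 s, onset - 1 s) within the block."""
    pre = stack.paradigm.pre_s
    return stack.frames(pre - 5.0 if pre >= 5.0 else 0.0, pre - 1.0)


def block_average(stack: BlockStack) -> np.ndarray:
    """Baseline-subtracted block average, (T_block, H, W).

    Per block, the mean over 1-5 s before stimulus onset is subtracted from
    every frame of the block; blocks are then averaged.
    """
    if stack.n_blocks == 0:
        raise ValueError("block stack is empty")
    base = stack.blocks[:, _baseline_window(stack)].mean(axis=1, keepdims=True)
    return (stack.blocks - base).mean(axis=0)


def peak_window(paradigm: StimParadigm, half_width_s: float = PEAK_WINDOW_S):
    """Within-block peak window [offset - w, offset + w) in seconds."""
    offset = paradigm.pre_s + paradigm.stim_s
    if offset + half_width_s > paradigm.block_s:
        raise ValueError("peak window exceeds block length")
    return offset - half_width_s, offset + half_width_s


def peak_map(avg: np.ndarray, paradigm: StimParadigm, frame_rate: float,
             half_width_s: float = PEAK_WINDOW_S) -> np.ndarray:
    """Mean response image over the peak window around stimulus offset."""
    t0, t1 = peak_window(paradigm, half_width_s)
    sl = slice(int(round(t0 * frame_rate)), int(round(t1 * frame_rate)))
    return avg[sl].mean(axis=0)


def group_threshold(baseline_peak_maps, mask: np.ndarray,
                    fraction: float = 0.75) -> float:
    """75%-of-maximum threshold from the group-mean baseline peak map.

    One threshold per group, reused for all mice and sessions.
    """
    maps = list(baseline_peak_maps)
    if not maps:
        raise ValueError("no baseline maps given")
    mean_map = np.mean(maps, axis=0)
    return float(fraction * mean_map[mask].max())


def response_metrics(peak: np.ndarray, threshold: float, mask: np.ndarray,
                     baseline_magnitude: float = float("nan"),
                     baseline_area: float = float("nan"),
                     region: np.ndarray | None = None,
                     subject: str = "", session: str = "") -> EvokedMap:
    """Threshold-based activation magnitude and area.

    area: count of mask pixels with peak >= threshold (inclusive).
    magnitude: maximum response within the group's baseline-defined
    activation ``region`` when given (so that attenuated post-stroke
    responses remain measurable at the established response site);
    otherwise the maximum over suprathreshold pixels, NaN if none.
    Normalized values divide by the group's mean baseline magnitude/area.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    supra = (peak >= threshold) & mask
    area = int(supra.sum())
    if region is not None:
        sel = np.asarray(region, bool) & mask
        magnitude = float(peak[sel].max()) if sel.any() else float("nan")
    else:
        magnitude = float(peak[supra].max()) if area > 0 else float("nan")
    return EvokedMap(
        peak=peak, threshold=threshold, magnitude=magnitude, area=area,
        magnitude_norm=magnitude / baseline_magnitude,
        area_norm=area / baseline_area if np.isfinite(baseline_area) else float("nan"),
        subject=subject, session=session)


def incidence_map(peak_maps, threshold: float, mask: np.ndarray) -> np.ndarray:
    """Per-pixel fraction of mice whose peak map reaches the threshold."""
    maps = list(peak_maps)
    if not maps:
        raise ValueError("no peak maps given")
    binar = np.stack([(m >= threshold) & mask for m in maps])
    return binar.mean(axis=0)


def t_map(stack: BlockStack, half_width_s: float = PEAK_WINDOW_S) -> TMap:
    """One-sample t of per-block peak-window means against zero.

    Pixels with zero across-block variance are flagged ``undefined`` and
    set to 0 in the t image.
    """
    if stack.n_blocks < 2:
        raise ValueError("t_map requires at least 2 blocks")
    base = stack.blocks[:, _baseline_window(stack)].mean(axis=1, keepdims=True)
    sub = stack.blocks - base
    t0, t1 = peak_window(stack.paradigm, half_width_s)
    sl = slice(int(round(t0 * stack.frame_rate)),
               int(round(t1 * stack.frame_rate)))
    block_vals = sub[:, sl].mean(axis=1)  # (n_blocks, H, W)
    n = stack.n_blocks
    mean = block_vals.mean(axis=0)
    sd = block_vals.std(axis=0, ddof=1)
    undefined = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[undefined] = 0.0
    return TMap(t=t, dof=n - 1, undefined=undefined)


def cohens_d_map(tmaps_a, tmaps_b, t_threshold: float = 2.0) -> EffectSizeMap:
    """Group effect-size map from mouse-level T-maps (group A minus B).

    Pixels are included where either group's mean T exceeds ``t_threshold``;
    d uses the two-group pooled SD (n-1 weights) of mouse-level T values.
    Pixels with degenerate pooled SD are set to NaN inside the mask.
    """
    a = np.stack([tm.t for tm in tmaps_a])
    b = np.stack([tm.t for tm in tmaps_b])
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 mice per group")
    inclusion = (a.mean(axis=0) > t_threshold) | (b.mean(axis=0) > t_threshold)
    na, nb = a.shape[0], b.shape[0]
    pooled_var = ((na - 1) * a.var(axis=0, ddof=1)
                  + (nb - 1) * b.var(axis=0, ddof=1)) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(pooled_var)
    d[~inclusion] = np.nan
    d[inclusion & (pooled_var == 0)] = np.nan
    return EffectSizeMap(d=d, inclusion_mask=inclusion)
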