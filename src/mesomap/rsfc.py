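"""Seed-based resting-state functional connectivity and node degree.

Zero-lag Pearson correlations of preprocessed HbT traces, Fisher-z
transformed for statistics. Whole-cortex pixelwise matrices are computed on
a configurable spatial downsample (default 2x) to bound memory; node degree
counts suprathreshold (z >= 0.4) connections per pixel over both
hemispheres.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectroscopy import HemoMovie

log = logging.getLogger(__name__)

#: clip |r| below 1 by this margin before atanh
R_CLIP = 1e-7


@dataclass(frozen=True)
class SeedROI:
    """Named pixel set used as a correlation seed.

    provenance records how the ROI was derived: baseline/week-4 evoked
    activation, PCA-derived, or a fixed target disc.
    """

    name: str
    pixels: np.ndarray  # (H, W) boolean
    provenance: str = "baseline evoked"

    def __post_init__(self):
        if not self.pixels.any():
            raise ValueError(f"ROI {self.name!r} is empty")

    @property
    def size(self) -> int:
        return int(self.pixels.sum())

    def centroid(self):
        rr, cc = np.nonzero(self.pixels)
        return float(rr.mean()), float(cc.mean())


@dataclass
class CorrMatrix:
    """Symmetric Fisher-z correlation matrix with its index bookkeeping.

    index holds the ordered unit labels (ROI names, or pixel (row, col)
    tuples), grouped by functional assignment then hemisphere when built
    from ROI sets. The diagonal is excluded from downstream statistics by
    convention (stored as 0).
    """

    z: np.ndarray
    index: tuple
    kind: str = "pixel"  # {"pixel", "roi"}
    bad_units: np.ndarray | None = None  # zero-variance units, flagged

    def __post_init__(self):
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("z must be square")
        if len(self.index) != self.z.shape[0]:
            raise ValueError("index length must match matrix dimension")

    @property
    def n(self) -> int:
        return self.z.shape[0]

    def offdiag(self) -> np.ndarray:
        return self.z[~np.eye(self.n, dtype=bool)]


def fisher_z(r) -> np.ndarray:
    """Variance-stabilizing Fisher transform z = atanh(r).

    |r| >= 1 is clipped to 1 - 1e-7 in magnitude with a warning (perfect
    correlations arise from self-pairs and degenerate traces).
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("|r| >= 1 clipped before Fisher transform", stacklevel=2)
    return np.arctanh(np.clip(r, -1.0 + R_CLIP, 1.0 - R_CLIP))


def roi_timecourse(movie: HemoMovie, roi: SeedROI) -> np.ndarray:
    """Unweighted mean HbT trace over the ROI's pixels (within the mask)."""
    sel = roi.pixels & movie.mask
    if not sel.any():
        raise ValueError(f"ROI {roi.name!r} does not intersect the brain mask")
    return movie.hbt[:, sel].mean(axis=1)


def _pearson_vs_all(seed: np.ndarray, flat: np.ndarray) -> np.ndarray:
    """Pearson r of a seed trace against every column of flat (T, K)."""
    s = seed - seed.mean()
    x = flat - flat.mean(axis=0, keepdims=True)
    s_norm = np.sqrt(s @ s)
    if s_norm == 0:
        raise ValueError("seed trace has zero variance")
    x_norm = np.sqrt((x ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (s @ x) / (s_norm * x_norm)
    r[x_norm == 0] = np.nan
    return r


def seed_map(movie: HemoMovie, roi: SeedROI) -> np.ndarray:
    """Fisher-z correlation image of the ROI trace vs every mask pixel.

    Zero-variance pixels are NaN; pixels outside the mask are NaN.
    """
    seed = roi_timecourse(movie, roi)
    m = movie.mask
    r = _pearson_vs_all(seed, movie.hbt[:, m])
    out = np.full(m.shape, np.nan)
    valid = ~np.isnan(r)
    vals = np.full(r.shape, np.nan)
    vals[valid] = fisher_z(r[valid])
    out[m] = vals
    return out


def corr_matrix(movie: HemoMovie, rois=None, spatial_downsample: int = 2) -> CorrMatrix:
    """All-pairs Fisher-z correlation matrix.

    With ``rois`` given: ROI-by-ROI matrix of ROI-mean traces, indexed by
    ROI name in the given order (callers order ROIs by functional
    assignment then hemisphere). Otherwise: pixelwise matrix over the brain
    mask, optionally on a ``spatial_downsample``-strided pixel grid (logged;
    bounds the matrix to a workable size). Zero-variance units are flagged
    and their rows/columns set to NaN. Diagonal is stored as 0 (excluded).
    """
    if rois is not None:
        traces = np.column_stack([roi_timecourse(movie, r) for r in rois])
        index = tuple(r.name for r in rois)
        kind = "roi"
    else:
        m = movie.mask.copy()
        if spatial_downsample > 1:
            grid = np.zeros_like(m)
            grid[::spatial_downsample, ::spatial_downsample] = True
            m &= grid
            log.info("pixelwise matrix on %dx spatial downsample: %d units",
                     spatial_downsample, int(m.sum()))
        rr, cc = np.nonzero(m)
        index = tuple(zip(rr.tolist(), cc.tolist()))
        traces = movie.hbt[:, m]
        kind = "pixel"
    if traces.shape[1] < 2:
        raise ValueError("need at least 2 units to correlate")
    sd = traces.std(axis=0)
    bad = sd == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance units flagged",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(traces, rowvar=False)
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, 0.0)  # self-pairs excluded; avoids atanh(1) clipping
    z = np.full_like(r, np.nan)
    finite = np.isfinite(r)
    z[finite] = fisher_z(r[finite])
    np.fill_diagonal(z, 0.0)
    return CorrMatrix(z=z, index=index, kind=kind, bad_units=bad)


def node_degree(matrix: CorrMatrix, thr_z: float = 0.4,
                shape=None) -> "NodeDegreeMap":
    """Count suprathreshold (z >= thr_z) connections per unit.

    Only positive exceedances count; self-pairs are excluded (diagonal is
    0 < thr_z by construction for thr_z > 0). For pixelwise matrices a
    degree image is filled at the matrix's pixel index when ``shape`` is
    given.
    """
    with np.errstate(invalid="ignore"):
        binar = matrix.z >= thr_z
    np.fill_diagonal(binar, False)
    degree = binar.sum(axis=1).astype(int)
    image = None
    if shape is not None and matrix.kind == "pixel":
        image = np.zeros(shape, dtype=int)
        for (rr, cc), d in zip(matrix.index, degree):
            image[rr, cc] = d
    return NodeDegreeMap(degree=degree, threshold_z=thr_z, image=image,
                         index=matrix.index)


@dataclass
class NodeDegreeMap:
    degree: np.ndarray  # per-unit counts
    threshold_z: float
    image: np.ndarray | None = None
    index: tuple = ()


def difference_matrix(group_a, group_b) -> CorrMatrix:
    """Elementwise mean(A) - mean(B) of matched correlation matrices."""
    mats_a = list(group_a)
    mats_b = list(group_b)
    if not mats_a or not mats_b:
        raise ValueError("both groups must be non-empty")
    index = mats_a[0].index
    for m in mats_a + mats_b:
        if m.index != index:
            raise ValueError("correlation matrices have mismatched indices")
    za = np.mean([m.z for m in mats_a], axis=0)
    zb = np.mean([m.z for m in mats_b], axis=0)
    return CorrMatrix(z=za - zb, index=index, kind=mats_a[0].kind)
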