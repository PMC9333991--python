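"""Run-level quality control, temporal filtering, global signal regression,
and landmark-based affine registration to atlas space.

Processing order mirrors standard widefield hemodynamic pipelines:
spectroscopy -> QC -> downsample (resting path only, 30 -> 1 Hz) ->
band-pass (0.009-0.08 Hz resting, 0.009-0.5 Hz task) -> global signal
regression -> affine transform to atlas -> shared brain mask.
``rsfc_pipeline`` / ``task_pipeline`` enforce and log this order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .spectroscopy import HemoMovie

log = logging.getLogger(__name__)

RSFC_BAND = (0.009, 0.08)
TASK_BAND = (0.009, 0.5)


# --------------------------------------------------------------------------
# quality control


@dataclass
class QCReport:
    """Per-run keep/reject decisions with the statistics that drove them."""

    table: pd.DataFrame  # columns: run, variance, max_jump, kept, reason

    @property
    def kept(self) -> np.ndarray:
        return self.table["kept"].to_numpy()

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())


def quality_check(runs, var_mult: float = 5.0, jump_mult: float = 10.0) -> QCReport:
    """Flag runs with outlying global variance or frame-to-frame jumps.

    ``runs`` is a sequence of (T, H, W) arrays (or objects with a ``.data``
    global trace); a run is rejected when the variance of its global-mean
    trace exceeds ``var_mult`` times the median across runs, or its maximum
    absolute frame-to-frame difference exceeds ``jump_mult`` times the
    median across runs. Deterministic; empty input yields an empty report.
    """
    records = []
    traces = []
    for arr in runs:
        arr = np.asarray(arr, dtype=float)
        traces.append(arr.reshape(arr.shape[0], -1).mean(axis=1))
    variances = np.array([t.var() for t in traces])
    jumps = np.array([np.abs(np.diff(t)).max() if t.size > 1 else 0.0
                      for t in traces])
    med_var = np.median(variances) if len(traces) else 0.0
    med_jump = np.median(jumps) if len(traces) else 0.0
    for i, (v, j) in enumerate(zip(variances, jumps)):
        reasons = []
        if np.isfinite(var_mult) and med_var > 0 and v > var_mult * med_var:
            reasons.append(f"variance {v:.3g} > {var_mult:g} x median")
        if np.isfinite(jump_mult) and med_jump > 0 and j > jump_mult * med_jump:
            reasons.append(f"jump {j:.3g} > {jump_mult:g} x median")
        records.append({"run": i, "variance": v, "max_jump": j,
                        "kept": not reasons, "reason": "; ".join(reasons)})
    cols = ["run", "variance", "max_jump", "kept", "reason"]
    return QCReport(pd.DataFrame(records, columns=cols))


# --------------------------------------------------------------------------
# temporal operations


def downsample(movie: HemoMovie, target_rate: float) -> HemoMovie:
    """Block-average temporal downsampling (anti-aliasing by integration).

    ``target_rate`` must divide the movie's frame rate to an integer ratio.
    """
    ratio = movie.frame_rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError("target_rate must integer-divide the frame rate")
    k = int(round(ratio))

    def block_mean(x):
        n = (x.shape[0] // k) * k
        return x[:n].reshape(-1, k, *x.shape[1:]).mean(axis=1)

    return HemoMovie(hbo=block_mean(movie.hbo), hbr=block_mean(movie.hbr),
                     hbt=block_mean(movie.hbt), frame_rate=target_rate,
                     mask=movie.mask, space=movie.space).validate(atol=1e-9)


def bandpass(movie: HemoMovie, low: float, high: float, order: int = 5) -> HemoMovie:
    """Zero-phase Butterworth band-pass along time, per pixel.

    5th-order filter applied forward-backward (``sosfiltfilt``); removes DC.
    Band edges must satisfy 0 < low < high < Nyquist.
    """
    nyq = movie.frame_rate / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=movie.frame_rate,
                        output="sos")
    hbo = signal.sosfiltfilt(sos, movie.hbo, axis=0)
    hbr = signal.sosfiltfilt(sos, movie.hbr, axis=0)
    return HemoMovie(hbo=hbo, hbr=hbr, hbt=hbo + hbr,
                     frame_rate=movie.frame_rate, mask=movie.mask,
                     space=movie.space).validate(atol=1e-9)


def global_signal_regress(movie: HemoMovie, mask: np.ndarray | None = None) -> HemoMovie:
    """Remove the brain-wide mean signal from every pixel by OLS projection.

    The global trace g(t) is the mean HbT over the mask; every pixel trace
    (each species separately, using that species' own global trace) is
    replaced by its residual after projection onto [g, 1]. Residual traces
    are orthogonal to g and mean-free. A zero-variance g degrades gracefully
    to mean-centering with a warning.
    """
    m = movie.mask if mask is None else np.asarray(mask, bool)
    if not m.any():
        raise ValueError("mask is empty")

    def regress(x):
        flat = x.reshape(x.shape[0], -1)
        g = x[:, m].mean(axis=1)
        gc = g - g.mean()
        denom = gc @ gc
        centered = flat - flat.mean(axis=0, keepdims=True)
        # relative guard: a global trace at round-off level (e.g. after a
        # previous GSR pass) must not be used as a regressor
        scale = (centered ** 2).sum() / max(flat.shape[1], 1)
        if denom <= 1e-20 * scale:
            if scale > 0:
                log.warning("global signal has zero variance; "
                            "mean-centering only")
            return centered.reshape(x.shape)
        beta = (gc @ centered) / denom
        resid = centered - gc[:, None] * beta[None, :]
        return resid.reshape(x.shape)

    hbo = regress(movie.hbo)
    hbr = regress(movie.hbr)
    return HemoMovie(hbo=hbo, hbr=hbr, hbt=hbo + hbr,
                     frame_rate=movie.frame_rate, mask=m,
                     space=movie.space).validate(atol=1e-9)


# --------------------------------------------------------------------------
# registration


@dataclass(frozen=True)
class AffineTransform:
    """2x3 affine mapping source pixel (row, col) to atlas pixel."""

    matrix: np.ndarray  # (2, 3): [A | t] acting on (row, col, 1)
    source_landmarks: tuple = ()
    target_landmarks: tuple = ()

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        homo = np.column_stack([pts, np.ones(len(pts))])
        return homo @ self.matrix.T

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(matrix=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))


def fit_affine(source, target) -> AffineTransform:
    """Exact 6-parameter affine from 3 non-collinear landmark pairs."""
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != (3, 2) or tgt.shape != (3, 2):
        raise ValueError("exactly 3 (row, col) landmark pairs are required")
    M = np.column_stack([src, np.ones(3)])
    if abs(np.linalg.det(M)) < 1e-9:
        raise ValueError("landmarks are collinear; affine is degenerate")
    sol = np.linalg.solve(M, tgt)  # (3, 2)
    matrix = sol.T  # rows: output row/col coefficients
    t = AffineTransform(matrix=matrix,
                        source_landmarks=tuple(map(tuple, src)),
                        target_landmarks=tuple(map(tuple, tgt)))
    if np.abs(t.apply_points(src) - tgt).max() > 1e-9:
        raise ValueError("affine fit failed to reproduce landmarks")
    if abs(np.linalg.det(t.linear)) < 1e-12:
        raise ValueError("affine linear part is singular")
    return t


def apply_affine(movie: HemoMovie, t: AffineTransform, out_shape) -> HemoMovie:
    """Resample a movie into atlas space (bilinear; mask nearest-neighbor)."""
    inv = np.linalg.inv(np.vstack([t.matrix, [0.0, 0.0, 1.0]]))

    def warp(frame, order):
        return ndimage.affine_transform(frame, inv[:2, :2], offset=inv[:2, 2],
                                        output_shape=tuple(out_shape),
                                        order=order, mode="constant", cval=0.0)

    def warp_movie(x):
        return np.stack([warp(fr, 1) for fr in x])

    mask = warp(movie.mask.astype(float), 0) > 0.5
    hbo = warp_movie(movie.hbo)
    hbr = warp_movie(movie.hbr)
    return HemoMovie(hbo=hbo, hbr=hbr, hbt=hbo + hbr,
                     frame_rate=movie.frame_rate, mask=mask,
                     space="atlas").validate(atol=1e-6)


def shared_mask(masks) -> np.ndarray:
    """Elementwise intersection of same-shape binary brain masks."""
    masks = [np.asarray(m, bool) for m in masks]
    if not masks:
        raise ValueError("no masks given")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("masks must share a common shape")
    out = masks[0].copy()
    for m in masks[1:]:
        out &= m
    return out


# --------------------------------------------------------------------------
# pipelines


def rsfc_pipeline(movie: HemoMovie, target_rate: float = 1.0,
                  band=RSFC_BAND, transform: AffineTransform | None = None,
                  out_shape=None) -> HemoMovie:
    """Resting-state path: downsample -> band-pass -> GSR (-> affine)."""
    log.info("RSFC preprocessing: %g Hz -> %g Hz, band %s", movie.frame_rate,
             target_rate, band)
    if movie.frame_rate != target_rate:
        movie = downsample(movie, target_rate)
    movie = bandpass(movie, *band)
    movie = global_signal_regress(movie)
    if transform is not None:
        movie = apply_affine(movie, transform,
                             out_shape or movie.hbt.shape[1:])
    return movie


def task_pipeline(movie: HemoMovie, band=TASK_BAND,
                  transform: AffineTransform | None = None,
                  out_shape=None) -> HemoMovie:
    """Task path: native rate, 0.009-0.5 Hz band -> GSR (-> affine)."""
    log.info("task preprocessing at native %g Hz, band %s",
             movie.frame_rate, band)
    movie = bandpass(movie, *band)
    movie = global_signal_regress(movie)
    if transform is not None:
        movie = apply_affine(movie, transform,
                             out_shape or movie.hbt.shape[1:])
    return movie
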