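"""Modified Beer-Lambert spectroscopy: reflectance -> hemoglobin movies.

Multi-wavelength diffuse reflectance R_lambda(t), expressed relative to its
temporal mean, is converted to pixelwise changes in oxygenated (HbO),
deoxygenated (HbR) and total (HbT = HbO + HbR) hemoglobin concentration by
solving, per pixel and time point, the linear system

    -ln R(lambda) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] L(lambda)

in the least-squares sense across wavelengths.

Array convention: movies are time-first, shape (T, H, W); reflectance stacks
are (n_wavelengths, T, H, W).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .optics import OpticsModel

log = logging.getLogger(__name__)


@dataclass
class ReflectanceStack:
    """Per-wavelength reflectance movie, relative to temporal mean.

    data        : (n_wavelengths, T, H, W), dimensionless, > 0 inside mask
    wavelengths : strictly increasing, nm
    frame_rate  : Hz per wavelength (hemodynamic sampling rate)
    mask        : (H, W) boolean brain mask
    """

    data: np.ndarray
    wavelengths: tuple
    frame_rate: float
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.data.ndim != 4 or self.data.shape[0] != wl.size:
            raise ValueError("data must be (n_wavelengths, T, H, W)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.wavelengths = tuple(wl)

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class HemoMovie:
    """Pixelwise hemoglobin concentration changes (M) from baseline.

    hbt is maintained as hbo + hbr by every transform; ``validate`` asserts
    the identity.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    hbt: np.ndarray
    frame_rate: float
    mask: np.ndarray
    space: str = "camera"  # {"camera", "atlas"}

    def validate(self, atol: float = 1e-12):
        if not (self.hbo.shape == self.hbr.shape == self.hbt.shape):
            raise ValueError("hbo/hbr/hbt shape mismatch")
        m = self.mask
        if not np.all(np.isfinite(self.hbt[:, m])):
            raise ValueError("non-finite concentrations inside mask")
        scale = max(np.abs(self.hbt[:, m]).max(), 1.0e-9)
        if np.abs(self.hbo + self.hbr - self.hbt)[:, m].max() > atol * max(scale, 1.0):
            raise ValueError("hbt != hbo + hbr")
        return self

    def copy_with(self, **traces) -> "HemoMovie":
        kw = dict(hbo=self.hbo, hbr=self.hbr, hbt=self.hbt,
                  frame_rate=self.frame_rate, mask=self.mask, space=self.space)
        kw.update(traces)
        return HemoMovie(**kw)

    @property
    def n_frames(self) -> int:
        return self.hbt.shape[0]


def normalize_reflectance(raw: np.ndarray, wavelengths, frame_rate: float,
                          mask: np.ndarray) -> ReflectanceStack:
    """Ratiometric normalization: divide each pixel trace by its temporal mean.

    Output traces have unit temporal mean per pixel and wavelength, which is
    the reference convention assumed by ``invert_beer_lambert``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 4:
        raise ValueError("raw stack must be (n_wavelengths, T, H, W)")
    if np.any(raw[:, :, mask] <= 0):
        raise ValueError("nonpositive raw intensity inside brain mask")
    mean = raw.mean(axis=1, keepdims=True)
    safe = np.where(mean > 0, mean, 1.0)
    return ReflectanceStack(data=raw / safe, wavelengths=tuple(wavelengths),
                            frame_rate=frame_rate, mask=np.asarray(mask, bool))


def invert_beer_lambert(stack: ReflectanceStack, optics: OpticsModel) -> HemoMovie:
    """Solve the pathlength-weighted extinction system for (dHbO, dHbR).

    Uses the pseudoinverse of E*L (orthogonal least squares), so any number
    of wavelengths >= 2 is handled uniformly; with exactly 2 the solve is
    exact. Raises on rank-deficient extinction matrices or nonpositive
    reflectance inside the mask.
    """
    wl = np.asarray(stack.wavelengths)
    if not np.allclose(wl, np.asarray(optics.wavelengths)):
        raise ValueError("stack and optics wavelengths disagree")
    A = optics.design_matrix  # (n_wl, 2)
    if np.linalg.matrix_rank(A) < 2:
        raise np.linalg.LinAlgError("extinction system is rank deficient")
    cond = optics.condition_number()
    log.info("Beer-Lambert inversion: %d wavelengths, condition number %.3g",
             len(stack.wavelengths), cond)
    data = stack.data
    if np.any(data[:, :, stack.mask] <= 0):
        raise ValueError("nonpositive reflectance inside brain mask")
    # attenuation change per unit pathlength, (n_wl, T, H, W)
    dmua = -np.log(np.clip(data, 1e-300, None))
    pinv = np.linalg.pinv(A)  # (2, n_wl)
    flat = dmua.reshape(len(stack.wavelengths), -1)
    conc = pinv @ flat  # (2, T*H*W)
    shape = data.shape[1:]
    hbo = conc[0].reshape(shape)
    hbr = conc[1].reshape(shape)
    movie = HemoMovie(hbo=hbo, hbr=hbr, hbt=hbo + hbr,
                      frame_rate=stack.frame_rate, mask=stack.mask)
    return movie.validate(atol=1e-9)
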