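"""Synthetic dorsal-cortex datasets with known ground truth.

Emulates the structure of a longitudinal widefield imaging study of stroke
recovery: multi-wavelength reflectance movies generated by a forward
Beer-Lambert model from planted hemoglobin dynamics, with

* a resting-state network of Gaussian cortical nodes with a specified
  inter-node correlation matrix (bilateral homotopic correlations and
  anterior-posterior anticorrelation),
* block-design evoked responses (electrical forepaw or optogenetic
  photostimulation paradigms) shaped by a gamma-variate impulse response,
* a focal lesion that attenuates a node's activity after the baseline
  session and an optional delayed "remapped" response site,
* ancillary behavior (paw-use) and qPCR expression tables with planted
  group effects.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import AtlasSpec
from .optics import OpticsModel
from .spectroscopy import HemoMovie, ReflectanceStack

SESSIONS = ("baseline", "week1", "week4")

#: default ratio dHbR/dHbO: activation raises HbT, lowers HbR
DEFAULT_COUPLING = -0.4


# --------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class Node:
    name: str
    center: tuple  # (row, col), pixels
    sigma: float   # spatial footprint SD, pixels
    hemisphere: str


@dataclass(frozen=True)
class NetworkSpec:
    """Resting-state network: nodes, target correlations, noise.

    noise_sd is the per-pixel white-noise SD relative to the unit-SD node
    fluctuation; global_sd is the SD of an optional shared brain-wide
    fluctuation (same relative units) added uniformly over the mask so that
    global signal regression has something to remove.
    """

    nodes: tuple
    edges: tuple  # (name_i, name_j, target r)
    noise_sd: float = 0.1
    global_sd: float = 0.0
    sampling_rate: float = 1.0
    duration: float = 300.0
    rest_amplitude: float = 1e-6  # node HbT fluctuation SD, M

    def node_index(self, name: str) -> int:
        for i, n in enumerate(self.nodes):
            if n.name == name:
                return i
        raise KeyError(f"unknown node {name!r}")

    def correlation_matrix(self) -> np.ndarray:
        n = len(self.nodes)
        c = np.eye(n)
        for a, b, r in self.edges:
            i, j = self.node_index(a), self.node_index(b)
            if not -1.0 <= r <= 1.0:
                raise ValueError("target correlations must lie in [-1, 1]")
            c[i, j] = c[j, i] = r
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("target correlation matrix is not positive semidefinite")
        return c


@dataclass(frozen=True)
class LesionSpec:
    """Focal lesion: silences nodes inside the disc after baseline.

    attenuation is the fractional loss applied to affected node amplitudes
    (1 = complete silencing). remap_center, if given, gains an evoked
    response from remap_onset_session onward with remap_fraction of the
    original amplitude.
    """

    center: tuple
    radius: float
    attenuation: float
    remap_center: tuple | None = None
    remap_onset_session: str = "week4"
    remap_fraction: float = 0.6

    def __post_init__(self):
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in [0, 1]")

    def covers(self, point) -> bool:
        return float(np.hypot(point[0] - self.center[0],
                              point[1] - self.center[1])) <= self.radius

    def active(self, session: str) -> bool:
        return session != "baseline"

    def remap_active(self, session: str) -> bool:
        if self.remap_center is None:
            return False
        order = list(SESSIONS)
        return order.index(session) >= order.index(self.remap_onset_session)


@dataclass(frozen=True)
class StimParadigm:
    kind: str            # {"electrical", "optogenetic"}
    pre_s: float
    stim_s: float
    post_s: float
    n_blocks: int
    pulse_rate: float

    def __post_init__(self):
        if min(self.pre_s, self.stim_s, self.post_s) <= 0:
            raise ValueError("all paradigm durations must be positive")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    @property
    def block_s(self) -> float:
        return self.pre_s + self.stim_s + self.post_s

    @property
    def duration_s(self) -> float:
        return self.n_blocks * self.block_s

    def onsets_s(self) -> np.ndarray:
        """Stimulus onset times (s), one per block."""
        return self.pre_s + np.arange(self.n_blocks) * self.block_s


def electrical_paradigm(n_blocks: int = 18) -> StimParadigm:
    """Transcutaneous forepaw stimulation: 5 s rest, 10 s stim at 3 Hz, 35 s rest."""
    return StimParadigm("electrical", pre_s=5.0, stim_s=10.0, post_s=35.0,
                        n_blocks=n_blocks, pulse_rate=3.0)


def optogenetic_paradigm(n_blocks: int = 30) -> StimParadigm:
    """Photostimulation blocks: 10 s of 10 Hz pulses followed by 50 s of rest."""
    return StimParadigm("optogenetic", pre_s=5.0, stim_s=10.0, post_s=45.0,
                        n_blocks=n_blocks, pulse_rate=10.0)


@dataclass
class GroundTruth:
    """Planted parameters and truth movies for parameter-recovery tests."""

    hbt: np.ndarray            # (T, H, W), M
    hbo: np.ndarray
    hbr: np.ndarray
    network: NetworkSpec | None
    lesion: LesionSpec | None
    evoked_amplitude: float | None
    rng_seed: int
    block_onsets_s: np.ndarray | None = None
    response_center: tuple | None = None
    node_timecourses: np.ndarray | None = None  # (T, n_nodes), unit SD targets
    extras: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# building blocks


def gamma_hrf(t: np.ndarray, peak_s: float = 2.0, fwhm_s: float = 3.0) -> np.ndarray:
    """Gamma-variate hemodynamic impulse response, unit peak.

    h(t) = (t/tp)^a exp(a (1 - t/tp)) with a set from the requested FWHM
    (FWHM ~ 2.35 tp / sqrt(a)).
    """
    a = (2.35 * peak_s / fwhm_s) ** 2
    tt = np.clip(np.asarray(t, dtype=float), 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = (tt / peak_s) ** a * np.exp(a * (1.0 - tt / peak_s))
    h[tt == 0] = 0.0
    return h


def evoked_timecourse(paradigm: StimParadigm, fs: float,
                      hrf_peak_s: float = 2.0, hrf_fwhm_s: float = 3.0) -> np.ndarray:
    """Unit-peak block response: stimulus boxcar convolved with the HRF.

    Returns the full-movie trace (all blocks), peak value exactly 1.
    """
    n = int(round(paradigm.duration_s * fs))
    t = np.arange(n) / fs
    box = np.zeros(n)
    for onset in paradigm.onsets_s():
        box[(t >= onset) & (t < onset + paradigm.stim_s)] = 1.0
    span = np.arange(int(round(12.0 * fs)) + 1) / fs  # HRF support ~12 s
    h = gamma_hrf(span, hrf_peak_s, hrf_fwhm_s)
    resp = np.convolve(box, h)[:n]
    peak = resp.max()
    return resp / peak if peak > 0 else resp


def node_footprints(atlas: AtlasSpec, nodes) -> np.ndarray:
    """(n_nodes, H, W) Gaussian spatial footprints, unit peak."""
    rows = np.arange(atlas.height)[:, None]
    cols = np.arange(atlas.width)[None, :]
    fp = np.empty((len(nodes), atlas.height, atlas.width))
    for i, nd in enumerate(nodes):
        d2 = (rows - nd.center[0]) ** 2 + (cols - nd.center[1]) ** 2
        fp[i] = np.exp(-d2 / (2.0 * nd.sigma ** 2))
    return fp


def node_timecourses(network: NetworkSpec, n_samples: int,
                     rng: np.random.Generator) -> np.ndarray:
    """(n_samples, n_nodes) zero-mean unit-SD draws with the target correlations."""
    c = network.correlation_matrix()
    # eigendecomposition square root: tolerant of exactly-singular targets
    w, v = np.linalg.eigh(c)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n_samples, len(network.nodes)))
    return z @ root.T


def default_network(atlas: AtlasSpec, noise_sd: float = 0.1,
                    global_sd: float = 0.0, sampling_rate: float = 1.0,
                    duration: float = 300.0) -> NetworkSpec:
    """Ten-node bilateral network over the dorsal cortex.

    Five homotopic pairs (forepaw somatosensory S1FP, motor M1, hindlimb HL,
    retrosplenial RS, visual V1) with homotopic correlations 0.5-0.7 and an
    anterior-posterior anticorrelation (-0.4) between motor and visual
    cortices.
    """
    h, w = atlas.height, atlas.width
    mid = atlas.midline_col
    half = w / 2.0
    sigma = 0.03 * w

    def pair(name, row_frac, col_frac):
        dr = row_frac * h
        dc = col_frac * half
        return (Node(f"{name}_L", (dr, mid - dc), sigma, "left"),
                Node(f"{name}_R", (dr, mid + dc), sigma, "right"))

    nodes = (*pair("M1", 0.30, 0.22), *pair("S1FP", 0.41, 0.41),
             *pair("HL", 0.45, 0.19), *pair("RS", 0.66, 0.13),
             *pair("V1", 0.74, 0.44))
    edges = (
        ("M1_L", "M1_R", 0.6),
        ("S1FP_L", "S1FP_R", 0.7),
        ("HL_L", "HL_R", 0.6),
        ("RS_L", "RS_R", 0.5),
        ("V1_L", "V1_R", 0.7),
        ("M1_L", "V1_L", -0.4),
        ("M1_R", "V1_R", -0.4),
        ("M1_L", "V1_R", -0.3),
        ("M1_R", "V1_L", -0.3),
        ("S1FP_L", "HL_L", 0.3),
        ("S1FP_R", "HL_R", 0.3),
    )
    return NetworkSpec(nodes=nodes, edges=edges, noise_sd=noise_sd,
                       global_sd=global_sd, sampling_rate=sampling_rate,
                       duration=duration)


def _hemo_from_hbt(hbt: np.ndarray, atlas: AtlasSpec, fs: float,
                   coupling: float) -> tuple:
    hbo = hbt / (1.0 + coupling)
    hbr = coupling * hbo
    movie = HemoMovie(hbo=hbo, hbr=hbr, hbt=hbo + hbr, frame_rate=fs,
                      mask=atlas.brain_mask, space="atlas")
    return movie, hbo, hbr


# --------------------------------------------------------------------------
# generators


def simulate_resting(atlas: AtlasSpec, network: NetworkSpec, seed: int,
                     coupling: float = DEFAULT_COUPLING,
                     lesion: LesionSpec | None = None,
                     session: str = "baseline"):
    """Resting-state hemoglobin movie with planted network correlations.

    Pixel HbT = sum over nodes of (footprint x node time course x amplitude)
    + independent white pixel noise (+ optional shared global fluctuation).
    A lesion, when active for the session, scales the amplitude of every
    node whose center falls inside the lesion disc by (1 - attenuation).

    Returns (HemoMovie in atlas space, GroundTruth).
    """
    rng = np.random.default_rng(seed)
    fs = network.sampling_rate
    n = int(round(network.duration * fs))
    tc = node_timecourses(network, n, rng)  # (n, N)
    amp = np.full(len(network.nodes), network.rest_amplitude)
    if lesion is not None and lesion.active(session):
        for i, nd in enumerate(network.nodes):
            if lesion.covers(nd.center):
                amp[i] *= (1.0 - lesion.attenuation)
    fp = node_footprints(atlas, network.nodes)
    hbt = np.einsum("tn,nhw->thw", tc * amp, fp, optimize=True)
    if network.global_sd > 0:
        g = rng.standard_normal(n) * network.global_sd * network.rest_amplitude
        hbt += g[:, None, None] * atlas.brain_mask
    if network.noise_sd > 0:
        hbt += rng.standard_normal(hbt.shape) * (
            network.noise_sd * network.rest_amplitude)
    movie, hbo, hbr = _hemo_from_hbt(hbt, atlas, fs, coupling)
    gt = GroundTruth(hbt=hbt, hbo=hbo, hbr=hbr, network=network,
                     lesion=lesion, evoked_amplitude=None, rng_seed=seed,
                     node_timecourses=tc)
    return movie, gt


def simulate_evoked(atlas: AtlasSpec, network: NetworkSpec,
                    paradigm: StimParadigm, target_node: str,
                    amplitude: float, seed: int,
                    coupling: float = DEFAULT_COUPLING,
                    lesion: LesionSpec | None = None,
                    session: str = "baseline"):
    """Block-design evoked movie: resting dynamics plus a planted response.

    The response at the target node is the stimulus boxcar convolved with a
    gamma-variate impulse response, normalized so the peak HbT change at the
    node center equals ``amplitude`` (M). An active lesion covering the
    target attenuates the response; once remapping is active, a response of
    ``remap_fraction x amplitude`` appears at the remap site instead.

    With ``amplitude == 0`` the output is bit-identical to
    ``simulate_resting`` at the same seed (the stochastic stream is drawn
    before the deterministic response is added).
    """
    net = replace(network, duration=paradigm.duration_s)
    movie, gt = simulate_resting(atlas, net, seed, coupling=coupling,
                                 lesion=lesion, session=session)
    idx = net.node_index(target_node)  # raises KeyError for unknown nodes
    node = net.nodes[idx]
    fs = net.sampling_rate
    trace = evoked_timecourse(paradigm, fs)  # unit peak

    responses = []  # (center, sigma, peak amplitude)
    amp_eff = amplitude
    if lesion is not None and lesion.active(session) and lesion.covers(node.center):
        amp_eff = amplitude * (1.0 - lesion.attenuation)
    responses.append((node.center, node.sigma, amp_eff))
    if lesion is not None and lesion.remap_active(session):
        responses.append((lesion.remap_center, node.sigma,
                          amplitude * lesion.remap_fraction))

    rows = np.arange(atlas.height)[:, None]
    cols = np.arange(atlas.width)[None, :]
    resp_hbt = np.zeros_like(movie.hbt)
    for center, sigma, amp in responses:
        if amp == 0.0:
            continue
        d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
        fp = np.exp(-d2 / (2.0 * sigma ** 2))
        resp_hbt += amp * trace[:, None, None] * fp
    hbt = movie.hbt + resp_hbt
    out, hbo, hbr = _hemo_from_hbt(hbt, atlas, fs, coupling)
    gt = replace(gt, hbt=hbt, hbo=hbo, hbr=hbr, evoked_amplitude=amplitude,
                 block_onsets_s=paradigm.onsets_s(),
                 response_center=node.center)
    return out, gt


def simulate_photostim(atlas: AtlasSpec, paradigm: StimParadigm,
                       target_center: tuple, amplitude: float, seed: int,
                       surround_weight: float = 0.0,
                       target_sigma: float = 4.0,
                       background_amp: float = 0.15,
                       background_sigma_frac: float = 0.31,
                       ring_radius_frac: float = 0.19,
                       ring_sigma_frac: float = 0.047,
                       noise_sd: float = 0.1,
                       coupling: float = DEFAULT_COUPLING,
                       frame_rate: float | None = None):
    """Photostimulus session: driven site plus graded surround coupling.

    The driven HbT time course s(t) (boxcar x HRF, unit peak) propagates
    with a spatial coupling map

        c(p) = exp(-d^2 / 2 sigma_t^2)                 (driven site)
             + background_amp * exp(-d^2 / 2 sigma_b^2)  (positive spread)
             + surround_weight * ring(p)                  (annular surround)

    where ring(p) is a unit-peak Gaussian annulus at ``ring_radius_frac x
    width`` from the target. With surround_weight < 0 an annulus of cortex
    becomes anticorrelated with the driven seed; the anticorrelated area
    grows smoothly as the weight becomes more negative. Fractions are of the
    atlas width, so scenarios scale with grid size. noise_sd is relative to
    ``amplitude``.
    """
    rng = np.random.default_rng(seed)
    if frame_rate is None:
        frame_rate = 10.0 if paradigm.kind == "optogenetic" else 1.0
    fs = float(frame_rate)
    trace = evoked_timecourse(paradigm, fs)
    n = trace.size
    rows = np.arange(atlas.height)[:, None]
    cols = np.arange(atlas.width)[None, :]
    d = np.hypot(rows - target_center[0], cols - target_center[1])
    sigma_b = background_sigma_frac * atlas.width
    r0 = ring_radius_frac * atlas.width
    sigma_r = ring_sigma_frac * atlas.width
    coupling_map = (np.exp(-d ** 2 / (2 * target_sigma ** 2))
                    + background_amp * np.exp(-d ** 2 / (2 * sigma_b ** 2))
                    + surround_weight * np.exp(-(d - r0) ** 2 / (2 * sigma_r ** 2)))
    hbt = amplitude * trace[:, None, None] * coupling_map[None, :, :]
    if noise_sd > 0:
        hbt = hbt + rng.standard_normal(hbt.shape) * (noise_sd * amplitude)
    movie, hbo, hbr = _hemo_from_hbt(hbt, atlas, fs, coupling)
    gt = GroundTruth(hbt=hbt, hbo=hbo, hbr=hbr, network=None, lesion=None,
                     evoked_amplitude=amplitude, rng_seed=seed,
                     block_onsets_s=paradigm.onsets_s(),
                     response_center=tuple(target_center),
                     extras={"coupling_map": coupling_map,
                             "surround_weight": surround_weight,
                             "frame_rate": fs})
    return movie, gt


def reflectance_forward(hbo: np.ndarray, hbr: np.ndarray, optics: OpticsModel,
                        frame_rate: float, mask: np.ndarray,
                        noise_sd: float = 0.0,
                        rng: np.random.Generator | None = None) -> ReflectanceStack:
    """Forward Beer-Lambert model: concentrations -> relative reflectance.

    R_lambda(t) = exp(-[eps_HbO dHbO + eps_HbR dHbR] L(lambda)), with the
    baseline reflectance set to 1 by convention. Optional multiplicative
    measurement noise of relative SD ``noise_sd``.
    """
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    if hbo.shape != hbr.shape:
        raise ValueError("hbo and hbr must share dimensions")
    A = optics.design_matrix  # (n_wl, 2), 1/M
    atten = (A[:, 0, None, None, None] * hbo[None]
             + A[:, 1, None, None, None] * hbr[None])
    data = np.exp(-atten)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        data = data * (1.0 + noise_sd * rng.standard_normal(data.shape))
    return ReflectanceStack(data=data, wavelengths=tuple(optics.wavelengths),
                            frame_rate=frame_rate,
                            mask=np.asarray(mask, bool))


# --------------------------------------------------------------------------
# ancillary tables


def simulate_behavior(group_effects: dict, n_mice: int, seed: int,
                      total_contact_s: float = 40.0) -> pd.DataFrame:
    """Paw-use contact-time table with planted group asymmetry effects.

    group_effects maps group name -> (mean asymmetry, SD). Asymmetry a in
    (-1, 1) is converted to single-paw wall-contact times with
    t_left + t_right = total_contact_s; t_both is an independent positive
    duration. Returns a tidy DataFrame (mouse, group, t_left, t_right,
    t_both).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in group_effects:
        mean, sd = group_effects[group]
        a = np.clip(rng.normal(mean, sd, size=n_mice), -0.95, 0.95)
        t_both = rng.uniform(5.0, 15.0, size=n_mice)
        for i in range(n_mice):
            rows.append({
                "mouse": f"{group}_{i:02d}",
                "group": group,
                "t_left": total_contact_s * (1.0 + a[i]) / 2.0,
                "t_right": total_contact_s * (1.0 - a[i]) / 2.0,
                "t_both": t_both[i],
            })
    return pd.DataFrame(rows)


def simulate_expression(n_genes: int, group_log2_effects: dict, sd: float,
                        seed: int, n_samples: int = 5,
                        reference_gene: str = "Gapdh") -> tuple:
    """qPCR Ct table with planted log2 fold-change group effects.

    group_log2_effects maps group name -> per-gene log2 fold changes
    relative to the first (control) group; entries may be scalars
    (broadcast) or length-n_genes arrays. Each sample gets a reference-gene
    Ct near 18 and target-gene Cts offset by gene-specific baselines minus
    the planted effect, plus N(0, sd) technical noise.

    Returns (ct_table, metadata): ct_table is a genes x samples DataFrame
    (reference gene included as a row); metadata maps sample -> group.
    """
    rng = np.random.default_rng(seed)
    genes = [f"gene{g:02d}" for g in range(n_genes)]
    base = rng.uniform(4.0, 8.0, size=n_genes)  # baseline dCt per gene
    columns, meta_rows, data = [], [], []
    for group, eff in group_log2_effects.items():
        eff = np.broadcast_to(np.asarray(eff, dtype=float), (n_genes,))
        for s in range(n_samples):
            sample = f"{group}_s{s:02d}"
            ct_ref = 18.0 + rng.normal(0.0, 0.1)
            ct = ct_ref + base - eff + rng.normal(0.0, sd, size=n_genes)
            columns.append(sample)
            meta_rows.append({"sample": sample, "group": group})
            data.append(np.concatenate([[ct_ref], ct]))
    table = pd.DataFrame(np.column_stack(data),
                         index=[reference_gene] + genes, columns=columns)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return table, meta
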