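"""Spatial PCA of correlation-difference matrices, permutation eigenvalue
testing, data-driven ROI derivation, and regional recovery summaries.

The group-level difference of whole-cortex correlation matrices is
eigendecomposed (after symmetric double mean-centering, which removes each
unit's mean connectivity offset while preserving symmetry); leading
components are spatial maps of the dominant between-group connectivity
differences. Their significance is assessed by permuting group labels and
re-measuring the first two eigenvalues (90th-percentile criterion).
Significant component maps are symmetrized about the midline, smoothed,
thresholded at 85% of extremum, and split into connected components to
yield data-driven ROIs for regional RSFC recovery analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sps

from .atlas import AtlasSpec
from .rsfc import CorrMatrix, SeedROI
from .stats import bh_fdr

log = logging.getLogger(__name__)


@dataclass
class PCResult:
    """Eigendecomposition of a (centered) symmetric difference matrix.

    components are unit-norm eigenvectors (optionally reshaped to mask
    images via ``component_map``); eigenvalues descend; variance_explained
    is each eigenvalue over the total absolute eigenvalue mass (signed).
    """

    components: np.ndarray        # (n, n): column k = PC k
    eigenvalues: np.ndarray       # descending
    variance_explained: np.ndarray
    index: tuple

    def component_map(self, k: int, shape) -> np.ndarray:
        """Reshape PC k to an image at the matrix's pixel index."""
        img = np.full(shape, np.nan)
        for (rr, cc), v in zip(self.index, self.components[:, k]):
            img[rr, cc] = v
    # NaN outside the sampled grid; callers interpolate or mask as needed
        return img


def _double_center(m: np.ndarray) -> np.ndarray:
    row = m.mean(axis=1, keepdims=True)
    col = m.mean(axis=0, keepdims=True)
    return m - row - col + m.mean()


def spatial_pca(diff: CorrMatrix, center: bool = True) -> PCResult:
    """Eigendecomposition of the symmetric correlation-difference matrix.

    ``center=True`` applies symmetric double mean-centering first.
    Eigenvalues are returned in descending order. Variance fractions are
    signed: eigenvalue / sum(|eigenvalues|), which reduces to the usual
    eigenvalue / trace for positive-semidefinite inputs but stays bounded
    for difference matrices whose spectrum straddles zero. The raw
    eigenvalue sum equals the trace of the (centered) matrix.
    """
    m = np.asarray(diff.z, dtype=float)
    if not np.allclose(m, m.T, atol=1e-10, equal_nan=True):
        raise ValueError("difference matrix must be symmetric")
    if not np.all(np.isfinite(m)):
        raise ValueError("difference matrix must be finite")
    if center:
        m = _double_center(m)
    w, v = np.linalg.eigh(m)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    total = np.abs(w).sum()
    frac = w / total if total > 0 else np.zeros_like(w)
    return PCResult(components=v, eigenvalues=w, variance_explained=frac,
                    index=diff.index)


@dataclass
class PermutationResult:
    null_eigenvalues: np.ndarray  # (n_iterations, 2)
    observed: np.ndarray          # first two observed eigenvalues
    percentile_criterion: float
    significant: np.ndarray       # (2,) booleans
    n_iterations: int
    seed: int


def _first_two_eigs(mats: np.ndarray, labels: np.ndarray, center: bool) -> np.ndarray:
    diff = mats[labels].mean(axis=0) - mats[~labels].mean(axis=0)
    if center:
        diff = _double_center(diff)
    w = np.linalg.eigvalsh(diff)
    return w[::-1][:2]


def permutation_eigen_test(mouse_matrices, labels, n: int = 3000,
                           percentile: float = 90.0, seed: int = 0,
                           center: bool = True,
                           statistic: str = "eigenvalue") -> PermutationResult:
    """Permutation null for the first two eigenvalues of the group difference.

    Each iteration shuffles the group labels, recomputes the group-mean
    difference matrix and its two leading eigenvalues. A component is
    significant when its observed eigenvalue exceeds the null's
    ``percentile``-th percentile. ``statistic="fraction"`` tests variance
    fractions instead of raw eigenvalues.

    Requires >= 3 mice per group; warns if fewer than ``n`` distinct
    permutations exist (labels are then resampled with replacement, which
    is what unrestricted shuffling does anyway).
    """
    mats = np.stack([m.z if isinstance(m, CorrMatrix) else np.asarray(m)
                     for m in mouse_matrices])
    labels = np.asarray(labels, dtype=bool)
    n_a, n_b = int(labels.sum()), int((~labels).sum())
    if min(n_a, n_b) < 3:
        raise ValueError("need at least 3 mice per group")
    from math import comb
    if comb(n_a + n_b, n_a) < n:
        warnings.warn("fewer distinct permutations than iterations; "
                      "sampling with replacement", stacklevel=2)

    def stat(lab):
        w = _first_two_eigs(mats, lab, center)
        if statistic == "fraction":
            diff = mats[lab].mean(axis=0) - mats[~lab].mean(axis=0)
            if center:
                diff = _double_center(diff)
            total = np.linalg.eigvalsh(diff).sum()
            return w / total if abs(total) > 0 else np.zeros(2)
        return w

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    null = np.empty((n, 2))
    for i in range(n):
        null[i] = stat(rng.permutation(labels))
    crit = np.percentile(null, percentile, axis=0)
    significant = observed > crit
    return PermutationResult(null_eigenvalues=null, observed=observed,
                             percentile_criterion=percentile,
                             significant=significant, n_iterations=n,
                             seed=seed)


@dataclass
class ROISet:
    rois: list                  # SeedROI
    per_hemisphere: dict        # hemisphere -> count
    sources: list               # (pc_index, sign) per ROI

    def __iter__(self):
        return iter(self.rois)

    def __len__(self):
        return len(self.rois)


def derive_rois(pc_map: np.ndarray, atlas: AtlasSpec, pc_index: int = 0,
                smooth_sigma: float = 2.0,
                threshold_frac: float = 0.85) -> ROISet:
    """Data-driven ROIs from a principal-component map.

    The map is averaged with its left-right mirror about the atlas midline,
    Gaussian-smoothed, and thresholded at ``threshold_frac`` of its maximum
    (positive lobe) and of its minimum (negative lobe). Surviving pixels are
    split into 8-connected components, split again at the midline so each
    ROI lies within one hemisphere. Empty thresholding yields an empty set
    with a warning.
    """
    m = np.where(atlas.brain_mask, np.nan_to_num(pc_map, nan=0.0), 0.0)
    mirrored = 0.5 * (m + m[:, ::-1])
    sm = ndimage.gaussian_filter(mirrored, smooth_sigma)
    sm[~atlas.brain_mask] = 0.0
    cols = np.arange(atlas.width)[None, :]
    hemi_masks = {"left": cols < atlas.midline_col,
                  "right": cols > atlas.midline_col}
    structure = np.ones((3, 3), bool)  # 8-connectivity

    rois, sources = [], []
    for sign, sel in (("pos", sm >= threshold_frac * sm.max() if sm.max() > 0
                       else np.zeros_like(sm, bool)),
                      ("neg", sm <= threshold_frac * sm.min() if sm.min() < 0
                       else np.zeros_like(sm, bool))):
        sel = sel & atlas.brain_mask
        if not sel.any():
            continue
        labeled, n_comp = ndimage.label(sel, structure=structure)
        for comp in range(1, n_comp + 1):
            comp_mask = labeled == comp
            for hemi, hmask in hemi_masks.items():
                part = comp_mask & np.broadcast_to(hmask, comp_mask.shape)
                if part.any():
                    rois.append(SeedROI(
                        name=f"PC{pc_index + 1}_{sign}_{len(rois)}_{hemi[0].upper()}",
                        pixels=part, provenance="PCA-derived"))
                    sources.append((pc_index, sign))
    if not rois:
        warnings.warn("ROI derivation produced an empty set at this threshold",
                      stacklevel=2)
    per_hemi = {"left": sum(r.name.endswith("_L") for r in rois),
                "right": sum(r.name.endswith("_R") for r in rois)}
    return ROISet(rois=rois, per_hemisphere=per_hemi, sources=sources)


@dataclass
class RecoveryMatrix:
    """Change in RSFC magnitude |z| from week 1 to week 4, ROI x ROI."""

    values: np.ndarray
    significant: np.ndarray
    q_values: np.ndarray
    index: tuple


def _check_matched(week4, week1):
    m4 = [m.z if isinstance(m, CorrMatrix) else np.asarray(m) for m in week4]
    m1 = [m.z if isinstance(m, CorrMatrix) else np.asarray(m) for m in week1]
    if len(m4) != len(m1) or not m4:
        raise ValueError("week-4 and week-1 matrices must be matched per mouse")
    if any(a.shape != m4[0].shape for a in m4 + m1):
        raise ValueError("matrix shapes mismatch")
    return np.stack(m4), np.stack(m1)


def recovery_matrix(week4, week1, index=None, q: float = 0.05) -> RecoveryMatrix:
    """Group-mean |z week4| - |z week1| with paired-test significance.

    Per element, the across-mice mean change in connection magnitude;
    significance from a paired t-test of per-mouse |z| changes across the
    upper triangle, BH-FDR corrected at ``q``.
    """
    m4, m1 = _check_matched(week4, week1)
    delta = np.abs(m4) - np.abs(m1)  # (mice, n, n)
    values = delta.mean(axis=0)
    n = values.shape[0]
    iu = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tres = sps.ttest_rel(delta[:, iu[0], iu[1]],
                             np.zeros_like(delta[:, iu[0], iu[1]]), axis=0)
    p = np.nan_to_num(tres.pvalue, nan=1.0)
    flags, adj = bh_fdr(p, q=q)
    sig = np.zeros((n, n), dtype=bool)
    qmat = np.ones((n, n))
    sig[iu] = flags
    sig |= sig.T
    qmat[iu] = adj
    qmat = np.minimum(qmat, qmat.T)
    if index is None:
        idx = week4[0].index if isinstance(week4[0], CorrMatrix) else tuple(range(n))
    else:
        idx = tuple(index)
    return RecoveryMatrix(values=values, significant=sig, q_values=qmat, index=idx)


def recovery_difference(group_a_week4, group_a_week1, group_b_week4,
                        group_b_week1, rois=None, q: float = 0.05):
    """Between-group difference of recovery matrices, plus a signed edge list.

    Computes per-mouse recovery (|z4| - |z1|) in each group, takes the
    difference of group means (A minus B), tests each edge with a Welch t
    across groups, BH-FDR corrects, and emits significant edges as a
    stick-and-ball table (ROI names, centroids when ``rois`` given, signed
    magnitude, q).
    """
    a4, a1 = _check_matched(group_a_week4, group_a_week1)
    b4, b1 = _check_matched(group_b_week4, group_b_week1)
    rec_a = np.abs(a4) - np.abs(a1)
    rec_b = np.abs(b4) - np.abs(b1)
    diff = rec_a.mean(axis=0) - rec_b.mean(axis=0)
    n = diff.shape[0]
    iu = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tres = sps.ttest_ind(rec_a[:, iu[0], iu[1]], rec_b[:, iu[0], iu[1]],
                             axis=0, equal_var=False)
    p = np.nan_to_num(tres.pvalue, nan=1.0)
    flags, adj = bh_fdr(p, q=q)
    index = (group_a_week4[0].index if isinstance(group_a_week4[0], CorrMatrix)
             else tuple(range(n)))
    edges = []
    centroids = {r.name: r.centroid() for r in rois} if rois else {}
    for k, (i, j) in enumerate(zip(*iu)):
        if flags[k]:
            edges.append({
                "roi_a": index[i], "roi_b": index[j],
                "delta_z": float(diff[i, j]),
                "sign": int(np.sign(diff[i, j])),
                "q_value": float(adj[k]),
                "centroid_a": centroids.get(index[i]),
                "centroid_b": centroids.get(index[j]),
            })
    return diff, edges
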