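"""Ancillary study metrics: paw-use asymmetry, infarct volume, comparative-Ct
expression quantification, clustering normalization, and fold-change tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .stats import bh_fdr, welch_t


# --------------------------------------------------------------------------
# behavior


def asymmetry_score(t_left: float, t_right: float, t_both: float = 0.0) -> float:
    """Paw-use asymmetry (% left - % right) / (% left + % right).

    Percentages are computed from single-paw wall-contact times only
    (both-paw contacts are excluded from numerator and denominator, under
    which the score reduces to (t_left - t_right) / (t_left + t_right)).
    Returns NaN when no single-paw contact was recorded.
    """
    if t_left < 0 or t_right < 0 or t_both < 0:
        raise ValueError("contact times must be non-negative")
    denom = t_left + t_right
    if denom == 0:
        return float("nan")
    return (t_left - t_right) / denom


def baseline_exclusion(scores: dict) -> list:
    """Drop mice with baseline |asymmetry| > 0.5 (strictly) for either limb.

    ``scores`` maps mouse -> baseline asymmetry; returns kept mouse ids in
    input order. A score of exactly 0.5 is kept.
    """
    return [m for m, s in scores.items() if abs(s) <= 0.5]


# --------------------------------------------------------------------------
# histology


def infarct_volume(areas_mm2, spacing_mm: float = 0.3) -> float:
    """Infarct volume: total cross-sectional infarct area x section spacing.

    Sections are 300 um apart by default. Empty input gives 0.
    """
    areas = np.asarray(list(areas_mm2), dtype=float)
    if areas.size and np.any(areas < 0):
        raise ValueError("infarct areas must be non-negative")
    return float(areas.sum() * spacing_mm)


# --------------------------------------------------------------------------
# expression


def comparative_ct(ct_table: pd.DataFrame, metadata: pd.DataFrame,
                   control_group: str,
                   reference_gene: str = "Gapdh") -> pd.DataFrame:
    """Relative expression by the comparative Ct (2^-ddCt) method.

    dCt = Ct_gene - Ct_reference per sample; ddCt subtracts the control
    group's mean dCt per gene; relative level = 2^-ddCt. Returns a genes x
    samples DataFrame (reference gene excluded — its relative level is
    identically 1).
    """
    if reference_gene not in ct_table.index:
        raise ValueError(f"reference gene {reference_gene!r} missing")
    control = metadata.index[metadata["group"] == control_group]
    if len(control) == 0:
        raise ValueError(f"control group {control_group!r} has no samples")
    dct = ct_table.drop(index=reference_gene).sub(
        ct_table.loc[reference_gene], axis=1)
    ddct = dct.sub(dct[control].mean(axis=1), axis=0)
    return 2.0 ** (-ddct)


def normalize_for_clustering(levels: pd.DataFrame):
    """Per gene: subtract the cross-group mean, scale to unit variance.

    Zero-variance (constant) genes are excluded and returned separately.
    """
    if levels.shape[1] < 2:
        raise ValueError("need at least 2 groups per gene")
    sd = levels.std(axis=1, ddof=1)
    flagged = levels.index[sd == 0].tolist()
    kept = levels.loc[sd > 0]
    normed = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return normed, flagged


def _canonical_order(link: np.ndarray, n_leaves: int, labels=None) -> list:
    """Leaf order with children swapped so the subtree containing the
    lexicographically smallest row label always comes first, making the
    order a function of the tree alone (invariant to input row order)."""
    if labels is None:
        labels = [str(i) for i in range(n_leaves)]
    min_leaf = {i: str(labels[i]) for i in range(n_leaves)}
    children = {}
    for k, (a, b, _, _) in enumerate(link):
        a, b = int(a), int(b)
        node = n_leaves + k
        if min(min_leaf[a], min_leaf[b]) == min_leaf[b]:
            a, b = b, a
        children[node] = (a, b)
        min_leaf[node] = min(min_leaf[a], min_leaf[b])

    order = []

    def walk(node):
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur < n_leaves:
                order.append(cur)
            else:
                a, b = children[cur]
                stack.extend([b, a])

    walk(n_leaves + len(link) - 1)
    return order


def hierarchical_cluster(matrix: pd.DataFrame, method: str = "average"):
    """Agglomerative clustering of genes (rows): average linkage, Euclidean.

    Returns (linkage matrix, leaf order as row labels). Child order within
    the tree is canonicalized (subtree containing the lexicographically
    smallest row label first) so topologically identical inputs yield
    identical leaf orders regardless of input row order.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    values = matrix.to_numpy(dtype=float)
    link = hierarchy.linkage(pdist(values, metric="euclidean"), method=method)
    order = _canonical_order(link, matrix.shape[0], labels=list(matrix.index))
    return link, [matrix.index[i] for i in order]


def fold_change_table(levels: pd.DataFrame, metadata: pd.DataFrame,
                      treated_group: str, control_group: str,
                      q: float = 0.1) -> pd.DataFrame:
    """Per-gene (and per-tissue, when present) fold change with Welch t + FDR.

    fold = mean relative level (treated) / mean relative level (control);
    the Welch t-test runs on log2 relative levels (the ddCt scale, which is
    variance-stabilizing); BH-FDR flags at ``q``. Requires >= 2 samples per
    cell; degenerate variances yield p = NaN (never flagged).
    """
    tissues = (sorted(metadata["tissue"].unique())
               if "tissue" in metadata.columns else [None])
    rows = []
    for tissue in tissues:
        meta = metadata if tissue is None else metadata[metadata["tissue"] == tissue]
        treated = meta.index[meta["group"] == treated_group]
        control = meta.index[meta["group"] == control_group]
        if len(treated) < 2 or len(control) < 2:
            raise ValueError("need at least 2 samples per group")
        for gene in levels.index:
            a = levels.loc[gene, treated].to_numpy(dtype=float)
            b = levels.loc[gene, control].to_numpy(dtype=float)
            fold = a.mean() / b.mean()
            la, lb = np.log2(a), np.log2(b)
            if la.var(ddof=1) == 0 and lb.var(ddof=1) == 0 and la.mean() != lb.mean():
                p = float("nan")
            else:
                p = welch_t(la, lb).p
            rows.append({"gene": gene, "tissue": tissue, "fold_change": fold,
                         "p_value": p})
    table = pd.DataFrame(rows)
    pvals = table["p_value"].fillna(1.0).to_numpy()
    flags, adj = bh_fdr(pvals, q=q)
    table["q_value"] = adj
    table["significant"] = flags & table["p_value"].notna().to_numpy()
    if tissues == [None]:
        table = table.drop(columns=["tissue"])
    return table
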