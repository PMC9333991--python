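"""End-to-end synthetic study: 2 groups x 3 sessions, all analyses.

Runs the full pipeline on a generated longitudinal stroke-recovery study:

* groups ``minus_stim`` (lesion, no intervention) and ``plus_stim``
  (lesion + contralesional photostimulation), sessions baseline / week1 /
  week4;
* per mouse and session: evoked electrical-stimulation movies, resting
  movies, and photostimulation movies, each passed through the forward
  optics model, Beer-Lambert inversion, and the preprocessing pipelines
  before analysis;
* planted recovery story: the lesion attenuates the left forepaw node by
  80% at week 1; by week 4 a remapped response appears perilesionally
  (strongly in minus_stim, weakly in plus_stim), homotopic forepaw RSFC
  recovers in minus_stim only, and the photostim inhibition surround is
  deeper in plus_stim;
* outputs deterministic CSV/JSON tables under ``outdir``.

Everything is a pure function of the master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancillary, evoked, pca, photostim, preprocess, rsfc
from .atlas import AtlasSpec, make_atlas
from .io import write_json
from .optics import default_optics
from .spectroscopy import invert_beer_lambert, normalize_reflectance
from .synthetic import (SESSIONS, LesionSpec, NetworkSpec, StimParadigm,
                        default_network, electrical_paradigm,
                        optogenetic_paradigm, reflectance_forward,
                        simulate_evoked, simulate_photostim, simulate_resting)

log = logging.getLogger(__name__)

GROUPS = ("minus_stim", "plus_stim")

FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class StudyConfig:
    """Problem sizes and planted effects for the synthetic study.

    The default is a desk-scale study: 64x64 grid, 3 mice per group,
    shortened paradigms. Planted effects follow the study narrative (see
    module docstring).
    """

    grid: int = 64
    pixel_size_mm: float = 0.156
    n_mice: int = 3
    evoked_blocks: int = 6
    evoked_rate_hz: float = 2.0
    evoked_amplitude: float = 5e-6
    rest_duration_s: float = 240.0
    rest_acq_rate_hz: float = 4.0
    photostim_blocks: int = 6
    photostim_rate_hz: float = 2.0
    lesion_attenuation: float = 0.8
    noise_sd: float = 0.1
    global_sd: float = 0.3
    perm_iterations: int = 200
    #: S1FP homotopic correlation per (group, session)
    s1fp_homotopic: tuple = (("minus_stim", "baseline", 0.7),
                             ("minus_stim", "week1", 0.2),
                             ("minus_stim", "week4", 0.6),
                             ("plus_stim", "baseline", 0.7),
                             ("plus_stim", "week1", 0.2),
                             ("plus_stim", "week4", 0.25))
    #: remapped-response amplitude fraction at week 4 per group
    remap_fraction: tuple = (("minus_stim", 0.9), ("plus_stim", 0.3))
    #: photostim anticorrelated-surround weight per (group, session)
    surround_weight: tuple = (("minus_stim", "baseline", 0.0),
                              ("minus_stim", "week1", -0.15),
                              ("minus_stim", "week4", -0.15),
                              ("plus_stim", "baseline", 0.0),
                              ("plus_stim", "week1", -0.5),
                              ("plus_stim", "week4", -0.5))

    def lookup(self, field_, *key):
        for entry in getattr(self, field_):
            if tuple(entry[:-1]) == key:
                return entry[-1]
        raise KeyError((field_, key))


def _seed_for(master: int, *tags) -> int:
    """Stable per-task integer seed derived from the master seed and tags."""
    import hashlib

    key = ":".join([str(master), *map(str, tags)]).encode()
    digest = hashlib.blake2s(key, digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2 ** 31 - 1)


def _study_network(cfg: StudyConfig, atlas: AtlasSpec, group: str,
                   session: str, rate_hz: float, duration_s: float) -> NetworkSpec:
    net = default_network(atlas, noise_sd=cfg.noise_sd,
                          global_sd=cfg.global_sd, sampling_rate=rate_hz,
                          duration=duration_s)
    target = cfg.lookup("s1fp_homotopic", group, session)
    edges = tuple(("S1FP_L", "S1FP_R", target) if (a, b) == ("S1FP_L", "S1FP_R")
                  else (a, b, r) for a, b, r in net.edges)
    net = replace(net, edges=edges)
    net.correlation_matrix()  # raises early if the edit broke PSD-ness
    return net


def _study_lesion(cfg: StudyConfig, net: NetworkSpec, group: str) -> LesionSpec:
    s1fp = net.nodes[net.node_index("S1FP_L")]
    dr = 0.09 * cfg.grid
    remap = (s1fp.center[0] + dr, s1fp.center[1] + 0.6 * dr)
    return LesionSpec(center=s1fp.center, radius=0.06 * cfg.grid,
                      attenuation=cfg.lesion_attenuation, remap_center=remap,
                      remap_onset_session="week4",
                      remap_fraction=cfg.lookup("remap_fraction", group))


def _acquire(movie, atlas, optics, seed_rng=None):
    """Forward optics -> raw counts -> normalization -> inversion.

    Emulates acquisition: relative reflectance is scaled to detector counts
    per wavelength before the ratiometric normalization recovers it.
    """
    stack = reflectance_forward(movie.hbo, movie.hbr, optics,
                                movie.frame_rate, atlas.brain_mask)
    gains = 400.0 + 50.0 * np.arange(len(optics.wavelengths))
    raw = stack.data * gains[:, None, None, None]
    stack = normalize_reflectance(raw, stack.wavelengths, stack.frame_rate,
                                  atlas.brain_mask)
    return invert_beer_lambert(stack, optics)


def run_study(seed: int, outdir, config: StudyConfig | None = None) -> dict:
    """Run the full synthetic study and write result tables under outdir.

    Returns a dict of the output DataFrames/objects for programmatic use.
    """
    cfg = config or StudyConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = make_atlas(cfg.grid, cfg.grid, cfg.pixel_size_mm)
    optics = default_optics()
    mask = atlas.brain_mask

    electrical = electrical_paradigm(cfg.evoked_blocks)
    opto = optogenetic_paradigm(cfg.photostim_blocks)
    mice = {g: [f"{g}_{i:02d}" for i in range(cfg.n_mice)] for g in GROUPS}

    peak_maps = {}      # (group, session, mouse) -> peak image
    tmaps = {}          # (group, session, mouse) -> TMap
    rest_movies = {}    # (group, session, mouse) -> preprocessed HemoMovie
    pixel_mats = {}     # (group, session, mouse) -> pixelwise CorrMatrix
    inhibition_rows = []
    qc_tables = []

    for group in GROUPS:
        for session in SESSIONS:
            net = _study_network(cfg, atlas, group, session,
                                 cfg.evoked_rate_hz, electrical.duration_s)
            lesion = _study_lesion(cfg, net, group)
            rest_net = _study_network(cfg, atlas, group, session,
                                      cfg.rest_acq_rate_hz, cfg.rest_duration_s)
            sw = cfg.lookup("surround_weight", group, session)
            s1fp_r = net.nodes[net.node_index("S1FP_R")].center
            rest_stacks = []
            for mouse in mice[group]:
                # --- evoked electrical path (task pipeline, native rate)
                mv, _ = simulate_evoked(
                    atlas, net, electrical, "S1FP_L", cfg.evoked_amplitude,
                    _seed_for(seed, group, session, mouse, "evoked"),
                    lesion=lesion, session=session)
                mv = _acquire(mv, atlas, optics)
                mv = preprocess.task_pipeline(mv)
                stack = evoked.extract_blocks(mv, electrical)
                avg = evoked.block_average(stack)
                peak_maps[(group, session, mouse)] = evoked.peak_map(
                    avg, electrical, mv.frame_rate)
                tmaps[(group, session, mouse)] = evoked.t_map(stack)

                # --- resting path (downsample to 1 Hz, RSFC band, GSR)
                rv, _ = simulate_resting(
                    atlas, rest_net,
                    _seed_for(seed, group, session, mouse, "rest"),
                    lesion=lesion, session=session)
                rest_stacks.append(reflectance_forward(
                    rv.hbo, rv.hbr, optics, rv.frame_rate, mask).data[0])
                rv = _acquire(rv, atlas, optics)
                rv = preprocess.rsfc_pipeline(rv, target_rate=1.0)
                rest_movies[(group, session, mouse)] = rv
                pixel_mats[(group, session, mouse)] = rsfc.corr_matrix(
                    rv, spatial_downsample=2)

                # --- photostimulation path (block-average denoising only)
                pv, _ = simulate_photostim(
                    atlas, opto, s1fp_r, cfg.evoked_amplitude,
                    _seed_for(seed, group, session, mouse, "photo"),
                    surround_weight=sw, target_sigma=0.03 * cfg.grid,
                    noise_sd=cfg.noise_sd, frame_rate=cfg.photostim_rate_hz)
                pv = _acquire(pv, atlas, optics)
                idx = photostim.session_inhibition(
                    pv, opto, photostim.StimTarget(s1fp_r),
                    pixel_size_mm=cfg.pixel_size_mm, subject=mouse,
                    session=session)
                inhibition_rows.append({
                    "mouse": mouse, "group": group, "session": session,
                    "anticorr_pixels": idx.value,
                    "anticorr_area_mm2": idx.area_mm2,
                    "anticorr_magnitude_sum": idx.magnitude_sum})
            qc = preprocess.quality_check(rest_stacks)
            t = qc.table.copy()
            t.insert(0, "session", session)
            t.insert(0, "group", group)
            qc_tables.append(t)

    results = {}

    # ---- evoked metrics: one 75% threshold per group from baseline maps
    ev_rows = []
    incidence_rows = []
    for group in GROUPS:
        base_maps = [peak_maps[(group, "baseline", m)] for m in mice[group]]
        thr = evoked.group_threshold(base_maps, mask)
        # response region from baseline AND week-4 group maps, so a
        # remapped representation is measured alongside the original one
        wk4_maps = [peak_maps[(group, "week4", m)] for m in mice[group]]
        region = ((np.mean(base_maps, axis=0) >= thr)
                  | (np.mean(wk4_maps, axis=0) >= thr))
        base = [evoked.response_metrics(pm, thr, mask, region=region)
                for pm in base_maps]
        base_mag = float(np.nanmean([b.magnitude for b in base]))
        base_area = float(np.mean([b.area for b in base]))
        for session in SESSIONS:
            maps = [peak_maps[(group, session, m)] for m in mice[group]]
            for mouse, pm in zip(mice[group], maps):
                em = evoked.response_metrics(
                    pm, thr, mask, baseline_magnitude=base_mag,
                    baseline_area=base_area, region=region,
                    subject=mouse, session=session)
                ev_rows.append({
                    "mouse": mouse, "group": group, "session": session,
                    "threshold": thr, "magnitude": em.magnitude,
                    "area_px": em.area, "magnitude_norm": em.magnitude_norm,
                    "area_norm": em.area_norm})
            inc = evoked.incidence_map(maps, thr, mask)
            net0 = default_network(atlas)
            s1fp_l = net0.nodes[net0.node_index("S1FP_L")].center
            incidence_rows.append({
                "group": group, "session": session,
                "incidence_at_s1fp": float(
                    inc[int(round(s1fp_l[0])), int(round(s1fp_l[1]))]),
                "suprathreshold_fraction": float(inc[mask].mean())})
    results["evoked_metrics"] = pd.DataFrame(ev_rows)
    results["incidence"] = pd.DataFrame(incidence_rows)

    # ---- week-4 effect size map (minus_stim minus plus_stim)
    esm = evoked.cohens_d_map(
        [tmaps[("minus_stim", "week4", m)] for m in mice["minus_stim"]],
        [tmaps[("plus_stim", "week4", m)] for m in mice["plus_stim"]])
    with np.errstate(invalid="ignore"):
        peak_d = (float(np.nanmax(esm.d)) if np.isfinite(esm.d).any()
                  else float("nan"))
    results["effect_size"] = pd.DataFrame([{
        "session": "week4", "included_pixels": int(esm.inclusion_mask.sum()),
        "peak_cohens_d": peak_d}])

    # ---- homotopic RSFC from node-footprint seed ROIs
    net0 = default_network(atlas)
    rsfc_rows = []
    for group in GROUPS:
        for session in SESSIONS:
            for mouse in mice[group]:
                rv = rest_movies[(group, session, mouse)]
                for name in ("S1FP", "M1", "V1"):
                    zl = _node_roi(net0, atlas, f"{name}_L")
                    zr = _node_roi(net0, atlas, f"{name}_R")
                    tl = rsfc.roi_timecourse(rv, zl)
                    tr = rsfc.roi_timecourse(rv, zr)
                    r = float(np.corrcoef(tl, tr)[0, 1])
                    rsfc_rows.append({
                        "mouse": mouse, "group": group, "session": session,
                        "pair": name, "z": float(rsfc.fisher_z(r))})
    results["rsfc_homotopic"] = pd.DataFrame(rsfc_rows)

    # ---- node degree
    deg_rows = []
    for (group, session, mouse), mat in pixel_mats.items():
        nd = rsfc.node_degree(mat, thr_z=0.4)
        deg_rows.append({"mouse": mouse, "group": group, "session": session,
                         "mean_degree": float(nd.degree.mean()),
                         "max_degree": int(nd.degree.max())})
    results["node_degree"] = pd.DataFrame(deg_rows)

    # ---- spatial PCA of the week-4 group difference + permutation test
    week4_mats = [pixel_mats[(g, "week4", m)] for g in GROUPS
                  for m in mice[g]]
    labels = np.array([g == "minus_stim" for g in
                       [g for g in GROUPS for _ in mice[g]]])
    diff = rsfc.difference_matrix(
        [pixel_mats[("minus_stim", "week4", m)] for m in mice["minus_stim"]],
        [pixel_mats[("plus_stim", "week4", m)] for m in mice["plus_stim"]])
    pcres = pca.spatial_pca(diff)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        perm = pca.permutation_eigen_test(
            week4_mats, labels, n=cfg.perm_iterations,
            seed=_seed_for(seed, "perm"))
    spec_rows = [{"component": k + 1,
                  "eigenvalue": float(pcres.eigenvalues[k]),
                  "variance_explained": float(pcres.variance_explained[k]),
                  "significant": bool(perm.significant[k]) if k < 2 else False}
                 for k in range(min(10, len(pcres.eigenvalues)))]
    results["pca_eigenspectrum"] = pd.DataFrame(spec_rows)

    # ---- PCA-derived ROIs and regional recovery
    pc1 = _upsample_component(pcres, 0, atlas, factor=2)
    roiset = pca.derive_rois(pc1, atlas, pc_index=0)
    results["roiset"] = roiset
    roi_json = [{"name": r.name, "provenance": r.provenance,
                 "hemisphere": "left" if r.name.endswith("_L") else "right",
                 "centroid": list(r.centroid()), "n_pixels": r.size}
                for r in roiset]
    if len(roiset) >= 2:
        regional = {
            (g, s, m): rsfc.corr_matrix(rest_movies[(g, s, m)],
                                        rois=list(roiset))
            for g in GROUPS for s in ("week1", "week4") for m in mice[g]}
        rec = {g: pca.recovery_matrix(
            [regional[(g, "week4", m)] for m in mice[g]],
            [regional[(g, "week1", m)] for m in mice[g]]) for g in GROUPS}
        diff_rec, edges = pca.recovery_difference(
            [regional[("plus_stim", "week4", m)] for m in mice["plus_stim"]],
            [regional[("plus_stim", "week1", m)] for m in mice["plus_stim"]],
            [regional[("minus_stim", "week4", m)] for m in mice["minus_stim"]],
            [regional[("minus_stim", "week1", m)] for m in mice["minus_stim"]],
            rois=list(roiset))
        results["recovery_edges"] = pd.DataFrame(
            edges, columns=["roi_a", "roi_b", "delta_z", "sign", "q_value",
                            "centroid_a", "centroid_b"])
        rec_rows = [{"group": g, "mean_recovery": float(rec[g].values[
            ~np.eye(rec[g].values.shape[0], dtype=bool)].mean())}
            for g in GROUPS]
        results["recovery_summary"] = pd.DataFrame(rec_rows)

    results["inhibition_index"] = pd.DataFrame(inhibition_rows)
    results["qc_report"] = pd.concat(qc_tables, ignore_index=True)

    # ---- behavior
    from .synthetic import simulate_behavior
    behavior_effects = {
        "baseline": {"minus_stim": (0.0, 0.1), "plus_stim": (0.0, 0.1)},
        "week1": {"minus_stim": (0.30, 0.12), "plus_stim": (0.30, 0.12)},
        "week4": {"minus_stim": (0.10, 0.10), "plus_stim": (0.28, 0.12)},
    }
    beh_rows = []
    n_beh = 8
    for session in SESSIONS:
        tab = simulate_behavior(behavior_effects[session], n_beh,
                                _seed_for(seed, "behavior", session))
        for _, row in tab.iterrows():
            beh_rows.append({
                "mouse": row["mouse"], "group": row["group"],
                "session": session,
                "score": ancillary.asymmetry_score(row["t_left"],
                                                   row["t_right"],
                                                   row["t_both"])})
    beh = pd.DataFrame(beh_rows)
    baseline_scores = {r["mouse"]: r["score"]
                       for _, r in beh[beh.session == "baseline"].iterrows()}
    kept = set(ancillary.baseline_exclusion(baseline_scores))
    beh["kept"] = beh["mouse"].isin(kept)
    results["behavior"] = beh

    # ---- expression
    from .synthetic import simulate_expression
    planted_log2 = np.array([1.2, -1.0, 0.8, 0.0, 0.0, -1.5,
                             0.6, 0.0, -0.7, 1.0, 0.0, 0.4])
    ct, meta = simulate_expression(
        n_genes=planted_log2.size,
        group_log2_effects={"minus_stim": 0.0, "plus_stim": planted_log2},
        sd=0.25, seed=_seed_for(seed, "expression"))
    levels = ancillary.comparative_ct(ct, meta, control_group="minus_stim")
    fc = ancillary.fold_change_table(levels, meta, treated_group="plus_stim",
                                     control_group="minus_stim", q=0.1)
    results["expression_fold_change"] = fc
    group_means = levels.T.groupby(meta["group"]).mean().T
    normed, _flagged = ancillary.normalize_for_clustering(group_means)
    _link, order = ancillary.hierarchical_cluster(normed)
    results["expression_cluster_order"] = list(order)

    # ---- write tables
    for name in ("evoked_metrics", "incidence", "effect_size",
                 "rsfc_homotopic", "node_degree", "pca_eigenspectrum",
                 "recovery_edges", "recovery_summary", "inhibition_index",
                 "qc_report", "behavior", "expression_fold_change"):
        if name in results:
            results[name].to_csv(out / f"{name}.csv", index=False,
                                 float_format=FLOAT_FMT)
    write_json(out / "pca_rois.json", roi_json)
    write_json(out / "expression_cluster_order.json",
               results["expression_cluster_order"])
    write_json(out / "study_config.json", {
        "seed": seed, "grid": cfg.grid, "n_mice": cfg.n_mice,
        "groups": list(GROUPS), "sessions": list(SESSIONS),
        "lesion_attenuation": cfg.lesion_attenuation})
    log.info("study complete: tables written to %s", out)
    return results


def _node_roi(net, atlas: AtlasSpec, name: str) -> rsfc.SeedROI:
    node = net.nodes[net.node_index(name)]
    rows = np.arange(atlas.height)[:, None]
    cols = np.arange(atlas.width)[None, :]
    d = np.hypot(rows - node.center[0], cols - node.center[1])
    return rsfc.SeedROI(name=name, pixels=(d <= node.sigma) & atlas.brain_mask,
                        provenance="baseline evoked")


def _upsample_component(pcres: pca.PCResult, k: int, atlas: AtlasSpec,
                        factor: int = 2) -> np.ndarray:
    """Fill a strided-grid PC map to full atlas resolution (block fill)."""
    img = np.zeros(atlas.shape)
    for (rr, cc), v in zip(pcres.index, pcres.components[:, k]):
        img[rr:rr + factor, cc:cc + factor] = v
    img[~atlas.brain_mask] = 0.0
    return img
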