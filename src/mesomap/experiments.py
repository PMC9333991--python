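"""Parameter-recovery experiments on synthetic data with known ground truth.

Each function plants a known quantity with the generator, runs the relevant
slice of the analysis pipeline, and measures how well the quantity is
recovered. These are the package's validation experiments: the tests assert
on their outputs, and the analysis drivers report them.
"""

from __future__ import annotations

import numpy as np

from . import evoked, photostim, preprocess, rsfc
from .atlas import make_atlas
from .optics import default_optics
from .pca import permutation_eigen_test
from .spectroscopy import invert_beer_lambert
from .synthetic import (LesionSpec, default_network, electrical_paradigm,
                        node_footprints, optogenetic_paradigm,
                        reflectance_forward, simulate_evoked,
                        simulate_photostim, simulate_resting)


def spectroscopy_roundtrip_error(seed: int, shape=(64, 64),
                                 n_frames: int = 300) -> dict:
    """Forward optics then Beer-Lambert inversion on noise-free dynamics.

    Relative error is max |recovered - planted| over the movie divided by
    max |planted| (pointwise relative error is ill-defined where the
    planted change crosses zero).
    """
    atlas = make_atlas(shape[1], shape[0])
    net = default_network(atlas, noise_sd=0.0, duration=float(n_frames),
                          sampling_rate=1.0)
    movie, gt = simulate_resting(atlas, net, seed)
    optics = default_optics()
    stack = reflectance_forward(gt.hbo, gt.hbr, optics, 1.0, atlas.brain_mask)
    rec = invert_beer_lambert(stack, optics)
    err_hbo = np.abs(rec.hbo - gt.hbo).max() / np.abs(gt.hbo).max()
    err_hbr = np.abs(rec.hbr - gt.hbr).max() / np.abs(gt.hbr).max()
    return {"max_rel_error": float(max(err_hbo, err_hbr)),
            "n": int(np.prod(shape)) * n_frames}


def correlation_recovery(seed: int, n_seeds: int = 20, grid: int = 64,
                         duration_s: float = 300.0) -> dict:
    """Planted network correlations vs pipeline Fisher-z estimates.

    For each seed: simulate resting dynamics on the default 10-node network
    (white node fluctuations at the 1 Hz analysis rate, so the Fisher-z
    sampling error is the textbook 1/sqrt(n-3)), run the forward optics and
    Beer-Lambert inversion, extract node-footprint ROI traces, and compare
    the empirical Fisher-z of all node pairs with atanh of the targets.
    Returns the pooled fraction of edges within 2/sqrt(n-3).
    """
    atlas = make_atlas(grid, grid)
    net = default_network(atlas, noise_sd=0.1, global_sd=0.0,
                          sampling_rate=1.0, duration=duration_s)
    optics = default_optics()
    target_z = np.arctanh(np.clip(net.correlation_matrix(), -0.999999, 0.999999))
    n = int(duration_s * net.sampling_rate)
    tol = 2.0 / np.sqrt(n - 3)
    fp = node_footprints(atlas, net.nodes)
    rois = [fp[i] >= np.exp(-0.5) for i in range(len(net.nodes))]  # d <= sigma

    within = total = 0
    errors = []
    for k in range(n_seeds):
        movie, gt = simulate_resting(atlas, net, seed + k)
        stack = reflectance_forward(gt.hbo, gt.hbr, optics,
                                    net.sampling_rate, atlas.brain_mask)
        rec = invert_beer_lambert(stack, optics)
        traces = np.column_stack([rec.hbt[:, m].mean(axis=1) for m in rois])
        z = np.arctanh(np.clip(np.corrcoef(traces, rowvar=False),
                               -0.999999, 0.999999))
        iu = np.triu_indices(len(net.nodes), k=1)
        err = np.abs(z[iu] - target_z[iu])
        errors.append(err)
        within += int((err <= tol).sum())
        total += err.size
    return {"fraction_within": within / total, "tolerance_z": float(tol),
            "n": total, "median_abs_error": float(np.median(np.concatenate(errors)))}


def _task_peak_map(atlas, net, paradigm, amplitude, seed, lesion, session):
    """Generator -> optics -> inversion -> task preprocessing -> peak map."""
    optics = default_optics()
    movie, gt = simulate_evoked(atlas, net, paradigm, "S1FP_L", amplitude,
                                seed, lesion=lesion, session=session)
    stack = reflectance_forward(gt.hbo, gt.hbr, optics, net.sampling_rate,
                                atlas.brain_mask)
    rec = invert_beer_lambert(stack, optics)
    rec = preprocess.task_pipeline(rec)
    blocks = evoked.extract_blocks(rec, paradigm)
    return evoked.peak_map(evoked.block_average(blocks), paradigm,
                           rec.frame_rate)


def evoked_recovery(seed: int, n_mice: int = 5, grid: int = 64,
                    attenuation: float = 0.8, n_blocks: int = 6,
                    amplitude: float = 5e-6) -> dict:
    """Lesion-attenuation recovery under the 75%-threshold procedure.

    Simulates one group at baseline and week 1 with a lesion of the given
    attenuation over the forepaw node, and measures the week-1 activation
    magnitude (normalized to the group baseline mean, measured within the
    baseline-defined activation region) and the week-1 activation area
    reduction.
    """
    atlas = make_atlas(grid, grid)
    paradigm = electrical_paradigm(n_blocks)
    net = default_network(atlas, noise_sd=0.1, global_sd=0.3,
                          sampling_rate=2.0, duration=paradigm.duration_s)
    s1fp = net.nodes[net.node_index("S1FP_L")]
    lesion = LesionSpec(center=s1fp.center, radius=0.06 * grid,
                        attenuation=attenuation)
    mask = atlas.brain_mask

    base_maps = [_task_peak_map(atlas, net, paradigm, amplitude, seed + i,
                                lesion, "baseline") for i in range(n_mice)]
    week1_maps = [_task_peak_map(atlas, net, paradigm, amplitude,
                                 seed + 100 + i, lesion, "week1")
                  for i in range(n_mice)]
    thr = evoked.group_threshold(base_maps, mask)
    region = np.mean(base_maps, axis=0) >= thr
    base = [evoked.response_metrics(m, thr, mask, region=region)
            for m in base_maps]
    base_mag = float(np.nanmean([b.magnitude for b in base]))
    base_area = float(np.mean([b.area for b in base]))
    week1 = [evoked.response_metrics(m, thr, mask,
                                     baseline_magnitude=base_mag,
                                     baseline_area=base_area, region=region)
             for m in week1_maps]
    mag_norm = float(np.nanmean([w.magnitude_norm for w in week1]))
    area_reduction = 1.0 - float(np.mean([w.area for w in week1])) / base_area
    return {"magnitude_norm_week1": mag_norm,
            "area_reduction": area_reduction,
            "n": n_mice}


def inhibition_monotonicity(seed: int, weights=(0.0, -0.2, -0.4, -0.6, -0.8),
                            n_seeds: int = 5, grid: int = 64,
                            n_blocks: int = 6, frame_rate: float = 2.0) -> dict:
    """Anticorrelated-surround weight vs global inhibition index.

    For each seed, sweeps the generator's surround coupling weight and
    records the per-session inhibition index (anticorrelated pixel count).
    Returns the counts and whether every sweep increased strictly.
    """
    atlas = make_atlas(grid, grid)
    paradigm = optogenetic_paradigm(n_blocks)
    center = (0.41 * grid, 0.7 * grid)
    target = photostim.StimTarget(center)
    counts = np.zeros((n_seeds, len(weights)), dtype=int)
    for s in range(n_seeds):
        for j, w in enumerate(weights):
            movie, _ = simulate_photostim(
                atlas, paradigm, center, 5e-6, seed + s,
                surround_weight=w, target_sigma=0.03 * grid,
                noise_sd=0.1, frame_rate=frame_rate)
            idx = photostim.session_inhibition(movie, paradigm, target)
            counts[s, j] = idx.value
    strict = bool(np.all(np.diff(counts, axis=1) > 0))
    return {"weights": list(weights), "counts": counts,
            "all_strictly_increasing": strict, "n": n_seeds}


def permutation_calibration(seed: int, n_runs: int = 200,
                            n_iterations: int = 200, n_mice: int = 10,
                            n_units: int = 16, percentile: float = 90.0) -> dict:
    """Type-I rate of the permutation eigenvalue criterion under the null.

    Each run draws per-mouse correlation-like symmetric matrices from one
    exchangeable population, splits them into two arbitrary groups, and
    applies the percentile criterion to the first eigenvalue. Under
    exchangeability the criterion should fire in about (100 - percentile)%
    of runs.
    """
    rng = np.random.default_rng(seed)
    labels = np.arange(n_mice) < n_mice // 2
    base = rng.standard_normal((n_units, n_units))
    base = 0.3 * (base + base.T) / np.sqrt(2)
    hits = 0
    for run in range(n_runs):
        noise = rng.standard_normal((n_mice, n_units, n_units))
        mats = base + 0.2 * (noise + noise.transpose(0, 2, 1)) / np.sqrt(2)
        res = permutation_eigen_test(
            list(mats), labels, n=n_iterations, percentile=percentile,
            seed=int(rng.integers(2 ** 31 - 1)))
        hits += int(res.significant[0])
    return {"rate": hits / n_runs, "n": n_runs,
            "expected": 1.0 - percentile / 100.0}
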