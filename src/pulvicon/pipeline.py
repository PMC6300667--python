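"""End-to-end pipeline driver composing all analysis stages.

``run_pipeline`` simulates (or loads) the multi-subject data, fits the
two-step coupling model, and writes every numeric result (similarity, MDS,
clusters, Dice, peaks, distance correlations, ISC, task indices) plus a
resolved-configuration snapshot into a deterministic directory layout.  All
randomness flows from the single configured seed via named substreams.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, isc, netstruct, synthdata, taskglm
from .connectivity import PulvinoCorticalModel
from .datatypes import SimulationConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def run_pipeline(config: io.PipelineConfig, output_dir=None) -> Path:
    """Run the full analysis; returns the results directory."""
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_config(config, out / "config_snapshot.txt")
    if not config.simulate:
        raise NotImplementedError(
            "only simulate=true runs are wired end-to-end; real data enter "
            "through the library API")

    results = {"seed": config.seed}

    # --- resting-state coupling ------------------------------------------
    sim = SimulationConfig(n_subjects=config.n_subjects,
                           seed=stage_seed(config.seed, "resting"))
    logger.info("stage resting: %d subjects, seed %d", sim.n_subjects, sim.seed)
    model, truth = PulvinoCorticalModel.from_simulation(
        sim, include_self=config.include_self,
        drop_seconds=config.drop_seconds,
        smooth_fwhm_mm=config.smooth_fwhm_mm, q=config.fdr_q)
    fit = model.fit()

    S = fit.map_similarity()
    names = fit.area_names
    io.write_table(pd.DataFrame(S, columns=names), out / "map_similarity.tsv")
    coords = fit.mds()
    io.write_table(pd.DataFrame({"area": names, "dim1": coords[:, 0],
                                 "dim2": coords[:, 1]}), out / "mds.tsv")
    labels = fit.clusters()
    dice = fit.dice_matrix(q=config.fdr_q)
    io.write_table(pd.DataFrame(dice, columns=names), out / "dice.tsv")

    dist = _hemi_average_distance(model.area_set)
    rel = netstruct.distance_relationships(dist, dice, labels)
    results["clusters"] = {n: int(l) for n, l in zip(names, labels)}
    results["n_clusters"] = int(labels.max() + 1)
    results["distance_vs_dice"] = rel
    results["planted_networks"] = truth.network_assignment

    peaks = {h: fit.peaks(h) for h in fit.hemispheres}
    peak_rows = []
    for name in names:
        if "L" in peaks and "R" in peaks:
            xyz = netstruct.bilateral_average(peaks["L"][name],
                                              peaks["R"][name])
        else:
            xyz = list(peaks.values())[0][name]
        peak_rows.append({"area": name, "x": xyz[0], "y": xyz[1],
                          "z": xyz[2]})
    io.write_table(pd.DataFrame(peak_rows), out / "peaks.tsv")

    if config.run_split_half and len(model.datasets) >= 4:
        sh = fit.split_half(iterations=config.split_half_iterations,
                            seed=stage_seed(config.seed, "split_half"))
        results["split_half"] = {h: {"mean": v["mean"], "sd": v["sd"]}
                                 for h, v in sh.items()}

    # subject-vs-group MDS permutation test for the first subject
    hemi0 = fit.hemispheres[0]
    subj_maps = fit.connectivity(hemi0).subject_maps
    subj_S = netstruct.map_similarity(
        np.where(np.isfinite(subj_maps[0]), subj_maps[0], 0.0), names)
    subj_coords = netstruct.classical_mds(
        netstruct.similarity_to_dissimilarity(subj_S))
    perm = netstruct.permutation_test_mds(
        subj_coords, coords, n_perm=config.n_permutations,
        seed=stage_seed(config.seed, "mds_perm"))
    results["mds_permutation"] = {"observed_sse": perm.observed_sse,
                                  "percentile": perm.percentile}

    # --- movie ISC --------------------------------------------------------
    if config.run_isc:
        movie = synthdata.generate_movie_dataset(
            synthdata.MovieConfig(seed=stage_seed(config.seed, "movie")))
        summary = isc.movie_isc_summary(movie, threshold=config.isc_threshold)
        results["isc"] = {
            region: {k: v for k, v in vals.items() if k != "maps"}
            for region, vals in summary.items()}

    # --- task GLM ---------------------------------------------------------
    if config.run_taskglm:
        results["task"] = _task_stage(stage_seed(config.seed, "task"))

    io.write_json(results, out / "results.json")
    logger.info("pipeline complete: %s", out)
    return out


def _hemi_average_distance(area_set) -> np.ndarray:
    """Cortical distances averaged across hemispheres (per area name)."""
    hemis = area_set.hemispheres
    mats = []
    for h in hemis:
        rows = area_set.rows_for_hemisphere(h)
        mats.append(area_set.distances_mm[np.ix_(rows, rows)])
    return np.mean(mats, axis=0)


def _task_stage(seed: int) -> dict:
    """Laterality / attention d-prime analysis on synthetic block data."""
    datasets, table, truth = synthdata.generate_laterality_dataset(
        SimulationConfig(seed=seed))
    ventral = truth.voxel_network["all"] == "ventral"
    lat, att = [], []
    for d in datasets:
        stats_ = taskglm.block_response_stats(d.voxel_series, table,
                                              d.tr_seconds)
        mu_c, sd_c = stats_["stim_contra"]
        mu_i, sd_i = stats_["stim_ipsi"]
        mu_a, sd_a = stats_["attend_contra"]
        lat.append([_safe_dprime(mu_c[v], sd_c[v], mu_i[v], sd_i[v])
                    for v in range(d.n_voxels)])
        att.append([_safe_dprime(mu_a[v], sd_a[v], mu_c[v], sd_c[v])
                    for v in range(d.n_voxels)])
    lat = np.array(lat)
    att = np.array(att)
    return {
        "laterality_dprime_ventral": float(lat[:, ventral].mean()),
        "laterality_dprime_dorsal": float(lat[:, ~ventral].mean()),
        "attention_dprime_ventral": float(att[:, ventral].mean()),
        "attention_dprime_dorsal": float(att[:, ~ventral].mean()),
    }


def _safe_dprime(mu_a, sd_a, mu_b, sd_b) -> float:
    try:
        return taskglm.dprime_index(mu_a, sd_a, mu_b, sd_b)
    except ValueError:
        return np.nan
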