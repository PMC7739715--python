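"""Orchestration: chain simulate -> segment -> quantify -> analyze.

Every stage draws its seed deterministically from the global seed, writes
its outputs under the configured output directory, and stamps each result
file with the config hash, so a full run is byte-reproducible (file
contents carry no timestamps; timings go to the log only).
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

from . import io as aio
from .config import RunConfig
from .mriseg import segment_depots
from .petkin import (
    KineticParams,
    build_frame_schedule,
    estimated_ki_static,
    extrapolate_idif_auc,
    mr_glucose,
    patlak_ki,
    tissue_curve,
)
from .phantoms import (
    BONE_MARROW,
    LIVER,
    CohortSpec,
    FengParams,
    PhantomSpec,
    generate_phantom,
    simulate_cohort,
    simulate_input_function,
    simulate_tissue_tac,
)
from .stats import ancova_group_time, mixed_model_group_time
from .volume import write_volume

log = logging.getLogger("adipoquant")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""


def _stamp(config: RunConfig, payload: dict) -> dict:
    # echo the scientific configuration (the output path is excluded so the
    # same run written elsewhere produces byte-identical result files)
    echoed = config.to_dict()
    echoed.pop("output_dir", None)
    return {"config_hash": config.hash(), "seed": config.seed, "config": echoed, **payload}


def run_pipeline(config: RunConfig, write_files: bool = True) -> dict:
    """Execute the selected stages in order and return the result bundle."""
    out_dir = Path(config.output_dir)
    if write_files:
        out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config.to_dict(), "config_hash": config.hash()}

    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                _stage_simulate(config, bundle, out_dir, write_files)
            elif stage == "segment":
                _stage_segment(config, bundle, out_dir, write_files)
            elif stage == "quantify":
                _stage_quantify(config, bundle, out_dir, write_files)
            elif stage == "analyze":
                _stage_analyze(config, bundle, out_dir, write_files)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
    return bundle


def _stage_simulate(config: RunConfig, bundle: dict, out_dir: Path, write_files: bool) -> None:
    pc = config.phantom
    spec = PhantomSpec(
        n_slices=pc.n_slices,
        pixel_size_mm=pc.pixel_size_mm,
        slice_pitch_mm=pc.slice_pitch_mm,
        body_radius_mm=pc.body_radius_mm,
        sat_thickness_mm=(pc.sat_thickness_mean_mm, pc.sat_thickness_amp_mm),
        internal_fat_fraction=pc.internal_fat_fraction,
        bias_amplitude=pc.bias_amplitude,
        noise_sd=pc.noise_sd,
        seed=config.stage_seed("simulate"),
    )
    mri, ct, truth = generate_phantom(spec, region=pc.region)
    bundle["phantom"] = {"mri": mri, "ct": ct, "truth": truth}

    cc = config.cohort
    cohort_spec = CohortSpec(
        n_per_group=cc.n_per_group,
        between_subject_cv=cc.between_subject_cv,
        within_subject_cv=cc.within_subject_cv,
        time_effect={
            "abdominal_sat": cc.sat_time_effect,
            "visceral": cc.visceral_time_effect,
            "femoral_sat": cc.sat_time_effect,
            "inter_muscular": 1.0,
        },
        group_effect=cc.group_effect,
        ki_ratio_visceral_over_sc=cc.ki_ratio_visceral_over_sc,
        seed=config.stage_seed("cohort"),
    )
    bundle["cohort_table"] = simulate_cohort(cohort_spec)

    if write_files:
        write_volume(mri, out_dir / "phantom_mri.nii.gz")
        write_volume(ct, out_dir / "phantom_ct.nii.gz")
        write_volume(truth.label_volume, out_dir / "phantom_labels.nii.gz")
        aio.write_json(
            _stamp(config, {
                "depot_masses_kg": truth.depot_masses_kg,
                "landmarks": truth.landmarks,
                "region": truth.region,
            }),
            out_dir / "phantom_truth.json",
        )
        aio.write_cohort_csv(bundle["cohort_table"], out_dir / "cohort.csv")


def _stage_segment(config: RunConfig, bundle: dict, out_dir: Path, write_files: bool) -> None:
    if "phantom" not in bundle:
        raise StageError("stage 'segment' failed: missing input 'phantom' "
                         "(run the simulate stage or provide volumes)")
    ph = bundle["phantom"]
    truth = ph["truth"]
    sc = config.segmentation
    labels = truth.label_volume.voxels
    result = segment_depots(
        ph["mri"],
        truth.landmarks,
        region=truth.region,
        liver_mask=(labels == LIVER) if (labels == LIVER).any() else None,
        marrow_mask=(labels == BONE_MARROW) if (labels == BONE_MARROW).any() else None,
        seed=config.stage_seed("segment"),
        delta=sc.smoothness_delta,
        n_angles=sc.n_angles,
        bias_degree=sc.bias_degree,
    )
    bundle["segmentation"] = result
    summary = {
        depot: {
            "volume_L": m.volume_L,
            "mass_kg": m.mass_kg,
            "n_slices_analyzed": m.n_slices_analyzed,
            "truth_mass_kg": truth.depot_masses_kg.get(depot),
        }
        for depot, m in result.masses.items()
    }
    bundle["masses"] = summary
    if write_files:
        aio.write_json(
            _stamp(config, {"threshold": result.threshold, "masses": summary}),
            out_dir / "masses.json",
        )


def _stage_quantify(config: RunConfig, bundle: dict, out_dir: Path, write_files: bool) -> None:
    pc = config.pet
    schedule = build_frame_schedule([tuple(p) for p in pc.frame_pattern])
    # densely sampled simulated blood curve standing in for the aortic IDIF;
    # a second sampling extended past the dynamic scan drives the late
    # (static-scan) tissue simulation
    times = np.arange(0.0, schedule.total_s / 60.0 + 1e-9, 0.1)
    input_function = simulate_input_function(FengParams(), times)
    times_long = np.arange(0.0, pc.static_mid_time_min + 1e-9, 0.1)
    input_long = simulate_input_function(FengParams(), times_long)
    seed = config.stage_seed("quantify")

    results: dict[str, dict] = {}
    for i, (tissue, kin) in enumerate(pc.tissues.items()):
        params = KineticParams(**kin)
        tac = simulate_tissue_tac(
            input_function, params, schedule, noise_sd=pc.tac_noise_sd, seed=seed + i
        )
        fit = patlak_ki(tac, input_function, t_star_min=pc.t_star_min)
        mrg = mr_glucose(
            fit.ki,
            pc.plasma_glucose_mmol_per_L,
            lumped_constant=pc.lumped_constant,
            density_g_per_ml=pc.density_g_per_ml,
        )
        # static late-scan estimate at the configured mid-time
        auc = extrapolate_idif_auc(input_function, to_time_min=pc.static_mid_time_min)
        ct_late = float(tissue_curve(params, input_long, np.array([pc.static_mid_time_min]))[0])
        static = estimated_ki_static(ct_late, auc, mid_time_min=pc.static_mid_time_min)
        results[tissue] = {
            "true_ki": params.ki,
            "patlak_ki": fit.ki,
            "patlak_V0": fit.intercept_V0,
            "patlak_r_squared": fit.r_squared,
            "estimated_ki_static": static.estimated_ki,
            "mr_glucose": mrg.mr_glucose,
        }
    if "visceral" in results and "abdominal_sat" in results:
        results["visceral_over_sc_uptake_ratio"] = (
            results["visceral"]["mr_glucose"] / results["abdominal_sat"]["mr_glucose"]
        )
    bundle["kinetics"] = results
    if write_files:
        aio.write_json(
            _stamp(config, {
                "settings": {
                    "t_star_min": pc.t_star_min,
                    "plasma_glucose_mmol_per_L": pc.plasma_glucose_mmol_per_L,
                    "lumped_constant": pc.lumped_constant,
                    "density_g_per_ml": pc.density_g_per_ml,
                    "static_mid_time_min": pc.static_mid_time_min,
                },
                "results": results,
            }),
            out_dir / "kinetics.json",
        )


def _stage_analyze(config: RunConfig, bundle: dict, out_dir: Path, write_files: bool) -> None:
    if "cohort_table" not in bundle:
        raise StageError("stage 'analyze' failed: missing input 'cohort_table' "
                         "(run the simulate stage or provide a cohort CSV)")
    ac = config.analysis
    table = bundle["cohort_table"]
    reports = {}
    for outcome in ac.outcomes:
        if ac.model == "ancova":
            rep = ancova_group_time(table, outcome, covariate=ac.covariate,
                                    log_scale=ac.log_scale)
        else:
            rep = mixed_model_group_time(table, outcome, log_scale=ac.log_scale)
        reports[outcome] = rep.to_dict()
    bundle["analysis"] = reports
    if write_files:
        aio.write_json(_stamp(config, {"reports": reports}), out_dir / "analysis.json")
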