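"""End-to-end pipeline: phantom -> segmentation -> centerline -> stenosis
detection -> virtual FFR (-> explicit-branch comparison) -> report.

``pipeline_run`` executes the stages in acquisition order and writes the
result bundle (centerline CSV, stenosis CSV, FFR JSON, markdown report),
each artifact stamped with the configuration hash so that two runs with the
same effective configuration are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import geometry, hemo, phantoms, stenosis
from .ioutils import RunConfig, config_hash

log = logging.getLogger("ivusffr")

__all__ = ["phantom_to_segmented", "vessel_spec_from_config", "boundary_from_config", "pipeline_run"]


def vessel_spec_from_config(config: RunConfig) -> phantoms.VesselSpec:
    v = config["vessel"]
    return phantoms.VesselSpec(
        length=v["length"],
        inlet_radius=v["inlet_radius"],
        taper=v["taper"],
        stenoses=tuple(phantoms.StenosisSpec(**st) for st in v["stenoses"]),
        branches=tuple(phantoms.BranchSpec(**br) for br in v["branches"]),
        seed=config["seed"],
    )


def boundary_from_config(config: RunConfig) -> hemo.BoundaryConditions:
    b = config["boundary"]
    if b["timi"] is not None:
        v_rest = hemo.timi_resting_velocity(*b["timi"])
    else:
        v_rest = b["resting_velocity_mm_s"]
    return hemo.BoundaryConditions(
        pa=b["pa_mmhg"],
        velocity=hemo.hyperemic_velocity(v_rest, b["hyperemia_factor"]),
        hyperemia_factor=b["hyperemia_factor"],
        fluid=hemo.FluidParams(viscosity=b["viscosity"], density=b["density"], k_t=b["k_t"]),
    )


def phantom_to_segmented(
    bundle: phantoms.PhantomBundle,
    *,
    contours=None,
    junction_halfwidth: float = 1.0,
    trigger: float = 0.20,
    merge_gap_mm: float = 2.0,
    boundary_ratio: float = 0.95,
    pullback_speed: float = 1.0,
):
    """Reconstruct and segment a phantom's centerline from its contours.

    ``contours`` defaults to the phantom's analytic (noise-free) contours;
    pass noisy or network-derived contours to exercise the full chain.
    Branch nodes are labeled from the phantom's ground-truth node table, as
    an operator would label them from the frames.
    """
    if contours is None:
        contours = bundle.contours()
    frame_rate = pullback_speed / bundle.frame_spacing
    model = geometry.contours_to_centerline(contours, pullback_speed, frame_rate)
    if bundle.branch_nodes:
        s_frames = bundle.frame_arclengths()
        node_frames = [int(np.argmin(np.abs(s_frames - nd["s"]))) for nd in bundle.branch_nodes]
        model = geometry.label_branch_nodes(
            model, node_frames, [nd["d_mb"] for nd in bundle.branch_nodes]
        )
    seg = geometry.split_at_branches(model, junction_halfwidth)
    ref = stenosis.fit_healthy_reference(model)
    found = stenosis.detect_stenoses(
        model, ref, trigger, merge_gap_mm=merge_gap_mm, boundary_ratio=boundary_ratio
    )
    seg = geometry.split_pieces_at_intervals(seg, [(st.s_start, st.s_end) for st in found])
    return seg, found, ref


def pipeline_run(config: RunConfig, outdir) -> dict:
    """Run every stage on a seeded phantom and write the result bundle.

    Returns a summary dict (also written as ``ffr.json``): distal vFFR,
    ischemia flag, detected stenoses, and — when ``compare_branch`` is on —
    the explicit-branch comparator's distal value.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    t0 = time.perf_counter()

    spec = vessel_spec_from_config(config)
    r = config["render"]
    bundle = phantoms.render_ivus_pullback(
        spec,
        pixel_size=r["pixel_size"],
        frame_size=r["frame_size"],
        frame_spacing=r["frame_spacing"],
        noise_amplitude=r["noise_amplitude"],
        wall_thickness=r["wall_thickness"],
    )
    log.info("phantom: %d frames, %.1f mm", len(bundle.frames), spec.length)

    segmode = config["segmentation"]["mode"]
    if segmode == "segan":
        from .segan import TrainSchedule, segment_pullback, train_segan

        masks = np.stack([bundle.lumen_masks, bundle.ma_masks], axis=1)
        state = train_segan(
            bundle.frames,
            masks,
            schedule=TrainSchedule(steps=config["segmentation"]["steps"]),
            seed=config["seed"],
        )
        frames_seg = segment_pullback(state, bundle.frames, bundle.pixel_size)
        contours = [f.contour for f in frames_seg]
    elif segmode == "analytic":
        rng = np.random.default_rng(config["seed"] + 1)
        contours = bundle.contours(
            radius_noise_frac=config["segmentation"]["radius_noise_frac"], rng=rng
        )
    else:
        raise ValueError(f"unknown segmentation mode {segmode!r}")

    det = config["detection"]
    seg, found, ref = phantom_to_segmented(
        bundle,
        contours=contours,
        junction_halfwidth=config["geometry"]["junction_halfwidth"],
        trigger=det["trigger"],
        merge_gap_mm=det["merge_gap_mm"],
        boundary_ratio=det["boundary_ratio"],
    )
    log.info("detected %d stenoses", len(found))

    bc = boundary_from_config(config)
    result = hemo.compute_ffr_profile(seg, bc, law=config["law"])

    # -- write artifacts --------------------------------------------------
    model_df = seg.model.to_frame()
    model_df.insert(0, "config_hash", chash)
    model_df.to_csv(outdir / "centerline.csv", index=False)

    import pandas as pd

    sten_df = pd.DataFrame(
        [
            {
                "s_start": st.s_start,
                "s_end": st.s_end,
                "throat_s": st.throat_s,
                "percent_DS": st.percent_diameter_stenosis,
            }
            for st in found
        ]
    )
    sten_df.insert(0, "config_hash", chash)
    sten_df.to_csv(outdir / "stenoses.csv", index=False)

    summary = {
        "config_hash": chash,
        "config": config.data,
        "distal_vffr": result.distal_vffr,
        "ischemic": bool(hemo.dichotomize(result, config["threshold"])),
        "n_stenoses": len(found),
        "stenoses": [
            {"throat_s": st.throat_s, "percent_DS": st.percent_diameter_stenosis}
            for st in found
        ],
        "profile": result.to_dict(),
    }

    if config["compare_branch"]:
        from .branchnet import build_branched_model, solve_network

        net = build_branched_model(seg, config["stub_length"], law=config["law"])
        sol = solve_network(net, bc)
        summary["distal_vffr_branch"] = sol.ffr.distal_vffr
        summary["ischemic_branch"] = bool(hemo.dichotomize(sol.ffr, config["threshold"]))

    (outdir / "ffr.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    lines = [
        f"# Virtual FFR report (config {chash})",
        "",
        f"- law: {config['law']}",
        f"- Pa: {bc.pa} mmHg, hyperemic velocity: {bc.velocity:.1f} mm/s",
        f"- vessel length: {spec.length} mm, {len(bundle.frames)} frames",
        f"- detected stenoses: {len(found)}",
    ]
    for st in found:
        lines.append(
            f"  - throat at {st.throat_s:.1f} mm, %DS {st.percent_diameter_stenosis:.1f}"
        )
    lines.append(f"- distal vFFR: {result.distal_vffr:.3f}")
    lines.append(f"- ischemic (<= {config['threshold']}): {summary['ischemic']}")
    if "distal_vffr_branch" in summary:
        lines.append(f"- distal vFFR (explicit branch): {summary['distal_vffr_branch']:.3f}")
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
    log.info("pipeline finished in %.2f s", time.perf_counter() - t0)
    return summary
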