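"""Stage orchestration for complete runs, with a reproducibility manifest.

A run walks through: synthetic generation (or raw input), image processing,
per-interval inverse estimation, morphometrics and a group report.  Every
stage writes plain files (TIFF/CSV/JSON) under the output directory and the
manifest records the configuration, package version, per-file checksums and
stage timings, so a rerun with the same config and seed can be verified
byte-for-byte on the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import RunConfig
from .forward import BiophysicalParams, SolverConfig, material_from_core
from .inverse import FitConfig, fit_timecourse, results_to_frame, save_results
from .mesh import PixelGrid, build_mesh, grid_to_mesh, save_mesh_txt
from .morphometrics import group_table, measure_frame
from .phantom import (
    GROUP_MEAN_TRAJECTORIES,
    GROUP_SD_TRAJECTORIES,
    PhantomConfig,
    RenderedTimecourse,
    emit_raw_acquisition,
    generate_timecourse,
    make_phantom,
)
from .pipeline import (
    deformation_at_nodes,
    load_raw_acquisition,
    observations_from_processed,
    process_timecourse,
)
from .imaging import DeformationField

log = logging.getLogger("spherofit")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _phantom_config(cfg: RunConfig, seed: int) -> PhantomConfig:
    p = cfg.phantom
    return PhantomConfig(
        field_size_um=p.field_size_um,
        pixel_size_um=p.pixel_size_um,
        core_radius_um=p.core_radius_um,
        plateau_density=p.plateau_density,
        falloff_width_um=p.falloff_width_um,
        bead_count=p.bead_count,
        bead_sigma_px=p.bead_sigma_px,
        cell_sigma_px=p.cell_sigma_px,
        noise_sigma=p.noise_sigma,
        shot_noise=p.shot_noise,
        mesh_target_edge_um=p.mesh_target_edge_um,
        t_start_h=p.t_start_h,
        interval_h=p.interval_h,
        rng_seed=seed,
    )


def _solver_config(cfg: RunConfig) -> SolverConfig:
    s = cfg.solver
    return SolverConfig(
        dt=s.dt,
        interval_hours=s.interval_hours,
        mechanics_update_every=s.mechanics_update_every,
        cfl_safety=s.cfl_safety,
        theta=s.theta,
    )


def _fit_config(cfg: RunConfig) -> FitConfig:
    f = cfg.fit
    return FitConfig(
        init_d0=f.init_d0,
        init_k=f.init_k,
        init_lambda=f.init_lambda,
        gamma=f.gamma,
        d0_bounds=f.d0_bounds,
        k_bounds=f.k_bounds,
        outer_tol=f.outer_tol,
        outer_max=f.outer_max,
    )


def system_parameters(
    group: str, n_intervals: int, seed: int, t_start: float = 24.0, interval: float = 12.0
) -> list[BiophysicalParams]:
    """Per-interval generating parameters for one synthetic system.

    Interval means follow the group presets; per-system variability is drawn
    from the matching per-interval group standard deviations (seeded).
    Trajectories shorter than the preset reuse its leading intervals.
    """
    rng = np.random.default_rng(seed)
    means = GROUP_MEAN_TRAJECTORIES[group]
    sds = GROUP_SD_TRAJECTORIES[group]
    hours = sorted(means)[:n_intervals]
    out = []
    for i, h in enumerate(hours):
        m, s = means[h], sds[h]
        d0 = max(1.0, rng.normal(m[0], s[0]))
        k = rng.normal(m[1], s[1])
        lam = rng.normal(m[2], s[2])
        t0 = t_start + i * interval
        out.append(BiophysicalParams(D0=d0, k=k, lam=lam, interval=(t0, t0 + interval)))
    return out


def _write_frames(outdir: Path, prefix: str, images, times) -> list[Path]:
    paths = []
    for t, img in zip(times, images):
        p = outdir / f"{prefix}_t{int(round(t)):03d}h.tif"
        tifffile.imwrite(p, np.asarray(img, dtype=np.float32))
        paths.append(p)
    return paths


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages end to end; returns the manifest dict.

    Stage failures abort with a :class:`StageError`; the partial manifest is
    still written with the failing stage tagged.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(cfg.model_dump_json()),
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "outputs": {},
    }
    logging.basicConfig(level=cfg.log_level.upper())

    def finish_stage(name: str, t0: float, files: list[Path]):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        manifest["outputs"].update({str(p.relative_to(outdir)): _sha256(p) for p in files})

    try:
        records = []  # morphometrics rows
        fit_rows = []  # fitted parameter rows
        systems: list[dict] = []

        # ------------------------------------------------ acquire / simulate
        t0 = time.time()
        stage_files: list[Path] = []
        if cfg.mode == "synthetic":
            for gi, group in enumerate(cfg.groups):
                for i in range(cfg.n_systems_per_group):
                    sys_seed = cfg.seed * 10007 + gi * 1009 + i * 101
                    pcfg = _phantom_config(cfg, seed=sys_seed % (2**31))
                    ph = make_phantom(pcfg)
                    params = system_parameters(
                        group, cfg.n_intervals, sys_seed % (2**31) + 1,
                        pcfg.t_start_h, pcfg.interval_h,
                    )
                    rendered, truth = generate_timecourse(ph, params, _solver_config(cfg))
                    sdir = outdir / f"{group}_{i}"
                    sdir.mkdir(exist_ok=True)
                    stage_files += _write_frames(sdir, "cell", rendered.cellularity_images, rendered.times_h)
                    stage_files += _write_frames(sdir, "bead", rendered.bead_images, rendered.times_h)
                    truth_df = pd.DataFrame(
                        [
                            {
                                "interval_end_h": p.interval[1],
                                "D0_um2_per_h": p.D0,
                                "k_per_h": p.k,
                                "lambda": p.lam,
                            }
                            for p in params
                        ]
                    )
                    tp = sdir / "true_params.csv"
                    truth_df.to_csv(tp, index=False)
                    stage_files.append(tp)
                    fj = sdir / "frames.json"
                    fj.write_text(json.dumps({
                        "times_h": [float(t) for t in rendered.times_h],
                        "pixel_size_um": rendered.grid.pixel_size,
                    }))
                    stage_files.append(fj)
                    if cfg.emit_tiles:
                        emit_raw_acquisition(rendered, sdir / "tiles", seed=pcfg.rng_seed)
                    systems.append(
                        {"group": group, "index": i, "rendered": rendered, "phantom": ph}
                    )
        elif cfg.mode == "raw_acquisition":
            rendered = load_raw_acquisition(cfg.input_dir)
            systems.append({"group": cfg.groups[0], "index": 0, "rendered": rendered, "phantom": None})
        else:  # prerendered_fields
            rendered = _load_prerendered(Path(cfg.input_dir))
            systems.append({"group": cfg.groups[0], "index": 0, "rendered": rendered, "phantom": None})
        finish_stage("acquire", t0, stage_files)

        # ------------------------------------------------ process + fit + morpho
        t0 = time.time()
        stage_files = []
        mesh = None
        for sysrec in systems:
            rendered = sysrec["rendered"]
            grid = rendered.grid
            if mesh is None:
                extent = (grid.width * grid.pixel_size, grid.height * grid.pixel_size)
                mesh = build_mesh(extent, cfg.phantom.mesh_target_edge_um)
                save_mesh_txt(mesh, outdir / "mesh_nodes.txt", outdir / "mesh_elements.txt")
                stage_files += [outdir / "mesh_nodes.txt", outdir / "mesh_elements.txt"]
            sdir = outdir / f"{sysrec['group']}_{sysrec['index']}"
            sdir.mkdir(exist_ok=True)
            # prerendered fields are already mutually registered: skip the
            # rigid (ICP) stage, keep normalization/segmentation/deformation
            proc = process_timecourse(
                rendered, register_rigid=(cfg.mode != "prerendered_fields")
            )
            obs = observations_from_processed(proc, mesh)
            for j, field in enumerate(proc.deformation_fields):
                px = sdir / f"defx_{j}.tif"
                py = sdir / f"defy_{j}.tif"
                tifffile.imwrite(px, field.ux.astype(np.float32))
                tifffile.imwrite(py, field.uy.astype(np.float32))
                stage_files += [px, py]
            material = material_from_core(
                mesh, obs[0].n_obs_start.values,
                core_threshold=cfg.core_threshold,
                youngs_ecm_pa=cfg.solver.youngs_ecm_pa,
                core_stiffening=cfg.solver.core_stiffening,
                nu=cfg.solver.poissons_ratio,
            )
            results = fit_timecourse(obs, mesh, material, _solver_config(cfg), _fit_config(cfg))
            save_results(results, sdir / "fit.csv", sdir / "fit.json")
            stage_files += [sdir / "fit.csv", sdir / "fit.json"]
            frame = results_to_frame(results)
            frame["group"] = sysrec["group"]
            frame["system"] = f"{sysrec['group']}_{sysrec['index']}"
            fit_rows.append(frame)
            for img, msk, th in zip(proc.cellularity_images, proc.roi_masks, proc.times_h):
                rec = measure_frame(
                    img, msk, grid, th, core_threshold=cfg.core_threshold,
                    system_id=f"{sysrec['group']}_{sysrec['index']}", group=sysrec["group"],
                )
                records.append(dataclasses.asdict(rec))
        finish_stage("process_fit", t0, stage_files)

        # ------------------------------------------------ report
        t0 = time.time()
        stage_files = []
        fits = pd.concat(fit_rows, ignore_index=True)
        fits.to_csv(outdir / "fitted_parameters.csv", index=False)
        morpho = pd.DataFrame.from_records(records)
        morpho.to_csv(outdir / "morphometrics.csv", index=False)
        stage_files += [outdir / "fitted_parameters.csv", outdir / "morphometrics.csv"]
        if len(cfg.groups) >= 2 and cfg.n_systems_per_group >= 2 and cfg.mode == "synthetic":
            table = group_table(
                fits.rename(columns={"interval_end_h": "time_h"}),
                ["D0_um2_per_h", "k_per_h", "lambda"],
                groups=(cfg.groups[0], cfg.groups[1]),
            )
            table.to_csv(outdir / "group_table.csv", index=False)
            stage_files.append(outdir / "group_table.csv")
        finish_stage("report", t0, stage_files)
    except Exception as exc:
        stage = "report" if manifest["stages"].get("process_fit") else (
            "process_fit" if manifest["stages"].get("acquire") else "acquire"
        )
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise StageError(stage, exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _load_prerendered(indir: Path) -> RenderedTimecourse:
    """Read flat per-frame cellularity/bead TIFFs written by the simulate stage."""
    meta_path = indir / "frames.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        times = np.asarray(meta["times_h"], float)
        pixel = float(meta["pixel_size_um"])
    else:
        cells = sorted(indir.glob("cell_t*.tif"))
        times = np.array([float(p.stem.split("_t")[1][:-1]) for p in cells])
        pixel = 5.0
    cell = [tifffile.imread(indir / f"cell_t{int(round(t)):03d}h.tif") for t in times]
    bead = [tifffile.imread(indir / f"bead_t{int(round(t)):03d}h.tif") for t in times]
    h, w = cell[0].shape
    return RenderedTimecourse(cell, bead, times, PixelGrid(w, h, pixel))
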