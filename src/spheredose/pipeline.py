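"""End-to-end pipeline driver: simulate → detect → kernel → dose → metrics.

The pipeline is configured by a plain dict (or JSON file): a ``stages``
list plus one sub-dict of keyword overrides per stage. Every intermediate
is written to the output directory with a provenance sidecar (config hash,
seed, package version); stages never mutate their inputs, and a rerun with
the same config and seed reproduces the report exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .detection import DetectionParams, detect_spheres
from .dosemap import bin_spheres_to_grid, convolve_dose, scale_dose_to_time, ldm_dose
from .grid import make_grid
from .io import _jsonable, write_sphere_table, write_volume
from .kernel import generate_dpk, save_kernel
from .metrics import cumulative_dvh, region_report, DEFAULT_REGIONS
from .nuclide import Y90
from .phantom import (PhantomSpec, make_phantom, render_microct,
                      render_pet_activity, sample_sphere_positions)
from .spheres import assign_sphere_activity

log = logging.getLogger("spheredose")

KNOWN_STAGES = ("simulate", "detect", "kernel", "dose", "metrics")
_DEPS = {"detect": ("simulate",), "dose": ("kernel",), "metrics": ("dose",)}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(_jsonable(config), sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Execute the requested stages in order; returns the report bundle.

    The bundle maps stage names to their key outputs (file paths and summary
    numbers); it is also written to ``report.json`` in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", KNOWN_STAGES))
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; known: {list(KNOWN_STAGES)}")
    for s in stages:
        for dep in _DEPS.get(s, ()):
            if dep not in stages:
                raise ValueError(f"stage {s!r} requires stage {dep!r} in the run")

    seed = int(config.get("seed", 0) if seed is None else seed)
    provenance = {"config_hash": _config_hash(config), "seed": seed,
                  "version": __version__}
    bundle: dict = {"provenance": provenance}
    density = float(config.get("density_g_per_ml", 1.03))

    truth = labels = microct = table = kern = dose = None

    if "simulate" in stages:
        sim = dict(config.get("simulate", {}))
        spec = PhantomSpec(**{**sim.get("phantom", {}), "seed": seed})
        labels = make_phantom(spec)
        truth = sample_sphere_positions(
            labels, n_spheres=int(sim.get("n_spheres", 2000)),
            tumor_to_normal_ratio=float(sim.get("tumor_to_normal_ratio", 3.0)),
            clustering=float(sim.get("clustering", 1.0)),
            seed=seed,
            total_activity_gbq=float(sim.get("total_activity_gbq", 0.019)))
        write_volume(labels, out / "labels.nii")
        write_sphere_table(truth.spheres, out / "ground_truth_spheres.csv")
        bundle["simulate"] = {
            "n_spheres": len(truth.spheres),
            "achieved_tumor_to_normal": truth.achieved_tumor_to_normal,
            "labels": str(out / "labels.nii"),
            "spheres": str(out / "ground_truth_spheres.csv")}
        if sim.get("render_microct", False):
            mgrid = make_grid(sim.get("microct_shape", (128, 128, 128)),
                              float(sim.get("microct_spacing_mm", 0.00874)),
                              sim.get("microct_origin_mm", (0.0, 0.0, 0.0)))
            microct = render_microct(truth, mgrid, seed=seed)
            write_volume(microct, out / "microct.nii")
            bundle["simulate"]["microct"] = str(out / "microct.nii")
        if sim.get("render_pet", False):
            pgrid = make_grid(sim.get("pet_shape", (20, 20, 20)),
                              float(sim.get("pet_spacing_mm", 2.0)),
                              sim.get("pet_origin_mm", (0.0, 0.0, 0.0)))
            pet = render_pet_activity(truth, pgrid, seed=seed)
            write_volume(pet, out / "pet_activity.nii")
            bundle["simulate"]["pet"] = str(out / "pet_activity.nii")

    if "detect" in stages:
        if microct is None:
            raise ValueError("detect stage needs a rendered microCT "
                             "(set simulate.render_microct)")
        params = DetectionParams(**config.get("detect", {}))
        table = detect_spheres(microct, params)
        if len(table) > 0:
            table = assign_sphere_activity(
                table, float(config.get("simulate", {}).get("total_activity_gbq", 0.019)))
        write_sphere_table(table, out / "detected_spheres.csv")
        bundle["detect"] = {"n_detected": len(table),
                            "table": str(out / "detected_spheres.csv")}

    if "kernel" in stages:
        kcfg = dict(config.get("kernel", {}))
        kern = generate_dpk(Y90, seed=seed, density_g_per_ml=density, **kcfg)
        save_kernel(kern, out / "dpk.h5")
        bundle["kernel"] = {"total_energy_mev": kern.total_energy_mev,
                            "spacing_mm": kern.spacing_mm,
                            "path": str(out / "dpk.h5")}

    if "dose" in stages:
        dcfg = dict(config.get("dose", {}))
        source = dcfg.get("source", "microct")
        src_table = table if (table is not None and source == "microct-detected") else (
            truth.spheres if truth is not None else table)
        if src_table is None:
            raise ValueError("dose stage needs sphere positions (simulate or detect)")
        shape = dcfg.get("shape")
        grid = make_grid(shape, kern.spacing_mm, dcfg.get("origin_mm", (0, 0, 0))) \
            if shape else labels.grid
        if abs(grid.spacing[0] - kern.spacing_mm) > 1e-12:
            raise ValueError("dose grid spacing must match the kernel spacing")
        decays = bin_spheres_to_grid(src_table, grid)
        dose = convolve_dose(decays, kern, density)
        trunc = dcfg.get("truncate_hours")
        if trunc is not None:
            dose = scale_dose_to_time(dose, truncation_h=float(trunc))
        write_volume(dose.volume, out / "dose.nii")
        bundle["dose"] = {"path": str(out / "dose.nii"), "delivery": dose.delivery,
                          "mean_gy": float(dose.data.mean())}

    if "metrics" in stages:
        if dose is None or labels is None:
            raise ValueError("metrics stage needs a dose map on the phantom grid")
        mcfg = dict(config.get("metrics", {}))
        report = region_report(dose, labels,
                               truncation_h=mcfg.get("truncation_h"))
        df = report.to_frame()
        df.to_csv(out / "region_report.csv")
        dvhs = {}
        for name, codes in DEFAULT_REGIONS.items():
            mask = np.isin(labels.data, codes)
            if mask.any():
                c = cumulative_dvh(dose, mask, region=name)
                dvhs[name] = {"edges_gy": c.bin_edges_gy.tolist(),
                              "volume_pct": c.volume_fraction_pct.tolist()}
        (out / "dvh.json").write_text(json.dumps(_jsonable(dvhs)))
        bundle["metrics"] = {"report": str(out / "region_report.csv"),
                             "t_n": report.t_n,
                             "table": _jsonable(df.to_dict())}

    (out / "report.json").write_text(json.dumps(_jsonable(bundle), indent=1, sort_keys=True))
    log.info("pipeline complete: %s", out / "report.json")
    return bundle
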