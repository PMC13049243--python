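"""End-to-end pipeline: pre-computation, reconstruction, and mapping.

Runs the five stages in order: (1) dictionary/basis, DCF, B0 and coil maps
from subspace-1 echo images; (2) image reconstruction (direct, low-rank, or
deep image prior); (3) dual-T2* fitting; (4) IDEAL fat/water separation and
pattern matching; (5) PDFF.  Outputs one NIfTI per map plus a JSON
provenance sidecar and a per-ROI summary table.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dfield, asdict
from pathlib import Path

import numpy as np

from rosettemrf import dictionary as dict_mod
from rosettemrf.dictionary import DictionaryConfig, build_dictionary, compress
from rosettemrf.field import (FieldModel, combine_coils, estimate_b0,
                              estimate_coils, support_mask)
from rosettemrf.mapping import (TissueMaps, calibrate_fat_response,
                                compute_pdff, fit_dual_t2star,
                                ideal_separate, pattern_match)
from rosettemrf.operators import KSpaceData, default_rotations
from rosettemrf.phantom import (DigitalPhantom, birdcage_coils,
                                make_cardiac_phantom, make_vial_phantom,
                                simulate_acquisition, smooth_b0_map)
from rosettemrf.recon.dip import DIPConfig, recon_dip
from rosettemrf.recon.direct import grid_subspace_echoes, make_echo_dcf, recon_direct
from rosettemrf.recon.lowrank import LowRankConfig, recon_lowrank
from rosettemrf.sequence import ScheduleConfig, build_schedule
from rosettemrf.trajectory import generate_rosette


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class PipelineConfig:
    matrix: int = 96
    fov_mm: float = 300.0
    kmax: float | None = None          # None: matched to matrix/FOV
    w1_cycles: float = 11.5
    w2_cycles: float = 7.5
    readout_ms: float = 18.4
    dt_us: float = 2.5
    rr_ms: float = 1000.0
    rank: int = 10
    method: str = "dip"
    seed: int = 0
    fat_shift_hz: float = 220.0
    # simulation request (used when no k-space is supplied)
    phantom: str = "cardiac"
    case: str = "healthy"
    n_coils: int = 1
    b0_amplitude_hz: float = 30.0
    noise_pct: float = 0.0
    estimate_field: bool = True
    dip: DIPConfig = dfield(default_factory=DIPConfig)
    lowrank: LowRankConfig = dfield(default_factory=LowRankConfig)
    output_dir: str | None = None


def roi_stats(map_2d: np.ndarray, label_map: np.ndarray, label: int):
    """(mean, voxelwise SD, n) of a map over one ROI label."""
    if map_2d.shape != label_map.shape:
        raise ValueError("map and label map shapes differ")
    sel = label_map == label
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"empty ROI for label {label}")
    vals = np.asarray(map_2d)[sel]
    return float(vals.mean()), float(vals.std()), n


def _prepare_inputs(cfg: PipelineConfig, kspace, phantom):
    n = cfg.matrix
    fov_m = cfg.fov_mm / 1000.0
    kmax = cfg.kmax if cfg.kmax is not None else n / (2.0 * fov_m)
    traj = generate_rosette(kmax, cfg.w1_cycles, cfg.w2_cycles,
                            cfg.readout_ms, cfg.dt_us)
    sched = build_schedule([cfg.rr_ms] * 15)
    truth = {}
    if kspace is None:
        if phantom is None:
            if cfg.phantom == "cardiac":
                phantom = make_cardiac_phantom(n, cfg.case)
            elif cfg.phantom == "vials":
                phantom = make_vial_phantom(n)
            else:
                raise ValueError(f"unknown phantom {cfg.phantom!r}")
        b0 = smooth_b0_map(n, cfg.b0_amplitude_hz)
        coils = (birdcage_coils(n, cfg.n_coils) if cfg.n_coils > 1
                 else np.ones((1, n, n), dtype=complex))
        kspace = simulate_acquisition(
            phantom, sched, traj, b0_hz=b0, coil_maps=coils,
            noise_pct=cfg.noise_pct, seed=cfg.seed,
            fat_shift_hz=cfg.fat_shift_hz)
        truth = {"b0_hz": b0, "coil_maps": coils}
    return traj, sched, kspace, phantom, truth


def run_pipeline(cfg: PipelineConfig, kspace: KSpaceData | None = None,
                 phantom: DigitalPhantom | None = None,
                 dictionary=None, basis=None, compressed=None,
                 shared: dict | None = None):
    """Execute the full pipeline; returns (TissueMaps, report dict).

    A pre-built dictionary/basis triple may be passed to avoid re-simulation
    across runs that share the schedule.  ``shared`` is an optional mutable
    cache reused across runs with identical trajectory/rotations/matrix
    (density weights, fat-response calibration, and the DIP encoding
    operator are stored there).
    """
    n = cfg.matrix
    fov_m = cfg.fov_mm / 1000.0
    report: dict = {"config": {k: v for k, v in asdict(cfg).items()
                               if not isinstance(v, dict)},
                    "stages": {}}
    t_start = time.time()

    stage = "inputs"
    try:
        traj, sched, kspace, phantom, truth = _prepare_inputs(cfg, kspace, phantom)
        rotations = kspace.rotations_deg
    except Exception as err:
        raise PipelineStageError(stage, err) from err

    stage = "precompute"
    try:
        t0 = time.time()
        if dictionary is None or basis is None:
            dictionary = build_dictionary(DictionaryConfig(), sched)
            basis, compressed = compress(dictionary, cfg.rank)
        elif compressed is None:
            compressed = dictionary.signals @ np.conj(basis.basis)
        if shared is not None and "dcf" in shared:
            dcf = shared["dcf"]
        else:
            dcf = make_echo_dcf(traj, rotations, n, fov_m)
            if shared is not None:
                shared["dcf"] = dcf
        echo_imgs_coils = grid_subspace_echoes(
            kspace, traj, basis.basis[:, :1], n, fov_m=fov_m,
            rotations_deg=rotations, dcf=dcf)[:, 0]   # (C, E, n, n)
        echo_times = np.array(
            [s.echo_time_ms for s in
             _full_segments(traj, kspace.te1_ms)])
        mask = support_mask(echo_imgs_coils)
        if cfg.estimate_field:
            if kspace.n_coils > 1:
                coils0 = estimate_coils(echo_imgs_coils)
                combined = combine_coils(echo_imgs_coils, coils0)
            else:
                combined = echo_imgs_coils[0]
            b0 = estimate_b0(combined, echo_times,
                             fat_shift_hz=cfg.fat_shift_hz, mask=mask)
            if kspace.n_coils > 1:
                te_s = echo_times * 1e-3
                corr = echo_imgs_coils * np.exp(
                    -2j * np.pi * b0 * te_s[:, None, None])[None]
                coil_maps = estimate_coils(corr)
            else:
                coil_maps = np.ones((1, n, n), dtype=complex)
        else:
            b0 = truth.get("b0_hz", np.zeros((n, n)))
            coil_maps = truth.get("coil_maps", np.ones((1, n, n), dtype=complex))
        fieldm = FieldModel(b0_hz=b0, coil_maps=coil_maps,
                            fat_shift_hz=cfg.fat_shift_hz, mask=mask)
        if shared is not None and "fat_phase" in shared:
            fat_phase = shared["fat_phase"]
        else:
            fat_phase = calibrate_fat_response(traj, rotations, n, fov_m, dcf,
                                               fat_shift_hz=cfg.fat_shift_hz,
                                               te1_ms=kspace.te1_ms)
            if shared is not None:
                shared["fat_phase"] = fat_phase
        report["stages"]["precompute"] = {"seconds": time.time() - t0}
    except Exception as err:
        raise PipelineStageError(stage, err) from err

    stage = f"recon[{cfg.method}]"
    try:
        t0 = time.time()
        if cfg.method == "direct":
            images = recon_direct(kspace, fieldm, traj, basis.basis, n,
                                  fov_m=fov_m, rotations_deg=rotations, dcf=dcf)
        elif cfg.method == "lowrank":
            images = recon_lowrank(kspace, fieldm, traj, basis.basis, n,
                                   cfg=cfg.lowrank, fov_m=fov_m,
                                   rotations_deg=rotations)
        elif cfg.method == "dip":
            dip_cfg = cfg.dip
            if dip_cfg.seed != cfg.seed:
                from dataclasses import replace
                dip_cfg = replace(dip_cfg, seed=cfg.seed)
            op = None
            if shared is not None and kspace.n_coils == 1:
                op = shared.get("dip_op")
                if op is None:
                    from rosettemrf.operators import EncodingOperator

                    op = EncodingOperator(traj, rotations, basis.basis, n,
                                          fov_m=fov_m, te1_ms=kspace.te1_ms,
                                          b0_correction=dip_cfg.b0_correction,
                                          dtype=np.complex64)
                    shared["dip_op"] = op
                # plans and Toeplitz kernels depend only on trajectory,
                # basis, and DCF; the field enters per application
                op.b0_hz = fieldm.b0_hz
            images, losses = recon_dip(kspace, fieldm, traj, basis.basis, n,
                                       cfg=dip_cfg, fov_m=fov_m,
                                       rotations_deg=rotations, op=op)
            report["stages"]["dip_loss"] = [float(losses[0]), float(losses[-1])]
        else:
            raise ValueError(f"unknown method {cfg.method!r}")
        report["stages"]["recon"] = {"seconds": time.time() - t0}
    except Exception as err:
        raise PipelineStageError(stage, err) from err

    stage = "t2star"
    try:
        t2s_w, t2s_f, _, _ = fit_dual_t2star(
            images.data[0], images.echo_times_ms, b0_hz=fieldm.b0_hz,
            fat_shift_hz=cfg.fat_shift_hz, mask=mask, fat_phase=fat_phase)
    except Exception as err:
        raise PipelineStageError(stage, err) from err

    stage = "ideal+match"
    try:
        water, fat = ideal_separate(images.data, fieldm.b0_hz, t2s_w, t2s_f,
                                    images.echo_times_ms,
                                    fat_shift_hz=cfg.fat_shift_hz,
                                    fat_phase=fat_phase)
        t1w, t2w, m0w = pattern_match(water, compressed, dictionary.entries,
                                      dictionary.norms, mask=mask)
        t1f, t2f, m0f = pattern_match(fat, compressed, dictionary.entries,
                                      dictionary.norms, mask=mask)
    except Exception as err:
        raise PipelineStageError(stage, err) from err

    stage = "pdff"
    try:
        pdff = compute_pdff(m0w, m0f)
    except Exception as err:
        raise PipelineStageError(stage, err) from err

    maps = TissueMaps(t1_w=t1w, t2_w=t2w, t1_f=t1f, t2_f=t2f,
                      t2star_w=t2s_w, t2star_f=t2s_f, m0_w=m0w, m0_f=m0f,
                      pdff=pdff, mask=mask)
    report["seconds_total"] = time.time() - t_start
    if phantom is not None:
        report["roi_summary"] = summarize_rois(maps, phantom)
    if cfg.output_dir:
        write_outputs(Path(cfg.output_dir), maps, report, cfg)
    return maps, report


def _full_segments(traj, te1_ms):
    from rosettemrf.trajectory import split_into_echoes
    return [s for s in split_into_echoes(traj, te1_ms=te1_ms) if s.is_full]


def summarize_rois(maps: TissueMaps, phantom: DigitalPhantom) -> dict:
    out = {}
    for lab, name in (phantom.label_names or
                      {l: str(l) for l in phantom.properties}).items():
        entry = {}
        for key, arr in maps.as_dict().items():
            mean, sd, nvox = roi_stats(arr, phantom.label_map, lab)
            entry[key] = {"mean": mean, "sd": sd, "n": nvox}
        out[name] = entry
    return out


def write_outputs(outdir: Path, maps: TissueMaps, report: dict,
                  cfg: PipelineConfig) -> None:
    import nibabel as nib

    outdir.mkdir(parents=True, exist_ok=True)
    units = {"pdff": "fraction", "m0_w": "arb", "m0_f": "arb"}
    for name, arr in maps.as_dict().items():
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32)[..., None],
                              affine=np.eye(4))
        nib.save(img, str(outdir / f"{name}.nii.gz".replace(".gz", "")))
        units.setdefault(name, "ms")
    prov = {"method": cfg.method, "seed": cfg.seed, "units": units,
            "report": _jsonable(report)}
    with open(outdir / "provenance.json", "w") as f:
        json.dump(prov, f, indent=1)
    with open(outdir / "resolved_config.json", "w") as f:
        json.dump(_jsonable(asdict(cfg)), f, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
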