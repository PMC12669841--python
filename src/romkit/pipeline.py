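"""End-to-end mobility pipeline: contact ROM, ligaments, filtering, volumes.

Stage order: lattice ROM simulation -> per-pose ligament lengths over the
viable set -> interpolation of failed solves -> strain thresholds ->
constrained pose set -> alpha-shape volumetry.  The run is deterministic
given the configuration and seed; every stage writes its table to the
output directory and the final report mirrors the volume/missed-volume
summary fields.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .contact import JointModel, MobilityResult, simulate_rom
from .errors import InvalidInputError
from .io import RunConfig, load_joint, read_pose_table, write_pose_table
from .ligaments import (evaluate_ligaments, interpolate_failed_lengths)
from .mobility import (alpha_volume, apply_strain_filter, derive_thresholds,
                       missed_volume, smallest_connecting_alpha)
from .posespace import generate_pose_grid, sine_correct

__all__ = ["run_pipeline", "ligament_lengths_for_mobility", "choose_alpha"]

log = logging.getLogger(__name__)


def ligament_lengths_for_mobility(joint: JointModel,
                                  mobility: MobilityResult,
                                  ligaments=None,
                                  path_config=None) -> pd.DataFrame:
    """Ligament lengths at every viable lattice pose, failures interpolated.

    Non-viable poses get NaN lengths; failed ligament solves at viable
    poses are filled from the surrounding sine-corrected rotational data.
    """
    ligaments = ligaments if ligaments is not None else joint.ligaments
    if not ligaments:
        raise InvalidInputError("no ligaments to evaluate")
    mask = mobility.viable_mask
    angles = mobility.grid.angles
    table = evaluate_ligaments(joint, ligaments, angles[mask],
                               mobility.translations[mask], path_config)
    full = pd.DataFrame({
        "fe": angles[:, 0], "abad": angles[:, 1], "lar": angles[:, 2],
        "tx": mobility.translations[:, 0],
        "ty": mobility.translations[:, 1],
        "tz": mobility.translations[:, 2]})
    for lig in ligaments:
        for prefix, fill in (("len", np.nan), ("strain", np.nan),
                             ("conv", False)):
            col = f"{prefix}_{lig.name}"
            out = np.full(len(full), fill)
            out[mask] = table[col].to_numpy()
            full[col] = out
    # interpolate failed solves within the viable subset only
    if mask.sum() >= 4:
        sub = full.loc[mask].reset_index(drop=True)
        sub = interpolate_failed_lengths(sub, skip_insufficient=True)
        for lig in ligaments:
            vals = full[f"len_{lig.name}"].to_numpy(dtype=float)
            vals[mask] = sub[f"len_{lig.name}"].to_numpy()
            full[f"len_{lig.name}"] = vals
            full[f"strain_{lig.name}"] = \
                100.0 * (vals / lig.rest_length - 1.0)
    return full


def choose_alpha(points: np.ndarray, step: float, policy) -> float:
    """Resolve the alpha policy: a number, or 'auto'.

    'auto' picks the smallest alpha — among multiples of the lattice step —
    that yields a single connected component, following the usual
    sensitivity-analysis approach; falls back to 3x the step.
    """
    if isinstance(policy, (int, float)):
        return float(policy)
    candidates = step * np.array([1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0])
    alpha = None
    if len(points) >= 4:
        alpha = smallest_connecting_alpha(points, candidates)
    return alpha if alpha is not None else 3.0 * step


def run_pipeline(config: RunConfig, joint: JointModel | None = None):
    """Run the full constrained-mobility pipeline and write all outputs.

    Returns the report dictionary (also written to ``report.json``).
    ``joint`` may be supplied directly to skip file loading.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name):
        log.info("pipeline stage: %s", name)
        report["stages"][name] = {"t": round(time.time() - t_start, 2)}
        return name

    try:
        stage("load")
        if joint is None:
            joint = load_joint(config)
        grid = generate_pose_grid(config.pose_ranges(), config.step)
        report["n_poses"] = len(grid)

        stage("rom")
        mobility = simulate_rom(joint, grid, config.contact_config())
        rom_df = mobility.to_dataframe()
        write_pose_table(rom_df, out / "rom.csv")
        report["n_viable"] = int(mobility.viable_mask.sum())

        stage("ligaments")
        if joint.ligaments:
            lengths = ligament_lengths_for_mobility(joint, mobility)
            write_pose_table(lengths, out / "ligament_lengths.csv")
        else:
            lengths = None

        stage("thresholds")
        if lengths is not None:
            if config.threshold_mode == "scaled_rest_plus_strain":
                thresholds = derive_thresholds(
                    "scaled_rest_plus_strain", ligaments=joint.ligaments,
                    scale=config.threshold_scale,
                    strain_factor=config.strain_factor)
            elif config.threshold_mode == "trajectory_max":
                thresholds = derive_thresholds(
                    "trajectory_max",
                    trajectory=read_pose_table(config.trajectory))
            elif config.threshold_mode == "rom_interpolated":
                thresholds = derive_thresholds(
                    "rom_interpolated",
                    trajectory=read_pose_table(config.trajectory),
                    rom_table=lengths)
            else:
                raise InvalidInputError(
                    f"unknown threshold mode {config.threshold_mode!r}")
            report["thresholds"] = {k: round(v, 6)
                                    for k, v in thresholds.max_length.items()}
            constrained_mask = apply_strain_filter(
                mobility.viable_mask, lengths, thresholds)
        else:
            thresholds = None
            constrained_mask = mobility.viable_mask.copy()
        constrained = rom_df.loc[constrained_mask]
        write_pose_table(constrained, out / "constrained.csv")
        report["n_constrained"] = int(constrained_mask.sum())

        stage("volumes")
        angles = grid.angles
        sets = {"osteological": mobility.viable_mask,
                "constrained": constrained_mask}
        volumes = {}
        alpha_used = {}
        for name, mask in sets.items():
            pts = sine_correct(angles[mask]) if mask.sum() else \
                np.empty((0, 3))
            alpha = choose_alpha(pts, config.step, config.alpha)
            mv = alpha_volume(pts, alpha) if len(pts) >= 4 else None
            volumes[name] = 0.0 if mv is None else mv.volume
            alpha_used[name] = alpha
        report["volume_deg3"] = {k: round(v, 3) for k, v in volumes.items()}
        report["alpha_deg"] = alpha_used
        if volumes["osteological"] > 0:
            # a degenerate constrained set simply misses everything
            ref_pts = sine_correct(angles[mobility.viable_mask])
            cand_pts = sine_correct(angles[constrained_mask])
            m_deg3, m_pct, se = missed_volume(
                ref_pts, cand_pts, alpha_used["osteological"],
                n_samples=config.mc_samples, seed=config.seed,
                alpha_candidate=alpha_used["constrained"])
            report["missed_deg3"] = round(float(m_deg3), 3)
            report["missed_pct"] = round(float(m_pct), 3)
            report["missed_mc_se_deg3"] = round(float(se), 3)
    except InvalidInputError:
        raise
    except Exception as exc:  # label the failing stage for the caller
        last = list(report["stages"])[-1] if report["stages"] else "?"
        raise RuntimeError(f"pipeline failed in stage '{last}': {exc}") \
            from exc

    report["elapsed_s"] = round(time.time() - t_start, 2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
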