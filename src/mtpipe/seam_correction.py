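"""Seam/register consensus and alignment-parameter corrections.

The seam check assigns each segment a class (k, register): its current
alignment corresponds to the true seam position rotated k times around
the helical axis (k multiples of the twist, with the matching k x rise
axial translation) and register-shifted by 0 or 1 monomer repeat (41 Å).
Segments of one tube must share a seam, so class assignments are unified
to the per-tube mode, and the consensus is converted into a Rot-angle
increment plus an axial translation decomposed into image-plane origin
updates.  The correction forms a group action: corrections compose
additively in k.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import helical_geometry as hg
from . import reference_matching as rm
from .star_io import ParticleTable, normalize_angle

__all__ = ["unify_seam_class", "apply_seam_correction",
           "verify_seam_convergence"]

logger = logging.getLogger(__name__)


def unify_seam_class(assignments) -> tuple[int, int]:
    """Modal (k, register) of a tube's per-segment seam classes.

    Ties break toward smaller |k|, then register 0, then smaller k.
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("need at least one assignment")
    counts: dict[tuple[int, int], int] = {}
    for a in assignments:
        key = (int(a[0]), int(a[1]))
        counts[key] = counts.get(key, 0) + 1
    ordered = sorted(counts.items(),
                     key=lambda kv: (-kv[1], abs(kv[0][0]), kv[0][1], kv[0][0]))
    return ordered[0][0]


def correction_params(params: hg.HelicalParams) -> tuple[float, float]:
    """(twist, rise) used for corrections: refinement-stage values where
    tabulated (13/14 PF), else the architecture table values."""
    if params.refine_twist is not None and params.refine_rise is not None:
        return params.refine_twist, params.refine_rise
    logger.warning("no refinement twist/rise for %s; using table values",
                   params.label)
    return params.twist, params.rise


def apply_seam_correction(tube: ParticleTable, consensus: tuple[int, int],
                          params: hg.HelicalParams) -> ParticleTable:
    """Correct a tube's Rot angles and origins for its consensus class.

    Rot increases by k x twist; the axial translation
    t = k x rise + register x 41 Å is decomposed into the image plane along
    u = sin(tilt) (cos psi, sin psi), the projected direction of the
    helical axis.  The identity consensus (0, 0) leaves the table
    unchanged.  Class labels are reset to the identity class.
    """
    k, reg = int(consensus[0]), int(consensus[1])
    twist, rise = correction_params(params)
    out = tube.copy()
    if k == 0 and reg == 0:
        return out
    df = out.df
    t = k * rise + reg * params.monomer_repeat
    df["rot"] = normalize_angle(df["rot"].to_numpy(dtype=float) + k * twist)
    tilt = df["tilt"].to_numpy(dtype=float)
    psi = df["psi"].to_numpy(dtype=float)
    u = np.stack([np.sin(np.deg2rad(tilt)) * np.cos(np.deg2rad(psi)),
                  np.sin(np.deg2rad(tilt)) * np.sin(np.deg2rad(psi))], axis=1)
    df["origin_x"] = df["origin_x"].to_numpy(dtype=float) + t * u[:, 0]
    df["origin_y"] = df["origin_y"].to_numpy(dtype=float) + t * u[:, 1]
    identity_class = hg.seam_offset_range(params.pf_number).index(0) + 1
    df["class_id"] = identity_class
    return out


def verify_seam_convergence(stack: np.ndarray, table: ParticleTable,
                            params_by_tube: dict,
                            resolution_limit: float = rm.RESOLUTION_LIMIT):
    """Classify -> unify -> correct -> re-classify; report convergence.

    For each tube (grouped by architecture) the seam check is run, the
    consensus correction applied, and the corrected parameters
    re-classified.  Returns ``(fraction_converged, report, corrected)``
    where a tube converges when its post-correction consensus is (0, 0).
    """
    df = table.df
    tubes = np.unique(df["tube_id"].to_numpy())
    corrected = table.copy()
    rows = []

    by_arch: dict[str, list] = {}
    for tube_id in tubes:
        by_arch.setdefault(params_by_tube[tube_id].label, []).append(tube_id)

    for label, tube_ids in sorted(by_arch.items()):
        params = params_by_tube[tube_ids[0]]
        if not params.has_seam:
            for tube_id in tube_ids:
                rows.append({"tube_id": int(tube_id), "arch": label,
                             "consensus_k": 0, "consensus_reg": 0,
                             "recheck_k": 0, "recheck_reg": 0,
                             "converged": True})
            continue
        sel = df["tube_id"].isin(tube_ids).to_numpy()
        sub = table.copy()
        sub.df = df.loc[sel].reset_index(drop=True)
        sub_stack = stack[sel]
        res = rm.seam_classify(sub_stack, sub, params,
                               resolution_limit=resolution_limit)

        # unify and correct per tube
        for tube_id in tube_ids:
            tsel = sub.df["tube_id"].to_numpy() == tube_id
            labels = [res.labels[c] for c in
                      res.df.loc[tsel, "class_index"].to_numpy()]
            cons = unify_seam_class(labels)
            tube_tbl = sub.copy()
            tube_tbl.df = sub.df.loc[tsel].reset_index(drop=True)
            fixed = apply_seam_correction(tube_tbl, cons, params)
            res2 = rm.seam_classify(stack[sel][tsel], fixed, params,
                                    resolution_limit=resolution_limit)
            labels2 = [res2.labels[c] for c in
                       res2.df["class_index"].to_numpy()]
            cons2 = unify_seam_class(labels2)
            glob = df["tube_id"].to_numpy() == tube_id
            for col in ("rot", "tilt", "psi", "origin_x", "origin_y",
                        "class_id"):
                corrected.df.loc[glob, col] = fixed.df[col].to_numpy()
            rows.append({"tube_id": int(tube_id), "arch": label,
                         "consensus_k": cons[0], "consensus_reg": cons[1],
                         "recheck_k": cons2[0], "recheck_reg": cons2[1],
                         "converged": cons2 == (0, 0)})

    report = pd.DataFrame(rows)
    fraction = float(report["converged"].mean()) if len(report) else 0.0
    return fraction, report, corrected
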