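"""Per-tube consistency enforcement for Rot angles and X/Y shifts.

Alignment against an undecorated (or weakly decorated) MT reference is
degenerate up to the protofilament register: trial Rot angles cluster at
multiples of the helical twist.  Within one filament all segments must
share a single register and drift only slowly (supertwist), so the Rot
series of a tube is cleaned by clustering angles on the circle (single
linkage, 8 deg tolerance — below the ~22-33 deg inter-register spacing),
regressing the dominant cluster on segment index, and imposing the fitted
line on every segment.  X/Y origins are treated the same way: runs broken
by axial mis-translations (±41/±82 Å) are detected as jumps against the
local median step, and the dominant run's linear trend is imposed.
Internally inconsistent tubes are rejected by quality control.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from . import helical_geometry as hg
from .star_io import ParticleTable, normalize_angle

__all__ = [
    "RotCluster", "circular_distance", "cluster_rot_angles",
    "unify_rot", "smooth_xy_shifts", "qc_reject_tubes",
]

ROT_CLUSTER_TOLERANCE = 8.0   # deg
XY_JUMP_THRESHOLD = 20.5      # Å, half the 41 Å monomer repeat
MIN_CLUSTER_FRACTION = 0.5    # QC: modal Rot cluster must hold >= this


def circular_distance(a, b):
    """Smallest absolute angular difference in degrees."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


@dataclasses.dataclass
class RotCluster:
    """A connected component of Rot angles on the circle."""

    indices: np.ndarray        # positions into the input arrays
    angles: np.ndarray         # degrees
    slope: float | None = None
    intercept: float | None = None

    @property
    def size(self) -> int:
        return len(self.indices)


def cluster_rot_angles(angles, tolerance: float = ROT_CLUSTER_TOLERANCE,
                       scores=None) -> list[RotCluster]:
    """Single-linkage circular clustering at the given angular tolerance.

    Equivalent to connected components of the pairwise circular-distance
    graph thresholded at ``tolerance``: sort the angles around the circle
    and cut at every gap larger than the tolerance.  Clusters are returned
    largest first (ties: larger mean score, then lowest member position).
    """
    angles = np.asarray(angles, dtype=float)
    n = len(angles)
    if n == 0:
        raise ValueError("need at least one angle")
    if scores is None:
        scores = np.zeros(n)
    scores = np.asarray(scores, dtype=float)

    wrapped = angles % 360.0
    order = np.argsort(wrapped, kind="stable")
    sw = wrapped[order]
    gaps = np.diff(sw)
    wrap_gap = sw[0] + 360.0 - sw[-1]
    cuts = np.where(gaps > tolerance)[0]   # cut between sorted i and i+1

    if len(cuts) == 0:
        groups = [order]
    else:
        groups = []
        bounds = [c + 1 for c in cuts]
        pieces = np.split(order, bounds)
        if wrap_gap <= tolerance and len(pieces) > 1:
            pieces[0] = np.concatenate([pieces[-1], pieces[0]])
            pieces = pieces[:-1]
        groups = pieces

    clusters = [RotCluster(np.sort(g), angles[np.sort(g)]) for g in groups]
    clusters.sort(key=lambda c: (-c.size, -scores[c.indices].mean(),
                                 c.indices.min()))
    return clusters


def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def _circular_mean(angles: np.ndarray) -> float:
    a = np.deg2rad(angles)
    return float(np.rad2deg(np.arctan2(np.sin(a).mean(), np.cos(a).mean())))


def unify_rot(tube: ParticleTable, tolerance: float = ROT_CLUSTER_TOLERANCE,
              scores=None) -> ParticleTable:
    """Impose one linear Rot trend (slope x segment_index + intercept).

    The most populated circular cluster defines the register; the line is
    fitted to its members (angles unwrapped about the cluster's circular
    mean) and imposed on every segment, members or not.  Falls back to a
    constant (the cluster's circular mean) when fewer than two distinct
    segment indices are available.  Idempotent.
    """
    df = tube.df
    angles = df["rot"].to_numpy(dtype=float)
    idx = df["segment_index"].to_numpy(dtype=float)
    clusters = cluster_rot_angles(angles, tolerance, scores)
    top = clusters[0]
    mu = _circular_mean(top.angles)
    y = mu + normalize_angle(top.angles - mu)
    x = idx[top.indices]
    if len(np.unique(x)) < 2:
        slope, intercept = 0.0, mu
    else:
        slope, intercept = _fit_line(x, y)
    out = tube.copy()
    out.df["rot"] = normalize_angle(slope * idx + intercept)
    return out


def smooth_xy_shifts(tube: ParticleTable,
                     jump_threshold: float = XY_JUMP_THRESHOLD) -> ParticleTable:
    """Impose linear origin_x/origin_y trends from the dominant run.

    The index-ordered origin sequence is split wherever the step deviates
    from the componentwise median step by more than ``jump_threshold``
    (half the 41 Å monomer repeat, the smallest mis-translation).  Lines
    are fitted to the largest contiguous run and imposed everywhere.
    """
    df = tube.df
    v = df[["origin_x", "origin_y"]].to_numpy(dtype=float)
    idx = df["segment_index"].to_numpy(dtype=float)
    n = len(v)
    if n == 0:
        raise ValueError("empty tube")
    if n == 1:
        return tube.copy()
    # detrend by the median step, then group segments whose residuals agree:
    # mis-translated blocks sit a lattice jump away from the true line, while
    # clean segments separated by such a block still cluster together.
    med = np.median(np.diff(v, axis=0), axis=0)
    resid = v - med * idx[:, None]
    d = np.linalg.norm(resid[:, None, :] - resid[None, :, :], axis=2)
    adj = csr_matrix(d <= jump_threshold)
    n_comp, comp = connected_components(adj, directed=False)
    clusters = [np.where(comp == c)[0] for c in range(n_comp)]
    # largest cluster; ties prefer the better-centred one (picks are roughly
    # centred, mis-translations are |41| Å or more), then the earliest
    clusters.sort(key=lambda r: (-len(r),
                                 np.median(np.linalg.norm(v[r], axis=1)),
                                 r.min()))
    top = clusters[0]
    out = tube.copy()
    for j, col in enumerate(("origin_x", "origin_y")):
        x, y = idx[top], v[top, j]
        if len(np.unique(x)) < 2:
            slope, intercept = 0.0, float(y.mean())
        else:
            slope, intercept = _fit_line(x, y)
        out.df[col] = slope * idx + intercept
    return out


def qc_reject_tubes(table: ParticleTable,
                    twist_by_tube: dict | float | None = None,
                    max_step: float | None = None,
                    min_cluster_fraction: float = MIN_CLUSTER_FRACTION,
                    tolerance: float = ROT_CLUSTER_TOLERANCE):
    """Reject tubes with internally inconsistent Rot series.

    A tube fails when any adjacent-segment circular Rot step exceeds
    ``max_step`` (default 2x the magnitude of the tube's helical twist) or
    when its largest Rot cluster holds less than ``min_cluster_fraction``
    of its segments.  Returns (kept tube_ids, rejected tube_ids, report).
    """
    rows = []
    kept, rejected = [], []
    for tube_id, g in table.df.groupby("tube_id"):
        g = g.sort_values("segment_index")
        rot = g["rot"].to_numpy(dtype=float)
        step = circular_distance(rot[1:], rot[:-1]).max() if len(rot) > 1 else 0.0
        top = cluster_rot_angles(rot, tolerance)[0]
        frac = top.size / len(rot)
        if max_step is not None:
            limit = max_step
        elif isinstance(twist_by_tube, dict):
            limit = 2.0 * abs(twist_by_tube[tube_id])
        elif twist_by_tube is not None:
            limit = 2.0 * abs(float(twist_by_tube))
        else:
            limit = 2.0 * abs(hg.ARCHITECTURES[(13, 3)][1])
        bad_step = step > limit
        bad_frac = frac < min_cluster_fraction
        ok = not (bad_step or bad_frac)
        (kept if ok else rejected).append(int(tube_id))
        rows.append({"tube_id": int(tube_id), "n_segments": len(rot),
                     "max_rot_step": float(step), "step_limit": float(limit),
                     "cluster_fraction": float(frac),
                     "rejected": not ok,
                     "reason": ("" if ok else
                                ("step" if bad_step else "") +
                                ("+" if bad_step and bad_frac else "") +
                                ("cluster" if bad_frac else ""))})
    return kept, rejected, pd.DataFrame(rows)


def plot_rot_series(table: ParticleTable, path, rejected=()) -> None:
    """Per-tube Rot-vs-segment QC plot (one panel per tube)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tubes = list(table.df.groupby("tube_id"))
    fig, axes = plt.subplots(len(tubes), 1, squeeze=False,
                             figsize=(6, 1.6 * len(tubes)))
    for ax, (tube_id, g) in zip(axes[:, 0], tubes):
        g = g.sort_values("segment_index")
        ax.plot(g["segment_index"], g["rot"], "o-", ms=3)
        tag = " (rejected)" if tube_id in set(rejected) else ""
        ax.set_ylabel(f"tube {tube_id}{tag}", fontsize=7)
    axes[-1, 0].set_xlabel("segment index")
    fig.suptitle("Rot angle per segment")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
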