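"""Segment averages ("super-particles") along filaments.

Adjacent segments of a filament are extracted one dimer repeat (82 Å)
apart, so consecutive boxes contain the same lattice up to the slow
supertwist Rot drift.  Averaging each segment with its +-half_window
neighbours (default 3, a 7-segment window) therefore boosts the
signal-to-noise ratio by up to the window size without blurring, which is
what makes the supervised classification stages reliable on noisy data.

Neighbours are brought into the central segment's frame using only what
is known at this stage: the Psi priors (in-plane rotation by the prior
difference — zero on straight picks) and the inter-segment spacing, whose
residual modulo the 82 Å lattice repeat is applied as an image shift
(zero at the default spacing).  Windows are truncated at filament ends.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from . import helical_geometry as hg
from .star_io import ParticleTable

__all__ = ["make_segment_averages", "recentre_and_reaverage"]

DEFAULT_HALF_WINDOW = 3


def _align_neighbor(img: np.ndarray, dpsi: float, shift_ang: np.ndarray,
                    pixel_size: float) -> np.ndarray:
    out = img
    if dpsi != 0.0:
        # rotate(P(psi_j), psi_j - psi_i) ~= P(psi_i)
        out = ndimage.rotate(out, dpsi, reshape=False, order=1,
                             mode="constant", cval=0.0)
    if shift_ang[0] or shift_ang[1]:
        out = ndimage.shift(out, (shift_ang[1] / pixel_size,
                                  shift_ang[0] / pixel_size),
                            order=1, mode="constant", cval=0.0)
    return out


def make_segment_averages(stack: np.ndarray, table: ParticleTable,
                          half_window: int = DEFAULT_HALF_WINDOW,
                          spacing: float = 82.0,
                          excluded: np.ndarray | None = None) -> np.ndarray:
    """Average each segment with its neighbours along the filament.

    Returns a stack of the same length.  ``excluded`` marks segments that
    do not contribute to any window (their own average is a copy of the
    raw image).
    """
    if len(stack) != len(table):
        raise ValueError("stack and table lengths differ")
    n = len(stack)
    if excluded is None:
        excluded = np.zeros(n, dtype=bool)
    out = np.empty_like(np.asarray(stack, dtype=float))
    df = table.df
    repeat = hg.DIMER_REPEAT

    for _, g in df.groupby("tube_id"):
        g = g.sort_values("segment_index")
        rows = g.index.to_numpy()
        refs = g["image_ref"].to_numpy(dtype=int)
        psis = g["psi_prior"].to_numpy(dtype=float)
        m = len(rows)
        for a in range(m):
            i_img = refs[a]
            if excluded[i_img]:
                out[i_img] = stack[i_img]
                continue
            acc = np.zeros_like(out[0])
            count = 0
            u = hg.axis_in_plane(90.0, psis[a])
            for b in range(max(0, a - half_window),
                           min(m, a + half_window + 1)):
                j_img = refs[b]
                if excluded[j_img]:
                    continue
                d = (b - a) * spacing
                resid = d - round(d / repeat) * repeat
                img = _align_neighbor(stack[j_img], psis[b] - psis[a],
                                      -resid * u, table.pixel_size)
                acc += img
                count += 1
            out[i_img] = acc / max(count, 1)
    return out


def recentre_and_reaverage(stack: np.ndarray, table: ParticleTable,
                           half_window: int = DEFAULT_HALF_WINDOW,
                           spacing: float = 82.0):
    """Re-centre segments on their refined origins, then re-average.

    The refined translations are folded into the picking coordinates
    (coords move by origin / pixel_size) and removed from the images by
    an interpolating shift; origins are reset to zero.  Segments whose
    refined centre leaves the box are flagged and excluded from their
    neighbours' windows.  Returns ``(averaged_stack, recentred_table,
    excluded_mask)``.
    """
    if len(stack) != len(table):
        raise ValueError("stack and table lengths differ")
    n = len(stack)
    out = table.copy()
    df = out.df
    apix = table.pixel_size
    limit = 0.5 * table.box_size * apix
    ox = df["origin_x"].to_numpy(dtype=float)
    oy = df["origin_y"].to_numpy(dtype=float)
    excluded = (np.abs(ox) > limit) | (np.abs(oy) > limit)

    recut = np.empty_like(np.asarray(stack, dtype=float))
    refs = df["image_ref"].to_numpy(dtype=int)
    for a in range(n):
        i = refs[a]
        if excluded[a]:
            recut[i] = stack[i]
            continue
        recut[i] = ndimage.shift(stack[i], (-oy[a] / apix, -ox[a] / apix),
                                 order=1, mode="constant", cval=0.0)
    df["coord_x"] = df["coord_x"].to_numpy(dtype=float) + ox / apix
    df["coord_y"] = df["coord_y"].to_numpy(dtype=float) + oy / apix
    df["origin_x"] = 0.0
    df["origin_y"] = 0.0

    exc_by_img = np.zeros(n, dtype=bool)
    exc_by_img[refs[excluded]] = True
    avg = make_segment_averages(recut, out, half_window, spacing, exc_by_img)
    return avg, out, excluded
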