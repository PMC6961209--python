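"""Supervised projection matching against synthetic reference sets.

A desk-scale stand-in for a single iteration of supervised 3D
classification: every segment image is scored by normalised
cross-correlation (NCC) against projections of a fixed reference set,
either over an exhaustive angle/shift grid (``align=True``; used for
protofilament-number sorting and the global Rot search) or at the
segment's current parameters only (``align=False``; used for the
seam/register check).  References are never re-estimated from the data.

Images and projections are band-limited (sharp Fourier mask, default
12 Å) before scoring.  Ties are broken deterministically: lower class
index, then smaller |shift|, then grid order.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from . import helical_geometry as hg
from .star_io import ParticleTable, group_by_tube, normalize_angle

__all__ = [
    "SearchGrid", "ReferenceSet", "MatchResult",
    "match", "pf_sort", "seam_classify",
    "unify_class_per_tube", "confidence_report",
]

RESOLUTION_LIMIT = 12.0       # Å, E-step band limit
REFERENCE_LOWPASS = 15.0      # Å, reference synthesis low-pass
COARSE_ANGULAR_STEP = 1.8     # deg, global-search sampling
FINE_ANGULAR_STEP = 0.9       # deg, local-search sampling
DEFAULT_MAX_SHIFT = 65.0      # Å, offset search range
MASK_DIAMETER = 580.0         # Å, circular particle mask


@dataclasses.dataclass
class SearchGrid:
    """Angle/shift search grid for ``align=True`` matching.

    ``rot_local_range`` of None means a full global Rot search; otherwise
    Rot is sampled within ±range around each segment's current value.
    Tilt and Psi are held at each segment's priors (the helical priors
    restrain them far more tightly than the Rot angle, which carries the
    register/seam ambiguity this module exists to resolve).
    """

    rot_step: float = COARSE_ANGULAR_STEP
    rot_local_range: float | None = None
    max_shift: float = DEFAULT_MAX_SHIFT   # Å
    shift_step: int = 1                    # px

    def rot_values(self, current: float) -> np.ndarray:
        if self.rot_local_range is None:
            return np.arange(-180.0, 180.0, self.rot_step)
        n = int(np.floor(self.rot_local_range / self.rot_step + 1e-9))
        return current + np.arange(-n, n + 1) * self.rot_step


class ReferenceSet:
    """Labelled lattice references sharing rendering geometry."""

    def __init__(self, lattices, labels, pixel_size: float, box_px: int,
                 lowpass: float = REFERENCE_LOWPASS, mode: str = "full"):
        if len(lattices) == 0:
            raise ValueError("empty reference list")
        if len(lattices) != len(labels):
            raise ValueError("labels must match references")
        self.lattices = list(lattices)
        self.labels = list(labels)
        self.pixel_size = float(pixel_size)
        self.box_px = int(box_px)
        self.lowpass = float(lowpass)
        self.mode = mode
        self._cache: dict = {}

    def __len__(self) -> int:
        return len(self.lattices)

    def projection(self, idx: int, rot: float, tilt: float, psi: float = 0.0,
                   origin_x: float = 0.0, origin_y: float = 0.0) -> np.ndarray:
        """Cached analytic projection (cache key quantised to 0.001 deg/Å)."""
        key = (idx, round(rot, 3), round(tilt, 3), round(psi, 3),
               round(origin_x, 3), round(origin_y, 3))
        img = self._cache.get(key)
        if img is None:
            img = hg.project_lattice(
                self.lattices[idx], rot, tilt, psi, origin_x, origin_y,
                pixel_size=self.pixel_size, box_px=self.box_px,
                lowpass=self.lowpass, mode=self.mode).data
            self._cache[key] = img
        return img


@dataclasses.dataclass
class MatchResult:
    """Per-segment best class and alignment parameters."""

    df: pd.DataFrame            # class_index, score, rot, tilt, psi, origins
    labels: list                # class_index -> label
    search: dict = dataclasses.field(default_factory=dict)
    scores: np.ndarray | None = None   # (n_images, n_classes), align=False only

    def apply_to(self, table: ParticleTable) -> ParticleTable:
        out = table.copy()
        for col in ("rot", "tilt", "psi", "origin_x", "origin_y"):
            out.df[col] = self.df[col].to_numpy()
        out.df["class_id"] = self.df["class_index"].to_numpy() + 1
        return out


def _band_mask(box: int, pixel_size: float, cutoff: float) -> np.ndarray:
    fy = np.fft.fftfreq(box, d=pixel_size)[:, None]
    fx = np.fft.rfftfreq(box, d=pixel_size)[None, :]
    mask = (fy ** 2 + fx ** 2) <= (1.0 / cutoff) ** 2
    mask[0, 0] = False   # remove DC: zero-mean scoring
    return mask


def _circular_mask(box: int, pixel_size: float,
                   diameter: float = MASK_DIAMETER) -> np.ndarray:
    r = min(0.5 * diameter / pixel_size, box / 2.0)
    c = box // 2
    y, x = np.ogrid[:box, :box]
    return ((y - c) ** 2 + (x - c) ** 2 <= r * r).astype(float)


def _shift_candidates(box: int, pixel_size: float, max_shift: float,
                      step: int):
    """Flat indices into the (box, box) correlation map, ordered by |shift|."""
    r = int(np.floor(max_shift / pixel_size))
    r = min(r, box // 2 - 1)
    cands = []
    for dy in range(-r, r + 1, step):
        for dx in range(-r, r + 1, step):
            if (dx * pixel_size) ** 2 + (dy * pixel_size) ** 2 <= max_shift ** 2:
                cands.append((dy * dy + dx * dx, dy, dx))
    cands.sort()
    idx = np.array([(dy % box) * box + (dx % box) for _, dy, dx in cands])
    shifts = np.array([(dx, dy) for _, dy, dx in cands], dtype=float)
    return idx, shifts * pixel_size


def _rotate_image(img: np.ndarray, deg: float) -> np.ndarray:
    """Rotate image content by ``deg`` about its centre.

    Sign convention: ``_rotate_image(P(psi), +psi) ~= P(0)``, i.e. rotating
    by a segment's Psi prior brings it to the canonical psi = 0 view.
    """
    if deg == 0.0:
        return img
    return ndimage.rotate(img, deg, reshape=False, order=1,
                          mode="constant", cval=0.0)


def _rz2(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s], [s, c]])


def match(stack: np.ndarray, table: ParticleTable, references: ReferenceSet,
          search: SearchGrid | None = None, align: bool = True,
          resolution_limit: float = RESOLUTION_LIMIT) -> MatchResult:
    """Exhaustively score segments against the reference set.

    With ``align=True`` each image is compared over the Rot grid and
    integer-pixel shift grid (Tilt/Psi at the priors); the best-scoring
    (class, Rot, shift) is returned.  With ``align=False`` each image is
    scored at its current table parameters against every class, returning
    the best class and the full score matrix.
    """
    if len(stack) != len(table):
        raise ValueError("stack and table lengths differ")
    if search is None:
        search = SearchGrid()
    box = references.box_px
    apix = references.pixel_size
    mask = _band_mask(box, apix, resolution_limit)
    n = len(stack)
    df = table.df

    out = {
        "class_index": np.zeros(n, dtype=int),
        "score": np.full(n, -np.inf),
        "rot": df["rot"].to_numpy(dtype=float).copy(),
        "tilt": df["tilt"].to_numpy(dtype=float).copy(),
        "psi": df["psi"].to_numpy(dtype=float).copy(),
        "origin_x": df["origin_x"].to_numpy(dtype=float).copy(),
        "origin_y": df["origin_y"].to_numpy(dtype=float).copy(),
    }

    circ = _circular_mask(box, apix)

    if not align:
        scores = np.empty((n, len(references)))
        for i in range(n):
            row = df.iloc[i]
            ib = np.fft.irfft2(np.fft.rfft2(stack[i]) * mask, s=(box, box))
            ni = np.sqrt(max(float((circ * ib * ib).sum()), 1e-30))
            best, best_c = -np.inf, 0
            for c in range(len(references)):
                proj = references.projection(
                    c, float(row["rot"]), float(row["tilt"]), float(row["psi"]),
                    float(row["origin_x"]), float(row["origin_y"]))
                mp = circ * np.fft.irfft2(np.fft.rfft2(proj) * mask,
                                          s=(box, box))
                s = float((ib * mp).sum()
                          / max(ni * np.linalg.norm(mp), 1e-30))
                scores[i, c] = s
                if s > best:
                    best, best_c = s, c
            out["class_index"][i] = best_c
            out["score"][i] = best
        res = pd.DataFrame(out)
        return MatchResult(res, references.labels,
                           {"align": False, "resolution_limit": resolution_limit},
                           scores)

    cand_idx, cand_shifts = _shift_candidates(
        box, apix, search.max_shift, search.shift_step)
    f_circ_conj = np.conj(np.fft.rfft2(circ))

    # cache of masked band-limited projection FFTs keyed by (class, rot, tilt)
    proj_fft: dict = {}

    def get_proj(c, rot, tilt):
        key = (c, round(rot, 3), round(tilt, 3))
        v = proj_fft.get(key)
        if v is None:
            p = np.fft.irfft2(
                np.fft.rfft2(references.projection(c, rot, tilt, 0.0)) * mask,
                s=(box, box))
            mp = circ * p   # mask fixed in the reference frame
            v = (np.conj(np.fft.rfft2(mp)), float(np.linalg.norm(mp)))
            proj_fft[key] = v
        return v

    for i in range(n):
        row = df.iloc[i]
        psi = float(row["psi_prior"])
        tilt = float(row["tilt_prior"])
        # undo the in-plane rotation: canon ~ view at psi = 0
        canon = _rotate_image(stack[i], psi)
        ib = np.fft.irfft2(np.fft.rfft2(canon) * mask, s=(box, box))
        fi = np.fft.rfft2(ib)
        # image norm under the mask, for every trial shift (masked NCC)
        den = np.fft.irfft2(np.fft.rfft2(ib * ib) * f_circ_conj, s=(box, box))
        den = np.sqrt(np.clip(den.flat[cand_idx], 1e-30, None))
        rots = search.rot_values(float(row["rot"]))
        best = (-np.inf, 0, 0.0, 0)   # score, class, rot, shift candidate
        for c in range(len(references)):
            for rot in rots:
                fp_conj, npr = get_proj(c, float(rot), tilt)
                cc = np.fft.irfft2(fi * fp_conj, s=(box, box))
                sc = cc.flat[cand_idx] / (den * max(npr, 1e-30))
                j = int(np.argmax(sc))
                if sc[j] > best[0]:
                    best = (float(sc[j]), c, float(rot), j)
        score, c, rot, j = best
        o = _rz2(psi) @ cand_shifts[j]
        out["class_index"][i] = c
        out["score"][i] = score
        out["rot"][i] = normalize_angle(rot)
        out["tilt"][i] = tilt
        out["psi"][i] = psi
        out["origin_x"][i] = o[0]
        out["origin_y"][i] = o[1]

    res = pd.DataFrame(out)
    meta = {"align": True, "rot_step": search.rot_step,
            "rot_local_range": search.rot_local_range,
            "max_shift": search.max_shift, "shift_step": search.shift_step,
            "resolution_limit": resolution_limit}
    return MatchResult(res, references.labels, meta)


def pf_sort(stack: np.ndarray, table: ParticleTable,
            architectures=None, search: SearchGrid | None = None,
            lattice_length: float | None = None) -> MatchResult:
    """Protofilament-number sorting: align segment averages to the six
    undecorated architecture references with coarse (1.8 deg) sampling."""
    if architectures is None:
        architectures = hg.all_architectures()
    if lattice_length is None:
        lattice_length = 1.5 * table.box_size * table.pixel_size
    lattices, labels = [], []
    for p in architectures:
        lattices.append(hg.build_lattice(
            p, lattice_length, decorated=False,
            seam_pf=0 if p.has_seam else None))
        labels.append(p.label)
    refs = ReferenceSet(lattices, labels, table.pixel_size, table.box_size,
                        mode="full")
    if search is None:
        search = SearchGrid(rot_step=COARSE_ANGULAR_STEP)
    return match(stack, table, refs, search, align=True)


def seam_classify(stack: np.ndarray, table: ParticleTable,
                  params: hg.HelicalParams,
                  base_lattice: hg.LatticeModel | None = None,
                  occupancy_lattice=None,
                  resolution_limit: float = RESOLUTION_LIMIT) -> MatchResult:
    """Seam/register check: classify centred segment averages against the
    2N decorator-only references, without alignment."""
    if base_lattice is None:
        base_lattice = hg.build_lattice(
            params, 1.5 * table.box_size * table.pixel_size,
            decorated=True, seam_pf=0)
    enum = hg.enumerate_seam_references(base_lattice, params)
    if len(enum) != 2 * params.pf_number:
        raise ValueError("seam reference count must be 2 x PF number")
    lattices = [lat for _, _, lat in enum]
    labels = [(k, reg) for k, reg, _ in enum]
    refs = ReferenceSet(lattices, labels, table.pixel_size, table.box_size,
                        mode="decorator_only")
    return match(stack, table, refs, align=False,
                 resolution_limit=resolution_limit)


def unify_class_per_tube(result_df: pd.DataFrame, table: ParticleTable):
    """Impose each tube's modal class on all its segments.

    Returns ``(unified_class_index per segment, per-tube report)`` where the
    report has columns tube_id, modal_class, confidence (percentage of the
    tube's segments in the modal class).  Ties go to the lowest class index.
    """
    if len(result_df) != len(table):
        raise ValueError("assignment/table length mismatch")
    tubes = table.df["tube_id"].to_numpy()
    cls = result_df["class_index"].to_numpy()
    unified = cls.copy()
    rows = []
    for tube in np.unique(tubes):
        sel = tubes == tube
        vals, counts = np.unique(cls[sel], return_counts=True)
        modal = int(vals[np.argmax(counts)])   # first max -> lowest class
        conf = 100.0 * counts.max() / sel.sum()
        unified[sel] = modal
        rows.append({"tube_id": int(tube), "modal_class": modal,
                     "confidence": conf, "n_segments": int(sel.sum())})
    return unified, pd.DataFrame(rows)


def confidence_report(per_tube: pd.DataFrame) -> pd.DataFrame:
    """Histogram of per-tube assignment confidence (percent of tubes per bin).

    Bins are the deciles [0,10), ..., [90,100), with exactly-100% tubes in
    their own bin, mirroring how assignment confidence is usually displayed.
    """
    if len(per_tube) == 0:
        raise ValueError("no tubes")
    conf = per_tube["confidence"].to_numpy()
    labels = [f"{lo}-{lo + 10}" for lo in range(0, 100, 10)] + ["100"]
    counts = np.zeros(len(labels))
    for c in conf:
        if c >= 100.0:
            counts[-1] += 1
        else:
            counts[int(c // 10)] += 1
    pct = 100.0 * counts / len(conf)
    return pd.DataFrame({"bin": labels, "percent_of_tubes": pct})
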