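"""RELION-style STAR particle metadata: reading, writing, grouping.

Per-segment alignment parameters for filament ("helical tube") processing
are carried in a :class:`ParticleTable`, a thin wrapper around a pandas
DataFrame with canonical column names and Ångström origins.  Two origin
dialects are supported on disk:

* ``legacy-px`` — ``rlnOriginX``/``rlnOriginY`` in pixels (RELION <= 3.0),
* ``angstrom``  — ``rlnOriginXAngst``/``rlnOriginYAngst`` in Å (RELION >= 3.1).

Internally origins are always Å.  Angles are degrees; Rot and Psi are
normalised to (-180, 180] on write, Tilt lives in [0, 180].
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "SegmentRecord",
    "ParticleTable",
    "StarFormatError",
    "read_particle_star",
    "write_particle_star",
    "set_priors_and_reset",
    "group_by_tube",
    "normalize_angle",
]

# canonical column -> RELION tag
_TAGS = {
    "micrograph_id": "_rlnMicrographName",
    "tube_id": "_rlnHelicalTubeID",
    "coord_x": "_rlnCoordinateX",
    "coord_y": "_rlnCoordinateY",
    "rot": "_rlnAngleRot",
    "tilt": "_rlnAngleTilt",
    "psi": "_rlnAnglePsi",
    "tilt_prior": "_rlnAngleTiltPrior",
    "psi_prior": "_rlnAnglePsiPrior",
    "class_id": "_rlnClassNumber",
}
_TAG_ORIGIN_PX = ("_rlnOriginX", "_rlnOriginY")
_TAG_ORIGIN_ANGST = ("_rlnOriginXAngst", "_rlnOriginYAngst")
_TAG_IMAGE = "_rlnImageName"
_TAG_TRACK = "_rlnHelicalTrackLengthAngst"

_MANDATORY = ("micrograph_id", "tube_id", "coord_x", "coord_y")
_FLOAT_COLS = (
    "coord_x", "coord_y", "rot", "tilt", "psi",
    "tilt_prior", "psi_prior", "origin_x", "origin_y",
)

COLUMNS = (
    "micrograph_id", "tube_id", "segment_index", "coord_x", "coord_y",
    "rot", "tilt", "psi", "tilt_prior", "psi_prior",
    "origin_x", "origin_y", "class_id", "image_ref",
)


class StarFormatError(ValueError):
    """Raised for malformed or unsupported STAR content."""


def normalize_angle(a):
    """Fold angle(s) in degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = -((-a) % 360.0)
    out = np.where(out <= -180.0, out + 360.0, out)
    return out if out.ndim else float(out)


@dataclasses.dataclass(frozen=True)
class SegmentRecord:
    """One extracted filament segment (one STAR row)."""

    micrograph_id: str
    tube_id: int
    segment_index: int
    coord_x: float
    coord_y: float
    rot: float
    tilt: float
    psi: float
    tilt_prior: float
    psi_prior: float
    origin_x: float   # Å
    origin_y: float   # Å
    class_id: int     # 0 == unset
    image_ref: int    # 0-based index into the stack


@dataclasses.dataclass
class ParticleTable:
    """Ordered collection of segment records plus global image metadata.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per segment, columns as in :data:`COLUMNS`; extra
        (pass-through) STAR columns are kept verbatim as strings.
    pixel_size : float
        Å per pixel of the particle images (after binning).
    box_size : int
        Box edge in pixels.
    binning : int
        Binning factor relative to the raw micrograph pixel size.
    stack_name : str
        File name referenced by ``rlnImageName`` entries.
    """

    df: pd.DataFrame
    pixel_size: float = 5.56
    box_size: int = 108
    binning: int = 4
    stack_name: str = "particles.mrcs"
    extra: pd.DataFrame | None = None

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be > 0")
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise StarFormatError(f"table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "ParticleTable":
        return dataclasses.replace(
            self, df=self.df.copy(),
            extra=None if self.extra is None else self.extra.copy())

    def records(self) -> Iterator[SegmentRecord]:
        for row in self.df.itertuples(index=False):
            yield SegmentRecord(
                str(row.micrograph_id), int(row.tube_id), int(row.segment_index),
                float(row.coord_x), float(row.coord_y),
                float(row.rot), float(row.tilt), float(row.psi),
                float(row.tilt_prior), float(row.psi_prior),
                float(row.origin_x), float(row.origin_y),
                int(row.class_id), int(row.image_ref))

    @property
    def tube_ids(self) -> np.ndarray:
        return np.unique(self.df["tube_id"].to_numpy())


def make_table(n: int, **meta) -> ParticleTable:
    """Blank n-row table with zeroed parameters (test/simulator helper)."""
    df = pd.DataFrame({
        "micrograph_id": ["mic_000"] * n,
        "tube_id": np.ones(n, dtype=int),
        "segment_index": np.arange(n, dtype=int),
        "coord_x": np.zeros(n), "coord_y": np.zeros(n),
        "rot": np.zeros(n), "tilt": np.full(n, 90.0), "psi": np.zeros(n),
        "tilt_prior": np.full(n, 90.0), "psi_prior": np.zeros(n),
        "origin_x": np.zeros(n), "origin_y": np.zeros(n),
        "class_id": np.zeros(n, dtype=int),
        "image_ref": np.arange(n, dtype=int),
    })
    return ParticleTable(df, **meta)


def _detect_dialect(tags: set[str]) -> str:
    has_px = any(t in tags for t in _TAG_ORIGIN_PX)
    has_angst = any(t in tags for t in _TAG_ORIGIN_ANGST)
    if has_px and has_angst:
        raise StarFormatError(
            "mixed origin dialects: both rlnOriginX and rlnOriginXAngst present")
    if has_angst:
        return "angstrom"
    if has_px:
        return "legacy-px"
    return "none"


def read_particle_star(
    path: str | Path,
    dialect: str = "auto",
    pixel_size: float | None = None,
    box_size: int = 108,
    binning: int = 4,
) -> ParticleTable:
    """Read a particles data block into a :class:`ParticleTable`.

    ``dialect`` may be ``auto`` (detect from columns), ``legacy-px`` or
    ``angstrom``.  For legacy pixel origins a ``pixel_size`` (Å/px) is
    required to convert origins to Å; defaults to 5.56 (1.39 Å/px, 4x bin).
    Segment order within each tube is reconstructed from the helical track
    length column when present, else from the coordinate along the tube's
    principal direction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = gemmi.cif.read_file(str(path))
    block = None
    for b in doc:
        tags = {item.loop.tags[i] for item in b
                if item.loop is not None for i in range(len(item.loop.tags))}
        if _TAGS["tube_id"] in tags:
            block = b
            break
    if block is None:
        # a particles block without tube ids is a specific, named failure
        for b in doc:
            for item in b:
                if item.loop is not None and _TAGS["coord_x"] in item.loop.tags:
                    raise StarFormatError("tube grouping column absent "
                                          f"({_TAGS['tube_id']})")
        raise StarFormatError("no particles data block found")

    loop = next(item.loop for item in block if item.loop is not None
                and _TAGS["tube_id"] in item.loop.tags)
    tags = list(loop.tags)
    ncol, nrow = len(tags), loop.length()
    raw = {tags[j]: [loop[i, j] for i in range(nrow)] for j in range(ncol)}
    tagset = set(tags)

    for col in _MANDATORY:
        if _TAGS[col] not in tagset:
            raise StarFormatError(f"mandatory column missing: {_TAGS[col]}")

    found = _detect_dialect(tagset)
    if dialect != "auto" and found != "none" and found != dialect:
        raise StarFormatError(
            f"requested dialect {dialect!r} but file has {found!r} origins")
    eff = found if dialect == "auto" else dialect

    if pixel_size is None:
        pixel_size = 5.56

    n = nrow
    data: dict[str, object] = {}
    data["micrograph_id"] = raw[_TAGS["micrograph_id"]]
    data["tube_id"] = np.array(raw[_TAGS["tube_id"]], dtype=int)
    for col in ("coord_x", "coord_y", "rot", "tilt", "psi",
                "tilt_prior", "psi_prior"):
        tag = _TAGS[col]
        if tag in tagset:
            data[col] = np.array(raw[tag], dtype=float)
        else:
            data[col] = np.full(n, np.nan) if col.endswith("_prior") else np.zeros(n)

    if eff == "angstrom" and _TAG_ORIGIN_ANGST[0] in tagset:
        data["origin_x"] = np.array(raw[_TAG_ORIGIN_ANGST[0]], dtype=float)
        data["origin_y"] = np.array(raw[_TAG_ORIGIN_ANGST[1]], dtype=float)
    elif eff == "legacy-px" and _TAG_ORIGIN_PX[0] in tagset:
        data["origin_x"] = np.array(raw[_TAG_ORIGIN_PX[0]], dtype=float) * pixel_size
        data["origin_y"] = np.array(raw[_TAG_ORIGIN_PX[1]], dtype=float) * pixel_size
    else:
        data["origin_x"] = np.zeros(n)
        data["origin_y"] = np.zeros(n)

    if _TAGS["class_id"] in tagset:
        data["class_id"] = np.array(raw[_TAGS["class_id"]], dtype=int)
    else:
        data["class_id"] = np.zeros(n, dtype=int)

    stack_name = "particles.mrcs"
    if _TAG_IMAGE in tagset:
        idx, names = [], []
        for v in raw[_TAG_IMAGE]:
            i, _, name = v.partition("@")
            idx.append(int(i) - 1)
            names.append(name)
        data["image_ref"] = np.array(idx, dtype=int)
        if names:
            stack_name = names[0]
    else:
        data["image_ref"] = np.arange(n, dtype=int)

    df = pd.DataFrame(data)

    # segment ordering within tubes
    if _TAG_TRACK in tagset:
        track = np.array(raw[_TAG_TRACK], dtype=float)
        df["_order"] = track
    else:
        order = np.zeros(n)
        for _, g in df.groupby("tube_id"):
            xy = g[["coord_x", "coord_y"]].to_numpy()
            c = xy - xy.mean(axis=0)
            if len(g) > 1:
                _, _, vt = np.linalg.svd(c, full_matrices=False)
                order[g.index] = c @ vt[0]
            else:
                order[g.index] = 0.0
        df["_order"] = order
    df["segment_index"] = 0
    for _, g in df.groupby("tube_id"):
        ranks = np.argsort(np.argsort(g["_order"].to_numpy(), kind="stable"))
        df.loc[g.index, "segment_index"] = ranks
    df = df.drop(columns="_order")
    df = df.sort_values(["tube_id", "segment_index"], kind="stable")
    perm = df.index.to_numpy()
    df = df.reset_index(drop=True)

    known = ({_TAGS[c] for c in _TAGS} | set(_TAG_ORIGIN_PX)
             | set(_TAG_ORIGIN_ANGST) | {_TAG_IMAGE, _TAG_TRACK})
    extra_tags = [t for t in tags if t not in known]
    extra = None
    if extra_tags:
        extra = pd.DataFrame({t: raw[t] for t in extra_tags})
        extra = extra.iloc[perm].reset_index(drop=True)

    return ParticleTable(df[list(COLUMNS)], pixel_size=pixel_size,
                         box_size=box_size, binning=binning,
                         stack_name=stack_name, extra=extra)


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return f"{v:.6f}"
    return str(v)


def write_particle_star(table: ParticleTable, path: str | Path,
                        dialect: str = "angstrom") -> None:
    """Write the particles block; origins expressed per ``dialect``."""
    if dialect not in ("angstrom", "legacy-px"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = table.df
    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")

    tags = [_TAGS["micrograph_id"], _TAGS["tube_id"],
            _TAGS["coord_x"], _TAGS["coord_y"],
            _TAGS["rot"], _TAGS["tilt"], _TAGS["psi"],
            _TAGS["tilt_prior"], _TAGS["psi_prior"]]
    if dialect == "angstrom":
        tags += list(_TAG_ORIGIN_ANGST)
        ox = df["origin_x"].to_numpy()
        oy = df["origin_y"].to_numpy()
    else:
        tags += list(_TAG_ORIGIN_PX)
        ox = df["origin_x"].to_numpy() / table.pixel_size
        oy = df["origin_y"].to_numpy() / table.pixel_size
    tags += [_TAGS["class_id"], _TAG_IMAGE, _TAG_TRACK]
    extra_tags = [] if table.extra is None else list(table.extra.columns)
    tags += extra_tags

    loop = block.init_loop("", tags)
    rot = normalize_angle(df["rot"].to_numpy())
    psi = normalize_angle(df["psi"].to_numpy())
    for i in range(len(df)):
        row = df.iloc[i]
        vals = [
            str(row["micrograph_id"]), str(int(row["tube_id"])),
            _fmt(float(row["coord_x"])), _fmt(float(row["coord_y"])),
            _fmt(float(rot[i])), _fmt(float(row["tilt"])), _fmt(float(psi[i])),
            _fmt(float(row["tilt_prior"])), _fmt(float(row["psi_prior"])),
            _fmt(float(ox[i])), _fmt(float(oy[i])),
            str(int(row["class_id"])),
            f"{int(row['image_ref']) + 1:06d}@{table.stack_name}",
            _fmt(float(row["segment_index"]) * 82.0),
        ]
        if extra_tags:
            vals += [str(table.extra.iloc[i][t]) for t in extra_tags]
        loop.add_row([gemmi.cif.quote(v) for v in vals])
    doc.write_file(str(path))


def set_priors_and_reset(table: ParticleTable, reset_rot: bool = True,
                         reset_shifts: bool = True) -> ParticleTable:
    """Set Tilt/Psi to their picking priors; optionally zero Rot and origins.

    Mirrors the pre-refinement reset used between pipeline stages: angles
    that are reliably known from picking geometry (out-of-plane tilt ~ 90
    deg, in-plane rotation from the pick direction) are restored to the
    priors, while the poorly determined Rot angle and translations restart
    from zero.  Idempotent.
    """
    df = table.df
    if df["tilt_prior"].isna().any() or df["psi_prior"].isna().any():
        raise StarFormatError("tilt/psi priors absent; run pre-processing first")
    out = table.copy()
    out.df["tilt"] = out.df["tilt_prior"]
    out.df["psi"] = out.df["psi_prior"]
    if reset_rot:
        out.df["rot"] = 0.0
    if reset_shifts:
        out.df["origin_x"] = 0.0
        out.df["origin_y"] = 0.0
    return out


def group_by_tube(table: ParticleTable) -> list[ParticleTable]:
    """Partition into per-tube tables, ordered by segment_index within each."""
    groups = []
    for _, g in table.df.groupby("tube_id", sort=True):
        g = g.sort_values("segment_index", kind="stable").reset_index(drop=True)
        groups.append(dataclasses.replace(table, df=g, extra=None))
    return groups
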