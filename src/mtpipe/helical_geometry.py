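"""Microtubule lattice geometry, synthetic references, and projections.

A microtubule (MT) with N protofilaments (PFs) and start number S is
modelled as a 1-start helical lattice of tubulin monomers on a cylinder:
protofilament p is rotated by the helical twist and raised by the helical
rise relative to protofilament p-1, and monomers repeat every 41 Å along
each PF (alpha/beta alternating; dimer repeat 82 Å).  For odd S the lattice
closes with a lateral offset of an odd number of monomers, producing
exactly one heterotypic (alpha-beta) lateral interface: the seam.  A
decorator protein bound once per dimer on the outside of the wall breaks
the alpha/beta ambiguity in projection images.

Densities are synthesised as isotropic Gaussian pseudo-atoms and low-pass
filtered; projections use the RELION ZYZ Euler convention
(A = Rz(psi) @ Ry(tilt) @ Rz(rot)).
"""

from __future__ import annotations

import dataclasses
import math

import gemmi
import numpy as np
from scipy import ndimage

__all__ = [
    "HelicalParams", "LatticeModel", "ReferenceVolume", "ProjectionImage",
    "helical_table", "build_lattice", "transform_lattice",
    "count_heterotypic_interfaces", "synthesize_volume",
    "enumerate_seam_references", "seam_offset_range",
    "project", "project_lattice", "euler_matrix", "axis_in_plane",
    "write_mrc", "read_mrc",
]

# (pf_number, start_number) -> (rise Å, twist deg) of the 1-start operation
ARCHITECTURES: dict[tuple[int, int], tuple[float, float]] = {
    (11, 3): (11.1, -32.5),
    (12, 3): (10.2, -29.9),
    (13, 3): (9.4, -27.7),
    (14, 3): (8.7, -25.8),
    (15, 4): (10.8, -23.8),
    (16, 4): (10.2, -22.4),
}

# refinement-stage helical parameters (twist deg, rise Å)
REFINEMENT_PARAMS: dict[int, tuple[float, float]] = {
    13: (-27.67, 9.46),
    14: (-25.71, 8.81),
}

MONOMER_REPEAT = 41.0   # Å
DIMER_REPEAT = 82.0     # Å

# pseudo-atom rendering constants (fixed; chosen so that alpha/beta and the
# decorator are distinguishable at the 15 Å low-pass used for references)
SIGMA_MONOMER = 8.0     # Å
SIGMA_DECORATOR = 10.0  # Å
AMP_ALPHA = 1.0
AMP_BETA = 0.9
AMP_DECORATOR = 1.5
RADIUS_CENTROID = 110.0   # Å, monomer centroid cylinder
RADIUS_DECORATOR = 150.0  # Å


@dataclasses.dataclass(frozen=True)
class HelicalParams:
    """Architecture descriptor: N protofilaments, S starts, 1-start rise/twist."""

    pf_number: int
    start_number: int
    rise: float            # Å per 1-start subunit step
    twist: float           # deg per 1-start subunit step (negative: left-handed)
    monomer_repeat: float = MONOMER_REPEAT
    dimer_repeat: float = DIMER_REPEAT
    refine_twist: float | None = None
    refine_rise: float | None = None

    @property
    def has_seam(self) -> bool:
        return self.start_number % 2 == 1

    @property
    def label(self) -> str:
        return f"{self.pf_number}-{self.start_number}"


def helical_table(pf_number: int, start_number: int) -> HelicalParams:
    """Tabulated helical constants for one of the six common architectures."""
    key = (int(pf_number), int(start_number))
    if key not in ARCHITECTURES:
        supported = ", ".join(f"{n}-{s}" for n, s in sorted(ARCHITECTURES))
        raise ValueError(
            f"unsupported architecture {key[0]}-{key[1]}; supported: {supported}")
    rise, twist = ARCHITECTURES[key]
    ref = REFINEMENT_PARAMS.get(key[0])
    return HelicalParams(key[0], key[1], rise, twist,
                         refine_twist=None if ref is None else ref[0],
                         refine_rise=None if ref is None else ref[1])


def all_architectures() -> list[HelicalParams]:
    return [helical_table(n, s) for n, s in sorted(ARCHITECTURES)]


@dataclasses.dataclass
class LatticeModel:
    """Pseudo-atomic MT lattice: monomer and decorator point sites (Å)."""

    positions: np.ndarray       # (M, 3) monomer centroids
    identity: np.ndarray        # (M,) 0 = alpha, 1 = beta
    pf_index: np.ndarray        # (M,)
    layer: np.ndarray           # (M,) axial monomer layer within PF
    decorators: np.ndarray      # (D, 3)
    params: HelicalParams
    length: float               # Å
    seam_pf: int | None = 0
    radius: float = RADIUS_CENTROID

    @property
    def n_monomers(self) -> int:
        return len(self.positions)


def build_lattice(params: HelicalParams, length: float, decorated: bool = True,
                  seam_pf: int | None = None, register_shift: int = 0,
                  radius: float = RADIUS_CENTROID,
                  decorator_radius: float = RADIUS_DECORATOR) -> LatticeModel:
    """Place monomer and decorator sites for one architecture.

    ``register_shift`` in {0, 1} translates the identity/decoration pattern
    by one monomer repeat (41 Å).  ``seam_pf`` relabels which lateral
    interface carries the seam by applying the helical (twist, rise)
    symmetry operation that many times; it is an error for even-start
    (truly helical, seamless) architectures.
    """
    if length < params.dimer_repeat:
        raise ValueError("lattice length must cover at least one dimer repeat")
    if register_shift not in (0, 1):
        raise ValueError("register_shift must be 0 or 1")
    if not params.has_seam:
        if seam_pf is not None:
            raise ValueError(
                f"architecture {params.label} has even start number and no seam")
    elif seam_pf is None:
        seam_pf = 0

    N = params.pf_number
    n_layers = int(math.floor(length / params.monomer_repeat + 1e-9))
    p = np.repeat(np.arange(N), n_layers)
    l = np.tile(np.arange(n_layers), N)
    phi = np.deg2rad(p * params.twist)
    z = p * params.rise + l * params.monomer_repeat
    pos = np.column_stack([radius * np.cos(phi), radius * np.sin(phi), z])
    identity = ((l + register_shift) % 2).astype(int)

    if decorated:
        n_dimers = n_layers // 2
        md = np.arange(n_dimers)
        pd_ = np.repeat(np.arange(N), n_dimers)
        mdd = np.tile(md, N)
        zd = (pd_ * params.rise
              + (2 * mdd + 1.5 + register_shift) * params.monomer_repeat)
        phid = np.deg2rad(pd_ * params.twist)
        dec = np.column_stack([decorator_radius * np.cos(phid),
                               decorator_radius * np.sin(phid), zd])
        keep = zd <= z.max() + params.monomer_repeat
        dec = dec[keep]
    else:
        dec = np.zeros((0, 3))

    zc = z.mean()
    pos[:, 2] -= zc
    if len(dec):
        dec[:, 2] -= zc

    lat = LatticeModel(pos, identity, p, l, dec, params, length,
                       seam_pf=seam_pf, radius=radius)
    if seam_pf:
        lat = transform_lattice(lat, seam_pf * params.twist,
                                seam_pf * params.rise)
        lat.seam_pf = seam_pf
    return lat


def transform_lattice(lattice: LatticeModel, rot_deg: float,
                      rise_shift: float) -> LatticeModel:
    """Rigid helical-frame transform: rotate about z, translate along z."""
    c, s = np.cos(np.deg2rad(rot_deg)), np.sin(np.deg2rad(rot_deg))
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    t = np.array([0.0, 0.0, rise_shift])
    return dataclasses.replace(
        lattice,
        positions=lattice.positions @ R.T + t,
        decorators=(lattice.decorators @ R.T + t
                    if len(lattice.decorators) else lattice.decorators),
    )


def count_heterotypic_interfaces(lattice: LatticeModel) -> int:
    """Count lateral PF interfaces whose contacts are majority alpha-beta."""
    N = lattice.params.pf_number
    count = 0
    for p in range(N):
        q = (p + 1) % N
        ip = np.where(lattice.pf_index == p)[0]
        iq = np.where(lattice.pf_index == q)[0]
        zp = lattice.positions[ip, 2]
        zq = lattice.positions[iq, 2]
        hetero = same = 0
        for a, za in zip(ip, zp):
            j = np.argmin(np.abs(zq - za))
            if abs(zq[j] - za) > lattice.params.monomer_repeat / 2:
                continue
            if lattice.identity[a] == lattice.identity[iq[j]]:
                same += 1
            else:
                hetero += 1
        if hetero > same:
            count += 1
    return count


@dataclasses.dataclass
class ReferenceVolume:
    """3D density grid (z, y, x) with voxel size in Å and provenance."""

    data: np.ndarray
    voxel_size: float
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")


@dataclasses.dataclass
class ProjectionImage:
    """2D pixel grid (y, x) with the Euler angles/shifts that generated it."""

    data: np.ndarray
    pixel_size: float
    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0
    origin_x: float = 0.0
    origin_y: float = 0.0


def _rz(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """ZYZ intrinsic rotation A = Rz(psi) @ Ry(tilt) @ Rz(rot)."""
    return _rz(psi) @ _ry(tilt) @ _rz(rot)


def axis_in_plane(tilt: float, psi: float) -> np.ndarray:
    """In-plane unit image of the helical (z) axis for given view angles.

    The reference z axis maps to A @ (0,0,1) = (sin t cos psi, sin t sin psi,
    cos t); an axial translation by d Å therefore shifts the projection by
    d * sin(t) * (cos psi, sin psi) in the image plane.
    """
    t, p = np.deg2rad(tilt), np.deg2rad(psi)
    return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p)])


def _lowpass_mask(shape, spacing, cutoff):
    """Boolean rFFT-layout mask keeping |freq| <= 1/cutoff (sharp)."""
    freqs = [np.fft.fftfreq(n, d=spacing) for n in shape[:-1]]
    freqs.append(np.fft.rfftfreq(shape[-1], d=spacing))
    grids = np.meshgrid(*freqs, indexing="ij", sparse=True)
    f2 = sum(g ** 2 for g in grids)
    return f2 <= (1.0 / cutoff) ** 2


def lowpass_filter(data: np.ndarray, spacing: float, cutoff: float) -> np.ndarray:
    """Sharp Fourier low-pass at ``cutoff`` Å (2D or 3D)."""
    ft = np.fft.rfftn(data)
    ft *= _lowpass_mask(data.shape, spacing, cutoff)
    return np.fft.irfftn(ft, s=data.shape, axes=range(data.ndim))


def _paint_gaussians(grid: np.ndarray, centers_vox: np.ndarray,
                     sigma_vox: float, amplitudes: np.ndarray) -> None:
    """Accumulate isotropic Gaussians into a 2D or 3D grid, in place.

    2D painting is vectorised over sites (the hot path of the analytic
    projector); 3D volumes are painted site by site.
    """
    ndim = grid.ndim
    r = int(np.ceil(4.0 * sigma_vox))
    shape = grid.shape
    if ndim == 2 and len(centers_vox):
        c = np.asarray(centers_vox, dtype=float)
        a = np.asarray(amplitudes, dtype=float)
        base = np.floor(c).astype(int)                      # (M, 2)
        offs = np.arange(-r, r + 2)                         # patch axis
        iy = base[:, 0, None] + offs[None, :]               # (M, P)
        ix = base[:, 1, None] + offs[None, :]
        gy = np.exp(-(iy - c[:, 0, None]) ** 2 / (2 * sigma_vox ** 2))
        gx = np.exp(-(ix - c[:, 1, None]) ** 2 / (2 * sigma_vox ** 2))
        patch = a[:, None, None] * gy[:, :, None] * gx[:, None, :]
        okr = (iy >= 0) & (iy < shape[0])
        okc = (ix >= 0) & (ix < shape[1])
        ok = okr[:, :, None] & okc[:, None, :]
        np.add.at(grid,
                  (np.broadcast_to(iy[:, :, None], ok.shape)[ok].clip(0),
                   np.broadcast_to(ix[:, None, :], ok.shape)[ok].clip(0)),
                  patch[ok])
        return
    for c, a in zip(centers_vox, amplitudes):
        lo = [max(0, int(np.floor(c[d] - r))) for d in range(ndim)]
        hi = [min(shape[d], int(np.ceil(c[d] + r)) + 1) for d in range(ndim)]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        axes = [np.arange(l, h) - c[d] for d, (l, h) in enumerate(zip(lo, hi))]
        grids = np.meshgrid(*axes, indexing="ij", sparse=True)
        d2 = sum(g ** 2 for g in grids)
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        grid[sl] += a * np.exp(-d2 / (2.0 * sigma_vox ** 2))


def synthesize_volume(lattice: LatticeModel, voxel_size: float,
                      lowpass: float = 15.0, mode: str = "full",
                      box_px: int | None = None) -> ReferenceVolume:
    """Render the lattice as a Gaussian pseudo-atom density volume.

    ``mode='decorator_only'`` renders only decorator blobs (the references
    used for seam/register classification).  The grid Nyquist must support
    the low-pass cutoff (2 * voxel_size <= lowpass).
    """
    if mode not in ("full", "decorator_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if 2.0 * voxel_size > lowpass:
        raise ValueError(
            f"voxel size {voxel_size} Å violates Nyquist for {lowpass} Å low-pass")
    if box_px is None:
        box_px = int(np.ceil(420.0 / voxel_size))
    grid = np.zeros((box_px, box_px, box_px))
    c = box_px // 2

    def vox(points):
        # (x, y, z) Å -> (z, y, x) voxel indices
        return points[:, ::-1] / voxel_size + c

    if mode == "full" and lattice.n_monomers:
        amps = np.where(lattice.identity == 0, AMP_ALPHA, AMP_BETA)
        _paint_gaussians(grid, vox(lattice.positions),
                         SIGMA_MONOMER / voxel_size, amps)
    if len(lattice.decorators):
        _paint_gaussians(grid, vox(lattice.decorators),
                         SIGMA_DECORATOR / voxel_size,
                         np.full(len(lattice.decorators), AMP_DECORATOR))
    grid = lowpass_filter(grid, voxel_size, lowpass)
    prov = {"architecture": lattice.params.label, "mode": mode,
            "seam_pf": lattice.seam_pf, "lowpass": lowpass}
    return ReferenceVolume(grid, voxel_size, prov)


def seam_offset_range(pf_number: int) -> list[int]:
    """The N consecutive integer seam offsets centred on 0 (e.g. -6..+6)."""
    n = int(pf_number)
    return list(range(-(n // 2), n - (n // 2)))


def enumerate_seam_references(base: LatticeModel, params: HelicalParams):
    """Enumerate the 2N seam/register reference lattices for odd-start MTs.

    Returns an ordered list of ``(k, register, LatticeModel)``: register 0
    block first, then register 1, k ascending within each block.  Reference
    (k, reg) is the base rotated by k * twist about the helical axis and
    translated by k * rise + reg * 41 Å along it.
    """
    if not params.has_seam:
        raise ValueError(
            f"architecture {params.label} is truly helical (even start): "
            "no seam references to enumerate")
    out = []
    for reg in (0, 1):
        for k in seam_offset_range(params.pf_number):
            lat = transform_lattice(
                base, k * params.twist,
                k * params.rise + reg * params.monomer_repeat)
            out.append((k, reg, lat))
    return out


def project(volume: ReferenceVolume, rot: float, tilt: float, psi: float,
            origin_x: float = 0.0, origin_y: float = 0.0) -> ProjectionImage:
    """Real-space projection: ZYZ rotation, sum along z, in-plane shift.

    Linear in the volume; ``project(v, ..., +s, 0)`` equals the unshifted
    projection translated by s Å along image x.
    """
    for a in (rot, tilt, psi, origin_x, origin_y):
        if not np.isfinite(a):
            raise ValueError("angles and origins must be finite")
    A = euler_matrix(rot, tilt, psi)
    n = volume.data.shape[0]
    c = np.array([n // 2] * 3, dtype=float)
    F = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
    M = F @ A.T @ F  # output (z,y,x) -> input (z,y,x)
    offset = c - M @ c
    rotated = ndimage.affine_transform(volume.data, M, offset=offset, order=1,
                                       mode="constant", cval=0.0)
    img = rotated.sum(axis=0) * volume.voxel_size
    if origin_x or origin_y:
        img = ndimage.shift(
            img, (origin_y / volume.voxel_size, origin_x / volume.voxel_size),
            order=1, mode="constant", cval=0.0)
    return ProjectionImage(img, volume.voxel_size, rot, tilt, psi,
                           origin_x, origin_y)


def project_lattice(lattice: LatticeModel, rot: float, tilt: float, psi: float,
                    origin_x: float = 0.0, origin_y: float = 0.0,
                    pixel_size: float = 5.56, box_px: int = 108,
                    lowpass: float = 15.0, mode: str = "full") -> ProjectionImage:
    """Analytic projection of the Gaussian pseudo-atom model.

    The projection of an isotropic 3D Gaussian is a 2D Gaussian of the same
    sigma scaled by sigma * sqrt(2 pi), so the lattice can be rendered
    directly in 2D after rotating the sites — exact (no gridding /
    interpolation) and much faster than projecting a voxel grid.
    """
    if mode not in ("full", "decorator_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if 2.0 * pixel_size > lowpass:
        raise ValueError(
            f"pixel size {pixel_size} Å violates Nyquist for {lowpass} Å low-pass")
    A = euler_matrix(rot, tilt, psi)
    img = np.zeros((box_px, box_px))
    c = box_px // 2
    shift = np.array([origin_x, origin_y])

    def paint(points, sigma, amps):
        q = points @ A.T
        xy = q[:, :2] + shift
        yx = xy[:, ::-1] / pixel_size + c
        scale = sigma * np.sqrt(2.0 * np.pi)
        _paint_gaussians(img, yx, sigma / pixel_size,
                         np.asarray(amps, dtype=float) * scale)

    if mode == "full" and lattice.n_monomers:
        paint(lattice.positions, SIGMA_MONOMER,
              np.where(lattice.identity == 0, AMP_ALPHA, AMP_BETA))
    if len(lattice.decorators):
        paint(lattice.decorators, SIGMA_DECORATOR,
              np.full(len(lattice.decorators), AMP_DECORATOR))
    img = lowpass_filter(img, pixel_size, lowpass)
    return ProjectionImage(img, pixel_size, rot, tilt, psi, origin_x, origin_y)


def write_mrc(path, data: np.ndarray, voxel_size: float) -> None:
    """Write a (z, y, x) array (volume or image stack) as an MRC/CCP4 map."""
    data = np.ascontiguousarray(data.transpose(2, 1, 0), dtype=np.float32)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(*data.shape)
    m.grid.array[:] = data
    m.grid.unit_cell = gemmi.UnitCell(*(s * voxel_size for s in data.shape),
                                      90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC/CCP4 map back to a (z, y, x) array and its voxel size."""
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid.array, copy=True).transpose(2, 1, 0)
    voxel = m.grid.unit_cell.a / m.grid.array.shape[0]
    return arr.astype(np.float64), float(voxel)
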