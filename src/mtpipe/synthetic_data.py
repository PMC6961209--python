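"""Synthetic decorated-microtubule particle stacks with ground truth.

Emulates the extraction geometry of filament processing — segments picked
along a tube every 82 Å (the tubulin dimer repeat) in ~600 Å boxes, tilt
prior 90 deg (tubes lie flat in the ice), psi prior from the picking
direction — and the error modes the pipeline exists to repair: blockwise
register mis-translations (±41 / ±82 Å along the axis), blockwise Rot
mis-registrations (multiples of the helical twist), and Gaussian angular
noise.  Every tube has a ground-truth architecture, seam offset k and
alpha/beta register drawn from the configured mix.

Because the lattice repeats every 82 Å along a protofilament, adjacent
segments of an ideal tube project to the same image up to the supertwist
Rot drift; each segment image is therefore the analytic projection of the
tube's reference lattice at its true parameters plus white Gaussian noise.
No CTF, background or filament curvature is simulated.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import helical_geometry as hg
from .star_io import ParticleTable, make_table, normalize_angle

__all__ = ["SimConfig", "SyntheticDataset", "simulate_dataset", "inject_errors"]


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the simulator.

    noise_sigma is the white-noise standard deviation in units of the mean
    clean-image RMS (so noise_sigma = 1 gives a per-segment SNR of ~1).
    Error rates are per-segment marginal probabilities, realised as
    contiguous runs (mean run length ``error_run_length``) rather than
    i.i.d. flips, matching how mis-alignments appear blockwise along real
    filaments.
    """

    pixel_size: float = 5.56          # Å/px (1.39 Å/px at 4x binning)
    box_size: float = 600.0           # Å
    spacing: float = 82.0             # Å between adjacent segment centres
    n_tubes: int = 20
    segments_per_tube: tuple[int, int] = (8, 12)   # uniform inclusive range
    arch_mix: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"13-3": 0.5, "14-3": 0.5})
    occupancy: float = 1.0            # decorator site occupancy
    noise_sigma: float = 1.0
    rot_slope: float | None = None    # deg/segment; None -> per-architecture
    rot_slope_supertwisted: float = 0.25   # used for non-13-PF architectures
    p_register_jump: float = 0.1
    p_rot_misregister: float = 0.1
    error_run_length: float = 3.0
    register_jump_choices: tuple = (-82.0, -41.0, 41.0, 82.0)
    rot_misregister_choices: tuple = (-2, -1, 1, 2)
    sigma_rot: float = 2.0            # deg, observed-vs-truth noise
    sigma_psi: float = 1.0
    sigma_tilt: float = 1.5
    lattice_length_factor: float = 1.5  # reference length / box edge
    render_lowpass: float | None = None  # Å; None -> Nyquist (2 * pixel_size)
    seed: int = 0

    def __post_init__(self):
        for p in (self.occupancy, self.p_register_jump, self.p_rot_misregister):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.spacing > self.box_size:
            raise ValueError("segment spacing must not exceed the box size")
        total = sum(self.arch_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError("arch_mix probabilities must sum to 1")

    @property
    def box_px(self) -> int:
        return int(round(self.box_size / self.pixel_size))

    @property
    def lattice_length(self) -> float:
        return self.lattice_length_factor * self.box_size

    def slope_for(self, params: hg.HelicalParams) -> float:
        if self.rot_slope is not None:
            return self.rot_slope
        return 0.0 if params.pf_number == 13 else self.rot_slope_supertwisted


@dataclasses.dataclass
class SyntheticDataset:
    """Particle stack + observed metadata + ground truth."""

    stack: np.ndarray           # (n, box, box) noisy images
    clean_stack: np.ndarray     # (n, box, box) noiseless images
    table: ParticleTable        # observed parameters (priors + errors)
    truth: pd.DataFrame         # per-segment ground truth and error flags
    config: SimConfig
    tube_lattices: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if len(self.stack) != len(self.table):
            raise ValueError("stack length must equal table length")


def _markov_runs(n: int, rate: float, run_length: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Boolean error mask with marginal P(True) = rate, geometric runs."""
    if rate <= 0.0 or n == 0:
        return np.zeros(n, dtype=bool)
    if rate >= 1.0:
        return np.ones(n, dtype=bool)
    leave = 1.0 / run_length
    enter = rate * leave / (1.0 - rate)
    enter = min(enter, 1.0)
    mask = np.zeros(n, dtype=bool)
    state = rng.random() < rate
    for i in range(n):
        mask[i] = state
        state = (rng.random() >= leave) if state else (rng.random() < enter)
    return mask


def inject_errors(truth: pd.DataFrame, config: SimConfig,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Derive the observed parameter columns from ground truth.

    Adds contiguous-run register jumps (axial ±41/±82 Å folded into the
    origins), contiguous-run Rot mis-registrations (±1 or ±2 times the
    helical twist), and per-segment Gaussian angular noise.  Flags are
    recorded in ``err_register`` / ``err_rot`` columns.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    out = truth.copy()
    n = len(out)
    out["obs_rot"] = out["true_rot"].astype(float)
    out["obs_tilt"] = out["true_tilt"].astype(float)
    out["obs_psi"] = out["true_psi"].astype(float)
    out["obs_origin_x"] = out["true_origin_x"].astype(float)
    out["obs_origin_y"] = out["true_origin_y"].astype(float)
    out["err_register"] = False
    out["err_rot"] = False
    out["register_jump"] = 0.0

    for tube in out["tube_id"].unique():
        sel = out.index[out["tube_id"] == tube]
        m = len(sel)
        twist = float(out.loc[sel[0], "twist"])
        u = hg.axis_in_plane(90.0, float(out.loc[sel[0], "psi_prior"]))

        mask = _markov_runs(m, config.p_register_jump,
                            config.error_run_length, rng)
        if mask.any():
            # one jump amount per contiguous run
            jumps = np.zeros(m)
            for i in range(m):
                if mask[i]:
                    if i == 0 or not mask[i - 1]:
                        run_amount = float(
                            rng.choice(config.register_jump_choices))
                    jumps[i] = run_amount
            out.loc[sel, "register_jump"] = jumps
            out.loc[sel, "obs_origin_x"] += jumps * u[0]
            out.loc[sel, "obs_origin_y"] += jumps * u[1]
            out.loc[sel, "err_register"] = mask

        mask_r = _markov_runs(m, config.p_rot_misregister,
                              config.error_run_length, rng)
        if mask_r.any():
            offs = np.zeros(m)
            for i in range(m):
                if mask_r[i]:
                    if i == 0 or not mask_r[i - 1]:
                        run_off = float(
                            rng.choice(config.rot_misregister_choices)) * twist
                    offs[i] = run_off
            out.loc[sel, "obs_rot"] = normalize_angle(
                out.loc[sel, "obs_rot"].to_numpy() + offs)
            out.loc[sel, "err_rot"] = mask_r

    if config.sigma_rot > 0:
        out["obs_rot"] = normalize_angle(
            out["obs_rot"].to_numpy() + rng.normal(0, config.sigma_rot, n))
    if config.sigma_tilt > 0:
        out["obs_tilt"] += rng.normal(0, config.sigma_tilt, n)
    if config.sigma_psi > 0:
        out["obs_psi"] = normalize_angle(
            out["obs_psi"].to_numpy() + rng.normal(0, config.sigma_psi, n))
    return out


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Simulate a decorated-MT segment dataset; reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    arch_labels = sorted(config.arch_mix)
    arch_probs = np.array([config.arch_mix[a] for a in arch_labels])

    rows = []
    tube_lattices: dict[int, hg.LatticeModel] = {}
    lowpass = (2.0 * config.pixel_size if config.render_lowpass is None
               else config.render_lowpass)

    for tube in range(1, config.n_tubes + 1):
        label = rng.choice(arch_labels, p=arch_probs)
        n_pf, n_start = (int(x) for x in label.split("-"))
        params = hg.helical_table(n_pf, n_start)
        if params.has_seam:
            k_true = int(rng.choice(hg.seam_offset_range(n_pf)))
            reg_true = int(rng.integers(0, 2))
        else:
            k_true, reg_true = 0, 0

        base = hg.build_lattice(params, config.lattice_length, decorated=True,
                                seam_pf=0 if params.has_seam else None)
        if config.occupancy < 1.0 and len(base.decorators):
            keep = rng.random(len(base.decorators)) < config.occupancy
            base = dataclasses.replace(base, decorators=base.decorators[keep])
        lat = hg.transform_lattice(
            base, k_true * params.twist,
            k_true * params.rise + reg_true * params.monomer_repeat)
        tube_lattices[tube] = lat

        nseg = int(rng.integers(config.segments_per_tube[0],
                                config.segments_per_tube[1] + 1))
        psi_tube = float(rng.uniform(-180.0, 180.0))
        rot0 = float(rng.uniform(-180.0, 180.0))
        slope = config.slope_for(params)
        ax, ay = rng.uniform(-5.0, 5.0, 2)
        bx, by = rng.uniform(-0.2, 0.2, 2)
        x0, y0 = rng.uniform(200.0, 3800.0, 2)
        d = np.array([np.cos(np.deg2rad(psi_tube)),
                      np.sin(np.deg2rad(psi_tube))])
        for i in range(nseg):
            rows.append({
                "tube_id": tube, "segment_index": i, "arch": label,
                "pf_number": n_pf, "start_number": n_start,
                "twist": params.twist, "rise": params.rise,
                "k_true": k_true, "reg_true": reg_true,
                "coord_x": x0 + i * config.spacing / config.pixel_size * d[0],
                "coord_y": y0 + i * config.spacing / config.pixel_size * d[1],
                "true_rot": float(normalize_angle(rot0 + slope * i)),
                "true_tilt": 90.0,
                "true_psi": psi_tube,
                "true_origin_x": ax + bx * i,
                "true_origin_y": ay + by * i,
                "tilt_prior": 90.0, "psi_prior": psi_tube,
            })
    truth = pd.DataFrame(rows)
    truth = inject_errors(truth, config, rng)

    n = len(truth)
    box = config.box_px
    clean = np.empty((n, box, box))
    for i, row in enumerate(truth.itertuples(index=False)):
        img = hg.project_lattice(
            tube_lattices[row.tube_id], row.true_rot, row.true_tilt,
            row.true_psi, row.true_origin_x, row.true_origin_y,
            pixel_size=config.pixel_size, box_px=box, lowpass=lowpass)
        clean[i] = img.data
    rms = np.sqrt(np.mean(clean ** 2, axis=(1, 2)))
    scale = 1.0 / max(rms.mean(), 1e-12)
    clean *= scale
    stack = clean + config.noise_sigma * rng.standard_normal(clean.shape)

    table = make_table(n, pixel_size=config.pixel_size, box_size=box)
    df = table.df
    for col_t, col_o in [("coord_x", "coord_x"), ("coord_y", "coord_y")]:
        df[col_t] = truth[col_o].to_numpy()
    df["tube_id"] = truth["tube_id"].to_numpy()
    df["segment_index"] = truth["segment_index"].to_numpy()
    df["rot"] = truth["obs_rot"].to_numpy()
    df["tilt"] = truth["obs_tilt"].to_numpy()
    df["psi"] = truth["obs_psi"].to_numpy()
    df["tilt_prior"] = truth["tilt_prior"].to_numpy()
    df["psi_prior"] = truth["psi_prior"].to_numpy()
    df["origin_x"] = truth["obs_origin_x"].to_numpy()
    df["origin_y"] = truth["obs_origin_y"].to_numpy()
    df["image_ref"] = np.arange(n)

    return SyntheticDataset(stack, clean, table, truth, config, tube_lattices)
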