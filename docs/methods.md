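# Methods

## The problem

Microtubules (MTs) polymerised in vitro are heterogeneous filaments: the
number of protofilaments (PFs) varies between 11 and 16, and most common
architectures (those with an odd helical start number) contain a seam — a
single lateral interface where alpha-tubulin contacts beta-tubulin,
breaking helical symmetry. Because alpha- and beta-tubulin are nearly
indistinguishable at the resolutions used for alignment, cryo-EM
refinement of MT segments is degenerate: a segment aligned to the wrong
PF register (a rotation by a multiple of the helical twist, with the
matching axial translation) or to the wrong alpha/beta register (a 41 Å
axial shift, half the 82 Å dimer repeat) still correlates almost as well
as the true alignment. This package implements the bespoke computational
stages that repair those degeneracies on RELION-style per-segment
metadata: supervised PF-number sorting with per-filament class
unification, per-filament Rot-angle and X/Y-shift smoothing, and an
explicit seam/register check with parameter corrections — together with a
synthetic decorated-MT simulator that makes every stage testable without
external data.

## Geometry model

`helical_geometry` encodes six architectures as (rise, twist) of the
1-start lattice operation on monomers:

| N-S  | rise (Å) | twist (deg) |
|------|----------|-------------|
| 11-3 | 11.1     | −32.5       |
| 12-3 | 10.2     | −29.9       |
| 13-3 | 9.4      | −27.7       |
| 14-3 | 8.7      | −25.8       |
| 15-4 | 10.8     | −23.8       |
| 16-4 | 10.2     | −22.4       |

For 13- and 14-PF MTs, refinement-stage constants (−27.67°/9.46 Å and
−25.71°/8.81 Å) are used when converting seam-class consensus into
parameter corrections.

A lattice is built per PF: protofilament p sits at azimuth p·twist and
axial offset p·rise, with monomers every 41 Å (alpha/beta by layer
parity) on a cylinder of centroid radius 110 Å. This construction closes
with an S·41 Å axial mismatch at the wrap interface; for odd S the parity
offset there is odd, producing exactly one heterotypic interface — the
seam — without any special-casing. Decorator sites (one per dimer, at the
inter-dimer position, radius 150 Å) emulate a kinesin-family or
CKK-like fiducial bound every 82 Å. Density is a sum of isotropic
Gaussian pseudo-atoms (sigma 8 Å monomer at amplitude 1.0/0.9 for
alpha/beta, sigma 10 Å decorator at 1.5) sharply low-pass filtered,
15 Å by default. These rendering constants are arbitrary but fixed;
they only need to make references distinguishable at the band limit.

Projections follow the RELION ZYZ convention A = Rz(psi)·Ry(tilt)·Rz(rot).
Two projectors exist: a voxel-grid projector (rotate with trilinear
interpolation, sum along z) for arbitrary volumes, and an analytic
projector that exploits the fact that the projection of an isotropic 3D
Gaussian is a 2D Gaussian of the same sigma — exact and roughly ten times
faster, used by the simulator and the matcher. The two agree to NCC
≈ 0.99 on identical lattices (the residual is grid-interpolation error
near the band edge). Under this convention the helical (z) axis projects
to the in-plane unit vector u = sin(tilt)·(cos psi, sin psi); axial
translations t map to image-plane origin updates t·u. The sign
conventions are not asserted a priori — they are pinned by simulator
round-trip tests (a projection generated at known parameters must be
recovered at those parameters).

## Simulator

`synthetic_data` emulates segment extraction along picked filaments:
boxes of 600 Å (108 px at 5.56 Å/px, i.e. 1.39 Å/px detector pixels at
4× binning) every 82 Å along a tube of random direction, with Tilt prior
90° (tubes lie flat in ice) and Psi prior equal to the picking direction.
Because the lattice repeats every 82 Å along a PF, adjacent segments of
an ideal tube are identical in projection up to the supertwist Rot drift;
each segment image is therefore the analytic projection of the tube's
reference lattice at its true parameters plus white Gaussian noise. Each
tube draws an architecture from the configured mix (default 50/50
13-3/14-3), a seam offset k uniform over the N offsets centred on 0, and
an alpha/beta register bit; the tube's lattice is the base lattice
transformed by (k·twist, k·rise + reg·41 Å).

Noise is calibrated in units of the mean clean-image RMS, so
`noise_sigma = 1` (the default, and the "moderate noise" condition of the
end-to-end tests) gives per-segment SNR ≈ 1 before segment averaging.
True origins follow a per-tube linear trend (intercept ±5 Å, slope
±0.2 Å/segment — picking jitter); the supertwist Rot slope defaults to 0
for 13-PF tubes (straight PFs) and 0.25°/segment otherwise. Error
injection mimics how mis-alignments appear in practice — in contiguous
blocks, not i.i.d.: a two-state Markov chain with stationary marginal
equal to the configured rate (default 0.1) and mean run length 3 selects
segments, each run receiving one axial jump (±41/±82 Å folded into the
origins along u) or one Rot register offset (±1 or ±2 twists). Gaussian
angular noise (sigma 2°/1.5°/1° for Rot/Tilt/Psi) separates the observed
from the true parameters. True Tilt/Psi equal the priors exactly; the
observed-versus-true discrepancy carries all the angular error. Not
simulated: CTF, ice/carbon background, filament curvature, lattice
defects, per-frame motion. Passing tests therefore demonstrate the
correctness of the parameter-repair logic under the stated error model,
not robustness to every pathology of real micrographs.

## Classification (supervised projection matching)

`reference_matching.match` is a desk-scale stand-in for one iteration of
supervised 3D classification: normalized cross-correlation of each
segment against projections of a fixed reference set, with references
never re-estimated from the data. Images and projections are band-limited
at 12 Å (sharp Fourier mask, DC removed) and masked with a 580 Å
circular mask. With `align=True`, Tilt/Psi are held at each segment's
priors (each image is rotated by −Psi to a canonical frame so projections
are shared across segments), Rot is searched globally (1.8° sampling) or
locally, and integer-pixel shifts are searched by FFT cross-correlation
using masked-NCC normalisation: the mask stays fixed in the reference
frame and the image norm is recomputed under the rolled mask via a second
FFT correlation. Without this, candidates at larger shifts are penalised
by mask-edge mismatch and exact self-matches are not recovered. Ties
break deterministically: lower class index, then smaller |shift|, then
grid order. With `align=False` each segment is scored at its current
parameters only, with the identical score definition (so searching can
never lower a score).

PF sorting matches 7-segment averages against the six undecorated
architecture references; each tube then receives its modal class, with
confidence = percentage of segments in the modal class. Seam checking
matches centred refined averages against the 2N decorator-only references
(base rotated k·twist and translated k·rise + reg·41 Å, k centred on 0,
both registers) without alignment.

## Per-tube smoothing

Rot angles from a global search cluster at multiples of the twist (one
cluster per PF register). `cluster_rot_angles` performs single-linkage
clustering on the circle at an 8° tolerance — below the smallest
inter-register spacing (22.4°) — implemented by sorting angles and
cutting gaps larger than the tolerance (equivalent to thresholding the
circular distance matrix). `unify_rot` fits a line (Rot versus segment
index, unwrapped about the dominant cluster's circular mean) to the most
populated cluster and imposes it on every segment; with fewer than two
distinct indices it falls back to the circular mean. The regression
abscissa is segment index (a proxy for axial position at the fixed 82 Å
spacing); regression is unweighted.

`smooth_xy_shifts` detrends the origin sequence by the median step and
groups segments by single-linkage on the detrended residuals at a
20.5 Å threshold (half the smallest 41 Å mis-translation) — clustering
rather than contiguous runs, so clean segments separated by an error
block still count together. The largest cluster wins; ties prefer the
better-centred cluster (picks are roughly centred, mis-translations are
≥ 41 Å), and separate lines for origin_x and origin_y are imposed on all
segments. A tube whose mis-translated register holds the outright
majority settles on that register's line — a constant lattice offset that
the subsequent seam/register check corrects.

QC rejects tubes whose adjacent-segment circular Rot step exceeds
2×|twist| or whose dominant Rot cluster holds under 50% of segments;
both thresholds are configuration keys.

## Seam correction

Per tube, the modal (k, register) seam class (ties: smaller |k|, then
register 0, then smaller k) is converted into Rot += k·twist and an axial
translation t = k·rise + reg·41 Å applied as t·u to the origins. The
correction is a group action, additive in k; applying it and
re-classifying must return the identity class. The convergence check
(classify → unify → correct → re-classify) validates the sign conventions
end to end. One caveat discovered during validation and reflected in the
tests: convergence alone is not diagnostic of seam information — any
systematic density (even tubulin alone) converges by construction,
because the correction rotates the previous argmax onto the identity
class. The informative null for undecorated data is that the first-pass
consensus agrees with the true seam only at chance level (~1/2N).

## Pipeline and problem sizes

`pipeline.process_dataset` chains the stages in order (priors/reset →
segment averages → PF sorting → global Rot search → Rot unification →
local origin re-search → X/Y smoothing → re-centred averages → seam
check/correction/re-check → QC), and `run_pipeline` persists each stage
as a numbered directory of STAR/MRC/TSV artifacts plus a manifest, fully
reproducible from the seed. Re-centring operates on the particle images
themselves (an interpolating shift with origins folded into coordinates),
which is equivalent to re-extraction for translations within the box.

The validation suite runs the full pipeline on 20 tubes of 8–12 segments
(≈200 segments) at the default moderate noise — about one minute on one
CPU — and checks ≥95% architecture recovery and ≥90% seam convergence.
The occupancy-ordering experiment uses one 400-segment tube at decorator
occupancy 0.6 and noise sigma 6 on raw (unaveraged) segments, emulating a
weakly decorated dataset where flank classes are populated; at default
conditions classification is error-free and the occupancy histogram is a
single spike. These sizes were chosen to exercise every stage at
realistic difficulty while keeping the suite fast.

## Known limitations

- The matcher is NCC-based, single-iteration, CTF-free; it stands in for
  a regularised-likelihood classifier and is not a reconstruction engine.
- Tilt/Psi are trusted to their priors during search; datasets with
  strongly out-of-plane tubes would need a Tilt search added to the grid.
- Segment averaging assumes the 82 Å spacing matches the dimer repeat;
  the residual-modulo-repeat shift handles other spacings but is untested
  against real picks.
- Absolute register recovery is per-tube modal: tubes whose error
  fraction exceeds 50% keep a lattice-offset register until the seam
  check, and a wrong PF-number consensus is not revisited downstream.
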