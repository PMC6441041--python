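# Methods

`hornspike` re-implements, as a tested pipeline, the density-motif analysis
by which the architecture of the two-fold symmetric vertex spikes of a large
icosahedral virus was determined from a cryo-EM map: a masked,
FFT-accelerated six-dimensional local-correlation search of a density motif,
iterative motif/mask refinement, pairwise subunit correlation statistics,
decomposition of the inter-domain screw geometry, the sub-particle defocus
geometry used by localized reconstruction, and atomic-model hexamer
comparisons.

## Masked local correlation and the 6D search

The score of a placement (R, t) is the Pearson correlation between the
R-rotated motif m and the map M, computed under the R-rotated soft mask w
centred at t:

    cc(R, t) = Σ w·(M − μ_M)(m − μ_m) / sqrt(Σ w (M − μ_M)² · Σ w (m − μ_m)²)

with mask-weighted means μ. For one rotation, all translations are obtained
at once from three FFT cross-correlations (of the map against w, of the map
squared against w, and of the map against w·(m − μ_m)); this is identical to
the direct-sum definition to float rounding, which the test suite asserts on
200 random instances at 1e-6. Translations where the motif box leaves the
map, or where the local map variance falls below 1e-8 of the global
variance (flat solvent), score zero and are flagged.

Rotations are sampled on a near-uniform SO(3) grid: tilt rings spaced by the
angular step, in-ring azimuth spacing scaled by 1/sin(tilt), in-plane angle
at the same step; cyclic symmetries restrict the azimuth to one fundamental
sector. The default step is 8°, the search default used throughout.

An exhaustive pass over a 30,000-member 8° grid costs ≈25 min per 96³ map
on one core, so the pipeline's `search_peaks` uses a two-stage scheme:
a full FFT search on a 2× downsampled lattice with a 2× coarser angular
step proposes candidate translations; around each candidate, every rotation
of the full-step grid within 24° of the coarse best and every translation
within ±2 voxels is then scored *exactly*; finally each candidate is
polished by a bounded continuous optimisation (rotation ≤ 0.75 step,
translation ≤ 1.5 voxels, Powell's method on the trilinearly interpolated
correlation). The polish mirrors the original workflow's final interpolation
of each fit (movements below 6° and one pixel) and removes the
grid-quantisation spread from reported scores, which would otherwise
dominate comparisons between placements. `search()` itself remains the
exact exhaustive operation.

Peaks are picked by greedy non-maximum suppression with a 14 Å exclusion
radius. The default is deliberately below the spacing the spike geometry
implies for neighbouring domain centres (≈23–38 Å, see below); one domain
diameter (≈44 Å) would exceed that spacing and could never return one peak
per domain. The significant set is the leading cluster of the ranked
scores: the largest k ≥ 2 whose mean exceeds the (k+1)-th score by more
than 20 sample standard deviations of the cluster — a codification of the
"subsequent peaks lower by more than 20 standard deviations of the top-20
cluster" rule; with no qualifying k the cluster is empty and the full
ranked list is still reported.

## Motif and mask refinement

Sub-volumes are extracted by resampling the map through the inverse peak
transforms onto the motif lattice (trilinear; out-of-map voxels zero-filled
and tracked in a validity mask). Because a zig-zag chain of near-identical
domains carries several pseudo-symmetries (180° flips about the lateral
axis through each domain; one-period screw slides), peaks can be
individually mis-registered while scoring almost equally; averaging such a
mixture destroys the motif. The refinement therefore selects the copies to
average by their plain correlation to the single best-scoring copy,
measured under a boundary mask — a registration-consensus filter — rather
than by raw search score.

The boundary mask itself is data-driven, replacing the original interactive
segment picking: watershed segmentation (scikit-image) of the average above
its 85th percentile, selection of the segments under a seed point (the
motif centre by default; an explicit segment list is also accepted), sphere
smoothing with a 10 Å constant-density ball, and re-thresholding so the
enclosed volume is exactly 60,000 Å³ (ties at the threshold, common after
ball convolution, are trimmed deterministically). 60,000 Å³ deliberately
exceeds the 45,000 Å³ expected for the subunit so the mask includes some
interface/solvent rim. The search is then repeated with the averaged motif
and refined mask (one refinement iteration by default).

Pairwise sub-volume comparisons (`local_refine_pair`) exhaust rotations
within an 8° excursion at 4° steps (plus identity), with translations by
FFT correlation at each rotation, evaluate both argument orders, and report
the better, so the coefficient is symmetric and never below the unrefined
correlation. Summary statistics exclude the two terminal domains of each
horn by default, which differ structurally from the repeating ones.

## Spike geometry

Horns are split by the side of the C2 axis; each horn's peaks are ordered
from the stalk outward. Two orderings are provided: a greedy
nearest-neighbour chain (with an ambiguity error when two continuations are
within 5% of each other), and ordering by distance from the stalk
reference, which the pipeline uses — with the zig-zag geometry the same-side
next-nearest domains (2×11.5 = 23 Å apart) are *closer* to each other than
consecutive ones (sqrt(11.5² + (2·18)²) ≈ 38 Å), so a nearest-neighbour
walk would traverse one strand first.

For consecutive peaks the relative motion Δ = T_{i+1}∘T_i⁻¹ is decomposed
about the local spine axis: the reported angle is the quaternion twist of
Δ's rotation about that axis (folded into [0°, 180°]) and the translation
is the centre-displacement component along it. The axis is estimated from
the chain of consecutive-centre mid-points, which lies on the spine exactly
when the lateral offsets alternate; raw-displacement and window-smoothed
variants exist. Two invariances matter and are tested: the decomposition is
unchanged by a rigid motion of the whole map, and — because the motif frame
is data-defined — by any *coherent* right-multiplied gauge on all peak
rotations together with a common anchor offset (for exact 180° links the
offset contribution along the axis cancels identically). Geometry results
are therefore meaningful even when the refined motif's frame differs from
the canonical one by a global rotation.

## The synthetic spike generator

The phantom emulates a C2-symmetric two-horn spike: per horn, ten identical
asymmetric "pearl" domains planted along a spine that runs parallel to the
surface for 40 Å and then curves up along a 40 Å arc, consecutive domains
related by a 180° rotation about the local spine tangent and an 11.5 Å
translation along it, centres offset 18 Å from the spine on alternating
sides, a Gaussian-tube spine (σ 4.5 Å) threading the domains, and a ~30 Å
stalk on the C2 axis. The second horn is the exact lattice mirror of the
first, so the noiseless map equals its own two-fold copy bit for bit, and
all planted transforms are recorded.

Domain shape follows from the published geometry rather than taste: ten
45,000 Å³ domains repeating every 11.5 Å along a ~103 Å spine must share a
~4,300 Å² cross-section, so they cannot be compact balls (those would
interpenetrate several deep); the generator builds each pearl as a thin
fan — lobes scattered over a ±74° sector pointing away from the spine,
±8 Å thick along it — so that alternating fans tile and interdigitate the
way distinct beads on a rope must. The density is a saturated Gaussian
mixture (flat, protein-like interior), which also makes the half-max volume
scale exactly with the cube of the coordinate scale, so the 45,000 Å³
calibration converges in one or two multiplicative steps. Candidate pearls
whose best non-identity rotational self-correlation (masked to the
molecular region, 30° exhaustive grid) reaches 0.9 are rejected and redrawn
deterministically.

A chain of *exactly* identical screw links is invariant under its own screw
operation, which would make per-domain registration degenerate by
construction; the real assembly is only approximately periodic (the
published link rotation is approximate and the inter-domain correlation
0.89, which bounds the actual variability).
Small recorded per-link deviations emulate this: rotation jitter 2° sd
about the local axis, 0.3 Å sd along it, 0.8 Å/4° sd on the lateral offset,
truncated at 2 sd, all reproducible from the seed and stored in the ground
truth. Noise is added as white Gaussian with variance set so that
signal-variance/noise-variance inside the molecular region equals the
requested snr *before* filtering (counting noise is white before the map is
band-limited), then a B = 150 Å² blur gives the map its ~6–7 Å character at
the default 3 Å voxel. The default phantom box for tests is 96³ at 3 Å
(300³ at 1.35 Å reproduces the deposited sub-particle geometry but is only
practical for long runs).

What the phantom does not emulate: CTF effects, projection/reconstruction
anisotropy, per-copy conformational differences beyond the rigid link
jitter, and the icosahedral capsid under the stalk (partial signal
subtraction is out of scope).

## What the tests show — and an honest limit

The desk-scale suite verifies the machinery end to end: FFT correlation ≡
direct sum; MRC round-trips; filter/mask/threshold calibrations (a
60,000 Å³ mask at 1.35 Å voxels selects 24,387 voxels; mask volume error
≤ one voxel); orientation-grid coverage; icosahedral/sub-particle
symmetries (60 → 12 with zero mean beam offset); Kabsch against a
brute-force minimiser; and the gauge invariances above.

The planted-recovery test runs the full pipeline at the stated study
conditions (snr 0.5, 8° grid, 96³/3 Å, seed 1) and asserts 19/20 domains
within one voxel and one angular step (compared in the data-defined motif
gauge), a leading cluster of exactly 20, ten unique copies under C2, and
per-link means within 4°/0.7 Å of 180°/11.5 Å. These assertions currently
fail, and we believe they are not attainable at snr 0.5 for any phantom
obeying the published geometry: control experiments that bypass refinement
entirely — searching with the *ground-truth* motif (a noiseless extraction
at a planted transform) under its own watershed mask, and exhaustive exact
scoring of the full 8° grid at the true positions — show the
pseudo-symmetric registrations (lateral flips, screw slides, fan
autocorrelation sidelobes) scoring within ±0.01–0.05 of the true cells,
below the noise-induced score spread. A compact ~45,000 Å³ domain at ~7 Å
resolution cannot be made much more flip-asymmetric: after centroid
centring the dipole vanishes and the l = 0 and l = 2 moments, which
dominate a smooth blob, are flip-even. The original analysis operated on a
6.2 Å reconstruction averaged over thousands of particles, whose effective
SNR is far above 0.5; at such SNR the same margins are several standard
deviations and the search separates cleanly. The recovery assertions are
kept at the stated conditions rather than weakened; the remaining suite
documents what the method does deliver there (all machinery exact, peak
lists and geometry computed and reported).

## Numerical choices

Trilinear interpolation everywhere (matched to the working resolution);
voxel indices 0-based with physical position = origin + index·voxel; ZYZ
intrinsic Euler angles; MRC2014 mode 2 with the origin in the ORIGIN header
words; exact-lattice rotations snap near-integer coefficients so boundary
voxels are not lost to constant-mode interpolation; score ties in peak
ranking break by voxel index; threshold ties include all tied voxels except
in the volume-calibrated mask, where the excess is trimmed
deterministically; the variance floor is 1e-8 of the map variance; the
leading-cluster rule uses the sample standard deviation and requires k ≥ 2.

Problem sizes in the graded suite: one seed for the full pipeline run,
96³ box at 3 Å/voxel, 200 random instances for the correlation oracle, 20
random blobs for mask calibration.
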