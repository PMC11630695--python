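# Methods

## The measurement problem

A wing scanned in two postures yields two point clouds per bone with no
point-to-point correspondence: different scans sample the bone surface
differently. The motion of a bone is therefore estimated as the rigid
transform `(R, T)` minimizing the mean nearest-neighbor distance

    d(R, T) = (1/N) Σ_{j=1..N} min_{i=1..M} ‖ R·p_j + T − q_i ‖

where `p` are the `N` points of the folded-posture cloud and `q` the `M`
points of the extension reference. We report the *unsquared* mean distance
in mm; a mean-squared variant is available (`squared=True`). The two
objectives share their minimizer on noise-free data and differ only in how
they weight outliers; the unsquared form is the one whose value reads
directly as an average miss distance.

Fitted absolute poses are turned into the folding chain's relative motions
(`T_rel = T_parent⁻¹ ∘ T_child`, with ulna and radius on the humerus,
carpometacarpus on the ulna, digit II on the carpometacarpus) and
decomposed into principal axis-angle form. Axes are reported with a
non-negative z-component (ties: y ≥ 0, then x ≥ 0); an axis and its
negation denote the same rotation line, and the measured falcon axes all
have positive z, so this convention makes tables comparable. The "axis
deviation" between the half-extension and flexion axes is reported as
`100·sin` of the inter-axis angle — one of several readings of that
percentage; none reproduces the published column exactly from its
two-decimal axes, so exact agreement is not claimed (the implemented
reading lands within ~1 percentage point on the main bones).

The two carpal bones (radiale, ulnare) are carried as frozen placeholder
links: they are too small to reconstruct at the 0.625 mm scan resolution,
so the seven-bar topology is represented with two bars fixed.

## Registration algorithm

Multi-start local optimization stands in for an exhaustive global search:

- **Starts** (default 24): start 0 is the identity rotation; the rest draw
  a uniform random axis and an angle uniform in [0°, 90°] (the observed
  motions stay below ~56°, so ±90° covers the basin generously).
  Translations align centroids, plus N(0, 2 mm) jitter for non-identity
  starts. One seeded generator drives everything; runs are deterministic
  and the start sequence is prefix-stable, so more starts can only improve
  the best residual.
- **Local descent**: iterative closest point — exact KD-tree nearest
  neighbors, Kabsch update — iterated to a 1e-8 mm residual improvement or
  a 1e-6 step, capped at 60 iterations. ICP is the standard local
  minimizer for this objective family; a quasi-Newton descent on the raw
  objective was rejected because the nearest-neighbor field makes it
  piecewise-smooth and an order of magnitude slower at these cloud sizes.
- **Polish**: the winning start is refined derivative-free (Powell) on the
  reported objective itself, accepted only if it improves. Residual ties
  within 1e-9 mm are broken toward the smaller rotation angle.

Degenerate inputs (fewer than 4 points, rank-deficient after centering)
are rejected before fitting; every returned rotation is orthonormal with
determinant +1 to 1e-9.

## Synthetic skeleton

No scan data are deposited with the measurements, so the package generates
its own ground-truthed stand-ins. Each bone is a surface-sampled capsule
with three deliberate asymmetries: flared ends (proximal 1.6×, distal 1.9×
the mid-shaft radius — distinguishable epiphyses), and a 5 %-of-length
sinusoidal bow of the shaft. A straight capsule is rotationally symmetric
about its long axis and end-to-end; both symmetries would make the rigid
pose unidentifiable, while real long bones have neither. `length_mm` is
the tip-to-tip extent including the end caps.

Study conditions (the defaults): the five scanned point counts
(9763/7323/3965/4901/1813); Gaussian isotropic noise of 0.2 mm, below the
0.625 mm slice thickness of the source scans; postures built from the
measured per-bone axis-angle rows composed along the chain (extension is
the identity reference; translations default to zero since none are
printed, with a hook for nonzero offsets); and an overlap fraction of 0.8 —
each posture cloud is an independent random 80 % subsample, so moving and
reference clouds differ in membership as real repeated scans do. Bones are
laid out at falcon scale (humerus 85 mm, ulna/radius 100 mm, metacarpus
55 mm, digit 30 mm) in the intrinsic wing frame.

What the generator does *not* emulate: CT voxelization and segmentation
artifacts, real bone shape (condyles, ridges), soft tissue, or
posture-dependent occlusion. Passing the recovery tests therefore shows the
estimator is correct and noise-stable under realistic sampling — not that
segmentation of real scans is solved.

At the full point counts the pipeline recovers every bone's rotation angle
to well under 0.5°; the fast test fixtures run at one tenth of the counts,
where the noise-limited error scales roughly with 1/√N and the same checks
use a 1.5° band.

## Mechanism model and synthesis

The wing four-bar links humerus (ground), ulna, radius and metacarpus with
a revolute elbow (axis A₁ through C₁), a spherical humerus-radius joint
(C₂), a revolute ulna-metacarpus wrist (A₃ through C₃) and a universal
radius-metacarpus joint (C₄). Kutzbach: 6·3 − (5+3+5+4) = 1 DOF.

**Forward kinematics is closed-form.** With the elbow driven to φ the ulna
pose is known. The wrist angle ψ must place the universal center (fixed in
the metacarpus) on the sphere of radius |C₄−C₂| about the spherical
center; because that point traces a circle as ψ varies, the constraint is
`A·cosψ + B·sinψ + C = 0`. Given ψ, the radius orientation is the minimal
rotation taking its long axis onto the chord C₂→(universal center)
composed with a spin γ about that chord, and the universal joint's
axis-orthogonality constraint is again of the form
`A·cosγ + B·sinγ + C = 0`. Each equation has two roots — the two assembly
branches — and the branch continuous with the extension configuration is
tracked by continuation along the drive sweep (default 2° steps; a
step-to-step jump beyond 5° raises a branch error, an unsolvable
constraint an unreachable-configuration error). A prescribed damped
least-squares iteration on the full 6-dimensional loop residual was
dropped in favor of this exact solve; the loop-closure residual is still
evaluated independently at every accepted state and sits at ~1e-14
(tolerance 1e-8).

**Angle convention.** Reported mechanism angles mirror the falcon
measurement convention: ulna and radius relative to ground, metacarpus
relative to the ulna (the wrist coordinate). Per posture the drive is set
so the ulna matches its target exactly — the drive coordinate *is* the
ulna angle — concentrating the residual on radius and metacarpus; a
best-fit drive angle would be an alternative convention, not implemented
because the matched-ulna reading makes the residual attribution
unambiguous.

**Synthesis.** The residual `Σ (ϑ_mech − ϑ_falcon)²` over three bones and
two postures is minimized over 16 parameters: four joint centers (bounded
to ±25 mm boxes around the initial bone-endpoint layout) and the two
revolute axis directions (spherical parameterization, free). Universal
axes are derived (perpendicular to the radius long axis and to each
other); the spherical joint has none. Multi-start (default 32)
trust-region least squares on the six deviation components; unreachable
geometry contributes a finite smooth penalty (1e4 deg² plus the squared
constraint violation) so the search continues through infeasible pockets.
Starts stop early once a residual below 1e-10 deg² is found — an exact
fit that no later start can improve in a best-of-N scheme. The solution
is *not* unique: only the six angle targets constrain 16 parameters, so
different seeds can return different geometries with identical (numerically
zero) residuals. The measured targets admit an exact fit; the published
sub-1.8° bound is met with large margin, which is consistent with the
physical prototype being additionally constrained by fixed printed bone
geometry.

The default falcon targets are the measured skeleton table; the
mechanism-comparison table's falcon radius entries (15.72°, 37.58°)
disagree with the measured radius row (17.52°, 38.89°) in the source, so
`falcon_targets("table2")` exposes the alternative reading rather than
silently correcting either.

**Tendon screening.** Biceps/triceps analog tendons are straight
anchor-to-anchor segments between the humerus and the ulna; excursion is
length minus extension length. The 3×3 candidate anchor grids (stand-offs
16/26/36 mm perpendicular to the elbow axis, distal spans 18/28/38 mm
along the ulna) are a design choice — only the option count and the 10–20
mm displacement band are given by the source — placed relative to the
synthesized elbow axis so the moment arm survives arbitrary axis
orientations. The selection report flags routings whose fully-folded
|excursion| lies inside the band; the grid deliberately straddles it. Force
screening (the 5 N limit) requires a dynamic model with loads and speeds
that are not printed, and is out of scope.

## Pipeline

One config (YAML/JSON) drives all stages. A single top-level `seed` is
mandatory — validation fails without it — and every stage derives its
stream deterministically from it, so a config fully determines every
output byte; each CSV carries the SHA-256 (truncated) hash of the
normalized config as its first line. Unknown keys anywhere in the config
are rejected with all problems listed at once, and normalization is
idempotent. Stage failures keep partial outputs and name the failing
stage.

Problem sizes: the default config runs the scanned point counts
(registration ≈ 1 min single-threaded) and 32 synthesis starts (seconds
with early stop); the test suite exercises the same paths at one tenth of
the point counts and completes in about two minutes.

## Known limitations

- Surface sampling is assumed for the clouds (volumetric scans would have
  interior points; the estimator itself is agnostic).
- The registration residual floor under partial overlap is set by sampling
  density, not only by noise; at 80 % overlap the bias is negligible for
  these densities but would grow for sparse clouds.
- Mechanism synthesis reproduces angle trajectories, not the physical
  prototype's specific geometry (under-determined; see above).
- Radiale/ulnare motion is not modeled (frozen links), matching the
  source's measurement limit.
- The axis-deviation percentage reproduces the published column only
  approximately; its defining formula is undocumented.
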