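# Methods

This note documents the model, the parameter choices that matter, what
the synthetic data does and does not emulate, and the numerical
decisions taken where the design was genuinely open.

## Problem statement

A single dental arch is an ordered sequence of 12–16 teeth, each a 3-D
point cloud in mm. The malocclusion state `X_start` and the corrected
state `X_end` of each tooth are related by a proper rigid transform
`X_end[i] = R_i X_start[i] + t_i`. The task is to predict `(R_i, t_i)`
per tooth from the malocclusion arch alone. Rotations are carried as
unit quaternions `(w, x, y, z)` with canonical sign `w ≥ 0`, which
avoids gimbal lock and removes the double-cover ambiguity from
serialized output. All transforms are expressed in the arch-local frame;
a global scan-to-world transform, if present, is case metadata only.

## Rigid core

Per-tooth transforms are fitted by SVD (Kabsch) alignment of
corresponded clouds: with centered covariance `S = X_cᵀ Y_c = U Σ Vᵀ`,
the rotation is `R = V M Uᵀ`, `M = diag(1, 1, det(V Uᵀ))` — the
reflection correction is the only choice that guarantees `det R = +1` —
and `t = ȳ − R x̄`. The alignment is exact (≤ 1e-8) on noise-free rigid
pairs of ≥ 3 non-collinear points; near-collinear inputs are rejected
(the in-line rotation is unobservable). Rotation sampling uses the
Rodrigues closed form `R = I cosθ + (1 − cosθ) n nᵀ + sinθ [n]×`.
Orthonormality tolerances: 1e-8 internally, 1e-6 on user input.

## Augmentation

**Interpolated intermediates.** Given a fitted pair transform, K
intermediate states are placed at fractions `u_k = k/(K+1)` (endpoints
excluded — the start and end cases already exist): rotation by SLERP
along the shortest geodesic, displacement scaled linearly. This makes
the intermediate at `u` carry exactly rotation angle `u·θ` and
translation `u·t`, which is the property tests assert. `K = 3` by
default (CLI-exposed); larger K multiplies the dataset without adding
information. Pairs whose per-tooth point counts disagree are first
resampled to a common count by farthest-point sampling, which is
rigid-invariant, so exactly-rigid pairs stay row-corresponded; emitted
intermediate cases carry the remaining transform to the corrected state
and are directly trainable.

**Bounded random perturbations.** Translation components are sampled
uniformly inside [−10, 10] mm and the rotation angle uniformly inside
[−10°, 10°] about one uniformly chosen coordinate axis — sampling
inside the box means the physiological limits hold with probability 1,
no clamping. A `per_axis` option composes three bounded axis rotations
instead; the composed angle may then exceed the per-axis bound (by at
most √3×), which the CLI logs. Uniform is used for the angle as well as
the translation; a taper that lowers extreme-case probability would be a
plausible alternative but is not assumed. Rotations pivot about the
tooth (or arch) centroid so the translation bound is exactly the bound
on tooth displacement.

## Synthetic arch generator

The generator replaces private clinical scans. Crowns are
superellipsoids with type-specific semi-axes and exponents (incisors
blade-like, cuspids pointed, molars boxy); this buys analytic landmarks
(surface extreme points: equatorial for Mesial/Distal/Lip/Tongue, 45°
meridians for molar corners) and exact local frames for free. Teeth sit
on the parabola `y = 25 − 0.055 x²` (occlusal +z, arch opening toward
−y, units mm) with 0.5 mm arc gaps, mirrored standard type sequence
(2 incisors, 1 cuspid, 2 premolars, 2–3 molars per side; only even
tooth counts in [12, 16] are generated). The malocclusion state applies
the *inverse* of a bounded random perturbation per tooth — per-axis
angles U(−σ_r, σ_r) composed, translations U(−σ_t, σ_t) per axis,
pivoting about the tooth centroid — and stores that perturbation as the
target transform, so ground truth is exact by construction and
recoverable by alignment to machine precision. Default severity is
(5 mm, 5°), half the physiological limits: strong enough that adjacent
teeth can collide, mild enough to stay clinically plausible. At that
severity the do-nothing predictor errs by ≈ 4.8° / 5.1 mm on average,
which is the floor any trained model must beat.

What the generator does **not** emulate: real crown morphology (cusps,
fissures, wear), roots and bone, gingiva, scan noise and holes,
inter-patient anatomical correlation, and two-jaw occlusion. Passing
tests therefore demonstrate the correctness of the pipeline's geometry,
losses, and learning dynamics — not clinical accuracy on real scans.

## Features

Each tooth yields a fixed-shape block regardless of type: an m-point
farthest-point subsample (deterministic: start at the centroid-nearest
point, ties to the lowest index), a 24-float landmark vector (6 slots ×
3 coords + 6 presence bits; absent slots zeroed — incisors use 2 slots,
molars all 6), the frame quaternion (Gram–Schmidt re-orthonormalized,
right-handedness enforced via the cross product), a 10-float OBB
descriptor (centroid, half-range extents, principal-axis quaternion
with a deterministic sign cascade), and a one-hot type code. PCA boxes
are preferred over exact minimum-volume boxes for stability and
reproducibility. The molar landmark name "DistantLip" follows the
annotation sheets this mirrors; "DistalLip" is accepted as an alias.

## Network

Per arch of T teeth: the flat feature vector is linearly embedded
(width 128); sinusoidal multi-frequency encodings (10 bands) of the 18
landmark coordinates (scale 50 mm) and of the frame quaternion are
concatenated and projected back to the model width; two pre-norm
multi-head self-attention blocks (4 heads) mix information across the
tooth sequence — where a tooth must go is mostly determined by its
neighbours; a residual mean-pool broadcast gives every tooth the arch
summary; a shared 128→64→7 head emits 4 quaternion components
(normalized in-graph; the head bias is initialized at the identity
quaternion) and 3 translation components (output scale 10 mm).
Attention operates across teeth only, not within a tooth's points — the
per-tooth geometry is already summarized by the feature block. The
network is permutation-equivariant in the tooth sequence and invariant
to point order within a tooth (FPS is order-invariant).

Everything runs on a small reverse-mode autodiff engine written on
numpy (broadcasted arithmetic, batched matmul, reductions, axis-wise
min with arg-min gradient routing, softmax); the same engine provides
the analytic loss gradients that are checked against central finite
differences.

## Loss

Six weighted terms, λ₁..λ₆ all 1.0 by default (config-overridable):

* `L_d` (collision): for each adjacent arch pair, `x = 1 + P_e/P_c`
  with `P_e` = closest approach + σ and `P_c` = centroid distance;
  `φ(x) = x⁻¹² − 2x⁻⁶` (Lennard-Jones 12-6, the canonical
  repulsive–attractive pair potential), and `L_d = RMS(φ)` ≥ 0.
  Minimizing the RMS drives φ toward 0, i.e. pushes interpenetrating
  neighbours apart. σ = 0.2 mm by default (empirical clearance offset).
  Coincident centroids are ε-guarded (1e-9). Note `φ ∈ [−1, 0)` at any
  finite separation, so `L_d` is small but nonzero even for a perfect
  prediction on an arch — the other five terms are exactly zero there.
* `L_core`: mean squared centroid distance.
* `L_C`: symmetric squared-nearest-neighbour chamfer distance, batch
  mean.
* `L_build`: per tooth `ω_i(γ·mean_p ‖p − C(p, X_t)‖² + α‖m(X_v) −
  m(X_t)‖²)`; the rigid descriptor `m(·)` is the cloud centroid
  (a mean-pairwise-distance statistic would be an alternative; the
  centroid keeps the term quadratic and cheap). γ = α = 1.
* `L_dof`: per pose component `d = |p − g|`: `β d² ω` if `d < 1`, else
  `d − β`; β = 0.5 is the unique value making the two branches agree at
  `d = 1` with unit weights.
* `L_re`: `mean_i ω_i ‖Δt_i‖² + mean_i (1 − |⟨p_r, g_r⟩|)`; the
  absolute value absorbs quaternion sign.

Per-tooth weight vectors ω default to uniform 1 (a config hook exists;
no type-priority scheme is assumed). Adjacency for the collision term is
consecutive arch indices. During training the point-cloud terms operate
on the 32-point FPS subsample of each tooth, keeping a step on a batch
of 8 arches in the tens of milliseconds on one CPU.

## Training protocol

Adam (lr 2e-3) with cosine annealing to 1% of the base rate, batch
size 8, global gradient-norm clip 5, fully seeded. The desk-scale
defaults — 200 cases, 500 epochs, width 128 — are the smallest
configuration that cleanly passes parameter recovery in a few minutes
on one CPU; the clinical-scale protocol (834 cases, 4000 epochs,
checkpoint every 1000) remains reachable through the config. Target
quaternions are sign-flipped onto the predicted hemisphere per batch
before the component-wise loss. Non-finite losses abort with
diagnostics. Under the default conditions the trained network reaches
≈ 1.8° / 1.2 mm on held-out cases versus the ≈ 4.9° / 5.1 mm identity
floor.

## Evaluation

`ME_r = 2·arccos|⟨p, g⟩|` in degrees, `ME_t = ‖Δt‖` in mm, averaged
over teeth then cases. CSA has no published formula; the default
interpretation is `mean_i |⟨p_r, g_r⟩|·exp(−‖Δt_i‖/τ)`, τ = 10 mm —
bounded in [0, 1], equal to 1 iff exact, monotone in both error kinds —
and is pluggable (`csa_fn`); no quantitative claim rests on it. Reports
aggregate CSA per case to mean/min/max and are order-invariant.

## Reproducibility

All randomness flows from explicit seeds; FPS is deterministic; files
are plain text or timestamp-free `.npy` (checkpoints are a JSON manifest
plus one flat parameter array; the feature archive is a directory of
`.npy` arrays with a JSON manifest — zip containers were avoided because
they embed modification times). Re-running any stage, or the whole CLI
pipeline, with identical seeds reproduces byte-identical artifacts.

## Known limitations

Crown geometry is schematic; landmark "prediction" is extraction from
annotations (synthetic teeth always carry them; a learned detector is
out of scope); collision handling is a soft penalty, not contact
resolution; only single-arch cases are modelled; the CSA column is an
interpretation; and reported error levels are specific to the synthetic
conditions — clinical benchmark numbers require the private scan
dataset and are out of scope.
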