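# dentalign

Tooth-position prediction for digital orthodontics: given the per-tooth
3-D point clouds of a single dental arch in a malocclusion state, predict
the rigid correction — a 6-DoF pose (unit quaternion + translation in mm)
per tooth — that moves every crown to its ideal position.

The package implements the full method as a tested library plus a CLI:

* **Physiological data augmentation.** *GAOS* fits each tooth's
  correction transform by SVD (Kabsch) alignment of corresponded
  start/end clouds, converts the rotation to a quaternion, and
  synthesizes intermediate states by SLERP on the rotation and linear
  interpolation of the displacement (fractions k/(K+1), endpoints
  excluded). *PARS* generates bounded random rigid variants: translation
  components uniform in [−10, 10] mm and a Rodrigues rotation about a
  coordinate axis with angle uniform in [−10°, 10°], both limits
  configurable and satisfied by construction.
* **Hierarchical feature extraction.** Per tooth: a farthest-point
  subsample of the crown cloud, per-type anatomical landmarks packed
  into a fixed-width masked vector (incisor/cuspid: Mesial, Distal;
  premolar: + Lip, Tongue; molar: six corner landmarks), the local tooth
  frame as a quaternion, a PCA oriented-bounding-box descriptor, and a
  one-hot type code.
* **F-VAMP pose regression.** Linear embedding → sinusoidal positional /
  orientation encodings → multi-head self-attention across the tooth
  sequence → residual mean-pool aggregation → shared MLP head emitting a
  normalized quaternion and a translation per tooth. Implemented on a
  compact numpy reverse-mode autodiff engine; trained with Adam and a
  cosine-annealed learning rate.
* **Jointly supervised loss.**
  `L = λ₁L_d + λ₂L_core + λ₃L_C + λ₄L_build + λ₅L_dof + λ₆L_re`:
  a Lennard-Jones 12-6 collision term over adjacent tooth pairs
  (φ(x) = x⁻¹² − 2x⁻⁶ at x = 1 + P_e/P_c, RMS-wrapped), centroid
  matching, symmetric chamfer distance, a rigid reconstruction term,
  a smooth-L1 pose-component term (continuous at unit error for
  β = 0.5), and a translation + quaternion-alignment term
  (1 − |⟨p_r, g_r⟩|, invariant to the quaternion double cover).
* **Evaluation.** Mean rotation error ME_r (degrees, geodesic), mean
  translation error ME_t (mm), and a CSA similarity score in [0, 1]
  (an interpretation — no closed form is published — and pluggable).
* **Synthetic arch generator.** Clinical scan datasets are private, so a
  first-class generator produces 12–16-tooth arches of superellipsoid
  crowns on a parabolic curve with analytic landmarks, frames, and exact
  per-tooth ground-truth correction transforms (default severity 5 mm /
  5° per axis, half the physiological movement limits).

## Worked example

```python
import dentalign as d

# 60 synthetic cases with exact ground truth, 8:2 split
cases = [d.generate_arch_case(rng_seed=i, case_id=f"c{i:02d}") for i in range(60)]
train_cases, test_cases = d.split_cases(cases, 0.8, rng_seed=7)

model, log = d.train(train_cases, test_cases, d.TrainConfig(epochs=150, rng_seed=7))
report = d.evaluate(model, test_cases)
baseline = d.identity_baseline(test_cases)
print(f"trained : ME_r {report.me_r:.2f} deg  ME_t {report.me_t:.2f} mm  CSA {report.csa_mean:.3f}")
print(f"identity: ME_r {baseline.me_r:.2f} deg  ME_t {baseline.me_t:.2f} mm")
```

Output:

```
trained : ME_r 4.21 deg  ME_t 3.14 mm  CSA 0.737
identity: ME_r 4.78 deg  ME_t 5.18 mm
```

ME_r / ME_t are the mean per-tooth rotation (degrees) and translation
(mm) errors of the predicted correction transforms against the stored
ground truth; the identity row is the do-nothing floor, equal to the
mean perturbation magnitudes of the generated malocclusions. Longer
training at the default scale (200 cases, 500 epochs) reduces the errors
to about 1.8° / 1.2 mm.

The same pipeline from the shell:

```bash
dentalign synth --n 20 --out cases --seed 7
dentalign pars  --in cases --out aug --max-t 10 --max-r 10 --n-aug 2 --seed 7
dentalign gaos  --start cases_start --end cases_end --out mids -K 3 --seed 7
dentalign train --cases aug --out run --seed 7
dentalign evaluate --model run/ckpt_final --cases cases --out report.json
```

Every stage is seeded and writes a resolved-config snapshot next to its
outputs; identical seeds reproduce byte-identical artifacts.

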