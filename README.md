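# morphfit

Single-image 3D face-shape reconstruction components for clinical
applications — building PCA morphable models from corresponded face
meshes, fitting them to 2D facial landmarks under a scaled orthographic
camera, evaluating the analytic model/loss pieces of deep
reconstruction pipelines, and validating reconstructions against
reference surfaces with Hausdorff-style distance statistics. It is
aimed at researchers who need a tested, reproducible geometric backbone
for face-reconstruction experiments (e.g. facial palsy assessment,
where a cheap single-camera pipeline must be checked against depth
sensors or medical imaging) without patient data: a seeded synthetic
generator stands in for scan corpora, landmark detectors and sensors.

## The model

A morphable model represents face shape as a mean plus a linear
combination of orthonormal principal modes,

```
S(α) = S0 + Σⱼ Bⱼ · sdⱼ · αⱼ
```

where `S0` is the mean shape vector (per-vertex interleaved
`x1,y1,z1,…`), `B` the PCA basis of a corresponded corpus, `sdⱼ` the
per-mode standard deviations and `α` dimensionless coefficients. A
face in an image is related to the model by a weak-perspective camera,

```
SOP(p) = s · (R p)₍₀:₂₎ + s · t
```

and fitting minimizes the landmark reprojection cost

```
E(α, R, t, s) = (1/L) Σᵢ ‖xᵢ − SOP(f0ᵢ + Σⱼ Bᵢⱼ sdⱼ αⱼ)‖² + λ‖α‖²
```

by alternating a POS-with-iteration pose step and a closed-form ridge
shape step (plus a guarded joint Gauss-Newton step; the cost trace is
non-increasing). Validation measures exact point-to-surface distances
after trimmed similarity-ICP registration and reports mean ± SD and
max (directed Hausdorff) in millimetres. See `docs/methods.md` for the
full account.

Also included: an articulated blendshape head model with linear blend
skinning, a dual identity/expression/texture 3DMM,
spherical-harmonics shading (9 basis functions), and the photometric /
landmark / perception / regularization / texture-flattening /
eye-closure / symmetry losses as evaluable scoring functions.

## Worked example

```python
import morphfit as mf

# a seeded synthetic study: truth model, 2 subjects, 1 px landmark
# noise, 1 mm reference-mesh noise
scenario = mf.make_scenario(42, n_subjects=2, m_vertices=300, k_modes=10,
                            landmark_noise_sd=1.0, mesh_noise_sd=1.0)
report = mf.run_experiment(scenario, mf.FitConfig())
for row in report.rows:
    print(row.subject, row.reference, round(row.mean_mm, 3),
          round(row.sd_mm, 3), round(row.max_mm, 3))
print(report.overall)
```

prints

```
1 kinect 0.827 0.656 3.2
1 mri 0.172 0.136 0.637
2 kinect 0.837 0.67 3.514
2 mri 0.218 0.155 0.763
{'kinect': {'mean_mm': 0.832, 'sd_mm': 0.663},
 'mri': {'mean_mm': 0.195, 'sd_mm': 0.146}}
```

Each row is one subject validated against one degraded reference: the
landmark fit recovers each subject's shape to well under a millimetre,
and the residual against the "kinect"-like reference is dominated by
that reference's own ~1 mm sensor noise (the smoother "mri"-like
reference yields correspondingly smaller numbers). The overall row is
the unweighted mean across subjects.

The estimators also compose with scikit-learn:
`MorphableModelPCA().fit(X).transform(X)` maps flattened shapes to
SD-unit coefficients, `LandmarkFitter(model=m).fit(landmarks)` exposes
`coeffs_`, `pose_` and `cost_trace_`, and
`SimilarityRegistration().fit(source, target)` exposes `rotation_`,
`translation_`, `scale_`.

A thin CLI wraps the library:

```
morphfit simulate --seed 7 --subjects 4 --out scenario/
morphfit fit --model scenario/truth_model.npz \
             --landmarks scenario/subject1_landmarks.csv --out fit.json
morphfit validate --recon recon.ply --ref ref.stl --out report.json
morphfit run --config experiment.yaml --out report
```

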