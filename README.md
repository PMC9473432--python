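# aortaview

Optimal 2D projection of 3D aortic centerlines.

Clinicians routinely judge aortic morphology — elongation, kinking,
dissection-related distortion — on a single 2D view of the vessel (the
"aortic view", classically a left-anterior-oblique ~45° projection chosen
by eye). Picking that view subjectively, or restricting it to the three
coordinate planes, loses length and exaggerates or hides curvature, and
makes pre/post-operative or cross-patient comparisons unstable.
`aortaview` computes the view objectively: given the ordered 3D
centerline of the aorta (in mm, as exported by image-reconstruction
software after segmentation and centerline extraction), it searches over
rigid rotations of the point set for the projection plane on which the
vessel is most unfolded, and feeds the resulting 2D curve into
tortuosity-based group statistics.

## Method

The centerline `P` (an *n* × 3 ordered point set) is rotated by the
composed Euler rotation

    E = RotZ(γ) · RotY(β) · RotX(α) · Pᵀ

(counterclockwise-positive about X and Z, clockwise-positive about Y,
applied in that fixed order) and projected onto the YOZ plane of the
rotated frame — the *reference projection plane* (RPP) — by discarding
the rotated x coordinate. Each candidate plane is graded by three
metrics:

- **CL** — projected contour length, `Σ ‖p_{k+1} − p_k‖` (mm). Projection
  can only shorten a polyline, so maximising CL (**MCL**) seeks the plane
  that loses the least length; `D = CL_3D − CL_2D` measures the loss.
- **EA** — enclosed area (mm²) of the implicitly closed projected curve,
  by fan triangulation from the first vertex with absolute triangle
  areas (**MEA** maximises it). EA is *undefined* for straight segments —
  no polygon ever closes.
- **SAR** — sum of absolute residuals `Σ |x_k − x̄|` (mm) of the rotated
  points: the total L1 deviation of the curve from the plane parallel to
  the RPP through its own mean. **mSAR** (minimum SAR) directly scores
  coplanarity and is the recommended criterion.

Because a rotation about X leaves the rotated x coordinate of every point
unchanged, the search space reduces to (β, γ) with α ≡ 0; the optimizer
runs a coarse grid (default 2°) over β ∈ [0, π) × γ ∈ [0, 2π) followed by
Nelder–Mead restarts. Searching (β, γ) is lossless: those two angles
already reach every unoriented projection direction.

On the optimal projection the **aortic tortuosity** AT (arc-chord ratio:
projected contour length over endpoint distance, ≥ 1) separates
dissection from control cohorts; the package includes the two-sample
Mann–Whitney U (= Wilcoxon rank-sum) and Kolmogorov–Smirnov stages used
for that validation, plus synthetic generators for centerlines and
cohorts.

## Worked example

```python
import numpy as np
from aortaview import (AortaTemplateSpec, make_question_mark,
                       evaluate_primary_planes)
from aortaview.model import ProjectionPlaneModel

# synthetic "?"-shaped aorta: 35 mm arch, 180 mm descending limb,
# 4 mm out-of-plane winding, 0.3 mm noise, random 3D orientation
spec = AortaTemplateSpec(out_of_plane_amp=4.0, noise_sd=0.3,
                         embed_angles="random", seed=7)
c = make_question_mark(spec)

for name, m in evaluate_primary_planes(c).items():
    print(name, f"CL={m.cl_2d:.2f} D={m.d:.2f} EA={m.ea:.2f} SAR={m.sar:.2f}")

res = ProjectionPlaneModel(c, criterion="msar").fit(mode="3d")
print(res.summary())
```

prints

```
YOZ CL=242.16 D=108.42 EA=2294.12 SAR=16476.14
XOZ CL=309.88 D=40.69 EA=7290.91 SAR=4451.28
XOY CL=280.44 D=70.13 EA=6040.29 SAR=8119.95
Optimal Projection Plane Results
================================================
centerline:       synthetic-question-mark  (n = 300)
criterion:        msar
search mode:      rotation_3d
------------------------------------------------
alpha, beta, gamma (rad):   0.0000  1.4223  0.9690
CL_3D (mm):             350.58
CL_2D (mm):             324.90
D = CL_3D-CL_2D:         25.68
EA (mm^2):             8872.75
SAR (mm):               610.33
tortuosity:             1.7867
================================================
```

The best primary plane (XOZ, SAR 4451 mm) still leaves the curve heavily
folded; the full rotation search cuts SAR by a factor of ~7 (610 mm) and
recovers 93% of the true 3D length in the projection. For a perfectly
planar centerline the search recovers the embedding plane to SAR below
1e-6 mm.

Cohort stage, with synthetic tortuosity cohorts at the dissection /
control summaries (3.16 ± 0.61 vs 2.92 ± 0.53, n = 69 / 71):

```python
from aortaview import CohortSpec, make_at_cohorts, compare_groups
ad, ctl = make_at_cohorts(CohortSpec(seed=1))
g = compare_groups(ad, ctl)          # MWU z=2.847 p=0.0044
```

The same pipeline is scriptable from the shell:

```sh
aortaview simulate question-mark --out curve.csv
aortaview optimize --input curve.csv --criterion msar --mode 3d \
    --out result.json --proj-out projection.csv
aortaview compare --group-a ad.csv --group-b control.csv --test mwu
```

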