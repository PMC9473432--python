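"""Synthetic centerlines and tortuosity cohorts for testing and simulation.

Three generators emulate the inputs the projection method sees in
practice:

* :func:`make_question_mark` — the thoracic aorta's "?" silhouette: a
  circular arch joined tangent-continuously to a straight descending
  limb, built planar (x = 0), optionally wound out of plane by a
  sinusoidal x-displacement, jittered with isotropic Gaussian noise, and
  embedded at an arbitrary 3D orientation.  Defaults (35 mm arch radius,
  1.1*pi arch span, 180 mm descending limb) give a ~301 mm centerline,
  the length scale of an adult thoracic aorta.
* :func:`make_straight_segment` — a near-straight mid-descending (SVS
  Zone 5 analogue) segment, the degenerate case where enclosed area is
  undefined.
* :func:`make_at_cohorts` — two cohorts of aortic tortuosity values,
  Normal with the dissection/control group means and SDs, truncated at 1
  by resampling (an arc-chord tortuosity cannot be below 1).

All generators are pure functions of their spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .centerline import Centerline3D, RotationAngles
from .exceptions import ValidationError
from .geometry import rotation_matrix

__all__ = [
    "AortaTemplateSpec",
    "CohortSpec",
    "make_question_mark",
    "make_straight_segment",
    "make_at_cohorts",
]


@dataclass(frozen=True)
class AortaTemplateSpec:
    """Parameters of the synthetic "?" aorta template (mm, radians)."""

    arch_radius: float = 35.0
    arch_span: float = 1.1 * np.pi
    descending_length: float = 180.0
    n_points: int = 300
    out_of_plane_amp: float = 0.0
    out_of_plane_cycles: int = 2
    noise_sd: float = 0.0
    embed_angles: RotationAngles | tuple | str = "random"
    seed: int = 0

    def validate(self) -> "AortaTemplateSpec":
        if self.arch_radius <= 0 or self.descending_length < 0:
            raise ValidationError("arch_radius must be > 0, descending_length >= 0")
        if not (0 < self.arch_span <= 2 * np.pi):
            raise ValidationError("arch_span must lie in (0, 2*pi]")
        if self.n_points < 2:
            raise ValidationError("n_points must be at least 2")
        if self.out_of_plane_amp < 0 or self.noise_sd < 0:
            raise ValidationError("amplitudes and noise SD must be non-negative")
        if self.out_of_plane_cycles < 0:
            raise ValidationError("out_of_plane_cycles must be non-negative")
        return self


@dataclass(frozen=True)
class CohortSpec:
    """Two-cohort tortuosity model: Normal(mean, sd) truncated at 1.

    Defaults are the dissection vs control summaries of the 3D-rotation
    projection (AD 3.16 +/- 0.61, n = 24 + 45 = 69; control
    2.92 +/- 0.53, n = 71).
    """

    n_ad: int = 69
    n_control: int = 71
    ad_at_mean: float = 3.16
    ad_at_sd: float = 0.61
    control_at_mean: float = 2.92
    control_at_sd: float = 0.53
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n_ad < 1 or self.n_control < 1:
            raise ValidationError("cohort sizes must be positive")
        if self.ad_at_sd <= 0 or self.control_at_sd <= 0:
            raise ValidationError("cohort SDs must be positive")
        return self


def _resolve_embedding(embed, rng) -> RotationAngles:
    if isinstance(embed, str):
        if embed != "random":
            raise ValidationError(f"embed_angles must be a triple or 'random', got {embed!r}")
        return RotationAngles(*rng.uniform(0.0, 2 * np.pi, 3))
    return RotationAngles(*embed).validate()


def make_question_mark(spec: AortaTemplateSpec = AortaTemplateSpec()) -> Centerline3D:
    """Generate the planar "?" aorta template, wound, jittered, embedded.

    The curve is built in the x = 0 plane: an arch arc of radius
    ``arch_radius`` sweeping ``arch_span`` radians, ending tangent to the
    straight descending limb.  Samples are uniform in arc length.  Zone
    bounds "arch" and "descending" are stored on the result.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    angles = _resolve_embedding(spec.embed_angles, rng)

    R, span, L, n = (
        spec.arch_radius,
        spec.arch_span,
        spec.descending_length,
        spec.n_points,
    )
    arc_len = R * span
    total = arc_len + L
    s = np.linspace(0.0, total, n)
    on_arc = s <= arc_len
    theta = span - s[on_arc] / R  # sweeps span -> 0, clockwise
    y = np.empty(n)
    z = np.empty(n)
    y[on_arc] = R * np.cos(theta)
    z[on_arc] = R * np.sin(theta)
    t = s[~on_arc] - arc_len  # straight limb, tangent (0, -1) at theta = 0
    y[~on_arc] = R
    z[~on_arc] = -t
    x = spec.out_of_plane_amp * np.sin(2 * np.pi * spec.out_of_plane_cycles * s / total)
    pts = np.column_stack([x, y, z])
    if spec.noise_sd > 0:
        pts = pts + rng.normal(0.0, spec.noise_sd, pts.shape)
    pts = pts @ rotation_matrix(angles).T
    k = int(on_arc.sum())
    zones = {"arch": (0, k), "descending": (k, n)} if 0 < k < n else None
    return Centerline3D(pts, label="synthetic-question-mark", zone_bounds=zones)


def make_straight_segment(
    length: float,
    n_points: int = 100,
    noise_sd: float = 0.0,
    embed_angles: RotationAngles | tuple | str = (0.0, 0.0, 0.0),
    seed: int = 0,
) -> Centerline3D:
    """Near-straight segment (SVS Zone 5 analogue), optionally embedded."""
    if not (length > 0):
        raise ValidationError(f"length must be positive, got {length}")
    if n_points < 2:
        raise ValidationError("n_points must be at least 2")
    if noise_sd < 0:
        raise ValidationError("noise SD must be non-negative")
    rng = np.random.default_rng(seed)
    angles = _resolve_embedding(embed_angles, rng)
    t = np.linspace(0.0, length, n_points)
    pts = np.column_stack([np.zeros_like(t), t, np.zeros_like(t)])
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    pts = pts @ rotation_matrix(angles).T
    return Centerline3D(pts, label="synthetic-straight-segment")


def make_at_cohorts(spec: CohortSpec = CohortSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Draw (dissection, control) tortuosity cohorts, truncated at 1."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    def draw(n, mean, sd):
        out = rng.normal(mean, sd, n)
        bad = out <= 1.0
        while np.any(bad):  # resample sub-physiological draws
            out[bad] = rng.normal(mean, sd, int(bad.sum()))
            bad = out <= 1.0
        return out

    ad = draw(spec.n_ad, spec.ad_at_mean, spec.ad_at_sd)
    control = draw(spec.n_control, spec.control_at_mean, spec.control_at_sd)
    return ad, control
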