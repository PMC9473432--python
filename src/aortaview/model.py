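"""Model/Results interface over the projection-plane search.

``ProjectionPlaneModel`` holds a centerline plus criterion choices;
``fit`` runs the requested search mode and returns
``ProjectionPlaneResults`` carrying the optimal angles, the plane
metrics, the optimal 2D projection, tortuosity, and a ``summary()``
table.  This is the high-level entry point; the functional surface lives
in :mod:`aortaview.optimize` and :mod:`aortaview.metrics`.

Example
-------
>>> from aortaview.synthetic import AortaTemplateSpec, make_question_mark
>>> from aortaview.model import ProjectionPlaneModel
>>> c = make_question_mark(AortaTemplateSpec(embed_angles=(0.3, 1.1, 2.0)))
>>> res = ProjectionPlaneModel(c, criterion="msar").fit(mode="3d")
>>> res.metrics.sar < 1e-6
True
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centerline import Centerline3D, Projection2D, RotationAngles
from .exceptions import ValidationError
from .geometry import project_to_rpp, rotate_points
from .metrics import PlaneMetrics, evaluate_plane
from .optimize import (
    CRITERIA,
    OptimizationResult,
    evaluate_primary_planes,
    optimize_3d,
    optimize_ppp,
    optimize_single_axis,
)
from .stats import tortuosity

__all__ = ["ProjectionPlaneModel", "ProjectionPlaneResults"]

_MODES = ("ppp", "axis-x", "axis-y", "axis-z", "3d")


class ProjectionPlaneModel:
    """Optimal-projection-plane model for one aortic centerline.

    Parameters
    ----------
    centerline : Centerline3D
    criterion : {"msar", "mcl", "mea"}
        Plane-quality criterion; mSAR (minimum sum of absolute
        residuals) is the recommended default.
    ea_mode : {"fan_abs", "signed_shoelace"}
        Enclosed-area construction used when reporting EA.
    """

    def __init__(
        self,
        centerline: Centerline3D,
        criterion: str = "msar",
        ea_mode: str = "fan_abs",
    ):
        if criterion not in CRITERIA:
            raise ValidationError(
                f"unknown criterion {criterion!r}; choose from {CRITERIA}"
            )
        self.centerline = centerline
        self.criterion = criterion
        self.ea_mode = ea_mode

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label: str = "",
        columns: tuple[str, str, str] = ("x", "y", "z"),
        **kwargs,
    ) -> "ProjectionPlaneModel":
        """Build from a DataFrame with x/y/z columns (mm)."""
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValidationError(f"dataframe lacks columns {missing}")
        pts = df.loc[:, list(columns)].to_numpy(dtype=float)
        return cls(Centerline3D(pts, label=label), **kwargs)

    def fit(
        self,
        mode: str = "3d",
        grid_deg: float = 2.0,
        refine: bool = True,
    ) -> "ProjectionPlaneResults":
        """Run the plane search and return a results object."""
        if mode not in _MODES:
            raise ValidationError(f"unknown mode {mode!r}; choose from {_MODES}")
        c = self.centerline
        if mode == "ppp":
            opt = optimize_ppp(c, self.criterion, self.ea_mode)
        elif mode.startswith("axis-"):
            opt = optimize_single_axis(
                c, mode[-1], self.criterion, grid_deg, self.ea_mode, refine=refine
            )
        else:
            opt = optimize_3d(
                c, self.criterion, grid_deg=grid_deg, ea_mode=self.ea_mode,
                refine=refine,
            )
        return ProjectionPlaneResults(model=self, optimization=opt)


@dataclass(frozen=True)
class ProjectionPlaneResults:
    """Fitted optimal projection plane for one centerline."""

    model: ProjectionPlaneModel
    optimization: OptimizationResult

    @property
    def angles(self) -> RotationAngles:
        return self.optimization.best_angles

    @property
    def canonical_angles(self) -> RotationAngles:
        return self.optimization.canonical_angles

    @property
    def metrics(self) -> PlaneMetrics:
        return self.optimization.best_metrics

    @property
    def plane_normal(self) -> np.ndarray:
        return self.optimization.plane_normal

    @property
    def projection(self) -> Projection2D:
        """The optimal 2D projected curve, (u, v) in mm."""
        return project_to_rpp(rotate_points(self.model.centerline, self.angles))

    def tortuosity(self) -> float:
        """Arc-chord tortuosity of the optimal projection."""
        return tortuosity(self.projection)

    def primary_planes(self) -> dict[str, PlaneMetrics]:
        """Metrics of the three primary planes, for comparison."""
        return evaluate_primary_planes(self.model.centerline, self.model.ea_mode)

    def to_dict(self) -> dict:
        opt = self.optimization
        out = {
            "label": self.model.centerline.label,
            "criterion": opt.criterion,
            "mode": opt.mode,
            "grid_resolution_rad": opt.grid_resolution,
            "angles_rad": [float(a) for a in opt.best_angles],
            "angles_rad_canonical": [float(a) for a in opt.canonical_angles],
            "plane_normal": [float(v) for v in opt.plane_normal],
        }
        out.update(self.metrics.to_dict())
        try:
            out["tortuosity"] = self.tortuosity()
        except Exception:
            out["tortuosity"] = None
        return out

    def summary(self) -> str:
        """Plain-text summary table in the style of a fitted-model report."""
        m = self.metrics
        a = self.canonical_angles
        ea = "undefined" if m.ea is None else f"{m.ea:12.2f}"
        tort = None
        try:
            tort = self.tortuosity()
        except Exception:
            pass
        lines = [
            "Optimal Projection Plane Results",
            "=" * 48,
            f"centerline:       {self.model.centerline.label or '<unnamed>'}"
            f"  (n = {len(self.model.centerline)})",
            f"criterion:        {self.optimization.criterion}",
            f"search mode:      {self.optimization.mode}",
            "-" * 48,
            f"alpha, beta, gamma (rad):  "
            f"{a.alpha:7.4f} {a.beta:7.4f} {a.gamma:7.4f}",
            f"CL_3D (mm):       {m.cl_3d:12.2f}",
            f"CL_2D (mm):       {m.cl_2d:12.2f}",
            f"D = CL_3D-CL_2D:  {m.d:12.2f}",
            f"EA (mm^2):        {ea}",
            f"SAR (mm):         {m.sar:12.2f}",
        ]
        if tort is not None:
            lines.append(f"tortuosity:       {tort:12.4f}")
        lines.append("=" * 48)
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        """Plot the optimal 2D projection (debug view)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = self.projection
        ax.plot(p.u, p.v, **kwargs)
        ax.set_aspect("equal")
        ax.set_xlabel("u (mm)")
        ax.set_ylabel("v (mm)")
        ax.set_title(
            f"{self.model.centerline.label or 'centerline'} — "
            f"{self.optimization.criterion} optimal projection"
        )
        return ax
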