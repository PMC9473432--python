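"""Projected-curve tortuosity and two-group nonparametric comparison.

Tortuosity here is the arc-chord ratio of the projected centerline:
projected contour length divided by the straight-line distance between
its endpoints (>= 1, dimensionless).  Dissected aortas elongate and
kink, so their tortuosity runs higher than healthy controls; the group
comparison stage quantifies that separation.

Three two-sample tests are provided: the Mann-Whitney U test (normal
approximation with tie and continuity corrections), the two-sample
Kolmogorov-Smirnov test (asymptotic, exact optional for small samples),
and "wilcoxon_rank", the Wilcoxon rank-sum test for independent samples
— which is the same statistic as Mann-Whitney U and is computed as such.
(A signed-rank test is undefined for independent cohorts of unequal
size.)  All p-values are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats as sps

from .centerline import Projection2D
from .exceptions import DegenerateInputError, ValidationError

__all__ = ["GroupComparison", "tortuosity", "compare_groups", "TESTS"]

TESTS = ("mann_whitney_u", "ks_two_sample", "wilcoxon_rank")


def tortuosity(p: Projection2D) -> float:
    """Arc-chord tortuosity of a projected curve (dimensionless, >= 1)."""
    if len(p) < 2:
        raise DegenerateInputError("tortuosity requires at least 2 points")
    chord = float(np.linalg.norm(p.points[-1] - p.points[0]))
    if chord < 1e-12:
        raise DegenerateInputError("tortuosity undefined: coincident endpoints")
    arc = float(np.linalg.norm(np.diff(p.points, axis=0), axis=1).sum())
    return arc / chord


@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-sample test; group a is the reference for Z's sign."""

    test: str
    z_value: float
    p_value: float
    n_a: int
    n_b: int
    summary_a: tuple[float, float]  # (mean, sd)
    summary_b: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "z_value": float(self.z_value),
            "p_value": float(self.p_value),
            "n_a": self.n_a,
            "n_b": self.n_b,
            "summary_a": [float(v) for v in self.summary_a],
            "summary_b": [float(v) for v in self.summary_b],
        }


def _validate_groups(a: np.ndarray, b: np.ndarray):
    if a.ndim != 1 or b.ndim != 1:
        raise ValidationError("group samples must be 1-D sequences")
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs at least 3 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("group values must be finite")


def _mwu_z(a: np.ndarray, b: np.ndarray) -> float:
    """Signed Mann-Whitney Z, tie- and continuity-corrected, a as reference."""
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    diff = u_a - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    return float((diff - cc) / np.sqrt(var))


def compare_groups(
    a,
    b,
    test: str = "mann_whitney_u",
    ks_method: str = "asymp",
) -> GroupComparison:
    """Two-sided two-sample comparison of tortuosity values.

    Parameters
    ----------
    a, b : sequences of float
        The two independent cohorts; ``a`` is the reference group whose
        tendency toward larger values gives Z a positive sign.
    test : {"mann_whitney_u", "ks_two_sample", "wilcoxon_rank"}
    ks_method : {"asymp", "exact"}
        Null distribution for the K-S test; "exact" is practical only
        for small samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _validate_groups(a, b)
    if test not in TESTS:
        raise ValidationError(f"unknown test {test!r}; choose from {TESTS}")
    summ_a = (float(a.mean()), float(a.std(ddof=1)))
    summ_b = (float(b.mean()), float(b.std(ddof=1)))

    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("identical constant samples; p-value is 1", stacklevel=2)
        return GroupComparison(test, 0.0, 1.0, len(a), len(b), summ_a, summ_b)

    if test in ("mann_whitney_u", "wilcoxon_rank"):
        z = _mwu_z(a, b)
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        res = sps.ks_2samp(a, b, method="exact" if ks_method == "exact" else "asymp")
        d = float(res.statistic)
        n1, n2 = len(a), len(b)
        z = d * np.sqrt(n1 * n2 / (n1 + n2))
        if ks_method == "exact":
            p = float(res.pvalue)
        else:
            p = float(special.kolmogorov(z))
    return GroupComparison(test, float(z), min(1.0, p), len(a), len(b), summ_a, summ_b)
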