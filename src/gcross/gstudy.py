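"""G study: variance components of the balanced p x t x r random-effects model.

The two-facet crossed design decomposes an observed score into

    y_ptr = mu + a_p + b_t + c_r + (ab)_pt + (ac)_pr + (bc)_tr + e_ptr

with all effects random, independent, zero-mean.  With one observation per
cell the three-way interaction is confounded with residual error, leaving
seven estimable variance components: person (the object of measurement),
task and rater (the facets), their three two-way interactions, and the
residual.

Estimation is the classical ANOVA / expected-mean-squares (EMS)
method-of-moments: compute the balanced three-way ANOVA mean squares, then
solve the triangular EMS system

    E[MS_e]  = s2_e
    E[MS_pt] = s2_e + n_r * s2_pt
    E[MS_pr] = s2_e + n_t * s2_pr
    E[MS_tr] = s2_e + n_p * s2_tr
    E[MS_p]  = s2_e + n_r * s2_pt + n_t * s2_pr + n_t * n_r * s2_p
    E[MS_t]  = s2_e + n_r * s2_pt + n_p * s2_tr + n_p * n_r * s2_t
    E[MS_r]  = s2_e + n_t * s2_pr + n_p * s2_tr + n_p * n_t * s2_r

Raw solutions can be negative by sampling error; reported components
truncate negatives to zero (the standard G-theory convention) while the raw
estimates are retained for bias studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._round import round_half_up
from .records import RatingCube

__all__ = [
    "COMPONENT_NAMES",
    "MeanSquares",
    "VarianceComponents",
    "EstimabilityError",
    "anova_mean_squares",
    "solve_variance_components",
    "estimate_components",
    "percent_of_total",
]

COMPONENT_NAMES = ("p", "t", "r", "pt", "pr", "tr", "e")

_EFFECTS = ("p", "t", "r", "pt", "pr", "tr", "e")


class EstimabilityError(ValueError):
    """A facet of size one leaves some effects unestimable."""


@dataclass(frozen=True)
class MeanSquares:
    """Balanced three-way ANOVA mean squares and degrees of freedom."""

    ms: dict[str, float]
    df: dict[str, int]
    n_p: int
    n_t: int
    n_r: int
    grand_mean: float

    def total_ss(self) -> float:
        """Sum over effects of df * MS (the total sum of squared deviations)."""
        return float(sum(self.df[k] * self.ms[k] for k in _EFFECTS))


@dataclass(frozen=True)
class VarianceComponents:
    """Estimated variance components of the two-facet crossed design.

    ``raw`` holds the untruncated EMS solutions (may be negative);
    ``sigma2`` the reported, zero-truncated values used in all D studies.
    """

    sigma2: dict[str, float]
    raw: dict[str, float]
    n_p: int
    n_t: int
    n_r: int

    def __post_init__(self) -> None:
        for name in COMPONENT_NAMES:
            if name not in self.sigma2 or name not in self.raw:
                raise ValueError(f"missing component {name!r}")
            if self.sigma2[name] < 0:
                raise ValueError(f"reported component {name!r} is negative")

    @classmethod
    def from_values(
        cls,
        sigma2: dict[str, float],
        n_p: int = 0,
        n_t: int = 0,
        n_r: int = 0,
    ) -> "VarianceComponents":
        """Build directly from known (nonnegative) components, e.g. a published table."""
        vals = {k: float(sigma2.get(k, 0.0)) for k in COMPONENT_NAMES}
        return cls(sigma2=vals, raw=dict(vals), n_p=n_p, n_t=n_t, n_r=n_r)

    def total(self) -> float:
        return float(sum(self.sigma2.values()))


def anova_mean_squares(cube: RatingCube) -> MeanSquares:
    """Balanced three-way ANOVA mean squares via marginal-total machine formulas.

    Requires all three facets of size >= 2 so that every one of the seven
    effects has positive degrees of freedom.
    """
    n_p, n_t, n_r = cube.n_p, cube.n_t, cube.n_r
    small = [
        name
        for name, n in (("person", n_p), ("task", n_t), ("rater", n_r))
        if n < 2
    ]
    if small:
        raise EstimabilityError(
            f"facet(s) {small} have size < 2; interaction and residual effects "
            "involving them are not estimable"
        )

    y = cube.scores
    n_total = n_p * n_t * n_r
    cf = y.sum() ** 2 / n_total  # correction factor

    # Uncorrected sums of squared marginal totals, each over its divisor.
    s_p = (y.sum(axis=(1, 2)) ** 2).sum() / (n_t * n_r)
    s_t = (y.sum(axis=(0, 2)) ** 2).sum() / (n_p * n_r)
    s_r = (y.sum(axis=(0, 1)) ** 2).sum() / (n_p * n_t)
    s_pt = (y.sum(axis=2) ** 2).sum() / n_r
    s_pr = (y.sum(axis=1) ** 2).sum() / n_t
    s_tr = (y.sum(axis=0) ** 2).sum() / n_p
    s_y = (y**2).sum()

    ss = {
        "p": s_p - cf,
        "t": s_t - cf,
        "r": s_r - cf,
        "pt": s_pt - s_p - s_t + cf,
        "pr": s_pr - s_p - s_r + cf,
        "tr": s_tr - s_t - s_r + cf,
        "e": s_y - s_pt - s_pr - s_tr + s_p + s_t + s_r - cf,
    }
    df = {
        "p": n_p - 1,
        "t": n_t - 1,
        "r": n_r - 1,
        "pt": (n_p - 1) * (n_t - 1),
        "pr": (n_p - 1) * (n_r - 1),
        "tr": (n_t - 1) * (n_r - 1),
        "e": (n_p - 1) * (n_t - 1) * (n_r - 1),
    }
    # machine formulas can leave tiny negative SS on constant data
    ms = {k: max(float(ss[k]), 0.0) / df[k] for k in _EFFECTS}
    return MeanSquares(
        ms=ms, df=df, n_p=n_p, n_t=n_t, n_r=n_r, grand_mean=float(y.mean())
    )


def solve_variance_components(ms: MeanSquares) -> VarianceComponents:
    """Solve the EMS system for the seven components (raw), truncating for report.

    The system is triangular: residual first, then the two-way interactions,
    then the main effects by substitution of the *raw* interaction solutions.
    """
    n_p, n_t, n_r = ms.n_p, ms.n_t, ms.n_r
    m = ms.ms
    raw = {}
    raw["e"] = m["e"]
    raw["pt"] = (m["pt"] - m["e"]) / n_r
    raw["pr"] = (m["pr"] - m["e"]) / n_t
    raw["tr"] = (m["tr"] - m["e"]) / n_p
    raw["p"] = (m["p"] - m["pt"] - m["pr"] + m["e"]) / (n_t * n_r)
    raw["t"] = (m["t"] - m["pt"] - m["tr"] + m["e"]) / (n_p * n_r)
    raw["r"] = (m["r"] - m["pr"] - m["tr"] + m["e"]) / (n_p * n_t)
    sigma2 = {k: max(v, 0.0) for k, v in raw.items()}
    return VarianceComponents(sigma2=sigma2, raw=raw, n_p=n_p, n_t=n_t, n_r=n_r)


def estimate_components(cube: RatingCube) -> VarianceComponents:
    """Convenience: ANOVA mean squares then EMS solution in one call."""
    return solve_variance_components(anova_mean_squares(cube))


def percent_of_total(vc: VarianceComponents, ndigits: int = 1) -> dict[str, float]:
    """Each reported component as a percent of the component total.

    Percentages are computed from the unrounded components and rounded
    half-up to ``ndigits`` decimals for presentation.
    """
    total = vc.total()
    if total <= 0:
        raise ValueError("all components are zero; percent decomposition undefined")
    return {
        k: round_half_up(100.0 * vc.sigma2[k] / total, ndigits) for k in COMPONENT_NAMES
    }
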