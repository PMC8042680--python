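"""D study: project G-study variance components onto hypothetical designs.

Given the estimated components, a decision study asks what reliability a
measurement procedure with ``n'_t`` tasks and ``n'_r`` raters (both treated
as random facets, scores averaged over them) would achieve.

Relative error variance (errors affecting rank-order decisions):

    s2_delta = s2_pt/n't + s2_pr/n'r + s2_e/(n't * n'r)

Generalizability coefficient (relative reliability):

    Erho2 = s2_p / (s2_p + s2_delta)

Absolute error variance additionally charges the facet main effects and
their interaction, giving the dependability coefficient Phi for
criterion-referenced decisions; it never exceeds Erho2.

All D-study formulas consume the *reported* (zero-truncated) components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .gstudy import VarianceComponents

__all__ = [
    "DStudyResult",
    "DEFAULT_DESIGNS",
    "UNATTAINABLE",
    "relative_error_variance",
    "absolute_error_variance",
    "g_coefficient",
    "phi_coefficient",
    "min_tasks_for_target",
    "g_table",
]

#: designs reported in the source tables: (n_tasks, n_raters)
DEFAULT_DESIGNS: tuple[tuple[int, int], ...] = ((2, 2), (10, 1), (20, 2))

#: sentinel returned by min_tasks_for_target when no finite number of tasks suffices
UNATTAINABLE = None


@dataclass(frozen=True)
class DStudyResult:
    """Error variances and reliability coefficients for one (n'_t, n'_r) design."""

    n_t_prime: int
    n_r_prime: int
    rel_error_var: float
    abs_error_var: float
    g_coefficient: float
    phi_coefficient: float


def _check_design(n_t_prime: int, n_r_prime: int) -> None:
    if n_t_prime < 1 or n_r_prime < 1:
        raise ValueError("facet sample sizes must be positive integers")


def relative_error_variance(
    vc: VarianceComponents, n_t_prime: int, n_r_prime: int
) -> float:
    """sigma^2_delta: error variance for relative (norm-referenced) decisions."""
    _check_design(n_t_prime, n_r_prime)
    s = vc.sigma2
    return (
        s["pt"] / n_t_prime
        + s["pr"] / n_r_prime
        + s["e"] / (n_t_prime * n_r_prime)
    )


def absolute_error_variance(
    vc: VarianceComponents, n_t_prime: int, n_r_prime: int
) -> float:
    """sigma^2_Delta: error variance for absolute (criterion-referenced) decisions."""
    _check_design(n_t_prime, n_r_prime)
    s = vc.sigma2
    return (
        s["t"] / n_t_prime
        + s["r"] / n_r_prime
        + s["pt"] / n_t_prime
        + s["pr"] / n_r_prime
        + (s["tr"] + s["e"]) / (n_t_prime * n_r_prime)
    )


def g_coefficient(vc: VarianceComponents, n_t_prime: int, n_r_prime: int) -> float:
    """Generalizability coefficient Erho^2 = s2_p / (s2_p + s2_delta)."""
    s2_p = vc.sigma2["p"]
    if s2_p <= 0:
        raise ValueError("person variance is zero: reliability undefined")
    return s2_p / (s2_p + relative_error_variance(vc, n_t_prime, n_r_prime))


def phi_coefficient(vc: VarianceComponents, n_t_prime: int, n_r_prime: int) -> float:
    """Dependability coefficient Phi = s2_p / (s2_p + s2_Delta)."""
    s2_p = vc.sigma2["p"]
    if s2_p <= 0:
        raise ValueError("person variance is zero: dependability undefined")
    return s2_p / (s2_p + absolute_error_variance(vc, n_t_prime, n_r_prime))


def min_tasks_for_target(
    vc: VarianceComponents, n_r_prime: int, target: float
) -> int | None:
    """Smallest number of tasks reaching g_coefficient >= target with n'_r raters.

    As n'_t grows, the coefficient approaches the asymptote
    s2_p / (s2_p + s2_pr/n'_r); when that limit is below the target the
    search returns :data:`UNATTAINABLE` (``None``).
    """
    if not 0.0 < target < 1.0:
        raise ValueError(f"target must be in (0, 1), got {target}")
    s2_p = vc.sigma2["p"]
    if s2_p <= 0:
        raise ValueError("person variance is zero: reliability undefined")
    limit = s2_p / (s2_p + vc.sigma2["pr"] / n_r_prime)
    if limit < target:
        return UNATTAINABLE
    # g is nondecreasing in n'_t; the exact crossing solves a linear inequality.
    # g >= target  <=>  n'_t >= (s2_pt + s2_e/n'_r) / (s2_p*(1-target)/target - s2_pr/n'_r)
    denom = s2_p * (1.0 - target) / target - vc.sigma2["pr"] / n_r_prime
    numer = vc.sigma2["pt"] + vc.sigma2["e"] / n_r_prime
    if numer == 0.0:
        return 1
    if denom <= 0.0:  # limit == target but approached only in the limit
        return UNATTAINABLE
    n_t = max(1, math.ceil(numer / denom - 1e-12))
    # guard against float slop at the boundary
    while g_coefficient(vc, n_t, n_r_prime) < target:
        n_t += 1
    while n_t > 1 and g_coefficient(vc, n_t - 1, n_r_prime) >= target:
        n_t -= 1
    return n_t


def g_table(
    vc: VarianceComponents,
    designs: list[tuple[int, int]] | tuple[tuple[int, int], ...] = DEFAULT_DESIGNS,
) -> list[DStudyResult]:
    """One DStudyResult per (n'_t, n'_r) design, in input order."""
    if not designs:
        raise ValueError("design list is empty")
    out = []
    for n_t, n_r in designs:
        out.append(
            DStudyResult(
                n_t_prime=n_t,
                n_r_prime=n_r,
                rel_error_var=relative_error_variance(vc, n_t, n_r),
                abs_error_var=absolute_error_variance(vc, n_t, n_r),
                g_coefficient=g_coefficient(vc, n_t, n_r),
                phi_coefficient=phi_coefficient(vc, n_t, n_r),
            )
        )
    return out
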