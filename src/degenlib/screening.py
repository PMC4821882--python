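"""Coupon-collector screening statistics for combinatorial libraries.

When T clones are picked at random (with replacement) from a library of n
equiprobable variants, the expected fraction of distinct variants observed
("coverage") is

    exact:   1 - (1 - 1/n)^T
    Poisson: 1 - exp(-T/n)

The Poisson approximation is the default because it is the convention used
in screening practice (picks for 95% coverage = ceil(n * ln 20), e.g. 48
picks for a 4x4 = 16-variant library) and is conservative: it never exceeds
the exact binomial value.  "Coverage" is the expected per-variant inclusion
fraction, not the probability that every variant is seen.  Everything here
is closed form; no simulation, so n = 10^10 costs the same as n = 16.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, exp, log

__all__ = [
    "CoverageReport",
    "expected_coverage",
    "picks_for_coverage",
    "oversampling_factor",
    "coverage_report",
]

_METHODS = ("poisson", "exact")


def _check_method(method: str) -> str:
    m = method.lower()
    if m in ("poisson_approx", "poisson-approx"):
        m = "poisson"
    if m not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    return m


def expected_coverage(n_variants: int, picks: int, method: str = "poisson") -> float:
    """Expected fraction of distinct variants seen after ``picks`` draws."""
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if picks < 0:
        raise ValueError("picks must be >= 0")
    method = _check_method(method)
    if method == "poisson":
        return 1.0 - exp(-picks / n_variants)
    return 1.0 - (1.0 - 1.0 / n_variants) ** picks


def picks_for_coverage(n_variants: int, goal_coverage: float, method: str = "poisson") -> int:
    """Smallest pick count reaching ``goal_coverage`` expected coverage.

    Poisson: ceil(n * ln(1/(1-goal))); exact: ceil(ln(1-goal)/ln(1-1/n)).
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if not 0.0 < goal_coverage < 1.0:
        raise ValueError(f"goal_coverage must be in (0, 1), got {goal_coverage}")
    method = _check_method(method)
    if method == "poisson":
        t = ceil(n_variants * log(1.0 / (1.0 - goal_coverage)))
    elif n_variants == 1:
        return 1
    else:
        t = ceil(log(1.0 - goal_coverage) / log(1.0 - 1.0 / n_variants))
    # guard against ceil landing one step off at float boundaries
    while t > 0 and expected_coverage(n_variants, t - 1, method) >= goal_coverage:
        t -= 1
    while expected_coverage(n_variants, t, method) < goal_coverage:
        t += 1
    return t


def oversampling_factor(picks: int, n_variants: int) -> float:
    """Picks divided by distinct variants; > 3 gives ~95% expected coverage."""
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    return picks / n_variants


@dataclass(frozen=True)
class CoverageReport:
    """Screening statistics for a (combined) library."""

    n_variants: int
    picks: int
    expected_coverage: float
    oversampling: float
    method: str

    def as_dict(self) -> dict:
        return {
            "n_variants": self.n_variants,
            "picks": self.picks,
            "expected_coverage": self.expected_coverage,
            "oversampling": self.oversampling,
            "method": self.method,
        }


def coverage_report(
    n_variants: int,
    picks: int | None = None,
    goal: float | None = None,
    method: str = "poisson",
) -> CoverageReport:
    """Build a :class:`CoverageReport` from either a pick budget or a goal.

    Exactly one of ``picks`` / ``goal`` must be given; with ``goal`` the
    minimal pick count is computed first.
    """
    if (picks is None) == (goal is None):
        raise ValueError("give exactly one of picks or goal")
    method = _check_method(method)
    if picks is None:
        picks = picks_for_coverage(n_variants, goal, method)
    return CoverageReport(
        n_variants=n_variants,
        picks=picks,
        expected_coverage=expected_coverage(n_variants, picks, method),
        oversampling=oversampling_factor(picks, n_variants),
        method=method,
    )
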