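"""Target distributions on the TIR axis and the Kolmogorov-Smirnov distance.

A candidate sub-library is a small multiset of predicted translation
initiation rates (TIRs).  It is scored against a *target* distribution —
uniform over the full accessible TIR range, uniform over a sub-range, or a
truncated Gaussian around a set point — by the one-sample KS distance

    d_KS = sup_x | F_actual(x) - F_target(x) |,

where F_actual is the empirical CDF of the member TIRs (F(x) = H_n / n with
H_n the number of members smaller than x).  Because every supported target
CDF is continuous, the supremum is attained at the sample points and is
computed exactly from the two one-sided gaps there; no grid is involved.
d_KS is used purely as a ranking objective (smaller = closer match), never
as a hypothesis test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = [
    "TargetDistribution",
    "make_target",
    "parse_target_spec",
    "ks_distance",
    "ks_distance_sorted",
]


@dataclass(frozen=True)
class TargetDistribution:
    """A continuous CDF on the TIR axis with support [lo, hi].

    kind is one of ``uniform`` (lo/hi default to the dataset range),
    ``uniform_subrange`` (same CDF, but bounds deliberately inside the
    range) or ``gaussian`` (normal with mean mu and width sigma, truncated
    to [lo, hi] and renormalized).
    """

    kind: str
    lo: float
    hi: float
    mu: float | None = None
    sigma: float | None = None

    def __post_init__(self):
        if self.kind not in ("uniform", "uniform_subrange", "gaussian"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        if not (np.isfinite(self.lo) and np.isfinite(self.hi) and self.lo < self.hi):
            raise ValueError(f"need finite lo < hi, got [{self.lo}, {self.hi}]")
        if self.kind == "gaussian":
            if self.mu is None or self.sigma is None:
                raise ValueError("gaussian target requires mu and sigma")
            if self.sigma <= 0:
                raise ValueError("sigma must be > 0")

    def cdf(self, x):
        """F_target evaluated elementwise; 0 below lo, 1 above hi."""
        x = np.asarray(x, dtype=float)
        if self.kind == "gaussian":
            z = ndtr((x - self.mu) / self.sigma)
            z_lo = ndtr((self.lo - self.mu) / self.sigma)
            z_hi = ndtr((self.hi - self.mu) / self.sigma)
            out = (z - z_lo) / (z_hi - z_lo)
        else:
            out = (x - self.lo) / (self.hi - self.lo)
        return np.clip(out, 0.0, 1.0)


def make_target(
    kind: str,
    dataset_range: tuple[float, float] | None = None,
    lo: float | None = None,
    hi: float | None = None,
    mu: float | None = None,
    sigma: float | None = None,
    as_fractions: bool = False,
    clamp: bool = True,
) -> TargetDistribution:
    """Build a :class:`TargetDistribution`.

    Parameters
    ----------
    kind : {"uniform", "uniform_subrange", "gaussian"}
    dataset_range : (tir_min, tir_max), required when bounds are omitted
        or given as fractions.
    lo, hi : explicit support bounds; for ``uniform`` they default to the
        dataset range ("uniform over the entire TIR space").
    mu, sigma : Gaussian center and width (required for kind="gaussian").
    as_fractions : interpret lo/hi (and mu/sigma) as fractions of the
        dataset range instead of absolute TIRs.
    clamp : clip sub-range bounds into the dataset range (with a warning)
        instead of raising.
    """
    import warnings

    if as_fractions or lo is None or hi is None:
        if dataset_range is None:
            raise ValueError("dataset_range required for default/fractional bounds")
        d_lo, d_hi = float(dataset_range[0]), float(dataset_range[1])
        if not d_lo < d_hi:
            raise ValueError("degenerate dataset range")
    if as_fractions:
        span = d_hi - d_lo
        lo = d_lo + span * float(lo if lo is not None else 0.0)
        hi = d_lo + span * float(hi if hi is not None else 1.0)
        if mu is not None:
            mu = d_lo + span * float(mu)
        if sigma is not None:
            sigma = span * float(sigma)
    else:
        lo = float(lo) if lo is not None else d_lo
        hi = float(hi) if hi is not None else d_hi

    if dataset_range is not None and kind == "uniform_subrange":
        d_lo, d_hi = float(dataset_range[0]), float(dataset_range[1])
        if lo < d_lo or hi > d_hi:
            if not clamp:
                raise ValueError(
                    f"sub-range [{lo}, {hi}] outside dataset range [{d_lo}, {d_hi}]"
                )
            warnings.warn(
                f"sub-range [{lo}, {hi}] clamped into dataset range [{d_lo}, {d_hi}]",
                stacklevel=2,
            )
            lo, hi = max(lo, d_lo), min(hi, d_hi)
    return TargetDistribution(kind=kind, lo=lo, hi=hi, mu=mu, sigma=sigma)


def parse_target_spec(spec: str, dataset_range: tuple[float, float] | None = None):
    """Parse a CLI-style target spec.

    Supported forms: ``uniform`` | ``uniform:lo,hi`` | ``uniform-frac:f_lo,f_hi``
    | ``gaussian:mu,sigma`` | ``gaussian-frac:f_mu,f_sigma``.
    """
    name, _, args = spec.partition(":")
    name = name.strip().lower()
    vals = [float(v) for v in args.split(",")] if args else []
    if name == "uniform" and not vals:
        return make_target("uniform", dataset_range=dataset_range)
    if name == "uniform":
        if len(vals) != 2:
            raise ValueError(f"uniform:lo,hi needs two values, got {spec!r}")
        return make_target(
            "uniform_subrange", dataset_range=dataset_range, lo=vals[0], hi=vals[1]
        )
    if name == "uniform-frac":
        if len(vals) != 2:
            raise ValueError(f"uniform-frac:f_lo,f_hi needs two values, got {spec!r}")
        return make_target(
            "uniform_subrange",
            dataset_range=dataset_range,
            lo=vals[0],
            hi=vals[1],
            as_fractions=True,
        )
    if name in ("gaussian", "gaussian-frac"):
        if len(vals) != 2:
            raise ValueError(f"{name}:mu,sigma needs two values, got {spec!r}")
        return make_target(
            "gaussian",
            dataset_range=dataset_range,
            mu=vals[0],
            sigma=vals[1],
            as_fractions=name.endswith("-frac"),
        )
    raise ValueError(f"unknown target spec {spec!r}")


def ks_distance(tirs, target: TargetDistribution) -> float:
    """Exact one-sample KS distance of a TIR multiset to a continuous target.

    For sorted values x_(1..n), d_KS = max_i max(F_t(x_(i)) - (i-1)/n,
    i/n - F_t(x_(i))).  Ties contribute through multiplicity (step heights
    k/n), matching the H_n/n strictly-smaller-than empirical CDF.
    """
    x = np.sort(np.asarray(tirs, dtype=float))
    if x.size == 0:
        raise ValueError("empty TIR multiset")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite TIR values")
    return float(ks_distance_sorted(x[None, :], target)[0])


def ks_distance_sorted(sorted_tirs: np.ndarray, target: TargetDistribution) -> np.ndarray:
    """Batched exact KS distance; rows of ``sorted_tirs`` must be ascending."""
    n = sorted_tirs.shape[-1]
    ft = target.cdf(sorted_tirs)
    below = np.arange(n, dtype=float) / n        # (i-1)/n
    above = np.arange(1, n + 1, dtype=float) / n  # i/n
    return np.maximum((ft - below).max(axis=-1), (above - ft).max(axis=-1))
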