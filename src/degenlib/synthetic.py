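"""Synthetic sequence→TIR tables emulating an RBS predictor export.

Real predictor output for a fully randomized Shine-Dalgarno window is
heavily skewed: almost all of the 4^L variants sit at the bottom of the
accessible TIR range (e.g. >99.5% below 10% of the range for a typical
N8 window), with a thin exponential tail of strong binders.  This module
reproduces that shape with the simplest mechanism that also makes the
library search non-trivial: an additive per-position pseudo-energy model
with an exponential link,

    TIR(s) = rate_max * exp(beta * (E(s) - E_max)),   E(s) = sum_p w[p, s_p]

A contiguous "hot" sub-window (anti-SD-core-like) carries large per-base
weights; the flanks carry small ones.  Additivity means the TIR multiset
of a degenerate candidate is structured (non-i.i.d.), as for real RBSs.
``beta`` sets the skew (beta -> 0 gives a flat table); ``calibrate_skew``
inverts it by bisection against a quantile specification.  No claim of
biophysical fidelity is made — tables are deterministic fixtures, complete
(4^L rows) and positive by construction.
"""

from __future__ import annotations

import itertools

import numpy as np

from .dataset import TirDataset

__all__ = ["SyntheticTirModel", "generate_table", "calibrate_skew", "CalibrationError"]

#: TIR of the strongest variant, arbitrary units (predictor-like scale).
DEFAULT_RATE_MAX = 150_000.0

#: Weight scale inside / outside the hot sub-window.
HOT_SCALE = 1.0
COLD_SCALE = 0.15


class CalibrationError(RuntimeError):
    """The requested skew cannot be reached with the weight scheme."""


class SyntheticTirModel:
    """Deterministic additive-energy TIR model for one randomized window.

    Parameters
    ----------
    window_length : int, 1..10 for complete tables.
    beta : float > 0, skew parameter of the exponential link.
    seed : int, draws the per-position per-base weights once.
    hot_window : (start, stop) or None; default the central
        min(4, L) positions.
    rate_max : float, TIR of the strongest variant (arbitrary units).
    """

    def __init__(
        self,
        window_length: int,
        beta: float = 2.0,
        seed: int = 0,
        hot_window: tuple[int, int] | None = None,
        rate_max: float = DEFAULT_RATE_MAX,
    ):
        if not 1 <= window_length <= 10:
            raise ValueError("window_length must be in 1..10 for complete tables")
        if beta <= 0:
            raise ValueError("beta must be > 0")
        if rate_max <= 0:
            raise ValueError("rate_max must be > 0")
        self.window_length = window_length
        self.beta = beta
        self.seed = seed
        self.rate_max = rate_max
        if hot_window is None:
            w = min(4, window_length)
            start = (window_length - w) // 2
            hot_window = (start, start + w)
        self.hot_window = hot_window
        rng = np.random.default_rng(seed)
        scale = np.full(window_length, COLD_SCALE)
        scale[hot_window[0]:hot_window[1]] = HOT_SCALE
        self.position_weights = rng.normal(0.0, 1.0, size=(window_length, 4)) * scale[:, None]

    def energies(self) -> np.ndarray:
        """E(s) for all 4^L sequences, indexed base-4 (A=0..T=3)."""
        e = np.zeros(1)
        for p in range(self.window_length):
            e = (e[:, None] + self.position_weights[p][None, :]).ravel()
        return e

    def tirs(self) -> np.ndarray:
        e = self.energies()
        return self.rate_max * np.exp(self.beta * (e - e.max()))

    def table(self, label: str = "") -> TirDataset:
        """Complete 4^L sequence→TIR table."""
        tirs = self.tirs()
        seqs = (
            "".join(b)
            for b in itertools.product("ACGT", repeat=self.window_length)
        )
        return TirDataset(
            entries={s: float(t) for s, t in zip(seqs, tirs)}, label=label
        )

    def fraction_below(self, fraction_of_range: float) -> float:
        """Fraction of variants with TIR below lo + f * (hi - lo)."""
        t = self.tirs()
        lo, hi = t.min(), t.max()
        return float(np.mean(t < lo + fraction_of_range * (hi - lo)))


def generate_table(
    length: int,
    beta: float = 2.0,
    seed: int = 0,
    label: str = "",
    **kwargs,
) -> TirDataset:
    """Complete synthetic sequence→TIR table (see :class:`SyntheticTirModel`)."""
    return SyntheticTirModel(length, beta=beta, seed=seed, **kwargs).table(label=label)


def calibrate_skew(
    length: int,
    target_fraction_below: float = 0.995,
    fraction_of_range: float = 0.10,
    seed: int = 0,
    beta_max: float = 64.0,
    tol: float = 1e-4,
    **kwargs,
) -> float:
    """Smallest beta whose table puts >= ``target_fraction_below`` of the
    variants below ``fraction_of_range`` of the TIR range.

    The fraction is non-decreasing in beta (the threshold energy
    E_max + ln(f)/beta rises with beta), so bisection applies.  Raises
    :class:`CalibrationError` if even ``beta_max`` falls short.
    """
    if not 0.0 < target_fraction_below < 1.0:
        raise ValueError("target_fraction_below must be in (0, 1)")
    if not 0.0 < fraction_of_range < 1.0:
        raise ValueError("fraction_of_range must be in (0, 1)")

    def frac(beta: float) -> float:
        return SyntheticTirModel(length, beta=beta, seed=seed, **kwargs).fraction_below(
            fraction_of_range
        )

    hi = beta_max
    if frac(hi) < target_fraction_below:
        raise CalibrationError(
            f"fraction {frac(hi):.4f} at beta={hi} below target "
            f"{target_fraction_below}; widen the weights or raise beta_max"
        )
    lo = tol
    if frac(lo) >= target_fraction_below:
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if frac(mid) >= target_fraction_below:
            hi = mid
        else:
            lo = mid
    return hi
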