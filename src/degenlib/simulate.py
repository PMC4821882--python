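"""In-silico screening: random picking from per-gene TIR libraries.

Emulates a low-throughput screen: each pick draws one member per gene,
independently and uniformly over that gene's library (a size-4 library
gives each member probability 25%), with replacement — picking clones from
a transformation plate re-samples the library.  The default budget of 252
picks corresponds to three 96-well microtiter plates minus controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PickingExperiment", "simulate_picking", "coverage_summary"]


@dataclass
class PickingExperiment:
    """Result of one seeded picking run.

    ``member_indices`` has shape (n_picks, n_genes): the member drawn per
    gene per pick.  ``tir_pairs`` carries the corresponding TIR tuples.
    Gene order follows ``labels``.
    """

    labels: list[str]
    libraries: dict[str, np.ndarray]
    n_picks: int
    seed: int
    member_indices: np.ndarray
    tir_pairs: np.ndarray

    @property
    def n_distinct_combinations(self) -> int:
        """Distinct member-index tuples among the picks."""
        if self.n_picks == 0:
            return 0
        return len({tuple(row) for row in self.member_indices})


def simulate_picking(
    libraries: dict[str, np.ndarray | list], n_picks: int = 252, seed: int = 0
) -> PickingExperiment:
    """Randomly pick ``n_picks`` per-gene TIR combinations.

    ``libraries`` maps gene label -> member TIR multiset (e.g. the ``tirs``
    of a ranked library, or a full dataset's TIR vector for a fully
    degenerate control).  Deterministic for a given seed; genes are drawn
    in label order as given.
    """
    if not libraries:
        raise ValueError("no libraries given")
    if n_picks < 0:
        raise ValueError("n_picks must be >= 0")
    labels = list(libraries)
    arrays = {}
    for g in labels:
        arr = np.asarray(libraries[g], dtype=float)
        if arr.size == 0:
            raise ValueError(f"library for gene {g!r} is empty")
        arrays[g] = arr
    rng = np.random.default_rng(seed)
    idx = np.empty((n_picks, len(labels)), dtype=np.int64)
    for j, g in enumerate(labels):
        idx[:, j] = rng.integers(0, arrays[g].size, size=n_picks)
    tirs = np.column_stack([arrays[g][idx[:, j]] for j, g in enumerate(labels)]) \
        if n_picks else np.empty((0, len(labels)))
    return PickingExperiment(
        labels=labels,
        libraries=arrays,
        n_picks=n_picks,
        seed=seed,
        member_indices=idx,
        tir_pairs=tirs,
    )


def coverage_summary(
    exp: PickingExperiment,
    bins_per_gene: int = 20,
    ranges: dict[str, tuple[float, float]] | None = None,
    log_scale: bool = False,
):
    """Quantify expression-space coverage of a picking experiment.

    Bins each gene's TIR axis (by default over the library's own min/max;
    pass ``ranges`` to bin over the full dataset's accessible range, which
    is what makes skewed libraries look sparse) and reports the fraction of
    occupied bins in the n-gene grid plus the distinct-combination count.
    """
    if exp.n_picks < 1:
        raise ValueError("experiment has no picks")
    if bins_per_gene < 1:
        raise ValueError("bins_per_gene must be >= 1")
    edges = []
    for g in exp.labels:
        lo, hi = (
            ranges[g] if ranges and g in ranges
            else (float(exp.libraries[g].min()), float(exp.libraries[g].max()))
        )
        if log_scale:
            if lo <= 0:
                raise ValueError(f"log binning needs positive range for {g!r}")
            e = np.geomspace(lo, hi, bins_per_gene + 1)
        else:
            e = np.linspace(lo, hi, bins_per_gene + 1)
        edges.append(e)
    coords = np.empty((exp.n_picks, len(exp.labels)), dtype=np.int64)
    for j, e in enumerate(edges):
        c = np.searchsorted(e, exp.tir_pairs[:, j], side="right") - 1
        coords[:, j] = np.clip(c, 0, bins_per_gene - 1)
    occupied = len({tuple(row) for row in coords})
    return {
        "occupied_bins": occupied,
        "total_bins": bins_per_gene ** len(exp.labels),
        "occupied_fraction": occupied / bins_per_gene ** len(exp.labels),
        "n_distinct_combinations": exp.n_distinct_combinations,
    }
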