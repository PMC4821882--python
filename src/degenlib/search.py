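"""Exhaustive search for globally optimal degenerate libraries.

Every degenerate sequence of the requested window length whose degeneracy
equals the requested library size is scored by the KS distance between its
member TIR multiset and the target distribution; the top-k (ascending
d_KS, ties broken by canonical sequence order) are returned.  Because the
search is exhaustive, the returned libraries are globally optimal for the
given TIR table, target and size.

Implementation notes
--------------------
Candidates are processed grouped by *structure*: an assignment of code
degeneracies (1/2/3/4) to window positions.  Within one structure all
candidates share the member count and the positions of their degenerate
codes, so member-TIR gathering, sorting and KS scoring are single
vectorized numpy operations over the whole group.  Grouping changes only
the evaluation order; ties in d_KS are broken by the canonical sequence
key, so the ranked output is provably independent of evaluation order and
of how structures are split into chunks — the determinism contract the
parallel mode relies on.  Only a bounded top-k per chunk is retained; the
full candidate set (70.2 million for L=8, size 24) is never materialized.

The estimator façade follows scikit-learn conventions: configure a
:class:`LibraryDesigner`, ``fit`` it on a sequence→TIR table, and read the
ranked libraries off fitted attributes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import prod

import numpy as np
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator

from .dataset import MissingMembersError, RankedLibrary, TirDataset
from .iupac import (
    BASE_INDEX,
    CANONICAL_ORDER,
    CANONICAL_RANK,
    CODES_BY_DEGENERACY,
    IUPAC_BASES,
    SizeError,
    _factorizations,
    _nearest_achievable,
    count_degenerate,
    is_achievable,
)
from .targets import TargetDistribution, ks_distance_sorted, parse_target_spec

__all__ = [
    "LibraryDesigner",
    "PathwayDesigner",
    "PathwayDesign",
    "rank_libraries",
    "design_pathway",
]


def _structures(length: int, size: int) -> list[tuple[int, ...]]:
    """All assignments of code degeneracies to positions with product
    ``size``, as tuples over {1,2,3,4}, in deterministic order."""
    out = []
    for k2, k3, k4 in _factorizations(size):
        d = k2 + k3 + k4
        if d > length:
            continue
        positions = range(length)
        for p2 in itertools.combinations(positions, k2):
            rest2 = [p for p in positions if p not in p2]
            for p3 in itertools.combinations(rest2, k3):
                rest3 = [p for p in rest2 if p not in p3]
                for p4 in itertools.combinations(rest3, k4):
                    cls = [1] * length
                    for p in p2:
                        cls[p] = 2
                    for p in p3:
                        cls[p] = 3
                    for p in p4:
                        cls[p] = 4
                    out.append(tuple(cls))
    return out


def _score_structure(
    cls_vec: tuple[int, ...],
    tir_vec: np.ndarray,
    target: TargetDistribution,
    top_k: int,
    skip_incomplete: bool,
):
    """Score every candidate of one structure; return its top-k.

    Returns (top list of (dks, key, sequence, sorted member TIRs),
    n_scored, n_skipped).
    """
    L = len(cls_vec)
    pow4 = 4 ** np.arange(L - 1, -1, -1, dtype=np.int64)
    offs = np.zeros((1, 1), dtype=np.int64)
    radices = []
    rank_maps = []
    for pos, c in enumerate(cls_vec):
        syms = CODES_BY_DEGENERACY[c]
        contrib = np.array(
            [[BASE_INDEX[b] * pow4[pos] for b in IUPAC_BASES[s]] for s in syms],
            dtype=np.int64,
        )
        ncand, nmem = offs.shape
        offs = (offs[:, None, :, None] + contrib[None, :, None, :]).reshape(
            ncand * len(syms), nmem * c
        )
        radices.append(len(syms))
        rank_maps.append(np.array([CANONICAL_RANK[s] for s in syms], dtype=np.int64))

    tirs = tir_vec[offs]
    n_scored = tirs.shape[0]
    n_skipped = 0
    keep = None
    if np.isnan(tirs).any():
        mask = ~np.isnan(tirs).any(axis=1)
        if not skip_incomplete:
            bad = int(np.flatnonzero(~mask)[0])
            seq = _decode(np.array([bad]), radices, rank_maps)[0]
            row = offs[bad]
            absent = row[np.isnan(tir_vec[row])]
            missing = [
                "".join("ACGT"[(int(m) >> (2 * (L - 1 - p))) & 3] for p in range(L))
                for m in absent
            ]
            raise MissingMembersError(seq, missing)
        n_skipped = int((~mask).sum())
        keep = np.flatnonzero(mask)
        tirs = tirs[keep]
        if tirs.shape[0] == 0:
            return [], n_scored - n_skipped, n_skipped
    n_scored -= n_skipped

    tirs.sort(axis=1)
    d = ks_distance_sorted(tirs, target)

    k = min(top_k, d.shape[0])
    thr = np.partition(d, k - 1)[k - 1]
    idx = np.flatnonzero(d <= thr)
    orig = keep[idx] if keep is not None else idx
    seqs = _decode(orig, radices, rank_maps)
    chosen = sorted(
        zip(d[idx].tolist(), seqs, idx.tolist()),
        key=lambda t: (t[0], _canon_key(t[1])),
    )[:k]
    return (
        [(dks, seq, tirs[i].copy()) for dks, seq, i in chosen],
        n_scored,
        n_skipped,
    )


def _canon_key(seq: str) -> tuple[int, ...]:
    """Sort key realizing the canonical symbol order for tie-breaking."""
    return tuple(CANONICAL_RANK[c] for c in seq)


def _decode(indices: np.ndarray, radices, rank_maps) -> list[str]:
    """Candidate index within a structure (mixed radix, position 0 most
    significant) -> degenerate sequence string."""
    rem = indices.copy()
    digits = []
    for r in reversed(radices):
        digits.append(rem % r)
        rem //= r
    digits.reverse()
    cols = [rank_maps[p][digits[p]] for p in range(len(radices))]
    ranks = np.stack(cols, axis=1)
    return ["".join(CANONICAL_ORDER[r] for r in row) for row in ranks]


def _search(
    data: TirDataset,
    size: int,
    target: TargetDistribution,
    top_k: int,
    chunks: int = 1,
    n_jobs: int | None = None,
    skip_incomplete: bool = False,
):
    L = data.window_length
    if not is_achievable(size):
        lo, hi = _nearest_achievable(size)
        raise SizeError(
            f"library size {size} is not achievable (2^a*3^b); "
            f"nearest achievable sizes are {lo} and {hi}"
        )
    if size > 4**L:
        raise SizeError(f"library size {size} exceeds 4^{L} = {4 ** L}")
    n_candidates = count_degenerate(L, size)
    if top_k > n_candidates:
        warnings.warn(
            f"top_k={top_k} exceeds the {n_candidates} candidates; returning all",
            stacklevel=2,
        )
        top_k = n_candidates

    tir_vec = data.tir_vector()
    structs = _structures(L, size)
    chunks = max(1, min(chunks, len(structs)))
    bounds = np.linspace(0, len(structs), chunks + 1).astype(int)
    chunk_lists = [structs[a:b] for a, b in zip(bounds, bounds[1:])]

    def _run_chunk(chunk):
        top, scored, skipped = [], 0, 0
        for cls_vec in chunk:
            t, ns, nk = _score_structure(
                cls_vec, tir_vec, target, top_k, skip_incomplete
            )
            top.extend(t)
            scored += ns
            skipped += nk
        top.sort(key=lambda t: (t[0], _canon_key(t[1])))
        return top[:top_k], scored, skipped

    if n_jobs in (None, 1) or chunks == 1:
        results = [_run_chunk(c) for c in chunk_lists]
    else:
        results = Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(_run_chunk)(c) for c in chunk_lists
        )

    merged = sorted(
        itertools.chain.from_iterable(r[0] for r in results),
        key=lambda t: (t[0], _canon_key(t[1])),
    )[:top_k]
    n_scored = sum(r[1] for r in results)
    n_skipped = sum(r[2] for r in results)
    ranked = [
        RankedLibrary(sequence=seq, tirs=tirs, dks=float(dks), rank=i + 1)
        for i, (dks, seq, tirs) in enumerate(merged)
    ]
    return ranked, n_scored, n_skipped


def _as_dataset(X) -> TirDataset:
    if isinstance(X, TirDataset):
        return X
    if isinstance(X, dict):
        return TirDataset(entries={str(k): float(v) for k, v in X.items()})
    try:
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            seq_col = next(c for c in X.columns if "seq" in str(c).lower())
            tir_col = next(
                c for c in X.columns
                if "tir" in str(c).lower() or "rate" in str(c).lower()
            )
            return TirDataset(
                entries=dict(zip(X[seq_col].astype(str), X[tir_col].astype(float)))
            )
    except StopIteration:
        raise ValueError(
            "DataFrame needs a /seq/i column and a /tir|rate/i column"
        ) from None
    raise TypeError(f"cannot interpret {type(X).__name__} as a TIR dataset")


def _resolve_target(target, data: TirDataset) -> TargetDistribution:
    if isinstance(target, TargetDistribution):
        return target
    if isinstance(target, str):
        return parse_target_spec(target, dataset_range=data.tir_range)
    raise TypeError(f"cannot interpret {type(target).__name__} as a target")


class LibraryDesigner(BaseEstimator):
    """Design a reduced degenerate library matching a target TIR distribution.

    Exhaustively scores all degenerate sequences of the dataset's window
    length with degeneracy exactly ``size`` and keeps the ``top_k`` with the
    smallest KS distance to ``target``.

    Parameters
    ----------
    size : int, default=12
        Library size (degeneracy) per candidate; must be of the form 2^a*3^b.
    target : str or TargetDistribution, default="uniform"
        Target TIR distribution.  Strings use the CLI grammar, e.g.
        ``"uniform"``, ``"uniform:200,900"``, ``"uniform-frac:0.5,1.0"``,
        ``"gaussian:500,120"``.
    top_k : int, default=10
        Number of ranked libraries to retain.
    chunks : int, default=1
        Number of contiguous structure chunks (result-neutral; enables
        parallelism).
    n_jobs : int or None, default=None
        Workers for chunk evaluation (joblib threads); None = serial.
    skip_incomplete : bool, default=False
        Silently drop candidates whose expansion has members absent from
        the dataset instead of raising.

    Attributes
    ----------
    ranked_libraries_ : list of RankedLibrary, ascending d_KS.
    best_sequence_, best_dks_ : the top-1 candidate and its score.
    n_candidates_ : number of candidates scored.
    n_skipped_ : candidates dropped by the skip_incomplete policy.
    target_ : the resolved TargetDistribution.

    Examples
    --------
    >>> data = {"A": 1.0, "C": 2.0, "G": 3.0, "T": 4.0}
    >>> d = LibraryDesigner(size=2, top_k=1).fit(data)
    >>> d.best_sequence_, round(d.best_dks_, 4)
    ('M', 0.3333)
    """

    def __init__(
        self,
        size: int = 12,
        target="uniform",
        top_k: int = 10,
        chunks: int = 1,
        n_jobs: int | None = None,
        skip_incomplete: bool = False,
    ):
        self.size = size
        self.target = target
        self.top_k = top_k
        self.chunks = chunks
        self.n_jobs = n_jobs
        self.skip_incomplete = skip_incomplete

    def fit(self, X, y=None):
        """Run the exhaustive search on a sequence→TIR table.

        X may be a TirDataset, a dict {sequence: tir}, or a DataFrame with
        sequence and TIR columns.  y is ignored (sklearn API).
        """
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        data = _as_dataset(X)
        target = _resolve_target(self.target, data)
        ranked, n_scored, n_skipped = _search(
            data,
            self.size,
            target,
            self.top_k,
            chunks=self.chunks,
            n_jobs=self.n_jobs,
            skip_incomplete=self.skip_incomplete,
        )
        self.dataset_ = data
        self.target_ = target
        self.ranked_libraries_ = ranked
        self.n_candidates_ = n_scored
        self.n_skipped_ = n_skipped
        self.best_sequence_ = ranked[0].sequence
        self.best_dks_ = ranked[0].dks
        return self

    def results_frame(self):
        """Fitted results as a tidy DataFrame (one row per ranked library)."""
        import pandas as pd

        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "ranked_libraries_")
        return pd.DataFrame(
            {
                "rank": [l.rank for l in self.ranked_libraries_],
                "degenerate_sequence": [l.sequence for l in self.ranked_libraries_],
                "degeneracy": [l.degeneracy for l in self.ranked_libraries_],
                "dks": [l.dks for l in self.ranked_libraries_],
                "member_tirs": [l.tirs.tolist() for l in self.ranked_libraries_],
            }
        )


@dataclass
class PathwayDesign:
    """Per-gene ranked libraries plus the combined combinatorial size.

    Genes are designed independently (scoring never couples genes); the
    combined library size is the product of per-gene library sizes, with
    genes held at a fixed explicit RBS contributing a factor of 1.
    """

    per_gene: dict[str, list[RankedLibrary]]
    fixed_genes: dict[str, str] = field(default_factory=dict)

    @property
    def combined_size(self) -> int:
        return prod(
            libs[0].degeneracy for g, libs in self.per_gene.items()
            if g not in self.fixed_genes
        )

    def coverage_report(self, picks=None, goal=None, method="poisson"):
        """Screening statistics for the combined library (see screening)."""
        from .screening import coverage_report

        return coverage_report(self.combined_size, picks=picks, goal=goal, method=method)


class PathwayDesigner(BaseEstimator):
    """Design one reduced library per pathway gene, independently.

    Parameters
    ----------
    sizes : int or dict gene -> int
        Library size per gene (a single int applies to all non-fixed genes).
    targets : target spec, TargetDistribution, or dict gene -> either,
        default="uniform".  Per-gene targets express e.g. the two-round
        heuristic (low sub-range for one gene, high sub-range for another).
    fixed : dict gene -> explicit RBS sequence, default None
        Genes whose RBS is held constant; they are not searched and
        contribute a factor of 1 to the combined size.
    top_k, chunks, n_jobs, skip_incomplete : as in LibraryDesigner.

    Attributes
    ----------
    design_ : PathwayDesign
    per_gene_ : dict gene -> list of RankedLibrary
    combined_size_ : int
    """

    def __init__(
        self,
        sizes=12,
        targets="uniform",
        fixed: dict[str, str] | None = None,
        top_k: int = 10,
        chunks: int = 1,
        n_jobs: int | None = None,
        skip_incomplete: bool = False,
    ):
        self.sizes = sizes
        self.targets = targets
        self.fixed = fixed
        self.top_k = top_k
        self.chunks = chunks
        self.n_jobs = n_jobs
        self.skip_incomplete = skip_incomplete

    def fit(self, X, y=None):
        """X: mapping gene label -> TIR table (TirDataset / dict / DataFrame)."""
        if not isinstance(X, dict) or not X:
            raise TypeError("X must be a non-empty mapping gene -> TIR table")
        fixed = dict(self.fixed or {})
        unknown = set(fixed) - set(X)
        if unknown:
            raise ValueError(f"fixed genes not in datasets: {sorted(unknown)}")
        per_gene: dict[str, list[RankedLibrary]] = {}
        for gene, table in X.items():
            data = _as_dataset(table)
            if gene in fixed:
                from .dataset import tirs_for

                rbs = fixed[gene]
                per_gene[gene] = [
                    RankedLibrary(sequence=rbs, tirs=tirs_for(rbs, data), dks=0.0, rank=1)
                ]
                continue
            size = self.sizes[gene] if isinstance(self.sizes, dict) else self.sizes
            target = (
                self.targets[gene] if isinstance(self.targets, dict) else self.targets
            )
            try:
                designer = LibraryDesigner(
                    size=size,
                    target=target,
                    top_k=self.top_k,
                    chunks=self.chunks,
                    n_jobs=self.n_jobs,
                    skip_incomplete=self.skip_incomplete,
                ).fit(data)
            except Exception as exc:
                raise type(exc)(f"gene {gene!r}: {exc}") from exc
            per_gene[gene] = designer.ranked_libraries_
        self.design_ = PathwayDesign(per_gene=per_gene, fixed_genes=fixed)
        self.per_gene_ = per_gene
        self.combined_size_ = self.design_.combined_size
        return self


def rank_libraries(
    data,
    size: int,
    target="uniform",
    top_k: int = 10,
    chunks: int = 1,
    n_jobs: int | None = None,
    skip_incomplete: bool = False,
) -> list[RankedLibrary]:
    """Functional wrapper over :class:`LibraryDesigner`."""
    return LibraryDesigner(
        size=size,
        target=target,
        top_k=top_k,
        chunks=chunks,
        n_jobs=n_jobs,
        skip_incomplete=skip_incomplete,
    ).fit(data).ranked_libraries_


def design_pathway(
    datasets: dict,
    sizes,
    targets="uniform",
    fixed: dict[str, str] | None = None,
    top_k: int = 10,
    **kwargs,
) -> PathwayDesign:
    """Functional wrapper over :class:`PathwayDesigner`."""
    return (
        PathwayDesigner(sizes=sizes, targets=targets, fixed=fixed, top_k=top_k, **kwargs)
        .fit(datasets)
        .design_
    )
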