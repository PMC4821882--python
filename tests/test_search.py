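import numpy as np
import pytest
from sklearn.base import clone

from brute_oracle import oracle_best_library, oracle_expand, oracle_ks
from degenlib.dataset import MissingMembersError, TirDataset, tirs_for
from degenlib.iupac import SizeError, count_degenerate, enumerate_degenerate
from degenlib.search import (
    LibraryDesigner,
    PathwayDesigner,
    design_pathway,
    rank_libraries,
)
from degenlib.targets import ks_distance, make_target


class TestLibraryDesigner:
    def test_single_candidate_window(self, l1_dataset):
        d = LibraryDesigner(size=4, top_k=1).fit(l1_dataset)
        assert d.best_sequence_ == "N"
        assert d.best_dks_ == pytest.approx(0.25)
        assert d.n_candidates_ == 1

    def test_size_one_picks_probability_median(self, random_dataset):
        """For m=1 the KS score is max(F_t(x), 1-F_t(x)); the winner is the
        explicit sequence closest to the target median in CDF terms."""
        data = random_dataset(2, seed=3)
        t = make_target("uniform", dataset_range=data.tir_range)
        d = LibraryDesigner(size=1, target=t, top_k=1).fit(data)
        scores = {
            s: max(float(t.cdf(v)), 1.0 - float(t.cdf(v)))
            for s, v in data.entries.items()
        }
        assert d.best_dks_ == pytest.approx(min(scores.values()))

    @pytest.mark.parametrize("size", [2, 4, 6])
    def test_matches_bruteforce_argmin(self, random_dataset, size):
        data = random_dataset(2, seed=17)
        t = make_target("uniform", dataset_range=data.tir_range)
        d = LibraryDesigner(size=size, target=t, top_k=3).fit(data)
        seq, dks = oracle_best_library(data.entries, size, lambda x: float(t.cdf(x)))
        assert d.best_sequence_ == seq
        assert d.best_dks_ == pytest.approx(dks, abs=1e-12)
        assert d.n_candidates_ == count_degenerate(2, size)

    def test_reported_scores_match_expand_and_rescore(self, random_dataset):
        """Optimized member lookup is observationally equivalent to
        expand() + tirs_for() + ks_distance()."""
        data = random_dataset(3, seed=23)
        t = make_target("uniform", dataset_range=data.tir_range)
        for lib in LibraryDesigner(size=6, target=t, top_k=10).fit(data).ranked_libraries_:
            direct = tirs_for(lib.sequence, data)
            assert np.array_equal(np.sort(direct), lib.tirs)
            assert ks_distance(direct, t) == pytest.approx(lib.dks, abs=1e-14)

    def test_output_is_ranked_and_tie_broken(self, random_dataset):
        data = random_dataset(2, seed=29)
        libs = rank_libraries(data, size=3, top_k=8)
        assert [l.rank for l in libs] == list(range(1, 9))
        assert all(a.dks <= b.dks for a, b in zip(libs, libs[1:]))

    def test_constant_tir_ties_resolve_canonically(self):
        """All candidates tie at the same d_KS; canonical sequence order
        must decide, giving the lexicographically first size-2 2-mer."""
        data = TirDataset(entries={s: 5.0 for s in
                                   ("AA AC AG AT CA CC CG CT "
                                    "GA GC GG GT TA TC TG TT").split()})
        t = make_target("uniform", lo=0.0, hi=10.0, dataset_range=(0, 10))
        libs = rank_libraries(data, size=2, target=t, top_k=3)
        assert [l.sequence for l in libs] == list(enumerate_degenerate(2, 2))[:3]

    @pytest.mark.parametrize("chunks,n_jobs", [(1, 1), (2, 2), (7, 2)])
    def test_chunking_is_result_neutral(self, random_dataset, chunks, n_jobs):
        data = random_dataset(3, seed=41)
        ref = rank_libraries(data, size=6, top_k=10, chunks=1)
        alt = rank_libraries(data, size=6, top_k=10, chunks=chunks, n_jobs=n_jobs)
        assert [(l.sequence, l.dks) for l in ref] == [(l.sequence, l.dks) for l in alt]

    def test_unachievable_size(self, random_dataset):
        with pytest.raises(SizeError, match="nearest"):
            LibraryDesigner(size=5).fit(random_dataset(2, seed=1))
        with pytest.raises(SizeError, match="exceeds"):
            LibraryDesigner(size=64).fit(random_dataset(2, seed=1))

    def test_top_k_exceeding_candidates_warns_and_returns_all(self, l1_dataset):
        with pytest.warns(UserWarning, match="returning all"):
            d = LibraryDesigner(size=4, top_k=10).fit(l1_dataset)
        assert len(d.ranked_libraries_) == 1

    def test_missing_members_error_by_default(self):
        entries = {s: float(i + 1) for i, s in enumerate(
            "AA AC AG AT CA CC CG CT GA GC GG GT TA TC TG".split())}  # TT absent
        data = TirDataset(entries=entries)
        with pytest.raises(MissingMembersError):
            LibraryDesigner(size=4).fit(data)

    def test_skip_incomplete_drops_and_counts(self):
        entries = {s: float(i + 1) for i, s in enumerate(
            "AA AC AG AT CA CC CG CT GA GC GG GT TA TC TG".split())}
        data = TirDataset(entries=entries)
        d = LibraryDesigner(size=4, skip_incomplete=True, top_k=5).fit(data)
        assert d.n_skipped_ > 0
        assert d.n_candidates_ + d.n_skipped_ == count_degenerate(2, 4)
        assert all("TT" not in oracle_expand(l.sequence) for l in d.ranked_libraries_)

    def test_monotone_sanity_on_rank_tirs(self):
        """On a table whose TIRs are the ranks themselves the optimizer's
        top-1 beats the median candidate (ranking discriminates)."""
        import itertools

        seqs = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
        data = TirDataset(entries={s: float(i + 1) for i, s in enumerate(seqs)})
        t = make_target("uniform", dataset_range=data.tir_range)
        top = rank_libraries(data, size=4, target=t, top_k=1)[0]
        all_scores = sorted(
            oracle_ks([data.entries[m] for m in oracle_expand(seq)],
                      lambda x: float(t.cdf(x)))
            for seq in enumerate_degenerate(3, 4)
        )
        median = all_scores[len(all_scores) // 2]
        assert top.dks <= median

    def test_sklearn_protocol(self, l1_dataset):
        d = LibraryDesigner(size=2, top_k=1)
        params = d.get_params()
        assert params["size"] == 2
        d2 = clone(d).set_params(size=4)
        assert d2.size == 4
        d2.fit(l1_dataset)
        assert hasattr(d2, "ranked_libraries_")

    def test_accepts_dataframe_and_dict(self, l1_dataset):
        import pandas as pd

        df = pd.DataFrame(
            {"sequence": list(l1_dataset.entries), "tir": list(l1_dataset.entries.values())}
        )
        a = LibraryDesigner(size=2, top_k=1).fit(df)
        b = LibraryDesigner(size=2, top_k=1).fit(dict(l1_dataset.entries))
        assert a.best_sequence_ == b.best_sequence_


class TestPathwayDesigner:
    def test_combined_size_three_genes(self, random_dataset):
        datasets = {g: random_dataset(4, seed=i) for i, g in enumerate("CDE")}
        design = design_pathway(datasets, sizes=24, top_k=1)
        assert design.combined_size == 24**3 == 13_824

    def test_combined_size_with_fixed_gene(self, random_dataset):
        datasets = {g: random_dataset(3, seed=50 + i) for i, g in enumerate("CDE")}
        design = design_pathway(
            datasets, sizes=8, fixed={"E": "ACG"}, top_k=1
        )
        assert design.combined_size == 8 * 8 == 64
        assert design.per_gene["E"][0].sequence == "ACG"
        assert design.per_gene["E"][0].degeneracy == 1

    def test_single_gene_size_one(self, random_dataset):
        design = design_pathway({"g": random_dataset(2, seed=9)}, sizes=1, top_k=1)
        assert design.combined_size == 1

    def test_genes_scored_independently(self, random_dataset):
        """Identical inputs per gene give identical ranked lists."""
        data = random_dataset(3, seed=77)
        design = design_pathway({"a": data, "b": data}, sizes=6, top_k=5)
        assert [(l.sequence, l.dks) for l in design.per_gene["a"]] == [
            (l.sequence, l.dks) for l in design.per_gene["b"]
        ]

    def test_per_gene_targets(self, random_dataset):
        data = random_dataset(3, seed=81)
        design = design_pathway(
            {"lo": data, "hi": data},
            sizes=4,
            targets={"lo": "uniform-frac:0,0.5", "hi": "uniform-frac:0.5,1"},
            top_k=1,
        )
        lo_med = float(np.median(design.per_gene["lo"][0].tirs))
        hi_med = float(np.median(design.per_gene["hi"][0].tirs))
        assert lo_med < hi_med

    def test_errors_annotated_with_gene(self, random_dataset):
        with pytest.raises(SizeError, match="gene 'g'"):
            design_pathway({"g": random_dataset(2, seed=2)}, sizes=5)

    def test_coverage_report_hookup(self, random_dataset):
        datasets = {g: random_dataset(3, seed=60 + i) for i, g in enumerate("ab")}
        design = design_pathway(datasets, sizes=4, top_k=1)
        rep = design.coverage_report(goal=0.95)
        assert rep.n_variants == 16
        assert rep.picks == 48

    def test_sklearn_protocol(self, random_dataset):
        est = PathwayDesigner(sizes=4, top_k=2)
        est2 = clone(est)
        est2.fit({"g": random_dataset(2, seed=4)})
        assert est2.combined_size_ == 4
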