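"""Module merging, epistasis map, clustering, enrichment oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from epicoex.downstream import (
    EpistasisMap,
    IntervalEnrichmentInput,
    build_epistasis_map,
    cluster_epistasis_map,
    interval_function_enrichment,
    linkage_to_newick,
    merge_module_markers,
    pair_function_enrichment,
    read_gmt,
)
from epicoex.io import GenotypeMatrix
from epicoex.model import ModuleCandidate, ModuleResult


def _geno(calls, chrom=None):
    calls = np.asarray(calls, dtype=int)
    markers = [f"m{i:02d}" for i in range(calls.shape[0])]
    chrom = chrom or ["chr1"] * calls.shape[0]
    iv = pd.DataFrame({"chromosome": chrom,
                       "start": [1 + 100 * i for i in range(calls.shape[0])],
                       "end": [90 + 100 * i for i in range(calls.shape[0])]},
                      index=pd.Index(markers, name="marker_id"))
    return GenotypeMatrix(markers, [f"s{j}" for j in range(calls.shape[1])], calls, iv)


def _res(g1, g2, m1, m2, p=1e-8, sig=True):
    flags = {"significant"} if sig else set()
    return ModuleResult(candidate=ModuleCandidate(g1, g2, m1, m2),
                        p_value=p, flags=flags)


class TestMergeModuleMarkers:
    def test_duplicates_on_near_identical_markers_collapse_keeping_best_p(self):
        calls = np.zeros((3, 30), dtype=int)
        calls[:, :15] = 1
        calls[1, 0] = 0  # m01 differs from m00 in one call
        calls[2, :] = np.arange(30) % 2  # m02 very different
        geno = _geno(calls)
        results = [_res("gA", "gB", "m00", "m02", p=1e-6),
                   _res("gA", "gB", "m01", "m02", p=1e-9)]
        merged, _ = merge_module_markers(results, geno, max_discordant=15)
        assert len(merged) == 1
        assert merged[0].p_value == 1e-9
        assert merged[0].candidate.marker_pair == ("m00", "m02")

    def test_threshold_zero_merges_only_identical(self):
        calls = np.zeros((2, 20), dtype=int)
        calls[1, 0] = 1
        results = [_res("gA", "gB", "m00", "m01")]
        merged, mmap = merge_module_markers(results, _geno(calls), max_discordant=0)
        assert len(mmap.groups) == 2  # nothing merged
        assert len(merged) == 1


class TestEpistasisMap:
    def test_empty_results_give_empty_map(self):
        emap = build_epistasis_map([])
        assert emap.locus_ids == [] and emap.counts.size == 0

    def test_single_module_symmetric_unit_count(self):
        emap = build_epistasis_map([_res("gA", "gB", "mx", "my")])
        assert emap.to_frame().loc["mx", "my"] == 1
        assert emap.to_frame().loc["my", "mx"] == 1
        assert np.diag(emap.counts).sum() == 0

    def test_hub_locus_row_sum_counts_partners(self):
        results = [_res("gA", f"g{i}", "hub", f"m{i}") for i in range(5)]
        emap = build_epistasis_map(results)
        assert emap.to_frame().loc["hub"].sum() == 5

    def test_counts_conserved_against_module_number(self):
        results = [_res("gA", "gB", "m1", "m2"), _res("gC", "gD", "m1", "m3"),
                   _res("gE", "gF", "m2", "m3")]
        emap = build_epistasis_map(results)
        assert emap.n_modules == 3

    def test_validation_rejects_asymmetric_or_diagonal(self):
        with pytest.raises(ValueError, match="symmetric"):
            EpistasisMap(["a", "b"], np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError, match="diagonal"):
            EpistasisMap(["a", "b"], np.array([[1, 1], [1, 0]]))


class TestClustering:
    def test_identical_profiles_merge_at_distance_zero(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 2] = counts[2, 0] = 1
        counts[1, 2] = counts[2, 1] = 1  # loci 0 and 1 share the profile {2}
        z, _ = cluster_epistasis_map(EpistasisMap(["a", "b", "c"], counts))
        assert z[0, 2] == pytest.approx(0.0)
        assert set(z[0, :2].astype(int)) == {0, 1}

    def test_planted_block_structure_recovered(self):
        rng = np.random.default_rng(0)
        n = 10
        counts = np.zeros((n, n), dtype=int)
        for i, j in itertools.combinations(range(5), 2):
            counts[i, j] = counts[j, i] = rng.integers(1, 4)
        for i, j in itertools.combinations(range(5, 10), 2):
            counts[i, j] = counts[j, i] = rng.integers(1, 4)
        emap = EpistasisMap([f"L{i}" for i in range(n)], counts)
        _, labels = cluster_epistasis_map(emap, n_clusters=2)
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_newick_export_contains_all_leaves(self):
        counts = np.array([[0, 2, 0], [2, 0, 1], [0, 1, 0]])
        emap = EpistasisMap(["a", "b", "c"], counts)
        z, _ = cluster_epistasis_map(emap)
        nwk = linkage_to_newick(z, emap.locus_ids)
        assert nwk.endswith(";")
        for leaf in "abc":
            assert leaf in nwk


class TestPairEnrichment:
    def test_zero_hits_give_p_one(self):
        ann = {"g1": {"A"}, "g2": {"B"}, "g3": {"C"}, "g4": {"D"}}
        universe = list(itertools.combinations(sorted(ann), 2))
        table = pair_function_enrichment([("g1", "g2")], universe, ann)
        other = table[table.function_pair == "C | D"]
        assert other.empty  # pairs absent from modules are not tested
        ab = table[table.function_pair == "A | B"]
        assert float(ab.p_raw.iloc[0]) < 1.0

    def test_matches_direct_combinatorial_sum(self):
        # N=10, M=3, n=4, k=3  ->  p = C(3,3) C(7,1) / C(10,4) = 7/210
        from epicoex.downstream import PairEnrichmentInput
        from scipy.stats import hypergeom

        inp = PairEnrichmentInput(N=10, M=3, n=4, k=3)
        p = float(hypergeom.sf(inp.k - 1, inp.N, inp.M, inp.n))
        assert p == pytest.approx(7 / 210, rel=1e-12)

    def test_unknown_genes_labelled_unknown_and_bonferroni_applied(self):
        ann = {"g1": {"A"}}
        universe = [("g1", "g2"), ("g1", "g3"), ("g2", "g3")]
        table = pair_function_enrichment([("g1", "g2"), ("g2", "g3")], universe, ann)
        labels = set(table.function_pair)
        assert "A | unknown" in labels and "unknown" in " ".join(labels)
        assert (table.p_bonferroni >= table.p_raw - 1e-15).all()
        assert (table.p_bonferroni <= 1.0).all()

    def test_invalid_counts_rejected(self):
        from epicoex.downstream import PairEnrichmentInput

        with pytest.raises(ValueError):
            PairEnrichmentInput(N=10, M=2, n=4, k=3)


class TestIntervalEnrichment:
    def test_single_interval_reduces_to_hypergeometric_tail(self):
        from scipy.stats import hypergeom

        inp = IntervalEnrichmentInput(N=50, M=10, m=[8], k=[4])
        expected = float(hypergeom.sf(3, 50, 10, 8))
        assert interval_function_enrichment(inp) == pytest.approx(expected, rel=1e-10)

    def test_zero_observed_gives_p_one(self):
        inp = IntervalEnrichmentInput(N=20, M=4, m=[3, 2], k=[0, 0])
        assert interval_function_enrichment(inp) == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_enumeration_on_toy(self):
        # independent draws K1 ~ HG(20,4,3), K2 ~ HG(20,4,2); P(K1+K2 >= 3)
        N, M, m = 20, 4, [3, 2]
        p_oracle = 0.0
        for k1 in range(min(m[0], M) + 1):
            for k2 in range(min(m[1], M) + 1):
                if k1 + k2 >= 3:
                    p1 = (math.comb(M, k1) * math.comb(N - M, m[0] - k1)
                          / math.comb(N, m[0]))
                    p2 = (math.comb(M, k2) * math.comb(N - M, m[1] - k2)
                          / math.comb(N, m[1]))
                    p_oracle += p1 * p2
        inp = IntervalEnrichmentInput(N=N, M=M, m=m, k=[2, 1])
        assert interval_function_enrichment(inp) == pytest.approx(p_oracle, rel=1e-10)

    def test_monotone_in_observed_count(self):
        ps = [interval_function_enrichment(
            IntervalEnrichmentInput(N=30, M=6, m=[4, 3], k=[k, 0]))
            for k in range(5)]
        assert ps == sorted(ps, reverse=True)

    def test_unit_intervals_agree_with_union_interval(self):
        single = interval_function_enrichment(
            IntervalEnrichmentInput(N=200, M=20, m=[3], k=[2]))
        units = interval_function_enrichment(
            IntervalEnrichmentInput(N=200, M=20, m=[1, 1, 1], k=[1, 1, 0]))
        # independent-unit convolution approximates the union draw closely
        assert units == pytest.approx(single, rel=0.05)

    def test_overfull_intervals_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            IntervalEnrichmentInput(N=5, M=2, m=[4, 3], k=[0, 0])


def test_read_gmt_round_trip(tmp_path):
    path = tmp_path / "ann.gmt"
    path.write_text("ribosome\tdesc\tgA\tgB\nsignaling\tdesc\tgB\tgC\n")
    ann = read_gmt(path)
    assert ann == {"gA": {"ribosome"}, "gB": {"ribosome", "signaling"},
                   "gC": {"signaling"}}
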