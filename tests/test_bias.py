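import math

import numpy as np
import pandas as pd
import pytest

from homeolyze import bias, quant


def make_bias_result(directions, degrees=None, genes=None):
    genes = genes or [f"g{i}" for i in range(len(directions))]
    degrees = degrees if degrees is not None else [
        1.0 if d == "A" else (-1.0 if d == "D" else 0.0) for d in directions
    ]
    return pd.DataFrame(
        {
            "degree": degrees,
            "log2_fc": degrees,
            "p": 0.001,
            "q": [0.001 if d != "none" else 0.9 for d in directions],
            "significant": [d != "none" for d in directions],
            "direction": directions,
        },
        index=genes,
    )


class TestBiasRatioAndSummary:
    def test_ratio_rounding(self):
        assert bias.bias_ratio(1_027, 1_033) == 0.99
        assert bias.bias_ratio(1_891, 1_815) == 1.04

    def test_zero_d_count_is_infinite(self):
        assert bias.bias_ratio(5, 0) == math.inf

    def test_summary_accounting(self):
        res = make_bias_result(["A", "A", "D", "none", "none"])
        summary = bias.bias_summary({"Mx": res}, {"Mx": 50}).iloc[0]
        assert summary["A_bias"] == 2 and summary["D_bias"] == 1
        assert summary["total_biased"] == 3
        assert summary["pct_biased"] == 6.0
        # invariant: ratio * D-count == A-count before rounding
        assert summary["bias_ratio"] * 1 == pytest.approx(2, abs=0.005)


class TestCallBias:
    def test_diploid_accession_rejected(self, small_study):
        with pytest.raises(ValueError, match="partition units"):
            bias.call_bias(small_study["counts"], small_study["samples"],
                           small_study["lengths"], "A2")

    def test_identical_partitions_are_unbiased(self):
        samples = pd.DataFrame(
            {"sample_id": ["P_1", "P_2", "P_3"], "accession": "P",
             "genome": "AD", "replicate": [1, 2, 3]}
        )
        rng = np.random.default_rng(0)
        rows = []
        for g in range(80):
            for sid in samples["sample_id"]:
                c = int(rng.poisson(100))
                rows.append((f"g{g}", sid, c, c, 0, c))
        counts = pd.DataFrame(
            rows, columns=["gene_id", "sample_id", "n_A", "n_D", "n_X", "n_N"]
        )
        lengths = pd.Series(1_000, index=[f"g{g}" for g in range(80)])
        res = bias.call_bias(counts, samples, lengths, "P")
        assert (res["direction"] == "none").all()
        assert np.allclose(res["degree"], 0.0)

    def test_presence_filter_excludes_genes(self, small_study):
        presence = quant.presence_calls(small_study["counts"],
                                        small_study["samples"],
                                        small_study["lengths"])
        res = bias.call_bias(small_study["counts"], small_study["samples"],
                             small_study["lengths"], "Maxxa",
                             presence=presence)
        hc = presence[(presence["accession"] == "Maxxa")
                      & presence["high_confidence"]]
        assert set(res.index) <= set(hc["gene_id"])

    def test_recovers_true_bias_with_correct_direction(self, small_study):
        res = bias.call_bias(small_study["counts"], small_study["samples"],
                             small_study["lengths"], "Maxxa")
        truth = small_study["truth"].loc[res.index]
        biased = truth["Maxxa.dir"] != "none"
        called = res.loc[biased & (res["direction"] != "none")]
        agree = (called["direction"]
                 == truth.loc[called.index, "Maxxa.dir"]).mean()
        assert agree > 0.99
        # sanity on this small mixed fixture; the calibrated sensitivity
        # claim is tested at full study conditions in test_acceptance
        assert (res.loc[biased, "direction"] != "none").mean() > 0.65


class TestVenn:
    def test_two_set_example(self):
        regions = bias.venn_partition({"X": {1, 2}, "Y": {2, 3}})
        assert regions[frozenset(["X"])] == 1
        assert regions[frozenset(["X", "Y"])] == 1
        assert regions[frozenset(["Y"])] == 1

    def test_identical_sets_all_shared(self):
        regions = bias.venn_partition({"X": {1, 2}, "Y": {1, 2}, "Z": {1, 2}})
        assert regions[frozenset("XYZ")] == 2
        assert sum(regions.values()) == 2

    def test_region_counts_against_membership_oracle(self):
        rng = np.random.default_rng(8)
        sets = {
            name: set(rng.choice(200, size=rng.integers(20, 80),
                                 replace=False))
            for name in "ABCD"
        }
        regions = bias.venn_partition(sets)
        union = set.union(*sets.values())
        assert sum(regions.values()) == len(union)
        # brute force: each element falls in exactly its membership region
        for el in union:
            membership = frozenset(n for n, s in sets.items() if el in s)
            assert regions[membership] >= 1
        oracle = {}
        for el in union:
            key = frozenset(n for n, s in sets.items() if el in s)
            oracle[key] = oracle.get(key, 0) + 1
        for key, count in oracle.items():
            assert regions[key] == count


class TestConservedDirection:
    def test_counts_and_contrarians(self):
        results = {
            "W": make_bias_result(["A", "D", "A"], genes=["g1", "g2", "g3"]),
            "X": make_bias_result(["A", "D", "A"], genes=["g1", "g2", "g3"]),
            "Y": make_bias_result(["A", "D", "A"], genes=["g1", "g2", "g3"]),
            "Z": make_bias_result(["A", "D", "D"], genes=["g1", "g2", "g3"]),
        }
        out = bias.conserved_direction(results)
        assert out["consistently_A"] == {"g1"}
        assert out["consistently_D"] == {"g2"}
        assert out["not_conserved"] == {"g3"}
        assert out["contrarian"]["Z"] == ["g3"]
        for acc in "WXY":
            assert out["contrarian"][acc] == []
        # conservation identity over the all-accession biased set
        assert (len(out["consistently_A"]) + len(out["consistently_D"])
                + len(out["not_conserved"])) == len(out["shared_biased"])

    def test_all_same_direction_no_contrarians(self):
        results = {a: make_bias_result(["A", "A"]) for a in "WXYZ"}
        out = bias.conserved_direction(results)
        assert all(not v for v in out["contrarian"].values())


class TestDegreeComparison:
    def test_fold_arithmetic(self):
        res = make_bias_result(["A"] * 4, degrees=[2, 2, 1, 1])
        fold, _ = bias.compare_bias_degree(["g0", "g1"], ["g2", "g3"], res)
        assert fold == pytest.approx(2.0)

    def test_identical_sets_tie_convention(self):
        res = make_bias_result(["A"] * 4, degrees=[1, 1, 1, 1])
        fold, p = bias.compare_bias_degree(["g0", "g1"], ["g2", "g3"], res)
        assert fold == 1.0 and p == 1.0

    def test_empty_set_rejected(self):
        res = make_bias_result(["A"])
        with pytest.raises(ValueError, match="empty"):
            bias.compare_bias_degree([], ["g0"], res)

    def test_simulated_separation_detected(self):
        rng = np.random.default_rng(12)
        degrees = np.concatenate([rng.normal(1.5, 0.3, 400),
                                  rng.normal(1.0, 0.3, 400)])
        res = make_bias_result(["A"] * 800, degrees=degrees)
        set1 = [f"g{i}" for i in range(400)]
        set2 = [f"g{i}" for i in range(400, 800)]
        fold, p = bias.compare_bias_degree(set1, set2, res)
        assert 1.3 <= fold <= 1.7
        assert p < 0.001


class TestChromosomeCorrelation:
    def test_proportional_counts_give_r_one(self):
        chroms = pd.Series(
            np.repeat([f"c{i}" for i in range(13)], np.arange(13) * 10 + 20),
        )
        chroms.index = [f"g{i}" for i in range(len(chroms))]
        biased = [g for i, g in enumerate(chroms.index) if i % 2 == 0]
        r, p = bias.chromosome_bias_correlation(biased, chroms)
        assert r > 0.99

    def test_constant_biased_counts_give_zero(self):
        chroms = pd.Series(
            np.repeat(["c1", "c2", "c3"], [10, 20, 30]),
            index=[f"g{i}" for i in range(60)],
        )
        biased = ["g0", "g10", "g30"]  # one per chromosome
        r, _ = bias.chromosome_bias_correlation(biased, chroms)
        assert abs(r) < 1e-9

    def test_single_chromosome_rejected(self):
        chroms = pd.Series(["c1"] * 10, index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError):
            bias.chromosome_bias_correlation(["g0"], chroms)

    def test_uniform_sampling_recovers_correlation(self):
        # chromosomes of unequal gene content, biased genes drawn uniformly
        rng = np.random.default_rng(13)
        sizes = np.arange(1, 14, dtype=float)
        chroms = pd.Series(
            rng.choice([f"c{i:02d}" for i in range(13)], size=5_000,
                       p=sizes / sizes.sum()),
            index=[f"g{i}" for i in range(5_000)],
        )
        biased = rng.choice(chroms.index, 800, replace=False)
        r, p = bias.chromosome_bias_correlation(biased, chroms)
        assert r > 0.8 and p < 0.005


class TestTeProximity:
    def test_overlapping_te_distance_zero(self):
        from homeolyze.io_formats import GeneModel

        genes = [GeneModel("g", "c1", "+", exons=((100, 200),))]
        te = pd.DataFrame({"chrom": ["c1"], "start": [150], "end": [300]})
        assert bias.te_distances(genes, te)["g"] == 0.0

    def test_no_tes_rejected(self):
        from homeolyze.io_formats import GeneModel

        genes = [GeneModel("g", "c1", "+", exons=((0, 10),))]
        with pytest.raises(ValueError, match="no TE"):
            bias.te_distances(genes, pd.DataFrame(columns=["chrom", "start",
                                                           "end"]))

    def test_monotone_construction_detected(self):
        degrees = np.linspace(-2, 2, 500)
        res = make_bias_result(["A"] * 500, degrees=degrees)
        dist = pd.Series(1_000 + 400 * degrees, index=res.index)
        rho, p, scatter = bias.te_association_from_distances(res, dist)
        assert abs(rho) >= 0.95 and p < 1e-6
        assert len(scatter) == 500

    def test_independent_distances_not_associated(self):
        rng = np.random.default_rng(14)
        rejections = 0
        for rep in range(100):
            degrees = rng.normal(0, 1, 200)
            res = make_bias_result(["A"] * 200, degrees=degrees)
            dist = pd.Series(rng.exponential(2_000, 200), index=res.index)
            _, p, _ = bias.te_association_from_distances(res, dist)
            rejections += p < 0.05
        assert rejections <= 12  # ~5% nominal
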