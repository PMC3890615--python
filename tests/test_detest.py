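import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from homeolyze import detest


# ---------------------------------------------------------------------- TMM

class TestTmm:
    def test_identical_samples_unit_factors(self):
        m = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(detest.tmm_factors(m), 1.0)

    def test_pure_depth_difference_absorbed(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(100, 400)
        m = pd.DataFrame({"a": base, "b": base * 2})
        f = detest.tmm_factors(m)
        assert f["a"] == pytest.approx(f["b"], rel=1e-9)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.poisson(60, (300, 5)),
                         columns=list("abcde"))
        f = detest.tmm_factors(m)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)

    def test_all_zero_sample_rejected(self):
        m = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            detest.tmm_factors(m)

    def test_asymmetric_de_corrected(self):
        # 20% of genes 8-fold up in one sample shifts naive totals; TMM
        # factors should keep the null genes' implied ratio near 1
        rng = np.random.default_rng(2)
        mu = rng.uniform(50, 200, 1_000)
        a = rng.poisson(mu)
        up = np.ones(1_000)
        up[:200] = 8.0
        b = rng.poisson(mu * up)
        m = pd.DataFrame({"a": a, "b": b})
        f = detest.tmm_factors(m)
        eff = m.sum() * f
        null_ratio = (b[200:] / eff["b"]).mean() / (a[200:] / eff["a"]).mean()
        assert abs(null_ratio - 1) < 0.05


# --------------------------------------------------------------- dispersion

class TestDispersion:
    def test_recovers_known_phi(self):
        rng = np.random.default_rng(42)
        phi, r = 0.1, 10.0
        mu = rng.lognormal(4, 1, 2_000)
        y = np.stack([rng.negative_binomial(r, r / (r + m), size=6)
                      for m in mu])
        df = pd.DataFrame(y, columns=[f"u{i}" for i in range(6)])
        groups = {"g1": ["u0", "u1", "u2"], "g2": ["u3", "u4", "u5"]}
        assert 0.08 <= detest.estimate_common_dispersion(df, groups) <= 0.12

    def test_poisson_data_at_boundary(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(rng.lognormal(4, 1, 1_000)[:, None], (1_000, 6))
        df = pd.DataFrame(y, columns=[f"u{i}" for i in range(6)])
        groups = {"g1": ["u0", "u1", "u2"], "g2": ["u3", "u4", "u5"]}
        assert detest.estimate_common_dispersion(df, groups) <= 0.01

    def test_identical_replicates_at_lower_bound(self):
        col = np.random.default_rng(4).poisson(50, 300)
        df = pd.DataFrame({f"u{i}": col for i in range(4)})
        groups = {"g": list(df.columns)}
        assert detest.estimate_common_dispersion(df, groups) == \
            detest.DISPERSION_BOUNDS[0]

    def test_no_replication_returns_zero_with_warning(self):
        df = pd.DataFrame({"u0": [10, 20], "u1": [12, 18]})
        with pytest.warns(UserWarning, match="dispersion"):
            phi = detest.estimate_common_dispersion(
                df, {"g1": ["u0"], "g2": ["u1"]}
            )
        assert phi == 0.0


# --------------------------------------------------------------- exact test

def oracle_pvalue(s1, s2, n1, n2, phi):
    """Independent brute-force enumeration using scipy distributions."""
    S = s1 + s2
    mu = S / (n1 + n2)
    if phi == 0:
        f1 = sps.poisson.pmf(np.arange(S + 1), n1 * mu)
        f2 = sps.poisson.pmf(np.arange(S + 1), n2 * mu)
    else:
        r1, r2 = n1 / phi, n2 / phi
        f1 = sps.nbinom.pmf(np.arange(S + 1), r1, r1 / (r1 + n1 * mu))
        f2 = sps.nbinom.pmf(np.arange(S + 1), r2, r2 / (r2 + n2 * mu))
    joint = f1 * f2[::-1]
    obs = joint[s1]
    return joint[joint <= obs * (1 + 1e-10)].sum() / joint.sum()


class TestExactTest:
    def test_phi_zero_binomial_worked_example(self):
        """1v1 replicates, counts 3 vs 1: Binomial(4, 1/2) gives 10/16."""
        assert detest.nb_exact_test([3], [1], 0.0) == pytest.approx(0.625)

    def test_equal_sums_give_p_one(self):
        for phi in (0.0, 0.1, 1.0):
            assert detest.nb_exact_test([5], [5], phi) == 1.0

    def test_empty_data_p_one(self):
        assert detest.exact_nb_pvalue(0, 0, 3, 3, 0.1) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            detest.nb_exact_test([-1], [2], 0.1)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.3])
    @pytest.mark.parametrize("n1,n2", [(1, 1), (3, 3), (2, 3)])
    def test_matches_enumeration_oracle(self, phi, n1, n2):
        rng = np.random.default_rng(17)
        for _ in range(40):
            S = int(rng.integers(1, 120))
            s1 = int(rng.integers(0, S + 1))
            mine = detest.exact_nb_pvalue(s1, S - s1, n1, n2, phi)
            assert mine == pytest.approx(oracle_pvalue(s1, S - s1, n1, n2, phi),
                                         abs=1e-12)

    def test_uniform_under_null(self):
        """p-value validity: P(p <= a) <= a + slack under H0."""
        rng = np.random.default_rng(5)
        phi, r = 0.05, 20.0
        ps = np.empty(4_000)
        for i in range(ps.size):
            a = rng.negative_binomial(r, r / (r + 50), size=3).sum()
            b = rng.negative_binomial(r, r / (r + 50), size=3).sum()
            ps[i] = detest.exact_nb_pvalue(int(a), int(b), 3, 3, phi)
        for alpha in (0.01, 0.05, 0.1):
            assert (ps <= alpha).mean() <= alpha + 0.02


# ----------------------------------------------------------------------- BH

class TestBhFdr:
    def test_closed_form_example(self):
        q = detest.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p_unchanged(self):
        assert detest.bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            detest.bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=60))
    def test_q_monotone_in_sorted_order_and_capped(self, ps):
        q = detest.bh_fdr(ps)
        assert (q <= 1.0 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(min_value=0, max_value=0.5), min_size=2,
                    max_size=40))
    def test_raising_pvalues_never_adds_discoveries(self, ps):
        ps = np.asarray(ps)
        bumped = np.minimum(ps * 1.5 + 0.01, 1.0)
        n_before = (detest.bh_fdr(ps) < 0.05).sum()
        n_after = (detest.bh_fdr(bumped) < 0.05).sum()
        assert n_after <= n_before


# ------------------------------------------------------------ run_contrast

class TestRunContrast:
    @pytest.fixture()
    def matrix(self):
        rng = np.random.default_rng(11)
        mu = rng.uniform(20, 200, 300)
        cols = {f"a{i}": rng.poisson(mu) for i in range(3)}
        cols.update({f"b{i}": rng.poisson(mu) for i in range(3)})
        return pd.DataFrame(cols, index=[f"g{i}" for i in range(300)])

    def test_group_against_itself_rejected(self, matrix):
        with pytest.raises(ValueError, match="disjoint"):
            detest.run_contrast(matrix, ["a0", "a1"], ["a1", "a2"])

    def test_empty_group_rejected(self, matrix):
        with pytest.raises(ValueError, match="zero units"):
            detest.run_contrast(matrix, [], ["b0"])

    def test_low_count_genes_reported_na(self, matrix):
        matrix = matrix.copy()
        matrix.iloc[0] = 0
        matrix.iloc[0, 0] = 2  # total 2 < 5
        res = detest.run_contrast(matrix, ["a0", "a1", "a2"],
                                  ["b0", "b1", "b2"])
        assert math.isnan(res.iloc[0]["p"])
        assert not res.iloc[0]["significant"]

    def test_fold_change_orientation(self):
        m = pd.DataFrame(
            {"a0": [100] * 60, "a1": [100] * 60,
             "b0": [200] * 60, "b1": [200] * 60},
            index=[f"g{i}" for i in range(60)],
        )
        res = detest.run_contrast(m, ["a0", "a1"], ["b0", "b1"],
                                  dispersion=0.05)
        # equalization removes the pure depth difference: fc ~ 0
        assert res["log2_fc"].abs().max() < 0.1

    def test_gene_subset_restricts_universe(self, matrix):
        res = detest.run_contrast(matrix, ["a0", "a1", "a2"],
                                  ["b0", "b1", "b2"],
                                  genes=["g1", "g2", "g3"])
        assert sorted(res.index) == ["g1", "g2", "g3"]
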