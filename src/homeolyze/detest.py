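"""Negative-binomial differential expression between groups of count units.

The model is the standard one for bulk RNA-seq read counts: counts are
NB-distributed with Var(Y) = mu + phi * mu^2, a single common dispersion phi
shared across genes.  The chain is

    TMM normalization  ->  common-dispersion estimation on library-size-
    equalized pseudo-counts  ->  per-gene conditional exact test  ->  BH FDR

which mirrors the classic exact-test workflow for small two-group designs.
Everything here is deterministic.

The conditional exact test: with n1 and n2 replicates per group at common
per-replicate mean mu, the group sums S1 and S2 are NB with sizes n1/phi and
n2/phi.  Conditional on S = S1 + S2, the probability of each split (s, S - s)
is f1(s) f2(S - s) / sum_s' f1(s') f2(S - s'), and the two-sided p-value is
the total conditional probability of all splits no more probable than the
observed one (ties included).  At phi = 0 this reduces to the binomial exact
test, Binomial(S, n1 / (n1 + n2)).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

#: relative log-probability slack under which two splits count as tied
_TIE_TOL = 1e-10

#: genes with fewer summed raw counts than this across a contrast's units
#: are not tested (exact test is degenerate there) and get NA results
MIN_TOTAL_COUNT = 5

DISPERSION_BOUNDS = (1e-6, 5.0)


# ---------------------------------------------------------------------------
# TMM normalization (Robinson & Oshlack 2010)
# ---------------------------------------------------------------------------

def tmm_factors(count_matrix: pd.DataFrame,
                trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, one per column.

    The reference column is the one whose 75th-percentile count fraction is
    closest to the mean across columns.  For every other column, M (log2
    ratio) and A (mean log2 abundance) values are computed over genes with
    positive counts in both columns, the most extreme ``trim_m`` of M and
    ``trim_a`` of A tails are discarded, and the factor is 2 to the
    precision-weighted mean of the surviving M values.  Factors are rescaled
    so their geometric mean is 1.
    """
    mat = count_matrix.to_numpy(dtype=np.float64)
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("TMM: sample with all-zero counts")
    # drop genes with zero total before trimming
    mat = mat[mat.sum(axis=1) > 0]
    frac75 = np.array([np.percentile(mat[:, k] / lib[k], 75) for k in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(frac75 - frac75.mean())))

    factors = np.ones(mat.shape[1])
    for k in range(mat.shape[1]):
        if k == ref:
            continue
        factors[k] = 2.0 ** _tmm_one(mat[:, k], mat[:, ref], lib[k], lib[ref],
                                     trim_m, trim_a)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=count_matrix.columns, name="tmm_factor")


def _tmm_one(obs, ref, n_obs, n_ref, trim_m, trim_a) -> float:
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) inverse variance of M
    w = 1.0 / ((n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref))
    if np.allclose(m, m[0]):
        return float(m[0])
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    return float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))


def effective_library_sizes(count_matrix: pd.DataFrame,
                            factors: pd.Series | None = None) -> pd.Series:
    if factors is None:
        factors = tmm_factors(count_matrix)
    return count_matrix.sum(axis=0) * factors


def equalize_counts(count_matrix: pd.DataFrame,
                    factors: pd.Series | None = None) -> pd.DataFrame:
    """Scale every column to the geometric-mean effective library size, rounded.

    These integer pseudo-counts are what the dispersion estimator and the
    exact test consume; rounding keeps the conditional enumeration exact.
    """
    eff = effective_library_sizes(count_matrix, factors)
    common = np.exp(np.mean(np.log(eff.to_numpy(dtype=float))))
    scaled = count_matrix.to_numpy(dtype=float) * (common / eff.to_numpy())[None, :]
    return pd.DataFrame(np.rint(scaled).astype(np.int64),
                        index=count_matrix.index, columns=count_matrix.columns)


# ---------------------------------------------------------------------------
# common dispersion by conditional maximum likelihood
# ---------------------------------------------------------------------------

def _cond_loglik(pseudo: np.ndarray, group_cols: list, phi: float) -> float:
    """Summed conditional NB log-likelihood (Dirichlet-multinomial form).

    For one gene in one group with replicate counts y_i summing to z, the
    distribution of (y_i) conditional on z is negative-hypergeometric with
    shape r = 1/phi per replicate; phi-dependent terms only are summed.
    """
    r = 1.0 / phi
    total = 0.0
    for cols in group_cols:
        y = pseudo[:, cols]
        n = y.shape[1]
        if n < 2:
            continue
        z = y.sum(axis=1)
        n_genes = y.shape[0]
        total += float(
            np.sum(gammaln(y + r))
            - n_genes * n * gammaln(r)
            + n_genes * gammaln(n * r)
            - np.sum(gammaln(z + n * r))
        )
    return total


def estimate_common_dispersion(count_matrix: pd.DataFrame,
                               groups: dict,
                               factors: pd.Series | None = None) -> float:
    """Common NB dispersion maximizing the conditional likelihood.

    ``groups`` maps group name -> list of column names; only groups with >= 2
    replicates inform the estimate.  Counts are first equalized to a common
    effective library size.  Maximization is a golden-section search on
    ``DISPERSION_BOUNDS``; with no replication anywhere the estimate is 0
    (with a warning) since the conditional likelihood is flat.
    """
    pseudo_df = equalize_counts(count_matrix, factors)
    keep = pseudo_df.sum(axis=1) >= MIN_TOTAL_COUNT
    pseudo = pseudo_df.loc[keep].to_numpy(dtype=np.float64)
    col_ix = {c: i for i, c in enumerate(pseudo_df.columns)}
    group_cols = [[col_ix[c] for c in cols] for cols in groups.values()]
    if all(len(cols) < 2 for cols in group_cols) or pseudo.shape[0] == 0:
        warnings.warn("no replicated group: dispersion set to 0", stacklevel=2)
        return 0.0

    lo, hi = DISPERSION_BOUNDS
    inv_gold = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - inv_gold * (b - a)
    d = a + inv_gold * (b - a)
    fc = _cond_loglik(pseudo, group_cols, c)
    fd = _cond_loglik(pseudo, group_cols, d)
    while b - a > 1e-7:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - inv_gold * (b - a)
            fc = _cond_loglik(pseudo, group_cols, c)
        else:
            a, c, fc = c, d, fd
            d = a + inv_gold * (b - a)
            fd = _cond_loglik(pseudo, group_cols, d)
    phi = 0.5 * (a + b)
    # the bounded search cannot reach the open endpoints; snap to them when
    # the likelihood is still climbing at the boundary
    if phi <= lo * 2:
        phi = lo
    return float(phi)


# ---------------------------------------------------------------------------
# conditional exact test
# ---------------------------------------------------------------------------

def _nb_logpmf(k: np.ndarray, mean: float, size: float) -> np.ndarray:
    k = np.asarray(k, dtype=np.float64)
    if mean == 0:
        return np.where(k == 0, 0.0, -np.inf)
    return (gammaln(k + size) - gammaln(size) - gammaln(k + 1)
            + size * np.log(size / (size + mean))
            + k * np.log(mean / (size + mean)))


def _poisson_logpmf(k: np.ndarray, mean: float) -> np.ndarray:
    k = np.asarray(k, dtype=np.float64)
    if mean == 0:
        return np.where(k == 0, 0.0, -np.inf)
    return k * np.log(mean) - mean - gammaln(k + 1)


def exact_nb_pvalue(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional exact NB p-value for group sums s1 vs s2.

    See the module docstring for the model.  ``n1``/``n2`` are replicate
    counts; inputs are equalized pseudo-counts so a common per-replicate mean
    mu = (s1 + s2) / (n1 + n2) applies under H0.
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("negative counts")
    total = s1 + s2
    if total == 0:
        return 1.0
    mu = total / (n1 + n2)
    s = np.arange(total + 1)
    if phi == 0:
        lp1 = _poisson_logpmf(s, n1 * mu)
        lp2 = _poisson_logpmf(s, n2 * mu)
    else:
        lp1 = _nb_logpmf(s, n1 * mu, n1 / phi)
        lp2 = _nb_logpmf(s, n2 * mu, n2 / phi)
    joint = lp1 + lp2[::-1]
    norm = logsumexp(joint)
    keep = joint <= joint[s1] + _TIE_TOL
    p = float(np.exp(logsumexp(joint[keep]) - norm))
    return min(p, 1.0)


def nb_exact_test(counts_g1, counts_g2, dispersion: float) -> float:
    """Exact test on two vectors of per-replicate equalized counts."""
    c1 = np.asarray(counts_g1, dtype=np.int64)
    c2 = np.asarray(counts_g2, dtype=np.int64)
    if (c1 < 0).any() or (c2 < 0).any():
        raise ValueError("negative counts")
    return exact_nb_pvalue(int(c1.sum()), int(c2.sum()), c1.size, c2.size,
                           dispersion)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values in the input order."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def run_contrast(count_matrix: pd.DataFrame,
                 group1: list,
                 group2: list,
                 dispersion: float | None = None,
                 genes=None,
                 alpha: float = 0.05,
                 min_total: int = MIN_TOTAL_COUNT) -> pd.DataFrame:
    """Full exact-test contrast of two disjoint groups of unit columns.

    Returns a per-gene table with ``log2_fc`` (group2 over group1 on
    normalized per-replicate means, pseudocount 0.5), ``p``, ``q`` and the
    boolean ``significant`` (q < alpha).  Genes outside ``genes`` (the
    presence-filtered universe, if given) are dropped; genes below
    ``min_total`` summed raw counts are reported with NA statistics.
    """
    group1, group2 = list(group1), list(group2)
    if not group1 or not group2:
        raise ValueError("contrast group with zero units")
    if set(group1) & set(group2):
        raise ValueError("contrast groups must be disjoint")
    sub = count_matrix[group1 + group2]
    if genes is not None:
        sub = sub.loc[sub.index.intersection(pd.Index(genes))]
    factors = tmm_factors(sub)
    if dispersion is None:
        dispersion = estimate_common_dispersion(
            sub, {"g1": group1, "g2": group2}, factors
        )
    pseudo = equalize_counts(sub, factors)
    y1 = pseudo[group1].to_numpy()
    y2 = pseudo[group2].to_numpy()
    raw_total = sub.sum(axis=1).to_numpy()
    n1, n2 = len(group1), len(group2)
    s1 = y1.sum(axis=1)
    s2 = y2.sum(axis=1)

    p = np.full(len(sub), np.nan)
    testable = raw_total >= min_total
    for i in np.nonzero(testable)[0]:
        p[i] = exact_nb_pvalue(int(s1[i]), int(s2[i]), n1, n2, dispersion)
    q = np.full_like(p, np.nan)
    if testable.any():
        q[testable] = bh_fdr(p[testable])
    log2_fc = np.log2((s2 / n2 + 0.5) / (s1 / n1 + 0.5))
    out = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p": p,
            "q": q,
            "significant": (q < alpha) & testable,
        },
        index=sub.index,
    )
    out.attrs["dispersion"] = dispersion
    return out
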