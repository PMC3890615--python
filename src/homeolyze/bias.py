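"""Homoeolog expression bias: calling and the bias-centric summaries.

A gene is biased in an accession when its A-partition and D-partition counts
differ significantly (NB exact test, BH q < 0.05) among genes passing the
high-confidence presence filter.  The signed *degree* of bias is the
replicate-mean difference log2(RPKM_A + 1) - log2(RPKM_D + 1); positive
degrees are A-biased.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from . import detest, quant
from .io_formats import expand_units, unit_count_matrix

FDR = 0.05


# ---------------------------------------------------------------------------
# per-accession bias calls
# ---------------------------------------------------------------------------

def call_bias(counts: pd.DataFrame, samples: pd.DataFrame,
              gene_lengths: pd.Series, accession: str,
              presence: pd.DataFrame | None = None,
              dispersion: float | None = None,
              alpha: float = FDR) -> pd.DataFrame:
    """BiasResult table for one polyploid accession.

    Runs the exact-test contrast of the accession's A units against its D
    units over genes passing the high-confidence (posterior >= 0.99)
    presence filter, and attaches the signed degree of bias.  Columns:
    degree, log2_fc, p, q, direction (A/D/none).
    """
    units = expand_units(samples)
    acc_units = units[units["accession"] == accession]
    a_units = acc_units.loc[acc_units["partition"] == "A", "unit_id"].tolist()
    d_units = acc_units.loc[acc_units["partition"] == "D", "unit_id"].tolist()
    if not a_units or not d_units:
        raise ValueError(
            f"{accession} lacks A/D partition units (diploid accession?)"
        )
    genes = None
    if presence is not None:
        ok = presence[(presence["accession"] == accession)
                      & presence["high_confidence"]]
        genes = ok["gene_id"]
    mat = unit_count_matrix(counts, samples)
    res = detest.run_contrast(mat, d_units, a_units, dispersion=dispersion,
                              genes=genes, alpha=alpha)
    # degree: replicate-mean log2(RPKM+1) difference, A minus D
    expr = quant.log2_rpkm(quant.rpkm_matrix(mat, gene_lengths))
    expr = pd.DataFrame(expr, index=mat.index, columns=mat.columns)
    degree = expr[a_units].mean(axis=1) - expr[d_units].mean(axis=1)
    out = res.copy()
    out["degree"] = degree.reindex(out.index)
    sign_source = np.where(out["degree"] != 0, out["degree"], out["log2_fc"])
    out["direction"] = np.where(
        ~out["significant"].fillna(False), "none",
        np.where(sign_source > 0, "A", "D"),
    )
    out.attrs["accession"] = accession
    out.attrs.setdefault("dispersion", res.attrs.get("dispersion"))
    return out


def biased_set(bias_result: pd.DataFrame) -> set:
    return set(bias_result.index[bias_result["direction"] != "none"])


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def bias_ratio(n_a: int, n_d: int) -> float:
    """A-biased over D-biased gene counts, 2 decimals; inf when D is empty."""
    if n_d == 0:
        return math.inf
    return round(n_a / n_d, 2)


def bias_summary(bias_results: dict, expressed_counts: dict,
                 n_annotated: int | None = None) -> pd.DataFrame:
    """Per-accession bias accounting (expressed, biased, A/D split, ratio).

    ``bias_results`` maps accession -> BiasResult table; ``expressed_counts``
    maps accession -> number of expressed genes (the denominator for the
    percent-biased column).
    """
    rows = []
    for acc, res in bias_results.items():
        called = res[res["direction"] != "none"]
        n_a = int((called["direction"] == "A").sum())
        n_d = int((called["direction"] == "D").sum())
        n_expressed = int(expressed_counts[acc])
        row = {
            "accession": acc,
            "total_expressed": n_expressed,
            "total_biased": n_a + n_d,
            "pct_biased": round(100.0 * (n_a + n_d) / n_expressed, 1)
            if n_expressed else 0.0,
            "A_bias": n_a,
            "D_bias": n_d,
            "bias_ratio": bias_ratio(n_a, n_d),
        }
        if n_annotated:
            row["pct_expressed"] = quant.percent_expressed(n_expressed, n_annotated)
        rows.append(row)
    return pd.DataFrame(rows)


def venn_partition(bias_sets: dict, universe=None) -> dict:
    """Counts for every region of the k-set Venn diagram of biased genes.

    Keys are frozensets of accession names (the accessions whose sets the
    region belongs to); regions with zero members are included.  Sets are
    restricted to ``universe`` (e.g. commonly expressed genes) when given.
    """
    names = sorted(bias_sets)
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    sets = {n: set(bias_sets[n]) for n in names}
    if universe is not None:
        universe = set(universe)
        sets = {n: s & universe for n, s in sets.items()}
    union = set.union(*sets.values())
    regions = {}
    from itertools import combinations

    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(
                *(sets[n] for n in names if n not in combo), set()
            )
            regions[frozenset(combo)] = len(inside - outside)
    assert sum(regions.values()) == len(union)
    return regions


def conserved_direction(bias_results: dict) -> dict:
    """Direction conservation among genes biased in *every* accession.

    Returns consistently-A and consistently-D gene sets, the non-conserved
    remainder, and per-accession "contrarian" lists: genes whose direction in
    that accession opposes the unanimous direction of all the others.
    """
    accs = sorted(bias_results)
    if len(accs) < 2:
        raise ValueError("need at least 2 accessions")
    shared = set.intersection(*(biased_set(bias_results[a]) for a in accs))
    direction = {
        a: bias_results[a]["direction"].reindex(list(shared)) for a in accs
    }
    table = pd.DataFrame(direction, index=sorted(shared))
    all_a = set(table.index[(table == "A").all(axis=1)])
    all_d = set(table.index[(table == "D").all(axis=1)])
    contrarian = {}
    for acc in accs:
        others = [a for a in accs if a != acc]
        other_tab = table[others]
        unanimous_a = (other_tab == "A").all(axis=1)
        unanimous_d = (other_tab == "D").all(axis=1)
        mine = table[acc]
        contrarian[acc] = sorted(
            set(table.index[(unanimous_a & (mine == "D"))
                            | (unanimous_d & (mine == "A"))])
        )
    return {
        "shared_biased": shared,
        "consistently_A": all_a,
        "consistently_D": all_d,
        "not_conserved": shared - all_a - all_d,
        "contrarian": contrarian,
    }


def compare_bias_degree(genes_1, genes_2, bias_result: pd.DataFrame):
    """Fold difference of mean |degree| between two gene sets + MWU p-value.

    Fold = mean|degree|(set 1) / mean|degree|(set 2); p from a two-sided
    Mann-Whitney U test on the |degree| values.  Identical inputs give
    p = 1 by the exact-tie convention.
    """
    g1 = [g for g in genes_1 if g in bias_result.index]
    g2 = [g for g in genes_2 if g in bias_result.index]
    if not g1 or not g2:
        raise ValueError("empty gene set")
    d1 = bias_result.loc[g1, "degree"].abs().to_numpy()
    d2 = bias_result.loc[g2, "degree"].abs().to_numpy()
    fold = float(d1.mean() / d2.mean())
    if np.ptp(np.concatenate([d1, d2])) == 0:
        return fold, 1.0
    p = float(stats.mannwhitneyu(d1, d2, alternative="two-sided").pvalue)
    return fold, p


def chromosome_bias_correlation(biased_genes, gene_chroms: pd.Series):
    """Pearson r (and p) of per-chromosome biased counts vs total gene counts."""
    totals = gene_chroms.value_counts().sort_index()
    if len(totals) < 3:
        raise ValueError("need at least 3 chromosomes")
    biased = gene_chroms.reindex(list(biased_genes)).value_counts()
    biased = biased.reindex(totals.index, fill_value=0)
    if np.ptp(biased.to_numpy()) == 0:
        return 0.0, 1.0
    r, p = stats.pearsonr(totals.to_numpy(dtype=float),
                          biased.to_numpy(dtype=float))
    return float(r), float(p)


# ---------------------------------------------------------------------------
# TE proximity
# ---------------------------------------------------------------------------

def te_distances(gene_models, te_intervals: pd.DataFrame) -> pd.Series:
    """bp from each gene span to the nearest TE interval (0 if overlapping)."""
    if te_intervals.empty:
        raise ValueError("no TE intervals")
    by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in te_intervals.groupby("chrom")
    }
    out = {}
    for g in gene_models:
        if g.chrom not in by_chrom:
            out[g.gene_id] = np.nan
            continue
        s_arr, e_arr = by_chrom[g.chrom]
        # gap to each interval: 0 when overlapping/touching the gene span
        gaps = np.maximum(0, np.maximum(s_arr - g.end, g.start - e_arr))
        out[g.gene_id] = float(gaps.min())
    return pd.Series(out, name="te_distance")


def te_association_from_distances(bias_result: pd.DataFrame,
                                  distances: pd.Series,
                                  method: str = "spearman"):
    """Associate signed degree of bias with per-gene TE distances.

    Returns (statistic, p, scatter); scatter holds the per-gene degree (x)
    and TE distance (y) pairs used, ready for plotting.
    """
    scatter = pd.DataFrame(
        {
            "degree": bias_result["degree"],
            "te_distance": distances.reindex(bias_result.index),
        }
    ).dropna()
    if method == "spearman":
        rho, p = stats.spearmanr(scatter["degree"], scatter["te_distance"])
        return float(rho), float(p), scatter
    if method == "linear":
        res = stats.linregress(scatter["degree"], scatter["te_distance"])
        return float(res.slope), float(res.pvalue), scatter
    raise ValueError(f"unknown method {method!r}")


def te_proximity_association(bias_result: pd.DataFrame, te_intervals,
                             gene_models, method: str = "spearman"):
    """Degree-of-bias vs nearest-TE-distance association from gene models.

    ``method`` is 'spearman' (default) or 'linear' (OLS slope t-test).
    """
    dist = te_distances(gene_models, te_intervals)
    return te_association_from_distances(bias_result, dist, method=method)


def plot_te_scatter(scatter: pd.DataFrame, path=None, accession: str = ""):
    """Degree-of-bias vs TE-distance scatter plot (degree on x)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(scatter["degree"], scatter["te_distance"], s=4, alpha=0.4)
    ax.set_xlabel(r"degree of bias, $\log_2$(A$_T$) $-$ $\log_2$(D$_T$)")
    ax.set_ylabel("distance to nearest TE (bp)")
    if accession:
        ax.set_title(accession)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
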