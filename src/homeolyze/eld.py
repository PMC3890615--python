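"""Expression-level-dominance classification into the twelve categories.

Each gene of a polyploid is characterized by three exact-test comparisons:
the two diploid progenitors against each other (A2 vs D5) and the polyploid
total expression P against each diploid.  The significance-thresholded signs

    t_AD = sign(A - D),  t_AP = sign(P - A),  t_DP = sign(P - D)

(0 = not significant at q >= 0.05) map onto twelve categories: additive
(I, XII), expression-level dominance where P matches one parent while the
parents differ (II, IV, IX, XI), transgressive up (V, VI, VIII) and down
(III, VII, X).  The orientation follows the Rapp-style convention: II/IV are
dominance at the *higher* parent's level, IX/XI at the lower; the ratio
(II + XI) / (IV + IX) measures D-genome dominance; VIII is A = D < P.
Triples satisfying no row (e.g. A = D, P > A but P = D) are Ambiguous and
reported as such, since they are exactly the low-signal artifact the
presence filter is meant to suppress.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import detest
from .io_formats import expand_units, unit_count_matrix

#: (t_AD, t_AP, t_DP) -> category; everything else is Ambiguous
CATEGORY_TABLE = {
    (1, -1, 1): "I",     # additive, A > D
    (-1, 1, 0): "II",    # P = D, higher parent
    (-1, -1, -1): "III",  # transgressive down, A < D
    (1, 0, 1): "IV",     # P = A, higher parent
    (-1, 1, 1): "V",     # transgressive up, A < D
    (1, 1, 1): "VI",     # transgressive up, A > D
    (0, -1, -1): "VII",   # transgressive down, A = D
    (0, 1, 1): "VIII",   # transgressive up, A = D
    (-1, 0, -1): "IX",   # P = A, lower parent
    (1, -1, -1): "X",    # transgressive down, A > D
    (1, -1, 0): "XI",    # P = D, lower parent
    (-1, 1, -1): "XII",  # additive, A < D
    (0, 0, 0): "NoChange",
}

HIGH_CATEGORIES = ("II", "IV", "V", "VI", "VIII")
LOW_CATEGORIES = ("III", "VII", "IX", "X", "XI")

ALL_CATEGORIES = tuple(
    c for c in CATEGORY_TABLE.values() if c != "NoChange"
) + ("NoChange", "Ambiguous")


def classify_eld(sign_triple) -> str:
    """Category for one (t_AD, t_AP, t_DP) triple; total on all 27 triples."""
    triple = tuple(int(t) for t in sign_triple)
    if len(triple) != 3 or any(t not in (-1, 0, 1) for t in triple):
        raise ValueError(f"invalid sign triple {sign_triple!r}")
    return CATEGORY_TABLE.get(triple, "Ambiguous")


def _signs(result: pd.DataFrame) -> pd.Series:
    """Thresholded sign of each contrast (group2 minus group1)."""
    sig = result["significant"].fillna(False)
    return pd.Series(
        np.where(sig, np.sign(result["log2_fc"]).astype(int), 0),
        index=result.index,
    )


def pairwise_calls(counts: pd.DataFrame, samples: pd.DataFrame,
                   polyploid: str,
                   presence: pd.DataFrame | None = None,
                   diploid_a: str = "A2", diploid_d: str = "D5",
                   dispersion: float | None = None,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Sign triples and categories for every gene of one polyploid.

    Three contrasts are run on total-expression units (all assigned reads,
    X excluded): A2 vs D5, P vs A2, P vs D5, each thresholded at q < alpha.
    Genes failing the presence filter (active in the polyploid or either
    diploid, when ``presence`` is given) are excluded.  Returns a table with
    t_AD, t_AP, t_DP and category.
    """
    units = expand_units(samples)

    def unit_list(acc, parts):
        sel = units[(units["accession"] == acc) & units["partition"].isin(parts)]
        if sel.empty:
            raise ValueError(f"no units for accession {acc!r}")
        return sel["unit_id"].tolist()

    a_units = unit_list(diploid_a, ["A", "total"])
    d_units = unit_list(diploid_d, ["D", "total"])
    p_units = unit_list(polyploid, ["total"])

    genes = None
    if presence is not None:
        active = presence[presence["active"]]
        keep = None
        for acc in (polyploid, diploid_a, diploid_d):
            acc_set = set(active.loc[active["accession"] == acc, "gene_id"])
            keep = acc_set if keep is None else keep | acc_set
        genes = sorted(keep)

    mat = unit_count_matrix(counts, samples)
    res_ad = detest.run_contrast(mat, a_units, d_units, dispersion=dispersion,
                                 genes=genes, alpha=alpha)
    res_ap = detest.run_contrast(mat, a_units, p_units, dispersion=dispersion,
                                 genes=genes, alpha=alpha)
    res_dp = detest.run_contrast(mat, d_units, p_units, dispersion=dispersion,
                                 genes=genes, alpha=alpha)
    # t_AD is sign(A - D): the A2-vs-D5 contrast reports D over A
    out = pd.DataFrame(
        {
            "t_AD": -_signs(res_ad),
            "t_AP": _signs(res_ap),
            "t_DP": _signs(res_dp),
        }
    )
    out["category"] = [
        classify_eld(t) for t in out.itertuples(index=False, name=None)
    ]
    out.attrs["polyploid"] = polyploid
    return out


def category_counts(eld_calls: pd.DataFrame) -> pd.Series:
    counts = eld_calls["category"].value_counts()
    return counts.reindex(ALL_CATEGORIES, fill_value=0)


def eld_ratio(counts) -> float:
    """D-dominance ratio (II + XI) / (IV + IX).

    Ratios near 1 mean neither parental genome's expression level dominates.
    """
    counts = pd.Series(counts)
    num = int(counts.get("II", 0)) + int(counts.get("XI", 0))
    den = int(counts.get("IV", 0)) + int(counts.get("IX", 0))
    if den == 0:
        raise ValueError("no genes in categories IV or IX: ratio undefined")
    return num / den


def category_group_counts(eld_calls: pd.DataFrame) -> dict:
    """Counts of 'high' (P at/above the higher parent) vs 'low' categories."""
    counts = category_counts(eld_calls)
    high = int(counts[list(HIGH_CATEGORIES)].sum())
    low = int(counts[list(LOW_CATEGORIES)].sum())
    return {
        "high": high,
        "low": low,
        "high_low_ratio": high / low if low else float("inf"),
    }


def category_bias_composition(eld_calls: pd.DataFrame,
                              bias_result: pd.DataFrame) -> pd.DataFrame:
    """Per ELD category, how many member genes are A-, D- or un-biased.

    Both call sets must come from the same polyploid accession; genes absent
    from the bias table (e.g. failing its stricter presence filter) count in
    the 'untested' column.
    """
    rows = []
    direction = bias_result["direction"]
    for cat in ALL_CATEGORIES:
        members = eld_calls.index[eld_calls["category"] == cat]
        d = direction.reindex(members)
        rows.append(
            {
                "category": cat,
                "n_genes": len(members),
                "A_biased": int((d == "A").sum()),
                "D_biased": int((d == "D").sum()),
                "unbiased": int((d == "none").sum()),
                "untested": int(d.isna().sum()),
            }
        )
    return pd.DataFrame(rows).set_index("category")
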