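"""Cross-classification of diploid differential expression vs polyploid bias.

Two complementary views of how expression differences survive
polyploidization:

* the 2x2 matrix of (differentially expressed between the diploids A2 and
  D5?) against (homoeolog bias in the polyploid?), with direction-change
  counts among genes differential in both; and
* per-subgenome change tables: the polyploid A partition against the A2
  diploid and the D partition against D5, split into up/down at q < 0.05.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import detest
from .io_formats import expand_units, unit_count_matrix

MATRIX_CELLS = ("equal_equal", "equal_different",
                "different_equal", "different_different")


def diploid_polyploid_matrix(diploid_de: pd.DataFrame,
                             polyploid_bias: pd.DataFrame) -> dict:
    """Tally genes by (diploid DE?, polyploid bias?) plus direction changes.

    Both tables must cover the same gene universe (typically the commonly
    expressed set).  ``diploid_de`` is the A2-vs-D5 contrast oriented so a
    positive fold change means A2 > D5; ``polyploid_bias`` is a BiasResult.
    Among genes significant in both, ``change_A_to_D`` counts genes whose
    diploid direction was A but whose polyploid bias is D, and vice versa.
    """
    if set(diploid_de.index) != set(polyploid_bias.index):
        raise ValueError("gene universes differ between the two call sets")
    de_sig = diploid_de["significant"].fillna(False)
    bias_dir = polyploid_bias["direction"].reindex(diploid_de.index)
    bias_sig = bias_dir != "none"
    de_dir = np.where(diploid_de["log2_fc"] > 0, "A", "D")

    both = de_sig & bias_sig
    a_to_d = int((both & (de_dir == "A") & (bias_dir == "D")).sum())
    d_to_a = int((both & (de_dir == "D") & (bias_dir == "A")).sum())
    out = {
        "equal_equal": int((~de_sig & ~bias_sig).sum()),
        "equal_different": int((~de_sig & bias_sig).sum()),
        "different_equal": int((de_sig & ~bias_sig).sum()),
        "different_different": int(both.sum()),
        "change_A_to_D": a_to_d,
        "change_D_to_A": d_to_a,
    }
    assert sum(out[c] for c in MATRIX_CELLS) == len(diploid_de)
    return out


def genome_change_table(counts: pd.DataFrame, samples: pd.DataFrame,
                        polyploid: str,
                        diploid_a: str = "A2", diploid_d: str = "D5",
                        genes=None, dispersion: float | None = None,
                        alpha: float = 0.05) -> dict:
    """Up/down counts of each tetraploid subgenome against its diploid.

    Runs A_T vs A2 and D_T vs D5 exact-test contrasts (q < alpha); "up"
    means the tetraploid partition is higher.  The categorizable-fraction
    difference between a partition and a whole diploid library is absorbed
    by the normalization factors.
    """
    units = expand_units(samples)

    def unit_list(acc, part):
        sel = units[(units["accession"] == acc) & (units["partition"] == part)]
        if sel.empty:
            raise ValueError(f"missing {part} units for {acc!r}")
        return sel["unit_id"].tolist()

    mat = unit_count_matrix(counts, samples)
    res_a = detest.run_contrast(mat, unit_list(diploid_a, "A"),
                                unit_list(polyploid, "A"),
                                dispersion=dispersion, genes=genes, alpha=alpha)
    res_d = detest.run_contrast(mat, unit_list(diploid_d, "D"),
                                unit_list(polyploid, "D"),
                                dispersion=dispersion, genes=genes, alpha=alpha)
    out = {}
    for name, res in (("A", res_a), ("D", res_d)):
        sig = res["significant"].fillna(False)
        out[f"{name}_up"] = int((sig & (res["log2_fc"] > 0)).sum())
        out[f"{name}_down"] = int((sig & (res["log2_fc"] < 0)).sum())
    out["total"] = sum(out.values())
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def natural_polyploid_average(rows: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of per-accession counts, rounded half-up to integers."""
    numeric = rows.select_dtypes(include=[np.number])
    return numeric.mean(axis=0).map(_round_half_up)


def matrix_table(matrices: dict) -> pd.DataFrame:
    """Stack per-accession matrices into one 6-column table."""
    return pd.DataFrame(matrices).T.rename_axis("accession")


def change_table(tables: dict) -> pd.DataFrame:
    frame = pd.DataFrame(tables).T.rename_axis("accession")
    return frame[["A_up", "A_down", "D_up", "D_down", "total"]]
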