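"""Expression phylogenies: SSD distances and neighbor-joining trees.

Two kinds of leaf profiles over the commonly expressed genes are supported:
per-unit expression on the log2(RPKM+1) scale (one leaf per accession-genome
partition, replicates averaged), and homoeolog-difference profiles (the
signed degree of bias per gene, one leaf per polyploid accession).  Pairwise
distance is the sum of squared per-gene differences; trees come from the
Saitou-Nei neighbor-joining algorithm with deterministic tie-breaking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy

from . import quant
from .io_formats import expand_units, unit_count_matrix


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def ssd_distance(profile_matrix: pd.DataFrame) -> pd.DataFrame:
    """Sum-of-squared-differences distance matrix between profile columns."""
    mat = profile_matrix.to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError("profiles contain NaN")
    diff = mat[:, :, None] - mat[:, None, :]
    d = np.einsum("gij,gij->ij", diff, diff)
    labels = list(profile_matrix.columns)
    return pd.DataFrame(d, index=labels, columns=labels)


def expression_profiles(counts: pd.DataFrame, samples: pd.DataFrame,
                        gene_lengths: pd.Series, genes=None,
                        include_diploids: bool = True,
                        log_scale: bool = True) -> pd.DataFrame:
    """Replicate-averaged expression per (accession, partition) leaf.

    Polyploids contribute their A and D partition profiles (leaves like
    ``Maxxa_A``); diploids contribute one leaf each when included.  Values
    are log2(RPKM+1) unless ``log_scale`` is off.
    """
    units = expand_units(samples)
    mat = unit_count_matrix(counts, samples)
    expr = quant.rpkm_matrix(mat, gene_lengths)
    if log_scale:
        expr = pd.DataFrame(quant.log2_rpkm(expr), index=expr.index,
                            columns=expr.columns)
    if genes is not None:
        expr = expr.loc[sorted(set(genes) & set(expr.index))]
    cols = {}
    for (acc, part), sub in units.groupby(["accession", "partition"],
                                          sort=True):
        if part == "total":
            continue
        genome_is_poly = (
            samples.loc[samples["accession"] == acc, "genome"].iloc[0] == "AD"
        )
        if genome_is_poly:
            label = f"{acc}_{part}"
        else:
            if not include_diploids:
                continue
            label = acc
        cols[label] = expr[sub["unit_id"]].mean(axis=1)
    return pd.DataFrame(cols)


def homoeolog_diff_profiles(counts: pd.DataFrame, samples: pd.DataFrame,
                            gene_lengths: pd.Series,
                            genes=None, accessions=None) -> pd.DataFrame:
    """Per-polyploid profiles of log2(RPKM_A+1) - log2(RPKM_D+1) per gene.

    ``accessions`` defaults to every polyploid in the sample table; naming a
    diploid explicitly is an error since it has no homoeolog pair.
    """
    units = expand_units(samples)
    mat = unit_count_matrix(counts, samples)
    expr = pd.DataFrame(
        quant.log2_rpkm(quant.rpkm_matrix(mat, gene_lengths)),
        index=mat.index, columns=mat.columns,
    )
    if genes is not None:
        expr = expr.loc[sorted(set(genes) & set(expr.index))]
    polyploids = set(
        samples.loc[samples["genome"] == "AD", "accession"]
    )
    if accessions is None:
        accessions = sorted(polyploids)
    cols = {}
    for acc in accessions:
        if acc not in polyploids:
            raise ValueError(f"{acc} is a diploid: no homoeolog pair")
        sub = units[units["accession"] == acc]
        a_units = sub.loc[sub["partition"] == "A", "unit_id"]
        d_units = sub.loc[sub["partition"] == "D", "unit_id"]
        cols[acc] = expr[list(a_units)].mean(axis=1) - expr[list(d_units)].mean(axis=1)
    if not cols:
        raise ValueError("no polyploid accessions with A/D partitions")
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(distance_matrix: pd.DataFrame) -> dendropy.Tree:
    """Saitou-Nei NJ tree from a symmetric distance matrix.

    Deterministic: Q-criterion ties break on the lexicographically smallest
    (label, label) pair, where an internal cluster carries its smallest leaf
    label.  Negative branch lengths are clamped to zero with the deficit
    moved to the sibling branch, keeping the pair's path length intact.
    Two leaves give the single-edge tree; fewer than two is an error.
    """
    d = distance_matrix.to_numpy(dtype=float).copy()
    labels = [str(c) for c in distance_matrix.columns]
    n = len(labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 leaves")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")

    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    sort_key = list(labels)  # smallest contained leaf label per cluster

    if n == 2:
        root = dendropy.Node()
        nodes[0].edge.length = d[0, 1]
        nodes[1].edge.length = 0.0
        root.add_child(nodes[0])
        root.add_child(nodes[1])
        tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
        tree.is_rooted = False
        return tree

    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12 * max(1.0, abs(qmin)))
        best = min(
            (tuple(sorted((sort_key[active[i]], sort_key[active[j]]))), i, j)
            for i, j in ties
        )
        i, j = best[1], best[2]
        if sort_key[active[i]] > sort_key[active[j]]:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, transferring the deficit to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = dendropy.Node()
        nodes[ai].edge.length = float(li)
        nodes[aj].edge.length = float(lj)
        parent.add_child(nodes[ai])
        parent.add_child(nodes[aj])

        new_row = 0.5 * (d[ai, :] + d[aj, :] - dij)
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        sort_key.append(min(sort_key[ai], sort_key[aj]))
        new_ix = d.shape[0] - 1
        active = [a for a in active if a not in (ai, aj)] + [new_ix]

    a, b = active
    root = dendropy.Node()
    nodes[a].edge.length = float(max(d[a, b], 0.0))
    nodes[b].edge.length = 0.0
    root.add_child(nodes[a])
    root.add_child(nodes[b])
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def tree_path_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf-to-leaf path-length distances (brute-force edge summation)."""
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    labels = [leaf.taxon.label for leaf in leaves]

    def path_to_root(node):
        path = []
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        return path

    out = pd.DataFrame(0.0, index=labels, columns=labels)
    paths = {leaf.taxon.label: path_to_root(leaf) for leaf in leaves}
    for i, la in enumerate(labels):
        pa = paths[la]
        sa = set(id(nd) for nd in pa)
        for lb in labels[i + 1:]:
            pb = paths[lb]
            common = {id(nd) for nd in pb if id(nd) in sa}
            dist = sum((nd.edge.length or 0.0) for nd in pa if id(nd) not in common)
            dist += sum((nd.edge.length or 0.0) for nd in pb if id(nd) not in common)
            out.loc[la, lb] = out.loc[lb, la] = dist
    return out


def two_main_clades(tree: dendropy.Tree) -> tuple:
    """Leaf bipartition across the tree's longest internal edge.

    On expression trees of partitioned polyploid data this is the split the
    A/D subgenome divergence induces.
    """
    best_edge, best_len = None, -1.0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is None or edge.tail_node is None:
            continue
        if edge.head_node.is_leaf():
            continue
        if (edge.length or 0.0) > best_len:
            best_edge, best_len = edge, edge.length or 0.0
    if best_edge is None:  # star-ish tree: fall back to root children
        kids = tree.seed_node.child_nodes()
        side = {leaf.taxon.label for leaf in kids[0].leaf_iter()}
    else:
        side = {leaf.taxon.label for leaf in best_edge.head_node.leaf_iter()}
    all_leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    return side, all_leaves - side
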