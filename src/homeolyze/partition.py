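"""Classify aligned reads by homoeo-SNP alleles and tally per-gene counts.

A mapped read votes at every homoeo-SNP it covers with an aligned (M/=/X)
base of sufficient quality: A if the base matches the A allele, D if it
matches the D allele; bases matching neither abstain (treated as sequencing
error).  The read's class is then

    A  -- at least one A vote and no D votes
    D  -- at least one D vote and no A votes
    X  -- votes for both subgenomes (chimeric)
    N  -- no votes (uninformative)

Reads are assigned to the gene whose exons they overlap by the most aligned
base pairs; ties and zero-overlap reads stay unassigned.  Only primary,
mapped alignments are counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .io_formats import COUNT_CLASSES, SnpIndex

logger = logging.getLogger(__name__)

DEFAULT_MIN_BASEQ = 20

READ_CLASSES = ("A", "D", "X", "N")


def classify_read(read: pysam.AlignedSegment, snp_lookup: dict,
                  min_baseq: int = DEFAULT_MIN_BASEQ,
                  warn_counter: dict | None = None) -> str:
    """Class of one aligned read given the per-chromosome SNP lookup.

    ``snp_lookup`` is :meth:`SnpIndex.lookup` output.  Unmapped reads are a
    caller error; reads on a chromosome absent from the index are N (a
    warning counter entry is bumped if one is supplied).
    """
    if read.is_unmapped:
        raise ValueError("classify_read requires a mapped read")
    chrom = read.reference_name
    if chrom not in snp_lookup:
        if warn_counter is not None:
            warn_counter["unknown_chrom"] = warn_counter.get("unknown_chrom", 0) + 1
        return "N"
    pos0, allele_a, allele_d = snp_lookup[chrom]
    lo = np.searchsorted(pos0, read.reference_start)
    hi = np.searchsorted(pos0, read.reference_end)
    if lo == hi:
        return "N"
    # query position of each aligned reference base (indels drop out here)
    ref_to_query = {
        rpos: qpos
        for qpos, rpos in read.get_aligned_pairs()
        if qpos is not None and rpos is not None
    }
    seq = read.query_sequence
    quals = read.query_qualities
    a_votes = d_votes = 0
    for k in range(lo, hi):
        qpos = ref_to_query.get(int(pos0[k]))
        if qpos is None:
            continue
        if quals is not None and quals[qpos] < min_baseq:
            continue
        base = seq[qpos].upper()
        if base == allele_a[k]:
            a_votes += 1
        elif base == allele_d[k]:
            d_votes += 1
        # other bases abstain
    if a_votes and d_votes:
        return "X"
    if a_votes:
        return "A"
    if d_votes:
        return "D"
    return "N"


def _exon_trees(gene_models) -> dict:
    trees = {}
    for g in gene_models:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exons:
            tree[s:e] = g.gene_id
    return trees


def assign_gene(read: pysam.AlignedSegment, exon_trees: dict) -> str | None:
    """Gene with maximal exonic overlap (bp); None on ties or no overlap."""
    tree = exon_trees.get(read.reference_name)
    if tree is None:
        return None
    overlap: dict = {}
    for iv in tree[read.reference_start:read.reference_end]:
        bp = min(iv.end, read.reference_end) - max(iv.begin, read.reference_start)
        overlap[iv.data] = overlap.get(iv.data, 0) + bp
    if not overlap:
        return None
    best = max(overlap.values())
    winners = [g for g, bp in overlap.items() if bp == best]
    return winners[0] if len(winners) == 1 else None


@dataclass
class PartitionResult:
    """Per-gene class counts for one sample plus unassigned-read tallies."""

    sample_id: str
    counts: pd.DataFrame  # gene_id, sample_id, n_A, n_D, n_X, n_N
    unassigned: dict = field(default_factory=dict)  # class -> reads off-gene
    n_mapped: int = 0
    warnings: dict = field(default_factory=dict)


def count_by_gene(alignment_path, gene_models, snp_index: SnpIndex,
                  sample_id: str | None = None,
                  min_baseq: int = DEFAULT_MIN_BASEQ) -> PartitionResult:
    """Stream a SAM/BAM and tally A/D/X/N read classes per gene.

    Secondary, supplementary and unmapped records are skipped.  Reads whose
    exon overlap ties between genes (or is zero) are counted in the
    per-sample unassigned tally so that class totals are conserved.
    """
    gene_models = list(gene_models)
    if not gene_models:
        raise ValueError("no gene models loaded")
    trees = _exon_trees(gene_models)
    lookup = snp_index.lookup()
    order = [g.gene_id for g in gene_models]
    tallies = {g: dict.fromkeys(READ_CLASSES, 0) for g in order}
    unassigned = dict.fromkeys(READ_CLASSES, 0)
    warn_counter: dict = {}
    n_mapped = 0

    path = str(alignment_path)
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        if sample_id is None:
            sample_id = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            n_mapped += 1
            cls = classify_read(read, lookup, min_baseq, warn_counter)
            gene = assign_gene(read, trees)
            if gene is None:
                unassigned[cls] += 1
            else:
                tallies[gene][cls] += 1
    if warn_counter:
        logger.warning("reads on chromosomes absent from the SNP index: %s",
                       warn_counter)
    counts = pd.DataFrame(
        [
            (g, sample_id, t["A"], t["D"], t["X"], t["N"])
            for g, t in tallies.items()
        ],
        columns=["gene_id", "sample_id", *COUNT_CLASSES],
    )
    return PartitionResult(sample_id=sample_id, counts=counts,
                           unassigned=unassigned, n_mapped=n_mapped,
                           warnings=warn_counter)


def summarize_partition(results) -> pd.DataFrame:
    """Per-sample read accounting: class totals, mapped, percent categorized.

    Totals are per-gene sums plus the unassigned (intergenic/tied) tallies,
    so every mapped read appears exactly once.  "Categorized" means A, D or
    X, i.e. the read overlapped at least one diagnostic SNP.
    """
    rows = []
    for res in results:
        sums = res.counts[list(COUNT_CLASSES)].sum()
        totals = {
            cls: int(sums[f"n_{cls}"]) + res.unassigned.get(cls, 0)
            for cls in READ_CLASSES
        }
        mapped = sum(totals.values())
        categorized = totals["A"] + totals["D"] + totals["X"]
        rows.append(
            {
                "sample_id": res.sample_id,
                "A": totals["A"],
                "D": totals["D"],
                "X": totals["X"],
                "N": totals["N"],
                "mapped": mapped,
                "pct_categorized": 100.0 * categorized / mapped if mapped else 0.0,
            }
        )
    return pd.DataFrame(rows)


def partition_samples(sam_paths: dict, gene_models, snp_index: SnpIndex,
                      min_baseq: int = DEFAULT_MIN_BASEQ):
    """Run :func:`count_by_gene` over {sample_id: path}; returns (counts, summary)."""
    results = [
        count_by_gene(path, gene_models, snp_index, sample_id=sid,
                      min_baseq=min_baseq)
        for sid, path in sam_paths.items()
    ]
    counts = pd.concat([r.counts for r in results], ignore_index=True)
    return counts, summarize_partition(results)
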