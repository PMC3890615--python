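"""Readers/writers for external formats and the canonical internal tables.

This module is the single home for coordinate conventions: everything held in
memory is 0-based, half-open; GFF3 and the homoeo-SNP index are 1-based on
disk and are converted exactly once, at the file boundary.

Canonical interchange tables (all TSV with a one-line header):

* SNP index        -- chrom, pos (1-based), allele_A, allele_D
* class counts     -- gene_id, sample_id, n_A, n_D, n_X, n_N
* sample table     -- sample_id, accession, genome (A|D|AD), replicate
* unit table       -- unit_id, sample_id, accession, partition, replicate
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

COUNT_CLASSES = ("n_A", "n_D", "n_X", "n_N")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# homoeo-SNP index
# ---------------------------------------------------------------------------

class SnpIndex:
    """Index of diagnostic homoeo-SNPs between the A and D subgenomes.

    Each record is (chrom, pos, allele_A, allele_D) with ``pos`` 1-based on
    the D reference (as on disk).  Internally a validated, (chrom, pos)-sorted
    DataFrame; :meth:`lookup` exposes 0-based positions for read classification.
    """

    COLUMNS = ("chrom", "pos", "allele_A", "allele_D")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        frame["chrom"] = frame["chrom"].astype(str)
        frame["pos"] = frame["pos"].astype(np.int64)
        for col in ("allele_A", "allele_D"):
            frame[col] = frame[col].astype(str).str.upper()
        if len(frame):
            if (frame["pos"] < 1).any():
                bad = frame.index[frame["pos"] < 1][0]
                raise FormatError(f"SNP index: pos < 1 at record {bad}")
            for col in ("allele_A", "allele_D"):
                bad = ~frame[col].isin(_BASES)
                if bad.any():
                    raise FormatError(
                        f"SNP index: invalid {col} {frame.loc[bad.idxmax(), col]!r}"
                    )
            same = frame["allele_A"] == frame["allele_D"]
            if same.any():
                i = same.idxmax()
                raise FormatError(
                    f"SNP index: allele_A == allele_D ({frame.loc[i, 'allele_A']}) "
                    f"at {frame.loc[i, 'chrom']}:{frame.loc[i, 'pos']} (record {i})"
                )
            dup = frame.duplicated(subset=["chrom", "pos"])
            if dup.any():
                i = dup.idxmax()
                raise FormatError(
                    f"SNP index: duplicate site {frame.loc[i, 'chrom']}:"
                    f"{frame.loc[i, 'pos']} (record {i})"
                )
        self.frame = frame.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, SnpIndex) and self.frame.equals(other.frame)

    @classmethod
    def from_records(cls, records) -> "SnpIndex":
        """Build from an iterable of (chrom, pos, allele_A, allele_D) tuples."""
        return cls(pd.DataFrame(list(records), columns=list(cls.COLUMNS)))

    @classmethod
    def from_tsv(cls, path) -> "SnpIndex":
        return read_snp_index(path)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def lookup(self) -> dict:
        """Per-chromosome arrays for fast classification.

        Returns ``{chrom: (pos0, allele_A, allele_D)}`` with ``pos0`` a sorted
        int64 array of 0-based positions.
        """
        out = {}
        for chrom, sub in self.frame.groupby("chrom", sort=True):
            out[str(chrom)] = (
                sub["pos"].to_numpy() - 1,
                sub["allele_A"].to_numpy(),
                sub["allele_D"].to_numpy(),
            )
        return out


def read_snp_index(path) -> SnpIndex:
    """Parse a homoeo-SNP index TSV (header optional, auto-detected).

    The first row whose second column is not an integer is treated as a
    header. Validation errors name the offending line.
    """
    rows = []
    first_data_line = 1
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    start = 0
    if lines:
        fields = lines[0].split("\t")
        if len(fields) < 4:
            raise FormatError(f"{path}: line 1: expected 4 tab-separated columns")
        try:
            int(fields[1])
        except ValueError:
            start = 1  # header row
            first_data_line = 2
    for offset, line in enumerate(lines[start:]):
        lineno = first_data_line + offset
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(
                f"{path}: line {lineno}: expected 4 tab-separated columns"
            )
        try:
            pos = int(fields[1])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-integer position") from exc
        rows.append((fields[0], pos, fields[2], fields[3], lineno))
    frame = pd.DataFrame(
        [(c, p, a, d) for c, p, a, d, _ in rows], columns=list(SnpIndex.COLUMNS)
    )
    try:
        return SnpIndex(frame)
    except FormatError as exc:
        # map record index back to a line number where possible
        msg = str(exc)
        if "(record " in msg:
            rec = int(msg.rsplit("(record ", 1)[1].rstrip(")"))
            msg = msg.split(" (record")[0] + f" (line {rows[rec][4]})"
        raise FormatError(f"{path}: {msg}") from None


# ---------------------------------------------------------------------------
# gene models (GFF3)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene as a set of exon intervals, 0-based half-open.

    ``length`` (the RPKM denominator) is the summed exon length; the gene
    span is [min start, max end).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple = field(default_factory=tuple)

    def __post_init__(self):
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        if not exons:
            raise FormatError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for s, e in exons:
            if e <= s:
                raise FormatError(f"gene {self.gene_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise FormatError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e
        object.__setattr__(self, "exons", exons)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


def read_gene_models(path_gff3) -> list:
    """Read gene/exon features from a GFF3 file into :class:`GeneModel`.

    GFF3 1-based closed coordinates become 0-based half-open. Exons whose
    Parent chain does not resolve to a gene are skipped with a warning; a
    gene with no exon children uses its own span as a single exon (logged).
    Malformed lines (wrong column count) raise with a line number.
    """
    path_gff3 = Path(path_gff3)
    with open(path_gff3) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise FormatError(
                    f"{path_gff3}: line {lineno}: expected 9 tab-separated columns"
                )
    db = gffutils.create_db(
        str(path_gff3),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    claimed_exons = set()
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = []
        for exon in db.children(gene, featuretype="exon", order_by="start"):
            claimed_exons.add(exon.id)
            exons.append((exon.start - 1, exon.end))
        if not exons:
            logger.info(
                "gene %s has no exon children; using its span as one exon", gene.id
            )
            exons = [(gene.start - 1, gene.end)]
        genes.append(
            GeneModel(
                gene_id=gene.id, chrom=gene.seqid, strand=gene.strand, exons=exons
            )
        )
    for exon in db.features_of_type("exon"):
        if exon.id not in claimed_exons:
            warnings.warn(
                f"exon {exon.id} at {exon.seqid}:{exon.start}-{exon.end} has no "
                "resolvable gene parent; skipped",
                stacklevel=2,
            )
    return genes


def write_gff3(genes, path) -> None:
    """Write GeneModels back to GFF3 (exact inverse of :func:`read_gene_models`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\thomeolyze\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\thomeolyze\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def gene_lengths(genes) -> pd.Series:
    return pd.Series({g.gene_id: g.length for g in genes}, name="length")


# ---------------------------------------------------------------------------
# TE intervals (BED3)
# ---------------------------------------------------------------------------

def read_te_bed(path) -> pd.DataFrame:
    """BED3 intervals (already 0-based half-open on disk)."""
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        comment="#",
        dtype={"chrom": str},
    )
    if (frame["end"] <= frame["start"]).any():
        raise FormatError(f"{path}: BED interval with end <= start")
    return frame


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# sample metadata and expression units
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ("sample_id", "accession", "genome", "replicate")
UNIT_COLUMNS = ("unit_id", "sample_id", "accession", "partition", "replicate")


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate the physical sample table (one row per sequencing library)."""
    samples = samples.loc[:, list(SAMPLE_COLUMNS)].copy()
    samples["replicate"] = samples["replicate"].astype(int)
    bad = ~samples["genome"].isin(["A", "D", "AD"])
    if bad.any():
        raise FormatError(f"sample table: genome must be A, D or AD, got "
                          f"{samples.loc[bad.idxmax(), 'genome']!r}")
    if samples["sample_id"].duplicated().any():
        raise FormatError("sample table: duplicate sample_id")
    if samples.duplicated(subset=["accession", "replicate"]).any():
        raise FormatError("sample table: duplicate (accession, replicate)")
    per_acc = samples.groupby("accession")["genome"].nunique()
    if (per_acc > 1).any():
        raise FormatError("sample table: inconsistent genome within an accession")
    return samples


def read_sample_table(path) -> pd.DataFrame:
    return validate_samples(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def expand_units(samples: pd.DataFrame) -> pd.DataFrame:
    """Derive expression units from the sample table.

    A diploid library is a single unit whose partition is its own genome;
    a polyploid (or F1-hybrid) library yields three units: the A and D
    read partitions plus the 'total' unit (all assigned reads, X excluded).
    Unit ids are ``accession.partition.replicate``; (accession, partition,
    replicate) is unique by construction.
    """
    samples = validate_samples(samples)
    rows = []
    for rec in samples.itertuples(index=False):
        partitions = ["A", "D", "total"] if rec.genome == "AD" else [rec.genome]
        for part in partitions:
            rows.append(
                (
                    f"{rec.accession}.{part}.{rec.replicate}",
                    rec.sample_id,
                    rec.accession,
                    part,
                    rec.replicate,
                )
            )
    return pd.DataFrame(rows, columns=list(UNIT_COLUMNS))


# ---------------------------------------------------------------------------
# class-count tables
# ---------------------------------------------------------------------------

def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    counts = counts.loc[:, ["gene_id", "sample_id", *COUNT_CLASSES]].copy()
    for col in COUNT_CLASSES:
        counts[col] = counts[col].astype(np.int64)
        if (counts[col] < 0).any():
            raise FormatError(f"counts: negative {col}")
    if counts.duplicated(subset=["gene_id", "sample_id"]).any():
        raise FormatError("counts: duplicate (gene_id, sample_id)")
    return counts


def read_counts(path) -> pd.DataFrame:
    return validate_counts(pd.read_csv(path, sep="\t", dtype={"gene_id": str,
                                                              "sample_id": str}))


def write_counts(counts: pd.DataFrame, path) -> None:
    validate_counts(counts).to_csv(path, sep="\t", index=False)


def unit_count_matrix(counts: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Genes x units count matrix from the long class-count table.

    Partition units take their class column; 'total' and diploid units take
    all assigned reads minus chimeric (X) reads, which are flagged artifacts.
    """
    counts = validate_counts(counts)
    units = expand_units(samples)
    wide = {
        cls: counts.pivot(index="gene_id", columns="sample_id", values=cls).fillna(0)
        for cls in COUNT_CLASSES
    }
    genes = wide["n_A"].index
    genome_of = dict(zip(samples["sample_id"], samples["genome"]))
    cols = {}
    for rec in units.itertuples(index=False):
        sid = rec.sample_id
        if rec.partition == "A" and genome_of[sid] == "AD":
            col = wide["n_A"][sid]
        elif rec.partition == "D" and genome_of[sid] == "AD":
            col = wide["n_D"][sid]
        else:  # 'total' unit or a whole diploid library
            col = wide["n_A"][sid] + wide["n_D"][sid] + wide["n_N"][sid]
        cols[rec.unit_id] = col.astype(np.int64)
    return pd.DataFrame(cols, index=genes)


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree) -> str:
    """Serialize an unrooted tree to Newick (>= 6 significant digits).

    Labels needing quoting are handled by dendropy's writer; duplicate leaf
    labels are an error because the tree would not round-trip.
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate leaf labels in tree")
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".9g",
    ).strip() + "\n"


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")
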