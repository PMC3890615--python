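"""Synthetic allopolyploid expression studies with known ground truth.

The generator emulates the structure of a diploid/polyploid cotton petal
experiment: two diploid progenitors (A2, D5), a diploid F1-hybrid, and
natural allotetraploid accessions, three replicate libraries each.  Per-gene
expression is negative-binomial with a common dispersion; polyploid
transcript pools are split between the A and D homoeologs according to an
assigned bias, and total polyploid expression relates to the two diploids
according to an assigned expression-level-dominance (ELD) category.

Two levels of realism are provided (counts-first design):

* :func:`generate_counts` draws read-class count tables directly -- fast,
  and sufficient for every statistical stage downstream of read partitioning;
* :func:`generate_reads` additionally writes a reference FASTA, gene models,
  a homoeo-SNP index, TE intervals and SAM alignments whose reads carry
  planted subgenome alleles, to exercise the read classifier against a
  per-read origin tag.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .io_formats import GeneModel, SnpIndex, write_bed, write_gff3

ELD_CATEGORIES = ("I", "II", "III", "IV", "V", "VI",
                  "VII", "VIII", "IX", "X", "XI", "XII")

#: expression multipliers (A2, D5, polyploid-total) realizing each category,
#: as functions of the transgression/divergence fold f > 1
_ELD_MULTIPLIERS = {
    "I":   lambda f: (f, 1 / f, (f + 1 / f) / 2),   # additive, A > D
    "II":  lambda f: (1 / f, 1.0, 1.0),             # P = D (higher parent)
    "III": lambda f: (1.0, f, 1 / f),               # transgressive down, A < D
    "IV":  lambda f: (f, 1.0, f),                   # P = A (higher parent)
    "V":   lambda f: (1 / f, 1.0, f),               # transgressive up, A < D
    "VI":  lambda f: (1.0, 1 / f, f),               # transgressive up, A > D
    "VII": lambda f: (1.0, 1.0, 1 / f),             # transgressive down, A = D
    "VIII": lambda f: (1.0, 1.0, f),                # transgressive up, A = D
    "IX":  lambda f: (1.0, f, 1.0),                 # P = A (lower parent)
    "X":   lambda f: (f, 1.0, 1 / f),               # transgressive down, A > D
    "XI":  lambda f: (f, 1.0, 1.0),                 # P = D (lower parent)
    "XII": lambda f: (1 / f, f, (f + 1 / f) / 2),   # additive, A < D
    "NoChange": lambda f: (1.0, 1.0, 1.0),
}

_DEFAULT_ACCESSIONS = {
    "A2": "A", "D5": "D", "F1": "AD", "Maxxa": "AD", "Tx": "AD", "Tom": "AD",
}

_DEFAULT_ELD_FRACTIONS = {
    "I": 0.02, "II": 0.04, "III": 0.008, "IV": 0.04, "V": 0.03, "VI": 0.03,
    "VII": 0.008, "VIII": 0.04, "IX": 0.008, "X": 0.008, "XI": 0.008,
    "XII": 0.02,
}


@dataclass
class SimConfig:
    """Knobs of the simulated study; defaults are the emulated conditions.

    ``depth`` is the expected read count of an average expressed gene in one
    library; ``phi`` the common NB dispersion; ``frac_biased`` the fraction
    of genes with a homoeolog bias of ``bias_log2`` log2-fold and
    ``frac_conserved`` the fraction (of all genes) whose bias direction is
    shared by every polyploid accession.  ``p_N``/``p_X`` mirror the
    uncategorizable and chimeric read proportions of real partitioned cotton
    libraries (~48% and ~2% of mapped reads).
    """

    seed: int
    n_genes: int = 2000
    n_chromosomes: int = 13
    accessions: dict = field(default_factory=lambda: dict(_DEFAULT_ACCESSIONS))
    replicates: int = 3
    depth: float = 200.0
    depth_sigma: float = 0.0
    phi: float = 0.05
    frac_expressed: float = 0.45
    frac_biased: float = 0.20
    frac_conserved: float = 0.10
    bias_log2: float = 1.0
    eld_fractions: dict = field(default_factory=lambda: dict(_DEFAULT_ELD_FRACTIONS))
    eld_fold: float = 2.0
    p_N: float = 0.48
    p_X: float = 0.02
    equal_libsizes: bool = True
    silent_mean_frac: float = 0.005
    snp_per_kb: float = 10.0
    read_length: int = 50
    error_rate: float = 0.005
    chimera_rate: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        fracs = {
            "frac_expressed": self.frac_expressed,
            "frac_biased": self.frac_biased,
            "frac_conserved": self.frac_conserved,
            "p_N": self.p_N,
            "p_X": self.p_X,
            **{f"eld_fractions[{k}]": v for k, v in self.eld_fractions.items()},
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.frac_conserved > self.frac_biased:
            raise ValueError("frac_conserved cannot exceed frac_biased")
        if sum(self.eld_fractions.values()) > 1.0 + 1e-12:
            raise ValueError("eld_fractions sum to more than 1")
        if self.p_N + self.p_X >= 1.0:
            raise ValueError("p_N + p_X must leave room for categorizable reads")
        unknown = set(self.eld_fractions) - set(ELD_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown ELD categories: {sorted(unknown)}")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        if self.read_length < 1:
            raise ValueError("read length must be >= 1")
        if self.eld_fold <= 1.0:
            raise ValueError("eld_fold must exceed 1")

    @property
    def polyploids(self) -> list:
        return [a for a, g in self.accessions.items() if g == "AD"]

    @property
    def p_AD(self) -> float:
        """Fraction of a polyploid library that is categorizable (A+D)."""
        return 1.0 - self.p_N - self.p_X


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def generate_truth(config: SimConfig) -> pd.DataFrame:
    """Per-gene ground truth for every downstream stage.

    Columns: chrom, length, expressed, eld_category, bias_direction (the
    conserved direction, 'none' if unbiased or unconserved), bias_log2, phi,
    te_distance, a2_mean, d5_mean, and per polyploid accession
    ``{acc}.total_mean`` / ``{acc}.A_mean`` / ``{acc}.D_mean`` /
    ``{acc}.dir``.  Means are expected read counts per library at the
    configured depth; homoeolog means are on the categorized-partition scale.
    """
    rng = _rng(config, 0)
    n = config.n_genes
    width = max(4, len(str(n)))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(n)])
    chroms = np.array(
        [f"chr{c + 1:02d}" for c in rng.integers(0, config.n_chromosomes, size=n)]
    )
    lengths = rng.integers(600, 3001, size=n)

    order = rng.permutation(n)
    n_expr = int(round(config.frac_expressed * n))
    expressed = np.zeros(n, dtype=bool)
    expressed[order[:n_expr]] = True

    # expressed genes sit at the configured per-gene depth; depth_sigma > 0
    # adds a mean-preserving lognormal spread around it
    sigma = config.depth_sigma
    spread = (
        np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=n)) if sigma > 0
        else np.ones(n)
    )
    baseline = np.where(
        expressed,
        config.depth * spread,
        config.depth * config.silent_mean_frac,
    )

    # ELD categories among expressed genes
    cats = list(config.eld_fractions) + ["NoChange"]
    probs = list(config.eld_fractions.values())
    probs.append(1.0 - sum(probs))
    category = np.full(n, "NoChange", dtype=object)
    category[expressed] = rng.choice(cats, size=n_expr, p=np.array(probs))

    # category multipliers, normalized to unit geometric mean so that mirror
    # categories (II/IV, IX/XI, ...) sit at mirrored overall depths and the
    # study carries no systematic dominance asymmetry
    mult = np.ones((n, 3))
    for cat in set(category[expressed]):
        mask = expressed & (category == cat)
        raw = np.array(_ELD_MULTIPLIERS[cat](config.eld_fold))
        mult[mask] = raw / np.exp(np.mean(np.log(raw)))
    a2_mean = baseline * mult[:, 0]
    d5_mean = baseline * mult[:, 1]
    p_mean = baseline * mult[:, 2]

    # homoeolog bias assignment among expressed genes
    expr_ix = np.nonzero(expressed)[0]
    shuffled = rng.permutation(expr_ix)
    n_biased = int(round(config.frac_biased * n_expr))
    n_cons = int(round(config.frac_conserved * n_expr))
    biased_ix = shuffled[:n_biased]
    conserved_ix = shuffled[:n_cons]
    bias_mag = np.zeros(n)
    bias_mag[biased_ix] = config.bias_log2
    cons_dir = np.full(n, "none", dtype=object)
    cons_dir[conserved_ix] = rng.choice(["A", "D"], size=n_cons)

    truth = pd.DataFrame(
        {
            "chrom": chroms,
            "length": lengths,
            "expressed": expressed,
            "eld_category": category,
            "bias_direction": cons_dir,
            "bias_log2": bias_mag,
            "bias_conserved": np.isin(np.arange(n), conserved_ix),
            "phi": config.phi,
            "te_distance": np.minimum(
                rng.exponential(2000.0, size=n).astype(np.int64), 9000
            ),
            "a2_mean": a2_mean,
            "d5_mean": d5_mean,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    unconserved_ix = shuffled[n_cons:n_biased]
    for acc in config.polyploids:
        acc_dir = cons_dir.copy()
        acc_dir[unconserved_ix] = rng.choice(["A", "D"], size=len(unconserved_ix))
        beta = np.where(
            acc_dir == "A", bias_mag, np.where(acc_dir == "D", -bias_mag, 0.0)
        )
        w_a = 2.0 ** beta / (1.0 + 2.0 ** beta)
        truth[f"{acc}.total_mean"] = p_mean
        truth[f"{acc}.A_mean"] = p_mean * config.p_AD * w_a
        truth[f"{acc}.D_mean"] = p_mean * config.p_AD * (1.0 - w_a)
        truth[f"{acc}.dir"] = acc_dir
    return truth


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean, phi):
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + np.maximum(mean, 1e-300))
    out = rng.negative_binomial(r, p)
    return np.where(mean == 0, 0, out)


def sample_table(config: SimConfig) -> pd.DataFrame:
    rows = [
        (f"{acc}_{rep}", acc, genome, rep)
        for acc, genome in config.accessions.items()
        for rep in range(1, config.replicates + 1)
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "accession", "genome", "replicate"]
    )


def generate_counts(truth: pd.DataFrame, config: SimConfig):
    """Draw the read-class count table for every library.

    Each gene's total in a library is NB(mean x library factor, phi); for
    polyploids the total is then split multinomially into N / X / A / D with
    the A:D odds set by the gene's true homoeolog means.  Diploid libraries
    put their categorizable reads entirely in their own genome's class.

    Returns ``(counts, samples)``: the long class-count table and the sample
    table.
    """
    rng = _rng(config, 1)
    samples = sample_table(config)
    phi = float(truth["phi"].iloc[0]) if len(truth) else config.phi
    if config.equal_libsizes:
        lib_factor = dict.fromkeys(samples["sample_id"], 1.0)
    else:
        draw = np.exp(rng.uniform(-0.5, 0.5, size=len(samples)) * np.log(2.0))
        lib_factor = dict(zip(samples["sample_id"], draw))

    gene_ids = truth.index.to_numpy()
    frames = []
    for rec in samples.itertuples(index=False):
        lf = lib_factor[rec.sample_id]
        if rec.genome == "AD":
            mean = truth[f"{rec.accession}.total_mean"].to_numpy() * lf
            total = _nb_draw(rng, mean, phi)
            n_n = rng.binomial(total, config.p_N)
            rem = total - n_n
            n_x = rng.binomial(rem, config.p_X / (1.0 - config.p_N))
            rem = rem - n_x
            ma = truth[f"{rec.accession}.A_mean"].to_numpy()
            md = truth[f"{rec.accession}.D_mean"].to_numpy()
            with np.errstate(invalid="ignore", divide="ignore"):
                w_a = np.where(ma + md > 0, ma / np.maximum(ma + md, 1e-300), 0.5)
            n_a = rng.binomial(rem, w_a)
            n_d = rem - n_a
        else:
            mean_col = "a2_mean" if rec.genome == "A" else "d5_mean"
            total = _nb_draw(rng, truth[mean_col].to_numpy() * lf, phi)
            n_n = rng.binomial(total, config.p_N)
            own = total - n_n
            n_x = np.zeros_like(total)
            n_a = own if rec.genome == "A" else np.zeros_like(total)
            n_d = own if rec.genome == "D" else np.zeros_like(total)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "sample_id": rec.sample_id,
                    "n_A": n_a,
                    "n_D": n_d,
                    "n_X": n_x,
                    "n_N": n_n,
                }
            )
        )
    counts = pd.concat(frames, ignore_index=True)
    return counts, samples


# ---------------------------------------------------------------------------
# read-level simulation
# ---------------------------------------------------------------------------

_TE_LENGTH = 300
_SPACER = 10_000
_INTRON = 100


def _layout_genome(truth: pd.DataFrame, config: SimConfig, rng):
    """Place genes, TEs and homoeo-SNPs on synthetic chromosomes.

    Each gene gets two exons separated by a short intron and a downstream TE
    at exactly its truth-assigned distance; a large spacer guarantees that
    TE is the nearest one.  The reference carries the D allele at every SNP.
    """
    genes, te_rows, snp_rows = [], [], []
    chrom_seqs = {}
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for chrom in sorted(truth["chrom"].unique()):
        sub = truth[truth["chrom"] == chrom]
        cursor = 500
        parts = []

        def emit(n_bp):
            seq = rng.integers(0, 4, size=n_bp)
            parts.append(seq)
            return seq

        emit(cursor)
        for gene_id, row in sub.iterrows():
            length = int(row["length"])
            exon1 = length // 2
            exon2 = length - exon1
            start = cursor
            exons = (
                (start, start + exon1),
                (start + exon1 + _INTRON, start + exon1 + _INTRON + exon2),
            )
            span = exon1 + _INTRON + exon2
            emit(span)
            cursor += span
            genes.append(GeneModel(gene_id=gene_id, chrom=chrom, strand="+",
                                   exons=exons))
            te_start = cursor + int(row["te_distance"])
            te_rows.append((chrom, te_start, te_start + _TE_LENGTH))
            tail = int(row["te_distance"]) + _TE_LENGTH + _SPACER
            emit(tail)
            cursor += tail
            # homoeo-SNPs inside exons
            n_snps = max(1, int(round(length * config.snp_per_kb / 1000.0)))
            exonic = np.concatenate([np.arange(s, e) for s, e in exons])
            pos0 = np.sort(rng.choice(exonic, size=min(n_snps, exonic.size),
                                      replace=False))
            snp_rows.append((chrom, pos0))
        chrom_seqs[chrom] = np.concatenate(parts)

    snp_records = []
    for chrom, pos0 in snp_rows:
        ref_code = chrom_seqs[chrom][pos0]
        alt_code = (ref_code + rng.integers(1, 4, size=pos0.size)) % 4
        for p, rc, ac in zip(pos0, ref_code, alt_code):
            snp_records.append(
                (chrom, int(p) + 1, bases[ac].decode(), bases[rc].decode())
            )
        # plant the A allele nowhere in the reference: reference is D
    seqs = {c: bases[v].tobytes().decode() for c, v in chrom_seqs.items()}
    te = pd.DataFrame(te_rows, columns=["chrom", "start", "end"])
    return seqs, genes, SnpIndex.from_records(snp_records), te


def generate_reads(truth: pd.DataFrame, config: SimConfig, out_dir,
                   accessions=None) -> dict:
    """Write FASTA/GFF3/SNP-index/BED and per-sample SAM with planted alleles.

    Every read carries its true origin in tag ``ZO`` (``A``/``D``; ``C`` for
    a planted chimera that mixes both alleles).  A-origin reads carry the A
    allele at each covered SNP except at ``error_rate`` per SNP base;
    D-origin reads match the reference.  Intended for desk-scale inputs
    (a few hundred genes).
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, 2)
    seqs, genes, snps, te = _layout_genome(truth, config, rng)

    fasta = out_dir / "reference.fa"
    with open(fasta, "w") as fh:
        for chrom in sorted(seqs):
            fh.write(f">{chrom}\n")
            seq = seqs[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    gff = out_dir / "genes.gff3"
    write_gff3(genes, gff)
    snp_path = out_dir / "snps.tsv"
    snps.to_tsv(snp_path)
    bed = out_dir / "te.bed"
    write_bed(te, bed)

    samples = sample_table(config)
    if accessions is None:
        accessions = config.polyploids
    samples = samples[samples["accession"].isin(list(accessions))]

    lookup = snps.lookup()
    chrom_names = sorted(seqs)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(seqs[c])} for c in chrom_names],
        }
    )
    base_order = "ACGT"
    sam_paths = {}
    rl = config.read_length
    phi = config.phi
    for rec in samples.itertuples(index=False):
        reads = []
        for gene in genes:
            row = truth.loc[gene.gene_id]
            if rec.genome == "AD":
                mean_a = row[f"{rec.accession}.A_mean"]
                mean_d = row[f"{rec.accession}.D_mean"]
                categorizable = mean_a + mean_d
                mean_total = row[f"{rec.accession}.total_mean"]
                w_a = mean_a / categorizable if categorizable > 0 else 0.5
            else:
                mean_total = row["a2_mean" if rec.genome == "A" else "d5_mean"]
                w_a = 1.0 if rec.genome == "A" else 0.0
            n_reads = int(_nb_draw(rng, np.array([mean_total]), phi)[0])
            span = gene.end - gene.start
            if span < rl:
                continue
            starts = gene.start + rng.integers(0, span - rl + 1, size=n_reads)
            origins = np.where(rng.random(n_reads) < w_a, "A", "D")
            chimeric = rng.random(n_reads) < config.chimera_rate
            chrom_seq = seqs[gene.chrom]
            pos0, allele_a, allele_d = lookup.get(
                gene.chrom, (np.array([], dtype=int), None, None)
            )
            for start, origin, chim in zip(starts, origins, chimeric):
                start = int(start)
                seq = list(chrom_seq[start:start + rl])
                lo = np.searchsorted(pos0, start)
                hi = np.searchsorted(pos0, start + rl)
                covered = range(lo, hi)
                tag = origin
                if chim and hi - lo >= 2:
                    # alternate A then D alleles across covered SNPs
                    for j, k in enumerate(covered):
                        seq[pos0[k] - start] = (
                            allele_a[k] if j % 2 == 0 else allele_d[k]
                        )
                    tag = "C"
                elif origin == "A":
                    for k in covered:
                        seq[pos0[k] - start] = allele_a[k]
                # D origin: reference already carries the D allele
                for k in covered:
                    if rng.random() < config.error_rate:
                        seq[pos0[k] - start] = base_order[rng.integers(0, 4)]
                reads.append((gene.chrom, start, "".join(seq), tag))
        reads.sort(key=lambda r: (r[0], r[1]))
        path = out_dir / f"{rec.sample_id}.sam"
        with pysam.AlignmentFile(str(path), "w", header=header,
                                 add_sam_header=True) as sam:
            for i, (chrom, start, seq, tag) in enumerate(reads):
                a = pysam.AlignedSegment(header)
                a.query_name = f"{rec.sample_id}.r{i:07d}"
                a.query_sequence = seq
                a.flag = 0
                a.reference_name = chrom
                a.reference_start = start
                a.mapping_quality = 60
                a.cigarstring = f"{len(seq)}M"
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                a.set_tag("ZO", tag, value_type="A")
                sam.write(a)
        sam_paths[rec.sample_id] = path

    return {
        "reference": fasta,
        "gff3": gff,
        "snps": snp_path,
        "te_bed": bed,
        "sams": sam_paths,
        "genes": genes,
        "snp_index": snps,
        "te": te,
        "samples": samples.reset_index(drop=True),
    }
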