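"""One-command orchestration of the whole analysis on simulated or user data.

``run_all`` executes (optionally) simulate -> partition -> quant -> bias ->
ELD -> cross-classification -> phylogenies, writing every stage's table as
TSV plus a manifest with the seed, a parameter hash and per-file checksums.
All randomness flows through the seed, and stage outputs are pure functions
of (inputs, config, seed): a rerun with the same seed reproduces every
result file byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, bias, crossclass, eld, phylo, quant
from .io_formats import (
    read_counts,
    read_gene_models,
    read_sample_table,
    read_snp_index,
    read_te_bed,
    gene_lengths as _gene_lengths,
    write_counts,
    write_newick,
    write_sample_table,
)
from .partition import partition_samples
from .synth import SimConfig, generate_counts, generate_reads, generate_truth

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and offending input."""


@dataclass
class RunConfig:
    """Everything a run needs: inputs or simulation settings plus thresholds."""

    seed: int
    out_dir: str = "homeolyze_out"
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # overrides for SimConfig
    simulate_reads: bool = False  # also exercise the read-level partitioner
    read_accessions: list | None = None
    # user-data inputs (used when simulate is off)
    counts_path: str | None = None
    samples_path: str | None = None
    gff_path: str | None = None
    snp_path: str | None = None
    te_bed_path: str | None = None
    sam_paths: dict = field(default_factory=dict)
    # thresholds
    fdr: float = 0.05
    presence_active: float = 0.5
    presence_high: float = 0.99
    min_baseq: int = 20
    min_counts: int = 5
    # stage toggles
    stages: tuple = ("partition", "quant", "bias", "eld", "crossclass", "phylo")

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is required")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if not 0 <= self.presence_active <= self.presence_high <= 1:
            raise ValueError("presence thresholds must satisfy "
                             "0 <= active <= high-confidence <= 1")
        if self.min_baseq < 0 or self.min_counts < 0:
            raise ValueError("min_baseq and min_counts must be >= 0")
        if not self.simulate:
            if self.counts_path is None and not self.sam_paths:
                raise ValueError("need counts_path or sam_paths when not simulating")
            if "partition" in self.stages and self.sam_paths and self.snp_path is None:
                raise ValueError("partition stage needs a SNP index")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _hash_params(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(frame: pd.DataFrame, path: Path, index=False):
    frame.to_csv(path, sep="\t", index=index)


def run_all(config: RunConfig) -> dict:
    """Execute every enabled stage; returns {artifact name: path or object}.

    Any stage failure aborts with :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    stage = "setup"
    try:
        # ------------------------------------------------------------- inputs
        stage = "simulate" if config.simulate else "load"
        te_distances = None
        genes_models = None
        te_intervals = None
        if config.simulate:
            sim = SimConfig(seed=config.seed, **config.sim)
            truth = generate_truth(sim)
            counts, samples = generate_counts(truth, sim)
            lengths = truth["length"]
            gene_chroms = truth["chrom"]
            te_distances = truth["te_distance"].astype(float)
            truth.to_csv(out / "truth.tsv", sep="\t")
            write_counts(counts, out / "counts.tsv")
            write_sample_table(samples, out / "samples.tsv")
            artifacts["truth"] = out / "truth.tsv"
            if config.simulate_reads and "partition" in config.stages:
                stage = "partition"
                sim_files = generate_reads(truth, sim, out / "reads",
                                           accessions=config.read_accessions)
                genes_models = sim_files["genes"]
                te_intervals = sim_files["te"]
                part_counts, part_summary = partition_samples(
                    sim_files["sams"], genes_models, sim_files["snp_index"],
                    min_baseq=config.min_baseq,
                )
                write_counts(part_counts, out / "partition_counts.tsv")
                _write(part_summary, out / "partition_summary.tsv")
                artifacts["partition_summary"] = out / "partition_summary.tsv"
        else:
            samples = read_sample_table(config.samples_path)
            if config.sam_paths:
                stage = "partition"
                genes_models = read_gene_models(config.gff_path)
                snps = read_snp_index(config.snp_path)
                counts, part_summary = partition_samples(
                    config.sam_paths, genes_models, snps,
                    min_baseq=config.min_baseq,
                )
                write_counts(counts, out / "counts.tsv")
                _write(part_summary, out / "partition_summary.tsv")
                lengths = _gene_lengths(genes_models)
                gene_chroms = pd.Series(
                    {g.gene_id: g.chrom for g in genes_models}
                )
            else:
                counts = read_counts(config.counts_path)
                genes_models = read_gene_models(config.gff_path)
                lengths = _gene_lengths(genes_models)
                gene_chroms = pd.Series(
                    {g.gene_id: g.chrom for g in genes_models}
                )
            if config.te_bed_path:
                te_intervals = read_te_bed(config.te_bed_path)

        polyploids = sorted(samples.loc[samples["genome"] == "AD", "accession"]
                            .unique())

        # -------------------------------------------------------------- quant
        stage = "quant"
        presence = sets = None
        if "quant" in config.stages:
            presence = quant.presence_calls(counts, samples, lengths)
            _write(presence, out / "presence.tsv")
            sets = quant.expressed_sets(presence)
            expressed_counts = {
                acc: len(s) for acc, s in sets["per_accession"].items()
            }
            summary = pd.DataFrame(
                {
                    "accession": list(expressed_counts),
                    "total_expressed": list(expressed_counts.values()),
                    "pct_expressed": [
                        quant.percent_expressed(v, len(lengths))
                        for v in expressed_counts.values()
                    ],
                }
            )
            summary.loc[len(summary)] = [
                "commonly_expressed", len(sets["common"]),
                quant.percent_expressed(len(sets["common"]), len(lengths)),
            ]
            _write(summary, out / "expressed_summary.tsv")
            artifacts["expressed_summary"] = out / "expressed_summary.tsv"

        # --------------------------------------------------------------- bias
        stage = "bias"
        bias_results = {}
        if "bias" in config.stages:
            for acc in polyploids:
                res = bias.call_bias(counts, samples, lengths, acc,
                                     presence=presence, alpha=config.fdr)
                bias_results[acc] = res
                _write(res, out / f"bias_{acc}.tsv", index=True)
            summary3 = bias.bias_summary(
                bias_results,
                {acc: len(sets["per_accession"][acc]) for acc in polyploids}
                if sets else
                {acc: len(counts["gene_id"].unique()) for acc in polyploids},
                n_annotated=len(lengths),
            )
            _write(summary3, out / "bias_summary.tsv")
            artifacts["bias_summary"] = out / "bias_summary.tsv"
            if len(polyploids) >= 2:
                common = sets["common"] if sets else None
                venn = bias.venn_partition(
                    {a: bias.biased_set(r) for a, r in bias_results.items()},
                    universe=common,
                )
                venn_df = pd.DataFrame(
                    sorted(
                        ("+".join(sorted(k)), v) for k, v in venn.items()
                    ),
                    columns=["region", "n_genes"],
                )
                _write(venn_df, out / "bias_venn.tsv")
                cons = bias.conserved_direction(bias_results)
                cons_df = pd.DataFrame(
                    {
                        "set": ["shared_biased", "consistently_A",
                                "consistently_D", "not_conserved"],
                        "n_genes": [
                            len(cons["shared_biased"]),
                            len(cons["consistently_A"]),
                            len(cons["consistently_D"]),
                            len(cons["not_conserved"]),
                        ],
                    }
                )
                _write(cons_df, out / "bias_conserved.tsv")
            chrom_stats = []
            for acc, res in bias_results.items():
                r, p = bias.chromosome_bias_correlation(
                    bias.biased_set(res), gene_chroms
                )
                chrom_stats.append({"accession": acc, "pearson_r": r, "p": p})
            _write(pd.DataFrame(chrom_stats), out / "bias_chromosome.tsv")
            if te_distances is not None or te_intervals is not None:
                te_rows = []
                for acc, res in bias_results.items():
                    if te_intervals is not None and genes_models is not None:
                        stat, p, scatter = bias.te_proximity_association(
                            res, te_intervals, genes_models
                        )
                    else:
                        stat, p, scatter = bias.te_association_from_distances(
                            res, te_distances
                        )
                    te_rows.append(
                        {"accession": acc, "spearman_rho": stat, "p": p}
                    )
                    _write(scatter, out / f"te_scatter_{acc}.tsv", index=True)
                _write(pd.DataFrame(te_rows), out / "te_association.tsv")

        # ---------------------------------------------------------------- ELD
        stage = "eld"
        eld_calls = {}
        if "eld" in config.stages and {"A2", "D5"} <= set(samples["accession"]):
            cat_tables = {}
            for acc in polyploids:
                calls = eld.pairwise_calls(counts, samples, acc,
                                           presence=presence, alpha=config.fdr)
                eld_calls[acc] = calls
                _write(calls, out / f"eld_{acc}.tsv", index=True)
                cat_tables[acc] = eld.category_counts(calls)
            cat_df = pd.DataFrame(cat_tables).rename_axis("category")
            _write(cat_df, out / "eld_categories.tsv", index=True)
            ratios = []
            for acc in polyploids:
                try:
                    ratio = eld.eld_ratio(cat_tables[acc])
                except ValueError:
                    ratio = float("nan")
                groups = eld.category_group_counts(eld_calls[acc])
                ratios.append({"accession": acc, "eld_ratio": ratio, **groups})
            _write(pd.DataFrame(ratios), out / "eld_ratios.tsv")
            artifacts["eld_categories"] = out / "eld_categories.tsv"
            if bias_results:
                for acc in polyploids:
                    comp = eld.category_bias_composition(
                        eld_calls[acc], bias_results[acc]
                    )
                    _write(comp, out / f"eld_bias_composition_{acc}.tsv",
                           index=True)

        # --------------------------------------------------------- crossclass
        stage = "crossclass"
        if ("crossclass" in config.stages and bias_results
                and {"A2", "D5"} <= set(samples["accession"])):
            from .io_formats import expand_units, unit_count_matrix
            from . import detest

            units = expand_units(samples)
            mat = unit_count_matrix(counts, samples)
            a2 = units.loc[units["accession"] == "A2", "unit_id"].tolist()
            d5 = units.loc[units["accession"] == "D5", "unit_id"].tolist()
            matrices = {}
            for acc in polyploids:
                universe = bias_results[acc].index
                diploid_de = detest.run_contrast(
                    mat, d5, a2, genes=universe, alpha=config.fdr
                )  # positive fold change = A2 > D5
                matrices[acc] = crossclass.diploid_polyploid_matrix(
                    diploid_de.loc[universe], bias_results[acc]
                )
            tab4 = crossclass.matrix_table(matrices)
            _write(tab4, out / "crossclass_matrix.tsv", index=True)
            changes = {
                acc: crossclass.genome_change_table(
                    counts, samples, acc,
                    genes=sets["common"] if sets else None,
                    alpha=config.fdr,
                )
                for acc in polyploids
            }
            tab5 = crossclass.change_table(changes)
            _write(tab5, out / "crossclass_changes.tsv", index=True)
            artifacts["crossclass"] = out / "crossclass_matrix.tsv"

        # -------------------------------------------------------------- phylo
        stage = "phylo"
        if "phylo" in config.stages:
            common = sorted(sets["common"]) if sets else None
            profiles = phylo.expression_profiles(counts, samples, lengths,
                                                 genes=common)
            if profiles.shape[1] >= 2:
                tree = phylo.neighbor_joining(phylo.ssd_distance(profiles))
                (out / "expression_tree.nwk").write_text(write_newick(tree))
                artifacts["expression_tree"] = out / "expression_tree.nwk"
            if len(polyploids) >= 2:
                diff = phylo.homoeolog_diff_profiles(counts, samples, lengths,
                                                     genes=common)
                tree2 = phylo.neighbor_joining(phylo.ssd_distance(diff))
                (out / "bias_tree.nwk").write_text(write_newick(tree2))
                artifacts["bias_tree"] = out / "bias_tree.nwk"
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    # ------------------------------------------------------------- manifest
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "param_hash": _hash_params(config),
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.nwk"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    artifacts["manifest"] = out / "manifest.json"
    return artifacts
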