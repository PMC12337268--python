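"""End-to-end orchestration and evaluation against planted ground truth.

``run_pipeline`` executes the stages in study order -- input validation,
expression preparation, PAV discovery, syntenic clustering + pangenome
partition, coexpression networks for both organisms, and the association
report -- writing every intermediate table.  The run is deterministic given
its inputs; no stage after data generation draws random numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pavcoex import expression, io, network, pav, report, synteny
from pavcoex.config import AnalysisConfig
from pavcoex.simulate import Dataset

log = logging.getLogger(__name__)

STAGES = ("data_io", "expression_prep", "pav_discovery", "synteny_pangenome",
          "coexpression", "association_report")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    config: AnalysisConfig
    trait_name: str
    # expression prep
    symbiont_status: pd.DataFrame | None = None
    symbiont_strain_means: pd.DataFrame | None = None
    host_strain_means: pd.DataFrame | None = None
    symbiont_pca: expression.PCAResult | None = None
    host_pca: expression.PCAResult | None = None
    # pav discovery
    expression_presence: pd.DataFrame | None = None
    onoff_genes: pd.Index | None = None
    gene_trait: pd.DataFrame | None = None
    sequence_hits: pd.DataFrame | None = None
    sequence_presence: pd.DataFrame | None = None
    confirmed_genes: pd.Index | None = None
    discordance: pd.Series | None = None
    # synteny + pangenome
    clusters: list = field(default_factory=list)
    singletons: list = field(default_factory=list)
    cluster_presence: pd.DataFrame | None = None
    cluster_tests: pd.DataFrame | None = None
    pangenome_classes: pd.DataFrame | None = None
    pangenome_summary: pd.DataFrame | None = None
    # coexpression
    symbiont_network: network.CoexpressionNetwork | None = None
    host_network: network.CoexpressionNetwork | None = None
    # association report
    module_trait: pd.DataFrame | None = None
    cross_edges: pd.DataFrame | None = None
    phenotype_summary: dict | None = None
    enrichment: pd.DataFrame | None = None
    manifest: dict | None = None


def run_pipeline_from_data(
    symbiont_counts: io.CountsMatrix,
    sample_sheet: pd.DataFrame,
    phenotypes: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    host_counts: io.CountsMatrix | None = None,
    gene_groups: pd.DataFrame | None = None,
    gene_seqs: dict | None = None,
    genomes=None,
    replicate_trait: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
    trait_name: str = "shoot_biomass",
    out_dir=None,
    categories: pd.Series | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs; optionally write the bundle."""
    config = config or AnalysisConfig()
    res = PipelineResult(config=config, trait_name=trait_name)

    stage = "data_io"
    try:
        sheet = io.validate_sample_sheet(sample_sheet)
        symbiont_counts = symbiont_counts.reorder_samples(sheet["sample_id"])
        if host_counts is not None:
            host_counts = host_counts.reorder_samples(sheet["sample_id"])
        if trait_name not in phenotypes.columns:
            raise ValueError(f"trait {trait_name!r} not in phenotype table")
        trait = phenotypes[trait_name]
    except StageError:
        raise
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "expression_prep"
    try:
        sym_logcpm = expression.logcpm(symbiont_counts, config.logcpm_prior)
        res.symbiont_status = expression.classify_expression_status(
            symbiont_counts, sheet, config.cpm_floor)
        res.symbiont_strain_means = expression.strain_means(sym_logcpm, sheet)
        res.symbiont_pca = expression.pca_strains(
            res.symbiont_strain_means, scale=config.pca_scale)
        if host_counts is not None:
            host_logcpm = expression.logcpm(host_counts, config.logcpm_prior)
            res.host_strain_means = expression.strain_means(host_logcpm, sheet)
            n_var = min(config.n_variable_host_genes, len(res.host_strain_means))
            host_var_genes = expression.select_variable_genes(res.host_strain_means, n_var)
            res.host_pca = expression.pca_strains(
                res.host_strain_means.loc[host_var_genes], scale=config.pca_scale)
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "pav_discovery"
    try:
        res.expression_presence = pav.call_presence_from_expression(
            symbiont_counts, sheet, config)
        res.onoff_genes = pav.filter_onoff(res.expression_presence, config)
        res.gene_trait = pav.correlate_presence_with_trait(
            res.expression_presence.loc[res.onoff_genes], trait, config,
            expression=res.symbiont_strain_means)
        candidates = pd.Index(
            res.gene_trait.loc[res.gene_trait["significant"], "unit_id"])
        if gene_seqs is not None and genomes is not None and len(candidates):
            queries = {g: gene_seqs[g] for g in candidates}
            strains = list(res.expression_presence.columns)
            res.sequence_hits, res.sequence_presence = pav.find_sequence_presence(
                queries, genomes, config, strains=strains)
            res.confirmed_genes, res.discordance = pav.agreement_filter(
                res.expression_presence.loc[candidates],
                res.sequence_presence.loc[candidates, strains],
            )
        else:
            res.confirmed_genes = candidates
            res.discordance = pd.Series(dtype=int)
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "synteny_pangenome"
    try:
        if annotation is not None and len(res.confirmed_genes):
            res.clusters, res.singletons = synteny.detect_clusters(
                annotation, res.confirmed_genes, gap=config.cluster_gap_bp)
            if res.clusters:
                res.cluster_presence = synteny.cluster_presence(
                    res.clusters, res.expression_presence,
                    rule=config.cluster_presence_rule)
                res.cluster_tests = synteny.cluster_trait_ttest(
                    res.cluster_presence, trait, welch=config.welch_ttest)
        if gene_groups is not None:
            strains = list(res.expression_presence.columns)
            group_presence = (
                gene_groups.assign(present=True)
                .pivot_table(index="group_id", columns="strain_id",
                             values="present", aggfunc="any", fill_value=False)
            )
            replicon_of = None
            if annotation is not None:
                replicon_of = annotation.set_index("gene_id")["replicon_id"]
            res.pangenome_classes, res.pangenome_summary = synteny.classify_pangenome(
                group_presence, config, replicon_of=replicon_of)
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "coexpression"
    try:
        sym_keep = network.prefilter_for_network(symbiont_counts, config.median_count_floor)
        res.symbiont_network = network.build_network(
            res.symbiont_strain_means.loc[sym_keep], config)
        if host_counts is not None:
            host_keep = network.prefilter_for_network(host_counts, config.median_count_floor)
            host_expr = res.host_strain_means.loc[host_keep]
            n_var = min(config.n_variable_host_genes, len(host_expr))
            host_var = expression.select_variable_genes(host_expr, n_var)
            res.host_network = network.build_network(host_expr.loc[host_var], config)
    except Exception as err:
        raise StageError(stage, err) from err

    stage = "association_report"
    try:
        res.module_trait = report.module_trait_correlation(
            res.symbiont_network.eigengenes, phenotypes, config)
        res.module_trait.insert(0, "organism", "symbiont")
        if res.host_network is not None:
            host_mt = report.module_trait_correlation(
                res.host_network.eigengenes, phenotypes, config)
            host_mt.insert(0, "organism", "host")
            res.module_trait = pd.concat([res.module_trait, host_mt],
                                         ignore_index=True)
            res.cross_edges = report.cross_network_correlation(
                res.host_network.eigengenes, res.symbiont_network.eigengenes,
                config, trait=trait)
        res.phenotype_summary = report.phenotype_summary(
            phenotypes, replicate_trait, trait=trait_name)
        if categories is None and annotation is not None:
            categories = annotation.set_index("gene_id")["replicon_id"]
        if categories is not None:
            res.enrichment = report.category_enrichment(
                res.symbiont_network.assignment,
                categories.reindex(res.symbiont_network.genes).dropna(),
                universe=res.symbiont_network.genes)
    except Exception as err:
        raise StageError(stage, err) from err

    if out_dir is not None:
        res.manifest = _write_bundle(res, out_dir, config)
    return res


def _write_bundle(res: PipelineResult, out_dir, config: AnalysisConfig) -> dict:
    tables = {}
    if res.expression_presence is not None:
        tables["expression_presence"] = res.expression_presence.astype(int).rename_axis("gene_id")
    if res.sequence_presence is not None:
        tables["sequence_presence"] = res.sequence_presence.astype(int).rename_axis("gene_id")
    if res.sequence_hits is not None:
        tables["sequence_hits"] = res.sequence_hits
    if res.gene_trait is not None:
        tables["gene_trait_association"] = res.gene_trait
    if res.cluster_tests is not None:
        tables["cluster_trait_tests"] = res.cluster_tests
    if res.cluster_presence is not None:
        tables["cluster_presence"] = res.cluster_presence.astype(int).rename_axis("cluster_id")
    if res.clusters:
        tables["clusters"] = pd.DataFrame(
            [(c.cluster_id, c.replicon_id, ";".join(c.genes), c.start, c.end, c.span)
             for c in res.clusters],
            columns=["cluster_id", "replicon_id", "members", "start", "end", "span"])
    if res.pangenome_classes is not None:
        tables["pangenome_classes"] = res.pangenome_classes.rename_axis("group_id")
    if res.pangenome_summary is not None:
        tables["pangenome_summary"] = res.pangenome_summary.rename_axis("replicon_id")
    if res.module_trait is not None:
        tables["module_trait"] = res.module_trait
    if res.cross_edges is not None:
        tables["cross_edges"] = res.cross_edges
    if res.enrichment is not None:
        tables["enrichment"] = res.enrichment
    for organism, net in (("symbiont", res.symbiont_network), ("host", res.host_network)):
        if net is not None:
            tables[f"{organism}_modules"] = net.assignment.rename("module").rename_axis("gene_id").reset_index()
            tables[f"{organism}_eigengenes"] = net.eigengenes.rename_axis("module")
            tables[f"{organism}_soft_power_fit"] = net.fit_table

    extra = {"stages": list(STAGES)}
    if res.phenotype_summary is not None:
        extra["phenotype_summary"] = {
            k: v for k, v in res.phenotype_summary.items() if k != "trait_correlations"
        }
        tables["trait_correlations"] = (
            res.phenotype_summary["trait_correlations"].rename_axis("trait"))
    for organism, net in (("symbiont", res.symbiont_network), ("host", res.host_network)):
        if net is not None:
            extra[f"{organism}_beta"] = net.beta
            extra[f"{organism}_module_sizes"] = net.module_sizes.to_dict()
    manifest = io.write_results(tables, out_dir, config=config,
                                seed=config.seed, extra_manifest=extra)
    md = report.markdown_report(res.gene_trait, res.cluster_tests,
                                res.module_trait, res.cross_edges,
                                res.phenotype_summary)
    (Path(out_dir) / "report.md").write_text(md)
    return manifest


def run_pipeline(config_path, out_dir=None) -> PipelineResult:
    """Run the pipeline from a YAML run configuration.

    The file has two top-level keys: ``inputs`` (paths: symbiont_counts,
    sample_sheet, phenotypes, and optionally host_counts, annotation,
    gene_groups, gene_sequences, assemblies_dir, replicate_biomass,
    trait_name) and ``config`` (AnalysisConfig overrides).
    """
    with open(config_path) as fh:
        run_cfg = yaml.safe_load(fh)
    config = AnalysisConfig.from_dict(run_cfg.get("config", {}) or {})
    inputs = run_cfg.get("inputs", {}) or {}
    base = Path(config_path).parent

    def p(key):
        val = inputs.get(key)
        if val is None:
            return None
        path = Path(val)
        return path if path.is_absolute() else base / path

    try:
        counts, sheet = io.read_expression_inputs(p("symbiont_counts"), p("sample_sheet"))
        host_counts = None
        if p("host_counts"):
            host_counts = io.read_counts(p("host_counts")).reorder_samples(sheet["sample_id"])
        phenotypes = io.read_phenotypes(p("phenotypes"))
        annotation = io.read_annotation(p("annotation")) if p("annotation") else None
        gene_groups = io.read_gene_groups(p("gene_groups")) if p("gene_groups") else None
        gene_seqs = None
        if p("gene_sequences"):
            from pyfaidx import Fasta
            fa = Fasta(str(p("gene_sequences")), sequence_always_upper=True)
            gene_seqs = {name: str(fa[name][:]) for name in fa.keys()}
        genomes = None
        if p("assemblies_dir"):
            fasta_by_strain = {
                f.stem: f for f in sorted(Path(p("assemblies_dir")).glob("*.fasta"))
            }
            genomes = io.read_genomes(fasta_by_strain)
        replicate_trait = None
        if p("replicate_biomass"):
            replicate_trait = pd.read_csv(p("replicate_biomass"), dtype={"strain_id": str})
    except StageError:
        raise
    except Exception as err:
        raise StageError("data_io", err) from err

    return run_pipeline_from_data(
        counts, sheet, phenotypes, annotation=annotation, host_counts=host_counts,
        gene_groups=gene_groups, gene_seqs=gene_seqs, genomes=genomes,
        replicate_trait=replicate_trait, config=config,
        trait_name=inputs.get("trait_name", "shoot_biomass"), out_dir=out_dir,
    )


# ---------------------------------------------------------------------------
# evaluation against planted truth

def adjusted_rand_index(labels_a, labels_b) -> float:
    """ARI by the closed-form pair-counting formula."""
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    ct = pd.crosstab(a, b).to_numpy()
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(ct).sum()
    sum_a = comb(ct.sum(axis=1)).sum()
    sum_b = comb(ct.sum(axis=0)).sum()
    n_pairs = comb(len(a))
    expected = sum_a * sum_b / n_pairs if n_pairs else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0 if sum_ij == expected else 0.0
    return float((sum_ij - expected) / (max_index - expected))


def _jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b) if a | b else 1.0


@dataclass
class EvaluationReport:
    presence_accuracy: float
    cluster_recall: float
    cluster_precision: float
    cluster_jaccard: dict  # planted trait-linked cluster name -> best Jaccard
    module_ari: dict  # organism -> ARI over that organism's network genes
    trait_gene_precision: float
    trait_gene_recall: float

    def to_dict(self) -> dict:
        return {
            "presence_accuracy": self.presence_accuracy,
            "cluster_recall": self.cluster_recall,
            "cluster_precision": self.cluster_precision,
            "cluster_jaccard": self.cluster_jaccard,
            "module_ari": self.module_ari,
            "trait_gene_precision": self.trait_gene_precision,
            "trait_gene_recall": self.trait_gene_recall,
        }


def evaluate_against_truth(res: PipelineResult, truth) -> EvaluationReport:
    """Score a pipeline run against the generator's ground truth."""
    if res.expression_presence is None:
        raise ValueError("pipeline result carries no presence calls")
    pred = res.expression_presence
    true = truth.presence.loc[pred.index, pred.columns]
    accuracy = float((pred.to_numpy() == true.to_numpy()).mean())

    planted = [cl for cl in truth.clusters if cl["effect"] != 0]
    detected = [set(c.genes) for c in res.clusters]
    jaccards = {}
    for cl in planted:
        jaccards[cl["name"]] = max(
            (_jaccard(cl["genes"], d) for d in detected), default=0.0)
    recall = (float(np.mean([j >= 0.5 for j in jaccards.values()]))
              if jaccards else float("nan"))
    if detected:
        all_planted = [set(cl["genes"]) for cl in truth.clusters]
        precision = float(np.mean([
            max((_jaccard(d, p) for p in all_planted), default=0.0) >= 0.5
            for d in detected]))
    else:
        precision = float("nan")

    module_ari = {}
    for organism, net in (("symbiont", res.symbiont_network), ("host", res.host_network)):
        if net is None or organism not in truth.module_membership:
            continue
        genes = net.genes
        true_labels = truth.module_membership[organism].reindex(genes).fillna("")
        pred_labels = net.assignment.reindex(genes).fillna(network.UNASSIGNED)
        module_ari[organism] = adjusted_rand_index(true_labels, pred_labels)

    true_trait_genes = {g for cl in planted for g in cl["genes"]}
    called = (set(res.gene_trait.loc[res.gene_trait["significant"], "unit_id"])
              if res.gene_trait is not None else set())
    tp = len(called & true_trait_genes)
    trait_precision = tp / len(called) if called else float("nan")
    trait_recall = tp / len(true_trait_genes) if true_trait_genes else float("nan")

    return EvaluationReport(
        presence_accuracy=accuracy,
        cluster_recall=recall,
        cluster_precision=precision,
        cluster_jaccard=jaccards,
        module_ari=module_ari,
        trait_gene_precision=trait_precision,
        trait_gene_recall=trait_recall,
    )


def run_on_dataset(ds: Dataset, config: AnalysisConfig | None = None,
                   out_dir=None, with_sequences: bool = True) -> PipelineResult:
    """Convenience wrapper: run the full pipeline on a simulated dataset."""
    return run_pipeline_from_data(
        ds.symbiont_counts, ds.sample_sheet, ds.phenotypes,
        annotation=ds.annotation, host_counts=ds.host_counts,
        gene_groups=ds.groups,
        gene_seqs=ds.gene_seqs if with_sequences and ds.gene_seqs else None,
        genomes=ds.genomes if with_sequences and ds.genomes else None,
        replicate_trait=ds.replicate_biomass, config=config, out_dir=out_dir,
    )
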