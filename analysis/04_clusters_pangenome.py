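#!/usr/bin/env python
"""Syntenic clusters of confirmed PAV genes and the pangenome partition.

Chains the sequence-confirmed trait-associated genes into syntenic clusters
(inter-feature gap <= 3 kb), tests each cluster's presence pattern against
shoot biomass with an independent t test, and partitions all gene groups into
core (> 99% of strains) / shell (15-95%) / cloud (< 15%) per replicon.
"""

import argparse
from pathlib import Path

from pavcoex import io, synteny
from pavcoex.config import AnalysisConfig


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/dataset"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    cfg = AnalysisConfig()

    annotation = io.read_annotation(args.data / "reference_annotation.gff3")
    confirmed = (args.out / "confirmed_genes.txt").read_text().split()
    presence = io.read_presence_matrix(args.out / "expression_presence.tsv")
    phenotypes = io.read_phenotypes(args.data / "phenotypes.csv")

    clusters, singletons = synteny.detect_clusters(
        annotation, confirmed, gap=cfg.cluster_gap_bp)
    print(f"{len(confirmed)} confirmed genes -> {len(clusters)} syntenic "
          f"clusters + {len(singletons)} singletons")
    for cl in clusters:
        print(f"  {cl.cluster_id}: {cl.size} genes on {cl.replicon_id}, "
              f"span {cl.span} bp")

    cl_presence = synteny.cluster_presence(clusters, presence,
                                           rule=cfg.cluster_presence_rule)
    tests = synteny.cluster_trait_ttest(cl_presence, phenotypes["shoot_biomass"],
                                        welch=cfg.welch_ttest)
    for row in tests.itertuples(index=False):
        if not row.undefined:
            print(f"  {row.unit_id}: carriers {row.mean_present:.3f} g vs "
                  f"non-carriers {row.mean_absent:.3f} g "
                  f"(t = {row.stat:.2f}, p = {row.p:.2g})")

    groups = io.read_gene_groups(args.data / "gene_groups.tsv")
    group_presence = (groups.assign(present=True)
                      .pivot_table(index="group_id", columns="strain_id",
                                   values="present", aggfunc="any",
                                   fill_value=False))
    classes, summary = synteny.classify_pangenome(
        group_presence, cfg,
        replicon_of=annotation.set_index("gene_id")["replicon_id"])
    print("pangenome partition (fraction of gene groups):")
    print(summary.round(3).to_string())

    tests.to_csv(args.out / "cluster_trait_tests.tsv", sep="\t", index=False)
    io.write_presence_matrix(cl_presence, args.out / "cluster_presence.tsv")
    classes.to_csv(args.out / "pangenome_classes.tsv", sep="\t")
    summary.to_csv(args.out / "pangenome_summary.tsv", sep="\t")
    print(f"tables written under {args.out}")


if __name__ == "__main__":
    main()
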